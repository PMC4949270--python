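"""Vote maps, confidence partitioning, and the majority-vote baseline.

Given J candidate segmentations with weights w^j, the per-voxel vote map

    v(x) = sum_j w^j L^j(x) / sum_j w^j

is the weighted fraction of candidates voting "structure", interpreted as
P(L(x) = 1). The grid is then split into a high-confidence set S_H, where
one class wins by a clear margin, and a low-confidence set S_L, which the
walk inference later refines:

    HIGH_FG  iff  v(x)     > LT1     (confident structure)
    HIGH_BG  iff  1 - v(x) > LT0     (confident background)
    LOW      otherwise

LT0 and LT1 are class-specific confidence thresholds in [0.5, 1]; the
defaults (0.8, 0.6) are deliberately asymmetric (background consensus is
cheaper to come by than structure consensus near a thin boundary). At
LT0 = LT1 = 0.5 the low-confidence set is empty and fusion degenerates to
plain majority vote.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .volumes import CandidateLabelSet, LabelVolume, as_array

__all__ = [
    "Category",
    "VoteMap",
    "Partition",
    "compute_vote_map",
    "majority_vote",
    "partition",
    "compute_rho",
]

TIE_POLICIES = ("background", "foreground")


class Category(IntEnum):
    """Per-voxel confidence class."""

    HIGH_BG = 0
    HIGH_FG = 1
    LOW = 2


@dataclass
class VoteMap:
    """Per-voxel probability of the structure label, v(x) = P(L(x)=1)."""

    v: np.ndarray

    def __post_init__(self):
        self.v = np.asarray(self.v, dtype=float)
        if self.v.ndim != 3:
            raise ValueError("vote map must be 3-D")
        if (self.v < 0).any() or (self.v > 1).any():
            raise ValueError("vote map values must lie in [0, 1]")

    @property
    def shape(self) -> tuple:
        return self.v.shape


@dataclass
class Partition:
    """Assignment of every voxel to HIGH_BG, HIGH_FG, or LOW."""

    category: np.ndarray
    lt0: float
    lt1: float

    @property
    def shape(self) -> tuple:
        return self.category.shape

    @property
    def low_mask(self) -> np.ndarray:
        return self.category == Category.LOW

    @property
    def high_mask(self) -> np.ndarray:
        return self.category != Category.LOW

    def counts(self) -> dict:
        cat = self.category
        return {
            "high_bg": int((cat == Category.HIGH_BG).sum()),
            "high_fg": int((cat == Category.HIGH_FG).sum()),
            "low": int((cat == Category.LOW).sum()),
        }


def compute_vote_map(candidates: CandidateLabelSet) -> VoteMap:
    """Weighted, voxel-wise normalized label-vote distribution."""
    w = candidates.weights
    acc = np.zeros(candidates.shape, dtype=float)
    for wj, lab in zip(w, candidates.labels):
        if wj != 0.0:
            acc += wj * lab.data
    return VoteMap(acc / w.sum())


def _check_tie_policy(tie_policy: str) -> None:
    if tie_policy not in TIE_POLICIES:
        raise ValueError(f"tie_policy must be one of {TIE_POLICIES}, got {tie_policy!r}")


def majority_vote(votes: VoteMap, tie_policy: str = "background") -> LabelVolume:
    """Fuse by per-voxel plurality: 1 where v > 0.5, 0 where v < 0.5.

    Exact ties (v == 0.5, possible with an even number of uniform-weight
    candidates) are resolved deterministically by ``tie_policy``; arbitrary
    tie-breaking is a known source of bias in vote fusion, so the policy is
    explicit and conservative by default.
    """
    _check_tie_policy(tie_policy)
    v = votes.v if isinstance(votes, VoteMap) else np.asarray(votes, dtype=float)
    out = (v > 0.5).astype(np.uint8)
    if tie_policy == "foreground":
        out[v == 0.5] = 1
    return LabelVolume(out)


def partition(
    votes: VoteMap,
    lt0: float = 0.8,
    lt1: float = 0.6,
    tie_policy: str = "background",
) -> Partition:
    """Split the grid into high- and low-confidence sets by vote thresholds.

    Comparisons are strict: HIGH_FG iff v > lt1, HIGH_BG iff (1-v) > lt0.
    A voxel at an exact vote tie (v == 0.5) is claimed by the majority-vote
    tie class only when the corresponding threshold is exactly 0.5 — that is
    the degenerate setting in which the low-confidence set must collapse to
    the empty set and fusion must reproduce majority vote verbatim. For any
    threshold above 0.5 tie voxels remain LOW, as the strict inequalities
    dictate.
    """
    _check_tie_policy(tie_policy)
    if not (0.5 <= lt0 <= 1.0) or not (0.5 <= lt1 <= 1.0):
        raise ValueError(f"thresholds must lie in [0.5, 1], got lt0={lt0}, lt1={lt1}")
    v = votes.v if isinstance(votes, VoteMap) else np.asarray(votes, dtype=float)
    cat = np.full(v.shape, Category.LOW, dtype=np.int8)
    cat[(1.0 - v) > lt0] = Category.HIGH_BG
    cat[v > lt1] = Category.HIGH_FG
    if tie_policy == "background" and lt0 == 0.5:
        cat[v == 0.5] = Category.HIGH_BG
    elif tie_policy == "foreground" and lt1 == 0.5:
        cat[v == 0.5] = Category.HIGH_FG
    return Partition(cat, float(lt0), float(lt1))


def compute_rho(part: Partition, fused_baseline) -> float:
    """Threshold-screening ratio rho = |S_L| / |{x : L(x) = 1}|.

    The denominator counts structure voxels of the baseline majority-vote
    labeling. Heuristically useful threshold pairs put rho in (0.5, 1):
    rho near 0 means the thresholds leave almost nothing to refine, rho
    above 1 means more voxels are in doubt than the structure itself holds.
    """
    baseline = as_array(fused_baseline)
    if baseline.shape != part.shape:
        raise ValueError(f"shape mismatch: {baseline.shape} vs {part.shape}")
    n_struct = int((baseline == 1).sum())
    if n_struct == 0:
        raise ValueError("rho is undefined: baseline labeling has no structure voxels")
    return float(part.low_mask.sum()) / n_struct
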