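"""End-to-end label fusion estimators and functional wrappers.

:class:`WalkFusion` is the full pipeline — vote map, confidence partition,
patch construction, per-patch Gaussian fits, MST walks — exposed as a
scikit-learn-style estimator: configure it, call ``fit(image, candidates)``,
and read the fused segmentation off ``labels_`` and diagnostics off
``report_``. :class:`MajorityVoteFusion` is the plurality baseline in the
same shape. The module-level :func:`fuse` / :func:`evaluate` functions are
thin wrappers for script use.

The pipeline is deterministic end to end: identical inputs and parameters
produce byte-identical label volumes. High-confidence voxels are never
relabeled; low-confidence voxels outside every patch, or disconnected from
their patch's seed, keep the majority-vote label.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import mrf, patching, voting, walks
from .volumes import CandidateLabelSet, IntensityVolume, LabelVolume, as_array, dice

__all__ = [
    "PRESETS",
    "MajorityVoteFusion",
    "WalkFusion",
    "fuse",
    "evaluate",
    "count_discordant_pairs",
]

# Named threshold presets. "default" suits adult T1 contrast; "neonate"
# uses the symmetric thresholds appropriate when the structure/background
# contrast is reversed and weaker (unmyelinated tissue).
PRESETS = {
    "default": {"lt0": 0.8, "lt1": 0.6},
    "neonate": {"lt0": 0.7, "lt1": 0.7},
}


def _coerce_candidates(candidates, weights=None) -> CandidateLabelSet:
    if isinstance(candidates, CandidateLabelSet):
        if weights is not None:
            return CandidateLabelSet(candidates.labels, weights)
        return candidates
    return CandidateLabelSet(list(candidates), weights)


class MajorityVoteFusion(BaseEstimator):
    """Plurality-vote label fusion baseline.

    Parameters
    ----------
    tie_policy : {"background", "foreground"}
        Deterministic resolution of exact vote ties (v == 0.5).

    Attributes
    ----------
    labels_ : ndarray of uint8
        The fused segmentation.
    vote_map_ : ndarray
        The per-voxel weighted vote fraction.
    """

    def __init__(self, tie_policy: str = "background"):
        self.tie_policy = tie_policy

    def fit(self, image, candidates, weights=None):
        cands = _coerce_candidates(candidates, weights)
        if image is not None and as_array(image).shape != cands.shape:
            raise ValueError("image and candidate grids differ")
        votes = voting.compute_vote_map(cands)
        self.vote_map_ = votes.v
        self.labels_ = voting.majority_vote(votes, self.tie_policy).data
        return self


class WalkFusion(BaseEstimator):
    """Label fusion with patch-local MRFs and spanning-tree walks.

    Refines the low-confidence voxels of a candidate-label ensemble by
    sequential conditional-MAP updates along intensity-guided minimum
    spanning trees; high-confidence voxels keep their consensus labels.

    Parameters
    ----------
    lt0, lt1 : float in [0.5, 1]
        Confidence thresholds for background and structure. At (0.5, 0.5)
        the output is exactly the majority vote.
    patch_length : odd int
        Side of the cubic patches, in voxels.
    mixing_ratio : float in (0, 1)
        Minimum high-confidence fraction required around a seed, scaled to
        the patch volume; (0.0075, 11) means at least 10 high-confidence
        voxels among the seed's 26 neighbors.
    lam : float >= 0
        Smoothness coupling of the MRF pairwise potential; 0 decouples
        neighbors (pure intensity classification of low voxels).
    tie_policy : {"background", "foreground"}
        Vote-tie resolution, shared with the baseline initialization.
    epsilon_sigma : float, optional
        Floor on fitted intensity standard deviations; defaults to 1e-3 of
        the image intensity range.
    n_min : int
        Minimum in-patch samples per class before the Gaussian fit falls
        back to whole-volume high-confidence statistics.

    Attributes
    ----------
    labels_ : ndarray of uint8
        The fused segmentation.
    report_ : dict
        Stage diagnostics: partition counts, rho, patch count, coverage,
        per-patch energies before/after the walk.
    vote_map_ : ndarray
    partition_ : voting.Partition
    """

    def __init__(
        self,
        lt0: float = 0.8,
        lt1: float = 0.6,
        patch_length: int = 11,
        mixing_ratio: float = 0.0075,
        lam: float = 0.2,
        tie_policy: str = "background",
        epsilon_sigma: float = None,
        n_min: int = 5,
    ):
        self.lt0 = lt0
        self.lt1 = lt1
        self.patch_length = patch_length
        self.mixing_ratio = mixing_ratio
        self.lam = lam
        self.tie_policy = tie_policy
        self.epsilon_sigma = epsilon_sigma
        self.n_min = n_min

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "WalkFusion":
        if name not in PRESETS:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
        params = dict(PRESETS[name])
        params.update(overrides)
        return cls(**params)

    def fit(self, image, candidates, weights=None):
        img = as_array(image)
        cands = _coerce_candidates(candidates, weights)
        if img.shape != cands.shape:
            raise ValueError(
                f"image grid {img.shape} does not match candidate grid {cands.shape}"
            )

        votes = voting.compute_vote_map(cands)
        baseline = voting.majority_vote(votes, self.tie_policy).data
        part = voting.partition(votes, self.lt0, self.lt1, self.tie_policy)
        out = baseline.copy()

        report = {
            **part.counts(),
            "n_candidates": cands.J,
            "lt0": self.lt0,
            "lt1": self.lt1,
        }
        n_struct = int((baseline == 1).sum())
        report["rho"] = (
            voting.compute_rho(part, baseline) if n_struct > 0 else float("nan")
        )

        n_low = report["low"]
        patch_reports = []
        if n_low > 0:
            seeds = patching.select_seeds(part, self.mixing_ratio, self.patch_length)
            result = patching.build_patches(part, seeds, self.patch_length)
            report["n_patches"] = len(result.patches)
            report["n_unreachable"] = len(result.unreachable)
            report["coverage"] = result.coverage()
            for pid, patch in enumerate(result.patches):
                g = mrf.estimate_gaussians(
                    patch, img, part, n_min=self.n_min, eps_sigma=self.epsilon_sigma
                )
                graph = mrf.PatchGraph(patch, img, part)
                init = graph.initial_configuration(baseline)
                tree = walks.build_mst(patch, img)
                e_before = mrf.total_energy(init, graph, g, self.lam)
                cfg = walks.walk_update(tree, graph, init, g, self.lam)
                e_after = mrf.total_energy(cfg, graph, g, self.lam)
                # only walked voxels change; disconnected LOW members keep
                # the baseline label already present in `out`
                for v in tree.order:
                    out[v] = cfg[v]
                patch_reports.append(
                    {
                        "patch": pid,
                        "seed": tuple(int(c) for c in patch.seed),
                        "n_low": int(len(patch.members_low)),
                        "n_walked": len(tree.order),
                        "energy_before": e_before,
                        "energy_after": e_after,
                    }
                )
        else:
            report["n_patches"] = 0
            report["n_unreachable"] = 0
            report["coverage"] = 1.0
        report["patches"] = patch_reports

        self.vote_map_ = votes.v
        self.partition_ = part
        self.labels_ = out.astype(np.uint8)
        self.report_ = report
        return self


def fuse(image, candidates, weights=None, preset: str = None, **params):
    """Run walk fusion and return ``(labels, report)``.

    ``preset`` selects a named threshold pair from :data:`PRESETS`;
    explicit keyword parameters override it.
    """
    if preset is not None:
        base = dict(PRESETS[preset]) if preset in PRESETS else None
        if base is None:
            raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
        base.update(params)
        params = base
    est = WalkFusion(**params).fit(image, candidates, weights)
    return est.labels_, est.report_


def evaluate(fused, reference, spacing=(1.0, 1.0, 1.0)) -> dict:
    """Overlap and volumetry of a fused segmentation against a reference.

    Reports the Dice coefficient, foreground volumes in voxels and mm^3,
    and the signed volume difference (reference minus automatic: positive
    means the automatic segmentation underestimates).
    """
    f = as_array(fused)
    r = as_array(reference)
    if f.shape != r.shape:
        raise ValueError(f"shape mismatch: {f.shape} vs {r.shape}")
    if isinstance(fused, (LabelVolume, IntensityVolume)):
        spacing = fused.spacing
    vox_mm3 = float(np.prod(spacing))
    nf, nr = int((f == 1).sum()), int((r == 1).sum())
    return {
        "dice": dice(f, r),
        "fused_voxels": nf,
        "reference_voxels": nr,
        "fused_mm3": nf * vox_mm3,
        "reference_mm3": nr * vox_mm3,
        "volume_difference_voxels": nr - nf,
        "volume_difference_mm3": (nr - nf) * vox_mm3,
    }


def count_discordant_pairs(labels) -> int:
    """Number of 6-adjacent voxel pairs with unequal labels (each unordered
    pair counted once) — a homogeneity diagnostic of a segmentation."""
    lab = as_array(labels)
    n = 0
    for axis in range(3):
        a = np.moveaxis(lab, axis, 0)
        n += int((a[1:] != a[:-1]).sum())
    return n
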