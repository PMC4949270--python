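"""Seed selection and cubic patch construction over the low-confidence set.

Low-confidence voxels are ranked by how many high-confidence voxels sit in
their 26-connected neighborhood; those meeting a minimum count become patch
seeds, and cubic patches of odd side L_patch are grown around them in rank
order. The count threshold is the "mixing ratio" scaled to the patch
volume, ceil(mixing_ratio * L_patch^3); with the defaults (0.0075, 11) this
is exactly a minimum of 10 high-confidence neighbors.

Cubes may overlap: a LOW voxel covered by several cubes belongs to the
patch whose seed is nearest (Euclidean, in voxel units), with the earlier
seed in processing order keeping equidistant voxels. LOW voxels covered by
no cube are "unreachable" and later keep their majority-vote label. The
result is a disjoint tiling: patch LOW memberships plus unreachable voxels
reproduce S_L exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .voting import Category, Partition

__all__ = [
    "Patch",
    "PatchingResult",
    "count_high_neighbors",
    "seed_count_threshold",
    "select_seeds",
    "build_patches",
]


@dataclass
class Patch:
    """A seeded cubic subvolume hosting one localized MRF.

    ``members_low`` are the LOW voxels owned by this patch after overlap
    resolution (the seed is always among them); ``members_high`` are all
    high-confidence voxels inside the (grid-clipped) cube, used both as
    Gaussian training data and as fixed boundary labels for the MRF.
    """

    seed: tuple
    length: int
    members_low: np.ndarray  # (n, 3) int voxel indices
    members_high: np.ndarray  # (m, 3) int voxel indices


@dataclass
class PatchingResult:
    patches: list
    unreachable: np.ndarray  # (k, 3) int voxel indices

    def n_low_covered(self) -> int:
        return sum(len(p.members_low) for p in self.patches)

    def coverage(self) -> float:
        """Fraction of S_L covered by patches (1.0 when nothing is unreachable)."""
        covered = self.n_low_covered()
        total = covered + len(self.unreachable)
        return covered / total if total else 1.0


def count_high_neighbors(part: Partition) -> np.ndarray:
    """Count of S_H voxels among each voxel's 26-connected neighbors.

    Neighbors outside the grid contribute 0, so corner voxels max out at 7
    and face voxels at 17.
    """
    high = (part.category != Category.LOW).astype(np.int32)
    kernel = np.ones((3, 3, 3), dtype=np.int32)
    kernel[1, 1, 1] = 0
    return ndimage.convolve(high, kernel, mode="constant", cval=0)


def seed_count_threshold(mixing_ratio: float, length: int) -> int:
    """Minimum S_H neighbor count for a seed: ceil(mixing_ratio * length^3)."""
    return int(math.ceil(mixing_ratio * length**3))


def _check_length(length: int) -> None:
    if length < 3 or length % 2 == 0:
        raise ValueError(f"patch length must be odd and >= 3, got {length}")


def select_seeds(
    part: Partition, mixing_ratio: float = 0.0075, length: int = 11
) -> np.ndarray:
    """Rank LOW voxels by S_H neighbor count and return the eligible seeds.

    Returns an ordered (K, 3) array of voxel indices: count descending,
    ties broken by lexicographic voxel index so the ordering is fully
    deterministic. May be empty.
    """
    if not (0.0 < mixing_ratio < 1.0):
        raise ValueError(f"mixing_ratio must be in (0, 1), got {mixing_ratio}")
    _check_length(length)
    counts = count_high_neighbors(part)
    low = np.argwhere(part.category == Category.LOW)
    if len(low) == 0:
        return low.reshape(0, 3)
    c = counts[low[:, 0], low[:, 1], low[:, 2]]
    thr = seed_count_threshold(mixing_ratio, length)
    keep = c >= thr
    low, c = low[keep], c[keep]
    # lexsort: last key is primary -> (-count, i, j, k)
    order = np.lexsort((low[:, 2], low[:, 1], low[:, 0], -c))
    return low[order]


def build_patches(part: Partition, seeds: np.ndarray, length: int) -> PatchingResult:
    """Grow cubic patches around seeds, in seed order, resolving overlaps.

    A voxel already owned by an earlier patch is skipped as a seed (a
    static sorted pass with a skip rule; this bounds the patch count and
    avoids near-duplicate cubes). Ownership of a contested LOW voxel goes
    to the nearest competing seed, earlier seed winning ties.
    """
    _check_length(length)
    cat = part.category
    shape = cat.shape
    seeds = np.asarray(seeds, dtype=int).reshape(-1, 3)
    for s in seeds:
        if cat[tuple(s)] != Category.LOW:
            raise ValueError(f"seed {tuple(s)} is not a low-confidence voxel")

    owner = np.full(shape, -1, dtype=np.int32)
    accepted: list = []  # seed coordinate per patch id
    half = length // 2

    def cube_slices(s):
        return tuple(
            slice(max(0, s[a] - half), min(shape[a], s[a] + half + 1)) for a in range(3)
        )

    for s in seeds:
        st = tuple(s)
        if owner[st] != -1:
            continue
        pid = len(accepted)
        accepted.append(st)
        sl = cube_slices(s)
        local_low = np.argwhere(cat[sl] == Category.LOW)
        coords = local_low + np.array([sl[0].start, sl[1].start, sl[2].start])
        cur = owner[coords[:, 0], coords[:, 1], coords[:, 2]]
        take = cur == -1
        if not take.all():
            contested = ~take
            d_new = ((coords[contested] - s) ** 2).sum(axis=1)
            prev_seeds = np.asarray(accepted)[cur[contested]]
            d_old = ((coords[contested] - prev_seeds) ** 2).sum(axis=1)
            steal = d_new < d_old  # equidistant stays with the earlier seed
            take[np.flatnonzero(contested)[steal]] = True
        tc = coords[take]
        owner[tc[:, 0], tc[:, 1], tc[:, 2]] = pid

    patches = []
    low_all = np.argwhere(cat == Category.LOW)
    owners_all = owner[low_all[:, 0], low_all[:, 1], low_all[:, 2]]
    for pid, st in enumerate(accepted):
        members_low = low_all[owners_all == pid]
        sl = cube_slices(np.asarray(st))
        local_high = np.argwhere(cat[sl] != Category.LOW)
        members_high = local_high + np.array([sl[0].start, sl[1].start, sl[2].start])
        patches.append(Patch(st, length, members_low, members_high))
    unreachable = low_all[owners_all == -1]
    return PatchingResult(patches, unreachable)
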