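"""Patch-local Markov random field: Gaussian intensity model and energies.

Each patch carries a binary MRF over its voxels (the owned low-confidence
voxels plus the high-confidence voxels inside the cube, whose labels stay
fixed). With 6-connectivity the cliques are singletons and adjacent pairs,
and the total energy of a label configuration y is

    U(y) = sum_i  V1(y_i)  +  sum_{(i,j)}  V2(y_i, y_j)

with the singleton potential the Gaussian negative log-likelihood of the
voxel intensity given its label,

    V1(y_i) = 1/2 log(2 pi sigma_{y_i}^2) + (f_i - mu_{y_i})^2 / (2 sigma_{y_i}^2),

so that minimizing U is MAP estimation, and the pairwise (doubleton)
potential an Ising-style smoothness term

    V2(y_i, y_j) = -lam  if y_i == y_j,   +lam  otherwise,   lam >= 0.

The class-conditional (mu, sigma) are estimated per patch from the
high-confidence voxels of that class inside the cube — the local "training
set" — mimicking a manual rater who reads intensity statistics off the
immediate neighborhood rather than off an atlas library. Pairs crossing
the patch boundary are not part of the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .patching import Patch
from .volumes import as_array
from .voting import Category, Partition

__all__ = [
    "GaussianParams",
    "PatchGraph",
    "default_sigma_floor",
    "estimate_gaussians",
    "singleton_potential",
    "pairwise_potential",
    "total_energy",
    "conditional_energy",
]

_OFFSETS6 = ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1))


@dataclass
class GaussianParams:
    """Class-conditional intensity model: N(mu0, sigma0^2) for background,
    N(mu1, sigma1^2) for structure."""

    mu0: float
    sigma0: float
    mu1: float
    sigma1: float

    def __post_init__(self):
        vals = (self.mu0, self.sigma0, self.mu1, self.sigma1)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"non-finite Gaussian parameters: {vals}")
        if self.sigma0 <= 0 or self.sigma1 <= 0:
            raise ValueError("sigmas must be positive")

    def mu(self, y: int) -> float:
        return self.mu1 if y else self.mu0

    def sigma(self, y: int) -> float:
        return self.sigma1 if y else self.sigma0


def default_sigma_floor(image) -> float:
    """Sigma floor guarding degenerate fits: 1e-3 of the intensity range."""
    img = as_array(image)
    rng = float(img.max() - img.min())
    return 1e-3 * rng if rng > 0 else 1e-3


def estimate_gaussians(
    patch: Patch,
    image,
    part: Partition,
    n_min: int = 5,
    eps_sigma: float = None,
) -> GaussianParams:
    """Fit per-class (mu, sigma) from the patch's high-confidence voxels.

    A class with fewer than ``n_min`` high-confidence samples inside the
    cube falls back to the whole-volume high-confidence statistics for that
    class (small boundary patches routinely contain only one class). A
    class with zero high-confidence voxels anywhere in the volume is an
    error — there is then no training data at all for that label. Sample
    standard deviations are floored at ``eps_sigma``.
    """
    img = as_array(image)
    cat = part.category
    if eps_sigma is None:
        eps_sigma = default_sigma_floor(img)
    mh = patch.members_high
    cat_in = cat[mh[:, 0], mh[:, 1], mh[:, 2]] if len(mh) else np.empty(0, dtype=np.int8)
    vals_in = img[mh[:, 0], mh[:, 1], mh[:, 2]] if len(mh) else np.empty(0)

    out = {}
    for y, hc in ((0, Category.HIGH_BG), (1, Category.HIGH_FG)):
        samples = vals_in[cat_in == hc]
        if len(samples) < n_min:
            samples = img[cat == hc]
        if len(samples) == 0:
            raise ValueError(
                f"no high-confidence voxels of class {y} anywhere in the volume"
            )
        mu = float(samples.mean())
        sd = float(samples.std(ddof=1)) if len(samples) > 1 else 0.0
        out[y] = (mu, max(sd, float(eps_sigma)))
    return GaussianParams(out[0][0], out[0][1], out[1][0], out[1][1])


def singleton_potential(f, y: int, g: GaussianParams):
    """Gaussian negative log-likelihood of intensity ``f`` under label ``y``.

    exp(-V1) is a normalized density in f, and lower energy means a better
    intensity fit, so minimizing the total energy is MAP labeling.
    """
    mu, sigma = g.mu(y), g.sigma(y)
    return 0.5 * np.log(2.0 * math.pi * sigma**2) + (f - mu) ** 2 / (2.0 * sigma**2)


def pairwise_potential(yi: int, yj: int, lam: float) -> float:
    """Ising smoothness: -lam for equal neighbor labels, +lam for unequal."""
    if lam < 0:
        raise ValueError("smoothness coefficient must be non-negative")
    return -lam if yi == yj else lam


class PatchGraph:
    """The 6-connected node graph of one patch's MRF.

    Nodes are the patch's owned LOW voxels plus the high-confidence voxels
    in the cube; high nodes carry fixed labels (1 for HIGH_FG, 0 for
    HIGH_BG). Label configurations are plain dicts mapping voxel index
    tuples to {0, 1} and must cover every node.
    """

    def __init__(self, patch: Patch, image, part: Partition):
        img = as_array(image)
        cat = part.category
        low = [tuple(v) for v in np.asarray(patch.members_low, dtype=int)]
        high = [tuple(v) for v in np.asarray(patch.members_high, dtype=int)]
        self.patch = patch
        self.low_nodes = low
        self.high_nodes = high
        self.nodes = low + high
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("patch LOW and HIGH member sets overlap")
        self.intensity = {n: float(img[n]) for n in self.nodes}
        self.fixed_label = {
            n: int(cat[n] == Category.HIGH_FG) for n in high
        }
        self.neighbors = {
            n: [
                (n[0] + di, n[1] + dj, n[2] + dk)
                for di, dj, dk in _OFFSETS6
                if (n[0] + di, n[1] + dj, n[2] + dk) in node_set
            ]
            for n in self.nodes
        }

    def initial_configuration(self, baseline) -> dict:
        """Start-of-walk labels: fixed labels on high nodes, the baseline
        (majority-vote) label elsewhere."""
        base = as_array(baseline)
        cfg = {n: int(base[n]) for n in self.low_nodes}
        cfg.update(self.fixed_label)
        return cfg

    def _check_cfg(self, cfg: dict) -> None:
        if len(cfg) < len(self.nodes) or any(n not in cfg for n in self.nodes):
            raise ValueError("configuration does not cover all patch nodes")


def total_energy(cfg: dict, graph: PatchGraph, g: GaussianParams, lam: float) -> float:
    """Total MRF energy of a configuration: all singletons plus each
    unordered 6-adjacent node pair once."""
    graph._check_cfg(cfg)
    u = 0.0
    for n in graph.nodes:
        u += float(singleton_potential(graph.intensity[n], cfg[n], g))
        for m in graph.neighbors[n]:
            if m > n:  # count each unordered pair once
                u += pairwise_potential(cfg[n], cfg[m], lam)
    return u


def conditional_energy(
    x: tuple, y: int, cfg: dict, graph: PatchGraph, g: GaussianParams, lam: float
) -> float:
    """Single-site energy of labeling voxel ``x`` as ``y`` given the current
    configuration of its in-patch 6-neighbors (high-confidence neighbors
    contribute their fixed labels through ``cfg``)."""
    x = tuple(x)
    u = float(singleton_potential(graph.intensity[x], y, g))
    for m in graph.neighbors[x]:
        u += pairwise_potential(y, cfg[m], lam)
    return u
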