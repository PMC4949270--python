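"""Shared builders for randomized partitions, patches, and MRF environments."""

import itertools

import numpy as np
import pytest

from walkfuse import patching
from walkfuse.mrf import PatchGraph, estimate_gaussians, total_energy
from walkfuse.voting import Category, Partition


def make_random_partition(rng, shape, p_low=0.35):
    probs = [(1 - p_low) / 2, (1 - p_low) / 2, p_low]
    cat = rng.choice(
        [Category.HIGH_BG, Category.HIGH_FG, Category.LOW], size=shape, p=probs
    ).astype(np.int8)
    return Partition(cat, 0.8, 0.6)


def make_patch_env(rng, shape=(6, 6, 6), p_low=0.4, length=5, max_low=None):
    """A single random patch with an informative two-class intensity field.

    Returns the partition, patch, its MRF graph, fitted Gaussian parameters,
    the image, and a random baseline initialization.
    """
    while True:
        part = make_random_partition(rng, shape, p_low)
        if (part.category == Category.HIGH_BG).sum() < 2:
            continue
        if (part.category == Category.HIGH_FG).sum() < 2:
            continue
        low = np.argwhere(part.category == Category.LOW)
        if len(low) == 0:
            continue
        seed = tuple(int(c) for c in low[rng.integers(len(low))])
        res = patching.build_patches(part, np.array([seed]), length)
        patch = res.patches[0]
        if max_low is not None and len(patch.members_low) > max_low:
            continue
        break
    image = rng.normal(60.0, 10.0, shape)
    image[part.category == Category.HIGH_FG] += 40.0
    g = estimate_gaussians(patch, image, part, n_min=2)
    graph = PatchGraph(patch, image, part)
    baseline = (part.category == Category.HIGH_FG).astype(np.uint8)
    lowmask = part.category == Category.LOW
    baseline[lowmask] = rng.integers(0, 2, int(lowmask.sum()))
    init = graph.initial_configuration(baseline)
    return {
        "part": part,
        "patch": patch,
        "graph": graph,
        "g": g,
        "image": image,
        "baseline": baseline,
        "init": init,
    }


def enumerate_configurations(graph, fixed_extra=None):
    """All label configurations of a graph's LOW nodes (HIGH nodes fixed).

    ``fixed_extra`` optionally pins additional nodes (e.g. LOW voxels a walk
    cannot reach because they are disconnected from the seed).
    """
    fixed_extra = fixed_extra or {}
    low = [n for n in graph.low_nodes if n not in fixed_extra]
    for bits in itertools.product((0, 1), repeat=len(low)):
        cfg = dict(graph.fixed_label)
        cfg.update(fixed_extra)
        cfg.update(zip(low, bits))
        yield cfg


def enumerate_min_energy(graph, g, lam, fixed_extra=None):
    """Exhaustive global minimum energy and the set of minimizing configs."""
    best_u, best = np.inf, []
    for cfg in enumerate_configurations(graph, fixed_extra):
        u = total_energy(cfg, graph, g, lam)
        if u < best_u - 1e-12:
            best_u, best = u, [dict(cfg)]
        elif abs(u - best_u) <= 1e-12:
            best.append(dict(cfg))
    return best_u, best


def graph_discordant_pairs(graph, cfg):
    """Unequal-label 6-adjacent node pairs within one patch graph."""
    n = 0
    for a in graph.nodes:
        for b in graph.neighbors[a]:
            if b > a and cfg[a] != cfg[b]:
                n += 1
    return n


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
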