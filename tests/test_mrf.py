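import itertools
import math

import numpy as np
import pytest
from scipy import integrate

from conftest import (
    enumerate_min_energy,
    graph_discordant_pairs,
    make_patch_env,
)
from walkfuse.mrf import (
    GaussianParams,
    conditional_energy,
    estimate_gaussians,
    pairwise_potential,
    singleton_potential,
    total_energy,
)
from walkfuse.patching import Patch
from walkfuse.voting import Category, Partition


def _env_for_class_stats(fg_values, bg_values):
    """A flat volume whose high-confidence voxels carry the given samples."""
    n_fg, n_bg = len(fg_values), len(bg_values)
    shape = (n_fg + n_bg + 1, 1, 1)
    img = np.zeros(shape)
    cat = np.full(shape, Category.LOW, dtype=np.int8)
    img[:n_fg, 0, 0] = fg_values
    cat[:n_fg] = Category.HIGH_FG
    img[n_fg : n_fg + n_bg, 0, 0] = bg_values
    cat[n_fg : n_fg + n_bg] = Category.HIGH_BG
    part = Partition(cat, 0.8, 0.6)
    members_high = np.argwhere(cat != Category.LOW)
    members_low = np.argwhere(cat == Category.LOW)
    patch = Patch(tuple(members_low[0]), 3, members_low, members_high)
    return patch, img, part


class TestEstimateGaussians:
    def test_sample_moments(self):
        patch, img, part = _env_for_class_stats([10, 12, 14], [0, 2, 4, 6])
        g = estimate_gaussians(patch, img, part, n_min=2)
        assert g.mu1 == pytest.approx(12.0)
        assert g.sigma1 == pytest.approx(2.0)  # sample SD, ddof=1
        assert g.mu0 == pytest.approx(3.0)

    def test_constant_intensities_hit_sigma_floor(self):
        patch, img, part = _env_for_class_stats([5, 5, 5], [1, 1, 1])
        g = estimate_gaussians(patch, img, part, n_min=2, eps_sigma=0.01)
        assert g.sigma0 == 0.01 and g.sigma1 == 0.01

    def test_volume_fallback_recovers_parameters(self, rng):
        # patch with no in-patch background voxels falls back to the
        # volume-wide background statistics: N(40, 5^2) at n = 10^4
        n = 10**4
        shape = (n, 1, 2)
        img = np.zeros(shape)
        cat = np.full(shape, Category.LOW, dtype=np.int8)
        img[:, 0, 0] = rng.normal(40.0, 5.0, n)
        cat[:, 0, 0] = Category.HIGH_BG
        img[:100, 0, 1] = rng.normal(80.0, 3.0, 100)
        cat[:100, 0, 1] = Category.HIGH_FG
        part = Partition(cat, 0.8, 0.6)
        # patch containing only foreground high voxels
        members_high = np.argwhere(cat == Category.HIGH_FG)[:50]
        members_low = np.array([[200, 0, 1]])
        patch = Patch((200, 0, 1), 3, members_low, members_high)
        g = estimate_gaussians(patch, img, part, n_min=5)
        assert g.mu0 == pytest.approx(40.0, abs=3 * 5.0 / math.sqrt(n))
        assert g.sigma0 == pytest.approx(5.0, abs=3 * 5.0 / math.sqrt(2 * n))

    def test_missing_class_everywhere_raises(self):
        shape = (4, 1, 1)
        img = np.zeros(shape)
        cat = np.full(shape, Category.HIGH_FG, dtype=np.int8)
        cat[0] = Category.LOW
        part = Partition(cat, 0.8, 0.6)
        patch = Patch((0, 0, 0), 3, np.array([[0, 0, 0]]), np.argwhere(cat != Category.LOW))
        with pytest.raises(ValueError):
            estimate_gaussians(patch, img, part)


class TestPotentials:
    def test_singleton_analytic_values(self):
        g = GaussianParams(0.0, 1.0, 10.0, 1.0)
        assert singleton_potential(10.0, 1, g) == pytest.approx(0.5 * math.log(2 * math.pi))
        assert singleton_potential(11.0, 1, g) == pytest.approx(
            0.5 * math.log(2 * math.pi) + 0.5
        )

    def test_singleton_is_normalized_density(self):
        g = GaussianParams(40.0, 5.0, 100.0, 12.0)
        for y in (0, 1):
            val, _ = integrate.quad(
                lambda f: math.exp(-singleton_potential(f, y, g)), -400, 600
            )
            assert val == pytest.approx(1.0, abs=1e-6)

    def test_pairwise_signs(self):
        assert pairwise_potential(1, 1, 0.2) == pytest.approx(-0.2)
        assert pairwise_potential(1, 0, 0.2) == pytest.approx(0.2)
        assert pairwise_potential(0, 1, 0.0) == 0.0
        with pytest.raises(ValueError):
            pairwise_potential(0, 0, -0.1)


class TestEnergies:
    def test_matches_independent_clique_enumeration(self, rng):
        # brute-force oracle: list all singleton and unordered adjacent
        # pairs explicitly and sum their potentials
        for _ in range(10):
            env = make_patch_env(rng, shape=(5, 5, 5), length=3)
            graph, g = env["graph"], env["g"]
            cfg = {n: int(rng.integers(0, 2)) for n in graph.low_nodes}
            cfg.update(graph.fixed_label)
            u = total_energy(cfg, graph, g, 0.2)
            nodes = set(graph.nodes)
            expected = sum(
                singleton_potential(graph.intensity[n], cfg[n], g) for n in nodes
            )
            pairs = set()
            for n in nodes:
                for d in itertools.permutations((1, 0, 0)):
                    for sgn in (1, -1):
                        m = tuple(np.add(n, np.multiply(sgn, d)))
                        if m in nodes:
                            pairs.add(frozenset((n, m)))
            for pair in pairs:
                a, b = tuple(pair)
                expected += pairwise_potential(cfg[a], cfg[b], 0.2)
            assert u == pytest.approx(expected)

    def test_flip_delta_equals_conditional_difference(self, rng):
        for _ in range(100):
            env = make_patch_env(rng, shape=(5, 5, 5), length=3)
            graph, g = env["graph"], env["g"]
            lam = float(rng.uniform(0, 1))
            cfg = {n: int(rng.integers(0, 2)) for n in graph.low_nodes}
            cfg.update(graph.fixed_label)
            x = graph.low_nodes[rng.integers(len(graph.low_nodes))]
            old, new = cfg[x], 1 - cfg[x]
            u_old = total_energy(cfg, graph, g, lam)
            flipped = dict(cfg)
            flipped[x] = new
            u_new = total_energy(flipped, graph, g, lam)
            delta = conditional_energy(x, new, cfg, graph, g, lam) - conditional_energy(
                x, old, cfg, graph, g, lam
            )
            assert u_new - u_old == pytest.approx(delta, abs=1e-9)

    def test_global_minimum_homogeneity_monotone_in_lam(self, rng):
        # exhaustive: among global minimizers (fewest discordant pairs on
        # ties), the discordant-pair count never rises with the coupling
        for _ in range(5):
            env = make_patch_env(rng, shape=(4, 4, 4), length=3, max_low=8)
            graph, g = env["graph"], env["g"]
            prev = None
            for lam in (0.0, 0.1, 0.2, 0.5, 1.0):
                _, minima = enumerate_min_energy(graph, g, lam)
                d = min(graph_discordant_pairs(graph, cfg) for cfg in minima)
                if prev is not None:
                    assert d <= prev
                prev = d

    def test_incomplete_configuration_rejected(self, rng):
        env = make_patch_env(rng, shape=(4, 4, 4), length=3)
        graph, g = env["graph"], env["g"]
        cfg = dict(graph.fixed_label)  # low nodes missing
        with pytest.raises(ValueError):
            total_energy(cfg, graph, g, 0.2)
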