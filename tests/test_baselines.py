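"""Tracking baselines (local/global SPT) and the PICS correlation fit."""

import itertools

import numpy as np
import pytest

from pnndiffusion import (FramePair, ParticleFrame, Rect, SimScenario,
                          estimate_D_spt, global_spt_link, local_spt_link,
                          make_pairwise_dataset, mle_D_from_steps,
                          pairwise_frame_pairs, pics_estimate)
from pnndiffusion.baselines import fit_pics_curve, pics_curve


def _pair(pre, post, dt=0.02):
    return FramePair(ParticleFrame(0, np.asarray(pre, dtype=float)),
                     ParticleFrame(1, np.asarray(post, dtype=float)), dt)


def brute_force_min_cost(pre, post):
    """Exhaustive minimum total squared displacement over one-to-one
    assignments of min(n, m) particles."""
    n, m = len(pre), len(post)
    pre, post = np.asarray(pre), np.asarray(post)
    best = np.inf
    if n <= m:
        for perm in itertools.permutations(range(m), n):
            cost = sum(np.sum((pre[i] - post[j]) ** 2)
                       for i, j in enumerate(perm))
            best = min(best, cost)
    else:
        for perm in itertools.permutations(range(n), m):
            cost = sum(np.sum((pre[i] - post[j]) ** 2)
                       for j, i in enumerate(perm))
            best = min(best, cost)
    return best


class TestLocalLinking:
    def test_shared_target_allowed(self):
        links = local_spt_link(_pair([[0, 0], [10, 0]], [[1, 0]]))
        assert links["post_index"].tolist() == [0, 0]
        assert links["distance"].tolist() == [1.0, 9.0]

    def test_well_separated_pairs_link_perfectly(self):
        pre = [[0, 0], [10, 0], [0, 10]]
        post = [[0.1, 0], [10, 0.1], [0.1, 10]]
        links = local_spt_link(_pair(pre, post))
        assert links["post_index"].tolist() == [0, 1, 2]


class TestGlobalLinking:
    def test_crossing_configuration_resolved(self):
        # greedy nearest pairing would cross; the optimal matching does not
        links = global_spt_link(_pair([[0, 0], [2, 0]], [[1.1, 0], [-0.9, 0]]))
        mapping = dict(zip(links["pre_index"], links["post_index"]))
        assert mapping == {0: 1, 1: 0}

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("shape", [(5, 5), (7, 7), (6, 4), (3, 7)])
    def test_matches_brute_force_optimum(self, seed, shape):
        rng = np.random.default_rng(seed)
        pre = rng.uniform(0, 3, (shape[0], 2))
        post = rng.uniform(0, 3, (shape[1], 2))
        links = global_spt_link(_pair(pre, post))
        assert len(links) == min(shape)
        cost = float(np.sum(links["distance"] ** 2))
        assert cost == pytest.approx(brute_force_min_cost(pre, post), rel=1e-12)

    def test_one_to_one(self, rng):
        pre = rng.uniform(0, 5, (20, 2))
        post = rng.uniform(0, 5, (25, 2))
        links = global_spt_link(_pair(pre, post))
        assert links["pre_index"].is_unique and links["post_index"].is_unique

    def test_max_distance_cap(self):
        links = global_spt_link(_pair([[0, 0]], [[5, 0]]), max_distance=1.0)
        assert len(links) == 0
        links = global_spt_link(_pair([[0, 0]], [[5, 0]]), max_distance=6.0)
        assert len(links) == 1


class TestStepMLE:
    def test_single_step_inversion(self):
        assert mle_D_from_steps([np.sqrt(0.08)], 0.02) == pytest.approx(1.0)

    def test_zero_steps(self):
        assert mle_D_from_steps([0.0, 0.0], 0.02) == 0.0
        with pytest.raises(ValueError):
            mle_D_from_steps([], 0.02)

    def test_recovers_D_on_true_links_at_low_density(self):
        sc = SimScenario.uniform(0.05, states=((1.0, 1.0),), n_pairs=20,
                                 seed=21)
        ds, _ = make_pairwise_dataset(sc)
        rep = estimate_D_spt(pairwise_frame_pairs(ds), mode="global",
                             area_of_interest=ds.area_of_interest)
        assert rep.diffusion_constants[0] == pytest.approx(1.0, rel=0.25)


class TestSPTDensityBias:
    def test_global_accurate_at_low_density(self):
        ests = []
        for seed in range(5):
            sc = SimScenario.uniform(0.1, states=((1.0, 1.0),), seed=seed)
            ds, _ = make_pairwise_dataset(sc)
            rep = estimate_D_spt(pairwise_frame_pairs(ds), mode="global",
                                 area_of_interest=ds.area_of_interest)
            ests.append(rep.diffusion_constants[0])
        assert np.mean(ests) == pytest.approx(1.0, rel=0.10)

    def test_local_biased_low_at_high_density(self):
        ests = []
        for seed in range(3):
            sc = SimScenario.uniform(10.0, states=((1.0, 1.0),), seed=seed)
            ds, _ = make_pairwise_dataset(sc)
            rep = estimate_D_spt(pairwise_frame_pairs(ds), mode="local",
                                 area_of_interest=ds.area_of_interest)
            ests.append(rep.diffusion_constants[0])
        assert np.mean(ests) < 0.6  # severe systematic underestimation


class TestPICS:
    def test_fit_recovers_analytic_curve(self):
        dt = 0.02
        grid = np.arange(0.02, 1.7, 0.02)
        truth = (1.3, 0.8, 2.0)
        values = pics_curve(grid, *truth, dt)
        A, D, rho = fit_pics_curve(grid, values, dt)
        assert A == pytest.approx(truth[0], abs=1e-6)
        assert D == pytest.approx(truth[1], abs=1e-6)
        assert rho == pytest.approx(truth[2], abs=1e-6)

    def test_uniform_simulation_recovery(self):
        ests, rhos = [], []
        for seed in range(5):
            sc = SimScenario.uniform(1.0, states=((1.0, 1.0),), seed=seed)
            ds, _ = make_pairwise_dataset(sc)
            rep = pics_estimate(pairwise_frame_pairs(ds),
                                area_of_interest=ds.area_of_interest)
            ests.append(rep.diffusion_constants[0])
            rhos.append(rep.extra["rho"])
        assert np.mean(ests) == pytest.approx(1.0, rel=0.30)
        assert np.mean(rhos) == pytest.approx(1.0, rel=0.25)

    def test_near_zero_background(self):
        # sparse data: the quadratic background term nearly vanishes
        sc = SimScenario.uniform(0.02, states=((1.0, 1.0),), n_pairs=50,
                                 seed=4)
        ds, _ = make_pairwise_dataset(sc)
        rep = pics_estimate(pairwise_frame_pairs(ds),
                            area_of_interest=ds.area_of_interest,
                            fit_range=1.0)
        assert rep.extra["rho"] < 0.05
        assert rep.diffusion_constants[0] == pytest.approx(1.0, rel=0.35)

    def test_fit_range_too_short(self):
        sc = SimScenario.uniform(1.0, states=((1.0, 1.0),), seed=2)
        ds, _ = make_pairwise_dataset(sc)
        with pytest.raises(ValueError, match="fit range"):
            pics_estimate(pairwise_frame_pairs(ds),
                          area_of_interest=ds.area_of_interest,
                          fit_range=0.05)
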