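"""Likelihood machinery: objective, partition function, sampler, recovery.

The expensive full-scale recovery check lives in the acceptance suite;
here the same machinery is exercised at small sample sizes.
"""

import numpy as np
import pytest
from scipy import stats

from mtorpot import (
    MtorParamSet,
    PAIRS,
    SegmentDataset,
    FoldedSegment,
    ReducedSequence,
    bundled_param_set,
    chain_energy,
    estimate_partition,
    fit_phase_angles,
    neg_log_likelihood,
    sample_boltzmann_fragments,
    scan_weights,
)
from mtorpot.fit import SampledFragmentSet
from conftest import brute_force_chain_energy, ideal_fragment

ZERO = MtorParamSet(weights={1: 0.0, 2: 0.0}, psi_deg=dict.fromkeys(PAIRS, 0.0))


def make_set(theta, gamma, rtypes="A" * 10):
    return SampledFragmentSet(theta=theta, gamma=gamma, rtypes=rtypes)


def dataset_from_fragments(geoms_seqs):
    segs = []
    for geom, seq in geoms_seqs:
        segs.append(FoldedSegment(source=("synthetic", "A"), start=0, length=geom.n,
                                  theta=geom.theta, gamma=geom.gamma, rtypes=seq))
    return SegmentDataset(segments=segs)


class TestNegLogLikelihood:
    def test_single_ideal_fragment_equals_chain_energy(self, zero_psi):
        geom, seq = ideal_fragment(7)
        ds = dataset_from_fragments([(geom, seq)])
        assert neg_log_likelihood(ds, zero_psi, RT=1.0) == pytest.approx(-0.25)
        assert neg_log_likelihood(ds, zero_psi, RT=1.0) == pytest.approx(
            chain_energy(geom, seq, zero_psi))

    def test_rt_rescales_energy_part(self, set_b):
        rng = np.random.default_rng(2)
        fs = make_set(rng.uniform(60, 120, (5, 8)), rng.uniform(0, 360, (5, 7)))
        assert neg_log_likelihood(fs, set_b, RT=2.0) == pytest.approx(
            neg_log_likelihood(fs, set_b, RT=1.0) / 2.0)

    def test_matches_per_fragment_brute_force(self, set_b):
        rng = np.random.default_rng(3)
        frags = []
        total = 0.0
        for _ in range(20):
            th = rng.uniform(30, 150, 8)
            ga = rng.uniform(0, 360, 7)
            frags.append((th, ga))
            total += brute_force_chain_energy(th, ga, "A" * 10, set_b)
        fs = make_set(np.stack([f[0] for f in frags]), np.stack([f[1] for f in frags]))
        assert neg_log_likelihood(fs, set_b, RT=1.0) == pytest.approx(total, abs=1e-9)


class TestEstimatePartition:
    def test_zero_potential_gives_exact_domain_volume(self):
        q, se = estimate_partition(10, ZERO, n_samples=1000, seed=0)
        assert q == 180.0 ** 8 * 360.0 ** 7
        assert se == 0.0

    def test_same_seed_reproduces_estimate(self, set_b):
        a = estimate_partition(9, set_b, RT=0.3, n_samples=2000, seed=42)
        b = estimate_partition(9, set_b, RT=0.3, n_samples=2000, seed=42)
        assert a == b

    def test_standard_error_shrinks_as_root_n(self, set_b):
        sizes = [2000, 8000, 32000]
        ses = [estimate_partition(8, set_b, RT=0.3, n_samples=s, seed=7)[1] for s in sizes]
        # four-fold sample size should roughly halve the SE
        assert ses[1] / ses[0] == pytest.approx(0.5, abs=0.25)
        assert ses[2] / ses[1] == pytest.approx(0.5, abs=0.25)


class TestFitPhaseAngles:
    def test_analytic_gradient_matches_finite_differences(self, set_b):
        rng = np.random.default_rng(8)
        fs = make_set(rng.uniform(60, 120, (30, 8)), rng.uniform(0, 120, (30, 7)))
        from mtorpot.fit import _fragment_groups
        from mtorpot.energy import chain_energy_and_angle_grads

        base = MtorParamSet(weights={1: 0.6, 2: 0.4}, psi_deg=dict.fromkeys(PAIRS, 0.0))
        psi0 = rng.uniform(-60, 60, 9)
        (n, (th, ga, pid)), = _fragment_groups(fs).items()

        def L(psi):
            return float(np.sum(
                __import__("mtorpot").chain_energy_angles(th, ga, pid, base.with_psi_vector(psi))))

        _, _, dga = chain_energy_and_angle_grads(th, ga, pid, base.with_psi_vector(psi0))
        grad = np.radians(1.0) * np.bincount(pid.ravel(), weights=dga.ravel(), minlength=9)
        h = 1e-5
        for k in range(9):
            dp, dm = psi0.copy(), psi0.copy()
            dp[k] += h
            dm[k] -= h
            fd = (L(dp) - L(dm)) / (2 * h)
            assert grad[k] == pytest.approx(fd, rel=1e-6, abs=1e-9)

    def test_recovers_generator_phase_angle(self, set_b):
        fs = sample_boltzmann_fragments(set_b, 10, 400, RT=0.05, seed=11,
                                        burn_in=300, thin=10)
        r = fit_phase_angles(fs, fixed_weights=(0.6, 0.4))
        assert r.converged
        assert r.grad_norm < 1e-6
        assert r.psi_deg["AA"] == pytest.approx(set_b.psi_deg["AA"], abs=3.0)
        # helix-rich data: fitted phase is negative and small in magnitude
        assert -60.0 < r.psi_deg["AA"] < 0.0

    def test_objective_value_equals_sum_v_over_rt(self, set_b):
        fs = sample_boltzmann_fragments(set_b, 10, 50, RT=0.2, seed=3, burn_in=50, thin=5)
        r = fit_phase_angles(fs, fixed_weights=(1.0, 0.0), RT=0.7)
        p = r.to_param_set()
        assert r.L == pytest.approx(neg_log_likelihood(fs, p, RT=0.7), rel=1e-9)


class TestScanWeights:
    def test_grid_covers_both_pure_multiplicities(self, set_b):
        fs = sample_boltzmann_fragments(set_b, 10, 40, RT=0.2, seed=5, burn_in=40, thin=5)
        results = scan_weights(fs, grid_step=0.2)
        assert len(results) == 6
        weights = {r.weights for r in results}
        assert (1.0, 0.0) in weights and (0.0, 1.0) in weights
        ls = [r.L for r in results]
        assert ls == sorted(ls)

    def test_without_lnq_an_extreme_weight_wins(self, set_b):
        # min over psi of sum(V) is concave in the weights, so the grid
        # minimum sits at a vertex of the simplex
        fs = sample_boltzmann_fragments(set_b, 10, 200, RT=0.2, seed=9, burn_in=150, thin=10)
        best = scan_weights(fs, grid_step=0.25)[0]
        assert best.weights[0] in (0.0, 1.0)


class TestBoltzmannSampler:
    def test_zero_potential_gives_uniform_marginals(self):
        fs = sample_boltzmann_fragments(ZERO, 10, 700, RT=1.0, seed=13, burn_in=30, thin=5)
        ks_gamma = stats.kstest(fs.gamma.ravel() / 360.0, "uniform").pvalue
        ks_theta = stats.kstest(fs.theta.ravel() / 180.0, "uniform").pvalue
        assert ks_gamma > 1e-3 and ks_theta > 1e-3

    def test_samples_are_biased_toward_low_energy(self, set_b):
        from mtorpot import chain_energy_angles, pair_indices
        fs = sample_boltzmann_fragments(set_b, 10, 300, RT=0.1, seed=17, burn_in=200, thin=10)
        pid = pair_indices(fs.rtypes)
        sampled = chain_energy_angles(fs.theta, fs.gamma, pid, set_b).mean()
        rng = np.random.default_rng(0)
        uniform = chain_energy_angles(rng.uniform(0, 180, (300, 8)),
                                      rng.uniform(0, 360, (300, 7)), pid, set_b).mean()
        assert sampled < uniform

    def test_same_seed_reproduces_fragments(self, set_b):
        a = sample_boltzmann_fragments(set_b, 9, 25, RT=0.2, seed=21, burn_in=20, thin=5)
        b = sample_boltzmann_fragments(set_b, 9, 25, RT=0.2, seed=21, burn_in=20, thin=5)
        assert np.array_equal(a.theta, b.theta) and np.array_equal(a.gamma, b.gamma)

    def test_angles_stay_in_valid_ranges(self, set_b):
        fs = sample_boltzmann_fragments(set_b, 9, 50, RT=0.1, seed=23, burn_in=40, thin=5)
        assert ((fs.theta > 0) & (fs.theta < 180)).all()
        assert ((fs.gamma >= 0) & (fs.gamma < 360)).all()

    def test_fragment_set_tsv_round_trip(self, tmp_path, set_b):
        fs = sample_boltzmann_fragments(set_b, 8, 10, RT=0.2, seed=29, burn_in=10, thin=2)
        tsv, man = tmp_path / "f.tsv", tmp_path / "f.json"
        fs.save(tsv, man)
        frame = __import__("pandas").read_csv(tsv, sep="\t")
        assert frame["fragment"].nunique() == 10
        assert (frame.groupby("fragment").size() == 6).all()   # n-2 rows each
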