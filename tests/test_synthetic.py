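"""Generator correctness: mixture sampling, photon streams, Langevin CV
series and coarse-grained frames, checked against closed forms."""

import numpy as np
import pytest
from scipy import stats

from memfret.synthetic import (
    DONOR,
    LandscapeSpec,
    MixtureSpec,
    MoleculeSim,
    TcspcSpec,
    default_mixture_spec,
    make_cg_frame,
    default_protein_bead_spec,
    sample_mixture_lifetimes,
    sample_nanotimes,
    simulate_condition,
    simulate_langevin_cv,
    simulate_photon_stream,
)


class TestMixtureSpec:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="increasing"):
            MixtureSpec([2.7, 1.3], [0.3, 0.3], {"a": [0.5, 0.5]})
        with pytest.raises(ValueError, match="sum to 1"):
            MixtureSpec([1.3, 2.7], [0.3, 0.3], {"a": [0.5, 0.6]})
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            MixtureSpec([1.3, 2.7], [0.3, 0.3], {"a": [-0.1, 1.1]})

    def test_presets_match_reported_amplitudes(self):
        spec = default_mixture_spec()
        assert spec.weights("30% POPS -EGF")[1] == pytest.approx(0.74)
        assert spec.weights("30% POPS +EGF")[1] == pytest.approx(0.96)
        assert spec.weights("DMPC +EGF")[1] == pytest.approx(0.42)


class TestMixtureSampling:
    def test_degenerate_width_returns_mean(self):
        spec = MixtureSpec([2.0], [0.0], {"only": [1.0]})
        x = sample_mixture_lifetimes(spec, "only", 5, seed=0)
        assert np.allclose(x, 2.0)

    def test_sample_mean_matches_mixture_moment(self, two_state_spec):
        # E[tau] = 0.25*1.3 + 0.75*2.7 = 2.35 for weights (0.25, 0.75)
        spec = MixtureSpec([1.3, 2.7], [0.35, 0.67], {"c": [0.25, 0.75]})
        n = 100_000
        x = sample_mixture_lifetimes(spec, "c", n, seed=42)
        var = 0.25 * (0.35**2 + 1.3**2) + 0.75 * (0.67**2 + 2.7**2) - 2.35**2
        se = np.sqrt(var / n)
        assert abs(x.mean() - 2.35) < 3 * se

    def test_same_seed_reproduces(self, two_state_spec):
        a = sample_mixture_lifetimes(two_state_spec, "mid", 1000, seed=7)
        b = sample_mixture_lifetimes(two_state_spec, "mid", 1000, seed=7)
        assert np.array_equal(a, b)

    def test_unknown_condition_raises(self, two_state_spec):
        with pytest.raises(KeyError, match="unknown condition"):
            sample_mixture_lifetimes(two_state_spec, "nope", 10, seed=0)

    def test_all_lifetimes_positive(self, two_state_spec):
        spec = MixtureSpec([0.3], [0.5], {"c": [1.0]})  # heavy mass below zero
        x = sample_mixture_lifetimes(spec, "c", 5000, seed=1)
        assert np.all(x > 0)

    def test_component_proportions_chi2(self, two_state_spec):
        """Empirical component proportions converge to the weights."""
        n = 100_000
        x = sample_mixture_lifetimes(two_state_spec, "mid", n, seed=3)
        # classify at a threshold and compare against the exact mixture mass
        # above it (truncation at zero is negligible for these parameters)
        thr = 1.95
        p_above = 0.26 * stats.norm.sf(thr, 1.3, 0.35) + 0.74 * stats.norm.sf(
            thr, 2.7, 0.67
        )
        observed = np.array([(x <= thr).sum(), (x > thr).sum()])
        expected = np.array([1 - p_above, p_above]) * n
        chi2 = ((observed - expected) ** 2 / expected).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=1)


class TestPhotonStream:
    def test_zero_rates_empty_stream(self, tcspc):
        mol = MoleculeSim(
            donor_rate_fret=0, donor_rate_postbleach=0, acceptor_rate=0, background_rate=0
        )
        s = simulate_photon_stream(mol, tcspc, duration=5.0, seed=0)
        assert s.n_photons == 0

    def test_nonpositive_duration_rejected(self, tcspc, mol_template):
        with pytest.raises(ValueError, match="duration"):
            simulate_photon_stream(mol_template, tcspc, duration=0.0, seed=0)

    def test_poisson_mean_before_acceptor_bleach(self, tcspc):
        mol = MoleculeSim(
            donor_rate_fret=500,
            donor_rate_postbleach=0,
            acceptor_rate=0,
            background_rate=0,
            acceptor_bleach_time=4.0,
            donor_bleach_time=4.0,
        )
        s = simulate_photon_stream(mol, tcspc, duration=10.0, seed=11)
        n = int((s.channel_times(DONOR) < 4.0).sum())
        assert abs(n - 2000) < 3 * np.sqrt(2000)

    def test_nanotime_mean_truncated_exponential(self):
        # irf_sigma = 0, irf_mean = 0, no background: nanotimes follow a
        # truncated exponential with mean tau - W/(exp(W/tau) - 1)
        tc = TcspcSpec(window=12.5, irf_mean=0.0, irf_sigma=0.0, background_fraction=0.0)
        rng = np.random.default_rng(5)
        tau, W = 2.0, 12.5
        x = sample_nanotimes(rng, 200_000, tau, tc)
        expected = tau - W / (np.exp(W / tau) - 1)
        assert x.mean() == pytest.approx(expected, abs=3 * x.std() / np.sqrt(len(x)))

    def test_nanotimes_within_window_and_sorted_macrotimes(self, tcspc, mol_template):
        s = simulate_photon_stream(mol_template, tcspc, duration=5.0, seed=2)
        assert np.all((s.nanotimes >= 0) & (s.nanotimes <= tcspc.window))
        assert np.all(np.diff(s.macrotimes) >= 0)

    def test_interphoton_intervals_exponential(self, tcspc):
        """Within a constant-rate stage, arrival gaps pass a KS test."""
        mol = MoleculeSim(
            donor_rate_fret=2000,
            donor_rate_postbleach=0,
            acceptor_rate=0,
            background_rate=0,
            acceptor_bleach_time=10.0,
            donor_bleach_time=10.0,
        )
        s = simulate_photon_stream(mol, tcspc, duration=10.0, seed=9)
        gaps = np.diff(s.channel_times(DONOR))
        assert len(gaps) > 10_000
        p = stats.kstest(gaps, "expon", args=(0, gaps.mean())).pvalue
        assert p > 0.01


class TestSimulateCondition:
    def test_degenerate_weights_single_state(self, tcspc, mol_template):
        spec = MixtureSpec([1.3, 2.7], [0.35, 0.67], {"c": [1.0, 0.0]})
        _, truth = simulate_condition(spec, "c", 50, mol_template, tcspc, duration=1.0, seed=0)
        assert (truth["state"] == 0).all()

    def test_state_counts_binomial(self, tcspc, mol_template):
        spec = MixtureSpec([1.3, 2.7], [0.35, 0.67], {"c": [0.25, 0.75]})
        _, truth = simulate_condition(spec, "c", 400, mol_template, tcspc, duration=0.5, seed=1)
        n1 = int((truth["state"] == 1).sum())
        assert abs(n1 - 300) <= 3 * np.sqrt(400 * 0.25 * 0.75)

    def test_truth_table_shape_and_determinism(self, two_state_spec, tcspc, mol_template):
        s1, t1 = simulate_condition(two_state_spec, "mid", 12, mol_template, tcspc, 1.0, seed=5)
        s2, t2 = simulate_condition(two_state_spec, "mid", 12, mol_template, tcspc, 1.0, seed=5)
        assert len(t1) == 12
        assert t1.equals(t2)
        assert all(
            np.array_equal(a.macrotimes, b.macrotimes) for a, b in zip(s1, s2)
        )


class TestLangevin:
    def test_biased_flat_potential_variance(self):
        """Stationary variance under bias k=1 kT/unit^2 on a flat landscape
        is kT/k = 1 (Gaussian stationary law)."""
        spec = LandscapeSpec(
            potential=lambda x: 0.0, windows=[(0.0, 1.0)], n_steps=400_000, seed=0
        )
        (w,) = simulate_langevin_cv(spec)
        assert w.cv_series.var() == pytest.approx(1.0, rel=0.05)

    def test_unbiased_diffusion_variance_grows(self):
        short = LandscapeSpec(lambda x: 0.0, [(0.0, 0.0)], n_steps=2_000, seed=1)
        long = LandscapeSpec(lambda x: 0.0, [(0.0, 0.0)], n_steps=50_000, seed=1)
        v_short = simulate_langevin_cv(short)[0].cv_series.var()
        v_long = simulate_langevin_cv(long)[0].cv_series.var()
        assert v_long > 3 * v_short

    def test_seed_determinism_and_zero_steps(self):
        spec = LandscapeSpec(lambda x: 0.5 * x**2, [(0.0, 2.0)], n_steps=500, seed=4)
        a = simulate_langevin_cv(spec)[0].cv_series
        b = simulate_langevin_cv(spec)[0].cv_series
        assert np.array_equal(a, b)
        with pytest.raises(ValueError, match="n_steps"):
            LandscapeSpec(lambda x: 0.0, [(0.0, 1.0)], n_steps=0)


class TestCgFrame:
    def test_protein_only_frame(self):
        frame = make_cg_frame(0, {721: [[10.0, 10.0, 10.0]]}, box=[50, 50, 50], seed=0)
        assert frame.n_beads == 1
        assert (frame.bead_kind == "protein").all()

    def test_lipid_density(self):
        frame = make_cg_frame(1000, {721: [[1, 1, 1]]}, box=[100, 100, 100], seed=2)
        density = 1000 / 100**3
        assert density == pytest.approx(1e-3)
        assert np.all(frame.coordinates >= 0) and np.all(frame.coordinates <= 100)

    def test_seed_reproducibility(self):
        spec = default_protein_bead_spec([80, 80, 80], seed=3)
        f1 = make_cg_frame(200, spec, box=[80, 80, 80], seed=3)
        f2 = make_cg_frame(200, spec, box=[80, 80, 80], seed=3)
        assert np.array_equal(f1.coordinates, f2.coordinates)

    def test_protein_bead_outside_box_rejected(self):
        with pytest.raises(ValueError, match="outside box"):
            make_cg_frame(10, {721: [[60.0, 10.0, 10.0]]}, box=[50, 50, 50], seed=0)
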