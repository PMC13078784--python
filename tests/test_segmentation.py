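"""Binning, Poisson change-point segmentation and bleach-step selection."""

import numpy as np
import pytest

from memfret.segmentation import (
    BinnedTrace,
    Segment,
    bin_photons,
    detect_changepoints,
    fret_nanotimes,
    select_traces,
)
from memfret.synthetic import (
    MixtureSpec,
    MoleculeSim,
    PhotonStream,
    simulate_condition,
)


def _stream(donor_times, acceptor_times=(), duration=None):
    macro = np.concatenate([np.asarray(donor_times), np.asarray(acceptor_times)])
    chan = np.concatenate(
        [np.zeros(len(donor_times), int), np.ones(len(acceptor_times), int)]
    )
    order = np.argsort(macro)
    dur = duration if duration is not None else (macro.max() if len(macro) else 0.0)
    return PhotonStream(
        macrotimes=macro[order],
        nanotimes=np.zeros(len(macro)),
        channels=chan[order],
        duration=dur,
    )


class TestBinning:
    def test_basic_counts(self):
        s = _stream([0.01, 0.05, 0.15], duration=0.2)
        trace = bin_photons(s, 0.1)
        assert trace.counts_donor.tolist() == [2, 1]

    def test_empty_stream(self):
        s = _stream([], duration=0.0)
        trace = bin_photons(s, 0.1)
        assert trace.n_bins == 0

    def test_trailing_partial_bin_dropped(self):
        s = _stream([0.05, 0.15, 0.25], duration=0.27)
        trace = bin_photons(s, 0.1)
        assert trace.counts_donor.tolist() == [1, 1]

    def test_poisson_rate_recovered(self):
        rng = np.random.default_rng(0)
        duration, rate = 20.0, 500.0
        times = np.sort(rng.uniform(0, duration, rng.poisson(rate * duration)))
        trace = bin_photons(_stream(times, duration=duration), 0.1)
        mean = trace.counts_donor.mean()
        assert abs(mean - 50) < 3 * np.sqrt(50) / np.sqrt(trace.n_bins)


class TestChangepoints:
    def test_noiseless_single_step(self):
        counts = np.array([50] * 30 + [0] * 30)
        segs = detect_changepoints(counts, alpha=0.01)
        assert [(s.start, s.end) for s in segs] == [(0, 30), (30, 60)]
        assert segs[0].mean_rate == 50.0 and segs[1].mean_rate == 0.0

    def test_segment_rates_are_sample_means(self):
        rng = np.random.default_rng(1)
        counts = np.concatenate([rng.poisson(40, 80), rng.poisson(5, 80)])
        segs = detect_changepoints(counts, alpha=0.01)
        for s in segs:
            assert s.mean_rate == pytest.approx(counts[s.start : s.end].mean())
        assert segs[0].end == segs[1].start  # contiguous

    def test_two_step_recovery(self):
        """Both change points of a two-step trace are recovered within +-2
        bins in at least 95% of simulated traces (rate gaps >= 5 sigma)."""
        rng = np.random.default_rng(2)
        hits = 0
        n_sim = 200
        for i in range(n_sim):
            counts = np.concatenate(
                [rng.poisson(60, 100), rng.poisson(30, 100), rng.poisson(5, 100)]
            )
            segs = detect_changepoints(counts, alpha=0.01, calibration_seed=i)
            cuts = [s.start for s in segs[1:]]
            ok = any(abs(c - 100) <= 2 for c in cuts) and any(
                abs(c - 200) <= 2 for c in cuts
            )
            hits += ok
        assert hits / n_sim >= 0.95

    def test_input_validation(self):
        with pytest.raises(ValueError, match="alpha"):
            detect_changepoints([1, 2, 3], alpha=1.5)
        with pytest.raises(ValueError, match="non-negative"):
            detect_changepoints([1, -2, 3], alpha=0.01)
        with pytest.raises(ValueError, match="integers"):
            detect_changepoints([1.5, 2.2], alpha=0.01)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        counts = np.concatenate([rng.poisson(30, 50), rng.poisson(8, 50)])
        a = detect_changepoints(counts, 0.01, calibration_seed=9)
        b = detect_changepoints(counts, 0.01, calibration_seed=9)
        assert [(s.start, s.end) for s in a] == [(s.start, s.end) for s in b]


def _segs(*spans):
    return [Segment(start=a, end=b, mean_rate=r) for a, b, r in spans]


class TestSelection:
    def test_clean_single_steps_accepted(self):
        trace = BinnedTrace(0.1, np.zeros(60, int), np.zeros(60, int))
        segs_d = _segs((0, 30, 50.0), (30, 50, 80.0), (50, 60, 1.0))
        segs_a = _segs((0, 30, 30.0), (30, 60, 1.0))
        sel = select_traces(trace, segs_d, segs_a, background_rate=1.0)
        assert sel.accepted
        assert sel.acceptor_bleach_bin == 30
        assert sel.donor_bleach_bin == 50
        assert sel.fret_window == (0.0, pytest.approx(3.0))

    def test_donor_two_down_steps_rejected(self):
        trace = BinnedTrace(0.1, np.zeros(60, int), np.zeros(60, int))
        segs_d = _segs((0, 20, 80.0), (20, 40, 40.0), (40, 60, 1.0))
        segs_a = _segs((0, 30, 30.0), (30, 60, 1.0))
        sel = select_traces(trace, segs_d, segs_a, background_rate=1.0)
        assert not sel.accepted
        assert sel.rejection_reason == "donor:multi-step"

    def test_no_bleach_rejected(self):
        trace = BinnedTrace(0.1, np.zeros(60, int), np.zeros(60, int))
        segs_d = _segs((0, 60, 50.0))
        segs_a = _segs((0, 30, 30.0), (30, 60, 1.0))
        sel = select_traces(trace, segs_d, segs_a, background_rate=1.0)
        assert sel.rejection_reason == "donor:no-bleach"

    def test_blinking_rejected(self):
        trace = BinnedTrace(0.1, np.zeros(80, int), np.zeros(80, int))
        segs_d = _segs((0, 30, 50.0), (30, 40, 1.0), (40, 60, 50.0), (60, 80, 1.0))
        segs_a = _segs((0, 30, 30.0), (30, 80, 1.0))
        sel = select_traces(trace, segs_d, segs_a, background_rate=1.0)
        assert not sel.accepted and "donor" in sel.rejection_reason

    def test_missing_acceptor_rejected(self):
        trace = BinnedTrace(0.1, np.zeros(60, int), np.zeros(60, int))
        segs_d = _segs((0, 50, 50.0), (50, 60, 1.0))
        segs_a = _segs((0, 30, 2.0), (30, 60, 1.0))  # pre-bleach rate ~ background
        sel = select_traces(trace, segs_d, segs_a, background_rate=1.0)
        assert sel.rejection_reason == "acceptor:no-acceptor"

    def test_selection_invariant_to_appended_background(self):
        """Appending post-donor-bleach background bins does not change the
        decision or the FRET window."""
        trace1 = BinnedTrace(0.1, np.zeros(60, int), np.zeros(60, int))
        segs_d = _segs((0, 30, 50.0), (30, 50, 80.0), (50, 60, 1.0))
        segs_a = _segs((0, 30, 30.0), (30, 60, 1.0))
        sel1 = select_traces(trace1, segs_d, segs_a, background_rate=1.0)
        trace2 = BinnedTrace(0.1, np.zeros(100, int), np.zeros(100, int))
        segs_d2 = _segs((0, 30, 50.0), (30, 50, 80.0), (50, 100, 1.0))
        segs_a2 = _segs((0, 30, 30.0), (30, 100, 1.0))
        sel2 = select_traces(trace2, segs_d2, segs_a2, background_rate=1.0)
        assert sel1.accepted == sel2.accepted
        assert sel1.fret_window == sel2.fret_window

    def test_fret_window_matches_ground_truth(self, tcspc, mol_template):
        """On simulated molecules with known bleach times, >= 90% of accepted
        traces place the FRET-window end within one bin of the true
        acceptor bleach time."""
        spec = MixtureSpec([1.3, 2.7], [0.35, 0.67], {"c": [0.3, 0.7]})
        streams, truth = simulate_condition(
            spec, "c", 200, mol_template, tcspc, duration=8.0, seed=17
        )
        bg = mol_template.background_rate * 0.1
        n_acc, n_good = 0, 0
        for s in streams:
            trace = bin_photons(s, 0.1)
            if trace.n_bins < 2:
                continue
            segs_d = detect_changepoints(trace.counts_donor, 0.01, calibration_seed=s.molecule_id)
            segs_a = detect_changepoints(
                trace.counts_acceptor, 0.01, calibration_seed=s.molecule_id + 1
            )
            sel = select_traces(trace, segs_d, segs_a, bg)
            if not sel.accepted:
                continue
            n_acc += 1
            true_ab = truth.loc[truth.molecule_id == s.molecule_id, "acceptor_bleach_s"].iloc[0]
            if abs(sel.fret_window[1] - min(true_ab, 8.0)) <= 0.1 + 1e-9:
                n_good += 1
            else:
                # photons restricted to the window still precede the true bleach
                assert sel.fret_window[1] <= true_ab + 0.1
        assert n_acc >= 100
        assert n_good / n_acc >= 0.90

    def test_fret_nanotimes_restricted_to_window(self):
        s = _stream([0.05, 0.15, 0.25, 0.35], duration=0.4)
        trace = bin_photons(s, 0.1)
        from memfret.segmentation import TraceSelection

        sel = TraceSelection(accepted=True, fret_window=(0.0, 0.2))
        assert len(fret_nanotimes(s, sel)) == 2
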