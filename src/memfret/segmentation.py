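"""Intensity-trace segmentation and single-bleach-step molecule selection.

Photon streams are binned at 100 ms into donor/acceptor count traces;
regions of constant intensity are found by recursive binary segmentation of
the Poisson counts with a Monte-Carlo-calibrated generalized
likelihood-ratio test; molecules are kept only if each channel shows a
single downward photobleaching step terminating at background, with the
acceptor bleaching first. Donor photons before acceptor photobleaching
constitute the FRET-level photon set passed to lifetime fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic import ACCEPTOR, DONOR, PhotonStream

__all__ = [
    "BinnedTrace",
    "Segment",
    "TraceSelection",
    "bin_photons",
    "detect_changepoints",
    "select_traces",
    "fret_nanotimes",
    "segments_table",
]


@dataclass
class BinnedTrace:
    """Donor/acceptor photon counts on a common time grid."""

    bin_width: float
    counts_donor: np.ndarray
    counts_acceptor: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.counts_donor = np.asarray(self.counts_donor, dtype=int)
        self.counts_acceptor = np.asarray(self.counts_acceptor, dtype=int)
        if len(self.counts_donor) != len(self.counts_acceptor):
            raise ValueError("channel traces must have equal length")

    @property
    def n_bins(self) -> int:
        return len(self.counts_donor)


@dataclass
class Segment:
    """Half-open bin interval [start, end) of constant intensity."""

    start: int
    end: int
    mean_rate: float  # counts per bin (Poisson MLE = segment sample mean)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("segment must satisfy start < end")


def bin_photons(stream: PhotonStream, bin_width: float = 0.1) -> BinnedTrace:
    """Bin a photon stream into per-channel count traces.

    ``counts[i]`` counts photons with macrotime in [i*w, (i+1)*w); the
    trailing partial bin (beyond ``floor(duration / w)`` full bins) is
    dropped. An empty stream yields a zero-length trace.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(np.floor(stream.duration / bin_width + 1e-12))
    counts = {}
    for channel in (DONOR, ACCEPTOR):
        t = stream.channel_times(channel)
        idx = np.floor(t / bin_width).astype(int)
        idx = idx[idx < n_bins]
        counts[channel] = np.bincount(idx, minlength=n_bins) if n_bins else np.zeros(0, int)
    return BinnedTrace(
        bin_width=bin_width,
        counts_donor=counts[DONOR],
        counts_acceptor=counts[ACCEPTOR],
    )


# ---------------------------------------------------------------------------
# Change-point detection


def _split_stats(counts: np.ndarray) -> np.ndarray:
    """GLR statistic 2[lnL(split) - lnL(const)] for every split 1..L-1.

    Poisson log-likelihood with the rate profiled out per side; the common
    terms (log factorials) cancel. 0*log(0) := 0.
    """
    L = len(counts)
    cum = np.cumsum(counts, dtype=float)
    total = cum[-1]
    j = np.arange(1, L)
    s1 = cum[:-1]
    s2 = total - s1

    def xlogx_over(n, m):  # n * log(n / m), 0 log 0 = 0
        with np.errstate(divide="ignore", invalid="ignore"):
            v = n * np.log(n / m)
        return np.where(n > 0, v, 0.0)

    ll_split = xlogx_over(s1, j) + xlogx_over(s2, L - j)
    ll_const = xlogx_over(total, L)
    return 2.0 * (ll_split - ll_const)


def _max_stat_null(
    rng: np.random.Generator, rate: float, length: int, n_sim: int
) -> np.ndarray:
    sims = rng.poisson(rate, size=(n_sim, length))
    cum = np.cumsum(sims, axis=1, dtype=float)
    total = cum[:, -1:]
    j = np.arange(1, length, dtype=float)
    s1 = cum[:, :-1]
    s2 = total - s1
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(s1 > 0, s1 * np.log(s1 / j), 0.0)
        ll += np.where(s2 > 0, s2 * np.log(s2 / (length - j)), 0.0)
        ll_const = np.where(total > 0, total * np.log(total / length), 0.0)
    return 2.0 * (ll.max(axis=1) - ll_const[:, 0])


def detect_changepoints(
    counts: Sequence[int],
    alpha: float = 0.01,
    n_sim: int = 199,
    calibration_seed: int = 0,
    max_depth: int = 30,
) -> list[Segment]:
    """Recursive binary segmentation of a Poisson count trace.

    At each segment the split maximizing the generalized likelihood-ratio
    statistic is accepted if its Monte-Carlo p-value — calibrated by
    simulating ``n_sim`` constant-rate traces at the segment's fitted rate —
    is below ``alpha``; accepted splits recurse into both halves. Ties in
    the split statistic break toward the earlier index. Deterministic
    given (counts, alpha, calibration_seed).
    """
    counts = np.asarray(counts)
    if counts.ndim != 1 or len(counts) < 2:
        raise ValueError("counts must be a 1-D sequence of length >= 2")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("counts must be integers")
        counts = np.round(counts).astype(int)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")

    rng = np.random.default_rng(calibration_seed)
    boundaries: list[int] = []

    def recurse(lo: int, hi: int, depth: int) -> None:
        seg = counts[lo:hi]
        if len(seg) < 2 or depth > max_depth:
            return
        stats = _split_stats(seg)
        best = int(np.argmax(stats))  # argmax takes the earliest tie
        obs = stats[best]
        if obs <= 0:
            return
        rate = seg.mean()
        null = _max_stat_null(rng, rate, len(seg), n_sim)
        p = (1 + int(np.sum(null >= obs))) / (n_sim + 1)
        if p < alpha:
            cut = lo + best + 1
            boundaries.append(cut)
            recurse(lo, cut, depth + 1)
            recurse(cut, hi, depth + 1)

    recurse(0, len(counts), 0)
    edges = [0] + sorted(boundaries) + [len(counts)]
    return [
        Segment(start=a, end=b, mean_rate=float(counts[a:b].mean()))
        for a, b in zip(edges[:-1], edges[1:])
    ]


# ---------------------------------------------------------------------------
# Trace selection


@dataclass
class TraceSelection:
    accepted: bool
    donor_bleach_bin: int | None = None
    acceptor_bleach_bin: int | None = None
    fret_window: tuple[float, float] | None = None
    rejection_reason: str | None = None


def _merge_transition_segments(
    segs: list[Segment], max_len: int = 1
) -> list[Segment]:
    """Drop short segments whose rate lies between their neighbours' rates.

    A rate step falling inside a bin produces a one-bin segment at an
    intermediate rate; it is part of the step, not a separate intensity
    level, so it is absorbed into the following segment (keeping its start
    so step positions stay bin-accurate).
    """
    out = list(segs)
    changed = True
    while changed and len(out) >= 3:
        changed = False
        for i in range(1, len(out) - 1):
            mid = out[i]
            lo, hi = sorted((out[i - 1].mean_rate, out[i + 1].mean_rate))
            if (mid.end - mid.start) <= max_len and lo <= mid.mean_rate <= hi:
                nxt = out[i + 1]
                out[i + 1] = Segment(
                    start=mid.start, end=nxt.end, mean_rate=nxt.mean_rate
                )
                del out[i]
                changed = True
                break
    return out


def _single_bleach(
    segs: list[Segment],
    background_rate: float,
    step_sigma: float,
) -> tuple[int | None, str | None]:
    """Locate a single downward step terminating at background.

    Returns (bleach_bin, None) on success or (None, reason). The post-step
    rate must sit within ``step_sigma`` standard errors of the background
    rate (Poisson SE = sqrt(bg / segment length) counts/bin).
    """
    segs = _merge_transition_segments(segs)
    rates = [s.mean_rate for s in segs]

    def is_background(seg: Segment) -> bool:
        tol = step_sigma * np.sqrt(max(background_rate, 1e-12) / (seg.end - seg.start))
        return abs(seg.mean_rate - background_rate) <= max(tol, 1e-9)

    downs = [i for i in range(len(segs) - 1) if rates[i + 1] < rates[i]]
    if not downs:
        return None, "no-bleach"
    if len(downs) > 1:
        return None, "multi-step"
    (i,) = downs
    if not all(is_background(s) for s in segs[i + 1 :]):
        return None, "no-bleach"
    if any(rates[j + 1] > rates[j] for j in range(i + 1, len(segs) - 1)):
        return None, "blinking"
    return segs[i + 1].start, None


def select_traces(
    trace: BinnedTrace,
    segs_d: list[Segment],
    segs_a: list[Segment],
    background_rate: float,
    step_sigma: float = 3.0,
    acceptor_presence_factor: float = 3.0,
) -> TraceSelection:
    """Accept a molecule iff both channels show a single photobleaching step.

    The donor channel must show exactly one downward step ending at
    background (the upward de-quenching step at acceptor bleaching is
    allowed), the acceptor likewise, the acceptor pre-bleach rate must
    exceed ``acceptor_presence_factor`` times background (acceptor
    actually present), and the acceptor must bleach no later than the
    donor. The FRET window runs from the trace start to the acceptor
    bleach time. ``background_rate`` is in counts per bin.
    """
    d_bin, d_reason = _single_bleach(segs_d, background_rate, step_sigma)
    if d_reason is not None:
        return TraceSelection(accepted=False, rejection_reason=f"donor:{d_reason}")
    a_bin, a_reason = _single_bleach(segs_a, background_rate, step_sigma)
    if a_reason is not None:
        return TraceSelection(accepted=False, rejection_reason=f"acceptor:{a_reason}")
    pre_rates = [s.mean_rate for s in segs_a if s.end <= a_bin]
    if not pre_rates or max(pre_rates) < acceptor_presence_factor * background_rate:
        return TraceSelection(accepted=False, rejection_reason="acceptor:no-acceptor")
    if a_bin > d_bin:
        return TraceSelection(accepted=False, rejection_reason="bleach-order")
    fret_end = trace.start_time + a_bin * trace.bin_width
    return TraceSelection(
        accepted=True,
        donor_bleach_bin=d_bin,
        acceptor_bleach_bin=a_bin,
        fret_window=(trace.start_time, fret_end),
    )


def fret_nanotimes(stream: PhotonStream, selection: TraceSelection) -> np.ndarray:
    """Donor-channel nanotimes inside the accepted FRET window, in macrotime
    order — the photon set that lifetime bunching consumes."""
    if not selection.accepted:
        raise ValueError("selection was rejected; no FRET window")
    lo, hi = selection.fret_window
    mask = (
        (stream.channels == DONOR)
        & (stream.macrotimes >= lo)
        & (stream.macrotimes < hi)
    )
    return stream.nanotimes[mask]


def segments_table(
    molecule_id: int, channel: str, segs: list[Segment]
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "molecule_id": molecule_id,
            "channel": channel,
            "start_bin": [s.start for s in segs],
            "end_bin": [s.end for s in segs],
            "rate_counts_per_bin": [s.mean_rate for s in segs],
        }
    )
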