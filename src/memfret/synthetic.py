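"""Seeded synthetic data with the statistical structure the pipeline assumes.

The experimental raw data for this kind of study — TCSPC photon streams from
immobilized receptor nanodiscs and coarse-grained trajectory frames — is
rarely deposited, so every downstream stage here is exercised on synthetic
inputs generated from reported summary statistics of this class of experiment:

* donor-lifetime mixtures with two conformational states (compact/open,
  peaks 1.3 ns and 2.7 ns, widths 0.35 ns and 0.67 ns) and per-condition
  open-state amplitudes between 42% and 96%;
* immobilized-molecule photon streams with Poisson arrivals, single-step
  acceptor then donor photobleaching, TCSPC nanotimes drawn from a
  Gaussian-IRF-convolved exponential decay truncated to the 12.5 ns laser
  period (80 MHz), mixed with uniform background;
* overdamped-Langevin collective-variable series under harmonic umbrella
  biases, and labelled coarse-grained bead clouds for contact counting.

All generators are reproducible from (seed, parameters); per-molecule
substreams derive from ``seed`` by counter so molecules are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .trajectory import ATP_SITE_RESIDUES, TrajectoryFrame, UmbrellaWindow

__all__ = [
    "MixtureSpec",
    "MoleculeSim",
    "TcspcSpec",
    "LandscapeSpec",
    "PhotonStream",
    "OPEN_STATE_AMPLITUDES",
    "default_mixture_spec",
    "sample_mixture_lifetimes",
    "simulate_photon_stream",
    "simulate_condition",
    "simulate_langevin_cv",
    "make_cg_frame",
]

#: Open-state (long-lifetime) amplitudes reported per membrane condition,
#: keyed by (lipid composition label, EGF present). Fractions of 1.
OPEN_STATE_AMPLITUDES: dict[tuple[str, bool], float] = {
    ("0% POPS", False): 0.87,
    ("0% POPS", True): 0.60,
    ("15% POPS", False): 0.69,
    ("15% POPS", True): 0.91,
    ("30% POPS", False): 0.74,
    ("30% POPS", True): 0.96,
    ("60% POPS", False): 0.91,
    ("60% POPS", True): 0.96,
    ("7.5% chol", False): 0.90,
    ("7.5% chol", True): 0.90,
    ("20% chol", False): 0.95,
    ("20% chol", True): 0.95,
    ("DMPC", False): 0.95,
    ("DMPC", True): 0.42,
}


def _condition_label(lipid: str, egf: bool) -> str:
    return f"{lipid} {'+EGF' if egf else '-EGF'}"


@dataclass
class MixtureSpec:
    """A shared-component Gaussian lifetime mixture with per-condition weights.

    ``means``/``widths`` (ns) are shared across conditions; only the
    amplitudes differ per condition, mirroring a global two-state fit.
    """

    means: Sequence[float]
    widths: Sequence[float]
    weights_per_condition: Mapping[str, Sequence[float]]

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        if np.any(np.diff(self.means) <= 0):
            raise ValueError("component means must be strictly increasing")
        if np.any(self.widths < 0):
            raise ValueError("component widths must be non-negative")
        clean = {}
        for cond, w in self.weights_per_condition.items():
            w = np.asarray(w, dtype=float)
            if w.shape != self.means.shape:
                raise ValueError(f"condition {cond!r}: weight count != component count")
            if np.any(w < 0) or np.any(w > 1):
                raise ValueError(f"condition {cond!r}: weights must lie in [0, 1]")
            if abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(f"condition {cond!r}: weights must sum to 1")
            clean[cond] = w
        self.weights_per_condition = clean

    @property
    def conditions(self) -> list[str]:
        return list(self.weights_per_condition)

    def weights(self, condition: str) -> np.ndarray:
        try:
            return self.weights_per_condition[condition]
        except KeyError:
            raise KeyError(
                f"unknown condition {condition!r}; known: {self.conditions}"
            ) from None


def default_mixture_spec(conditions: Sequence[str] | None = None) -> MixtureSpec:
    """Two-state mixture with the reference two-state global-fit parameters.

    Peaks 1.3/2.7 ns, widths 0.35/0.67 ns; per-condition open-state
    amplitudes from :data:`OPEN_STATE_AMPLITUDES`. ``conditions`` selects a
    subset of labels like ``"30% POPS +EGF"`` (default: all).
    """
    weights = {
        _condition_label(lipid, egf): [1.0 - a_open, a_open]
        for (lipid, egf), a_open in OPEN_STATE_AMPLITUDES.items()
    }
    if conditions is not None:
        weights = {c: weights[c] for c in conditions}
    return MixtureSpec(means=[1.3, 2.7], widths=[0.35, 0.67], weights_per_condition=weights)


@dataclass
class TcspcSpec:
    """TCSPC detection model: pulse window, Gaussian IRF, uniform background.

    ``window`` defaults to 12.5 ns (80 MHz repetition rate).
    ``background_fraction`` is the fraction of detected photons whose
    nanotime is uniform over the window (dark counts/afterpulsing).
    """

    window: float = 12.5
    irf_mean: float = 2.0
    irf_sigma: float = 0.15
    background_fraction: float = 0.0
    channel_width: float = 0.016

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")
        if not (0 <= self.background_fraction < 1):
            raise ValueError("background_fraction must be in [0, 1)")
        if self.irf_sigma < 0:
            raise ValueError("irf_sigma must be non-negative")


@dataclass
class MoleculeSim:
    """Emission model for one immobilized molecule.

    Rates are mean detected photons/s. The donor emits at
    ``donor_rate_fret`` with lifetime ``lifetime_fret_ns`` until the
    acceptor bleaches, then at ``donor_rate_postbleach`` with the
    donor-only lifetime until it bleaches itself; afterwards only
    background remains. ``background_rate`` applies per channel for the
    whole acquisition.
    """

    state_index: int = 0
    donor_rate_fret: float = 3000.0
    donor_rate_postbleach: float = 6000.0
    acceptor_rate: float = 2000.0
    acceptor_bleach_time: float = 2.0
    donor_bleach_time: float = 4.0
    background_rate: float = 30.0
    lifetime_fret_ns: float = 2.0
    lifetime_donor_only_ns: float = 3.02

    def __post_init__(self) -> None:
        for name in (
            "donor_rate_fret",
            "donor_rate_postbleach",
            "acceptor_rate",
            "background_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.acceptor_bleach_time <= 0 or self.donor_bleach_time <= 0:
            raise ValueError("bleach times must be positive")


DONOR, ACCEPTOR = 0, 1


@dataclass
class PhotonStream:
    """Per-molecule photon records, time-sorted.

    macrotimes in seconds, nanotimes in ns, channel 0 = donor, 1 = acceptor.
    """

    macrotimes: np.ndarray
    nanotimes: np.ndarray
    channels: np.ndarray
    duration: float
    molecule_id: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.macrotimes = np.asarray(self.macrotimes, dtype=float)
        self.nanotimes = np.asarray(self.nanotimes, dtype=float)
        self.channels = np.asarray(self.channels, dtype=np.int8)

    @property
    def n_photons(self) -> int:
        return len(self.macrotimes)

    def channel_times(self, channel: int) -> np.ndarray:
        return self.macrotimes[self.channels == channel]


# ---------------------------------------------------------------------------
# Lifetime mixture sampling


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _positive_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Draws from N(mean, sd) with non-positive values rejected and redrawn."""
    if sd == 0:
        if mean <= 0:
            raise ValueError("degenerate component with non-positive mean")
        return np.full(n, mean)
    out = rng.normal(mean, sd, size=n)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= 0
    return out


def sample_mixture_lifetimes(
    spec: MixtureSpec, condition: str, n: int, seed=None
) -> np.ndarray:
    """Draw ``n`` positive lifetimes (ns) from a condition's Gaussian mixture."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = _rng(seed)
    w = spec.weights(condition)
    comp = rng.choice(len(w), size=n, p=w)
    out = np.empty(n)
    for k in range(len(w)):
        mask = comp == k
        if mask.any():
            out[mask] = _positive_normal(rng, spec.means[k], spec.widths[k], int(mask.sum()))
    return out


# ---------------------------------------------------------------------------
# Photon stream simulation


def sample_nanotimes(
    rng: np.random.Generator, n: int, lifetime_ns: float, tcspc: TcspcSpec
) -> np.ndarray:
    """Signal nanotimes: Gaussian IRF + exponential decay, redrawn into the
    window (no wrap-around), mixed with uniform background photons."""
    if n == 0:
        return np.empty(0)
    is_bg = rng.random(n) < tcspc.background_fraction
    n_sig = int((~is_bg).sum())
    sig = np.empty(n_sig)
    filled = 0
    for _ in range(1000):
        need = n_sig - filled
        if need == 0:
            break
        draw = rng.normal(tcspc.irf_mean, tcspc.irf_sigma, size=need) + rng.exponential(
            lifetime_ns, size=need
        )
        ok = (draw >= 0) & (draw < tcspc.window)
        k = int(ok.sum())
        sig[filled : filled + k] = draw[ok]
        filled += k
    else:
        raise RuntimeError("nanotime rejection sampling failed to fill the window")
    out = np.empty(n)
    out[~is_bg] = sig
    out[is_bg] = rng.uniform(0, tcspc.window, size=int(is_bg.sum()))
    return out


def _poisson_arrivals(
    rng: np.random.Generator, rate: float, t0: float, t1: float
) -> np.ndarray:
    if rate <= 0 or t1 <= t0:
        return np.empty(0)
    n = rng.poisson(rate * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, size=n))


def simulate_photon_stream(
    mol: MoleculeSim, tcspc: TcspcSpec, duration: float, seed=None
) -> PhotonStream:
    """Simulate one molecule's acquisition until ``duration`` seconds.

    Three stages: FRET (donor quenched, acceptor emitting) until the
    acceptor bleaches; donor-only until the donor bleaches; background
    only afterwards. Arrivals are Poisson at the stage rate; donor
    nanotimes follow the stage lifetime under the TCSPC model; acceptor
    and background nanotimes are uniform over the window.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = _rng(seed)
    ab = min(mol.acceptor_bleach_time, duration)
    db = min(max(mol.donor_bleach_time, ab), duration)

    parts = []  # (macrotimes, nanotimes, channel)
    t_fret = _poisson_arrivals(rng, mol.donor_rate_fret, 0.0, ab)
    parts.append(
        (t_fret, sample_nanotimes(rng, len(t_fret), mol.lifetime_fret_ns, tcspc), DONOR)
    )
    t_post = _poisson_arrivals(rng, mol.donor_rate_postbleach, ab, db)
    parts.append(
        (
            t_post,
            sample_nanotimes(rng, len(t_post), mol.lifetime_donor_only_ns, tcspc),
            DONOR,
        )
    )
    t_acc = _poisson_arrivals(rng, mol.acceptor_rate, 0.0, ab)
    parts.append((t_acc, rng.uniform(0, tcspc.window, size=len(t_acc)), ACCEPTOR))
    for channel in (DONOR, ACCEPTOR):
        t_bg = _poisson_arrivals(rng, mol.background_rate, 0.0, duration)
        parts.append((t_bg, rng.uniform(0, tcspc.window, size=len(t_bg)), channel))

    macro = np.concatenate([p[0] for p in parts])
    nano = np.concatenate([p[1] for p in parts])
    chan = np.concatenate([np.full(len(p[0]), p[2], dtype=np.int8) for p in parts])
    order = np.argsort(macro, kind="stable")
    return PhotonStream(
        macrotimes=macro[order],
        nanotimes=nano[order],
        channels=chan[order],
        duration=duration,
        meta={
            "acceptor_bleach_time": ab,
            "donor_bleach_time": db,
            "lifetime_fret_ns": mol.lifetime_fret_ns,
        },
    )


def simulate_condition(
    spec: MixtureSpec,
    condition: str,
    n_molecules: int,
    mol_template: MoleculeSim,
    tcspc: TcspcSpec,
    duration: float = 8.0,
    seed: int = 0,
) -> tuple[list[PhotonStream], pd.DataFrame]:
    """Simulate a condition's molecules plus a ground-truth table.

    Each molecule draws a conformational state from the condition weights
    and a FRET-stage donor lifetime from that state's Gaussian; acceptor
    and donor bleach times are exponential with the template values as
    means (single-step photobleaching is memoryless), the donor bleaching
    after the acceptor. The donor count rate rises by tau_D/tau_DA on
    acceptor bleaching (loss of the FRET de-excitation path). The
    ground-truth table records the realized state, lifetime and bleach
    times per molecule.
    """
    if n_molecules <= 0:
        raise ValueError("n_molecules must be positive")
    weights = spec.weights(condition)
    streams = []
    rows = []
    for m in range(n_molecules):
        rng = np.random.default_rng([int(seed), m])  # counter-derived substream
        state = int(rng.choice(len(weights), p=weights))
        lifetime = float(
            _positive_normal(rng, spec.means[state], spec.widths[state], 1)[0]
        )
        ab = float(rng.exponential(mol_template.acceptor_bleach_time))
        db = ab + float(
            rng.exponential(
                max(mol_template.donor_bleach_time - mol_template.acceptor_bleach_time, 1e-6)
            )
        )
        # donor de-quenching on acceptor bleach: rate scales by tau_D/tau_DA
        # (=1/(1-E)); lifetimes at/above tau_D mean E <= 0, i.e. no transfer
        # and no rate change
        dequench = max(mol_template.lifetime_donor_only_ns / lifetime, 1.0)
        mol = replace(
            mol_template,
            state_index=state,
            lifetime_fret_ns=lifetime,
            acceptor_bleach_time=ab,
            donor_bleach_time=db,
            donor_rate_postbleach=mol_template.donor_rate_fret * dequench,
        )
        stream = simulate_photon_stream(mol, tcspc, duration, seed=rng)
        stream.molecule_id = m
        stream.meta["condition"] = condition
        streams.append(stream)
        rows.append(
            {
                "molecule_id": m,
                "condition": condition,
                "state": state,
                "lifetime_ns": lifetime,
                "acceptor_bleach_s": ab,
                "donor_bleach_s": db,
            }
        )
    return streams, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Langevin umbrella sampling


@dataclass
class LandscapeSpec:
    """1-D landscape sampled by overdamped Langevin dynamics under harmonic
    umbrella biases. ``potential`` returns energy in kT; ``windows`` is a
    list of (center, spring_k in kT/unit^2)."""

    potential: Callable[[float], float]
    windows: Sequence[tuple[float, float]]
    n_steps: int = 200000
    step_size: float = 0.01
    friction: float = 1.0
    burn_in: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_steps <= 0:
            raise ValueError("n_steps must be positive")
        if len(self.windows) == 0:
            raise ValueError("need at least one window")
        if any(k < 0 for _, k in self.windows):
            raise ValueError("spring constants must be non-negative")


def _grad(potential: Callable, x: float, h: float = 1e-5) -> float:
    return (potential(x + h) - potential(x - h)) / (2 * h)


def simulate_langevin_cv(spec: LandscapeSpec) -> list[UmbrellaWindow]:
    """Euler–Maruyama overdamped Langevin series per umbrella window.

    dx = -(dt/gamma) d(U + bias)/dx + sqrt(2 dt/gamma) xi; the stationary
    law of each window approaches exp(-[U(x) + k/2 (x-c)^2]) for small
    steps and long runs. Deterministic given ``spec.seed``.
    """
    out = []
    dt = spec.step_size
    mob = dt / spec.friction
    noise_sd = np.sqrt(2 * mob)
    for w_index, (center, k) in enumerate(spec.windows):
        rng = np.random.default_rng([int(spec.seed), w_index])
        x = center
        xs = np.empty(spec.n_steps)
        noise = rng.standard_normal(spec.n_steps + spec.burn_in) * noise_sd
        for i in range(spec.n_steps + spec.burn_in):
            force = -_grad(spec.potential, x) - k * (x - center)
            x = x + mob * force + noise[i]
            if i >= spec.burn_in:
                xs[i - spec.burn_in] = x
        out.append(UmbrellaWindow(center=center, spring_k=k, cv_series=xs))
    return out


# ---------------------------------------------------------------------------
# Coarse-grained frames


def make_cg_frame(
    n_lipid_beads: int,
    protein_bead_spec: Mapping[int, np.ndarray] | Sequence[tuple[int, Sequence[float]]],
    box: Sequence[float],
    seed=None,
) -> TrajectoryFrame:
    """Build a frame with uniform lipid beads and caller-placed protein beads.

    ``protein_bead_spec`` maps residue id -> one or more (x, y, z) positions
    in Angstrom (or a sequence of (resid, xyz) pairs). Protein beads must
    lie inside the box.
    """
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError("box edges must be positive")
    rng = _rng(seed)
    if isinstance(protein_bead_spec, Mapping):
        items = [(r, np.atleast_2d(np.asarray(c, float))) for r, c in protein_bead_spec.items()]
    else:
        items = [(r, np.atleast_2d(np.asarray(c, float))) for r, c in protein_bead_spec]
    prot_coords, prot_res = [], []
    for resid, coords in items:
        if np.any(coords < 0) or np.any(coords > box):
            raise ValueError(f"protein bead of residue {resid} outside box")
        prot_coords.append(coords)
        prot_res.extend([resid] * len(coords))
    lipids = rng.uniform(0, box, size=(n_lipid_beads, 3))
    coords = np.vstack([lipids] + prot_coords) if prot_coords else lipids
    kinds = np.array(
        ["lipid"] * n_lipid_beads + ["protein"] * len(prot_res), dtype=object
    )
    resids = np.array([0] * n_lipid_beads + prot_res, dtype=int)
    return TrajectoryFrame(
        coordinates=coords, bead_kind=kinds, residue_id=resids, box=box, periodic=True
    )


def default_protein_bead_spec(
    box: Sequence[float], seed=None
) -> dict[int, np.ndarray]:
    """ATP-site residues plus residues 721 and 1186 scattered in the lower
    half of the box — a convenient fixture layout for contact counting."""
    rng = _rng(seed)
    box = np.asarray(box, dtype=float)
    residues = sorted(ATP_SITE_RESIDUES) + [721, 1186]
    center = box * np.array([0.5, 0.5, 0.25])
    spread = min(box) * 0.1
    out = {}
    for r in residues:
        pos = np.clip(center + rng.normal(0, spread, size=3), 0, box * (1 - 1e-9))
        out[r] = pos[None, :]
    return out
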