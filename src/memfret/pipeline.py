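"""End-to-end orchestration: simulate -> segment -> fit -> convert -> model.

A single :class:`RunConfig` (YAML-loadable) drives the stages; all
randomness flows from one top-level seed, every artifact is written with
provenance (config hash, seed, package version), and a machine-readable
JSON report collects the fitted parameters, BIC table, Ashman matrix,
distance table and EGF amplitude-change table.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fret import FretParams, distance_table, median_distance_ci
from .lifetimes import (
    DEFAULT_BUNCH_SIZE,
    bunch_photons,
    fit_decay_mle,
    fits_table,
)
from .photon_io import write_photon_csv
from .segmentation import (
    bin_photons,
    detect_changepoints,
    fret_nanotimes,
    segments_table,
    select_traces,
)
from .statemodel import (
    comparisons_table,
    egf_amplitude_change,
    fit_global_mixture,
    select_k,
)
from .synthetic import (
    MixtureSpec,
    MoleculeSim,
    TcspcSpec,
    default_mixture_spec,
    simulate_condition,
)

logger = logging.getLogger("memfret")

__all__ = ["RunConfig", "RunReport", "run_pipeline", "write_report", "load_config"]

ALL_STAGES = ("simulate", "segment", "fit", "convert", "model", "report")


@dataclass
class ConditionConfig:
    label: str
    egf: bool
    pair_with: str | None = None  # label of the matching -EGF condition
    weights: list[float] | None = None  # None -> preset amplitudes by label


@dataclass
class RunConfig:
    conditions: list[ConditionConfig]
    n_molecules: int = 200
    duration_s: float = 8.0
    bin_width_s: float = 0.1
    alpha: float = 0.01
    bunch_size: int = DEFAULT_BUNCH_SIZE
    n_boot: int = 10000
    r0_nm: float = 8.4
    tau_d_ns: float = 3.02
    donor_rate_fret: float = 3000.0
    acceptor_rate: float = 2000.0
    background_rate: float = 30.0
    acceptor_bleach_mean_s: float = 2.0
    donor_bleach_mean_s: float = 4.0
    tcspc: TcspcSpec = field(default_factory=lambda: TcspcSpec(background_fraction=0.02))
    candidate_k: tuple[int, ...] = (1, 2, 3)
    stages: tuple[str, ...] = ALL_STAGES
    write_photons: bool = False

    def mixture_spec(self) -> MixtureSpec:
        preset = default_mixture_spec()
        weights = {}
        for cond in self.conditions:
            if cond.weights is not None:
                weights[cond.label] = cond.weights
            else:
                weights[cond.label] = preset.weights_per_condition[cond.label]
        return MixtureSpec(
            means=preset.means, widths=preset.widths, weights_per_condition=weights
        )

    def molecule_template(self) -> MoleculeSim:
        return MoleculeSim(
            donor_rate_fret=self.donor_rate_fret,
            acceptor_rate=self.acceptor_rate,
            background_rate=self.background_rate,
            acceptor_bleach_time=self.acceptor_bleach_mean_s,
            donor_bleach_time=self.donor_bleach_mean_s,
            lifetime_donor_only_ns=self.tau_d_ns,
        )

    def effective_background_fraction(self) -> float:
        """Nanotime background fraction seen by the fitter in the FRET stage:
        dark counts plus the TCSPC uniform component (the 'blank')."""
        total = self.background_rate + self.donor_rate_fret
        return (
            self.background_rate
            + self.tcspc.background_fraction * self.donor_rate_fret
        ) / total

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    conditions = [ConditionConfig(**c) for c in raw.pop("conditions")]
    tcspc = TcspcSpec(**raw.pop("tcspc", {}))
    for key in ("candidate_k", "stages"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(conditions=conditions, tcspc=tcspc, **raw)


@dataclass
class RunReport:
    seed: int
    config_hash: str
    version: str
    counts: dict = field(default_factory=dict)
    model: dict | None = None
    two_state: dict | None = None
    bic_table: list | None = None
    ashman: list | None = None
    distances: pd.DataFrame | None = None
    comparisons: pd.DataFrame | None = None
    lifetimes: dict[str, np.ndarray] = field(default_factory=dict)
    truth: pd.DataFrame | None = None


def run_pipeline(config: RunConfig, seed: int = 0, outdir=None) -> RunReport:
    """Execute the enabled stages in order; idempotent given (config, seed).

    Raises with a stage-tagged error on failure; artifacts written before
    the failure are preserved.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=seed, config_hash=config.config_hash(), version=__version__)
    stages = config.stages
    spec = config.mixture_spec()
    tmpl = config.molecule_template()
    bg_per_bin = config.background_rate * config.bin_width_s
    b_eff = config.effective_background_fraction()

    streams_by_cond: dict[str, list] = {}
    truth_frames = []
    try:
        if "simulate" in stages:
            for ci, cond in enumerate(config.conditions):
                streams, truth = simulate_condition(
                    spec,
                    cond.label,
                    config.n_molecules,
                    tmpl,
                    config.tcspc,
                    duration=config.duration_s,
                    seed=_stage_seed(seed, 1, ci),
                )
                streams_by_cond[cond.label] = streams
                truth_frames.append(truth)
                logger.info("simulate: %s -> %d molecules", cond.label, len(streams))
            report.truth = pd.concat(truth_frames, ignore_index=True)
            if out is not None:
                report.truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
                if config.write_photons:
                    for cond, streams in streams_by_cond.items():
                        safe = cond.replace("%", "pct").replace(" ", "_")
                        write_photon_csv(streams, out / f"photons_{safe}.csv")
    except Exception as err:  # pragma: no cover - defensive tagging
        raise RuntimeError(f"stage 'simulate' failed: {err}") from err

    nanotimes_by_cond: dict[str, list] = {}
    seg_rows, sel_rows = [], []
    if "segment" in stages:
        try:
            for ci, cond in enumerate(config.conditions):
                kept = 0
                nanotimes_by_cond[cond.label] = []
                for stream in streams_by_cond[cond.label]:
                    trace = bin_photons(stream, config.bin_width_s)
                    if trace.n_bins < 2:
                        continue
                    cal = _stage_seed(seed, 2, ci * 100003 + stream.molecule_id)
                    segs_d = detect_changepoints(
                        trace.counts_donor, config.alpha, calibration_seed=cal
                    )
                    segs_a = detect_changepoints(
                        trace.counts_acceptor, config.alpha, calibration_seed=cal + 1
                    )
                    sel = select_traces(trace, segs_d, segs_a, bg_per_bin)
                    seg_rows.append(segments_table(stream.molecule_id, "donor", segs_d))
                    seg_rows.append(segments_table(stream.molecule_id, "acceptor", segs_a))
                    sel_rows.append(
                        {
                            "condition": cond.label,
                            "molecule_id": stream.molecule_id,
                            "accepted": sel.accepted,
                            "rejection_reason": sel.rejection_reason or "",
                        }
                    )
                    if sel.accepted:
                        kept += 1
                        nanotimes_by_cond[cond.label].append(
                            (stream.molecule_id, fret_nanotimes(stream, sel))
                        )
                logger.info(
                    "segment: %s accepted %d/%d molecules", cond.label, kept,
                    len(streams_by_cond[cond.label]),
                )
                report.counts[cond.label] = {
                    "molecules": len(streams_by_cond[cond.label]),
                    "accepted": kept,
                }
            if out is not None:
                pd.concat(seg_rows, ignore_index=True).to_csv(
                    out / "segments.tsv", sep="\t", index=False
                )
                pd.DataFrame(sel_rows).to_csv(out / "selection.tsv", sep="\t", index=False)
        except Exception as err:
            raise RuntimeError(f"stage 'segment' failed: {err}") from err

    if "fit" in stages:
        try:
            all_fits = []
            for cond in config.conditions:
                taus = []
                for mol_id, nts in nanotimes_by_cond[cond.label]:
                    for bunch in bunch_photons(nts, config.bunch_size, molecule_id=mol_id):
                        fit = fit_decay_mle(bunch, config.tcspc, b_eff)
                        all_fits.append((cond.label, fit))
                        if fit.converged:
                            taus.append(fit.lifetime)
                report.lifetimes[cond.label] = np.asarray(taus)
                report.counts.setdefault(cond.label, {})["bunches"] = len(taus)
                logger.info("fit: %s -> %d converged bunches", cond.label, len(taus))
            if out is not None:
                tbl = fits_table([f for _, f in all_fits])
                tbl.insert(0, "condition", [c for c, _ in all_fits])
                tbl.to_csv(out / "bunch_fits.tsv", sep="\t", index=False)
        except Exception as err:
            raise RuntimeError(f"stage 'fit' failed: {err}") from err

    if "convert" in stages:
        try:
            params = FretParams(r0=config.r0_nm, tau_d=config.tau_d_ns)
            estimates = [
                median_distance_ci(
                    taus,
                    params,
                    n_boot=config.n_boot,
                    seed=_stage_seed(seed, 3, ci),
                    condition=cond,
                )
                for ci, (cond, taus) in enumerate(report.lifetimes.items())
                if len(taus) >= 10
            ]
            report.distances = distance_table(estimates)
            if out is not None:
                report.distances.to_csv(out / "distances.tsv", sep="\t", index=False)
        except Exception as err:
            raise RuntimeError(f"stage 'convert' failed: {err}") from err

    if "model" in stages:
        try:
            usable = {
                c: t
                for c, t in report.lifetimes.items()
                if len(t) >= 10 * max(config.candidate_k)
            }
            models = [
                fit_global_mixture(usable, k, seed=_stage_seed(seed, 4, k))
                for k in config.candidate_k
            ]
            chosen = select_k(models) if len(models) > 1 else models[0]
            # the open/compact equilibrium is defined on the two-state model;
            # amplitude comparisons use the k=2 fit even if BIC prefers
            # another k (the BIC table reports the full comparison)
            two_state = next((m for m in models if m.k == 2), chosen)
            report.bic_table = [
                {"k": m.k, "log_likelihood": m.log_likelihood, "bic": m.bic}
                for m in models
            ]
            report.model = {
                "k": chosen.k,
                "means_ns": chosen.means.tolist(),
                "sigmas_ns": chosen.sigmas.tolist(),
                "weights": {c: w.tolist() for c, w in chosen.weights.items()},
                "log_likelihood": chosen.log_likelihood,
                "bic": chosen.bic,
                "n_total": chosen.n_total,
            }
            report.ashman = chosen.ashman_d.tolist() if chosen.k >= 2 else None
            if two_state.k == 2:
                report.two_state = {
                    "means_ns": two_state.means.tolist(),
                    "sigmas_ns": two_state.sigmas.tolist(),
                    "open_fraction": {
                        c: two_state.open_fraction(c) for c in two_state.weights
                    },
                }
            pairs = [
                (c.pair_with, c.label)
                for c in config.conditions
                if c.egf and c.pair_with and c.pair_with in two_state.weights
                and c.label in two_state.weights
            ]
            if pairs and two_state.k == 2:
                report.comparisons = comparisons_table(
                    egf_amplitude_change(two_state, pairs)
                )
                if out is not None:
                    report.comparisons.to_csv(
                        out / "amplitude_changes.tsv", sep="\t", index=False
                    )
            logger.info(
                "model: selected k=%d, means=%s", chosen.k,
                np.round(chosen.means, 3).tolist(),
            )
        except Exception as err:
            raise RuntimeError(f"stage 'model' failed: {err}") from err

    if "report" in stages and out is not None:
        write_report(report, out / "report.json")
    return report


def write_report(report: RunReport, path) -> dict:
    """Serialize a run report as JSON (returns the written dict)."""
    doc = {
        "provenance": {
            "seed": report.seed,
            "config_hash": report.config_hash,
            "version": report.version,
        },
        "counts": report.counts,
        "model": report.model,
        "two_state": report.two_state,
        "bic_table": report.bic_table,
        "ashman_d": report.ashman,
        "distance_table": (
            report.distances.to_dict(orient="records")
            if report.distances is not None
            else []
        ),
        "amplitude_changes": (
            report.comparisons.to_dict(orient="records")
            if report.comparisons is not None
            else []
        ),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
    return doc


def _stage_seed(seed: int, stage: int, index: int) -> int:
    """Derive a sub-seed < 2^31 from (run seed, stage, index)."""
    h = hashlib.sha256(f"{seed}:{stage}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)
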