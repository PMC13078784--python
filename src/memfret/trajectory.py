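"""Post-simulation metrics for coarse-grained membrane-receptor trajectories.

Implements the accessibility and reweighting analyses run on coarse-grained
frames of a membrane-embedded receptor: lipid contacts with the ATP-binding
site (a steric proxy for nucleotide accessibility), the kinase-site to
C-terminus residue distance, WHAM reweighting of umbrella-biased collective
variable (CV) series, and three-partition block error estimates.

Distances are stored in Angstrom internally; residue distances are reported
in nm. Periodic frames use the minimum-image convention on an orthorhombic
box.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

__all__ = [
    "ATP_SITE_RESIDUES",
    "TrajectoryFrame",
    "UmbrellaWindow",
    "WhamResult",
    "BlockEstimate",
    "count_atp_site_contacts",
    "residue_distance",
    "wham_reweight",
    "block_stats",
    "write_gro",
    "read_gro",
    "write_xyz_table",
    "read_xyz_table",
]

#: Residues forming the ATP-binding pocket of the receptor kinase domain.
ATP_SITE_RESIDUES = frozenset(
    list(range(694, 704)) + [719] + list(range(766, 770)) + [772, 773, 817, 820, 831]
)

#: Default lipid/ATP-site contact cutoff (Angstrom), set by the molecular
#: radius of the fluorescent ATP analogue used in the binding assay (~17 A).
CONTACT_CUTOFF_A = 16.0


@dataclass
class TrajectoryFrame:
    """One coarse-grained frame: labelled beads in an orthorhombic box.

    Parameters
    ----------
    coordinates : (n, 3) array, Angstrom.
    bead_kind : (n,) array of {"lipid", "protein", "solvent"}.
    residue_id : (n,) int array; 0 for non-protein beads.
    box : (3,) edge lengths in Angstrom, or None for a non-periodic frame.
    periodic : whether the minimum-image convention applies.
    """

    coordinates: np.ndarray
    bead_kind: np.ndarray
    residue_id: np.ndarray
    box: np.ndarray | None = None
    periodic: bool = False

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        self.bead_kind = np.asarray(self.bead_kind, dtype=object)
        self.residue_id = np.asarray(self.residue_id, dtype=int)
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if np.any(self.box <= 0):
                raise ValueError("box edge lengths must be positive")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        if len(self.bead_kind) != len(self.coordinates) or len(self.residue_id) != len(
            self.coordinates
        ):
            raise ValueError("bead_kind/residue_id must match coordinate count")
        if np.any(self.residue_id < 0):
            raise ValueError("residue ids must be non-negative")
        if self.periodic and self.box is None:
            raise ValueError("periodic frame requires a box")

    @property
    def n_beads(self) -> int:
        return len(self.coordinates)

    def beads_of_kind(self, kind: str) -> np.ndarray:
        return self.coordinates[self.bead_kind == kind]

    def protein_coords(self, residues: Sequence[int] | frozenset) -> np.ndarray:
        mask = (self.bead_kind == "protein") & np.isin(self.residue_id, list(residues))
        return self.coordinates[mask]


def _min_image_delta(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    return delta - box * np.round(delta / box)


def _pair_distances(a: np.ndarray, b: np.ndarray, frame: TrajectoryFrame) -> np.ndarray:
    delta = a[:, None, :] - b[None, :, :]
    if frame.periodic:
        delta = _min_image_delta(delta, frame.box)
    return np.sqrt((delta**2).sum(axis=-1))


def count_atp_site_contacts(
    frame: TrajectoryFrame,
    atp_site_residues: Sequence[int] | frozenset = ATP_SITE_RESIDUES,
    cutoff: float = CONTACT_CUTOFF_A,
) -> int:
    """Count (lipid bead, ATP-site bead) pairs strictly closer than ``cutoff``.

    The contact number is a steric proxy for ATP-site accessibility: the
    more lipid beads crowd the pocket residues, the less accessible the
    site. Periodic frames use minimum-image distances. Uses a cell-list
    (kd-tree) candidate search followed by an exact strict-inequality
    distance filter, so the result equals the O(N^2) definition.
    """
    lipids = frame.beads_of_kind("lipid")
    site = frame.protein_coords(atp_site_residues)
    if len(lipids) == 0 or len(site) == 0:
        raise ValueError("frame must contain lipid beads and ATP-site beads")
    if frame.periodic:
        box = frame.box
        # cKDTree with boxsize needs coordinates wrapped into [0, box)
        lw = np.mod(lipids, box)
        sw = np.mod(site, box)
        tree = cKDTree(lw, boxsize=box)
        candidates = tree.query_ball_point(sw, r=cutoff)
        count = 0
        for si, idx in enumerate(candidates):
            if not idx:
                continue
            d = _min_image_delta(lw[idx] - sw[si], box)
            count += int(np.sum(np.sqrt((d**2).sum(axis=1)) < cutoff))
        return count
    d = _pair_distances(site, lipids, frame)
    return int(np.sum(d < cutoff))


def residue_distance(
    frame: TrajectoryFrame,
    res_a: int = 721,
    res_b: int = 1186,
    mode: str = "centroid",
) -> float:
    """Distance (nm) between two protein residues' bead centroids.

    Residue 721 flanks the ATP-binding site and residue 1186 is the receptor
    C-terminus, so this pair tracks how far the disordered tail sits from
    the kinase domain. With ``mode="centroid"`` multi-bead residues are
    reduced to their centroid (beads re-imaged relative to the first bead
    so a residue straddling the boundary is not torn apart); ``mode="first"``
    uses the first (backbone) bead.
    """
    out = []
    for res in (res_a, res_b):
        coords = frame.protein_coords([res])
        if len(coords) == 0:
            raise ValueError(f"residue {res} not present in frame")
        if mode == "first":
            out.append(coords[0])
        elif mode == "centroid":
            ref = coords[0]
            rel = coords - ref
            if frame.periodic:
                rel = _min_image_delta(rel, frame.box)
            out.append(ref + rel.mean(axis=0))
        else:
            raise ValueError(f"unknown mode {mode!r}")
    delta = out[0] - out[1]
    if frame.periodic:
        delta = _min_image_delta(delta, frame.box)
    return float(np.linalg.norm(delta)) / 10.0


# ---------------------------------------------------------------------------
# Umbrella sampling / WHAM


@dataclass
class UmbrellaWindow:
    """A harmonically biased CV series: bias U_b(x) = k/2 (x - c)^2 in kT."""

    center: float
    spring_k: float
    cv_series: np.ndarray

    def __post_init__(self) -> None:
        self.cv_series = np.asarray(self.cv_series, dtype=float)
        if self.spring_k < 0:
            raise ValueError("spring constant must be non-negative")
        if self.cv_series.size == 0:
            raise ValueError("cv_series must be non-empty")

    def bias(self, x: np.ndarray) -> np.ndarray:
        return 0.5 * self.spring_k * (np.asarray(x) - self.center) ** 2


@dataclass
class WhamResult:
    bin_centers: np.ndarray
    probability: np.ndarray        # unbiased probability per bin (sums to 1)
    pmf: np.ndarray                # -kT ln p, shifted so min = 0 (units of kT*kT_scale)
    window_free_energies: np.ndarray
    n_iterations: int
    kT: float
    reweighted_mean: float | None = None
    sample_weights: np.ndarray | None = None


def wham_reweight(
    windows: Sequence[UmbrellaWindow],
    bins: int | np.ndarray = 100,
    kT: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 100000,
    observable: Sequence[np.ndarray] | Callable[[np.ndarray], np.ndarray] | None = None,
) -> WhamResult:
    """Self-consistent WHAM over harmonically biased 1-D windows.

    Iterates the standard coupled equations

        p(x_m) = sum_w n_w(x_m) / sum_w N_w exp(f_w - u_w(x_m))
        exp(-f_w) = sum_m p(x_m) exp(-u_w(x_m))

    (bias energies ``u`` in kT) until the largest change in any window free
    energy f_w is below ``tol``. The PMF is ``-kT ln p`` shifted to zero at
    its minimum. If ``observable`` is given (one array per window aligned
    with its samples, or a callable of the CV), the unbiased mean is
    computed with per-sample weights ``w_i ∝ 1 / sum_w N_w exp(f_w - u_w(x_i))``.
    """
    windows = list(windows)
    if len(windows) == 0:
        raise ValueError("need at least one window")
    samples = [w.cv_series for w in windows]
    all_x = np.concatenate(samples)
    if np.isscalar(bins):
        edges = np.linspace(all_x.min(), all_x.max(), int(bins) + 1)
        # widen the last edge marginally so the max sample lands inside
        edges[-1] = np.nextafter(edges[-1], np.inf)
    else:
        edges = np.asarray(bins, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])

    counts = np.array([np.histogram(x, bins=edges)[0] for x in samples], dtype=float)
    n_w = counts.sum(axis=1)  # samples per window inside the range
    if np.any(n_w == 0):
        raise ValueError("a window has no samples inside the histogram range")

    # Overlap diagnostic: windows must form one connected component through
    # shared occupied bins, otherwise relative free energies are undefined.
    occupied = counts > 0
    adj = (occupied @ occupied.T) > 0
    n_comp, _ = connected_components(adj, directed=False)
    if n_comp > 1:
        raise ValueError(
            f"umbrella windows do not overlap: {n_comp} disconnected groups "
            "of windows share no histogram bins"
        )

    bias = np.array([w.bias(centers) for w in windows])  # (W, M), in kT
    total = counts.sum(axis=0)
    f = np.zeros(len(windows))
    for it in range(1, max_iter + 1):
        # log-denominator per bin, stabilized
        log_terms = np.log(n_w)[:, None] + f[:, None] - bias  # (W, M)
        log_denom = _logsumexp(log_terms, axis=0)
        with np.errstate(divide="ignore"):
            log_p = np.where(total > 0, np.log(total) - log_denom, -np.inf)
        log_p -= _logsumexp(log_p)
        f_new = -_logsumexp(log_p[None, :] - bias, axis=1)
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol:
            break
    else:
        raise RuntimeError(f"WHAM did not converge in {max_iter} iterations")

    p = np.exp(log_p)
    with np.errstate(divide="ignore"):
        pmf = -kT * log_p
    pmf -= pmf.min()

    reweighted = None
    weights = None
    if observable is not None:
        if callable(observable):
            obs = [observable(x) for x in samples]
        else:
            obs = [np.asarray(o, dtype=float) for o in observable]
            if len(obs) != len(windows) or any(
                len(o) != len(x) for o, x in zip(obs, samples)
            ):
                raise ValueError("observable must align with window samples")
        log_w = [
            -_logsumexp(
                np.log(n_w)[:, None] + f[:, None] - np.array([w.bias(x) for w in windows]),
                axis=0,
            )
            for x in samples
        ]
        lw = np.concatenate(log_w)
        lw -= lw.max()
        w_i = np.exp(lw)
        w_i /= w_i.sum()
        reweighted = float(np.dot(w_i, np.concatenate(obs)))
        weights = w_i

    return WhamResult(
        bin_centers=centers,
        probability=p,
        pmf=pmf,
        window_free_energies=f * kT,
        n_iterations=it,
        kT=kT,
        reweighted_mean=reweighted,
        sample_weights=weights,
    )


def _logsumexp(a: np.ndarray, axis: int | None = None) -> np.ndarray:
    from scipy.special import logsumexp

    return logsumexp(a, axis=axis)


# ---------------------------------------------------------------------------
# Block errors


@dataclass
class BlockEstimate:
    """Overall statistic plus a [min, max] interval over contiguous blocks."""

    value: float
    block_values: np.ndarray
    low: float
    high: float


_REDUCERS = {"mean": np.mean, "median": np.median}


def block_stats(
    series: Sequence[float], n_blocks: int = 3, reducer: str = "mean"
) -> BlockEstimate:
    """Split a series into ``n_blocks`` contiguous equal parts and report the
    overall statistic with the block min/max as the error interval.

    The remainder of an uneven split goes to the last block. This is the
    three-equal-partition error bar convention used for simulation
    observables.
    """
    x = np.asarray(series, dtype=float)
    if x.size < n_blocks:
        raise ValueError(f"series of length {x.size} cannot form {n_blocks} blocks")
    if reducer not in _REDUCERS:
        raise ValueError(f"reducer must be one of {sorted(_REDUCERS)}")
    fn = _REDUCERS[reducer]
    size = x.size // n_blocks
    blocks = [x[i * size : (i + 1) * size] for i in range(n_blocks - 1)]
    blocks.append(x[(n_blocks - 1) * size :])
    vals = np.array([fn(b) for b in blocks])
    return BlockEstimate(
        value=float(fn(x)),
        block_values=vals,
        low=float(vals.min()),
        high=float(vals.max()),
    )


# ---------------------------------------------------------------------------
# Frame I/O: minimal GRO-format text and a flat labelled-XYZ table

_KIND_TO_RESNAME = {"lipid": "LIP", "protein": "PRO", "solvent": "SOL"}
_RESNAME_TO_KIND = {v: k for k, v in _KIND_TO_RESNAME.items()}


def write_gro(frame: TrajectoryFrame, path, title: str = "memfret frame") -> None:
    """Write a frame as GRO-format text (positions in nm)."""
    lines = [title, f"{frame.n_beads:5d}"]
    lip_res = 0
    for i in range(frame.n_beads):
        kind = frame.bead_kind[i]
        resname = _KIND_TO_RESNAME.get(kind, "UNK")
        if kind == "protein":
            resid = int(frame.residue_id[i])
        else:
            lip_res += 1
            resid = lip_res
        x, y, z = frame.coordinates[i] / 10.0
        name = "BB" if kind == "protein" else kind[:1].upper() + "1"
        lines.append(
            f"{resid % 100000:5d}{resname:<5s}{name:>5s}{(i + 1) % 100000:5d}"
            f"{x:8.3f}{y:8.3f}{z:8.3f}"
        )
    box = frame.box if frame.box is not None else np.zeros(3)
    lines.append(f"{box[0] / 10.0:10.5f}{box[1] / 10.0:10.5f}{box[2] / 10.0:10.5f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gro(path, periodic: bool | None = None) -> TrajectoryFrame:
    """Read a GRO-format frame written by :func:`write_gro` (returns Angstrom)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    n = int(lines[1])
    coords = np.empty((n, 3))
    kinds = np.empty(n, dtype=object)
    resids = np.zeros(n, dtype=int)
    for i, line in enumerate(lines[2 : 2 + n]):
        resid = int(line[0:5])
        resname = line[5:10].strip()
        coords[i] = [float(line[20:28]), float(line[28:36]), float(line[36:44])]
        kind = _RESNAME_TO_KIND.get(resname, "solvent")
        kinds[i] = kind
        resids[i] = resid if kind == "protein" else 0
    coords *= 10.0
    box = np.array([float(v) for v in lines[2 + n].split()[:3]]) * 10.0
    has_box = np.all(box > 0)
    return TrajectoryFrame(
        coordinates=coords,
        bead_kind=kinds,
        residue_id=resids,
        box=box if has_box else None,
        periodic=bool(has_box) if periodic is None else periodic,
    )


def write_xyz_table(frame: TrajectoryFrame, path) -> None:
    """Write a flat labelled coordinate table (TSV, Angstrom)."""
    df = pd.DataFrame(
        {
            "bead_kind": frame.bead_kind,
            "residue_id": frame.residue_id,
            "x_A": frame.coordinates[:, 0],
            "y_A": frame.coordinates[:, 1],
            "z_A": frame.coordinates[:, 2],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_xyz_table(path, box=None, periodic: bool = False) -> TrajectoryFrame:
    df = pd.read_csv(path, sep="\t")
    return TrajectoryFrame(
        coordinates=df[["x_A", "y_A", "z_A"]].to_numpy(),
        bead_kind=df["bead_kind"].to_numpy(dtype=object),
        residue_id=df["residue_id"].to_numpy(dtype=int),
        box=box,
        periodic=periodic,
    )
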