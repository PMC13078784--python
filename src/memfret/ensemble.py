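"""Relative ATP binding from gel-band intensities.

The bound fluorescent ATP analogue band (atto647N) is normalized per
replicate by the receptor-production band (snap surface 488, which labels
the receptor stoichiometrically); the reported value is the mean ratio
over biological replicates with its standard error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["BandQuantification", "normalize_atp_binding", "quantify_conditions"]


@dataclass
class BandQuantification:
    condition: str | None
    ratios: np.ndarray
    mean_ratio: float
    sem: float  # NaN for a single replicate

    @property
    def n_replicates(self) -> int:
        return len(self.ratios)


def normalize_atp_binding(
    atto647n: Sequence[float],
    ss488: Sequence[float],
    condition: str | None = None,
) -> BandQuantification:
    """Per-replicate atto647N/ss488 intensity ratio, mean and SEM.

    Intensities must be positive and paired; the common-exposure scale
    cancels in the ratio.
    """
    a = np.asarray(atto647n, dtype=float)
    s = np.asarray(ss488, dtype=float)
    if a.shape != s.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("atto647N and ss488 must be equal-length non-empty vectors")
    if np.any(a <= 0) or np.any(s <= 0):
        raise ValueError("band intensities must be positive")
    ratios = a / s
    sem = float(ratios.std(ddof=1) / np.sqrt(ratios.size)) if ratios.size > 1 else float("nan")
    return BandQuantification(
        condition=condition,
        ratios=ratios,
        mean_ratio=float(ratios.mean()),
        sem=sem,
    )


def quantify_conditions(df: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`normalize_atp_binding` per condition of a replicate table
    with columns (condition, replicate, atto647N, ss488)."""
    rows = []
    for cond, sub in df.groupby("condition", sort=False):
        q = normalize_atp_binding(
            sub["atto647N"].to_numpy(), sub["ss488"].to_numpy(), condition=cond
        )
        rows.append(
            {"condition": cond, "mean_ratio": q.mean_ratio, "sem": q.sem, "n": q.n_replicates}
        )
    return pd.DataFrame(rows)
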