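"""Spearman correlation between the two municipal quality measures,
overall and stratified by socioeconomic-index quartile.

The analysis deliberately reports no p-values or confidence intervals:
the municipalities constitute the whole population under study, not a
sample from one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "StratifiedCorrelation",
    "spearman",
    "quartile_assign",
    "stratified_correlation",
]

QUARTILE_LABELS = ["Q1", "Q2", "Q3", "Q4"]


@dataclass(frozen=True)
class StratifiedCorrelation:
    overall_rho: float
    per_quartile_rho: tuple[float, float, float, float]  # NaN when undefined
    quartile_bounds: tuple[float, float, float]
    n_per_quartile: tuple[int, int, int, int]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"stratum": "overall", "rho": self.overall_rho, "n": sum(self.n_per_quartile)}]
        for label, rho, n in zip(QUARTILE_LABELS, self.per_quartile_rho, self.n_per_quartile):
            rows.append({"stratum": label, "rho": rho, "n": n})
        return pd.DataFrame(rows)


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Ties receive average ranks.  Inputs must be equal-length (>= 3) and
    not constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d sequences")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: rank correlation undefined")
    rx = rankdata(x, method="average")
    ry = rankdata(y, method="average")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))


def quartile_assign(index: Sequence[float]) -> np.ndarray:
    """Quartile labels Q1..Q4 from the p25/p50/p75 cut points of ``index``.

    Values <= p25 go to Q1, (p25, p50] to Q2, (p50, p75] to Q3, the rest
    to Q4.  With heavy ties the strata can collapse (a degenerate-strata
    warning is emitted); the partition property always holds.
    """
    values = np.asarray(index, dtype=float)
    if values.ndim != 1 or len(values) < 4:
        raise ValueError("need at least 4 values to form quartiles")
    cuts = np.percentile(values, [25, 50, 75])
    codes = np.searchsorted(cuts, values, side="left").clip(0, 3)
    labels = np.asarray(QUARTILE_LABELS, dtype=object)[codes]
    if len(np.unique(codes)) < 4:
        warnings.warn("degenerate strata: ties collapse one or more quartiles", stacklevel=2)
    return labels


def stratified_correlation(
    flaw_pct: Sequence[float],
    garbage_pct: Sequence[float],
    index: Sequence[float],
) -> StratifiedCorrelation:
    """Overall and per-quartile Spearman correlation of the two measures.

    A stratum with fewer than 3 members (or constant values) gets NaN.
    """
    flaw = np.asarray(flaw_pct, dtype=float)
    garbage = np.asarray(garbage_pct, dtype=float)
    idx = np.asarray(index, dtype=float)
    if not (len(flaw) == len(garbage) == len(idx)):
        raise ValueError("the three sequences must be aligned and equal-length")
    labels = quartile_assign(idx)
    cuts = tuple(np.percentile(idx, [25, 50, 75]))
    rhos, ns = [], []
    for label in QUARTILE_LABELS:
        mask = labels == label
        ns.append(int(mask.sum()))
        try:
            rhos.append(spearman(flaw[mask], garbage[mask]))
        except ValueError:
            rhos.append(float("nan"))
    return StratifiedCorrelation(
        overall_rho=spearman(flaw, garbage),
        per_quartile_rho=tuple(rhos),
        quartile_bounds=cuts,
        n_per_quartile=tuple(ns),
    )
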