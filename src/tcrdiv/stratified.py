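"""Descriptive cohort statistics: binned medians with bootstrap confidence
intervals, stratified and conditional curves, and rank correlations.

Medians are computed in fixed bins of a covariate (decade-wide age bins by
default), with percentile-bootstrap CIs from within-bin resampling, plus
central 50% and 90% empirical bands.  Spearman correlation uses mid-rank
tie handling via scipy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError

logger = logging.getLogger(__name__)

#: Bins with fewer subjects than this are flagged (median reported as NaN).
MIN_BIN_OCCUPANCY = 20

#: Default decade-wide age bin edges starting at 20.
DEFAULT_AGE_EDGES = [20, 30, 40, 50, 60, 70, 80]


@dataclass
class BinnedCurve:
    """Per-bin medians of y over bins of x, with bootstrap CIs and bands."""

    bin_edges: np.ndarray
    bin_medians: np.ndarray          # NaN where a bin is flagged
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_per_bin: np.ndarray
    stratum_label: str = ""
    band50: tuple[np.ndarray, np.ndarray] | None = None  # 25-75% quantiles
    band90: tuple[np.ndarray, np.ndarray] | None = None  # 5-95% quantiles
    flagged: np.ndarray = field(default_factory=lambda: np.empty(0, bool))

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low": self.bin_edges[:-1],
                "bin_high": self.bin_edges[1:],
                "n": self.n_per_bin,
                "median": self.bin_medians,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "stratum": self.stratum_label,
            }
        )


def binned_median_curve(
    x,
    y,
    edges,
    n_boot: int = 1000,
    seed: int = 0,
    stratum_label: str = "",
    ci_level: float = 0.95,
    min_occupancy: int = MIN_BIN_OCCUPANCY,
    bands: bool = False,
) -> BinnedCurve:
    """Median of y in bins of x with a percentile bootstrap CI per bin.

    Bins below ``min_occupancy`` (including empty bins) are flagged and
    their median reported as NaN rather than silently dropped.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    edges = np.asarray(edges, float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing with >= 2 values")
    rng = np.random.default_rng(seed)
    nb = len(edges) - 1
    medians = np.full(nb, np.nan)
    lo = np.full(nb, np.nan)
    hi = np.full(nb, np.nan)
    n_per = np.zeros(nb, int)
    flagged = np.zeros(nb, bool)
    q_lo, q_hi = 100 * (1 - ci_level) / 2, 100 * (1 + ci_level) / 2
    b50 = (np.full(nb, np.nan), np.full(nb, np.nan))
    b90 = (np.full(nb, np.nan), np.full(nb, np.nan))

    idx = np.digitize(x, edges) - 1
    idx[x == edges[-1]] = nb - 1  # right edge inclusive
    for b in range(nb):
        vals = y[idx == b]
        n_per[b] = vals.size
        if vals.size < max(min_occupancy, 1):
            flagged[b] = True
            if vals.size == 0:
                continue
        medians[b] = np.median(vals)
        if vals.size:
            boots = np.median(
                rng.choice(vals, size=(n_boot, vals.size), replace=True), axis=1
            )
            lo[b], hi[b] = np.percentile(boots, [q_lo, q_hi])
            if bands:
                b50[0][b], b50[1][b] = np.percentile(vals, [25, 75])
                b90[0][b], b90[1][b] = np.percentile(vals, [5, 95])
    if flagged.any():
        logger.info(
            "binned_median_curve[%s]: %d bin(s) below occupancy floor %d",
            stratum_label, int(flagged.sum()), min_occupancy,
        )
    return BinnedCurve(
        bin_edges=edges,
        bin_medians=medians,
        ci_low=lo,
        ci_high=hi,
        n_per_bin=n_per,
        stratum_label=stratum_label,
        band50=b50 if bands else None,
        band90=b90 if bands else None,
        flagged=flagged,
    )


def stratified_curves(
    cohort: pd.DataFrame,
    y: str,
    stratify_by: str,
    x: str,
    edges,
    n_boot: int = 1000,
    seed: int = 0,
    min_occupancy: int = MIN_BIN_OCCUPANCY,
) -> list[BinnedCurve]:
    """One binned-median curve of ``y`` vs ``x`` per level of ``stratify_by``.

    All curves share the same bin edges; central 50%/90% bands are attached.
    """
    for col in (y, stratify_by, x):
        if col not in cohort.columns:
            raise KeyError(f"column {col!r} not in cohort table")
    levels = sorted(cohort[stratify_by].astype(str).unique())
    if len(levels) == 1:
        logger.warning("stratified_curves: %r is constant; single curve", stratify_by)
    curves = []
    for j, level in enumerate(levels):
        sub = cohort[cohort[stratify_by].astype(str) == level]
        curves.append(
            binned_median_curve(
                sub[x], sub[y], edges,
                n_boot=n_boot, seed=seed + j, stratum_label=f"{stratify_by}={level}",
                min_occupancy=min_occupancy, bands=True,
            )
        )
    return curves


def conditional_median_grid(
    cohort: pd.DataFrame,
    y: str,
    x: str,
    condition_on: str,
    condition_edges,
    x_edges,
    n_boot: int = 200,
    seed: int = 0,
    min_occupancy: int = MIN_BIN_OCCUPANCY,
) -> list[BinnedCurve]:
    """Median y vs x within each bin of a conditioning metric.

    Returns one curve per conditioning bin, labelled by the bin interval;
    empty grid cells are flagged within each curve.
    """
    for col in (y, x, condition_on):
        if col not in cohort.columns:
            raise KeyError(f"column {col!r} not in cohort table")
    cond_edges = np.asarray(condition_edges, float)
    curves = []
    cvals = cohort[condition_on].to_numpy(float)
    idx = np.digitize(cvals, cond_edges) - 1
    idx[cvals == cond_edges[-1]] = len(cond_edges) - 2
    for b in range(len(cond_edges) - 1):
        sub = cohort[idx == b]
        label = f"{condition_on} in [{cond_edges[b]:g}, {cond_edges[b + 1]:g})"
        curves.append(
            binned_median_curve(
                sub[x], sub[y], x_edges,
                n_boot=n_boot, seed=seed + b, stratum_label=label,
                min_occupancy=min_occupancy,
            )
        )
    return curves


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation (mid-rank ties) with two-sided p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError("need at least 3 paired finite values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateInputError("Spearman correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
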