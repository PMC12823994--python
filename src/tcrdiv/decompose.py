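"""Measurement-error floor and intrinsic-scatter decomposition.

Repertoire size and diversity share correlated measurement errors, so the
measurement floor — the minimum achievable error, MAE — is estimated from
the ratio D/S: for paired repeat measurements of the same subjects, the
MAE is the standard deviation of the pair differences in log10(D/S).

A model whose residual scatter is sigma_r (dex) then carries intrinsic
biological scatter

    sigma_i = sqrt(sigma_r**2 - sigma_m**2),

the quadrature subtraction of the measurement floor sigma_m from the
residual.  All quantities are in dex (base-10 log units).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, OverSubtractionError
from .models import FitResult


@dataclass(frozen=True)
class VarianceDecomposition:
    """sigma_r = model residual; sigma_m = measurement floor; sigma_i intrinsic.

    fraction_unexplained is reported two ways: 1 - R²(CV) and the variance
    ratio (sigma_i / sigma_total)² where sigma_total is the cohort sd of
    log10 D after the same quadrature correction for measurement error.
    """

    sigma_r: float
    sigma_m: float
    sigma_i: float
    fraction_unexplained: float                   # 1 - r2_cv
    fraction_unexplained_variance_ratio: float | None = None

    def rounded(self, sig: int = 2) -> dict:
        return {k: round_sig(v, sig) for k, v in self.__dict__.items() if v is not None}


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (display convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def _pairs_to_arrays(replicate_pairs):
    """Accept a replicates DataFrame (S_1, D_1, S_2, D_2) or a sequence of
    ((D, S), (D, S)) pairs; return (d1, s1, d2, s2) arrays."""
    if isinstance(replicate_pairs, pd.DataFrame):
        df = replicate_pairs
        return (
            df["D_1"].to_numpy(float), df["S_1"].to_numpy(float),
            df["D_2"].to_numpy(float), df["S_2"].to_numpy(float),
        )
    pairs = list(replicate_pairs)
    d1 = np.array([p[0][0] for p in pairs], float)
    s1 = np.array([p[0][1] for p in pairs], float)
    d2 = np.array([p[1][0] for p in pairs], float)
    s2 = np.array([p[1][1] for p in pairs], float)
    return d1, s1, d2, s2


def estimate_mae(replicate_pairs, sqrt2_correction: bool = False) -> float:
    """Minimum achievable error from paired repeat measurements.

    Returns the sample standard deviation (ddof=1) of the pair differences
    in log10(D/S) — the difference-scale convention used directly in the
    quadrature decomposition.  With ``sqrt2_correction`` the result is
    divided by sqrt(2), giving the implied per-measurement sd instead.
    """
    d1, s1, d2, s2 = _pairs_to_arrays(replicate_pairs)
    if d1.size < 2:
        raise InsufficientDataError("need at least 2 replicate pairs")
    if np.any(d1 <= 0) or np.any(d2 <= 0) or np.any(s1 <= 0) or np.any(s2 <= 0):
        raise ValueError("all D and S must be positive")
    diffs = np.log10(d1 / s1) - np.log10(d2 / s2)
    sd = float(np.std(diffs, ddof=1))
    return sd / math.sqrt(2.0) if sqrt2_correction else sd


def intrinsic_scatter(sigma_r: float, sigma_m: float) -> float:
    """Quadrature subtraction sqrt(sigma_r² - sigma_m²), in dex."""
    if sigma_r < 0 or sigma_m < 0:
        raise ValueError("sigmas must be non-negative")
    if sigma_m > sigma_r:
        raise OverSubtractionError(
            f"measurement floor sigma_m={sigma_m:g} exceeds model residual "
            f"sigma_r={sigma_r:g}: the residual is below the measurement floor"
        )
    return math.sqrt(sigma_r**2 - sigma_m**2)


def decompose(
    fit: FitResult, replicate_pairs, log10_d=None
) -> VarianceDecomposition:
    """Full decomposition: sigma_r from the fit, sigma_m from replicates,
    sigma_i by quadrature.

    ``log10_d`` (optional, cohort log10 D values) enables the
    variance-ratio form of the unexplained fraction, with the cohort
    dispersion itself corrected for measurement error in quadrature.
    """
    sigma_r = fit.residual_sd_dex
    sigma_m = estimate_mae(replicate_pairs)
    sigma_i = intrinsic_scatter(sigma_r, sigma_m)
    ratio = None
    if log10_d is not None:
        total_sd = float(np.std(np.asarray(log10_d, float), ddof=1))
        if total_sd > sigma_m:
            total_intrinsic = math.sqrt(total_sd**2 - sigma_m**2)
            if total_intrinsic > 0:
                ratio = (sigma_i / total_intrinsic) ** 2
    return VarianceDecomposition(
        sigma_r=sigma_r,
        sigma_m=sigma_m,
        sigma_i=sigma_i,
        fraction_unexplained=1.0 - fit.r2_cv,
        fraction_unexplained_variance_ratio=ratio,
    )
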