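"""Cosinor rhythmicity detection at a fixed 24-h period.

Each gene is fit by ordinary least squares to

    y(t) = M + A * cos(2*pi*(t - phi)/P)

via the linear regressors {1, cos(2*pi*t/P), sin(2*pi*t/P)}; M is the mesor,
A = sqrt(b_cos^2 + b_sin^2) the amplitude and phi the acrophase. Significance
is the F-test of the two rhythm coefficients against the intercept-only
model. A gene is called cycling when its raw p-value falls below the
threshold (default 0.0005); no multiple-testing correction is applied — the
raw cutoff is the detection rule, exposed as a parameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix

__all__ = [
    "CosinorFit",
    "cosinor_fit",
    "detect_cycling",
    "amplitude_class",
    "DEFAULT_ALPHA",
]

DEFAULT_ALPHA = 0.0005


@dataclass(frozen=True)
class CosinorFit:
    """Mesor, amplitude, acrophase (hours), R² and rhythm p-value for one gene."""

    mesor: float
    amplitude: float
    acrophase: float
    r_squared: float
    p_value: float
    period: float = 24.0

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.mesor + self.amplitude * np.cos(
            2 * np.pi * (t - self.acrophase) / self.period
        )


def _fit_batch(
    times: np.ndarray, Y: np.ndarray, period: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Cosinor OLS for every row of Y against the shared time vector.

    Returns (mesor, amplitude, acrophase, r2, p). Rows with zero variance get
    amplitude 0 and p 1.
    """
    t = np.asarray(times, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if len(np.unique(t)) < 4:
        raise ValueError("cosinor fit needs at least 4 distinct time points")
    w = 2 * np.pi * t / period
    X = np.column_stack([np.ones_like(t), np.cos(w), np.sin(w)])
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # (3, n_genes)
    fitted = (X @ beta).T
    resid = Y - fitted
    rss = np.sum(resid**2, axis=1)
    tss = np.sum((Y - Y.mean(axis=1, keepdims=True)) ** 2, axis=1)
    n = t.size
    df_resid = n - 3
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((tss - rss) / 2.0) / np.maximum(rss, 1e-300) * df_resid
        p = stats.f.sf(F, 2, df_resid)
        r2 = np.where(tss > 0, 1.0 - rss / np.maximum(tss, 1e-300), 0.0)
    mesor = beta[0]
    amplitude = np.hypot(beta[1], beta[2])
    acrophase = (period / (2 * np.pi)) * np.arctan2(beta[2], beta[1]) % period
    flat = tss <= 1e-300
    amplitude = np.where(flat, 0.0, amplitude)
    acrophase = np.where(flat, 0.0, acrophase)
    p = np.where(flat, 1.0, p)
    r2 = np.clip(np.where(flat, 0.0, r2), 0.0, 1.0)
    return mesor, amplitude, acrophase, r2, p


def cosinor_fit(times, values, period: float = 24.0) -> CosinorFit:
    """Fit the single-component cosinor to (time, value) samples.

    Replicates are passed as repeated time entries. Requires at least four
    distinct time points so the F-test has residual degrees of freedom.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape:
        raise ValueError("times and values must have the same shape")
    mesor, amp, acro, r2, p = _fit_batch(t, y[None, :], period)
    return CosinorFit(
        mesor=float(mesor[0]),
        amplitude=float(amp[0]),
        acrophase=float(acro[0]),
        r_squared=float(r2[0]),
        p_value=float(p[0]),
        period=period,
    )


def detect_cycling(
    matrix: ExpressionMatrix,
    alpha: float = DEFAULT_ALPHA,
    period: float = 24.0,
) -> pd.DataFrame:
    """Cosinor-fit every gene and call cycling at the raw p-value threshold.

    Returns a gene-indexed frame with columns mesor, amplitude, acrophase,
    r_squared, p_value, is_cycling.
    """
    t = matrix.samples["zt"].to_numpy(dtype=float)
    Y = matrix.data.to_numpy(dtype=float)
    mesor, amp, acro, r2, p = _fit_batch(t, Y, period)
    return pd.DataFrame(
        {
            "mesor": mesor,
            "amplitude": amp,
            "acrophase": acro,
            "r_squared": r2,
            "p_value": p,
            "is_cycling": p < alpha,
        },
        index=matrix.genes,
    )


def amplitude_class(
    fit_young: CosinorFit,
    fit_old: CosinorFit,
    low: float = 2.0 / 3.0,
    high: float = 1.5,
) -> Literal["similar", "higher", "lower"]:
    """Classify the old/young amplitude ratio of a commonly cycling gene.

    'lower' below ``low``, 'higher' above ``high``, otherwise 'similar'.
    """
    if fit_young.amplitude == 0:
        raise ValueError("young amplitude is zero; ratio undefined")
    ratio = fit_old.amplitude / fit_young.amplitude
    if ratio < low:
        return "lower"
    if ratio > high:
        return "higher"
    return "similar"
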