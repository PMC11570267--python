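"""Single-cycle waveform parameterization.

A daily expression (or luminescence) cycle is summarized by its crest, its
ascending and descending sections, and its full width at half maximum (FWHM):
after min-max normalization the curve is scanned for contiguous regions at or
above 0.5, and the half-maximum crossing times on either side of a single such
region are located by linear interpolation between the bracketing samples.
The FWHM — the circular distance from the ascending to the descending
crossing — measures the duration of each day that a gene spends above half of
its peak expression, and is the unit of "rhythmic alteration" analysis: the
age-dependent reshaping of diurnal waveforms beyond amplitude and phase.

Curves are treated circularly on the 24-h day by default, so a peak near
midnight wraps across the cycle boundary; a linear (non-wrapping) mode is
available for free-running windows.
"""

from __future__ import annotations

from dataclasses import dataclass, replace


import numpy as np
import pandas as pd
from scipy import stats


__all__ = [
    "Trace",
    "Curve",
    "FWHMResult",
    "Sections",
    "PeriodEstimate",
    "normalize_minmax",
    "normalize_by_mean",
    "detrend",
    "crest_time",
    "half_max_crossing",
    "fwhm",
    "sections",
    "period_estimate",
    "percent_change",
]


@dataclass(frozen=True)
class Trace:
    """A measured time series: strictly increasing times (hours) and values.

    The container for multi-day single-trace recordings (e.g. luciferase
    luminescence sampled every 20 min for several days).
    """

    times: np.ndarray
    values: np.ndarray
    replicate: str | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise ValueError("times and values must be 1-D and equally long")
        if t.size < 3:
            raise ValueError("a trace needs at least 3 samples")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise ValueError("times and values must be finite")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def span(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass(frozen=True)
class Curve:
    """One daily cycle: sample times within a cycle window and their values.

    ``cycle_length`` is 24 h in diurnal mode. Times must be strictly
    increasing and span less than one cycle, so each clock time appears once.
    """

    times: np.ndarray
    values: np.ndarray
    cycle_length: float = 24.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise ValueError("times and values must be 1-D and equally long")
        if t.size < 3:
            raise ValueError("a curve needs at least 3 samples")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise ValueError("times and values must be finite")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.cycle_length <= 0:
            raise ValueError("cycle_length must be positive")
        if t[-1] - t[0] >= self.cycle_length:
            raise ValueError("curve spans at least one full cycle")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class FWHMResult:
    """Crest, half-maximum crossings and duration of one daily waveform.

    ``n_segments`` counts the maximal contiguous super-half-maximum regions
    (with circular wraparound when requested). Crossings and ``fwhm`` are
    reported only when there is exactly one such region; multi-peak
    adjudication is left to the permutation test.
    """

    crest_time: float
    ascend_cross: float
    descend_cross: float
    fwhm: float
    n_segments: int

    @property
    def is_single(self) -> bool:
        return self.n_segments == 1


@dataclass(frozen=True)
class Sections:
    """Ascending (trough to crest) and descending (crest to trough) durations."""

    ascending: float
    descending: float
    trough_tie: bool = False


@dataclass(frozen=True)
class PeriodEstimate:
    """Best-fitting period from a cosinor scan, with its goodness of fit."""

    period: float
    r_squared: float
    p_value: float
    rhythmic: bool


def normalize_minmax(curve: Curve) -> Curve:
    """Affinely rescale a curve so its minimum is 0 and its maximum is 1."""
    v = curve.values
    lo, hi = float(v.min()), float(v.max())
    if hi <= lo:
        raise ValueError("constant curve cannot be min-max normalized")
    return replace(curve, values=(v - lo) / (hi - lo))


def normalize_by_mean(curve: Curve) -> Curve:
    """Divide every value by the across-time mean, giving a mean-1 curve.

    Used to overlay ages with different overall expression: relative waveform
    shape is kept while absolute level is discarded.
    """
    m = float(curve.values.mean())
    if m <= 0:
        raise ValueError("mean must be positive for mean normalization")
    return replace(curve, values=curve.values / m)


def detrend(trace: Trace, window: float = 24.0, trim: bool = False) -> Trace:
    """Subtract a centered running mean of width ``window`` hours.

    Removes the slow baseline drift of multi-day recordings so that the
    oscillation around zero remains. The window should be at least one
    period. Edge samples use a shortened window and are distorted over the
    outer half-window on each side; ``trim`` drops them, which is
    recommended before period estimation.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if window > trace.span:
        raise ValueError("window longer than the trace")
    dt = float(np.median(np.diff(trace.times)))
    n = max(1, int(round(window / dt)))
    if n % 2 == 0:
        n += 1
    trend = (
        pd.Series(trace.values)
        .rolling(n, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    resid = trace.values - trend
    if trim:
        h = n // 2
        if trace.times.size - 2 * h < 3:
            raise ValueError("trace too short to trim detrending edges")
        sl = slice(h, trace.times.size - h)
        return Trace(trace.times[sl], resid[sl], trace.replicate)
    return Trace(trace.times, resid, trace.replicate)


def crest_time(curve: Curve) -> float:
    """Time of the maximum sample; plateau ties break to the earliest time."""
    v = curve.values
    if float(v.max()) == float(v.min()):
        raise ValueError("constant curve has no crest")
    return float(curve.times[int(np.argmax(v))])


def half_max_crossing(t1: float, f1: float, t2: float, f2: float) -> float:
    """Time where the segment (t1, f1)-(t2, f2) crosses the half maximum 0.5.

    Linear interpolation: ``t = [t2*(f1 - 0.5) - t1*(f2 - 0.5)] / (f1 - f2)``.
    An endpoint exactly at 0.5 is the crossing itself; otherwise the two
    values must strictly bracket 0.5.
    """
    if f1 == f2:
        raise ValueError("degenerate segment: f1 == f2")
    if f1 == 0.5:
        return float(t1)
    if f2 == 0.5:
        return float(t2)
    if (f1 - 0.5) * (f2 - 0.5) > 0:
        raise ValueError("segment does not bracket the half maximum")
    return float((t2 * (f1 - 0.5) - t1 * (f2 - 0.5)) / (f1 - f2))


def _fwhm_batch(
    times: np.ndarray, values: np.ndarray, cycle_length: float, circular: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized FWHM over rows of min-max-normalized curves.

    ``values`` is (m, T); every row must already be normalized to [0, 1].
    Returns (n_segments, crest, ascend, descend, fwhm); the last three are NaN
    for rows without exactly one super-half-max segment. Shared by the
    per-curve API and the permutation-ensemble machinery so both paths agree
    exactly.
    """
    V = np.atleast_2d(np.asarray(values, dtype=float))
    t = np.asarray(times, dtype=float)
    m, T = V.shape
    B = V >= 0.5
    if circular:
        prev = np.roll(B, 1, axis=1)
        nxt = np.roll(B, -1, axis=1)
    else:
        prev = np.zeros_like(B)
        prev[:, 1:] = B[:, :-1]
        nxt = np.zeros_like(B)
        nxt[:, :-1] = B[:, 1:]
    rising = B & ~prev
    falling = B & ~nxt
    nseg = rising.sum(axis=1)
    full = B.all(axis=1)
    nseg[full] = 1  # the whole cycle is one (degenerate) region

    crest = t[np.argmax(V, axis=1)].astype(float)
    ascend = np.full(m, np.nan)
    descend = np.full(m, np.nan)
    width = np.full(m, np.nan)

    ok = (nseg == 1) & ~full
    if circular:
        single = ok
    else:
        # in linear mode a segment touching the window edge has no bracket
        single = ok & ~B[:, 0] & ~B[:, -1]
    if single.any():
        rows = np.flatnonzero(single)
        s = np.argmax(rising[rows], axis=1)
        e = np.argmax(falling[rows], axis=1)
        sm1 = (s - 1) % T
        ep1 = (e + 1) % T
        t_s = t[s]
        t_sm1 = np.where(s == 0, t[sm1] - cycle_length, t[sm1])
        t_e = t[e]
        t_ep1 = np.where(e == T - 1, t[ep1] + cycle_length, t[ep1])
        v_s = V[rows, s]
        v_sm1 = V[rows, sm1]
        v_e = V[rows, e]
        v_ep1 = V[rows, ep1]
        # the interpolation formula returns t1 when f1 == 0.5 and t2 when
        # f2 == 0.5, so the endpoint convention needs no special case
        a = (t_s * (v_sm1 - 0.5) - t_sm1 * (v_s - 0.5)) / (v_sm1 - v_s)
        d = (t_ep1 * (v_e - 0.5) - t_e * (v_ep1 - 0.5)) / (v_e - v_ep1)
        ascend[rows] = a
        descend[rows] = d
        width[rows] = (d - a) % cycle_length
    return nseg.astype(int), crest, ascend, descend, width


def fwhm(curve: Curve, circular: bool = True) -> FWHMResult:
    """Locate the super-half-maximum region(s) and measure the FWHM.

    The curve must be min-max normalized (exact 0 minimum and 1 maximum).
    With ``circular`` a region may wrap across the cycle boundary, in which
    case the descending crossing is earlier in clock time than the ascending
    one and the width is taken on the circle.
    """
    v = curve.values
    if float(v.max()) == float(v.min()):
        raise ValueError("constant curve is degenerate for FWHM")
    if not (abs(float(v.min())) < 1e-9 and abs(float(v.max()) - 1.0) < 1e-9):
        raise ValueError("curve must be min-max normalized before FWHM")
    nseg, crest, asc, desc, width = _fwhm_batch(
        curve.times, v[None, :], curve.cycle_length, circular=circular
    )
    return FWHMResult(
        crest_time=float(crest[0]),
        ascend_cross=float(asc[0]),
        descend_cross=float(desc[0]),
        fwhm=float(width[0]),
        n_segments=int(nseg[0]),
    )


def sections(curve: Curve) -> Sections:
    """Split one cycle at crest and trough into ascending/descending sections.

    ascending = (crest - trough) mod cycle_length; descending is the
    complement, so the two always sum to the cycle length. Ties at the trough
    break to the earliest time and are flagged.
    """
    v = curve.values
    if float(v.max()) == float(v.min()):
        raise ValueError("constant curve has no sections")
    crest = crest_time(curve)
    i_trough = int(np.argmin(v))
    tie = bool(np.sum(v == v[i_trough]) > 1)
    trough = float(curve.times[i_trough])
    ascending = (crest - trough) % curve.cycle_length
    return Sections(
        ascending=ascending,
        descending=curve.cycle_length - ascending,
        trough_tie=tie,
    )


def percent_change(before: float, after: float) -> float:
    """Percent change from ``before`` to ``after``: 100 * (after - before) / before."""
    if before == 0:
        raise ValueError("percent change undefined for a zero baseline")
    return 100.0 * (after - before) / before


def _cosinor_design(times: np.ndarray, period: float) -> np.ndarray:
    w = 2.0 * np.pi * times / period
    return np.column_stack([np.ones_like(times), np.cos(w), np.sin(w)])


def period_estimate(
    trace: Trace,
    scan_range: tuple[float, float] = (20.0, 30.0),
    step: float = 0.05,
    alpha: float | None = None,
) -> PeriodEstimate:
    """Estimate the free-running period by a cosinor scan.

    Fits ``mesor + a*cos + b*sin`` at every candidate period on a grid over
    ``scan_range`` and returns the period maximizing R². The trace should be
    detrended and span at least two cycles of the lower scan bound. A trace
    whose best fit is not significant (default alpha = 0.05 Bonferroni-divided
    by the number of scanned periods) is flagged non-rhythmic.
    """
    lo, hi = scan_range
    if lo <= 0 or hi <= lo:
        raise ValueError("invalid scan range")
    if trace.span < 2 * lo:
        raise ValueError("trace must span at least two cycles of the scan lower bound")
    periods = np.arange(lo, hi + step / 2, step)
    if alpha is None:
        alpha = 0.05 / len(periods)
    t = trace.times
    y = trace.values
    n = y.size
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    best = (0.0, -np.inf)  # (r2, -period) placeholder
    best_period = periods[0]
    best_r2 = -np.inf
    best_rss = ss_tot
    for p in periods:
        X = _cosinor_design(t, p)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta) ** 2))
        r2 = 1.0 - rss / ss_tot if ss_tot > 0 else 0.0
        if r2 > best_r2:
            best_r2, best_period, best_rss = r2, float(p), rss
    if ss_tot <= 0:
        return PeriodEstimate(best_period, 0.0, 1.0, False)
    df_resid = n - 3
    num = max(ss_tot - best_rss, 0.0) / 2.0
    den = max(best_rss, 1e-300) / df_resid
    p_value = float(stats.f.sf(num / den, 2, df_resid))
    return PeriodEstimate(best_period, best_r2, p_value, bool(p_value < alpha))
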