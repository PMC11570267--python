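"""Synthetic diurnal time courses with known ground-truth waveforms.

Generates the study designs every downstream stage is exercised on:

* transcriptome mode — 6 time points (ZT1, 5, 9, 13, 17, 21) x 3 replicates
  per age;
* qPCR mode — 30-min-resolution sampling over 24 h;
* reporter mode — multi-day traces at 20-min resolution, optionally with a
  free-running (non-24-h) period and a slow linear trend.

The waveform family is a powered half-cosine ramp:

    w(t) = baseline + amplitude * s(t)**sharpness

where s(t) rises 0 -> 1 over ``rise`` hours before the crest and falls
1 -> 0 over ``fall`` hours after it (rise + fall = period), extended
periodically. Phase (``peak_phase``), skew (rise vs fall) and width
(``sharpness``) are controlled independently: sharpness 1 gives an FWHM of
exactly half the period regardless of skew, larger values narrow the peak and
values below 1 broaden it. Aging is emulated as amplitude attenuation, phase
shift, and sharpening/broadening applied to a fraction of the cycling genes.

All randomness flows from one seed; each gene draws from its own sub-stream
so generated matrices are stable under gene subsetting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Mapping

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .waveform import Trace

__all__ = [
    "WaveformParams",
    "AgeEffect",
    "SimConfig",
    "make_waveform",
    "true_fwhm",
    "sharpness_for_fwhm",
    "simulate_expression_matrix",
    "simulate_trace",
]


@dataclass(frozen=True)
class WaveformParams:
    """Shape parameters of one cycling gene's daily waveform.

    ``rise`` + ``fall`` must equal ``period``; the waveform attains
    ``baseline + amplitude`` exactly at ``peak_phase`` and ``baseline`` at the
    trough. ``sharpness`` > 0 (values in (0, 1) broaden the peak beyond half
    the period, values above 1 narrow it).
    """

    peak_phase: float
    rise: float
    fall: float
    sharpness: float = 1.0
    amplitude: float = 1.0
    baseline: float = 0.0
    period: float = 24.0

    def __post_init__(self) -> None:
        if self.rise <= 0 or self.fall <= 0:
            raise ValueError("rise and fall must be positive")
        if abs(self.rise + self.fall - self.period) > 1e-9:
            raise ValueError("rise + fall must equal period")
        if self.sharpness <= 0:
            raise ValueError("sharpness must be positive")
        if self.amplitude < 0 or self.baseline < 0:
            raise ValueError("amplitude and baseline must be non-negative")


@dataclass(frozen=True)
class AgeEffect:
    """How one age reshapes cycling genes relative to the reference shapes.

    Applied to a fraction ``applies_to`` of cycling genes (the affected subset
    is drawn once per gene from its sub-stream, so it is stable).
    ``fwhm_delta_mode`` 'sharpen' multiplies sharpness by ``sharpness_factor``
    (narrower peak), 'broaden' divides by it (wider peak, FWHM can exceed half
    the period); rise + fall is untouched so the period is preserved.
    """

    amplitude_scale: float = 1.0
    phase_shift: float = 0.0
    fwhm_delta_mode: Literal["sharpen", "broaden", "none"] = "none"
    applies_to: float = 1.0
    sharpness_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.amplitude_scale <= 0:
            raise ValueError("amplitude_scale must be positive")
        if not 0.0 <= self.applies_to <= 1.0:
            raise ValueError("applies_to must be in [0, 1]")
        if self.fwhm_delta_mode not in ("sharpen", "broaden", "none"):
            raise ValueError("unknown fwhm_delta_mode")
        if self.sharpness_factor <= 0:
            raise ValueError("sharpness_factor must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Design of a simulated multi-age diurnal expression experiment."""

    n_cycling: int = 100
    n_flat: int = 100
    timepoints: tuple[float, ...] = (1.0, 5.0, 9.0, 13.0, 17.0, 21.0)
    n_replicates: int = 3
    noise_cv: float = 0.1
    noise_model: Literal["additive-gaussian", "multiplicative-lognormal"] = (
        "multiplicative-lognormal"
    )
    seed: int = 0
    ages: Mapping[str, AgeEffect] = field(
        default_factory=lambda: {"young": AgeEffect()}
    )
    period: float = 24.0

    def __post_init__(self) -> None:
        tps = tuple(float(t) for t in self.timepoints)
        if len(tps) == 0:
            raise ValueError("timepoints must be non-empty")
        if any(not 0 <= t < self.period for t in tps):
            raise ValueError("timepoints must lie in [0, period)")
        if any(b <= a for a, b in zip(tps, tps[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.noise_model not in ("additive-gaussian", "multiplicative-lognormal"):
            raise ValueError("unknown noise model")
        if not self.ages:
            raise ValueError("at least one age is required")
        object.__setattr__(self, "timepoints", tps)
        object.__setattr__(self, "ages", dict(self.ages))


def make_waveform(params: WaveformParams) -> Callable[[np.ndarray], np.ndarray]:
    """Periodic waveform w(t) for the given parameters (t in hours)."""
    p = params

    def w(t):
        t = np.asarray(t, dtype=float)
        # hours since the trough preceding the crest
        x = (t - (p.peak_phase - p.rise)) % p.period
        s = np.where(
            x <= p.rise,
            0.5 * (1.0 - np.cos(np.pi * np.minimum(x, p.rise) / p.rise)),
            0.5 * (1.0 + np.cos(np.pi * np.minimum(x - p.rise, p.fall) / p.fall)),
        )
        return p.baseline + p.amplitude * s**p.sharpness

    return w


def true_fwhm(params: WaveformParams, step: float = 0.001) -> float:
    """Ground-truth FWHM of the min-max-normalized waveform by dense grid.

    Evaluates the waveform on a grid of spacing ``step`` hours across one
    period starting at the crest (so the single super-half-max region never
    wraps) and interpolates the two half-maximum crossings. Independent of the
    curve-analysis module by construction.
    """
    if step <= 0 or step > 0.001 + 1e-12:
        raise ValueError("step must be positive and at most 0.001 h")
    p = params
    # grid centered on the crest: the super-half-max region sits in the
    # interior (the window edges are the trough), so it never wraps
    t = (p.peak_phase - p.period / 2) + np.arange(0.0, p.period, step)
    v = make_waveform(p)(t)
    lo, hi = v.min(), v.max()
    u = (v - lo) / (hi - lo)
    above = u >= 0.5
    i_first = int(np.argmax(above))
    i_last = len(above) - 1 - int(np.argmax(above[::-1]))

    def cross(i1: int, i2: int) -> float:
        f1, f2 = u[i1], u[i2]
        return (t[i2] * (f1 - 0.5) - t[i1] * (f2 - 0.5)) / (f1 - f2)

    asc = cross(i_first - 1, i_first)
    desc = cross(i_last, i_last + 1)
    return float(desc - asc)


def sharpness_for_fwhm(
    rise: float, fall: float, target_fwhm: float, period: float = 24.0
) -> float:
    """Sharpness k whose powered half-cosine waveform has the target FWHM.

    Closed form of the crossing geometry: with c = 0.5**(1/k) the normalized
    ramp s**k equals 0.5 where s = c, giving

        FWHM(c) = rise * (1 - acos(1 - 2c)/pi) + fall * acos(2c - 1)/pi,

    strictly increasing in c; c is found by bisection and inverted to k.
    Targets must lie strictly inside (0, period).
    """
    if not 0 < target_fwhm < period:
        raise ValueError("target FWHM must be inside (0, period)")
    if abs(rise + fall - period) > 1e-9:
        raise ValueError("rise + fall must equal period")

    def width(c: float) -> float:
        return rise * (1 - np.arccos(1 - 2 * c) / np.pi) + fall * np.arccos(
            2 * c - 1
        ) / np.pi

    # width is strictly decreasing in c (a higher threshold trims the region)
    lo, hi = 1e-12, 1.0 - 1e-12
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if width(mid) > target_fwhm:
            lo = mid
        else:
            hi = mid
    c = 0.5 * (lo + hi)
    return float(np.log(0.5) / np.log(c))


# -- parameter sampling ----------------------------------------------------

# default cycling-gene parameter ranges (uniform draws); chosen to span the
# phases, skews and widths seen in diurnal transcriptome waveforms
_PEAK_RANGE = (0.0, 24.0)
_RISE_RANGE = (6.0, 18.0)
_SHARPNESS_RANGE = (1.0, 3.0)
_AMPLITUDE_RANGE = (2.0, 10.0)
_BASELINE_RANGE = (0.5, 2.0)
_FLAT_MEAN_RANGE = (1.0, 10.0)


def _gene_rng(seed: int, gene_index: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(gene_index)])


def _sample_params(rng: np.random.Generator, period: float) -> WaveformParams:
    rise = rng.uniform(*_RISE_RANGE)
    return WaveformParams(
        peak_phase=rng.uniform(*_PEAK_RANGE) % period,
        rise=rise,
        fall=period - rise,
        sharpness=rng.uniform(*_SHARPNESS_RANGE),
        amplitude=rng.uniform(*_AMPLITUDE_RANGE),
        baseline=rng.uniform(*_BASELINE_RANGE),
        period=period,
    )


def _apply_age(params: WaveformParams, eff: AgeEffect, affected: bool) -> WaveformParams:
    if not affected:
        return params
    k = params.sharpness
    if eff.fwhm_delta_mode == "sharpen":
        k = k * eff.sharpness_factor
    elif eff.fwhm_delta_mode == "broaden":
        k = k / eff.sharpness_factor
    return replace(
        params,
        amplitude=params.amplitude * eff.amplitude_scale,
        peak_phase=(params.peak_phase + eff.phase_shift) % params.period,
        sharpness=k,
    )


def _add_noise(
    rng: np.random.Generator, mean: np.ndarray, cv: float, model: str
) -> np.ndarray:
    if cv == 0:
        return mean.copy()
    if model == "multiplicative-lognormal":
        sigma = float(np.sqrt(np.log1p(cv**2)))
        factors = rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=mean.shape)
        return mean * factors
    return mean + rng.normal(0.0, cv * np.abs(mean), size=mean.shape)


def simulate_expression_matrix(
    config: SimConfig,
) -> tuple[dict[str, ExpressionMatrix], pd.DataFrame]:
    """Simulate one expression matrix per age plus a ground-truth table.

    Cycling genes draw waveform parameters from the default ranges; each age's
    :class:`AgeEffect` reshapes its affected subset. Flat genes are constant
    mean plus noise. The ground truth records, per gene and age, the realized
    parameters, the dense-grid FWHM and the peak phase.

    Deterministic given ``config.seed``; per-gene sub-streams keep the output
    stable if genes are added or removed at the end of the list.
    """
    tps = np.asarray(config.timepoints, dtype=float)
    genes = [f"cyc{i:04d}" for i in range(config.n_cycling)] + [
        f"flat{i:04d}" for i in range(config.n_flat)
    ]
    n_genes = len(genes)
    age_names = list(config.ages)
    values = {
        age: np.empty((n_genes, tps.size, config.n_replicates)) for age in age_names
    }
    truth_rows = []
    for gi, gene in enumerate(genes):
        rng = _gene_rng(config.seed, gi)
        cycling = gi < config.n_cycling
        if cycling:
            base_params = _sample_params(rng, config.period)
        else:
            flat_mean = rng.uniform(*_FLAT_MEAN_RANGE)
        u_affected = rng.uniform()
        for ai, age in enumerate(age_names):
            eff = config.ages[age]
            noise_rng = np.random.default_rng([int(config.seed), gi, ai])
            if cycling:
                params = _apply_age(base_params, eff, u_affected < eff.applies_to)
                mean = make_waveform(params)(tps)
                truth_rows.append(
                    {
                        "gene": gene,
                        "age": age,
                        "is_cycling": True,
                        "peak_phase": params.peak_phase,
                        "rise": params.rise,
                        "fall": params.fall,
                        "sharpness": params.sharpness,
                        "amplitude": params.amplitude,
                        "baseline": params.baseline,
                        "period": params.period,
                        "true_peak": params.peak_phase,
                        "true_fwhm": true_fwhm(params),
                    }
                )
            else:
                mean = np.full(tps.size, flat_mean)
                truth_rows.append(
                    {
                        "gene": gene,
                        "age": age,
                        "is_cycling": False,
                        "peak_phase": np.nan,
                        "rise": np.nan,
                        "fall": np.nan,
                        "sharpness": np.nan,
                        "amplitude": 0.0,
                        "baseline": flat_mean,
                        "period": config.period,
                        "true_peak": np.nan,
                        "true_fwhm": np.nan,
                    }
                )
            mean_grid = np.repeat(mean[:, None], config.n_replicates, axis=1)
            values[age][gi] = _add_noise(
                noise_rng, mean_grid, config.noise_cv, config.noise_model
            )
    matrices = {
        age: ExpressionMatrix.from_values(
            values[age], genes, age, tps, config.n_replicates
        )
        for age in age_names
    }
    truth = pd.DataFrame(truth_rows)
    return matrices, truth


def simulate_trace(
    params: WaveformParams,
    duration: float,
    interval: float,
    trend: float = 0.0,
    noise_cv: float = 0.0,
    seed: int = 0,
    noise_model: str = "multiplicative-lognormal",
) -> Trace:
    """Simulate a single multi-day trace: waveform + linear trend + noise.

    Emulates luminescence recordings (e.g. 20-min interval over 4 days);
    a free-running period is set through ``params.period``.
    """
    if duration <= params.period:
        raise ValueError("duration must exceed one period")
    if interval <= 0 or interval >= duration:
        raise ValueError("interval must be positive and shorter than duration")
    t = np.arange(0.0, duration + interval / 2, interval)
    mean = make_waveform(params)(t) + trend * t
    rng = np.random.default_rng(int(seed))
    vals = _add_noise(rng, mean, noise_cv, noise_model)
    return Trace(t, vals)
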