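"""Circular "physiological time" estimation from expression profiles.

Two ridge-penalized linear models map a per-sample expression profile to the
cosine and sine of its sampling time on the 24-h circle:

    o1 ~ cos(2*pi*t/24),   o2 ~ sin(2*pi*t/24)

and a profile's predicted time is the angle of the point (o1, o2):
t_hat = (24/2*pi) * atan2(o2, o1) mod 24. Trained on a reference age, the
model places any other transcriptome on the reference's clock, which is how
age-warped "subjective time" curves are read out. Errors between clock times
are circular: err(a, b) = min(|a-b|, 24-|a-b|), at most 12 h.

Features are centered and scaled on the training samples so the shared ridge
penalty treats genes comparably; the penalty defaults to the ridge
regressor's standard value of 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge

from .matrix import ExpressionMatrix

__all__ = [
    "TimeModel",
    "TimePrediction",
    "SubjectiveTimeCurve",
    "fit_time_model",
    "predict_time",
    "circular_error",
    "loocv_by_timepoint",
    "subjective_time_curve",
    "distance_from_reference_time",
]


@dataclass(frozen=True)
class TimeModel:
    """Fitted cos/sin ridge pair with its feature list and scaling."""

    features: list[str]
    coef_cos: np.ndarray
    coef_sin: np.ndarray
    intercept_cos: float
    intercept_sin: float
    center: np.ndarray
    scale: np.ndarray
    ridge_penalty: float
    period: float = 24.0
    reference_label: str | None = None


@dataclass(frozen=True)
class TimePrediction:
    """A point on the 24-h circle plus the raw regressor outputs."""

    predicted_time: float
    raw_outputs: tuple[float, float]

    @property
    def norm(self) -> float:
        """Distance of (o1, o2) from the origin; a confidence proxy (a clean
        rhythmic profile lands near the unit circle, noise near 0)."""
        o1, o2 = self.raw_outputs
        return float(np.hypot(o1, o2))


@dataclass(frozen=True)
class SubjectiveTimeCurve:
    """Reference-frame time per query ZT, with spans between consecutive ZTs."""

    query_zts: np.ndarray
    predicted: np.ndarray  # circular mean over replicates, reference frame
    spans: np.ndarray  # hours of reference time between consecutive query ZTs
    period: float = 24.0


def _profiles(matrix: ExpressionMatrix, features: list[str]) -> np.ndarray:
    missing = [f for f in features if f not in matrix.data.index]
    if missing:
        raise KeyError(f"features missing from matrix: {missing[:5]}...")
    return matrix.data.loc[features].to_numpy(dtype=float).T  # samples x genes


def fit_time_model(
    matrix: ExpressionMatrix,
    penalty: float = 1.0,
    feature_set: list[str] | None = None,
    reference_label: str | None = None,
    period: float = 24.0,
) -> TimeModel:
    """Fit the two ridge predictors of cos/sin sampling time.

    ``feature_set`` defaults to every gene in the matrix; in the full analysis
    the common-SOG list is the conventional choice.
    """
    if len(np.unique(matrix.samples["zt"])) < 3:
        raise ValueError("need at least 3 distinct time points to fit")
    features = list(feature_set) if feature_set is not None else list(matrix.genes)
    X = _profiles(matrix, features)
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    Xs = (X - center) / scale
    t = matrix.samples["zt"].to_numpy(dtype=float)
    ang = 2 * np.pi * t / period
    rc = Ridge(alpha=penalty).fit(Xs, np.cos(ang))
    rs = Ridge(alpha=penalty).fit(Xs, np.sin(ang))
    return TimeModel(
        features=features,
        coef_cos=rc.coef_.copy(),
        coef_sin=rs.coef_.copy(),
        intercept_cos=float(rc.intercept_),
        intercept_sin=float(rs.intercept_),
        center=center,
        scale=scale,
        ridge_penalty=float(penalty),
        period=period,
        reference_label=reference_label
        or (matrix.ages[0] if matrix.ages else None),
    )


def predict_time(model: TimeModel, profile) -> TimePrediction:
    """Predict the circular sampling time of one expression profile.

    ``profile`` is a mapping/Series of gene -> value covering every model
    feature (no imputation: a missing feature raises).
    """
    if isinstance(profile, pd.Series):
        try:
            x = profile[model.features].to_numpy(dtype=float)
        except KeyError as e:
            raise KeyError(f"profile lacks model features: {e}") from e
        if np.isnan(x).any():
            raise KeyError("profile lacks model features (NaN after reindex)")
    else:
        x = np.asarray(profile, dtype=float)
        if x.shape != (len(model.features),):
            raise ValueError("profile length must match the model feature list")
    xs = (x - model.center) / model.scale
    o1 = float(xs @ model.coef_cos + model.intercept_cos)
    o2 = float(xs @ model.coef_sin + model.intercept_sin)
    t_hat = (model.period / (2 * np.pi)) * np.arctan2(o2, o1) % model.period
    return TimePrediction(predicted_time=float(t_hat), raw_outputs=(o1, o2))


def _predict_samples(model: TimeModel, matrix: ExpressionMatrix) -> np.ndarray:
    X = _profiles(matrix, model.features)
    Xs = (X - model.center) / model.scale
    o1 = Xs @ model.coef_cos + model.intercept_cos
    o2 = Xs @ model.coef_sin + model.intercept_sin
    return (model.period / (2 * np.pi)) * np.arctan2(o2, o1) % model.period


def circular_error(t_pred, t_true, period: float = 24.0):
    """Shortest distance between two clock times on the circle, in [0, period/2]."""
    d = np.abs(np.asarray(t_pred, dtype=float) - np.asarray(t_true, dtype=float))
    d = d % period
    out = np.minimum(d, period - d)
    return float(out) if out.ndim == 0 else out


def loocv_by_timepoint(
    matrix: ExpressionMatrix,
    penalty: float = 1.0,
    feature_set: list[str] | None = None,
    period: float = 24.0,
) -> pd.DataFrame:
    """Leave-one-time-point-out cross-validation of the time model.

    For each distinct ZT, all its samples are held out, the model refit on
    the rest, and the held-out samples' predicted times compared with truth.
    Returns one row per held-out sample (zt, sample, predicted, error).
    """
    zts = matrix.zts
    if zts.size < 3:
        raise ValueError("need at least 3 distinct time points for LOOCV")
    rows = []
    for zt in zts:
        held = matrix.samples["zt"] == zt
        train = ExpressionMatrix(
            matrix.data.loc[:, ~held.to_numpy()], matrix.samples[~held]
        )
        test = ExpressionMatrix(
            matrix.data.loc[:, held.to_numpy()], matrix.samples[held]
        )
        model = fit_time_model(
            train, penalty=penalty, feature_set=feature_set, period=period
        )
        preds = _predict_samples(model, test)
        for sample, pred in zip(test.samples.index, preds):
            rows.append(
                {
                    "zt": float(zt),
                    "sample": sample,
                    "predicted": float(pred),
                    "error": circular_error(pred, zt, period),
                }
            )
    return pd.DataFrame(rows)


def _circular_mean(hours: np.ndarray, period: float) -> float:
    ang = 2 * np.pi * np.asarray(hours, dtype=float) / period
    return float(
        (period / (2 * np.pi)) * np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
        % period
    )


def subjective_time_curve(
    model: TimeModel, query_matrix: ExpressionMatrix
) -> SubjectiveTimeCurve:
    """Map each query ZT to reference-frame time (circular replicate mean).

    ``spans[i]`` is the reference-frame hours elapsed between query ZT i and
    ZT i+1 (wrapping at the end), so over a full cycle the spans sum to a
    multiple of the period.
    """
    preds = _predict_samples(model, query_matrix)
    zts = query_matrix.zts
    per_zt = np.array(
        [
            _circular_mean(
                preds[(query_matrix.samples["zt"] == zt).to_numpy()], model.period
            )
            for zt in zts
        ]
    )
    nxt = np.roll(per_zt, -1)
    spans = (nxt - per_zt) % model.period
    return SubjectiveTimeCurve(
        query_zts=zts, predicted=per_zt, spans=spans, period=model.period
    )


def distance_from_reference_time(
    curve: SubjectiveTimeCurve, reference_time: float = 8.0
) -> pd.Series:
    """Circular distance of each query ZT's predicted time from a reference
    clock time (default ZT8, mid-light under LD 16:8 — the 'noon' profile)."""
    d = circular_error(curve.predicted, reference_time, curve.period)
    return pd.Series(d, index=pd.Index(curve.query_zts, name="zt"), name="distance")
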