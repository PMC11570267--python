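"""Replicate-permutation tests for single-oscillation genes and FWHM change.

For a gene measured with r replicates at each of T time points, a permutation
curve draws one replicate value per time point uniformly at random (r**T
possible combinations, sampled with replacement). Repeating this n times
(default 10,000) gives an ensemble of plausible daily curves; the fraction of
curves with exactly one contiguous super-half-maximum region after min-max
normalization is the gene's single-FWHM ratio, and a ratio above 0.95 defines
a single-oscillation gene (SOG). The same ensembles support the FWHM-change
test between two ages: the difference of ensemble-mean FWHMs, gated at
|dFWHM| > 2 h, with a p-value from label resampling between the pooled
ensembles' FWHM values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .waveform import Curve, _fwhm_batch, normalize_minmax, fwhm as _fwhm_one

__all__ = [
    "PermutationEnsemble",
    "SOGCall",
    "FWHMChange",
    "permutation_curves",
    "is_single_fwhm",
    "sog_test",
    "sog_test_matrix",
    "fwhm_change_test",
    "classify_sog_sets",
    "DEFAULT_N_PERM",
    "DEFAULT_SOG_THRESHOLD",
]

DEFAULT_N_PERM = 10_000
DEFAULT_SOG_THRESHOLD = 0.95


@dataclass(frozen=True)
class PermutationEnsemble:
    """n resampled daily curves for one gene (one replicate per time point)."""

    times: np.ndarray
    values: np.ndarray  # (n_curves, T)
    seed: int
    gene: str | None = None

    @property
    def n_curves(self) -> int:
        return self.values.shape[0]

    def curve(self, i: int, cycle_length: float = 24.0) -> Curve:
        return Curve(self.times, self.values[i], cycle_length=cycle_length)


@dataclass(frozen=True)
class SOGCall:
    """Single-FWHM ratio and SOG flag for one gene."""

    gene: str | None
    single_ratio: float
    is_sog: bool
    fwhm_mean: float
    threshold: float = DEFAULT_SOG_THRESHOLD


@dataclass(frozen=True)
class FWHMChange:
    """Old-minus-young ensemble-mean FWHM difference and its permutation test."""

    gene: str | None
    delta_fwhm: float
    p_value: float
    significant: bool
    direction: Literal["shortened", "lengthened", "unchanged"]
    fwhm_young: float
    fwhm_old: float


def permutation_curves(
    times: Sequence[float],
    replicate_values: Sequence[np.ndarray],
    n: int = DEFAULT_N_PERM,
    seed: int = 0,
    gene: str | None = None,
) -> PermutationEnsemble:
    """Build n curves, each drawing one replicate value per time point."""
    t = np.asarray(times, dtype=float)
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(replicate_values) != t.size:
        raise ValueError("one replicate array needed per time point")
    reps = [np.asarray(r, dtype=float) for r in replicate_values]
    if any(r.size == 0 for r in reps):
        raise ValueError("every time point needs at least one replicate")
    rng = np.random.default_rng(int(seed))
    V = np.empty((n, t.size))
    for j, r in enumerate(reps):
        V[:, j] = r[rng.integers(0, r.size, size=n)]
    return PermutationEnsemble(times=t, values=V, seed=int(seed), gene=gene)


def _single_mask_and_fwhm(
    ensemble: PermutationEnsemble, cycle_length: float = 24.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(single?, fwhm, ascend, descend) per ensemble curve.

    Constant (degenerate) curves count as non-single. Normalization and
    segment analysis share the waveform module's batch kernel.
    """
    V = ensemble.values
    lo = V.min(axis=1, keepdims=True)
    hi = V.max(axis=1, keepdims=True)
    rng_ok = (hi - lo).ravel() > 0
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    U = (V - lo) / span
    nseg, _, asc, desc, width = _fwhm_batch(ensemble.times, U, cycle_length)
    single = (nseg == 1) & rng_ok
    width = np.where(single, width, np.nan)
    asc = np.where(single, asc, np.nan)
    desc = np.where(single, desc, np.nan)
    return single, width, asc, desc


def is_single_fwhm(curve: Curve) -> bool:
    """True iff the min-max-normalized curve has exactly one circular
    super-half-maximum region; constant curves are degenerate and non-single."""
    if float(curve.values.max()) == float(curve.values.min()):
        return False
    return _fwhm_one(normalize_minmax(curve), circular=True).n_segments == 1


def _circular_mean(hours: np.ndarray, period: float = 24.0) -> float:
    ang = 2 * np.pi * np.asarray(hours, dtype=float) / period
    return float(
        (period / (2 * np.pi)) * np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
        % period
    )


def sog_test(
    times: Sequence[float],
    replicate_values: Sequence[np.ndarray],
    n: int = DEFAULT_N_PERM,
    threshold: float = DEFAULT_SOG_THRESHOLD,
    seed: int = 0,
    gene: str | None = None,
    cycle_length: float = 24.0,
) -> SOGCall:
    """Single-FWHM ratio over a permutation ensemble and the SOG call.

    ``fwhm_mean`` averages the FWHM over the single-FWHM curves only (NaN if
    none pass).
    """
    ens = permutation_curves(times, replicate_values, n=n, seed=seed, gene=gene)
    single, width, _, _ = _single_mask_and_fwhm(ens, cycle_length)
    ratio = float(single.mean())
    mean_width = float(np.nanmean(width)) if single.any() else float("nan")
    return SOGCall(
        gene=gene,
        single_ratio=ratio,
        is_sog=bool(ratio > threshold),
        fwhm_mean=mean_width,
        threshold=threshold,
    )


def sog_test_matrix(
    matrix: ExpressionMatrix,
    n: int = DEFAULT_N_PERM,
    threshold: float = DEFAULT_SOG_THRESHOLD,
    seed: int = 0,
    cycle_length: float = 24.0,
) -> pd.DataFrame:
    """Run :func:`sog_test` for every gene of a matrix.

    Per-gene sub-seeds derive from ``seed`` and the gene's position, so the
    result is deterministic and stable under subsetting. Adds ensemble-mean
    ascending/descending crossings (circular means) for the FWHM timetable.
    """
    rows = []
    for gi, gene in enumerate(matrix.genes):
        zts, reps = matrix.replicate_values(gene)
        gene_seed = int(np.random.default_rng([int(seed), gi]).integers(0, 2**31))
        ens = permutation_curves(zts, reps, n=n, seed=gene_seed, gene=gene)
        single, width, asc, desc = _single_mask_and_fwhm(ens, cycle_length)
        ratio = float(single.mean())
        ok = single.any()
        rows.append(
            {
                "gene": gene,
                "single_ratio": ratio,
                "is_sog": bool(ratio > threshold),
                "fwhm_mean": float(np.nanmean(width)) if ok else np.nan,
                "ascend_mean": _circular_mean(asc[single], cycle_length)
                if ok
                else np.nan,
                "descend_mean": _circular_mean(desc[single], cycle_length)
                if ok
                else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def _label_resample_pvalue(
    pooled: np.ndarray,
    n_young: int,
    observed_abs: float,
    n_resample: int,
    rng: np.random.Generator,
) -> float:
    """Two-sided tail probability of |mean(old) - mean(young)| under label
    exchange between the pooled ensemble FWHM values."""
    total = pooled.sum()
    n_all = pooled.size
    hits = 0
    # chunked vectorized permutations to bound memory
    chunk = max(1, int(2e7 / n_all))
    done = 0
    while done < n_resample:
        b = min(chunk, n_resample - done)
        keys = rng.random((b, n_all))
        idx = np.argpartition(keys, n_young - 1, axis=1)[:, :n_young]
        young_sum = np.take_along_axis(
            np.broadcast_to(pooled, (b, n_all)), idx, axis=1
        ).sum(axis=1)
        young_mean = young_sum / n_young
        old_mean = (total - young_sum) / (n_all - n_young)
        hits += int(np.sum(np.abs(old_mean - young_mean) >= observed_abs - 1e-12))
        done += b
    return (1 + hits) / (1 + n_resample)


def fwhm_change_test(
    times: Sequence[float],
    young_replicates: Sequence[np.ndarray],
    old_replicates: Sequence[np.ndarray],
    n: int = DEFAULT_N_PERM,
    seed: int = 0,
    gene: str | None = None,
    p_threshold: float = 0.05,
    delta_threshold: float = 2.0,
    sog_threshold: float | None = DEFAULT_SOG_THRESHOLD,
    n_resample: int = 1000,
    cycle_length: float = 24.0,
) -> FWHMChange:
    """Test for an age-dependent change in ensemble-mean FWHM.

    Both ages must qualify as SOG (single-FWHM ratio above ``sog_threshold``),
    else a ValueError is raised; pass ``sog_threshold=None`` when SOG status
    was already adjudicated (the re-drawn ensembles here would otherwise
    re-randomize a borderline call).
    delta_fwhm = mean FWHM(old) - mean FWHM(young)
    over each ensemble's single-FWHM curves; the p-value resamples group
    labels between the two pooled FWHM distributions; a change is significant
    only when p < ``p_threshold`` AND |delta| > ``delta_threshold`` hours.
    """
    rng = np.random.default_rng(int(seed))
    seeds = rng.integers(0, 2**31, size=3)
    ens_y = permutation_curves(times, young_replicates, n=n, seed=int(seeds[0]))
    ens_o = permutation_curves(times, old_replicates, n=n, seed=int(seeds[1]))
    single_y, width_y, _, _ = _single_mask_and_fwhm(ens_y, cycle_length)
    single_o, width_o, _, _ = _single_mask_and_fwhm(ens_o, cycle_length)
    ratio_y = float(single_y.mean())
    ratio_o = float(single_o.mean())
    if sog_threshold is not None and (
        ratio_y <= sog_threshold or ratio_o <= sog_threshold
    ):
        raise ValueError(
            f"gene is not a SOG at both ages (single ratios {ratio_y:.3f}, {ratio_o:.3f})"
        )
    if not (single_y.any() and single_o.any()):
        raise ValueError("no single-FWHM curves in one of the ensembles")
    fy = width_y[single_y]
    fo = width_o[single_o]
    mean_y = float(fy.mean())
    mean_o = float(fo.mean())
    delta = mean_o - mean_y
    pooled = np.concatenate([fy, fo])
    p = _label_resample_pvalue(
        pooled, fy.size, abs(delta), n_resample, np.random.default_rng(int(seeds[2]))
    )
    significant = bool(p < p_threshold and abs(delta) > delta_threshold)
    if not significant:
        direction = "unchanged"
    else:
        direction = "lengthened" if delta > 0 else "shortened"
    return FWHMChange(
        gene=gene,
        delta_fwhm=delta,
        p_value=p,
        significant=significant,
        direction=direction,
        fwhm_young=mean_y,
        fwhm_old=mean_o,
    )


def classify_sog_sets(
    calls_young: pd.DataFrame, calls_old: pd.DataFrame
) -> dict[str, set[str]]:
    """Partition SOG calls from two ages into common / young-only / old-only.

    Both frames must come from the same gene universe (identical index sets).
    """
    if set(calls_young.index) != set(calls_old.index):
        raise ValueError("SOG calls come from different gene universes")
    young = set(calls_young.index[calls_young["is_sog"]])
    old = set(calls_old.index[calls_old["is_sog"]])
    return {
        "common": young & old,
        "young_only": young - old,
        "old_only": old - young,
    }
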