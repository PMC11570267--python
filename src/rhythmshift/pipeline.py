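"""End-to-end orchestration of the rhythmic-alteration analysis.

simulate (optional) -> cosinor detection per age -> SOG permutation tests ->
common-SOG FWHM-change tests -> physiological-time model on the reference
age -> descriptive summaries (set overlaps, ZT-by-ZT correlation matrix with
best matches, PCA coordinates, polar peak histogram, FWHM timetable).

Every count in the report is recomputable from the emitted TSV tables; the
JSON report additionally records the seed and a hash of the configuration so
equal configurations can be recognized as producing equal outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from sklearn.decomposition import PCA

from .matrix import ExpressionMatrix
from .phystime import (
    distance_from_reference_time,
    fit_time_model,
    loocv_by_timepoint,
    subjective_time_curve,
)
from .rhythmicity import DEFAULT_ALPHA, detect_cycling
from .sog import (
    DEFAULT_N_PERM,
    DEFAULT_SOG_THRESHOLD,
    classify_sog_sets,
    fwhm_change_test,
    sog_test_matrix,
)
from .synthetic import AgeEffect, SimConfig, simulate_expression_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "ReportBundle",
    "CorrelationResult",
    "correlation_matrix",
    "pca_projection",
    "polar_peak_histogram",
    "run_full_analysis",
    "study_sim_config",
]


def study_sim_config(
    seed: int = 0,
    n_cycling: int = 100,
    n_flat: int = 100,
    noise_cv: float = 0.1,
) -> SimConfig:
    """A two-age simulation emulating the study design: 6 ZTs x 3 replicates,
    a young reference age and an old age with attenuated amplitude, a slight
    phase advance, and broadened waveforms in half of the cycling genes."""
    return SimConfig(
        n_cycling=n_cycling,
        n_flat=n_flat,
        timepoints=(1, 5, 9, 13, 17, 21),
        n_replicates=3,
        noise_cv=noise_cv,
        seed=seed,
        ages={
            "young": AgeEffect(),
            "old": AgeEffect(
                amplitude_scale=0.5,
                phase_shift=-1.0,
                fwhm_delta_mode="broaden",
                applies_to=0.5,
            ),
        },
    )


@dataclass
class RunConfig:
    """Gates, sizes and seeds for one full analysis run."""

    sim: SimConfig
    reference_age: str | None = None  # defaults to the first age
    query_age: str | None = None  # defaults to the last age
    alpha: float = DEFAULT_ALPHA
    n_perm: int = DEFAULT_N_PERM
    sog_threshold: float = DEFAULT_SOG_THRESHOLD
    fwhm_p_threshold: float = 0.05
    fwhm_delta_threshold: float = 2.0
    n_resample: int = 1000
    ridge_penalty: float = 1.0
    peak_bin_width: float = 4.0
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        for gate in (
            self.alpha,
            self.sog_threshold,
            self.fwhm_p_threshold,
            self.fwhm_delta_threshold,
        ):
            if gate <= 0:
                raise ValueError("all gates must be positive")

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        sim = dict(d.pop("sim"))
        ages = {
            name: AgeEffect(**(eff or {})) for name, eff in sim.pop("ages", {}).items()
        } or {"young": AgeEffect()}
        if "timepoints" in sim:
            sim["timepoints"] = tuple(sim["timepoints"])
        return cls(sim=SimConfig(ages=ages, **sim), **d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        # the output location is not an analysis parameter
        payload = asdict(self)
        payload.pop("out_dir", None)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class CorrelationResult:
    """Query-ZT x reference-ZT Pearson matrix with best/second-best matches."""

    corr: pd.DataFrame  # rows: query ZT, cols: reference ZT
    best_match: pd.DataFrame  # per query ZT: best and second-best reference ZT


@dataclass
class ReportBundle:
    """Counts and tables summarizing one full run."""

    cycling_counts: dict
    cycling_overlap: dict
    sog_counts: dict
    sog_overlap: dict
    fwhm_change_counts: dict
    n_common_sog: int
    n_significant_change: int
    pct_significant_change: float
    correlation: CorrelationResult
    pca: pd.DataFrame
    pca_explained_variance: list
    polar: pd.DataFrame
    timetable: pd.DataFrame
    subjective_time: pd.DataFrame
    loocv_max_error: float
    seed: int
    config_hash: str
    tables: dict = field(default_factory=dict)


def correlation_matrix(
    reference: ExpressionMatrix,
    query: ExpressionMatrix,
    gene_set=None,
) -> CorrelationResult:
    """Pearson correlation between replicate-averaged ZT profiles of two
    matrices over a shared gene set, with best-match annotation per query ZT."""
    genes = list(gene_set) if gene_set is not None else list(
        reference.genes.intersection(query.genes)
    )
    if not genes:
        raise ValueError("shared gene set is empty")
    prof_ref = reference.zt_profiles(genes)
    prof_qry = query.zt_profiles(genes)
    corr = pd.DataFrame(
        index=pd.Index(prof_qry.columns, name="query_zt"),
        columns=pd.Index(prof_ref.columns, name="reference_zt"),
        dtype=float,
    )
    for q in prof_qry.columns:
        x = prof_qry[q].to_numpy()
        for r in prof_ref.columns:
            y = prof_ref[r].to_numpy()
            if x.std() == 0 or y.std() == 0:
                logger.warning("zero-variance profile at query %s / reference %s", q, r)
                corr.loc[q, r] = np.nan
            else:
                corr.loc[q, r] = float(np.corrcoef(x, y)[0, 1])
    best_rows = []
    for q in corr.index:
        row = corr.loc[q].dropna()
        order = row.sort_values(ascending=False)
        best_rows.append(
            {
                "query_zt": q,
                "best_reference_zt": order.index[0] if len(order) else np.nan,
                "best_pcc": order.iloc[0] if len(order) else np.nan,
                "second_reference_zt": order.index[1] if len(order) > 1 else np.nan,
                "second_pcc": order.iloc[1] if len(order) > 1 else np.nan,
            }
        )
    return CorrelationResult(corr=corr, best_match=pd.DataFrame(best_rows))


def pca_projection(
    matrices: Mapping[str, ExpressionMatrix],
    n_components: int = 3,
    normalize: bool = False,
    gene_set=None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples across ages; optionally normalize each gene by its
    per-age across-time mean first (merging amplitude-separated ages).

    Returns (coordinates with sample metadata, explained variance ratios).
    Degenerate covariance reduces the component count with a warning.
    """
    blocks, meta = [], []
    for age, m in matrices.items():
        data = m.data if gene_set is None else m.data.loc[list(gene_set)]
        vals = data.to_numpy(dtype=float)
        if normalize:
            means = vals.mean(axis=1, keepdims=True)
            means = np.where(means != 0, means, 1.0)
            vals = vals / means
        blocks.append(vals.T)  # samples x genes
        meta.append(m.samples.assign(age=age))
    X = np.vstack(blocks)
    samples = pd.concat(meta)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    rank = min(X.shape[0] - 1, X.shape[1])
    k = min(n_components, rank)
    if k < n_components:
        logger.warning("reducing PCA components from %d to %d (rank)", n_components, k)
    pca = PCA(n_components=k)
    coords = pca.fit_transform(X)
    out = samples.reset_index(names="sample")
    for i in range(k):
        out[f"PC{i + 1}"] = coords[:, i]
    return out, pca.explained_variance_ratio_


def polar_peak_histogram(
    directions: pd.Series,
    peak_times: pd.Series,
    bin_width: float = 4.0,
    period: float = 24.0,
) -> pd.DataFrame:
    """Count genes by peak-time bin and FWHM-change direction.

    ``directions`` maps gene -> 'shortened'/'lengthened' (other labels are
    ignored); ``peak_times`` maps gene -> peak hour in [0, period). Bin edges
    start at 0 with width ``bin_width``.
    """
    if period % bin_width != 0:
        raise ValueError("bin_width must divide the period")
    edges = np.arange(0.0, period + bin_width / 2, bin_width)
    labels = edges[:-1]
    keep = directions[directions.isin(["shortened", "lengthened"])]
    out = pd.DataFrame(
        0, index=pd.Index(labels, name="bin_start"), columns=["shortened", "lengthened"]
    )
    for gene, direction in keep.items():
        peak = float(peak_times[gene]) % period
        b = labels[int(peak // bin_width)]
        out.loc[b, direction] += 1
    return out


def _stage(name: str):
    logger.info("stage %s", name)
    return time.perf_counter()


def run_full_analysis(config: RunConfig) -> ReportBundle:
    """Run the whole analysis on a simulated two-age experiment.

    Writes one TSV per stage plus ``report.json`` when ``config.out_dir`` is
    set; aborts with a stage-labeled error on failure, keeping the tables
    written so far.
    """
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}
    timings: dict[str, float] = {}

    def emit(name: str, frame: pd.DataFrame, index: bool = True) -> None:
        tables[name] = frame
        if out_dir:
            frame.to_csv(out_dir / f"{name}.tsv", sep="\t", index=index)

    def run_stage(name: str, fn):
        t0 = _stage(name)
        try:
            result = fn()
        except Exception as e:  # pragma: no cover - error path
            raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
        timings[name] = time.perf_counter() - t0
        return result

    # -- simulate ----------------------------------------------------------
    matrices, truth = run_stage(
        "simulate", lambda: simulate_expression_matrix(config.sim)
    )
    ages = list(matrices)
    ref_age = config.reference_age or ages[0]
    qry_age = config.query_age or ages[-1]
    emit("ground_truth", truth, index=False)
    for age, m in matrices.items():
        emit(f"matrix_{age}", m.data)

    # -- rhythmicity -------------------------------------------------------
    cycling = run_stage(
        "detect_cycling",
        lambda: {a: detect_cycling(m, alpha=config.alpha) for a, m in matrices.items()},
    )
    for age, frame in cycling.items():
        emit(f"cosinor_{age}", frame)
    cyc_sets = {a: set(f.index[f["is_cycling"]]) for a, f in cycling.items()}
    cycling_counts = {a: len(s) for a, s in cyc_sets.items()}
    cycling_overlap = {
        "common": len(cyc_sets[ref_age] & cyc_sets[qry_age]),
        "reference_only": len(cyc_sets[ref_age] - cyc_sets[qry_age]),
        "query_only": len(cyc_sets[qry_age] - cyc_sets[ref_age]),
    }

    # -- SOG ---------------------------------------------------------------
    rng = np.random.default_rng(int(config.seed))
    sog_seeds = {a: int(s) for a, s in zip(ages, rng.integers(0, 2**31, len(ages)))}
    sog_calls = run_stage(
        "sog_test",
        lambda: {
            a: sog_test_matrix(
                matrices[a],
                n=config.n_perm,
                threshold=config.sog_threshold,
                seed=sog_seeds[a],
            )
            for a in ages
        },
    )
    for age, frame in sog_calls.items():
        emit(f"sog_{age}", frame)
    partition = classify_sog_sets(sog_calls[ref_age], sog_calls[qry_age])
    sog_counts = {a: int(sog_calls[a]["is_sog"].sum()) for a in ages}
    sog_overlap = {k: len(v) for k, v in partition.items()}
    common_sogs = sorted(partition["common"])

    # FWHM timetable: ensemble-mean crossings per gene per age
    timetable = pd.concat(
        {
            a: sog_calls[a].loc[
                sog_calls[a]["is_sog"], ["ascend_mean", "descend_mean", "fwhm_mean"]
            ]
            for a in ages
        },
        names=["age", "gene"],
    ).reset_index()
    emit("fwhm_timetable", timetable, index=False)

    # -- FWHM change on common SOGs ---------------------------------------
    def change_stage():
        rows = []
        change_rng = np.random.default_rng(int(config.seed) + 1)
        for gene in common_sogs:
            zts_y, reps_y = matrices[ref_age].replicate_values(gene)
            _, reps_o = matrices[qry_age].replicate_values(gene)
            res = fwhm_change_test(
                zts_y,
                reps_y,
                reps_o,
                n=config.n_perm,
                seed=int(change_rng.integers(0, 2**31)),
                gene=gene,
                p_threshold=config.fwhm_p_threshold,
                delta_threshold=config.fwhm_delta_threshold,
                sog_threshold=None,  # common-SOG status already adjudicated
                n_resample=config.n_resample,
            )
            rows.append(
                {
                    "gene": gene,
                    "fwhm_young": res.fwhm_young,
                    "fwhm_old": res.fwhm_old,
                    "delta_fwhm": res.delta_fwhm,
                    "p_value": res.p_value,
                    "significant": res.significant,
                    "direction": res.direction,
                }
            )
        return pd.DataFrame(rows)

    changes = run_stage("fwhm_change", change_stage)
    emit("fwhm_change", changes, index=False)
    if len(changes):
        changes_idx = changes.set_index("gene")
        n_sig = int(changes_idx["significant"].sum())
        counts = {
            "shortened": int((changes_idx["direction"] == "shortened").sum()),
            "lengthened": int((changes_idx["direction"] == "lengthened").sum()),
            "unchanged": int((changes_idx["direction"] == "unchanged").sum()),
        }
    else:
        changes_idx = changes
        n_sig = 0
        counts = {"shortened": 0, "lengthened": 0, "unchanged": 0}
    pct_sig = 100.0 * n_sig / len(common_sogs) if common_sogs else 0.0

    # -- physiological time ------------------------------------------------
    features = common_sogs or list(matrices[ref_age].genes)
    model = run_stage(
        "fit_time_model",
        lambda: fit_time_model(
            matrices[ref_age],
            penalty=config.ridge_penalty,
            feature_set=features,
            reference_label=ref_age,
        ),
    )
    loocv = run_stage(
        "loocv",
        lambda: loocv_by_timepoint(
            matrices[ref_age], penalty=config.ridge_penalty, feature_set=features
        ),
    )
    emit("loocv", loocv, index=False)
    curve = run_stage(
        "subjective_time", lambda: subjective_time_curve(model, matrices[qry_age])
    )
    distances = distance_from_reference_time(curve)
    subjective = pd.DataFrame(
        {
            "query_zt": curve.query_zts,
            "predicted_reference_time": curve.predicted,
            "span_to_next": curve.spans,
            "distance_from_noon": distances.to_numpy(),
        }
    )
    emit("subjective_time", subjective, index=False)

    # -- descriptive summaries --------------------------------------------
    corr = run_stage(
        "correlation",
        lambda: correlation_matrix(matrices[ref_age], matrices[qry_age], features),
    )
    emit("correlation", corr.corr)
    emit("correlation_best", corr.best_match, index=False)
    pca_coords, evr = run_stage(
        "pca", lambda: pca_projection(matrices, n_components=3, normalize=True,
                                      gene_set=features)
    )
    emit("pca", pca_coords, index=False)
    peaks = cycling[ref_age]["acrophase"]
    polar = run_stage(
        "polar_histogram",
        lambda: polar_peak_histogram(
            changes_idx["direction"] if len(changes) else pd.Series(dtype=object),
            peaks,
            bin_width=config.peak_bin_width,
        ),
    )
    emit("polar_histogram", polar)

    bundle = ReportBundle(
        cycling_counts=cycling_counts,
        cycling_overlap=cycling_overlap,
        sog_counts=sog_counts,
        sog_overlap=sog_overlap,
        fwhm_change_counts=counts,
        n_common_sog=len(common_sogs),
        n_significant_change=n_sig,
        pct_significant_change=pct_sig,
        correlation=corr,
        pca=pca_coords,
        pca_explained_variance=[float(x) for x in evr],
        polar=polar,
        timetable=timetable,
        subjective_time=subjective,
        loocv_max_error=float(loocv["error"].max()),
        seed=config.seed,
        config_hash=config.config_hash(),
        tables=tables,
    )
    if out_dir:
        report = {
            "seed": bundle.seed,
            "config_hash": bundle.config_hash,
            "cycling_counts": bundle.cycling_counts,
            "cycling_overlap": bundle.cycling_overlap,
            "sog_counts": bundle.sog_counts,
            "sog_overlap": bundle.sog_overlap,
            "n_common_sog": bundle.n_common_sog,
            "fwhm_change_counts": bundle.fwhm_change_counts,
            "n_significant_change": bundle.n_significant_change,
            "pct_significant_change": bundle.pct_significant_change,
            "loocv_max_error": bundle.loocv_max_error,
            "pca_explained_variance": bundle.pca_explained_variance,
            "stage_seconds": timings,
        }
        (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    logger.info("run complete: %s", {k: round(v, 2) for k, v in timings.items()})
    return bundle
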