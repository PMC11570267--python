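"""Gene x sample expression matrices with diurnal sampling metadata.

Samples are named ``<age>_ZT<h>_rep<k>`` (e.g. ``21DAS_ZT1_rep2``); the
metadata table carries the age label, Zeitgeber time in decimal hours, and
replicate id per sample, so downstream stages never re-parse column names.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .waveform import Curve

__all__ = ["ExpressionMatrix", "sample_name", "parse_sample_name"]

_SAMPLE_RE = re.compile(r"^(?P<age>.+)_ZT(?P<zt>\d+(?:\.\d+)?)_rep(?P<rep>\d+)$")


def sample_name(age: str, zt: float, rep: int) -> str:
    return f"{age}_ZT{zt:g}_rep{rep}"


def parse_sample_name(name: str) -> tuple[str, float, int]:
    m = _SAMPLE_RE.match(name)
    if m is None:
        raise ValueError(f"sample name {name!r} is not <age>_ZT<h>_rep<k>")
    return m.group("age"), float(m.group("zt")), int(m.group("rep"))


@dataclass
class ExpressionMatrix:
    """Genes x samples table plus per-sample (age, ZT, replicate) metadata."""

    data: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.data.columns.equals(self.samples.index):
            raise ValueError("sample metadata must match data columns")
        for col in ("age", "zt", "replicate"):
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata lacks column {col!r}")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_values(
        cls,
        values: np.ndarray,
        genes: list[str],
        age: str,
        timepoints: np.ndarray,
        n_replicates: int,
    ) -> "ExpressionMatrix":
        """Build from a (genes, timepoints, replicates) value array."""
        values = np.asarray(values, dtype=float)
        tps = np.asarray(timepoints, dtype=float)
        if values.shape != (len(genes), tps.size, n_replicates):
            raise ValueError("values shape must be (genes, timepoints, replicates)")
        cols, ages, zts, reps = [], [], [], []
        for zt in tps:
            for r in range(1, n_replicates + 1):
                cols.append(sample_name(age, float(zt), r))
                ages.append(age)
                zts.append(float(zt))
                reps.append(r)
        data = pd.DataFrame(
            values.reshape(len(genes), -1), index=genes, columns=cols
        )
        samples = pd.DataFrame(
            {"age": ages, "zt": zts, "replicate": reps}, index=pd.Index(cols)
        )
        return cls(data, samples)

    @classmethod
    def read_tsv(cls, path) -> "ExpressionMatrix":
        data = pd.read_csv(path, sep="\t", index_col=0)
        meta = [parse_sample_name(c) for c in data.columns]
        samples = pd.DataFrame(
            meta, columns=["age", "zt", "replicate"], index=data.columns
        )
        return cls(data, samples)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene")

    # -- views -------------------------------------------------------------

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def zts(self) -> np.ndarray:
        """Sorted unique sampling times (hours)."""
        return np.sort(self.samples["zt"].unique())

    @property
    def ages(self) -> list[str]:
        return list(dict.fromkeys(self.samples["age"]))

    def subset_age(self, age: str) -> "ExpressionMatrix":
        mask = self.samples["age"] == age
        if not mask.any():
            raise KeyError(f"no samples with age {age!r}")
        return ExpressionMatrix(self.data.loc[:, mask.to_numpy()], self.samples[mask])

    def replicate_values(self, gene: str) -> tuple[np.ndarray, list[np.ndarray]]:
        """Per-time-point replicate values: (sorted ZTs, list of value arrays)."""
        row = self.data.loc[gene]
        zts = self.zts
        out = []
        for zt in zts:
            cols = self.samples.index[self.samples["zt"] == zt]
            out.append(row[cols].to_numpy(dtype=float))
        return zts, out

    def gene_curve(self, gene: str, cycle_length: float = 24.0) -> Curve:
        """Replicate-averaged daily curve for one gene."""
        zts, reps = self.replicate_values(gene)
        means = np.array([r.mean() for r in reps])
        return Curve(zts, means, cycle_length=cycle_length)

    def zt_profiles(self, gene_set=None) -> pd.DataFrame:
        """Replicate-averaged genes x ZT profile table."""
        data = self.data if gene_set is None else self.data.loc[list(gene_set)]
        grouped = data.T.groupby(self.samples["zt"]).mean().T
        return grouped[np.sort(grouped.columns)]

    def with_shifted_times(self, delta: float, period: float = 24.0) -> "ExpressionMatrix":
        """Same data with all sample ZT labels shifted by ``delta`` (mod period)."""
        samples = self.samples.copy()
        samples["zt"] = (samples["zt"] + delta) % period
        return ExpressionMatrix(self.data.copy(), samples)
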