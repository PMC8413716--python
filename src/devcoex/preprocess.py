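"""Probe collapsing, sample QC, expression filtering and age intervals.

The preprocessing contract mirrors a standard exon-array reanalysis: probes
are collapsed to one row per gene (representative probe = highest mean
intensity), samples are kept only above an RNA-quality threshold
(RIN >= 8 by default), genes are kept only if consistently expressed
(log2 intensity >= 6 in every region x interval group), and samples are
partitioned into developmental intervals on a unified age axis.

The unified age axis is years relative to birth, with birth fixed at
38 weeks postconception, so prenatal ages are negative.  The default
interval scheme is:

    I-1  10-38 weeks postconception (prenatal)
    I-2  birth to < 6 years
    I-3  6 to < 40 years
    I-4  >= 40 years
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IntervalScheme",
    "FilterConfig",
    "age_to_years",
    "collapse_probes",
    "filter_samples",
    "filter_genes",
    "assign_intervals",
    "DEFAULT_SCHEME",
]

#: gestation length used to place birth on the weeks-postconception axis
BIRTH_WPC = 38.0
WEEKS_PER_YEAR = 365.25 / 7.0

_AGE_UNITS = ("weeks_postconception", "years")


def age_to_years(age_value: float, age_unit: str) -> float:
    """Convert an age to years since birth (negative = prenatal).

    ``weeks_postconception`` maps through birth at 38 WPC; ``years`` pass
    through unchanged.
    """
    if age_value < 0:
        raise ValueError(f"negative age {age_value}")
    if age_unit == "years":
        return float(age_value)
    if age_unit == "weeks_postconception":
        return (float(age_value) - BIRTH_WPC) / WEEKS_PER_YEAR
    raise ValueError(f"unknown age unit {age_unit!r}; expected one of {_AGE_UNITS}")


@dataclass(frozen=True)
class IntervalScheme:
    """Ordered, disjoint age intervals [lower, upper) on the unified axis."""

    intervals: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        ivs = tuple((str(l), float(a), float(b)) for l, a, b in self.intervals)
        object.__setattr__(self, "intervals", ivs)
        if not ivs:
            raise ValueError("interval scheme is empty")
        for label, lo, hi in ivs:
            if not lo < hi:
                raise ValueError(f"interval {label!r} has lower {lo} >= upper {hi}")
        for (l1, _, hi1), (l2, lo2, _) in zip(ivs, ivs[1:]):
            if hi1 > lo2:
                raise ValueError(f"intervals {l1!r} and {l2!r} overlap")
        if len({l for l, _, _ in ivs}) != len(ivs):
            raise ValueError("duplicate interval labels")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(l for l, _, _ in self.intervals)

    def assign(self, age_years: float) -> str | None:
        for label, lo, hi in self.intervals:
            if lo <= age_years < hi:
                return label
        return None

    @classmethod
    def default(cls) -> "IntervalScheme":
        return DEFAULT_SCHEME

    @classmethod
    def from_dict(cls, spec: Sequence[Mapping]) -> "IntervalScheme":
        """Build from YAML-style records with keys label/lower/upper."""
        return cls(tuple((d["label"], d["lower"], d["upper"]) for d in spec))

    def to_dict(self) -> list[dict]:
        return [{"label": l, "lower": lo, "upper": hi} for l, lo, hi in self.intervals]


DEFAULT_SCHEME = IntervalScheme(
    (
        ("I-1", age_to_years(10.0, "weeks_postconception"), 0.0),
        ("I-2", 0.0, 6.0),
        ("I-3", 6.0, 40.0),
        ("I-4", 40.0, float("inf")),
    )
)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for sample QC and the minimum-expression gene filter.

    ``summary`` chooses how the "expressed in every region and period" rule
    is evaluated within each (region x interval) group: ``"group_mean"``
    (default; robust to single outlier samples) or ``"per_sample_min"``
    (every individual sample must clear the threshold).
    """

    min_log2_intensity: float = 6.0
    min_rin: float = 8.0
    summary: str = "group_mean"

    def __post_init__(self) -> None:
        if not np.isfinite(self.min_log2_intensity) or not np.isfinite(self.min_rin):
            raise ValueError("filter thresholds must be finite")
        if self.summary not in ("group_mean", "per_sample_min"):
            raise ValueError(f"unknown summary mode {self.summary!r}")


def collapse_probes(
    probe_matrix: pd.DataFrame, probe_to_gene: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Collapse a probes x samples matrix to one row per gene.

    For genes measured by several probes the representative probe is the one
    with the highest mean intensity across samples; probes without a gene
    mapping are dropped.  Output rows are ordered by first appearance of the
    gene in the probe matrix.
    """
    mapping = pd.Series(dict(probe_to_gene) if not isinstance(probe_to_gene, pd.Series) else probe_to_gene)
    mapping = mapping.dropna()
    if mapping.empty:
        raise ValueError("probe-to-gene mapping is empty")
    mapped = probe_matrix.loc[probe_matrix.index.intersection(mapping.index)]
    if mapped.empty:
        raise ValueError("no probe in the matrix has a gene mapping")
    genes = mapping.loc[mapped.index].astype(str)
    means = mapped.mean(axis=1)
    # representative probe per gene: highest mean intensity
    order = pd.DataFrame({"gene": genes, "mean": means, "pos": range(len(mapped))})
    best = order.sort_values(["mean", "pos"], ascending=[False, True]).drop_duplicates("gene")
    best = best.sort_values("pos")  # preserve first-appearance order of genes
    out = mapped.loc[best.index]
    out.index = pd.Index(best["gene"].values, name="gene")
    return out


def filter_samples(samples: pd.DataFrame, cfg: FilterConfig) -> pd.DataFrame:
    """Retain samples with RIN >= cfg.min_rin (inclusive)."""
    if "RIN" not in samples.columns:
        raise ValueError("sample table has no RIN column")
    if samples["RIN"].isna().any():
        bad = samples.index[samples["RIN"].isna()].tolist()
        raise ValueError(f"missing RIN for samples {bad[:5]}")
    return samples.loc[samples["RIN"] >= cfg.min_rin]


def assign_intervals(samples: pd.DataFrame, scheme: IntervalScheme) -> pd.Series:
    """Map every sample to its developmental interval label.

    Samples whose age falls outside all intervals get ``pd.NA`` (flagged,
    never silently dropped).  Negative ages raise.
    """
    ages = [
        age_to_years(v, u) for v, u in zip(samples["age_value"], samples["age_unit"])
    ]
    labels = [scheme.assign(a) for a in ages]
    out = pd.Series(labels, index=samples.index, name="interval", dtype="object")
    return out.where(out.notna(), other=pd.NA)


def filter_genes(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    cfg: FilterConfig,
    scheme: IntervalScheme,
) -> pd.DataFrame:
    """Keep genes expressed at >= cfg.min_log2_intensity in every group.

    Groups are the full product of regions observed in the sample table and
    the scheme's intervals; an empty (region, interval) cell is an error
    naming the cell.  The per-group summary is the group mean by default
    (``cfg.summary``).  Row order is preserved.
    """
    missing = set(matrix.columns) - set(samples.index)
    if missing:
        raise ValueError(f"matrix columns not in the sample table: {sorted(missing)[:5]}")
    sub = samples.loc[list(matrix.columns)]
    intervals = assign_intervals(sub, scheme)
    regions = sorted(sub["region"].unique())
    keep = pd.Series(True, index=matrix.index)
    for label in scheme.labels:
        for region in regions:
            cols = matrix.columns[(intervals == label).values & (sub["region"] == region).values]
            if len(cols) == 0:
                raise ValueError(f"empty group: region={region!r}, interval={label!r}")
            block = matrix[cols]
            summary = block.mean(axis=1) if cfg.summary == "group_mean" else block.min(axis=1)
            keep &= summary >= cfg.min_log2_intensity
    return matrix.loc[keep]
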