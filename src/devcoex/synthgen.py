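"""Seeded synthetic expression data with planted coexpression modules.

The generator emulates the statistical structure that weighted coexpression
analysis assumes: groups of genes driven by a shared latent profile plus
independent Gaussian noise, on a log2-intensity scale.  Gene ``g`` in module
``m`` has expression

    x_gs = baseline + lambda_g * f_m(s) + sqrt(1 - lambda_g^2) * noise_sd * eps_gs

with ``f_m`` a standard-normal latent profile across samples, ``lambda_g``
drawn uniformly from ``loading_range`` (positive, so unsigned adjacency sees
the structure), and ``eps`` standard normal.  The loading is the
correlation root of the factor model: at ``noise_sd = 1`` two genes of the
same module correlate at ``lambda_g * lambda_h``, and as ``noise_sd -> 0``
within-module correlations go to 1 — the same convention the trait
strengths use.  Background genes are pure noise around the baseline
(``noise_sd * eps``).  Sample traits can be tied to chosen latent
profiles at a configured correlation strength, marker lists are subsets of
planted modules, and a risk list can be enriched in one module — giving
every downstream stage a known ground truth.

All randomness flows from a single integer seed through named sub-streams,
so identical configs produce bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enrich import GeneSetCollection, write_gmt

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_dataset",
    "generate_marker_collection",
    "generate_risk_list",
    "write_dataset",
]

REGIONS = ("DFC", "M1C", "HIP", "STR")

#: birth on the weeks-postconception axis; kept consistent with preprocess
_BIRTH_WPC = 38.0


class SynthConfigError(ValueError):
    """Raised when a :class:`SynthConfig` violates its invariants."""


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic study.

    ``module_sizes`` are the planted module sizes; genes not covered by them
    are background (pure noise).  ``background_fraction`` is optional and,
    when given, must agree with ``n_genes - sum(module_sizes)``.

    ``trait_spec`` entries are ``(name, module_index, strength)``: a numeric
    sample trait correlated at ``strength`` with the latent profile of the
    1-based module index.  ``marker_spec`` maps module index to marker-list
    size; ``risk_spec`` is ``(module_index, list_size, fraction_from_module)``.

    ``low_expression_fraction`` converts that fraction of the background
    genes to a low baseline (default 5.0) so the minimum-intensity filter
    has something to remove.  ``goi_name`` renames the first gene of
    ``goi_module`` (e.g. to "DDR1") so a gene of interest can be planted.
    """

    n_genes: int
    n_samples: int
    module_sizes: tuple[int, ...]
    noise_sd: float = 1.0
    loading_range: tuple[float, float] = (0.7, 0.9)
    background_fraction: float | None = None
    trait_spec: tuple[tuple[str, int, float], ...] = ()
    marker_spec: Mapping[int, int] = field(default_factory=dict)
    risk_spec: tuple[int, int, float] | None = None
    low_expression_fraction: float = 0.0
    baseline: float = 8.0
    low_baseline: float = 5.0
    prenatal_fraction: float = 0.25
    goi_name: str | None = None
    goi_module: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "module_sizes", tuple(int(s) for s in self.module_sizes))
        object.__setattr__(self, "marker_spec", dict(self.marker_spec))
        object.__setattr__(
            self, "trait_spec", tuple((str(n), int(m), float(r)) for n, m, r in self.trait_spec)
        )
        self.validate()

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    @property
    def n_background(self) -> int:
        return self.n_genes - sum(self.module_sizes)

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_samples < 1:
            raise SynthConfigError("n_genes and n_samples must be positive")
        if any(s < 1 for s in self.module_sizes):
            raise SynthConfigError("every module size must be >= 1")
        if self.n_background < 0:
            raise SynthConfigError(
                f"module_sizes sum to {sum(self.module_sizes)} > n_genes={self.n_genes}"
            )
        if self.background_fraction is not None:
            if not (0 <= self.background_fraction < 1):
                raise SynthConfigError("background_fraction must be in [0, 1)")
            implied = int(round(self.n_genes * self.background_fraction))
            if implied != self.n_background:
                raise SynthConfigError(
                    f"background_fraction implies {implied} background genes but "
                    f"n_genes - sum(module_sizes) = {self.n_background}"
                )
        if self.noise_sd < 0:
            raise SynthConfigError("noise_sd must be >= 0")
        lo, hi = self.loading_range
        if not (0 < lo <= hi <= 1):
            raise SynthConfigError("loading_range must satisfy 0 < lo <= hi <= 1")
        if not (0 <= self.low_expression_fraction < 1):
            raise SynthConfigError("low_expression_fraction must be in [0, 1)")
        n_low = int(round(self.low_expression_fraction * self.n_genes))
        if n_low > self.n_background:
            raise SynthConfigError("low-expression genes exceed the background pool")
        if not (0 <= self.prenatal_fraction <= 1):
            raise SynthConfigError("prenatal_fraction must be in [0, 1]")
        for name, m, r in self.trait_spec:
            if not (1 <= m <= self.n_modules):
                raise SynthConfigError(f"trait {name!r} references module {m}")
            if not (-1 <= r <= 1):
                raise SynthConfigError(f"trait {name!r} strength {r} outside [-1, 1]")
        for m, size in self.marker_spec.items():
            if not (1 <= m <= self.n_modules):
                raise SynthConfigError(f"marker_spec references module {m}")
            if size > self.module_sizes[m - 1]:
                raise SynthConfigError(
                    f"marker list of {size} exceeds module {m} size {self.module_sizes[m - 1]}"
                )
        if self.risk_spec is not None:
            m, size, frac = self.risk_spec
            if not (1 <= m <= self.n_modules):
                raise SynthConfigError(f"risk_spec references module {m}")
            if size > self.n_genes:
                raise SynthConfigError("risk list larger than the gene universe")
            if not (0 <= frac <= 1):
                raise SynthConfigError("risk fraction must be in [0, 1]")
            if int(round(frac * size)) > self.module_sizes[m - 1]:
                raise SynthConfigError("risk list demands more module genes than exist")
        if self.goi_name is not None and not (1 <= self.goi_module <= self.n_modules):
            raise SynthConfigError(f"goi_module {self.goi_module} does not exist")


@dataclass
class GroundTruth:
    """Planted structure of a generated dataset."""

    assignment: pd.Series  # gene -> module label, 0 = background
    latent_profiles: pd.DataFrame  # modules (M1..Mk) x samples
    marker_lists: GeneSetCollection | None = None
    risk_list: list[str] | None = None

    def module_genes(self, module: int) -> list[str]:
        return list(self.assignment.index[self.assignment == module])


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ("profiles", "loadings", "noise", "metadata", "traits", "markers", "risk")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _gene_names(cfg: SynthConfig) -> list[str]:
    names = [f"G{i:05d}" for i in range(cfg.n_genes)]
    if cfg.goi_name is not None:
        first = sum(cfg.module_sizes[: cfg.goi_module - 1])
        names[first] = str(cfg.goi_name).upper()
    return names


def _sample_metadata(cfg: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_samples
    prenatal = rng.random(n) < cfg.prenatal_fraction
    age_value = np.where(prenatal, rng.uniform(10.0, _BIRTH_WPC, n), rng.uniform(0.0, 60.0, n))
    return pd.DataFrame(
        {
            "sample_id": [f"S{i:04d}" for i in range(n)],
            "subject_id": [f"D{i:04d}" for i in range(n)],
            "age_value": age_value,
            "age_unit": np.where(prenatal, "weeks_postconception", "years"),
            "region": rng.choice(REGIONS, n),
            "hemisphere": rng.choice(["L", "R"], n),
            "sex": rng.choice(["F", "M"], n),
            "PMI": np.clip(rng.normal(15.0, 5.0, n), 1.0, None),
            "pH": rng.normal(6.5, 0.2, n),
            "RIN": rng.uniform(8.0, 10.0, n),
        }
    ).set_index("sample_id", drop=False)


def generate_dataset(
    config: SynthConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (expression matrix, sample table, ground truth).

    The expression matrix is genes x samples on a log2-like scale centred at
    ``config.baseline``.  If ``marker_spec`` / ``risk_spec`` are set, the
    returned truth carries the corresponding marker collection and risk list.
    """
    config.validate()
    rng = _streams(config.seed)

    genes = _gene_names(config)
    labels = np.zeros(config.n_genes, dtype=int)
    pos = 0
    for m, size in enumerate(config.module_sizes, start=1):
        labels[pos : pos + size] = m
        pos += size
    assignment = pd.Series(labels, index=pd.Index(genes, name="gene"), name="module")

    samples = _sample_metadata(config, rng["metadata"])
    profiles = rng["profiles"].standard_normal((config.n_modules, config.n_samples))
    lo, hi = config.loading_range
    loadings = rng["loadings"].uniform(lo, hi, config.n_genes)

    expr = np.full((config.n_genes, config.n_samples), config.baseline)
    module_rows = labels > 0
    expr[module_rows] += loadings[module_rows, None] * profiles[labels[module_rows] - 1]
    noise_scale = np.where(module_rows, np.sqrt(1.0 - loadings**2), 1.0) * config.noise_sd
    expr += noise_scale[:, None] * rng["noise"].standard_normal(expr.shape)

    n_low = int(round(config.low_expression_fraction * config.n_genes))
    if n_low:
        # last n_low background genes sit below the intensity filter
        bg_idx = np.flatnonzero(~module_rows)[-n_low:]
        expr[bg_idx] += config.low_baseline - config.baseline

    matrix = pd.DataFrame(expr, index=assignment.index, columns=samples.index)

    for name, m, strength in config.trait_spec:
        z = rng["traits"].standard_normal(config.n_samples)
        samples[name] = strength * profiles[m - 1] + np.sqrt(1.0 - strength**2) * z

    truth = GroundTruth(
        assignment=assignment,
        latent_profiles=pd.DataFrame(
            profiles,
            index=[f"M{m}" for m in range(1, config.n_modules + 1)],
            columns=samples.index,
        ),
    )
    if config.marker_spec:
        truth.marker_lists = generate_marker_collection(truth, config)
    if config.risk_spec is not None:
        truth.risk_list = generate_risk_list(truth, config)
    return matrix, samples, truth


def generate_marker_collection(truth: GroundTruth, config: SynthConfig) -> GeneSetCollection:
    """Named marker lists, each a uniform random subset of one planted module.

    Stands in for curated cell-type marker collections: every marker truly
    belongs to its module, so enrichment of recovered modules against these
    lists has a known answer.
    """
    rng = _streams(config.seed)["markers"]
    sets: dict[str, frozenset[str]] = {}
    for m, size in sorted(config.marker_spec.items()):
        pool = truth.module_genes(m)
        if size > len(pool):
            raise SynthConfigError(f"marker list of {size} exceeds module {m} size {len(pool)}")
        chosen = rng.choice(np.array(sorted(pool)), size=size, replace=False)
        sets[f"M{m}_markers"] = frozenset(str(g) for g in chosen)
    return GeneSetCollection(sets=sets, provenance="synthetic planted-module markers")


def generate_risk_list(truth: GroundTruth, config: SynthConfig) -> list[str]:
    """Risk-gene list with a configured fraction drawn from one module.

    The remainder is drawn uniformly from all genes outside that module;
    no duplicates.  With fraction 1.0 the list sits entirely inside the
    module (the construction used to exercise the bootstrap p floor).
    """
    if config.risk_spec is None:
        raise SynthConfigError("risk_spec is not set")
    m, size, frac = config.risk_spec
    rng = _streams(config.seed)["risk"]
    inside_pool = np.array(sorted(truth.module_genes(m)))
    outside_pool = np.array(sorted(set(truth.assignment.index) - set(inside_pool)))
    n_in = int(round(frac * size))
    n_out = size - n_in
    if n_out > len(outside_pool):
        raise SynthConfigError("risk list larger than the non-module universe")
    picked = []
    if n_in:
        picked.extend(rng.choice(inside_pool, size=n_in, replace=False))
    if n_out:
        picked.extend(rng.choice(outside_pool, size=n_out, replace=False))
    return [str(g) for g in picked]


def write_dataset(
    outdir: str | Path,
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    truth: GroundTruth,
) -> dict[str, Path]:
    """Write a generated study to TSV/GMT/plain-text files; returns the paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "samples": out / "samples.tsv",
        "truth": out / "true_modules.tsv",
    }
    matrix.to_csv(paths["expression"], sep="\t", float_format="%.10g")
    samples.to_csv(paths["samples"], sep="\t", index=False, float_format="%.10g")
    truth.assignment.to_frame().to_csv(paths["truth"], sep="\t")
    if truth.marker_lists is not None:
        paths["markers"] = out / "markers.gmt"
        write_gmt(truth.marker_lists, paths["markers"])
    if truth.risk_list is not None:
        paths["risk"] = out / "risk_genes.txt"
        paths["risk"].write_text("\n".join(truth.risk_list) + "\n")
    return paths
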