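"""End-to-end orchestration of the per-interval coexpression analysis.

For each developmental interval the pipeline runs: expression filter ->
soft-power selection -> adjacency -> TOM -> average-linkage clustering ->
dynamic tree cut -> size-ordered relabelling -> module eigengenes ->
eigengene-trait correlations -> gene-list enrichment (Bonferroni within
the interval) -> bootstrap risk-list overlap on the module containing the
gene of interest.  Across intervals, module labels of intervals 2..k are
matched to interval 1 by hypergeometric overlap so the same biology keeps
the same label.

Every stage is logged with its parameters; a fixed seed makes the whole
study byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import enrich as _enrich
from . import modstats, netbuild, preprocess, treecut
from .enrich import BootstrapResult, GeneSetCollection
from .modstats import EigengeneSet
from .netbuild import NetworkConfig, PowerSelection
from .preprocess import FilterConfig, IntervalScheme
from .treecut import TreeCutConfig

__all__ = ["StudyConfig", "IntervalReport", "run_interval", "run_study", "write_reports"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StudyConfig:
    """Everything needed to re-run one study."""

    expression: str | None = None
    samples: str | None = None
    collections: tuple[str, ...] = ()
    risk_list: str | None = None
    scheme: IntervalScheme = field(default_factory=IntervalScheme.default)
    filter: FilterConfig = field(default_factory=FilterConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    treecut: TreeCutConfig = field(default_factory=TreeCutConfig)
    match_p_threshold: float = 0.05
    bootstrap_B: int = 10_000
    bootstrap_convention: str = "floor"
    exclude_goi_from_module: bool = False
    gene_of_interest: str = "DDR1"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        for key in (
            "expression",
            "samples",
            "risk_list",
            "match_p_threshold",
            "bootstrap_B",
            "bootstrap_convention",
            "exclude_goi_from_module",
            "gene_of_interest",
            "seed",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "collections" in raw:
            kwargs["collections"] = tuple(raw["collections"])
        if "scheme" in raw:
            kwargs["scheme"] = IntervalScheme.from_dict(raw["scheme"])
        for key, cls_ in (("filter", FilterConfig), ("network", NetworkConfig), ("treecut", TreeCutConfig)):
            if key in raw:
                kwargs[key] = cls_(**raw[key])
        return cls(**kwargs)

    def to_manifest(self) -> dict:
        """JSON-serialisable record of every parameter (for the run log)."""
        d = dataclasses.asdict(self)
        d["scheme"] = self.scheme.to_dict()
        return d


@dataclass
class IntervalReport:
    """Everything the pipeline learned about one interval."""

    interval: str
    n_samples: int
    n_genes: int
    power: int
    power_warning: bool
    scale_free_r2: float
    assignment: pd.Series
    module_count: int
    eigengenes: EigengeneSet | None
    trait_correlations: pd.DataFrame | None
    enrichment: pd.DataFrame | None
    goi_module: int | None  # None = gene of interest absent after filtering
    bootstrap: BootstrapResult | None
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None

    def summary(self) -> dict:
        return {
            "interval": self.interval,
            "n_samples": self.n_samples,
            "n_genes": self.n_genes,
            "power": self.power,
            "power_warning": self.power_warning,
            "scale_free_r2": self.scale_free_r2,
            "module_count": self.module_count,
            "goi_module": self.goi_module,
            "bootstrap_p": None if self.bootstrap is None else self.bootstrap.empirical_p,
            "error": self.error,
        }


def run_interval(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    cfg: StudyConfig,
    collections: GeneSetCollection | None = None,
    risk_list: Sequence[str] | None = None,
    interval_label: str = "all",
    apply_gene_filter: bool = True,
) -> IntervalReport:
    """Run the full single-interval analysis on an in-memory dataset.

    ``matrix`` is genes x samples for this interval only; the expression
    filter (if applied) groups by region within the interval.  Enrichment
    is Bonferroni-corrected over all (module, list) tests of this interval.
    The bootstrap runs on the module containing ``cfg.gene_of_interest``
    and is skipped with a warning when the gene is absent or in module 0.
    """
    if matrix.shape[1] < 8:
        raise ValueError(f"interval {interval_label!r} has {matrix.shape[1]} samples; need >= 8")
    if matrix.shape[1] < 15:
        logger.warning("interval %s has only %d samples; power may be low", interval_label, matrix.shape[1])

    if apply_gene_filter:
        ages = [
            preprocess.age_to_years(v, u)
            for v, u in zip(samples["age_value"], samples["age_unit"])
        ]
        lo, hi = min(ages), max(ages)
        one_interval = IntervalScheme(((interval_label, lo, np.nextafter(hi, np.inf)),))
        matrix = preprocess.filter_genes(matrix, samples, cfg.filter, one_interval)
    logger.info("interval %s: %d genes x %d samples", interval_label, *matrix.shape)

    selection = netbuild.pick_power(matrix, cfg.network)
    logger.info(
        "interval %s: power=%d r2=%.3f slope=%.2f warning=%s",
        interval_label, selection.power, selection.fit.r2, selection.fit.slope, selection.warning,
    )
    cor = netbuild.correlation_matrix(matrix)
    adj = netbuild.adjacency(cor, selection.power, cfg.network.network_sign)
    tom = netbuild.tom(adj)
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    Z = treecut.cluster_tree(diss)
    assignment = treecut.cut_tree_dynamic(Z, diss, cfg.treecut, gene_ids=list(matrix.index))
    if cfg.treecut.merge_similar and assignment.max() > 1:
        assignment = modstats.merge_similar_modules(matrix, assignment)
    module_count = int(assignment.max())
    logger.info("interval %s: %d modules (+%d background genes)",
                interval_label, module_count, int((assignment == 0).sum()))

    mes = trait_table = None
    if module_count:
        mes = modstats.module_eigengenes(matrix, assignment)
        trait_table = modstats.eigengene_trait_correlation(mes, samples)

    background = [str(g).upper() for g in matrix.index]
    enrichment = None
    if collections is not None and len(collections):
        restricted = _enrich.restrict_to_background(collections, background)
        if len(restricted) and module_count:
            enrichment = _enrich.hypergeom_enrichment(assignment, restricted, background)
    if enrichment is None:
        enrichment = pd.DataFrame(
            columns=["module", "list", "module_size", "list_size",
                     "background_size", "overlap", "p", "adjP", "significant"]
        )

    goi = cfg.gene_of_interest.upper()
    goi_module: int | None = None
    bootstrap = None
    upper_index = {str(g).upper(): g for g in assignment.index}
    if goi in upper_index:
        goi_module = int(assignment[upper_index[goi]])
        if risk_list is not None and goi_module > 0:
            module_genes = {
                str(g).upper() for g in assignment.index[assignment == goi_module]
            }
            if cfg.exclude_goi_from_module:
                module_genes.discard(goi)
            bootstrap = _enrich.bootstrap_overlap(
                module_genes,
                risk_list,
                background,
                B=cfg.bootstrap_B,
                seed=_interval_seed(cfg.seed, interval_label),
                convention=cfg.bootstrap_convention,
            )
            logger.info(
                "interval %s: gene of interest in module %d; overlap=%d empirical_p=%g",
                interval_label, goi_module, bootstrap.observed_overlap, bootstrap.empirical_p,
            )
        elif risk_list is not None:
            logger.warning(
                "interval %s: gene of interest %s is background (module 0); bootstrap skipped",
                interval_label, goi,
            )
    else:
        logger.warning(
            "interval %s: gene of interest %s absent after filtering; bootstrap skipped",
            interval_label, goi,
        )

    return IntervalReport(
        interval=interval_label,
        n_samples=matrix.shape[1],
        n_genes=matrix.shape[0],
        power=selection.power,
        power_warning=selection.warning,
        scale_free_r2=selection.fit.r2,
        assignment=assignment,
        module_count=module_count,
        eigengenes=mes,
        trait_correlations=trait_table,
        enrichment=enrichment,
        goi_module=goi_module,
        bootstrap=bootstrap,
    )


def _interval_seed(seed: int, label: str) -> int:
    """Stable per-interval sub-seed (< 2**31)."""
    h = np.random.SeedSequence([seed, zlib.crc32(label.encode()) % (2**31)])
    return int(h.generate_state(1)[0] % (2**31))


def _stub_report(label: str, err: Exception) -> IntervalReport:
    return IntervalReport(
        interval=label, n_samples=0, n_genes=0, power=0, power_warning=False,
        scale_free_r2=float("nan"), assignment=pd.Series(dtype=int), module_count=0,
        eigengenes=None, trait_correlations=None, enrichment=None,
        goi_module=None, bootstrap=None, error=f"{type(err).__name__}: {err}",
    )


def run_study(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    cfg: StudyConfig,
    collections: GeneSetCollection | None = None,
    risk_list: Sequence[str] | None = None,
) -> tuple[list[IntervalReport], pd.DataFrame]:
    """Run the whole multi-interval study on in-memory data.

    Sample QC (RIN) and the global expression filter (region x interval)
    run first; the cohort is then split by interval and analysed
    independently.  Module labels of later intervals are matched to the
    first interval's.  An interval that errors yields a stub report; the
    other intervals still run.  Returns (reports, summary table).
    """
    samples = preprocess.filter_samples(samples, cfg.filter)
    matrix = matrix[samples.index.intersection(matrix.columns)]
    matrix = preprocess.filter_genes(matrix, samples, cfg.filter, cfg.scheme)
    intervals = preprocess.assign_intervals(samples, cfg.scheme)
    n_out = int(intervals.isna().sum())
    if n_out:
        logger.warning("%d samples fall outside every interval and are set aside", n_out)

    reports: list[IntervalReport] = []
    for label in cfg.scheme.labels:
        cols = samples.index[(intervals == label).fillna(False)]
        cols = matrix.columns.intersection(cols)
        try:
            if len(cols) == 0:
                raise ValueError(f"interval {label!r} has no samples")
            report = run_interval(
                matrix[cols], samples.loc[cols], cfg,
                collections=collections, risk_list=risk_list,
                interval_label=label, apply_gene_filter=False,
            )
        except Exception as err:  # failure isolation across intervals
            logger.error("interval %s failed: %s", label, err)
            report = _stub_report(label, err)
        reports.append(report)

    reference = next((r for r in reports if r.ok and r.module_count), None)
    if reference is not None:
        for r in reports:
            if r is reference or not r.ok or not r.module_count:
                continue
            r.assignment = modstats.match_labels(
                reference.assignment, r.assignment, cfg.match_p_threshold
            )
            if r.goi_module is not None and r.goi_module > 0:
                upper_index = {str(g).upper(): g for g in r.assignment.index}
                goi = cfg.gene_of_interest.upper()
                if goi in upper_index:
                    r.goi_module = int(r.assignment[upper_index[goi]])
            r.module_count = int(r.assignment.max())

    summary = pd.DataFrame([r.summary() for r in reports])
    return reports, summary


def run_study_files(cfg: StudyConfig, outdir: str | Path | None = None):
    """Load the study inputs from ``cfg`` paths, run, optionally write."""
    if cfg.expression is None or cfg.samples is None:
        raise ValueError("study config must name expression and sample tables")
    matrix = pd.read_csv(cfg.expression, sep="\t", index_col=0)
    samples = pd.read_csv(cfg.samples, sep="\t")
    samples = samples.set_index("sample_id", drop=False)
    collections = None
    if cfg.collections:
        merged: dict[str, frozenset[str]] = {}
        for path in cfg.collections:
            merged.update(dict(_enrich.read_gmt(path).sets))
        collections = GeneSetCollection(sets=merged, provenance=";".join(cfg.collections))
    risk = _enrich.read_gene_list(cfg.risk_list) if cfg.risk_list else None
    reports, summary = run_study(matrix, samples, cfg, collections, risk)
    if outdir is not None:
        write_reports(reports, summary, cfg, outdir)
    return reports, summary


def write_reports(
    reports: Sequence[IntervalReport],
    summary: pd.DataFrame,
    cfg: StudyConfig,
    outdir: str | Path,
) -> None:
    """Persist per-interval TSV tables plus a JSON run manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = "%.10g"
    summary.to_csv(out / "summary.tsv", sep="\t", index=False, float_format=fmt)
    for r in reports:
        if not r.ok:
            continue
        tag = r.interval.replace("/", "_")
        ann = r.assignment.to_frame()
        ann["color"] = [treecut.module_color(int(m)) for m in ann["module"]]
        ann.to_csv(out / f"{tag}.modules.tsv", sep="\t")
        if r.eigengenes is not None:
            r.eigengenes.eigengenes.to_csv(out / f"{tag}.eigengenes.tsv", sep="\t", float_format=fmt)
            r.eigengenes.variance_explained.to_frame().to_csv(
                out / f"{tag}.variance_explained.tsv", sep="\t", float_format=fmt
            )
        if r.trait_correlations is not None:
            r.trait_correlations.to_csv(
                out / f"{tag}.trait_correlations.tsv", sep="\t", index=False, float_format=fmt
            )
        if r.enrichment is not None:
            r.enrichment.to_csv(out / f"{tag}.enrichment.tsv", sep="\t", index=False, float_format=fmt)
        if r.bootstrap is not None:
            pd.DataFrame({"null_overlap": r.bootstrap.null_overlaps}).to_csv(
                out / f"{tag}.bootstrap_null.tsv", sep="\t", index=False
            )
    manifest = {
        "config": cfg.to_manifest(),
        "intervals": [r.summary() for r in reports],
        "bootstrap": {
            r.interval: r.bootstrap.summary() for r in reports if r.bootstrap is not None
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
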