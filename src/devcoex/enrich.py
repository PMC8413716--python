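"""Gene-set enrichment of coexpression modules and the bootstrap overlap test.

Two statistics live here.  The first is the classical hypergeometric
over-representation test of each module against each curated gene list
(cell-type markers, myelin genes, ...), with the upper-tail probability
P(X >= x) computed on the background of analysed genes and Bonferroni
correction over all (module, list) tests of a run.  The second is an
empirical overlap test for a single gene list against a single module:
draw B random gene sets of the module's size from the background, count
their overlap with the risk list, and report the fraction of replicates
whose overlap reaches the observed one.  With the default convention
``max(r, 1) / B`` the smallest attainable p is 1/B (1e-4 at B = 10,000).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "GeneSetCollection",
    "BootstrapResult",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "restrict_to_background",
    "hypergeom_tail",
    "hypergeom_enrichment",
    "bonferroni",
    "bootstrap_overlap",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (e.g. cell-type marker lists) with a provenance label.

    Identifiers are uppercased on construction; empty sets are rejected.
    """

    sets: Mapping[str, frozenset[str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for name, genes in self.sets.items():
            genes = frozenset(str(g).upper() for g in genes)
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            clean[str(name)] = genes
        object.__setattr__(self, "sets", clean)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]


def read_gmt(path: str | Path, provenance: str | None = None) -> GeneSetCollection:
    """Read a GMT file (tab-separated: name, description, genes...)."""
    sets: dict[str, frozenset[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[fields[0]] = frozenset(g.upper() for g in fields[2:] if g)
    return GeneSetCollection(sets=sets, provenance=provenance or str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, collection.provenance or "na", *sorted(genes)])
        for name, genes in collection
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines ignored; uppercased."""
    return [
        line.strip().upper() for line in Path(path).read_text().splitlines() if line.strip()
    ]


def restrict_to_background(
    collection: GeneSetCollection, background: Iterable[str]
) -> GeneSetCollection:
    """Intersect every list with the analysed gene universe.

    Lists emptied by the restriction are dropped with a warning — they can
    contribute no overlap and would only inflate the test count.
    """
    bg = frozenset(str(g).upper() for g in background)
    if not bg:
        raise ValueError("background is empty")
    kept: dict[str, frozenset[str]] = {}
    for name, genes in collection:
        inter = genes & bg
        if inter:
            kept[name] = inter
        else:
            logger.warning("gene set %r has no genes in the background; dropped", name)
    return GeneSetCollection(sets=kept, provenance=collection.provenance)


def hypergeom_tail(x: int, N: int, l: int, m: int) -> float:
    """Upper-tail P(X >= x), X ~ Hypergeom(population N, successes l, draws m)."""
    if x <= 0:
        return 1.0
    return float(hypergeom.sf(x - 1, N, l, m))


def hypergeom_enrichment(
    assignment: pd.Series,
    collection: GeneSetCollection,
    background: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of every module in every gene list.

    ``assignment`` maps gene -> module label; module 0 (background genes) is
    excluded from testing.  Raw p is the inclusive upper tail; adjP is
    Bonferroni over all (module, list) pairs tested in this call, capped at 1.
    """
    bg = frozenset(str(g).upper() for g in background)
    assignment = assignment.copy()
    assignment.index = assignment.index.astype(str).str.upper()
    N = len(bg)
    modules = sorted(int(m) for m in assignment.unique() if int(m) != 0)
    rows = []
    for m in modules:
        module_genes = frozenset(assignment.index[assignment == m]) & bg
        if len(module_genes) > N:
            raise ValueError(f"module {m} is larger than the background")
        for name, genes in collection:
            genes = genes & bg
            x = len(module_genes & genes)
            rows.append(
                {
                    "module": m,
                    "list": name,
                    "module_size": len(module_genes),
                    "list_size": len(genes),
                    "background_size": N,
                    "overlap": x,
                    "p": hypergeom_tail(x, N, len(genes), len(module_genes)),
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "module",
            "list",
            "module_size",
            "list_size",
            "background_size",
            "overlap",
            "p",
        ],
    )
    return bonferroni(table, n_tests=len(table)) if len(table) else table.assign(adjP=[], significant=[])


def bonferroni(results: pd.DataFrame, n_tests: int, alpha: float = 0.05) -> pd.DataFrame:
    """Bonferroni-adjust the ``p`` column: adjP = min(1, p * n_tests)."""
    if n_tests < len(results):
        raise ValueError(f"n_tests={n_tests} smaller than the number of results {len(results)}")
    out = results.copy()
    out["adjP"] = np.minimum(1.0, out["p"] * n_tests)
    out["significant"] = out["adjP"] < alpha
    return out


@dataclass
class BootstrapResult:
    """Outcome of the randomized-overlap (bootstrap) test for one module."""

    observed_overlap: int
    replicates: int
    null_overlaps: np.ndarray
    empirical_p: float
    seed: int | None
    convention: str = "floor"

    def summary(self) -> dict:
        return {
            "observed_overlap": int(self.observed_overlap),
            "replicates": int(self.replicates),
            "null_mean": float(np.mean(self.null_overlaps)),
            "null_max": int(np.max(self.null_overlaps)),
            "empirical_p": float(self.empirical_p),
            "convention": self.convention,
        }


def bootstrap_overlap(
    module_genes: Iterable[str],
    risk_list: Iterable[str],
    background: Iterable[str],
    B: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    convention: str = "floor",
) -> BootstrapResult:
    """Empirical overlap test of a gene list with one module.

    Draws ``B`` uniform random subsets of the background, each of the
    module's size and without replacement, and counts how many overlap the
    risk list at least as much as the module does.  ``convention='floor'``
    gives ``p = max(r, 1) / B`` (floor 1/B); ``'add_one'`` gives
    ``(r + 1) / (B + 1)``.  The risk list is restricted to the background
    before counting.
    """
    if convention not in ("floor", "add_one"):
        raise ValueError(f"unknown convention {convention!r}")
    bg = sorted({str(g).upper() for g in background})
    module = {str(g).upper() for g in module_genes}
    if not module <= set(bg):
        raise ValueError("module genes must be a subset of the background")
    if B < 1:
        raise ValueError("B must be >= 1")
    risk = {str(g).upper() for g in risk_list} & set(bg)
    m = len(module)
    if m > len(bg):
        raise ValueError("module larger than the background")
    x_obs = len(module & risk)
    if rng is None:
        rng = np.random.default_rng(seed)
    risk_mask = np.fromiter((g in risk for g in bg), dtype=bool, count=len(bg))
    n = len(bg)
    null = np.empty(B, dtype=np.int64)
    for b in range(B):
        draw = rng.choice(n, size=m, replace=False)
        null[b] = int(risk_mask[draw].sum())
    r = int(np.count_nonzero(null >= x_obs))
    if convention == "floor":
        p = max(r, 1) / B
    else:
        p = (r + 1) / (B + 1)
    return BootstrapResult(
        observed_overlap=x_obs,
        replicates=B,
        null_overlaps=null,
        empirical_p=p,
        seed=seed,
        convention=convention,
    )
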