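"""Module eigengenes, eigengene-trait correlations, and label matching.

The module eigengene (ME) summarises a module per sample: member genes are
standardised across samples and the first principal component of the
member x sample matrix is taken as the sample-wise score vector, oriented
so it correlates positively with the module's mean standardised expression
and scaled to unit variance.  Variance explained is the leading eigenvalue
share of the member covariance spectrum.

Eigengene-trait correlation is plain Pearson r with the exact t-transform
p-value (t = r * sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom).  Two-level
categorical traits are encoded 0/1; multi-level factors expand to one
indicator per level.

Label matching aligns module labels of one network to a reference network
(typically the first developmental interval) by hypergeometric overlap:
pairs are matched greedily in ascending p, each reference label used at
most once; unmatched test modules receive fresh labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrich import hypergeom_tail

__all__ = [
    "EigengeneSet",
    "module_eigengenes",
    "eigengene_trait_correlation",
    "match_labels",
    "merge_similar_modules",
]


@dataclass
class EigengeneSet:
    """First-principal-component summaries of every module.

    ``eigengenes``: samples x modules (columns "ME1", "ME2", ...), each
    column mean-free up to orientation and unit variance.
    ``variance_explained``: module label -> leading eigenvalue share.
    """

    eigengenes: pd.DataFrame
    variance_explained: pd.Series

    @property
    def modules(self) -> list[int]:
        return [int(c[2:]) for c in self.eigengenes.columns]


def _standardize(values: np.ndarray) -> np.ndarray:
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant gene inside a module; cannot standardise")
    return (values - mean) / sd


def module_eigengenes(matrix: pd.DataFrame, assignment: pd.Series) -> EigengeneSet:
    """Compute the eigengene of every module (label >= 1).

    Modules with fewer than two member genes present in the matrix raise.
    Module 0 (background) is excluded.
    """
    assignment = assignment.reindex(matrix.index)
    labels = sorted(int(m) for m in assignment.dropna().unique() if int(m) != 0)
    if not labels:
        raise ValueError("no modules (labels >= 1) in the assignment")
    cols: dict[str, np.ndarray] = {}
    var_exp: dict[int, float] = {}
    for m in labels:
        members = matrix.index[(assignment == m).fillna(False)]
        if len(members) < 2:
            raise ValueError(f"module {m} has {len(members)} gene(s); need >= 2")
        X = _standardize(np.asarray(matrix.loc[members], dtype=float))
        # first right singular vector = sample-wise PC scores direction
        _, s, vt = np.linalg.svd(X, full_matrices=False)
        me = vt[0]
        mean_profile = X.mean(axis=0)
        if np.dot(me, mean_profile) < 0:
            me = -me
        sd = me.std(ddof=1)
        if sd > 0:
            me = me / sd
        cols[f"ME{m}"] = me
        var_exp[m] = float(s[0] ** 2 / np.sum(s**2))
    eigengenes = pd.DataFrame(cols, index=matrix.columns)
    return EigengeneSet(
        eigengenes=eigengenes,
        variance_explained=pd.Series(var_exp, name="variance_explained"),
    )


def _encode_trait(values: pd.Series) -> dict[str, np.ndarray] | None:
    """Numeric passthrough; 2-level factors -> 0/1; k-level -> k indicators."""
    if pd.api.types.is_numeric_dtype(values):
        return {values.name: np.asarray(values, dtype=float)}
    levels = sorted(values.dropna().astype(str).unique())
    if len(levels) < 2:
        return None
    if len(levels) == 2:
        return {values.name: (values.astype(str) == levels[1]).to_numpy(dtype=float)}
    return {
        f"{values.name}={lev}": (values.astype(str) == lev).to_numpy(dtype=float)
        for lev in levels
    }


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and its exact two-sided t-transform p on n-2 df."""
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def eigengene_trait_correlation(
    mes: EigengeneSet,
    samples: pd.DataFrame,
    traits: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Correlate every eigengene with every (encoded) sample trait.

    ``traits`` defaults to every column except identifier columns.  Traits
    with a single unique value are excluded and recorded in the result's
    ``attrs["excluded_traits"]``.
    """
    if traits is None:
        traits = [c for c in samples.columns if c not in ("sample_id", "subject_id")]
    samples = samples.loc[mes.eigengenes.index]
    encoded: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    for name in traits:
        col = samples[name]
        if col.nunique(dropna=True) < 2:
            excluded.append(name)
            continue
        enc = _encode_trait(col.rename(name))
        if enc is None:
            excluded.append(name)
        else:
            encoded.update(enc)
    rows = []
    for me_name in mes.eigengenes.columns:
        me = mes.eigengenes[me_name].to_numpy()
        for trait, values in encoded.items():
            r, p = pearson_with_p(me, values)
            rows.append({"module": int(me_name[2:]), "trait": trait, "r": r, "p": p})
    table = pd.DataFrame(rows, columns=["module", "trait", "r", "p"])
    table.attrs["excluded_traits"] = excluded
    return table


def match_labels(
    reference: pd.Series,
    test: pd.Series,
    p_threshold: float = 0.05,
) -> pd.Series:
    """Relabel ``test`` modules to match ``reference`` modules by overlap.

    For every (test module, reference module) pair the hypergeometric
    overlap p is computed on the shared gene universe; pairs are matched
    greedily in ascending p (ties: larger overlap, then smaller reference
    label), each side used at most once, only while p < ``p_threshold``.
    Unmatched test modules get fresh labels after the reference maximum,
    in decreasing size order.  Module 0 stays 0.
    """
    universe = reference.index.intersection(test.index)
    if len(universe) == 0:
        raise ValueError("reference and test assignments share no genes")
    ref = reference.loc[universe]
    tst = test.loc[universe]
    N = len(universe)
    ref_modules = sorted(int(m) for m in ref.unique() if int(m) != 0)
    test_modules = sorted(int(m) for m in tst.unique() if int(m) != 0)
    pairs = []
    for tm in test_modules:
        t_genes = set(tst.index[tst == tm])
        for rm in ref_modules:
            r_genes = set(ref.index[ref == rm])
            x = len(t_genes & r_genes)
            p = hypergeom_tail(x, N, len(r_genes), len(t_genes))
            pairs.append((p, -x, rm, tm))
    mapping: dict[int, int] = {}
    used_ref: set[int] = set()
    for p, neg_x, rm, tm in sorted(pairs):
        if p >= p_threshold:
            break
        if tm in mapping or rm in used_ref:
            continue
        mapping[tm] = rm
        used_ref.add(rm)
    next_label = max(ref_modules, default=0) + 1
    sizes = tst.value_counts()
    for tm in sorted(
        (m for m in test_modules if m not in mapping),
        key=lambda m: (-sizes.get(m, 0), m),
    ):
        mapping[tm] = next_label
        next_label += 1
    mapping[0] = 0
    return test.map(mapping).astype(int).rename("module")


def merge_similar_modules(
    matrix: pd.DataFrame,
    assignment: pd.Series,
    cor_threshold: float = 0.8,
) -> pd.Series:
    """Merge modules whose eigengenes correlate above ``cor_threshold``.

    Single-linkage grouping on the eigengene correlation graph; merged
    groups keep the label of their largest member and the result is
    re-ordered by size.  Off by default in the pipeline.
    """
    mes = module_eigengenes(matrix, assignment)
    labels = mes.modules
    if len(labels) < 2:
        return assignment
    cor = np.corrcoef(mes.eigengenes.to_numpy().T)
    parent = {m: m for m in labels}

    def find(m: int) -> int:
        while parent[m] != m:
            parent[m] = parent[parent[m]]
            m = parent[m]
        return m

    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            if cor[i, j] >= cor_threshold:
                parent[find(labels[j])] = find(a)
    sizes = assignment.value_counts()
    group_leader: dict[int, int] = {}
    for m in labels:
        root = find(m)
        cur = group_leader.get(root)
        if cur is None or sizes.get(m, 0) > sizes.get(cur, 0):
            group_leader[root] = m
    remap = {m: group_leader[find(m)] for m in labels}
    remap[0] = 0
    from .treecut import relabel_by_size

    return relabel_by_size(assignment.map(remap).astype(int))
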