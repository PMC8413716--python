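"""Hierarchical clustering of TOM dissimilarity and dynamic branch cutting.

Modules are branches of the average-linkage dendrogram of 1 - TOM.  A
static cut at ``cut_height`` (0.99 by default) defines candidate branches;
each branch is then examined recursively and split where both sub-branches
look like distinct modules.  Distinctness is judged by two criteria derived
from the ``deep_split`` sensitivity level:

* core scatter — the mean of a branch's lowest merge heights (its "core")
  must stay below a ceiling; tightly coexpressed modules merge low, loose
  background clumps merge high;
* gap — the joining height minus the branch's core top must exceed a
  minimum, i.e. the branch must sit well below the merge that attaches it.

Both thresholds are expressed relative to the tree: scaled between the 5th
percentile of merge heights and the cut height.  ``deep_split`` in 0..4
maps linearly to a core-scatter ceiling of 0.64..0.98 with
``min_gap = 0.75 * (1 - ceiling)``; level 1 (the default, medium
sensitivity) gives ceiling 0.725 and gap 0.206.

Branches that never pass the criteria, and clusters smaller than
``min_module_size``, are dissolved into module 0 (the grey background).
Surviving clusters are labelled 1..M by decreasing size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

__all__ = [
    "TreeCutConfig",
    "cluster_tree",
    "cut_tree_dynamic",
    "relabel_by_size",
    "module_color",
    "MODULE_COLORS",
]

#: conventional size-ordered module palette; index = module label
MODULE_COLORS = (
    "grey",
    "turquoise",
    "blue",
    "brown",
    "yellow",
    "green",
    "red",
    "black",
    "pink",
    "magenta",
    "purple",
    "greenyellow",
    "tan",
    "salmon",
    "cyan",
    "midnightblue",
    "lightcyan",
)


def module_color(label: int) -> str:
    """Conventional colour name for a size-ordered module label (0 = grey)."""
    if label < len(MODULE_COLORS):
        return MODULE_COLORS[label]
    return f"module{label}"


@dataclass(frozen=True)
class TreeCutConfig:
    """Dynamic tree cut parameters.

    ``pam_stage`` optionally reassigns unlabelled genes to the nearest
    module by mean dissimilarity (off by default); ``merge_similar`` is a
    flag consumed by the pipeline to merge modules with highly correlated
    eigengenes (also off by default).
    """

    deep_split: int = 1
    cut_height: float = 0.99
    min_module_size: int = 27
    merge_similar: bool = False
    pam_stage: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.deep_split <= 4):
            raise ValueError("deep_split must be in 0..4")
        if not (0 < self.cut_height <= 1):
            raise ValueError("cut_height must be in (0, 1]")
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be >= 1")

    @property
    def max_core_scatter(self) -> float:
        return 0.64 + self.deep_split * (0.98 - 0.64) / 4.0

    @property
    def min_gap(self) -> float:
        return 0.75 * (1.0 - self.max_core_scatter)


def cluster_tree(disstom: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Average-linkage hierarchical clustering of a dissimilarity matrix.

    Returns a scipy linkage matrix.  The input must be symmetric with a
    zero diagonal and values in [0, 1].
    """
    d = np.asarray(disstom, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    if d.min() < -1e-10 or d.max() > 1 + 1e-10:
        raise ValueError("dissimilarities must lie in [0, 1]")
    condensed = squareform(np.clip((d + d.T) / 2.0, 0.0, None), checks=False)
    return linkage(condensed, method="average")


class _Tree:
    """Per-node statistics of a linkage tree used by the dynamic cut.

    For every node we keep the subtree's leaf count and its "core": the
    sorted lowest ``core_size`` merge heights inside the subtree.  The core
    mean is the scatter; the core maximum is the height the gap criterion
    measures from.
    """

    def __init__(self, Z: np.ndarray, core_size: int):
        n = Z.shape[0] + 1
        self.n = n
        self.Z = Z
        self.left = Z[:, 0].astype(int)
        self.right = Z[:, 1].astype(int)
        self.height = Z[:, 2].astype(float)
        self.size = np.empty(n - 1, dtype=int)
        cores: list[np.ndarray] = []
        empty = np.empty(0)
        for i in range(n - 1):
            l, r = self.left[i], self.right[i]
            cl = empty if l < n else cores[l - n]
            cr = empty if r < n else cores[r - n]
            sl = 1 if l < n else self.size[l - n]
            sr = 1 if r < n else self.size[r - n]
            self.size[i] = sl + sr
            merged = np.concatenate([cl, cr, [self.height[i]]])
            merged.sort()
            cores.append(merged[:core_size])
        self.cores = cores

    def node_size(self, node: int) -> int:
        return 1 if node < self.n else int(self.size[node - self.n])

    def node_height(self, node: int) -> float:
        return 0.0 if node < self.n else float(self.height[node - self.n])

    def scatter(self, node: int) -> float:
        if node < self.n:
            return 0.0
        return float(self.cores[node - self.n].mean())

    def core_top(self, node: int) -> float:
        if node < self.n:
            return 0.0
        return float(self.cores[node - self.n][-1])

    def leaves(self, node: int) -> list[int]:
        out: list[int] = []
        stack = [node]
        while stack:
            v = stack.pop()
            if v < self.n:
                out.append(v)
            else:
                stack.append(int(self.left[v - self.n]))
                stack.append(int(self.right[v - self.n]))
        return out

    def branch_roots(self, cut_height: float) -> list[int]:
        """Maximal nodes whose merge height is <= cut_height."""
        n = self.n
        parent = np.full(2 * n - 1, -1, dtype=int)
        for i in range(n - 1):
            parent[self.left[i]] = n + i
            parent[self.right[i]] = n + i
        roots = []
        for v in range(2 * n - 1):
            h = self.node_height(v)
            if h > cut_height:
                continue
            p = parent[v]
            if p == -1 or self.node_height(p) > cut_height:
                roots.append(v)
        return roots


def _absorb_onto_cores(tree: "_Tree", labels: np.ndarray, cut_height: float) -> np.ndarray:
    """Attach unlabelled leaves to the unique core on their branch.

    A cluster's core is found by the split recursion; genes that merge onto
    that branch above the core top but below the static cut height belong
    to the same branch and are absorbed into the core.  A leaf whose
    smallest labelled-containing subtree spans several cores (or that only
    joins the tree above the cut height) stays background.
    """
    n = tree.n
    # unique core label per subtree: 0 = none, -1 = several
    core_of = np.zeros(2 * n - 1, dtype=int)
    core_of[:n] = labels
    for i in range(n - 1):
        l, r = int(tree.left[i]), int(tree.right[i])
        cl, cr = core_of[l], core_of[r]
        if cl == cr:
            core_of[n + i] = cl
        elif cl == 0 or cr == 0:
            core_of[n + i] = cl or cr
        else:
            core_of[n + i] = -1
    parent = np.full(2 * n - 1, -1, dtype=int)
    for i in range(n - 1):
        parent[int(tree.left[i])] = n + i
        parent[int(tree.right[i])] = n + i
    out = labels.copy()
    for leaf in np.flatnonzero(labels == 0):
        v = int(parent[leaf])
        while v != -1 and tree.node_height(v) <= cut_height and core_of[v] == 0:
            v = int(parent[v])
        if v != -1 and tree.node_height(v) <= cut_height and core_of[v] > 0:
            out[leaf] = core_of[v]
    return out


def cut_tree_dynamic(
    Z: np.ndarray,
    disstom: np.ndarray | pd.DataFrame,
    cfg: TreeCutConfig,
    gene_ids: Sequence[str] | None = None,
) -> pd.Series:
    """Cut a dendrogram into modules; module 0 collects background genes.

    ``disstom`` is the dissimilarity the tree was built from (used by the
    optional PAM stage).  Returns gene -> module label, labels 1..M ordered
    by decreasing module size.
    """
    if not (0 < cfg.cut_height <= 1):
        raise ValueError("cut_height must be in (0, 1]")
    d = np.asarray(disstom, dtype=float)
    n = Z.shape[0] + 1
    if d.shape != (n, n):
        raise ValueError("dissimilarity matrix does not match the dendrogram")
    if gene_ids is None:
        gene_ids = (
            list(disstom.index) if isinstance(disstom, pd.DataFrame) else [str(i) for i in range(n)]
        )

    tree = _Tree(Z, core_size=max(cfg.min_module_size - 1, 1))
    heights = tree.height
    base = float(np.quantile(heights, 0.05)) if heights.size else 0.0
    base = min(base, cfg.cut_height)
    span = cfg.cut_height - base
    max_abs_scatter = base + cfg.max_core_scatter * span
    min_abs_gap = cfg.min_gap * span

    def viable(node: int, join_height: float) -> bool:
        return (
            tree.node_size(node) >= cfg.min_module_size
            and tree.scatter(node) <= max_abs_scatter
            and join_height - tree.core_top(node) >= min_abs_gap
        )

    clusters: list[list[int]] = []
    for root in tree.branch_roots(cfg.cut_height):
        stack = [root]
        while stack:
            node = stack.pop()
            if node < tree.n:
                continue  # lone leaf -> background
            i = node - tree.n
            l, r = int(tree.left[i]), int(tree.right[i])
            h = float(tree.height[i])
            vl, vr = viable(l, h), viable(r, h)
            if vl and vr:
                stack += [l, r]
            elif vl and tree.node_size(r) >= cfg.min_module_size:
                stack += [l, r]
            elif vr and tree.node_size(l) >= cfg.min_module_size:
                stack += [l, r]
            elif vl:
                stack.append(l)  # small side twig -> background
            elif vr:
                stack.append(r)
            else:
                if (
                    tree.node_size(node) >= cfg.min_module_size
                    and tree.scatter(node) <= max_abs_scatter
                ):
                    clusters.append(tree.leaves(node))
                # else: incoherent branch -> background

    labels = np.zeros(n, dtype=int)
    for m, members in enumerate(clusters, start=1):
        labels[members] = m

    if clusters:
        labels = _absorb_onto_cores(tree, labels, cfg.cut_height)

    if cfg.pam_stage and clusters:
        unassigned = np.flatnonzero(labels == 0)
        for g in unassigned:
            mean_d = [d[g, members].mean() for members in clusters]
            best = int(np.argmin(mean_d))
            if mean_d[best] <= cfg.cut_height:
                labels[g] = best + 1

    assignment = pd.Series(labels, index=pd.Index(gene_ids, name="gene"), name="module")
    return relabel_by_size(assignment)


def relabel_by_size(assignment: pd.Series) -> pd.Series:
    """Relabel modules 1..M by decreasing size; module 0 is untouched.

    Ties are broken by the lexicographically smallest member gene id.
    """
    out = assignment.copy()
    sizes = assignment[assignment != 0].value_counts()
    keyed = sorted(
        sizes.index,
        key=lambda m: (-sizes[m], min(str(g) for g in assignment.index[assignment == m])),
    )
    mapping = {old: new for new, old in enumerate(keyed, start=1)}
    mapping[0] = 0
    return out.map(mapping).astype(int).rename("module")
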