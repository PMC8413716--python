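"""Weighted coexpression network construction.

Pearson correlation -> soft-thresholded adjacency -> scale-free topology
fit -> soft-power selection -> topological overlap matrix (TOM).

The soft threshold beta raises correlation magnitudes to a power so that
the weighted network approximates scale-free topology.  The fit index R^2
is the squared correlation of log10 p(k) against log10 k over a binned
connectivity distribution; the selection rule takes the smallest candidate
power reaching the target R^2 (0.85 by default), falling back to the
best-fitting power with a warning when none qualifies.

Topological overlap between genes i and j combines their direct adjacency
with the adjacency they share through common neighbours:

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),   i != j

with L_ij = sum_{u != i,j} a_iu a_uj and k_i the connectivity of gene i.
1 - TOM is the clustering dissimilarity used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NetworkConfig",
    "ScaleFreeFit",
    "PowerSelection",
    "Network",
    "correlation_matrix",
    "adjacency",
    "connectivity",
    "scale_free_fit",
    "soft_threshold_scan",
    "select_power",
    "pick_power",
    "tom",
    "build_network",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Soft-threshold search space and scale-free fit settings."""

    candidate_powers: tuple[int, ...] = tuple(range(1, 21))
    r2_target: float = 0.85
    network_sign: str = "unsigned"
    n_bins: int = 10

    def __post_init__(self) -> None:
        powers = tuple(int(p) for p in self.candidate_powers)
        object.__setattr__(self, "candidate_powers", powers)
        if not powers:
            raise ValueError("candidate_powers is empty")
        if any(p < 1 for p in powers) or any(a >= b for a, b in zip(powers, powers[1:])):
            raise ValueError("candidate_powers must be strictly increasing positive integers")
        if not (0 < self.r2_target <= 1):
            raise ValueError("r2_target must be in (0, 1]")
        if self.network_sign not in ("unsigned", "signed"):
            raise ValueError(f"unknown network sign {self.network_sign!r}")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


@dataclass(frozen=True)
class ScaleFreeFit:
    """Scale-free topology diagnostics at one soft power."""

    power: int
    r2: float
    slope: float
    mean_connectivity: float

    @property
    def r2_signed(self) -> float:
        """Signed variant: R^2 negated when the log-log slope is positive."""
        return -np.sign(self.slope) * self.r2 if self.slope != 0 else self.r2


@dataclass(frozen=True)
class PowerSelection:
    """Outcome of the soft-power search.

    ``warning`` is set when no candidate reached the R^2 target and the
    best-fitting power was returned instead.
    """

    power: int
    fit: ScaleFreeFit
    scan: tuple[ScaleFreeFit, ...]
    warning: bool

    def __int__(self) -> int:
        return self.power


@dataclass
class Network:
    """Adjacency and TOM for one gene set at one soft power."""

    gene_ids: list[str]
    adjacency: np.ndarray
    tom: np.ndarray
    power: int
    fit: ScaleFreeFit


def correlation_matrix(matrix: pd.DataFrame) -> np.ndarray:
    """Pearson correlation of genes (rows) across samples (columns)."""
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate")
    values = np.asarray(matrix, dtype=float)
    sd = values.std(axis=1)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        names = [str(matrix.index[i]) for i in constant[:5]]
        raise ValueError(f"constant gene(s) cannot be correlated: {names}")
    cor = np.corrcoef(values)
    np.fill_diagonal(cor, 1.0)
    return np.clip(cor, -1.0, 1.0)


def adjacency(cor: np.ndarray, power: int, sign: str = "unsigned") -> np.ndarray:
    """Soft-threshold a correlation matrix into a weighted adjacency.

    unsigned: a_ij = |cor_ij|^power;  signed: a_ij = ((1 + cor_ij)/2)^power.
    The diagonal is forced to 1.
    """
    if power < 1:
        raise ValueError("power must be >= 1")
    if sign == "unsigned":
        adj = np.abs(cor) ** power
    elif sign == "signed":
        adj = ((1.0 + cor) / 2.0) ** power
    else:
        raise ValueError(f"unknown network sign {sign!r}")
    np.fill_diagonal(adj, 1.0)
    return adj


def connectivity(adj: np.ndarray) -> np.ndarray:
    """Per-gene connectivity k_i = sum of off-diagonal adjacencies."""
    return adj.sum(axis=1) - np.diag(adj)


def scale_free_fit(k: np.ndarray, n_bins: int = 10, power: int = 0) -> ScaleFreeFit:
    """Fit log10 p(k) against log10 k over an equal-width binning of k.

    Empty bins are dropped; R^2 is the squared correlation of the simple
    linear regression (reported unsigned — the slope's sign is carried
    separately).
    """
    k = np.asarray(k, dtype=float)
    if k.size < 2 or np.ptp(k) == 0:
        raise ValueError("scale-free fit undefined: all connectivities identical")
    counts, edges = np.histogram(k, bins=n_bins)
    sums, _ = np.histogram(k, bins=edges, weights=k)
    nonempty = counts > 0
    mean_k = sums[nonempty] / counts[nonempty]
    p_k = counts[nonempty] / k.size
    ok = mean_k > 0
    if ok.sum() < 2:
        raise ValueError("scale-free fit undefined: fewer than 2 usable bins")
    x = np.log10(mean_k[ok])
    y = np.log10(p_k[ok])
    res = stats.linregress(x, y)
    return ScaleFreeFit(
        power=power,
        r2=float(res.rvalue**2),
        slope=float(res.slope),
        mean_connectivity=float(k.mean()),
    )


def soft_threshold_scan(matrix: pd.DataFrame, cfg: NetworkConfig) -> tuple[ScaleFreeFit, ...]:
    """Scale-free fit diagnostics for every candidate power."""
    cor = correlation_matrix(matrix)
    fits = []
    for p in cfg.candidate_powers:
        adj = adjacency(cor, p, cfg.network_sign)
        fits.append(scale_free_fit(connectivity(adj), cfg.n_bins, power=p))
    return tuple(fits)


def select_power(fits: Sequence[ScaleFreeFit] | Mapping[int, float], r2_target: float) -> tuple[int, bool]:
    """Smallest power with R^2 >= target; else the best R^2 with a warning.

    Accepts either ScaleFreeFit records or a {power: r2} mapping (ordered by
    power either way).  Returns (power, warning_flag).
    """
    if isinstance(fits, Mapping):
        items = sorted((int(p), float(r2)) for p, r2 in fits.items())
    else:
        items = [(f.power, f.r2) for f in fits]
    for power, r2 in items:
        if r2 >= r2_target:
            return power, False
    best = max(items, key=lambda pr: (pr[1], -pr[0]))
    return best[0], True


def pick_power(matrix: pd.DataFrame, cfg: NetworkConfig) -> PowerSelection:
    """Select the soft-threshold power for one expression matrix."""
    scan = soft_threshold_scan(matrix, cfg)
    power, warning = select_power(scan, cfg.r2_target)
    fit = next(f for f in scan if f.power == power)
    return PowerSelection(power=power, fit=fit, scan=scan, warning=warning)


def tom(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of an adjacency matrix (unit diagonal)."""
    a = np.asarray(adj, dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a  # L_ij = sum_u a_iu a_uj (u != i,j since diag is 0)
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (shared + a) / denom
    t = np.nan_to_num(t, nan=0.0)
    np.fill_diagonal(t, 1.0)
    return np.clip(t, 0.0, 1.0)


def build_network(matrix: pd.DataFrame, cfg: NetworkConfig) -> Network:
    """Full network build: correlation, power selection, adjacency, TOM."""
    selection = pick_power(matrix, cfg)
    cor = correlation_matrix(matrix)
    adj = adjacency(cor, selection.power, cfg.network_sign)
    return Network(
        gene_ids=[str(g) for g in matrix.index],
        adjacency=adj,
        tom=tom(adj),
        power=selection.power,
        fit=selection.fit,
    )
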