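"""OTU co-occurrence network: prevalence/abundance filter, pairwise
correlations with P-values, thresholding, GEXF-ready graph.

Correlations are computed on absolute abundances (counts) of the OTUs that
survive the filter (overall relative abundance >= ``min_rel_abundance`` and
presence in >= ``min_samples`` samples).  Spearman is Pearson on midranks;
two-sided P-values come from the t statistic r * sqrt((n-2)/(1-r^2)) on
n - 2 degrees of freedom.  Edges keep pairs with |r| >= ``r_min`` and
p <= ``p_max``; no multiple-testing correction is applied by default (a
Benjamini-Hochberg option exists but is off), and negative correlations are
kept on magnitude unless ``positive_only`` is set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats as _sstats

from .otu_inference import OtuTable

__all__ = [
    "NetworkParams",
    "filter_network_otus",
    "correlate_pairs",
    "build_network",
]


@dataclass(frozen=True)
class NetworkParams:
    min_rel_abundance: float = 0.001
    min_samples: int = 2
    method: str = "spearman"
    r_min: float = 0.6
    p_max: float = 0.01
    positive_only: bool = False
    bh_correction: bool = False
    include_isolated: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_rel_abundance < 1.0):
            raise ValueError("min_rel_abundance must be in [0, 1)")
        if not (0.0 < self.r_min <= 1.0):
            raise ValueError("r_min must be in (0, 1]")
        if not (0.0 < self.p_max < 1.0):
            raise ValueError("p_max must be in (0, 1)")
        if self.method not in ("spearman", "pearson"):
            raise ValueError("method must be 'spearman' or 'pearson'")


def filter_network_otus(table: OtuTable, params: NetworkParams = NetworkParams()) -> OtuTable:
    """Drop infrequent OTUs: overall relative abundance below the threshold
    or present in fewer than ``min_samples`` samples."""
    total = table.counts.sum()
    if total == 0:
        raise ValueError("empty OTU table")
    overall = table.counts.sum(axis=0) / total
    prevalence = (table.counts > 0).sum(axis=0)
    keep = (overall >= params.min_rel_abundance) & (prevalence >= params.min_samples)
    return OtuTable(
        samples=table.samples,
        otus=tuple(o for o, k in zip(table.otus, keep) if k),
        counts=table.counts[:, keep],
    )


def _midranks(x: np.ndarray) -> np.ndarray:
    return _sstats.rankdata(x, method="average")


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n = x.size
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    r = float((xc * yc).sum() / denom)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * _sstats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def correlate_pairs(
    table: OtuTable, method: str = "spearman"
) -> list[tuple[int, int, float, float]]:
    """Correlation and two-sided P-value for every unordered OTU pair.

    Pairs involving a constant abundance vector are skipped with a warning
    (the coefficient is undefined).
    """
    if len(table.samples) < 4:
        raise ValueError("need at least 4 samples for correlation P-values")
    x = table.counts.astype(float)
    if method == "spearman":
        x = np.apply_along_axis(_midranks, 0, x)
    elif method != "pearson":
        raise ValueError("method must be 'spearman' or 'pearson'")
    constant = x.std(axis=0) == 0
    out: list[tuple[int, int, float, float]] = []
    n_otus = x.shape[1]
    for i in range(n_otus):
        for j in range(i + 1, n_otus):
            if constant[i] or constant[j]:
                warnings.warn(
                    f"constant abundance vector for pair ({i}, {j}); skipped"
                )
                continue
            r, p = _pearson_with_p(x[:, i], x[:, j])
            out.append((i, j, r, p))
    return out


def build_network(
    table: OtuTable,
    pairs: Sequence[tuple[int, int, float, float]],
    taxonomy: Mapping[str, str] | None = None,
    params: NetworkParams = NetworkParams(),
) -> nx.Graph:
    """Threshold correlation pairs into an undirected co-occurrence graph.

    Nodes carry taxonomy and total abundance; edges carry r (as weight), the
    P-value and the correlation method.  Isolated OTUs are excluded unless
    ``params.include_isolated``.
    """
    pvals = np.array([p for _, _, _, p in pairs])
    if params.bh_correction and pvals.size:
        order = np.argsort(pvals)
        m = pvals.size
        adj = np.empty(m)
        running = 1.0
        for rank_pos in range(m - 1, -1, -1):
            idx = order[rank_pos]
            running = min(running, pvals[idx] * m / (rank_pos + 1))
            adj[idx] = running
        pvals = adj

    g = nx.Graph()
    otu_ids = table.otu_ids
    totals = table.counts.sum(axis=0)

    def _add_node(j: int) -> None:
        oid = otu_ids[j]
        if not g.has_node(oid):
            g.add_node(
                oid,
                taxonomy=(taxonomy or {}).get(oid, "unclassified"),
                abundance=int(totals[j]),
            )

    if params.include_isolated:
        for j in range(len(otu_ids)):
            _add_node(j)
    for (i, j, r, _), p in zip(pairs, pvals):
        if params.positive_only:
            if r < params.r_min:
                continue
        elif abs(r) < params.r_min:
            continue
        if p > params.p_max:
            continue
        _add_node(i)
        _add_node(j)
        g.add_edge(
            otu_ids[i], otu_ids[j], weight=float(r), p_value=float(p),
            method=params.method,
        )
    return g
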