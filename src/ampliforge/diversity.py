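"""Alpha/beta diversity, rarefaction, UPGMA sample trees, ordination, and
permutation tests for group structure.

Alpha-diversity formulas (Mothur-compatible definitions):

* sobs       — number of OTUs with count > 0
* chao       — Chao1: Sobs + n1(n1-1) / (2(n2+1))
* ace        — abundance-based coverage estimator, rare cutoff 10
* jackknife  — first-order jackknife: Sobs + n1(N-1)/N
* shannon    — -sum p ln p (natural log)
* npshannon  — Chao-Shen coverage-adjusted Shannon
* simpson    — sum n_i(n_i - 1) / (N(N - 1))

Beta dissimilarities: Jclass (1 - Jaccard on shared membership), Jest (same
with Chao1-estimated richnesses), ThetaYC (Yue & Clayton theta on relative
abundances), Bray-Curtis on counts.

UPGMA delegates to :func:`scipy.cluster.hierarchy.linkage` with average
linkage (exactly UPGMA on a condensed matrix); node heights are half the
merge distance, so the tree is ultrametric.  PCoA delegates to scikit-bio's
classical scaling (Gower double-centering of -d^2/2); NMDS wraps
scikit-learn's nonmetric MDS with Kruskal stress-1 reported.

AMOVA tests for location differences among groups with the pseudo-F
statistic computed from squared distances (among = total - within;
within = sum over groups of pairwise d^2 / group size); HOMOVA tests
dispersion homogeneity with a Bartlett-style statistic on within-group mean
squared distances.  Both p-values come from label permutation, reported as
(1 + more-extreme) / (1 + n_perm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from skbio import TreeNode

from .otu_inference import OtuTable

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "PermutationTestResult",
    "ALPHA_INDICES",
    "BETA_MEASURES",
    "alpha_diversity",
    "rarefaction_curve",
    "rank_abundance",
    "beta_distance",
    "upgma_tree",
    "pcoa",
    "nmds",
    "amova",
    "homova",
]

ALPHA_INDICES = ("sobs", "chao", "ace", "jackknife", "shannon", "npshannon", "simpson")
BETA_MEASURES = ("jclass", "jest", "thetayc", "braycurtis")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric sample-pair dissimilarities with ordered labels."""

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        object.__setattr__(self, "d", d)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.d[iu]


@dataclass(frozen=True)
class OrdinationResult:
    """Sample coordinates with axis importance (eigenvalues or final stress)."""

    labels: tuple[str, ...]
    coordinates: np.ndarray  # (n_samples, n_axes)
    eigenvalues: np.ndarray | None = None  # PCoA
    stress: float | None = None  # NMDS (Kruskal stress-1)
    seed: int | None = None


@dataclass(frozen=True)
class PermutationTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: int | None = None


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def _counts_array(counts: Sequence[int]) -> np.ndarray:
    c = np.asarray(counts)
    if c.size == 0 or (c < 0).any() or not c.sum():
        raise ValueError("counts must be non-negative integers, not all zero")
    return c[c > 0].astype(np.int64)


def alpha_diversity(counts: Sequence[int], index_name: str) -> float:
    """One sample's alpha-diversity index; formulas in the module docstring."""
    c = _counts_array(counts)
    n = int(c.sum())
    sobs = int(c.size)
    n1 = int(np.count_nonzero(c == 1))
    n2 = int(np.count_nonzero(c == 2))

    if index_name == "sobs":
        return float(sobs)
    if index_name == "chao":
        return sobs + n1 * (n1 - 1) / (2.0 * (n2 + 1))
    if index_name == "jackknife":
        return sobs + n1 * (n - 1) / n
    if index_name == "shannon":
        p = c / n
        return float(-(p * np.log(p)).sum())
    if index_name == "npshannon":
        # Chao-Shen: coverage-adjusted abundances with Horvitz-Thompson correction
        cov = 1.0 - n1 / n
        if cov == 0.0:
            cov = 1.0 / n  # all singletons; keep the estimator finite
        p = cov * c / n
        return float(-(p * np.log(p) / (1.0 - (1.0 - p) ** n)).sum())
    if index_name == "simpson":
        if n < 2:
            return 0.0
        return float((c * (c - 1)).sum() / (n * (n - 1)))
    if index_name == "ace":
        return _ace(c)
    raise ValueError(f"unknown alpha index {index_name!r}")


def _ace(c: np.ndarray, rare_cutoff: int = 10) -> float:
    rare = c[c <= rare_cutoff]
    abund = c[c > rare_cutoff]
    s_abund = abund.size
    s_rare = rare.size
    n_rare = int(rare.sum())
    n1 = int(np.count_nonzero(c == 1))
    if n_rare == 0 or n_rare == n1:
        # no information about undetected OTUs; fall back to Chao1
        n2 = int(np.count_nonzero(c == 2))
        return c.size + n1 * (n1 - 1) / (2.0 * (n2 + 1))
    c_ace = 1.0 - n1 / n_rare
    i = np.arange(1, rare_cutoff + 1)
    f = np.array([np.count_nonzero(rare == k) for k in i])
    gamma = max(
        (s_rare / c_ace) * (i * (i - 1) * f).sum() / (n_rare * (n_rare - 1)) - 1.0,
        0.0,
    )
    return s_abund + s_rare / c_ace + (n1 / c_ace) * gamma


def rarefaction_curve(
    counts: Sequence[int],
    step: int = 100,
    n_resamples: int = 100,
    seed: int | None = None,
) -> list[tuple[int, float]]:
    """Mean observed OTU count at increasing subsampling depths.

    Depths run ``step, 2*step, ...`` plus the full sample total; at each depth
    the mean sobs over ``n_resamples`` draws without replacement is reported
    (the endpoint needs no resampling).
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    c = np.asarray(counts, dtype=np.int64)
    total = int(c.sum())
    rng = np.random.default_rng(seed)
    depths = list(range(step, total, step)) + [total]
    curve: list[tuple[int, float]] = []
    for depth in depths:
        if depth == total:
            curve.append((depth, float(np.count_nonzero(c))))
            continue
        sub = rng.multivariate_hypergeometric(c, depth, size=n_resamples)
        curve.append((depth, float(np.count_nonzero(sub, axis=1).mean())))
    return curve


def rank_abundance(counts: Sequence[int]) -> list[tuple[int, float]]:
    """(rank, relative abundance) pairs, descending; zero-count OTUs excluded.

    Ties keep the stable order of the input OTU ids.
    """
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("counts must not be all zero")
    order = np.argsort(-c, kind="stable")
    out = []
    rank = 0
    for idx in order:
        if c[idx] <= 0:
            break
        rank += 1
        out.append((rank, float(c[idx] / total)))
    return out


# ---------------------------------------------------------------------------
# Beta diversity
# ---------------------------------------------------------------------------

def _pair_dissimilarity(a: np.ndarray, b: np.ndarray, measure: str) -> float:
    if measure == "braycurtis":
        denom = (a + b).sum()
        return float(np.abs(a - b).sum() / denom) if denom else 0.0
    if measure == "jclass":
        sa, sb = a > 0, b > 0
        shared = int((sa & sb).sum())
        union = int(sa.sum() + sb.sum() - shared)
        return 1.0 - shared / union if union else 0.0
    if measure == "jest":
        shared_mask = (a > 0) & (b > 0)
        s_a = alpha_diversity(a, "chao") if a.sum() else 0.0
        s_b = alpha_diversity(b, "chao") if b.sum() else 0.0
        shared_counts_a = a[shared_mask]
        shared_counts_b = b[shared_mask]
        if shared_counts_a.size == 0:
            return 1.0
        s_ab = alpha_diversity(np.minimum(shared_counts_a, shared_counts_b), "chao")
        denom = s_a + s_b - s_ab
        return float(max(0.0, min(1.0, 1.0 - s_ab / denom))) if denom else 0.0
    if measure == "thetayc":
        pa = a / a.sum() if a.sum() else a.astype(float)
        pb = b / b.sum() if b.sum() else b.astype(float)
        cross = float((pa * pb).sum())
        denom = float((pa**2).sum() + (pb**2).sum() - cross)
        return 1.0 - cross / denom if denom else 0.0
    raise ValueError(f"unknown beta measure {measure!r}")


def beta_distance(table: OtuTable, measure: str) -> DistanceMatrix:
    """All-pairs sample dissimilarity matrix for one measure."""
    if measure not in BETA_MEASURES:
        raise ValueError(f"unknown beta measure {measure!r}")
    if len(table.samples) < 2:
        raise ValueError("need at least 2 samples")
    counts = table.counts.astype(np.int64)
    n = len(table.samples)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _pair_dissimilarity(counts[i], counts[j], measure)
    return DistanceMatrix(labels=table.samples, d=d)


# ---------------------------------------------------------------------------
# Trees and ordination
# ---------------------------------------------------------------------------

def upgma_tree(dm: DistanceMatrix) -> TreeNode:
    """Average-linkage (UPGMA) ultrametric tree over the samples.

    Leaf-to-root height equals half the final merge distance; internal branch
    lengths are derived from successive merge heights.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need at least 2 samples")
    Z = linkage(dm.condensed(), method="average")
    nodes: dict[int, tuple[TreeNode, float]] = {
        i: (TreeNode(name=dm.labels[i]), 0.0) for i in range(n)
    }
    for k, (i, j, dist, _) in enumerate(Z):
        hi = dist / 2.0
        left, h_left = nodes.pop(int(i))
        right, h_right = nodes.pop(int(j))
        left.length = hi - h_left
        right.length = hi - h_right
        parent = TreeNode(children=[left, right])
        nodes[n + k] = (parent, hi)
    root, _ = nodes.popitem()[1]
    return root


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Principal coordinate analysis (classical scaling) of a distance matrix.

    Coordinates are scaled by the square roots of the positive eigenvalues;
    axes are ordered by descending eigenvalue.  Negative-eigenvalue axes are
    dropped.
    """
    if len(dm.labels) < 3:
        raise ValueError("need at least 3 samples")
    from skbio.stats.ordination import pcoa as _skbio_pcoa

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns on negative eigenvalues
        res = _skbio_pcoa(dm.d, method="eigh")
    eig = res.eigvals.to_numpy()
    keep = eig > 1e-12
    return OrdinationResult(
        labels=dm.labels,
        coordinates=res.samples.to_numpy()[:, keep],
        eigenvalues=eig[keep],
    )


def kruskal_stress(d_obs: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against observed dissimilarities,
    using the monotone (isotonic) regression of configuration distances on
    the observed ranks."""
    from scipy.spatial.distance import pdist
    from sklearn.isotonic import IsotonicRegression

    iu = np.triu_indices(d_obs.shape[0], k=1)
    obs = d_obs[iu]
    fit = pdist(coords)
    disparities = IsotonicRegression().fit_transform(obs, fit)
    denom = float((fit**2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((fit - disparities) ** 2).sum() / denom))


def nmds(
    dm: DistanceMatrix,
    n_axes: int = 2,
    n_starts: int = 20,
    seed: int | None = None,
    max_iter: int = 300,
) -> OrdinationResult:
    """Non-metric multidimensional scaling; best configuration over
    ``n_starts`` random starts, Kruskal stress-1 reported."""
    if len(dm.labels) < 4:
        raise ValueError("need at least 4 samples")
    if not dm.d.any():
        # all samples identical under this measure; embedding is a point
        return OrdinationResult(
            labels=dm.labels,
            coordinates=np.zeros((len(dm.labels), n_axes)),
            stress=0.0,
            seed=seed,
        )
    from sklearn.manifold import MDS

    import inspect

    kwargs: dict = dict(
        n_components=n_axes,
        n_init=n_starts,
        max_iter=max_iter,
        random_state=int(np.random.default_rng(seed).integers(2**31)),
        normalized_stress=False,
    )
    if "metric_mds" in inspect.signature(MDS.__init__).parameters:
        kwargs.update(metric_mds=False, metric="precomputed", init="random")
    else:  # older scikit-learn API
        kwargs.update(metric=False, dissimilarity="precomputed")
    mds = MDS(**kwargs)
    coords = mds.fit_transform(dm.d)
    return OrdinationResult(
        labels=dm.labels,
        coordinates=coords,
        stress=kruskal_stress(dm.d, coords),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# AMOVA / HOMOVA
# ---------------------------------------------------------------------------

def _group_indices(
    labels: Sequence[str], groups: Mapping[str, str]
) -> list[np.ndarray]:
    by_group: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        if lab not in groups:
            raise ValueError(f"sample {lab!r} has no group assignment")
        by_group.setdefault(groups[lab], []).append(i)
    idx = [np.asarray(v) for v in by_group.values()]
    if len(idx) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(v) < 2 for v in idx):
        raise ValueError("every group needs at least 2 samples")
    return idx


def _amova_F(d2: np.ndarray, group_idx: list[np.ndarray]) -> float:
    n = d2.shape[0]
    k = len(group_idx)
    iu = np.triu_indices(n, k=1)
    ss_total = float(d2[iu].sum()) / n
    ss_within = 0.0
    for idx in group_idx:
        sub = d2[np.ix_(idx, idx)]
        ss_within += float(np.triu(sub, k=1).sum()) / len(idx)
    ss_among = ss_total - ss_within
    if ss_within == 0.0:
        # perfectly tight groups: infinite separation unless everything is 0
        return float("inf") if ss_among > 1e-12 else 0.0
    return (ss_among / (k - 1)) / (ss_within / (n - k))


def _homova_B(d2: np.ndarray, group_idx: list[np.ndarray]) -> float:
    # Bartlett-style statistic on within-group mean squared distances
    n = d2.shape[0]
    k = len(group_idx)
    ss_w = []
    dfs = []
    for idx in group_idx:
        ni = len(idx)
        sub = d2[np.ix_(idx, idx)]
        ss_w.append(float(np.triu(sub, k=1).sum()) / ni)
        dfs.append(ni - 1)
    ss_w = np.asarray(ss_w)
    dfs = np.asarray(dfs, dtype=float)
    pooled = ss_w.sum() / dfs.sum()
    if pooled <= 0 or (ss_w <= 0).any():
        return 0.0
    return float(dfs.sum() * np.log(pooled) - (dfs * np.log(ss_w / dfs)).sum())


def _permutation_test(
    dm: DistanceMatrix,
    groups: Mapping[str, str],
    stat_fn,
    n_perm: int,
    seed: int | None,
) -> PermutationTestResult:
    group_idx = _group_indices(dm.labels, groups)
    d2 = dm.d**2
    observed = stat_fn(d2, group_idx)
    sizes = [len(idx) for idx in group_idx]
    order = np.concatenate(group_idx)
    rng = np.random.default_rng(seed)
    more_extreme = 0
    n = len(dm.labels)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        shuffled = order[perm]
        start = 0
        perm_idx = []
        for s in sizes:
            perm_idx.append(shuffled[start : start + s])
            start += s
        if stat_fn(d2, perm_idx) >= observed:
            more_extreme += 1
    p = (1 + more_extreme) / (1 + n_perm)
    return PermutationTestResult(
        statistic=float(observed), p_value=p, n_permutations=n_perm, seed=seed
    )


def amova(
    dm: DistanceMatrix,
    groups: Mapping[str, str],
    n_perm: int = 999,
    seed: int | None = None,
) -> PermutationTestResult:
    """Analysis of molecular variance: permutation test on the pseudo-F
    statistic for among-group location differences."""
    return _permutation_test(dm, groups, _amova_F, n_perm, seed)


def homova(
    dm: DistanceMatrix,
    groups: Mapping[str, str],
    n_perm: int = 999,
    seed: int | None = None,
) -> PermutationTestResult:
    """Homogeneity of molecular variance: permutation test on a
    Bartlett-style statistic for unequal within-group dispersion."""
    return _permutation_test(dm, groups, _homova_B, n_perm, seed)
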