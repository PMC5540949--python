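"""OTU inference: dereplication, singleton removal, greedy centroid
clustering with de novo chimera flagging, read mapping and rarefaction.

Clustering follows the greedy abundance-ordered strategy: unique sequences
are visited in order of decreasing abundance (ties broken lexicographically
on the sequence, which makes the whole stage deterministic); each either
joins the best existing centroid at identity >= the cutoff, is discarded as a
chimera of two more-abundant centroids, or founds a new OTU.

Identity between two sequences is computed from a global alignment with free
terminal gaps (match +1, mismatch -1, gap -2) as matches / alignment columns,
terminal-gap columns excluded.  Equal-length sequence pairs whose ungapped
identity is already >= 0.9 take a fast ungapped path — for the
substitution-dominated divergence of amplicon reads the optimal alignment is
then gap-free, and after fixed-length truncation this is the hot path.

The chimera test is a simplified two-parent single-crossover model: a query
is flagged when some prefix matches one >=2x-more-abundant parent at >=0.99
identity and the complementary suffix matches a different parent at >=0.99,
while no single parent reaches the clustering cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align

from .io_formats import SequenceRecord, ValidationError

__all__ = [
    "UniqueSequence",
    "Otu",
    "OtuTable",
    "ClusterParams",
    "pairwise_identity",
    "dereplicate",
    "remove_singletons",
    "flag_chimera",
    "cluster_otus",
    "build_otu_table",
    "rarefy_table",
]


@dataclass(frozen=True)
class UniqueSequence:
    """A dereplicated sequence with its total and per-sample read counts."""

    bases: str
    size: int
    per_sample: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.size != sum(self.per_sample.values()):
            raise ValidationError("unique size must equal sum of per-sample counts")
        if self.size < 1:
            raise ValidationError("unique size must be >= 1")


@dataclass(frozen=True)
class Otu:
    otu_id: str
    centroid: str
    size: int


@dataclass(frozen=True)
class OtuTable:
    """Samples x OTUs count matrix with centroid sequences."""

    samples: tuple[str, ...]
    otus: tuple[Otu, ...]
    counts: np.ndarray  # shape (n_samples, n_otus), non-negative ints

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.samples), len(self.otus)):
            raise ValidationError("count matrix shape mismatch")
        if counts.size and (counts < 0).any():
            raise ValidationError("counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def otu_ids(self) -> list[str]:
        return [o.otu_id for o in self.otus]

    def sample_counts(self, sample: str) -> np.ndarray:
        return self.counts[self.samples.index(sample)]

    def relative_abundances(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        totals[totals == 0] = 1.0
        return self.counts / totals

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, OtuTable)
            and self.samples == other.samples
            and self.otu_ids == other.otu_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass(frozen=True)
class ClusterParams:
    """Greedy-clustering configuration.

    similarity_cutoff: centroid-joining identity threshold (CLI -s).
    min_size: minimum unique abundance to seed clustering (2 = singleton discard).
    chimera_skew: required parent/query abundance ratio for chimera parents.
    chimera_segment_identity: per-segment identity for the crossover test.
    map_singletons: whether reads from discarded singleton uniques are still
        mapped back to centroids when building the OTU table.
    """

    similarity_cutoff: float = 0.97
    min_size: int = 2
    chimera_skew: float = 2.0
    chimera_segment_identity: float = 0.99
    map_singletons: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.similarity_cutoff <= 1.0):
            raise ValueError("similarity_cutoff must be in (0, 1]")


# ---------------------------------------------------------------------------
# Identity
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1
    al.mismatch_score = -1
    al.open_gap_score = -2
    al.extend_gap_score = -2
    al.end_gap_score = 0  # terminal gaps free
    return al


def _ungapped_identity(a: str, b: str) -> float:
    x = np.frombuffer(a.encode(), dtype=np.uint8)
    y = np.frombuffer(b.encode(), dtype=np.uint8)
    return float(np.count_nonzero(x == y)) / len(x)


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical columns in the best semi-global alignment of two sequences.

    Terminal-gap columns are excluded from the denominator, so a sequence is
    100% identical to itself plus a terminal overhang.  Symmetric.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if a == b:
        return 1.0
    if len(a) == len(b):
        ident = _ungapped_identity(a, b)
        if ident >= 0.9:
            return ident
    aln = _aligner().align(a, b)[0]
    blocks_a, blocks_b = aln.aligned
    if len(blocks_a) == 0:
        return 0.0
    matches = 0
    aligned_cols = 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        seg_a, seg_b = a[a0:a1], b[b0:b1]
        matches += sum(1 for x, y in zip(seg_a, seg_b) if x == y)
        aligned_cols += a1 - a0
    # internal gap columns between consecutive aligned blocks
    gap_cols = 0
    for k in range(1, len(blocks_a)):
        gap_cols += blocks_a[k][0] - blocks_a[k - 1][1]
        gap_cols += blocks_b[k][0] - blocks_b[k - 1][1]
    total = aligned_cols + gap_cols
    return matches / total if total else 0.0


def _screened_identity(a: str, b: str, cutoff: float) -> float:
    """Identity with a screening shortcut for the clustering/mapping loops.

    For equal-length pairs whose ungapped identity falls more than 0.05 below
    the decision cutoff, the ungapped value is returned without running the
    full alignment: a gapped alignment cannot plausibly rescue such a pair
    across the cutoff for substitution-dominated amplicon divergence.  Pairs
    near or above the cutoff get the exact :func:`pairwise_identity`.
    """
    if len(a) == len(b):
        u = _ungapped_identity(a, b)
        if u >= 0.9:
            return u
        if u < cutoff - 0.05:
            return u
    return pairwise_identity(a, b)


# ---------------------------------------------------------------------------
# Dereplication
# ---------------------------------------------------------------------------

def dereplicate(reads: Sequence[SequenceRecord]) -> list[UniqueSequence]:
    """Collapse identical base strings, keeping per-sample counts.

    Output is sorted by abundance descending, ties by lexicographic sequence.
    """
    by_seq: dict[str, dict[str, int]] = {}
    for rec in reads:
        sample = rec.sample or ""
        per = by_seq.setdefault(rec.bases, {})
        per[sample] = per.get(sample, 0) + 1
    uniques = [
        UniqueSequence(bases=seq, size=sum(per.values()), per_sample=per)
        for seq, per in by_seq.items()
    ]
    uniques.sort(key=lambda u: (-u.size, u.bases))
    return uniques


def remove_singletons(uniques: Sequence[UniqueSequence], min_size: int = 2) -> list[UniqueSequence]:
    return [u for u in uniques if u.size >= min_size]


# ---------------------------------------------------------------------------
# Chimera flagging
# ---------------------------------------------------------------------------

def _match_profile(query: str, parent: str) -> np.ndarray | None:
    """Boolean per-query-position match vector against a parent.

    Equal lengths compare position-wise; otherwise the parent is aligned to
    the query and gap columns count as mismatches.
    """
    if len(parent) == len(query):
        q = np.frombuffer(query.encode(), dtype=np.uint8)
        p = np.frombuffer(parent.encode(), dtype=np.uint8)
        return q == p
    aln = _aligner().align(query, parent)[0]
    prof = np.zeros(len(query), dtype=bool)
    for (q0, q1), (p0, p1) in zip(*aln.aligned):
        seg_q, seg_p = query[q0:q1], parent[p0:p1]
        prof[q0:q1] = [x == y for x, y in zip(seg_q, seg_p)]
    return prof


def flag_chimera(
    query: UniqueSequence,
    parents: Sequence[UniqueSequence],
    params: ClusterParams = ClusterParams(),
) -> bool:
    """Two-parent single-crossover chimera test.

    True iff some crossover column c gives prefix identity >= the segment
    threshold against one eligible parent and suffix identity >= the threshold
    against a different one, while no single parent alone reaches the
    clustering cutoff.  Eligible parents must be >= ``chimera_skew`` times as
    abundant as the query.
    """
    eligible = [p for p in parents if p.size >= params.chimera_skew * query.size]
    if len(eligible) < 2:
        return False
    L = len(query.bases)
    profiles = [_match_profile(query.bases, p.bases) for p in eligible]
    idents = [float(prof.mean()) for prof in profiles]
    if max(idents) >= params.similarity_cutoff:
        return False

    thr = params.chimera_segment_identity
    pre = np.stack([np.cumsum(prof) for prof in profiles])  # (P, L)
    totals = pre[:, -1]
    cols = np.arange(1, L)  # crossover after column c: prefix len c, suffix L-c
    pre_ident = pre[:, cols - 1] / cols  # (P, L-1)
    suf_ident = (totals[:, None] - pre[:, cols - 1]) / (L - cols)
    pre_ok = pre_ident >= thr
    suf_ok = suf_ident >= thr
    for c_idx in range(L - 1):
        left = np.flatnonzero(pre_ok[:, c_idx])
        right = np.flatnonzero(suf_ok[:, c_idx])
        if left.size and right.size:
            if left.size > 1 or right.size > 1 or left[0] != right[0]:
                return True
    return False


# ---------------------------------------------------------------------------
# Clustering and mapping
# ---------------------------------------------------------------------------

def cluster_otus(
    uniques: Sequence[UniqueSequence], params: ClusterParams = ClusterParams()
) -> list[Otu]:
    """Greedy abundance-ordered centroid formation with chimera discard.

    ``uniques`` must already be abundance-sorted with singletons removed (as
    produced by :func:`dereplicate` + :func:`remove_singletons`).  OTU ids are
    assigned in creation order: OTU_1, OTU_2, ...
    """
    centroids: list[UniqueSequence] = []
    for u in uniques:
        best_idx, best_ident = -1, -1.0
        for i, c in enumerate(centroids):
            ident = _screened_identity(u.bases, c.bases, params.similarity_cutoff)
            if ident > best_ident:
                best_idx, best_ident = i, ident
        if best_idx >= 0 and best_ident >= params.similarity_cutoff:
            continue  # joins an existing OTU; membership resolved at mapping
        if flag_chimera(u, centroids, params):
            continue
        centroids.append(u)
    return [
        Otu(otu_id=f"OTU_{i + 1}", centroid=c.bases, size=0)
        for i, c in enumerate(centroids)
    ]


def build_otu_table(
    reads: Sequence[SequenceRecord],
    otus: Sequence[Otu],
    params: ClusterParams = ClusterParams(),
) -> OtuTable:
    """Map every read to its best centroid at identity >= the cutoff.

    Reads from former singleton uniques are included by default
    (``params.map_singletons``); reads matching no centroid are dropped.
    Sample order follows first appearance in the input reads.
    """
    if not otus:
        raise ValueError("no OTUs to map against")
    uniques = dereplicate(reads)
    if not params.map_singletons:
        uniques = remove_singletons(uniques, params.min_size)

    samples: list[str] = []
    seen: set[str] = set()
    for rec in reads:
        s = rec.sample or ""
        if s not in seen:
            seen.add(s)
            samples.append(s)
    sample_idx = {s: i for i, s in enumerate(samples)}

    counts = np.zeros((len(samples), len(otus)), dtype=np.int64)
    mapped_sizes = np.zeros(len(otus), dtype=np.int64)
    for u in uniques:
        best_j, best_ident = -1, -1.0
        for j, otu in enumerate(otus):
            ident = _screened_identity(u.bases, otu.centroid, params.similarity_cutoff)
            if ident > best_ident:
                best_j, best_ident = j, ident
        if best_ident < params.similarity_cutoff:
            continue
        for s, n in u.per_sample.items():
            counts[sample_idx[s], best_j] += n
        mapped_sizes[best_j] += u.size

    otus_sized = tuple(
        replace(o, size=int(mapped_sizes[j])) for j, o in enumerate(otus)
    )
    return OtuTable(samples=tuple(samples), otus=otus_sized, counts=counts)


def rarefy_table(
    table: OtuTable, depth: int, seed: int | None = None
) -> OtuTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped (with a
    warning).  Deterministic given ``seed``.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    kept_samples: list[str] = []
    rows: list[np.ndarray] = []
    for i, sample in enumerate(table.samples):
        total = int(table.counts[i].sum())
        if total < depth:
            import warnings

            warnings.warn(
                f"sample {sample!r} has {total} reads < depth {depth}; dropped"
            )
            continue
        if total == depth:
            rows.append(table.counts[i].copy())
        else:
            rows.append(
                rng.multivariate_hypergeometric(table.counts[i], depth).astype(np.int64)
            )
        kept_samples.append(sample)
    counts = (
        np.vstack(rows) if rows else np.zeros((0, len(table.otus)), dtype=np.int64)
    )
    return OtuTable(samples=tuple(kept_samples), otus=table.otus, counts=counts)
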