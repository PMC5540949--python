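"""Naive-Bayes k-mer taxonomy classification with bootstrap confidence.

The classifier scores a query's k-mer (word) *set* against per-genus word
profiles learned from a labelled reference collection, following the
established naive-Bayes approach for amplicon taxonomy:

* word prior over the whole reference set:  P(w) = (n(w) + 0.5) / (N + 1)
* genus conditional:                        P(w|g) = (m(w,g) + P(w)) / (M_g + 1)
* query score for genus g:                  sum over query words of log P(w|g)

where ``n(w)`` / ``m(w,g)`` count reference sequences containing word ``w``
overall / within genus g, ``N`` is the total number of references and ``M_g``
the number in genus g.  Duplicate words within one sequence count once
(presence, not abundance).

Confidence comes from bootstrap resampling: ``n_boot`` draws of ``len(W)//8``
words with replacement from the query's word set; the confidence of a taxon
at any rank is the fraction of resamples whose winning genus lies under that
taxon.  Ranks whose confidence falls below the cutoff are reported
"unclassified".  The reference database is pluggable (FASTA plus a
tab-separated taxonomy file in the ``id<TAB>Domain;...;Genus;`` dialect).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ReferenceDb",
    "TaxonomyAssignment",
    "train_classifier",
    "classify",
    "read_reference_db",
    "RANKS",
]

RANKS = ("domain", "phylum", "class", "order", "family", "genus")

_BASE_TO_BITS = {"A": 0, "C": 1, "G": 2, "T": 3}


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """Distinct k-mer integer codes present in ``seq`` (k-mers with non-ACGT skipped)."""
    codes = set()
    for i in range(len(seq) - k + 1):
        word = seq[i : i + k]
        code = 0
        ok = True
        for b in word:
            v = _BASE_TO_BITS.get(b)
            if v is None:
                ok = False
                break
            code = (code << 2) | v
        if ok:
            codes.add(code)
    return np.fromiter(sorted(codes), dtype=np.int64, count=len(codes))


@dataclass(frozen=True)
class ReferenceDb:
    """Trained per-genus word profiles.

    ``log_cond`` is a dense (n_genera, 4**k) matrix of log P(w|g);
    ``genus_lineages`` maps each genus row to its full ranked lineage.
    """

    k: int
    genera: tuple[str, ...]
    genus_lineages: tuple[tuple[str, ...], ...]
    log_cond: np.ndarray

    @property
    def n_genera(self) -> int:
        return len(self.genera)


@dataclass(frozen=True)
class TaxonomyAssignment:
    """Ranked lineage with per-rank bootstrap confidence.

    ``per_rank`` holds one (taxon name, confidence in [0, 1]) pair per rank,
    domain to genus; ranks below the confidence cutoff carry the name
    ``unclassified``.
    """

    per_rank: tuple[tuple[str, float], ...]

    def name(self, rank: str) -> str:
        return self.per_rank[RANKS.index(rank)][0]

    def confidence(self, rank: str) -> float:
        return self.per_rank[RANKS.index(rank)][1]

    def lineage_string(self) -> str:
        return ";".join(
            f"{name}({conf * 100:.0f})" for name, conf in self.per_rank
        )


def train_classifier(
    refs: Sequence[tuple[str, Sequence[str]]], k: int = 8
) -> ReferenceDb:
    """Build per-genus word profiles from (sequence, lineage) references.

    Lineages must all have the same depth (domain → genus).  Duplicate
    reference sequences are allowed and counted once per record.
    """
    if not 4 <= k <= 12:
        raise ValueError("k must be in [4, 12]")
    depths = {len(lineage) for _, lineage in refs}
    if len(depths) != 1:
        raise ValueError(f"inconsistent lineage depths: {sorted(depths)}")
    depth = depths.pop()
    if depth != len(RANKS):
        raise ValueError(f"lineages must have {len(RANKS)} ranks, got {depth}")

    genera: list[str] = []
    genus_lineages: list[tuple[str, ...]] = []
    genus_idx: dict[tuple[str, ...], int] = {}
    for _, lineage in refs:
        key = tuple(lineage)
        if key not in genus_idx:
            genus_idx[key] = len(genera)
            genera.append(lineage[-1])
            genus_lineages.append(key)
    if len(genera) < 2:
        raise ValueError("need references from at least 2 distinct genera")

    n_words = 4**k
    n_refs = len(refs)
    overall = np.zeros(n_words, dtype=np.float64)
    per_genus = np.zeros((len(genera), n_words), dtype=np.float64)
    genus_sizes = np.zeros(len(genera), dtype=np.float64)
    for seq, lineage in refs:
        g = genus_idx[tuple(lineage)]
        codes = _kmer_codes(seq.upper(), k)
        overall[codes] += 1
        per_genus[g, codes] += 1
        genus_sizes[g] += 1

    prior = (overall + 0.5) / (n_refs + 1.0)
    log_cond = np.log(per_genus + prior[None, :]) - np.log(genus_sizes + 1.0)[:, None]
    return ReferenceDb(
        k=k,
        genera=tuple(genera),
        genus_lineages=tuple(genus_lineages),
        log_cond=log_cond,
    )


def classify(
    seq: str,
    db: ReferenceDb,
    n_boot: int = 100,
    conf_cutoff: float = 0.80,
    seed: int | None = None,
) -> TaxonomyAssignment:
    """Assign a ranked lineage with bootstrap confidences to a query sequence."""
    seq = seq.upper()
    if len(seq) < db.k:
        raise ValueError(f"query shorter than k={db.k}")
    codes = _kmer_codes(seq, db.k)
    if codes.size == 0:
        raise ValueError("query contains no valid words (all ambiguous?)")
    rng = np.random.default_rng(seed)

    subset = max(1, codes.size // 8)
    word_scores = db.log_cond[:, codes]  # (G, W)
    draws = rng.integers(0, codes.size, size=(n_boot, subset))
    # scores per bootstrap: sum over drawn words for every genus
    boot_scores = word_scores[:, draws].sum(axis=2)  # (G, n_boot)
    winners = np.argmax(boot_scores, axis=0)  # (n_boot,)

    per_rank: list[tuple[str, float]] = []
    win_lineages = [db.genus_lineages[w] for w in winners]
    for r in range(len(RANKS)):
        names, counts = np.unique([lin[r] for lin in win_lineages], return_counts=True)
        top = int(np.argmax(counts))
        conf = counts[top] / n_boot
        name = str(names[top]) if conf >= conf_cutoff else "unclassified"
        per_rank.append((name, float(conf)))
    return TaxonomyAssignment(per_rank=tuple(per_rank))


def read_reference_db(
    fasta_path: str | Path, taxonomy_path: str | Path, k: int = 8
) -> ReferenceDb:
    """Load a reference set from FASTA + tab-separated taxonomy file.

    Taxonomy lines: ``id<TAB>Domain;Phylum;Class;Order;Family;Genus;`` —
    a trailing semicolon is tolerated.
    """
    from Bio import SeqIO

    lineages: dict[str, tuple[str, ...]] = {}
    with open(taxonomy_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            try:
                rid, tax = line.split("\t")
            except ValueError as exc:
                raise ValueError(
                    f"{taxonomy_path}: line {lineno}: expected 'id<TAB>lineage'"
                ) from exc
            parts = [p for p in tax.strip().split(";") if p]
            lineages[rid] = tuple(parts)
    refs = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in lineages:
            raise ValueError(f"reference {rec.id!r} missing from taxonomy file")
        refs.append((str(rec.seq), lineages[rec.id]))
    return train_classifier(refs, k=k)
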