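"""Read preparation: merge read pairs, trim primers, quality-filter, pool.

The stage order is fixed — merge, then primer trim, then quality filter — and
is not configurable.  Rejections are values (a :class:`Rejection` with a
reason tag), never exceptions, so the caller can account for every input read.

Pair merging aligns the forward read against the reverse-complement of the
reverse read by exhaustive scan over all ungapped offsets with overlap at
least ``min_overlap_len`` (score = matches - mismatches, ties broken toward
the longer overlap).  In the overlap a single base and quality is derived per
column: agreeing bases get ``min(q1 + q2, 45)``; for disagreeing bases the
higher-quality base is kept with quality ``max(2, |q1 - q2|)``.  ``N`` counts
as a mismatch everywhere.

Quality filtering truncates to a fixed length and discards reads whose
expected error count ``EE = sum(10^(-Q/10))`` over the truncated prefix
exceeds ``maxee``; reads shorter than the truncation length are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import (
    IUPAC_CODES,
    MappingEntry,
    PrimerSet,
    SequenceRecord,
    read_fasta_with_qual,
    read_fastq,
    reverse_complement,
)

__all__ = [
    "MergeParams",
    "FilterParams",
    "PrepStats",
    "Rejection",
    "merge_pair",
    "trim_primers",
    "quality_filter",
    "pool_samples",
    "expected_errors",
]

MAX_MERGED_QUAL = 45


@dataclass(frozen=True)
class MergeParams:
    """Pair-merging thresholds (CLI -minoverlen / -maxdiffs)."""

    min_overlap_len: int = 100
    max_diffs: int = 8

    def __post_init__(self) -> None:
        if self.min_overlap_len < 1:
            raise ValueError("min_overlap_len must be >= 1")
        if self.max_diffs < 0:
            raise ValueError("max_diffs must be >= 0")


@dataclass(frozen=True)
class FilterParams:
    """Primer-trim and quality-filter thresholds (-pdiffs / -maxee / -trunclen)."""

    trunclen: int = 250
    maxee: float = 1.0
    pdiffs: int = 2

    def __post_init__(self) -> None:
        if self.trunclen < 1:
            raise ValueError("trunclen must be >= 1")
        if self.maxee < 0:
            raise ValueError("maxee must be >= 0")
        if self.pdiffs < 0:
            raise ValueError("pdiffs must be >= 0")


@dataclass(frozen=True)
class Rejection:
    """A read discarded at some stage, tagged with the reason."""

    reason: str


@dataclass
class PrepStats:
    """Per-sample read accounting: input count, survivors, discards by reason.

    Invariant: ``input == passed + sum(discarded.values())`` per sample.
    """

    input: dict[str, int] = field(default_factory=dict)
    passed: dict[str, int] = field(default_factory=dict)
    discarded: dict[str, dict[str, int]] = field(default_factory=dict)

    def record(self, sample: str, outcome: str) -> None:
        self.input[sample] = self.input.get(sample, 0) + 1
        if outcome == "passed":
            self.passed[sample] = self.passed.get(sample, 0) + 1
        else:
            per = self.discarded.setdefault(sample, {})
            per[outcome] = per.get(outcome, 0) + 1

    def ensure_sample(self, sample: str) -> None:
        self.input.setdefault(sample, 0)
        self.passed.setdefault(sample, 0)
        self.discarded.setdefault(sample, {})

    def total_discarded(self, reason: str) -> int:
        return sum(per.get(reason, 0) for per in self.discarded.values())


_BASE_CODE = np.full(128, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _BASE_CODE[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def merge_pair(
    fwd: SequenceRecord, rev: SequenceRecord, params: MergeParams = MergeParams()
) -> SequenceRecord | Rejection:
    """Merge a read pair into one record, or reject it.

    Returns ``Rejection("short_overlap")`` when no candidate overlap reaches
    ``min_overlap_len`` and ``Rejection("too_many_diffs")`` when the best
    overlap has more than ``max_diffs`` mismatches.
    """
    if fwd.quals is None or rev.quals is None:
        raise ValueError("merge_pair requires qualities on both reads")

    rc_bases = reverse_complement(rev.bases)
    rc_quals = rev.quals[::-1]
    f = _encode(fwd.bases)
    r = _encode(rc_bases)
    nf, nr = len(f), len(r)
    max_ov = min(nf, nr)

    # Overlap of length o aligns fwd suffix f[nf-o:] with rc prefix r[:o].
    # N (code 4) mismatches everything, including another N.  The best
    # overlap is found over ALL offsets and only then classified, so a true
    # overlap shorter than the minimum is reported as short, not noisy.
    best = None  # (score, overlap, diffs)
    for o in range(1, max_ov + 1):
        a = f[nf - o :]
        b = r[:o]
        eq = a == b
        matches = int(np.count_nonzero(eq & (a != 4)))
        diffs = o - matches
        score = matches - diffs
        if best is None or score > best[0] or (score == best[0] and o > best[1]):
            best = (score, o, diffs)

    _, overlap, diffs = best
    if overlap < params.min_overlap_len:
        return Rejection("short_overlap")
    if diffs > params.max_diffs:
        return Rejection("too_many_diffs")

    merged_bases = list(fwd.bases[: nf - overlap])
    merged_quals = list(fwd.quals[: nf - overlap])
    for k in range(overlap):
        b1, q1 = fwd.bases[nf - overlap + k], fwd.quals[nf - overlap + k]
        b2, q2 = rc_bases[k], rc_quals[k]
        if b1 == b2 and b1 != "N":
            merged_bases.append(b1)
            merged_quals.append(min(q1 + q2, MAX_MERGED_QUAL))
        else:
            if q1 >= q2:
                merged_bases.append(b1)
            else:
                merged_bases.append(b2)
            merged_quals.append(max(2, abs(q1 - q2)))
    merged_bases.extend(rc_bases[overlap:])
    merged_quals.extend(rc_quals[overlap:])

    return SequenceRecord(
        id=fwd.id,
        bases="".join(merged_bases),
        quals=tuple(merged_quals),
        sample=fwd.sample,
    )


def _primer_mismatches(primer: str, segment: str) -> int:
    """Mismatch count of an IUPAC primer against a plain-base segment; N in the read mismatches."""
    mism = 0
    for p, b in zip(primer, segment):
        if b == "N" or b not in IUPAC_CODES[p]:
            mism += 1
    return mism


def trim_primers(
    rec: SequenceRecord, primers: PrimerSet, pdiffs: int = 2
) -> SequenceRecord | Rejection:
    """Locate and remove the forward primer at the 5' end and the
    reverse-complemented reverse primer at the 3' end.

    Primer comparison is IUPAC-aware and anchored (position 0 / read end); the
    best-matching primer of each direction is used.  Rejections:
    ``no_forward_primer`` / ``no_reverse_primer``.
    """
    best_f = None
    for p in primers.forward:
        if len(p) > len(rec.bases):
            continue
        m = _primer_mismatches(p, rec.bases[: len(p)])
        if m <= pdiffs and (best_f is None or m < best_f[0]):
            best_f = (m, len(p))
    if best_f is None:
        return Rejection("no_forward_primer")

    best_r = None
    for p in primers.reverse:
        if len(p) > len(rec.bases) - best_f[1]:
            continue
        # the read ends with the reverse complement of the reverse primer
        rc = reverse_complement(p)
        m = _primer_mismatches(rc, rec.bases[len(rec.bases) - len(rc) :])
        if m <= pdiffs and (best_r is None or m < best_r[0]):
            best_r = (m, len(p))
    if best_r is None:
        return Rejection("no_reverse_primer")

    return rec.slice(best_f[1], len(rec.bases) - best_r[1])


def expected_errors(quals: Sequence[int]) -> float:
    """EE = sum of per-base error probabilities 10^(-Q/10)."""
    q = np.asarray(quals, dtype=float)
    return float(np.sum(10.0 ** (-q / 10.0)))


def quality_filter(
    rec: SequenceRecord, params: FilterParams
) -> SequenceRecord | Rejection:
    """Truncate to ``trunclen`` and apply the expected-errors filter.

    Rejections: ``too_short`` (read shorter than the truncation length) and
    ``maxee_exceeded`` (EE over the truncated prefix above ``maxee``).
    """
    if rec.quals is None:
        raise ValueError("quality_filter requires qualities")
    if len(rec.bases) < params.trunclen:
        return Rejection("too_short")
    truncated = rec.slice(0, params.trunclen)
    if expected_errors(truncated.quals) > params.maxee:
        return Rejection("maxee_exceeded")
    return truncated


def _load_reads(path: str, seqformat: str) -> list[SequenceRecord]:
    if seqformat == "fastq":
        return read_fastq(path)
    if seqformat == "fasta":
        import os

        qual = path + ".qual"
        return read_fasta_with_qual(path, qual if os.path.exists(qual) else None)
    raise ValueError(f"unknown seqformat {seqformat!r}")


def pool_samples(
    entries: Sequence[MappingEntry],
    primers: PrimerSet,
    merge_params: MergeParams = MergeParams(),
    filter_params: FilterParams = FilterParams(),
    seqformat: str = "fastq",
) -> tuple[list[SequenceRecord], PrepStats]:
    """Run merge → primer trim → quality filter for every sample and pool.

    Every surviving record carries its sample label; the returned
    :class:`PrepStats` reconciles exactly (input = passed + discarded).
    Single-end entries (no read2) skip the merging stage.
    """
    pooled: list[SequenceRecord] = []
    stats = PrepStats()
    for entry in entries:
        stats.ensure_sample(entry.sample_name)
        try:
            reads1 = _load_reads(entry.read1, seqformat)
            reads2 = _load_reads(entry.read2, seqformat) if entry.paired else None
        except OSError as exc:
            raise OSError(
                f"sample {entry.sample_name!r}: cannot read input: {exc}"
            ) from exc
        if reads2 is not None and len(reads1) != len(reads2):
            raise ValueError(
                f"sample {entry.sample_name!r}: read1/read2 record counts differ "
                f"({len(reads1)} vs {len(reads2)})"
            )
        for i, fwd in enumerate(reads1):
            if reads2 is not None:
                merged = merge_pair(fwd, reads2[i], merge_params)
                if isinstance(merged, Rejection):
                    stats.record(entry.sample_name, merged.reason)
                    continue
            else:
                merged = fwd
            trimmed = trim_primers(merged, primers, filter_params.pdiffs)
            if isinstance(trimmed, Rejection):
                stats.record(entry.sample_name, trimmed.reason)
                continue
            filtered = quality_filter(trimmed, filter_params)
            if isinstance(filtered, Rejection):
                stats.record(entry.sample_name, filtered.reason)
                continue
            stats.record(entry.sample_name, "passed")
            pooled.append(filtered.with_sample(entry.sample_name))
    return pooled, stats
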