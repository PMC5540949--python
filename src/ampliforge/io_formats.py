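"""Readers and writers for every file format the pipeline touches.

Sequence I/O (FASTQ, FASTA with optional ``.qual`` companions) is built on
:mod:`Bio.SeqIO`; graph output uses :func:`networkx.write_gexf`; sample trees
are serialized through :class:`skbio.TreeNode`.  All parsers validate against
the pipeline's domain invariants and raise :class:`ParseError` /
:class:`ValidationError` with file context rather than letting library
exceptions escape.

FASTQ qualities are assumed Phred+33 (the MiSeq convention); Phred+64 input is
not supported.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "SequenceRecord",
    "MappingEntry",
    "PrimerSet",
    "ParseError",
    "ValidationError",
    "IUPAC_CODES",
    "read_fastq",
    "write_fastq",
    "read_fasta_with_qual",
    "write_fasta",
    "read_mapping",
    "read_oligos",
    "read_shared_table",
    "write_shared_table",
    "write_newick",
    "write_gexf",
    "reverse_complement",
]

MAX_PHRED = 45

#: IUPAC nucleotide codes mapped to the set of plain bases each matches.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"), "U": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHV", "TGCAANYRSWMKVHDB")


class ParseError(ValueError):
    """A file could not be parsed into the expected record structure."""


class ValidationError(ValueError):
    """A parsed file violates a domain invariant (e.g. duplicate samples)."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """One read or sequence, with optional per-base Phred qualities.

    ``quals`` (when present) has one integer per base, each within
    [0, 45].  ``sample`` carries the sample label inserted during pooling.
    """

    id: str
    bases: str
    quals: tuple[int, ...] | None = None
    sample: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence record id must be non-empty")
        if self.quals is not None:
            if len(self.quals) != len(self.bases):
                raise ValidationError(
                    f"record {self.id!r}: {len(self.quals)} quality scores "
                    f"for {len(self.bases)} bases"
                )
            if self.quals and (min(self.quals) < 0 or max(self.quals) > MAX_PHRED):
                raise ValidationError(
                    f"record {self.id!r}: Phred scores must lie in [0, {MAX_PHRED}]"
                )

    def __len__(self) -> int:
        return len(self.bases)

    def slice(self, start: int, stop: int) -> "SequenceRecord":
        """Return the sub-record covering ``bases[start:stop]``, qualities sliced identically."""
        quals = self.quals[start:stop] if self.quals is not None else None
        return replace(self, bases=self.bases[start:stop], quals=quals)

    def with_sample(self, sample: str) -> "SequenceRecord":
        return replace(self, sample=sample)


@dataclass(frozen=True)
class MappingEntry:
    """One line of the mapping file: sample name, treatment group, strand, read paths."""

    sample_name: str
    treatment: str
    strand: str
    read1: str
    read2: str | None = None

    @property
    def paired(self) -> bool:
        return self.read2 is not None


@dataclass(frozen=True)
class PrimerSet:
    """Forward and reverse amplicon primers (IUPAC codes allowed)."""

    forward: tuple[str, ...]
    reverse: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.forward or not self.reverse:
            raise ValidationError("need at least one forward and one reverse primer")
        for p in (*self.forward, *self.reverse):
            bad = set(p) - set(IUPAC_CODES)
            if bad:
                raise ParseError(
                    f"primer {p!r} contains non-IUPAC characters: {sorted(bad)}"
                )


# ---------------------------------------------------------------------------
# FASTQ / FASTA
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read a Phred+33 FASTQ file into records with integer qualities.

    Malformed records (missing ``+`` separator, base/quality length mismatch,
    truncated final record) raise :class:`ParseError` naming the line.
    """
    records: list[SequenceRecord] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) % 4 != 0:
        raise ParseError(
            f"{path}: truncated FASTQ record starting at line {4 * (len(lines) // 4) + 1}"
        )
    for i in range(0, len(lines), 4):
        header, seq, plus, qual = lines[i : i + 4]
        lineno = i + 1
        if not header.startswith("@"):
            raise ParseError(f"{path}: line {lineno}: expected '@' header")
        if not plus.startswith("+"):
            raise ParseError(f"{path}: line {lineno + 2}: expected '+' separator")
        if len(seq) != len(qual):
            raise ParseError(
                f"{path}: line {lineno + 3}: quality string length {len(qual)} "
                f"does not match sequence length {len(seq)}"
            )
        quals = tuple(ord(c) - 33 for c in qual)
        if quals and (min(quals) < 0 or max(quals) > MAX_PHRED):
            raise ParseError(
                f"{path}: line {lineno + 3}: Phred score outside [0, {MAX_PHRED}] "
                "(is this Phred+33?)"
            )
        records.append(
            SequenceRecord(id=header[1:].split()[0], bases=seq.upper(), quals=quals)
        )
    return records


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.quals is None:
                raise ValidationError(f"record {rec.id!r} lacks qualities; cannot write FASTQ")
            qual = "".join(chr(q + 33) for q in rec.quals)
            fh.write(f"@{rec.id}\n{rec.bases}\n+\n{qual}\n")


def read_fasta_with_qual(
    fasta_path: str | Path, qual_path: str | Path | None = None
) -> list[SequenceRecord]:
    """Read FASTA, optionally pairing each record with a matching ``.qual`` file.

    Quality file ids must match the FASTA ids in order; a mismatch raises
    :class:`ParseError`.
    """
    from Bio import SeqIO

    seqs = list(SeqIO.parse(str(fasta_path), "fasta"))
    if qual_path is None:
        return [SequenceRecord(id=s.id, bases=str(s.seq).upper()) for s in seqs]
    quals = list(SeqIO.parse(str(qual_path), "qual"))
    if len(quals) != len(seqs):
        raise ParseError(
            f"{qual_path}: {len(quals)} quality records for {len(seqs)} sequences"
        )
    out = []
    for s, q in zip(seqs, quals):
        if s.id != q.id:
            raise ParseError(
                f"quality id {q.id!r} does not pair with sequence id {s.id!r}"
            )
        out.append(
            SequenceRecord(
                id=s.id,
                bases=str(s.seq).upper(),
                quals=tuple(q.letter_annotations["phred_quality"]),
            )
        )
    return out


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.bases}\n")


# ---------------------------------------------------------------------------
# Mapping / oligos
# ---------------------------------------------------------------------------

def read_mapping(path: str | Path) -> list[MappingEntry]:
    """Read the 5-column whitespace-separated mapping file.

    Columns: sample name, treatment, strand, read1, read2.  Lines starting
    with ``#`` are comments; 4-column lines describe single-end samples.
    """
    entries: list[MappingEntry] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 4:
                raise ParseError(
                    f"{path}: line {lineno}: expected 4 or 5 columns, got {len(cols)}"
                )
            sample, treatment, strand, read1 = cols[:4]
            read2 = cols[4] if len(cols) >= 5 else None
            if sample in seen:
                raise ValidationError(
                    f"{path}: line {lineno}: duplicate sample name {sample!r}"
                )
            seen.add(sample)
            entries.append(MappingEntry(sample, treatment, strand, read1, read2))
    return entries


def read_oligos(path: str | Path) -> PrimerSet:
    """Read the oligos file: lines ``forward <seq>`` / ``reverse <seq>``.

    Multiple primers per direction are allowed, one per line; IUPAC ambiguity
    codes are accepted and sequences are upper-cased.
    """
    fwd: list[str] = []
    rev: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) != 2 or cols[0].lower() not in ("forward", "reverse"):
                raise ParseError(
                    f"{path}: line {lineno}: expected 'forward <seq>' or 'reverse <seq>'"
                )
            seq = cols[1].upper()
            bad = set(seq) - set(IUPAC_CODES)
            if bad:
                raise ParseError(
                    f"{path}: line {lineno}: non-IUPAC characters {sorted(bad)} in primer"
                )
            (fwd if cols[0].lower() == "forward" else rev).append(seq)
    if not fwd or not rev:
        raise ParseError(f"{path}: need at least one forward and one reverse primer")
    return PrimerSet(forward=tuple(fwd), reverse=tuple(rev))


# ---------------------------------------------------------------------------
# Shared table (Mothur "shared" layout: label, Group, numOtus, counts)
# ---------------------------------------------------------------------------

def write_shared_table(table, path: str | Path, label: str = "0.03") -> None:
    """Write an OTU table in the Mothur shared-file layout (TSV)."""
    otu_ids = [o.otu_id for o in table.otus]
    with open(path, "w") as fh:
        fh.write("label\tGroup\tnumOtus\t" + "\t".join(otu_ids) + "\n")
        for i, sample in enumerate(table.samples):
            counts = "\t".join(str(int(c)) for c in table.counts[i])
            fh.write(f"{label}\t{sample}\t{len(otu_ids)}\t{counts}\n")


def read_shared_table(path: str | Path):
    """Read a Mothur-layout shared table back into an :class:`OtuTable`.

    Centroid sequences are not stored in the shared format, so the returned
    table carries empty-centroid placeholders ("N").
    """
    from .otu_inference import Otu, OtuTable

    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["label", "Group", "numOtus"]:
            raise ParseError(f"{path}: not a shared table (bad header)")
        otu_ids = header[3:]
        samples: list[str] = []
        rows: list[list[int]] = []
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            cols = raw.rstrip("\n").split("\t")
            if len(cols) != 3 + len(otu_ids):
                raise ParseError(f"{path}: line {lineno}: wrong column count")
            counts = [int(c) for c in cols[3:]]
            if any(c < 0 for c in counts):
                raise ValidationError(f"{path}: line {lineno}: negative count")
            samples.append(cols[1])
            rows.append(counts)
    otus = [Otu(otu_id=oid, centroid="N", size=0) for oid in otu_ids]
    counts = np.asarray(rows, dtype=np.int64).reshape(len(samples), len(otu_ids))
    otus = [
        replace(o, size=int(counts[:, j].sum())) for j, o in enumerate(otus)
    ]
    return OtuTable(samples=tuple(samples), otus=tuple(otus), counts=counts)


# ---------------------------------------------------------------------------
# Newick / GEXF
# ---------------------------------------------------------------------------

def write_newick(tree, path: str | Path) -> None:
    """Serialize a rooted tree (skbio.TreeNode) to Newick; duplicate leaf labels rejected."""
    leaves = [t.name for t in tree.tips()]
    if len(leaves) != len(set(leaves)):
        raise ValidationError("duplicate leaf labels in tree")
    buf = io.StringIO()
    tree.write(buf, format="newick")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def write_gexf(graph: nx.Graph, path: str | Path) -> None:
    """Write a co-occurrence graph as GEXF 1.2 XML (Gephi-readable)."""
    nx.write_gexf(graph, str(path), version="1.2draft")
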