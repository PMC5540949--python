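"""Synthetic mock-community generator.

Emulates multi-sample barcoded 16S amplicon sequencing of mock communities of
known composition so every pipeline stage can be validated without any
external data: reference 16S genes with controlled pairwise divergence and
indistinguishable strain groups, three community designs (equal-cell ECC,
equal-protein EPC, uneven UEC), 16S copy-number weighting of expected
abundances, an Illumina-like position-dependent substitution error model with
self-consistent quality scores, and between-sample index cross-talk with a
truth log.

Reference genes are built by mutating a random ancestor independently per
species (a star topology), rejection-sampling until all between-class insert
identities fall below the divergence target.  Each gene carries an exact
forward-primer site and reverse-primer complement so in-silico PCR yields a
427 nt insert, and the whole construct is padded to ~1500 nt.

The error model is substitution-only (no indels), with per-position error
probability rising linearly from ``base_error_rate`` at the 5' end to
``base_error_rate * three_prime_inflation`` at the 3' end, and the emitted
Phred score is exactly ``round(-10 log10 p)`` at each position.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_formats import SequenceRecord, reverse_complement, write_fastq

__all__ = [
    "MockCommunitySpec",
    "ErrorModel",
    "FORWARD_PRIMER",
    "REVERSE_PRIMER",
    "AMPLICON_INSERT_LEN",
    "generate_references",
    "community_profile",
    "simulate_read_pairs",
    "inject_crosstalk",
    "generate_mock_dataset",
    "generate_disjoint_dataset",
]

#: 3' amplification segments of the 341F / 805R bacterial primer pair.
FORWARD_PRIMER = "CCTACGGGAGGCAGCAG"
REVERSE_PRIMER = "GACTACHVGGGTATCTAATCC"

#: Insert length between the primers, so primer-trimmed amplicons are 427 nt.
AMPLICON_INSERT_LEN = 427

GENE_LEN = 1500

_TAXA_POOL = (
    "Agrobacterium", "Alteromonas", "Bacillus", "Burkholderia", "Chromobacterium",
    "Cupriavidus", "Escherichia", "Paracoccus", "Pseudomonas", "Rhizobium",
    "Roseobacter", "Salmonella", "Staphylococcus", "Stenotrophomonas", "Thermus",
    "Nitrosospira", "Desulfovibrio", "Nitrosomonas", "Aeromicrobium",
    "Sphingomonas", "Shewanella", "Vibrio", "Clostridium", "Lactobacillus",
)


@dataclass(frozen=True)
class MockCommunitySpec:
    """Design of one mock community.

    ``strain_groups`` lists the sizes of groups of strains that share an
    identical 16S sequence (the default (2, 2, 3) mirrors a community with
    two strains of two species and three strains of a third, i.e. 21 members
    in 17 distinguishable sequence classes).  ``divergence`` is the minimum
    between-class insert divergence (1 - identity).
    """

    n_species: int = 21
    profile: str = "ECC"
    strain_groups: tuple[int, ...] = (2, 2, 3)
    copy_numbers: tuple[int, ...] | None = None
    low_abundance_tail: float = 1e-4
    divergence: float = 0.06

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if self.profile not in ("ECC", "EPC", "UEC"):
            raise ValueError("profile must be ECC, EPC or UEC")
        if sum(self.strain_groups) > self.n_species:
            raise ValueError("strain groups cannot exceed n_species")
        if self.copy_numbers is not None and len(self.copy_numbers) != self.n_species:
            raise ValueError("copy_numbers length must equal n_species")

    @property
    def n_classes(self) -> int:
        """Number of distinguishable 16S sequence classes."""
        return self.n_species - sum(self.strain_groups) + len(self.strain_groups)


@dataclass(frozen=True)
class ErrorModel:
    """Position-dependent substitution error model with consistent qualities."""

    base_error_rate: float = 0.001
    three_prime_inflation: float = 3.0

    def error_probs(self, read_len: int) -> np.ndarray:
        pos = np.arange(read_len) / max(read_len - 1, 1)
        return self.base_error_rate * (1.0 + (self.three_prime_inflation - 1.0) * pos)

    def quals(self, read_len: int) -> np.ndarray:
        p = self.error_probs(read_len)
        q = np.round(-10.0 * np.log10(np.clip(p, 1e-4, 1.0)))
        return np.clip(q, 2, 40).astype(int)


@dataclass(frozen=True)
class ReferenceSpecies:
    name: str
    gene: str
    lineage: tuple[str, ...]
    seq_class: int  # index of the distinguishable sequence class


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.array(list(seq))
    hit = np.flatnonzero(rng.random(arr.size) < rate)
    for i in hit:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _concrete(primer: str, rng: np.random.Generator) -> str:
    """Pick one concrete realization of an IUPAC primer."""
    from .io_formats import IUPAC_CODES

    return "".join(sorted(IUPAC_CODES[c])[rng.integers(0, len(IUPAC_CODES[c]))] for c in primer)


def generate_references(
    spec: MockCommunitySpec, seed: int | None = None
) -> list[ReferenceSpecies]:
    """Generate full-length 16S genes for every community member.

    Members of one strain group share an identical gene; all between-class
    insert identities are rejection-sampled below ``1 - spec.divergence``.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    n_classes = spec.n_classes
    if n_classes > len(_TAXA_POOL):
        raise ValueError(
            f"divergence design supports at most {len(_TAXA_POOL)} sequence classes"
        )

    # per-branch mutation rate ~ divergence: two branches separate a pair
    rate = spec.divergence
    max_ident = 1.0 - spec.divergence
    for _attempt in range(50):
        ancestor = _random_seq(rng, AMPLICON_INSERT_LEN)
        inserts = [_mutate(rng, ancestor, rate) for _ in range(n_classes)]
        ok = True
        for i in range(n_classes):
            a = np.array(list(inserts[i]))
            for j in range(i + 1, n_classes):
                b = np.array(list(inserts[j]))
                if (a == b).mean() >= max_ident:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            break
    else:
        raise ValueError("divergence target unreachable for requested n_species")

    fwd_site = _concrete(FORWARD_PRIMER, rng)
    rev_site = reverse_complement(_concrete(REVERSE_PRIMER, rng))
    pad_total = GENE_LEN - len(fwd_site) - AMPLICON_INSERT_LEN - len(rev_site)
    left_pad = _random_seq(rng, pad_total // 2)
    right_pad = _random_seq(rng, pad_total - len(left_pad))

    # assign species to classes: strain groups first, then singles
    class_of_species: list[int] = []
    for g, size in enumerate(spec.strain_groups):
        class_of_species.extend([g] * size)
    next_class = len(spec.strain_groups)
    while len(class_of_species) < spec.n_species:
        class_of_species.append(next_class)
        next_class += 1

    refs: list[ReferenceSpecies] = []
    strain_counter: dict[int, int] = {}
    for s, cls in enumerate(class_of_species):
        genus = _TAXA_POOL[cls]
        strain_counter[cls] = strain_counter.get(cls, 0) + 1
        suffix = f"_strain{strain_counter[cls]}" if class_of_species.count(cls) > 1 else ""
        gene = left_pad + fwd_site + inserts[cls] + rev_site + right_pad
        lineage = (
            "Bacteria",
            f"Phylum_{cls % 5 + 1}",
            f"Class_{cls % 5 + 1}",
            f"Order_{cls // 2 + 1}",
            f"Family_{cls // 2 + 1}",
            genus,
        )
        refs.append(
            ReferenceSpecies(
                name=f"{genus}{suffix}", gene=gene, lineage=lineage, seq_class=cls
            )
        )
    return refs


def community_profile(
    spec: MockCommunitySpec, seed: int | None = None
) -> np.ndarray:
    """Per-species expected relative read abundances, copy-number corrected.

    ECC: equal cell counts; EPC: cell counts inversely proportional to a
    lognormal(0, 0.5) per-species protein mass; UEC: a geometric abundance
    ladder spanning ~3.5 orders of magnitude, placed so the post-
    normalization minimum sits near ``low_abundance_tail``.  In every design
    the cell-level weights are multiplied by the 16S copy number and
    renormalized — amplicon reads sample gene copies, not cells.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_species
    copy = (
        np.asarray(spec.copy_numbers, dtype=float)
        if spec.copy_numbers is not None
        else rng.integers(1, 11, size=n).astype(float)
    )
    if spec.profile == "ECC":
        cells = np.ones(n)
    elif spec.profile == "EPC":
        protein_mass = rng.lognormal(mean=0.0, sigma=0.5, size=n)
        cells = 1.0 / protein_mass
    else:  # UEC
        span = -np.log10(spec.low_abundance_tail) - 0.5
        ladder = 10.0 ** (-span * np.arange(n) / (n - 1))
        cells = rng.permutation(ladder)
    weights = cells * copy
    return weights / weights.sum()


def simulate_read_pairs(
    references: Sequence[ReferenceSpecies],
    abundances: Sequence[float],
    n_pairs: int,
    read_len: int = 300,
    error_model: ErrorModel = ErrorModel(),
    seed: int | None = None,
    id_prefix: str = "r",
) -> list[tuple[SequenceRecord, SequenceRecord]]:
    """Draw paired-end reads from the primered amplicons.

    Each pair's species is drawn with probability equal to its abundance; the
    forward read covers the amplicon 5' end and the reverse read is the
    reverse complement of its 3' end.  Substitution errors are injected per
    the error model, and the read id encodes the source species after a ``|``
    separator for truth tracking.
    """
    rng = np.random.default_rng(seed)
    abund = np.asarray(abundances, dtype=float)
    abund = abund / abund.sum()
    amplicons = []
    for ref in references:
        # locate the primered amplicon by the known construct layout
        pad = (GENE_LEN - len(FORWARD_PRIMER) - AMPLICON_INSERT_LEN - len(REVERSE_PRIMER)) // 2
        amplicons.append(
            ref.gene[pad : pad + len(FORWARD_PRIMER) + AMPLICON_INSERT_LEN + len(REVERSE_PRIMER)]
        )
    if any(len(a) < read_len for a in amplicons):
        raise ValueError("read_len exceeds amplicon length")

    probs = error_model.error_probs(read_len)
    quals = tuple(int(q) for q in error_model.quals(read_len))
    species_draw = rng.choice(len(references), size=n_pairs, p=abund)

    bases = np.array(list("ACGT"))
    pairs: list[tuple[SequenceRecord, SequenceRecord]] = []
    for i, s in enumerate(species_draw):
        amp = amplicons[s]
        fwd_t = amp[:read_len]
        rev_t = reverse_complement(amp[len(amp) - read_len :])
        out = []
        for template in (fwd_t, rev_t):
            arr = np.array(list(template))
            hit = np.flatnonzero(rng.random(read_len) < probs)
            for h in hit:
                choices = bases[bases != arr[h]]
                arr[h] = choices[rng.integers(0, 3)]
            out.append("".join(arr))
        rid = f"{id_prefix}{i:06d}|{references[s].name}"
        pairs.append(
            (
                SequenceRecord(id=rid, bases=out[0], quals=quals),
                SequenceRecord(id=rid, bases=out[1], quals=quals),
            )
        )
    return pairs


def inject_crosstalk(
    sample_reads: Mapping[str, list],
    rate: float,
    seed: int | None = None,
) -> tuple[dict[str, list], list[tuple[str, str, str]]]:
    """Reassign each read to a uniformly random other sample with probability
    ``rate`` (index hopping).  Returns the shuffled samples and a truth log of
    (read id, donor sample, recipient sample) for every moved read."""
    if not (0.0 <= rate < 0.1):
        raise ValueError("cross-talk rate must be in [0, 0.1)")
    samples = list(sample_reads)
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    out: dict[str, list] = {s: [] for s in samples}
    log: list[tuple[str, str, str]] = []
    for donor in samples:
        others = [s for s in samples if s != donor]
        for read in sample_reads[donor]:
            if rate > 0 and rng.random() < rate:
                recipient = others[rng.integers(0, len(others))]
                rid = read[0].id if isinstance(read, tuple) else read.id
                log.append((rid, donor, recipient))
                out[recipient].append(read)
            else:
                out[donor].append(read)
    return out, log


def generate_disjoint_dataset(
    outdir: str | Path,
    n_samples: int = 3,
    classes_per_sample: int = 7,
    n_pairs: int = 6000,
    crosstalk_rate: float = 0.02,
    seed: int = 1,
    error_model: ErrorModel = ErrorModel(),
) -> dict:
    """Simulate samples with mutually disjoint communities plus index hopping.

    Cross-talk between samples that share no species is directly observable:
    every foreign read lands in an OTU that is otherwise absent from the
    recipient.  Each sample gets an equal-abundance community over its own
    block of sequence classes.  Returns a manifest with the reference set,
    per-sample class blocks, FASTQ/mapping/oligos paths and the reassignment
    truth log.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    n_species = n_samples * classes_per_sample
    spec = MockCommunitySpec(n_species=n_species, strain_groups=())
    refs = generate_references(spec, seed=int(master.integers(2**31)))

    sample_pairs: dict[str, list] = {}
    sample_classes: dict[str, list[int]] = {}
    for k in range(n_samples):
        sample = f"S{k + 1}"
        block = list(range(k * classes_per_sample, (k + 1) * classes_per_sample))
        sample_classes[sample] = block
        abund = np.zeros(n_species)
        abund[block] = 1.0 / classes_per_sample
        sample_pairs[sample] = simulate_read_pairs(
            refs,
            abund,
            n_pairs,
            error_model=error_model,
            seed=int(master.integers(2**31)),
            id_prefix=f"{sample}_",
        )

    truth_log: list[tuple[str, str, str]] = []
    if crosstalk_rate > 0:
        sample_pairs, truth_log = inject_crosstalk(
            sample_pairs, crosstalk_rate, seed=int(master.integers(2**31))
        )

    mapping_path = outdir / "mapping.txt"
    with open(mapping_path, "w") as fh:
        fh.write("#Sample\ttreatment\tstrand\tread1\tread2\n")
        for sample, pairs in sample_pairs.items():
            r1 = outdir / f"{sample}_R1.fastq"
            r2 = outdir / f"{sample}_R2.fastq"
            write_fastq((p[0] for p in pairs), r1)
            write_fastq((p[1] for p in pairs), r2)
            fh.write(f"{sample} {sample} + {r1} {r2}\n")
    oligos_path = outdir / "oligos.txt"
    with open(oligos_path, "w") as fh:
        fh.write(f"forward {FORWARD_PRIMER}\nreverse {REVERSE_PRIMER}\n")

    return {
        "references": refs,
        "sample_classes": sample_classes,
        "mapping": mapping_path,
        "oligos": oligos_path,
        "truth_log": truth_log,
    }


def generate_mock_dataset(
    outdir: str | Path,
    profiles: Sequence[str] = ("ECC", "EPC", "UEC"),
    n_replicates: int = 4,
    n_pairs: int = 5000,
    seed: int = 1,
    crosstalk_rate: float = 0.0,
    spec_template: MockCommunitySpec | None = None,
    error_model: ErrorModel = ErrorModel(),
    read_len: int = 300,
) -> dict:
    """Write a complete simulated study: paired FASTQ per sample, mapping.txt,
    oligos.txt, reference FASTA + taxonomy, expected-abundance truth table,
    and (when cross-talk is injected) the reassignment truth log.

    Returns a manifest dict with the references, per-sample expected class
    abundances, and file paths.  One reference set is shared by all samples;
    each profile gets one abundance vector shared by its replicates (the
    replicates differ only by sampling noise, emulating biological/technical
    replicates of one community design).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)

    base_spec = spec_template or MockCommunitySpec()
    refs = generate_references(base_spec, seed=int(master.integers(2**31)))

    profile_abund: dict[str, np.ndarray] = {}
    for profile in profiles:
        pspec = MockCommunitySpec(
            n_species=base_spec.n_species,
            profile=profile,
            strain_groups=base_spec.strain_groups,
            copy_numbers=base_spec.copy_numbers,
            low_abundance_tail=base_spec.low_abundance_tail,
            divergence=base_spec.divergence,
        )
        profile_abund[profile] = community_profile(
            pspec, seed=int(master.integers(2**31))
        )

    sample_pairs: dict[str, list] = {}
    sample_treatment: dict[str, str] = {}
    for profile in profiles:
        for rep in range(1, n_replicates + 1):
            sample = f"{profile}_{rep}"
            sample_treatment[sample] = profile
            sample_pairs[sample] = simulate_read_pairs(
                refs,
                profile_abund[profile],
                n_pairs,
                read_len=read_len,
                error_model=error_model,
                seed=int(master.integers(2**31)),
                id_prefix=f"{sample}_",
            )

    truth_log: list[tuple[str, str, str]] = []
    if crosstalk_rate > 0:
        sample_pairs, truth_log = inject_crosstalk(
            sample_pairs, crosstalk_rate, seed=int(master.integers(2**31))
        )

    mapping_path = outdir / "mapping.txt"
    with open(mapping_path, "w") as fh:
        fh.write("#Sample\ttreatment\tstrand\tread1\tread2\n")
        for sample, pairs in sample_pairs.items():
            r1 = outdir / f"{sample}_R1.fastq"
            r2 = outdir / f"{sample}_R2.fastq"
            write_fastq((p[0] for p in pairs), r1)
            write_fastq((p[1] for p in pairs), r2)
            fh.write(
                f"{sample} {sample_treatment[sample]} + {r1} {r2}\n"
            )

    oligos_path = outdir / "oligos.txt"
    with open(oligos_path, "w") as fh:
        fh.write(f"forward {FORWARD_PRIMER}\nreverse {REVERSE_PRIMER}\n")

    ref_fasta = outdir / "references.fasta"
    ref_tax = outdir / "references.tax"
    with open(ref_fasta, "w") as fa, open(ref_tax, "w") as tx:
        for ref in refs:
            fa.write(f">{ref.name}\n{ref.gene}\n")
            tx.write(f"{ref.name}\t{';'.join(ref.lineage)};\n")

    truth_path = outdir / "truth_abundances.tsv"
    with open(truth_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["sample", "species", "seq_class", "expected_fraction"])
        for sample, treatment in sample_treatment.items():
            for ref, frac in zip(refs, profile_abund[treatment]):
                w.writerow([sample, ref.name, ref.seq_class, f"{frac:.8g}"])

    crosstalk_path = None
    if truth_log:
        crosstalk_path = outdir / "crosstalk_truth.tsv"
        with open(crosstalk_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["read_id", "donor", "recipient"])
            w.writerows(truth_log)

    return {
        "references": refs,
        "profile_abundances": profile_abund,
        "sample_treatment": sample_treatment,
        "mapping": mapping_path,
        "oligos": oligos_path,
        "reference_fasta": ref_fasta,
        "reference_taxonomy": ref_tax,
        "truth_abundances": truth_path,
        "crosstalk_truth": crosstalk_path,
        "truth_log": truth_log,
    }
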