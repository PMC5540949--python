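"""Pair merging, primer trimming, expected-error filtering, pooling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ampliforge.io_formats import PrimerSet, SequenceRecord, reverse_complement, write_fastq
from ampliforge.read_prep import (
    FilterParams,
    MergeParams,
    Rejection,
    expected_errors,
    merge_pair,
    pool_samples,
    quality_filter,
    trim_primers,
)
from conftest import random_dna


def make_pair(template: str, fwd_len: int, rev_len: int, q: int = 35):
    """Error-free read pair from a template: forward prefix, reverse-complement suffix."""
    fwd = SequenceRecord(id="p", bases=template[:fwd_len], quals=(q,) * fwd_len)
    rev = SequenceRecord(
        id="p",
        bases=reverse_complement(template[len(template) - rev_len :]),
        quals=(q,) * rev_len,
    )
    return fwd, rev


class TestMergePair:
    def test_exact_overlap_reconstructs_template(self, rng):
        template = random_dna(rng, 200)
        fwd, rev = make_pair(template, 150, 150)  # overlap 100
        merged = merge_pair(fwd, rev, MergeParams())
        assert merged.bases == template
        assert len(merged.bases) == 200

    def test_overlap_below_minimum_rejected(self, rng):
        template = random_dna(rng, 201)
        fwd, rev = make_pair(template, 150, 150)  # overlap 99
        result = merge_pair(fwd, rev, MergeParams(min_overlap_len=100))
        assert result == Rejection("short_overlap")

    def test_too_many_mismatches_rejected(self, rng):
        template = random_dna(rng, 200)
        fwd, rev = make_pair(template, 150, 150)
        # overlap covers template[50:150] = rev read positions 50..149
        bases = list(rev.bases)
        for i in rng.choice(np.arange(55, 145), size=9, replace=False):
            bases[i] = [b for b in "ACGT" if b != bases[i]][0]
        rev = SequenceRecord(id="p", bases="".join(bases), quals=rev.quals)
        assert merge_pair(fwd, rev, MergeParams(max_diffs=8)) == Rejection(
            "too_many_diffs"
        )
        merged = merge_pair(fwd, rev, MergeParams(max_diffs=9))
        assert isinstance(merged, SequenceRecord)

    def test_posterior_quality_rule(self, rng):
        template = random_dna(rng, 200)
        # agreeing column: qualities add (capped at 45)
        fwd, rev = make_pair(template, 150, 150, q=30)
        merged = merge_pair(fwd, rev, MergeParams())
        overlap_quals = merged.quals[50:150]
        assert all(q == 45 for q in overlap_quals)  # min(30+30, 45)
        # disagreeing column: higher-quality base wins, q = max(2, |q1-q2|)
        fwd2 = SequenceRecord(id="p", bases=fwd.bases, quals=(40,) * 150)
        bases = list(rev.bases)
        i = 50  # inside overlap on the reverse read
        pos_on_template = 199 - i
        bases[i] = [b for b in "ACGT" if b != bases[i]][0]
        rev2 = SequenceRecord(id="p", bases="".join(bases), quals=(20,) * 150)
        merged2 = merge_pair(fwd2, rev2, MergeParams())
        assert merged2.bases[pos_on_template] == template[pos_on_template]
        assert merged2.quals[pos_on_template] == 20  # |40 - 20|

    def test_requires_qualities(self):
        a = SequenceRecord(id="a", bases="ACGT" * 50)
        b = SequenceRecord(id="a", bases="ACGT" * 50, quals=(30,) * 200)
        with pytest.raises(ValueError):
            merge_pair(a, b)

    @settings(deadline=None, max_examples=20)
    @given(st.integers(min_value=150, max_value=200), st.integers(min_value=0, max_value=10**6))
    def test_error_free_pairs_reconstruct_template_exactly(self, total_len, seed):
        """For any template length with sufficient overlap, merging inverts pair construction."""
        rng = np.random.default_rng(seed)
        template = random_dna(rng, total_len)
        fwd, rev = make_pair(template, 150, 150)
        merged = merge_pair(fwd, rev, MergeParams())
        assert isinstance(merged, SequenceRecord)
        assert merged.bases == template


class TestTrimPrimers:
    primers = PrimerSet(
        forward=("CCTACGGGAGGCAGCAG",), reverse=("GACTACHVGGGTATCTAATCC",)
    )

    def _read(self, insert: str) -> SequenceRecord:
        bases = (
            "CCTACGGGAGGCAGCAG" + insert + reverse_complement("GACTACAGGGGTATCTAATCC")
        )
        return SequenceRecord(id="r", bases=bases, quals=(35,) * len(bases))

    def test_mock_amplicon_yields_427nt_insert(self, rng):
        insert = random_dna(rng, 427)
        out = trim_primers(self._read(insert), self.primers, pdiffs=0)
        assert out.bases == insert
        assert len(out.bases) == 427
        assert len(out.quals) == 427

    def test_missing_reverse_primer(self, rng):
        bases = "CCTACGGGAGGCAGCAG" + random_dna(rng, 100)
        rec = SequenceRecord(id="r", bases=bases, quals=(35,) * len(bases))
        assert trim_primers(rec, self.primers, 0) == Rejection("no_reverse_primer")

    def test_pdiffs_threshold_semantics(self, rng):
        insert = random_dna(rng, 100)
        rec = self._read(insert)
        bases = list(rec.bases)
        bases[3] = "T" if bases[3] != "T" else "G"  # 1 mismatch in forward primer
        rec = SequenceRecord(id="r", bases="".join(bases), quals=rec.quals)
        assert isinstance(trim_primers(rec, self.primers, pdiffs=2), SequenceRecord)
        assert trim_primers(rec, self.primers, pdiffs=0) == Rejection(
            "no_forward_primer"
        )

    @pytest.mark.parametrize("base", ["A", "C", "T"])
    def test_iupac_H_matches_A_C_T(self, base):
        primers = PrimerSet(forward=("AHA",), reverse=("CCC",))
        bases = "A" + base + "A" + "TTTT" + "GGG"
        rec = SequenceRecord(id="r", bases=bases, quals=(35,) * len(bases))
        out = trim_primers(rec, primers, pdiffs=0)
        assert out.bases == "TTTT"

    def test_trimmed_length_identity(self, rng):
        insert = random_dna(rng, 200)
        rec = self._read(insert)
        out = trim_primers(rec, self.primers, 0)
        assert len(out.bases) == len(rec.bases) - 17 - 21


class TestQualityFilter:
    def test_ee_boundary_inclusive(self):
        rec = SequenceRecord(id="r", bases="A" * 100, quals=(20,) * 100)
        # EE = 100 * 10^-2 = 1.0 exactly
        assert expected_errors(rec.quals) == pytest.approx(1.0)
        out = quality_filter(rec, FilterParams(trunclen=100, maxee=1.0))
        assert isinstance(out, SequenceRecord)
        assert quality_filter(rec, FilterParams(trunclen=100, maxee=0.5)) == Rejection(
            "maxee_exceeded"
        )

    def test_short_read_rejected(self):
        rec = SequenceRecord(id="r", bases="A" * 99, quals=(40,) * 99)
        assert quality_filter(rec, FilterParams(trunclen=100)) == Rejection("too_short")

    def test_truncation_to_exact_length(self):
        rec = SequenceRecord(id="r", bases="A" * 150, quals=(40,) * 150)
        out = quality_filter(rec, FilterParams(trunclen=100, maxee=1.0))
        assert len(out.bases) == 100 and len(out.quals) == 100

    def test_ee_monotone_in_prefix_and_maxee(self, rng):
        quals = tuple(int(q) for q in rng.integers(2, 41, 200))
        ees = [expected_errors(quals[:k]) for k in range(1, 201)]
        assert all(b >= a for a, b in zip(ees, ees[1:]))
        # lowering maxee never increases the pass count
        recs = [
            SequenceRecord(
                id=f"r{i}",
                bases="A" * 120,
                quals=tuple(int(q) for q in rng.integers(2, 41, 120)),
            )
            for i in range(50)
        ]
        def n_pass(maxee):
            return sum(
                isinstance(quality_filter(r, FilterParams(trunclen=100, maxee=maxee)), SequenceRecord)
                for r in recs
            )
        counts = [n_pass(m) for m in (2.0, 1.0, 0.5, 0.25)]
        assert counts == sorted(counts, reverse=True)


class TestPoolSamples:
    def _write_sample(self, tmp_path, name, pairs):
        r1 = tmp_path / f"{name}_1.fastq"
        r2 = tmp_path / f"{name}_2.fastq"
        write_fastq([p[0] for p in pairs], r1)
        write_fastq([p[1] for p in pairs], r2)
        return r1, r2

    def test_labels_and_stats_reconcile(self, tmp_path, rng):
        from ampliforge.io_formats import MappingEntry

        primers = PrimerSet(forward=("CCTACGG",), reverse=("GACTACA",))
        template = "CCTACGG" + random_dna(rng, 150) + reverse_complement("GACTACA")
        pairs = [make_pair(template, 120, 120) for _ in range(10)]
        entries = []
        for name in ("S1", "S2"):
            r1, r2 = self._write_sample(tmp_path, name, pairs)
            entries.append(MappingEntry(name, "grp", "+", str(r1), str(r2)))
        reads, stats = pool_samples(
            entries,
            primers,
            MergeParams(min_overlap_len=50),
            FilterParams(trunclen=100, maxee=1.0),
        )
        assert len(reads) == 20
        assert {r.sample for r in reads} == {"S1", "S2"}
        for s in ("S1", "S2"):
            assert stats.input[s] == 10 and stats.passed[s] == 10

    def test_empty_sample_has_stats_row(self, tmp_path):
        from ampliforge.io_formats import MappingEntry

        (tmp_path / "e_1.fastq").write_text("")
        (tmp_path / "e_2.fastq").write_text("")
        primers = PrimerSet(forward=("AAAA",), reverse=("TTTT",))
        reads, stats = pool_samples(
            [MappingEntry("E", "g", "+", str(tmp_path / "e_1.fastq"), str(tmp_path / "e_2.fastq"))],
            primers,
        )
        assert reads == [] and stats.input["E"] == 0

    def test_unreadable_file_names_sample(self, tmp_path):
        from ampliforge.io_formats import MappingEntry

        primers = PrimerSet(forward=("AAAA",), reverse=("TTTT",))
        with pytest.raises(OSError, match="S_bad"):
            pool_samples(
                [MappingEntry("S_bad", "g", "+", str(tmp_path / "nope.fastq"), None)],
                primers,
            )
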