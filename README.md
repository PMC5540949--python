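# ampliforge

A self-contained pipeline for 16S rRNA gene amplicon sequencing data:
paired-end read merging, primer trimming, expected-error quality filtering,
greedy OTU clustering with chimera screening, naive-Bayes taxonomy with
bootstrap confidence, alpha/beta diversity with UPGMA trees, PCoA/NMDS
ordination, AMOVA/HOMOVA hypothesis tests, and OTU co-occurrence networks —
plus a mock-community read simulator that lets every stage be validated
end-to-end against known community composition, with no external databases
or downloads.

It is aimed at microbial ecologists who want push-of-a-button processing of
demultiplexed MiSeq amplicon runs, and at method developers who need a
transparent, fully scriptable reference implementation of the standard
OTU-based workflow.

## The method

Starting from per-sample FASTQ pairs, the pipeline applies a fixed stage
order:

1. **Merging.** Each pair is merged by aligning the forward read against the
   reverse-complement of the reverse read over every ungapped offset; the
   best-scoring overlap (matches − mismatches) is kept. Pairs whose best
   overlap is shorter than `minoverlen` (default 100 nt) or has more than
   `maxdiffs` (default 8) mismatches are discarded. In the overlap a
   posterior base and quality are derived per column: agreeing bases get
   Q₁+Q₂ (capped at 45); at disagreements the higher-quality base wins with
   quality max(2, |Q₁−Q₂|).
2. **Primer trimming.** Reads must carry the forward primer at the 5′ end
   and the reverse-complemented reverse primer at the 3′ end (IUPAC-aware,
   ≤ `pdiffs` mismatches each); both are removed.
3. **Quality filtering.** Reads are truncated to `trunclen` (default 250 nt)
   and discarded when the expected error count EE = Σ 10^(−Q/10) over the
   truncated read exceeds `maxee` (default 1.0), or when shorter than the
   truncation length.
4. **OTU inference.** Pooled reads are dereplicated; singletons are set
   aside; unique sequences are visited in decreasing abundance and greedily
   clustered at 97% identity (global alignment, free terminal gaps), with a
   two-parent crossover chimera test applied to candidates that match no
   centroid. All reads — including former singletons — are then mapped back
   to the best centroid at ≥ 97% identity to form the sample × OTU table,
   which is also rarefied to a common depth.
5. **Taxonomy.** Centroids are classified with a word-set naive-Bayes
   classifier (k = 8) against a pluggable reference; per-rank confidence is
   the agreement fraction over 100 bootstrap resamples of one eighth of the
   query's words, with ranks below 80% reported "unclassified".
6. **Diversity and tests.** Alpha indices (sobs, chao, ace, jackknife,
   shannon, npshannon, simpson), rarefaction and rank-abundance curves;
   Jclass/Jest/ThetaYC/Bray-Curtis dissimilarities; UPGMA sample trees
   (Newick); PCoA and non-metric MDS; AMOVA and HOMOVA permutation tests
   for group location and dispersion.
7. **Networks.** OTUs below 0.1% overall abundance or present in a single
   sample are dropped; Spearman (or Pearson) correlations between the
   remaining OTUs are thresholded at |r| ≥ 0.6 and P ≤ 0.01 and exported as
   a GEXF graph for Gephi.

The built-in simulator generates mock communities in three designs — equal
cell numbers (ECC), equal protein mass (EPC), and an uneven community
spanning roughly four orders of magnitude down to ~0.01% (UEC) — from
synthetic ~1,500 nt 16S genes whose primer-delimited inserts are 427 nt and
diverge by a controlled amount between species, with groups of strains that
are indistinguishable at the 16S level. Expected abundances are corrected by
per-species 16S copy number, substitution errors follow a position-dependent
Illumina-like model with self-consistent quality scores, and index hopping
("cross-talk") between samples can be injected at a configurable rate with
a read-level truth log.

## Worked example

```python
from ampliforge.simulate import generate_mock_dataset
from ampliforge.pipeline import PipelineConfig, run_pipeline

man = generate_mock_dataset("demo", profiles=("ECC", "UEC"),
                            n_replicates=4, n_pairs=1000, seed=42)
cfg = PipelineConfig(analysis_name="demo",
                     mapping=str(man["mapping"]), oligos=str(man["oligos"]),
                     reference_fasta=str(man["reference_fasta"]),
                     reference_taxonomy=str(man["reference_taxonomy"]),
                     seed=1)
res = run_pipeline(cfg, "demo/out")
print(f"OTUs inferred: {len(res.otu_table.otus)}")
am = res.tests["amova_braycurtis"]
print(f"AMOVA (Bray-Curtis): F = {am.statistic:.2f}, p = {am.p_value:.3f}")
```

prints

```
OTUs inferred: 17
AMOVA (Bray-Curtis): F = 263.41, p = 0.025
```

The simulated community holds 21 species in 17 distinguishable 16S sequence
classes (three multi-strain groups collapse), and exactly 17 OTUs are
recovered. The AMOVA pseudo-F of 263 says nearly all squared Bray-Curtis
distance lies between the ECC and UEC groups; with 4 + 4 samples the
permutation p-value of 0.025 is close to the smallest attainable for this
design. The results directory also holds, e.g., per-sample alpha diversity
(`alpha_diversity.rarefied.tsv`):

```
sample  sobs       chao       ace        jackknife  shannon   npshannon  simpson
ECC_1   17.000000  17.000000  17.000000  17.000000  2.560049  2.560698   0.092522
```

— all 17 OTUs observed; Shannon 2.56 is a little under ln 17 ≈ 2.83 because
copy-number weighting makes even the "equal-cell" community moderately
uneven — and per-OTU taxonomy with bootstrap percentages
(`taxonomy.tsv`):

```
otu    size  taxonomy
OTU_1  1491  Bacteria(100);Phylum_1(100);Class_1(100);Order_1(100);Family_1(100);Agrobacterium(100)
```

The same pipeline is available from the shell:

```sh
ampliforge simulate -o demo --profiles ECC,UEC --replicates 4 --pairs 1000 --seed 42
ampliforge run -an demo -map demo/mapping.txt -oligos demo/oligos.txt -o demo/out --seed 1
ampliforge crosstalk demo/out/otu_table.shared -o demo/crosstalk.tsv
```

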