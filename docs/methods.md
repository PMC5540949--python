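# Methods

This note records the models, numerical choices and known limitations behind
ampliforge, at the level of detail a maintainer or reviewer needs. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Read preparation

**Pair merging.** The forward read is aligned to the reverse-complement of
the reverse read by exhaustive scan over every ungapped offset (overlap
lengths 1 … min(len₁, len₂)); the score is matches − mismatches, ties broken
toward the longer overlap, and `N` counts as a mismatch against everything
including another `N`. The best overlap is found first and only then
classified, so a pair whose true overlap is 99 nt is reported
`short_overlap` (below the 100 nt minimum) rather than as a noisy longer
overlap. Exhaustive scan is exact and affordable at amplicon scale
(~300 offsets × one vectorized comparison per pair); production mergers use
heuristics for throughput we do not need.

**Posterior qualities.** The published description of merging says only that
a single base and quality is derived per overlap column. We use: agreeing
bases → Q = min(Q₁+Q₂, 45); disagreeing → keep the higher-quality base with
Q = max(2, |Q₁−Q₂|). This mirrors posterior-error mergers in spirit; the sum
rule is the independence approximation on error probabilities, and the cap
at 45 keeps scores in the Phred+33 printable range the rest of the pipeline
assumes. Quality filtering operates on these posterior qualities — they are
what exists after merging.

**Primer matching** is anchored: the forward primer at position 0, the
reverse-complemented reverse primer flush with the read end, each compared
IUPAC-aware with at most `pdiffs` mismatches and the best-matching primer
chosen per direction. No floating search window: merged amplicons start and
end at the primers by construction.

**Defaults.** `minoverlen` 100 and `maxdiffs` 8 are the benchmark
configuration; `maxee` 1.0, `trunclen` 250, `pdiffs` 2 and the 97%
similarity cutoff are package defaults chosen as the values practitioners
commonly run (one expected error per read; a truncation length safely inside
a 427 nt insert; a small primer-mismatch allowance). Every resolved default
is written to the run log.

## OTU inference

**Identity.** `pairwise_identity` is matches / alignment-columns of a global
alignment with free terminal gaps (match +1, mismatch −1, gap −2), terminal
gap columns excluded — so a sequence is 100% identical to itself plus an
overhang. Two shortcuts, both documented in the code: equal-length pairs
with ungapped identity ≥ 0.9 take the ungapped value (for
substitution-dominated amplicon divergence the optimal alignment is then
gap-free); and inside the clustering/mapping loops, equal-length pairs more
than 0.05 *below* the decision cutoff skip the full alignment, since a
gapped alignment cannot plausibly rescue them across the cutoff. After
fixed-length truncation every pipeline read is the same length, so these are
the hot paths; the exact alignment handles everything else.

**Greedy clustering.** Unique sequences (singletons removed) are visited by
decreasing abundance, ties broken lexicographically on the sequence — this
single rule makes the whole stage deterministic. Each unique joins the
best centroid at identity ≥ the cutoff, else is tested as a chimera, else
founds a new OTU.

**Chimera model.** A deliberately simple two-parent single-crossover test:
a query is chimeric when some prefix matches one parent at ≥ 0.99 identity
and the complementary suffix matches a different parent at ≥ 0.99, parents
must be ≥ 2× the query's abundance, and no single parent may reach the
clustering cutoff on its own. Crossovers are scanned exhaustively via
cumulative match counts (O(L) per parent pair). The thresholds (0.99, 2.0)
are configuration with defaults; this is not a reimplementation of any
published chimera detector, and reference-based detection is out of scope.

**Read mapping.** All quality-passed reads — including members of discarded
singleton uniques — are mapped to the best centroid at ≥ cutoff identity
(singletons are excluded only from centroid formation, where they would
seed error OTUs). The `map_singletons` switch disables this.

**Rarefaction** subsamples each sample to a common depth without replacement
via the multivariate hypergeometric distribution; samples below the depth
are dropped with a warning. The default depth is the smallest sample total.

## Taxonomy

A word-set (presence, not count) naive-Bayes classifier: word prior
P(w) = (n(w)+0.5)/(N+1) over reference sequences, genus conditional
P(w|g) = (m(w,g)+P(w))/(M_g+1), query score Σ log P(w|g). Confidence per
rank is the fraction of 100 bootstrap resamples of ⌊W/8⌋ query words whose
winning genus lies under that rank's taxon; ranks below 0.80 report
"unclassified". k = 8, the subsampling fraction, bootstrap count and cutoff
are all configurable. The reference database is pluggable (FASTA plus a
tab-separated `id → Domain;…;Genus;` file); the test suite ships only
synthetic references, and no external database is required anywhere.

## Diversity

Alpha formulas are the Mothur-compatible definitions (chao1 with the +1
bias correction, ACE with rare cutoff 10, first-order jackknife, natural-log
Shannon, Chao–Shen coverage-adjusted npshannon, the unbiased Simpson
Σnᵢ(nᵢ−1)/(N(N−1))). Degenerate cases: a single-OTU sample has shannon 0 and
simpson 1; ACE falls back to chao1 when all rare reads are singletons (its
coverage term is undefined there).

Beta measures: jclass = 1 − shared/union on membership; thetayc on relative
abundances; braycurtis on counts; jest replaces the observed richnesses in
the Jaccard formula with chao1 estimates, estimating shared richness by
chao1 on the pairwise-minimum counts of shared OTUs (the estimator family
for shared richness is not uniquely fixed in the literature; this choice is
documented rather than claimed canonical).

UPGMA uses average linkage on the condensed matrix (scipy), node heights =
half the merge distance, which makes the tree ultrametric by construction.
PCoA is classical scaling (Gower double-centering of −d²/2, eigh);
negative-eigenvalue axes are dropped. NMDS wraps scikit-learn's non-metric
SMACOF (20 random starts, 300 iterations, tol 1e-6) and reports Kruskal
stress-1 computed against the isotonic regression of configuration
distances on observed ranks; an all-zero distance matrix (all samples
identical under the measure) embeds as a single point with stress 0.

AMOVA uses the pseudo-F on squared distances: SS_within = Σ_g Σ_{i<j∈g}
d²/n_g, SS_total = Σ_{i<j} d²/N, SS_among = total − within,
F = (SS_among/(k−1))/(SS_within/(N−k)); when SS_within is exactly 0 the
statistic is +∞ for separated groups and 0 for an all-zero matrix. HOMOVA is
the Bartlett-style statistic (Σdf)·ln(pooled) − Σ df·ln(SS_w/df) on
within-group dispersions, zero when dispersions are equal. Both p-values are
label-permutation tests reported as (1 + #more-extreme)/(1 + n_perm), which
can never be zero. Note the permutation granularity: with 4 + 4 samples the
original partition recurs in ~3% of permutations, so p ≤ 0.01 is attainable
only with more samples or more groups.

## Networks

The infrequent-OTU filter keeps OTUs at ≥ 0.1% overall relative abundance
present in ≥ 2 samples; correlations are then computed on absolute counts
(on a rarefied table, counts and relative abundances are proportional, so
the distinction is immaterial there). Spearman is Pearson on midranks;
two-sided p from t = r√((n−2)/(1−r²)) on n−2 df. Edges require |r| ≥ 0.6
and p ≤ 0.01 with no multiple-testing correction by default (a
Benjamini–Hochberg option exists but is off); negative correlations are
kept by magnitude, with a `positive_only` switch for the strictly positive
reading. Constant abundance vectors make r undefined; such pairs are
skipped with a warning.

## Simulator

The simulator emulates a multiplexed MiSeq amplicon run of mock communities
with known composition:

- **References**: a random 427 nt ancestor insert is mutated independently
  per sequence class (star topology) at the divergence rate (default 0.06
  per branch) and rejection-sampled until every between-class insert
  identity is below 1 − divergence; classes are flanked by exact primer
  sites and shared random padding to ~1,500 nt. Strain groups (default
  2 + 2 + 3 of 21 members, giving 17 classes) share identical genes,
  emulating species indistinguishable at the 16S level. The shared flanks
  mean whole genes stay similar while the amplified insert separates
  classes — as with real conserved/variable rRNA structure.
- **Designs**: ECC weights species by equal cells, EPC by cells ∝ 1/protein
  mass with mass ~ lognormal(0, 0.5) (no per-species masses are published;
  σ = 0.5 gives the few-fold protein-size spread typical of bacteria), UEC
  by a geometric ladder spanning 10^3.5 placed so the post-normalization
  minimum sits near 0.01%. All designs multiply by per-species 16S copy
  number (default uniform 1–10) and renormalize, because amplicon reads
  sample gene copies, not cells.
- **Reads**: 2 × 300 nt pairs from the 465 nt primered amplicon;
  substitution-only errors with per-position probability rising linearly
  from 0.001 (5′) to 3 × 0.001 (3′), and Phred scores equal to
  round(−10 log₁₀ p) by construction. No indels and no PCR chimeras are
  simulated — chimera tests construct chimeric sequences directly — so
  passing the end-to-end tests demonstrates correct behavior under
  substitution noise, not robustness to indel-rich platforms.
- **Cross-talk**: each read is reassigned to a uniformly random other sample
  with the configured probability (default experiments use 2%, the order of
  contamination reported for MiSeq runs), with an exact read-level truth
  log.

What the simulator does **not** emulate: primer bias and taxon dropout, cell
lysis/extraction bias, indels and homopolymer errors, quality-score
miscalibration, chimera formation, and real SILVA-scale reference diversity.
End-to-end recovery results on simulated data are therefore a correctness
check of the pipeline's algorithms, not a claim about accuracy on real
communities.

## Benchmark scale and determinism

The validation study in `scripts/acceptance.py` uses 3 designs × 4
replicates × 5,000 pairs — enough that every class expected at ≥ 0.1% is
drawn hundreds of times while a full run stays in the minutes range on one
CPU — plus a 3-sample disjoint-community cross-talk experiment (6,000 pairs
per sample) and a 200-replicate AMOVA null calibration. One CLI/config seed
feeds an `numpy` `default_rng` from which all stage seeds (rarefaction,
classifier bootstraps, NMDS starts, permutations) are drawn, so identical
configs reproduce byte-identical tabular outputs.

## Known limitations

- The mapping file's `strand` column is recorded but never acted on; reads
  are assumed to be in forward orientation (the file format does not define
  the column's semantics).
- Classification on the unrarefied table; diversity on both raw and
  rarefied tables, with ordination/tests on the rarefied one.
- UniFrac and parsimony tests are intentionally absent: they need an OTU
  phylogeny this pipeline does not build.
- Jest's shared-richness estimator is a documented choice (see above).
- The screened identity shortcut assumes substitution-dominated divergence;
  data with frequent long indels would need the `pairwise_identity` exact
  path throughout.
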