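# Methods

This note records the models, numerical choices and known limitations behind
`spotseq`. It covers what each component assumes, why the defaults are what
they are, and what the synthetic-data tests do and do not demonstrate about
real data.

## Array model and barcode decoding

A barcode whitelist is a set of 18 nt sequences whose *true* minimum pairwise
Hamming distance is recomputed at construction by brute force. The default
generator enforces distance ≥ 5: with a 2-mismatch decoding budget `k = 2`,
separation `2k + 1 = 5` makes decoding provably unambiguous — any read within
2 substitutions of one barcode is at least 3 from every other. The array
itself only fixes the barcodes' *placement*; the published grid is 33 × 35 =
1,155 spots at 200 µm pitch with 1,007 unique interior barcodes. The exact
frame geometry reconciling those two numbers is not public, so the default
layout marks the full perimeter (132 spots) plus four 2 × 2 interior blocks
adjacent to the corners (16 spots) as frame, which reproduces the 1,007
count; any other geometry can be supplied as a TSV.

Decoding uses pigeonhole candidate retrieval: the barcode is cut into three
disjoint 6-mers, and a read with ≤ 2 substitutions must match at least one
segment of its source exactly, so an exact-match index over segments returns
a candidate set guaranteed to contain every admissible hit. Candidates are
then ranked by exact Hamming distance (an `N` mismatches every base,
including another `N`). Ties at the minimal distance return UNASSIGNED rather
than an arbitrary pick — a decoder must not manufacture crosstalk. The same
tie contract is implemented twice (k-mer path and full scan) and the two are
checked against each other and against an independent pure-python oracle in
the tests.

The UMI is validated against the semi-randomized template `WSNNWSNNV`
(12,288 valid 9-mers). Invalid UMIs are discarded and tallied, never
error-corrected: at a per-base error rate worth worrying about, correction
would merge real molecules more often than it rescues reads.

## Counting

Gene assignment in simulations is exact-substring matching of the 121 nt
mate against a toy transcriptome (one 500 nt transcript per gene), with
reads present in two or more transcripts flagged ambiguous and discarded —
the conservative analogue of intersection-based counting. Real alignments
can be imported as a `(read_id, gene_id)` table and flow through the same
filters. Reads on ribosomal-flagged genes and on a named-removal list
(default `{MALAT1}`, a known self-priming artefact) are dropped before
counting.

Molecules are counted per (gene, barcode) as connected components of the
UMI graph joining sequences at Hamming distance ≤ 1 (threshold exposed;
0 = distinct sequences). Single-linkage components are the simplest reading
of cluster-based duplicate removal; the directional-network refinement that
weights clusters by read support is deliberately out of scope. Collapse is
permutation- and duplication-invariant, and monotone: adding reads never
decreases a count.

## Simulator

The generator's defaults are the study conditions, chosen once:

- **Placement.** Sorted mode occupies each interior spot independently with
  probability 0.47 (the reported indexed-sorting efficiency); occupied
  multiplicity is 1/2/3/4 cells with probability 0.75/0.15/0.06/0.04 so that
  background, single, doublet and cluster groups all occur. Smear mode
  scatters a fixed cell count uniformly. Centroids jitter ≤ 30 µm from the
  spot centre, inside the 50 µm colocalization radius.
- **Expression.** Per-gene means on a lognormal grid (log2 mean 2.0, sd
  1.2), negative-binomial counts with dispersion θ = 2 and Bernoulli
  dropout 0.3 — typical of shallow single-cell libraries and reproducing
  the qualitative CV-versus-mean decay (CV² = 1/µ + 1/θ). Expression
  programs up-regulate 20-gene blocks by 2 log2-fold for clustering tests.
  Ribosomal, mitochondrial and MALAT1-like decoy genes get high means so
  the filters are exercised.
- **Background.** Empty spots draw cell-free molecules from the pooled mean
  profile, with the total scaled so the expected background share of all
  molecules is 5%.
- **Reads.** Each molecule draws a UMI uniformly from the valid space
  (collisions allowed) and is sequenced 1 + Poisson(0.5) times. R1 =
  barcode + UMI + oligo-dT filler (31 nt), R2 = a random 121 nt transcript
  substring. Substitution errors are iid per base; barcode swaps move a
  read to a uniformly random other barcode and are flagged in the truth
  table.

Ground truth is kept at three levels (per-spot, per-cell, per-read with
molecule ids). Because UMIs can collide, "the true matrix" for end-to-end
comparison is defined through the collision-aware oracle
(`expected_dedup_counts`): molecules whose UMIs land in one Hamming cluster
are merged exactly as any decoder must merge them. The raw drawn-molecule
matrix is also kept and equals the per-read truth aggregated by molecule id.

What the simulator does **not** model: PCR amplification bias, quality-score
realism (constant qualities), cDNA diffusion between spots, gene-length or
GC effects, doublet expression interactions beyond additivity, and any
realistic transcriptome homology (ambiguity is exercised only via explicit
shared subsequences in tests). Passing the synthetic suite therefore
demonstrates algorithmic correctness and statistical calibration, not
robustness to alignment artefacts in real libraries.

## QC statistics

Saturation curves subsample reads **without replacement** (the
with/without-replacement choice is not documented for the original curves;
without replacement matches the finite-library interpretation) and re-run
UMI collapse per depth. The dropout rate between profiles a and b is
`100 · |expressed(b) \ expressed(a)| / |expressed(b)|`, asymmetric by
construction, with "expressed" meaning a post-collapse count > 0. CV-vs-rank
uses pre-log normalized values with a rolling window of 25. The library
filter keeps single-cell libraries with raw reads strictly above the cohort
mean ("above" read strictly; `inclusive` switches to ≥). The background
gene list is the top 50 by total background-spot counts, excluding
housekeeping genes.

## Crosstalk

Only non-orthologous genes carry species information, so declared ortholog
pairs are excluded before counting. Misassignment is wrong-species
species-specific reads over total species-specific reads (× 100), per
barcode and aggregated; raw read counts (pre-collapse) are used, matching
how purity is assessed. Note that a nominal swap rate `s` in a 50/50 mix
yields measured misassignment ≈ `s/2` — a read swapped onto a same-species
barcode is undetectable — so recovery is validated against the realized
truth from the per-read table, not against the nominal rate. Species calling
cuts an average-linkage tree on 1 − Pearson distances of species-specific
profiles into two clusters and labels each by majority signal; a majority
below 60% yields UNRESOLVED rather than a guess.

## Normalization and differential expression

Counts are scaled per barcode to a fixed total (200,000 for cell lines,
10,000 for small lymphocytes whose libraries are an order of magnitude
shallower), then log2(x + 1). Variable genes are ranked by CV of the pre-log
values; the abundance filter keeps genes with pre-log mean ≥ 6.5 (TP10K
scale, "at least" read inclusively) and mean-centres the log matrix.

PC significance is a permutation (parallel-analysis / jackstraw-style)
test: each permutation shuffles every gene independently across cells,
destroying covariance while preserving marginals; the p-value of component
i is `(1 + #{perm λᵢ ≥ observed λᵢ}) / (n_perm + 1)` and the result is the
leading run with p < α (default 0.01, 100 permutations — the smallest
resolvable p is then 1/101 < 0.01). On planted rank-2 data (100 × 500,
singular values 80/60 against a Marchenko–Pastur noise edge near 32) this
recovers exactly 2 components across seeds; on pure noise it reports 0.

The differential-expression test is a two-part likelihood-ratio test per
gene: detection (value > 0 on the log2(x+1) scale) ~ Bernoulli(π), positive
values ~ Normal(µ, σ²) with σ² pooled across clusters for stability in
small clusters. Null: shared (π, µ); alternative: cluster-specific. Λ =
2(ℓ_alt − ℓ_null) is referred to χ² with 2(K−1) df; a component is dropped
— with matching df reduction — when it is unidentifiable (constant
detection, or fewer than two clusters with positive observations). Raw
p-value thresholds (0.001 for DE, 0.01 for PCs) are used without multiple-
testing correction, matching the analysis style this pipeline reproduces.
Monte-Carlo calibration under the exact generating model gives type-I error
indistinguishable from nominal (0.05 ± 3 SD at 2,000 genes) and power > 99%
for a 1 log2-unit shift at 100 cells/cluster; real data deviating from
log-normal positives will inflate or deflate these rates.

Hierarchical clustering uses 1 − Pearson distance with average linkage
(linkage configurable; the original choice is undocumented). t-SNE runs on
the significant PC scores with perplexity 30 and 10,000 iterations by
default, seeded.

## Cell cycle

Candidate genes for the five phases are filtered by Pearson r > 0.3 against
their phase's mean candidate profile. Scores are normalized in two steps —
the published description says only "two steps", so the Macosko-style
double z-score is adopted and documented as such: (1) z-score each gene
across cells, average within each phase; (2) z-score each phase's scores
across cells; then the five scores are centred within each cell, making them
relative phase preferences (per-cell mean 0). The cycling call threshold
(max score ≥ 1.0 on the z scale) is not published; 1.0 is the default, and
the null false-call rate is bounded by the tail of the max of five
correlated z-like scores (≤ 5·Φ̄(1), measured far lower on null
simulations). Phase-program strength in the recovery simulations is +3 SD
on 60 genes/phase, chosen a priori so that (by the normal-tail analysis)
cycling cells score ≫ 1 while the null max stays below 1 with probability
≈ 0.999 at that gene count. A group-wise mode redoes both z-steps within
each group (e.g. patient subset) for subset-specific scores.

## Problem sizes

Test and acceptance simulations run on reduced arrays (9 × 9 and 14 × 14
grids, 40–160 genes/species, 20k–80k reads) — sizes at which every check
including the exhaustive oracles completes in seconds while the asymptotics
they probe (binomial error tails, χ² calibration, eigenvalue separation)
are already in force. The decoder checks use the full 1,007-barcode
whitelist.
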