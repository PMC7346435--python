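# Methods

## Expression calls

A gene is **expressed** in a dataset when its TPM is strictly greater than a
threshold (default 1.0) in *every* replicate. The strict inequality matters
only for genes sitting exactly on the threshold; it is exposed as a
parameter. **Highly expressed** genes are found among the expressed ones:
within each replicate, z-scores are computed over the log TPM of the
expressed genes (so no pseudocount is needed — expressed genes have
TPM > 1), and a gene qualifies when its z exceeds 1.5 in at least
`min_replicates` replicates. The 2-of-3 default generalises to
`ceil(2/3 · n)` for other designs.

Numerical choices: the log base cancels inside a z-score, so only the logged
values themselves depend on it (log2 by default). The standard deviation is
the sample SD (ddof = 1), switchable to the population SD; with hundreds to
thousands of expressed genes the two are indistinguishable in practice. A
replicate with zero SD over the expressed genes is degenerate and raises.

## Quantile assignment and mapping

Expressed genes are ranked by mean TPM across replicates (arithmetic mean;
the ranking statistic is a parameter of interpretation, not of the data
model) with ties broken by gene ID, and split into `n` contiguous blocks
(default 10). When the count is not divisible by `n` the earlier
(higher-expression) quantiles take the extra genes; block sizes therefore
differ by at most one. Both rules make the assignment fully deterministic.

The mapping between two datasets is an `(n+2) × (n+2)` table. The counting
unit in the `n × n` grid is the **high-confidence ortholog pair**: a
many-to-many family contributes one count per pair, which keeps the grid an
honest cross-tabulation of the orthology relation. Because "how many genes"
is a different question from "how many pairs", unique-gene summaries per
category (grid / unexpressed-partner / no-ortholog) are computed alongside.
Row/column `n+1` collects genes whose high-confidence orthologs are all
unexpressed on the other side; `n+2` genes with no high-confidence ortholog
at all (a gene with only low-confidence orthologs counts here). In
same-species mode genes are matched by identity and `n+1` holds the genes
unique to one dataset.

## Region enrichment

Over the `N` pairs in the grid, a rectangular region is tested by Fisher's
exact test on the 2 × 2 table of region-row × region-column membership.
This choice is consistent with quoting a uniform expectation of `N/n²` per
cell: under independence of row and column membership the expected count of
a single cell with 1/n of each margin is exactly that. Two-sided p-values
are the default; the one-sided (`greater`) alternative is available since
over-representation is usually the question. The uniform expectation
`N · |rows| · |cols| / n²` is reported alongside the Fisher odds ratio.

## Highly concordant orthologous genes

A query-side (human) gene qualifies for one comparison when **any** of its
high-confidence expressed ortholog pairs lands in the top `k × k` block
(k = 3 of 10 deciles: top 30 % in both species). Genes qualifying in every
query dataset form the concordant set; the overlap percentage is defined
relative to the smaller per-dataset set. Ranking uses the grand mean of raw
TPM over every replicate of every dataset; in datasets that do not carry the
gene itself the expressed high-confidence orthologs stand in, averaged
gene-level first so a large ortholog family is not over-weighted. Genes
whose ranking pooled more than one ortholog are flagged in the output.

## Sample similarity

The signal matrix (log TPM of the chosen gene set × samples) is
row-normalized (gene-wise mean 0, SD 1, sample SD convention) before
clustering. UPGMA uses the Pearson distance `d = 1 − r` (not `(1 − r)/2`;
the halving rescales heights but cannot change the topology). PCA is the
centered SVD of the samples. ANOSIM and adonis run on Euclidean distances
over the retained PC scores — all components by default, in which case the
distances equal centered Euclidean distances on the raw matrix and the PCA
step is a faithful rotation, not a filter.

ANOSIM follows Clarke: `R = (r̄_between − r̄_within)/(M/2)` on the ranks of
all `M = n(n−1)/2` pairwise distances. adonis partitions the squared
distances Gower-style: `R² = 1 − SS_within/SS_total` with
`SS_total = Σ d²/n`. Both p-values count label assignments whose statistic
reaches the observed one. When the number of distinct label orderings is at
most 10,000 (e.g. 20 for 3+3, 1680 for 3+3+3) the tests enumerate all of
them — the p-value is then exact and its floor is 1/enumerated; otherwise
999 seeded permutations are used with the `(1 + count)/(B + 1)` estimator.

## Over-representation and the EASE score

One-sided hypergeometric tail `P(X ≥ hits)` for Fisher; the EASE score
recomputes it after removing one hit (`max(hits − 1, 0)`), so single-gene
categories can never be significant and small categories are penalised —
the conservative construction popularised by the DAVID tool. Bonferroni
correction over the sets with at least one hit is reported as a separate
column; the default significance criterion is raw EASE ≤ 0.05, with the
corrected criterion available by flag. The default universe is the union of
the collection's genes and the analysed list, and is configurable because
the right background depends on how the list was derived.

## Synthetic studies

The generator emulates the statistical shape of the three-dataset oocyte
design: 24,000/26,000 genes, three replicates, zero-TPM fractions
0.75/0.65/0.45 and sub-1-TPM fractions 0.87/0.80/0.61 (H1/H2/ZF), an
orthology relation covering 60 % of the query species' protein-coding genes
with ~32 % extra many-to-many edges and a 53 % high-confidence rate.

Model: every gene has a latent standard-normal score. Ortholog pairs are
coupled by a Gaussian copula with correlation `concordance_rho` (default
0.7), raised by `concordance_bias_top` (default 0.2) when the driving gene
lies in the top expression stratum (top 20 %) — the analysis is rank-based,
so only the copula, not the marginal, matters for concordance. Same-species
datasets share their species latent with pairwise correlation `dataset_rho`
(default 0.9, giving the high cross-human expressed-set overlap seen in real
data). Latent scores are scaled to log2 expression and exponentiated;
structural zeros take the configured fraction of genes, preferentially the
lowest-latent ones (jittered so the boundary is soft); replicates receive
multiplicative log-normal noise with CV 0.3; every replicate is renormalised
to 10⁶ TPM, reproducing the compositional constraint of TPM data.

The log2 spread per dataset is **calibrated numerically** (bisection on the
realized latent draws) so the fraction of non-zero genes below 1 TPM matches
the configured value exactly in the noiseless matrix. A closed-form
log-normal calibration is badly biased here: with spreads of ~3–5 log2
units the normalizing sum is dominated by the few largest genes and sits far
from its expectation, and any planted genes distort it further; calibrating
against the realized draws side-steps both problems.

Planted signal: when `planted_high_fraction > 0`, a set sized at that
fraction of the largest per-species expressed count is planted at
`planted_effect_sd` (default 4) latent SDs, with a tight 0.15-SD spread,
re-asserted within every dataset so the truth is exactly "genes planted at
+4 SD in that dataset". All orthology partners of planted genes are planted
too — otherwise the copula would push partner genes to planted-level
expression without them being in the answer key. The 10 %-of-expressed
sizing keeps the planted component large enough that the natural upper tail
of the continuous body (which any z-threshold rule must also flag) stays
small relative to it; this is what makes planted-vs-detected agreement a
meaningful measure of the caller rather than of the body's tail mass.

What the generator does **not** emulate: transcript-level structure and
isoform switching, GC/length biases, batch effects between datasets beyond
a scalar latent decorrelation, count-level sampling noise (TPM is generated
directly), and biotype-specific expression profiles (biotypes are sampled
independently of the latent). Passing recovery tests therefore shows the
pipeline's inferential machinery is sound under the stated statistical
shape, not that real oocyte data meet that shape.

## Pipeline

The orchestrator validates all paths before any compute, runs the stages in
dependency order, and writes a `MANIFEST.json` with SHA-256 checksums of
every artifact; with a fixed seed and config, reruns are checksum-identical.
Reported percentages are rounded half-away-from-zero to integers. Gene IDs
are opaque case-sensitive strings; Ensembl-style version suffixes are kept
unless stripping is requested explicitly, because silently harmonising IDs
across annotation releases changes set intersections.

## Problem sizes used by the validation suite

Unit and property tests run on matrices of tens to a few thousand genes;
the recovery checks use studies of 3,000–4,000 genes per species with 20
replicate simulations per condition, and the planted-recovery and
acceptance runs use the full 24k/26k-gene default configuration. These
sizes were chosen so the statistical assertions (Jaccard, monotone odds
ratios, null uniformity) have comfortable margins while the whole suite
stays quick to run.

## Known limitations

* The quantile grid counts pairs, so a single large ortholog family can
  dominate a cell; the unique-gene summaries are provided but the Fisher
  test treats pairs as exchangeable units.
* The EASE/Fisher universe is a modelling choice; absolute enriched-set
  counts are only comparable under a fixed universe and annotation version.
* ANOSIM/adonis assume exchangeable samples under the null; with three
  replicates per dataset the permutation floor (1/1680 three-way, 1/20
  pairwise) limits attainable significance, which is a property of the
  design, not of the implementation.
* Orthology is consumed as a file and taken at face value; no attempt is
  made to reconcile gene trees or collapse paralog families.
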