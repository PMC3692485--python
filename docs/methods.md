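# Methods

## Signal quantification

Aligned reads (BED6) are extended to a fixed 100 bp in the direction of
their strand — the approximate fragment length of the ChIP-seq protocols
this analysis targets — and clipped at position 0. A region's signal is

    log2(count / region_bp + pseudocount),    pseudocount = 0.01

where `count` is the number of extended reads overlapping the region union
by ≥ 1 bp. A read is counted at most once per region even when it spans
two exons of the same union; fractional assignment of boundary-spanning
reads was considered and rejected as needless complexity at the read
depths involved. Gene-level signals use the non-redundant exon union
(nucleosomes, and hence marks, concentrate in exons), so gene expression
and mark signals share one normalization and the exon inclusion value is a
plain difference of log2 densities. Promoter signals follow the
promoter-modelling convention of logging the raw read sum in a 4,001 bp
window centered on the strand-aware TSS; the same 0.01 pseudocount guards
log(0) there, a deliberate (and documented) extension of that convention.

Everything is 0-based half-open internally; GTF input is converted at
parse time. Multi-isoform genes merge to one exon union per `gene_id`, and
duplicate exon coordinates collapse to one record. First and last exons
never enter analysis sets (transcription initiation/termination dominate
them); internal exons are classified against an event table by exact
coordinate match — cassette events define the cassette set, exons matching
no event are constitutive, and exons matching non-cassette or conflicting
events are excluded from both.

## Regression and cross-validation

Ordinary least squares throughout, with the interaction design adding all
C(N,2) pairwise products. Features are not standardized, so coefficients
stay on the raw log2-signal scale. Coefficient p-values (two-sided t) are
Benjamini–Hochberg adjusted across the non-intercept family; "significant"
defaults to adjusted p < 0.001. Cross-validation uses 10 seeded random
folds (remainder rows spread one per fold); the score is the mean per-fold
Pearson r between measured and predicted values. The shuffle control fits
each fold on correctly ordered columns and deranges the held-out rows'
columns before predicting — a column permutation applied to both fit and
prediction would be a no-op, since OLS is symmetric in column order; the
control is only meaningful when trained coefficients meet the wrong
inputs. Derangements are sampled by rejection from uniform permutations
(acceptance ≈ 1/e, so a couple of tries on average).

BIC uses the Gaussian likelihood at the MLE variance RSS/m:

    BIC = m·(ln(2π·RSS/m) + 1) + d·ln(m)

with d counting the intercept. RSS ≤ 1e-8·m is treated as numerically
zero and rejected (degenerate likelihood).

## Partial-correlation network

Full-conditional partial correlations come from the inverse of the
correlation matrix; the definitional double-residual-regression route is
retained in the package (`partial_correlation_residual`) and the test
suite keeps both routes in agreement to 1e-8, with the V = 3 closed form
as a second, independent check. Correlation matrices with condition number
above 1e10 are rejected, naming the most nearly collinear columns.

The network score of an edge set is the sum over nodes of the BIC of each
node's OLS regression on its current neighbors (intercept-only when
isolated). This is one of several defensible liftings of a single-model
BIC to a network: it degenerates to the per-model BIC when only one
response node has neighbors, scores every edge addition (both endpoint
neighborhoods change), and is cheap to maintain incrementally. A
node-wise-sum alternative based on a joint Gaussian likelihood would
differ by a model-complexity bookkeeping constant; the choice is isolated
in `network_bic` and pluggable.

Threshold selection sorts all V(V−1)/2 pairs by descending |pcor| (ties
broken lexicographically for determinism), scores the nested networks
obtained by adding pairs one at a time (the empty network is step 0, so
every pair has a BIC difference), and keeps every pair up to and
*including the last* whose difference is ≥ 20% of the maximum difference —
early small dips do not truncate the network. The threshold is the |pcor|
of the last kept pair. Ranking and thresholding use absolute pcors; edges
retain their signs, and edge/node weights are reported normalized by the
maximum absolute value.

The permutation null deranges every column independently (no value stays
in its own row, preserving each marginal exactly), recomputes all pairwise
pcors per permutation, and pools them across permutations and pairs; the
threshold's z-score is computed against that pooled distribution. The
pooled null mixes all pairs, matching how a single threshold is screened
against the whole network.

## Combination and redundancy analyses

Median binning marks a row High for a feature when its value strictly
exceeds the feature's median (ties fall to Low, a convention that matters
only for discretized data). Bin contrasts use two-sided Mann–Whitney
rank-sum tests — a distribution-free default for comparing bin response
distributions. Neighborhood interaction tests fit singleton and
all-pairwise-product models of each network node on its ≥ 2 neighbors and
compare cross-validated r. Stepwise BIC adds features in order of
descending |pcor with the response|, dropping collinear additions. The
clustered matrix export orders rows by ascending response and features by
average-linkage hierarchical clustering on 1 − Pearson distance.

## Cross-cell transfer

Each shared variable's affine map is the OLS line of the reference cell's
values on the source cell's values over matched exons (≥ 3 required);
applying it turns that line into y = x, and the map is idempotent. The
non-reference cell is the one normalized; the model is trained on it and
evaluated on the reference cell. (The opposite fit direction is a
symmetric design choice; the implementation keeps it switchable.) Normalization is fit on all matched exons, not expressed exons only.
Fold filters keep exons with |Δlog2 expression| ≥ log2(k), inclusive at
the boundary and symmetric in the two cells.

## Synthetic data

The generator is a pure function of (parameters, seed) and exports its
full truth, so every downstream stage can be scored without re-deriving
anything.

*Feature matrices.* Rows are i.i.d. multivariate normal with a declared
unit-diagonal precision matrix (off-diagonal −ρ gives a true partial
correlation of exactly ρ on each declared edge; positive definiteness is
checked). Optional gene- and exon-expression columns are linear children
with Gaussian noise; the joint precision is tracked analytically through
each child addition, so true pcors, the true edge support (including the
edges a child induces among its parents), and the closed-form √R² of the
exon regression are all available. Product interaction terms can be added,
which voids the Gaussian closed forms (flagged as such).

*Presets.* `small` — 10 marks with a sparse dependency structure, gene
expression driven by H3K4me3/RNAPII, exon expression by gene expression
plus H3K36me3 and H4K20me1 (noise sd 0.6), m = 2000: the desk-scale
stand-in for 38 marks + RNAPII over ~17,700 exons, with the same driver
pair the CD4+ analysis highlights. `interaction` adds a 0.8·H3K36me3·H4K20me1
product. `ggm10` — a 10-node ring with true pcor 0.3, the network-recovery
testbed. `single_driver` — one mark carries the whole signal, the cleanest
setting for the shuffle control. `full_scale` — 39 marks + gene + exon at
m = 17713 for scale checks. Preset parameters were fixed when the presets
were defined and are not tuned per test.

*Read level.* A toy genome lays genes head to tail (default 30 genes × 5
exons of 400 bp); per-region read counts are Poisson with rate
`region_bp·(2^signal − pseudocount)` and 25 bp stranded reads are placed
uniformly inside each exon, so the quantification pipeline inverts the
construction exactly in expectation. At the default depth (~50–1000 reads
per exon) recovered signals track generating intensities with Spearman ρ
≈ 0.98. The toy genome has no intergenic reads, no peak shape, no
mappability structure and no duplicate-read artifacts — passing the round
trip validates the counting/normalization arithmetic, not robustness to
those real-data features.

*Second cell.* The same exons keep their latent feature state up to
N(0, 0.1) jitter; expression is recomputed with the same coefficients and
fresh noise; each variable is affinely distorted; and a chosen fraction of
exons gets expression shifted by log2(fold)·U(1.5, 2.5) with random sign —
comfortably past the filter boundary relative to the noise scale, so
filter-recovery tests measure the filter, not boundary luck.

## Problem sizes and numerical choices

The analysis scripts and acceptance checks run at m = 2000–5000 rows and
10–12 variables (20 seeds for coefficient recovery, 10 for network
recovery, 100 permutations), sizes at which every estimate's sampling
error is far inside the tolerances being checked while a full run stays in
the minutes range on one core. Determinism: all randomness flows through
`numpy.random.default_rng` with explicit seeds; pipeline outputs are
byte-identical across reruns of the same config. Degenerate inputs
(constant columns, rank-deficient designs, empty regions/bins, impossible
derangements, non-positive-definite precision matrices) raise informative
errors rather than propagating NaNs.

## Known limitations

Real ChIP-seq inputs would need duplicate handling, input-control
subtraction and mappability filtering before these models — all out of
scope here. The exact-coordinate alt-event matching misses events recorded
with slightly different boundaries. The network BIC's node-wise-sum
convention is one choice among several (see above). The permutation null
pools all pairs; a per-pair null would be stricter for hub variables.
Cross-cell normalization assumes a single affine relation per variable,
which cannot absorb nonlinear saturation effects between platforms.
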