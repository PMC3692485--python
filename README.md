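# histonet

Quantitative analysis of how histone-modification levels on transcribed
regions and exons relate to gene and exon expression: signal
quantification from aligned reads, regression and interaction modelling
with cross-validation, a full-conditional partial-correlation network with
BIC-based threshold selection and permutation significance, combination
and redundancy analyses, and cross-cell-type model transfer. It is written
for computational epigenomics work of the kind done on the CD4+ T-cell
compendium of 38 histone-modification ChIP-seq tracks plus RNAPII and
RNA-seq, and ships a synthetic-data generator with known ground truth so
that every stage can be validated end to end without genome-scale data.

## The models

**Signals.** Reads are extended to 100 bp along their strand; for a region
(a gene's exon union, a single exon, or a 4,001 bp promoter window around
the TSS) the signal is `log2(count/region_bp + 0.01)` — length-normalized
density with a pseudocount (promoters log the raw count). The exon
*inclusion value* is the log2 ratio of exon to gene expression; negative
values flag alternatively spliced exons. First/last exons are excluded;
internal exons are split into constitutive and cassette sets by a
KnownAlt-style event table.

**Regression.** Expression is modelled as
`e = b + Σᵢ aᵢ hᵢ` (main effects) or
`e = b + Σᵢ aᵢ hᵢ + Σ_{i<j} a_{ij} hᵢ hⱼ` (all pairwise interactions),
fit by OLS with two-sided t-tests and Benjamini–Hochberg adjustment.
Predictive power is the mean Pearson r between measured and predicted
values over seeded ten-fold cross-validation; the
*improvement ratio* `(P_singleton − P_interaction)/P_singleton` compares
the two model families. A shuffle control feeds each trained model
deranged inputs (no feature in its own place) at prediction time.

**Network.** For variables A, B among marks, gene expression and exon
expression, the full-conditional partial correlation is
`P_{AB·rest} = −Ω_AB/√(Ω_AA Ω_BB)` with Ω the inverse correlation matrix
(equivalently, the correlation of double-regression residuals). Pairs
sorted by descending |pcor| are added to a growing network scored by
`BIC = −2 ln L + d ln m` summed over node-wise regressions; the threshold
is the |pcor| of the last pair whose BIC drop is ≥ 20% of the maximum
drop, and its significance is the z-score against a pooled null from 100
column-derangement permutations.

**Cross-cell transfer.** Each shared variable in a second cell type is
mapped onto the reference scale by the affine transform that turns the
between-cell regression line into y = x; the model fit on the normalized
cell predicts exon expression in the reference cell, overall and within
2/5/10-fold-changed exon subsets.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data with known truth (all accept `--seed`, default 1; tables land in
`results/`, bulk data in `scratch/`):

```
$ python analysis/03_regression.py
main-effects CV r = 0.8726 (closed-form sqrt(R^2) = 0.8729)
interaction CV r  = 0.8714; improvement ratio = 0.14%
...
$ python analysis/04_network.py
threshold = 0.2838 after 12 of 66 pairs
permutation null: z = 19.93, max |null pcor| = 0.0594 (below threshold)
exon_expr connects to: ['H3K36me3', 'H4K20me1', 'gene_expr'] (generating drivers: H3K36me3, H4K20me1, gene_expr)
ggm10: 10 edges selected at threshold 0.255, F1 vs true ring = 1.000
```

Reading the output: cross-validated prediction of exon expression from the
marks reaches the generator's theoretical ceiling (r ≈ 0.87); adding 55
pairwise interaction terms changes prediction by 0.14% — the marks act
accumulatively, not synergistically. The BIC trace keeps 12 of 66 variable
pairs; the exon-expression node connects exactly to the three variables
that generated it, and no permutation produces a partial correlation
anywhere near the selected threshold (z ≈ 20). The same machinery recovers
a 10-node Gaussian-graphical-model ring perfectly (F1 = 1.0).

`analysis/05_combination_modes.py` shows the median-binning view of the
same additivity (bin means LL −0.98 < HL/LH +0.12/−0.17 < HH +0.87) and
the redundancy ordering: BIC drops steeply for the first three additions
(H3K36me3, H4K20me1, gene expression) and changes on the ln(m) penalty
scale afterwards. `analysis/06_cross_cell.py` transfers the model across
an affine-distorted second cell type (transfer r 0.84 vs within-cell 0.87,
stable across fold-change filters).

A single config-driven run of everything:

```python
from histonet.pipeline import RunConfig, run_pipeline
report = run_pipeline(RunConfig(out_dir="out", preset="small", seed=1))
```

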