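# Methods

## The problem and the estimator

The pipeline asks whether a small panel of genes, selected from
multi-tissue RNA-seq counts of a small balanced cohort (by default
9 high-feed-efficiency and 9 low-feed-efficiency animals across five
tissues), can classify held-out animals, and whether a two-step
selector — random-forest screening followed by boosted-tree ranking —
yields smaller panels at equal or better accuracy than classical
differential-expression tests or either learner alone.

Selection quality is never read off training data: all selectors run
inside a nested threefold cross-validation and are judged by an
independent SVM on the held-out fold.

## Preprocessing

Counts are normalized by TMM: the reference sample is the one whose
upper-quartile count fraction is closest to the cohort mean; for every
other sample, log2 expression ratios (M) and average log2 abundances
(A) are formed over genes nonzero in both, the extreme 30% of M and 5%
of A are discarded, and the factor is 2 to the inverse-variance
weighted mean of the surviving M values, the weights being the
delta-method binomial variances. Factors are rescaled to geometric
mean one. The implementation was verified to 10 decimal places against
the Bioconductor reference implementation on composition-biased
matrices; the shipped test uses an independent plain-loop oracle.

CPM uses the TMM-adjusted effective library size. A gene is kept when
it reaches ≥ 1 CPM in at least `ceil(n/2)` samples; the filter is
applied per tissue, after factor computation (computing factors on the
unfiltered matrix is the common convention; the alternative ordering
changes factors only marginally). Learners and correlations consume
`log2(CPM + 1)`; the pseudo-count avoids −∞ at zero counts.

## Differential-expression benchmarks

*t*-test: Welch (unequal variance) per gene on log2-CPM. Genes with
zero variance in both groups get p = 1 (equal means) or p = 0 (unequal
means) as the limiting convention. No multiple-testing correction —
the raw p < 0.05 rule is deliberate, because the output feeds a
classifier rather than an inference table.

NB exact test: a conditional exact test with a single common
dispersion φ. Counts are quantile-mapped to the geometric-mean
effective library size (mid-CDF through the sample-specific NB law,
back through the quantile function at the common mean), group totals
are formed, and the two-sided p-value sums the conditional
probabilities of all splits of the grand total no more probable than
the observed one. Because group totals of n iid NB(μ, φ) variables
are NB with shape n/φ and a shared success probability, the
conditional split law is negative hypergeometric and free of μ; it is
evaluated through cumulative log sums, which stay exact even as
φ → 0 (where the test provably reduces to the binomial exact test).
φ is estimated by the method of moments — per-gene
`(within-class variance − mean) / mean²` on depth-equalized counts —
aggregated by a 10% trimmed mean over genes with mean ≥ 5. The trim
matters: a plain μ⁴-weighted least-squares fit is dominated by a
handful of high-count genes and wanders between 0.06 and 0.15 when the
truth is 0.1, which alone moves the test's size off its nominal level.

## Machine-learning selectors

**Random forest.** Bagged CART trees (bootstrap of the animals,
`mtry` candidate genes per split). Importance is the permutation VIM:
for each tree and each gene the tree splits on, the gene's values are
shuffled among the tree's out-of-bag animals and the drop in OOB
accuracy recorded; a gene's VIM is the mean drop over the trees
containing it, and genes with VIM > 0 are selected. The forest is
built tree-by-tree precisely because off-the-shelf forests do not
expose OOB permutation importance; a side benefit is that validation
error curves over the number of trees come from vote prefixes of a
single fit.

**XGBoost.** Binary-logistic boosted trees, depth ≤ 6, per-tree column
subsampling. Importance is total split Gain, normalized to sum to one
over used genes; genes used in at least one split (Gain > 0) are
selected. `min_child_weight` is set to 0: the default of 1 is a
hessian threshold that blocks *every* split when the training fold
holds only a few animals (the logistic hessian contributes at most
0.25 per sample). Boosting runs up to 500 rounds with early stopping
(patience 25) on the validation fold.

**RX.** RF first; the genes with positive VIM are handed to XGBoost;
the RX panel is the Gain-positive subset, hence always contained in
the RF-positive set.

**Tuning.** Grids: ntree ∈ {500…5,000} by default,
mtry ∈ {1, ⌊√M⌋, ⌊0.1 M⌋}, η ∈ {0.01, 0.05, 0.1, 0.2}, column
subsample ∈ {0.1, 0.05, 0.03, 0.01}. For each setting the model is
fit on the training fold and its error measured on the validation
fold; the chosen point is where the error-rate curve plateaus
(three-point window with relative spread < 1%), ties going to cheaper
settings (fewer trees, larger η). Ties across mtry rules go to the
classification default √M: on small separable folds all three rules
often reach identical (zero) validation error, and √M concentrates
the importance best.

**Refit for selection.** After tuning, the final importance model is
refit on the pooled train + validation animals (12). This is the
standard nested-CV pattern and keeps the data budget equal to the DE
benchmarks, which derive their gene lists from the same 12 animals.
It matters quantitatively: with 18 animals, a random non-informative
gene perfectly separates two groups of 3 + 3 with probability
2/C(6,3) = 0.1, so a 6-animal fit cannot distinguish hundreds of
lucky noise genes from real signal (measured RX precision ≈ 0.33 on
2,000-gene synthetic data); with 12 animals that probability drops to
2/C(12,6) ≈ 0.002 and measured precision rises to 0.89–1.00. The
held-out test fold is never touched by selection or tuning, which a
structural assertion on the fold plan enforces.

## Evaluation

Folds are stratified: each of the three folds holds 3 animals per
class. Rotating the test fold gives three train/validation/test
splits; DE selectors merge the two non-test folds, ML selectors use
them as train and validation. The judge is an RBF-kernel SVM (C = 1,
γ = 1/n_features, features z-scored with training statistics only)
trained on the 12 non-test animals restricted to the selected panel.
Metrics follow the standard confusion-table formulas with HFE
positive; 0/0 ratios are reported as 0 and flagged. Fold means and
SDs are aggregated per tissue; the across-tissue overall average is
the arithmetic mean of tissue means. Per-tissue and per-method panel
sizes are reported per fold together with their union ("total").
Failed folds (empty panels) are recorded and skipped, not fatal.

## Co-expression networks

PCIT: for every trio (x, y, z) the three first-order partial
correlations r_xy·z = (r_xy − r_xz r_yz)/√((1−r_xz²)(1−r_yz²)) are
formed; the trio tolerance is one third of the sum of the
partial-to-direct ratios (terms with zero direct correlation are
skipped); pair (x, y) is dominated in the trio if |r_xy| is below the
tolerance-scaled magnitude of both other correlations, and an edge is
significant iff it is dominated in no trio. Two conventions close the
degenerate corners: a partial correlation with a vanishing denominator
(|r| = 1 off-diagonal) saturates at ±1, and pairs with exactly zero
correlation are never significant. The production implementation is
vectorized over the controlled gene; its flags are required to be
bit-identical to a brute-force trio enumeration in the tests.

Within-tissue networks are built over the union of RX-selected genes;
nodes keep fold-averaged Gain, edges keep the signed Pearson r,
topology is unweighted. Centralities use the conventions of the
familiar interactive network-analysis tools: raw (unnormalized)
betweenness; closeness = reciprocal mean shortest-path distance within
the component; radiality = (Δ + 1 − mean distance)/Δ with Δ the
component diameter; neighborhood connectivity = mean neighbor degree;
topological coefficient averaged over nodes sharing at least one
neighbor, 0 for nodes with fewer than two neighbors; singleton
components get closeness and radiality 0. Gain–centrality association
is plain Pearson correlation per centrality, with a per-tissue table
and an across-tissue average row; constant centrality columns are
reported missing.

Cross-tissue comparison: for each class, every animal contributes one
observation column per tissue (tissues stacked as extra observations —
the only structure under which a handful of animals supports the
correlation estimate of a panel of tens of genes). PCIT networks are
built per class over the genes expressed in all tissues; each gene is
colored by its tissue of maximum average expression; per-tissue
connection counts sum the degrees of that tissue's genes, and
differential connectivity is the per-gene HFE − LFE degree change.
The sum of per-gene deltas equals 2(|E_HFE| − |E_LFE|) by the
handshake identity, which the tests assert on generated pairs.

## Synthetic data

Counts are gamma-Poisson: baseline relative abundances are log-normal
(σ = 1 on the natural log), library sizes uniform in a configurable
range (default 0.8–1.2 million reads — desk scale; the per-gene count
magnitudes, not the absolute depth, drive every method here), and
NB(μ, φ) sampling with φ = 0.1 by default. Differential genes split
the effect symmetrically (2^{+fc/2} vs 2^{−fc/2}) so the overall mean
carries no class information. Module genes share an additive Gaussian
factor on the log mean whose variance share equals `module_rho`; the
total latent SD defaults to 1.0, chosen before the build by an
independent simulation so that the *observed* log-scale correlation
(attenuated by NB sampling noise) stays within 0.15 of `module_rho`.
The log-normal multiplier is mean-centered (−σ²/2) so modules do not
shift expression levels. DE gene identities are shared across tissues
by default, supporting the cross-tissue analysis.

What the generator does **not** model: pedigree/half-sib covariance
among animals, batch and lane effects, gene length (so only
within-gene, between-sample comparisons are meaningful), and
heavy-tailed per-gene dispersion heterogeneity. Passing tests
therefore show that the machinery is correct and well calibrated under
its stated model, not that any particular panel from a real cohort is
biologically right.

## Problem sizes, determinism, calibration

Tests and the acceptance script run the recovery analysis at 2,000
genes, 40 DE genes, log2 fold change 2, dispersion 0.1, 9 + 9 animals,
with forests up to 2,000 trees and 5 replicate seeds — sizes at which
the qualitative regime (clean separability, compact RX panels) is
stable. Type-I calibration uses 50 null datasets with `n_modules = 0`:
module genes are over-dispersed relative to any common-dispersion NB
model by construction, so a size check for the NB test is meaningful
only under the test's own null; the t-test is insensitive to this
choice. Every stochastic component (generator, bootstrap, permutation,
boosting, fold assignment) is seeded, forests fix per-tree seeds from
one stream, and XGBoost runs single-threaded with the exact tree
method, so identical inputs give byte-identical outputs.

## Known limitations

- The NB exact test is a classic common-dispersion conditional test,
  not a reimplementation of any particular package's moderated
  pipeline; with strong per-gene dispersion heterogeneity it will be
  anti-conservative for the most over-dispersed genes.
- With 18 animals the SVM judge saturates at accuracy 1.0 for effect
  sizes ≥ ~1.5 log2 units, so method ranking on synthetic data is
  driven by panel size and precision rather than accuracy differences.
- PCIT is O(n³) in panel size; fine for panels of tens to a few
  hundred genes, not for transcriptome-wide networks.
- Error-curve tuning assumes validation error is meaningful on six
  animals; with such folds it mostly acts as a sanity filter, and the
  plateau rule's cheap-tie-break does the real work.
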