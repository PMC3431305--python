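# Methods

## Data model and reduction

A feature table holds nonnegative peak-area intensities for observations
(biological line × technical replicate) over features identified as
`"<rt>_<mz>"` (retention time in minutes to 2 decimals, m/z in daltons to 4
decimals). Absence is encoded as 0; the package performs no imputation.
Replicate averaging precedes filtering, so both filters act on line-level
means.

*Presence filter* (default fraction 0.8): a feature survives if, in at least
one class, the fraction of that class's lines with strictly positive
intensity is ≥ the threshold. "Present" means intensity > 0, matching how
alignment software encodes absent peaks. The per-class disjunction keeps ions
that are characteristic of a single class even when absent elsewhere —
exactly the ions a discriminant model needs.

*Mean-intensity filter* (default 1.0, peak-area units): a feature survives
if its mean over all lines, pooled across classes, is ≥ the threshold. Both
thresholds are inclusive.

*Pareto scaling*: each column is centered and divided by the square root of
its sample standard deviation (n−1 denominator). Compared with unit-variance
scaling this leaves part of the magnitude structure intact, so intense ions
still carry more weight but cannot dominate outright. Columns with zero
variance map to all-zero columns rather than NaN. The fitted means and
standard deviations are returned so held-out observations can be projected
with training parameters.

## PCA and OPLS-DA

PCA is computed by SVD of the centered matrix; per-component explained
variance `r2x` comes from squared singular values. Component signs are fixed
so each component's largest-magnitude loading is positive, removing
eigenvector sign ambiguity from downstream comparisons. Hotelling T²
ellipses use semi-axes `s_i · sqrt(2(n²−1)/(n(n−2)) · F(1−α; 2, n−2))` and
flag observations whose T² exceeds the critical value.

OPLS-DA dummy-codes the K class labels as a 0/1 matrix with one column per
class and centers it. Orthogonal components are extracted first, one at a
time: a NIPALS PLS2 component (w, t, p) is fit on the current matrix, the
orthogonal weight is the part of p not aligned with w
(`w_o ∝ p − (wᵀp)w`), and the resulting component `t_o p_oᵀ` is deflated
from X. Predictive components are then fitted on the deflated matrix with
both X and Y deflation. Because `p_o` is the regression of X on `t_o`,
predictive scores are exactly orthogonal to all orthogonal scores, and
R2Xp + R2Xo equals the total explained X variation by Pythagoras.

With K classes at most K−1 predictive components are allowed. The automatic
component rule grows (n_pred, n_orth) greedily while cross-validated
Q2Y(cum) improves by more than 0.01 — a documented, reproducible surrogate
for proprietary significance rules in commercial chemometrics software.
A practical consequence of the single-w orthogonal filter in the multi-class
(K > 2) setting is that orthogonal components can siphon off part of the
second predictive direction; the automatic rule guards against this by
refusing orthogonal components that do not raise Q2.

Classification converts the predicted dummy response to pseudo-probabilities
by softmax and takes the argmax (ties broken by class order, with a
warning). The choice of monotone link does not affect the confusion table.
Confusion tables are summarized by the generalized hypergeometric point
probability of the observed table given fixed margins,
`∏(row sums)! ∏(col sums)! / (N! ∏ cells!)`, computed with log-gamma so
large tables cannot overflow. The point-probability convention (not a tail
sum) is deliberate: it is the quantity the model summaries report.

## Cross-validation

Q2Y(cum) = 1 − PRESS/SS, with PRESS accumulated over held-out centered
dummy-Y predictions and SS the total centered sum of squares of the dummy
matrix. Folds (default 7) are stratified by class with a seeded round-robin
assignment; the seed is a required, logged parameter. A class with fewer
members than folds simply spans fewer folds — every training split still
contains it — and only classes with a single member are rejected, since then
some training split would lack the class entirely.

## Biomarker selection

For the first predictive score t1, each feature's covariance
`cov_i = t1ᵀx_i/(n−1)` and correlation `pcorr_i = cov_i/(s_t1 s_xi)` are
computed with sample (n−1) statistics; the n−1 convention matches the rest
of the package and is documented because some implementations use n.
Zero-variance features get pcorr = 0 and a flag.

Jack-knifed confidence intervals use the delete-a-fold (grouped) jackknife
over the same stratified segments as cross-validation: the model is refit
with each fold removed, refit t1 is sign-aligned to the full-model t1 by
their correlation on the retained rows (an alignment failure raises a
diagnostic error), and the interval is the full-data covariance ±
`t(1−α/2, k−1)` times the grouped-jackknife standard error. Selection
replaces manual S-plot tail-picking with explicit dual thresholds — feature
kept iff |cov| and |pcorr| both reach their thresholds (default: the 95th
percentile of each absolute statistic) and the interval excludes 0 — and
returns ions sorted ascending by covariance, so ions elevated in the
positive-scoring class appear last.

## Clustering metrics

Single-linkage agglomeration on Euclidean distances over the first one or
two predictive score columns (scipy's implementation; deterministic index-
order tie-breaking). *Compactness* of a cluster node is read as its merge
height — the distance from 0 on the dendrogram axis — which is the only
interpretation consistent with using "node height from 0" as a similarity
summary. *Distinctness* is the parent's height minus the node's height;
the root has distinctness 0 by convention, having no parent. Display order
puts the larger subtree second ("sorted by size" by leaf count; ordering has
no numeric consequence). Dendrograms serialize to Newick with branch lengths
equal to height differences, making the tree ultrametric.

## Adduct annotation

Monoisotopic masses use IUPAC atomic masses (C 12 exactly, H 1.00782503,
O 15.99491462, N 14.00307401, P 30.97376200, S 31.97207117, Na 22.98976928,
K 38.96370649, Li 7.01600344, Cl 34.96885268). Ion m/z is
`(M + Σ carrier masses)/z` where ionizing carriers are *cation* masses
(atomic minus electron mass: proton 1.00727646, Na⁺ 22.98922, K⁺ 38.96316,
Li⁺ 7.01545) and neutral losses/gains (H₂O 18.01056, CH₃OH 32.02621) enter
with their neutral masses. The electron-corrected convention reproduces the
reference sodiated and disodiated rows of the bundled ion table at their
printed ppm errors; the uncorrected convention does not. Fourteen ESI+
adduct modes are implemented with charges +1 except [M+2H]2+, [M+H+Na]2+,
[M+2Na]2+ (2+) and [M+3H]3+, [M+2H+Na]3+, [M+2Na+H]3+ (3+).

Matching keeps candidates with |Δppm| ≤ tolerance (default 10), ranks by
|Δppm|, reports all members of an exact tie, and emits a single NC
placeholder when nothing matches. Lipid Maps categories map to broad
polarity classes FA, ST → NP; GL, GP, PR, PK, SP, SL → PL; ON, OS, NC → NC
(overridable). The bundled reference table transcribes 36 rows (35 unique
ions; one ion appears twice as a mass-error tie between a fatty-acyl and a
glycerophospholipid identity). One bundled row's printed neutral mass
differs from the recomputed value in the 4th decimal (356.2926 vs a
computed 356.29266 → 356.2927), a rounding artifact of the source table;
mass checks therefore use a one-unit-in-the-4th-decimal tolerance. A
handful of the table's printed ppm errors are search-engine-internal values
that no adduct arithmetic reproduces exactly; masses, not ppm entries, are
the quantities this package treats as checkable.

## Synthetic data

The generator emulates the study design this pipeline was built around:
45 lines in classes of 6 (durum), 27 (hard bread) and 12 (soft bread) with
color/habit subclasses (6/4/8/9 and 6/2/4), 9 technical replicates (405
rows), 3727 features over RT 0–35 min and m/z 50–1500.

Intensities are built multiplicatively, reflecting the right-skew of LC-MS
peak areas: a log-normal base level per feature (location 3.0, scale 1.0 on
the log scale), a log-normal line effect (scale 0.25 — moderate biological
variation between lines), and proportional replicate noise (CV 0.2, floored
at 0). Ten marker features carry a 3× multiplicative shift in their elevated
class (assigned round-robin across classes); three features per non-first
subclass carry a weaker nested 1.5× shift so within-class models have
structure to find. 64% of features are dropout noise: a line carries the
feature with probability 0.3, and a dropped line is zero in *all* its
replicates — dropout acts at the line level because presence is judged on
the averaged table, where independent per-replicate dropout would almost
never produce an averaged zero. 12% of features are scaled far below the
intensity threshold. These fractions were chosen so that, in expectation,
the presence filter removes ~63% of features and ~935 of 3727 survive both
filters, the reduction profile the pipeline is designed around; the exact
binomial survival probability of a dropout feature is exposed as
`presence_survival_probability` for analytic test bounds.

What the generator does *not* emulate: retention-time drift, batch and
run-order effects, correlated features (adduct/isotope families of one
compound), heteroscedastic detector noise, and structured Y-orthogonal
biology (e.g. environment). Passing tests therefore demonstrate that the
pipeline recovers planted multiplicative class structure under idealized
independence, not that it is robust to instrument artifacts.

## Problem sizes and determinism

All simulations and fits are pure functions of their seeds; every stochastic
entry point takes a seed parameter. The test suite runs the full 405 × 3727
study scale end to end (generation, filtering, one 3-class and two 2-class
models, jackknife selection over ~950 features) in a few seconds; unit tests
use a 300-feature version of the same design. `scripts/acceptance.py`
reports the deterministic monoisotopic-mass benchmarks.

## Known limitations

- The multi-class orthogonal filter uses a single NIPALS weight vector per
  deflation step; with K > 2 well-separated classes the automatic rule
  usually selects zero orthogonal components (see above).
- The softmax "modeled probability" is a monotone surrogate, not a
  calibrated posterior.
- Jackknife intervals quantify refit stability across cross-validation
  segments, not full sampling uncertainty; with k segments the t quantile
  has only k−1 degrees of freedom.
- Annotation is m/z-only: no isotope patterns, MS/MS evidence or retention
  prediction, so identities are tentative by construction.
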