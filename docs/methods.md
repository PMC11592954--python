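# Methods

## Model and evidence function

All inference is for the normal linear fixed-effects model
y ~ N(Xβ, σ²I) with a full-column-rank design X (n × r), covering
t-tests, regression, and fixed-effects ANOVA.  Two nested candidate
models are compared: model 2 (full, r mean parameters) and model 1
(model 2 with q linear restrictions imposed, either by dropping q design
columns, "formulation A", or by constraints Lβ = h, "formulation B").

The evidence function is the difference of Schwarz information criteria,

    ΔSIC = SIC₁ − SIC₂ = G² − q·log n
         = n·log(1 + q·F/(n − r)) − q·log n,

where G² is the generalized likelihood-ratio statistic and F the classical
nested-model F statistic.  Positive values favor the larger model 2;
negative values favor the restricted model 1.  ΔSIC/n (written ΔK̂) is a
consistent estimate of the difference of Kullback–Leibler divergences of
the two fitted model families from the data-generating process, and is
the quantity comparable across data sets.  Natural logarithms are used
everywhere; ΔK comparability across studies requires a common log base.

Least squares is solved by QR/SVD-based routines, never by explicitly
inverting X'X; a design is declared rank deficient when its smallest
singular value falls below 1e−8 times its largest, and the error names
the aliased columns.  Categorical predictors default to treatment
("leave one column out") coding; sum coding is also available.  F, G²
and ΔSIC are invariant to the coding (tested); the coefficient vector β₂
entering noncentrality formulas is coding-dependent, so λ computations
take explicit design-matrix blocks.

Residual sums of squares within 1e−24 (relative to ‖y‖²) of zero are
snapped to exactly zero so that degenerate, perfectly fitting inputs
behave deterministically instead of depending on round-off.  When both
models fit perfectly the likelihood ratio is 1 and F = 0; when only the
full model is saturated the comparison raises a degenerate-fit error.

## Noncentral F convention

Pre-data design and post-data probabilities are tail areas of the
noncentral F(q, n−r, λ).  The noncentrality convention is fixed to the
Poisson-mixture form with weights of mean λ/2, matching R's `ncp` and
scipy's `nc`.  Because some software parameterizes by λ/2, the package
ships `convention_check`, a seeded Monte Carlo guard comparing a sample
mean against the closed form ν₂(ν₁+λ)/(ν₁(ν₂−2)): at (ν₁, ν₂) = (1, 3)
the mean is 9 under λ = 2 but 15 under λ = 4, which separates the two
conventions unambiguously.  The check's tolerance is max(3 standard
errors, 2% of the mean); the 2% floor covers ν₂ ≤ 4, where the sampling
variance is infinite but the law of large numbers still applies.

The pdf is computed from the mixture series directly, truncated when the
accumulated Poisson weight exceeds 1 − 1e−12 (a dominated-tail bound).
The cdf and quantile are delegated to scipy's `ncf`; for very large λ
(beyond roughly 2·10³, where scipy's routine returns NaN) the cdf falls
back to the same mixture series evaluated outward from the dominant
Poisson index.

λ is computed from designs two equivalent ways: the dropped-columns
quadratic form β₂'(X₂'X₂ − X₂'X₁(X₁'X₁)⁻¹X₁'X₂)β₂/σ², or the constraint
form (Lβ−h)'(L(X'X)⁻¹L')⁻¹(Lβ−h)/σ².  The identity λ = 2K − design load
connects λ to the symmetric KL distance 2K = β₂'X₂'X₂β₂/σ² between the
nested models; the nonnegative design load measures how correlation of
X₂ with X₁ dilutes the information the design carries about β₂.

## Study design

The investigator fixes a per-observation relative effect size δ (in
units of the residual standard deviation): departures of model 2 from
model 1 smaller than δσ per observation are inside the "zone of
indifference" and considered consistent with model 1.  For balanced
designs the boundary noncentrality is λ = nδ².  With caps γ₁, γ₂ on the
two misleading-evidence probabilities, the thresholds are

    k₁ = transform of ψ₁ (the γ₂ quantile of ncF(q, n−r, nδ²)),
    k₂ = transform of ψ₂ (the 1−γ₁ quantile),

so that M₂ ≤ γ₂ and M₁ ≤ γ₁ at the boundary by construction (asserted
to 1e−8 in tests).  Evidence below k₁ is strong for model 1, above k₂
strong for model 2, and in between inconclusive; a value exactly at a
threshold is classified inconclusive (conservative tie-break for a
measure-zero event).  Misleading probabilities for the model-1 scenario
default to the boundary λ = nδ² rather than the literal null λ = 0; the
literal null remains available (`lam1=0` in `error_probabilities`,
`model1_lam="null"` in the sample-size search).

Sample-size determination inverts the threshold construction.  The
misleading probability as a function of n is continuous once df and λ
are allowed real values, so a bracketing root-finder locates the n where
it equals γ and the implementation then selects the compliant adjacent
integer.  Two regimes arise and are handled direction-aware:

* predesignated k₁: M₂(n) is zero while k₁ < −q·log n (unreachable by
  any F ≥ 0), rises to a hump, then decays; the smallest integer past
  the final downward crossing is returned, and the cap then holds for
  all larger n.
* predesignated k₂ under the boundary scenario: M₁(n) *increases* in n
  (the boundary evidence distribution drifts past the fixed k₂), so the
  largest compliant integer is returned.  Under the literal null the
  usual smallest-n logic applies.

A related subtlety, asserted in the tests: with fixed thresholds, M₁ at
λ = 0 and M₂ at the boundary both vanish as n grows, but M₂ peaks just
past the designed n before decaying, and boundary-M₁ grows without
bound.  The "both error probabilities go to zero" guarantee is a
statement about data generated by the models, not about the boundary
scenario at fixed thresholds.

## Post-data quantities

Given an observed Δsic favoring model 1, P₂ is the largest probability,
under model 2 at the boundary λ = nδ², of evidence at least that
favorable to model 1 (a noncentral-F cdf at the inverted evidence
point); P₁ = 1 − P₂.  P₂ is strictly decreasing in δ, so the smallest δ
at which the observed evidence counts as strong (P₂ = target) is found
by monotone bracketing.  For the citrus example this root is δ ≈ 0.94.

## Bootstraps

Three schemes estimate the sampling distribution of ΔSIC; all refit both
models per replicate with the design matrices held fixed (responses only
are resampled — conditional, "local" inference) and all are deterministic
given a seed:

* **parametric** — responses redrawn from N(Xβ̂, σ̃²I) of a chosen
  generating model, with σ̃² = RSS/(n−r) (the ML estimate RSS/n would
  understate the noise when n−r is small);
* **residual semiparametric** — fitted values plus residuals resampled
  with replacement;
* **stratified balanced** — for ANOVA-style data: within each factor
  cell, residuals about the cell median are inflated by
  sᵢ = sqrt(nᵢ/(nᵢ−1)) so their expected sample variance matches the
  cell population variance, then resampled within the cell.  Balance is
  realized by concatenating B copies of each cell's residual pool,
  permuting within the cell, and slicing into B replicates, so every
  residual is used exactly B times across the set (audited exactly in
  tests).  The non-root inflation factor nᵢ/(nᵢ−1) is selectable
  (`scaling="literal"`), but over-inflates the variance by a second
  factor and is not the default.

Refits are vectorized: with Q an orthonormal basis of a design's column
space, SSE = ‖y‖² − ‖Q'y‖², evaluated for all B replicates in one matrix
product; tests assert this agrees with the one-at-a-time fitting route
to 1e−9.

Summaries are percentile-method confidence intervals (the reported
confidence points are plain quantiles), the mean and median, and the
apparent reliability aR — the proportion of the bootstrap evidence
distribution sharing the sign of the identified model.  Identification
defaults to the sign of the bootstrap mean (for the citrus data the
point evidence is mildly negative while the bootstrap distribution puts
≈0.59 of its mass on the positive side, and aR reports that majority);
an explicit `identified_sign` argument switches to the observed-evidence
convention.  ΔK̂ intervals are ΔSIC intervals divided by n.

Degenerate replicates: with 2 observations per cell, a stratified
replicate draws a tied pair in a cell with probability 1/2, and an
all-tied replicate (probability 2^−#cells; expected ≈0.25 occurrences in
a 12-cell design at B = 1024) has SSE = 0 under the full model, making
Δsic* = +∞ — the formula's correct value for an unbounded likelihood
ratio.  Quantiles, aR and the EDF are robust to such replicates; the
bootstrap mean may be infinite.  This is a limitation of mean-based
summaries at minimal replication, not of the resampling scheme.

## Synthetic data

`generate_factorial` draws balanced two-factor data sets at a chosen
interaction effect size: the interaction coefficient vector is a fixed
alternating ±1 reference pattern rescaled so that the realized
noncentrality of the interaction comparison equals exactly nδ² (the
direction in coefficient space is not identified by δ alone, so a fixed
reference pattern is used).  Main effects are user-supplied sum-to-zero
vectors.  `generate_regression` uses fixed low-discrepancy grids (van
der Corput) for designed predictors — identical across seeds — and
standard-normal draws for undesigned ones.  All generators take explicit
seeds; there is no global RNG state.

What the generators emulate: exactly the model the method assumes
(normal, homoscedastic, independent errors; correct mean structure at a
known boundary effect size).  What they do not emulate: misspecification
— non-normal or heteroscedastic noise, dependence, missing cells.
Passing tests therefore certify the internal consistency and the
designed error control of the machinery under correct specification,
not robustness to misspecified data.

## Simulation scales and numerical choices

The packaged replication of the cell-size study simulates 100 outer data
sets per cell size with B = 200 bootstrap replicates each (cell sizes 2,
4, 8), averaging the 0.05/0.50/0.95 confidence points of ΔK̂; the
pseudo-true ΔK is taken as λ/n of the generating fit, the large-n limit
of the ΔSIC/n estimand.  At these scales the qualitative findings are
stable across seeds: medians sit below the pseudo-truth, parametric and
stratified intervals agree within a few percent from 4 observations per
cell, and the 90% interval's lower end crosses zero around cell size 8.
One caveat found consistently (also at 400×400): the averaged median ΔK̂
at cell size 2 is *elevated* relative to cell size 4 — with r = 12 mean
parameters on n = 24 observations, the overfitting inflation of G²
outweighs the shrinking SIC penalty — so the approach to the pseudo-truth
from below is monotone only from moderate replication upward.

Other numerical choices: threshold and effect-size root-finding uses
Brent's method (xtol 1e−8 on n, 1e−10 on δ); misleading probabilities at
evidence thresholds below −q·log n are exactly 0 by convention; boundary
classifications are inconclusive; quantile probabilities must lie
strictly inside (0, 1).

## Known limitations

Fixed effects only (no mixed models, GLMs, or weighted least squares);
sequential (type-I) sums of squares in the ANOVA table, so term order
matters for unbalanced data; the five-category evidence scheme is not
built in (only the two-threshold trichotomy, though any thresholds can
be classified against); no kernel smoothing of bootstrap EDFs; aR and
mean summaries are unstable at minimal within-cell replication as
described above.
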