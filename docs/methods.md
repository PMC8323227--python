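# Methods

## The two-sample MR model

Each instrument j carries a SNP–exposure association γ̂<sub>j</sub>
(SD units of the exposure per effect-allele copy, with standard error
σ<sub>Xj</sub>) and a SNP–outcome association Γ̂<sub>j</sub> (log odds
ratio per copy, SE σ<sub>Yj</sub>), estimated in non-overlapping
samples. Under the instrumental-variable assumptions (association with
the exposure; independence of confounders; effect on the outcome only
through the exposure) every valid instrument satisfies
Γ<sub>j</sub> = β γ<sub>j</sub>, and the per-SNP Wald ratio
β̂<sub>j</sub> = Γ̂<sub>j</sub>/γ̂<sub>j</sub> estimates the causal
effect β — the log-OR per 1-SD exposure increase. Horizontal
pleiotropy adds a direct effect α<sub>j</sub>
(Γ<sub>j</sub> = β γ<sub>j</sub> + α<sub>j</sub>) and is what the
sensitivity battery probes.

First-order Wald SEs (σ<sub>Yj</sub>/|γ<sub>j</sub>|) are used
throughout, with no correction for uncertainty in γ̂. The neglected
term scales as (β σ<sub>Xj</sub>/γ<sub>j</sub>)², i.e. 1/F per
instrument; the instrument sets this package targets have per-SNP
F ≫ 10, and the multiplicative overdispersion below absorbs the small
residual underdispersion.

## Harmonization

Instruments are exposure-panel variants with p < 5×10⁻⁸ (strict
inequality; a variant at exactly the threshold is excluded), minus a
blacklist of known-pleiotropic loci. A variant absent from the outcome
panel may be replaced by the best available LD proxy with r² > 0.8
(strict); the proxy's effect is phased to the original via the sign of
the LD correlation (r > 0: the two effect alleles ride the same
haplotype). Proxy ties on r² break lexicographically by variant id for
determinism.

Allele alignment expresses both effects per copy of the exposure
panel's effect allele: swapped alleles negate the outcome beta and
complement its frequency; alleles matching only after strand
complement are complemented first. Palindromic variants (A/T, C/G)
with allele frequency within 0.08 of 0.5 on either panel
(eaf ∈ [0.42, 0.58]) are dropped — frequencies that close to one half
cannot disambiguate strand; outside that window the strand is inferred
from frequency concordance. The window is configurable; 0.08 is the
repository default.

Instrument sets are assumed pre-pruned for independence, as GWAS
reports of independent loci are; a greedy r² < 0.01 pruning pass is
available for synthetic data.

## Estimators

* **IVW (primary, random effects).** Inverse-variance-weighted mean of
  the Wald ratios with weights γ<sub>j</sub>²/σ<sub>Yj</sub>²,
  equivalently WLS of Γ̂ on γ̂ through the origin. The SE is the
  fixed-effect SE inflated by √max(1, Q/(J−1)) — multiplicative
  overdispersion floored at the fixed-effect model. The floor makes the
  test slightly conservative at small J (the exact null size at J = 10
  is ≈ 0.039 rather than 0.050); this is the common convention and is
  kept.
* **Cochran's Q** on the ratio estimates measures heterogeneity;
  significant Q flags the weighted-median estimate for reporting.
* **MR-Egger.** Weighted regression of Γ̂ on γ̂ *with* an intercept,
  after re-signing instruments so γ̂<sub>j</sub> ≥ 0 (the InSiDE
  orientation). The slope is the pleiotropy-adjusted estimate; the
  intercept estimates average directional pleiotropy. p-values and CIs
  use t(J−2) — the method's published convention — because the
  overdispersion is estimated; with normal quantiles the intercept
  test's measured size under balanced pleiotropy was ≈ 0.09 at J = 10
  versus ≈ 0.05 with t.
* **Weighted median.** Weighted 50th percentile of the ratios
  (midpoint cumulative-weight convention, linear interpolation);
  consistent while valid instruments hold > 50% of the weight. SE by
  parametric bootstrap of the summary associations (seeded). The
  bootstrap resamples around observed ratios, whose spread exceeds the
  truth's, so the SE runs ~10–15% conservative at J = 10.
* **Mode-based estimation.** Maximizer of a weighted Gaussian kernel
  density over the ratios; bandwidth φ × 0.9·min(sd, MAD)·J^(−1/5)
  with φ = 1 by default; maximization over a 512-point grid spanning
  the ratio range ± 2 bandwidths; bootstrap SE.
* **MR-PRESSO.** Observed weighted residual sum of squares about
  leave-one-out IVW predictions, compared against a parametric
  bootstrap under no pleiotropy (default 5,000 simulations; Monte-Carlo
  p-values use the (k+1)/(n+1) convention). Per-SNP outlier p-values
  are Bonferroni-adjusted at 0.05; when outliers are found the
  outlier-corrected IVW is reported along with a distortion-test p
  (shift against random same-size removals). A very extreme outlier
  contaminates its neighbours' leave-one-out slopes, so additional
  variants can be flagged alongside it; the corrected estimate remains
  accurate.
* **MR-Robust.** IRLS regression of Γ̂ on γ̂ through the origin on
  precision-standardized data with the Tukey biweight (c = 4.685, 95%
  Gaussian efficiency), scale re-estimated by the normalized MAD each
  iteration; convergence tolerance 10⁻¹⁰, 200 iterations, explicit
  non-convergence error. Exact fits fall back to the WLS solution.
* **MR-RAPS.** Maximizes the robust adjusted profile likelihood
  −Σ[ρ<sub>k</sub>(t<sub>j</sub>) + (δ/2) log s<sub>j</sub>²] over
  (β, τ²), τ² ≥ 0, where
  t<sub>j</sub> = (Γ̂<sub>j</sub> − β γ̂<sub>j</sub>)/s<sub>j</sub>,
  s<sub>j</sub>² = σ<sub>Yj</sub>² + β²σ<sub>Xj</sub>² + τ²,
  ρ<sub>k</sub> is the Huber loss (k = 1.345) and δ = 2Φ(k) − 1 is the
  consistency constant (δ → 1 recovers the Gaussian profile
  likelihood, whose gradient is the classical unbiased adjusted
  profile score). τ² models a random-effects distribution of
  pleiotropic effects. The SE is the model-based sandwich
  √c₂/(c₁ √Σ γ̂<sub>j</sub>²/s<sub>j</sub>²) with c₁ = E[ψ′(Z)],
  c₂ = E[ψ(Z)²] under the fitted model: with only ~10 instruments the
  empirical score sums are noisy and correlated with the realized
  error, and a purely empirical sandwich undercovers badly (measured
  89.8% for a nominal 95% CI) while the model-based version covers
  96.8%.
* **Multivariable IVW.** Weighted multiple regression of Γ̂ on all
  exposure-effect columns without intercept; conditional estimate per
  exposure; rank-deficiency raises a collinearity error.

All betas are reported with normal-based 95% CIs (z = 1.959964) and
two-sided normal p-values, except MR-Egger (t, above); odds ratios are
exp(β) with exponentiated CI endpoints. Significance stars follow
\*p<0.05, \*\*p<0.01, \*\*\*p<0.001. Reporting flags: the
outlier-corrected estimates are highlighted when the PRESSO global
p < 0.01; the weighted median when Cochran's Q p < 0.05.

## Power

For a binary outcome with case fraction K, total N, instrument
variance explained R² and true odds ratio OR, the attenuated
risk-difference effect is b = K(OR/(1 + K(OR − 1)) − 1), its variance
v = (K(1−K) − b²)/(N R²), and power is the upper-tail probability of a
noncentral χ²(1, b²/v) beyond the central 1−α quantile. Power at
OR = 1 equals α exactly. The minimum detectable OR inverts this on a
0.01 grid: the smallest OR > 1 (largest OR < 1) whose power reaches
the 80% target. A continuous-outcome analogue (noncentrality N R² β²)
is provided for reverse-direction designs.

## Meta-analysis

DerSimonian–Laird: fixed-effect weights 1/se² give Q about the
fixed-effect mean; τ² = max(0, (Q − df)/(S₁ − S₂/S₁)); random-effects
weights 1/(se² + τ²) give the pooled log-scale mean with a normal 95%
CI; I² = max(0, (Q − df)/Q). Published ratio CIs convert to SEs as
(ln hi − ln lo)/(2 × 1.959964); two-decimal published values make this
slightly lossy, so comparisons against published pooled values are at
two decimals. Egger's asymmetry test regresses effect/se on 1/se
(t-based p, n − 2 df).

## Synthetic data

The generator draws summary statistics directly from their asymptotic
sampling distributions — no individual-level genotypes — which is fast
and gives exact control of the truth. Defaults mirror the study shape
the package targets: J = 10 instruments, target R² = 0.0187 (achieved
exactly by construction), exposure GWAS n = 52,018, and a large
case-control outcome (N = 247,173 with 133,384 cases, the
best-powered replication-scale design; UK-Biobank-style rare-outcome
designs are a parameter change away). Allele frequencies are uniform
on [0.1, 0.5]; instrument effect magnitudes are uniform on a 0.5–1.5
relative range before scaling, because selected genome-wide-significant
instruments are bounded away from zero — a half-normal draw would
produce near-null instruments whose sign-orientation step corrupts
directional-pleiotropy recovery. Exposure and outcome noise are
independent (two-sample design, no overlap). The binary-outcome SE
uses the logistic score approximation
1/(N K(1−K)·2f(1−f)); pleiotropy assigns a configurable fraction of
instruments a direct effect α<sub>j</sub> ~ N(mean, sd²) (directional)
or N(0, sd²) (balanced); an optional LD block around the first index
SNP supports proxy-substitution tests.

What the generator does **not** emulate: realistic LD structure from
reference haplotypes, winner's-curse selection of instruments (effects
are true effects plus noise, not selected maxima), sample overlap, and
non-normal estimation error. Passing calibration tests therefore show
the estimators behave correctly under the stated sampling model, not
that consortium data meet that model.

The calibration suite (see `tests/test_acceptance.py`) uses: 2,000
replicates for type-I error and CI coverage, 500 for recovery and
robustness means, 200 for MR-PRESSO specificity (1,000 bootstrap
simulations each), bootstrap size 200 inside coverage loops — sizes
chosen to keep Monte-Carlo SEs a few per mille while the whole suite
runs in well under a minute per check. Per-replicate seeds derive from
`SeedSequence((base, rep))` since the generator takes one seed per
dataset.

## Numerical choices and edge cases

- Proxy ties and grid-argmax ties resolve deterministically
  (lexicographic id; first grid maximum).
- Monte-Carlo p-values are floored away from zero by the (k+1)/(n+1)
  convention; simulated p-value columns are floored at the smallest
  positive double so record validation (p ∈ (0, 1]) holds.
- A single-instrument set reduces IVW to the Wald ratio exactly;
  methods needing ≥3 (or ≥4 for PRESSO) instruments record a
  not-applicable failure instead of aborting the suite.
- The palindromic frequency window comparison carries a 10⁻¹²
  epsilon so the documented closed interval [0.42, 0.58] includes its
  endpoints despite float representation.
- `mr_robust` accepts a starting value, making converged points
  verifiable fixed points.

## Known limitations

- The floored multiplicative random-effects IVW is conservative at
  small J (null size ≈ 0.039 at J = 10); additive random-effects
  variants are out of scope.
- The weighted-median bootstrap SE is conservative by construction
  (~10–15% at J = 10).
- MR-Egger retains its weight-misspecification sensitivity: under
  balanced pleiotropy whose variance is unrelated to the outcome SEs,
  the intercept test's size grows with J (≈ 0.076 at J = 50).
- No NOME/weak-instrument correction, no Steiger filtering, no
  correlated-instrument (generalized) IVW, no sample-overlap
  adjustment.
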