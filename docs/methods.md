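# Methods

## Setting

`mrselect` implements two-sample summary-data Mendelian randomization (MR):
genetic variants serve as instrumental variables for estimating the causal
effect of one or more exposures on a (typically binary) outcome, using only
per-variant association summaries from two non-overlapping GWAS samples.
For variant *j*, `γ̂_j` is the variant–exposure association (per allele, in
SD units of a z-standardized exposure) with standard error `σ_{γ,j}`, and
`Γ̂_j` the variant–outcome association (log-odds) with standard error
`σ_{Γ,j}`.

The identifying assumptions are the usual instrumental-variable triple:
the variant is associated with the exposure (relevance), shares no
confounder with the outcome, and affects the outcome only through the
exposure (exclusion). Multivariable MR (MVMR) replaces the single exposure
with K exposures and estimates *direct* effects, each conditional on the
co-included exposures.

## Instrument selection and harmonization

Instruments are variants with exposure p-value below 5×10⁻⁸, pruned per
chromosome by a greedy distance rule: keep the smallest-p remaining
variant, discard all others within a 10,000 kb window, repeat. This
replaces LD-based clumping (r² thresholding against a reference panel)
with a distance-only approximation; for the simulated data the variants
are independent by construction, so pruning is exact there.

Harmonization aligns every table to the first exposure table's effect
allele: swapped alleles negate the beta and complement the frequency;
strand flips are resolved through allele complements. Palindromic variants
(A/T, C/G) cannot be strand-resolved from allele codes, so they are aligned
by allele frequency and dropped entirely when any table's frequency lies
within 0.08 of 0.5 (the conventional ambiguity band). For MVMR the
instrument set is the union of each exposure's instruments, restricted to
variants present in every table — which is why the number of instruments
varies with the outcome dataset. Every dropped variant carries a provenance
flag (`dropped_palindromic`, `dropped_missing`).

## Univariable estimators

* **Wald ratio** `θ̂_j = Γ̂_j/γ̂_j`, first-order SE `σ_{Γ,j}/|γ̂_j|`. The
  delta-method SE ignores `σ_γ`; with the instrument strengths used here
  (per-variant F ≳ 30) the second-order term is negligible.
* **IVW**: inverse-variance weighted mean of the ratios, weights
  `w_j = γ̂_j²/σ_{Γ,j}²`, equivalent to WLS of `Γ̂` on `γ̂` through the
  origin. Fixed-effect SE `(Σw_j)^{-1/2}` by default; a multiplicative
  random-effects model scales it by `max(1, √(Q/(L−1)))`.
* **MR-Egger**: the same regression with an intercept, after orienting all
  `γ̂_j ≥ 0`; the intercept estimates average directional pleiotropy under
  the InSIDE assumption. SEs use the WLS covariance scaled by
  `max(1, σ̂)`.
* **Weighted median**: the ordered ratios interpolated at standardized
  cumulative weight 0.5; consistent when >50% of weight comes from valid
  instruments. SE by seeded parametric bootstrap (resampling `γ̂, Γ̂` from
  their sampling normals; default 1000 draws).
* **Weighted mode**: argmax of a weighted normal-kernel density over the
  ratios on a 1024-point grid, bandwidth = modified Silverman rule
  `0.9·min(sd, IQR/1.34)·L^{−1/5}` times a user multiplier (default 1);
  consistent when the largest cluster of instruments is valid (ZEMPA).
  Bootstrap SE as for the median.

**Heterogeneity.** Cochran's `Q = Σ w_j (θ̂_j − θ̂_IVW)²` with df `L−1`.
The outlier filter is a single pass: variant *j* is flagged when the
chi-square(1) upper tail of its Q contribution falls below `0.05/L`
(Bonferroni over instruments); the filter refuses to empty the instrument
set. Iterating the filter to convergence would remove progressively milder
outliers; a single evaluation matches how the diagnostic is normally
reported.

## Multivariable MR

`mvmr_ivw` solves WLS of `Γ̂` on the K columns of `γ̂` without intercept,
weights `1/σ_Γ²`; at K=1 it reproduces univariable IVW exactly. Rank
deficiency raises an error naming the (near-)collinear exposure pairs.

**Conditional F.** Instrument strength for exposure k conditional on the
others: regress `γ̂_{·k}` on the remaining columns by WLS where the weight
of instrument j is the inverse sampling variance of the residualized
association, `σ²_{jk} + Σ_m δ_m² σ²_{jm}` (minus cross-covariance terms
when a K×K between-trait correlation is supplied; with summary data these
covariances are rarely available and default to zero). Because the
coefficients δ enter their own weights, the pair is iterated to a fixed
point (init: unit-weight regression; tol 1e-8; cap 200 iterations). The
statistic is `F_k = Q̃_k/(L − K + 1)` with `Q̃_k` the weighted residual sum
of squares. The conventional adequacy threshold is 10.

**Adjusted Q.** Residual pleiotropy after an MVMR fit:
`Q_A = Σ_j (Γ̂_j − Σ_k β̂_k γ̂_{jk})² / (σ_{Γ,j}² + Σ_k β̂_k² σ_{jk}²)`,
df `L − K`.

## Forward selection by conditional instrument strength

Fitting many correlated exposures at once collapses conditional F; the
selection algorithm finds the largest exposure set keeping every
conditional F ≥ 10:

1. Fit all C(K,2) two-exposure models. Score each pair by
   `score = mean(F_a, F_b)/(1 + |F_a − F_b|)`. The inverse-difference
   weighting is deliberately bounded: the raw `mean/|ΔF|` form (available
   behind a flag, with |ΔF| floored at machine epsilon) is undefined
   exactly where it matters most — a perfectly balanced pair — while the
   bounded form preserves the intended ordering (a balanced pair beats an
   unbalanced pair of equal mean, because it can absorb the attenuation
   later additions cause).
2. Seed with the highest-scoring pair whose two conditional Fs both meet
   the threshold.
3. For each remaining exposure, fit the augmented model; candidates are
   additions under which every conditional F (incumbents' and the
   candidate's) stays ≥ 10. Among candidates, add the one maximizing the
   *minimum* conditional F — the most robust to later additions — breaking
   ties by mean conditional F, then name. Exposures that fail feasibility
   are excluded permanently (strict forward selection, no backtracking).
4. Stop when no candidate is feasible. Every evaluation is recorded in an
   audited trace; when no pair is feasible the result is an empty model
   with a stop record, not an exception.

The attenuation mechanism this protects against: when an added exposure
lies on the path from a set of instruments to an incumbent exposure, the
incumbent's instrument strength is partly attributable to that
relationship and is removed by conditioning, dragging its conditional F
down — possibly below usability.

## Synthetic data generator

The generator emulates the kind of data the workflow consumes without any
external download. Per variant: maf ~ U(maf range), dosages Binomial(2,
maf) under HWE, no LD (instruments are independent, as post-clumping data
should be). Exposures: `X_k = G b_k + (mediation terms) + c_k U + ε`,
z-standardized; U is a single standard-normal confounder standing in for
all shared non-genetic structure (age, sex, batch and the like are not
modelled separately). Outcome: liability `η = Xθ + Gπ + c_y U` with direct
variant effects π (horizontal pleiotropy); binary Y from a logistic model
with intercept solved so the population prevalence matches the target
(a liability-threshold variant is also available). Exposure and outcome
cohorts are disjoint draws from separate seeded substreams.

The outcome GWAS runs per-variant simple logistic regressions (vectorized
Newton–Raphson, verified against IRLS) on an incident-style case-control
subsample with 10 controls per case. A linear-regression route plus the
`β/(μ(1−μ))` log-odds conversion exists to mirror linear-mixed-model GWAS
pipelines.

**Prevalent-case selection.** Each case is retained with probability
`expit(a + X s)`, the intercept solved so mean retention hits a target
(default 0.5). With a negative survival coefficient, surviving cases are
enriched for low exposure, which biases MR estimates for that exposure
negatively even when its causal effect is zero — the mechanism suspected
when prevalent-case GWAS produce paradoxical protective associations.

**Non-collapsibility.** With a binary outcome the marginal per-variant
log-odds slope is an attenuated version of the liability coefficient. The
truth record therefore includes the implied *marginal* log-odds effects,
computed by integrating the remaining liability empirically and solving
the population logistic score equations over dosage 0/1/2 with HWE
weights. Estimator checks compare against these marginal values — the
actual estimands of a log-odds-scale analysis. For the Egger intercept the
estimand is additionally weight-adjusted: directional pleiotropy enriches
carriers among cases, shrinking those variants' outcome SEs, so the WLS
intercept targets the `1/σ_Γ²`-weighted mean of the marginal direct
effects rather than the unweighted mean.

### Canonical fixtures (study conditions)

| fixture | K | J | n (exp/out) | causal θ | notes |
|---|---|---|---|---|---|
| `null` | 1 | 30 | 10k/10k | 0 | valid instruments, b ~ U(0.15, 0.30) |
| `valid_instruments` | 1 | 50 | 20k/20k | 0.2 | bimodal b (0.08/0.26) for γ̂ spread |
| `pleiotropic` | 1 | 50 | 20k/40k | 0 | 30% of variants, direct effect 0.25 |
| `mediator_13` | 13 | 60 | 20k/20k | on 4 cores | 4 disjoint blocks + 9 mediated traits |
| `selection_bias` | 1 | 30 | 10k/40k | 0 | survival coefficient −0.6, retention 0.5 |

Prevalence is 0.08 throughout so a full 1:10 case:control draw fits inside
the cohort. Replicate counts and cohort sizes were fixed by a prior power
analysis (documented choices, not tuned constants): e.g. the bimodal
effect-size design in `valid_instruments` maximizes the γ̂ spread the
Egger slope needs while keeping total genetic variance plausible (~55%)
and nearly all variants genome-wide significant, limiting winner's curse.
In `mediator_13`, the nine mediated traits carry staggered strong loadings
(0.60/0.51/0.53/0.44) on one core plus a weak 0.2 loading on another, so
every mediator-involving pair is either infeasible or strongly unbalanced
and the designated four-exposure model is the unique stable selection.

### What the generator does not emulate

No LD (so distance pruning is exact, unlike real data), no sample overlap,
no population stratification, no sex-specific effects, a single shared
confounder, and exact two-sample separation. Passing tests therefore
demonstrate correctness of the estimators and the selection logic under
the model's own assumptions — not robustness to the additional failure
modes of real consortium data.

## Numerical choices

- P-values are two-sided normal (summary data from large-n GWAS; no
  small-sample t correction). CIs are `β ± 1.96σ`.
- Bootstrap SEs require an explicit seed; all generator randomness flows
  from one integer seed through crc32-named substreams.
- The weighted-mode grid spans the ratio range ± 3 bandwidths with 1024
  points; an exact-consensus set short-circuits to the common value.
- Degenerate inputs raise typed errors: zero `γ̂` (Wald ratio), all
  instruments flagged as outliers, L ≤ K (adjusted Q), collinear exposure
  columns (MVMR), non-convergent conditional-F iteration (carries the last
  iterate).
- Ties in instrument pruning break by (p-value, position, id); ties in
  candidate addition by (min F, mean F, name); both make runs bit-for-bit
  reproducible.

## Known limitations

Distance pruning under-prunes real LD; conditional-F cross-trait
covariances default to zero when no phenotypic covariance is supplied;
the outlier filter is single-pass by design; no MVMR-Egger or
median/mode MVMR variants; the forward selection is greedy and offers no
optimality guarantee beyond the audited feasibility invariant.
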