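# Methods

## Data model and recoding

A cohort is a flat table of participants: case/control status, sex, age,
an optional matched-pair identifier, and categorical exposures validated
against a codebook. The default codebook carries the hypertension study's
variables and their collapse-to-binary recodes: for the three-level
behaviours (drinking, smoking, sports) `occasionally` and `regular` both
count as exposed; taste is exposed only for `salty`; work/life pressure is
exposed for `little` or `more`. Recoded values are the strings `"0"`/`"1"`,
and the recode passes its own image through unchanged, so it is idempotent.
Missing values (empty CSV fields) are excluded from analyses of that
variable only, with exclusion counts logged; no imputation is attempted
because the analyses are all complete-case contingency methods.

The file dialect is fixed (UTF-8, comma-separated, mandatory header, empty
string = missing) to keep round-trips byte-stable. Age is stored in whole
years; the 5-year matching tolerance is a property of the generator, not a
constraint enforced on read, since an analysis file may legitimately contain
unmatched subjects.

## Individual effects

Crude odds ratios are `ad/bc` on the fourfold table with the Woolf
log-normal interval, `exp(ln OR ∓ z·√(1/a+1/b+1/c+1/d))`, `z = 1.959964`
at 95%. A table containing a zero cell receives the Haldane–Anscombe
correction (+0.5 to every cell) and the estimate is flagged; this keeps all
estimates finite at the cost of a small bias toward the null. The 2×2
chi-square is the closed form `N(ad−bc)²/∏margins` on 1 df; the two-sample
t test pools variances (the matched design gives equal arms, so Student and
Welch coincide asymptotically).

Logistic regression is unconditional maximum likelihood, fitted by Newton
iteration (iteratively reweighted least squares) through statsmodels, with
a parameter-change tolerance of 1e-10 and at most 50 iterations;
non-convergence is returned as an explicit flag rather than raised, while a
rank-deficient design raises an error naming the collinear columns (QR
pivot diagnostic). Ordinal covariates enter as integer level scores
(0, 1, 2, …) in codebook order, so each variable contributes a single
degree of freedom; Wald statistics are (B/SE)² on 1 df and OR intervals are
`exp(B ∓ z·SE)`. The matched design is deliberately analysed
unconditionally — the reproduced study tables are all crude/unconditional —
and conditional (pair-matched) logistic regression is out of scope. With a
single binary covariate the fit is saturated and `exp(B)` equals the crude
OR exactly; the test suite exploits this as an independent cross-check.

## Additive interaction

Stratum odds ratios OR₀₁, OR₁₀, OR₁₁ are computed by collapsing each
non-reference cell of the 2×2×2 table against the double-unexposed cell and
applying the crude-OR machinery. The measures are

    RERI = OR11 − OR10 − OR01 + 1
    SI   = (OR11 − 1) / ((OR10 − 1) + (OR01 − 1))
    AP   = RERI / OR11
    PAP  = RERI / (OR11 − 1)

computed at full floating precision; rounding (OR 3 decimals, RERI/SI 2,
AP/PAP two-decimal percent, half-even) happens only at rendering. An SI
with zero denominator and a PAP at OR₁₁ = 1 are reported as undefined
rather than infinite, so non-finite values never propagate into reports.
All measures are odds-ratio approximations of their risk-ratio originals,
the only option a case-control design leaves.

Two direction verdicts are always reported side by side, because the
published sum rule (OR₁₁ vs OR₁₀ + OR₀₁) tests RERI against 1 while the
conventional rule tests RERI against 0; silently picking either would
misrepresent the other. They disagree exactly when 0 < RERI < 1, and the
reproduced tables include pairs on both sides.

### Interval estimation

The default interval is the delta method on the log-odds scale. For the
saturated two-factor model the covariance of the three stratum log odds
ratios has closed form — `var(ln OR_s) = 1/a_s + 1/b_s + 1/a₀ + 1/b₀` and
`cov = 1/a₀ + 1/b₀` between strata — which is identical to the inverse
information of the saturated logistic fit; a test verifies the identity
against an actual fit. Gradients: RERI `(−OR10, −OR01, OR11)`; AP via
`1 − e^{β1−β3} − e^{β2−β3} + e^{−β3}`; SI on the log scale,
`ln SI = ln(OR11−1) − ln(OR10+OR01−2)`, defined only when OR₁₁ > 1 and
OR₁₀+OR₀₁ > 2. The bootstrap resamples case and control stratum counts
from separate multinomials (≥1000 replicates, explicit seed required),
applies the zero-cell correction within replicates, and takes percentile
intervals; replicates with undefined SI are counted, and more than 10%
undefined attaches a warning to the result. Delta intervals are symmetric
and can be anti-conservative in small tables where the RERI sampling
distribution is skewed; the bootstrap is the cross-check for such tables.

## Synthetic cohorts

The generator works directly in exposure-stratum space: controls are drawn
from the specified joint distribution over the four (e1, e2) strata, cases
from the distribution proportional to control probability × stratum OR.
A case-control design identifies only the odds ratios, so no latent
disease model is simulated and the specified ORs — hence the true
RERI/SI/AP/PAP — hold exactly in the population; `expected_tables` returns
the analytic expected counts and recovers the specified ORs to machine
precision, which the tests use as a closed-form oracle.

Sex and age are generated independently of the exposures, so matched and
unmatched analyses agree asymptotically. Under pair matching each pair
shares its sex, the case age is uniform over the configured range (default
28–87 years, the study's span) and the control age is the case age plus a
uniform offset bounded by the matching tolerance (default 5 years), clipped
into the range — a constructive scheme that never needs rejection attempts.
Optional extra variables are independent Bernoulli noise exposures with
equal prevalence in both arms. One master seed drives per-component
substreams (numpy `SeedSequence.spawn`), making an identical spec produce a
byte-identical cohort file.

What the generator does *not* emulate: confounding between matching
variables and exposures (exposures are age- and sex-independent by
construction), correlation among the extra noise exposures, misclassified
or missing exposure data, and any within-pair residual correlation beyond
the shared matching variables. Tests passing on these cohorts therefore
demonstrate correctness of the estimators under the stated sampling model,
not robustness to confounding or measurement error in field data.

## Reproduction of the published tables

The six published cross-classifications ship as packaged fixtures exactly
as printed. Thirteen of the eighteen printed stratum odds ratios reproduce
from their own printed counts to the printed three decimals; five do not
(the family-history × diabetes joint OR among them), and whether those are
typos or adjusted estimates is unknowable — the reproduction report flags
them and only the internally consistent cells are treated as checkable
values. Printed confidence intervals are compared nowhere: the published
interval method is unstated and Woolf recomputation does not match it.

The published worked example for family history × diabetes chains its
arithmetic through rounded intermediates: RERI and SI are computed from the
3-decimal printed ORs and rounded to two decimals, then AP% and PAP% are
computed *from the two-decimal RERI* and truncated at two decimals. The
`footnote_measures` renderer reproduces that chain literally (8.68, 2.27,
52.48%, 55.86%); the full-precision path yields 52.48%/55.85% from the same
printed ORs. Both are exposed; analyses use full precision.

## Problem sizes and calibration settings

Simulation studies use sizes at which the asymptotic methods are in their
regime while keeping the whole suite fast: truth recovery at 100,000 per
arm (2% relative tolerance on RERI and OR₁₁), interval coverage with 1,000
replicate tables of 2,000 per arm under a null-RERI spec with stratum ORs
(2, 2, 3) and control distribution (0.40, 0.25, 0.25, 0.10), logistic slope
recovery (intercept −1, slope 1.4) at n = 50,000 with ±0.05 tolerance, and
the saturated-fit equivalence across 200 random tables at 1e-6. Replicate
tables for simulation studies are drawn in count space
(`sample_joint_table`), the same multinomial core the full record-level
generator uses.

## Known limitations

- No conditional logistic regression, Firth correction, exact tests,
  multiplicative-interaction model or three-way interactions.
- Delta intervals on heavily skewed small-sample RERI distributions can
  undercover; use the bootstrap there.
- The generator's matched pairs are informative only through sex and age;
  a confounded mode (exposure prevalence varying with age) is not
  implemented, so matched-vs-unmatched divergence cannot be demonstrated
  within the package.
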