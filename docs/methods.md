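# Methods

## Statistical model

The data are a 2×2 cross-classification of a dichotomous index test
against a reference standard in one cohort of suspected patients. The
two accuracy components are modelled as independent binomials:
TP ~ Binomial(n_D, Se) among the n_D = TP+FN diseased and
TN ~ Binomial(n_N, Sp) among the n_N = FP+TN non-diseased.
Independence of the two margins, a perfect reference standard, and no
indeterminate index-test results are assumed throughout.

The study hypothesis is joint,

    H1: Se ≥ MAC(Se) and Sp ≥ MAC(Sp)
    H0: Se < MAC(Se) and/or Sp < MAC(Sp),

with the alternative the rectangle [MAC(Se), 1] × [MAC(Sp), 1] in
(Se, Sp) coordinates ("target region"; it always contains the
perfect-test corner). Boundary convention: a value exactly at MAC
belongs to the alternative, so all comparisons use ≥.

## The intersection–union test

Each component is tested one-sided and exactly:
p_Se = P(X ≥ TP | n_D, MAC(Se)) and analogously for specificity; the
joint p-value is max(p_Se, p_Sp) and H0 is rejected when it is ≤ α.
Because H0 is a union, rejecting only when *both* components reject
controls the size at α without any multiplicity adjustment across the
two components — the familiar conservatism of intersection–union tests;
the realised size at a boundary point (one component at its MAC, the
other well inside) is essentially the single-binomial size. When
several candidate strategies are evaluated at once, no adjustment is
applied across strategies either; each is reported at its own α and the
output says so.

Exact one-sided binomial p-values pair with Clopper–Pearson one-sided
lower bounds: the bound L solves P(X ≥ k | n, L) = α (via the
incomplete-beta inverse, `beta.ppf(α, k, n−k+1)`; L = 0 at k = 0), and
the tail probability is increasing in p, so p ≤ α exactly when L ≥ MAC.
Rejection is therefore equivalent to the graphical criterion "both
one-sided (1−α) lower limits clear their MAC", i.e. the one-sided
rectangular confidence region [sens_lower, 1] × [spec_lower, 1] lies in
the target region. One degenerate corner: with MAC = 0 and 0 successes
the p-value is 1 while the bound (0) still "clears" MAC 0; the
equivalence holds for MAC in (0, 1), which is the meaningful range. A
Wilson-score lower bound is offered as an alternative for reporting;
the exact bound is the default because it is conservative and is the
exact dual of the test.

## Deriving MAC from consequences

Two quantitative constructions are implemented; combining them (e.g. an
LR-based floor plus a positivity cap) is left to the caller, since no
single combination rule suits every pathway.

* **Positivity cap.** The positivity rate of a test with sensitivity s
  and specificity x at prevalence π is πs + (1−π)(1−x). Given a cap r
  (e.g. a maximum acceptable prescription rate) the minimal specificity
  is x = 1 − (r − πs)/(1−π). A cap below πs is infeasible and raises an
  error naming the minimum achievable rate. The
  `per_hundred_integer` mode does the same arithmetic in whole patients
  per 100 — expected true positives rounded first (half away from zero),
  result also reported to the nearest percent — matching how the
  back-of-the-envelope derivation is done in practice (0.35·0.85·100 =
  29.75 → 30 prescriptions; a 40% cap leaves 10 false positives among
  65, specificity 85%). Rounding half away from zero is deliberate:
  round-half-even would turn 29.75 → 30 as well but 30.5 → 30, which is
  not how per-100 clinical arithmetic is done.
* **Minimum LR+.** A required post-test probability t at prevalence π
  needs LR+ ≥ [t/(1−t)]·[(1−π)/π] (Bayes on the odds scale). This
  accepts a triangle Se ≥ LR·(1−Sp) in ROC space, which includes
  clinically useless low-sensitivity points; the rectangle refinement
  adds a sensitivity floor, and the number needed to test (the inverse
  of the positivity rate, exposed on the cohort-expectation object)
  bounds test burden.

## Sample size

Per component, the normal-approximation size for the one-sided test of
H0: p ≤ MAC at expected value p, level α and target power is

    n = ⌈( z₁₋α √(MAC(1−MAC)) + z_pow √(p(1−p)) )² / (p − MAC)² ⌉.

The exact-binomial alternative scans n upward and returns the smallest
n whose exact one-sided test attains the target power — requiring the
target to hold for the following 20 values of n as well, because exact
power is sawtoothed in n and a lucky single n can sit in a notch.
The cohort total is max(⌈n_D/π⌉, ⌈n_N/(1−π)⌉); both per-group inflations
are reported because which one binds depends on the prevalence. At the
reference design (MAC 0.85/0.85, expected 0.92/0.95, α 0.05, power
0.90, π 0.35) this gives 179/76 and a total of 512.

Two caveats are surfaced by `power_at_n` rather than hidden: the normal
formula under-powers slightly at these proportions (exact power at
n = 179 is ≈ 0.87 against the nominal 0.90), and the *joint* power at
the designed sizes is the product of the marginal powers (≈ 0.87 × 0.91
≈ 0.80 at the reference design), below the per-component nominal power
— sizing each component at the target power does not size the joint
claim at that power. α is one-sided everywhere.

## Simulation

`TruthScenario` draws synthetic studies under a known truth. Two
sampling modes: `binomial_prevalence` draws the diseased count
Binomial(n, π) (one consecutive cohort — the realistic design); 
`fixed_margins` pins it at round(nπ) (group-targeted recruitment, and
the mode in which joint power factorizes exactly into the product of
the marginal powers, used as an analytic cross-check). Replicates with
an empty margin cannot reject and are counted as non-rejections and
tallied separately — dropping them would bias power upward when nπ is
small. The generator is numpy's seedable, platform-stable PCG64; its
identity is recorded in every report. Default 10⁴ replicates (95%
Monte-Carlo half-width ≤ 0.98%), configurable down to 10² for smoke
tests.

What the generator emulates — and does not: it produces exactly the
binomial two-margin model the test assumes. Real accuracy data add
imperfect reference standards, verification bias, correlated or
indeterminate results, and between-setting heterogeneity; passing
operating-characteristic checks here validates the statistical
procedure under its own assumptions, not robustness to those features.

## Numerical choices

* Exact tails via `scipy.stats.binom.sf(k−1, n, p)`; bounds via
  `beta.ppf`; z-quantiles via `norm.ppf` (1.6449 at α 0.05, 1.2816 at
  power 0.90).
* Ceilings use `ceil(x − 1e−9)` to absorb float noise at integer
  boundaries.
* Diagnostic odds ratio with any zero cell: 0.5 added to all four cells
  and flagged, keeping the statistic finite and reportable.
* Threshold scan candidates are the midpoints between adjacent distinct
  scores plus ±∞; observations equal to a threshold are classified
  positive in the `higher_positive` direction (closed on the positive
  side), so every achievable 2×2 table appears exactly once.
* Expected cohort counts are kept as reals; display rounding (half away
  from zero) is a separate method.

## Problem sizes used in verification

The test suite checks the Clopper–Pearson/p-value duality exhaustively
for every success count at margins up to 40, validates bounds and tails
against a brute-force bisection/enumeration oracle to 10⁻⁸ for n ≤ 50,
and runs the Monte-Carlo checks at 10⁴ replicates with the reference
margins 179/76. These sizes give sub-percent Monte-Carlo resolution
while the whole suite stays fast enough to run on every change.

## Known limitations

* Single-test, single-threshold evaluation only: no paired or
  comparative designs (relative likelihood ratios), no ROC summary
  measures, no adjustment for imperfect reference standards or missing
  data.
* Predictive values are not primary outputs; the framework is built on
  sensitivity and specificity.
* MAC elicitation by expert survey or formal decision analysis is out
  of scope; the package takes the quantitative consequence statements
  as inputs.
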