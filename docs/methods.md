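# Methods

## Model and analysis unit

The analysis unit is the matched case-control pair and, per hypothesis,
the three-character ICD-10 group (uppercase letter + two digits). Codes
are uppercased and stripped of punctuation before the prefix is taken,
since administrative extracts differ in dialect (`S06.5X1A`, `s065`);
Canadian-extension characters beyond position three are handled by the
same truncation. The full A00–Z99 grid (2,600 groups) defines group
*validity*; the multiplicity family m at every stage is the set of codes
actually observed and testable in the data at hand, not the grid size.

Exposure is binary presence: patient i is exposed to group j if any
emergency-department or acute-care visit in the observation window
carries a code truncating to j. The window runs from `lookback_years`
(default 5, converted to days as round(5 × 365.25)) before the index
date to `washout_days` (default 30) before it, both edges inclusive.
The washout excludes the visit cluster immediately preceding the index
event from the "pre-index" phase; the index admission itself therefore
never contributes exposure. Controls carry their own index date in the
input (a qualifying non-case discharge date); how that date is chosen
when a control has several qualifying discharges is left to the data
supplier, as the package takes the supplied column as-is.

## Matching

1:1, without replacement, exact on sex, income quintile, and
rural/urban residence, with an inclusive 2-year caliper on age. The
algorithm within each exact stratum is greedy nearest-age with the
cases visited in a seeded random order, ties broken by smallest age gap
then lowest control id — chosen for determinism and O(n·k) cost at
population scale. Greedy matching can strand a case that an optimal
assignment would pair; a minimum-total-age-gap variant (Hungarian
algorithm) is available behind `method="optimal"`. Unmatched cases are
always reported, never dropped silently.

## Paired tests and effect estimates

McNemar's χ² without continuity correction is the default, switching to
the exact two-sided binomial test when n10 + n01 < 25 (threshold
configurable). The exact p-value uses the doubling convention
min(1, 2·min-tail), stated explicitly because conventions differ. A code
with no discordant pairs is degenerate — statistic 0, p = 1, flagged —
rather than an error, so screening over thousands of sparse codes never
aborts.

The conditional OR is n10/n01 with a Wald CI on the log scale and
z = 1.96 rather than the exact 0.975 normal quantile; the two differ
only in the fourth decimal and 1.96 is the convention in the kind of
published tables this package is designed to reproduce and invert. Zero
discordant cells are flagged (`zero_cell` / `no_discordant`) and yield
NaN estimates by default; a +0.5 continuity correction to all four cells
is opt-in. Flagged codes are excluded from OR-based relevance filtering
— an infinite OR estimate is evidence of sparsity, not of effect size.

`evaluate.reconstruct_counts` inverts a printed (OR, CI) pair by
exhaustive integer search over (n10, n01), returning the minimal-n01
solution whose forward Wald computation rounds back to the printed
2-decimal values. Published tables that print estimates without counts
can thereby be checked for internal consistency; some printed rows admit
no exact integer reconstruction (rounding in the source), which the
search reports as None.

## Multiple-testing procedures

Bonferroni, BH, and BY are implemented directly from their step-up
definitions in a shared routine: stable sort on p with label
tie-breaks, threshold scan for the largest passing rank, and the
monotone adjusted p-value adj₍ᵢ₎ = min₍ⱼ≥ᵢ₎ min(1, scale·m·p₍ⱼ₎/j) with
scale = 1 (BH) or c(m) = Σ 1/i (BY), so that `adjusted_p ≤ level`
reproduces the step-up rejection set exactly and boundary p-values
(p = threshold) are rejected. Tied p-values necessarily share a fate:
the running minimum propagates the smallest ratio across the tied
ranks. BY(q) ≡ BH(q/c(m)) is an identity of the implementation, checked
property-style, and the whole construction is cross-checked against an
independent library implementation in the tests.

## Screening protocol

Pairs are split 50–25–25 at the pair level by seeded permutation with
largest-remainder rounding (each subset within one pair of its target).
Stage 1 tests every observed, testable code on the training pairs,
applies BY at q = 0.05 with m = number tested, and keeps rejected codes
with OR strictly greater than 1. Stage 2 re-tests the kept set on the
validation pairs with BY at m = |kept|; codes untestable in validation
keep p = 1, still count toward m, and cannot be confirmed. Stage 3
computes ORs and CIs on the test pairs only, sorted descending. The
stage sets nest (confirmed ⊆ relevant ⊆ significant) and the three
stages touch disjoint pairs, recorded in the report's provenance.

## Synthetic cohorts

The generator draws, per code, a control prevalence p0_j uniform on
`prevalence_range` (default 0.005–0.05: a plausible range for
three-character groups over a multi-year window — common enough to be
testable, rare enough to keep discordant counts realistic) and a
planted conditional OR ψ_j, equal to 1 for the null fraction 1 − π₁.
Case exposure probability follows logit(p1) = logit(p0) + ln ψ. Within a
pair, case and control exposures are independent given the code
parameters, which makes E(n10)/E(n01) = ψ exactly — the estimand equals
the marginal OR, so parameter recovery is a clean test. An optional
pair-level frailty (shared logit shift, sd τ, default 0) breaks that
independence for robustness checks.

Cross-code dependence uses a latent Gaussian one-factor block model:
z = √ρ·u_block + √(1−ρ)·ε thresholded at the marginal normal quantile,
giving exact Bernoulli marginals with within-block latent correlation ρ
(default block 50). This is the simplest mechanism that violates the
independence assumption BH relies on, exercising BY's raison d'être.
Protective codes receive ln ψ < 0, reproducing the inverse associations
that care-seeking selection produces in real data — planted directly,
not mechanistically simulated. A fast path samples per-code discordant
counts binomially (valid only at ρ = 0, τ = 0; distributionally
identical to the full path there) and makes thousand-replicate error
rate studies cheap.

What the generator does **not** emulate: realistic per-group ICD-10
prevalence profiles, visit-level coding noise or misclassification,
time-varying exposure, or the selection mechanisms behind collider
codes. Passing tests therefore demonstrate the statistical machinery's
correctness and calibration under the stated generative model, not
robustness to every artefact of real administrative data.

`synthetic_sample_table` is a clearly-labelled synthetic stand-in for an
illustrative per-code results table: it plants, by construction, an
exact number of codes below the BY step-up cutoff (defaults: 1,239
codes, 781 significant, 686 of those with OR > 1) so the adjustment
path can be verified against a table whose answer is known. Its
statistic and CI columns are filled in for format fidelity only.

## Monte-Carlo evaluation

`evaluate_procedure` measures empirical FWER (fraction of replicates
with ≥ 1 false rejection), empirical FDR (mean of V/max(R,1) — zero
when nothing is rejected), and power (mean fraction of non-nulls
rejected) over seeded replicates. Replicate r uses a seed derived from
SeedSequence((root, r)), so procedures compared at the same root seed
see identical data while different roots give independent streams.
Stochastic assertions in the tests allow the target bound plus three
binomial standard errors, bounding the suite's false-alarm rate.

Problem sizes used by the shipped checks: the full-scale FDR study runs
m = 2,600 codes × 2,000 pairs × 200 replicates under block dependence
(ρ = 0.5), and the FWER study 1,000 replicates under the complete null
via the fast path; unit-level studies use a few hundred codes and tens
of replicates, chosen so the whole suite completes in a few minutes on
one core while keeping Monte-Carlo error well below the tolerances
asserted.

## Numerical choices and limitations

- p-values equal to their threshold are rejected (≤, not <) in every
  procedure; fractions in the splitter must sum to 1 within 1e-9.
- The exact/χ² switch at 25 discordant pairs is a convention; results
  near the boundary differ slightly between modes, which matters only
  for codes right at the significance edge.
- Results TSVs format statistics to 2 decimals, p-values to 4
  significant digits (scientific), ORs/CIs to 2 decimals; rounding is
  presentation-only and write→read→write round-trips byte-identically.
- Holm's procedure, q-value estimation, resampling or stratified FDR,
  conditional logistic regression, exact conditional CIs, many-to-one
  or propensity-score matching, and comorbidity interactions are out of
  scope.
- Greedy matching is order-dependent by design (seeded); two runs with
  different seeds can pair different patients while both satisfying the
  constraints.
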