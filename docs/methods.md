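# Methods

This note documents the statistical model, the numerical choices, and the
design decisions behind `adcvigil`, in the spirit of a package vignette.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and cleaning

A *case report* is one version of one spontaneous report: demographics
(sex, age), reporter qualification, seriousness and outcome codes, a
country, one or more drugs with role codes (primary/secondary suspect,
concomitant, interacting) and optional therapy-start dates, one or more
MedDRA preferred-term (PT) events, and an earliest event date. Two on-disk
dialects are supported: the dollar-delimited FAERS quarterly ASCII tables
(DEMO/DRUG/REAC/OUTC/THER joined on `primaryid`; embedded `$` is not
escaped, matching the upstream convention, so fields are split naively)
and a simplified one-row-per-(case, drug, event) CSV. Malformed rows and
orphan rows are counted and logged, never silently dropped; a report with
no events is excluded and counted.

**Deduplication** keeps exactly one record per `case_id`: the greatest
version identifier (numeric comparison when both versions are numeric,
else lexicographic), ties broken by the latest receipt date, and a final
deterministic content fingerprint so the result is independent of input
order. This is the standard caseid/caseversion rule; it is idempotent and
permutation-stable (both property-tested).

**Exposure** is suspect-role only: primary and secondary suspects count,
concomitant and interacting drugs are background. Drug names are matched
against the registry after deterministic normalization (lowercase, trim,
parentheticals and trailing salt words stripped, the 4-letter FDA
nonproprietary suffix removed); there is no fuzzy matching — determinism
is preferred over recall, and the registry carries brand-name aliases to
compensate.

**Component registry.** The packaged registry lists the 14 ADCs approved
through 2024 with antibody subtype, linker type, payload category and DAR
class transcribed from product labels; 13 carry `include=True` and one
(datopotamab deruxtecan, the most recent approval) ships excluded to match
the 13-drug analysis population. DAR classes use `<3`, the closed interval
`[3, 5]`, and `>5`; a numeric DAR, when present, must agree with its class
or loading fails. The PT→SOC map must be total: in strict mode an unmapped
PT aborts the run; in lenient mode it is routed to the sentinel SOC
`Unmapped` — never both silently.

## Contingency tables

For stratum *S* and event *x*, counting is at the report level: a report
contributes to cell `a` when any suspect drug is a member of *S* **and**
*x* is among its events, at most once per (report, event) pair. The
comparator is every other report in the analyzed collection (the usual
full-background convention, which keeps N constant across strata); an
ADC-only background is available via `comparator="adc_only"`. Pooled
component strata count a report naming two member ADCs once (union, not
sum). Tables with `a = 0` are retained but can never become signals; no
continuity correction is applied at the counting stage. The vectorized
tabulation is cross-checked in the tests against a nested-loop recount.

PT-level event tallies (sum over reports of distinct PTs) are reported
separately from report counts throughout, because the two units are easy
to conflate in spontaneous-report work.

## Estimators

Given `a, b, c, d`, `N = a+b+c+d`, `E = (a+b)(a+c)/N`:

| method | statistic | interval | positivity |
|--------|-----------|----------|------------|
| ROR    | ad/bc     | exp(ln ROR ± z√(1/a+1/b+1/c+1/d)), z = 1.959964 | a ≥ 3 and lower bound > 1 |
| PRR    | [a/(a+b)]/[c/(c+d)] | Pearson χ², no Yates correction | a ≥ 3, PRR ≥ 2, χ² ≥ 4 |
| IC     | log₂((a+½)/(E+½)) | IC025 = log₂ of the 2.5% quantile of Gamma(a+½, rate E+½) | IC025 > 0 |
| EBGM   | exp E[ln λ \| a] | EB05 = 5% posterior quantile | EB05 > 2 |

These thresholds are the canonical published criteria for the four
methods; all are configurable. The χ² omits the Yates correction by
default because the PRR ≥ 2 / χ² ≥ 4 rule was defined without it (Yates is
a config switch). The IC uses the additive-shrinkage closed form with a
gamma credible interval rather than the original four-prior Bayesian
confidence propagation network, for determinism and because it is the
variant in regulatory use.

Undefined situations propagate as explicit markers, never silent zeros:
`a = 0` gives ROR 0 with an undefined CI; a zero in `b`, `c` or `d` marks
the ROR infinite with the flag forced off; `c = 0` leaves the PRR infinite
but still flaggable, marked *unstable*; `E = 0` (event absent) leaves IC
and EBGM undefined with flags off.

**EBGM prior.** λ has a two-component gamma mixture prior
(α₁,β₁,α₂,β₂,P), so each count is marginally a mixture of negative
binomials with means λE. The prior is fitted once per run on the
collection of per-drug (ADC × PT) tables — a database-wide shrinkage model
reused for all component strata — by direct maximization of the marginal
log-likelihood (L-BFGS-B on log/logit-transformed parameters, started from
the classical values (0.2, 0.1, 2.0, 4.0, ⅓), convergence tolerance 1e-8).
With fewer than 50 usable tables the configured default prior is used and
a warning logged; hitting the iteration cap raises an error carrying the
last iterate. The posterior is the weighted pair Gamma(αⱼ+a, rate βⱼ+E)
with weights proportional to Pⱼ·NB(a; αⱼ, βⱼ/(βⱼ+E)); EBGM is the
exponentiated posterior mean of ln λ (digamma closed form) and EB05 is
found by monotone bisection of the mixture CDF on the bracket
[1e-8, 10·max(a/E, prior mean)], widened adaptively, to ~30 decimal digits
of interval reduction. Tests cross-check IC025, EB05 and EBGM against
Monte-Carlo quantiles of the stated posteriors and verify prior-mean
recovery from data simulated under a known single-gamma prior.

Two textbook-style monotonicity caveats, discovered while property-testing
and encoded accordingly: with `b, c, d` fixed, increasing `a` also
increases E, so IC and EBGM need not increase on very small tables (they
are monotone in `a` at fixed E, which is what the property test asserts);
and EBGM, being a geometric mean, can fall slightly below both the prior
mean and a/E — the arithmetic posterior mean is the quantity bracketed by
them.

## Consensus, prioritization, sensitivity layer

The multi-method consensus criterion (MCC) is the conjunction of the four
flags; an undefined flag counts as negative. Because it is an
intersection, the consensus set is a subset of every single-method
positive set — asserted on every synthetic run.

Strong signals are the top 20 MCC positives per stratum by ROR, ties
broken by larger `a` then lexicographic PT (making the ranking
permutation-stable); a stratum with at most 10 positives keeps all of them
(the small-class exception, default threshold 10 to cover classes with
about eight positives).

The sensitivity layer computes a two-sided Fisher exact p for every pair
by full hypergeometric enumeration (point-probability rule: sum of
outcomes no more probable than the observed table, the common library
default; verified exhaustively against enumeration for all tables with
N ≤ 40). Benjamini–Hochberg adjustment runs within one stratification
scheme — the narrowest family consistent with testing each
component-type/event combination — with a global-family switch.
Significance is the strict inequality q < 0.05. The concordance report
compares the MCC set against its FDR-significant subset (counts and
Jaccard index); with strong effects the two coincide.

## Baseline descriptives

Percentages use half-up rounding so printed-style cells recompute exactly
from their counts. Categorical group differences use Cramér's V
√(χ²/(N·min(r−1, c−1))) with the χ² p-value; degenerate margins are marked
undefined, and all-zero rows/columns are dropped before the statistic.
Continuous variables pass a Shapiro–Wilk gate at α = 0.05 (on at most
5,000 values per sample; samples under 3 skip the gate): both normal →
two-sample t, otherwise Mann–Whitney U with normal approximation and tie
correction. Quantiles are linear-interpolation order statistics
(config-switchable in spirit; the choice is deliberate since published
tables rarely state one). Age bins are <18, [18, 65), [65, 85], >85 —
chosen to make the conventional printed labels disjoint and exhaustive.

Onset time is the difference in days between the earliest suspect-ADC
therapy start and the earliest recorded event date (spontaneous-report
databases log the date the patient first experienced *any* AE, and this
package mirrors that exactly); missing dates and negative intervals are
excluded and counted separately. Published baseline tables of this kind
can contain internal inconsistencies — a pooled onset median outside the
range of its subgroup medians, or an effect size that does not recompute
from its printed counts — so the package always reports its own
oracle-checked values and never hard-codes a published statistic.

## Synthetic data generator

The generator emulates the structure the estimators assume: independent
reports, one exposure drug per case (a study ADC with probability
`study_share`, default 0.3, else an anonymous background drug), events
drawn with replacement from a background law (zipf with s = 1.1 by
default, or uniform) and de-duplicated within the case, with a
zero-truncated Poisson (λ = 2) number of event draws. A planted effect
multiplies the sampling weight of one PT by `rrr` for cases exposed to a
target drug or component class (classes expand to member ADCs; overlapping
effects take the maximum).

Default marginals are chosen to resemble large oncology spontaneous-report
cohorts: ≈55% female / 27% male, ≈80% serious with outcome codes drawn
death 22.7% / hospitalization 21.7% / life-threatening 3.3% / disability
0.8% / other 51.5%, ≈76% healthcare-professional reporters, ≈47% missing
age (normal(59, 16) clipped to [0.2, 110] otherwise), and a US/JP/FR/CA/CN
-heavy country mix. Onset times are exponential with a configurable median
(default 26 days); each of the two dates is independently blanked with
`missing_date_fraction` (default 0.3 — real onset data are heavily
missing) and a small fraction (default 2%) is made implausible (event
before therapy start) to exercise the exclusion rules. `duplicate_fraction`
of cases are re-emitted with an incremented version and a later receipt
date.

Randomness flows from a single numpy generator seeded with `SimConfig.seed`
and the generation is fully vectorized; identical seed + config gives
byte-identical output files (tested). Vectorized single-stream generation
was chosen over per-case counter-derived streams to keep 200-replicate
calibration suites fast; the reproducibility contract is unchanged.

Deliberately not modelled, hence not demonstrated by passing tests:
reporting biases (notoriety, masking/competition), time-varying reporting
rates, correlated multi-drug exposures (multi-drug cases appear only in
hand-built fixtures), country effects, and real MedDRA vocabulary — the
simulated PT→SOC map assigns synthetic PTs round-robin to the 27 real SOC
names. Results on synthetic data validate the machinery, not the
epidemiology of any real drug.

## Problem sizes in the test and acceptance suites

The suites run comfortably on one CPU: null calibration uses 200
replicates of 5,000 cases (30 events, 15 background drugs, drug-level
stratification); planted-signal recovery uses 50 seeds of 10,000 cases
with one rrr = 20 effect (expected exposed-event count in the hundreds);
prior recovery fits 100,000 simulated tables; the Monte-Carlo posterior
oracles use 10⁶ draws per grid point on (a, E) ∈ {1,3,10,100} ×
{0.1,1,10}; the Fisher oracle enumerates all ~136,000 tables with N ≤ 40.
`scripts/acceptance.py` uses 10 planted and 20 null replicates.

## Known limitations

- Exact per-drug DAR values differ between label revisions; the registry
  pins one value per drug and validates class consistency, but users with
  different conventions should supply their own registry CSV.
- The Wald ROR interval is poor at very small counts; the a ≥ 3 rule
  guards the flag but the printed interval is still Wald.
- The EBGM mixture likelihood is multimodal; the fit starts from the
  classical prior and is not multi-started. Parameter *recovery* is only
  asserted for the prior mean, which is what shrinkage depends on.
- BH control is proven under independence/PRDS; contingency tables across
  strata share reports and are not independent. The null-calibration suite
  measures the realized false-discovery proportion empirically instead of
  assuming it.
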