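# Methods

This note documents the models, conventions and design choices behind
`pvsignal`, in the spirit of a statistical package's model documentation:
what is computed, under which assumptions, and what the validation on
synthetic data does and does not establish.

## Data model and ingestion

A spontaneous report is one case version: case identifier, version number,
receipt date, drugs (name, suspect/concomitant role, route, indication PT,
therapy start), a non-empty list of reaction PTs with optional onset dates,
demographics (sex, age, country, reporter type), and FAERS outcome codes
(DE, LT, HO, DS, CA, RI, OT).  Reports without any reaction are dropped at
ingestion (with a logged count): every downstream quantity conditions on at
least one adverse event.

FAERS dates come in three precisions (YYYY, YYYYMM, YYYYMMDD).  Receipt
dates with at least month precision are usable for quarter assignment
(month-precision dates are anchored to the first of the month); year-only
receipt dates have no quarter and fall outside any quarter window.  Event
and therapy dates must be full dates to be used — day-level arithmetic on a
partial date would be fabricated — otherwise they are missing, and the
affected report lands in the "unspecified" time-to-onset bin.

Drug-name standardization is an exact lookup (case- and
whitespace-insensitive) in a synonym table mapping raw strings (trade
names, spelling variants) to canonical ingredient names; unmatched strings
pass through unchanged and are logged once.  This deliberately replaces
NLP-based name normalization with a transparent, auditable table.

### Deduplication

Two stages, both deterministic:

1. **Version collapse.**  One report survives per case identifier: the
   highest version, ties broken by latest receipt date, then first input
   position.
2. **Cross-identifier collapse.**  Reports with distinct case identifiers
   but identical (sex, age, country, drug-name set, PT set, event-date
   multiset) collapse to the earliest received.  Matching is exact — no
   fuzzy similarity — and only reports whose verification fields are
   *complete* (sex specified, age and country present, at least one event
   date) participate.  The completeness requirement is essential: fields
   that are absent cannot verify a duplicate, and without it, distinct
   cases sharing an all-"not specified" profile and a common single PT
   would be merged wholesale (about 0.5% of cases in synthetic databases).

Deduplication is idempotent and order-preserving.

### Cohort extraction

The analysis cohort contains every deduplicated in-window report carrying
the target drug as a *suspect* drug with an indication in the configured
set; all other in-window reports form the background.  The two sets
partition the in-window reports.  The background intentionally includes
target-drug reports for other indications: those are excluded from the
cohort, not from the database.

## Contingency tables

The counting unit is the distinct (report, event) pair: a PT repeated
within one report counts once, and at SOC level a report counts once per
distinct SOC among its PTs.  For each event with at least one cohort
report, the table is `a` (cohort, event), `b = |cohort| − a`, `c`
(background, event), `d = |background| − c`, with `N = a+b+c+d` and
`E = (a+b)(a+c)/N`.  Tables are crude (no age/sex/year stratification).
Any minimum-count gate (the `a ≥ 3` signal condition) is applied at
evaluation time so descriptive outputs stay complete.

## Disproportionality statistics

**ROR and PRR** use the standard point estimates and log-scale Wald
intervals with z = 1.96 (formulas in the README).  Zero cells make them
non-computable; no continuity correction is applied, because silent
corrections distort rankings and the `a ≥ 3` gate already removes the
cases where a correction would matter.  The corresponding signal flag is
then false, with the reason recorded on the result.

**BCPNN information component.**  The implemented IC is the shrinkage form
`IC = log2((a+½)/(E+½))` with the credibility approximation
`IC025 = IC − 3.3(a+½)^{−1/2} − 2(a+½)^{−3/2}`.  This variant was chosen
over the original multivariate-Beta formulation because it is
deterministic, standard in modern practice, and exactly testable: it is
the posterior-mean summary of `λ | a ~ Gamma(a+½, E+½)` under a
Jeffreys-style gamma prior on the relative reporting rate.  The package
ships a seeded Monte-Carlo oracle that samples that exact posterior
(`IC = log2 λ`) as an independent validation route.  The closed form logs
the posterior mean of λ while the oracle averages `log λ`, so they differ
by O(1/a) — about 0.07 bits at a = 10 — and converge as counts grow; the
oracle is *not* a Monte-Carlo estimate of the Beta-marginal BCPNN, whose
estimand differs from the shrinkage IC by ~0.5 bits at small counts and
would validate a different statistic.

**MGPS / EBGM.**  Counts follow `a ~ Poisson(λE)` with the two-component
gamma mixture prior on λ.  The prior is fitted by maximizing the marginal
likelihood — a two-component negative-binomial mixture — over all
(suspect drug, PT) cells of the database, zeros included, on log/logit
transformed parameters with L-BFGS-B from the canonical start
(0.2, 0.1, 2, 4, ⅓) plus four seeded random restarts; the best restart
wins and total failure is a hard error.  The posterior per cell is a
gamma mixture with components `Gamma(αᵢ+a, βᵢ+E)` and likelihood-updated
weights; `EBGM = exp(Σᵢ qᵢ (ψ(αᵢ+a) − ln(βᵢ+E)))` via the digamma closed
form, and the lower bound solves the posterior CDF by Brent root-finding
to relative tolerance 1e-8.  The lower bound defaults to the conventional
EB05 (5th percentile); a 2.5th-percentile option exists because "lower
limit of the 95% CI" is ambiguous between the two in parts of the applied
literature — results tables should state which was used.

### Signal criterion

All four per-method thresholds (README) must hold simultaneously,
evaluated on full-precision values; display rounding to 2 decimals happens
only at CSV export.  All inequalities are implemented exactly as stated,
including the point-estimate requirement `ROR ≥ 3` (stricter than the
common `ROR_lo > 1`-only rule).  The intersection criterion is
deliberately conservative: on null synthetic databases the combined
false-positive rate among events with `a ≥ 3` is far below 1%.

## Descriptive summaries

Percentages round half-up to 2 decimals.  Denominators are documented per
block because no single convention fits all: whole cohort for sex, age
bands, reporter, country, route and year; the cohort again for
time-to-onset bins (so the "unspecified" share is visible), with the
median/IQR computed over classifiable rows only; the number of outcome
*entries* for outcome codes, since reports may carry several.  Quantiles
(age, TTO) interpolate linearly between order statistics.  TTO is the
earliest event date minus the earliest therapy start of the target drug,
in whole days; negative or incomputable values are "unspecified"; bins are
half-open and lower-inclusive (`[0,7), [7,28), [28,60), [60,∞)`), pinning
down the boundary ambiguity of printed ranges like "7–28"/"28–60".
Per-SOC fatality counts a report toward every SOC its PTs map to, flags it
fatal when outcomes include DE, and omits SOCs with no cohort reports.

## Synthetic databases

The generator draws per-report PT incidence as independent Bernoullis from
a ~50-term catalog whose rates (0.002–0.09 per report) are shaped like a
biologic's event mix in an inflammatory-bowel-disease population; planting
multiplies the cohort rate of chosen PTs by a configured ratio.  Reports
that would have no reaction are redrawn, which conditions the marginals on
non-emptiness: each empirical rate converges to `r/(1−p₀)` with
`p₀ = Π(1−rⱼ)`, not to the raw `r` — tests check against the conditional
value.  Default sizes are 5,000 cohort / 100,000 background reports with a
10% duplicate-resubmission rate; duplicates are re-emitted as version 2 of
the same case.  Demographics, missingness ("not specified" shares), route
mix, reporter mix and outcome rates are set to resemble a published
ustekinumab/Crohn's-disease cohort characterization (e.g. ~37% missing
age, ~7% unspecified sex, ~80% subcutaneous route, cardiac SOC with the
highest fatality rate); time-to-onset is log-normal with median 80 days
and log-SD 2 (upper tail clipped at 100 years so dates stay on the
calendar).  Each field group draws from its own stream split off the
master seed, so adding a field never perturbs other groups, and identical
configs serialize byte-identically.

A detected planted signal on this generator demonstrates that the
pipeline's plumbing and statistics work under ideal reporting; it does not
demonstrate robustness to real FAERS phenomena the generator deliberately
omits (stimulated reporting, the Weber effect, coding drift, correlated
PT co-reporting, indication-dependent demographics).

One quantitative consequence of the design is worth flagging: a planted
rate ratio of 10 does *not* produce EBGM ≈ 10.  The cohort's own elevated
counts inflate the event's database-wide margin and hence `E`, and
shrinkage pulls the estimate further toward the prior; with the default
sizes the planted pair lands near EBGM ≈ 7 (and ROR ≈ 11).  The ROR, whose
comparator excludes the cohort, is the statistic that recovers the planted
ratio most directly.

## Problem sizes and numerical conventions

Validation runs use: 20,000 cells for mixture-prior recovery and 5,000 for
the null-calibration fit; 2×10⁵ posterior draws for the IC oracle and 10⁶
for the EB05 quantile check; a 5,000/100,000-report database for the
planted-recovery pilot and twenty 1,500/15,000 databases for the null
false-positive rate — sizes chosen so every statistical check has
comfortable resolution while the whole suite stays interactive.  Ties in
signal ranking break by the secondary key (report count vs ROR) and then
event name, making all orderings total and reproducible.  CSV outputs are
written to a temporary directory and moved into place only on success, so
a failed run leaves no partial outputs.

## Known limitations

* Exact-match deduplication cannot catch near-duplicates with
  transcription differences; real FAERS curation does fuzzier matching.
* Crude (unstratified) tables; confounding by age/sex/year is untouched.
* The packaged PT→SOC table is a toy stand-in for licensed MedDRA; any
  real analysis must supply a proper dictionary export.
* No multiplicity adjustment across events — standard for screening, but
  the outputs are hypothesis-generating, not confirmatory.
* The negative-binomial mixture likelihood is fitted on all cells of one
  database snapshot; very small databases (few drugs or events) give the
  prior little to learn from, and EBGM then shrinks aggressively.
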