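# Methods

## Problem and model

`phenomatch` addresses case ascertainment when a phenotype is
under-coded in billing data. The model has three layers:

1. **Latent status.** Each patient carries an unobserved Bernoulli case
   status with marginal prevalence π. Observed coding is a noisy,
   one-sided censoring of that status: a latent case is ever coded with
   probability σ (the coding sensitivity), and a non-case is never
   coded. There is no over-coding in the model — a case-definition code
   is taken at face value.
2. **Comorbidity signal.** Each comorbidity code *B* is assigned per
   patient by an independent Bernoulli draw at baseline rate ρ₀ for
   non-cases and min(1, r·ρ₀) for latent cases. Conditional
   independence of codes given latent status is the default; the mining
   statistic is pairwise, so no higher-order structure is needed for
   the method to be exercised. The implied posterior is

       P(latent | B) = r·ρ₀·π / (r·ρ₀·π + ρ₀·(1 − π)) = rπ / (rπ + 1 − π)

   and the observed conditional probability P(coded case | B) converges
   to σ times a closely related quantity; both are verified empirically
   against the generator.
3. **Ascertainment by matching.** A logistic model estimates
   P(coded case | covariates); comparators (never-coded patients) whose
   propensity logit sits close to a case's are claimed as matches.
   Because the covariates carry the comorbidity signal and latent
   uncoded cases have case-like comorbidity profiles, matched
   comparators are enriched for latent cases. That enrichment — the
   prevalence ratio of latent status between matched comparators and
   the whole comparator pool — is the quantity the pipeline is designed
   to drive above 1, and the evaluation stage measures it directly
   against the generator's truth table.

## Pipeline stages and their conventions

**Case definition.** A codeset file lists exact ICD-10-CM codes and
`PREFIX*` families, each tagged ideation / self_harm / attempt /
history_of_self_harm. Codes are canonicalised by dot-stripping and
uppercasing. History-of-self-harm entries count toward case status and
fold into the self-harm subtype. Patient grain is "ever coded"; the
encounter grain flags only codes on that encounter. The shipped
reference codeset is a synthetic stand-in built from the
intentional-self-harm prefix families (X71–X83) plus the individually
documented ideation (R45.851), attempt (T14.91 family) and
self-harm-history codes; the file is the source of truth and users with
access to a fully enumerated published codeset should substitute it via
`codeset_path`.

**Comorbidity mining.** Counting is at patient grain (a code and case
status co-occurring in the same patient, not necessarily the same
visit). Strata are one axis at a time: overall, each age band, each
sex, each subtype (for subtype strata the case event is restricted to
that subtype; the universe stays full). The processing order is fixed:
support filter first (codes in fewer than `min_patient_support` = 20
patients are dropped; exactly 20 is retained), then top-k (k = 20) by
conditional probability, with ties broken by joint count then
lexicographic code. The chi-square test reconstructs the 2×2
(B × case) table from the four patient counts and applies Yates'
continuity correction by default (`yates: false` disables it; the
uncorrected statistic is the right reference when comparing rejection
rates to a nominal α, since the corrected test is deliberately
conservative). The Bonferroni family m is the number of tests actually
reported — all filtered, top-k rows across strata — and is logged with
every run. "Top-scoring" means highest conditional probability;
`rank_by: chi2` is available because either reading is defensible.

**Feature matrix.** One row per patient at an index encounter: for
cases, the first encounter carrying a case-definition code (so the
features describe the patient *as of* ascertainment); for comparators,
the last in-window encounter by default (maximising accumulated
history; `comparator_index: first` gives the conservative alternative).
Every feature uses only information dated on or before the index date:
age-band/sex/race indicators, count of strictly-prior encounters,
note-type counts up to and including the index visit, DSM-5 category
indicators (longest-prefix mapping, `unmapped` excluded), and
indicators for the selected comorbidity codes. Patients matching the
case definition never contribute comparator rows.

**Propensity and matching.** The logistic fit standardises non-binary
columns internally and applies a small ridge penalty (λ = 10⁻⁴ on the
standardised scale) by default: rare significant code indicators make
complete separation a real risk, and the penalty keeps coefficients
finite without materially biasing them at the sample sizes used. With
λ = 0 a saturated fit raises an explicit separation error. Scores are
clipped to [10⁻¹², 1 − 10⁻¹²] before the logit. Matching is greedy 1:1
nearest-neighbour without replacement on the logit, cases processed in
a seeded random order; ties break toward the lower logit then the
smaller id, so results are independent of comparator input order. No
caliper by default; one can be set in logit units. k > 1 and matching
with replacement are flags.

**Evaluation.** Percentages are rounded half-away-from-zero to one
decimal. The two-proportion z test uses the pooled-variance form (its
square equals the uncorrected chi-square on the same table). Odds-ratio
intervals are Wald on the log scale with Haldane–Anscombe +0.5 applied
(and flagged) when any cell is zero.

## Generator defaults (the emulated study conditions)

| Parameter | Default | Rationale |
|---|---|---|
| n_patients | 20,000 | scaled-down cohort; large enough for stable stratum counts |
| study window | 2016-06-01 – 2022-06-01 | six-year extract |
| π (latent prevalence) | 0.07 | yields coded patient prevalence ≈ 3.7% at σ below |
| σ (coding sensitivity) | 0.534 | roughly half of true cases ever coded |
| subtype mix | ideation 0.862, self-harm 0.390, attempt 0.067 | subtype frequencies among coded cases; subtypes co-occur |
| sex | male 0.5165 / female 0.4825 / unknown 0.001 | near-even pediatric ED mix with a small unknown level |
| age | 51.9% aged 6–11 at first visit | two-band pediatric split |
| encounters | 1 + Poisson(0.52) per patient | ≈ 1.5 visits/patient |
| risk multipliers | 2× female, 4× adolescent | demographic asymmetry in latency, renormalised to keep the marginal at π |
| planted codes | 16 risk codes + 6 null codes | ρ₀ spanning 0.003–0.16; r back-solved from target conditional probabilities via r = (1−π)p/(π(1−p)) |

The demo configuration uses n = 5,000 so a full run completes in
seconds; the simulation studies in the tests and the acceptance script
use n = 20,000 and ten seeds, sizes at which every property checked has
comfortable Monte-Carlo margin.

What the generator emulates: a pediatric ED population with two age
bands, under-coding, demographically skewed latency, planted pairwise
comorbidity structure, note-type utilization correlated with latency.
What it does not: realistic national code-frequency distributions,
correlated comorbidity codes, per-encounter coding noise, longitudinal
disease progression, over-coding, or free-text evidence. Passing tests
therefore demonstrate that the pipeline recovers planted pairwise
structure under one-sided patient-level under-coding — not that it
would achieve any particular yield on real data, where unmeasured
confounding and coding-practice drift are untested.

## Numerical choices

- All randomness flows from one `numpy` Generator per stage;
  the global seed fans out via `SeedSequence(entropy=seed,
  spawn_key=(stage_index,))`, so stages are independently re-runnable
  and every derived seed stays below 2³¹.
- Degenerate 2×2 tables (a zero marginal) are not errors: the test
  reports chi² = 0, p = 1 with a `degenerate` flag and cannot become
  significant.
- lbfgs occasionally stops at the iteration cap with a numerically
  negligible gradient on near-collinear indicator blocks; the fit is
  accepted when the gradient norm is below 10⁻⁴·n, and rejected (with
  the gradient norm in the error) otherwise.
- Report files are written with deterministic column order and row
  sort; reruns at a fixed seed are byte-identical, which the manifest's
  SHA-256 digests make checkable.
- Ages are completed calendar years; bands are closed on both ends.
  Synthetic birth dates are placed ≥ 2 days away from a band-crossing
  anniversary so later visits cannot silently leave the age range.

## Open design choices made here

- Row grain for matching is one row per patient at an index encounter
  (matching the patient-level case counts the method reports), not one
  row per encounter.
- Patients with missing or unrecognised sex/race are retained under an
  `unknown` level rather than dropped.
- A patient's stratum age band is taken at their first in-window
  encounter.
- The comparator pool is every patient never matching the case
  definition, with no further exclusions.

## Limitations

- Enrichment is measurable only against a truth table, i.e. on
  synthetic data; on real extracts the evaluation stage reports the
  observable summaries (score distributions, balance) and omits
  enrichment with a notice.
- Greedy matching is order-dependent by construction; the seeded case
  order makes it reproducible, not optimal. An optimal-assignment
  variant is a natural extension and deliberately out of scope.
- The Bonferroni family counts only reported tests; screening implicitly
  performed by ranking (top-k selection) is not separately corrected,
  which mirrors common practice but is anti-conservative in principle.
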