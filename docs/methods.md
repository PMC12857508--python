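# Methods

## Scope and unit of analysis

`panelattr` operates on outpatient claim lines in two dialects — carrier
(professional services) and outpatient facility — restricted to the medical
HCPCS range 90281–99607 (purely numeric 5-digit codes; alphanumeric codes
are outside the range by definition), with evaluation-and-management (E&M)
services identified as 99201–99499. Both range checks are inclusive. The
unit of analysis for attribution is the *encounter*: all retained claim
lines for one patient with one provider identifier on one service date.
Fees are summed across the distinct lines of an encounter, and the
encounter is E&M if any constituent line is. Exact duplicate claim records
— a known artifact of encounter data feeds — are collapsed before fees are
summed, so duplicate injection leaves both encounter counts and fee totals
unchanged.

When a carrier claim and an outpatient claim share (patient, HCPCS code,
service date), the two records are taken to describe the same service; the
outpatient record is suppressed so the carrier record — which carries the
richer clinician fields — represents the encounter. Carrier records are
never suppressed, and an outpatient claim is suppressed at most once.

## Provider enrichment

Every claim receives an *assigned NPI* from the first present **and
check-digit-valid** identifier in its dialect's fallback order (carrier:
line performing → base rendering → organization; outpatient: base attending
→ organization). Invalid identifiers are treated as missing so that a
corrupted field falls through to the next source rather than polluting
attribution. NPI validity means: 10 digits, leading digit 1 or 2, and a
correct Luhn check digit computed over the 80840-prefixed 9-digit base.

Specialty codes resolve through four steps, each attempted only when all
earlier steps fail, with a provenance tag recording the winning step:

1. the specialty code recorded on the claim;
2. the assigned NPI matched to the annual NPI→specialty roster at the
   claim's calendar year — if that year is absent for the identifier, the
   nearest earlier year within two years is used (annual roster files lag
   the claims they describe); the match is attempted for every assigned
   NPI, including organization-sourced ones, since a successful roster match
   indicates the organization field actually carried an individual's NPI;
3. the organization taxonomy code on the claim, translated through the
   taxonomy→specialty crosswalk;
4. the assigned NPI's registry primary taxonomy, through the same crosswalk.

A crosswalk that maps one taxonomy to conflicting specialties is rejected at
load time. Specialty codes are opaque strings validated only against the
designation reference (PCP / SCP / APP / OTHER); the bundled default
reference uses real CMS specialty and taxonomy code values but any CSV with
the documented columns can be supplied. Entity type (individual vs
organization) comes from the registry; identifiers absent from the registry
are `unknown`.

When constituent lines of one encounter disagree on designation (possible
when specialty sources differ), the modal designation wins, with ties broken
by the priority PCP > SCP > APP > OTHER — favouring primary-care
sensitivity. The encounter's specialty code is likewise the modal resolved
code, ties broken lexicographically.

## Attribution

A patient-year is *gated* on data completeness: at least
`completeness_threshold` (default 0.5, inclusive) of the patient's medical
encounters that year must be *mapped* — carry both a provider identifier and
a resolved specialty. The gate is always evaluated over medical encounters,
even when the method then attributes on E&M encounters only, and it is
evaluated per year used: a patient failing the current-year gate can still
be attributed from a prior year that passes. Patients with zero medical
encounters fail with reason `no_eligible_encounters`.

Within the gated, in-scope encounter set, the patient is attributed to the
identifier with the plurality of encounters; count ties break by total
standardized fee (resource intensity), and residual double ties by smallest
identifier string, so results are order-independent and reproducible. Two
alternative tiebreak modes exist: `FEE_THEN_COUNT` (resource intensity
primary, count secondary, then smallest identifier) and `COUNT_ONLY`, in
which an unbroken count tie leaves the patient unattributed. An unbroken
tie terminates the patient's entire tier sequence — later tiers and the
lookback year are not consulted — so the set of patients attributed without
the fee tiebreak is exactly a same-identifier subset of the baseline
method's, which is the property that makes tiebreaker-elimination a clean
sensitivity probe.

Tier order for the hierarchical scope with lookback is current-PCP →
current-ALL → prior-PCP → prior-ALL: the current year is exhausted before
looking back, because lookback is defined as conditional on current-year
failure. (The alternative ordering that prefers prior-year PCP evidence over
current-year specialist evidence is available via `prior_pcp_first` but is
not the default.) Lookback re-runs the full tier sequence on the prior
year's data alone; the two years are never pooled. `app_as_pcp` widens only
the PCP tier/scope, not the MDs-only scope.

Practice-level attribution (`level="TIN"`) re-aggregates NPI-level
encounters to (patient, billing TIN, date), so clinicians of one practice
seen the same day merge into one practice encounter; mapping at TIN level
requires a TIN and a resolved specialty. The two-stage variant
(`TIN_THEN_NPI`) first finds the plurality TIN, then re-runs the plurality
rule over NPI-level encounters restricted to that TIN; if the winning
practice has no mapped clinician-level encounters the patient ends that tier
unattributed. A TIN-attributed identifier's entity type is reported as
`unknown` — a TIN is not an NPI, so registry entity types do not apply — and
the organization-NPI share metric is meaningful only for NPI-level runs.

When every tier fails, the reported reason comes from the current (primary)
year — gate failure, empty candidate set, or unbroken tie — except that a
tie anywhere in the sequence reports `tie_unbroken`, since it is the most
informative outcome.

## Metrics

Fraction attributed = attributed patients / enrolled patients for the year.
Stability = among patients attributed in year *t* **and enrolled in year
t−1**, the share attributed to the same identifier in t−1; prior-year
non-attribution counts as not-same, which deliberately penalises methods
that only attribute intermittently. Patients not enrolled in the prior year
are excluded from the stability denominator. Empty denominators yield a
missing value, never 0. Stability conflates true affiliation churn with
spurious attribution; it is a relative measure for comparing methods, not an
accuracy estimate — which is precisely why the synthetic generator, where
truth is known, complements it with a direct recovery rate.

## The synthetic generator

The generator emulates what the method consumes, not real file layouts:
an enrollment roster; single-designation practices, each with a TIN, an
organization NPI and an organization taxonomy; individual providers with
valid NPIs, specialties drawn from the bundled designation reference, and
roster entries for every simulated year (organization NPIs are enumerated
in the registry but deliberately never rostered, so the taxonomy fallback
path is exercised); and claim lines derived from visits.

Each patient-year has exactly one true affiliated provider, drawn by
designation weight (default 70% PCP, 15% SCP, 15% APP) and kept from year to
year except with probability `churn`, when a different provider is drawn.
Visits go to the true provider with probability `concentration` (default
0.6) and otherwise scatter uniformly over a random designation — the
simplest model that makes plurality recovery tunable. Visit counts per
patient-year are zero-inflated Poisson (default mean 6, 5% visit-free), each
visit becomes one carrier (70%) or outpatient line plus occasional extra
same-day lines (20%) and paired facility claims (15%), the latter exercising
carrier/outpatient suppression. Fees are gamma-distributed with
designation-specific means (PCP $120, SCP $210, APP $90, OTHER $70; facility
$60) so fee tiebreaks are non-degenerate. HCPCS codes are drawn from the
medical range with `em_share` (default 0.55) in the E&M range.

Field-level missingness is applied as independent per-field Bernoulli masks.
All randomness flows from one root seed through named substreams (provider
synthesis, cohort, visit structure, one per missingness field), which gives
two guarantees: identical (spec, seed) runs are byte-identical, and changing
one presence probability re-thresholds the *same* uniforms, so realized
presence is exactly monotone in the parameter — the property behind the
completeness-ordering tests. Independence of the missingness fields is an
assumption; correlated missingness (e.g., specialty and NPI missing
together) is not modelled.

Two scenario presets define the plan-type comparison conditions.
*MA-like*: clinician NPI on roughly two-thirds of claims, specialty recorded
on 10%, organization-NPI field carrying an individual NPI 55% of the time,
30% annual churn, visit-free years rare (5%), mean 6 visits. *TM-like*:
near-complete fields (95–99%), 8% churn, 18% visit-free, mean 4.5 visits.
These encode the substantive contrast — managed-care populations have more
regular provider contact but weaker clinician ties and worse provider-field
completeness — and the package's tests assert only the directional pattern
this implies (higher fraction attributed, lower stability for MA-like),
comparing per-method means over 10 seeds.

What passing tests on this generator do **not** show: robustness to
correlated missingness, to invalid-but-plausible identifiers at scale, to
clinicians changing practices mid-year (affiliations are annual), to
alphanumeric HCPCS usage patterns, or to real-world duplicate structures
beyond exact copies.

## Problem sizes and numerical choices

The test suite runs cohorts of 60–2000 patients; the oracle-equivalence
layer cross-checks the vectorized engine against a pure-Python brute-force
implementation on 50 random cohorts of ≤20 patients with adversarial
small fee/count sets that force ties; ground-truth recovery uses 2000
patients with ≥5 visits at concentration 0.8, where a binomial argument
makes ≥99% recovery the expected outcome. The acceptance script uses 800
patients per scenario. Fees in tie-sensitive tests are multiples of 50 so
float summation is exact; production fee comparisons use exact float
equality, which is intended — a tie in real currency amounts is an exact
event. Dates are ISO strings throughout, avoiding timezone and dtype
round-trip hazards in CSV artifacts.

## Known limitations

- Standardized fees are an input column; no fee schedule is computed.
- No risk scoring, geographic appends, or population descriptives.
- Prospective attribution and episode-based specialist attribution are out
  of scope; custom specialty sets cover the specialist-scope use case.
- The stability definition requires prior-year enrollment; studies using a
  prior-year-attribution denominator will report different levels (the
  ordering of methods is typically unaffected).
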