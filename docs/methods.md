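# Methods

## Problem and design

The package answers a case-ascertainment question: given one year of
tabular ED extracts (visits with reason-for-attending text, specialty chart
notes, laboratory results, discharge diagnoses), find every acute
intoxication visit and characterise the yield of each search channel.  The
pipeline has four stages — arm-level search, combination with overlap
control, rule-based adjudication, statistics — each usable on its own, all
deterministic.

## Matching rules

All text is Unicode-casefolded and tokenized at non-alphanumeric
characters.  Three concept kinds:

* **whole-token** (`drug`, `fire`): the token must match exactly, so
  `drugstore` and `firearm` are not hits;
* **prefix wildcard** (`intox*`, `hypoglycem*`): any token *starting* with
  the stem matches (`intoxicated`), but the stem inside or at the end of a
  longer token does not (`detox`);
* **phrase** (`per mille`, `impaired consciousness`, `blood test for
  poison`): contiguous token sequences, wildcard allowed on the final word.

Reason keywords use the same machinery (a `substring` mode is exposed in
configuration for sites whose triage text conventions require it; the
tokenised mode is the default because unrestricted substring matching
over-triggers on compounds).  The free word search scans chart headings and
bodies of all six specialty streams by default (general practice, surgery,
internal medicine, pulmonology, neurology, external referrals).  Negation
("denies alcohol use") is deliberately *not* handled at search time: the
search stage is a high-sensitivity screen and rejection is the
adjudicator's job, mirroring how a manual review follows an automated
query.  No stemming, lemmatisation or fuzzy matching is attempted; the
packaged lexicon ships English surfaces with a `variants` mechanism through
which a site supplies inflections or synonyms for its own language.

The ICD-10 arm matches at the three-character category level: a code
specification lists single categories, `#`-marked categories and inclusive
ranges (`T51-T65`); every category matches any of its subcodes (`F10`
matches `F10.2`).  The `#` marker is treated as a display convention for
"any subcode", which is how the default specification's arithmetic reaches
exactly 43 categories (8 F + 10 X00–X09 + 6 X44–X49 + X69 + T36 + T40 +
T50 + 15 T51–T65); whether neighbouring T37–T39 categories were ever
intended cannot be settled from a printed list, so the expansion is kept
literal and user-overridable.

The laboratory arm hits on a qualitative screen flagged positive or a
quantitative value strictly above the analyte's reporting threshold
(default 0, so any measurable ethanol is suspicious).  The default panel
covers ethanol (blood mmol/L and breath ‰), urine screens for amphetamines,
benzodiazepines, cannabinoids, opioids and cocaine, serum paracetamol and
an antidepressant screen; it is a configurable stand-in for a site-specific
analyte list and carries each analyte's substance class, unit, kind and
threshold.

## Overlap control and Venn bookkeeping

Candidates deduplicate on (patient identifier, calendar date): two visit
rows of one patient on one date collapse to one candidate (canonical id =
smallest visit id), keeping the union of their hits.  Midnight-spanning
visits therefore count once per calendar date — a known simplification of
date-keyed overlap control.  `venn_regions` partitions candidate visits by
the exact set of arms that hit them; patient-level regions take the union
of arms over a patient's confirmed visits.

## Adjudication

The manual-review criteria are codified as a deterministic rule engine over
structured evidence fields (per-visit booleans and lists supplied alongside
the extracts; free text is never re-interpreted at this stage).  A
candidate is confirmed iff at least one of:

1. a positive laboratory finding for a non-ethanol intoxicant;
2. a documented antidote response (e.g. flumazenil), which also counts the
   substance as used;
3. a documented history of use/exposure together with clinical signs of
   intoxication;
4. ethanol with an AAI grade of at least mild; the paramedic-report BAC is
   used when no in-hospital value exists.  A subthreshold BAC (< 10.9
   mmol/L) confirms only with both signs and history and no other
   intoxicant in play.

`history_of_use` is read broadly as a documented exposure/ingestion
history, which is what lets purely accidental poisonings (carbon monoxide,
envenomation, medication error) confirm under rule 3.  Rejection is a
value, not an error, and adjudication is order-independent across visits.

**Units and grading.**  21.7 mmol/L ≡ 1.00 ‰ anchors the conversion;
display values round half-up to two decimals (half-up throughout the
package, because the reporting convention for percentages and per-mille
values is ties-away-from-zero, not banker's rounding).  AAI intervals are
half-open on mmol/L — subthreshold [0, 10.9), mild [10.9, 21.7), moderate
[21.7, 65.1), severe [65.1, ∞) — which reconciles printed labels such as
"mild up to 21.6" with "moderate from 21.7", and "severe > 65.1 mmol/L"
with "≥ 3.00 ‰".  AAI of any grade additionally requires the
`signs_present` flag (clinically significant behavioural or psychological
changes); how strong those signs must be is not quantified anywhere
authoritative, so the engine accepts a boolean rather than inventing a
symptom scale.  Breath-test readings in ‰ are normalised through the same
anchor.

**Primary intoxicant.**  The clinical criterion is toxicity *and*
correlation to the documented symptoms.  A static class ranking alone
cannot express that (a sedative found incidentally on a screen must not
displace the ethanol that explains the presentation), so each evidenced
substance is scored lexicographically by (symptom-correlated flag, toxicity
weight), ties broken by ranking order.  The default toxicity order — other
toxins > opioids > other pharmaceuticals > amphetamines > cocaine >
benzodiazepines > ethanol-at-or-above-moderate > cannabinoids >
low-ethanol — is a configurable convention, with the BAC-dependent ethanol
split ensuring severe alcohol intoxication outranks incidental cannabinoid
positivity.  Intent precedence when flags conflict is self-harm > accident
> recreational abuse (the conservative clinical convention; configurable).

**Recurrence.**  A patient's index visit is the earliest confirmed visit of
the study year (ties by visit id); buckets are one / two-or-more.
Concomitant-problem flags (mental-health, chronic substance use, somatic
disease) ride on the evidence table, where diagnoses of the index year and
the two preceding years count as active.

## Statistics

Percentages are integers, rounded half-up, with the denominators
conventional for each table: visits for intent and intoxicant rows,
patients for recurrence and concomitant problems; a zero denominator omits
the percentage and keeps the count.  (Half-up means 93/110 prints as 85;
a source table that prints 84 for that cell is at odds with its own
convention, and the package does not special-case it.)  Incremental yield
of an arm is 100 × |only-new| / |baseline union|, undefined (not infinite)
on an empty baseline.  Medians and IQRs use linear-interpolation quantiles.
The chi-square test is Pearson's (scipy's implementation), continuity
correction off by default and available by flag; a zero expected cell
raises with the standard advice to merge sparse categories.  No
multiple-testing machinery is applied.

## Synthetic cohorts

`GeneratorParams` drives the parametric generator: number of patients,
mean visits per patient (≥ 1; extra visits Poisson), per-visit intoxication
prevalence, per-arm discoverability probabilities, a common-shock overlap
correlation ρ (with probability ρ all arms share one latent uniform, so
P(a ∧ b) = ρ·min(p_a, p_b) + (1−ρ)·p_a·p_b), per-arm false-positive rates,
sex ratio, intent and intoxicant mixes (defaulting to the calibration
profile's visit-level proportions), a lognormal BAC for ethanol visits, and
an `evidence_completeness` probability.  Complete-evidence cases carry a
full structured evidence record and are confirmed with sensitivity and
specificity 1.0 by construction — that is the generator's contract, checked
by running the matchers and adjudicator as the generator's own oracle.
Degraded-evidence cases keep their planted search content but lose the
documentation (no history, no signs, at most a low ethanol value), so they
exercise the rejection paths.  All randomness flows from one seeded
generator; identical parameters and seed give byte-identical CSVs.

The `pilot2019` profile plants its yield structure by stratified
assignment — counts first, attributes second — so the candidate and
confirmed counts are exact for every seed.  Planted marginals follow the
profile's reference tables: 94/37 patients and 110/55 visits by sex; intent
6/124/35 (4/93/13 men, 2/31/22 women); primary intoxicants
111/16/14/7/8/3/1/5 across ethanol, benzodiazepines, other
pharmaceuticals, cannabinoids, amphetamines, opioids, cocaine and other
toxins, with 64 secondary mentions; exact median BAC 43.6 mmol/L (men) and
31.2 mmol/L (women) among ethanol-primary visits and exactly 13 severe-AAI
values; 99 one-visit and 32 multi-visit patients; concomitant flags
70/48/77.  Two calibration caveats are deliberate: (i) the per-sex
recurrence split is left to fall out of the sex-by-visit-count plan
(16 men / 16 women with repeat visits) because the reference marginals for
visits-by-sex and repeat-visits-by-sex are mutually inconsistent by simple
counting, and the totals take precedence; (ii) the overlap between
false-positive candidates of the free word search and of the traditional
arms is a free parameter not fixed by any published total — the profile
makes the false-positive sets disjoint (105 traditional: 40 reason / 35
laboratory / 30 ICD; 119 free-word-search).  These tables are *planted
calibration*, not independent reproductions: recovering them shows the
pipeline is count-exact and internally consistent, not that real data
would produce them.

What the generator does **not** emulate: realistic clinical prose (notes
are templated sentences sufficient to exercise the matchers), misspellings
and notation drift, laboratory cross-reactivity, inter-rater variability in
review, midnight-spanning visits, or seasonal structure.  Passing tests
therefore demonstrate correctness of the search/adjudication machinery
under the stated matching rules, not free-text NLP robustness.

Default background volume is 2,000 visits per year rather than a full
~45,000-visit ED year; the structure scales linearly and the volume is
configurable upward (all planted counts are unaffected).

## Configuration schema

YAML/JSON, all keys optional:

```yaml
keywords: [intoxication, intoxicant, impaired consciousness, ...]
reason_mode: token          # or: substring
code_spec: [F10, F11-F16, F19, X00-X09, X44-X49, X69, "T36#", T40, T50, T51-T65]
lexicon:
  - "Intox*"
  - surface: Amphetamine
    variants: [methamphetamine, mdma]
lab_panel:
  ethanol_blood: {unit: mmol_per_L, kind: quantitative, threshold: 0.0,
                  substance_class: ethanol}
thresholds: {ethanol_blood: 0.0}
```

Generator parameters files mirror `GeneratorParams` field names.

## Numerical and degenerate-input choices

Half-up rounding everywhere a printed convention exists; exact decimal
arithmetic via `decimal` for the rounding step.  Empty candidate sets,
empty baselines, zero denominators and missing BACs are values, not errors.
Duplicate visit ids and malformed codes/ranges fail fast with named-column
error messages.  Evidence rows absent for a candidate default to
all-negative evidence (rejection).

## Known limitations

The adjudicator consumes structured evidence; abstraction from real
free-text charts is out of scope.  Date-keyed overlap control merges
legitimate same-day revisits.  The toxicity ranking is a convention, not a
pharmacological model; no pharmacokinetic back-extrapolation of BAC is
attempted.  Statistical output is descriptive plus Pearson chi-square only.
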