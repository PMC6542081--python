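# Methods

## Audit model

The package audits one-day point-prevalence medication charts from
institutional elderly care. A chart row is one prescription (patient id,
age, gender, drug, as-needed flag, optional dose/time); a cohort is one
timepoint's set of residents. Residents younger than 65 are excluded at
load time and counted. Both regular and as-needed (PRN) prescriptions
count toward exposure — a point-prevalence audit measures what is
prescribed, not what is administered — which is known to overestimate
daily use; the choice is recorded in every report's metadata.

Because the long-format CSV has one row per prescription, a resident on
no psychotropics would otherwise vanish from the file while still
belonging to every "all patients" denominator. A row with an empty
`drug_name` therefore registers a resident without prescriptions; the
writer emits such rows and the reader accepts them.

Substance identity is ATC level 5; duplicate regular+PRN entries of one
substance collapse to a single exposure before any indicator is
evaluated. Category membership is decided by the ATC level-3 prefix
(N06A, N05A, N05B, N05C, N03A), with anxiolytics and hypnotics merged
into one category on the assumption of comparable adverse-effect profiles
in this population. Lithium (N05AN) classifies with the antipsychotics by
its ATC placement. The shipped registry maps the 49 substances occurring
in the audited cohorts to their WHO ATC codes and carries the two
PIPS flags; it is a CSV users can export, edit and reload. Unknown drug
names are rejected by default (silent drops would bias denominators),
with an explicit skip-and-log option.

## Indicators

* Polypharmacy: ≥ 3 distinct substances.
* PICP: ≥ 2 distinct substances within one category. The ≥ 2
  antiepileptics rule is tabulated but excluded from the overall PICP
  flag (antiepileptic co-prescription is often rational in epilepsy). The
  ≥ 2 anticholinergics rule is a drug-property rule and counts across
  categories: an anticholinergic antidepressant plus an anticholinergic
  antipsychotic qualifies.
* PIPS: any substance flagged long-acting benzodiazepine (diazepam,
  nitrazepam, flunitrazepam) or anticholinergic (amitriptyline,
  clomipramine, nortriptyline, chlorpromazine, chlorprothixene,
  levomepromazine, prochlorperazine, hydroxyzine).

Denominator conventions follow audit-report practice: stratum rows
("k or more drugs") are percentages of the cohort; category shares within
a stratum use the stratum count; sub-rows of the combination, PICP and
PIPS families use the family count, which surfaces the most frequent
inappropriate prescribing within each family. Percentages are rounded
half-up to one decimal (Python's banker's rounding would change printed
values such as 6.25 → 6.2 vs 6.3). An empty cohort yields a table with
zero denominators and missing percentages — never a division.

The indicators were originally formulated for ages ≥ 75 but are applied
to every cohort member (≥ 65); the report metadata records this choice.

## Interaction ranking

Knowledge-base entries are unordered substance pairs with mechanism,
recommended action (informative / monitor / adjust dose / avoid),
documentation (theoretical / case / study / extensive) and severity
(mild / moderate / severe). For ranking, monitor and adjust-dose collapse
to one level and study and extensive collapse to one level, giving three
ordered levels per attribute. The first-ranked interaction per patient is
the lexicographic maximum of (action, documentation, severity): action
dominates because a contraindication matters regardless of evidence
grade; severity ranks last because compendia label many interactions
potentially severe on thin evidence. Ties on the full collapsed triple
are broken deterministically by the alphabetically first sorted pair, and
the occurrence of a tie is counted in the report metadata — the selection
hierarchy itself gives no guidance here, so determinism is the design
goal rather than clinical priority.

Mechanism is curated knowledge-base data, never inferred from the
description text. Some compendium entries with a pharmacokinetic label
carry an additional pharmacodynamic effect not explained by plasma-level
changes; adjudicating those requires expert reading of the prose, so the
engine stores whatever mechanism the curator assigned and imposes no
reclassification rule.

The shipped fixture encodes the fifteen pairs inferable from the
published first-ranked-interaction classification. Where that table
leaves an attribute unstated for a pair, the fixture fills in a
field-plausible level (e.g. monitor/study/moderate for the
pharmacokinetic plasma-level pairs); those fills, and the eight
additional sedation pairs of the *extended* fixture, are synthetic and
marked as such. The fixture is a test and demonstration object, not a
substitute for a curated interaction database.

## Comparison statistics

Proportions: Pearson chi-square without continuity correction on the 2×2
table; Fisher's exact two-sided test when any expected cell is below 5
(Cochran's rule; the uncorrected chi-square reproduces the printed
significance calls at these sample sizes). Note that the conservative
two-sided Fisher p can exceed the chi-square p by several percentage
points on mid-range tables even with all expected cells ≥ 20; the two
tests nonetheless agree on the p < 0.01 significance calls in all checks.
Continuous variables: two-sided Mann-Whitney U with tie correction —
exact null distribution on small tie-free samples, otherwise the
tie-corrected normal approximation without continuity correction (so
identical samples give p = 1 exactly).

Logistic procedure: outcome = ≥ 1 matched interaction; analysis
population = residents on ≥ 2 distinct psychotropics; predictors are
gender (male = 1), age (years, continuous), number of distinct
psychotropics (continuous) and the four category indicators (0/1).
Step 1 fits each univariate model, step 2 the fully adjusted model, and
step 3 refits over predictors with p < 0.25 in *either* of the first two
steps (the disjunction — the looser and more inclusive reading — recorded
in the report notes). Estimates are odds ratios with Wald 95% CIs.
Perfect separation or non-convergence suppresses that predictor's
estimates and flags the row rather than reporting unstable numbers.
Multicollinearity is screened by regressing each predictor on the others:
tolerance = 1 − R², VIF = 1/tolerance.

## Synthetic cohorts

The generator emulates the audit's published marginal structure only:

* ages: normal (defaults 84.6 ± 7.2 and 84.3 ± 8.1 years for the two
  timepoint presets), rejection-sampled above 64.5 and rounded to integer
  years, matching the integer-age ≥ 65 cohort definition;
* gender: Bernoulli (male fraction 0.264 / 0.339);
* per-patient psychotropic count: a categorical distribution on 0..6.
  The presets were calibrated once so that the implied ≥ 1 / ≥ 2 / ≥ 3
  prevalences approximate the published 59.6/24.4/6.2% (earlier) and
  80.5/56.0/29.6% (later) values, with supports matching the reported
  concurrent-use ranges (up to four, respectively six);
* drugs: given the count, distinct substances are sampled without
  replacement with probability proportional to the published per-drug
  patient counts for the chosen year; each prescription is independently
  marked PRN with probability 0.3 (as-needed prescribing is common in
  this setting but its rate is not reported per drug).

Drugs are sampled independently of category given the count, so category
co-occurrence, PICP and interaction rates are emergent rather than
fitted; the published data report only marginals, and this is the
simplest generative model consistent with them. Consequently passing
tests show that the pipeline's rules and statistics behave correctly on
cohorts with realistic marginal structure — they do not validate any
joint structure of real charts (ward type, dementia status, comorbidity,
prescriber effects are all absent), and logistic coefficients estimated
on synthetic cohorts are properties of the generator, not of any real
population.

Determinism: one seeded `numpy` generator drives every draw, so a given
configuration reproduces byte-identical cohort files, and the whole
report bundle is reproducible byte-for-byte from cohort + knowledge base
+ configuration.

## Problem sizes and numerical choices

The test suite exercises the oracle-equivalence properties at 1000 random
patients (first-ranked selection), 20-patient random fixtures (indicator
recount), exhaustive enumeration for Fisher (margin-fixed tables) and
Mann-Whitney (n ≤ 4 per group), parameter recovery at n = 2000 and
marginal-prevalence recovery at n = 5000 against a 20000–40000-patient
same-generator reference; these sizes give stable checks in seconds.
Wald CIs use z = 1.96; predictor estimates with standard errors above 50
on the logit scale are treated as separated and suppressed. Tolerance is
floored at 1e-12 before inversion to a VIF.

## Known limitations

* The indicator set is the audit's own; no Beers/STOPP/NORGEP catalogues
  (the rule tables are user-editable).
* No dose analysis: doses and administration times are carried through
  but never interpreted, so maximum-daily-dose problems are invisible.
* Interaction screening is only as good as the knowledge base; the
  bundled fixture is deliberately small, and severity/action levels are
  not stratified by age, gender or dose.
* Collapsing anxiolytics and hypnotics into one category can overestimate
  same-category combination rates.
* The cohort comparison treats the two timepoints as independent samples;
  residents present at both timepoints (unknowable from the chart format)
  would violate this.
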