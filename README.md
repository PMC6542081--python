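# psyaudit

Prescribing-quality audit of psychotropic drugs in elderly (nursing-home)
cohorts: indicator computation, drug-interaction screening with a
first-ranked selection hierarchy, and two-timepoint comparison statistics,
plus a synthetic-cohort generator so the whole pipeline runs without any
patient data.

Intended users are pharmacoepidemiologists and clinical pharmacologists
auditing one-day point-prevalence medication charts from institutional
care, and methodologists who want a reproducible reference implementation
of the common psychotropic prescribing-quality indicators.

## What it computes

Drugs are classified with the WHO ATC system; five subgroups are in scope
— antidepressants (N06A), antipsychotics (N05A), anxiolytics (N05B),
hypnotics (N05C) and antiepileptics (N03A) — with anxiolytics and
hypnotics collapsed into one category. For each resident aged ≥ 65, with
both regular and as-needed prescriptions counted and duplicates collapsed
at ATC level 5:

* **Psychotropic polypharmacy** — ≥ 3 concurrent distinct psychotropic
  substances.
* **PICP** (potentially inappropriate psychotropic combinations) — ≥ 2
  psychotropics from the same ATC level-3 category, plus a drug-property
  rule for ≥ 2 anticholinergic psychotropics (a ≥ 2 antiepileptics rule
  is tabulated but excluded from the overall PICP flag).
* **PIPS** (potentially inappropriate psychotropic substances) —
  long-acting benzodiazepines or anticholinergic psychotropics.
* **Interaction screening** — every substance pair is matched against a
  knowledge base whose entries carry mechanism (pharmacodynamic /
  pharmacokinetic), recommended action, documentation and severity. The
  raw attribute vocabularies collapse to three ordered levels each, and a
  patient's *first-ranked* interaction is the lexicographic maximum of

  `(action, documentation, severity)` with
  action: informative < monitor-or-adjust-dose < avoid,
  documentation: theoretical < case < study,
  severity: mild < moderate < severe.

* **Two-cohort comparison** — proportions by Pearson chi-square (no
  continuity correction) or Fisher's exact test when any expected cell
  < 5; continuous variables by the Mann-Whitney U test; and a three-step
  logistic regression of interaction risk (univariate models, the fully
  adjusted model, then a final model over predictors with p < 0.25 in
  either step) with VIF/tolerance multicollinearity screening.
  Significance is read at p < 0.01.

## Worked example

```sh
python examples/02_interaction_ranking.py
```

```
matched pairs (2):
  citalopram + haloperidol: action=avoid, documentation=theoretical, severity=severe (QT-prolongation)
  mirtazapine + oxazepam: action=monitor_or_adjust, documentation=theoretical, severity=moderate (sedation)
first-ranked: citalopram + haloperidol -> QT-prolongation
```

The citalopram–haloperidol pair is selected as first-ranked even though
both candidates are only theoretically documented: its recommended action
("avoid") sits at the top of the dominant ranking axis. The other
examples cover the indicator profile of a single resident
(`01_indicator_profile.py`), the full synthetic two-timepoint audit
(`03_two_cohort_audit.py` — e.g. synthetic polypharmacy rising from 5.4%
to 30.0% of residents, chi-square p ≈ 2e-19) and the three-step logistic
model (`04_logistic_predictors.py`).

A thin CLI wraps the same library calls:

```sh
psyaudit generate --seed 7 --out data/            # synthetic cohorts + KB fixture
psyaudit audit   --cohort data/cohort_2016.csv --kb data/interaction_kb.csv --out report/
psyaudit compare --cohort data/cohort_2000.csv --cohort data/cohort_2016.csv \
                 --kb data/interaction_kb.csv --out report/
```

`compare` writes a TSV bundle (drug frequencies, indicator tables,
combination/PICP/PIPS tables, first-ranked interaction classification,
logistic report, run metadata); re-running on identical inputs produces
byte-identical files.

## Layout

* `src/psyaudit/formulary.py` — ATC codes, categories, drug registry with
  PIPS flags (a default registry covering the audited substances ships in
  `data/`).
* `src/psyaudit/cohort_io.py` — long-format chart CSV reading/validation,
  age-65 inclusion filter, per-patient substance and category sets.
* `src/psyaudit/indicators.py` — polypharmacy, PICP, PIPS and the cohort
  tables.
* `src/psyaudit/interaction_engine.py` — knowledge base, level
  collapsing, first-ranked selection, mechanism summary.
* `src/psyaudit/comparative_stats.py` — proportion tests, Mann-Whitney,
  three-step logistic procedure.
* `src/psyaudit/synthetic_data.py` — cohort generator and the interaction
  knowledge-base fixture.
* `src/psyaudit/reporting.py`, `src/psyaudit/cli.py` — report bundle and
  the `psyaudit` command.

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
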