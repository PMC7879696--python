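# Methods

This note documents the statistical procedures, the data model, the
synthetic-data generator and the design decisions behind `dispro`.  It
states no empirical claim that the test suite or `scripts/acceptance.py`
does not itself compute.

## Report data model and I/O

A spontaneous report is a case version: demographics (age band, sex,
reporter type), one or more drug entries (normalized name, role among
primary suspect / suspect / concomitant / interacting, per-drug
indications), and one or more reaction terms.  The on-disk dialect mirrors
the public FAERS quarterly ASCII layout: `$`-delimited tables DEMO, DRUG,
REAC, INDI joined on `primaryid`, one header line each.  Two deliberate
deviations from raw FAERS: the DEMO table carries an explicit `quarter`
column and a pre-binned `age_band` column (raw FAERS spreads these over
archive provenance and age/age-code pairs), and DRUG carries `drug_seq` so
indications attach losslessly to the drug they belong to.  Unmodeled columns
are ignored with a logged notice; malformed rows are counted and skipped;
detail rows whose key is missing from DEMO are skipped with a warning; a
missing DEMO table is a hard error.  Blank or unrecognized age/sex/reporter
codes map to `unknown` rather than dropping the report.

In memory the store is columnar (four pandas DataFrames), because the test
battery routinely pushes several hundred thousand reports through the
pipeline; `Report`/`DrugEntry` dataclass views exist for small-scale work
and for the brute-force oracles in the test suite, and a read→write→read
round trip is lossless on every modeled field.

**Deduplication.** A case may appear as several versions; analyses keep
exactly one report per case id.  The rule: highest `caseversion` wins (the
regulatory convention for case revisions); a version tie is broken by later
quarter; a full tie keeps the first row encountered and logs a warning.  The
operation is idempotent and the retained count equals the number of distinct
case ids.

## Vocabulary

Term sets are flat lists of normalized strings (lowercase, trademark glyphs
stripped, whitespace collapsed) with an explicit match mode.  Drug sets
default to substring matching because verbatim drug fields embed active
moieties in product strings (salts, brands, combinations); reaction and
indication sets are MedDRA-style preferred terms matched exactly.  No
hierarchy traversal or fuzzy matching is attempted.

The built-in exposure set is the ten-member SGLT2-inhibitor list
(canagliflozin, empagliflozin, dapagliflozin, ertugliflozin, ipragliflozin,
sotagliflozin, and the four marketed fixed combinations); the focal event
set is {atrial fibrillation, atrial flutter}, combined because the two
entities are hard to distinguish clinically.  The companion sets (ATC-A10
comparator, insulin, anti-arrhythmics, renal/CVD/diabetes indications,
competing adverse events, control sets) ship realistic term lists flagged
`placeholder=True`: their authoritative published search-term lists are not
reproduced here, and users with access to them should override via the YAML
term-set config.  Load-time assertions enforce the disjointness the analyses
rely on (SGLT2i ∩ insulin = ∅, AF ∩ competing events = ∅).

## Cohorts and exclusion cascades

A report is *exposed* iff any drug entry whose role is in the counted role
set (default: primary suspect, suspect, concomitant) matches the exposure
set; comparator membership is analogous.  Because a report may list drugs
from both sets, an overlap policy resolves the conflict.  The default,
`exclude_from_comparator`, treats any report carrying the exposure drug as
exposed and never as comparator — the natural reading of an active-vs-control
framing — but `exclude_from_both` and `allow` are selectable because the
choice is genuinely open; nothing in the source workflow fixes it.

Filters are report-level and deliberately coarse:

* a drug predicate looks at every drug on the report regardless of role
  (excluding anti-arrhythmic *users*, not anti-arrhythmic suspects);
* an indication predicate matches indications attached to *any* drug;
* a reaction predicate removes the whole report when any reaction matches
  (excluding a competing-event *report*, not a reaction row);
* `require_report` inverts the logic (the diabetes-indication restriction
  keeps only reports where some drug carries a diabetes indication — a
  report with no indications at all is dropped);
* `applies_to` restricts a step to one arm; the insulin exclusion removes
  insulin reports from the comparator only.

Attrition is recorded per filter in order, so the emitted table reconstructs
the exclusion cascade exactly.

## Disproportionality statistics

For a table (a, b, c, d) — see the README for the layout — the package
computes PRR = (a/(a+b))/(c/(c+d)) with the log-scale Wald interval,
SE(ln PRR) = √(1/a − 1/(a+b) + 1/c − 1/(c+d)), z = 1.959964 by default.
This is the standard construction for reporting-ratio intervals; applied to
the worked-example table (295/62,098 vs 5,565/642,031) it reproduces the
published display values 0.55 (0.49–0.62), which the test suite checks both
at display precision and against a 50-digit decimal re-evaluation (agreement
to ten significant digits).

Numerical choices:

* **Zero cells.** If either event cell is zero, the Haldane–Anscombe
  correction adds 0.5 to all four cells for PRR and CI, and the result is
  flagged `zero_cell_corrected`; rates are always computed from the original
  counts.  An empty arm (a+b = 0 or c+d = 0) raises an error — the cohort is
  unanalyzable, not correctable.
* **Chi-square.** Pearson's test on the 2×2 without continuity correction
  (1 df), via `scipy.stats.chi2_contingency`; Yates' correction is available
  behind a flag.  At the report counts this package targets the choice is
  immaterial.  A zero margin leaves the statistic undefined (NaN in the
  orchestrated results; an error from the direct call).
* **Significance.** Strict `p < 0.05`; a NaN p-value is never significant.
* **Rounding.** All statistics are carried at full double precision;
  display rounding (2 decimals for PRR/CI, 1 for rates) happens only in the
  formatting layer.

## The analysis battery

The built-in plan contains 18 analyses and 5 controls.  The cascade —
anti-arrhythmic exclusion, renal-indication exclusion, insulin-from-
comparator exclusion, CVD-indication exclusion downstream of the insulin
exclusion, competing-event exclusion — is encoded as *independent branches*
off the main comparison plus one fully combined analysis, and each branch is
duplicated under the diabetes-indication restriction.  Sub-analyses restrict
the drug role to primary suspect (for both arms), the reporter type to
healthcare professionals (physician, other HCP, pharmacist), or stratify by
sex (unknown-sex reports drop out of both strata).

Controls are drug–event pairs with a declared expected direction, judged
purely from the confidence interval: `increase` passes iff ci_low > 1,
`decrease` iff ci_high < 1, `null` iff the CI contains 1.  The positive AF
control (ibrutinib) uses the rest of the database as comparator since its
natural comparator is not part of the two-arm design — an assumption, as the
source workflow does not state one.  The four SGLT2i controls (appendicitis
and stroke null; heart failure and chronic kidney disease decreased) reuse
the ATC-A10 comparator.

`run_plan` is a pure function of (store, plan): an analysis whose cohort
ends up with an empty arm yields a flagged row, never an exception, and the
CLI surfaces this as exit code 2.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes — not
the marginal drug/event distributions of any real database.  Each report is
modelled as triggered by an adverse-event complex:

1. Competing adverse events (urinary tract infection, diabetic ketoacidosis,
   Fournier's gangrene, amputation) are drawn per event with arm-specific
   probabilities.
2. A report carrying a competing event does not carry the focal AF event.
   This negative dependence is the masking/dilution mechanism: competing
   reports inflate the arm's denominator without contributing focal events.
3. Among competing-free reports, the focal event appears with probability
   `p_event_comparator` in the comparator arm and
   `true_ratio × p_event_comparator` in the exposed arm.  `true_ratio` is
   therefore the ground-truth *conditional* reporting ratio, recovered
   exactly by an analysis that excludes competing-event reports; the
   marginal ratio is `true_ratio × (1−q_e)/(1−q_c)` where `q` is the
   per-arm probability of any competing event.  With the default competing
   probabilities (totals ≈ 0.020 exposed, 0.006 comparator) the marginal
   ratio is ≈ 0.986 × true_ratio — a ~1.4% dilution, within the recovery
   tolerance the tests use.  `masking_scenario(config, s)` scales the
   exposed-arm competing probabilities by `s` (capped at 1), widening the
   gap; the paired-simulation test shows the competing-event exclusion then
   moves the estimate toward truth.
4. Independent low-probability control-event reactions exercise the control
   analyses; reports with no reaction at all receive a filler term from an
   innocuous vocabulary asserted disjoint from every analytic term set.

Defaults are the study conditions the package was built around: arm sizes
62,098 / 642,031; comparator focal rate 8.7/1000; true ratio 0.55; insulin
on 31% of comparator reports (the share by which the insulin exclusion
shrinks the comparator); primary-suspect shares 56.0% / 29.7% with the
remaining role mass split 1:2 between secondary suspect and concomitant.
Values the source material does not pin down were chosen once as realistic
and are listed in `GeneratorConfig`: anti-arrhythmic co-medication 2%,
renal indication 3%, CVD indication 8%, diabetes indication 60%, duplicate
rate 5%, demographics roughly matching an elderly, mixed-reporter case mix
(52% aged ≥65, 47/45/8 male/female/unknown, ~57% healthcare-professional
reporters).

Two structural simplifications, and what they imply for test evidence:
events are assigned independently of demographics (the analyses never adjust
for covariates, so correlated structure would add nothing to what the tests
can show), and exposed reports draw single-agent SGLT2i names only by
default — combination products substring-match comparator drugs (e.g.
"metformin and canagliflozin" contains "metformin"), which is realistic but
makes generator labels unrecoverable under the `allow` overlap policy that
the label-recovery oracle test relies on; `include_combination_products=True`
restores them.  Passing tests on this generator demonstrate the pipeline's
internal correctness and the estimator's behaviour under the stated model;
they say nothing about reporting biases in real spontaneous data beyond the
masking mechanism explicitly modelled.

Duplicates are injected as superseded version-1 copies of a random fraction
of cases; deduplication must (and does, by test) recover exactly the unique
cases at any duplicate rate.  Generation is a pure function of the config,
seed included.

## Problem sizes in the test suite

The simulation tests use: 100 random stores of ≲ 1,200 reports for the
brute-force oracle equivalence; 1,000 binomial tables at the worked
example's arm sizes and rates for CI coverage (expected coverage 93–97%);
200 seeds at 200,000 reports/arm for parameter recovery (median PRR within
±0.02 of the true 0.55); and 100 paired seeds at 50,000 reports/arm under
masking strength 5 for the dilution property.  The full suite runs in
roughly ten minutes on one CPU.

## Known limitations

* Placeholder term lists (see Vocabulary) are realistic, not authoritative;
  analyses on real FAERS extracts should supply curated lists.
* No reporting-odds-ratio, IC or EBGM estimators, no signal-screening
  thresholds, no multiple-testing adjustment — the package implements a
  PRR-with-controls workflow, not a general signal-detection toolbox.
* The reader handles the `$`-delimited ASCII dialect only (no SGML/E2B XML),
  and no download client is included.
* Pharmacovigilance data support relative reporting comparisons only; none
  of the outputs are incidence estimates, and the synthetic generator's
  ground truth is a reporting ratio, not a clinical effect.
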