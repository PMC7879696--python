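"""Orchestration of the full analysis battery with internal controls.

A plan is an ordered list of named analyses (each a cohort specification and
a focal event set) plus a list of control specifications with an expected
direction of disproportionality.  The built-in plan is the battery this
package was designed around: the main SGLT2-inhibitor vs other-ATC-A10
comparison, role/reporter/sex sub-analyses, a cascade of exclusions
(anti-arrhythmics, renal-disease indication, insulin in the comparator,
cardiovascular-disease indication, competing adverse events), the
all-filters-combined analysis, each of the cascade analyses duplicated under
a diabetes-indication restriction, and five internal controls (a positive AF
control drug and negative/positive control events for the exposure).

``run_plan`` is deterministic: one result row per analysis, with unanalyzable
cohorts (an empty group after filtering) flagged rather than fatal.
``evaluate_controls`` turns control rows into pass/fail verdicts from their
confidence intervals.  ``render_forest`` draws the customary forest plot
(point estimates with 95% CIs against a reference line at PRR = 1) and a
monospace text rendering for logs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd

from .cohorts import DEFAULT_ROLES, REST_OF_DATABASE, CohortSpec, FilterSpec, build_contingency
from .faers_io import ReportStore
from .stats import UndefinedCohortError, compute_prr
from .vocabulary import VocabularyConfig, builtin_term_sets

__all__ = [
    "Analysis",
    "ControlSpec",
    "AnalysisPlan",
    "plan_from_yaml",
    "builtin_plan",
    "run_plan",
    "evaluate_controls",
    "render_forest",
    "render_forest_text",
    "RESULT_COLUMNS",
]

_DIRECTIONS = frozenset({"increase", "decrease", "null"})

RESULT_COLUMNS = [
    "analysis_name",
    "kind",
    "a",
    "b",
    "c",
    "d",
    "n_exposed",
    "n_comparator",
    "rate_exposed_per_1000",
    "rate_comparator_per_1000",
    "prr",
    "ci_low",
    "ci_high",
    "chi2",
    "p",
    "significant",
    "flag",
    "expected_direction",
]


@dataclass(frozen=True)
class Analysis:
    """One named analysis: a cohort spec and the focal event set."""

    name: str
    spec: CohortSpec
    event_set: str = "af"


@dataclass(frozen=True)
class ControlSpec:
    """A drug–event pair with a known expected direction of effect."""

    name: str
    exposure_set: str
    comparator_set: str
    event_set: str
    expected_direction: str

    def __post_init__(self):
        if self.expected_direction not in _DIRECTIONS:
            raise ValueError(f"unknown expected direction {self.expected_direction!r}")

    def as_analysis(self) -> Analysis:
        return Analysis(
            name=self.name,
            spec=CohortSpec(exposure_set=self.exposure_set, comparator_set=self.comparator_set),
            event_set=self.event_set,
        )


@dataclass
class AnalysisPlan:
    """Ordered analyses plus controls; names must be unique."""

    analyses: list = field(default_factory=list)
    controls: list = field(default_factory=list)

    def __post_init__(self):
        names = [a.name for a in self.analyses] + [c.name for c in self.controls]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate analysis names: {dupes}")


def plan_from_yaml(path) -> AnalysisPlan:
    """Load an analysis plan from a structured-text (YAML) file.

    Schema: ``analyses`` — list of {name, exposure_set, comparator_set,
    drug_roles?, overlap_policy?, sex?, reporters?, event_set?, filters?};
    each filter is {name, action, predicate_kind, set_name, applies_to?}.
    ``controls`` — list of {name, exposure_set, comparator_set, event_set,
    expected_direction}.
    """
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    analyses = []
    for a in doc.get("analyses") or []:
        filters = tuple(
            FilterSpec(
                name=f["name"],
                action=f["action"],
                predicate_kind=f["predicate_kind"],
                set_name=f["set_name"],
                applies_to=f.get("applies_to", "both"),
            )
            for f in a.get("filters") or []
        )
        spec = CohortSpec(
            exposure_set=a["exposure_set"],
            comparator_set=a["comparator_set"],
            drug_roles=frozenset(a.get("drug_roles") or DEFAULT_ROLES),
            filters=filters,
            overlap_policy=a.get("overlap_policy", "exclude_from_comparator"),
            sex_restrict=a.get("sex"),
            reporter_restrict=frozenset(a["reporters"]) if a.get("reporters") else None,
        )
        analyses.append(Analysis(name=a["name"], spec=spec, event_set=a.get("event_set", "af")))
    controls = [
        ControlSpec(
            name=c["name"],
            exposure_set=c["exposure_set"],
            comparator_set=c["comparator_set"],
            event_set=c["event_set"],
            expected_direction=c["expected_direction"],
        )
        for c in doc.get("controls") or []
    ]
    return AnalysisPlan(analyses=analyses, controls=controls)


# --------------------------------------------------------------------------
# Built-in plan
# --------------------------------------------------------------------------

_F_ANTIARR = FilterSpec("excl_anti_arrhythmics", "exclude_report", "drug_in_set", "anti_arrhythmics")
_F_RENAL = FilterSpec("excl_renal_indication", "exclude_report", "indication_in_set", "renal_indication")
_F_INSULIN = FilterSpec(
    "excl_insulin_comparator", "exclude_report", "drug_in_set", "insulin", applies_to="comparator"
)
_F_CVD = FilterSpec("excl_cvd_indication", "exclude_report", "indication_in_set", "cvd_indication")
_F_COMPETING = FilterSpec("excl_competing_ae", "exclude_report", "reaction_in_set", "competing_ae")
_F_DIABETES = FilterSpec("require_diabetes_indication", "require_report", "indication_in_set", "diabetes_indication")


def builtin_plan() -> AnalysisPlan:
    """The default analysis battery (see module docstring).

    The exclusion analyses are independent branches off the main comparison,
    except the CVD-indication exclusion which is applied downstream of the
    insulin exclusion, and the final analysis which combines every filter;
    each branch is duplicated with the diabetes-indication restriction.
    """
    base = CohortSpec(exposure_set="sglt2i", comparator_set="atc_a10_comparator")

    cascade = [
        ("main", base),
        ("excl anti-arrhythmics", base.with_filters(_F_ANTIARR)),
        ("excl renal indication", base.with_filters(_F_RENAL)),
        ("excl insulin (comparator)", base.with_filters(_F_INSULIN)),
        ("excl insulin + CVD indication", base.with_filters(_F_INSULIN, _F_CVD)),
        ("excl competing AEs", base.with_filters(_F_COMPETING)),
        (
            "all filters combined",
            base.with_filters(_F_ANTIARR, _F_RENAL, _F_INSULIN, _F_CVD, _F_COMPETING),
        ),
    ]
    analyses = [Analysis(name, spec) for name, spec in cascade]
    # sub-analyses: restricted drug role, reporter type, sex strata
    analyses.insert(
        1, Analysis("primary suspect only", replace(base, drug_roles=frozenset({"primary_suspect"})))
    )
    analyses.insert(
        2,
        Analysis(
            "HCP reporters only",
            replace(base, reporter_restrict=frozenset({"physician", "other_hcp", "pharmacist"})),
        ),
    )
    analyses.insert(3, Analysis("males", replace(base, sex_restrict="male")))
    analyses.insert(4, Analysis("females", replace(base, sex_restrict="female")))
    # diabetes-indication duplicates of the cascade branches
    for name, spec in cascade:
        analyses.append(Analysis(f"{name} [diabetes indication]", spec.with_filters(_F_DIABETES)))

    controls = [
        ControlSpec("control: ibrutinib -> AF", "ibrutinib", REST_OF_DATABASE, "af", "increase"),
        ControlSpec("control: appendicitis", "sglt2i", "atc_a10_comparator", "appendicitis", "null"),
        ControlSpec("control: stroke", "sglt2i", "atc_a10_comparator", "stroke", "null"),
        ControlSpec("control: heart failure", "sglt2i", "atc_a10_comparator", "heart_failure", "decrease"),
        ControlSpec(
            "control: chronic kidney disease", "sglt2i", "atc_a10_comparator", "chronic_kidney_disease", "decrease"
        ),
    ]
    return AnalysisPlan(analyses=analyses, controls=controls)


# --------------------------------------------------------------------------
# Execution
# --------------------------------------------------------------------------

def _flagged_row(name, kind, direction):
    row = dict.fromkeys(RESULT_COLUMNS)
    row.update(analysis_name=name, kind=kind, flag="unanalyzable", expected_direction=direction)
    return row


def _run_one(store, analysis, vocab, kind, direction=""):
    try:
        table, cohort = build_contingency(store, analysis.spec, analysis.event_set, vocab)
        res = compute_prr(table)
    except UndefinedCohortError:
        return _flagged_row(analysis.name, kind, direction), None
    row = {
        "analysis_name": analysis.name,
        "kind": kind,
        "a": table.a,
        "b": table.b,
        "c": table.c,
        "d": table.d,
        "n_exposed": table.n_exposed,
        "n_comparator": table.n_comparator,
        "rate_exposed_per_1000": res.rate_exposed_per_1000,
        "rate_comparator_per_1000": res.rate_comparator_per_1000,
        "prr": res.prr,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "chi2": res.chi2,
        "p": res.p_value,
        "significant": res.significant,
        "flag": "zero_cell_corrected" if res.zero_cell_corrected else "ok",
        "expected_direction": direction,
    }
    return row, cohort


def run_plan(store: ReportStore, plan: AnalysisPlan = None, vocab: VocabularyConfig = None, return_attrition: bool = False):
    """Run every analysis and control of ``plan`` against ``store``.

    The store is expected to be deduplicated.  Returns a results DataFrame
    (one row per analysis/control, plan order preserved); with
    ``return_attrition=True`` also returns a long attrition table.  Output is
    a pure function of (store, plan).
    """
    plan = plan or builtin_plan()
    vocab = vocab or builtin_term_sets()
    rows, attrition_rows = [], []
    for analysis in plan.analyses:
        row, cohort = _run_one(store, analysis, vocab, "analysis")
        rows.append(row)
        if cohort is not None:
            att = cohort.attrition_frame()
            att.insert(0, "analysis_name", analysis.name)
            attrition_rows.append(att)
    for control in plan.controls:
        row, _ = _run_one(store, control.as_analysis(), vocab, "control", control.expected_direction)
        rows.append(row)
    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if return_attrition:
        attrition = (
            pd.concat(attrition_rows, ignore_index=True)
            if attrition_rows
            else pd.DataFrame(
                columns=["analysis_name", "step", "exposed_n", "comparator_n", "exposed_removed", "comparator_removed"]
            )
        )
        return results, attrition
    return results


def evaluate_controls(results: pd.DataFrame, plan: AnalysisPlan) -> pd.DataFrame:
    """Pass/fail verdicts for the plan's controls from their CIs.

    ``increase`` passes iff ci_low > 1; ``decrease`` iff ci_high < 1;
    ``null`` iff the CI contains 1.  Controls whose cohort was unanalyzable
    get the verdict ``"unanalyzable"``.
    """
    by_name = results.set_index("analysis_name")
    rows = []
    for control in plan.controls:
        if control.name not in by_name.index:
            raise KeyError(f"results are missing control row {control.name!r}")
        r = by_name.loc[control.name]
        lo, hi = r["ci_low"], r["ci_high"]
        if r["flag"] == "unanalyzable" or pd.isna(lo) or pd.isna(hi):
            verdict = "unanalyzable"
        elif control.expected_direction == "increase":
            verdict = "pass" if lo > 1.0 else "fail"
        elif control.expected_direction == "decrease":
            verdict = "pass" if hi < 1.0 else "fail"
        else:
            verdict = "pass" if lo <= 1.0 <= hi else "fail"
        rows.append(
            {
                "control": control.name,
                "expected_direction": control.expected_direction,
                "prr": r["prr"],
                "ci_low": lo,
                "ci_high": hi,
                "verdict": verdict,
            }
        )
    return pd.DataFrame(rows, columns=["control", "expected_direction", "prr", "ci_low", "ci_high", "verdict"])


# --------------------------------------------------------------------------
# Forest rendering
# --------------------------------------------------------------------------

def render_forest(results: pd.DataFrame, path=None):
    """Forest plot of PRR point estimates with 95% CIs (log-scaled x axis,
    reference line at 1.0, plan order preserved top to bottom).  Returns the
    matplotlib Figure; saves to ``path`` when given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plot = results[results["prr"].notna()].reset_index(drop=True)
    if plot.empty:
        raise ValueError("no analyzable rows to render")
    y = range(len(plot) - 1, -1, -1)  # first analysis on top
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(plot) + 1.5))
    err_lo = plot["prr"] - plot["ci_low"]
    err_hi = plot["ci_high"] - plot["prr"]
    ax.errorbar(plot["prr"], list(y), xerr=[err_lo, err_hi], fmt="s", color="black", capsize=3, lw=1)
    ax.axvline(1.0, color="grey", ls="--", lw=1)
    ax.set_yticks(list(y))
    ax.set_yticklabels(plot["analysis_name"])
    ax.set_xscale("log")
    ax.set_xlabel("PRR (95% CI), log scale")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig


def render_forest_text(results: pd.DataFrame, width: int = 41) -> str:
    """Monospace forest rendering for logs.

    One row per analyzable analysis: the name, ``PRR [lo, hi]``, and an
    axis spanning two decades around 1.0 with ``<``/``>`` CI bounds, ``*``
    the point estimate, and ``|`` the reference line at 1.0.
    """
    plot = results[results["prr"].notna()]
    if plot.empty:
        return "(no analyzable rows)"
    name_w = max(len(n) for n in plot["analysis_name"]) + 2
    lo_log, hi_log = -1.0, 1.0  # PRR 0.1 .. 10 on log10 axis

    def col(value):
        x = min(max(math.log10(value), lo_log), hi_log)
        return int(round((x - lo_log) / (hi_log - lo_log) * (width - 1)))

    ref = col(1.0)
    lines = []
    for _, r in plot.iterrows():
        axis = [" "] * width
        axis[ref] = "|"
        for pos in range(col(r["ci_low"]), col(r["ci_high"]) + 1):
            if axis[pos] == " ":
                axis[pos] = "-"
        axis[col(r["ci_low"])] = "<"
        axis[col(r["ci_high"])] = ">"
        axis[col(r["prr"])] = "*"
        label = f"{r['analysis_name']:<{name_w}}{r['prr']:6.2f} [{r['ci_low']:5.2f}, {r['ci_high']:5.2f}]  "
        lines.append(label + "".join(axis))
    return "\n".join(lines)
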