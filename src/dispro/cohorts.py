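"""Cohort construction and exclusion cascades over a report store.

An analysis compares two cohorts of reports: an *exposure* group (reports
listing any drug from the exposure term set in one of the counted roles) and
a *comparator* group (the same for the comparator set, or every other report
when the comparator is the rest of the database).  A report listing drugs
from both sets is resolved by the overlap policy.  An ordered list of filters
is then applied — each either excluding reports where a predicate holds
(e.g. "lists an anti-arrhythmic") or requiring it (e.g. "carries a diabetes
indication") — with per-filter attrition accounting.  Finally the focal event
is counted, yielding the 2×2 table handed to :mod:`dispro.stats`.

Predicates are deliberately report-level: a drug predicate looks at every
drug on the report regardless of role, an indication predicate at indications
attached to *any* drug, and a reaction predicate removes the whole report if
any reaction matches (excluding a competing adverse event means dropping the
report, not the reaction).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .faers_io import DRUG_ROLES, REPORTERS, SEXES, ReportStore
from .stats import ContingencyTable, UndefinedCohortError
from .vocabulary import VocabularyConfig, builtin_term_sets

__all__ = [
    "REST_OF_DATABASE",
    "FilterSpec",
    "CohortSpec",
    "CohortResult",
    "assign_exposure",
    "apply_filters",
    "count_events",
    "build_contingency",
]

#: Sentinel comparator: all reports not in the exposure group.
REST_OF_DATABASE = "__rest__"

_ACTIONS = frozenset({"exclude_report", "require_report"})
_PREDICATES = frozenset({"drug_in_set", "indication_in_set", "reaction_in_set"})
_POLICIES = frozenset({"exclude_from_comparator", "exclude_from_both", "allow"})
_APPLIES = frozenset({"both", "exposed", "comparator"})
_PREDICATE_KIND_FOR_SET = {"drug_in_set": "drug", "indication_in_set": "indication", "reaction_in_set": "reaction"}

DEFAULT_ROLES = frozenset({"primary_suspect", "suspect", "concomitant"})


@dataclass(frozen=True)
class FilterSpec:
    """One step of an exclusion cascade.

    ``action`` is ``exclude_report`` (drop reports where the predicate holds)
    or ``require_report`` (keep only reports where it holds); the predicate
    tests whether any drug/indication/reaction on the report matches the
    named term set.  ``applies_to`` restricts the step to one group — used
    for comparator-only exclusions such as removing insulin reports from the
    control arm.
    """

    name: str
    action: str
    predicate_kind: str
    set_name: str
    applies_to: str = "both"

    def __post_init__(self):
        if self.action not in _ACTIONS:
            raise ValueError(f"unknown filter action {self.action!r}")
        if self.predicate_kind not in _PREDICATES:
            raise ValueError(f"unknown predicate kind {self.predicate_kind!r}")
        if self.applies_to not in _APPLIES:
            raise ValueError(f"unknown applies_to {self.applies_to!r}")


@dataclass(frozen=True)
class CohortSpec:
    """Exposure/comparator definition plus the ordered exclusion cascade.

    ``drug_roles`` are the roles that count as exposure (default: primary
    suspect, suspect and concomitant; restrict to ``{"primary_suspect"}`` for
    a primary-suspect-only sub-analysis).  ``sex_restrict`` /
    ``reporter_restrict`` stratify the store before cohort building
    (sub-analyses by sex and by healthcare-professional reporters).
    """

    exposure_set: str
    comparator_set: str
    drug_roles: frozenset = DEFAULT_ROLES
    filters: tuple = ()
    overlap_policy: str = "exclude_from_comparator"
    sex_restrict: str = None
    reporter_restrict: frozenset = None

    def __post_init__(self):
        if self.exposure_set == self.comparator_set:
            raise ValueError("exposure and comparator sets must differ")
        if self.overlap_policy not in _POLICIES:
            raise ValueError(f"unknown overlap policy {self.overlap_policy!r}")
        roles = frozenset(self.drug_roles)
        if not roles <= frozenset(DRUG_ROLES):
            raise ValueError(f"unknown drug roles {roles - frozenset(DRUG_ROLES)}")
        object.__setattr__(self, "drug_roles", roles)
        object.__setattr__(self, "filters", tuple(self.filters))
        if self.sex_restrict is not None and self.sex_restrict not in SEXES:
            raise ValueError(f"unknown sex {self.sex_restrict!r}")
        if self.reporter_restrict is not None:
            rr = frozenset(self.reporter_restrict)
            if not rr <= frozenset(REPORTERS):
                raise ValueError(f"unknown reporters {rr - frozenset(REPORTERS)}")
            object.__setattr__(self, "reporter_restrict", rr)

    def with_filters(self, *extra: FilterSpec) -> "CohortSpec":
        return replace(self, filters=self.filters + tuple(extra))


@dataclass
class CohortResult:
    """Exposed/comparator case-id sets with attrition bookkeeping.

    ``attrition`` is an ordered list of ``(step name, exposed removed,
    comparator removed)``; the first entry records the initial assignment.
    """

    exposed_ids: frozenset
    comparator_ids: frozenset
    attrition: list = field(default_factory=list)

    def __post_init__(self):
        self.exposed_ids = frozenset(self.exposed_ids)
        self.comparator_ids = frozenset(self.comparator_ids)

    @property
    def n_exposed(self) -> int:
        return len(self.exposed_ids)

    @property
    def n_comparator(self) -> int:
        return len(self.comparator_ids)

    def attrition_frame(self) -> pd.DataFrame:
        rows, n_e, n_c = [], None, None
        for name, rem_e, rem_c in self.attrition:
            if n_e is None:  # first row records initial sizes
                n_e, n_c = rem_e, rem_c
                rows.append((name, n_e, n_c, 0, 0))
            else:
                n_e, n_c = n_e - rem_e, n_c - rem_c
                rows.append((name, n_e, n_c, rem_e, rem_c))
        return pd.DataFrame(
            rows, columns=["step", "exposed_n", "comparator_n", "exposed_removed", "comparator_removed"]
        )


# --------------------------------------------------------------------------
# Predicate evaluation (vectorized, returns sets of case ids)
# --------------------------------------------------------------------------

def _cases_matching(demo: pd.DataFrame, frame: pd.DataFrame, column: str, term_set) -> frozenset:
    if frame.empty:
        return frozenset()
    hit = term_set.match_series(frame[column])
    pids = frame.loc[hit.values, "primaryid"]
    mapping = pd.Series(demo["caseid"].values, index=demo["primaryid"].values)
    return frozenset(mapping.reindex(pids.unique()).dropna())


def _predicate_cases(store: ReportStore, spec: FilterSpec, vocab: VocabularyConfig) -> frozenset:
    term_set = vocab[spec.set_name]
    expected_kind = _PREDICATE_KIND_FOR_SET[spec.predicate_kind]
    if term_set.kind != expected_kind:
        raise ValueError(
            f"filter {spec.name!r}: predicate {spec.predicate_kind} needs a "
            f"{expected_kind} set, but {spec.set_name!r} has kind {term_set.kind!r}"
        )
    if spec.predicate_kind == "drug_in_set":
        return _cases_matching(store.demo, store.drugs, "drugname", term_set)
    if spec.predicate_kind == "indication_in_set":
        return _cases_matching(store.demo, store.indications, "indi_pt", term_set)
    return _cases_matching(store.demo, store.reactions, "pt", term_set)


def _restrict_demo(store: ReportStore, spec: CohortSpec) -> pd.DataFrame:
    demo = store.demo
    if spec.sex_restrict is not None:
        demo = demo[demo["sex"] == spec.sex_restrict]
    if spec.reporter_restrict is not None:
        demo = demo[demo["occp_cod"].isin(spec.reporter_restrict)]
    return demo


# --------------------------------------------------------------------------
# Operations
# --------------------------------------------------------------------------

def assign_exposure(store: ReportStore, spec: CohortSpec, vocab: VocabularyConfig = None) -> CohortResult:
    """Assign each report to the exposure and/or comparator group.

    A report is exposed iff any drug entry whose role is in
    ``spec.drug_roles`` matches the exposure set; comparator membership is
    analogous (or "every non-exposed report" for the
    :data:`REST_OF_DATABASE` comparator).  Overlap between the two raw groups
    is resolved by ``spec.overlap_policy``.  The store is expected to be
    deduplicated, so case ids identify reports uniquely.
    """
    vocab = vocab or builtin_term_sets()
    demo = _restrict_demo(store, spec)
    universe = frozenset(demo["caseid"])

    drugs = store.drugs
    role_ok = drugs["role_cod"].isin(spec.drug_roles)
    drugs = drugs[role_ok.values]

    exposed = _cases_matching(store.demo, drugs, "drugname", vocab[spec.exposure_set]) & universe
    if spec.comparator_set == REST_OF_DATABASE:
        comparator = universe - exposed
    else:
        comparator = _cases_matching(store.demo, drugs, "drugname", vocab[spec.comparator_set]) & universe

    overlap = exposed & comparator
    if spec.overlap_policy == "exclude_from_comparator":
        comparator -= overlap
    elif spec.overlap_policy == "exclude_from_both":
        exposed -= overlap
        comparator -= overlap
    return CohortResult(
        exposed_ids=exposed,
        comparator_ids=comparator,
        attrition=[("assigned", len(exposed), len(comparator))],
    )


def apply_filters(
    store: ReportStore,
    cohort: CohortResult,
    filters,
    vocab: VocabularyConfig = None,
) -> CohortResult:
    """Apply an ordered exclusion cascade, recording per-filter attrition.

    Each ``exclude_report`` step removes reports where the predicate holds;
    ``require_report`` keeps only reports where it holds (so a report with no
    indications fails an indication requirement).  Group sizes never grow.
    """
    vocab = vocab or builtin_term_sets()
    exposed, comparator = cohort.exposed_ids, cohort.comparator_ids
    attrition = list(cohort.attrition)
    for f in filters:
        pred = _predicate_cases(store, f, vocab)
        if f.action == "exclude_report":
            new_exposed = exposed - pred if f.applies_to in ("both", "exposed") else exposed
            new_comparator = comparator - pred if f.applies_to in ("both", "comparator") else comparator
        else:  # require_report
            new_exposed = exposed & pred if f.applies_to in ("both", "exposed") else exposed
            new_comparator = comparator & pred if f.applies_to in ("both", "comparator") else comparator
        attrition.append((f.name, len(exposed) - len(new_exposed), len(comparator) - len(new_comparator)))
        exposed, comparator = new_exposed, new_comparator
    return CohortResult(exposed_ids=exposed, comparator_ids=comparator, attrition=attrition)


def count_events(store: ReportStore, cohort: CohortResult, event_set) -> ContingencyTable:
    """Count focal-event reports in each group, yielding the 2×2 table.

    ``a`` = exposed reports with at least one reaction matching the event
    set, ``b`` = exposed without, ``c``/``d`` likewise for the comparator.
    An empty group makes the cohort unanalyzable and raises
    :class:`~dispro.stats.UndefinedCohortError`.
    """
    if cohort.n_exposed == 0 or cohort.n_comparator == 0:
        raise UndefinedCohortError("cohort has an empty group; nothing to compare")
    event_cases = _cases_matching(store.demo, store.reactions, "pt", event_set)
    a = len(cohort.exposed_ids & event_cases)
    c = len(cohort.comparator_ids & event_cases)
    return ContingencyTable(a=a, b=cohort.n_exposed - a, c=c, d=cohort.n_comparator - c)


def build_contingency(
    store: ReportStore,
    spec: CohortSpec,
    event_set_name: str = "af",
    vocab: VocabularyConfig = None,
):
    """Convenience pipeline: assign → filter → count.

    Returns ``(ContingencyTable, CohortResult)``.
    """
    vocab = vocab or builtin_term_sets()
    cohort = assign_exposure(store, spec, vocab)
    cohort = apply_filters(store, cohort, spec.filters, vocab)
    table = count_events(store, cohort, vocab[event_set_name])
    return table, cohort
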