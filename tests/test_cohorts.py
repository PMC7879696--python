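import numpy as np
import pytest

from oracles import oracle_pipeline

from dispro.cohorts import (
    CohortSpec,
    FilterSpec,
    apply_filters,
    assign_exposure,
    build_contingency,
    count_events,
)
from dispro.faers_io import DrugEntry, Report, ReportStore, dedup_latest
from dispro.stats import UndefinedCohortError
from dispro.synthetic import GeneratorConfig, generate

EXCL_AA = FilterSpec("no_aa", "exclude_report", "drug_in_set", "anti_arrhythmics")
REQ_DIAB = FilterSpec("diab", "require_report", "indication_in_set", "diabetes_indication")
EXCL_COMPETING = FilterSpec("no_comp", "exclude_report", "reaction_in_set", "competing_ae")
EXCL_INSULIN_CMP = FilterSpec(
    "no_ins", "exclude_report", "drug_in_set", "insulin", applies_to="comparator"
)


def _report(case_id, drugs, reactions=("headache",), **kw):
    return Report(case_id=case_id, drugs=tuple(drugs), reactions=tuple(reactions), **kw)


@pytest.fixture()
def tiny_store():
    return ReportStore.from_reports(
        [
            _report("R1", [DrugEntry("dapagliflozin", "concomitant"), DrugEntry("metformin", "suspect")]),
            _report("R2", [DrugEntry("metformin", "primary_suspect")]),
            _report("R3", [DrugEntry("empagliflozin", "primary_suspect")], reactions=("atrial fibrillation",)),
            _report("R4", [DrugEntry("sitagliptin", "suspect"), DrugEntry("amiodarone", "concomitant")],
                    reactions=("atrial flutter",)),
            _report("R5", [DrugEntry("insulin glargine", "suspect")]),
            _report("R6", [DrugEntry("ibuprofen", "primary_suspect")]),
        ]
    )


BASE = CohortSpec(exposure_set="sglt2i", comparator_set="atc_a10_comparator")


class TestAssignExposure:
    def test_overlap_goes_to_exposure_by_default(self, tiny_store, vocab):
        cohort = assign_exposure(tiny_store, BASE, vocab)
        assert "R1" in cohort.exposed_ids and "R1" not in cohort.comparator_ids
        assert cohort.exposed_ids == {"R1", "R3"}
        assert cohort.comparator_ids == {"R2", "R4", "R5"}

    def test_overlap_policies(self, tiny_store, vocab):
        both = assign_exposure(
            tiny_store, CohortSpec("sglt2i", "atc_a10_comparator", overlap_policy="allow"), vocab
        )
        assert "R1" in both.exposed_ids and "R1" in both.comparator_ids
        neither = assign_exposure(
            tiny_store, CohortSpec("sglt2i", "atc_a10_comparator", overlap_policy="exclude_from_both"), vocab
        )
        assert "R1" not in neither.exposed_ids and "R1" not in neither.comparator_ids

    def test_pure_comparator_report(self, tiny_store, vocab):
        cohort = assign_exposure(tiny_store, BASE, vocab)
        assert "R2" in cohort.comparator_ids and "R2" not in cohort.exposed_ids

    def test_role_restriction(self, tiny_store, vocab):
        spec = CohortSpec("sglt2i", "atc_a10_comparator", drug_roles=frozenset({"primary_suspect"}))
        cohort = assign_exposure(tiny_store, spec, vocab)
        # R1's SGLT2i is concomitant-only, so it drops out of the exposure group
        assert cohort.exposed_ids == {"R3"}

    def test_unknown_set_name_is_hard_error(self, tiny_store, vocab):
        with pytest.raises(KeyError):
            assign_exposure(tiny_store, CohortSpec("sglt2i", "nonexistent"), vocab)

    def test_recovers_generator_labels_under_allow_policy(self, vocab):
        store, truth = generate(GeneratorConfig(n_exposed=400, n_comparator=1600, seed=11))
        store = dedup_latest(store)
        spec = CohortSpec("sglt2i", "atc_a10_comparator", overlap_policy="allow")
        cohort = assign_exposure(store, spec, vocab)
        assert cohort.exposed_ids == truth.exposed_ids
        assert cohort.comparator_ids == truth.comparator_ids


class TestApplyFilters:
    def test_antiarrhythmic_exclusion_removes_report(self, tiny_store, vocab):
        cohort = assign_exposure(tiny_store, BASE, vocab)
        filtered = apply_filters(tiny_store, cohort, [EXCL_AA], vocab)
        assert "R4" not in filtered.comparator_ids
        assert filtered.exposed_ids == cohort.exposed_ids

    def test_require_indication_removes_reports_without_it(self, tiny_store, vocab):
        cohort = assign_exposure(tiny_store, BASE, vocab)
        filtered = apply_filters(tiny_store, cohort, [REQ_DIAB], vocab)
        assert filtered.exposed_ids == frozenset() and filtered.comparator_ids == frozenset()

    def test_comparator_only_filter_leaves_exposed_alone(self, tiny_store, vocab):
        cohort = assign_exposure(tiny_store, BASE, vocab)
        filtered = apply_filters(tiny_store, cohort, [EXCL_INSULIN_CMP], vocab)
        assert "R5" not in filtered.comparator_ids
        assert filtered.exposed_ids == cohort.exposed_ids

    def test_attrition_accounting(self, tiny_store, vocab):
        cohort = assign_exposure(tiny_store, BASE, vocab)
        filtered = apply_filters(tiny_store, cohort, [EXCL_AA, EXCL_INSULIN_CMP], vocab)
        frame = filtered.attrition_frame()
        assert list(frame["step"]) == ["assigned", "no_aa", "no_ins"]
        assert frame["exposed_n"].iloc[-1] == filtered.n_exposed
        assert frame["comparator_n"].iloc[-1] == filtered.n_comparator
        total_removed = frame[["exposed_removed", "comparator_removed"]].to_numpy().sum()
        assert total_removed == (cohort.n_exposed + cohort.n_comparator) - (
            filtered.n_exposed + filtered.n_comparator
        )

    def test_filters_idempotent_and_monotone(self, vocab):
        store, _ = generate(GeneratorConfig(n_exposed=200, n_comparator=800, seed=5))
        store = dedup_latest(store)
        cohort = assign_exposure(store, BASE, vocab)
        once = apply_filters(store, cohort, [EXCL_AA, EXCL_COMPETING], vocab)
        twice = apply_filters(store, once, [EXCL_AA, EXCL_COMPETING], vocab)
        assert once.exposed_ids == twice.exposed_ids
        assert once.comparator_ids == twice.comparator_ids
        assert once.n_exposed <= cohort.n_exposed
        assert once.n_comparator <= cohort.n_comparator

    def test_random_filter_sequences_match_set_algebra_oracle(self, vocab):
        rng = np.random.default_rng(17)
        store, _ = generate(
            GeneratorConfig(n_exposed=300, n_comparator=900, p_event_comparator=0.05, seed=23)
        )
        store = dedup_latest(store)
        reports = store.to_reports()
        pool = [EXCL_AA, REQ_DIAB, EXCL_COMPETING, EXCL_INSULIN_CMP,
                FilterSpec("no_renal", "exclude_report", "indication_in_set", "renal_indication")]
        for _ in range(5):
            chosen = [pool[i] for i in rng.permutation(len(pool))[: rng.integers(1, len(pool) + 1)]]
            spec = CohortSpec("sglt2i", "atc_a10_comparator", filters=tuple(chosen))
            cohort = assign_exposure(store, spec, vocab)
            filtered = apply_filters(store, cohort, spec.filters, vocab)
            oracle_exp, oracle_cmp, _ = oracle_pipeline(reports, spec, vocab)
            assert filtered.exposed_ids == oracle_exp
            assert filtered.comparator_ids == oracle_cmp


class TestCountEvents:
    def test_counts_tiny_example(self, vocab):
        store = ReportStore.from_reports(
            [
                _report("r1", [DrugEntry("dapagliflozin")], reactions=("atrial fibrillation",)),
                _report("r2", [DrugEntry("dapagliflozin")]),
                _report("r3", [DrugEntry("metformin")], reactions=("atrial fibrillation",)),
            ]
        )
        cohort = assign_exposure(store, BASE, vocab)
        t = count_events(store, cohort, vocab["af"])
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 0)

    def test_unmatched_event_set_gives_zero_event_cells(self, tiny_store, vocab):
        cohort = assign_exposure(tiny_store, BASE, vocab)
        t = count_events(tiny_store, cohort, vocab["appendicitis"])
        assert t.a == 0 and t.c == 0
        assert t.n_exposed == cohort.n_exposed and t.n_comparator == cohort.n_comparator

    def test_empty_group_is_unanalyzable(self, vocab):
        store = ReportStore.from_reports([_report("r1", [DrugEntry("dapagliflozin")])])
        cohort = assign_exposure(store, BASE, vocab)
        with pytest.raises(UndefinedCohortError):
            count_events(store, cohort, vocab["af"])

    def test_counts_match_generator_labels(self, vocab):
        store, truth = generate(
            GeneratorConfig(n_exposed=500, n_comparator=1500, p_event_comparator=0.05, seed=29)
        )
        store = dedup_latest(store)
        spec = CohortSpec("sglt2i", "atc_a10_comparator", overlap_policy="allow")
        table, _ = build_contingency(store, spec, "af", vocab)
        lab = truth.labels
        assert table.a == int(lab[(lab["group"] == "exposed") & lab["has_focal_event"]].shape[0])
        assert table.c == int(lab[(lab["group"] == "comparator") & lab["has_focal_event"]].shape[0])
        assert table.n_exposed == 500 and table.n_comparator == 1500


def test_totals_bounded_by_store_size(vocab):
    store, _ = generate(GeneratorConfig(n_exposed=150, n_comparator=450, seed=31))
    store = dedup_latest(store)
    table, _ = build_contingency(store, BASE, "af", vocab)
    assert table.a + table.b + table.c + table.d <= len(store)


def test_spec_validation():
    with pytest.raises(ValueError):
        CohortSpec("sglt2i", "sglt2i")
    with pytest.raises(ValueError):
        CohortSpec("a", "b", overlap_policy="coin_flip")
    with pytest.raises(ValueError):
        FilterSpec("f", "obliterate", "drug_in_set", "sglt2i")
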