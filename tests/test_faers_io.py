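import tempfile
from pathlib import Path

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dispro.faers_io import (
    DrugEntry,
    FaersIOError,
    Report,
    ReportStore,
    dedup_latest,
    read_faers_ascii,
    write_faers_ascii,
)
from dispro.synthetic import GeneratorConfig, generate


def _write(path, lines):
    Path(path).write_text("\n".join(lines) + "\n")


def _bundle(tmp_path, demo, drug=(), reac=(), indi=()):
    _write(tmp_path / "DEMO.txt", ["primaryid$caseid$caseversion$quarter$age_band$sex$occp_cod", *demo])
    _write(tmp_path / "DRUG.txt", ["primaryid$drug_seq$drugname$role_cod", *drug])
    _write(tmp_path / "REAC.txt", ["primaryid$pt", *reac])
    _write(tmp_path / "INDI.txt", ["primaryid$drug_seq$indi_pt", *indi])
    return tmp_path


class TestDomainTypes:
    def test_report_validation(self):
        with pytest.raises(ValueError):
            Report(case_id="")
        with pytest.raises(ValueError):
            Report(case_id="C1", quarter="2014")
        with pytest.raises(ValueError):
            Report(case_id="C1", sex="m")
        with pytest.raises(ValueError):
            DrugEntry(term="metformin", role="bystander")

    def test_primaryid_combines_case_and_version(self):
        assert Report(case_id="C1", case_version=3).primaryid == "C1-3"


class TestReadFaersAscii:
    def test_joins_detail_rows_onto_demo(self, tmp_path):
        bundle = _bundle(
            tmp_path,
            demo=["K1-1$K1$1$2015q2$18-64$F$MD"],
            drug=["K1-1$1$DrugA$SS", "K1-1$2$DrugB$C"],
            reac=["K1-1$Atrial Fibrillation"],
        )
        store = read_faers_ascii(bundle)
        reports = store.to_reports()
        assert len(reports) == 1
        (r,) = reports
        assert r.case_id == "K1" and r.sex == "female" and r.reporter == "physician"
        assert [d.term for d in r.drugs] == ["druga", "drugb"]
        assert [d.role for d in r.drugs] == ["suspect", "concomitant"]
        assert r.reactions == ("atrial fibrillation",)

    def test_two_versions_before_dedup_one_after(self, tmp_path):
        bundle = _bundle(
            tmp_path,
            demo=["C7-1$C7$1$2015q2$unknown$$", "C7-2$C7$2$2015q3$unknown$$"],
            drug=["C7-1$1$metformin$PS", "C7-2$1$metformin$PS"],
            reac=["C7-1$headache", "C7-2$headache"],
        )
        store = read_faers_ascii(bundle)
        assert len(store) == 2
        deduped = dedup_latest(store)
        assert len(deduped) == 1
        assert deduped.to_reports()[0].case_version == 2

    def test_missing_demo_is_hard_error(self, tmp_path):
        _write(tmp_path / "DRUG.txt", ["primaryid$drug_seq$drugname$role_cod"])
        with pytest.raises(FaersIOError):
            read_faers_ascii(tmp_path)

    def test_orphan_drug_rows_skipped_with_warning(self, tmp_path, caplog):
        bundle = _bundle(
            tmp_path,
            demo=["K1-1$K1$1$2015q2$unknown$$"],
            drug=["K1-1$1$metformin$PS", "GHOST-1$1$aspirin$C"],
            reac=["K1-1$headache"],
        )
        with caplog.at_level("WARNING"):
            store = read_faers_ascii(bundle)
        assert len(store.drugs) == 1
        assert any("absent from DEMO" in m for m in caplog.messages)

    def test_unknown_codes_map_to_unknown(self, tmp_path):
        bundle = _bundle(
            tmp_path,
            demo=["K1-1$K1$1$2015q2$$X$ZZ"],
            drug=["K1-1$1$metformin$PS"],
            reac=["K1-1$headache"],
        )
        (r,) = read_faers_ascii(bundle).to_reports()
        assert (r.age_band, r.sex, r.reporter) == ("unknown", "unknown", "unknown")


class TestWriteFaersAscii:
    def test_empty_store_writes_header_only_files(self, tmp_path):
        paths = write_faers_ascii(ReportStore(), tmp_path)
        assert set(paths) == {"DEMO", "DRUG", "REAC", "INDI"}
        for p in paths.values():
            lines = Path(p).read_text().splitlines()
            assert len(lines) == 1 and "$" in lines[0]

    def test_single_report_store_has_one_demo_row(self, tmp_path):
        store = ReportStore.from_reports(
            [Report(case_id="C1", drugs=(DrugEntry("metformin"),), reactions=("headache",))]
        )
        paths = write_faers_ascii(store, tmp_path)
        assert len(Path(paths["DEMO"]).read_text().splitlines()) == 2

    def test_repeated_writes_are_byte_identical(self, tmp_path):
        store, _ = generate(GeneratorConfig(n_exposed=40, n_comparator=60, seed=7))
        first = {k: Path(p).read_bytes() for k, p in write_faers_ascii(store, tmp_path / "a").items()}
        second = {k: Path(p).read_bytes() for k, p in write_faers_ascii(store, tmp_path / "b").items()}
        assert first == second


class TestRoundTrip:
    def test_synthetic_store_round_trips_losslessly(self, tmp_path):
        store, _ = generate(GeneratorConfig(n_exposed=40, n_comparator=60, seed=7))
        write_faers_ascii(store, tmp_path)
        assert read_faers_ascii(tmp_path).same_contents(store)

    @given(
        st.lists(
            st.builds(
                Report,
                case_id=st.sampled_from(["A", "B", "C", "D", "E"]),
                case_version=st.integers(1, 3),
                quarter=st.sampled_from(["2014q1", "2017q3", "2019q4"]),
                age_band=st.sampled_from(["<18", "18-64", ">=65", "unknown"]),
                sex=st.sampled_from(["male", "female", "unknown"]),
                reporter=st.sampled_from(["physician", "consumer", "unknown"]),
                drugs=st.lists(
                    st.builds(
                        DrugEntry,
                        term=st.sampled_from(["metformin", "dapagliflozin", "amiodarone"]),
                        role=st.sampled_from(["primary_suspect", "suspect", "concomitant"]),
                        indications=st.lists(
                            st.sampled_from(["type 2 diabetes mellitus", "renal impairment"]),
                            max_size=2,
                            unique=True,
                        ),
                    ),
                    min_size=1,
                    max_size=3,
                ),
                reactions=st.lists(
                    st.sampled_from(["headache", "atrial fibrillation", "urinary tract infection"]),
                    min_size=1,
                    max_size=3,
                    unique=True,
                ),
            ),
            max_size=8,
            unique_by=lambda r: (r.case_id, r.case_version),
        )
    )
    @settings(max_examples=20)
    def test_round_trip_property(self, reports):
        # reactions/indications are sets per report in the ASCII dialect
        store = ReportStore.from_reports(reports)
        with tempfile.TemporaryDirectory() as d:
            write_faers_ascii(store, d)
            assert read_faers_ascii(d).same_contents(store)


class TestDedupLatest:
    def test_keeps_highest_version(self):
        reports = [
            Report(case_id="C", case_version=v, drugs=(DrugEntry("metformin"),), reactions=("headache",))
            for v in (1, 2, 3)
        ]
        out = dedup_latest(ReportStore.from_reports(reports)).to_reports()
        assert len(out) == 1 and out[0].case_version == 3

    def test_unique_case_ids_unchanged(self):
        reports = [
            Report(case_id=f"C{i}", drugs=(DrugEntry("metformin"),), reactions=("headache",))
            for i in range(5)
        ]
        store = ReportStore.from_reports(reports)
        assert dedup_latest(store).same_contents(store)

    def test_version_tie_keeps_later_quarter(self):
        reports = [
            Report(case_id="C", case_version=1, quarter="2014q1", drugs=(DrugEntry("a"),), reactions=("x",)),
            Report(case_id="C", case_version=1, quarter="2016q4", drugs=(DrugEntry("b"),), reactions=("y",)),
        ]
        # distinct primaryids are required by the store; emulate revision rows
        store = ReportStore.from_reports([reports[0]])
        other = ReportStore.from_reports([reports[1]])
        other.demo["primaryid"] = "C-1b"
        other.drugs["primaryid"] = "C-1b"
        other.reactions["primaryid"] = "C-1b"
        import pandas as pd

        merged = ReportStore(
            demo=pd.concat([store.demo, other.demo], ignore_index=True),
            drugs=pd.concat([store.drugs, other.drugs], ignore_index=True),
            reactions=pd.concat([store.reactions, other.reactions], ignore_index=True),
        )
        out = dedup_latest(merged)
        assert list(out.demo["quarter"]) == ["2016q4"]

    def test_matches_brute_force_grouping(self):
        store, truth = generate(
            GeneratorConfig(n_exposed=100, n_comparator=900, duplicate_rate=0.10, seed=3)
        )
        deduped = dedup_latest(store)
        # brute force: group Report objects by case_id, keep max version
        best = {}
        for r in store.to_reports():
            if r.case_id not in best or r.case_version > best[r.case_id].case_version:
                best[r.case_id] = r
        assert len(deduped) == len(best) == len(set(store.demo["caseid"]))
        got = {r.case_id: r.case_version for r in deduped.to_reports()}
        assert got == {cid: r.case_version for cid, r in best.items()}

    def test_idempotent(self):
        store, _ = generate(GeneratorConfig(n_exposed=50, n_comparator=150, duplicate_rate=0.2, seed=9))
        once = dedup_latest(store)
        twice = dedup_latest(once)
        assert once.same_contents(twice)
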