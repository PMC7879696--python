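"""Domain types and I/O for spontaneous adverse-event reports.

The public FDA adverse-event reporting system (FAERS) ships quarterly archives
of ``$``-delimited ASCII tables: DEMO (one row per report version, with
demographics), DRUG (one row per drug mention, with its role), REAC (one row
per reaction term) and INDI (one row per drug indication).  Rows join on a
``primaryid`` key; a *case* may appear in several versions and analyses keep
only the most recent one.

This module models that record structure with two containers:

* :class:`Report` / :class:`DrugEntry` — per-report dataclass views, the
  domain model used by documentation, small examples and the brute-force
  oracles in the test suite;
* :class:`ReportStore` — the columnar workhorse: four pandas DataFrames
  mirroring the ASCII tables.  All pipeline operations (deduplication, cohort
  assignment, filtering, counting) run vectorized on the store, which keeps
  stores of several hundred thousand reports cheap.

Readers normalize verbatim drug/reaction/indication strings through
:func:`dispro.vocabulary.normalize_term` and map the FAERS code vocabularies
(role_cod PS/SS/C/I, sex M/F, occp_cod MD/PH/OT/CN/LW) onto the package's
closed enums; writers invert the mapping, so a read/write round trip is
lossless on every modeled field.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .vocabulary import normalize_series, normalize_term

logger = logging.getLogger(__name__)

__all__ = [
    "AGE_BANDS",
    "SEXES",
    "REPORTERS",
    "DRUG_ROLES",
    "DrugEntry",
    "Report",
    "ReportStore",
    "FaersIOError",
    "read_faers_ascii",
    "write_faers_ascii",
    "dedup_latest",
]

AGE_BANDS = ("<18", "18-64", ">=65", "unknown")
SEXES = ("male", "female", "unknown")
REPORTERS = ("physician", "other_hcp", "consumer", "pharmacist", "other", "unknown")
DRUG_ROLES = ("primary_suspect", "suspect", "concomitant", "interacting")

_QUARTER_RE = re.compile(r"^\d{4}q[1-4]$")

# FAERS code vocabularies <-> package enums
_ROLE_FROM_COD = {"PS": "primary_suspect", "SS": "suspect", "C": "concomitant", "I": "interacting"}
_ROLE_TO_COD = {v: k for k, v in _ROLE_FROM_COD.items()}
_SEX_FROM_COD = {"M": "male", "F": "female"}
_SEX_TO_COD = {"male": "M", "female": "F", "unknown": ""}
_REPORTER_FROM_COD = {"MD": "physician", "PH": "pharmacist", "OT": "other_hcp", "CN": "consumer", "LW": "other"}
_REPORTER_TO_COD = {"physician": "MD", "pharmacist": "PH", "other_hcp": "OT", "consumer": "CN", "other": "LW", "unknown": ""}

_DEMO_COLS = ["primaryid", "caseid", "caseversion", "quarter", "age_band", "sex", "occp_cod"]
_DRUG_COLS = ["primaryid", "drug_seq", "drugname", "role_cod"]
_REAC_COLS = ["primaryid", "pt"]
_INDI_COLS = ["primaryid", "drug_seq", "indi_pt"]


class FaersIOError(Exception):
    """Raised for unreadable/incomplete FAERS file bundles."""


def quarter_key(quarter: str) -> int:
    """Sortable integer for a ``YYYYq[1-4]`` quarter label."""
    return int(quarter[:4]) * 4 + int(quarter[-1])


@dataclass(frozen=True)
class DrugEntry:
    """One drug mention on a report: normalized name, role, its indications."""

    term: str
    role: str = "suspect"
    indications: tuple = ()

    def __post_init__(self):
        if not self.term:
            raise ValueError("drug term must be nonempty")
        if self.role not in DRUG_ROLES:
            raise ValueError(f"unknown drug role {self.role!r}")
        object.__setattr__(self, "indications", tuple(self.indications))


@dataclass(frozen=True)
class Report:
    """One spontaneous adverse-event report (a single case version)."""

    case_id: str
    case_version: int = 1
    quarter: str = "2014q1"
    age_band: str = "unknown"
    sex: str = "unknown"
    reporter: str = "unknown"
    drugs: tuple = ()
    reactions: tuple = ()

    def __post_init__(self):
        if not self.case_id:
            raise ValueError("case_id must be nonempty")
        if self.case_version < 0:
            raise ValueError("case_version must be non-negative")
        if not _QUARTER_RE.match(self.quarter):
            raise ValueError(f"quarter {self.quarter!r} does not parse as YYYYq[1-4]")
        for val, allowed in ((self.age_band, AGE_BANDS), (self.sex, SEXES), (self.reporter, REPORTERS)):
            if val not in allowed:
                raise ValueError(f"{val!r} not in {allowed}")
        object.__setattr__(self, "drugs", tuple(self.drugs))
        object.__setattr__(self, "reactions", tuple(self.reactions))

    @property
    def primaryid(self) -> str:
        return f"{self.case_id}-{self.case_version}"


def _empty_frame(cols) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in cols})


@dataclass
class ReportStore:
    """Columnar collection of reports (DEMO/DRUG/REAC/INDI DataFrames).

    ``demo`` has one row per report version keyed by ``primaryid``; the other
    frames hold the per-report detail rows.  ``caseversion`` is integer typed;
    all other columns are strings already passed through term normalization.
    """

    demo: pd.DataFrame = field(default_factory=lambda: _empty_frame(_DEMO_COLS))
    drugs: pd.DataFrame = field(default_factory=lambda: _empty_frame(_DRUG_COLS))
    reactions: pd.DataFrame = field(default_factory=lambda: _empty_frame(_REAC_COLS))
    indications: pd.DataFrame = field(default_factory=lambda: _empty_frame(_INDI_COLS))
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.demo = self.demo.reset_index(drop=True)
        if self.demo["primaryid"].duplicated().any():
            raise ValueError("duplicate primaryid in DEMO")

    def __len__(self) -> int:
        return len(self.demo)

    @property
    def n_reports(self) -> int:
        return len(self.demo)

    def case_ids(self) -> pd.Series:
        return self.demo["caseid"]

    def subset(self, primaryids) -> "ReportStore":
        """New store restricted to the given primaryids (order preserved)."""
        keep = set(primaryids)
        return ReportStore(
            demo=self.demo[self.demo["primaryid"].isin(keep)].reset_index(drop=True),
            drugs=self.drugs[self.drugs["primaryid"].isin(keep)].reset_index(drop=True),
            reactions=self.reactions[self.reactions["primaryid"].isin(keep)].reset_index(drop=True),
            indications=self.indications[self.indications["primaryid"].isin(keep)].reset_index(drop=True),
            provenance=list(self.provenance),
        )

    # -- record-level views ------------------------------------------------

    def to_reports(self) -> list:
        """Materialize the store as a list of :class:`Report` (sorted by
        primaryid).  Intended for small stores, docs and oracles."""
        drug_rows = {}
        for pid, seq, name, role in self.drugs[_DRUG_COLS].itertuples(index=False):
            drug_rows.setdefault(pid, []).append((int(seq), name, role))
        indi_rows = {}
        for pid, seq, term in self.indications[_INDI_COLS].itertuples(index=False):
            indi_rows.setdefault((pid, int(seq)), []).append(term)
        reac_rows = {}
        for pid, pt in self.reactions[_REAC_COLS].itertuples(index=False):
            reac_rows.setdefault(pid, []).append(pt)
        out = []
        demo = self.demo.sort_values("primaryid", kind="stable")
        for row in demo.itertuples(index=False):
            pid = row.primaryid
            entries = []
            for seq, name, role in sorted(drug_rows.get(pid, [])):
                entries.append(
                    DrugEntry(term=name, role=role, indications=tuple(sorted(indi_rows.get((pid, seq), []))))
                )
            out.append(
                Report(
                    case_id=row.caseid,
                    case_version=int(row.caseversion),
                    quarter=row.quarter,
                    age_band=row.age_band,
                    sex=row.sex,
                    reporter=row.occp_cod,
                    drugs=tuple(entries),
                    reactions=tuple(sorted(reac_rows.get(pid, []))),
                )
            )
        return out

    @classmethod
    def from_reports(cls, reports, provenance=None) -> "ReportStore":
        demo, drug, reac, indi = [], [], [], []
        for r in reports:
            pid = r.primaryid
            demo.append((pid, r.case_id, int(r.case_version), r.quarter, r.age_band, r.sex, r.reporter))
            for seq, entry in enumerate(r.drugs, start=1):
                drug.append((pid, str(seq), entry.term, entry.role))
                for term in entry.indications:
                    indi.append((pid, str(seq), term))
            for pt in r.reactions:
                reac.append((pid, pt))
        return cls(
            demo=pd.DataFrame(demo, columns=_DEMO_COLS) if demo else _empty_frame(_DEMO_COLS),
            drugs=pd.DataFrame(drug, columns=_DRUG_COLS) if drug else _empty_frame(_DRUG_COLS),
            reactions=pd.DataFrame(reac, columns=_REAC_COLS) if reac else _empty_frame(_REAC_COLS),
            indications=pd.DataFrame(indi, columns=_INDI_COLS) if indi else _empty_frame(_INDI_COLS),
            provenance=list(provenance or []),
        )

    def same_contents(self, other: "ReportStore") -> bool:
        """Order-insensitive equality on all modeled fields."""
        return sorted(self.to_reports(), key=lambda r: r.primaryid) == sorted(
            other.to_reports(), key=lambda r: r.primaryid
        )


# --------------------------------------------------------------------------
# Reading
# --------------------------------------------------------------------------

def _read_table(path, required_cols, bad_rows_counter):
    def _on_bad(row):  # count and skip malformed rows
        bad_rows_counter.append(row)
        return None

    df = pd.read_csv(
        path,
        sep="$",
        dtype=str,
        keep_default_na=False,
        engine="python",
        on_bad_lines=_on_bad,
    )
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in required_cols if c not in df.columns]
    if missing:
        raise FaersIOError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in required_cols]
    if extra:
        logger.info("%s: ignoring unmodeled columns %s", path, extra)
    return df[list(required_cols)]


def _resolve_paths(paths) -> dict:
    """Accept a mapping {demo/drug/reac/indi: path}, a directory, or a list of
    paths whose filenames start with the table name."""
    if isinstance(paths, dict):
        return {k.lower(): Path(v) for k, v in paths.items()}
    p = Path(paths) if isinstance(paths, (str, Path)) else None
    if p is not None and p.is_dir():
        paths = sorted(p.iterdir())
    out = {}
    for item in paths:
        item = Path(item)
        stem = item.name.lower()
        for kind in ("demo", "drug", "reac", "indi"):
            if stem.startswith(kind):
                out[kind] = item
                break
        else:
            logger.warning("ignoring unrecognized file %s", item)
    return out


def read_faers_ascii(paths, dialect=None) -> ReportStore:
    """Read a FAERS-dialect ASCII bundle into a :class:`ReportStore`.

    ``paths`` may be a directory, a list of files (tagged by filename prefix
    DEMO/DRUG/REAC/INDI), or an explicit mapping.  A missing DEMO table is a
    hard error (there is nothing to join onto); detail rows whose key is
    absent from DEMO are skipped with a warning; malformed rows are counted
    and logged, never fatal.  Verbatim term strings are normalized on entry.
    """
    tagged = _resolve_paths(paths)
    if "demo" not in tagged:
        raise FaersIOError("no DEMO file in bundle: nothing to join onto")
    for kind, path in tagged.items():
        if not Path(path).exists():
            raise FaersIOError(f"{kind.upper()} file {path} does not exist")

    bad_rows = []
    demo = _read_table(tagged["demo"], _DEMO_COLS, bad_rows)
    demo = demo[demo["primaryid"] != ""]
    demo["caseversion"] = pd.to_numeric(demo["caseversion"], errors="coerce").fillna(1).astype(int)
    demo["quarter"] = demo["quarter"].str.strip().str.lower()
    ok_quarter = demo["quarter"].str.match(_QUARTER_RE)
    if not ok_quarter.all():
        n_bad = int((~ok_quarter).sum())
        logger.warning("dropping %d DEMO rows with unparseable quarter", n_bad)
        demo = demo[ok_quarter]
    demo["age_band"] = demo["age_band"].where(demo["age_band"].isin(AGE_BANDS), "unknown")
    demo["sex"] = demo["sex"].str.strip().str.upper().map(_SEX_FROM_COD).fillna("unknown")
    demo["occp_cod"] = demo["occp_cod"].str.strip().str.upper().map(_REPORTER_FROM_COD).fillna("unknown")
    dup = demo["primaryid"].duplicated()
    if dup.any():
        logger.warning("dropping %d DEMO rows with duplicated primaryid", int(dup.sum()))
        demo = demo[~dup]
    known = set(demo["primaryid"])

    def _detail(kind, cols):
        if kind not in tagged:
            logger.info("bundle has no %s file; treating as empty", kind.upper())
            return _empty_frame(cols)
        df = _read_table(tagged[kind], cols, bad_rows)
        orphan = ~df["primaryid"].isin(known)
        if orphan.any():
            logger.warning("%s: skipping %d rows with keys absent from DEMO", kind.upper(), int(orphan.sum()))
            df = df[~orphan]
        return df.reset_index(drop=True)

    drugs = _detail("drug", _DRUG_COLS)
    drugs["drugname"] = normalize_series(drugs["drugname"])
    drugs["role_cod"] = drugs["role_cod"].str.strip().str.upper().map(_ROLE_FROM_COD).fillna("suspect")
    drugs = drugs[drugs["drugname"] != ""].reset_index(drop=True)

    reactions = _detail("reac", _REAC_COLS)
    reactions["pt"] = normalize_series(reactions["pt"])
    reactions = reactions[reactions["pt"] != ""].reset_index(drop=True)

    indications = _detail("indi", _INDI_COLS)
    indications["indi_pt"] = normalize_series(indications["indi_pt"])
    indications = indications[indications["indi_pt"] != ""].reset_index(drop=True)

    if bad_rows:
        logger.warning("skipped %d unparseable rows across the bundle", len(bad_rows))

    provenance = [str(tagged[k]) for k in sorted(tagged)]
    return ReportStore(
        demo=demo.reset_index(drop=True),
        drugs=drugs,
        reactions=reactions,
        indications=indications,
        provenance=provenance,
    )


# --------------------------------------------------------------------------
# Writing
# --------------------------------------------------------------------------

def write_faers_ascii(store: ReportStore, out_dir) -> dict:
    """Write ``store`` as a DEMO/DRUG/REAC/INDI bundle under ``out_dir``.

    Emits the same ``$``-delimited dialect :func:`read_faers_ascii` consumes;
    rows are sorted so repeated writes of the same store are byte-identical.
    Returns a mapping table-name -> written path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    demo = store.demo.copy()
    demo["sex"] = demo["sex"].map(_SEX_TO_COD).fillna("")
    demo["occp_cod"] = demo["occp_cod"].map(_REPORTER_TO_COD).fillna("")
    demo = demo.sort_values("primaryid", kind="stable")

    drugs = store.drugs.copy()
    drugs["role_cod"] = drugs["role_cod"].map(_ROLE_TO_COD).fillna("SS")
    drugs = drugs.sort_values(["primaryid", "drug_seq"], kind="stable")

    reactions = store.reactions.sort_values(["primaryid", "pt"], kind="stable")
    indications = store.indications.sort_values(["primaryid", "drug_seq", "indi_pt"], kind="stable")

    paths = {}
    for name, frame, cols in (
        ("DEMO", demo, _DEMO_COLS),
        ("DRUG", drugs, _DRUG_COLS),
        ("REAC", reactions, _REAC_COLS),
        ("INDI", indications, _INDI_COLS),
    ):
        path = out / f"{name}.txt"
        frame[list(cols)].to_csv(path, sep="$", index=False, lineterminator="\n")
        paths[name] = path
    return paths


# --------------------------------------------------------------------------
# Deduplication
# --------------------------------------------------------------------------

def dedup_latest(store: ReportStore) -> ReportStore:
    """Keep the most recent version of each case.

    For every ``caseid`` the row with the highest ``caseversion`` is retained;
    a version tie is broken by later quarter, and a full tie keeps the first
    row encountered (with a warning).  The number of removed duplicates is
    logged.  Idempotent.
    """
    demo = store.demo
    if demo.empty:
        return store
    codes, uniques = pd.factorize(demo["quarter"])
    qkey = np.array([quarter_key(q) for q in uniques])[codes]
    order = demo.assign(_q=qkey).sort_values(
        ["caseversion", "_q"], ascending=False, kind="stable"
    )
    dup_mask = order.duplicated(subset="caseid", keep="first")
    if not dup_mask.any():
        return store
    # within equal (version, quarter), stable descending sort preserves the
    # original order, so keep="first" retains the first-encountered row
    full_tie = order.duplicated(subset=["caseid", "caseversion", "_q"], keep=False)
    if full_tie.any():
        logger.warning(
            "%d reports tie on (caseid, caseversion, quarter); keeping first encountered",
            int(full_tie.sum()),
        )
    removed_pids = set(order.loc[dup_mask.values, "primaryid"])
    logger.info("dedup_latest removed %d duplicate report versions", len(removed_pids))

    def _drop(frame):
        return frame[~frame["primaryid"].isin(removed_pids)].reset_index(drop=True)

    return ReportStore(
        demo=_drop(store.demo),
        drugs=_drop(store.drugs),
        reactions=_drop(store.reactions),
        indications=_drop(store.indications),
        provenance=list(store.provenance),
    )
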