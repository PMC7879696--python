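"""Named, normalized term sets for drug groups, reaction sets and indication sets.

Spontaneous-report databases record drugs and adverse events as verbatim
strings (brand names, salts, trademark glyphs, inconsistent casing).  Every
analysis in this package is phrased against *term sets*: named collections of
normalized strings with an explicit matching mode.  Drug sets default to
substring matching because verbatim drug fields embed the active moiety inside
longer product strings ("dapagliflozin propanediol"); reaction and indication
sets match MedDRA-style preferred terms and use exact matching by default.

The built-in vocabulary ships the exposure definition for SGLT2 inhibitors
(sodium-glucose cotransporter-2 inhibitors, the glucose-lowering class whose
atrial-fibrillation reporting this package was written to study) and the
companion sets needed by the sensitivity cascade: the ATC-A10 comparator class,
insulin, anti-arrhythmics, renal/cardiovascular/diabetes indications, the
competing adverse events preferentially reported for SGLT2i, and the
positive/negative control sets.  Sets whose full published search-term lists
are not reproducible here are marked ``placeholder=True`` and are meant to be
completed or overridden from a config file.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TermSet",
    "VocabularyConfig",
    "normalize_term",
    "normalize_series",
    "builtin_term_sets",
    "matches",
]

_KINDS = frozenset({"drug", "reaction", "indication"})
_MATCH_MODES = frozenset({"exact", "substring"})

# trademark / typographic punctuation stripped during normalization
_STRIP_CHARS = "®™©"  # (R), (TM), (C)
_STRIP_TABLE = str.maketrans("", "", _STRIP_CHARS)
_WS_RE = re.compile(r"\s+")


def normalize_term(raw: str) -> str:
    """Normalize a verbatim term: lowercase, strip trademark punctuation,
    collapse internal whitespace, trim.  Deterministic and idempotent;
    empty input yields an empty string."""
    if raw is None:
        return ""
    return _WS_RE.sub(" ", str(raw).translate(_STRIP_TABLE)).strip().lower()


def normalize_series(s: pd.Series) -> pd.Series:
    """Vectorized :func:`normalize_term` over a pandas Series of strings.

    Normalization is computed once per unique value (term vocabularies are
    tiny compared with row counts), then broadcast back by code.
    """
    codes, uniques = pd.factorize(s)
    normalized = np.array([normalize_term(u) for u in uniques] + [""], dtype=object)
    return pd.Series(normalized[codes], index=s.index)  # code -1 (NaN) -> ""


@dataclass(frozen=True)
class TermSet:
    """A named set of normalized terms with a matching mode.

    Parameters
    ----------
    name : str
        Unique identifier used by cohort and filter specifications.
    kind : {"drug", "reaction", "indication"}
        Which report field the set is matched against.
    terms : frozenset of str
        Normalized member terms (the constructor normalizes for you).
    match_mode : {"exact", "substring"}
        ``exact`` – a candidate matches iff its normalized form is a member;
        ``substring`` – a candidate matches iff any member occurs inside its
        normalized form.
    placeholder : bool
        True for built-in sets whose authoritative published term lists are
        not reproduced here; they are realistic but user-completable.
    """

    name: str
    kind: str
    terms: frozenset
    match_mode: str = "exact"
    placeholder: bool = False

    def __post_init__(self):
        if not self.name:
            raise ValueError("TermSet name must be nonempty")
        if self.kind not in _KINDS:
            raise ValueError(f"unknown TermSet kind {self.kind!r}")
        if self.match_mode not in _MATCH_MODES:
            raise ValueError(f"unknown match_mode {self.match_mode!r}")
        normalized = frozenset(normalize_term(t) for t in self.terms)
        normalized = frozenset(t for t in normalized if t)
        if not normalized:
            raise ValueError(f"TermSet {self.name!r} has no nonempty terms")
        object.__setattr__(self, "terms", normalized)

    def contains(self, term: str) -> bool:
        """True iff ``term`` matches this set under its match mode."""
        t = normalize_term(term)
        if self.match_mode == "exact":
            return t in self.terms
        return any(member in t for member in self.terms)

    def match_series(self, s: pd.Series) -> pd.Series:
        """Vectorized membership over a Series of verbatim terms.

        Matching is computed once per unique value, so the cost scales with
        vocabulary size rather than row count.
        """
        codes, uniques = pd.factorize(s)
        norm_unique = [normalize_term(u) for u in uniques]
        if self.match_mode == "exact":
            flags = [u in self.terms for u in norm_unique]
        else:
            pattern = re.compile("|".join(re.escape(t) for t in sorted(self.terms)))
            flags = [bool(pattern.search(u)) for u in norm_unique]
        hits = np.array(flags + [False])  # code -1 (NaN) never matches
        return pd.Series(hits[codes], index=s.index)


def matches(term_set: TermSet, term: str) -> bool:
    """Functional alias for :meth:`TermSet.contains`."""
    return term_set.contains(term)


@dataclass
class VocabularyConfig:
    """A collection of uniquely named term sets plus the normalization rules
    (which are fixed: case folding, trademark-punctuation stripping and
    whitespace collapse, applied by :func:`normalize_term`)."""

    term_sets: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, ts in self.term_sets.items():
            if name != ts.name:
                raise ValueError(f"term set registered under {name!r} is named {ts.name!r}")

    def __getitem__(self, name: str) -> TermSet:
        try:
            return self.term_sets[name]
        except KeyError:
            raise KeyError(
                f"unknown term set {name!r}; available: {sorted(self.term_sets)}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self.term_sets

    def add(self, term_set: TermSet, replace: bool = False) -> None:
        if term_set.name in self.term_sets and not replace:
            raise ValueError(f"term set {term_set.name!r} already defined")
        self.term_sets[term_set.name] = term_set

    # -- config file round-trip -------------------------------------------

    def to_yaml(self, path) -> None:
        doc = {
            "term_sets": {
                name: {
                    "kind": ts.kind,
                    "match_mode": ts.match_mode,
                    "placeholder": ts.placeholder,
                    "terms": sorted(ts.terms),
                }
                for name, ts in sorted(self.term_sets.items())
            }
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)

    @classmethod
    def from_yaml(cls, path) -> "VocabularyConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        sets = {}
        for name, spec in (doc.get("term_sets") or {}).items():
            sets[name] = TermSet(
                name=name,
                kind=spec["kind"],
                terms=frozenset(spec["terms"]),
                match_mode=spec.get("match_mode", "exact"),
                placeholder=bool(spec.get("placeholder", False)),
            )
        return cls(term_sets=sets)


# --------------------------------------------------------------------------
# Built-in vocabulary
# --------------------------------------------------------------------------

# The SGLT2-inhibitor exposure definition: ten members, including the fixed
# combination products marketed in the study window.
_SGLT2I_TERMS = (
    "canagliflozin",
    "empagliflozin",
    "dapagliflozin",
    "metformin and canagliflozin",
    "linagliptin and empagliflozin",
    "metformin and empagliflozin",
    "ertugliflozin",
    "ipragliflozin",
    "metformin and dapagliflozin",
    "sotagliflozin",
)

_AF_TERMS = ("atrial fibrillation", "atrial flutter")

# Comparator: other glucose-lowering drugs of ATC class A10 (insulin A10A and
# non-insulin A10B).  Placeholder list of generic names; with substring
# matching, "insulin" covers all insulin products.
_ATC_A10_COMPARATOR = (
    "metformin",
    "glimepiride",
    "glipizide",
    "glyburide",
    "glibenclamide",
    "gliclazide",
    "sitagliptin",
    "saxagliptin",
    "linagliptin",
    "alogliptin",
    "vildagliptin",
    "liraglutide",
    "exenatide",
    "dulaglutide",
    "semaglutide",
    "lixisenatide",
    "pioglitazone",
    "rosiglitazone",
    "acarbose",
    "miglitol",
    "repaglinide",
    "nateglinide",
    "insulin",
)

_ANTI_ARRHYTHMICS = (
    "amiodarone",
    "dronedarone",
    "sotalol",
    "flecainide",
    "propafenone",
    "dofetilide",
    "ibutilide",
    "quinidine",
    "disopyramide",
    "mexiletine",
)

_RENAL_INDICATIONS = (
    "renal failure",
    "renal impairment",
    "acute kidney injury",
    "chronic kidney disease",
    "diabetic nephropathy",
    "nephropathy",
)

_CVD_INDICATIONS = (
    "coronary artery disease",
    "myocardial infarction",
    "cardiac failure",
    "angina pectoris",
    "hypertension",
    "atherosclerosis",
    "myocardial ischaemia",
)

_DIABETES_INDICATIONS = (
    "diabetes mellitus",
    "type 2 diabetes mellitus",
    "type 1 diabetes mellitus",
)

# Competing adverse events reported preferentially for SGLT2i: genitourinary
# tract infections, diabetic ketoacidosis, Fournier's gangrene, amputations.
_COMPETING_AE = (
    "urinary tract infection",
    "genitourinary tract infection",
    "genital infection fungal",
    "vulvovaginal candidiasis",
    "vulvovaginal mycotic infection",
    "balanoposthitis",
    "diabetic ketoacidosis",
    "ketoacidosis",
    "fournier's gangrene",
    "necrotising fasciitis",
    "amputation",
    "toe amputation",
    "leg amputation",
)

_STROKE = ("cerebrovascular accident", "ischaemic stroke", "haemorrhagic stroke", "stroke")
_HEART_FAILURE = ("cardiac failure", "cardiac failure congestive", "heart failure")
_CKD_REACTIONS = ("chronic kidney disease", "renal failure chronic")


def builtin_term_sets() -> VocabularyConfig:
    """The built-in vocabulary used by the default analysis battery.

    The SGLT2I and AF sets are authoritative; sets flagged ``placeholder``
    carry realistic but user-completable term lists.  Load-time assertions
    enforce the disjointness the analyses rely on (SGLT2i vs insulin terms,
    focal AF terms vs competing-AE terms).
    """
    sets = [
        TermSet("sglt2i", "drug", frozenset(_SGLT2I_TERMS), "substring"),
        TermSet("af", "reaction", frozenset(_AF_TERMS), "exact"),
        TermSet("atc_a10_comparator", "drug", frozenset(_ATC_A10_COMPARATOR), "substring", True),
        TermSet("insulin", "drug", frozenset({"insulin"}), "substring", True),
        TermSet("anti_arrhythmics", "drug", frozenset(_ANTI_ARRHYTHMICS), "substring", True),
        TermSet("renal_indication", "indication", frozenset(_RENAL_INDICATIONS), "exact", True),
        TermSet("cvd_indication", "indication", frozenset(_CVD_INDICATIONS), "exact", True),
        TermSet("diabetes_indication", "indication", frozenset(_DIABETES_INDICATIONS), "substring", True),
        TermSet("competing_ae", "reaction", frozenset(_COMPETING_AE), "exact", True),
        TermSet("ibrutinib", "drug", frozenset({"ibrutinib"}), "substring"),
        TermSet("appendicitis", "reaction", frozenset({"appendicitis"}), "exact"),
        TermSet("stroke", "reaction", frozenset(_STROKE), "exact", True),
        TermSet("heart_failure", "reaction", frozenset(_HEART_FAILURE), "exact", True),
        TermSet("chronic_kidney_disease", "reaction", frozenset(_CKD_REACTIONS), "exact", True),
    ]
    vocab = VocabularyConfig(term_sets={ts.name: ts for ts in sets})
    # disjointness the analyses depend on
    assert not (vocab["sglt2i"].terms & vocab["insulin"].terms)
    assert not (vocab["af"].terms & vocab["competing_ae"].terms)
    return vocab
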