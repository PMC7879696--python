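"""Seeded generator of FAERS-like report stores with known ground truth.

Real spontaneous-report data cannot be bundled, so every pipeline stage is
exercised on synthetic stores that emulate the statistical structure the
analysis assumes: two exposure arms (SGLT2-inhibitor reports vs reports for
other ATC-A10 glucose-lowering drugs), per-report drug roles, indications,
demographics, case-version duplicates, a focal event (atrial fibrillation /
flutter) with a configurable reporting ratio, and competing adverse events
that can *mask* the focal event.

Report model
------------
Each report is triggered by an adverse-event complex.  Competing adverse
events (genitourinary infections, ketoacidosis, Fournier's gangrene,
amputations) are drawn first, per event, with arm-specific probabilities; a
report that carries a competing event does not also carry the focal event —
this is precisely the masking/dilution mechanism of interest: competing
reports inflate the arm's denominator without contributing focal events.
Among competing-free reports the focal event appears with probability
``p_event_comparator`` in the comparator arm and ``true_ratio ×
p_event_comparator`` in the exposed arm, so ``true_ratio`` is the ground-truth
reporting ratio recovered by an analysis that excludes competing-event
reports.  Under the default (small, realistic) competing probabilities the
marginal ratio differs from ``true_ratio`` by well under 2%; scaling the
exposed-arm competing probabilities (:func:`masking_scenario`) widens that gap
and lets the dilution argument be tested as a simulation property.

Defaults mirror the study conditions this package was built around: arm sizes
62,098 / 642,031, comparator focal-event rate 8.7 per 1000, true ratio 0.55,
insulin on 31% of comparator reports, primary-suspect shares 56.0% (exposed)
and 29.7% (comparator).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import faers_io
from .faers_io import ReportStore
from .vocabulary import builtin_term_sets

__all__ = ["GeneratorConfig", "GroundTruth", "generate", "masking_scenario"]

# Exposed-arm drug vocabulary: single-agent SGLT2 inhibitors.  Fixed
# combinations (e.g. "metformin and canagliflozin") are excluded by default
# because their names substring-match comparator drugs, which would make the
# generated group labels ambiguous; include_combination_products restores them.
_SGLT2I_SINGLE = (
    "canagliflozin",
    "empagliflozin",
    "dapagliflozin",
    "ertugliflozin",
    "ipragliflozin",
    "sotagliflozin",
)
_SGLT2I_COMBOS = (
    "metformin and canagliflozin",
    "linagliptin and empagliflozin",
    "metformin and empagliflozin",
    "metformin and dapagliflozin",
)
_COMPARATOR_NON_INSULIN = (
    "metformin",
    "glimepiride",
    "sitagliptin",
    "linagliptin",
    "liraglutide",
    "dulaglutide",
    "pioglitazone",
    "glipizide",
)
_INSULIN_PRODUCTS = ("insulin glargine", "insulin aspart", "insulin human", "insulin detemir")
_ANTI_ARRHYTHMIC_POOL = ("amiodarone", "sotalol", "flecainide", "dronedarone")
_FOCAL_TERMS = ("atrial fibrillation", "atrial flutter")
# innocuous filler vocabulary, disjoint from every analytic term set
_FILLER_TERMS = ("headache", "nausea", "dizziness", "fatigue", "rash", "diarrhoea")
_QUARTERS = tuple(f"{y}q{q}" for y in range(2014, 2020) for q in range(1, 5))


def _default_competing():
    # name -> (p_exposed, p_comparator); totals ~0.020 vs ~0.0062
    return {
        "urinary tract infection": (0.010, 0.004),
        "diabetic ketoacidosis": (0.005, 0.001),
        "fournier's gangrene": (0.001, 0.0002),
        "toe amputation": (0.004, 0.001),
    }


def _default_control_events():
    # independent extra reactions exercising the built-in control analyses
    return {
        "appendicitis": (0.0002, 0.0002),
        "cerebrovascular accident": (0.0019, 0.0020),
        "cardiac failure": (0.0016, 0.0100),
        "chronic kidney disease": (0.0010, 0.0031),
    }


def _default_demographics():
    return {
        "age_band": {"<18": 0.01, "18-64": 0.38, ">=65": 0.52, "unknown": 0.09},
        "sex": {"male": 0.47, "female": 0.45, "unknown": 0.08},
        "reporter": {
            "physician": 0.33,
            "other_hcp": 0.18,
            "pharmacist": 0.06,
            "consumer": 0.30,
            "other": 0.05,
            "unknown": 0.08,
        },
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic report generator (all seeded, all bounded).

    Probabilities are per report; ``competing_ae_probs`` maps a competing
    reaction term to its (exposed, comparator) per-report probabilities.
    ``true_ratio`` must satisfy ``true_ratio × p_event_comparator ≤ 1``.
    """

    n_exposed: int = 62_098
    n_comparator: int = 642_031
    true_ratio: float = 0.55
    p_event_comparator: float = 0.0087
    p_insulin_comparator: float = 0.31
    p_antiarrhythmic: float = 0.02
    p_cvd_indication: float = 0.08
    p_renal_indication: float = 0.03
    p_diabetes_indication: float = 0.60
    competing_ae_probs: dict = field(default_factory=_default_competing)
    control_event_probs: dict = field(default_factory=_default_control_events)
    duplicate_rate: float = 0.05
    p_primary_suspect_exposed: float = 0.560
    p_primary_suspect_comparator: float = 0.297
    include_combination_products: bool = False
    demographics: dict = field(default_factory=_default_demographics)
    seed: int = 0

    def __post_init__(self):
        if self.n_exposed < 0 or self.n_comparator < 0:
            raise ValueError("arm sizes must be non-negative")
        probs = [
            self.p_event_comparator,
            self.p_insulin_comparator,
            self.p_antiarrhythmic,
            self.p_cvd_indication,
            self.p_renal_indication,
            self.p_diabetes_indication,
            self.duplicate_rate,
            self.p_primary_suspect_exposed,
            self.p_primary_suspect_comparator,
        ]
        for probmap in (self.competing_ae_probs, self.control_event_probs):
            for pe, pc in probmap.values():
                probs.extend([pe, pc])
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.true_ratio <= 0:
            raise ValueError("true_ratio must be positive")
        if self.true_ratio * self.p_event_comparator > 1.0:
            raise ValueError("true_ratio × p_event_comparator exceeds 1")
        for key, dist in self.demographics.items():
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"demographic distribution {key!r} sums to {total}, not 1")


@dataclass
class GroundTruth:
    """Per-case generator labels, aligned with the emitted store.

    ``labels`` has one row per unique case with columns: ``caseid``,
    ``group`` (exposed/comparator), ``has_focal_event``, ``has_competing``,
    ``insulin``, ``antiarrhythmic``, ``diabetes_indication``,
    ``renal_indication``, ``cvd_indication``, ``primary_suspect``, ``sex``,
    ``reporter`` and ``duplicate_of`` (the superseded primaryid, or "").
    """

    labels: pd.DataFrame
    config: GeneratorConfig

    @property
    def exposed_ids(self) -> frozenset:
        return frozenset(self.labels.loc[self.labels["group"] == "exposed", "caseid"])

    @property
    def comparator_ids(self) -> frozenset:
        return frozenset(self.labels.loc[self.labels["group"] == "comparator", "caseid"])

    def to_tsv(self, path) -> None:
        self.labels.to_csv(path, sep="\t", index=False)


def masking_scenario(config: GeneratorConfig, masking_strength: float) -> GeneratorConfig:
    """Scale the exposed-arm competing-event probabilities by
    ``masking_strength`` (capped at 1); everything else is unchanged.
    Strength 0 removes competing events from the exposed arm; strength 1 is
    the identity."""
    if masking_strength < 0:
        raise ValueError("masking_strength must be non-negative")
    scaled = {
        name: (min(1.0, pe * masking_strength), pc)
        for name, (pe, pc) in config.competing_ae_probs.items()
    }
    return dataclasses.replace(config, competing_ae_probs=scaled)


def _choice(rng, options, probs, n):
    return rng.choice(np.asarray(options, dtype=object), size=n, p=np.asarray(probs))


def generate(config: GeneratorConfig = None) -> tuple:
    """Generate a seeded synthetic report store and its ground truth.

    Returns ``(ReportStore, GroundTruth)``.  The store contains
    ``n_exposed + n_comparator`` unique cases plus injected duplicate case
    versions; :func:`dispro.faers_io.dedup_latest` recovers exactly the
    unique cases.  Output is a pure function of the config (seed included).
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    n_e, n_c = config.n_exposed, config.n_comparator
    n = n_e + n_c

    _assert_filler_disjoint()

    exposed = np.zeros(n, dtype=bool)
    exposed[:n_e] = True
    caseid = np.array([f"SYN{i:08d}" for i in range(n)], dtype=object)

    # competing adverse events (arm-specific probabilities)
    comp_hits = {}
    has_comp = np.zeros(n, dtype=bool)
    for name, (pe, pc) in config.competing_ae_probs.items():
        p = np.where(exposed, pe, pc)
        hit = rng.random(n) < p
        comp_hits[name] = hit
        has_comp |= hit

    # focal event: competing-free reports only (see module docstring)
    p_focal = np.where(exposed, config.true_ratio * config.p_event_comparator, config.p_event_comparator)
    focal = (rng.random(n) < p_focal) & ~has_comp
    focal_term = np.array(_FOCAL_TERMS, dtype=object)[(rng.random(n) < 0.5).astype(int)]

    # independent control-event reactions
    control_hits = {}
    any_control = np.zeros(n, dtype=bool)
    for name, (pe, pc) in config.control_event_probs.items():
        hit = rng.random(n) < np.where(exposed, pe, pc)
        control_hits[name] = hit
        any_control |= hit

    filler_needed = ~(focal | has_comp | any_control)
    filler_term = _choice(rng, _FILLER_TERMS, [1 / len(_FILLER_TERMS)] * len(_FILLER_TERMS), n)

    # primary drug (drug_seq 1)
    sglt2i_pool = _SGLT2I_SINGLE + (_SGLT2I_COMBOS if config.include_combination_products else ())
    drug1 = np.empty(n, dtype=object)
    drug1[exposed] = rng.choice(np.asarray(sglt2i_pool, dtype=object), size=n_e)
    insulin = np.zeros(n, dtype=bool)
    insulin[n_e:] = rng.random(n_c) < config.p_insulin_comparator
    comp_drug = rng.choice(np.asarray(_COMPARATOR_NON_INSULIN, dtype=object), size=n_c)
    ins_drug = rng.choice(np.asarray(_INSULIN_PRODUCTS, dtype=object), size=n_c)
    drug1[n_e:] = np.where(insulin[n_e:], ins_drug, comp_drug)

    p_ps = np.where(exposed, config.p_primary_suspect_exposed, config.p_primary_suspect_comparator)
    u = rng.random(n)
    # remaining role mass split 1:2 between secondary suspect and concomitant
    role_code = np.where(u < p_ps, 0, np.where(u < p_ps + (1 - p_ps) / 3, 1, 2))
    role1 = np.array(["primary_suspect", "suspect", "concomitant"], dtype=object)[role_code]

    antiarrhythmic = rng.random(n) < config.p_antiarrhythmic
    aa_drug = rng.choice(np.asarray(_ANTI_ARRHYTHMIC_POOL, dtype=object), size=n)

    # indications attached to the primary drug
    diabetes_ind = rng.random(n) < config.p_diabetes_indication
    renal_ind = rng.random(n) < config.p_renal_indication
    cvd_ind = rng.random(n) < config.p_cvd_indication

    demo_draws = {
        key: _choice(rng, list(dist), list(dist.values()), n)
        for key, dist in config.demographics.items()
    }
    quarter = _choice(rng, _QUARTERS, [1 / len(_QUARTERS)] * len(_QUARTERS), n)

    # duplicate injection: chosen cases get a superseded version-1 copy
    n_dup = int(round(config.duplicate_rate * n))
    dup_idx = rng.choice(n, size=n_dup, replace=False) if n_dup else np.array([], dtype=int)
    is_dup = np.zeros(n, dtype=bool)
    is_dup[dup_idx] = True
    version = np.where(is_dup, 2, 1)
    old_pid = caseid + "-1"  # object arrays support elementwise concat
    primaryid = old_pid.copy()
    primaryid[dup_idx] = caseid[dup_idx] + "-2"

    # ---- assemble frames (numpy-level; detail rows reference reports by
    # index, then duplicated cases get superseded copies of their rows) ----

    def _with_dup_rows(report_idx, columns):
        """Append copies of rows belonging to duplicated reports, keyed by
        the superseded version-1 primaryid; returns the final dict."""
        report_idx = np.asarray(report_idx)
        pid = primaryid[report_idx]
        m = is_dup[report_idx]
        out = {"primaryid": np.concatenate([pid, old_pid[report_idx[m]]])}
        for name, col in columns.items():
            col = np.asarray(col, dtype=object)
            out[name] = np.concatenate([col, col[m]])
        return out

    all_idx = np.arange(n)
    demo_cols = _with_dup_rows(
        all_idx,
        {
            "caseid": caseid,
            "quarter": quarter,
            "age_band": demo_draws["age_band"],
            "sex": demo_draws["sex"],
            "occp_cod": demo_draws["reporter"],
        },
    )
    demo_cols["caseversion"] = np.concatenate([version, np.ones(n_dup, dtype=int)])
    demo = pd.DataFrame(demo_cols)[
        ["primaryid", "caseid", "caseversion", "quarter", "age_band", "sex", "occp_cod"]
    ]

    aa_idx = np.flatnonzero(antiarrhythmic)
    drug_idx = np.concatenate([all_idx, aa_idx])
    drugs = pd.DataFrame(
        _with_dup_rows(
            drug_idx,
            {
                "drug_seq": np.concatenate(
                    [np.full(n, "1", dtype=object), np.full(len(aa_idx), "2", dtype=object)]
                ),
                "drugname": np.concatenate([drug1, aa_drug[aa_idx]]),
                "role_cod": np.concatenate(
                    [role1, np.full(len(aa_idx), "concomitant", dtype=object)]
                ),
            },
        )
    )[["primaryid", "drug_seq", "drugname", "role_cod"]]

    reac_idx_parts, reac_pt_parts = [np.flatnonzero(focal)], [focal_term[focal]]
    for name, hit in {**comp_hits, **control_hits}.items():
        idx = np.flatnonzero(hit)
        reac_idx_parts.append(idx)
        reac_pt_parts.append(np.full(len(idx), name, dtype=object))
    filler_idx = np.flatnonzero(filler_needed)
    reac_idx_parts.append(filler_idx)
    reac_pt_parts.append(filler_term[filler_idx])
    reactions = pd.DataFrame(
        _with_dup_rows(np.concatenate(reac_idx_parts), {"pt": np.concatenate(reac_pt_parts)})
    )[["primaryid", "pt"]]

    indi_idx_parts, indi_pt_parts = [], []
    for mask, term in (
        (diabetes_ind, "type 2 diabetes mellitus"),
        (renal_ind, "renal impairment"),
        (cvd_ind, "coronary artery disease"),
    ):
        idx = np.flatnonzero(mask)
        indi_idx_parts.append(idx)
        indi_pt_parts.append(np.full(len(idx), term, dtype=object))
    indi_idx = np.concatenate(indi_idx_parts)
    indications = pd.DataFrame(
        _with_dup_rows(
            indi_idx,
            {
                "drug_seq": np.full(len(indi_idx), "1", dtype=object),
                "indi_pt": np.concatenate(indi_pt_parts),
            },
        )
    )[["primaryid", "drug_seq", "indi_pt"]]

    store = ReportStore(
        demo=demo,
        drugs=drugs,
        reactions=reactions,
        indications=indications,
        provenance=[f"synthetic(seed={config.seed})"],
    )

    duplicate_of = np.full(n, "", dtype=object)
    if n_dup:
        duplicate_of[dup_idx] = caseid[dup_idx] + "-1"
    labels = pd.DataFrame(
        {
            "caseid": caseid.astype(object),
            "group": np.where(exposed, "exposed", "comparator"),
            "has_focal_event": focal,
            "has_competing": has_comp,
            "insulin": insulin,
            "antiarrhythmic": antiarrhythmic,
            "diabetes_indication": diabetes_ind,
            "renal_indication": renal_ind,
            "cvd_indication": cvd_ind,
            "primary_suspect": role1 == "primary_suspect",
            "sex": demo_draws["sex"],
            "reporter": demo_draws["reporter"],
            "duplicate_of": duplicate_of,
        }
    )
    return store, GroundTruth(labels=labels, config=config)


def _assert_filler_disjoint():
    """Filler reactions must not collide with any analytic term set."""
    vocab = builtin_term_sets()
    for ts in vocab.term_sets.values():
        if ts.kind == "reaction":
            clash = set(_FILLER_TERMS) & ts.terms
            assert not clash, f"filler terms {clash} collide with term set {ts.name!r}"
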