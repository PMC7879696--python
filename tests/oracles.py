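"""Independent brute-force oracles used to cross-check the pipeline.

Everything here works on lists of Report dataclasses with plain Python loops
and set algebra, and re-implements term matching and the PRR formula from
first principles (scalar string operations; 50-digit decimal arithmetic), so
that agreement with the vectorized pandas pipeline is a meaningful check.
"""

from decimal import Decimal, getcontext

from dispro.cohorts import REST_OF_DATABASE

getcontext().prec = 50


# --------------------------------------------------------------------------
# scalar term matching (independent of TermSet.match_series)
# --------------------------------------------------------------------------

def _norm(raw):
    out = []
    for ch in str(raw):
        if ch in "®™©":
            continue
        out.append(ch)
    return " ".join("".join(out).split()).lower()


def term_matches(term_set, term):
    t = _norm(term)
    if term_set.match_mode == "exact":
        return t in term_set.terms
    return any(member in t for member in term_set.terms)


# --------------------------------------------------------------------------
# report-level predicates and pipeline
# --------------------------------------------------------------------------

def report_predicate(report, filter_spec, vocab):
    ts = vocab[filter_spec.set_name]
    if filter_spec.predicate_kind == "drug_in_set":
        return any(term_matches(ts, d.term) for d in report.drugs)
    if filter_spec.predicate_kind == "indication_in_set":
        return any(term_matches(ts, ind) for d in report.drugs for ind in d.indications)
    return any(term_matches(ts, pt) for pt in report.reactions)


def oracle_pipeline(reports, spec, vocab, event_set_name="af"):
    """One-pass enumeration of assign → filter → count.

    Returns (exposed_ids, comparator_ids, (a, b, c, d)); the counts are None
    if either final group is empty.
    """
    pool = [
        r
        for r in reports
        if (spec.sex_restrict is None or r.sex == spec.sex_restrict)
        and (spec.reporter_restrict is None or r.reporter in spec.reporter_restrict)
    ]
    exposure_set = vocab[spec.exposure_set]
    exposed, comparator = set(), set()
    for r in pool:
        in_exp = any(
            term_matches(exposure_set, d.term) for d in r.drugs if d.role in spec.drug_roles
        )
        if spec.comparator_set == REST_OF_DATABASE:
            in_cmp = not in_exp
        else:
            in_cmp = any(
                term_matches(vocab[spec.comparator_set], d.term)
                for d in r.drugs
                if d.role in spec.drug_roles
            )
        if in_exp:
            exposed.add(r.case_id)
        if in_cmp:
            comparator.add(r.case_id)
    overlap = exposed & comparator
    if spec.overlap_policy == "exclude_from_comparator":
        comparator -= overlap
    elif spec.overlap_policy == "exclude_from_both":
        exposed -= overlap
        comparator -= overlap

    by_id = {r.case_id: r for r in pool}
    for f in spec.filters:
        holds = {cid for cid, r in by_id.items() if report_predicate(r, f, vocab)}
        if f.action == "exclude_report":
            if f.applies_to in ("both", "exposed"):
                exposed -= holds
            if f.applies_to in ("both", "comparator"):
                comparator -= holds
        else:
            if f.applies_to in ("both", "exposed"):
                exposed &= holds
            if f.applies_to in ("both", "comparator"):
                comparator &= holds

    if not exposed or not comparator:
        return exposed, comparator, None
    event_set = vocab[event_set_name]
    with_event = {
        cid for cid, r in by_id.items() if any(term_matches(event_set, pt) for pt in r.reactions)
    }
    a = len(exposed & with_event)
    c = len(comparator & with_event)
    return exposed, comparator, (a, len(exposed) - a, c, len(comparator) - c)


# --------------------------------------------------------------------------
# arbitrary-precision PRR / CI / chi-square
# --------------------------------------------------------------------------

def prr_decimal(a, b, c, d, z=Decimal("1.959964")):
    """PRR and log-Wald CI at 50-digit precision, with the same +0.5
    zero-cell rule as the implementation.  Returns Decimals (prr, lo, hi)."""
    half = Decimal("0.5")
    if a == 0 or c == 0:
        A, B, C, D = (Decimal(x) + half for x in (a, b, c, d))
    else:
        A, B, C, D = (Decimal(x) for x in (a, b, c, d))
    prr = (A / (A + B)) / (C / (C + D))
    se = (1 / A - 1 / (A + B) + 1 / C - 1 / (C + D)).sqrt()
    ln = prr.ln()
    return prr, (ln - z * se).exp(), (ln + z * se).exp()


def chi2_expected_counts(a, b, c, d):
    """Pearson chi-square via explicit expected-count enumeration."""
    n = a + b + c + d
    observed = {(0, 0): a, (0, 1): b, (1, 0): c, (1, 1): d}
    row = {0: a + b, 1: c + d}
    col = {0: a + c, 1: b + d}
    stat = 0.0
    for (i, j), o in observed.items():
        e = row[i] * col[j] / n
        stat += (o - e) ** 2 / e
    return stat
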