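"""Disproportionality statistics on a 2×2 report-count table.

The proportional reporting ratio (PRR) compares how often an adverse event
appears among reports for a drug group of interest versus a comparator group::

                 a / (a + b)        a = exposed reports with the event
        PRR  =  -------------       b = exposed reports without it
                 c / (c + d)        c, d = the same for the comparator

PRR < 1 means the event is reported disproportionally *less* often with the
exposure.  The 95% confidence interval is the standard log-scale Wald
interval, with

        SE(ln PRR) = sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d))

and CI = exp(ln PRR ± z·SE).  Reporting proportions are expressed per 1000
reports, and the two proportions are compared with Pearson's chi-square test
on the 2×2 table (no continuity correction by default; a flag enables Yates'
correction).  When an event cell is zero the Haldane–Anscombe correction adds
0.5 to all four cells before computing PRR and CI, and the result is flagged.

All statistics are carried at full precision; display rounding (2 decimals
for PRR/CI, 1 for rates) is applied only by the formatting helpers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats as _scipy_stats

__all__ = [
    "ContingencyTable",
    "DisproResult",
    "UndefinedCohortError",
    "compute_prr",
    "rate_per_1000",
    "chi_square",
    "significance_flag",
    "format_result",
]

Z_95 = 1.959964  # two-sided 95% normal quantile


class UndefinedCohortError(ValueError):
    """Raised when a group margin is zero and the statistic is undefined."""


@dataclass(frozen=True)
class ContingencyTable:
    """Counts of (event, no-event) × (exposed, comparator) reports."""

    a: int  # exposed, event
    b: int  # exposed, no event
    c: int  # comparator, event
    d: int  # comparator, no event

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, int(v))

    @property
    def n_exposed(self) -> int:
        return self.a + self.b

    @property
    def n_comparator(self) -> int:
        return self.c + self.d

    @classmethod
    def from_margins(cls, events_exposed, total_exposed, events_comparator, total_comparator):
        """Build from (events, totals) as printed in study reports."""
        return cls(
            a=events_exposed,
            b=total_exposed - events_exposed,
            c=events_comparator,
            d=total_comparator - events_comparator,
        )


@dataclass(frozen=True)
class DisproResult:
    """PRR point estimate with CI, rates, and the chi-square comparison."""

    prr: float
    ci_low: float
    ci_high: float
    rate_exposed_per_1000: float
    rate_comparator_per_1000: float
    chi2: float
    p_value: float
    zero_cell_corrected: bool = False

    @property
    def significant(self) -> bool:
        return significance_flag(self.p_value)


def rate_per_1000(events: int, total: int) -> float:
    """Reporting proportion per 1000 reports."""
    if total <= 0:
        raise UndefinedCohortError("rate undefined for an empty group")
    return 1000.0 * events / total


def chi_square(t: ContingencyTable, correction: bool = False):
    """Pearson chi-square on the 2×2 table (1 df).

    ``correction=True`` applies Yates' continuity correction.  Raises
    :class:`UndefinedCohortError` when any row or column margin is zero
    (an expected count of zero leaves the statistic undefined).
    """
    if t.n_exposed == 0 or t.n_comparator == 0 or (t.a + t.c) == 0 or (t.b + t.d) == 0:
        raise UndefinedCohortError("chi-square undefined: a table margin is zero")
    res = _scipy_stats.chi2_contingency([[t.a, t.b], [t.c, t.d]], correction=correction)
    return float(res.statistic), float(res.pvalue)


def significance_flag(p: float, alpha: float = 0.05) -> bool:
    """Strict threshold: significant iff ``p < alpha`` (NaN is not)."""
    if p is None or math.isnan(p):
        return False
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p!r} outside [0, 1]")
    return p < alpha


def compute_prr(t: ContingencyTable, z: float = Z_95, chi2_correction: bool = False) -> DisproResult:
    """PRR with log-Wald 95% CI, rates per 1000, and the chi-square test.

    Rates are always computed from the uncorrected counts.  If the event
    count is zero in either group, the Haldane–Anscombe +0.5 correction is
    applied to all four cells for the PRR and CI (``zero_cell_corrected``
    set).  The chi-square is computed on the original table when all margins
    are positive, and reported as NaN otherwise.
    """
    if t.n_exposed == 0 or t.n_comparator == 0:
        raise UndefinedCohortError("PRR undefined: an exposure group is empty")

    rate_e = rate_per_1000(t.a, t.n_exposed)
    rate_c = rate_per_1000(t.c, t.n_comparator)

    corrected = t.a == 0 or t.c == 0
    a, b, c, d = (
        (t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5) if corrected else (t.a, t.b, t.c, t.d)
    )
    prr = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1.0 / a - 1.0 / (a + b) + 1.0 / c - 1.0 / (c + d))
    log_prr = math.log(prr)
    ci_low = math.exp(log_prr - z * se)
    ci_high = math.exp(log_prr + z * se)

    try:
        chi2, p = chi_square(t, correction=chi2_correction)
    except UndefinedCohortError:
        chi2, p = float("nan"), float("nan")

    return DisproResult(
        prr=prr,
        ci_low=ci_low,
        ci_high=ci_high,
        rate_exposed_per_1000=rate_e,
        rate_comparator_per_1000=rate_c,
        chi2=chi2,
        p_value=p,
        zero_cell_corrected=corrected,
    )


def format_result(r: DisproResult) -> dict:
    """Display-rounded view: 2 decimals for PRR/CI, 1 for rates."""
    return {
        "prr": round(r.prr, 2),
        "ci_low": round(r.ci_low, 2),
        "ci_high": round(r.ci_high, 2),
        "rate_exposed_per_1000": round(r.rate_exposed_per_1000, 1),
        "rate_comparator_per_1000": round(r.rate_comparator_per_1000, 1),
        "chi2": round(r.chi2, 2) if not math.isnan(r.chi2) else None,
        "p": "<0.001" if (not math.isnan(r.p_value) and r.p_value < 0.001) else (
            round(r.p_value, 3) if not math.isnan(r.p_value) else None
        ),
        "significant": r.significant,
        "zero_cell_corrected": r.zero_cell_corrected,
    }
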