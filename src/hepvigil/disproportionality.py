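"""Disproportionality statistics on drug-event 2x2 tables.

For a drug D and adverse event E over a corpus of deduplicated spontaneous
reports, the contingency table is::

                 event E     other events
    drug D          a             b
    other drugs     c             d

The proportional reporting ratio compares the event's share within the
drug's reports to its share elsewhere,

    PRR = [a/(a+b)] / [c/(c+d)],

while the reporting odds ratio is the cross-product ratio

    ROR = (a/c)/(b/d) = ad/bc.

Confidence intervals are log-scale Wald intervals: the standard errors of
the log estimates are

    SE(ln ROR) = sqrt(1/a + 1/b + 1/c + 1/d)
    SE(ln PRR) = sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d))

and bounds are exp(ln point -/+ z * SE) with z the exact 97.5% normal
quantile.  Two screening rules are applied:

* PRR rule:  PRR > 2  and  chi^2 > 4  and  N > 2,
* ROR rule:  lower 95% ROR bound > 1  and  N > 2,

with N the number of target-event reports for the drug (cell a) and chi^2
the Pearson statistic (Yates continuity correction available by flag).  When
any cell is zero, 0.5 is added to all four cells (Haldane-Anscombe) before
the ratios and intervals are computed, and the result is marked corrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Sequence

import pandas as pd
from scipy.special import ndtri

from . import faers_io
from .faers_io import (
    AEReport,
    DrugDictionary,
    SUSPECT_ROLES,
    match_hit_pt,
    report_mentions_drug,
)

#: Exact two-sided 95% normal quantile (what standard statistical software
#: uses for "1.96").
Z95: float = float(ndtri(0.975))


class DegenerateTableError(ValueError):
    """A statistic is undefined for this table (zero margin or cell)."""


@dataclass(frozen=True)
class ContingencyTable:
    """Integer cells of one drug-event 2x2 table."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError("cells must be non-negative integers")
        if sum(cells) == 0:
            raise ValueError("table must contain at least one report")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def has_zero_cell(self) -> bool:
        return 0 in (self.a, self.b, self.c, self.d)

    def effective_cells(self, correct_zeros: bool = True) -> tuple[float, float, float, float, bool]:
        """Cells as floats, Haldane-Anscombe corrected if any cell is zero.

        Returns (a, b, c, d, corrected).  The +0.5 correction is applied to
        all four cells, and only when at least one cell is zero, so exact
        reproduction of printed statistics on fully populated tables is
        untouched.
        """
        if correct_zeros and self.has_zero_cell:
            return (self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5, True)
        return (float(self.a), float(self.b), float(self.c), float(self.d), False)

    def swap_rows_and_columns(self) -> "ContingencyTable":
        return ContingencyTable(self.d, self.c, self.b, self.a)


@dataclass(frozen=True)
class SignalStats:
    """PRR/ROR/chi2 and screening flags for one drug-event pair."""

    prr: float
    prr_ci: tuple[float, float]
    ror: float
    ror_ci: tuple[float, float]
    chi2: float
    n_reports: int  # cell a
    corrected: bool = False
    prr_signal: bool = False
    ror_signal: bool = False


def compute_prr(table: ContingencyTable, correct_zeros: bool = True) -> float:
    """PRR = [a/(a+b)] / [c/(c+d)]."""
    a, b, c, d, _ = table.effective_cells(correct_zeros)
    if a + b == 0:
        raise DegenerateTableError("PRR undefined: no reports for the drug (a+b=0)")
    if c + d == 0:
        raise DegenerateTableError("PRR undefined: no comparator reports (c+d=0)")
    if c == 0:
        raise DegenerateTableError("PRR undefined: event absent in comparator (c=0)")
    return (a / (a + b)) / (c / (c + d))


def compute_ror(table: ContingencyTable, correct_zeros: bool = True) -> float:
    """ROR = ad/bc."""
    a, b, c, d, _ = table.effective_cells(correct_zeros)
    if b == 0 or c == 0:
        raise DegenerateTableError("ROR undefined: zero off-diagonal cell (b or c)")
    return (a * d) / (b * c)


def compute_chi2(table: ContingencyTable, yates: bool = False) -> float:
    """Pearson chi-square on the 2x2 table, optional Yates correction.

    chi2 = N (|ad - bc| [- N/2])^2 / [(a+b)(c+d)(a+c)(b+d)], the continuity
    term clamped so the statistic never goes negative.
    """
    a, b, c, d = (float(table.a), float(table.b), float(table.c), float(table.d))
    n = a + b + c + d
    margins = (a + b, c + d, a + c, b + d)
    if any(m == 0 for m in margins):
        raise DegenerateTableError("chi2 undefined: zero row or column margin")
    dev = abs(a * d - b * c)
    if yates:
        dev = max(0.0, dev - n / 2)
    return n * dev * dev / math.prod(margins)


def _log_se(table: ContingencyTable, kind: str, correct_zeros: bool) -> tuple[float, bool]:
    a, b, c, d, corrected = table.effective_cells(correct_zeros)
    if kind == "ror":
        if min(a, b, c, d) <= 0:
            raise DegenerateTableError("ROR CI undefined: zero cell without correction")
        return math.sqrt(1 / a + 1 / b + 1 / c + 1 / d), corrected
    if kind == "prr":
        if a <= 0 or c <= 0:
            raise DegenerateTableError("PRR CI undefined: a or c is zero without correction")
        return math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d)), corrected
    raise ValueError(f"unknown interval kind {kind!r}")


def wald_ci(
    point: float,
    table: ContingencyTable,
    kind: str,
    correct_zeros: bool = True,
    z: float = Z95,
) -> tuple[float, float]:
    """Two-sided log-scale Wald interval around a PRR or ROR point estimate.

    The point estimate equals the geometric mean of the bounds.
    """
    se, _ = _log_se(table, kind, correct_zeros)
    log_point = math.log(point)
    return (math.exp(log_point - z * se), math.exp(log_point + z * se))


def apply_signal_criteria(stats: SignalStats) -> SignalStats:
    """Set the two screening flags (strict inequalities).

    PRR rule: PRR > 2 and chi2 > 4 and N > 2; ROR rule: lower 95% bound of
    the ROR > 1 and N > 2, with N the count of target-event reports for the
    drug (cell a).
    """
    n_ok = stats.n_reports > 2
    return replace(
        stats,
        prr_signal=bool(n_ok and stats.prr > 2 and stats.chi2 > 4),
        ror_signal=bool(n_ok and stats.ror_ci[0] > 1),
    )


def signal_stats(
    table: ContingencyTable, yates: bool = False, correct_zeros: bool = True
) -> SignalStats:
    """All disproportionality statistics plus screening flags for one table."""
    prr = compute_prr(table, correct_zeros)
    ror = compute_ror(table, correct_zeros)
    chi2 = compute_chi2(table, yates)
    corrected = correct_zeros and table.has_zero_cell
    stats = SignalStats(
        prr=prr,
        prr_ci=wald_ci(prr, table, "prr", correct_zeros),
        ror=ror,
        ror_ci=wald_ci(ror, table, "ror", correct_zeros),
        chi2=chi2,
        n_reports=table.a,
        corrected=corrected,
    )
    return apply_signal_criteria(stats)


# ---------------------------------------------------------------------------
# Corpus screening
# ---------------------------------------------------------------------------

def build_contingency(
    reports: Sequence[AEReport],
    generic: str,
    dictionary: DrugDictionary,
    event_matcher: Callable[[Sequence[str]], bool] = match_hit_pt,
    roles: frozenset[str] = SUSPECT_ROLES,
) -> ContingencyTable:
    """2x2 table for one generic against the event over deduplicated reports.

    The unit of counting is the report: a + b + c + d equals the corpus
    size regardless of how many drugs a report lists.
    """
    a = b = c = d = 0
    for rep in reports:
        exposed = report_mentions_drug(rep, generic, dictionary, roles)
        event = event_matcher(rep.reactions)
        if exposed and event:
            a += 1
        elif exposed:
            b += 1
        elif event:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


SIGNAL_COLUMNS = [
    "drug",
    "a",
    "b",
    "c",
    "d",
    "prr",
    "prr_l95",
    "prr_u95",
    "ror",
    "ror_l95",
    "ror_u95",
    "chi2",
    "n",
    "prr_signal",
    "ror_signal",
    "corrected",
]


def screen_pairs(
    reports: Sequence[AEReport],
    drugs: Iterable[str],
    dictionary: DrugDictionary | None = None,
    event_matcher: Callable[[Sequence[str]], bool] = match_hit_pt,
    roles: frozenset[str] = SUSPECT_ROLES,
    yates: bool = False,
) -> pd.DataFrame:
    """One SignalStats row per drug against the event matcher.

    Reports must already be deduplicated.  A drug with no target-event
    reports still yields a row (n=0, no flags); statistics that are
    undefined even after zero-cell correction come out as NaN.
    """
    dictionary = dictionary or faers_io.default_lmwh_dictionary()
    rows = []
    for generic in drugs:
        t = build_contingency(reports, generic, dictionary, event_matcher, roles)
        try:
            s = signal_stats(t, yates=yates)
        except DegenerateTableError:
            s = SignalStats(
                prr=float("nan"),
                prr_ci=(float("nan"), float("nan")),
                ror=float("nan"),
                ror_ci=(float("nan"), float("nan")),
                chi2=float("nan"),
                n_reports=t.a,
                corrected=t.has_zero_cell,
            )
        rows.append(
            {
                "drug": generic,
                "a": t.a,
                "b": t.b,
                "c": t.c,
                "d": t.d,
                "prr": s.prr,
                "prr_l95": s.prr_ci[0],
                "prr_u95": s.prr_ci[1],
                "ror": s.ror,
                "ror_l95": s.ror_ci[0],
                "ror_u95": s.ror_ci[1],
                "chi2": s.chi2,
                "n": s.n_reports,
                "prr_signal": s.prr_signal,
                "ror_signal": s.ror_signal,
                "corrected": s.corrected,
            }
        )
    return pd.DataFrame(rows, columns=SIGNAL_COLUMNS)


__all__ = [
    "ContingencyTable",
    "DegenerateTableError",
    "SIGNAL_COLUMNS",
    "SignalStats",
    "Z95",
    "apply_signal_criteria",
    "build_contingency",
    "compute_chi2",
    "compute_prr",
    "compute_ror",
    "screen_pairs",
    "signal_stats",
    "wald_ci",
]
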