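"""Inverse reconstruction of 2x2 tables from printed disproportionality stats.

Published signal tables usually print a drug's target-event count (cell a)
together with rounded statistics (PRR or ROR, a 95% CI and chi-square) but
not the remaining cells b, c, d.  This module recovers integer cells whose
forward statistics reproduce the printed values to their printed precision,
which turns a printed table into a checkable oracle.

Two entry points:

* :func:`reconstruct_table` — one drug in isolation.  The printed point
  estimate, CI and chi-square pin the three unknown cells up to printing
  precision, but when the inputs are a ROR with its CI and chi-square the
  system is exactly symmetric under swapping b and c, so two solution
  branches exist and statistics not supplied remain ambiguous between them.
* :func:`reconstruct_corpus` — several drugs screened against the same
  event over one reporting corpus.  Coherence across drugs (shared totals:
  every drug sees the same overall corpus size T and the same overall event
  count H) reduces the unknowns to T, H and one drug-total per drug, which
  resolves the branch ambiguity and pins held-out statistics far more
  tightly than any single row can.

The search works in two stages: a continuous least-squares fit of the
printed values (each residual scaled by half a unit in its last printed
decimal, "half-ULP"), then an exhaustive integer polish minimising the
maximum scaled residual.  Chi-square is the workhorse constraint: printed
to two or three decimals on values in the thousands it carries ~1e-7
relative precision.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

from .disproportionality import Z95, ContingencyTable

_STAT_KEYS = ("point", "ci_low", "ci_high", "chi2")


class ReconstructionError(ValueError):
    """No integer table reproduces the printed statistics within tolerance."""

    def __init__(self, message: str, best: "ReconstructionResult | None" = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class PrintedStats:
    """One drug's printed inputs: point estimate with CI, plus chi-square.

    ``kind`` says whether the point/CI triple is a PRR or a ROR.
    ``decimals`` gives the printed precision per statistic (defaults to two
    decimal places for everything).
    """

    a: int
    kind: str  # 'prr' | 'ror'
    point: float
    ci: tuple[float, float]
    chi2: float
    decimals: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("prr", "ror"):
            raise ValueError("kind must be 'prr' or 'ror'")
        if self.a < 1:
            raise ValueError("cell a must be a positive count")
        if not (0 < self.ci[0] < self.point < self.ci[1]):
            raise ValueError("need ci_low < point < ci_high, all positive")

    def half_ulp(self, key: str) -> float:
        return 0.5 * 10.0 ** (-self.decimals.get(key, 2))

    def targets(self) -> dict[str, float]:
        return {
            "point": self.point,
            "ci_low": self.ci[0],
            "ci_high": self.ci[1],
            "chi2": self.chi2,
        }


def _forward(a: float, b: float, c: float, d: float, kind: str, z: float, yates: bool
             ) -> dict[str, float]:
    """Forward statistics on (possibly non-integer) cells, as a dict."""
    n = a + b + c + d
    dev = abs(a * d - b * c)
    if yates:
        dev = max(0.0, dev - n / 2)
    chi2 = n * dev * dev / ((a + b) * (c + d) * (a + c) * (b + d))
    if kind == "ror":
        point = (a * d) / (b * c)
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    else:
        point = (a / (a + b)) / (c / (c + d))
        se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    return {
        "point": point,
        "ci_low": point * math.exp(-z * se),
        "ci_high": point * math.exp(z * se),
        "chi2": chi2,
    }


def _scaled_residuals(cells: tuple[float, float, float, float], printed: PrintedStats,
                      z: float, yates: bool) -> dict[str, float]:
    fwd = _forward(*cells, printed.kind, z, yates)
    return {k: (fwd[k] - v) / printed.half_ulp(k) for k, v in printed.targets().items()}


@dataclass(frozen=True)
class ReconstructionResult:
    table: ContingencyTable
    printed: PrintedStats
    residuals: Mapping[str, float]         # forward minus printed, raw units
    scaled_residuals: Mapping[str, float]  # in half-ULPs of the printed value
    n_candidates: int = 1

    @property
    def max_scaled_residual(self) -> float:
        return max(abs(v) for v in self.scaled_residuals.values())


def _result_for(cells: tuple[int, int, int, int], printed: PrintedStats,
                z: float, yates: bool, n_candidates: int = 1) -> ReconstructionResult:
    fcells = tuple(float(x) for x in cells)
    fwd = _forward(*fcells, printed.kind, z, yates)
    return ReconstructionResult(
        table=ContingencyTable(*cells),
        printed=printed,
        residuals={k: fwd[k] - v for k, v in printed.targets().items()},
        scaled_residuals=_scaled_residuals(fcells, printed, z, yates),
        n_candidates=n_candidates,
    )


def _chi2_only(a: float, b: float, c: float, d: float, yates: bool) -> float:
    n = a + b + c + d
    dev = abs(a * d - b * c)
    if yates:
        dev = max(0.0, dev - n / 2)
    return n * dev * dev / ((a + b) * (c + d) * (a + c) * (b + d))


def _solve_d_from_chi2(a: float, b: float, c: float, chi2: float, yates: bool,
                       d_hi: float = 1e12) -> float | None:
    """Root of chi2(a,b,c,d) = chi2 in d, beyond the independence point."""

    def g(d: float) -> float:
        return _chi2_only(a, b, c, d, yates) - chi2

    lo = b * c / a + 1.0  # ad > bc: association in the target direction
    try:
        if g(lo) * g(d_hi) > 0:
            return None
        return brentq(g, lo, d_hi, xtol=1e-6)
    except ValueError:
        return None


def _se2_bounds(printed: PrintedStats, z: float) -> tuple[float, float]:
    """Range of the squared log-SE consistent with the rounded CI."""
    lo, hi = printed.ci
    h_lo, h_hi = printed.half_ulp("ci_low"), printed.half_ulp("ci_high")
    tight = (math.log((hi - h_hi) / (lo + h_lo)) / (2 * z)) ** 2
    wide = (math.log((hi + h_hi) / (lo - h_lo)) / (2 * z)) ** 2
    return tight, wide


def _candidate_checks(printed: PrintedStats, b: int, c: int, chi2_val: float,
                      z: float, yates: bool, tolerance: float,
                      hits: list[tuple[int, int, int]]) -> None:
    """Solve d from chi-square and record integer cells passing all checks."""
    a = float(printed.a)
    d_real = _solve_d_from_chi2(a, float(b), float(c), chi2_val, yates)
    if d_real is None:
        return
    span = max(3, int(math.ceil(printed.half_ulp("chi2") * d_real / max(chi2_val, 1e-12))))
    for d in range(max(int(d_real) - span, 1), int(d_real) + span + 2):
        scaled = _scaled_residuals((a, float(b), float(c), float(d)), printed, z, yates)
        if max(abs(v) for v in scaled.values()) <= tolerance:
            hits.append((b, c, d))


def _search_prr_kind(printed: PrintedStats, z: float, yates: bool, tolerance: float,
                     max_secondary: int) -> list[tuple[int, int, int]]:
    """Scan integer b; solve c, d per candidate from the point and chi2.

    For PRR = P with k = a/(a+b), writing M = c + d gives c = M k / P and
    the squared log-SE identity collapses to M = (P/k - 1)/s0 with
    s0 = SE^2 - 1/a + 1/(a+b) — so b bounds itself: s0 must stay positive.
    """
    a = float(printed.a)
    _, se2_wide = _se2_bounds(printed, z)
    hits: list[tuple[int, int, int]] = []
    h_pt = printed.half_ulp("point")
    for b in range(1, max_secondary + 1):
        k = a / (a + b)
        s0 = se2_wide - 1 / a + 1 / (a + b)
        if s0 <= 0:
            break
        c_window: set[int] = set()
        for pt in (printed.point - h_pt, printed.point, printed.point + h_pt):
            def f(m: float, pt: float = pt) -> float:
                c = m * k / pt
                return _chi2_only(a, float(b), c, m - c, yates) - printed.chi2
            try:
                if f(10.0) * f(1e12) > 0:
                    continue
                m = brentq(f, 10.0, 1e12, xtol=1e-6)
            except ValueError:
                continue
            c_mid = m * k / pt
            c_window.update(range(max(1, int(c_mid) - 2), int(c_mid) + 3))
        for c in sorted(c_window):
            _candidate_checks(printed, b, c, printed.chi2, z, yates, tolerance, hits)
    return sorted(set(hits))


def _search_ror_kind(printed: PrintedStats, z: float, yates: bool, tolerance: float,
                     max_secondary: int) -> list[tuple[int, int, int]]:
    """Scan integer c; solve b, d per candidate from the point and chi2.

    SE^2 - 1/a = 1/b + 1/c + 1/d bounds c from below (and b symmetrically),
    giving a finite scan range; both b<->c branches fall inside it.
    """
    a = float(printed.a)
    se2_tight, se2_wide = _se2_bounds(printed, z)
    s_lo = se2_tight - 1 / a
    if s_lo <= 0:
        s_lo = 1e-9
    c_min = max(1, int(0.9 / (se2_wide - 1 / a)))
    c_max = min(max_secondary, int(60.0 / s_lo))
    hits: list[tuple[int, int, int]] = []
    h_pt = printed.half_ulp("point")
    for c in range(c_min, c_max + 1):
        b_window: set[int] = set()
        for pt in (printed.point - h_pt, printed.point, printed.point + h_pt):
            def f(b: float, pt: float = pt) -> float:
                d = pt * b * c / a
                return _chi2_only(a, b, float(c), d, yates) - printed.chi2
            try:
                if f(1.0) * f(1e8) > 0:
                    continue
                b_mid = brentq(f, 1.0, 1e8, xtol=1e-9)
            except ValueError:
                continue
            b_window.update(range(max(1, int(b_mid) - 2), int(b_mid) + 3))
        for b in sorted(b_window):
            _candidate_checks(printed, b, c, printed.chi2, z, yates, tolerance, hits)
    return sorted(set(hits))


def reconstruct_table(
    printed: PrintedStats,
    z: float = Z95,
    yates: bool = True,
    tolerance: float = 1.0,
    max_secondary: int = 200_000,
) -> ReconstructionResult:
    """Find integer cells b, c, d matching one drug's printed statistics.

    All four printed inputs must be reproduced within ``tolerance`` half-ULPs
    (1.0 = half a unit in the last printed decimal).  Among all integer
    candidates the one minimising the maximum scaled residual is returned;
    ``n_candidates`` reports how many tables passed, which is also a measure
    of how much ambiguity remains for statistics not supplied.

    Raises :class:`ReconstructionError` with the best near-miss attached when
    no candidate passes.
    """
    search = _search_prr_kind if printed.kind == "prr" else _search_ror_kind
    hits = search(printed, z, yates, tolerance, max_secondary)
    if not hits:
        best = _best_near_miss(printed, z, yates)
        raise ReconstructionError(
            f"no integer table reproduces the printed {printed.kind.upper()} inputs "
            f"within {tolerance} half-ULP; best candidate "
            f"{best.table if best else 'not found'} has residuals "
            f"{dict(best.scaled_residuals) if best else '?'}",
            best=best,
        )
    a = printed.a
    best_cells = min(
        hits,
        key=lambda bc: max(
            abs(v)
            for v in _scaled_residuals(
                (float(a), float(bc[0]), float(bc[1]), float(bc[2])), printed, z, yates
            ).values()
        ),
    )
    return _result_for((a, *best_cells), printed, z, yates, n_candidates=len(hits))


def _continuous_solutions(printed: PrintedStats, z: float, yates: bool
                          ) -> list[tuple[float, float, float]]:
    """Continuous (b,c,d) minimisers from a grid of starts, deduplicated."""
    a = float(printed.a)

    def resid(x: np.ndarray) -> list[float]:
        with np.errstate(all="ignore"):
            b, c, d = np.exp(np.clip(x, -30, 30))
            try:
                scaled = _scaled_residuals((a, b, c, d), printed, z, yates)
            except (ValueError, ZeroDivisionError, OverflowError):
                return [1e6] * 4
        vals = [scaled[k] for k in _STAT_KEYS]
        return vals if all(math.isfinite(v) for v in vals) else [1e6] * 4

    found: list[tuple[float, float, float]] = []
    for b0, c0, d0 in itertools.product((1e2, 1e3, 1e4, 1e5), (1e2, 1e3, 1e4),
                                        (1e5, 1e6, 1e7, 1e8)):
        try:
            fit = least_squares(resid, np.log([b0, c0, d0]), method="lm", max_nfev=4000)
        except Exception:
            continue
        if fit.cost > 50.0:  # far from reproducing the printed values
            continue
        sol = tuple(np.exp(fit.x))
        if not any(
            all(abs(u - v) / v < 1e-3 for u, v in zip(sol, prev)) for prev in found
        ):
            found.append(sol)
    return found


def _best_near_miss(printed: PrintedStats, z: float, yates: bool
                    ) -> ReconstructionResult | None:
    sols = _continuous_solutions(printed, z, yates)
    best: ReconstructionResult | None = None
    for b, c, d in sols:
        cells = (printed.a, max(1, round(b)), max(1, round(c)), max(1, round(d)))
        res = _result_for(cells, printed, z, yates)
        if best is None or res.max_scaled_residual < best.max_scaled_residual:
            best = res
    return best


# ---------------------------------------------------------------------------
# Joint corpus reconstruction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorpusReconstruction:
    """Coherent tables for several drugs screened over one corpus."""

    tables: Mapping[str, ContingencyTable]
    results: Mapping[str, ReconstructionResult]
    event_total: int   # H: corpus-wide count of target-event reports
    corpus_total: int  # T: corpus-wide report count

    @property
    def max_scaled_residual(self) -> float:
        return max(r.max_scaled_residual for r in self.results.values())


def _corpus_cells(a: Sequence[int], h: float, t: float, b: Sequence[float]
                  ) -> list[tuple[float, float, float, float]]:
    return [
        (float(ai), float(bi), h - ai, t - ai - bi - (h - ai))
        for ai, bi in zip(a, b)
    ]


def reconstruct_corpus(
    entries: Mapping[str, PrintedStats],
    z: float = Z95,
    yates: bool = True,
    tolerance: float = 1.0,
    span_b: int = 3,
    span_h: int = 3,
    span_t: int = 5000,
) -> CorpusReconstruction:
    """Jointly reconstruct one table per drug under shared corpus margins.

    Unknowns are the corpus totals H (target-event reports) and T (all
    reports) plus each drug's report total; cells follow as b_i = n_i - a_i,
    c_i = H - a_i, d_i = T - n_i - c_i.  A continuous least-squares fit of
    all printed inputs is polished over the integer lattice (H and the b_i
    within ``span_b``/``span_h`` of the rounded fit, T within ``span_t``)
    minimising the maximum scaled residual across every printed statistic.

    Raises :class:`ReconstructionError` when even the best integer corpus
    leaves some printed value off by more than ``tolerance`` half-ULPs.
    """
    names = list(entries)
    a = [entries[n].a for n in names]

    # Stage 0: branch-robust starting point from per-drug continuous solves.
    per_drug = [_continuous_solutions(entries[n], z, yates) for n in names]
    if any(not sols for sols in per_drug):
        missing = [n for n, sols in zip(names, per_drug) if not sols]
        raise ReconstructionError(f"no continuous solution for {missing}")
    best_combo = None
    for combo in itertools.product(*per_drug):
        hs = [c + ai for (b, c, d), ai in zip(combo, a)]
        ts = [ai + b + c + d for (b, c, d), ai in zip(combo, a)]
        spread = np.std(hs) / np.mean(hs) + np.std(ts) / np.mean(ts)
        if best_combo is None or spread < best_combo[0]:
            best_combo = (spread, combo)
    combo = best_combo[1]
    x0 = np.log(
        [np.mean([c + ai for (b, c, d), ai in zip(combo, a)])]
        + [np.mean([ai + b + c + d for (b, c, d), ai in zip(combo, a)])]
        + [b for (b, c, d) in combo]
    )

    # Stage 1: continuous joint fit.
    def resid(x: np.ndarray) -> list[float]:
        with np.errstate(all="ignore"):
            h, t, *bs = np.exp(np.clip(x, -30, 30))
            out: list[float] = []
            for name, cells in zip(names, _corpus_cells(a, h, t, bs)):
                if min(cells[1:]) <= 0:
                    return [1e6] * (4 * len(names))
                try:
                    scaled = _scaled_residuals(cells, entries[name], z, yates)
                except (ValueError, ZeroDivisionError, OverflowError):
                    return [1e6] * (4 * len(names))
                out.extend(scaled[k] for k in _STAT_KEYS)
        return out if all(math.isfinite(v) for v in out) else [1e6] * (4 * len(names))

    fit = least_squares(resid, x0, method="lm", max_nfev=40_000)
    h0, t0, *b0 = (int(round(v)) for v in np.exp(fit.x))

    # Stage 2: integer minimax polish, vectorised over T.
    t_grid = np.arange(t0 - span_t, t0 + span_t + 1, dtype=float)
    best: tuple[float, tuple[int, ...]] | None = None
    b_ranges = [range(bi - span_b, bi + span_b + 1) for bi in b0]
    for h in range(h0 - span_h, h0 + span_h + 1):
        for bs in itertools.product(*b_ranges):
            worst = np.zeros_like(t_grid)
            ok = True
            for name, ai, bi in zip(names, a, bs):
                printed = entries[name]
                ci = float(h - ai)
                if ci < 1 or bi < 1:
                    ok = False
                    break
                di = t_grid - ai - bi - ci
                fwd = _forward_vec(float(ai), float(bi), ci, di, printed.kind, z, yates)
                for k in _STAT_KEYS:
                    scaled = np.abs(fwd[k] - printed.targets()[k]) / printed.half_ulp(k)
                    worst = np.maximum(worst, scaled)
            if not ok:
                continue
            i = int(np.argmin(worst))
            if best is None or worst[i] < best[0]:
                best = (float(worst[i]), (h, int(t_grid[i]), *bs))
    if best is None:
        raise ReconstructionError("integer polish found no feasible corpus")

    max_resid, (h, t, *bs) = best
    tables = {
        name: ContingencyTable(ai, bi, h - ai, t - ai - bi - (h - ai))
        for name, ai, bi in zip(names, a, bs)
    }
    results = {
        name: _result_for(
            (tab.a, tab.b, tab.c, tab.d), entries[name], z, yates
        )
        for name, tab in tables.items()
    }
    recon = CorpusReconstruction(
        tables=tables, results=results, event_total=h, corpus_total=t
    )
    if max_resid > tolerance:
        raise ReconstructionError(
            f"best integer corpus leaves a printed statistic {max_resid:.2f} "
            f"half-ULPs off (tolerance {tolerance})",
            best=None,
        )
    return recon


def _forward_vec(a: float, b: float, c: float, d: np.ndarray, kind: str,
                 z: float, yates: bool) -> dict[str, np.ndarray]:
    n = a + b + c + d
    dev = np.abs(a * d - b * c)
    if yates:
        dev = np.maximum(0.0, dev - n / 2)
    chi2 = n * dev * dev / ((a + b) * (c + d) * (a + c) * (b + d))
    if kind == "ror":
        point = (a * d) / (b * c)
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    else:
        point = (a / (a + b)) / (c / (c + d))
        se = np.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    return {
        "point": point,
        "ci_low": point * np.exp(-z * se),
        "ci_high": point * np.exp(z * se),
        "chi2": chi2,
    }


__all__ = [
    "CorpusReconstruction",
    "PrintedStats",
    "ReconstructionError",
    "ReconstructionResult",
    "reconstruct_corpus",
    "reconstruct_table",
]
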