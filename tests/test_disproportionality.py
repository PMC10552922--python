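"""PRR/ROR/chi-square/Wald-CI formulas against independent oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from hepvigil.disproportionality import (
    ContingencyTable,
    DegenerateTableError,
    SignalStats,
    Z95,
    apply_signal_criteria,
    build_contingency,
    compute_chi2,
    compute_prr,
    compute_ror,
    screen_pairs,
    signal_stats,
    wald_ci,
)
from hepvigil.faers_io import deduplicate, default_lmwh_dictionary

positive_cells = st.tuples(
    st.integers(1, 500), st.integers(1, 500), st.integers(1, 500), st.integers(1, 500)
)


def _chi2_expected_counts(t: ContingencyTable, yates: bool) -> float:
    """Brute-force oracle: sum (|O-E| [- 1/2])^2 / E over the four cells."""
    obs = np.array([[t.a, t.b], [t.c, t.d]], dtype=float)
    total = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    dev = np.abs(obs - expected)
    if yates:
        dev = np.maximum(0.0, dev - 0.5)
    return float((dev**2 / expected).sum())


# ---------------------------------------------------------------------------
# Point estimates
# ---------------------------------------------------------------------------

def test_prr_hand_arithmetic():
    assert compute_prr(ContingencyTable(10, 90, 10, 890)) == pytest.approx(9.0)
    assert compute_prr(ContingencyTable(5, 5, 5, 5)) == pytest.approx(1.0)


def test_ror_hand_arithmetic():
    assert compute_ror(ContingencyTable(10, 90, 10, 890)) == pytest.approx(8900 / 900)
    assert compute_ror(ContingencyTable(3, 12, 7, 28)) == pytest.approx(1.0)


def test_chi2_hand_cases():
    t = ContingencyTable(10, 90, 10, 890)
    assert compute_chi2(t) == pytest.approx(_chi2_expected_counts(t, False), rel=1e-12)
    assert compute_chi2(ContingencyTable(10, 90, 20, 180)) == pytest.approx(0.0)


def test_degenerate_tables_raise_with_reason():
    with pytest.raises(DegenerateTableError, match="comparator"):
        compute_prr(ContingencyTable(1, 1, 0, 0), correct_zeros=False)
    with pytest.raises(DegenerateTableError, match="margin"):
        compute_chi2(ContingencyTable(0, 0, 3, 5))
    with pytest.raises(DegenerateTableError, match="zero cell"):
        wald_ci(2.0, ContingencyTable(1, 0, 1, 5), "ror", correct_zeros=False)


def test_zero_cells_get_haldane_anscombe_and_are_flagged():
    t = ContingencyTable(0, 10, 5, 100)
    s = signal_stats(t)
    assert s.corrected
    assert s.ror == pytest.approx((0.5 * 100.5) / (10.5 * 5.5))
    # fully populated tables are untouched
    assert not signal_stats(ContingencyTable(1, 10, 5, 100)).corrected


@given(positive_cells)
def test_formulas_agree_with_oracles_on_random_tables(cells):
    t = ContingencyTable(*cells)
    a, b, c, d = (float(x) for x in cells)
    assert compute_prr(t) == pytest.approx((a / (a + b)) / (c / (c + d)), rel=1e-12)
    assert compute_ror(t) == pytest.approx((a * d) / (b * c), rel=1e-12)
    for yates in (False, True):
        assert compute_chi2(t, yates) == pytest.approx(
            _chi2_expected_counts(t, yates), rel=1e-9, abs=1e-12
        )


@given(positive_cells)
def test_chi2_matches_scipy_contingency(cells):
    t = ContingencyTable(*cells)
    for yates in (False, True):
        ref = chi2_contingency(
            np.array([[t.a, t.b], [t.c, t.d]]), correction=yates
        ).statistic
        assert compute_chi2(t, yates) == pytest.approx(float(ref), rel=1e-9, abs=1e-12)


# ---------------------------------------------------------------------------
# Wald intervals
# ---------------------------------------------------------------------------

@given(positive_cells)
def test_wald_ci_matches_direct_formula_and_log_symmetry(cells):
    t = ContingencyTable(*cells)
    a, b, c, d = (float(x) for x in cells)
    ror = compute_ror(t)
    lo, hi = wald_ci(ror, t, "ror")
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    assert lo == pytest.approx(ror * math.exp(-Z95 * se), rel=1e-12)
    assert hi == pytest.approx(ror * math.exp(Z95 * se), rel=1e-12)
    assert math.sqrt(lo * hi) == pytest.approx(ror, rel=1e-9)

    prr = compute_prr(t)
    plo, phi = wald_ci(prr, t, "prr")
    pse = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    assert plo == pytest.approx(prr * math.exp(-Z95 * pse), rel=1e-12)
    assert phi == pytest.approx(prr * math.exp(Z95 * pse), rel=1e-12)


def test_ror_ci_matches_statsmodels_table2x2():
    statsmodels = pytest.importorskip("statsmodels.stats.contingency_tables")
    t = ContingencyTable(12, 488, 37, 9463)
    lo, hi = wald_ci(compute_ror(t), t, "ror")
    table = statsmodels.Table2x2(np.array([[t.a, t.b], [t.c, t.d]]))
    ref_lo, ref_hi = table.oddsratio_confint(0.05)
    assert lo == pytest.approx(ref_lo, rel=1e-9)
    assert hi == pytest.approx(ref_hi, rel=1e-9)


# ---------------------------------------------------------------------------
# Structural invariants
# ---------------------------------------------------------------------------

@given(positive_cells)
def test_ror_exceeds_prr_iff_association_positive(cells):
    t = ContingencyTable(*cells)
    prr, ror = compute_prr(t), compute_ror(t)
    if math.isclose(ror, 1.0, rel_tol=1e-12):
        assert math.isclose(prr, 1.0, rel_tol=1e-9)
    elif ror > 1:
        assert ror > prr
    else:
        assert ror < prr


@given(positive_cells, st.integers(1, 50))
def test_prr_and_ror_strictly_increase_in_a(cells, bump):
    t = ContingencyTable(*cells)
    bumped = ContingencyTable(t.a + bump, t.b, t.c, t.d)
    assert compute_prr(bumped) > compute_prr(t)
    assert compute_ror(bumped) > compute_ror(t)


@given(positive_cells)
def test_chi2_invariant_under_row_and_column_swap(cells):
    t = ContingencyTable(*cells)
    swapped = t.swap_rows_and_columns()
    for yates in (False, True):
        assert compute_chi2(t, yates) == pytest.approx(
            compute_chi2(swapped, yates), rel=1e-12
        )


# ---------------------------------------------------------------------------
# Screening criteria and corpus screening
# ---------------------------------------------------------------------------

def _stats(prr=1.0, chi2=0.0, n=10, ror=1.0, ror_l=0.5):
    return SignalStats(
        prr=prr,
        prr_ci=(prr / 2, prr * 2),
        ror=ror,
        ror_ci=(ror_l, ror * 2),
        chi2=chi2,
        n_reports=n,
    )


@pytest.mark.parametrize(
    "kwargs, prr_flag, ror_flag",
    [
        (dict(prr=2.5, chi2=5.0, n=3), True, False),
        (dict(prr=2.5, chi2=5.0, n=2), False, False),  # N must exceed 2
        (dict(prr=2.0, chi2=5.0, n=3), False, False),  # strict PRR > 2
        (dict(prr=2.5, chi2=4.0, n=3), False, False),  # strict chi2 > 4
        (dict(ror=3.0, ror_l=1.0, n=5), False, False),  # strict lower bound > 1
        (dict(ror=3.0, ror_l=1.01, n=5), False, True),
    ],
)
def test_signal_criteria_thresholds_are_strict(kwargs, prr_flag, ror_flag):
    flagged = apply_signal_criteria(_stats(**kwargs))
    assert flagged.prr_signal is prr_flag
    assert flagged.ror_signal is ror_flag


def test_screen_pairs_partitions_the_corpus(small_corpus):
    cfg, stream, _ = small_corpus
    reports = deduplicate(stream)
    dictionary = default_lmwh_dictionary()
    table = screen_pairs(reports, list(cfg.drugs), dictionary)
    assert (table[["a", "b", "c", "d"]].sum(axis=1) == len(reports)).all()
    # disjoint report sets (one drug per synthetic report): a+b counts
    # exactly the reports naming that drug
    from hepvigil.faers_io import report_mentions_drug

    for row in table.itertuples(index=False):
        expected = sum(
            report_mentions_drug(r, row.drug, dictionary) for r in reports
        )
        assert row.a + row.b == expected
        assert row.n == row.a


def test_screen_pairs_emits_row_for_absent_drug(small_corpus):
    _, stream, _ = small_corpus
    reports = deduplicate(stream[:50])
    table = screen_pairs(reports, ["reviparin"])
    row = table.iloc[0]
    assert row["a"] == 0 and not row["prr_signal"] and not row["ror_signal"]


def test_build_contingency_counts_suspect_roles_only(lmwh_dictionary):
    from datetime import date

    from hepvigil.faers_io import AEReport, DrugMention

    hit = ("Heparin-induced thrombocytopenia",)
    reports = [
        AEReport("A", 1, date(2020, 1, 1), (DrugMention("LOVENOX", "PS"),), hit),
        AEReport("B", 1, date(2020, 1, 1), (DrugMention("lovenox", "C"),), hit),
        AEReport("C", 1, date(2020, 1, 1), (DrugMention("aspirin", "PS"),), ("Rash",)),
    ]
    t = build_contingency(reports, "enoxaparin", lmwh_dictionary)
    assert (t.a, t.b, t.c, t.d) == (1, 0, 1, 1)
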