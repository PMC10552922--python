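"""Ingestion, deduplication, drug normalisation and the baseline table."""

from __future__ import annotations

from collections import Counter
from datetime import date

import pytest
from hypothesis import given
from hypothesis import strategies as st

from hepvigil.faers_io import (
    AEReport,
    DrugDictionary,
    DrugMention,
    FaersDialect,
    MissingColumnError,
    baseline_table,
    deduplicate,
    default_lmwh_dictionary,
    match_hit_pt,
    normalize_drug,
    read_reports,
    write_reports,
)
from hepvigil.synthetic import SimConfig, generate_reports


def _report(case_id="C1", version=1, day=1, **kwargs):
    defaults = dict(
        case_id=case_id,
        case_version=version,
        receipt_date=date(2020, 1, day),
        drugs=(DrugMention("enoxaparin", "PS"),),
        reactions=("Heparin-induced thrombocytopenia",),
    )
    defaults.update(kwargs)
    return AEReport(**defaults)


# ---------------------------------------------------------------------------
# read_reports
# ---------------------------------------------------------------------------

def _write_toy_quarter(tmp_path, demo_rows, drug_rows, reac_rows):
    (tmp_path / "demo.txt").write_text(
        "primaryid$caseid$caseversion$fda_dt$age$sex$outc_cod$occr_country\n"
        + "\n".join(demo_rows)
        + "\n"
    )
    (tmp_path / "drug.txt").write_text(
        "primaryid$role_cod$drugname\n" + "\n".join(drug_rows) + "\n"
    )
    (tmp_path / "reac.txt").write_text(
        "primaryid$pt\n" + "\n".join(reac_rows) + "\n"
    )
    return tmp_path / "demo.txt", tmp_path / "drug.txt", tmp_path / "reac.txt"


def test_toy_quarter_joins_drugs_and_reactions(tmp_path):
    demo, drug, reac = _write_toy_quarter(
        tmp_path,
        ["P1$A$1$20200115$64$F$HO$US", "P2$B$1$20200116$$M$$FR"],
        ["P1$PS$LOVENOX", "P1$C$aspirin", "P2$PS$warfarin"],
        ["P1$Heparin-induced thrombocytopenia", "P1$Rash", "P2$Nausea"],
    )
    reports, stats = read_reports(demo, drug, reac)
    assert stats.n_reports == 2 and stats.n_excluded == 0
    by_case = {r.case_id: r for r in reports}
    assert [m.verbatim for m in by_case["A"].drugs] == ["LOVENOX", "aspirin"]
    assert by_case["A"].reactions == ("Heparin-induced thrombocytopenia", "Rash")
    assert by_case["A"].age_years == 64.0
    assert by_case["A"].sex == "female"
    assert by_case["A"].outcome_code == "hospitalization"
    assert by_case["B"].age_years is None
    assert by_case["B"].outcome_code == "missing"


def test_orphan_child_rows_counted_not_joined(tmp_path):
    demo, drug, reac = _write_toy_quarter(
        tmp_path,
        ["P1$A$1$20200115$64$F$HO$US"],
        ["P1$PS$LOVENOX", "P9$PS$warfarin"],
        ["P1$Rash", "P9$Nausea"],
    )
    reports, stats = read_reports(demo, drug, reac)
    assert len(reports) == 1
    assert stats.n_orphan_drug_rows == 1
    assert stats.n_orphan_reac_rows == 1


def test_report_without_reactions_excluded_and_counted(tmp_path):
    demo, drug, reac = _write_toy_quarter(
        tmp_path,
        ["P1$A$1$20200115$64$F$HO$US", "P2$B$1$20200116$50$M$OT$FR"],
        ["P1$PS$LOVENOX", "P2$PS$warfarin"],
        ["P1$Rash"],
    )
    reports, stats = read_reports(demo, drug, reac)
    assert len(reports) == 1
    assert stats.n_excluded_no_reaction == 1


def test_missing_mandatory_column_is_a_hard_error(tmp_path):
    demo, drug, reac = _write_toy_quarter(
        tmp_path, ["P1$A$1$20200115$64$F$HO$US"], ["P1$PS$LOVENOX"], ["P1$Rash"]
    )
    (tmp_path / "drug.txt").write_text("primaryid$drugname\nP1$LOVENOX\n")
    with pytest.raises(MissingColumnError, match="role_cod"):
        read_reports(demo, drug, reac)


def test_synthetic_corpus_round_trips_through_the_dialect(tmp_path, small_corpus):
    _, reports, _ = small_corpus
    subset = reports[:200]
    paths = write_reports(subset, tmp_path, FaersDialect())
    back, stats = read_reports(paths["demo"], paths["drug"], paths["reac"])
    assert stats.n_excluded == 0 and stats.n_malformed_fields == 0
    assert back == subset


# ---------------------------------------------------------------------------
# deduplicate
# ---------------------------------------------------------------------------

def test_deduplicate_keeps_highest_version_then_latest_date():
    versions = [_report(version=v) for v in (1, 3, 2)]
    assert deduplicate(versions) == [versions[1]]
    dated = [_report(version=2, day=d) for d in (5, 9, 2)]
    assert deduplicate(dated) == [dated[1]]


def test_deduplicate_keeps_distinct_cases_and_is_idempotent():
    reports = [_report("X", 1), _report("Y", 2), _report("X", 2)]
    once = deduplicate(reports)
    assert Counter(r.case_id for r in once) == Counter({"X": 1, "Y": 1})
    assert deduplicate(once) == once


@given(
    st.lists(
        st.tuples(st.sampled_from("ABCD"), st.integers(1, 5), st.integers(1, 28)),
        max_size=25,
    )
)
def test_deduplicate_never_increases_count_and_covers_each_case(spec):
    reports = [_report(cid, v, day) for cid, v, day in spec]
    deduped = deduplicate(reports)
    assert len(deduped) <= len(reports)
    assert {r.case_id for r in deduped} == {r.case_id for r in reports}
    assert deduplicate(deduped) == deduped
    for survivor in deduped:
        rivals = [r for r in reports if r.case_id == survivor.case_id]
        assert survivor.case_version == max(r.case_version for r in rivals)


# ---------------------------------------------------------------------------
# drug dictionary and PT matching
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "verbatim, expected",
    [
        ("LOVENOX", "enoxaparin"),
        ("ENOXAPARIN SODIUM.", "enoxaparin"),
        ("  Fragmin ", "dalteparin"),
        ("innohep", "tinzaparin"),
        ("Fraxiparine", "nadroparin"),
        ("warfarin", None),
        ("enoxaparin-sodium", "enoxaparin"),
    ],
)
def test_normalize_drug(verbatim, expected, lmwh_dictionary):
    assert normalize_drug(verbatim, lmwh_dictionary) == expected


def test_dictionary_rejects_overlapping_synonyms():
    with pytest.raises(ValueError, match="maps to both"):
        DrugDictionary(
            {"enoxaparin": frozenset({"lovenox"}), "dalteparin": frozenset({"Lovenox"})}
        )


@pytest.mark.parametrize(
    "reactions, expected",
    [
        (["Heparin-induced thrombocytopenia"], True),
        (["HEPARIN-INDUCED THROMBOCYTOPENIA TEST POSITIVE"], True),
        (["heparin-induced  thrombocytopenia   test"], True),
        (["Thrombocytopenia"], False),
        (["Rash", "Nausea"], False),
        ([], False),
    ],
)
def test_match_hit_pt_is_exact_after_folding(reactions, expected):
    assert match_hit_pt(reactions) is expected


# ---------------------------------------------------------------------------
# baseline table
# ---------------------------------------------------------------------------

def test_baseline_all_age_seventy_fills_one_band():
    reports = [_report(f"C{i}", age_years=70.0) for i in range(4)]
    table = baseline_table(reports)
    age = table[table.block == "Age"].set_index("level")
    assert age.loc[">60", "count"] == 4 and age.loc[">60", "pct"] == 100.0
    assert age.loc["<18", "count"] == 0


def test_baseline_percentages_match_independent_tally(small_corpus):
    _, reports, _ = small_corpus
    subset = reports[:500]
    table = baseline_table(subset)

    tally: Counter[tuple[str, str]] = Counter()
    for r in subset:
        if r.age_years is None:
            tally[("Age", "Unknown")] += 1
        elif r.age_years < 18:
            tally[("Age", "<18")] += 1
        elif r.age_years <= 60:
            tally[("Age", "18-60")] += 1
        else:
            tally[("Age", ">60")] += 1
        tally[("Gender", r.sex.capitalize() if r.sex != "unknown" else "Unknown")] += 1
        us = (r.reporter_country or "").casefold() in {"us", "usa", "united states"}
        tally[("Reporter country", "US" if us else "Other countries")] += 1
    for row in table.itertuples(index=False):
        if row.block in ("Age", "Gender", "Reporter country"):
            expected = tally.get((row.block, row.level), 0)
            assert row.count == expected
            assert row.pct == round(100 * expected / len(subset), 2)


def test_baseline_each_block_partitions_the_reports(small_corpus):
    _, reports, _ = small_corpus
    table = baseline_table(reports[:300])
    sums = table.groupby("block")["count"].sum()
    assert set(sums) == {300}


def test_baseline_empty_input_is_all_zero():
    table = baseline_table([])
    assert (table["count"] == 0).all() and (table["pct"] == 0.0).all()
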