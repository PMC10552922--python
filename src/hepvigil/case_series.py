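"""Case-series analytics for LMWH-induced heparin-induced thrombocytopenia.

Represents literature case reports of type II HIT after low-molecular-weight
heparin, scores the Warkentin 4Ts pretest probability, and aggregates the
series into the frequency tables a descriptive study reports: demographics
and drug (patient characteristics), onset timing / clinical manifestations /
platelet laboratory findings (clinical manifestations), and treatments with
outcomes.

The 4Ts score sums four criteria, each 0-2 points:

* Thrombocytopenia - magnitude of the platelet fall and the nadir count,
* Timing - days from heparin start to the fall (5-10 days is typical,
  or <=1 day on re-exposure within 30 days),
* Thrombosis - new thrombosis, skin necrosis or acute systemic reaction,
* oTher causes - whether another explanation for the fall exists.

Total 0-3 is low, 4-5 intermediate, 6-8 high pretest probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from ._util import pct

CASE_DRUGS = ("enoxaparin", "nadroparin", "dalteparin", "tinzaparin", "bemiparin")
AGE_BANDS = ("<18", "18-60", ">60")
ONSET_BANDS = ("<5", "5-10", ">10")
NADIR_BANDS = ("<10", "10-19", "20-49", "50-100", ">100")
DECREASE_BANDS = ("<30%", "30-50%", ">50%")
FOUR_T_BANDS = ("0-3", "4-5", "6-8")
RECOVERY_BANDS = ("<5", "5-10", ">10")
OUTCOMES = ("recovery", "worse", "death")

#: Every reviewed case had the culprit LMWH withdrawn.
WITHDRAWAL = "withdrawal"


@dataclass(frozen=True)
class CaseRecord:
    """One literature case of LMWH-induced HIT (banded feature set)."""

    case_label: str
    sex: str
    age_band: str
    drug: str
    #: Primary disease(s) prompting anticoagulation.  Set-valued: published
    #: series count 44 indications over 43 patients, so one case may carry two.
    indications: frozenset[str] = frozenset()
    history: frozenset[str] = frozenset()          # empty = no risk factors
    combined_drugs: frozenset[str] = frozenset()   # empty = no co-medication
    onset_band: str = "5-10"
    symptoms: frozenset[str] = frozenset()
    nadir_plt_band: str | None = None              # x10^9/L
    plt_decrease_band: str | None = None
    anti_pf4: str | None = None                    # 'positive' or unreported
    four_t_band: str | None = None
    d_dimer_elevated: bool | None = None
    liver_kidney_abnormal: bool | None = None
    treatments: frozenset[str] = frozenset({WITHDRAWAL})
    alt_anticoagulants: frozenset[str] = frozenset()
    recovery_band: str | None = None
    outcome: str = "recovery"

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be female/male, got {self.sex!r}")
        if self.age_band not in AGE_BANDS:
            raise ValueError(f"unknown age band {self.age_band!r}")
        if self.drug not in CASE_DRUGS:
            raise ValueError(f"drug must be one of {CASE_DRUGS}, got {self.drug!r}")
        if not self.indications:
            raise ValueError("at least one indication is required")
        if self.onset_band not in ONSET_BANDS:
            raise ValueError(f"unknown onset band {self.onset_band!r}")
        for value, bands in (
            (self.nadir_plt_band, NADIR_BANDS),
            (self.plt_decrease_band, DECREASE_BANDS),
            (self.four_t_band, FOUR_T_BANDS),
            (self.recovery_band, RECOVERY_BANDS),
        ):
            if value is not None and value not in bands:
                raise ValueError(f"unknown band {value!r}")
        if self.anti_pf4 not in (None, "positive"):
            raise ValueError("anti_pf4 is 'positive' or None (unreported)")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if WITHDRAWAL not in self.treatments:
            raise ValueError("every case record must include drug withdrawal")


# ---------------------------------------------------------------------------
# Warkentin 4Ts score
# ---------------------------------------------------------------------------

THROMBOSIS_LEVELS = {
    "none": 0,
    "possible": 1,
    "confirmed_new": 2,
    "skin_necrosis": 2,
    "acute_systemic_reaction": 2,
}
OTHER_CAUSE_LEVELS = {"definite": 0, "possible": 1, "none": 2}

_CRITERIA = ("thrombocytopenia", "timing", "thrombosis", "other_cause")


@dataclass(frozen=True)
class FourTInputs:
    """Observations feeding the four 4Ts criteria.

    Any field left None marks that criterion unobserved; the score is then
    reported as missing rather than imputed.
    """

    platelet_fall_pct: float | None = None   # percent fall from baseline, 0-100
    nadir_plt: float | None = None           # x10^9/L
    onset_day: float | None = None           # days since first LMWH dose
    reexposure_within_30d: bool = False      # heparin exposure in prior 30 d
    prior_exposure_30_100d: bool = False
    timing_unclear: bool = False
    thrombosis: str | None = None            # key of THROMBOSIS_LEVELS
    other_cause: str | None = None           # key of OTHER_CAUSE_LEVELS

    def __post_init__(self) -> None:
        if self.platelet_fall_pct is not None and not 0 <= self.platelet_fall_pct <= 100:
            raise ValueError("platelet_fall_pct must be within [0, 100]")
        if self.onset_day is not None and self.onset_day < 0:
            raise ValueError("onset_day must be non-negative")
        if self.thrombosis is not None and self.thrombosis not in THROMBOSIS_LEVELS:
            raise ValueError(f"unknown thrombosis level {self.thrombosis!r}")
        if self.other_cause is not None and self.other_cause not in OTHER_CAUSE_LEVELS:
            raise ValueError(f"unknown other-cause level {self.other_cause!r}")


@dataclass(frozen=True)
class FourTResult:
    score: int | None
    category: str | None                     # low | intermediate | high
    subscores: Mapping[str, int]
    missing: tuple[str, ...] = ()

    @property
    def complete(self) -> bool:
        return not self.missing


def _score_thrombocytopenia(fall: float, nadir: float) -> int:
    # The published rows overlap (a >50% fall can coexist with a nadir <10);
    # the 0-point features dominate, the 2-point row requires both features,
    # which keeps the sub-score monotone in either feature alone.
    if fall < 30 or nadir < 10:
        return 0
    if fall > 50 and nadir >= 20:
        return 2
    return 1


def _score_timing(x: FourTInputs) -> int:
    day = x.onset_day
    if 5 <= day <= 10 or (day <= 1 and x.reexposure_within_30d):
        return 2
    if day > 10 or x.timing_unclear or (day <= 1 and x.prior_exposure_30_100d):
        return 1
    return 0


def four_t_category(score: int) -> str:
    if score <= 3:
        return "low"
    return "intermediate" if score <= 5 else "high"


def four_t_score(x: FourTInputs) -> FourTResult:
    """Score the 4Ts criteria; total 0-8 and pretest-probability category.

    Each criterion contributes 0, 1 or 2 points.  If any criterion is
    unobserved the result carries ``score=None`` with the missing criteria
    listed - scores are never imputed.
    """
    missing = []
    if x.platelet_fall_pct is None or x.nadir_plt is None:
        missing.append("thrombocytopenia")
    if x.onset_day is None and not x.timing_unclear:
        missing.append("timing")
    if x.thrombosis is None:
        missing.append("thrombosis")
    if x.other_cause is None:
        missing.append("other_cause")
    if missing:
        return FourTResult(None, None, {}, tuple(missing))

    subscores = {
        "thrombocytopenia": _score_thrombocytopenia(x.platelet_fall_pct, x.nadir_plt),
        "timing": 1 if x.onset_day is None else _score_timing(x),
        "thrombosis": THROMBOSIS_LEVELS[x.thrombosis],
        "other_cause": OTHER_CAUSE_LEVELS[x.other_cause],
    }
    total = sum(subscores.values())
    return FourTResult(total, four_t_category(total), subscores)


# ---------------------------------------------------------------------------
# Frequency tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariableSpec:
    """How one case attribute is tabulated."""

    name: str
    getter: Callable[[CaseRecord], object]
    levels: tuple[str, ...] | None = None   # fixed ordering, else by count
    multi: bool = False                     # set-valued attribute
    empty_level: str | None = None          # label counted when the set is empty
    drop_empty: bool = False                # denominator = cases with non-empty set
    per_drug: bool = False                  # drug-stratified sub-rows


def _bool_level(value: bool | None) -> str | None:
    if value is None:
        return None
    return "yes" if value else "no"


VARIABLES: tuple[VariableSpec, ...] = (
    VariableSpec("sex", lambda c: c.sex, levels=("male", "female")),
    VariableSpec("age_band", lambda c: c.age_band, levels=AGE_BANDS),
    VariableSpec("drug", lambda c: c.drug, levels=CASE_DRUGS),
    VariableSpec("indications", lambda c: c.indications, multi=True),
    VariableSpec("history", lambda c: c.history, multi=True, empty_level="no risk factors"),
    VariableSpec(
        "combined_drugs",
        lambda c: c.combined_drugs,
        multi=True,
        empty_level="without other drugs",
    ),
    VariableSpec("onset_band", lambda c: c.onset_band, levels=ONSET_BANDS, per_drug=True),
    VariableSpec("symptoms", lambda c: c.symptoms, multi=True),
    VariableSpec(
        "nadir_plt_band", lambda c: c.nadir_plt_band, levels=NADIR_BANDS, per_drug=True
    ),
    VariableSpec(
        "plt_decrease_band",
        lambda c: c.plt_decrease_band,
        levels=DECREASE_BANDS,
        per_drug=True,
    ),
    VariableSpec("anti_pf4", lambda c: c.anti_pf4, levels=("positive",), per_drug=True),
    VariableSpec("four_t_band", lambda c: c.four_t_band, levels=FOUR_T_BANDS, per_drug=True),
    VariableSpec("d_dimer_elevated", lambda c: _bool_level(c.d_dimer_elevated)),
    VariableSpec("liver_kidney_abnormal", lambda c: _bool_level(c.liver_kidney_abnormal)),
    VariableSpec("treatments", lambda c: c.treatments, multi=True),
    VariableSpec(
        "alt_anticoagulants", lambda c: c.alt_anticoagulants, multi=True, drop_empty=True
    ),
    VariableSpec(
        "recovery_band", lambda c: c.recovery_band, levels=RECOVERY_BANDS, per_drug=True
    ),
    VariableSpec("outcome", lambda c: c.outcome, levels=OUTCOMES),
)

_VARIABLE_INDEX = {v.name: v for v in VARIABLES}

TABLE_COLUMNS = ["variable", "level", "drug", "count", "pct", "denominator"]


def _tabulate(
    cases: Sequence[CaseRecord],
    spec: VariableSpec,
    denominator_override: int | None = None,
) -> pd.DataFrame:
    if spec.multi:
        observed = [
            (case, spec.getter(case)) for case in cases
            if not (spec.drop_empty and not spec.getter(case))
        ]
    else:
        observed = [
            (case, spec.getter(case)) for case in cases if spec.getter(case) is not None
        ]
    denominator = denominator_override if denominator_override is not None else len(observed)

    counts: dict[str, int] = {}
    by_drug: dict[tuple[str, str], int] = {}
    for case, value in observed:
        if spec.multi:
            levels = sorted(value) if value else (
                [spec.empty_level] if spec.empty_level else []
            )
        else:
            levels = [value]
        for level in levels:
            counts[level] = counts.get(level, 0) + 1
            if spec.per_drug:
                key = (level, case.drug)
                by_drug[key] = by_drug.get(key, 0) + 1

    if spec.levels:
        ordered = [lv for lv in spec.levels if lv in counts or not spec.multi]
        ordered += sorted(set(counts) - set(ordered), key=lambda lv: -counts[lv])
        if spec.empty_level and spec.empty_level in counts and spec.empty_level not in ordered:
            ordered.append(spec.empty_level)
    else:
        ordered = sorted(counts, key=lambda lv: (-counts[lv], str(lv)))
        if spec.empty_level and spec.empty_level in ordered:
            ordered.remove(spec.empty_level)
            ordered.append(spec.empty_level)

    rows = []
    for level in ordered:
        count = counts.get(level, 0)
        rows.append(
            {
                "variable": spec.name,
                "level": level,
                "drug": "all",
                "count": count,
                "pct": pct(count, denominator),
                "denominator": denominator,
            }
        )
        if spec.per_drug:
            drug_counts = {
                drug: by_drug.get((level, drug), 0) for drug in CASE_DRUGS
            }
            for drug in sorted(drug_counts, key=lambda g: -drug_counts[g]):
                if drug_counts[drug]:
                    rows.append(
                        {
                            "variable": spec.name,
                            "level": level,
                            "drug": drug,
                            "count": drug_counts[drug],
                            "pct": pct(drug_counts[drug], denominator),
                            "denominator": denominator,
                        }
                    )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def frequency_tables(
    cases: Sequence[CaseRecord],
    denominators: Mapping[str, int] | None = None,
) -> dict[str, pd.DataFrame]:
    """Counts and percentages per variable, with drug-stratified sub-rows.

    Percentages use each variable's non-missing denominator (for set-valued
    variables: all cases, or cases with a non-empty set where the variable
    is only tabulated among treated patients).  ``denominators`` overrides
    specific variables, which publication layouts sometimes need.  Empty
    input yields empty tables with zero denominators.
    """
    denominators = denominators or {}
    return {
        spec.name: _tabulate(cases, spec, denominators.get(spec.name))
        for spec in VARIABLES
    }


#: The published characteristics table divides the co-medication block by 42,
#: not 43 (one case apparently excluded); mirrored here so emitted tables
#: reproduce the published percentages.
PUBLICATION_DENOMINATORS = {"combined_drugs": 42}

_TABLE_LAYOUT = {
    "patient_characteristics": ("sex", "age_band", "drug", "indications", "history",
                                 "combined_drugs"),
    "clinical_manifestations": ("onset_band", "symptoms", "nadir_plt_band",
                                 "plt_decrease_band", "anti_pf4", "four_t_band",
                                 "d_dimer_elevated", "liver_kidney_abnormal"),
    "treatments_outcomes": ("treatments", "alt_anticoagulants", "recovery_band",
                             "outcome"),
}


def publication_tables(cases: Sequence[CaseRecord]) -> dict[str, pd.DataFrame]:
    """The three publication-shaped tables (characteristics, clinical, treatment)."""
    tables = frequency_tables(cases, denominators=PUBLICATION_DENOMINATORS)
    out = {}
    for name, variables in _TABLE_LAYOUT.items():
        out[name] = pd.concat(
            [tables[v] for v in variables], ignore_index=True
        )
    return out


def summarize_series(cases: Sequence[CaseRecord]) -> dict[str, object]:
    """Headline summary of the series.

    Onset is only available in bands, so the modal band is reported with an
    explicit ``binned_only`` marker instead of a median.  Symptom prevalence
    uses x/n notation over the full series.
    """
    n = len(cases)
    onset_counts = {band: 0 for band in ONSET_BANDS}
    symptom_counts: dict[str, int] = {}
    outcome_counts = {oc: 0 for oc in OUTCOMES}
    anti_pf4_positive = 0
    four_t_observed = 0
    four_t_high = 0
    for case in cases:
        onset_counts[case.onset_band] += 1
        for s in case.symptoms:
            symptom_counts[s] = symptom_counts.get(s, 0) + 1
        outcome_counts[case.outcome] += 1
        if case.anti_pf4 == "positive":
            anti_pf4_positive += 1
        if case.four_t_band is not None:
            four_t_observed += 1
            if case.four_t_band == "6-8":
                four_t_high += 1
    modal_band = max(onset_counts, key=onset_counts.get) if n else None
    ranked_symptoms = sorted(symptom_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return {
        "n": n,
        "onset_bands": onset_counts,
        "onset_modal_band": modal_band,
        "onset_binned_only": True,
        "onset_median_days": None,
        "symptoms": {name: f"{count}/{n}" for name, count in ranked_symptoms},
        "most_common_symptom": ranked_symptoms[0][0] if ranked_symptoms else None,
        "anti_pf4_positive": anti_pf4_positive,
        "four_t_high": four_t_high,
        "four_t_observed": four_t_observed,
        "four_t_high_pct": pct(four_t_high, four_t_observed),
        "outcomes": {
            oc: {"count": cnt, "pct": pct(cnt, n)} for oc, cnt in outcome_counts.items()
        },
    }


__all__ = [
    "AGE_BANDS",
    "CASE_DRUGS",
    "CaseRecord",
    "DECREASE_BANDS",
    "FOUR_T_BANDS",
    "FourTInputs",
    "FourTResult",
    "NADIR_BANDS",
    "ONSET_BANDS",
    "OUTCOMES",
    "PUBLICATION_DENOMINATORS",
    "RECOVERY_BANDS",
    "THROMBOSIS_LEVELS",
    "VariableSpec",
    "WITHDRAWAL",
    "four_t_category",
    "four_t_score",
    "frequency_tables",
    "publication_tables",
    "summarize_series",
]
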