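"""Synthetic FAERS-like corpora with known ground truth, and the case fixture.

Two generators live here:

* :func:`generate_reports` draws a spontaneous-report corpus in which one
  designated drug carries a known reporting odds ratio for the HIT event,
  so the whole read -> deduplicate -> screen pipeline can be exercised and
  checked against truth without any database download.  Event assignment
  uses the exact logistic relation p1 = sigmoid(logit(p0) + ln OR), making
  the injected OR the true conditional odds ratio, not an approximation.
* :func:`build_case_fixture` deterministically constructs the 43-patient
  HIT case series whose drug-stratified marginals match the published
  descriptive tables; cross-variable structure not constrained by those
  marginals is filled by seeded permutation and is arbitrary by design.

All randomness flows through one :class:`numpy.random.Generator` (PCG64)
seeded from the config, so corpora and fixture are reproducible across
platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .case_series import WITHDRAWAL, CaseRecord
from .disproportionality import ContingencyTable
from .faers_io import (
    AEReport,
    DrugDictionary,
    DrugMention,
    HIT_PREFERRED_TERMS,
    default_lmwh_dictionary,
)

#: Comparator (non-LMWH) drugs that absorb the rest of the exposure mass.
COMPARATOR_DRUGS = (
    "acetaminophen",
    "metformin",
    "lisinopril",
    "atorvastatin",
    "omeprazole",
    "amoxicillin",
    "sertraline",
    "amlodipine",
)

#: Non-HIT reaction PT pool for background reports.
BACKGROUND_PTS = (
    "Nausea",
    "Headache",
    "Rash",
    "Dizziness",
    "Pyrexia",
    "Fatigue",
    "Vomiting",
    "Diarrhoea",
    "Pruritus",
    "Dyspnoea",
)

_COUNTRIES = ("FR", "GB", "DE", "JP", "CA", "IT", "ES", "CN", "AU", "BR")


class ConfigError(ValueError):
    """The simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic corpus.

    Defaults model a rare event (HIT-like background reporting probability
    of 0.5%) and a commonly reported anticoagulant (5% exposure share for
    the target drug), the regime in which the screening rules operate.
    """

    n_reports: int = 20_000
    drugs: Mapping[str, float] = field(
        default_factory=lambda: {
            "enoxaparin": 0.05,
            "nadroparin": 0.010,
            "dalteparin": 0.008,
            "tinzaparin": 0.004,
        }
    )
    target_drug: str = "enoxaparin"
    target_or: float = 10.0
    background_event_prob: float = 0.005
    duplicate_rate: float = 0.05
    concomitant_rate: float = 0.0   # chance of an extra role-C drug mention
    missingness: Mapping[str, float] = field(
        default_factory=lambda: {"age": 0.13, "sex": 0.09, "country": 0.03, "outcome": 0.05}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports <= 0:
            raise ConfigError("n_reports must be positive")
        if self.target_or <= 0:
            raise ConfigError("target_or must be positive")
        if not 0 <= self.background_event_prob < 1:
            raise ConfigError("background_event_prob must lie in [0, 1)")
        probs = list(self.drugs.values())
        if any(not 0 <= p <= 1 for p in probs) or sum(probs) > 1:
            raise ConfigError("drug exposure probabilities must be in [0,1] and sum <= 1")
        if self.target_drug not in self.drugs:
            raise ConfigError(f"target drug {self.target_drug!r} missing from drugs")
        if not 0 <= self.duplicate_rate < 1:
            raise ConfigError("duplicate_rate must lie in [0, 1)")
        for name, p in self.missingness.items():
            if not 0 <= p <= 1:
                raise ConfigError(f"missingness[{name!r}] must lie in [0, 1]")

    @property
    def exposed_event_prob(self) -> float:
        """p1 = sigmoid(logit(p0) + ln OR): the exact conditional probability."""
        p0 = self.background_event_prob
        return p0 * self.target_or / (1 - p0 + p0 * self.target_or)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually injected (for validating the pipeline)."""

    target_drug: str
    target_or: float
    exposed_event_prob: float
    background_event_prob: float
    tables: Mapping[str, ContingencyTable]   # realized, on the base corpus
    duplicate_case_ids: tuple[str, ...]

    def to_dict(self) -> dict[str, object]:
        return {
            "target_drug": self.target_drug,
            "target_or": self.target_or,
            "exposed_event_prob": self.exposed_event_prob,
            "background_event_prob": self.background_event_prob,
            "tables": {
                drug: {"a": t.a, "b": t.b, "c": t.c, "d": t.d}
                for drug, t in self.tables.items()
            },
            "duplicate_case_ids": list(self.duplicate_case_ids),
        }


def _verbatim(generic: str, dictionary: DrugDictionary, rng: np.random.Generator) -> str:
    synonyms = [generic, *sorted(dictionary.synonyms.get(generic, ()))]
    name = synonyms[rng.integers(len(synonyms))]
    style = rng.integers(3)
    return name.upper() if style == 0 else name.title() if style == 1 else name


def generate_reports(cfg: SimConfig) -> tuple[list[AEReport], GroundTruth]:
    """Draw a corpus of AEReports with a known drug-event association.

    One drug per report (a concomitant role-C mention may be added with
    ``concomitant_rate``; concomitants never influence the event).  The HIT
    PT fires with probability p0, or p1 for the target drug.  A fraction of
    cases is re-submitted with an incremented version to exercise
    deduplication; the ground-truth tables are counted on the base corpus,
    which deduplication must restore.
    """
    rng = np.random.default_rng(cfg.seed)
    dictionary = default_lmwh_dictionary()

    names = list(cfg.drugs) + list(COMPARATOR_DRUGS)
    lmwh_probs = np.array([cfg.drugs[n] for n in cfg.drugs])
    rest = (1.0 - lmwh_probs.sum()) / len(COMPARATOR_DRUGS)
    probs = np.concatenate([lmwh_probs, np.full(len(COMPARATOR_DRUGS), rest)])

    n = cfg.n_reports
    drug_idx = rng.choice(len(names), size=n, p=probs)
    target_idx = names.index(cfg.target_drug)
    p_event = np.where(drug_idx == target_idx, cfg.exposed_event_prob,
                       cfg.background_event_prob)
    is_event = rng.random(n) < p_event

    age_missing = rng.random(n) < cfg.missingness.get("age", 0.0)
    sex_missing = rng.random(n) < cfg.missingness.get("sex", 0.0)
    country_missing = rng.random(n) < cfg.missingness.get("country", 0.0)
    outcome_missing = rng.random(n) < cfg.missingness.get("outcome", 0.0)
    band_draw = rng.random(n)
    ages = np.where(
        band_draw < 0.01,
        rng.integers(1, 18, n),
        np.where(band_draw < 0.28, rng.integers(18, 61, n), rng.integers(61, 91, n)),
    ).astype(float)
    sexes = np.where(rng.random(n) < 0.5, "female", "male")
    outcome_draw = rng.random(n)
    start = date(2004, 1, 1)
    day_offsets = rng.integers(0, 6_850, n)
    concomitant = rng.random(n) < cfg.concomitant_rate

    reports: list[AEReport] = []
    for i in range(n):
        generic = names[drug_idx[i]]
        if generic in cfg.drugs:
            verbatim = _verbatim(generic, dictionary, rng)
        else:
            verbatim = generic
        mentions = [DrugMention(verbatim, "PS")]
        if concomitant[i]:
            mentions.append(
                DrugMention(COMPARATOR_DRUGS[rng.integers(len(COMPARATOR_DRUGS))], "C")
            )
        if is_event[i]:
            reactions = [HIT_PREFERRED_TERMS[rng.integers(3)]]
            if rng.random() < 0.3:
                reactions.append(BACKGROUND_PTS[rng.integers(len(BACKGROUND_PTS))])
        else:
            k = 1 + rng.integers(3)
            reactions = list(
                np.array(BACKGROUND_PTS)[rng.choice(len(BACKGROUND_PTS), k, replace=False)]
            )
        od = outcome_draw[i]
        outcome = (
            "missing" if outcome_missing[i]
            else "death" if od < 0.24
            else "hospitalization" if od < 0.69
            else "life_threatening" if od < 0.79
            else "disability" if od < 0.84
            else "other"
        )
        reports.append(
            AEReport(
                case_id=f"C{i:07d}",
                case_version=1,
                receipt_date=start + timedelta(days=int(day_offsets[i])),
                drugs=tuple(mentions),
                reactions=tuple(reactions),
                age_years=None if age_missing[i] else float(ages[i]),
                sex="unknown" if sex_missing[i] else str(sexes[i]),
                outcome_code=outcome,
                reporter_country=None if country_missing[i]
                else ("US" if rng.random() < 0.35
                      else _COUNTRIES[rng.integers(len(_COUNTRIES))]),
            )
        )

    tables = {}
    for generic in cfg.drugs:
        gi = names.index(generic)
        exposed = drug_idx == gi
        a = int(np.sum(exposed & is_event))
        b = int(np.sum(exposed & ~is_event))
        c = int(np.sum(~exposed & is_event))
        d = int(np.sum(~exposed & ~is_event))
        tables[generic] = ContingencyTable(a, b, c, d)

    n_dup = int(round(cfg.duplicate_rate * n))
    dup_idx = rng.choice(n, size=n_dup, replace=False) if n_dup else np.array([], dtype=int)
    duplicates = []
    for i in dup_idx:
        base = reports[i]
        duplicates.append(
            AEReport(
                case_id=base.case_id,
                case_version=base.case_version + 1,
                receipt_date=base.receipt_date + timedelta(days=int(rng.integers(1, 60))),
                drugs=base.drugs,
                reactions=base.reactions,
                age_years=base.age_years,
                sex=base.sex,
                outcome_code=base.outcome_code,
                reporter_country=base.reporter_country,
            )
        )
    stream = reports + duplicates
    order = rng.permutation(len(stream))
    stream = [stream[int(j)] for j in order]

    truth = GroundTruth(
        target_drug=cfg.target_drug,
        target_or=cfg.target_or,
        exposed_event_prob=cfg.exposed_event_prob,
        background_event_prob=cfg.background_event_prob,
        tables=tables,
        duplicate_case_ids=tuple(sorted(reports[int(i)].case_id for i in dup_idx)),
    )
    return stream, truth


def simulate_tables(
    cfg: SimConfig, n_corpora: int, seed: int | None = None
) -> np.ndarray:
    """Count-level equivalent of generate_reports, vectorised over corpora.

    Because each synthetic report reduces to (exposed to target?, event?)
    for the target-drug table, the realized 2x2 cells are jointly binomial;
    drawing them directly is distributionally identical to building report
    objects and tabulating, and fast enough for repeated-corpus experiments.
    Returns an (n_corpora, 4) array of [a, b, c, d].
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    p_target = cfg.drugs[cfg.target_drug]
    n_exposed = rng.binomial(cfg.n_reports, p_target, size=n_corpora)
    a = rng.binomial(n_exposed, cfg.exposed_event_prob)
    c = rng.binomial(cfg.n_reports - n_exposed, cfg.background_event_prob)
    b = n_exposed - a
    d = cfg.n_reports - n_exposed - c
    return np.stack([a, b, c, d], axis=1)


# ---------------------------------------------------------------------------
# The 43-case series fixture
# ---------------------------------------------------------------------------
# Drug-stratified marginal targets of the published descriptive tables.
# Joint structure across variables is NOT constrained by the publication and
# is filled by seeded permutation (arbitrary, and documented as such).

DRUG_TOTALS = {
    "enoxaparin": 21,
    "nadroparin": 14,
    "dalteparin": 4,
    "tinzaparin": 2,
    "bemiparin": 2,
}

ONSET_BY_DRUG = {
    "<5": {"enoxaparin": 3, "nadroparin": 1, "tinzaparin": 1},
    "5-10": {"enoxaparin": 13, "nadroparin": 10, "bemiparin": 1},
    ">10": {"enoxaparin": 5, "dalteparin": 4, "nadroparin": 3, "bemiparin": 1,
            "tinzaparin": 1},
}
NADIR_BY_DRUG = {
    "<10": {"nadroparin": 1},
    "10-19": {"enoxaparin": 1, "dalteparin": 1, "nadroparin": 1},
    "20-49": {"enoxaparin": 8, "nadroparin": 2, "dalteparin": 1, "bemiparin": 1,
              "tinzaparin": 1},
    "50-100": {"enoxaparin": 7, "nadroparin": 5, "dalteparin": 1, "bemiparin": 1},
    ">100": {"enoxaparin": 5, "nadroparin": 2, "dalteparin": 1, "tinzaparin": 1},
}
DECREASE_BY_DRUG = {
    "<30%": {"tinzaparin": 1},
    "30-50%": {"enoxaparin": 2, "nadroparin": 1},
    ">50%": {"enoxaparin": 19, "nadroparin": 8, "dalteparin": 3, "bemiparin": 2,
             "tinzaparin": 1},
}
ANTI_PF4_BY_DRUG = {
    "positive": {"enoxaparin": 17, "nadroparin": 12, "dalteparin": 4, "bemiparin": 2,
                 "tinzaparin": 1},
}
FOUR_T_BY_DRUG = {
    "4-5": {"dalteparin": 2, "enoxaparin": 1},
    "6-8": {"nadroparin": 9, "enoxaparin": 6, "bemiparin": 2, "tinzaparin": 1},
}
RECOVERY_BY_DRUG = {
    "<5": {"nadroparin": 4, "enoxaparin": 3, "dalteparin": 2},
    "5-10": {"enoxaparin": 11, "nadroparin": 4, "bemiparin": 1, "tinzaparin": 1},
    ">10": {"nadroparin": 5, "enoxaparin": 2, "bemiparin": 1},
}

SEX_COUNTS = {"male": 12, "female": 31}
AGE_COUNTS = {"<18": 1, "18-60": 15, ">60": 27}
INDICATION_COUNTS = {
    "embolism": 10,
    "joint operation": 9,
    "fracture": 5,
    "surgery": 5,
    "dialysis": 4,
    "tumor": 3,
    "heart failure": 3,
    "traffic accident": 2,
    "infection": 2,
    "pregnancy": 1,
}
HISTORY_COUNTS = {
    "diabetes": 10,
    "surgery": 9,
    "obesity": 6,
    "hypertension": 6,
    "tumor": 4,
    "chronic renal insufficiency": 3,
    "myocardial disease": 3,
    "cholecystectomy": 1,
    "immune-related diseases": 1,
    "thrombus history": 1,
}
HISTORY_NONE = 9
COMBINED_COUNTS = {
    "antihypertensive drugs": 4,
    "antidiabetic drugs": 2,
    "antibiotics": 2,
    "chemotherapeutic drugs": 1,
    "other anticoagulants": 1,
}
COMBINED_NONE = 36
SYMPTOM_COUNTS = {
    "thrombus": 39,
    "skin lesions": 15,
    "dyspnea": 13,
    "hemorrhage": 9,
    "limb necrosis": 5,
    "cerebral infarction": 5,
    "heart failure": 5,
    "acute renal failure": 2,
    "shock": 1,
    "fever": 1,
}
D_DIMER_COUNTS = {True: 5, False: 6}        # 32 untested
LIVER_KIDNEY_COUNTS = {True: 5, False: 3}   # 35 untested
TREATMENT_EXTRA_COUNTS = {
    "surgical thrombectomy": 6,
    "platelet transfusion": 2,
    "emergency treatment": 1,
    "thrombolytic agent": 1,
    "glucocorticoid": 1,
}
ALT_ANTICOAGULANT_COUNTS = {
    "fondaparinux": 17,
    "lepirudin": 11,
    "argatroban": 7,
    "warfarin": 5,
    "acenocoumarol": 5,
    "rivaroxaban": 4,
    "apixaban": 2,
    "dabigatran": 1,
    "clopidogrel": 1,
}
ALT_NONE = 4
OUTCOME_COUNTS = {"recovery": 41, "worse": 1, "death": 1}

N_CASES = sum(DRUG_TOTALS.values())


class FixtureConstraintError(RuntimeError):
    """The constructed fixture violates a published marginal."""


def _spread_single(counts: Mapping[str, int], slots: int,
                   rng: np.random.Generator) -> list[str | None]:
    """A shuffled value list of length ``slots`` (None pads missing)."""
    values: list[str | None] = []
    for level, count in counts.items():
        values.extend([level] * count)
    values.extend([None] * (slots - len(values)))
    return [values[int(i)] for i in rng.permutation(slots)]


def _deal_multi(counts: Mapping[str, int], holders: Sequence[int], slots: int,
                rng: np.random.Generator) -> list[set[str]]:
    """Deal item mentions round-robin over holder indices.

    Items are expanded by count (largest first) and dealt across a shuffled
    holder order; an item never repeats on one holder as long as its count
    does not exceed the number of holders.
    """
    mentions: list[str] = []
    for item, count in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        mentions.extend([item] * count)
    order = [holders[int(i)] for i in rng.permutation(len(holders))]
    out: list[set[str]] = [set() for _ in range(slots)]
    for j, item in enumerate(mentions):
        out[order[j % len(order)]].add(item)
    return out


def build_case_fixture(seed: int = 0) -> list[CaseRecord]:
    """Construct the 43-case series satisfying every published marginal.

    Deterministic for a given seed.  Drug-stratified attributes (onset,
    platelet bands, anti-PF4, 4Ts band, recovery) are permuted within each
    drug's block; everything else is permuted across the whole series.
    The result is validated against the marginal targets before returning.
    """
    rng = np.random.default_rng(seed)

    drugs: list[str] = []
    for drug, total in DRUG_TOTALS.items():
        drugs.extend([drug] * total)
    slots_by_drug = {
        drug: [i for i, g in enumerate(drugs) if g == drug] for drug in DRUG_TOTALS
    }

    def stratified(table: Mapping[str, Mapping[str, int]]) -> list[str | None]:
        out: list[str | None] = [None] * N_CASES
        for drug, slots in slots_by_drug.items():
            counts = {band: per_drug.get(drug, 0) for band, per_drug in table.items()}
            values = _spread_single(counts, len(slots), rng)
            for slot, value in zip(slots, values):
                out[slot] = value
        return out

    onset = stratified(ONSET_BY_DRUG)
    nadir = stratified(NADIR_BY_DRUG)
    decrease = stratified(DECREASE_BY_DRUG)
    anti_pf4 = stratified(ANTI_PF4_BY_DRUG)
    four_t = stratified(FOUR_T_BY_DRUG)
    recovery = stratified(RECOVERY_BY_DRUG)

    sex = _spread_single(SEX_COUNTS, N_CASES, rng)
    age = _spread_single(AGE_COUNTS, N_CASES, rng)
    # 44 indication mentions over 43 patients: exactly one case carries two.
    indications = _deal_multi(INDICATION_COUNTS, list(range(N_CASES)), N_CASES, rng)
    outcome = _spread_single(OUTCOME_COUNTS, N_CASES, rng)
    d_dimer = _spread_single(
        {"yes": D_DIMER_COUNTS[True], "no": D_DIMER_COUNTS[False]}, N_CASES, rng
    )
    liver_kidney = _spread_single(
        {"yes": LIVER_KIDNEY_COUNTS[True], "no": LIVER_KIDNEY_COUNTS[False]}, N_CASES, rng
    )

    all_slots = list(range(N_CASES))
    history_holders = [int(i) for i in rng.permutation(N_CASES)][: N_CASES - HISTORY_NONE]
    history = _deal_multi(HISTORY_COUNTS, history_holders, N_CASES, rng)
    combined_holders = [int(i) for i in rng.permutation(N_CASES)][: N_CASES - COMBINED_NONE]
    combined = _deal_multi(COMBINED_COUNTS, combined_holders, N_CASES, rng)
    symptoms = _deal_multi(SYMPTOM_COUNTS, all_slots, N_CASES, rng)
    treatments = _deal_multi(TREATMENT_EXTRA_COUNTS, all_slots, N_CASES, rng)
    alt_holders = [int(i) for i in rng.permutation(N_CASES)][: N_CASES - ALT_NONE]
    alt = _deal_multi(ALT_ANTICOAGULANT_COUNTS, alt_holders, N_CASES, rng)

    def tri(value: str | None) -> bool | None:
        return None if value is None else value == "yes"

    cases = [
        CaseRecord(
            case_label=f"case-{i + 1:02d}",
            sex=sex[i],
            age_band=age[i],
            drug=drugs[i],
            indications=frozenset(indications[i]),
            history=frozenset(history[i]),
            combined_drugs=frozenset(combined[i]),
            onset_band=onset[i],
            symptoms=frozenset(symptoms[i]),
            nadir_plt_band=nadir[i],
            plt_decrease_band=decrease[i],
            anti_pf4=anti_pf4[i],
            four_t_band=four_t[i],
            d_dimer_elevated=tri(d_dimer[i]),
            liver_kidney_abnormal=tri(liver_kidney[i]),
            treatments=frozenset({WITHDRAWAL, *treatments[i]}),
            alt_anticoagulants=frozenset(alt[i]),
            recovery_band=recovery[i],
            outcome=outcome[i],
        )
        for i in range(N_CASES)
    ]
    validate_fixture(cases)
    return cases


def validate_fixture(cases: Sequence[CaseRecord]) -> None:
    """Check every published marginal; raise naming the first violation."""

    def check(label: str, expected: int, actual: int) -> None:
        if expected != actual:
            raise FixtureConstraintError(
                f"marginal violated: {label} expected {expected}, got {actual}"
            )

    check("n cases", N_CASES, len(cases))
    for drug, total in DRUG_TOTALS.items():
        check(f"drug {drug}", total, sum(c.drug == drug for c in cases))
    for label, counts, getter in (
        ("sex", SEX_COUNTS, lambda c: c.sex),
        ("age", AGE_COUNTS, lambda c: c.age_band),
        ("outcome", OUTCOME_COUNTS, lambda c: c.outcome),
    ):
        for level, expected in counts.items():
            check(f"{label}={level}", expected, sum(getter(c) == level for c in cases))
    for label, table, getter in (
        ("onset", ONSET_BY_DRUG, lambda c: c.onset_band),
        ("nadir", NADIR_BY_DRUG, lambda c: c.nadir_plt_band),
        ("decrease", DECREASE_BY_DRUG, lambda c: c.plt_decrease_band),
        ("anti_pf4", ANTI_PF4_BY_DRUG, lambda c: c.anti_pf4),
        ("four_t", FOUR_T_BY_DRUG, lambda c: c.four_t_band),
        ("recovery", RECOVERY_BY_DRUG, lambda c: c.recovery_band),
    ):
        for band, per_drug in table.items():
            for drug, expected in per_drug.items():
                check(
                    f"{label}={band}/{drug}",
                    expected,
                    sum(getter(c) == band and c.drug == drug for c in cases),
                )
    for item, expected in INDICATION_COUNTS.items():
        check(f"indication={item}", expected, sum(item in c.indications for c in cases))
    for item, expected in HISTORY_COUNTS.items():
        check(f"history={item}", expected, sum(item in c.history for c in cases))
    check("history=none", HISTORY_NONE, sum(not c.history for c in cases))
    for item, expected in COMBINED_COUNTS.items():
        check(f"combined={item}", expected, sum(item in c.combined_drugs for c in cases))
    check("combined=none", COMBINED_NONE, sum(not c.combined_drugs for c in cases))
    for item, expected in SYMPTOM_COUNTS.items():
        check(f"symptom={item}", expected, sum(item in c.symptoms for c in cases))
    check(
        "treatment=withdrawal", N_CASES, sum(WITHDRAWAL in c.treatments for c in cases)
    )
    for item, expected in TREATMENT_EXTRA_COUNTS.items():
        check(f"treatment={item}", expected, sum(item in c.treatments for c in cases))
    for item, expected in ALT_ANTICOAGULANT_COUNTS.items():
        check(
            f"alt_anticoagulant={item}",
            expected,
            sum(item in c.alt_anticoagulants for c in cases),
        )
    check("alt_anticoagulant=none", ALT_NONE, sum(not c.alt_anticoagulants for c in cases))
    check(
        "d_dimer tested", sum(D_DIMER_COUNTS.values()),
        sum(c.d_dimer_elevated is not None for c in cases),
    )
    check(
        "d_dimer elevated", D_DIMER_COUNTS[True],
        sum(bool(c.d_dimer_elevated) for c in cases),
    )
    check(
        "liver_kidney tested", sum(LIVER_KIDNEY_COUNTS.values()),
        sum(c.liver_kidney_abnormal is not None for c in cases),
    )
    check(
        "liver_kidney abnormal", LIVER_KIDNEY_COUNTS[True],
        sum(bool(c.liver_kidney_abnormal) for c in cases),
    )


_SET_SEP = ";"
_FIXTURE_COLUMNS = [
    "case_label", "sex", "age_band", "drug", "indications", "history",
    "combined_drugs", "onset_band", "symptoms", "nadir_plt_band",
    "plt_decrease_band", "anti_pf4", "four_t_band", "d_dimer_elevated",
    "liver_kidney_abnormal", "treatments", "alt_anticoagulants",
    "recovery_band", "outcome",
]


def cases_to_frame(cases: Sequence[CaseRecord]) -> pd.DataFrame:
    """Flatten case records to a DataFrame (sets joined with ';')."""

    def join(values: frozenset[str]) -> str:
        return _SET_SEP.join(sorted(values))

    def tri(value: bool | None) -> str:
        return "" if value is None else ("yes" if value else "no")

    rows = [
        {
            "case_label": c.case_label,
            "sex": c.sex,
            "age_band": c.age_band,
            "drug": c.drug,
            "indications": join(c.indications),
            "history": join(c.history),
            "combined_drugs": join(c.combined_drugs),
            "onset_band": c.onset_band,
            "symptoms": join(c.symptoms),
            "nadir_plt_band": c.nadir_plt_band or "",
            "plt_decrease_band": c.plt_decrease_band or "",
            "anti_pf4": c.anti_pf4 or "",
            "four_t_band": c.four_t_band or "",
            "d_dimer_elevated": tri(c.d_dimer_elevated),
            "liver_kidney_abnormal": tri(c.liver_kidney_abnormal),
            "treatments": join(c.treatments),
            "alt_anticoagulants": join(c.alt_anticoagulants),
            "recovery_band": c.recovery_band or "",
            "outcome": c.outcome,
        }
        for c in cases
    ]
    return pd.DataFrame(rows, columns=_FIXTURE_COLUMNS)


def frame_to_cases(frame: pd.DataFrame) -> list[CaseRecord]:
    """Inverse of :func:`cases_to_frame`."""

    def split(raw: object) -> frozenset[str]:
        text = str(raw) if raw is not None else ""
        return frozenset(t for t in text.split(_SET_SEP) if t)

    def opt(raw: object) -> str | None:
        text = str(raw) if raw is not None else ""
        return text or None

    def tri(raw: object) -> bool | None:
        text = str(raw) if raw is not None else ""
        return None if not text else text == "yes"

    return [
        CaseRecord(
            case_label=str(row.case_label),
            sex=str(row.sex),
            age_band=str(row.age_band),
            drug=str(row.drug),
            indications=split(row.indications),
            history=split(row.history),
            combined_drugs=split(row.combined_drugs),
            onset_band=str(row.onset_band),
            symptoms=split(row.symptoms),
            nadir_plt_band=opt(row.nadir_plt_band),
            plt_decrease_band=opt(row.plt_decrease_band),
            anti_pf4=opt(row.anti_pf4),
            four_t_band=opt(row.four_t_band),
            d_dimer_elevated=tri(row.d_dimer_elevated),
            liver_kidney_abnormal=tri(row.liver_kidney_abnormal),
            treatments=split(row.treatments),
            alt_anticoagulants=split(row.alt_anticoagulants),
            recovery_band=opt(row.recovery_band),
            outcome=str(row.outcome),
        )
        for row in frame.fillna("").itertuples(index=False)
    ]


def write_case_fixture(path: str | Path, seed: int = 0) -> Path:
    """Write the fixture CSV (byte-stable for a given seed)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cases_to_frame(build_case_fixture(seed)).to_csv(path, index=False, lineterminator="\n")
    return path


def load_case_fixture(path: str | Path | None = None) -> list[CaseRecord]:
    """Load the packaged 43-case fixture (or a user CSV in the same layout)."""
    if path is None:
        from importlib.resources import files

        resource = files("hepvigil") / "data" / "hit_case_series_synthetic.csv"
        with resource.open("r") as handle:
            frame = pd.read_csv(handle, dtype=str, keep_default_na=False)
    else:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    return frame_to_cases(frame)


__all__ = [
    "ALT_ANTICOAGULANT_COUNTS",
    "BACKGROUND_PTS",
    "COMPARATOR_DRUGS",
    "ConfigError",
    "DRUG_TOTALS",
    "FixtureConstraintError",
    "GroundTruth",
    "N_CASES",
    "SimConfig",
    "build_case_fixture",
    "cases_to_frame",
    "frame_to_cases",
    "generate_reports",
    "load_case_fixture",
    "simulate_tables",
    "validate_fixture",
    "write_case_fixture",
]
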