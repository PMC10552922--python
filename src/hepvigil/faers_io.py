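"""Reading, deduplicating and normalising FAERS-style spontaneous reports.

The FDA Adverse Event Reporting System releases quarterly delimited ASCII
tables: demographics (DEMO), drugs (DRUG) and reactions (REAC), joined on a
primary report id.  This module ingests that shape (with a configurable
dialect), keeps one report per case (the latest version), maps verbatim drug
names onto low-molecular-weight heparin (LMWH) generics through a synonym
dictionary, flags reports whose reactions match the heparin-induced
thrombocytopenia (HIT) MedDRA Preferred Terms, and builds the stratified
baseline table (age / sex / outcome / reporter country).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import pct

logger = logging.getLogger(__name__)

#: MedDRA Preferred Terms counted as a HIT event (closed keyword list).
HIT_PREFERRED_TERMS: tuple[str, ...] = (
    "heparin-induced thrombocytopenia",
    "heparin-induced thrombocytopenia test",
    "heparin-induced thrombocytopenia test positive",
)

#: The seven LMWH generics under surveillance.
LMWH_GENERICS: tuple[str, ...] = (
    "enoxaparin",
    "nadroparin",
    "dalteparin",
    "tinzaparin",
    "bemiparin",
    "reviparin",
    "parnaparin",
)

SEXES = ("female", "male", "unknown")
OUTCOME_CODES = (
    "death",
    "hospitalization",
    "life_threatening",
    "disability",
    "other",
    "missing",
)
ROLE_CODES = ("PS", "SS", "C", "I")

#: Suspect roles: primary suspect and secondary suspect.  Concomitant (C) and
#: interacting (I) mentions are excluded from signal counting by default.
SUSPECT_ROLES = frozenset({"PS", "SS"})


class MissingColumnError(ValueError):
    """A mandatory column is absent from an input table."""


@dataclass(frozen=True)
class DrugMention:
    verbatim: str
    role_code: str  # one of PS/SS/C/I

    def __post_init__(self) -> None:
        if self.role_code not in ROLE_CODES:
            raise ValueError(f"unknown drug role code {self.role_code!r}")


@dataclass(frozen=True)
class AEReport:
    """One spontaneous adverse-event report (one version of one case)."""

    case_id: str
    case_version: int
    receipt_date: date
    drugs: tuple[DrugMention, ...]
    reactions: tuple[str, ...]
    age_years: float | None = None
    sex: str = "unknown"
    outcome_code: str = "missing"
    reporter_country: str | None = None

    def __post_init__(self) -> None:
        if self.case_version < 1:
            raise ValueError("case_version must be >= 1")
        if not self.drugs:
            raise ValueError("report must carry at least one drug mention")
        if not self.reactions:
            raise ValueError("report must carry at least one reaction PT")
        if self.age_years is not None and self.age_years < 0:
            raise ValueError("age_years must be non-negative")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.outcome_code not in OUTCOME_CODES:
            raise ValueError(f"unknown outcome code {self.outcome_code!r}")


def _normalize_name(name: str) -> str:
    """Case-fold, strip punctuation, collapse whitespace."""
    cleaned = re.sub(r"[^a-z0-9 ]+", " ", name.casefold())
    return " ".join(cleaned.split())


_SALT_SUFFIXES = ("sodium", "calcium")


@dataclass(frozen=True)
class DrugDictionary:
    """Generic name -> synonym set (brand, trade and salt spellings).

    Lookup is insensitive to case, whitespace and punctuation; a trailing
    salt token (sodium/calcium) is also tolerated.  Synonym sets must be
    disjoint across generics.
    """

    synonyms: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        lookup: dict[str, str] = {}
        for generic, names in self.synonyms.items():
            for name in {generic, *names}:
                key = _normalize_name(name)
                if lookup.get(key, generic) != generic:
                    raise ValueError(
                        f"synonym {name!r} maps to both {lookup[key]!r} and {generic!r}"
                    )
                lookup[key] = generic
        object.__setattr__(self, "_lookup", lookup)

    def match(self, verbatim: str) -> str | None:
        """Return the generic name for a verbatim drug string, or None."""
        key = _normalize_name(verbatim)
        lookup: Mapping[str, str] = self._lookup  # type: ignore[attr-defined]
        if key in lookup:
            return lookup[key]
        tokens = key.split()
        if len(tokens) > 1 and tokens[-1] in _SALT_SUFFIXES:
            return lookup.get(" ".join(tokens[:-1]))
        return None

    @property
    def generics(self) -> tuple[str, ...]:
        return tuple(self.synonyms)


def default_lmwh_dictionary() -> DrugDictionary:
    """The shipped synonym dictionary for the seven LMWH generics."""
    return DrugDictionary(
        {
            "enoxaparin": frozenset(
                {"enoxaparin sodium", "lovenox", "clexane", "klexane", "inhixa", "xaparin"}
            ),
            "nadroparin": frozenset(
                {"nadroparin calcium", "fraxiparine", "fraxiparin", "fraxodi"}
            ),
            "dalteparin": frozenset({"dalteparin sodium", "fragmin"}),
            "tinzaparin": frozenset({"tinzaparin sodium", "innohep", "logiparin"}),
            "bemiparin": frozenset({"bemiparin sodium", "zibor", "ivor", "badyket"}),
            "reviparin": frozenset({"reviparin sodium", "clivarin", "clivarine"}),
            "parnaparin": frozenset({"parnaparin sodium", "fluxum"}),
        }
    )


def normalize_drug(verbatim: str, dictionary: DrugDictionary) -> str | None:
    """Map a verbatim drug name to its generic, or None when unmatched."""
    return dictionary.match(verbatim)


def match_hit_pt(
    reactions: Iterable[str], keywords: Sequence[str] = HIT_PREFERRED_TERMS
) -> bool:
    """True iff any reaction equals one of the HIT Preferred Terms.

    Matching is exact after case-folding and whitespace collapse: the PT
    keyword list is closed, so substring matching would over-count (e.g.
    plain "thrombocytopenia" must not match).
    """
    normalized_keywords = {" ".join(k.casefold().split()) for k in keywords}
    return any(" ".join(r.casefold().split()) in normalized_keywords for r in reactions)


# ---------------------------------------------------------------------------
# Delimited-file dialect
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FaersDialect:
    """Column naming and delimiter for one quarter's DEMO/DRUG/REAC tables.

    The default mimics the FAERS ASCII release ("$"-delimited) with the
    outcome code folded into DEMO (the real release keeps it in a separate
    OUTC table; a single precedence-resolved code per report is modelled
    here, multiple codes may be given separated by ";").
    """

    delimiter: str = "$"
    demo_columns: Mapping[str, str] = field(
        default_factory=lambda: {
            "primaryid": "primaryid",
            "caseid": "caseid",
            "caseversion": "caseversion",
            "receipt_date": "fda_dt",
            "age": "age",
            "sex": "sex",
            "outcome": "outc_cod",
            "country": "occr_country",
        }
    )
    drug_columns: Mapping[str, str] = field(
        default_factory=lambda: {
            "primaryid": "primaryid",
            "role": "role_cod",
            "drugname": "drugname",
        }
    )
    reac_columns: Mapping[str, str] = field(
        default_factory=lambda: {"primaryid": "primaryid", "pt": "pt"}
    )


_OUTCOME_ALIASES = {
    "de": "death",
    "death": "death",
    "ho": "hospitalization",
    "hospitalization": "hospitalization",
    "lt": "life_threatening",
    "life_threatening": "life_threatening",
    "ds": "disability",
    "disability": "disability",
    "ot": "other",
    "other": "other",
    "ca": "other",
    "ri": "other",
}

#: Precedence when a report carries several outcome codes: death dominates,
#: then the serious hospitalization/life-threatening/disability group.
_OUTCOME_PRECEDENCE = {
    "death": 0,
    "hospitalization": 1,
    "life_threatening": 1,
    "disability": 1,
    "other": 2,
    "missing": 3,
}


def _parse_outcome(raw: str | None) -> str:
    if raw is None or not str(raw).strip():
        return "missing"
    codes = [
        _OUTCOME_ALIASES.get(tok.strip().casefold())
        for tok in str(raw).split(";")
        if tok.strip()
    ]
    codes = [c for c in codes if c is not None]
    if not codes:
        return "missing"
    return min(codes, key=lambda c: _OUTCOME_PRECEDENCE[c])


def _parse_sex(raw: str | None) -> str:
    if raw is None:
        return "unknown"
    key = str(raw).strip().casefold()
    return {"f": "female", "female": "female", "m": "male", "male": "male"}.get(
        key, "unknown"
    )


@dataclass
class IngestReport:
    """Counts of what ingestion kept, fixed up, or excluded."""

    n_demo_rows: int = 0
    n_reports: int = 0
    n_orphan_drug_rows: int = 0
    n_orphan_reac_rows: int = 0
    n_excluded_no_drug: int = 0
    n_excluded_no_reaction: int = 0
    n_malformed_fields: int = 0

    @property
    def n_excluded(self) -> int:
        return self.n_excluded_no_drug + self.n_excluded_no_reaction


def _read_table(path: str | Path, delimiter: str) -> pd.DataFrame:
    frame = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    frame.columns = [c.strip().casefold() for c in frame.columns]
    return frame


def _require_columns(frame: pd.DataFrame, needed: Iterable[str], path: str | Path) -> None:
    for col in needed:
        if col.casefold() not in frame.columns:
            raise MissingColumnError(f"{path}: missing mandatory column {col!r}")


def read_reports(
    demo_path: str | Path,
    drug_path: str | Path,
    reac_path: str | Path,
    dialect: FaersDialect | None = None,
) -> tuple[list[AEReport], IngestReport]:
    """Join one quarter's DEMO/DRUG/REAC tables into AEReport objects.

    Every case version present in DEMO yields one report (deduplication is a
    separate, explicit step).  Child rows whose primary id has no DEMO row
    are orphans: counted and logged, never silently dropped.  Reports with no
    drug or no reaction rows are excluded (and counted) because downstream
    counting is undefined for them.
    """
    dialect = dialect or FaersDialect()
    stats = IngestReport()

    demo = _read_table(demo_path, dialect.delimiter)
    drug = _read_table(drug_path, dialect.delimiter)
    reac = _read_table(reac_path, dialect.delimiter)

    dcols = {k: v.casefold() for k, v in dialect.demo_columns.items()}
    gcols = {k: v.casefold() for k, v in dialect.drug_columns.items()}
    rcols = {k: v.casefold() for k, v in dialect.reac_columns.items()}
    _require_columns(demo, dcols.values(), demo_path)
    _require_columns(drug, gcols.values(), drug_path)
    _require_columns(reac, rcols.values(), reac_path)

    stats.n_demo_rows = len(demo)
    demo_ids = set(demo[dcols["primaryid"]])

    drugs_by_id: dict[str, list[DrugMention]] = {}
    for _, row in drug.iterrows():
        pid = row[gcols["primaryid"]]
        if pid not in demo_ids:
            stats.n_orphan_drug_rows += 1
            continue
        role = str(row[gcols["role"]]).strip().upper() or "PS"
        if role not in ROLE_CODES:
            stats.n_malformed_fields += 1
            role = "PS"
        name = str(row[gcols["drugname"]]).strip()
        if name:
            drugs_by_id.setdefault(pid, []).append(DrugMention(name, role))

    reacs_by_id: dict[str, list[str]] = {}
    for _, row in reac.iterrows():
        pid = row[rcols["primaryid"]]
        if pid not in demo_ids:
            stats.n_orphan_reac_rows += 1
            continue
        pt = str(row[rcols["pt"]]).strip()
        if pt:
            reacs_by_id.setdefault(pid, []).append(pt)

    reports: list[AEReport] = []
    for _, row in demo.iterrows():
        pid = row[dcols["primaryid"]]
        mentions = drugs_by_id.get(pid, [])
        reactions = reacs_by_id.get(pid, [])
        if not mentions:
            stats.n_excluded_no_drug += 1
            continue
        if not reactions:
            stats.n_excluded_no_reaction += 1
            continue

        try:
            version = int(str(row[dcols["caseversion"]]).strip() or "1")
        except ValueError:
            stats.n_malformed_fields += 1
            version = 1
        try:
            receipt = datetime.strptime(
                str(row[dcols["receipt_date"]]).strip(), "%Y%m%d"
            ).date()
        except ValueError:
            stats.n_malformed_fields += 1
            receipt = date(1900, 1, 1)
        raw_age = str(row[dcols["age"]]).strip()
        age: float | None
        if not raw_age:
            age = None
        else:
            try:
                age = float(raw_age)
                if age < 0:
                    raise ValueError
            except ValueError:
                stats.n_malformed_fields += 1
                age = None
        country = str(row[dcols["country"]]).strip() or None

        reports.append(
            AEReport(
                case_id=str(row[dcols["caseid"]]).strip(),
                case_version=max(version, 1),
                receipt_date=receipt,
                drugs=tuple(mentions),
                reactions=tuple(reactions),
                age_years=age,
                sex=_parse_sex(row[dcols["sex"]]),
                outcome_code=_parse_outcome(row[dcols["outcome"]]),
                reporter_country=country,
            )
        )

    stats.n_reports = len(reports)
    if stats.n_orphan_drug_rows or stats.n_orphan_reac_rows:
        logger.warning(
            "excluded orphan child rows: %d drug, %d reaction",
            stats.n_orphan_drug_rows,
            stats.n_orphan_reac_rows,
        )
    if stats.n_excluded:
        logger.warning(
            "excluded reports: %d without drugs, %d without reactions",
            stats.n_excluded_no_drug,
            stats.n_excluded_no_reaction,
        )
    return reports, stats


def write_reports(
    reports: Iterable[AEReport],
    out_dir: str | Path,
    dialect: FaersDialect | None = None,
) -> dict[str, Path]:
    """Write reports back to the DEMO/DRUG/REAC delimited dialect.

    Inverse of :func:`read_reports` on all modelled fields (round-trip safe).
    """
    dialect = dialect or FaersDialect()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dcols, gcols, rcols = dialect.demo_columns, dialect.drug_columns, dialect.reac_columns

    demo_rows, drug_rows, reac_rows = [], [], []
    for i, rep in enumerate(reports):
        pid = f"{rep.case_id}-{rep.case_version}-{i}"
        demo_rows.append(
            {
                dcols["primaryid"]: pid,
                dcols["caseid"]: rep.case_id,
                dcols["caseversion"]: rep.case_version,
                dcols["receipt_date"]: rep.receipt_date.strftime("%Y%m%d"),
                dcols["age"]: "" if rep.age_years is None else repr(rep.age_years),
                dcols["sex"]: {"female": "F", "male": "M", "unknown": ""}[rep.sex],
                dcols["outcome"]: ""
                if rep.outcome_code == "missing"
                else {
                    "death": "DE",
                    "hospitalization": "HO",
                    "life_threatening": "LT",
                    "disability": "DS",
                    "other": "OT",
                }[rep.outcome_code],
                dcols["country"]: rep.reporter_country or "",
            }
        )
        for m in rep.drugs:
            drug_rows.append(
                {gcols["primaryid"]: pid, gcols["role"]: m.role_code, gcols["drugname"]: m.verbatim}
            )
        for pt in rep.reactions:
            reac_rows.append({rcols["primaryid"]: pid, rcols["pt"]: pt})

    paths = {
        "demo": out / "demo.txt",
        "drug": out / "drug.txt",
        "reac": out / "reac.txt",
    }
    pd.DataFrame(demo_rows, columns=list(dcols.values())).to_csv(
        paths["demo"], sep=dialect.delimiter, index=False
    )
    pd.DataFrame(drug_rows, columns=list(gcols.values())).to_csv(
        paths["drug"], sep=dialect.delimiter, index=False
    )
    pd.DataFrame(reac_rows, columns=list(rcols.values())).to_csv(
        paths["reac"], sep=dialect.delimiter, index=False
    )
    return paths


# ---------------------------------------------------------------------------
# Deduplication and counting
# ---------------------------------------------------------------------------

def deduplicate(reports: Sequence[AEReport]) -> list[AEReport]:
    """Keep exactly one report per case id.

    The survivor is the highest case version; ties break by latest receipt
    date, then by stable input order (the first of exact ties stays).
    Idempotent, never increases the count; output preserves first-seen case
    order.
    """
    chosen: dict[str, tuple[tuple[int, date], AEReport]] = {}
    for rep in reports:
        key = (rep.case_version, rep.receipt_date)
        if rep.case_id not in chosen or key > chosen[rep.case_id][0]:
            chosen[rep.case_id] = (key, rep)
    return [rep for _, rep in chosen.values()]


def report_mentions_drug(
    report: AEReport,
    generic: str,
    dictionary: DrugDictionary,
    roles: frozenset[str] = SUSPECT_ROLES,
) -> bool:
    """True iff the report lists the generic with one of the given roles."""
    return any(
        m.role_code in roles and dictionary.match(m.verbatim) == generic
        for m in report.drugs
    )


AGE_BANDS = ("<18", "18-60", ">60", "Unknown")
OUTCOME_GROUPS = (
    "Death",
    "Hospitalization-initial or prolonged/disability/life-threatening",
    "Others",
)
_US_NAMES = {"us", "usa", "united states", "united states of america"}


def age_band(age_years: float | None) -> str:
    if age_years is None:
        return "Unknown"
    if age_years < 18:
        return "<18"
    if age_years <= 60:  # boundaries 18 and 60 belong to the middle band
        return "18-60"
    return ">60"


def outcome_group(outcome_code: str) -> str:
    if outcome_code == "death":
        return OUTCOME_GROUPS[0]
    if outcome_code in ("hospitalization", "life_threatening", "disability"):
        return OUTCOME_GROUPS[1]
    return OUTCOME_GROUPS[2]


def baseline_table(reports: Sequence[AEReport]) -> pd.DataFrame:
    """Stratified counts/percentages of a set of reports (one drug's HIT AEs).

    Blocks: age band, sex, outcome group, reporter country (US vs other).
    Each report falls in exactly one band per block, so each block's counts
    sum to the total and its percentages to 100 up to rounding.  Empty input
    produces an all-zero table.
    """
    n = len(reports)
    rows: list[dict[str, object]] = []

    def block(name: str, levels: Sequence[str], level_of) -> None:
        counts = {lv: 0 for lv in levels}
        for rep in reports:
            counts[level_of(rep)] += 1
        for lv in levels:
            rows.append(
                {
                    "block": name,
                    "level": lv,
                    "count": counts[lv],
                    "pct": pct(counts[lv], n),
                }
            )

    block("Age", AGE_BANDS, lambda r: age_band(r.age_years))
    block(
        "Gender",
        ("Female", "Male", "Unknown"),
        lambda r: r.sex.capitalize() if r.sex != "unknown" else "Unknown",
    )
    block("Outcome of events", OUTCOME_GROUPS, lambda r: outcome_group(r.outcome_code))
    block(
        "Reporter country",
        ("US", "Other countries"),
        lambda r: "US"
        if (r.reporter_country or "").strip().casefold() in _US_NAMES
        else "Other countries",
    )
    frame = pd.DataFrame(rows, columns=["block", "level", "count", "pct"])
    frame.attrs["n"] = n
    return frame


__all__ = [
    "AEReport",
    "AGE_BANDS",
    "DrugDictionary",
    "DrugMention",
    "FaersDialect",
    "HIT_PREFERRED_TERMS",
    "IngestReport",
    "LMWH_GENERICS",
    "MissingColumnError",
    "OUTCOME_GROUPS",
    "SUSPECT_ROLES",
    "age_band",
    "baseline_table",
    "deduplicate",
    "default_lmwh_dictionary",
    "match_hit_pt",
    "normalize_drug",
    "outcome_group",
    "read_reports",
    "report_mentions_drug",
    "write_reports",
]
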