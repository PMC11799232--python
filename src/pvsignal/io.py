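"""Reading, validating, deduplicating and summarising spontaneous-report extracts.

The expected input is a delimited text extract in the style produced by
OpenVigil-type FAERS front ends: one row per report x drug x event, with a
case identifier, a report version, the drug name and its role code
(PS/SS/C/I), the MedDRA Preferred Term (PT) of the event, and per-case
demographics (sex, age + age unit, reporting country, receipt date).

Internally the package works on two equivalent representations:

* a list of :class:`ReportRecord` (validated row objects, convenient for
  small fixtures and round-tripping), and
* a "canonical frame" — a :class:`pandas.DataFrame` with normalised columns
  ``caseid, version, drug, role, pt, sex, age, country, date`` — which every
  analysis routine uses internally (see :func:`as_frame`).
"""

from __future__ import annotations

import csv
import io as _stdio
import logging
from dataclasses import dataclass, field, replace
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger("pvsignal")

ROLE_CODES = ("PS", "SS", "C", "I")
SEX_LEVELS = ("female", "male", "unknown")

#: age bins used in demographic summaries (upper bounds are exclusive,
#: so an integer printed boundary like "18-44" covers ages in [18, 45)).
AGE_BINS = ("<18", "18-44", "45-64", ">=65", "unknown")
_AGE_EDGES = (18.0, 45.0, 65.0)

MAX_AGE_YEARS = 150.0

REQUIRED_COLUMNS = ("caseid", "reportid", "drugname", "role_cod", "pt")
OPTIONAL_COLUMNS = ("sex", "age", "age_cod", "occr_country", "receipt_date")

#: conversion factors from FAERS age units to years
AGE_UNIT_YEARS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1775,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}


class ExtractFormatError(ValueError):
    """Raised when an extract file is structurally unusable (e.g. a
    required column is missing)."""


@dataclass(frozen=True)
class ReportRecord:
    """One validated report x drug x event row.

    ``case_id`` identifies the FAERS case; ``report_version`` orders
    successive versions of the same case (deduplication keeps the highest).
    ``drug_name`` and ``pt`` are stored normalised (trimmed, case-folded).
    """

    case_id: str
    report_version: int
    drug_name: str
    role: str
    pt: str
    sex: str = "unknown"
    age_years: float | None = None
    country: str | None = None
    received_date: date | None = None
    extra: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.role not in ROLE_CODES:
            raise ValueError(f"unknown drug role code {self.role!r}")
        if self.sex not in SEX_LEVELS:
            raise ValueError(f"unknown sex level {self.sex!r}")
        if not self.drug_name or not self.pt:
            raise ValueError("drug_name and pt must be non-empty after normalization")
        if self.report_version < 1:
            raise ValueError("report_version must be >= 1")
        if self.age_years is not None and not (0 <= self.age_years < MAX_AGE_YEARS):
            raise ValueError(f"age_years out of range: {self.age_years}")


def normalize_term(value: str) -> str:
    """Normalise a drug or PT name: trim and case-fold."""
    return " ".join(str(value).split()).casefold()


def _parse_sex(raw: object) -> str:
    s = str(raw).strip().casefold()
    if s in ("f", "female", "1"):
        return "female"
    if s in ("m", "male", "2"):
        return "male"
    return "unknown"


def _parse_age(raw: object, unit: object, lineno: int) -> float | None:
    s = str(raw).strip()
    if s in ("", "nan", "none", "NA", "na"):
        return None
    try:
        value = float(s)
    except ValueError:
        logger.warning("line %d: unparseable age %r, set to missing", lineno, raw)
        return None
    code = str(unit).strip().upper() or "YR"
    if code in ("", "NAN", "NONE", "NA"):
        code = "YR"
    factor = AGE_UNIT_YEARS.get(code)
    if factor is None:
        logger.warning("line %d: unknown age unit %r, age set to missing", lineno, unit)
        return None
    years = value * factor
    if not (0 <= years < MAX_AGE_YEARS):
        logger.warning("line %d: implausible age %s years, set to missing", lineno, years)
        return None
    return years


def _parse_date(raw: object, lineno: int) -> date | None:
    s = str(raw).strip()
    if s in ("", "nan", "none", "NA", "na"):
        return None
    for fmt in ("%Y-%m-%d", "%Y%m%d", "%d/%m/%Y", "%m/%d/%Y"):
        try:
            return datetime.strptime(s, fmt).date()
        except ValueError:
            continue
    logger.warning("line %d: unparseable date %r, set to missing", lineno, raw)
    return None


def _sniff_delimiter(path: Path, default: str = ",") -> str:
    if path.suffix.lower() in (".tsv", ".tab"):
        return "\t"
    with open(path, "r", encoding="utf-8", newline="") as fh:
        head = fh.readline()
    try:
        return csv.Sniffer().sniff(head, delimiters=",\t;").delimiter
    except csv.Error:
        return default


def read_reports(
    path: str | Path,
    delimiter: str | None = None,
    strict: bool = False,
) -> list[ReportRecord]:
    """Read a delimited report-level extract into validated records.

    Rows that cannot be parsed into a valid :class:`ReportRecord` (unknown
    role code, empty drug or PT) are rejected with a line-numbered
    diagnostic; with ``strict=True`` the first rejection raises instead.
    A missing required column is always fatal. Unparseable ages or dates do
    not reject the row — the field is set missing with a logged warning.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise ExtractFormatError(
                f"{path}: missing required column(s) {', '.join(missing)}"
            )
        passthrough = [
            c for c in header if c not in REQUIRED_COLUMNS + OPTIONAL_COLUMNS
        ]
        records: list[ReportRecord] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                version = int(float(str(row["reportid"]).strip() or "1"))
                rec = ReportRecord(
                    case_id=str(row["caseid"]).strip(),
                    report_version=version,
                    drug_name=normalize_term(row["drugname"]),
                    role=str(row["role_cod"]).strip().upper(),
                    pt=normalize_term(row["pt"]),
                    sex=_parse_sex(row.get("sex") or ""),
                    age_years=_parse_age(row.get("age") or "", row.get("age_cod") or "YR", lineno),
                    country=(str(row.get("occr_country") or "").strip().upper() or None),
                    received_date=_parse_date(row.get("receipt_date") or "", lineno),
                    extra=tuple((c, str(row.get(c) or "")) for c in passthrough),
                )
            except (ValueError, KeyError) as exc:
                msg = f"{path}:{lineno}: rejected row ({exc}); row={row!r}"
                if strict:
                    raise ExtractFormatError(msg) from exc
                logger.warning(msg)
                continue
            records.append(rec)
    return records


def write_reports(
    records: Iterable[ReportRecord], path: str | Path, delimiter: str = ","
) -> None:
    """Write records back out in the standard extract layout."""
    records = list(records)
    passthrough: list[str] = []
    for rec in records:
        for key, _ in rec.extra:
            if key not in passthrough:
                passthrough.append(key)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(list(REQUIRED_COLUMNS + OPTIONAL_COLUMNS) + passthrough)
        for rec in records:
            extra = dict(rec.extra)
            writer.writerow(
                [
                    rec.case_id,
                    rec.report_version,
                    rec.drug_name,
                    rec.role,
                    rec.pt,
                    rec.sex,
                    "" if rec.age_years is None else format(rec.age_years, "g"),
                    "YR",
                    rec.country or "",
                    rec.received_date.isoformat() if rec.received_date else "",
                ]
                + [extra.get(c, "") for c in passthrough]
            )


# ---------------------------------------------------------------------------
# canonical frame
# ---------------------------------------------------------------------------

FRAME_COLUMNS = ("caseid", "version", "drug", "role", "pt", "sex", "age", "country", "date")

Records = Union[Sequence[ReportRecord], pd.DataFrame]


def to_frame(records: Sequence[ReportRecord]) -> pd.DataFrame:
    """Convert record objects to the canonical frame."""
    return pd.DataFrame(
        {
            "caseid": [r.case_id for r in records],
            "version": [r.report_version for r in records],
            "drug": [r.drug_name for r in records],
            "role": [r.role for r in records],
            "pt": [r.pt for r in records],
            "sex": [r.sex for r in records],
            "age": [np.nan if r.age_years is None else r.age_years for r in records],
            "country": [r.country for r in records],
            "date": [r.received_date for r in records],
        }
    )


def as_frame(records: Records) -> pd.DataFrame:
    """Accept either record objects or a canonical frame; return the frame."""
    if isinstance(records, pd.DataFrame):
        missing = [c for c in ("caseid", "version", "drug", "role", "pt") if c not in records.columns]
        if missing:
            raise ExtractFormatError(f"frame missing canonical column(s) {missing}")
        return records
    return to_frame(list(records))


def from_frame(frame: pd.DataFrame) -> list[ReportRecord]:
    """Convert a canonical frame back to record objects."""
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            ReportRecord(
                case_id=str(row.caseid),
                report_version=int(row.version),
                drug_name=str(row.drug),
                role=str(row.role),
                pt=str(row.pt),
                sex=getattr(row, "sex", "unknown") or "unknown",
                age_years=None if pd.isna(getattr(row, "age", np.nan)) else float(row.age),
                country=getattr(row, "country", None) or None,
                received_date=getattr(row, "date", None) or None,
            )
        )
    return out


def deduplicate(records: Records) -> Records:
    """Keep, for each case, only the rows of its highest report version.

    FAERS cases are re-submitted as new versions; counting all versions
    would double-count patients. Order of the surviving rows is preserved.
    Returns the same representation it was given.
    """
    frame = as_frame(records)
    if frame.empty:
        return records
    top = frame.groupby("caseid")["version"].transform("max")
    kept = frame[frame["version"] == top]
    if isinstance(records, pd.DataFrame):
        return kept.reset_index(drop=True)
    keep_mask = (frame["version"] == top).to_numpy()
    return [r for r, k in zip(list(records), keep_mask) if k]


def n_cases(records: Records) -> int:
    """Number of distinct cases in the extract."""
    return int(as_frame(records)["caseid"].nunique())


# ---------------------------------------------------------------------------
# demographics
# ---------------------------------------------------------------------------


def age_bin(age_years: float | None) -> str:
    """Assign an age in years to the demographic bins <18 / 18-44 / 45-64 / >=65."""
    if age_years is None or (isinstance(age_years, float) and np.isnan(age_years)):
        return "unknown"
    for label, edge in zip(AGE_BINS, _AGE_EDGES):
        if age_years < edge:
            return label
    return ">=65"


def percent_breakdown(counts: Mapping[str, int], total: int | None = None) -> dict[str, float]:
    """Percentages (rounded to 2 decimals) of each count against the total.

    This is the arithmetic behind every percentage column of the
    demographics table: ``count / total * 100`` rounded to two decimals.
    """
    if total is None:
        total = sum(counts.values())
    if total <= 0:
        return {k: 0.0 for k in counts}
    return {k: round(100.0 * v / total, 2) for k, v in counts.items()}


@dataclass(frozen=True)
class DemographicsSummary:
    """Per-drug demographic breakdown of primary-suspect reports.

    Counts are distinct cases (one per case after deduplication), not rows.
    """

    drug: str
    total_reports: int
    sex_counts: dict[str, int]
    age_bin_counts: dict[str, int]
    top_countries: tuple[tuple[str, int], ...]

    @property
    def sex_percent(self) -> dict[str, float]:
        return percent_breakdown(self.sex_counts, self.total_reports)

    @property
    def age_percent(self) -> dict[str, float]:
        return percent_breakdown(self.age_bin_counts, self.total_reports)

    @property
    def country_percent(self) -> dict[str, float]:
        return percent_breakdown(dict(self.top_countries), self.total_reports)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table mirroring the usual demographics layout
        (characteristic, level, count, percent)."""
        rows = []
        for level in SEX_LEVELS:
            rows.append(("sex", level, self.sex_counts.get(level, 0)))
        for level in AGE_BINS:
            rows.append(("age", level, self.age_bin_counts.get(level, 0)))
        for country, count in self.top_countries:
            rows.append(("country", country, count))
        out = pd.DataFrame(rows, columns=["characteristic", "level", "count"])
        total = self.total_reports
        out["percent"] = [
            round(100.0 * c / total, 2) if total else 0.0 for c in out["count"]
        ]
        out.insert(0, "drug", self.drug)
        return out


def demographics_summary(
    records: Records, drug: str, top_countries: int = 5
) -> DemographicsSummary:
    """Summarise sex, age bins and top reporting countries for one drug.

    Counts distinct cases in which ``drug`` appears with role PS. Missing
    sex/age map to "unknown" bins; missing countries are excluded from the
    country ranking. ``records`` should already be deduplicated.
    """
    frame = as_frame(records)
    drug = normalize_term(drug)
    ps = frame[(frame["drug"] == drug) & (frame["role"] == "PS")]
    if ps.empty:
        return DemographicsSummary(
            drug=drug,
            total_reports=0,
            sex_counts={k: 0 for k in SEX_LEVELS},
            age_bin_counts={k: 0 for k in AGE_BINS},
            top_countries=(),
        )
    # one row per case; demographics are case-level so any row serves
    cases = ps.drop_duplicates(subset="caseid")
    total = len(cases)
    sex_counts = {k: 0 for k in SEX_LEVELS}
    for s, n in cases["sex"].fillna("unknown").value_counts().items():
        sex_counts[s if s in SEX_LEVELS else "unknown"] += int(n)
    age_counts = {k: 0 for k in AGE_BINS}
    for a in cases["age"]:
        age_counts[age_bin(None if pd.isna(a) else float(a))] += 1
    by_country = cases["country"].dropna()
    by_country = by_country[by_country != ""]
    vc = by_country.value_counts()
    # ties broken alphabetically for a deterministic ranking
    ranked = sorted(vc.items(), key=lambda kv: (-kv[1], kv[0]))[:top_countries]
    return DemographicsSummary(
        drug=drug,
        total_reports=total,
        sex_counts=sex_counts,
        age_bin_counts=age_counts,
        top_countries=tuple((str(c), int(n)) for c, n in ranked),
    )
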