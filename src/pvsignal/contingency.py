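"""2x2 contingency tables for (drug, event) pairs.

The disproportionality 2x2 table partitions the deduplicated reports of an
extract by (i) whether the target drug appears with role Primary Suspect
(PS) and (ii) whether the target event appears:

=============  ===========  ==========
.              target AEs   other AEs
target drug    a            b
other drugs    c            d
=============  ===========  ==========

Counting is case-level: a report in which the drug is PS twice, or in which
the PT occurs on several rows, still contributes one unit. The comparator
(c, d) is every report of the supplied extract in which the target drug
does not appear as PS — a drug present only as SS/C/I belongs to the
comparator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection, Sequence

import pandas as pd

from .io import Records, as_frame, normalize_term


@dataclass(frozen=True)
class ContingencyTable:
    """Counts a, b, c, d for one (drug, event) pair.

    ``event`` is a PT or, for organ-class level analyses, a SOC label; the
    cells may be real-valued when the table is an expected (analytic) table
    rather than an observed one.
    """

    drug: str
    event: str
    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    def cells(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)


def _case_sets(frame: pd.DataFrame, drug: str, pts: Collection[str]):
    ps_cases = set(frame.loc[(frame["drug"] == drug) & (frame["role"] == "PS"), "caseid"])
    event_cases = set(frame.loc[frame["pt"].isin(pts), "caseid"])
    return ps_cases, event_cases


def build_contingency(
    records: Records,
    drug: str,
    event: str,
    member_pts: Collection[str] | None = None,
) -> ContingencyTable:
    """Build the 2x2 table for one (drug, event) pair.

    ``event`` is normally a single PT. For SOC-level tables pass the SOC
    label as ``event`` and the set of member PTs as ``member_pts``; a report
    then counts as exposed to the event if it carries at least one member PT.

    ``records`` must already be deduplicated; an empty extract raises.
    """
    frame = as_frame(records)
    if frame.empty:
        raise ValueError("cannot build a contingency table from zero reports")
    drug = normalize_term(drug)
    if member_pts is None:
        pts: Collection[str] = {normalize_term(event)}
    else:
        pts = {normalize_term(p) for p in member_pts}
    total = frame["caseid"].nunique()
    ps_cases, event_cases = _case_sets(frame, drug, pts)
    a = len(ps_cases & event_cases)
    b = len(ps_cases) - a
    c = len(event_cases) - a
    d = total - a - b - c
    return ContingencyTable(drug=drug, event=normalize_term(event), a=a, b=b, c=c, d=d)


def enumerate_pairs(records: Records, drugs: Sequence[str]) -> list[ContingencyTable]:
    """One table per observed (drug, PT) pair with a >= 1.

    For each drug in ``drugs``, every PT occurring in at least one report
    where the drug is PS yields a table. Output order is deterministic:
    drugs in the given order, PTs lexicographic.
    """
    if not drugs:
        raise ValueError("drugs must be non-empty")
    frame = as_frame(records)
    if frame.empty:
        return []
    total = frame["caseid"].nunique()
    # distinct (case, pt) incidences, counted once per case
    case_pt = frame[["caseid", "pt"]].drop_duplicates()
    pt_case_totals = case_pt.groupby("pt")["caseid"].size()
    tables: list[ContingencyTable] = []
    for raw_drug in drugs:
        drug = normalize_term(raw_drug)
        ps_cases = set(
            frame.loc[(frame["drug"] == drug) & (frame["role"] == "PS"), "caseid"]
        )
        n_ps = len(ps_cases)
        if n_ps == 0:
            continue
        exposed = case_pt[case_pt["caseid"].isin(ps_cases)]
        a_by_pt = exposed.groupby("pt")["caseid"].size().sort_index()
        for pt, a in a_by_pt.items():
            a = int(a)
            c = int(pt_case_totals[pt]) - a
            b = n_ps - a
            d = total - a - b - c
            tables.append(ContingencyTable(drug=drug, event=str(pt), a=a, b=b, c=c, d=d))
    return tables
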