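"""Shared fixtures: record builders, random extract fixtures, and an
independent brute-force contingency counter used as an oracle."""

from __future__ import annotations

import numpy as np
import pytest

from pvsignal.io import ReportRecord


def make_record(
    case_id: str,
    drug: str = "drugx",
    role: str = "PS",
    pt: str = "pty",
    version: int = 1,
    **kwargs,
) -> ReportRecord:
    return ReportRecord(
        case_id=case_id,
        report_version=version,
        drug_name=drug,
        role=role,
        pt=pt,
        **kwargs,
    )


def brute_force_table(records, drug: str, event: str) -> tuple[int, int, int, int]:
    """Independent double-loop counter over cases: the oracle for
    build_contingency. Deliberately naive — no pandas, no set algebra."""
    cases: dict[str, list[ReportRecord]] = {}
    for rec in records:
        cases.setdefault(rec.case_id, []).append(rec)
    a = b = c = d = 0
    for rows in cases.values():
        has_drug = False
        has_event = False
        for r in rows:
            if r.drug_name == drug and r.role == "PS":
                has_drug = True
            if r.pt == event:
                has_event = True
        if has_drug and has_event:
            a += 1
        elif has_drug:
            b += 1
        elif has_event:
            c += 1
        else:
            d += 1
    return a, b, c, d


def random_extract(rng: np.random.Generator, max_reports: int = 200) -> list[ReportRecord]:
    """A random small extract: multi-row cases, several drugs/PTs/roles."""
    n_cases = int(rng.integers(5, max_reports + 1))
    drugs = [f"drug{i}" for i in range(int(rng.integers(2, 6)))]
    pts = [f"pt{i}" for i in range(int(rng.integers(2, 8)))]
    roles = ["PS", "SS", "C", "I"]
    records = []
    for i in range(n_cases):
        for _ in range(int(rng.integers(1, 5))):
            records.append(
                make_record(
                    case_id=f"case{i}",
                    drug=str(rng.choice(drugs)),
                    role=str(rng.choice(roles, p=[0.5, 0.2, 0.2, 0.1])),
                    pt=str(rng.choice(pts)),
                )
            )
    return records


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230901)
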