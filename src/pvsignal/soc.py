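"""MedDRA PT -> System Organ Class mapping and SOC-level analyses.

MedDRA is multi-axial — a PT can belong to several SOCs but has exactly one
*primary* SOC. The pipeline counts each signal once, under its PT's primary
SOC, so per-drug SOC percentages sum to 100. The mapping itself is supplied
as a small delimited file (``pt, soc[, is_primary]``), standing in for the
licensed MedDRA distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .contingency import build_contingency
from .io import Records, as_frame, normalize_term
from .stats import DEFAULT_CRITERIA, SignalCriteria, SignalStats, signal_stats

logger = logging.getLogger("pvsignal")

#: the 27 MedDRA System Organ Classes
MEDDRA_SOCS = (
    "Blood and lymphatic system disorders",
    "Cardiac disorders",
    "Congenital, familial and genetic disorders",
    "Ear and labyrinth disorders",
    "Endocrine disorders",
    "Eye disorders",
    "Gastrointestinal disorders",
    "General disorders and administration site conditions",
    "Hepatobiliary disorders",
    "Immune system disorders",
    "Infections and infestations",
    "Injury, poisoning and procedural complications",
    "Investigations",
    "Metabolism and nutrition disorders",
    "Musculoskeletal and connective tissue disorders",
    "Neoplasms benign, malignant and unspecified (incl cysts and polyps)",
    "Nervous system disorders",
    "Pregnancy, puerperium and perinatal conditions",
    "Product issues",
    "Psychiatric disorders",
    "Renal and urinary disorders",
    "Reproductive system and breast disorders",
    "Respiratory, thoracic and mediastinal disorders",
    "Skin and subcutaneous tissue disorders",
    "Social circumstances",
    "Surgical and medical procedures",
    "Vascular disorders",
)

_CANONICAL_SOC = {normalize_term(s): s for s in MEDDRA_SOCS}

UNMAPPED = "Unmapped"


class SocMapError(ValueError):
    """Raised for unusable PT->SOC mapping files (conflicting duplicates)."""


@dataclass(frozen=True)
class SocMap:
    """Mapping from normalized PT to its (primary) SOC."""

    entries: Mapping[str, str]

    def soc_of(self, pt: str) -> str | None:
        return self.entries.get(normalize_term(pt))

    def members(self, soc: str) -> set[str]:
        """All PTs whose primary SOC is ``soc`` (case-insensitive)."""
        key = normalize_term(soc)
        return {pt for pt, s in self.entries.items() if normalize_term(s) == key}

    def __len__(self) -> int:
        return len(self.entries)


def load_soc_map(path: str | Path, strict_socs: bool = False) -> SocMap:
    """Load a PT->SOC mapping file (columns: pt, soc[, is_primary]).

    Rows with ``is_primary`` false are ignored (only the primary axis is
    used for counting). Duplicate identical rows are collapsed silently;
    duplicates that map one PT to two different SOCs are fatal, with both
    line numbers cited. SOC labels outside the 27 MedDRA classes log a
    warning (or raise, with ``strict_socs=True``).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    frame = pd.read_csv(path, sep=sep, dtype=str)
    cols = {c.strip().lower(): c for c in frame.columns}
    if "pt" not in cols or "soc" not in cols:
        raise SocMapError(f"{path}: mapping file needs 'pt' and 'soc' columns")
    entries: dict[str, str] = {}
    first_line: dict[str, int] = {}
    for idx, row in frame.iterrows():
        lineno = int(idx) + 2  # header is line 1
        if "is_primary" in cols:
            flag = str(row[cols["is_primary"]]).strip().casefold()
            if flag in ("0", "false", "no", "n"):
                continue
        pt = normalize_term(row[cols["pt"]])
        soc_raw = " ".join(str(row[cols["soc"]]).split())
        soc = _CANONICAL_SOC.get(normalize_term(soc_raw), soc_raw)
        if soc not in MEDDRA_SOCS:
            msg = f"{path}:{lineno}: SOC label {soc_raw!r} is not one of the 27 MedDRA SOCs"
            if strict_socs:
                raise SocMapError(msg)
            logger.warning(msg)
        if pt in entries:
            if entries[pt] != soc:
                raise SocMapError(
                    f"{path}: PT {pt!r} mapped to conflicting SOCs "
                    f"{entries[pt]!r} (line {first_line[pt]}) and {soc!r} (line {lineno})"
                )
            continue
        entries[pt] = soc
        first_line[pt] = lineno
    return SocMap(entries=entries)


@dataclass(frozen=True)
class SocDistribution:
    """Per-SOC signal counts and percentage shares for one drug.

    Percentages are shares of the drug's signal count (not of reports);
    unmapped PTs are pooled under the "Unmapped" label.
    """

    drug: str
    soc_counts: dict[str, int]
    soc_percent: dict[str, float]

    @property
    def total_signals(self) -> int:
        return sum(self.soc_counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.soc_counts.items(), key=lambda kv: (-kv[1], kv[0]))
        out = pd.DataFrame(rows, columns=["soc", "n_signals"])
        out["percent"] = [self.soc_percent[s] for s in out["soc"]]
        out.insert(0, "drug", self.drug)
        return out


def soc_aggregate(signals: Sequence[SignalStats], soc_map: SocMap) -> SocDistribution:
    """Classify one drug's signals by the primary SOC of their PT.

    Each signal counts exactly once; PTs absent from the map fall into the
    "Unmapped" bucket with a logged warning. Percentages are
    ``count / total signals * 100`` (unrounded; round at display time).
    """
    signals = [s for s in signals if s.is_signal]
    drugs = {s.drug for s in signals}
    if len(drugs) > 1:
        raise ValueError(f"soc_aggregate expects signals of a single drug, got {sorted(drugs)}")
    drug = signals[0].drug if signals else ""
    counts: dict[str, int] = {}
    for s in signals:
        soc = soc_map.soc_of(s.event)
        if soc is None:
            logger.warning("PT %r has no SOC mapping; counted as Unmapped", s.event)
            soc = UNMAPPED
        counts[soc] = counts.get(soc, 0) + 1
    total = sum(counts.values())
    percent = {soc: 100.0 * n / total for soc, n in counts.items()} if total else {}
    return SocDistribution(drug=drug, soc_counts=counts, soc_percent=percent)


def soc_level_ror(
    records: Records,
    drug: str,
    soc: str,
    soc_map: SocMap,
    criteria: SignalCriteria = DEFAULT_CRITERIA,
    chi2_variant: str = "pearson",
    haldane: bool = False,
) -> SignalStats:
    """ROR (with CI) of a drug against a whole organ class.

    The event is "the report carries at least one PT whose primary SOC is
    ``soc``"; the 2x2 table is built case-level like PT-level tables, so the
    SOC-level a is the size of the union of member-PT case sets.
    """
    members = soc_map.members(soc)
    if not members:
        raise KeyError(f"SOC {soc!r} has no member PTs in the supplied mapping")
    table = build_contingency(records, drug, event=soc, member_pts=members)
    return signal_stats(table, criteria=criteria, chi2_variant=chi2_variant, haldane=haldane)
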