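"""Model / Results interface for a full disproportionality analysis.

:class:`DisproportionalityModel` is built from a report-level extract plus
the analysis configuration (target drugs, signal thresholds, chi-square
variant, deduplication switch); :meth:`DisproportionalityModel.fit` runs the
whole pipeline — deduplicate, enumerate (drug, PT) pairs, compute
ROR/PRR/chi-square with CIs, apply the joint signal criteria — and returns a
:class:`DisproportionalityResults` carrying the per-pair statistics,
demographics, SOC aggregations and a text ``summary()``.

Example
-------
>>> from pvsignal import DisproportionalityModel, simulate
>>> scenario = simulate.default_scenario(seed=7)
>>> reports = simulate.generate_reports(scenario)
>>> res = DisproportionalityModel(reports, drugs=["voriconazole"]).fit()
>>> res.signals.head()
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as report_io
from .contingency import enumerate_pairs
from .soc import SocDistribution, SocMap, soc_aggregate, soc_level_ror
from .stats import (
    DEFAULT_CRITERIA,
    SignalCriteria,
    SignalStats,
    rank_signals,
    signal_stats,
    stats_frame,
)

logger = logging.getLogger("pvsignal")


class DisproportionalityModel:
    """Disproportionality signal-mining model for one extract.

    Parameters
    ----------
    reports : list of ReportRecord or canonical DataFrame
        The report-level extract (one row per report x drug x event).
    drugs : sequence of str, optional
        Target drugs; defaults to every drug observed with role PS.
    soc_map : SocMap, optional
        PT -> primary SOC mapping, required for SOC-level results.
    criteria : SignalCriteria
        Joint signal thresholds (default: a >= 3, ROR CI low > 1, PRR > 2).
    dedup : bool
        Collapse case versions before analysis (keep highest version).
    chi2_variant : {"pearson", "yates"}
    haldane : bool
        Add 0.5 to every cell before estimating (zero-cell correction);
        off by default so undefined tables stay visibly undefined.
    """

    def __init__(
        self,
        reports: report_io.Records,
        drugs: Sequence[str] | None = None,
        soc_map: SocMap | None = None,
        criteria: SignalCriteria = DEFAULT_CRITERIA,
        dedup: bool = True,
        chi2_variant: str = "pearson",
        haldane: bool = False,
    ) -> None:
        self.frame = report_io.as_frame(reports)
        self.soc_map = soc_map
        self.criteria = criteria
        self.dedup = dedup
        self.chi2_variant = chi2_variant
        self.haldane = haldane
        if drugs is None:
            observed = self.frame.loc[self.frame["role"] == "PS", "drug"].unique()
            drugs = sorted(observed)
        self.drugs = [report_io.normalize_term(d) for d in drugs]

    @classmethod
    def from_csv(cls, path: str | Path, delimiter: str | None = None, **kwargs) -> "DisproportionalityModel":
        """Build the model straight from an extract file."""
        records = report_io.read_reports(path, delimiter=delimiter)
        return cls(records, **kwargs)

    def fit(self) -> "DisproportionalityResults":
        """Run the pipeline and return the results object."""
        raw = self.frame
        funnel = {"rows_in": len(raw), "cases_in": int(raw["caseid"].nunique())}
        frame = report_io.deduplicate(raw) if self.dedup else raw
        funnel["rows_dedup"] = len(frame)
        funnel["cases_dedup"] = int(frame["caseid"].nunique())
        tables = enumerate_pairs(frame, self.drugs)
        funnel["pairs"] = len(tables)
        all_stats = [
            signal_stats(
                t,
                criteria=self.criteria,
                chi2_variant=self.chi2_variant,
                haldane=self.haldane,
            )
            for t in tables
        ]
        funnel["signals"] = sum(s.is_signal for s in all_stats)
        for step, count in funnel.items():
            logger.info("fit funnel %s=%d", step, count)
        return DisproportionalityResults(model=self, frame=frame, pair_stats=all_stats, funnel=funnel)


@dataclass
class DisproportionalityResults:
    """Fitted disproportionality analysis.

    ``stats`` tabulates every observed (drug, PT) pair; ``signals`` the
    subset meeting the joint criteria. Demographics and SOC views are
    computed lazily from the deduplicated frame.
    """

    model: DisproportionalityModel
    frame: pd.DataFrame
    pair_stats: list[SignalStats]
    funnel: dict[str, int]

    @property
    def stats(self) -> pd.DataFrame:
        return stats_frame(self.pair_stats)

    @property
    def signals(self) -> pd.DataFrame:
        return stats_frame([s for s in self.pair_stats if s.is_signal])

    def signal_count(self, drug: str | None = None) -> int:
        if drug is None:
            return sum(s.is_signal for s in self.pair_stats)
        drug = report_io.normalize_term(drug)
        return sum(s.is_signal for s in self.pair_stats if s.drug == drug)

    def top(self, drug: str | None = None, n: int = 20) -> pd.DataFrame:
        """Top-``n`` signals by report count (ties: ROR desc, then PT)."""
        stats = self.pair_stats
        if drug is not None:
            drug = report_io.normalize_term(drug)
            stats = [s for s in stats if s.drug == drug]
        return stats_frame(rank_signals(stats, n))

    def demographics(self, drug: str, top_countries: int = 5) -> report_io.DemographicsSummary:
        return report_io.demographics_summary(self.frame, drug, top_countries=top_countries)

    def soc_distribution(self, drug: str) -> SocDistribution:
        if self.model.soc_map is None:
            raise ValueError("model was built without a SOC map")
        drug = report_io.normalize_term(drug)
        per_drug = [s for s in self.pair_stats if s.drug == drug and s.is_signal]
        return soc_aggregate(per_drug, self.model.soc_map)

    def soc_ror(self, drug: str, socs: Sequence[str]) -> pd.DataFrame:
        """SOC-level ROR/CI rows for the given organ classes."""
        if self.model.soc_map is None:
            raise ValueError("model was built without a SOC map")
        rows = [
            soc_level_ror(
                self.frame, drug, soc, self.model.soc_map,
                criteria=self.model.criteria,
                chi2_variant=self.model.chi2_variant,
                haldane=self.model.haldane,
            )
            for soc in socs
        ]
        out = stats_frame(rows).rename(columns={"pt": "soc"})
        return out

    def summary(self, top_n: int = 10) -> str:
        """Human-readable overview of the fit."""
        lines = ["Disproportionality analysis", "=" * 27]
        lines.append(
            f"reports: {self.funnel['cases_in']} cases in, "
            f"{self.funnel['cases_dedup']} after dedup; "
            f"{self.funnel['pairs']} (drug, PT) pairs; "
            f"{self.funnel['signals']} signals"
        )
        lines.append(
            f"criteria: a >= {self.model.criteria.a_min}, "
            f"ROR CI low > {self.model.criteria.ror_ci_low_min}, "
            f"PRR > {self.model.criteria.prr_min}"
        )
        for drug in self.model.drugs:
            k = self.signal_count(drug)
            lines.append("")
            lines.append(f"{drug}: {k} signal(s)")
            top = self.top(drug, n=top_n)
            if top.empty:
                continue
            header = f"  {'PT':<36} {'a':>5} {'PRR':>9} {'ROR':>9} {'95% CI':>19}"
            lines.append(header)
            lines.append("  " + "-" * (len(header) - 2))
            for row in top.itertuples(index=False):
                ci = f"({row.ror_ci_low:.3f}-{row.ror_ci_high:.3f})"
                lines.append(
                    f"  {row.pt:<36} {row.a:>5d} {row.prr:>9.3f} {row.ror:>9.3f} {ci:>19}"
                )
        return "\n".join(lines)

    # -- plotting -----------------------------------------------------------

    def plot_soc_distribution(self, drug: str, ax=None):
        """Horizontal bar chart of the drug's signal share per SOC."""
        import matplotlib.pyplot as plt

        dist = self.soc_distribution(drug).to_frame()
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 0.35 * max(len(dist), 4) + 1))
        ax.barh(dist["soc"][::-1], dist["percent"][::-1])
        ax.set_xlabel("share of signals (%)")
        ax.set_title(f"SOC distribution of {drug} signals")
        return ax

    def plot_soc_forest(self, socs: Sequence[str], drugs: Sequence[str] | None = None, ax=None):
        """Forest plot of SOC-level RORs (log scale) per drug."""
        import matplotlib.pyplot as plt

        drugs = list(drugs or self.model.drugs)
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 0.4 * len(socs) * len(drugs) + 1))
        y = 0
        ticks, labels = [], []
        for soc in socs:
            for drug in drugs:
                row = self.soc_ror(drug, [soc]).iloc[0]
                if not np.isnan(row["ror"]):
                    ax.plot([row["ror_ci_low"], row["ror_ci_high"]], [y, y], "-", color="C0")
                    ax.plot([row["ror"]], [y], "o", color="C0")
                ticks.append(y)
                labels.append(f"{soc} / {drug}")
                y += 1
        ax.axvline(1.0, color="grey", lw=0.8)
        ax.set_xscale("log")
        ax.set_yticks(ticks, labels)
        ax.set_xlabel("ROR (95% CI)")
        return ax
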