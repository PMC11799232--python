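"""FAERS-like synthetic report extracts with known ground truth.

The generator emulates the statistical structure a spontaneous-reporting
extract presents to a disproportionality analysis:

* each case has exactly one Primary Suspect (PS) drug, drawn from a drug
  catalogue with fixed weights, and possibly one concomitant drug (SS/C/I);
* each case carries one "primary" event drawn from a heavy-tailed (Zipf)
  PT catalogue, plus independent extra events, so every case has >= 1 PT
  and the marginal occurrence probability of PT *e* is closed-form:
  ``q_e = 1 - (1 - pi_e) (1 - r_e)`` with ``pi`` the primary multinomial and
  ``r_e = mean_extra_events * pi_e`` the extra-event Bernoulli rates;
* demographics (sex, age with missing mass, country, receipt date) are
  sampled per case and shared by all of the case's rows;
* a fraction of cases is emitted twice with an incremented report version,
  so the deduplication step has real work to do.

Associations are *planted* on the conditional odds scale: for a planted
(drug g, event e, target ROR rho), the odds of e among g's PS reports are
scaled by rho while the comparator is left untouched, so the expected 2x2
table has exactly ROR = rho (see :func:`expected_table`). PRR is not
directly controlled but converges to the ROR for rare events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from datetime import date, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .contingency import ContingencyTable
from .io import FRAME_COLUMNS, normalize_term
from .soc import MEDDRA_SOCS, SocMap


class ScenarioError(ValueError):
    """Raised for infeasible generative parameters (e.g. an odds scaling
    that no probability can realise)."""


def zipf_weights(k: int, exponent: float = 1.0) -> np.ndarray:
    """Normalised Zipf weights 1/rank**exponent for k items."""
    w = 1.0 / np.arange(1, k + 1, dtype=float) ** exponent
    return w / w.sum()


@dataclass(frozen=True)
class SimScenario:
    """Generative parameters of one synthetic extract.

    ``n_reports`` counts unique cases; duplicated case versions come on
    top. ``drug_weights``/``event_weights`` need not be pre-normalised.
    ``planted`` holds (drug, pt, target_ror) triples. ``seed`` is mandatory:
    there is no hidden global randomness.
    """

    n_reports: int
    drugs: tuple[str, ...]
    drug_weights: tuple[float, ...]
    events: tuple[str, ...]
    event_weights: tuple[float, ...]
    seed: int
    mean_extra_events: float = 1.5
    planted: tuple[tuple[str, str, float], ...] = ()
    sex_probs: tuple[float, float, float] = (0.3211, 0.5031, 0.1758)
    age_missing: float = 0.2961
    age_bin_probs: tuple[float, float, float, float] = (0.0936, 0.1574, 0.3300, 0.4190)
    age_bin_ranges: tuple[tuple[float, float], ...] = ((0, 18), (18, 45), (45, 65), (65, 95))
    country_weights: tuple[tuple[str, float], ...] = (
        ("US", 0.4388), ("JP", 0.1088), ("FR", 0.0783), ("CN", 0.0719),
        ("GB", 0.0392), ("DE", 0.0250), ("ES", 0.0150), ("", 0.2230),
    )
    secondary_drug_prob: float = 0.6
    secondary_role_probs: tuple[float, float, float] = (0.5, 0.4, 0.1)  # SS, C, I
    duplicate_case_rate: float = 0.05
    date_range: tuple[str, str] = ("2005-01-01", "2023-09-30")

    # -- derived, validated quantities -------------------------------------

    def drug_p(self) -> np.ndarray:
        w = np.asarray(self.drug_weights, dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise ScenarioError("drug weights must be non-negative with positive sum")
        return w / w.sum()

    def event_pi(self) -> np.ndarray:
        w = np.asarray(self.event_weights, dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise ScenarioError("event weights must be non-negative with positive sum")
        return w / w.sum()

    def extra_rates(self) -> np.ndarray:
        r = self.mean_extra_events * self.event_pi()
        if (r >= 1.0).any():
            raise ScenarioError(
                "mean_extra_events too large: an extra-event probability "
                "reaches 1; lower it or flatten the event weights"
            )
        return r

    def baseline_q(self) -> np.ndarray:
        """Marginal probability that each PT occurs in a (non-planted) report."""
        pi = self.event_pi()
        return 1.0 - (1.0 - pi) * (1.0 - self.extra_rates())

    def planted_q(self, drug: str, pt: str) -> float:
        """Occurrence probability of ``pt`` in reports whose PS drug is
        ``drug``, honouring any planted association."""
        drug, pt = normalize_term(drug), normalize_term(pt)
        e = self._event_index(pt)
        q = float(self.baseline_q()[e])
        for g, p, rho in self.planted:
            if normalize_term(g) == drug and normalize_term(p) == pt:
                odds = rho * q / (1.0 - q)
                q = odds / (1.0 + odds)
        return q

    def _drug_index(self, drug: str) -> int:
        key = normalize_term(drug)
        for i, d in enumerate(self.drugs):
            if normalize_term(d) == key:
                return i
        raise KeyError(f"drug {drug!r} not in scenario catalogue")

    def _event_index(self, pt: str) -> int:
        key = normalize_term(pt)
        for i, e in enumerate(self.events):
            if normalize_term(e) == key:
                return i
        raise KeyError(f"PT {pt!r} not in scenario catalogue")

    def _planted_extra_rate(self, drug_idx: int, event_idx: int) -> float:
        """Extra-event rate realising the planted occurrence probability.

        Occurrence is primary-OR-extra, so the adjusted extra rate is
        ``r' = 1 - (1 - q') / (1 - pi_e)``; infeasible (negative) r' means
        the requested odds scaling cannot be realised.
        """
        pi_e = float(self.event_pi()[event_idx])
        q_target = self.planted_q(self.drugs[drug_idx], self.events[event_idx])
        r = 1.0 - (1.0 - q_target) / (1.0 - pi_e)
        if not (0.0 <= r < 1.0):
            raise ScenarioError(
                f"planted odds scaling for ({self.drugs[drug_idx]}, "
                f"{self.events[event_idx]}) needs occurrence probability "
                f"{q_target:.4f} below the primary-event floor; use a larger "
                "target ROR or a smaller baseline"
            )
        return r

    # -- (de)serialisation ---------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimScenario":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if "seed" not in data:
            raise ScenarioError("scenario config must set an explicit seed")

        def _tupled(value):
            if isinstance(value, list):
                return tuple(_tupled(v) for v in value)
            return value

        return cls(**{k: _tupled(v) for k, v in data.items()})


def default_scenario(
    seed: int,
    n_reports: int = 20_000,
    planted: Sequence[tuple[str, str, float]] = (("voriconazole", "event_030", 5.0),),
) -> SimScenario:
    """The reference FAERS-like scenario.

    Three triazole antifungals with PS shares proportional to their
    real-world report volumes (roughly 9.4 : 2.1 : 1) plus nine background
    drugs; 120 PTs with Zipf(1) baseline frequencies and on average 2.5 PTs
    per report; demographics matching a large antifungal safety extract
    (50% male, ~30% missing age, US-dominated reporting).
    """
    background = zipf_weights(9, 1.0) * (1.0 - 0.265)
    drugs = ("voriconazole", "posaconazole", "isavuconazole") + tuple(
        f"bg_drug_{i:02d}" for i in range(1, 10)
    )
    drug_weights = (0.200, 0.044, 0.021) + tuple(float(x) for x in background)
    events = tuple(f"event_{i:03d}" for i in range(1, 121))
    event_weights = tuple(float(x) for x in zipf_weights(120, 1.0))
    return SimScenario(
        n_reports=n_reports,
        drugs=drugs,
        drug_weights=drug_weights,
        events=events,
        event_weights=event_weights,
        planted=tuple((d, p, float(r)) for d, p, r in planted),
        seed=seed,
    )


def scenario_soc_map(scenario: SimScenario) -> SocMap:
    """Deterministic PT->SOC assignment for a synthetic catalogue
    (round-robin over the 27 MedDRA SOC labels)."""
    entries = {
        normalize_term(pt): MEDDRA_SOCS[i % len(MEDDRA_SOCS)]
        for i, pt in enumerate(scenario.events)
    }
    return SocMap(entries=entries)


def scenario_soc_table(scenario: SimScenario) -> pd.DataFrame:
    """The same assignment as a writable (pt, soc, is_primary) table."""
    soc_map = scenario_soc_map(scenario)
    return pd.DataFrame(
        {
            "pt": list(scenario.events),
            "soc": [soc_map.soc_of(pt) for pt in scenario.events],
            "is_primary": True,
        }
    )


def generate_reports(scenario: SimScenario, seed: int | None = None) -> pd.DataFrame:
    """Generate one synthetic extract as a canonical report frame.

    Deterministic given the scenario (or the overriding ``seed``). The
    returned frame contains the duplicated case versions; run
    :func:`pvsignal.io.deduplicate` before analysis, as with a real extract.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    n = int(scenario.n_reports)
    if n <= 0:
        raise ScenarioError("n_reports must be positive")
    drugs = np.asarray([normalize_term(d) for d in scenario.drugs])
    events = np.asarray([normalize_term(e) for e in scenario.events])
    n_events = len(events)

    ps_idx = rng.choice(len(drugs), size=n, p=scenario.drug_p())
    primary = rng.choice(n_events, size=n, p=scenario.event_pi())
    extras = rng.random((n, n_events)) < scenario.extra_rates()[None, :]
    for g, p, _rho in scenario.planted:
        gi = scenario._drug_index(g)
        ei = scenario._event_index(p)
        r_adj = scenario._planted_extra_rate(gi, ei)
        rows = np.flatnonzero(ps_idx == gi)
        extras[rows, ei] = rng.random(rows.size) < r_adj
    occurs = extras
    occurs[np.arange(n), primary] = True

    # case-level demographics
    sex = rng.choice(np.asarray(["female", "male", "unknown"]), size=n,
                     p=np.asarray(scenario.sex_probs) / sum(scenario.sex_probs))
    age = np.full(n, np.nan)
    observed = rng.random(n) >= scenario.age_missing
    bins = rng.choice(len(scenario.age_bin_probs), size=n,
                      p=np.asarray(scenario.age_bin_probs) / sum(scenario.age_bin_probs))
    lo = np.asarray([r[0] for r in scenario.age_bin_ranges])[bins]
    hi = np.asarray([r[1] for r in scenario.age_bin_ranges])[bins]
    sampled = lo + rng.random(n) * (hi - lo)
    age[observed] = np.round(sampled[observed], 1)
    countries, cw = zip(*scenario.country_weights)
    country = rng.choice(np.asarray(countries, dtype=object), size=n,
                         p=np.asarray(cw) / sum(cw))
    d0 = date.fromisoformat(scenario.date_range[0])
    d1 = date.fromisoformat(scenario.date_range[1])
    offsets = rng.integers(0, (d1 - d0).days + 1, size=n)
    received = np.asarray([d0 + timedelta(days=int(o)) for o in offsets], dtype=object)

    # secondary (concomitant) drugs: at most one per case, never the PS drug
    has_secondary = rng.random(n) < scenario.secondary_drug_prob
    sec_idx = rng.integers(0, len(drugs), size=n)
    clash = sec_idx == ps_idx
    sec_idx[clash] = (sec_idx[clash] + 1) % len(drugs)
    sec_role = rng.choice(np.asarray(["SS", "C", "I"]), size=n,
                          p=np.asarray(scenario.secondary_role_probs)
                          / sum(scenario.secondary_role_probs))

    dup = rng.random(n) < scenario.duplicate_case_rate
    version = np.where(dup, 2, 1)

    case_ids = np.asarray([f"C{i:07d}" for i in range(n)], dtype=object)

    rep_i, ev_j = np.nonzero(occurs)
    country = np.where(country == "", None, country)
    blocks = []

    def _rows(i_arr, drug_arr, role_arr, pt_arr, version_arr):
        return pd.DataFrame(
            {
                "caseid": case_ids[i_arr],
                "version": version_arr,
                "drug": drug_arr,
                "role": role_arr,
                "pt": pt_arr,
                "sex": sex[i_arr],
                "age": age[i_arr],
                "country": country[i_arr],
                "date": received[i_arr],
            }
        )

    blocks.append(
        _rows(rep_i, drugs[ps_idx[rep_i]], np.repeat("PS", rep_i.size),
              events[ev_j], version[rep_i])
    )
    sec_rows = has_secondary[rep_i]
    i_sec = rep_i[sec_rows]
    blocks.append(
        _rows(i_sec, drugs[sec_idx[i_sec]], sec_role[i_sec],
              events[ev_j[sec_rows]], version[i_sec])
    )
    frame = pd.concat(blocks, ignore_index=True)

    # earlier versions of duplicated cases (identical content, version - 1)
    older = frame[frame["version"] == 2].copy()
    older["version"] = 1
    frame = pd.concat([frame, older], ignore_index=True)
    frame = frame.sort_values(["caseid", "version", "role", "pt"], kind="stable").reset_index(drop=True)
    return frame[list(FRAME_COLUMNS)]


def expected_table(scenario: SimScenario, drug: str, pt: str) -> ContingencyTable:
    """Analytic expected 2x2 table (real-valued cells) for one pair.

    Cells are expectations over the generative model of the deduplicated
    extract (duplicated versions collapse back to their case). For a pair
    planted with target ROR rho — and no other planting on the same PT —
    the ROR of this table is exactly rho.
    """
    drug_n, pt_n = normalize_term(drug), normalize_term(pt)
    gi = scenario._drug_index(drug_n)
    w = scenario.drug_p()
    n = float(scenario.n_reports)
    q_target = scenario.planted_q(drug_n, pt_n)
    # comparator occurrence: mixture over the other PS drugs
    q_by_drug = np.array(
        [scenario.planted_q(g, pt_n) for g in scenario.drugs], dtype=float
    )
    w_other = np.delete(w, gi)
    q_other = np.delete(q_by_drug, gi)
    q_comp = float((w_other * q_other).sum() / w_other.sum())
    a = n * w[gi] * q_target
    b = n * w[gi] * (1.0 - q_target)
    c = n * (1.0 - w[gi]) * q_comp
    d = n * (1.0 - w[gi]) * (1.0 - q_comp)
    return ContingencyTable(drug=drug_n, event=pt_n, a=a, b=b, c=c, d=d)


def ground_truth_table(scenario: SimScenario) -> pd.DataFrame:
    """Expected tables and target RORs for every planted pair (the sidecar
    written next to a simulated extract)."""
    rows = []
    for g, p, rho in scenario.planted:
        t = expected_table(scenario, g, p)
        rows.append((normalize_term(g), normalize_term(p), rho, t.a, t.b, t.c, t.d))
    return pd.DataFrame(
        rows, columns=["drug", "pt", "target_ror", "exp_a", "exp_b", "exp_c", "exp_d"]
    )


# ---------------------------------------------------------------------------
# validation studies
# ---------------------------------------------------------------------------


def _derived_seed(base_seed: int, index: int) -> int:
    """Independent per-replicate seed stream, kept below 2**31."""
    return int(np.random.SeedSequence(entropy=(base_seed, index)).generate_state(1)[0] % (2**31))


def coverage_study(
    seed: int,
    n_replicates: int = 500,
    n_reports: int = 20_000,
    target_ror: float = 5.0,
    drug: str = "voriconazole",
    pt: str = "event_030",
) -> dict:
    """Empirical 95% CI coverage for a planted association.

    Repeatedly simulates an extract with (``drug``, ``pt``) planted at
    ``target_ror``, runs the real pipeline (dedup -> 2x2 table -> ROR with
    CI) and checks whether the CI contains the target. With a calibrated
    generator and the lognormal CI, coverage should sit near the nominal
    95%.
    """
    from .io import deduplicate
    from .contingency import build_contingency
    from .stats import compute_ror

    scenario = default_scenario(seed=seed, n_reports=n_reports,
                                planted=((drug, pt, target_ror),))
    covered = 0
    estimates = []
    for i in range(n_replicates):
        frame = generate_reports(scenario, seed=_derived_seed(seed, i))
        table = build_contingency(deduplicate(frame), drug, pt)
        ror = compute_ror(table)
        estimates.append(ror.value)
        if ror.ci_low <= target_ror <= ror.ci_high:
            covered += 1
    return {
        "n_replicates": n_replicates,
        "n_reports": n_reports,
        "target_ror": target_ror,
        "coverage": covered / n_replicates,
        "median_ror": float(np.median(estimates)),
    }


def null_rate_study(
    seed: int,
    n_reports: int = 50_000,
    n_pairs: int | None = None,
    criteria=None,
) -> dict:
    """False-positive behaviour on an extract with no planted associations.

    Generates one null extract, takes the observed (drug, PT) pairs with
    a >= 3 (all of them by default; a random subsample of ``n_pairs`` when
    given), and reports (i) the fraction whose ROR 95% CI lower bound
    exceeds 1 — nominally ~2.5% for a two-sided 95% CI under the null, and
    (ii) the fraction flagged by the full joint signal criteria, which is
    lower still because of the PRR > 2 condition.
    """
    from .io import deduplicate
    from .contingency import enumerate_pairs
    from .stats import DEFAULT_CRITERIA, signal_stats

    criteria = criteria or DEFAULT_CRITERIA
    scenario = default_scenario(seed=seed, n_reports=n_reports, planted=())
    frame = deduplicate(generate_reports(scenario))
    tables = [t for t in enumerate_pairs(frame, list(scenario.drugs)) if t.a >= 3]
    if n_pairs is not None and n_pairs < len(tables):
        rng = np.random.default_rng(_derived_seed(seed, 10**6))
        idx = rng.choice(len(tables), size=n_pairs, replace=False)
        tables = [tables[i] for i in sorted(idx)]
    stats = [signal_stats(t, criteria=criteria) for t in tables]
    n = len(stats)
    return {
        "n_pairs": n,
        "n_reports": n_reports,
        "ci_low_gt1_rate": sum(s.ror_ci_low > 1 for s in stats) / n,
        "signal_rate": sum(s.is_signal for s in stats) / n,
    }


def recovery_study(
    seed: int,
    target_rors: Sequence[float] = (2.0, 5.0, 20.0),
    n_replicates: int = 11,
    n_reports: int = 50_000,
    drug: str = "voriconazole",
) -> dict:
    """Median recovered ROR for planted associations of varying strength.

    Plants one association per target strength (on distinct mid-tail PTs of
    the default catalogue, all for the same drug) and reports the median
    estimated ROR across replicates for each.
    """
    from .io import deduplicate
    from .contingency import build_contingency
    from .stats import compute_ror

    pts = [f"event_{30 + 10 * k:03d}" for k in range(len(target_rors))]
    planted = tuple((drug, pt, float(r)) for pt, r in zip(pts, target_rors))
    scenario = default_scenario(seed=seed, n_reports=n_reports, planted=planted)
    estimates: dict[float, list[float]] = {r: [] for r in target_rors}
    for i in range(n_replicates):
        frame = deduplicate(generate_reports(scenario, seed=_derived_seed(seed, 5000 + i)))
        for pt, rho in zip(pts, target_rors):
            estimates[rho].append(compute_ror(build_contingency(frame, drug, pt)).value)
    return {
        "n_replicates": n_replicates,
        "n_reports": n_reports,
        "median_ror": {rho: float(np.median(v)) for rho, v in estimates.items()},
    }


def write_extract(frame: pd.DataFrame, path: str | Path, delimiter: str = ",") -> None:
    """Write a canonical report frame in the external extract layout."""
    out = pd.DataFrame(
        {
            "caseid": frame["caseid"],
            "reportid": frame["version"],
            "drugname": frame["drug"],
            "role_cod": frame["role"],
            "pt": frame["pt"],
            "sex": frame["sex"],
            "age": frame["age"].map(lambda v: "" if pd.isna(v) else format(v, "g")),
            "age_cod": "YR",
            "occr_country": frame["country"].fillna(""),
            "receipt_date": frame["date"].map(lambda d: d.isoformat() if d else ""),
        }
    )
    out.to_csv(path, sep=delimiter, index=False)
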