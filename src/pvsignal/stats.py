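"""Disproportionality statistics: ROR, PRR, chi-square, signal criteria,
ranking, and inversion of published summary rows.

For a 2x2 table (a, b, c, d) of case counts (see :mod:`pvsignal.contingency`):

* reporting odds ratio        ROR = ad / bc, with the lognormal (Woolf) 95% CI
  ``exp(ln ROR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d))``;
* proportional reporting ratio PRR = [a/(a+b)] / [c/(c+d)], with 95% CI
  ``exp(ln PRR +/- 1.96 * sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d)))``;
* Pearson chi-square ``N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))``, optionally
  with the Yates continuity correction.

A (drug, event) pair is a signal when, simultaneously, a >= 3, the lower
95% CI bound of the ROR exceeds 1, and PRR exceeds 2 (the latter two
strictly). z = 1.96 is used verbatim rather than the exact normal quantile,
matching common pharmacovigilance practice.

Useful algebraic facts implemented and tested here:

* for an all-positive table, ROR > PRR iff ROR > 1 (and ROR = PRR iff
  ROR = 1): the two measures always sit on the same side of 1;
* both CIs are symmetric on the log scale, so the geometric mean of the
  bounds reproduces the point estimate — a cheap self-consistency check for
  published rows;
* given a published (a, PRR, ROR, CI) row, the remaining cells b, c, d are
  identified exactly (see :func:`invert_summary`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import pandas as pd

from .contingency import ContingencyTable

Z95 = 1.96


class RatioCI(NamedTuple):
    """A point estimate with its 95% confidence bounds.

    All three fields are NaN when the estimate is undefined (zero cell
    without continuity correction).
    """

    value: float
    ci_low: float
    ci_high: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.value)


@dataclass(frozen=True)
class SignalCriteria:
    """Joint disproportionality signal thresholds.

    a_min is inclusive (>=); the PRR and ROR-CI thresholds are strict (>).
    """

    a_min: int = 3
    prr_min: float = 2.0
    ror_ci_low_min: float = 1.0


DEFAULT_CRITERIA = SignalCriteria()


@dataclass(frozen=True)
class SignalStats:
    """All statistics for one (drug, event) pair plus the signal verdict."""

    drug: str
    event: str
    a: int
    ror: float
    ror_ci_low: float
    ror_ci_high: float
    prr: float
    prr_ci_low: float
    prr_ci_high: float
    chi2: float
    is_signal: bool
    reason: str = ""


def _haldane(table: ContingencyTable) -> tuple[float, float, float, float]:
    return (table.a + 0.5, table.b + 0.5, table.c + 0.5, table.d + 0.5)


def compute_ror(table: ContingencyTable, haldane: bool = False) -> RatioCI:
    """ROR = ad/bc with its lognormal 95% CI.

    A zero in any cell makes the estimate undefined (all-NaN result) unless
    ``haldane`` is set, in which case 0.5 is added to every cell first.
    """
    a, b, c, d = _haldane(table) if haldane else table.cells()
    if min(a, b, c, d) <= 0:
        return RatioCI(math.nan, math.nan, math.nan)
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_ror = math.log(ror)
    return RatioCI(ror, math.exp(log_ror - Z95 * se), math.exp(log_ror + Z95 * se))


def compute_prr(table: ContingencyTable, haldane: bool = False) -> RatioCI:
    """PRR = [a/(a+b)] / [c/(c+d)] with its lognormal 95% CI."""
    a, b, c, d = _haldane(table) if haldane else table.cells()
    if min(a, b, c, d) <= 0:
        return RatioCI(math.nan, math.nan, math.nan)
    prr = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    log_prr = math.log(prr)
    return RatioCI(prr, math.exp(log_prr - Z95 * se), math.exp(log_prr + Z95 * se))


def chi_square(table: ContingencyTable, variant: str = "pearson") -> float:
    """Chi-square statistic of the 2x2 table.

    ``variant="pearson"`` is the uncorrected statistic; ``"yates"`` applies
    the continuity correction (numerator floored at zero). NaN when a row or
    column margin is zero.
    """
    a, b, c, d = table.cells()
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom <= 0:
        return math.nan
    if variant == "pearson":
        num = (a * d - b * c) ** 2
    elif variant == "yates":
        num = max(abs(a * d - b * c) - n / 2.0, 0.0) ** 2
    else:
        raise ValueError(f"unknown chi-square variant {variant!r}")
    return n * num / denom


def apply_signal_criteria(
    stats: "SignalStats | tuple[int, float, float]",
    criteria: SignalCriteria = DEFAULT_CRITERIA,
) -> tuple[bool, str]:
    """Evaluate the joint signal rule; returns (is_signal, reason).

    ``reason`` is empty for a signal and names the first failed condition
    otherwise ("undefined" when the statistics could not be computed).
    """
    if isinstance(stats, SignalStats):
        a, ror_ci_low, prr = stats.a, stats.ror_ci_low, stats.prr
    else:
        a, ror_ci_low, prr = stats
    if math.isnan(ror_ci_low) or math.isnan(prr):
        return False, "undefined"
    if a < criteria.a_min:
        return False, f"a<{criteria.a_min}"
    if not ror_ci_low > criteria.ror_ci_low_min:
        return False, f"ror_ci_low<={criteria.ror_ci_low_min}"
    if not prr > criteria.prr_min:
        return False, f"prr<={criteria.prr_min}"
    return True, ""


def signal_stats(
    table: ContingencyTable,
    criteria: SignalCriteria = DEFAULT_CRITERIA,
    chi2_variant: str = "pearson",
    haldane: bool = False,
) -> SignalStats:
    """Compute the full statistic set for one table and apply the criteria."""
    ror = compute_ror(table, haldane=haldane)
    prr = compute_prr(table, haldane=haldane)
    chi2 = chi_square(table, variant=chi2_variant)
    flag, reason = apply_signal_criteria((int(round(table.a)), ror.ci_low, prr.value), criteria)
    return SignalStats(
        drug=table.drug,
        event=table.event,
        a=int(round(table.a)),
        ror=ror.value,
        ror_ci_low=ror.ci_low,
        ror_ci_high=ror.ci_high,
        prr=prr.value,
        prr_ci_low=prr.ci_low,
        prr_ci_high=prr.ci_high,
        chi2=chi2,
        is_signal=flag,
        reason=reason,
    )


def stats_frame(stats: Iterable[SignalStats]) -> pd.DataFrame:
    """Tabulate SignalStats objects (column layout of the signal exports)."""
    cols = [
        "drug", "pt", "a", "prr", "prr_ci_low", "prr_ci_high",
        "chi2", "ror", "ror_ci_low", "ror_ci_high", "is_signal", "reason",
    ]
    rows = [
        (
            s.drug, s.event, s.a, s.prr, s.prr_ci_low, s.prr_ci_high,
            s.chi2, s.ror, s.ror_ci_low, s.ror_ci_high, s.is_signal, s.reason,
        )
        for s in stats
    ]
    return pd.DataFrame(rows, columns=cols)


def rank_signals(stats: Sequence[SignalStats], n: int | None = None) -> list[SignalStats]:
    """Signals only, sorted by report count a (desc), then ROR (desc), then
    event name; truncated to the top ``n`` when given."""
    signals = [s for s in stats if s.is_signal]
    signals.sort(key=lambda s: (-s.a, -s.ror, s.event))
    return signals if n is None else signals[:n]


# ---------------------------------------------------------------------------
# inversion of published summary rows
# ---------------------------------------------------------------------------


class InconsistentSummaryError(ValueError):
    """A published (a, PRR, ROR, CI) row violates an algebraic relation the
    statistics must satisfy, so no 2x2 table can reproduce it."""


@dataclass(frozen=True)
class InversionResult:
    """Outcome of inverting a published summary row.

    ``table`` is the exact continuous solution; ``rounded`` its
    nearest-integer version. ``residuals`` maps statistic name to the
    relative error between the input value and the statistic recomputed
    from the rounded table (the continuous table reproduces the inputs to
    machine precision by construction).
    """

    table: ContingencyTable
    rounded: ContingencyTable
    residuals: dict[str, float]


def _relerr(x: float, ref: float) -> float:
    return abs(x - ref) / abs(ref)


def invert_summary(
    a: float,
    prr: float,
    ror: float,
    ror_ci_low: float,
    ror_ci_high: float,
    gm_tol: float = 0.005,
) -> InversionResult:
    """Recover the 2x2 table behind a published (a, PRR, ROR, 95% CI) row.

    The three relations ROR = ad/bc, PRR = [a/(a+b)]/[c/(c+d)] and
    ``1/a + 1/b + 1/c + 1/d = (ln(hi/lo) / (2 * 1.96))^2`` identify b, c, d
    given a. The system reduces analytically:

    * the PRR and ROR relations combine to ``b = a (PRR - 1) / (ROR - PRR)``;
    * substituting d = ROR*b*c/a into the CI-width relation leaves a linear
      equation in 1/c.

    Before solving, two internal-consistency checks are applied and their
    violation raises :class:`InconsistentSummaryError`: the geometric mean
    of the CI bounds must reproduce the ROR (relative tolerance ``gm_tol``),
    and PRR and ROR must sit on the same side of 1 with
    |ROR - 1| >= |PRR - 1| ordering (ROR > PRR iff ROR > 1) — a row with
    e.g. PRR > ROR > 1 cannot come from any positive table.
    """
    if min(a, prr, ror, ror_ci_low, ror_ci_high) <= 0:
        raise InconsistentSummaryError("all summary inputs must be positive")
    gm = math.sqrt(ror_ci_low * ror_ci_high)
    if _relerr(gm, ror) >= gm_tol:
        raise InconsistentSummaryError(
            "geometric mean of CI bounds "
            f"({gm:.4f}) does not reproduce ROR ({ror:.4f}): "
            "violates the lognormal-CI symmetry relation"
        )
    if (ror > 1 and not prr < ror) or (ror < 1 and not prr > ror) or (ror == 1 and prr != 1):
        raise InconsistentSummaryError(
            f"PRR ({prr}) and ROR ({ror}) violate the ordering relation "
            "ROR > PRR iff ROR > 1: no positive 2x2 table can produce this row"
        )
    if prr == ror:
        raise InconsistentSummaryError(
            "PRR = ROR != 1 admits no solution, and PRR = ROR = 1 leaves the "
            "table underdetermined"
        )
    b = a * (prr - 1.0) / (ror - prr)
    if b <= 0:
        raise InconsistentSummaryError(
            "implied b cell is non-positive: PRR and ROR sit on opposite sides of 1"
        )
    s = (math.log(ror_ci_high / ror_ci_low) / (2.0 * Z95)) ** 2
    t = s - 1.0 / a - 1.0 / b
    if t <= 0:
        raise InconsistentSummaryError(
            "CI width is too narrow for the implied a and b cells "
            "(1/a + 1/b already exceeds the squared log-CI half-width)"
        )
    c = (1.0 + a / (ror * b)) / t
    d = ror * b * c / a
    table = ContingencyTable(drug="", event="", a=float(a), b=b, c=c, d=d)
    rounded = ContingencyTable(
        drug="", event="",
        a=int(round(a)), b=max(int(round(b)), 1),
        c=max(int(round(c)), 1), d=max(int(round(d)), 1),
    )
    re_ror = compute_ror(rounded)
    re_prr = compute_prr(rounded)
    residuals = {
        "prr": _relerr(re_prr.value, prr),
        "ror": _relerr(re_ror.value, ror),
        "ror_ci_low": _relerr(re_ror.ci_low, ror_ci_low),
        "ror_ci_high": _relerr(re_ror.ci_high, ror_ci_high),
    }
    return InversionResult(table=table, rounded=rounded, residuals=residuals)
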