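"""Disproportionality statistics on drug–event 2×2 contingency tables.

Implements the classic frequentist signal-detection toolkit used on
spontaneous-report databases: the Reporting Odds Ratio (ROR), the
Proportional Reporting Ratio (PRR), the (Yates-corrected) chi-squared
statistic, and the Information Component (IC) with a delta-method
standard deviation, plus the three-way signal classification

    (PRR >= 2 and chi2 >= 4 and n_ij >= 3)  and  (IC - 2*SD > 0)
    and  (ROR - 1.96*SE > 1, i.e. the 95% CI lower bound exceeds 1).

All counts are distinct deduplicated case reports: ``n_ij`` cases with
both the drug of interest and the event of interest, ``n_i`` cases with
the event (any drug), ``n_j`` cases with the drug (any event), ``n``
total cases in the analysed window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "ContingencyTable",
    "SignalMetrics",
    "SignalCriteria",
    "SignalDecision",
    "UndefinedMetricError",
    "build_table",
    "compute_ror",
    "compute_prr",
    "compute_chi2",
    "compute_ic",
    "compute_metrics",
    "classify",
    "signal_frame",
    "write_signal_table",
]

#: 97.5% standard-normal quantile used for all 95% confidence intervals.
Z95 = 1.959963984540054
_LN2 = math.log(2.0)

SIGNAL_TABLE_COLUMNS = [
    "pt", "n_ij", "n_i", "n_j", "n",
    "ror", "ror_low", "ror_high",
    "prr", "prr_low", "prr_high",
    "chi2", "ic", "ic_low",
    "prr_chi2_n", "ic_positive", "ror_positive", "overall",
]


class UndefinedMetricError(ValueError):
    """A ratio statistic is undefined for this table (zero cell/margin)."""


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 drug–event table stored via its margins.

    Cells are derived:  a = n_ij (drug & event), b = n_j - n_ij
    (drug, other events), c = n_i - n_ij (event, other drugs),
    d = n - n_i - n_j + n_ij (neither).
    """

    n_ij: int
    n_i: int
    n_j: int
    n: int

    def __post_init__(self) -> None:
        for name in ("n_ij", "n_i", "n_j", "n"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise TypeError(f"{name} must be an integer, got {v!r}")
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.n < 1:
            raise ValueError("total case count n must be >= 1")
        if self.n_ij > min(self.n_i, self.n_j):
            raise ValueError(
                f"n_ij={self.n_ij} exceeds a margin (n_i={self.n_i}, n_j={self.n_j})"
            )
        if self.d < 0:
            raise ValueError(
                f"inconsistent margins: d = n - n_i - n_j + n_ij = {self.d} < 0"
            )

    @classmethod
    def from_cells(cls, a: int, b: int, c: int, d: int) -> "ContingencyTable":
        return cls(n_ij=a, n_i=a + c, n_j=a + b, n=a + b + c + d)

    @property
    def a(self) -> int:
        return self.n_ij

    @property
    def b(self) -> int:
        return self.n_j - self.n_ij

    @property
    def c(self) -> int:
        return self.n_i - self.n_ij

    @property
    def d(self) -> int:
        return self.n - self.n_i - self.n_j + self.n_ij

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    @property
    def has_zero_cell(self) -> bool:
        return min(self.cells()) == 0

    def expected_n_ij(self) -> float:
        """Expected joint count under independence, n_i * n_j / n."""
        return self.n_i * self.n_j / self.n


def build_table(pt: str, drug_case_ids: set, all_cases: dict) -> ContingencyTable:
    """Count the 2×2 table for one canonical PT over deduplicated cases.

    ``all_cases`` maps case_id -> an object with an ``events`` set of
    canonical PT keys (a :class:`~pvsignal.cases.CaseReport`).  Counts are
    distinct cases.  A PT absent from the data yields n_ij = n_i = 0,
    which downstream metrics handle (or flag) explicitly.
    """
    if not all_cases:
        raise ValueError("cannot build a contingency table over zero cases")
    drug_ids = drug_case_ids & all_cases.keys()
    n = len(all_cases)
    n_j = len(drug_ids)
    n_i = 0
    n_ij = 0
    for case_id, case in all_cases.items():
        if pt in case.events:
            n_i += 1
            if case_id in drug_ids:
                n_ij += 1
    return ContingencyTable(n_ij=n_ij, n_i=n_i, n_j=n_j, n=n)


class RatioEstimate(NamedTuple):
    estimate: float
    low: float
    high: float
    corrected: bool


def _working_cells(
    t: ContingencyTable, zero_cell_correction: bool, metric: str
) -> tuple[float, float, float, float, bool]:
    """Apply the +0.5 continuity correction to all four cells, but only
    when some cell is zero (nonzero tables are left untouched)."""
    if not t.has_zero_cell:
        return (*map(float, t.cells()), False)
    if not zero_cell_correction:
        raise UndefinedMetricError(
            f"{metric} undefined: table {t.cells()} has a zero cell and the "
            "continuity correction is disabled"
        )
    a, b, c, d = t.cells()
    return (a + 0.5, b + 0.5, c + 0.5, d + 0.5, True)


def compute_ror(
    t: ContingencyTable, *, zero_cell_correction: bool = True
) -> RatioEstimate:
    """Reporting odds ratio (a·d)/(b·c) with its Woolf 95% CI.

    SE(ln ROR) = sqrt(1/a + 1/b + 1/c + 1/d); the interval is
    exp(ln ROR ± 1.96·SE).  When a cell is zero, 0.5 is added to all four
    cells (flagged in the result) unless the correction is disabled, in
    which case the statistic is reported undefined.
    """
    a, b, c, d, corrected = _working_cells(t, zero_cell_correction, "ROR")
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_ror = math.log(ror)
    return RatioEstimate(
        ror, math.exp(log_ror - Z95 * se), math.exp(log_ror + Z95 * se), corrected
    )


def compute_prr(
    t: ContingencyTable, *, zero_cell_correction: bool = True
) -> RatioEstimate:
    """Proportional reporting ratio [a/(a+b)] / [c/(c+d)] with 95% CI.

    SE(ln PRR) = sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d)); the interval is
    exp(ln PRR ± 1.96·SE).  Zero cells handled as for :func:`compute_ror`.
    """
    a, b, c, d, corrected = _working_cells(t, zero_cell_correction, "PRR")
    prr = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    log_prr = math.log(prr)
    return RatioEstimate(
        prr, math.exp(log_prr - Z95 * se), math.exp(log_prr + Z95 * se), corrected
    )


def compute_chi2(t: ContingencyTable, *, yates: bool = True) -> float:
    """Chi-squared statistic of the 2×2 table, Yates-corrected by default.

    Yates form: n·(max(|ad−bc| − n/2, 0))² / ((a+b)(c+d)(a+c)(b+d)).
    The historical PRR ≥ 2 / chi2 ≥ 4 / n ≥ 3 criterion uses the corrected
    statistic; pass ``yates=False`` for the plain Pearson form.
    """
    a, b, c, d = t.cells()
    n = t.n
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        raise UndefinedMetricError(
            f"chi-squared undefined: table {t.cells()} has a zero margin"
        )
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2.0, 0.0)
    return n * diff * diff / denom


class ICEstimate(NamedTuple):
    ic: float
    low: float
    sd: float


def compute_ic(t: ContingencyTable, *, shrinkage: bool = True) -> ICEstimate:
    """Information component, log2 of observed over expected joint count.

    The default shrinkage form adds 0.5 to both the observed count and the
    independence expectation E = n_i·n_j/n,

        IC = log2((n_ij + 0.5) / (E + 0.5)),   SD = 1 / (ln2 · sqrt(n_ij + 0.5)),

    which keeps the statistic finite at n_ij = 0 and pulls small counts
    toward 0.  ``shrinkage=False`` gives the plain log2(n_ij·n / (n_i·n_j)),
    undefined at n_ij = 0.  The signal bound is IC − 2·SD.
    """
    if t.n_i == 0 or t.n_j == 0:
        raise UndefinedMetricError(
            f"IC undefined: zero margin (n_i={t.n_i}, n_j={t.n_j})"
        )
    expected = t.expected_n_ij()
    if shrinkage:
        ic = math.log2((t.n_ij + 0.5) / (expected + 0.5))
        sd = 1.0 / (_LN2 * math.sqrt(t.n_ij + 0.5))
    else:
        if t.n_ij == 0:
            raise UndefinedMetricError("unshrunk IC undefined at n_ij = 0")
        ic = math.log2(t.n_ij / expected)
        sd = 1.0 / (_LN2 * math.sqrt(t.n_ij))
    return ICEstimate(ic, ic - 2.0 * sd, sd)


@dataclass(frozen=True)
class SignalMetrics:
    """Point estimates and interval bounds for one drug–event pair.

    Undefined statistics are stored as NaN with the reason recorded in
    ``undefined_reasons``; every signal rule treats NaN as failed.
    """

    pt: str
    n_ij: int
    n_i: int
    n_j: int
    n: int
    ror: float = math.nan
    ror_low: float = math.nan
    ror_high: float = math.nan
    prr: float = math.nan
    prr_low: float = math.nan
    prr_high: float = math.nan
    chi2: float = math.nan
    ic: float = math.nan
    ic_low: float = math.nan
    ic_sd: float = math.nan
    correction_applied: bool = False
    undefined_reasons: tuple[str, ...] = ()


def compute_metrics(
    t: ContingencyTable,
    pt: str = "",
    *,
    zero_cell_correction: bool = True,
    yates: bool = True,
    ic_shrinkage: bool = True,
) -> SignalMetrics:
    """Evaluate ROR, PRR, chi-squared and IC on one table.

    Statistics that are undefined for the table are reported as NaN with
    a human-readable reason instead of raising, so a whole PT list can be
    scored in one pass.
    """
    values: dict[str, float] = {}
    reasons: list[str] = []
    corrected = False
    try:
        ror = compute_ror(t, zero_cell_correction=zero_cell_correction)
        values.update(ror=ror.estimate, ror_low=ror.low, ror_high=ror.high)
        corrected = corrected or ror.corrected
    except UndefinedMetricError as exc:
        reasons.append(str(exc))
    try:
        prr = compute_prr(t, zero_cell_correction=zero_cell_correction)
        values.update(prr=prr.estimate, prr_low=prr.low, prr_high=prr.high)
        corrected = corrected or prr.corrected
    except UndefinedMetricError as exc:
        reasons.append(str(exc))
    try:
        values["chi2"] = compute_chi2(t, yates=yates)
    except UndefinedMetricError as exc:
        reasons.append(str(exc))
    try:
        ic = compute_ic(t, shrinkage=ic_shrinkage)
        values.update(ic=ic.ic, ic_low=ic.low, ic_sd=ic.sd)
    except UndefinedMetricError as exc:
        reasons.append(str(exc))
    return SignalMetrics(
        pt=pt,
        n_ij=t.n_ij,
        n_i=t.n_i,
        n_j=t.n_j,
        n=t.n,
        correction_applied=corrected,
        undefined_reasons=tuple(reasons),
        **values,
    )


@dataclass(frozen=True)
class SignalCriteria:
    """Thresholds of the three-way signal rule.

    Defaults are the standard ones: PRR ≥ 2 with chi-squared ≥ 4 and at
    least 3 reports; IC − 2·SD > 0; ROR 95% CI lower bound > 1 (strict).
    """

    prr_threshold: float = 2.0
    chi2_threshold: float = 4.0
    min_reports: int = 3

    def __post_init__(self) -> None:
        if self.prr_threshold <= 0 or self.chi2_threshold <= 0 or self.min_reports <= 0:
            raise ValueError("signal-criteria thresholds must be strictly positive")


@dataclass(frozen=True)
class SignalDecision:
    pt: str
    prr_chi2_n: bool
    ic_positive: bool
    ror_positive: bool
    overall: bool = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "overall", self.prr_chi2_n and self.ic_positive and self.ror_positive
        )


def classify(metrics: SignalMetrics, criteria: SignalCriteria | None = None) -> SignalDecision:
    """Apply the three signal criteria to one pair's metrics.

    NaN (undefined) statistics fail their criterion.  The ROR and IC rules
    are strict inequalities: a lower bound exactly at the null is not a
    signal.
    """
    c = criteria or SignalCriteria()
    prr_chi2_n = (
        metrics.prr >= c.prr_threshold
        and metrics.chi2 >= c.chi2_threshold
        and metrics.n_ij >= c.min_reports
    )
    ic_positive = metrics.ic_low > 0.0
    ror_positive = metrics.ror_low > 1.0
    return SignalDecision(
        pt=metrics.pt,
        prr_chi2_n=bool(prr_chi2_n),
        ic_positive=bool(ic_positive),
        ror_positive=bool(ror_positive),
    )


def signal_frame(
    metrics: Iterable[SignalMetrics], criteria: SignalCriteria | None = None
) -> pd.DataFrame:
    """Tabulate metrics + decisions, ranked by n_ij descending then PT.

    The ordering mirrors how spontaneous-report studies present their
    findings: most-reported pair first.
    """
    rows = []
    for m in metrics:
        d = classify(m, criteria)
        rows.append(
            {
                "pt": m.pt, "n_ij": m.n_ij, "n_i": m.n_i, "n_j": m.n_j, "n": m.n,
                "ror": m.ror, "ror_low": m.ror_low, "ror_high": m.ror_high,
                "prr": m.prr, "prr_low": m.prr_low, "prr_high": m.prr_high,
                "chi2": m.chi2, "ic": m.ic, "ic_low": m.ic_low,
                "prr_chi2_n": d.prr_chi2_n, "ic_positive": d.ic_positive,
                "ror_positive": d.ror_positive, "overall": d.overall,
            }
        )
    frame = pd.DataFrame(rows, columns=SIGNAL_TABLE_COLUMNS)
    frame = frame.sort_values(
        ["n_ij", "pt"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return frame


def write_signal_table(frame: pd.DataFrame, path) -> None:
    """Write the signal table as CSV, floats at 6 significant digits."""
    frame.to_csv(path, index=False, float_format="%.6g")
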