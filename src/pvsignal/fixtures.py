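"""Published levonorgestrel point values used as classification fixtures.

A 2018 FAERS disproportionality study of levonorgestrel (the emergency
oral contraceptive) screened 15 clinically relevant MedDRA preferred
terms and printed, for each, point values of the Information Component
(IC), Reporting Odds Ratio (ROR) and Proportional Reporting Ratio (PRR),
plus 95% CI bounds for the ten terms it called signals.  Those printed
numbers are inputs here: they exercise the classification logic on real
published values without needing the underlying database, whose raw
counts are not public at desk scale.

Note the published IC column is not on the usual log2 observed/expected
scale (values reach 129.22, impossible for log2 ratios given the printed
margins); it is carried verbatim and used only for sign/threshold
comparisons, never re-derived.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import pandas as pd

__all__ = [
    "PublishedRow",
    "TABLE1",
    "CI_LOWER_BOUNDS",
    "REPORT_COUNTS",
    "PointDecision",
    "classify_point_fixtures",
]


class PublishedRow(NamedTuple):
    pt: str
    ic: float
    ror: float
    prr: float


#: The 15 screened preferred terms with their printed (IC, ROR, PRR).
TABLE1: tuple[PublishedRow, ...] = (
    PublishedRow("Breast enlargement", 1.16, 1.7, 1.7),
    PublishedRow("Breast tenderness", 12.38, 3.7, 3.68),
    PublishedRow("Dysmenorrhea", 9.72, 3.46, 3.44),
    PublishedRow("Ectopic pregnancy", 0.5, 1.3, 1.3),
    PublishedRow("Menorrhagia", 1.86, 1.89, 1.88),
    PublishedRow("Menstruation delayed", 28.24, 4.53, 4.49),
    PublishedRow("Metrorrhagia", 4.2, 2.63, 2.61),
    PublishedRow("Nipple disorder", 4.8, 2.83, 2.83),
    PublishedRow("Pregnancy after post coital contraception", 129.22, 6.51, 6.49),
    PublishedRow("Premenstrual syndrome", 0.52, 1.5, 1.5),
    PublishedRow("Diarrhoea", -0.26, -1.36, -1.34),
    PublishedRow("Dysuria", -0.37, -0.27, -0.27),
    PublishedRow("Fungal infection", -0.25, 0.08, 0.08),
    PublishedRow("Muscle spasm", -0.05, -0.18, -0.18),
    PublishedRow("Pollakiuria", -0.13, 0.16, 0.16),
)

#: Printed 95% CI lower bounds (ror_low, prr_low, ic_low) for the ten
#: terms reported as signals; the other five terms have no printed CIs.
CI_LOWER_BOUNDS: dict[str, tuple[float, float, float]] = {
    "Pregnancy after post coital contraception": (6.34, 6.32, 128.67),
    "Menstruation delayed": (4.46, 4.43, 28.03),
    "Breast tenderness": (3.62, 3.6, 12.12),
    "Dysmenorrhea": (3.38, 3.36, 9.46),
    "Nipple disorder": (2.65, 2.65, 4.20),
    "Metrorrhagia": (2.56, 2.54, 3.96),
    "Menorrhagia": (1.8, 1.79, 1.57),
    "Breast enlargement": (1.47, 1.47, 0.38),
    "Premenstrual syndrome": (1.16, 1.16, -0.61),
    "Ectopic pregnancy": (1.04, 1.04, -0.35),
}

#: Published report counts for the ten signal terms (distinct reports).
REPORT_COUNTS: dict[str, int] = {
    "Menstruation delayed": 1791,
    "Pregnancy after post coital contraception": 942,
    "Breast tenderness": 901,
    "Metrorrhagia": 899,
    "Dysmenorrhea": 822,
    "Menorrhagia": 541,
    "Nipple disorder": 141,
    "Breast enlargement": 77,
    "Ectopic pregnancy": 61,
    "Premenstrual syndrome": 35,
}


@dataclass(frozen=True)
class PointDecision:
    """Null-comparison verdicts for one published row.

    Point rules compare the printed point values to their nulls
    (IC > 0, ROR > 1, PRR > 1); CI rules, where bounds were printed,
    compare the lower bounds (ror_low > 1, prr_low > 1, ic_low > 0).
    """

    pt: str
    ic_positive: bool
    ror_positive: bool
    prr_positive: bool
    overall_point: bool
    has_ci: bool
    ror_ci_positive: bool | None = None
    prr_ci_positive: bool | None = None
    ic_ci_positive: bool | None = None


def classify_point_fixtures() -> list[PointDecision]:
    """Apply the point-value (and, where printed, CI) rules to every row."""
    decisions = []
    for row in TABLE1:
        ic_pos = row.ic > 0.0
        ror_pos = row.ror > 1.0
        prr_pos = row.prr > 1.0
        ci = CI_LOWER_BOUNDS.get(row.pt)
        decisions.append(
            PointDecision(
                pt=row.pt,
                ic_positive=ic_pos,
                ror_positive=ror_pos,
                prr_positive=prr_pos,
                overall_point=ic_pos and ror_pos and prr_pos,
                has_ci=ci is not None,
                ror_ci_positive=None if ci is None else ci[0] > 1.0,
                prr_ci_positive=None if ci is None else ci[1] > 1.0,
                ic_ci_positive=None if ci is None else ci[2] > 0.0,
            )
        )
    return decisions


def fixtures_frame() -> pd.DataFrame:
    """Published values plus decisions in one table, for printing."""
    decisions = {d.pt: d for d in classify_point_fixtures()}
    rows = []
    for row in TABLE1:
        d = decisions[row.pt]
        rows.append(
            {
                "pt": row.pt, "ic": row.ic, "ror": row.ror, "prr": row.prr,
                "ic_positive": d.ic_positive, "ror_positive": d.ror_positive,
                "prr_positive": d.prr_positive, "overall_point": d.overall_point,
                "reports": REPORT_COUNTS.get(row.pt),
            }
        )
    return pd.DataFrame(rows)
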