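"""Case assembly: drug-query selection, deduplication, event tallies.

Reproduces the standard spontaneous-report workflow: isolate the case
ids whose drug rows match the query under a suspect-role filter
(primary/secondary suspect by default, concomitant and interacting
excluded), collapse duplicate case versions to the latest, join each
case to its reaction rows, and tally per-quarter event frequencies.

The counting unit everywhere is the distinct case: a preferred term
mentioned twice in one report still counts once, and a drug listed on
two rows of one case selects that case once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .faers_io import QuarterBundle

__all__ = [
    "DrugQuery",
    "CaseReport",
    "DedupReport",
    "FrequencyTable",
    "select_drug_cases",
    "deduplicate",
    "tally_events",
]


@dataclass(frozen=True)
class DrugQuery:
    """A drug of interest: canonical name plus synonyms and matching rules.

    match_mode 'substring' (the default) treats a row as a match when any
    query name occurs inside the verbatim drug string, catching salt and
    brand decorations; 'exact' requires whole-string equality.  Matching
    is case-insensitive in both modes.
    """

    canonical_name: str
    synonyms: tuple[str, ...] = ()
    match_mode: str = "substring"
    roles_included: frozenset[str] = frozenset({"PS", "SS"})

    def __post_init__(self) -> None:
        object.__setattr__(self, "synonyms", tuple(self.synonyms))
        object.__setattr__(self, "roles_included", frozenset(self.roles_included))
        if not self.names:
            raise ValueError("drug query needs a canonical name or at least one synonym")
        if self.match_mode not in ("exact", "substring"):
            raise ValueError(f"unknown match_mode {self.match_mode!r}")
        if not self.roles_included:
            raise ValueError("roles_included must be a non-empty role set")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(
            n.strip().casefold()
            for n in (self.canonical_name, *self.synonyms)
            if n and n.strip()
        )

    def matches_name(self, drug_name: str) -> bool:
        hay = str(drug_name).casefold()
        if self.match_mode == "exact":
            return any(hay.strip() == n for n in self.names)
        return any(n in hay for n in self.names)


def select_drug_cases(
    bundles: Iterable[QuarterBundle], query: DrugQuery
) -> set[str]:
    """Case ids with ≥1 drug row matching the query name AND role filter.

    Name match and role inclusion must hold on the *same* row: a case
    listing the drug only as concomitant is excluded under the default
    PS/SS filter even if other drugs on the case are suspects.
    """
    selected: set[str] = set()
    for bundle in bundles:
        drugs = bundle.drugs
        if drugs.empty:
            continue
        name_hit = drugs["drug_name"].map(query.matches_name)
        role_hit = drugs["role_code"].isin(query.roles_included)
        selected.update(drugs.loc[name_hit & role_hit, "case_id"])
    return selected


@dataclass(frozen=True)
class CaseReport:
    """One deduplicated safety report."""

    case_id: str
    latest_version_key: str
    version: int
    drugs: tuple[tuple[str, str], ...]   # (drug_name, role_code)
    events: frozenset[str]               # canonical PT keys
    quarter_first_seen: str


@dataclass(frozen=True)
class DedupReport:
    n_case_versions: int
    n_cases: int

    @property
    def collapsed_versions(self) -> int:
        return self.n_case_versions - self.n_cases


def deduplicate(
    bundles: Sequence[QuarterBundle], mode: str = "latest"
) -> tuple[dict[str, CaseReport], DedupReport]:
    """Collapse case versions to one CaseReport per case id.

    mode='latest' keeps, per case id, the version with the highest
    version number (ties broken by the larger case_key); its drug and
    reaction rows define the case.  mode='off' performs no collapsing:
    every case version becomes its own unit, keyed by case_key.
    quarter_first_seen is the earliest quarter in which any version of
    the case appeared.
    """
    if mode not in ("latest", "off"):
        raise ValueError(f"unknown dedup mode {mode!r}")

    demo_frames = []
    for order, bundle in enumerate(bundles):
        d = bundle.demo[["case_key", "case_id", "version"]].copy()
        d["quarter"] = bundle.quarter
        d["quarter_order"] = order
        demo_frames.append(d)
    if not demo_frames:
        return {}, DedupReport(0, 0)
    demo = pd.concat(demo_frames, ignore_index=True)
    n_versions = len(demo)

    if mode == "off":
        demo = demo.assign(unit_id=demo["case_key"])
    else:
        demo = demo.assign(unit_id=demo["case_id"])

    # Latest version per unit: highest version number, then highest key.
    demo = demo.sort_values(
        ["unit_id", "version", "case_key"], kind="mergesort"
    )
    latest = demo.groupby("unit_id", sort=False).tail(1)
    first_seen = (
        demo.sort_values(["unit_id", "quarter_order"], kind="mergesort")
        .groupby("unit_id", sort=False)
        .head(1)
        .set_index("unit_id")["quarter"]
    )

    drug_rows: dict[str, list[tuple[str, str]]] = {}
    event_rows: dict[str, set[str]] = {}
    for bundle in bundles:
        for row in bundle.drugs.itertuples(index=False):
            drug_rows.setdefault(row.case_key, []).append((row.drug_name, row.role_code))
        for row in bundle.reactions.itertuples(index=False):
            event_rows.setdefault(row.case_key, set()).add(row.pt_key)

    cases: dict[str, CaseReport] = {}
    for row in latest.itertuples(index=False):
        unit = row.unit_id
        cases[unit] = CaseReport(
            case_id=unit,
            latest_version_key=row.case_key,
            version=int(row.version),
            drugs=tuple(drug_rows.get(row.case_key, [])),
            events=frozenset(event_rows.get(row.case_key, set())),
            quarter_first_seen=first_seen[unit],
        )
    return cases, DedupReport(n_case_versions=n_versions, n_cases=len(cases))


@dataclass
class FrequencyTable:
    """Distinct-case counts per canonical PT, per quarter and overall."""

    quarters: tuple[str, ...]
    counts: pd.DataFrame          # index: pt key (alphabetical); columns: quarters
    orphaned_case_ids: tuple[str, ...] = ()

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Long form with columns pt, quarter, count, total."""
        rows = []
        for pt, row in self.counts.iterrows():
            total = int(row.sum())
            for q in self.quarters:
                rows.append({"pt": pt, "quarter": q, "count": int(row[q]), "total": total})
        return pd.DataFrame(rows, columns=["pt", "quarter", "count", "total"])

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def tally_events(
    case_ids: Iterable[str],
    cases: Mapping[str, CaseReport],
    quarters: Sequence[str],
) -> FrequencyTable:
    """Per-quarter distinct-case counts of each PT among the given cases.

    A case contributes at most 1 to each of its PTs (reaction rows are a
    set per case), in the quarter the case was first seen.  Quarters with
    no occurrences appear as explicit zeros; selected case ids that have
    no reaction rows at all are returned as orphans.
    """
    quarters = tuple(quarters)
    wanted = [cid for cid in case_ids if cid in cases]
    orphans = []
    tallies: dict[str, dict[str, int]] = {}
    for cid in wanted:
        case = cases[cid]
        if not case.events:
            orphans.append(cid)
            continue
        q = case.quarter_first_seen
        for pt in case.events:
            per_q = tallies.setdefault(pt, {})
            per_q[q] = per_q.get(q, 0) + 1
    index = sorted(tallies)
    counts = pd.DataFrame(0, index=index, columns=list(quarters), dtype=int)
    for pt, per_q in tallies.items():
        for q, c in per_q.items():
            if q in counts.columns:
                counts.loc[pt, q] = c
    counts.index.name = "pt"
    return FrequencyTable(
        quarters=quarters, counts=counts, orphaned_case_ids=tuple(sorted(orphans))
    )
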