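"""End-to-end study orchestration: quarters in, ranked signal table out.

``run`` wires the stages together — parse each quarter's files,
deduplicate case versions, select the query drug's cases under the
suspect-role filter, tally events, build a 2×2 table per analysed
preferred term, score it, classify it — and emits a run report with the
case funnel (parsed versions → deduplicated cases → query-matched
cases), mirroring how spontaneous-report studies account for their data.

Everything is deterministic given the input files and configuration; the
run report carries no timestamps, so reruns are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import cases as _cases
from . import disproportionality as _disp
from . import faers_io as _io
from .cases import CaseReport, DedupReport, DrugQuery, FrequencyTable
from .disproportionality import SignalCriteria, SignalMetrics
from .faers_io import normalize_pt
from .synth import quarter_file_names

__all__ = [
    "RunConfig",
    "RunReport",
    "RunResult",
    "NoQueryCasesError",
    "run",
    "load_run_config",
]


class NoQueryCasesError(RuntimeError):
    """No case matched the drug query: the analysis has an empty exposure."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full analysis run.

    pt_whitelist restricts the scored terms (the 'clinically relevant
    PTs' step is a human judgment and enters only as this optional
    list); when absent, every PT observed among the query drug's cases
    is scored.
    """

    input_dir: str | Path
    quarters: tuple[str, ...]
    query: DrugQuery
    pt_whitelist: tuple[str, ...] | None = None
    criteria: SignalCriteria = field(default_factory=SignalCriteria)
    dedup: str = "latest"
    dialect: str = "auto"
    zero_cell_correction: bool = True
    yates: bool = True
    ic_shrinkage: bool = True
    output_dir: str | Path | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "quarters", tuple(self.quarters))
        if not self.quarters:
            raise ValueError("quarter range must be non-empty")
        if list(self.quarters) != sorted(set(self.quarters)):
            raise ValueError("quarters must be unique and in ascending order")
        if self.pt_whitelist is not None:
            object.__setattr__(
                self, "pt_whitelist", tuple(normalize_pt(p) for p in self.pt_whitelist)
            )


@dataclass
class RunReport:
    """Per-stage case funnel plus data-quality counts."""

    quarters: tuple[str, ...]
    parsed_case_versions: int
    deduplicated_cases: int
    collapsed_versions: int
    query_matched_cases: int
    analysed_pts: int
    rejected_rows: int
    orphaned_reaction_keys: int
    per_quarter_versions: dict[str, int]

    def to_text(self) -> str:
        lines = [
            "analysis run report",
            f"quarters analysed: {len(self.quarters)} ({self.quarters[0]}..{self.quarters[-1]})",
            f"parsed case versions: {self.parsed_case_versions}",
            f"deduplicated cases: {self.deduplicated_cases}",
            f"collapsed duplicate versions: {self.collapsed_versions}",
            f"query-matched cases: {self.query_matched_cases}",
            f"preferred terms analysed: {self.analysed_pts}",
            f"rejected rows: {self.rejected_rows}",
            f"orphaned reaction keys: {self.orphaned_reaction_keys}",
            "case versions per quarter:",
        ]
        for q in self.quarters:
            lines.append(f"  {q}: {self.per_quarter_versions.get(q, 0)}")
        return "\n".join(lines)


@dataclass
class RunResult:
    signal_frame: pd.DataFrame
    frequency_table: FrequencyTable
    report: RunReport
    metrics: list[SignalMetrics]
    dedup_report: DedupReport
    cases: dict[str, CaseReport]
    query_case_ids: set[str]


def _bundle_paths(input_dir: Path, quarter: str) -> tuple[Path, Path, Path]:
    demo, drug, reac = quarter_file_names(quarter)
    return input_dir / demo, input_dir / drug, input_dir / reac


def run(config: RunConfig) -> RunResult:
    """Execute the full pipeline and (optionally) write its outputs.

    Raises :class:`NoQueryCasesError` when the drug query matches zero
    cases; an empty signal table is never written.
    """
    input_dir = Path(config.input_dir)
    bundles = []
    for quarter in config.quarters:
        demo, drug, reac = _bundle_paths(input_dir, quarter)
        bundles.append(
            _io.read_quarter(demo, drug, reac, dialect=config.dialect, quarter=quarter)
        )

    all_cases, dedup_report = _cases.deduplicate(bundles, mode=config.dedup)
    query_ids = _cases.select_drug_cases(bundles, config.query)
    query_ids &= all_cases.keys()
    if not query_ids:
        raise NoQueryCasesError(
            f"drug query {config.query.canonical_name!r} matched no cases in "
            f"{len(bundles)} quarter(s)"
        )

    freq = _cases.tally_events(query_ids, all_cases, config.quarters)
    observed_pts = list(freq.counts.index)
    if config.pt_whitelist is not None:
        analysed = [pt for pt in config.pt_whitelist]
    else:
        analysed = observed_pts

    metrics = []
    for pt in analysed:
        table = _disp.build_table(pt, query_ids, all_cases)
        metrics.append(
            _disp.compute_metrics(
                table,
                pt=pt,
                zero_cell_correction=config.zero_cell_correction,
                yates=config.yates,
                ic_shrinkage=config.ic_shrinkage,
            )
        )
    frame = _disp.signal_frame(metrics, config.criteria)

    report = RunReport(
        quarters=config.quarters,
        parsed_case_versions=dedup_report.n_case_versions,
        deduplicated_cases=dedup_report.n_cases,
        collapsed_versions=dedup_report.collapsed_versions,
        query_matched_cases=len(query_ids),
        analysed_pts=len(analysed),
        rejected_rows=sum(b.rejects.total_rejected for b in bundles),
        orphaned_reaction_keys=sum(b.rejects.orphaned_reaction_keys for b in bundles),
        per_quarter_versions={b.quarter: b.n_case_versions for b in bundles},
    )

    result = RunResult(
        signal_frame=frame,
        frequency_table=freq,
        report=report,
        metrics=metrics,
        dedup_report=dedup_report,
        cases=all_cases,
        query_case_ids=query_ids,
    )
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        _disp.write_signal_table(frame, out / "signal_table.csv")
        freq.write_csv(out / "frequency_table.csv")
        (out / "run_report.txt").write_text(report.to_text() + "\n", encoding="utf-8")
    return result


def load_run_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML.

    Schema: input_dir, quarters (list), query {canonical_name, synonyms,
    match_mode, roles_included}, optional pt_whitelist, criteria
    {prr_threshold, chi2_threshold, min_reports}, dedup, dialect,
    output_dir, seed.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    q = raw["query"]
    query = DrugQuery(
        canonical_name=q["canonical_name"],
        synonyms=tuple(q.get("synonyms", ())),
        match_mode=q.get("match_mode", "substring"),
        roles_included=frozenset(q.get("roles_included", ("PS", "SS"))),
    )
    crit_raw = raw.get("criteria", {})
    criteria = SignalCriteria(
        prr_threshold=float(crit_raw.get("prr_threshold", 2.0)),
        chi2_threshold=float(crit_raw.get("chi2_threshold", 4.0)),
        min_reports=int(crit_raw.get("min_reports", 3)),
    )
    return RunConfig(
        input_dir=raw["input_dir"],
        quarters=tuple(raw["quarters"]),
        query=query,
        pt_whitelist=tuple(raw["pt_whitelist"]) if raw.get("pt_whitelist") else None,
        criteria=criteria,
        dedup=raw.get("dedup", "latest"),
        dialect=raw.get("dialect", "auto"),
        zero_cell_correction=bool(raw.get("zero_cell_correction", True)),
        yates=bool(raw.get("yates", True)),
        ic_shrinkage=bool(raw.get("ic_shrinkage", True)),
        output_dir=raw.get("output_dir"),
        seed=int(raw.get("seed", 0)),
    )
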