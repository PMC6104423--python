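"""Readers for "$"-delimited quarterly DEMO/DRUG/REAC extract files.

Two column dialects are supported, reflecting the 2012Q4 switch in the
FDA's quarterly extracts: the *legacy* layout keys every row by an ISR
number with a separate CASE column, while the *modern* layout keys rows
by primaryid with a caseid and explicit caseversion.  Both normalise to
one record model (case_key, case_id, version, drug/reaction rows), so
downstream assembly is dialect-agnostic.

Malformed rows (embedded delimiters, missing mandatory fields, empty
PTs) are never silently dropped: they are counted in a
:class:`RejectsReport` alongside the first few offending lines.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pandas as pd

__all__ = [
    "DrugRow",
    "ReactionRow",
    "QuarterBundle",
    "RejectsReport",
    "DIALECTS",
    "KNOWN_ROLE_CODES",
    "read_quarter",
    "normalize_pt",
    "display_pt",
    "detect_dialect",
]

KNOWN_ROLE_CODES = frozenset({"PS", "SS", "C", "I"})

#: Logical-name -> file-column-name mapping per dialect and file kind.
#: Kept as data, not code: new extract layouts mean a new entry here.
DIALECTS: dict[str, dict[str, dict[str, str]]] = {
    "legacy": {
        "demo": {"case_key": "ISR", "case_id": "CASE", "version": "FOLL_SEQ",
                 "age": "AGE", "age_unit": "AGE_COD", "sex": "GNDR_COD"},
        "drug": {"case_key": "ISR", "role_code": "ROLE_COD", "drug_name": "DRUGNAME"},
        "reac": {"case_key": "ISR", "pt": "PT"},
    },
    "modern": {
        "demo": {"case_key": "primaryid", "case_id": "caseid", "version": "caseversion",
                 "age": "age", "age_unit": "age_cod", "sex": "sex"},
        "drug": {"case_key": "primaryid", "case_id": "caseid",
                 "role_code": "role_cod", "drug_name": "drugname"},
        "reac": {"case_key": "primaryid", "case_id": "caseid", "pt": "pt"},
    },
}


def normalize_pt(raw: str) -> str:
    """Canonical comparison key for a MedDRA preferred-term string.

    Trims, collapses internal whitespace runs, and case-folds, so
    ' Menstruation   delayed ' and 'MENSTRUATION DELAYED' share one key.
    """
    key = " ".join(str(raw).split()).casefold()
    if not key:
        raise ValueError("empty preferred-term string after trimming")
    return key


def display_pt(raw: str) -> str:
    """Display form: trimmed and whitespace-collapsed, case preserved."""
    return " ".join(str(raw).split())


@dataclass(frozen=True, slots=True)
class DrugRow:
    case_key: str
    case_id: str
    drug_name: str
    role_code: str


@dataclass(frozen=True, slots=True)
class ReactionRow:
    case_key: str
    pt: str        # display form
    pt_key: str    # canonical comparison key


@dataclass
class RejectsReport:
    """Rows that could not be parsed, plus data-quality flags."""

    max_examples: int = 10
    counts: dict[str, int] = field(default_factory=dict)
    examples: dict[str, list[str]] = field(default_factory=dict)
    replacement_characters: int = 0
    unrecognized_role_codes: int = 0
    orphaned_reaction_keys: int = 0

    def add(self, kind: str, line: str) -> None:
        self.counts[kind] = self.counts.get(kind, 0) + 1
        bucket = self.examples.setdefault(kind, [])
        if len(bucket) < self.max_examples:
            bucket.append(line)

    @property
    def total_rejected(self) -> int:
        return sum(self.counts.values())

    def to_text(self) -> str:
        lines = [f"rejected rows: {self.total_rejected}"]
        for kind in sorted(self.counts):
            lines.append(f"  {kind}: {self.counts[kind]}")
            for ex in self.examples.get(kind, []):
                lines.append(f"    | {ex}")
        lines.append(f"replacement characters: {self.replacement_characters}")
        lines.append(f"unrecognized role codes: {self.unrecognized_role_codes}")
        lines.append(f"orphaned reaction case keys: {self.orphaned_reaction_keys}")
        return "\n".join(lines)


@dataclass
class QuarterBundle:
    """One parsed quarter, normalised to logical column names.

    ``demo``, ``drugs`` and ``reactions`` are DataFrames with string
    dtype: demo has case_key/case_id/version (version numeric), drugs has
    case_key/case_id/drug_name/role_code/role_known, reactions has
    case_key/case_id/pt/pt_key.
    """

    quarter: str
    dialect: str
    demo: pd.DataFrame
    drugs: pd.DataFrame
    reactions: pd.DataFrame
    rejects: RejectsReport

    def iter_drug_rows(self) -> Iterator[DrugRow]:
        for row in self.drugs.itertuples(index=False):
            yield DrugRow(row.case_key, row.case_id, row.drug_name, row.role_code)

    def iter_reaction_rows(self) -> Iterator[ReactionRow]:
        for row in self.reactions.itertuples(index=False):
            yield ReactionRow(row.case_key, row.pt, row.pt_key)

    @property
    def n_case_versions(self) -> int:
        return self.demo["case_key"].nunique()


def _read_text(path: Path, rejects: RejectsReport) -> str:
    raw = path.read_bytes()
    try:
        text = raw.decode("utf-8")
    except UnicodeDecodeError:
        text = raw.decode("latin-1")
    rejects.replacement_characters += text.count("�")
    return text


def detect_dialect(header_columns: list[str]) -> str:
    """Decide the dialect from header column names."""
    cols = set(header_columns)
    if "ISR" in cols:
        return "legacy"
    if "primaryid" in cols:
        return "modern"
    raise ValueError(
        f"cannot detect dialect from header columns {header_columns}: "
        "expected an 'ISR' (legacy) or 'primaryid' (modern) column"
    )


def _parse_file(
    path: Path, kind: str, dialect: str, rejects: RejectsReport
) -> tuple[pd.DataFrame, str]:
    """Parse one file; returns (frame with logical columns, dialect used)."""
    text = _read_text(Path(path), rejects)
    if not text.strip():
        raise ValueError(f"{path}: empty file")

    def on_bad_line(fields: list[str]) -> None:
        rejects.add(f"{kind}: wrong field count", "$".join(map(str, fields)))
        return None

    frame = pd.read_csv(
        io.StringIO(text),
        sep="$",
        engine="python",
        dtype=str,
        on_bad_lines=on_bad_line,
        keep_default_na=False,
    )
    if dialect == "auto":
        dialect = detect_dialect(list(frame.columns))
    mapping = DIALECTS[dialect][kind]
    missing = [col for col in mapping.values() if col not in frame.columns]
    if missing:
        raise ValueError(
            f"{path}: missing mandatory column(s) {missing} for dialect "
            f"{dialect!r} ({kind} file)"
        )
    out = frame[[mapping[k] for k in mapping]].copy()
    out.columns = list(mapping)

    # Rows with an empty mandatory key field are rejected, not guessed at.
    # pt gets its own dedicated emptiness check after normalisation
    key_fields = [k for k in ("case_key", "case_id", "drug_name") if k in out.columns]
    bad = pd.Series(False, index=out.index)
    for k in key_fields:
        bad |= out[k].str.strip() == ""
    for _, row in out[bad].iterrows():
        rejects.add(f"{kind}: empty mandatory field", "$".join(map(str, row.tolist())))
    out = out[~bad].copy()
    return out, dialect


def read_quarter(
    demo_path: str | Path,
    drug_path: str | Path,
    reac_path: str | Path,
    dialect: str = "auto",
    quarter: str = "",
    max_examples: int = 10,
) -> QuarterBundle:
    """Read one quarter's DEMO/DRUG/REAC files into a QuarterBundle.

    ``dialect`` is 'legacy', 'modern' or 'auto' (detected from the DEMO
    header).  In the legacy layout the drug and reaction files carry no
    case-id column of their own; case ids are resolved through the demo
    file's ISR→CASE map, falling back to the case_key itself for keys the
    demo file does not list.
    """
    if dialect not in ("legacy", "modern", "auto"):
        raise ValueError(f"unknown dialect {dialect!r}")
    rejects = RejectsReport(max_examples=max_examples)

    demo, resolved = _parse_file(Path(demo_path), "demo", dialect, rejects)
    drugs, _ = _parse_file(Path(drug_path), "drug", resolved, rejects)
    reactions, _ = _parse_file(Path(reac_path), "reac", resolved, rejects)

    demo["version"] = pd.to_numeric(demo["version"], errors="coerce")
    bad_version = demo["version"].isna()
    for _, row in demo[bad_version].iterrows():
        rejects.add("demo: non-numeric version", str(row["case_key"]))
    demo = demo[~bad_version].copy()
    demo["version"] = demo["version"].astype(int)

    key_to_case = dict(zip(demo["case_key"], demo["case_id"]))
    if "case_id" not in drugs.columns:
        drugs["case_id"] = drugs["case_key"].map(key_to_case).fillna(drugs["case_key"])

    drugs["role_code"] = drugs["role_code"].str.strip().str.upper()
    drugs["role_known"] = drugs["role_code"].isin(KNOWN_ROLE_CODES)
    rejects.unrecognized_role_codes = int((~drugs["role_known"]).sum())

    reactions["pt"] = reactions["pt"].map(display_pt)
    empty_pt = reactions["pt"] == ""
    for _, row in reactions[empty_pt].iterrows():
        rejects.add("reac: empty preferred term", str(row["case_key"]))
    reactions = reactions[~empty_pt].copy()
    reactions["pt_key"] = reactions["pt"].str.casefold()
    if "case_id" not in reactions.columns:
        reactions["case_id"] = reactions["case_key"].map(key_to_case).fillna(
            reactions["case_key"]
        )

    # Orphaned reactions (case_key absent from the drug file) are kept but
    # counted, so total-count semantics stay explicit downstream.
    drug_keys = set(drugs["case_key"])
    rejects.orphaned_reaction_keys = int(
        (~reactions["case_key"].isin(drug_keys)).sum()
    )

    return QuarterBundle(
        quarter=quarter,
        dialect=resolved,
        demo=demo.reset_index(drop=True),
        drugs=drugs.reset_index(drop=True),
        reactions=reactions.reset_index(drop=True),
        rejects=rejects,
    )
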