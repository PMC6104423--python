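"""Independent brute-force oracle for the analysis pipeline.

Re-derives the drug-query case set, deduplication, and 2×2 counts
straight from the raw "$"-delimited files with plain string handling —
no code shared with the package's parser or assembly modules — so that
pipeline outputs can be checked for exact agreement on small datasets.
"""

from __future__ import annotations

import math
from pathlib import Path


def _read_rows(path: Path) -> list[dict[str, str]]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    header = lines[0].split("$")
    rows = []
    for line in lines[1:]:
        fields = line.split("$")
        if len(fields) != len(header):
            continue  # malformed rows are out of scope for count oracles
        rows.append(dict(zip(header, fields)))
    return rows


def _norm_pt(raw: str) -> str:
    return " ".join(raw.split()).casefold()


def brute_counts(
    quarter_paths: list[tuple[Path, Path, Path]],
    query_names: list[str],
    roles_included: set[str] = frozenset({"PS", "SS"}),
    match_mode: str = "substring",
):
    """Recount everything from scratch.

    Returns (n, query_case_ids, events_by_case, pt_counts) where
    pt_counts maps pt key -> (n_ij, n_i).
    """
    query_names = [q.casefold() for q in query_names]

    # case_key -> (case_id, version); per file dialect inferred from header
    versions: dict[str, tuple[str, int]] = {}
    drugs: dict[str, list[tuple[str, str]]] = {}
    events: dict[str, set[str]] = {}
    for demo_path, drug_path, reac_path in quarter_paths:
        for row in _read_rows(demo_path):
            key = row.get("ISR") or row.get("primaryid")
            cid = row.get("CASE") or row.get("caseid")
            ver = int(row.get("FOLL_SEQ") or row.get("caseversion"))
            versions[key] = (cid, ver)
        for row in _read_rows(drug_path):
            key = row.get("ISR") or row.get("primaryid")
            name = row.get("DRUGNAME") or row.get("drugname")
            role = (row.get("ROLE_COD") or row.get("role_cod")).strip().upper()
            drugs.setdefault(key, []).append((name, role))
        for row in _read_rows(reac_path):
            key = row.get("ISR") or row.get("primaryid")
            pt = _norm_pt(row.get("PT") or row.get("pt"))
            if pt:
                events.setdefault(key, set()).add(pt)

    # dedup: per case id keep the key with the highest (version, key)
    best: dict[str, tuple[int, str]] = {}
    for key, (cid, ver) in versions.items():
        cur = best.get(cid)
        if cur is None or (ver, key) > cur:
            best[cid] = (ver, key)
    latest_key = {cid: key for cid, (ver, key) in best.items()}

    def name_match(name: str) -> bool:
        hay = name.casefold()
        if match_mode == "exact":
            return any(hay.strip() == q for q in query_names)
        return any(q in hay for q in query_names)

    query_ids = set()
    for key, rows in drugs.items():
        cid = versions[key][0] if key in versions else key
        for name, role in rows:
            if role in roles_included and name_match(name):
                query_ids.add(cid)
                break

    events_by_case = {cid: events.get(key, set()) for cid, key in latest_key.items()}
    n = len(latest_key)
    pt_counts: dict[str, tuple[int, int]] = {}
    all_pts = set().union(*events_by_case.values()) if events_by_case else set()
    for pt in all_pts:
        n_i = sum(1 for ev in events_by_case.values() if pt in ev)
        n_ij = sum(
            1 for cid, ev in events_by_case.items() if pt in ev and cid in query_ids
        )
        pt_counts[pt] = (n_ij, n_i)
    return n, query_ids, events_by_case, pt_counts


def textbook_chi2(a: int, b: int, c: int, d: int, yates: bool) -> float:
    """Chi-squared via the expected-cell formula, independent of the
    cross-product shortcut used in the implementation."""
    n = a + b + c + d
    obs = [[a, b], [c, d]]
    rows = [a + b, c + d]
    cols = [a + c, b + d]
    stat = 0.0
    for i in range(2):
        for j in range(2):
            exp = rows[i] * cols[j] / n
            diff = abs(obs[i][j] - exp)
            if yates:
                diff = max(diff - 0.5, 0.0)
            stat += diff * diff / exp
    return stat


def textbook_metrics(a: float, b: float, c: float, d: float) -> dict[str, float]:
    """ROR/PRR/IC recomputed step by step from first principles."""
    z = 1.959963984540054
    ror = (a / c) / (b / d)  # odds of event given drug over odds given no drug
    se_ror = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    prr = (a / (a + b)) / (c / (c + d))
    se_prr = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    n = a + b + c + d
    expected = (a + c) * (a + b) / n
    ic = math.log((a + 0.5) / (expected + 0.5)) / math.log(2)
    ic_sd = 1 / (math.log(2) * math.sqrt(a + 0.5))
    return {
        "ror": ror,
        "ror_low": math.exp(math.log(ror) - z * se_ror),
        "ror_high": math.exp(math.log(ror) + z * se_ror),
        "prr": prr,
        "prr_low": math.exp(math.log(prr) - z * se_prr),
        "prr_high": math.exp(math.log(prr) + z * se_prr),
        "ic": ic,
        "ic_low": ic - 2 * ic_sd,
    }
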