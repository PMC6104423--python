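"""Synthetic quarterly spontaneous-report files with known ground truth.

Emulates a FAERS-like report stream: each quarter is a triple of
"$"-delimited DEMO/DRUG/REAC files containing multi-drug, multi-event
case reports with suspect-role codes, duplicate case versions, and
planted drug–event associations of configurable strength.

Generative model (per case, all draws independent across cases):

* each vocabulary drug is present with its marginal probability
  (independent Bernoulli per drug — not a simplex);
* each vocabulary event is present with its marginal probability,
  except that for a planted (drug, event, rate_ratio) pair the event
  probability is multiplied by ``rate_ratio`` when the drug is present
  (capped at 1; the cap is reported);
* every drug row carries a suspect-role code (PS/SS/C) drawn from a
  configurable distribution;
* a configurable fraction of cases is emitted twice under version 1 and
  version 2 of the same case id, identical except for a perturbed
  demographic field, so deduplication is observable downstream.

Because the model is fully factorised, every expected margin and joint
count — and the exact odds ratio of the role-filtered 2×2 table the
analysis pipeline will build — has a closed form (:func:`expected_counts`),
which is what makes the generator usable as a ground-truth oracle.

Cases that draw no vocabulary drug (or no vocabulary event) receive a
filler row (``OTHER-SUSPECT`` / ``Unevaluable event``) so that every case
id appears in all three files, without disturbing the vocabulary
marginals the closed forms rely on.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import yaml

__all__ = [
    "SynthConfig",
    "PairTruth",
    "GroundTruth",
    "QuarterFiles",
    "FILLER_DRUG",
    "FILLER_EVENT",
    "parse_quarter",
    "dialect_for_quarter",
    "quarter_file_names",
    "generate_quarter",
    "generate_dataset",
    "expected_counts",
    "true_odds_ratio",
    "simulate_pair_tables",
    "load_synth_config",
]

QUARTER_RE = re.compile(r"^(\d{4})Q([1-4])$")

#: Quarter after which the modern (primaryid/caseid) column layout applies.
LEGACY_LAST_QUARTER = (2012, 3)

FILLER_DRUG = "OTHER-SUSPECT"
FILLER_EVENT = "Unevaluable event"

ROLE_CODES = ("PS", "SS", "C")


def parse_quarter(label: str) -> tuple[int, int]:
    """Parse 'YYYYQn' into (year, quarter); reject anything else."""
    m = QUARTER_RE.match(label)
    if not m:
        raise ValueError(
            f"invalid quarter label {label!r}: expected 'YYYYQn' with n in 1-4"
        )
    return int(m.group(1)), int(m.group(2))


def dialect_for_quarter(label: str) -> str:
    """'legacy' (ISR-keyed) through 2012Q3, 'modern' from 2012Q4 on."""
    return "legacy" if parse_quarter(label) <= LEGACY_LAST_QUARTER else "modern"


def quarter_file_names(label: str) -> tuple[str, str, str]:
    """DEMO/DRUG/REAC file names for a quarter, e.g. DRUG12Q3.txt."""
    year, q = parse_quarter(label)
    suffix = f"{year % 100:02d}Q{q}"
    return (f"DEMO{suffix}.txt", f"DRUG{suffix}.txt", f"REAC{suffix}.txt")


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic report stream.

    drug_vocabulary / event_vocabulary are sequences of (name, marginal
    probability) pairs; presence is an independent Bernoulli per item.
    planted_associations are (drug, event, rate_ratio) triples; at most
    one planted drug per event so joint expectations stay in closed form.
    """

    n_cases_per_quarter: int
    quarters: tuple[str, ...]
    drug_vocabulary: tuple[tuple[str, float], ...]
    event_vocabulary: tuple[tuple[str, float], ...]
    planted_associations: tuple[tuple[str, str, float], ...] = ()
    duplicate_fraction: float = 0.0
    suspect_role_distribution: tuple[float, float, float] = (0.6, 0.3, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "quarters", tuple(self.quarters))
        object.__setattr__(
            self, "drug_vocabulary", tuple((n, float(p)) for n, p in self.drug_vocabulary)
        )
        object.__setattr__(
            self, "event_vocabulary", tuple((n, float(p)) for n, p in self.event_vocabulary)
        )
        object.__setattr__(
            self,
            "planted_associations",
            tuple((d, e, float(r)) for d, e, r in self.planted_associations),
        )
        object.__setattr__(
            self,
            "suspect_role_distribution",
            tuple(float(p) for p in self.suspect_role_distribution),
        )
        if self.n_cases_per_quarter <= 0:
            raise ValueError("n_cases_per_quarter must be positive")
        if not self.quarters:
            raise ValueError("at least one quarter is required")
        for q in self.quarters:
            parse_quarter(q)
        for name, p in self.drug_vocabulary + self.event_vocabulary:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"marginal probability for {name!r} outside [0,1]: {p}")
        if not 0.0 <= self.duplicate_fraction < 1.0:
            raise ValueError("duplicate_fraction must lie in [0, 1)")
        roles = self.suspect_role_distribution
        if len(roles) != 3 or any(p < 0 for p in roles) or abs(sum(roles) - 1.0) > 1e-9:
            raise ValueError(
                "suspect_role_distribution must be 3 nonnegative probabilities "
                "(PS, SS, C) summing to 1"
            )
        drug_names = {n for n, _ in self.drug_vocabulary}
        event_names = {n for n, _ in self.event_vocabulary}
        planted_events: set[str] = set()
        for d, e, r in self.planted_associations:
            if d not in drug_names:
                raise ValueError(f"planted drug {d!r} not in drug_vocabulary")
            if e not in event_names:
                raise ValueError(f"planted event {e!r} not in event_vocabulary")
            if r < 0:
                raise ValueError(f"rate_ratio must be >= 0 for ({d!r}, {e!r})")
            if e in planted_events:
                raise ValueError(
                    f"event {e!r} appears in more than one planted association; "
                    "only one planted drug per event is supported"
                )
            planted_events.add(e)

    @property
    def n_cases_total(self) -> int:
        return self.n_cases_per_quarter * len(self.quarters)

    def drug_probability(self, name: str) -> float:
        return dict(self.drug_vocabulary)[name]

    def event_probability(self, name: str) -> float:
        return dict(self.event_vocabulary)[name]


class QuarterFiles(NamedTuple):
    demo: Path
    drug: Path
    reac: Path


def _quarter_rng(config: SynthConfig, quarter_index: int) -> np.random.Generator:
    # Seeded per quarter so each quarter's draws are independent yet the
    # whole dataset is reproducible from the single config seed.
    return np.random.default_rng([config.seed, quarter_index])


def _draw_quarter(config: SynthConfig, rng: np.random.Generator):
    """Draw presence/role matrices for one quarter's cases."""
    n = config.n_cases_per_quarter
    drug_names = [d for d, _ in config.drug_vocabulary]
    drug_p = np.array([p for _, p in config.drug_vocabulary])
    event_names = [e for e, _ in config.event_vocabulary]
    event_p = np.array([p for _, p in config.event_vocabulary])

    drug_present = rng.random((n, len(drug_names))) < drug_p

    event_prob = np.broadcast_to(event_p, (n, len(event_names))).copy()
    drug_index = {d: i for i, d in enumerate(drug_names)}
    event_index = {e: i for i, e in enumerate(event_names)}
    for d, e, r in config.planted_associations:
        rows = drug_present[:, drug_index[d]]
        event_prob[rows, event_index[e]] = min(1.0, r * event_p[event_index[e]])
    event_present = rng.random((n, len(event_names))) < event_prob

    role_draws = rng.choice(
        len(ROLE_CODES),
        size=(n, len(drug_names) + 1),  # +1 slot for a possible filler drug
        p=np.asarray(config.suspect_role_distribution),
    )
    ages = rng.integers(15, 61, size=n)
    sexes = np.where(rng.random(n) < 0.9, "F", "M")

    dup_count = int(round(config.duplicate_fraction * n))
    dup_rows = set(rng.choice(n, size=dup_count, replace=False).tolist()) if dup_count else set()
    return drug_names, event_names, drug_present, event_present, role_draws, ages, sexes, dup_rows


def generate_quarter(
    config: SynthConfig, quarter: str, out_dir: str | Path
) -> QuarterFiles:
    """Write one quarter's DEMO/DRUG/REAC "$"-delimited files.

    The column layout follows the quarter's era: ISR/CASE keyed through
    2012Q3, primaryid/caseid keyed afterwards.  Every case id appears in
    all three files with at least one drug and one reaction row;
    duplicated cases are emitted under two version numbers.
    """
    parse_quarter(quarter)
    if quarter not in config.quarters:
        raise ValueError(
            f"quarter {quarter!r} not in config.quarters {list(config.quarters)}"
        )
    qindex = config.quarters.index(quarter)
    rng = _quarter_rng(config, qindex)
    (drug_names, event_names, drug_present, event_present,
     role_draws, ages, sexes, dup_rows) = _draw_quarter(config, rng)

    dialect = dialect_for_quarter(quarter)
    demo_name, drug_name_file, reac_name = quarter_file_names(quarter)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    demo_lines: list[str] = []
    drug_lines: list[str] = []
    reac_lines: list[str] = []
    if dialect == "legacy":
        demo_lines.append("ISR$CASE$FOLL_SEQ$AGE$AGE_COD$GNDR_COD")
        drug_lines.append("ISR$DRUG_SEQ$ROLE_COD$DRUGNAME")
        reac_lines.append("ISR$PT")
    else:
        demo_lines.append("primaryid$caseid$caseversion$age$age_cod$sex")
        drug_lines.append("primaryid$caseid$drug_seq$role_cod$drugname")
        reac_lines.append("primaryid$caseid$pt")

    n = config.n_cases_per_quarter
    for i in range(n):
        case_id = (qindex + 1) * 1_000_000 + i
        versions = (1, 2) if i in dup_rows else (1,)
        case_drugs: list[tuple[str, str]] = []
        for k, dname in enumerate(drug_names):
            if drug_present[i, k]:
                case_drugs.append((dname, ROLE_CODES[role_draws[i, k]]))
        if not case_drugs:
            case_drugs.append((FILLER_DRUG, ROLE_CODES[role_draws[i, -1]]))
        case_events = [event_names[k] for k in range(len(event_names)) if event_present[i, k]]
        if not case_events:
            case_events.append(FILLER_EVENT)

        for version in versions:
            case_key = case_id * 10 + version
            age = int(ages[i]) + (version - 1)  # duplicates differ only here
            if dialect == "legacy":
                demo_lines.append(f"{case_key}${case_id}${version}${age}$YR${sexes[i]}")
                for seq, (dname, role) in enumerate(case_drugs, start=1):
                    drug_lines.append(f"{case_key}${seq}${role}${dname}")
                for pt in case_events:
                    reac_lines.append(f"{case_key}${pt}")
            else:
                demo_lines.append(
                    f"{case_key}${case_id}${version}${age}$YR${sexes[i]}"
                )
                for seq, (dname, role) in enumerate(case_drugs, start=1):
                    drug_lines.append(f"{case_key}${case_id}${seq}${role}${dname}")
                for pt in case_events:
                    reac_lines.append(f"{case_key}${case_id}${pt}")

    paths = QuarterFiles(
        demo=out_dir / demo_name, drug=out_dir / drug_name_file, reac=out_dir / reac_name
    )
    paths.demo.write_text("\n".join(demo_lines) + "\n", encoding="utf-8")
    paths.drug.write_text("\n".join(drug_lines) + "\n", encoding="utf-8")
    paths.reac.write_text("\n".join(reac_lines) + "\n", encoding="utf-8")
    return paths


def generate_dataset(config: SynthConfig, out_dir: str | Path) -> list[QuarterFiles]:
    """Write every configured quarter plus a ground-truth sidecar file."""
    out_dir = Path(out_dir)
    files = [generate_quarter(config, q, out_dir) for q in config.quarters]
    lines = ["drug\tevent\trate_ratio"]
    for d, e, r in config.planted_associations:
        lines.append(f"{d}\t{e}\t{r:g}")
    (out_dir / "ground_truth.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
    return files


# ---------------------------------------------------------------------------
# Closed-form expectations (the oracle side of the generator)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairTruth:
    """Closed-form truth for one (drug, event) pair under a config."""

    drug: str
    event: str
    rate_ratio: float
    e_nij: float
    e_ni: float
    e_nj: float
    n: int
    odds_ratio: float


@dataclass(frozen=True)
class GroundTruth:
    pairs: Mapping[tuple[str, str], PairTruth]
    n: int

    def __getitem__(self, key: tuple[str, str]) -> PairTruth:
        return self.pairs[key]


def _event_marginal(config: SynthConfig, event: str) -> float:
    """P(event) accounting for a planting on this event, if any."""
    p_e = config.event_probability(event)
    for d, e, r in config.planted_associations:
        if e == event:
            p_d = config.drug_probability(d)
            q = r * p_e  # validated <= 1 by expected_counts
            return p_d * q + (1.0 - p_d) * p_e
    return p_e


def true_odds_ratio(
    p_drug: float,
    p_event: float,
    rate_ratio: float,
    p_role_included: float = 1.0,
) -> float:
    """Exact odds ratio of the role-filtered 2×2 table under the model.

    ``p_role_included`` is the probability that a drug row's role code
    falls in the analysis's included set (e.g. PS+SS).  Cases that carry
    the drug under an excluded role keep the elevated event probability
    but count in the comparator column, which dilutes the observable
    odds ratio below the planted rate ratio; this function gives the
    value the ROR actually estimates.
    """
    q1 = min(1.0, rate_ratio * p_event)
    p_in = p_drug * p_role_included
    if p_in >= 1.0:
        raise ValueError("comparator column is empty: p_drug * p_role_included >= 1")
    q0 = (p_drug * (1.0 - p_role_included) * q1 + (1.0 - p_drug) * p_event) / (1.0 - p_in)
    if q1 >= 1.0 or q0 <= 0.0 or q0 >= 1.0:
        raise ValueError("odds ratio undefined for degenerate probabilities")
    return (q1 / (1.0 - q1)) / (q0 / (1.0 - q0))


def expected_counts(
    config: SynthConfig, roles_included: Sequence[str] | None = None
) -> GroundTruth:
    """Closed-form E[Nij], E[Ni], E[Nj] for every vocabulary pair.

    With ``roles_included`` given (a subset of PS/SS/C), the drug margin
    and joint count are those of the role-filtered analysis; the event
    margin is unaffected.  A planted rate_ratio that would push a
    conditional event probability past 1 is rejected.
    """
    for d, e, r in config.planted_associations:
        if r * config.event_probability(e) > 1.0 + 1e-12:
            raise ValueError(
                f"planted association ({d!r}, {e!r}, rate_ratio={r}) makes the "
                "conditional event probability exceed 1"
            )
    if roles_included is None:
        p_incl = 1.0
    else:
        role_p = dict(zip(ROLE_CODES, config.suspect_role_distribution))
        unknown = set(roles_included) - set(ROLE_CODES)
        if unknown:
            raise ValueError(f"unknown role codes {sorted(unknown)}")
        p_incl = sum(role_p[r] for r in set(roles_included))

    n = config.n_cases_total
    planted = {(d, e): r for d, e, r in config.planted_associations}
    pairs: dict[tuple[str, str], PairTruth] = {}
    for d, p_d in config.drug_vocabulary:
        for e, p_e in config.event_vocabulary:
            rr = planted.get((d, e), 1.0)
            if (d, e) in planted:
                q1 = min(1.0, rr * p_e)
                e_nij = n * p_d * p_incl * q1
                e_ni = n * (p_d * q1 + (1.0 - p_d) * p_e)
                odds = true_odds_ratio(p_d, p_e, rr, p_incl) if 0 < p_e < 1 and 0 < p_d < 1 else float("nan")
            else:
                # The drug is independent of the event even when the event is
                # planted with a *different* drug; only the marginal changes.
                p_event_marg = _event_marginal(config, e)
                e_nij = n * p_d * p_incl * p_event_marg
                e_ni = n * p_event_marg
                odds = 1.0
            e_nj = n * p_d * p_incl
            pairs[(d, e)] = PairTruth(
                drug=d, event=e, rate_ratio=rr,
                e_nij=e_nij, e_ni=e_ni, e_nj=e_nj, n=n, odds_ratio=odds,
            )
    return GroundTruth(pairs=pairs, n=n)


def simulate_pair_tables(
    n: int,
    p_drug: float,
    p_event: float,
    rate_ratio: float,
    rng: np.random.Generator,
    p_role_included: float = 1.0,
    size: int = 1,
) -> np.ndarray:
    """Draw 2×2 tables for one drug–event pair directly at count level.

    Samples from exactly the same generative law as the file-level
    generator (drug presence, elevated event probability, role filter)
    but skips report assembly, so thousands of large replicates are cheap.
    Returns an integer array of shape (size, 4) with columns a, b, c, d.
    """
    q1 = min(1.0, rate_ratio * p_event)
    n_drug = rng.binomial(n, p_drug, size=size)
    ev_with_drug = rng.binomial(n_drug, q1)
    ev_without = rng.binomial(n - n_drug, p_event)
    incl_ev = rng.binomial(ev_with_drug, p_role_included)
    incl_noev = rng.binomial(n_drug - ev_with_drug, p_role_included)
    a = incl_ev
    n_j = incl_ev + incl_noev
    n_i = ev_with_drug + ev_without
    b = n_j - a
    c = n_i - a
    d = n - n_i - n_j + a
    return np.stack([a, b, c, d], axis=1)


def load_synth_config(path: str | Path) -> SynthConfig:
    """Load a SynthConfig from a YAML file (keys mirror the field names)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return SynthConfig(
        n_cases_per_quarter=int(raw["n_cases_per_quarter"]),
        quarters=tuple(raw["quarters"]),
        drug_vocabulary=tuple((d["name"], d["probability"]) for d in raw["drug_vocabulary"]),
        event_vocabulary=tuple((e["name"], e["probability"]) for e in raw["event_vocabulary"]),
        planted_associations=tuple(
            (a["drug"], a["event"], a["rate_ratio"])
            for a in raw.get("planted_associations", [])
        ),
        duplicate_fraction=float(raw.get("duplicate_fraction", 0.0)),
        suspect_role_distribution=tuple(
            raw.get("suspect_role_distribution", (0.6, 0.3, 0.1))
        ),
        seed=int(raw.get("seed", 0)),
    )
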