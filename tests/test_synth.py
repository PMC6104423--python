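"""Tests for the synthetic quarterly report generator and its oracle."""

import hashlib
import math
from pathlib import Path

import numpy as np
import pytest
from scipy.stats import binom

from pvsignal.synth import (
    FILLER_DRUG,
    SynthConfig,
    dialect_for_quarter,
    expected_counts,
    generate_dataset,
    generate_quarter,
    parse_quarter,
    quarter_file_names,
    simulate_pair_tables,
    true_odds_ratio,
)

from conftest import small_config


def _file_hashes(paths):
    return [hashlib.sha256(Path(p).read_bytes()).hexdigest() for p in paths]


def _case_column(path: Path, column: str) -> list[str]:
    lines = path.read_text().splitlines()
    header = lines[0].split("$")
    idx = header.index(column)
    return [line.split("$")[idx] for line in lines[1:]]


class TestQuarterLabels:
    def test_parse_and_era(self):
        assert parse_quarter("2012Q3") == (2012, 3)
        assert dialect_for_quarter("2012Q3") == "legacy"
        assert dialect_for_quarter("2012Q4") == "modern"
        assert quarter_file_names("2012Q3") == ("DEMO12Q3.txt", "DRUG12Q3.txt", "REAC12Q3.txt")

    @pytest.mark.parametrize("label", ["2012q3", "12Q3", "2012Q5", "2012-Q1", ""])
    def test_invalid_labels_rejected_with_expected_pattern(self, label):
        with pytest.raises(ValueError, match="YYYYQn"):
            parse_quarter(label)

    def test_quarter_outside_config_rejected(self, tmp_path):
        config = small_config()
        with pytest.raises(ValueError, match="not in config.quarters"):
            generate_quarter(config, "1999Q1", tmp_path)


class TestGeneration:
    def test_same_seed_and_config_byte_identical(self, tmp_path):
        config = small_config(n_cases_per_quarter=300)
        files_a = generate_dataset(config, tmp_path / "a")
        files_b = generate_dataset(config, tmp_path / "b")
        for qa, qb in zip(files_a, files_b):
            assert _file_hashes(qa) == _file_hashes(qb)

    def test_different_seed_changes_output(self, tmp_path):
        a = generate_quarter(small_config(n_cases_per_quarter=300), "2012Q2", tmp_path / "a")
        b = generate_quarter(
            small_config(n_cases_per_quarter=300, seed=1), "2012Q2", tmp_path / "b"
        )
        assert _file_hashes(a) != _file_hashes(b)

    def test_no_duplication_gives_exact_case_count(self, tmp_path):
        config = small_config(
            n_cases_per_quarter=100, duplicate_fraction=0.0, quarters=("2010Q1",)
        )
        files = generate_quarter(config, "2010Q1", tmp_path)
        for path, col in ((files.demo, "CASE"), (files.drug, "ISR"), (files.reac, "ISR")):
            values = _case_column(path, col)
            if col == "CASE":
                assert len(set(values)) == len(values) == 100
            else:
                assert len(set(values)) == 100

    def test_duplicate_fraction_emits_second_versions(self, tmp_path):
        config = small_config(
            n_cases_per_quarter=200, duplicate_fraction=0.25, quarters=("2014Q1",)
        )
        files = generate_quarter(config, "2014Q1", tmp_path)
        case_ids = _case_column(files.demo, "caseid")
        versions = _case_column(files.demo, "caseversion")
        assert len(set(case_ids)) == 200
        assert len(case_ids) == 250  # 50 cases have a second version
        assert versions.count("2") == 50

    def test_every_case_has_drug_and_reaction_rows(self, tmp_path):
        config = small_config(n_cases_per_quarter=150, quarters=("2011Q2",))
        files = generate_quarter(config, "2011Q2", tmp_path)
        demo_keys = set(_case_column(files.demo, "ISR"))
        assert demo_keys == set(_case_column(files.drug, "ISR"))
        assert demo_keys == set(_case_column(files.reac, "ISR"))

    def test_degenerate_certainty_case(self, tmp_path):
        config = SynthConfig(
            n_cases_per_quarter=50,
            quarters=("2013Q1",),
            drug_vocabulary=(("DRUGX", 1.0),),
            event_vocabulary=(("Eventy", 1.0),),
            seed=3,
        )
        files = generate_quarter(config, "2013Q1", tmp_path)
        drugs = _case_column(files.drug, "drugname")
        events = _case_column(files.reac, "pt")
        assert drugs.count("DRUGX") == 50 and FILLER_DRUG not in drugs
        assert events.count("Eventy") == 50

    def test_planted_joint_count_matches_expectation(self, tmp_path):
        """Empirical Nij within 3 Poisson SD of the closed-form E[Nij]."""
        config = SynthConfig(
            n_cases_per_quarter=50_000,
            quarters=("2011Q1",),
            drug_vocabulary=(("DRUGX", 0.1),),
            event_vocabulary=(("Eventy", 0.05),),
            planted_associations=(("DRUGX", "Eventy", 4.0),),
            seed=5,
        )
        files = generate_quarter(config, "2011Q1", tmp_path)
        drug_keys = set(_case_column(files.drug, "ISR")) - {
            k for k, n in zip(_case_column(files.drug, "ISR"),
                              _case_column(files.drug, "DRUGNAME"))
            if n != "DRUGX"
        }
        event_keys = {
            k for k, p in zip(_case_column(files.reac, "ISR"),
                              _case_column(files.reac, "PT"))
            if p == "Eventy"
        }
        nij = len(drug_keys & event_keys)
        e_nij = expected_counts(config)[("DRUGX", "Eventy")].e_nij
        assert e_nij == pytest.approx(50_000 * 0.1 * 0.2)
        assert abs(nij - e_nij) <= 3 * math.sqrt(e_nij)

    def test_ground_truth_sidecar_written(self, dataset):
        config, out, _ = dataset
        sidecar = (out / "ground_truth.txt").read_text().splitlines()
        assert sidecar[0] == "drug\tevent\trate_ratio"
        assert sidecar[1].split("\t")[0] == "LEVONORGESTREL"


class TestConfigValidation:
    @pytest.mark.parametrize(
        "overrides, message",
        [
            (dict(duplicate_fraction=1.0), "duplicate_fraction"),
            (dict(n_cases_per_quarter=0), "positive"),
            (dict(suspect_role_distribution=(0.5, 0.5, 0.5)), "summing to 1"),
            (dict(drug_vocabulary=(("X", 1.2),)), "outside"),
            (dict(planted_associations=(("NOPE", "Headache", 2.0),)), "not in drug_vocabulary"),
            (dict(planted_associations=(("IBUPROFEN", "Headache", -1.0),)), ">= 0"),
        ],
    )
    def test_bad_configs_rejected(self, overrides, message):
        with pytest.raises(ValueError, match=message):
            small_config(**overrides)

    def test_two_plantings_on_one_event_rejected(self):
        with pytest.raises(ValueError, match="more than one planted association"):
            small_config(
                planted_associations=(
                    ("LEVONORGESTREL", "Headache", 2.0),
                    ("IBUPROFEN", "Headache", 3.0),
                )
            )


class TestExpectedCounts:
    def _pair_config(self, rate_ratio):
        return SynthConfig(
            n_cases_per_quarter=10_000,
            quarters=("2010Q1",),
            drug_vocabulary=(("DRUGX", 0.1),),
            event_vocabulary=(("Eventy", 0.05),),
            planted_associations=(
                (("DRUGX", "Eventy", rate_ratio),) if rate_ratio != 1 else ()
            ),
            seed=0,
        )

    @pytest.mark.parametrize("rate_ratio, e_nij", [(1.0, 50.0), (4.0, 200.0), (0.0, 0.0)])
    def test_closed_form_joint_expectations(self, rate_ratio, e_nij):
        truth = expected_counts(self._pair_config(rate_ratio))
        pair = truth[("DRUGX", "Eventy")]
        assert pair.e_nij == pytest.approx(e_nij)
        assert pair.e_nj == pytest.approx(1000.0)
        assert pair.e_nij <= min(pair.e_ni, pair.e_nj) + 1e-9 <= truth.n + 1e-9

    def test_impossible_conditional_probability_rejected(self):
        config = self._pair_config(25.0)  # 25 * 0.05 > 1
        with pytest.raises(ValueError, match="DRUGX"):
            expected_counts(config)

    def test_role_filter_scales_drug_margin_only(self):
        config = small_config()
        full = expected_counts(config)
        filtered = expected_counts(config, roles_included=("PS", "SS"))
        pair = ("LEVONORGESTREL", "Menstruation delayed")
        assert filtered[pair].e_nj == pytest.approx(0.9 * full[pair].e_nj)
        assert filtered[pair].e_nij == pytest.approx(0.9 * full[pair].e_nij)
        assert filtered[pair].e_ni == pytest.approx(full[pair].e_ni)

    def test_unplanted_pair_with_planted_event_keeps_unit_odds(self):
        truth = expected_counts(small_config())
        assert truth[("IBUPROFEN", "Menstruation delayed")].odds_ratio == pytest.approx(1.0)


class TestMarginalCalibration:
    def test_empirical_marginals_within_binomial_bands(self, tmp_path):
        """Pooled over 20 seeds, each marginal lies inside its 99.9% band."""
        n, seeds = 400, 20
        drug_hits = {"LEVONORGESTREL": 0, "IBUPROFEN": 0}
        event_hits = {"headache": 0, "nausea": 0}
        for seed in range(seeds):
            config = small_config(
                n_cases_per_quarter=n, quarters=("2013Q2",),
                duplicate_fraction=0.0, seed=seed,
            )
            files = generate_quarter(config, "2013Q2", tmp_path / str(seed))
            names = _case_column(files.drug, "drugname")
            keys = _case_column(files.drug, "primaryid")
            for d in drug_hits:
                drug_hits[d] += len({k for k, x in zip(keys, names) if x == d})
            pts = [p.casefold() for p in _case_column(files.reac, "pt")]
            rkeys = _case_column(files.reac, "primaryid")
            for e in event_hits:
                event_hits[e] += len({k for k, x in zip(rkeys, pts) if x == e})
        total = n * seeds
        config = small_config()
        for name, hits in drug_hits.items():
            p = dict(config.drug_vocabulary)[name]
            lo, hi = binom.ppf([0.0005, 0.9995], total, p)
            assert lo <= hits <= hi, name
        for name, hits in event_hits.items():
            p = dict((k.casefold(), v) for k, v in config.event_vocabulary)[name]
            lo, hi = binom.ppf([0.0005, 0.9995], total, p)
            assert lo <= hits <= hi, name


class TestCountLevelSimulator:
    def test_matches_closed_form_expectations(self):
        rng = np.random.default_rng(9)
        tables = simulate_pair_tables(
            n=20_000, p_drug=0.1, p_event=0.01, rate_ratio=4.0, rng=rng,
            p_role_included=0.9, size=2000,
        )
        a = tables[:, 0]
        e_a = 20_000 * 0.1 * 0.9 * 0.04
        assert a.mean() == pytest.approx(e_a, rel=0.05)
        n_check = tables.sum(axis=1)
        assert (n_check == 20_000).all()

    def test_true_odds_ratio_reduces_to_rate_ratio_without_filtering(self):
        # with full inclusion and a rare event the OR barely exceeds the RR
        odds = true_odds_ratio(0.1, 0.001, 4.0, p_role_included=1.0)
        assert odds == pytest.approx(4.0, rel=0.01)
        assert odds > 4.0
        assert true_odds_ratio(0.3, 0.05, 1.0, 0.9) == pytest.approx(1.0)
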