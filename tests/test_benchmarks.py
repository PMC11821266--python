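"""Benchmark split construction: clustering, filters, validators."""

import numpy as np
import pytest

import sfprobe as sp
from conftest import fake_record

KEY_A = "AAAAAAAAAAAAAA-AAAAAAAAAA-N"
KEY_B = "BBBBBBBBBBBBBB-BBBBBBBBBB-N"
KEY_C = "CCCCCCCCCCCCCC-CCCCCCCCCC-N"


class TestClusterByInchikey:
    def test_pairs_cluster_singletons_reported(self):
        recs = [
            fake_record("c1", KEY_A, 5.0),
            fake_record("c2", KEY_A, 8.0),
            fake_record("c3", KEY_B, 6.0),
        ]
        clusters, singles = sp.cluster_by_inchikey(recs)
        assert len(clusters) == 1
        assert clusters[0].inchikey == KEY_A and len(clusters[0]) == 2
        assert singles == ["c3"]

    def test_all_unique_yields_no_clusters(self):
        recs = [fake_record(f"c{i}", k, 6.0) for i, k in enumerate([KEY_A, KEY_B, KEY_C])]
        clusters, singles = sp.cluster_by_inchikey(recs)
        assert clusters == [] and len(singles) == 3

    def test_planted_duplicates_recovered(self):
        cfg = sp.GeneratorConfig(n_complexes=40, ligand_library_size=10, seed=13)
        records, gt = sp.generate_records(cfg)
        clusters, singles = sp.cluster_by_inchikey(records)
        want = {}
        for cid, info in gt.complexes.items():
            want.setdefault(info["inchikey"], []).append(cid)
        want_clusters = {k: sorted(v) for k, v in want.items() if len(v) >= 2}
        got = {c.inchikey: sorted(c.member_ids) for c in clusters}
        assert got == want_clusters


class TestZeroLigandBiasFilter:
    def test_mean_and_variance_rules(self):
        recs = [
            fake_record("a1", KEY_A, 5.0), fake_record("a2", KEY_A, 8.0),   # mean 6.5, var 4.5 -> keep
            fake_record("b1", KEY_B, 6.4), fake_record("b2", KEY_B, 6.6),   # var 0.02 -> reject
            fake_record("c1", KEY_C, 8.0), fake_record("c2", KEY_C, 9.0),   # mean 8.5 -> reject
        ]
        split = sp.zero_ligand_bias_filter(recs)
        assert split.test_ids == {"a1", "a2"}
        assert split.train_ids == {"b1", "b2", "c1", "c2"}

    def test_mean_endpoints_inclusive_variance_strict(self):
        at_edge = [fake_record("e1", KEY_A, 4.0), fake_record("e2", KEY_A, 8.0)]  # mean 6.0 inclusive
        split = sp.zero_ligand_bias_filter(at_edge)
        assert split.test_ids == {"e1", "e2"}
        # sample variance exactly 1 must be rejected (strictly greater rule);
        # {5.5, 6.5, 7.5} has mean 6.5 and sample variance exactly 1.0
        exact_var1 = [
            fake_record("v1", KEY_B, 5.5),
            fake_record("v2", KEY_B, 6.5),
            fake_record("v3", KEY_B, 7.5),
        ]
        split2 = sp.zero_ligand_bias_filter(exact_var1)
        assert split2.test_ids == set()

    def test_train_side_ligand_leakage_excluded(self):
        recs = [
            fake_record("a1", KEY_A, 5.0), fake_record("a2", KEY_A, 8.0),
            fake_record("a3", KEY_A, 6.2),  # same ligand, would leak into train
            fake_record("b1", KEY_B, 7.0),
        ]
        split = sp.zero_ligand_bias_filter(recs)
        assert "a3" in split.test_ids or "a3" in split.excluded_ids
        assert "a3" not in split.train_ids

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_brute_force_on_random_label_tables(self, trial):
        """Group-by/filter reimplementation agrees on randomized pk tables."""
        rng = np.random.default_rng(trial)
        keys = [f"{chr(65 + i) * 14}-{chr(65 + i) * 10}-N" for i in range(8)]
        recs = []
        for i in range(60):
            k = keys[int(rng.integers(0, len(keys)))]
            recs.append(fake_record(f"r{i}", k, float(rng.uniform(3, 10))))
        split = sp.zero_ligand_bias_filter(recs)
        # oracle
        from collections import defaultdict

        groups = defaultdict(list)
        for r in recs:
            groups[r.ligand.inchikey].append(r)
        expect_test = set()
        for k, members in groups.items():
            if len(members) < 2:
                continue
            pks = np.array([m.label.pk for m in members])
            if 6.0 <= pks.mean() <= 7.0 and pks.var(ddof=1) > 1.0:
                expect_test.update(m.complex_id for m in members)
        assert split.test_ids == expect_test
        test_keys = {r.ligand.inchikey for r in recs if r.complex_id in expect_test}
        for r in recs:
            if r.complex_id not in expect_test and r.ligand.inchikey in test_keys:
                assert r.complex_id in split.excluded_ids

    def test_no_key_in_both_train_and_test(self):
        rng = np.random.default_rng(7)
        keys = [KEY_A, KEY_B, KEY_C]
        recs = [
            fake_record(f"r{i}", keys[int(rng.integers(0, 3))], float(rng.uniform(4, 9)))
            for i in range(30)
        ]
        split = sp.zero_ligand_bias_filter(recs)
        by_id = {r.complex_id: r for r in recs}
        train_keys = {by_id[i].ligand.inchikey for i in split.train_ids}
        test_keys = {by_id[i].ligand.inchikey for i in split.test_ids}
        assert not (train_keys & test_keys)


class TestPeptideHoldout:
    def test_substring_rule(self):
        recs = [
            fake_record("p1", KEY_A, 6, code="3MER"),
            fake_record("p2", KEY_B, 6, code="ATP"),
            fake_record("p3", KEY_C, 6, code="MER"),
        ]
        split = sp.peptide_holdout(recs)
        assert split.test_ids == {"p1", "p3"}
        assert split.train_ids == {"p2"}

    def test_case_insensitive(self):
        recs = [fake_record("p1", KEY_A, 6, code="mer-like"), fake_record("p2", KEY_B, 6, code="abc")]
        split = sp.peptide_holdout(recs)
        assert split.test_ids == {"p1"}

    def test_no_match_warns_empty_test(self):
        recs = [fake_record("p1", KEY_A, 6, code="ATP")]
        with pytest.warns(UserWarning):
            split = sp.peptide_holdout(recs)
        assert split.test_ids == set()


class TestTimeSplit:
    def test_cutoff_year_inclusive(self):
        recs = [fake_record(f"y{y}", KEY_A, 6, year=y) for y in (2018, 2019, 2020)]
        split = sp.time_split(recs, cutoff_year=2019)
        assert split.test_ids == {"y2019", "y2020"}
        assert split.train_ids == {"y2018"}

    def test_missing_year_in_neither_set(self):
        recs = [fake_record("a", KEY_A, 6, year=2015), fake_record("b", KEY_B, 6, year=None)]
        split = sp.time_split(recs)
        assert split.excluded_ids == {"b"}
        assert "b" not in split.train_ids | split.test_ids

    def test_all_precutoff_warns(self):
        recs = [fake_record("a", KEY_A, 6, year=2001)]
        with pytest.warns(UserWarning):
            split = sp.time_split(recs)
        assert split.test_ids == set()


class TestValidator:
    @pytest.mark.parametrize("trial", range(10))
    def test_all_three_builders_validate_on_random_fixtures(self, trial):
        rng = np.random.default_rng(200 + trial)
        keys = [f"{chr(65 + i) * 14}-{chr(65 + i) * 10}-N" for i in range(6)]
        codes = ["ATP", "1MER", "NAD", "2MER", "GLC"]
        recs = [
            fake_record(
                f"r{i}",
                keys[int(rng.integers(0, len(keys)))],
                float(rng.uniform(3, 10)),
                code=codes[int(rng.integers(0, len(codes)))],
                year=int(rng.integers(2010, 2023)) if rng.random() > 0.1 else None,
            )
            for i in range(50)
        ]
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for split in (
                sp.zero_ligand_bias_filter(recs),
                sp.peptide_holdout(recs),
                sp.time_split(recs),
            ):
                sp.validate_split(split, recs)

    def test_validator_catches_leak(self):
        recs = [fake_record("a", KEY_A, 6, year=2015), fake_record("b", KEY_B, 6, year=2020)]
        split = sp.time_split(recs)
        split.train_ids.add("b")
        split.test_ids.discard("b")
        with pytest.raises(AssertionError):
            sp.validate_split(split, recs)


def test_split_csv_roundtrip(tmp_path):
    recs = [fake_record(f"y{y}", KEY_A, 6, year=y) for y in (2018, 2019, 2020)]
    split = sp.time_split(recs)
    sp.benchmarks.write_split(split, tmp_path / "split.csv", tmp_path / "rule.json")
    import pandas as pd

    df = pd.read_csv(tmp_path / "split.csv")
    assert set(df["role"]) <= {"train", "test", "excluded"}
    assert len(df) == 3
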