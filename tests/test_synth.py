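"""Synthetic-data generator: determinism, ground-truth structure, round trips."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

import sfprobe as sp
from sfprobe.synth import ligand_effect_of, pocket_effect_of


def tree_hash(root):
    h = hashlib.sha256()
    for p in sorted(Path(root).rglob("*")):
        if p.is_file():
            h.update(str(p.relative_to(root)).encode())
            h.update(p.read_bytes())
    return h.hexdigest()


class TestLigandLibrary:
    def test_deterministic(self):
        a, _, _ = sp.generate_ligand_library(1, seed=7)
        b, _, _ = sp.generate_ligand_library(1, seed=7)
        assert a[0].inchikey == b[0].inchikey
        np.testing.assert_array_equal(a[0].coords, b[0].coords)

    def test_twenty_valid_molecules(self):
        ligands, effects, replaced = sp.generate_ligand_library(20, seed=1)
        assert len(ligands) == 20 and not replaced
        assert len({l.inchikey for l in ligands}) == 20
        assert all(len(l.inchikey) == 27 for l in ligands)

    def test_oversized_request_flagged(self):
        ligands, _, replaced = sp.generate_ligand_library(60, seed=2)
        assert len(ligands) == 60 and replaced

    def test_effect_tracks_molecular_size(self):
        ligands, effects, _ = sp.generate_ligand_library(40, seed=3)
        heavy = [l.mol.GetNumHeavyAtoms() for l in ligands]
        r = np.corrcoef(heavy, effects)[0, 1]
        assert abs(r) > 0.5  # by construction (size-derived effect)


class TestGeneratePocket:
    def test_requested_composition_recovered(self, small_library):
        ligands, _ = small_library
        comp = np.zeros(20, dtype=int)
        comp[7] = 3  # GLY only
        prot = sp.generate_pocket(comp, ligands[0].coords, seed=5)
        counts = sp.pocket_residue_counts(prot, ligands[0], 15.0).counts
        np.testing.assert_array_equal(counts[:20], comp)
        assert counts[20] == 0

    def test_distractors_outside_shell(self, small_library):
        ligands, _ = small_library
        comp = np.zeros(20, dtype=int)
        comp[[1, 4]] = [3, 2]
        prot = sp.generate_pocket(comp, ligands[0].coords, seed=6, n_distractors=4)
        assert sp.pocket_residue_counts(prot, ligands[0], 15.0).total() == 5
        assert sp.pocket_residue_counts(prot, ligands[0], 30.0).total() == 9

    def test_deterministic_pdb_text(self, tmp_path, small_library):
        ligands, _ = small_library
        comp = np.zeros(20, dtype=int)
        comp[0] = 4
        for name in ("a", "b"):
            prot = sp.generate_pocket(comp, ligands[0].coords, seed=11)
            sp.write_protein(prot, tmp_path / f"{name}.pdb")
        assert (tmp_path / "a.pdb").read_bytes() == (tmp_path / "b.pdb").read_bytes()


class TestGenerateDataset:
    def test_shared_ligand_identical_pk_when_ligand_only_noiseless(self):
        cfg = sp.GeneratorConfig(n_complexes=40, ligand_library_size=8,
                                 beta_pocket=0.0, noise_sd=0.0, seed=4)
        records, gt = sp.generate_records(cfg)
        by_key = {}
        for r in records:
            by_key.setdefault(r.ligand.inchikey, []).append(r.label.pk)
        shared = [v for v in by_key.values() if len(v) > 1]
        assert shared
        for pks in shared:
            assert max(pks) - min(pks) < 1e-12

    def test_alpha_zero_pk_varies_with_pocket_only(self):
        cfg = sp.GeneratorConfig(n_complexes=30, ligand_library_size=5,
                                 alpha_ligand=0.0, noise_sd=0.0, seed=5)
        records, gt = sp.generate_records(cfg)
        for cid, info in gt.complexes.items():
            assert info["pk"] == pytest.approx(
                cfg.base_pk + cfg.beta_pocket * info["pocket_effect"], abs=1e-12
            )

    def test_variance_decomposition(self):
        cfg = sp.GeneratorConfig(n_complexes=500, seed=6)
        records, gt = sp.generate_records(cfg)
        info = list(gt.complexes.values())
        pk = np.array([d["pk"] for d in info])
        le = np.array([d["ligand_effect"] for d in info])
        pe = np.array([d["pocket_effect"] for d in info])
        expected = (
            cfg.alpha_ligand**2 * le.var() + cfg.beta_pocket**2 * pe.var() + cfg.noise_sd**2
        )
        assert pk.var() == pytest.approx(expected, rel=0.2)

    def test_roundtrip_through_load_dataset(self, tmp_path):
        cfg = sp.GeneratorConfig(n_complexes=12, seed=7)
        out, gt = sp.generate_dataset(cfg, tmp_path / "ds")
        records, report = sp.load_dataset(out / "index.txt", out)
        assert len(records) == 12 and len(report) == 0
        for rec in records:
            assert rec.label.pk == pytest.approx(gt.pk_of(rec.complex_id), abs=1e-3)
            assert rec.ligand.inchikey == gt.complexes[rec.complex_id]["inchikey"]

    def test_byte_identical_fixture_trees(self, tmp_path):
        cfg = sp.GeneratorConfig(n_complexes=6, seed=8)
        sp.generate_dataset(cfg, tmp_path / "a")
        sp.generate_dataset(cfg, tmp_path / "b")
        assert tree_hash(tmp_path / "a") == tree_hash(tmp_path / "b")

    def test_rejects_empty_config(self):
        with pytest.raises(ValueError):
            sp.GeneratorConfig(n_complexes=0)


class TestZeroBiasTestbed:
    def test_filter_retains_exactly_planted_clusters(self):
        cfg = sp.GeneratorConfig(alpha_ligand=0.0, seed=9)
        records, gt = sp.generate_zero_bias_testbed(cfg, n_planted=5)
        split = sp.zero_ligand_bias_filter(records)
        planted_ids = set(sum(gt.plan["planted"].values(), []))
        assert split.test_ids == planted_ids

    def test_out_of_range_plants_excluded(self):
        cfg = sp.GeneratorConfig(alpha_ligand=0.0, seed=10)
        records, gt = sp.generate_zero_bias_testbed(cfg)
        split = sp.zero_ligand_bias_filter(records)
        decoy_ids = set(sum(gt.plan["decoy"].values(), []))
        assert not (split.test_ids & decoy_ids)

    def test_nonzero_alpha_rejected(self):
        cfg = sp.GeneratorConfig(alpha_ligand=1.0, seed=1)
        with pytest.raises(ValueError):
            sp.generate_zero_bias_testbed(cfg)

    def test_planted_statistics_satisfy_filter_rule(self):
        cfg = sp.GeneratorConfig(alpha_ligand=0.0, seed=12)
        records, gt = sp.generate_zero_bias_testbed(cfg)
        by_id = {r.complex_id: r for r in records}
        for key, ids in gt.plan["planted"].items():
            pks = np.array([by_id[i].label.pk for i in ids])
            assert 6.0 <= pks.mean() <= 7.0
            assert pks.var(ddof=1) > 1.0


class TestPoseDecoys:
    def test_zero_target_is_identity(self, small_library):
        ligands, _ = small_library
        ps = sp.generate_pose_decoys(ligands[0], [0.0], seed=1)
        assert ps.poses[0].rmsd_to_reference == 0.0
        np.testing.assert_array_equal(ps.poses[0].coords, ligands[0].heavy_coords())

    def test_targets_hit_within_tolerance(self, small_library):
        ligands, _ = small_library
        targets = [0.5, 1.5, 3.0, 5.0]
        ps = sp.generate_pose_decoys(ligands[1], targets, seed=2)
        for pose, t in zip(ps.poses, targets):
            realized = sp.rmsd(ps.reference_coords, pose.coords)
            assert realized == pytest.approx(t, abs=0.05)

    def test_full_ladder_fills_every_bin(self, small_library):
        ligands, _ = small_library
        mids = [(lo + hi) / 2 for lo, hi in sp.DEFAULT_RMSD_BINS]
        ps = sp.generate_pose_decoys(ligands[2], mids, seed=3)
        binning = sp.select_binned_poses(ps)
        assert all(pid is not None for pid in binning.selection.values())


def test_effect_functionals_are_fixed():
    """Effects depend only on identity/composition, not on random state."""
    ligands, _, _ = sp.generate_ligand_library(3, seed=0)
    assert ligand_effect_of(ligands[0].mol) == ligand_effect_of(ligands[0].mol)
    comp = np.zeros(20)
    comp[[3, 8]] = [10, 20]
    assert pocket_effect_of(comp) == pocket_effect_of(comp.copy())
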