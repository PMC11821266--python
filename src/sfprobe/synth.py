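"""Synthetic protein-ligand datasets with known ground-truth bias structure.

The generator emulates exactly the statistical structure the bias
baselines exploit, nothing more: every complex's label decomposes as

    pK = base + alpha * ligand_effect + beta * pocket_effect + noise

where ``ligand_effect`` is a fixed functional of ligand identity (a
size-like descriptor), ``pocket_effect`` is a fixed linear functional of
the pocket's residue composition, and noise is Gaussian in pK units.
Setting ``beta = 0`` gives a ligand-bias-only world, ``alpha = 0`` a
pocket-bias-only world, and both nonzero an additive world.

Pockets are geometric residue scatters, not folded proteins: rigid
five-atom residue templates placed at 5-12 A from the ligand centroid
(safely inside a 15 A pocket shell), with optional distractor residues
beyond 25 A.  Every in-scope computation depends only on residue
identity and atom distances, which scatters control exactly, so
pocket composition recovery by the featurizer is exact by construction.

Everything is deterministic from the seed, down to byte-identical
on-disk fixture trees, and datasets are written in the same on-disk
layout :func:`sfprobe.io.load_dataset` consumes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .featurize import STANDARD_AA, pocket_residue_counts
from .io import (
    AffinityLabel,
    ComplexRecord,
    LigandMolecule,
    ProteinStructure,
    ligand_from_mol,
    write_ligand_pose,
    write_protein,
)
from .perturb import Pose, PoseSet, rmsd

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "DRUGLIKE_SMILES",
    "generate_ligand_library",
    "generate_pocket",
    "generate_records",
    "generate_dataset",
    "generate_zero_bias_testbed",
    "generate_pose_decoys",
    "ligand_effect_of",
    "pocket_effect_of",
]

#: Curated drug-like small molecules (line notation), the ligand library.
DRUGLIKE_SMILES: tuple[str, ...] = (
    "CCO", "CC(=O)Oc1ccccc1C(=O)O", "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "CC(=O)Nc1ccc(O)cc1", "Cn1cnc2c1c(=O)n(C)c(=O)n2C", "c1ccccc1",
    "OC(=O)c1ccccc1", "Nc1ccc(cc1)S(N)(=O)=O", "CC(N)Cc1ccccc1",
    "CN1CCC[C@H]1c1cccnc1", "OCC(O)CO", "CC(C)(C)NCC(O)c1ccc(O)c(CO)c1",
    "CN(C)CCOC(c1ccccc1)c1ccccc1", "COc1ccc2cc(ccc2c1)C(C)C(=O)O",
    "Clc1ccccc1", "NCCc1ccc(O)c(O)c1", "OC(=O)CC(O)(CC(=O)O)C(=O)O",
    "CCN(CC)CCNC(=O)c1ccc(N)cc1", "CC12CCC3C(CCc4cc(O)ccc34)C1CCC2O",
    "CC(=O)NCCc1c[nH]c2ccc(OC)cc12", "NC(Cc1ccccc1)C(=O)O",
    "NC(CO)C(=O)O", "CSCCC(N)C(=O)O", "NC(Cc1c[nH]c2ccccc12)C(=O)O",
    "OC(=O)c1cc(O)c(O)c(O)c1", "COc1cc(C=CC(=O)O)ccc1O",
    "Oc1ccc(C=Cc2cc(O)cc(O)c2)cc1", "CN1C2CCC1CC(C2)OC(=O)C(CO)c1ccccc1",
    "CCOC(=O)c1ccc(N)cc1", "CC(C)NCC(O)COc1cccc2ccccc12",
    "OCC1OC(O)C(O)C(O)C1O", "NC1CCCCC1", "O=C(O)c1ccccc1O",
    "CN(C)c1ccc(cc1)C=O", "O=C1CCCCC1", "CC(C)=CCCC(C)=CCO",
    "Cc1ccc(cc1)S(=O)(=O)N", "OC(c1ccccc1)c1ccccc1",
    "CC(C)Cc1ccccc1", "CN1CCN(CC1)c1ccccc1",
)

# Fixed effect functionals (chosen once; roughly unit variance over the
# library / over randomly sampled pockets, so alpha and beta are
# comparable knobs in pK units).
_LIGAND_EFFECT_CENTER = 12.0
_LIGAND_EFFECT_SCALE = 4.0
_POCKET_EFFECT_SCALE = 23.0

# Kyte-Doolittle hydropathy, standardized over the 20-residue alphabet,
# used only as an arbitrary fixed weight vector over compositions.
_KD = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5, "MET": 1.9,
    "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8, "TRP": -0.9,
    "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5, "GLN": -3.5,
    "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}
_W = np.array([_KD[a] for a in STANDARD_AA], dtype=float)
_W = (_W - _W.mean()) / _W.std()

# Rigid 5-atom residue template (backbone-like), angstrom offsets from
# the residue anchor.  Geometry is schematic: only identity and distance
# matter to any in-scope computation.
_RES_TEMPLATE = np.array(
    [(-1.46, 0.0, 0.0), (0.0, 0.0, 0.0), (1.53, 0.0, 0.0),
     (2.15, 1.05, 0.0), (-0.50, 1.40, 0.0)]
)
_RES_ELEMENTS = ("N", "C", "C", "O", "C")


def ligand_effect_of(mol: Chem.Mol) -> float:
    """Fixed ligand-identity signal: standardized heavy-atom count."""
    return (mol.GetNumHeavyAtoms() - _LIGAND_EFFECT_CENTER) / _LIGAND_EFFECT_SCALE


def pocket_effect_of(composition: np.ndarray) -> float:
    """Fixed linear functional of a 20-vector residue composition."""
    composition = np.asarray(composition, dtype=float).reshape(-1)
    if composition.shape[0] == len(STANDARD_AA) + 1:
        composition = composition[: len(STANDARD_AA)]  # drop UNK bucket
    return float(_W @ composition) / _POCKET_EFFECT_SCALE


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic dataset.

    ``alpha_ligand`` and ``beta_pocket`` weight the two bias channels in
    pK units per unit effect; ``noise_sd`` is Gaussian label noise in pK
    units.  Defaults define the standard simulation conditions: 500
    complexes over a 40-molecule library (so ligands repeat across
    pockets), additive signal of comparable strength in both channels,
    and mild label noise.
    """

    n_complexes: int = 500
    ligand_library_size: int = 40
    duplicate_ligand_fraction: float = 0.3
    alpha_ligand: float = 1.0
    beta_pocket: float = 1.0
    noise_sd: float = 0.3
    base_pk: float = 6.5
    year_range: tuple[int, int] = (2010, 2022)
    peptide_code_fraction: float = 0.1
    n_distractor_range: tuple[int, int] = (0, 4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_complexes < 1:
            raise ValueError("n_complexes must be >= 1")
        if not (0.0 <= self.duplicate_ligand_fraction <= 1.0):
            raise ValueError("duplicate_ligand_fraction must be in [0, 1]")
        for v in (self.alpha_ligand, self.beta_pocket, self.noise_sd):
            if not math.isfinite(v):
                raise ValueError("effect weights and noise must be finite")


@dataclass
class GroundTruth:
    """Per-complex signal decomposition plus the generation plan."""

    config: dict
    complexes: dict[str, dict] = field(default_factory=dict)
    plan: dict = field(default_factory=dict)

    def pk_of(self, cid: str) -> float:
        return self.complexes[cid]["pk"]

    def to_json(self) -> str:
        return json.dumps(
            {"config": self.config, "complexes": self.complexes, "plan": self.plan},
            indent=1, sort_keys=True,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(config=d["config"], complexes=d["complexes"], plan=d.get("plan", {}))


def _embed_seed(seed: int, idx: int) -> int:
    return int((seed * 1_000_003 + idx * 7_919 + 17) % (2**31 - 1))


def generate_ligand_library(size: int, seed: int) -> tuple[list[LigandMolecule], list[float], bool]:
    """Drug-like molecules with deterministic 3D coordinates.

    Returns (ligands, ligand_effects, sampled_with_replacement).  When
    ``size`` exceeds the built-in library, molecules are reused (flagged
    by the third return value).  Coordinates come from a seeded distance-
    geometry embedding, so the same (size, seed) reproduces byte-identical
    molecules.
    """
    if size < 1:
        raise ValueError("library size must be >= 1")
    rng = np.random.default_rng(seed)
    n_base = len(DRUGLIKE_SMILES)
    replaced = size > n_base
    if replaced:
        order = list(rng.permutation(n_base)) + list(rng.integers(0, n_base, size - n_base))
    else:
        order = list(rng.permutation(n_base)[:size])
    ligands: list[LigandMolecule] = []
    effects: list[float] = []
    for i, smi_idx in enumerate(order):
        mol = Chem.MolFromSmiles(DRUGLIKE_SMILES[int(smi_idx)])
        params = AllChem.ETKDGv3()
        params.randomSeed = _embed_seed(seed, i)
        if AllChem.EmbedMolecule(mol, params) != 0:
            AllChem.Compute2DCoords(mol)  # planar fallback, still deterministic
        else:
            # make the realized stereochemistry explicit so identity is
            # stable across SDF write/read cycles
            Chem.AssignStereochemistryFrom3D(mol)
        code = f"L{int(smi_idx):02d}"
        ligands.append(ligand_from_mol(mol, code=code))
        effects.append(ligand_effect_of(mol))
    return ligands, effects, replaced


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def generate_pocket(
    composition: np.ndarray,
    ligand_coords: np.ndarray,
    seed: int,
    n_distractors: int = 0,
    threshold_A: float = 15.0,
) -> ProteinStructure:
    """Place rigid residue templates around a ligand.

    In-shell residues sit with every atom within ``threshold_A`` of some
    ligand atom (placed 5-12 A from the ligand centroid with a 1 A safety
    margin, verified per residue); distractor residues are verified to be
    more than 25 A from every ligand atom.  The featurizer's pocket count
    at ``threshold_A`` therefore recovers ``composition`` exactly.
    """
    composition = np.asarray(composition, dtype=int).reshape(-1)
    if composition.shape[0] != len(STANDARD_AA):
        raise ValueError(f"composition must have {len(STANDARD_AA)} entries")
    if composition.sum() < 1:
        raise ValueError("pocket needs at least one residue")
    rng = np.random.default_rng(seed)
    ligand_coords = np.asarray(ligand_coords, dtype=float).reshape(-1, 3)
    centroid = ligand_coords.mean(axis=0)

    elements: list[str] = []
    res_names: list[str] = []
    res_ids: list[tuple[str, int, str]] = []
    coords: list[np.ndarray] = []
    res_num = 0

    def _place(res_name: str, radius_range: tuple[float, float], in_shell: bool) -> None:
        nonlocal res_num
        for _ in range(200):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            radius = rng.uniform(*radius_range)
            anchor = centroid + radius * direction
            atoms = anchor + (_random_rotation(rng) @ _RES_TEMPLATE.T).T
            dmin = np.min(np.linalg.norm(atoms[:, None, :] - ligand_coords[None], axis=2))
            if in_shell:
                ok = dmin <= threshold_A - 1.0 and dmin >= 2.5
            else:
                ok = dmin > 25.5
            if ok:
                res_num += 1
                for el, xyz in zip(_RES_ELEMENTS, atoms):
                    elements.append(el)
                    res_names.append(res_name)
                    res_ids.append(("A", res_num, ""))
                    coords.append(xyz)
                return
        raise RuntimeError(f"could not place residue {res_name} after 200 attempts")

    for aa, count in zip(STANDARD_AA, composition):
        for _ in range(int(count)):
            _place(aa, (5.0, 12.0), in_shell=True)
    for _ in range(n_distractors):
        aa = STANDARD_AA[int(rng.integers(0, len(STANDARD_AA)))]
        _place(aa, (28.0, 34.0), in_shell=False)
    return ProteinStructure(elements, res_names, res_ids, np.array(coords))


def _sample_composition(rng: np.random.Generator) -> np.ndarray:
    """25-45 residues concentrated on 5 residue types (high between-pocket spread)."""
    types = rng.choice(len(STANDARD_AA), size=5, replace=False)
    probs = rng.dirichlet(np.full(5, 0.5))
    n_res = int(rng.integers(25, 46))
    counts = np.zeros(len(STANDARD_AA), dtype=int)
    counts[types] = rng.multinomial(n_res, probs)
    if counts.sum() == 0:
        counts[types[0]] = n_res
    return counts


def _assign_ligands(config: GeneratorConfig, rng: np.random.Generator) -> list[int]:
    """Ligand index per complex, honouring the duplicate fraction at small n.

    The first round(frac*n) complexes draw from a reduced pool so their
    ligands repeat; the rest use distinct ligands while the library
    lasts, then reuse (inevitable once n exceeds the library).
    """
    n, size = config.n_complexes, config.ligand_library_size
    n_dup = int(round(config.duplicate_ligand_fraction * n))
    pool_size = max(1, min(size, n_dup // 2 or 1))
    idx: list[int] = [int(rng.integers(0, pool_size)) for _ in range(n_dup)]
    remaining = [i for i in range(size) if i >= pool_size] or list(range(size))
    fresh = list(rng.permutation(remaining))
    for k in range(n - n_dup):
        if k < len(fresh):
            idx.append(int(fresh[k]))
        else:
            idx.append(int(rng.integers(0, size)))
    rng.shuffle(idx)
    return idx


def generate_records(config: GeneratorConfig) -> tuple[list[ComplexRecord], GroundTruth]:
    """Generate an in-memory synthetic dataset.

    Labels satisfy pK = base + alpha*ligand_effect + beta*pocket_effect +
    N(0, noise_sd^2); a controllable fraction of complexes reuse library
    ligands across different pockets.
    """
    rng = np.random.default_rng(config.seed)
    ligands, effects, replaced = generate_ligand_library(
        config.ligand_library_size, config.seed
    )
    lig_idx = _assign_ligands(config, rng)
    n_pep = int(round(config.peptide_code_fraction * config.ligand_library_size))
    pep_codes = {i: f"{i % 9 + 1}MER" for i in range(n_pep)}

    records: list[ComplexRecord] = []
    gt = GroundTruth(config=asdict(config))
    gt.plan["library_sampled_with_replacement"] = replaced
    years = rng.integers(config.year_range[0], config.year_range[1] + 1, config.n_complexes)
    mtypes = rng.choice(["Ki", "Kd", "IC50"], size=config.n_complexes)
    for i in range(config.n_complexes):
        cid = f"s{i:04d}"
        li = lig_idx[i]
        lig = ligands[li]
        code = pep_codes.get(li, lig.code)
        composition = _sample_composition(rng)
        pocket_seed = _embed_seed(config.seed, 100_000 + i)
        n_distract = int(rng.integers(config.n_distractor_range[0], config.n_distractor_range[1] + 1))
        protein = generate_pocket(composition, lig.coords, pocket_seed, n_distractors=n_distract)
        le = effects[li]
        pe = pocket_effect_of(composition)
        noise = float(rng.normal(0.0, config.noise_sd)) if config.noise_sd > 0 else 0.0
        pk = config.base_pk + config.alpha_ligand * le + config.beta_pocket * pe + noise
        label = AffinityLabel(str(mtypes[i]), 10.0 ** (-pk), "M", "=", pk=pk)
        lig_rec = LigandMolecule(mol=lig.mol, inchikey=lig.inchikey, code=code)
        records.append(ComplexRecord(cid, protein, lig_rec, label, int(years[i])))
        gt.complexes[cid] = {
            "ligand_index": li,
            "inchikey": lig.inchikey,
            "ligand_effect": le,
            "pocket_effect": pe,
            "noise": noise,
            "pk": pk,
            "year": int(years[i]),
            "code": code,
        }
    return records, gt


_UNITS_DESC = (("M", 1.0), ("mM", 1e-3), ("uM", 1e-6), ("nM", 1e-9), ("pM", 1e-12), ("fM", 1e-15))


def _format_affinity(mtype: str, pk: float) -> str:
    v_molar = 10.0 ** (-pk)
    for unit, factor in _UNITS_DESC:
        val = v_molar / factor
        if 1.0 <= val < 1000.0:
            return f"{mtype}={val:.6g}{unit}"
    unit, factor = ("M", 1.0) if v_molar >= 1 else ("fM", 1e-15)
    return f"{mtype}={v_molar / factor:.6g}{unit}"


def write_records(records: list[ComplexRecord], gt: GroundTruth, out_dir: str | Path) -> Path:
    """Write records in the on-disk layout ``load_dataset`` consumes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = ["# synthetic affinity index", "# id  resolution  year  -logK  measurement  //  (code)"]
    for rec in records:
        d = out_dir / rec.complex_id
        d.mkdir(exist_ok=True)
        write_protein(rec.protein, d / f"{rec.complex_id}_protein.pdb")
        write_ligand_pose(rec.ligand, rec.ligand.coords, d / f"{rec.complex_id}_ligand.sdf")
        meas = _format_affinity(rec.label.measurement_type, rec.label.pk)
        year = rec.year if rec.year is not None else "-"
        lines.append(
            f"{rec.complex_id}  2.00  {year}  {rec.label.pk:.4f}  {meas}  // ({rec.ligand.code})"
        )
    (out_dir / "index.txt").write_text("\n".join(lines) + "\n")
    gt.save(out_dir / "ground_truth.json")
    return out_dir


def generate_dataset(config: GeneratorConfig, out_dir: str | Path) -> tuple[Path, GroundTruth]:
    """Generate and write a full fixture tree (PDB + SDF + index + truth)."""
    records, gt = generate_records(config)
    return write_records(records, gt, out_dir), gt


def generate_zero_bias_testbed(
    config: GeneratorConfig,
    n_planted: int = 12,
    cluster_size_range: tuple[int, int] = (2, 4),
    n_decoy_clusters: int = 4,
    n_singletons: int = 12,
    planted_mean_range: tuple[float, float] = (6.2, 6.8),
    planted_var_range: tuple[float, float] = (1.5, 3.0),
) -> tuple[list[ComplexRecord], GroundTruth]:
    """A testbed whose duplicate-ligand clusters are planted by design.

    Planted clusters have sample mean pK inside [6, 7] and sample
    variance above 1, with the within-cluster spread carried entirely by
    the pocket channel (``alpha_ligand`` must be 0: ligand identity
    cannot explain within-cluster spread).  Decoy clusters (wrong mean or
    low variance) and singleton ligands are added so that the
    zero-ligand-bias filter's precision is a meaningful quantity; the
    plan records exactly which clusters were planted.
    """
    if config.alpha_ligand != 0.0:
        raise ValueError("zero-bias testbed requires alpha_ligand = 0")
    lo_m, hi_m = planted_mean_range
    if not (6.0 < lo_m <= hi_m < 7.0):
        raise ValueError("planted means must lie strictly inside [6, 7]")
    rng = np.random.default_rng(config.seed)
    n_ligs = n_planted + n_decoy_clusters + n_singletons
    size = max(config.ligand_library_size, n_ligs)
    ligands, _, _ = generate_ligand_library(size, config.seed)
    order = rng.permutation(size)

    records: list[ComplexRecord] = []
    gt = GroundTruth(config=asdict(config))
    gt.plan = {"planted": {}, "decoy": {}, "singletons": []}
    counter = 0
    years = iter(rng.integers(config.year_range[0], config.year_range[1] + 1, 10_000).tolist())

    def _member(lig: LigandMolecule, composition: np.ndarray, pk: float, kind: str) -> str:
        nonlocal counter
        cid = f"z{counter:04d}"
        counter += 1
        pocket_seed = _embed_seed(config.seed, 500_000 + counter)
        protein = generate_pocket(composition, lig.coords, pocket_seed)
        label = AffinityLabel("Kd", 10.0 ** (-pk), "M", "=", pk=pk)
        records.append(
            ComplexRecord(cid, protein, LigandMolecule(lig.mol, lig.inchikey, lig.code),
                          label, int(next(years)))
        )
        gt.complexes[cid] = {
            "inchikey": lig.inchikey,
            "pocket_effect": pocket_effect_of(composition),
            "pk": pk,
            "kind": kind,
        }
        return cid

    def _planted_cluster(lig: LigandMolecule, center: float, target_var: float, kind: str) -> list[str]:
        m = int(rng.integers(cluster_size_range[0], cluster_size_range[1] + 1))
        for _ in range(100):
            comps = [_sample_composition(rng) for _ in range(m)]
            effects = np.array([pocket_effect_of(c) for c in comps])
            dev = effects - effects.mean()
            if np.sum(dev**2) > 1e-6:
                break
        else:
            raise RuntimeError("degenerate pocket effects")
        scale = math.sqrt(target_var * (m - 1) / float(np.sum(dev**2)))
        pks = center + scale * dev
        return [_member(lig, c, float(p), kind) for c, p in zip(comps, pks)]

    lig_cursor = 0
    for _ in range(n_planted):
        lig = ligands[order[lig_cursor]]; lig_cursor += 1
        center = float(rng.uniform(lo_m, hi_m))
        tv = float(rng.uniform(*planted_var_range))
        ids = _planted_cluster(lig, center, tv, "planted")
        gt.plan["planted"][lig.inchikey] = ids
    for k in range(n_decoy_clusters):
        lig = ligands[order[lig_cursor]]; lig_cursor += 1
        if k % 2 == 0:
            center = float(rng.uniform(4.0, 5.5) if rng.random() < 0.5 else rng.uniform(7.5, 9.0))
            ids = _planted_cluster(lig, center, 2.0, "decoy_mean")
        else:
            center = float(rng.uniform(lo_m, hi_m))
            ids = _planted_cluster(lig, center, 0.04, "decoy_var")
        gt.plan["decoy"][lig.inchikey] = ids
    for _ in range(n_singletons):
        lig = ligands[order[lig_cursor]]; lig_cursor += 1
        comp = _sample_composition(rng)
        pk = float(rng.uniform(3.0, 10.0))
        cid = _member(lig, comp, pk, "singleton")
        gt.plan["singletons"].append(cid)
    return records, gt


def generate_pose_decoys(
    reference: LigandMolecule | np.ndarray,
    target_rmsds: list[float],
    seed: int = 0,
    complex_id: str = "decoy",
    tol: float = 0.01,
) -> PoseSet:
    """Rigid decoy poses at prescribed in-place RMSDs from a reference.

    Each decoy is a random rotation about the centroid (capped so the
    rotation alone contributes at most half the target) followed by a
    translation whose magnitude is found by bisection on the realized
    RMSD.  Realized RMSDs match targets within ``tol`` (default 0.01 A,
    well inside the 0.05 A contract).
    """
    if isinstance(reference, LigandMolecule):
        ref = reference.heavy_coords()
    else:
        ref = np.asarray(reference, dtype=float).reshape(-1, 3)
    rng = np.random.default_rng(seed)
    centroid = ref.mean(axis=0)
    pose_set = PoseSet(complex_id=complex_id, reference_coords=ref)
    for i, target in enumerate(target_rmsds):
        if target < 0:
            raise ValueError("target RMSD must be >= 0")
        pid = f"decoy_{i:03d}"
        if target == 0:
            pose_set.add(Pose(pid, ref.copy(), 0.0, provenance="minimized"))
            continue
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        # cap the rotation so translation can always reach the target
        theta = float(rng.uniform(0.05, 0.6))
        rotated = None
        for _ in range(60):
            R = _axis_angle(axis, theta)
            rotated = (R @ (ref - centroid).T).T + centroid
            if rmsd(ref, rotated) <= 0.5 * target:
                break
            theta *= 0.5
        v_mean = (rotated - ref).mean(axis=0)
        if float(v_mean @ u) < 0:
            u = -u  # ensure RMSD is monotone increasing in the translation
        lo, hi = 0.0, max(2.0 * target, 1.0)
        while rmsd(ref, rotated + hi * u) < target:
            hi *= 2.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if rmsd(ref, rotated + mid * u) < target:
                lo = mid
            else:
                hi = mid
            if hi - lo < 1e-9:
                break
        coords = rotated + 0.5 * (lo + hi) * u
        realized = rmsd(ref, coords)
        if abs(realized - target) > tol:
            raise RuntimeError(f"decoy {pid}: realized RMSD {realized:.4f} != target {target}")
        pose_set.add(Pose(pid, coords, realized, provenance="docked"))
    return pose_set


def _axis_angle(axis: np.ndarray, theta: float) -> np.ndarray:
    x, y, z = axis
    c, s, C = math.cos(theta), math.sin(theta), 1 - math.cos(theta)
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )
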