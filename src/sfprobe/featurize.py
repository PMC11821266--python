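"""Feature views for bias-only baseline models.

Three views are computed:

* ligand-only: 1D/2D RDKit descriptors of the ligand graph (never the 3D
  pose, so every conformer of a molecule maps to the same vector);
* pocket-only: counts of each amino-acid type with any heavy atom within
  a distance cutoff (default 15 A) of any ligand heavy atom;
* both: the concatenation, ligand block first.

The descriptor battery is frozen into a :class:`DescriptorSchema` at
training time: any descriptor that is non-finite or astronomically large
on any training ligand is excluded, and the schema (with training medians
for predict-time imputation) is serializable so a saved model always sees
the exact feature order it was trained with.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from rdkit.Chem import Descriptors
from scipy.spatial import cKDTree

from .io import LigandMolecule, ProteinStructure

__all__ = [
    "STANDARD_AA",
    "POCKET_FEATURE_NAMES",
    "DescriptorSchema",
    "PocketComposition",
    "rdkit_descriptor_battery",
    "build_descriptor_schema",
    "ligand_descriptors",
    "pocket_residue_counts",
    "concat_features",
]

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, fixed alphabetical 3-letter-code order.
STANDARD_AA = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)
#: Pocket feature order: the 20 standard residues plus an UNK bucket.
POCKET_FEATURE_NAMES = STANDARD_AA + ("UNK",)


def rdkit_descriptor_battery() -> dict[str, Callable]:
    """The full named RDKit 1D/2D descriptor battery (graph-based only)."""
    return dict(Descriptors.descList)


@dataclass
class DescriptorSchema:
    """The frozen ligand-descriptor list a model was trained with.

    ``names`` is the ordered retained list; ``exclusion_log`` records each
    dropped descriptor with its reason (``nan`` or ``overflow``);
    ``medians`` holds per-descriptor training medians used to impute
    predict-time failures.
    """

    names: list[str]
    exclusion_log: list[tuple[str, str]]
    overflow_threshold: float
    medians: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        excluded = {n for n, _ in self.exclusion_log}
        if excluded & set(self.names):
            raise ValueError("retained and excluded descriptor names overlap")

    def to_json(self) -> str:
        payload = {
            "names": list(self.names),
            "exclusion_log": [list(pair) for pair in self.exclusion_log],
            "overflow_threshold": self.overflow_threshold,
            "medians": {k: self.medians[k] for k in sorted(self.medians)},
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "DescriptorSchema":
        d = json.loads(text)
        return cls(
            names=list(d["names"]),
            exclusion_log=[tuple(pair) for pair in d["exclusion_log"]],
            overflow_threshold=float(d["overflow_threshold"]),
            medians={k: float(v) for k, v in d.get("medians", {}).items()},
        )

    @classmethod
    def load(cls, path: str | Path) -> "DescriptorSchema":
        return cls.from_json(Path(path).read_text())


@dataclass
class PocketComposition:
    """Residue-type counts of a binding pocket at a distance threshold."""

    counts: np.ndarray
    threshold_A: float = 15.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(POCKET_FEATURE_NAMES),):
            raise ValueError(f"pocket composition must have {len(POCKET_FEATURE_NAMES)} entries")
        if (self.counts < 0).any():
            raise ValueError("negative residue count")

    def as_vector(self) -> np.ndarray:
        return self.counts.astype(float)

    def total(self) -> int:
        return int(self.counts.sum())


def _compute_one(fn: Callable, mol) -> float:
    try:
        v = fn(mol)
    except Exception:
        return math.nan
    try:
        return float(v)
    except (TypeError, ValueError):
        return math.nan


def build_descriptor_schema(
    training_ligands: Sequence[LigandMolecule],
    overflow_threshold: float = 1e8,
    battery: Mapping[str, Callable] | None = None,
) -> DescriptorSchema:
    """Freeze the descriptor list on a training ligand set.

    A descriptor is excluded if on ANY training ligand it raises, returns
    a non-finite value (reason ``nan``), or exceeds ``overflow_threshold``
    in magnitude (reason ``overflow``).  Retained names are sorted
    alphabetically so two builds on the same ligands serialize
    byte-identically.
    """
    if not training_ligands:
        raise ValueError("empty training ligand list")
    if battery is None:
        battery = rdkit_descriptor_battery()
    values: dict[str, list[float]] = {name: [] for name in battery}
    for lig in training_ligands:
        for name, fn in battery.items():
            values[name].append(_compute_one(fn, lig.mol))
    names: list[str] = []
    exclusion_log: list[tuple[str, str]] = []
    medians: dict[str, float] = {}
    for name in sorted(battery):
        arr = np.array(values[name], dtype=float)
        if not np.all(np.isfinite(arr)):
            exclusion_log.append((name, "nan"))
        elif np.any(np.abs(arr) > overflow_threshold):
            exclusion_log.append((name, "overflow"))
        else:
            names.append(name)
            medians[name] = float(np.median(arr))
    if not names:
        raise ValueError("all descriptors excluded; check overflow_threshold / battery")
    return DescriptorSchema(names, exclusion_log, overflow_threshold, medians)


def ligand_descriptors(
    ligand: LigandMolecule,
    schema: DescriptorSchema,
    battery: Mapping[str, Callable] | None = None,
) -> np.ndarray:
    """Descriptor vector for one ligand under a frozen schema.

    Values are functions of the 2D molecular graph only, so all conformers
    and rigid poses of one molecule give identical vectors.  A descriptor
    that fails at predict time is imputed with its training median (and
    logged loudly).
    """
    if battery is None:
        battery = rdkit_descriptor_battery()
    out = np.empty(len(schema.names), dtype=float)
    for j, name in enumerate(schema.names):
        v = _compute_one(battery[name], ligand.mol)
        if not math.isfinite(v):
            v = schema.medians.get(name, 0.0)
            logger.warning(
                "descriptor %s failed for ligand %s; imputed training median %.6g",
                name, ligand.inchikey, v,
            )
        out[j] = v
    return out


def pocket_residue_counts(
    protein: ProteinStructure,
    ligand: LigandMolecule,
    threshold_A: float = 15.0,
    heavy_only: bool = True,
) -> PocketComposition:
    """Count pocket residues by amino-acid type.

    A residue is in the pocket if ANY of its atoms lies within
    ``threshold_A`` (Euclidean, inclusive) of ANY ligand atom; it counts
    once regardless of how many atoms qualify.  By default only heavy
    atoms enter the distance check (hydrogen placement is inconsistent
    across PDB files).  Residue names outside the 20 standard codes go to
    the UNK bucket.  An empty pocket is a legal all-zeros result.
    """
    lig_coords = ligand.coords
    prot_coords = protein.coords
    prot_mask = np.ones(protein.n_atoms, dtype=bool)
    if heavy_only:
        lig_coords = lig_coords[ligand.heavy_mask()]
        prot_mask = protein.heavy_mask()
    counts = np.zeros(len(POCKET_FEATURE_NAMES), dtype=int)
    aa_index = {aa: i for i, aa in enumerate(STANDARD_AA)}
    if len(lig_coords) == 0:
        return PocketComposition(counts, threshold_A)
    tree = cKDTree(lig_coords)
    # nearest ligand-atom distance for every (kept) protein atom
    min_dist = np.full(protein.n_atoms, np.inf)
    if prot_mask.any():
        d, _ = tree.query(prot_coords[prot_mask])
        min_dist[prot_mask] = d
    for _, res_name, atom_idx in protein.residues():
        if np.min(min_dist[atom_idx]) <= threshold_A:
            counts[aa_index.get(res_name.upper(), len(STANDARD_AA))] += 1
    return PocketComposition(counts, threshold_A)


def concat_features(ligand_vec: np.ndarray, pocket: PocketComposition) -> np.ndarray:
    """Ligand block first, then the 21 pocket counts."""
    ligand_vec = np.asarray(ligand_vec, dtype=float)
    if ligand_vec.ndim != 1:
        raise ValueError("ligand feature vector must be 1-D")
    if not np.all(np.isfinite(ligand_vec)):
        raise ValueError("non-finite ligand feature")
    return np.concatenate([ligand_vec, pocket.as_vector()])
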