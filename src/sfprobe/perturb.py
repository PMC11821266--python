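"""Structural stress-test generators: steric clashes and RMSD-binned decoys.

Clash series: the crystal ligand pose is rigidly translated INTO the
protein along the unit vector from the globally closest ligand atom to
the globally closest protein atom, 1 A at a time (ten steps by default).
The direction is computed once from the unperturbed complex and reused
for every step, so RMSD to the reference grows exactly linearly.

Decoy binning: alternative poses are binned by in-place RMSD to the
crystal pose (no superposition — pose accuracy is positional) over the
standard ladder 0-1, 1-2, 2-4, 4-6, 6-8, 8-10, 10-15, 15-20, 20-25,
25-30 A, and within each bin the pose closest to the bin midpoint is
selected ("if available": empty bins stay empty).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import LigandMolecule, ProteinStructure

__all__ = [
    "DEFAULT_RMSD_BINS",
    "Pose",
    "PoseSet",
    "RmsdBinning",
    "clash_direction",
    "translate_series",
    "rmsd",
    "select_binned_poses",
]

#: The standard RMSD ladder (A).  Bins are half-open [lo, hi) except the
#: last, which is closed at its upper edge so a 30.0 A pose is binnable.
DEFAULT_RMSD_BINS: tuple[tuple[float, float], ...] = (
    (0, 1), (1, 2), (2, 4), (4, 6), (6, 8), (8, 10),
    (10, 15), (15, 20), (20, 25), (25, 30),
)


class GeometryError(ValueError):
    pass


@dataclass
class Pose:
    pose_id: str
    coords: np.ndarray
    rmsd_to_reference: float
    provenance: str = "docked"  # docked | minimized | translated

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if self.rmsd_to_reference < 0:
            raise ValueError("negative RMSD")


@dataclass
class PoseSet:
    """Alternative poses of one ligand, annotated with RMSD to the crystal pose."""

    complex_id: str
    reference_coords: np.ndarray
    poses: list[Pose] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.reference_coords = np.asarray(self.reference_coords, dtype=float).reshape(-1, 3)
        for p in self.poses:
            if p.coords.shape != self.reference_coords.shape:
                raise ValueError(f"pose {p.pose_id}: atom count differs from reference")

    def add(self, pose: Pose) -> None:
        if pose.coords.shape != self.reference_coords.shape:
            raise ValueError(f"pose {pose.pose_id}: atom count differs from reference")
        self.poses.append(pose)


@dataclass
class RmsdBinning:
    """Per-bin selected pose (or None where the bin had no candidate)."""

    edges: tuple[tuple[float, float], ...]
    selection: dict[tuple[float, float], str | None]


def _heavy_coords(obj) -> np.ndarray:
    if isinstance(obj, ProteinStructure):
        return obj.coords[obj.heavy_mask()]
    if isinstance(obj, LigandMolecule):
        return obj.heavy_coords()
    return np.asarray(obj, dtype=float).reshape(-1, 3)


def clash_direction(protein, ligand_coords) -> np.ndarray:
    """Unit vector from the closest ligand atom toward the closest protein atom.

    The globally closest (ligand atom, protein atom) pair over heavy
    atoms defines the direction (p* - l*)/||p* - l*||, pointing from the
    ligand into the protein.  Distance ties are broken by the lowest
    (ligand index, protein index) pair, deterministically.
    """
    P = _heavy_coords(protein)
    L = _heavy_coords(ligand_coords)
    if len(P) == 0 or len(L) == 0:
        raise GeometryError("empty structure")
    # L is small (a ligand): the full (n_lig, n_prot) distance matrix is cheap
    diff = L[:, None, :] - P[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    flat = int(np.argmin(d2))  # row-major argmin = lowest (ligand, protein) tie-break
    li, pi = divmod(flat, d2.shape[1])
    v = P[pi] - L[li]
    norm = float(np.linalg.norm(v))
    if norm == 0.0:
        raise GeometryError("closest ligand and protein atoms coincide")
    return v / norm


def translate_series(
    ligand_coords: np.ndarray,
    direction: np.ndarray,
    step_A: float = 1.0,
    n_steps: int = 10,
) -> list[np.ndarray]:
    """Rigid translation ladder: k-th output = input + k * step_A * direction.

    The direction must be unit length; it is supplied once (computed from
    the unperturbed complex) and reused for all steps, so
    rmsd(input, k-th pose) = k * step_A exactly.
    """
    ligand_coords = np.asarray(ligand_coords, dtype=float).reshape(-1, 3)
    direction = np.asarray(direction, dtype=float).reshape(3)
    if abs(np.linalg.norm(direction) - 1.0) > 1e-9:
        raise ValueError("direction must be a unit vector")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    return [ligand_coords + (k * step_A) * direction for k in range(1, n_steps + 1)]


def rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """In-place RMSD (A): no superposition, matched atom order.

    sqrt(mean over atoms of squared displacement).  Callers supply
    heavy-atom coordinates; atom counts must match.
    """
    a = np.asarray(coords_a, dtype=float).reshape(-1, 3)
    b = np.asarray(coords_b, dtype=float).reshape(-1, 3)
    if a.shape != b.shape:
        raise ValueError(f"coordinate shapes differ: {a.shape} vs {b.shape}")
    if len(a) == 0:
        raise ValueError("empty coordinate arrays")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _in_bin(value: float, lo: float, hi: float, is_last: bool) -> bool:
    if is_last:
        return lo <= value <= hi
    return lo <= value < hi


def select_binned_poses(
    pose_set: PoseSet,
    edges: Sequence[tuple[float, float]] = DEFAULT_RMSD_BINS,
) -> RmsdBinning:
    """Pick, per RMSD bin, the pose closest to the bin midpoint.

    Bins are half-open [lo, hi), the final bin closed at its upper edge.
    Ties on distance-to-midpoint are broken by the lowest pose_id.  Bins
    with no candidate stay empty.
    """
    edges = tuple((float(lo), float(hi)) for lo, hi in edges)
    for (lo, hi), (lo2, _) in zip(edges, edges[1:]):
        if hi > lo2:
            raise ValueError("bins must be non-overlapping and ascending")
    selection: dict[tuple[float, float], str | None] = {}
    for i, (lo, hi) in enumerate(edges):
        mid = (lo + hi) / 2.0
        best: tuple[float, str] | None = None
        for pose in pose_set.poses:
            if _in_bin(pose.rmsd_to_reference, lo, hi, i == len(edges) - 1):
                key = (abs(pose.rmsd_to_reference - mid), pose.pose_id)
                if best is None or key < best:
                    best = key
        selection[(lo, hi)] = best[1] if best is not None else None
    return RmsdBinning(edges=edges, selection=selection)
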