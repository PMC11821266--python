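"""Reading and writing protein-ligand complex data.

Protein structures come from PDB files (parsed with gemmi), ligands from
SDF or MOL2 files (parsed with RDKit), and affinity labels from a
PDBBind-style whitespace index file.  ``load_dataset`` assembles validated
:class:`ComplexRecord` collections, excluding (and reporting) entries that
cannot be parsed -- unparsable complexes are dropped rather than repaired.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

__all__ = [
    "ProteinStructure",
    "LigandMolecule",
    "AffinityLabel",
    "ComplexRecord",
    "IndexEntry",
    "ExclusionReport",
    "read_protein",
    "read_ligand",
    "ligand_from_mol",
    "pk_from_affinity",
    "parse_affinity_index",
    "load_dataset",
    "write_ligand_pose",
    "write_protein",
]

RDLogger.DisableLog("rdApp.*")

#: Conversion factors to molar for the units an affinity string may carry.
UNIT_TO_MOLAR = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "nM": 1e-9,
    "pM": 1e-12,
    "fM": 1e-15,
}

_WATER_RESNAMES = {"HOH", "WAT", "DOD", "H2O"}
_INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")
_MEASUREMENT_RE = re.compile(
    r"^(Ki|Kd|IC50)(>=|<=|=|~|>|<)([0-9.eE+\-]+)(fM|pM|nM|uM|mM|M)$"
)


class StructureError(ValueError):
    """Raised for unusable structural input (empty, non-finite, malformed)."""


@dataclass
class ProteinStructure:
    """A protein as flat per-atom arrays.

    Atom *i* has element ``elements[i]``, 3-letter residue name
    ``res_names[i]``, residue identity ``res_ids[i]`` (chain, seqnum,
    insertion code -- insertion codes are part of residue identity) and
    coordinates ``coords[i]`` in angstroms.
    """

    elements: list[str]
    res_names: list[str]
    res_ids: list[tuple[str, int, str]]
    coords: np.ndarray
    source_path: str | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.elements) == 0:
            raise StructureError("protein structure has no atoms")
        if not (len(self.elements) == len(self.res_names) == len(self.res_ids) == len(self.coords)):
            raise StructureError("per-atom arrays have inconsistent lengths")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite protein coordinates")
        if any(not name for name in self.res_names):
            raise StructureError("empty residue name")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def heavy_mask(self) -> np.ndarray:
        return np.array([e.upper() not in ("H", "D") for e in self.elements], dtype=bool)

    def residues(self) -> list[tuple[tuple[str, int, str], str, np.ndarray]]:
        """Unique residues in first-seen order as (res_id, res_name, atom indices)."""
        order: dict[tuple, int] = {}
        groups: dict[tuple, list[int]] = {}
        names: dict[tuple, str] = {}
        for i, rid in enumerate(self.res_ids):
            if rid not in order:
                order[rid] = len(order)
                groups[rid] = []
                names[rid] = self.res_names[i]
            groups[rid].append(i)
        out = []
        for rid in sorted(order, key=order.get):
            out.append((rid, names[rid], np.array(groups[rid], dtype=int)))
        return out


@dataclass
class LigandMolecule:
    """A small molecule with 3D coordinates, wrapping an RDKit mol.

    ``inchikey`` is the full 27-character key and is the identity used for
    duplicate-ligand clustering; conformers of the same molecule share it.
    """

    mol: Chem.Mol
    inchikey: str
    code: str = ""
    source_path: str | None = None

    def __post_init__(self) -> None:
        if not _INCHIKEY_RE.match(self.inchikey or ""):
            raise StructureError(f"malformed InChI-Key: {self.inchikey!r}")
        if self.mol.GetNumConformers() == 0:
            raise StructureError("ligand has no conformer (3D coordinates required)")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite ligand coordinates")

    @property
    def coords(self) -> np.ndarray:
        return np.array(self.mol.GetConformer().GetPositions(), dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.GetSymbol() for a in self.mol.GetAtoms()]

    def heavy_mask(self) -> np.ndarray:
        return np.array([a.GetAtomicNum() > 1 for a in self.mol.GetAtoms()], dtype=bool)

    def heavy_coords(self) -> np.ndarray:
        return self.coords[self.heavy_mask()]


@dataclass(frozen=True)
class AffinityLabel:
    """A measured binding affinity and its derived pK.

    Ki, Kd and IC50 are deliberately merged onto a single pK scale
    (pK = -log10 of the value in molar); ``measurement_type`` is retained
    so users can re-stratify.  Qualifiers (>, <, ~, >=, <=) are stored but
    by default the value is treated as exact.
    """

    measurement_type: str
    value: float
    unit: str
    qualifier: str = "="
    pk: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.value is None or self.value <= 0:
            raise ValueError(f"affinity value must be positive, got {self.value}")
        if self.unit not in UNIT_TO_MOLAR:
            raise ValueError(f"unknown affinity unit {self.unit!r}")
        if self.measurement_type not in ("Ki", "Kd", "IC50"):
            raise ValueError(f"unknown measurement type {self.measurement_type!r}")
        if self.pk is None:
            object.__setattr__(self, "pk", pk_from_affinity(self.value, self.unit))


@dataclass
class ComplexRecord:
    """One protein-ligand complex: structure pair, label, deposition year."""

    complex_id: str
    protein: ProteinStructure
    ligand: LigandMolecule
    label: AffinityLabel
    year: int | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.label.pk):
            raise ValueError(f"{self.complex_id}: non-finite pK")


@dataclass(frozen=True)
class IndexEntry:
    complex_id: str
    label: AffinityLabel
    year: int | None
    ligand_code: str = ""


@dataclass
class ExclusionReport:
    """IDs dropped during dataset assembly, each with a reason.

    Reasons: ``missing_file``, ``protein_parse``, ``ligand_parse``,
    ``label_parse``.
    """

    exclusions: list[tuple[str, str]] = field(default_factory=list)

    def add(self, complex_id: str, reason: str) -> None:
        self.exclusions.append((complex_id, reason))

    def __len__(self) -> int:
        return len(self.exclusions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.exclusions, columns=["complex_id", "reason"])

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def pk_from_affinity(value: float, unit: str) -> float:
    """pK = -log10 of an affinity converted to molar.

    (1, "uM") -> 6.0; (1, "nM") -> 9.0.  Ki, Kd and IC50 are treated
    identically, so the measurement type does not enter.
    """
    if value is None or not math.isfinite(value) or value <= 0:
        raise ValueError(f"affinity value must be a positive finite number, got {value}")
    try:
        factor = UNIT_TO_MOLAR[unit]
    except KeyError:
        raise ValueError(f"unknown affinity unit {unit!r}") from None
    return -math.log10(value * factor)


def read_protein(path: str | Path, strip_nonchain: bool = True) -> ProteinStructure:
    """Read a PDB file into a :class:`ProteinStructure`.

    With ``strip_nonchain`` (default) waters and HETATM records are
    dropped, keeping only polymer-chain ATOM records.  Altloc 'A' (or
    blank) is kept; insertion codes are retained in residue identity.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse PDB {path}: {exc}") from exc

    elements: list[str] = []
    res_names: list[str] = []
    res_ids: list[tuple[str, int, str]] = []
    coords: list[tuple[float, float, float]] = []
    if len(st) == 0:
        raise StructureError(f"{path}: no model in PDB file")
    model = st[0]
    for chain in model:
        for res in chain:
            if strip_nonchain:
                if res.name in _WATER_RESNAMES or res.is_water():
                    continue
                if res.het_flag == "H":
                    continue
            for atom in res:
                if atom.altloc not in ("\0", "", "A"):
                    continue
                elements.append(atom.element.name)
                res_names.append(res.name)
                icode = res.seqid.icode.strip() if res.seqid.icode else ""
                res_ids.append((chain.name, res.seqid.num, icode))
                coords.append((atom.pos.x, atom.pos.y, atom.pos.z))
    if not elements:
        raise StructureError(f"{path}: no atoms left after filtering")
    return ProteinStructure(elements, res_names, res_ids, np.array(coords), str(path))


def write_protein(protein: ProteinStructure, path: str | Path) -> None:
    """Write a :class:`ProteinStructure` to a PDB file via gemmi."""
    st = gemmi.Structure()
    st.name = "sfprobe"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    current: dict[str, tuple[int, str] | None] = {}
    serial = 0
    for i in range(protein.n_atoms):
        chain_name, seqnum, icode = protein.res_ids[i]
        if chain_name not in chains:
            chains[chain_name] = gemmi.Chain(chain_name)
            current[chain_name] = None
        chain = chains[chain_name]
        if current[chain_name] != (seqnum, icode, protein.res_names[i]):
            res = gemmi.Residue()
            res.name = protein.res_names[i]
            res.seqid = gemmi.SeqId(seqnum, icode if icode else " ")
            chain.add_residue(res)
            current[chain_name] = (seqnum, icode, protein.res_names[i])
        res = chain[len(chain) - 1]
        atom = gemmi.Atom()
        serial += 1
        atom.serial = serial
        el = protein.elements[i]
        atom.element = gemmi.Element(el)
        # unique-ish atom names within a residue keep PDB readers happy
        atom.name = f"{el}{len(res)}"
        x, y, z = protein.coords[i]
        atom.pos = gemmi.Position(float(x), float(y), float(z))
        res.add_atom(atom)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_minimal_pdb(str(path))


def ligand_from_mol(mol: Chem.Mol, code: str = "", source_path: str | None = None) -> LigandMolecule:
    """Wrap an RDKit mol (with a conformer) as a :class:`LigandMolecule`."""
    key = Chem.MolToInchiKey(mol)
    if not key:
        raise StructureError("could not compute InChI-Key")
    return LigandMolecule(mol=mol, inchikey=key, code=code, source_path=source_path)


def read_ligand(path: str | Path, code: str = "") -> LigandMolecule:
    """Read a single-molecule SDF or MOL2 file.

    Hydrogens are retained if present.  The InChI-Key is computed on read
    and is format-independent: the same molecule read from SDF and MOL2
    yields the same key.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    mol: Chem.Mol | None
    if suffix == ".mol2":
        mol = Chem.MolFromMol2File(str(path), removeHs=False)
    else:
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        mol = supplier[0] if len(supplier) else None
    if mol is None:
        raise StructureError(f"cannot parse ligand file {path}")
    # stereo lives in the 3D coordinates; perceive it so the InChI-Key is
    # identical to the one computed on the stereo-tagged source molecule
    if mol.GetNumConformers() and mol.GetConformer().Is3D():
        for bond in mol.GetBonds():
            if bond.GetStereo() == Chem.BondStereo.STEREOANY:
                bond.SetStereo(Chem.BondStereo.STEREONONE)
        Chem.AssignStereochemistryFrom3D(mol)
    return ligand_from_mol(mol, code=code, source_path=str(path))


def parse_affinity_index(path: str | Path) -> tuple[dict[str, IndexEntry], int]:
    """Parse a PDBBind-dialect index file.

    Lines are whitespace-delimited::

        <id> <resolution> <year> <-logK> <meas> // <comment... (CODE)>

    where ``<meas>`` looks like ``Kd=49uM`` (also Ki/IC50 and qualifiers
    ``~ > < >= <=``).  Comment lines start with ``#``.  A trailing
    parenthesised token in the comment, if present, is taken as the ligand
    code.  Malformed lines are skipped with a warning; the skip count is
    returned alongside the entries.
    """
    path = Path(path)
    entries: dict[str, IndexEntry] = {}
    skipped = 0
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        try:
            if len(tokens) < 5:
                raise ValueError("too few columns")
            complex_id = tokens[0]
            year: int | None
            try:
                year = int(tokens[2])
            except ValueError:
                if tokens[2] in ("-", "NA", "None"):
                    year = None
                else:
                    raise ValueError(f"bad year field {tokens[2]!r}")
            m = _MEASUREMENT_RE.match(tokens[4])
            if not m:
                raise ValueError(f"bad measurement field {tokens[4]!r}")
            mtype, qualifier, value_s, unit = m.groups()
            label = AffinityLabel(mtype, float(value_s), unit, qualifier)
        except ValueError as exc:
            warnings.warn(f"{path.name}:{lineno}: skipping line ({exc})", stacklevel=2)
            skipped += 1
            continue
        code = ""
        if "//" in tokens:
            comment = tokens[tokens.index("//") + 1:]
            for tok in reversed(comment):
                if tok.startswith("(") and tok.endswith(")"):
                    code = tok[1:-1]
                    break
        entries[complex_id] = IndexEntry(complex_id, label, year, code)
    return entries, skipped


def load_dataset(
    index_path: str | Path,
    structure_dir: str | Path,
    protein_pattern: str = "{cid}/{cid}_protein.pdb",
    ligand_pattern: str = "{cid}/{cid}_ligand.sdf",
    exclude_qualified: bool = False,
) -> tuple[list[ComplexRecord], ExclusionReport]:
    """Assemble :class:`ComplexRecord` objects from an index + structure tree.

    Every returned record is fully parsed; entries that fail protein,
    ligand or label parsing (or whose files are absent) are dropped and
    listed in the exclusion report with a reason.  An empty result is a
    fatal error.

    ``exclude_qualified`` drops entries whose affinity carries a
    non-exact qualifier (>, <, ~, >=, <=).
    """
    structure_dir = Path(structure_dir)
    entries, n_skipped = parse_affinity_index(index_path)
    report = ExclusionReport()
    records: list[ComplexRecord] = []
    for cid, entry in entries.items():
        if exclude_qualified and entry.label.qualifier != "=":
            report.add(cid, "qualified_label")
            continue
        ppath = structure_dir / protein_pattern.format(cid=cid)
        lpath = structure_dir / ligand_pattern.format(cid=cid)
        if not ppath.exists() or not lpath.exists():
            report.add(cid, "missing_file")
            continue
        try:
            protein = read_protein(ppath)
        except (StructureError, FileNotFoundError):
            report.add(cid, "protein_parse")
            continue
        try:
            ligand = read_ligand(lpath, code=entry.ligand_code)
        except (StructureError, FileNotFoundError):
            report.add(cid, "ligand_parse")
            continue
        records.append(ComplexRecord(cid, protein, ligand, entry.label, entry.year))
    if n_skipped:
        # index lines that never made it to an IndexEntry
        report.add(f"<{n_skipped} index lines>", "label_parse")
    if not records:
        raise StructureError("dataset is empty after exclusions")
    return records, report


def write_ligand_pose(ligand: LigandMolecule, coords: np.ndarray, path: str | Path) -> None:
    """Write the ligand with replacement coordinates as a single-record SDF.

    Connectivity is untouched; the written file re-reads to a molecule
    with identical bonds and the new coordinates (to SDF precision,
    1e-4 A).
    """
    coords = np.asarray(coords, dtype=float)
    n = ligand.mol.GetNumAtoms()
    if coords.shape != (n, 3):
        raise ValueError(f"coords shape {coords.shape} does not match {n} atoms")
    mol = Chem.Mol(ligand.mol)
    conf = mol.GetConformer()
    for i in range(n):
        conf.SetAtomPosition(i, tuple(float(v) for v in coords[i]))
    writer = Chem.SDWriter(str(path))
    try:
        writer.write(mol)
    finally:
        writer.close()
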