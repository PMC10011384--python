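"""Molecule input, conformer preparation and atomic feature perception.

Molecules enter as SMILES (one per line, optional identifier) or SDF.  A
:class:`MoleculeRecord` wraps the RDKit molecule together with the per-atom
:class:`AtomDescriptor` table that every downstream equation consumes:
hybridisation, heavy-neighbour count, hydrogen count, lone-pair count, ring
membership, and — once a charge backend has run — partial charges and van
der Waals radii.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Optional

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .exceptions import (
    ConformerError,
    EmptyInputError,
    ForceFieldError,
    UnsupportedElementError,
    UnsupportedHybridisationError,
)
from .eeq import SUPPORTED_ELEMENTS

logger = logging.getLogger(__name__)

#: default conformer-embedding seed; any fixed value gives reproducible runs.
DEFAULT_SEED = 1910

Hybridisation = Literal["sp1", "sp2", "sp3", "other"]
ConformerSource = Literal["as-provided", "embedded-minimised"]

#: valence electrons for the lone-pair rule.
_VALENCE_ELECTRONS = {
    "H": 1, "B": 3, "C": 4, "N": 5, "O": 6, "F": 7,
    "Si": 4, "P": 5, "S": 6, "Cl": 7, "Br": 7, "I": 7,
}

_HYB_MAP = {
    Chem.HybridizationType.SP: "sp1",
    Chem.HybridizationType.SP2: "sp2",
    Chem.HybridizationType.SP3: "sp3",
}


@dataclass
class AtomDescriptor:
    """Per-atom perception record feeding the strength and energy equations."""

    index: int
    element: str
    formal_charge: int
    hyb: Hybridisation
    n_l: int          # non-hydrogen neighbours
    n_H: int          # bonded hydrogens
    n_LP: int         # lone pairs
    in_ring: bool
    q: Optional[float] = None       # partial charge, e
    r_vdw: Optional[float] = None   # van der Waals radius, Angstrom


@dataclass
class MoleculeRecord:
    """A molecule with conformer, bond graph and perceived atomic features."""

    identifier: str
    smiles: str
    mol: Chem.Mol
    conformer_source: Optional[ConformerSource] = None
    atoms: list[AtomDescriptor] = field(default_factory=list)
    _dm: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def n_atoms(self) -> int:
        return self.mol.GetNumAtoms()

    @property
    def bonds(self) -> list[tuple[int, int, float]]:
        return [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
            for b in self.mol.GetBonds()
        ]

    @property
    def coordinates(self) -> np.ndarray:
        """Per-atom 3D positions in Angstrom."""
        if self.mol.GetNumConformers() == 0:
            raise ConformerError(f"{self.identifier}: no conformer present")
        return np.array(self.mol.GetConformer().GetPositions(), dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.GetSymbol() for a in self.mol.GetAtoms()]

    @property
    def total_charge(self) -> int:
        return Chem.GetFormalCharge(self.mol)

    def distance_matrix(self) -> np.ndarray:
        """Topological (bond-count) distance matrix."""
        if self._dm is None or self._dm.shape[0] != self.n_atoms:
            self._dm = np.asarray(Chem.GetDistanceMatrix(self.mol))
        return self._dm

    @property
    def charges(self) -> np.ndarray:
        from .exceptions import ChargesMissingError

        if not self.atoms or self.atoms[0].q is None:
            raise ChargesMissingError(
                f"{self.identifier}: partial charges have not been computed"
            )
        return np.array([a.q for a in self.atoms], dtype=float)


@dataclass
class LoadFailure:
    """A parse failure, reported rather than silently dropped."""

    position: int       # 1-based line (SMILES) or record (SDF) number
    content: str
    reason: str


@dataclass
class LoadResult:
    records: list[MoleculeRecord]
    failures: list[LoadFailure]

    def __iter__(self) -> Iterator[MoleculeRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _record_from_mol(mol: Chem.Mol, identifier: str) -> MoleculeRecord:
    smiles = Chem.MolToSmiles(Chem.RemoveHs(Chem.Mol(mol)))
    rec = MoleculeRecord(identifier=identifier, smiles=smiles, mol=mol)
    if mol.GetNumConformers() > 0:
        rec.conformer_source = "as-provided"
    return rec


def load_molecules(path: str | Path, format: str = "smiles") -> LoadResult:
    """Read a SMILES or SDF file into molecule records.

    Input order is preserved; entries that fail to parse are collected in
    ``LoadResult.failures`` with their line/record number.  Raises
    :class:`EmptyInputError` when nothing parses.
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"cannot read molecule file: {path}")
    records: list[MoleculeRecord] = []
    failures: list[LoadFailure] = []

    if format == "smiles":
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smi = parts[0]
            ident = parts[1].strip() if len(parts) > 1 else f"mol{lineno}"
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                failures.append(LoadFailure(lineno, line, "unparseable SMILES"))
                continue
            records.append(MoleculeRecord(identifier=ident, smiles=Chem.MolToSmiles(mol), mol=mol))
    elif format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False)
        for recno, mol in enumerate(supplier, start=1):
            if mol is None:
                failures.append(LoadFailure(recno, f"record {recno}", "unparseable SDF block"))
                continue
            ident = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{recno}"
            records.append(_record_from_mol(mol, ident))
    else:
        raise ValueError(f"unknown format {format!r}; expected 'smiles' or 'sdf'")

    for f in failures:
        logger.warning("%s: entry %d not parseable (%s)", path.name, f.position, f.reason)
    if not records:
        raise EmptyInputError(f"{path}: no parseable molecules")
    return LoadResult(records, failures)


def from_smiles(smiles: str, identifier: str | None = None) -> MoleculeRecord:
    """Convenience constructor for a single molecule."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return MoleculeRecord(identifier=identifier or smiles, smiles=Chem.MolToSmiles(mol), mol=mol)


def prepare_conformer(
    record: MoleculeRecord,
    seed: int = DEFAULT_SEED,
    preserve: bool = False,
) -> MoleculeRecord:
    """Add hydrogens and supply a 3D conformer.

    With ``preserve=True`` (SDF ligands carrying active conformations) the
    provided coordinates are kept and hydrogens are added onto them.
    Otherwise a single conformer is embedded deterministically from ``seed``
    and minimised with MMFF94; repeated calls with the same seed give
    bitwise-identical coordinates.
    """
    if preserve:
        if record.mol.GetNumConformers() == 0:
            raise ConformerError(
                f"{record.identifier}: preserve requested but no 3D coordinates present"
            )
        mol = Chem.AddHs(record.mol, addCoords=True)
        record.mol = mol
        record.conformer_source = "as-provided"
        record._dm = None
        return record

    mol = Chem.AddHs(record.mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise ConformerError(f"{record.identifier}: 3D embedding failed")
    props = AllChem.MMFFGetMoleculeProperties(mol)
    if props is None:
        raise ForceFieldError(
            f"{record.identifier}: MMFF94 has no parameters for this molecule"
        )
    AllChem.MMFFOptimizeMolecule(mol)
    record.mol = mol
    record.conformer_source = "embedded-minimised"
    record._dm = None
    return record


def lone_pairs(atom: Chem.Atom) -> int:
    """Lone-pair count from the element/valence rule.

    ``n_LP = (valence electrons - formal charge - total bond order) / 2``,
    with one override: aromatic nitrogen/phosphorus whose lone pair is part
    of the aromatic sextet (pyrrole-type, three sigma neighbours) gets 0.
    Carbon and hydrogen always get 0.
    """
    el = atom.GetSymbol()
    if el not in _VALENCE_ELECTRONS:
        raise UnsupportedElementError(
            f"element {el!r} (atom index {atom.GetIdx()}) has no lone-pair rule"
        )
    if el in ("C", "H", "B", "Si"):
        return 0
    if el in ("N", "P") and atom.GetIsAromatic() and atom.GetTotalDegree() == 3:
        return 0
    ve = _VALENCE_ELECTRONS[el]
    n = (ve - atom.GetFormalCharge() - atom.GetTotalValence()) // 2
    return max(0, int(n))


def perceive_features(record: MoleculeRecord) -> list[AtomDescriptor]:
    """Fill hybridisation, neighbour counts, lone pairs and ring membership.

    Requires explicit hydrogens.  Heavy atoms outside sp1/sp2/sp3 (e.g.
    hypervalent centres) raise :class:`UnsupportedHybridisationError`
    because the surface equation defines the hybridisation number only for
    sp1..sp3.
    """
    mol = record.mol
    descriptors: list[AtomDescriptor] = []
    ring_info = mol.GetRingInfo()
    for atom in mol.GetAtoms():
        idx = atom.GetIdx()
        el = atom.GetSymbol()
        if el not in SUPPORTED_ELEMENTS:
            raise UnsupportedElementError(
                f"{record.identifier}: element {el!r} (atom {idx}) unsupported"
            )
        if el == "H":
            hyb: Hybridisation = "other"
        elif atom.GetIsAromatic():
            hyb = "sp2"
        else:
            mapped = _HYB_MAP.get(atom.GetHybridization())
            if mapped is None:
                raise UnsupportedHybridisationError(
                    f"{record.identifier}: atom {idx} ({el}) has hybridisation "
                    f"{atom.GetHybridization()}, outside sp1/sp2/sp3"
                )
            hyb = mapped
        n_h = sum(1 for nb in atom.GetNeighbors() if nb.GetAtomicNum() == 1)
        n_l = sum(1 for nb in atom.GetNeighbors() if nb.GetAtomicNum() != 1)
        descriptors.append(
            AtomDescriptor(
                index=idx,
                element=el,
                formal_charge=atom.GetFormalCharge(),
                hyb=hyb,
                n_l=n_l,
                n_H=n_h,
                n_LP=lone_pairs(atom),
                in_ring=ring_info.NumAtomRings(idx) > 0,
            )
        )
    record.atoms = descriptors
    return descriptors


def count_pi_and_rings(record: MoleculeRecord) -> tuple[int, int, int]:
    """(N_pi2, N_pi1, N_r): pi-orbital counts over heavy atoms + SSSR rings.

    sp1 atoms contribute two pi orbitals, sp2 atoms one; the ring count is
    the smallest-set-of-smallest-rings size.
    """
    if not record.atoms:
        perceive_features(record)
    n_pi2 = 2 * sum(1 for a in record.atoms if a.element != "H" and a.hyb == "sp1")
    n_pi1 = sum(1 for a in record.atoms if a.element != "H" and a.hyb == "sp2")
    n_r = len(Chem.GetSSSR(record.mol))
    return n_pi2, n_pi1, n_r
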