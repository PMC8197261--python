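"""Molecular graph data model, atom featurization, and dataset readers.

A molecule is represented as a heavy-atom graph: element symbols, typed
bonds stored as a five-channel adjacency stack (one channel per bond type,
with an explicit self-bond channel), optional 3-D coordinates, and a fixed
60-dimensional one-hot initial feature vector per atom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BondType",
    "MolecularGraph",
    "ELEMENTS",
    "FEATURE_DIM",
    "FEATURE_LAYOUT",
    "featurize_atom",
    "build_adjacency",
    "mol_from_smiles",
    "read_csv_dataset",
    "read_sdf_dataset",
]


class BondType(IntEnum):
    """Bond-type channels of the adjacency stack.

    The self channel (an atom's bond to itself) is index 0 and is always the
    identity matrix; the four chemical bond types fill channels 1-4.
    """

    SELF = 0
    SINGLE = 1
    DOUBLE = 2
    TRIPLE = 3
    AROMATIC = 4


N_BOND_CHANNELS = len(BondType)

# 42 supported element symbols: the twelve organic-chemistry staples first,
# then thirty further common elements in atomic-number order.  The position
# in this tuple is the one-hot index of the element block.
ELEMENTS: tuple[str, ...] = (
    "H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Br", "I",
    "Li", "Be", "Na", "Mg", "Al", "K", "Ca", "Ti", "V", "Cr", "Mn", "Fe",
    "Co", "Ni", "Cu", "Zn", "Ga", "Ge", "As", "Se", "Zr", "Ag", "Cd", "Sn",
    "Sb", "Te", "Pt", "Au", "Hg", "Pb",
)
_ELEMENT_INDEX = {sym: i for i, sym in enumerate(ELEMENTS)}

# One-hot block layout: element(42) | degree(6: 0..5) | num_h(5: 0..4)
# | formal charge(5: -2..+2) | aromatic flag(1) | in-ring flag(1)  = 60.
_N_ELEM = len(ELEMENTS)
_N_DEGREE = 6
_N_NUMH = 5
_N_CHARGE = 5
FEATURE_DIM = _N_ELEM + _N_DEGREE + _N_NUMH + _N_CHARGE + 2
FEATURE_LAYOUT = {
    "version": 1,
    "blocks": [
        {"name": "element", "size": _N_ELEM, "values": list(ELEMENTS)},
        {"name": "degree", "size": _N_DEGREE, "values": list(range(_N_DEGREE))},
        {"name": "num_h", "size": _N_NUMH, "values": list(range(_N_NUMH))},
        {"name": "charge", "size": _N_CHARGE, "values": list(range(-2, 3))},
        {"name": "aromatic", "size": 1},
        {"name": "in_ring", "size": 1},
    ],
}


def featurize_atom(element: str, degree: int, num_h: int, charge: int,
                   aromatic: bool, in_ring: bool) -> np.ndarray:
    """Build the 60-dimensional one-hot feature vector of one atom.

    Parameters
    ----------
    element
        Element symbol; must be one of the 42 supported symbols.
    degree
        Number of bonded heavy-atom neighbours, 0-5.
    num_h
        Number of (implicit plus explicit) hydrogens, 0-4.
    charge
        Formal charge, -2..+2.
    aromatic, in_ring
        Atom-level flags.

    Returns
    -------
    numpy.ndarray
        Binary vector of length 60 with four one-hot blocks plus two flags,
        so its sum is 4, 5 or 6.
    """
    if element not in _ELEMENT_INDEX:
        raise ValueError(f"unsupported element symbol: {element!r}")
    if not 0 <= degree < _N_DEGREE:
        raise ValueError(f"degree {degree} outside 0..{_N_DEGREE - 1}")
    if not 0 <= num_h < _N_NUMH:
        raise ValueError(f"hydrogen count {num_h} outside 0..{_N_NUMH - 1}")
    if not -2 <= charge <= 2:
        raise ValueError(f"formal charge {charge} outside -2..+2")
    v = np.zeros(FEATURE_DIM)
    v[_ELEMENT_INDEX[element]] = 1.0
    v[_N_ELEM + degree] = 1.0
    v[_N_ELEM + _N_DEGREE + num_h] = 1.0
    v[_N_ELEM + _N_DEGREE + _N_NUMH + charge + 2] = 1.0
    if aromatic:
        v[FEATURE_DIM - 2] = 1.0
    if in_ring:
        v[FEATURE_DIM - 1] = 1.0
    return v


def build_adjacency(bonds: Iterable[tuple[int, int, BondType]],
                    n_atoms: int) -> np.ndarray:
    """Build the [5, N, N] binary adjacency stack from a typed bond list.

    The self channel is set to the identity; each real bond fills a
    symmetric pair of entries in its type's channel.  A pair of atoms may
    carry at most one bond type, and self-loops must not be listed (the
    self channel is implicit).
    """
    A = np.zeros((N_BOND_CHANNELS, n_atoms, n_atoms))
    A[BondType.SELF] = np.eye(n_atoms)
    seen: dict[tuple[int, int], BondType] = {}
    for i, j, btype in bonds:
        btype = BondType(btype)
        if i == j:
            raise ValueError(f"self-bond listed for atom {i}; the self channel is implicit")
        if not (0 <= i < n_atoms and 0 <= j < n_atoms):
            raise ValueError(f"bond ({i},{j}) outside 0..{n_atoms - 1}")
        if btype == BondType.SELF:
            raise ValueError("SELF is not a listable bond type")
        key = (min(i, j), max(i, j))
        if key in seen:
            if seen[key] != btype:
                raise ValueError(f"conflicting bond types for atom pair {key}")
            raise ValueError(f"duplicate bond for atom pair {key}")
        seen[key] = btype
        A[btype, i, j] = 1.0
        A[btype, j, i] = 1.0
    return A


def bonds_from_adjacency(A: np.ndarray) -> set[tuple[int, int, BondType]]:
    """Recover the typed bond set (i < j) from an adjacency stack."""
    out: set[tuple[int, int, BondType]] = set()
    for btype in BondType:
        if btype == BondType.SELF:
            continue
        ii, jj = np.nonzero(np.triu(A[btype], k=1))
        for i, j in zip(ii, jj):
            out.add((int(i), int(j), btype))
    return out


@dataclass
class MolecularGraph:
    """A molecule as a typed graph with features and optional coordinates.

    Attributes
    ----------
    elements
        Heavy-atom element symbols, length N.
    A
        Binary [5, N, N] adjacency stack; channel 0 is the identity.
    H_init
        [N, 60] initial one-hot atom features.
    C
        Optional [N, 3] coordinates (arbitrary length units).
    id
        Free-form label (e.g. the source SMILES or SDF title).
    """

    elements: tuple[str, ...]
    A: np.ndarray
    H_init: np.ndarray
    C: np.ndarray | None = None
    id: str = ""

    def __post_init__(self) -> None:
        n = len(self.elements)
        if self.A.shape != (N_BOND_CHANNELS, n, n):
            raise ValueError(f"adjacency shape {self.A.shape} != (5, {n}, {n})")
        if self.H_init.shape[0] != n:
            raise ValueError("H_init row count does not match atom count")
        if self.C is not None and self.C.shape != (n, 3):
            raise ValueError(f"coordinate shape {self.C.shape} != ({n}, 3)")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def bonds(self) -> set[tuple[int, int, BondType]]:
        return bonds_from_adjacency(self.A)

    def neighbor_mask(self) -> np.ndarray:
        """[N, N] indicator of the neighbour sets N(i), which include i."""
        return (self.A.sum(axis=0) > 0).astype(float)

    def permuted(self, perm: Sequence[int]) -> "MolecularGraph":
        """Return the graph with atoms reindexed by ``perm`` (new index of old atom k is perm[k])."""
        perm = np.asarray(perm)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        return MolecularGraph(
            elements=tuple(self.elements[k] for k in inv),
            A=self.A[:, inv][:, :, inv],
            H_init=self.H_init[inv],
            C=None if self.C is None else self.C[inv],
            id=self.id,
        )


# ---------------------------------------------------------------------------
# RDKit-backed construction


_RDKIT_BOND = {
    "SINGLE": BondType.SINGLE,
    "DOUBLE": BondType.DOUBLE,
    "TRIPLE": BondType.TRIPLE,
    "AROMATIC": BondType.AROMATIC,
}


def _graph_from_rdkit(mol, coords: np.ndarray | None, label: str) -> MolecularGraph:
    elements = tuple(a.GetSymbol() for a in mol.GetAtoms())
    bonds = []
    for b in mol.GetBonds():
        name = str(b.GetBondType())
        if name not in _RDKIT_BOND:
            raise ValueError(f"unsupported bond type {name} in {label!r}")
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _RDKIT_BOND[name]))
    A = build_adjacency(bonds, mol.GetNumAtoms())
    H = np.stack([
        featurize_atom(
            a.GetSymbol(),
            degree=min(a.GetDegree(), _N_DEGREE - 1),
            num_h=min(a.GetTotalNumHs(), _N_NUMH - 1),
            charge=int(np.clip(a.GetFormalCharge(), -2, 2)),
            aromatic=a.GetIsAromatic(),
            in_ring=a.IsInRing(),
        )
        for a in mol.GetAtoms()
    ]) if mol.GetNumAtoms() else np.zeros((0, FEATURE_DIM))
    return MolecularGraph(elements=elements, A=A, H_init=H, C=coords, id=label)


def mol_from_smiles(smiles: str, embed_3d: bool = False,
                    seed: int = 0) -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    Hydrogens stay implicit (heavy-atom graph); aromatic ring bonds map to
    the aromatic channel.  With ``embed_3d`` a single conformer is embedded
    with a seeded distance-geometry run; molecules that fail to embed fall
    back to a deterministic 2-D layout lifted to z=0, with a warning.
    """
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    coords = None
    if embed_3d:
        coords = _embed_coordinates(mol, seed, smiles)
    return _graph_from_rdkit(mol, coords, smiles)


def _embed_coordinates(mol, seed: int, label: str) -> np.ndarray:
    from rdkit import Chem
    from rdkit.Chem import AllChem

    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    ok = AllChem.EmbedMolecule(molh, params)
    if ok == 0:
        conf = Chem.RemoveHs(molh).GetConformer()
    else:
        logger.warning("3-D embedding failed for %r; using flat 2-D layout", label)
        AllChem.Compute2DCoords(mol)
        conf = mol.GetConformer()
    return np.array([[conf.GetAtomPosition(i).x,
                      conf.GetAtomPosition(i).y,
                      conf.GetAtomPosition(i).z]
                     for i in range(conf.GetNumAtoms())])


# ---------------------------------------------------------------------------
# Dataset readers


def read_csv_dataset(path: str | Path, smiles_col: str = "smiles",
                     target_col: str = "target", embed_3d: bool = False,
                     seed: int = 0) -> list[tuple[MolecularGraph, float]]:
    """Read a (SMILES, target) dataset from CSV.

    Rows whose SMILES cannot be parsed are skipped with a logged warning;
    the skip count is logged at the end.
    """
    df = pd.read_csv(path)
    for col in (smiles_col, target_col):
        if col not in df.columns:
            raise KeyError(
                f"column {col!r} not in {path}; available: {list(df.columns)}")
    records: list[tuple[MolecularGraph, float]] = []
    skipped = 0
    for smiles, target in zip(df[smiles_col], df[target_col]):
        try:
            graph = mol_from_smiles(str(smiles), embed_3d=embed_3d, seed=seed)
        except ValueError:
            logger.warning("skipping unparseable SMILES: %r", smiles)
            skipped += 1
            continue
        records.append((graph, float(target)))
    if skipped:
        logger.warning("skipped %d of %d rows in %s", skipped, len(df), path)
    return records


def read_sdf_dataset(path: str | Path,
                     property_field: str = "target") -> list[tuple[MolecularGraph, float]]:
    """Read a V2000 SDF with 3-D coordinates and a named property field.

    Coordinates are taken from the atom block as written (no re-embedding).
    Records missing the property field are skipped with a warning.  Records
    are parsed without valence sanitization so that synthetic (chemically
    unconstrained) graphs round-trip.
    """
    from rdkit import Chem

    if Path(path).stat().st_size == 0:
        return []
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    records: list[tuple[MolecularGraph, float]] = []
    for k, mol in enumerate(supplier):
        if mol is None:
            logger.warning("skipping unreadable SDF record %d", k)
            continue
        if not mol.HasProp(property_field):
            logger.warning("SDF record %d lacks property %r; skipped", k, property_field)
            continue
        target = float(mol.GetProp(property_field))
        mol.UpdatePropertyCache(strict=False)  # hydrogen counts without valence checks
        Chem.FastFindRings(mol)
        conf = mol.GetConformer()
        coords = np.array([[conf.GetAtomPosition(i).x,
                            conf.GetAtomPosition(i).y,
                            conf.GetAtomPosition(i).z]
                           for i in range(mol.GetNumAtoms())])
        label = mol.GetProp("_Name") if mol.HasProp("_Name") else f"record-{k}"
        records.append((_graph_from_rdkit(mol, coords, label), target))
    return records


def write_featurized(records: Sequence[tuple[MolecularGraph, float]],
                     path: str | Path) -> None:
    """Dump featurized graphs as a compressed .npz plus a JSON layout sidecar.

    Arrays are stored per record (adjacency stack, initial features,
    coordinates where present, target); ``<path>.json`` records the feature
    block layout so downstream consumers can interpret the 60 columns.
    """
    import json

    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    for k, (g, y) in enumerate(records):
        arrays[f"A_{k}"] = g.A
        arrays[f"H_{k}"] = g.H_init
        if g.C is not None:
            arrays[f"C_{k}"] = g.C
        arrays[f"y_{k}"] = np.array(y)
    np.savez_compressed(path, n_records=np.array(len(records)), **arrays)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(FEATURE_LAYOUT, indent=2))
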