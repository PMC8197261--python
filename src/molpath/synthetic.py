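"""Synthetic molecular graphs with known structure-property ground truth.

The generator draws connected random graphs (a degree-capped random tree
plus optional ring-closing edges), assigns element symbols and typed
bonds, and places atoms with Gaussian 3-D coordinates scaled to unit mean
bond length.  Targets come from one of four exactly known rules, each
designed to be informative for one feature-extraction path:

* ``composition`` — sum of per-element weights (node path);
* ``bondtype``    — weighted count of bond types (edge path);
* ``geometry``    — mean pairwise Euclidean distance (3-D path);
* ``mixed``       — composition + bondtype (multi-path).

Chemical validity is deliberately not enforced: the model consumes graphs,
not molecules, and unconstrained graphs keep the ground truth exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .molgraph import (BondType, MolecularGraph, build_adjacency,
                       featurize_atom)

logger = logging.getLogger(__name__)

__all__ = ["SynthSpec", "SynthRecord", "COMPOSITION_WEIGHTS", "BOND_WEIGHTS",
           "random_molecular_graph", "noiseless_property", "make_dataset",
           "matched_bondtype_pair", "write_sdf", "write_csv"]

# per-element weights of the composition target
COMPOSITION_WEIGHTS = {"C": 1.0, "N": 2.0, "O": 3.0, "S": 4.0}
_DEFAULT_ELEMENT_WEIGHT = 0.5

# per-bond-type weights of the bondtype target
BOND_WEIGHTS = {BondType.SINGLE: 1.0, BondType.DOUBLE: 3.0,
                BondType.TRIPLE: 5.0, BondType.AROMATIC: 2.0}

_MAX_DEGREE = 5  # featurization bounds the degree block at 5


@dataclass
class SynthSpec:
    """Study conditions for one synthetic dataset."""

    n_molecules: int = 400
    atoms_range: tuple[int, int] = (4, 12)
    element_probs: dict[str, float] = field(default_factory=lambda: {
        "C": 0.5, "N": 0.2, "O": 0.2, "S": 0.1})
    bond_probs: dict[BondType, float] = field(default_factory=lambda: {
        BondType.SINGLE: 0.6, BondType.DOUBLE: 0.2,
        BondType.TRIPLE: 0.1, BondType.AROMATIC: 0.1})
    ring_prob: float = 0.3
    mode: str = "composition"   # composition | bondtype | geometry | mixed
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for probs in (self.element_probs, self.bond_probs):
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"probabilities sum to {total}, not 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.mode not in ("composition", "bondtype", "geometry", "mixed"):
            raise ValueError(f"unknown task mode {self.mode!r}")


@dataclass
class SynthRecord:
    graph: MolecularGraph
    target: float
    noiseless_target: float


def _random_bonds(n: int, spec: SynthSpec,
                  rng: np.random.Generator) -> list[tuple[int, int, BondType]]:
    """Connected random graph: degree-capped random-attachment tree plus
    optional ring-closing edges."""
    types = list(spec.bond_probs)
    probs = np.array([spec.bond_probs[t] for t in types])
    degree = np.zeros(n, dtype=int)
    bonds: list[tuple[int, int, BondType]] = []

    def draw_type() -> BondType:
        return types[rng.choice(len(types), p=probs)]

    for i in range(1, n):
        candidates = [j for j in range(i) if degree[j] < _MAX_DEGREE]
        j = int(rng.choice(candidates))
        bonds.append((j, i, draw_type()))
        degree[i] += 1
        degree[j] += 1
    if n >= 3 and rng.random() < spec.ring_prob:
        bonded = {(min(i, j), max(i, j)) for i, j, _ in bonds}
        open_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)
                      if (i, j) not in bonded
                      and degree[i] < _MAX_DEGREE and degree[j] < _MAX_DEGREE]
        if open_pairs:
            i, j = open_pairs[int(rng.choice(len(open_pairs)))]
            bonds.append((i, j, draw_type()))
    return bonds


def _featurize_graph(elements: Sequence[str],
                     bonds: Sequence[tuple[int, int, BondType]]) -> np.ndarray:
    n = len(elements)
    g = nx.Graph((i, j) for i, j, _ in bonds)
    g.add_nodes_from(range(n))
    in_cycle = set().union(*nx.cycle_basis(g)) if n else set()
    degree = np.zeros(n, dtype=int)
    aromatic = np.zeros(n, dtype=bool)
    for i, j, btype in bonds:
        degree[i] += 1
        degree[j] += 1
        if btype == BondType.AROMATIC:
            aromatic[i] = aromatic[j] = True
    return np.stack([
        featurize_atom(elements[i], degree=int(degree[i]), num_h=0, charge=0,
                       aromatic=bool(aromatic[i]), in_ring=i in in_cycle)
        for i in range(n)
    ])


def random_molecular_graph(spec: SynthSpec,
                           rng: np.random.Generator) -> MolecularGraph:
    """Draw one connected random molecular graph with 3-D coordinates."""
    lo, hi = spec.atoms_range
    n = int(rng.integers(lo, hi + 1))
    symbols = list(spec.element_probs)
    elements = tuple(symbols[k] for k in
                     rng.choice(len(symbols), size=n,
                                p=[spec.element_probs[s] for s in symbols]))
    bonds = _random_bonds(n, spec, rng)
    coords = rng.standard_normal((n, 3))
    if bonds:
        lengths = [np.linalg.norm(coords[i] - coords[j]) for i, j, _ in bonds]
        coords = coords / np.mean(lengths)  # unit mean bond length
    return MolecularGraph(elements=elements,
                          A=build_adjacency(bonds, n),
                          H_init=_featurize_graph(elements, bonds),
                          C=coords,
                          id=f"synth-{rng.integers(0, 2**31):d}")


def noiseless_property(graph: MolecularGraph, mode: str) -> float:
    """Exact ground-truth target of a graph under a task mode."""
    if mode == "composition":
        return float(sum(COMPOSITION_WEIGHTS.get(e, _DEFAULT_ELEMENT_WEIGHT)
                         for e in graph.elements))
    if mode == "bondtype":
        return float(sum(BOND_WEIGHTS[btype] for _, _, btype in graph.bonds))
    if mode == "geometry":
        if graph.C is None:
            raise ValueError("geometry mode requires coordinates")
        n = graph.n_atoms
        if n < 2:
            return 0.0
        diffs = graph.C[:, None, :] - graph.C[None, :, :]
        dist = np.sqrt((diffs ** 2).sum(-1))
        iu = np.triu_indices(n, k=1)
        return float(dist[iu].mean())
    if mode == "mixed":
        return (noiseless_property(graph, "composition")
                + noiseless_property(graph, "bondtype"))
    raise ValueError(f"unknown task mode {mode!r}")


def make_dataset(spec: SynthSpec) -> list[SynthRecord]:
    """n_molecules records with target = truth + Gaussian(0, noise_sd)."""
    rng = np.random.default_rng(spec.seed)
    records = []
    for _ in range(spec.n_molecules):
        graph = random_molecular_graph(spec, rng)
        truth = noiseless_property(graph, spec.mode)
        noise = rng.normal(0.0, spec.noise_sd) if spec.noise_sd else 0.0
        records.append(SynthRecord(graph=graph, target=truth + noise,
                                   noiseless_target=truth))
    return records


def matched_bondtype_pair(spec: SynthSpec, rng: np.random.Generator
                          ) -> tuple[MolecularGraph, MolecularGraph]:
    """Two graphs identical except one single bond swapped to double.

    Neither bond type touches the atom features or connectivity, so a
    model seeing only unlabeled connectivity (node path) cannot tell them
    apart, while bond-type-aware models (edge path) can.
    """
    while True:
        graph = random_molecular_graph(spec, rng)
        singles = [b for b in graph.bonds if b[2] == BondType.SINGLE]
        if singles:
            break
    i, j, _ = sorted(singles)[0]
    bonds = {b for b in graph.bonds if b != (i, j, BondType.SINGLE)}
    bonds.add((i, j, BondType.DOUBLE))
    twin = MolecularGraph(elements=graph.elements,
                          A=build_adjacency(bonds, graph.n_atoms),
                          H_init=graph.H_init.copy(),
                          C=None if graph.C is None else graph.C.copy(),
                          id=graph.id + "-twin")
    return graph, twin


# ---------------------------------------------------------------------------
# writers (dialects the molgraph readers consume)

_SDF_BOND_CODE = {BondType.SINGLE: 1, BondType.DOUBLE: 2,
                  BondType.TRIPLE: 3, BondType.AROMATIC: 4}


def write_sdf(records: Sequence[SynthRecord], path: str | Path,
              property_field: str = "target") -> None:
    """Write records as a V2000 SDF with coordinates and the target as a
    named property field; round-trips through ``read_sdf_dataset``."""
    lines: list[str] = []
    for rec in records:
        g = rec.graph
        bonds = sorted(g.bonds)
        lines += [g.id, "  molpath", ""]
        lines.append(f"{g.n_atoms:3d}{len(bonds):3d}  0  0  0  0  0  0  0  0999 V2000")
        coords = g.C if g.C is not None else np.zeros((g.n_atoms, 3))
        for sym, (x, y, z) in zip(g.elements, coords):
            lines.append(f"{x:10.4f}{y:10.4f}{z:10.4f} {sym:<3s} 0  0  0  0  0  0  0  0  0  0  0  0")
        for i, j, btype in bonds:
            lines.append(f"{i + 1:3d}{j + 1:3d}{_SDF_BOND_CODE[btype]:3d}  0")
        lines += ["M  END", f">  <{property_field}>", repr(rec.target), "", "$$$$"]
    Path(path).write_text("\n".join(lines) + "\n")


def write_csv(records: Sequence[SynthRecord], path: str | Path,
              smiles_col: str = "smiles", target_col: str = "target") -> None:
    """Write a (SMILES, target) CSV for records RDKit can serialize.

    Synthetic graphs may be chemically invalid (by design); records whose
    graph cannot be expressed as parseable SMILES are skipped with a
    warning.
    """
    from rdkit import Chem

    rows = []
    skipped = 0
    for rec in records:
        smiles = _graph_to_smiles(rec.graph)
        if smiles is None or Chem.MolFromSmiles(smiles) is None:
            skipped += 1
            continue
        rows.append((smiles, rec.target))
    if skipped:
        logger.warning("write_csv: skipped %d records not expressible as "
                       "valid SMILES", skipped)
    import pandas as pd
    pd.DataFrame(rows, columns=[smiles_col, target_col]).to_csv(path, index=False)


def _graph_to_smiles(graph: MolecularGraph) -> str | None:
    from rdkit import Chem

    _ORDER = {BondType.SINGLE: Chem.BondType.SINGLE,
              BondType.DOUBLE: Chem.BondType.DOUBLE,
              BondType.TRIPLE: Chem.BondType.TRIPLE,
              BondType.AROMATIC: Chem.BondType.AROMATIC}
    mol = Chem.RWMol()
    for sym in graph.elements:
        mol.AddAtom(Chem.Atom(sym))
    for i, j, btype in sorted(graph.bonds):
        mol.AddBond(int(i), int(j), _ORDER[btype])
    try:
        Chem.SanitizeMol(mol)
        return Chem.MolToSmiles(mol)
    except Exception:
        return None
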