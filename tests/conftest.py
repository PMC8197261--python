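"""Shared fixtures: tiny hand-built graphs, random graphs, and naive
per-node loop oracles for the three path updates.

The oracles implement the update equations exactly as written — an
explicit double loop over nodes and neighbours — and are kept independent
of the vectorized implementations they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from molpath.molgraph import BondType, MolecularGraph, build_adjacency
from molpath.paths import relative_coords
from molpath.synthetic import SynthSpec, random_molecular_graph


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def neighbor_indices(graph: MolecularGraph) -> list[list[int]]:
    mask = graph.neighbor_mask()
    return [np.nonzero(mask[i])[0].tolist() for i in range(graph.n_atoms)]


# ---------------------------------------------------------------------------
# loop oracles


def node_path_loop(H, graph, W_np, B_np, W_n, B_n):
    N, M = H.shape
    out = np.zeros((N, M))
    for i in range(N):
        acc = np.zeros(M)
        for j in neighbor_indices(graph)[i]:
            P_ij = relu(W_np @ np.concatenate([H[i], H[j]]) + B_np)
            acc += W_n @ P_ij
        out[i] = relu(acc + B_n)
    return out


def edge_path_loop(H, graph, W_ep, B_ep, W_e, B_e, w, c):
    N, M = H.shape
    E = np.zeros((N, N))
    for b in range(5):
        E += w[b] * graph.A[b]
    E += c
    out = np.zeros((N, M))
    for i in range(N):
        acc = np.zeros(M)
        for j in neighbor_indices(graph)[i]:
            P_ij = relu(E[i, j] * (W_ep @ np.concatenate([H[i], H[j]])) + B_ep)
            acc += W_e @ P_ij
        out[i] = relu(acc + B_e)
    return out


def threed_path_loop(H, graph, W_tp, B_tp, W_tq, B_tq, W_t=None, W_ns=None,
                     include_self=True):
    N, M = H.shape
    R = relative_coords(graph.C)
    out = np.zeros((N, M))
    for i in range(N):
        acc = np.zeros(M)
        for j in neighbor_indices(graph)[i]:
            pre = np.zeros(M)
            for k in range(3):
                pre += R[k, i, j] * (W_tp @ np.concatenate([H[i], H[j]]))
            acc += W_tq @ relu(pre + B_tp)
        Q_i = relu(acc + B_tq)
        if include_self:
            out[i] = relu(W_t @ np.concatenate([H[i], Q_i]))
        else:
            out[i] = relu(W_ns @ Q_i)
    return out


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def two_atom_graph() -> MolecularGraph:
    """Two carbons joined by a single bond, feature width 1, on the x axis."""
    return MolecularGraph(
        elements=("C", "C"),
        A=build_adjacency([(0, 1, BondType.SINGLE)], 2),
        H_init=np.array([[1.0], [2.0]]),
        C=np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]),
    )


@pytest.fixture
def benzene_like_graph() -> MolecularGraph:
    """Six-ring of aromatic bonds (adjacency only; features are ones)."""
    bonds = [(i, (i + 1) % 6, BondType.AROMATIC) for i in range(6)]
    return MolecularGraph(
        elements=("C",) * 6,
        A=build_adjacency(bonds, 6),
        H_init=np.ones((6, 1)),
    )


def random_graph(rng: np.random.Generator, n_atoms: int | None = None,
                 M: int = 4) -> MolecularGraph:
    """Random connected graph with coordinates and random positive features
    of width ``M`` (replacing the one-hot featurization)."""
    lo_hi = (n_atoms, n_atoms) if n_atoms else (2, 8)
    spec = SynthSpec(atoms_range=lo_hi, seed=0)
    g = random_molecular_graph(spec, rng)
    g.H_init = np.abs(rng.standard_normal((g.n_atoms, M)))
    return g
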