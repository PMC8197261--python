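"""The three feature-extraction path layers: node, edge, and 3-D.

Each path updates per-atom feature vectors H [N, M] once per layer:

* node path — pair features from concatenated endpoint features, summed
  over the neighbourhood (which includes the atom itself);
* edge path — the same pair features scaled by a scalar edge parameter
  E_ij derived from the five bond-type adjacency channels through a 1x1
  convolution (learnable weights per channel plus a bias), or fixed to the
  categorical values 1..5;
* 3-D path — pair features scaled by the summed relative coordinates
  x_i - x_j (+ y, z), accumulated into an intermediate feature Q_i, then
  recombined with the atom's own feature (or not, in the no-self variant).

All activations are rectified linear units, so outputs are nonnegative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tensor import Tensor, concat
from .molgraph import MolecularGraph, N_BOND_CHANNELS

__all__ = [
    "NodePathParams",
    "EdgePathParams",
    "ThreeDPathParams",
    "FIXED_EDGE_WEIGHTS",
    "glorot",
    "node_path_update",
    "edge_parameter_matrix",
    "edge_path_update",
    "relative_coords",
    "threed_path_update",
    "neighbor_sets",
]

# Fixed categorical edge values per channel: 1 self, 2 single, 3 double,
# 4 triple, 5 aromatic.
FIXED_EDGE_WEIGHTS = np.array([1.0, 2.0, 3.0, 4.0, 5.0])


def glorot(rng: np.random.Generator, fan_out: int, fan_in: int) -> Tensor:
    """Glorot-uniform initialized weight matrix [fan_out, fan_in]."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=(fan_out, fan_in)),
                  requires_grad=True)


def _zeros(*shape: int) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


@dataclass
class NodePathParams:
    """One node-path layer: pair map (W_np, B_np) and update map (W_n, B_n)."""

    W_np: Tensor  # [M, 2M]
    B_np: Tensor  # [M]
    W_n: Tensor   # [M, M]
    B_n: Tensor   # [M]

    @classmethod
    def init(cls, M: int, rng: np.random.Generator) -> "NodePathParams":
        return cls(W_np=glorot(rng, M, 2 * M), B_np=_zeros(M),
                   W_n=glorot(rng, M, M), B_n=_zeros(M))

    def tensors(self) -> dict[str, Tensor]:
        return {"W_np": self.W_np, "B_np": self.B_np,
                "W_n": self.W_n, "B_n": self.B_n}


@dataclass
class EdgePathParams:
    """One edge-path layer.

    ``w`` (one scalar per bond channel) and ``c`` realize the 1x1
    convolution across the five adjacency channels.  In ``fixed_mode`` they
    hold the categorical values (1..5, bias 0) and are excluded from
    training.
    """

    W_ep: Tensor  # [M, 2M]
    B_ep: Tensor  # [M]
    W_e: Tensor   # [M, M]
    B_e: Tensor   # [M]
    w: Tensor     # [5] edge-channel weights
    c: Tensor     # scalar edge bias
    fixed_mode: bool = False

    @classmethod
    def init(cls, M: int, rng: np.random.Generator,
             fixed_mode: bool = False) -> "EdgePathParams":
        if fixed_mode:
            w = Tensor(FIXED_EDGE_WEIGHTS.copy())
            c = Tensor(0.0)
        else:
            # warm start at the categorical values, scaled down
            w = Tensor(0.1 * FIXED_EDGE_WEIGHTS, requires_grad=True)
            c = Tensor(0.0, requires_grad=True)
        return cls(W_ep=glorot(rng, M, 2 * M), B_ep=_zeros(M),
                   W_e=glorot(rng, M, M), B_e=_zeros(M),
                   w=w, c=c, fixed_mode=fixed_mode)

    def tensors(self) -> dict[str, Tensor]:
        return {"W_ep": self.W_ep, "B_ep": self.B_ep, "W_e": self.W_e,
                "B_e": self.B_e, "w": self.w, "c": self.c}


@dataclass
class ThreeDPathParams:
    """One 3-D-path layer; ``include_self`` selects recombination with the
    atom's own feature (W_t on H_i || Q_i) versus the no-self variant
    (a separate square matrix W_ns on Q_i alone)."""

    W_tp: Tensor  # [M, 2M]
    B_tp: Tensor  # [M]
    W_tq: Tensor  # [M, M]
    B_tq: Tensor  # [M]
    W_t: Tensor   # [M, 2M], used when include_self
    W_ns: Tensor  # [M, M], used when not include_self
    include_self: bool = True

    @classmethod
    def init(cls, M: int, rng: np.random.Generator,
             include_self: bool = True) -> "ThreeDPathParams":
        return cls(W_tp=glorot(rng, M, 2 * M), B_tp=_zeros(M),
                   W_tq=glorot(rng, M, M), B_tq=_zeros(M),
                   W_t=glorot(rng, M, 2 * M) if include_self else Tensor(np.zeros((M, 2 * M))),
                   W_ns=glorot(rng, M, M) if not include_self else Tensor(np.zeros((M, M))),
                   include_self=include_self)

    def tensors(self) -> dict[str, Tensor]:
        d = {"W_tp": self.W_tp, "B_tp": self.B_tp,
             "W_tq": self.W_tq, "B_tq": self.B_tq}
        if self.include_self:
            d["W_t"] = self.W_t
        else:
            d["W_ns"] = self.W_ns
        return d


# ---------------------------------------------------------------------------
# forward computations


def _check_width(H: Tensor, W: Tensor, path: str) -> None:
    M2 = W.shape[1]
    if 2 * H.shape[-1] != M2:
        raise ValueError(
            f"{path} path: feature width {H.shape[-1]} incompatible with "
            f"pair weight expecting {M2 // 2}")


def _pair_concat(H: Tensor) -> Tensor:
    """[N, N, 2M] tensor of concatenated endpoint features H_i || H_j."""
    n = H.shape[0]
    left = H.reshape(n, 1, -1) + Tensor(np.zeros((1, n, 1)))
    right = H.reshape(1, n, -1) + Tensor(np.zeros((n, 1, 1)))
    return concat([left, right], axis=-1)


def neighbor_sets(graph: MolecularGraph) -> list[list[int]]:
    """Neighbour sets N(i), each including i itself, as sorted index lists."""
    mask = graph.neighbor_mask()
    return [sorted(np.nonzero(mask[i])[0].tolist()) for i in range(graph.n_atoms)]


def node_path_update(H: Tensor, graph: MolecularGraph,
                     params: NodePathParams) -> Tensor:
    """One node-path layer: H_i <- relu(sum_{j in N(i)} W_n P_ij + B_n) with
    pair features P_ij = relu(W_np (H_i || H_j) + B_np)."""
    _check_width(H, params.W_np, "node")
    pair = _pair_concat(H)
    P = (pair @ _t(params.W_np) + params.B_np).relu()          # [N, N, M]
    mask = Tensor(graph.neighbor_mask()[:, :, None])
    agg = (mask * P).sum(axis=1)                                # [N, M]
    return (agg @ _t(params.W_n) + params.B_n).relu()


def edge_parameter_matrix(A: np.ndarray, w, c) -> "np.ndarray | Tensor":
    """Edge parameters E = sum_b w[b] A[b] + c — a 1x1 convolution over the
    five bond channels.  Differentiable when ``w``/``c`` are tensors."""
    if A.shape[0] != N_BOND_CHANNELS:
        raise ValueError(f"adjacency stack must have {N_BOND_CHANNELS} channels")
    if isinstance(w, Tensor) or isinstance(c, Tensor):
        w = w if isinstance(w, Tensor) else Tensor(w)
        c = c if isinstance(c, Tensor) else Tensor(c)
        return (w.reshape(N_BOND_CHANNELS, 1, 1) * Tensor(A)).sum(axis=0) + c
    return np.tensordot(np.asarray(w, dtype=float), A, axes=1) + float(c)


def edge_path_update(H: Tensor, graph: MolecularGraph,
                     params: EdgePathParams) -> Tensor:
    """One edge-path layer: as the node path, but the pair pre-activation
    W_ep (H_i || H_j) is scaled by the scalar edge parameter E_ij before the
    bias is added."""
    _check_width(H, params.W_ep, "edge")
    E = edge_parameter_matrix(graph.A, params.w, params.c)
    if not isinstance(E, Tensor):
        E = Tensor(E)
    pair = _pair_concat(H)
    n = H.shape[0]
    P = (E.reshape(n, n, 1) * (pair @ _t(params.W_ep)) + params.B_ep).relu()
    mask = Tensor(graph.neighbor_mask()[:, :, None])
    agg = (mask * P).sum(axis=1)
    return (agg @ _t(params.W_e) + params.B_e).relu()


def relative_coords(C: np.ndarray | None) -> np.ndarray:
    """Relative coordinates R[k][i][j] = C[i][k] - C[j][k], shape [3, N, N].

    Antisymmetric in (i, j) with zero diagonal; invariant to translating C.
    """
    if C is None:
        raise ValueError(
            "graph has no coordinates; embed a conformer or load from SDF")
    C = np.asarray(C, dtype=float)
    return (C[:, None, :] - C[None, :, :]).transpose(2, 0, 1)


def threed_path_update(H: Tensor, graph: MolecularGraph,
                       params: ThreeDPathParams) -> Tensor:
    """One 3-D-path layer.

    P_ij = relu(sum_k R(k)_ij * W_tp (H_i || H_j) + B_tp);
    Q_i  = relu(sum_{j in N(i)} W_tq P_ij + B_tq);
    then H_i <- relu(W_t (H_i || Q_i)) with the self node included, or
    H_i <- relu(W_ns Q_i) without it.
    """
    _check_width(H, params.W_tp, "3d")
    R = relative_coords(graph.C)
    S = Tensor(R.sum(axis=0)[:, :, None])   # sum over x, y, z axes
    pair = _pair_concat(H)
    P = (S * (pair @ _t(params.W_tp)) + params.B_tp).relu()
    mask = Tensor(graph.neighbor_mask()[:, :, None])
    Q = ((mask * P).sum(axis=1) @ _t(params.W_tq) + params.B_tq).relu()
    if params.include_self:
        return (concat([H, Q], axis=-1) @ _t(params.W_t)).relu()
    return (Q @ _t(params.W_ns)).relu()


def _t(W: Tensor) -> Tensor:
    """Transpose of a 2-D weight tensor (differentiable)."""
    return W.T
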