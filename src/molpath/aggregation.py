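"""Combine per-path node features into a single node feature.

The default aggregator is a per-node attention over the enabled paths:
every atom gets a scalar score per path (computed from its initial feature
and that path's output), scores pass through a softmax, and the weighted
sum of path features is linearly mixed and rectified.  Concatenation,
summation and elementwise-maximum aggregators are provided as
alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from ._tensor import Tensor, concat, maximum, softmax

__all__ = [
    "PATH_ORDER",
    "AttentionParams",
    "AltAggParams",
    "attention_scores",
    "attention_weights",
    "aggregate_attention",
    "aggregate_alt",
]

# canonical ordering of paths everywhere (score columns, CSV exports, ...)
PATH_ORDER = ("node", "edge", "3d")


def _ordered(paths) -> list[str]:
    return [p for p in PATH_ORDER if p in paths]


@dataclass
class AttentionParams:
    """Attention aggregator parameters.

    ``W_att`` is [1, 2M] so each (atom, path) score is a scalar, as the
    per-node softmax over paths requires.
    """

    W_init: Tensor                 # [M, M]
    W_k: dict[str, Tensor]         # per enabled path, [M, M]
    W_att: Tensor                  # [1, 2M]
    W_agg: Tensor                  # [M, M]

    @classmethod
    def init(cls, M: int, paths, rng: np.random.Generator) -> "AttentionParams":
        from .paths import glorot
        return cls(W_init=glorot(rng, M, M),
                   W_k={p: glorot(rng, M, M) for p in _ordered(paths)},
                   W_att=glorot(rng, 1, 2 * M),
                   W_agg=glorot(rng, M, M))

    def tensors(self) -> dict[str, Tensor]:
        d = {"W_init": self.W_init, "W_att": self.W_att, "W_agg": self.W_agg}
        for p, w in self.W_k.items():
            d[f"W_k_{p}"] = w
        return d


@dataclass
class AltAggParams:
    """Concat/sum/max aggregator; only the matrix matching ``mode`` exists."""

    mode: str                      # "concat" | "sum" | "max"
    W: Tensor                      # [M, M*P] for concat, else [M, M]

    @classmethod
    def init(cls, mode: str, M: int, n_paths: int,
             rng: np.random.Generator) -> "AltAggParams":
        from .paths import glorot
        if mode == "concat":
            return cls(mode=mode, W=glorot(rng, M, M * n_paths))
        if mode in ("sum", "max"):
            return cls(mode=mode, W=glorot(rng, M, M))
        raise ValueError(f"unknown aggregation mode {mode!r}")

    def tensors(self) -> dict[str, Tensor]:
        return {f"W_{self.mode}": self.W}


def attention_scores(H_init: Tensor | np.ndarray,
                     H_paths: Mapping[str, Tensor],
                     params: AttentionParams) -> Tensor:
    """Per-atom, per-path attention scores e, shape [N, P].

    e_i^p = W_att (relu(H_i^init W_init) || relu(H_i^p W_p)); columns follow
    the canonical path order restricted to the enabled paths.
    """
    if not isinstance(H_init, Tensor):
        H_init = Tensor(H_init)
    order = _ordered(params.W_k)
    for p in order:
        if p not in H_paths:
            raise KeyError(f"path {p!r} missing from H_paths")
    left = (H_init @ params.W_init).relu()            # [N, M]
    cols = []
    for p in order:
        right = (H_paths[p] @ params.W_k[p]).relu()   # [N, M]
        cols.append(concat([left, right], axis=-1) @ params.W_att.T)  # [N, 1]
    return concat(cols, axis=-1)                      # [N, P]


def attention_weights(e: Tensor | np.ndarray) -> Tensor:
    """Softmax of the scores across paths: rows sum to one."""
    if not isinstance(e, Tensor):
        e = Tensor(e)
    return softmax(e, axis=-1)


def aggregate_attention(H_paths: Mapping[str, Tensor], alpha: Tensor,
                        params: AttentionParams) -> Tensor:
    """H_i = relu(W_agg sum_p alpha_i^p H_i^p)."""
    if not isinstance(alpha, Tensor):
        alpha = Tensor(alpha)
    order = _ordered(params.W_k)
    mixed = None
    for k, p in enumerate(order):
        term = _column(alpha, k) * H_paths[p]
        mixed = term if mixed is None else mixed + term
    return (mixed @ params.W_agg.T).relu()


def _column(t: Tensor, k: int) -> Tensor:
    """Differentiable selection of column k as an [N, 1] tensor."""
    n, p = t.shape
    sel = np.zeros((p, 1))
    sel[k, 0] = 1.0
    return t @ Tensor(sel)


def aggregate_alt(H_paths: Mapping[str, Tensor],
                  params: AltAggParams) -> Tensor:
    """Concat / sum / elementwise-max aggregation followed by a linear mix
    and rectification."""
    order = _ordered(H_paths)
    hs = [H_paths[p] for p in order]
    if params.mode == "concat":
        if params.W.shape[1] != hs[0].shape[-1] * len(hs):
            raise ValueError(
                f"concat aggregator expects {params.W.shape[1] // hs[0].shape[-1]} "
                f"paths, got {len(hs)}")
        merged = concat(hs, axis=-1)
    elif params.mode == "sum":
        merged = hs[0]
        for h in hs[1:]:
            merged = merged + h
    elif params.mode == "max":
        merged = hs[0]
        for h in hs[1:]:
            merged = maximum(merged, h)
    else:
        raise ValueError(f"unknown aggregation mode {params.mode!r}")
    return (merged @ params.W.T).relu()
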