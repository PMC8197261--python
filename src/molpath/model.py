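"""Model assembly: path stacks, aggregator, sum readout, and affine head.

A :class:`MultiPathModel` runs each enabled path as its own stream of T
stacked layers starting from the initial atom features (the default), or —
with ``aggregate_placement="every_layer"`` — re-aggregates the paths after
every layer.  Atom features are then summed per dimension into one
molecular vector and mapped to the prediction by a single affine head;
classification passes the raw output through a logistic at inference.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from ._tensor import Tensor
from .aggregation import (PATH_ORDER, AltAggParams, AttentionParams,
                          aggregate_alt, aggregate_attention,
                          attention_scores, attention_weights)
from .molgraph import FEATURE_DIM, FEATURE_LAYOUT, MolecularGraph
from .paths import (EdgePathParams, NodePathParams, ThreeDPathParams,
                    edge_path_update, node_path_update, threed_path_update)

__all__ = ["ModelConfig", "MultiPathModel", "build_model", "forward",
           "forward_tensor", "count_parameters", "parameter_report",
           "save_checkpoint", "load_checkpoint"]

_PATH_PARAM_CLS = {"node": NodePathParams, "edge": EdgePathParams,
                   "3d": ThreeDPathParams}
_PATH_UPDATE = {"node": node_path_update, "edge": edge_path_update,
                "3d": threed_path_update}


@dataclass
class ModelConfig:
    """Hyperparameters of a multi-path model.

    ``feature_dim`` is both the input featurization width and the hidden
    width of every layer; ``paths`` is any nonempty subset of
    {node, edge, 3d}.  With a single path the aggregator is an identity
    pass-through and allocates no parameters.
    """

    feature_dim: int = FEATURE_DIM
    n_layers: int = 2
    paths: tuple[str, ...] = ("node", "edge", "3d")
    aggregation: str = "attention"          # attention | concat | sum | max
    aggregate_placement: str = "final"      # final | every_layer
    edge_mode: str = "learned"              # learned | fixed
    include_self_3d: bool = True
    task: str = "regression"                # regression | classification
    seed: int = 0

    def __post_init__(self) -> None:
        self.paths = tuple(p for p in PATH_ORDER if p in self.paths)
        if not self.paths:
            raise ValueError("at least one path must be enabled (node, edge, 3d)")
        if self.feature_dim < 1 or self.n_layers < 1:
            raise ValueError("feature_dim and n_layers must be positive")
        if self.aggregation not in ("attention", "concat", "sum", "max"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        if self.aggregate_placement not in ("final", "every_layer"):
            raise ValueError(f"unknown placement {self.aggregate_placement!r}")
        if self.edge_mode not in ("learned", "fixed"):
            raise ValueError(f"unknown edge mode {self.edge_mode!r}")
        if self.task not in ("regression", "classification"):
            raise ValueError(f"unknown task {self.task!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["paths"] = list(self.paths)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelConfig":
        d = dict(d)
        d["paths"] = tuple(d.get("paths", ("node", "edge", "3d")))
        return cls(**d)


@dataclass
class MultiPathModel:
    """A built model: per-path layer stacks, aggregator, and head."""

    config: ModelConfig
    path_layers: dict[str, list]            # path -> [params per layer]
    agg: AttentionParams | AltAggParams | None
    W_fc: Tensor                            # [1, M]
    b_fc: Tensor                            # scalar
    target_mean: float = 0.0
    target_std: float = 1.0
    temp_heads: dict[str, tuple[Tensor, Tensor]] = field(default_factory=dict)

    # -- parameter access ----------------------------------------------------
    def path_tensors(self, path: str) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for t, layer in enumerate(self.path_layers[path]):
            for name, tensor in layer.tensors().items():
                out[f"{path}/layer{t}/{name}"] = tensor
        return out

    def agg_tensors(self) -> dict[str, Tensor]:
        if self.agg is None:
            return {}
        return {f"agg/{k}": v for k, v in self.agg.tensors().items()}

    def head_tensors(self) -> dict[str, Tensor]:
        return {"head/W_fc": self.W_fc, "head/b_fc": self.b_fc}

    def named_tensors(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for p in self.config.paths:
            out.update(self.path_tensors(p))
        out.update(self.agg_tensors())
        out.update(self.head_tensors())
        return out

    def predict(self, graph: MolecularGraph) -> float:
        """Prediction on the original target scale (probability for
        classification)."""
        return forward(self, graph)


def build_model(config: ModelConfig) -> MultiPathModel:
    """Allocate and seed all parameters; identical seeds give bitwise
    identical models."""
    rng = np.random.default_rng(config.seed)
    M = config.feature_dim
    layers: dict[str, list] = {}
    for p in config.paths:                      # canonical order fixes the draw order
        cls = _PATH_PARAM_CLS[p]
        stack = []
        for _ in range(config.n_layers):
            if p == "edge":
                stack.append(cls.init(M, rng, fixed_mode=config.edge_mode == "fixed"))
            elif p == "3d":
                stack.append(cls.init(M, rng, include_self=config.include_self_3d))
            else:
                stack.append(cls.init(M, rng))
        layers[p] = stack
    agg: AttentionParams | AltAggParams | None = None
    if len(config.paths) > 1:
        if config.aggregation == "attention":
            agg = AttentionParams.init(M, config.paths, rng)
        else:
            agg = AltAggParams.init(config.aggregation, M, len(config.paths), rng)
    from .paths import glorot
    W_fc = glorot(rng, 1, M)
    b_fc = Tensor(0.0, requires_grad=True)
    return MultiPathModel(config=config, path_layers=layers, agg=agg,
                          W_fc=W_fc, b_fc=b_fc)


# ---------------------------------------------------------------------------
# forward passes


def _run_path_stream(model: MultiPathModel, graph: MolecularGraph,
                     path: str, H: Tensor) -> Tensor:
    for layer in model.path_layers[path]:
        H = _PATH_UPDATE[path](H, graph, layer)
    return H


def _aggregate(model: MultiPathModel, H0: Tensor,
               H_paths: dict[str, Tensor]) -> tuple[Tensor, Tensor | None]:
    if len(model.config.paths) == 1:
        return H_paths[model.config.paths[0]], None
    if isinstance(model.agg, AttentionParams):
        e = attention_scores(H0, H_paths, model.agg)
        alpha = attention_weights(e)
        return aggregate_attention(H_paths, alpha, model.agg), alpha
    return aggregate_alt(H_paths, model.agg), None


def forward_tensor(model: MultiPathModel, graph: MolecularGraph
                   ) -> tuple[Tensor, Tensor | None]:
    """Differentiable forward pass.

    Returns the raw (standardized-scale) scalar prediction tensor and, when
    attention aggregation is active, the [N, P] attention weights.
    """
    M = model.config.feature_dim
    if graph.H_init.shape[1] != M:
        raise ValueError(
            f"graph feature width {graph.H_init.shape[1]} != model feature_dim {M}")
    if "3d" in model.config.paths and graph.C is None:
        raise ValueError("3d path enabled but graph has no coordinates")
    H0 = Tensor(graph.H_init)
    alpha: Tensor | None = None
    if model.config.aggregate_placement == "final":
        H_paths = {p: _run_path_stream(model, graph, p, H0)
                   for p in model.config.paths}
        H, alpha = _aggregate(model, H0, H_paths)
    else:  # every_layer: one shared stream, re-aggregated after each layer
        H = H0
        for t in range(model.config.n_layers):
            H_paths = {p: _PATH_UPDATE[p](H, graph, model.path_layers[p][t])
                       for p in model.config.paths}
            H, alpha = _aggregate(model, H0, H_paths)
    vec = H.sum(axis=0)                                   # [M] molecular vector
    pred = vec.reshape(1, -1) @ model.W_fc.T + model.b_fc
    return pred.reshape(()), alpha


def forward(model: MultiPathModel, graph: MolecularGraph,
            return_attention: bool = False):
    """Predict on the original target scale.

    Regression outputs are de-standardized with the training-split scaler;
    classification outputs are logistic probabilities.  With
    ``return_attention`` also returns the [N, P] attention-weight array.
    """
    raw, alpha = forward_tensor(model, graph)
    if model.config.task == "classification":
        value = float(1.0 / (1.0 + np.exp(-raw.data)))
    else:
        value = float(raw.data) * model.target_std + model.target_mean
    if return_attention:
        return value, None if alpha is None else alpha.data.copy()
    return value


# ---------------------------------------------------------------------------
# parameter accounting and checkpointing


def parameter_report(model: MultiPathModel) -> dict[str, int]:
    """Scalar parameter count per group (each path, aggregator, head)."""
    report: dict[str, int] = {}
    for p in model.config.paths:
        report[p] = sum(t.data.size for t in model.path_tensors(p).values())
    report["aggregator"] = sum(t.data.size for t in model.agg_tensors().values())
    report["head"] = sum(t.data.size for t in model.head_tensors().values())
    return report


def count_parameters(model: MultiPathModel, trainable_only: bool = False) -> int:
    """Exact count of scalar parameters in the model."""
    return sum(t.data.size for t in model.named_tensors().values()
               if t.requires_grad or not trainable_only)


def save_checkpoint(model: MultiPathModel, path: str | Path) -> None:
    """Write a single-file archive: config JSON plus named parameter arrays."""
    meta = {
        "config": model.config.to_dict(),
        "layout_version": FEATURE_LAYOUT["version"],
        "target_mean": model.target_mean,
        "target_std": model.target_std,
        "groups": parameter_report(model),
    }
    arrays = {name.replace("/", "__"): t.data
              for name, t in model.named_tensors().items()}
    np.savez(path, __meta__=np.array(json.dumps(meta)), **arrays)


def load_checkpoint(path: str | Path,
                    expected_config: ModelConfig | None = None) -> MultiPathModel:
    """Rebuild a model from :func:`save_checkpoint` output.

    Raises if the featurization layout version differs from the current
    package, or if ``expected_config`` is given and does not match.
    """
    with np.load(path) as data:
        meta = json.loads(str(data["__meta__"]))
        if meta["layout_version"] != FEATURE_LAYOUT["version"]:
            raise ValueError(
                f"checkpoint featurization layout v{meta['layout_version']} "
                f"!= current v{FEATURE_LAYOUT['version']}")
        config = ModelConfig.from_dict(meta["config"])
        if expected_config is not None and config.to_dict() != expected_config.to_dict():
            raise ValueError("checkpoint config does not match the expected config")
        model = build_model(config)
        model.target_mean = float(meta["target_mean"])
        model.target_std = float(meta["target_std"])
        for name, tensor in model.named_tensors().items():
            stored = data[name.replace("/", "__")]
            if stored.shape != tensor.data.shape:
                raise ValueError(f"shape mismatch for {name}: "
                                 f"{stored.shape} vs {tensor.data.shape}")
            tensor.data = stored.astype(np.float64)
    return model
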