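"""Masked graph convolutional network.

The network re-weights message passing with a single learnable edge
mask shared by every layer.  The mask is parameterized as
``M = sigmoid(V + V^T)`` over a free matrix ``V``, which guarantees
symmetry and entries strictly inside (0, 1).  Each layer propagates

    H_{l+1} = phi( ((M + I) ⊙ S) H_l Theta_l ),        S = D̃^{-1/2} Ã D̃^{-1/2}

so that edge (i, j) contributes with weight ``(M_ij + [i == j]) S_ij``;
the identity term keeps the filter from degenerating to the null
operator when the mask is driven to zero.  After the first layer the
node embeddings are concatenated with the per-region anatomical
statistics, a second masked layer follows, node embeddings are
mean-pooled and a dense readout produces the prediction (two outputs
for joint crystallized/fluid cognition regression, class logits for
classification).

Everything is NumPy; gradients are analytic (see
:func:`maskgnn.objective.loss_and_grads`) and verified against central
finite differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .graph import BrainGraph

__all__ = [
    "EdgeMask",
    "LayerParams",
    "ModelParams",
    "GraphSample",
    "mask_from_params",
    "sigmoid",
    "maskgnn_layer",
    "fuse_as",
    "forward",
    "gradient_wrt_as",
    "init_params",
    "save_params",
    "load_params",
]

CHECKPOINT_VERSION = 1

_ACTIVATIONS = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda z: (z > 0).astype(float)),
    "identity": (lambda z: z, lambda z: np.ones_like(z)),
    "tanh": (np.tanh, lambda z: 1.0 - np.tanh(z) ** 2),
}


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


def mask_from_params(v_params: np.ndarray) -> np.ndarray:
    """Symmetric edge mask ``sigmoid(V + V^T)`` with entries in (0, 1)."""
    v = np.asarray(v_params, dtype=float)
    if v.ndim != 2 or v.shape[0] != v.shape[1]:
        raise ValueError("mask parameter matrix must be square")
    return sigmoid(v + v.T)


@dataclass
class EdgeMask:
    """Free parameter matrix V and the derived symmetric mask."""

    v_params: np.ndarray

    def __post_init__(self) -> None:
        self.v_params = np.asarray(self.v_params, dtype=float)
        if self.v_params.ndim != 2 or self.v_params.shape[0] != self.v_params.shape[1]:
            raise ValueError("v_params must be square")

    @property
    def mask(self) -> np.ndarray:
        return mask_from_params(self.v_params)

    @property
    def n_nodes(self) -> int:
        return self.v_params.shape[0]


@dataclass
class LayerParams:
    weight: np.ndarray  # (d_in, d_out)
    bias: np.ndarray | None = None  # (d_out,)
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")

    def apply_activation(self, z: np.ndarray) -> np.ndarray:
        return _ACTIVATIONS[self.activation][0](z)

    def activation_grad(self, z: np.ndarray) -> np.ndarray:
        return _ACTIVATIONS[self.activation][1](z)


@dataclass
class ModelParams:
    """Full parameter set; the edge mask is a single shared instance."""

    mask: EdgeMask
    layer1: LayerParams
    layer2: LayerParams
    readout_weight: np.ndarray  # (d2, n_outputs)
    readout_bias: np.ndarray  # (n_outputs,)
    pooling: str = "mean"
    dropout: float = 0.0  # applied to the pooled vector during training only

    def __post_init__(self) -> None:
        if self.pooling != "mean":
            raise ValueError("only mean pooling is implemented")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")

    @property
    def n_outputs(self) -> int:
        return self.readout_weight.shape[1]

    def copy(self) -> "ModelParams":
        return ModelParams(
            mask=EdgeMask(self.mask.v_params.copy()),
            layer1=LayerParams(
                self.layer1.weight.copy(),
                None if self.layer1.bias is None else self.layer1.bias.copy(),
                self.layer1.activation,
            ),
            layer2=LayerParams(
                self.layer2.weight.copy(),
                None if self.layer2.bias is None else self.layer2.bias.copy(),
                self.layer2.activation,
            ),
            readout_weight=self.readout_weight.copy(),
            readout_bias=self.readout_bias.copy(),
            pooling=self.pooling,
            dropout=self.dropout,
        )


@dataclass
class GraphSample:
    """One subject: graph, anatomical statistics and supervision target."""

    graph: BrainGraph
    as_features: np.ndarray  # (Q, d_c); d_c may be 0
    label: np.ndarray  # regression targets or integer class
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.as_features = np.atleast_2d(np.asarray(self.as_features, dtype=float))
        if self.as_features.size == 0:
            self.as_features = np.zeros((self.graph.n_nodes, 0))
        if self.as_features.shape[0] != self.graph.n_nodes:
            raise ValueError("anatomical statistics row count must equal node count")
        self.label = np.atleast_1d(np.asarray(self.label))


def maskgnn_layer(
    h: np.ndarray,
    graph: BrainGraph,
    mask: np.ndarray,
    layer: LayerParams,
) -> np.ndarray:
    """One masked graph convolution: phi(((M + I) ⊙ S) H Theta)."""
    p = (mask + np.eye(mask.shape[0])) * graph.norm_adjacency
    z = p @ (h @ layer.weight)
    if layer.bias is not None:
        z = z + layer.bias
    return layer.apply_activation(z)


def fuse_as(h1: np.ndarray, as_features: np.ndarray) -> np.ndarray:
    """Node-wise concatenation of layer-1 embeddings with anatomy."""
    as_features = np.atleast_2d(np.asarray(as_features, dtype=float))
    if as_features.size == 0:
        return h1
    if h1.shape[0] != as_features.shape[0]:
        raise ValueError("node count mismatch between embeddings and AS table")
    return np.hstack([h1, as_features])


def forward(
    sample: GraphSample,
    params: ModelParams,
    dropout_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, dict]:
    """Full forward pass.

    Returns the prediction and an intermediates cache exposing, in
    particular, the last-layer node embeddings (consumed by the
    manifold regularizer) and the fused features (consumed by the
    gradient-saliency interpretation).  ``dropout_mask`` is a
    pre-drawn 0/1 vector over the pooled embedding; ``None`` means
    evaluation mode (no dropout, fully deterministic).
    """
    graph = sample.graph
    m = params.mask.mask
    p = (m + np.eye(m.shape[0])) * graph.norm_adjacency

    u1 = sample.graph.node_features @ params.layer1.weight
    z1 = p @ u1
    if params.layer1.bias is not None:
        z1 = z1 + params.layer1.bias
    a1 = params.layer1.apply_activation(z1)

    h1 = fuse_as(a1, sample.as_features)

    u2 = h1 @ params.layer2.weight
    z2 = p @ u2
    if params.layer2.bias is not None:
        z2 = z2 + params.layer2.bias
    h2 = params.layer2.apply_activation(z2)

    pooled = h2.mean(axis=0)
    if dropout_mask is not None and params.dropout > 0:
        pooled_kept = pooled * dropout_mask / (1.0 - params.dropout)
    else:
        pooled_kept = pooled
    prediction = pooled_kept @ params.readout_weight + params.readout_bias

    cache = {
        "propagator": p,
        "z1": z1,
        "a1": a1,
        "fused": h1,
        "z2": z2,
        "embeddings": h2,
        "pooled": pooled,
        "pooled_kept": pooled_kept,
        "dropout_mask": dropout_mask,
    }
    return prediction, cache


def gradient_wrt_as(
    sample: GraphSample,
    params: ModelParams,
    output_index: int = 0,
) -> np.ndarray:
    """Gradient of one scalar model output w.r.t. the fused AS block.

    Backpropagates d prediction[output_index] / d C through the
    readout, pooling and second masked layer; the AS block enters the
    network only there, so the chain stops at the fusion boundary.
    Returns a (Q, d_c) matrix.
    """
    prediction, cache = forward(sample, params)
    if not 0 <= output_index < prediction.size:
        raise ValueError("output_index out of range")
    q = sample.graph.n_nodes
    d1 = cache["a1"].shape[1]
    d_h2 = np.full((q, 1), 1.0 / q) * params.readout_weight[:, output_index][None, :]
    d_z2 = d_h2 * params.layer2.activation_grad(cache["z2"])
    d_u2 = cache["propagator"].T @ d_z2
    d_h1 = d_u2 @ params.layer2.weight.T
    return d_h1[:, d1:]


def init_params(
    rng: np.random.Generator,
    n_nodes: int,
    d_in: int,
    d_c: int,
    hidden1: int = 32,
    hidden2: int = 32,
    n_outputs: int = 1,
    dropout: float = 0.0,
    bias: bool = True,
) -> ModelParams:
    """Glorot-initialized parameters; mask parameters start at zero
    so every mask entry begins at the neutral value 0.5."""

    def glorot(fan_in: int, fan_out: int) -> np.ndarray:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_in, fan_out))

    return ModelParams(
        mask=EdgeMask(np.zeros((n_nodes, n_nodes))),
        layer1=LayerParams(
            weight=glorot(d_in, hidden1),
            bias=np.zeros(hidden1) if bias else None,
            activation="relu",
        ),
        layer2=LayerParams(
            weight=glorot(hidden1 + d_c, hidden2),
            bias=np.zeros(hidden2) if bias else None,
            activation="identity",
        ),
        readout_weight=glorot(hidden2, n_outputs),
        readout_bias=np.zeros(n_outputs),
        dropout=dropout,
    )


def save_params(params: ModelParams, path: str | Path) -> None:
    """Versioned flat-array checkpoint with a JSON shape manifest."""
    path = Path(path)
    manifest = {
        "version": CHECKPOINT_VERSION,
        "pooling": params.pooling,
        "dropout": params.dropout,
        "activation1": params.layer1.activation,
        "activation2": params.layer2.activation,
        "has_bias1": params.layer1.bias is not None,
        "has_bias2": params.layer2.bias is not None,
        "shapes": {
            "v_params": list(params.mask.v_params.shape),
            "w1": list(params.layer1.weight.shape),
            "w2": list(params.layer2.weight.shape),
            "readout_weight": list(params.readout_weight.shape),
        },
    }
    arrays = {
        "v_params": params.mask.v_params,
        "w1": params.layer1.weight,
        "w2": params.layer2.weight,
        "readout_weight": params.readout_weight,
        "readout_bias": params.readout_bias,
        "manifest": np.frombuffer(json.dumps(manifest).encode(), dtype=np.uint8),
    }
    if params.layer1.bias is not None:
        arrays["b1"] = params.layer1.bias
    if params.layer2.bias is not None:
        arrays["b2"] = params.layer2.bias
    np.savez(path, **arrays)


def load_params(path: str | Path) -> ModelParams:
    with np.load(path) as data:
        manifest = json.loads(bytes(data["manifest"]).decode())
        if manifest["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {manifest['version']}")
        return ModelParams(
            mask=EdgeMask(data["v_params"]),
            layer1=LayerParams(
                weight=data["w1"],
                bias=data["b1"] if manifest["has_bias1"] else None,
                activation=manifest["activation1"],
            ),
            layer2=LayerParams(
                weight=data["w2"],
                bias=data["b2"] if manifest["has_bias2"] else None,
                activation=manifest["activation2"],
            ),
            readout_weight=data["readout_weight"],
            readout_bias=data["readout_bias"],
            pooling=manifest["pooling"],
            dropout=float(manifest["dropout"]),
        )
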