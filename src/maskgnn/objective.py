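"""Composite training objective.

    L = L_e(ŷ, y) + α · L_manifold + L_mask

* ``L_e`` — mean squared error for regression or cross-entropy on
  logits for classification.
* ``L_manifold = ½ Σ_q Σ_{j∈N(q)} ‖h_q − h_j‖² = trace(HᵀLH)`` —
  smoothness of the last-layer node embeddings over graph edges,
  countering oversmoothing control via a monitored threshold.
* ``L_mask = λ₁‖M‖₁ + λ₂‖M‖_F² + λ₃‖MMᵀ − I‖_F`` — sparsity plus a
  soft orthonormality pull on the edge mask.  The λ₃ term uses the
  plain (unsquared) Frobenius norm and is non-smooth exactly at
  MMᵀ = I, where the zero subgradient is taken.

The module also provides :func:`loss_and_grads`, the analytic reverse-
mode differentiation of the total loss through the two masked graph
convolutions, the anatomy fusion, pooling and readout — verified
against central finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import GraphSample, ModelParams, forward

__all__ = [
    "LossConfig",
    "manifold_loss",
    "manifold_loss_pairwise",
    "mask_penalty",
    "mask_penalty_grad",
    "prediction_loss",
    "total_loss",
    "loss_and_grads",
    "Gradients",
]


@dataclass
class LossConfig:
    alpha: float = 0.001  # manifold weight
    lambda1: float = 1e-4  # L1 mask sparsity
    lambda2: float = 1e-4  # squared-Frobenius mask shrinkage
    lambda3: float = 1e-4  # orthonormality pull
    manifold_threshold: float = float("inf")  # monitoring bound
    task: str = "regression"

    def __post_init__(self) -> None:
        if min(self.alpha, self.lambda1, self.lambda2, self.lambda3) < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.task not in ("regression", "classification"):
            raise ValueError("task must be 'regression' or 'classification'")


def manifold_loss(h: np.ndarray, laplacian: np.ndarray) -> float:
    """Smoothness of node embeddings over the graph, trace(HᵀLH)."""
    h = np.atleast_2d(np.asarray(h, dtype=float))
    return float(np.trace(h.T @ laplacian @ h))


def manifold_loss_pairwise(h: np.ndarray, adjacency: np.ndarray) -> float:
    """Equivalent pairwise form ½ Σ_q Σ_{j∈N(q)} ‖h_q − h_j‖²."""
    h = np.atleast_2d(np.asarray(h, dtype=float))
    total = 0.0
    q = adjacency.shape[0]
    for i in range(q):
        for j in range(q):
            if adjacency[i, j]:
                diff = h[i] - h[j]
                total += float(diff @ diff)
    return 0.5 * total


def mask_penalty(mask: np.ndarray, cfg: LossConfig) -> float:
    """λ₁‖M‖₁ + λ₂‖M‖_F² + λ₃‖MMᵀ − I‖_F."""
    m = np.asarray(mask, dtype=float)
    if m.shape[0] != m.shape[1]:
        raise ValueError("mask must be square")
    l1 = np.abs(m).sum()
    fro2 = (m * m).sum()
    ortho = np.linalg.norm(m @ m.T - np.eye(m.shape[0]), "fro")
    return float(cfg.lambda1 * l1 + cfg.lambda2 * fro2 + cfg.lambda3 * ortho)


def mask_penalty_grad(mask: np.ndarray, cfg: LossConfig) -> np.ndarray:
    """Gradient of :func:`mask_penalty` w.r.t. the mask entries."""
    m = np.asarray(mask, dtype=float)
    grad = cfg.lambda1 * np.sign(m) + 2.0 * cfg.lambda2 * m
    e = m @ m.T - np.eye(m.shape[0])
    norm = np.linalg.norm(e, "fro")
    if norm > 0 and cfg.lambda3 > 0:
        grad = grad + cfg.lambda3 * 2.0 * (e @ m) / norm
    return grad


def prediction_loss(pred: np.ndarray, label: np.ndarray, task: str) -> float:
    """MSE (mean over batch and targets) or cross-entropy on logits.

    Accepts single samples (1-D) or batches (2-D, one row per sample).
    """
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    if task == "regression":
        label = np.atleast_2d(np.asarray(label, dtype=float))
        if pred.shape != label.shape:
            raise ValueError(f"shape mismatch: pred {pred.shape} vs label {label.shape}")
        return float(np.mean((pred - label) ** 2))
    if task == "classification":
        label = np.atleast_1d(np.asarray(label)).astype(int).ravel()
        if label.size != pred.shape[0]:
            raise ValueError("one integer class label per sample required")
        if (label < 0).any() or (label >= pred.shape[1]).any():
            raise ValueError("class label out of range")
        shifted = pred - pred.max(axis=1, keepdims=True)
        log_z = np.log(np.exp(shifted).sum(axis=1))
        return float(np.mean(log_z - shifted[np.arange(label.size), label]))
    raise ValueError(f"unknown task {task!r}")


def total_loss(
    pred: np.ndarray,
    label: np.ndarray,
    h: np.ndarray,
    laplacian: np.ndarray,
    mask: np.ndarray,
    cfg: LossConfig,
) -> tuple[float, dict[str, float]]:
    """Weighted sum of the three components, with the breakdown."""
    le = prediction_loss(pred, label, cfg.task)
    lman = manifold_loss(h, laplacian)
    lmask = mask_penalty(mask, cfg)
    total = le + cfg.alpha * lman + lmask
    components = {
        "prediction": le,
        "manifold": lman,
        "mask_penalty": lmask,
        "total": total,
    }
    return total, components


@dataclass
class Gradients:
    """Gradients of the batch total loss w.r.t. every free parameter."""

    v_params: np.ndarray
    w1: np.ndarray
    b1: np.ndarray | None
    w2: np.ndarray
    b2: np.ndarray | None
    readout_weight: np.ndarray
    readout_bias: np.ndarray


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max()
    e = np.exp(z)
    return e / e.sum()


def loss_and_grads(
    batch: list[GraphSample],
    params: ModelParams,
    cfg: LossConfig,
    dropout_masks: list[np.ndarray] | None = None,
) -> tuple[float, dict[str, float], Gradients]:
    """Batch total loss and its analytic gradients.

    The prediction loss and the manifold term are averaged over the
    batch; the mask penalty enters once.  ``dropout_masks`` (one 0/1
    vector per sample over the pooled embedding) are pre-drawn by the
    caller so that the loss is an exact deterministic function of the
    parameters — which is what makes finite-difference verification
    possible.
    """
    if not batch:
        raise ValueError("empty batch")
    n = len(batch)
    m = params.mask.mask
    q = m.shape[0]

    g = Gradients(
        v_params=np.zeros_like(params.mask.v_params),
        w1=np.zeros_like(params.layer1.weight),
        b1=None if params.layer1.bias is None else np.zeros_like(params.layer1.bias),
        w2=np.zeros_like(params.layer2.weight),
        b2=None if params.layer2.bias is None else np.zeros_like(params.layer2.bias),
        readout_weight=np.zeros_like(params.readout_weight),
        readout_bias=np.zeros_like(params.readout_bias),
    )
    d_mask = np.zeros((q, q))
    le_sum = 0.0
    lman_sum = 0.0

    for s_idx, sample in enumerate(batch):
        dmask = dropout_masks[s_idx] if dropout_masks is not None else None
        pred, cache = forward(sample, params, dropout_mask=dmask)
        p = cache["propagator"]
        h2 = cache["embeddings"]
        lap = sample.graph.laplacian

        # prediction-loss gradient at the output
        if cfg.task == "regression":
            y = np.asarray(sample.label, dtype=float).ravel()
            le_sum += float(np.mean((pred - y) ** 2))
            d_pred = 2.0 * (pred - y) / (pred.size * n)
        else:
            y = int(np.asarray(sample.label).ravel()[0])
            probs = _softmax(pred)
            le_sum += float(-np.log(probs[y]))
            d_pred = probs.copy()
            d_pred[y] -= 1.0
            d_pred /= n

        lman_sum += manifold_loss(h2, lap)

        # readout
        g.readout_weight += np.outer(cache["pooled_kept"], d_pred)
        g.readout_bias += d_pred
        d_pooled = params.readout_weight @ d_pred
        if dmask is not None and params.dropout > 0:
            d_pooled = d_pooled * dmask / (1.0 - params.dropout)

        # pooling + manifold term both feed the last-layer embeddings
        d_h2 = np.full((q, 1), 1.0 / q) * d_pooled[None, :]
        d_h2 = d_h2 + (cfg.alpha * 2.0 / n) * (lap @ h2)

        # layer 2
        d_z2 = d_h2 * params.layer2.activation_grad(cache["z2"])
        u2 = cache["fused"] @ params.layer2.weight
        d_p = d_z2 @ u2.T
        d_u2 = p.T @ d_z2
        g.w2 += cache["fused"].T @ d_u2
        if g.b2 is not None:
            g.b2 += d_z2.sum(axis=0)
        d_h1 = d_u2 @ params.layer2.weight.T

        # fusion boundary: only the embedding block backpropagates
        d1 = cache["a1"].shape[1]
        d_a1 = d_h1[:, :d1]

        # layer 1
        d_z1 = d_a1 * params.layer1.activation_grad(cache["z1"])
        u1 = sample.graph.node_features @ params.layer1.weight
        d_p += d_z1 @ u1.T
        d_u1 = p.T @ d_z1
        g.w1 += sample.graph.node_features.T @ d_u1
        if g.b1 is not None:
            g.b1 += d_z1.sum(axis=0)

        # propagator -> mask (P = (M + I) ⊙ S, elementwise in M)
        d_mask += d_p * sample.graph.norm_adjacency

    d_mask += mask_penalty_grad(m, cfg)

    # mask -> free parameters: M = sigmoid(V + V^T)
    d_s = d_mask * m * (1.0 - m)
    g.v_params = d_s + d_s.T

    lmask = mask_penalty(m, cfg)
    le = le_sum / n
    lman = lman_sum / n
    total = le + cfg.alpha * lman + lmask
    components = {
        "prediction": le,
        "manifold": lman,
        "mask_penalty": lmask,
        "total": total,
    }
    return total, components, g
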