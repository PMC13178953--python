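"""Edge-level and feature-level model interpretation.

Three views of a trained model:

* **Thresholded mask** — the learned edge mask re-passed through a
  logistic and cut at a display threshold.  Because mask entries lie
  in (0, 1), their logistic lies in (0.5, 0.731), which is why the
  conventional display thresholds 0.52 / 0.53 are meaningful.
* **Gradient saliency** (Grad-RAM for regression targets, Grad-CAM
  for class logits) — the gradient of a scalar model output with
  respect to the fused anatomical-statistics block, multiplied
  elementwise by the feature values, rectified, averaged over nodes
  and subjects, and softmax-normalized into one importance vector.
* **Network summary** — surviving mask edges aggregated into an
  inter-network weight table over named functional networks, the
  input of a chord diagram; intra-network weight is reported
  separately.

A validation utility scores how well the mask ranks planted edges in
synthetic cohorts (area under the ROC curve over the off-diagonal
upper triangle).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import GraphSample, ModelParams, gradient_wrt_as, sigmoid

__all__ = [
    "ThresholdedMask",
    "SaliencyMap",
    "NetworkSummary",
    "DEFAULT_DISPLAY_THRESHOLD",
    "threshold_mask",
    "grad_saliency",
    "network_summary",
    "mask_recovery_score",
]

DEFAULT_DISPLAY_THRESHOLD = 0.52
FIGURE_THRESHOLD = 0.53


@dataclass
class ThresholdedMask:
    values: np.ndarray  # suppressed entries zeroed, kept entries unchanged
    threshold: float

    @property
    def n_edges(self) -> int:
        """Surviving off-diagonal edges, counted once per pair."""
        off = self.values.copy()
        np.fill_diagonal(off, 0.0)
        return int(np.count_nonzero(np.triu(off, 1)))


@dataclass
class SaliencyMap:
    scores: np.ndarray  # length d_c, nonnegative, sums to 1
    mode: str  # grad_ram_regression | grad_cam_classification
    feature_names: list[str] = field(default_factory=list)

    def ranking(self) -> np.ndarray:
        """Feature indices from most to least important."""
        return np.argsort(-self.scores, kind="stable")


@dataclass
class NetworkSummary:
    networks: list[str]
    inter: np.ndarray  # symmetric, nonnegative, zero diagonal
    intra: np.ndarray  # per-network within-network weight


def threshold_mask(mask: np.ndarray, threshold: float = DEFAULT_DISPLAY_THRESHOLD) -> ThresholdedMask:
    """Suppress weak mask entries for display.

    An entry is kept (at its original value) iff ``sigmoid(M_ij) >
    threshold``; the second logistic compresses the already-(0,1)
    mask into (0.5, 0.731), the range in which the display thresholds
    live.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    m = np.asarray(mask, dtype=float)
    keep = sigmoid(m) > threshold
    return ThresholdedMask(values=np.where(keep, m, 0.0), threshold=threshold)


def grad_saliency(
    params: ModelParams,
    samples: list[GraphSample],
    mode: str = "grad_ram_regression",
    output_index: int = 0,
    feature_names: list[str] | None = None,
) -> SaliencyMap:
    """Gradient-weighted activation mapping over anatomical features.

    For each subject, the gradient of the selected model output
    (regression target for Grad-RAM, class logit for Grad-CAM) with
    respect to the fused anatomical block is multiplied elementwise
    with the feature values; the rectified products are averaged over
    nodes, then over subjects, then softmax-normalized.
    """
    if mode not in ("grad_ram_regression", "grad_cam_classification"):
        raise ValueError(f"unknown saliency mode {mode!r}")
    if not samples:
        raise ValueError("at least one sample required")
    d_c = samples[0].as_features.shape[1]
    if d_c == 0:
        raise ValueError("model has no anatomical-statistics block to attribute")
    acc = np.zeros(d_c)
    for sample in samples:
        g = gradient_wrt_as(sample, params, output_index=output_index)
        contrib = np.maximum(g * sample.as_features, 0.0)
        acc += contrib.mean(axis=0)
    acc /= len(samples)
    z = acc - acc.max()
    scores = np.exp(z)
    scores /= scores.sum()
    return SaliencyMap(
        scores=scores,
        mode=mode,
        feature_names=list(feature_names) if feature_names else [],
    )


def network_summary(
    tmask: ThresholdedMask,
    roi_networks: list[str],
    counts: bool = False,
) -> NetworkSummary:
    """Aggregate surviving edges into inter-network weights.

    Entry (a, b), a != b, sums the surviving mask values over ROI
    pairs spanning networks a and b (or counts them with
    ``counts=True``); within-network weight is kept out of the chord
    table and reported separately.
    """
    m = tmask.values
    q = m.shape[0]
    if len(roi_networks) != q:
        raise ValueError("every ROI must be assigned to exactly one network")
    networks = sorted(set(roi_networks))
    index = {name: i for i, name in enumerate(networks)}
    inter = np.zeros((len(networks), len(networks)))
    intra = np.zeros(len(networks))
    for i in range(q):
        for j in range(i + 1, q):
            if m[i, j] == 0:
                continue
            w = 1.0 if counts else m[i, j]
            a, b = index[roi_networks[i]], index[roi_networks[j]]
            if a == b:
                intra[a] += w
            else:
                inter[a, b] += w
                inter[b, a] += w
    return NetworkSummary(networks=networks, inter=inter, intra=intra)


def mask_recovery_score(
    mask: np.ndarray, planted_edges: list[tuple[int, int]]
) -> float:
    """AUC of the mask as a ranker of planted vs non-planted edges.

    Considers every off-diagonal upper-triangle entry a candidate;
    planted edges are the positives.
    """
    from sklearn.metrics import roc_auc_score

    m = np.asarray(mask, dtype=float)
    q = m.shape[0]
    planted = {(min(i, j), max(i, j)) for i, j in planted_edges}
    if not planted:
        raise ValueError("planted edge set is empty")
    n_pairs = q * (q - 1) // 2
    if len(planted) >= n_pairs:
        raise ValueError("planted edge set covers every pair; ranking undefined")
    for i, j in planted:
        if not (0 <= i < j < q):
            raise ValueError(f"planted edge ({i}, {j}) out of range")
    iu, ju = np.triu_indices(q, 1)
    scores = m[iu, ju]
    labels = np.array([(i, j) in planted for i, j in zip(iu, ju)], dtype=int)
    if np.ptp(scores) == 0:
        return 0.5  # constant mask carries no ranking information
    return float(roc_auc_score(labels, scores))
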