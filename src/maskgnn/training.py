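"""Optimization loop, cohort splits and bootstrap evaluation.

Training minimizes the composite objective with Adam (first-order
adaptive optimizer; the L2 weight-decay coefficient is added to the
gradients) and halves the learning rate when the validation loss
plateaus (ReduceLROnPlateau behaviour, patience in epochs).  Repeated
evaluation follows the repeated-random-split convention: each
iteration re-splits the cohort 70/10/20 with a fresh seed, retrains
and evaluates, and variants are compared with paired t-tests on the
per-iteration metrics; resampling with replacement is available
behind a flag.

All feature normalization is per subject, so splits cannot leak test
statistics into training.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as _sstats

from . import features as F
from .graph import BrainGraph, build_adjacency, make_node_features
from .model import GraphSample, ModelParams, forward, init_params
from .objective import Gradients, LossConfig, loss_and_grads
from .synthetic import SyntheticSubject

__all__ = [
    "TrainConfig",
    "EvalReport",
    "prepare_samples",
    "split_cohort",
    "train_model",
    "evaluate",
    "bootstrap_compare",
    "run_experiment",
]


@dataclass
class TrainConfig:
    learning_rate: float = 0.005
    batch_size: int = 32
    max_epochs: int = 50
    weight_decay: float = 1e-6
    scheduler_patience: int = 10
    scheduler_factor: float = 0.5
    split_fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)
    bootstrap_iterations: int = 10
    seed: int = 0
    hidden1: int = 32
    hidden2: int = 32
    dropout: float = 0.0
    stop_on_manifold_breach: bool = False

    def __post_init__(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if min(self.learning_rate, self.batch_size, self.max_epochs) <= 0:
            raise ValueError("learning rate, batch size and epochs must be positive")


@dataclass
class EvalReport:
    task: str
    metrics: dict[str, float]
    per_target: dict[str, dict[str, float]] = field(default_factory=dict)
    n_samples: int = 0


def prepare_samples(
    subjects: list[SyntheticSubject],
    mode: str = "fc_sc",
    use_as: bool = True,
    k: int = 30,
    threshold: float = 0.001,
) -> list[GraphSample]:
    """Run the per-subject feature pipeline and build graph samples.

    The graph source follows the modality set: the FC-derived
    adjacency for any run that includes FC, the SC-derived adjacency
    for SC-only runs.  All normalization statistics are per subject.
    """
    if mode not in ("fc_only", "sc_only", "fc_sc"):
        raise ValueError(f"unknown mode {mode!r}")
    samples = []
    for subject in subjects:
        fc = F.compute_fc(subject.time_series)
        fc_scaled = F.minmax_scale(fc.values, exclude_diagonal=True)
        np.fill_diagonal(fc_scaled, 1.0)
        sc_norm = F.normalize_sc(subject.sc)

        if use_as:
            ints = np.array(
                [
                    F.compute_int(subject.time_series.values[:, r], subject.time_series.tr)[0]
                    for r in range(fc.n_rois)
                ]
            )
            coupling = F.compute_coupling(sc_norm, fc, on_constant="zero")
            morph = F.normalize_as(subject.raw_as)
            as_table = F.assemble_as(
                morph, ints, coupling, feature_names=subject.as_feature_names
            ).values
        else:
            as_table = np.zeros((fc.n_rois, 0))

        graph_source = sc_norm.values if mode == "sc_only" else fc_scaled
        adjacency = build_adjacency(graph_source, k=k, threshold=threshold)
        node_features = make_node_features(fc_scaled, sc_norm.values, mode)
        graph = BrainGraph(adjacency=adjacency, node_features=node_features)
        samples.append(
            GraphSample(
                graph=graph,
                as_features=as_table,
                label=subject.label,
                subject_id=subject.subject_id,
            )
        )
    return samples


def split_cohort(
    subject_ids: list[str],
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> tuple[list[str], list[str], list[str]]:
    """Deterministic disjoint train/validation/test partition."""
    ids = list(subject_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("subject ids must be unique")
    if len(ids) < 10:
        raise ValueError("cohort must contain at least 10 subjects")
    if abs(sum(fractions) - 1.0) > 1e-9 or min(fractions) <= 0:
        raise ValueError("fractions must be positive and sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n = len(ids)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    n_val = max(1, n_val)
    n_train = min(n_train, n - n_val - 1)
    train = [ids[i] for i in order[:n_train]]
    val = [ids[i] for i in order[n_train : n_train + n_val]]
    test = [ids[i] for i in order[n_train + n_val :]]
    return train, val, test


class _Adam:
    """Standard Adam over the flat list of parameter arrays."""

    def __init__(self, arrays: list[np.ndarray], lr: float, weight_decay: float):
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(a) for a in arrays]
        self.v = [np.zeros_like(a) for a in arrays]
        self.t = 0

    def step(self, arrays: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (a, g) in enumerate(zip(arrays, grads)):
            if self.weight_decay:
                g = g + self.weight_decay * a
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            m_hat = self.m[i] / (1 - self.beta1**self.t)
            v_hat = self.v[i] / (1 - self.beta2**self.t)
            a -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _param_arrays(params: ModelParams) -> list[np.ndarray]:
    arrays = [params.mask.v_params, params.layer1.weight]
    if params.layer1.bias is not None:
        arrays.append(params.layer1.bias)
    arrays.append(params.layer2.weight)
    if params.layer2.bias is not None:
        arrays.append(params.layer2.bias)
    arrays += [params.readout_weight, params.readout_bias]
    return arrays


def _grad_arrays(g: Gradients, params: ModelParams) -> list[np.ndarray]:
    arrays = [g.v_params, g.w1]
    if params.layer1.bias is not None:
        arrays.append(g.b1)
    arrays.append(g.w2)
    if params.layer2.bias is not None:
        arrays.append(g.b2)
    arrays += [g.readout_weight, g.readout_bias]
    return arrays


def _validation_loss(
    samples: list[GraphSample], params: ModelParams, cfg: LossConfig
) -> float:
    total, _, _ = loss_and_grads(samples, params, cfg)
    return total


def train_model(
    train_samples: list[GraphSample],
    val_samples: list[GraphSample],
    loss_cfg: LossConfig,
    train_cfg: TrainConfig,
    params: ModelParams | None = None,
) -> tuple[ModelParams, list[dict]]:
    """Mini-batch Adam on the composite loss with plateau LR decay.

    Returns the trained parameters and a per-epoch history of loss
    components, learning rate and validation loss.  Fully reproducible
    from ``train_cfg.seed``.
    """
    if not train_samples or not val_samples:
        raise ValueError("train and validation sets must be nonempty")
    rng = np.random.default_rng(train_cfg.seed)
    first = train_samples[0]
    task = loss_cfg.task
    if params is None:
        if task == "classification":
            n_out = int(max(int(np.asarray(s.label).ravel()[0]) for s in train_samples)) + 1
        else:
            n_out = first.label.size
        params = init_params(
            rng,
            n_nodes=first.graph.n_nodes,
            d_in=first.graph.node_features.shape[1],
            d_c=first.as_features.shape[1],
            hidden1=train_cfg.hidden1,
            hidden2=train_cfg.hidden2,
            n_outputs=n_out,
            dropout=train_cfg.dropout,
        )
    else:
        params = params.copy()

    arrays = _param_arrays(params)
    opt = _Adam(arrays, train_cfg.learning_rate, train_cfg.weight_decay)
    history: list[dict] = []
    best_val = math.inf
    epochs_since_best = 0

    for epoch in range(train_cfg.max_epochs):
        order = rng.permutation(len(train_samples))
        epoch_components = {"prediction": 0.0, "manifold": 0.0, "mask_penalty": 0.0, "total": 0.0}
        n_batches = 0
        for start in range(0, len(order), train_cfg.batch_size):
            batch = [train_samples[i] for i in order[start : start + train_cfg.batch_size]]
            if params.dropout > 0:
                dmasks = [
                    (rng.random(train_cfg.hidden2) >= params.dropout).astype(float)
                    for _ in batch
                ]
            else:
                dmasks = None
            loss, components, grads = loss_and_grads(batch, params, loss_cfg, dmasks)
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: non-finite loss {loss!r}"
                )
            opt.step(arrays, _grad_arrays(grads, params))
            for key in epoch_components:
                epoch_components[key] += components[key]
            n_batches += 1
        for key in epoch_components:
            epoch_components[key] /= n_batches

        val_loss = _validation_loss(val_samples, params, loss_cfg)
        record = {
            "epoch": epoch,
            "lr": opt.lr,
            "val_loss": val_loss,
            **{f"train_{k}": v for k, v in epoch_components.items()},
        }
        history.append(record)

        if epoch_components["manifold"] > loss_cfg.manifold_threshold:
            warnings.warn(
                f"manifold loss {epoch_components['manifold']:.4g} exceeded the "
                f"monitoring threshold {loss_cfg.manifold_threshold:.4g} at epoch {epoch}",
                RuntimeWarning,
                stacklevel=2,
            )
            if train_cfg.stop_on_manifold_breach:
                break

        # ReduceLROnPlateau on the validation loss
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best > train_cfg.scheduler_patience:
                opt.lr *= train_cfg.scheduler_factor
                epochs_since_best = 0

    return params, history


def evaluate(params: ModelParams, test_samples: list[GraphSample], task: str) -> EvalReport:
    """Test-set metrics: RMSE/MAE for regression, accuracy/F1/AUC for
    classification."""
    if not test_samples:
        raise ValueError("empty test set")
    preds = np.array([forward(s, params)[0] for s in test_samples])
    if task == "regression":
        labels = np.array([np.asarray(s.label, dtype=float).ravel() for s in test_samples])
        err = preds - labels
        rmse = float(np.sqrt(np.mean(err**2)))
        mae = float(np.mean(np.abs(err)))
        per_target = {
            f"target_{t}": {
                "rmse": float(np.sqrt(np.mean(err[:, t] ** 2))),
                "mae": float(np.mean(np.abs(err[:, t]))),
            }
            for t in range(labels.shape[1])
        }
        return EvalReport(
            task=task,
            metrics={"rmse": rmse, "mae": mae},
            per_target=per_target,
            n_samples=len(test_samples),
        )
    if task == "classification":
        from sklearn.metrics import accuracy_score, f1_score, roc_auc_score

        labels = np.array([int(np.asarray(s.label).ravel()[0]) for s in test_samples])
        shifted = preds - preds.max(axis=1, keepdims=True)
        probs = np.exp(shifted)
        probs /= probs.sum(axis=1, keepdims=True)
        hard = probs.argmax(axis=1)
        metrics = {
            "accuracy": float(accuracy_score(labels, hard)),
            "f1": float(f1_score(labels, hard)),
        }
        if len(np.unique(labels)) > 1:
            metrics["auc"] = float(roc_auc_score(labels, probs[:, 1]))
        else:
            metrics["auc"] = float("nan")
        return EvalReport(task=task, metrics=metrics, n_samples=len(test_samples))
    raise ValueError(f"unknown task {task!r}")


def run_experiment(
    samples: list[GraphSample],
    loss_cfg: LossConfig,
    train_cfg: TrainConfig,
    split_seed: int | None = None,
) -> tuple[ModelParams, list[dict], EvalReport]:
    """Split, train and evaluate once."""
    ids = [s.subject_id for s in samples]
    by_id = {s.subject_id: s for s in samples}
    tr, va, te = split_cohort(
        ids, train_cfg.split_fractions, split_seed if split_seed is not None else train_cfg.seed
    )
    params, history = train_model(
        [by_id[i] for i in tr], [by_id[i] for i in va], loss_cfg, train_cfg
    )
    report = evaluate(params, [by_id[i] for i in te], loss_cfg.task)
    return params, history, report


def bootstrap_compare(
    variants: dict[str, list[GraphSample]],
    loss_cfg: LossConfig,
    train_cfg: TrainConfig,
    iterations: int = 10,
    seed: int = 0,
    metric: str | None = None,
    resample: bool = False,
) -> dict:
    """Repeated split-train-evaluate comparison of model variants.

    Every variant shares the iteration's split (and, with
    ``resample=True``, a bootstrap resampling of subjects drawn with
    replacement before splitting), so per-iteration metrics are
    paired.  Reports mean ± sd per metric and paired t-test p-values
    of every variant against the first; a comparison with zero
    difference everywhere (e.g. a variant against itself) is reported
    with p-value 1.
    """
    if iterations < 2:
        raise ValueError("at least 2 iterations required")
    names = list(variants)
    metric = metric or ("rmse" if loss_cfg.task == "regression" else "accuracy")
    per_iter: dict[str, list[dict[str, float]]] = {name: [] for name in names}
    master = np.random.default_rng(seed)
    for it in range(iterations):
        iter_seed = int(master.integers(0, 2**31 - 1))
        if resample:
            idx_rng = np.random.default_rng(iter_seed + 1)
            n = len(next(iter(variants.values())))
            draw = idx_rng.integers(0, n, size=n)
        for name in names:
            samples = variants[name]
            if resample:
                samples = [
                    replace(samples[i], subject_id=f"{samples[i].subject_id}#{pos}")
                    for pos, i in enumerate(draw)
                ]
            cfg = replace(train_cfg, seed=iter_seed)
            _, _, report = run_experiment(samples, loss_cfg, cfg, split_seed=iter_seed)
            per_iter[name].append(report.metrics)

    table: dict[str, dict] = {}
    ref = np.array([m[metric] for m in per_iter[names[0]]])
    for name in names:
        vals = {
            key: np.array([m[key] for m in per_iter[name]])
            for key in per_iter[name][0]
        }
        row = {
            f"{key}_mean": float(v.mean()) for key, v in vals.items()
        } | {f"{key}_sd": float(v.std(ddof=1)) for key, v in vals.items()}
        diffs = vals[metric] - ref
        if np.allclose(diffs, 0):
            row["p_value_vs_reference"] = 1.0
        else:
            row["p_value_vs_reference"] = float(
                _sstats.ttest_rel(vals[metric], ref).pvalue
            )
        row["per_iteration"] = {k: v.tolist() for k, v in vals.items()}
        table[name] = row
    return {"metric": metric, "iterations": iterations, "reference": names[0], "table": table}
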