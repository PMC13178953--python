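"""Synthetic multimodal cohorts with planted ground truth.

The generator emulates the statistical structure the feature pipeline
assumes — multivariate ROI time series with AR(1) temporal memory and
controllable cross-ROI covariance, sparse nonnegative symmetric
streamline-count matrices, per-ROI gray-matter volumes and raw
anatomical-statistics tables — and plants a known signal:

* a subset of functional edges whose correlation strength varies
  across subjects and drives the label,
* optionally a subset of structural edges whose (volume-normalized,
  scaled) connectivity drives the label,
* optionally anatomical-statistics columns whose subject-specific
  loading on a zero-mean ROI pattern drives the label (a pattern
  contrast, not an additive shift, so the signal survives the
  per-subject min-max normalization applied downstream).

The label is the linear combination of these contributions plus
Gaussian noise; classification cohorts threshold the same score at
its cohort median, giving balanced groups.  Every draw flows from a
single seed, so cohorts are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .features import (
    MORPHOLOGICAL_FEATURES,
    StructuralConnectome,
    TimeSeriesMatrix,
    compute_fc,
    normalize_sc,
)

__all__ = [
    "SyntheticCohortSpec",
    "SyntheticSubject",
    "generate_cohort",
    "population_int",
    "population_fc",
]

# morphological columns drawn on a log scale (strictly positive measures)
_LOGNORMAL_FEATURES = {
    "num_vertices": (6.0, 0.4),
    "surface_area": (6.5, 0.35),
    "gm_volume": (7.5, 0.3),
    "thickness_mean": (0.9, 0.1),
    "thickness_sd": (-0.7, 0.2),
    "folding_index": (1.2, 0.3),
}
# curvature-type columns take both signs
_NORMAL_FEATURES = {
    "curvature_mean": (0.1, 0.05),
    "curvature_gaussian": (0.0, 0.15),
    "curvature_index": (0.4, 0.2),
}


@dataclass
class SyntheticCohortSpec:
    """Study conditions for one generated cohort."""

    n_subjects: int = 200
    n_rois: int = 20
    n_timepoints: int = 200
    tr: float = 0.8
    ar_coefficient: float | Sequence[float] = 0.5
    base_covariance: np.ndarray | None = None  # population innovation covariance
    fc_edge_sd: float = 0.35  # subject-level sd of planted-edge correlation
    sc_density: float = 0.3
    sc_scale: float = 1000.0
    planted_edges: tuple[tuple[int, int], ...] = ()
    planted_edge_effects: tuple[float, ...] | None = None  # default 1.0 each
    planted_sc_edges: tuple[tuple[int, int], ...] = ()
    planted_sc_effects: tuple[float, ...] | None = None
    planted_as_features: tuple[tuple[int, float], ...] = ()  # (column, effect)
    noise_sd: float = 0.1
    task: str = "regression"
    seed: int = 0

    def __post_init__(self) -> None:
        q = self.n_rois
        self.planted_edges = tuple((min(i, j), max(i, j)) for i, j in self.planted_edges)
        for i, j in self.planted_edges + tuple(
            (min(i, j), max(i, j)) for i, j in self.planted_sc_edges
        ):
            if not (0 <= i < j < q):
                raise ValueError(f"planted edge ({i}, {j}) outside the upper triangle")
        rho = np.atleast_1d(np.asarray(self.ar_coefficient, dtype=float))
        if ((rho < 0) | (rho >= 1)).any():
            raise ValueError("ar_coefficient must satisfy 0 <= rho < 1")
        if self.task not in ("regression", "classification"):
            raise ValueError("task must be 'regression' or 'classification'")
        if not 0 < self.sc_density <= 1:
            raise ValueError("sc_density must lie in (0, 1]")

    @property
    def ar_vector(self) -> np.ndarray:
        rho = np.atleast_1d(np.asarray(self.ar_coefficient, dtype=float))
        if rho.size == 1:
            rho = np.full(self.n_rois, rho[0])
        if rho.size != self.n_rois:
            raise ValueError("ar_coefficient must be scalar or length n_rois")
        return rho

    def edge_effects(self) -> np.ndarray:
        if self.planted_edge_effects is None:
            return np.ones(len(self.planted_edges))
        return np.asarray(self.planted_edge_effects, dtype=float)

    def sc_effects(self) -> np.ndarray:
        if self.planted_sc_effects is None:
            return np.ones(len(self.planted_sc_edges))
        return np.asarray(self.planted_sc_effects, dtype=float)


@dataclass
class SyntheticSubject:
    subject_id: str
    time_series: TimeSeriesMatrix
    sc: StructuralConnectome  # raw streamline counts + gm volumes
    raw_as: np.ndarray  # (Q, 9) raw morphology table
    as_feature_names: list[str]
    label: np.ndarray
    score: float  # continuous score behind classification labels
    ground_truth: dict = field(default_factory=dict)


def population_int(ar_coefficient: float, tr: float) -> float:
    """Expected intrinsic neural timescale of an AR(1) process.

    The autocorrelation at lag k is rho**k, all positive, so the area
    under the initial positive phase is the full geometric series:
    tr * rho / (1 - rho).
    """
    rho = float(ar_coefficient)
    if not 0 <= rho < 1:
        raise ValueError("ar_coefficient must satisfy 0 <= rho < 1")
    return tr * rho / (1.0 - rho)


def population_fc(spec: SyntheticCohortSpec) -> np.ndarray:
    """Population correlation of the stationary AR(1) process.

    With innovation covariance S and per-ROI coefficients rho, the
    stationary covariance is C_ij = S_ij / (1 - rho_i rho_j); the
    returned matrix is its correlation.
    """
    s = _base_covariance(spec)
    rho = spec.ar_vector
    c = s / (1.0 - np.outer(rho, rho))
    d = 1.0 / np.sqrt(np.diag(c))
    return c * np.outer(d, d)


def _base_covariance(spec: SyntheticCohortSpec) -> np.ndarray:
    if spec.base_covariance is not None:
        s = np.asarray(spec.base_covariance, dtype=float)
        if s.shape != (spec.n_rois, spec.n_rois):
            raise ValueError("base_covariance must be Q x Q")
        if not np.allclose(s, s.T):
            raise ValueError("base_covariance must be symmetric")
        if np.linalg.eigvalsh(s).min() <= 0:
            raise ValueError("base_covariance must be positive definite")
        return s
    # default: random two-factor correlation structure, fixed by the seed
    rng = np.random.default_rng(spec.seed + 101)
    loadings = rng.normal(0.0, 0.45, size=(spec.n_rois, 2))
    s = loadings @ loadings.T + np.eye(spec.n_rois)
    d = 1.0 / np.sqrt(np.diag(s))
    return s * np.outer(d, d)


def _nearest_correlation(s: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix to a positive-definite correlation."""
    w, v = np.linalg.eigh((s + s.T) / 2.0)
    w = np.clip(w, 1e-6, None)
    c = (v * w) @ v.T
    d = 1.0 / np.sqrt(np.diag(c))
    return c * np.outer(d, d)


def _simulate_ar1(
    rng: np.random.Generator,
    cov: np.ndarray,
    rho: np.ndarray,
    t: int,
    burn_in: int = 100,
) -> np.ndarray:
    chol = np.linalg.cholesky(cov)
    q = cov.shape[0]
    innovations = rng.standard_normal((t + burn_in, q)) @ chol.T
    x = np.zeros((t + burn_in, q))
    x[0] = innovations[0]
    for step in range(1, t + burn_in):
        x[step] = rho * x[step - 1] + innovations[step]
    return x[burn_in:]


def generate_cohort(spec: SyntheticCohortSpec) -> list[SyntheticSubject]:
    """Draw a fully reproducible cohort with planted importance."""
    rng = np.random.default_rng(spec.seed)
    q = spec.n_rois
    rho = spec.ar_vector
    base = _base_covariance(spec)

    # cohort-level structural support: planted edges always present
    upper = [(i, j) for i in range(q) for j in range(i + 1, q)]
    support = np.zeros((q, q), dtype=bool)
    for i, j in upper:
        if rng.random() < spec.sc_density:
            support[i, j] = support[j, i] = True
    for i, j in spec.planted_sc_edges:
        support[i, j] = support[j, i] = True
    base_counts = np.zeros((q, q))
    base_counts[support] = 1.0
    base_counts *= spec.sc_scale * np.exp(rng.normal(0.0, 0.8, size=(q, q)))
    base_counts = np.triu(base_counts, 1)
    base_counts = base_counts + base_counts.T

    # cohort-level anatomy: base value per (ROI, feature)
    as_base = np.zeros((q, len(MORPHOLOGICAL_FEATURES)))
    for col, name in enumerate(MORPHOLOGICAL_FEATURES):
        if name in _LOGNORMAL_FEATURES:
            mu, sd = _LOGNORMAL_FEATURES[name]
            as_base[:, col] = rng.lognormal(mu, sd, size=q)
        else:
            mu, sd = _NORMAL_FEATURES[name]
            as_base[:, col] = rng.normal(mu, sd, size=q)
    # ROI patterns carrying the planted anatomy signal: localized on
    # mid-range regions so the per-subject min-max normalization applied
    # downstream (anchored by the extreme regions) preserves the
    # subject loading in the normalized column
    as_patterns = {}
    for col, _effect in spec.planted_as_features:
        if not 0 <= col < as_base.shape[1]:
            raise ValueError(f"planted AS column {col} out of range")
        base_col = as_base[:, col]
        lo, hi = np.quantile(base_col, [0.25, 0.75])
        mid = (base_col >= lo) & (base_col <= hi)
        pattern = np.zeros(q)
        pattern[mid] = np.abs(rng.normal(1.0, 0.3, size=int(mid.sum())))
        # amplitude tied to the column's regional spread, which is what
        # sets the dynamic range of the min-max-normalized column: the
        # extreme ROIs stay the anchors for |loading| of a few units
        as_patterns[col] = pattern * (0.5 * (hi - lo) + 1e-12)

    edge_effects = spec.edge_effects()
    sc_effects = spec.sc_effects()
    subjects: list[SyntheticSubject] = []
    scores = np.zeros(spec.n_subjects)

    for s_idx in range(spec.n_subjects):
        sid = f"sub-{s_idx + 1:04d}"
        # subject covariance: perturb planted-edge correlations
        cov = base.copy()
        for (i, j), _w in zip(spec.planted_edges, edge_effects):
            shift = rng.normal(0.0, spec.fc_edge_sd)
            val = np.clip(base[i, j] + shift, -0.85, 0.85)
            cov[i, j] = cov[j, i] = val
        cov = _nearest_correlation(cov)

        ts_values = _simulate_ar1(rng, cov, rho, spec.n_timepoints)
        ts = TimeSeriesMatrix(
            values=ts_values, tr=spec.tr, unit_labels=[f"ROI_{r + 1}" for r in range(q)]
        )
        fc = compute_fc(ts)

        # structural counts: subject jitter, planted edges carry a latent
        counts = base_counts * np.exp(rng.normal(0.0, 0.2, size=(q, q)))
        counts = np.triu(counts, 1)
        counts = counts + counts.T
        sc_latents = rng.normal(0.0, 1.0, size=len(spec.planted_sc_edges))
        for (i, j), latent in zip(spec.planted_sc_edges, sc_latents):
            counts[i, j] = counts[j, i] = base_counts[i, j] * np.exp(0.7 * latent)
        gm = rng.lognormal(8.0, 0.15, size=q)
        sc = StructuralConnectome(
            values=counts, gm_volumes=gm, roi_ids=[f"ROI_{r + 1}" for r in range(q)]
        )

        # anatomy: base + subject noise + planted pattern loading
        raw_as = as_base * np.exp(rng.normal(0.0, 0.05, size=as_base.shape))
        as_loadings = {}
        for col, _effect in spec.planted_as_features:
            u = rng.normal(0.0, 1.0)
            as_loadings[col] = u
            raw_as[:, col] = raw_as[:, col] + u * as_patterns[col]

        # label assembly
        score = 0.0
        for (i, j), w in zip(spec.planted_edges, edge_effects):
            score += w * fc.values[i, j]
        if spec.planted_sc_edges:
            sc_norm = normalize_sc(sc)
            for (i, j), w in zip(spec.planted_sc_edges, sc_effects):
                score += w * sc_norm.values[i, j]
        for col, effect in spec.planted_as_features:
            score += effect * as_loadings[col]
        score += rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
        scores[s_idx] = score

        subjects.append(
            SyntheticSubject(
                subject_id=sid,
                time_series=ts,
                sc=sc,
                raw_as=raw_as,
                as_feature_names=list(MORPHOLOGICAL_FEATURES),
                label=np.array([score]),
                score=float(score),
                ground_truth={
                    "planted_edges": list(spec.planted_edges),
                    "planted_sc_edges": list(spec.planted_sc_edges),
                    "planted_as_features": list(spec.planted_as_features),
                    "population_int": [
                        population_int(r, spec.tr) for r in spec.ar_vector
                    ],
                },
            )
        )

    if spec.task == "classification":
        median = np.median(scores)
        for subject in subjects:
            subject.label = np.array([int(subject.score > median)])

    return subjects
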