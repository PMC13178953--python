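"""ROI-level and connectivity-level feature derivation.

Given a parcellated functional time series, a raw streamline-count
structural connectome and a table of per-ROI morphological statistics,
this module derives the three feature families the model consumes:

* **FC** — Pearson functional connectivity, min-max scaled off-diagonal.
* **SC** — structural connectivity normalized by the square root of the
  product of the connected regions' gray-matter volumes, then min-max
  scaled.
* **AS** — anatomical statistics: nine morphological columns,
  variance-stabilized with a signed log transform and min-max scaled
  per column, augmented with the intrinsic neural timescale (INT) and
  the structure-function coupling of each ROI.

INT is the repetition-time-scaled area under the autocorrelation
function over its initial positive phase — a proxy for how long neural
information persists in a local circuit.  Structure-function coupling
is the Spearman rank correlation between a region's structural and
functional connection profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "TimeSeriesMatrix",
    "FunctionalConnectome",
    "StructuralConnectome",
    "IntResult",
    "AnatomicalStats",
    "DegenerateSignalError",
    "DegenerateRangeError",
    "MORPHOLOGICAL_FEATURES",
    "AS_FEATURE_ORDER",
    "compute_fc",
    "minmax_scale",
    "normalize_sc",
    "compute_int",
    "aggregate_int",
    "compute_coupling",
    "normalize_as",
    "assemble_as",
]


class DegenerateSignalError(ValueError):
    """A signal or column is constant where variance is required."""


class DegenerateRangeError(ValueError):
    """Min-max scaling was requested on a constant range."""


#: Canonical morphological column order for anatomical-statistics tables.
MORPHOLOGICAL_FEATURES = (
    "num_vertices",
    "surface_area",
    "gm_volume",
    "thickness_mean",
    "thickness_sd",
    "curvature_mean",
    "curvature_gaussian",
    "curvature_index",
    "folding_index",
)

#: Full assembled AS column order (d_c = 11).
AS_FEATURE_ORDER = MORPHOLOGICAL_FEATURES + ("int", "coupling")


@dataclass
class TimeSeriesMatrix:
    """Signal matrix, one column per unit (voxel or ROI), one row per frame."""

    values: np.ndarray  # (T, U)
    tr: float  # repetition time, seconds
    unit_labels: list[str] | None = None  # optional unit -> ROI assignment

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D (T x U) matrix")
        if self.values.shape[0] < 3:
            raise ValueError("time series needs at least 3 timepoints")
        if np.isnan(self.values).any():
            raise ValueError("time series contains NaN")
        if self.tr <= 0:
            raise ValueError("repetition time must be positive")

    @property
    def n_units(self) -> int:
        return self.values.shape[1]


@dataclass
class FunctionalConnectome:
    values: np.ndarray  # (Q, Q) Pearson correlations
    roi_ids: list[str]

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass
class StructuralConnectome:
    values: np.ndarray  # (Q, Q), nonnegative
    gm_volumes: np.ndarray  # (Q,), mm^3, strictly positive
    roi_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gm_volumes = np.asarray(self.gm_volumes, dtype=float)
        if self.values.shape[0] != self.values.shape[1]:
            raise ValueError("structural connectome must be square")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("structural connectome must be symmetric")
        if (self.values < 0).any():
            raise ValueError("structural connectome must be nonnegative")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass
class IntResult:
    """Per-unit intrinsic neural timescale and the lag count used."""

    values: np.ndarray  # seconds
    lags_used: np.ndarray  # N_v per unit


@dataclass
class AnatomicalStats:
    """ROI x d_c feature table; entries in [0, 1] after normalization."""

    values: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match column count")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def compute_fc(ts: TimeSeriesMatrix) -> FunctionalConnectome:
    """Pearson correlation between every pair of unit time series.

    Raises
    ------
    DegenerateSignalError
        If any column has zero variance (correlation undefined).
    """
    x = ts.values
    sd = x.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise DegenerateSignalError(
            f"zero-variance time series in column(s) {bad.tolist()}"
        )
    fc = np.corrcoef(x, rowvar=False)
    fc = (fc + fc.T) / 2.0
    np.fill_diagonal(fc, 1.0)
    labels = ts.unit_labels or [f"ROI_{i + 1}" for i in range(x.shape[1])]
    return FunctionalConnectome(values=fc, roi_ids=list(labels))


def minmax_scale(values: np.ndarray, exclude_diagonal: bool = False) -> np.ndarray:
    """Min-max scale entries to [0, 1].

    With ``exclude_diagonal`` the diagonal is neither used to determine
    the range nor rescaled (self-connections are constant by
    construction and would distort the range).
    """
    values = np.asarray(values, dtype=float)
    out = values.copy()
    if exclude_diagonal:
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("exclude_diagonal requires a square matrix")
        mask = ~np.eye(values.shape[0], dtype=bool)
        entries = values[mask]
        lo, hi = entries.min(), entries.max()
        if hi == lo:
            raise DegenerateRangeError("constant off-diagonal range; cannot scale")
        out[mask] = (entries - lo) / (hi - lo)
        return out
    lo, hi = values.min(), values.max()
    if hi == lo:
        raise DegenerateRangeError("constant input; cannot min-max scale")
    return (values - lo) / (hi - lo)


def normalize_sc(sc: StructuralConnectome, scale: bool = True) -> StructuralConnectome:
    """Volume-normalize streamline counts, then min-max scale.

    Each entry is divided by the square root of the product of the
    gray-matter volumes of the two connected regions, correcting for
    the tendency of larger regions to accrue more streamlines.  The
    min-max step covers the off-diagonal entries; the (conventionally
    zero) diagonal is left untouched.
    """
    if (sc.gm_volumes <= 0).any():
        bad = np.flatnonzero(sc.gm_volumes <= 0)
        raise ValueError(f"nonpositive gray-matter volume for ROI(s) {bad.tolist()}")
    denom = np.sqrt(np.outer(sc.gm_volumes, sc.gm_volumes))
    normalized = sc.values / denom
    if scale:
        normalized = minmax_scale(normalized, exclude_diagonal=True)
        np.fill_diagonal(normalized, 0.0)
    return StructuralConnectome(
        values=normalized, gm_volumes=sc.gm_volumes.copy(), roi_ids=list(sc.roi_ids)
    )


def compute_int(signal: np.ndarray, tr: float) -> tuple[float, int]:
    """Intrinsic neural timescale of one signal.

    The lag-k autocorrelation uses the full-series sum of squares as
    denominator at every lag (the biased estimator).  ``N`` is the lag
    immediately preceding the first negative autocorrelation; INT is
    ``tr`` times the sum of the autocorrelations over lags ``1..N``
    (area under the initial positive phase).  Returns ``(INT, N)``.
    """
    y = np.asarray(signal, dtype=float).ravel()
    T = y.size
    if T < 3:
        raise ValueError("signal must have at least 3 timepoints")
    yc = y - y.mean()
    denom = np.dot(yc, yc)
    if denom == 0:
        raise DegenerateSignalError("constant signal: autocorrelation undefined")
    # full acf via FFT, lags 1..T-1
    nfft = 1 << int(np.ceil(np.log2(2 * T - 1)))
    f = np.fft.rfft(yc, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:T]
    acf = acov / denom  # acf[0] == 1
    lags = acf[1:]
    negative = np.flatnonzero(lags < 0)
    n_lags = int(negative[0]) if negative.size else lags.size
    int_value = float(tr * lags[:n_lags].sum())
    return int_value, n_lags


def aggregate_int(
    voxel_ints: np.ndarray,
    unit_labels: list[str],
    roi_ids: list[str] | None = None,
) -> dict[str, float]:
    """Average unit-level INT within each ROI.

    Returns an ordered mapping ROI -> mean INT; order follows
    ``roi_ids`` when given (an ROI without any assigned unit is an
    error), otherwise first appearance in ``unit_labels``.
    """
    voxel_ints = np.asarray(voxel_ints, dtype=float)
    if voxel_ints.size != len(unit_labels):
        raise ValueError("voxel_ints and unit_labels length mismatch")
    groups: dict[str, list[float]] = {}
    for v, lab in zip(voxel_ints, unit_labels):
        groups.setdefault(lab, []).append(float(v))
    order = list(roi_ids) if roi_ids is not None else list(groups)
    missing = [r for r in order if r not in groups]
    if missing:
        raise ValueError(f"ROI(s) with no units: {missing}")
    return {r: float(np.mean(groups[r])) for r in order}


def compute_coupling(
    sc: StructuralConnectome,
    fc: FunctionalConnectome,
    on_constant: str = "error",
) -> np.ndarray:
    """Per-ROI structure-function coupling.

    For each region the Spearman rank correlation between its SC and FC
    connection profiles, each profile being the Q-1 off-diagonal entries
    of that region's row.  Ties receive average ranks.

    ``on_constant`` controls the degenerate case of a constant profile:
    ``"error"`` raises, ``"zero"`` emits 0 with a warning.
    """
    if sc.n_rois != fc.n_rois:
        raise ValueError("SC and FC must have the same number of ROIs")
    if on_constant not in ("error", "zero"):
        raise ValueError("on_constant must be 'error' or 'zero'")
    q = sc.n_rois
    rho = np.empty(q)
    for i in range(q):
        keep = np.arange(q) != i
        s_prof = sc.values[i, keep]
        f_prof = fc.values[i, keep]
        if np.ptp(s_prof) == 0 or np.ptp(f_prof) == 0:
            if on_constant == "error":
                raise DegenerateSignalError(
                    f"constant connectivity profile for ROI index {i}; "
                    "Spearman coefficient undefined"
                )
            import warnings

            warnings.warn(
                f"constant profile for ROI index {i}; coupling set to 0",
                RuntimeWarning,
                stacklevel=2,
            )
            rho[i] = 0.0
            continue
        rho[i] = stats.spearmanr(s_prof, f_prof).statistic
    return rho


def normalize_as(raw_stats: np.ndarray) -> np.ndarray:
    """Variance-stabilize and scale a raw anatomical-statistics table.

    Per column: signed log transform ``sign(x) * log1p(|x|)`` (defined
    on all of R, monotone, variance-stabilizing) followed by min-max
    scaling to [0, 1].
    """
    x = np.asarray(raw_stats, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D (Q x d) table")
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = np.sign(x[:, j]) * np.log1p(np.abs(x[:, j]))
        if np.ptp(col) == 0:
            raise DegenerateRangeError(f"constant anatomical feature column {j}")
        out[:, j] = (col - col.min()) / np.ptp(col)
    return out


def assemble_as(
    stats: np.ndarray,
    roi_int: np.ndarray,
    coupling: np.ndarray,
    feature_names: list[str] | None = None,
) -> AnatomicalStats:
    """Concatenate normalized morphology with INT and coupling columns.

    ``stats`` is the already-normalized morphological table; INT and
    coupling are appended as the last two columns, each min-max scaled
    across ROIs so that the full table lies in [0, 1].
    """
    stats = np.asarray(stats, dtype=float)
    roi_int = np.asarray(roi_int, dtype=float).ravel()
    coupling = np.asarray(coupling, dtype=float).ravel()
    q = stats.shape[0]
    if roi_int.size != q or coupling.size != q:
        raise ValueError("stats, roi_int and coupling must agree on ROI count")
    if feature_names is None:
        if stats.shape[1] == len(MORPHOLOGICAL_FEATURES):
            feature_names = list(MORPHOLOGICAL_FEATURES)
        else:
            feature_names = [f"morph_{j}" for j in range(stats.shape[1])]
    cols = [stats, minmax_scale(roi_int)[:, None], minmax_scale(coupling)[:, None]]
    values = np.hstack(cols)
    return AnatomicalStats(values=values, feature_names=list(feature_names) + ["int", "coupling"])
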