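"""Delimited-text readers/writers, manifests and run configuration.

All file interfaces are dialect-fixed: comma-delimited, dot decimal,
UTF-8, one header row of ROI ids.  ROI labels are matched exactly
across modalities per subject; a mismatch is fatal rather than
silently reordered.  ROI indexing is 0-based in memory and 1-based in
files.  Readers reject NaN and report the file and cell.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import StructuralConnectome, TimeSeriesMatrix
from .synthetic import SyntheticCohortSpec, SyntheticSubject

__all__ = [
    "read_matrix",
    "write_matrix",
    "classify_groups",
    "RunConfig",
    "write_cohort",
    "load_cohort",
    "write_edge_list",
]

LOW_SCORE_BOUND = 80.0  # below borderline
HIGH_SCORE_BOUND = 130.0  # very superior


def write_matrix(values: np.ndarray, path: str | Path, roi_ids: list[str], index: bool = False) -> None:
    """Write a labeled matrix: header row of ROI ids, optional ROI index
    column for square matrices."""
    df = pd.DataFrame(np.asarray(values, dtype=float), columns=roi_ids)
    if index:
        df.index = pd.Index(roi_ids, name="roi")
    # %.17g guarantees an exact float64 round trip through text
    df.to_csv(path, index=index, float_format="%.17g")


def read_matrix(path: str | Path, index: bool = False) -> tuple[np.ndarray, list[str]]:
    """Read a labeled matrix, rejecting ragged rows and NaN.

    Returns ``(values, roi_ids)``.
    """
    path = Path(path)
    try:
        # round_trip parsing keeps the text <-> float64 mapping exact
        df = pd.read_csv(path, index_col=0 if index else None, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed delimited text ({exc})") from exc
    if df.isna().any().any():
        rows, cols = np.nonzero(df.isna().to_numpy())
        r, c = int(rows[0]), int(cols[0])
        raise ValueError(
            f"{path}: missing value at row {r + 2}, column {df.columns[c]!r}"
        )
    columns = [str(c) for c in df.columns]
    if index and [str(i) for i in df.index] != columns:
        raise ValueError(f"{path}: ROI label mismatch between rows and columns")
    values = df.to_numpy(dtype=float)
    return values, columns


def classify_groups(
    scores: np.ndarray,
    low_bound: float = LOW_SCORE_BOUND,
    high_bound: float = HIGH_SCORE_BOUND,
) -> np.ndarray:
    """Two-group assignment by extreme cognition scores.

    Score below ``low_bound`` -> group 0, above ``high_bound`` ->
    group 1; everything between is excluded (-1).
    """
    if not low_bound < high_bound:
        raise ValueError("low_bound must be below high_bound")
    scores = np.asarray(scores, dtype=float)
    if np.isnan(scores).any():
        raise ValueError("non-numeric score in cohort")
    out = np.full(scores.shape, -1, dtype=int)
    out[scores < low_bound] = 0
    out[scores > high_bound] = 1
    return out


@dataclass
class RunConfig:
    """Merged run settings, persisted verbatim alongside results."""

    seed: int = 0
    task: str = "regression"
    mode: str = "fc_sc"  # fc_only | sc_only | fc_sc
    use_as: bool = True
    top_k: int = 30
    edge_threshold: float = 0.001
    hidden1: int = 32
    hidden2: int = 32
    dropout: float = 0.0
    learning_rate: float = 0.005
    batch_size: int = 32
    max_epochs: int = 50
    weight_decay: float = 1e-6
    scheduler_patience: int = 10
    split_fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)
    bootstrap_iterations: int = 10
    alpha: float = 0.001
    lambda1: float = 1e-4
    lambda2: float = 1e-4
    lambda3: float = 1e-4
    manifold_threshold: float = float("inf")
    display_threshold: float = 0.52

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        valid = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - valid
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        if "split_fractions" in raw:
            raw["split_fractions"] = tuple(raw["split_fractions"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["split_fractions"] = list(data["split_fractions"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def write_edge_list(matrix: np.ndarray, path: str | Path, weights: bool = True) -> None:
    """Export nonzero upper-triangle entries as (roi_i, roi_j, value)
    rows with 1-based ROI indices."""
    m = np.asarray(matrix, dtype=float)
    rows = []
    iu, ju = np.triu_indices(m.shape[0], 1)
    for i, j in zip(iu, ju):
        if m[i, j] != 0:
            rows.append((i + 1, j + 1, m[i, j] if weights else 1))
    pd.DataFrame(rows, columns=["roi_i", "roi_j", "weight"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# cohort persistence: the same formats real-data readers consume


def write_cohort(subjects: list[SyntheticSubject], out_dir: str | Path, spec: SyntheticCohortSpec | None = None) -> Path:
    """Write one directory per cohort: per-subject matrices, a manifest
    and (for synthetic cohorts) the ground truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        roi_ids = s.time_series.unit_labels or [
            f"ROI_{i + 1}" for i in range(s.time_series.n_units)
        ]
        ts_path = out_dir / f"{s.subject_id}_timeseries.csv"
        sc_path = out_dir / f"{s.subject_id}_sc.csv"
        gm_path = out_dir / f"{s.subject_id}_gm.csv"
        as_path = out_dir / f"{s.subject_id}_as.csv"
        write_matrix(s.time_series.values, ts_path, roi_ids)
        write_matrix(s.sc.values, sc_path, roi_ids, index=True)
        pd.DataFrame({"roi": roi_ids, "gm_volume": s.sc.gm_volumes}).to_csv(
            gm_path, index=False, float_format="%.17g"
        )
        pd.DataFrame(s.raw_as, columns=s.as_feature_names).assign(roi=roi_ids).set_index(
            "roi"
        ).to_csv(as_path, float_format="%.17g")
        label = np.asarray(s.label).ravel()
        row = {
            "subject_id": s.subject_id,
            "timeseries": ts_path.name,
            "sc": sc_path.name,
            "gm": gm_path.name,
            "as": as_path.name,
            "tr": s.time_series.tr,
        }
        for t, v in enumerate(label):
            row[f"label_{t}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False, float_format="%.17g")
    gt = subjects[0].ground_truth if subjects else {}
    if gt:
        (out_dir / "ground_truth.json").write_text(json.dumps(gt, indent=2))
    if spec is not None:
        meta = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in asdict(spec).items()
        }
        (out_dir / "cohort_spec.json").write_text(json.dumps(meta, indent=2, default=list))
    return out_dir


def load_cohort(cohort_dir: str | Path) -> list[SyntheticSubject]:
    """Load a cohort written by :func:`write_cohort` (or assembled by
    hand in the same layout)."""
    cohort_dir = Path(cohort_dir)
    manifest_path = cohort_dir / "manifest.csv"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.csv in {cohort_dir}")
    manifest = pd.read_csv(manifest_path)
    if manifest["subject_id"].duplicated().any():
        dupes = manifest["subject_id"][manifest["subject_id"].duplicated()].tolist()
        raise ValueError(f"duplicate subject id(s) in manifest: {dupes}")
    gt_path = cohort_dir / "ground_truth.json"
    ground_truth = json.loads(gt_path.read_text()) if gt_path.exists() else {}
    if "planted_edges" in ground_truth:
        ground_truth["planted_edges"] = [tuple(e) for e in ground_truth["planted_edges"]]
    if "planted_sc_edges" in ground_truth:
        ground_truth["planted_sc_edges"] = [
            tuple(e) for e in ground_truth["planted_sc_edges"]
        ]

    label_cols = sorted(c for c in manifest.columns if c.startswith("label_"))
    subjects = []
    for _, row in manifest.iterrows():
        for key in ("timeseries", "sc", "gm", "as"):
            if not (cohort_dir / row[key]).exists():
                raise FileNotFoundError(f"{row[key]} referenced by manifest is missing")
        ts_values, roi_ids = read_matrix(cohort_dir / row["timeseries"])
        sc_values, sc_ids = read_matrix(cohort_dir / row["sc"], index=True)
        if sc_ids != roi_ids:
            raise ValueError(
                f"ROI label mismatch between time series and SC for {row['subject_id']}"
            )
        gm = pd.read_csv(cohort_dir / row["gm"])
        if gm["roi"].astype(str).tolist() != roi_ids:
            raise ValueError(f"ROI label mismatch in gm volumes for {row['subject_id']}")
        as_df = pd.read_csv(cohort_dir / row["as"], index_col=0)
        if [str(i) for i in as_df.index] != roi_ids:
            raise ValueError(f"ROI label mismatch in AS table for {row['subject_id']}")
        label = np.array([row[c] for c in label_cols], dtype=float)
        subjects.append(
            SyntheticSubject(
                subject_id=str(row["subject_id"]),
                time_series=TimeSeriesMatrix(
                    values=ts_values, tr=float(row["tr"]), unit_labels=roi_ids
                ),
                sc=StructuralConnectome(
                    values=sc_values,
                    gm_volumes=gm["gm_volume"].to_numpy(float),
                    roi_ids=roi_ids,
                ),
                raw_as=as_df.to_numpy(float),
                as_feature_names=[str(c) for c in as_df.columns],
                label=label,
                score=float(label[0]),
                ground_truth=ground_truth,
            )
        )
    return subjects
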