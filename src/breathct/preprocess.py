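"""Raw-trace feature extraction, PCA outlier removal and feature-table I/O.

The study's tabular unit is the *feature table*: one row per breath
measurement, 18 columns of per-sensor R0/R features (baseline resistance over
steady-state breath resistance) plus metadata identifying device, subject,
visit and meal status. Tables are plain CSV with the fixed header
``sample_id,device_id,subject_id,visit,timepoint,class,s01..s18``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

N_SENSORS = 18
FEATURE_COLUMNS = [f"s{i + 1:02d}" for i in range(N_SENSORS)]
META_COLUMNS = ["sample_id", "device_id", "subject_id", "visit", "timepoint", "class"]
ALL_COLUMNS = META_COLUMNS + FEATURE_COLUMNS
CLASSES = ("meal", "no-meal")
TIMEPOINT_TO_CLASS = {"pre": "no-meal", "post": "meal"}

# window lengths in seconds fixed by the acquisition firmware
BASELINE_SECONDS = 10.0
BREATH_SECONDS = 20.0
STEADY_STATE_SECONDS = 5.0


@dataclass
class RawMeasurement:
    """One sensor's resistance trace for one breath measurement.

    ``phase`` annotates each time point as ``baseline``, ``breath`` or
    ``cleaning``; the baseline phase must precede the breath phase and the
    breath phase must last at least 5 s (the steady-state window).
    """

    sample_id: str
    sensor_id: str
    t_seconds: np.ndarray
    resistance_ohm: np.ndarray
    phase: np.ndarray  # array of str

    def __post_init__(self) -> None:
        self.t_seconds = np.asarray(self.t_seconds, dtype=float)
        self.resistance_ohm = np.asarray(self.resistance_ohm, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)


def extract_feature(trace: RawMeasurement) -> float:
    """R0/R feature of a single sensor trace.

    R0 is the mean resistance over the baseline phase (room air); R is the
    mean resistance over the final 5 s of the breath phase, where the sensor
    response is steady. Returns the dimensionless ratio R0/R.
    """
    if np.any(trace.resistance_ohm <= 0):
        raise ValueError(f"trace {trace.sample_id}/{trace.sensor_id}: nonpositive resistance")
    base = trace.phase == "baseline"
    breath = trace.phase == "breath"
    if not base.any() or not breath.any():
        raise ValueError("trace must contain baseline and breath phases")
    t_base_end = trace.t_seconds[base].max()
    t_breath = trace.t_seconds[breath]
    if t_breath.min() < t_base_end:
        raise ValueError("baseline phase must precede breath phase")
    span = t_breath.max() - t_breath.min()
    if span < STEADY_STATE_SECONDS:
        raise ValueError(
            f"breath phase lasts {span:.2f} s; need >= {STEADY_STATE_SECONDS} s"
        )
    r0 = trace.resistance_ohm[base].mean()
    # trailing 5-s window, right-closed: (t_end - 5, t_end]
    steady = breath & (trace.t_seconds > t_breath.max() - STEADY_STATE_SECONDS)
    r = trace.resistance_ohm[steady].mean()
    return float(r0 / r)


def features_from_traces(traces: list[RawMeasurement]) -> pd.Series:
    """Per-sensor R0/R features of one measurement, indexed by sensor_id."""
    return pd.Series({tr.sensor_id: extract_feature(tr) for tr in traces})


def remove_outliers(
    data: pd.DataFrame,
    n_components: int = 2,
    z_threshold: float = 3.0,
    per_device: bool = True,
) -> tuple[pd.DataFrame, list]:
    """Remove rows with extreme PCA score distances.

    Rows are scored by the Euclidean norm of their projection on the first
    ``n_components`` principal components (fit per device by default); a row
    is flagged when its robust z-score (median/MAD) of that distance exceeds
    ``z_threshold``. Returns the retained table and the removed sample ids.
    Deterministic for fixed input.
    """
    if per_device and "device_id" in data.columns:
        groups = [g for _, g in data.groupby("device_id", sort=True)]
    else:
        groups = [data]
    removed: list = []
    for g in groups:
        if len(g) < n_components + 2:
            raise ValueError(
                f"need at least n_components + 2 = {n_components + 2} rows, got {len(g)}"
            )
        X = g[FEATURE_COLUMNS].to_numpy(dtype=float)
        scores = PCA(n_components=n_components).fit_transform(X)
        d = np.linalg.norm(scores, axis=1)
        med = np.median(d)
        mad = np.median(np.abs(d - med)) * 1.4826
        if mad <= 0:
            continue  # all distances identical: nothing to flag
        z = (d - med) / mad
        flag = z > z_threshold
        if flag.all():
            raise ValueError("outlier threshold flags every row (degenerate)")
        removed.extend(g.loc[flag, "sample_id"].tolist())
    kept = data[~data["sample_id"].isin(removed)].reset_index(drop=True)
    return kept, removed


def validate_feature_table(data: pd.DataFrame) -> pd.DataFrame:
    """Check schema, numeric features and class labels; returns the table."""
    missing = [c for c in ALL_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"feature table is missing column(s): {', '.join(missing)}")
    vals = data[FEATURE_COLUMNS]
    for col in FEATURE_COLUMNS:
        numeric = pd.to_numeric(vals[col], errors="coerce")
        bad = numeric.isna() | ~np.isfinite(numeric)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"non-numeric or non-finite feature in column {col}, row {row}")
    bad_class = ~data["class"].isin(CLASSES)
    if bad_class.any():
        row = int(np.flatnonzero(bad_class.to_numpy())[0])
        raise ValueError(
            f"unknown class label {data['class'].iloc[row]!r} in row {row}; "
            f"expected one of {CLASSES}"
        )
    return data


def read_feature_table(path) -> pd.DataFrame:
    data = pd.read_csv(path)
    validate_feature_table(data)
    data[FEATURE_COLUMNS] = data[FEATURE_COLUMNS].astype(float)
    return data[ALL_COLUMNS]


def write_feature_table(data: pd.DataFrame, path) -> None:
    validate_feature_table(data)
    data[ALL_COLUMNS].to_csv(path, index=False)


def feature_values(data: pd.DataFrame) -> np.ndarray:
    """The n x 18 feature block of a table as a float array."""
    return data[FEATURE_COLUMNS].to_numpy(dtype=float)
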