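"""Marker-trajectory file I/O, filtering, calibration and the batch pipeline.

The canonical on-disk format is a wide CSV with header
``frame,time,M3_x,M3_y,M3_z,...,M13_z`` (millimetres, seconds); the
tab-delimited TRC mocap text format is supported read-only.  Raw marker
series are smoothed with a centered (zero-lag) moving average before angle
extraction — analysis is offline, so a symmetric window introduces no lag.
Frames with a missing marker are flagged and skipped, never interpolated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, GeometryError, MissingMarkerError, TribsError
from .euclidean_angles import PoseAngles, extract_pose, humeral_category
from .frames import EulerTransform, build_transform
from .model import ANGLE_LABELS, MARKER_NAMES, LimbModel, Point3, default_model
from .tps_inverse import angles_via_tps

MARKER_COLUMNS = tuple(f"{m}_{ax}" for m in MARKER_NAMES for ax in "xyz")
#: rest-pose reference values used by departure detection (theta3 is
#: undefined at rest and excluded; theta5 rests at 90 deg by convention)
REST_REFERENCE = {
    "theta1": 0.0,
    "theta2": 0.0,
    "theta4": 0.0,
    "theta5": 90.0,
    "theta6": 0.0,
    "theta7": 0.0,
    "theta8": 0.0,
}


@dataclass(frozen=True)
class MarkerFrame:
    """One time sample: six named world-frame markers plus a missing mask."""

    frame: int
    time: float
    points: dict[str, np.ndarray]
    missing: frozenset[str] = frozenset()

    @property
    def is_complete(self) -> bool:
        return not self.missing

    def as_id_dict(self) -> dict[int, np.ndarray]:
        return {int(name[1:]): xyz for name, xyz in self.points.items()}


class MarkerSeries:
    """A validated marker trajectory table (wide format, world frame, mm)."""

    def __init__(self, data: pd.DataFrame):
        missing_cols = [c for c in ("frame", "time", *MARKER_COLUMNS) if c not in data.columns]
        if missing_cols:
            raise ConfigError(
                f"marker table lacks column(s) {missing_cols}; expected "
                f"frame,time,{','.join(MARKER_COLUMNS)}"
            )
        extra = [c for c in data.columns if c not in ("frame", "time", *MARKER_COLUMNS)]
        if extra:
            raise ConfigError(f"unknown marker column(s): {extra}")
        if len(data) == 0:
            raise ConfigError("empty marker series")
        df = data.reset_index(drop=True).copy()
        t = df["time"].to_numpy(dtype=float)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ConfigError("time column must be strictly increasing")
        f = df["frame"].to_numpy()
        if not np.array_equal(f, f[0] + np.arange(len(f))):
            raise ConfigError("frame indices must be contiguous")
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    @property
    def times(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    def marker_array(self, name: str) -> np.ndarray:
        return self.data[[f"{name}_{ax}" for ax in "xyz"]].to_numpy(dtype=float)

    def missing_mask(self) -> pd.DataFrame:
        out = {}
        for name in MARKER_NAMES:
            out[name] = ~np.all(np.isfinite(self.marker_array(name)), axis=1)
        return pd.DataFrame(out, index=self.data.index)

    def frames(self):
        mask = self.missing_mask()
        for i, row in self.data.iterrows():
            pts = {
                name: np.array([row[f"{name}_x"], row[f"{name}_y"], row[f"{name}_z"]])
                for name in MARKER_NAMES
            }
            missing = frozenset(n for n in MARKER_NAMES if mask.at[i, n])
            yield MarkerFrame(int(row["frame"]), float(row["time"]), pts, missing)

    def mirrored(self) -> "MarkerSeries":
        """Negate all x coordinates (left-arm convention)."""
        df = self.data.copy()
        for name in MARKER_NAMES:
            df[f"{name}_x"] = -df[f"{name}_x"]
        return MarkerSeries(df)


def read_markers(path, fmt: str | None = None) -> MarkerSeries:
    """Read a marker trajectory file (wide CSV, or TRC when ``fmt='trc'``)."""
    path = Path(path)
    if fmt is None:
        fmt = "trc" if path.suffix.lower() == ".trc" else "csv"
    if fmt == "csv":
        return MarkerSeries(pd.read_csv(path))
    if fmt == "trc":
        return _read_trc(path)
    raise ConfigError(f"unknown marker format {fmt!r}")


def write_markers(series, path) -> None:
    """Write a marker series as the canonical wide CSV (9 significant digits)."""
    df = series.data if isinstance(series, MarkerSeries) else series
    df.to_csv(path, index=False, float_format="%.9g")


def _read_trc(path: Path) -> MarkerSeries:
    """Parse the tab-delimited TRC mocap text format (coordinates in mm)."""
    lines = Path(path).read_text().splitlines()
    label_idx = next(
        (i for i, ln in enumerate(lines) if ln.split("\t")[:1] == ["Frame#"]), None
    )
    if label_idx is None:
        raise ConfigError(f"{path}: no 'Frame#' label row; not a TRC file?")
    labels = [s for s in lines[label_idx].split("\t")[2:] if s.strip()]
    unknown = [m for m in labels if m not in MARKER_NAMES]
    if unknown or set(labels) != set(MARKER_NAMES):
        raise ConfigError(
            f"{path}: TRC markers {labels} do not match expected {list(MARKER_NAMES)}"
        )
    rows = []
    for ln in lines[label_idx + 2 :]:  # skip the X/Y/Z sub-header row
        parts = ln.split("\t")
        if len(parts) < 2 or not parts[0].strip():
            continue
        vals = [float(p) if p.strip() else math.nan for p in parts]
        rows.append(vals[: 2 + 3 * len(labels)])
    if not rows:
        raise ConfigError(f"{path}: TRC file has no data rows")
    arr = np.array(rows)
    cols = {"frame": arr[:, 0].astype(int), "time": arr[:, 1]}
    for j, name in enumerate(labels):
        for k, ax in enumerate("xyz"):
            cols[f"{name}_{ax}"] = arr[:, 2 + 3 * j + k]
    df = pd.DataFrame(cols)[["frame", "time", *MARKER_COLUMNS]]
    return MarkerSeries(df)


def moving_average(series, window: int = 25):
    """Centered moving average per coordinate, shrinking symmetric edge windows.

    ``window`` must be odd (a sample count, 25 by default ≈ 0.42 s at
    60 Hz).  Missing (NaN) samples are excluded from their windows.  Accepts
    and returns a :class:`MarkerSeries` (or a plain DataFrame).
    """
    if window < 1 or window % 2 == 0:
        raise ConfigError(f"filter window must be a positive odd integer, got {window}")
    df = series.data if isinstance(series, MarkerSeries) else series
    out = df.copy()
    if window == 1:
        return MarkerSeries(out) if isinstance(series, MarkerSeries) else out
    x = df[list(MARKER_COLUMNS)].to_numpy(dtype=float)
    n = len(x)
    sm = np.empty_like(x)
    half = window // 2
    with np.errstate(invalid="ignore"):
        for i in range(n):
            h = min(half, i, n - 1 - i)
            block = x[i - h : i + h + 1]
            finite = np.isfinite(block)
            cnt = finite.sum(axis=0)
            s = np.where(finite, block, 0.0).sum(axis=0)
            sm[i] = np.where(cnt > 0, s / np.maximum(cnt, 1), np.nan)
    out[list(MARKER_COLUMNS)] = sm
    return MarkerSeries(out) if isinstance(series, MarkerSeries) else out


def calibrate_lengths(series: MarkerSeries, window=None, transform=None) -> np.ndarray:
    """Estimate segment lengths L1..L4 (mm) from a calibration window.

    Uses the per-frame medians of |P4−P3|, |P9−P8|, |P10−P9|, |P13−P10| over
    the complete frames of ``window`` (a slice or frame count; default: the
    whole series).  Distances are frame-invariant, so a transform is
    accepted for API symmetry but not needed.
    """
    df = series.data
    if isinstance(window, int):
        df = df.iloc[:window]
    elif isinstance(window, slice):
        df = df.iloc[window]
    sub = MarkerSeries(df.reset_index(drop=True)) if len(df) else None
    if sub is None:
        raise ConfigError("empty calibration window")
    complete = ~sub.missing_mask().any(axis=1)
    if int(complete.sum()) < 10:
        raise ConfigError(
            f"calibration needs >= 10 complete frames, found {int(complete.sum())}"
        )
    pairs = (("M4", "M3"), ("M9", "M8"), ("M10", "M9"), ("M13", "M10"))
    out = np.empty(4)
    for k, (a, b) in enumerate(pairs):
        d = np.linalg.norm(sub.marker_array(a) - sub.marker_array(b), axis=1)
        out[k] = float(np.median(d[complete.to_numpy()]))
    return out


@dataclass
class PipelineResult:
    """Output bundle of :func:`run_pipeline`."""

    angles: pd.DataFrame
    features: pd.DataFrame | None
    report: dict
    transform: EulerTransform
    model: LimbModel


def _pose_row(pose: PoseAngles, prefix: str = "") -> dict:
    row = {f"{prefix}{lab}": pose.theta[lab] for lab in ANGLE_LABELS}
    if not prefix:
        for lab in ANGLE_LABELS:
            row[f"valid_{lab}"] = pose.validity[lab]
    return row


def detect_category(angles: pd.DataFrame, threshold_deg: float = 2.0, n_frames: int = 10) -> str:
    """Humeral-category detection from the initial motion frames.

    Departure from rest is the first frame where any defined angle deviates
    from its rest reference by more than ``threshold_deg``; the category
    compares the mean θ4 and θ5 over the next ``n_frames`` frames.
    """
    dep = 0
    found = False
    for i in range(len(angles)):
        for lab, rest in REST_REFERENCE.items():
            v = angles[lab].iloc[i]
            if math.isfinite(v) and abs(v - rest) > threshold_deg:
                dep, found = i, True
                break
        if found:
            break
    if not found:
        return "undetermined"
    window = angles.iloc[dep : dep + n_frames]
    t4 = window["theta4"].to_numpy(dtype=float)
    t5 = window["theta5"].to_numpy(dtype=float)
    t4 = t4[np.isfinite(t4)]
    t5 = t5[np.isfinite(t5)]
    if len(t4) == 0 or len(t5) == 0:
        return "undetermined"
    return humeral_category(float(t4.mean()), float(t5.mean()))


def run_pipeline(config: dict) -> PipelineResult:
    """End-to-end batch run: file → filter → calibrate → angles (→ features).

    Config keys (defaults in parentheses): ``input`` path or ``markers``
    series/DataFrame; ``format`` (inferred); ``side`` ("right");
    ``filter_window`` (25); ``beta_deg``/``gamma_deg`` (required);
    ``lengths_mm`` mapping or ``calibrate_window`` (whole series);
    ``calibration_frame_index`` (first fully filtered frame);
    ``resolve_alpha_per_frame`` (False);
    ``method`` ("euclid" | "tps" | "both"); ``wanted_angles`` (all);
    ``compute_features`` (False); optional output paths ``angles_out``,
    ``features_out``, ``markers_out``.
    """
    from . import __version__  # local import to avoid cycle at module load
    from .descriptors import motion_features

    if "markers" in config:
        m = config["markers"]
        series = m if isinstance(m, MarkerSeries) else MarkerSeries(m)
    elif "input" in config:
        series = read_markers(config["input"], config.get("format"))
    else:
        raise ConfigError("config needs 'input' or 'markers'")
    if config.get("side", "right") == "left":
        series = series.mirrored()

    window = int(config.get("filter_window", 25))
    filtered = moving_average(series, window)

    if "lengths_mm" in config:
        lm = config["lengths_mm"]
        lengths = [float(lm[k]) for k in ("L1", "L2", "L3", "L4")]
    else:
        lengths = calibrate_lengths(filtered, config.get("calibrate_window"))
    model = default_model(lengths, clavicle_offset_deg=float(config.get("clavicle_offset_deg", 20.0)))

    try:
        beta = float(config["beta_deg"])
        gamma = float(config["gamma_deg"])
    except KeyError as exc:
        raise ConfigError(f"config needs world-frame angle {exc}") from exc

    # default calibration frame: the first one covered by a full filter
    # window (the shrinking edge windows smooth the leading frames less)
    cal_idx = config.get("calibration_frame_index")
    if cal_idx is None:
        cal_idx = min(window // 2, len(filtered) - 1)
    cal = filtered.data.iloc[int(cal_idx)]
    p3 = Point3(cal["M3_x"], cal["M3_y"], cal["M3_z"], "world")
    p4 = Point3(cal["M4_x"], cal["M4_y"], cal["M4_z"], "world")
    transform = build_transform(p3, p4, beta, gamma, model)

    method = config.get("method", "euclid")
    if method not in ("euclid", "tps", "both"):
        raise ConfigError(f"method must be euclid|tps|both, got {method!r}")
    wanted = config.get("wanted_angles")
    per_frame_alpha = bool(config.get("resolve_alpha_per_frame", False))

    rows = []
    local_frames = []
    n_skipped = 0
    for mf in filtered.frames():
        row = {"frame": mf.frame, "time": mf.time}
        if not mf.is_complete:
            n_skipped += 1
            row["skipped"] = "missing:" + "+".join(sorted(mf.missing))
            rows.append(row)
            continue
        row["skipped"] = ""
        t = transform
        if per_frame_alpha:
            t = build_transform(
                Point3.from_array(mf.points["M3"], "world"),
                Point3.from_array(mf.points["M4"], "world"),
                beta,
                gamma,
                model,
            )
        try:
            if method in ("euclid", "both"):
                pose = extract_pose(mf.points, model, t, wanted)
                row.update(_pose_row(pose))
            if method in ("tps", "both"):
                tpose = angles_via_tps(mf.points, model, t, wanted)
                prefix = "tps_" if method == "both" else ""
                row.update(_pose_row(tpose, prefix))
                if method == "both":
                    for lab in ANGLE_LABELS:
                        row[f"disc_{lab}"] = row[f"tps_{lab}"] - row[lab]
            local_frames.append(
                {pid: t.to_local(xyz) for pid, xyz in mf.as_id_dict().items()}
            )
        except TribsError as exc:
            raise type(exc)(f"frame {mf.frame}: {exc}") from exc
        rows.append(row)
    angles = pd.DataFrame(rows)
    if angles["skipped"].eq("").sum() == 0:
        raise GeometryError("no complete frames in input")

    category = "undetermined"
    if {"theta4", "theta5"} <= set(angles.columns):
        category = detect_category(angles[angles["skipped"] == ""])

    features = None
    if config.get("compute_features", False):
        features = motion_features(local_frames, model, label=config.get("label"))

    report = {
        "version": __version__,
        "n_frames": len(filtered),
        "n_skipped": n_skipped,
        "filter_window": window,
        "alpha_deg": transform.alpha_deg,
        "beta_deg": beta,
        "gamma_deg": gamma,
        "lengths_mm": dict(zip(("L1", "L2", "L3", "L4"), (float(v) for v in model.lengths))),
        "method": method,
        "humeral_category": category,
        "side": config.get("side", "right"),
    }
    if "angles_out" in config:
        angles.to_csv(config["angles_out"], index=False, float_format="%.9g")
    if features is not None and "features_out" in config:
        features.to_csv(config["features_out"], index=False, float_format="%.9g")
    if "markers_out" in config:
        write_markers(filtered, config["markers_out"])
    return PipelineResult(angles, features, report, transform, model)
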