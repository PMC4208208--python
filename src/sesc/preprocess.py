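"""Sensor-stream conditioning: resampling, zero-phase filtering, static
window detection, skeleton-to-posture conversion and CSV readers/writers.

Input streams are time-stamped (possibly irregular): segment orientations
or skeleton joint positions on one side, ground-plane center of pressure
on the other.  The pipeline aligns both onto a shared uniform grid,
optionally low-pass filters them (zero phase, forward-backward
Butterworth), and slides a 1-second window looking for static postures:
a window is static when the CoP standard deviation on each axis stays
below 3 mm and every segment's orientation dispersion (geodesic angle to
the window mean rotation) stays below 5 degrees.  Overlapping static
windows are merged and time-averaged into one posture/CoP pair each.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import interpolate, signal

from ._rotations import nearest_rotation
from .body_model import Posture
from .sesc_core import regressor_block_from_matrices

#: 15-joint skeleton schema, column order of skeleton CSV files
JOINT_NAMES: tuple[str, ...] = (
    "head", "neck", "torso",
    "r_shoulder", "r_elbow", "r_hand",
    "l_shoulder", "l_elbow", "l_hand",
    "r_hip", "r_knee", "r_foot",
    "l_hip", "l_knee", "l_foot",
)

#: limb segment id -> (proximal joint, distal joint)
LIMB_BONES: dict[int, tuple[str, str]] = {
    2: ("r_shoulder", "r_elbow"),
    3: ("r_elbow", "r_hand"),
    4: ("l_shoulder", "l_elbow"),
    5: ("l_elbow", "l_hand"),
    6: ("r_hip", "r_knee"),
    7: ("r_knee", "r_foot"),
    8: ("l_hip", "l_knee"),
    9: ("l_knee", "l_foot"),
}

_MIN_BONE_LENGTH = 1e-9


class StreamValidationError(ValueError):
    """A timed series violates its contract (ordering, shape, NaNs)."""


@dataclass
class TimedSeries:
    """Time-stamped samples; ``values`` may have any trailing shape.

    ``kind="rotations"`` marks streams of 3x3 orientation matrices, which
    are re-orthonormalized after any linear operation (resampling,
    filtering, averaging).
    """

    timestamps: np.ndarray
    values: np.ndarray
    kind: str = "generic"
    name: str = ""

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float).reshape(-1)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.timestamps) != len(self.values):
            raise StreamValidationError("timestamps and values must have equal length")
        if np.any(np.diff(self.timestamps) < 0):
            raise StreamValidationError("timestamps must be non-decreasing")
        if not np.all(np.isfinite(self.values)):
            raise StreamValidationError("values contain NaN/inf; clean the stream first")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def rate(self) -> float:
        """Median sampling rate (Hz)."""
        dt = np.diff(self.timestamps)
        if len(dt) == 0 or np.median(dt) <= 0:
            raise StreamValidationError("cannot infer rate from < 2 distinct timestamps")
        return float(1.0 / np.median(dt))


def _interp_onto(series: TimedSeries, grid: np.ndarray) -> TimedSeries:
    t, values = series.timestamps, series.values
    keep = np.concatenate([[True], np.diff(t) > 0])  # splines need strict order
    t, values = t[keep], values[keep]
    flat = values.reshape(len(t), -1)
    k = min(3, len(t) - 1)
    spline = interpolate.make_interp_spline(t, flat, k=k, axis=0)
    out = spline(np.clip(grid, t[0], t[-1]))
    values = out.reshape((len(grid),) + series.values.shape[1:])
    return TimedSeries(grid, values, kind=series.kind, name=series.name)


def resample(series: TimedSeries, rate: float) -> TimedSeries:
    """Spline interpolation onto a uniform grid at ``rate`` Hz.

    Cubic where the series allows it (lower order for very short
    series); exact for affine signals and for samples already on the
    target grid."""
    if len(series) < 2:
        raise StreamValidationError("resampling needs at least 2 samples")
    t0, t1 = series.timestamps[0], series.timestamps[-1]
    if t1 - t0 < 1.0 / rate:
        raise StreamValidationError("series shorter than one sample period")
    n = int(np.floor((t1 - t0) * rate)) + 1
    grid = t0 + np.arange(n) / rate
    return _interp_onto(series, grid)


def align_streams(a: TimedSeries, b: TimedSeries, rate: float) -> tuple[TimedSeries, TimedSeries]:
    """Interpolate two sensor streams onto a shared uniform grid over their
    overlapping time span."""
    t0 = max(a.timestamps[0], b.timestamps[0])
    t1 = min(a.timestamps[-1], b.timestamps[-1])
    if t1 - t0 < 1.0 / rate:
        raise StreamValidationError("streams do not overlap long enough to align")
    n = int(np.floor((t1 - t0) * rate)) + 1
    grid = t0 + np.arange(n) / rate
    return _interp_onto(a, grid), _interp_onto(b, grid)


def zero_phase_lowpass(series: TimedSeries, cutoff: float, order: int = 2) -> TimedSeries:
    """Forward-backward Butterworth low-pass (zero net phase shift).

    The effective magnitude response is the filter's squared, so the gain
    at the cutoff frequency is -3 dB applied twice (amplitude ~0.5).
    """
    dt = np.diff(series.timestamps)
    # tolerate sub-millisecond jitter such as CSV timestamp quantization
    if len(dt) == 0 or np.abs(dt - dt.mean()).max() > 1e-3 * dt.mean():
        raise StreamValidationError("zero-phase filtering requires uniform sampling")
    fs = 1.0 / dt.mean()
    if cutoff >= fs / 2.0:
        raise StreamValidationError(
            f"cutoff {cutoff} Hz must be below the Nyquist frequency {fs / 2.0} Hz"
        )
    sos = signal.butter(order, cutoff, fs=fs, output="sos")
    flat = series.values.reshape(len(series), -1)
    out = signal.sosfiltfilt(sos, flat, axis=0)
    values = out.reshape(series.values.shape)
    # rotation streams are filtered entrywise and left unprojected so that
    # linear averaging downstream stays exact; consumers needing a true
    # rotation (Posture construction) project with nearest_rotation
    return TimedSeries(series.timestamps.copy(), values, kind=series.kind, name=series.name)


@dataclass
class StaticWindow:
    """A merged static interval: time-averaged posture and CoP plus the
    dispersion levels that qualified it.

    ``mean_regressor`` is the exact linear time-average of the per-sample
    regressor rows (regressor entries are linear in the orientation
    matrix entries); ``mean_posture`` carries the nearest-rotation
    projection of the averaged orientations for estimation and display.
    """

    start: float
    end: float
    mean_posture: Posture
    mean_cop: np.ndarray
    cop_std_mm: float
    max_orientation_std_deg: float
    n_samples: int
    mean_regressor: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mean_cop = np.asarray(self.mean_cop, dtype=float).reshape(2)


def detect_static_windows(
    orientations: TimedSeries,
    cop: TimedSeries,
    root: TimedSeries | None = None,
    window_s: float = 1.0,
    orient_thresh_deg: float = 5.0,
    cop_thresh_mm: float = 3.0,
) -> list[StaticWindow]:
    """Find static postures by sliding a fixed-length window (step 1 sample).

    ``orientations`` holds (N, 9, 3, 3) segment orientation matrices and
    ``cop`` (N, 2) ground-plane CoP in meters, on the same uniform grid;
    ``root`` optionally carries the (N, 3) root origin so the averaged
    postures are complete.  A window is static iff each CoP axis has a
    standard deviation strictly below the threshold and every segment's
    orientation dispersion about the window mean stays strictly below the
    orientation threshold.  Overlapping static windows are merged and
    averaged over their union (mean rotations re-orthonormalized).
    """
    if len(orientations) != len(cop) or not np.allclose(
        orientations.timestamps, cop.timestamps, atol=1e-9
    ):
        raise StreamValidationError("orientation and CoP streams must share one grid")
    if root is not None and len(root) != len(cop):
        raise StreamValidationError("root stream must share the common grid")
    rate = orientations.rate
    w = int(round(window_s * rate))
    n = len(orientations)
    if w < 2:
        raise StreamValidationError("window too short for the sampling rate")
    if n < w:
        warnings.warn("streams shorter than one window; no static windows", stacklevel=2)
        return []

    R = orientations.values.reshape(n, 9, 3, 3)
    P = cop.values.reshape(n, 2)
    nw = n - w + 1

    cop_wins = sliding_window_view(P, w, axis=0)  # (nw, 2, w)
    cop_ok = (cop_wins.std(axis=-1) < cop_thresh_mm / 1000.0).all(axis=1)

    # window-mean rotations via cumulative sums, then per-sample geodesic angles
    csum = np.concatenate([np.zeros((1, 9, 3, 3)), np.cumsum(R, axis=0)], axis=0)
    mean_R = nearest_rotation((csum[w:] - csum[:-w]) / w)  # (nw, 9, 3, 3)
    sq = np.zeros((nw, 9))
    for j in range(w):
        tr = np.einsum("nsij,nsij->ns", mean_R, R[j : j + nw])
        sq += np.arccos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0)) ** 2
    disp = np.sqrt(sq / w)  # rad, rms geodesic displacement about the mean
    orient_ok = (disp < np.deg2rad(orient_thresh_deg)).all(axis=1)

    static = cop_ok & orient_ok
    ts = orientations.timestamps
    windows: list[StaticWindow] = []
    i = 0
    while i < nw:
        if not static[i]:
            i += 1
            continue
        j = i
        while j + 1 < nw and static[j + 1]:
            j += 1
        sl = slice(i, j + w)  # union of samples covered by windows i..j
        raw_mean = R[sl].mean(axis=0)
        mean_root = (
            root.values.reshape(n, 3)[sl].mean(axis=0) if root is not None else np.zeros(3)
        )
        t_mid = 0.5 * (ts[i] + ts[j + w - 1])
        windows.append(
            StaticWindow(
                start=float(ts[i]),
                end=float(ts[j + w - 1]),
                mean_posture=Posture(
                    timestamp=t_mid,
                    orientations=nearest_rotation(raw_mean),
                    root_origin=mean_root,
                ),
                mean_cop=P[sl].mean(axis=0),
                cop_std_mm=float(P[sl].std(axis=0).max() * 1000.0),
                max_orientation_std_deg=float(np.rad2deg(disp[i : j + 1].max())),
                n_samples=sl.stop - sl.start,
                mean_regressor=regressor_block_from_matrices(raw_mean),
            )
        )
        i = j + 1
    return windows


# ---------------------------------------------------------------------------
# skeleton joints -> segment orientations

def _unit(v: np.ndarray, what: str) -> np.ndarray:
    norm = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(norm < _MIN_BONE_LENGTH):
        raise StreamValidationError(f"zero-length bone: {what} (coincident joints)")
    return v / norm


def _limb_frames(prox: np.ndarray, dist: np.ndarray, what: str) -> np.ndarray:
    """Rotation matrices whose z-axis is the proximal->distal unit vector.

    Limb twist about the bone is unobservable from two joints, so the
    frame is completed deterministically with the minimal (twist-free)
    rotation that carries the hanging direction (0, 0, -1) onto the bone.
    This map is continuous in the bone direction everywhere except a bone
    pointing straight up (where it falls back to an x-axis reference), so
    static-window dispersion is not polluted by completion jumps between
    neighbouring samples.  Shapes (..., 3) -> (..., 3, 3).
    """
    z = _unit(dist - prox, what)
    # minimal rotation R taking a = (0,0,-1) to z: R = I + [v]x + [v]x^2/(1+c)
    c = -z[..., 2]  # a . z
    v = np.stack([z[..., 1], -z[..., 0], np.zeros_like(c)], axis=-1)  # a x z
    V = np.zeros(z.shape[:-1] + (3, 3))
    V[..., 0, 1], V[..., 0, 2] = -v[..., 2], v[..., 1]
    V[..., 1, 0], V[..., 1, 2] = v[..., 2], -v[..., 0]
    V[..., 2, 0], V[..., 2, 1] = -v[..., 1], v[..., 0]
    eye = np.broadcast_to(np.eye(3), V.shape)
    safe = 1.0 + c > 1e-12
    scale = np.where(safe, 1.0 / np.where(safe, 1.0 + c, 1.0), 0.0)
    R = eye + V + np.matmul(V, V) * scale[..., None, None]
    A = R @ np.diag([1.0, -1.0, -1.0])  # post-rotate the hanging frame
    if not np.all(safe):  # bone (numerically) straight up: Gram-Schmidt vs x
        zz = z[~safe]
        x = np.broadcast_to(np.array([1.0, 0.0, 0.0]), zz.shape).copy()
        x -= np.einsum("...i,...i->...", x, zz)[..., None] * zz
        x = _unit(x, what)
        A[~safe] = np.stack([x, np.cross(zz, x), zz], axis=-1)
    return A


def _torso_frames(neck: np.ndarray, r_hip: np.ndarray, l_hip: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Torso orientation and root origin from neck and hip joints: z runs
    mid-hip -> neck, y is the left->right hip direction orthogonalized
    against z, x = y cross z.  Returns (A1 (..., 3, 3), root (..., 3))."""
    mid_hip = 0.5 * (r_hip + l_hip)
    z = _unit(neck - mid_hip, "mid_hip->neck")
    ydir = r_hip - l_hip
    y = ydir - (np.einsum("...i,...i->...", ydir, z))[..., None] * z
    y = _unit(y, "hip line")
    x = np.cross(y, z)
    return np.stack([x, y, z], axis=-1), mid_hip


def joints_to_posture(joints: Mapping[str, np.ndarray], timestamp: float = 0.0) -> Posture:
    """Convert one sample of named 3-D joint positions to a posture.

    Limb twist about the bone axis is unobservable from two points; the
    deterministic completion fixes it, which is harmless downstream since
    CoM estimation only uses the limb z-axes.
    """
    missing = [j for j in ("neck", "r_hip", "l_hip") if j not in joints]
    for sid, (p, d) in LIMB_BONES.items():
        missing += [j for j in (p, d) if j not in joints]
    if missing:
        raise StreamValidationError(f"missing joints: {sorted(set(missing))}")
    get = lambda name: np.asarray(joints[name], dtype=float).reshape(3)
    A = np.empty((9, 3, 3))
    A[0], root = _torso_frames(get("neck"), get("r_hip"), get("l_hip"))
    for sid, (p, d) in LIMB_BONES.items():
        A[sid - 1] = _limb_frames(get(p), get(d), f"{p}->{d}")
    return Posture(timestamp=timestamp, orientations=A, root_origin=root)


def skeleton_to_posture_series(skeleton: TimedSeries) -> tuple[TimedSeries, TimedSeries]:
    """Vectorized joint->orientation conversion for a whole stream.

    ``skeleton.values`` is (N, 15, 3) in :data:`JOINT_NAMES` order; returns
    an orientation stream (N, 9, 3, 3) and a root-origin stream (N, 3).
    """
    J = skeleton.values.reshape(len(skeleton), len(JOINT_NAMES), 3)
    idx = {name: k for k, name in enumerate(JOINT_NAMES)}
    A = np.empty((len(skeleton), 9, 3, 3))
    A[:, 0], root = _torso_frames(J[:, idx["neck"]], J[:, idx["r_hip"]], J[:, idx["l_hip"]])
    for sid, (p, d) in LIMB_BONES.items():
        A[:, sid - 1] = _limb_frames(J[:, idx[p]], J[:, idx[d]], f"{p}->{d}")
    return (
        TimedSeries(skeleton.timestamps.copy(), A, kind="rotations", name="orientations"),
        TimedSeries(skeleton.timestamps.copy(), root, name="root_origin"),
    )


# ---------------------------------------------------------------------------
# CSV readers and writers (meters, '#'-prefixed metadata header lines)

def _write_csv(path: str | Path, df: pd.DataFrame, meta: Mapping[str, str] | None) -> None:
    with open(path, "w") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, index=False, float_format="%.6f")


def write_skeleton_csv(
    path: str | Path, skeleton: TimedSeries, meta: Mapping[str, str] | None = None
) -> None:
    """Skeleton stream: columns ``time_s`` plus ``<joint>_x/_y/_z`` (m)."""
    J = skeleton.values.reshape(len(skeleton), len(JOINT_NAMES), 3)
    cols: dict[str, np.ndarray] = {"time_s": skeleton.timestamps}
    for k, joint in enumerate(JOINT_NAMES):
        for a, ax in enumerate("xyz"):
            cols[f"{joint}_{ax}"] = J[:, k, a]
    _write_csv(path, pd.DataFrame(cols), {"units": "m", **(meta or {})})


def read_skeleton_csv(path: str | Path) -> TimedSeries:
    df = pd.read_csv(path, comment="#")
    if "time_s" not in df.columns:
        raise StreamValidationError(f"{path}: missing time_s column")
    missing = [
        f"{j}_{ax}" for j in JOINT_NAMES for ax in "xyz" if f"{j}_{ax}" not in df.columns
    ]
    if missing:
        raise StreamValidationError(f"{path}: missing joint columns {missing[:6]}...")
    J = np.stack(
        [df[[f"{j}_x", f"{j}_y", f"{j}_z"]].to_numpy(dtype=float) for j in JOINT_NAMES],
        axis=1,
    )
    return TimedSeries(df["time_s"].to_numpy(dtype=float), J, name="skeleton")


def write_cop_csv(
    path: str | Path, cop: TimedSeries, meta: Mapping[str, str] | None = None
) -> None:
    """CoP stream: columns ``time_s, cop_x_m, cop_y_m``."""
    P = cop.values.reshape(len(cop), 2)
    df = pd.DataFrame({"time_s": cop.timestamps, "cop_x_m": P[:, 0], "cop_y_m": P[:, 1]})
    _write_csv(path, df, {"units": "m", **(meta or {})})


def read_cop_csv(path: str | Path) -> TimedSeries:
    df = pd.read_csv(path, comment="#")
    for col in ("time_s", "cop_x_m", "cop_y_m"):
        if col not in df.columns:
            raise StreamValidationError(f"{path}: missing column {col}")
    return TimedSeries(
        df["time_s"].to_numpy(dtype=float),
        df[["cop_x_m", "cop_y_m"]].to_numpy(dtype=float),
        name="cop",
    )
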