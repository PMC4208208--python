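"""Virtual subjects and virtual recording sessions.

Stands in for the motion-capture + force-plate hardware: a virtual
subject is a 9-segment body model whose mass distribution deviates from
the literature table by a controlled amount (left/right tied, so it
remains bilaterally symmetric); a virtual session renders a sequence of
held static postures joined by short smooth transitions, computes the
ground-truth CoM directly from the model, sets the CoP equal to the CoM
ground projection (exact during holds, by the quiet-stance assumption),
and perturbs orientations, root origin and CoP with sensor-like noise.

Noise presets: ``vicon_like`` (0.5 deg, 1 mm CoP, 2 mm root) and
``kinect_like`` (5 deg, 3 mm CoP, 15 mm root).  Orientation noise is an
i.i.d. per-sample random small rotation (angle ~ |N(0, sigma)|, uniform
axis); real depth-camera noise is temporally correlated, which this
generator deliberately does not emulate.

All randomness flows from a single integer seed through named
sub-streams, so repeated calls are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation, Slerp

from . import __version__
from ._rotations import nearest_rotation, random_small_rotations, rot_x, rot_y, rot_z
from .anthropometry import (
    AnthropometricTable,
    SegmentFractions,
    body_model_from_table,
    winter_table,
)
from .body_model import (
    BodyModel,
    Posture,
    forward_kinematics_batch,
    whole_body_com_batch,
)
from .preprocess import JOINT_NAMES, StaticWindow, TimedSeries, write_cop_csv, write_skeleton_csv
from .sesc_core import regressor_block_from_matrices


@dataclass(frozen=True)
class NoiseProfile:
    """Sensor noise magnitudes (standard deviations)."""

    orientation_noise_deg: float
    cop_noise_mm: float
    root_noise_mm: float
    name: str = ""

    def __post_init__(self) -> None:
        if min(self.orientation_noise_deg, self.cop_noise_mm, self.root_noise_mm) < 0:
            raise ValueError("noise standard deviations must be >= 0")


NOISE_PRESETS: dict[str, NoiseProfile] = {
    "none": NoiseProfile(0.0, 0.0, 0.0, name="none"),
    "vicon_like": NoiseProfile(0.5, 1.0, 2.0, name="vicon_like"),
    "kinect_like": NoiseProfile(5.0, 3.0, 15.0, name="kinect_like"),
}


def noise_preset(name: str) -> NoiseProfile:
    try:
        return NOISE_PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown noise preset {name!r}; choose from {sorted(NOISE_PRESETS)}"
        ) from None


def _stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Named sub-stream of the session seed (stable across platforms)."""
    digest = hashlib.sha256(f"{seed}:{stream}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


# ---------------------------------------------------------------------------
# virtual subjects

def generate_subject(
    seed: int,
    height: float = 1.76,
    mass: float = 76.1,
    deviation: float = 0.0,
    table: AnthropometricTable | None = None,
) -> BodyModel:
    """A body model whose mass/CoM fractions deviate from the table.

    Each merged-segment mass fraction is multiplied by ``1 + deviation*u``
    with ``u ~ U(-1, 1)`` (left and right tied), then renormalized to sum
    to one; CoM fractions are perturbed the same way.  ``deviation=0``
    returns exactly the table model.  Defaults match the study cohort's
    mean stature and mass.
    """
    if not 0.0 <= deviation < 1.0:
        raise ValueError("deviation must be in [0, 1)")
    table = table or winter_table()
    if deviation == 0.0:
        return body_model_from_table(height, mass, table)
    rng = _stream_rng(seed, "subject")
    names = list(table.segments)
    for _ in range(100):
        u_mass = rng.uniform(-1.0, 1.0, size=len(names))
        u_com = rng.uniform(-1.0, 1.0, size=len(names))
        masses = {
            n: table.segments[n].mass * (1.0 + deviation * u)
            for n, u in zip(names, u_mass)
        }
        coms = {
            n: table.segments[n].com * (1.0 + deviation * u)
            for n, u in zip(names, u_com)
        }
        if any(m <= 0 for m in masses.values()):
            continue
        total = masses["torso"] + 2.0 * sum(
            v for n, v in masses.items() if n != "torso"
        )
        masses = {n: v / total for n, v in masses.items()}
        if any(not 0.0 < c < 1.0 for c in coms.values()) or any(
            not 0.0 < m < 1.0 for m in masses.values()
        ):
            continue
        perturbed = replace(
            table,
            name=f"{table.name}+dev{deviation}",
            segments={
                n: SegmentFractions(mass=masses[n], length=table.segments[n].length, com=coms[n])
                for n in names
            },
        )
        return body_model_from_table(height, mass, perturbed)
    raise ValueError("could not draw a valid perturbed mass distribution in 100 attempts")


# ---------------------------------------------------------------------------
# posture sampling

#: per-joint angle ranges (degrees) spanning arm raises, leans and
#: single-leg-style variants; stratified across holds for excitation.
ANGLE_RANGES_DEG: dict[str, tuple[float, float]] = {
    "root_pitch": (-15.0, 15.0),
    "root_roll": (-10.0, 10.0),
    "root_yaw": (-20.0, 20.0),
    "r_shoulder_flexion": (-30.0, 150.0),
    "r_shoulder_abduction": (-5.0, 120.0),
    "r_elbow_flexion": (0.0, 130.0),
    "l_shoulder_flexion": (-30.0, 150.0),
    "l_shoulder_abduction": (-5.0, 120.0),
    "l_elbow_flexion": (0.0, 130.0),
    "r_hip_flexion": (-10.0, 70.0),
    "r_hip_abduction": (-5.0, 35.0),
    "r_knee_flexion": (0.0, 90.0),
    "l_hip_flexion": (-10.0, 70.0),
    "l_hip_abduction": (-5.0, 35.0),
    "l_knee_flexion": (0.0, 90.0),
}

#: root-origin shift ranges (m) in the ground plane
ROOT_SHIFT_RANGE_M = (-0.05, 0.05)


def _stratified(rng: np.random.Generator, lo: float, hi: float, n: int) -> np.ndarray:
    """One sample per equal-width bin, bins visited in random order."""
    bins = rng.permutation(n)
    return lo + (bins + rng.uniform(size=n)) * (hi - lo) / n


def sample_hold_angles(rng: np.random.Generator, n_holds: int) -> dict[str, np.ndarray]:
    """Stratified joint angles (radians) for ``n_holds`` static postures."""
    angles = {
        name: np.deg2rad(_stratified(rng, lo, hi, n_holds))
        for name, (lo, hi) in ANGLE_RANGES_DEG.items()
    }
    angles["root_shift_x"] = _stratified(rng, *ROOT_SHIFT_RANGE_M, n_holds)
    angles["root_shift_y"] = _stratified(rng, *ROOT_SHIFT_RANGE_M, n_holds)
    return angles


_FLIP = rot_x(np.pi)  # neutral hanging pose: limb z points down in the parent frame


def _hold_rotations(angles: dict[str, np.ndarray], k: int) -> tuple[np.ndarray, np.ndarray]:
    """Relative joint rotations (9, 3, 3) and root rotation for hold ``k``."""
    a = {name: vals[k] for name, vals in angles.items()}
    rel = np.empty((9, 3, 3))
    rel[0] = np.eye(3)
    for side, sgn in (("r", +1.0), ("l", -1.0)):
        shoulder = (
            rot_y(-a[f"{side}_shoulder_flexion"])
            @ rot_x(sgn * a[f"{side}_shoulder_abduction"])
            @ _FLIP
        )
        elbow = rot_y(-a[f"{side}_elbow_flexion"])
        hip = (
            rot_y(-a[f"{side}_hip_flexion"])
            @ rot_x(sgn * a[f"{side}_hip_abduction"])
            @ _FLIP
        )
        knee = rot_y(a[f"{side}_knee_flexion"])
        if side == "r":
            rel[1], rel[2], rel[5], rel[6] = shoulder, elbow, hip, knee
        else:
            rel[3], rel[4], rel[7], rel[8] = shoulder, elbow, hip, knee
    root_rot = rot_z(a["root_yaw"]) @ rot_y(a["root_pitch"]) @ rot_x(a["root_roll"])
    return rel, root_rot


# ---------------------------------------------------------------------------
# sessions

@dataclass
class VirtualSession:
    """Rendered session: noisy measurement streams plus ground truth."""

    model: BodyModel
    noise: NoiseProfile
    seed: int
    rate: float
    hold_s: float
    transition_s: float
    orientations: TimedSeries  # noisy (N, 9, 3, 3)
    root: TimedSeries  # noisy (N, 3)
    cop: TimedSeries  # noisy (N, 2)
    clean_orientations: TimedSeries
    clean_root: TimedSeries
    truth_com: np.ndarray  # (N, 3)
    hold_labels: list[tuple[float, float]]

    @property
    def n_holds(self) -> int:
        return len(self.hold_labels)


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def generate_session(
    model: BodyModel,
    n_holds: int,
    hold_s: float = 5.0,
    rate: float = 15.0,
    noise: NoiseProfile | str = "none",
    seed: int = 0,
    transition_s: float = 1.0,
) -> VirtualSession:
    """Render ``n_holds`` held static postures with smooth transitions.

    Each hold lasts ``hold_s`` seconds at the given sampling rate;
    consecutive holds are joined by ``transition_s``-long eased movements
    (excluded from the hold labels).  The CoP equals the ground projection
    of the direct-model CoM plus noise; orientations and the measured
    root origin are perturbed per the noise profile.
    """
    if n_holds < 1:
        raise ValueError("n_holds must be >= 1")
    if isinstance(noise, str):
        noise = noise_preset(noise)

    rng_post = _stream_rng(seed, "postures")
    angles = sample_hold_angles(rng_post, n_holds)
    rels, root_rots = zip(*(_hold_rotations(angles, k) for k in range(n_holds)))

    leg_len = model.segment(6).length + model.segment(7).length
    root_keys = np.stack(
        [
            np.array([angles["root_shift_x"][k], angles["root_shift_y"][k], leg_len])
            for k in range(n_holds)
        ]
    )

    # keyframe times: each hold contributes (start, end), transitions between
    starts = np.arange(n_holds) * (hold_s + transition_s)
    key_times = np.empty(2 * n_holds)
    key_times[0::2] = starts
    key_times[1::2] = starts + hold_s
    total = key_times[-1]
    t = np.arange(int(np.floor(total * rate)) + 1) / rate

    # warp query times so transitions follow a smoothstep profile
    t_warp = t.copy()
    for k in range(n_holds - 1):
        e = starts[k] + hold_s
        in_tr = (t > e) & (t < starts[k + 1])
        t_warp[in_tr] = e + _smoothstep((t[in_tr] - e) / transition_s) * transition_s

    def _interp_rotations(key_mats: np.ndarray) -> np.ndarray:
        keys = np.repeat(key_mats, 2, axis=0)  # hold start == hold end
        slerp = Slerp(key_times, Rotation.from_matrix(keys))
        return slerp(np.clip(t_warp, key_times[0], key_times[-1])).as_matrix()

    T = len(t)
    rel_t = np.empty((T, 9, 3, 3))
    for i in range(9):
        rel_t[:, i] = _interp_rotations(np.stack([r[i] for r in rels]))
    root_rot_t = _interp_rotations(np.stack(root_rots))
    root_t = np.empty((T, 3))
    keys_rep = np.repeat(root_keys, 2, axis=0)
    for a in range(3):
        root_t[:, a] = np.interp(t_warp, key_times, keys_rep[:, a])

    A_clean, origins = forward_kinematics_batch(model, rel_t, root_rot_t, root_t)
    truth_com = whole_body_com_batch(model, A_clean, origins)

    sigma_rad = np.deg2rad(noise.orientation_noise_deg)
    noise_R = random_small_rotations(_stream_rng(seed, "orientation_noise"), (T, 9), sigma_rad)
    A_noisy = np.einsum("tsij,tsjk->tsik", noise_R, A_clean)
    root_noisy = root_t + _stream_rng(seed, "root_noise").normal(
        0.0, noise.root_noise_mm / 1000.0, size=(T, 3)
    )
    cop = truth_com[:, :2] + _stream_rng(seed, "cop_noise").normal(
        0.0, noise.cop_noise_mm / 1000.0, size=(T, 2)
    )

    labels = [(float(starts[k]), float(starts[k] + hold_s)) for k in range(n_holds)]
    return VirtualSession(
        model=model,
        noise=noise,
        seed=seed,
        rate=rate,
        hold_s=hold_s,
        transition_s=transition_s,
        orientations=TimedSeries(t, A_noisy, kind="rotations", name="orientations"),
        root=TimedSeries(t, root_noisy, name="root_origin"),
        cop=TimedSeries(t, cop, name="cop"),
        clean_orientations=TimedSeries(t, A_clean, kind="rotations", name="orientations"),
        clean_root=TimedSeries(t, root_t, name="root_origin"),
        truth_com=truth_com,
        hold_labels=labels,
    )


def windows_from_session(session: VirtualSession, clean: bool = False) -> list[StaticWindow]:
    """Average each labeled hold into one static window (label oracle).

    With ``clean=True`` the noiseless streams are averaged instead, which
    is useful for exact-recovery checks.
    """
    t = session.cop.timestamps
    A = (session.clean_orientations if clean else session.orientations).values
    root = (session.clean_root if clean else session.root).values
    P = session.cop.values if not clean else session.truth_com[:, :2]
    windows = []
    for t0, t1 in session.hold_labels:
        mask = (t >= t0 - 1e-9) & (t <= t1 + 1e-9)
        raw_mean = A[mask].mean(axis=0)
        posture = Posture(
            timestamp=0.5 * (t0 + t1),
            orientations=nearest_rotation(raw_mean),
            root_origin=root[mask].mean(axis=0),
        )
        windows.append(
            StaticWindow(
                start=t0,
                end=t1,
                mean_posture=posture,
                mean_cop=P[mask].mean(axis=0),
                cop_std_mm=float(P[mask].std(axis=0).max() * 1000.0),
                max_orientation_std_deg=0.0,
                n_samples=int(mask.sum()),
                mean_regressor=regressor_block_from_matrices(raw_mean),
            )
        )
    return windows


# ---------------------------------------------------------------------------
# skeleton rendering and session bundles

def joint_positions(model: BodyModel, A: np.ndarray, root: np.ndarray) -> np.ndarray:
    """Skeleton joint positions (T, 15, 3) from orientations and root origin.

    Joint origins are walked down the chain with the given (possibly
    noisy) orientations; distal joints sit at each segment's length along
    its z-axis.  The head marker is a fixed 0.15 m above the neck along
    the torso axis (cosmetic: nothing downstream uses it).
    """
    T = A.shape[0]
    O = np.empty((T, 9, 3))
    O[:, 0] = root
    from .body_model import TOPOLOGY  # local import to avoid cycle noise

    for sid in range(2, 10):
        p = TOPOLOGY[sid] - 1
        O[:, sid - 1] = O[:, p] + np.einsum(
            "tij,j->ti", A[:, p], model.segment(sid).attach_offset
        )

    def distal(idx: int) -> np.ndarray:
        seg = model.segments[idx]
        return O[:, idx] + A[:, idx, :, 2] * seg.length

    neck = distal(0)
    out = {
        "neck": neck,
        "head": neck + A[:, 0, :, 2] * 0.15,
        "torso": O[:, 0] + A[:, 0, :, 2] * (model.segment(1).length / 2.0),
        "r_shoulder": O[:, 1], "r_elbow": O[:, 2], "r_hand": distal(2),
        "l_shoulder": O[:, 3], "l_elbow": O[:, 4], "l_hand": distal(4),
        "r_hip": O[:, 5], "r_knee": O[:, 6], "r_foot": distal(6),
        "l_hip": O[:, 7], "l_knee": O[:, 8], "l_foot": distal(8),
    }
    return np.stack([out[name] for name in JOINT_NAMES], axis=1)


def session_skeleton(session: VirtualSession, clean: bool = False) -> TimedSeries:
    """Skeleton stream rendered from the session's (noisy) orientations."""
    A = (session.clean_orientations if clean else session.orientations).values
    root = (session.clean_root if clean else session.root).values
    return TimedSeries(
        session.cop.timestamps.copy(),
        joint_positions(session.model, A, root),
        name="skeleton",
    )


def save_session(session: VirtualSession, out_dir: str | Path) -> Path:
    """Write a session bundle: model.json, skeleton.csv, cop.csv,
    labels.json, manifest.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    session.model.to_json(out / "model.json")
    meta = {"seed": str(session.seed), "noise": session.noise.name or "custom"}
    write_skeleton_csv(out / "skeleton.csv", session_skeleton(session), meta)
    write_cop_csv(out / "cop.csv", session.cop, meta)
    (out / "labels.json").write_text(json.dumps({"holds_s": session.hold_labels}, indent=2))
    manifest = {
        "seed": session.seed,
        "noise_profile": {
            "name": session.noise.name,
            "orientation_noise_deg": session.noise.orientation_noise_deg,
            "cop_noise_mm": session.noise.cop_noise_mm,
            "root_noise_mm": session.noise.root_noise_mm,
        },
        "rate_hz": session.rate,
        "n_holds": session.n_holds,
        "hold_s": session.hold_s,
        "transition_s": session.transition_s,
        "height_m": session.model.height,
        "mass_kg": session.model.total_mass,
        "package_version": __version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


@dataclass
class LoadedSession:
    """A session bundle read back from disk (measurement view only)."""

    model: BodyModel
    skeleton: TimedSeries
    cop: TimedSeries
    hold_labels: list[tuple[float, float]]
    manifest: dict


def load_session(bundle_dir: str | Path) -> LoadedSession:
    from .preprocess import read_cop_csv, read_skeleton_csv

    d = Path(bundle_dir)
    labels = json.loads((d / "labels.json").read_text())["holds_s"]
    return LoadedSession(
        model=BodyModel.from_json(d / "model.json"),
        skeleton=read_skeleton_csv(d / "skeleton.csv"),
        cop=read_cop_csv(d / "cop.csv"),
        hold_labels=[(float(a), float(b)) for a, b in labels],
        manifest=json.loads((d / "manifest.json").read_text()),
    )


#: (name, noise preset, deviation, seed) of the standard fixture sessions
FIXTURE_SPECS: tuple[tuple[str, str, float, int], ...] = (
    ("vicon_dev0", "vicon_like", 0.0, 101),
    ("vicon_dev02", "vicon_like", 0.2, 102),
    ("kinect_dev0", "kinect_like", 0.0, 103),
    ("kinect_dev02", "kinect_like", 0.2, 104),
)


def make_fixture_suite(out_dir: str | Path, n_holds: int = 10) -> list[Path]:
    """Write the four standard seeded fixture sessions (generated at run
    time; nothing is shipped on disk)."""
    out = Path(out_dir)
    paths = []
    for name, profile, deviation, seed in FIXTURE_SPECS:
        model = generate_subject(seed, deviation=deviation)
        session = generate_session(
            model, n_holds=n_holds, noise=noise_preset(profile), seed=seed
        )
        paths.append(save_session(session, out / name))
    return paths
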