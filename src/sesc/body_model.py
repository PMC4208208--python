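"""Nine-segment rigid-body humanoid: topology, forward kinematics and the
direct (mass-weighted) whole-body center of mass.

The body is modelled as nine rigid segments connected in a tree rooted at
the torso: 1 = torso (head and neck merged in), 2/3 = right upper arm /
forearm (hand merged), 4/5 = the left arm pair, 6/7 = right thigh / shank
(foot merged), 8/9 = the left leg pair.  Frame conventions:

* global frame: x anterior (AP), y toward the subject's right (ML),
  z vertical up; the ground plane is z = 0 and "ground projection" means
  the (x, y) pair;
* each segment's local z-axis points from its proximal joint toward its
  distal joint, so limb CoM offsets are on-axis vectors ``(0, 0, c_z)``
  with ``c_z >= 0`` measured from the proximal joint.

``whole_body_com_direct`` computes CoM as the mass-weighted mean of the
segment CoM positions; it serves as the ground-truth oracle against which
the serial-chain estimator is checked.
"""

from __future__ import annotations

import json
from dataclasses import InitVar, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._rotations import is_rotation, orthonormality_defect

#: child -> parent segment ids; 0 is the world (the torso is the floating root).
TOPOLOGY: dict[int, int] = {1: 0, 2: 1, 3: 2, 4: 1, 5: 4, 6: 1, 7: 6, 8: 1, 9: 8}

#: right/left pairs that must match under bilateral symmetry.
SYMMETRY_PAIRS: tuple[tuple[int, int], ...] = ((2, 4), (3, 5), (6, 8), (7, 9))

SEGMENT_NAMES: dict[int, str] = {
    1: "torso",
    2: "right upper arm",
    3: "right forearm",
    4: "left upper arm",
    5: "left forearm",
    6: "right thigh",
    7: "right shank",
    8: "left thigh",
    9: "left shank",
}


class ModelValidationError(ValueError):
    """A body model violates topology, symmetry or mass constraints."""


class DegenerateModelError(ModelValidationError):
    """Total mass is zero: the center of mass is undefined."""


class PostureValidationError(ValueError):
    """An orientation matrix is not a proper rotation."""


def _vec3(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float).reshape(-1)
    if arr.shape != (3,):
        raise ModelValidationError(f"{name} must be a 3-vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ModelValidationError(f"{name} must be finite")
    return arr


@dataclass(frozen=True)
class BodySegment:
    """One rigid segment of the humanoid.

    ``attach_offset`` is the position of this segment's proximal joint in
    the *parent's* local frame; ``com_offset`` is the segment CoM in its
    own frame.  ``length`` is the distance to the child joint along the
    local z-axis.
    """

    id: int
    parent_id: int
    mass: float
    length: float
    com_offset: np.ndarray
    attach_offset: np.ndarray

    def __post_init__(self) -> None:
        if self.id not in TOPOLOGY:
            raise ModelValidationError(f"segment id must be 1..9, got {self.id}")
        if self.parent_id != TOPOLOGY[self.id]:
            raise ModelValidationError(
                f"segment {self.id} must have parent {TOPOLOGY[self.id]}, "
                f"got {self.parent_id}"
            )
        if self.mass < 0:
            raise ModelValidationError(f"segment {self.id}: mass must be >= 0")
        if self.length < 0:
            raise ModelValidationError(f"segment {self.id}: length must be >= 0")
        object.__setattr__(self, "com_offset", _vec3(self.com_offset, "com_offset"))
        object.__setattr__(self, "attach_offset", _vec3(self.attach_offset, "attach_offset"))
        if self.id >= 2 and np.abs(self.com_offset[:2]).max() > 1e-12:
            # limb CoM restricted to the proximal->distal axis (model reduction)
            raise ModelValidationError(
                f"segment {self.id} ({SEGMENT_NAMES[self.id]}): limb com_offset "
                "must be on-axis (zero x, y components)"
            )

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "parent_id": self.parent_id,
            "mass_kg": self.mass,
            "length_m": self.length,
            "com_offset_m": list(self.com_offset),
            "attach_offset_m": list(self.attach_offset),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BodySegment":
        return cls(
            id=int(d["id"]),
            parent_id=int(d["parent_id"]),
            mass=float(d["mass_kg"]),
            length=float(d["length_m"]),
            com_offset=d["com_offset_m"],
            attach_offset=d["attach_offset_m"],
        )


@dataclass
class BodyModel:
    """Ordered collection of the nine segments plus subject height."""

    segments: tuple[BodySegment, ...]
    height: float

    def __post_init__(self) -> None:
        self.segments = tuple(self.segments)
        if len(self.segments) != 9:
            raise ModelValidationError(f"expected 9 segments, got {len(self.segments)}")
        ids = [s.id for s in self.segments]
        if ids != list(range(1, 10)):
            raise ModelValidationError(f"segments must be ordered by id 1..9, got {ids}")
        if self.height <= 0:
            raise ModelValidationError("height must be positive")

    @property
    def total_mass(self) -> float:
        return float(sum(s.mass for s in self.segments))

    def segment(self, sid: int) -> BodySegment:
        return self.segments[sid - 1]

    def is_symmetric(self, tol: float = 1e-9) -> bool:
        """True when right/left pairs share mass, length and CoM offset."""
        for r, l in SYMMETRY_PAIRS:
            a, b = self.segment(r), self.segment(l)
            if abs(a.mass - b.mass) > tol or abs(a.length - b.length) > tol:
                return False
            if np.abs(a.com_offset - b.com_offset).max() > tol:
                return False
        return True

    def to_dict(self) -> dict:
        return {
            "height_m": self.height,
            "total_mass_kg": self.total_mass,
            "segments": [s.to_dict() for s in self.segments],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BodyModel":
        segs = sorted((BodySegment.from_dict(s) for s in d["segments"]), key=lambda s: s.id)
        return cls(segments=tuple(segs), height=float(d["height_m"]))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "BodyModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class Posture:
    """Per-segment global orientations plus the torso-root origin at one instant.

    ``orientations[i]`` is the 3x3 matrix mapping segment ``i+1``'s local frame
    to the global frame; ``root_origin`` is the global position of the torso
    frame origin (the mid-hip point).
    """

    timestamp: float
    orientations: np.ndarray
    root_origin: np.ndarray
    validate: InitVar[bool] = True

    def __post_init__(self, validate: bool) -> None:
        self.orientations = np.asarray(self.orientations, dtype=float).reshape(9, 3, 3)
        self.root_origin = _vec3(self.root_origin, "root_origin")
        if validate:
            for i in range(9):
                defect = orthonormality_defect(self.orientations[i])
                if defect > 1e-9:
                    raise PostureValidationError(
                        f"orientation of segment {i + 1} ({SEGMENT_NAMES[i + 1]}) is "
                        f"not a proper rotation (defect {defect:.2e})"
                    )


@dataclass
class PostureSequence:
    """Time-ordered postures on a uniform grid."""

    postures: list[Posture]
    sampling_rate: float

    def __post_init__(self) -> None:
        ts = np.array([p.timestamp for p in self.postures])
        if len(ts) > 1 and not np.all(np.diff(ts) > 0):
            raise ValueError("posture timestamps must be strictly increasing")


def forward_kinematics(
    model: BodyModel,
    joint_rotations: Sequence[np.ndarray] | np.ndarray,
    root_rotation: np.ndarray | None = None,
    root_origin: np.ndarray | Iterable[float] = (0.0, 0.0, 0.0),
    timestamp: float = 0.0,
) -> Posture:
    """Compose per-joint relative rotations down the chain into a posture.

    ``joint_rotations`` holds nine rotations of each segment relative to its
    parent frame (entry 0, the torso's, is composed onto ``root_rotation``
    and is the identity in typical use).
    """
    rel = np.asarray(joint_rotations, dtype=float).reshape(9, 3, 3)
    for i in range(9):
        if not is_rotation(rel[i], tol=1e-8):
            raise PostureValidationError(
                f"relative rotation of segment {i + 1} ({SEGMENT_NAMES[i + 1]}) "
                "is not orthonormal"
            )
    root_rot = np.eye(3) if root_rotation is None else np.asarray(root_rotation, float)
    if not is_rotation(root_rot, tol=1e-8):
        raise PostureValidationError("root rotation is not orthonormal")

    A = np.empty((9, 3, 3))
    A[0] = root_rot @ rel[0]
    for sid in range(2, 10):
        A[sid - 1] = A[TOPOLOGY[sid] - 1] @ rel[sid - 1]
    return Posture(timestamp=timestamp, orientations=A, root_origin=np.asarray(root_origin, float))


def segment_origins(model: BodyModel, posture: Posture) -> np.ndarray:
    """Global origin of each segment frame, (9, 3), by walking the chain."""
    A = posture.orientations
    origins = np.empty((9, 3))
    origins[0] = posture.root_origin
    for sid in range(2, 10):
        p = TOPOLOGY[sid] - 1
        origins[sid - 1] = origins[p] + A[p] @ model.segment(sid).attach_offset
    return origins


def whole_body_com_direct(model: BodyModel, posture: Posture) -> np.ndarray:
    """Mass-weighted whole-body CoM in the global frame (the oracle).

    ``CoM = (1/M) * sum_i m_i (A_i c_i + d_i)`` with ``d_i`` the global
    origin of segment frame ``i``.
    """
    M = model.total_mass
    if M <= 0:
        raise DegenerateModelError("total mass is zero; CoM undefined")
    origins = segment_origins(model, posture)
    masses = np.array([s.mass for s in model.segments])
    coms = np.einsum("sij,sj->si", posture.orientations,
                     np.stack([s.com_offset for s in model.segments])) + origins
    return (masses[:, None] * coms).sum(axis=0) / M


# ---------------------------------------------------------------------------
# batched (time-axis) variants used by the virtual-session generator

def forward_kinematics_batch(
    model: BodyModel,
    rel: np.ndarray,
    root_rot: np.ndarray,
    root_origin: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized chain composition over a time axis.

    Parameters are ``rel`` (T, 9, 3, 3) relative rotations, ``root_rot``
    (T, 3, 3) and ``root_origin`` (T, 3); returns global orientations
    (T, 9, 3, 3) and frame origins (T, 9, 3).
    """
    T = rel.shape[0]
    A = np.empty((T, 9, 3, 3))
    O = np.empty((T, 9, 3))
    A[:, 0] = np.einsum("tij,tjk->tik", root_rot, rel[:, 0])
    O[:, 0] = root_origin
    for sid in range(2, 10):
        p = TOPOLOGY[sid] - 1
        A[:, sid - 1] = np.einsum("tij,tjk->tik", A[:, p], rel[:, sid - 1])
        O[:, sid - 1] = O[:, p] + np.einsum(
            "tij,j->ti", A[:, p], model.segment(sid).attach_offset
        )
    return A, O


def whole_body_com_batch(model: BodyModel, A: np.ndarray, origins: np.ndarray) -> np.ndarray:
    """Direct CoM per time sample for batched orientations/origins, (T, 3)."""
    M = model.total_mass
    if M <= 0:
        raise DegenerateModelError("total mass is zero; CoM undefined")
    masses = np.array([s.mass for s in model.segments])
    offs = np.stack([s.com_offset for s in model.segments])
    coms = np.einsum("tsij,sj->tsi", A, offs) + origins
    return np.einsum("s,tsi->ti", masses, coms) / M
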