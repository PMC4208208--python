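"""Statically equivalent serial chain (SESC): parameters, regressor,
least-squares identification and CoM estimation.

The whole-body CoM of a rigid multi-body chain can be written as the end
effector of an open serial chain whose constant geometry encodes the mass
distribution.  Expressed relative to the torso root, the CoM ground
projection observed in each static posture is linear in a constant
parameter vector, here reduced to seven numbers by (a) restricting limb
CoMs to the segment axis and (b) bilateral symmetry:

``C - d0 = A1 r1 + (a2 + a4) r2 + (a3 + a5) r3 + (a6 + a8) r6 + (a7 + a9) r7``

where ``d0`` is the root origin, ``A1`` the torso orientation, ``a_i``
the global z-axis (third column) of segment ``i``'s orientation, ``r1``
a 3-vector in torso axes, and ``r2, r3, r6, r7`` on-axis scalars for the
upper-arm, forearm(+hand), thigh and shank(+foot) pairs.  Stacking the
x/y rows of this relation over many static postures, with the measured
center of pressure standing in for the CoM ground projection, gives an
overdetermined linear system solved by Moore-Penrose pseudo-inverse.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .body_model import (
    BodyModel,
    DegenerateModelError,
    ModelValidationError,
    Posture,
)

PARAMETER_LABELS: tuple[str, ...] = ("r1x", "r1y", "r1z", "r2", "r3", "r6", "r7")

#: relative singular-value cutoff used for rank decisions and pseudo-inversion
SVD_RCOND = 1e-10


class RankDeficiencyError(ValueError):
    """The stacked regressor does not excite all seven parameters."""

    def __init__(self, rank: int, cond: float):
        self.rank = rank
        self.cond = cond
        super().__init__(
            f"identification system is rank deficient (rank {rank} < 7, "
            f"cond {cond:.3g}); record a wider variety of static postures"
        )


@dataclass
class SESCParameters:
    """Reduced 7-parameter chain: ``r1`` (torso, 3-vector in torso-local
    axes, meters) and on-axis scalars ``r2, r3, r6, r7`` (meters) for the
    bilaterally tied limb pairs.  ``height`` enables normalization for
    between-subject comparison."""

    r1: np.ndarray
    r2: float
    r3: float
    r6: float
    r7: float
    height: float | None = None

    def __post_init__(self) -> None:
        self.r1 = np.asarray(self.r1, dtype=float).reshape(3)
        vec = self.as_vector()
        if not np.all(np.isfinite(vec)):
            raise ValueError("SESC parameters must be finite")
        if self.height is not None and self.height <= 0:
            raise ValueError("height must be positive when given")

    def as_vector(self) -> np.ndarray:
        """Parameter vector ordered ``(r1x, r1y, r1z, r2, r3, r6, r7)``."""
        return np.concatenate([self.r1, [self.r2, self.r3, self.r6, self.r7]])

    @classmethod
    def from_vector(cls, v: np.ndarray, height: float | None = None) -> "SESCParameters":
        v = np.asarray(v, dtype=float).reshape(7)
        return cls(r1=v[:3], r2=v[3], r3=v[4], r6=v[5], r7=v[6], height=height)

    def normalized(self) -> np.ndarray:
        """Height-normalized (dimensionless) parameter vector."""
        if self.height is None or self.height <= 0:
            raise ValueError("height must be set for normalization")
        return self.as_vector() / self.height

    def to_dict(self, height_normalized: bool = False) -> dict:
        vec = self.normalized() if height_normalized else self.as_vector()
        return {
            "units": "dimensionless (height-normalized)" if height_normalized else "m",
            "height_normalized": height_normalized,
            "height_m": self.height,
            "parameters": dict(zip(PARAMETER_LABELS, (float(x) for x in vec))),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SESCParameters":
        vec = np.array([d["parameters"][k] for k in PARAMETER_LABELS], dtype=float)
        height = d.get("height_m")
        if d.get("height_normalized"):
            if height is None:
                raise ValueError("height_m required to denormalize parameters")
            vec = vec * height
        return cls.from_vector(vec, height=height)

    def to_json(self, path: str | Path, height_normalized: bool = False) -> None:
        Path(path).write_text(json.dumps(self.to_dict(height_normalized), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SESCParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class IdentificationSystem:
    """Stacked regressor ``D`` (2m x 7) and root-relative CoP targets ``y``.

    Each static posture contributes one x-row and one y-row (interleaved).
    """

    D: np.ndarray
    y: np.ndarray
    posture_count: int
    metadata: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        self.y = np.asarray(self.y, dtype=float).reshape(-1)
        if self.D.ndim != 2 or self.D.shape[1] != 7:
            raise ValueError(f"D must be (2m, 7), got {self.D.shape}")
        if self.D.shape[0] != 2 * self.posture_count or len(self.y) != self.D.shape[0]:
            raise ValueError("row count must be 2 * posture_count, matching y")

    def to_csv(self, path: str | Path) -> None:
        """Audit export: one row per stacked equation, columns D | y."""
        header = ",".join(list(PARAMETER_LABELS) + ["y_m"])
        data = np.column_stack([self.D, self.y])
        np.savetxt(path, data, delimiter=",", header=header, comments="# ")


def true_sesc_from_model(model: BodyModel, symmetry_tol: float = 1e-9) -> SESCParameters:
    """Ground-truth reduced SESC parameters of a known symmetric body model.

    ``r1`` collects the torso CoM plus the limb attachment points weighted
    by the mass hanging from each (the full arm or leg chain's mass); the
    on-axis scalars carry each limb pair's own mass distribution:

    ``r1 = (c1 m1 + d12 (m2+m3) + d14 (m4+m5) + d16 (m6+m7) + d18 (m8+m9)) / M``
    ``r2 = (c2 m2 + l2 m3) / M``, ``r3 = c3 m3 / M`` and analogously for
    the legs (``l`` is segment length; everything divided by total mass).
    """
    M = model.total_mass
    if M <= 0:
        raise DegenerateModelError("total mass is zero; SESC undefined")
    if not model.is_symmetric(tol=symmetry_tol):
        raise ModelValidationError(
            "reduced 7-parameter SESC requires a bilaterally symmetric model"
        )
    s = model.segment
    r1 = (
        s(1).com_offset * s(1).mass
        + s(2).attach_offset * (s(2).mass + s(3).mass)
        + s(4).attach_offset * (s(4).mass + s(5).mass)
        + s(6).attach_offset * (s(6).mass + s(7).mass)
        + s(8).attach_offset * (s(8).mass + s(9).mass)
    ) / M
    r2 = (s(2).com_offset[2] * s(2).mass + s(2).length * s(3).mass) / M
    r3 = s(3).com_offset[2] * s(3).mass / M
    r6 = (s(6).com_offset[2] * s(6).mass + s(6).length * s(7).mass) / M
    r7 = s(7).com_offset[2] * s(7).mass / M
    return SESCParameters(r1=r1, r2=r2, r3=r3, r6=r6, r7=r7, height=model.height)


def regressor_block_from_matrices(A: np.ndarray) -> np.ndarray:
    """Regressor rows from a (9, 3, 3) stack of orientation matrices.

    Every entry is linear in the matrix entries, so this may be applied
    to time-averaged (not exactly orthonormal) matrices: averaging the
    regressor commutes with averaging the orientations.
    """
    A = np.asarray(A, dtype=float).reshape(9, 3, 3)
    a = A[:, :, 2]  # third columns: segment z-axes in the global frame
    block = np.empty((2, 7))
    block[:, 0:3] = A[0][:2, :]
    block[:, 3] = (a[1] + a[3])[:2]
    block[:, 4] = (a[2] + a[4])[:2]
    block[:, 5] = (a[5] + a[7])[:2]
    block[:, 6] = (a[6] + a[8])[:2]
    return block


def build_regressor_block(posture: Posture) -> np.ndarray:
    """The 2x7 regressor rows contributed by one posture.

    Columns 1-3 are the x/y rows of the torso orientation; columns 4-7
    are the ground components of the summed limb-pair z-axes.
    """
    return regressor_block_from_matrices(posture.orientations)


def _window_block_cop(window) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(regressor block, cop, root ground projection) of one window.

    Static windows carry the exact linear average of the per-sample
    regressor (``mean_regressor``); plain ``(posture, cop)`` pairs fall
    back to the block of the averaged posture.
    """
    if isinstance(window, tuple):
        posture, cop = window
        block = build_regressor_block(posture)
        root_xy = posture.root_origin[:2]
    else:  # StaticWindow-like
        block = getattr(window, "mean_regressor", None)
        if block is None:
            block = build_regressor_block(window.mean_posture)
        cop = window.mean_cop
        root_xy = window.mean_posture.root_origin[:2]
    return np.asarray(block, float), np.asarray(cop, dtype=float).reshape(2), root_xy


def assemble_identification_system(
    static_windows: Sequence,
) -> IdentificationSystem:
    """Stack regressor blocks and root-relative CoP targets over windows.

    Accepts ``StaticWindow`` objects or ``(mean_posture, mean_cop)`` pairs;
    each window is one time-averaged static posture.  The target rows are
    the CoP minus the root origin's ground projection, making the solved
    parameters root-relative constants.
    """
    windows = list(static_windows)
    if not windows:
        raise ValueError("at least one static window is required")
    D_rows, y_rows, meta = [], [], []
    for w in windows:
        block, cop, root_xy = _window_block_cop(w)
        D_rows.append(block)
        y_rows.extend(cop - root_xy)
        meta.append(w)
    return IdentificationSystem(
        D=np.vstack(D_rows), y=np.array(y_rows), posture_count=len(windows), metadata=meta
    )


def identify(system: IdentificationSystem, min_rank_check: bool = True) -> SESCParameters:
    """Least-squares SESC parameters via SVD pseudo-inverse.

    With ``min_rank_check`` on (default), a regressor of column rank < 7
    raises :class:`RankDeficiencyError`; switching it off returns the
    minimum-norm least-squares solution with a warning.
    """
    sol, _, rank, s = np.linalg.lstsq(system.D, system.y, rcond=SVD_RCOND)
    cond = float(s[0] / s[-1]) if s[-1] > 0 else float("inf")
    if rank < 7:
        if min_rank_check:
            raise RankDeficiencyError(rank=int(rank), cond=cond)
        warnings.warn(
            f"rank-deficient system (rank {rank} < 7); returning the "
            "minimum-norm least-squares solution",
            RuntimeWarning,
            stacklevel=2,
        )
    return SESCParameters.from_vector(sol)


def estimate_com(params: SESCParameters, posture: Posture) -> np.ndarray:
    """3-D CoM estimate for an arbitrary posture from identified parameters.

    ``C = d0 + A1 r1 + (a2+a4) r2 + (a3+a5) r3 + (a6+a8) r6 + (a7+a9) r7``;
    the ground projection is the (x, y) pair of the result.
    """
    A = posture.orientations
    a = A[:, :, 2]
    return (
        posture.root_origin
        + A[0] @ params.r1
        + (a[1] + a[3]) * params.r2
        + (a[2] + a[4]) * params.r3
        + (a[5] + a[7]) * params.r6
        + (a[6] + a[8]) * params.r7
    )


def estimate_com_batch(
    params: SESCParameters, A: np.ndarray, root_origin: np.ndarray
) -> np.ndarray:
    """Vectorized :func:`estimate_com` over a time axis of orientations."""
    a = A[:, :, :, 2]
    return (
        np.asarray(root_origin, dtype=float)
        + np.einsum("tij,j->ti", A[:, 0], params.r1)
        + (a[:, 1] + a[:, 3]) * params.r2
        + (a[:, 2] + a[:, 4]) * params.r3
        + (a[:, 5] + a[:, 7]) * params.r6
        + (a[:, 6] + a[:, 8]) * params.r7
    )
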