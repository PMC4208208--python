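"""Small rotation-matrix utilities shared across modules.

All functions operate on arrays whose last two axes are 3x3 rotation
matrices and broadcast over any leading axes.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

_EYE3 = np.eye(3)


def nearest_rotation(m: np.ndarray) -> np.ndarray:
    """Project matrices onto SO(3) (orthogonal Procrustes, det +1).

    Used to re-orthonormalize time-averaged or filtered orientation
    matrices; for inputs close to a rotation this is the geodesically
    nearest rotation.
    """
    m = np.asarray(m, dtype=float)
    u, _, vt = np.linalg.svd(m)
    det = np.linalg.det(np.matmul(u, vt))
    u = u.copy()
    flip = np.where(det < 0.0, -1.0, 1.0)
    u[..., :, -1] *= np.asarray(flip)[..., None]
    return np.matmul(u, vt)


def orthonormality_defect(m: np.ndarray) -> float:
    """Max absolute entry of ``m^T m - I`` plus ``|det(m) - 1|`` (scalar input)."""
    m = np.asarray(m, dtype=float)
    return float(np.abs(m.T @ m - _EYE3).max() + abs(np.linalg.det(m) - 1.0))


def is_rotation(m: np.ndarray, tol: float = 1e-9) -> bool:
    return orthonormality_defect(m) <= tol


def geodesic_angle(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation angle (rad) between matrices ``a`` and ``b``, broadcast."""
    tr = np.einsum("...ij,...ij->...", np.asarray(a, float), np.asarray(b, float))
    return np.arccos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0))


def rot_x(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def rot_y(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rot_z(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def random_rotations(rng: np.random.Generator, n: int | None = None) -> np.ndarray:
    """Uniformly distributed rotation matrices."""
    return Rotation.random(n, random_state=rng).as_matrix()


def random_small_rotations(
    rng: np.random.Generator, shape: tuple[int, ...], sigma_rad: float
) -> np.ndarray:
    """Perturbation rotations: angle ~ |N(0, sigma)|, axis uniform on the sphere."""
    shape = tuple(shape)
    if sigma_rad == 0.0:
        return np.broadcast_to(_EYE3, shape + (3, 3)).copy()
    axes = rng.normal(size=shape + (3,))
    axes /= np.linalg.norm(axes, axis=-1, keepdims=True)
    angles = np.abs(rng.normal(0.0, sigma_rad, size=shape))
    rotvec = (axes * angles[..., None]).reshape(-1, 3)
    return Rotation.from_rotvec(rotvec).as_matrix().reshape(shape + (3, 3))
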