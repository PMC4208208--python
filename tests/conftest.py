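import numpy as np
import pytest

from sesc._rotations import random_rotations
from sesc.anthropometry import winter_body_model
from sesc.body_model import BodyModel, BodySegment, Posture, forward_kinematics


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def winter_model():
    return winter_body_model(height=1.75, mass=70.0)


def _random_symmetric_model(rng: np.random.Generator) -> BodyModel:
    """A random bilaterally symmetric 9-segment model (independent of the
    anthropometric-table construction)."""
    def limb(sid, parent, mass, length, attach):
        return BodySegment(sid, parent, mass, length,
                           com_offset=(0.0, 0.0, rng.uniform(0.2, 0.8) * length),
                           attach_offset=attach)

    torso_len = rng.uniform(0.4, 0.6)
    w_sh, w_hip = rng.uniform(0.1, 0.25), rng.uniform(0.05, 0.15)
    m = rng.uniform(0.5, 10.0, size=5)  # torso, upper arm, forearm, thigh, shank
    L = rng.uniform(0.2, 0.5, size=4)
    torso = BodySegment(1, 0, m[0], torso_len,
                        com_offset=rng.uniform(-0.1, 0.3, size=3),
                        attach_offset=(0.0, 0.0, 0.0))
    ua_r = limb(2, 1, m[1], L[0], (0.0, +w_sh, torso_len))
    fa_r = BodySegment(3, 2, m[2], L[1], ua_r.com_offset * 0 + (0, 0, rng.uniform(0.1, 0.4)),
                       attach_offset=(0.0, 0.0, L[0]))
    th_r = limb(6, 1, m[3], L[2], (0.0, +w_hip, 0.0))
    sh_r = BodySegment(7, 6, m[4], L[3], (0.0, 0.0, rng.uniform(0.1, 0.4)),
                       attach_offset=(0.0, 0.0, L[2]))
    mirror = np.array([1.0, -1.0, 1.0])

    def mirrored(seg, sid, parent):
        return BodySegment(sid, parent, seg.mass, seg.length,
                           com_offset=seg.com_offset,
                           attach_offset=seg.attach_offset * mirror)

    segments = (torso, ua_r, fa_r,
                mirrored(ua_r, 4, 1), mirrored(fa_r, 5, 4),
                th_r, sh_r,
                mirrored(th_r, 8, 1), mirrored(sh_r, 9, 8))
    return BodyModel(segments=segments, height=rng.uniform(1.5, 2.0))


@pytest.fixture
def random_symmetric_model(rng):
    return _random_symmetric_model(rng)


@pytest.fixture
def make_symmetric_model():
    return _random_symmetric_model


def _random_posture(rng: np.random.Generator, model: BodyModel) -> Posture:
    return forward_kinematics(
        model,
        random_rotations(rng, 9),
        root_rotation=random_rotations(rng),
        root_origin=rng.normal(scale=0.5, size=3),
    )


@pytest.fixture
def make_posture():
    return _random_posture
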