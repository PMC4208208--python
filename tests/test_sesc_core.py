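"""SESC construction, regressor assembly, identification and estimation."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from sesc._rotations import random_rotations, rot_x, rot_y
from sesc.body_model import (
    BodyModel,
    BodySegment,
    ModelValidationError,
    Posture,
    forward_kinematics,
    whole_body_com_direct,
)
from sesc.sesc_core import (
    RankDeficiencyError,
    SESCParameters,
    assemble_identification_system,
    build_regressor_block,
    estimate_com,
    identify,
    true_sesc_from_model,
)

I9 = np.broadcast_to(np.eye(3), (9, 3, 3))


def test_all_mass_in_torso_collapses_to_torso_com(winter_model):
    segs = [
        BodySegment(s.id, s.parent_id, s.mass if s.id == 1 else 0.0, s.length,
                    s.com_offset, s.attach_offset)
        for s in winter_model.segments
    ]
    model = BodyModel(segments=tuple(segs), height=winter_model.height)
    params = true_sesc_from_model(model)
    assert params.r2 == params.r3 == params.r6 == params.r7 == 0.0
    assert np.allclose(params.r1, model.segment(1).com_offset)


def test_sesc_identity_oracle(rng, make_symmetric_model, make_posture):
    """Core theorem: chain estimate == direct mass-weighted CoM, any posture."""
    for _ in range(20):
        model = make_symmetric_model(rng)
        params = true_sesc_from_model(model)
        for _ in range(5):
            p = make_posture(rng, model)
            assert np.abs(
                estimate_com(params, p) - whole_body_com_direct(model, p)
            ).max() < 1e-9


def test_asymmetric_model_rejected(winter_model):
    segs = list(winter_model.segments)
    s = segs[1]
    segs[1] = BodySegment(s.id, s.parent_id, s.mass * 1.1, s.length,
                          s.com_offset, s.attach_offset)
    model = BodyModel(segments=tuple(segs), height=winter_model.height)
    with pytest.raises(ModelValidationError, match="symmetric"):
        true_sesc_from_model(model)


def test_regressor_block_identity_posture():
    p = Posture(0.0, I9, np.zeros(3))
    block = build_regressor_block(p)
    expected = np.zeros((2, 7))
    expected[0, 0] = expected[1, 1] = 1.0  # torso x/y rows; vertical limb axes vanish
    assert np.allclose(block, expected)


def test_regressor_block_horizontal_arm(winter_model):
    # right arm raised to horizontal along +x; left arm stays vertical
    rel = np.array(I9)
    rel[1] = rot_y(np.pi / 2)
    p = forward_kinematics(winter_model, rel)
    block = build_regressor_block(p)
    assert np.allclose(block[:, 3], [1.0, 0.0], atol=1e-12)  # a2 + a4 = (1,0,0)+(0,0,1)


def test_regressor_block_mirror_symmetry_cancels_ml():
    rel = np.array(I9)
    rel[1], rel[3] = rot_x(0.7), rot_x(-0.7)  # arms
    rel[5], rel[7] = rot_x(0.3), rot_x(-0.3)  # legs
    p = forward_kinematics(
        BodyModel(segments=_unit_segments(), height=1.7), rel
    )
    block = build_regressor_block(p)
    assert np.allclose(block[1, 3:], 0.0, atol=1e-12)


def _unit_segments():
    attach = {2: (0, 0.2, 0.5), 4: (0, -0.2, 0.5), 6: (0, 0.1, 0), 8: (0, -0.1, 0),
              3: (0, 0, 0.3), 5: (0, 0, 0.3), 7: (0, 0, 0.4), 9: (0, 0, 0.4)}
    segs = [BodySegment(1, 0, 1.0, 0.5, (0, 0, 0.3), (0, 0, 0))]
    for sid in range(2, 10):
        segs.append(BodySegment(sid, {2: 1, 3: 2, 4: 1, 5: 4, 6: 1, 7: 6, 8: 1, 9: 8}[sid],
                                1.0, 0.35, (0, 0, 0.15), attach[sid]))
    return tuple(segs)


def _windows_from_model(rng, model, params, n):
    """Noiseless (posture, cop) pairs consistent with the true parameters."""
    windows = []
    for _ in range(n):
        p = forward_kinematics(
            model, random_rotations(rng, 9), random_rotations(rng),
            rng.normal(size=3),
        )
        cop = whole_body_com_direct(model, p)[:2]
        windows.append((p, cop))
    return windows


def test_assemble_shapes_and_noiseless_consistency(rng, random_symmetric_model):
    model = random_symmetric_model
    params = true_sesc_from_model(model)
    windows = _windows_from_model(rng, model, params, 40)
    system = assemble_identification_system(windows[:1])
    assert system.D.shape == (2, 7) and system.y.shape == (2,)
    system = assemble_identification_system(windows)
    assert np.abs(system.y - system.D @ params.as_vector()).max() < 1e-12


def test_duplicated_window_leaves_solution_unchanged(rng, random_symmetric_model):
    model = random_symmetric_model
    windows = _windows_from_model(rng, model, true_sesc_from_model(model), 12)
    sol_a = identify(assemble_identification_system(windows)).as_vector()
    sol_b = identify(assemble_identification_system(windows + windows[:1])).as_vector()
    assert np.allclose(sol_a, sol_b, atol=1e-10)


def test_noiseless_identification_recovers_truth(rng, random_symmetric_model):
    model = random_symmetric_model
    params = true_sesc_from_model(model)
    system = assemble_identification_system(
        _windows_from_model(rng, model, params, 40)
    )
    sol = identify(system)
    assert np.abs(sol.as_vector() - params.as_vector()).max() < 1e-9


def test_rank_deficiency_raised_for_repeated_posture(rng, random_symmetric_model):
    model = random_symmetric_model
    w = _windows_from_model(rng, model, true_sesc_from_model(model), 1)
    system = assemble_identification_system(w * 2)
    with pytest.raises(RankDeficiencyError) as exc:
        identify(system)
    assert exc.value.rank < 7


def test_zero_target_gives_zero_parameters(rng, random_symmetric_model):
    model = random_symmetric_model
    windows = _windows_from_model(rng, model, true_sesc_from_model(model), 10)
    system = assemble_identification_system(windows)
    system.y = np.zeros_like(system.y)
    assert np.allclose(identify(system).as_vector(), 0.0)


def test_minimum_norm_contract_when_overridden(rng, random_symmetric_model):
    """Rank-deficient override returns the SVD minimum-norm solution."""
    model = random_symmetric_model
    w = _windows_from_model(rng, model, true_sesc_from_model(model), 2)
    system = assemble_identification_system(w + w)  # 8 rows, rank <= 4
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sol = identify(system, min_rank_check=False).as_vector()
    oracle = np.linalg.pinv(system.D, rcond=1e-10) @ system.y
    assert np.allclose(sol, oracle, atol=1e-10)
    # any least-squares solution has norm >= the minimum-norm one
    assert np.linalg.norm(sol) <= np.linalg.norm(oracle) + 1e-12


@settings(max_examples=40, derandomize=True, deadline=None)
@given(
    v=arrays(np.float64, (3,), elements=st.floats(-10.0, 10.0)),
    seed=st.integers(0, 2**16),
)
def test_estimate_com_translation_equivariance(v, seed):
    """Shifting the root shifts the chain estimate by exactly the same vector."""
    local = np.random.default_rng(seed)
    from tests.conftest import _random_posture, _random_symmetric_model

    model = _random_symmetric_model(local)
    params = true_sesc_from_model(model)
    p = _random_posture(local, model)
    p_shift = Posture(p.timestamp, p.orientations, p.root_origin + v)
    assert np.allclose(estimate_com(params, p_shift), estimate_com(params, p) + v,
                       atol=1e-9)


def test_parameters_json_roundtrip(tmp_path):
    params = SESCParameters(r1=[0.01, -0.02, 0.23], r2=0.011, r3=0.004,
                            r6=0.045, r7=0.015, height=1.8)
    path = tmp_path / "params.json"
    params.to_json(path, height_normalized=True)
    loaded = SESCParameters.from_json(path)
    assert np.allclose(loaded.as_vector(), params.as_vector())
    assert loaded.height == params.height


def test_system_csv_export(tmp_path, rng, random_symmetric_model):
    model = random_symmetric_model
    system = assemble_identification_system(
        _windows_from_model(rng, model, true_sesc_from_model(model), 5)
    )
    path = tmp_path / "system.csv"
    system.to_csv(path)
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    assert np.allclose(data[:, :7], system.D)
    assert np.allclose(data[:, 7], system.y)
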