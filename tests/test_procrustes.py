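import numpy as np
import pytest

from emats import procrustes
from emats.data import EmaTrajectory, SensorLayout
from emats.procrustes import (
    ProcrustesParams,
    apply_matching,
    estimate_params,
    match_corpus,
    shape_from_trajectories,
    unapply_matching,
)


def _canonical_shape(n=40, rng_seed=0):
    """Shape in canonical pose: centroid ~origin, lip axis vertical."""
    rng = np.random.default_rng(rng_seed)
    pts, labels = [], []
    for sensor, (v0, a0) in {
        "TT": (0.0, 12.0), "TB": (-3.0, 5.0), "TR": (-6.0, -4.0),
        "UL": (10.0, 2.0), "LL": (-10.0, 2.0), "JAW": (-14.0, -10.0),
    }.items():
        p = np.column_stack([
            v0 + rng.normal(0, 1.5, n), a0 + rng.normal(0, 1.5, n)
        ])
        pts.append(p)
        labels.append(np.full(n, sensor))
    pts = np.concatenate(pts)
    labels = np.concatenate(labels)
    pts -= pts.mean(axis=0)
    # re-align lip axis exactly vertical
    shape = procrustes.Shape(points=pts, sensor=labels)
    params = estimate_params(shape)
    R = params.rotation_matrix()
    return procrustes.Shape(points=(pts - [params.c_v, params.c_a]) @ R.T, sensor=labels)


def _transform_points(points, theta, shift):
    """Forward speaker transform: inverse-rotate canonical points, then translate."""
    p = ProcrustesParams(c_v=shift[0], c_a=shift[1], theta=theta)
    Rinv = p.rotation_matrix().T
    return points @ Rinv.T + shift


class TestEstimate:
    def test_canonical_pose_gives_identity(self):
        shape = _canonical_shape()
        params = estimate_params(shape)
        assert abs(params.theta) < 1e-9
        assert abs(params.c_v) < 1e-9 and abs(params.c_a) < 1e-9

    @pytest.mark.parametrize("theta,shift", [
        (np.deg2rad(30), (5.0, -2.0)),
        (-0.7, (0.0, 3.0)),
        (2.5, (-4.0, -4.0)),
    ])
    def test_recovers_planted_transform(self, theta, shift):
        shape = _canonical_shape()
        moved = procrustes.Shape(
            points=_transform_points(shape.points, theta, np.asarray(shift)),
            sensor=shape.sensor,
        )
        params = estimate_params(moved)
        assert params.theta == pytest.approx(theta, abs=1e-9)
        assert params.c_v == pytest.approx(shift[0], abs=1e-9)
        assert params.c_a == pytest.approx(shift[1], abs=1e-9)

    def test_unit_size_shape_is_scale_fixed_point(self):
        shape = _canonical_shape()
        pts = shape.points - shape.points.mean(axis=0)
        pts = pts / np.sqrt(np.sum(pts**2, axis=0))  # unit size per axis
        unit = procrustes.Shape(points=pts, sensor=shape.sensor)
        params = estimate_params(unit, use_scale=True)
        assert params.beta_v == pytest.approx(1.0, abs=1e-9)
        assert params.beta_a == pytest.approx(1.0, abs=1e-9)

    def test_coincident_lip_centroids_error(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        shape = procrustes.Shape(points=pts, sensor=np.array(["UL", "LL", "TT"]))
        with pytest.raises(ValueError, match="rotation undefined"):
            estimate_params(shape)


def _traj_from_plane(points_v, points_a, rate=100.0):
    """Embed one sensor path per sensor into a full 18-channel trajectory."""
    layout = SensorLayout()
    T = points_v.shape[0]
    samples = np.zeros((T, 18))
    for i, sensor in enumerate(layout.sensor_names):
        samples[:, layout.column(sensor, procrustes.VERTICAL_DIM)] = points_v[:, i]
        samples[:, layout.column(sensor, procrustes.ANTPOST_DIM)] = points_a[:, i]
        samples[:, layout.column(sensor, "y")] = 0.5 * i
    return EmaTrajectory(samples=samples, rate=rate, layout=layout)


class TestApply:
    def test_identity_params_noop(self):
        rng = np.random.default_rng(1)
        ema = _traj_from_plane(rng.normal(size=(20, 6)), rng.normal(size=(20, 6)))
        out = apply_matching(ema, procrustes.IDENTITY_PARAMS)
        np.testing.assert_array_equal(out.samples, ema.samples)

    def test_rotation_convention_90_degrees(self):
        # point (v, a) = (1, 0) must map to (0, -1) under theta = +90 deg
        ema = _traj_from_plane(np.ones((2, 6)), np.zeros((2, 6)))
        params = ProcrustesParams(c_v=0.0, c_a=0.0, theta=np.pi / 2)
        out = apply_matching(ema, params)
        lay = ema.layout
        for sensor in lay.sensor_names:
            assert out.samples[0, lay.column(sensor, procrustes.VERTICAL_DIM)] == pytest.approx(0.0, abs=1e-12)
            assert out.samples[0, lay.column(sensor, procrustes.ANTPOST_DIM)] == pytest.approx(-1.0, abs=1e-12)

    def test_lateral_channel_untouched(self):
        rng = np.random.default_rng(2)
        ema = _traj_from_plane(rng.normal(size=(15, 6)), rng.normal(size=(15, 6)))
        params = ProcrustesParams(c_v=3.0, c_a=-1.0, theta=0.7)
        out = apply_matching(ema, params)
        lay = ema.layout
        for sensor in lay.sensor_names:
            col = lay.column(sensor, "y")
            np.testing.assert_array_equal(out.samples[:, col], ema.samples[:, col])

    def test_rigid_motion_preserves_pairwise_distances(self):
        rng = np.random.default_rng(3)
        ema = _traj_from_plane(rng.normal(size=(30, 6)), rng.normal(size=(30, 6)))
        params = ProcrustesParams(c_v=2.0, c_a=-5.0, theta=1.1)
        out = apply_matching(ema, params)
        for t in (0, 15, 29):
            a = ema.samples[t].reshape(6, 3)
            b = out.samples[t].reshape(6, 3)
            da = np.linalg.norm(a[:, None] - a[None, :], axis=-1)
            db = np.linalg.norm(b[:, None] - b[None, :], axis=-1)
            np.testing.assert_allclose(da, db, atol=1e-9)

    def test_unapply_inverts_apply(self):
        rng = np.random.default_rng(4)
        ema = _traj_from_plane(rng.normal(size=(10, 6)), rng.normal(size=(10, 6)))
        params = ProcrustesParams(c_v=1.0, c_a=2.0, theta=-0.6, beta_v=0.5, beta_a=2.0)
        back = unapply_matching(apply_matching(ema, params), params)
        np.testing.assert_allclose(back.samples, ema.samples, atol=1e-9)


class TestMatchCorpus:
    def test_planted_rotations_removed_exactly(self, clean_corpus):
        corpora, _ = clean_corpus
        matched, _ = match_corpus(corpora, level="sentence")
        ref = matched[0]
        for other in matched[1:]:
            for u0, u1 in zip(ref.utterances, other.utterances):
                lay = u0.ema.layout
                for sensor in lay.sensor_names:
                    for dim in (procrustes.VERTICAL_DIM, procrustes.ANTPOST_DIM):
                        col = lay.column(sensor, dim)
                        np.testing.assert_allclose(
                            u0.ema.samples[:, col], u1.ema.samples[:, col], atol=1e-6
                        )

    def test_idempotent(self, clean_corpus):
        corpora, _ = clean_corpus
        matched, _ = match_corpus(corpora, level="sentence")
        _, registry = match_corpus(matched, level="sentence")
        for reg in registry.values():
            for params in reg.values():
                assert abs(params.theta) < 1e-9
                assert abs(params.c_v) < 1e-9 and abs(params.c_a) < 1e-9

    def test_default_is_no_scale(self, clean_corpus):
        corpora, _ = clean_corpus
        _, registry = match_corpus(corpora)
        for reg in registry.values():
            for params in reg.values():
                assert params.beta_v == 1.0 and params.beta_a == 1.0

    def test_speaker_level_uses_one_param_set(self, tiny_corpus):
        corpora, _ = tiny_corpus
        matched, registry = match_corpus(corpora, level="speaker")
        for spk, reg in registry.items():
            assert list(reg) == ["speaker"]
        assert len(matched) == len(corpora)
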