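"""Fiducial detection, drift correction and channel alignment."""

import numpy as np
import pytest

from glycoatlas.errors import AlignmentError, DriftUnavailableError, ParameterError
from glycoatlas.registration import (
    DriftTrace,
    FiducialTrack,
    align_channels,
    apply_drift,
    detect_fiducials,
    estimate_drift,
    invert_trace,
    remove_fiducial_localizations,
)

from conftest import make_table


def fiducial_table(rng, positions, n_frames=1000, jitter=2.0, extra=None):
    frames, xs, ys = [], [], []
    for (px, py) in positions:
        frames.append(np.arange(n_frames))
        xs.append(px + rng.normal(0, jitter, n_frames))
        ys.append(py + rng.normal(0, jitter, n_frames))
    if extra is not None:
        ef, ex, ey = extra
        frames.append(ef)
        xs.append(ex)
        ys.append(ey)
    return make_table(
        np.concatenate(frames), np.concatenate(xs), np.concatenate(ys), n_frames=n_frames
    )


class TestDetection:
    def test_planted_fiducial_recovered(self, rng):
        t = fiducial_table(rng, [(1000.0, 2000.0)])
        tracks = detect_fiducials(t)
        assert len(tracks) == 1
        assert len(tracks[0]) >= 990
        assert np.hypot(*(tracks[0].mean_xy - [1000, 2000])) < 1.0

    def test_sparse_blinker_not_a_fiducial(self, rng):
        """A site present in 0.5% of frames is far below the presence cut."""
        n = 5
        t = make_table(
            rng.choice(1000, n, replace=False), np.full(n, 500.0), np.full(n, 500.0),
            n_frames=1000,
        )
        assert detect_fiducials(t, min_presence_fraction=0.5) == []

    def test_two_fiducials_give_two_disjoint_tracks(self, rng):
        t = fiducial_table(rng, [(1000.0, 1000.0), (6000.0, 1000.0)])
        tracks = detect_fiducials(t)
        assert len(tracks) == 2
        means = np.array([tr.mean_xy for tr in tracks])
        assert np.hypot(*(means[0] - means[1])) == pytest.approx(5000.0, abs=5)


class TestDrift:
    def test_linear_drift_reproduced_exactly(self):
        """A noiseless linear track yields the drift line after re-centering."""
        n = 1000
        fr = np.arange(n)
        track = FiducialTrack(0, fr, 100.0 + 0.01 * fr, np.full(n, 50.0))
        trace = estimate_drift([track], n)
        expected = 0.01 * fr - (0.01 * fr).mean()
        np.testing.assert_allclose(trace.dx_nm, expected, atol=1e-9)
        np.testing.assert_allclose(trace.dy_nm, 0.0, atol=1e-9)

    def test_two_noisy_tracks_average_down_noise(self, rng):
        """Residual error of the estimate is ~sigma/sqrt(2) per frame."""
        n = 1000
        fr = np.arange(n)
        drift = 0.05 * fr
        tracks = [
            FiducialTrack(i, fr, 1000 * i + drift + rng.normal(0, 2.0, n),
                          rng.normal(0, 2.0, n))
            for i in range(2)
        ]
        trace = estimate_drift(tracks, n)
        truth = drift - drift.mean()
        rms = np.sqrt(np.mean((trace.dx_nm - truth) ** 2))
        assert rms < 2.0  # sigma/sqrt(2) ~ 1.41 plus estimation slack

    def test_static_tracks_give_zero_trace(self):
        n = 100
        tracks = [FiducialTrack(0, np.arange(n), np.full(n, 5.0), np.full(n, 7.0))]
        trace = estimate_drift(tracks, n)
        np.testing.assert_allclose(trace.dx_nm, 0.0, atol=1e-12)

    def test_no_tracks_is_an_error(self):
        with pytest.raises(DriftUnavailableError):
            estimate_drift([])

    def test_apply_then_inverse_is_identity(self, rng):
        t = make_table(np.arange(100), rng.uniform(0, 1e4, 100), rng.uniform(0, 1e4, 100))
        trace = DriftTrace(rng.normal(0, 5, 100), rng.normal(0, 5, 100))
        back = apply_drift(apply_drift(t, trace), invert_trace(trace))
        np.testing.assert_allclose(back.xy, t.xy, atol=1e-9)

    def test_zero_trace_is_identity(self, rng):
        t = make_table(np.arange(10), rng.uniform(0, 100, 10), rng.uniform(0, 100, 10))
        out = apply_drift(t, DriftTrace(np.zeros(10), np.zeros(10)))
        np.testing.assert_array_equal(out.xy, t.xy)

    def test_frame_outside_trace_is_an_error(self):
        t = make_table([5], [0.0], [0.0])
        with pytest.raises(ParameterError):
            apply_drift(t, DriftTrace(np.zeros(3), np.zeros(3)))

    def test_corrected_fiducial_spread_near_jitter(self, rng):
        """After correcting a planted drifted bead, its positional spread
        is at most 1.2x the localization jitter."""
        n, jitter = 2000, 2.0
        fr = np.arange(n)
        drift = 0.05 * fr  # 100 nm total
        t = make_table(fr, 3000 + drift + rng.normal(0, jitter, n),
                       4000 + rng.normal(0, jitter, n), n_frames=n)
        tracks = detect_fiducials(t)
        corrected = apply_drift(t, estimate_drift(tracks, n))
        spread = corrected.xy.std(axis=0).max()
        assert spread <= 1.2 * jitter


class TestAlignment:
    def make_tracks(self, rng, means, jitter=0.0, n=200):
        out = []
        for i, (mx, my) in enumerate(means):
            fr = np.arange(n)
            out.append(FiducialTrack(i, fr, mx + rng.normal(0, jitter, n),
                                     my + rng.normal(0, jitter, n)))
        return out

    def test_planted_translation_recovered(self, rng):
        means = [(1000.0, 1000.0), (5000.0, 2000.0), (3000.0, 8000.0)]
        ref = self.make_tracks(rng, means)
        mov = self.make_tracks(rng, [(x + 10, y - 5) for x, y in means])
        tf = align_channels(ref, mov, "translation")
        assert tf.tx_nm == pytest.approx(-10.0, abs=1e-6)
        assert tf.ty_nm == pytest.approx(5.0, abs=1e-6)
        assert tf.n_matched == 3

    def test_identity_for_identical_tracks(self, rng):
        tr = self.make_tracks(rng, [(100.0, 100.0), (900.0, 400.0)])
        tf = align_channels(tr, tr, "translation")
        assert abs(tf.tx_nm) < 1e-12 and abs(tf.ty_nm) < 1e-12

    def test_rigid_recovers_rotation_and_shift(self, rng):
        """Closed-form Procrustes check: 0.5 degrees about the centroid plus
        a shift is recovered within 1e-3."""
        means = np.array([(1000.0, 1000.0), (5000.0, 2000.0), (3000.0, 8000.0)])
        theta = np.deg2rad(0.5)
        c, s = np.cos(theta), np.sin(theta)
        centroid = means.mean(axis=0)
        rotated = (means - centroid) @ np.array([[c, -s], [s, c]]).T + centroid + [120, -80]
        ref = self.make_tracks(rng, means)
        mov = self.make_tracks(rng, rotated)
        tf = align_channels(ref, mov, "rigid", pairing_radius_nm=500)
        assert tf.theta_rad == pytest.approx(-theta, abs=1e-3)
        back = tf.apply_xy(rotated)
        np.testing.assert_allclose(back, means, atol=1e-3)
        assert tf.residual_rms_nm < 1e-3

    def test_insufficient_matches_is_an_error(self, rng):
        ref = self.make_tracks(rng, [(0.0, 0.0)])
        mov = self.make_tracks(rng, [(9e6, 9e6)])
        with pytest.raises(AlignmentError, match="0 matched"):
            align_channels(ref, mov, "translation")

    def test_transform_preserves_pairwise_distances(self, rng):
        from glycoatlas.registration import ChannelTransform

        tf = ChannelTransform(12.3, -4.5, theta_rad=0.01)
        xy = rng.uniform(0, 1e4, size=(50, 2))
        out = tf.apply_xy(xy)
        d_in = np.hypot(*(xy[:, None, :] - xy[None, :, :]).transpose(2, 0, 1))
        d_out = np.hypot(*(out[:, None, :] - out[None, :, :]).transpose(2, 0, 1))
        np.testing.assert_allclose(d_out, d_in, atol=1e-9)


def test_fiducial_exclusion_removes_bead_signal(rng):
    t = fiducial_table(
        rng, [(1000.0, 1000.0)],
        extra=(np.array([0, 1]), np.array([5000.0, 5000.0]), np.array([5000.0, 5001.0])),
    )
    tracks = detect_fiducials(t)
    cleaned = remove_fiducial_localizations(t, tracks)
    assert len(cleaned) == 2  # only the non-bead pair survives
    assert (cleaned.xy[:, 0] > 4000).all()
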