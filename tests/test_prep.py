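import numpy as np
import pytest

from surfhomog import (
    bandpass,
    compute_reho,
    despike,
    detrend,
    friston24,
    grand_mean_scale,
    motion_metrics,
    qc_filter,
    regress_nuisance,
)
from surfhomog.prep import BoldSurface, QCRecord, prep_chain
from surfhomog.synthetic import MotionTrace


def _ts(signal, tr=2.0):
    return BoldSurface(signal=np.atleast_2d(np.asarray(signal, float)),
                       repetition_time=tr)


class TestDespike:
    def test_identity_within_band(self, rng):
        x = rng.standard_normal((5, 50))
        out = despike(_ts(x), clip_sigma=10.0)
        np.testing.assert_array_equal(out.signal, x)

    def test_spike_compressed_by_stated_map(self, rng):
        x = rng.standard_normal(101)
        m0 = np.median(x)
        rsd0 = 1.4826 * np.median(np.abs(x - m0))
        x = np.append(x, m0 + 10 * rsd0)
        # evaluate the stated map with the post-modification robust center
        m = np.median(x)
        c = 3.0 * 1.4826 * np.median(np.abs(x - m))
        expected = m + c * np.tanh((x[-1] - m) / c)
        out = despike(_ts(x), clip_sigma=3.0)
        assert out.signal[0, -1] == pytest.approx(expected)
        assert np.abs(out.signal - np.median(x)).max() <= c + 1e-12

    def test_constant_series_unchanged(self):
        x = np.full((3, 20), 7.0)
        out = despike(_ts(x), clip_sigma=3.0)
        np.testing.assert_array_equal(out.signal, x)


class TestGrandMeanScale:
    def test_scales_to_target(self):
        x = np.full((4, 10), 500.0)
        out = grand_mean_scale(_ts(x))
        np.testing.assert_allclose(out.signal, 10000.0)

    def test_identity_at_target(self, rng):
        x = rng.random((4, 10)) + 1
        x *= 10000.0 / x.mean()
        out = grand_mean_scale(_ts(x))
        np.testing.assert_allclose(out.signal, x)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            grand_mean_scale(_ts(np.full((2, 5), -1.0)))

    def test_reho_invariant_to_scaling(self, mesh2, table2_ring1, rng):
        """Ranks are invariant under positive scaling, so ReHo is too."""
        x = 100 + rng.standard_normal((mesh2.n_vertices, 30))
        a = compute_reho(_ts(x), table2_ring1).values
        b = compute_reho(grand_mean_scale(_ts(x)), table2_ring1).values
        np.testing.assert_array_equal(a, b)


class TestFriston24:
    def test_zero_motion(self):
        out = friston24(np.zeros((10, 6)))
        assert out.shape == (10, 24)
        np.testing.assert_array_equal(out, 0.0)

    def test_shape_contract(self, rng):
        assert friston24(rng.standard_normal((33, 6))).shape == (33, 24)

    def test_hand_computed_expansion(self):
        m = np.zeros((3, 6))
        m[:, 0] = [0.0, 1.0, 2.0]
        out = friston24(m)
        np.testing.assert_array_equal(out[:, 0], [0, 1, 2])       # m_t
        np.testing.assert_array_equal(out[:, 6], [0, 0, 1])       # m_{t-1}, padded
        np.testing.assert_array_equal(out[:, 12], [0, 1, 4])      # m_t^2
        np.testing.assert_array_equal(out[:, 18], [0, 0, 1])      # m_{t-1}^2

    def test_wrong_column_count(self):
        with pytest.raises(ValueError):
            friston24(np.zeros((10, 5)))


class TestRegressNuisance:
    def test_orthogonal_regressors_identity(self):
        t = np.arange(20)
        reg = np.sin(2 * np.pi * t / 20)[:, None]  # zero-mean
        sig = np.vstack([np.cos(2 * np.pi * t / 20),  # orthogonal to reg
                         np.full(20, 5.0)])
        out = regress_nuisance(_ts(sig), reg)
        np.testing.assert_allclose(out.signal, sig, atol=1e-10)

    def test_perfect_fit_leaves_mean(self, rng):
        reg = rng.standard_normal((30, 1))
        sig = (3.0 * reg.ravel() + 2.0)[None, :]
        out = regress_nuisance(_ts(sig), reg)
        np.testing.assert_allclose(out.signal, np.full((1, 30), sig.mean()), atol=1e-10)

    def test_residuals_orthogonal(self, rng):
        reg = rng.standard_normal((20, 3))
        sig = rng.standard_normal((7, 20))
        out = regress_nuisance(_ts(sig), reg)
        resid = out.signal - out.signal.mean(axis=1, keepdims=True)
        assert np.abs(resid @ (reg - reg.mean(0))).max() < 1e-8

    def test_mean_preserved(self, rng):
        reg = rng.standard_normal((25, 2))
        sig = 50 + rng.standard_normal((4, 25))
        out = regress_nuisance(_ts(sig), reg)
        np.testing.assert_allclose(out.signal.mean(axis=1), sig.mean(axis=1))

    def test_collinear_columns_named(self, rng):
        base = rng.standard_normal((15, 1))
        reg = np.hstack([base, 2 * base])
        with pytest.raises(ValueError, match="collinear"):
            regress_nuisance(_ts(rng.standard_normal((2, 15))), reg)


class TestBandpass:
    TR = 2.0
    T = 100  # 0.05 Hz and 0.2 Hz sit exactly on FFT bins

    def _sine(self, f):
        t = np.arange(self.T) * self.TR
        return np.sin(2 * np.pi * f * t)

    def test_passband_preserved(self):
        x = self._sine(0.05)
        out = bandpass(_ts(x, self.TR)).signal.ravel()
        assert np.abs(out - x).max() < 0.01

    def test_stopband_removed(self):
        x = self._sine(0.2)
        out = bandpass(_ts(x, self.TR)).signal.ravel()
        assert np.abs(out).max() < 0.01

    def test_linearity(self):
        x = self._sine(0.05) + self._sine(0.2)
        out = bandpass(_ts(x, self.TR)).signal.ravel()
        np.testing.assert_allclose(out, self._sine(0.05), atol=0.01)

    def test_mean_restored(self, rng):
        x = 300 + rng.standard_normal((3, self.T))
        out = bandpass(_ts(x, self.TR))
        np.testing.assert_allclose(out.signal.mean(axis=1), x.mean(axis=1))

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass(_ts(np.zeros(50), tr=4.0), low=0.01, high=0.2)


class TestDetrend:
    def test_quadratic_becomes_constant(self):
        t = np.arange(30, dtype=float)
        x = 2.0 - 0.3 * t + 0.01 * t**2
        out = detrend(_ts(x)).signal.ravel()
        np.testing.assert_allclose(out, x.mean(), atol=1e-8)

    def test_residual_uncorrelated_with_trend(self, rng):
        x = rng.standard_normal((5, 60))
        out = detrend(_ts(x)).signal
        t = np.arange(60, dtype=float)
        for basis in (t - t.mean(), t**2 - (t**2).mean()):
            proj = (out - out.mean(axis=1, keepdims=True)) @ basis
            assert np.abs(proj).max() < 1e-6

    def test_idempotent(self, rng):
        x = rng.standard_normal((3, 40))
        once = detrend(_ts(x)).signal
        twice = detrend(detrend(_ts(x))).signal
        np.testing.assert_allclose(once, twice, atol=1e-10)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            detrend(_ts(np.zeros(3)))


class TestMotionMetrics:
    def test_zero_trace(self):
        assert motion_metrics(np.zeros((5, 6))) == (0.0, 0.0, 0.0)

    def test_single_translation_jump(self):
        m = np.zeros((4, 6))
        m[2:, 0] = 0.3
        max_tran, max_rot, mean_fd = motion_metrics(m)
        assert max_tran == pytest.approx(0.3)
        assert max_rot == 0.0
        assert mean_fd == pytest.approx(0.3 / 3)

    def test_constant_offset(self):
        m = np.zeros((6, 6))
        m[:, :3] = [1.0, 2.0, 2.0]
        max_tran, _, mean_fd = motion_metrics(m)
        assert max_tran == pytest.approx(3.0)
        assert mean_fd == 0.0

    def test_rotation_arc_length(self):
        m = np.zeros((2, 6))
        m[1, 3] = 1.0  # 1 degree step on one axis
        _, max_rot, mean_fd = motion_metrics(m)
        assert max_rot == pytest.approx(1.0)
        assert mean_fd == pytest.approx(50.0 * np.deg2rad(1.0))

    def test_too_few_frames(self):
        with pytest.raises(ValueError):
            motion_metrics(np.zeros((1, 6)))


class TestQCFilter:
    def _rec(self, tran, rot, fd, bbr, sid="s"):
        return QCRecord(subject_id=sid, max_tran=tran, max_rot=rot,
                        mean_fd=fd, mc_bbr=bbr)

    def test_clean_record_retained(self):
        retained, excluded = qc_filter([self._rec(1.0, 1.0, 0.2, 0.5)])
        assert retained == ["s"] and not excluded

    def test_fd_violation_reported(self):
        retained, excluded = qc_filter([self._rec(1.0, 1.0, 0.5, 0.5)])
        assert retained == []
        assert excluded["s"] == ["meanFD"]

    def test_boundary_semantics(self):
        """maxTran/maxRot/meanFD pass at their thresholds; mcBBR must be
        strictly below 0.75."""
        retained, _ = qc_filter([self._rec(2.0, 2.0, 0.4, 0.7499)])
        assert retained == ["s"]
        _, excluded = qc_filter([self._rec(2.0, 2.0, 0.4, 0.75)])
        assert excluded["s"] == ["mcBBR"]

    def test_multiple_reasons_enumerated(self):
        _, excluded = qc_filter([self._rec(3.0, 2.5, 0.5, 0.9)])
        assert excluded["s"] == ["maxTran", "maxRot", "meanFD", "mcBBR"]

    def test_missing_metric(self):
        _, excluded = qc_filter([self._rec(1.0, None, 0.2, 0.5)])
        assert excluded["s"] == ["missing-qc"]


def test_prep_chain_deterministic_and_order_sensitive(mesh2, rng):
    x = 1000 + 10 * rng.standard_normal((mesh2.n_vertices, 64))
    ts = BoldSurface(signal=x, repetition_time=2.0)
    a = prep_chain(ts).signal
    b = prep_chain(BoldSurface(signal=x.copy(), repetition_time=2.0)).signal
    np.testing.assert_array_equal(a, b)
    reordered = prep_chain(ts, steps=("detrend", "bandpass", "scale", "despike")).signal
    assert not np.allclose(a, reordered)


def test_reho_invariant_to_scale_placement(mesh2, table2_ring1, rng):
    """Moving grand-mean scaling anywhere in the chain leaves ReHo unchanged."""
    x = 1000 + 10 * rng.standard_normal((mesh2.n_vertices, 64))
    early = prep_chain(BoldSurface(signal=x, repetition_time=2.0),
                       steps=("scale", "bandpass", "detrend"))
    late = prep_chain(BoldSurface(signal=x, repetition_time=2.0),
                      steps=("bandpass", "detrend", "scale"))
    np.testing.assert_allclose(
        compute_reho(early, table2_ring1).values,
        compute_reho(late, table2_ring1).values, atol=1e-12,
    )
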