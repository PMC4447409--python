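import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ivim_ablate import ivim_model as im
from ivim_ablate.errors import FitError, ParameterError
from ivim_ablate.synthetic_cohort import rician


def rel_err(fit, truth):
    return max(
        abs(getattr(fit, n) - getattr(truth, n)) / abs(getattr(truth, n))
        for n in ("S0", "f", "D", "D_star")
    )


class TestSignal:
    def test_b_zero_returns_s0(self):
        p = im.IVIMParams(S0=123.0, f=0.2, D=1e-3, D_star=0.05)
        assert im.ivim_signal(0.0, p) == pytest.approx(123.0)

    def test_monoexponential_scalar(self):
        # 100 * exp(-800 * 1e-3) = 100 * exp(-0.8)
        p = im.IVIMParams(S0=100.0, f=0.0, D=1.0e-3, D_star=0.1)
        assert im.ivim_signal(800.0, p) == pytest.approx(100.0 * math.exp(-0.8))
        assert im.ivim_signal(800.0, p) == pytest.approx(44.933, abs=5e-4)

    def test_biexponential_scalar(self):
        # 0.15 e^-3 + 0.85 e^-0.046, from hand evaluation
        p = im.IVIMParams(S0=1.0, f=0.15, D=0.92e-3, D_star=0.06)
        expected = 0.15 * math.exp(-3.0) + 0.85 * math.exp(-0.046)
        assert im.ivim_signal(50.0, p) == pytest.approx(expected, rel=1e-12)
        assert im.ivim_signal(50.0, p) == pytest.approx(0.8193, abs=5e-5)

    def test_vectorized_over_b(self, b_values):
        p = im.IVIMParams(S0=10.0, f=0.3, D=0.7e-3, D_star=0.1)
        out = im.ivim_signal(b_values, p)
        assert out.shape == b_values.shape
        assert out[0] == pytest.approx(10.0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            im.ivim_signal(0.0, im.IVIMParams(S0=1.0, f=1.5, D=1e-3, D_star=0.1))
        with pytest.raises(ParameterError):
            im.ivim_signal(0.0, im.IVIMParams(S0=1.0, f=0.1, D=1e-3, D_star=1e-4))
        with pytest.raises(ParameterError):
            im.ivim_signal(-5.0, im.IVIMParams(S0=1.0, f=0.1, D=1e-3, D_star=0.1))

    @given(
        f=st.floats(0.01, 0.6),
        d=st.floats(2e-4, 3e-3),
        mult=st.floats(5.0, 100.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_strictly_decreasing_in_b(self, f, d, mult):
        d_star = min(d * mult, 0.5)
        p = im.IVIMParams(S0=1.0, f=f, D=d, D_star=d_star)
        b = np.linspace(0, 800, 30)
        s = im.ivim_signal(b, p)
        assert np.all(np.diff(s) < 0)


class TestSegmented:
    def test_noiseless_round_trip(self, b_values):
        truth = im.IVIMParams(S0=100.0, f=0.30, D=0.7e-3, D_star=0.10)
        s = im.ivim_signal(b_values, truth)
        fit, q = im.fit_ivim_segmented(s, b_values)
        assert q.algorithm == "SEGMENTED"
        assert rel_err(fit, truth) <= 1e-4  # refined below 1e-6 by the full fit
        full, _ = im.fit_ivim_full(s, b_values, fit)
        assert rel_err(full, truth) <= 1e-6

    def test_monoexponential_gives_zero_f(self, b_values):
        truth = im.IVIMParams(S0=50.0, f=1e-12, D=1.1e-3, D_star=0.1)
        s = 50.0 * np.exp(-b_values * 1.1e-3)
        fit, _ = im.fit_ivim_segmented(s, b_values)
        assert fit.f <= 1e-8
        assert fit.D == pytest.approx(1.1e-3, rel=1e-9)

    def test_constant_signal_clamps(self, b_values):
        s = np.full(b_values.size, 7.0)
        fit, q = im.fit_ivim_segmented(s, b_values)
        assert fit.D == im.D_BOUNDS[0]
        assert not q.converged

    def test_too_few_points(self):
        with pytest.raises(FitError):
            im.fit_ivim_segmented([1.0, 0.9, 0.8], [0.0, 400.0, 800.0])

    def test_nonpositive_signal_rejected(self, b_values):
        s = np.ones(b_values.size)
        s[3] = -1.0
        with pytest.raises(FitError):
            im.fit_ivim_segmented(s, b_values)


class TestFullFit:
    def test_truth_is_fixed_point(self, b_values):
        truth = im.IVIMParams(S0=100.0, f=0.25, D=0.8e-3, D_star=0.08)
        s = im.ivim_signal(b_values, truth)
        fit, q = im.fit_ivim_full(s, b_values, truth)
        assert q.rss == pytest.approx(0.0, abs=1e-20)
        assert rel_err(fit, truth) <= 1e-9

    def test_refinement_never_worse(self, b_values, rng):
        truth = im.IVIMParams(S0=1000.0, f=0.29, D=0.61e-3, D_star=0.13)
        s = rician(im.ivim_signal(b_values, truth), 20.0, rng)
        seg, seg_q = im.fit_ivim_segmented(s, b_values)
        full, full_q = im.fit_ivim_full(s, b_values, seg)
        assert full_q.rss <= seg_q.rss * (1 + 1e-9)

    def test_monte_carlo_f_recovery(self, b_values):
        # 1000 voxels at SNR 50; the mean fitted perfusion fraction must
        # land within +/-0.02 of the generating 0.15
        truth = im.IVIMParams(S0=1000.0, f=0.15, D=0.92e-3, D_star=0.06)
        clean = im.ivim_signal(b_values, truth)
        gen = np.random.default_rng(42)
        fs = []
        for _ in range(1000):
            noisy = rician(clean, 20.0, gen)
            fit, _ = im.fit_ivim(noisy, b_values)
            fs.append(fit.f)
        assert np.mean(fs) == pytest.approx(0.15, abs=0.02)

    def test_bounds_always_respected(self, b_values, rng):
        for _ in range(50):
            s = rng.uniform(0.5, 2.0, size=b_values.size) * np.exp(
                -b_values * rng.uniform(1e-4, 2e-3)
            )
            fit, _ = im.fit_ivim(s, b_values)
            assert 0.0 <= fit.f <= 1.0
            assert im.D_BOUNDS[0] <= fit.D <= im.D_BOUNDS[1]
            assert im.DSTAR_BOUNDS[0] <= fit.D_star <= im.DSTAR_BOUNDS[1]


class TestIdentifiability:
    @given(
        d=st.floats(1e-4, 3e-3),
        mult=st.floats(5.0, 150.0),
        f=st.floats(0.05, 0.6),
        s0=st.floats(1.0, 1e4),
    )
    @settings(max_examples=40, deadline=None)
    def test_noiseless_recovery(self, b_values, d, mult, f, s0):
        d_star = float(np.clip(d * mult, 3.5e-3, 0.45))
        truth = im.IVIMParams(S0=s0, f=f, D=d, D_star=d_star)
        s = im.ivim_signal(b_values, truth)
        fit, _ = im.fit_ivim(s, b_values)
        assert rel_err(fit, truth) <= 1e-6

    def test_scale_equivariance(self, b_values):
        truth = im.IVIMParams(S0=100.0, f=0.2, D=1e-3, D_star=0.05)
        s = im.ivim_signal(b_values, truth)
        base, _ = im.fit_ivim(s, b_values)
        scaled, _ = im.fit_ivim(7.5 * s, b_values)
        assert scaled.S0 == pytest.approx(7.5 * base.S0, rel=1e-9)
        assert scaled.f == pytest.approx(base.f, rel=1e-7, abs=1e-12)
        assert scaled.D == pytest.approx(base.D, rel=1e-7)
        assert scaled.D_star == pytest.approx(base.D_star, rel=1e-6)


class TestVolume:
    def test_all_false_mask(self, b_values):
        dwi = np.ones((3, 3, 2, b_values.size))
        maps = im.fit_ivim_volume(dwi, b_values, np.zeros((3, 3, 2), bool))
        assert np.all(np.isnan(maps.f_map))

    def test_single_voxel_matches_series_fit(self, b_values):
        truth = im.IVIMParams(S0=100.0, f=0.3, D=0.7e-3, D_star=0.1)
        dwi = np.zeros((2, 2, 1, b_values.size))
        dwi[1, 0, 0] = im.ivim_signal(b_values, truth)
        mask = np.zeros((2, 2, 1), bool)
        mask[1, 0, 0] = True
        maps = im.fit_ivim_volume(dwi, b_values, mask)
        direct, _ = im.fit_ivim(dwi[1, 0, 0], b_values)
        assert maps.f_map[1, 0, 0] == pytest.approx(direct.f, rel=1e-12)
        assert maps.D_map[1, 0, 0] == pytest.approx(direct.D, rel=1e-12)
        assert np.isnan(maps.f_map[0, 0, 0])

    def test_noiseless_phantom_recovers_class_truth(self, b_values):
        classes = {
            1: im.IVIMParams(S0=1000.0, f=0.15, D=0.92e-3, D_star=0.06),
            2: im.IVIMParams(S0=1000.0, f=0.42, D=0.79e-3, D_star=0.11),
        }
        labels = np.zeros((4, 4, 1), dtype=int)
        labels[:2] = 1
        labels[2:] = 2
        dwi = np.zeros(labels.shape + (b_values.size,))
        for code, params in classes.items():
            dwi[labels == code] = im.ivim_signal(b_values, params)
        maps = im.fit_ivim_volume(dwi, b_values, labels > 0)
        for code, params in classes.items():
            assert np.nanmean(maps.f_map[labels == code]) == pytest.approx(
                params.f, rel=1e-6
            )
            assert np.nanmean(maps.D_map[labels == code]) == pytest.approx(
                params.D, rel=1e-6
            )
            assert np.nanmean(maps.Dstar_map[labels == code]) == pytest.approx(
                params.D_star, rel=1e-6
            )

    def test_shape_mismatch_rejected(self, b_values):
        dwi = np.ones((3, 3, 2, b_values.size - 1))
        with pytest.raises(FitError):
            im.fit_ivim_volume(dwi, b_values, np.ones((3, 3, 2), bool))
        with pytest.raises(FitError):
            im.fit_ivim_volume(
                np.ones((3, 3, 2, b_values.size)), b_values, np.ones((2, 2, 2), bool)
            )

    def test_degenerate_voxel_does_not_abort(self, b_values):
        dwi = np.ones((1, 1, 1, b_values.size))  # flat signal
        maps = im.fit_ivim_volume(dwi, b_values, np.ones((1, 1, 1), bool))
        assert maps.D_map[0, 0, 0] == pytest.approx(im.D_BOUNDS[0], rel=1e-6)

    def test_roi_fit_requires_present_code(self, b_values):
        dwi = np.ones((2, 2, 1, b_values.size))
        with pytest.raises(FitError):
            im.fit_ivim_roi(dwi, np.zeros((2, 2, 1), int), 3, b_values)
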