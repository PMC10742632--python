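"""Decay fitting, ROI averaging and organ iron metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ferriscope.relaxometry import (
    EchoSeries,
    FitError,
    default_echo_times,
    fit_offset_model,
    fit_truncated_model,
    lic_from_liver_t2star,
    pancreas_global,
    roi_mean_decay,
    select_fit,
)
from tests.conftest import decay_series


class TestRoiMeanDecay:
    def test_constant_images_give_their_values(self, te10):
        stack = np.stack([np.full((4, 4), v) for v in (100.0, 50.0, 25.0)])
        mask = np.zeros((4, 4), dtype=bool)
        mask[1:3, 1:3] = True
        s = roi_mean_decay(stack, mask, te10[:3])
        assert np.allclose(s.signal, [100, 50, 25])

    def test_single_pixel_mask_is_identity(self, te10, rng):
        stack = rng.uniform(1, 100, size=(10, 6, 6))
        mask = np.zeros((6, 6), dtype=bool)
        mask[2, 3] = True
        s = roi_mean_decay(stack, mask, te10)
        assert np.array_equal(s.signal, stack[:, 2, 3])

    def test_matches_per_pixel_loop_oracle(self, te10, rng):
        stack = rng.uniform(1, 100, size=(10, 8, 8))
        mask = np.zeros((8, 8), dtype=bool)
        mask.ravel()[rng.choice(64, size=12, replace=False)] = True
        s = roi_mean_decay(stack, mask, te10)
        for k in range(10):
            total = n = 0
            for i in range(8):
                for j in range(8):
                    if mask[i, j]:
                        total += stack[k, i, j]
                        n += 1
            assert s.signal[k] == pytest.approx(total / n, rel=1e-12)

    def test_empty_mask_and_shape_mismatch_error(self, te10):
        stack = np.ones((10, 4, 4))
        with pytest.raises(ValueError, match="empty ROI"):
            roi_mean_decay(stack, np.zeros((4, 4), dtype=bool), te10)
        with pytest.raises(ValueError, match="shape"):
            roi_mean_decay(stack, np.ones((5, 5), dtype=bool), te10)
        with pytest.raises(ValueError, match="echo count"):
            roi_mean_decay(stack, np.ones((4, 4), dtype=bool), te10[:7])


class TestOffsetModel:
    def test_exact_recovery_with_offset(self):
        s = decay_series(t2star=20.0, s0=100.0, offset=5.0)
        fit = fit_offset_model(s)
        assert fit.t2star == pytest.approx(20.0, abs=1e-6)
        assert fit.s0 == pytest.approx(100.0, abs=1e-6)
        assert fit.offset == pytest.approx(5.0, abs=1e-6)
        assert fit.model == "offset"

    def test_uses_all_ten_default_echoes(self):
        fit = fit_offset_model(decay_series(t2star=15.0))
        assert fit.n_echoes_used == 10
        assert np.allclose(np.diff(default_echo_times()), 2.26)

    def test_matches_grid_search_oracle_under_rician_noise(self):
        """Optimizer lands within 1% of a dense (S0, T2*, C) grid search."""
        s = decay_series(t2star=8.0, s0=80.0, offset=3.0, rician_sigma=1.0, seed=7)
        fit = fit_offset_model(s)
        te, sig = s.echo_times, s.signal
        # coarse-to-fine brute force, written independently of the optimizer
        s0g = np.linspace(60, 100, 81)
        t2g = np.linspace(4, 12, 161)
        cg = np.linspace(0, 8, 33)
        best_sse, best_p = np.inf, None
        for s0 in s0g:
            decays = s0 * np.exp(-np.outer(1.0 / t2g, te))      # (t2, te)
            for ci in cg:
                sse = ((decays + ci - sig) ** 2).sum(axis=1)
                j = int(np.argmin(sse))
                if sse[j] < best_sse:
                    best_sse, best_p = sse[j], (s0, t2g[j], ci)
        assert fit.t2star == pytest.approx(best_p[1], rel=0.01)
        assert fit.s0 == pytest.approx(best_p[0], rel=0.01)
        assert fit.rmse ** 2 * te.size <= best_sse + 1e-9

    def test_no_decay_and_too_few_echoes_error(self, te10):
        with pytest.raises(FitError, match="no decay"):
            fit_offset_model(EchoSeries(te10, np.full(10, 7.0)))
        with pytest.raises(FitError, match="4 echoes"):
            fit_offset_model(decay_series(t2star=10.0, te=te10[:3]))

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None)
    def test_rescaling_invariance(self, scale):
        """Scaling the signal by k scales S0 and C by k, leaves T2* alone."""
        base = decay_series(t2star=12.0, s0=90.0, offset=4.0, rician_sigma=0.5, seed=3)
        scaled = EchoSeries(base.echo_times, base.signal * scale)
        f0, f1 = fit_offset_model(base), fit_offset_model(scaled)
        assert f1.t2star == pytest.approx(f0.t2star, rel=1e-6)
        assert f1.s0 == pytest.approx(f0.s0 * scale, rel=1e-6)
        assert f1.offset == pytest.approx(f0.offset * scale, rel=1e-4, abs=1e-9 * scale)


class TestTruncatedModel:
    def test_no_truncation_when_all_points_clear_floor(self):
        s = decay_series(t2star=20.0, noise_sd=0.5)
        fit = fit_truncated_model(s)
        assert fit.n_echoes_used == 10
        assert fit.t2star == pytest.approx(20.0, abs=1e-6)
        assert fit.offset == 0.0
        assert fit.model == "truncation"

    def test_retained_count_matches_inequality_oracle(self):
        """Echoes below the 2*noise_sd floor are dropped from the tail."""
        s = decay_series(t2star=2.0, s0=100.0, noise_sd=1.0)
        fit = fit_truncated_model(s)
        floor = 2.0 * 1.0
        n_keep = 10
        while n_keep > 3 and s.signal[n_keep - 1] < floor:
            n_keep -= 1
        assert fit.n_echoes_used == n_keep

    def test_truncation_beats_offset_fit_in_heavy_iron(self):
        """At T2* = 1.5 ms the truncated fit has smaller mean |error|."""
        errs_trunc, errs_off = [], []
        for rep in range(200):
            s = decay_series(t2star=1.5, s0=100.0, noise_sd=2.0,
                             rician_sigma=2.0, seed=1000 + rep)
            errs_trunc.append(abs(fit_truncated_model(s).t2star - 1.5))
            errs_off.append(abs(fit_offset_model(s).t2star - 1.5))
        assert np.mean(errs_trunc) <= np.mean(errs_off)

    def test_too_few_echoes_error(self, te10):
        with pytest.raises(FitError):
            fit_truncated_model(decay_series(t2star=5.0, te=te10[:2]))


class TestSelectFit:
    @pytest.mark.parametrize("t2star,expected_model",
                             [(30.0, "offset"), (4.0, "truncation")])
    def test_model_routing(self, t2star, expected_model):
        fit = select_fit(decay_series(t2star=t2star, noise_sd=0.05))
        assert fit.model == expected_model
        assert fit.t2star == pytest.approx(t2star, rel=1e-5)

    def test_switch_happens_exactly_at_threshold(self):
        s = decay_series(t2star=10.0)
        for threshold in (8.0, 9.0, 9.999):
            assert select_fit(s, threshold).model == "offset"
        for threshold in (10.001, 11.0, 12.0):
            assert select_fit(s, threshold).model == "truncation"


class TestPancreasGlobal:
    def test_mean_and_symmetry(self):
        assert pancreas_global(12.0, 10.0, 8.0).global_value == pytest.approx(10.0)
        a = pancreas_global(12.0, 10.0, 8.0)
        b = pancreas_global(8.0, 12.0, 10.0)
        assert a.global_value == pytest.approx(b.global_value)

    def test_at_the_normal_cutoff(self):
        assert pancreas_global(26.0, 26.0, 26.0).global_value == pytest.approx(26.0)

    def test_nonfinite_errors(self):
        with pytest.raises(ValueError):
            pancreas_global(12.0, float("nan"), 8.0)


class TestLiverIron:
    def test_default_calibration_value(self):
        iron = lic_from_liver_t2star(8.466)
        assert iron.lic == pytest.approx(0.0254 * (1000 / 8.466) + 0.202, rel=1e-12)
        assert iron.lic == pytest.approx(3.202, abs=5e-4)
        assert iron.calibration_id == "linear_r2star_default"

    def test_limit_and_monotonicity(self):
        assert lic_from_liver_t2star(1e12).lic == pytest.approx(0.202, abs=1e-6)
        for t in (2.0, 5.0, 14.0, 40.0):
            assert lic_from_liver_t2star(t / 2).lic > lic_from_liver_t2star(t).lic

    def test_invalid_t2star(self):
        with pytest.raises(ValueError):
            lic_from_liver_t2star(0.0)


class TestRecoveryInvariants:
    @pytest.mark.parametrize("t2star", [2.0, 8.0, 20.0, 40.0])
    def test_noiseless_six_digit_recovery_both_modes(self, t2star):
        f_off = fit_offset_model(decay_series(t2star=t2star, offset=0.0))
        f_trunc = fit_truncated_model(decay_series(t2star=t2star))
        for f in (f_off, f_trunc):
            assert f.t2star == pytest.approx(t2star, rel=1e-6)
            assert f.s0 == pytest.approx(100.0, rel=1e-6)

    @pytest.mark.parametrize("t2star", [2.0, 10.0, 20.0, 40.0])
    def test_median_relative_error_under_5pct_rician(self, t2star):
        """ROI-mean decays at pixel sigma/S0 = 0.05: median |dT2*|/T2* <= 5%.

        Fitting operates on ROI-mean signals (the module's contract), so the
        simulation averages 150 Rician pixels per echo, a typical clinical
        ROI size; 500 replicates.
        """
        te = default_echo_times()
        clean = 100.0 * np.exp(-te / t2star)
        errs = []
        for rep in range(500):
            g = np.random.default_rng(20_000 + rep)
            pix = np.hypot(clean[:, None] + g.normal(0, 5.0, (te.size, 150)),
                           g.normal(0, 5.0, (te.size, 150)))
            s = EchoSeries(te, pix.mean(axis=1), noise_sd=5.0)
            errs.append(abs(select_fit(s).t2star - t2star) / t2star)
        assert np.median(errs) <= 0.05
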