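import numpy as np
import pytest
from hypothesis import given, strategies as st

from vsimri import (
    EchoSeries,
    ParameterMap,
    characteristic_frequency,
    compute_adc_map,
    compute_delta_map,
    compute_mvd,
    compute_q,
    compute_rate_map,
    compute_vsi,
    fit_monoexponential,
    fit_monoexponential_stack,
    make_brain_phantom,
    mvd_from_q,
    q_from_rates,
    render_series,
    vsi_from_rates,
)
from vsimri.phantom import MEGE_TES


class TestMonoexponentialFit:
    def test_constant_signal(self):
        s0, rate = fit_monoexponential([1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0])
        assert rate == pytest.approx(0.0, abs=1e-12)
        assert s0 == pytest.approx(5.0, rel=1e-12)

    def test_adc_recovery_from_bvalues(self):
        b = np.array([100, 200, 400, 600, 800, 1000], dtype=float)
        y = 1000.0 * np.exp(-8e-4 * b)
        s0, rate = fit_monoexponential(b, y)
        assert rate * 1e6 == pytest.approx(800.0, rel=1e-6)
        assert s0 == pytest.approx(1000.0, rel=1e-6)

    def test_rate_recovery_from_echo_train(self):
        te = np.arange(8.0, 161.0, 8.0)
        y = np.exp(-0.02 * te)
        _, rate = fit_monoexponential(te, y)
        assert rate * 1e3 == pytest.approx(20.0, rel=1e-6)

    @given(
        s0=st.floats(min_value=10.0, max_value=1e4),
        rate=st.floats(min_value=1e-4, max_value=0.05),
    )
    def test_noiseless_round_trip(self, s0, rate):
        x = np.arange(8.0, 161.0, 8.0)
        fit_s0, fit_rate = fit_monoexponential(x, s0 * np.exp(-rate * x))
        assert fit_rate == pytest.approx(rate, rel=1e-6)
        assert fit_s0 == pytest.approx(s0, rel=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_monoexponential([1.0, 2.0], [1.0, 0.5])

    def test_all_zero_signal_invalid(self):
        _, _, ok = fit_monoexponential_stack(
            np.arange(1.0, 7.0), np.zeros((1, 6))
        )
        assert not ok[0]

    def test_rician_bias_small_in_sensitive_range(self):
        """At SNR 40 the fitted-rate bias stays under 2% of truth."""
        rng = np.random.default_rng(0)
        n = 10_000
        te = MEGE_TES
        rate_true = 0.03  # per ms -> 30 s^-1, well sampled by the 3-59 ms train
        clean = 1000.0 * np.exp(-rate_true * te)[None, :]
        sigma = 1000.0 / 40.0
        noisy = np.sqrt(
            (clean + rng.normal(0, sigma, (n, te.size))) ** 2
            + rng.normal(0, sigma, (n, te.size)) ** 2
        )
        _, rates, ok = fit_monoexponential_stack(te, noisy)
        bias = abs(rates[ok].mean() - rate_true) / rate_true
        assert bias < 0.02


class TestMapOperations:
    def test_noiseless_phantom_exact(self, small_truth):
        dwi = render_series(small_truth, "dwi", snr=np.inf)
        adc = compute_adc_map(dwi)
        sel = adc.valid_mask & small_truth.brain_mask
        truth = small_truth.maps["adc"][sel]
        assert np.max(np.abs(adc.values[sel] - truth) / truth) < 1e-6

    def test_snr40_phantom_recovers_adc(self, small_truth):
        """Voxel-wise ADC error at SNR 40 sits near the Cramer-Rao bound.

        With 6 b-values (100-1000 s/mm^2) and sigma = S0/40, the CRB for
        the decay rate of S = S0 exp(-a b) gives the attainable per-voxel
        precision; the least-squares fit should achieve it to within ~30%.
        """
        spec = small_truth.spec
        b = np.array([100, 200, 400, 600, 800, 1000], dtype=float)
        a = spec.adc_normal * 1e-6  # mm^2/s
        s = spec.s0 * np.exp(-a * b)
        sigma = spec.s0 / 40.0
        # Fisher matrix for (s0, a)
        j = np.stack([s / spec.s0, -b * s], axis=1)
        fisher = j.T @ j / sigma**2
        crb_rel_sd = np.sqrt(np.linalg.inv(fisher)[1, 1]) / a
        expected_median = 0.6745 * crb_rel_sd  # half the probable error

        dwi = render_series(small_truth, "dwi", snr=40.0, seed=11)
        adc = compute_adc_map(dwi)
        sel = adc.valid_mask & small_truth.brain_mask & ~small_truth.rois["lesion"]
        rel = np.abs(adc.values[sel] - small_truth.maps["adc"][sel]) / small_truth.maps[
            "adc"
        ][sel]
        assert np.median(rel) < 1.3 * expected_median
        lesion = small_truth.rois["lesion"] & adc.valid_mask
        contra = small_truth.rois["contra_subcortex"] & adc.valid_mask
        assert adc.values[contra].mean() - adc.values[lesion].mean() > 200.0

    def test_wrong_axis_kind_rejected(self, small_truth):
        series = render_series(small_truth, "msme_pre", snr=np.inf)
        with pytest.raises(ValueError):
            compute_adc_map(series)
        with pytest.raises(ValueError):
            compute_rate_map(render_series(small_truth, "dwi", snr=np.inf))


class TestDeltaMap:
    def _series_pair(self, rate_pre, rate_post, shape=(4, 4, 2)):
        te = np.arange(8.0, 161.0, 8.0)
        def mk(rate):
            vol = 1000.0 * np.exp(-rate * 1e-3 * te)[:, None, None, None]
            return EchoSeries(np.broadcast_to(vol, (te.size, *shape)).copy(), te, "te")
        return mk(rate_pre), mk(rate_post)

    def test_identical_series_give_zero(self):
        pre, post = self._series_pair(20.0, 20.0)
        d = compute_delta_map(pre, post, "fitted_train", scale_factor=1.0)
        assert np.allclose(d.values, 0.0, atol=1e-8)

    def test_fitted_train_with_unit_scale(self):
        pre, post = self._series_pair(20.0, 24.0)
        d = compute_delta_map(pre, post, "fitted_train", scale_factor=1.0)
        assert np.allclose(d.values, 4.0, rtol=1e-6)
        assert d.provenance["scale_factor"] == 1.0

    def test_default_scale_applied_to_fitted_train(self):
        pre, post = self._series_pair(20.0, 24.0)
        d = compute_delta_map(pre, post, "fitted_train")
        assert np.allclose(d.values, 4.0 * 4.375, rtol=1e-6)
        assert d.provenance["scale_factor"] == 4.375

    def test_first_echo_mode(self):
        pre, post = self._series_pair(20.0, 24.0)
        d = compute_delta_map(pre, post, "first_echo")
        assert np.allclose(d.values, 4.0, rtol=1e-6)
        assert d.provenance["scale_factor"] == 1.0

    def test_negative_delta_marked_invalid_but_kept(self):
        pre, post = self._series_pair(24.0, 20.0)
        d = compute_delta_map(pre, post, "fitted_train", scale_factor=1.0)
        assert np.allclose(d.values, -4.0, rtol=1e-6)
        assert not d.valid_mask.any()

    def test_geometry_mismatch_rejected(self):
        pre, _ = self._series_pair(20.0, 24.0)
        _, post = self._series_pair(20.0, 24.0, shape=(5, 4, 2))
        with pytest.raises(ValueError):
            compute_delta_map(pre, post, "fitted_train")


class TestMicrovascularIndices:
    def _map(self, value, shape=(3, 3, 2)):
        return ParameterMap(np.full(shape, float(value)), "s^-1", np.ones(shape, bool))

    def test_vsi_equal_rates(self, physics):
        dwc = characteristic_frequency(physics)
        vsi = vsi_from_rates(10.0, 10.0, 800.0, dwc)
        assert vsi == pytest.approx(0.424 * np.sqrt(800.0 / dwc), rel=1e-12)
        assert vsi == pytest.approx(0.413, abs=5e-4)

    def test_vsi_ratio_scaling(self, physics):
        dwc = characteristic_frequency(physics)
        v1 = vsi_from_rates(10.0, 10.0, 800.0, dwc)
        v4 = vsi_from_rates(10.0, 40.0, 800.0, dwc)
        assert v4 == pytest.approx(8.0 * v1, rel=1e-12)
        assert v4 == pytest.approx(3.305, abs=2e-3)

    def test_q_examples(self):
        assert q_from_rates(20.0, 40.0) == pytest.approx(1.710, abs=1e-3)
        assert q_from_rates(0.0, 40.0) == 0.0
        with pytest.raises(ValueError):
            q_from_rates(20.0, 0.0)

    def test_mvd_examples(self):
        assert mvd_from_q(1.07, 800.0) == pytest.approx(324.1, abs=0.5)
        assert mvd_from_q(1.0, 800.0) == pytest.approx(264.6, abs=0.1)
        assert mvd_from_q(0.0, 800.0) == 0.0

    def test_vsi_map_invalidates_nonpositive_rates(self, physics):
        dwc = characteristic_frequency(physics)
        dr2 = self._map(0.0)
        dr2s = self._map(40.0)
        vsi = compute_vsi(dr2, dr2s, 800.0, dwc)
        assert not vsi.valid_mask.any()

    def test_mvd_is_q_cubed_identity(self, physics):
        rng = np.random.default_rng(0)
        shape = (6, 5, 4)
        dr2 = ParameterMap(rng.uniform(1, 30, shape), "s^-1", np.ones(shape, bool))
        dr2s = ParameterMap(
            dr2.values * rng.uniform(1, 6, shape), "s^-1", np.ones(shape, bool)
        )
        q = compute_q(dr2, dr2s)
        mvd = compute_mvd(q, 800.0)
        expected = q.values**3 / (4.725 * 800.0) * 1e6
        assert np.array_equal(mvd.values[q.valid_mask], expected[q.valid_mask])

    def test_vsi_monotone_in_ratio_q_monotone_in_dr2(self, physics):
        dwc = characteristic_frequency(physics)
        ratios = np.linspace(1.0, 8.0, 20)
        vsis = [vsi_from_rates(10.0, 10.0 * r, 800.0, dwc) for r in ratios]
        assert np.all(np.diff(vsis) > 0)
        qs = [q_from_rates(d, 40.0) for d in np.linspace(1.0, 30.0, 20)]
        assert np.all(np.diff(qs) > 0)

    def test_geometry_mismatch_rejected(self, physics):
        dwc = characteristic_frequency(physics)
        with pytest.raises(ValueError):
            compute_vsi(self._map(10.0), self._map(20.0, shape=(4, 3, 2)), 800.0, dwc)
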