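import numpy as np
import pytest

from dwihist import (AcquisitionScheme, BiExpParams, FitOptions, MonoExpParams,
                     StretchedExpParams, bem_signal, mem_signal, sem_signal,
                     fit_bem, fit_mem, fit_sem, fit_volume)
from dwihist.containers import DwiSeries, VoiMask
from dwihist.phantom import add_rician_noise

from _oracles import grid_fit_bem, grid_fit_sem

SOFT_BEM = dict(d=0.55e-3, d_star=4.2e-3, f=0.25)
SOFT_SEM = dict(ddc=0.78e-3, alpha=0.77)


class TestMem:
    def test_closed_form_inversion(self, scheme):
        sig = mem_signal(MonoExpParams(100, 0.60e-3), scheme.b)
        r = fit_mem(sig, scheme)
        assert r.converged
        assert r.params.adc == pytest.approx(0.60e-3, rel=1e-12)
        assert r.params.s0 == 100

    def test_no_decay_gives_zero_adc(self, scheme):
        r = fit_mem(np.full(12, 50.0), scheme)
        assert r.converged and r.params.adc == 0.0

    def test_negative_implied_adc_marks_voxel_invalid(self, scheme):
        sig = np.full(12, 100.0)
        sig[scheme.index_of(1000.0)] = 120.0
        assert not fit_mem(sig, scheme).converged

    def test_nonpositive_signal_marks_voxel_invalid(self, scheme):
        sig = mem_signal(MonoExpParams(100, 1e-3), scheme.b)
        sig[0] = 0.0
        assert not fit_mem(sig, scheme).converged


class TestBem:
    def test_noiseless_roundtrip_within_1pct_and_oracle_agrees(self, scheme):
        truth = BiExpParams(100, **SOFT_BEM)
        sig = bem_signal(truth, scheme.b)
        r = fit_bem(sig, scheme)
        assert r.converged
        for attr in ("d", "d_star", "f"):
            assert getattr(r.params, attr) == pytest.approx(
                getattr(truth, attr), rel=0.01)
        oracle = grid_fit_bem(sig, scheme.b)
        assert oracle["d"] == pytest.approx(truth.d, rel=0.02)
        assert oracle["d_star"] == pytest.approx(truth.d_star, rel=0.02)
        assert oracle["f"] == pytest.approx(truth.f, rel=0.02)

    def test_mono_exponential_input_gives_negligible_f(self, scheme):
        sig = mem_signal(MonoExpParams(100, 0.8e-3), scheme.b)
        r = fit_bem(sig, scheme)
        assert r.converged
        assert r.params.f <= 0.01
        assert r.params.d == pytest.approx(0.8e-3, rel=0.01)

    def test_constant_signal_flagged_degenerate(self, scheme):
        assert not fit_bem(np.full(12, 80.0), scheme).converged

    def test_ssr_never_exceeds_initialization(self, scheme, rng):
        # optimizer only accepts cost-decreasing steps from the segmented init
        truth = BiExpParams(100, **SOFT_BEM)
        clean = bem_signal(truth, scheme.b)
        for _ in range(20):
            sig = np.array([add_rician_noise(clean[k], 2.0, scheme.nex[k],
                                             rng)[()] for k in range(12)])
            r = fit_bem(sig, scheme)
            from dwihist.fitting import _segmented_init, _weights
            w = _weights(scheme, FitOptions())
            x0 = _segmented_init(scheme.b, sig, w, FitOptions())
            s0, d, ds, f = x0
            init_ssr = np.sum(
                (w * (sig - bem_signal(
                    BiExpParams(s0, min(d, ds), ds, f), scheme.b))) ** 2)
            assert r.residual_norm <= init_ssr + 1e-9

    def test_weighting_option_changes_fit(self, scheme, rng):
        truth = BiExpParams(100, **SOFT_BEM)
        clean = bem_signal(truth, scheme.b)
        sig = np.array([add_rician_noise(clean[k], 2.0, scheme.nex[k],
                                         rng)[()] for k in range(12)])
        r_nex = fit_bem(sig, scheme, FitOptions(weighting="nex"))
        r_unw = fit_bem(sig, scheme, FitOptions(weighting="none"))
        assert r_nex.params.d != r_unw.params.d

    def test_b_subset_option_restricts_fit(self, scheme):
        truth = BiExpParams(100, **SOFT_BEM)
        sig = bem_signal(truth, scheme.b)
        r = fit_bem(sig, scheme, FitOptions(b_max=1000))
        assert r.converged
        assert r.params.d == pytest.approx(truth.d, rel=0.05)


class TestSem:
    def test_noiseless_roundtrip_within_1pct_and_oracle_agrees(self, scheme):
        truth = StretchedExpParams(100, **SOFT_SEM)
        sig = sem_signal(truth, scheme.b)
        r = fit_sem(sig, scheme)
        assert r.converged
        assert r.params.ddc == pytest.approx(truth.ddc, rel=0.01)
        assert r.params.alpha == pytest.approx(truth.alpha, rel=0.01)
        oracle = grid_fit_sem(sig, scheme.b)
        assert oracle["ddc"] == pytest.approx(truth.ddc, rel=0.02)
        assert oracle["alpha"] == pytest.approx(truth.alpha, rel=0.02)

    def test_mono_exponential_input_pushes_alpha_to_one(self, scheme):
        sig = mem_signal(MonoExpParams(100, 0.8e-3), scheme.b)
        r = fit_sem(sig, scheme)
        assert r.converged and r.params.alpha >= 0.99

    def test_two_point_exact_mono_decay_recovers_adc_at_alpha_one(self):
        two = AcquisitionScheme((0.0, 1000.0), (1, 1))
        sig = mem_signal(MonoExpParams(100, 0.9e-3), two.b)
        r = fit_sem(sig, two)
        assert r.converged
        assert r.params.ddc == pytest.approx(0.9e-3, rel=1e-4)
        assert r.params.alpha == pytest.approx(1.0, abs=1e-6)


class TestFitVolume:
    def _series(self, scheme, params, shape=(3, 3, 2)):
        sig = bem_signal(params, scheme.b)
        data = np.broadcast_to(sig, shape + (len(scheme),)).copy()
        return DwiSeries(data=data, scheme=scheme)

    def test_constant_truth_recovered_everywhere(self, scheme):
        truth = BiExpParams(100, **SOFT_BEM)
        dwi = self._series(scheme, truth)
        mask = VoiMask(np.ones(dwi.spatial_shape, dtype=bool))
        pm = fit_volume(dwi, mask, "bem")
        assert pm.valid_mask.all()
        np.testing.assert_allclose(pm.maps["D"], truth.d, rtol=0.01)
        np.testing.assert_allclose(pm.maps["f"], truth.f, rtol=0.01)

    def test_single_voxel_mask_matches_scalar_fitter(self, scheme):
        truth = BiExpParams(100, **SOFT_BEM)
        dwi = self._series(scheme, truth)
        mask = np.zeros(dwi.spatial_shape, dtype=bool)
        mask[1, 2, 0] = True
        pm = fit_volume(dwi, VoiMask(mask), "bem")
        scalar = fit_bem(dwi.data[1, 2, 0], scheme)
        assert pm.maps["D"][1, 2, 0] == scalar.params.d
        assert pm.maps["Dstar"][1, 2, 0] == scalar.params.d_star

    def test_two_region_phantom_matches_scalar_loop_bitwise(self, scheme):
        a = BiExpParams(100, d=0.5e-3, d_star=4e-3, f=0.2)
        b = BiExpParams(100, d=0.9e-3, d_star=8e-3, f=0.35)
        data = np.empty((4, 2, 1, len(scheme)))
        data[:2] = bem_signal(a, scheme.b)
        data[2:] = bem_signal(b, scheme.b)
        dwi = DwiSeries(data=data, scheme=scheme)
        mask = VoiMask(np.ones((4, 2, 1), dtype=bool))
        pm = fit_volume(dwi, mask, "bem")
        for idx in np.argwhere(mask.data):
            r = fit_bem(data[tuple(idx)], scheme)
            assert pm.maps["D"][tuple(idx)] == r.params.d  # bit-identical
        assert np.nanmedian(pm.maps["D"][:2]) == pytest.approx(a.d, rel=0.02)
        assert np.nanmedian(pm.maps["D"][2:]) == pytest.approx(b.d, rel=0.02)

    def test_empty_mask_and_shape_mismatch_raise(self, scheme):
        dwi = self._series(scheme, BiExpParams(100, **SOFT_BEM))
        with pytest.raises(ValueError, match="empty"):
            fit_volume(dwi, VoiMask(np.zeros(dwi.spatial_shape, bool)), "mem")
        with pytest.raises(ValueError, match="shape"):
            fit_volume(dwi, VoiMask(np.ones((5, 5, 5), bool)), "mem")

    def test_invalid_voxels_are_nan_and_excluded(self, scheme):
        dwi = self._series(scheme, BiExpParams(100, **SOFT_BEM))
        dwi.data[0, 0, 0, :] = 0.0      # dead voxel
        mask = VoiMask(np.ones(dwi.spatial_shape, dtype=bool))
        pm = fit_volume(dwi, mask, "mem")
        assert not pm.valid_mask[0, 0, 0]
        assert np.isnan(pm.maps["ADC"][0, 0, 0])
        assert pm.meta["n_converged"] == mask.n_voxels - 1
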