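"""FXR forward model composition and per-voxel parameter estimation."""

import numpy as np
import pytest

from sspkrecur import (
    AcquisitionParams,
    PKParams,
    ShutterSpeedVoxelModel,
    compute_kep,
    fit_voxel_fxr,
    fxr_forward_timecourse,
    population_aif,
    spgr_signal,
    summarize_roi,
    tofts_concentration,
)
from sspkrecur.relaxometry import fxr_longitudinal_rate


class TestPKParams:
    def test_kep_derived(self):
        assert PKParams(0.20, 0.50, 1.0).kep == pytest.approx(0.40)
        assert PKParams(0.0, 0.3, 1.0).kep == 0.0

    def test_compute_kep_values(self):
        assert compute_kep(0.20, 0.50) == pytest.approx(0.40)
        assert compute_kep(0.0, 0.7) == 0.0
        assert compute_kep(0.14, 0.54) == pytest.approx(0.2593, abs=1e-4)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            compute_kep(0.2, 0.0)
        with pytest.raises(ValueError):
            PKParams(0.2, 1.5, 1.0)
        with pytest.raises(ValueError):
            PKParams(0.2, 0.5, -1.0)


class TestForwardModel:
    def test_zero_ktrans_flat_at_baseline(self, acq, aif):
        sig = fxr_forward_timecourse(PKParams(0.0, 0.5, 1.0), 1.4, acq, aif, 100.0)
        assert np.allclose(sig, sig[0])
        assert sig[0] == pytest.approx(
            spgr_signal(1 / 1.4, acq.flip_angle_dce, acq.tr_dce, 100.0))

    def test_linear_in_signal_scale(self, acq, aif):
        pk = PKParams(0.1, 0.5, 0.8)
        assert np.allclose(fxr_forward_timecourse(pk, 1.4, acq, aif, 2.0),
                           2.0 * fxr_forward_timecourse(pk, 1.4, acq, aif, 1.0))

    def test_baseline_frames_precontrast(self, acq, aif):
        sig = fxr_forward_timecourse(PKParams(0.3, 0.5, 0.8), 1.4, acq, aif, 1.0)
        base = spgr_signal(1 / 1.4, acq.flip_angle_dce, acq.tr_dce, 1.0)
        assert sig[0] == pytest.approx(base, rel=1e-12)
        assert sig[1] == pytest.approx(base, rel=1e-12)
        assert sig[acq.injection_frame:].max() > base

    def test_matches_straight_line_composition(self, acq, aif):
        # independently coded chain of the four sub-operations on the same grid
        pk = PKParams(0.18, 0.45, 0.9)
        t10, s0 = 1.2, 750.0
        tau_end = acq.frame_times[-1] - acq.injection_time
        fine = np.linspace(0.0, tau_end, int(tau_end) + 1)
        ct_fine = tofts_concentration(pk.ktrans, pk.ve, population_aif(fine, aif), fine)
        expected = np.empty(acq.n_frames)
        for j, t in enumerate(acq.frame_times):
            tau = t - acq.injection_time
            ct = 0.0 if tau < 0 else float(np.interp(tau, fine, ct_fine))
            r1 = fxr_longitudinal_rate(ct, pk.ve, pk.tau_i, 1 / t10,
                                       acq.relaxivity_r1)
            expected[j] = spgr_signal(r1, acq.flip_angle_dce, acq.tr_dce, s0)
        got = fxr_forward_timecourse(pk, t10, acq, aif, s0)
        assert np.allclose(got, expected, rtol=1e-12, atol=1e-12)

    def test_fxl_limit_matches_linear_tofts_model(self, acq, aif):
        # tau_i -> 0: forward curve equals a standard-Tofts linear-relaxation model
        tau_end = acq.frame_times[-1] - acq.injection_time
        fine = np.linspace(0.0, tau_end, int(tau_end) + 1)
        cp = population_aif(fine, aif)
        base = spgr_signal(1 / 1.4, acq.flip_angle_dce, acq.tr_dce, 1.0)
        # grid spans the tumor-mean range actually encountered (the exchange
        # correction grows quadratically in Ct/ve and would exceed the bound
        # for much larger Ktrans)
        for ktrans in (0.03, 0.1, 0.2):
            for ve in (0.4, 0.6, 0.8):
                ct_fine = tofts_concentration(ktrans, ve, cp, fine)
                ct = np.interp(acq.frame_times - acq.injection_time, fine, ct_fine)
                ct[acq.frame_times < acq.injection_time] = 0.0
                linear = spgr_signal(1 / 1.4 + acq.relaxivity_r1 * ct,
                                     acq.flip_angle_dce, acq.tr_dce, 1.0)
                fxr = fxr_forward_timecourse(PKParams(ktrans, ve, 1e-3),
                                             1.4, acq, aif, 1.0)
                assert np.max(np.abs(fxr - linear)) < 1e-3 * base


class TestVoxelFit:
    def test_noiseless_round_trip(self, acq, aif):
        truth = PKParams(0.14, 0.54, 0.78)
        sig = fxr_forward_timecourse(truth, 1.4, acq, aif, 1000.0)
        res = fit_voxel_fxr(sig, 1.4, acq, aif)
        assert res.converged
        assert res.params.ktrans == pytest.approx(truth.ktrans, rel=0.01)
        assert res.params.ve == pytest.approx(truth.ve, rel=0.01)
        assert res.params.tau_i == pytest.approx(truth.tau_i, rel=0.01)

    def test_flat_curve_fits_zero_ktrans(self, acq, aif):
        base = spgr_signal(1 / 1.4, acq.flip_angle_dce, acq.tr_dce, 1000.0)
        res = fit_voxel_fxr(np.full(acq.n_frames, base), 1.4, acq, aif)
        assert res.params.ktrans == pytest.approx(0.0, abs=1e-6)

    def test_recovery_error_shrinks_with_noise(self, acq, aif, rng):
        truth = PKParams(0.14, 0.54, 0.78)
        clean = fxr_forward_timecourse(truth, 1.4, acq, aif, 1000.0)
        errs = []
        for noise in (8.0, 2.0, 0.0):
            sig = clean + rng.normal(0.0, noise, clean.shape)
            res = fit_voxel_fxr(sig, 1.4, acq, aif)
            errs.append(abs(res.params.ktrans - truth.ktrans) / truth.ktrans)
        assert errs[0] > errs[2]
        assert errs[1] > errs[2]

    def test_requires_enough_frames(self, acq, aif):
        short = AcquisitionParams(frame_times=np.arange(8) * 15.0)
        base = np.ones(8)
        with pytest.raises(ValueError):
            ShutterSpeedVoxelModel(base, 1.4, short, aif)

    def test_s0_fixed_from_baseline(self, acq, aif):
        truth = PKParams(0.1, 0.5, 0.8)
        sig = fxr_forward_timecourse(truth, 1.4, acq, aif, 640.0)
        model = ShutterSpeedVoxelModel(sig, 1.4, acq, aif)
        assert model.s0 == pytest.approx(640.0, rel=1e-9)


class TestROISummary:
    def test_uniform_map(self):
        maps = {k: np.full((4, 4), v)
                for k, v in (("ktrans", 0.2), ("ve", 0.5), ("tau_i", 1.0))}
        means, n = summarize_roi(maps, np.ones((4, 4), dtype=bool))
        assert n == 16
        assert means["ktrans"] == pytest.approx(0.2)
        assert means["kep"] == pytest.approx(0.4)

    def test_two_voxel_mean(self):
        maps = {"ktrans": np.array([0.1, 0.3]), "ve": np.array([0.5, 0.5]),
                "tau_i": np.array([1.0, 1.0])}
        means, n = summarize_roi(maps, np.array([True, True]))
        assert means["ktrans"] == pytest.approx(0.2)

    def test_random_map_matches_direct_mean(self, rng):
        mask = rng.random((5, 10)) > 0.3
        maps = {"ktrans": rng.random((5, 10)), "ve": rng.random((5, 10)) * 0.9 + 0.05,
                "tau_i": rng.random((5, 10)) + 0.1}
        means, n = summarize_roi(maps, mask)
        assert n == mask.sum()
        assert means["tau_i"] == pytest.approx(maps["tau_i"][mask].mean())
        # kep is the mean of voxelwise ratios, not the ratio of means
        assert means["kep"] == pytest.approx(
            (maps["ktrans"][mask] / maps["ve"][mask]).mean())

    def test_empty_roi_rejected(self):
        maps = {"ktrans": np.zeros((2, 2)), "ve": np.ones((2, 2)),
                "tau_i": np.ones((2, 2))}
        with pytest.raises(ValueError):
            summarize_roi(maps, np.zeros((2, 2), dtype=bool))
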