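"""B0 mapping, EPI unwarping and DAM B1+ mapping closed-loop checks."""

import numpy as np
import pytest

from livert1 import field_maps as fm
from livert1.sequence_models import make_pulse, slice_profile


def _phase_volume(field_hz, delta_te_ms, base_phase=0.3):
    e1 = np.full(field_hz.shape, 1.0) * np.exp(1j * base_phase)
    e2 = e1 * np.exp(2j * np.pi * field_hz * delta_te_ms * 1e-3)
    return e1, e2


class TestComputeB0:
    def test_identical_phases_give_zero(self):
        e1, e2 = _phase_volume(np.zeros((16, 16)), 2.39)
        b0 = fm.compute_b0(e1, e2, 2.39, mask=np.ones((16, 16), bool))
        assert np.allclose(b0.offres_hz, 0.0, atol=1e-10)

    def test_uniform_pi_phase_difference(self):
        # 0.5 cycles / 2.39 ms = 209.2 Hz
        e1, e2 = _phase_volume(np.full((8, 8), 0.5 / 2.39e-3), 2.39)
        b0 = fm.compute_b0(e1, e2, 2.39, mask=np.ones((8, 8), bool))
        assert np.nanmean(np.abs(b0.offres_hz)) == pytest.approx(209.2, abs=0.1)

    def test_wrapped_linear_field_recovered(self):
        nx, ny = 64, 64
        field = 150.0 * np.linspace(-1, 1, nx)[:, None] * np.ones((1, ny))
        e1, e2 = _phase_volume(field, 2.39)
        b0 = fm.compute_b0(e1, e2, 2.39, mask=np.ones((nx, ny), bool))
        rms = np.sqrt(np.mean((b0.offres_hz - field) ** 2))
        assert rms < 1.0

    def test_low_magnitude_masked_out(self):
        e1, e2 = _phase_volume(np.zeros((16, 16)), 2.39)
        e1[:4] *= 1e-4
        e2[:4] *= 1e-4
        b0 = fm.compute_b0(e1, e2, 2.39, background_sd=0.01)
        assert not b0.mask[:4].any()
        assert np.isnan(b0.offres_hz[:4]).all()

    def test_rejects_mismatched_geometry(self):
        with pytest.raises(ValueError):
            fm.compute_b0(np.ones((4, 4), complex), np.ones((5, 5), complex), 2.39)


class TestUnwarpEpi:
    def test_zero_field_is_identity(self, rng):
        img = rng.random((24, 24))
        b0 = fm.B0Map(np.zeros((24, 24)), np.ones((24, 24), bool), 2.39)
        out, flagged = fm.unwarp_epi(img, b0, 0.3)
        assert np.allclose(out, img)
        assert not flagged.any()

    def test_uniform_shift_round_trip(self):
        # smooth image, uniform 50 Hz, dwell 0.3 ms x 52 lines = 0.78 voxels
        y = np.linspace(0, 3 * np.pi, 52)
        img = np.tile(1.5 + np.sin(y), (52, 1))
        b0 = fm.B0Map(np.full((52, 52), 50.0), np.ones((52, 52), bool), 2.39)
        out, _ = fm.unwarp_epi(img, b0, 0.3)
        b0n = fm.B0Map(np.full((52, 52), -50.0), np.ones((52, 52), bool), 2.39)
        back, _ = fm.unwarp_epi(out, b0n, 0.3)
        interior = np.s_[:, 2:-2]
        assert np.max(np.abs(back - img)[interior]) < 1e-2  # linear-interp error

    def test_landmark_displacement_matches_analytic_shift(self):
        nx = 64
        img = np.zeros((4, nx))
        img[:, 30] = 1.0  # landmark
        shift_hz = 100.0
        b0 = fm.B0Map(np.full((4, nx), shift_hz), np.ones((4, nx), bool), 2.39)
        out, _ = fm.unwarp_epi(img, b0, 0.3)
        expected = shift_hz * 0.3e-3 * nx  # 1.92 voxels
        com = (np.arange(nx) * out[0]).sum() / out[0].sum()
        assert com == pytest.approx(30.0 - expected, abs=0.25)

    def test_excessive_shift_flagged(self):
        img = np.ones((8, 16))
        b0 = fm.B0Map(np.full((8, 16), 5000.0), np.ones((8, 16), bool), 2.39)
        _, flagged = fm.unwarp_epi(img, b0, 0.3)
        assert flagged.all()


class TestDam3d:
    @pytest.mark.parametrize("b1_true", [0.4, 0.6, 0.8, 1.0, 1.2, 1.3])
    def test_forward_inverse_identity(self, b1_true):
        a = 65.0
        s1 = np.full((4, 4), np.sin(np.deg2rad(b1_true * a)))
        s2 = np.full((4, 4), np.sin(np.deg2rad(2 * b1_true * a)))
        res = fm.dam_b1_3d(s1, s2, a, mask=np.ones((4, 4), bool))
        assert res.b1_factor[0, 0] == pytest.approx(b1_true, abs=1e-6)

    def test_known_ratio_gives_080(self):
        # sin(104)/sin(52) = 1.2313 -> b1 = 0.800
        s1 = np.array([[np.sin(np.deg2rad(52.0))]])
        s2 = np.array([[np.sin(np.deg2rad(104.0))]])
        assert s2[0, 0] / s1[0, 0] == pytest.approx(1.2313, abs=1e-4)
        res = fm.dam_b1_3d(s1, s2, 65.0, mask=np.ones((1, 1), bool))
        assert res.b1_factor[0, 0] == pytest.approx(0.800, abs=1e-6)

    def test_zero_signal_masked(self):
        s1 = np.zeros((2, 2))
        s2 = np.ones((2, 2))
        res = fm.dam_b1_3d(s1, s2, 65.0, mask=np.ones((2, 2), bool))
        assert not res.mask.any()
        assert res.n_masked_out == 4


class TestDam2dCorrected:
    def _epi_pair(self, b1_true, gz=0.0, pulse=None, te=11.0):
        pulse = pulse or make_pulse("hann_sinc")
        vals = []
        for nom in (65.0, 130.0):
            z, prof = slice_profile(pulse, nom, b1_true, 8.0, n_z=129)
            w = np.exp(2j * np.pi * gz * z * te * 1e-3)
            vals.append(abs(np.trapezoid(np.sin(np.deg2rad(prof)) * w, z)))
        return np.full((3, 3), vals[0]), np.full((3, 3), vals[1])

    @pytest.mark.parametrize("b1_true", [0.6, 0.75, 0.9, 1.05, 1.2])
    def test_closed_loop_recovery(self, b1_true, dam_lookup):
        s1, s2 = self._epi_pair(b1_true)
        res = fm.dam_b1_2d_corrected(s1, s2, lookup=dam_lookup,
                                     mask=np.ones((3, 3), bool))
        assert res.b1_factor[0, 0] == pytest.approx(b1_true, abs=0.01)

    def test_uncorrected_closed_form_is_biased(self, dam_lookup):
        s1, s2 = self._epi_pair(1.0)
        naive = np.rad2deg(np.arccos(s2[0, 0] / (2 * s1[0, 0]))) / 65.0
        assert abs(naive - 1.0) > 0.05  # slice profile bias
        res = fm.dam_b1_2d_corrected(s1, s2, lookup=dam_lookup,
                                     mask=np.ones((3, 3), bool))
        assert abs(res.b1_factor[0, 0] - 1.0) < 0.01

    def test_through_slice_gradient_corrected(self, dam_lookup):
        gz = 2.0  # Hz/mm
        s1, s2 = self._epi_pair(0.75, gz=gz)
        ratio = s2[0, 0] / s1[0, 0]
        biased = dam_lookup.invert(np.array([ratio]), 0.0)[0]
        corrected = dam_lookup.invert(np.array([ratio]), gz)[0]
        assert abs(corrected - 0.75) < 0.01
        assert abs(biased - 0.75) > abs(corrected - 0.75)

    def test_hard_pulse_no_gradient_reduces_to_3d_dam(self):
        hard = make_pulse("hard")
        lk = fm.DamLookup(pulse=hard)
        b1_true = 0.85
        s1 = np.array([[np.sin(np.deg2rad(b1_true * 65.0))]])
        s2 = np.array([[np.sin(np.deg2rad(b1_true * 130.0))]])
        res = fm.dam_b1_2d_corrected(s1, s2, lookup=lk,
                                     mask=np.ones((1, 1), bool))
        ref = fm.dam_b1_3d(s1, s2, 65.0, mask=np.ones((1, 1), bool))
        assert res.b1_factor[0, 0] == pytest.approx(ref.b1_factor[0, 0],
                                                    abs=2e-3)

    def test_lookup_monotone_decreasing(self, dam_lookup):
        assert np.all(np.diff(dam_lookup.ratio, axis=0) < 0)
        assert dam_lookup.b1_grid[-1] >= 1.3

    def test_ratio_outside_lookup_masked(self, dam_lookup):
        s1 = np.array([[1.0]])
        s2 = np.array([[5.0]])  # ratio 5: impossible
        res = fm.dam_b1_2d_corrected(s1, s2, lookup=dam_lookup,
                                     mask=np.ones((1, 1), bool))
        assert not res.mask.any()


class TestResampleB1:
    def test_identity_on_same_grid(self, rng):
        b1 = fm.B1Map(rng.uniform(0.6, 1.2, (8, 8, 4)),
                      np.ones((8, 8, 4), bool))
        out = fm.resample_b1_to_spgr(b1, np.eye(4), np.eye(4), (8, 8, 4))
        assert np.allclose(out.b1_factor, b1.b1_factor, atol=1e-12)

    def test_constant_stays_constant(self):
        b1 = fm.B1Map(np.full((8, 8, 4), 0.9), np.ones((8, 8, 4), bool))
        src = np.diag([3.0, 3.0, 10.0, 1.0])
        tgt = np.diag([1.5, 1.5, 3.0, 1.0])
        out = fm.resample_b1_to_spgr(b1, src, tgt, (12, 12, 6))
        assert np.allclose(out.b1_factor[out.mask], 0.9)

    def test_linear_in_z_exact_at_half_spacing(self):
        nz = 8
        prof = np.linspace(0.7, 1.1, nz)
        b1 = fm.B1Map(np.tile(prof, (4, 4, 1)), np.ones((4, 4, nz), bool))
        src = np.diag([1.0, 1.0, 2.0, 1.0])        # 2 mm slices
        tgt = np.diag([1.0, 1.0, 1.0, 1.0])        # 1 mm target
        out = fm.resample_b1_to_spgr(b1, src, tgt, (4, 4, 2 * nz - 1))
        expect = np.interp(np.arange(2 * nz - 1) * 0.5, np.arange(nz), prof)
        got = out.b1_factor[2, 2]
        assert np.allclose(got[out.mask[2, 2]], expect[out.mask[2, 2]],
                           atol=1e-12)

    def test_out_of_coverage_masked(self):
        b1 = fm.B1Map(np.full((4, 4, 2), 1.0), np.ones((4, 4, 2), bool))
        out = fm.resample_b1_to_spgr(b1, np.eye(4), np.eye(4), (4, 4, 6))
        assert not out.mask[:, :, 3:].any()
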