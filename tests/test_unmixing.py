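"""Spectral unmixing: compensation algebra, least-squares recovery,
sO2 invariances, ROI statistics."""

import numpy as np
import pytest

from oxylight import (
    ChromophoreSpectra,
    FluenceMap,
    PAImage,
    SO2Map,
    amplitude_mask,
    average_frames,
    compensate_fluence,
    linear_unmix,
    roi_mean_so2,
    so2_map,
)
from oxylight.unmixing import CompensatedImage, ConcentrationMaps


def _fluence(values, wl=750, pitch=0.074):
    return FluenceMap(
        values=np.asarray(values, dtype=np.float64),
        wavelength_nm=wl,
        photons=0,
        seed=0,
        spacing_mm=pitch,
    )


def _comp(pixels, wl):
    pixels = np.asarray(pixels, dtype=float)
    return CompensatedImage(
        pixels=pixels,
        wavelength_nm=wl,
        valid=np.ones_like(pixels, dtype=bool),
        floor_applied=np.zeros_like(pixels, dtype=bool),
    )


class TestSpectra:
    def test_extinction_ordering_straddles_isosbestic_point(self, spectra):
        # HbR dominates at 750 nm, HbO2 at 850 nm
        assert spectra.eps_hbr[0] > spectra.eps_hbo2[0]
        assert spectra.eps_hbo2[1] > spectra.eps_hbr[1]

    def test_matrix_is_well_conditioned(self, spectra):
        assert np.linalg.cond(spectra.matrix) < 1e3

    def test_singular_matrix_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            ChromophoreSpectra((750, 850), (1.0, 2.0), (2.0, 4.0))


class TestCompensation:
    def test_uniform_fluence_is_a_global_rescale(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, (32, 32))
        pa = PAImage(p, 750, pulse_energy_uJ=100.0)
        b = compensate_fluence(pa, _fluence(np.full((32, 32), 0.25)))
        assert np.allclose(b.pixels, p / 100.0 / 0.25)

    def test_forward_model_inversion_recovers_absorption(self):
        """p = Gamma*mua*Phi synthesized, then divided by Phi -> Gamma*mua."""
        rng = np.random.default_rng(1)
        mua = rng.uniform(0.05, 5.0, (24, 24))
        phi = np.exp(-np.linspace(0, 4, 24))[:, None] * np.ones((24, 24))
        gamma = 0.7
        pa = PAImage(gamma * mua * phi, 850, pulse_energy_uJ=1.0)
        b = compensate_fluence(pa, _fluence(phi, wl=850), floor_fraction=1e-6)
        assert np.allclose(b.pixels[b.valid], (gamma * mua)[b.valid], rtol=1e-12)

    def test_fluence_floor_flags_deep_pixels_without_infinities(self):
        phi = np.ones((16, 16))
        phi[-4:, :] = 1e-9
        pa = PAImage(np.ones((16, 16)), 750)
        b = compensate_fluence(pa, _fluence(phi), floor_fraction=1e-3)
        assert b.floor_applied[-4:, :].all()
        assert not b.floor_applied[:-4, :].any()
        assert np.all(np.isfinite(b.pixels))

    def test_shape_mismatch_raises(self):
        pa = PAImage(np.ones((8, 8)), 750)
        with pytest.raises(ValueError, match="shape"):
            compensate_fluence(pa, _fluence(np.ones((8, 9))))


class TestLinearUnmix:
    def test_pure_chromophore_column_recovers_axis(self, spectra):
        a = spectra.matrix
        k = 3.7
        b750 = _comp(np.full((4, 4), k * a[0, 1]), 750)
        b850 = _comp(np.full((4, 4), k * a[1, 1]), 850)
        conc = linear_unmix(b750, b850, spectra)
        assert np.allclose(conc.c_hbr, 0.0, atol=1e-12 * k)
        assert np.allclose(conc.c_hbo2, k)

    def test_random_concentrations_recovered_exactly(self, spectra):
        """Forward-multiply oracle: b := A c, solve, compare to 1e-10."""
        rng = np.random.default_rng(42)
        c = rng.uniform(0.1, 10.0, (2, 50, 50))
        a = spectra.matrix
        b750 = _comp(a[0, 0] * c[0] + a[0, 1] * c[1], 750)
        b850 = _comp(a[1, 0] * c[0] + a[1, 1] * c[1], 850)
        conc = linear_unmix(b750, b850, spectra)
        assert np.allclose(conc.c_hbr, c[0], rtol=1e-10)
        assert np.allclose(conc.c_hbo2, c[1], rtol=1e-10)

    def test_linearity_in_b(self, spectra):
        rng = np.random.default_rng(3)
        b1 = rng.uniform(0.5, 2.0, (8, 8))
        b2 = rng.uniform(0.5, 2.0, (8, 8))
        one = linear_unmix(_comp(b1, 750), _comp(b2, 850), spectra)
        three = linear_unmix(_comp(3 * b1, 750), _comp(3 * b2, 850), spectra)
        assert np.allclose(three.c_hbr, 3 * one.c_hbr)
        assert np.allclose(three.c_hbo2, 3 * one.c_hbo2)

    def test_wavelength_order_enforced(self, spectra):
        with pytest.raises(ValueError, match="do not match"):
            linear_unmix(
                _comp(np.ones((4, 4)), 850), _comp(np.ones((4, 4)), 750), spectra
            )


class TestSO2:
    @pytest.mark.parametrize(
        "hbr,hbo2,expected",
        [(0.0, 1.0, 100.0), (1.0, 1.0, 50.0), (1.0, 3.0, 75.0), (2.5, 7.5, 75.0)],
    )
    def test_ratio_values_and_scale_invariance(self, hbr, hbo2, expected):
        conc = ConcentrationMaps(
            c_hbr=np.full((4, 4), hbr),
            c_hbo2=np.full((4, 4), hbo2),
            valid=np.ones((4, 4), dtype=bool),
        )
        m = so2_map(conc)
        assert np.allclose(m.so2[m.valid], expected)

    def test_so2_invariant_to_global_rescaling_of_b_and_A(self, spectra):
        """Neither the Grüneisen scale nor the extinction log convention
        can bias sO2."""
        rng = np.random.default_rng(7)
        c = rng.uniform(0.1, 5.0, (2, 16, 16))
        a = spectra.matrix
        b1 = a[0, 0] * c[0] + a[0, 1] * c[1]
        b2 = a[1, 0] * c[0] + a[1, 1] * c[1]
        base = so2_map(
            linear_unmix(_comp(b1, 750), _comp(b2, 850), spectra)
        )
        # (i) rescale both compensated images
        scaled_b = so2_map(
            linear_unmix(_comp(5.3 * b1, 750), _comp(5.3 * b2, 850), spectra)
        )
        # (ii) rescale the extinction matrix (base-10 vs natural log)
        scaled_a = ChromophoreSpectra(
            spectra.wavelengths_nm,
            tuple(np.log(10) * np.array(spectra.eps_hbr)),
            tuple(np.log(10) * np.array(spectra.eps_hbo2)),
        )
        scaled_spec = so2_map(
            linear_unmix(_comp(b1, 750), _comp(b2, 850), scaled_a)
        )
        assert np.allclose(base.so2, scaled_b.so2, atol=1e-9)
        assert np.allclose(base.so2, scaled_spec.so2, atol=1e-9)

    def test_swapping_wavelength_channels_breaks_recovery(self, spectra):
        """Channel order matters: swapped inputs give a wrong sO2."""
        c = np.array([0.04, 0.96])  # 96 percent
        a = spectra.matrix
        b = a @ c
        good = so2_map(
            linear_unmix(
                _comp(np.full((2, 2), b[0]), 750),
                _comp(np.full((2, 2), b[1]), 850),
                spectra,
            )
        )
        swapped = so2_map(
            linear_unmix(
                _comp(np.full((2, 2), b[1]), 750),
                _comp(np.full((2, 2), b[0]), 850),
                spectra,
            )
        )
        assert np.allclose(good.so2, 96.0, atol=1e-9)
        assert not np.allclose(swapped.so2, 96.0, atol=1.0)

    def test_nonpositive_total_marked_invalid(self):
        conc = ConcentrationMaps(
            c_hbr=np.array([[1.0, -2.0]]),
            c_hbo2=np.array([[1.0, 1.0]]),
            valid=np.ones((1, 2), dtype=bool),
        )
        m = so2_map(conc)
        assert m.valid[0, 0] and not m.valid[0, 1]
        assert np.isnan(m.so2[0, 1])


class TestROI:
    def _map(self, values, valid=None):
        values = np.asarray(values, dtype=float)
        if valid is None:
            valid = np.ones_like(values, dtype=bool)
        return SO2Map(so2=values, valid=valid, pixel_pitch_mm=0.1)

    def test_uniform_map_mean(self):
        m = self._map(np.full((40, 40), 80.0))
        mean, n = roi_mean_so2(m, (-1.0, 1.0, 1.0, 2.0))
        assert mean == pytest.approx(80.0)
        assert n > 0

    def test_two_level_roi_averages(self):
        v = np.full((40, 40), 60.0)
        v[20:, :] = 100.0
        m = self._map(v)
        mean, _ = roi_mean_so2(m, (-0.5, 0.5, 1.0, 3.0))
        assert mean == pytest.approx(80.0)

    def test_fully_invalid_roi_raises(self):
        m = self._map(np.full((20, 20), 50.0), valid=np.zeros((20, 20), bool))
        with pytest.raises(ValueError, match="no valid pixels"):
            roi_mean_so2(m, (-0.5, 0.5, 0.5, 1.0))


class TestFrameUtilities:
    def test_average_frames_reduces_noise(self):
        rng = np.random.default_rng(11)
        truth = np.ones((16, 16))
        frames = [
            PAImage(truth + rng.normal(0, 0.5, truth.shape), 750)
            for _ in range(20)
        ]
        avg = average_frames(frames)
        assert np.std(avg.pixels - truth) < 0.5 / np.sqrt(20) * 1.5

    def test_amplitude_mask_keeps_signal_rejects_background(self):
        rng = np.random.default_rng(13)
        p = rng.normal(0, 0.01, (64, 64))
        p[30:34, 30:34] += 1.0
        m = amplitude_mask(PAImage(p, 750), PAImage(p, 850))
        assert m[30:34, 30:34].all()
        assert m.mean() < 0.3
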