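"""PSF generation, modified-OTF degradation and Poisson noise."""

import numpy as np
import pytest
from scipy.signal import fftconvolve

from abersim import optics as O
from abersim.phantom import PhantomConfig, generate_phantom
from abersim.volio import as_array
from abersim.zernike import (AberrationSpec, rescale_max, sample_coefficients,
                             simulation_preset)


def _spec_with(index, value, m=14):
    c = [0.0] * (m + 1)
    c[index] = value
    return AberrationSpec(tuple(c))


class TestIdealPsf:
    def test_center_peak_and_unit_sum(self, small_optics):
        psf = as_array(O.ideal_psf(small_optics))
        assert psf.min() >= 0
        assert psf.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.unravel_index(psf.argmax(), psf.shape) == (16, 16, 16)

    def test_lateral_fwhm_matches_diffraction_limit(self):
        # fine lateral sampling so the FWHM is resolved
        cfg = O.OpticalConfig(shape=(16, 128, 128),
                              voxel_um=(0.2, 0.02, 0.02),
                              modality="widefield")
        psf = as_array(O.ideal_psf(cfg))
        prof = psf[8, 64, :]
        half = prof.max() / 2.0
        above = np.where(prof >= half)[0]
        # interpolated width at half maximum
        fwhm = (above.max() - above.min()) * 0.02
        expected = 0.51 * cfg.wavelength_um / cfg.na
        assert fwhm == pytest.approx(expected, rel=0.2)

    def test_na_above_medium_index_rejected(self):
        with pytest.raises(ValueError):
            O.OpticalConfig(na=1.4, n_medium=1.33)

    def test_lightsheet_is_axially_tighter_than_widefield(self):
        ls = O.OpticalConfig(shape=(64, 32, 32), modality="lightsheet")
        wf = O.OpticalConfig(shape=(64, 32, 32), modality="widefield")
        z_ls = as_array(O.ideal_psf(ls)).sum(axis=(1, 2))
        z_wf = as_array(O.ideal_psf(wf)).sum(axis=(1, 2))
        spread = lambda p: np.sqrt(np.sum(p * (np.arange(64) - 32.0) ** 2))
        assert spread(z_ls) < spread(z_wf)


class TestAberratedPsf:
    def test_zero_spec_reproduces_ideal_bitwise(self, small_optics):
        ideal = as_array(O.ideal_psf(small_optics))
        aber = as_array(O.aberrated_psf(small_optics,
                                        AberrationSpec.zeros(14)))
        assert np.array_equal(ideal, aber)

    def test_defocus_shifts_peak_plane_monotonically(self, small_optics):
        planes = []
        for c4 in (-1.5, -0.5, 0.5, 1.5):
            psf = as_array(O.aberrated_psf(small_optics, _spec_with(4, c4)))
            planes.append(np.unravel_index(psf.argmax(), psf.shape)[0])
        assert planes == sorted(planes) and planes[0] < planes[-1]

    def test_spherical_reduces_strehl(self, small_optics):
        ideal = as_array(O.ideal_psf(small_optics))
        aber = as_array(O.aberrated_psf(small_optics, _spec_with(12, 2.0)))
        assert aber.max() / ideal.max() < 1.0
        assert aber.sum() == pytest.approx(1.0, abs=1e-6)


class TestModifiedOtf:
    def test_self_ratio_is_unity_inside_support(self, small_optics):
        psf = as_array(O.ideal_psf(small_optics))
        motf = O.modified_otf(psf, psf, eps=1e-3)
        assert motf[0, 0, 0].real == pytest.approx(1.0, abs=2e-3)
        support = motf != 0
        assert np.abs(motf[support]).max() <= 1.0 + 1e-9

    def test_spherical_damps_mid_frequencies(self, small_optics):
        ipsf = as_array(O.ideal_psf(small_optics))
        apsf = as_array(O.aberrated_psf(small_optics, _spec_with(12, 2.0)))
        m_ab = np.abs(O.modified_otf(apsf, ipsf))
        m_id = np.abs(O.modified_otf(ipsf, ipsf))
        # mid-frequency lateral shell of the DC plane
        shell = m_ab[0, 0, 4:10]
        assert np.all(shell <= m_id[0, 0, 4:10] + 1e-9)

    def test_shape_mismatch_rejected(self, small_optics):
        psf = as_array(O.ideal_psf(small_optics))
        with pytest.raises(ValueError):
            O.modified_otf(psf, psf[:16])


class TestDegrade:
    def test_unit_transfer_is_identity(self, rng):
        img = rng.uniform(0, 1, (16, 16, 16))
        out = O.degrade(img, np.ones(img.shape, dtype=complex))
        assert np.allclose(out, img, atol=1e-12)

    def test_constant_image_scales_by_dc(self, small_optics):
        psf = as_array(O.ideal_psf(small_optics))
        motf = O.modified_otf(psf, psf, eps=1e-3)
        img = np.full((32, 32, 32), 5.0)
        out = O.degrade(img, motf)
        assert np.allclose(out, 5.0 * motf[0, 0, 0].real, atol=1e-9)

    def test_matches_direct_aberrated_convolution(self, medium_optics):
        """mOTF applied to an ideally blurred phantom ~ direct aPSF blur."""
        ipsf = as_array(O.ideal_psf(medium_optics))
        rng = np.random.default_rng(2)
        preset = simulation_preset()
        spec = rescale_max(sample_coefficients(preset, rng), 2.0, preset)
        apsf = as_array(O.aberrated_psf(medium_optics, spec))
        # interior phantom: structures kept away from the FFT boundary
        cfg = PhantomConfig(shape=(32, 32, 32), n_dots=4, n_lines=2,
                            n_circles=1, n_spheres=1, n_shells=1, seed=3)
        inner = as_array(generate_phantom(cfg))
        ph = np.zeros((64, 64, 64))
        ph[16:48, 16:48, 16:48] = inner
        gt = fftconvolve(ph, ipsf, mode="same")
        direct = fftconvolve(ph, apsf, mode="same")
        deg = O.degrade(gt, O.modified_otf(apsf, ipsf))
        rel = np.linalg.norm(deg - direct) / np.linalg.norm(direct)
        assert rel < 0.05

    def test_linearity_before_clipping(self, small_optics, rng):
        psf = as_array(O.ideal_psf(small_optics))
        motf = O.modified_otf(psf, psf)
        x = rng.uniform(0, 1, (32, 32, 32))
        y = rng.uniform(0, 1, (32, 32, 32))
        lhs = O.degrade(2.0 * x + 3.0 * y, motf)
        rhs = 2.0 * O.degrade(x, motf) + 3.0 * O.degrade(y, motf)
        assert np.allclose(lhs, rhs, atol=1e-9)


class TestPoissonNoise:
    def test_scaling_hits_target_signal_level(self, rng):
        img = rng.uniform(0.5, 1.0, (24, 24, 24))
        spec = O.NoiseSpec(target_snr=16.0)
        mask = img > 0.01 * img.max()
        scale = spec.target_snr**2 / img[mask].mean()
        scaled = img * scale
        assert scaled[mask].mean() == pytest.approx(256.0)
        noisy = O.add_poisson(img, spec, rng=rng)
        assert noisy.min() >= 0 and np.issubdtype(noisy.dtype, np.floating)

    def test_round_trip_snr_estimate(self, rng):
        img = rng.uniform(0.5, 1.0, (32, 32, 32))
        noisy = O.add_poisson(img, O.NoiseSpec(target_snr=10.0), rng=rng)
        assert O.measure_snr(noisy) == pytest.approx(10.0, rel=0.05)

    def test_poisson_statistics_at_bright_voxel(self, rng):
        v = 400.0
        draws = rng.poisson(v, size=10_000)
        assert draws.mean() / draws.std() == pytest.approx(np.sqrt(v), rel=0.05)

    def test_measure_snr_examples(self):
        img = np.full((8, 8, 8), 25.0)
        assert O.measure_snr(img) == pytest.approx(5.0)
        assert O.measure_snr(img * 4) == pytest.approx(10.0)
        with pytest.raises(ValueError):
            O.measure_snr(np.zeros((8, 8, 8)))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            O.add_poisson(np.zeros((8, 8, 8)), O.NoiseSpec(target_snr=4.0))
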