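"""Scalar-diffraction PSF/OTF models and the modified-OTF degradation operator.

The point spread function is computed by scalar Fourier-optics pupil
propagation: a circular pupil of radius NA/lambda in transverse spatial
frequency, an axial defocus phasor ``exp(i z sqrt((2 pi n / lambda)^2 -
k_perp^2))`` per plane, and the squared modulus of the inverse 2D transform.
Aberrations enter as a pupil phase ``exp(i phi)`` with ``phi`` the Zernike
wavefront.  For light-sheet detection the 3D PSF is further multiplied by a
Gaussian axial sheet-excitation profile of the configured FWHM.

Synthetic degradation follows the modified-OTF construction: an ideally
blurred ground-truth volume is Fourier transformed, multiplied by the ratio
of aberrated to ideal OTFs (Wiener-regularized), inverse transformed and
clipped, which re-blurs it as if it had been acquired with the aberrated
PSF.  Poisson noise is injected at a target SNR defined through the mean
signal S of above-threshold voxels, with SNR = sqrt(S).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import fft as sfft

from .volio import VolumeImage, as_array
from .zernike import AberrationSpec, wavefront

__all__ = [
    "OpticalConfig",
    "NoiseSpec",
    "ideal_psf",
    "aberrated_psf",
    "modified_otf",
    "degrade",
    "add_poisson",
    "measure_snr",
]

_GAUSS_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # FWHM / sigma


@dataclass(frozen=True)
class OpticalConfig:
    """Imaging-system parameters for PSF generation.

    Defaults mirror a 1.1 NA water-dipping light-sheet detection arm with
    0.532 µm emission and a 2 µm-thick (FWHM) Gaussian sheet, on a
    0.13 µm isotropic grid.  ``shape`` is (nz, ny, nx).
    """

    na: float = 1.1
    wavelength_um: float = 0.532
    n_medium: float = 1.33
    voxel_um: tuple[float, float, float] = (0.13, 0.13, 0.13)  # (dz, dy, dx)
    shape: tuple[int, int, int] = (64, 64, 64)
    modality: Literal["widefield", "lightsheet"] = "lightsheet"
    sheet_fwhm_um: float = 2.0

    def __post_init__(self) -> None:
        if self.na >= self.n_medium:
            raise ValueError(
                f"NA ({self.na}) must be below the medium index ({self.n_medium})"
            )
        if any(v <= 0 for v in self.voxel_um):
            raise ValueError("voxel sizes must be positive")
        if any(s < 16 for s in self.shape):
            raise ValueError("grid must be at least 16 voxels per axis")
        if self.modality not in ("widefield", "lightsheet"):
            raise ValueError(f"unknown modality {self.modality!r}")


@dataclass(frozen=True)
class NoiseSpec:
    """Target SNR for Poisson noise injection.

    ``target_snr`` is sqrt(S) where S is the mean of voxels brighter than
    ``signal_threshold_frac`` times the volume maximum.
    """

    target_snr: float = 16.0
    signal_threshold_frac: float = 0.01
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.target_snr <= 0:
            raise ValueError("target_snr must be > 0")
        if not 0 < self.signal_threshold_frac < 1:
            raise ValueError("signal_threshold_frac must be in (0, 1)")


def _pupil_grids(cfg: OpticalConfig):
    """Transverse frequency grids in FFT order: (k_perp, rho, theta, kz)."""
    nz, ny, nx = cfg.shape
    dz, dy, dx = cfg.voxel_um
    kx = 2.0 * np.pi * sfft.fftfreq(nx, d=dx)
    ky = 2.0 * np.pi * sfft.fftfreq(ny, d=dy)
    kyy, kxx = np.meshgrid(ky, kx, indexing="ij")
    k_perp2 = kxx**2 + kyy**2
    k_max = 2.0 * np.pi * cfg.na / cfg.wavelength_um
    rho = np.sqrt(k_perp2) / k_max
    theta = np.arctan2(kyy, kxx)
    k_n = 2.0 * np.pi * cfg.n_medium / cfg.wavelength_um
    kz = np.sqrt(np.maximum(k_n**2 - k_perp2, 0.0))
    return rho, theta, kz


def _psf_from_pupil_phase(cfg: OpticalConfig, phase: np.ndarray | None) -> np.ndarray:
    rho, theta, kz = _pupil_grids(cfg)
    pupil = (rho <= 1.0).astype(complex)
    if phase is not None:
        pupil = pupil * np.exp(1j * phase)
    nz = cfg.shape[0]
    dz = cfg.voxel_um[0]
    z = (np.arange(nz) - nz // 2) * dz
    # propagate all planes at once: (nz, ny, nx)
    phasor = np.exp(1j * kz[None, :, :] * z[:, None, None])
    fields = sfft.ifft2(pupil[None, :, :] * phasor, axes=(-2, -1), workers=-1)
    psf = np.abs(fields) ** 2
    psf = sfft.fftshift(psf, axes=(-2, -1))
    if cfg.modality == "lightsheet":
        sigma = cfg.sheet_fwhm_um / _GAUSS_FWHM
        psf *= np.exp(-(z**2) / (2.0 * sigma**2))[:, None, None]
    total = psf.sum()
    if total <= 0:
        raise ValueError("degenerate PSF: zero total intensity")
    return psf / total


def ideal_psf(cfg: OpticalConfig) -> VolumeImage:
    """Unaberrated PSF on the configured grid; nonnegative, unit sum."""
    psf = _psf_from_pupil_phase(cfg, None)
    return VolumeImage(psf, voxel_um=cfg.voxel_um, provenance=["ideal_psf"])


def aberrated_psf(cfg: OpticalConfig, spec: AberrationSpec) -> VolumeImage:
    """PSF with the aberration applied as a pupil phase.

    A zero coefficient vector reproduces :func:`ideal_psf` bit-for-bit.
    """
    if all(c == 0.0 for c in spec.coeffs):
        psf = _psf_from_pupil_phase(cfg, None)
    else:
        rho, theta, _ = _pupil_grids(cfg)
        phase = np.where(rho <= 1.0, wavefront(spec, rho, theta), 0.0)
        psf = _psf_from_pupil_phase(cfg, phase)
    return VolumeImage(psf, voxel_um=cfg.voxel_um, provenance=["aberrated_psf"])


def modified_otf(apsf: VolumeImage | np.ndarray, ipsf: VolumeImage | np.ndarray,
                 eps: float = 1e-3, support_frac: float = 1e-8) -> np.ndarray:
    """Ratio of aberrated to ideal OTFs, Wiener-regularized.

    mOTF = H_a conj(H_i) / (|H_i|^2 + eps * max|H_i|^2), zeroed outside the
    ideal OTF's support (|H_i| below ``support_frac`` of its maximum).
    Multiplying an ideally blurred spectrum by this re-blurs the volume to
    match the aberrated PSF.
    """
    a = as_array(apsf)
    i = as_array(ipsf)
    if a.shape != i.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {i.shape}")
    ha = sfft.fftn(a, workers=-1)
    hi = sfft.fftn(i, workers=-1)
    mag2 = np.abs(hi) ** 2
    peak2 = mag2.max()
    motf = ha * np.conj(hi) / (mag2 + eps * peak2)
    motf[mag2 <= (support_frac**2) * peak2] = 0.0
    return motf


def degrade(gt: VolumeImage | np.ndarray, motf: np.ndarray) -> VolumeImage | np.ndarray:
    """Apply the modified OTF in Fourier space; clip negatives to zero.

    Noise is injected separately by :func:`add_poisson`.
    """
    data = as_array(gt)
    if data.shape != motf.shape:
        raise ValueError(f"grid mismatch: {data.shape} vs {motf.shape}")
    out = sfft.ifftn(sfft.fftn(data, workers=-1) * motf, workers=-1).real
    np.clip(out, 0.0, None, out=out)
    if isinstance(gt, VolumeImage):
        return gt.with_data(out, "degrade:motf")
    return out


def _signal_mask(data: np.ndarray, threshold_frac: float) -> np.ndarray:
    peak = data.max()
    if peak <= 0:
        raise ValueError("degenerate input: no positive voxels")
    mask = data > threshold_frac * peak
    if not mask.any():
        raise ValueError("degenerate input: no voxel above the signal threshold")
    return mask


def add_poisson(img: VolumeImage | np.ndarray, noise: NoiseSpec,
                rng: np.random.Generator | None = None) -> VolumeImage | np.ndarray:
    """Rescale to the target SNR's photon level and Poisson-sample.

    The volume is scaled so that the mean signal S of above-threshold voxels
    equals ``target_snr**2``, then each voxel is replaced by a Poisson draw
    with that mean.
    """
    data = np.asarray(as_array(img), dtype=float)
    if data.min() < 0:
        raise ValueError("input must be nonnegative")
    mask = _signal_mask(data, noise.signal_threshold_frac)
    s_current = data[mask].mean()
    scale = noise.target_snr**2 / s_current
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    noisy = rng.poisson(data * scale).astype(float)
    if isinstance(img, VolumeImage):
        return img.with_data(
            noisy, f"add_poisson:snr={noise.target_snr},scale={scale:.6g}"
        )
    return noisy


def measure_snr(img: VolumeImage | np.ndarray,
                signal_threshold_frac: float = 0.01) -> float:
    """sqrt of the mean intensity of voxels above the signal threshold."""
    data = as_array(img)
    if data.size == 0:
        raise ValueError("empty image")
    mask = _signal_mask(data, signal_threshold_frac)
    return float(np.sqrt(data[mask].mean()))
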