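"""Seeded 3D phantom generator for restoration benchmarks.

Phantoms contain five structure classes — dots, lines, circles (rings),
filled spheres and spherical shells — randomly oriented and positioned in
the volume (structures may extend past the edges).  Intensities are drawn
per structure; overlaps keep the brighter value.  Ground truth for the
simulation benchmark is the phantom convolved with the ideal, noise-free
PSF (zero-padded linear convolution).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft

from .optics import OpticalConfig, ideal_psf
from .volio import VolumeImage, as_array

__all__ = [
    "PhantomConfig",
    "generate_phantom",
    "generate_phantom_labeled",
    "render_ground_truth",
    "CLASS_NAMES",
]

CLASS_NAMES = ("dots", "lines", "circles", "spheres", "shells")


@dataclass(frozen=True)
class PhantomConfig:
    """Structure counts, size ranges (voxels) and intensity range."""

    shape: tuple[int, int, int] = (256, 256, 256)
    voxel_um: tuple[float, float, float] = (0.13, 0.13, 0.13)
    n_dots: int = 30
    n_lines: int = 20
    n_circles: int = 15
    n_spheres: int = 15
    n_shells: int = 10
    dot_radius: tuple[float, float] = (1.0, 2.0)
    line_thickness: tuple[float, float] = (1.0, 2.0)
    line_length: tuple[float, float] = (20.0, 120.0)
    circle_radius: tuple[float, float] = (8.0, 20.0)
    circle_thickness: float = 1.0
    sphere_radius: tuple[float, float] = (5.0, 15.0)
    shell_radius: tuple[float, float] = (8.0, 20.0)
    shell_thickness: tuple[float, float] = (1.0, 2.0)
    intensity: tuple[float, float] = (0.5, 1.0)
    seed: int | None = None

    def counts(self) -> dict[str, int]:
        return {
            "dots": self.n_dots,
            "lines": self.n_lines,
            "circles": self.n_circles,
            "spheres": self.n_spheres,
            "shells": self.n_shells,
        }

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts().values()):
            raise ValueError("structure counts must be >= 0")


def _stamp_ball(vol: np.ndarray, labels: np.ndarray | None, label: int,
                center: np.ndarray, radius: float, value: float) -> None:
    lo = np.maximum(np.floor(center - radius - 1).astype(int), 0)
    hi = np.minimum(np.ceil(center + radius + 2).astype(int), vol.shape)
    if np.any(lo >= hi):
        return
    grids = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    inside = d2 <= radius**2
    box = vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    np.maximum(box, np.where(inside, value, 0.0), out=box)
    if labels is not None:
        lab = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        lab[inside & (lab == 0)] = label


def _stamp_shell(vol: np.ndarray, labels: np.ndarray | None, label: int,
                 center: np.ndarray, radius: float, thickness: float,
                 value: float) -> None:
    r_out = radius + thickness / 2.0
    lo = np.maximum(np.floor(center - r_out - 1).astype(int), 0)
    hi = np.minimum(np.ceil(center + r_out + 2).astype(int), vol.shape)
    if np.any(lo >= hi):
        return
    grids = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    d = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center)))
    inside = np.abs(d - radius) <= thickness / 2.0
    box = vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    np.maximum(box, np.where(inside, value, 0.0), out=box)
    if labels is not None:
        lab = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        lab[inside & (lab == 0)] = label


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _stamp_curve(vol, labels, label, points: np.ndarray, radius: float,
                 value: float) -> None:
    for p in points:
        _stamp_ball(vol, labels, label, p, radius, value)


def _render(cfg: PhantomConfig, rng: np.random.Generator,
            labels: np.ndarray | None) -> np.ndarray:
    shape = cfg.shape
    vol = np.zeros(shape, dtype=np.float64)
    lo_i, hi_i = cfg.intensity

    def rand_center() -> np.ndarray:
        return rng.uniform(0, np.asarray(shape, dtype=float) - 1)

    for _ in range(cfg.n_dots):
        _stamp_ball(vol, labels, 1, rand_center(),
                    rng.uniform(*cfg.dot_radius), rng.uniform(lo_i, hi_i))

    for _ in range(cfg.n_lines):
        start = rand_center()
        direction = _random_unit_vector(rng)
        length = rng.uniform(*cfg.line_length)
        thickness = rng.uniform(*cfg.line_thickness)
        steps = max(int(np.ceil(length / 0.5)), 2)
        t = np.linspace(0.0, length, steps)
        points = start[None, :] + t[:, None] * direction[None, :]
        _stamp_curve(vol, labels, 2, points, thickness / 2.0,
                     rng.uniform(lo_i, hi_i))

    for _ in range(cfg.n_circles):
        center = rand_center()
        radius = rng.uniform(*cfg.circle_radius)
        # orthonormal in-plane axes of a randomly oriented plane
        normal = _random_unit_vector(rng)
        helper = _random_unit_vector(rng)
        u = np.cross(normal, helper)
        while np.linalg.norm(u) < 1e-6:  # pragma: no cover - measure-zero
            helper = _random_unit_vector(rng)
            u = np.cross(normal, helper)
        u /= np.linalg.norm(u)
        w = np.cross(normal, u)
        n_pts = max(int(np.ceil(4 * np.pi * radius)), 8)
        ang = np.linspace(0, 2 * np.pi, n_pts, endpoint=False)
        points = (center[None, :]
                  + radius * np.cos(ang)[:, None] * u[None, :]
                  + radius * np.sin(ang)[:, None] * w[None, :])
        _stamp_curve(vol, labels, 3, points, cfg.circle_thickness / 2.0 + 0.5,
                     rng.uniform(lo_i, hi_i))

    for _ in range(cfg.n_spheres):
        _stamp_ball(vol, labels, 4, rand_center(),
                    rng.uniform(*cfg.sphere_radius), rng.uniform(lo_i, hi_i))

    for _ in range(cfg.n_shells):
        _stamp_shell(vol, labels, 5, rand_center(),
                     rng.uniform(*cfg.shell_radius),
                     rng.uniform(*cfg.shell_thickness),
                     rng.uniform(lo_i, hi_i))

    return vol


def generate_phantom(cfg: PhantomConfig,
                     rng: np.random.Generator | None = None) -> VolumeImage:
    """Render one phantom; deterministic for a fixed seed/generator."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    vol = _render(cfg, rng, None)
    return VolumeImage(vol, voxel_um=cfg.voxel_um, provenance=["phantom"])


def generate_phantom_labeled(
    cfg: PhantomConfig, rng: np.random.Generator | None = None
) -> tuple[VolumeImage, np.ndarray, dict[str, int]]:
    """Phantom plus a per-voxel class-label map and per-class voxel counts.

    Labels are 1..5 for dots, lines, circles, spheres, shells (first stamp
    wins on overlap); 0 is background.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    labels = np.zeros(cfg.shape, dtype=np.uint8)
    vol = _render(cfg, rng, labels)
    counts = {name: int((labels == i + 1).sum())
              for i, name in enumerate(CLASS_NAMES)}
    return (
        VolumeImage(vol, voxel_um=cfg.voxel_um, provenance=["phantom"]),
        labels,
        counts,
    )


def render_ground_truth(phantom: VolumeImage | np.ndarray,
                        cfg: OpticalConfig,
                        psf: VolumeImage | np.ndarray | None = None) -> VolumeImage:
    """Blur the phantom with the ideal PSF to form the benchmark ground truth.

    The PSF is generated on the optics grid (``cfg.shape``) unless supplied;
    convolution is linear (zero-padded) and cropped back to the phantom grid.
    """
    from .deconv import _embed_psf, _support_halfwidths

    data = as_array(phantom)
    if psf is None:
        psf = ideal_psf(cfg)
    kernel = as_array(psf)
    if any(k > s for k, s in zip(kernel.shape, data.shape)):
        raise ValueError(
            f"PSF grid {kernel.shape} exceeds phantom grid {data.shape}"
        )
    # centered zero-padded convolution: the PSF peak stays on its voxel
    pads = _support_halfwidths(kernel)
    work = np.pad(data, [(p, p) for p in pads])
    otf = sfft.fftn(sfft.ifftshift(_embed_psf(kernel, work.shape)),
                    workers=-1)
    gt = sfft.ifftn(sfft.fftn(work, workers=-1) * otf, workers=-1).real
    gt = gt[tuple(slice(p, s - p) for p, s in zip(pads, work.shape))]
    gt = np.ascontiguousarray(gt)
    np.clip(gt, 0.0, None, out=gt)
    voxel = phantom.voxel_um if isinstance(phantom, VolumeImage) else cfg.voxel_um
    prov = (phantom.provenance if isinstance(phantom, VolumeImage) else [])
    return VolumeImage(gt, voxel_um=voxel, provenance=[*prov, "ideal_blur"])
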