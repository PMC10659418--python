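"""3D fiber orientation by weighted vector summation and directional variance.

For every voxel inside a segmented fiber mask, the surrounding ``n^3``
window is searched for fiber voxels whose straight segment to the center
stays within the mask.  Each such segment contributes a candidate vector,
weighted by its length and by the inverse intensity variation along it
(1 / (1 + CV), CV the coefficient of variation), and the direction of the
weighted vector sum defines the local fiber orientation.

Angle conventions (degrees, fibers are axial so all angles live on a
half-circle):

* ``theta``: azimuth of the xy-projection from +x, in [0, 180)
* ``beta``:  angle of the zx-projection from +x, in [0, 180)
* ``gamma``: angle of the yz-projection from -y, in [0, 180)
* ``phi``:   polar angle from +z, in [0, 180]; related to the projections
  by tan^2(phi) = 1/tan^2(beta) + 1/tan^2(gamma).

The 3D directional variance over a region of k fiber voxels is

    DV = 1 - sqrt(Cbar^2 + Sbar^2 + Zbar^2),

with Cbar = (1/k) sum (f_j/sqrt(1+f_j^2)) cos(2 theta_j) (Sbar analogous
with sine), Zbar = (1/k) sum SI_j/sqrt(1+f_j^2),
f_j = sqrt(1/tan^2(2 beta_j) + 1/tan^2(2 gamma_j)) and SI_j = -sign(phi_j -
90 deg).  DV is 0 for perfectly parallel fibers and approaches 1 for
isotropically disordered ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import line_nd
from skimage.filters import threshold_multiotsu

from .volio import VolumeImage, as_array

__all__ = [
    "WindowConfig",
    "VoxelOrientation",
    "OrientationField",
    "DVStats",
    "segment_fibers",
    "angles_from_vector",
    "local_orientation",
    "orientation_field",
    "directional_variance",
    "directional_variance_from_angles",
    "orientation_histogram",
]

_F_CLAMP = 1e12  # cap for f_j when a doubled-angle tangent degenerates


@dataclass(frozen=True)
class WindowConfig:
    """Local-window parameters; ``n`` should be 2-3x the fiber thickness."""

    n: int = 9
    otsu_levels: int = 6
    min_fiber_voxels: int = 1

    def __post_init__(self) -> None:
        if self.n < 3 or self.n % 2 == 0:
            raise ValueError("window edge n must be odd and >= 3")
        if self.otsu_levels < 2:
            raise ValueError("otsu_levels must be >= 2")


@dataclass(frozen=True)
class VoxelOrientation:
    """Orientation angles (degrees) at one voxel; invalid if too few vectors."""

    theta_deg: float
    beta_deg: float
    gamma_deg: float
    phi_deg: float
    valid: bool


@dataclass
class OrientationField:
    """Per-voxel orientation maps over a fiber mask (NaN where invalid)."""

    mask: np.ndarray
    theta: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    phi: np.ndarray
    valid: np.ndarray

    def angles_in(self, region: np.ndarray | None = None):
        """Valid (theta, beta, gamma, phi) arrays within an optional region."""
        sel = self.valid if region is None else (self.valid & region)
        return (self.theta[sel], self.beta[sel],
                self.gamma[sel], self.phi[sel])


@dataclass(frozen=True)
class DVStats:
    """Directional-variance summary over a region of k fiber voxels."""

    dv: float
    c_bar: float
    s_bar: float
    z_bar: float
    k: int


def segment_fibers(vol: VolumeImage | np.ndarray, levels: int = 6) -> np.ndarray:
    """Multi-level Otsu fiber mask: lowest class is background.

    ``levels`` intensity classes are separated by ``levels - 1`` thresholds;
    the union of the upper ``levels - 1`` classes is the fiber mask.
    """
    data = np.asarray(as_array(vol), dtype=float)
    if data.max() == data.min():
        raise ValueError("constant image cannot be thresholded")
    n_unique = np.unique(data).size
    classes = min(levels, n_unique)
    thresholds = threshold_multiotsu(data, classes=classes,
                                     nbins=max(256, classes * 8))
    return data > thresholds[0]


def _canonical_hemisphere(v: np.ndarray) -> np.ndarray:
    """Flip axial vectors into the x >= 0 hemisphere (ties by y, then z)."""
    x, y, z = v
    if x < 0 or (x == 0 and (y < 0 or (y == 0 and z < 0))):
        return -v
    return v


def angles_from_vector(v: np.ndarray | tuple[float, float, float]
                       ) -> tuple[float, float, float, float]:
    """(theta, beta, gamma, phi) in degrees for a 3D direction (x, y, z)."""
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("zero vector has no orientation")
    x, y, z = _canonical_hemisphere(v / norm)
    theta = np.degrees(np.arctan2(y, x)) % 180.0
    beta = np.degrees(np.arctan2(z, x)) % 180.0
    gamma = np.degrees(np.arctan2(z, -y)) % 180.0
    phi = np.degrees(np.arccos(np.clip(z, -1.0, 1.0)))
    return float(theta), float(beta), float(gamma), float(phi)


def angles_from_vectors(v: np.ndarray) -> np.ndarray:
    """Vectorized :func:`angles_from_vector` for an (N, 3) array of (x, y, z).

    Returns an (N, 4) array of (theta, beta, gamma, phi) in degrees.
    """
    v = np.asarray(v, dtype=float)
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero vector has no orientation")
    u = v / norms[:, None]
    flip = (u[:, 0] < 0) | ((u[:, 0] == 0) & ((u[:, 1] < 0) |
            ((u[:, 1] == 0) & (u[:, 2] < 0))))
    u[flip] *= -1.0
    x, y, z = u.T
    theta = np.degrees(np.arctan2(y, x)) % 180.0
    beta = np.degrees(np.arctan2(z, x)) % 180.0
    gamma = np.degrees(np.arctan2(z, -y)) % 180.0
    phi = np.degrees(np.arccos(np.clip(z, -1.0, 1.0)))
    return np.column_stack([theta, beta, gamma, phi])


def _candidate_vectors(data: np.ndarray, mask: np.ndarray,
                       center: tuple[int, int, int], n: int):
    """Weighted candidate vectors from the center to in-window fiber voxels.

    A fiber voxel contributes only if the discretized segment from the
    center stays entirely inside the mask; the weight is segment length
    times 1/(1+CV) of the intensities along it.
    """
    h = n // 2
    cz, cy, cx = center
    lo = [max(c - h, 0) for c in center]
    hi = [min(c + h + 1, s) for c, s in zip(center, mask.shape)]
    sub = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    coords = np.argwhere(sub) + np.array(lo)
    vectors, weights = [], []
    for vz, vy, vx in coords:
        if (vz, vy, vx) == (cz, cy, cx):
            continue
        line = line_nd((cz, cy, cx), (vz, vy, vx), endpoint=True)
        if not mask[line].all():
            continue
        intens = data[line]
        mean = intens.mean()
        cv = intens.std() / mean if mean > 0 else 0.0
        vec = np.array([vx - cx, vy - cy, vz - cz], dtype=float)
        length = np.linalg.norm(vec)
        vectors.append(_canonical_hemisphere(vec / length))
        weights.append(length / (1.0 + cv))
    return vectors, weights


def local_orientation(vol: VolumeImage | np.ndarray, mask: np.ndarray,
                      center: tuple[int, int, int],
                      cfg: WindowConfig = WindowConfig()) -> VoxelOrientation:
    """Orientation of the fiber at one mask voxel (``center`` in z, y, x)."""
    data = np.asarray(as_array(vol), dtype=float)
    if not mask[center]:
        raise ValueError(f"center voxel {center} is not a fiber voxel")
    vectors, weights = _candidate_vectors(data, mask, center, cfg.n)
    if len(vectors) < max(cfg.min_fiber_voxels, 1):
        return VoxelOrientation(np.nan, np.nan, np.nan, np.nan, valid=False)
    resultant = np.sum([w * v for v, w in zip(vectors, weights)], axis=0)
    if np.linalg.norm(resultant) == 0:
        return VoxelOrientation(np.nan, np.nan, np.nan, np.nan, valid=False)
    theta, beta, gamma, phi = angles_from_vector(resultant)
    return VoxelOrientation(theta, beta, gamma, phi, valid=True)


def orientation_field(vol: VolumeImage | np.ndarray,
                      cfg: WindowConfig = WindowConfig(),
                      mask: np.ndarray | None = None) -> OrientationField:
    """Per-voxel orientation over the whole fiber mask.

    Segments the volume first (multi-level Otsu) unless a mask is given.
    Deterministic for fixed input.
    """
    data = np.asarray(as_array(vol), dtype=float)
    if mask is None:
        mask = segment_fibers(data, levels=cfg.otsu_levels)
    shape = data.shape
    theta = np.full(shape, np.nan)
    beta = np.full(shape, np.nan)
    gamma = np.full(shape, np.nan)
    phi = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    for center in map(tuple, np.argwhere(mask)):
        o = local_orientation(data, mask, center, cfg)
        if o.valid:
            theta[center] = o.theta_deg
            beta[center] = o.beta_deg
            gamma[center] = o.gamma_deg
            phi[center] = o.phi_deg
            valid[center] = True
    return OrientationField(mask=mask, theta=theta, beta=beta,
                            gamma=gamma, phi=phi, valid=valid)


def _planar_weight(beta_deg: np.ndarray, gamma_deg: np.ndarray):
    """f_j and its normalizations, with degenerate tangents taken by limit."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t2b = np.tan(np.radians(2.0 * beta_deg))
        t2g = np.tan(np.radians(2.0 * gamma_deg))
        inv = np.where(t2b == 0.0, np.inf, 1.0 / t2b**2) \
            + np.where(t2g == 0.0, np.inf, 1.0 / t2g**2)
    f = np.sqrt(inv)
    f = np.minimum(f, _F_CLAMP)
    planar = f / np.sqrt(1.0 + f**2)   # -> 1 as f -> inf
    axial = 1.0 / np.sqrt(1.0 + f**2)  # -> 0 as f -> inf
    return f, planar, axial


def directional_variance_from_angles(theta_deg, beta_deg, gamma_deg,
                                     phi_deg) -> DVStats:
    """Directional variance of a set of per-voxel orientations (degrees)."""
    theta = np.atleast_1d(np.asarray(theta_deg, dtype=float))
    beta = np.atleast_1d(np.asarray(beta_deg, dtype=float))
    gamma = np.atleast_1d(np.asarray(gamma_deg, dtype=float))
    phi = np.atleast_1d(np.asarray(phi_deg, dtype=float))
    k = theta.size
    if k == 0:
        raise ValueError("empty region: no valid orientations")
    _, planar, axial = _planar_weight(beta, gamma)
    # SI = -sign(phi - 90 deg); the +1 convention at phi = 90 is harmless
    # because its axial weight vanishes in the same limit.
    si = np.where(phi <= 90.0, 1.0, -1.0)
    c_bar = float(np.mean(planar * np.cos(np.radians(2.0 * theta))))
    s_bar = float(np.mean(planar * np.sin(np.radians(2.0 * theta))))
    z_bar = float(np.mean(si * axial))
    resultant = np.sqrt(c_bar**2 + s_bar**2 + z_bar**2)
    dv = float(np.clip(1.0 - resultant, 0.0, 1.0))
    return DVStats(dv=dv, c_bar=c_bar, s_bar=s_bar, z_bar=z_bar, k=int(k))


def directional_variance(field: OrientationField,
                         region: np.ndarray | None = None) -> DVStats:
    """Directional variance over the valid voxels of a region."""
    theta, beta, gamma, phi = field.angles_in(region)
    if theta.size == 0:
        raise ValueError("empty region: no valid orientations")
    return directional_variance_from_angles(theta, beta, gamma, phi)


def orientation_histogram(field: OrientationField | np.ndarray,
                          region: np.ndarray | None = None,
                          bin_deg: float = 5.0):
    """Histogram of theta over [0, 180) plus the FWHM of the modal peak.

    Returns ``(counts, bin_edges, fwhm_deg)``.  The FWHM is measured by
    linear interpolation of the half-maximum crossings around the modal
    bin; a single occupied bin reports the bin width.
    """
    if isinstance(field, OrientationField):
        thetas = field.angles_in(region)[0]
    else:
        thetas = np.asarray(field, dtype=float)
        if region is not None:
            thetas = thetas[region]
        thetas = thetas[np.isfinite(thetas)]
    if thetas.size == 0:
        raise ValueError("empty region: no valid orientations")
    n_bins = int(round(180.0 / bin_deg))
    counts, edges = np.histogram(thetas, bins=n_bins, range=(0.0, 180.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    peak = int(np.argmax(counts))
    half = counts[peak] / 2.0

    def _cross(direction: int) -> float:
        i = peak
        while 0 <= i + direction < len(counts) and counts[i + direction] >= half:
            i += direction
        j = i + direction
        if j < 0 or j >= len(counts):
            return centers[i] + direction * bin_deg / 2.0
        # linear interpolation between bin centers i and j
        c0, c1 = counts[i], counts[j]
        frac = (c0 - half) / (c0 - c1) if c0 != c1 else 0.5
        return centers[i] + direction * frac * bin_deg

    fwhm = float(_cross(+1) - _cross(-1))
    return counts, edges, fwhm
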