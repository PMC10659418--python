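"""ANSI-indexed Zernike basis, aberration sampling presets and RMS arithmetic.

Wavefront aberrations at the objective back focal plane are expanded on the
orthonormal (RMS-normalized) Zernike polynomials over the unit pupil disk,

    phi(r, theta) = sum_m c_m * Z_m(r, theta),

with the single-index ``m`` following the ANSI/OSA convention.  With the
orthonormal normalization the RMS wavefront distortion over the pupil equals
the Euclidean norm of the coefficients, so RMS bookkeeping reduces to
coefficient arithmetic.  Piston and tilt (ANSI 0, 1, 2) merely translate the
image and are excluded from every sampled aberration and from every RMS.

Coefficients are always expressed in radians of phase.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "ZernikeIndex",
    "AberrationSpec",
    "SamplingPreset",
    "ansi_to_nm",
    "nm_to_ansi",
    "max_index_for_order",
    "zernike_basis",
    "wavefront",
    "experimental_preset",
    "simulation_preset",
    "defocus_only_preset",
    "sample_coefficients",
    "rms",
    "rms_bound",
    "rescale_max",
    "rescale_fixed",
    "single_mode_spec",
    "SINGLE_MODE_INDICES",
]

#: ANSI index pairs carrying each named low-order aberration mode.  Two-index
#: modes list (cosine-like, sine-like) partners whose quadrature sum is the
#: mode amplitude.
SINGLE_MODE_INDICES: dict[str, tuple[int, ...]] = {
    "defocus": (4,),
    "astigmatism": (3, 5),
    "coma": (7, 8),
    "trefoil": (6, 9),
    "spherical": (12,),
}


# ---------------------------------------------------------------------------
# Index bookkeeping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ZernikeIndex:
    """ANSI single index ``j`` with its (radial order, azimuthal frequency)."""

    j: int
    n: int
    m_az: int

    def __post_init__(self) -> None:
        if self.j != (self.n * (self.n + 2) + self.m_az) // 2:
            raise ValueError(f"inconsistent ANSI triple {self}")

    @classmethod
    def from_j(cls, j: int) -> "ZernikeIndex":
        n, m_az = ansi_to_nm(j)
        return cls(j=j, n=n, m_az=m_az)


def ansi_to_nm(j: int) -> tuple[int, int]:
    """Invert the ANSI pyramid enumeration: ``j -> (n, m_az)``.

    ANSI orders modes by radial order ``n`` and, within an order, by
    increasing azimuthal frequency ``m_az`` from ``-n`` to ``+n`` in steps
    of two, so that ``j = (n(n+2) + m_az) / 2``.
    """
    j = int(j)
    if j < 0:
        raise ValueError(f"ANSI index must be >= 0, got {j}")
    n = int((math.isqrt(8 * j + 1) - 1) // 2)
    m_az = 2 * j - n * (n + 2)
    return n, m_az


def nm_to_ansi(n: int, m_az: int) -> int:
    """Map (radial order, azimuthal frequency) to the ANSI single index."""
    if n < 0 or abs(m_az) > n or (n - m_az) % 2:
        raise ValueError(f"invalid Zernike pair (n={n}, m_az={m_az})")
    return (n * (n + 2) + m_az) // 2


def max_index_for_order(order: int) -> int:
    """Largest ANSI index among modes with radial order <= ``order``.

    The pyramid through order ``n`` holds ``(n+1)(n+2)/2`` modes, so the
    maximum index is that count minus one (14 for order 4, 35 for order 7).
    """
    order = int(order)
    if order < 0:
        raise ValueError(f"radial order must be >= 0, got {order}")
    return (order + 1) * (order + 2) // 2 - 1


# ---------------------------------------------------------------------------
# Basis evaluation
# ---------------------------------------------------------------------------

def _radial_poly(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    """Zernike radial polynomial R_n^m (m >= 0) by the explicit factorial sum."""
    out = np.zeros_like(rho, dtype=float)
    for k in range((n - m) // 2 + 1):
        c = (
            (-1) ** k
            * math.factorial(n - k)
            / (
                math.factorial(k)
                * math.factorial((n + m) // 2 - k)
                * math.factorial((n - m) // 2 - k)
            )
        )
        out += c * rho ** (n - 2 * k)
    return out


def zernike_basis(j: int, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Orthonormal Zernike polynomial ``Z_j`` sampled on polar pupil coords.

    ``rho`` is normalized so the pupil edge is 1; values with ``rho > 1``
    return 0.  Normalization is such that the mean over the disk is 0 for
    j >= 1 and the RMS over the disk is 1, hence phase RMS equals the
    coefficient norm.
    """
    rho = np.asarray(rho, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if rho.size == 0:
        raise ValueError("empty pupil grid")
    n, m_az = ansi_to_nm(j)
    m = abs(m_az)
    norm = math.sqrt(n + 1) if m == 0 else math.sqrt(2 * (n + 1))
    radial = _radial_poly(n, m, np.clip(rho, 0.0, 1.0))
    if m_az > 0:
        angular = np.cos(m * theta)
    elif m_az < 0:
        angular = np.sin(m * theta)
    else:
        angular = np.ones_like(theta)
    out = norm * radial * angular
    out = np.where(rho <= 1.0, out, 0.0)
    return out


def wavefront(spec: "AberrationSpec", rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Phase map (radians) of the aberration: coefficient-weighted basis sum."""
    rho = np.asarray(rho, dtype=float)
    out = np.zeros(np.broadcast(rho, theta).shape, dtype=float)
    for j, c in enumerate(spec.coeffs):
        if c != 0.0:
            out += c * zernike_basis(j, rho, theta)
    return out


# ---------------------------------------------------------------------------
# Aberration specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AberrationSpec:
    """Zernike coefficient vector in radians, ANSI-indexed 0..M."""

    coeffs: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "coeffs", tuple(float(c) for c in self.coeffs))
        if len(self.coeffs) < 1:
            raise ValueError("coefficient vector must not be empty")

    @property
    def max_index(self) -> int:
        return len(self.coeffs) - 1

    def rms(self) -> float:
        return rms(self)

    def to_json(self) -> str:
        return json.dumps(
            [
                {"ansi_index": j, "coeff_rad": c}
                for j, c in enumerate(self.coeffs)
            ]
        )

    @classmethod
    def from_json(cls, text: str) -> "AberrationSpec":
        entries = json.loads(text)
        coeffs = [0.0] * (max(e["ansi_index"] for e in entries) + 1)
        for e in entries:
            coeffs[int(e["ansi_index"])] = float(e["coeff_rad"])
        return cls(tuple(coeffs))

    @classmethod
    def zeros(cls, max_index: int) -> "AberrationSpec":
        return cls((0.0,) * (max_index + 1))


def rms(spec: AberrationSpec | Sequence[float]) -> float:
    """RMS wavefront distortion: sqrt of summed squared coefficients, j >= 3."""
    coeffs = np.asarray(
        spec.coeffs if isinstance(spec, AberrationSpec) else spec, dtype=float
    )
    return float(np.sqrt(np.sum(coeffs[3:] ** 2)))


# ---------------------------------------------------------------------------
# Sampling presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SamplingPreset:
    """Per-index upper bounds ``T_m`` plus an optional rescaling rule.

    ``rescale`` is one of ``"none"``, ``"max_rms"`` (divide by the bound RMS
    and multiply by ``omega``, so sampled aberrations never exceed ``omega``)
    or ``"fixed_rms"`` (normalize each draw to exactly ``upsilon``).
    """

    name: str
    bounds: tuple[float, ...]
    rescale: str = "none"
    omega: float | None = None
    upsilon: float | None = None
    mode: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "bounds", tuple(float(t) for t in self.bounds))
        if any(t < 0 for t in self.bounds):
            raise ValueError("bounds must be nonnegative")
        if any(t != 0.0 for t in self.bounds[:3]):
            raise ValueError("piston/tilt bounds (ANSI 0,1,2) must be 0")
        if self.rescale not in ("none", "max_rms", "fixed_rms"):
            raise ValueError(f"unknown rescale rule {self.rescale!r}")
        if self.rescale == "max_rms" and self.omega is None:
            raise ValueError("max_rms rescale requires omega")
        if self.rescale == "fixed_rms" and self.upsilon is None:
            raise ValueError("fixed_rms rescale requires upsilon")

    @property
    def max_index(self) -> int:
        return len(self.bounds) - 1

    def to_yaml(self) -> str:
        d = {
            "name": self.name,
            "bounds": list(self.bounds),
            "rescale": self.rescale,
        }
        if self.omega is not None:
            d["omega"] = self.omega
        if self.upsilon is not None:
            d["upsilon"] = self.upsilon
        if self.mode is not None:
            d["mode"] = self.mode
        return yaml.safe_dump(d)

    @classmethod
    def from_yaml(cls, text: str) -> "SamplingPreset":
        d = yaml.safe_load(text)
        return cls(
            name=d["name"],
            bounds=tuple(d["bounds"]),
            rescale=d.get("rescale", "none"),
            omega=d.get("omega"),
            upsilon=d.get("upsilon"),
            mode=d.get("mode"),
        )


def rms_bound(preset: SamplingPreset) -> float:
    """RMS of the bound vector itself: sqrt(sum T_m^2) over m >= 3."""
    return rms(preset.bounds)


def _bounds_array(max_index: int, heavy: Iterable[int], heavy_val: float,
                  base_val: float) -> tuple[float, ...]:
    t = np.full(max_index + 1, base_val)
    t[:3] = 0.0
    for j in heavy:
        if j <= max_index:
            t[j] = heavy_val
    return tuple(t)


def experimental_preset(max_index: int = 14, *, rescale: str = "none",
                        omega: float | None = None,
                        upsilon: float | None = None) -> SamplingPreset:
    """Bounds used for experimental data: 0.5 rad baseline with an extra
    1 rad on defocus (ANSI 4) and primary spherical (ANSI 12)."""
    return SamplingPreset(
        name="experimental",
        bounds=_bounds_array(max_index, (4, 12), 1.5, 0.5),
        rescale=rescale, omega=omega, upsilon=upsilon,
    )


def simulation_preset(max_index: int = 14, *, rescale: str = "none",
                      omega: float | None = None,
                      upsilon: float | None = None) -> SamplingPreset:
    """Bounds used for phantom simulations: 1.5 rad on defocus, both
    primary astigmatisms and spherical (ANSI 3, 4, 5, 12); 0.5 rad otherwise."""
    return SamplingPreset(
        name="simulation",
        bounds=_bounds_array(max_index, (3, 4, 5, 12), 1.5, 0.5),
        rescale=rescale, omega=omega, upsilon=upsilon,
    )


def defocus_only_preset(max_index: int = 14, *, rescale: str = "none",
                        omega: float | None = None,
                        upsilon: float | None = None) -> SamplingPreset:
    """Single-mode bounds: 1.5 rad on defocus (ANSI 4), zero elsewhere."""
    t = [0.0] * (max_index + 1)
    t[4] = 1.5
    return SamplingPreset(name="defocus_only", bounds=tuple(t),
                          rescale=rescale, omega=omega, upsilon=upsilon)


_PRESET_FACTORIES = {
    "experimental": experimental_preset,
    "simulation": simulation_preset,
    "defocus_only": defocus_only_preset,
}


def preset_by_name(name: str, max_index: int = 14, **kwargs) -> SamplingPreset:
    try:
        factory = _PRESET_FACTORIES[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(_PRESET_FACTORIES)}"
        ) from None
    return factory(max_index, **kwargs)


def sample_coefficients(preset: SamplingPreset,
                        rng: np.random.Generator) -> AberrationSpec:
    """Draw one aberration: each c_m uniform on [-T_m, T_m], then rescale."""
    t = np.asarray(preset.bounds)
    coeffs = rng.uniform(-t, t)
    coeffs[t == 0.0] = 0.0  # uniform(-0,0) is already 0; make it exact
    spec = AberrationSpec(tuple(coeffs))
    if preset.rescale == "max_rms":
        spec = rescale_max(spec, preset.omega, preset)
    elif preset.rescale == "fixed_rms":
        spec = rescale_fixed(spec, preset.upsilon)
    return spec


def rescale_max(spec: AberrationSpec, omega: float,
                preset: SamplingPreset) -> AberrationSpec:
    """Rescale so the *bound* RMS maps to ``omega``; sampled RMS <= omega.

    Every coefficient is multiplied by omega / RMS_T where RMS_T is the RMS
    of the preset's bound vector, so the bound configuration itself lands
    exactly at omega and every draw below the bounds lands below it.
    """
    bound = rms_bound(preset)
    if bound <= 0:
        raise ValueError("preset bound RMS is zero; cannot rescale")
    scale = float(omega) / bound
    return AberrationSpec(tuple(c * scale for c in spec.coeffs))


def rescale_fixed(spec: AberrationSpec, upsilon: float) -> AberrationSpec:
    """Rescale the draw itself to an exact RMS of ``upsilon``."""
    r = rms(spec)
    if r <= 0:
        raise ValueError("cannot rescale a zero-RMS aberration to a fixed RMS")
    scale = float(upsilon) / r
    return AberrationSpec(tuple(c * scale for c in spec.coeffs))


def single_mode_spec(mode: str, upsilon: float, *, split: float = 0.0,
                     max_index: int = 14,
                     rng: np.random.Generator | None = None) -> AberrationSpec:
    """Aberration containing a single named mode at RMS ``upsilon``.

    Two-component modes (astigmatism, coma, trefoil) distribute the
    amplitude over their ANSI pair as (cos, sin) of ``split * pi/2`` so the
    quadrature sum is exactly ``upsilon``; pass ``rng`` to draw the split
    uniformly instead.
    """
    if upsilon < 0:
        raise ValueError("upsilon must be >= 0")
    try:
        indices = SINGLE_MODE_INDICES[mode]
    except KeyError:
        raise ValueError(
            f"unknown mode {mode!r}; choose from {sorted(SINGLE_MODE_INDICES)}"
        ) from None
    coeffs = [0.0] * (max_index + 1)
    if len(indices) == 1:
        coeffs[indices[0]] = float(upsilon)
    else:
        if rng is not None:
            split = float(rng.uniform(0.0, 1.0))
        if not 0.0 <= split <= 1.0:
            raise ValueError("split must lie in [0, 1]")
        a, b = indices
        coeffs[a] = float(upsilon) * math.cos(math.pi * split / 2.0)
        coeffs[b] = float(upsilon) * math.sin(math.pi * split / 2.0)
    return AberrationSpec(tuple(coeffs))
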