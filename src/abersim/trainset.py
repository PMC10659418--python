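"""Assembly of (ground truth, synthetically aberrated) training pairs.

Ground-truth volumes come either from phantoms blurred with the ideal PSF
or from shallow subvolumes of experimental stacks (the planes nearest the
detection objective, least contaminated by sample-induced aberration).
Each ground truth is degraded ``augment`` times (default 10) with
independently sampled aberrations via the modified-OTF operator plus
Poisson noise, so 50 sources yield 500 pairs per session.

Restoration is delegated to a narrow pluggable backend contract
(train(pairs, cfg) -> handle; apply(handle, volume) -> volume) so that
externally trained deep networks can be slotted in.  The shipped
``baseline`` backend is not a learned model: it stores the mean sampled
aberrated PSF and restores by Richardson–Lucy deconvolution with it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Protocol, Sequence

import numpy as np

from .deconv import DeconConfig, richardson_lucy
from .optics import (NoiseSpec, OpticalConfig, aberrated_psf, add_poisson,
                     degrade, ideal_psf, modified_otf)
from .volio import VolumeImage, as_array, write_volume
from .zernike import AberrationSpec, SamplingPreset, sample_coefficients

__all__ = [
    "TrainingPair",
    "ShallowCrop",
    "extract_shallow_subvolumes",
    "build_pairs",
    "write_dataset",
    "RestorationModel",
    "train_restoration",
    "apply_restoration",
    "register_backend",
]


@dataclass(frozen=True)
class ShallowCrop:
    """A shallow-side crop: z-range (0-based, half-open) plus an xy box."""

    z_range: tuple[int, int]
    y_range: tuple[int, int] | None = None
    x_range: tuple[int, int] | None = None
    source_id: str = ""
    tile_target_bytes: int | None = None  # subdivide large crops (~80 MB typ.)


@dataclass
class TrainingPair:
    """One ground-truth volume with its synthetically degraded partner."""

    gt: VolumeImage
    degraded: VolumeImage
    spec: AberrationSpec
    noise: NoiseSpec | None
    source_id: str = ""
    seed: int | None = None

    def manifest_entry(self) -> dict[str, Any]:
        return {
            "source_id": self.source_id,
            "seed": self.seed,
            "spec": {str(j): c for j, c in enumerate(self.spec.coeffs)},
            "noise": None if self.noise is None else {
                "target_snr": self.noise.target_snr,
                "signal_threshold_frac": self.noise.signal_threshold_frac,
            },
        }


def _tile_counts(shape: tuple[int, int, int], target_bytes: int,
                 bytes_per_voxel: int = 4) -> tuple[int, int, int]:
    """Per-axis tile counts so each tile stays under the byte target.

    Tiles split the lateral axes first (isotropy of content is better
    preserved by keeping full z), by ceil-division bookkeeping.
    """
    total = int(np.prod(shape)) * bytes_per_voxel
    n_tiles = max(-(-total // target_bytes), 1)  # ceil
    ny = int(np.ceil(np.sqrt(n_tiles)))
    nx = int(np.ceil(n_tiles / ny))
    return (1, ny, nx)


def extract_shallow_subvolumes(
    stack: VolumeImage, crops: Sequence[ShallowCrop]
) -> list[VolumeImage]:
    """Crop shallow subvolumes (optionally tiled) out of a source stack."""
    out: list[VolumeImage] = []
    nz, ny, nx = stack.data.shape
    for crop in crops:
        z0, z1 = crop.z_range
        y0, y1 = crop.y_range if crop.y_range else (0, ny)
        x0, x1 = crop.x_range if crop.x_range else (0, nx)
        if not (0 <= z0 < z1 <= nz and 0 <= y0 < y1 <= ny and 0 <= x0 < x1 <= nx):
            raise ValueError(f"crop {crop} out of range for stack {stack.data.shape}")
        sub = stack.data[z0:z1, y0:y1, x0:x1]
        if crop.tile_target_bytes:
            tz, ty, tx = _tile_counts(sub.shape, crop.tile_target_bytes)
            z_edges = np.linspace(0, sub.shape[0], tz + 1, dtype=int)
            y_edges = np.linspace(0, sub.shape[1], ty + 1, dtype=int)
            x_edges = np.linspace(0, sub.shape[2], tx + 1, dtype=int)
            for iz in range(tz):
                for iy in range(ty):
                    for ix in range(tx):
                        tile = sub[z_edges[iz]:z_edges[iz + 1],
                                   y_edges[iy]:y_edges[iy + 1],
                                   x_edges[ix]:x_edges[ix + 1]]
                        out.append(stack.with_data(
                            tile.copy(),
                            f"shallow_crop:{crop.source_id}:tile{iz},{iy},{ix}",
                        ))
        else:
            out.append(stack.with_data(
                sub.copy(), f"shallow_crop:{crop.source_id}:z[{z0},{z1})"
            ))
    return out


def build_pairs(
    gts: Sequence[VolumeImage],
    preset: SamplingPreset,
    cfg: OpticalConfig,
    noise: NoiseSpec | None = None,
    augment: int = 10,
    seed: int | None = None,
) -> list[TrainingPair]:
    """Degrade each ground truth with ``augment`` independent aberrations.

    For every (gt, draw) an aberration is sampled from the preset, turned
    into an aberrated PSF, applied through the modified OTF, and Poisson
    noise is added at the configured SNR.  The pair count is always
    ``len(gts) * augment``.  A master seed fans out to one child seed per
    pair so any pair can be reproduced in isolation.
    """
    if augment < 1:
        raise ValueError("augment must be >= 1")
    master = np.random.SeedSequence(seed)
    children = master.spawn(len(gts) * augment)
    ipsf = ideal_psf(cfg)
    pairs: list[TrainingPair] = []
    k = 0
    for gi, gt in enumerate(gts):
        for _ in range(augment):
            child = children[k]
            child_seed = int(child.generate_state(1)[0] % (2**31))
            rng = np.random.default_rng(child_seed)
            spec = sample_coefficients(preset, rng)
            apsf = aberrated_psf(cfg, spec)
            if all(c == 0.0 for c in spec.coeffs):
                # zero aberration degrades identically; skip the
                # regularized OTF ratio, which would damp band edges
                deg = gt.with_data(as_array(gt).copy(), "degrade:identity") \
                    if isinstance(gt, VolumeImage) else as_array(gt).copy()
            else:
                motf = modified_otf(apsf, ipsf)
                deg = degrade(gt, motf)
            if noise is not None:
                deg = add_poisson(deg, noise, rng=rng)
            pairs.append(TrainingPair(
                gt=gt,
                degraded=deg if isinstance(deg, VolumeImage)
                else VolumeImage(deg, voxel_um=cfg.voxel_um),
                spec=spec,
                noise=noise,
                source_id=f"gt{gi:04d}",
                seed=child_seed,
            ))
            k += 1
    return pairs


def write_dataset(pairs: Sequence[TrainingPair], out_dir: str | Path,
                  cfg: OpticalConfig | None = None,
                  master_seed: int | None = None) -> Path:
    """Write paired TIFFs (gt_XXXX.tif / deg_XXXX.tif) and manifest.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, pair in enumerate(pairs):
        write_volume(pair.gt, out_dir / f"gt_{i:04d}.tif")
        write_volume(pair.degraded, out_dir / f"deg_{i:04d}.tif")
        entries.append({"index": i, **pair.manifest_entry()})
    manifest = {
        "n_pairs": len(pairs),
        "master_seed": master_seed,
        "optics": None if cfg is None else {
            "na": cfg.na, "wavelength_um": cfg.wavelength_um,
            "n_medium": cfg.n_medium, "voxel_um": list(cfg.voxel_um),
            "shape": list(cfg.shape), "modality": cfg.modality,
            "sheet_fwhm_um": cfg.sheet_fwhm_um,
        },
        "pairs": entries,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out_dir / "manifest.json"


# ---------------------------------------------------------------------------
# Restoration backend contract
# ---------------------------------------------------------------------------

@dataclass
class RestorationModel:
    """Opaque handle returned by a backend, with a training manifest."""

    backend: str
    state: Any
    manifest: dict[str, Any] = field(default_factory=dict)


class RestorationBackend(Protocol):  # pragma: no cover - typing contract
    def train(self, pairs: Sequence[TrainingPair],
              config: dict[str, Any]) -> RestorationModel: ...

    def apply(self, model: RestorationModel,
              vol: VolumeImage) -> VolumeImage: ...


#: Training hyper-parameter defaults recorded in every manifest (epochs,
#: steps per epoch and patch size match the published network settings; the
#: baseline backend records but does not consume them).
DEFAULT_BACKEND_CONFIG: dict[str, Any] = {
    "epochs": 200,
    "steps_per_epoch": 400,
    "patch_size": 64,
    "residual_blocks": 5,
    "residual_groups": 5,
    "channels": 32,
}


class BaselineBackend:
    """Non-learned reference backend: mean aberrated PSF + RL deconvolution.

    Training averages the aberrated PSFs implied by each pair's recorded
    aberration; applying runs Richardson–Lucy with that mean PSF.
    """

    name = "baseline"

    def __init__(self, optics: OpticalConfig, iterations: int = 20) -> None:
        self.optics = optics
        self.iterations = iterations

    def train(self, pairs: Sequence[TrainingPair],
              config: dict[str, Any]) -> RestorationModel:
        mean_psf = np.zeros(self.optics.shape, dtype=float)
        for pair in pairs:
            mean_psf += as_array(aberrated_psf(self.optics, pair.spec))
        mean_psf /= len(pairs)
        mean_psf /= mean_psf.sum()
        return RestorationModel(
            backend=self.name,
            state={"mean_apsf": mean_psf, "iterations": self.iterations},
            manifest={**config, "n_pairs": len(pairs),
                      "backend": self.name, "learned": False},
        )

    def apply(self, model: RestorationModel, vol: VolumeImage) -> VolumeImage:
        cfg = DeconConfig(iterations=model.state["iterations"])
        return richardson_lucy(vol, model.state["mean_apsf"], cfg)


_BACKENDS: dict[str, Callable[..., RestorationBackend]] = {
    "baseline": BaselineBackend,
}


def register_backend(name: str, factory: Callable[..., RestorationBackend]) -> None:
    _BACKENDS[name] = factory


def train_restoration(
    pairs: Sequence[TrainingPair],
    backend: str | RestorationBackend = "baseline",
    backend_config: dict[str, Any] | None = None,
    **backend_kwargs: Any,
) -> RestorationModel:
    """Train (or fit) a restoration backend on the pairs; returns a handle."""
    if len(pairs) == 0:
        raise ValueError("cannot train a restoration backend on zero pairs")
    config = {**DEFAULT_BACKEND_CONFIG, **(backend_config or {})}
    if isinstance(backend, str):
        try:
            backend = _BACKENDS[backend](**backend_kwargs)
        except KeyError:
            raise ValueError(f"unknown restoration backend {backend!r}") from None
    try:
        return backend.train(pairs, config)
    except Exception as exc:
        raise RuntimeError(
            f"restoration backend {getattr(backend, 'name', backend)!r} "
            f"failed during training: {exc}"
        ) from exc


def apply_restoration(model: RestorationModel,
                      vol: VolumeImage,
                      backend: RestorationBackend | None = None) -> VolumeImage:
    """Apply a trained backend to a volume; output shape equals input shape."""
    if backend is None:
        if model.backend != "baseline":
            raise ValueError(
                f"no backend instance supplied for {model.backend!r}"
            )
        shape = model.state["mean_apsf"].shape
        backend = BaselineBackend(OpticalConfig(shape=shape))
    out = backend.apply(model, vol)
    if as_array(out).shape != as_array(vol).shape:
        raise RuntimeError(
            f"backend {model.backend!r} changed the volume shape"
        )
    return out
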