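"""Synthetic phantoms and noise models.

Real micro-CT test data (stained rodent brain at ~10 μm/voxel) is large
and not redistributable, so every quantitative check in this package
runs on phantoms: piecewise-constant volumes built from spheres, boxes
and striped slabs — the last emulating the lamellar fissure-and-lobe
structure of the cerebellar vermis at phantom scale — corrupted with a
chosen noise model.  Generation is deterministic: the same spec and seed
reproduce the volume bit for bit.

Noise kinds:

* ``gaussian`` — additive Gaussian white noise, the base model of
  standard NLM;
* ``poisson_gaussian`` — Poisson shot noise (photon-count statistics at
  a given gain) plus Gaussian read noise, a common CT detector model;
* ``rician`` — magnitude of a complex signal with Gaussian noise in both
  channels; stands in for non-Gaussian envelope noise.

The last two exercise the kernel-shape exponent for non-AGWN data.
Phantom intensities are kept un-clamped internally (noise can excurse
outside [0, gsv_levels-1]); clamping happens only on export, so noise
statistics stay exact for the estimator tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError, ValidationError
from .volio import Volume

__all__ = [
    "Sphere",
    "Box",
    "Lamellae",
    "PhantomSpec",
    "NoiseModel",
    "generate_phantom",
    "add_noise",
]

# stable per-operation stream ids so phantom geometry and noise draws are
# independently reproducible regardless of call order
_STREAM_NOISE = 0x6E6F6973  # "nois"


@dataclass(frozen=True)
class Sphere:
    center: tuple[float, float, float]  # (z, y, x) voxel coordinates
    radius: float
    intensity: float


@dataclass(frozen=True)
class Box:
    corner: tuple[int, int, int]  # lowest (z, y, x) corner
    size: tuple[int, int, int]
    intensity: float


@dataclass(frozen=True)
class Lamellae:
    """Striped slab: planes of the given thickness repeating every
    ``period`` voxels along ``axis``, starting at ``origin``."""

    origin: int
    period: int
    thickness: int
    intensity: float
    axis: int = 0

    def __post_init__(self) -> None:
        if self.period < 1 or not (0 < self.thickness <= self.period):
            raise ValidationError("lamellae need 0 < thickness <= period")
        if self.axis not in (0, 1, 2):
            raise ValidationError("lamellae axis must be 0, 1 or 2")


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative description of a synthetic phantom.

    Primitives are drawn in list order (later overwrites earlier);
    primitives extending outside the volume are clipped silently.
    """

    shape: tuple[int, int, int] = (32, 32, 32)
    background: float = 50.0
    shapes: tuple = ()
    gsv_levels: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or min(self.shape) < 1:
            raise ValidationError("phantom shape must be 3 positive entries")
        if self.gsv_levels < 2:
            raise ValidationError("gsv_levels must be >= 2")


@dataclass(frozen=True)
class NoiseModel:
    """Noise to apply in image space (post-acquisition standpoint)."""

    kind: str = "gaussian"
    sigma: float = 10.0
    gain: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "poisson_gaussian", "rician"):
            raise ValidationError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")
        if self.kind == "poisson_gaussian" and self.gain <= 0:
            raise ValidationError("gain must be > 0 for poisson_gaussian")


def generate_phantom(spec: PhantomSpec) -> Volume:
    """Render a noiseless phantom volume from its spec (deterministic)."""
    data = np.full(spec.shape, float(spec.background), dtype=np.float64)
    zz, yy, xx = np.indices(spec.shape)
    for prim in spec.shapes:
        if isinstance(prim, Sphere):
            cz, cy, cx = prim.center
            mask = (
                (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2
                <= prim.radius**2
            )
            data[mask] = prim.intensity
        elif isinstance(prim, Box):
            sl = tuple(
                slice(max(0, c), max(0, c + s))
                for c, s in zip(prim.corner, prim.size)
            )
            data[sl] = prim.intensity
        elif isinstance(prim, Lamellae):
            coord = (zz, yy, xx)[prim.axis]
            mask = (coord - prim.origin) % prim.period < prim.thickness
            mask &= coord >= prim.origin
            data[mask] = prim.intensity
        else:
            raise ValidationError(f"unknown primitive {type(prim).__name__}")
    return Volume(
        data=data,
        gsv_levels=spec.gsv_levels,
        provenance=f"phantom(seed={spec.seed})",
    )


def add_noise(volume: Volume, model: NoiseModel) -> Volume:
    """Corrupt a volume with the given noise model (seeded, reproducible)."""
    rng = np.random.default_rng([_STREAM_NOISE, int(model.seed)])
    u = volume.data
    if model.kind == "gaussian":
        noisy = u if model.sigma == 0 else u + rng.normal(0.0, model.sigma, u.shape)
    elif model.kind == "poisson_gaussian":
        noisy = rng.poisson(np.maximum(model.gain * u, 0.0)).astype(np.float64)
        noisy /= model.gain
        if model.sigma > 0:
            noisy += rng.normal(0.0, model.sigma, u.shape)
    else:  # rician
        if np.any(u < 0):
            raise ContractError("rician requires non-negative input")
        n1 = rng.normal(0.0, model.sigma, u.shape)
        n2 = rng.normal(0.0, model.sigma, u.shape)
        noisy = np.sqrt((u + n1) ** 2 + n2**2)
    out = volume.with_data(noisy)
    out.provenance = (volume.provenance + f" +{model.kind}(sigma={model.sigma})").strip()
    return out


def clamp_to_levels(volume: Volume) -> Volume:
    """Clamp intensities to [0, gsv_levels - 1]; used on export only."""
    out = volume.with_data(np.clip(volume.data, 0.0, volume.gsv_levels - 1))
    out.provenance = volume.provenance
    return out


def standard_phantom(
    shape: tuple[int, int, int] = (32, 32, 32),
    low: float = 50.0,
    high: float = 150.0,
    gsv_levels: int = 256,
    seed: int = 0,
) -> Volume:
    """Two-intensity benchmark phantom: background ``low`` with a
    centred sphere of intensity ``high`` (radius a third of the shortest
    edge)."""
    center = tuple((n - 1) / 2.0 for n in shape)
    radius = min(shape) / 3.0
    return generate_phantom(
        PhantomSpec(
            shape=shape,
            background=low,
            shapes=(Sphere(center=center, radius=radius, intensity=high),),
            gsv_levels=gsv_levels,
            seed=seed,
        )
    )


def two_sigma_fixture(
    shape: tuple[int, int, int] = (64, 64, 64),
    sigma_low: float = 2.0,
    sigma_high: float = 10.0,
    seed: int = 0,
    structured: bool = True,
) -> tuple[Volume, Volume]:
    """Spatially varying noise fixture: low-σ left half, high-σ right half.

    Returns ``(clean, noisy)``.  With ``structured`` the clean volume
    carries lamellar stripes in both halves so that over- or
    under-smoothing is visible in PSNR; otherwise both halves are
    constant.  The split is along x (axis 2).
    """
    shapes = ()
    if structured:
        shapes = (Lamellae(origin=4, period=8, thickness=4, intensity=150.0, axis=1),)
    clean = generate_phantom(
        PhantomSpec(shape=shape, background=50.0, shapes=shapes, seed=seed)
    )
    half = shape[2] // 2
    rng_lo = np.random.default_rng([_STREAM_NOISE, int(seed), 1])
    rng_hi = np.random.default_rng([_STREAM_NOISE, int(seed), 2])
    noisy = clean.data.copy()
    noisy[:, :, :half] += rng_lo.normal(0.0, sigma_low, noisy[:, :, :half].shape)
    noisy[:, :, half:] += rng_hi.normal(0.0, sigma_high, noisy[:, :, half:].shape)
    noisy_vol = clean.with_data(noisy)
    noisy_vol.provenance = f"two-sigma(sigma={sigma_low}/{sigma_high},seed={seed})"
    return clean, noisy_vol
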