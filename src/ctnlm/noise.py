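"""Local noise estimation and automatic smoothing-parameter selection.

Instead of asking the user for the noise standard deviation — a number
nobody has for a fresh scan — the noise is estimated from the volume
itself via pseudo-residuals, blockwise so that spatially varying noise
(common in cone-beam micro-CT) gets a locally correct estimate rather
than a single whole-volume value.  The per-block estimate σ̂ is then
turned into the NLM smoothing bandwidth

    h = max(h_min, sqrt(2 · β · σ̂² · |N|))

where |N| is the patch voxel count and β a dimensionless tuning scale,
following the classical automatic-bandwidth rule for patch-based
denoising under additive Gaussian noise.  Because σ̂ carries intensity
units, h is automatically equivariant under intensity stretch; the
number of representable gray-scale values enters only through the floor
``h_min``, which scales linearly with it so that 8-bit and 16-bit
encodings of the same scene denoise identically after the stretch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ContractError, ValidationError
from .volio import Volume

__all__ = [
    "NoiseMap",
    "SmoothingPolicy",
    "pseudo_residuals",
    "estimate_noise_local",
    "smoothing_parameter",
]

@dataclass(frozen=True)
class NoiseMap:
    """Per-block noise standard-deviation estimates over a volume.

    ``sigma[i, j, k]`` is the σ̂ of the block covering voxels
    ``[i*block_size:(i+1)*block_size, ...]``; edge blocks are truncated to
    the voxels that exist.
    """

    block_size: int
    sigma: np.ndarray
    grid_shape: tuple[int, int, int]
    method: str = "pseudo-residual"

    def __post_init__(self) -> None:
        if not (np.all(self.sigma >= 0) and np.all(np.isfinite(self.sigma))):
            raise ValidationError("noise map sigma must be finite and >= 0")
        if self.sigma.shape != tuple(self.grid_shape):
            raise ValidationError("noise map grid_shape mismatch")

    def sigma_at(self, index: tuple[int, int, int]) -> float:
        """σ̂ of the block containing voxel ``index`` (nearest-block lookup)."""
        block = tuple(min(i // self.block_size, g - 1)
                      for i, g in zip(index, self.grid_shape))
        return float(self.sigma[block])

    def sigma_volume(self, shape: tuple[int, int, int]) -> np.ndarray:
        """Expand σ̂ to a full per-voxel array (piecewise constant)."""
        idx = [
            np.minimum(np.arange(n) // self.block_size, g - 1)
            for n, g in zip(shape, self.grid_shape)
        ]
        return self.sigma[np.ix_(*idx)]


@dataclass(frozen=True)
class SmoothingPolicy:
    """How σ̂ becomes the NLM bandwidth h.

    Parameters
    ----------
    beta
        Dimensionless scale on the squared bandwidth; 1.0 reproduces the
        standard automatic choice ``h² = 2σ̂²|N|``.
    gsv_ref
        Reference gray-scale-level count at which ``h_min`` is quoted
        (default 256, i.e. 8-bit).
    shape_p
        Kernel-shape exponent; 1 is the Gaussian kernel for additive
        Gaussian white noise, values ≠ 1 reshape the kernel for
        heavier- or lighter-tailed noise.
    h_min
        Strictly positive bandwidth floor, in intensity units at
        ``gsv_ref`` levels; scaled by ``gsv_levels / gsv_ref`` at use.
        Keeps weights defined in noise-free blocks, where NLM then only
        averages exactly identical patches.
    """

    beta: float = 1.0
    gsv_ref: int = 256
    shape_p: float = 1.0
    h_min: float = 256e-6

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValidationError("beta must be > 0")
        if self.shape_p <= 0:
            raise ValidationError("shape_p must be > 0")
        if self.h_min <= 0:
            raise ValidationError("h_min must be > 0")
        if self.gsv_ref < 2:
            raise ValidationError("gsv_ref must be >= 2")


def pseudo_residuals(volume: Volume) -> np.ndarray:
    """Pseudo-residuals ε of a volume.

    ε_i = sqrt(6/7) · (u_i − mean of the 6 face neighbours of u_i), with
    mirror padding at the boundary.  Under i.i.d. additive noise on a
    locally constant field, Var(ε) is an unbiased estimate of the noise
    variance; structure leaks in only at edges, which blockwise medians
    downweight.
    """
    u = volume.data
    if min(u.shape) < 2:
        raise ContractError("volume too thin for 3D residuals (axis of length 1)")
    return _residuals_any(u)


def _residuals_any(u: np.ndarray) -> np.ndarray:
    """Pseudo-residuals using face neighbours along every non-degenerate axis.

    With k usable neighbours the normalization is sqrt(k/(k+1)), which is
    sqrt(6/7) in the full 3D case and sqrt(4/5) for a single-slice volume.
    """
    axes = [ax for ax in range(3) if u.shape[ax] >= 2]
    k = 2 * len(axes)
    if k == 0:
        raise ContractError("volume too thin for residuals on every axis")
    pad = tuple((1, 1) if ax in axes else (0, 0) for ax in range(3))
    p = np.pad(u, pad, mode="reflect")
    core = tuple(slice(1, -1) if ax in axes else slice(None) for ax in range(3))
    neighbour_sum = np.zeros_like(u)
    for ax in axes:
        for shift in (0, 2):
            sl = list(core)
            sl[ax] = slice(shift, p.shape[ax] - 2 + shift)
            neighbour_sum += p[tuple(sl)]
    return math.sqrt(k / (k + 1.0)) * (u - neighbour_sum / k)


def estimate_noise_local(volume: Volume, block_size: int = 16) -> NoiseMap:
    """Blockwise noise estimate: σ̂ = sqrt(mean ε²) per block.

    The volume is partitioned into cubes of ``block_size`` voxels per
    edge (edge blocks truncated); each block gets its own estimate, so
    spatially varying noise is tracked instead of averaged away.
    """
    if block_size < 4:
        raise ContractError("block too small for stable estimate (block_size < 4)")
    eps2 = _residuals_any(volume.data) ** 2
    grid_shape = tuple(-(-n // block_size) for n in volume.shape)
    sigma = np.empty(grid_shape, dtype=np.float64)
    for bi in range(grid_shape[0]):
        for bj in range(grid_shape[1]):
            for bk in range(grid_shape[2]):
                block = eps2[
                    bi * block_size:(bi + 1) * block_size,
                    bj * block_size:(bj + 1) * block_size,
                    bk * block_size:(bk + 1) * block_size,
                ]
                sigma[bi, bj, bk] = math.sqrt(float(block.mean()))
    return NoiseMap(block_size=block_size, sigma=sigma, grid_shape=grid_shape)


def smoothing_parameter(
    sigma_hat: float,
    patch_voxels: int,
    policy: SmoothingPolicy = SmoothingPolicy(),
    gsv_levels: int = 256,
) -> float:
    """NLM bandwidth h from a local noise estimate.

    ``h = max(h_min · gsv_levels / gsv_ref, sqrt(2 β σ̂² |N|))`` — strictly
    positive always; monotone non-decreasing in σ̂, β and |N|.
    """
    if sigma_hat < 0:
        raise ContractError("sigma_hat must be >= 0")
    if patch_voxels < 1:
        raise ContractError("patch_voxels must be >= 1")
    floor = policy.h_min * (gsv_levels / policy.gsv_ref)
    return max(floor, math.sqrt(2.0 * policy.beta * sigma_hat**2 * patch_voxels))
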