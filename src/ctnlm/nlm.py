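"""Non-local-means denoising core.

Each output voxel is a weighted average of the voxels inside a search
window around it, the weight of a candidate falling off with the sum of
squared differences (SSD) between the intensity patch around the
candidate and the patch around the voxel being denoised:

    w(i, j) = exp( -( SSD(i, j) / h_i² )^p )

The bandwidth h_i is derived per voxel from the blockwise noise map
(:mod:`ctnlm.noise`), so regions with different noise levels are smoothed
by different amounts.  The exponent ``p`` reshapes the kernel: ``p = 1``
is the standard Gaussian kernel for additive Gaussian white noise,
``p ≠ 1`` adjusts the fall-off for noise with lighter or heavier tails.

The SSD computation dominates NLM runtime.  Between adjacent centers
along a scan line the two patch cubes share all but two end slices, so
for each fixed search offset the SSD is updated incrementally — subtract
the departing slice's squared differences, add the arriving slice's —
instead of being resummed (a pseudo moving-average filter).  For a patch
of edge M and a row of N centers this costs M³ + (N−1)·2·M² difference
operations against N·M³ for the naive resummation.  The recursion runs
along the fastest-varying axis (x) and is re-initialized at each row
start, which also bounds floating-point drift of the running sums.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .errors import ContractError, ValidationError
from .noise import NoiseMap, SmoothingPolicy, estimate_noise_local
from .volio import Volume

__all__ = [
    "NLMParams",
    "SSDField",
    "OpCounter",
    "ssd_naive",
    "ssd_map_maf",
    "nlm_weight",
    "denoise",
]


@dataclass(frozen=True)
class NLMParams:
    """Parameters of the denoiser.

    Defaults follow the fixed-window policy for 3D patch-based denoising:
    a 3³ patch (``patch_radius=1``) inside an 11³ search window
    (``search_radius=5``); larger search windows buy little quality
    because patch-similarity statistics degrade with distance.

    ``block_size=None`` switches the noise model from blockwise-local to
    a single whole-volume estimate (useful as a baseline; the local mode
    is the point of the method).
    """

    patch_radius: int = 1
    search_radius: int = 5
    policy: SmoothingPolicy = field(default_factory=SmoothingPolicy)
    block_size: int | None = 16
    boundary: str = "mirror"

    def __post_init__(self) -> None:
        if self.patch_radius < 1:
            raise ValidationError("patch_radius must be >= 1")
        if self.search_radius < self.patch_radius:
            raise ValidationError("search_radius must be >= patch_radius")
        if self.block_size is not None and self.block_size < 4:
            raise ValidationError("block_size must be >= 4 (or None for global)")
        if self.boundary != "mirror":
            raise ValidationError("only 'mirror' boundary handling is supported")

    @property
    def patch_edge(self) -> int:
        return 2 * self.patch_radius + 1

    @property
    def window_edge(self) -> int:
        return 2 * self.search_radius + 1

    @property
    def patch_voxels(self) -> int:
        return self.patch_edge**3


@dataclass(frozen=True)
class SSDField:
    """Patch SSD values for one center voxel across all search offsets.

    ``values[a, b, c]`` is the SSD between the patch at ``center`` and the
    patch at ``center + (a - rz, b - ry, c - rx)`` where ``(rz, ry, rx)``
    are the per-axis search radii (axes of length 1 collapse to radius 0).
    """

    center: tuple[int, int, int]
    values: np.ndarray
    offsets_radius: int

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValidationError("SSD values must be >= 0")


class OpCounter:
    """Tallies difference operations actually executed by the SSD paths.

    Naive SSD counts one operation per patch-element difference computed;
    the moving-average path counts the elements of every patch slice it
    consumes (full cube at row start, one arriving plus one departing
    slice per step).  ``rows`` records how many scan lines contributed,
    so per-row counts are ``difference_ops / rows``.
    """

    def __init__(self) -> None:
        self.difference_ops = 0
        self.rows = 0

    def add(self, n: int) -> None:
        self.difference_ops += int(n)


def _axis_radii(shape: tuple[int, ...], radius: int) -> tuple[int, ...]:
    # degenerate 2D mode: axes of length 1 get radius 0
    return tuple(0 if n == 1 else radius for n in shape)


def ssd_naive(
    volume: Volume,
    center: tuple[int, int, int],
    offset: tuple[int, int, int],
    patch_radius: int,
    counter: OpCounter | None = None,
) -> float:
    """Brute-force patch SSD between ``center`` and ``center + offset``.

    Sums squared intensity differences over the full patch cube, with
    mirror padding outside the volume.  This is the oracle the
    moving-average path is checked against.
    """
    u = volume.data
    radii = _axis_radii(u.shape, patch_radius)
    pad = tuple(r + abs(o) for r, o in zip(radii, offset))
    p = np.pad(u, tuple((w, w) for w in pad), mode="reflect")
    c = tuple(ci + wi for ci, wi in zip(center, pad))
    a = p[tuple(slice(ci - r, ci + r + 1) for ci, r in zip(c, radii))]
    b = p[
        tuple(
            slice(ci + o - r, ci + o + r + 1)
            for ci, o, r in zip(c, offset, radii)
        )
    ]
    if counter is not None:
        counter.add(a.size)
    return float(((a - b) ** 2).sum())


def _sliding_sum(a: np.ndarray, window: int, axis: int) -> np.ndarray:
    """Box sum of length ``window`` along ``axis`` (output trimmed to valid)."""
    if window == 1:
        return a
    c = np.cumsum(a, axis=axis, dtype=np.float64)
    n = a.shape[axis]
    out = np.take(c, np.arange(window - 1, n), axis=axis).copy()
    sl = (slice(None),) * axis + (slice(1, None),)
    out[sl] -= np.take(c, np.arange(0, n - window), axis=axis)
    return out


def _offset_ssd_maps(
    volume: Volume,
    params: NLMParams,
    counter: OpCounter | None = None,
) -> Iterator[tuple[tuple[int, int, int], np.ndarray]]:
    """Yield ``(offset, ssd_map)`` for every search offset.

    ``ssd_map`` has the volume's shape and holds, per center voxel, the
    patch SSD at that offset.  Per offset the y/z patch extents are
    aggregated into per-x-slice cross-section sums, and the x extent is
    then accumulated with the moving-average recursion: full cube at the
    row start, one arriving and one departing slice per subsequent
    center.
    """
    u = volume.data
    nz, ny, nx = u.shape
    prz, pry, prx = _axis_radii(u.shape, params.patch_radius)
    srz, sry, srx = _axis_radii(u.shape, params.search_radius)
    pad = (prz + srz, pry + sry, prx + srx)
    padded = np.pad(u, tuple((w, w) for w in pad), mode="reflect")

    mz, my, mx = 2 * prz + 1, 2 * pry + 1, 2 * prx + 1
    slice_elems = mz * my  # voxels per x-slice of the patch cube
    lo = tuple(p - r for p, r in zip(pad, (prz, pry, prx)))
    hi = tuple(
        p + n + r for p, n, r in zip(pad, (nz, ny, nx), (prz, pry, prx))
    )
    core = padded[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]

    for dz in range(-srz, srz + 1):
        for dy in range(-sry, sry + 1):
            for dx in range(-srx, srx + 1):
                shifted = padded[
                    lo[0] + dz:hi[0] + dz,
                    lo[1] + dy:hi[1] + dy,
                    lo[2] + dx:hi[2] + dx,
                ]
                d2 = core - shifted
                np.square(d2, out=d2)
                # aggregate the patch's y/z extents -> per-x-slice sums
                cross = _sliding_sum(_sliding_sum(d2, mz, 0), my, 1)
                # moving-average recursion along x, re-init per row
                ssd = np.empty((nz, ny, nx), dtype=np.float64)
                s = cross[:, :, :mx].sum(axis=2)
                ssd[:, :, 0] = s
                if counter is not None:
                    counter.add(nz * ny * mx * slice_elems)
                    counter.rows += nz * ny
                for x in range(1, nx):
                    s = s + cross[:, :, x + mx - 1] - cross[:, :, x - 1]
                    ssd[:, :, x] = s
                    if counter is not None:
                        counter.add(nz * ny * 2 * slice_elems)
                # guard against -0.0 / tiny negative from cancellation
                np.maximum(ssd, 0.0, out=ssd)
                yield (dz, dy, dx), ssd


def ssd_map_maf(
    volume: Volume,
    params: NLMParams,
    counter: OpCounter | None = None,
) -> Iterator[SSDField]:
    """Stream one :class:`SSDField` per voxel, computed via the MAF path.

    Materializes all per-offset SSD maps first (offset-major is the
    natural order of the recursion), then re-slices per center; intended
    for inspection and testing at small volume sizes.  :func:`denoise`
    consumes the offset-major stream directly and never materializes
    this.
    """
    u = volume.data
    srz, sry, srx = _axis_radii(u.shape, params.search_radius)
    wz, wy, wx = 2 * srz + 1, 2 * sry + 1, 2 * srx + 1
    full = np.empty((wz, wy, wx) + u.shape, dtype=np.float64)
    for (dz, dy, dx), ssd in _offset_ssd_maps(volume, params, counter):
        full[dz + srz, dy + sry, dx + srx] = ssd
    for z in range(u.shape[0]):
        for y in range(u.shape[1]):
            for x in range(u.shape[2]):
                yield SSDField(
                    center=(z, y, x),
                    values=full[:, :, :, z, y, x].copy(),
                    offsets_radius=params.search_radius,
                )


def nlm_weight(
    ssd: float | np.ndarray,
    h: float | np.ndarray,
    shape_p: float = 1.0,
) -> float | np.ndarray:
    """NLM weight ``exp(-(ssd/h²)^p)`` in [0, 1].

    ``shape_p = 1`` recovers the standard Gaussian kernel; larger ``p``
    sharpens the cut-off between similar and dissimilar patches (useful
    when the noise is not additive Gaussian white noise).
    """
    if np.any(np.asarray(h) <= 0):
        raise ContractError("smoothing parameter h must be > 0")
    ratio = np.asarray(ssd, dtype=np.float64) / np.square(
        np.asarray(h, dtype=np.float64)
    )
    if shape_p != 1.0:
        ratio = ratio**shape_p
    out = np.exp(-ratio)
    return float(out) if np.isscalar(ssd) else out


def _bandwidth_map(volume: Volume, params: NLMParams) -> tuple[np.ndarray, NoiseMap]:
    """Per-voxel bandwidth h from the blockwise (or global) noise map."""
    prz, pry, prx = _axis_radii(volume.shape, params.patch_radius)
    patch_voxels = (2 * prz + 1) * (2 * pry + 1) * (2 * prx + 1)
    block = params.block_size
    if block is None:
        block = max(volume.shape)  # single block: whole-volume estimate
    noise_map = estimate_noise_local(volume, block_size=max(4, block))
    sigma = noise_map.sigma_volume(volume.shape)
    floor = params.policy.h_min * (volume.gsv_levels / params.policy.gsv_ref)
    h = np.maximum(
        floor,
        np.sqrt(2.0 * params.policy.beta * patch_voxels) * sigma,
    )
    return h, noise_map


def denoise(
    volume: Volume,
    params: NLMParams | None = None,
    counter: OpCounter | None = None,
    return_noise_map: bool = False,
):
    """Denoise a volume with locally adaptive non-local means.

    The bandwidth is derived per voxel from the blockwise noise map, so
    no noise level needs to be supplied.  The self-weight of each voxel
    is set to the maximum weight among its other candidates (the standard
    convention; weight 1 would let the noisy voxel dominate its own
    average).  Output intensities are convex combinations of input
    intensities and are clipped to the input range to keep the bound
    exact under floating-point rounding; a constant volume is a fixed
    point, exactly.

    Returns the denoised :class:`~ctnlm.volio.Volume` (and the
    :class:`~ctnlm.noise.NoiseMap` if ``return_noise_map``).
    """
    if params is None:
        params = NLMParams()
    u = volume.data
    for n in u.shape:
        if 1 < n < params.patch_edge:
            raise ContractError(
                "volume too small for patch size "
                f"(axis {n} < patch edge {params.patch_edge})"
            )

    h, noise_map = _bandwidth_map(volume, params)
    h2 = np.square(h)
    p = params.policy.shape_p

    srz, sry, srx = _axis_radii(u.shape, params.search_radius)
    pad = (srz, sry, srx)
    padded = np.pad(u, tuple((w, w) for w in pad), mode="reflect")

    num = np.zeros(u.shape, dtype=np.float64)
    den = np.zeros(u.shape, dtype=np.float64)
    wmax = np.zeros(u.shape, dtype=np.float64)
    for (dz, dy, dx), ssd in _offset_ssd_maps(volume, params, counter):
        if dz == 0 and dy == 0 and dx == 0:
            continue
        ratio = ssd / h2
        if p != 1.0:
            ratio **= p
        w = np.exp(-ratio)
        v = padded[
            pad[0] + dz:pad[0] + dz + u.shape[0],
            pad[1] + dy:pad[1] + dy + u.shape[1],
            pad[2] + dx:pad[2] + dx + u.shape[2],
        ]
        num += w * (v - u)
        den += w
        np.maximum(wmax, w, out=wmax)

    # difference form: the self term contributes wmax·(u-u)=0 to the
    # numerator, so a constant volume maps to itself exactly
    out = u + num / (den + wmax)
    np.clip(out, u.min(), u.max(), out=out)
    result = volume.with_data(out)
    result.provenance = (volume.provenance + " +nlm").strip()
    if return_noise_map:
        return result, noise_map
    return result
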