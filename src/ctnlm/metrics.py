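"""Denoising evaluation: line profiles, fidelity metrics, op-count model.

The field's routine qualitative check for denoising is the grayscale
line profile: intensities sampled along a segment through the volume,
whose spread about the local anatomy shrinks when noise is removed.
``profile_variability`` turns that visual check into a number — the
standard deviation of the profile about its moving median, so structural
edges do not count as noise.  PSNR against a known clean reference backs
this up on phantoms, and ``count_difference_ops`` evaluates the
difference-operation cost model of the naive versus moving-average SSD
paths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates, median_filter

from .errors import ContractError, ValidationError
from .volio import Volume

__all__ = [
    "LineProfile",
    "OpCountQuery",
    "line_profile",
    "profile_variability",
    "psnr",
    "count_difference_ops",
]


@dataclass(frozen=True)
class LineProfile:
    """Intensities sampled along a segment through a volume.

    ``positions`` is arc length in voxel units (index space), strictly
    increasing, with one entry per sample; endpoints are included.
    """

    start: tuple[float, float, float]
    end: tuple[float, float, float]
    n_samples: int
    positions: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        if len(self.positions) != self.n_samples:
            raise ValidationError("positions length must equal n_samples")
        if np.any(np.diff(self.positions) <= 0):
            raise ValidationError("positions must be strictly increasing")


@dataclass(frozen=True)
class OpCountQuery:
    """Inputs of the SSD difference-operation cost model.

    ``M`` is the patch edge length in voxels (so ``M**3`` is the patch
    voxel count) and ``N`` the number of SSD evaluations along the
    sliding traversal.
    """

    M: int
    N: int

    def __post_init__(self) -> None:
        if self.M < 1 or self.M % 2 == 0:
            raise ValidationError("M must be odd and >= 1")
        if self.N < 1:
            raise ValidationError("N must be >= 1")


def line_profile(
    volume: Volume,
    start: tuple[float, float, float],
    end: tuple[float, float, float],
    n_samples: int = 100,
) -> LineProfile:
    """Sample intensities at equally spaced points from start to end.

    Coordinates are (z, y, x) in voxel index space; sampling is
    trilinear.  Endpoints must lie inside the volume.
    """
    if n_samples < 2:
        raise ContractError("n_samples must be >= 2")
    start = tuple(float(c) for c in start)
    end = tuple(float(c) for c in end)
    for pt in (start, end):
        for c, n in zip(pt, volume.shape):
            if not (0 <= c <= n - 1):
                raise ContractError(f"endpoint {pt} outside volume of shape {volume.shape}")
    t = np.linspace(0.0, 1.0, n_samples)
    coords = np.stack(
        [s + t * (e - s) for s, e in zip(start, end)], axis=0
    )
    intensities = map_coordinates(volume.data, coords, order=1, mode="nearest")
    length = math.dist(start, end)
    return LineProfile(
        start=start,
        end=end,
        n_samples=n_samples,
        positions=t * length if length > 0 else np.arange(n_samples, dtype=float),
        intensities=intensities,
    )


def profile_variability(profile: LineProfile, detrend_window: int = 9) -> float:
    """Spread of a profile about its local structure.

    Standard deviation of (intensities − moving median over
    ``detrend_window`` samples).  The moving median tracks anatomy
    (plateaus, ramps, edges) so what remains is noise; a denoised scan
    shows a strictly smaller value along the same segment.
    """
    if detrend_window % 2 == 0 or detrend_window < 3:
        raise ContractError("detrend_window must be odd and >= 3")
    if detrend_window > profile.n_samples:
        raise ContractError("detrend_window must be <= n_samples")
    trend = median_filter(profile.intensities, size=detrend_window, mode="nearest")
    return float(np.std(profile.intensities - trend))


def psnr(reference: Volume, test: Volume, peak: float | None = None) -> float:
    """Peak signal-to-noise ratio 10·log10(peak²/MSE) in dB.

    ``peak`` defaults to ``gsv_levels − 1`` of the reference.  Identical
    volumes give +infinity.
    """
    if reference.shape != test.shape:
        raise ContractError(
            f"shape mismatch: {reference.shape} vs {test.shape}"
        )
    if peak is None:
        peak = float(reference.gsv_levels - 1)
    if peak <= 0:
        raise ContractError("peak must be > 0")
    mse = float(np.mean((reference.data - test.data) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(peak**2 / mse)


def count_difference_ops(query: OpCountQuery, method: str) -> int:
    """Difference-operation count of one sliding SSD traversal.

    ``naive`` resums every patch: N·M³ operations.  ``maf`` sums the
    first patch cube and then updates incrementally with the two end
    slices: M³ + (N−1)·2·M².  Exact integer arithmetic.
    """
    m, n = query.M, query.N
    if method == "naive":
        return n * m**3
    if method == "maf":
        return m**3 + (n - 1) * 2 * m**2
    raise ValidationError(f"unknown method {method!r}; use 'naive' or 'maf'")
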