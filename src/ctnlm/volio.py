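"""Volume container and 3D volume I/O.

Micro-CT pipelines produce volumes in scanner-dependent formats: in vivo
systems typically emit DICOM series (one single-frame file per slice),
high-resolution ex vivo systems emit netCDF files, and multi-page TIFF
stacks serve as a light interchange format for fixtures and QC.  This
module normalizes all three into one internal representation.

Conventions
-----------
* Axis order is ``(z, y, x)`` with the slice axis first; every offset in
  the package is documented in this order.
* Intensities are held as ``float64`` regardless of the source bit depth;
  the source's representable-level count is preserved as ``gsv_levels``
  (256 for 8-bit, 65536 for 16-bit) because the automatic smoothing
  parameter depends on it.
* Voxel spacing is carried in micrometres per voxel edge.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ValidationError, VolumeIOError

logger = logging.getLogger(__name__)

__all__ = [
    "Volume",
    "read_dicom_series",
    "write_dicom_series",
    "read_netcdf",
    "write_netcdf",
    "read_tiff_stack",
    "write_tiff_stack",
    "read_volume",
    "write_volume",
]


@dataclass
class Volume:
    """A 3D scalar intensity grid with voxel spacing and intensity metadata.

    Parameters
    ----------
    data
        3D array of intensities, axis order ``(z, y, x)``.  Stored as
        ``float64`` internally whatever the input dtype.
    spacing_um
        Voxel edge length per axis ``(dz, dy, dx)`` in micrometres.
    gsv_levels
        Number of representable gray-scale values of the source (e.g. 256
        for 8-bit data); feeds the smoothing-parameter floor.
    provenance
        Free-text tag describing where the volume came from.
    """

    data: np.ndarray
    spacing_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    gsv_levels: int = 256
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValidationError(
                f"volume data must be 3D, got ndim={self.data.ndim}"
            )
        if min(self.data.shape) < 1:
            raise ValidationError("volume shape entries must all be >= 1")
        self.spacing_um = tuple(float(s) for s in self.spacing_um)
        if len(self.spacing_um) != 3 or any(s <= 0 for s in self.spacing_um):
            raise ValidationError("spacing_um entries must all be > 0")
        self.gsv_levels = int(self.gsv_levels)
        if self.gsv_levels < 2:
            raise ValidationError("gsv_levels must be >= 2")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("volume intensities must all be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "Volume":
        """Copy of this volume with new intensities, metadata unchanged."""
        return replace(self, data=np.asarray(data, dtype=np.float64))


def _levels_to_bits(gsv_levels: int) -> int:
    return max(1, math.ceil(math.log2(gsv_levels)))


def _quantize(data: np.ndarray, bits: int) -> tuple[np.ndarray, float, float]:
    """Map ``data`` onto unsigned integers of ``bits`` bits.

    Returns ``(stored, slope, intercept)`` with
    ``value = slope * stored + intercept``.  Data already integral and in
    range passes through unscaled; anything else is affinely rescaled to
    use the full integer range, with a logged warning.
    """
    vmax_repr = 2**bits - 1
    dmin = float(data.min())
    dmax = float(data.max())
    integral = bool(np.all(data == np.round(data)))
    if integral and dmin >= 0 and dmax <= vmax_repr:
        return data.astype(np.uint32), 1.0, 0.0
    if dmax == dmin:
        return np.zeros(data.shape, dtype=np.uint32), 1.0, dmin
    slope = (dmax - dmin) / vmax_repr
    logger.warning(
        "intensities [%g, %g] not representable in %d bits; rescaling with "
        "slope=%g intercept=%g",
        dmin, dmax, bits, slope, dmin,
    )
    stored = np.round((data - dmin) / slope).astype(np.uint32)
    return stored, slope, dmin


# ---------------------------------------------------------------------------
# DICOM series
# ---------------------------------------------------------------------------

def write_dicom_series(volume: Volume, directory: str | Path) -> None:
    """Write ``volume`` as a single-frame DICOM series, one file per slice.

    Slices share a generated SeriesInstanceUID; positions run along +z at
    the volume's slice spacing.  Intensities that do not fit the target
    bit depth are encoded through RescaleSlope/RescaleIntercept, so the
    read-back reproduces them to within one quantization step.
    """
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - depends on fs permissions
        raise VolumeIOError(f"cannot create directory {directory}: {exc}") from exc

    bits = min(16, max(8, _levels_to_bits(volume.gsv_levels)))
    stored, slope, intercept = _quantize(volume.data, bits)
    stored16 = stored.astype(np.uint16)

    series_uid = generate_uid()
    study_uid = generate_uid()
    dz_mm, dy_mm, dx_mm = (s / 1000.0 for s in volume.spacing_um)
    nz = volume.shape[0]
    ndigits = len(str(nz))
    for i in range(nz):
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.SOPClassUID = ds.file_meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.InstanceNumber = i + 1
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [0.0, 0.0, i * dz_mm]
        ds.PixelSpacing = [dy_mm, dx_mm]
        ds.SliceThickness = dz_mm
        ds.SpacingBetweenSlices = dz_mm
        ds.Rows, ds.Columns = volume.shape[1], volume.shape[2]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = bits
        ds.HighBit = bits - 1
        ds.PixelRepresentation = 0
        ds.RescaleSlope = slope
        ds.RescaleIntercept = intercept
        ds.PixelData = stored16[i].tobytes()
        ds.save_as(
            directory / f"slice_{i:0{ndigits}d}.dcm", enforce_file_format=True
        )


def read_dicom_series(directory: str | Path) -> Volume:
    """Read a single-frame DICOM series from ``directory``.

    Slices are sorted by the projection of ImagePositionPatient onto the
    slice normal (ties broken by InstanceNumber), rescale slope/intercept
    are applied, and ``gsv_levels`` is set to ``2**BitsStored``.  Missing
    spacing attributes default to 1.0 with a logged warning.
    """
    import pydicom

    directory = Path(directory)
    if not directory.is_dir():
        raise VolumeIOError(f"no input: {directory} is not a directory")
    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            datasets.append(pydicom.dcmread(p))
        except Exception:
            continue  # non-DICOM files in the directory are ignored
    if not datasets:
        raise VolumeIOError(f"no input: no DICOM files found in {directory}")

    series_uids = {str(ds.get("SeriesInstanceUID", "")) for ds in datasets}
    if len(series_uids) != 1:
        raise VolumeIOError(
            f"inconsistent series: found {len(series_uids)} series identifiers"
        )

    def sort_key(ds):
        orient = ds.get("ImageOrientationPatient")
        pos = ds.get("ImagePositionPatient")
        instance = int(ds.get("InstanceNumber", 0))
        if orient is not None and pos is not None:
            row = np.asarray(orient[:3], dtype=float)
            col = np.asarray(orient[3:], dtype=float)
            normal = np.cross(row, col)
            return (float(np.dot(normal, np.asarray(pos, dtype=float))), instance)
        return (0.0, instance)

    datasets.sort(key=sort_key)

    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(ds.get("RescaleSlope", 1.0))
        intercept = float(ds.get("RescaleIntercept", 0.0))
        slices.append(slope * arr + intercept)
    data = np.stack(slices, axis=0)

    first = datasets[0]
    pixel_spacing = first.get("PixelSpacing")
    if pixel_spacing is not None:
        dy_um = float(pixel_spacing[0]) * 1000.0
        dx_um = float(pixel_spacing[1]) * 1000.0
    else:
        logger.warning("PixelSpacing missing; in-plane spacing defaults to 1.0")
        dy_um = dx_um = 1.0
    dz_um = None
    if len(datasets) >= 2:
        z0, z1 = sort_key(datasets[0])[0], sort_key(datasets[1])[0]
        if z1 != z0:
            dz_um = abs(z1 - z0) * 1000.0
    if dz_um is None:
        between = first.get("SpacingBetweenSlices", first.get("SliceThickness"))
        if between is not None:
            dz_um = float(between) * 1000.0
        else:
            logger.warning("slice spacing missing; defaults to 1.0")
            dz_um = 1.0

    bits = int(first.get("BitsStored", first.get("BitsAllocated", 16)))
    return Volume(
        data=data,
        spacing_um=(dz_um, dy_um, dx_um),
        gsv_levels=2**bits,
        provenance=f"dicom:{directory}",
    )


# ---------------------------------------------------------------------------
# netCDF
# ---------------------------------------------------------------------------

_NC_VARIABLE = "volume"


def write_netcdf(volume: Volume, path: str | Path) -> None:
    """Write ``volume`` as a classic netCDF file.

    The intensity grid is stored as a double variable named ``volume``
    over dimensions ``(z, y, x)``; per-axis coordinate variables hold
    voxel-centre positions in micrometres, from which spacing is
    recovered on read.
    """
    from scipy.io import netcdf_file

    path = Path(path)
    try:
        f = netcdf_file(str(path), "w")
    except OSError as exc:
        raise VolumeIOError(f"cannot write {path}: {exc}") from exc
    try:
        nz, ny, nx = volume.shape
        for name, n, d in zip("zyx", (nz, ny, nx), volume.spacing_um):
            f.createDimension(name, n)
            coord = f.createVariable(name, "d", (name,))
            coord[:] = np.arange(n, dtype=np.float64) * d
            coord.units = b"micrometre"
        var = f.createVariable(_NC_VARIABLE, "d", ("z", "y", "x"))
        var[:, :, :] = volume.data
        f.gsv_levels = np.int32(volume.gsv_levels)
        f.provenance = volume.provenance.encode()
    finally:
        f.close()


def read_netcdf(path: str | Path, variable: str | None = None) -> Volume:
    """Read a 3D variable from a classic netCDF file.

    If ``variable`` is not given, the file must contain exactly one 3D
    variable; spacing is taken from per-dimension coordinate variables
    when present, else 1.0.
    """
    from scipy.io import netcdf_file

    path = Path(path)
    try:
        f = netcdf_file(str(path), "r", mmap=False)
    except OSError as exc:
        raise VolumeIOError(f"cannot read {path}: {exc}") from exc
    try:
        three_d = {
            name: var
            for name, var in f.variables.items()
            if var.data.ndim == 3
        }
        if variable is not None:
            if variable not in three_d:
                raise VolumeIOError(
                    f"no volume found: variable {variable!r} absent or not 3D"
                )
            var = three_d[variable]
        elif len(three_d) == 0:
            raise VolumeIOError("no volume found: file has no 3D variable")
        elif len(three_d) > 1:
            raise VolumeIOError(
                "ambiguous variable: file has "
                f"{len(three_d)} 3D variables ({sorted(three_d)}); pass a name"
            )
        else:
            (var,) = three_d.values()

        data = np.array(var.data, dtype=np.float64)
        spacing = []
        for dim in var.dimensions:
            coord = f.variables.get(dim)
            if coord is not None and coord.data.ndim == 1 and coord.data.size >= 2:
                spacing.append(float(coord.data[1] - coord.data[0]))
            else:
                spacing.append(1.0)
        gsv = getattr(f, "gsv_levels", None)
        if gsv is None:
            gsv = 65536
        return Volume(
            data=data,
            spacing_um=tuple(spacing),
            gsv_levels=int(gsv),
            provenance=f"netcdf:{path}",
        )
    finally:
        f.close()


# ---------------------------------------------------------------------------
# TIFF stacks
# ---------------------------------------------------------------------------

def write_tiff_stack(volume: Volume, path: str | Path) -> None:
    """Write ``volume`` as a multi-page grayscale TIFF.

    The sample format follows ``gsv_levels`` (uint8 up to 256 levels,
    uint16 beyond); out-of-range or non-integral data is rescaled with a
    logged warning.  Spacing and gsv metadata ride along in the image
    description as JSON.
    """
    import tifffile

    path = Path(path)
    bits = 8 if volume.gsv_levels <= 256 else 16
    stored, slope, intercept = _quantize(volume.data, bits)
    dtype = np.uint8 if bits == 8 else np.uint16
    description = json.dumps(
        {
            "spacing_um": list(volume.spacing_um),
            "gsv_levels": volume.gsv_levels,
            "rescale_slope": slope,
            "rescale_intercept": intercept,
        }
    )
    try:
        tifffile.imwrite(
            str(path),
            stored.astype(dtype),
            photometric="minisblack",
            description=description,
        )
    except OSError as exc:
        raise VolumeIOError(f"cannot write {path}: {exc}") from exc


def read_tiff_stack(path: str | Path) -> Volume:
    """Read a multi-page grayscale TIFF; page *i* becomes slice *i*.

    ``gsv_levels`` is derived from the sample bit depth.  RGB input is
    rejected.  Stored values are returned as-is (the writer's rescale, if
    any, is recorded in the description but deliberately not undone).
    """
    import tifffile

    path = Path(path)
    try:
        with tifffile.TiffFile(str(path)) as tf:
            page = tf.pages[0]
            if page.photometric not in (
                tifffile.PHOTOMETRIC.MINISBLACK,
                tifffile.PHOTOMETRIC.MINISWHITE,
            ):
                raise VolumeIOError(
                    "unsupported photometric interpretation: "
                    f"{page.photometric.name}"
                )
            data = tf.asarray()
            description = page.description
    except FileNotFoundError as exc:
        raise VolumeIOError(f"no input: {path}") from exc
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim != 3:
        raise VolumeIOError(
            f"unsupported TIFF layout: expected grayscale pages, got shape {data.shape}"
        )

    spacing = (1.0, 1.0, 1.0)
    gsv = None
    if description:
        try:
            meta = json.loads(description)
            spacing = tuple(meta.get("spacing_um", spacing))
            gsv = meta.get("gsv_levels")
        except (json.JSONDecodeError, TypeError):
            pass
    if gsv is None:
        itemsize = data.dtype.itemsize
        gsv = 256 if itemsize == 1 else 65536
    return Volume(
        data=data.astype(np.float64),
        spacing_um=spacing,
        gsv_levels=int(gsv),
        provenance=f"tiff:{path}",
    )


# ---------------------------------------------------------------------------
# Format dispatch
# ---------------------------------------------------------------------------

_READERS = {
    "dicom": read_dicom_series,
    "netcdf": read_netcdf,
    "tiff": read_tiff_stack,
}
_WRITERS = {
    "dicom": write_dicom_series,
    "netcdf": write_netcdf,
    "tiff": write_tiff_stack,
}


def detect_format(path: str | Path) -> str:
    """Guess a volume format from a path: directory → DICOM, else extension."""
    path = Path(path)
    if path.is_dir() or path.suffix.lower() in {".dcm", ""}:
        return "dicom"
    suffix = path.suffix.lower()
    if suffix in {".nc", ".cdf", ".netcdf"}:
        return "netcdf"
    if suffix in {".tif", ".tiff"}:
        return "tiff"
    raise ValidationError(f"cannot detect volume format from path {path}")


def read_volume(path: str | Path, fmt: str | None = None) -> Volume:
    """Read a volume, auto-detecting the format unless ``fmt`` is given."""
    fmt = fmt or detect_format(path)
    if fmt not in _READERS:
        raise ValidationError(f"unknown volume format {fmt!r}")
    return _READERS[fmt](path)


def write_volume(volume: Volume, path: str | Path, fmt: str | None = None) -> None:
    """Write a volume, auto-detecting the format unless ``fmt`` is given."""
    fmt = fmt or detect_format(path)
    if fmt not in _WRITERS:
        raise ValidationError(f"unknown volume format {fmt!r}")
    _WRITERS[fmt](volume, path)
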