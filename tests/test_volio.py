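"""Volume container invariants and format round trips."""

import logging

import numpy as np
import pytest

from ctnlm import ValidationError, Volume, VolumeIOError
from ctnlm.volio import (
    detect_format,
    read_dicom_series,
    read_netcdf,
    read_tiff_stack,
    write_dicom_series,
    write_netcdf,
    write_tiff_stack,
)


def _volume(rng, shape=(4, 5, 6), spacing=(10.7, 10.7, 10.7), gsv=256):
    data = rng.integers(0, gsv, shape).astype(np.float64)
    return Volume(data, spacing_um=spacing, gsv_levels=gsv)


class TestVolumeType:
    def test_rejects_non_3d(self):
        with pytest.raises(ValidationError):
            Volume(np.zeros((4, 4)))

    def test_rejects_bad_spacing(self):
        with pytest.raises(ValidationError):
            Volume(np.zeros((2, 2, 2)), spacing_um=(0.0, 1.0, 1.0))

    def test_rejects_nonfinite(self):
        data = np.zeros((2, 2, 2))
        data[0, 0, 0] = np.nan
        with pytest.raises(ValidationError):
            Volume(data)

    def test_rejects_degenerate_gsv(self):
        with pytest.raises(ValidationError):
            Volume(np.zeros((2, 2, 2)), gsv_levels=1)

    def test_data_held_as_float(self):
        v = Volume(np.ones((2, 2, 2), dtype=np.uint16))
        assert v.data.dtype == np.float64


@pytest.mark.parametrize(
    "write,read,suffix",
    [
        (write_dicom_series, read_dicom_series, "series"),
        (write_netcdf, read_netcdf, "v.nc"),
        (write_tiff_stack, read_tiff_stack, "v.tif"),
    ],
    ids=["dicom", "netcdf", "tiff"],
)
class TestRoundTrips:
    def test_data_shape_spacing_round_trip(self, tmp_path, rng, write, read, suffix):
        # spacing fixed at the ex vivo scanner's 10.7 um/voxel resolution
        v = _volume(rng)
        path = tmp_path / suffix
        write(v, path)
        r = read(path)
        assert np.array_equal(r.data, v.data)
        assert r.shape == v.shape
        assert r.spacing_um == pytest.approx(v.spacing_um)
        assert r.gsv_levels == v.gsv_levels

    def test_second_cycle_is_stable(self, tmp_path, rng, write, read, suffix):
        # after one write/read cycle, further cycles reproduce data exactly
        v = Volume(rng.normal(500.0, 100.0, (3, 4, 4)), gsv_levels=65536)
        first = tmp_path / f"a_{suffix}"
        second = tmp_path / f"b_{suffix}"
        write(v, first)
        r1 = read(first)
        write(r1, second)
        r2 = read(second)
        assert np.array_equal(r2.data, r1.data)

    def test_reading_does_not_mutate(self, tmp_path, rng, write, read, suffix):
        v = _volume(rng)
        path = tmp_path / suffix
        write(v, path)
        files = sorted(path.iterdir()) if path.is_dir() else [path]
        before = [f.read_bytes() for f in files]
        read(path)
        assert [f.read_bytes() for f in files] == before


class TestDicom:
    def test_rescale_slope_intercept_applied(self, tmp_path):
        # stored 100 with slope 2, intercept -1000 -> output -800
        import pydicom
        from pydicom.dataset import Dataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, generate_uid

        series = generate_uid()
        d = tmp_path / "series"
        d.mkdir()
        for i in range(3):
            ds = Dataset()
            ds.file_meta = FileMetaDataset()
            ds.file_meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
            ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
            ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
            ds.SOPClassUID = ds.file_meta.MediaStorageSOPClassUID
            ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
            ds.SeriesInstanceUID = series
            ds.InstanceNumber = i + 1
            ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
            ds.ImagePositionPatient = [0.0, 0.0, float(i)]
            ds.PixelSpacing = [1.0, 1.0]
            ds.Rows = ds.Columns = 4
            ds.SamplesPerPixel = 1
            ds.PhotometricInterpretation = "MONOCHROME2"
            ds.BitsAllocated = ds.BitsStored = 16
            ds.HighBit = 15
            ds.PixelRepresentation = 0
            ds.RescaleSlope = 2.0
            ds.RescaleIntercept = -1000.0
            ds.PixelData = np.full((4, 4), 100, dtype=np.uint16).tobytes()
            ds.save_as(d / f"s{i}.dcm", enforce_file_format=True)
        v = read_dicom_series(d)
        assert np.all(v.data == -800.0)

    def test_slices_sorted_by_position(self, tmp_path, rng):
        # files written in lexical order with z positions 2, 0, 1 must come
        # back ascending in z
        v = Volume(
            np.stack([np.full((3, 3), val) for val in (20.0, 0.0, 10.0)])
        )
        d = tmp_path / "series"
        write_dicom_series(v, d)
        files = sorted(d.iterdir())
        import pydicom

        for f, z in zip(files, (2.0, 0.0, 1.0)):
            ds = pydicom.dcmread(f)
            ds.ImagePositionPatient = [0.0, 0.0, z]
            ds.save_as(f, enforce_file_format=True)
        r = read_dicom_series(d)
        assert [r.data[i, 0, 0] for i in range(3)] == [0.0, 10.0, 20.0]
        # slice spacing recomputed from the rewritten positions (1 mm apart)
        assert r.spacing_um[0] == pytest.approx(1000.0)
        assert r.spacing_um[1:] == pytest.approx((1.0, 1.0))

    def test_empty_directory_is_no_input(self, tmp_path):
        empty = tmp_path / "empty"
        empty.mkdir()
        with pytest.raises(VolumeIOError, match="no input"):
            read_dicom_series(empty)

    def test_mixed_series_rejected(self, tmp_path, rng):
        d = tmp_path / "series"
        write_dicom_series(_volume(rng, shape=(2, 3, 3)), d)
        import pydicom
        from pydicom.uid import generate_uid

        f = sorted(d.iterdir())[0]
        ds = pydicom.dcmread(f)
        ds.SeriesInstanceUID = generate_uid()
        ds.save_as(f, enforce_file_format=True)
        with pytest.raises(VolumeIOError, match="inconsistent series"):
            read_dicom_series(d)

    def test_gsv_levels_from_bits_stored(self, tmp_path, rng):
        d = tmp_path / "series"
        write_dicom_series(_volume(rng, gsv=65536), d)
        assert read_dicom_series(d).gsv_levels == 65536

    def test_float_data_rescaled_with_warning(self, tmp_path, rng, caplog):
        v = Volume(rng.normal(1e6, 1e5, (2, 3, 3)), gsv_levels=65536)
        with caplog.at_level(logging.WARNING, logger="ctnlm.volio"):
            write_dicom_series(v, tmp_path / "series")
        assert any("rescal" in rec.message for rec in caplog.records)
        r = read_dicom_series(tmp_path / "series")
        step = (v.data.max() - v.data.min()) / 65535
        assert np.abs(r.data - v.data).max() <= step / 2 + 1e-6


class TestNetcdf:
    def test_shape_passthrough(self, tmp_path, rng):
        v = _volume(rng, shape=(4, 5, 6))
        write_netcdf(v, tmp_path / "v.nc")
        assert read_netcdf(tmp_path / "v.nc").shape == (4, 5, 6)

    def test_two_3d_variables_ambiguous(self, tmp_path):
        from scipy.io import netcdf_file

        with netcdf_file(str(tmp_path / "two.nc"), "w") as f:
            f.createDimension("z", 2)
            f.createDimension("y", 2)
            f.createDimension("x", 2)
            for name in ("a", "b"):
                var = f.createVariable(name, "d", ("z", "y", "x"))
                var[:] = np.zeros((2, 2, 2))
        with pytest.raises(VolumeIOError, match="ambiguous variable"):
            read_netcdf(tmp_path / "two.nc")
        # explicit name disambiguates
        assert read_netcdf(tmp_path / "two.nc", variable="a").shape == (2, 2, 2)

    def test_no_3d_variable(self, tmp_path):
        from scipy.io import netcdf_file

        with netcdf_file(str(tmp_path / "flat.nc"), "w") as f:
            f.createDimension("x", 4)
            var = f.createVariable("line", "d", ("x",))
            var[:] = np.arange(4.0)
        with pytest.raises(VolumeIOError, match="no volume found"):
            read_netcdf(tmp_path / "flat.nc")


class TestTiff:
    def test_8bit_stack(self, tmp_path, rng):
        v = _volume(rng, shape=(5, 16, 16), gsv=256)
        write_tiff_stack(v, tmp_path / "v.tif")
        r = read_tiff_stack(tmp_path / "v.tif")
        assert r.shape == (5, 16, 16)
        assert r.gsv_levels == 256

    def test_16bit_stack(self, tmp_path, rng):
        v = _volume(rng, shape=(2, 4, 4), gsv=65536)
        write_tiff_stack(v, tmp_path / "v.tif")
        assert read_tiff_stack(tmp_path / "v.tif").gsv_levels == 65536

    def test_plain_16bit_file_infers_gsv(self, tmp_path, rng):
        import tifffile

        tifffile.imwrite(
            str(tmp_path / "raw.tif"),
            rng.integers(0, 1000, (3, 8, 8)).astype(np.uint16),
            photometric="minisblack",
        )
        assert read_tiff_stack(tmp_path / "raw.tif").gsv_levels == 65536

    def test_rgb_rejected(self, tmp_path, rng):
        import tifffile

        tifffile.imwrite(
            str(tmp_path / "rgb.tif"),
            rng.integers(0, 255, (4, 4, 3)).astype(np.uint8),
            photometric="rgb",
        )
        with pytest.raises(VolumeIOError, match="photometric"):
            read_tiff_stack(tmp_path / "rgb.tif")


def test_format_detection(tmp_path):
    assert detect_format("stack.tiff") == "tiff"
    assert detect_format("scan.nc") == "netcdf"
    d = tmp_path / "series"
    d.mkdir()
    assert detect_format(d) == "dicom"
    with pytest.raises(ValidationError):
        detect_format("scan.jpg")
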