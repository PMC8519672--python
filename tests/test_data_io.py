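"""Readers, writers, windowing and triplet construction."""

import numpy as np
import nibabel as nib
import pydicom
import pytest
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

from liverseg import data_io
from liverseg.data_io import (
    CTVolume,
    WindowSpec,
    make_triplets,
    read_dicom_series,
    read_nifti_volume,
    window_normalize,
    write_mask,
    write_volume,
)


# ----------------------------------------------------------------- NIfTI I/O
def test_nifti_round_trip_preserves_array_and_shape(tmp_path):
    voxels = np.arange(8 * 32 * 32, dtype=float).reshape(8, 32, 32)
    write_volume(CTVolume(voxels), tmp_path / "volume-0.nii")
    back = read_nifti_volume(tmp_path / "volume-0.nii")
    assert back.shape == (8, 32, 32)
    assert np.allclose(back.voxels, voxels)


def test_nifti_4d_input_raises_shape_error(tmp_path):
    img = nib.Nifti1Image(np.zeros((4, 4, 4, 2)), np.eye(4))
    nib.save(img, str(tmp_path / "fourd.nii"))
    with pytest.raises(ValueError, match="3-d"):
        read_nifti_volume(tmp_path / "fourd.nii")


def test_nifti_missing_file_raises_io_error(tmp_path):
    with pytest.raises(IOError):
        read_nifti_volume(tmp_path / "absent.nii")


def test_mask_round_trip_is_exact_and_affine_preserved(tmp_path):
    rng = np.random.default_rng(0)
    reference = CTVolume(rng.normal(size=(5, 8, 8)), spacing=(2.5, 0.7, 0.7))
    mask = (rng.random((5, 8, 8)) > 0.6).astype(np.uint8)
    write_mask(mask, reference, tmp_path / "segmentation-0.nii")
    back = read_nifti_volume(tmp_path / "segmentation-0.nii")
    assert np.array_equal(back.voxels.astype(np.uint8), mask)
    assert np.allclose(back.affine, reference.affine)


def test_mask_writer_thresholds_soft_input(tmp_path, caplog):
    reference = CTVolume(np.zeros((2, 4, 4)))
    soft = np.full((2, 4, 4), 0.7)
    with caplog.at_level("WARNING"):
        write_mask(soft, reference, tmp_path / "segmentation-0.nii")
    assert any("thresholded" in r.message for r in caplog.records)
    back = read_nifti_volume(tmp_path / "segmentation-0.nii")
    assert np.array_equal(back.voxels, np.ones((2, 4, 4)))


def test_mask_writer_rejects_shape_mismatch(tmp_path):
    with pytest.raises(ValueError, match="shape"):
        write_mask(np.zeros((2, 3, 3)), CTVolume(np.zeros((2, 4, 4))),
                   tmp_path / "m.nii")


# ----------------------------------------------------------------- DICOM I/O
def _write_dicom_slice(path, pixels, *, series_uid, z, instance, slope=1.0,
                       intercept=0.0):
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.SeriesInstanceUID = series_uid
    ds.InstanceNumber = instance
    ds.ImagePositionPatient = [0.0, 0.0, float(z)]
    ds.ImageOrientationPatient = [1.0, 0.0, 0.0, 0.0, 1.0, 0.0]
    ds.PixelSpacing = [0.8, 0.8]
    ds.RescaleSlope = slope
    ds.RescaleIntercept = intercept
    ds.Rows, ds.Columns = pixels.shape
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = pixels.astype(np.uint16).tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def test_dicom_series_sorted_by_position_not_filename(tmp_path):
    series = generate_uid()
    # shuffled filenames: file 'a' holds the topmost slice
    order = [(f"a.dcm", 4), ("b.dcm", 0), ("c.dcm", 2), ("d.dcm", 1), ("e.dcm", 3)]
    for name, z in order:
        pixels = np.full((4, 4), 100 * z, dtype=np.uint16)
        _write_dicom_slice(tmp_path / name, pixels, series_uid=series, z=z,
                           instance=z + 1)
    vol = read_dicom_series(tmp_path)
    assert vol.shape == (5, 4, 4)
    assert [int(vol.voxels[k, 0, 0]) for k in range(5)] == [0, 100, 200, 300, 400]
    assert vol.spacing == (1.0, 0.8, 0.8)


def test_dicom_rescale_slope_intercept_applied(tmp_path):
    series = generate_uid()
    pixels = np.full((4, 4), 600, dtype=np.uint16)
    _write_dicom_slice(tmp_path / "s.dcm", pixels, series_uid=series, z=0,
                       instance=1, slope=2.0, intercept=-1024.0)
    vol = read_dicom_series(tmp_path)
    assert np.all(vol.voxels == 176.0)  # 600*2 - 1024


def test_dicom_mixed_series_uids_rejected(tmp_path):
    for i in range(2):
        _write_dicom_slice(tmp_path / f"{i}.dcm", np.zeros((4, 4)),
                           series_uid=generate_uid(), z=i, instance=i + 1)
    with pytest.raises(ValueError, match="SeriesInstanceUID"):
        read_dicom_series(tmp_path)


def test_dicom_empty_directory_rejected(tmp_path):
    with pytest.raises(IOError, match="no .dcm"):
        read_dicom_series(tmp_path)


# ----------------------------------------------------------------- windowing
def test_window_endpoints_and_midpoint():
    window = WindowSpec(hu_min=-200.0, hu_max=250.0)
    vol = CTVolume(np.array([[[-200.0, 250.0, 25.0, -500.0, 1000.0]]]))
    out = window_normalize(vol, window).voxels[0, 0]
    assert out[0] == 0.0
    assert out[1] == 1.0
    assert out[2] == pytest.approx(0.5)  # (25 + 200) / 450
    assert out[3] == 0.0  # clipped below
    assert out[4] == 1.0  # clipped above


def test_window_monotone_and_idempotent(rng):
    values = np.sort(rng.normal(scale=300, size=64)).reshape(1, 8, 8)
    window = WindowSpec(-200, 250)
    out = window_normalize(CTVolume(values), window).voxels
    assert np.all(np.diff(out.reshape(-1)) >= 0)
    unit = WindowSpec(0.0, 1.0)
    again = window_normalize(window_normalize(CTVolume(values), window), unit).voxels
    assert np.allclose(again, out)


def test_invalid_window_rejected():
    with pytest.raises(ValueError):
        WindowSpec(hu_min=100.0, hu_max=100.0)


# ------------------------------------------------------------------ triplets
def test_make_triplets_count_edges_and_reconstruction(rng):
    voxels = rng.normal(size=(8, 6, 6))
    triplets = make_triplets(CTVolume(voxels))
    assert len(triplets) == 8
    # boundary replication
    assert np.array_equal(triplets[0].stack[0], voxels[0])
    assert np.array_equal(triplets[0].stack[2], voxels[1])
    assert np.array_equal(triplets[-1].stack[2], voxels[-1])
    # middle channels reconstruct the volume exactly
    rebuilt = np.stack([t.stack[1] for t in triplets])
    assert np.array_equal(rebuilt, voxels)
    assert [t.center_index for t in triplets] == list(range(8))


def test_load_dataset_reports_unpaired_files(tmp_path):
    write_volume(CTVolume(np.zeros((3, 4, 4))), tmp_path / "volume-0.nii")
    with pytest.raises(ValueError, match=r"\[0\]"):
        data_io.load_dataset(tmp_path)
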