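"""Volume I/O, intensity windowing, and 2.5D slice-triplet construction.

Axis convention throughout the package: arrays are ``(depth, height, width)``
with axial slices along axis 0.  NIfTI files store ``(x, y, z)``; readers
and writers transpose so that round trips are exact.  DICOM series are
sorted by the projection of each slice's patient position onto the slice
normal — never by filename.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom

logger = logging.getLogger(__name__)

__all__ = [
    "CTVolume",
    "SliceTriplet",
    "WindowSpec",
    "read_nifti_volume",
    "read_dicom_series",
    "write_volume",
    "write_mask",
    "window_normalize",
    "make_triplets",
    "load_dataset",
]


@dataclass
class CTVolume:
    """A 3-d scalar image: voxels (D, H, W), mm spacing, and a NIfTI affine."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"volume must be 3-d, got shape {self.voxels.shape}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite voxel values")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be positive, got {self.spacing}")
        if self.affine is None:
            sd, sh, sw = self.spacing
            # array axis (D,H,W) = (z,y,x); NIfTI stores (x,y,z)
            self.affine = np.diag([sw, sh, sd, 1.0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class SliceTriplet:
    """Three adjacent axial slices stacked as channels (z-1, z, z+1)."""

    stack: np.ndarray
    center_index: int

    def __post_init__(self):
        self.stack = np.asarray(self.stack)
        if self.stack.ndim != 3 or self.stack.shape[0] != 3:
            raise ValueError(f"triplet stack must be (3, H, W), got {self.stack.shape}")


@dataclass(frozen=True)
class WindowSpec:
    """Intensity window: clip to [hu_min, hu_max], map linearly to [0, 1].

    The default [-200, 250] HU is a common liver CT window.
    """

    hu_min: float = -200.0
    hu_max: float = 250.0

    def __post_init__(self):
        if not self.hu_min < self.hu_max:
            raise ValueError(f"require hu_min < hu_max, got {self.hu_min} >= {self.hu_max}")


# --------------------------------------------------------------------- NIfTI
def read_nifti_volume(path) -> CTVolume:
    """Read a NIfTI-1 volume, canonicalized to (depth, height, width)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    if img.ndim != 3:
        raise ValueError(f"expected a 3-d image, got {img.ndim}-d in {path}")
    data = np.asarray(img.get_fdata())
    voxels = data.transpose(2, 1, 0)  # (x,y,z) -> (z,y,x) = (D,H,W)
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return CTVolume(voxels=voxels, spacing=spacing, affine=np.asarray(img.affine))


def write_volume(vol: CTVolume, path) -> None:
    """Write a CTVolume to NIfTI, inverting the reader's axis transpose."""
    data = np.asarray(vol.voxels, dtype=np.float64).transpose(2, 1, 0)
    nib.save(nib.Nifti1Image(data, vol.affine), str(path))


def write_mask(mask, reference: CTVolume, path) -> None:
    """Write a binary mask with the reference volume's affine.

    Non-binary input is thresholded at 0.5 with a logged warning; output
    voxels are unsigned 8-bit {0, 1}.
    """
    mask = np.asarray(mask)
    if mask.shape != reference.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match reference {reference.shape}"
        )
    values = np.unique(mask)
    if not np.isin(values, (0, 1)).all():
        logger.warning("write_mask: non-binary input thresholded at 0.5")
        mask = (mask >= 0.5)
    data = mask.astype(np.uint8).transpose(2, 1, 0)
    nib.save(nib.Nifti1Image(data, reference.affine), str(path))


# --------------------------------------------------------------------- DICOM
def read_dicom_series(directory) -> CTVolume:
    """Read a single-frame DICOM series from ``directory``.

    Slices are ordered by image position projected onto the slice normal;
    rescale slope/intercept are applied to produce HU values.
    """
    directory = Path(directory)
    files = sorted(directory.glob("*.dcm")) if directory.is_dir() else []
    if not directory.is_dir():
        raise IOError(f"not a directory: {directory}")
    if not files:
        raise IOError(f"no .dcm files found in {directory}")
    datasets = [pydicom.dcmread(str(f)) for f in files]

    uids = {str(getattr(ds, "SeriesInstanceUID", "")) for ds in datasets}
    if len(uids) > 1:
        raise ValueError(f"mixed SeriesInstanceUIDs in {directory}: {sorted(uids)}")

    have_pos = all(
        hasattr(ds, "ImagePositionPatient") and hasattr(ds, "ImageOrientationPatient")
        for ds in datasets
    )
    if have_pos:
        iop = np.asarray(datasets[0].ImageOrientationPatient, dtype=float)
        normal = np.cross(iop[:3], iop[3:])
        positions = [
            float(np.dot(np.asarray(ds.ImagePositionPatient, dtype=float), normal))
            for ds in datasets
        ]
        order = np.argsort(positions)
    else:
        logger.warning(
            "read_dicom_series: missing position tags in %s; "
            "falling back to InstanceNumber ordering", directory
        )
        order = np.argsort([int(getattr(ds, "InstanceNumber", i))
                            for i, ds in enumerate(datasets)])
    datasets = [datasets[i] for i in order]

    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    voxels = np.stack(slices, axis=0)

    px = getattr(datasets[0], "PixelSpacing", [1.0, 1.0])
    if have_pos and len(datasets) > 1:
        positions = sorted(positions)
        dz = float(np.median(np.diff(positions)))
        dz = abs(dz) if dz != 0 else 1.0
    else:
        dz = float(getattr(datasets[0], "SliceThickness", 1.0) or 1.0)
    return CTVolume(voxels=voxels, spacing=(dz, float(px[0]), float(px[1])))


# ---------------------------------------------------------------- transforms
def window_normalize(vol: CTVolume, window: WindowSpec = WindowSpec()) -> CTVolume:
    """Clip to the window and map linearly onto [0, 1]."""
    clipped = np.clip(vol.voxels, window.hu_min, window.hu_max)
    scaled = (clipped - window.hu_min) / (window.hu_max - window.hu_min)
    return CTVolume(voxels=scaled, spacing=vol.spacing, affine=vol.affine)


def make_triplets(vol: CTVolume | np.ndarray) -> list[SliceTriplet]:
    """One triplet per axial slice; edge slices replicate their neighbor.

    The middle channel of triplet ``z`` is exactly slice ``z``, so stacking
    middle channels reconstructs the volume.
    """
    voxels = vol.voxels if isinstance(vol, CTVolume) else np.asarray(vol)
    if voxels.ndim != 3:
        raise ValueError(f"expected (D, H, W) voxels, got shape {voxels.shape}")
    padded = np.pad(voxels, ((1, 1), (0, 0), (0, 0)), mode="edge")
    return [
        SliceTriplet(stack=padded[z : z + 3].copy(), center_index=z)
        for z in range(voxels.shape[0])
    ]


# ------------------------------------------------------------------ datasets
def load_dataset(directory) -> list[tuple[int, CTVolume, np.ndarray]]:
    """Load LiTS-style ``volume-i.nii`` / ``segmentation-i.nii`` pairs.

    Returns ``(index, volume, mask)`` triples sorted by case index; raises
    if any volume lacks its segmentation (or vice versa).
    """
    directory = Path(directory)
    vols = {int(p.name.split("-")[1].split(".")[0]): p
            for p in directory.glob("volume-*.nii*")}
    segs = {int(p.name.split("-")[1].split(".")[0]): p
            for p in directory.glob("segmentation-*.nii*")}
    unpaired = sorted(set(vols) ^ set(segs))
    if unpaired:
        raise ValueError(f"unpaired case indices in {directory}: {unpaired}")
    if not vols:
        raise IOError(f"no volume-*.nii files found in {directory}")
    out = []
    for idx in sorted(vols):
        vol = read_nifti_volume(vols[idx])
        mask = read_nifti_volume(segs[idx]).voxels
        out.append((idx, vol, (mask >= 0.5).astype(np.uint8)))
    return out
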