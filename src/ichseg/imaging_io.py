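"""Reading and writing calibrated head-CT volumes and segmentation masks.

The package-wide axis convention is ``(slice, row, col)`` with 0-based
indices; spacing is ``(slice_thickness_mm, row_mm, col_mm)``.  CT voxels are
kept in Hounsfield units (HU) until :func:`apply_window` maps them through
the diagnostic brain window onto ``[0, 1]``.

NIfTI files written by this module store the array transposed to
``(col, row, slice)`` so the affine diagonal carries ``(col, row, slice)``
spacing; reading transposes back.  DICOM series are read slice-wise with the
stored rescale slope/intercept applied and slices sorted by physical
position along the scan axis.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import nibabel as nib
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .errors import InconsistentSeriesError, SeriesReadError, ValidationError

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .region_growing import SegmentationMask

#: tolerance (mm) for slice-to-slice spacing consistency in a series
SLICE_SPACING_TOL_MM = 1e-3


@dataclass(frozen=True)
class WindowSettings:
    """A CT display window: ``center`` and ``width`` in HU.

    Defaults are the standard brain window used for acute hemorrhage
    reading (width 100 HU, center 45 HU).
    """

    center: float = 45.0
    width: float = 100.0

    def __post_init__(self):
        if not self.width > 0:
            raise ValidationError(f"window width must be > 0, got {self.width}")

    @property
    def lower(self) -> float:
        return self.center - self.width / 2.0

    @property
    def upper(self) -> float:
        return self.center + self.width / 2.0


@dataclass
class CTVolume:
    """A 3-D CT grid in Hounsfield units.

    Attributes
    ----------
    voxels : ndarray, shape (n_slices, n_rows, n_cols)
        HU values, finite.
    spacing : (float, float, float)
        (slice thickness, row pitch, col pitch) in mm, all > 0.
    origin : (float, float, float)
        Physical offset in mm of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValidationError(
                f"CT volume must be 3-D (slice, row, col), got ndim={self.voxels.ndim}"
            )
        if self.voxels.shape[0] < 1:
            raise ValidationError("CT volume needs at least one slice")
        if any(not s > 0 for s in self.spacing):
            raise ValidationError(f"voxel spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValidationError("CT volume contains non-finite HU values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.spacing[0] * self.spacing[1] * self.spacing[2])


@dataclass
class NormalizedVolume:
    """A windowed CT volume with values in [0, 1].

    Bone saturates at 1.0 and air at 0.0 under the default window, a fact
    the parenchyma-extraction stage exploits.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    window: WindowSettings = field(default_factory=WindowSettings)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValidationError("normalized volume must be 3-D")
        if self.values.size and (self.values.min() < 0.0 or self.values.max() > 1.0):
            raise ValidationError("normalized values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.spacing[0] * self.spacing[1] * self.spacing[2])


def apply_window(vol: CTVolume, window: WindowSettings | None = None) -> NormalizedVolume:
    """Window a CT volume and map it linearly onto [0, 1].

    The display window and the 0-1 normalization compose into a single
    clamped linear map::

        value = clip((HU - (center - width/2)) / width, 0, 1)

    which is monotone non-decreasing in HU.
    """
    window = window or WindowSettings()
    values = np.clip((vol.voxels - window.lower) / window.width, 0.0, 1.0)
    return NormalizedVolume(values=values, spacing=vol.spacing, window=window)


def normalized_to_hu(vol: NormalizedVolume) -> CTVolume:
    """Re-express a normalized volume in HU (inverse of the window map on
    the non-clipped range)."""
    w = vol.window
    return CTVolume(voxels=vol.values * w.width + w.lower, spacing=vol.spacing)


# ---------------------------------------------------------------------------
# NIfTI read/write
# ---------------------------------------------------------------------------

def _affine(spacing: Sequence[float], origin: Sequence[float]) -> np.ndarray:
    aff = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
    aff[:3, 3] = [origin[2], origin[1], origin[0]]
    return aff


def write_volume(vol: CTVolume, path: str | os.PathLike) -> None:
    """Write a CT volume as NIfTI (HU preserved exactly via float64)."""
    img = nib.Nifti1Image(
        np.transpose(np.asarray(vol.voxels, dtype=np.float64), (2, 1, 0)),
        _affine(vol.spacing, vol.origin),
    )
    nib.save(img, os.fspath(path))


def read_nifti_volume(path: str | os.PathLike) -> CTVolume:
    img = nib.load(os.fspath(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 2:
        data = data[:, :, np.newaxis]
    if data.ndim != 3:
        raise ValidationError(f"expected a 3-D NIfTI volume, got ndim={data.ndim}")
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    origin = tuple(float(x) for x in img.affine[:3, 3][::-1])
    return CTVolume(voxels=np.transpose(data, (2, 1, 0)).astype(np.float64),
                    spacing=spacing, origin=origin)


def write_mask(mask: "SegmentationMask", path: str | os.PathLike,
               reference: CTVolume | NormalizedVolume | None = None) -> None:
    """Write a binary mask as a {0,1}-valued uint8 NIfTI.

    Geometry (spacing/origin) is copied from ``reference`` when given,
    otherwise taken from the mask's own spacing.
    """
    voxels = np.asarray(mask.voxels)
    if reference is not None and voxels.shape != reference.shape:
        raise ValidationError(
            f"mask shape {voxels.shape} does not match reference {reference.shape}"
        )
    spacing = reference.spacing if reference is not None else mask.spacing
    origin = getattr(reference, "origin", (0.0, 0.0, 0.0))
    img = nib.Nifti1Image(
        np.transpose((voxels > 0).astype(np.uint8), (2, 1, 0)),
        _affine(spacing, origin),
    )
    nib.save(img, os.fspath(path))


def read_mask(path: str | os.PathLike) -> "SegmentationMask":
    """Read a binary NIfTI mask written by :func:`write_mask` (or any
    {0,1}-valued NIfTI)."""
    from .region_growing import SegmentationMask

    vol = read_nifti_volume(path)
    return SegmentationMask(voxels=(vol.voxels > 0.5).astype(np.uint8),
                            spacing=vol.spacing, provenance="external")


# ---------------------------------------------------------------------------
# DICOM series
# ---------------------------------------------------------------------------

def read_dicom_series(path: str | os.PathLike) -> CTVolume:
    """Read a directory of single-frame CT DICOM slices into one volume.

    Slices are sorted by the z component of ImagePositionPatient (falling
    back to InstanceNumber), rescaled to HU with the stored slope and
    intercept, and checked for consistent in-plane geometry and uniform
    slice spacing (tolerance ``SLICE_SPACING_TOL_MM``).
    """
    directory = Path(path)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            ds = pydicom.dcmread(os.fspath(p))
        except Exception as exc:  # noqa: BLE001 - surface as I/O error
            raise SeriesReadError(f"cannot read DICOM file {p.name}: {exc}") from exc
        if hasattr(ds, "PixelData"):
            datasets.append((p.name, ds))
    if not datasets:
        raise SeriesReadError(f"no DICOM image files found in {directory}")

    def _zpos(item):
        name, ds = item
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None:
            return float(ipp[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=_zpos)

    slices, zs = [], []
    ref_shape, ref_px = None, None
    for name, ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
        px = [float(x) for x in getattr(ds, "PixelSpacing", [1.0, 1.0])]
        if ref_shape is None:
            ref_shape, ref_px = arr.shape, px
        elif arr.shape != ref_shape or not np.allclose(px, ref_px, atol=1e-6):
            raise InconsistentSeriesError(
                f"slice {name}: geometry {arr.shape}/{px} differs from "
                f"{ref_shape}/{ref_px}"
            )
        ipp = getattr(ds, "ImagePositionPatient", None)
        zs.append(float(ipp[2]) if ipp is not None else None)

    if len(slices) > 1 and all(z is not None for z in zs):
        dz = np.diff(zs)
        if np.ptp(dz) > SLICE_SPACING_TOL_MM:
            bad = [datasets[i + 1][0] for i in range(len(dz))
                   if abs(dz[i] - dz[0]) > SLICE_SPACING_TOL_MM]
            raise InconsistentSeriesError(
                f"non-uniform slice spacing (range {dz.min():.4f}-{dz.max():.4f} mm); "
                f"offending slices: {', '.join(bad)}"
            )
        thickness = float(abs(dz[0]))
    else:
        thickness = float(getattr(datasets[0][1], "SliceThickness", 1.0))

    origin_z = zs[0] if zs[0] is not None else 0.0
    return CTVolume(
        voxels=np.stack(slices, axis=0),
        spacing=(thickness, ref_px[0], ref_px[1]),
        origin=(origin_z, 0.0, 0.0),
    )


def read_ct_series(path: str | os.PathLike) -> CTVolume:
    """Read a head-CT study from a DICOM directory or a NIfTI file."""
    p = Path(path)
    if p.is_dir():
        return read_dicom_series(p)
    if p.suffix in {".nii", ".gz"} or p.name.endswith(".nii.gz"):
        return read_nifti_volume(p)
    raise SeriesReadError(f"unrecognized CT input: {p}")


def write_dicom_series(vol: CTVolume, directory: str | os.PathLike,
                       series_uid: str | None = None) -> list[Path]:
    """Write a CT volume as a directory of single-frame DICOM slices.

    Intended for round-trip testing of :func:`read_dicom_series` with
    synthetic volumes; HU are stored as int16 with slope 1 / intercept
    -1024 (the common CT convention).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = series_uid or generate_uid()
    study_uid = generate_uid()
    frame_uid = generate_uid()
    paths = []
    for i in range(vol.shape[0]):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.InstanceNumber = i + 1
        ds.ImagePositionPatient = [float(vol.origin[2]), float(vol.origin[1]),
                                   float(vol.origin[0] + i * vol.spacing[0])]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [vol.spacing[1], vol.spacing[2]]
        ds.SliceThickness = vol.spacing[0]
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = -1024.0
        ds.Rows, ds.Columns = vol.shape[1], vol.shape[2]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0  # unsigned stored values
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        stored = np.rint(vol.voxels[i] + 1024.0)
        if stored.min() < 0 or stored.max() > 65535:
            raise ValidationError("HU out of range for int16 DICOM storage")
        ds.PixelData = stored.astype(np.uint16).tobytes()
        out = directory / f"slice_{i:04d}.dcm"
        ds.save_as(os.fspath(out), enforce_file_format=True)
        paths.append(out)
    return paths
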