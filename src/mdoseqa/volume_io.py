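"""Reading, writing and resampling of CT / dose / structure data.

Supported formats: DICOM CT series, DICOM RTDOSE and RTSTRUCT (read and a
minimal write used for synthetic fixtures and export), and NRRD as the
portable volume format for all synthetic data.  Only axis-aligned volumes
(identity direction cosines) are accepted; oblique data raises.

Geometry note: DICOM stores in-plane positions as (x, y) patient
coordinates; internally everything is (z, y, x) with voxel-center origins —
see :mod:`mdoseqa.core`.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pydicom
import SimpleITK as sitk
from matplotlib.path import Path as MplPath
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from scipy import ndimage

from .core import StructureSet, VolumeGrid

__all__ = [
    "read_ct_series",
    "write_ct_series",
    "read_rtdose",
    "write_rtdose",
    "read_rtstruct",
    "write_rtstruct",
    "read_nrrd",
    "write_nrrd",
    "resample_to_grid",
]

_CT_SOP = "1.2.840.10008.5.1.4.1.1.2"
_RTDOSE_SOP = "1.2.840.10008.5.1.4.1.1.481.2"
_RTSTRUCT_SOP = "1.2.840.10008.5.1.4.1.1.481.3"

_ORIENT_TOL = 1e-4


def _check_axis_aligned(iop: Sequence[float]) -> None:
    if not np.allclose(np.asarray(iop, float), [1, 0, 0, 0, 1, 0], atol=_ORIENT_TOL):
        raise ValueError(
            f"only axis-aligned volumes are supported (ImageOrientationPatient={list(iop)})"
        )


# ---------------------------------------------------------------------------
# DICOM CT series
# ---------------------------------------------------------------------------

def read_ct_series(path: str | Path) -> VolumeGrid:
    """Read one DICOM CT series from a directory into an HU volume.

    Slices are sorted by z position; RescaleSlope/Intercept are applied.
    Mixed series, missing geometry, non-uniform slice spacing and gaps all
    raise descriptive errors.
    """
    path = Path(path)
    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix.lower() != ".txt")
    datasets = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue
        if getattr(ds, "SOPClassUID", None) == _CT_SOP or getattr(ds, "Modality", "") == "CT":
            datasets.append(ds)
    if not datasets:
        raise ValueError(f"no CT slices found under {path}")

    uids = {ds.SeriesInstanceUID for ds in datasets}
    if len(uids) > 1:
        raise ValueError(f"directory contains {len(uids)} mixed CT series: {sorted(uids)}")
    for ds in datasets:
        if "ImagePositionPatient" not in ds or "PixelSpacing" not in ds:
            raise ValueError("CT slice is missing geometry tags (ImagePositionPatient/PixelSpacing)")
        _check_axis_aligned(ds.ImageOrientationPatient)

    datasets.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in datasets])
    if len(zs) > 1:
        steps = np.diff(zs)
        ref = np.median(steps)
        if ref <= 0:
            raise ValueError("duplicate or unsorted slice positions")
        bad = np.where(np.abs(steps - ref) > 0.01 * ref + 1e-3)[0]
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"non-uniform slice spacing: gap of {steps[i]:.3f} mm between "
                f"z={zs[i]:.3f} and z={zs[i + 1]:.3f} (expected {ref:.3f} mm)"
            )
        dz = float(ref)
    else:
        dz = float(getattr(datasets[0], "SliceThickness", 1.0) or 1.0)

    ref_ds = datasets[0]
    dy, dx = (float(v) for v in ref_ds.PixelSpacing)
    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    data = np.stack(slices, axis=0)
    x0, y0 = float(ref_ds.ImagePositionPatient[0]), float(ref_ds.ImagePositionPatient[1])
    return VolumeGrid(data, spacing=(dz, dy, dx), origin=(float(zs[0]), y0, x0))


def write_ct_series(ct: VolumeGrid, path: str | Path, series_uid: str | None = None) -> List[Path]:
    """Write an HU volume as a DICOM CT series (int16, slope 1 / intercept −1024)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    series_uid = series_uid or generate_uid()
    study_uid = generate_uid()
    frame_uid = generate_uid()
    intercept = -1024.0
    stored = np.rint(ct.data - intercept).astype(np.int16)
    if np.any(ct.data < intercept) or np.any(ct.data - intercept > 32767):
        raise ValueError("HU range not representable with int16/intercept -1024")

    out = []
    nz = ct.shape[0]
    for k in range(nz):
        ds = Dataset()
        ds.SOPClassUID = _CT_SOP
        ds.SOPInstanceUID = generate_uid()
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.InstanceNumber = k + 1
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [
            ct.origin[2],
            ct.origin[1],
            ct.origin[0] + k * ct.spacing[0],
        ]
        ds.PixelSpacing = [ct.spacing[1], ct.spacing[2]]
        ds.SliceThickness = ct.spacing[0]
        ds.Rows, ds.Columns = ct.shape[1], ct.shape[2]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = intercept
        ds.PixelData = stored[k].tobytes()
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = ds.SOPClassUID
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta
        fname = path / f"ct_{k:04d}.dcm"
        ds.save_as(fname, enforce_file_format=True)
        out.append(fname)
    return out


# ---------------------------------------------------------------------------
# DICOM RTDOSE
# ---------------------------------------------------------------------------

def read_rtdose(path: str | Path) -> VolumeGrid:
    """Read a DICOM RTDOSE file into a Gy volume.

    Stored integers are scaled by DoseGridScaling; GridFrameOffsetVector
    defines the slice positions.
    """
    ds = pydicom.dcmread(path)
    if "DoseGridScaling" not in ds:
        raise ValueError("RTDOSE file is missing DoseGridScaling")
    _check_axis_aligned(ds.ImageOrientationPatient)
    scaling = float(ds.DoseGridScaling)
    data = ds.pixel_array.astype(np.float64) * scaling
    if data.ndim == 2:
        data = data[None]
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector], dtype=float)
    if len(offsets) != data.shape[0]:
        raise ValueError("GridFrameOffsetVector length does not match number of frames")
    steps = np.diff(offsets)
    if len(steps) and not np.allclose(steps, steps[0], atol=1e-3):
        raise ValueError("non-uniform GridFrameOffsetVector is not supported")
    dz = float(steps[0]) if len(steps) else 1.0
    dy, dx = (float(v) for v in ds.PixelSpacing)
    x0, y0, z0 = (float(v) for v in ds.ImagePositionPatient)
    return VolumeGrid(data, spacing=(dz, dy, dx), origin=(z0 + offsets[0], y0, x0))


def write_rtdose(dose: VolumeGrid, path: str | Path) -> Path:
    """Write a Gy volume as DICOM RTDOSE (uint32, automatic DoseGridScaling)."""
    path = Path(path)
    dmax = float(np.max(dose.data))
    scaling = dmax / (2**32 - 1) if dmax > 0 else 1.0
    stored = np.rint(dose.data / scaling).astype(np.uint32) if dmax > 0 else np.zeros(
        dose.shape, np.uint32
    )
    ds = Dataset()
    ds.SOPClassUID = _RTDOSE_SOP
    ds.SOPInstanceUID = generate_uid()
    ds.Modality = "RTDOSE"
    ds.SeriesInstanceUID = generate_uid()
    ds.StudyInstanceUID = generate_uid()
    ds.FrameOfReferenceUID = generate_uid()
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.ImagePositionPatient = [dose.origin[2], dose.origin[1], dose.origin[0]]
    ds.PixelSpacing = [dose.spacing[1], dose.spacing[2]]
    ds.GridFrameOffsetVector = [k * dose.spacing[0] for k in range(dose.shape[0])]
    ds.NumberOfFrames = dose.shape[0]
    ds.Rows, ds.Columns = dose.shape[1], dose.shape[2]
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.DoseGridScaling = scaling
    ds.PixelData = stored.tobytes()
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = ds.SOPClassUID
    meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds.file_meta = meta
    ds.save_as(path, enforce_file_format=True)
    return path


# ---------------------------------------------------------------------------
# DICOM RTSTRUCT
# ---------------------------------------------------------------------------

def read_rtstruct(path: str | Path, ct: VolumeGrid) -> StructureSet:
    """Rasterize RTSTRUCT contours onto the CT grid.

    Each ROI becomes a boolean mask via per-slice point-in-polygon tests on
    voxel centers; several contours on one slice are unioned.  A contour
    whose plane does not match a CT slice (within half a slice spacing) is
    assigned to the nearest slice with a warning.
    """
    ds = pydicom.dcmread(path)
    structures = StructureSet(ct)
    roi_names = {
        int(roi.ROINumber): str(roi.ROIName) for roi in getattr(ds, "StructureSetROISequence", [])
    }
    zs = ct.voxel_centers(0)
    ys = ct.voxel_centers(1)
    xs = ct.voxel_centers(2)
    gx, gy = np.meshgrid(xs, ys)  # (ny, nx) center coordinates
    points = np.column_stack([gx.ravel(), gy.ravel()])

    for roi_contour in getattr(ds, "ROIContourSequence", []):
        number = int(roi_contour.ReferencedROINumber)
        name = roi_names.get(number, f"ROI_{number}")
        mask = np.zeros(ct.shape, dtype=bool)
        for contour in getattr(roi_contour, "ContourSequence", []):
            pts = np.asarray([float(v) for v in contour.ContourData]).reshape(-1, 3)
            if pts.shape[0] < 3:
                continue
            z = float(np.mean(pts[:, 2]))
            k = int(np.argmin(np.abs(zs - z)))
            if abs(zs[k] - z) > 0.5 * ct.spacing[0] + 1e-6:
                warnings.warn(
                    f"contour of {name!r} at z={z:.3f} mm matches no CT slice; "
                    f"assigned to nearest slice z={zs[k]:.3f} mm",
                    stacklevel=2,
                )
            poly = MplPath(pts[:, :2])
            inside = poly.contains_points(points).reshape(len(ys), len(xs))
            mask[k] |= inside
        structures.add(name, mask)
    return structures


def write_rtstruct(
    contours: dict,
    ct: VolumeGrid,
    path: str | Path,
) -> Path:
    """Write planar contours as a minimal DICOM RTSTRUCT.

    ``contours`` maps structure name -> list of (z_mm, ndarray (N, 2) of
    (x, y) mm vertices).
    """
    path = Path(path)
    ds = Dataset()
    ds.SOPClassUID = _RTSTRUCT_SOP
    ds.SOPInstanceUID = generate_uid()
    ds.Modality = "RTSTRUCT"
    ds.SeriesInstanceUID = generate_uid()
    ds.StudyInstanceUID = generate_uid()
    ds.StructureSetLabel = "mdoseqa"
    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    for i, (name, planar) in enumerate(contours.items(), start=1):
        roi = Dataset()
        roi.ROINumber = i
        roi.ROIName = name
        roi.ReferencedFrameOfReferenceUID = generate_uid()
        ds.StructureSetROISequence.append(roi)
        rc = Dataset()
        rc.ReferencedROINumber = i
        rc.ContourSequence = []
        for z, verts in planar:
            verts = np.asarray(verts, dtype=float)
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.NumberOfContourPoints = verts.shape[0]
            data = np.column_stack([verts, np.full(verts.shape[0], float(z))])
            c.ContourData = [f"{v:.6f}" for v in data.ravel()]
            rc.ContourSequence.append(c)
        ds.ROIContourSequence.append(rc)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = ds.SOPClassUID
    meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds.file_meta = meta
    ds.save_as(path, enforce_file_format=True)
    return path


# ---------------------------------------------------------------------------
# NRRD (portable volumes)
# ---------------------------------------------------------------------------

def read_nrrd(path: str | Path) -> VolumeGrid:
    img = sitk.ReadImage(str(path))
    if not np.allclose(img.GetDirection(), np.eye(3).ravel(), atol=_ORIENT_TOL):
        raise ValueError("only axis-aligned NRRD volumes are supported")
    data = sitk.GetArrayFromImage(img)  # (z, y, x)
    sx, sy, sz = img.GetSpacing()
    ox, oy, oz = img.GetOrigin()
    return VolumeGrid(data, spacing=(sz, sy, sx), origin=(oz, oy, ox))


def write_nrrd(vol: VolumeGrid, path: str | Path) -> Path:
    img = sitk.GetImageFromArray(np.asarray(vol.data))
    img.SetSpacing((vol.spacing[2], vol.spacing[1], vol.spacing[0]))
    img.SetOrigin((vol.origin[2], vol.origin[1], vol.origin[0]))
    sitk.WriteImage(img, str(path))
    return Path(path)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_to_grid(src: VolumeGrid, target: VolumeGrid) -> VolumeGrid:
    """Trilinearly resample ``src`` onto the geometry of ``target``.

    Values are interpolated at the target voxel centers; points outside the
    source extent are zero-padded.  Returns a volume with the target's
    geometry.  When the grids coincide the data is returned unchanged.
    """
    if any(n < 1 for n in target.shape):
        raise ValueError("degenerate target grid")
    if src.same_geometry(target):
        return target.copy_with(np.asarray(src.data).copy())
    coords = []
    for ax in range(3):
        world = target.voxel_centers(ax)
        coords.append((world - src.origin[ax]) / src.spacing[ax])
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    out = ndimage.map_coordinates(
        np.asarray(src.data, dtype=np.float64),
        [zz, yy, xx],
        order=1,
        mode="constant",
        cval=0.0,
        prefilter=False,
    )
    return target.copy_with(out)
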