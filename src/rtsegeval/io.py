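"""File formats, resampling and cropping.

Volumes travel as NIfTI (``.nii``/``.nii.gz``) or MetaImage (``.mha``/``.mhd``)
through SimpleITK; structure sets as DICOM RT-struct and dose grids as DICOM
RTDOSE through pydicom. Internally everything lives on the package's
``(z, y, x)`` LPS lattice (see :mod:`rtsegeval.grids`); SimpleITK's
``(x, y, z)`` metadata order is translated at the boundary. Images read with a
non-identity direction matrix are rejected rather than silently reoriented.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pydicom
import SimpleITK as sitk
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .contours import ContourSet, ContourSlice
from .grids import BinaryMask3D, DoseGrid, GeometryError, Image3D

__all__ = [
    "resample_to_grid",
    "crop_centered",
    "read_image",
    "read_dose",
    "write_volume",
    "read_rtstruct",
    "write_rtstruct",
]

_RTSTRUCT_CLASS_UID = "1.2.840.10008.5.1.4.1.1.481.3"

_VOLUME_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")


# ---------------------------------------------------------------------------
# SimpleITK bridge
# ---------------------------------------------------------------------------

def _to_sitk(obj: Image3D) -> sitk.Image:
    arr = obj.values
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(tuple(reversed(obj.spacing)))
    img.SetOrigin(tuple(reversed(obj.origin)))
    return img


def _from_sitk(img: sitk.Image, kind: type = Image3D) -> Image3D:
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise ValueError(
            "only identity-direction volumes are supported; got direction "
            f"{direction.tolist()}"
        )
    arr = sitk.GetArrayFromImage(img)
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    if kind is BinaryMask3D:
        return BinaryMask3D(arr > 0.5, spacing, origin)
    return kind(arr, spacing, origin)


# ---------------------------------------------------------------------------
# Resampling and cropping
# ---------------------------------------------------------------------------

def resample_to_grid(
    obj: Image3D,
    spacing: tuple[float, float, float] | None = None,
    like: Image3D | None = None,
) -> Image3D:
    """Resample onto a new lattice: masks nearest-neighbour, images linearly.

    Either a target ``spacing`` (mm per axis, ``(z, y, x)``; extent preserved)
    or a full reference geometry ``like`` must be given. Masks stay binary by
    construction of the nearest-neighbour interpolator.
    """
    if (spacing is None) == (like is None):
        raise ValueError("give exactly one of `spacing` or `like`")
    if like is not None:
        target_spacing = like.spacing
        target_origin = like.origin
        target_shape = like.shape
        lo_t = np.asarray(like.origin)
        hi_t = lo_t + (np.asarray(like.shape) - 1) * np.asarray(like.spacing)
        lo_s = np.asarray(obj.origin)
        hi_s = lo_s + (np.asarray(obj.shape) - 1) * np.asarray(obj.spacing)
        if np.any(hi_t < lo_s) or np.any(lo_t > hi_s):
            raise GeometryError(
                f"target grid [{lo_t}, {hi_t}] mm does not overlap source "
                f"[{lo_s}, {hi_s}] mm"
            )
    else:
        target_spacing = tuple(float(s) for s in spacing)  # type: ignore[arg-type]
        if any(s <= 0 for s in target_spacing):
            raise ValueError(f"target spacing must be positive, got {target_spacing}")
        extent = (np.asarray(obj.shape) - 1) * np.asarray(obj.spacing)
        target_shape = tuple(
            int(np.floor(e / s)) + 1 for e, s in zip(extent, target_spacing)
        )
        target_origin = obj.origin

    is_mask = isinstance(obj, BinaryMask3D)
    interp = sitk.sitkNearestNeighbor if is_mask else sitk.sitkLinear
    img = _to_sitk(obj)
    out = sitk.Resample(
        img,
        tuple(reversed(target_shape)),
        sitk.Transform(),
        interp,
        tuple(reversed(target_origin)),
        tuple(reversed(target_spacing)),
        img.GetDirection(),
        0.0,
        img.GetPixelID(),
    )
    kind = type(obj)
    return _from_sitk(out, BinaryMask3D if is_mask else kind)


def crop_centered(
    obj: Image3D, center_mm: tuple[float, float, float], size: tuple[int, int, int]
) -> Image3D:
    """Crop a block of exactly ``size`` voxels centered at ``center_mm``.

    The center is snapped to the nearest voxel; regions extending past the
    grid are zero-padded with a warning. Raises if the center itself lies
    outside the grid.
    """
    size = tuple(int(s) for s in size)
    if any(s <= 0 for s in size):
        raise ValueError(f"crop size must be positive, got {size}")
    idx = np.rint(obj.mm_to_index(np.asarray(center_mm))).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.asarray(obj.shape)):
        raise ValueError(
            f"crop center {center_mm} mm (index {tuple(idx)}) lies outside the "
            f"grid of shape {obj.shape}"
        )
    start = idx - np.asarray(size) // 2
    stop = start + np.asarray(size)
    src_lo = np.maximum(start, 0)
    src_hi = np.minimum(stop, obj.shape)
    if np.any(src_lo != start) or np.any(src_hi != stop):
        warnings.warn("crop extends beyond the grid; zero-padding the overhang")
    out = np.zeros(size, dtype=obj.values.dtype)
    dst_lo = src_lo - start
    dst_hi = dst_lo + (src_hi - src_lo)
    out[
        dst_lo[0] : dst_hi[0], dst_lo[1] : dst_hi[1], dst_lo[2] : dst_hi[2]
    ] = obj.values[src_lo[0] : src_hi[0], src_lo[1] : src_hi[1], src_lo[2] : src_hi[2]]
    new_origin = tuple(
        obj.origin[a] + start[a] * obj.spacing[a] for a in range(3)
    )
    kind = type(obj)
    return kind(out, obj.spacing, new_origin)


# ---------------------------------------------------------------------------
# Volume formats
# ---------------------------------------------------------------------------

def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _VOLUME_SUFFIXES):
        raise ValueError(
            f"unknown volume format {path.name!r}; supported: {_VOLUME_SUFFIXES}"
        )


def write_volume(obj: Image3D, path: str | Path) -> None:
    """Write a volume as NIfTI or MetaImage, chosen by file extension."""
    path = Path(path)
    _check_suffix(path)
    sitk.WriteImage(_to_sitk(obj), str(path))


def read_image(path: str | Path) -> Image3D:
    """Read a NIfTI/MetaImage scalar volume."""
    path = Path(path)
    _check_suffix(path)
    return _from_sitk(sitk.ReadImage(str(path)), Image3D)


def read_mask(path: str | Path) -> BinaryMask3D:
    """Read a NIfTI/MetaImage volume as a binary mask (values > 0.5)."""
    path = Path(path)
    _check_suffix(path)
    return _from_sitk(sitk.ReadImage(str(path)), BinaryMask3D)  # type: ignore[return-value]


def read_dose(path: str | Path) -> DoseGrid:
    """Read a dose grid in Gy from DICOM RTDOSE or NIfTI/MetaImage.

    For RTDOSE the stored integers are multiplied by ``DoseGridScaling`` so
    the returned values are absolute Gy. Negative doses are rejected.
    """
    path = Path(path)
    if path.suffix.lower() == ".dcm":
        ds = pydicom.dcmread(str(path))
        for elem in ("DoseGridScaling", "ImagePositionPatient", "PixelSpacing",
                     "GridFrameOffsetVector"):
            if elem not in ds:
                raise ValueError(f"RTDOSE file missing required element {elem}")
        scaling = float(ds.DoseGridScaling)
        arr = ds.pixel_array.astype(float) * scaling  # (frames, rows, cols)
        offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
        dz = float(offsets[1] - offsets[0]) if len(offsets) > 1 else 1.0
        if len(offsets) > 2 and not np.allclose(np.diff(offsets), dz):
            raise ValueError("non-uniform GridFrameOffsetVector is not supported")
        row_sp, col_sp = (float(v) for v in ds.PixelSpacing)
        ipp = [float(v) for v in ds.ImagePositionPatient]  # (x, y, z)
        origin = (ipp[2] + float(offsets[0]), ipp[1], ipp[0])
        return DoseGrid(arr, (abs(dz), row_sp, col_sp), origin)
    _check_suffix(path)
    img = _from_sitk(sitk.ReadImage(str(path)), Image3D)
    return DoseGrid(img.values, img.spacing, img.origin)


# ---------------------------------------------------------------------------
# DICOM RT-struct
# ---------------------------------------------------------------------------

def write_rtstruct(
    contours: ContourSet, reference: Image3D, path: str | Path
) -> None:
    """Write a minimal RT structure set holding the contour polygons.

    The geometry of ``reference`` is only used for the frame-of-reference
    bookkeeping; vertex coordinates are stored as given, in patient-space mm.
    """
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = _RTSTRUCT_CLASS_UID
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = _RTSTRUCT_CLASS_UID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTSTRUCT"
    ds.StructureSetLabel = "rtsegeval"
    frame_uid = generate_uid()
    ds.FrameOfReferenceUID = frame_uid

    roi_seq = []
    contour_seq = []
    for number, (name, slices) in enumerate(contours.structures.items(), start=1):
        roi = Dataset()
        roi.ROINumber = number
        roi.ROIName = name
        roi.ReferencedFrameOfReferenceUID = frame_uid
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        roi_seq.append(roi)

        rc = Dataset()
        rc.ReferencedROINumber = number
        items = []
        for sl in slices:
            for poly in sl.polygons:
                item = Dataset()
                item.ContourGeometricType = "CLOSED_PLANAR"
                item.NumberOfContourPoints = len(poly)
                data: list[float] = []
                for x, y in poly:
                    data.extend([float(x), float(y), float(sl.z)])
                item.ContourData = data
                items.append(item)
        rc.ContourSequence = items
        contour_seq.append(rc)

    ds.StructureSetROISequence = roi_seq
    ds.ROIContourSequence = contour_seq
    ds.is_little_endian = True
    ds.is_implicit_VR = False
    pydicom.dcmwrite(str(path), ds, enforce_file_format=True)


def read_rtstruct(path: str | Path) -> ContourSet:
    """Read a DICOM RT-struct into a :class:`ContourSet`.

    Raises with the missing element's name when the file lacks the structure
    set ROI or ROI contour sequences.
    """
    ds = pydicom.dcmread(str(path))
    for elem in ("StructureSetROISequence", "ROIContourSequence"):
        if elem not in ds:
            raise ValueError(f"RT-struct file missing required element {elem}")
    names = {int(roi.ROINumber): str(roi.ROIName) for roi in ds.StructureSetROISequence}
    structures: dict[str, list[ContourSlice]] = {}
    for rc in ds.ROIContourSequence:
        name = names.get(int(rc.ReferencedROINumber))
        if name is None:
            raise ValueError(
                f"ROIContourSequence references unknown ROINumber "
                f"{rc.ReferencedROINumber}"
            )
        by_z: dict[float, list[np.ndarray]] = {}
        for item in getattr(rc, "ContourSequence", []):
            pts = np.asarray([float(v) for v in item.ContourData]).reshape(-1, 3)
            z = float(np.round(pts[:, 2].mean(), 6))
            by_z.setdefault(z, []).append(pts[:, :2])
        structures[name] = [
            ContourSlice(z=z, polygons=polys) for z, polys in sorted(by_z.items())
        ]
    return ContourSet(structures=structures)
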