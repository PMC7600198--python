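"""Reading and writing head-CT volumes and masks.

Arrays are indexed ``(row, column, slice)``: axial slices are the last axis
and all per-slice processing operates on ``voxels[:, :, k]``. Voxel indices
are 0-based and physical positions refer to voxel centers. Intensities are
Hounsfield units (HU) throughout; non-CT DICOM modalities are rejected
rather than guessed because HU semantics are assumed downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pydicom

__all__ = ["CTVolume", "load_dicom_series", "load_nifti", "write_mask"]

#: relative tolerance on slice-gap uniformity before a warning is emitted
SLICE_GAP_RTOL = 0.01


@dataclass
class CTVolume:
    """A 3D CT image in Hounsfield units with physical geometry.

    Attributes
    ----------
    voxels:
        ``(rows, cols, slices)`` float array in HU.
    spacing:
        Physical voxel size ``(row, column, slice)`` in mm, all positive.
    origin:
        Physical position of voxel ``(0, 0, 0)`` in mm.
    patient_age:
        Age in years, if known (used as a classifier covariate).
    scan_id:
        Opaque identifier for the scan.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    patient_age: Optional[float] = None
    scan_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D, got shape {self.voxels.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels contain non-finite values after HU conversion")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


def _require_tag(ds: pydicom.Dataset, name: str, fname: str):
    if not hasattr(ds, name) or getattr(ds, name) is None:
        raise ValueError(f"DICOM file {fname} is missing required geometry tag {name!r}")
    return getattr(ds, name)


def load_dicom_series(directory) -> CTVolume:
    """Load one axial DICOM series from *directory* into a :class:`CTVolume`.

    Raw stored values are converted to HU with the series' rescale slope and
    intercept; slices are sorted by axial position; spacing comes from
    PixelSpacing and the inter-slice distance (falling back to
    SliceThickness for single-slice series).
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            ds = pydicom.dcmread(str(p))
        except Exception:
            continue  # skip non-DICOM files (e.g. DICOMDIR clutter)
        if not hasattr(ds, "PixelData"):
            continue
        datasets.append((p.name, ds))
    if not datasets:
        raise ValueError(f"no DICOM images found in {directory}")

    modality = getattr(datasets[0][1], "Modality", "CT")
    if modality not in ("CT", None):
        raise ValueError(f"expected a CT series, got modality {modality!r}")

    uids = {getattr(ds, "SeriesInstanceUID", None) for _, ds in datasets}
    if len(uids) > 1:
        raise ValueError(f"directory mixes {len(uids)} DICOM series; expected one")

    slices = []
    for fname, ds in datasets:
        pixel_spacing = _require_tag(ds, "PixelSpacing", fname)
        ipp = _require_tag(ds, "ImagePositionPatient", fname)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        hu = ds.pixel_array.astype(np.float64) * slope + intercept
        slices.append((float(ipp[2]), hu, tuple(float(v) for v in pixel_spacing), fname))

    slices.sort(key=lambda t: t[0])
    spacings = {s[2] for s in slices}
    if len(spacings) > 1:
        raise ValueError("inconsistent PixelSpacing across series slices")
    shapes = {s[1].shape for s in slices}
    if len(shapes) > 1:
        raise ValueError("inconsistent image dimensions across series slices")

    zpos = np.array([s[0] for s in slices])
    if len(slices) > 1:
        gaps = np.diff(zpos)
        slice_spacing = float(np.median(np.abs(gaps)))
        if slice_spacing <= 0:
            raise ValueError("duplicate slice positions in series")
        if np.any(np.abs(np.abs(gaps) - slice_spacing) > SLICE_GAP_RTOL * slice_spacing):
            warnings.warn(
                f"non-uniform slice gaps (range {gaps.min():.3f}..{gaps.max():.3f} mm)",
                stacklevel=2,
            )
    else:
        slice_spacing = float(getattr(slices[0][3] and datasets[0][1], "SliceThickness", 1.0))

    voxels = np.stack([s[1] for s in slices], axis=-1)
    row_sp, col_sp = slices[0][2]
    ds0 = datasets[0][1]
    origin_xyz = [float(v) for v in getattr(ds0, "ImagePositionPatient", (0, 0, zpos[0]))]
    age = _parse_dicom_age(getattr(ds0, "PatientAge", None))
    return CTVolume(
        voxels=voxels,
        spacing=(row_sp, col_sp, slice_spacing),
        origin=(origin_xyz[0], origin_xyz[1], float(zpos[0])),
        patient_age=age,
        scan_id=str(getattr(ds0, "SeriesInstanceUID", directory.name)),
    )


def _parse_dicom_age(age_str) -> Optional[float]:
    # DICOM AS format: "045Y", "018M", ...
    if not age_str:
        return None
    s = str(age_str)
    try:
        value = float(s.rstrip("YMWD").lstrip("0") or "0")
    except ValueError:
        return None
    unit = s[-1] if s and s[-1] in "YMWD" else "Y"
    factor = {"Y": 1.0, "M": 1 / 12, "W": 1 / 52, "D": 1 / 365}[unit]
    return value * factor


def load_nifti(path) -> CTVolume:
    """Load a 3D NIfTI volume; intensities are assumed already in HU."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"NIfTI file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got {data.ndim}D in {path}")
    affine = img.affine
    rot = affine[:3, :3]
    # reject shears/oblique affines: columns must be mutually orthogonal
    norms = np.linalg.norm(rot, axis=0)
    if np.any(norms <= 0):
        raise ValueError(f"degenerate affine in {path}")
    unit = rot / norms
    if not np.allclose(unit.T @ unit, np.eye(3), atol=1e-4):
        raise ValueError(f"non-orthogonal affine in {path}; resample first")
    spacing = tuple(float(n) for n in norms)
    origin = tuple(float(v) for v in affine[:3, 3])
    return CTVolume(
        voxels=data.astype(np.float64),
        spacing=spacing,  # type: ignore[arg-type]
        origin=origin,  # type: ignore[arg-type]
        scan_id=path.stem.replace(".nii", ""),
    )


def _affine_from(geometry: CTVolume) -> np.ndarray:
    affine = np.diag(list(geometry.spacing) + [1.0])
    affine[:3, 3] = geometry.origin
    return affine


def write_volume(volume: CTVolume, path) -> None:
    """Write a CTVolume as NIfTI-1 with its geometry in the affine."""
    img = nib.Nifti1Image(volume.voxels.astype(np.float32), _affine_from(volume))
    nib.save(img, str(path))


def write_mask(mask: np.ndarray, geometry: CTVolume, path) -> None:
    """Write a boolean mask as NIfTI-1 sharing *geometry* so overlays align."""
    mask = np.asarray(mask)
    if mask.shape != geometry.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match geometry shape {geometry.shape}"
        )
    img = nib.Nifti1Image(mask.astype(np.uint8), _affine_from(geometry))
    nib.save(img, str(path))


def read_mask(path) -> np.ndarray:
    """Read a mask written by :func:`write_mask` back as a boolean array."""
    vol = load_nifti(path)
    return vol.voxels > 0.5
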