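"""Batch ingestion of DICOM series and NIfTI volumes, privacy-field removal,
axial slice extraction, CT windowing, and PNG output.

Conventions fixed here (and relied on by the manifest):

* slice indices are 0-based and follow anatomical order, inferior to
  superior (ascending through-plane position, instance number as tiebreak);
* CT intensities are Hounsfield units after rescale slope/intercept;
* windowing maps ``[center - width/2, center + width/2]`` linearly onto
  ``[0, 1]`` and clips outside;
* PNG output is 8-bit grayscale, ``round-half-up(pixel * 255)``, named
  ``{patient_id}_{series_id}_{slice_index:04d}.png``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
from PIL import Image

from . import _dicomlite
from .errors import (
    FormatError,
    InconsistentGeometryError,
    InconsistentSeriesError,
    InvalidWindowError,
    NoInputError,
    NotAVolumeError,
    WriteError,
)

#: direct identifiers removed by default; ``descrip`` covers the NIfTI
#: free-text header field, which fixtures deliberately abuse for private text
DEFAULT_PRIVATE_FIELDS = (
    "PatientName",
    "PatientBirthDate",
    "PatientAddress",
    "PatientTelephoneNumbers",
    "OperatorsName",
    "ReferringPhysicianName",
    "InstitutionName",
    "descrip",
)


@dataclass(frozen=True)
class AnonymizationPolicy:
    """Deny-list of header fields to strip before anything leaves ingestion."""

    fields_to_remove: Tuple[str, ...] = DEFAULT_PRIVATE_FIELDS
    replacement_token: str = "ANON"

    def scrub(self, metadata: Dict[str, object]) -> Dict[str, object]:
        """Return ``metadata`` without any policy-listed field."""
        banned = set(self.fields_to_remove)
        return {k: v for k, v in metadata.items() if k not in banned}


@dataclass
class VolumeRecord:
    """One ingested volume: (slices, rows, cols) intensity grid plus the
    retained, already-anonymized header fields."""

    patient_id: str
    series_id: str
    voxels: np.ndarray
    slice_order: List[int]
    metadata: Dict[str, object] = field(default_factory=dict)

    @property
    def n_slices(self) -> int:
        return int(self.voxels.shape[0])


@dataclass
class SliceImage:
    """A single axial slice with pixels windowed into [0, 1]."""

    patient_id: str
    series_id: str
    slice_index: int
    pixels: np.ndarray
    source_path: str = ""

    @property
    def key(self) -> Tuple[str, str, int]:
        return (self.patient_id, self.series_id, self.slice_index)


def load_dicom_series(dir_path, policy: AnonymizationPolicy | None = None) -> VolumeRecord:
    """Read a directory of single-frame DICOM files as one volume.

    Slices are sorted by through-plane position (z of ImagePositionPatient,
    falling back to SliceLocation), with InstanceNumber as tiebreak. Rescale
    slope/intercept are applied, so CT voxels come out in Hounsfield units.
    All fields named by the anonymization policy are stripped from the
    retained metadata.
    """
    policy = policy or AnonymizationPolicy()
    dir_path = Path(dir_path)
    files = sorted(p for p in dir_path.iterdir() if p.is_file()) if dir_path.is_dir() else []
    files = [p for p in files if _dicomlite.looks_like_dicom(p)]
    if not files:
        raise NoInputError(f"no input: no readable DICOM files in {dir_path}")

    datasets = []
    for p in files:
        try:
            ds = _dicomlite.read_file(p)
        except ValueError as exc:
            raise FormatError(f"format error: {p}: {exc}") from exc
        datasets.append((p, ds))

    series_ids = {ds.get("SeriesInstanceUID") for _, ds in datasets}
    if len(series_ids) != 1:
        raise InconsistentSeriesError(
            f"inconsistent series: {len(series_ids)} series identities in {dir_path}"
        )
    shapes = {ds["PixelData"].shape for _, ds in datasets}
    if len(shapes) != 1:
        raise InconsistentGeometryError(
            f"inconsistent geometry: in-plane dimensions {sorted(shapes)} in {dir_path}"
        )

    def sort_key(item):
        _, ds = item
        pos = ds.get("ImagePositionPatient")
        if isinstance(pos, (list, tuple)) and len(pos) == 3:
            z = float(pos[2])
        elif pos is not None and np.isscalar(pos):
            z = float(pos)
        elif ds.get("SliceLocation") is not None:
            z = float(ds["SliceLocation"])
        else:
            z = 0.0
        return (z, ds.get("InstanceNumber") or 0)

    order = sorted(range(len(datasets)), key=lambda i: sort_key(datasets[i]))

    slices = []
    for _, ds in datasets:
        slope = float(ds.get("RescaleSlope") or 1.0)
        intercept = float(ds.get("RescaleIntercept") or 0.0)
        slices.append(ds["PixelData"].astype(np.float32) * slope + intercept)
    voxels = np.stack(slices, axis=0)

    first = datasets[0][1]
    metadata = {
        k: v for k, v in first.items()
        if k not in ("PixelData", "Rows", "Columns") and v is not None
    }
    metadata = policy.scrub(metadata)
    patient_id = str(first.get("PatientID") or dir_path.name)
    series_id = str(first.get("SeriesInstanceUID") or dir_path.name)
    return VolumeRecord(
        patient_id=patient_id,
        series_id=series_id,
        voxels=voxels,
        slice_order=list(order),
        metadata=metadata,
    )


def load_nifti_volume(path, policy: AnonymizationPolicy | None = None) -> VolumeRecord:
    """Read a NIfTI volume; the axial axis is chosen from the stored affine.

    The through-plane (superior-inferior) array axis is moved to axis 0.
    When the affine points that axis inferior-ward, ``slice_order`` reverses
    the storage order so index 0 of the ordering is the most inferior slice.
    4-D inputs take volume 0.
    """
    import nibabel as nib

    policy = policy or AnonymizationPolicy()
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(dtype=np.float32))
    except Exception as exc:
        raise FormatError(f"format error: {path}: {exc}") from exc

    if data.ndim < 3:
        raise NotAVolumeError(f"not a volume: {path} has {data.ndim} dimensions")
    if data.ndim > 3:
        data = data[..., 0] if data.ndim == 4 else data.reshape(data.shape[:3] + (-1,))[..., 0]

    ornt = nib.orientations.io_orientation(img.affine)  # rows: (output axis, flip)
    axial_axis = int(np.where(ornt[:, 0] == 2)[0][0])   # array axis mapping to S-I
    ascending = ornt[axial_axis, 1] > 0                 # +1: index grows superior-ward

    voxels = np.moveaxis(data, axial_axis, 0)
    n = voxels.shape[0]
    order = list(range(n)) if ascending else list(range(n - 1, -1, -1))

    header = img.header
    metadata = {
        "descrip": header["descrip"].tobytes().decode("ascii", "replace").rstrip("\x00"),
        "dim": [int(d) for d in header["dim"][1:4]],
        "source_file": path.name,
    }
    metadata = policy.scrub(metadata)
    stem = path.name.removesuffix(".gz").removesuffix(".nii")
    return VolumeRecord(
        patient_id=stem,
        series_id=stem,
        voxels=voxels,
        slice_order=order,
        metadata=metadata,
    )


def split_axial(volume: VolumeRecord, window_center: float = 40.0,
                window_width: float = 400.0, source_path: str = "") -> List[SliceImage]:
    """Window every slice into [0, 1] and emit them in anatomical order.

    The output ``slice_index`` counts positions in ``slice_order`` (0 = most
    inferior slice), not storage positions, so manifests stay stable across
    storage layouts of the same anatomy.
    """
    if window_width <= 0:
        raise InvalidWindowError(f"invalid window: width {window_width} must be > 0")
    lo = window_center - window_width / 2.0
    out = []
    for out_idx, store_idx in enumerate(volume.slice_order):
        pixels = np.clip((volume.voxels[store_idx] - lo) / window_width, 0.0, 1.0)
        out.append(SliceImage(
            patient_id=volume.patient_id,
            series_id=volume.series_id,
            slice_index=out_idx,
            pixels=pixels.astype(np.float64),
            source_path=source_path,
        ))
    return out


def write_png(slice_image: SliceImage, out_dir) -> str:
    """Write an 8-bit grayscale PNG; returns the file path.

    Byte values are ``floor(pixel * 255 + 0.5)`` (round half up); read-back
    reproduces them exactly. No textual metadata chunks are embedded.
    """
    out_dir = Path(out_dir)
    name = f"{slice_image.patient_id}_{slice_image.series_id}_{slice_image.slice_index:04d}.png"
    path = out_dir / name
    data = np.floor(np.clip(slice_image.pixels, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        Image.fromarray(data, mode="L").save(path, format="PNG")
    except OSError as exc:
        raise WriteError(f"I/O error: cannot write {path}: {exc}") from exc
    return str(path)


def read_png(path) -> np.ndarray:
    """Load a grayscale PNG back to a [0, 1] float grid (inverse of write_png
    up to the 8-bit quantization)."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=np.float64)
    return arr / 255.0
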