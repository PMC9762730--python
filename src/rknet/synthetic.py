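"""Phantom CT-like cohorts with per-slice ground-truth relevance.

Each patient volume is a stack of axial slices in Hounsfield-like units:

* background: a constant soft-tissue base plus a few low-frequency cosine
  components with seeded random frequencies/phases (the phases drift slowly
  through-plane so the stack is smooth in 3-D), plus i.i.d. Gaussian noise;
* lesion: inside the ``tumor_run`` slice interval, a Gaussian-feathered
  ellipse of amplitude ``separation * noise_sd`` whose cross-section waxes
  and wanes across the run. Patient classes differ only in the lesion's
  internal speckle: the speckle standard deviation is a class-specific
  fraction of the lesion amplitude, so at ``separation == 0`` the two
  classes (and tumor vs non-tumor slices) are statistically identical.

Volumes can be materialized as NIfTI files or DICOM series; both variants
plant one deliberately private header field (a fake patient name) so
anonymization is exercised end to end.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from . import _dicomlite
from .errors import BadTumorRunError, DegenerateSplitError, InvalidInputError

CLASS1 = "Class1"
CLASS2 = "Class2"


@dataclass(frozen=True)
class PhantomSpec:
    n_patients: int = 20
    n_slices: int = 40
    image_size: Tuple[int, int] = (64, 64)
    tumor_run: Tuple[int, int] = (15, 24)  # inclusive interval of lesion slices
    separation: float = 3.0                # lesion amplitude in noise-sd units
    noise_sd: float = 20.0                 # HU
    background_base: float = 30.0          # HU, soft-tissue plateau
    background_amplitude: float = 35.0     # HU, total cosine texture swing
    n_background_components: int = 4
    class_speckle_frac: Dict[str, float] = field(
        default_factory=lambda: {CLASS1: 0.1, CLASS2: 0.6}
    )
    seed: int = 0

    def __post_init__(self):
        start, end = self.tumor_run
        if not (0 <= start <= end < self.n_slices):
            raise BadTumorRunError(
                f"bad tumor_run: ({start}, {end}) outside 0..{self.n_slices - 1}"
            )
        if self.separation < 0:
            raise InvalidInputError("invalid input: separation must be >= 0")
        if self.n_patients < 1 or self.n_slices < 1:
            raise InvalidInputError("invalid input: need >=1 patient and slice")


@dataclass
class TruthTable:
    """Ground truth: per-slice relevance and per-patient class."""

    slices: pd.DataFrame    # patient_id, series_id, slice_index, relevant
    patients: pd.DataFrame  # patient_id, class_label

    def relevant_keys(self, patient_id: str | None = None) -> List[Tuple[str, str, int]]:
        frame = self.slices[self.slices["relevant"]]
        if patient_id is not None:
            frame = frame[frame["patient_id"] == patient_id]
        return [tuple(r) for r in frame[["patient_id", "series_id", "slice_index"]].itertuples(index=False)]


def patient_ids(spec: PhantomSpec) -> List[str]:
    return [f"P{i:03d}" for i in range(spec.n_patients)]


def patient_class(spec: PhantomSpec, index: int) -> str:
    # parity keeps classes balanced under any patient-level split
    return CLASS1 if index % 2 == 0 else CLASS2


def generate_volume(spec: PhantomSpec, patient_index: int) -> np.ndarray:
    """One (n_slices, rows, cols) phantom volume in HU, deterministic per
    (spec.seed, patient_index)."""
    rng = np.random.default_rng([spec.seed, patient_index])
    rows, cols = spec.image_size
    yy, xx = np.mgrid[0:rows, 0:cols].astype(np.float64)
    yn, xn = yy / rows, xx / cols

    amp_each = spec.background_amplitude / spec.n_background_components
    comps = []
    for _ in range(spec.n_background_components):
        fx, fy = rng.uniform(0.5, 2.0, size=2)
        phase = rng.uniform(0, 2 * np.pi)
        drift = rng.uniform(-0.02, 0.02)  # radians per slice: slow 3-D variation
        comps.append((fx, fy, phase, drift))

    start, end = spec.tumor_run
    run_len = end - start + 1
    cy = rows / 2 + rng.uniform(-rows / 12, rows / 12)
    cx = cols / 2 + rng.uniform(-cols / 12, cols / 12)
    ry = rows / 6 * rng.uniform(0.8, 1.2)
    rx = cols / 6 * rng.uniform(0.8, 1.2)

    amplitude = spec.separation * spec.noise_sd
    speckle_frac = spec.class_speckle_frac[patient_class(spec, patient_index)]

    volume = np.empty((spec.n_slices, rows, cols), dtype=np.float32)
    for z in range(spec.n_slices):
        img = np.full((rows, cols), spec.background_base, dtype=np.float64)
        for fx, fy, phase, drift in comps:
            img += amp_each * np.cos(2 * np.pi * (fx * xn + fy * yn) + phase + drift * z)
        img += rng.normal(0.0, spec.noise_sd, size=(rows, cols))

        if start <= z <= end and amplitude > 0:
            # elliptical cross-section largest mid-run; the floor keeps
            # edge-of-run lesions visible rather than vanishingly small
            scale = 0.6 + 0.4 * np.sin(np.pi * (z - start + 0.5) / run_len)
            e = ((yy - cy) / (ry * scale)) ** 2 + ((xx - cx) / (rx * scale)) ** 2
            mask = 1.0 / (1.0 + np.exp((np.sqrt(e) - 1.0) / 0.08))
            speckle = rng.normal(0.0, 1.0, size=(rows, cols))
            img += amplitude * mask * (1.0 + speckle_frac * speckle)
        volume[z] = img
    return volume


def truth_table(spec: PhantomSpec) -> TruthTable:
    start, end = spec.tumor_run
    slice_rows = []
    patient_rows = []
    for i, pid in enumerate(patient_ids(spec)):
        patient_rows.append({"patient_id": pid, "class_label": patient_class(spec, i)})
        for z in range(spec.n_slices):
            slice_rows.append({
                "patient_id": pid,
                "series_id": pid,
                "slice_index": z,
                "relevant": start <= z <= end,
            })
    return TruthTable(slices=pd.DataFrame(slice_rows), patients=pd.DataFrame(patient_rows))


def _write_nifti(volume: np.ndarray, path: Path, pid: str) -> None:
    import nibabel as nib

    # storage (x, y, z) with z the through-plane axis; identity-scale affine
    data = np.moveaxis(volume, 0, 2).astype(np.float32)
    img = nib.Nifti1Image(data, affine=np.eye(4))
    # deliberately plant private free text for the anonymization tests
    img.header["descrip"] = f"PatientName={pid} DOB=19700101".encode("ascii")[:79]
    nib.save(img, str(path))


def _write_dicom_series(volume: np.ndarray, series_dir: Path, pid: str) -> None:
    series_dir.mkdir(parents=True, exist_ok=True)
    series_uid = f"1.2.826.0.1.999.{zlib.crc32(pid.encode()) % 10**8}"
    intercept = -1024.0
    for z in range(volume.shape[0]):
        stored = np.clip(np.round(volume[z] - intercept), 0, 4095).astype("<u2")
        ds = {
            "SOPInstanceUID": f"{series_uid}.{z}",
            "Modality": "CT",
            "PatientName": f"DOE^{pid}",  # planted private field
            "PatientID": pid,
            "PatientBirthDate": "19700101",
            "SeriesInstanceUID": series_uid,
            "InstanceNumber": z + 1,
            "ImagePositionPatient": [0.0, 0.0, float(z) * 5.0],
            "SliceLocation": float(z) * 5.0,
            "Rows": volume.shape[1],
            "Columns": volume.shape[2],
            "BitsAllocated": 16,
            "BitsStored": 12,
            "HighBit": 11,
            "PixelRepresentation": 0,
            "RescaleIntercept": intercept,
            "RescaleSlope": 1.0,
            "PixelData": stored,
        }
        _dicomlite.write_file(series_dir / f"slice{z:04d}.dcm", ds)


def generate_cohort(spec: PhantomSpec, out_dir, fmt: str = "nifti") -> TruthTable:
    """Write one volume per patient under ``out_dir`` and return the truth.

    ``fmt`` is ``nifti`` (one ``P###.nii`` per patient) or ``dicom`` (one
    single-frame series directory per patient).
    """
    if fmt not in ("nifti", "dicom"):
        raise InvalidInputError(f"invalid input: unknown fixture format {fmt!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, pid in enumerate(patient_ids(spec)):
        volume = generate_volume(spec, i)
        if fmt == "nifti":
            _write_nifti(volume, out_dir / f"{pid}.nii", pid)
        else:
            _write_dicom_series(volume, out_dir / pid, pid)
    return truth_table(spec)


def generate_labeled_split(spec: PhantomSpec, train_fraction: float,
                           seed: int | None = None) -> Tuple[List[str], List[str]]:
    """Patient-level train/test split (never slice-level), seeded."""
    if not (0.0 < train_fraction < 1.0):
        raise InvalidInputError("invalid input: train_fraction must be in (0, 1)")
    pids = patient_ids(spec)
    n_train = int(round(train_fraction * len(pids)))
    if n_train == 0 or n_train == len(pids):
        raise DegenerateSplitError(
            f"degenerate split: fraction {train_fraction} on {len(pids)} patients"
        )
    rng = np.random.default_rng([spec.seed if seed is None else seed, 104729])
    order = rng.permutation(len(pids))
    train = sorted(pids[i] for i in order[:n_train])
    test = sorted(pids[i] for i in order[n_train:])
    return train, test


def with_separation(spec: PhantomSpec, separation: float) -> PhantomSpec:
    return replace(spec, separation=separation)
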