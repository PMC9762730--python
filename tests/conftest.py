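import numpy as np
import pytest

from rknet import _dicomlite
from rknet.imgio import SliceImage
from rknet.synthetic import PhantomSpec


@pytest.fixture
def make_dicom_series(tmp_path):
    """Factory writing a synthetic single-frame DICOM series.

    ``positions`` gives the through-plane z per file (file order = write
    order, not anatomical order).
    """

    def _make(positions=(30.0, 10.0, 20.0), *, series_uid="1.2.3.4", shape=(8, 8),
              slope=1.0, intercept=0.0, patient_name="DOE^JANE",
              stored_value=None, subdir="series", prefix=""):
        series_dir = tmp_path / subdir
        series_dir.mkdir(parents=True, exist_ok=True)
        for i, z in enumerate(positions):
            stored = np.full(shape, stored_value if stored_value is not None else 100 + i,
                             dtype="<u2")
            fname = f"{prefix}{series_uid.replace('.', '_')}_{i}.dcm"
            _dicomlite.write_file(series_dir / fname, {
                "SOPInstanceUID": f"{series_uid}.{i}",
                "Modality": "CT",
                "PatientName": patient_name,
                "PatientID": "PAT01",
                "PatientBirthDate": "19800101",
                "SeriesInstanceUID": series_uid,
                "InstanceNumber": i + 1,
                "ImagePositionPatient": [0.0, 0.0, float(z)],
                "SliceLocation": float(z),
                "Rows": shape[0],
                "Columns": shape[1],
                "BitsAllocated": 16,
                "BitsStored": 16,
                "HighBit": 15,
                "PixelRepresentation": 0,
                "RescaleIntercept": intercept,
                "RescaleSlope": slope,
                "PixelData": stored,
            })
        return series_dir

    return _make


@pytest.fixture
def make_nifti(tmp_path):
    """Factory writing a small NIfTI volume with a chosen affine."""
    import nibabel as nib

    def _make(shape=(4, 4, 5), affine=None, name="vol.nii", descrip=None, data=None):
        if data is None:
            rng = np.random.default_rng(0)
            data = rng.normal(0, 10, size=shape).astype(np.float32)
        img = nib.Nifti1Image(np.asarray(data, dtype=np.float32),
                              affine=np.eye(4) if affine is None else affine)
        if descrip is not None:
            img.header["descrip"] = descrip.encode("ascii")[:79]
        path = tmp_path / name
        nib.save(img, str(path))
        return path, np.asarray(data, dtype=np.float32)

    return _make


def make_slice(pixels, patient="P0", series="S0", index=0):
    return SliceImage(patient_id=patient, series_id=series, slice_index=index,
                      pixels=np.asarray(pixels, dtype=np.float64))


@pytest.fixture
def small_spec():
    """Phantom cohort small enough for per-test use."""
    return PhantomSpec(n_patients=4, n_slices=12, image_size=(32, 32),
                       tumor_run=(4, 7), separation=3.0, seed=0)
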