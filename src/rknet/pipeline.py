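"""End-to-end orchestration: ingest -> window/split -> embed -> cluster ->
map relevance -> sort PNGs into folders -> write CSV + JSON manifests.

Output layout::

    {output_root}/relevant/{patient_id}/{patient}_{series}_{idx:04d}.png
    {output_root}/irrelevant/{patient_id}/...
    {output_root}/manifest.csv        (RFC-4180, fixed header, stable order)
    {output_root}/run_manifest.json   (run id, config snapshot, counts, errors)

A re-run with the same inputs, config and seed reproduces the CSV body
byte-for-byte. Series that fail ingestion are logged, recorded in the JSON
manifest and skipped; only a run with zero successful series fails.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .clustering import (
    RELEVANT,
    kmeans_fit,
    map_clusters_to_relevance,
)
from .config import PipelineConfig
from .errors import EmptyRunError, RknetError, WriteError
from .features import ExtractorConfig, FeatureMatrix, SliceKey, extract_matrix
from .imgio import (
    AnonymizationPolicy,
    SliceImage,
    VolumeRecord,
    load_dicom_series,
    load_nifti_volume,
    split_axial,
    write_png,
)
from . import _dicomlite

logger = logging.getLogger(__name__)

MANIFEST_HEADER = [
    "patient_id", "series_id", "slice_index", "cluster", "relevance",
    "distance_to_centroid", "low_separation", "source_path", "output_path",
]


@dataclass
class ManifestRecord:
    patient_id: str
    series_id: str
    slice_index: int
    cluster: int
    relevance: str
    distance_to_centroid: float
    low_separation: bool
    source_path: str
    output_path: str

    def row(self) -> List[str]:
        return [
            self.patient_id, self.series_id, str(self.slice_index),
            str(self.cluster), self.relevance,
            f"{self.distance_to_centroid:.6f}",
            str(int(self.low_separation)),
            self.source_path, self.output_path,
        ]


@dataclass
class SliceManifest:
    records: List[ManifestRecord]
    run_id: str
    config_snapshot: dict
    counts: Dict[str, int]
    errors: List[dict] = field(default_factory=list)

    @property
    def n_slices(self) -> int:
        return len(self.records)


def discover_series(input_root) -> List[Tuple[str, Path]]:
    """Find ingestible inputs: NIfTI files anywhere under the root, and
    directories whose immediate files are DICOM."""
    root = Path(input_root)
    found: List[Tuple[str, Path]] = []
    if not root.exists():
        return found
    for path in sorted(root.rglob("*")):
        if path.is_file() and (path.name.endswith(".nii") or path.name.endswith(".nii.gz")):
            found.append(("nifti", path))
        elif path.is_dir():
            files = [p for p in path.iterdir() if p.is_file()]
            if files and any(_dicomlite.looks_like_dicom(p) for p in files):
                found.append(("dicom", path))
    return found


def ingest_series(kind: str, path: Path, policy: AnonymizationPolicy) -> VolumeRecord:
    if kind == "dicom":
        return load_dicom_series(path, policy)
    return load_nifti_volume(path, policy)


def _cluster_and_map(matrix: FeatureMatrix, config: PipelineConfig,
                     exemplars: Optional[Sequence[SliceKey]]):
    model = kmeans_fit(
        matrix, k=config.k, init_method=config.init_method, seed=config.seed,
        max_iter=config.max_iter, tol=config.tol, n_restarts=config.n_restarts,
    )
    mapping = map_clusters_to_relevance(model, matrix, rule=config.rule,
                                        exemplars=exemplars)
    sep = float(np.linalg.norm(model.centroids[0] - model.centroids[1]))
    low_sep = sep < config.min_centroid_separation
    return model, mapping, low_sep


def run_rknet(input_root, output_root, config: PipelineConfig | None = None,
              exemplars: Optional[Sequence[SliceKey]] = None,
              policy: AnonymizationPolicy | None = None) -> SliceManifest:
    """Run the full filtering flow over every series under ``input_root``."""
    config = config or PipelineConfig()
    policy = policy or AnonymizationPolicy()
    output_root = Path(output_root)
    output_root.mkdir(parents=True, exist_ok=True)
    exemplars = [tuple(e) for e in exemplars] if exemplars else None

    series_slices: List[List[SliceImage]] = []
    errors: List[dict] = []
    for kind, path in discover_series(input_root):
        try:
            volume = ingest_series(kind, path, policy)
            slices = split_axial(volume, config.window_center, config.window_width,
                                 source_path=str(path))
            series_slices.append(slices)
            logger.info("ingested %s series %s: %d slices", kind, path, len(slices))
        except RknetError as exc:
            logger.warning("skipping %s: %s", path, exc)
            errors.append({"path": str(path), "error": str(exc)})
    if not series_slices:
        raise EmptyRunError(f"empty run: no series ingested from {input_root}")

    ext_cfg = ExtractorConfig(name=config.extractor_name, input_size=config.input_size)

    # (matrix, model, mapping, low_sep) per clustering unit
    units = []
    if config.scope == "per-series":
        for slices in series_slices:
            matrix = extract_matrix(slices, ext_cfg, config.normalize_features)
            keys = set(matrix.row_keys)
            unit_ex = [e for e in exemplars if e in keys] if exemplars else None
            units.append((slices, matrix, *_cluster_and_map(matrix, config, unit_ex)))
    else:
        all_slices = [s for slices in series_slices for s in slices]
        matrix = extract_matrix(all_slices, ext_cfg, config.normalize_features)
        units.append((all_slices, matrix, *_cluster_and_map(matrix, config, exemplars)))

    records: List[ManifestRecord] = []
    for slices, matrix, model, mapping, low_sep in units:
        for row, slice_image in enumerate(slices):
            cluster = int(model.assignments[row])
            relevance = mapping[cluster]
            dist = float(np.linalg.norm(matrix.values[row] - model.centroids[cluster]))
            out_dir = output_root / relevance / slice_image.patient_id
            out_path = write_png(slice_image, out_dir)
            records.append(ManifestRecord(
                patient_id=slice_image.patient_id,
                series_id=slice_image.series_id,
                slice_index=slice_image.slice_index,
                cluster=cluster,
                relevance=relevance,
                distance_to_centroid=dist,
                low_separation=low_sep,
                source_path=slice_image.source_path,
                output_path=out_path,
            ))

    records.sort(key=lambda r: (r.patient_id, r.series_id, r.slice_index))
    counts = {RELEVANT: 0, "irrelevant": 0}
    for r in records:
        counts[r.relevance] += 1

    snapshot = config.to_dict()
    run_id = hashlib.sha256(
        json.dumps({"config": snapshot, "input": str(input_root)},
                   sort_keys=True).encode()
    ).hexdigest()[:16]

    manifest = SliceManifest(
        records=records, run_id=run_id, config_snapshot=snapshot,
        counts=counts, errors=errors,
    )
    write_manifest_csv(manifest, output_root / "manifest.csv")
    _write_run_manifest(manifest, output_root / "run_manifest.json")
    return manifest


def write_manifest_csv(manifest: SliceManifest, path) -> str:
    """RFC-4180 CSV (CRLF, UTF-8) with a fixed header and stable row order."""
    path = Path(path)
    try:
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(MANIFEST_HEADER)
            for record in manifest.records:
                writer.writerow(record.row())
    except OSError as exc:
        raise WriteError(f"write error: {path}: {exc}") from exc
    return str(path)


def _write_run_manifest(manifest: SliceManifest, path: Path) -> None:
    payload = {
        "run_id": manifest.run_id,
        "config": manifest.config_snapshot,
        "counts": manifest.counts,
        "n_records": manifest.n_slices,
        "errors": manifest.errors,
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_manifest_csv(path) -> List[dict]:
    with open(path, newline="", encoding="utf-8") as fh:
        return list(csv.DictReader(fh))


def default_exemplars(spec, n_exemplars: int = 3) -> List[SliceKey]:
    """A few known tumor-level keys per phantom patient (mid-run slices),
    emulating the handful of slices a radiologist would point at."""
    from . import synthetic

    start, end = spec.tumor_run
    mid = (start + end) // 2
    picks = [mid + off for off in (0, -1, 1, -2, 2)][:n_exemplars]
    picks = [z for z in picks if start <= z <= end]
    return [(pid, pid, z) for pid in synthetic.patient_ids(spec) for z in picks]


def filter_phantom_cohort(spec, config: PipelineConfig | None = None,
                          n_exemplars: int = 3) -> Dict[SliceKey, str]:
    """Run window -> embed -> cluster -> map on an in-memory phantom cohort.

    Skips file round-trips (which the disk pipeline covers elsewhere) so
    sweeps over many seeds/separations stay cheap. Returns the predicted
    relevance per slice key.
    """
    from . import synthetic
    from .imgio import SliceImage as _SliceImage

    config = config or PipelineConfig(rule="exemplar")
    ext_cfg = ExtractorConfig(name=config.extractor_name, input_size=config.input_size)
    exemplars = default_exemplars(spec, n_exemplars) if config.rule == "exemplar" else None

    lo = config.window_center - config.window_width / 2.0
    predicted: Dict[SliceKey, str] = {}
    for i, pid in enumerate(synthetic.patient_ids(spec)):
        volume = synthetic.generate_volume(spec, i)
        slices = [
            _SliceImage(pid, pid, z,
                        np.clip((volume[z] - lo) / config.window_width, 0.0, 1.0))
            for z in range(volume.shape[0])
        ]
        matrix = extract_matrix(slices, ext_cfg, config.normalize_features)
        unit_ex = ([e for e in exemplars if e[0] == pid] if exemplars else None)
        model, mapping, _ = _cluster_and_map(matrix, config, unit_ex)
        for row, s in enumerate(slices):
            predicted[s.key] = mapping[int(model.assignments[row])]
    return predicted


def recovery_rate(predicted: Dict[SliceKey, str], truth) -> float:
    """Fraction of truth tumor-level slices predicted relevant."""
    keys = truth.relevant_keys()
    if not keys:
        return float("nan")
    hit = sum(1 for key in keys if predicted.get(key) == RELEVANT)
    return hit / len(keys)
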