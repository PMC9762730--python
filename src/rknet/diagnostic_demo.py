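"""Desk-scale stand-in for the downstream diagnostic model.

A multinomial logistic (linear softmax) classifier trained with mini-batch
SGD and cross-entropy loss replaces the GPU-scale CNN: the comparison of
interest is between *training data* variants (unfiltered vs filtered vs
oracle-screened slices), not backbone capacity. Defaults copy the original
training recipe: learning rate 0.1, batch size 32, cross-entropy.

Slice-level training labels inherit the patient class. Test metrics are
reported both per slice and per patient (majority vote over the patient's
test slices).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import PipelineConfig
from .errors import ConfigError, DegenerateLabelsError, InvalidInputError
from .features import ExtractorConfig, SliceKey, extract_matrix, zscore_columns
from .metrics import MetricsReport, evaluate
from .pipeline import RELEVANT


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.1
    batch_size: int = 32
    n_steps: int = 400
    seed: int = 0
    shuffle: bool = True  # reshuffle the sample order every epoch

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")
        if self.n_steps < 1:
            raise ConfigError("n_steps must be >= 1")


@dataclass
class TrainTrace:
    losses: List[float] = field(default_factory=list)
    accuracies: List[float] = field(default_factory=list)
    test_report: Optional[MetricsReport] = None

    @property
    def final_loss(self) -> float:
        return self.losses[-1]

    @property
    def final_accuracy(self) -> float:
        return self.accuracies[-1]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class LinearModel:
    weights: np.ndarray          # (d + 1, n_classes), last row is the bias
    classes: List[object]

    def predict(self, X: np.ndarray) -> List[object]:
        Xb = np.hstack([X, np.ones((X.shape[0], 1))])
        idx = np.argmax(Xb @ self.weights, axis=1)
        return [self.classes[i] for i in idx]


def train_linear_sgd(features: np.ndarray, labels: Sequence[object],
                     cfg: TrainConfig | None = None) -> Tuple[LinearModel, TrainTrace]:
    """Mini-batch SGD on softmax cross-entropy; deterministic per seed.

    Records batch loss and batch accuracy at every step.
    """
    cfg = cfg or TrainConfig()
    X = np.asarray(features, dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("invalid input: non-finite features")
    classes = sorted(set(labels), key=str)
    if len(classes) < 2:
        raise DegenerateLabelsError("degenerate labels: need >=2 classes")
    class_index = {c: i for i, c in enumerate(classes)}
    y = np.array([class_index[l] for l in labels], dtype=np.intp)
    n, d = X.shape
    Xb = np.hstack([X, np.ones((n, 1))])
    onehot = np.eye(len(classes))[y]

    rng = np.random.default_rng(cfg.seed)
    W = np.zeros((d + 1, len(classes)))
    trace = TrainTrace()
    order = np.arange(n)
    pos = n  # force an initial (re)shuffle
    for _ in range(cfg.n_steps):
        if pos + cfg.batch_size > n:
            order = rng.permutation(n) if cfg.shuffle else np.arange(n)
            pos = 0
        batch = order[pos:pos + cfg.batch_size]
        pos += cfg.batch_size

        logits = Xb[batch] @ W
        probs = _softmax(logits)
        eps = 1e-12
        loss = -np.mean(np.log(probs[np.arange(len(batch)), y[batch]] + eps))
        acc = float(np.mean(np.argmax(probs, axis=1) == y[batch]))
        grad = Xb[batch].T @ (probs - onehot[batch]) / len(batch)
        W -= cfg.learning_rate * grad
        trace.losses.append(float(loss))
        trace.accuracies.append(acc)

    return LinearModel(weights=W, classes=classes), trace


@dataclass
class DemoCohort:
    """Slice features plus everything needed to form the comparison arms."""

    features: np.ndarray                 # (n_slices_total, d), z-scored
    keys: List[SliceKey]
    slice_relevant: Dict[SliceKey, bool]          # ground truth
    predicted_relevant: Dict[SliceKey, bool]      # composite-filter output
    patient_class: Dict[str, str]
    train_patients: List[str]
    test_patients: List[str]


def build_demo_cohort(spec, train_fraction: float = 0.75,
                      pipeline_config: PipelineConfig | None = None) -> DemoCohort:
    """Generate phantoms in memory, embed all slices, and run the filter."""
    from . import synthetic

    pipeline_config = pipeline_config or PipelineConfig(rule="exemplar", seed=spec.seed)
    truth = synthetic.truth_table(spec)
    train_patients, test_patients = synthetic.generate_labeled_split(spec, train_fraction)

    ext_cfg = ExtractorConfig(name=pipeline_config.extractor_name,
                              input_size=pipeline_config.input_size)
    lo = pipeline_config.window_center - pipeline_config.window_width / 2.0
    from .imgio import SliceImage
    from .pipeline import _cluster_and_map, default_exemplars

    exemplars = (default_exemplars(spec) if pipeline_config.rule == "exemplar" else None)

    # single pass per patient: one extraction feeds both the per-series
    # clustering (normalized per series) and the pooled classifier features
    predicted: Dict[SliceKey, str] = {}
    keys: List[SliceKey] = []
    raw_rows: List[np.ndarray] = []
    for i, pid in enumerate(synthetic.patient_ids(spec)):
        volume = synthetic.generate_volume(spec, i)
        slices = [
            SliceImage(pid, pid, z,
                       np.clip((volume[z] - lo) / pipeline_config.window_width, 0.0, 1.0))
            for z in range(volume.shape[0])
        ]
        series_matrix = extract_matrix(slices, ext_cfg, do_normalize=False)
        raw_rows.append(series_matrix.values)
        keys.extend(series_matrix.row_keys)
        series_matrix.values = zscore_columns(series_matrix.values)
        series_matrix.normalized = True
        unit_ex = ([e for e in exemplars if e[0] == pid] if exemplars else None)
        model, mapping, _ = _cluster_and_map(series_matrix, pipeline_config, unit_ex)
        for row, s in enumerate(slices):
            predicted[s.key] = mapping[int(model.assignments[row])]

    values = zscore_columns(np.vstack(raw_rows))

    slice_relevant = {
        (r.patient_id, r.series_id, r.slice_index): bool(r.relevant)
        for r in truth.slices.itertuples(index=False)
    }
    patient_class = dict(zip(truth.patients["patient_id"], truth.patients["class_label"]))
    return DemoCohort(
        features=values,
        keys=keys,
        slice_relevant=slice_relevant,
        predicted_relevant={k: v == RELEVANT for k, v in predicted.items()},
        patient_class=patient_class,
        train_patients=list(train_patients),
        test_patients=list(test_patients),
    )


ARM_UNFILTERED = "unfiltered"
ARM_FILTERED = "rknet-filtered"
ARM_ORACLE = "oracle-screened"
ALL_ARMS = (ARM_UNFILTERED, ARM_FILTERED, ARM_ORACLE)


@dataclass
class ArmResult:
    arm: str
    trace: TrainTrace
    slice_metrics: MetricsReport
    patient_metrics: MetricsReport
    n_train_slices: int


def _train_mask(cohort: DemoCohort, arm: str) -> np.ndarray:
    train_set = set(cohort.train_patients)
    mask = np.zeros(len(cohort.keys), dtype=bool)
    for i, key in enumerate(cohort.keys):
        if key[0] not in train_set:
            continue
        if arm == ARM_UNFILTERED:
            keep = True
        elif arm == ARM_ORACLE:
            keep = cohort.slice_relevant[key]
        elif arm == ARM_FILTERED:
            keep = cohort.predicted_relevant.get(key, False)
        else:
            raise InvalidInputError(f"invalid input: unknown arm {arm!r}")
        mask[i] = keep
    return mask


def compare_filtering_arms(cohort: DemoCohort, arms: Sequence[str] = ALL_ARMS,
                           cfg: TrainConfig | None = None) -> Dict[str, ArmResult]:
    """Train the identical classifier per arm and evaluate on held-out
    patients.

    The test set is fixed across arms (truth tumor-level slices of the test
    patients) so accuracies are directly comparable; empty arms are recorded
    and skipped.
    """
    from . import synthetic

    cfg = cfg or TrainConfig()
    test_set = set(cohort.test_patients)
    test_idx = [i for i, key in enumerate(cohort.keys)
                if key[0] in test_set and cohort.slice_relevant[key]]
    test_X = cohort.features[test_idx]
    test_keys = [cohort.keys[i] for i in test_idx]
    test_truth = [cohort.patient_class[key[0]] for key in test_keys]

    results: Dict[str, ArmResult] = {}
    for arm in arms:
        mask = _train_mask(cohort, arm)
        if not mask.any():
            results[arm] = ArmResult(arm=arm, trace=TrainTrace(),
                                     slice_metrics=None, patient_metrics=None,
                                     n_train_slices=0)
            continue
        labels = [cohort.patient_class[cohort.keys[i][0]] for i in np.where(mask)[0]]
        model, trace = train_linear_sgd(cohort.features[mask], labels, cfg)

        pred = model.predict(test_X)
        slice_metrics = evaluate(pred, test_truth, positive_label=synthetic.CLASS1)

        per_patient_votes: Dict[str, List[object]] = {}
        for key, p in zip(test_keys, pred):
            per_patient_votes.setdefault(key[0], []).append(p)
        patients = sorted(per_patient_votes)
        patient_pred = []
        for pid in patients:
            votes = per_patient_votes[pid]
            # majority vote, deterministic tie-break by class name
            patient_pred.append(max(sorted(set(votes), key=str), key=votes.count))
        patient_truth = [cohort.patient_class[pid] for pid in patients]
        patient_metrics = evaluate(patient_pred, patient_truth,
                                   positive_label=synthetic.CLASS1)

        trace.test_report = slice_metrics
        results[arm] = ArmResult(arm=arm, trace=trace, slice_metrics=slice_metrics,
                                 patient_metrics=patient_metrics,
                                 n_train_slices=int(mask.sum()))
    return results
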