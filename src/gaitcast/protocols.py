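"""Intra-subject and inter-subject (leave-one-out) evaluation protocols.

*Intra-subject*: for each subject, pool all speed conditions, split the
windows randomly 70/30, train on 70% and report metrics on the held-out
30%.  *Inter-subject*: for each subject, train on the pooled windows of
every other subject and test on all of the held-out subject's windows.
In both protocols the z-score normalizer is fitted on the training
windows only and applied unchanged to the test windows.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import asdict, dataclass, field

import numpy as np

from . import metrics as mx
from .errors import ValidationError
from .forecaster import ForecastConfig, build_model, split_validation, train
from .io_preprocess import SensorRecording
from .phase_labeling import FootSwitchTrace, debounce, detect_events, label_phases
from .windowing import WindowSpec, WindowedDataset, make_windows, select_trajectory_targets

SEGMENTS = ("thigh", "shank", "foot")
TRAIN_FRACTION = 0.7
VAL_FRACTION = 0.15  # of the training pool, for early stopping


@dataclass
class SubjectResult:
    """Metrics for one evaluation fold (one subject's test set)."""

    subject_id: str
    n_train: int
    n_test: int
    trajectory: dict[str, dict] | None = None  # per segment
    per_frame_mae: list[float] | None = None
    per_phase_error: dict[str, dict] | None = None
    phase: dict | None = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class EvaluationReport:
    """Aggregated outcome of one protocol run."""

    protocol: str  # "intra" or "inter"
    task: str
    config: dict
    seed: int
    subjects: list[SubjectResult] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "task": self.task,
            "config": self.config,
            "seed": self.seed,
            "subjects": [s.to_dict() for s in self.subjects],
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "EvaluationReport":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        subjects = [SubjectResult(**s) for s in payload.pop("subjects")]
        return cls(subjects=subjects, **payload)

    def mean_metric(self, segment: str, name: str) -> float:
        vals = [s.trajectory[segment][name] for s in self.subjects if s.trajectory]
        return float(np.mean(vals))

    def mean_accuracy(self) -> float:
        vals = [s.phase["accuracy"] for s in self.subjects if s.phase]
        return float(np.mean(vals))


def label_recording(rec: SensorRecording, ipsi_side: str = "right",
                    min_duration: int = 2):
    """Foot-switch pipeline: debounce, detect events, label phases."""
    if rec.footswitches is None:
        raise ValidationError("recording has no footswitch channels")
    left = FootSwitchTrace("contralateral" if ipsi_side == "right" else "ipsilateral",
                           rec.footswitches[:, :4])
    right = FootSwitchTrace("ipsilateral" if ipsi_side == "right" else "contralateral",
                            rec.footswitches[:, 4:])
    ipsi, contra = (right, left) if ipsi_side == "right" else (left, right)
    ipsi = debounce(ipsi, min_duration)
    contra = debounce(contra, min_duration)
    events = detect_events(ipsi, contra)
    return label_phases(events, rec.n_samples)


def window_cohort(cohort: list[SensorRecording], spec: WindowSpec,
                  ipsi_side: str = "right") -> WindowedDataset:
    """Label and window every recording, then pool the windows."""
    parts = []
    for rec in cohort:
        labels = label_recording(rec, ipsi_side)
        targets = select_trajectory_targets(rec, side=ipsi_side)
        parts.append(make_windows(rec, labels, spec, targets))
    return WindowedDataset.concatenate(parts)


def _apply_norm(ds: WindowedDataset, mean, sd, target_idx) -> WindowedDataset:
    """Z-score window tensors with training-set statistics.

    Trajectory targets are channels of the same recording, so they are
    scaled with the corresponding per-channel parameters; phase targets
    are untouched.
    """
    norm = WindowedDataset(
        inputs=((ds.inputs - mean) / sd).astype(np.float32),
        targets_trajectory=((ds.targets_trajectory - mean[target_idx]) / sd[target_idx]).astype(np.float32),
        targets_phase=ds.targets_phase.astype(np.float32),
        subjects=ds.subjects,
        speeds=ds.speeds,
        starts=ds.starts,
        target_channel_names=ds.target_channel_names,
        n_dropped=ds.n_dropped,
    )
    return norm


def _target_indices(cohort: list[SensorRecording], names: tuple[str, ...]) -> np.ndarray:
    rec = cohort[0]
    return np.array([rec.channel_index(n) for n in names])


def _evaluate_fold(model, test_ds: WindowedDataset, task: str) -> dict:
    if task == "phase":
        pred = model.predict_labels(test_ds.inputs)
        true = test_ds.phase_labels
        return {"phase": mx.evaluate_phase(true, pred).to_dict()}
    pred = model.predict(test_ds.inputs)
    true = test_ds.targets_trajectory
    per_segment = {}
    names = test_ds.target_channel_names
    for d, name in enumerate(names):
        segment = next((s for s in SEGMENTS if s in name), name)
        per_segment[segment] = mx.evaluate_trajectory(true[:, :, d], pred[:, :, d]).to_dict()
    err = (true - pred).mean(axis=2)  # signed error pooled over channels, (n, f)
    stats = mx.per_phase_error_stats(err, test_ds.phase_labels)
    return {
        "trajectory": per_segment,
        "per_frame_mae": mx.per_frame_mae(true, pred).tolist(),
        "per_phase_error": stats,
    }


def _train_and_eval(config: ForecastConfig, train_ds: WindowedDataset,
                    test_ds: WindowedDataset, target_idx: np.ndarray,
                    subject_id: str) -> SubjectResult:
    mean, sd = _fit_stats(train_ds)
    train_n = _apply_norm(train_ds, mean, sd, target_idx)
    test_n = _apply_norm(test_ds, mean, sd, target_idx)
    fit_part, val_part = split_validation(train_n, VAL_FRACTION, config.seed)
    n_targets = 5 if config.task == "phase" else train_ds.targets_trajectory.shape[2]
    model = build_model(config, train_ds.inputs.shape[2], n_targets)
    train(model, fit_part, val_part)
    result = SubjectResult(
        subject_id=subject_id, n_train=len(train_ds), n_test=len(test_ds),
        **_evaluate_fold(model, test_n, config.task),
    )
    return result


def _fit_stats(train_ds: WindowedDataset, sd_floor: float = 1e-8):
    flat = train_ds.inputs.reshape(-1, train_ds.inputs.shape[2])
    mean = flat.mean(axis=0)
    sd = np.maximum(flat.std(axis=0), sd_floor)
    return mean, sd


def run_intra(cohort: list[SensorRecording], config: ForecastConfig,
              split_seed: int = 0, window_spec: WindowSpec | None = None,
              ipsi_side: str = "right") -> EvaluationReport:
    """70/30 within-subject evaluation, one fold per subject.

    All speed conditions of a subject are pooled before the random
    window-level split; the split is reproducible from ``split_seed``.
    Subjects with too few windows to split are skipped with a warning.
    """
    if window_spec is None:
        window_spec = WindowSpec(p=config.p, f=config.f)
    target_idx = _target_indices(cohort, tuple(select_trajectory_targets(cohort[0], ipsi_side)))
    report = EvaluationReport(protocol="intra", task=config.task,
                              config=asdict(config), seed=split_seed)
    subjects = sorted({rec.subject_id for rec in cohort})
    for subject in subjects:
        recs = [r for r in cohort if r.subject_id == subject]
        pooled = window_cohort(recs, window_spec, ipsi_side)
        if len(pooled) < 10:
            warnings.warn(f"subject {subject}: too few windows for a 70/30 split")
            continue
        rng = np.random.default_rng((split_seed, zlib.crc32(subject.encode())))
        order = rng.permutation(len(pooled))
        n_train = int(round(TRAIN_FRACTION * len(pooled)))
        train_ds = pooled.subset(order[:n_train])
        test_ds = pooled.subset(order[n_train:])
        report.subjects.append(
            _train_and_eval(config, train_ds, test_ds, target_idx, subject)
        )
    return report


def run_inter(cohort: list[SensorRecording], config: ForecastConfig,
              window_spec: WindowSpec | None = None,
              ipsi_side: str = "right") -> EvaluationReport:
    """Leave-one-subject-out evaluation, one fold per held-out subject."""
    subjects = sorted({rec.subject_id for rec in cohort})
    if len(subjects) < 2:
        raise ValidationError("inter-subject protocol requires >= 2 subjects")
    if window_spec is None:
        window_spec = WindowSpec(p=config.p, f=config.f)
    target_idx = _target_indices(cohort, tuple(select_trajectory_targets(cohort[0], ipsi_side)))
    pooled = window_cohort(cohort, window_spec, ipsi_side)
    report = EvaluationReport(protocol="inter", task=config.task,
                              config=asdict(config), seed=config.seed)
    for subject in subjects:
        held_out = pooled.subjects == subject
        train_ds = pooled.subset(~held_out)
        test_ds = pooled.subset(held_out)
        assert not np.any(train_ds.subjects == subject)  # provenance audit
        report.subjects.append(
            _train_and_eval(config, train_ds, test_ds, target_idx, subject)
        )
    return report
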