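"""Sliding-window construction of (past, future) training pairs.

A window anchored at ``start`` pairs the ``p`` input samples
``[start, start+p)`` with the ``f`` target samples ``[start+p, start+p+f)``.
With stride ``slide`` the number of windows in an M-sample recording is
``floor((M - p - f) / slide) + 1`` (zero when ``M < p + f``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .io_preprocess import SensorRecording
from .phase_labeling import N_PHASES, UNLABELED, PhaseSequence, one_hot

#: Default sagittal-plane (mediolateral) gyroscope axis per site.  The
#: mounting convention is configuration, not a property of the data.
DEFAULT_SAGITTAL_AXIS = "z"


@dataclass(frozen=True)
class WindowSpec:
    """Input length ``p``, horizon ``f`` and stride, all in samples.

    At the 50 Hz working rate the standard configurations are
    ``(p=10, f=5)`` for 100 ms ahead and ``(p=30, f=10)`` for 200 ms ahead.
    """

    p: int = 30
    f: int = 10
    slide: int = 1

    def __post_init__(self) -> None:
        if self.p < 1 or self.f < 1 or self.slide < 1:
            raise ValidationError("p, f and slide must all be >= 1")

    def n_windows(self, M: int) -> int:
        if M < self.p + self.f:
            return 0
        return (M - self.p - self.f) // self.slide + 1


@dataclass
class WindowedDataset:
    """Aligned window tensors with per-window provenance.

    ``inputs`` is (n, p, N); ``targets_trajectory`` (n, f, D) holds the
    future values of the selected target channels; ``targets_phase``
    (n, f, 5) holds one-hot phase labels.  ``subjects``, ``speeds`` and
    ``starts`` record where each window came from so that evaluation
    protocols can audit train/test separation.
    """

    inputs: np.ndarray
    targets_trajectory: np.ndarray
    targets_phase: np.ndarray
    subjects: np.ndarray
    speeds: np.ndarray
    starts: np.ndarray
    target_channel_names: tuple[str, ...] = ()
    n_dropped: int = 0

    def __post_init__(self) -> None:
        n = len(self.inputs)
        for arr in (self.targets_trajectory, self.targets_phase, self.subjects,
                    self.speeds, self.starts):
            if len(arr) != n:
                raise ValidationError("window tensors must share their first axis")

    def __len__(self) -> int:
        return len(self.inputs)

    @property
    def phase_labels(self) -> np.ndarray:
        """(n, f) integer phase codes recovered from the one-hot targets."""
        return np.argmax(self.targets_phase, axis=2)

    def subset(self, idx: np.ndarray) -> "WindowedDataset":
        return WindowedDataset(
            inputs=self.inputs[idx],
            targets_trajectory=self.targets_trajectory[idx],
            targets_phase=self.targets_phase[idx],
            subjects=self.subjects[idx],
            speeds=self.speeds[idx],
            starts=self.starts[idx],
            target_channel_names=self.target_channel_names,
        )

    @staticmethod
    def concatenate(parts: list["WindowedDataset"]) -> "WindowedDataset":
        parts = [d for d in parts if len(d) > 0]
        if not parts:
            raise ValidationError("no non-empty datasets to concatenate")
        names = parts[0].target_channel_names
        if any(d.target_channel_names != names for d in parts):
            raise ValidationError("datasets have mismatched target channels")
        return WindowedDataset(
            inputs=np.concatenate([d.inputs for d in parts]),
            targets_trajectory=np.concatenate([d.targets_trajectory for d in parts]),
            targets_phase=np.concatenate([d.targets_phase for d in parts]),
            subjects=np.concatenate([d.subjects for d in parts]),
            speeds=np.concatenate([d.speeds for d in parts]),
            starts=np.concatenate([d.starts for d in parts]),
            target_channel_names=names,
            n_dropped=sum(d.n_dropped for d in parts),
        )

    def save(self, path) -> None:
        np.savez(
            path,
            inputs=self.inputs,
            targets_trajectory=self.targets_trajectory,
            targets_phase=self.targets_phase,
            subjects=self.subjects,
            speeds=self.speeds,
            starts=self.starts,
            target_channel_names=np.array(self.target_channel_names),
            n_dropped=self.n_dropped,
        )

    @classmethod
    def load(cls, path) -> "WindowedDataset":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                inputs=z["inputs"],
                targets_trajectory=z["targets_trajectory"],
                targets_phase=z["targets_phase"],
                subjects=z["subjects"],
                speeds=z["speeds"],
                starts=z["starts"],
                target_channel_names=tuple(z["target_channel_names"]),
                n_dropped=int(z["n_dropped"]),
            )


def select_trajectory_targets(
    rec: SensorRecording,
    side: str = "right",
    sagittal_axis: str | dict[str, str] = DEFAULT_SAGITTAL_AXIS,
) -> list[str]:
    """Names of the ipsilateral sagittal-plane angular-velocity channels.

    The evaluated trajectory is the angular velocity of the thigh, shank
    and foot of the analysed limb about the mediolateral axis.  Which local
    gyroscope axis that is depends on sensor mounting and is configurable
    per site.
    """
    if side not in ("left", "right"):
        raise ValidationError("side must be 'left' or 'right'")
    names = []
    for segment in ("thigh", "shank", "foot"):
        site = f"{side}_{segment}"
        axis = sagittal_axis if isinstance(sagittal_axis, str) else sagittal_axis[site]
        name = f"{site}_gyr_{axis}"
        rec.channel_index(name)  # raises ValidationError when absent
        names.append(name)
    return names


def make_windows(
    rec: SensorRecording,
    labels: PhaseSequence,
    spec: WindowSpec,
    target_channels: list[str] | None = None,
) -> WindowedDataset:
    """Slice one recording into aligned (input, target) window pairs.

    Windows whose target span contains unlabeled samples are dropped and
    counted in ``n_dropped``.  Recordings shorter than ``p + f`` produce an
    empty dataset with a warning.
    """
    if len(labels) != rec.n_samples:
        raise ValidationError("labels length must match the recording")
    if target_channels is None:
        target_channels = select_trajectory_targets(rec)
    target_idx = np.array([rec.channel_index(n) for n in target_channels])

    M, p, f = rec.n_samples, spec.p, spec.f
    n_total = spec.n_windows(M)
    if n_total == 0:
        warnings.warn(f"recording of {M} samples cannot fit p+f={p + f}; no windows")
        return _empty_dataset(p, rec.n_channels, f, len(target_idx), target_channels)

    starts = np.arange(n_total) * spec.slide
    target_spans = starts[:, None] + p + np.arange(f)[None, :]
    keep = (labels.labels[target_spans] != UNLABELED).all(axis=1)
    kept_starts = starts[keep]
    n = len(kept_starts)
    if n == 0:
        return _empty_dataset(p, rec.n_channels, f, len(target_idx), target_channels,
                              n_dropped=n_total)

    input_spans = kept_starts[:, None] + np.arange(p)[None, :]
    inputs = rec.samples[input_spans]
    tspans = kept_starts[:, None] + p + np.arange(f)[None, :]
    targets_trajectory = rec.samples[:, target_idx][tspans]
    phase_flat = one_hot(labels.labels[tspans].ravel())
    targets_phase = phase_flat.reshape(n, f, N_PHASES)

    return WindowedDataset(
        inputs=inputs,
        targets_trajectory=targets_trajectory,
        targets_phase=targets_phase,
        subjects=np.full(n, str(rec.subject_id)),
        speeds=np.full(n, rec.speed_level, dtype=np.int64),
        starts=kept_starts,
        target_channel_names=tuple(target_channels),
        n_dropped=n_total - n,
    )


def _empty_dataset(p, N, f, D, target_channels, n_dropped: int = 0) -> WindowedDataset:
    return WindowedDataset(
        inputs=np.empty((0, p, N)),
        targets_trajectory=np.empty((0, f, D)),
        targets_phase=np.empty((0, f, N_PHASES)),
        subjects=np.empty(0, dtype="U32"),
        speeds=np.empty(0, dtype=np.int64),
        starts=np.empty(0, dtype=np.int64),
        target_channel_names=tuple(target_channels),
        n_dropped=n_dropped,
    )
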