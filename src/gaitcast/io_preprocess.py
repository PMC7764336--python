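"""Reading, resampling and z-score normalization of multichannel IMU recordings.

A full recording carries 63 continuous channels — 7 sensor sites (pelvis,
both thighs, both shanks, both feet), each providing 3-axis acceleration,
angular velocity and magnetic field — plus an optional block of 8 binary
foot-switch channels (heel, first and fifth metatarsal heads, big toe on
each foot).  Column naming follows ``<site>_<modality>_<axis>`` for sensor
channels and ``fsw_<side>_<location>`` for switches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import FormatError, UnsupportedRateError, ValidationError

SITES = (
    "pelvis",
    "left_thigh",
    "right_thigh",
    "left_shank",
    "right_shank",
    "left_foot",
    "right_foot",
)
MODALITIES = ("acc", "gyr", "mag")
AXES = ("x", "y", "z")
FSW_SIDES = ("left", "right")
FSW_LOCATIONS = ("heel", "met1", "met5", "toe")

#: Floor applied to per-channel standard deviations so constant channels
#: normalize to zero instead of dividing by zero.
SD_FLOOR = 1e-8


@dataclass(frozen=True)
class ChannelDescriptor:
    """One continuous sensor channel: a (site, modality, axis) triple."""

    site: str
    modality: str
    axis: str

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValidationError(f"unknown sensor site {self.site!r}")
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r}")
        if self.axis not in AXES:
            raise ValidationError(f"unknown axis {self.axis!r}")

    @property
    def name(self) -> str:
        return f"{self.site}_{self.modality}_{self.axis}"

    @classmethod
    def from_name(cls, name: str) -> "ChannelDescriptor":
        parts = name.split("_")
        if len(parts) < 3:
            raise FormatError(f"cannot parse channel name {name!r}")
        site = "_".join(parts[:-2])
        return cls(site=site, modality=parts[-2], axis=parts[-1])


def canonical_channels() -> list[ChannelDescriptor]:
    """The 63 descriptors in canonical order: site-major, then modality, axis."""
    return [
        ChannelDescriptor(site, modality, axis)
        for site in SITES
        for modality in MODALITIES
        for axis in AXES
    ]


FOOTSWITCH_COLUMNS = tuple(
    f"fsw_{side}_{loc}" for side in FSW_SIDES for loc in FSW_LOCATIONS
)


@dataclass
class SensorRecording:
    """One subject's walk at one treadmill speed.

    ``samples`` is an (M, N) float matrix whose columns follow ``channels``;
    ``footswitches`` is an optional (M, 8) binary matrix ordered as
    :data:`FOOTSWITCH_COLUMNS`.
    """

    subject_id: str
    speed_level: int
    sample_rate: float
    samples: np.ndarray
    channels: list[ChannelDescriptor] = field(default_factory=canonical_channels)
    footswitches: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValidationError("samples must be a 2-D (M, N) matrix")
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")
        if self.samples.shape[1] != len(self.channels):
            raise ValidationError(
                f"{self.samples.shape[1]} sample columns but "
                f"{len(self.channels)} channel descriptors"
            )
        if self.footswitches is not None:
            self.footswitches = np.asarray(self.footswitches)
            if self.footswitches.shape != (self.samples.shape[0], 8):
                raise ValidationError("footswitches must be (M, 8)")
            if not np.isin(self.footswitches, (0, 1)).all():
                raise ValidationError("footswitch values must be binary (0/1)")
            self.footswitches = self.footswitches.astype(np.int8)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    def channel_index(self, name: str) -> int:
        for i, ch in enumerate(self.channels):
            if ch.name == name:
                return i
        raise ValidationError(f"channel {name!r} not present in recording")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.samples, columns=[c.name for c in self.channels])
        if self.footswitches is not None:
            for j, col in enumerate(FOOTSWITCH_COLUMNS):
                df[col] = self.footswitches[:, j]
        return df


@dataclass
class NormalizationParams:
    """Per-channel mean and standard deviation for z-score normalization.

    The standard deviation uses the population convention (divide by n) and
    is floored at ``sd_floor`` to keep constant channels finite.
    """

    mean: np.ndarray
    sd: np.ndarray
    channel_names: tuple[str, ...]
    sd_floor: float = SD_FLOOR

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if not (len(self.mean) == len(self.sd) == len(self.channel_names)):
            raise ValidationError("mean, sd and channel_names must align")
        if (self.sd < self.sd_floor).any():
            raise ValidationError("sd below sd_floor; use fit_normalizer")


def read_recording(
    path,
    subject_id: str | None = None,
    speed_level: int = 1,
    sample_rate: float = 50.0,
) -> SensorRecording:
    """Read a delimited-text recording with one header row.

    Sensor columns may appear in any order; they are returned in canonical
    order.  Foot-switch columns are attached when all 8 are present.
    Metadata not stored in the file (subject, speed, rate) is supplied by
    the caller.
    """
    df = pd.read_csv(path)
    if df.shape[0] == 0:
        raise ValidationError(f"no samples in {path}")
    cols = list(df.columns)
    expected = [c.name for c in canonical_channels()]
    missing = [name for name in expected if name not in cols]
    if missing:
        raise FormatError(
            f"missing channel column(s): {', '.join(missing[:5])}"
            + ("…" if len(missing) > 5 else "")
        )
    for name in expected:
        if cols.count(name) > 1:
            raise FormatError(f"duplicate channel column {name!r}")
    samples = df[expected].to_numpy(dtype=float)

    fsw = None
    present = [c for c in FOOTSWITCH_COLUMNS if c in cols]
    if present:
        if len(present) != 8:
            absent = sorted(set(FOOTSWITCH_COLUMNS) - set(present))
            raise FormatError(f"incomplete footswitch block; missing {absent}")
        fsw = df[list(FOOTSWITCH_COLUMNS)].to_numpy()
        if not np.isin(fsw, (0, 1)).all():
            raise ValidationError("non-binary footswitch values")
    return SensorRecording(
        subject_id=subject_id if subject_id is not None else str(path),
        speed_level=speed_level,
        sample_rate=sample_rate,
        samples=samples,
        channels=canonical_channels(),
        footswitches=fsw,
    )


def write_recording(rec: SensorRecording, path) -> None:
    """Write a recording as CSV in the same schema read_recording expects."""
    rec.to_frame().to_csv(path, index=False)


def downsample(rec: SensorRecording, target_rate: float) -> SensorRecording:
    """Decimate a recording to ``target_rate``.

    Continuous channels are low-pass filtered (zero-phase Butterworth,
    cutoff 0.4 x target rate) before taking every k-th sample, so
    high-frequency noise does not alias into the working band.  Binary
    foot-switch channels are instead decimated by majority vote within each
    k-sample block (ties count as "on"); filtering a binary signal is
    meaningless.  Output length is floor(M / k).
    """
    if target_rate <= 0:
        raise ValidationError("target_rate must be positive")
    ratio = rec.sample_rate / target_rate
    k = int(round(ratio))
    if abs(ratio - k) > 1e-9 or k < 1:
        raise UnsupportedRateError(
            f"{rec.sample_rate} Hz -> {target_rate} Hz is not an integer decimation"
        )
    if k == 1:
        return replace(rec)
    m_out = rec.n_samples // k
    if m_out == 0:
        raise ValidationError("recording shorter than one decimation block")

    sos = sps.butter(4, 0.4 * target_rate, btype="low", fs=rec.sample_rate, output="sos")
    padlen = min(rec.n_samples - 1, 3 * (2 * sos.shape[0] + 1))
    filtered = sps.sosfiltfilt(sos, rec.samples, axis=0, padlen=padlen)
    samples = filtered[: m_out * k : k]

    fsw = None
    if rec.footswitches is not None:
        blocks = rec.footswitches[: m_out * k].reshape(m_out, k, 8)
        # mean >= 0.5 implements majority vote with ties resolved to "on"
        fsw = (blocks.mean(axis=1) >= 0.5).astype(np.int8)
    return replace(rec, sample_rate=float(target_rate), samples=samples, footswitches=fsw)


def fit_normalizer(
    rec: SensorRecording,
    rows: np.ndarray | None = None,
    sd_floor: float = SD_FLOOR,
) -> NormalizationParams:
    """Fit per-channel z-score parameters on a row subset.

    Fitting on the training rows only (and applying to test rows) avoids
    leaking test statistics into the model.
    """
    data = rec.samples if rows is None else rec.samples[np.asarray(rows)]
    if data.shape[0] == 0:
        raise ValidationError("cannot fit normalizer on an empty row subset")
    if data.shape[0] == 1:
        warnings.warn("normalizer fitted on a single row; sd set to floor")
    mean = data.mean(axis=0)
    sd = data.std(axis=0)  # population convention (ddof=0)
    sd = np.maximum(sd, sd_floor)
    return NormalizationParams(
        mean=mean,
        sd=sd,
        channel_names=tuple(c.name for c in rec.channels),
        sd_floor=sd_floor,
    )


def _check_channels(rec: SensorRecording, params: NormalizationParams) -> None:
    names = tuple(c.name for c in rec.channels)
    if names != params.channel_names:
        raise ValidationError("normalizer channel set does not match recording")


def apply_normalizer(rec: SensorRecording, params: NormalizationParams) -> SensorRecording:
    """Return a copy with z-scored sensor channels; footswitches untouched."""
    _check_channels(rec, params)
    samples = (rec.samples - params.mean) / params.sd
    return replace(rec, samples=samples)


def invert_normalizer(rec: SensorRecording, params: NormalizationParams) -> SensorRecording:
    """Undo :func:`apply_normalizer` with the same parameters."""
    _check_channels(rec, params)
    samples = rec.samples * params.sd + params.mean
    return replace(rec, samples=samples)
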