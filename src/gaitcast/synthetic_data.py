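"""Quasi-periodic synthetic gait recordings with consistent foot switches.

Real treadmill walking is close to periodic: every continuous channel is
phase-locked to the stride.  The generator therefore builds each of the 63
sensor channels as a sum of harmonics of the stride frequency with
subject-specific random amplitudes and phase offsets, adds white noise,
and derives both feet's switch traces from the same cycle clock, so that
the canonical event sequence

    ipsi foot contact -> contra foot off -> ipsi heel off
        -> contra foot contact -> ipsi foot off

occurs at the cumulative phase-fraction boundaries of every cycle.  The
contralateral limb is the ipsilateral pattern shifted by exactly half a
cycle, which requires ``MS + TS + PSw = 0.5`` of the cycle (the default
fractions satisfy this).  Per-cycle duration jitter makes the signals
quasi-periodic rather than strictly periodic.

The default cycle duration is drawn per subject from 0.98-1.07 s, the
adult range; the five speed conditions scale stride frequency from 0.8x
to 1.2x.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io_preprocess import MODALITIES, SensorRecording, canonical_channels

#: Stride-frequency multipliers for the five ordinal speed conditions.
SPEED_FACTORS = (0.8, 0.9, 1.0, 1.1, 1.2)

#: Forefoot switch-on delays (fraction of cycle after foot contact).
MET_DELAY = 0.03
TOE_DELAY = 0.06


@dataclass(frozen=True)
class SyntheticGaitSpec:
    """Study-condition parameters of the synthetic cohort.

    ``cycle_duration=None`` draws a per-subject duration uniformly from
    0.98-1.07 s.  ``cycle_jitter`` is the fractional SD of per-cycle
    duration; ``noise_sd`` the white-noise SD in units of each channel's
    own signal SD; ``phase_fractions`` the (LR, MS, TS, PSw, Sw) shares of
    the cycle.
    """

    n_subjects: int = 12
    duration: float = 60.0
    sample_rate: float = 50.0
    cycle_duration: float | None = None
    cycle_jitter: float = 0.02
    phase_fractions: tuple[float, ...] = (0.10, 0.20, 0.20, 0.10, 0.40)
    n_harmonics: int = 4
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        fr = np.asarray(self.phase_fractions, dtype=float)
        if len(fr) != 5 or (fr <= 0).any():
            raise ValidationError("phase_fractions must be 5 positive numbers")
        if abs(fr.sum() - 1.0) > 1e-9:
            raise ValidationError("phase_fractions must sum to 1 within 1e-9")
        if abs(fr[1] + fr[2] + fr[3] - 0.5) > 1e-9:
            raise ValidationError(
                "half-cycle limb symmetry requires MS + TS + PSw = 0.5"
            )
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if self.duration <= 0 or self.sample_rate <= 0:
            raise ValidationError("duration and sample_rate must be positive")


def _cycle_starts(rng: np.random.Generator, base: float, jitter: float,
                  t_end: float, t_begin: float) -> np.ndarray:
    """Cycle start times covering [t_begin, t_end] with jittered durations."""
    starts = [t_begin]
    while starts[-1] < t_end:
        dur = base * max(0.2, 1.0 + jitter * rng.standard_normal())
        starts.append(starts[-1] + dur)
    return np.asarray(starts)


def _cycle_phase(t: np.ndarray, starts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(cycle index, within-cycle fraction in [0,1)) for each sample time."""
    idx = np.searchsorted(starts, t, side="right") - 1
    durs = np.diff(starts)
    frac = (t - starts[idx]) / durs[np.clip(idx, 0, len(durs) - 1)]
    return idx, frac


def _switch_trace(frac: np.ndarray, stance_end: float, heel_off: float) -> np.ndarray:
    """(M, 4) binary switches for one foot from its cycle fraction."""
    heel = (frac >= 0.0) & (frac < heel_off)
    met1 = (frac >= MET_DELAY) & (frac < stance_end)
    met5 = (frac >= MET_DELAY) & (frac < stance_end)
    toe = (frac >= TOE_DELAY) & (frac < stance_end)
    return np.column_stack([heel, met1, met5, toe]).astype(np.int8)


def _subject_channel_params(spec: SyntheticGaitSpec, subject_index: int):
    """Per-subject harmonic amplitudes/phases for all 63 channels."""
    rng = np.random.default_rng((spec.seed, subject_index, 0))
    n_ch = 63
    amps = rng.uniform(0.3, 1.0, size=(n_ch, spec.n_harmonics))
    amps *= 1.0 / (1.0 + np.arange(spec.n_harmonics))  # decaying spectrum
    phases = rng.uniform(0, 2 * np.pi, size=(n_ch, spec.n_harmonics))
    offsets = rng.uniform(-1.0, 1.0, size=n_ch)
    # magnetometer channels vary slowly: keep only the fundamental
    for i, ch in enumerate(canonical_channels()):
        if ch.modality == "mag":
            amps[i, 1:] = 0.0
            amps[i, 0] *= 0.3
    scale = {"acc": 9.81, "gyr": 3.0, "mag": 0.5}
    gains = np.array([scale[ch.modality] for ch in canonical_channels()])
    base_cycle = (
        spec.cycle_duration
        if spec.cycle_duration is not None
        else float(rng.uniform(0.98, 1.07))
    )
    return amps, phases, offsets, gains, base_cycle


def generate_subject(spec: SyntheticGaitSpec, subject_index: int,
                     speed_level: int) -> SensorRecording:
    """One recording: a subject walking at one of the five speed levels.

    Deterministic for a fixed spec seed; the same subject keeps the same
    channel parameters across speeds, only the stride frequency, jitter
    realisation and noise change.
    """
    if not 1 <= speed_level <= 5:
        raise ValidationError("speed_level must be in 1..5")
    amps, phases, offsets, gains, base_cycle = _subject_channel_params(spec, subject_index)
    cycle = base_cycle / SPEED_FACTORS[speed_level - 1]
    rng = np.random.default_rng((spec.seed, subject_index, speed_level))

    M = int(round(spec.duration * spec.sample_rate))
    t = np.arange(M) / spec.sample_rate
    # right (ipsilateral) clock starts one cycle before t=0 so that both
    # feet are mid-pattern at the first sample
    r_starts = _cycle_starts(rng, cycle, spec.cycle_jitter, t[-1] + 2 * cycle, -cycle)
    r_durs = np.diff(r_starts)
    l_starts = r_starts[:-1] + r_durs / 2.0  # half-cycle shifted

    r_idx, r_frac = _cycle_phase(t, r_starts)
    l_idx, l_frac = _cycle_phase(t, l_starts)

    fr = np.asarray(spec.phase_fractions)
    heel_off = fr[0] + fr[1]          # ipsi heel off boundary
    stance_end = 1.0 - fr[4]          # ipsi foot off boundary
    right = _switch_trace(r_frac, stance_end, heel_off)
    left = _switch_trace(l_frac, stance_end, heel_off)
    fsw = np.column_stack([left, right])  # column order: left block, right block

    harm = np.arange(1, spec.n_harmonics + 1)
    # global stride phase, continuous across cycles (jitter-coherent)
    g_phase = r_idx + r_frac
    angle = 2 * np.pi * g_phase[:, None] * harm[None, :]  # (M, n_harmonics)
    signals = np.empty((M, 63))
    for ch in range(63):
        clean = (amps[ch] * np.sin(angle + phases[ch])).sum(axis=1) + offsets[ch]
        signals[:, ch] = clean
    sds = signals.std(axis=0)
    if spec.noise_sd > 0:
        signals += rng.standard_normal((M, 63)) * (spec.noise_sd * sds)
    signals *= gains

    return SensorRecording(
        subject_id=f"S{subject_index:02d}",
        speed_level=speed_level,
        sample_rate=spec.sample_rate,
        samples=signals,
        channels=canonical_channels(),
        footswitches=fsw,
    )


def generate_cohort(spec: SyntheticGaitSpec) -> list[SensorRecording]:
    """All subjects at all five speed levels (n_subjects x 5 recordings)."""
    return [
        generate_subject(spec, s, level)
        for s in range(spec.n_subjects)
        for level in range(1, 6)
    ]
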