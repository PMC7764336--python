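"""Gait-phase ground truth from bilateral foot-switch traces.

Each foot carries four binary pressure switches (heel, first and fifth
metatarsal heads, big toe).  Switch on/off transitions define three events
per side — foot contact, heel off, foot off — and the events of both sides
partition each gait cycle of the analysed (ipsilateral) limb into five
phases:

=====  ==========================================================
LR     ipsilateral foot contact  -> contralateral foot off
MS     contralateral foot off    -> ipsilateral heel off
TS     ipsilateral heel off      -> contralateral foot contact
PSw    contralateral foot contact-> ipsilateral foot off
Sw     ipsilateral foot off      -> next ipsilateral foot contact
=====  ==========================================================

All intervals are half-open (start inclusive, end exclusive) so every
sample receives exactly one label.  Samples outside complete cycles are
marked :data:`UNLABELED` and excluded downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import PhaseLabelingError, ValidationError

PHASES = ("LR", "MS", "TS", "PSw", "Sw")
PHASE_CODES = {name: i for i, name in enumerate(PHASES)}
N_PHASES = 5
UNLABELED = -1

#: Switch column order within a single-foot trace.
SWITCH_LOCATIONS = ("heel", "met1", "met5", "toe")
HEEL = 0

FOOT_CONTACT = "foot_contact"
HEEL_OFF = "heel_off"
FOOT_OFF = "foot_off"


@dataclass
class FootSwitchTrace:
    """Binary (M, 4) switch matrix for one foot."""

    side: str  # "ipsilateral" or "contralateral"
    switches: np.ndarray

    def __post_init__(self) -> None:
        self.switches = np.asarray(self.switches)
        if self.switches.ndim != 2 or self.switches.shape[1] != 4:
            raise ValidationError("switches must be an (M, 4) matrix")
        if not np.isin(self.switches, (0, 1)).all():
            raise ValidationError("switch values must be binary (0/1)")
        self.switches = self.switches.astype(np.int8)

    def __len__(self) -> int:
        return self.switches.shape[0]


@dataclass
class GaitEvents:
    """Ordered (sample index, kind) event lists, one per side."""

    ipsi: list[tuple[int, str]] = field(default_factory=list)
    contra: list[tuple[int, str]] = field(default_factory=list)

    def of_kind(self, side: str, kind: str) -> list[int]:
        events = self.ipsi if side == "ipsi" else self.contra
        return [i for i, k in events if k == kind]


@dataclass
class PhaseSequence:
    """Per-sample integer phase codes (0-4), with -1 for unlabeled samples."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise ValidationError("labels must be a 1-D vector")
        bad = (self.labels < UNLABELED) | (self.labels >= N_PHASES)
        if bad.any():
            raise ValidationError("labels must lie in {-1, 0..4}")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def labeled_mask(self) -> np.ndarray:
        return self.labels != UNLABELED

    def names(self) -> list[str]:
        return [PHASES[c] if c != UNLABELED else "unlabeled" for c in self.labels]


def _merge_short_runs(column: np.ndarray, min_duration: int) -> np.ndarray:
    """Merge on/off runs shorter than min_duration into their neighbors."""
    vals = column.astype(np.int8).tolist()
    # run-length encode
    runs: list[list[int]] = []  # [value, length]
    for v in vals:
        if runs and runs[-1][0] == v:
            runs[-1][1] += 1
        else:
            runs.append([v, 1])
    changed = True
    while changed and len(runs) > 1:
        changed = False
        for i, (v, ln) in enumerate(runs):
            if ln < min_duration:
                runs[i][0] = 1 - v  # flip into neighbor value
                merged: list[list[int]] = []
                for val, length in runs:
                    if merged and merged[-1][0] == val:
                        merged[-1][1] += length
                    else:
                        merged.append([val, length])
                runs = merged
                changed = True
                break
    out = np.concatenate([np.full(ln, v, dtype=np.int8) for v, ln in runs])
    return out


def debounce(trace: FootSwitchTrace, min_duration: int = 2) -> FootSwitchTrace:
    """Remove switch glitches shorter than ``min_duration`` samples.

    Idempotent; ``min_duration=1`` is the identity.
    """
    if min_duration < 1:
        raise ValidationError("min_duration must be >= 1")
    if min_duration == 1:
        return FootSwitchTrace(trace.side, trace.switches.copy())
    cleaned = np.column_stack(
        [_merge_short_runs(trace.switches[:, j], min_duration) for j in range(4)]
    )
    return FootSwitchTrace(trace.side, cleaned)


def _detect_side(switches: np.ndarray) -> list[tuple[int, str]]:
    any_on = switches.any(axis=1)
    heel_on = switches[:, HEEL] == 1
    forefoot_on = switches[:, 1:].any(axis=1)
    events: list[tuple[int, str]] = []
    in_contact = bool(any_on[0])
    heel_was_on = bool(heel_on[0])
    for t in range(1, len(any_on)):
        if any_on[t] and not in_contact:
            events.append((t, FOOT_CONTACT))
            in_contact = True
            heel_was_on = bool(heel_on[t])
        elif in_contact:
            if heel_was_on and not heel_on[t] and forefoot_on[t]:
                events.append((t, HEEL_OFF))
                heel_was_on = False
            if not any_on[t]:
                events.append((t, FOOT_OFF))
                in_contact = False
            elif heel_on[t]:
                heel_was_on = True
    return events


def detect_events(ipsi: FootSwitchTrace, contra: FootSwitchTrace) -> GaitEvents:
    """Extract foot-contact / heel-off / foot-off events from both sides.

    Foot contact is the first sample where any switch turns on after an
    all-off period; heel off the first sample where the heel switch turns
    off while at least one forefoot switch remains on; foot off the first
    sample where all four switches are off after a contact period.
    """
    if len(ipsi) != len(contra):
        raise ValidationError("ipsi and contra traces must have equal length")
    events = GaitEvents(
        ipsi=_detect_side(ipsi.switches), contra=_detect_side(contra.switches)
    )
    for side, lst in (("ipsilateral", events.ipsi), ("contralateral", events.contra)):
        if not any(k == FOOT_CONTACT for _, k in lst):
            warnings.warn(f"no contact period detected on the {side} side")
    return events


def label_phases(events: GaitEvents, M: int) -> PhaseSequence:
    """Assign one of the five phase labels to every sample of a recording.

    Cycles are anchored at consecutive ipsilateral foot contacts.  Cycles
    truncated at the recording edges are left unlabeled; a complete cycle
    whose internal events are out of order raises
    :class:`~gaitcast.errors.PhaseLabelingError`.
    """
    labels = np.full(M, UNLABELED, dtype=np.int64)
    ipsi_fc = events.of_kind("ipsi", FOOT_CONTACT)
    ipsi_ho = events.of_kind("ipsi", HEEL_OFF)
    ipsi_fo = events.of_kind("ipsi", FOOT_OFF)
    contra_fc = events.of_kind("contra", FOOT_CONTACT)
    contra_fo = events.of_kind("contra", FOOT_OFF)

    def first_in(candidates: list[int], lo: int, hi: int) -> int | None:
        for c in candidates:
            if lo < c < hi:
                return c
        return None

    for k in range(len(ipsi_fc) - 1):
        fc, fc_next = ipsi_fc[k], ipsi_fc[k + 1]
        c_fo = first_in(contra_fo, fc, fc_next)
        ho = first_in(ipsi_ho, fc, fc_next)
        c_fc = first_in(contra_fc, fc, fc_next)
        fo = first_in(ipsi_fo, fc, fc_next)
        if None in (c_fo, ho, c_fc, fo):
            missing = [
                name
                for name, e in (
                    ("contralateral foot_off", c_fo),
                    ("ipsilateral heel_off", ho),
                    ("contralateral foot_contact", c_fc),
                    ("ipsilateral foot_off", fo),
                )
                if e is None
            ]
            raise PhaseLabelingError(
                f"cycle starting at sample {fc}: missing {', '.join(missing)}"
            )
        if not (fc < c_fo < ho < c_fc < fo < fc_next):
            raise PhaseLabelingError(
                f"cycle starting at sample {fc}: events out of canonical order "
                f"(contraFO={c_fo}, ipsiHO={ho}, contraFC={c_fc}, ipsiFO={fo})"
            )
        labels[fc:c_fo] = PHASE_CODES["LR"]
        labels[c_fo:ho] = PHASE_CODES["MS"]
        labels[ho:c_fc] = PHASE_CODES["TS"]
        labels[c_fc:fo] = PHASE_CODES["PSw"]
        labels[fo:fc_next] = PHASE_CODES["Sw"]
    return PhaseSequence(labels)


def one_hot(seq: PhaseSequence | np.ndarray) -> np.ndarray:
    """Encode phase labels as an (M, 5) one-hot matrix (column order LR..Sw)."""
    labels = seq.labels if isinstance(seq, PhaseSequence) else np.asarray(seq)
    if (labels == UNLABELED).any():
        raise ValidationError("cannot one-hot encode unlabeled samples")
    if ((labels < 0) | (labels >= N_PHASES)).any():
        raise ValidationError("labels must lie in 0..4")
    out = np.zeros((len(labels), N_PHASES))
    out[np.arange(len(labels)), labels] = 1.0
    return out
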