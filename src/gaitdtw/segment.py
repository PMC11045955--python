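"""Toe-off detection and gait-cycle segmentation.

Cycles are anchored at TOE-OFF (swing phase first), inverting the usual
heel-strike convention, so a classifier sees the mode-discriminative swing
portion at the start of every cycle. Toe-off is detected from the in-shoe
force-sensing resistors: the first sample at which both the heel and the
ball FSR have dropped below a low threshold after a stance interval, then
refined to the nearest local extremum of the instrumented-shank
accelerometer z-axis (which spikes at push-off) within a short window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, SchemaError
from .types import Axis, ChannelId, GaitCycle, GaitRecording, Location, Modality, Mode

log = logging.getLogger(__name__)

HEEL_FSR = ChannelId(Location.INSTR_HEEL, Modality.FSR)
BALL_FSR = ChannelId(Location.INSTR_BALL, Modality.FSR)
SHANK_ACCEL_Z = ChannelId(Location.INSTR_SHANK, Modality.ACCEL, Axis.Z)


@dataclass(frozen=True)
class ToeOffDetectorSpec:
    fsr_low_threshold: float = 0.05   # normalised pressure
    hysteresis: float = 0.02
    min_cycle_duration_s: float = 0.6
    max_cycle_duration_s: float = 2.5
    refine_window_s: float = 0.05
    heel_channel: ChannelId = HEEL_FSR
    ball_channel: ChannelId = BALL_FSR
    accel_channel: ChannelId | None = SHANK_ACCEL_Z

    def __post_init__(self) -> None:
        if not 0 < self.fsr_low_threshold < 1:
            raise ParameterError("fsr_low_threshold must be in (0, 1)")
        if self.min_cycle_duration_s >= self.max_cycle_duration_s:
            raise ParameterError("min cycle duration must be < max")


def _local_extrema(x: np.ndarray) -> np.ndarray:
    """Indices of strict sign changes of the first difference."""
    d = np.diff(x)
    return np.nonzero(np.sign(d[1:]) * np.sign(d[:-1]) < 0)[0] + 1


def detect_toe_off(
    recording: GaitRecording, spec: ToeOffDetectorSpec = ToeOffDetectorSpec()
) -> list[int]:
    """Toe-off sample indices, strictly increasing.

    A candidate fires at the first sample where both FSRs are below
    ``fsr_low_threshold`` following a stance interval (both above threshold +
    hysteresis); candidates closer than the minimum cycle duration to the
    previous accepted toe-off are rejected. If the shank accel-z channel is
    present, each candidate is moved to the nearest local extremum of that
    signal within +/- ``refine_window_s``.
    """
    heel = recording.channel_data(spec.heel_channel)
    ball = recording.channel_data(spec.ball_channel)
    fs = recording.sampling_rate
    high = spec.fsr_low_threshold + spec.hysteresis
    low = spec.fsr_low_threshold

    accel = None
    if spec.accel_channel is not None and spec.accel_channel in recording.channels:
        accel = recording.channel_data(spec.accel_channel)

    min_gap = int(round(spec.min_cycle_duration_s * fs))
    win = int(round(spec.refine_window_s * fs))
    n = recording.n_samples

    events: list[int] = []
    in_stance = False
    last = -(10**9)
    for k in range(n):
        loaded = heel[k] > high and ball[k] > high
        unloaded = heel[k] < low and ball[k] < low
        if loaded:
            in_stance = True
        elif unloaded and in_stance:
            in_stance = False
            idx = k
            if accel is not None:
                lo, hi = max(0, idx - win), min(n, idx + win + 1)
                ext = _local_extrema(accel[lo:hi])
                if ext.size:
                    idx = lo + int(ext[np.argmin(np.abs(lo + ext - idx))])
            if idx - last < min_gap:
                log.debug("toe-off at %d rejected (refractory, last=%d)", idx, last)
                continue
            events.append(idx)
            last = idx

    if not events and recording.labels:
        log.warning(
            "no toe-off events detected on %s despite %d labelled intervals",
            recording.subject_id,
            len(recording.labels),
        )
    return events


def _mode_at(recording: GaitRecording, sample: int) -> Mode | None:
    for start, end, mode in recording.labels:
        if start <= sample < end:
            return mode
    return None


def segment_cycles(
    recording: GaitRecording,
    toe_offs: list[int],
    min_cycle_duration_s: float = 0.6,
    max_cycle_duration_s: float = 2.5,
) -> list[GaitCycle]:
    """Cut the recording into toe-off-to-toe-off cycles.

    Cycle k spans ``[toe_offs[k], toe_offs[k+1])``; its mode is taken from
    the label interval containing the cycle midpoint (else unlabeled).
    Cycles outside the [min, max] duration bounds are dropped and logged —
    this stands in for manual curation of irregular strides.
    """
    if len(toe_offs) < 2:
        return []
    if any(b <= a for a, b in zip(toe_offs, toe_offs[1:])):
        raise ParameterError("toe-off indices must be strictly increasing")
    fs = recording.sampling_rate
    lo = int(round(min_cycle_duration_s * fs))
    hi = int(round(max_cycle_duration_s * fs))
    cycles: list[GaitCycle] = []
    n_dropped = 0
    for start, end in zip(toe_offs, toe_offs[1:]):
        length = end - start
        if not lo <= length <= hi:
            n_dropped += 1
            continue
        mode = _mode_at(recording, (start + end) // 2)
        cycles.append(
            GaitCycle(
                subject_id=recording.subject_id,
                mode=mode,
                channels=list(recording.channels),
                data=recording.data[:, start:end].copy(),
                fs=fs,
                source_span=(start, end),
            )
        )
    log.info(
        "segmented %s: %d cycles (%d dropped by duration bounds)",
        recording.subject_id,
        len(cycles),
        n_dropped,
    )
    return cycles
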