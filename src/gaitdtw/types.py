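"""Domain types: sensor channels, locomotion modes, recordings and gait cycles.

Units throughout: accelerations in m/s^2, angular rates in deg/s, angles in
degrees, plantar pressure normalised to [0, 1], time in samples unless a
sampling rate is given.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError, SchemaError


class Location(str, enum.Enum):
    """Body-segment placement of a sensor.

    The instrumented side is the leg wearing the sensorised exoskeleton
    (the prosthesis side in deployment); ``*_heel`` / ``*_ball`` are the
    in-shoe force-sensing-resistor sites under the calcaneus and the first
    metatarsal head.
    """

    INSTR_THIGH = "instr_thigh"
    INSTR_SHANK = "instr_shank"
    UNINSTR_THIGH = "uninstr_thigh"
    UNINSTR_SHANK = "uninstr_shank"
    CHEST = "chest"
    INSTR_FOOT = "instr_foot"
    UNINSTR_FOOT = "uninstr_foot"
    INSTR_KNEE = "instr_knee"
    INSTR_ANKLE = "instr_ankle"
    INSTR_HIP = "instr_hip"
    UNINSTR_HIP = "uninstr_hip"
    INSTR_HEEL = "instr_heel"
    INSTR_BALL = "instr_ball"
    UNINSTR_HEEL = "uninstr_heel"
    UNINSTR_BALL = "uninstr_ball"


class Modality(str, enum.Enum):
    ACCEL = "accel"
    GYRO = "gyro"
    JOINT_ANGLE = "joint_angle"
    SEGMENT_ANGLE = "segment_angle"
    FSR = "fsr"


class Axis(str, enum.Enum):
    X = "x"
    Y = "y"
    Z = "z"
    NONE = "none"


#: modalities that carry no spatial axis
_AXISLESS = {Modality.JOINT_ANGLE, Modality.SEGMENT_ANGLE, Modality.FSR}


@dataclass(frozen=True, order=True)
class ChannelId:
    """Identity of one sensor signal: where, what, and which axis.

    The string form ``location.modality[.axis]`` is unique and round-trips
    through :meth:`parse` / ``str()``.
    """

    location: Location
    modality: Modality
    axis: Axis = Axis.NONE

    def __post_init__(self) -> None:
        if self.modality in _AXISLESS and self.axis is not Axis.NONE:
            raise ParameterError(
                f"{self.modality.value} channels carry no axis (got {self.axis.value})"
            )
        if self.modality in (Modality.ACCEL, Modality.GYRO) and self.axis is Axis.NONE:
            raise ParameterError(f"{self.modality.value} channels need an axis")

    def __str__(self) -> str:
        if self.axis is Axis.NONE:
            return f"{self.location.value}.{self.modality.value}"
        return f"{self.location.value}.{self.modality.value}.{self.axis.value}"

    @classmethod
    def parse(cls, text: str) -> "ChannelId":
        parts = text.strip().split(".")
        if len(parts) == 2:
            loc, mod = parts
            ax = "none"
        elif len(parts) == 3:
            loc, mod, ax = parts
        else:
            raise ParameterError(f"cannot parse channel id {text!r}")
        try:
            return cls(Location(loc), Modality(mod), Axis(ax))
        except ValueError as exc:  # unknown enum member
            raise ParameterError(f"cannot parse channel id {text!r}: {exc}") from exc


class Mode(str, enum.Enum):
    """The three locomotive states: steady level walking and the two
    walking-to-stair transitions."""

    LW = "LW"        # level walking
    LW_SC = "LW_SC"  # level walking -> stair climbing transition
    LW_SD = "LW_SD"  # level walking -> stair descending transition


#: fixed mode order used for confusion matrices and deterministic tie-breaks
MODE_ORDER: tuple[Mode, Mode, Mode] = (Mode.LW, Mode.LW_SC, Mode.LW_SD)


class GaitEvent(str, enum.Enum):
    TOE_OFF = "toe_off"
    HEEL_STRIKE = "heel_strike"


@dataclass
class GaitRecording:
    """A continuous multichannel recording from one subject.

    ``data`` is channels x samples; ``events`` are (sample_index, GaitEvent)
    pairs; ``labels`` are half-open ``[start, end)`` sample intervals tagged
    with a :class:`Mode`. Sample indexing is 0-based.
    """

    subject_id: str
    sampling_rate: float
    channels: list[ChannelId]
    data: np.ndarray
    events: list[tuple[int, GaitEvent]] = field(default_factory=list)
    labels: list[tuple[int, int, Mode]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be > 0")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise SchemaError(
                f"data must be (n_channels={len(self.channels)}) x samples, "
                f"got shape {self.data.shape}"
            )
        n = self.data.shape[1]
        for idx, _ in self.events:
            if not 0 <= idx < n:
                raise ParameterError(f"event index {idx} outside [0, {n})")
        prev_end = None
        for start, end, _ in sorted(self.labels):
            if not (0 <= start < end <= n):
                raise ParameterError(f"label interval [{start}, {end}) outside data")
            if prev_end is not None and start < prev_end:
                raise ParameterError("label intervals overlap")
            prev_end = end

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel_index(self, channel: ChannelId) -> int:
        try:
            return self.channels.index(channel)
        except ValueError:
            raise SchemaError(f"channel {channel} not in recording") from None

    def channel_data(self, channel: ChannelId) -> np.ndarray:
        return self.data[self.channel_index(channel)]


@dataclass
class GaitCycle:
    """One toe-off-to-toe-off segment of a recording (swing phase first).

    ``cycle_id`` identifies the cycle; ``parent_id`` links an augmented cycle
    back to the raw cycle it was derived from (``None`` for raw cycles) and
    ``origin`` records the deriving transform.
    """

    subject_id: str
    mode: Mode | None
    channels: list[ChannelId]
    data: np.ndarray
    fs: float
    source_span: tuple[int, int] | None = None
    cycle_id: str = ""
    parent_id: str | None = None
    origin: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise SchemaError(
                f"cycle data must be (n_channels={len(self.channels)}) x samples, "
                f"got shape {self.data.shape}"
            )
        if not self.cycle_id:
            span = self.source_span or (0, self.data.shape[1])
            self.cycle_id = f"{self.subject_id}:{span[0]}-{span[1]}"

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel_index(self, channel: ChannelId) -> int:
        try:
            return self.channels.index(channel)
        except ValueError:
            raise SchemaError(f"channel {channel} not in cycle") from None

    def select_channels(self, channels: list[ChannelId]) -> np.ndarray:
        """Return the d x m submatrix for ``channels`` in the given order."""
        rows = [self.channel_index(c) for c in channels]
        return self.data[rows]

    def derived(self, data: np.ndarray, origin: str) -> "GaitCycle":
        """A copy with new sample data, provenance-linked to this cycle."""
        root = self.parent_id or self.cycle_id
        return replace(
            self,
            data=np.asarray(data, dtype=float),
            cycle_id=f"{self.cycle_id}|{origin}",
            parent_id=root,
            origin=origin,
        )


def root_id(cycle: GaitCycle) -> str:
    """Identity of the raw cycle a (possibly augmented) cycle descends from."""
    return cycle.parent_id or cycle.cycle_id
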