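"""Synthetic multi-subject gait-recording generator with known ground truth.

Emulates the structure of a wearable-sensor gait study: quasi-periodic
multichannel cycles in three locomotive states (LW, LW-SC, LW-SD), per-subject
amplitude/phase variation, cycle-length jitter, white sensor noise, in-shoe
FSR channels following a swing-zero / stance-plateau pattern, and a push-off
spike on the shank accelerometer z-axis — so toe-off detection, template
building and classification can all be validated against analytic truth.

Mode prototypes are low-order harmonic series (<= 6 harmonics per channel)
whose coefficients are drawn deterministically per channel; the transition
modes deviate from level walking by additive harmonic offsets that are
non-zero from the very start of the cycle, so early-swing (prefix)
recognition is possible by construction. These are analytic stand-ins shaped
like sagittal gait curves, not recorded gait morphologies.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .preprocess import FilterSpec, lowpass_filter
from .segment import BALL_FSR, HEEL_FSR, SHANK_ACCEL_Z
from .types import (
    Axis,
    ChannelId,
    GaitCycle,
    GaitEvent,
    GaitRecording,
    Location,
    Modality,
    Mode,
)

log = logging.getLogger(__name__)

#: default signal channels: the six discriminative sensor signals commonly
#: selected for stair-transition recognition, plus two extra IMU axes
DEFAULT_SIGNAL_CHANNELS: tuple[ChannelId, ...] = (
    ChannelId(Location.INSTR_HIP, Modality.JOINT_ANGLE),
    ChannelId(Location.UNINSTR_HIP, Modality.JOINT_ANGLE),
    ChannelId(Location.UNINSTR_SHANK, Modality.ACCEL, Axis.Y),
    ChannelId(Location.INSTR_THIGH, Modality.GYRO, Axis.Z),
    ChannelId(Location.CHEST, Modality.ACCEL, Axis.Y),
    ChannelId(Location.CHEST, Modality.ACCEL, Axis.Z),
    ChannelId(Location.INSTR_THIGH, Modality.ACCEL, Axis.X),
    SHANK_ACCEL_Z,
)

TRANSITIONS = frozenset({Mode.LW_SC, Mode.LW_SD})


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for the synthetic benchmark.

    ``informative`` maps channel -> the set of transition modes whose
    prototype deviates from LW on that channel; ``None`` means every signal
    channel discriminates both transitions. FSR channels are appended
    automatically and never carry mode information.
    """

    n_subjects: int = 9
    channels: tuple[ChannelId, ...] = DEFAULT_SIGNAL_CHANNELS
    fs: float = 100.0
    n_cycles: int = 20
    cycle_duration_mean_s: float = 1.2
    cycle_duration_sd_s: float = 0.08
    subject_amp_sd: float = 0.10      # lognormal sigma of per-channel gain
    subject_phase_sd_s: float = 0.02  # per-subject phase shift, seconds
    noise_snr_db: float = 30.0        # inf = noiseless
    transition_rate: tuple[float, float] = (0.1, 0.1)
    min_cycles_per_mode: int = 2
    informative: dict[ChannelId, frozenset[Mode]] | None = None
    deviant_subjects: tuple[int, ...] = ()
    deviant_sd: float = 0.6
    stance_onset: float = 0.4         # stance starts ~40% into a toe-off cycle
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cycle_duration_mean_s <= 0 or self.fs <= 0:
            raise ParameterError("cycle duration and fs must be > 0")
        if int(round(self.cycle_duration_mean_s * self.fs)) < 20:
            raise ParameterError("cycles must span at least 20 samples")
        if sum(self.transition_rate) >= 1:
            raise ParameterError("transition rates must sum to < 1")
        if self.n_cycles < 3 * self.min_cycles_per_mode:
            raise ParameterError("n_cycles too small for min_cycles_per_mode")

    def informative_modes(self, channel: ChannelId) -> frozenset[Mode]:
        if channel.modality is Modality.FSR:
            return frozenset()
        if self.informative is None:
            return TRANSITIONS
        return self.informative.get(channel, frozenset())


def _channel_rng(channel: ChannelId) -> np.random.Generator:
    # crc32 is stable across platforms/runs, unlike hash()
    return np.random.default_rng(zlib.crc32(str(channel).encode()) & 0x7FFFFFFF)


def _harmonics(rng: np.random.Generator, n: int = 4) -> tuple[float, np.ndarray, np.ndarray]:
    a0 = float(rng.uniform(-0.5, 0.5))
    k = np.arange(1, n + 1)
    return a0, rng.normal(0, 1, n) / k, rng.normal(0, 1, n) / k


def _eval_harmonics(a0: float, a: np.ndarray, b: np.ndarray, u: np.ndarray) -> np.ndarray:
    k = np.arange(1, a.size + 1)[:, None]
    ang = 2 * np.pi * k * u[None, :]
    return a0 + (a[:, None] * np.cos(ang)).sum(0) + (b[:, None] * np.sin(ang)).sum(0)


def prototype(
    spec: GeneratorSpec, channel: ChannelId, mode: Mode, u: np.ndarray
) -> np.ndarray:
    """Noise-free mode prototype of one signal channel at cycle phase u in [0,1).

    The LW base curve is a 4-harmonic series per channel; LW-SC / LW-SD add
    channel-specific offsets that are bounded away from zero on the first 10%
    of the cycle (and differ between the two transitions).
    """
    rng = _channel_rng(channel)
    base = _eval_harmonics(*_harmonics(rng), u)
    sc_scale = float(rng.uniform(0.8, 1.2))
    sd_scale = float(rng.uniform(0.8, 1.2))
    info = spec.informative_modes(channel)
    if mode is Mode.LW_SC and mode in info:
        base = base + sc_scale * (
            0.9 + 0.6 * np.cos(2 * np.pi * u) - 0.3 * np.sin(2 * np.pi * u)
        )
    elif mode is Mode.LW_SD and mode in info:
        base = base - sd_scale * (
            0.8 + 0.4 * np.cos(4 * np.pi * u) + 0.2 * np.sin(2 * np.pi * u)
        )
    return base


def _check_separation(spec: GeneratorSpec) -> None:
    """Prototypes of distinct modes must differ on the first 10% of the cycle
    for at least one channel (else swing-phase recognition is impossible)."""
    if not any(spec.informative_modes(ch) for ch in spec.channels):
        # deliberate null benchmark (all channels carry no mode information)
        log.warning("no informative channels: classification is at chance level")
        return
    u = np.linspace(0, 0.1, 16)
    pairs = [(Mode.LW, Mode.LW_SC), (Mode.LW, Mode.LW_SD), (Mode.LW_SC, Mode.LW_SD)]
    separated = {p: False for p in pairs}
    for ch in spec.channels:
        if not spec.informative_modes(ch):
            continue
        curves = {m: prototype(spec, ch, m, u) for m in Mode}
        for a, b in pairs:
            if np.max(np.abs(curves[a] - curves[b])) > 1e-6:
                separated[(a, b)] = True
    if not all(separated.values()):
        missing = [f"{a.value}/{b.value}" for (a, b), v in separated.items() if not v]
        raise ParameterError(
            "mode pairs not separated on the first 10% of the cycle: "
            + ", ".join(missing)
        )


def _mode_sequence(spec: GeneratorSpec, rng: np.random.Generator) -> list[Mode]:
    p_sc, p_sd = spec.transition_rate
    draws = rng.choice(
        3, size=spec.n_cycles, p=[1 - p_sc - p_sd, p_sc, p_sd]
    )
    modes = [ (Mode.LW, Mode.LW_SC, Mode.LW_SD)[d] for d in draws ]
    # guarantee template feasibility: top up under-represented modes by
    # flipping cycles of the currently most frequent other mode
    for target in (Mode.LW_SC, Mode.LW_SD, Mode.LW):
        while modes.count(target) < spec.min_cycles_per_mode:
            donor = max(
                (m for m in Mode if m is not target), key=modes.count
            )
            positions = [
                i for i, m in enumerate(modes)
                if m is donor and modes.count(donor) > spec.min_cycles_per_mode
            ] or [i for i, m in enumerate(modes) if m is donor]
            if not positions:
                raise ParameterError("cannot satisfy min_cycles_per_mode")
            modes[int(rng.choice(positions))] = target
    return modes


def _fsr_pattern(L: int, s0: int, which: str) -> np.ndarray:
    """Swing-zero / stance-plateau FSR trace for one cycle of length L.

    The heel unloads a few samples before the cycle boundary; the ball stays
    marginally loaded until the boundary itself, so the first sample at which
    both are unloaded is exactly the next toe-off.
    """
    x = np.zeros(L)
    ramp = 5
    if which == "heel":
        start = s0
        fall_start, fall_len = L - 10, 7
    else:
        start = min(s0 + 3, L - 15)
        fall_start, fall_len = L - 6, 6
    x[start : start + ramp] = np.linspace(0, 1, ramp, endpoint=False)
    x[start + ramp : fall_start] = 1.0
    k = np.arange(fall_len)
    fall = 1.0 - (k + 1) / (fall_len + 1)
    end = min(L, fall_start + fall_len)
    x[fall_start:end] = fall[: end - fall_start]
    if which == "heel" and end < L:
        x[end:L] = 0.0
    return x


def generate_recording(
    spec: GeneratorSpec, subject: int
) -> tuple[GaitRecording, dict]:
    """One subject's continuous recording plus its ground truth.

    Truth carries the exact cycle boundaries (toe-off samples), per-cycle
    modes and durations. The recording is fully reproducible from
    ``(spec.seed, subject)``.
    """
    if not 0 <= subject < spec.n_subjects:
        raise ParameterError(f"subject index {subject} out of range")
    _check_separation(spec)
    rng = np.random.default_rng([spec.seed, subject])

    sig_channels = list(spec.channels)
    all_channels = sig_channels + [HEEL_FSR, BALL_FSR]
    modes = _mode_sequence(spec, rng)
    durations = np.clip(
        rng.normal(spec.cycle_duration_mean_s, spec.cycle_duration_sd_s, spec.n_cycles),
        0.7 * spec.cycle_duration_mean_s,
        1.4 * spec.cycle_duration_mean_s,
    )
    lengths = np.maximum(20, np.round(durations * spec.fs).astype(int))

    amp = np.exp(rng.normal(0.0, spec.subject_amp_sd, len(sig_channels)))
    tau = float(rng.normal(0.0, spec.subject_phase_sd_s))
    deviant = subject in spec.deviant_subjects
    dev_coef: dict[tuple[ChannelId, Mode], tuple] = {}
    if deviant:
        for ch in sig_channels:
            for m in Mode:
                dev_coef[(ch, m)] = (
                    float(rng.normal(0, spec.deviant_sd)),
                    rng.normal(0, spec.deviant_sd, 2),
                    rng.normal(0, spec.deviant_sd, 2),
                )

    chunks: list[np.ndarray] = []
    boundaries = [0]
    for L, mode, dur in zip(lengths, modes, durations):
        u = np.arange(L) / L
        u_shift = (u + tau / dur) % 1.0
        block = np.empty((len(all_channels), L))
        for r, ch in enumerate(sig_channels):
            sig = prototype(spec, ch, mode, u_shift) * amp[r]
            if deviant:
                sig = sig + _eval_harmonics(*dev_coef[(ch, mode)], u_shift)
            if ch == SHANK_ACCEL_Z:
                # push-off spike anchored at the toe-off boundary (unshifted)
                s = 0.02 / dur
                sig = sig + 4.0 * (
                    np.exp(-(u**2) / (2 * s**2)) + np.exp(-((u - 1) ** 2) / (2 * s**2))
                )
            block[r] = sig
        s0 = int(round(spec.stance_onset * L))
        block[len(sig_channels)] = _fsr_pattern(L, s0, "heel")
        block[len(sig_channels) + 1] = _fsr_pattern(L, s0, "ball")
        chunks.append(block)
        boundaries.append(int(boundaries[-1] + L))

    data = np.concatenate(chunks, axis=1)
    if np.isfinite(spec.noise_snr_db):
        power = np.mean(data**2, axis=1)
        sigma = np.sqrt(power / 10.0 ** (spec.noise_snr_db / 10.0))
        data = data + rng.standard_normal(data.shape) * sigma[:, None]
        nfsr = len(sig_channels)
        data[nfsr:] = np.clip(data[nfsr:], 0.0, None)

    subject_id = f"S{subject + 1:02d}"
    events = [(b, GaitEvent.TOE_OFF) for b in boundaries[:-1]]
    events += [
        (boundaries[i] + int(round(spec.stance_onset * lengths[i])), GaitEvent.HEEL_STRIKE)
        for i in range(spec.n_cycles)
    ]
    labels = [
        (boundaries[i], boundaries[i + 1], modes[i]) for i in range(spec.n_cycles)
    ]
    rec = GaitRecording(
        subject_id=subject_id,
        sampling_rate=spec.fs,
        channels=all_channels,
        data=data,
        events=sorted(events),
        labels=labels,
    )
    truth = {
        "subject_id": subject_id,
        "boundaries": boundaries,
        "toe_offs": boundaries[:-1],
        "cycle_modes": [m.value for m in modes],
        "durations_s": durations.tolist(),
        "phase_shift_s": tau,
        "deviant": deviant,
    }
    return rec, truth


def make_benchmark(
    spec: GeneratorSpec, filter_cycles: bool = True
) -> tuple[list[GaitCycle], dict]:
    """Segmented, labelled multi-subject cycle corpus plus a truth manifest.

    Cycles are cut at the TRUE toe-off boundaries (segmentation-error-free,
    so downstream template/classifier behaviour is tested in isolation).
    ``filter_cycles`` applies the 15 Hz low-pass to the signal channels.
    """
    if spec.n_subjects < 3:
        raise ParameterError("benchmark needs at least 3 subjects")
    fspec = FilterSpec()
    cycles: list[GaitCycle] = []
    manifest: dict = {"spec_seed": spec.seed, "subjects": []}
    for s in range(spec.n_subjects):
        rec, truth = generate_recording(spec, s)
        if filter_cycles:
            for r, ch in enumerate(rec.channels):
                if ch.modality is not Modality.FSR:
                    rec.data[r] = lowpass_filter(rec.data[r], rec.sampling_rate, fspec)
        b = truth["boundaries"]
        for k in range(len(b) - 1):
            cycles.append(
                GaitCycle(
                    subject_id=rec.subject_id,
                    mode=Mode(truth["cycle_modes"][k]),
                    channels=list(rec.channels),
                    data=rec.data[:, b[k] : b[k + 1]].copy(),
                    fs=rec.sampling_rate,
                    source_span=(b[k], b[k + 1]),
                )
            )
        manifest["subjects"].append(truth)
    log.info(
        "benchmark: %d subjects, %d cycles, SNR=%s dB",
        spec.n_subjects,
        len(cycles),
        spec.noise_snr_db,
    )
    return cycles, manifest


def forward_selection_spec(seed: int = 0, **kw) -> GeneratorSpec:
    """Variant with exactly two informative channels among eight.

    The first informative channel separates only LW-SC from the rest, the
    second only LW-SD, so neither alone suffices — forward selection must
    pick both before stopping.
    """
    channels = DEFAULT_SIGNAL_CHANNELS
    informative = {ch: frozenset() for ch in channels}
    informative[channels[0]] = frozenset({Mode.LW_SC})
    informative[channels[1]] = frozenset({Mode.LW_SD})
    return GeneratorSpec(channels=channels, informative=informative, seed=seed, **kw)
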