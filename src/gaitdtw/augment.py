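"""Cycle augmentation for class balancing.

Transitional gait cycles (LW-SC, LW-SD) are far rarer than steady walking
cycles; the class is expanded by amplitude scaling (96/98/102/104 % of the
original), time resampling by the same symmetric factors, and additive white
Gaussian noise at SNR 30/35/40/45 dB. Every derived cycle is provenance-linked
to its raw original so evaluation folds can audit for leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateSignalError, ParameterError
from .types import GaitCycle


@dataclass(frozen=True)
class AugmentationSpec:
    amplitude_factors: tuple[float, ...] = (0.96, 0.98, 1.02, 1.04)
    resample_factors: tuple[float, ...] = (0.96, 0.98, 1.02, 1.04)
    snr_levels_db: tuple[float, ...] = (30.0, 35.0, 40.0, 45.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.amplitude_factors + self.resample_factors):
            raise ParameterError("all augmentation factors must be > 0")
        if any(not np.isfinite(s) for s in self.snr_levels_db):
            raise ParameterError("SNR levels must be finite")

    @property
    def multiplier(self) -> int:
        """Output/input count ratio: originals plus one copy per factor."""
        return 1 + len(self.amplitude_factors) + len(self.resample_factors) + len(
            self.snr_levels_db
        )


def scale_amplitude(cycle: GaitCycle, factor: float) -> GaitCycle:
    """Multiply every sample by ``factor`` (> 0); length unchanged."""
    if factor <= 0:
        raise ParameterError(f"amplitude factor must be > 0, got {factor}")
    return cycle.derived(cycle.data * factor, origin=f"scale:{factor:g}")


def resample_1d(x: np.ndarray, new_len: int) -> np.ndarray:
    """Linear interpolation of a 1-D signal onto a uniform grid of new_len."""
    old_len = x.shape[-1]
    if new_len == old_len:
        return np.array(x, dtype=float)
    grid = np.linspace(0.0, old_len - 1, new_len)
    return np.interp(grid, np.arange(old_len), x)


def resample_cycle(cycle: GaitCycle, factor: float) -> GaitCycle:
    """Resample to round(len * factor) samples by linear interpolation.

    Endpoints are preserved exactly; affine signals stay affine.
    """
    if factor <= 0:
        raise ParameterError(f"resample factor must be > 0, got {factor}")
    new_len = int(round(cycle.n_samples * factor))
    if new_len < 4:
        raise ParameterError(
            f"resampling to {new_len} samples (< 4) is not allowed"
        )
    data = np.vstack([resample_1d(row, new_len) for row in cycle.data])
    return cycle.derived(data, origin=f"resample:{factor:g}")


def add_awgn(cycle: GaitCycle, snr_db: float, rng_seed: int) -> GaitCycle:
    """Add white Gaussian noise per channel at the given SNR.

    Noise variance per channel = signal power / 10^(snr_db/10) with power
    the mean square of the channel. ``snr_db = inf`` returns an identical
    copy (noiseless sentinel).
    """
    if np.isposinf(snr_db):
        return cycle.derived(cycle.data.copy(), origin="awgn:inf")
    power = np.mean(cycle.data**2, axis=1)
    if np.any(power <= 0):
        raise DegenerateSignalError("zero-power channel: SNR undefined")
    rng = np.random.default_rng(rng_seed)
    sigma = np.sqrt(power / 10.0 ** (snr_db / 10.0))
    noise = rng.standard_normal(cycle.data.shape) * sigma[:, np.newaxis]
    return cycle.derived(cycle.data + noise, origin=f"awgn:{snr_db:g}dB")


def augment_class(
    cycles: list[GaitCycle], spec: AugmentationSpec = AugmentationSpec()
) -> list[GaitCycle]:
    """Expand a class: originals plus one derived cycle per factor/level.

    Output count is exactly ``len(cycles) * spec.multiplier``; derived cycles
    inherit label and subject and carry provenance to their original.
    """
    if not cycles:
        raise ParameterError("augment_class needs at least one cycle")
    out: list[GaitCycle] = []
    for k, cyc in enumerate(cycles):
        out.append(cyc)
        for f in spec.amplitude_factors:
            out.append(scale_amplitude(cyc, f))
        for f in spec.resample_factors:
            out.append(resample_cycle(cyc, f))
        for i, snr in enumerate(spec.snr_levels_db):
            out.append(add_awgn(cyc, snr, rng_seed=(spec.seed + 1009 * k + i) % 2**31))
    return out
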