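"""Signal conditioning: low-pass filtering, z-score normalisation, and
IMU-based segment tilt estimation.

The tilt estimator mirrors the common wearable-IMU pipeline: an
accelerometer-derived gravity angle is fused with the integrated gyroscope
rate through a complementary filter, and the fused angle is then smoothed by
a two-state linear Kalman filter (state = [tilt angle, gyro bias]) whose
prediction is driven by the raw gyroscope rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import DegenerateSignalError, ParameterError

GRAVITY = 9.80665  # m/s^2


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth filter parameters.

    ``zero_phase`` applies the filter forward and backward (no group delay;
    the magnitude response is squared, i.e. attenuation doubles in dB).
    """

    order: int = 2
    cutoff_hz: float = 15.0
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ParameterError("filter order must be >= 1")
        if self.cutoff_hz <= 0:
            raise ParameterError("cutoff must be > 0")


def lowpass_filter(x: np.ndarray, fs: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Low-pass Butterworth filter of a 1-D signal; length-preserving.

    Raises :class:`ParameterError` if the cutoff reaches Nyquist or the
    signal is too short for the filter's edge padding.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ParameterError("lowpass_filter expects a 1-D signal")
    if spec.cutoff_hz >= fs / 2:
        raise ParameterError(
            f"cutoff {spec.cutoff_hz} Hz >= Nyquist {fs / 2} Hz"
        )
    sos = sps.butter(spec.order, spec.cutoff_hz, btype="low", fs=fs, output="sos")
    if spec.zero_phase:
        # padlen of sosfiltfilt: 3 * (2 * n_sections + 1 - min(order % 2, 1))
        padlen = 3 * (2 * sos.shape[0] + 1)
        if x.size <= padlen:
            raise ParameterError(
                f"signal of length {x.size} too short for zero-phase padding "
                f"({padlen + 1} samples needed)"
            )
        return sps.sosfiltfilt(sos, x)
    if x.size <= 3 * spec.order:
        raise ParameterError("signal shorter than 3 x filter order")
    return sps.sosfilt(sos, x)


@dataclass(frozen=True)
class NormalizationParams:
    """Per-channel affine statistics for z-scoring (sample std, ddof=1)."""

    mean: float
    std: float
    scope: str = "per_recording"  # or "per_training_corpus"

    def __post_init__(self) -> None:
        if self.std <= 0:
            raise ParameterError("normalization std must be > 0")


def normalize(
    x: np.ndarray, params: NormalizationParams | None = None
) -> tuple[np.ndarray, NormalizationParams]:
    """z-score a 1-D signal, or apply previously fitted statistics.

    With ``params=None`` the signal's own mean and sample standard deviation
    are fitted and returned, so training statistics can later be applied to
    query data (consistent normalisation of partial cycles).
    """
    x = np.asarray(x, dtype=float)
    if params is None:
        sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
        if not np.isfinite(sd) or sd <= 0:
            raise DegenerateSignalError("cannot z-score a constant signal")
        params = NormalizationParams(mean=float(np.mean(x)), std=sd)
    return (x - params.mean) / params.std, params


@dataclass(frozen=True)
class KalmanSpec:
    """Process/measurement variances of the tilt Kalman filter (per second)."""

    q_angle: float = 1e-3   # deg^2/s, angle process noise
    q_bias: float = 3e-3    # (deg/s)^2/s, bias random walk
    r_angle: float = 0.5    # deg^2, measurement noise of the fused angle
    alpha: float = 0.98     # complementary-filter gyro weight


@dataclass
class OrientationEstimate:
    """Tilt estimate series with final filter state."""

    angle: np.ndarray          # deg, sagittal tilt vs vertical
    gyro_bias: float           # deg/s, final bias estimate
    covariance: np.ndarray     # 2x2 state covariance, symmetric PSD


def _accel_tilt(accel: np.ndarray) -> np.ndarray:
    """Gravity-referenced sagittal tilt (deg) from a 3-axis accelerometer.

    Convention: z points along the segment (reads +g when vertical), y is the
    anterior axis; tilt about the mediolateral x-axis.
    """
    return np.degrees(np.arctan2(accel[:, 1], accel[:, 2]))


def estimate_segment_angle(
    accel: np.ndarray,
    gyro: np.ndarray,
    fs: float,
    spec: KalmanSpec = KalmanSpec(),
    return_state: bool = False,
) -> np.ndarray | OrientationEstimate:
    """Sagittal segment tilt (deg) fused from accelerometer and gyroscope.

    ``accel`` is n x 3 in m/s^2, ``gyro`` n x 3 in deg/s (tilt rate on the
    x-axis). Complementary-filter fusion of accelerometer tilt with the
    integrated gyro rate, then Kalman smoothing with gyro-driven prediction
    and the fused angle as measurement.
    """
    accel = np.asarray(accel, dtype=float)
    gyro = np.asarray(gyro, dtype=float)
    if accel.shape != gyro.shape or accel.ndim != 2 or accel.shape[1] != 3:
        raise ParameterError("accel and gyro must both be n x 3 and equal length")
    if fs <= 0:
        raise ParameterError("fs must be > 0")
    dt = 1.0 / fs
    theta_acc = _accel_tilt(accel)
    rate = gyro[:, 0]
    n = theta_acc.size

    # complementary filter
    theta_cf = np.empty(n)
    theta_cf[0] = theta_acc[0]
    a = spec.alpha
    for k in range(1, n):
        theta_cf[k] = a * (theta_cf[k - 1] + rate[k] * dt) + (1 - a) * theta_acc[k]

    # Kalman: state [angle, bias], gyro prediction, fused-angle measurement
    x = np.array([theta_acc[0], 0.0])
    P = np.eye(2)
    Q = np.array([[spec.q_angle * dt, 0.0], [0.0, spec.q_bias * dt]])
    R = spec.r_angle
    out = np.empty(n)
    out[0] = x[0]
    for k in range(1, n):
        # predict
        x = np.array([x[0] + (rate[k] - x[1]) * dt, x[1]])
        F = np.array([[1.0, -dt], [0.0, 1.0]])
        P = F @ P @ F.T + Q
        # update with the complementary-filter angle
        S = P[0, 0] + R
        K = P[:, 0] / S
        innov = theta_cf[k] - x[0]
        x = x + K * innov
        P = P - np.outer(K, P[0, :])
        P = 0.5 * (P + P.T)  # keep symmetric against round-off
        out[k] = x[0]

    if return_state:
        return OrientationEstimate(angle=out, gyro_bias=float(x[1]), covariance=P)
    return out
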