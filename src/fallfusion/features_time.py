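"""Time-domain features: statistics, peaks/steps, jerk, temporal dynamics,
altimeter kinematics, and the maximum windowed altitude drop.

Degenerate inputs (flat signals, no detected peaks, zero variance) map
to defined sentinel values rather than NaN so downstream feature tables
never contain non-finite entries; each sentinel is noted on the
operation that owns it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .errors import DataError

#: samples-per-second threshold below which a velocity is treated as "still"
VELOCITY_EPS = 0.02  # m/s


@dataclass
class PeakParams:
    """Peak-detection knobs for the step/impact features.

    ``prominence`` is both the topographic prominence floor and the
    required height above the median baseline; ``separation`` is the
    minimum spacing between accepted peaks.
    """

    prominence: float = 0.5   # g
    separation: float = 0.25  # s

    def __post_init__(self) -> None:
        if self.prominence <= 0 or self.separation <= 0:
            raise DataError("peak prominence and separation must be positive")


def stat_features(x: np.ndarray) -> dict[str, float]:
    """Sample statistics: mean, median, std, IQR, excess kurtosis, skewness.

    Skewness is the adjusted Fisher-Pearson (bias-corrected) form and
    kurtosis is bias-corrected excess kurtosis; both are defined as 0
    for a zero-variance series. Quantiles use linear interpolation
    (the "type 7" convention), which fixes the IQR value.
    """
    x = np.asarray(x, float)
    if len(x) < 4:
        raise DataError(f"need >= 4 samples for statistics, got {len(x)}")
    std = float(np.std(x, ddof=1))
    if std == 0.0:
        skew = kurt = 0.0
    else:
        skew = float(stats.skew(x, bias=False))
        kurt = float(stats.kurtosis(x, bias=False))  # excess
    q75, q25 = np.percentile(x, [75, 25])
    return {
        "mean": float(np.mean(x)),
        "median": float(np.median(x)),
        "std": std,
        "iqr": float(q75 - q25),
        "kurtosis": kurt,
        "skewness": skew,
    }


def find_signal_peaks(x: np.ndarray, fs: float, params: PeakParams) -> np.ndarray:
    """Indices of local maxima above the median baseline.

    A peak must (a) rise at least ``prominence`` above the series
    median, (b) have topographic prominence >= ``prominence`` and
    (c) be >= ``separation`` seconds from its neighbours.
    """
    x = np.asarray(x, float)
    baseline = float(np.median(x))
    distance = max(1, int(round(params.separation * fs)))
    idx, _ = signal.find_peaks(
        x, height=baseline + params.prominence, prominence=params.prominence, distance=distance
    )
    return idx


def peak_features(avm: np.ndarray, fs: float, params: PeakParams | None = None) -> dict[str, float]:
    """Step/impact summary of the AVM channel.

    With fewer than 2 peaks the inter-peak interval is undefined; the
    sentinel rule reports the full recording duration instead (a "one
    long stride" reading) with zero variability. With no peaks at all
    the mean amplitude is 0.
    """
    avm = np.asarray(avm, float)
    params = params or PeakParams()
    if len(avm) < 0.5 * fs:
        raise DataError("need at least 0.5 s of signal for peak features")
    idx = find_signal_peaks(avm, fs, params)
    duration = len(avm) / fs
    if len(idx) == 0:
        return {
            "mean_peak_amplitude": 0.0,
            "peak_amplitude_variability": 0.0,
            "mean_step_interval": duration,
        }
    heights = avm[idx]
    if len(idx) < 2:
        return {
            "mean_peak_amplitude": float(np.mean(heights)),
            "peak_amplitude_variability": 0.0,
            "mean_step_interval": duration,
        }
    return {
        "mean_peak_amplitude": float(np.mean(heights)),
        "peak_amplitude_variability": float(np.std(heights)),
        "mean_step_interval": float(np.mean(np.diff(idx)) / fs),
    }


def jerk_features(x: np.ndarray, fs: float) -> dict[str, float]:
    """Jerk (rate of change of acceleration) summary.

    j = first finite difference scaled by fs. ``jerk_mean`` is the mean
    |j|, ``jerk_variability`` the population std of signed j, and
    ``jerk_rms`` the root mean square, so that
    rms^2 = variability^2 + mean(signed j)^2 holds exactly.
    """
    x = np.asarray(x, float)
    if len(x) < 3:
        raise DataError(f"need >= 3 samples for jerk, got {len(x)}")
    j = np.diff(x) * fs
    return {
        "jerk_mean": float(np.mean(np.abs(j))),
        "jerk_variability": float(np.std(j)),
        "jerk_rms": float(np.sqrt(np.mean(j**2))),
    }


def temporal_features(x: np.ndarray) -> dict[str, float]:
    """Lag-1 autocorrelation and zero-crossing rate of the centered series.

    The autocorrelation is normalized, R(1)/R(0) on the mean-removed
    series, so it is amplitude-comparable across recordings; a
    zero-variance series maps to 0. Rhythmic activities (gait) score
    near 1, abrupt irregular ones lower.
    """
    x = np.asarray(x, float)
    if len(x) < 3:
        raise DataError(f"need >= 3 samples, got {len(x)}")
    xc = x - np.mean(x)
    r0 = float(np.dot(xc, xc))
    if r0 == 0.0:
        return {"lag1_autocorr": 0.0, "zero_crossing_rate": 0.0}
    r1 = float(np.dot(xc[:-1], xc[1:]))
    crossings = int(np.count_nonzero(xc[:-1] * xc[1:] < 0))
    return {
        "lag1_autocorr": r1 / r0,
        "zero_crossing_rate": crossings / (len(x) - 1),
    }


def kinematic_features(h_filt: np.ndarray, v_vert: np.ndarray, fs: float) -> dict[str, float]:
    """Vertical-motion summary from the filtered altitude and its velocity.

    Ascent/descent durations count samples whose velocity exceeds
    +/-``VELOCITY_EPS`` (0.02 m/s); ``alt_jerk_rms`` is the RMS of the
    third finite difference of altitude scaled by fs^3 (jerk as the
    third derivative of position).
    """
    h_filt = np.asarray(h_filt, float)
    v_vert = np.asarray(v_vert, float)
    if len(h_filt) != len(v_vert) or len(h_filt) < 3:
        raise DataError("altitude and velocity must have equal length >= 3")
    if len(h_filt) < 4:
        j3_rms = 0.0
    else:
        j3 = np.diff(h_filt, 3) * fs**3
        j3_rms = float(np.sqrt(np.mean(j3**2)))
    return {
        "mean_vert_velocity": float(np.mean(v_vert)),
        "max_vert_velocity": float(np.max(v_vert)),
        "min_vert_velocity": float(np.min(v_vert)),
        "rms_vert_velocity": float(np.sqrt(np.mean(v_vert**2))),
        "max_ascent_speed": float(max(np.max(v_vert), 0.0)),
        "max_descent_speed": float(abs(min(np.min(v_vert), 0.0))),
        "ascent_duration": float(np.count_nonzero(v_vert > VELOCITY_EPS) / fs),
        "descent_duration": float(np.count_nonzero(v_vert < -VELOCITY_EPS) / fs),
        "altitude_change": float(np.max(h_filt) - np.min(h_filt)),
        "alt_jerk_rms": j3_rms,
    }


def delta_h(h_filt: np.ndarray, fs: float, window: float) -> float:
    """Maximum drop between consecutive windowed altitude averages (m).

    The series is partitioned into consecutive non-overlapping,
    left-aligned windows of the given length (trailing partial window
    dropped); with window means hbar[i], the feature is
    max_i(hbar[i] - hbar[i+1]). Positive for descents; can be negative
    if the altitude only rises.
    """
    h_filt = np.asarray(h_filt, float)
    w = int(round(window * fs))
    if w < 1:
        raise DataError("window shorter than one sample")
    k = len(h_filt) // w
    if k < 2:
        raise DataError(
            f"series of {len(h_filt) / fs:.2f} s spans fewer than 2 windows of {window} s"
        )
    means = h_filt[: k * w].reshape(k, w).mean(axis=1)
    return float(np.max(means[:-1] - means[1:]))
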