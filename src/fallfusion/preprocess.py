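"""Signal derivation: AVM, barometric altitude, filtering, vertical velocity.

The acceleration vector magnitude (AVM) collapses the tri-axial
accelerometer into a single orientation-invariant channel,

    AVM(n) = sqrt(ax(n)^2 + ay(n)^2 + az(n)^2),

so that at rest AVM = 1 g regardless of how the device is worn.

Altitude is derived from barometric pressure p (kPa) and ambient
temperature T (degC) through the barometric formula

    h(p, T) = (T + 273.15) / 0.0065 * (1 - (p / p0)^0.19),

with p0 = 101.325 kPa the standard-atmosphere reference. The raw
altitude channel carries decimeter-scale sensor noise, so it is smoothed
with a zero-phase (forward-backward) Butterworth low-pass, 1 Hz cutoff
by default; zero-phase filtering preserves event timing, which matters
because several features measure *when* the altitude drops.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .config import RunConfig
from .errors import ConfigError, DataError
from .io import Recording

KELVIN_OFFSET = 273.15
LAPSE_RATE = 0.0065  # K/m, standard troposphere
BARO_EXPONENT = 0.19


@dataclass
class DerivedSignals:
    """Per-recording derived channels, all the same length as the source."""

    avm: np.ndarray     # g
    h_raw: np.ndarray   # m
    h_filt: np.ndarray  # m, zero-phase low-passed
    v_vert: np.ndarray  # m/s, from h_filt
    fs: float


def compute_avm(ax: np.ndarray, ay: np.ndarray, az: np.ndarray) -> np.ndarray:
    """Euclidean norm of the tri-axial acceleration, elementwise (g)."""
    ax, ay, az = np.asarray(ax, float), np.asarray(ay, float), np.asarray(az, float)
    if not (len(ax) == len(ay) == len(az)):
        raise DataError(f"axis length mismatch: {len(ax)}, {len(ay)}, {len(az)}")
    return np.sqrt(ax**2 + ay**2 + az**2)


def pressure_to_altitude(p: np.ndarray, T: np.ndarray | float, p0: float = 101.325) -> np.ndarray:
    """Barometric altitude (m) from pressure (kPa) and temperature (degC).

    Strictly decreasing in p; exactly 0 at p = p0 for any temperature.
    """
    p = np.asarray(p, float)
    if np.any(p <= 0) or p0 <= 0:
        raise DataError("pressure must be strictly positive")
    T = np.asarray(T, float)
    return (T + KELVIN_OFFSET) / LAPSE_RATE * (1.0 - (p / p0) ** BARO_EXPONENT)


def altitude_to_pressure(h: np.ndarray, T: np.ndarray | float, p0: float = 101.325) -> np.ndarray:
    """Inverse of :func:`pressure_to_altitude`; used by the simulator."""
    h = np.asarray(h, float)
    T = np.asarray(T, float)
    return p0 * (1.0 - LAPSE_RATE * h / (T + KELVIN_OFFSET)) ** (1.0 / BARO_EXPONENT)


def lowpass_filter(x: np.ndarray, fs: float, cutoff: float = 1.0, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass (applied forward and backward).

    The effective magnitude response is the square of the single-pass
    Butterworth response, so a 10x-cutoff tone is attenuated far below
    the single-pass -3 dB-per-octave-roll-off figure.
    """
    x = np.asarray(x, float)
    if not 0 < cutoff < fs / 2:
        raise ConfigError(f"cutoff {cutoff} Hz must lie in (0, fs/2) = (0, {fs / 2})")
    if len(x) <= 3 * order:
        raise DataError(f"series of length {len(x)} too short for order-{order} filtering")
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def vertical_velocity(h_filt: np.ndarray, fs: float) -> np.ndarray:
    """Vertical velocity (m/s) by central differences of the filtered altitude.

    Endpoints use one-sided differences; the result has the same length
    as the input. Velocity is taken on the *filtered* altitude because
    differentiating the raw channel would amplify its noise to several
    m/s of jitter.
    """
    h_filt = np.asarray(h_filt, float)
    if len(h_filt) < 2:
        raise DataError("need at least 2 samples to differentiate")
    return np.gradient(h_filt, 1.0 / fs)


def derive_signals(rec: Recording, cfg: RunConfig | None = None) -> DerivedSignals:
    """Run the full derivation chain on one recording."""
    cfg = cfg or RunConfig()
    avm = compute_avm(rec.ax, rec.ay, rec.az)
    h_raw = pressure_to_altitude(rec.p, rec.T, cfg.p0_kpa)
    h_filt = lowpass_filter(h_raw, rec.fs, cfg.cutoff_hz, cfg.filter_order)
    v_vert = vertical_velocity(h_filt, rec.fs)
    return DerivedSignals(avm=avm, h_raw=h_raw, h_filt=h_filt, v_vert=v_vert, fs=rec.fs)
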