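"""Frequency-domain and energy/complexity features.

Spectra are one-sided power spectra (|X_k|^2 over k = 0..N/2) of the
mean-removed series, no taper. The mean is removed so the DC bin cannot
dominate centroid/entropy; DC is retained in the container but excluded
from all shape features, which is the standard convention for motion
signals. Recordings are single segmented activities, so spectra are
computed on whole recordings rather than sliding windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DataError


@dataclass
class Spectrum:
    """One-sided power spectrum of a real series."""

    freqs: np.ndarray  # Hz, 0..fs/2
    power: np.ndarray  # |X_k|^2, same length as freqs
    fs: float
    n: int             # transform length

    @property
    def nondc_power(self) -> np.ndarray:
        return self.power[1:]

    @property
    def nondc_freqs(self) -> np.ndarray:
        return self.freqs[1:]


def power_spectrum(x: np.ndarray, fs: float) -> Spectrum:
    """DFT power spectrum of the mean-removed series (rectangular window)."""
    x = np.asarray(x, float)
    if len(x) < 8:
        raise DataError(f"need >= 8 samples for a spectrum, got {len(x)}")
    if np.ptp(x) == 0.0:
        # exactly constant: define an exactly zero spectrum rather than
        # transforming the rounding residue of mean removal
        xc = np.zeros_like(x)
    else:
        xc = x - np.mean(x)
    X = np.fft.rfft(xc)
    return Spectrum(
        freqs=np.fft.rfftfreq(len(x), 1.0 / fs),
        power=np.abs(X) ** 2,
        fs=fs,
        n=len(x),
    )


def spectral_shape(S: Spectrum) -> dict[str, float]:
    """Spectral centroid and spread (Hz) and normalized spectral entropy.

    Computed over non-DC bins with power-normalized weights w_k:
    centroid = sum w_k f_k, spread = sqrt(sum w_k (f_k - centroid)^2),
    entropy = -sum w_k log w_k / log(#bins) in [0, 1]. All three are 0
    when there is no non-DC power (flat signal).
    """
    p = S.nondc_power
    f = S.nondc_freqs
    total = float(np.sum(p))
    if total <= 0.0:
        return {"spectral_centroid": 0.0, "spectral_spread": 0.0, "spectral_entropy": 0.0}
    w = p / total
    centroid = float(np.sum(w * f))
    spread = float(np.sqrt(np.sum(w * (f - centroid) ** 2)))
    nz = w[w > 0]
    entropy = float(-np.sum(nz * np.log(nz)) / np.log(len(w))) if len(w) > 1 else 0.0
    return {"spectral_centroid": centroid, "spectral_spread": spread, "spectral_entropy": entropy}


def dominant_frequency(S: Spectrum) -> dict[str, float]:
    """Strongest non-DC bin; ties break toward the lower frequency.

    A degenerate (powerless) spectrum maps to (0, 0).
    """
    p = S.nondc_power
    if len(p) == 0 or float(np.sum(p)) <= 0.0:
        return {"dominant_frequency": 0.0, "power_at_dominant": 0.0}
    k = int(np.argmax(p))  # argmax returns the first (lowest-frequency) maximum
    return {
        "dominant_frequency": float(S.nondc_freqs[k]),
        "power_at_dominant": float(p[k]),
    }


#: ratio reported when the low band is empty but the high band is not
HIGH_LOW_SENTINEL = 1e6


def band_power_ratio(
    S: Spectrum, low_band: tuple[float, float], high_band: tuple[float, float]
) -> float:
    """High-band power divided by low-band power.

    Band membership: low band is closed [a, b]; the high band is
    half-open (a, b] so that bands sharing an edge do not double-count
    the shared bin. Zero low-band power maps to 0 when the high band is
    also empty, else to the documented sentinel 1e6.
    """
    nyq = S.fs / 2
    (l0, l1), (h0, h1) = low_band, high_band
    if not (0 <= l0 < l1 <= nyq and 0 <= h0 < h1 <= nyq):
        raise ConfigError(f"bands must be within [0, {nyq}] Hz and non-degenerate")
    if h0 < l1 and l0 < h1 and not np.isclose(h0, l1):
        raise ConfigError("low and high bands overlap")
    if h0 < l0:
        raise ConfigError("low band must lie below the high band")
    f = S.freqs
    low = float(np.sum(S.power[(f >= l0) & (f <= l1)]))
    high = float(np.sum(S.power[(f > h0) & (f <= h1)]))
    if low == 0.0:
        return 0.0 if high == 0.0 else HIGH_LOW_SENTINEL
    return high / low


def energy_complexity(x: np.ndarray, bins: int = 16) -> dict[str, float]:
    """Signal energy (power per sample) and amplitude-histogram entropy.

    Energy is the mean squared mean-removed sample, so recordings of
    different durations are comparable. Shannon entropy is taken over a
    ``bins``-bin equal-width amplitude histogram spanning [min, max],
    normalized to [0, 1]; a constant series has entropy 0. This is an
    amplitude-distribution complexity measure, distinct from the
    spectral entropy.
    """
    x = np.asarray(x, float)
    if len(x) < 8:
        raise DataError(f"need >= 8 samples, got {len(x)}")
    xc = x - np.mean(x)
    energy = float(np.mean(xc**2))
    if np.ptp(x) == 0.0:
        return {"signal_energy": 0.0, "shannon_entropy": 0.0}
    counts, _ = np.histogram(x, bins=bins, range=(float(np.min(x)), float(np.max(x))))
    p = counts[counts > 0] / len(x)
    entropy = float(-np.sum(p * np.log(p)) / np.log(bins))
    return {"signal_energy": energy, "shannon_entropy": entropy}
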