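"""Per-recording feature extraction and feature-table assembly.

Every recording is reduced to a named scalar feature vector drawn from
two channels: the (unfiltered) acceleration vector magnitude and the
filtered barometric altitude. The full inventory is a superset of the
canonical 27-feature preset; :func:`build_feature_table` subsets to a
preset when asked.

Altimeter statistical features are computed on the filtered altitude
re-referenced to the mean of its first second, so they describe the
level change within the recording rather than the arbitrary absolute
altitude of the room.
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import DataError
from .features_freq import (
    band_power_ratio,
    dominant_frequency,
    energy_complexity,
    power_spectrum,
    spectral_shape,
)
from .features_time import (
    PeakParams,
    delta_h,
    jerk_features,
    kinematic_features,
    peak_features,
    stat_features,
    temporal_features,
)
from .io import META_COLUMNS, Recording
from .preprocess import DerivedSignals, derive_signals
from .select import canonical_preset


def _prefixed(prefix: str, d: dict[str, float]) -> dict[str, float]:
    return {f"{prefix}_{k}": v for k, v in d.items()}


def extract_features(rec: Recording, cfg: RunConfig | None = None,
                     derived: DerivedSignals | None = None) -> dict[str, float]:
    """Full feature vector (superset of the canonical preset) for one recording."""
    cfg = cfg or RunConfig()
    d = derived or derive_signals(rec, cfg)
    fs = d.fs
    feats: dict[str, float] = {}

    # --- AVM channel ---
    avm = d.avm
    feats.update(_prefixed("avm", stat_features(avm)))
    feats.update(_prefixed("avm", peak_features(
        avm, fs, PeakParams(cfg.peak_prominence_g, cfg.peak_separation_s))))
    feats.update(_prefixed("avm", jerk_features(avm, fs)))
    feats.update(_prefixed("avm", temporal_features(avm)))
    S = power_spectrum(avm, fs)
    feats.update(_prefixed("avm", spectral_shape(S)))
    feats.update(_prefixed("avm", dominant_frequency(S)))
    feats["avm_high_band_power_ratio"] = band_power_ratio(
        S, cfg.avm_low_band_hz, cfg.avm_high_band_hz)
    feats.update(_prefixed("avm", energy_complexity(avm, cfg.entropy_bins)))

    # --- altitude channel ---
    n_ref = max(1, min(int(round(fs)), len(d.h_filt)))
    h = d.h_filt - float(np.mean(d.h_filt[:n_ref]))
    v = d.v_vert
    feats.update(_prefixed("alt", stat_features(h)))
    feats.update(_prefixed("alt", temporal_features(h)))
    kin = kinematic_features(h, v, fs)
    alt_jerk = kin.pop("alt_jerk_rms")
    feats.update(_prefixed("alt", kin))
    feats["alt_jerk_rms"] = alt_jerk
    feats["alt_delta_h"] = delta_h(h, fs, cfg.delta_h_window_s)
    feats["alt_delta_h_w2"] = delta_h(h, fs, cfg.w2_s)
    S_alt = power_spectrum(h, fs)
    feats.update(_prefixed("alt", spectral_shape(S_alt)))
    feats.update(_prefixed("alt", dominant_frequency(S_alt)))
    feats["alt_high_band_power_ratio"] = band_power_ratio(
        S_alt, cfg.alt_low_band_hz, cfg.alt_high_band_hz)
    feats.update(_prefixed("alt", energy_complexity(h, cfg.entropy_bins)))

    bad = [k for k, v_ in feats.items() if not np.isfinite(v_)]
    if bad:
        raise DataError(f"{rec.recording_id}: non-finite feature(s) {bad}")
    return feats


def build_feature_table(recordings: Iterable[Recording], cfg: RunConfig | None = None,
                        preset: list[str] | str | None = None) -> pd.DataFrame:
    """Stack per-recording feature vectors into a labeled table.

    ``preset`` may be a sensor arm name (``fusion``/``avm``/``alt``) or
    an explicit ordered feature list; ``None`` keeps the full inventory.
    Metadata columns come first, feature columns follow in preset order.
    """
    cfg = cfg or RunConfig()
    if isinstance(preset, str):
        preset = canonical_preset(preset)
    rows = []
    for rec in recordings:
        row = {
            "recording_id": rec.recording_id,
            "subject_id": rec.subject_id,
            "dataset_tag": rec.dataset_tag,
            "placement": rec.placement,
            "label": rec.label,
        }
        row.update(extract_features(rec, cfg))
        rows.append(row)
    if not rows:
        raise DataError("no recordings to extract features from")
    df = pd.DataFrame(rows)
    if preset is not None:
        missing = [f for f in preset if f not in df.columns]
        if missing:
            raise DataError(f"preset feature(s) not extracted: {missing}")
        df = df[list(META_COLUMNS) + list(preset)]
    else:
        feats = [c for c in df.columns if c not in META_COLUMNS]
        df = df[list(META_COLUMNS) + feats]
    return df
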