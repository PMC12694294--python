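"""Feature scaling, Spearman redundancy pruning, and the canonical preset.

Feature names carry their sensor provenance as a prefix: ``avm_*``
features come from the acceleration vector magnitude, ``alt_*`` features
from the barometric altitude channel. The canonical preset is the
27-feature fused set (12 AVM + 15 altimeter) that survives redundancy
pruning at |rho| = 0.85 on the combined activity corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, UsageError
from .io import META_COLUMNS

SPEARMAN_THRESHOLD = 0.85

#: canonical fused feature set: 12 AVM + 15 altimeter features, in order
_PRESET_AVM = (
    "avm_median",
    "avm_iqr",
    "avm_kurtosis",
    "avm_mean_peak_amplitude",
    "avm_mean_step_interval",
    "avm_jerk_mean",
    "avm_jerk_rms",
    "avm_signal_energy",
    "avm_spectral_centroid",
    "avm_spectral_spread",
    "avm_spectral_entropy",
    "avm_dominant_frequency",
)
_PRESET_ALT = (
    "alt_median",
    "alt_iqr",
    "alt_skewness",
    "alt_kurtosis",
    "alt_mean_vert_velocity",
    "alt_max_vert_velocity",
    "alt_min_vert_velocity",
    "alt_jerk_rms",
    "alt_altitude_change",
    "alt_rms_vert_velocity",
    "alt_signal_energy",
    "alt_spectral_centroid",
    "alt_spectral_spread",
    "alt_high_band_power_ratio",
    "alt_delta_h",
)


def canonical_preset(arm: str = "fusion") -> list[str]:
    """Return the canonical feature list for a sensor arm.

    ``fusion`` is the full 27-name set; ``avm`` and ``alt`` are its
    12-feature accelerometer and 15-feature altimeter subsets.
    """
    if arm == "fusion":
        return list(_PRESET_AVM + _PRESET_ALT)
    if arm == "avm":
        return list(_PRESET_AVM)
    if arm == "alt":
        return list(_PRESET_ALT)
    raise UsageError(f"unknown sensor arm {arm!r} (expected fusion|avm|alt)")


def provenance(feature_name: str) -> str:
    """Sensor provenance of a feature name: 'avm' or 'alt'."""
    prefix = feature_name.split("_", 1)[0]
    if prefix not in ("avm", "alt"):
        raise UsageError(f"feature {feature_name!r} has no recognizable provenance prefix")
    return prefix


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


@dataclass
class ScalerState:
    """Per-feature z-score parameters estimated on a fit partition.

    Population (divide-by-n) standard deviations. Zero-variance columns
    are flagged and their transform degrades to identity-minus-mean
    (i.e. the column becomes all zeros).
    """

    features: list[str]
    mean: np.ndarray
    std: np.ndarray
    degenerate: list[str] = field(default_factory=list)

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        X = out[self.features].to_numpy(dtype=float)
        safe_std = np.where(self.std == 0.0, 1.0, self.std)
        out[self.features] = (X - self.mean) / safe_std
        return out


def fit_scaler(table: pd.DataFrame, fit_rows: np.ndarray | list | None = None) -> ScalerState:
    """Estimate z-score parameters from ``fit_rows`` only (default: all rows)."""
    feats = feature_columns(table)
    sub = table if fit_rows is None else table.iloc[np.asarray(fit_rows)]
    if len(sub) < 2:
        raise DataError("need at least 2 rows to fit a scaler")
    X = sub[feats].to_numpy(dtype=float)
    mean = X.mean(axis=0)
    std = X.std(axis=0)  # population convention
    degenerate = [f for f, s in zip(feats, std) if s == 0.0]
    return ScalerState(features=feats, mean=mean, std=std, degenerate=degenerate)


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation with average ranks for ties.

    Rank-based, hence robust to outliers and invariant under monotone
    transforms of either argument. Zero rank variance (a constant
    vector) maps to 0 by convention.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise DataError("need two equal-length vectors with n >= 3")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return 0.0
    rho = stats.spearmanr(x, y).statistic
    return 0.0 if np.isnan(rho) else float(rho)


@dataclass
class SelectionReport:
    """Outcome of redundancy pruning; every drop names its kept partner."""

    kept: list[str]
    dropped: list[tuple[str, str, float]]  # (feature, partner, rho)
    threshold: float

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "kept": self.kept,
            "dropped": [
                {"feature": f, "partner": p, "rho": r} for f, p, r in self.dropped
            ],
        }


def _canonical_order(feats: list[str]) -> list[str]:
    preset = canonical_preset("fusion")
    in_preset = [f for f in preset if f in feats]
    rest = sorted(f for f in feats if f not in preset)
    return in_preset + rest


def prune_redundant(
    table: pd.DataFrame, threshold: float = SPEARMAN_THRESHOLD, order: list[str] | None = None
) -> SelectionReport:
    """Greedy keep-first redundancy pruning at |rho| >= ``threshold``.

    Features are visited in a fixed canonical order (the canonical
    preset order first, then the remainder alphabetically) and a feature
    is dropped iff it correlates at |rho| >= threshold with an
    already-kept feature; the partner and rho are recorded, making the
    report re-verifiable from the input table. Deterministic given the
    table and order, and idempotent.
    """
    feats = feature_columns(table)
    if len(feats) < 2:
        raise DataError("need at least 2 features to prune")
    order = order or _canonical_order(feats)
    X = table[feats].to_numpy(dtype=float)
    n_feats = len(feats)
    if len(table) >= 3:
        rho_mat = stats.spearmanr(X).statistic
        if np.ndim(rho_mat) == 0:  # spearmanr collapses 2-feature input to a scalar
            r = float(rho_mat)
            rho_mat = np.array([[1.0, r], [r, 1.0]])
        rho_mat = np.nan_to_num(rho_mat, nan=0.0)
    else:
        rho_mat = np.zeros((n_feats, n_feats))
    col = {f: i for i, f in enumerate(feats)}
    kept: list[str] = []
    dropped: list[tuple[str, str, float]] = []
    for f in order:
        if f not in col:
            continue
        partners = [(g, rho_mat[col[f], col[g]]) for g in kept]
        over = [(g, r) for g, r in partners if abs(r) >= threshold]
        if over:
            partner, r = max(over, key=lambda t: abs(t[1]))
            dropped.append((f, partner, float(r)))
        else:
            kept.append(f)
    return SelectionReport(kept=kept, dropped=dropped, threshold=threshold)
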