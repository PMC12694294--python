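"""Domain types and CSV readers/writers.

A :class:`Recording` is one labeled activity trial: synchronized
tri-axial acceleration (g), barometric pressure (kPa) and ambient
temperature (degC) channels sampled at a common rate. Interchange format
is plain CSV with mandatory headers:

* recording CSV: ``t,ax,ay,az,p_kPa,T_C``
* manifest CSV: ``file,recording_id,subject_id,dataset_tag,placement,label``
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, UsageError

ACTIVITIES = ("falling", "jumping", "running", "sitting", "walking")
PLACEMENTS = ("navel", "hip", "wrist")

RECORDING_COLUMNS = ("t", "ax", "ay", "az", "p_kPa", "T_C")
MANIFEST_COLUMNS = ("file", "recording_id", "subject_id", "dataset_tag", "placement", "label")

#: metadata columns carried alongside features in a feature table
META_COLUMNS = ("recording_id", "subject_id", "dataset_tag", "placement", "label")


@dataclass
class Recording:
    """One labeled activity trial with synchronized sensor channels."""

    recording_id: str
    subject_id: str
    dataset_tag: str
    placement: str
    label: str
    fs: float
    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    p: np.ndarray  # kPa
    T: np.ndarray  # degC

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return self.n / self.fs

    def validate(self) -> None:
        arrays = [self.t, self.ax, self.ay, self.az, self.p, self.T]
        lengths = {len(a) for a in arrays}
        if len(lengths) != 1:
            raise DataError(f"{self.recording_id}: channel lengths differ: {sorted(lengths)}")
        if self.n < 2:
            raise DataError(f"{self.recording_id}: fewer than 2 samples")
        if self.fs <= 0:
            raise DataError(f"{self.recording_id}: fs must be positive")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise DataError(f"{self.recording_id}: time vector not strictly increasing")
        if np.any(self.p <= 0):
            raise DataError(f"{self.recording_id}: non-positive pressure sample")
        if self.label not in ACTIVITIES:
            raise DataError(f"{self.recording_id}: unknown label {self.label!r}")


def read_recording(path: str | Path, manifest_row: dict | pd.Series) -> Recording:
    """Parse a recording CSV; fs is inferred from the median time spacing.

    If the manifest declares an ``fs``, a mismatch of more than 1% against
    the inferred rate is an error (guards silently resampled files).
    """
    df = pd.read_csv(path)
    missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    if len(df) < 2:
        raise DataError(f"{path}: fewer than 2 samples")
    t = df["t"].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise DataError(f"{path}: time column not strictly increasing (duplicate or reversed timestamps)")
    fs = 1.0 / float(np.median(dt))
    declared = manifest_row.get("fs") if hasattr(manifest_row, "get") else None
    if declared is not None and not (isinstance(declared, float) and np.isnan(declared)):
        if abs(fs - float(declared)) > 0.01 * float(declared):
            raise DataError(
                f"{path}: inferred fs {fs:.2f} Hz deviates >1% from declared {declared} Hz"
            )
    return Recording(
        recording_id=str(manifest_row["recording_id"]),
        subject_id=str(manifest_row["subject_id"]),
        dataset_tag=str(manifest_row["dataset_tag"]),
        placement=str(manifest_row["placement"]),
        label=str(manifest_row["label"]),
        fs=fs,
        t=t,
        ax=df["ax"].to_numpy(dtype=float),
        ay=df["ay"].to_numpy(dtype=float),
        az=df["az"].to_numpy(dtype=float),
        p=df["p_kPa"].to_numpy(dtype=float),
        T=df["T_C"].to_numpy(dtype=float),
    )


def write_recording(rec: Recording, path: str | Path) -> None:
    pd.DataFrame(
        {"t": rec.t, "ax": rec.ax, "ay": rec.ay, "az": rec.az, "p_kPa": rec.p, "T_C": rec.T}
    ).to_csv(path, index=False, float_format="%.12g")


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: manifest missing column(s) {missing}")
    if df["recording_id"].duplicated().any():
        dup = df.loc[df["recording_id"].duplicated(), "recording_id"].iloc[0]
        raise DataError(f"{path}: duplicate recording_id {dup!r}")
    bad = set(df["label"]) - set(ACTIVITIES)
    if bad:
        raise DataError(f"{path}: unknown label(s) {sorted(bad)}")
    return df


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table (one row per recording) to CSV.

    Values are written with 12 significant digits so a round-trip read
    reproduces them at that precision. Non-finite entries are rejected
    with the offending feature and recording named.
    """
    if len(table) == 0:
        raise UsageError("refusing to write an empty feature table")
    feats = [c for c in table.columns if c not in META_COLUMNS]
    block = table[feats].to_numpy(dtype=float)
    if not np.all(np.isfinite(block)):
        i, j = np.argwhere(~np.isfinite(block))[0]
        rid = table.iloc[int(i)].get("recording_id", f"row {i}")
        raise DataError(f"non-finite value in feature {feats[int(j)]!r} of recording {rid!r}")
    table.to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    feats = [c for c in df.columns if c not in META_COLUMNS]
    block = df[feats].to_numpy(dtype=float)
    if not np.all(np.isfinite(block)):
        i, j = np.argwhere(~np.isfinite(block))[0]
        raise DataError(f"non-finite value in feature {feats[int(j)]!r} at row {i}")
    return df


def write_meta(path: str | Path, *, config_hash: str, seed: int, **extra) -> None:
    """Sidecar metadata (config hash, seed) accompanying a CSV artifact."""
    meta = {"config_hash": config_hash, "seed": seed, **extra}
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
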