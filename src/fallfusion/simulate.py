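"""Synthetic wearable-signal generator.

Real fall/ADL corpora of synchronized accelerometer + barometric
altimeter recordings are scarce, so this module generates recordings
with the structure such datasets exhibit:

* **falls** follow a three-phase profile: a quiet pre-fall phase near
  1 g, a free-fall dip below 1 g during which the altitude drops by
  0.5-1.0 m over 0.3-0.8 s, a sharp impact spike (3-8 g) at the end of
  the descent, and a quiet rest phase;
* **sitting** is a smooth 0.4-0.6 m descent over 1-2 s with a mild
  acceleration bump that stays below 2 g;
* **walking/running** are periodic AVM oscillations (1.6-2.2 Hz /
  2.4-3.2 Hz, running with larger amplitude) over flat altitude;
* **jumping** is a 0.8-1.5 Hz spike/dip cycle with a sub-0.5 m altitude
  oscillation.

Tri-axial components are produced by projecting the AVM profile onto a
random unit orientation (per phase for falls) — AVM is
orientation-invariant, so downstream features do not depend on this
choice. Pressure is synthesized by inverting the barometric formula at
the simulated temperature, so preprocessing recovers the altitude
exactly in the noiseless limit. Accelerometer "physiological"
fluctuation is band-limited (smooth) with a small white sensor-noise
floor on top; altitude noise is white Gaussian (default sd 0.15 m),
which the 1 Hz low-pass reduces to centimeters.

The default class mixture mirrors a heavily imbalanced sitting/fall
corpus scaled to n = 600 (392 sitting, 178 falls, 10 each of
walking/running/jumping), split across two dataset tags; the second tag
optionally applies a wrist-placement transform (per-recording amplitude
jitter x U(0.7, 1.3) and doubled sensor noise) to emulate acquisition
differences between cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .errors import UsageError
from .io import Recording
from .preprocess import altitude_to_pressure

DEFAULT_COUNTS = {"sitting": 392, "falling": 178, "walking": 10, "running": 10, "jumping": 10}
BALANCED_COUNTS = {k: 40 for k in DEFAULT_COUNTS}


@dataclass
class SimConfig:
    """Generator settings; defaults are the study conditions."""

    counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    duration_range_s: tuple[float, float] = (6.0, 9.0)
    fs: float = 201.0
    # falls
    prefall_range_s: tuple[float, float] = (1.5, 3.0)
    freefall_dip_g: tuple[float, float] = (0.2, 0.6)
    impact_peak_g: tuple[float, float] = (3.0, 8.0)
    fall_drop_m: tuple[float, float] = (0.5, 1.0)
    fall_drop_duration_s: tuple[float, float] = (0.3, 0.8)
    # sitting
    sit_depth_m: tuple[float, float] = (0.4, 0.6)
    sit_duration_s: tuple[float, float] = (1.0, 2.0)
    sit_bump_g: tuple[float, float] = (0.2, 0.6)
    # gait / jumping
    walk_freq_hz: tuple[float, float] = (1.6, 2.2)
    walk_amp_g: tuple[float, float] = (0.25, 0.45)
    run_freq_hz: tuple[float, float] = (2.4, 3.2)
    run_amp_g: tuple[float, float] = (0.6, 1.0)
    jump_freq_hz: tuple[float, float] = (0.8, 1.5)
    jump_amp_g: tuple[float, float] = (0.8, 1.5)
    jump_alt_amp_m: tuple[float, float] = (0.1, 0.25)
    # noise
    avm_fluctuation_g: float = 0.05      # band-limited body sway (sd)
    accel_noise_g: float = 0.008         # white sensor noise per axis (sd)
    alt_noise_m: float = 0.15            # white altitude noise pre-filter (sd)
    temp_baseline_c: tuple[float, float] = (20.0, 28.0)
    temp_drift_c_per_s: float = 0.002
    # cohorts
    dataset_tags: tuple[str, str] = ("synthA", "synthB")
    tag_b_fraction: float = 0.5
    placement_shift: bool = True         # wrist transform on the second tag
    wrist_jitter: tuple[float, float] = (0.7, 1.3)
    n_subjects: int = 30
    seed: int = 20250101

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise UsageError("class counts must be non-negative")
        if self.fs <= 0:
            raise UsageError("fs must be positive")
        if self.impact_peak_g[0] <= 1.0 - self.freefall_dip_g[0]:
            # impact must tower over everything else for the phase model to hold
            raise UsageError("impact peak range must exceed the free-fall dip level")


@dataclass
class FallAnnotation:
    """Ground truth for one simulated fall."""

    recording_id: str
    impact_sample: int
    impact_time_s: float
    drop_m: float


@dataclass
class SimDataset:
    recordings: list[Recording]
    manifest: pd.DataFrame
    annotations: list[FallAnnotation]


# ------------------------------------------------------------ helpers ----


def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _smooth_noise(rng: np.random.Generator, n: int, fs: float, sd: float,
                  cutoff: float = 3.0) -> np.ndarray:
    """Band-limited Gaussian fluctuation with the requested sd."""
    if sd == 0.0 or n < 30:
        return np.zeros(n)
    raw = rng.normal(size=n)
    sos = signal.butter(2, cutoff, btype="low", fs=fs, output="sos")
    sm = signal.sosfiltfilt(sos, raw)
    s = np.std(sm)
    return sm / s * sd if s > 0 else np.zeros(n)


def _ramp(n: int) -> np.ndarray:
    """Smooth 0 -> 1 cosine ramp over n samples."""
    return 0.5 * (1 - np.cos(np.linspace(0, np.pi, n)))


def _uniform(rng: np.random.Generator, lohi: tuple[float, float]) -> float:
    return float(rng.uniform(*lohi))


def _assemble(rec_id: str, subject: str, tag: str, placement: str, label: str,
              cfg: SimConfig, rng: np.random.Generator, avm_profile: np.ndarray,
              altitude: np.ndarray, phase_bounds: list[int], wrist: bool) -> Recording:
    """Project an AVM profile onto random orientations and synthesize pressure."""
    n = len(avm_profile)
    fs = cfg.fs
    t = np.arange(n) / fs
    profile = avm_profile.copy()
    noise_scale = 2.0 if wrist else 1.0
    if wrist:
        jitter = _uniform(rng, cfg.wrist_jitter)
        profile = 1.0 + (profile - 1.0) * jitter
    profile = profile + _smooth_noise(rng, n, fs, cfg.avm_fluctuation_g * noise_scale)
    profile = np.clip(profile, 0.05, None)

    # orientation per phase (bodies rotate during falls)
    axes = np.empty((3, n))
    bounds = [0] + sorted(phase_bounds) + [n]
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b <= a:
            continue
        u = _unit_vector(rng)
        axes[:, a:b] = np.outer(u, profile[a:b])
    axes += rng.normal(scale=cfg.accel_noise_g * noise_scale, size=(3, n))

    T = _uniform(rng, cfg.temp_baseline_c) + cfg.temp_drift_c_per_s * t
    h_noisy = altitude + rng.normal(scale=cfg.alt_noise_m, size=n)
    p = altitude_to_pressure(h_noisy, T)
    return Recording(
        recording_id=rec_id, subject_id=subject, dataset_tag=tag, placement=placement,
        label=label, fs=fs, t=t, ax=axes[0], ay=axes[1], az=axes[2], p=p, T=T,
    )


# --------------------------------------------------------- generators ----


def simulate_fall(cfg: SimConfig, rng: np.random.Generator, rec_id: str = "fall",
                  subject: str = "s0", tag: str = "synthA", placement: str = "navel",
                  wrist: bool = False) -> tuple[Recording, FallAnnotation]:
    """One three-phase fall with ground-truth impact time and altitude drop."""
    fs = cfg.fs
    n = int(round(_uniform(rng, cfg.duration_range_s) * fs))
    pre = int(round(_uniform(rng, cfg.prefall_range_s) * fs))
    drop_dur = int(round(_uniform(rng, cfg.fall_drop_duration_s) * fs))
    impact = pre + drop_dur                       # impact ends the descent
    impact_width = int(round(rng.uniform(0.06, 0.12) * fs))
    rest_start = impact + impact_width
    if rest_start >= n - 1:
        n = rest_start + int(round(1.0 * fs))     # guarantee a rest phase

    avm = np.ones(n)
    dip = 1.0 - _uniform(rng, cfg.freefall_dip_g)
    # free fall: AVM sinks toward the dip level
    avm[pre:impact] = 1.0 - (1.0 - dip) * _ramp(impact - pre)
    # impact: sharp spike, half-sine of the drawn peak height
    peak = _uniform(rng, cfg.impact_peak_g)
    spike = peak * np.sin(np.linspace(0, np.pi, impact_width))
    avm[impact:rest_start] = np.maximum(1.0, spike)

    drop = _uniform(rng, cfg.fall_drop_m)
    base = float(rng.uniform(0.5, 3.0))
    h = np.full(n, base)
    h[pre:impact] = base - drop * _ramp(impact - pre)
    h[impact:] = base - drop

    rec = _assemble(rec_id, subject, tag, "wrist" if wrist else placement, "falling",
                    cfg, rng, avm, h, [pre, impact, rest_start], wrist)
    peak_sample = impact + int(np.argmax(avm[impact:rest_start]))
    ann = FallAnnotation(recording_id=rec_id, impact_sample=peak_sample,
                         impact_time_s=peak_sample / fs, drop_m=drop)
    return rec, ann


def simulate_adl(cfg: SimConfig, activity: str, rng: np.random.Generator,
                 rec_id: str = "adl", subject: str = "s0", tag: str = "synthA",
                 placement: str = "navel", wrist: bool = False) -> Recording:
    """One activity-of-daily-living recording."""
    fs = cfg.fs
    n = int(round(_uniform(rng, cfg.duration_range_s) * fs))
    t = np.arange(n) / fs
    base = float(rng.uniform(0.5, 3.0))
    phase_bounds: list[int] = []

    if activity == "sitting":
        avm = np.ones(n)
        h = np.full(n, base)
        dur = int(round(_uniform(rng, cfg.sit_duration_s) * fs))
        start = int(rng.uniform(0.15, 0.5) * (n - dur))
        depth = _uniform(rng, cfg.sit_depth_m)
        h[start:start + dur] = base - depth * _ramp(dur)
        h[start + dur:] = base - depth
        bump = _uniform(rng, cfg.sit_bump_g)
        avm[start:start + dur] += bump * np.sin(np.linspace(0, np.pi, dur))
        phase_bounds = [start, start + dur]
    elif activity in ("walking", "running"):
        f = _uniform(rng, cfg.walk_freq_hz if activity == "walking" else cfg.run_freq_hz)
        a = _uniform(rng, cfg.walk_amp_g if activity == "walking" else cfg.run_amp_g)
        phi = rng.uniform(0, 2 * np.pi)
        avm = 1.0 + a * np.sin(2 * np.pi * f * t + phi)
        # mild second harmonic sharpens steps without moving the dominant bin
        avm += 0.15 * a * np.sin(4 * np.pi * f * t + 2 * phi)
        h = np.full(n, base)
    elif activity == "jumping":
        f = _uniform(rng, cfg.jump_freq_hz)
        a = _uniform(rng, cfg.jump_amp_g)
        phi = rng.uniform(0, 2 * np.pi)
        cyc = np.sin(2 * np.pi * f * t + phi)
        # rectified-ish cycle: sharp landing spikes, deep flight dips
        avm = 1.0 + a * np.where(cyc > 0, cyc**2 * 1.3, cyc * 0.6)
        h = base + _uniform(rng, cfg.jump_alt_amp_m) * np.sin(2 * np.pi * f * t + phi)
    else:
        raise UsageError(f"unknown activity {activity!r}")

    return _assemble(rec_id, subject, tag, "wrist" if wrist else placement, activity,
                     cfg, rng, avm, h, phase_bounds, wrist)


def simulate_dataset(cfg: SimConfig | None = None) -> SimDataset:
    """Generate the configured class mixture across subjects and two tags.

    Recordings alternate deterministically between the two dataset tags
    at ``tag_b_fraction``; the second tag applies the wrist transform
    when ``placement_shift`` is set. Fully deterministic given the seed.
    """
    cfg = cfg or SimConfig()
    if sum(cfg.counts.values()) == 0:
        raise UsageError("all class counts are zero")
    rng = np.random.default_rng(cfg.seed)
    recordings: list[Recording] = []
    annotations: list[FallAnnotation] = []
    rows = []
    idx = 0
    for label in sorted(cfg.counts):
        for k in range(cfg.counts[label]):
            rec_id = f"{label}_{k:04d}"
            subject = f"subj{idx % cfg.n_subjects:02d}"
            # deterministic Bresenham interleave at the configured fraction
            frac = min(max(cfg.tag_b_fraction, 0.0), 1.0)
            tag_b = int((k + 1) * frac) > int(k * frac)
            tag = cfg.dataset_tags[1] if tag_b else cfg.dataset_tags[0]
            wrist = tag_b and cfg.placement_shift
            if label == "falling":
                rec, ann = simulate_fall(cfg, rng, rec_id, subject, tag, wrist=wrist)
                annotations.append(ann)
            else:
                rec = simulate_adl(cfg, label, rng, rec_id, subject, tag, wrist=wrist)
            recordings.append(rec)
            rows.append({
                "file": f"{rec_id}.csv",
                "recording_id": rec_id,
                "subject_id": subject,
                "dataset_tag": tag,
                "placement": rec.placement,
                "label": label,
            })
            idx += 1
    manifest = pd.DataFrame(rows)
    return SimDataset(recordings=recordings, manifest=manifest, annotations=annotations)


def write_dataset(ds: SimDataset, out_dir: str | Path) -> None:
    """Dump recordings, manifest and ground truth to a directory of CSV/JSON."""
    from .io import write_recording

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in ds.recordings:
        write_recording(rec, out / f"{rec.recording_id}.csv")
    ds.manifest.to_csv(out / "manifest.csv", index=False)
    gt = [
        {"recording_id": a.recording_id, "impact_sample": a.impact_sample,
         "impact_time_s": a.impact_time_s, "drop_m": a.drop_m}
        for a in ds.annotations
    ]
    import json

    (out / "ground_truth.json").write_text(json.dumps(gt, indent=2) + "\n")
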