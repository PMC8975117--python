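"""Severity-graded synthetic Leg Agility cohorts.

The Leg Agility task — raising and stomping the foot at least 10 times, as
high and fast as possible, from a seated posture — is simulated as a train
of raised-cosine pitch pulses of the thigh:

    theta(t) = A_i / 2 * (1 - cos(2*pi*(t - s_i) / T_i)),   t in cycle i

with per-cycle amplitude decrement, cycle-time jitter, hesitation pauses,
optional early interruption and a superimposed 5 Hz tremor term.  Angular
velocity about x is the analytic time derivative of pitch; vertical
acceleration is gravity plus the second derivative of the vertical sensor
excursion (lever * sin(theta)) plus a short impulse at each foot strike.
The device is mounted with a small random tilt about x, so the gravity
vector leaks into the y-axis until recalibration.

Severity (the clinical 0-4 score) maps linearly onto the motor parameters:
slower and smaller movement, faster decrement, more hesitations and jitter
as severity grows.  The anchors are frozen so that a severity-0 recording
matches the young-adult envelope a modern smartphone IMU must cover (gyro
peaks around 236 dps, acceleration peaks around 1.1-1.5 g), and all samples
are quantized to the sensor resolution (40 mg, 60 mdps) and clipped to the
sensor range (+-2 g, +-2000 dps) at 200 Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .sensor_io import (
    CohortManifest,
    InertialRecording,
    ManifestEntry,
    RatingSet,
    write_manifest,
    write_recording,
)
from ._utils import round_half_away

GRAVITY_MS2 = 9.80665

#: Default cohort severity mix, emulating the skew of a movement-disorder
#: outpatient population (most recordings mild-to-moderate, few severe).
DEFAULT_SEVERITY_MIX = {0: 0.10, 1: 0.25, 2: 0.35, 3: 0.22, 4: 0.08}


@dataclass
class SeverityProfile:
    """Motor parameters of one Leg Agility execution at a given severity."""

    severity: float
    base_frequency: float       # Hz, stomping rate
    base_amplitude: float       # degrees of pitch excursion
    amplitude_decrement_rate: float  # fractional amplitude loss per repetition
    hesitation_rate: float      # expected pauses per 10 s
    hesitation_duration: float  # s
    interruption_prob: float    # chance of stopping early
    jitter: float               # cycle-time coefficient of variation
    tremor_amplitude: float     # degrees, 5 Hz superimposed component

    @classmethod
    def from_severity(cls, severity: float) -> "SeverityProfile":
        """Linear interpolation between the frozen severity anchors.

        Severity 0: 3.0 Hz / 25 deg (gyro peak A*pi*f ~ 236 dps);
        severity 4: 1.0 Hz / 6 deg with heavy decrement and hesitations.
        """
        s = float(np.clip(severity, 0.0, 4.0))
        return cls(
            severity=s,
            base_frequency=3.0 - 0.5 * s,
            base_amplitude=25.0 - 4.75 * s,
            amplitude_decrement_rate=0.005 + 0.02 * s,
            hesitation_rate=0.5 * s,
            hesitation_duration=0.4,
            interruption_prob=0.03 * s,
            jitter=0.03 + 0.03 * s,
            # rest tremor is largely suppressed during voluntary movement;
            # a small superimposed component keeps the power concentrated
            # in the <4 Hz movement band
            tremor_amplitude=0.15 * s,
        )


@dataclass
class SensorModel:
    """Smartphone IMU envelope: range, resolution, rate, noise."""

    fs: float = 200.0
    accel_range: float = 2.0          # g
    accel_resolution: float = 0.040   # g (40 mg)
    gyro_range: float = 2000.0        # dps
    gyro_resolution: float = 0.060    # dps (60 mdps)
    accel_noise_sd: float = 0.01      # g
    gyro_noise_sd: float = 1.0        # dps
    pitch_noise_sd: float = 0.1       # degrees


#: Effective hip-to-sensor lever arm (m) converting pitch to vertical
#: excursion; calibrated so severity-0 acceleration peaks sit near 1.1-1.5 g.
LEVER_M = 0.04
#: Foot-strike impulse: peak amplitude (g, at severity-0 amplitude) and
#: Gaussian half-width (s).  Real stomp sharpness is unpublished; this
#: default concentrates the impulse well above the 4 Hz analysis band.
STOMP_AMPLITUDE_G = 0.25
STOMP_WIDTH_S = 0.02
TREMOR_HZ = 5.0


def _quantize(x: np.ndarray, resolution: float, vrange: float) -> np.ndarray:
    return np.clip(np.round(x / resolution) * resolution, -vrange, vrange)


def simulate_recording(
    profile: SeverityProfile,
    sensor: SensorModel | None = None,
    duration: float = 10.0,
    seed: int = 0,
    recording_id: str = "sim",
    subject_id: str = "subj",
    leg: str = "left",
) -> InertialRecording:
    """Simulate one Leg Agility execution.

    Reproducible: the same (profile, sensor, duration, seed) always yields
    an identical recording.
    """
    if duration < 5.0:
        raise ValueError("duration must be >= 5 s")
    sensor = sensor or SensorModel()
    rng = np.random.default_rng(seed)
    fs = sensor.fs
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    dt = 1.0 / fs

    # --- segment plan: cycles with decrement/jitter, plus hesitation pauses
    T0 = 1.0 / profile.base_frequency
    segments: list[tuple[str, float, float]] = []  # (kind, duration, amplitude)
    total, i = 0.0, 0
    while total < duration:
        Ti = T0 * max(0.3, 1.0 + profile.jitter * rng.standard_normal())
        Ai = profile.base_amplitude * (1.0 - profile.amplitude_decrement_rate) ** i
        segments.append(("cycle", Ti, Ai))
        total += Ti
        i += 1
    n_cycles = i
    if n_cycles < 1:
        warnings.warn(f"{recording_id}: degenerate recording with < 1 full cycle")

    n_pauses = rng.poisson(profile.hesitation_rate * duration / 10.0)
    for _ in range(n_pauses):
        pos = rng.integers(1, len(segments) + 1)
        dur = profile.hesitation_duration * (0.6 + 0.8 * rng.random())
        segments.insert(int(pos), ("pause", dur, 0.0))

    if n_cycles >= 3 and rng.random() < profile.interruption_prob:
        # early stop: keep at least 60% of the planned cycles, rest quiet
        keep = int(np.ceil(0.6 * len(segments))) + int(rng.integers(0, max(1, len(segments) // 4)))
        segments = segments[:min(keep, len(segments))]

    # --- analytic pitch and angular velocity
    theta = np.zeros(n)
    omega = np.zeros(n)
    strikes: list[tuple[float, float]] = []  # (time, relative amplitude)
    start = 0.0
    for kind, seg_dur, amp in segments:
        if start >= duration:
            break
        if kind == "cycle":
            a, b = start, min(start + seg_dur, duration)
            sl = (t >= a) & (t < b)
            phase = 2.0 * np.pi * (t[sl] - start) / seg_dur
            theta[sl] = amp / 2.0 * (1.0 - np.cos(phase))
            omega[sl] = amp * np.pi / seg_dur * np.sin(phase)
            if start + seg_dur <= duration:
                strikes.append((start + seg_dur, amp / 25.0))
        start += seg_dur

    if profile.tremor_amplitude > 0:
        theta = theta + profile.tremor_amplitude * np.sin(2 * np.pi * TREMOR_HZ * t)
        omega = omega + profile.tremor_amplitude * 2 * np.pi * TREMOR_HZ * np.cos(2 * np.pi * TREMOR_HZ * t)

    # --- vertical acceleration (world frame, g): gravity + excursion + stomps
    h = LEVER_M * np.sin(np.radians(theta))
    a_dyn = np.gradient(np.gradient(h, dt), dt) / GRAVITY_MS2
    a_z = 1.0 + a_dyn
    for ts, rel in strikes:
        a_z += STOMP_AMPLITUDE_G * rel * np.exp(-0.5 * ((t - ts) / STOMP_WIDTH_S) ** 2)

    # --- device frame: fixed mounting tilt about x leaks gravity into y
    tilt = np.radians(rng.normal(8.0, 2.0))
    accel = np.column_stack([
        np.zeros(n),
        np.sin(tilt) * a_z,
        np.cos(tilt) * a_z,
    ])
    gyro = np.column_stack([omega, np.zeros(n), np.zeros(n)])

    accel += rng.normal(0.0, sensor.accel_noise_sd, size=accel.shape)
    gyro += rng.normal(0.0, sensor.gyro_noise_sd, size=gyro.shape)
    pitch = theta + np.degrees(tilt) + rng.normal(0.0, sensor.pitch_noise_sd, size=n)

    accel = _quantize(accel, sensor.accel_resolution, sensor.accel_range)
    gyro = _quantize(gyro, sensor.gyro_resolution, sensor.gyro_range)

    return InertialRecording(
        recording_id=recording_id,
        subject_id=subject_id,
        leg=leg,
        fs=fs,
        t=t,
        accel=accel,
        gyro=gyro,
        pitch=pitch,
    )


def simulate_raters(true_severity: float, n_raters: int = 4, rater_sd: float = 0.5,
                    seed: int = 0, recording_id: str = "sim") -> RatingSet:
    """Noisy integer ratings: clip(round(true + N(0, sd)), 0, 4) per rater."""
    if n_raters < 1:
        raise ValueError("need at least one rater")
    rng = np.random.default_rng(seed)
    raw = true_severity + rng.normal(0.0, rater_sd, size=n_raters)
    scores = np.clip(round_half_away(raw), 0, 4).astype(int)
    return RatingSet(recording_id=recording_id, scores=list(scores))


def simulate_cohort(
    n_subjects: int,
    severity_mix: dict[int, float] | None = None,
    seed: int = 0,
    out_dir=None,
    duration: float = 10.0,
    n_raters: int = 4,
    rater_sd: float = 0.5,
    single_leg_prob: float = 0.02,
    subject_sd: float = 0.3,
    sensor: SensorModel | None = None,
) -> tuple[CohortManifest, pd.DataFrame]:
    """Simulate a full cohort: two recordings per subject (rarely one).

    Each subject draws a severity class from ``severity_mix``; the two legs
    share the subject's effect and deviate from it with SD ``subject_sd``,
    so legs usually share a label and occasionally differ by one.

    Returns the manifest (with in-memory recordings, or file paths when
    ``out_dir`` is given) and a ground-truth table with each recording's
    true severity — bookkeeping the real study never has.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    mix = dict(severity_mix or DEFAULT_SEVERITY_MIX)
    classes = sorted(mix)
    probs = np.array([mix[c] for c in classes], dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError(f"severity mix must sum to 1, got {probs.sum():.3f}")

    rng = np.random.default_rng(seed)
    sensor = sensor or SensorModel()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    entries: list[ManifestEntry] = []
    truth_rows = []
    for s in range(n_subjects):
        subject_id = f"S{s + 1:03d}"
        cls = int(rng.choice(classes, p=probs))
        subject_sev = float(np.clip(cls + rng.normal(0.0, 0.15), 0.0, 4.0))
        legs = ["left", "right"]
        if rng.random() < single_leg_prob:
            legs = [legs[int(rng.integers(0, 2))]]
        for leg in legs:
            rid = f"{subject_id}_{leg}"
            sev = float(np.clip(subject_sev + rng.normal(0.0, subject_sd), 0.0, 4.0))
            rec_seed = int(rng.integers(0, 2**31 - 1))
            rate_seed = int(rng.integers(0, 2**31 - 1))
            rec = simulate_recording(
                SeverityProfile.from_severity(sev), sensor, duration,
                seed=rec_seed, recording_id=rid, subject_id=subject_id, leg=leg,
            )
            ratings = simulate_raters(sev, n_raters, rater_sd, seed=rate_seed,
                                      recording_id=rid)
            path = None
            if out is not None:
                path = str(out / f"{rid}.csv")
                write_recording(rec, path)
            entries.append(ManifestEntry(
                recording_id=rid, subject_id=subject_id, leg=leg,
                path=path, ratings=ratings,
                recording=None if out is not None else rec,
            ))
            truth_rows.append({"recording_id": rid, "subject_id": subject_id,
                               "leg": leg, "true_severity": sev,
                               "severity_class": cls})

    manifest = CohortManifest(entries=entries)
    truth = pd.DataFrame(truth_rows).set_index("recording_id")
    if out is not None:
        write_manifest(manifest, out / "manifest.csv", max_raters=n_raters)
        truth.to_csv(out / "truth.csv")
    return manifest, truth
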