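"""Gravity recalibration, mean removal and zero-lag low-pass filtering.

The device is strapped to the thigh with the y-axis along the femur, so in
the ideal mounting gravity acts only on the accelerometer z-axis.  Real
mountings deviate by a few degrees; :func:`recalibrate` estimates the mean
gravity direction over a reference window and applies the shortest-arc
quaternion rotation that maps it onto +z, to both the accelerometer and the
gyroscope.  Signals are then mean-removed and low-pass filtered with an
order-2 Butterworth applied forward-backward (zero phase).  The 4 Hz default
cutoff retains at least 90% of the signal power of rhythmic leg-agility
movement (fundamental ~1-3 Hz plus low harmonics); :func:`select_cutoff`
recomputes that power-retention cutoff from a collection of spectra.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps
from scipy.spatial.transform import Rotation

from .errors import CalibrationError
from .sensor_io import InertialRecording

DEFAULT_CUTOFF_HZ = 4.0
DEFAULT_ORDER = 2
DEFAULT_RETAIN = 0.9


@dataclass
class CalibratedRecording:
    """A recording after gravity alignment (and optionally filtering).

    ``rotation`` is the unit quaternion (x, y, z, w) that was applied;
    ``gravity_residual`` is the magnitude of the mean x/y acceleration after
    rotation, in g — near zero when the static gravity correction succeeded.
    """

    recording_id: str
    subject_id: str
    leg: str
    fs: float
    t: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    pitch: np.ndarray
    rotation: np.ndarray
    gravity_residual: float
    filtered: bool = False

    @property
    def theta_x(self) -> np.ndarray:
        """Pitch about the device x-axis, degrees."""
        return self.pitch

    @property
    def omega_x(self) -> np.ndarray:
        """Angular velocity about the device x-axis, dps."""
        return self.gyro[:, 0]

    @property
    def alpha_z(self) -> np.ndarray:
        """Vertical (z-axis) acceleration, g."""
        return self.accel[:, 2]


def _shortest_arc_quaternion(v: np.ndarray, target: np.ndarray) -> Rotation:
    """Rotation taking unit vector ``v`` onto unit vector ``target`` along
    the shortest arc; the antiparallel degenerate case rotates pi about x."""
    v = v / np.linalg.norm(v)
    target = target / np.linalg.norm(target)
    dot = float(np.clip(np.dot(v, target), -1.0, 1.0))
    if dot > 1.0 - 1e-12:
        return Rotation.identity()
    if dot < -1.0 + 1e-12:
        return Rotation.from_rotvec(np.pi * np.array([1.0, 0.0, 0.0]))
    axis = np.cross(v, target)
    axis /= np.linalg.norm(axis)
    angle = np.arccos(dot)
    return Rotation.from_rotvec(angle * axis)


def recalibrate(rec: InertialRecording, window: Optional[float] = None) -> CalibratedRecording:
    """Rotate device axes so the mean gravity direction becomes +z.

    Parameters
    ----------
    rec
        The raw recording.
    window
        Reference window length in seconds from the start of the recording
        over which mean acceleration estimates gravity.  Default: the whole
        recording (the task is seated and the thigh returns to rest between
        stomps, so the full-record mean is gravity-dominated).

    Raises
    ------
    CalibrationError
        If the reference-window mean acceleration magnitude is outside
        [0.5, 1.5] g — the device was likely moving or mis-scaled.
    """
    if window is not None:
        if window > rec.duration:
            raise CalibrationError(
                f"reference window {window} s exceeds recording duration {rec.duration:.2f} s"
            )
        mask = rec.t - rec.t[0] <= window
    else:
        mask = np.ones(len(rec.t), dtype=bool)

    g_vec = rec.accel[mask].mean(axis=0)
    g_mag = float(np.linalg.norm(g_vec))
    if not (0.5 <= g_mag <= 1.5):
        raise CalibrationError(
            f"{rec.recording_id}: reference accel magnitude {g_mag:.3f} g outside [0.5, 1.5]"
        )

    rot = _shortest_arc_quaternion(g_vec, np.array([0.0, 0.0, 1.0]))
    accel = rot.apply(rec.accel)
    gyro = rot.apply(rec.gyro)

    if rec.pitch is not None:
        pitch = np.asarray(rec.pitch, dtype=float)
    else:
        # Recompute pitch about x from the rotated gravity direction:
        # rotation about x tilts the y-z plane, so theta_x = atan2(-a_y, a_z).
        pitch = np.degrees(np.arctan2(-accel[:, 1], accel[:, 2]))

    residual = float(np.linalg.norm(accel[mask].mean(axis=0)[:2]))
    return CalibratedRecording(
        recording_id=rec.recording_id,
        subject_id=rec.subject_id,
        leg=rec.leg,
        fs=rec.fs,
        t=rec.t,
        accel=accel,
        gyro=gyro,
        pitch=pitch,
        rotation=rot.as_quat(),
        gravity_residual=residual,
    )


def select_cutoff(spectra: Sequence, retain: float = DEFAULT_RETAIN) -> float:
    """Smallest frequency retaining ``retain`` of the cohort's mean power.

    Each spectrum's power is normalized to unit total, the cumulative
    distributions are averaged across spectra, and the smallest frequency
    bin whose averaged cumulative power reaches ``retain`` is returned.
    """
    if not (0.0 < retain < 1.0):
        raise ValueError(f"retain must be in (0, 1), got {retain}")
    spectra = list(spectra)
    if not spectra:
        raise ValueError("empty spectrum list")
    freqs = np.asarray(spectra[0].freqs)
    cum = np.zeros_like(freqs, dtype=float)
    for spec in spectra:
        if len(spec.freqs) != len(freqs) or not np.allclose(spec.freqs, freqs):
            raise ValueError("spectra must share a common frequency grid")
        p = np.asarray(spec.power, dtype=float)
        cum += np.cumsum(p) / p.sum()
    cum /= len(spectra)
    idx = int(np.searchsorted(cum, retain - 1e-12))
    idx = min(idx, len(freqs) - 1)
    return float(freqs[idx])


def lowpass_zero_lag(x: np.ndarray, fs: float, cutoff: float = DEFAULT_CUTOFF_HZ,
                     order: int = DEFAULT_ORDER) -> np.ndarray:
    """Mean-remove and low-pass filter with a forward-backward Butterworth.

    The order-``order`` design is applied in both directions (``filtfilt``),
    giving zero phase; the effective magnitude response is the square of the
    one-pass response.  Edges use the default odd-reflection padding of
    three filter lengths.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if not (0.0 < cutoff < fs / 2.0):
        raise ValueError(f"cutoff {cutoff} Hz must lie in (0, Nyquist={fs / 2:.1f})")
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    b, a = sps.butter(order, cutoff, btype="low", fs=fs)
    return sps.filtfilt(b, a, x)


def preprocess_recording(rec: InertialRecording, cutoff_hz: float = DEFAULT_CUTOFF_HZ,
                         order: int = DEFAULT_ORDER,
                         reference_window_s: Optional[float] = None) -> CalibratedRecording:
    """Full preprocessing: recalibrate, mean-remove, zero-lag low-pass.

    Applies the gravity correction, then removes the mean and filters every
    analysis channel (pitch, all accelerometer and gyroscope axes).
    """
    cal = recalibrate(rec, window=reference_window_s)
    accel = np.column_stack(
        [lowpass_zero_lag(cal.accel[:, i], cal.fs, cutoff_hz, order) for i in range(3)]
    )
    gyro = np.column_stack(
        [lowpass_zero_lag(cal.gyro[:, i], cal.fs, cutoff_hz, order) for i in range(3)]
    )
    pitch = lowpass_zero_lag(cal.pitch, cal.fs, cutoff_hz, order)
    return CalibratedRecording(
        recording_id=cal.recording_id,
        subject_id=cal.subject_id,
        leg=cal.leg,
        fs=cal.fs,
        t=cal.t,
        accel=accel,
        gyro=gyro,
        pitch=pitch,
        rotation=cal.rotation,
        gravity_residual=cal.gravity_residual,
        filtered=True,
    )
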