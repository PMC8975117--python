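"""The 36-feature kinematic/spectral catalog of a Leg Agility recording.

Twelve feature families are computed on each of the three analysis signals
theta_x (pitch about the device x-axis, degrees), omega_x (angular velocity
about x, dps) and alpha_z (vertical acceleration, g):

    dominant_frequency, entropy, minimum, maximum, rms, range,
    spectral_entropy, mean_amplitude, regularity, dominant_ratio,
    standard_deviation, mean_peak_value

Spectra are one-sided FFTs of the mean-removed signal with a rectangular
window; spectral leakage at ~10 s record lengths is acceptable for these
descriptors.  Conventions that the literature leaves open are fixed here and
documented: the time-domain entropy is the Shannon entropy of a 16-bin
amplitude histogram; mean_amplitude is the mean peak-to-peak excursion over
movement cycles segmented on the pitch signal's rising zero crossings (it
tracks the amplitude criterion of the clinical scale); harmonic widths are
full width at half maximum with linear interpolation between bins.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ChannelError, DegenerateSpectrumError
from .preprocess import CalibratedRecording

logger = logging.getLogger(__name__)

SIGNALS = ("theta_x", "omega_x", "alpha_z")
FAMILIES = (
    "dominant_frequency",
    "entropy",
    "minimum",
    "maximum",
    "rms",
    "range",
    "spectral_entropy",
    "mean_amplitude",
    "regularity",
    "dominant_ratio",
    "standard_deviation",
    "mean_peak_value",
)
#: The frozen 36-name feature catalog (12 families x 3 signals).
FEATURE_NAMES = tuple(f"{fam}_{sig}" for sig in SIGNALS for fam in FAMILIES)

DEFAULT_REL_THRESHOLD = 0.1
DEFAULT_MIN_SEPARATION_HZ = 0.25
DEFAULT_BAND_HALFWIDTH_HZ = 0.25
ENTROPY_BINS = 16


@dataclass
class Spectrum:
    """One-sided spectrum of a mean-removed signal.

    ``magnitude`` is the amplitude per bin (a unit sine contributes ~1 at
    its bin); ``power`` is scaled so that ``sum(power)`` equals the signal's
    mean squared value (time-averaged power, Parseval).
    """

    freqs: np.ndarray
    magnitude: np.ndarray
    power: np.ndarray
    resolution: float


@dataclass
class HarmonicSet:
    """Spectral peaks: (frequency Hz, amplitude, FWHM width Hz) triples."""

    peaks: list[tuple[float, float, float]]
    dominant_index: int = 0

    @property
    def n_harmonics(self) -> int:
        return len(self.peaks)

    @property
    def dominant(self) -> tuple[float, float, float]:
        return self.peaks[self.dominant_index]


@dataclass
class FeatureVector:
    recording_id: str
    values: dict[str, float]

    def __post_init__(self):
        missing = [n for n in FEATURE_NAMES if n not in self.values]
        if missing:
            raise ValueError(f"feature vector incomplete, missing {missing[:3]}...")


def compute_spectrum(x: np.ndarray, fs: float) -> Spectrum:
    """One-sided FFT magnitude/power spectrum of the mean-removed signal."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2 * fs:
        raise ValueError(f"need >= 2*fs samples, got {n} at fs={fs}")
    x = x - x.mean()
    if np.allclose(x, 0.0):
        raise DegenerateSpectrumError("constant signal has no spectrum")
    X = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    # one-sided scaling: double interior bins (DC and Nyquist are unique)
    scale = np.full(len(X), 2.0)
    scale[0] = 1.0
    if n % 2 == 0:
        scale[-1] = 1.0
    magnitude = scale * np.abs(X) / n
    power = scale * np.abs(X) ** 2 / n**2
    return Spectrum(freqs=freqs, magnitude=magnitude, power=power,
                    resolution=float(freqs[1] - freqs[0]))


def dominant_frequency(spec: Spectrum) -> float:
    """Frequency of the largest-magnitude bin; ties go to the lower frequency."""
    return float(spec.freqs[int(np.argmax(spec.magnitude))])


def _fwhm(freqs: np.ndarray, mag: np.ndarray, idx: int) -> float:
    """Full width at half maximum around bin ``idx``, linearly interpolated.

    Flanks that never fall below half maximum extend to the spectrum edge.
    """
    half = mag[idx] / 2.0
    left = freqs[0]
    for i in range(idx, 0, -1):
        if mag[i - 1] <= half:
            frac = (mag[i] - half) / (mag[i] - mag[i - 1])
            left = freqs[i] - frac * (freqs[i] - freqs[i - 1])
            break
    right = freqs[-1]
    for i in range(idx, len(mag) - 1):
        if mag[i + 1] <= half:
            frac = (mag[i] - half) / (mag[i] - mag[i + 1])
            right = freqs[i] + frac * (freqs[i + 1] - freqs[i])
            break
    return float(max(right - left, 1e-12))


def detect_harmonics(spec: Spectrum, rel_threshold: float = DEFAULT_REL_THRESHOLD,
                     min_separation: float = DEFAULT_MIN_SEPARATION_HZ) -> HarmonicSet:
    """Spectral peaks above ``rel_threshold`` of the dominant amplitude.

    Local maxima of the magnitude spectrum at least ``min_separation`` Hz
    apart; when two candidates are closer, the larger-amplitude one wins.
    """
    mag = spec.magnitude
    freqs = spec.freqs
    peak_idx = [
        i for i in range(1, len(mag) - 1)
        if mag[i] > mag[i - 1] and mag[i] >= mag[i + 1]
    ]
    if not peak_idx:
        peak_idx = [int(np.argmax(mag))]
    thr = rel_threshold * mag[max(peak_idx, key=lambda i: mag[i])]
    peak_idx = [i for i in peak_idx if mag[i] >= thr]
    # greedy separation enforcement, highest amplitude first
    accepted: list[int] = []
    for i in sorted(peak_idx, key=lambda i: (-mag[i], freqs[i])):
        if all(abs(freqs[i] - freqs[j]) >= min_separation for j in accepted):
            accepted.append(i)
    accepted.sort()
    peaks = [(float(freqs[i]), float(mag[i]), _fwhm(freqs, mag, i)) for i in accepted]
    dom = int(np.argmax([p[1] for p in peaks]))
    return HarmonicSet(peaks=peaks, dominant_index=dom)


def spectral_entropy(spec: Spectrum) -> float:
    """Shannon entropy of the power distribution, normalized to [0, 1].

    Power per bin is normalized to a probability distribution and the
    entropy divided by log(n_bins), so the value is base-agnostic: 0 for a
    point mass, 1 for white (uniform) power.
    """
    p = np.asarray(spec.power, dtype=float)
    total = p.sum()
    if total <= 0:
        raise DegenerateSpectrumError("zero total power")
    p = p / total
    nz = p[p > 0]
    h = -np.sum(nz * np.log(nz))
    return float(h / np.log(len(p)))


def regularity(x: np.ndarray) -> float:
    """First positive-lag autocorrelation peak over the lag-0 value.

    Near 1 for metronomic movement, near 0 for erratic movement.  Uses the
    biased autocorrelation estimate; returns 0 (with a warning) when no
    positive-lag local maximum exists.
    """
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    ac = np.correlate(x, x, mode="full")[len(x) - 1:]
    if ac[0] <= 0:
        warnings.warn("constant signal: regularity undefined, returning 0")
        return 0.0
    for k in range(1, len(ac) - 1):
        if ac[k] > ac[k - 1] and ac[k] >= ac[k + 1]:
            return float(ac[k] / ac[0])
    warnings.warn("no positive-lag autocorrelation maximum; returning 0")
    return 0.0


def dominant_ratio(spec: Spectrum, band_halfwidth: float = DEFAULT_BAND_HALFWIDTH_HZ) -> float:
    """Fraction of total power within +-``band_halfwidth`` of the dominant
    frequency — a rhythmicity/purity index in (0, 1]."""
    fd = dominant_frequency(spec)
    band = np.abs(spec.freqs - fd) <= band_halfwidth
    return float(spec.power[band].sum() / spec.power.sum())


def _cycle_bounds_from_zero_crossings(ref: np.ndarray) -> list[tuple[int, int]]:
    """Movement-cycle index ranges delimited by rising zero crossings."""
    sign = np.signbit(ref)
    rising = np.flatnonzero(sign[:-1] & ~sign[1:]) + 1
    return [(int(a), int(b)) for a, b in zip(rising[:-1], rising[1:])]


def mean_cycle_amplitude(x: np.ndarray, cycles: Optional[Sequence[tuple[int, int]]] = None) -> float:
    """Mean peak-to-peak excursion over movement cycles.

    ``cycles`` are (start, stop) index pairs, normally segmented on the
    pitch signal's rising zero crossings; without cycles (or with fewer
    than two crossings) the whole-signal peak-to-peak value is returned.
    """
    x = np.asarray(x, dtype=float)
    if cycles is None:
        cycles = _cycle_bounds_from_zero_crossings(x - x.mean())
    if not cycles:
        return float(np.ptp(x))
    return float(np.mean([np.ptp(x[a:b]) for a, b in cycles if b > a]))


def time_features(x: np.ndarray, cycles: Optional[Sequence[tuple[int, int]]] = None) -> dict[str, float]:
    """Time-domain family: histogram entropy, min, max, rms, range,
    mean cycle amplitude, standard deviation."""
    x = np.asarray(x, dtype=float)
    if len(x) == 0:
        raise ValueError("empty signal")
    rng = float(np.ptp(x))
    if rng == 0.0:
        ent = 0.0
    else:
        counts, _ = np.histogram(x, bins=ENTROPY_BINS)
        p = counts[counts > 0] / counts.sum()
        ent = float(-np.sum(p * np.log(p)))
    return {
        "entropy": ent,
        "minimum": float(x.min()),
        "maximum": float(x.max()),
        "rms": float(np.sqrt(np.mean(x**2))),
        "range": rng,
        "mean_amplitude": mean_cycle_amplitude(x, cycles),
        "standard_deviation": float(x.std()),
    }


def mean_peak_value(h: HarmonicSet) -> float:
    """Mean amplitude across detected harmonics — a combined descriptor of
    harmonic count and strength."""
    if not h.peaks:
        warnings.warn("empty harmonic set; mean_peak_value = 0")
        return 0.0
    return float(np.mean([p[1] for p in h.peaks]))


def extract_features(rec: CalibratedRecording,
                     rel_threshold: float = DEFAULT_REL_THRESHOLD,
                     min_separation: float = DEFAULT_MIN_SEPARATION_HZ,
                     band_halfwidth: float = DEFAULT_BAND_HALFWIDTH_HZ) -> FeatureVector:
    """Compute the full 36-feature vector of a preprocessed recording.

    Movement cycles for the amplitude features are segmented once on the
    pitch signal and shared by all three channels.
    """
    channels = {}
    for name in SIGNALS:
        sig = getattr(rec, name, None)
        if sig is None:
            raise ChannelError(f"recording {rec.recording_id} lacks channel {name}")
        channels[name] = np.asarray(sig, dtype=float)

    cycles = _cycle_bounds_from_zero_crossings(channels["theta_x"] - channels["theta_x"].mean())
    values: dict[str, float] = {}
    for name, sig in channels.items():
        spec = compute_spectrum(sig, rec.fs)
        harm = detect_harmonics(spec, rel_threshold, min_separation)
        values[f"dominant_frequency_{name}"] = dominant_frequency(spec)
        values[f"spectral_entropy_{name}"] = spectral_entropy(spec)
        values[f"regularity_{name}"] = regularity(sig)
        values[f"dominant_ratio_{name}"] = dominant_ratio(spec, band_halfwidth)
        values[f"mean_peak_value_{name}"] = mean_peak_value(harm)
        for fam, v in time_features(sig, cycles).items():
            values[f"{fam}_{name}"] = v
    fv = FeatureVector(recording_id=rec.recording_id, values=values)
    bad = [k for k, v in fv.values.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"{rec.recording_id}: non-finite features {bad}")
    return fv
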