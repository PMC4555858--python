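"""Temporal and spectral feature extraction for pulsed broadband threat calls.

The calls analysed here are trains of 3-20 broadband noise bursts ("pulses")
repeated at a few Hz.  Their transient structure rules out pitch or formant
analysis, so the measurement set is:

temporal (from the smoothed, normalised amplitude envelope of the rhythmic
portion of the call):
  * ``duration``    onset of the first pulse to offset of the last pulse (s)
  * ``n_pulses``    number of envelope threshold up-crossings
  * ``pulse_rate``  ``n_pulses / duration`` (Hz) -- note this convention, not
                    ``(n - 1) / span``; it changes values and is stated here
                    deliberately.

spectral (from the Welch mean power spectrum of the same rhythmic portion):
  * ``f_max``       frequency of maximal energy (Hz)
  * ``centroid``    energy-weighted mean frequency (Hz)
  * ``q25/q50/q75`` frequencies below which 25/50/75 % of total energy lies
  * ``bw12``        width of the contiguous band around ``f_max`` within 12 dB
                    of the spectral peak (Hz)

plus, when an absolute calibration (pascals per digital full scale) is
available, ``db_peak``: peak sound pressure level in dB re 20 uPa at 1 m.
Peak rather than RMS level is the appropriate amplitude measure for impulsive
signals.

All spectral quantities are reported at FFT-bin resolution, no interpolation.
Calls are expected pre-trimmed of any introductory/terminal non-rhythmic
material; the envelope threshold crossings then delimit the rhythmic portion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import fft as spfft
from scipy import signal as sps

from .errors import CalibrationRequiredError, DegenerateSignalError

logger = logging.getLogger(__name__)

P_REF = 20e-6  # reference pressure, Pa

#: default smoothing window expressed in ms: 41 samples at the 48 kHz
#: recorder rate.  Expressing it in ms keeps behaviour consistent across
#: sample rates.
DEFAULT_SMOOTH_MS = 41.0 / 48000.0 * 1000.0


@dataclass
class AnalysisConfig:
    """Tunable measurement parameters.

    band_high    upper edge of the analysis band for the envelope (Hz)
    smooth_ms    moving-average envelope smoothing window (ms)
    threshold    pulse-detection threshold, fraction of envelope max
    min_gap      minimum inter-onset gap (s); closer crossings are merged
    nperseg      Welch segment length (samples), Hann window
    """

    band_high: float = 6000.0
    smooth_ms: float = DEFAULT_SMOOTH_MS
    threshold: float = 0.15
    min_gap: float = 0.05
    nperseg: int = 4096


DEFAULT_CONFIG = AnalysisConfig()


@dataclass
class CallWaveform:
    """A single-channel call waveform with optional absolute calibration.

    ``samples`` are in [-1, 1] digital full scale; ``calibration`` gives
    pascals per full-scale unit when the recording chain was calibrated.
    ``context`` distinguishes calls directed at a rival from non-directed ones.
    """

    samples: np.ndarray
    sample_rate: float
    calibration: float | None = None
    male_id: str | None = None
    year: int | None = None
    context: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise DegenerateSignalError("empty waveform")
        if self.sample_rate <= 0:
            raise DegenerateSignalError("sample_rate must be positive")
        if self.calibration is not None and self.calibration <= 0:
            raise DegenerateSignalError("calibration must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass
class Envelope:
    """Smoothed, peak-normalised magnitude envelope of a call."""

    values: np.ndarray
    sample_rate: float
    degenerate: bool = False

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.sample_rate


@dataclass
class CallFeatures:
    """The nine temporal/spectral measures plus optional peak level for one call."""

    duration: float
    n_pulses: int
    pulse_rate: float
    f_max: float
    centroid: float
    q25: float
    q50: float
    q75: float
    bw12: float
    db_peak: float | None = None
    male_id: str | None = None
    year: int | None = None
    context: str | None = None

    def as_dict(self) -> dict:
        return {
            "male_id": self.male_id,
            "year": self.year,
            "context": self.context,
            "duration_s": self.duration,
            "n_pulses": self.n_pulses,
            "pulse_rate_hz": self.pulse_rate,
            "f_max_hz": self.f_max,
            "centroid_hz": self.centroid,
            "q25_hz": self.q25,
            "q50_hz": self.q50,
            "q75_hz": self.q75,
            "bw12_hz": self.bw12,
            "db_peak": self.db_peak,
        }


FEATURE_COLUMNS = [
    "duration_s",
    "n_pulses",
    "pulse_rate_hz",
    "f_max_hz",
    "centroid_hz",
    "q25_hz",
    "q50_hz",
    "q75_hz",
    "bw12_hz",
]


def envelope(wave: CallWaveform, config: AnalysisConfig = DEFAULT_CONFIG) -> Envelope:
    """Band-limited magnitude envelope: low-pass, Hilbert magnitude, smoothing.

    The signal is low-passed at ``config.band_high`` (skipped when the band
    edge is at or above Nyquist), the analytic magnitude taken, then smoothed
    with a centred moving average of ``config.smooth_ms`` and peak-normalised.
    A silent input yields an all-zero envelope flagged ``degenerate``.
    """
    x = wave.samples
    n_smooth = max(3, int(round(config.smooth_ms * 1e-3 * wave.sample_rate)))
    n_smooth += 1 - n_smooth % 2  # odd, so the average is centred
    if x.size <= max(n_smooth, 30):
        raise DegenerateSignalError(
            f"waveform too short for envelope analysis ({x.size} samples)"
        )
    nyq = wave.sample_rate / 2.0
    if 0 < config.band_high < nyq:
        sos = sps.butter(4, config.band_high / nyq, btype="low", output="sos")
        x = sps.sosfiltfilt(sos, x)
    # pad to a fast FFT length; the analytic signal of the padded block agrees
    # with the unpadded one away from the (zero) tail
    n_fast = spfft.next_fast_len(x.size)
    mag = np.abs(sps.hilbert(x, N=n_fast))[: x.size]
    kernel = np.ones(n_smooth) / n_smooth
    smooth = np.convolve(mag, kernel, mode="same")
    peak = smooth.max()
    if peak <= 0:
        return Envelope(values=np.zeros_like(smooth), sample_rate=wave.sample_rate,
                        degenerate=True)
    return Envelope(values=smooth / peak, sample_rate=wave.sample_rate)


def detect_pulses(
    env: Envelope,
    threshold: float = DEFAULT_CONFIG.threshold,
    min_gap: float = DEFAULT_CONFIG.min_gap,
) -> np.ndarray:
    """Onset times (s) of envelope threshold up-crossings separated by >= min_gap.

    The envelope is segmented into above-threshold runs; runs separated by a
    silent gap shorter than ``min_gap`` are ripple within the same pulse and
    are merged, so accepted onsets are always >= ``min_gap`` apart.  A
    degenerate (silent) envelope yields an empty result.
    """
    if env.degenerate:
        return np.array([])
    v = env.values
    above = v >= threshold
    starts = np.flatnonzero(~above[:-1] & above[1:]) + 1
    ends = np.flatnonzero(above[:-1] & ~above[1:]) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [v.size]])
    if starts.size == 0:
        return np.array([])
    min_samples = min_gap * env.sample_rate
    onsets = [starts[0]]
    last_end = ends[0]
    for s, e in zip(starts[1:], ends[1:]):
        if s - last_end >= min_samples:
            onsets.append(s)
        last_end = e
    return np.asarray(onsets) / env.sample_rate


def _offset_time(env: Envelope, threshold: float) -> float:
    """Time (s) of the last sample at or above threshold: the call offset."""
    idx = np.flatnonzero(env.values >= threshold)
    if idx.size == 0:
        raise DegenerateSignalError("envelope never reaches threshold")
    return idx[-1] / env.sample_rate


def temporal_features(
    onsets: np.ndarray,
    env: Envelope,
    threshold: float = DEFAULT_CONFIG.threshold,
) -> tuple[float, int, float]:
    """(duration, n_pulses, pulse_rate) from detected onsets and the envelope.

    Duration runs from the first onset to the offset of the last pulse (last
    threshold down-crossing), and pulse rate is ``n_pulses / duration``.
    """
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size == 0:
        raise DegenerateSignalError("no pulses detected; temporal features undefined")
    duration = _offset_time(env, threshold) - onsets[0]
    if duration <= 0:
        raise DegenerateSignalError("non-positive call duration")
    n = int(onsets.size)
    return duration, n, n / duration


def mean_power_spectrum(
    wave: CallWaveform, config: AnalysisConfig = DEFAULT_CONFIG
) -> tuple[np.ndarray, np.ndarray]:
    """Welch mean power spectrum (Hann window) of the waveform."""
    nperseg = min(config.nperseg, wave.samples.size)
    freqs, power = sps.welch(
        wave.samples,
        fs=wave.sample_rate,
        window="hann",
        nperseg=nperseg,
        detrend=False,
    )
    return freqs, power


def spectral_features(
    wave: CallWaveform, config: AnalysisConfig = DEFAULT_CONFIG
) -> tuple[float, float, float, float, float, float]:
    """(f_max, centroid, q25, q50, q75, bw12) of the supplied (pre-trimmed) waveform.

    Energy quartiles are the first FFT bins at which the cumulative power
    reaches 25/50/75 % of the total; the centroid is the power-weighted mean
    frequency; ``bw12`` is the contiguous band around the peak bin within
    12 dB of the maximum.
    """
    if not np.any(wave.samples):
        raise DegenerateSignalError("all-zero signal; spectral features undefined")
    freqs, power = mean_power_spectrum(wave, config)
    total = power.sum()
    if total <= 0:
        raise DegenerateSignalError("zero spectral energy")
    i_max = int(np.argmax(power))
    f_max = float(freqs[i_max])
    centroid = float((freqs * power).sum() / total)
    cum = np.cumsum(power) / total
    q25, q50, q75 = (float(freqs[np.searchsorted(cum, q)]) for q in (0.25, 0.50, 0.75))
    # contiguous -12 dB band around the peak
    floor = power[i_max] * 10.0 ** (-12.0 / 10.0)
    lo = i_max
    while lo > 0 and power[lo - 1] >= floor:
        lo -= 1
    hi = i_max
    while hi < power.size - 1 and power[hi + 1] >= floor:
        hi += 1
    bw12 = float(freqs[hi] - freqs[lo])
    return f_max, centroid, q25, q50, q75, bw12


def peak_level(wave: CallWaveform) -> float:
    """Peak sound pressure level, dB re 20 uPa at 1 m (requires calibration)."""
    if wave.calibration is None:
        raise CalibrationRequiredError(
            "peak_level requires a calibration (pascals per full-scale unit)"
        )
    peak_pa = np.abs(wave.samples).max() * wave.calibration
    if peak_pa <= 0:
        raise DegenerateSignalError("silent waveform has no peak level")
    return float(20.0 * np.log10(peak_pa / P_REF))


def rhythmic_portion(
    wave: CallWaveform, config: AnalysisConfig = DEFAULT_CONFIG
) -> tuple[CallWaveform, np.ndarray, Envelope]:
    """Trim the call to onset-of-first .. offset-of-last pulse.

    Returns the trimmed waveform, the pulse onset times (s, relative to the
    original waveform) and the envelope they were measured on.
    """
    env = envelope(wave, config)
    if env.degenerate:
        raise DegenerateSignalError("silent waveform")
    onsets = detect_pulses(env, config.threshold, config.min_gap)
    if onsets.size == 0:
        raise DegenerateSignalError("no pulses detected")
    offset = _offset_time(env, config.threshold)
    i0 = int(onsets[0] * wave.sample_rate)
    i1 = int(np.ceil(offset * wave.sample_rate)) + 1
    trimmed = replace(wave, samples=wave.samples[i0:i1])
    return trimmed, onsets, env


def extract_features(
    wave: CallWaveform, config: AnalysisConfig = DEFAULT_CONFIG
) -> CallFeatures:
    """Full measurement of one call: envelope -> pulses -> temporal + spectral.

    Spectral measures are computed over the rhythmic portion only (first
    onset to last offset).  ``db_peak`` is included when the waveform carries
    a calibration, otherwise left ``None``.
    """
    trimmed, onsets, env = rhythmic_portion(wave, config)
    duration, n_pulses, pulse_rate = temporal_features(onsets, env, config.threshold)
    f_max, centroid, q25, q50, q75, bw12 = spectral_features(trimmed, config)
    db = peak_level(wave) if wave.calibration is not None else None
    return CallFeatures(
        duration=duration,
        n_pulses=n_pulses,
        pulse_rate=pulse_rate,
        f_max=f_max,
        centroid=centroid,
        q25=q25,
        q50=q50,
        q75=q75,
        bw12=bw12,
        db_peak=db,
        male_id=wave.male_id,
        year=wave.year,
        context=wave.context,
    )


def fft_bin_width(wave: CallWaveform, config: AnalysisConfig = DEFAULT_CONFIG) -> float:
    """Frequency resolution (Hz) of the spectral measures for this waveform."""
    nperseg = min(config.nperseg, wave.samples.size)
    return wave.sample_rate / nperseg
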