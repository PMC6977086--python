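"""Beta-band preprocessing: peak detection, band-pass + Hilbert envelope, artefact rejection.

The analysis operates on single-channel "virtual sensor" time series (one
motor ROI per hemisphere).  Raw oscillatory recordings are band-pass
filtered around the subject's individual beta peak (peak ± 6 Hz by
default), the analytic amplitude is taken, and the envelope is
anti-alias-resampled to 100 Hz before any event modelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import gcd

import numpy as np
from scipy import signal

__all__ = [
    "ContinuousRecording",
    "BandSpec",
    "detect_beta_peak",
    "compute_envelope",
    "reject_variance_outliers",
    "CANONICAL_BETA_BAND",
]

#: Canonical beta band (Hz) used as the default peak search range.
CANONICAL_BETA_BAND = (15.0, 28.0)

#: Frequency returned when no spectral peak can be found (band centre).
FALLBACK_PEAK_HZ = 21.5


@dataclass
class ContinuousRecording:
    """A continuous single-channel signal.

    ``kind`` distinguishes raw oscillatory data from a non-negative
    amplitude envelope; several operations accept only one of the two.
    """

    values: np.ndarray
    fs: float
    kind: str = "raw"  # {"raw", "envelope"}
    subject_id: str = ""
    group: str = ""
    channel_label: str = "roi"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.kind not in ("raw", "envelope"):
            raise ValueError(f"unknown recording kind {self.kind!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("recording contains non-finite values")
        if self.kind == "envelope" and np.any(self.values < 0):
            raise ValueError("an amplitude envelope must be non-negative")

    @property
    def duration(self) -> float:
        return self.values.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.fs


@dataclass
class BandSpec:
    """A frequency band centred on a subject-specific beta peak."""

    peak_freq: float
    half_width: float = 6.0
    fallback: bool = False

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")
        if self.peak_freq - self.half_width <= 0:
            raise ValueError("band lower edge must be positive")

    @property
    def band(self) -> tuple[float, float]:
        return (self.peak_freq - self.half_width, self.peak_freq + self.half_width)


def detect_beta_peak(
    recording: ContinuousRecording,
    search_band: tuple[float, float] = CANONICAL_BETA_BAND,
    half_width: float = 6.0,
) -> BandSpec:
    """Locate the subject-specific beta peak in a raw recording.

    A Welch spectrum is corrected for the aperiodic 1/f background by a
    log-log linear fit over 4-45 Hz (excluding 13-30 Hz, so the beta bump
    does not bias the fit) and the largest local maximum of the corrected
    spectrum inside ``search_band`` is returned.  If no local maximum
    exists the band centre is used and ``fallback`` is flagged.
    """
    if recording.kind != "raw":
        raise ValueError("peak detection requires a raw recording, not an envelope")
    if recording.duration < 10.0:
        raise ValueError("recording too short for peak detection (need >= 10 s)")

    fs = recording.fs
    nperseg = min(int(4 * fs), recording.values.size)
    freqs, pxx = signal.welch(recording.values, fs=fs, nperseg=nperseg)

    # 1/f correction: straight line in log-log space, beta range excluded.
    fit_mask = (freqs >= 4) & (freqs <= 45) & ~((freqs >= 13) & (freqs <= 30))
    fit_mask &= pxx > 0
    logf = np.log10(freqs[fit_mask])
    logp = np.log10(pxx[fit_mask])
    slope, intercept = np.polyfit(logf, logp, 1)

    search = (freqs >= search_band[0]) & (freqs <= search_band[1]) & (freqs > 0)
    idx = np.flatnonzero(search)
    with np.errstate(divide="ignore"):
        corrected = np.log10(np.maximum(pxx[idx], 1e-300)) - (
            slope * np.log10(freqs[idx]) + intercept
        )

    # local maxima strictly above both neighbours (within the search range)
    peaks, _ = signal.find_peaks(corrected)
    if peaks.size == 0:
        return BandSpec(FALLBACK_PEAK_HZ, half_width=half_width, fallback=True)
    best = peaks[np.argmax(corrected[peaks])]
    return BandSpec(float(freqs[idx][best]), half_width=half_width)


def _bandpass_fir(band: tuple[float, float], fs: float, half_width: float) -> np.ndarray:
    """Zero-phase-ready FIR band-pass; transition width = 0.25 x band half-width."""
    trans = 0.25 * half_width
    numtaps = int(np.ceil(3.3 * fs / trans))
    numtaps += 1 - numtaps % 2  # odd length, type-I linear phase
    return signal.firwin(numtaps, band, pass_zero=False, fs=fs)


def compute_envelope(
    recording: ContinuousRecording,
    band: BandSpec,
    target_fs: float = 100.0,
) -> ContinuousRecording:
    """Band-pass filter, Hilbert amplitude, and polyphase resample to ``target_fs``.

    The filter is applied forward-backward (zero phase) so event timing is
    not shifted; the envelope is the magnitude of the analytic signal and
    is resampled with an anti-aliasing polyphase filter.
    """
    if recording.kind != "raw":
        raise ValueError("compute_envelope expects a raw recording")
    lo, hi = band.band
    nyq = recording.fs / 2
    if hi >= nyq:
        raise ValueError(f"band upper edge {hi} Hz >= Nyquist {nyq} Hz")

    taps = _bandpass_fir((lo, hi), recording.fs, band.half_width)
    padlen = min(3 * taps.size, recording.values.size - 1)
    filtered = signal.filtfilt(taps, 1.0, recording.values, padlen=padlen)
    env = np.abs(signal.hilbert(filtered))

    if target_fs != recording.fs:
        frac_num = int(round(target_fs * 1000))
        frac_den = int(round(recording.fs * 1000))
        g = gcd(frac_num, frac_den)
        up, down = frac_num // g, frac_den // g
        env = signal.resample_poly(env, up, down)
    # polyphase ringing may slightly undershoot zero
    np.maximum(env, 0.0, out=env)
    return ContinuousRecording(
        env,
        fs=target_fs,
        kind="envelope",
        subject_id=recording.subject_id,
        group=recording.group,
        channel_label=recording.channel_label,
    )


def reject_variance_outliers(
    epochs: np.ndarray,
    weight_threshold: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Robust-regression rejection of high-variance epochs.

    Fits a robust location (IRLS, Tukey bisquare) to the per-epoch
    variance; epochs whose final IRLS weight falls below
    ``weight_threshold`` are removed.  Returns ``(kept_ids, weights)``.
    """
    import statsmodels.api as sm

    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim != 2:
        raise ValueError("epochs must be a 2-D (trial x time) array")
    n = epochs.shape[0]
    if n < 5:
        raise ValueError("need at least 5 epochs for robust outlier rejection")

    variances = epochs.var(axis=1)
    spread = np.median(np.abs(variances - np.median(variances)))
    if spread == 0:
        # robust scale degenerate: identical variances, nothing to reject
        weights = np.ones(n)
    else:
        model = sm.RLM(variances, np.ones((n, 1)), M=sm.robust.norms.TukeyBiweight())
        weights = model.fit().weights
    kept = np.flatnonzero(weights >= weight_threshold)
    return kept, np.asarray(weights)
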