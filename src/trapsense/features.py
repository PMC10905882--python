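"""Data cleaning and spectrogram feature extraction.

Cleaning replaces the manual inspection step of a laboratory dataset build:
recordings showing a double flight (two transit envelopes) or a wall hit
(truncated, clipped envelope) are rejected before training.  Features are a
short-time Fourier magnitude spectrogram cropped to the wingbeat band,
summarized into a fixed-length vector (per-frequency-bin mean magnitude over
frames, so transits of different durations map to the same dimension), plus
a harmonic-product-spectrum estimate of the fundamental wingbeat frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.signal.windows import hann

from .types import Recording

__all__ = [
    "CleaningConfig",
    "CleaningVerdict",
    "CleanReason",
    "clean_recording",
    "SpectrogramConfig",
    "SpectrogramFeatures",
    "compute_spectrogram",
    "estimate_f0",
    "extract_feature_table",
    "feature_matrix",
]


# ---------------------------------------------------------------------------
# Cleaning

import enum


class CleanReason(str, enum.Enum):
    OK = "OK"
    DOUBLE_FLIGHT = "DOUBLE_FLIGHT"
    WALL_HIT = "WALL_HIT"
    TOO_SHORT = "TOO_SHORT"
    SILENT = "SILENT"


@dataclass(frozen=True)
class CleaningVerdict:
    valid: bool
    reason: CleanReason

    def __post_init__(self) -> None:
        assert self.valid == (self.reason is CleanReason.OK)


@dataclass(frozen=True)
class CleaningConfig:
    """Thresholds for the automated cleaning heuristics.

    min_duration:      shortest usable transit (s).
    silent_peak:       peak |amplitude| below which a recording is SILENT.
    clip_level:        |amplitude| at or above which a sample counts as clipped.
    clip_fraction:     clipped-sample fraction that flags a WALL_HIT.
    edge_fraction:     envelope level at either edge, relative to the envelope
                       maximum, that flags a truncated transit (WALL_HIT).
    peak_rel_height:   minimum envelope-peak height (relative to max) for a
                       secondary transit peak.
    peak_rel_prominence: minimum relative prominence of that secondary peak
                       (the dip between transits) to call a DOUBLE_FLIGHT.
    smooth_ms:         RMS-envelope smoothing window (ms).
    """

    min_duration: float = 0.03
    silent_peak: float = 0.05
    clip_level: float = 0.999
    clip_fraction: float = 0.02
    edge_fraction: float = 0.5
    peak_rel_height: float = 0.35
    peak_rel_prominence: float = 0.25
    smooth_ms: float = 8.0


def _rms_envelope(x: np.ndarray, sample_rate: float, smooth_ms: float) -> np.ndarray:
    win = max(int(sample_rate * smooth_ms / 1000.0), 3)
    kernel = np.ones(win) / win
    return np.sqrt(np.convolve(x * x, kernel, mode="same"))


def clean_recording(
    rec: Recording, config: Optional[CleaningConfig] = None
) -> CleaningVerdict:
    """Automated stand-in for manual data cleaning of lab recordings.

    Flags DOUBLE_FLIGHT when the smoothed amplitude envelope shows two or
    more separated transit peaks, WALL_HIT when a substantial fraction of
    samples is clipped or the envelope is truncated at an edge, and
    TOO_SHORT/SILENT for degenerate inputs.
    """
    cfg = config or CleaningConfig()
    x = np.asarray(rec.samples, float)
    if x.size == 0:
        raise ValueError("empty waveform")
    if rec.duration < cfg.min_duration:
        return CleaningVerdict(False, CleanReason.TOO_SHORT)
    peak = np.abs(x).max()
    if peak < cfg.silent_peak:
        return CleaningVerdict(False, CleanReason.SILENT)

    clipped = np.mean(np.abs(x) >= cfg.clip_level)
    env = _rms_envelope(x, rec.sample_rate, cfg.smooth_ms)
    env_max = env.max()
    edge = max(env[0], env[-1]) / env_max if env_max > 0 else 0.0
    if clipped >= cfg.clip_fraction or edge >= cfg.edge_fraction:
        return CleaningVerdict(False, CleanReason.WALL_HIT)

    min_sep = int(0.02 * rec.sample_rate)  # transit peaks >= 20 ms apart
    peaks, _ = find_peaks(
        env,
        height=cfg.peak_rel_height * env_max,
        prominence=cfg.peak_rel_prominence * env_max,
        distance=min_sep,
    )
    if len(peaks) >= 2:
        return CleaningVerdict(False, CleanReason.DOUBLE_FLIGHT)
    return CleaningVerdict(True, CleanReason.OK)


# ---------------------------------------------------------------------------
# Spectrogram features

@dataclass(frozen=True)
class SpectrogramConfig:
    window_length: int = 256
    overlap: float = 0.5
    max_freq: float = 2000.0
    f0_min: float = 80.0
    f0_max: float = 1200.0
    f0_harmonics: int = 3
    f0_nfft: int = 8192  # zero-padded FFT length for the fundamental estimate


@dataclass
class SpectrogramFeatures:
    """Time-frequency magnitudes and derived fixed-length features.

    ``matrix`` has shape (frequency bins <= max_freq, frames);
    ``flat_vector`` is the per-bin mean magnitude over frames, identical in
    length for every recording processed under one config; ``f0_estimate``
    is NaN when undefined (silent input).
    """

    matrix: np.ndarray
    freq_resolution: float
    time_resolution: float
    flat_vector: np.ndarray
    f0_estimate: float

    @property
    def f0_defined(self) -> bool:
        return bool(np.isfinite(self.f0_estimate))


def _frame(x: np.ndarray, window_length: int, hop: int) -> np.ndarray:
    n_frames = 1 + (len(x) - window_length) // hop
    idx = np.arange(window_length)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


def estimate_f0(
    x: np.ndarray, sample_rate: float, config: Optional[SpectrogramConfig] = None
) -> float:
    """Harmonic-product-spectrum estimate of the fundamental (Hz).

    The magnitude spectra at 1×, 2×, ... f0_harmonics× a candidate frequency
    are multiplied; the product peaks at the true fundamental even when a
    harmonic outweighs it.  Zero padding refines the grid to ~1 Hz.
    Returns NaN for an (effectively) silent signal.
    """
    cfg = config or SpectrogramConfig()
    x = np.asarray(x, float)
    if x.size == 0 or np.max(np.abs(x)) <= 0:
        return float("nan")
    nfft = max(cfg.f0_nfft, len(x))
    spec = np.abs(np.fft.rfft(x * hann(len(x), sym=True), n=nfft))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / sample_rate)
    lo = np.searchsorted(freqs, cfg.f0_min)
    hi = np.searchsorted(freqs, cfg.f0_max)
    if hi <= lo:
        return float("nan")
    hps = np.log(spec[lo:hi] + 1e-12).copy()
    for h in range(2, cfg.f0_harmonics + 1):
        idx = np.minimum(np.arange(lo, hi) * h, len(spec) - 1)
        hps += np.log(spec[idx] + 1e-12)
    return float(freqs[lo + int(np.argmax(hps))])


def compute_spectrogram(
    rec: Recording, config: Optional[SpectrogramConfig] = None
) -> SpectrogramFeatures:
    """Short-time Fourier magnitude features of one recording.

    Hann-windowed frames of ``window_length`` samples with fractional
    ``overlap``; magnitudes are cropped to [0, max_freq].  The flat feature
    vector is the per-bin time-average of the cropped magnitudes.
    """
    cfg = config or SpectrogramConfig()
    x = np.asarray(rec.samples, float)
    if not (0.0 <= cfg.overlap < 1.0):
        raise ValueError("overlap must be in [0, 1)")
    if cfg.window_length > len(x):
        raise ValueError("window longer than signal")
    hop = max(int(round(cfg.window_length * (1.0 - cfg.overlap))), 1)
    frames = _frame(x, cfg.window_length, hop)
    win = hann(cfg.window_length, sym=False)
    mags = np.abs(np.fft.rfft(frames * win, axis=1)).T  # (bins, frames)
    freqs = np.fft.rfftfreq(cfg.window_length, d=1.0 / rec.sample_rate)
    keep = freqs <= cfg.max_freq
    matrix = mags[keep]
    flat = matrix.mean(axis=1)
    return SpectrogramFeatures(
        matrix=matrix,
        freq_resolution=float(freqs[1] - freqs[0]),
        time_resolution=hop / rec.sample_rate,
        flat_vector=flat,
        f0_estimate=estimate_f0(x, rec.sample_rate, cfg),
    )


# ---------------------------------------------------------------------------
# Batch feature tables

def extract_feature_table(
    recordings: Sequence[Recording],
    config: Optional[SpectrogramConfig] = None,
) -> pd.DataFrame:
    """One row per recording: metadata, f0 estimate, then flat-vector columns.

    The resulting frame is the CSV-persistable feature store consumed by the
    classifier and the Gaussian target gate.
    """
    cfg = config or SpectrogramConfig()
    rows = []
    for i, rec in enumerate(recordings):
        feats = compute_spectrogram(rec, cfg)
        row: dict = {
            "id": i,
            "label": rec.true_label.value if rec.true_label else "",
            "timestamp": rec.timestamp,
            "temperature": rec.temperature,
            "f0_estimate": feats.f0_estimate,
        }
        for j, v in enumerate(feats.flat_vector):
            row[f"b{j:03d}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def feature_matrix(table: pd.DataFrame) -> np.ndarray:
    """Numeric feature matrix: flat-vector bins followed by the f0 estimate."""
    bins = [c for c in table.columns if c.startswith("b") and c[1:].isdigit()]
    X = table[bins].to_numpy(float)
    f0 = table["f0_estimate"].to_numpy(float)[:, None]
    return np.hstack([X, f0])
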