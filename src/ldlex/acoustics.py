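"""Frequency-band-summary (FBS) acoustic features.

A waveform is segmented into chunks at interior minima of its smoothed
Hilbert envelope. Within each chunk, consecutive non-overlapping 5-ms
windows yield power spectra that are pooled into 21 triangular MEL-scale
bands; the log band intensities of the whole token are discretized into
five levels (per-token quantile bins by default), and each band's level
sequence within each chunk is summarized by its start, median, minimum,
maximum and end levels, rendered as a feature string such as
``band1-start1-median2-min1-max4-end2-part1``. The set of such strings is
the token's acoustic cue set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile
from scipy.signal import find_peaks, hilbert

from ._utils import LdlexError

N_BANDS = 21
WINDOW_MS = 5.0
N_LEVELS = 5
SMOOTHING_MS = 20.0
#: minimum envelope-dip prominence (fraction of envelope peak) for a chunk split
MIN_PROMINENCE = 0.05


@dataclass
class AudioToken:
    samples: np.ndarray
    sample_rate: int

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.sample_rate <= 0:
            raise LdlexError("AudioToken: sample_rate must be positive")
        if self.samples.size < self.window_samples:
            raise LdlexError("AudioToken: signal shorter than one analysis window")

    @property
    def window_samples(self) -> int:
        return max(1, int(round(self.sample_rate * WINDOW_MS / 1000.0)))

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


def read_wav(path) -> AudioToken:
    """Read a PCM WAV file (stereo averaged to mono, scaled to [-1, 1])."""
    sr, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return AudioToken(data.astype(float), int(sr))


def write_wav(path, audio: AudioToken) -> None:
    peak = np.abs(audio.samples).max()
    scaled = audio.samples / peak if peak > 0 else audio.samples
    wavfile.write(path, audio.sample_rate,
                  (scaled * 32767).astype(np.int16))


def envelope(audio: AudioToken, smoothing_ms: float = SMOOTHING_MS) -> np.ndarray:
    """Moving-average-smoothed magnitude of the analytic signal."""
    env = np.abs(hilbert(audio.samples))
    w = max(1, int(round(audio.sample_rate * smoothing_ms / 1000.0)))
    kernel = np.ones(w) / w
    return np.convolve(env, kernel, mode="same")


def chunk_signal(audio: AudioToken, smoothing_ms: float = SMOOTHING_MS,
                 min_prominence: float = MIN_PROMINENCE) -> list[tuple[int, int]]:
    """Split the signal at interior minima of the smoothed envelope.

    Returns contiguous half-open sample intervals tiling [0, n) exactly.
    Minima must have a dip prominence of at least ``min_prominence`` times
    the envelope peak, so constant-amplitude signals stay in one chunk;
    plateau minima take their leftmost index.
    """
    env = envelope(audio, smoothing_ms)
    n = env.size
    prominence = min_prominence * float(env.max()) if env.max() > 0 else None
    idx, props = find_peaks(-env, prominence=prominence, plateau_size=1)
    splits = sorted(int(i) for i in props.get("left_edges", idx) if 0 < i < n - 1)
    bounds = [0] + splits + [n]
    return [(a, b) for a, b in zip(bounds, bounds[1:]) if b > a]


def mel_filterbank(n_bands: int, n_fft: int, sample_rate: int) -> np.ndarray:
    """Triangular MEL-spaced filters spanning 0 Hz to Nyquist."""
    def to_mel(f):
        return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)

    def from_mel(m):
        return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)

    nyquist = sample_rate / 2.0
    mel_pts = np.linspace(0.0, to_mel(nyquist), n_bands + 2)
    hz_pts = from_mel(mel_pts)
    fft_freqs = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate)
    fb = np.zeros((n_bands, fft_freqs.size))
    for b in range(n_bands):
        lo, ctr, hi = hz_pts[b], hz_pts[b + 1], hz_pts[b + 2]
        up = (fft_freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - fft_freqs) / max(hi - ctr, 1e-12)
        fb[b] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def band_intensity_series(audio: AudioToken, interval: tuple[int, int],
                          n_bands: int = N_BANDS,
                          window_ms: float = WINDOW_MS) -> np.ndarray:
    """Log MEL-band intensities per consecutive window of one chunk.

    Windows are non-overlapping; a trailing partial window is dropped.
    Returns an (n_bands, n_windows) matrix.
    """
    start, end = interval
    if not (0 <= start < end <= audio.samples.size):
        raise LdlexError(f"band_intensity_series: bad interval {interval}")
    win = max(1, int(round(audio.sample_rate * window_ms / 1000.0)))
    segment = audio.samples[start:end]
    n_windows = segment.size // win
    if n_windows == 0:
        raise LdlexError("band_intensity_series: interval shorter than one window")
    frames = segment[: n_windows * win].reshape(n_windows, win)
    power = np.abs(np.fft.rfft(frames, axis=1)) ** 2
    fb = mel_filterbank(n_bands, win, audio.sample_rate)
    band_power = power @ fb.T  # (n_windows, n_bands)
    return np.log(band_power.T + 1e-12)


def discretize(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Map intensities to integer levels 1..(len(edges)+1) via bin edges."""
    return np.searchsorted(edges, values, side="left") + 1


def quantile_edges(pooled: np.ndarray, n_levels: int = N_LEVELS) -> np.ndarray:
    qs = np.arange(1, n_levels) / n_levels
    return np.quantile(np.asarray(pooled, dtype=float).ravel(), qs)


def range_edges(pooled: np.ndarray, n_levels: int = N_LEVELS) -> np.ndarray:
    pooled = np.asarray(pooled, dtype=float).ravel()
    return np.linspace(pooled.min(), pooled.max(), n_levels + 1)[1:-1]


@dataclass
class BandSummary:
    band: int
    part: int
    start: int
    end: int
    min: int
    max: int
    median: int

    def __post_init__(self):
        for lv in (self.start, self.end, self.min, self.max, self.median):
            if not 1 <= lv <= N_LEVELS:
                raise LdlexError(f"BandSummary: level {lv} outside 1..{N_LEVELS}")
        if not self.min <= self.median <= self.max:
            raise LdlexError("BandSummary: min <= median <= max violated")

    @property
    def string(self) -> str:
        return (f"band{self.band}-start{self.start}-median{self.median}"
                f"-min{self.min}-max{self.max}-end{self.end}-part{self.part}")


def summarize_band(levels, band: int, part: int) -> BandSummary:
    """Summarize a discretized level sequence of one band in one chunk.

    The median of an even-length series is the lower median, keeping the
    summary on the integer level grid.
    """
    levels = [int(l) for l in levels]
    if not levels:
        raise LdlexError("summarize_band: empty level series")
    ordered = sorted(levels)
    return BandSummary(
        band=band, part=part,
        start=levels[0], end=levels[-1],
        min=ordered[0], max=ordered[-1],
        median=ordered[(len(ordered) - 1) // 2],
    )


def extract_fbs(audio: AudioToken, smoothing_ms: float = SMOOTHING_MS,
                window_ms: float = WINDOW_MS, n_bands: int = N_BANDS,
                n_levels: int = N_LEVELS,
                binning: str = "quantile") -> set[str]:
    """Full FBS feature set of one audio token.

    Chunks shorter than one analysis window are merged into the preceding
    chunk (the first into the following one) so the partition is kept.
    Discretization edges are computed once from the token's pooled band
    intensities (``binning="quantile"`` or ``"range"``), which makes the
    level patterns invariant to uniform amplitude scaling in quantile mode.
    """
    win = max(1, int(round(audio.sample_rate * window_ms / 1000.0)))
    chunks = chunk_signal(audio, smoothing_ms)
    merged: list[tuple[int, int]] = []
    for iv in chunks:
        if merged and (iv[1] - iv[0] < win or merged[-1][1] - merged[-1][0] < win):
            merged[-1] = (merged[-1][0], iv[1])
        else:
            merged.append(iv)
    if len(merged) > 1 and merged[0][1] - merged[0][0] < win:
        merged[1:2] = [(merged[0][0], merged[1][1])]
        merged.pop(0)
    series = [band_intensity_series(audio, iv, n_bands, window_ms) for iv in merged]
    pooled = np.concatenate([m.ravel() for m in series])
    if binning == "quantile":
        edges = quantile_edges(pooled, n_levels)
    elif binning == "range":
        edges = range_edges(pooled, n_levels)
    else:
        raise LdlexError(f"extract_fbs: unknown binning {binning!r}")
    features: set[str] = set()
    for part, m in enumerate(series, start=1):
        lv = discretize(m, edges)
        for b in range(n_bands):
            features.add(summarize_band(lv[b], band=b + 1, part=part).string)
    return features
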