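"""Call segmentation, spectral features and call-type clustering.

The analysis chain mirrors the classic semi-automated sorting of
zebra-finch vocalizations: sounds crossing an amplitude threshold are
cut out of the recording, a small set of sorting parameters (average,
modal and fundamental frequency, Wiener entropy, duration, plus the
per-window standard deviations of the spectral measures) is computed
for each sound, and k-means groups the sounds into call types, with a
distance-quantile rule standing in for manual noise elimination.

A richer 14-feature spectral description of whole calls (moments of the
mean normalized spectrum, flatness, entropy, peak/dominant frequencies,
duration) supports the individual-distinctiveness analysis.

All spectra are short-time power spectra: Hann window of ``n_fft``
samples (default 512 at 44.1 kHz, i.e. ~86 Hz resolution), 50% overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks
from sklearn.cluster import KMeans

NOISE = -1
#: spectral floor of zebra finch vocalizations; content below is ignored
HIGHPASS_HZ = 85.0

__all__ = [
    "NOISE",
    "VocalSegment",
    "FFTParams",
    "SortingFeatures",
    "SpectralFeatures14",
    "ClusterAssignment",
    "segment_sounds",
    "wiener_entropy",
    "compute_sorting_features",
    "compute_features14",
    "cluster_calls",
    "apply_manual_edits",
]


@dataclass
class VocalSegment:
    """A waveform slice extracted from a recording."""

    samples: np.ndarray
    sample_rate: int
    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.offset_s <= self.onset_s:
            raise ValueError("offset_s must exceed onset_s")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass(frozen=True)
class FFTParams:
    """Short-time analysis settings (Hann window, 50% overlap)."""

    n_fft: int = 512
    hop: int = 256

    def frame(self, x: np.ndarray) -> np.ndarray:
        """Frame ``x`` into overlapping windows; at least one frame
        (zero-padded) is returned for inputs shorter than ``n_fft``."""
        n = len(x)
        if n < self.n_fft:
            x = np.pad(x, (0, self.n_fft - n))
            n = self.n_fft
        n_frames = 1 + (n - self.n_fft) // self.hop
        idx = np.arange(self.n_fft)[None, :] + self.hop * np.arange(n_frames)[:, None]
        return x[idx]

    def power_spectra(self, x: np.ndarray, sample_rate: int) -> tuple[np.ndarray, np.ndarray]:
        """Per-window one-sided power spectra and their frequency axis."""
        frames = self.frame(np.asarray(x, dtype=np.float64))
        win = np.hanning(self.n_fft)
        spec = np.fft.rfft(frames * win, axis=1)
        power = np.abs(spec) ** 2
        freqs = np.fft.rfftfreq(self.n_fft, d=1.0 / sample_rate)
        return power, freqs


def segment_sounds(
    audio: np.ndarray,
    sample_rate: int,
    threshold: float,
    min_gap_s: float = 0.010,
    min_dur_s: float = 0.005,
    smooth_s: float = 0.002,
) -> list[VocalSegment]:
    """Extract sounds whose smoothed amplitude envelope reaches ``threshold``.

    The envelope is a moving average of ``|audio|`` over ``smooth_s``.
    Above-threshold runs closer than ``min_gap_s`` are merged; runs
    shorter than ``min_dur_s`` are discarded.  Segments are
    non-overlapping and time-ordered.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    audio = np.asarray(audio, dtype=np.float64)
    if audio.size == 0:
        return []
    w = max(1, int(round(smooth_s * sample_rate)))
    env = np.convolve(np.abs(audio), np.ones(w) / w, mode="same")
    mask = env >= threshold
    if not mask.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(np.int8)))
    starts, stops = edges[0::2], edges[1::2]
    # merge runs separated by less than min_gap_s
    min_gap = int(round(min_gap_s * sample_rate))
    merged: list[list[int]] = [[int(starts[0]), int(stops[0])]]
    for s, e in zip(starts[1:], stops[1:]):
        if s - merged[-1][1] < min_gap:
            merged[-1][1] = int(e)
        else:
            merged.append([int(s), int(e)])
    min_len = int(round(min_dur_s * sample_rate))
    out = []
    for s, e in merged:
        if e - s < min_len:
            continue
        out.append(
            VocalSegment(
                samples=audio[s:e],
                sample_rate=sample_rate,
                onset_s=s / sample_rate,
                offset_s=e / sample_rate,
            )
        )
    return out


def wiener_entropy(power_spectrum: np.ndarray) -> float:
    """Wiener entropy of a power spectrum, on the linear [0, 1] scale.

    Ratio of geometric to arithmetic mean of the power bins: 1 for a
    flat (white) spectrum, 0 when any bin is silent (pure-tone limit).
    """
    p = np.asarray(power_spectrum, dtype=np.float64)
    if np.any(p < 0):
        raise ValueError("power spectrum must be non-negative")
    am = p.mean()
    if am == 0:
        raise ValueError("silent frame")
    if np.any(p == 0):
        return 0.0
    gm = np.exp(np.mean(np.log(p)))
    return float(gm / am)


def _first_peak_hz(
    power: np.ndarray,
    freqs: np.ndarray,
    min_hz: float = HIGHPASS_HZ,
    rel_prominence: float = 0.05,
) -> float:
    """Fundamental frequency as the lowest prominent spectral peak.

    Peaks are detected on the power spectrum with prominence at least
    ``rel_prominence`` of the spectrum maximum; the lowest-frequency
    peak above ``min_hz`` wins.  Falls back to the argmax bin when no
    peak qualifies (e.g. very short or noisy frames).
    """
    valid = freqs >= min_hz
    p = np.where(valid, power, 0.0)
    if p.max() == 0:
        raise ValueError("silent frame")
    peaks, _ = find_peaks(p, prominence=rel_prominence * p.max())
    if len(peaks) == 0:
        return float(freqs[int(np.argmax(p))])
    return float(freqs[int(peaks[0])])


@dataclass(frozen=True)
class SortingFeatures:
    """Per-call sorting parameters (means and across-window SDs)."""

    average_frequency: float
    modal_frequency: float
    fundamental_frequency: float
    wiener_entropy: float
    duration: float
    average_frequency_sd: float
    modal_frequency_sd: float
    fundamental_frequency_sd: float
    wiener_entropy_sd: float

    @classmethod
    def names(cls) -> list[str]:
        return [f.name for f in dc_fields(cls)]

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.names()], dtype=np.float64)


def compute_sorting_features(
    seg: VocalSegment,
    fft_params: FFTParams = FFTParams(),
    min_window_power: float = 0.1,
) -> SortingFeatures:
    """Compute the sorting parameters of one extracted sound.

    Per analysis window: spectral centroid (average frequency), argmax
    bin (modal frequency), first-prominent-peak fundamental and Wiener
    entropy; the call-level value is the mean across windows, variation
    the SD across windows.  Duration comes from the segment bounds.
    Content below 85 Hz is excluded throughout, and windows carrying
    less than ``min_window_power`` of the loudest window's power (the
    fade-in/out edges) are skipped — per-window statistics are
    meaningless where there is no signal.
    """
    if len(seg.samples) < 2:
        raise ValueError("segment too short for spectral analysis")
    power, freqs = fft_params.power_spectra(seg.samples, seg.sample_rate)
    band = freqs >= HIGHPASS_HZ
    power = power[:, band]
    freqs = freqs[band]
    tot = power.sum(axis=1)
    live = tot >= min_window_power * tot.max()
    if tot.max() == 0:
        raise ValueError("silent segment")
    power, tot = power[live], tot[live]
    centroid = (power * freqs).sum(axis=1) / tot
    modal = freqs[np.argmax(power, axis=1)]
    fund = np.array([_first_peak_hz(p, freqs) for p in power])
    went = np.array([wiener_entropy(p) for p in power])

    def ms(x: np.ndarray) -> tuple[float, float]:
        return float(np.mean(x)), float(np.std(x))

    (c_m, c_s), (m_m, m_s), (f_m, f_s), (w_m, w_s) = ms(centroid), ms(modal), ms(fund), ms(went)
    return SortingFeatures(
        average_frequency=c_m,
        modal_frequency=m_m,
        fundamental_frequency=f_m,
        wiener_entropy=w_m,
        duration=seg.duration_s,
        average_frequency_sd=c_s,
        modal_frequency_sd=m_s,
        fundamental_frequency_sd=f_s,
        wiener_entropy_sd=w_s,
    )


@dataclass(frozen=True)
class SpectralFeatures14:
    """14-feature spectral description of a whole call.

    Moment features (mean/sd/median/skew/kurtosis, mode) are taken on
    the mean normalized power spectrum treated as a probability
    distribution over frequency; flatness and entropy summarize its
    shape; dominant-frequency statistics track the per-window peak.
    """

    mean_freq: float
    sd_freq: float
    median_freq: float
    skew: float
    kurtosis: float
    spectral_flatness: float
    entropy: float
    mode_freq: float
    freq_precision: float
    peak_freq: float
    fundamental_freq: float
    dominant_freq: float
    max_dominant_freq: float
    duration: float

    @classmethod
    def names(cls) -> list[str]:
        return [f.name for f in dc_fields(cls)]

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.names()], dtype=np.float64)


def compute_features14(seg: VocalSegment, fft_params: FFTParams = FFTParams()) -> SpectralFeatures14:
    if len(seg.samples) < 2:
        raise ValueError("segment too short for spectral analysis")
    power, freqs = fft_params.power_spectra(seg.samples, seg.sample_rate)
    band = freqs >= HIGHPASS_HZ
    power = power[:, band]
    freqs = freqs[band]
    tot = power.sum(axis=1)
    live = tot > 0
    if not live.any():
        raise ValueError("silent segment")
    power = power[live]
    mean_spec = power.mean(axis=0)
    p = mean_spec / mean_spec.sum()

    mean_f = float((p * freqs).sum())
    var_f = float((p * (freqs - mean_f) ** 2).sum())
    sd_f = float(np.sqrt(var_f))
    cdf = np.cumsum(p)
    median_f = float(freqs[int(np.searchsorted(cdf, 0.5))])
    if sd_f > 0:
        z = (freqs - mean_f) / sd_f
        skew = float((p * z**3).sum())
        kurt = float((p * z**4).sum())
    else:  # single-bin spectrum
        skew, kurt = 0.0, 0.0
    flat = wiener_entropy(mean_spec)
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum() / np.log(len(p))) if len(p) > 1 else 0.0
    mode_f = float(freqs[int(np.argmax(p))])
    precision = float(freqs[1] - freqs[0]) if len(freqs) > 1 else float("nan")
    dom = freqs[np.argmax(power, axis=1)]
    return SpectralFeatures14(
        mean_freq=mean_f,
        sd_freq=sd_f,
        median_freq=median_f,
        skew=skew,
        kurtosis=kurt,
        spectral_flatness=flat,
        entropy=entropy,
        mode_freq=mode_f,
        freq_precision=precision,
        peak_freq=mode_f if len(dom) == 0 else float(freqs[int(np.argmax(mean_spec))]),
        fundamental_freq=_first_peak_hz(mean_spec, freqs),
        dominant_freq=float(dom.mean()),
        max_dominant_freq=float(dom.max()),
        duration=seg.duration_s,
    )


@dataclass
class ClusterAssignment:
    """K-means labels per segment; ``NOISE`` (-1) marks outliers."""

    labels: np.ndarray
    centroids: np.ndarray
    distances: np.ndarray
    noise_threshold: float | None

    @property
    def is_noise(self) -> np.ndarray:
        return self.labels == NOISE

    def __len__(self) -> int:
        return len(self.labels)


def _as_matrix(features: Sequence[SortingFeatures] | np.ndarray) -> np.ndarray:
    if isinstance(features, np.ndarray):
        return np.asarray(features, dtype=np.float64)
    return np.stack([f.to_array() for f in features])


def cluster_calls(
    features: Sequence[SortingFeatures] | np.ndarray,
    k: int,
    seed: int,
    noise_quantile: float | None = 0.99,
    n_init: int = 10,
) -> ClusterAssignment:
    """Cluster call feature vectors into ``k`` call types.

    Features are z-scored per dimension, then k-means with ``n_init``
    restarts is run.  Segments whose distance to their centroid exceeds
    the ``noise_quantile`` quantile of all such distances are relabelled
    ``NOISE`` (pass ``None`` to keep every segment).  Labels are
    arbitrary; compare partitions, not raw label values.
    """
    X = _as_matrix(features)
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(X) < k:
        raise ValueError(f"need at least k={k} feature vectors, got {len(X)}")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    km = KMeans(n_clusters=k, n_init=n_init, random_state=int(seed) % (2**31))
    labels = km.fit_predict(Z)
    dist = np.linalg.norm(Z - km.cluster_centers_[labels], axis=1)
    thr = None
    if noise_quantile is not None:
        thr = float(np.quantile(dist, noise_quantile))
        labels = np.where(dist > thr, NOISE, labels)
    return ClusterAssignment(labels=labels, centroids=km.cluster_centers_, distances=dist, noise_threshold=thr)


def apply_manual_edits(assignment: ClusterAssignment, edits: dict[int, int]) -> ClusterAssignment:
    """Apply curator overrides (segment index -> label) to an assignment.

    Stands in for the manual refinement step of interactive sorting;
    accepts the contents of an edits CSV parsed to a dict.
    """
    labels = assignment.labels.copy()
    for idx, lab in edits.items():
        labels[int(idx)] = int(lab)
    return ClusterAssignment(
        labels=labels,
        centroids=assignment.centroids,
        distances=assignment.distances,
        noise_threshold=assignment.noise_threshold,
    )
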