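"""Waveform → labeled log-frequency spectrogram RGB images.

The pipeline mirrors standard sleep-spectrogram imaging practice:

1. resample every channel to a common 512 Hz (256 Hz bandwidth);
2. cut each annotated 30-s epoch into overlapping 10-s windows with a
   1-s stride (90% overlap, 21 windows per epoch), each window
   inheriting the epoch's stage label and the record's disorder label;
3. magnitude STFT of each window (Hann taper, 256-sample segments,
   hop 128, 512-point FFT → ~2 Hz resolution, enough to resolve delta);
4. interpolate the frequency axis onto geometrically spaced bin centres
   (log-frequency scale) and the time axis onto a linear grid;
5. convert to dB, normalise with per-modality *average* minima/maxima
   fitted on training images only, and map through the classic
   piecewise-linear jet colormap into an 8-bit RGB image with low
   frequencies at the bottom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import TYPE_CHECKING

import numpy as np
from PIL import Image
from scipy import signal as sps

from .labels import validate_modality

if TYPE_CHECKING:  # avoid circular import; records are duck-typed here
    from .signal_io import MultimodalRecord

logger = logging.getLogger(__name__)

DB_EPS = 1e-10  # floor inside 20*log10(|S| + eps)

__all__ = [
    "WindowSpec",
    "StftConfig",
    "NormStats",
    "SpectrogramImage",
    "Window",
    "standardize_sampling",
    "extract_windows",
    "compute_spectrogram",
    "map_to_log_frequency",
    "amplitude_to_db",
    "fit_modality_norm",
    "jet_colormap",
    "render_rgb",
]


@dataclass(frozen=True)
class WindowSpec:
    """Epoch-windowing geometry (seconds)."""

    window_len: float = 10.0
    stride: float = 1.0
    epoch_len: float = 30.0

    def __post_init__(self) -> None:
        if not 0 < self.stride <= self.window_len <= self.epoch_len:
            raise ValueError(
                f"require 0 < stride <= window_len <= epoch_len, got "
                f"{self.stride}/{self.window_len}/{self.epoch_len}"
            )

    @property
    def windows_per_epoch(self) -> int:
        return int((self.epoch_len - self.window_len) / self.stride) + 1


@dataclass(frozen=True)
class StftConfig:
    """STFT and log-frequency resampling parameters."""

    target_rate: float = 512.0
    segment_len: int = 256
    hop: int = 128
    fft_len: int = 512
    taper: str = "hann"
    fmin: float = 0.5
    n_freq_bins: int = 224
    n_time_bins: int = 224

    def __post_init__(self) -> None:
        if self.segment_len > self.fft_len:
            raise ValueError("segment_len must be <= fft_len")
        if not 0 < self.fmin < self.target_rate / 2:
            raise ValueError("require 0 < fmin < target_rate/2")
        if self.n_freq_bins < 2 or self.n_time_bins < 2:
            raise ValueError("n_freq_bins and n_time_bins must be >= 2")

    def log_bin_centers(self) -> np.ndarray:
        """Geometrically spaced frequency-bin centres in [fmin, Nyquist]."""
        return np.geomspace(self.fmin, self.target_rate / 2, self.n_freq_bins)


@dataclass(frozen=True)
class NormStats:
    """Per-modality normalisation range: mean of per-image minima/maxima (dB)."""

    modality: str
    avg_min: float
    avg_max: float

    def __post_init__(self) -> None:
        validate_modality(self.modality)
        if not self.avg_min < self.avg_max:
            raise ValueError(
                f"degenerate normalisation range [{self.avg_min}, {self.avg_max}]"
            )


@dataclass(frozen=True)
class Window:
    """A labeled 10-s waveform segment with full provenance."""

    samples: np.ndarray
    record_id: str
    modality: str
    channel: str
    epoch_index: int
    offset_s: float
    stage: str
    disorder: str

    @property
    def key(self) -> tuple[str, int, float]:
        return (self.record_id, self.epoch_index, self.offset_s)


@dataclass(frozen=True)
class SpectrogramImage:
    """H×W×3 8-bit RGB spectrogram image with provenance and both labels."""

    pixels: np.ndarray  # uint8, H x W x 3
    record_id: str
    modality: str
    channel: str
    epoch_index: int
    offset_s: float
    stage: str
    disorder: str

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must be HxWx3, got {px.shape}")
        if px.dtype != np.uint8:
            raise ValueError("pixels must be uint8")

    @property
    def key(self) -> tuple[str, int, float]:
        return (self.record_id, self.epoch_index, self.offset_s)


def standardize_sampling(
    samples: np.ndarray, source_rate: float, target_rate: float
) -> np.ndarray:
    """Resample a channel to ``target_rate`` with band-limited interpolation.

    Downsampling applies the anti-alias FIR low-pass built into
    polyphase resampling; an already-conforming channel is returned
    unchanged (as a copy).  Duration is preserved to within one sample.
    """
    samples = np.asarray(samples, dtype=float)
    if source_rate <= 0 or target_rate <= 0:
        raise ValueError("sampling rates must be > 0")
    if not np.all(np.isfinite(samples)):
        raise ValueError("channel contains non-finite samples")
    if source_rate == target_rate:
        return samples.copy()
    frac = Fraction(target_rate / source_rate).limit_denominator(10_000)
    # high-attenuation Kaiser taper keeps passband ripple ~1e-6
    return sps.resample_poly(
        samples, frac.numerator, frac.denominator, window=("kaiser", 14.0)
    )


def extract_windows(
    record: "MultimodalRecord",
    modality: str,
    channel: str,
    spec: WindowSpec = WindowSpec(),
    target_rate: float = 512.0,
) -> list[Window]:
    """Cut one channel of a record into labeled within-epoch windows.

    Windows never cross a 30-s epoch boundary; each carries its parent
    epoch's stage label, the record's disorder label, and offset
    provenance.  Spans without an annotation are skipped with a warning.
    """
    validate_modality(modality)
    ch = record.get_channel(modality, channel)
    x = standardize_sampling(ch.samples, ch.sampling_rate, target_rate)
    wlen = int(round(spec.window_len * target_rate))
    stride = int(round(spec.stride * target_rate))
    elen = int(round(spec.epoch_len * target_rate))
    n_annotated = len(record.annotations) * elen
    if len(x) > n_annotated:
        logger.warning(
            "record %s channel %s: %d samples beyond the annotated span skipped",
            record.record_id, channel, len(x) - n_annotated,
        )
    windows: list[Window] = []
    for ann in record.annotations:
        start = int(round(ann.start_time * target_rate))
        if start + elen > len(x):
            raise ValueError(
                f"record {record.record_id}: epoch {ann.epoch_index} extends past "
                f"the end of channel {channel!r}"
            )
        for off in range(0, elen - wlen + 1, stride):
            windows.append(
                Window(
                    samples=x[start + off : start + off + wlen],
                    record_id=record.record_id,
                    modality=modality,
                    channel=channel,
                    epoch_index=ann.epoch_index,
                    offset_s=off / target_rate,
                    stage=ann.stage,
                    disorder=record.disorder,
                )
            )
    return windows


def compute_spectrogram(
    window: np.ndarray, cfg: StftConfig = StftConfig(), window_len_s: float = 10.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Magnitude STFT of one window.

    Returns ``(magnitude, freqs, times)`` where ``magnitude`` has shape
    (native frequency bins × time frames).
    """
    window = np.asarray(window, dtype=float)
    expected = int(round(window_len_s * cfg.target_rate))
    if window.shape != (expected,):
        raise ValueError(
            f"window must hold {expected} samples ({window_len_s} s at "
            f"{cfg.target_rate} Hz), got {window.shape}"
        )
    freqs, times, Z = sps.stft(
        window,
        fs=cfg.target_rate,
        window=cfg.taper,
        nperseg=cfg.segment_len,
        noverlap=cfg.segment_len - cfg.hop,
        nfft=cfg.fft_len,
        boundary="zeros",
        padded=True,
    )
    return np.abs(Z), freqs, times


def _interp_matrix(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Dense linear-interpolation operator mapping samples at ``src`` to ``dst``."""
    w = np.zeros((dst.size, src.size))
    idx = np.clip(np.searchsorted(src, dst) - 1, 0, src.size - 2)
    denom = src[idx + 1] - src[idx]
    frac = np.clip((dst - src[idx]) / denom, 0.0, 1.0)
    w[np.arange(dst.size), idx] = 1.0 - frac
    w[np.arange(dst.size), idx + 1] += frac
    return w


def map_to_log_frequency(
    magnitude: np.ndarray,
    freqs: np.ndarray,
    times: np.ndarray,
    cfg: StftConfig = StftConfig(),
) -> np.ndarray:
    """Resample a native-grid spectrogram onto (log-frequency × linear-time) axes.

    The frequency axis is linearly interpolated onto ``n_freq_bins``
    geometrically spaced centres in [fmin, Nyquist]; the time axis onto
    ``n_time_bins`` linearly spaced centres.  Row 0 of the result is the
    lowest-frequency bin.
    """
    magnitude = np.asarray(magnitude, dtype=float)
    if magnitude.shape != (freqs.size, times.size):
        raise ValueError("magnitude shape does not match freq/time axes")
    centers = cfg.log_bin_centers()
    wf = _interp_matrix(np.asarray(freqs, float), centers)
    tt = np.linspace(times[0], times[-1], cfg.n_time_bins)
    wt = _interp_matrix(np.asarray(times, float), tt)
    return wf @ magnitude @ wt.T


def amplitude_to_db(magnitude: np.ndarray) -> np.ndarray:
    """20·log10(|S| + 1e-10): the dB scale used throughout normalisation."""
    return 20.0 * np.log10(np.asarray(magnitude, dtype=float) + DB_EPS)


def fit_modality_norm(
    spectrograms_db: list[np.ndarray], modality: str
) -> NormStats:
    """Average of per-image minima and maxima over one modality's images."""
    validate_modality(modality)
    if not spectrograms_db:
        raise ValueError("need at least one spectrogram to fit normalisation")
    mins = [float(np.min(s)) for s in spectrograms_db]
    maxs = [float(np.max(s)) for s in spectrograms_db]
    return NormStats(
        modality=modality, avg_min=float(np.mean(mins)), avg_max=float(np.mean(maxs))
    )


# Classic piecewise-linear jet segment map (control points of the widely
# used blue→cyan→yellow→red colormap), evaluated continuously.
_JET_SEGMENTS = {
    "red": [(0.0, 0.0), (0.35, 0.0), (0.66, 1.0), (0.89, 1.0), (1.0, 0.5)],
    "green": [(0.0, 0.0), (0.125, 0.0), (0.375, 1.0), (0.64, 1.0), (0.91, 0.0), (1.0, 0.0)],
    "blue": [(0.0, 0.5), (0.11, 1.0), (0.34, 1.0), (0.65, 0.0), (1.0, 0.0)],
}


def jet_colormap(x: np.ndarray) -> np.ndarray:
    """Evaluate the jet colormap at values in [0, 1] → float RGB in [0, 1]."""
    x = np.clip(np.asarray(x, dtype=float), 0.0, 1.0)
    out = np.empty(x.shape + (3,))
    for i, name in enumerate(("red", "green", "blue")):
        pts = np.array(_JET_SEGMENTS[name])
        out[..., i] = np.interp(x, pts[:, 0], pts[:, 1])
    return out


def render_rgb(
    spec_db: np.ndarray,
    norm: NormStats,
    image_size: int,
    *,
    record_id: str = "",
    channel: str = "",
    epoch_index: int = 0,
    offset_s: float = 0.0,
    stage: str = "W",
    disorder: str = "N",
) -> SpectrogramImage:
    """Normalise a dB spectrogram and render it as a jet RGB image.

    Values are affinely mapped from [avg_min, avg_max] to [0, 1] with
    clamping, passed through the jet colormap, flipped so low
    frequencies sit at the bottom row, and resampled to
    ``image_size × image_size``.
    """
    spec_db = np.asarray(spec_db, dtype=float)
    unit = (spec_db - norm.avg_min) / (norm.avg_max - norm.avg_min)
    rgb = jet_colormap(np.clip(unit, 0.0, 1.0))
    pixels = np.round(rgb * 255.0).astype(np.uint8)
    pixels = pixels[::-1, :, :]  # row 0 was lowest frequency -> move to bottom
    if pixels.shape[0] != image_size or pixels.shape[1] != image_size:
        img = Image.fromarray(pixels, mode="RGB").resize(
            (image_size, image_size), Image.BILINEAR
        )
        pixels = np.asarray(img)
    return SpectrogramImage(
        pixels=pixels,
        record_id=record_id,
        modality=norm.modality,
        channel=channel,
        epoch_index=epoch_index,
        offset_s=offset_s,
        stage=stage,
        disorder=disorder,
    )
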