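"""The five model-input modalities derived from a 5-s EEG segment.

Starting from a 5-s segment sampled at 1,000 Hz (5,000 samples):

* ``raw500`` — block-average downsampling to 100 Hz, 500 points;
* ``pgram100`` — periodogram power averaged in 1-Hz bands covering 0-99 Hz,
  100 points;
* ``stft_img`` — 20 x 50 gray spectrogram image (frequency rows x time
  columns) of the downsampled trace, Hamming window, log-compressed,
  min-max normalized to [0, 1];
* ``wave_img`` — 40 x 250 black-and-white rasterization of the downsampled
  waveform (two samples per pixel column, amplitude mapped to rows with a
  fixed per-recording display gain);
* ``ctx_img`` — 40 x 750 horizontal concatenation of the waveform images
  2.5 min before, at, and 2.5 min after a time point, so the classifier sees
  pre-/post-event context.

Rasterization uses a per-recording :class:`RasterScale` rather than
per-segment min-max: per-segment normalization would erase exactly the
amplitude contrast between seizure and background that detection relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from skimage.transform import resize

from .io import EEGRecord

__all__ = [
    "MODALITIES",
    "RasterScale",
    "block_downsample",
    "periodogram_100",
    "stft_image",
    "rasterize_waveform",
    "concat_context",
    "pair_sequence",
    "segment_to_input",
]

#: modality name -> output shape (1-D length or 2-D shape)
MODALITIES = {
    "raw500": (500,),
    "pgram100": (100,),
    "stft_img": (20, 50),
    "wave_img": (40, 250),
    "ctx_img": (40, 750),
}


@dataclass(frozen=True)
class RasterScale:
    """Fixed display gain for waveform rasterization.

    ``center`` is the recording's median and ``half_range`` half of its
    0.5-99.5 percentile span, so one scale applies to every segment of a
    recording (mimics a fixed screen gain during visual review).
    """

    center: float
    half_range: float

    def __post_init__(self) -> None:
        if self.half_range <= 0:
            raise ValueError("half_range must be positive")

    @classmethod
    def from_record(cls, record: EEGRecord, channel: int = 0) -> "RasterScale":
        x = record.samples[channel]
        lo, hi = np.percentile(x, [0.5, 99.5])
        return cls(center=float(np.median(x)), half_range=float(max((hi - lo) / 2, 1e-9)))


def block_downsample(samples: np.ndarray, factor: int = 10) -> np.ndarray:
    """Average-sampling decimation: output[i] = mean(samples[i*f:(i+1)*f])."""
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D sample array")
    if factor < 1 or x.size % factor:
        raise ValueError(f"length {x.size} not divisible by factor {factor}")
    return x.reshape(-1, factor).mean(axis=1)


def periodogram_100(samples: np.ndarray, fs: float = 1000.0) -> np.ndarray:
    """Periodogram power in 1-Hz bands [k, k+1) for k = 0..99.

    Computed on the full-rate 5,000-sample segment (0.2-Hz resolution, five
    DFT bins averaged per band). All values are >= 0 and scale quadratically
    with input amplitude.
    """
    x = np.asarray(samples, dtype=float)
    if x.size != int(5 * fs):
        raise ValueError(f"expected {int(5 * fs)} samples at {fs} Hz, got {x.size}")
    freqs, p = signal.periodogram(x, fs=fs, window="boxcar", detrend=False)
    bins_per_band = int(round(x.size / fs))  # resolution fs/N = 0.2 Hz -> 5 bins/Hz
    return p[: 100 * bins_per_band].reshape(100, bins_per_band).mean(axis=1)


def stft_image(
    samples: np.ndarray,
    fs: float = 1000.0,
    out_shape: tuple[int, int] = (20, 50),
    window_s: float = 0.5,
    overlap: float = 0.75,
) -> np.ndarray:
    """Gray spectrogram image, frequency rows (low at row 0) x time columns.

    Magnitude STFT (Hamming window) of the 100-Hz downsampled trace,
    log-compressed as log(1+|S|), resampled with anti-aliasing to
    ``out_shape`` and min-max normalized to [0, 1]. An all-zero segment maps
    to an all-zero image.
    """
    x = np.asarray(samples, dtype=float)
    if x.size != int(5 * fs):
        raise ValueError(f"expected {int(5 * fs)} samples at {fs} Hz, got {x.size}")
    factor = int(round(fs / 100.0))
    x100 = block_downsample(x, factor) if factor > 1 else x
    nperseg = int(round(window_s * 100))
    noverlap = int(round(overlap * nperseg))
    _, _, S = signal.stft(
        x100, fs=100, window="hamming", nperseg=nperseg, noverlap=noverlap,
        boundary=None, padded=False,
    )
    img = np.log1p(np.abs(S))
    img = resize(img, out_shape, order=1, mode="edge", anti_aliasing=True)
    lo, hi = img.min(), img.max()
    if hi - lo < 1e-12:
        return np.zeros(out_shape)
    return (img - lo) / (hi - lo)


def _to_row(values: np.ndarray, scale: RasterScale, n_rows: int) -> np.ndarray:
    """Amplitude -> row index; top row (0) is the positive extreme."""
    u = (np.asarray(values, dtype=float) - (scale.center - scale.half_range)) / (2 * scale.half_range)
    u = np.clip(u, 0.0, 1.0)
    return np.round((1.0 - u) * (n_rows - 1)).astype(int)


def rasterize_waveform(
    raw500: np.ndarray,
    scale: RasterScale,
    shape: tuple[int, int] = (40, 250),
) -> np.ndarray:
    """Render a 500-point trace as a binary image, two samples per column.

    Each column turns on the contiguous vertical span covering its two
    samples and the last sample of the previous column, so the trace is a
    connected line across the image.
    """
    x = np.asarray(raw500, dtype=float)
    n_rows, n_cols = shape
    if x.size != 2 * n_cols:
        raise ValueError(f"expected {2 * n_cols} values for {n_cols} columns, got {x.size}")
    rows = _to_row(x, scale, n_rows).reshape(n_cols, 2)
    img = np.zeros(shape, dtype=np.uint8)
    prev = rows[0, 0]
    for c in range(n_cols):
        lo = min(rows[c, 0], rows[c, 1], prev)
        hi = max(rows[c, 0], rows[c, 1], prev)
        img[lo : hi + 1, c] = 1
        prev = rows[c, 1]
    return img


def concat_context(
    record: EEGRecord,
    t_center_s: float,
    scale: RasterScale,
    gap_s: float = 150.0,
    channel: int = 0,
) -> np.ndarray:
    """40 x 750 image: waveform rasters at t-150 s, t, t+150 s side by side.

    Window starts are clamped to the record (never zero-padded), so context
    near an edge reuses the nearest valid 5-s window.
    """
    T = record.duration_s
    if T < 5:
        raise ValueError("record shorter than one 5-s window")
    factor = int(round(record.fs / 100.0))
    blocks = []
    for t0 in (t_center_s - gap_s, t_center_s, t_center_s + gap_s):
        t0 = min(max(t0, 0.0), T - 5.0)
        i0 = int(round(t0 * record.fs))
        seg = record.samples[channel, i0 : i0 + int(round(5 * record.fs))]
        raw = block_downsample(seg, factor) if factor > 1 else seg
        blocks.append(rasterize_waveform(raw, scale))
    return np.concatenate(blocks, axis=1)


def pair_sequence(vector: np.ndarray) -> np.ndarray:
    """Non-overlapping consecutive pairs: length-n vector -> (n/2, 2) steps."""
    x = np.asarray(vector, dtype=float)
    if x.ndim != 1 or x.size % 2:
        raise ValueError("pair_sequence requires an even-length 1-D vector")
    return x.reshape(-1, 2)


def segment_to_input(
    samples: np.ndarray,
    modality: str,
    fs: float = 1000.0,
    scale: RasterScale | None = None,
    record: EEGRecord | None = None,
    start_s: float | None = None,
) -> np.ndarray:
    """Dispatch a 5-s segment to the requested modality.

    ``wave_img`` needs a :class:`RasterScale`; ``ctx_img`` additionally needs
    the source record and the segment start time (for the +/-2.5-min
    context windows).
    """
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    if modality == "raw500":
        return block_downsample(samples, int(round(fs / 100.0)))
    if modality == "pgram100":
        return periodogram_100(samples, fs)
    if modality == "stft_img":
        return stft_image(samples, fs)
    if scale is None:
        raise ValueError(f"{modality} requires a RasterScale")
    if modality == "wave_img":
        return rasterize_waveform(block_downsample(samples, int(round(fs / 100.0))), scale)
    if record is None or start_s is None:
        raise ValueError("ctx_img requires the source record and segment start time")
    return concat_context(record, start_s, scale, channel=0)
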