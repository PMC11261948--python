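"""Morlet time-frequency images: the model's event representation.

Each detected event is represented by the magnitude of its Morlet wavelet
transform over +/-285 ms around the event center and 10-290 Hz (1 Hz
steps), resized bilinearly to 64 x 64 and min-max normalized to [0, 1].
Min-max normalization makes the image invariant to amplitude scaling of
the underlying trace; morphology alone is retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

__all__ = [
    "FeatureConfig",
    "TFImage",
    "event_tf_image",
    "flip_time_axis",
    "events_to_images",
    "minmax_normalize",
]


def minmax_normalize(images: np.ndarray) -> np.ndarray:
    """Per-image min-max normalization to [0, 1]; constant images become 0.

    Every image entering the inference pipeline satisfies this contract, so
    generated (decoded) images must be re-normalized before re-encoding.
    """
    images = np.asarray(images, dtype=np.float64)
    single = images.ndim == 2
    x = images[np.newaxis] if single else images
    lo = x.min(axis=(1, 2), keepdims=True)
    hi = x.max(axis=(1, 2), keepdims=True)
    span = hi - lo
    out = np.where(span > 0, (x - lo) / np.where(span > 0, span, 1.0), 0.0)
    return out[0] if single else out


@dataclass(frozen=True)
class FeatureConfig:
    half_window_s: float = 0.285
    freq_range: tuple[float, float] = (10.0, 290.0)
    freq_step: float = 1.0
    n_cycles: float = 7.0
    out_size: tuple[int, int] = (64, 64)

    def __post_init__(self) -> None:
        if self.half_window_s <= 0:
            raise ValueError("half_window_s must be positive")

    def freqs(self) -> np.ndarray:
        lo, hi = self.freq_range
        return np.arange(lo, hi, self.freq_step)


@dataclass
class TFImage:
    """64x64 normalized scalogram with axis calibration.

    Row 0 is the lowest frequency; time runs left to right with the event
    center at the midpoint column. ``constant_input`` flags an all-zero
    window (the image is defined as all zeros, never NaN); ``padded`` flags
    zero-padding at trace edges.
    """

    pixels: np.ndarray
    times_ms: np.ndarray
    freqs_hz: np.ndarray
    event_id: str = ""
    constant_input: bool = False
    padded: bool = False


def _morlet_power(segment: np.ndarray, fs: float, freqs: np.ndarray, n_cycles: float) -> np.ndarray:
    from mne.time_frequency import tfr_array_morlet

    data = segment[np.newaxis, np.newaxis, :]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = tfr_array_morlet(
            data, sfreq=fs, freqs=freqs, n_cycles=n_cycles, output="complex", verbose="error"
        )
    return np.abs(out[0, 0])  # (n_freqs, n_times)


def event_tf_image(
    trace: np.ndarray,
    center_time: float,
    fs: float,
    config: FeatureConfig | None = None,
    event_id: str = "",
) -> TFImage:
    """Morlet scalogram of the +/-half_window around ``center_time``.

    The raw segment is taken wide enough to hold the longest wavelet
    (7 cycles at the lowest frequency), zero-padded at trace edges, then the
    scalogram is cropped to the +/-285 ms analysis window, resized to 64x64
    and min-max normalized.
    """
    config = config or FeatureConfig()
    trace = np.asarray(trace, dtype=np.float64)
    freqs = config.freqs()
    half = int(round(config.half_window_s * fs))
    # margin covers half the longest wavelet so cropped columns are edge-free
    margin = int(np.ceil(config.n_cycles / (2 * freqs[0]) * fs)) + 1
    c = int(round(center_time * fs))
    lo, hi = c - half - margin, c + half + margin + 1
    segment = np.zeros(hi - lo)
    src_lo, src_hi = max(lo, 0), min(hi, len(trace))
    padded = src_lo != lo or src_hi != hi
    segment[src_lo - lo : src_hi - lo] = trace[src_lo:src_hi]

    if not np.any(segment):
        pixels = np.zeros(config.out_size)
        constant = True
    else:
        power = _morlet_power(segment, fs, freqs, config.n_cycles)
        power = power[:, margin : margin + 2 * half + 1]
        pixels = resize(power, config.out_size, order=1, anti_aliasing=True)
        lo_v, hi_v = pixels.min(), pixels.max()
        constant = hi_v - lo_v <= 0
        pixels = np.zeros(config.out_size) if constant else (pixels - lo_v) / (hi_v - lo_v)

    n_t, n_f = config.out_size[1], config.out_size[0]
    times_ms = np.linspace(-config.half_window_s * 1e3, config.half_window_s * 1e3, n_t)
    freqs_axis = np.linspace(freqs[0], freqs[-1], n_f)
    return TFImage(
        pixels=pixels,
        times_ms=times_ms,
        freqs_hz=freqs_axis,
        event_id=event_id,
        constant_input=constant,
        padded=padded,
    )


def flip_time_axis(image: np.ndarray | TFImage):
    """Reverse the time (column) axis; an involution."""
    if isinstance(image, TFImage):
        return TFImage(
            pixels=image.pixels[:, ::-1].copy(),
            times_ms=image.times_ms,
            freqs_hz=image.freqs_hz,
            event_id=image.event_id,
            constant_input=image.constant_input,
            padded=image.padded,
        )
    return np.asarray(image)[:, ::-1].copy()


def events_to_images(
    recording,
    events,
    config: FeatureConfig | None = None,
) -> np.ndarray:
    """Vector of TF images (n, 64, 64) for an event table on one recording."""
    config = config or FeatureConfig()
    images = []
    for _, row in events.iterrows():
        center = 0.5 * (row["start_s"] + row["end_s"])
        trace = recording.channel(row["channel"])
        img = event_tf_image(trace, center, recording.fs, config)
        images.append(img.pixels)
    if not images:
        return np.zeros((0, *config.out_size))
    return np.stack(images)
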