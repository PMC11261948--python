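"""Automated HFO detection in the 80-300 Hz ripple band.

Two classical detectors are implemented:

- STE (short-term energy): a moving-RMS threshold detector. Events are
  intervals where the 3 ms moving RMS of the band-passed signal exceeds the
  epoch mean + 5 SD for at least 6 ms, with at least 6 rectified peaks above
  mean + 3 SD; events closer than 10 ms are merged.
- MNI: a baseline-percentile detector. Background ("baseline") segments are
  identified by high normalized spectral entropy; the detection threshold is
  a high percentile (by default 99.9999) of a gamma fit to baseline band
  energy. When no baseline is found the detector falls back to a continuous
  whole-trace percentile.

Both thresholds are data-relative, so detection counts are invariant to
global amplitude scaling. Overlapping events from multiple detectors are
merged by interval union, and a transparent amplitude rule tags events that
co-occur with a 10-80 Hz spike transient.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .io import empty_event_table

__all__ = [
    "SteParams",
    "MniParams",
    "SpikeTagParams",
    "detect_ste",
    "detect_mni",
    "merge_events",
    "tag_spike_cooccurrence",
    "detect_recording",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SteParams:
    band: tuple[float, float] = (80.0, 300.0)
    rms_window_s: float = 0.003
    threshold_sd: float = 5.0
    min_duration_s: float = 0.006
    min_gap_s: float = 0.010
    min_peaks: int = 6
    peak_threshold_sd: float = 3.0
    epoch_len_s: float = 600.0


@dataclass(frozen=True)
class MniParams:
    band: tuple[float, float] = (80.0, 300.0)
    energy_percentile: float = 99.9999
    min_duration_s: float = 0.010
    baseline_window_s: float = 0.125
    baseline_entropy_threshold: float = 0.90
    min_baseline_s: float = 5.0
    min_gap_s: float = 0.010

    def __post_init__(self) -> None:
        if not 0.0 < self.energy_percentile < 100.0:
            raise ValueError("energy_percentile must lie in (0, 100)")


@dataclass(frozen=True)
class SpikeTagParams:
    band: tuple[float, float] = (10.0, 80.0)
    half_window_s: float = 0.100
    threshold_sd: float = 4.0


def _bandpass(trace: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    nyq = fs / 2.0
    hi = min(band[1], 0.95 * nyq)
    sos = signal.butter(4, [band[0], hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, trace)


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs where mask is True."""
    if not mask.any():
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    stops = list(np.flatnonzero(diff == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    return list(zip(starts, stops))


def _join_close(runs: list[tuple[int, int]], max_gap: int) -> list[tuple[int, int]]:
    if not runs:
        return []
    joined = [list(runs[0])]
    for start, stop in runs[1:]:
        if start - joined[-1][1] < max_gap:
            joined[-1][1] = stop
        else:
            joined.append([start, stop])
    return [(s, e) for s, e in joined]


def _events_frame(runs, fs, channel, detector, subject="") -> pd.DataFrame:
    if not runs:
        return empty_event_table()
    return pd.DataFrame(
        {
            "subject": subject,
            "channel": channel,
            "start_s": [s / fs for s, _ in runs],
            "end_s": [e / fs for _, e in runs],
            "detector": detector,
            "tags": "",
        }
    )


def detect_ste(
    trace: np.ndarray,
    fs: float,
    params: SteParams | None = None,
    channel: str = "ch0",
    subject: str = "",
) -> pd.DataFrame:
    """Short-term-energy (moving RMS threshold) ripple detector."""
    params = params or SteParams()
    trace = np.asarray(trace, dtype=np.float64)
    if not np.any(trace):
        return empty_event_table()
    band = _bandpass(trace, fs, params.band)
    win = max(int(round(params.rms_window_s * fs)), 1)
    rms = np.sqrt(
        signal.convolve(band**2, np.ones(win) / win, mode="same")
    )
    rect = np.abs(band)

    epoch = int(round(params.epoch_len_s * fs))
    if len(trace) < epoch:
        warnings.warn("trace shorter than detection epoch; single-epoch fallback")
    runs_all: list[tuple[int, int]] = []
    for e0 in range(0, len(trace), epoch):
        e1 = min(e0 + epoch, len(trace))
        seg_rms = rms[e0:e1]
        thr = seg_rms.mean() + params.threshold_sd * seg_rms.std()
        peak_thr = rect[e0:e1].mean() + params.peak_threshold_sd * rect[e0:e1].std()
        runs = _runs_above(seg_rms > thr)
        runs = _join_close(runs, max_gap=int(round(params.min_gap_s * fs)))
        min_len = int(round(params.min_duration_s * fs))
        for s, e in runs:
            if e - s < min_len:
                continue
            seg = rect[e0 + s : e0 + e]
            peaks, _ = signal.find_peaks(seg, height=peak_thr)
            if len(peaks) >= params.min_peaks:
                runs_all.append((e0 + s, e0 + e))
    return _events_frame(runs_all, fs, channel, "STE", subject)


def _spectral_entropy(segment: np.ndarray) -> float:
    """Normalized spectral entropy in [0, 1]; 1 = flat (background-like)."""
    psd = np.abs(np.fft.rfft(segment)) ** 2
    psd = psd[1:]  # drop DC
    total = psd.sum()
    if total <= 0:
        return 1.0
    p = psd / total
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.nansum(p * np.log(np.where(p > 0, p, 1.0)))
    return float(h / np.log(len(p)))


def detect_mni(
    trace: np.ndarray,
    fs: float,
    params: MniParams | None = None,
    channel: str = "ch0",
    subject: str = "",
) -> pd.DataFrame:
    """Baseline-percentile (MNI-style) ripple detector.

    Baseline segments are 125 ms windows of the band-passed signal whose
    normalized spectral entropy exceeds a threshold (oscillation-free
    background looks spectrally flat within the band). The detection
    threshold is the configured percentile of a gamma distribution fitted
    to baseline energy; with insufficient baseline the whole trace is used
    (continuous-mode fallback, logged).
    """
    params = params or MniParams()
    trace = np.asarray(trace, dtype=np.float64)
    if not np.any(trace):
        return empty_event_table()
    band = _bandpass(trace, fs, params.band)
    win = max(int(round(0.010 * fs)), 1)
    energy = signal.convolve(band**2, np.ones(win) / win, mode="same")

    wlen = int(round(params.baseline_window_s * fs))
    n_windows = len(band) // wlen
    baseline_mask = np.zeros(len(band), dtype=bool)
    for w in range(n_windows):
        seg = band[w * wlen : (w + 1) * wlen]
        if _spectral_entropy(seg) >= params.baseline_entropy_threshold:
            baseline_mask[w * wlen : (w + 1) * wlen] = True

    if baseline_mask.sum() >= params.min_baseline_s * fs:
        ref_energy = energy[baseline_mask]
    else:
        logger.info("channel %s: no baseline found, continuous-mode fallback", channel)
        ref_energy = energy

    ref = ref_energy[ref_energy > 0]
    if len(ref) < 100:
        return empty_event_table()
    shape, loc, scale = stats.gamma.fit(ref, floc=0.0)
    thr = stats.gamma.ppf(params.energy_percentile / 100.0, shape, loc=loc, scale=scale)

    runs = _runs_above(energy > thr)
    runs = _join_close(runs, max_gap=int(round(params.min_gap_s * fs)))
    min_len = int(round(params.min_duration_s * fs))
    runs = [(s, e) for s, e in runs if e - s >= min_len]
    return _events_frame(runs, fs, channel, "MNI", subject)


def merge_events(*tables: pd.DataFrame) -> pd.DataFrame:
    """Union overlapping intervals per (subject, channel) across detectors.

    Any shared sample merges two events (half-open interval arithmetic);
    the output's intervals are pairwise disjoint, detector field "merged".
    Idempotent and invariant to input table order.
    """
    frames = [t for t in tables if t is not None and len(t)]
    if not frames:
        return empty_event_table()
    allev = pd.concat(frames, ignore_index=True)
    out_rows = []
    for (subject, channel), grp in allev.groupby(["subject", "channel"], sort=True):
        ivals = sorted(zip(grp["start_s"], grp["end_s"]))
        merged = [list(ivals[0])]
        for s, e in ivals[1:]:
            if s < merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            out_rows.append(
                {
                    "subject": subject,
                    "channel": channel,
                    "start_s": s,
                    "end_s": e,
                    "detector": "merged",
                    "tags": "",
                }
            )
    return pd.DataFrame(out_rows, columns=list(empty_event_table().columns))


def tag_spike_cooccurrence(
    trace: np.ndarray,
    event: tuple[float, float],
    fs: float,
    params: SpikeTagParams | None = None,
) -> bool:
    """True iff a 10-80 Hz transient near the event exceeds k SD of that band.

    The 10-80 Hz band-passed signal within +/-100 ms of the event center is
    compared against k times the SD of the same band over the whole channel
    (a transparent stand-in for a trained spike classifier).
    """
    params = params or SpikeTagParams()
    trace = np.asarray(trace, dtype=np.float64)
    low = _bandpass(trace, fs, params.band)
    sd = low.std()
    if sd == 0:
        return False
    center = 0.5 * (event[0] + event[1])
    half = int(round(params.half_window_s * fs))
    c = int(round(center * fs))
    if c - half < 0 or c + half > len(trace):
        warnings.warn("spike tag window exceeds trace; truncated")
    lo = max(0, c - half)
    hi = min(len(trace), c + half)
    return bool(np.max(np.abs(low[lo:hi])) > params.threshold_sd * sd)


def detect_recording(
    recording,
    subject: str = "",
    ste_params: SteParams | None = None,
    mni_params: MniParams | None = None,
    tag_params: SpikeTagParams | None = None,
) -> pd.DataFrame:
    """Run both detectors on every channel, merge, and tag spike co-occurrence."""
    tables = []
    for name in recording.ch_names:
        trace = recording.channel(name)
        tables.append(detect_ste(trace, recording.fs, ste_params, channel=name, subject=subject))
        tables.append(detect_mni(trace, recording.fs, mni_params, channel=name, subject=subject))
    merged = merge_events(*tables)
    tags = []
    for _, row in merged.iterrows():
        trace = recording.channel(row["channel"])
        spk = tag_spike_cooccurrence(
            trace, (row["start_s"], row["end_s"]), recording.fs, tag_params
        )
        tags.append("spk" if spk else "")
    if len(merged):
        merged["tags"] = tags
    return merged
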