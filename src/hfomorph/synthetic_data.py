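"""Synthetic iEEG cohorts with ground-truth event classes.

The generator emulates the statistical structure the analysis pipeline
assumes: 1/f background activity, ripple-band (80-300 Hz) bursts, a
pathological event class whose bursts co-occur with a biphasic spike
transient and gamma (30-80 Hz) energy in the sub-HFO (10-80 Hz) band, a
physiological class of isolated ripples, and broadband artifact transients.
Channel metadata (seizure-onset-zone and resection flags) and subject
metadata (site, demographics, Engel-I outcome) are generated alongside so
that the clinical labeling rule and outcome models can be exercised.

Pathological events are preferentially placed on resected channels of
seizure-free subjects, controlled by an odds multiplier (``enrichment``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import Recording, write_edf

__all__ = [
    "NoiseSpec",
    "CohortSpec",
    "GroundTruthEvent",
    "render_background",
    "render_event",
    "generate_cohort",
    "write_cohort",
    "Cohort",
]

CLASSES = ("pathological", "physiological", "artifact")

#: half-width of the exclusion zone between event centers (s); keeps the
#: +/-285 ms feature windows of distinct events from sharing a center.
MIN_CENTER_SEPARATION_S = 0.200


@dataclass(frozen=True)
class NoiseSpec:
    """1/f background: power spectrum ~ 1/f**alpha, scaled to rms microvolts."""

    alpha: float = 1.0
    rms: float = 10.0


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition knobs for a synthetic cohort.

    ``class_mix`` gives proportions over (pathological, physiological,
    artifact) and must sum to 1. ``enrichment`` multiplies the placement
    odds of pathological events on resected channels of seizure-free
    subjects; ``math.inf`` forces all of them there.
    """

    n_subjects: int = 5
    channels_per_subject: int = 8
    duration_s: float = 300.0
    fs: float = 1000.0
    class_mix: tuple[float, float, float] = (0.40, 0.35, 0.25)
    events_per_channel_rate: float = 2.0  # events / min
    soz_fraction: float = 0.25
    resected_fraction: float = 0.5
    seizure_free_fraction: float = 0.7
    enrichment: float = 5.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        for frac in (self.soz_fraction, self.resected_fraction, self.seizure_free_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.fs < 1000:
            raise ValueError("sampling rate must be >= 1000 Hz")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")


@dataclass(frozen=True)
class GroundTruthEvent:
    subject: str
    channel: str
    start_s: float
    end_s: float  # half-open [start_s, end_s)
    true_class: str
    ripple_freq: float
    spike_amplitude: float
    gamma_power: float

    def __post_init__(self) -> None:
        if self.true_class not in CLASSES:
            raise ValueError(f"unknown event class {self.true_class!r}")
        if self.true_class != "artifact" and not 80.0 <= self.ripple_freq <= 300.0:
            raise ValueError("ripple_freq must lie in [80, 300] Hz")

    @property
    def center_s(self) -> float:
        return 0.5 * (self.start_s + self.end_s)


@dataclass
class Cohort:
    """In-memory synthetic cohort: one Recording per subject plus metadata."""

    recordings: dict[str, Recording]
    events: list[GroundTruthEvent]
    channels: pd.DataFrame  # subject, name, type, soz, resected, bad
    subjects: pd.DataFrame  # id, site, sex, age, pathology, resected, engel1
    spec: CohortSpec
    n_rejected: int = 0

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": [e.subject for e in self.events],
                "channel": [e.channel for e in self.events],
                "start_s": [e.start_s for e in self.events],
                "end_s": [e.end_s for e in self.events],
                "true_class": [e.true_class for e in self.events],
                "ripple_freq": [e.ripple_freq for e in self.events],
                "spike_amplitude": [e.spike_amplitude for e in self.events],
                "gamma_power": [e.gamma_power for e in self.events],
            }
        )


# ---------------------------------------------------------------------------
# waveform primitives
# ---------------------------------------------------------------------------

def render_background(duration_s: float, fs: float, noise: NoiseSpec, seed: int) -> np.ndarray:
    """Colored 1/f**alpha noise of length round(duration_s * fs), in microvolts.

    Synthesized by shaping white Gaussian noise in the Fourier domain and
    rescaling to the requested RMS; deterministic for a given seed.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = freqs[nonzero] ** (-noise.alpha / 2.0)
    shaping[0] = 0.0  # zero-mean
    x = np.fft.irfft(spectrum * shaping, n=n)
    rms = np.sqrt(np.mean(x**2))
    if rms > 0:
        x *= noise.rms / rms
    return x


def _hann_burst(freq: float, duration_s: float, fs: float, phase: float) -> np.ndarray:
    n = max(int(round(duration_s * fs)), 8)
    t = np.arange(n) / fs
    return np.hanning(n) * np.sin(2 * np.pi * freq * t + phase)


def _biphasic_spike(fs: float, width_s: float) -> np.ndarray:
    """Biphasic transient (difference of offset Gaussians); energy mostly 10-80 Hz."""
    half = int(round(3 * width_s * fs))
    t = np.arange(-half, half + 1) / fs
    s1 = np.exp(-0.5 * (t / width_s) ** 2)
    s2 = np.exp(-0.5 * ((t - 1.2 * width_s) / (1.6 * width_s)) ** 2)
    spike = s1 - 0.6 * s2
    return spike / np.max(np.abs(spike))


def render_event(
    true_class: str,
    params: dict,
    fs: float,
    seed: int,
) -> np.ndarray:
    """Render one event waveform (microvolts) centered in the returned array.

    Parameters in ``params`` (all optional, class-dependent):

    - ``ripple_freq`` (Hz, default 120), ``ripple_duration`` (s, default 0.07),
      ``ripple_amplitude`` (peak uV, default 60) for both HFO classes;
    - ``spike_amplitude`` (peak uV, default 100) and ``gamma_power``
      (peak uV of the 30-80 Hz burst, default 30) for the pathological class;
    - ``amplitude`` (default 150) for the artifact class.

    A pathological event with ``spike_amplitude=0`` and ``gamma_power=0``
    degenerates exactly to the physiological rendering for the same seed.
    """
    if true_class not in CLASSES:
        raise ValueError(f"unknown event class {true_class!r}")
    rng = np.random.default_rng(seed)
    n = int(round(0.400 * fs))  # 400 ms canvas
    wave = np.zeros(n)
    center = n // 2

    if true_class == "artifact":
        # artifacts are deliberately heterogeneous (movement, electrode pops,
        # amplifier glitches): a random mixture of impulses, steps, ringing
        # at arbitrary frequencies, and slow drift
        amp = params.get("amplitude", 150.0)
        n_impulses = int(rng.integers(1, 4))
        for _ in range(n_impulses):
            a = amp * rng.uniform(0.5, 1.0) * rng.choice([-1.0, 1.0])
            pos = center + int(round(rng.uniform(-0.08, 0.08) * fs))
            width = max(int(round(rng.uniform(0.001, 0.004) * fs)), 1)
            kind = rng.integers(0, 3)
            if kind == 0:  # one-sided decaying impulse
                tail = int(round(rng.uniform(0.005, 0.02) * fs))
                seg = a * np.exp(-np.arange(tail) / max(width, 1))
                hi = min(pos + tail, n)
                wave[pos:hi] += seg[: hi - pos]
            elif kind == 1:  # sharp biphasic glitch
                lo = max(pos - width, 0)
                seg = a * np.concatenate([np.ones(width), -np.ones(width)])
                wave[lo : lo + len(seg)] += seg[: n - lo]
            else:  # boxcar step
                dur = int(round(rng.uniform(0.003, 0.02) * fs))
                lo = max(pos - dur // 2, 0)
                wave[lo : lo + dur] += a
        n_rings = int(rng.integers(0, 3))
        for _ in range(n_rings):
            ring = amp * rng.uniform(0.1, 0.4)
            f_ring = rng.uniform(30.0, min(450.0, 0.45 * fs))
            dur = rng.uniform(0.01, 0.06)
            seg = ring * _hann_burst(f_ring, dur, fs, rng.uniform(0, 2 * np.pi))
            lo = center + int(round(rng.uniform(-0.08, 0.08) * fs)) - len(seg) // 2
            lo = max(lo, 0)
            wave[lo : lo + len(seg)] += seg[: n - lo]
        if rng.random() < 0.5:  # slow drift packet
            drift = amp * rng.uniform(0.1, 0.3)
            seg = drift * _hann_burst(rng.uniform(2.0, 8.0), rng.uniform(0.1, 0.3), fs,
                                      rng.uniform(0, 2 * np.pi))
            lo = max(center - len(seg) // 2, 0)
            wave[lo : lo + len(seg)] += seg[: n - lo]
        return wave

    ripple_freq = params.get("ripple_freq", 120.0)
    duration = params.get("ripple_duration", 0.07)
    amplitude = params.get("ripple_amplitude", 60.0)
    phase = rng.uniform(0, 2 * np.pi)
    burst = amplitude * _hann_burst(ripple_freq, duration, fs, phase)
    start = center - len(burst) // 2
    wave[start : start + len(burst)] += burst

    if true_class == "pathological":
        spike_amp = params.get("spike_amplitude", 100.0)
        gamma_amp = params.get("gamma_power", 30.0)
        if spike_amp > 0:
            spike = spike_amp * _biphasic_spike(fs, params.get("spike_width", 0.012))
            s0 = center - len(spike) // 2
            wave[s0 : s0 + len(spike)] += spike
        if gamma_amp > 0:
            gfreq = params.get("gamma_freq", rng.uniform(35.0, 70.0))
            gburst = gamma_amp * _hann_burst(gfreq, 0.12, fs, rng.uniform(0, 2 * np.pi))
            g0 = center - len(gburst) // 2
            wave[g0 : g0 + len(gburst)] += gburst
    return wave


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def _subject_table(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    ids = [f"sub{i:03d}" for i in range(spec.n_subjects)]
    n_free = int(round(spec.seizure_free_fraction * spec.n_subjects))
    engel1 = np.zeros(spec.n_subjects, dtype=bool)
    engel1[rng.permutation(spec.n_subjects)[:n_free]] = True
    sites = np.where(np.arange(spec.n_subjects) % 2 == 0, "siteA", "siteB")
    pathologies = rng.choice(["FCD", "HS", "Tumor", "Others"], size=spec.n_subjects,
                             p=[0.41, 0.07, 0.19, 0.33])
    return pd.DataFrame(
        {
            "id": ids,
            "site": sites,
            "sex": rng.choice(["F", "M"], size=spec.n_subjects),
            "age": rng.integers(2, 45, size=spec.n_subjects),
            "pathology": pathologies,
            "resected": True,
            "engel1": engel1,
        }
    )


def _channel_table(spec: CohortSpec, subjects: pd.DataFrame,
                   rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    n_ch = spec.channels_per_subject
    n_soz = max(1, int(round(spec.soz_fraction * n_ch)))
    n_res = max(n_soz, int(round(spec.resected_fraction * n_ch)))
    for _, sub in subjects.iterrows():
        perm = rng.permutation(n_ch)
        soz = np.zeros(n_ch, dtype=bool)
        resected = np.zeros(n_ch, dtype=bool)
        soz[perm[:n_soz]] = True
        resected[perm[:n_res]] = True  # resections cover the SOZ
        for c in range(n_ch):
            rows.append(
                {
                    "subject": sub["id"],
                    "name": f"G{c + 1}",
                    "type": "grid",
                    "soz": soz[c],
                    "resected": resected[c],
                    "bad": False,
                }
            )
    return pd.DataFrame(rows)


def _place_centers(n_events: int, duration_s: float, rng: np.random.Generator,
                   margin_s: float = 0.35) -> tuple[np.ndarray, int]:
    """Jittered event centers with a minimum separation; rejection sampling."""
    centers: list[float] = []
    rejected = 0
    attempts = 0
    max_attempts = 50 * max(n_events, 1)
    while len(centers) < n_events and attempts < max_attempts:
        attempts += 1
        c = rng.uniform(margin_s, duration_s - margin_s)
        if all(abs(c - other) >= MIN_CENTER_SEPARATION_S for other in centers):
            centers.append(c)
        else:
            rejected += 1
    if len(centers) < n_events:
        raise RuntimeError(
            f"generation capacity exceeded: placed {len(centers)}/{n_events} events"
        )
    return np.sort(np.array(centers)), rejected


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate recordings, ground-truth events, and metadata tables.

    Events are embedded additively into per-channel 1/f background at
    jittered times, at least 200 ms apart per channel. Ripple amplitudes are
    drawn at 5-10x the background RMS so that detectability is guaranteed by
    construction. Pathological events are placed on resected channels of
    seizure-free subjects with odds multiplied by ``spec.enrichment``.
    """
    rng = np.random.default_rng(spec.seed)
    subjects = _subject_table(spec, rng)
    channels = _channel_table(spec, subjects, rng)

    recordings: dict[str, Recording] = {}
    events: list[GroundTruthEvent] = []
    n_rejected_total = 0

    n_events_per_channel = int(round(spec.events_per_channel_rate * spec.duration_s / 60.0))
    class_p = np.asarray(spec.class_mix, dtype=float)

    for _, sub in subjects.iterrows():
        sid = str(sub["id"])
        ch_meta = channels[channels["subject"] == sid].reset_index(drop=True)
        names = list(ch_meta["name"])
        data = np.stack(
            [
                render_background(
                    spec.duration_s, spec.fs, spec.noise,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                for _ in names
            ]
        )
        # per-channel placements first, then classes, then (for pathological
        # events of seizure-free subjects) re-draw the channel with enriched
        # odds on resected channels.
        resected_mask = np.asarray(ch_meta["resected"], dtype=bool)
        planned: list[tuple[int, float, str]] = []
        for ci in range(len(names)):
            centers, rejected = _place_centers(n_events_per_channel, spec.duration_s, rng)
            n_rejected_total += rejected
            for c in centers:
                cls = CLASSES[rng.choice(3, p=class_p)]
                planned.append((ci, float(c), cls))

        if bool(sub["engel1"]) and resected_mask.any():
            weights = np.where(resected_mask, spec.enrichment, 1.0)
            if math.isinf(spec.enrichment):
                weights = np.where(resected_mask, 1.0, 0.0)
            weights = weights / weights.sum()
            rerouted = []
            occupied: dict[int, list[float]] = {
                ci: [c for cj, c, _ in planned if cj == ci] for ci in range(len(names))
            }
            for ci, c, cls in planned:
                if cls != "pathological":
                    rerouted.append((ci, c, cls))
                    continue
                new_ci = int(rng.choice(len(names), p=weights))
                if new_ci != ci:
                    others = occupied[new_ci]
                    if all(abs(c - o) >= MIN_CENTER_SEPARATION_S for o in others):
                        occupied[ci].remove(c)
                        occupied[new_ci].append(c)
                        ci = new_ci
                rerouted.append((ci, c, cls))
            planned = rerouted

        background_rms = spec.noise.rms
        for ci, center, cls in planned:
            seed_ev = int(rng.integers(0, 2**31 - 1))
            if cls == "artifact":
                params = {"amplitude": rng.uniform(10, 20) * background_rms}
                ripple_freq = 0.0
                spike_amp = 0.0
                gamma_amp = 0.0
                half_dur = 0.03
            else:
                ripple_freq = rng.uniform(85.0, 150.0)
                dur = rng.uniform(0.04, 0.10)
                params = {
                    "ripple_freq": ripple_freq,
                    "ripple_duration": dur,
                    "ripple_amplitude": rng.uniform(5.0, 10.0) * background_rms,
                }
                spike_amp = 0.0
                gamma_amp = 0.0
                if cls == "pathological":
                    spike_amp = rng.uniform(8.0, 15.0) * background_rms
                    gamma_amp = rng.uniform(3.0, 6.0) * background_rms
                    params["spike_amplitude"] = spike_amp
                    params["gamma_power"] = gamma_amp
                half_dur = dur / 2.0
            wave = render_event(cls, params, spec.fs, seed_ev)
            i0 = int(round(center * spec.fs)) - len(wave) // 2
            i0 = max(0, min(i0, data.shape[1] - len(wave)))
            data[ci, i0 : i0 + len(wave)] += wave
            events.append(
                GroundTruthEvent(
                    subject=sid,
                    channel=names[ci],
                    start_s=center - half_dur,
                    end_s=center + half_dur,
                    true_class=cls,
                    ripple_freq=ripple_freq,
                    spike_amplitude=spike_amp,
                    gamma_power=gamma_amp,
                )
            )
        recordings[sid] = Recording(data=data, fs=spec.fs, ch_names=names)

    events.sort(key=lambda e: (e.subject, e.channel, e.start_s))
    return Cohort(
        recordings=recordings,
        events=events,
        channels=channels,
        subjects=subjects,
        spec=spec,
        n_rejected=n_rejected_total,
    )


def write_cohort(cohort: Cohort, out_dir) -> Path:
    """Write EDFs plus channels.tsv / subjects.tsv / truth_events.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sid, rec in cohort.recordings.items():
        write_edf(rec, out / f"{sid}.edf")
    channels = cohort.channels.copy()
    for col in ("soz", "resected", "bad"):
        channels[col] = channels[col].astype(int)
    channels.to_csv(out / "channels.tsv", sep="\t", index=False)
    subjects = cohort.subjects.copy()
    subjects["engel1"] = subjects["engel1"].astype(int)
    subjects["resected"] = subjects["resected"].astype(int)
    subjects.to_csv(out / "subjects.tsv", sep="\t", index=False)
    truth = cohort.events_frame()
    truth.to_csv(out / "truth_events.tsv", sep="\t", index=False, float_format="%.6f")
    return out
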