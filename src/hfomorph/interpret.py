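"""Interpretability analyses of the learned HFO morphology.

Four tools open up the model: (1) pixel-wise Welch t-tests across subjects
build the cone-shaped time-frequency template of pixels consistently
higher in mpHFOs; (2) per-dimension effect sizes locate the latent
dimension that separates mpHFOs from non-mpHFOs; (3) latent traversal
sweeps that dimension over empirical percentiles, decoding images and
re-running the inference pipeline to read out band power and model
confidence; (4) time-domain perturbation stretches the sub-HFO (10-80 Hz)
band component of the raw signal, testing whether slowed low-frequency
context flips mpHFO predictions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal, stats

from .cluster import HfoClassifier, predict_events
from .features import FeatureConfig, event_tf_image, minmax_normalize

__all__ = [
    "BandDefinitions",
    "TemplateMask",
    "PerturbationSpec",
    "TraversalResult",
    "pixelwise_cone_template",
    "find_pathological_dimension",
    "latent_traversal",
    "stretch_subhfo",
    "perturbation_flip_rate",
]


@dataclass(frozen=True)
class BandDefinitions:
    sub_hfo: tuple[float, float] = (10.0, 80.0)
    gamma: tuple[float, float] = (30.0, 80.0)
    hfo: tuple[float, float] = (80.0, 290.0)
    beta: tuple[float, float] = (10.0, 30.0)


@dataclass
class TemplateMask:
    """Pixels significantly higher in mpHFOs in >50% of subjects."""

    mask: np.ndarray  # (64, 64) boolean
    fraction: np.ndarray  # per-pixel fraction of subjects significant
    alpha: float
    n_subjects: int


@dataclass(frozen=True)
class PerturbationSpec:
    stretch_factor: float = 5.0
    split_freq: float = 80.0

    def __post_init__(self) -> None:
        if self.stretch_factor < 1:
            raise ValueError("stretch factor must be >= 1 (1 is the identity)")


@dataclass
class TraversalResult:
    grid_percentiles: np.ndarray
    grid_values: np.ndarray
    decoded: np.ndarray  # (n_base, n_grid, 64, 64)
    power_above_30: np.ndarray  # (n_base, n_grid) fraction inside template
    beta_power: np.ndarray  # (n_base, n_grid)
    p_mphfo: np.ndarray  # (n_base, n_grid)


def pixelwise_cone_template(
    per_subject_images: dict[str, dict[str, np.ndarray]],
    alpha: float = 0.05,
) -> TemplateMask:
    """Consensus mask of pixels higher in mpHFO images across subjects.

    ``per_subject_images`` maps subject -> {"mpHFO": (n,64,64),
    "non-mpHFO": (m,64,64)}. Per subject and pixel a two-sided Welch t-test
    compares classes; a pixel enters the mask iff it is significantly
    *higher* in mpHFO (p < alpha and positive difference) in more than half
    of the usable subjects. Subjects missing a class (or with fewer than two
    images of one) are excluded. No multiple-comparison correction is
    applied; the cross-subject consensus is the robustness device.
    """
    counts = None
    n_used = 0
    for subject, groups in per_subject_images.items():
        mp = np.asarray(groups.get("mpHFO", np.empty((0, 0, 0))))
        non = np.asarray(groups.get("non-mpHFO", np.empty((0, 0, 0))))
        if len(mp) < 2 or len(non) < 2:
            continue
        t, p = stats.ttest_ind(mp, non, axis=0, equal_var=False)
        sig_higher = (p < alpha) & (t > 0)
        counts = sig_higher.astype(int) if counts is None else counts + sig_higher
        n_used += 1
    if n_used < 2:
        raise ValueError("need >= 2 subjects with both classes for the template")
    fraction = counts / n_used
    return TemplateMask(mask=fraction > 0.5, fraction=fraction, alpha=alpha, n_subjects=n_used)


def find_pathological_dimension(
    latents: np.ndarray, labels
) -> tuple[int, np.ndarray, bool]:
    """Latent dimension best separating mpHFO from non-mpHFO.

    Returns (dimension index, per-dimension Cohen's d, stable flag). d is
    oriented so positive means mpHFO-higher. The argmax of |d| is flagged
    unstable when max |d| < 0.2.
    """
    latents = np.asarray(latents, dtype=float)
    labels = np.asarray(labels)
    mp = latents[labels == "mpHFO"]
    non = latents[labels == "non-mpHFO"]
    if len(mp) == 0 or len(non) == 0:
        raise ValueError("both classes must be present")
    diff = mp.mean(axis=0) - non.mean(axis=0)
    n1, n2 = len(mp), len(non)
    pooled = np.sqrt(
        ((n1 - 1) * mp.var(axis=0, ddof=1) + (n2 - 1) * non.var(axis=0, ddof=1))
        / max(n1 + n2 - 2, 1)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(pooled > 0, diff / pooled, 0.0)
    dim = int(np.argmax(np.abs(d)))
    stable = bool(np.max(np.abs(d)) >= 0.2)
    return dim, d, stable


def _band_rows(freqs_hz: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    return (freqs_hz >= band[0]) & (freqs_hz <= band[1])


def latent_traversal(
    model,
    classifier: HfoClassifier,
    dim: int,
    base_latents: np.ndarray,
    percentiles: np.ndarray | None = None,
    template: TemplateMask | None = None,
    bands: BandDefinitions | None = None,
    freqs_hz: np.ndarray | None = None,
) -> TraversalResult:
    """Sweep one latent dimension over empirical percentiles of its values.

    For every base latent and grid value, the decoded image is scored by
    (a) the fraction of image power above 30 Hz inside the template mask
    (whole image when no template is given), (b) beta-band (10-30 Hz)
    power, and (c) P(mpHFO) of the re-encoded decoded image — the decoded
    image is pushed back through encoder and GMMs, matching deployment.
    """
    bands = bands or BandDefinitions()
    base_latents = np.atleast_2d(np.asarray(base_latents, dtype=float))
    if not 0 <= dim < base_latents.shape[1]:
        raise ValueError(f"latent dimension {dim} out of range")
    if percentiles is None:
        percentiles = np.linspace(5, 95, 7)
    percentiles = np.asarray(percentiles, dtype=float)
    if percentiles.size == 0:
        empty = np.zeros((len(base_latents), 0))
        return TraversalResult(
            grid_percentiles=percentiles,
            grid_values=np.zeros(0),
            decoded=np.zeros((len(base_latents), 0, 64, 64)),
            power_above_30=empty,
            beta_power=empty.copy(),
            p_mphfo=empty.copy(),
        )
    grid_values = np.percentile(base_latents[:, dim], percentiles)
    if freqs_hz is None:
        cfg = FeatureConfig()
        freqs_hz = np.linspace(cfg.freq_range[0], cfg.freqs()[-1], 64)

    n_base, n_grid = len(base_latents), len(grid_values)
    decoded = np.zeros((n_base, n_grid, 64, 64))
    power30 = np.zeros((n_base, n_grid))
    beta_power = np.zeros((n_base, n_grid))
    p_mphfo = np.zeros((n_base, n_grid))

    above30 = freqs_hz >= 30.0
    beta_rows = _band_rows(freqs_hz, bands.beta)
    mask = template.mask if template is not None else np.ones((64, 64), dtype=bool)

    for g, value in enumerate(grid_values):
        z = base_latents.copy()
        z[:, dim] = value
        imgs = model.decode(z)
        decoded[:, g] = imgs
        total = imgs.sum(axis=(1, 2))
        total[total == 0] = 1.0
        sel = mask & above30[:, None]
        power30[:, g] = (imgs * sel).sum(axis=(1, 2)) / total
        beta_power[:, g] = imgs[:, beta_rows, :].sum(axis=(1, 2)) / total
        _, p = predict_events(classifier, minmax_normalize(imgs))
        p_mphfo[:, g] = p

    return TraversalResult(
        grid_percentiles=percentiles,
        grid_values=grid_values,
        decoded=decoded,
        power_above_30=power30,
        beta_power=beta_power,
        p_mphfo=p_mphfo,
    )


def stretch_subhfo(
    segment: np.ndarray,
    fs: float,
    spec: PerturbationSpec,
) -> np.ndarray:
    """Temporally stretch the sub-HFO band component of a signal segment.

    The segment is split at 80 Hz into complementary low and high
    components by a zero-phase low-pass (high = original - low, so the
    split is exactly complementary). The low component is resampled by the
    stretch factor (frequencies divided by the factor) and center-cropped
    to the original length; the output is stretched-low + original-high.
    Factor 1 is the identity.
    """
    if spec.stretch_factor < 1:
        raise ValueError("stretch factor must be >= 1")
    segment = np.asarray(segment, dtype=np.float64)
    # steep split so the >=80 Hz component is conserved to <0.1% relative
    sos = signal.butter(12, spec.split_freq, btype="lowpass", fs=fs, output="sos")
    low = signal.sosfiltfilt(sos, segment)
    high = segment - low
    if spec.stretch_factor == 1:
        return low + high

    frac = Fraction(spec.stretch_factor).limit_denominator(64)
    stretched = signal.resample_poly(low, frac.numerator, frac.denominator)
    n = len(segment)
    center = len(stretched) // 2
    lo = center - n // 2
    crop = stretched[lo : lo + n]
    if len(crop) < n:  # degenerate short segments
        crop = np.pad(crop, (0, n - len(crop)))
    return crop + high


def perturbation_flip_rate(
    classifier: HfoClassifier,
    recordings: dict,
    events,
    factor: float,
    feature_config: FeatureConfig | None = None,
    spec_split_freq: float = 80.0,
) -> tuple[float, np.ndarray]:
    """Fraction of predicted-mpHFO events whose label flips after stretching.

    Every event in ``events`` (rows: subject, channel, start_s, end_s) is
    assumed predicted mpHFO. Each is perturbed by stretching the sub-HFO
    band of a window around its center by ``factor``, re-featurized, and
    re-predicted; the flip rate is the fraction with new label != mpHFO.
    Returns (flip_rate, new_labels).
    """
    if len(events) == 0:
        raise ValueError("no predicted mpHFO events; flip fraction undefined")
    feature_config = feature_config or FeatureConfig()
    spec = PerturbationSpec(stretch_factor=factor, split_freq=spec_split_freq)
    half = feature_config.half_window_s

    new_labels = []
    for _, row in events.iterrows():
        rec = recordings[row["subject"]]
        trace = rec.channel(row["channel"])
        center = 0.5 * (row["start_s"] + row["end_s"])
        fs = rec.fs
        # window comfortably larger than the feature window so the stretch
        # crop cannot clip the analysis region
        pad_s = 2.0 * half + 0.2
        c = int(round(center * fs))
        lo = max(0, c - int(round(pad_s * fs)))
        hi = min(len(trace), c + int(round(pad_s * fs)))
        segment = trace[lo:hi]
        perturbed = stretch_subhfo(segment, fs, spec)
        img = event_tf_image(perturbed, (c - lo) / fs, fs, feature_config)
        labels, _ = predict_events(classifier, img.pixels)
        new_labels.append(labels[0])
    new_labels = np.asarray(new_labels, dtype=object)
    flip_rate = float(np.mean(new_labels != "mpHFO"))
    return flip_rate, new_labels


def embed_2d_shape_check(coords: np.ndarray) -> bool:
    """Visualization-only guard: t-SNE output is (n, 2) and finite."""
    coords = np.asarray(coords)
    return coords.ndim == 2 and coords.shape[1] == 2 and bool(np.isfinite(coords).all())
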