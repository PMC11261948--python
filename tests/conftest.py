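"""Shared fixtures: a small synthetic cohort and a fully trained pipeline.

The end-to-end pipeline (detect -> featurize -> VAE -> two-stage GMM) is
expensive, so it is run once per session at the reference seed and shared
by the cluster, interpret, workflow and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hfomorph.synthetic_data import CohortSpec, generate_cohort
from hfomorph.workflow import analyze_cohort, match_events_to_truth

#: study conditions for the desk-scale cohort used throughout the suite
SMALL_COHORT_KW = dict(
    n_subjects=5,
    channels_per_subject=6,
    duration_s=120.0,
    events_per_channel_rate=4.0,
)


def make_cohort(seed: int, **overrides):
    kw = {**SMALL_COHORT_KW, **overrides}
    return generate_cohort(CohortSpec(seed=seed, **kw))


def run_end_to_end(seed: int, **overrides):
    cohort = make_cohort(seed, **overrides)
    result = analyze_cohort(cohort, seed=seed)
    return cohort, result


def matched_predictions(cohort, result) -> pd.DataFrame:
    """All ground-truth events with predicted labels; "missed" when undetected."""
    truth = cohort.events_frame()
    matched = match_events_to_truth(result.events, truth)
    idx = matched["detected_index"].to_numpy()
    pred = np.where(idx >= 0, result.labels[np.maximum(idx, 0)], "missed")
    matched["pred"] = pred
    return matched


def class_metrics(matched: pd.DataFrame) -> tuple[float, float]:
    """(pathological-vs-physiological balanced accuracy, artifact recall).

    Computed over ground-truth events recovered by the detectors; detection
    recall itself is asserted separately.
    """
    hit = matched[matched.pred != "missed"]
    tp = ((hit.true_class == "pathological") & (hit.pred == "mpHFO")).sum()
    fn = ((hit.true_class == "pathological") & (hit.pred != "mpHFO")).sum()
    tn = ((hit.true_class == "physiological") & (hit.pred == "non-mpHFO")).sum()
    fp = ((hit.true_class == "physiological") & (hit.pred != "non-mpHFO")).sum()
    balanced = 0.5 * (tp / max(tp + fn, 1) + tn / max(tn + fp, 1))
    art = hit[hit.true_class == "artifact"]
    recall = float((art.pred == "mArtifact").mean()) if len(art) else np.nan
    return float(balanced), recall


@pytest.fixture(scope="session")
def cohort0():
    return make_cohort(0)


@pytest.fixture(scope="session")
def pipeline0(cohort0):
    return analyze_cohort(cohort0, seed=0)


@pytest.fixture(scope="session")
def matched0(cohort0, pipeline0) -> pd.DataFrame:
    return matched_predictions(cohort0, pipeline0)


def brute_force_em(x: np.ndarray, k: int, seed: int, n_iter: int = 200):
    """Independent full-covariance EM oracle for tiny GMM instances.

    Deliberately naive: explicit E/M loops over responsibilities, random
    mean initialization. Used only to cross-check clustering assignments.
    """
    from scipy.stats import multivariate_normal

    rng = np.random.default_rng(seed)
    n, d = x.shape
    # farthest-point initialization: first mean random, next means maximize
    # distance to those already chosen (keeps the oracle deterministic-ish
    # and immune to collapsing both means into one blob)
    chosen = [int(rng.integers(n))]
    while len(chosen) < k:
        dists = np.min(
            [np.linalg.norm(x - x[c], axis=1) for c in chosen], axis=0
        )
        chosen.append(int(np.argmax(dists)))
    means = x[chosen].copy()
    # hard nearest-mean partition seeds per-component covariances at the
    # within-cluster scale (the pooled covariance is dominated by the
    # between-cluster direction and flattens the responsibilities)
    nearest = np.argmin(
        [np.linalg.norm(x - m, axis=1) for m in means], axis=0
    )
    covs = []
    for j in range(k):
        members = x[nearest == j]
        covs.append(np.cov(members.T) + 1e-6 * np.eye(d))
    weights = np.full(k, 1.0 / k)
    resp = np.zeros((n, k))
    for _ in range(n_iter):
        for j in range(k):
            resp[:, j] = weights[j] * multivariate_normal.pdf(
                x, means[j], covs[j], allow_singular=True
            )
        resp /= resp.sum(axis=1, keepdims=True)
        nk = resp.sum(axis=0)
        weights = nk / n
        means = (resp.T @ x) / nk[:, None]
        for j in range(k):
            diff = x - means[j]
            covs[j] = (resp[:, j, None] * diff).T @ diff / nk[j] + 1e-6 * np.eye(d)
    return resp.argmax(axis=1)


def blob_images(n: int, band: tuple[int, int], seed: int) -> np.ndarray:
    """Synthetic 64x64 images with energy confined to a row band, in [0, 1]."""
    rng = np.random.default_rng(seed)
    images = np.zeros((n, 64, 64))
    rows = np.arange(64)
    for i in range(n):
        center = rng.uniform(*band)
        width = rng.uniform(3, 6)
        profile = np.exp(-0.5 * ((rows - center) / width) ** 2)
        cols = np.exp(-0.5 * ((np.arange(64) - rng.uniform(24, 40)) / rng.uniform(6, 12)) ** 2)
        images[i] = np.outer(profile, cols)
        images[i] += 0.05 * rng.random((64, 64))
        images[i] /= images[i].max()
    return images
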