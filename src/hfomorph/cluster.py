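"""Two-stage Gaussian-mixture discovery of HFO morphology classes.

Stage 1 clusters latent codes augmented with a standardized
log-reconstruction-error feature, with k=2, and labels as artifacts
(mArtifact) the cluster whose events have the higher mean reconstruction
error — the VAE reconstructs the diverse morphologies of artifacts poorly,
so both the codes and the error carry the artifact signature. Stage 2
clusters the remaining events with a second k=2 GMM; the minimal clinical
labeling rule deems pathological (mpHFO) the cluster with the higher
fraction of events on resected channels of seizure-free subjects. The
inference pipeline encodes new events and routes them through both GMMs,
yielding a class label and P(mpHFO).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .vae import TrainedVae

__all__ = [
    "ClusterConfig",
    "HfoClassifier",
    "LabelingError",
    "fit_stage1",
    "fit_stage2",
    "assign_pathology_labels",
    "predict_events",
    "predict_latents",
    "fit_classifier",
]

LABELS = ("mpHFO", "non-mpHFO", "mArtifact")


class LabelingError(RuntimeError):
    """Raised when the clinical labeling rule cannot be applied."""


@dataclass(frozen=True)
class ClusterConfig:
    stage1_k: int = 2
    stage1_cap: int = 10_000
    stage2_k: int = 2
    stage2_cap: int = 2_000
    covariance: str = "full"
    n_init: int = 5
    reg_covar: float = 1e-6
    err_weight: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stage1_k < 2 or self.stage2_k < 2:
            raise ValueError("cluster counts must be >= 2")
        if self.stage1_cap < 1 or self.stage2_cap < 1:
            raise ValueError("caps must be >= 1")


@dataclass
class HfoClassifier:
    """Trained VAE plus both fitted GMMs and the cluster -> label map.

    ``err_mean``/``err_std`` standardize the log reconstruction error into
    the stage-1 feature space; they are fixed at fit time.
    """

    vae: TrainedVae
    stage1_gmm: GaussianMixture
    artifact_cluster: int
    stage2_gmm: GaussianMixture
    pathological_cluster: int | None = None
    err_mean: float = 0.0
    err_std: float = 1.0
    err_weight: float = 3.0
    seed: int = 0

    @property
    def labeled(self) -> bool:
        return self.pathological_cluster is not None


def error_feature_stats(recon_errors: np.ndarray) -> tuple[float, float]:
    """Mean/SD of log reconstruction error, for the stage-1 feature."""
    log_err = np.log(np.asarray(recon_errors, dtype=float) + 1e-12)
    return float(log_err.mean()), float(log_err.std() or 1.0)


def augment_with_error(
    latents: np.ndarray,
    recon_errors: np.ndarray,
    stats: tuple[float, float],
    weight: float = 3.0,
) -> np.ndarray:
    """Latents with a weighted standardized log-error column appended.

    The weight makes reconstruction quality a dominant axis of the stage-1
    space, so the k=2 split separates poorly-reconstructed (artifact-like)
    events from well-modeled HFOs rather than cutting along whichever
    morphology axis happens to carry the most variance.
    """
    mean, std = stats
    feat = (np.log(np.asarray(recon_errors, dtype=float) + 1e-12) - mean) / std
    return np.column_stack([np.asarray(latents, dtype=float), weight * feat])


def _stratified_cap(subject_ids: np.ndarray, cap: int, rng: np.random.Generator) -> np.ndarray:
    """Indices keeping at most ``cap`` events per subject."""
    keep: list[np.ndarray] = []
    for s in sorted(set(subject_ids)):
        idx = np.flatnonzero(subject_ids == s)
        if len(idx) > cap:
            idx = rng.choice(idx, size=cap, replace=False)
        keep.append(np.sort(idx))
    return np.concatenate(keep) if keep else np.array([], dtype=int)


def _fit_gmm(latents: np.ndarray, k: int, config: ClusterConfig) -> GaussianMixture:
    if len(latents) < k:
        raise ValueError(f"need at least {k} events to fit a {k}-component GMM")
    gmm = GaussianMixture(
        n_components=k,
        covariance_type=config.covariance,
        n_init=config.n_init,
        init_params="kmeans",
        reg_covar=config.reg_covar,
        random_state=config.seed,
    )
    gmm.fit(latents)
    return gmm


def fit_stage1(
    latents: np.ndarray,
    recon_errors: np.ndarray,
    subject_ids,
    config: ClusterConfig | None = None,
) -> tuple[GaussianMixture, int]:
    """Fit the artifact-separation GMM and identify the artifact cluster.

    The artifact cluster is the one whose assigned events have the higher
    mean reconstruction error; exact ties break to the lower cluster index
    with a warning.
    """
    config = config or ClusterConfig()
    latents = np.asarray(latents, dtype=float)
    recon_errors = np.asarray(recon_errors, dtype=float)
    subject_ids = np.asarray([str(s) for s in subject_ids])
    rng = np.random.default_rng(config.seed)
    keep = _stratified_cap(subject_ids, config.stage1_cap, rng)
    features = augment_with_error(
        latents, recon_errors, error_feature_stats(recon_errors), config.err_weight
    )
    gmm = _fit_gmm(features[keep], config.stage1_k, config)

    assign = gmm.predict(features)
    mean_err = np.array(
        [
            recon_errors[assign == c].mean() if (assign == c).any() else -np.inf
            for c in range(config.stage1_k)
        ]
    )
    top = np.flatnonzero(mean_err == mean_err.max())
    if len(top) > 1:
        warnings.warn("stage-1 mean reconstruction errors tie; lower cluster index chosen")
    return gmm, int(top[0])


def fit_stage2(
    non_artifact_latents: np.ndarray,
    subject_ids,
    config: ClusterConfig | None = None,
) -> GaussianMixture:
    """Fit the pathological/physiological GMM on non-artifact latents."""
    config = config or ClusterConfig()
    latents = np.asarray(non_artifact_latents, dtype=float)
    subject_ids = np.asarray([str(s) for s in subject_ids])
    rng = np.random.default_rng(config.seed + 1)
    keep = _stratified_cap(subject_ids, config.stage2_cap, rng)
    return _fit_gmm(latents[keep], config.stage2_k, config)


def assign_pathology_labels(
    stage2_assignments: np.ndarray,
    events: pd.DataFrame,
    channel_metadata: pd.DataFrame,
    subject_metadata: pd.DataFrame,
) -> int:
    """Clinical labeling rule: the mpHFO cluster has the higher resected
    fraction among seizure-free resected subjects.

    ``events`` rows (subject, channel) must align with ``stage2_assignments``.
    Raises :class:`LabelingError` when no qualifying subject exists or the
    resected fractions tie exactly (manual override required).
    """
    assignments = np.asarray(stage2_assignments)
    if len(assignments) != len(events):
        raise ValueError("one assignment per event required")

    subs = subject_metadata.set_index("id")
    resected_col = subs["resected"] if "resected" in subs.columns else pd.Series(True, index=subs.index)
    qualifying = {
        sid
        for sid in subs.index
        if bool(subs.loc[sid, "engel1"]) and bool(resected_col.loc[sid])
    }
    if not qualifying:
        raise LabelingError("no seizure-free resected subjects; clusters left unlabeled")

    ch = channel_metadata.copy()
    if "subject" in ch.columns:
        resected_map = {(r["subject"], r["name"]): bool(r["resected"]) for _, r in ch.iterrows()}
        key = lambda row: (row["subject"], row["channel"])
    else:
        resected_map = {r["name"]: bool(r["resected"]) for _, r in ch.iterrows()}
        key = lambda row: row["channel"]

    clusters = sorted(set(assignments.tolist()))
    fractions = {}
    for c in clusters:
        n_total = 0
        n_resected = 0
        for (_, row), a in zip(events.iterrows(), assignments):
            if a != c or row["subject"] not in qualifying:
                continue
            n_total += 1
            n_resected += int(resected_map.get(key(row), False))
        fractions[c] = n_resected / n_total if n_total else np.nan
    valid = {c: f for c, f in fractions.items() if np.isfinite(f)}
    if len(valid) < 2:
        raise LabelingError(
            "labeling rule needs events from qualifying subjects in both clusters"
        )
    values = sorted(valid.values())
    if values[-1] == values[-2]:
        raise LabelingError(
            "resected fractions tie exactly; manual override required"
        )
    return int(max(valid, key=valid.get))


def predict_latents(classifier: HfoClassifier, latents: np.ndarray,
                    recon_errors: np.ndarray | None = None):
    """Route latent codes through both GMMs -> (labels, P_mpHFO).

    Events most responsible to the stage-1 artifact cluster become
    mArtifact with P_mpHFO = 0; otherwise the stage-2 posterior of the
    pathological cluster is P_mpHFO and the argmax cluster gives the label.
    ``recon_errors`` completes the stage-1 feature space; use
    :func:`predict_events` to compute them from images automatically.
    """
    if not classifier.labeled:
        raise LabelingError("classifier has unlabeled clusters")
    latents = np.atleast_2d(np.asarray(latents, dtype=float))
    if recon_errors is None:
        raise ValueError("recon_errors required (stage 1 clusters on codes + error)")
    features = augment_with_error(
        latents,
        np.atleast_1d(recon_errors),
        (classifier.err_mean, classifier.err_std),
        classifier.err_weight,
    )
    stage1_post = classifier.stage1_gmm.predict_proba(features)
    is_artifact = stage1_post.argmax(axis=1) == classifier.artifact_cluster

    labels = np.empty(len(latents), dtype=object)
    p_mphfo = np.zeros(len(latents))
    labels[is_artifact] = "mArtifact"
    rest = ~is_artifact
    if rest.any():
        stage2_post = classifier.stage2_gmm.predict_proba(latents[rest])
        p_path = stage2_post[:, classifier.pathological_cluster]
        argmax = stage2_post.argmax(axis=1)
        sub_labels = np.where(argmax == classifier.pathological_cluster, "mpHFO", "non-mpHFO")
        labels[rest] = sub_labels
        p_mphfo[rest] = p_path
    return labels, p_mphfo


def predict_events(classifier: HfoClassifier, images: np.ndarray):
    """Inference pipeline: encode images, then classify latents."""
    from .vae import reconstruction_error

    images = np.asarray(images, dtype=float)
    if images.ndim == 2:
        images = images[np.newaxis]
    mu, _ = classifier.vae.encode(images)
    errors = reconstruction_error(classifier.vae, images)
    return predict_latents(classifier, mu, np.atleast_1d(errors))


def fit_classifier(
    vae: TrainedVae,
    images: np.ndarray,
    events: pd.DataFrame,
    channel_metadata: pd.DataFrame,
    subject_metadata: pd.DataFrame,
    config: ClusterConfig | None = None,
) -> HfoClassifier:
    """Fit both stages and apply the labeling rule; the standard train path."""
    from .vae import reconstruction_error

    config = config or ClusterConfig()
    mu, _ = vae.encode(images)
    errors = reconstruction_error(vae, images)
    subject_ids = events["subject"].to_numpy()

    gmm1, artifact_id = fit_stage1(mu, errors, subject_ids, config)
    assign1 = gmm1.predict(
        augment_with_error(mu, errors, error_feature_stats(errors), config.err_weight)
    )
    non_art = assign1 != artifact_id
    if non_art.sum() < config.stage2_k:
        raise ValueError("too few non-artifact events for stage-2 clustering")
    gmm2 = fit_stage2(mu[non_art], subject_ids[non_art], config)

    assign2 = gmm2.predict(mu[non_art])
    path_id = assign_pathology_labels(
        assign2, events.loc[non_art].reset_index(drop=True), channel_metadata, subject_metadata
    )
    err_mean, err_std = error_feature_stats(errors)
    return HfoClassifier(
        vae=vae,
        stage1_gmm=gmm1,
        artifact_cluster=artifact_id,
        stage2_gmm=gmm2,
        pathological_cluster=path_id,
        err_mean=err_mean,
        err_std=err_std,
        err_weight=config.err_weight,
        seed=config.seed,
    )
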