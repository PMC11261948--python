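"""Config-driven orchestration of the full analysis pipeline.

The stage order mirrors the study flow: preprocess -> detect -> featurize
-> train VAE -> two-stage clustering with the clinical labeling rule ->
prediction -> outcome models. :func:`analyze_cohort` runs the chain
in memory (the workhorse for synthetic experiments); :func:`run_pipeline`
is the file-based, resumable variant driven by a :class:`RunConfig`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .cluster import ClusterConfig, HfoClassifier, fit_classifier, predict_events
from .detect import detect_recording
from .features import FeatureConfig, events_to_images
from .preprocess import PreprocConfig, apply_montage, select_channels, standardize
from .vae import VaeConfig, train_vae

__all__ = [
    "RunConfig",
    "PipelineResult",
    "analyze_cohort",
    "run_pipeline",
    "match_events_to_truth",
]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    data_dir: str
    out_dir: str
    seed: int = 0
    stages: dict = field(default_factory=lambda: {
        "preprocess": True,
        "detect": True,
        "featurize": True,
        "train": True,
        "cluster": True,
        "outcome": True,
    })
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    vae: VaeConfig = field(default_factory=VaeConfig.small)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        kwargs = dict(data_dir=raw["data_dir"], out_dir=raw["out_dir"])
        kwargs["seed"] = int(raw.get("seed", 0))
        if "stages" in raw:
            kwargs["stages"] = dict(raw["stages"])
        if "vae" in raw:
            kwargs["vae"] = VaeConfig(**raw["vae"])
        if "cluster" in raw:
            kwargs["cluster"] = ClusterConfig(**raw["cluster"])
        return RunConfig(**kwargs)


@dataclass
class PipelineResult:
    recordings: dict
    events: pd.DataFrame
    images: np.ndarray
    classifier: HfoClassifier
    labels: np.ndarray
    p_mphfo: np.ndarray
    report: dict


def preprocess_recording(rec, channel_meta, config: PreprocConfig | None = None):
    """select bad channels out -> montage -> resample + notch."""
    config = config or PreprocConfig()
    rec = select_channels(rec, channel_meta)
    rec = apply_montage(rec, channel_meta)
    return standardize(rec, config)


def analyze_cohort(
    cohort,
    vae_config: VaeConfig | None = None,
    cluster_config: ClusterConfig | None = None,
    feature_config: FeatureConfig | None = None,
    seed: int = 0,
    preprocess: bool = True,
) -> PipelineResult:
    """Run the full in-memory pipeline on a synthetic or loaded cohort."""
    vae_config = vae_config or VaeConfig.small()
    cluster_config = cluster_config or ClusterConfig(seed=seed)
    feature_config = feature_config or FeatureConfig()

    recordings = {}
    event_frames = []
    for sid, rec in cohort.recordings.items():
        meta = cohort.channels[cohort.channels["subject"] == sid]
        rec_pp = preprocess_recording(rec, meta) if preprocess else rec
        recordings[sid] = rec_pp
        events = detect_recording(rec_pp, subject=sid)
        event_frames.append(events)
        logger.info("subject %s: %d merged events", sid, len(events))
    events = pd.concat(event_frames, ignore_index=True)

    images_list = [
        events_to_images(recordings[sid], grp, feature_config)
        for sid, grp in events.groupby("subject", sort=False)
    ]
    images = np.concatenate([im for im in images_list if len(im)], axis=0)
    # groupby(sort=False) preserves first-appearance order matching events
    sites = dict(zip(cohort.subjects["id"], cohort.subjects["site"]))
    model = train_vae(
        images,
        events["subject"].to_numpy(),
        vae_config,
        seed=seed,
        sites=sites,
    )
    classifier = fit_classifier(
        model, images, events, cohort.channels, cohort.subjects, cluster_config
    )
    labels, p_mphfo = predict_events(classifier, images)

    report = {
        "n_subjects": len(cohort.recordings),
        "n_events": int(len(events)),
        "n_images": int(len(images)),
        "best_epoch": int(model.history.get("best_epoch", -1)),
        "label_counts": {
            label: int((labels == label).sum()) for label in sorted(set(labels.tolist()))
        },
    }
    return PipelineResult(
        recordings=recordings,
        events=events,
        images=images,
        classifier=classifier,
        labels=labels,
        p_mphfo=p_mphfo,
        report=report,
    )


def match_events_to_truth(
    detected: pd.DataFrame, truth: pd.DataFrame
) -> pd.DataFrame:
    """Match detections to ground-truth events by interval overlap.

    Returns the truth table with ``detected_index`` (-1 when missed): for
    each truth event, the detection on the same subject/channel with the
    largest overlap of half-open intervals.
    """
    out = truth.copy().reset_index(drop=True)
    out["detected_index"] = -1
    for i, t in out.iterrows():
        cand = detected[
            (detected["subject"] == t["subject"]) & (detected["channel"] == t["channel"])
        ]
        best, best_overlap = -1, 0.0
        for j, d in cand.iterrows():
            overlap = min(t["end_s"], d["end_s"]) - max(t["start_s"], d["start_s"])
            if overlap > best_overlap:
                best, best_overlap = j, overlap
        out.loc[i, "detected_index"] = best
    return out


# ---------------------------------------------------------------------------
# file-based, resumable runner
# ---------------------------------------------------------------------------

def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"stage {stage!r}: missing artifact {path}")
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute enabled stages in order, writing artifacts and a JSON report.

    Disabled stages must find their artifact on disk from a previous run;
    otherwise a missing-artifact error names the file. Deterministic given
    the config seed.
    """
    data = Path(config.data_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}

    channels = hio.read_channel_metadata(_require(data / "channels.tsv", "input"))
    subjects = hio.read_subject_metadata(_require(data / "subjects.tsv", "input"))
    subject_ids = list(subjects["id"])

    # preprocess ---------------------------------------------------------
    pp_dir = out / "preprocessed"
    if config.stages.get("preprocess", True):
        pp_dir.mkdir(exist_ok=True)
        for sid in subject_ids:
            rec = hio.read_recording(_require(data / f"{sid}.edf", "preprocess"))
            meta = channels[channels["subject"] == sid]
            rec_pp = preprocess_recording(rec, meta, config.preproc)
            hio.write_edf(rec_pp, pp_dir / f"{sid}.edf")
        report["stages"]["preprocess"] = {"n_subjects": len(subject_ids)}

    def _load_pp(sid: str):
        return hio.read_recording(_require(pp_dir / f"{sid}.edf", "preprocess"))

    # detect -------------------------------------------------------------
    events_path = out / "events.tsv"
    if config.stages.get("detect", True):
        frames = [detect_recording(_load_pp(sid), subject=sid) for sid in subject_ids]
        events = pd.concat(frames, ignore_index=True)
        hio.write_event_table(events, events_path)
        report["stages"]["detect"] = {"n_events": int(len(events))}
    events = hio.read_event_table(_require(events_path, "detect"))

    # featurize ----------------------------------------------------------
    images_path = out / "images.h5"
    if config.stages.get("featurize", True):
        image_blocks = []
        index_rows = []
        for sid, grp in events.groupby("subject", sort=False):
            rec = _load_pp(sid)
            image_blocks.append(events_to_images(rec, grp, config.features))
            for _, row in grp.iterrows():
                index_rows.append(
                    {
                        "subject": sid,
                        "channel": row["channel"],
                        "center_s": 0.5 * (row["start_s"] + row["end_s"]),
                    }
                )
        images = np.concatenate([b for b in image_blocks if len(b)], axis=0)
        hio.write_image_store(images_path, images, pd.DataFrame(index_rows))
        report["stages"]["featurize"] = {"n_images": int(len(images))}
    images, image_index = hio.read_image_store(_require(images_path, "featurize"))

    # train + cluster ----------------------------------------------------
    bundle_path = out / "classifier.h5"
    if config.stages.get("train", True) or config.stages.get("cluster", True):
        if config.stages.get("train", True):
            sites = dict(zip(subjects["id"], subjects["site"]))
            model = train_vae(
                images,
                image_index["subject"].to_numpy(),
                config.vae,
                seed=config.seed,
                sites=sites,
            )
            report["stages"]["train"] = {
                "best_epoch": int(model.history["best_epoch"]),
                "val_loss": model.history["val_loss"][int(model.history["best_epoch"])],
            }
        else:
            model = hio.load_bundle(_require(bundle_path, "train")).vae
        if config.stages.get("cluster", True):
            classifier = fit_classifier(
                model, images, events, channels, subjects,
                ClusterConfig(seed=config.seed),
            )
            hio.save_bundle(classifier, bundle_path)
            report["stages"]["cluster"] = {
                "artifact_cluster": classifier.artifact_cluster,
                "pathological_cluster": classifier.pathological_cluster,
            }
    classifier = hio.load_bundle(_require(bundle_path, "cluster"))

    # predict + outcome --------------------------------------------------
    labels_path = out / "labels.tsv"
    labels, p_mphfo = predict_events(classifier, images)
    labeled = events.copy()
    labeled["label"] = labels
    labeled["p_mphfo"] = p_mphfo
    labeled.to_csv(labels_path, sep="\t", index=False)
    report["stages"]["predict"] = {
        label: int((labels == label).sum()) for label in sorted(set(labels.tolist()))
    }

    if config.stages.get("outcome", True):
        from .outcome import cohort_summary

        summary = cohort_summary(subjects)
        summary.to_csv(out / "cohort_summary.tsv", sep="\t", index=False)
        report["stages"]["outcome"] = {"n_sites": int(len(summary)) - 1}

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
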