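"""Two-stage GMM discovery, the clinical labeling rule, and inference."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from conftest import brute_force_em
from hfomorph.cluster import (
    ClusterConfig,
    LabelingError,
    assign_pathology_labels,
    fit_stage1,
    fit_stage2,
    predict_latents,
    predict_events,
)


def two_blobs(n_per=60, seed=0, sep=8.0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 0.5, (n_per, 8))
    b = rng.normal(0.0, 0.5, (n_per, 8))
    b[:, 0] += sep
    return np.concatenate([a, b]), np.array([0] * n_per + [1] * n_per)


class TestStage1:
    def test_high_error_blob_is_artifact(self):
        latents, blob = two_blobs(seed=1)
        errors = np.where(blob == 1, 10.0, 1.0)
        subjects = ["s0"] * len(latents)
        gmm, artifact_id = fit_stage1(latents, errors, subjects, ClusterConfig(seed=0))
        from hfomorph.cluster import augment_with_error, error_feature_stats

        assign = gmm.predict(
            augment_with_error(latents, errors, error_feature_stats(errors))
        )
        # the artifact cluster must be the one holding blob B
        b_cluster = np.bincount(assign[blob == 1]).argmax()
        assert artifact_id == b_cluster

    def test_equal_errors_tie_break_warns(self):
        latents, _ = two_blobs(seed=2)
        errors = np.ones(len(latents))
        with pytest.warns(UserWarning, match="tie"):
            _, artifact_id = fit_stage1(latents, errors, ["s"] * len(latents),
                                        ClusterConfig(seed=0))
        assert artifact_id == 0

    def test_stratified_cap_limits_contributions(self):
        from hfomorph.cluster import _stratified_cap

        subjects = np.repeat([f"s{i}" for i in range(100)], 5)
        rng = np.random.default_rng(0)
        keep = _stratified_cap(subjects, cap=1, rng=rng)
        assert len(keep) == 100
        assert len(set(subjects[keep])) == 100

    def test_too_few_events(self):
        with pytest.raises(ValueError):
            fit_stage1(np.zeros((1, 8)), np.zeros(1), ["s"], ClusterConfig(seed=0))


class TestStage2:
    def test_matches_brute_force_em_oracle(self):
        """sklearn-backed fit vs an independent naive EM: ARI = 1 on blobs."""
        latents, blob = two_blobs(n_per=80, seed=3)
        gmm = fit_stage2(latents, ["s"] * len(latents), ClusterConfig(seed=0))
        assign = gmm.predict(latents)
        oracle = brute_force_em(latents, k=2, seed=0)
        assert adjusted_rand_score(assign, oracle) == 1.0
        assert adjusted_rand_score(assign, blob) == 1.0

    def test_single_blob_soft_posteriors(self):
        rng = np.random.default_rng(4)
        latents = rng.normal(0, 1, (200, 8))
        gmm = fit_stage2(latents, ["s"] * 200, ClusterConfig(seed=0))
        post = gmm.predict_proba(latents)
        np.testing.assert_allclose(post.sum(axis=1), 1.0)

    def test_duplicated_points_regularized(self):
        latents = np.tile(np.arange(8.0), (50, 1))
        latents[25:, 0] += 5.0
        gmm = fit_stage2(latents, ["s"] * 50, ClusterConfig(seed=0))
        assert np.isfinite(gmm.means_).all()


def _label_fixture(frac_a: float, frac_b: float):
    """Events of two clusters with controlled resected fractions."""
    n = 20
    events, assignments = [], []
    resected_flags = {}
    for cluster, frac in ((0, frac_a), (1, frac_b)):
        for i in range(n):
            ch = f"c{cluster}_{i}"
            events.append({"subject": "s0", "channel": ch, "start_s": i, "end_s": i + 0.1})
            assignments.append(cluster)
            resected_flags[ch] = i < frac * n
    channels = pd.DataFrame(
        {
            "subject": "s0",
            "name": list(resected_flags),
            "type": "grid",
            "soz": False,
            "resected": list(resected_flags.values()),
            "bad": False,
        }
    )
    subjects = pd.DataFrame(
        {"id": ["s0"], "site": ["A"], "sex": ["F"], "age": [10],
         "pathology": ["FCD"], "resected": [True], "engel1": [True]}
    )
    return np.array(assignments), pd.DataFrame(events), channels, subjects


class TestLabelingRule:
    def test_higher_resected_fraction_wins(self):
        assignments, events, channels, subjects = _label_fixture(0.8, 0.2)
        assert assign_pathology_labels(assignments, events, channels, subjects) == 0

    def test_exact_tie_raises(self):
        assignments, events, channels, subjects = _label_fixture(0.5, 0.5)
        with pytest.raises(LabelingError, match="tie"):
            assign_pathology_labels(assignments, events, channels, subjects)

    def test_no_qualifying_subjects(self):
        assignments, events, channels, subjects = _label_fixture(0.8, 0.2)
        subjects["engel1"] = False
        with pytest.raises(LabelingError, match="seizure-free"):
            assign_pathology_labels(assignments, events, channels, subjects)


class TestPredict:
    def test_pathological_mean_predicts_mphfo(self, pipeline0):
        clf = pipeline0.classifier
        z = clf.stage2_gmm.means_[clf.pathological_cluster]
        typical_err = np.exp(clf.err_mean - clf.err_std)  # clearly non-artifact
        labels, p = predict_latents(clf, z[np.newaxis], np.array([typical_err]))
        assert labels[0] == "mpHFO"
        assert p[0] > 0.5

    def test_probability_bounds_and_normalization(self, pipeline0):
        labels, p = predict_events(pipeline0.classifier, pipeline0.images[:50])
        assert ((p >= 0) & (p <= 1)).all()
        mu, _ = pipeline0.classifier.vae.encode(pipeline0.images[:50])
        post = pipeline0.classifier.stage2_gmm.predict_proba(mu)
        np.testing.assert_allclose(post.sum(axis=1), 1.0)

    def test_label_map_invariant_to_component_permutation(self, pipeline0):
        """Swapping GMM component order (and the id map) leaves labels fixed."""
        from sklearn.mixture import GaussianMixture

        clf = pipeline0.classifier
        g = clf.stage2_gmm
        swapped = GaussianMixture(n_components=2, covariance_type=g.covariance_type)
        swapped.weights_ = g.weights_[::-1].copy()
        swapped.means_ = g.means_[::-1].copy()
        swapped.covariances_ = g.covariances_[::-1].copy()
        swapped.precisions_cholesky_ = g.precisions_cholesky_[::-1].copy()
        clf2 = dataclasses.replace(
            clf, stage2_gmm=swapped, pathological_cluster=1 - clf.pathological_cluster
        )
        l1, p1 = predict_events(clf, pipeline0.images[:40])
        l2, p2 = predict_events(clf2, pipeline0.images[:40])
        assert (l1 == l2).all()
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_unlabeled_classifier_rejected(self, pipeline0):
        clf = dataclasses.replace(pipeline0.classifier, pathological_cluster=None)
        with pytest.raises(LabelingError):
            predict_events(clf, pipeline0.images[:2])
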