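"""Resection ratios, event rates, permutation tests, outcome models."""

import numpy as np
import pandas as pd
import pytest

from hfomorph.detect import merge_events
from hfomorph.outcome import (
    CvSpec,
    assign_folds,
    cohort_summary,
    covariate_separability,
    embed_2d,
    event_rates,
    outcome_models,
    resection_ratio,
)


def _channels(resected_names, all_names, subject="s0"):
    return pd.DataFrame(
        {
            "subject": subject,
            "name": all_names,
            "type": "grid",
            "soz": False,
            "resected": [n in resected_names for n in all_names],
            "bad": False,
        }
    )


def _events(channel_list, subject="s0"):
    return pd.DataFrame(
        {
            "subject": subject,
            "channel": channel_list,
            "start_s": np.arange(len(channel_list), dtype=float),
            "end_s": np.arange(len(channel_list), dtype=float) + 0.1,
            "detector": "merged",
            "tags": "",
        }
    )


class TestResectionRatio:
    def test_basic_fraction(self):
        ev = _events(["a"] * 4 + ["b"] * 6)
        ch = _channels({"a"}, ["a", "b"])
        assert resection_ratio(ev, ch, "s0") == pytest.approx(0.4)

    def test_all_resected(self):
        ev = _events(["a", "b", "a"])
        ch = _channels({"a", "b"}, ["a", "b"])
        assert resection_ratio(ev, ch, "s0") == 1.0

    def test_duplicates_counted_once_after_merge(self):
        ste = _events(["a"])
        mni = _events(["a"])
        mni["start_s"] += 0.05  # overlapping duplicate of the same burst
        merged = merge_events(ste, mni)
        assert len(merged) == 1
        ch = _channels({"a"}, ["a", "b"])
        assert resection_ratio(merged, ch, "s0") == 1.0

    def test_zero_events_rejected(self):
        ch = _channels({"a"}, ["a"])
        with pytest.raises(ValueError, match="no events"):
            resection_ratio(_events([]), ch, "s0")

    def test_subset_monotonicity(self):
        """Adding a resected-channel event never decreases the ratio."""
        ch = _channels({"a"}, ["a", "b"])
        rng = np.random.default_rng(0)
        chans = list(rng.choice(["a", "b"], 10))
        before = resection_ratio(_events(chans), ch, "s0")
        after = resection_ratio(_events(chans + ["a"]), ch, "s0")
        assert after >= before


class TestEventRates:
    def test_counts_per_minute(self):
        ev = _events(["a"] * 30)
        ch = _channels(set(), ["a", "b"])
        rates, _ = event_rates(ev, ["mpHFO"] * 30, ch, duration_min=10.0)
        assert rates.set_index("channel").loc["a", "rate_mpHFO"] == 3.0

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            event_rates(_events(["a"]), ["mpHFO"], _channels(set(), ["a"]), 0.0)

    def test_zero_events_warns(self):
        with pytest.warns(UserWarning, match="no events"):
            _, comp = event_rates(_events([]), [], _channels(set(), ["a"]), 10.0)
        assert comp == {}

    def test_enriched_cohort_soz_rate_higher(self):
        """With enrichment > 1, pathological SOZ rates beat non-SOZ (t-test)."""
        from conftest import make_cohort

        cohort = make_cohort(42, n_subjects=10, channels_per_subject=6, duration_s=120.0)
        truth = cohort.events_frame()
        labels = truth["true_class"].map(
            {"pathological": "mpHFO", "physiological": "non-mpHFO", "artifact": "mArtifact"}
        ).to_numpy()
        assert len(cohort.channels) >= 40
        _, comp = event_rates(truth, labels, cohort.channels, duration_min=2.0)
        assert comp["mpHFO"]["soz_mean"] > comp["mpHFO"]["non_soz_mean"]
        assert comp["mpHFO"]["p"] < 0.05


class TestCovariateSeparability:
    def test_constructed_signal_detected(self):
        rng = np.random.default_rng(0)
        latents = rng.standard_normal((300, 8))
        labels = np.where(latents[:, 0] > 0, "A", "B")
        real, permuted, p = covariate_separability(latents, labels, n_permutations=5, seed=0)
        assert real.mean() > permuted.mean()
        assert p < 0.01

    def test_chance_level_for_balanced_permuted(self):
        rng = np.random.default_rng(1)
        latents = rng.standard_normal((300, 8))
        labels = np.array(["A", "B", "C"] * 100)
        _, permuted, _ = covariate_separability(latents, labels, n_permutations=5, seed=0)
        assert abs(permuted.mean() - 1 / 3) < 0.1

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            covariate_separability(np.zeros((10, 8)), ["A"] * 10)


def _subject_frame(n, seed, separating=False):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "id": [f"s{i}" for i in range(n)],
            "site": ["A", "B"] * (n // 2),
            "outcome": rng.random(n) < 0.7,
            "age": rng.integers(2, 45, n),
            "sex": rng.choice(["F", "M"], n),
            "soz_resected": rng.integers(0, 2, n).astype(float),
        }
    )
    df["ratio_mphfo"] = (
        np.where(df.outcome, 0.9, 0.1) if separating else rng.random(n)
    )
    return df


class TestOutcomeModels:
    def test_perfect_feature_auc_one(self):
        df = _subject_frame(40, seed=0, separating=True)
        res = outcome_models(df, CvSpec(seed=0), ratio_columns=("ratio_mphfo",), n_trees=100)
        assert res["logistic_auc"]["ratio_mphfo"] == 1.0
        assert res["rf"]["ratio_mphfo"]["f1_mean"] == 1.0

    def test_beta_drawn_ratios_recoverable(self):
        """Subjects with outcome-linked Beta(8,2)/Beta(2,8) ratios: AUC > 0.85."""
        aucs = []
        for s in range(10):
            rng = np.random.default_rng(500 + s)
            df = _subject_frame(60, seed=s)
            df["ratio_mphfo"] = np.where(
                df.outcome, rng.beta(8, 2, len(df)), rng.beta(2, 8, len(df))
            )
            res = outcome_models(df, CvSpec(seed=s), ratio_columns=("ratio_mphfo",), n_trees=50)
            aucs.append(res["logistic_auc"]["ratio_mphfo"])
        assert all(a > 0.85 for a in aucs)

    def test_multivariable_model_present(self):
        df = _subject_frame(40, seed=2, separating=True)
        res = outcome_models(df, CvSpec(seed=0), ratio_columns=("ratio_mphfo",), n_trees=50)
        assert "ratio_mphfo+base+soz" in res["logistic_auc"]
        assert "base+soz" in res["rf"]


class TestFolds:
    def test_every_subject_once_and_site_balanced(self):
        df = _subject_frame(40, seed=3)
        folds = assign_folds(df["id"].to_numpy(), df["site"].to_numpy(), CvSpec(seed=1))
        assert len(folds) == 40
        counts = np.bincount(folds, minlength=5)
        assert counts.sum() == 40
        for site in ("A", "B"):
            site_counts = np.bincount(folds[(df["site"] == site).to_numpy()], minlength=5)
            assert site_counts.max() - site_counts.min() <= 1

    def test_pure_function_of_seed(self):
        df = _subject_frame(30, seed=4)
        a = assign_folds(df["id"].to_numpy(), df["site"].to_numpy(), CvSpec(seed=7))
        b = assign_folds(df["id"].to_numpy(), df["site"].to_numpy(), CvSpec(seed=7))
        np.testing.assert_array_equal(a, b)


class TestCohortSummary:
    def test_simple_percentages(self):
        df = pd.DataFrame(
            {
                "id": ["a", "b", "c", "d"],
                "site": ["X"] * 4,
                "engel1": [True, True, True, False],
                "pathology": ["FCD", "FCD", "Tumor", "HS"],
                "resected": [True] * 4,
            }
        )
        s = cohort_summary(df).set_index("site")
        assert s.loc["overall", "pct_seizure_free"] == 75.0
        assert s.loc["overall", "pct_FCD"] == 50.0

    def test_empty_table_reports_na(self):
        df = pd.DataFrame(columns=["id", "site", "engel1", "pathology", "resected"])
        s = cohort_summary(df)
        assert s["n_resected"].sum() == 0
        assert s["pct_seizure_free"].isna().all()

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            cohort_summary(pd.DataFrame({"id": ["a"]}))


class TestEmbed2d:
    def test_deterministic(self):
        lat = np.random.default_rng(5).standard_normal((60, 8))
        np.testing.assert_array_equal(embed_2d(lat, seed=3), embed_2d(lat, seed=3))

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            embed_2d(np.zeros((3, 8)))

    def test_separated_blobs_positive_silhouette(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(6)
        lat = rng.normal(0, 0.5, (100, 8))
        lat[50:, 0] += 10.0
        coords = embed_2d(lat, seed=0)
        labels = np.array([0] * 50 + [1] * 50)
        assert silhouette_score(coords, labels) > 0
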