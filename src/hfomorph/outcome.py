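"""Clinical correlation: event rates, resection ratios, and outcome models.

The per-subject resection ratio — events of a class on resected channels
divided by all events of that class — is the key predictor of postoperative
seizure freedom (Engel class I at 12 months). Single- and multivariable
logistic regressions and a random forest are evaluated with subject-wise,
site-stratified five-fold cross-validation: AUC on pooled test folds for
the logistic models, per-fold accuracy/F1 (mean +/- SEM) for the forest.
Covariate-separability permutation tests ask whether latent morphology
encodes a covariate (site, sex, age band, pathology) better than chance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score
from sklearn.manifold import TSNE

__all__ = [
    "CvSpec",
    "assign_folds",
    "resection_ratio",
    "event_rates",
    "covariate_separability",
    "outcome_models",
    "cohort_summary",
    "embed_2d",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CvSpec:
    n_folds: int = 5
    seed: int = 0


def assign_folds(subjects, sites, spec: CvSpec) -> np.ndarray:
    """Site-stratified subject-wise folds; pure function of inputs and seed.

    Subjects are shuffled within each site and dealt round-robin, so every
    subject is tested exactly once and site strata are balanced within one
    subject.
    """
    subjects = np.asarray(subjects)
    sites = np.asarray(sites)
    rng = np.random.default_rng(spec.seed)
    folds = np.zeros(len(subjects), dtype=int)
    offset = 0
    for site in sorted(set(sites.tolist())):
        idx = np.flatnonzero(sites == site)
        order = idx[np.argsort(subjects[idx], kind="stable")]
        rng.shuffle(order)
        for j, i in enumerate(order):
            folds[i] = (j + offset) % spec.n_folds
        offset += len(order)
    return folds


def resection_ratio(
    merged_events: pd.DataFrame,
    channel_metadata: pd.DataFrame,
    subject: str,
    labels: np.ndarray | None = None,
    event_class: str | None = None,
) -> float:
    """Events of ``event_class`` on resected channels / all such events.

    ``merged_events`` must hold disjoint (merged) events so duplicated
    STE/MNI detections of one burst count once. ``event_class`` of None
    uses all events; "spk" selects spike-tagged events; otherwise the
    predicted label (requires ``labels`` aligned with the table rows).
    """
    ev = merged_events[merged_events["subject"] == subject]
    sel = np.ones(len(ev), dtype=bool)
    if event_class == "spk":
        sel &= ev["tags"].str.contains("spk").to_numpy()
    elif event_class is not None:
        if labels is None:
            raise ValueError("labels required to select a predicted class")
        sel &= np.asarray(labels)[ev.index] == event_class
    ev = ev[sel]
    if len(ev) == 0:
        raise ValueError(f"subject {subject}: no events of class {event_class!r}")
    ch = channel_metadata
    if "subject" in ch.columns:
        ch = ch[ch["subject"] == subject]
    resected = set(ch.loc[ch["resected"].astype(bool), "name"])
    n_res = int(ev["channel"].isin(resected).sum())
    return n_res / len(ev)


def event_rates(
    events: pd.DataFrame,
    labels: np.ndarray,
    channel_metadata: pd.DataFrame,
    duration_min: float,
) -> tuple[pd.DataFrame, dict]:
    """Per-channel event rates (count/min) per label and SOZ comparison.

    Returns the rate table and, per label, a two-sample t-test of SOZ vs
    non-SOZ channel mean rates (skipped with a warning when either group
    is empty or there are no events).
    """
    if duration_min <= 0:
        raise ValueError("duration must be positive")
    ch = channel_metadata.copy()
    if "subject" not in ch.columns:
        ch["subject"] = ""
    ev = events.copy()
    ev["label"] = np.asarray(labels)

    rows = []
    for _, c in ch.iterrows():
        on_channel = ev[(ev["subject"] == c["subject"]) & (ev["channel"] == c["name"])]
        row = {
            "subject": c["subject"],
            "channel": c["name"],
            "soz": bool(c["soz"]),
        }
        for label in sorted(set(ev["label"].tolist())) or []:
            row[f"rate_{label}"] = (on_channel["label"] == label).sum() / duration_min
        rows.append(row)
    rates = pd.DataFrame(rows)

    comparisons: dict = {}
    if len(ev) == 0:
        warnings.warn("no events; SOZ comparison skipped")
        return rates, comparisons
    for label in sorted(set(ev["label"].tolist())):
        col = f"rate_{label}"
        soz_rates = rates.loc[rates["soz"], col]
        non_rates = rates.loc[~rates["soz"], col]
        if len(soz_rates) < 2 or len(non_rates) < 2:
            warnings.warn(f"label {label}: insufficient channels for SOZ comparison")
            continue
        t, p = stats.ttest_ind(soz_rates, non_rates, equal_var=False)
        comparisons[label] = {
            "soz_mean": float(soz_rates.mean()),
            "non_soz_mean": float(non_rates.mean()),
            "t": float(t),
            "p": float(p),
        }
    return rates, comparisons


def covariate_separability(
    latents: np.ndarray,
    covariate_labels,
    n_permutations: int = 10,
    seed: int = 0,
    n_folds: int = 5,
    n_repeats: int = 5,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Is a covariate decodable from latent morphology beyond chance?

    A multinomial logistic classifier is trained/tested across repeated CV
    folds on the true labels and, separately, on label-permuted data (the
    chance reference). Returns (real accuracies, permuted accuracies, p)
    with p from a Welch t-test between the two accuracy collections
    (folds x repeats vs folds x permutations).
    """
    latents = np.asarray(latents, dtype=float)
    labels = np.asarray(covariate_labels)
    levels = sorted(set(labels.tolist()))
    if len(levels) < 2:
        raise ValueError("covariate needs at least two levels")
    rng = np.random.default_rng(seed)

    def _cv_accuracies(y: np.ndarray, fold_seed: int) -> list[float]:
        local = np.random.default_rng(fold_seed)
        folds = np.arange(len(y)) % n_folds
        local.shuffle(folds)
        accs = []
        for f in range(n_folds):
            test = folds == f
            if len(set(y[~test].tolist())) < 2:
                continue
            clf = LogisticRegression(max_iter=500)
            clf.fit(latents[~test], y[~test])
            accs.append(accuracy_score(y[test], clf.predict(latents[test])))
        return accs

    real: list[float] = []
    for _ in range(n_repeats):
        real.extend(_cv_accuracies(labels, int(rng.integers(2**31 - 1))))
    permuted: list[float] = []
    for _ in range(n_permutations):
        y_perm = labels[rng.permutation(len(labels))]
        permuted.extend(_cv_accuracies(y_perm, int(rng.integers(2**31 - 1))))
    _, p = stats.ttest_ind(real, permuted, equal_var=False)
    return np.asarray(real), np.asarray(permuted), float(p)


def outcome_models(
    subject_features: pd.DataFrame,
    cv: CvSpec | None = None,
    ratio_columns: tuple[str, ...] = ("ratio_hfo", "ratio_spk", "ratio_mphfo"),
    n_trees: int = 500,
) -> dict:
    """Postoperative seizure-freedom prediction from subject features.

    ``subject_features`` columns: id, site, outcome (bool), age, sex,
    soz_resected, plus resection-ratio columns. Logistic models (one per
    ratio, plus multivariable ratio + age + sex + SOZ-resection) are scored
    by AUC on pooled test folds; a random forest per feature set reports
    per-fold accuracy and F1 as mean +/- SEM. Subjects with NaN in a
    model's features are excluded from that model (count logged).
    """
    cv = cv or CvSpec()
    df = subject_features.reset_index(drop=True)
    y_all = df["outcome"].astype(int).to_numpy()
    sex_num = (df["sex"].astype(str) == "F").astype(float).to_numpy()

    def _feature_matrix(cols: list[str]) -> np.ndarray:
        mats = []
        for c in cols:
            if c == "sex":
                mats.append(sex_num)
            else:
                mats.append(df[c].astype(float).to_numpy())
        return np.column_stack(mats)

    folds = assign_folds(df["id"].to_numpy(), df["site"].to_numpy(), cv)
    results: dict = {"logistic_auc": {}, "rf": {}, "excluded": {}}

    feature_sets: dict[str, list[str]] = {}
    for col in ratio_columns:
        if col in df.columns:
            feature_sets[col] = [col]
            feature_sets[f"{col}+base+soz"] = [col, "age", "sex", "soz_resected"]
    feature_sets["base+soz"] = ["age", "sex", "soz_resected"]

    for name, cols in feature_sets.items():
        X = _feature_matrix(cols)
        valid = np.isfinite(X).all(axis=1)
        n_excluded = int((~valid).sum())
        if n_excluded:
            logger.info("model %s: excluded %d subjects with undefined features", name, n_excluded)
        results["excluded"][name] = n_excluded
        Xv, yv, fv = X[valid], y_all[valid], folds[valid]

        pooled_true, pooled_score = [], []
        fold_acc, fold_f1 = [], []
        for f in range(cv.n_folds):
            test = fv == f
            if test.sum() == 0 or len(set(yv[~test].tolist())) < 2:
                warnings.warn(f"model {name}: fold {f} degenerate, refolded into pool")
                continue
            lr = LogisticRegression(C=1e6, max_iter=1000)
            lr.fit(Xv[~test], yv[~test])
            pooled_true.extend(yv[test].tolist())
            pooled_score.extend(lr.predict_proba(Xv[test])[:, 1].tolist())

            rf = RandomForestClassifier(
                n_estimators=n_trees, random_state=cv.seed, n_jobs=1
            )
            rf.fit(Xv[~test], yv[~test])
            pred = rf.predict(Xv[test])
            fold_acc.append(accuracy_score(yv[test], pred))
            fold_f1.append(f1_score(yv[test], pred, zero_division=0))

        if len(set(pooled_true)) == 2:
            results["logistic_auc"][name] = float(roc_auc_score(pooled_true, pooled_score))
        sem = lambda v: float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
        results["rf"][name] = {
            "accuracy_mean": float(np.mean(fold_acc)) if fold_acc else np.nan,
            "accuracy_sem": sem(fold_acc),
            "f1_mean": float(np.mean(fold_f1)) if fold_f1 else np.nan,
            "f1_sem": sem(fold_f1),
        }
    return results


def cohort_summary(subject_metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-site and overall counts with percentages (1 decimal).

    Reports resected counts, seizure-free percentage among resected
    subjects, and pathology-category percentages among resected subjects.
    Empty input yields zero counts with percentages reported as NA.
    """
    required = {"id", "site", "engel1", "pathology"}
    missing = required - set(subject_metadata.columns)
    if missing:
        raise ValueError(f"subject metadata missing column(s): {', '.join(sorted(missing))}")
    df = subject_metadata.copy()
    if "resected" not in df.columns:
        df["resected"] = True
    df["resected"] = df["resected"].astype(bool)
    df["engel1"] = df["engel1"].astype(bool)

    def _percent(num: int, den: int) -> float:
        return round(100.0 * num / den, 1) if den else np.nan

    rows = []
    sites = sorted(set(df["site"].tolist())) + ["overall"]
    for site in sites:
        sub = df if site == "overall" else df[df["site"] == site]
        res = sub[sub["resected"]]
        row = {
            "site": site,
            "n_subjects": len(sub),
            "n_resected": len(res),
            "n_seizure_free": int(res["engel1"].sum()),
            "pct_seizure_free": _percent(int(res["engel1"].sum()), len(res)),
        }
        for pathology in sorted(set(df["pathology"].dropna().tolist())):
            n = int((res["pathology"] == pathology).sum())
            row[f"n_{pathology}"] = n
            row[f"pct_{pathology}"] = _percent(n, len(res))
        rows.append(row)
    return pd.DataFrame(rows)


def embed_2d(latents: np.ndarray, seed: int = 0) -> np.ndarray:
    """t-SNE projection to 2-D for visualization; deterministic per seed."""
    latents = np.asarray(latents, dtype=float)
    if len(latents) < 5:
        raise ValueError("need at least 5 points for a 2-D embedding")
    perplexity = min(30.0, (len(latents) - 1) / 3.0)
    tsne = TSNE(n_components=2, random_state=seed, perplexity=perplexity, init="pca")
    return tsne.fit_transform(latents)
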