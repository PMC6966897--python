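"""Predicting principal-loop-enriched bins from linear genomic features.

Bins are first labelled by an elbow rule on their sorted specific
principal-loop participation counts: the elbow is the rank maximizing the
perpendicular distance to the line joining the first and last sorted counts;
the top fraction (default 20%) of above-elbow bins are *enriched*, the
remaining above-elbow bins are discarded as ambiguous, and everything below
the elbow is *not enriched*.

A random-forest classifier (500 trees) is then trained on z-scored per-bin
feature tracks.  Each tree sees a balanced bootstrap (equal numbers of
positive and negative samples, countering the strong class imbalance), and
generalization is estimated by the out-of-bag (OOB) vote error and by
stratified cross-validated ROC AUC.  Feature importances are reported both
as mean decrease in accuracy (permutation on each tree's OOB samples) and as
mean decrease in Gini impurity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentLabels:
    counts: np.ndarray
    elbow_index: int          # rank position of the elbow in the sorted counts
    labels: np.ndarray        # "enriched" | "not_enriched" | "discarded"

    @property
    def enriched(self) -> np.ndarray:
        return np.flatnonzero(self.labels == "enriched")


def elbow_label(counts, top_fraction: float = 0.2) -> EnrichmentLabels:
    """Label bins by the elbow rule on sorted participation counts.

    The elbow is the sorted-rank index with maximal perpendicular distance
    from the line joining (first rank, max count) to (last rank, min count).
    Above-elbow bins are ranked and the top ``top_fraction`` kept as
    enriched; the remaining above-elbow bins are discarded; all below-elbow
    bins are not_enriched.  Constant counts (or an elbow at an end, as for
    exactly linear counts) are an error: no inflection exists.
    """
    counts = np.asarray(counts, dtype=float)
    n = len(counts)
    if n < 3 or np.ptp(counts) == 0:
        raise ValueError("no elbow in constant or trivial counts")
    order = np.argsort(-counts, kind="stable")
    sorted_counts = counts[order]
    x = np.arange(n, dtype=float)
    # perpendicular distance from (x, y) to the chord between endpoints
    x0, y0, x1, y1 = 0.0, sorted_counts[0], float(n - 1), sorted_counts[-1]
    num = np.abs((y1 - y0) * x - (x1 - x0) * sorted_counts + x1 * y0 - y1 * x0)
    dist = num / np.hypot(y1 - y0, x1 - x0)
    elbow = int(np.argmax(dist))
    if elbow == 0 or elbow == n - 1 or np.isclose(dist[elbow], 0.0):
        raise ValueError("degenerate counts: elbow falls at an end")
    above = order[:elbow + 1]  # bins at or above the elbow rank
    n_keep = max(1, int(round(top_fraction * len(above))))
    labels = np.full(n, "not_enriched", dtype=object)
    labels[above] = "discarded"
    labels[above[:n_keep]] = "enriched"
    logger.info("elbow_label: elbow at rank %d, %d enriched, %d discarded",
                elbow, n_keep, len(above) - n_keep)
    return EnrichmentLabels(counts, elbow, np.asarray(labels, dtype=object))


def zscore(features: pd.DataFrame, fit_on=None) -> pd.DataFrame:
    """Column-wise z-scoring; statistics fitted on ``fit_on`` rows if given
    (leakage guard for train/test splits)."""
    ref = features if fit_on is None else features.loc[fit_on]
    mu = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=0).replace(0, 1.0)
    return (features - mu) / sd


@dataclass
class BalancedForest:
    """Random forest with per-tree balanced bootstrap and OOB tracking."""

    trees: list
    oob_error: float
    feature_names: list
    oob_votes: np.ndarray
    seed: int

    def predict_proba(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        votes = np.zeros(len(x))
        for tree in self.trees:
            votes += tree.predict(x)
        return votes / len(self.trees)

    def predict(self, x) -> np.ndarray:
        return (self.predict_proba(x) >= 0.5).astype(int)


def train_classifier(features, labels, n_trees: int = 500,
                     seed: int = 0) -> BalancedForest:
    """Balanced-bootstrap random forest with out-of-bag error.

    Each of the ``n_trees`` decision trees is grown on a bootstrap holding
    equal numbers of positive and negative samples (the minority count from
    each class, drawn with replacement); OOB error is the balanced
    (class-averaged) misclassification rate of majority OOB votes.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if x.ndim != 2 or len(x) != len(y):
        raise ValueError("features must be (n_samples, n_features) matching labels")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training requires both classes present")
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    per_class = min(len(pos), len(neg))
    votes = np.zeros(len(y))
    n_votes = np.zeros(len(y))
    trees = []
    for t in range(n_trees):
        bp = rng.choice(pos, size=per_class, replace=True)
        bn = rng.choice(neg, size=per_class, replace=True)
        idx = np.concatenate([bp, bn])
        tree = DecisionTreeClassifier(
            max_features="sqrt", random_state=int(rng.integers(2 ** 31)))
        tree.fit(x[idx], y[idx])
        trees.append(tree)
        oob = np.ones(len(y), dtype=bool)
        oob[idx] = False
        if oob.any():
            votes[oob] += tree.predict(x[oob])
            n_votes[oob] += 1
    seen = n_votes > 0
    pred = votes[seen] / n_votes[seen] >= 0.5
    truth = y[seen] == 1
    # balanced OOB error: mean of class-conditional error rates, matching
    # the balanced training objective (plain error would be dominated by
    # the majority class)
    errs = [np.mean(pred[truth == c] != c) for c in (False, True)
            if (truth == c).any()]
    oob_error = float(np.mean(errs))
    names = (list(features.columns) if isinstance(features, pd.DataFrame)
             else [f"f{i}" for i in range(x.shape[1])])
    logger.info("train_classifier: %d trees, %d per class per tree, OOB "
                "error %.3f", n_trees, per_class, oob_error)
    return BalancedForest(trees, oob_error, names, votes, seed)


def evaluate(features, labels, n_trees: int = 500, k_folds: int = 5,
             seed: int = 0) -> float:
    """Mean held-out ROC AUC over stratified k-fold cross-validation.

    z-scoring is fitted on each training fold only and applied to the held
    out fold.
    """
    x = pd.DataFrame(features)
    y = np.asarray(labels, dtype=int)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    aucs = []
    for fold, (tr, te) in enumerate(skf.split(x, y)):
        if len(np.unique(y[te])) < 2:
            raise ValueError(f"fold {fold} lacks a class; reduce k_folds")
        mu = x.iloc[tr].mean()
        sd = x.iloc[tr].std(ddof=0).replace(0, 1.0)
        xtr = (x.iloc[tr] - mu) / sd
        xte = (x.iloc[te] - mu) / sd
        model = train_classifier(xtr, y[tr], n_trees=n_trees, seed=seed + fold)
        aucs.append(roc_auc_score(y[te], model.predict_proba(xte)))
    return float(np.mean(aucs))


def feature_importance(model: BalancedForest, features, labels,
                       seed: int = 0) -> pd.DataFrame:
    """Mean decrease in accuracy (OOB permutation) and Gini decrease.

    Both importances per feature, sorted descending by accuracy decrease.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    n_features = x.shape[1]
    gini = np.mean([t.feature_importances_ for t in model.trees], axis=0)
    base = np.array([t.predict(x) == y for t in model.trees], dtype=float)
    mda = np.zeros(n_features)
    for f in range(n_features):
        xp = x.copy()
        xp[:, f] = rng.permutation(xp[:, f])
        drop = []
        for t, tree in enumerate(model.trees):
            drop.append(base[t].mean() - np.mean(tree.predict(xp) == y))
        mda[f] = np.mean(drop)
    out = pd.DataFrame({"mean_decrease_accuracy": mda,
                        "gini_decrease": gini},
                       index=model.feature_names)
    return out.sort_values("mean_decrease_accuracy", ascending=False)


def marker_tests(features: pd.DataFrame, labels) -> pd.DataFrame:
    """Mann-Whitney U per feature: enriched vs not-enriched distributions."""
    y = np.asarray(labels, dtype=int)
    rows = {}
    for col in features.columns:
        a = features[col][y == 1]
        b = features[col][y == 0]
        stat, p = mannwhitneyu(a, b, alternative="two-sided")
        rows[col] = {"U": float(stat), "p_value": float(p),
                     "median_enriched": float(np.median(a)),
                     "median_not_enriched": float(np.median(b))}
    return pd.DataFrame(rows).T.sort_values("p_value")
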