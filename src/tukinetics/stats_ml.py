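"""Statistical comparisons and learned models over kinetic scores.

Thirds-based rank-sum tests, feature-speed Pearson correlations with BH
adjustment, Gaussian naive Bayes classification with stratified 10-fold CV
pooled into a single ROC/AUC, random-forest regression with permutation-
importance feature selection (out-of-bag predictions only), and
Kolmogorov-Smirnov comparison of length distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ThirdsSplit",
    "thirds_split",
    "wilcoxon_thirds",
    "feature_speed_correlations",
    "bh_adjust",
    "nb_classifier_cv",
    "rf_regression",
    "ks_lengths",
]


@dataclass
class ThirdsSplit:
    """Fastest/slowest thirds of a ranked score list (middle unused)."""

    ranked_ids: list[str]
    fastest: list[str]
    slowest: list[str]
    middle: list[str]


def thirds_split(scores: pd.Series) -> ThirdsSplit:
    """Split ids into fastest/slowest thirds of size floor(n/3).

    Ranking is by descending score; ties are broken by a stable sort on id,
    so all-equal scores split purely by id order.
    """
    s = pd.Series(scores).astype(float)
    order = sorted(s.index.astype(str), key=lambda i: (-s[i], i))
    k = len(order) // 3
    if k < 1:
        raise ValueError("need at least 3 scores")
    return ThirdsSplit(
        ranked_ids=order,
        fastest=order[:k],
        slowest=order[-k:],
        middle=order[k : len(order) - k],
    )


def wilcoxon_thirds(values: pd.Series, split: ThirdsSplit):
    """Two-sided rank-sum (Mann-Whitney) test between fastest and slowest.

    Exact null distribution for small groups, normal approximation with tie
    correction otherwise (scipy's automatic policy).
    """
    v = pd.Series(values).astype(float)
    x = v.loc[split.fastest].to_numpy()
    y = v.loc[split.slowest].to_numpy()
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaNs passed through)."""
    p = np.asarray(pvals, dtype=float)
    out = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def feature_speed_correlations(
    features: pd.DataFrame,
    speeds: pd.Series,
    subsets: dict[str, pd.Index] | None = None,
) -> pd.DataFrame:
    """Per-feature Pearson correlation with the speed score.

    Computed for the full gene set and any named subsets (e.g. RP and
    non-RP panels).  Constant features are reported with NaN r/p.  Raw p
    and BH-adjusted p are reported side by side.
    """
    speeds = pd.Series(speeds).astype(float)
    subsets = {"all": features.index, **(subsets or {})}
    rows = []
    for subset_name, idx in subsets.items():
        sub = features.loc[idx]
        sub_speed = speeds.loc[idx]
        raw = []
        for col in sub.columns:
            x = sub[col].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(sub_speed.to_numpy())
            if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(sub_speed[ok]) == 0:
                raw.append((col, math.nan, math.nan, int(ok.sum())))
                continue
            r, p = stats.pearsonr(x[ok], sub_speed.to_numpy()[ok])
            raw.append((col, float(r), float(p), int(ok.sum())))
        padj = bh_adjust([p for _, _, p, _ in raw])
        for (col, r, p, n), q in zip(raw, padj):
            rows.append(
                {
                    "subset": subset_name,
                    "feature": col,
                    "pearson_r": r,
                    "p_value": p,
                    "p_adj_bh": float(q) if np.isfinite(q) else math.nan,
                    "n": n,
                }
            )
    return pd.DataFrame(rows)


def nb_classifier_cv(
    features: pd.DataFrame | np.ndarray,
    labels,
    folds: int = 10,
    seed: int = 0,
):
    """Gaussian naive Bayes with stratified k-fold CV, pooled ROC/AUC.

    Out-of-fold class-1 probabilities from all folds are pooled into a
    single ROC curve and AUC (never in-sample scores).
    Returns (roc DataFrame with fpr/tpr/threshold, auc, pooled scores).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) != 2:
        raise ValueError("binary labels required")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.empty(len(y))
    for train, test in skf.split(X, y):
        clf = GaussianNB()
        clf.fit(X[train], y[train])
        scores[test] = clf.predict_proba(X[test])[:, 1]
    fpr, tpr, thresh = roc_curve(y, scores)
    auc = float(roc_auc_score(y, scores))
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresh})
    return roc, auc, scores


def rf_regression(
    features: pd.DataFrame,
    speeds,
    seed: int = 0,
    n_trees: int = 500,
    importance_threshold: float = 0.01,
    n_importance_repeats: int = 5,
):
    """Random-forest regression with automatic feature selection.

    A forest (``n_trees`` trees, default depth) is fit on all features;
    permutation importance (mean decrease in R^2 over
    ``n_importance_repeats`` shuffles) selects features above
    ``importance_threshold``; the forest is refit on the selection and
    evaluated through *out-of-bag* predictions only.  When no feature
    passes, all features are kept.  Returns a dict with oob predictions,
    Pearson r (observed vs predicted), and the selected feature names.
    """
    X = pd.DataFrame(features)
    y = np.asarray(speeds, dtype=float)
    rf = RandomForestRegressor(
        n_estimators=n_trees, oob_score=True, random_state=seed, bootstrap=True
    )
    rf.fit(X.to_numpy(), y)
    imp = permutation_importance(
        rf, X.to_numpy(), y, n_repeats=n_importance_repeats, random_state=seed
    )
    selected = [
        c
        for c, m in zip(X.columns, imp.importances_mean)
        if m > importance_threshold
    ]
    if not selected:
        selected = list(X.columns)
    rf2 = RandomForestRegressor(
        n_estimators=n_trees, oob_score=True, random_state=seed, bootstrap=True
    )
    rf2.fit(X[selected].to_numpy(), y)
    pred = rf2.oob_prediction_
    if np.std(pred) == 0 or np.std(y) == 0:
        r = math.nan
    else:
        r = float(stats.pearsonr(y, pred)[0])
    return {
        "predicted": pred,
        "pearson_r": r,
        "selected_features": selected,
        "importances": dict(zip(X.columns, imp.importances_mean)),
    }


def ks_lengths(lengths_a, lengths_b):
    """Two-sample Kolmogorov-Smirnov test on length distributions."""
    res = stats.ks_2samp(
        np.asarray(lengths_a, dtype=float), np.asarray(lengths_b, dtype=float)
    )
    return float(res.statistic), float(res.pvalue)
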