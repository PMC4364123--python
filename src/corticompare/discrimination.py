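"""ROI-based discrimination: gated forward selection, logistic scoring,
ROC/AUC with Hanley-McNeil errors, and correlated-AUC comparison.

Candidate ROIs are gated by effect size (|g| > 0.8 cross-sectionally,
> 0.6 longitudinally) and ranked by decreasing |g|; a sequential forward
search then grows the feature set greedily, accepting an ROI only when it
improves the seeded 5-fold cross-validated AUC of the logistic score.
AUC is the Mann-Whitney statistic (tie-corrected); its standard error is
the Hanley-McNeil (1982) binormal-free formula.  Two pipelines' AUCs on
the same subjects are compared with the correlated-AUC z-test, the
between-score correlation r estimated as the average of the within-class
score correlations (a DeLong covariance alternative is provided as the
exact cross-check).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

log = logging.getLogger(__name__)

GATE_CROSS_SECTIONAL = 0.8
GATE_LONGITUDINAL = 0.6


@dataclasses.dataclass
class ROCResult:
    auc: float
    se_auc: float
    ci95: tuple
    selected_rois: list
    scores: np.ndarray
    labels: np.ndarray


@dataclasses.dataclass
class AUCComparison:
    auc1: float
    auc2: float
    r: float
    z: float
    p: float


def gate_candidates(effect_sizes: dict, threshold: float) -> list:
    """ROIs with |g| above the gate, ordered by decreasing |g| (ties by id)."""
    passed = [(roi, abs(g)) for roi, g in effect_sizes.items()
              if abs(g) > threshold]
    passed.sort(key=lambda t: (-t[1], t[0]))
    return [roi for roi, _ in passed]


def _feature_matrix(table: pd.DataFrame, rois, subjects) -> np.ndarray:
    wide = table.pivot_table(index="subject", columns="roi_id",
                             values="thickness")
    X = wide.loc[subjects, list(rois)].to_numpy(float)
    if np.any(np.isnan(X)):
        raise ValueError("missing thickness for a selected subject/ROI")
    return X


def fit_logistic_score(table: pd.DataFrame, labels: pd.Series, roi_set,
                       return_cv: bool = False, n_folds: int = 5,
                       seed: int = 0):
    """Maximum-likelihood logistic score on ROI mean thicknesses.

    Returns in-sample predicted probabilities (and seeded CV-fold
    out-of-fold probabilities when requested).  On perfect separation the
    unpenalized fit cannot converge, so a ridge-penalized fit is used and
    noted in the log.
    """
    if not len(roi_set):
        raise ValueError("roi_set must be non-empty")
    subjects = labels.index.to_numpy()
    y = labels.to_numpy().astype(int)
    X = _feature_matrix(table, roi_set, subjects)
    model = _fit_logistic(X, y)
    scores = model.predict_proba(X)[:, 1]
    if not return_cv:
        return scores
    cv_scores = np.full(len(y), np.nan)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for tr, te in skf.split(X, y):
        m = _fit_logistic(X[tr], y[tr])
        cv_scores[te] = m.predict_proba(X[te])[:, 1]
    return scores, cv_scores


def _fit_logistic(X, y) -> LogisticRegression:
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("error")
        try:
            return LogisticRegression(penalty=None, max_iter=2000).fit(X, y)
        except Exception:
            log.info("unpenalized logistic fit failed (likely separation); "
                     "falling back to ridge penalty")
    return LogisticRegression(C=1.0, max_iter=2000).fit(X, y)


def forward_select(table: pd.DataFrame, labels: pd.Series, candidates,
                   max_k: int | None = None, n_folds: int = 5,
                   seed: int = 0) -> list:
    """Greedy sequential forward ROI selection on cross-validated AUC.

    Starting from the empty set, each step adds the candidate maximizing
    the seeded ``n_folds``-fold CV AUC of the logistic score; stops when
    no addition improves the AUC (or at ``max_k`` features).
    """
    if not len(candidates):
        raise ValueError("no candidate ROIs")
    y = labels.to_numpy().astype(int)
    if min((y == 0).sum(), (y == 1).sum()) < 3:
        raise ValueError("need at least 3 subjects per class")
    selected: list = []
    best_auc = -np.inf
    max_k = max_k or len(candidates)
    remaining = list(candidates)
    while remaining and len(selected) < max_k:
        trial_aucs = []
        for roi in remaining:
            _, cv = fit_logistic_score(table, labels, selected + [roi],
                                       return_cv=True, n_folds=n_folds,
                                       seed=seed)
            trial_aucs.append(roc_auc(cv, y).auc)
        k = int(np.argmax(trial_aucs))
        if trial_aucs[k] <= best_auc:
            break
        best_auc = trial_aucs[k]
        selected.append(remaining.pop(k))
    return selected


def roc_auc(scores, labels) -> ROCResult:
    """AUC via the Mann-Whitney statistic with tie correction.

    se is the Hanley-McNeil (1982) formula from (AUC, n_pos, n_neg);
    ci95 = auc +/- 1.96 se, clipped to [0, 1].
    """
    scores = np.asarray(scores, float)
    y = np.asarray(labels).astype(int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    se = hanley_mcneil_se(auc, n_pos, n_neg)
    ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))
    return ROCResult(float(auc), float(se), ci, [], scores, y)


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc ** 2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc ** 2)
           + (n_neg - 1) * (q2 - auc ** 2)) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def _within_class_score_correlation(s1, s2, y, method: str = "pearson") -> float:
    """Average of the two within-class correlations between score sets."""
    rs = []
    for cls in (0, 1):
        a, b = s1[y == cls], s2[y == cls]
        if np.std(a) == 0 or np.std(b) == 0:
            rs.append(0.0)
        elif method == "kendall":
            tau = stats.kendalltau(a, b).statistic
            rs.append(np.sin(np.pi * tau / 2.0))
        else:
            rs.append(stats.pearsonr(a, b)[0])
    return float(np.mean(rs))


def compare_auc(result1: ROCResult, result2: ROCResult, paired: bool = True,
                r_method: str = "pearson", use_delong: bool = False
                ) -> AUCComparison:
    """Correlated-AUC z-test between two score sets on the same subjects.

    z = (auc1 - auc2) / sqrt(se1^2 + se2^2 - 2 r se1 se2), where r is the
    average within-class correlation between the score sets (rank-based
    via Kendall's tau when ``r_method='kendall'``); with r = 0 this
    reduces to the independent-AUC z.  ``use_delong`` replaces the whole
    covariance with the exact DeLong estimate.
    """
    if paired:
        if len(result1.scores) != len(result2.scores) or \
                not np.array_equal(result1.labels, result2.labels):
            raise ValueError("paired comparison requires the same subjects "
                             "and labels in both results")
    a1, a2 = result1.auc, result2.auc
    if use_delong:
        var1, var2, cov = delong_covariance(result1.scores, result2.scores,
                                            result1.labels)
        se_diff = np.sqrt(max(var1 + var2 - 2 * cov, 1e-300))
        r = cov / np.sqrt(var1 * var2) if var1 > 0 and var2 > 0 else 0.0
    else:
        r = 0.0
        if paired:
            r = _within_class_score_correlation(result1.scores, result2.scores,
                                                result1.labels, r_method)
        se1, se2 = result1.se_auc, result2.se_auc
        se_diff = np.sqrt(max(se1 ** 2 + se2 ** 2 - 2 * r * se1 * se2, 1e-300))
    z = (a1 - a2) / se_diff
    return AUCComparison(a1, a2, float(r), float(z),
                         float(2 * stats.norm.sf(abs(z))))


def delong_covariance(scores1, scores2, labels):
    """DeLong variance/covariance of two paired AUCs (structural components)."""
    y = np.asarray(labels).astype(int)
    pos = y == 1
    neg = y == 0
    m, n = int(pos.sum()), int(neg.sum())

    def components(s):
        sp, sn = s[pos], s[neg]
        # placement values via midranks (tie-aware)
        v10 = np.array([(np.sum(x > sn) + 0.5 * np.sum(x == sn)) / n
                        for x in sp])
        v01 = np.array([(np.sum(sp > x) + 0.5 * np.sum(sp == x)) / m
                        for x in sn])
        return v10, v01

    v10_1, v01_1 = components(np.asarray(scores1, float))
    v10_2, v01_2 = components(np.asarray(scores2, float))
    s10 = np.cov(np.vstack([v10_1, v10_2]))
    s01 = np.cov(np.vstack([v01_1, v01_2]))
    var1 = s10[0, 0] / m + s01[0, 0] / n
    var2 = s10[1, 1] / m + s01[1, 1] / n
    cov = s10[0, 1] / m + s01[0, 1] / n
    return float(var1), float(var2), float(cov)
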