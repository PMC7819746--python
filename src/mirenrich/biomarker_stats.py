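"""Urinary biomarker statistics.

Relative qPCR quantification by the 2^-ddCt method with a configurable
reference assay (endogenous U6 for tissue, exogenous spiked cel-miR-39
for urine), two-group Mann-Whitney comparison, ROC analysis with DeLong
or bootstrap confidence intervals, and a multivariable logistic
combination of markers fitted by iteratively reweighted least squares.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def delta_delta_ct(ct: pd.DataFrame, target: str, reference: str,
                   calibrator_group: str,
                   group_col: str = "group_label") -> pd.DataFrame:
    """Relative quantification: rq = 2^-(ddCt) per subject.

    dCt = Ct_target - Ct_reference per subject (replicate rows averaged);
    ddCt = dCt - mean(dCt over the calibrator group); by construction the
    calibrator group's geometric mean rq is 1. Subjects missing either
    assay are dropped with a warning.
    """
    t = ct[ct["assay"] == target].groupby("subject_id")["ct"].mean()
    r = ct[ct["assay"] == reference].groupby("subject_id")["ct"].mean()
    groups = ct.drop_duplicates("subject_id").set_index("subject_id")[group_col]
    subjects = t.index.intersection(r.index)
    dropped = sorted(set(t.index).symmetric_difference(r.index))
    if dropped:
        warnings.warn(f"subjects missing target or reference Ct dropped: {dropped}")
    if subjects.empty:
        raise ValueError("no subject has both target and reference Ct values")
    dct = (t.loc[subjects] - r.loc[subjects]).rename("delta_ct")
    grp = groups.loc[subjects]
    calib = dct[grp == calibrator_group]
    if calib.empty:
        raise ValueError(f"calibrator group {calibrator_group!r} is empty")
    ddct = dct - calib.mean()
    out = pd.DataFrame({"group_label": grp, "delta_ct": dct,
                        "delta_delta_ct": ddct, "rq": 2.0 ** (-ddct)})
    out["reference_used"] = reference
    out.attrs["target"] = target
    out.attrs["calibrator_group"] = calibrator_group
    return out


def group_fold_change(rq_table: pd.DataFrame, group: str,
                      calibrator_group: str) -> dict:
    """Fold change of rq between groups, as ratio of means and of medians."""
    g = rq_table[rq_table["group_label"] == group]["rq"]
    c = rq_table[rq_table["group_label"] == calibrator_group]["rq"]
    return {"mean_ratio": float(g.mean() / c.mean()),
            "median_ratio": float(g.median() / c.median())}


def mann_whitney(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U: exact for pooled n <= 20 without ties, else
    tie-corrected normal approximation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    method: str


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _auc_and_placements(pos: np.ndarray, neg: np.ndarray):
    """AUC by the Mann-Whitney pair-counting identity, with the DeLong
    placement values of each observation."""
    m, n = len(pos), len(neg)
    allv = np.concatenate([pos, neg])
    r_all = _midrank(allv)
    r_pos = _midrank(pos)
    r_neg = _midrank(neg)
    v10 = (r_all[:m] - r_pos) / n               # placements of positives
    v01 = 1.0 - (r_all[m:] - r_neg) / m         # placements of negatives
    auc = v10.mean()
    return auc, v10, v01


def roc_auc(scores, labels, ci_method: str = "delong", level: float = 0.95,
            seed: int | None = None, n_boot: int = 2000) -> RocResult:
    """AUC with half-credit for ties plus a confidence interval.

    DeLong's covariance of placement values gives the default CI
    (truncated to [0, 1]); a within-class percentile bootstrap is the
    alternative.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    auc, v10, v01 = _auc_and_placements(pos, neg)
    z = stats.norm.ppf(0.5 + level / 2)
    if ci_method == "delong":
        var = (np.var(v10, ddof=1) / len(pos) if len(pos) > 1 else 0.0) \
            + (np.var(v01, ddof=1) / len(neg) if len(neg) > 1 else 0.0)
        half = z * np.sqrt(var)
        lo, hi = auc - half, auc + half
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            p = rng.choice(pos, size=len(pos), replace=True)
            q = rng.choice(neg, size=len(neg), replace=True)
            reps[b] = _auc_and_placements(p, q)[0]
        lo, hi = np.quantile(reps, [(1 - level) / 2, 0.5 + level / 2])
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return RocResult(auc=float(auc), ci_low=float(max(0.0, lo)),
                     ci_high=float(min(1.0, hi)), n_pos=len(pos),
                     n_neg=len(neg), method=ci_method)


def roc_points(scores, labels) -> pd.DataFrame:
    """(FPR, TPR) pairs over all score thresholds, for plot export."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    thresholds = np.unique(s)[::-1]
    p, n = y.sum(), (1 - y).sum()
    rows = [{"threshold": np.inf, "fpr": 0.0, "tpr": 0.0}]
    for t in thresholds:
        pred = s >= t
        rows.append({"threshold": t,
                     "fpr": float(((pred) & (y == 0)).sum() / n),
                     "tpr": float(((pred) & (y == 1)).sum() / p)})
    return pd.DataFrame(rows)


@dataclass
class LogisticCombination:
    coef: np.ndarray            # [intercept, beta_1, ..., beta_k]
    scores: np.ndarray          # linear predictor per subject
    converged: bool
    separated: bool
    n_iter: int
    roc: RocResult
    se: np.ndarray | None = None


def combine_markers_logistic(features, labels, max_iter: int = 100,
                             tol: float = 1e-8, ridge: float = 1e-8,
                             ci_method: str = "delong",
                             seed: int | None = None) -> LogisticCombination:
    """Multivariable binomial logistic combination of markers.

    Maximum-likelihood fit by iteratively reweighted least squares with a
    small ridge jitter on the normal equations so collinear marker sets
    stay solvable. Complete separation is detected via a diverging weight
    norm and flagged; the linear-predictor scores of the last iterate are
    still returned, and the combined score's AUC is reported.
    """
    X = np.asarray(features, float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels).astype(float)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more subjects ({n}) than markers ({k})")
    Xd = np.column_stack([np.ones(n), X])
    beta = np.zeros(k + 1)
    converged = separated = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = Xd @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = np.clip(p * (1 - p), 1e-10, None)
        zvec = eta + (y - p) / w
        A = Xd.T @ (w[:, None] * Xd) + ridge * np.eye(k + 1)
        beta_new = np.linalg.solve(A, Xd.T @ (w * zvec))
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        eta = Xd @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        perfectly_split = np.all(np.abs(eta) > 12) and \
            np.array_equal((p > 0.5).astype(float), y)
        if np.linalg.norm(beta) > 1e4 or perfectly_split:
            separated = True
            break
        if step < tol:
            converged = True
            break
    if not converged and not separated:
        warnings.warn(f"logistic fit did not converge in {max_iter} iterations")
    scores = Xd @ beta
    roc = roc_auc(scores, labels, ci_method=ci_method, seed=seed)
    se = None
    if converged and not separated:
        eta = Xd @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = np.clip(p * (1 - p), 1e-10, None)
        cov = np.linalg.inv(Xd.T @ (w[:, None] * Xd) + ridge * np.eye(k + 1))
        se = np.sqrt(np.diag(cov))
    return LogisticCombination(coef=beta, scores=scores, converged=converged,
                               separated=separated, n_iter=it, roc=roc, se=se)


def creatinine_normalize(value, creatinine):
    """Elementwise analyte / creatinine ratio to correct urinary dilution."""
    value = np.asarray(value, float)
    creatinine = np.asarray(creatinine, float)
    if (creatinine <= 0).any():
        raise ValueError("creatinine concentrations must be positive")
    return value / creatinine
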