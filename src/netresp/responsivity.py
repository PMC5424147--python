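"""Condition GLMs on component time-courses, the responsivity index, the
responsivity-performance heuristic and the task-positive (MCR/MTR) search.

Responsivity of a component in a task, for one subject, is the difference
between the standardized GLM betas of the task's more-demanding and
less-demanding conditions: both the component time-course and every
condition regressor are z-scored before the multiple regression, so the
index is invariant to the scaling of either side.

MCR (multiple component responsivity) is the per-subject mean responsivity
over a component set; the task-positive set is found by ranking components
on signed cohort-mean responsivity and scanning the top-k sets for the one
whose MCR best correlates with task score (MTR = MCR at the optimum k).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import DesignMatrix
from .stats import CollinearityError, pearson_ci, residualize


def _zscore(x: np.ndarray, axis=-1) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd


def fit_component_glm(timecourse: np.ndarray,
                      design: DesignMatrix) -> dict:
    """Standardized betas of one component time-course on the task design.

    Returns {condition_name: beta}.  The time-course and every regressor
    are z-scored; an intercept is included.
    """
    tc = np.asarray(timecourse, dtype=float)
    if tc.shape[0] != design.n_volumes:
        raise ValueError("time-course length does not match design")
    Z = _zscore(design.regressors, axis=0)
    X = np.column_stack([np.ones(len(tc)), Z])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _collinear_conditions(Z, design.condition_names)
        raise CollinearityError(
            f"rank-deficient design; offending conditions: {bad}")
    y = _zscore(tc)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return dict(zip(design.condition_names, beta[1:]))


def _collinear_conditions(Z, names):
    bad = []
    for i in range(Z.shape[1]):
        others = np.delete(Z, i, axis=1)
        proj, *_ = np.linalg.lstsq(others, Z[:, i], rcond=None)
        if np.linalg.norm(Z[:, i] - others @ proj) < 1e-8 * \
                max(np.linalg.norm(Z[:, i]), 1e-30):
            bad.append(names[i])
    return bad or list(names)


def responsivity_index(betas: dict, contrast: tuple) -> float:
    """r = beta(more demanding) − beta(less demanding)."""
    more, less = contrast
    for c in (more, less):
        if c not in betas:
            raise KeyError(f"condition {c!r} missing from fitted betas")
    return float(betas[more] - betas[less])


def responsivity_table(timecourses: np.ndarray,
                       design: DesignMatrix) -> np.ndarray:
    """Vectorized responsivity for (n_subjects, n_components, n_volumes)
    time-courses; returns (n_subjects, n_components)."""
    tcs = np.asarray(timecourses, dtype=float)
    n_sub, n_comp, n_vol = tcs.shape
    Z = _zscore(design.regressors, axis=0)
    X = np.column_stack([np.ones(n_vol), Z])
    pinv = np.linalg.pinv(X)
    Y = _zscore(tcs.reshape(-1, n_vol)).T           # n_vol x (sub*comp)
    betas = (pinv @ Y)[1:]                          # n_cond x (sub*comp)
    more, less = design.conditions_of_interest
    mi = design.condition_names.index(more)
    li = design.condition_names.index(less)
    r = (betas[mi] - betas[li]).reshape(n_sub, n_comp)
    return r


def mean_absolute_responsivity(table: np.ndarray, n_boot: int = 2000,
                               seed: int = 0) -> dict:
    """Cohort summary: mean |responsivity| over subjects x components, with
    a percentile bootstrap 95% CI over subjects."""
    R = np.abs(np.asarray(table, dtype=float))
    if R.size == 0:
        raise ValueError("empty responsivity table")
    point = float(R.mean())
    rng = np.random.default_rng(seed)
    n = R.shape[0]
    boots = np.array([R[rng.integers(0, n, n)].mean()
                      for _ in range(n_boot)])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return {"mean_abs_responsivity": point,
            "ci_low": float(lo), "ci_high": float(hi)}


def heuristic_validation(table: np.ndarray, scores, covariates=None,
                         partial_age=None) -> dict:
    """Test that more responsive components relate more to performance.

    Per component: across-subject correlation of responsivity with score
    (on covariate residuals; optionally partialling age out of both).
    Across components: correlation of cohort-mean responsivity with those
    per-component correlations.  The responsivity magnitude is taken as
    |cohort mean| so that strongly suppressed components count as strongly
    responsive.
    """
    R = np.asarray(table, dtype=float)
    if R.shape[1] < 3:
        raise ValueError("need at least 3 components")
    scores = np.asarray(scores, dtype=float)
    cov = covariates
    if partial_age is not None:
        age = np.asarray(partial_age, dtype=float)[:, None]
        cov = age if cov is None else np.column_stack([cov, age])
    s_res = residualize(scores, cov)
    comp_corr = np.array([
        pearson_ci(residualize(R[:, j], cov), s_res).r
        for j in range(R.shape[1])])
    mean_resp = R.mean(axis=0)
    across_signed = pearson_ci(mean_resp, comp_corr)
    # magnitude version: strong suppression counts as strong responsivity
    signs = np.where(mean_resp >= 0, 1.0, -1.0)
    across_abs = pearson_ci(np.abs(mean_resp), signs * comp_corr)
    return {"component_score_r": comp_corr, "mean_responsivity": mean_resp,
            "across_component_r": across_signed.r,
            "across_component_p": across_signed.p,
            "across_component_abs_r": across_abs.r}


@dataclass
class TaskPositiveResult:
    ranking: np.ndarray           # component indices, most responsive first
    k_scan: np.ndarray            # correlation(MCR_k, score) for k = 1..K
    k_star: int
    task_positive: np.ndarray     # component indices of the selected set
    mtr: np.ndarray               # per-subject MTR


def mcr(table: np.ndarray, component_set) -> np.ndarray:
    """Multiple component responsivity: per-subject mean responsivity over
    a component set."""
    idx = np.asarray(list(component_set), dtype=int)
    if idx.size == 0:
        raise ValueError("empty component set")
    return np.asarray(table, dtype=float)[:, idx].mean(axis=1)


def select_task_positive(table: np.ndarray, scores, covariates=None,
                         include_age=None,
                         max_k: int | None = None) -> TaskPositiveResult:
    """Iterative top-k scan for the task-positive component set.

    Components are ranked by signed cohort-mean responsivity (descending);
    for each k the MCR of the top-k set is correlated with task score on
    covariate residuals (optionally also partialling age); k* is the argmax
    (ties to the smaller k) and MTR is the MCR of the k* set.
    """
    R = np.asarray(table, dtype=float)
    if R.shape[1] < 2:
        raise ValueError("need at least 2 components")
    scores = np.asarray(scores, dtype=float)
    if np.std(scores) == 0:
        raise ValueError("degenerate scores: no variance")
    cov = covariates
    if include_age is not None:
        age = np.asarray(include_age, dtype=float)[:, None]
        cov = age if cov is None else np.column_stack([cov, age])
    ranking = np.argsort(-R.mean(axis=0), kind="stable")
    K = R.shape[1] if max_k is None else min(max_k, R.shape[1])
    s_res = residualize(scores, cov)
    k_scan = np.empty(K)
    for k in range(1, K + 1):
        m = mcr(R, ranking[:k])
        k_scan[k - 1] = pearson_ci(residualize(m, cov), s_res).r
    k_star = int(np.argmax(k_scan)) + 1
    task_positive = ranking[:k_star]
    return TaskPositiveResult(ranking=ranking, k_scan=k_scan, k_star=k_star,
                              task_positive=task_positive,
                              mtr=mcr(R, task_positive))
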