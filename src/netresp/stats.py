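"""Statistical framework: covariate residualization, correlation inference,
correlation comparison, moderation, mediation, and the compensation screens.

All tests operate on covariate residuals: nuisance covariates (education,
handedness, gender by default) are regressed out of each variable of
interest and the test is run on the residuals.  Mediation uses the
product-of-coefficients decomposition of nested linear models with a
percentile bootstrap over subjects; for linear models the indirect (ACME)
and direct (ADE) effects sum exactly to the total effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


class DegenerateDataError(ValueError):
    """Raised when an input has no variance or is otherwise degenerate."""


class CollinearityError(ValueError):
    """Raised when a design/covariate matrix is rank deficient."""


def _as_matrix(covariates) -> np.ndarray:
    c = np.asarray(covariates, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    return c


def _design_with_intercept(covariates, n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    c = _as_matrix(covariates)
    if c.shape[0] != n:
        raise ValueError("covariate rows must match data length")
    X = np.column_stack([np.ones(n), c])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError("covariate matrix is rank deficient")
    return X


def residualize(values, covariates) -> np.ndarray:
    """OLS residuals of ``values`` on [intercept, covariates].

    With ``covariates=None`` this just centers the values.  Residuals are
    orthogonal to every covariate column and the operation is idempotent.
    """
    y = np.asarray(values, dtype=float)
    X = _design_with_intercept(covariates, y.shape[0])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    df: int
    ci_low: float
    ci_high: float
    p: float


def pearson_ci(x, y) -> CorrelationResult:
    """Pearson correlation with Fisher-z 95% CI and two-sided t-test p.

    CI: tanh(atanh(r) ± 1.96/sqrt(n−3)); p from t = r·sqrt((n−2)/(1−r²))
    on n−2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateDataError("zero variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0 - 1e-15:
        ci_low = ci_high = r
        p = 0.0
    else:
        z = np.arctanh(r)
        half = 1.959963984540054 / np.sqrt(n - 3)
        ci_low, ci_high = float(np.tanh(z - half)), float(np.tanh(z + half))
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2 * sps.t.sf(abs(t), n - 2))
    return CorrelationResult(r=r, n=n, df=n - 2,
                             ci_low=ci_low, ci_high=ci_high, p=p)


@dataclass(frozen=True)
class CorrelationComparison:
    statistic: float
    p: float
    kind: str      # "independent-z" or "dependent-t"
    df: float | None = None


def compare_correlations(r1: float, n1: int, r2: float, n2: int,
                         r12: float | None = None) -> CorrelationComparison:
    """Test the difference between two Pearson correlations.

    Without ``r12``: independent-samples Fisher-z test,
    z = (atanh r1 − atanh r2) / sqrt(1/(n1−3) + 1/(n2−3)).

    With ``r12`` (the correlation between the two non-shared variables,
    measured on the same n = n1 = n2 subjects): Williams/Steiger t-test for
    dependent correlations sharing one variable, on n−3 df.
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("correlations must be strictly inside (-1, 1)")
    if r12 is None:
        se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
        z = (np.arctanh(r1) - np.arctanh(r2)) / se
        p = float(2 * sps.norm.sf(abs(z)))
        return CorrelationComparison(statistic=float(z), p=p,
                                     kind="independent-z")
    if n1 != n2:
        raise ValueError("dependent test requires equal sample sizes")
    n = n1
    detR = 1 - r1 * r1 - r2 * r2 - r12 * r12 + 2 * r1 * r2 * r12
    rbar = 0.5 * (r1 + r2)
    denom = 2 * ((n - 1) / (n - 3)) * detR + rbar * rbar * (1 - r12) ** 3
    if denom <= 0:
        raise DegenerateDataError("non-positive variance in dependent test")
    t = (r1 - r2) * np.sqrt((n - 1) * (1 + r12) / denom)
    p = float(2 * sps.t.sf(abs(t), n - 3))
    return CorrelationComparison(statistic=float(t), p=p,
                                 kind="dependent-t", df=float(n - 3))


@dataclass(frozen=True)
class ModerationResult:
    interaction_coef: float
    partial_r2: float
    p: float
    n: int


def _ols_sse(X: np.ndarray, y: np.ndarray):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), beta


def moderation_test(y, x, z, covariates=None) -> ModerationResult:
    """Moderation of the x→y relation by z via the x·z interaction term.

    x and z are mean-centered before forming the interaction.  Partial R²
    of the interaction = (SSE_reduced − SSE_full) / SSE_reduced, with a
    1-df F-test for significance.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    n = y.shape[0]
    xc = x - x.mean()
    zc = z - z.mean()
    cov = _as_matrix(covariates) if covariates is not None else \
        np.empty((n, 0))
    X_red = np.column_stack([np.ones(n), xc, zc, cov])
    X_full = np.column_stack([X_red, xc * zc])
    if n <= X_full.shape[1] + 2:
        raise ValueError("too few observations for moderation model")
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise CollinearityError("moderation design is rank deficient")
    sse_red, _ = _ols_sse(X_red, y)
    sse_full, beta = _ols_sse(X_full, y)
    if sse_red <= 0:
        raise DegenerateDataError("reduced model fits exactly")
    partial_r2 = max(0.0, (sse_red - sse_full) / sse_red)
    df_resid = n - X_full.shape[1]
    if sse_full <= 1e-300:
        p = 0.0
    else:
        f = (sse_red - sse_full) / (sse_full / df_resid)
        p = float(sps.f.sf(f, 1, df_resid))
    return ModerationResult(interaction_coef=float(beta[-1]),
                            partial_r2=float(partial_r2), p=p, n=n)


@dataclass(frozen=True)
class MediationResult:
    acme: float
    ade: float
    total: float
    proportion_mediated: float | None
    acme_ci: tuple
    ade_ci: tuple
    total_ci: tuple
    proportion_ci: tuple | None
    n: int
    n_boot: int
    seed: int


def _mediation_point(x, m, y, cov) -> tuple:
    n = x.shape[0]
    Xm = np.column_stack([np.ones(n), x, cov])
    _, beta_m = _ols_sse(Xm, m)
    a = beta_m[1]
    Xy = np.column_stack([np.ones(n), x, m, cov])
    _, beta_y = _ols_sse(Xy, y)
    cprime, b = beta_y[1], beta_y[2]
    Xt = np.column_stack([np.ones(n), x, cov])
    _, beta_t = _ols_sse(Xt, y)
    c = beta_t[1]
    return a * b, cprime, c


def mediate(x, m, y, covariates=None, n_boot: int = 1000,
            seed: int = 0) -> MediationResult:
    """Linear mediation: ACME = a·b, ADE = c′, total = c, with percentile
    bootstrap CIs over subject resamples.

    Fits m ~ x (+cov) and y ~ x + m (+cov); in linear OLS the identity
    ACME + ADE = total holds to numerical precision.  ``proportion_mediated``
    is ACME/total, reported as None when the total effect is ~0.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if n < 10:
        raise ValueError("mediation requires n >= 10")
    cov = _as_matrix(covariates) if covariates is not None else \
        np.empty((n, 0))
    acme, ade, total = _mediation_point(x, m, y, cov)

    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, 3))
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        boots[i] = _mediation_point(x[idx], m[idx], y[idx], cov[idx])
    lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)

    scale = max(abs(total), np.std(y) / max(np.std(x), 1e-300))
    total_is_zero = abs(total) < 1e-10 * max(scale, 1e-300)
    if total_is_zero:
        prop, prop_ci = None, None
    else:
        prop = acme / total
        pboot = boots[:, 0] / boots[:, 2]
        pboot = pboot[np.isfinite(pboot)]
        prop_ci = tuple(np.percentile(pboot, [2.5, 97.5])) if len(pboot) \
            else None
    return MediationResult(
        acme=float(acme), ade=float(ade), total=float(total),
        proportion_mediated=None if prop is None else float(prop),
        acme_ci=(float(lo[0]), float(hi[0])),
        ade_ci=(float(lo[1]), float(hi[1])),
        total_ci=(float(lo[2]), float(hi[2])),
        proportion_ci=prop_ci, n=n, n_boot=n_boot, seed=seed)


def implied_mediator_outcome_corr(r_xm: float, r_xy: float,
                                  proportion: float) -> float:
    """Correlation r(m, y) implied by a target proportion mediated.

    For standardized trivariate data, a = r_xm, c = r_xy and
    b = (r_my − r_xy·r_xm)/(1 − r_xm²); setting a·b/c = proportion and
    solving for r_my gives the closed form below.
    """
    if r_xm == 0:
        raise ValueError("r_xm must be nonzero")
    b = proportion * r_xy / r_xm
    return b * (1.0 - r_xm ** 2) + r_xy * r_xm


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    mean: float
    ci_low: float
    ci_high: float


def one_sample_t(values) -> TTestResult:
    """Two-sided one-sample t-test of the mean against zero, with 95% CI."""
    v = np.asarray(values, dtype=float)
    n = v.shape[0]
    if n < 3:
        raise ValueError("need at least 3 observations")
    sd = v.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("zero variance input")
    se = sd / np.sqrt(n)
    mean = float(v.mean())
    t = mean / se
    p = float(2 * sps.t.sf(abs(t), n - 1))
    half = sps.t.ppf(0.975, n - 1) * se
    return TTestResult(t=float(t), df=n - 1, p=p, mean=mean,
                       ci_low=mean - half, ci_high=mean + half)


def compensation_screen(responsivity, ages, scores, older_mask,
                        covariates=None, alpha: float = 0.01):
    """Screen components for signatures of functional compensation.

    ``responsivity``: subjects x components array of responsivity values.
    Two uncorrected tests per component:

    * Test 1 (recruitment) — for positively activated components
      (cohort-mean responsivity > 0), a positive correlation between
      responsivity and age within the older group at p < alpha.
    * Test 2 (performance coupling) — a positive responsivity x age
      interaction in predicting score at p < alpha, over the whole cohort.

    Returns a list of per-component dicts with both tests' statistics and
    flags.
    """
    R = np.asarray(responsivity, dtype=float)
    ages = np.asarray(ages, dtype=float)
    scores = np.asarray(scores, dtype=float)
    older_mask = np.asarray(older_mask, dtype=bool)
    if not older_mask.any():
        raise ValueError("older group is empty")
    cov = _as_matrix(covariates) if covariates is not None else None
    cov_older = None
    if cov is not None:
        co = cov[older_mask]
        # covariate columns constant within the older group are absorbed
        # by the intercept; keep only informative columns
        keep = co.std(axis=0) > 0
        cov_older = co[:, keep] if keep.any() else None
    out = []
    for j in range(R.shape[1]):
        rj = R[:, j]
        activated = rj.mean() > 0
        rec_r = rec_p = None
        rec_flag = False
        if activated and older_mask.sum() >= 4:
            ro = residualize(rj[older_mask], cov_older)
            ao = residualize(ages[older_mask], cov_older)
            cr = pearson_ci(ro, ao)
            rec_r, rec_p = cr.r, cr.p
            rec_flag = (cr.r > 0) and (cr.p < alpha)
        mod = moderation_test(scores, rj, ages, covariates=cov)
        mod_flag = (mod.interaction_coef > 0) and (mod.p < alpha)
        out.append({
            "component": j, "activated": bool(activated),
            "test1_r": rec_r, "test1_p": rec_p, "test1_flag": bool(rec_flag),
            "test2_coef": mod.interaction_coef, "test2_partial_r2":
                mod.partial_r2, "test2_p": mod.p, "test2_flag": bool(mod_flag),
        })
    return out


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH-adjusted p-values (optional convenience; off by default upstream)."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        k = n - rank_from_top
        prev = min(prev, p[idx] * n / k)
        adj[idx] = prev
    return adj
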