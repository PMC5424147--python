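"""Condition-specific functional connectivity between components.

Component time-courses are first cleaned of motion (the 6 realignment
parameters expanded to 24: parameters, first-difference derivatives, and
the squares of both) and of the HRF-convolved conditions of non-interest.
Connectivity is the Fisher z-transformed Pearson correlation of a component
pair's residual activity restricted to volumes where at least one
condition-of-interest regressor exceeds a threshold (0.05 on regressors
normalized so a long block plateaus at 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DesignMatrix
from .stats import one_sample_t

MASK_THRESHOLD = 0.05
MIN_COVERAGE = 10
_Z_CLIP = 1.0 - 1e-15


class InsufficientCoverageError(ValueError):
    pass


def expand_motion_parameters(motion: np.ndarray) -> np.ndarray:
    """Expand 6 realignment parameters to the 24-parameter set:
    [params, first-difference derivatives, squared params, squared
    derivatives]."""
    m = np.asarray(motion, dtype=float)
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError("expected an n_volumes x 6 motion array")
    d = np.vstack([np.zeros((1, 6)), np.diff(m, axis=0)])
    return np.column_stack([m, d, m ** 2, d ** 2])


def clean_timecourse_fc(timecourse: np.ndarray, motion: np.ndarray,
                        nuisance_regressors: np.ndarray | None = None
                        ) -> np.ndarray:
    """Residualize a component time-course on [intercept, 24 motion
    regressors, HRF-convolved conditions of non-interest].

    Collinear columns are dropped with a warning rather than failing.
    """
    tc = np.asarray(timecourse, dtype=float)
    cols = [np.ones(len(tc)), expand_motion_parameters(motion)]
    if nuisance_regressors is not None and \
            np.asarray(nuisance_regressors).size:
        nr = np.asarray(nuisance_regressors, dtype=float)
        if nr.ndim == 1:
            nr = nr[:, None]
        cols.append(nr)
    X = np.column_stack(cols)
    # drop collinear columns by rank-revealing QR-style greedy pass
    keep = []
    for j in range(X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
    if len(keep) < X.shape[1]:
        warnings.warn(f"dropped {X.shape[1] - len(keep)} collinear "
                      "nuisance columns")
    X = X[:, keep]
    beta, *_ = np.linalg.lstsq(X, tc, rcond=None)
    return tc - X @ beta


def condition_mask(design: DesignMatrix,
                   threshold: float = MASK_THRESHOLD) -> np.ndarray:
    """Boolean volume mask: True where at least one condition-of-interest
    regressor exceeds the threshold."""
    more, less = design.interest_columns()
    mask = (more > threshold) | (less > threshold)
    if not mask.any():
        raise InsufficientCoverageError(
            "no volume exceeds the condition mask threshold")
    return mask


def condition_fc(tc_i: np.ndarray, tc_j: np.ndarray,
                 mask: np.ndarray, min_coverage: int = MIN_COVERAGE
                 ) -> float:
    """Fisher z (atanh r) of the Pearson correlation between two component
    time-courses over the masked volumes.  |r| = 1 is clipped just inside
    the boundary so z stays finite."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < min_coverage:
        raise InsufficientCoverageError(
            f"mask covers {int(mask.sum())} volumes < {min_coverage}")
    a = np.asarray(tc_i, dtype=float)[mask]
    b = np.asarray(tc_j, dtype=float)[mask]
    if a.std() == 0 or b.std() == 0:
        return 0.0
    r = float(np.corrcoef(a, b)[0, 1])
    r = float(np.clip(r, -_Z_CLIP, _Z_CLIP))
    return float(np.arctanh(r))


def fc_matrix(timecourses: np.ndarray, mask: np.ndarray,
              motion: np.ndarray | None = None,
              nuisance: np.ndarray | None = None) -> np.ndarray:
    """Symmetric Fisher-z FC matrix for (n_volumes x k) time-courses of one
    subject/task, after motion/nuisance cleaning (if given).  Diagonal is
    NaN."""
    tcs = np.asarray(timecourses, dtype=float)
    if motion is not None:
        tcs = np.column_stack([
            clean_timecourse_fc(tcs[:, c], motion, nuisance)
            for c in range(tcs.shape[1])])
    k = tcs.shape[1]
    Z = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            z = condition_fc(tcs[:, i], tcs[:, j], mask)
            Z[i, j] = Z[j, i] = z
    return Z


@dataclass
class GroupFCSummary:
    mean_z: float
    ci_low: float
    ci_high: float
    t: float
    p: float
    n_subjects: int
    n_pairs: int


def group_fc_summary(fc_by_subject: list, set_a, set_b) -> GroupFCSummary:
    """Mean inter-set FC across subjects with a one-sample t-test against 0.

    ``fc_by_subject``: list of symmetric z matrices; ``set_a``/``set_b``:
    disjoint component index sets (e.g. task-positive vs default-mode).
    The per-subject statistic is the mean z over all (a, b) pairs.
    """
    a = np.asarray(list(set_a), dtype=int)
    b = np.asarray(list(set_b), dtype=int)
    if a.size == 0 or b.size == 0:
        raise ValueError("component sets must be nonempty")
    if np.intersect1d(a, b).size:
        raise ValueError("component sets must be disjoint")
    per_subject = np.array([Z[np.ix_(a, b)].mean() for Z in fc_by_subject])
    tt = one_sample_t(per_subject)
    return GroupFCSummary(mean_z=tt.mean, ci_low=tt.ci_low,
                          ci_high=tt.ci_high, t=tt.t, p=tt.p,
                          n_subjects=len(per_subject),
                          n_pairs=int(a.size * b.size))


def fc_long_table(fc_by_key: dict) -> pd.DataFrame:
    """Long-format FC table (key, comp_i, comp_j, z) for persistence."""
    rows = []
    for key, Z in fc_by_key.items():
        k = Z.shape[0]
        for i in range(k):
            for j in range(i + 1, k):
                rows.append({"key": str(key), "comp_i": i, "comp_j": j,
                             "z": Z[i, j]})
    return pd.DataFrame(rows)
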