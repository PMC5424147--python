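"""Component classification: map thresholding, spectral and tissue metrics,
non-neural exclusion and default-mode identification.

A component is kept as neural when its (subject-averaged) time-course has a
low-to-high frequency power ratio >= 0.65 and a spectral dynamic range
>= 0.0175, and its thresholded spatial map has >= 75% loading-weighted
overlap with the grey-matter mask.  Spectral conventions (band edges
0.01-0.10 Hz vs 0.15-0.25 Hz; dynamic range = peak power minus the minimum
power above the peak, on the unit-total-power spectrum) are declared here
and configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import welch

from .preprocess import GridError

LOW_BAND = (0.01, 0.10)
HIGH_BAND = (0.15, 0.25)

RATIO_THRESHOLD = 0.65
DYNAMIC_RANGE_THRESHOLD = 0.0175
GM_OVERLAP_THRESHOLD = 0.75
DM_OVERLAP_THRESHOLD = 0.5


@dataclass(frozen=True)
class ThresholdedMap:
    retained: np.ndarray          # boolean, voxels
    loadings: np.ndarray          # original loadings (zero outside retained)
    threshold: float
    converged: bool

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())


def _em_two_gaussians(x: np.ndarray, max_iter: int = 200,
                      tol: float = 1e-8):
    """EM for a two-component Gaussian mixture (null + signal with larger
    mean).  Returns (pi, mu, sigma, converged)."""
    mu = np.array([np.percentile(x, 30), np.percentile(x, 95)])
    if mu[1] - mu[0] < 1e-12:
        return None
    sd = np.array([x.std(), x.std()]) + 1e-12
    pi = np.array([0.8, 0.2])
    prev = -np.inf
    for _ in range(max_iter):
        logp = (np.log(pi)[:, None]
                - 0.5 * np.log(2 * np.pi * sd[:, None] ** 2)
                - 0.5 * ((x[None, :] - mu[:, None]) / sd[:, None]) ** 2)
        m = logp.max(axis=0)
        lse = m + np.log(np.exp(logp - m).sum(axis=0))
        resp = np.exp(logp - lse)
        ll = lse.sum()
        nk = resp.sum(axis=1) + 1e-300
        pi = nk / len(x)
        mu = (resp @ x) / nk
        sd = np.sqrt((resp * (x[None, :] - mu[:, None]) ** 2).sum(axis=1)
                     / nk) + 1e-12
        if abs(ll - prev) < tol * (abs(prev) + 1):
            order = np.argsort(mu)
            return pi[order], mu[order], sd[order], True
        prev = ll
    order = np.argsort(mu)
    return pi[order], mu[order], sd[order], False


def threshold_map_mixture(loadings: np.ndarray) -> ThresholdedMap:
    """Threshold a spatial map with a two-Gaussian mixture model.

    Voxels whose posterior probability of belonging to the larger-mean
    (signal) Gaussian exceeds 0.5 are retained.  Degenerate maps return an
    empty set; EM non-convergence falls back to a z > 2 cut with a warning.
    """
    x = np.asarray(loadings, dtype=float).ravel()
    if x.shape[0] < 100:
        raise ValueError("need at least 100 voxels to fit the mixture")
    if np.allclose(x, x[0]):
        return ThresholdedMap(retained=np.zeros_like(x, dtype=bool),
                              loadings=np.zeros_like(x),
                              threshold=np.inf, converged=False)
    fit = _em_two_gaussians(x)
    if fit is None or not fit[3]:
        warnings.warn("mixture EM did not converge; falling back to z > 2")
        z = (x - x.mean()) / x.std()
        retained = z > 2.0
        thr = x.mean() + 2.0 * x.std()
    else:
        pi, mu, sd, _ = fit
        log_null = np.log(pi[0] + 1e-300) - np.log(sd[0]) \
            - 0.5 * ((x - mu[0]) / sd[0]) ** 2
        log_sig = np.log(pi[1] + 1e-300) - np.log(sd[1]) \
            - 0.5 * ((x - mu[1]) / sd[1]) ** 2
        retained = log_sig > log_null
        # guard against a degenerate fit swallowing the whole map
        if retained.mean() > 0.9:
            warnings.warn("mixture fit degenerate; falling back to z > 2")
            z = (x - x.mean()) / x.std()
            retained = z > 2.0
        above = x[retained]
        thr = float(above.min()) if retained.any() else np.inf
    kept = np.where(retained, x, 0.0)
    return ThresholdedMap(retained=retained, loadings=kept,
                          threshold=float(thr), converged=True)


def equal_variance_crossing(mu0: float, mu1: float, sigma: float,
                            pi0: float = 0.5) -> float:
    """Posterior crossing point of two equal-variance Gaussians (closed
    form) — the decision threshold the mixture implies."""
    if mu1 == mu0:
        raise ValueError("means must differ")
    pi1 = 1.0 - pi0
    return 0.5 * (mu0 + mu1) + sigma ** 2 * np.log(pi0 / pi1) / (mu1 - mu0)


def tissue_overlap(thresholded: ThresholdedMap, mask: np.ndarray) -> float:
    """Loading-weighted overlap of retained voxels with a tissue mask:
    sum(|loading| * mask) / sum(|loading|).  NaN for empty retained sets
    (component auto-excluded upstream)."""
    mask = np.asarray(mask, dtype=bool).ravel()
    if mask.shape[0] != thresholded.loadings.shape[0]:
        raise GridError("mask grid does not match map")
    w = np.abs(thresholded.loadings)
    total = w.sum()
    if total == 0:
        return float("nan")
    return float((w * mask).sum() / total)


def spectral_metrics(timecourse: np.ndarray, tr: float,
                     low_band=LOW_BAND, high_band=HIGH_BAND) -> tuple:
    """(low_high_ratio, dynamic_range) of a component time-course.

    Welch power spectrum normalized to unit total power; ratio = mean power
    in the low band / mean power in the high band (inf when the high band
    is empty of power); dynamic range = peak power minus the minimum power
    at frequencies above the peak.
    """
    if tr <= 0:
        raise ValueError("TR must be positive")
    x = np.asarray(timecourse, dtype=float)
    if x.shape[0] < 64:
        raise ValueError("need at least 64 volumes for spectral metrics")
    fs = 1.0 / tr
    nperseg = min(128, x.shape[0])
    freqs, power = welch(x, fs=fs, nperseg=nperseg)
    total = power.sum()
    if total <= 0:
        return 0.0, 0.0
    power = power / total
    low = power[(freqs >= low_band[0]) & (freqs <= low_band[1])]
    high = power[(freqs >= high_band[0]) & (freqs <= high_band[1])]
    low_mean = low.mean() if len(low) else 0.0
    high_mean = high.mean() if len(high) else 0.0
    ratio = float(low_mean / high_mean) if high_mean > 0 else float("inf")
    peak = int(np.argmax(power))
    after = power[peak:]
    dynamic_range = float(power[peak] - after.min())
    return ratio, dynamic_range


def component_metrics(subject_timecourses: dict, group_maps: np.ndarray,
                      masks: dict, tr_by_key=None,
                      tr: float = 1.97) -> pd.DataFrame:
    """Metrics table per component: spectral metrics averaged over the
    subject/task time-courses, plus tissue overlaps of the thresholded
    group maps.

    ``subject_timecourses``: {key: (n_volumes x k) array}.
    ``masks``: {"gm": ..., "wm": ..., "csf": ...} boolean grids.
    """
    k = group_maps.shape[0]
    ratios = np.zeros(k)
    dranges = np.zeros(k)
    n_keys = 0
    for key, tcs in subject_timecourses.items():
        this_tr = tr if tr_by_key is None else tr_by_key(key)
        for c in range(k):
            r, d = spectral_metrics(tcs[:, c], this_tr)
            ratios[c] += min(r, 1e6)     # cap inf for averaging
            dranges[c] += d
        n_keys += 1
    ratios /= max(n_keys, 1)
    dranges /= max(n_keys, 1)
    rows = []
    for c in range(k):
        thr = threshold_map_mixture(group_maps[c])
        rows.append({
            "component": c,
            "low_high_ratio": ratios[c],
            "dynamic_range": dranges[c],
            "gm_overlap": tissue_overlap(thr, masks["gm"]),
            "wm_overlap": tissue_overlap(thr, masks["wm"]),
            "csf_overlap": tissue_overlap(thr, masks["csf"]),
            "n_retained": thr.n_retained,
        })
    return pd.DataFrame(rows)


def classify_components(metrics: pd.DataFrame,
                        ratio_threshold: float = RATIO_THRESHOLD,
                        dynamic_range_threshold: float =
                        DYNAMIC_RANGE_THRESHOLD,
                        gm_threshold: float = GM_OVERLAP_THRESHOLD,
                        motor_exclude: tuple = ()) -> pd.DataFrame:
    """Flag components as neural/non-neural from the metrics table.

    neural <=> ratio >= 0.65 AND dynamic range >= 0.0175 AND grey-matter
    overlap >= 0.75.  Components with empty thresholded maps (NaN overlap)
    are excluded.  ``motor_exclude`` lists component ids removed by
    explicit judgment (e.g. primary motor components driven by response
    execution); they keep neural=True but get motor_excluded=True.
    """
    out = metrics.copy()
    gm = out["gm_overlap"].to_numpy()
    neural = ((out["low_high_ratio"] >= ratio_threshold)
              & (out["dynamic_range"] >= dynamic_range_threshold)
              & ~np.isnan(gm) & (gm >= gm_threshold))
    out["neural"] = neural
    out["motor_excluded"] = out["component"].isin(motor_exclude)
    out["included"] = out["neural"] & ~out["motor_excluded"]
    return out


def identify_dm(group_maps: np.ndarray, dm_templates: dict,
                overlap_threshold: float = DM_OVERLAP_THRESHOLD,
                candidates=None) -> pd.DataFrame:
    """Rank components by loading-weighted overlap with the default-mode
    template (union of region masks) and select members above threshold.

    Returns a table (component, dm_overlap, best_region, dm_member,
    dm_medial) where dm_medial excludes members whose dominant region is
    lateral parietal.
    """
    union = np.zeros(group_maps.shape[1], dtype=bool)
    region_masks = {}
    for label, m in dm_templates.items():
        flat = np.asarray(m, dtype=bool).ravel()
        region_masks[label] = flat
        union |= flat
    rows = []
    comp_ids = range(group_maps.shape[0]) if candidates is None else candidates
    for c in comp_ids:
        thr = threshold_map_mixture(group_maps[c])
        ov = tissue_overlap(thr, union)
        per_region = {lab: tissue_overlap(thr, m)
                      for lab, m in region_masks.items()}
        best = max(per_region, key=lambda k: (per_region[k]
                                              if np.isfinite(per_region[k])
                                              else -1))
        member = bool(np.isfinite(ov) and ov >= overlap_threshold)
        rows.append({"component": c, "dm_overlap": ov,
                     "best_region": best, "dm_member": member,
                     "dm_medial": member and best not in
                     ("ipl_left", "ipl_right")})
    df = pd.DataFrame(rows).sort_values("dm_overlap", ascending=False)
    if not df["dm_member"].any():
        warnings.warn("no component exceeds the DM overlap threshold")
    return df.reset_index(drop=True)
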