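"""Task scores from trial tables and age-windowed outlier exclusion.

Three score types are supported, one per task family:

* fluid reasoning (self-paced block task): hits-minus-misses,
  hard_correct − hard_incorrect + easy_correct − easy_incorrect;
* picture naming: percent correct, with a synonym map and with
  scrambled-image baseline trials excluded from the denominator;
* sentence comprehension: reaction-time contrast in ms between the
  subordinate (most syntactic reinterpretation) and unambiguous conditions,
  computed on inverse-transformed RTs (1000/RT) whose condition means are
  reverse-transformed back to ms; anticipatory responses (<200 ms) dropped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class InsufficientTrialsError(ValueError):
    pass


def score_fluid(hard_correct: int, hard_incorrect: int,
                easy_correct: int, easy_incorrect: int) -> int:
    """Hits-minus-misses score balancing speed and accuracy."""
    counts = (hard_correct, hard_incorrect, easy_correct, easy_incorrect)
    if any(c < 0 for c in counts):
        raise ValueError("trial counts must be non-negative")
    return hard_correct - hard_incorrect + easy_correct - easy_incorrect


def score_naming(trials: pd.DataFrame, synonyms: dict | None = None,
                 target_col: str = "target", response_col: str = "response",
                 condition_col: str = "condition",
                 baseline_condition: str = "scrambled") -> float:
    """Percent of correctly named picture trials.

    A response is correct if it equals the target or is listed in the
    synonym map for that target.  Baseline (scrambled-image) trials do not
    enter the denominator.
    """
    synonyms = synonyms or {}
    scored = trials[trials[condition_col] != baseline_condition]
    if len(scored) == 0:
        raise InsufficientTrialsError("no scorable naming trials")
    def ok(row):
        resp = str(row[response_col]).strip().lower()
        tgt = str(row[target_col]).strip().lower()
        if resp == tgt:
            return True
        accepted = {s.strip().lower() for s in synonyms.get(tgt, ())}
        return resp in accepted
    n_correct = int(scored.apply(ok, axis=1).sum())
    return 100.0 * n_correct / len(scored)


def score_sentence_rt(trials: pd.DataFrame, rt_col: str = "rt_ms",
                      condition_col: str = "condition",
                      more_demanding: str = "subordinate",
                      less_demanding: str = "unambiguous",
                      min_rt_ms: float = 200.0) -> float:
    """Subordinate − unambiguous RT difference (ms) on inverse-transformed RTs.

    Per condition: drop RT < 200 ms, take the mean of 1000/RT, then
    reverse-transform (1000/mean) so the result is in ms; slower responding
    to subordinate sentences gives a positive difference.
    """
    means = {}
    for cond in (more_demanding, less_demanding):
        rts = trials.loc[trials[condition_col] == cond, rt_col].to_numpy(
            dtype=float)
        rts = rts[rts >= min_rt_ms]
        if len(rts) == 0:
            raise InsufficientTrialsError(
                f"no valid trials in condition {cond!r}")
        means[cond] = 1000.0 / np.mean(1000.0 / rts)
    return means[more_demanding] - means[less_demanding]


def sliding_window_outliers(scores, ages, half_width: float = 15.0,
                            z_thresh: float = 2.5,
                            min_window: int = 3) -> np.ndarray:
    """Flag subjects whose score is an outlier within their age window.

    For each subject, the window is every subject with |age − age_s| <=
    half_width (the subject included); the subject is flagged when
    |score_s − window mean| > z_thresh x window s.d. (sample s.d., n−1).
    Flags are computed simultaneously from the original data — no
    iterative re-exclusion.  Windows smaller than ``min_window`` never
    flag.
    """
    scores = np.asarray(scores, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if scores.shape != ages.shape:
        raise ValueError("scores and ages must be aligned")
    n = len(scores)
    flags = np.zeros(n, dtype=bool)
    for i in range(n):
        window = np.abs(ages - ages[i]) <= half_width
        if window.sum() < min_window:
            continue
        w = scores[window]
        sd = w.std(ddof=1)
        if sd == 0:
            continue
        flags[i] = abs(scores[i] - w.mean()) > z_thresh * sd
    return flags
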