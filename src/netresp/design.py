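"""Haemodynamic response modelling and task design matrices.

Condition regressors are built by convolving unit-height boxcars (one per
event, width = duration) with a canonical double-gamma HRF on a fine time
grid, then sampling at volume acquisition times.  The HRF kernel is scaled
so that the convolution of a long block plateaus at exactly 1: this fixes
the physical scale of the regressors, which matters downstream where a
fixed threshold (e.g. 0.05) is applied to regressor values to define
condition-specific time windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as _gamma_dist


def double_gamma_hrf(dt: float, duration: float = 32.0,
                     peak_delay: float = 6.0, undershoot_delay: float = 16.0,
                     peak_disp: float = 1.0, undershoot_disp: float = 1.0,
                     ratio: float = 6.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at resolution ``dt`` seconds.

    Parameters follow the common convention (peak at ~6 s, undershoot at
    ~16 s, peak:undershoot ratio 6, 32 s support).  The kernel is scaled so
    that ``sum(kernel) * dt == 1``, i.e. convolution with a unit boxcar of
    long duration plateaus at 1.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0, duration + dt, dt)
    peak = _gamma_dist.pdf(t, peak_delay / peak_disp, scale=peak_disp)
    under = _gamma_dist.pdf(t, undershoot_delay / undershoot_disp,
                            scale=undershoot_disp)
    h = peak - under / ratio
    area = h.sum() * dt
    return h / area


@dataclass(frozen=True)
class Condition:
    """One task condition: named set of events (onsets/durations, seconds)."""
    name: str
    onsets: tuple
    durations: tuple

    def __post_init__(self):
        if len(self.onsets) != len(self.durations):
            raise ValueError("onsets and durations must have equal length")
        if any(d < 0 for d in self.durations):
            raise ValueError("durations must be non-negative")


@dataclass(frozen=True)
class DesignMatrix:
    """HRF-convolved condition regressors on a volume grid.

    ``conditions_of_interest`` is the ordered (more_demanding,
    less_demanding) pair used for the responsivity contrast.
    """
    condition_names: tuple
    regressors: np.ndarray          # n_volumes x n_conditions
    tr: float
    conditions_of_interest: tuple   # (more_demanding, less_demanding)

    def __post_init__(self):
        more, less = self.conditions_of_interest
        if more == less:
            raise ValueError("conditions of interest must be distinct")
        for c in (more, less):
            if c not in self.condition_names:
                raise ValueError(f"condition of interest {c!r} not in design")
        if not np.all(np.isfinite(self.regressors)):
            raise ValueError("regressors must be finite")

    @property
    def n_volumes(self) -> int:
        return self.regressors.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.regressors[:, self.condition_names.index(name)]

    def interest_columns(self) -> tuple:
        more, less = self.conditions_of_interest
        return self.column(more), self.column(less)

    def nuisance_columns(self) -> np.ndarray:
        """Regressors of the conditions of non-interest (may be empty)."""
        keep = [i for i, n in enumerate(self.condition_names)
                if n not in self.conditions_of_interest]
        return self.regressors[:, keep]


def convolve_condition(cond: Condition, n_volumes: int, tr: float,
                       oversample: int = 16) -> np.ndarray:
    """HRF-convolved regressor for one condition, sampled at volume times.

    Events beyond the end of the run raise an error.
    """
    if tr <= 0:
        raise ValueError("TR must be positive")
    run_len = n_volumes * tr
    for onset in cond.onsets:
        if onset < 0 or onset >= run_len:
            raise ValueError(
                f"onset {onset}s outside run of length {run_len}s")
    dt = tr / oversample
    n_fine = int(np.ceil(run_len / dt)) + 1
    box = np.zeros(n_fine)
    tfine = np.arange(n_fine) * dt
    for onset, dur in zip(cond.onsets, cond.durations):
        box[(tfine >= onset) & (tfine < onset + dur)] = 1.0
    h = double_gamma_hrf(dt)
    reg_fine = np.convolve(box, h)[:n_fine] * dt
    vol_idx = np.round(np.arange(n_volumes) * tr / dt).astype(int)
    return reg_fine[vol_idx]


def build_design(conditions: list, n_volumes: int, tr: float,
                 conditions_of_interest: tuple,
                 oversample: int = 16) -> DesignMatrix:
    """Assemble a DesignMatrix from a list of :class:`Condition`."""
    names = tuple(c.name for c in conditions)
    if len(set(names)) != len(names):
        raise ValueError("duplicate condition names")
    regs = np.column_stack([
        convolve_condition(c, n_volumes, tr, oversample) for c in conditions])
    return DesignMatrix(condition_names=names, regressors=regs, tr=tr,
                        conditions_of_interest=tuple(conditions_of_interest))
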