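"""Synthetic multi-subject task-fMRI generator with planted ground truth.

The generator emulates the structure the analysis pipeline assumes: each
subject's BOLD signal is a linear mixture of spatial components (smooth
Gaussian blobs) whose time-courses contain HRF-convolved condition
responses with subject-specific amplitudes.  Condition-contrast amplitudes
("responsivity" ground truth) decline with age for the task-positive
components, load on a latent per-subject efficiency factor that also
drives behavioural scores, and are negative for default-mode-like
components.  Non-neural components carry band-limited high-frequency
(vascular-band) or white-noise time-courses and sit over white-matter/CSF
territory, giving the component classifier true positives and negatives.

Everything is a pure function of (spec, seed): identical inputs give
identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import Condition, DesignMatrix, build_design


class InvalidSpecError(ValueError):
    pass


# --------------------------------------------------------------------------
# Cohort
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Cohort of healthy adults spanning the adult lifespan."""
    n_subjects: int = 98
    age_range: tuple = (23.0, 87.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 4:
            raise InvalidSpecError("n_subjects must be >= 4")
        if not self.age_range[0] < self.age_range[1]:
            raise InvalidSpecError("age range must have min < max")


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort table: age (uniform on range), education (ordinal 1-4),
    handedness (-100..100), gender (binary), and a latent neural-efficiency
    factor ``latent_g`` used to couple brain responsivity and behaviour.
    """
    rng = np.random.default_rng([spec.seed, 101])
    n = spec.n_subjects
    lo, hi = spec.age_range
    ages = rng.uniform(lo, hi, n)
    education = rng.choice([1, 2, 3, 4], size=n, p=[0.05, 0.10, 0.20, 0.65])
    handedness = np.clip(rng.normal(60, 40, n), -100, 100)
    gender = rng.integers(0, 2, n)
    latent_g = rng.standard_normal(n)
    return pd.DataFrame({
        "subject": [f"sub-{i:03d}" for i in range(n)],
        "age": ages,
        "education": education,
        "handedness": handedness,
        "gender": gender,
        "latent_g": latent_g,
    })


def zscore_age(ages, age_range=(23.0, 87.0)) -> np.ndarray:
    """Standardize age against the design range of a uniform cohort."""
    lo, hi = age_range
    mid = 0.5 * (lo + hi)
    sd = (hi - lo) / np.sqrt(12.0)
    return (np.asarray(ages, dtype=float) - mid) / sd


def age_group_masks(ages, bounds=((23, 45), (46, 64), (65, 87))):
    """Boolean masks (young, middle, older) from age-group bounds."""
    ages = np.asarray(ages, dtype=float)
    return tuple((ages >= lo) & (ages <= hi + 1) for lo, hi in bounds)


# --------------------------------------------------------------------------
# Scenario specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AmplitudeModel:
    """Condition-amplitude model for one component in one task.

    amplitude(less_demanding) = base
    amplitude(more_demanding) = base + contrast + age_slope * z(age)
                                + perf_loading * g + sd * eps
    Other (nuisance) conditions get the base amplitude.
    """
    base: float = 0.0
    contrast: float = 0.0
    age_slope: float = 0.0
    perf_loading: float = 0.0
    sd: float = 0.0


@dataclass(frozen=True)
class ComponentSpec:
    name: str
    center: tuple                 # voxel coordinates
    sigma: float
    kind: str                     # neural | dm | vascular | noise
    amplitudes: dict = field(default_factory=dict)   # task -> AmplitudeModel
    fc_weight: float = 0.0        # loading on shared low-frequency factor

    def __post_init__(self):
        if self.kind not in ("neural", "dm", "vascular", "noise"):
            raise InvalidSpecError(f"unknown component kind {self.kind!r}")
        if self.sigma <= 0:
            raise InvalidSpecError("sigma must be positive")


@dataclass(frozen=True)
class TaskSpec:
    name: str
    tr: float
    n_volumes: int
    conditions: tuple             # of design.Condition
    conditions_of_interest: tuple
    # behavioural score model: score = offset + scale*(age_slope*z_age
    #                                   + perf_loading*g + noise_sd*eta)
    score_offset: float = 0.0
    score_scale: float = 1.0
    score_age_slope: float = 0.0
    score_perf_loading: float = 1.0
    score_noise_sd: float = 0.5

    def __post_init__(self):
        if self.tr <= 0:
            raise InvalidSpecError("TR must be positive")
        run_len = self.n_volumes * self.tr
        for c in self.conditions:
            for onset in c.onsets:
                if onset >= run_len:
                    raise InvalidSpecError(
                        f"onset {onset}s beyond run end {run_len}s "
                        f"in condition {c.name!r}")

    def design(self) -> DesignMatrix:
        return build_design(list(self.conditions), self.n_volumes, self.tr,
                            self.conditions_of_interest)


@dataclass(frozen=True)
class GenerativeScenario:
    grid_shape: tuple
    components: tuple             # of ComponentSpec
    tasks: tuple                  # of TaskSpec
    voxel_noise_sd: float = 1.0
    tc_noise_sd: float = 1.0      # baseline component time-course noise
    fc_factor_sd: float = 1.0     # shared factor driving inter-component FC
    ar_coefficient: float = 0.0   # optional AR(1) on voxel noise

    def __post_init__(self):
        if self.voxel_noise_sd < 0 or self.tc_noise_sd < 0:
            raise InvalidSpecError("noise sds must be non-negative")
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise InvalidSpecError("duplicate component names")

    @property
    def n_components(self) -> int:
        return len(self.components)

    def task(self, name: str) -> TaskSpec:
        for t in self.tasks:
            if t.name == name:
                return t
        raise KeyError(name)

    def component_kinds(self) -> np.ndarray:
        return np.array([c.kind for c in self.components])


# --------------------------------------------------------------------------
# Spatial structure
# --------------------------------------------------------------------------

def component_maps(scenario: GenerativeScenario) -> np.ndarray:
    """Ground-truth spatial maps, (n_components, n_voxels), blob peak = 1."""
    nx, ny, nz = scenario.grid_shape
    xs, ys, zs = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    maps = np.empty((scenario.n_components, nx * ny * nz))
    for i, comp in enumerate(scenario.components):
        cx, cy, cz = comp.center
        d2 = (xs - cx) ** 2 + (ys - cy) ** 2 + (zs - cz) ** 2
        maps[i] = np.exp(-d2 / (2.0 * comp.sigma ** 2)).ravel()
    return maps


def tissue_masks(grid_shape) -> dict:
    """Synthetic tissue segmentation of the grid.

    The bottom two slices form the non-grey zone (CSF for x < nx/2, WM for
    x >= nx/2); everything above is grey matter.  Non-neural components are
    placed in the non-grey zone.
    """
    nx, ny, nz = grid_shape
    gm = np.zeros(grid_shape, dtype=bool)
    wm = np.zeros(grid_shape, dtype=bool)
    csf = np.zeros(grid_shape, dtype=bool)
    gm[:, :, 2:] = True
    csf[: nx // 2, :, :2] = True
    wm[nx // 2:, :, :2] = True
    return {"gm": gm, "wm": wm, "csf": csf}


#: canonical default-mode region slots on the synthetic grid (label, center)
DM_REGION_CENTERS = (
    ("mpfc_ventral", (2.5, 6.5, 7.5)),
    ("mpfc_dorsal", (2.5, 6.5, 10.5)),
    ("pcc", (10.5, 6.5, 7.5)),
    ("precuneus", (13.5, 6.5, 10.5)),
    ("ipl_left", (6.5, 2.5, 7.5)),
    ("ipl_right", (6.5, 13.5, 7.5)),
)

DM_LATERAL_REGIONS = ("ipl_left", "ipl_right")


def dm_template_masks(grid_shape, radius: float = 2.5) -> dict:
    """Coarse synthetic default-mode region masks (stand-ins for canonical
    medial prefrontal, posterior cingulate, precuneus and lateral parietal
    regions), as balls around the designated DM slots."""
    nx, ny, nz = grid_shape
    xs, ys, zs = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    masks = {}
    for label, (cx, cy, cz) in DM_REGION_CENTERS:
        d2 = (xs - cx) ** 2 + (ys - cy) ** 2 + (zs - cz) ** 2
        masks[label] = d2 <= radius ** 2
    return masks


# --------------------------------------------------------------------------
# Default scenario
# --------------------------------------------------------------------------

def _fi_task() -> TaskSpec:
    """Block-design fluid-reasoning-like task: 30 s hard/easy blocks
    alternating, four blocks per condition, TR 1.97 s, 150 volumes."""
    hard = Condition("hard", onsets=(10.0, 70.0, 130.0, 190.0),
                     durations=(30.0,) * 4)
    easy = Condition("easy", onsets=(40.0, 100.0, 160.0, 220.0),
                     durations=(30.0,) * 4)
    return TaskSpec(
        name="FI", tr=1.97, n_volumes=150, conditions=(hard, easy),
        conditions_of_interest=("hard", "easy"),
        score_offset=20.0, score_scale=6.0,
        score_age_slope=-0.68, score_perf_loading=0.385,
        score_noise_sd=0.624)


def _pn_task() -> TaskSpec:
    """Event-related picture-naming-like task: brief picture events with
    interleaved scrambled-image baseline events."""
    pic_onsets = tuple(np.arange(8.0, 280.0, 9.0))      # 31 events
    scr_onsets = tuple(np.arange(12.5, 280.0, 27.0))    # 10 events
    pic = Condition("picture", onsets=pic_onsets,
                    durations=(1.0,) * len(pic_onsets))
    scr = Condition("scrambled", onsets=scr_onsets,
                    durations=(1.0,) * len(scr_onsets))
    return TaskSpec(
        name="PN", tr=1.97, n_volumes=150, conditions=(pic, scr),
        conditions_of_interest=("picture", "scrambled"),
        score_offset=85.0, score_scale=6.0,
        score_age_slope=-0.59, score_perf_loading=0.30,
        score_noise_sd=0.75)


def default_scenario(n_other: int = 14, include_pn: bool = True,
                     voxel_noise_sd: float = 1.0) -> GenerativeScenario:
    """Default 30-component scenario on a 16 x 16 x 12 grid.

    Components: 4 task-positive signal components (positive condition
    contrast declining with age and loading on the latent performance
    factor), 6 default-mode components (suppressed, suppression weakening
    with age), ``n_other`` weakly/non-responsive neural components, 4
    vascular-band components and 2 white-noise components over WM/CSF.
    """
    tasks = [_fi_task()] + ([_pn_task()] if include_pn else [])

    # grey-matter lattice slots (z >= 4.5), excluding the 6 DM slots
    lattice = [(x, y, z)
               for x in (2.5, 6.5, 10.5, 13.5)
               for y in (2.5, 6.5, 10.5, 13.5)
               for z in (4.5, 7.5, 10.5)]
    dm_centers = [c for _, c in DM_REGION_CENTERS]
    free = [p for p in lattice if p not in dm_centers]

    comps = []
    # -- task-positive signal components -------------------------------
    # Contrast bases fix the responsivity ranking (top four); the age
    # slopes and performance loadings grow along the ranking so that the
    # fourth component still adds real predictive signal, mirroring the
    # steady gain up to four components that the analysis is meant to
    # detect.  Idiosyncratic sd reflects subject-level strategy/arousal
    # variation unrelated to age or ability.
    signal_contrasts = (1.3, 1.2, 1.1, 1.0)
    signal_age_slopes = (-0.50, -0.65, -0.80, -0.95)
    signal_loadings = (0.35, 0.50, 0.65, 0.80)
    for j, base_c in enumerate(signal_contrasts):
        amp = {}
        for t in tasks:
            scale = 1.0 if t.name == "FI" else 0.45
            amp[t.name] = AmplitudeModel(
                base=0.3, contrast=base_c * scale,
                age_slope=signal_age_slopes[j] * scale,
                perf_loading=signal_loadings[j] * scale,
                sd=0.55)
        comps.append(ComponentSpec(
            name=f"signal_{j}", center=free.pop(0), sigma=1.3,
            kind="neural", amplitudes=amp, fc_weight=0.6))
    # -- default-mode components ---------------------------------------
    for label, center in DM_REGION_CENTERS:
        amp = {}
        for t in tasks:
            scale = 1.0 if t.name == "FI" else 0.6
            amp[t.name] = AmplitudeModel(
                base=0.2, contrast=-0.5 * scale,
                age_slope=0.25 * scale, perf_loading=-0.15 * scale,
                sd=0.35)
        comps.append(ComponentSpec(
            name=f"dm_{label}", center=center, sigma=1.3, kind="dm",
            amplitudes=amp, fc_weight=-0.6))
    # -- other neural components (weak/no condition response) ----------
    # Large task-unrelated condition variability: engaged-but-irrelevant
    # components whose inclusion dilutes the performance prediction.
    rng = np.random.default_rng(20170508)   # fixed: part of the scenario
    other_contrasts = rng.uniform(-0.12, 0.12, n_other)
    for j in range(n_other):
        amp = {t.name: AmplitudeModel(base=0.2,
                                      contrast=float(other_contrasts[j]),
                                      sd=1.8)
               for t in tasks}
        comps.append(ComponentSpec(
            name=f"neural_{j}", center=free.pop(0), sigma=1.3,
            kind="neural", amplitudes=amp, fc_weight=0.0))
    # -- non-neural components over WM/CSF -----------------------------
    nonneural_centers = [(3.0, 3.0, 1.0), (3.0, 13.0, 1.0),
                         (13.0, 3.0, 1.0), (13.0, 13.0, 1.0),
                         (3.0, 8.0, 1.0), (13.0, 8.0, 1.0)]
    for j in range(4):
        comps.append(ComponentSpec(
            name=f"vascular_{j}", center=nonneural_centers[j], sigma=1.2,
            kind="vascular"))
    for j in range(2):
        comps.append(ComponentSpec(
            name=f"noise_{j}", center=nonneural_centers[4 + j], sigma=1.2,
            kind="noise"))

    return GenerativeScenario(
        grid_shape=(16, 16, 12), components=tuple(comps),
        tasks=tuple(tasks), voxel_noise_sd=voxel_noise_sd,
        tc_noise_sd=1.0, fc_factor_sd=1.0)


def small_scenario(voxel_noise_sd: float = 0.5) -> GenerativeScenario:
    """Reduced 12-component scenario for fast end-to-end runs:
    4 signal + 3 DM + 2 other neural + 2 vascular + 1 noise."""
    base = default_scenario(n_other=2, include_pn=True,
                            voxel_noise_sd=voxel_noise_sd)
    keep_dm = ("dm_mpfc_ventral", "dm_pcc", "dm_precuneus")
    comps = [c for c in base.components
             if c.kind != "dm" or c.name in keep_dm]
    comps = [c for c in comps if c.name not in
             ("vascular_2", "vascular_3", "noise_1")]
    return replace(base, components=tuple(comps))


# --------------------------------------------------------------------------
# Signal generation
# --------------------------------------------------------------------------

def _band_noise(rng, n_t: int, tr: float, band: tuple) -> np.ndarray:
    """Unit-sd noise band-limited to ``band`` Hz via FFT masking."""
    white = rng.standard_normal(n_t)
    freqs = np.fft.rfftfreq(n_t, d=tr)
    spec = np.fft.rfft(white)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    spec[~keep] = 0.0
    x = np.fft.irfft(spec, n=n_t)
    sd = x.std()
    return x / sd if sd > 0 else x


_BASELINE_BANDS = {"neural": (0.01, 0.10), "dm": (0.01, 0.10),
                   "vascular": (0.15, 0.25)}


def subject_condition_amplitudes(cohort: pd.DataFrame,
                                 scenario: GenerativeScenario,
                                 task: TaskSpec, seed: int) -> np.ndarray:
    """Planted condition amplitudes, (n_subjects, n_components, n_conditions).

    The more-demanding condition of interest carries the planted contrast
    (base + contrast + age and performance terms + idiosyncratic noise);
    all other conditions get the base amplitude.
    """
    rng = np.random.default_rng([seed, 7, _task_tag(task.name)])
    n_sub = len(cohort)
    zage = zscore_age(cohort["age"].to_numpy())
    g = cohort["latent_g"].to_numpy()
    cond_names = [c.name for c in task.conditions]
    more, _less = task.conditions_of_interest
    more_idx = cond_names.index(more)
    amps = np.zeros((n_sub, scenario.n_components, len(cond_names)))
    for ci, comp in enumerate(scenario.components):
        model = comp.amplitudes.get(task.name)
        if model is None:
            continue
        amps[:, ci, :] = model.base
        eps = rng.standard_normal(n_sub)
        amps[:, ci, more_idx] = (model.base + model.contrast
                                 + model.age_slope * zage
                                 + model.perf_loading * g
                                 + model.sd * eps)
    return amps


def true_responsivity(cohort, scenario, task, seed) -> np.ndarray:
    """Planted contrast amplitude (more − less demanding), per subject and
    component — the generative ground truth of the responsivity index up to
    the GLM's standardization."""
    amps = subject_condition_amplitudes(cohort, scenario, task, seed)
    cond_names = [c.name for c in task.conditions]
    more, less = task.conditions_of_interest
    return amps[:, :, cond_names.index(more)] - \
        amps[:, :, cond_names.index(less)]


def _task_tag(name: str) -> int:
    return int.from_bytes(name.encode()[:4].ljust(4, b"\0"), "little")


def simulate_component_timecourses(cohort: pd.DataFrame,
                                   scenario: GenerativeScenario,
                                   seed: int = 0,
                                   noiseless: bool = False) -> dict:
    """Component time-courses per task, bypassing spatial mixing.

    Returns {task_name: array (n_subjects, n_components, n_volumes)}.
    Each time-course is the sum of condition regressors weighted by the
    subject's planted amplitudes, a kind-specific baseline noise process
    (low-frequency for neural/DM, vascular-band for vascular, white for
    noise components), and a shared low-frequency factor scaled by the
    component's fc_weight (planting inter-component connectivity
    structure).  ``noiseless`` disables the stochastic terms.
    """
    out = {}
    n_sub = len(cohort)
    for task in scenario.tasks:
        design = task.design()
        amps = subject_condition_amplitudes(cohort, scenario, task, seed)
        rng = np.random.default_rng([seed, 13, _task_tag(task.name)])
        tcs = np.einsum("sck,tk->sct", amps, design.regressors)
        if not noiseless:
            for s in range(n_sub):
                shared = scenario.fc_factor_sd * _band_noise(
                    rng, task.n_volumes, task.tr, (0.01, 0.10))
                for ci, comp in enumerate(scenario.components):
                    band = _BASELINE_BANDS.get(comp.kind)
                    if band is None:                      # white noise
                        b = rng.standard_normal(task.n_volumes)
                    else:
                        b = _band_noise(rng, task.n_volumes, task.tr, band)
                    tcs[s, ci] += scenario.tc_noise_sd * b
                    if comp.fc_weight:
                        tcs[s, ci] += comp.fc_weight * shared
        out[task.name] = tcs
    return out


def simulate_motion(n_volumes: int, rng) -> np.ndarray:
    """Six smooth realignment-parameter traces (random walks, mm/rad)."""
    steps = rng.normal(0.0, 0.02, size=(n_volumes, 6))
    return np.cumsum(steps, axis=0)


def events_table(task: TaskSpec) -> pd.DataFrame:
    """BIDS-style events table (onset, duration, trial_type)."""
    rows = []
    for cond in task.conditions:
        for onset, dur in zip(cond.onsets, cond.durations):
            rows.append({"onset": onset, "duration": dur,
                         "trial_type": cond.name})
    return pd.DataFrame(rows).sort_values("onset").reset_index(drop=True)


def simulate_task_bold(cohort: pd.DataFrame, scenario: GenerativeScenario,
                       seed: int = 0, noiseless: bool = False) -> dict:
    """Forward-model 4D BOLD per subject and task.

    Each voxel time-series is the spatial-map-weighted sum of the component
    time-courses plus i.i.d. (optionally AR(1)) Gaussian voxel noise.

    Returns a dict with keys: ``images`` {(subject, task): 4D array},
    ``events`` {task: DataFrame}, ``motion`` {(subject, task): array},
    ``timecourses`` {task: (n_sub, n_comp, n_vol)}, ``maps`` (truth),
    ``designs`` {task: DesignMatrix}.
    """
    maps = component_maps(scenario)
    tcs = simulate_component_timecourses(cohort, scenario, seed,
                                         noiseless=noiseless)
    images, motion, designs, events = {}, {}, {}, {}
    nx, ny, nz = scenario.grid_shape
    for task in scenario.tasks:
        designs[task.name] = task.design()
        events[task.name] = events_table(task)
        rng = np.random.default_rng([seed, 29, _task_tag(task.name)])
        for s, subject in enumerate(cohort["subject"]):
            sig = maps.T @ tcs[task.name][s]          # voxels x time
            if not noiseless and scenario.voxel_noise_sd > 0:
                noise = rng.standard_normal(sig.shape)
                if scenario.ar_coefficient > 0:
                    phi = scenario.ar_coefficient
                    for t in range(1, noise.shape[1]):
                        noise[:, t] += phi * noise[:, t - 1]
                    noise *= np.sqrt(1 - phi ** 2)
                sig = sig + scenario.voxel_noise_sd * noise
            images[(subject, task.name)] = \
                sig.reshape(nx, ny, nz, task.n_volumes).astype(np.float32)
            motion[(subject, task.name)] = simulate_motion(
                task.n_volumes, rng)
    return {"images": images, "events": events, "motion": motion,
            "timecourses": tcs, "maps": maps, "designs": designs}


def make_behavior(cohort: pd.DataFrame, scenario: GenerativeScenario,
                  seed: int = 0) -> pd.DataFrame:
    """Behavioural scores per subject and task, driven by the same age and
    latent-efficiency terms as the planted component amplitudes."""
    zage = zscore_age(cohort["age"].to_numpy())
    g = cohort["latent_g"].to_numpy()
    rows = []
    for task in scenario.tasks:
        rng = np.random.default_rng([seed, 41, _task_tag(task.name)])
        eta = rng.standard_normal(len(cohort))
        score = task.score_offset + task.score_scale * (
            task.score_age_slope * zage
            + task.score_perf_loading * g
            + task.score_noise_sd * eta)
        for subj, sc in zip(cohort["subject"], score):
            rows.append({"subject": subj, "task": task.name,
                         "score": float(sc), "excluded": False})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Trivariate sampler for mediation analyses
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrivariateSpec:
    """(age, mediator, outcome) correlation structure for direct sampling."""
    correlation_matrix: tuple     # 3x3, rows as tuples
    n: int
    seed: int = 0

    def matrix(self) -> np.ndarray:
        C = np.asarray(self.correlation_matrix, dtype=float)
        if C.shape != (3, 3):
            raise InvalidSpecError("correlation matrix must be 3x3")
        if not np.allclose(C, C.T):
            raise InvalidSpecError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(C), 1.0):
            raise InvalidSpecError("correlation matrix needs unit diagonal")
        if np.linalg.eigvalsh(C).min() < -1e-10:
            raise InvalidSpecError(
                "correlation matrix is not positive semi-definite")
        return C


def sample_trivariate(spec: TrivariateSpec) -> pd.DataFrame:
    """Multivariate-normal sample with the requested correlation structure,
    columns (age, mediator, outcome)."""
    C = spec.matrix()
    rng = np.random.default_rng([spec.seed, 53])
    L = np.linalg.cholesky(C + 1e-12 * np.eye(3))
    X = rng.standard_normal((spec.n, 3)) @ L.T
    return pd.DataFrame(X, columns=["age", "mediator", "outcome"])
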