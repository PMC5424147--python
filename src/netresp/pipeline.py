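"""End-to-end orchestration: simulate/load -> clean -> group ICA ->
classify -> responsivity -> behaviour -> task-positive selection -> group
statistics (maintenance, compensation screens, mediation, default-mode
suppression) -> condition-specific functional connectivity.

Every stage is a thin call into the library modules; stage outputs are
written under the output directory as TSV/JSON so any stage can be
inspected or re-run.  The run is deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import behavior as beh
from . import classify as cls
from . import connectivity as fc
from . import ica
from . import preprocess as pre
from . import responsivity as resp
from . import stats
from . import synth

log = logging.getLogger("netresp")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class PipelineConfig:
    """All tunable constants of the analysis, with the documented defaults."""
    mode: str = "synthetic"              # synthetic | nifti
    seed: int = 0
    n_subjects: int = 16
    scenario: str = "small"              # small | default (synthetic mode)
    input_dir: str | None = None         # nifti mode
    n_components: int | None = None      # ICA order; None = scenario truth
    candidate_ks: tuple | None = None    # enables dimensionality selection
    ica_repeats: int = 8
    ratio_threshold: float = 0.65
    dynamic_range_threshold: float = 0.0175
    gm_overlap_threshold: float = 0.75
    dm_overlap_threshold: float = 0.5
    fc_mask_threshold: float = 0.05
    outlier_half_width: float = 15.0
    outlier_z: float = 2.5
    covariates: tuple = ("education", "handedness", "gender")
    age_group_bounds: tuple = ((23, 45), (46, 64), (65, 87))
    motor_exclude: tuple = ()
    n_boot: int = 1000
    max_k_report: int = 15


def load_config(path) -> PipelineConfig:
    """Read a YAML config file; unknown keys raise, missing keys default."""
    raw = yaml.safe_load(pathlib.Path(path).read_text()) or {}
    fields = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - fields
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("covariates", "motor_exclude", "candidate_ks"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    if "age_group_bounds" in raw:
        raw["age_group_bounds"] = tuple(tuple(b) for b in
                                        raw["age_group_bounds"])
    return PipelineConfig(**raw)


def _covariate_matrix(cohort: pd.DataFrame, names) -> np.ndarray | None:
    if not names:
        return None
    return cohort.loc[:, list(names)].to_numpy(dtype=float)


def _round(obj, nd=10):
    if isinstance(obj, dict):
        return {k: _round(v, nd) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round(v, nd) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), nd)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round(obj.tolist(), nd)
    return obj


def _load_nifti_inputs(config: PipelineConfig):
    """Minimal reader for pre-simulated/real inputs laid out on disk."""
    root = pathlib.Path(config.input_dir or "")
    if not root.is_dir():
        raise FileNotFoundError(f"input directory {root} not found")
    cohort_path = root / "cohort.tsv"
    if not cohort_path.exists():
        raise FileNotFoundError("cohort.tsv missing from input directory")
    cohort = pd.read_csv(cohort_path, sep="\t")
    masks = {t: pre.load_mask(root / f"{t}_mask.nii")
             for t in ("gm", "wm", "csf")}
    from .design import Condition, build_design
    images, designs, motion = {}, {}, {}
    tasks = sorted({p.name.split("_")[1] for p in root.glob("sub-*_bold.nii")})
    if not tasks:
        raise FileNotFoundError("no *_bold.nii images found")
    for task in tasks:
        ev_path = root / f"{task}_events.tsv"
        if not ev_path.exists():
            raise FileNotFoundError(f"events file missing for task {task}")
        ev = pd.read_csv(ev_path, sep="\t")
        meta = yaml.safe_load((root / f"{task}_meta.yaml").read_text())
        conds = [Condition(name, tuple(g["onset"]), tuple(g["duration"]))
                 for name, g in ev.groupby("trial_type")]
        designs[task] = build_design(
            conds, meta["n_volumes"], meta["tr"],
            tuple(meta["conditions_of_interest"]))
        for subj in cohort["subject"]:
            img_path = root / f"{subj}_{task}_bold.nii"
            if not img_path.exists():
                raise FileNotFoundError(f"missing image {img_path.name}")
            images[(subj, task)] = pre.load_bold(img_path)
            mot_path = root / f"{subj}_{task}_motion.tsv"
            motion[(subj, task)] = (
                np.loadtxt(mot_path, delimiter="\t")
                if mot_path.exists()
                else np.zeros((meta["n_volumes"], 6)))
    behaviour = pd.read_csv(root / "behaviour.tsv", sep="\t")
    return cohort, images, designs, motion, masks, behaviour, tasks


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the full analysis; returns the result bundle and writes tables,
    a JSON summary and a log under ``outdir``."""
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                log.info("stage %s: start", name)
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc
        return inner
    return wrap


def _run(config: PipelineConfig, out: pathlib.Path) -> dict:
    log.info("seed=%d mode=%s", config.seed, config.mode)
    summary: dict = {"seed": config.seed, "mode": config.mode}

    # ---------------- inputs ------------------------------------------
    @_stage("inputs")
    def stage_inputs():
        if config.mode == "synthetic":
            scenario = (synth.small_scenario() if config.scenario == "small"
                        else synth.default_scenario())
            cohort = synth.make_cohort(synth.CohortSpec(
                n_subjects=config.n_subjects, seed=config.seed))
            sim = synth.simulate_task_bold(cohort, scenario,
                                           seed=config.seed)
            masks = synth.tissue_masks(scenario.grid_shape)
            behaviour = synth.make_behavior(cohort, scenario,
                                            seed=config.seed)
            tasks = [t.name for t in scenario.tasks]
            return (cohort, sim["images"], sim["designs"], sim["motion"],
                    masks, behaviour, tasks, scenario)
        cohort, images, designs, motion, masks, behaviour, tasks = \
            _load_nifti_inputs(config)
        return cohort, images, designs, motion, masks, behaviour, tasks, None

    (cohort, images, designs, motion, masks, behaviour, tasks,
     scenario) = stage_inputs()
    cohort.to_csv(out / "cohort.tsv", sep="\t", index=False)

    # ---------------- cleaning ----------------------------------------
    @_stage("clean")
    def stage_clean():
        return {key: pre.clean_voxelwise(img, masks["wm"], masks["csf"])
                for key, img in images.items()}

    cleaned = stage_clean()

    # ---------------- group ICA ---------------------------------------
    @_stage("ica")
    def stage_ica():
        order = [(subj, task) for task in tasks
                 for subj in cohort["subject"]]
        pairs = [(key, cleaned[key]) for key in order]
        if config.candidate_ks:
            per_task = {task: [(key, cleaned[key]) for key in order
                               if key[1] == task] for task in tasks}
            k, scan = ica.select_dimensionality(
                per_task, config.candidate_ks,
                n_repeats=max(2, config.ica_repeats // 2), seed=config.seed)
            log.info("dimensionality scan %s -> k*=%d", scan, k)
        else:
            k = config.n_components or (scenario.n_components
                                        if scenario else 20)
        reduced = ica.concatenate_and_reduce(pairs, k)
        decomp = ica.run_stable_ica(reduced, k, config.ica_repeats,
                                    seed=config.seed)
        subj_data = ica.back_reconstruct_gica3(decomp, reduced, cleaned)
        return k, reduced, decomp, subj_data

    k, reduced, decomp, subj_data = stage_ica()
    ica.save_decomposition(decomp, reduced, out / "ica")
    summary["n_components"] = k
    summary["stability_iq"] = _round(decomp.stability_iq)

    # ---------------- classification ----------------------------------
    @_stage("classify")
    def stage_classify():
        tr_map = {t: designs[t].tr for t in tasks}
        metrics = cls.component_metrics(
            subj_data.timecourses, decomp.maps, masks,
            tr_by_key=lambda key: tr_map[key[1]])
        flags = cls.classify_components(
            metrics, config.ratio_threshold, config.dynamic_range_threshold,
            config.gm_overlap_threshold, config.motor_exclude)
        grid = reduced.grid_shape
        dm_table = cls.identify_dm(
            decomp.maps, synth.dm_template_masks(grid),
            config.dm_overlap_threshold,
            candidates=flags.loc[flags["included"], "component"].tolist())
        return metrics, flags, dm_table

    metrics, flags, dm_table = stage_classify()
    flags.to_csv(out / "component_metrics.tsv", sep="\t", index=False)
    dm_table.to_csv(out / "dm_components.tsv", sep="\t", index=False)
    included = flags.loc[flags["included"], "component"].to_numpy()
    dm_set = dm_table.loc[dm_table["dm_member"], "component"].to_numpy()
    dm_medial = dm_table.loc[dm_table["dm_medial"], "component"].to_numpy()
    summary["n_neural"] = int(flags["neural"].sum())
    summary["n_included"] = len(included)
    summary["dm_components"] = [int(c) for c in dm_set]

    # ---------------- responsivity ------------------------------------
    @_stage("responsivity")
    def stage_responsivity():
        tables = {}
        for task in tasks:
            tcs = np.stack([subj_data.timecourses[(s, task)].T
                            for s in cohort["subject"]])
            tables[task] = resp.responsivity_table(tcs, designs[task])
        return tables

    resp_tables = stage_responsivity()
    for task in tasks:
        pd.DataFrame(resp_tables[task],
                     index=cohort["subject"]).to_csv(
            out / f"responsivity_{task}.tsv", sep="\t")

    # ---------------- behaviour ---------------------------------------
    @_stage("behaviour")
    def stage_behaviour():
        tab = behaviour.copy()
        for task in tasks:
            sel = tab["task"] == task
            scores = tab.loc[sel, "score"].to_numpy()
            flags_ = beh.sliding_window_outliers(
                scores, cohort["age"].to_numpy(),
                config.outlier_half_width, config.outlier_z)
            tab.loc[sel, "excluded"] = flags_
            log.info("task %s: %d behavioural outliers", task,
                     int(flags_.sum()))
        return tab

    behaviour = stage_behaviour()
    behaviour.to_csv(out / "behaviour.tsv", sep="\t", index=False)

    # ---------------- task-positive selection and statistics ----------
    cov_full = _covariate_matrix(cohort, config.covariates)
    ages = cohort["age"].to_numpy()
    older = (ages >= config.age_group_bounds[2][0])
    task_results = {}

    @_stage("stats")
    def stage_stats():
        for task in tasks:
            R_incl = resp_tables[task][:, included]
            scores = behaviour.loc[behaviour["task"] == task,
                                   "score"].to_numpy()
            keep = ~behaviour.loc[behaviour["task"] == task,
                                  "excluded"].to_numpy(dtype=bool)
            cov = cov_full[keep] if cov_full is not None else None
            Rk, sk, agek = R_incl[keep], scores[keep], ages[keep]
            heur = resp.heuristic_validation(Rk, sk, cov)
            sel = resp.select_task_positive(Rk, sk, cov)
            sel_age = resp.select_task_positive(Rk, sk, cov,
                                                include_age=agek)
            tp_components = included[sel.task_positive]
            mar = resp.mean_absolute_responsivity(Rk, seed=config.seed)
            maint = report_maintenance(sel.mtr, sk, agek,
                                       older[keep], cov)
            comp_screen = stats.compensation_screen(
                Rk, agek, sk, older[keep], cov)
            med = stats.mediate(agek, sel.mtr, sk, cov,
                                n_boot=config.n_boot, seed=config.seed)
            dm_stats = {}
            for label, comps in (("all", dm_set), ("medial", dm_medial)):
                if len(comps) == 0:
                    continue
                idx = [int(np.where(included == c)[0][0]) for c in comps
                       if c in included]
                dm_mcr = resp.mcr(Rk, idx)
                tt = stats.one_sample_t(dm_mcr)
                age_corr = stats.pearson_ci(
                    stats.residualize(dm_mcr, cov),
                    stats.residualize(agek, cov))
                dm_stats[label] = {
                    "mean_responsivity": tt.mean,
                    "ci": [tt.ci_low, tt.ci_high], "p": tt.p,
                    "age_r": age_corr.r, "age_p": age_corr.p,
                    "components": [int(c) for c in comps],
                }
            task_results[task] = {
                "k_star": sel.k_star,
                "k_star_age_controlled": sel_age.k_star,
                "task_positive": [int(c) for c in tp_components],
                "k_scan": sel.k_scan[:config.max_k_report],
                "mtr": sel.mtr,
                "keep": keep,
                "mean_abs_responsivity": mar,
                "heuristic_r": heur["across_component_r"],
                "maintenance": maint,
                "mediation": med,
                "dm": dm_stats,
                "n_compensation_flags": int(sum(
                    r["test1_flag"] or r["test2_flag"]
                    for r in comp_screen)),
            }
            pd.DataFrame({"k": np.arange(1, len(sel.k_scan) + 1),
                          "r": sel.k_scan}).to_csv(
                out / f"kscan_{task}.tsv", sep="\t", index=False)

    stage_stats()

    # ---------------- functional connectivity -------------------------
    @_stage("fc")
    def stage_fc():
        fc_out = {}
        for task in tasks:
            design = designs[task]
            mask = fc.condition_mask(design, config.fc_mask_threshold)
            nuis = design.nuisance_columns()
            mats = []
            for s in cohort["subject"]:
                tcs = subj_data.timecourses[(s, task)][:, included]
                mats.append(fc.fc_matrix(tcs, mask,
                                         motion=motion[(s, task)],
                                         nuisance=nuis))
            tp_local = [int(np.where(included == c)[0][0])
                        for c in task_results[task]["task_positive"]]
            dm_local = [int(np.where(included == c)[0][0]) for c in dm_set
                        if c in included and
                        c not in task_results[task]["task_positive"]]
            if dm_local:
                summary_fc = fc.group_fc_summary(mats, tp_local, dm_local)
                fc_out[task] = summary_fc
            fc.fc_long_table(
                {s: m for s, m in zip(cohort["subject"], mats)}).to_csv(
                out / f"fc_{task}.tsv", sep="\t", index=False)
        return fc_out

    fc_summaries = stage_fc()

    # ---------------- summary -----------------------------------------
    for task in tasks:
        tr = task_results[task]
        med = tr["mediation"]
        summary[task] = {
            "k_star": tr["k_star"],
            "k_star_age_controlled": tr["k_star_age_controlled"],
            "task_positive": tr["task_positive"],
            "mean_abs_responsivity": _round(tr["mean_abs_responsivity"]),
            "heuristic_across_component_r": _round(tr["heuristic_r"]),
            "maintenance_older_r": _round(tr["maintenance"]["r"]),
            "maintenance_older_p": _round(tr["maintenance"]["p"]),
            "mediation_proportion": _round(med.proportion_mediated),
            "mediation_acme": _round(med.acme),
            "mediation_total": _round(med.total),
            "dm": _round(tr["dm"]),
            "n_compensation_flags": tr["n_compensation_flags"],
        }
        if task in fc_summaries:
            s = fc_summaries[task]
            summary[task]["tp_dm_fc_mean_z"] = _round(s.mean_z)
            summary[task]["tp_dm_fc_p"] = _round(s.p)
    (out / "summary.json").write_text(
        json.dumps(_round(summary), indent=2, sort_keys=True))
    return {"summary": summary, "task_results": task_results,
            "flags": flags, "dm_table": dm_table,
            "responsivity": resp_tables, "behaviour": behaviour,
            "decomposition": decomp, "cohort": cohort}


def report_maintenance(mtr, scores, ages, older_mask, covariates=None
                       ) -> dict:
    """Older-group correlation between MTR and task score (on covariate
    residuals): the functional-maintenance test."""
    older_mask = np.asarray(older_mask, dtype=bool)
    if older_mask.sum() < 5:
        raise ValueError("older group too small for the maintenance test")
    mtr = np.asarray(mtr, dtype=float)[older_mask]
    scores = np.asarray(scores, dtype=float)[older_mask]
    cov = None if covariates is None else \
        np.asarray(covariates, dtype=float)[older_mask]
    if cov is not None:
        # constant columns within the subgroup (e.g. a binary covariate
        # with a single level among older subjects) are absorbed by the
        # intercept; keep only informative columns
        keep_cols = cov.std(axis=0) > 0
        cov = cov[:, keep_cols] if keep_cols.any() else None
    res = stats.pearson_ci(stats.residualize(mtr, cov),
                           stats.residualize(scores, cov))
    return {"r": res.r, "p": res.p, "ci": [res.ci_low, res.ci_high],
            "n": res.n}
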