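"""End-to-end orchestration: simulate a cohort, score it, run the full
behavioral statistics battery and the EEG analysis, and compare the
competing reactivation models' diagnostic signatures.

Per-stage seeds are derived from one master seed through independent
spawn keys, so any stage can be rerun in isolation and identical configs
yield identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, design as design_mod, eeg, eegsim, scoring, stats

__all__ = [
    "RunConfig",
    "ValidationError",
    "stage_rng",
    "simulate_participant",
    "simulate_cohort",
    "behavioral_stats",
    "run_eeg_cohort",
    "run_experiment",
    "compare_hypotheses",
]

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    """Configuration of a full simulated study run.

    Cohort size defaults to the study's 31 participants; cue repetitions
    per sound vary across participants (truncated normal around 11, range
    1–24, matching the observed between-participant spread). The
    permutation and subsample counts default to fast settings suited to a
    complete run on one CPU; both can be raised to the study's 10^6 / 500.
    """

    master_seed: int = 0
    n_participants: int = 31
    model: dict = field(default_factory=dict)  # ReactivationModelParams overrides
    rep_mean: float = 11.0
    rep_sd: float = 5.6
    rep_range: tuple[int, int] = (1, 24)
    eeg_enabled: bool = True
    eeg_fs: float = 512.0
    eeg_n_passes: int = 4  # sleep passes synthesized per participant for EEG
    evoked: dict = field(default_factory=dict)  # EvokedResponseParams overrides
    n_perm: int = 10_000
    n_subsamples: int = 100
    run_subsampling: bool = False
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValidationError("n_participants must be >= 1")
        if self.rep_range[0] < 0 or self.rep_range[0] > self.rep_range[1]:
            raise ValidationError("invalid rep_range")
        behavior.ReactivationModelParams(**self.model)  # validate overrides
        eegsim.EvokedResponseParams(**self.evoked)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rep_range"] = list(d["rep_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "rep_range" in d:
            d["rep_range"] = tuple(d["rep_range"])
        return cls(**d)

    def model_params(self) -> behavior.ReactivationModelParams:
        return behavior.ReactivationModelParams(**self.model)

    def evoked_params(self) -> eegsim.EvokedResponseParams:
        return eegsim.EvokedResponseParams(**self.evoked)


def stage_rng(master_seed: int, *key) -> np.random.Generator:
    """Counter-keyed RNG: every (stage, participant, ...) key gets an
    independent stream derived from the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(int(k) for k in key))
    )


def _draw_passes(rng: np.random.Generator, cfg: RunConfig) -> int:
    n = int(round(rng.normal(cfg.rep_mean, cfg.rep_sd)))
    return int(np.clip(n, cfg.rep_range[0], cfg.rep_range[1]))


def simulate_participant(
    pid: str,
    layout: design_mod.Layout,
    params: behavior.ReactivationModelParams,
    rng: np.random.Generator,
    n_passes: int,
    grid: design_mod.GridSpec | None = None,
    light: bool = False,
):
    """Simulate one participant end to end (behavior only).

    Returns (scored items, summaries, design, cue schedule). With
    ``light`` the block schedule and the explicit cue-event sequence are
    skipped (repetition counts alone drive the behavior), which speeds up
    cohort-level simulation studies; neither enters the behavioral
    statistics.
    """
    dsg = design_mod.build_design(rng, grid=grid, layout=layout, assign_blocks=not light)
    pre = behavior.simulate_pre_sleep(dsg, params, rng, participant_id=pid)
    pre_scored = scoring.score_single_phase(pre, dsg)
    set_sum = scoring.presleep_set_summaries(pre_scored)
    cued = design_mod.balance_cuing(set_sum, rng)
    dsg.sets["cued"] = dsg.sets["set_id"].map(cued)
    dsg.sets.loc[dsg.sets["set_id"] == "NOVEL", "cued"] = True  # novel sound always played
    cued_sounds = dsg.sets[(dsg.sets["cued"] == True)][["sound_id", "size_k"]]  # noqa: E712
    if light:
        schedule = n_passes
    else:
        schedule = design_mod.build_cue_sequence(cued_sounds, n_passes, rng)
    post = behavior.simulate_post_sleep(pre, dsg, schedule, params, rng)
    placements = pd.concat([pre, post], ignore_index=True)
    scored, summaries = scoring.score_dataset(placements, dsg, compute_summaries=not light)
    scored["n_passes"] = n_passes
    return scored, summaries, dsg, schedule


def simulate_cohort(
    cfg: RunConfig,
    layout: design_mod.Layout | None = None,
    keep_designs: bool = False,
    light: bool = False,
):
    """Simulate a full behavioral cohort.

    One candidate-location layout is generated per cohort and shared by all
    participants (cuing balance, placements, repetition counts and block
    schedules remain per-participant); layout geometry does not enter the
    behavioral statistics, and sharing it keeps cohort-level simulation
    studies tractable.
    """
    grid = design_mod.GridSpec()
    params = cfg.model_params()
    if layout is None:
        sizes_rng = stage_rng(cfg.master_seed, 0)
        multi = [f"M{i + 1:02d}" for i in range(24)]
        single = [f"S{i + 1:02d}" for i in range(21)]
        six = sizes_rng.choice(multi, size=6, replace=False)
        sizes = {lb: (6 if lb in set(six) else 2) for lb in multi}
        sizes.update({lb: 1 for lb in single})
        layout = design_mod.build_layout(grid, sizes, sizes_rng)
    scored_all, summaries_all, designs, schedules = [], [], {}, {}
    for i in range(cfg.n_participants):
        pid = f"p{i + 1:02d}"
        rng = stage_rng(cfg.master_seed, 1, i)
        n_passes = _draw_passes(rng, cfg)
        scored, summaries, dsg, schedule = simulate_participant(
            pid, layout, params, rng, n_passes, grid=grid, light=light
        )
        scored_all.append(scored)
        summaries_all.append(summaries)
        if keep_designs:
            designs[pid] = dsg
            schedules[pid] = schedule
    scored = pd.concat(scored_all, ignore_index=True)
    summaries = (
        pd.concat(summaries_all, ignore_index=True) if summaries_all[0] is not None else None
    )
    return scored, summaries, layout, designs, schedules


def _cell_means(scored: pd.DataFrame, value: str, sizes=None) -> pd.DataFrame:
    df = scored if sizes is None else scored[scored["size_k"].isin(sizes)]
    out = (
        df.groupby(["participant_id", "size_k", "cued"], dropna=False)[value]
        .mean()
        .reset_index()
    )
    out["cued"] = out["cued"].astype(bool)
    return out


def behavioral_stats(
    scored: pd.DataFrame,
    cfg: RunConfig,
    rng_seed=None,
) -> dict:
    """Run the full behavioral statistics battery on a scored cohort.

    Covers: swap-error ANOVAs (pre-sleep and over-sleep change, two- and
    six-item sets), pre-sleep accuracy ANOVA with Tukey HSD over set sizes,
    the benefit ANOVA (cuing × set size) with the BIC Bayes factor for the
    interaction, the pre-sleep regression adjustment, the lenient-criterion
    ANOVA, cumulative per-set benefits, ICC permutation tests, the max-|Z|
    outlier comparison, repetition–benefit correlations, and the
    familiarity-covariate model. Optionally the subsampling robustness
    procedure. Returns a nested dict of plain numbers.
    """
    rng = np.random.default_rng(rng_seed)
    out: dict = {}
    sc = scored.copy()
    sc["cued"] = sc["cued"].astype(bool)
    sc["swap_change"] = sc["swap_post"].astype(float) - sc["swap_pre"].astype(float)
    sc["lenient_change"] = sc["lenient_post"].astype(float) - sc["lenient_pre"].astype(float)

    # swap errors: multi-item sets only (outliers undefined for singletons)
    swaps_pre = _cell_means(sc, "swap_pre", sizes=(2, 6))
    out["swap_pre_anova"] = stats.rm_anova(
        swaps_pre, "swap_pre", ["cued", "size_k"], "participant_id"
    ).to_dict()
    out["swap_rate_pre"] = (
        sc[sc.size_k.isin((2, 6))].groupby("size_k")["swap_pre"].mean().to_dict()
    )
    swap_change = _cell_means(sc, "swap_change", sizes=(2, 6))
    out["swap_change_anova"] = stats.rm_anova(
        swap_change, "swap_change", ["cued", "size_k"], "participant_id"
    ).to_dict()

    # pre-sleep accuracy error + Tukey HSD over set sizes
    err_pre = _cell_means(sc, "err_pre")
    out["err_pre_anova"] = stats.rm_anova(
        err_pre, "err_pre", ["cued", "size_k"], "participant_id"
    ).to_dict()
    size_only = err_pre.groupby(["participant_id", "size_k"])["err_pre"].mean().reset_index()
    size_anova = stats.rm_anova(size_only, "err_pre", "size_k", "participant_id")
    eff = size_anova["size_k"]
    level_means = size_only.groupby("size_k")["err_pre"].mean()
    n_subj = size_only["participant_id"].nunique()
    # reconstruct MSE of the size error term for the HSD
    cell = size_only.pivot(index="participant_id", columns="size_k", values="err_pre").to_numpy()
    resid = cell - cell.mean(0) - cell.mean(1)[:, None] + cell.mean()
    ms_err = (resid**2).sum() / eff.df2
    out["err_pre_tukey"] = stats.tukey_hsd(level_means, n_subj, ms_err, eff.df2).to_dict("records")

    # the headline benefit ANOVA and its interaction Bayes factor
    ben = _cell_means(sc, "benefit")
    out["benefit_anova"] = stats.rm_anova(ben, "benefit", ["cued", "size_k"], "participant_id").to_dict()
    ben_for_bf = ben.rename(columns={"benefit": "benefit"})
    out["bf01_interaction"] = stats.interaction_bic_bayes_factor(ben_for_bf)
    out["mean_benefit_cued"] = float(ben.loc[ben.cued, "benefit"].mean())
    out["mean_benefit_noncued"] = float(ben.loc[~ben.cued, "benefit"].mean())

    # regression adjustment of over-sleep forgetting on pre-sleep error
    adj_rows = []
    for pid, grp in sc.dropna(subset=["benefit"]).groupby("participant_id"):
        forgetting = -grp["benefit"].to_numpy(float)
        adj = stats.regress_out_presleep(grp["err_pre"].to_numpy(float), forgetting)
        adj_rows.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "size_k": grp["size_k"],
                    "cued": grp["cued"],
                    "adj_benefit": -adj,
                }
            )
        )
    adj = pd.concat(adj_rows, ignore_index=True)
    adj_cells = (
        adj.groupby(["participant_id", "size_k", "cued"])["adj_benefit"].mean().reset_index()
    )
    out["benefit_adjusted_anova"] = stats.rm_anova(
        adj_cells, "adj_benefit", ["cued", "size_k"], "participant_id"
    ).to_dict()

    # lenient criterion
    out["lenient_pre_pct"] = 100.0 * float(sc["lenient_pre"].mean())
    lenient = _cell_means(sc, "lenient_change")
    out["lenient_change_anova"] = stats.rm_anova(
        lenient, "lenient_change", ["cued", "size_k"], "participant_id"
    ).to_dict()

    # cumulative per-set benefit
    cum = (
        sc.groupby(["participant_id", "set_id", "size_k", "cued"])["benefit"]
        .sum(min_count=1)
        .reset_index(name="cum_benefit")
        .groupby(["participant_id", "size_k", "cued"])["cum_benefit"]
        .mean()
        .reset_index()
    )
    out["cumulative_benefit_anova"] = stats.rm_anova(
        cum, "cum_benefit", ["cued", "size_k"], "participant_id"
    ).to_dict()

    # within-set agreement: ICC permutation per multi-item size class
    out["icc"] = {}
    for size in (6, 2):
        sub = sc[sc["size_k"] == size][["participant_id", "set_id", "cued", "benefit"]].copy()
        sub["set_id"] = sub["participant_id"].astype(str) + ":" + sub["set_id"].astype(str)
        try:
            res = stats.icc_with_permutation(
                sub, n_perm=cfg.n_perm, rng_seed=rng.integers(2**31)
            )
            out["icc"][f"size_{size}"] = dataclasses.asdict(res)
        except ValueError as err:
            out["icc"][f"size_{size}"] = {"error": str(err)}

    # max-|Z| outlier statistic, six-item sets with all benefits present
    six = sc[sc["size_k"] == 6].dropna(subset=["benefit"])
    zrows = {True: [], False: []}
    for (pid, sid, cued_flag), grp in six.groupby(["participant_id", "set_id", "cued"]):
        if len(grp) == 6 and grp["benefit"].std(ddof=1) > 0:
            zrows[bool(cued_flag)].append(stats.max_abs_z(grp["benefit"].to_numpy()))
    if len(zrows[True]) >= 2 and len(zrows[False]) >= 2:
        t, df_z, p, d = stats.compare_outlier_scores(zrows[True], zrows[False])
        out["max_abs_z"] = {"t": t, "df": df_z, "p": p, "cohen_d": d,
                            "n_cued": len(zrows[True]), "n_noncued": len(zrows[False])}

    # repetition-benefit correlations by size class (+ probability variant)
    out["repetition_correlations"] = {}
    cued_only = sc[sc["cued"]].dropna(subset=["benefit"])
    for size in (1, 2, 6):
        grp = (
            cued_only[cued_only["size_k"] == size]
            .groupby("participant_id")
            .agg(benefit=("benefit", "mean"), reps=("n_passes", "mean"))
        )
        entry = {}
        try:
            r, p = stats.repetition_benefit_correlation(grp["benefit"], grp["reps"])
            entry.update(r=r, p=p)
            if size > 1:
                r2, p2 = stats.repetition_benefit_correlation(
                    grp["benefit"], grp["reps"],
                    transform=lambda n, k=size: behavior.reactivation_probability(k, int(round(n))),
                )
                entry.update(r_prob=r2, p_prob=p2)
        except ValueError as err:
            entry["error"] = str(err)
        out["repetition_correlations"][f"size_{size}"] = entry

    # familiarity covariate (training exposure varies within size class)
    out["familiarity"] = None  # filled by run_experiment when exposure is simulated

    if cfg.run_subsampling:
        rep = stats.subsample_robustness(
            sc, n_datasets=cfg.n_subsamples, rng_seed=rng.integers(2**31)
        )
        out["subsampling"] = {
            k: v for k, v in dataclasses.asdict(rep).items() if not isinstance(v, np.ndarray)
        }
    return out


def run_eeg_cohort(
    cfg: RunConfig,
    designs: dict,
    schedules: dict,
    scored: pd.DataFrame | None = None,
):
    """Synthesize and analyze the sleep-EEG arm of a cohort.

    Per participant: an NREM background is synthesized to cover that
    participant's cue schedule, cue responses are injected with the
    ground-truth set-size modulation, spindles are detected, and cue-locked
    corrected spectrograms are computed. Across participants: t-map
    clusters are extracted (falling back to canonical delta-theta/sigma
    windows when the map yields none), per-trial cluster modulations feed
    the set-size mixed models, and per-item behavioral benefits join the
    per-sound sigma modulation for the memory-physiology model.
    """
    evoked = cfg.evoked_params()
    subj_maps, trial_rows, spindle_rows = [], [], []
    spec_grid = None
    for i, (pid, dsg) in enumerate(designs.items()):
        schedule = schedules[pid]
        # truncate to the configured number of EEG passes to bound runtime
        events = [e for e in schedule.events if e.pass_idx < cfg.eeg_n_passes]
        if not events:
            continue
        sub_sched = design_mod.CueSchedule(events=events, pass_count=cfg.eeg_n_passes)
        dur = events[-1].onset_s + 8.0
        rng = stage_rng(cfg.master_seed, 2, i)
        rec = eegsim.synthesize_background(dur, fs=cfg.eeg_fs, rng_seed=rng)
        rec, truth = eegsim.inject_cue_responses(rec, sub_sched, evoked, rng)
        spec = eeg.epoch_and_spectrogram(rec)
        corrected = eeg.baseline_correct(spec.power, spec.times, shared_baseline=True)
        subj_maps.append(corrected.mean(axis=0))
        spec_grid = (spec.times, spec.freqs)
        spindles = eeg.detect_spindles(rec.samples, rec.fs)
        trial_rows.append((pid, spec.trial_index, corrected))
        spindle_rows.append((pid, spindles, events))

    if not subj_maps:
        raise ValidationError("no EEG participants simulated")
    times, freqs = spec_grid
    clusters = eeg.cluster_tmap(np.stack(subj_maps), times, freqs)

    def _pick(lo, hi, fallback, min_bins: int = 10):
        for c in clusters:
            if c.sign > 0 and lo <= c.freq_lo and c.freq_hi <= hi and c.mask.sum() >= min_bins:
                return c, "tmap"
        mask = np.zeros((len(freqs), len(times)), bool)
        fsel = (freqs >= fallback[0]) & (freqs <= fallback[1])
        tsel = (times >= fallback[2]) & (times <= fallback[3])
        mask[np.ix_(fsel, tsel)] = True
        return (
            eeg.TFCluster(fallback[0], fallback[1], fallback[2], fallback[3], mask=mask),
            "fallback",
        )

    dt_cluster, dt_src = _pick(0.0, 11.0, (0.25, 11.0, 0.31, 0.87))
    sg_cluster, sg_src = _pick(11.0, 18.0, (11.5, 17.25, 0.94, 1.44))

    mod_rows = []
    for pid, tindex, corrected in trial_rows:
        df = tindex.copy()
        df["participant_id"] = pid
        df["deltatheta"] = eeg.cluster_power(corrected, dt_cluster)
        df["sigma"] = eeg.cluster_power(corrected, sg_cluster)
        mod_rows.append(df)
    trials = pd.concat(mod_rows, ignore_index=True)
    trials = trials.rename(columns={"size_k": "set_size"})

    sp_metrics = []
    for pid, spindles, events in spindle_rows:
        m = eeg.per_trial_spindle_metrics(spindles, events, (sg_cluster.t_lo, sg_cluster.t_hi))
        m["participant_id"] = pid
        sp_metrics.append(m)
    sp = pd.concat(sp_metrics, ignore_index=True).rename(columns={"size_k": "set_size"})
    sp["spindle_present"] = sp["spindle_present"].astype(float)

    results = {
        "clusters": {
            "deltatheta": {
                "freq_lo": dt_cluster.freq_lo, "freq_hi": dt_cluster.freq_hi,
                "t_lo": dt_cluster.t_lo, "t_hi": dt_cluster.t_hi, "source": dt_src,
            },
            "sigma": {
                "freq_lo": sg_cluster.freq_lo, "freq_hi": sg_cluster.freq_hi,
                "t_lo": sg_cluster.t_lo, "t_hi": sg_cluster.t_hi, "source": sg_src,
            },
        },
        "n_trials": int(len(trials)),
    }
    for name, frame, col in [
        ("deltatheta_power", trials, "deltatheta"),
        ("sigma_power", trials, "sigma"),
        ("spindle_probability", sp, "spindle_present"),
    ]:
        res = eeg.fit_setsize_lmm(frame.rename(columns={col: "modulation"}), "modulation")
        results[name] = dataclasses.asdict(res)
    amp = sp.dropna(subset=["max_spindle_amp_uv"])
    if len(amp) >= 10 and amp["participant_id"].nunique() >= 2:
        res = eeg.fit_setsize_lmm(
            amp.rename(columns={"max_spindle_amp_uv": "modulation"}), "modulation"
        )
        results["spindle_amplitude"] = dataclasses.asdict(res)

    if scored is not None:
        per_sound = (
            trials.groupby(["participant_id", "sound_id"])
            .agg(modulation=("sigma", "mean"), set_size=("set_size", "first"))
            .reset_index()
        )
        items = scored.dropna(subset=["benefit"]).copy()
        items["sound_id"] = "snd_" + items["set_id"].astype(str)
        joined = items.merge(per_sound, on=["participant_id", "sound_id"], how="inner")
        if len(joined):
            try:
                mm = eeg.fit_memory_physiology_lmm(joined)
                results["memory_physiology"] = {k: dataclasses.asdict(v) for k, v in mm.items()}
            except ValueError as err:
                results["memory_physiology"] = {"error": str(err)}
    return results


def run_experiment(cfg: RunConfig) -> dict:
    """Execute the full pipeline and return (and optionally write) the report.

    Stages: design/behavior simulation → scoring → behavioral statistics →
    training-exposure familiarity model → EEG simulation and analysis.
    Identical configs produce identical reports; the manifest records the
    config and per-stage seeds. Any stage failure is re-raised annotated
    with the stage name.
    """
    report: dict = {"config": cfg.to_dict(), "stages": []}
    stage = "simulate_behavior"
    try:
        scored, summaries, layout, designs, schedules = simulate_cohort(cfg, keep_designs=True)
        report["stages"].append(stage)
        report["n_scored_items"] = int(
            scored.groupby("participant_id")["item_id"].nunique().median()
        )

        stage = "behavioral_stats"
        report["behavior"] = behavioral_stats(scored, cfg, rng_seed=stage_rng(cfg.master_seed, 3))
        report["stages"].append(stage)

        stage = "familiarity"
        fam_rows = []
        for i, (pid, dsg) in enumerate(designs.items()):
            _, sound_counts = behavior.simulate_training_exposure(
                dsg, stage_rng(cfg.master_seed, 4, i)
            )
            per_set = (
                scored[scored["participant_id"] == pid]
                .groupby(["set_id", "size_k", "cued"], dropna=False)["benefit"]
                .mean()
                .reset_index()
                .merge(sound_counts[["set_id", "sound_plays"]], on="set_id")
                .rename(columns={"sound_plays": "familiarity"})
            )
            per_set["participant_id"] = pid
            fam_rows.append(per_set)
        fam = pd.concat(fam_rows, ignore_index=True)
        fam_res = stats.familiarity_covariate_analysis(fam)
        report["behavior"]["familiarity"] = {
            k: v for k, v in fam_res.items() if k not in ("model", "params")
        }
        report["stages"].append(stage)

        if cfg.eeg_enabled:
            stage = "eeg"
            report["eeg"] = run_eeg_cohort(cfg, designs, schedules, scored=scored)
            report["stages"].append(stage)
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        scored.to_csv(out / "scored_items.csv", index=False)
        summaries.to_csv(out / "summaries.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_jsonable)
    return report


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def compare_hypotheses(
    models: list[str],
    n_cohorts: int = 20,
    n_participants: int = 31,
    master_seed: int = 0,
    alpha: float = 0.05,
    model_overrides: dict | None = None,
    layout: design_mod.Layout | None = None,
) -> pd.DataFrame:
    """Diagnostic firing rates per reactivation model across cohorts.

    For each model, the fraction of simulated cohorts in which each
    behavioral diagnostic fires: a significant cuing main effect, a
    significant cuing × set-size interaction, a positive multi-item
    repetition–benefit correlation, and a cued-below-non-cued six-item-set
    ICC difference. One layout is generated per call and shared by all
    cohorts; everything else varies with the cohort seed.
    """
    if not models:
        raise ValidationError("need at least one model")
    shared_layout = layout
    rows = []
    for mi, model in enumerate(models):
        fires = {
            "cuing": [],
            "interaction": [],
            "cuing_no_interaction": [],
            "rep_corr_positive": [],
            "icc_cued_lower": [],
        }
        for c in range(n_cohorts):
            overrides = dict(model_overrides or {})
            overrides["model"] = model
            cfg = RunConfig(
                master_seed=int(
                    np.random.SeedSequence(entropy=master_seed, spawn_key=(mi, c))
                    .generate_state(1)[0] % 2**31
                ),
                n_participants=n_participants,
                model=overrides,
                eeg_enabled=False,
            )
            scored, _, shared_layout, _, _ = simulate_cohort(
                cfg, layout=shared_layout, light=True
            )
            sc = scored.copy()
            sc["cued"] = sc["cued"].astype(bool)
            ben = _cell_means(sc, "benefit")
            res = stats.rm_anova(ben, "benefit", ["cued", "size_k"], "participant_id")
            cue_sig = res["cued"].p < alpha and (
                ben.loc[ben.cued, "benefit"].mean() > ben.loc[~ben.cued, "benefit"].mean()
            )
            int_sig = res["cued:size_k"].p < alpha
            fires["cuing"].append(cue_sig)
            fires["interaction"].append(int_sig)
            fires["cuing_no_interaction"].append(cue_sig and not int_sig)

            grp = (
                sc[sc["cued"] & (sc["size_k"] == 6)]
                .dropna(subset=["benefit"])
                .groupby("participant_id")
                .agg(benefit=("benefit", "mean"), reps=("n_passes", "mean"))
            )
            try:
                r, _p = stats.repetition_benefit_correlation(grp["benefit"], grp["reps"])
                fires["rep_corr_positive"].append(r > 0)
            except ValueError:
                fires["rep_corr_positive"].append(False)

            six = sc[sc["size_k"] == 6][["participant_id", "set_id", "cued", "benefit"]].copy()
            six["set_id"] = six["participant_id"].astype(str) + ":" + six["set_id"].astype(str)
            try:
                groups = {
                    flag: [
                        g["benefit"].dropna().to_numpy()
                        for _, g in six[six["cued"] == flag].groupby("set_id")
                    ]
                    for flag in (True, False)
                }
                icc_c = stats.icc_oneway([g for g in groups[True] if len(g)])
                icc_n = stats.icc_oneway([g for g in groups[False] if len(g)])
                fires["icc_cued_lower"].append(icc_c < icc_n)
            except ValueError:
                fires["icc_cued_lower"].append(False)
        rows.append(
            {
                "model": model,
                **{f"rate_{k}": float(np.mean(v)) for k, v in fires.items()},
                "n_cohorts": n_cohorts,
            }
        )
    return pd.DataFrame(rows)
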