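"""End-to-end pipeline: generate -> kinematics -> model fit -> time-frequency
-> decoding -> stats, driven by one structured config with a single seed.

Every stage reads its inputs from, and writes its outputs to, the artifact
directory, so stages can be re-run independently (the CLI exposes them as
subcommands).  All randomness derives deterministically from the top-level
seed through fixed named substreams; running the same config twice produces
byte-identical tables.  A manifest records the config hash and library
versions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import adaptation, decoding, kinematics, stats, synthgen, timefreq

__all__ = [
    "PipelineConfig",
    "DesignConfig",
    "AnalysisConfig",
    "DecoderConfig",
    "load_config",
    "run_pipeline",
    "decoding_experiment",
    "STAGES",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DesignConfig:
    n_subjects: int = 8
    trials_per_block: int = 30
    rotation_increment: float = 0.2
    rotation_ceiling: float = 20.0


@dataclass(frozen=True)
class DecoderConfig:
    C: float = 1.0
    n_perm: int = 1000
    correction: str = "max"
    # (band, group, alignment) triplets; None = every combination.
    targets: tuple[tuple[str, str, str], ...] | None = None


@dataclass(frozen=True)
class AnalysisConfig:
    wavelet_mode: str = "fixed_cycles"
    n_cycles: float = 3.0
    fixed_window_s: float = 0.2
    # Channels carried through the time-frequency analysis.
    tfr_channels: tuple[str, ...] = ("Fz", "C3", "P3", "Pz", "P4")
    baseline_reach: tuple[float, float] = (-1.5, -1.0)
    baseline_feedback: tuple[float, float] = (-0.1, 0.0)
    outlier_window: int = 5
    outlier_k: float = 3.0
    fit_intercept: bool = False
    d_convention: str = "dz"
    decoder: DecoderConfig = field(default_factory=DecoderConfig)


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    design: DesignConfig = field(default_factory=DesignConfig)
    learner: synthgen.LearnerParams = field(default_factory=synthgen.LearnerParams)
    inject_outliers: int = 2
    eeg: synthgen.EEGParams | None = field(default_factory=synthgen.EEGParams)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)


def _build(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ValueError(f"config section {path or '<root>'} must be a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - names)
    if unknown:
        raise ValueError(f"unknown config key(s) {unknown} in section {path or '<root>'}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        sub = _SUBSECTIONS.get((cls, f.name))
        if sub is not None and v is not None:
            v = _build(sub, v, f"{path}.{f.name}" if path else f.name)
        elif (cls, f.name) in _TUPLE_FIELDS and v is not None:
            v = _TUPLE_FIELDS[(cls, f.name)](v)
        kwargs[f.name] = v
    return cls(**kwargs)


def _parse_effects(items) -> tuple[synthgen.EEGEffect, ...]:
    effects = []
    for i, d in enumerate(items):
        eff = _build(synthgen.EEGEffect, dict(d), f"eeg.effects[{i}]")
        effects.append(
            dataclasses.replace(
                eff,
                band=tuple(eff.band),
                channels=tuple(eff.channels),
                window=tuple(eff.window),
            )
        )
    return tuple(effects)


_SUBSECTIONS = {
    (PipelineConfig, "design"): DesignConfig,
    (PipelineConfig, "learner"): synthgen.LearnerParams,
    (PipelineConfig, "eeg"): synthgen.EEGParams,
    (PipelineConfig, "analysis"): AnalysisConfig,
    (AnalysisConfig, "decoder"): DecoderConfig,
}

_TUPLE_FIELDS = {
    (synthgen.EEGParams, "channels"): tuple,
    (synthgen.EEGParams, "effects"): _parse_effects,
    (AnalysisConfig, "tfr_channels"): tuple,
    (AnalysisConfig, "baseline_reach"): tuple,
    (AnalysisConfig, "baseline_feedback"): tuple,
    (DecoderConfig, "targets"): lambda v: tuple(tuple(t) for t in v),
    (synthgen.LearnerParams, "rt_mean"): dict,
    (synthgen.LearnerParams, "fixation_delay_range"): tuple,
    (synthgen.EEGEffect, "band"): tuple,
    (synthgen.EEGEffect, "channels"): tuple,
    (synthgen.EEGEffect, "window"): tuple,
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML config (unknown keys rejected); ``None`` gives defaults."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        data.update(overrides)
    return _build(PipelineConfig, data, "")


def _config_dict(cfg) -> dict:
    if dataclasses.is_dataclass(cfg):
        return {f.name: _config_dict(getattr(cfg, f.name)) for f in dataclasses.fields(cfg)}
    if isinstance(cfg, (list, tuple)):
        return [_config_dict(v) for v in cfg]
    if isinstance(cfg, dict):
        return {k: _config_dict(v) for k, v in cfg.items()}
    if isinstance(cfg, np.ndarray):
        return cfg.tolist()
    return cfg


def config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(_config_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


# --------------------------------------------------------------------------
# Stages
# --------------------------------------------------------------------------

def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage {stage!r}: missing prerequisite file {path}; run the earlier stages first"
        )
    return path


def stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    design = synthgen.make_design(
        n_subjects=cfg.design.n_subjects,
        seed=cfg.seed,
        trials_per_block=cfg.design.trials_per_block,
        rotation_increment=cfg.design.rotation_increment,
        rotation_ceiling=cfg.design.rotation_ceiling,
    )
    trials, traj = synthgen.simulate_behavior(
        design, cfg.learner, inject_outliers=cfg.inject_outliers
    )
    recordings = None
    if cfg.eeg is not None:
        recordings = synthgen.simulate_eeg(design, trials, cfg.eeg)
    synthgen.write_dataset(out / "dataset", trials, traj, recordings)
    log.info("stage=simulate subjects=%d trials=%d", design.n_subjects, len(trials))


def stage_behavior(cfg: PipelineConfig, out: Path) -> None:
    trials = pd.read_csv(_require(out / "dataset" / "trials.csv", "behavior"))
    traj = pd.read_csv(_require(out / "dataset" / "trajectories.csv", "behavior"))
    kin = kinematics.compute_trial_kinematics(
        trials, traj, outlier_window=cfg.analysis.outlier_window, outlier_k=cfg.analysis.outlier_k
    )
    kin.to_csv(out / "kinematics.csv", index=False, float_format="%.17g")
    log.info(
        "stage=behavior trials=%d excluded=%d", len(kin), int(kin["excluded"].sum())
    )


def _schedule_from_cfg(cfg: PipelineConfig) -> adaptation.RotationSchedule:
    tpb = cfg.design.trials_per_block
    return adaptation.build_rotation_schedule(
        n_baseline=tpb,
        n_adapt=4 * tpb,
        n_washout=tpb,
        increment=cfg.design.rotation_increment,
        ceiling=cfg.design.rotation_ceiling,
    )


def stage_fit(cfg: PipelineConfig, out: Path) -> None:
    kin = pd.read_csv(_require(out / "kinematics.csv", "fit"))
    sched = _schedule_from_cfg(cfg)
    tpb = cfg.design.trials_per_block
    fit_rows, summary_rows = [], []
    for (subject, task), sub in kin.groupby(["subject", "task"], sort=True):
        sub = sub.sort_values("trial_overall")
        adapt = sub[sub["block_role"] == "adaptation"]
        fit = adaptation.estimate_state_space(
            adapt["hand_angle_deg"].to_numpy(float),
            sched,
            valid=~adapt["excluded"].to_numpy(bool) & np.isfinite(adapt["hand_angle_deg"]),
            intercept=cfg.analysis.fit_intercept,
        )
        fit_rows.append(
            dict(subject=subject, task=task, A_hat=fit.A_hat, B_hat=fit.B_hat,
                 R2=fit.r2, n_pairs=fit.n_pairs)
        )
        summ = adaptation.adaptation_metrics(sub, sched)
        row = dict(subject=subject, task=task, baseline_sd_deg=summ.baseline_sd,
                   aftereffect_deg=summ.aftereffect)
        for i in range(4):
            row[f"block{i + 1}_mean_hand_angle_deg"] = summ.block_mean_hand_angle[i]
            row[f"block{i + 1}_mean_abs_error_deg"] = summ.block_mean_abs_error[i]
        for name, v in summ.block_mean_rt.items():
            row[f"rt_{name}_s"] = v
        for name, v in summ.block_mean_mt.items():
            row[f"mt_{name}_s"] = v
        summary_rows.append(row)
    pd.DataFrame(fit_rows).to_csv(out / "fits.csv", index=False, float_format="%.17g")
    pd.DataFrame(summary_rows).to_csv(out / "summary.csv", index=False, float_format="%.17g")
    log.info("stage=fit series=%d adaptation_trials=%d", len(fit_rows), 4 * tpb)


def stage_tfr(cfg: PipelineConfig, out: Path) -> None:
    if cfg.eeg is None:
        raise ValueError("stage 'tfr': the configuration disables EEG simulation")
    _require(out / "dataset" / "eeg", "tfr")
    _, _, recordings = synthgen.read_dataset(out / "dataset", load_eeg=True)
    if not recordings:
        raise FileNotFoundError("stage 'tfr': no EEG recordings found in the dataset")
    baselines = {
        "reach_onset": cfg.analysis.baseline_reach,
        "feedback": cfg.analysis.baseline_feedback,
    }
    per_electrode, per_group = [], []
    t0 = time.perf_counter()
    for (subject, task), rec in sorted(recordings.items()):
        keep = [c for c in cfg.analysis.tfr_channels if c in rec.channels]
        idx = [rec.channels.index(c) for c in keep]
        rec = timefreq.EEGRecording(
            channels=tuple(keep), fs=rec.fs, data=rec.data[idx], markers=rec.markers
        )
        rec = timefreq.ica_clean(timefreq.preprocess_raw(rec))
        for align in ("reach_onset", "feedback"):
            epochs = timefreq.epoch_by_event(rec, align)
            tf = timefreq.morlet_tfr(
                epochs,
                mode=cfg.analysis.wavelet_mode,
                n_cycles=cfg.analysis.n_cycles,
                window_s=cfg.analysis.fixed_window_s,
            )
            tf_db = timefreq.db_normalize(tf, baselines[align])
            singles = {c: (c,) for c in keep}
            bp_e = timefreq.band_average(tf_db, electrode_groups=singles)
            bp_e = bp_e.rename(columns={"group": "electrode", "value": "db"})
            bp_e.insert(0, "subject", subject)
            bp_e.insert(1, "task", task)
            bp_e.insert(2, "alignment", align)
            per_electrode.append(bp_e)
            groups = {
                g: chans
                for g, chans in timefreq.ELECTRODE_GROUPS.items()
                if set(chans) <= set(keep)
            }
            bp_g = timefreq.band_average(tf_db, electrode_groups=groups)
            bp_g = bp_g.rename(columns={"value": "db"})
            bp_g.insert(0, "subject", subject)
            bp_g.insert(1, "task", task)
            bp_g.insert(2, "alignment", align)
            per_group.append(bp_g)
    pd.concat(per_electrode, ignore_index=True).to_csv(
        out / "bandpower_electrode.csv", index=False, float_format="%.17g"
    )
    pd.concat(per_group, ignore_index=True).to_csv(
        out / "bandpower_group.csv", index=False, float_format="%.17g"
    )
    log.info(
        "stage=tfr recordings=%d elapsed=%.1fs", len(recordings), time.perf_counter() - t0
    )


def _decoder_targets(cfg: PipelineConfig) -> tuple[tuple[str, str, str], ...]:
    if cfg.analysis.decoder.targets is not None:
        return cfg.analysis.decoder.targets
    return tuple(
        (band, group, align)
        for band in timefreq.BANDS
        for group in timefreq.ELECTRODE_GROUPS
        for align in ("feedback", "reach_onset")
    )


def stage_decode(cfg: PipelineConfig, out: Path) -> None:
    bp = pd.read_csv(_require(out / "bandpower_electrode.csv", "decode"))
    dec_dir = out / "decoding"
    dec_dir.mkdir(exist_ok=True)
    rng = synthgen._rng(cfg.seed, 3)  # decoding permutation substream
    d = cfg.analysis.decoder
    for band, group, align in _decoder_targets(cfg):
        electrodes = timefreq.ELECTRODE_GROUPS.get(group, (group,))
        ds = decoding.assemble_features(bp, band, electrodes, align)
        res = decoding.permutation_null(
            ds, n_perm=d.n_perm, seed=rng, correction=d.correction, C=d.C
        )
        tab = pd.DataFrame(
            dict(
                time_ms=res.times_ms,
                accuracy=res.accuracy,
                chance=res.chance,
                threshold=res.threshold,
                significant=res.significant,
            )
        )
        stem = f"{band}_{group}_{align}"
        tab.to_csv(dec_dir / f"{stem}.csv", index=False, float_format="%.17g")
        null = res.null if res.null.ndim == 2 else res.null[:, None]
        pd.DataFrame(null).to_csv(
            dec_dir / f"{stem}_null.csv", index=False, float_format="%.17g"
        )
        log.info(
            "stage=decode target=%s max_accuracy=%.3f significant_bins=%d",
            stem, float(res.accuracy.max()), int(res.significant.sum()),
        )


def stage_stats(cfg: PipelineConfig, out: Path) -> None:
    fits = pd.read_csv(_require(out / "fits.csv", "stats"))
    summary = pd.read_csv(_require(out / "summary.csv", "stats"))
    conv = cfg.analysis.d_convention

    t_rows = []
    paired_measures = {
        "retention_rate_A": (fits, "A_hat"),
        "adaptation_rate_B": (fits, "B_hat"),
        "baseline_sd_deg": (summary, "baseline_sd_deg"),
        "aftereffect_deg": (summary, "aftereffect_deg"),
    }
    for name, (tab, col) in paired_measures.items():
        wide = tab.pivot(index="subject", columns="task", values=col)
        res = stats.paired_t_cohen_d(
            wide["visual"].to_numpy(), wide["memory"].to_numpy(), d_convention=conv
        )
        t_rows.append(
            dict(measure=name, test="paired_t", df1=res.df, df2="", statistic=res.t,
                 p=res.p, effect_size=res.d, effect_convention=res.d_convention,
                 mean_diff_visual_minus_memory=res.mean_diff)
        )
    pd.DataFrame(t_rows).to_csv(out / "stats_t.csv", index=False, float_format="%.17g")

    anova_rows = []
    anova_specs = {
        "mean_hand_angle_deg": [f"block{i}_mean_hand_angle_deg" for i in range(1, 5)],
        "mean_abs_error_deg": [f"block{i}_mean_abs_error_deg" for i in range(1, 5)],
        "reaction_time_s": ["rt_baseline_s"] + [f"rt_adaptation_{i}_s" for i in range(1, 5)],
        "movement_time_s": ["mt_baseline_s"] + [f"mt_adaptation_{i}_s" for i in range(1, 5)],
    }
    for measure, cols in anova_specs.items():
        if not set(cols) <= set(summary.columns):
            continue
        long = summary.melt(
            id_vars=["subject", "task"], value_vars=cols, var_name="block", value_name="y"
        )
        res = stats.rm_anova_two_way(long, "y", "subject", "task", "block")
        res.insert(0, "measure", measure)
        anova_rows.append(res)
    pd.concat(anova_rows, ignore_index=True).to_csv(
        out / "stats_anova.csv", index=False, float_format="%.17g"
    )
    log.info("stage=stats paired_tests=%d anovas=%d", len(t_rows), len(anova_rows))


def stage_report(cfg: PipelineConfig, out: Path) -> None:
    lines = ["# reachadapt pipeline report", ""]
    lines.append(f"- config hash: `{config_hash(cfg)}`")
    lines.append(f"- seed: {cfg.seed}")
    lines.append(f"- subjects: {cfg.design.n_subjects}; trials/block: {cfg.design.trials_per_block}")
    lines.append("")
    kin_path = out / "kinematics.csv"
    if kin_path.exists():
        kin = pd.read_csv(kin_path)
        lines.append("## Behaviour")
        lines.append(f"- trials analysed: {len(kin)}; excluded: {int(kin['excluded'].sum())}")
        reasons = kin.loc[kin["excluded"], "exclusion_reason"].value_counts().to_dict()
        if reasons:
            lines.append(f"- exclusion reasons: {reasons}")
        lines.append("")
    fits_path = out / "fits.csv"
    if fits_path.exists():
        fits = pd.read_csv(fits_path)
        lines.append("## State-space fits (per subject, adaptation block)")
        for task, sub in fits.groupby("task"):
            lines.append(
                f"- {task}: A = {sub['A_hat'].mean():.3f} +/- {sub['A_hat'].std(ddof=1):.3f}, "
                f"B = {sub['B_hat'].mean():.3f} +/- {sub['B_hat'].std(ddof=1):.3f}, "
                f"R2 = {sub['R2'].mean():.3f} +/- {sub['R2'].std(ddof=1):.3f}"
            )
        lines.append("")
    stats_path = out / "stats_t.csv"
    if stats_path.exists():
        t_tab = pd.read_csv(stats_path)
        lines.append("## Paired t tests (visual - memory)")
        for row in t_tab.itertuples(index=False):
            lines.append(
                f"- {row.measure}: t({row.df1}) = {row.statistic:.3f}, p = {row.p:.3f}, "
                f"d_{row.effect_convention} = {row.effect_size:.3f}"
            )
        lines.append("")
    anova_path = out / "stats_anova.csv"
    if anova_path.exists():
        an = pd.read_csv(anova_path)
        lines.append("## Repeated-measures ANOVA (task x block)")
        for row in an.itertuples(index=False):
            lines.append(
                f"- {row.measure} / {row.effect}: F({row.df_effect},{row.df_error}) = "
                f"{row.F:.3f}, p = {row.p:.3f}, partial eta^2 = {row.partial_eta_sq:.3f}"
            )
        lines.append("")
    dec_dir = out / "decoding"
    if dec_dir.is_dir():
        lines.append("## Decoding (task type from band power)")
        any_sig = False
        for f in sorted(dec_dir.glob("*.csv")):
            if f.name.endswith("_null.csv"):
                continue
            tab = pd.read_csv(f)
            sig = tab[tab["significant"]]
            if len(sig):
                any_sig = True
                wins = ", ".join(f"{int(t)} ms" for t in sig["time_ms"])
                lines.append(
                    f"- {f.stem}: max accuracy {tab['accuracy'].max():.3f}; "
                    f"significant at {wins}"
                )
            else:
                lines.append(
                    f"- {f.stem}: max accuracy {tab['accuracy'].max():.3f}; "
                    f"no significant time bins"
                )
        if not any_sig:
            lines.append("- no significant decoding windows in any target")
        lines.append("")
    (out / "report.md").write_text("\n".join(lines))

    import scipy
    import sklearn

    manifest = dict(
        config_hash=config_hash(cfg),
        config=_config_dict(cfg),
        versions=dict(
            numpy=np.__version__,
            scipy=scipy.__version__,
            pandas=pd.__version__,
            sklearn=sklearn.__version__,
        ),
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def decoding_experiment(
    seed: int,
    db_difference: float = 3.0,
    n_subjects: int = 8,
    trials_per_block: int = 3,
    n_perm: int = 200,
    band: str = "delta",
    electrodes: tuple[str, ...] = ("P3", "Pz", "P4"),
    align: str = "feedback",
    window: tuple[float, float] = (0.0, 1.0),
) -> tuple[decoding.DecodingResult, pd.DataFrame]:
    """One in-memory generator -> time-frequency -> decoder experiment.

    Simulates a (possibly scaled-down) two-task experiment whose EEG carries a
    band-limited effect of ``db_difference`` dB (visual - memory) on
    ``electrodes`` around the ``align`` event, runs the canonical analysis
    chain on those channels, and returns the permutation-calibrated decoding
    result together with the per-electrode band-power table.  Closes the loop
    between the generator's declared effect sizes and the analysis modules;
    used by calibration studies and the acceptance script.
    """
    band_hz = timefreq.BANDS[band]
    design = synthgen.make_design(n_subjects, seed=seed, trials_per_block=trials_per_block)
    trials, _ = synthgen.simulate_behavior(design, inject_outliers=0)
    effects = ()
    if db_difference != 0.0:
        effects = (
            synthgen.EEGEffect(
                band=band_hz, channels=electrodes, align=align,
                window=window, db_difference=db_difference,
            ),
        )
    params = synthgen.EEGParams(channels=electrodes, effects=effects)
    recordings = synthgen.simulate_eeg(design, trials, params)
    rows = []
    for (subject, task), rec in sorted(recordings.items()):
        rec = timefreq.preprocess_raw(rec)
        epochs = timefreq.epoch_by_event(rec, align)
        tf_db = timefreq.db_normalize(timefreq.morlet_tfr(epochs))
        bp = timefreq.band_average(tf_db, electrode_groups={c: (c,) for c in rec.channels})
        bp = bp.rename(columns={"group": "electrode", "value": "db"})
        bp.insert(0, "subject", subject)
        bp.insert(1, "task", task)
        bp.insert(2, "alignment", align)
        rows.append(bp)
    table = pd.concat(rows, ignore_index=True)
    ds = decoding.assemble_features(table, band, electrodes, align)
    result = decoding.permutation_null(ds, n_perm=n_perm, seed=seed + 1)
    return result, table


STAGES = {
    "simulate": stage_simulate,
    "behavior": stage_behavior,
    "fit": stage_fit,
    "tfr": stage_tfr,
    "decode": stage_decode,
    "stats": stage_stats,
    "report": stage_report,
}


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> Path:
    """Run every stage in order and return the artifact directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, fn in STAGES.items():
        if cfg.eeg is None and name in ("tfr", "decode"):
            log.info("stage=%s skipped (EEG disabled in config)", name)
            continue
        t0 = time.perf_counter()
        fn(cfg, out)
        log.info("stage=%s done elapsed=%.1fs", name, time.perf_counter() - t0)
    return out
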