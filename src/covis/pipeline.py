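"""End-to-end pipeline: simulate -> behavior -> erp -> pupil -> rsa -> clusters.

Each stage is self-contained and re-derives its inputs from the seeded
generators, so stages can run independently and memory stays bounded
(EEG epochs for one subject at a time). ``run_pipeline`` executes all
six stages, writes their artifacts under ``config.out_dir`` and
returns a serializable run report; a stage failure is recorded with
its cause and the downstream stages are skipped.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from covis import behavior as beh
from covis import cluster_stats as cs
from covis import erp as erp_mod
from covis import io as cio
from covis import pupil as pup
from covis import rsa as rsa_mod
from covis.config import PipelineConfig
from covis.synth import build_design, simulate_behavior, simulate_eeg, simulate_pupil

STAGES = ("simulate", "behavior", "erp", "pupil", "rsa", "clusters")


@dataclass
class RunReport:
    seed: int
    config: dict
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(asdict(self), indent=2, default=str))
        return path


def _subject_tables(cfg: PipelineConfig, subject: int,
                    n_per_type: int | None = None):
    gp = cfg.gen_params(subject)
    design = build_design(
        n_per_type=n_per_type or cfg.n_per_type,
        n_blocks=cfg.n_blocks if (n_per_type or cfg.n_per_type) % cfg.n_blocks == 0 else 1,
        seed=gp.seed,
    )
    behavior = simulate_behavior(design, gp)
    return gp, design, behavior


def stage_simulate(cfg: PipelineConfig, out: Path) -> dict:
    """Generate and store the per-subject designs and behavioral tables."""
    frames = []
    for s in range(1, cfg.n_subjects + 1):
        _, design, behavior = _subject_tables(cfg, s)
        behavior.insert(0, "subject", s)
        frames.append(behavior)
    table = pd.concat(frames, ignore_index=True)
    path = cio.write_trial_table(table, out / "behavior.csv")
    return {"behavior_csv": str(path), "n_trials": int(len(table))}


def stage_behavior(cfg: PipelineConfig, out: Path) -> dict:
    """Psychometric fits, type-2 AUC, and context contrasts per measure."""
    table = cio.read_trial_table(out / "behavior.csv")
    fits = beh.fit_weibull_table(table, by=("subject", "context"))

    aucs = []
    for (s, ctx), grp in table.groupby(["subject", "context"]):
        roc = beh.type2_auc(grp["correct"].to_numpy(),
                            grp["confidence"].to_numpy())
        aucs.append({"subject": s, "context": ctx, "auc": roc.auc})
    fits = fits.merge(pd.DataFrame(aucs), on=["subject", "context"])
    fits.to_csv(out / "behavior_fits.csv", index=False)

    contrasts = {}
    per_measure = {
        "accuracy": table.groupby(["subject", "context"])["correct"]
        .mean().rename("value").reset_index(),
        "rt": table.groupby(["subject", "context"])["rt_ms"]
        .mean().rename("value").reset_index(),
        "confidence": table.groupby(["subject", "context"])["confidence"]
        .mean().rename("value").reset_index(),
        "auc": pd.DataFrame(aucs).rename(columns={"auc": "value"}),
        "lambda": fits.rename(columns={"lambda_hat": "value"})[
            ["subject", "context", "value"]
        ],
    }
    for name, df in per_measure.items():
        res = beh.two_stage_contrast(df)
        contrasts[name] = {
            "t": res.t, "df": res.df, "p": res.p, "d": res.cohens_d,
            "mean_public_minus_private": res.mean_diff,
        }
    (out / "behavior_contrasts.json").write_text(json.dumps(contrasts, indent=2))
    return {"fits_csv": str(out / "behavior_fits.csv"), "contrasts": contrasts}


def stage_erp(cfg: PipelineConfig, out: Path) -> dict:
    """Single-trial CPP amplitudes and the group coherence/context checks."""
    rows = []
    for s in range(1, cfg.n_subjects + 1):
        gp, design, behavior = _subject_tables(cfg, s)
        epochs = simulate_eeg(
            design, behavior, gp,
            epoch_window_ms=cfg.epoch_window_ms, fs_hz=cfg.eeg_fs_hz,
        )
        amp = erp_mod.cpp_amplitude(
            epochs, window_ms=cfg.cpp_window_ms, baseline_ms=cfg.cpp_baseline_ms
        )
        amp.insert(0, "subject", s)
        amp = amp.merge(design[["trial_id", "coherence", "context"]],
                        on="trial_id")
        rows.append(amp)
    table = pd.concat(rows, ignore_index=True)
    cio.write_trial_table(table, out / "cpp.csv")

    # two-stage group tests: per-subject coherence slope; context difference
    slopes, ctx_vals = [], []
    for s, grp in table.groupby("subject"):
        x = np.log2(grp["coherence"].to_numpy(dtype=float))
        b = np.polyfit(x, grp["amplitude"].to_numpy(), 1)[0]
        slopes.append(b)
        for ctx, g2 in grp.groupby("context"):
            ctx_vals.append({"subject": s, "context": ctx,
                             "value": g2["amplitude"].mean()})
    slopes = np.asarray(slopes)
    from scipy import stats as sps

    t_slope, p_slope = sps.ttest_1samp(slopes, 0.0)
    ctx_res = beh.two_stage_contrast(pd.DataFrame(ctx_vals))
    summary = {
        "coherence_slope": {"t": float(t_slope), "p": float(p_slope),
                            "mean": float(slopes.mean())},
        "context": {"t": ctx_res.t, "p": ctx_res.p, "d": ctx_res.cohens_d},
    }
    (out / "cpp_group.json").write_text(json.dumps(summary, indent=2))
    return {"cpp_csv": str(out / "cpp.csv"), "group": summary}


def stage_pupil(cfg: PipelineConfig, out: Path) -> dict:
    """Pupil cleaning chain, epoching, windowed means, time-resolved GLM."""
    n_subj = cfg.pupil_subjects or cfg.n_subjects
    n_per_type = cfg.pupil_n_per_type or cfg.n_per_type
    all_epochs, infos, resp_rows = [], [], []
    for s in range(1, n_subj + 1):
        gp, design, behavior = _subject_tables(cfg, s, n_per_type=n_per_type)
        rec = simulate_pupil(design, behavior, gp)
        cleaned, interp_mask = pup.preprocess(
            rec.left, rec.right, rec.blink_events, n_mad=cfg.n_mad
        )
        epochs = pup.epoch_and_baseline(
            cleaned, rec.motion_onset_s,
            baseline_ms=cfg.pupil_baseline_ms,
            trial_ids=rec.trial_ids, interp_mask=interp_mask,
        )
        keep = np.isin(design["trial_id"].to_numpy(), epochs.trial_ids)
        info = design.loc[keep, ["coherence", "context"]].copy()
        info["confidence"] = behavior.loc[keep, "confidence"].to_numpy()
        info["subject"] = s
        all_epochs.append(epochs)
        infos.append(info)

        rl = pup.response_locked_mean(cleaned, rec.response_s, layout="post")
        ctx = design.loc[keep, "context"].to_numpy()
        for v, c in zip(rl[keep], ctx):
            if np.isfinite(v):
                resp_rows.append({"subject": s, "context": c, "value": v})

    from covis.containers import PupilEpochs

    data = np.vstack([e.data for e in all_epochs])
    merged = PupilEpochs(
        data=data,
        time_s=all_epochs[0].time_s,
        trial_ids=np.arange(1, data.shape[0] + 1),
    )
    info = pd.concat(infos, ignore_index=True)
    glm = pup.timewise_glm(merged, info, alpha=cfg.alpha)
    glm_df = pd.DataFrame({"time_s": glm.time_s})
    for j, name in enumerate(glm.predictors):
        glm_df[f"beta_{name}"] = glm.beta[j]
        glm_df[f"p_{name}"] = glm.p[j]
        glm_df[f"sig_{name}"] = glm.fdr_mask[j]
    glm_df.to_csv(out / "pupil_glm.csv", index=False)

    resp_res = beh.two_stage_contrast(pd.DataFrame(resp_rows))
    summary = {
        "glm_windows": glm.windows,
        "response_locked_context": {"t": resp_res.t, "p": resp_res.p,
                                    "d": resp_res.cohens_d},
    }
    (out / "pupil_summary.json").write_text(json.dumps(summary, indent=2))
    return {"glm_csv": str(out / "pupil_glm.csv"), "summary": summary}


def stage_rsa(cfg: PipelineConfig, out: Path) -> dict:
    """Whole-sensor RSA time courses per subject."""
    models = {
        "coherence": rsa_mod.model_rdm_coherence(),
        "context": rsa_mod.model_rdm_context(),
    }
    rows = []
    for s in range(1, cfg.n_subjects + 1):
        gp, design, behavior = _subject_tables(cfg, s)
        epochs = simulate_eeg(
            design, behavior, gp,
            epoch_window_ms=cfg.epoch_window_ms, fs_hz=cfg.eeg_fs_hz,
        )
        res = rsa_mod.rsa_timecourse(
            epochs, design, models,
            baseline_ms=cfg.rsa_baseline_ms,
            shrinkage=cfg.shrinkage, stride=cfg.rsa_stride,
        )
        for model, tau in res.tau.items():
            rows.append(pd.DataFrame({
                "subject": s, "time_ms": res.times_ms, "model": model,
                "tau": tau,
            }))
    series = pd.concat(rows, ignore_index=True)
    cio.write_rsa_series(series, out / "rsa_series.csv")
    return {"rsa_csv": str(out / "rsa_series.csv"),
            "n_subjects": cfg.n_subjects}


def stage_clusters(cfg: PipelineConfig, out: Path) -> dict:
    """Cluster-mass permutation tests on the RSA time courses."""
    series = cio.read_rsa_series(out / "rsa_series.csv")
    results, effects = [], {}
    for model, grp in series.groupby("model"):
        wide = grp.pivot_table(index="subject", columns="time_ms",
                               values="tau")
        times = wide.columns.to_numpy(dtype=float)
        values = wide.to_numpy()
        clusters = cs.cluster_permutation_test(
            values, times_ms=times, n_perm=cfg.n_perm,
            alpha_entry=cfg.alpha, seed=cfg.seed,
        )
        for c in clusters:
            results.append({
                "model": model, "t_start_ms": c.time_range_ms[0],
                "t_end_ms": c.time_range_ms[1], "mass": c.mass,
                "peak_t": c.peak_t, "mean_t": c.mean_t, "df": c.df,
                "p_corrected": c.p_corrected,
            })
        sig = [c for c in clusters if c.p_corrected is not None
               and c.p_corrected < cfg.alpha]
        if sig:
            top = max(sig, key=lambda c: c.mass)
            eff = cs.cluster_effect_size(values, top, times_ms=times)
            effects[model] = {
                "window_ms": list(top.time_range_ms),
                "mean_tau": eff.mean_stat, "sd": eff.sd,
                "cohens_d": eff.cohens_d, "ci95": list(eff.ci95),
            }
    pd.DataFrame(results).to_csv(out / "clusters.csv", index=False)
    (out / "cluster_effects.json").write_text(json.dumps(effects, indent=2))
    return {"clusters_csv": str(out / "clusters.csv"), "effects": effects}


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "behavior": stage_behavior,
    "erp": stage_erp,
    "pupil": stage_pupil,
    "rsa": stage_rsa,
    "clusters": stage_clusters,
}


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all six stages in order, recording outputs and wall time."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed, config=config.to_dict())
    failed = False
    for stage in STAGES:
        if failed:
            report.stages[stage] = {"status": "skipped"}
            continue
        t0 = time.perf_counter()
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                info = _STAGE_FUNCS[stage](config, out)
            for w in caught:
                report.warnings.append(f"{stage}: {w.message}")
            report.stages[stage] = {
                "status": "ok",
                "seconds": round(time.perf_counter() - t0, 3),
                **info,
            }
        except Exception as exc:
            report.stages[stage] = {"status": "failed", "error": str(exc)}
            failed = True

    if not failed:
        report.summary = {
            "behavioral_context_null": {
                m: report.stages["behavior"]["contrasts"][m]["p"]
                for m in ("accuracy", "rt", "confidence", "auc")
            },
            "cpp_context_null_p": report.stages["erp"]["group"]["context"]["p"],
            "pupil_context_windows_s":
                report.stages["pupil"]["summary"]["glm_windows"].get("context", []),
            "rsa_cluster_effects": report.stages["clusters"]["effects"],
        }
    report.to_json(out / "run_report.json")
    return report
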