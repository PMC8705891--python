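"""End-to-end pipeline: synthesis -> two engines -> GPS -> outcome stats.

Stage structure mirrors the study workflow: a synthetic gait laboratory
produces marker trials for a TD reference cohort and a paired pre/post CP
cohort; both kinematics engines (direct Cardan kinematics, "dk", and
multibody-optimisation inverse kinematics, "ik") reduce every trial to the
nine-variable gait vector; each engine scores every limb against its own
age-matched TD reference (model definitions are kept consistent within each
approach); and the outcome stage compares engines and classifies surgical
response against the clinical labels.

Every artefact is written under ``outdir`` with the config hash recorded in
the manifest; runs are deterministic given (config, seed).
"""

from __future__ import annotations

import hashlib
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import directkin, ik, metrics, stats, synth, trcio
from .config import PipelineConfig
from .errors import GaitProfileError
from .metrics import VARIABLES
from .model import anthropometry_of, build_generic_model

log = logging.getLogger("gaitprofile.pipeline")


@dataclass
class PipelineState:
    """In-memory hand-off between stages."""

    config: PipelineConfig
    model: object = None
    bundle: synth.CohortBundle | None = None
    limb_means: pd.DataFrame | None = None       # one row per (subject, session, engine, side)
    cycle_waveforms: list = field(default_factory=list)
    references: dict = field(default_factory=dict)
    scores: pd.DataFrame | None = None
    outcome: dict = field(default_factory=dict)
    files: list[Path] = field(default_factory=list)


def _write(state: PipelineState, path: Path, writer) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    writer(path)
    state.files.append(path)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_synth(state: PipelineState) -> None:
    cfg = state.config
    c = cfg.cohort
    sta = synth.STAModel(amplitude=c.sta_amplitude, tau=c.sta_tau,
                         harmonic_fraction=c.sta_harmonic_fraction)
    spec = synth.SyntheticCohortSpec(
        n_td=tuple(c.n_td), n_cp=c.n_cp, responder_fraction=c.responder_fraction,
        surgical_effect=dict(c.surgical_effect),
        non_responder_effect=dict(c.non_responder_effect),
        seed=cfg.seed, clinical_disagreement=c.clinical_disagreement,
        operated_bilateral_fraction=c.operated_bilateral_fraction,
        trials_per_session=c.trials_per_session, n_cycles=c.n_cycles, rate=c.rate,
        sta=sta, td_offset_sd=tuple(c.td_offset_sd),
        cp_hip_rotation_offset=tuple(c.cp_hip_rotation_offset),
        cp_knee_flexion_offset=tuple(c.cp_knee_flexion_offset),
        session_jitter_sd=c.session_jitter_sd)
    state.model = build_generic_model(subtalar_locked=cfg.subtalar_locked)
    log.info("synth: generating cohort (seed=%d, hash=%s)", cfg.seed, cfg.config_hash())
    state.bundle = synth.generate_cohort(spec, state.model)

    out = Path(cfg.outdir) / "cohort"
    _write(state, out / "metadata.csv", lambda p: state.bundle.metadata.to_csv(p, index=False))
    _write(state, out / "ground_truth.csv",
           lambda p: state.bundle.ground_truth.to_csv(p, index=False))
    for trial in state.bundle.trials:
        stem = f"{trial.meta['subject']}_{trial.meta['session']}_t{trial.meta['trial_id']}"
        _write(state, out / f"{stem}.trc", lambda p, t=trial: trcio.write_trc(t, p))
        _write(state, out / f"{stem}_events.csv",
               lambda p, t=trial: trcio.write_events_csv(t, p))


def stage_engines(state: PipelineState) -> None:
    cfg = state.config
    anth = anthropometry_of(state.model)
    ik_cfg = ik.IKConfig()
    rows = []
    all_cycles = []
    t0 = _time.time()
    for trial in state.bundle.trials:
        per_engine = {}
        if "dk" in cfg.engines:
            frames = directkin.build_pig_frames(trial, anth)
            per_engine["dk"] = directkin.extract_waveforms_dk(trial, frames, T=cfg.T)
        if "ik" in cfg.engines:
            result = ik.solve_trial(state.model, trial, ik_cfg)
            per_engine["ik"] = ik.extract_waveforms_ik(state.model, trial, result, T=cfg.T)
        for engine, wfs in per_engine.items():
            all_cycles.extend(wfs)
            for side in ("right", "left"):
                cyc = [w for w in wfs if w.side == side]
                if not cyc:
                    continue
                mean = metrics.average_trials(cyc)
                rows.append({"subject": trial.meta["subject"],
                             "session": trial.meta["session"],
                             "group": trial.meta["group"],
                             "trial_id": trial.meta["trial_id"],
                             "engine": engine, "side": side, "waveform": mean})
    log.info("engines: %d trials x %s in %.1f s", len(state.bundle.trials),
             cfg.engines, _time.time() - t0)
    df = pd.DataFrame(rows)
    # limb mean across trials of a session
    merged = []
    for (subject, session, engine, side), sub in df.groupby(
            ["subject", "session", "engine", "side"]):
        mean = metrics.average_trials(list(sub["waveform"]))
        mean.meta.update(subject=subject, session=session, engine=engine)
        merged.append({"subject": subject, "session": session, "engine": engine,
                       "side": side, "group": sub["group"].iloc[0], "waveform": mean})
    state.limb_means = pd.DataFrame(merged)
    state.cycle_waveforms = all_cycles
    out = Path(cfg.outdir) / "waveforms"
    _write(state, out / "limb_mean_waveforms.csv",
           lambda p: trcio.waveforms_to_frame(list(state.limb_means["waveform"])).to_csv(
               p, index=False))


def stage_metrics(state: PipelineState) -> None:
    cfg = state.config
    ages = dict(zip(state.bundle.metadata["subject"], state.bundle.metadata["age"]))
    lm = state.limb_means
    refs: dict[str, dict[str, metrics.ReferenceProfile]] = {}
    for engine in cfg.engines:
        td = lm[(lm.engine == engine) & (lm.group == "TD")]
        refs[engine] = metrics.build_reference(
            list(td["waveform"]), [ages[s] for s in td["subject"]],
            tuple(cfg.age_group_boundaries))
    state.references = refs

    rows = []
    for _, rec in lm.iterrows():
        group = metrics.age_group_of(ages[rec.subject], tuple(cfg.age_group_boundaries))
        gvs_vec = metrics.gvs(rec.waveform, refs[rec.engine][group])
        gps_score = metrics.gps(gvs_vec)
        row = {"subject": rec.subject, "session": rec.session, "engine": rec.engine,
               "side": rec.side, "group": rec.group, "age_group": group,
               "gps": gps_score.value}
        row.update({f"gvs_{v}": s for v, s in zip(VARIABLES, gvs_vec.scores)})
        rows.append(row)
    scores = pd.DataFrame(rows)

    si_rows = []
    for (subject, session, engine), sub in scores.groupby(["subject", "session", "engine"]):
        if set(sub["side"]) == {"right", "left"}:
            gl = sub[sub.side == "left"]["gps"].iloc[0]
            gr = sub[sub.side == "right"]["gps"].iloc[0]
            si = metrics.symmetry_index(
                metrics.GPSScore(gl, 9, "left", session),
                metrics.GPSScore(gr, 9, "right", session))
            si_rows.append({"subject": subject, "session": session, "engine": engine,
                            "symmetry_index": si})
    state.scores = scores
    out = Path(cfg.outdir) / "scores"
    _write(state, out / "gps_gvs.csv", lambda p: scores.to_csv(p, index=False))
    _write(state, out / "symmetry_index.csv",
           lambda p: pd.DataFrame(si_rows).to_csv(p, index=False))


def stage_outcomes(state: PipelineState) -> None:
    cfg = state.config
    scores = state.scores
    gt = state.bundle.ground_truth
    results: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed}

    # --- responder classification & agreement (CP operated limbs) ---------
    if len(cfg.engines) >= 1:
        records = []
        cp_gt = gt[(gt.group == "CP")]
        for _, row in cp_gt.iterrows():
            sub = scores[(scores.subject == row.subject) & (scores.side == row.side)]
            pre = {e: sub[(sub.engine == e) & (sub.session == "pre")]["gps"].iloc[0]
                   for e in cfg.engines}
            post = {e: sub[(sub.engine == e) & (sub.session == "post")]["gps"].iloc[0]
                    for e in cfg.engines}
            records.append(stats.OutcomeRecord(
                subject=row.subject, limb=row.side, operated=bool(row.operated),
                gps_pre=pre, gps_post=post, clinical_label=row.clinical_label,
                mcid=cfg.mcid))
        state.outcome["records"] = records
        operated = [r for r in records if r.operated]
        truth = {(row.subject, row.side): row.responder_true
                 for _, row in cp_gt.iterrows()}
        accuracy = {e: float(np.mean([r.responder[e] == truth[(r.subject, r.limb)]
                                      for r in operated])) for e in cfg.engines}
        results["responder_recovery"] = accuracy
        if len(cfg.engines) == 2:
            summary = stats.tabulate_agreement(records)
            results["agreement"] = {
                "n_limbs": summary.n_limbs,
                "engine_vs_clinical": summary.engine_vs_clinical,
                "engine_concordance": summary.engine_concordance,
                "concordance_fraction": summary.engine_concordance / summary.n_limbs,
                "n_discordant": len(summary.discordant)}
            results["discordant"] = summary.discordant

    # --- engine comparison -------------------------------------------------
    if len(cfg.engines) == 2:
        dk_s = scores[scores.engine == "dk"].set_index(["subject", "session", "side"])
        ik_s = scores[scores.engine == "ik"].set_index(["subject", "session", "side"])
        joined = dk_s.join(ik_s, lsuffix="_dk", rsuffix="_ik", how="inner")
        rho, p_rho, _ = stats.paired_tests(joined["gps_dk"], joined["gps_ik"], "spearman")
        w_stat, p_w, _ = stats.paired_tests(joined["gps_dk"], joined["gps_ik"], "wilcoxon")
        results["gps_consistency"] = {
            "spearman_rho": rho, "spearman_p": p_rho,
            "wilcoxon_statistic": w_stat, "wilcoxon_p": p_w,
            "mean_abs_difference": float(np.mean(np.abs(joined.gps_dk - joined.gps_ik))),
            "n": int(len(joined))}

        operated = [r for r in state.outcome["records"] if r.operated]
        if len(operated) >= 2:
            d_dk = [r.delta_gps["dk"] for r in operated]
            d_ik = [r.delta_gps["ik"] for r in operated]
            ba = stats.bland_altman(d_dk, d_ik)
            results["delta_gps_agreement"] = {
                "bias": ba.bias, "sd": ba.sd, "loa_low": ba.loa_low,
                "loa_high": ba.loa_high}
            if len(operated) >= 3:
                t_stat, p_t, _ = stats.paired_tests(d_dk, d_ik, "paired_t")
                results["delta_gps_agreement"].update(paired_t=t_stat, paired_t_p=p_t)

        # per-variable RMSD / R2 between engines on TD cycles (paired by cycle)
        td_cycles: dict = {}
        for w in state.cycle_waveforms:
            if w.meta.get("group") != "TD":
                continue
            key = (w.meta["subject"], w.meta["session"], w.meta["trial_id"],
                   w.side, w.cycle_id)
            td_cycles.setdefault(key, {})[w.meta["engine"]] = w
        rmsd_rows, r2_rows = [], []
        for key, pair in td_cycles.items():
            if set(pair) != {"dk", "ik"}:
                continue
            rmsd_rows.append({"subject": key[0], "side": key[3],
                              **stats.waveform_rmsd(pair["dk"], pair["ik"])})
            r2_rows.append({"subject": key[0], "side": key[3],
                            **stats.waveform_r2(pair["dk"], pair["ik"])})
        rmsd_df = pd.DataFrame(rmsd_rows)
        results["rmsd_summary"] = {
            v: {"median": float(rmsd_df[v].median()),
                "iqr": float(rmsd_df[v].quantile(0.75) - rmsd_df[v].quantile(0.25))}
            for v in VARIABLES} if len(rmsd_df) else {}
        state.outcome["rmsd_df"] = rmsd_df
        state.outcome["r2_df"] = pd.DataFrame(r2_rows)

        # pointwise TD waveform comparison between engines (paired by limb)
        lm = state.limb_means
        td = lm[lm.group == "TD"]
        pairs = {}
        for _, rec in td.iterrows():
            pairs.setdefault((rec.subject, rec.side), {})[rec.engine] = rec.waveform
        a = [p["dk"].values for p in pairs.values() if set(p) == {"dk", "ik"}]
        b = [p["ik"].values for p in pairs.values() if set(p) == {"dk", "ik"}]
        if len(a) >= 2:
            test = stats.pointwise_waveform_test(
                np.stack(a), np.stack(b), cfg.alpha_family, cfg.n_comparisons,
                cfg.n_permutations, seed=cfg.seed)
            results["pointwise_test"] = {
                "alpha_per_test": test.alpha_per_test,
                "significant_fraction": {v: float(m.mean()) for v, m in test.masks.items()},
                "p_values": test.p_values}

    # --- knee-axis correction group comparison -----------------------------
    kad = {
        "TD": gt[gt.group == "TD"]["kad_angle_pre"].dropna().to_numpy(),
        "CP_pre": gt[gt.group == "CP"]["kad_angle_pre"].dropna().to_numpy(),
        "CP_post": gt[gt.group == "CP"]["kad_angle_post"].dropna().to_numpy(),
    }
    if all(v.size >= 2 for v in kad.values()):
        cmp_res = stats.group_axis_comparison(kad)
        results["knee_axis_groups"] = {
            "kruskal_H": cmp_res.statistic, "p_omnibus": cmp_res.p_omnibus,
            "pairwise": cmp_res.pairwise.to_dict(orient="records")}

    state.outcome["results"] = results
    out = Path(cfg.outdir) / "outcomes"
    if "records" in state.outcome:
        rec_df = pd.DataFrame([{
            "subject": r.subject, "limb": r.limb, "operated": r.operated,
            **{f"gps_pre_{e}": r.gps_pre[e] for e in r.gps_pre},
            **{f"gps_post_{e}": r.gps_post[e] for e in r.gps_post},
            **{f"delta_gps_{e}": r.delta_gps[e] for e in r.delta_gps},
            **{f"responder_{e}": r.responder[e] for e in r.responder},
            "clinical_label": r.clinical_label} for r in state.outcome["records"]])
        _write(state, out / "outcome_records.csv", lambda p: rec_df.to_csv(p, index=False))
    if "rmsd_df" in state.outcome and len(state.outcome["rmsd_df"]):
        _write(state, out / "engine_rmsd.csv",
               lambda p: state.outcome["rmsd_df"].to_csv(p, index=False))
        _write(state, out / "engine_r2.csv",
               lambda p: state.outcome["r2_df"].to_csv(p, index=False))
    _write(state, out / "statistics.json", lambda p: trcio.write_json(p, results))


def stage_report(state: PipelineState) -> dict:
    cfg = state.config
    manifest = {
        "config": cfg.model_dump(mode="json"),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "engines_run": cfg.engines,
        "skipped_stages": [e for e in ("dk", "ik") if e not in cfg.engines],
        "files": [],
    }
    for path in state.files:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        manifest["files"].append({"path": str(path), "sha256": digest})
    out = Path(cfg.outdir) / "manifest.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    trcio.write_json(out, manifest)
    return manifest


STAGES = {"synth": stage_synth, "engines": stage_engines,
          "metrics": stage_metrics, "outcomes": stage_outcomes}
STAGE_ORDER = ("synth", "engines", "metrics", "outcomes")


def run_pipeline(config: PipelineConfig, until: str = "outcomes") -> dict:
    """Execute the pipeline through ``until`` (inclusive) and write the
    manifest.  Any stage failure aborts with the stage name."""
    if until not in STAGE_ORDER:
        raise GaitProfileError(f"unknown stage {until!r}")
    state = PipelineState(config=config)
    for name in STAGE_ORDER:
        try:
            STAGES[name](state)
        except GaitProfileError as exc:
            raise GaitProfileError(f"stage {name} failed: {exc}") from exc
        if name == until:
            break
    manifest = stage_report(state)
    manifest["results"] = state.outcome.get("results", {})
    manifest["state"] = state
    return manifest
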