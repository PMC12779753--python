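"""End-to-end synthetic pipeline orchestration.

Generates a session, simulates trial kinematics and motion, segments
and measures every trial, reduces the measures to component scores,
runs motion QC, simulates ROI BOLD with known ground truth, fits the
parametric-modulation GLMs, and writes tabular outputs.  Every trial is
accounted for in exactly one ledger category: accepted, tracking_loss,
feedback_bug, unexpected_movement, moved_in_no_movement, or
parse_failure.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import dimred, glm, io, motionqc, segment, synth

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "default_rois"]

LEDGER_CATEGORIES = (
    "accepted",
    "tracking_loss",
    "feedback_bug",
    "unexpected_movement",
    "moved_in_no_movement",
    "parse_failure",
)


def default_rois() -> dict:
    """Six motor-network ROIs with ground-truth BOLD effects.

    Modulator betas plant kinematic effects in a subset of regions so
    recovery is testable; M1 carries a motion artifact contribution.
    """
    mk = synth.BoldGenParams
    return {
        "M1": mk(modulator_betas={"PC1": 0.8}, motion_beta=0.02),
        "PMd": mk(modulator_betas={"PC1": 0.5, "PC2": 0.4}),
        "PMv": mk(modulator_betas={}),
        "SMA": mk(modulator_betas={"PC2": 0.6}),
        "SPL": mk(modulator_betas={"PC3": 0.5}),
        "IPS": mk(modulator_betas={"PC1": 0.4, "PC3": 0.4}),
    }


@dataclass
class PipelineConfig:
    """All knobs of the synthetic pipeline, with study-like defaults."""

    session: synth.SessionSpec = field(default_factory=synth.SessionSpec)
    motion: synth.MotionGenParams = field(default_factory=synth.MotionGenParams)
    error_rates: synth.ErrorRates = field(default_factory=synth.ErrorRates)
    rois: dict = field(default_factory=default_rois)
    noise_sd_mm: float = 1.0
    dropout_prob: float = 0.002
    smoothing_window: int = 5
    min_run_s: float = 0.1
    max_gap_frames: int = 10
    pca_n_perm: int = 1000
    pca_percentile: float = 95.0
    fd_thresholds: tuple = (0.5, 0.2)
    hrf: glm.HRFParams = field(default_factory=glm.HRFParams)
    event_duration_s: float = 0.0
    ar_model: str = "ar1"
    alpha: float = 0.05
    out_dir: str | None = None
    seed: int = 0

    def validate(self) -> None:
        self.session.validate()
        self.motion.validate()
        for params in self.rois.values():
            params.validate()

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        kwargs = dict(raw)
        if "session" in kwargs:
            kwargs["session"] = synth.SessionSpec(**kwargs["session"])
        if "motion" in kwargs:
            kwargs["motion"] = synth.MotionGenParams(**kwargs["motion"])
        if "error_rates" in kwargs:
            kwargs["error_rates"] = synth.ErrorRates(**kwargs["error_rates"])
        if "hrf" in kwargs:
            kwargs["hrf"] = glm.HRFParams(**kwargs["hrf"])
        if "rois" in kwargs:
            kwargs["rois"] = {
                name: synth.BoldGenParams(**p) for name, p in kwargs["rois"].items()
            }
        if "fd_thresholds" in kwargs:
            kwargs["fd_thresholds"] = tuple(kwargs["fd_thresholds"])
        return cls(**kwargs)


@dataclass
class PipelineResult:
    """Output bundle of one pipeline execution."""

    ledger: pd.DataFrame
    features: pd.DataFrame
    scores: pd.DataFrame
    component_model: dimred.ComponentModel | None
    confounds: dict
    qc_summary: dict
    glm_results: pd.DataFrame
    log: list

    @property
    def accounting(self) -> pd.Series:
        counts = self.ledger["category"].value_counts()
        return counts.reindex(LEDGER_CATEGORIES, fill_value=0)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _fitting_ground_truth(rng, grip_type, window_s, frame_rate):
    """Draw generative trial parameters that fit the trial window."""
    for _ in range(100):
        gt = synth.sample_ground_truth(rng, grip_type)
        if gt.boundaries(frame_rate)[3] / frame_rate <= window_s - 0.3:
            return gt
    # extremely tight window: shrink the grip phase to fit
    gt.grip_duration_s = max(
        0.4,
        window_s - 0.35 - gt.reaction_latency_s - gt.reaching_duration_s
        - gt.back_duration_s,
    )
    return gt


def _simulate_trials(config: PipelineConfig, ledger: pd.DataFrame, seed: int) -> dict:
    """Simulate kinematics for every trial in the ledger."""
    fr = config.session.frame_rate_hz
    trials = {}
    rng = np.random.default_rng(seed)
    for (part, run), events in ledger.groupby(["participant", "run"]):
        onsets = events["onset"].to_numpy()
        windows = np.append(np.diff(onsets), 8.0)
        for (idx, row), window in zip(events.iterrows(), windows):
            window = float(min(window, 12.0))
            trial_seed = int(rng.integers(2**31))
            is_movement = row["trial_type"] in synth.MOVEMENT_CONDITIONS
            moves = is_movement or bool(row.get("inject_movement", False))
            gt = _fitting_ground_truth(rng, row["grip_type"], window, fr)
            trial = synth.simulate_trial(
                gt,
                frame_rate_hz=fr,
                noise_sd_mm=config.noise_sd_mm,
                dropout_prob=config.dropout_prob if is_movement else 0.0,
                window_s=window,
                seed=trial_seed,
                still=not moves,
                inject_tracking_loss=bool(row.get("inject_tracking_loss", False)),
                inject_extra_movement=row.get("annotation", "ok")
                == "unexpected_movement",
            )
            trial.condition = row["trial_type"]
            trial.participant = int(part)
            trial.run = int(run)
            trials[idx] = trial
    return trials


def _classify_and_measure(config: PipelineConfig, ledger, trials, seed):
    """Segment every trial, fill the accounting ledger, extract features."""
    from .features import extract_features

    fr = config.session.frame_rate_hz
    categories = {}
    segmentations = {}
    feature_rows = {}
    for idx, row in ledger.iterrows():
        trial = trials[idx]
        if row.get("annotation", "ok") != "ok":
            categories[idx] = row["annotation"]
            continue
        seg = segment.segment_trial(
            trial.positions("wrist"),
            fr,
            window=config.smoothing_window,
            min_run_s=config.min_run_s,
            max_gap_frames=config.max_gap_frames,
            seed=seed,
        )
        segmentations[idx] = seg
        is_movement = row["trial_type"] in synth.MOVEMENT_CONDITIONS
        if is_movement:
            if seg.parse_ok:
                categories[idx] = "accepted"
                clean = trial.interpolated(config.smoothing_window,
                                           config.max_gap_frames)
                feature_rows[idx] = extract_features(clean, seg,
                                                     config.smoothing_window)
            elif seg.failure_reason == "tracking_loss":
                categories[idx] = "tracking_loss"
            else:
                categories[idx] = "parse_failure"
        else:
            # a no-movement trial counts as moved only if the parsed
            # "movement" is physically plausible, not clustered jitter
            moved = False
            if seg.parse_ok:
                clean = segment.interpolate_dropouts(
                    trial.positions("wrist"), config.smoothing_window,
                    config.max_gap_frames,
                )
                vmax = segment.smooth(
                    segment.compute_speed(clean, fr), config.smoothing_window
                ).values.max()
                moved = vmax > 150.0
            categories[idx] = "moved_in_no_movement" if moved else "accepted"
    out = ledger.copy()
    out["category"] = pd.Series(categories)
    features = pd.DataFrame(feature_rows).T
    features.index.name = "trial_index"
    return out, segmentations, features


def _motion_and_qc(config, ledger, seed):
    """Simulate per-run motion and summarise motion QC."""
    spec = config.session
    seeds = iter(_spawn_seeds(seed, spec.participants * spec.runs_per_participant))
    confounds = {}
    per_subject_arm_r = {}
    per_subject_hand_r = {}
    fd_summary = []
    for (part, run), events in ledger.groupby(["participant", "run"]):
        motion = synth.simulate_motion_series(
            events, config.motion, spec.tr_s, seed=next(seeds)
        )
        deltas = motionqc.params_to_deltas(
            motion[list(motionqc.MOTION_PARAM_COLUMNS)]
        )
        head_fd = motionqc.framewise_displacement(
            deltas, motionqc.EFFECTOR_RADII_MM["head"], "head", spec.tr_s
        )
        motion["framewise_displacement"] = head_fd.values
        confounds[(part, run)] = motion
        mask = motion["is_movement"].to_numpy()
        if mask.sum() >= 3:
            per_subject_arm_r.setdefault(part, []).append(
                motionqc.fd_correlation(head_fd.values, motion["arm_fd"], mask)
            )
            per_subject_hand_r.setdefault(part, []).append(
                motionqc.fd_correlation(head_fd.values, motion["hand_fd"], mask)
            )
        labels = np.where(mask, "Movement", motion["block"].to_numpy())
        stats = motionqc.censoring_stats(head_fd, labels, config.fd_thresholds)
        stats.insert(0, "participant", part)
        stats.insert(1, "run", run)
        fd_summary.append(stats)
        fd_summary[-1]["rmsd_mm"] = motionqc.rmsd(
            motion[list(motionqc.MOTION_PARAM_COLUMNS)]
        )

    arm_rs = [float(np.mean(v)) for v in per_subject_arm_r.values()]
    hand_rs = [float(np.mean(v)) for v in per_subject_hand_r.values()]
    qc = {
        "mean_fd_mm": {},
        "censoring": pd.concat(fd_summary, ignore_index=True).to_dict("records"),
        "fd_coupling": {},
    }
    all_fd = np.concatenate(
        [c["framewise_displacement"].to_numpy() for c in confounds.values()]
    )
    all_move = np.concatenate([c["is_movement"].to_numpy() for c in confounds.values()])
    all_block = np.concatenate([c["block"].to_numpy() for c in confounds.values()])
    qc["mean_fd_mm"]["movement_blocks"] = float(all_fd[all_move].mean())
    nm = all_block == "NoMovement"
    if nm.any():
        qc["mean_fd_mm"]["no_movement_blocks"] = float(all_fd[nm].mean())
    for name, rs in (("arm", arm_rs), ("hand", hand_rs)):
        entry = {"per_subject_r": rs}
        if len(rs) >= 2:
            entry.update(motionqc.fd_correlation_group(rs))
        qc["fd_coupling"][name] = entry
    return confounds, qc


def _fit_glms(config, ledger, scores, confounds, seed):
    """Simulate ROI BOLD per run and fit the modulation GLMs."""
    spec = config.session
    rows = []
    seeds = iter(_spawn_seeds(seed, len(config.rois) * spec.participants
                              * spec.runs_per_participant + 1))
    for (part, run), events in ledger.groupby(["participant", "run"]):
        motion = confounds[(part, run)]
        n_tr = len(motion)
        head_fd = motion["framewise_displacement"].to_numpy()
        run_events = events.copy()
        run_events["error"] = run_events["category"] != "accepted"
        run_events["error_moved"] = run_events["category"].isin(
            ("moved_in_no_movement",)
        ) | (
            run_events["error"]
            & run_events["trial_type"].isin(synth.MOVEMENT_CONDITIONS)
        )
        run_scores = (
            scores.loc[scores.index.intersection(run_events.index)]
            if scores is not None and len(scores)
            else None
        )
        design = glm.build_design_matrix(
            run_events,
            run_scores,
            spec.tr_s,
            n_tr,
            fd_head=head_fd,
            fd_arm=motion["arm_fd"].to_numpy(),
            fd_hand=motion["hand_fd"].to_numpy(),
            hrf_params=config.hrf,
            event_duration_s=config.event_duration_s,
        )
        mod_cols = [c for c in design.columns if "_x_" in c]
        roi_bold = {}
        for roi, params in config.rois.items():
            y = synth.simulate_bold(
                run_events, run_scores, params, n_tr, spec.tr_s,
                fd=head_fd, seed=next(seeds),
            )
            roi_bold[roi] = y
            fit = glm.fit(design, y, ar_model=config.ar_model)
            res = {
                "participant": part, "run": run, "roi": roi,
                "ar_rho": fit.ar_rho,
                "motion_variance_share_pct": glm.motion_variance_share(fit),
            }
            for cond in spec.conditions:
                if cond in fit.betas:
                    res[f"beta_{cond}"] = fit.betas[cond]
            if mod_cols:
                ftest = glm.modulation_F(fit, mod_cols)
                res.update(
                    {"modulation_F": ftest["F"], "modulation_p": ftest["p"]}
                )
            rows.append(res)
        panel = pd.DataFrame(roi_bold)
        motion["std_dvars"] = motionqc.std_dvars(panel)
    results = pd.DataFrame(rows)
    if "modulation_p" in results.columns:
        adj = []
        for _, sub in results.groupby(["participant", "run"]):
            adj.append(glm.bh_correct(sub["modulation_p"], config.alpha)
                       .set_index(sub.index))
        adj = pd.concat(adj).sort_index()
        results["modulation_p_fdr"] = adj["p_fdr"]
        results["modulation_significant"] = adj["significant"]
    return results


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage on synthetic data; deterministic given the seed."""
    config.validate()
    log = []
    t_start = time.perf_counter()

    def tick(stage):
        log.append(f"{stage}: t={time.perf_counter() - t_start:.1f}s")

    seeds = _spawn_seeds(config.seed, 8)
    log.append(f"seed: {config.seed}")

    ledger = synth.build_session(config.session, seed=seeds[0])
    ledger = synth.inject_annotations(ledger, config.error_rates, seed=seeds[1])
    tick("session")

    trials = _simulate_trials(config, ledger, seeds[2])
    tick("kinematics")

    ledger, segmentations, features = _classify_and_measure(
        config, ledger, trials, seeds[3]
    )
    tick("segmentation+features")

    scores = pd.DataFrame()
    model = None
    if len(features) >= 4:
        participants = ledger.loc[features.index, "participant"].to_numpy()
        imputed = dimred.impute_missing(features, participants)
        z, mean, sd = dimred.standardize(imputed)
        k = dimred.parallel_analysis(
            z, n_perm=config.pca_n_perm, percentile=config.pca_percentile,
            seed=seeds[4],
        )
        k = max(k, 1)
        model = dimred.fit_pca_varimax(z, k, mean, sd)
        scores = dimred.score_trials(z, model)
    tick("pca")

    confounds, qc = _motion_and_qc(config, ledger, seeds[5])
    tick("motion-qc")

    glm_results = _fit_glms(config, ledger, scores, confounds, seeds[6])
    tick("glm")

    qc["trial_accounting"] = {
        cat: int(n)
        for cat, n in ledger["category"].value_counts().items()
    }
    if model is not None:
        qc["pca"] = {
            "n_components": model.n_components,
            "total_variance_pct": model.total_variance_pct,
        }

    if config.out_dir:
        _write_outputs(config, ledger, features, scores, model, confounds,
                       qc, glm_results, log)
    tick("done")
    return PipelineResult(
        ledger=ledger,
        features=features,
        scores=scores,
        component_model=model,
        confounds=confounds,
        qc_summary=qc,
        glm_results=glm_results,
        log=log,
    )


def _write_outputs(config, ledger, features, scores, model, confounds, qc,
                   glm_results, log):
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_events(ledger, out / "events.tsv")
    feat = features.copy()
    if len(feat):
        ids = ledger.loc[feat.index, ["participant", "run", "block", "trial",
                                      "trial_type", "grip_type"]]
        feat = pd.concat([ids, feat], axis=1)
    io.write_tsv(feat.reset_index(), out / "features.tsv")
    if len(scores):
        io.write_tsv(scores.reset_index(names="trial_index"), out / "scores.tsv")
    if model is not None:
        io.write_tsv(model.loadings.reset_index(names="measure"),
                     out / "loadings.tsv")
    for (part, run), table in confounds.items():
        io.write_tsv(table, out / f"confounds_sub-{part:02d}_run-{run:02d}.tsv")
    io.write_tsv(glm_results, out / "glm_results.tsv")
    (out / "qc_summary.json").write_text(json.dumps(qc, indent=1, default=str))
    (out / "pipeline_log.txt").write_text("\n".join(log) + "\n")
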