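"""End-to-end orchestration: simulate -> align -> detect -> epoch -> stats.

A run executes the full analysis order on a cohort of synthetic
sessions: device-clock alignment from the force regression,
landmark detection and goal/non-goal classification, the kinematic
similarity gate, ERP epoching with artifact rejection and the >50-trial
inclusion rule, second-level cluster-corrected statistics on the ERP and
beta-band ERSP maps, and the tactile-coincidence comparison.  Every
stage writes its intermediates (TSV/JSON/arrays) into the run directory
together with a provenance record, so each reported number can be
recomputed from stored files.
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

from . import __version__
from . import clocksync, eegprep, eventnet, kinematics, robuststat, synthio, timefreq
from . import io as tio
from .containers import EventSet
from .montage import Montage

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs for one pipeline run, serializable to/from YAML."""

    out_dir: str = "tapflow_run"
    seed: int = 0
    n_subjects: int = 12
    # stage toggles
    do_align: bool = True
    do_detect: bool = True          # False -> use ground-truth events (bypass)
    do_erp_stats: bool = True
    do_tfr_stats: bool = True
    do_tactile: bool = True
    # session scale (desk-scale defaults; see docs/methods.md)
    session: dict = field(default_factory=lambda: dict(
        duration_s=400.0, n_goal=90, n_nongoal=60,
        eeg=dict(n_channels=32, eeg_srate=250.0),
    ))
    # detector scale
    detector: dict = field(default_factory=lambda: dict(max_epochs=4, patience=4))
    align_model: str = "linear"
    # analysis parameters (study defaults)
    erp_band: tuple = (0.5, 30.0)
    spectral_band: tuple = (0.5, 45.0)
    window_ms: tuple = (-2000.0, 2000.0)
    baseline_ms: tuple = (-2000.0, -1500.0)
    artifact_limit_uv: float = 80.0
    min_trials: int = 50
    similarity_threshold: float = 0.8
    alpha: float = 0.05
    n_boot: int = 1000
    beta_band: tuple = (12.0, 30.0)
    tfr_freqs: tuple = (12.0, 33.0, 3.0)   # start, stop, step
    tfr_decim: int = 4
    stat_time_points: int = 200

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("erp_band", "spectral_band", "window_ms", "baseline_ms",
                    "beta_band", "tfr_freqs"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _session_config(cfg: RunConfig, subject: int) -> synthio.SessionConfig:
    sess = dict(cfg.session)
    eeg_kw = dict(sess.pop("eeg", {}))
    rng = np.random.default_rng(cfg.seed * 1009 + subject)
    # subject-level amplitude variability around the template defaults
    eeg_kw.setdefault("amp_scale", float(np.clip(1.0 + 0.15 * rng.standard_normal(),
                                                 0.5, 1.5)))
    return synthio.SessionConfig(
        seed=int(cfg.seed * 100003 + 17 * subject + 1) % (2**31 - 1),
        eeg=synthio.EEGParams(**eeg_kw),
        **sess,
    )


@dataclass
class SubjectOutcome:
    subject: int
    included: bool = True
    exclusion_reason: str = ""
    delay_ms: float = np.nan
    delay_error_ms: float = np.nan
    peak_corr: float = np.nan
    f2: float = np.nan
    similarity_r: float = np.nan
    n_goal_trials: int = 0
    n_nongoal_trials: int = 0


def _process_subject(cfg: RunConfig, subject: int, subj_dir: Path):
    """Simulate and analyze one subject; returns (outcome, epoch dict)."""
    out = SubjectOutcome(subject)
    scfg = _session_config(cfg, subject)
    session = synthio.simulate_session(scfg)
    tio.write_times(subj_dir / "touch_device.tsv",
                    session.touch_log_device_ms, "touch")
    tio.write_times(subj_dir / "tactile.tsv", session.tactile_times_ms, "tactile")
    tio.write_trace(subj_dir / "movement.bin", session.movement, scfg.srate,
                    "movement")
    tio.write_trace(subj_dir / "force.bin", session.force, scfg.srate, "force")

    # --- clock alignment ---------------------------------------------------
    if cfg.do_align:
        events, report, _ = clocksync.align_session(
            session.movement, session.force, session.touch_log_device_ms,
            seed=scfg.seed, model=cfg.align_model)
        out.delay_ms = report.delay_ms
        out.delay_error_ms = report.delay_ms - scfg.clock_offset_ms
        out.peak_corr = report.peak_corr
        (subj_dir / "alignment.json").write_text(
            json.dumps(dataclasses.asdict(report), default=float, indent=1))
        if not report.passed:
            out.included = False
            out.exclusion_reason = "misaligned (QC below threshold)"
            return out, None
        touch_lab = events.get("touch")
    else:
        touch_lab = session.truth.true_touch_times_lab
        events = EventSet({"touch": touch_lab}, {"touch": "ground truth (bypass)"})

    # --- landmark detection ------------------------------------------------
    movement_bp = kinematics.bandpass_movement(session.movement,
                                               srate=scfg.srate)
    if cfg.do_detect:
        det_cfg = eventnet.DetectorConfig(seed=scfg.seed, **cfg.detector)
        match, _ = eventnet.detect_session(movement_bp, touch_lab, det_cfg,
                                           srate=scfg.srate)
        out.f2 = match.f2
        goal_ms, nongoal_ms = match.goal_ms, match.non_goal_ms
    else:
        match = eventnet.classify_landmarks(
            np.concatenate([session.truth.true_touch_times_lab,
                            session.truth.true_nongoal_times_lab]),
            touch_lab)
        goal_ms, nongoal_ms = match.goal_ms, match.non_goal_ms
    events = events.with_label("goal", goal_ms, "detector")
    events = events.with_label("non_goal", nongoal_ms, "detector")
    events = events.with_label("ignored", match.ignored_ms, "detector")
    events = events.with_label("tactile", session.tactile_times_ms, "trigger")
    tio.write_events(subj_dir / "events.tsv", events)
    if len(goal_ms) < 2 or len(nongoal_ms) < 2:
        out.included = False
        out.exclusion_reason = "too few detected landmarks"
        return out, None

    # --- kinematic similarity gate ------------------------------------------
    g_ep = kinematics.epoch_movement(movement_bp, goal_ms, srate=scfg.srate,
                                     label="goal")
    n_ep = kinematics.epoch_movement(movement_bp, nongoal_ms, srate=scfg.srate,
                                     label="non_goal")
    r, include = kinematics.similarity(g_ep, n_ep, cfg.similarity_threshold)
    out.similarity_r = r
    if not include:
        out.included = False
        out.exclusion_reason = f"kinematic similarity R={r:.2f} <= " \
            f"{cfg.similarity_threshold}"
        return out, None

    # --- EEG epoching -------------------------------------------------------
    erp_rec = eegprep.bandpass_eeg(session.eeg, cfg.erp_band)
    epochs = {}
    for name, ev in (("goal", goal_ms), ("non_goal", nongoal_ms)):
        ep = eegprep.epoch(erp_rec, ev, cfg.window_ms, cfg.baseline_ms, name)
        ep = eegprep.reject_artifacts(ep, cfg.artifact_limit_uv)
        epochs[name] = ep
        tio.write_epochs(subj_dir / f"epochs_{name}", ep)
    out.n_goal_trials = epochs["goal"].n_trials
    out.n_nongoal_trials = epochs["non_goal"].n_trials
    if not eegprep.enforce_min_trials(*epochs.values(), minimum=cfg.min_trials):
        out.included = False
        out.exclusion_reason = (
            f"<= {cfg.min_trials} trials after rejection "
            f"({out.n_goal_trials} goal / {out.n_nongoal_trials} non-goal)")
        return out, None

    # --- spectral epochs ----------------------------------------------------
    if cfg.do_tfr_stats:
        spec_rec = eegprep.bandpass_eeg(session.eeg, cfg.spectral_band)
        for name, ev in (("goal", goal_ms), ("non_goal", nongoal_ms)):
            ep = eegprep.epoch(spec_rec, ev, cfg.window_ms, cfg.baseline_ms,
                               f"spec_{name}")
            ep = eegprep.reject_artifacts(ep, cfg.artifact_limit_uv)
            epochs[f"spec_{name}"] = ep

    # --- tactile epochs -----------------------------------------------------
    if cfg.do_tactile:
        tg, tn = eegprep.tactile_epochs(session.eeg, session.tactile_times_ms,
                                        goal_ms, nongoal_ms)
        epochs["tactile_goal"], epochs["tactile_non_goal"] = tg, tn
    return out, epochs


def _subject_maps(cfg: RunConfig, epochs: dict):
    """Per-subject average maps on the common statistics grid."""
    maps = {}
    step = max(1, epochs["goal"].data.shape[2] // cfg.stat_time_points)
    for name in ("goal", "non_goal"):
        maps[name] = epochs[name].average()[:, ::step]
    if "spec_goal" in epochs and epochs.get("spec_goal") is not None:
        freqs = np.arange(*cfg.tfr_freqs)
        for name in ("goal", "non_goal"):
            spec = timefreq.morlet_cwt(epochs[f"spec_{name}"], freqs,
                                       decim=cfg.tfr_decim)
            spec = timefreq.ersp(spec, cfg.baseline_ms)
            band, _ = timefreq.band_average(spec, cfg.beta_band)
            maps[f"beta_{name}"] = band.mean(axis=0)
    for name in ("tactile_goal", "tactile_non_goal"):
        ep = epochs.get(name)
        if ep is not None:
            maps[name] = ep.average()
    return maps


def run_all(cfg: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    t0 = time.time()
    run_dir = Path(cfg.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(run_dir / "config.yaml")
    provenance = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "tapflow": __version__,
        "numpy": np.__version__,
    }
    (run_dir / "provenance.json").write_text(json.dumps(provenance, indent=1))

    outcomes: list[SubjectOutcome] = []
    subject_maps: dict[str, list[np.ndarray]] = {}
    goal_lists, nongoal_lists = [], []
    try:
        for s in range(cfg.n_subjects):
            subj_dir = run_dir / f"sub-{s:02d}"
            subj_dir.mkdir(exist_ok=True)
            outcome, epochs = _process_subject(cfg, s, subj_dir)
            outcomes.append(outcome)
            if epochs is None:
                logger.info("subject %d excluded: %s", s,
                            outcome.exclusion_reason)
                continue
            ev = tio.read_events(subj_dir / "events.tsv")
            goal_lists.append(ev.get("goal"))
            nongoal_lists.append(ev.get("non_goal"))
            for name, m in _subject_maps(cfg, epochs).items():
                subject_maps.setdefault(name, []).append(m)
    except Exception as err:  # preserve partial outputs with a machine record
        (run_dir / "error.json").write_text(json.dumps(
            {"stage": "subjects", "error": str(err),
             "type": type(err).__name__}))
        raise

    pd.DataFrame([dataclasses.asdict(o) for o in outcomes]).to_csv(
        run_dir / "subjects.tsv", sep="\t", index=False)

    # behavioral ordering statistic
    results: dict[str, object] = {}
    if len(goal_lists) >= 2:
        t, p, _ = kinematics.ordering_bias(goal_lists, nongoal_lists)
        results["ordering_bias"] = {"t": t, "p": p, "n_subjects": len(goal_lists)}

    # population-level statistics
    montage = Montage(int(cfg.session.get("eeg", {}).get("n_channels", 64)))
    adj = robuststat.build_adjacency(montage.positions, names=montage.names)
    contrasts = []
    if cfg.do_erp_stats:
        contrasts += [("erp_goal", "goal", None), ("erp_non_goal", "non_goal", None),
                      ("erp_paired", "goal", "non_goal")]
    if cfg.do_tfr_stats:
        contrasts += [("beta_goal", "beta_goal", None),
                      ("beta_paired", "beta_goal", "beta_non_goal")]
    if cfg.do_tactile:
        contrasts += [("tactile_goal", "tactile_goal", None),
                      ("tactile_non_goal", "tactile_non_goal", None)]
    for label, a, b in contrasts:
        if a not in subject_maps or len(subject_maps[a]) < 10:
            logger.info("contrast %s skipped: fewer than 10 included subjects",
                        label)
            continue
        try:
            if b is None:
                res = robuststat.cluster_correct(
                    np.stack(subject_maps[a]), adj, "one_sample",
                    cfg.alpha, cfg.n_boot, cfg.seed)
            else:
                res = robuststat.cluster_correct(
                    (np.stack(subject_maps[a]), np.stack(subject_maps[b])),
                    adj, "paired", cfg.alpha, cfg.n_boot, cfg.seed)
        except ValueError as err:
            logger.warning("contrast %s failed: %s", label, err)
            continue
        _write_stat_result(run_dir, label, res, montage)
        results[label] = {
            "n_clusters": len(res.clusters),
            "n_significant": int(sum(c.p_value < cfg.alpha
                                     for c in res.clusters)),
        }
    (run_dir / "results.json").write_text(
        json.dumps(results, indent=1, default=float))
    (run_dir / "report.md").write_text(summarize(run_dir))
    provenance["elapsed_s"] = round(time.time() - t0, 1)
    (run_dir / "provenance.json").write_text(json.dumps(provenance, indent=1))
    return run_dir


def _write_stat_result(run_dir: Path, label: str, res: robuststat.StatResult,
                       montage: Montage) -> None:
    np.savez(run_dir / f"stats_{label}.npz", stat_map=res.stat_map,
             p_map=res.p_map, labels=res.cluster_labels, mask=res.mask)
    rows = []
    for k, c in enumerate(res.clusters, start=1):
        ch = sorted(set(c.cells[0]))
        rows.append({
            "cluster": k, "sign": c.sign,
            "channels": ",".join(montage.names[i] for i in ch),
            "extent_cells": len(c.cells[0]),
            "mass": c.mass, "p": c.p_value,
        })
    pd.DataFrame(rows, columns=["cluster", "sign", "channels", "extent_cells",
                                "mass", "p"]).to_csv(
        run_dir / f"clusters_{label}.tsv", sep="\t", index=False)


def summarize(run_dir) -> str:
    """Human-readable report assembled from stored run intermediates."""
    run_dir = Path(run_dir)
    subj_file = run_dir / "subjects.tsv"
    if not subj_file.exists():
        raise ValueError(f"{run_dir} contains no completed run (subjects.tsv)")
    df = pd.read_csv(subj_file, sep="\t")
    lines = ["# tapflow run report", ""]
    prov = run_dir / "provenance.json"
    if prov.exists():
        meta = json.loads(prov.read_text())
        lines.append(f"seed {meta.get('seed')} | config {meta.get('config_hash')} "
                     f"| tapflow {meta.get('tapflow')}")
        lines.append("")
    lines.append("## Subjects")
    lines.append("")
    lines.append(df.to_string(index=False,
                              float_format=lambda v: f"{v:.3f}"))
    lines.append("")
    n_inc = int(df["included"].sum())
    lines.append(f"{n_inc} of {len(df)} subjects included.")
    results_file = run_dir / "results.json"
    if results_file.exists():
        results = json.loads(results_file.read_text())
        lines.append("")
        lines.append("## Statistics")
        lines.append("")
        for label, val in results.items():
            lines.append(f"- {label}: {json.dumps(val)}")
        for tsv in sorted(run_dir.glob("clusters_*.tsv")):
            tbl = pd.read_csv(tsv, sep="\t")
            if len(tbl):
                lines.append("")
                lines.append(f"### {tsv.stem}")
                lines.append(tbl.to_string(index=False))
    return "\n".join(lines) + "\n"
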