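"""End-to-end orchestration: simulate a cohort, write session files, re-read
and analyze them, and emit tidy report tables, a QC table, and a manifest.

One structured config governs all modules; every random draw derives from the
single root seed, so a rerun with the same config is byte-identical for all
text outputs (the manifest additionally records wall-clock timestamps).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import events as ev
from . import photometry as ph
from . import simulate as sim
from . import tracking as trk
from .config import (DEFAULT_DAYS, AgentConfig, PhotometryGenConfig, TaskConfig,
                     replace_fields)
from .errors import ConfigurationError

logger = logging.getLogger("photoperant")

#: Default peri-event alignment per phase.
PHASE_ALIGNS = {"I": ("tone_on", "lick_bout_onset"),
                "II": ("lever_press", "lick_bout_onset"),
                "III": ("tone_on", "lever_press")}


@dataclass
class RunConfig:
    """Cohort layout and per-module parameter blocks."""

    seed: int = 0
    n_mice: int = 2
    phases: tuple[str, ...] = ("I", "II", "III")
    days: dict = field(default_factory=dict)      # per-phase override
    tests_per_day: int = 2
    task: dict = field(default_factory=dict)      # TaskConfig overrides
    agent: dict = field(default_factory=dict)     # AgentConfig overrides
    photometry: dict = field(default_factory=dict)
    include_pose: bool = False
    peri_event_pre_s: float = 2.0
    peri_event_post_s: float = 8.0
    peri_event_decimate: int = 10   # thin the long-format peri-event table
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        valid = {f.name for f in dataclasses.fields(cls)}
        for key in d:
            if key not in valid:
                raise ConfigurationError(f"unknown run-config key: {key!r}")
        cfg = cls(**d)
        for phase in cfg.phases:
            if phase not in ("I", "II", "III"):
                raise ConfigurationError(f"unknown phase {phase!r}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def phase_days(self, phase: str) -> int:
        return int(self.days.get(phase, DEFAULT_DAYS[phase]))


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_root: str) -> dict:
    """Simulate, analyze, and report an entire cohort. Returns the manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    os.makedirs(out_root, exist_ok=True)
    report_dir = os.path.join(out_root, "reports")
    os.makedirs(report_dir, exist_ok=True)

    per_trial_rows, per_test_rows, peak_rows, qc_rows = [], [], [], []
    peri_rows: dict[tuple, list] = {}

    mice = [f"m{i + 1:02d}" for i in range(config.n_mice)]
    for mi, mouse in enumerate(mice):
        for phase in config.phases:
            task = replace_fields(TaskConfig(phase=phase), **config.task)
            task = replace_fields(task, days=config.phase_days(phase),
                                  tests_per_day=config.tests_per_day)
            agent = replace_fields(AgentConfig(), **config.agent)
            pcfg = replace_fields(PhotometryGenConfig(), **config.photometry)
            for day in range(1, task.days + 1):
                for test in range(1, task.tests_per_day + 1):
                    _run_session(config, out_root, mouse, mi, phase, day, test,
                                 task, agent, pcfg, per_trial_rows,
                                 per_test_rows, peak_rows, qc_rows, peri_rows)

    tables = _write_reports(config, report_dir, per_trial_rows, per_test_rows,
                            peak_rows, qc_rows, peri_rows)
    manifest = {
        "software": {"package": "photoperant", "version": __version__},
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "created_unix": time.time(),
        "files": {},
    }
    for base, _, names in os.walk(out_root):
        for name in sorted(names):
            p = os.path.join(base, name)
            rel = os.path.relpath(p, out_root)
            if rel == "manifest.json":
                continue
            manifest["files"][rel] = {"sha256": _sha256(p),
                                      "bytes": os.path.getsize(p)}
    with open(os.path.join(out_root, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    logger.info("pipeline complete: %d files under %s", len(manifest["files"]), out_root)
    manifest["tables"] = tables
    return manifest


def _run_session(config, out_root, mouse, mi, phase, day, test, task, agent,
                 pcfg, per_trial_rows, per_test_rows, peak_rows, qc_rows,
                 peri_rows) -> None:
    key = {"mouse": mouse, "phase": phase, "day": day, "test": test}
    rng_b = np.random.default_rng([config.seed, mi, sim._PHASE_CODE[phase], day, test, 0])
    rng_p = np.random.default_rng([config.seed, mi, sim._PHASE_CODE[phase], day, test, 1])
    rng_v = np.random.default_rng([config.seed, mi, sim._PHASE_CODE[phase], day, test, 2])

    log, truth = sim.run_task_state_machine(task, agent, day, test, mouse=mouse, rng=rng_b)
    rec, truth = sim.generate_photometry(log, truth, pcfg, rng=rng_p)
    pose = (sim.generate_pose_track(log, task, agent, rng=rng_v)
            if config.include_pose else None)

    sess_dir = os.path.join(out_root, mouse, f"phase_{phase}", f"day{day:02d}_test{test}")
    paths = sim.write_session(log, rec, pose, truth, sess_dir)

    # analyze from the files, exercising the full read path
    log = ev.read_event_log(paths["events"])
    rec = ph.read_photometry(paths["photometry"])
    trials = ev.segment_trials(log)
    per_trial = ev.compute_metrics(trials, phase)
    for r in per_trial.to_dict("records"):
        per_trial_rows.append({**key, **r})
    if len(per_trial):
        per_test_rows.append({**key, **summ(per_trial, phase)})

    trace = ph.process_recording(rec)
    peaks = ph.detect_peaks(trace)
    linked = ph.link_peaks_to_behavior(peaks, ph.behavior_anchors(log))
    for r in linked.to_dict("records"):
        peak_rows.append({**key, **r})

    for align in PHASE_ALIGNS[phase]:
        pem = ph.build_peri_event_matrix(trace, trials, align,
                                         config.peri_event_pre_s,
                                         config.peri_event_post_s)
        step = max(1, int(config.peri_event_decimate))
        for r in range(pem.n_trials):
            for c in range(0, pem.n_bins, step):
                peri_rows.setdefault((phase, align), []).append(
                    {**key, "trial_idx": pem.trial_idx[r],
                     "outcome": pem.outcomes[r],
                     "time_s": round(float(pem.time_s[c]), 4),
                     "dff": pem.matrix[r, c]})

    qc_rows.append({**key, "session_sd": trace.session_sd,
                    "n_peaks": len(peaks), "n_trials": len(trials),
                    "n_events": log.n_events,
                    "pct_masked_pose": (100.0 * trk.masked_fraction(
                        trk.read_pose(paths["pose"]), "head")
                        if pose is not None else np.nan)})


def summ(per_trial: pd.DataFrame, phase: str) -> dict:
    return ev.summarize_test(per_trial, phase).to_dict()


def _write_reports(config, report_dir, per_trial_rows, per_test_rows,
                   peak_rows, qc_rows, peri_rows) -> dict:
    tables = {}
    ff = "%.6g"
    tables["behavior_per_trial"] = pd.DataFrame(per_trial_rows)
    tables["behavior_per_test"] = pd.DataFrame(per_test_rows)
    if per_test_rows:
        per_test = pd.DataFrame(per_test_rows)
        tables["behavior_summary"] = pd.concat(
            [ev.aggregate_by_day(sub).assign(phase=phase)
             for phase, sub in per_test.groupby("phase")],
            ignore_index=True)
    tables["peaks"] = pd.DataFrame(peak_rows)
    if peak_rows:
        linked = tables["peaks"].dropna(subset=["linked_event"])
        if len(linked):
            tables["amplitude_by_day"] = (
                linked.groupby(["phase", "day", "linked_event"])["amplitude"]
                .agg(["mean", "sem", "count"]).reset_index())
    tables["qc"] = pd.DataFrame(qc_rows)
    for (phase, align), rows in peri_rows.items():
        tables[f"peri_event_{phase}_{align}"] = pd.DataFrame(rows)
    for name, df in tables.items():
        df.to_csv(os.path.join(report_dir, f"{name}.csv"), index=False,
                  float_format=ff)
    return tables


# ---------------------------------------------------------------------------
# figures
# ---------------------------------------------------------------------------

def make_figures(report_dir: str, fig_dir: str | None = None) -> list[str]:
    """Render the standard panels from the report tables: behavior-by-day
    curves (per-mouse gray, cohort mean on top), group-mean peri-event traces
    with SEM ribbons, and trial x time heatmaps. Empty tables are skipped
    with a warning."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig_dir = fig_dir or os.path.join(report_dir, "figures")
    os.makedirs(fig_dir, exist_ok=True)
    written = []

    def _read(name):
        p = os.path.join(report_dir, f"{name}.csv")
        if not os.path.exists(p):
            return None
        df = pd.read_csv(p)
        return df if len(df) else None

    per_test = _read("behavior_per_test")
    if per_test is None:
        logger.warning("behavior_per_test table empty; skipping behavior figure")
    else:
        metrics = [("latency_first_lick_s", "latency to first lick (s)"),
                   ("pct_successful_trials", "% successful trials")]
        for phase, sub in per_test.groupby("phase"):
            fig, axes = plt.subplots(1, len(metrics), figsize=(9, 3.2))
            sub = sub.assign(x=(sub["day"] - 1) * sub["test"].max() + sub["test"])
            for ax, (mcol, label) in zip(np.atleast_1d(axes), metrics):
                for _, m in sub.groupby("mouse"):
                    ax.plot(m["x"], m[mcol], color="0.7", lw=0.8)
                mean = sub.groupby("x")[mcol].mean()
                ax.plot(mean.index, mean.values, color="tab:orange", lw=2)
                ax.set_xlabel("test (day x 2)")
                ax.set_ylabel(label)
            fig.suptitle(f"Phase {phase} behavior (photoperant {__version__})",
                         fontsize=9)
            fig.tight_layout()
            p = os.path.join(fig_dir, f"behavior_phase_{phase}.png")
            fig.savefig(p, dpi=110)
            plt.close(fig)
            written.append(p)

    for name in sorted(os.listdir(report_dir)):
        if not (name.startswith("peri_event_") and name.endswith(".csv")):
            continue
        df = _read(name[:-4])
        if df is None:
            continue
        label = name[len("peri_event_"):-4]
        g = df.groupby(["outcome", "time_s"])["dff"]
        mean, sem = g.mean().unstack(0), g.sem(ddof=1).unstack(0)
        fig, ax = plt.subplots(figsize=(5, 3.2))
        for outcome in mean.columns:
            ax.plot(mean.index, mean[outcome], label=outcome)
            ax.fill_between(mean.index, mean[outcome] - sem[outcome],
                            mean[outcome] + sem[outcome], alpha=0.25)
        ax.axvline(0.0, color="k", ls=":", lw=0.8)
        ax.set_xlabel("time from event onset (s)")
        ax.set_ylabel("ΔF/F")
        ax.legend(fontsize=7)
        ax.set_title(label, fontsize=9)
        fig.tight_layout()
        p = os.path.join(fig_dir, f"{name[:-4]}_mean.png")
        fig.savefig(p, dpi=110)
        plt.close(fig)
        written.append(p)

        # trial x time heatmap for one example session (first mouse, last day)
        one = df[(df["mouse"] == df["mouse"].iloc[0])
                 & (df["day"] == df["day"].max()) & (df["test"] == 1)]
        if len(one):
            pv = one.pivot_table(index="trial_idx", columns="time_s", values="dff")
            fig, ax = plt.subplots(figsize=(5, 3.2))
            im = ax.imshow(pv.to_numpy(), aspect="auto", origin="lower",
                           extent=[pv.columns.min(), pv.columns.max(),
                                   -0.5, len(pv) - 0.5], cmap="viridis")
            fig.colorbar(im, ax=ax, label="ΔF/F")
            ax.set_xlabel("time from event onset (s)")
            ax.set_ylabel("trial")
            ax.set_title(f"{label} (example session)", fontsize=9)
            fig.tight_layout()
            p = os.path.join(fig_dir, f"{name[:-4]}_heatmap.png")
            fig.savefig(p, dpi=110)
            plt.close(fig)
            written.append(p)
    return written
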