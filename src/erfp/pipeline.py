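"""Config-driven end-to-end runner: simulate or ingest, preprocess, compute
variability time courses, run cluster permutation tests and behavioral
statistics, and write tables, figures and a provenance manifest.

The configuration is a nested dict (or a YAML/JSON file path) with one block
per stage; :data:`DEFAULT_CONFIG` documents every key.  Outputs land in
``out_dir``: ``exclusions.csv``, ``timecourses.csv``, ``clusters.csv``,
``behavior.json``, one figure per contrast and ``manifest.json`` carrying
the seed and a hash of the resolved configuration.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as bh
from . import io as fio
from . import preprocess as pp
from . import synth
from . import variability as vb
from .cluster import PairedDesign, PermutationConfig, permutation_test
from .exceptions import ErfpError, PipelineError, PlottingError

log = logging.getLogger("erfp")

DEFAULT_CONFIG: dict = {
    "mode": "simulate",  # simulate | ingest
    "experiment": 1,
    "seed": 0,
    "out_dir": "erfp_output",
    "simulate": {"behavior": {}, "sway": {}},  # constructor overrides
    "ingest": {"recordings": {}, "events": {}, "trials": None},
    "filter": {"cutoff_hz": 10.0, "order": 4, "mode": "dual_pass_4"},
    "epoch": {
        "align_code": "CUE_ONSET",
        "window_ms": [-550.0, 3050.0],
        "analysis_window_ms": [-500.0, 3000.0],
    },
    "exclusion": {"rt_sd_multiplier": 3.0},
    "variability": {
        "window_ms": 100.0,
        "step_ms": 1.0,
        "window_alignment": "centered",
        "axes": "combined",
    },
    "cluster": {"n_perm": 2000, "alpha": 0.05, "cluster_alpha": 0.05},
    "plot": True,
}

#: contrasts run per experiment: name -> (grouping condition A, condition B)
EXP1_CONTRASTS = {"soa_100_vs_1000": ((100,), (1000,))}
EXP2_CONTRASTS = {
    "soa_within_report": ((100, "report"), (1000, "report")),
    "soa_within_ignore": ((100, "ignore"), (1000, "ignore")),
    "load_within_short_soa": ((100, "report"), (100, "ignore")),
    "load_within_long_soa": ((1000, "report"), (1000, "ignore")),
}


@dataclass
class RunReport:
    """What a pipeline run produced and where."""

    out_dir: Path
    manifest: dict
    clusters: dict = field(default_factory=dict)
    behavior: dict = field(default_factory=dict)
    exclusion_percentages: dict = field(default_factory=dict)


def load_config(source) -> dict:
    """Resolve a config dict or YAML/JSON path against the defaults."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            source = yaml.safe_load(fh)
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for key, value in (source or {}).items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except ErfpError as exc:
                if isinstance(exc, PipelineError):
                    raise
                raise PipelineError(name, str(exc)) from exc

        return wrapper

    return deco


@_stage("input")
def _acquire(cfg):
    if cfg["mode"] == "simulate":
        behavior = (
            synth.BehaviorParams.experiment1(**cfg["simulate"]["behavior"])
            if cfg["experiment"] == 1
            else synth.BehaviorParams.experiment2(**cfg["simulate"]["behavior"])
        )
        sway = synth.SwayParams(**cfg["simulate"]["sway"])
        recordings, trials = synth.make_study(
            cfg["experiment"], behavior, sway, seed=cfg["seed"]
        )
        return recordings, trials
    ing = cfg["ingest"]
    if not ing.get("trials"):
        raise PipelineError("input", "ingest mode requires ingest.trials")
    trials = fio.read_trials(ing["trials"])
    recordings = {}
    for participant, rec_path in ing["recordings"].items():
        ev_path = ing["events"].get(participant)
        if ev_path is None:
            raise PipelineError("input", f"missing events file for participant {participant}")
        events = fio.read_events(ev_path)
        sub = trials[trials["participant"] == participant]
        fio.check_events_against_trials(events, sub)
        recordings[participant] = fio.read_recording(
            rec_path, events=events, participant=participant
        )
    return recordings, trials


@_stage("variability")
def _participant_timecourses(cfg, recordings, trials, included):
    """Filter, segment and reduce every recording to per-trial variability."""
    fcfg, ecfg, vcfg = cfg["filter"], cfg["epoch"], cfg["variability"]
    trial_series = []
    for participant, rec in recordings.items():
        mx = pp.butterworth_lowpass(
            rec.channel("Mx"), rec.sample_rate, fcfg["cutoff_hz"], fcfg["order"], fcfg["mode"]
        )
        my = pp.butterworth_lowpass(
            rec.channel("My"), rec.sample_rate, fcfg["cutoff_hz"], fcfg["order"], fcfg["mode"]
        )
        filtered = fio.ForcePlateRecording(
            sample_rate=rec.sample_rate,
            samples=rec.samples.assign(Mx=mx, My=my),
            events=rec.events,
            participant=participant,
        )
        keep = {
            int(t)
            for t in trials.loc[
                included & (trials["participant"] == participant), "trial"
            ]
        }
        epochs = pp.segment(
            filtered,
            align_code=ecfg["align_code"],
            window_ms=tuple(ecfg["window_ms"]),
        )
        for ep in epochs:
            if ep.trial not in keep:
                continue
            series = vb.epoch_variability(
                ep,
                sample_rate=rec.sample_rate,
                window_ms=vcfg["window_ms"],
                step_ms=vcfg["step_ms"],
                axes=vcfg["axes"],
                alignment=vcfg["window_alignment"],
                analysis_window_ms=tuple(ecfg["analysis_window_ms"]),
            )
            trial_series.append((participant, ep.trial, series))
    return trial_series


@_stage("behavior")
def _behavioral_report(cfg, trials):
    experiment = cfg["experiment"]
    rt_report = pp.apply_exclusions(
        trials, "rt_and_forceplate", cfg["exclusion"]["rt_sd_multiplier"]
    )
    clean = trials[rt_report.included]
    out = {"effects": bh.summarize_effects(clean, experiment)}
    if experiment == 1:
        cm = bh.cell_means(clean, factors=("soa",))
        out["rt_soa_t_test"] = bh.paired_t(cm[100], cm[1000]).to_dict()
    else:
        out["rt_anova"] = {
            k: v.to_dict()
            for k, v in bh.rm_anova_2x2(clean, dv="rt_ms").items()
        }
    # error rates, each over its analysis-specific exclusion set
    err = trials[pp.apply_exclusions(trials, "rt_task_errors").included]
    err = err.assign(manual_pct=err["manual_error"].astype(float) * 100.0)
    if experiment == 1:
        cm = bh.cell_means(err, dv="manual_pct", factors=("soa",))
        out["manual_error_t_test"] = bh.paired_t(cm[100], cm[1000]).to_dict()
    else:
        out["manual_error_anova"] = {
            k: v.to_dict() for k, v in bh.rm_anova_2x2(err, dv="manual_pct").items()
        }
    out["exclusion_percentages"] = rt_report.percentages
    return out


@_stage("cluster")
def _cluster_analyses(cfg, timecourses, experiment):
    contrasts = EXP1_CONTRASTS if experiment == 1 else EXP2_CONTRASTS
    ccfg = cfg["cluster"]
    results = {}
    for i, (name, (cond_a, cond_b)) in enumerate(contrasts.items()):
        design = PairedDesign.from_timecourses(timecourses, cond_a, cond_b)
        config = PermutationConfig(
            n_perm=ccfg["n_perm"],
            seed=int(np.random.SeedSequence([cfg["seed"], 1000 + i]).generate_state(1)[0] % (2**31)),
            alpha=ccfg["alpha"],
            cluster_alpha=ccfg["cluster_alpha"],
        )
        clusters, _ = permutation_test(design, config)
        results[name] = clusters
        log.info("contrast %s: %d cluster(s)", name, len(clusters))
    return results


def run(config) -> RunReport:
    """Execute the full pipeline and write all outputs.

    ``config`` is a dict or a YAML/JSON file path; see
    :data:`DEFAULT_CONFIG`.  Returns a :class:`RunReport`; every table
    written names the exclusion set and config hash it derived from via the
    manifest.
    """
    cfg = load_config(config)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    experiment = cfg["experiment"]
    if experiment not in (1, 2):
        raise PipelineError("config", f"experiment must be 1 or 2, got {experiment}")

    recordings, trials = _acquire(cfg)
    log.info("acquired %d recordings, %d trials", len(recordings), len(trials))

    excl = pp.apply_exclusions(
        trials, "rt_and_forceplate", cfg["exclusion"]["rt_sd_multiplier"]
    )
    pd.concat([trials.reset_index(drop=True), excl.flags.reset_index(drop=True)], axis=1).to_csv(
        out_dir / "exclusions.csv", index=False
    )
    log.info(
        "exclusions (%s): %.1f%% excluded", excl.analysis, excl.percentages["excluded"]
    )

    trial_series = _participant_timecourses(cfg, recordings, trials, excl.included)
    grouping = ["soa"] if experiment == 1 else ["soa", "task_load"]
    timecourses = vb.aggregate(trial_series, trials, grouping)
    vb.timecourses_to_frame(timecourses).to_csv(out_dir / "timecourses.csv", index=False)

    cluster_results = _cluster_analyses(cfg, timecourses, experiment)
    fio.write_clusters(cluster_results, out_dir / "clusters.csv")

    behavior_report = _behavioral_report(cfg, trials)
    with open(out_dir / "behavior.json", "w") as fh:
        json.dump(behavior_report, fh, indent=2)

    figures = []
    if cfg["plot"]:
        for name, clusters in cluster_results.items():
            fig_path = out_dir / f"timecourse_{name}.png"
            conds = (EXP1_CONTRASTS if experiment == 1 else EXP2_CONTRASTS)[name]
            subset = [tc for tc in timecourses if tc.condition in conds]
            plot_timecourse(subset, clusters, fig_path, alpha=cfg["cluster"]["alpha"])
            figures.append(str(fig_path))

    manifest = {
        "config": cfg,
        "config_hash": config_hash(cfg),
        "seed": cfg["seed"],
        "experiment": experiment,
        "exclusion_set": "rt_and_forceplate",
        "n_participants": int(trials["participant"].nunique()),
        "n_trials": int(len(trials)),
        "n_trials_included": int(excl.included.sum()),
        "contrasts": {
            name: [
                {
                    "start_ms": c.start_ms,
                    "end_ms": c.end_ms,
                    "mass": c.mass,
                    "p_value": c.p_value,
                    "sign": c.sign,
                }
                for c in clusters
            ]
            for name, clusters in cluster_results.items()
        },
        "outputs": [
            str(out_dir / "exclusions.csv"),
            str(out_dir / "timecourses.csv"),
            str(out_dir / "clusters.csv"),
            str(out_dir / "behavior.json"),
            *figures,
        ],
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return RunReport(
        out_dir=out_dir,
        manifest=manifest,
        clusters=cluster_results,
        behavior=behavior_report,
        exclusion_percentages=excl.percentages,
    )


EVENT_LINES_MS = (0.0, 1000.0, 1100.0, 2000.0)


def plot_timecourse(
    timecourses,
    clusters,
    out,
    ci_level: float = 0.95,
    alpha: float = 0.05,
    events_ms=EVENT_LINES_MS,
    title: str | None = None,
):
    """Condition-mean variability traces with CI ribbons and cluster bands.

    Vertical lines mark cue onset, visual-target onset and the two possible
    auditory-target onsets; grey bands above the x-axis span significant
    clusters.  Writes ``out`` and returns the path.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    timecourses = list(timecourses)
    if not timecourses:
        raise PlottingError("no time courses to plot")
    conditions = sorted({tc.condition for tc in timecourses}, key=str)
    times = timecourses[0].series.times_ms
    try:
        ribbons = vb.within_subject_ci(timecourses, level=ci_level)
    except ErfpError:
        ribbons = {}

    fig, ax = plt.subplots(figsize=(8, 4.5))
    for cond in conditions:
        stack = np.array(
            [tc.series.values for tc in timecourses if tc.condition == cond]
        )
        mean = stack.mean(axis=0)
        label = "/".join(map(str, cond))
        (line,) = ax.plot(times, mean, label=label, lw=1.2)
        if cond in ribbons:
            ax.fill_between(
                times, mean - ribbons[cond], mean + ribbons[cond],
                color=line.get_color(), alpha=0.2, lw=0,
            )
    for t in events_ms:
        ax.axvline(t, color="0.4", ls=":", lw=0.8)
    y0 = ax.get_ylim()[0]
    band = 0.03 * (ax.get_ylim()[1] - y0)
    for c in clusters or ():
        if c.p_value <= alpha:
            ax.fill_between(
                [c.start_ms, c.end_ms], y0, y0 + band, color="0.6", zorder=0
            )
    ax.set_xlabel("time from cue onset (ms)")
    ax.set_ylabel("moment variability (mN·m)")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(out, dpi=110)
    plt.close(fig)
    return Path(out)
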