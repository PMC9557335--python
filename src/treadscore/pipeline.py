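"""End-to-end session and cohort runs driven by a config mapping.

The config is a plain mapping (usually loaded from YAML) with keys:

``output_dir``, ``seed``, ``schedule`` (speeds/step_duration/off_duration or
a CSV path), ``cohort`` (list of {animal, day, pose, photometry} records
with file paths), ``synthetic`` (n_animals, n_days, skill_curve,
dms_amplitude_curve — used by ``simulate``), ``score`` (weights,
likelihood_threshold), ``peaks`` (prominence_min, min_separation, ...),
``behavior`` (delta, window, refractory, half_window).

Every output table starts with a provenance comment line carrying the
config hash, the seed and the package version, so identical configs can be
recognized as producing identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import (
    HEAD_POSITION,
    STEP_LENGTH,
    detect_behavior_events,
    event_triggered_average,
    events_frame as behavior_events_frame,
    normalize_unit_range,
    peri_event_frame,
)
from .coordination import ScoreConfig, compute_components, score_cohort
from .photometry import (
    PeakParams,
    RawPhotometry,
    acceleration_triggered_average,
    detect_events,
    epoch_stats,
    epoch_stats_frame,
    events_frame,
    process,
)
from .pose import (
    RIGHT_FRONT,
    align_to_schedule,
    filter_likelihood,
    normalize_to_box,
    read_tracking_table,
    write_tracking_table,
)
from .protocol import SessionSchedule, build_standard_schedule
from .synthetic import (
    SyntheticPhotometryConfig,
    SyntheticPoseConfig,
    simulate_learning_cohort,
)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    cfg.setdefault("output_dir", "treadscore_out")
    cfg.setdefault("seed", 0)
    return cfg


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def schedule_from_config(config: dict) -> SessionSchedule:
    spec = config.get("schedule") or {}
    if isinstance(spec, str):
        return SessionSchedule.from_csv(spec)
    kwargs = {}
    if "speeds" in spec:
        kwargs["speeds"] = spec["speeds"]
    if "step_duration" in spec:
        kwargs["step_duration"] = spec["step_duration"]
    if "off_duration" in spec:
        kwargs["off_duration"] = spec["off_duration"]
    return build_standard_schedule(**kwargs)


def _provenance(config: dict) -> str:
    return (
        f"# treadscore {__version__} config_hash={config_hash(config)} "
        f"seed={config.get('seed', 0)}"
    )


def write_table(df: pd.DataFrame, path, config: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance(config) + "\n")
        df.to_csv(fh, index=False)


def _peak_params(config: dict) -> PeakParams:
    return PeakParams(**(config.get("peaks") or {}))


def _score_config(config: dict) -> ScoreConfig:
    opts = dict(config.get("score") or {})
    opts.pop("likelihood_threshold", None)
    if "weights" in opts:
        opts["weights"] = tuple(opts["weights"])
    return ScoreConfig(**opts)


# ---------------------------------------------------------------------------
# simulation to disk


def simulate_to_dir(config: dict, out_dir=None) -> list[dict]:
    """Generate a synthetic cohort and write it in the real-data formats.

    Writes one DLC-dialect pose CSV and one photometry CSV per animal-day,
    the schedule CSV, and a ground-truth JSON sidecar; returns (and stores
    in the config) the cohort roster pointing at the files.
    """
    out = Path(out_dir or config["output_dir"]) / "synthetic"
    out.mkdir(parents=True, exist_ok=True)
    schedule = schedule_from_config(config)
    syn = config.get("synthetic") or {}
    n_animals = int(syn.get("n_animals", 2))
    n_days = int(syn.get("n_days", 3))
    skill_curve = syn.get("skill_curve")
    if skill_curve is None:
        skill_curve = np.linspace(0.1, 0.9, n_days)
    pose_cfg = SyntheticPoseConfig(**(syn.get("pose") or {}))
    records = simulate_learning_cohort(
        n_animals,
        n_days,
        skill_curve,
        dms_amplitude_curve=syn.get("dms_amplitude_curve"),
        pose_cfg=pose_cfg,
        phot_cfg=SyntheticPhotometryConfig(**(syn.get("photometry") or {})),
        schedule=schedule,
        seed=int(config.get("seed", 0)),
    )
    config["box"] = list(pose_cfg.box)
    schedule.to_csv(out / "schedule.csv")
    roster = []
    truth: dict = {}
    for rec in records:
        stem = f"a{rec.animal:02d}_d{rec.day:02d}"
        pose_path = out / f"pose_{stem}.csv"
        write_tracking_table(rec.pose, pose_path)
        phot_path = None
        if rec.photometry is not None:
            phot_path = out / f"photometry_{stem}.csv"
            rec.photometry.to_csv(phot_path)
        roster.append(
            {
                "animal": rec.animal,
                "day": rec.day,
                "pose": str(pose_path),
                "photometry": str(phot_path) if phot_path else None,
            }
        )
        truth[stem] = {
            "skill": rec.skill,
            "back_wall_times": rec.pose_truth["back_wall_times"],
            "n_transients": 0 if rec.photometry_truth is None
            else int(len(rec.photometry_truth)),
        }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    config["cohort"] = roster
    config.setdefault("schedule", {})
    return roster


# ---------------------------------------------------------------------------
# per-session run


def _find_session(config: dict, animal: int, day: int) -> dict:
    for rec in config.get("cohort") or []:
        if rec["animal"] == animal and rec["day"] == day:
            return rec
    raise FileNotFoundError(f"no cohort entry for animal {animal} day {day}")


def run_session(config: dict, animal: int, day: int) -> dict:
    """Process one animal-day end to end; writes tidy CSVs, returns a bundle.

    Outputs under ``<output_dir>/a<animal>_d<day>/``: components.csv,
    calcium_events.csv, epoch_stats.csv, peri_acceleration.csv,
    behavior_events.csv, peri_behavior.csv (behavior/peri files only when
    photometry is present).
    """
    rec = _find_session(config, animal, day)
    pose_path = rec.get("pose")
    if not pose_path or not Path(pose_path).exists():
        raise FileNotFoundError(f"missing pose file {pose_path!r}")
    schedule = schedule_from_config(config)
    out = Path(config["output_dir"]) / f"a{animal:02d}_d{day:02d}"

    session = read_tracking_table(pose_path)
    threshold = (config.get("score") or {}).get("likelihood_threshold", 0.9)
    session = filter_likelihood(session, threshold)
    if session.box is None:
        session.box = tuple((config.get("box") or (0.0, 640.0, 0.0, 320.0)))
    session = normalize_to_box(session)
    session = align_to_schedule(session, schedule, rec.get("sync_offset", 0.0))

    components = compute_components(session, schedule, _score_config(config))
    comp_row = pd.DataFrame(
        [
            {
                "animal": animal,
                "day": day,
                "zone_expectation": components.zone_expectation,
                "lateral_sd": components.lateral_sd,
                "paw_instability": components.paw_instability,
                **{f"step_mean_{k}": v for k, v in components.step_length_means.items()},
            }
        ]
    )
    write_table(comp_row, out / "components.csv", config)
    bundle = {"components": components, "session": session}

    phot_path = rec.get("photometry")
    if phot_path:
        if not Path(phot_path).exists():
            raise FileNotFoundError(f"missing photometry file {phot_path!r}")
        params = _peak_params(config)
        raw = RawPhotometry.from_csv(phot_path)
        trace = process(raw, params)
        events = detect_events(trace.dff, params, time=trace.time)
        write_table(events_frame(events), out / "calcium_events.csv", config)

        stats = epoch_stats(events, trace, schedule.pooled_intervals())
        sdf = epoch_stats_frame(stats)
        sdf.insert(0, "day", day)
        sdf.insert(0, "animal", animal)
        write_table(sdf, out / "epoch_stats.csv", config)

        bopts = config.get("behavior") or {}
        half_window = float(bopts.get("half_window", 5.0))
        accel = acceleration_triggered_average(
            trace, schedule.acceleration_times(), half_window
        )
        write_table(peri_event_frame(accel), out / "peri_acceleration.csv", config)

        behavior_rows = []
        peri_frames = []
        head_x = session["head"].x
        paw = session[RIGHT_FRONT]
        step_series = np.concatenate([[0.0], np.hypot(np.diff(paw.x), np.diff(paw.y))])
        for measure, series in ((HEAD_POSITION, head_x), (STEP_LENGTH, step_series)):
            try:
                norm = normalize_unit_range(series)
            except ValueError:
                continue
            evts = detect_behavior_events(
                norm,
                delta=float(bopts.get("delta", 0.1)),
                window=int(bopts.get("window", 30)),
                refractory=float(bopts.get("refractory", 2.0)),
                rate=session.frame_rate,
                measure=measure,
                time=session.frame_times,
            )
            behavior_rows.append(behavior_events_frame(evts))
            if evts:
                try:
                    pea = event_triggered_average(trace, evts, half_window)
                except ValueError:
                    continue
                pf = peri_event_frame(pea)
                pf.insert(0, "measure", measure)
                peri_frames.append(pf)
        bdf = (
            pd.concat(behavior_rows, ignore_index=True)
            if behavior_rows
            else pd.DataFrame(columns=["t_s", "measure", "direction", "magnitude"])
        )
        write_table(bdf, out / "behavior_events.csv", config)
        if peri_frames:
            write_table(
                pd.concat(peri_frames, ignore_index=True),
                out / "peri_behavior.csv",
                config,
            )
        bundle.update(trace=trace, events=events, stats=stats)
    return bundle


def run_cohort(config: dict) -> dict:
    """Process every animal-day, pool the cohort score, summarize per day.

    Failures on individual sessions are collected into a partial-failure
    report rather than aborting the cohort; at least two sessions must
    succeed for scoring.  Writes scores.csv, day_summary.csv, epoch_stats
    pooled across sessions, and failures.csv when applicable.
    """
    roster = config.get("cohort") or []
    if len(roster) < 2:
        raise ValueError("cohort needs >= 2 animal-days")
    out = Path(config["output_dir"])

    results, failures = [], []
    for rec in roster:
        try:
            bundle = run_session(config, rec["animal"], rec["day"])
        except Exception as exc:  # noqa: BLE001 - partial-failure report
            failures.append(
                {"animal": rec["animal"], "day": rec["day"], "error": str(exc)}
            )
            continue
        results.append((rec, bundle))
    if failures:
        write_table(pd.DataFrame(failures), out / "failures.csv", config)
    if len(results) < 2:
        raise ValueError(
            f"only {len(results)} session(s) succeeded; cannot score a cohort"
        )

    comps = [b["components"] for _, b in results]
    scores = score_cohort(comps, _score_config(config))
    scores.insert(0, "day", [r["day"] for r, _ in results])
    scores.insert(0, "animal", [r["animal"] for r, _ in results])
    write_table(scores, out / "scores.csv", config)

    day_summary = (
        scores.groupby("day")["score"]
        .agg(mean_score="mean", sem_score="sem", n="count")
        .reset_index()
    )
    write_table(day_summary, out / "day_summary.csv", config)

    stat_frames = [
        epoch_stats_frame(b["stats"]).assign(animal=r["animal"], day=r["day"])
        for r, b in results
        if "stats" in b
    ]
    if stat_frames:
        write_table(
            pd.concat(stat_frames, ignore_index=True),
            out / "cohort_epoch_stats.csv",
            config,
        )
    return {"scores": scores, "day_summary": day_summary, "failures": failures}


def report(config: dict) -> pd.DataFrame:
    """Per-day mean ± SEM table from an existing scores.csv."""
    path = Path(config["output_dir"]) / "scores.csv"
    scores = pd.read_csv(path, comment="#")
    return (
        scores.groupby("day")["score"]
        .agg(mean_score="mean", sem_score="sem", n="count")
        .reset_index()
    )
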