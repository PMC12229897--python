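"""End-to-end analysis pipeline.

Chains the stages: synthetic-data generation (or session files) ->
dF/F + transient masking -> spatial maps -> place-field detection ->
multi-day stability -> discrimination/behavior metrics -> BTSP
detection -> generative models, writing one CSV per result table plus
a JSON run manifest with the seeds used.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import btsp as btsp_mod
from . import metrics as metrics_mod
from . import models as models_mod
from . import placefields as pf_mod
from . import signal as signal_mod
from . import stability as stab_mod
from .session import SessionRecording
from .synth import GeneratorConfig, generate_experiment

DEFAULT_CONFIG = {
    "generator": {"n_cells": 200, "n_days": 3, "laps_per_session": 40, "seed": 0},
    "analysis": {"n_shuffles": 300, "window_cm": 30.0},
    "models": {"n_replicates": 20},
}


def _merge(base: dict, override: dict) -> dict:
    out = {k: dict(v) for k, v in base.items()}
    for k, v in (override or {}).items():
        out.setdefault(k, {})
        out[k].update(v)
    return out


def load_config(path) -> dict:
    import yaml

    with open(path) as f:
        return _merge(DEFAULT_CONFIG, yaml.safe_load(f) or {})


def analyze_session(
    session: SessionRecording,
    n_shuffles: int = 300,
    n_bins: int = 50,
    rng: np.random.Generator | None = None,
):
    """Signal processing + PF and BTSP detection for one session.

    Returns (spatial map, place-field table, BTSP event table).
    """
    rng = np.random.default_rng() if rng is None else rng
    activity = np.empty_like(session.traces, dtype=float)
    for c in range(session.n_cells):
        dff = signal_mod.compute_dff(session.traces[c], session.frame_rate)
        signal_mod.estimate_baseline_noise(dff)
        activity[c] = signal_mod.functional_activity(dff)
    smap = signal_mod.compute_spatial_map(
        activity, session.position, session.velocity, session.lap_index,
        session.lap_condition, n_bins=n_bins, track_length=session.track_length,
    )
    pf_table = pf_mod.detect_place_fields(
        smap, day=session.day, n_shuffles=n_shuffles, rng=rng
    )
    pf_table.insert(0, "mouse", session.mouse)

    lap_vel = smap.lap_velocity()
    events = []
    for condition in ("RL1", "RL2"):
        cond_laps = np.flatnonzero(smap.lap_condition == condition)
        if cond_laps.size < 6:
            continue
        for cell in range(session.n_cells):
            evs = btsp_mod.detect_btsp_events(
                smap.values[cell][cond_laps],
                lap_vel[cond_laps],
                bin_width=smap.bin_width,
                track_length=smap.track_length,
                cell=cell,
                day=session.day,
                condition=condition,
            )
            for ev in evs:
                row = ev.to_dict()
                row["lap"] = int(cond_laps[row["lap"]])  # back to session laps
                row["mouse"] = session.mouse
                events.append(row)
    btsp_table = pd.DataFrame(
        events,
        columns=[
            "cell", "day", "condition", "lap", "amplitude", "peak_location_cm",
            "com_shift_cm", "induction_velocity", "pf_width_cm",
            "is_first_of_session", "mouse",
        ],
    )
    return smap, pf_table, btsp_table


def run_pipeline(config: dict | None = None, out_dir=None, seed: int | None = None) -> dict:
    """Run the full pipeline on a synthetic experiment.

    ``config`` follows :data:`DEFAULT_CONFIG`; ``seed`` overrides the
    generator seed. When ``out_dir`` is given every result table is
    written as CSV together with a manifest.json. Returns the tables.
    """
    config = _merge(DEFAULT_CONFIG, config or {})
    gen_kwargs = dict(config["generator"])
    if seed is not None:
        gen_kwargs["seed"] = int(seed)
    gcfg = GeneratorConfig(**gen_kwargs)
    sessions, truth = generate_experiment(gcfg)

    n_shuffles = int(config["analysis"].get("n_shuffles", 300))
    window = float(config["analysis"].get("window_cm", 30.0))
    rng = np.random.default_rng([gcfg.seed, 104729])

    pf_tables, btsp_tables, metric_rows = [], [], []
    for session in sessions:
        smap, pf_table, btsp_table = analyze_session(
            session, n_shuffles=n_shuffles, n_bins=gcfg.n_bins, rng=rng
        )
        pf_tables.append(pf_table)
        btsp_tables.append(btsp_table)

        pcs = pf_table["cell"].unique()
        pdi = float("nan")
        if pcs.size >= 2:
            pop = metrics_mod.similarity_matrix(
                [smap.values[c] for c in pcs], smap.lap_condition
            )
            pdi = metrics_mod.discrimination_index(pop)
        lick_table = metrics_mod.lick_probability_map(
            session.licks, session.position, session.lap_index,
            session.n_laps, n_bins=gcfg.n_bins, track_length=gcfg.track_length,
        )
        reward_bins = (session.reward_cm / gcfg.bin_width).astype(int)
        cue_bin = int(40.0 / gcfg.bin_width)
        lick_sel = metrics_mod.licking_selectivity(lick_table, reward_bins, cue_bin)
        metric_rows.append(
            {
                "mouse": session.mouse,
                "day": session.day,
                "pdi": pdi,
                "licking_selectivity": lick_sel,
                "n_pcs": int(pcs.size),
            }
        )
    pf_all = pd.concat(pf_tables, ignore_index=True)
    btsp_all = pd.concat(btsp_tables, ignore_index=True)
    metrics_table = pd.DataFrame(metric_rows)

    chains, cohort_counts = stab_mod.build_consistency_chains(pf_all, window=window)
    if not chains.empty:
        chains["class_counts"] = stab_mod.classify_cells(chains, "counts")
        chains["class_properties"] = stab_mod.classify_cells(chains, "properties")
    past_new = stab_mod.count_past_new(pf_all, window=window)

    mcfg = config["models"]
    reps = int(mcfg.get("n_replicates", 20))
    tp = models_mod.three_pool_simulate(models_mod.ThreePoolConfig(), n_days=7)
    cas = models_mod.cascade_simulate(
        models_mod.CascadeConfig(n_replicates=reps),
        rng=np.random.default_rng([gcfg.seed, 15485863]),
    )
    prog = models_mod.progressive_simulate(
        models_mod.ProgressiveConfig(n_replicates=reps),
        rng=np.random.default_rng([gcfg.seed, 32452843]),
    )
    model_counts = pd.concat(
        [
            pd.DataFrame(
                {
                    "model": "three_pool",
                    "day": tp["day"],
                    "count": tp["total_pcs"],
                    "replicate": 0,
                }
            ),
            pd.DataFrame(
                {
                    "model": "cascade",
                    "day": np.tile(np.arange(1, cas.counts.shape[1] + 1), reps),
                    "count": cas.counts.ravel(),
                    "replicate": np.repeat(np.arange(reps), cas.counts.shape[1]),
                }
            ),
            pd.DataFrame(
                {
                    "model": "progressive",
                    "day": np.tile(np.arange(1, prog.counts.shape[1] + 1), reps),
                    "count": prog.counts.ravel(),
                    "replicate": np.repeat(np.arange(reps), prog.counts.shape[1]),
                }
            ),
        ],
        ignore_index=True,
    )

    tables = {
        "place_fields": pf_all,
        "btsp_events": btsp_all,
        "metrics": metrics_table,
        "chains": chains,
        "cohort_counts": cohort_counts,
        "past_new": past_new,
        "model_counts": model_counts,
        "ground_truth": truth.events,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in tables.items():
            table.to_csv(out / f"{name}.csv", index=False)
        manifest = {
            "seed": gcfg.seed,
            "config": {k: dict(v) for k, v in config.items()},
            "n_sessions": len(sessions),
            "tables": sorted(tables),
        }
        with open(out / "manifest.json", "w") as f:
            json.dump(manifest, f, indent=2, default=str)
    return tables
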