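"""End-to-end pipeline: simulate -> locate pores -> features -> divergence ->
classification -> survival.

A structured YAML config drives every stage; all stage seeds derive
deterministically from one global seed, so re-running an identical config
reproduces identical artifacts. Each artifact is written next to a
provenance sidecar carrying the config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import divergence as div
from . import ml, porefind, survival, synthetic
from .events import events_to_frame, write_events
from .surface import feature_matrix

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "synthetic": {
        "box_xy": 30.0,
        "n_lipids_per_leaflet": 700,
        "compositions": ["APM", "BPM"],
        "correlation_length": 3.0,
        "heterogeneity": 1.2,
        "order_coupling": 0.8,
    },
    "hazard": {
        "endpoints": [0.0, 3.0, 15.0],
        "baseline_rates": [0.02, 0.25],
        "betas": {"APM-dep": 0.0, "APM-hyp": 1.0, "BPM-dep": -0.7, "BPM-hyp": 0.6},
        "censor_time": 15.0,
        "coupling": 3.0,
        "n_per_system": 30,
    },
    "pore_search": {"n_demo_replicas": 2, "n_frames": 40},
    "features": {"n_frames": 21, "dt": 0.1, "r_smooth": 1.5},
    "locations": {"grid_n": 31, "target_non_porated": 300, "exclusion_fraction": 0.067},
    "ml": {"scheme": "cross-composition", "algorithm": "random-forest"},
    "survival": {"width": 1.5, "variant": "constant", "n_steps": 2000, "n_burn": 800},
}

REQUIRED_BLOCKS = ["synthetic", "hazard", "features", "locations", "ml", "survival"]


def load_config(path: str | Path | None = None, seed: int | None = None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for block, value in user.items():
            if isinstance(value, dict) and isinstance(cfg.get(block), dict):
                cfg[block].update(value)
            else:
                cfg[block] = value
    if seed is not None:
        cfg["seed"] = int(seed)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    missing = [b for b in REQUIRED_BLOCKS if b not in cfg]
    if missing:
        raise ValueError(f"config missing stage block(s): {', '.join(missing)}")
    if "seed" not in cfg:
        raise ValueError("config missing global seed")


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def _sidecar(path: Path, cfg: dict, stage: str) -> None:
    meta = {"stage": stage, "config_hash": config_hash(cfg)}
    path.with_suffix(path.suffix + ".provenance.json").write_text(
        json.dumps(meta, indent=1))


def _membrane_systems(composition: str) -> list[str]:
    return [f"{composition}-dep", f"{composition}-hyp"]


def stage_simulate(cfg: dict, outdir: Path) -> dict:
    """Generate composition fields and hazard-driven poration events per
    membrane; write the pooled event table."""
    t0 = _time.time()
    seed = cfg["seed"]
    syn = cfg["synthetic"]
    hz = cfg["hazard"]
    bundle = {"fields": {}, "configs": {}, "events": []}
    for m, comp in enumerate(syn["compositions"]):
        mem_id = f"{comp}-mem{m + 1}"
        config = synthetic.SyntheticConfig(
            box_xy=syn["box_xy"], n_lipids_per_leaflet=syn["n_lipids_per_leaflet"],
            composition=comp, correlation_length=syn["correlation_length"],
            heterogeneity=syn["heterogeneity"], order_coupling=syn["order_coupling"],
            seed=seed + m)
        fields = synthetic.gen_composition_fields(config)
        spec = synthetic.HazardSpec(
            interval_endpoints=np.asarray(hz["endpoints"], float),
            baseline_rates=np.asarray(hz["baseline_rates"], float),
            betas={s: hz["betas"][s] for s in _membrane_systems(comp)},
            censor_time=hz.get("censor_time"))
        events = synthetic.sample_poration_dataset(
            spec, hz["n_per_system"], pu_field=fields.pu_field(smooth_nm=1.5),
            coupling=hz["coupling"], seed=seed + m, membrane_id=mem_id)
        bundle["fields"][mem_id] = fields
        bundle["configs"][mem_id] = config
        bundle["events"].extend(events)
    events_df = events_to_frame(bundle["events"])
    out = outdir / "events.csv"
    write_events(events_df, out)
    _sidecar(out, cfg, "simulate")
    bundle["events_df"] = events_df
    log.info("simulate: %d events in %.1fs", len(events_df), _time.time() - t0)
    return bundle


def stage_locate_pores(cfg: dict, outdir: Path, bundle: dict) -> pd.DataFrame:
    """Plant pores per sampled event into short trajectories and re-detect
    them with the two-stage search (a localization self-check)."""
    t0 = _time.time()
    ps = cfg["pore_search"]
    params = porefind.PoreSearchParams()
    rows = []
    events = bundle["events_df"]
    observed = events.loc[~events["censored"]]
    demo = observed.head(ps["n_demo_replicas"])
    for _, ev in demo.iterrows():
        config = bundle["configs"][ev["membrane_id"]]
        fields = bundle["fields"][ev["membrane_id"]]
        traj = synthetic.gen_trajectory(config, ps["n_frames"], dt=0.1,
                                        fields=fields, seed=cfg["seed"] + int(ev["replica"]))
        # keep the planted onset early enough that the strided coarse scan
        # still visits a frame at or after it
        latest = ps["n_frames"] - params.coarse_stride - params.persistence - 1
        onset = min(int(ev["t_ns"] / traj.dt), latest)
        loc = (ev["x_rel"] * config.box_xy, ev["y_rel"] * config.box_xy)
        planted = synthetic.plant_pore(traj, loc, n_waters=15,
                                       start_frame=max(onset, params.start_frame + 1),
                                       seed=cfg["seed"])
        found = porefind.locate_first_pore(planted, params,
                                           membrane_id=ev["membrane_id"],
                                           system=ev["system"],
                                           replica=int(ev["replica"]))
        rows.append(asdict(found))
    located = pd.DataFrame(rows)
    out = outdir / "located_events.csv"
    located.to_csv(out, index=False)
    _sidecar(out, cfg, "locate-pores")
    log.info("locate-pores: %d replicas in %.1fs", len(located), _time.time() - t0)
    return located


def stage_features(cfg: dict, outdir: Path, bundle: dict) -> pd.DataFrame:
    """Porated/non-porated location sets and the per-(location, frame)
    feature matrix over a pre-field trajectory of every membrane."""
    t0 = _time.time()
    fc = cfg["features"]
    lc = cfg["locations"]
    events = bundle["events_df"]
    frames = []
    for mem_id, config in bundle["configs"].items():
        ev = events[(events["membrane_id"] == mem_id) & (~events["censored"])]
        porated = ev[["x_rel", "y_rel"]].to_numpy()
        nonporated = div.sample_nonporated(
            config.box_xy, porated, grid_n=lc["grid_n"],
            exclusion_fraction=lc["exclusion_fraction"],
            target=lc["target_non_porated"], seed=cfg["seed"])
        locations = pd.DataFrame({
            "x_rel": np.concatenate([porated[:, 0], nonporated[:, 0]]),
            "y_rel": np.concatenate([porated[:, 1], nonporated[:, 1]]),
            "label": np.concatenate([np.ones(len(porated), int),
                                     np.zeros(len(nonporated), int)]),
        })
        traj = synthetic.gen_trajectory(config, fc["n_frames"], dt=fc["dt"],
                                        fields=bundle["fields"][mem_id],
                                        seed=config.seed)
        fm = feature_matrix(traj, locations, r_smooth=fc["r_smooth"],
                            membrane_id=mem_id)
        fm["system"] = f"{config.composition}-dep"
        frames.append(fm)
    features = pd.concat(frames, ignore_index=True)
    out = outdir / "features.csv"
    features.to_csv(out, index=False)
    _sidecar(out, cfg, "extract-features")
    log.info("extract-features: %d rows in %.1fs", len(features), _time.time() - t0)
    return features


def stage_rank_features(cfg: dict, outdir: Path, features: pd.DataFrame) -> pd.DataFrame:
    table = div.divergence_table(features)
    out = outdir / "divergences.csv"
    table.to_csv(out, index=False)
    _sidecar(out, cfg, "rank-features")
    return table


def stage_classify(cfg: dict, outdir: Path, features: pd.DataFrame) -> dict:
    mlc = cfg["ml"]
    mems = sorted(features["membrane_id"].unique())
    if mlc["scheme"] == "cross-composition":
        apm = [m for m in mems if m.startswith("APM")]
        bpm = [m for m in mems if m.startswith("BPM")]
        scheme = ml.SplitScheme("pairwise-membranes", train=apm, test=bpm,
                                seed=cfg["seed"])
    elif mlc["scheme"] == "pairwise-membranes":
        scheme = ml.SplitScheme("pairwise-membranes", train=mems[: len(mems) // 2],
                                test=mems[len(mems) // 2:], seed=cfg["seed"])
    else:
        scheme = ml.SplitScheme(mlc["scheme"], seed=cfg["seed"])
    report = ml.run_scheme(features, scheme, algorithm=mlc["algorithm"],
                           seed=cfg["seed"])
    payload = asdict(report)
    out = outdir / "ml_report.json"
    out.write_text(json.dumps(payload, indent=1))
    _sidecar(out, cfg, "classify")
    return payload


def stage_survival(cfg: dict, outdir: Path, events: pd.DataFrame) -> dict:
    sv = cfg["survival"]
    spec = survival.HazardModelSpec(width=sv["width"])
    post = survival.fit_hazard(events, spec, variant=sv["variant"],
                               n_steps=sv["n_steps"], n_burn=sv["n_burn"],
                               seed=cfg["seed"])
    np.savez(outdir / "posterior.npz",
             endpoints=post.endpoints, lambda_draws=post.lambda_draws,
             beta_draws=post.beta_draws,
             systems=np.asarray(post.systems, dtype=object))
    summary: dict = {
        "systems": post.systems,
        "converged": post.converged,
        "rhat_max": post.rhat["max"],
        "lambda_median": np.median(post.lambda_draws, axis=0).tolist(),
        "beta_median": np.median(post.beta_draws, axis=0).tolist(),
        "rate_ratios": {},
        "barrier_differences_kT": {},
    }
    for i, si in enumerate(post.systems):
        for sj in post.systems[i + 1:]:
            rr = survival.rate_ratio(post, si, sj)
            bd = survival.barrier_difference(post, si, sj)
            key = f"{si}/{sj}"
            summary["rate_ratios"][key] = {
                "median": rr["median"], "interval": list(rr["interval"])}
            summary["barrier_differences_kT"][key] = {
                "median": bd["median"], "interval": list(bd["interval"])}
    ppc = survival.posterior_predictive(post, events, seed=cfg["seed"])
    summary["posterior_predictive_ks"] = ppc["ks_statistic"]
    summary["posterior_predictive_p"] = ppc["p_value"]
    out = outdir / "survival_summary.json"
    out.write_text(json.dumps(summary, indent=1))
    _sidecar(out, cfg, "survival")
    return summary


def run_pipeline(cfg: dict, outdir: str | Path) -> dict:
    """Execute all stages in order; each writes its artifact under ``outdir``."""
    validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": config_hash(cfg)}
    try:
        bundle = stage_simulate(cfg, outdir)
        report["n_events"] = len(bundle["events_df"])
        located = stage_locate_pores(cfg, outdir, bundle)
        report["n_located"] = int((~located["censored"]).sum())
        features = stage_features(cfg, outdir, bundle)
        report["n_feature_rows"] = len(features)
        ranking = stage_rank_features(cfg, outdir, features)
        report["top_feature"] = str(ranking.iloc[0]["feature"])
        report["ml"] = stage_classify(cfg, outdir, features)
        report["survival"] = stage_survival(cfg, outdir, bundle["events_df"])
    except Exception as err:
        raise RuntimeError(f"pipeline stage failed: {err}") from err
    (outdir / "report.json").write_text(json.dumps(report, indent=1))
    return report
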