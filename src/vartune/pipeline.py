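"""Stage orchestration: synthetic data -> tuning -> clustering -> decoding
-> ring scan, with a YAML-configurable run manifest.

Stages communicate only through file artifacts in the output directory:

- ``dataset_*`` (events/stimuli/meta/truth CSV+JSON) from ``simulate-data``;
- ``summaries.csv`` + ``fits.json`` from ``analyze-tuning``;
- ``clusters.csv`` (labels, PC scores, vulnerability score) + ``wcss.csv``
  + ``cluster_model.json`` from ``cluster``;
- ``decoding_<task>.csv`` accuracy time courses from ``decode``;
- ``ringscan.h5`` (or CSV) parameter maps from ``ringscan``;
- ``manifest.json`` recording config, seeds and package version.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from vartune import clustering, decoding, ringmodel, synthetic, tuning

log = logging.getLogger("vartune")

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "population": {
        "n_neurons": 60,
        "resilient_fraction": 85 / 249,
    },
    "simulate": {"n_trials": 15, "dispersion": 1.0},
    "decode": {
        "tasks": ["theta"],
        "theta_b_theta": "low",  # lowest-variance orientation decoder
        "windows": None,  # None = all 61 windows
        "C": 1.0,
        "test_frac": 0.15,
    },
    "ringscan": {
        "enabled": False,
        "kappa_range": [0.35, 7.0],
        "steps": 10,
        "n_btheta": 8,
        "n_theta": 16,
        "n_units": 128,
    },
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge a YAML config file (and overrides) into the defaults."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy

    def merge(dst, src):
        for k, v in src.items():
            if k not in dst:
                raise KeyError(f"unknown config key: {k!r}")
            if isinstance(v, dict) and isinstance(dst[k], dict):
                merge(dst[k], v)
            else:
                dst[k] = v

    if path is not None:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        merge(cfg, yaml.safe_load(path.read_text()) or {})
    if overrides:
        merge(cfg, overrides)
    return cfg


def _stage_simulate(cfg, outdir, seed):
    pop = synthetic.sample_population(
        cfg["population"]["n_neurons"],
        cfg["population"]["resilient_fraction"], seed=seed)
    dataset = synthetic.simulate_trials(
        pop, n_trials=cfg["simulate"]["n_trials"], seed=seed + 1,
        dispersion=cfg["simulate"]["dispersion"])
    dataset.to_csv(outdir / "dataset")
    return dataset


def _stage_tuning(dataset, outdir):
    summaries, table = tuning.summarize_population(dataset)
    table.to_csv(outdir / "summaries.csv", index=False)
    fits = {
        str(s.neuron_id): {
            "nkr": asdict(s.nkr),
            "von_mises": [asdict(f) for f in s.vm_fits],
        } for s in summaries}
    (outdir / "fits.json").write_text(json.dumps(fits, indent=1))
    return summaries, table


def _stage_cluster(table, outdir, seed):
    fm = clustering.assemble_features(table)
    model = clustering.cluster(fm, seed=seed)
    scores = clustering.vulnerability_score(fm, model=model)
    out = pd.DataFrame({
        "neuron_id": table["neuron_id"],
        "label": model.labels,
        "pc1": model.pc_scores[:, 0],
        "pc2": model.pc_scores[:, 1],
        "vulnerability_score": scores,
    })
    out.to_csv(outdir / "clusters.csv", index=False)
    pd.DataFrame({"k": np.arange(1, len(model.wcss) + 1),
                  "wcss": model.wcss}).to_csv(outdir / "wcss.csv", index=False)
    (outdir / "cluster_model.json").write_text(json.dumps({
        "loadings": model.loadings.tolist(),
        "explained_variance": model.explained_variance.tolist(),
        "weights": model.weights,
        "columns": model.columns,
    }, indent=1))
    return model, scores


def _stage_decode(dataset, cfg, outdir, seed):
    dcfg = cfg["decode"]
    bthetas = np.sort(dataset.stimuli["b_theta_deg"].unique())
    results = []
    for task in dcfg["tasks"]:
        b = None
        if task == "theta":
            b = {"low": bthetas[0], "high": bthetas[-1]}.get(
                dcfg["theta_b_theta"], dcfg["theta_b_theta"])
        mat = decoding.windowed_counts(dataset, task, b_theta=b)
        run = decoding.decode_timecourse(
            mat, seed=seed, windows=dcfg["windows"], C=dcfg["C"],
            test_frac=dcfg["test_frac"])
        df = pd.DataFrame({"task": task, "b_theta": b,
                           "window_start_ms": run.window_starts,
                           "balanced_accuracy": run.accuracy,
                           "chance": run.chance})
        df.to_csv(outdir / f"decoding_{task}.csv", index=False)
        results.append(df)
    return results


def _stage_ringscan(cfg, outdir):
    rcfg = cfg["ringscan"]
    config = ringmodel.RingConfig(n_units=rcfg["n_units"])
    maps = ringmodel.scan(kappa_range=tuple(rcfg["kappa_range"]),
                          steps=rcfg["steps"], config=config,
                          n_btheta=rcfg["n_btheta"],
                          n_theta=rcfg["n_theta"])
    try:
        import h5py

        with h5py.File(outdir / "ringscan.h5", "w") as h5:
            for key, arr in maps.items():
                h5.create_dataset(key, data=arr)
    except Exception:  # pragma: no cover - h5py present in supported envs
        pass
    rows = []
    kappas = maps["kappas"]
    for i, ke in enumerate(kappas):
        for j, ki in enumerate(kappas):
            rows.append({"kappa_exc": ke, "kappa_inh": ki,
                         "log_n": maps["log_n"][i, j],
                         "b_theta50": maps["b_theta50"][i, j],
                         "f0": maps["f0"][i, j],
                         "tau_half_ms": maps["tau_half_ms"][i, j]})
    pd.DataFrame(rows).to_csv(outdir / "ringscan.csv", index=False)
    return maps


def run_pipeline(config: dict | None = None, outdir="vartune_run",
                 stages=("simulate", "tuning", "cluster", "decode"),
                 seed: int | None = None) -> dict:
    """Run the selected stages end to end; idempotent for identical config.

    Returns a dict of in-memory stage products.  Partial results stay on
    disk if a later stage raises.
    """
    cfg = config or load_config()
    if seed is not None:
        cfg["seed"] = seed
    seed = cfg["seed"]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    products: dict = {"config": cfg}
    manifest = {"config": cfg, "stages": list(stages),
                "started": time.strftime("%Y-%m-%dT%H:%M:%S")}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))

    if "simulate" in stages:
        log.info("stage=simulate n_neurons=%d seed=%d",
                 cfg["population"]["n_neurons"], seed)
        products["dataset"] = _stage_simulate(cfg, outdir, seed)
    dataset = products.get("dataset")
    if dataset is None and any(s in stages for s in ("tuning", "decode")):
        dataset = synthetic.SpikeDataset.from_csv(outdir / "dataset")
        products["dataset"] = dataset

    if "tuning" in stages:
        log.info("stage=tuning")
        products["summaries"], products["summary_table"] = _stage_tuning(
            dataset, outdir)
    if "cluster" in stages:
        log.info("stage=cluster")
        table = products.get("summary_table")
        if table is None:
            table = pd.read_csv(outdir / "summaries.csv")
        products["cluster_model"], products["scores"] = _stage_cluster(
            table, outdir, seed)
    if "decode" in stages:
        log.info("stage=decode tasks=%s", cfg["decode"]["tasks"])
        products["decoding"] = _stage_decode(dataset, cfg, outdir, seed)
    if "ringscan" in stages or cfg["ringscan"]["enabled"]:
        log.info("stage=ringscan steps=%d", cfg["ringscan"]["steps"])
        products["ringscan"] = _stage_ringscan(cfg, outdir)

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return products
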