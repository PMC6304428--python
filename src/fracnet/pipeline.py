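"""End-to-end pipeline: FD tables (or label volumes) -> networks -> reports.

A YAML/JSON config drives every stage; a manifest records the config,
the seeds, package versions, and a checksum for every output file, so a
rerun from the same config and seed reproduces the outputs bit for bit.
Stages write their results as they finish, so a failure partway leaves
the earlier outputs on disk with a failure record in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import covnet, fd3d, graphmetrics, groupstats, resilience
from .covnet import ThresholdRule
from .network import save_network

log = logging.getLogger("fracnet")

__all__ = ["load_config", "run_pipeline"]

DEFAULTS = {
    "rule_mode": "p_value",
    "alpha": 0.05,
    "density_target": 0.20,
    "sweep_grid": list(groupstats.DEFAULT_SWEEP_GRID),
    "n_perm": 1000,
    "n_random": 100,
    "attack_realizations": 100,
    "lp_convention": "harmonic",
    "metrics": ["global_efficiency", "clustering", "char_path_length",
                "largest_component", "density", "mean_degree"],
    "seed": 0,
    "box_base": 3,
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_group(cfg_group: dict, cfg: dict, base: Path) -> covnet.CohortTable:
    """One input modality per group: either a cohort CSV pair or a list of
    labelled volumes to run FD extraction on."""
    if ("cohort" in cfg_group) == ("volumes" in cfg_group):
        raise ValueError("each group needs exactly one of 'cohort' or 'volumes'")
    if "cohort" in cfg_group:
        return covnet.load_cohort(
            base / cfg_group["cohort"], base / cfg_group["covariates"]
        )
    merge_map = (
        fd3d.read_merge_map(base / cfg["merge_map"]) if cfg.get("merge_map") else None
    )
    columns = {}
    for entry in cfg_group["volumes"]:
        vol = fd3d.load_label_volume(base / entry["path"])
        if merge_map is not None:
            vol = fd3d.merge_regions(vol, merge_map)
        table = fd3d.regional_fd(vol, base=cfg.get("box_base", 3))
        columns[entry["subject"]] = table["fd"]
    values = pd.DataFrame(columns)
    values = values.dropna()
    cov = pd.DataFrame(
        {
            "age": [e["age"] for e in cfg_group["volumes"]],
            "sex": [e["sex"] for e in cfg_group["volumes"]],
        },
        index=[e["subject"] for e in cfg_group["volumes"]],
    )
    return covnet.CohortTable(values, cov)


def run_pipeline(config: dict, out_dir: str | Path, base_dir: str | Path = ".") -> dict:
    """Run every stage of the group comparison and write a report bundle.

    Returns the manifest dict (also written as ``manifest.json``).
    """
    cfg = {**DEFAULTS, **config}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = Path(base_dir)
    manifest: dict = {
        "config": cfg,
        "seed": cfg["seed"],
        "versions": _versions(),
        "outputs": {},
        "stages": [],
    }
    root_seed = np.random.SeedSequence(cfg["seed"])
    stage_seeds = {
        name: int(ss.generate_state(1)[0] % (2**31))
        for name, ss in zip(
            ("random_baseline", "permutation", "nodal", "attack"), root_seed.spawn(4)
        )
    }
    manifest["stage_seeds"] = stage_seeds

    def record(path: Path) -> None:
        manifest["outputs"][str(path.relative_to(out))] = _sha256(path)

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                fn()
                manifest["stages"].append(
                    {"stage": name, "status": "ok",
                     "seconds": round(time.perf_counter() - t0, 3)}
                )
            except Exception as exc:  # keep earlier outputs, record failure
                manifest["stages"].append(
                    {"stage": name, "status": "failed", "error": str(exc)}
                )
                _write_manifest(out, manifest)
                raise
        return wrap

    groups: dict[str, covnet.CohortTable] = {}

    @stage("load")
    def _load():
        for name in ("a", "b"):
            groups[name] = _load_group(cfg[f"group_{name}"], cfg, base)
            covnet.save_cohort(
                groups[name], out / f"cohort_{name}.csv", out / f"covariates_{name}.csv"
            )
            record(out / f"cohort_{name}.csv")
            record(out / f"covariates_{name}.csv")

    rule = ThresholdRule(cfg["rule_mode"], cfg["alpha"], cfg["density_target"])
    nets = {}

    @stage("networks")
    def _networks():
        for name, table in groups.items():
            resid = covnet.residualize(table)
            res = covnet.correlate(resid)
            pd.DataFrame(res.r, index=res.region_names, columns=res.region_names).to_csv(
                out / f"r_{name}.csv"
            )
            pd.DataFrame(res.p, index=res.region_names, columns=res.region_names).to_csv(
                out / f"p_{name}.csv"
            )
            with open(out / f"coefficients_{name}.json", "w") as fh:
                json.dump(covnet.describe_coefficients(res), fh, indent=2)
            net = covnet.threshold(res, rule)
            nets[name] = net
            save_network(net, out / f"network_{name}.csv")
            save_network(net, out / f"network_{name}.graphml")
            for suffix in ("csv", "graphml"):
                record(out / f"network_{name}.{suffix}")
            record(out / f"r_{name}.csv")
            record(out / f"p_{name}.csv")
            record(out / f"coefficients_{name}.json")

    @stage("metrics")
    def _metrics():
        for name, net in nets.items():
            glob = graphmetrics.global_metrics(net, cfg["lp_convention"])
            glob["random_baseline"] = graphmetrics.random_network_baseline(
                net, cfg["n_random"], seed=stage_seeds["random_baseline"],
                lp_convention=cfg["lp_convention"],
            )
            with open(out / f"global_metrics_{name}.json", "w") as fh:
                json.dump(glob, fh, indent=2)
            graphmetrics.nodal_metrics(net).to_csv(out / f"nodal_metrics_{name}.csv")
            record(out / f"global_metrics_{name}.json")
            record(out / f"nodal_metrics_{name}.csv")

    @stage("sweep")
    def _sweep():
        sw = groupstats.sweep(
            groups["a"], groups["b"], cfg["sweep_grid"], cfg["rule_mode"],
            cfg["lp_convention"],
        )
        sw.table.to_csv(out / "sweep.csv", index=False)
        record(out / "sweep.csv")

    @stage("permutation")
    def _permutation():
        results = {}
        for i, metric in enumerate(cfg["metrics"]):
            res = groupstats.permutation_test(
                groups["a"], groups["b"], metric, rule,
                n_perm=cfg["n_perm"], seed=stage_seeds["permutation"] + i,
            )
            results[metric] = {
                "observed_diff": res.observed_diff,
                "critical_value": res.critical_value,
                "significant": res.significant,
                "direction": res.direction,
                "p_value": res.p_value,
                "n_perm": res.n_perm,
            }
            pd.DataFrame({"null_diff": res.null_diffs}).to_csv(
                out / f"null_{metric}.csv", index=False
            )
            record(out / f"null_{metric}.csv")
        with open(out / "permutation.json", "w") as fh:
            json.dump(results, fh, indent=2)
        record(out / "permutation.json")

    @stage("nodal")
    def _nodal():
        top = groupstats.nodal_betweenness_decrease(
            groups["a"], groups["b"], rule,
            n_perm=cfg["n_perm"], seed=stage_seeds["nodal"],
            p_cut=max(0.001, 1.5 / (cfg["n_perm"] + 1)),
        )
        top.to_csv(out / "betweenness_decrease.csv")
        record(out / "betweenness_decrease.csv")

    @stage("attack")
    def _attack():
        frames = []
        for name, net in nets.items():
            for strategy in ("targeted", "random"):
                curve = resilience.attack(
                    net, strategy,
                    n_realizations=cfg["attack_realizations"],
                    seed=stage_seeds["attack"],
                )
                df = curve.to_frame()
                df.insert(0, "group", name)
                frames.append(df)
        pd.concat(frames).to_csv(out / "attack_curves.csv", index=False)
        record(out / "attack_curves.csv")

    _write_manifest(out, manifest)
    return manifest


def _versions() -> dict:
    import networkx
    import scipy

    from . import __version__

    return {
        "fracnet": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "networkx": networkx.__version__,
    }


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
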