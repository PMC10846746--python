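"""Config-driven pipeline: simulate -> fit -> graphs -> recommend -> evaluate.

Every stage writes its artifacts under the configured output directory and
records them in a manifest with the stage name, seed and a hash of the
configuration, so a rerun with an identical config reproduces every
stochastic stage draw for draw.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import cohort as cohort_mod
from .evaluate import compare_variants, cross_validate, make_folds
from .graph import NormalRanges, build_graph
from .io import save_posterior
from .model import ModelSpec, SamplerConfig, fit
from .recommend import RecommendationQuery, recommend

log = logging.getLogger("renalrec")

__all__ = ["RunConfig", "run_pipeline", "config_hash"]

DEFAULTS = {
    "output_dir": "renalrec_out",
    "seed": 0,
    "stages": ["simulate", "fit", "graphs", "recommend"],
    "cohort": {"preset": "default", "path": None},
    "model": {"variant": "two_level", "priors": {}},
    "sampler": {"chains": 4, "draws": 3000, "warmup": 1000,
                "max_treedepth": 8, "target_accept": 0.8},
    "recommendation": {"confidence": 0.9, "samples": 10000,
                       "l_x": 0.5, "l_beta": 0.5, "patients": None},
    "ranges": {"source": None, "age": None},
    "crossval": {"folds": 10},
    "compare": {"variants": ["two_level", "single_level"]},
}


class RunConfig(dict):
    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw):
        cfg = cls()
        for key, val in DEFAULTS.items():
            if isinstance(val, dict):
                merged = dict(val)
                merged.update(raw.get(key, {}) or {})
                cfg[key] = merged
            else:
                cfg[key] = raw.get(key, val)
        return cfg


def config_hash(cfg) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: RunConfig):
    """Execute the requested stages in order; returns the artifact manifest.
    A stage failure raises with the failing stage named; artifacts written by
    earlier stages remain on disk."""
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    h = config_hash(cfg)
    manifest = {"config_hash": h, "seed": seed, "artifacts": []}

    def record(stage, path):
        manifest["artifacts"].append(
            {"stage": stage, "path": str(path), "seed": seed,
             "config_hash": h})

    data = post = None
    try:
        for stage in cfg["stages"]:
            log.info("stage %s", stage)
            if stage == "simulate":
                preset = cfg["cohort"].get("preset", "default")
                maker = (cohort_mod.default_config if preset == "default"
                         else cohort_mod.toy_config)
                config = maker(seed=seed)
                data, truth = cohort_mod.generate_cohort(config)
                path = out / "cohort.csv"
                cohort_mod.write_cohort(data, path, truth=truth, config=config)
                record(stage, path)
            elif stage == "fit":
                if data is None:
                    data = cohort_mod.read_cohort(cfg["cohort"]["path"]
                                                  or out / "cohort.csv")
                spec = ModelSpec(variant=cfg["model"]["variant"],
                                 priors=cfg["model"].get("priors", {}))
                sc = cfg["sampler"]
                sampler = SamplerConfig(
                    chains=sc["chains"], draws=sc["draws"],
                    warmup=sc["warmup"], max_treedepth=sc["max_treedepth"],
                    target_accept=sc["target_accept"], seed=seed)
                post = fit(data, spec, sampler)
                path = out / "posterior.npz"
                save_posterior(post, path)
                post.diagnostics.to_csv(out / "diagnostics.csv", index=False)
                record(stage, path)
                record(stage, out / "diagnostics.csv")
            elif stage in ("graphs", "recommend"):
                if post is None or data is None:
                    raise RuntimeError("fit stage required first")
                rcfg = cfg["recommendation"]
                ranges = (NormalRanges.from_yaml(cfg["ranges"]["source"],
                                                 cfg["ranges"].get("age"))
                          if cfg["ranges"]["source"]
                          else NormalRanges.for_age(cfg["ranges"].get("age")))
                patients = rcfg.get("patients") or data.patients.tolist()
                results = {}
                for k in patients:
                    graph = build_graph(post, data, k, ranges)
                    if stage == "graphs":
                        gpath = out / f"graph_patient{k}.json"
                        with open(gpath, "w") as fh:
                            json.dump(graph.to_json_dict(), fh, indent=1)
                        record(stage, gpath)
                    else:
                        queried = [q for q in
                                   ("potassium_mg", "phosphorus_mg")
                                   if q in data.predictor_names]
                        if not queried:  # toy cohorts: first two predictors
                            queried = data.predictor_names[:2]
                        query = RecommendationQuery(
                            queried=queried,
                            proposal_bounds={
                                q: (0.0, 5800.0) if "potassium" in q
                                else (0.0, 2550.0) if "phosphorus" in q
                                else (0.0, float(np.nanmax(
                                    data.df[q].to_numpy()) * 2 + 1))
                                for q in queried},
                            S=rcfg["samples"], conf_level=rcfg["confidence"],
                            l_x=rcfg["l_x"], l_beta=rcfg["l_beta"],
                            seed=seed + int(k))
                        res = recommend(graph, query)
                        results[int(k)] = {
                            "queried": res.queried,
                            "q_min": _nanlist(res.q_min),
                            "q_max": _nanlist(res.q_max),
                            "mu_q0": res.mu_q0.tolist(),
                            "p_m_max": res.p_m_max.tolist(),
                            "p_max": res.p_max,
                            "reachable": {
                                r: bool(res.p_m_max[m] > rcfg["confidence"])
                                for m, r in enumerate(post.response_names)},
                            "succeeded": bool(res.succeeded),
                        }
                if stage == "recommend":
                    rpath = out / "recommendations.json"
                    with open(rpath, "w") as fh:
                        json.dump(results, fh, indent=1)
                    record(stage, rpath)
            elif stage == "crossval":
                if data is None:
                    data = cohort_mod.read_cohort(cfg["cohort"]["path"]
                                                  or out / "cohort.csv")
                sc = cfg["sampler"]
                sampler = SamplerConfig(
                    chains=sc["chains"], draws=sc["draws"],
                    warmup=sc["warmup"], seed=seed)
                folds = make_folds(data, cfg["crossval"]["folds"], seed)
                rep_in, rep_cv = cross_validate(
                    data, ModelSpec(variant=cfg["model"]["variant"]),
                    folds, sampler)
                path = out / "crossval.csv"
                import pandas as pd
                combined = pd.concat([
                    rep_in.per_km.assign(kind="in_sample"),
                    rep_cv.per_km.assign(kind="cv")], ignore_index=True)
                combined.to_csv(path, index=False)
                record(stage, path)
            elif stage == "compare":
                if data is None:
                    data = cohort_mod.read_cohort(cfg["cohort"]["path"]
                                                  or out / "cohort.csv")
                sc = cfg["sampler"]
                sampler = SamplerConfig(chains=sc["chains"], draws=sc["draws"],
                                        warmup=sc["warmup"], seed=seed)
                table, _ = compare_variants(data, cfg["compare"]["variants"],
                                            sampler)
                path = out / "variant_comparison.csv"
                table.to_csv(path, index=False)
                record(stage, path)
            else:
                raise ValueError(f"unknown stage '{stage}'")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _nanlist(a):
    return [None if np.isnan(v) else float(v) for v in np.asarray(a, float)]
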