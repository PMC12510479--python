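"""Staged pipeline: simulate → load → networks → nbda → decompose → sidechoice → report.

Configuration is a YAML mapping with every behavioural window and
threshold exposed under named keys (defaults below); a single global seed
governs all stochastic components.  Each stage writes CSV/JSON outputs to
the run directory and records them — with row counts and content hashes —
in a :class:`RunManifest`, so reruns with the same config and seed produce
identical numeric outputs.
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

from tadanet import __version__, events as ev, networks as nw, regressions as rg
from tadanet import synthetic as syn
from tadanet.networks import LAYERS
from tadanet.nbda import (
    DiffusionData,
    build_diffusion_data,
    enumerate_model_set,
    fit_model_set,
    model_averaged_median,
    pathway_decomposition,
    percent_st,
    profile_ci,
    summed_support,
)
from tadanet.nbda.decompose import pathway_class_summary
from tadanet.nbda.modelset import akaike_weights

logger = logging.getLogger(__name__)

STAGES = ("simulate", "load", "networks", "nbda", "decompose", "sidechoice", "report")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "scenario": {},  # ScenarioConfig overrides
    "windows": {
        "network_days": 7.0,
        "presence_days": 7.0,
        "scrounge_s": 2.0,
        "social_s": 300.0,
        "personal_s": 3600.0,
        "dependence_days": 15.0,
    },
    "thresholds": {
        "knowledgeable_solves": 10,
        "acquisition_solve": 3,
        "min_registrations": 10,
        "min_site_events": 3,
        "parental_strategy_cutoff": 0.9,
        "support_cutoff": 0.5,
    },
    "nbda": {
        "baselines": ["constant", "weibull"],
        "n_ilvs": 2,
        "n_starts": 3,
        "k_max": 10,
        "profile_level": 0.95,
    },
}


def load_config(source) -> dict:
    """Merge a YAML path / mapping over the defaults (two-level merge)."""
    if source is None:
        user = {}
    elif isinstance(source, dict):
        user = source
    else:
        if not os.path.exists(source):
            raise FileNotFoundError(f"config file not found: {source}")
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for k, v in user.items():
        if k not in cfg and k != "seed":
            raise ValueError(f"unknown config key {k!r}")
        if isinstance(v, dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str = __version__
    stages: list = field(default_factory=list)

    def record(self, stage: str, status: str, outputs: dict[str, str]) -> None:
        entry = {"stage": stage, "status": status, "outputs": []}
        for name, path in outputs.items():
            info = {"name": name, "path": path}
            if os.path.exists(path):
                with open(path, "rb") as fh:
                    data = fh.read()
                info["sha256"] = hashlib.sha256(data).hexdigest()[:16]
                info["rows"] = max(data.count(b"\n") - 1, 0)
            self.outputs_of(stage)  # no-op; keeps record append-only
            entry["outputs"].append(info)
        self.stages.append(entry)

    def outputs_of(self, stage: str) -> list:
        return [e for e in self.stages if e["stage"] == stage]

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


class PipelineState:
    """In-memory hand-off between stages within one invocation."""

    def __init__(self, cfg: dict, outdir: str):
        self.cfg = cfg
        self.outdir = outdir
        os.makedirs(outdir, exist_ok=True)
        self.population = None
        self.sim = None
        self.registry = None
        self.detections = None
        self.puzzle = None
        self.knowledge = None
        self.diffusion: DiffusionData | None = None
        self.fits = None
        self.best_fit = None
        self.chosen_baseline = None

    def path(self, name: str) -> str:
        return os.path.join(self.outdir, name)


def _scenario_config(cfg: dict) -> syn.ScenarioConfig:
    return syn.ScenarioConfig(seed=int(cfg["seed"]), **cfg["scenario"])


def stage_simulate(state: PipelineState) -> dict[str, str]:
    config = _scenario_config(state.cfg)
    pop, detections, sim, puzzle = syn.generate_scenario(config)
    state.population, state.sim = pop, sim
    paths = syn.write_scenario_csvs(pop, detections, puzzle, state.outdir)
    truth = state.path("ground_truth_events.csv")
    sim.events.to_csv(truth, index=False)
    paths["ground_truth"] = truth
    return paths


def stage_load(state: PipelineState) -> dict[str, str]:
    paths = {
        "pedigree": state.path("pedigree.csv"),
        "detections": state.path("detections.csv"),
        "puzzle": state.path("puzzle_events.csv"),
    }
    for p in paths.values():
        if not os.path.exists(p):
            raise FileNotFoundError(f"missing input file: {p}")
    registry, detections, puzzle = ev.load_event_tables(paths)
    th = state.cfg["thresholds"]
    knowledge = ev.knowledge_states(
        puzzle,
        registry,
        diffusion_start=0.0,
        knowledgeable_solves=th["knowledgeable_solves"],
        acquisition_solve=th["acquisition_solve"],
    )
    scrounges = ev.derive_scrounges(puzzle, window_s=state.cfg["windows"]["scrounge_s"])
    state.registry, state.detections, state.puzzle = registry, detections, puzzle
    state.knowledge = knowledge
    out = {
        "knowledge_states": state.path("knowledge_states.csv"),
        "scrounges": state.path("scrounges.csv"),
    }
    knowledge.to_csv(out["knowledge_states"], index=False)
    scrounges.to_csv(out["scrounges"], index=False)
    return out


def _require_streams(state: PipelineState) -> None:
    if state.registry is None:
        stage_load(state)


def _build_diffusion(state: PipelineState) -> DiffusionData:
    if state.diffusion is None:
        _require_streams(state)
        w, th, nb = state.cfg["windows"], state.cfg["thresholds"], state.cfg["nbda"]
        state.diffusion = build_diffusion_data(
            state.detections,
            state.puzzle,
            state.registry,
            diffusion_start=0.0,
            window_days=w["network_days"],
            min_registrations=th["min_registrations"],
            k_max=nb["k_max"],
            min_site_events=th["min_site_events"],
            seed=int(state.cfg["seed"]),
        )
    return state.diffusion


def stage_networks(state: PipelineState) -> dict[str, str]:
    _require_streams(state)
    from tadanet.nbda.data import acquisition_events

    acq = acquisition_events(state.knowledge, state.puzzle, diffusion_start=0.0)
    w, th = state.cfg["windows"], state.cfg["thresholds"]
    feeders = state.detections[state.detections["source"] == "network_feeder"]
    counts = feeders["bird_id"].value_counts()
    included = [
        b for b in state.registry.bird_ids
        if counts.get(b, 0) >= th["min_registrations"]
    ]
    gatherings = (
        nw.gathering_events_in_window(
            feeders[feeders["bird_id"].isin(included)],
            float(feeders["timestamp"].min()),
            float(feeders["timestamp"].max()),
            k_max=state.cfg["nbda"]["k_max"],
            seed=int(state.cfg["seed"]),
        )
        if not feeders.empty
        else []
    )
    edges = []
    for r in acq.itertuples(index=False):
        net = nw.dynamic_network(
            state.detections,
            state.registry,
            r.timestamp,
            window_days=w["network_days"],
            min_registrations=th["min_registrations"],
            k_max=state.cfg["nbda"]["k_max"],
            seed=int(state.cfg["seed"]),
            gatherings=gatherings,
        )
        el = net.to_edgelist()
        el.insert(0, "event_time", r.timestamp)
        el.insert(0, "learner_id", r.learner_id)
        edges.append(el)
    pres = nw.presence_matrix(
        state.detections, state.puzzle, acq, state.registry,
        lookback_days=w["presence_days"],
    )
    out = {
        "acquisition_events": state.path("acquisition_events.csv"),
        "network_edges": state.path("network_edges.csv"),
        "presence": state.path("presence_matrix.csv"),
    }
    acq.to_csv(out["acquisition_events"], index=False)
    pd.concat(edges, ignore_index=True).to_csv(out["network_edges"], index=False)
    pres.to_csv(out["presence"])
    return out


def stage_nbda(state: PipelineState) -> dict[str, str]:
    data = _build_diffusion(state)
    nb = state.cfg["nbda"]
    all_fits, tables = [], []
    for baseline in nb["baselines"]:
        specs = enumerate_model_set(LAYERS, nb["n_ilvs"], baseline)
        fits, table = fit_model_set(
            data, specs, n_starts=nb["n_starts"], seed=int(state.cfg["seed"])
        )
        all_fits.extend(fits)
        tables.append(table)
    # baseline families compared by summed weight over the union
    aicc_all = np.array([f.aicc for f in all_fits])
    w_all = akaike_weights(aicc_all)
    baseline_support = {
        b: float(sum(w for f, w in zip(all_fits, w_all) if f.spec.baseline == b))
        for b in nb["baselines"]
    }
    chosen = max(baseline_support, key=baseline_support.get)
    family = [f for f in all_fits if f.spec.baseline == chosen]
    w_family = akaike_weights([f.aicc for f in family])
    for f, wi in zip(family, w_family):
        f.akaike_weight = float(wi)
    specs = [f.spec for f in family]
    supports = {l: summed_support(specs, w_family, l) for l in LAYERS}
    supports["social"] = summed_support(specs, w_family, "social")
    for i in range(min(nb["n_ilvs"], len(data.ilv_names))):
        name = data.ilv_names[i]
        supports[f"{name}_asocial"] = summed_support(specs, w_family, "ilv_asocial", i)
        supports[f"{name}_social"] = summed_support(specs, w_family, "ilv_social", i)
    state.fits = family
    state.chosen_baseline = chosen
    state.best_fit = family[int(np.argmin([f.aicc for f in family]))]
    out = {
        "model_table": state.path("model_table.csv"),
        "supports": state.path("supports.json"),
        "best_model": state.path("best_model.json"),
    }
    pd.concat(tables, ignore_index=True).sort_values("AICc").to_csv(
        out["model_table"], index=False
    )
    with open(out["supports"], "w") as fh:
        json.dump(
            {
                "baseline_support": baseline_support,
                "chosen_baseline": chosen,
                "summed_support": supports,
                "n_events": data.n_events,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    bf = state.best_fit
    with open(out["best_model"], "w") as fh:
        json.dump(
            {
                "model": bf.spec.label(),
                "networks": list(bf.spec.networks),
                "ilv_placement": list(bf.spec.ilv_placement),
                "baseline": bf.spec.baseline,
                "free": list(map(float, bf.free)),
                "params": {k: float(v) for k, v in bf.param_dict(data.ilv_names).items()},
                "loglik": bf.loglik,
                "AICc": bf.aicc,
                "weight": bf.akaike_weight,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    return out


def stage_decompose(state: PipelineState) -> dict[str, str]:
    if state.best_fit is None:
        if not os.path.exists(state.path("best_model.json")):
            raise FileNotFoundError(
                "decompose requires a prior nbda stage (best_model.json not found)"
            )
        stage_nbda(state)
    data = _build_diffusion(state)
    fit = state.best_fit
    table = pathway_decomposition(data, fit)
    pct = percent_st(table)
    cls = pathway_class_summary(table)
    # profile CIs for the social rates of the best model
    cis = {}
    for layer in fit.spec.networks:
        ci = profile_ci(
            data, fit.spec, fit, f"s_{layer}",
            level=state.cfg["nbda"]["profile_level"], ilv_names=data.ilv_names,
        )
        cis[f"s_{layer}"] = {
            "lower": float(ci.lower),
            "upper": None if ci.upper_open else float(ci.upper),
            "upper_open": ci.upper_open,
        }
    # model-averaged medians for components with summed support > cutoff
    specs = [f.spec for f in state.fits]
    weights = [f.akaike_weight for f in state.fits]
    cutoff = state.cfg["thresholds"]["support_cutoff"]
    averaged = {}
    for layer in LAYERS:
        if summed_support(specs, weights, layer) > cutoff:
            vals = {
                m: f.param_dict(data.ilv_names).get(f"s_{layer}")
                for m, f in enumerate(state.fits)
            }
            averaged[f"s_{layer}"] = model_averaged_median(specs, weights, vals, layer)
    out = {
        "pathway_table": state.path("pathway_table.csv"),
        "percent_st": state.path("percent_st.csv"),
        "pathway_by_class": state.path("pathway_by_class.csv"),
        "profile_cis": state.path("profile_cis.json"),
    }
    table.to_csv(out["pathway_table"], index=False)
    pct.rename("percent").to_csv(out["percent_st"])
    cls.to_csv(out["pathway_by_class"], index=False)
    with open(out["profile_cis"], "w") as fh:
        json.dump(
            {"profile_cis": cis, "model_averaged_medians": averaged},
            fh, indent=2, sort_keys=True,
        )
    return out


def stage_sidechoice(state: PipelineState) -> dict[str, str]:
    _require_streams(state)
    w = state.cfg["windows"]
    exposure = rg.build_exposure_records(
        state.puzzle, state.registry, state.knowledge,
        dependence_days=w["dependence_days"],
    )
    records = rg.build_side_choice_records(
        state.puzzle, state.registry,
        social_window_s=w["social_s"], personal_window_s=w["personal_s"],
    )
    out = {
        "exposure_records": state.path("exposure_records.csv"),
        "side_choice_records": state.path("side_choice_records.csv"),
        "exposure_model": state.path("exposure_model.csv"),
    }
    exposure.to_csv(out["exposure_records"], index=False)
    records.to_csv(out["side_choice_records"], index=False)
    rg.fit_exposure_model(exposure).to_csv(out["exposure_model"], index=False)
    for model in rg.SIDE_CHOICE_MODELS:
        res = rg.fit_side_choice_models(records, model, exposure=exposure)
        p = state.path(f"side_choice_{model}.csv")
        res.to_csv(p, index=False)
        out[f"side_choice_{model}"] = p
    return out


def stage_report(state: PipelineState) -> dict[str, str]:
    """Aggregate existing stage outputs into one JSON report (no recomputation)."""
    report: dict = {"version": __version__, "seed": int(state.cfg["seed"])}
    for name in (
        "supports.json",
        "best_model.json",
        "profile_cis.json",
    ):
        p = state.path(name)
        if os.path.exists(p):
            with open(p) as fh:
                report[name.removesuffix(".json")] = json.load(fh)
    for name in ("percent_st.csv", "exposure_model.csv"):
        p = state.path(name)
        if os.path.exists(p):
            report[name.removesuffix(".csv")] = pd.read_csv(p).to_dict("records")
    out = {"report": state.path("report.json")}
    with open(out["report"], "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return out


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "load": stage_load,
    "networks": stage_networks,
    "nbda": stage_nbda,
    "decompose": stage_decompose,
    "sidechoice": stage_sidechoice,
    "report": stage_report,
}


def run_pipeline(
    config=None,
    outdir: str = "tadanet_run",
    seed: int | None = None,
    stages: list[str] | None = None,
) -> RunManifest:
    """Run the requested stages (default: all) and write the manifest."""
    cfg = load_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    stages = list(stages) if stages else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    state = PipelineState(cfg, outdir)
    manifest = RunManifest(config_hash=config_hash(cfg), seed=int(cfg["seed"]))
    for stage in STAGES:
        if stage not in stages:
            continue
        t0 = time.time()
        try:
            outputs = STAGE_FUNCS[stage](state)
        except Exception:
            manifest.record(stage, "failed", {})
            manifest.write(state.path("manifest.json"))
            raise
        logger.info("stage %s done in %.1f s", stage, time.time() - t0)
        manifest.record(stage, "ok", outputs)
    manifest.write(state.path("manifest.json"))
    return manifest
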