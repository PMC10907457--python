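"""Pipeline orchestration: simulate/load → profile → domains → networks →
metrics → effects, driven by one validated config, with a run manifest.

Every stage writes its tables under the output directory; the manifest
records the config hash, seed, package version and per-stage row counts
so a run is auditable and re-runnable.  Identical config + seed produces
byte-identical outputs (no timestamps enter any artifact).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .battery import (BatterySpec, TrialDataset, compute_contrasts, default_battery,
                      load_trial, orient_scores, write_trial)
from .deficits import NormTable, deviance_rate, zscore_vs_norms
from .domains import DomainExtractor
from .effects import effect_table
from .metrics import global_metrics_table, hubness_table, select_top_hubs
from .networks import NetworkBuilder
from .simulate import SimConfig, generate_norms, generate_trial

log = logging.getLogger("neurocognet")


class SimulateBlock(BaseModel):
    seed: Optional[int] = None  # falls back to RunConfig.seed
    n_placebo: int = 41
    n_active: int = 42
    effect_mean: dict[str, float] = Field(default_factory=dict)
    effect_network: float = 1.0
    test_retest_r: float = 0.7
    missing_rate: float = 0.01


class RunConfig(BaseModel):
    """Validated pipeline configuration (JSON on disk)."""

    input_csv: Optional[str] = None
    norms_csv: Optional[str] = None
    simulate: Optional[SimulateBlock] = None
    battery_spec: Optional[str] = None  # path to a BatterySpec JSON; default battery if absent
    alpha: float = 0.05
    density: float = 0.20
    cutoff: float = -1.0
    hub_fraction: float = 0.20
    n_random: int = 20
    variance_target: float = 0.70
    n_components: Optional[int] = None
    seed: int = 0
    outdir: str = "neurocognet_out"
    verbosity: int = 1

    @model_validator(mode="after")
    def _validate(self) -> "RunConfig":
        if (self.input_csv is None) == (self.simulate is None):
            raise ValueError("exactly one of input_csv / simulate must be given")
        if not (0.0 < self.density <= 1.0):
            raise ValueError("density must be in (0, 1]")
        if not (0.0 < self.hub_fraction <= 1.0):
            raise ValueError("hub_fraction must be in (0, 1]")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.battery_spec is not None and not Path(self.battery_spec).exists():
            raise ValueError(f"battery spec path does not exist: {self.battery_spec}")
        return self


def validate_config(path: Union[str, Path]) -> RunConfig:
    """Parse + schema-validate a JSON config file; raises on failure."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"unparseable config {path}: line {exc.lineno} col {exc.colno}: {exc.msg}")
    return RunConfig.model_validate(payload)


def _config_hash(config: RunConfig) -> str:
    # hash the scientific configuration only, not where it is written
    canonical = json.dumps(config.model_dump(exclude={"outdir", "verbosity"}), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, manifest: dict, stage: str) -> None:
    df.to_csv(path, index=False, float_format="%.10g")
    manifest["tables"][path.name] = {"stage": stage, "rows": int(len(df))}


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order; returns the manifest dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    spec = BatterySpec.from_json(config.battery_spec) if config.battery_spec else default_battery()
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "tables": {},
        "warnings": [],
    }
    caught: list[str] = []

    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")

        # -- stage 1: data --------------------------------------------------
        if config.simulate is not None:
            sim = SimConfig(
                seed=config.simulate.seed if config.simulate.seed is not None else config.seed,
                n_placebo=config.simulate.n_placebo,
                n_active=config.simulate.n_active,
                effect_mean=dict(config.simulate.effect_mean),
                effect_network=config.simulate.effect_network,
                test_retest_r=config.simulate.test_retest_r,
                missing_rate=config.simulate.missing_rate,
            )
            data, truth = generate_trial(sim, spec)
            norms = generate_norms(sim, spec)
            write_trial(data, out / "trial.csv")
            manifest["tables"]["trial.csv"] = {"stage": "simulate", "rows": int(len(data.scores))}
            norms.to_csv(out / "norms.csv")
            manifest["tables"]["norms.csv"] = {"stage": "simulate", "rows": int(len(norms.table))}
            (out / "ground_truth.json").write_text(json.dumps({
                "effect_mean": truth.effect_mean,
                "effect_network": truth.effect_network,
                "domains": truth.domain_names,
            }, indent=2))
        else:
            data = load_trial(config.input_csv, spec)
            norms = NormTable.from_csv(config.norms_csv) if config.norms_csv else None

        oriented = orient_scores(data, spec)
        full = compute_contrasts(oriented, spec)

        # -- stage 2: deficit profile --------------------------------------
        if norms is not None:
            z = zscore_vs_norms(oriented, norms, spec)
            profile = deviance_rate(z, cutoff=config.cutoff)
            _write(profile, out / "deficit_profile.csv", manifest, "profile")

        # -- stage 3: domains ----------------------------------------------
        base = full.timepoint("baseline")
        extractor = DomainExtractor(
            n_components=config.n_components, variance_target=config.variance_target
        ).fit(base)
        loadings = extractor.loadings_.reset_index(names="variable")
        _write(loadings, out / "domain_loadings.csv", manifest, "domains")
        var_df = pd.DataFrame({
            "component": extractor.variance_explained_.index,
            "variance_explained": extractor.variance_explained_.to_numpy(),
            "cumulative": extractor.cumulative_variance_.to_numpy(),
        })
        _write(var_df, out / "domain_variance.csv", manifest, "domains")
        domain_scores = extractor.score_frame(full)
        _write(domain_scores, out / "domain_scores.csv", manifest, "domains")

        # -- stage 4: networks ----------------------------------------------
        builder = NetworkBuilder(alpha=config.alpha, density=config.density).fit(base)
        networks = builder.build_networks(full)
        skel = builder.skeleton_.to_frame().reset_index(names="variable")
        _write(skel, out / "skeleton.csv", manifest, "networks")
        edges = pd.concat([n.edge_frame() for n in networks], ignore_index=True)
        _write(edges, out / "network_edges.csv", manifest, "networks")
        gml_dir = out / "networks"
        gml_dir.mkdir(exist_ok=True)
        import networkx as nx
        for net in networks:
            nx.write_graphml(net.to_graph(), gml_dir / f"{net.participant_id}_{net.timepoint}.graphml")

        # -- stage 5: metrics -----------------------------------------------
        gm = global_metrics_table(networks, n_random=config.n_random, seed=config.seed)
        _write(gm, out / "global_metrics.csv", manifest, "metrics")
        hub = hubness_table(networks)
        _write(hub, out / "hubness.csv", manifest, "metrics")
        top = select_top_hubs(hub[hub["timepoint"] == "baseline"], fraction=config.hub_fraction)
        (out / "top_hubs.json").write_text(json.dumps(top, indent=2))

        # -- stage 6: effects -----------------------------------------------
        demo = data.demographics
        dom_idx = domain_scores.set_index(["id", "timepoint"]).drop(columns=[], errors="ignore")
        dom_effects = effect_table(dom_idx, demo)
        _write(dom_effects, out / "domain_effects.csv", manifest, "effects")

        gm_idx = gm.rename(columns={"participant": "id"}).set_index(["id", "timepoint"])
        net_effects = effect_table(gm_idx, demo)
        hub_wide = hub[hub["variable"].isin(top)].pivot_table(
            index=["participant", "timepoint"], columns="variable", values="hubness"
        )
        hub_wide.index = hub_wide.index.set_names(["id", "timepoint"])
        hub_effects = effect_table(hub_wide, demo)
        _write(pd.concat([net_effects, hub_effects], ignore_index=True),
               out / "network_effects.csv", manifest, "effects")

        caught = sorted({str(w.message) for w in wrec})

    manifest["warnings"] = caught
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
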