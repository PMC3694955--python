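"""Named scenario configurations and end-to-end runners.

Each scenario bundles a gradient set, a genotype and simulation
parameters into a single validated configuration, loaded from the YAML
files shipped under ``retinotopy/data``.  Scenario names follow the
regimes they reproduce: ``fig2_strong_no_counter``,
``fig3_weak_no_counter``, ``fig4_weak_counter``, ``fig5_hom_knockin``,
``fig6_math5``, ``fig7_grid`` and ``tradeoff_sweep``.

``run_scenario`` executes gradients -> simulator -> analysis and returns
(and optionally writes) a report bundle with snapshots, order metrics and
a manifest sufficient to reproduce the run.  ``run_tradeoff_sweep``
explores the countergradient-strength x compensation-decay plane and
summarises which decay minimises the map error at each countergradient
scale.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import (MapEstimate, fit_experimental_map, map_estimate,
                       order_metrics, split_and_score_double_map,
                       synth_experimental_map)
from .genotypes import Genotype, build_genotype_retinal_epha
from .gradients import GradientSet, build_gradient_set
from .simulate import SimConfig, SimResult, run

__all__ = ["Scenario", "list_scenarios", "load_scenario", "run_scenario",
           "run_tradeoff_sweep", "ScenarioReport"]

SCENARIO_NAMES = (
    "fig2_strong_no_counter",
    "fig3_weak_no_counter",
    "fig4_weak_counter",
    "fig5_hom_knockin",
    "fig6_math5",
    "fig7_grid",
    "tradeoff_sweep",
)


def _load_yaml(name: str) -> dict:
    ref = resources.files("retinotopy.data").joinpath(f"{name}.yaml")
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def list_scenarios() -> list[str]:
    return list(SCENARIO_NAMES)


@dataclass(frozen=True)
class Scenario:
    """A complete, validated single-run scenario configuration."""

    name: str
    gradients: GradientSet
    genotype: Genotype
    sim: SimConfig
    retinal_epha_source: str = "gradient"   # "gradient" or "measured"
    description: str = ""
    raw: dict = field(default_factory=dict, compare=False)

    def resolved_gradients(self) -> GradientSet:
        """Gradient set with the per-RGC retinal EphA vector when needed."""
        if self.retinal_epha_source == "measured" or \
                self.genotype.epha3_knockin != "none":
            epha, _ = build_genotype_retinal_epha(self.genotype,
                                                  n_rgc=self.sim.n_rgc)
            return replace(self.gradients, retinal_epha=epha)
        return self.gradients


def _gradient_set_from(spec: dict) -> GradientSet:
    return build_gradient_set(
        spec["retinal_epha"]["height"], spec["retinal_epha"]["rate"],
        spec["retinal_ephrina"]["height"], spec["retinal_ephrina"]["rate"],
        spec["sc_ephrina"]["height"], spec["sc_ephrina"]["rate"],
        spec["sc_epha"]["height"], spec["sc_epha"]["rate"],
    )


def load_scenario(name: str, seed: int = 0,
                  n_steps: Optional[int] = None) -> Scenario:
    """Load and validate a named single-run scenario.

    ``fig7_grid`` and ``tradeoff_sweep`` are multi-run scenarios; use
    :func:`run_scenario` / :func:`run_tradeoff_sweep` on them directly.
    """
    if name not in SCENARIO_NAMES:
        raise ValueError(
            f"unknown scenario {name!r}; choices: {', '.join(SCENARIO_NAMES)}")
    raw = _load_yaml(name)
    if "regimes" in raw or "scales" in raw:
        raise ValueError(f"{name} is a multi-run scenario")
    sim = dict(raw["sim"])
    if n_steps is not None:
        sim["n_steps"] = n_steps
    config = SimConfig(seed=seed, **sim)
    return Scenario(
        name=name,
        gradients=_gradient_set_from(raw["gradients"]),
        genotype=Genotype(**raw["genotype"]),
        sim=config,
        retinal_epha_source=raw.get("retinal_epha_source", "gradient"),
        description=raw.get("description", ""),
        raw=raw,
    )


@dataclass
class ScenarioReport:
    """Result bundle of one scenario run."""

    scenario: Scenario
    result: SimResult
    estimate: MapEstimate
    metrics: dict
    manifest: dict

    def write(self, outdir) -> Path:
        """Write CSV/JSON artefacts under ``outdir`` (fixed layout)."""
        outdir = Path(outdir)
        (outdir / "snapshots").mkdir(parents=True, exist_ok=True)
        res = self.result
        states = dict(res.snapshots)
        states[res.final.step] = res.final
        for step, state in sorted(states.items()):
            pd.DataFrame(state.counts).to_csv(
                outdir / "snapshots" / f"counts_step{step}.csv", index=False)
            pd.DataFrame({"y": res.sc_pos, "density": state.density,
                          "compensation": state.compensation}).to_csv(
                outdir / "snapshots" / f"profiles_step{step}.csv", index=False)
        self.estimate.df.to_csv(outdir / "map.csv", index=False)
        inh = pd.DataFrame(res.molecular)
        inh.insert(0, "rgc_index", res.rgc_index)
        inh.insert(1, "x", res.retinal_pos)
        inh.to_csv(outdir / "inhibition.csv", index=False)
        (outdir / "metrics.json").write_text(json.dumps(self.metrics, indent=2))
        (outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=2))
        return outdir


def _manifest(scenario: Scenario, seed: int) -> dict:
    cfg = {"name": scenario.name, "seed": seed,
           "sim": asdict(scenario.sim),
           "genotype": asdict(scenario.genotype),
           "raw": scenario.raw}
    digest = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()
    return {"config": cfg, "config_sha256": digest, "version": __version__}


def _population_metrics(estimate: MapEstimate) -> dict:
    """Per-population maps and their decile-wise separation (double maps)."""
    out = {}
    if len(estimate.populations) < 2:
        return out
    df = estimate.df
    deciles = np.floor(df["x"] * 10).clip(0, 9).astype(int)
    sep = (df.assign(decile=deciles)
             .groupby(["decile", "population"])["mean_sc"].mean()
             .unstack("population"))
    out["decile_mean_sc"] = {
        str(pop): sep[pop].round(6).tolist() for pop in sep.columns}
    out["ki_rostral_of_wt_all_deciles"] = bool(
        np.all(sep["ki"].to_numpy() < sep["wt"].to_numpy()))
    out["population_separation"] = float(
        (sep["wt"] - sep["ki"]).mean())
    return out


def run_scenario(scenario, seed: int = 0, outdir=None,
                 n_steps: Optional[int] = None):
    """Run a scenario end-to-end; reproducible under ``seed``.

    For single-run scenarios returns a :class:`ScenarioReport`.  For the
    ``fig7_grid`` scenario returns a dict of reports keyed by
    ``(regime, genotype)``.  ``tradeoff_sweep`` has its own runner.
    """
    if isinstance(scenario, str):
        if scenario == "tradeoff_sweep":
            raise ValueError("use run_tradeoff_sweep for the sweep scenario")
        if scenario == "fig7_grid":
            return _run_fig7_grid(seed, outdir, n_steps)
        scenario = load_scenario(scenario, seed=seed, n_steps=n_steps)
    result = run(scenario.sim, scenario.resolved_gradients(),
                 scenario.genotype)
    estimate = map_estimate(result)
    metrics = order_metrics(estimate, density=result.final.density)
    metrics.update(_population_metrics(estimate))
    metrics["accepted_move_rate"] = result.accepted_rate
    report = ScenarioReport(scenario=scenario, result=result,
                            estimate=estimate, metrics=metrics,
                            manifest=_manifest(scenario, seed))
    if outdir is not None:
        report.write(outdir)
    return report


def _run_fig7_grid(seed: int, outdir, n_steps: Optional[int]):
    raw = _load_yaml("fig7_grid")
    base_gradients = _gradient_set_from(raw["gradients"])
    sim = dict(raw["sim"])
    if n_steps is not None:
        sim["n_steps"] = n_steps
    reports = {}
    for regime, rspec in raw["regimes"].items():
        gradients = replace(
            base_gradients,
            retinal_ephrina=base_gradients.retinal_ephrina.scaled(
                rspec["retinal_ephrina_scale"]))
        for gname, gspec in raw["genotypes"].items():
            scen = Scenario(
                name=f"fig7_{regime}_{gname}",
                gradients=gradients,
                genotype=Genotype(**gspec),
                sim=SimConfig(seed=seed, mu=rspec["mu"], **sim),
                retinal_epha_source=raw.get("retinal_epha_source", "gradient"),
                description=raw.get("description", ""),
                raw=raw,
            )
            sub = None if outdir is None else Path(outdir) / regime / gname
            reports[(regime, gname)] = run_scenario(scen, seed=seed,
                                                    outdir=sub)
    return reports


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Independent child seeds below 2**31 derived from ``seed``."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def run_tradeoff_sweep(seed: int = 0, scales=None, mus=None,
                       n_seeds: Optional[int] = None, outdir=None,
                       n_steps: Optional[int] = None):
    """Sweep countergradient scale x compensation decay on wild-type maps.

    Both countergradient heights are scaled relative to the fig4 baseline
    (scale 2 = exactly matched gradients and countergradients).  The map
    error per run is the goodness-of-fit g of the wild-type map against a
    synthetic identity target map.

    Returns ``(table, argmin)``: a tidy DataFrame of per-run errors and a
    DataFrame with, per scale, the decay value minimising the seed-mean
    error.
    """
    raw = _load_yaml("tradeoff_sweep")
    scales = list(raw["scales"] if scales is None else scales)
    mus = list(raw["mus"] if mus is None else mus)
    n_seeds = int(raw["n_seeds"] if n_seeds is None else n_seeds)
    if len(scales) < 2 or len(mus) < 2:
        raise ValueError("need at least a 2 x 2 grid")
    base = load_scenario(raw["base_scenario"])
    sim = dict(raw["sim"])
    if n_steps is not None:
        sim["n_steps"] = n_steps
    tgt = raw["target"]
    map_seed, *run_seeds = _spawn_seeds(seed, 1 + n_seeds)

    target = synth_experimental_map(lambda x: x, tgt["noise_sd"],
                                    tgt["n_points"], seed=map_seed)
    fits = fit_experimental_map(target)

    rows = []
    for scale in scales:
        gradients = base.gradients.with_countergradient_scale(scale)
        for mu in mus:
            for s in run_seeds:
                config = SimConfig(seed=s, mu=mu, **sim)
                result = run(config, gradients, Genotype())
                est = map_estimate(result)
                score = split_and_score_double_map(est, fits)
                metrics = order_metrics(est)
                rows.append({"scale": scale, "mu": mu, "seed": s,
                             "map_error": score.g,
                             "rms_from_identity":
                                 metrics["rms_from_identity"]})
    table = pd.DataFrame(rows)
    cell = table.groupby(["scale", "mu"])["map_error"].agg(["mean", "std"])
    argmin = (cell["mean"].reset_index()
              .loc[lambda d: d.groupby("scale")["mean"].idxmin()]
              .rename(columns={"mu": "best_mu", "mean": "map_error"})
              .reset_index(drop=True))
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "sweep_table.csv", index=False)
        argmin.to_csv(outdir / "sweep_argmin.csv", index=False)
        (outdir / "manifest.json").write_text(json.dumps(
            {"seed": seed, "scales": scales, "mus": mus, "n_seeds": n_seeds,
             "sim": sim, "version": __version__}, indent=2))
    return table, argmin
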