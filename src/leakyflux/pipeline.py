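"""End-to-end analysis: correct -> fit -> profile -> Monte Carlo -> report.

The run configuration is a YAML file::

    seed: 7
    model: fixture:central_carbon     # or a path to a model file
    step_min: 6.0
    output: results/
    datasets:
      FM: {measurements: fm.csv, preset: FM}
      EM: {measurements: em.csv, preset: EM}
    fit:
      n_starts: 6
      profile: ["u_LACX[FM]", "u_LACX[EM]"]
      monte_carlo: 0                  # replicates; 0 skips the stage

Every stage's tabular output is written to the output directory so it
can be reloaded as the next stage's input; the JSON report embeds the
seed, a hash of the configuration and the package version.  Seeds are
mandatory — there is no wall-clock seeding.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .flux_fit import (
    CHI2_95_1DOF,
    estimate,
    monte_carlo_errors,
    profile_ci,
)
from .fluxes import u_to_ratio
from .measurement_model import MeasurementSet, correct_measurement_set
from .network_model import load_model
from .synthetic_data import build_fit_problem, load_fixture_model

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger("leakyflux")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending record."""


class RunConfig:
    """Validated run configuration."""

    def __init__(self, raw: dict, root: Path):
        self.raw = raw
        self.root = root
        try:
            self.seed = int(raw["seed"])
        except KeyError:
            raise PipelineError("config: a seed is mandatory") from None
        self.model_ref = raw.get("model", "fixture:central_carbon")
        self.step_min = float(raw.get("step_min", 6.0))
        self.output = root / raw.get("output", "leakyflux_out")
        self.datasets = {}
        for name, spec in raw.get("datasets", {}).items():
            path = root / spec["measurements"]
            if not path.exists():
                raise PipelineError(
                    f"config: dataset {name}: missing measurement file {path}"
                )
            self.datasets[name] = {"path": path, "preset": spec.get("preset", name)}
        if not self.datasets:
            raise PipelineError("config: at least one dataset is required")
        fit = raw.get("fit", {})
        self.n_starts = int(fit.get("n_starts", 6))
        self.profile = list(fit.get("profile", []))
        self.monte_carlo = int(fit.get("monte_carlo", 0))
        self.threshold = float(fit.get("threshold", CHI2_95_1DOF))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(raw, path.parent)

    @property
    def config_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def load_network(self):
        if self.model_ref.startswith("fixture:"):
            return load_fixture_model(self.model_ref.split(":", 1)[1])
        return load_model(self.root / self.model_ref)


def run_pipeline(config: RunConfig | str | Path,
                 stages: tuple[str, ...] = ("fit", "profile", "montecarlo")) -> dict:
    """Execute the pipeline and return (and write) the report dictionary."""
    if not isinstance(config, RunConfig):
        config = RunConfig.from_yaml(config)
    out = config.output
    out.mkdir(parents=True, exist_ok=True)

    # stage: load + correct measurements
    measurements = {}
    for name, spec in config.datasets.items():
        try:
            ms = MeasurementSet.from_csv(spec["path"], label=name)
            ms = correct_measurement_set(ms)
        except Exception as exc:
            raise PipelineError(f"stage correct: dataset {name}: {exc}") from exc
        measurements[spec["preset"]] = ms
        ms.to_csv(out / f"corrected_{name}.csv")

    try:
        problem = build_fit_problem(
            measurements, model=config.load_network(), step_min=config.step_min
        )
    except Exception as exc:
        raise PipelineError(f"stage setup: {exc}") from exc

    report = {
        "package": "leakyflux",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash,
        "step_min": config.step_min,
        "datasets": sorted(measurements),
    }

    result = None
    if "fit" in stages:
        log.info("fitting %d parameters", len(problem.param_names))
        try:
            result = estimate(problem, n_starts=config.n_starts, seed=config.seed)
        except Exception as exc:
            raise PipelineError(f"stage fit: {exc}") from exc
        report["fit"] = {
            "parameters": {k: float(v) for k, v in result.params.items()},
            "ssr": result.ssr,
            "per_dataset_ssr": result.per_dataset_ssr,
            "n_starts": result.n_starts,
            "weakly_identified": result.weakly_identified,
        }
        ratios = {
            name: u_to_ratio(min(v, 0.9999))
            for name, v in result.params.items()
            if name.split("[")[0].startswith("u_")
        }
        report["fit"]["reversibility_ratios"] = ratios
        log.info("SSR %.3f", result.ssr)
        _write_tables(problem, result, out)

    if "profile" in stages and config.profile and result is not None:
        cis = {}
        for name in config.profile:
            try:
                ci = profile_ci(problem, result, name, threshold=config.threshold)
            except Exception as exc:
                raise PipelineError(f"stage profile: parameter {name}: {exc}") from exc
            entry = {
                "estimate": ci.estimate, "lower": ci.lower, "upper": ci.upper,
                "upper_unbounded": ci.upper_unbounded,
                "lower_at_bound": ci.lower_at_bound,
            }
            if name.split("[")[0].startswith("u_"):
                r = ci.to_ratio()
                entry["ratio"] = {
                    "estimate": r.estimate, "lower": r.lower,
                    "upper": None if r.upper_unbounded else r.upper,
                }
            cis[name] = entry
        report["profile"] = cis

    if "montecarlo" in stages and config.monte_carlo and result is not None:
        try:
            mc = monte_carlo_errors(problem, result, n=config.monte_carlo,
                                    seed=config.seed)
        except Exception as exc:
            raise PipelineError(f"stage montecarlo: {exc}") from exc
        report["monte_carlo"] = {
            "n": mc.n_requested,
            "n_failed": mc.n_failed,
            "standard_errors": mc.standard_errors,
        }
        mc.replicates.to_csv(out / "monte_carlo_replicates.csv", index=False)

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _write_tables(problem, result, out: Path) -> None:
    import pandas as pd

    pd.DataFrame(
        {"parameter": result.names, "estimate": result.x}
    ).to_csv(out / "estimates.csv", index=False)
    res = problem.residuals(result.x)
    rows = []
    pos = 0
    for ds, align in zip(problem.datasets, problem._align):
        for (t_idx, met, kind, k, value, sigma) in align:
            rows.append({
                "dataset": ds.name,
                "time_min": ds.config.record_times[t_idx],
                "metabolite": met,
                "quantity": "conc" if kind == "conc" else f"M{k}",
                "observed": value, "sigma": sigma,
                "weighted_residual": res[pos],
            })
            pos += 1
    pd.DataFrame(rows).to_csv(out / "residuals.csv", index=False)
    for ds in problem.datasets:
        traj = problem.simulator.run(
            problem.fluxes_for(ds, result.x),
            problem.initial_conc_for(ds, result.x),
            ds.label_input, ds.config, ds.initial_pool_labelling,
        )
        traj.to_frame().to_csv(out / f"trajectory_{ds.name}.csv", index=False)
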