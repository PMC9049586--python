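"""Run configuration schema, loading and result serialization.

A RunConfig is a YAML document validated against a strict pydantic schema
(unknown keys are rejected).  It names either a pre-built scenario or an
inline protocol, optionally overrides parameter values, and carries solver
settings and the output directory.  write_results produces a deterministic
file set per run: tidy per-condition trajectory CSVs, a metrics JSON, the
fully resolved configuration (sufficient to reproduce the run) and a run
log.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .defaults import default_parameterization
from .network import Parameterization, build_default_network
from .protocols import Protocol, Pulse
from .scenarios import SCENARIOS, ScenarioResult, run_scenario
from .simulate import simulate, total_pkc_series

__all__ = ["RunConfig", "ConfigError", "load_config", "execute", "write_results"]

logger = logging.getLogger("pkclife")


class ConfigError(ValueError):
    """Invalid run configuration; the message names the offending key."""


class PulseConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    t_on: float = Field(ge=0)
    duration: float = Field(gt=0)
    amplitude: float = Field(default=1.0, ge=0)


class ProtocolConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    t_end: float = Field(gt=0)
    synthesis_pulses: list[PulseConfig] = []
    activator_pulses: list[PulseConfig] = []
    k17_block_windows: list[tuple[float, float]] = []
    phlpp_block_fraction: float = Field(default=0.0, ge=0.0, le=1.0)
    hsp70_multiplier: float = Field(default=1.0, ge=0.0)

    def build(self) -> Protocol:
        return Protocol(
            t_end=self.t_end,
            synthesis_pulses=tuple(
                Pulse(p.t_on, p.duration, p.amplitude)
                for p in self.synthesis_pulses),
            activator_pulses=tuple(
                Pulse(p.t_on, p.duration, p.amplitude)
                for p in self.activator_pulses),
            k17_block_windows=tuple(self.k17_block_windows),
            phlpp_block_fraction=self.phlpp_block_fraction,
            hsp70_multiplier=self.hsp70_multiplier,
        )


class SolverConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    rtol: float = Field(default=1e-8, gt=0)
    atol: float = Field(default=1e-12, gt=0)
    output_dt: float = Field(default=0.5, gt=0)


class RunConfig(BaseModel):
    """Validated run description with defaults filled."""

    model_config = ConfigDict(extra="forbid")

    scenario: str | None = None
    protocol: ProtocolConfig | None = None
    parameters: str | None = None            # path to a parameter YAML
    parameter_overrides: dict[str, float] = {}
    solver: SolverConfig = SolverConfig()
    outdir: str = "results"
    dual_degradation: bool = False

    @field_validator("scenario")
    @classmethod
    def _known_scenario(cls, v):
        if v is not None and v not in SCENARIOS:
            raise ValueError(
                f"scenario: unknown name {v!r}; known: {sorted(SCENARIOS)}")
        return v

    def resolve_parameterization(self) -> Parameterization:
        if self.parameters is None:
            base = default_parameterization().to_dict()
        else:
            with open(self.parameters) as fh:
                base = yaml.safe_load(fh)
        base.update(self.parameter_overrides)
        try:
            return Parameterization.from_dict(base)
        except (ValueError, KeyError) as exc:
            raise ConfigError(f"parameters: {exc}") from exc

    def resolved_dict(self) -> dict:
        d = self.model_dump(mode="json")
        d["resolved_parameters"] = self.resolve_parameterization().to_dict()
        return d


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Raises ConfigError naming the offending key on schema violations and
    FileNotFoundError if the file is missing.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a YAML mapping")
    try:
        cfg = RunConfig.model_validate(raw)
    except Exception as exc:
        raise ConfigError(str(exc)) from exc
    if cfg.scenario is None and cfg.protocol is None:
        raise ConfigError("either 'scenario' or 'protocol' must be given")
    cfg.resolve_parameterization()   # surface parameter errors early
    return cfg


def execute(cfg: RunConfig) -> ScenarioResult:
    """Run the configured scenario or ad-hoc protocol."""
    params = cfg.resolve_parameterization()
    if cfg.dual_degradation and params.lam5 == 0.0:
        params = params.with_(lam5=2.0e-4)
    if cfg.scenario is not None:
        logger.info("running scenario %s", cfg.scenario)
        return run_scenario(cfg.scenario, params)
    proto = cfg.protocol.build()
    net = build_default_network(variant=params.lam5 > 0)
    logger.info("running inline protocol to t_end=%g min", proto.t_end)
    traj = simulate(net, params, proto,
                    output_dt=cfg.solver.output_dt,
                    rtol=cfg.solver.rtol, atol=cfg.solver.atol)
    tot = total_pkc_series(traj)
    metrics = {
        "final_total": float(tot.iloc[-1]),
        "max_total": float(tot.max()),
    }
    return ScenarioResult("custom", [{"condition": "custom",
                                      "final_total": metrics["final_total"]}],
                          {"custom": traj}, metrics)


def _json_default(o):
    import numpy as np

    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_results(result: ScenarioResult, outdir: str | Path,
                  config: RunConfig | None = None) -> list[Path]:
    """Write the deterministic per-run file set and return the paths:
    one tidy trajectory CSV per condition, metrics.json, conditions.csv,
    resolved_config.yaml (when a config is given) and run.log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for key, traj in result.trajectories.items():
        path = outdir / f"trajectory_{key}.csv"
        traj.to_frame().to_csv(path, index=False, float_format="%.10g",
                               lineterminator="\n")
        written.append(path)
    mpath = outdir / "metrics.json"
    mpath.write_text(json.dumps(result.metrics, indent=2, sort_keys=True,
                                default=_json_default) + "\n")
    written.append(mpath)
    cpath = outdir / "conditions.csv"
    result.condition_frame().to_csv(cpath, index=False, float_format="%.10g",
                                    lineterminator="\n")
    written.append(cpath)
    if config is not None:
        rpath = outdir / "resolved_config.yaml"
        rpath.write_text(yaml.safe_dump(config.resolved_dict(),
                                        sort_keys=True))
        written.append(rpath)
    lpath = outdir / "run.log"
    lines = [f"scenario: {result.scenario}",
             f"conditions: {len(result.conditions)}",
             f"files: {len(written) + 1}"]
    lpath.write_text("\n".join(lines) + "\n")
    written.append(lpath)
    return written
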