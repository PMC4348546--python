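"""Run configuration: a single validated schema for simulations.

A run is specified either by a named scenario (``scenario: source_line_low``)
or by an inline tissue + parameters + response function.  Unknown keys are
rejected; validation errors are reported as an itemized list.  YAML and JSON
are both accepted (YAML is a superset here).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .dynamics import IntegratorOptions
from .model import ConfigurationError, ModelParams, ResponseFunction, TissueGraph
from .scenarios import (
    Scenario,
    make_grid,
    make_line,
    scenario_grid_patches,
    scenario_sink_line,
    scenario_source_line,
)

__all__ = ["RunConfig", "load_config", "save_config", "build_run", "named_scenarios"]


def named_scenarios() -> dict[str, Scenario]:
    """The built-in study conditions, by name."""
    return {
        "grid_patches": scenario_grid_patches(),
        "grid_patches_diffusive": scenario_grid_patches(diffusive=True),
        "sink_line": scenario_sink_line(),
        "source_line_low": scenario_source_line("low_source"),
        "source_line_high": scenario_source_line("high_source"),
        "source_line_background": scenario_source_line("background"),
    }


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TissueSpec(_Strict):
    kind: Literal["grid", "line", "custom"]
    rows: int | None = None
    cols: int | None = None
    L: int | None = None
    periodic: bool = False
    regular: bool = True
    seed: int | None = None
    n_cells: int | None = None
    edges: list[tuple[int, int]] | None = None
    volumes: list[float] | None = None
    areas: list[float] | None = None

    def build(self) -> TissueGraph:
        if self.kind == "grid":
            if self.rows is None or self.cols is None:
                raise ConfigurationError("grid tissue needs rows and cols")
            return make_grid(self.rows, self.cols, self.regular, self.seed)
        if self.kind == "line":
            if self.L is None:
                raise ConfigurationError("line tissue needs L")
            return make_line(self.L, self.periodic)
        if self.n_cells is None or self.edges is None:
            raise ConfigurationError("custom tissue needs n_cells and edges")
        return TissueGraph(self.n_cells, self.edges, self.volumes, self.areas)


class ParamsSpec(_Strict):
    alpha_a: float | list[float] = 1.0
    beta_a: float | list[float] = 1.0
    gamma_D: float = 0.0
    gamma_A: float = 1.0
    rho0: float = 0.0
    mu: float = 1.0
    lam: float = 1.0
    alpha_p: float = 1.0
    beta_p: float = 1.0

    def build(self) -> ModelParams:
        import numpy as np

        def conv(v):
            return np.asarray(v, dtype=float) if isinstance(v, list) else v

        return ModelParams(alpha_a=conv(self.alpha_a), beta_a=conv(self.beta_a),
                           gamma_D=self.gamma_D, gamma_A=self.gamma_A,
                           rho0=self.rho0, mu=self.mu, lam=self.lam,
                           alpha_p=self.alpha_p, beta_p=self.beta_p)


class ResponseSpec(_Strict):
    kind: Literal["linear", "quadratic", "hill", "power"] = "quadratic"
    kappa: float = 1.0
    j_ref: float = 1.0
    rho: float = 1.0
    theta: float = 1.0
    n: float = 2.0

    def build(self) -> ResponseFunction:
        return ResponseFunction(kind=self.kind, kappa=self.kappa, j_ref=self.j_ref,
                                rho=self.rho, theta=self.theta, n=self.n)


class IntegratorSpec(_Strict):
    t_max: float = 1e4
    rtol: float = 1e-8
    atol: float = 1e-10
    conv_tol: float = 1e-8
    blowup_threshold: float = 1e6
    oscillation_window: float = 0.2
    p_max: float | None = None
    method: str | None = None
    n_eval: int | None = None

    def build(self, seed: int | None = None) -> IntegratorOptions:
        return IntegratorOptions(t_max=self.t_max, rtol=self.rtol, atol=self.atol,
                                 conv_tol=self.conv_tol,
                                 blowup_threshold=self.blowup_threshold,
                                 oscillation_window=self.oscillation_window,
                                 p_max=self.p_max, method=self.method,
                                 n_eval=self.n_eval, seed=seed)


class RunConfig(_Strict):
    """Validated description of one simulation run."""

    scenario: str | None = None
    variant: Literal["full", "extended", "slow"] | None = None
    tissue: TissueSpec | None = None
    params: ParamsSpec | None = None
    response: ResponseSpec | None = None
    pin_init: float = 0.1
    jitter: float = 0.01
    integrator: IntegratorSpec = Field(default_factory=IntegratorSpec)
    seed: int = 0

    def scenario_object(self) -> Scenario:
        if self.scenario is not None:
            catalog = named_scenarios()
            if self.scenario not in catalog:
                raise ConfigurationError(
                    f"unknown scenario {self.scenario!r}; "
                    f"known: {sorted(catalog)}")
            return catalog[self.scenario]
        missing = [k for k in ("variant", "tissue", "params", "response")
                   if getattr(self, k) is None]
        if missing:
            raise ConfigurationError(
                "config needs either a scenario name or explicit "
                + ", ".join(missing))
        return Scenario(
            name="inline", variant=self.variant, tissue=self.tissue.build(),
            params=self.params.build(), phi=self.response.build(),
            pin_init=self.pin_init, jitter=self.jitter)


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML/JSON run configuration."""
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ConfigurationError("config file must contain a mapping")
    try:
        return RunConfig.model_validate(doc)
    except ValidationError as exc:
        items = [
            f"  - {'.'.join(str(p) for p in err['loc']) or '<root>'}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ConfigurationError(
            "invalid run configuration:\n" + "\n".join(items)) from None


def save_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    doc = config.model_dump(exclude_none=True)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def build_run(config: RunConfig):
    """Materialize (scenario, integrator options) from a validated config."""
    scenario = config.scenario_object()
    return scenario, config.integrator.build(config.seed)
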