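"""Run configuration: the discretisation shorthand and YAML round-trip.

The discretisation string ``n adapt_{k,l}`` fixes every resolution knob at
once: fine bulk mesh divisor N_f = 2^k, coarse divisor N_c = 2^l, time step
tau = 1e-3 / n (n = 1 when omitted) and, by default, the number of membrane
vertices K_Gamma = 2^k + 1.  ``K_gamma`` may be overridden explicitly for
scaled-down studies.  The method contains no randomness, so no seed is part
of the configuration.
"""

from __future__ import annotations

import re
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from .errors import ConfigError

__all__ = ["RunConfig", "parse_discretization", "load_config", "save_config"]

_DISC_RE = re.compile(
    r"^\s*(?:(\d+)\s*)?adapt_(?:\{(\d+),\s*(\d+)\}|(\d+)_(\d+))\s*$")


def parse_discretization(text: str):
    """Parse ``n adapt_{k,l}`` (also accepted: ``2adapt_6_3``).

    Returns (n, N_f, N_c, tau, K_Gamma) with N_f = 2^k, N_c = 2^l,
    tau = 1e-3/n and K_Gamma = 2^k + 1; requires k > l.
    """
    m = _DISC_RE.match(text)
    if not m:
        raise ConfigError(f"malformed discretisation string {text!r}")
    n = int(m.group(1) or 1)
    k = int(m.group(2) or m.group(4))
    l = int(m.group(3) or m.group(5))
    if k <= l:
        raise ConfigError(f"discretisation needs k > l, got k={k}, l={l}")
    if n < 1:
        raise ConfigError("time-step divisor n must be a positive integer")
    return n, 2**k, 2**l, 1e-3 / n, 2**k + 1


_PARAM_KEYS = {"rho_minus", "rho_plus", "mu_minus", "mu_plus", "rho_gamma",
               "mu_gamma", "alpha"}


class RunConfig(BaseModel):
    """Validated run description; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    preset: str
    discretization: str = "adapt_{5,2}"
    T: float = 1.0
    ell: int = 1
    K_gamma: Optional[int] = None
    solver: str = "direct"
    output_dir: Optional[str] = None
    output_every: int = 20
    check_every: int = 10
    params: dict = {}

    @field_validator("ell")
    @classmethod
    def _ell(cls, v):
        if v not in (1, 2):
            raise ValueError("ell must be 1 or 2")
        return v

    @field_validator("solver")
    @classmethod
    def _solver(cls, v):
        if v not in ("direct", "schur"):
            raise ValueError("solver must be 'direct' or 'schur'")
        return v

    @field_validator("params")
    @classmethod
    def _params(cls, v):
        unknown = set(v) - _PARAM_KEYS
        if unknown:
            raise ValueError(f"unknown physical parameter(s): {sorted(unknown)}")
        return v

    def discretisation(self):
        return parse_discretization(self.discretization)

    def build_simulation(self):
        from .stepper import Simulation
        n, nf, nc, tau, k_default = self.discretisation()
        return Simulation(self.preset, nf, nc, tau,
                          self.K_gamma or k_default, ell=self.ell,
                          solver=self.solver, check_every=self.check_every,
                          param_overrides=self.params)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    try:
        return RunConfig(**data)
    except Exception as exc:
        raise ConfigError(str(exc)) from exc


def save_config(path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=False)
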