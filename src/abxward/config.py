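"""Scenario configuration: build model objects from a YAML/dict config.

A scenario file names one strategy and one tradeoff value and may override
any epidemiological, pharmacodynamic, MIC or integration setting; omitted
blocks fall back to the standard parameter set.  Example::

    strategy: {name: COCKTAIL_SEP}
    omega: 1.0
    epi: {beta: 1.0, sigma: 0.25, gamma: 0.25, cost_c: 0.1}
    pharmacodynamics: {phi_max: 0.25, phi_min: -0.25, hill_k: 1.0}
    mic: {base_a1: 240, base_b2: 240}
    integration: {dt: 0.1, convergence_tol: 1.0e-12}
    initial: {x: 0.96, s: 0.01, r1: 0.01, r2: 0.01, r3: 0.01}

An optional ``strains`` block replaces the standard MIC schema entirely with
explicit per-strain entries (``name``, ``mic_a``, ``mic_b``, ``pays_cost``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .engine import IntegrationSettings
from .pharmacodynamics import PharmacodynamicParams, StrainProfile, standard_strains
from .population import EpiParams
from .treatments import StrategySchedule

__all__ = ["Scenario", "load_scenario"]


class ConfigError(ValueError):
    """Raised for malformed scenario configuration."""


@dataclass(frozen=True)
class Scenario:
    schedule: StrategySchedule
    omega: float
    epi: EpiParams
    pd_params: PharmacodynamicParams
    strains: tuple[StrainProfile, ...]
    settings: IntegrationSettings
    initial: np.ndarray | None

    @classmethod
    def from_dict(cls, raw: dict) -> "Scenario":
        try:
            strat = dict(raw.get("strategy") or {})
            schedule = StrategySchedule(
                name=strat.get("name", "SINGLE"),
                period_pi=strat.get("pi"),
                dose_budget=float(strat.get("dose_budget", 240.0)),
            )
            omega = float(raw.get("omega", 0.0))
            epi = EpiParams(**(raw.get("epi") or {}))
            pd_params = PharmacodynamicParams(**(raw.get("pharmacodynamics") or {}))
            if "strains" in raw:
                strains = tuple(StrainProfile(**s) for s in raw["strains"])
                if len(strains) != 4:
                    raise ConfigError("strains block must list exactly 4 strains")
            else:
                mic = raw.get("mic") or {}
                strains = standard_strains(
                    omega, float(mic.get("base_a1", 240.0)), float(mic.get("base_b2", 240.0))
                )
            settings = IntegrationSettings(**(raw.get("integration") or {}))
            initial = None
            if "initial" in raw:
                ini = raw["initial"]
                initial = np.array(
                    [ini.get(k, 0.0) for k in ("x", "s", "r1", "r2", "r3")], dtype=float
                )
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid scenario configuration: {exc}") from exc
        return cls(schedule, omega, epi, pd_params, strains, settings, initial)


def load_scenario(path) -> Scenario:
    """Load a scenario from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    return Scenario.from_dict(raw)
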