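"""Synthetic kinetics series: Arrhenius, convex-Arrhenius, flash-yield and
pump-dump action traces, each with attached ground truth.

Default Arrhenius truth: barrier 91 kJ/mol with a 2600-s recovery time at
293 K and a small temperature-independent channel A1, giving
A1 = 2e-5 s^-1 and A2 = (1/2600 - A1) * exp(Ea/(R*293)) s^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..kinetics import (
    FlashYieldSeries,
    RateSeries,
    action_trace,
    arrhenius_rate,
    convex_rate,
    flash_yield,
)
from ..units import R_GAS

R_KJ = R_GAS / 1000.0

_EA_DEFAULT = 91.0          # kJ/mol
_A1_DEFAULT = 2.0e-5        # s^-1
_TAU_293 = 2600.0           # s


def default_arrhenius_truth() -> dict:
    a2 = (1.0 / _TAU_293 - _A1_DEFAULT) * math.exp(_EA_DEFAULT / (R_KJ * 293.0))
    return {"a1": _A1_DEFAULT, "a2": a2, "ea": _EA_DEFAULT}


def default_convex_truth() -> dict:
    return {"k1": 5.0e10, "e1": 75.0, "k2": 5.0e14, "e2": 105.0,
            "delta_g": 8.0}


def default_flash_yield_truth() -> dict:
    return {"phi": 0.35, "sigma_lin": 1.2, "sigma_nl": 0.15}


def default_action_trace_truth() -> dict:
    return {"pump_fwhm": 100.0, "dump_fwhm": 100.0, "es_lifetime": 7.6,
            "depth": 0.4}


@dataclass
class SyntheticKineticsSpec:
    model: str = "arrhenius"   # arrhenius | convex | flash_yield | action_trace
    parameters: dict = field(default_factory=dict)
    grid: np.ndarray | None = None
    relative_noise: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.model not in ("arrhenius", "convex", "flash_yield",
                              "action_trace"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.relative_noise < 0:
            raise ValueError("noise must be non-negative")
        if self.grid is not None:
            self.grid = np.asarray(self.grid, float)
            if self.model in ("arrhenius", "convex") and (
                    (self.grid < 250).any() or (self.grid > 350).any()):
                raise ValueError("temperatures must lie in 250-350 K")


def make_kinetics_series(spec: SyntheticKineticsSpec | None = None):
    """Forward model on the grid plus noise; returns (series, truth)."""
    spec = spec or SyntheticKineticsSpec()
    rng = np.random.default_rng(spec.seed)
    noise = spec.relative_noise

    if spec.model == "arrhenius":
        truth = {**default_arrhenius_truth(), **spec.parameters}
        t = spec.grid if spec.grid is not None else np.linspace(284.0, 323.0, 8)
        clean = arrhenius_rate(t, truth["a1"], truth["a2"], truth["ea"])
        rates = clean * (1.0 + noise * rng.standard_normal(len(t)))
        rates = np.abs(rates)
        sig = noise * clean if noise > 0 else None
        return RateSeries(t, rates, sig), truth

    if spec.model == "convex":
        truth = {**default_convex_truth(), **spec.parameters}
        t = spec.grid if spec.grid is not None else np.linspace(270.0, 340.0, 15)
        clean = convex_rate(t, truth["k1"], truth["e1"], truth["k2"],
                            truth["e2"], truth["delta_g"])
        rates = np.abs(clean * (1.0 + noise * rng.standard_normal(len(t))))
        sig = noise * clean if noise > 0 else None
        return RateSeries(t, rates, sig), truth

    if spec.model == "flash_yield":
        truth = {**default_flash_yield_truth(), **spec.parameters}
        f = spec.grid if spec.grid is not None else np.linspace(0.0, 10.0, 15)
        clean = flash_yield(f, truth["phi"], truth["sigma_lin"],
                            truth["sigma_nl"])
        yields = np.clip(clean + noise * clean.max()
                         * rng.standard_normal(len(f)), 0.0, 1.0)
        sig = np.full(len(f), noise * clean.max()) if noise > 0 else None
        return FlashYieldSeries(f, yields, sig), truth

    truth = {**default_action_trace_truth(), **spec.parameters}
    d = spec.grid if spec.grid is not None else np.linspace(-600.0, 3000.0, 40)
    clean = action_trace(d, truth["pump_fwhm"], truth["dump_fwhm"],
                         truth["es_lifetime"], truth["depth"])
    trace = clean + noise * rng.standard_normal(len(d))
    return (d, trace), truth
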