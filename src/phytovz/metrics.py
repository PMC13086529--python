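"""Ecological summary metrics and error measures against field targets.

Metrics are evaluated on a (steady-state or time-averaged) molar state and
converted to the count currency with the elemental quotas where needed.
Percentages follow the conventions of plankton-virus field studies: the
infected fraction is taken over the whole phytoplankton population, the
resistant fraction over uninfected cells only, and the virus-induced share
of mortality compares per-capita lysis with grazing and basal death.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import COMPARTMENTS, CommunityParams

#: sentinel mirroring the "N.D." (not defined) entries of field tables
NOT_DEFINED = float("nan")


@dataclass
class EcologyMetrics:
    percent_infected: float     # %I = 100·I/(S+I+R)
    percent_resistant: float    # %R = 100·R/(S+R)
    mV: float                   # per-capita virus-induced mortality, d⁻¹
    mZ: float                   # per-capita grazing mortality, d⁻¹
    percent_viral_mortality: float  # %Vm = 100·mV/(mV+mZ+dS)
    NPP: float                  # net primary production, μmolC·L⁻¹·d⁻¹
    VP_count_ratio: float       # virus:phytoplankton count ratio
    counts: dict                # per-compartment count concentrations, ind·L⁻¹

    @property
    def defined(self) -> bool:
        return not math.isnan(self.percent_infected)


@dataclass
class TargetSet:
    """Field target concentrations and ecological constraint bounds.

    ``targets`` maps tracer name ('P', 'V', 'Z') to a count concentration
    (ind·L⁻¹).  ``percent_infected_bounds`` and
    ``percent_viral_mortality_bounds`` are closed intervals in percent;
    ``require_VP_above_one`` demands a virus:phytoplankton count ratio > 1.
    ``weight`` is the error weight αe of the environment the set belongs to.
    """

    environment: str
    targets: dict
    percent_infected_bounds: tuple = (0.0, 100.0)
    percent_viral_mortality_bounds: tuple = (0.0, 50.0)
    require_VP_above_one: bool = True
    weight: float = 1.0

    def __post_init__(self) -> None:
        for name, value in self.targets.items():
            if value <= 0:
                raise ValueError(f"target for {name} must be positive")
        for lo, hi in (
            self.percent_infected_bounds,
            self.percent_viral_mortality_bounds,
        ):
            if lo > hi:
                raise ValueError("constraint bounds must be ordered")
        if self.weight <= 0:
            raise ValueError("weight must be positive")


def ecology_metrics(state: np.ndarray, p: CommunityParams) -> EcologyMetrics:
    """Summary metrics of a molar state ``[S, I, V, R, Z]``.

    When the total phytoplankton concentration is zero the percentage
    metrics are returned as NaN (the tables' "N.D.").
    """
    S, I, V, R, Z = (float(x) for x in np.asarray(state, dtype=float))
    P = S + I + R
    counts = {
        "S": S / p.Qp,
        "I": I / p.Qp,
        "R": R / p.Qp,
        "P": P / p.Qp,
        "V": V / p.Qv,
        "Z": Z / p.Qz,
    }
    NPP = (p.mu * S + p.mu * p.zeta * R) * 106.0 / 16.0
    if P <= 0:
        return EcologyMetrics(
            percent_infected=NOT_DEFINED,
            percent_resistant=NOT_DEFINED,
            mV=0.0,
            mZ=p.gZ * Z,
            percent_viral_mortality=NOT_DEFINED,
            NPP=NPP,
            VP_count_ratio=NOT_DEFINED,
            counts=counts,
        )
    pct_I = 100.0 * I / P
    pct_R = 100.0 * R / (S + R) if (S + R) > 0 else NOT_DEFINED
    mV = (I / P) / p.tau
    mZ = p.gZ * Z
    pct_Vm = 100.0 * mV / (mV + mZ + p.dS)
    vp = counts["V"] / counts["P"]
    return EcologyMetrics(
        percent_infected=pct_I,
        percent_resistant=pct_R,
        mV=mV,
        mZ=mZ,
        percent_viral_mortality=pct_Vm,
        NPP=NPP,
        VP_count_ratio=vp,
        counts=counts,
    )


def error_to_targets(metrics: EcologyMetrics, targets: TargetSet) -> float:
    """Total absolute relative error D_e (%) across the P, V, Z tracers."""
    total = 0.0
    for tracer, target in targets.targets.items():
        if target <= 0:
            raise ValueError(f"target for {tracer} must be positive")
        model = metrics.counts[tracer]
        total += abs(model - target) / target
    return 100.0 * total


def weighted_error(D_per_env: dict, weights: dict | None = None) -> float:
    """Weighted mean error D̄ (%) across environments: Σ αe·D_e / Σ αe."""
    if not D_per_env:
        raise ValueError("no per-environment errors given")
    weights = weights or {env: 1.0 for env in D_per_env}
    num = sum(weights[e] * D for e, D in D_per_env.items())
    den = sum(weights[e] for e in D_per_env)
    if den <= 0:
        raise ValueError("weights must sum to a positive value")
    return num / den


def constraints_satisfied(
    metrics: EcologyMetrics, targets: TargetSet
) -> bool:
    """Ecological constraint screen with closed interval bounds.

    Checks the infected-cell percentage against the environment's interval,
    the virus-induced mortality percentage against its interval, and (when
    required) a virus:phytoplankton count ratio above one.
    """
    if not metrics.defined:
        return False
    lo, hi = targets.percent_infected_bounds
    if not (lo <= metrics.percent_infected <= hi):
        return False
    lo, hi = targets.percent_viral_mortality_bounds
    if not (lo <= metrics.percent_viral_mortality <= hi):
        return False
    if targets.require_VP_above_one and not (metrics.VP_count_ratio > 1.0):
        return False
    return True
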