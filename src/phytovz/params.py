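"""Parameter and state containers shared by all model variants.

The four model variants share one parameter set (:class:`CommunityParams`)
and one 5-slot state layout ``[S, I, V, R, Z]`` (μmolN·L⁻¹); compartments
that a variant does not resolve are simply held at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

#: canonical compartment order of every state vector
COMPARTMENTS = ("S", "I", "V", "R", "Z")

MODEL_IDS = ("svz", "sivz", "svrz", "sivrz")


def model_flags(model_id: str) -> tuple[bool, bool]:
    """``(has_infected, has_resistant)`` flags of a model variant."""
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model id {model_id!r}; expected one of {MODEL_IDS}")
    return model_id in ("sivz", "sivrz"), model_id in ("svrz", "sivrz")


def active_compartments(model_id: str) -> tuple[str, ...]:
    has_i, has_r = model_flags(model_id)
    out = ["S"]
    if has_i:
        out.append("I")
    out.append("V")
    if has_r:
        out.append("R")
    out.append("Z")
    return tuple(out)


# order of the packed parameter vector consumed by the numba kernels
PARAM_ORDER = (
    "mu",
    "dS",
    "phiS",
    "phiR",
    "epsV",
    "epsVR",
    "tau",
    "beta",
    "dV",
    "dV2",
    "gZ",
    "epsZ",
    "dZ",
    "dZ2",
    "K",
    "tauK",
    "r",
    "zeta",
    "gamma",
    "Qp",
    "Qv",
    "Qz",
)


@dataclass
class CommunityParams:
    """Full parameter set of one host–virus–grazer triple.

    Rates are per day, volumetric rates in L·d⁻¹, quadratic mortalities in
    (μmolN·L⁻¹)⁻¹·d⁻¹, quotas in μmolN·ind⁻¹.  ``epsV``/``epsVR`` are
    infection probabilities (inverse intracellular resistance), ``zeta`` the
    growth retention of the resistant type (cost of resistance = 1 − ζ),
    ``r`` the mutation fraction and ``gamma`` the lysate shunt fraction.
    """

    mu: float          # division rate of susceptible cells, d⁻¹
    dS: float          # linear cell mortality, d⁻¹
    phiS: float        # adsorption rate to susceptible cells, L·d⁻¹
    Qp: float          # phytoplankton quota, μmolN·cell⁻¹
    Qv: float          # virion quota, μmolN·virion⁻¹
    Qz: float          # grazer quota, μmolN·ind⁻¹
    beta: float = 15.0     # burst size, virions per lysis
    tau: float = 0.37      # latent period, d
    dV: float = 0.06       # linear viral decay, d⁻¹
    dV2: float = 0.0       # quadratic viral loss
    gZ: float = 9.8        # grazing clearance, (μmolN·L⁻¹)⁻¹·d⁻¹
    epsZ: float = 0.3      # gross growth efficiency of the grazer
    dZ: float = 0.067      # linear grazer mortality, d⁻¹
    dZ2: float = 0.0       # quadratic grazer loss
    K: float = 0.2         # carrying capacity, μmolN·L⁻¹
    tauK: float = 1.0      # carrying-capacity relaxation time, d
    epsV: float = 1.0      # infection probability, susceptible type
    epsVR: float = 1.0     # infection probability, resistant type
    phiR: float = 0.0      # adsorption rate to resistant cells, L·d⁻¹
    r: float = 0.0         # S↔R mutation fraction
    zeta: float = 1.0      # growth retention of the resistant type
    gamma: float = 0.5     # lysate shunt (DON) fraction
    env_label: str | None = None  # set once environment factors are folded in

    def validate(self, model_id: str | None = None) -> None:
        nonneg = (
            "mu dS phiS phiR tau beta dV dV2 gZ dZ dZ2 K tauK r Qp Qv Qz".split()
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name} must be >= 0")
        for name in ("epsV", "epsVR", "epsZ", "zeta", "gamma", "r"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"parameter {name} must lie in [0, 1]")
        if min(self.Qp, self.Qv, self.Qz) <= 0:
            raise ValueError("quotas must be strictly positive")
        if self.K <= 0 or self.tauK <= 0:
            raise ValueError("K and tauK must be strictly positive")
        if self.beta < 1:
            raise ValueError("burst size must be >= 1")
        if model_id is not None:
            has_i, _ = model_flags(model_id)
            if has_i and self.tau <= 0:
                raise ValueError("latent period tau must be > 0 for I-class models")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAM_ORDER], dtype=np.float64)

    def with_(self, **updates) -> "CommunityParams":
        """A copy with the given fields replaced."""
        return replace(self, **updates)


def state_vector(
    S: float = 0.0, I: float = 0.0, V: float = 0.0, R: float = 0.0, Z: float = 0.0
) -> np.ndarray:
    """Pack compartment concentrations into the canonical 5-vector."""
    y = np.array([S, I, V, R, Z], dtype=np.float64)
    if np.any(y < 0):
        raise ValueError("state concentrations must be non-negative")
    return y


def default_initial_state(
    model_id: str, p: CommunityParams, *, predator_count: float = 1.0e3
) -> np.ndarray:
    """Default initial condition: host near half carrying capacity, predators
    seeded at ``predator_count`` ind·L⁻¹ equivalents, R seeded by mutation."""
    has_i, has_r = model_flags(model_id)
    S0 = 0.5 * p.K
    return state_vector(
        S=S0,
        I=0.0,
        V=predator_count * p.Qv,
        R=p.r * S0 if has_r else 0.0,
        Z=predator_count * p.Qz,
    )


def counts_from_molar(y: np.ndarray, p: CommunityParams) -> np.ndarray:
    """Convert a molar state (μmolN·L⁻¹) to count concentrations (ind·L⁻¹)."""
    y = np.asarray(y, dtype=np.float64)
    quotas = np.array([p.Qp, p.Qp, p.Qv, p.Qp, p.Qz])
    return y / quotas


def molar_from_counts(counts: np.ndarray, p: CommunityParams) -> np.ndarray:
    counts = np.asarray(counts, dtype=np.float64)
    quotas = np.array([p.Qp, p.Qp, p.Qv, p.Qp, p.Qz])
    return counts * quotas
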