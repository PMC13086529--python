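"""Canonical scenario configurations and synthetic-data generators.

This module is the single source of truth for the study conditions: four
phytoplankton types (*Prochlorococcus*, *Synechococcus*, a picoeukaryote
and a small diatom), each paired with its virus and grazer, and two
idealised epipelagic environments (oligotrophic, mesotrophic).  Organism
sizes and a handful of literature rate constants live in YAML configs; every
derived constant (quotas, encounter kernels, growth rates, carrying
capacities) is regenerated from the trait layer, and the copies stored under
``derived:`` in the configs exist only so that audits can detect drift.

It also provides the synthetic fixtures the test-bench uses: target sets
planted at a known equilibrium, and analytic toy trajectories.
"""

from __future__ import annotations

import importlib.resources as resources
import math
from dataclasses import dataclass

import numpy as np
import yaml

from . import traits
from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .dynamics import DAYS_PER_YEAR, DEFAULT_STEP_D, Trajectory
from .metrics import TargetSet, ecology_metrics
from .params import CommunityParams, state_vector


def _load_yaml(name: str) -> dict:
    with resources.files("phytovz.data").joinpath(name).open("r") as fh:
        return yaml.safe_load(fh)


def organism_names() -> tuple:
    return tuple(_load_yaml("organisms.yaml")["organisms"].keys())


def environment_names() -> tuple:
    return tuple(_load_yaml("environments.yaml")["environments"].keys())


def organism_config(name: str) -> dict:
    cfg = _load_yaml("organisms.yaml")
    try:
        return {**cfg["shared_defaults"], **cfg["organisms"][name]}
    except KeyError:
        raise ValueError(
            f"unknown organism {name!r}; available: {sorted(cfg['organisms'])}"
        ) from None


def environment_spec(name: str) -> traits.EnvironmentSpec:
    cfg = _load_yaml("environments.yaml")["environments"]
    try:
        e = cfg[name]
    except KeyError:
        raise ValueError(
            f"unknown environment {name!r}; available: {sorted(cfg)}"
        ) from None
    return traits.EnvironmentSpec(
        label=name,
        deep_nutrient=e["deep_nutrient"],
        surface_nutrient=e["surface_nutrient"],
        mixing_rate=e["mixing_rate"],
        temperature=e["temperature"],
        eppley_scale=e["eppley_scale"],
        eppley_slope=e["eppley_slope"],
        eppley_ref_temp=e["eppley_ref_temp"],
        error_weight=e.get("error_weight", 1.0),
    )


def derived_traits(
    name: str, consts: PhysicalConstants = DEFAULT_CONSTANTS
) -> dict:
    """Recompute every derived trait constant of one organism from sizes."""
    cfg = organism_config(name)
    host = traits.OrganismSpec(group=cfg["group"], volume=cfg["volume_um3"])
    virion = traits.OrganismSpec(group="virus", radius=cfg["virion_radius_nm"])
    grazer_vol = traits.sphere_volume(cfg["grazer_radius_um"])
    mu_max = traits.max_growth_rate(cfg["group"], cfg["volume_um3"])
    Qmin = cfg["uptake"]["min_quota_fraction"] * traits.phyto_nitrogen_quota(
        host, consts
    )
    allom = traits.UptakeAllometry(
        half_sat_uptake=cfg["uptake"]["half_sat_uptake"],
        min_quota=Qmin,
        max_uptake=cfg["uptake"]["max_uptake_per_day_quota"] * mu_max * Qmin,
    )
    return {
        "Qp": traits.phyto_nitrogen_quota(host, consts),
        "Qv": traits.virus_nitrogen_quota(cfg["virion_radius_nm"], consts),
        "Qz": traits.grazer_nitrogen_quota(grazer_vol, consts),
        "mu_max": mu_max,
        "phi_th": traits.encounter_rate(host, virion, None, consts),
        "Nc": traits.half_saturation(mu_max, allom),
        "host_radius_um": host.radius,
        "grazer_volume_um3": grazer_vol,
    }


def base_params(name: str) -> CommunityParams:
    """Environment-free default parameter set of one organism triple.

    The adsorption rate defaults to the theoretical encounter kernel at the
    reference temperature; regime sweeps override it.
    """
    cfg = organism_config(name)
    d = derived_traits(name)
    return CommunityParams(
        mu=d["mu_max"],
        dS=cfg["dS"],
        phiS=d["phi_th"],
        Qp=d["Qp"],
        Qv=d["Qv"],
        Qz=d["Qz"],
        beta=cfg["beta"],
        tau=cfg["tau_d"],
        dV=cfg["dV"],
        dV2=cfg.get("dV2", 0.0),
        gZ=cfg["gZ"],
        epsZ=cfg["epsZ"],
        dZ=cfg["dZ"],
        dZ2=cfg.get("dZ2", 0.0),
        K=cfg["K"],
        tauK=cfg["tauK"],
        r=cfg.get("r", 0.0),
        zeta=cfg.get("zeta", 1.0),
        gamma=cfg.get("gamma", 0.5),
    )


def apply_environment(
    p: CommunityParams, organism: str, environment: str
) -> CommunityParams:
    """Fold one environment's factors into a parameter set, exactly once.

    The nutrient factor N/(N+Nc) multiplies the growth rate; the temperature
    factor γT multiplies the growth rate and all mortality parameters
    (dS, dV, dZ and both quadratic terms), but not the adsorption rate,
    latent period or burst size.  The carrying capacity is replaced by the
    resource–consumer equivalence K = w(Ndeep−N)(N+Nc)/(μT·N).
    """
    if p.env_label is not None:
        raise ValueError(
            f"environment factors already applied ({p.env_label!r}); refusing "
            "a second application"
        )
    env = environment_spec(environment)
    d = derived_traits(organism)
    nutrient, gamma_T = traits.growth_limitation(env, d["Nc"])
    mu_T = p.mu * gamma_T
    K = traits.carrying_capacity(env, mu_T, d["Nc"])
    return p.with_(
        mu=mu_T * nutrient,
        dS=p.dS * gamma_T,
        dV=p.dV * gamma_T,
        dZ=p.dZ * gamma_T,
        dV2=p.dV2 * gamma_T,
        dZ2=p.dZ2 * gamma_T,
        K=K,
        env_label=environment,
    )


def target_set(organism: str, environment: str) -> TargetSet:
    cfg = _load_yaml("targets.yaml")["targets"]
    try:
        t = cfg[organism][environment]
    except KeyError:
        raise ValueError(
            f"no targets for organism {organism!r} in environment {environment!r}"
        ) from None
    return TargetSet(
        environment=environment,
        targets={"P": float(t["P"]), "V": float(t["V"]), "Z": float(t["Z"])},
        percent_infected_bounds=tuple(t["percent_infected_bounds"]),
        percent_viral_mortality_bounds=tuple(t["percent_viral_mortality_bounds"]),
        require_VP_above_one=bool(t.get("require_VP_above_one", True)),
        weight=float(t.get("weight", 1.0)),
    )


def build_scenario(
    organism: str, environment: str | None = None
) -> tuple[CommunityParams, TargetSet | None]:
    """Fully resolved parameter set (+ targets) of one organism/environment."""
    p = base_params(organism)
    if environment is None:
        return p, None
    p = apply_environment(p, organism, environment)
    return p, target_set(organism, environment)


# ---------------------------------------------------------------------------
# synthetic data


def synth_targets(
    p: CommunityParams, noise_level: float = 0.0, seed: int = 0
) -> TargetSet:
    """Target set planted at a stable coexistence equilibrium of ``p``.

    Target counts are the equilibrium count concentrations multiplied by
    log-normal noise (σ = ``noise_level`` in relative terms); constraint
    bounds are widened so the planted truth always satisfies them.
    """
    from .equilibria import sivz_equilibria

    interior = [
        e for e in sivz_equilibria(p) if e.label == "interior" and e.stable
    ]
    if not interior:
        raise ValueError("parameter set has no stable coexistence equilibrium")
    eq = interior[0]
    m = ecology_metrics(eq.state, p)
    rng = np.random.default_rng(seed)
    noise = (
        np.exp(rng.normal(0.0, noise_level, size=3))
        if noise_level > 0
        else np.ones(3)
    )
    return TargetSet(
        environment="synthetic",
        targets={
            "P": m.counts["P"] * noise[0],
            "V": m.counts["V"] * noise[1],
            "Z": m.counts["Z"] * noise[2],
        },
        percent_infected_bounds=(0.0, 100.0),
        percent_viral_mortality_bounds=(0.0, 100.0),
        require_VP_above_one=m.VP_count_ratio > 1.0,
        weight=1.0,
    )


_UNIT_QUOTA_PARAMS = dict(
    mu=1.0, dS=0.0, phiS=0.0, Qp=1.0, Qv=1.0, Qz=1.0, beta=1.0, tau=1.0,
    dV=0.0, gZ=0.0, dZ=0.0, K=1.0, tauK=1.0,
)


def synth_trajectory(
    kind: str,
    *,
    duration: float = 2.0 * DAYS_PER_YEAR,
    step: float = DEFAULT_STEP_D,
    mean: float = 0.0,
    amplitude: float = 1.0,
    period: float = 30.0,
    lv_params: tuple = (0.5, 0.02, 0.01, 0.3),
    state0: tuple = (40.0, 9.0),
    seed: int = 0,
) -> Trajectory:
    """Analytic toy trajectories for the analysis fixtures.

    ``kind`` ∈ {'constant', 'sinusoid', 'lotka_volterra_cycle'}.  All five
    compartments carry the same series except the Lotka–Volterra cycle,
    which puts prey in S and predator in Z (independent high-accuracy
    adaptive integration, not the package's RK4).  Quotas are 1, so molar
    and count series coincide.
    """
    times = np.arange(0.0, duration + 0.5 * step, step)
    p = CommunityParams(**_UNIT_QUOTA_PARAMS)
    if kind == "constant":
        series = np.full_like(times, mean)
        states = np.tile(series[:, None], (1, 5))
    elif kind == "sinusoid":
        series = mean + amplitude * np.sin(2 * math.pi * times / period)
        states = np.tile(series[:, None], (1, 5))
    elif kind == "lotka_volterra_cycle":
        from scipy.integrate import solve_ivp

        alpha, beta_, delta, gamma_ = lv_params

        def f(_, y):
            x, z = y
            return [alpha * x - beta_ * x * z, delta * x * z - gamma_ * z]

        sol = solve_ivp(
            f, (times[0], times[-1]), state0, t_eval=times,
            rtol=1e-10, atol=1e-12, method="DOP853",
        )
        states = np.zeros((times.size, 5))
        states[:, 0] = sol.y[0]
        states[:, 4] = sol.y[1]
    else:
        raise ValueError(f"unknown synthetic trajectory kind {kind!r}")
    return Trajectory(
        model_id="synthetic", times=times, states=states, step=step, params=p
    )


def scenario_table() -> "object":
    """Flat audit table of derived parameters per organism × environment."""
    import pandas as pd

    rows = []
    for org in organism_names():
        for env in (None, *environment_names()):
            p, _ = build_scenario(org, env)
            d = derived_traits(org)
            rows.append(
                {
                    "organism": org,
                    "environment": env or "none",
                    **{k: getattr(p, k) for k in (
                        "mu", "dS", "phiS", "beta", "tau", "dV", "dV2",
                        "gZ", "epsZ", "dZ", "dZ2", "K", "tauK",
                        "Qp", "Qv", "Qz",
                    )},
                    "phi_th": d["phi_th"],
                    "Nc": d["Nc"],
                }
            )
    return pd.DataFrame(rows)
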