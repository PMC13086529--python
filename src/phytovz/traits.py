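"""Allometric life-history trait layer.

Converts organism sizes and environment settings into the rate and quota
parameters of the community models: nitrogen quotas of cells, virions and
grazers; diffusive virus–host encounter kernels; maximum growth rates;
half-saturation constants; carrying capacities; and nutrient/temperature
growth limitation factors.

Unit conventions are those of :mod:`phytovz.constants`; virion radii enter
the capsid-quota polynomial in nanometres (the convention of the empirical
capsid relationship this layer implements).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal

from .constants import (
    DEFAULT_CONSTANTS,
    LITRES_PER_M3,
    REFERENCE_TEMPERATURE_K,
    SECONDS_PER_DAY,
    PhysicalConstants,
)

Group = Literal["cyanobacteria", "eukaryote_non_diatom", "diatom", "virus", "grazer"]

PHYTO_GROUPS = ("cyanobacteria", "eukaryote_non_diatom", "diatom")

#: validated virion radius range (nm) of the capsid-quota relationship
VIRION_RADIUS_VALID_NM = (20.0, 120.0)


@dataclass(frozen=True)
class OrganismSpec:
    """Size specification of one organism.

    ``volume`` is in μm³ for cells and grazers; ``radius`` is in μm for
    cells/grazers and in **nm** for virions.  For spherical organisms either
    may be given; the other is filled in assuming a sphere.
    """

    group: Group
    volume: float | None = None
    radius: float | None = None

    def __post_init__(self) -> None:
        if self.group not in (*PHYTO_GROUPS, "virus", "grazer"):
            raise ValueError(f"unknown organism group: {self.group!r}")
        if self.volume is None and self.radius is None:
            raise ValueError("an OrganismSpec needs a volume or a radius")
        if self.volume is not None and self.volume <= 0:
            raise ValueError("volume must be strictly positive")
        if self.radius is not None and self.radius <= 0:
            raise ValueError("radius must be strictly positive")
        if self.group != "virus":
            if self.volume is None:
                object.__setattr__(
                    self, "volume", sphere_volume(self.radius)
                )
            elif self.radius is None:
                object.__setattr__(
                    self, "radius", sphere_radius(self.volume)
                )


@dataclass(frozen=True)
class EnvironmentSpec:
    """One idealised epipelagic environment.

    Nutrients in μmolN·L⁻¹, mixing rate ``w`` in d⁻¹, temperatures in K.
    ``eppley_scale``/``eppley_slope``/``eppley_ref_temp`` parameterise the
    temperature modulation factor γT; ``error_weight`` is the weight αe of
    this environment in the cross-environment fit error.
    """

    label: str
    deep_nutrient: float
    surface_nutrient: float
    mixing_rate: float
    temperature: float
    eppley_scale: float = 0.8
    eppley_slope: float = 4000.0
    eppley_ref_temp: float = 293.15
    error_weight: float = 1.0

    def __post_init__(self) -> None:
        if not (self.deep_nutrient >= self.surface_nutrient >= 0):
            raise ValueError("require Ndeep >= N >= 0")
        if self.mixing_rate < 0:
            raise ValueError("mixing rate w must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (K)")
        if self.error_weight <= 0:
            raise ValueError("error weight must be positive")


@dataclass(frozen=True)
class UptakeAllometry:
    """Nutrient-uptake allometry of one cell, already evaluated at its volume.

    ``half_sat_uptake`` (Hc, μmolN·L⁻¹), ``min_quota`` (Qmin, μmolN·cell⁻¹)
    and ``max_uptake`` (Umax, μmolN·cell⁻¹·d⁻¹) combine into the population
    half-saturation constant Nc = Hc·μmax·Qmin/Umax.
    """

    half_sat_uptake: float
    min_quota: float
    max_uptake: float

    def __post_init__(self) -> None:
        if min(self.half_sat_uptake, self.min_quota, self.max_uptake) <= 0:
            raise ValueError("all uptake allometry components must be positive")


def sphere_volume(radius: float) -> float:
    """Volume (μm³) of a sphere of ``radius`` μm."""
    return 4.0 / 3.0 * math.pi * radius**3


def sphere_radius(volume: float) -> float:
    """Radius (μm) of a sphere of ``volume`` μm³."""
    return (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)


def _pgC_to_umolN(quota_pgC: float, consts: PhysicalConstants) -> float:
    # pgC·cell⁻¹ → μgC (×1e-6) → μmolC (/MMC) → μmolN (×16/106)
    return quota_pgC * 1.0e-6 / consts.molar_mass_C * consts.redfield_N_to_C


def phyto_nitrogen_quota(
    spec: OrganismSpec, consts: PhysicalConstants = DEFAULT_CONSTANTS
) -> float:
    """Nitrogen quota of a phytoplankton cell, μmolN·cell⁻¹.

    Diatoms and non-diatom eukaryotes use carbon-content allometries
    (log10 QC[pgC] linear in log10 Vol); cyanobacteria use a constant
    cellular carbon density.  Carbon is converted to nitrogen with the
    Redfield ratio.
    """
    if spec.group not in PHYTO_GROUPS:
        raise ValueError(
            f"phyto_nitrogen_quota needs a phytoplankton group, got {spec.group!r}"
        )
    vol = spec.volume
    if vol is None or vol <= 0:
        raise ValueError("cell volume must be strictly positive")
    if spec.group == "cyanobacteria":
        # d·Vol [fgC] ×1e-9 → μgC → μmolC → μmolN
        return (
            consts.cyanobacterial_carbon_density
            * vol
            * 1.0e-9
            / consts.molar_mass_C
            * consts.redfield_N_to_C
        )
    if spec.group == "diatom":
        q_pgC = 10.0 ** (-0.541 + 0.811 * math.log10(vol))
    else:  # eukaryote_non_diatom
        q_pgC = 10.0 ** (-0.665 + 0.939 * math.log10(vol))
    return _pgC_to_umolN(q_pgC, consts)


def virus_nitrogen_quota(
    radius_nm: float, consts: PhysicalConstants = DEFAULT_CONSTANTS
) -> float:
    """Nitrogen quota of a virion, μmolN·virion⁻¹, from its capsid radius (nm).

    The capsid polynomial 16(rv−2.5)³ + 367.5(rv² − 18.75·rv + 15.63) counts
    nitrogen atoms per virion (genome core plus protein shell); dividing by
    Avogadro's number and scaling to μmol gives the molar quota.  The choice
    of atom counts (rather than a mass) is fixed by requiring the published
    count↔molar concentration pairs for marine virions to round-trip.
    """
    if radius_nm <= 0:
        raise ValueError("virion radius must be strictly positive")
    lo, hi = VIRION_RADIUS_VALID_NM
    if not (lo <= radius_nm <= hi):
        warnings.warn(
            f"virion radius {radius_nm} nm outside validated range "
            f"[{lo}, {hi}] nm; quota extrapolated",
            stacklevel=2,
        )
    atoms = 16.0 * (radius_nm - 2.5) ** 3 + 367.5 * (
        radius_nm**2 - 18.75 * radius_nm + 15.63
    )
    return 1.0e6 * atoms / consts.avogadro


def grazer_nitrogen_quota(
    volume: float, consts: PhysicalConstants = DEFAULT_CONSTANTS
) -> float:
    """Nitrogen quota of a grazer, μmolN·ind⁻¹, from its volume (μm³)."""
    if volume <= 0:
        raise ValueError("grazer volume must be strictly positive")
    q_pgC = 10.0 ** (-0.547 + 0.9 * math.log10(volume))
    return _pgC_to_umolN(q_pgC, consts)


def swimming_speed(radius_cm: float, group: Group) -> float:
    """Swimming speed (m·s⁻¹) of a phytoplankton cell of radius ``radius_cm``.

    Only non-diatom eukaryotes swim (log10 u[cm/s] = 0.4 + 0.8·log10(2r[cm]));
    cyanobacteria and diatoms rely on diffusion alone and return exactly 0.
    """
    if radius_cm <= 0:
        raise ValueError("radius must be strictly positive")
    if group != "eukaryote_non_diatom":
        return 0.0
    u_cm_s = 10.0 ** (0.4 + 0.8 * math.log10(2.0 * radius_cm))
    return u_cm_s * 1.0e-2


def virus_diffusivity(
    radius_nm: float,
    temperature: float = REFERENCE_TEMPERATURE_K,
    consts: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Stokes–Einstein diffusivity of a virion (m²·s⁻¹)."""
    if radius_nm <= 0 or temperature <= 0:
        raise ValueError("radius and temperature must be positive")
    r_m = radius_nm * 1.0e-9
    return consts.boltzmann_constant * temperature / (
        6.0 * math.pi * consts.water_viscosity * r_m
    )


def encounter_rate(
    host: OrganismSpec,
    virion: OrganismSpec,
    env: EnvironmentSpec | None = None,
    consts: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Theoretical virus–host encounter kernel φ_th, L·d⁻¹.

    Smoluchowski diffusive capture 4π(r_p + r_v)·D_v augmented by a
    multiplicative host-swimming factor ½[1 + (1 + 2·u·r_p/D_v)^{1/3}].
    With u = 0 the factor is 1 and the kernel is pure diffusion.
    """
    if host.group not in PHYTO_GROUPS:
        raise ValueError("host must be a phytoplankton group")
    if virion.group != "virus":
        raise ValueError("virion spec must have group 'virus'")
    T = env.temperature if env is not None else REFERENCE_TEMPERATURE_K
    r_host_m = host.radius * 1.0e-6  # μm → m
    r_vir_m = virion.radius * 1.0e-9  # nm → m
    D = virus_diffusivity(virion.radius, T, consts)
    u = swimming_speed(host.radius * 1.0e-4, host.group)  # μm → cm
    swim = 0.5 * (1.0 + (1.0 + 2.0 * u * r_host_m / D) ** (1.0 / 3.0))
    phi_m3_s = 4.0 * math.pi * (r_host_m + r_vir_m) * D * swim
    return phi_m3_s * LITRES_PER_M3 * SECONDS_PER_DAY


def max_growth_rate(group: Group, volume: float) -> float:
    """Maximum growth rate μmax (d⁻¹) of a phytoplankton cell.

    μmax = a_t·Vol^b with a_t ∈ {diatom 3.9, other eukaryote 1.4,
    cyanobacteria 0.8}, b = −0.08 for diatoms/picoeukaryotes and +0.08 for
    cyanobacteria.
    """
    if volume <= 0:
        raise ValueError("volume must be strictly positive")
    try:
        a_t, b = {
            "diatom": (3.9, -0.08),
            "eukaryote_non_diatom": (1.4, -0.08),
            "cyanobacteria": (0.8, 0.08),
        }[group]
    except KeyError:
        raise ValueError(f"unknown phytoplankton group: {group!r}") from None
    return a_t * volume**b


def half_saturation(mu_max: float, allom: UptakeAllometry) -> float:
    """Population growth half-saturation constant Nc = Hc·μmax·Qmin/Umax."""
    if allom.max_uptake == 0:
        raise ValueError("Umax must be non-zero")
    return allom.half_sat_uptake * mu_max * allom.min_quota / allom.max_uptake


def carrying_capacity(env: EnvironmentSpec, mu: float, half_sat: float) -> float:
    """Carrying capacity K (μmolN·L⁻¹) equivalent to a resource–consumer model.

    K = w·(Ndeep − N)·(N + Nc)/(μ·N), the consumer equilibrium at fixed
    surface nutrient concentration N.
    """
    if env.surface_nutrient == 0:
        raise ValueError("surface nutrient N must be > 0 for a carrying capacity")
    if mu == 0:
        raise ValueError("growth rate μ must be > 0")
    N = env.surface_nutrient
    return (
        env.mixing_rate
        * (env.deep_nutrient - N)
        * (N + half_sat)
        / (mu * N)
    )


def growth_limitation(env: EnvironmentSpec, half_sat: float) -> tuple[float, float]:
    """Nutrient and temperature growth-limitation factors of an environment.

    Returns ``(nutrient_factor, temperature_factor)`` with
    nutrient_factor = N/(N + Nc) ∈ (0, 1] and the Eppley-curve factor
    γT = τT·exp(−AT·(1/T − 1/TN)).  The nutrient factor multiplies the
    growth rate only; γT multiplies the growth rate and the mortality
    parameters.
    """
    if half_sat < 0:
        raise ValueError("half saturation must be >= 0")
    N = env.surface_nutrient
    nutrient = N / (N + half_sat) if (N + half_sat) > 0 else 0.0
    gamma_T = env.eppley_scale * math.exp(
        -env.eppley_slope * (1.0 / env.temperature - 1.0 / env.eppley_ref_temp)
    )
    return nutrient, gamma_T
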