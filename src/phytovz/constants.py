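"""Physical constants and unit conventions.

All model-facing quantities use the following currencies:

* concentrations: μmolN·L⁻¹ (molar) or ind·L⁻¹ (counts)
* rates: d⁻¹; volumetric rates: L·d⁻¹
* cell volumes: μm³; cell/grazer radii: μm; virion radii: nm
"""

from __future__ import annotations

from dataclasses import dataclass

#: seconds per day, used for SI → model-unit rate conversions
SECONDS_PER_DAY = 86400.0
#: litres per cubic metre
LITRES_PER_M3 = 1.0e3


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants of the trait layer.

    Attributes
    ----------
    boltzmann_constant : float
        kB in J·K⁻¹.
    water_viscosity : float
        Dynamic viscosity of (surface sea-)water η in Pa·s.
    avogadro : float
        NA in mol⁻¹.
    molar_mass_C, molar_mass_N : float
        Molar masses in g·mol⁻¹.
    cyanobacterial_carbon_density : float
        Cell carbon mass density d in fgC·μm⁻³ (measured on *Synechococcus*,
        consistent with *Prochlorococcus*).
    redfield_N_to_C : float
        Molar N:C Redfield ratio, 16/106.
    """

    boltzmann_constant: float = 1.380649e-23
    water_viscosity: float = 1.0e-3
    avogadro: float = 6.02214076e23
    molar_mass_C: float = 12.011
    molar_mass_N: float = 14.007
    cyanobacterial_carbon_density: float = 470.0
    redfield_N_to_C: float = 16.0 / 106.0

    def __post_init__(self) -> None:
        for name in (
            "boltzmann_constant",
            "water_viscosity",
            "avogadro",
            "molar_mass_C",
            "molar_mass_N",
            "cyanobacterial_carbon_density",
            "redfield_N_to_C",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.redfield_N_to_C >= 1:
            raise ValueError("redfield_N_to_C must be < 1")


#: module-level default constants (T = 293.15 K and η = 1e-3 Pa·s are the
#: reference conditions unless an environment overrides the temperature)
DEFAULT_CONSTANTS = PhysicalConstants()
#: reference temperature (K) for encounter-rate evaluation outside any
#: environment context
REFERENCE_TEMPERATURE_K = 293.15
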