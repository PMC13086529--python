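# Field target count concentrations (ind·L⁻¹) and ecological constraint
# bounds per organism × environment.
#
# Phytoplankton/virus targets are published field values; zooplankton totals
# (1–2×10⁵ ind·L⁻¹) are split 1×10⁵ (oligotrophic) / 2×10⁵ (mesotrophic) for
# the cyanobacteria grazers.  Targets not printed for an organism are
# back-derived from the published best-fit concentration/percent-error pairs
# and rounded to one significant figure (marked BACK-DERIVED).
#
# Constraint bounds (closed intervals, percent): infected cells 0–5
# oligotrophic and 0.5–10 mesotrophic (upper bound relaxed for the diatom),
# virus-induced mortality 0–50, and a virus:phytoplankton count ratio > 1.

targets:
  prochlorococcus:
    oligotrophic:
      P: 1.5e8
      V: 5.0e8
      Z: 1.0e5
      percent_infected_bounds: [0.0, 5.0]
      percent_viral_mortality_bounds: [0.0, 50.0]
      require_VP_above_one: true
      weight: 1.0
    mesotrophic:
      P: 2.0e8
      V: 1.0e9
      Z: 2.0e5
      percent_infected_bounds: [0.5, 10.0]
      percent_viral_mortality_bounds: [0.0, 50.0]
      require_VP_above_one: true
      weight: 1.0
  synechococcus:
    oligotrophic:           # BACK-DERIVED P
      P: 2.0e7
      V: 5.0e8
      Z: 1.0e5
      percent_infected_bounds: [0.0, 5.0]
      percent_viral_mortality_bounds: [0.0, 50.0]
      require_VP_above_one: true
      weight: 1.0
    mesotrophic:            # BACK-DERIVED P
      P: 5.0e7
      V: 1.0e9
      Z: 2.0e5
      percent_infected_bounds: [0.5, 10.0]
      percent_viral_mortality_bounds: [0.0, 50.0]
      require_VP_above_one: true
      weight: 1.0
  picoeukaryote:
    oligotrophic:           # BACK-DERIVED P, V, Z
      P: 1.0e7
      V: 1.0e8
      Z: 1.0e4
      percent_infected_bounds: [0.0, 5.0]
      percent_viral_mortality_bounds: [0.0, 50.0]
      require_VP_above_one: true
      weight: 1.0
    mesotrophic:            # BACK-DERIVED Z
      P: 2.0e7
      V: 2.0e7
      Z: 5.0e4
      percent_infected_bounds: [0.5, 10.0]
      percent_viral_mortality_bounds: [0.0, 50.0]
      require_VP_above_one: true
      weight: 2.0
  diatom:
    oligotrophic:           # BACK-DERIVED P, V, Z
      P: 5.0e5
      V: 2.0e8
      Z: 1.0e4
      percent_infected_bounds: [0.0, 100.0]
      percent_viral_mortality_bounds: [0.0, 50.0]
      require_VP_above_one: true
      weight: 1.0
    mesotrophic:            # BACK-DERIVED Z
      P: 2.0e6
      V: 1.0e9
      Z: 5.0e4
      percent_infected_bounds: [0.5, 100.0]
      percent_viral_mortality_bounds: [0.0, 50.0]
      require_VP_above_one: true
      weight: 2.0
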