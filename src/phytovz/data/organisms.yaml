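# Canonical organism configurations: four phytoplankton types, each with its
# virus and grazer.  Sizes and literature rate constants are inputs; the
# `derived:` blocks are regenerated by the trait layer and stored here only
# for audit (tests assert bit-for-bit agreement).
#
# Units: volumes μm³, cell/grazer radii μm, virion radii nm, rates d⁻¹,
# volumetric rates L·d⁻¹, quadratic mortalities (μmolN·L⁻¹)⁻¹·d⁻¹,
# quotas μmolN·ind⁻¹, concentrations μmolN·L⁻¹.
#
# Entries marked PLACEHOLDER are not pinned by published main-text values;
# they are fixed package defaults chosen once at realistic field magnitudes
# and exposed here for a single-point edit.

shared_defaults:
  dS: 0.1            # PLACEHOLDER linear host mortality
  dV: 0.06           # linear viral decay; bracketed by the predator-exchange
                     # adsorption threshold of the instantaneous-burst model
  dV2: 0.0           # quadratic viral loss is off by default (sweeps enable it)
  dV2_reference: 1400.0  # PLACEHOLDER field-fitted quadratic viral loss
  gZ: 9.8            # grazing clearance rate
  epsZ: 0.3          # grazer gross growth efficiency
  dZ: 0.067          # linear grazer mortality
  dZ2: 0.0           # quadratic grazer loss off by default
  dZ2_reference: 1.4 # field closure value used when quadratic grazing is on
  K: 1.0             # PLACEHOLDER carrying capacity without environment factors
  tauK: 1.0          # PLACEHOLDER carrying-capacity relaxation time (d)
  r: 1.0e-7          # PLACEHOLDER S<->R mutation fraction
  zeta: 0.8          # resistant-type growth retention (20% cost of resistance)
  gamma: 0.5         # PLACEHOLDER lysate shunt (DON) fraction
  uptake:
    half_sat_uptake: 0.05      # PLACEHOLDER Hc, μmolN·L⁻¹
    min_quota_fraction: 0.5    # PLACEHOLDER Qmin as a fraction of Qp
    max_uptake_per_day_quota: 1.0  # PLACEHOLDER Umax = this × μmax × Qmin

organisms:
  prochlorococcus:
    group: cyanobacteria
    volume_um3: 0.1
    virion_radius_nm: 35.0
    grazer_radius_um: 2.5
    beta: 15.0         # burst size from the life-history trait model
    tau_d: 0.37        # latent period from the life-history trait model
    uptake: {half_sat_uptake: 0.02, min_quota_fraction: 0.5, max_uptake_per_day_quota: 1.0}
  synechococcus:
    group: cyanobacteria
    volume_um3: 1.0
    virion_radius_nm: 40.0
    grazer_radius_um: 2.5
    beta: 30.0         # PLACEHOLDER
    tau_d: 0.45        # PLACEHOLDER
    uptake: {half_sat_uptake: 0.05, min_quota_fraction: 0.5, max_uptake_per_day_quota: 1.0}
  picoeukaryote:
    group: eukaryote_non_diatom
    volume_um3: 4.19
    virion_radius_nm: 60.0
    grazer_radius_um: 5.0
    beta: 400.0        # PLACEHOLDER
    tau_d: 0.7         # PLACEHOLDER
    uptake: {half_sat_uptake: 0.1, min_quota_fraction: 0.5, max_uptake_per_day_quota: 1.0}
  diatom:
    group: diatom
    volume_um3: 65.45
    virion_radius_nm: 20.0
    grazer_radius_um: 5.0
    beta: 50.0         # PLACEHOLDER
    tau_d: 1.0         # PLACEHOLDER
    uptake: {half_sat_uptake: 0.3, min_quota_fraction: 0.5, max_uptake_per_day_quota: 1.0}

# Derived constants regenerated by the trait layer (audit copies;
# tests assert bit-for-bit agreement with traits-layer output).
derived:
  prochlorococcus:
    Qp: 5.90653536145326e-10
    Qv: 1.2686678715228171e-12
    Qz: 1.53657131772569e-07
    mu_max: 0.6654110168821368
    phi_th: 2.151052761961346e-09
    Nc: 0.020000000000000004
    host_radius_um: 0.28794119114848615
    grazer_volume_um3: 65.44984694978736
  synechococcus:
    Qp: 5.90653536145326e-09
    Qv: 1.929328906951687e-12
    Qz: 1.53657131772569e-07
    mu_max: 0.8
    phi_th: 3.84866560217229e-09
    Nc: 0.05000000000000001
    host_radius_um: 0.6203504908994001
    grazer_volume_um3: 65.44984694978736
  picoeukaryote:
    Qp: 1.043503519033711e-08
    Qv: 6.570846950777684e-12
    Qz: 9.984669879959598e-07
    mu_max: 1.2483918186274234
    phi_th: 7.294565566701195e-09
    Nc: 0.1
    host_radius_um: 1.0000962631772907
    grazer_volume_um3: 523.5987755982989
  diatom:
    Qp: 1.0738353023286311e-07
    Qv: 1.6718560560514032e-13
    Qz: 9.984669879959598e-07
    mu_max: 2.7912056462033337
    phi_th: 2.9374233686530134e-08
    Nc: 0.3
    host_radius_um: 2.5000019486943117
    grazer_volume_um3: 523.5987755982989
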