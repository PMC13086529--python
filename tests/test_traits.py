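"""Trait-layer unit tests: quotas, kernels, allometries and unit round-trips."""

import math
from decimal import Decimal, getcontext

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phytovz import constants, traits
from phytovz.params import CommunityParams, counts_from_molar, molar_from_counts
from phytovz.scenarios import _load_yaml, derived_traits, organism_names

C = constants.DEFAULT_CONSTANTS


class TestPhytoQuota:
    def test_cyanobacterium_carbon_density_route(self):
        # independent evaluation: 470 fgC/μm³ × 0.1 μm³ → μmolN
        expected = 470.0 * 0.1 * 1e-9 / 12.011 * (16.0 / 106.0)
        spec = traits.OrganismSpec(group="cyanobacteria", volume=0.1)
        assert traits.phyto_nitrogen_quota(spec, C) == pytest.approx(
            expected, rel=1e-14
        )
        assert expected == pytest.approx(5.9065e-10, rel=1e-4)

    def test_diatom_log_allometry_at_unit_volume(self):
        # log10 Vol = 0, so QC = 10^-0.541 pgC exactly
        spec = traits.OrganismSpec(group="diatom", volume=1.0)
        expected = 10 ** (-0.541) * 1e-6 / 12.011 * (16.0 / 106.0)
        assert traits.phyto_nitrogen_quota(spec, C) == pytest.approx(
            expected, rel=1e-14
        )

    @given(
        v1=st.floats(0.01, 1e4),
        factor=st.floats(1.01, 100.0),
        group=st.sampled_from(["cyanobacteria", "eukaryote_non_diatom", "diatom"]),
    )
    @settings(max_examples=50, deadline=None)
    def test_quota_strictly_increasing_in_volume(self, v1, factor, group):
        q1 = traits.phyto_nitrogen_quota(
            traits.OrganismSpec(group=group, volume=v1), C
        )
        q2 = traits.phyto_nitrogen_quota(
            traits.OrganismSpec(group=group, volume=v1 * factor), C
        )
        assert 0 < q1 < q2

    def test_rejects_unknown_group_and_bad_volume(self):
        with pytest.raises(ValueError, match="phytoplankton group"):
            traits.phyto_nitrogen_quota(
                traits.OrganismSpec(group="grazer", volume=1.0), C
            )
        with pytest.raises(ValueError):
            traits.OrganismSpec(group="diatom", volume=-1.0)


class TestVirusQuota:
    def test_high_precision_polynomial(self):
        getcontext().prec = 50
        rv = Decimal(35)
        atoms = 16 * (rv - Decimal("2.5")) ** 3 + Decimal("367.5") * (
            rv**2 - Decimal("18.75") * rv + Decimal("15.63")
        )
        expected = float(Decimal(10) ** 6 * atoms / Decimal("6.02214076e23"))
        assert traits.virus_nitrogen_quota(35.0, C) == pytest.approx(
            expected, rel=1e-14
        )

    def test_monotone_in_radius(self):
        assert traits.virus_nitrogen_quota(70.0, C) > traits.virus_nitrogen_quota(
            35.0, C
        )

    def test_out_of_range_warns_but_returns(self):
        with pytest.warns(UserWarning, match="outside validated range"):
            q = traits.virus_nitrogen_quota(150.0, C)
        assert q > 0

    def test_published_count_molar_pairs_roundtrip(self):
        # marine virion concentrations: 1e-3.4 μmolN/L should correspond to
        # ~1e8.5 virions/L for a cyanophage-sized capsid
        q = traits.virus_nitrogen_quota(35.0, C)
        assert 10 ** (-3.4) / q == pytest.approx(10**8.5, rel=0.15)


class TestGrazerQuota:
    def test_unit_volume(self):
        expected = 10 ** (-0.547) * 1e-6 / 12.011 * (16.0 / 106.0)
        assert traits.grazer_nitrogen_quota(1.0, C) == pytest.approx(
            expected, rel=1e-14
        )

    def test_sphere_route_for_cyanobacteria_grazer(self):
        vol = 4.0 / 3.0 * math.pi * 2.5**3
        assert traits.grazer_nitrogen_quota(
            traits.sphere_volume(2.5), C
        ) == pytest.approx(traits.grazer_nitrogen_quota(vol, C), rel=1e-14)

    def test_power_law_doubling(self):
        q1 = traits.grazer_nitrogen_quota(3.0, C)
        q2 = traits.grazer_nitrogen_quota(6.0, C)
        assert q2 / q1 == pytest.approx(2**0.9, rel=1e-12)


class TestSwimmingAndEncounter:
    def test_non_swimmers_return_zero(self):
        assert traits.swimming_speed(1e-4, "cyanobacteria") == 0.0
        assert traits.swimming_speed(1e-3, "diatom") == 0.0

    def test_eukaryote_empirical_model(self):
        r_cm = 1e-4
        expected = 10 ** (0.4 + 0.8 * math.log10(2 * r_cm)) * 1e-2
        assert traits.swimming_speed(r_cm, "eukaryote_non_diatom") == pytest.approx(
            expected, rel=1e-14
        )
        assert traits.swimming_speed(
            2e-4, "eukaryote_non_diatom"
        ) > traits.swimming_speed(1e-4, "eukaryote_non_diatom")

    def test_smoluchowski_limit_without_swimming(self):
        host = traits.OrganismSpec(group="cyanobacteria", volume=0.1)
        virion = traits.OrganismSpec(group="virus", radius=35.0)
        D = traits.virus_diffusivity(35.0, 293.15, C)
        expected = (
            4.0
            * math.pi
            * (host.radius * 1e-6 + 35e-9)
            * D
            * 1e3
            * 86400.0
        )
        assert traits.encounter_rate(host, virion, None, C) == pytest.approx(
            expected, rel=1e-14
        )

    def test_kernel_temperature_and_viscosity_structure(self):
        host = traits.OrganismSpec(group="cyanobacteria", volume=0.1)
        virion = traits.OrganismSpec(group="virus", radius=35.0)
        warm = traits.EnvironmentSpec("w", 2.0, 0.1, 0.1, 303.15)
        cold = traits.EnvironmentSpec("c", 2.0, 0.1, 0.1, 283.15)
        assert traits.encounter_rate(host, virion, warm, C) > traits.encounter_rate(
            host, virion, cold, C
        )
        thick = constants.PhysicalConstants(water_viscosity=2e-3)
        assert traits.encounter_rate(host, virion, None, thick) < (
            traits.encounter_rate(host, virion, None, C)
        )


class TestGrowthAndEnvironment:
    @pytest.mark.parametrize(
        "group,vol,expected",
        [("cyanobacteria", 1.0, 0.8), ("diatom", 1.0, 3.9),
         ("eukaryote_non_diatom", 1.0, 1.4)],
    )
    def test_unit_volume_rates(self, group, vol, expected):
        assert traits.max_growth_rate(group, vol) == expected

    def test_allometric_slopes(self):
        assert traits.max_growth_rate("diatom", 100.0) < 3.9
        assert traits.max_growth_rate("cyanobacteria", 10.0) > 0.8

    def test_half_saturation_identity_and_linearity(self):
        allom = traits.UptakeAllometry(1.0, 1.0, 1.0)
        assert traits.half_saturation(1.0, allom) == 1.0
        assert traits.half_saturation(2.0, allom) == 2.0

    def test_carrying_capacity_limits(self):
        env = traits.EnvironmentSpec("x", 2.0, 2.0, 0.1, 293.15)
        assert traits.carrying_capacity(env, 0.5, 0.1) == 0.0
        env1 = traits.EnvironmentSpec("x", 2.0, 0.1, 0.1, 293.15)
        env2 = traits.EnvironmentSpec("x", 2.0, 0.1, 0.2, 293.15)
        assert traits.carrying_capacity(env2, 0.5, 0.1) == pytest.approx(
            2 * traits.carrying_capacity(env1, 0.5, 0.1)
        )

    def test_growth_limitation_anchors(self):
        env = traits.EnvironmentSpec("x", 2.0, 0.1, 0.1, 293.15,
                                     eppley_scale=0.8)
        nut, gT = traits.growth_limitation(env, 0.1)
        assert nut == pytest.approx(0.5)
        assert gT == pytest.approx(0.8)  # T = TN
        nut_sat, _ = traits.growth_limitation(
            traits.EnvironmentSpec("x", 1e9, 1e8, 0.1, 293.15), 0.1
        )
        assert nut_sat == pytest.approx(1.0, abs=1e-8)


class TestUnitRoundTrips:
    def test_count_molar_inversion(self, pro):
        y = np.array([0.1, 0.01, 1e-4, 0.0, 0.05])
        back = molar_from_counts(counts_from_molar(y, pro), pro)
        assert np.allclose(back, y, rtol=1e-12)


class TestConfigRegeneration:
    @pytest.mark.parametrize("organism", list(organism_names()))
    def test_traits_layer_regenerates_stored_constants(self, organism):
        """The YAML `derived:` audit copies must match the trait layer exactly."""
        stored = _load_yaml("organisms.yaml")["derived"][organism]
        fresh = derived_traits(organism)
        for key, val in stored.items():
            assert fresh[key] == val, f"{organism}.{key} drifted"
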