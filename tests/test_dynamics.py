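"""Dynamics tests: right-hand sides, RK4 fidelity, outcome classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phytovz as pv
from phytovz.dynamics import DAYS_PER_YEAR, Trajectory, detect_oscillation
from phytovz.params import CommunityParams, state_vector


def toy_params(**kw):
    base = dict(
        mu=0.6, dS=0.1, phiS=2e-10, Qp=5.9e-10, Qv=1.27e-12, Qz=1.5e-7,
        beta=15.0, tau=0.4, dV=0.06, gZ=9.8, epsZ=0.3, dZ=0.067, K=1.0,
        tauK=1.0,
    )
    base.update(kw)
    return CommunityParams(**base)


class TestRhs:
    @pytest.mark.parametrize("model", ["svz", "sivz", "svrz", "sivrz"])
    def test_zero_state_gives_zero_derivative(self, model):
        p = toy_params(r=1e-7, phiR=1e-11, zeta=0.8)
        assert np.all(pv.rhs(model, np.zeros(5), p) == 0.0)

    def test_svz_host_only_reduces_to_logistic(self):
        p = toy_params()
        s = 0.3
        d = pv.rhs("svz", state_vector(S=s), p)
        assert d[0] == pytest.approx(
            p.mu * s - p.dS * s - s**2 / (p.tauK * p.K), rel=1e-14
        )
        assert np.all(d[1:] == 0.0)

    def test_rhs_vanishes_at_algebraic_interior_state(self, pro_stable_interior):
        """Cross-module oracle: the equilibria module's interior root must
        zero the dynamics module's right-hand side."""
        interior = [
            e for e in pv.sivz_equilibria(pro_stable_interior)
            if e.label == "interior"
        ][0]
        resid = pv.rhs("sivz", interior.state, pro_stable_interior)
        assert np.max(np.abs(resid)) <= 1e-9

    def test_rejects_negative_state_and_model_mismatch(self):
        p = toy_params()
        with pytest.raises(ValueError):
            pv.rhs("svz", np.array([-0.1, 0, 0, 0, 0]), p)
        with pytest.raises(ValueError, match="no infected class"):
            pv.rhs("svz", np.array([0.1, 0.01, 0, 0, 0]), p)

    def test_mutation_exchange_is_antisymmetric(self):
        p = toy_params(r=1e-3, phiR=0.0, zeta=0.8)
        y = state_vector(S=0.1, R=0.05)
        d0 = pv.rhs("svrz", y, p)
        d_nomut = pv.rhs("svrz", y, p.with_(r=0.0))
        exchange_S = d0[0] - d_nomut[0]
        exchange_R = d0[3] - d_nomut[3]
        assert exchange_S == pytest.approx(
            p.mu * p.r * (p.zeta * 0.05 - 0.1), rel=1e-12
        )
        assert exchange_S == pytest.approx(-exchange_R, rel=1e-12)


class TestLysateFluxes:
    def test_anchor_cases(self):
        p = toy_params()
        assert pv.lysate_fluxes(0.0, p).total == 0.0
        assert pv.lysate_fluxes(0.5, p.with_(gamma=1.0)).J_PON == 0.0
        # all lysed nitrogen leaves as virions when β·Qv = Qp
        p_full = p.with_(beta=p.Qp / p.Qv)
        fx = pv.lysate_fluxes(0.5, p_full)
        assert fx.J_DON == pytest.approx(0.0, abs=1e-18)
        assert fx.J_PON == pytest.approx(0.0, abs=1e-18)

    def test_split_and_positivity(self):
        p = toy_params(gamma=0.3)
        fx = pv.lysate_fluxes(0.2, p)
        assert fx.J_DON == pytest.approx(fx.total * 0.3, rel=1e-12)
        assert fx.total >= 0

    def test_nitrogen_budget_of_infected_class_models(self):
        """Term-level conservation audit: growth input μS balances the sum of
        compartment changes, lysate fluxes, basal mortality, viral decay and
        virion adsorption into cells."""
        p = toy_params(gamma=0.4)
        y = state_vector(S=0.05, I=0.01, V=0.002, Z=0.0)
        d = pv.rhs("sivz", y, p)
        fx = pv.lysate_fluxes(y[1], p)
        bottom_up = y[0] ** 2 / (p.tauK * p.K)
        budget = (
            d[0] + d[1] + d[2]
            + fx.total
            + p.dS * (y[0] + y[1])
            + p.dV * y[2]
            + p.phiS / p.Qp * y[0] * y[2]
            + bottom_up
        )
        assert budget == pytest.approx(p.mu * y[0], rel=1e-10)


class TestIntegrator:
    def test_pure_viral_decay_matches_closed_form(self):
        p = toy_params(dV=0.1)
        traj = pv.integrate(
            "svz", p, state_vector(V=1.0), duration=DAYS_PER_YEAR
        )
        expected = np.exp(-0.1 * traj.times)
        err = np.max(np.abs(traj.states[:, 2] - expected) / expected)
        assert err <= 1e-10

    def test_rk4_fourth_order_convergence(self):
        # logistic host growth has a closed form
        p = toy_params()
        r = p.mu - p.dS
        Kc = p.tauK * p.K * r
        s0 = 0.01

        def exact(t):
            return Kc / (1 + (Kc / s0 - 1) * np.exp(-r * t))

        errs = []
        for step in (1.0, 0.5):
            traj = pv.integrate(
                "svz", p, state_vector(S=s0), step=step, duration=15.0
            )
            errs.append(abs(traj.states[-1, 0] - exact(traj.final_time)))
        order = math.log2(errs[0] / errs[1])
        assert 3.5 < order < 4.5

    def test_deterministic(self, pro_coex):
        t1 = pv.integrate("sivz", pro_coex, duration=2 * DAYS_PER_YEAR)
        t2 = pv.integrate("sivz", pro_coex, duration=2 * DAYS_PER_YEAR)
        assert np.array_equal(t1.states, t2.states)

    @given(
        phi=st.floats(1e-12, 1e-8),
        tau=st.floats(0.1, 10.0),
        dv2=st.sampled_from([0.0, 100.0]),
        dz2=st.sampled_from([0.0, 1.4]),
    )
    @settings(max_examples=12, deadline=None)
    def test_nonnegativity_preserved(self, phi, tau, dv2, dz2):
        p = toy_params(phiS=phi, tau=tau, dV2=dv2, dZ2=dz2)
        traj = pv.integrate("sivz", p, duration=2 * DAYS_PER_YEAR)
        assert np.all(traj.states >= 0)


class TestClassification:
    def test_all_zero_trajectory_collapses(self, pro):
        traj = pv.integrate(
            "sivz", pro, np.zeros(5), duration=DAYS_PER_YEAR
        )
        rec = pv.classify_outcome(traj)
        assert rec.collapsed and not any(rec.present.values())

    def test_virus_excluded_at_low_adsorption(self, pro):
        """A nearly non-adsorbing virus dies out while host and grazer persist."""
        traj = pv.integrate("svz", pro.with_(phiS=1e-11))
        rec = pv.classify_outcome(traj)
        assert rec.present["S"] and rec.present["Z"] and not rec.present["V"]

    def test_zooplankton_excluded_at_high_adsorption(self, pro):
        traj = pv.integrate("svz", pro.with_(phiS=3e-10), duration=25 * DAYS_PER_YEAR)
        rec = pv.classify_outcome(traj)
        assert rec.present["V"] and not rec.present["Z"]

    def test_sivz_collapse_at_extreme_virulence(self, pro):
        """Very virulent virus + short latent period drives all tracers out."""
        traj = pv.integrate("sivz", pro.with_(phiS=1e-8, tau=0.37))
        rec = pv.classify_outcome(traj)
        assert rec.collapsed

    def test_mean_mode_is_stricter_than_max(self, pro_coex):
        traj = pv.integrate("sivz", pro_coex)
        rec_max = pv.classify_outcome(traj, mode="max")
        rec_mean = pv.classify_outcome(traj, mode="mean")
        for k in rec_max.present:
            assert rec_max.present[k] or not rec_mean.present[k]


class TestOscillationDetection:
    def _traj(self, series, p):
        times = np.arange(series.size) / 48.0
        states = np.tile(series[:, None], (1, 5)) * np.array(
            [p.Qp, p.Qp, p.Qv, p.Qp, p.Qz]
        )
        return Trajectory("sivz", times, states, 1.0 / 48.0, p)

    def test_constant_series_not_oscillatory(self, pro):
        n = int(DAYS_PER_YEAR * 48) + 1
        assert not detect_oscillation(self._traj(np.full(n, 1e6), pro))

    def test_large_sinusoid_is_oscillatory(self, pro):
        n = int(DAYS_PER_YEAR * 48) + 1
        t = np.arange(n) / 48.0
        series = 1e6 + 1e4 * np.sin(2 * np.pi * t / 30.0)
        assert detect_oscillation(self._traj(series, pro))

    def test_subthreshold_sinusoid_is_not(self, pro):
        n = int(DAYS_PER_YEAR * 48) + 1
        t = np.arange(n) / 48.0
        series = 1e6 + 0.4 * np.sin(2 * np.pi * t / 30.0)
        assert not detect_oscillation(self._traj(series, pro))

    def test_stability_verdict_matches_fourier(self, pro_stable_interior, pro_coex):
        """Eigenvalue-stable runs settle (no oscillation flag); the limit-cycle
        band runs oscillate."""
        stable = pv.integrate("sivz", pro_stable_interior)
        assert not pv.classify_outcome(stable).oscillatory
        cycling = pv.integrate("sivz", pro_coex)
        assert pv.classify_outcome(cycling).oscillatory


class TestRegimeGrid:
    def test_single_cell_grid_reduces_to_classify(self, pro_coex):
        grid = pv.regime_grid(
            "sivz", pro_coex, np.array([pro_coex.phiS]),
            np.array([pro_coex.tau]),
        )
        traj = pv.integrate("sivz", pro_coex, record_every=12)
        rec = pv.classify_outcome(traj)
        assert grid.outcomes[0][0].code == rec.code
        assert grid.coexistence[0, 0] == rec.coexistence()

    def test_long_table_shape(self, pro):
        grid = pv.regime_grid(
            "svz", pro, np.geomspace(1e-11, 1e-9, 3),
            duration=DAYS_PER_YEAR,
        )
        df = grid.to_long_table()
        assert len(df) == 3
        assert set(df.columns) >= {"phiS", "code", "coexistence"}

    def test_quadratic_grazer_loss_opens_low_adsorption_coexistence(self, pro):
        """With grazer quadratic losses the virus persists at adsorption rates
        where it was competitively excluded."""
        p = pro.with_(dZ2=1.4)
        traj = pv.integrate("svz", p.with_(phiS=1e-10), duration=25 * DAYS_PER_YEAR)
        rec = pv.classify_outcome(traj)
        assert rec.coexistence()
        # same adsorption without the quadratic term: virus excluded
        traj0 = pv.integrate(
            "svz", pro.with_(phiS=1e-10), duration=25 * DAYS_PER_YEAR
        )
        assert not pv.classify_outcome(traj0).coexistence()
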