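"""Analytic steady states of the community models and their stability.

The infected-class models admit a small catalogue of steady states: for the
SIVZ model {extinction, host-only, host+grazer, host+virus, full interior};
for the SIVRZ model the same skeleton is doubled by the resistant type,
including δ-states where one host type persists only at trace abundance
through mutation inflow from the other.

Interior states are obtained by reducing the steady-state conditions to a
two-unknown system in (S, Z) — the virus balance fixes V given (S, Z) and
the infection balance fixes I — solved with damped Newton iteration from a
deterministic multistart list.  Every returned state is verified against
the full right-hand side (residual ≤ 1e−9).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .dynamics import rhs
from .params import (
    COMPARTMENTS,
    CommunityParams,
    active_compartments,
    counts_from_molar,
    model_flags,
    state_vector,
)

RESIDUAL_TOL = 1.0e-9
STEADY_INPUT_TOL = 1.0e-6
#: count concentration (ind·L⁻¹) below which a host type is in a δ-state
DELTA_THRESHOLD_COUNT = 10.0


@dataclass
class EquilibriumResult:
    """One steady state with its class label and stability verdict."""

    model_id: str
    label: str
    state: np.ndarray
    max_real_eigenvalue: float
    feasible: bool
    residual: float

    @property
    def stable(self) -> bool:
        return self.feasible and self.max_real_eigenvalue < 0


# ---------------------------------------------------------------------------
# Jacobians


def jacobian(model_id: str, state: np.ndarray, p: CommunityParams) -> np.ndarray:
    """Analytic Jacobian of the model right-hand side, restricted to the
    variant's active compartments."""
    has_i, has_r = model_flags(model_id)
    S, I, V, R, Z = (float(x) for x in state)
    if not has_r:
        R = 0.0
    if not has_i:
        I = 0.0
    a = p.epsV * p.phiS / p.Qv
    aR = p.epsVR * p.phiR / p.Qv
    c = p.phiS / p.Qp
    cR = p.phiR / p.Qp
    b = p.beta * p.Qv / (p.tau * p.Qp) if p.tau > 0 else 0.0
    L = 1.0 / (p.tauK * p.K)
    D0 = p.dS + (1.0 / p.tau if p.tau > 0 else 0.0)

    J = np.zeros((5, 5))
    iS, iI, iV, iR, iZ = range(5)

    J[iS, iS] = p.mu - p.dS - a * V - p.gZ * Z - L * (2 * S + R)
    J[iS, iV] = -a * S
    J[iS, iZ] = -p.gZ * S
    if has_r:
        J[iS, iS] -= p.mu * p.r
        J[iS, iR] = -L * S + p.mu * p.r * p.zeta
        J[iR, iS] = -L * R + p.mu * p.r
        J[iR, iR] = (
            p.mu * p.zeta
            - p.dS
            - L * (S + 2 * R)
            - aR * V
            - p.gZ * Z
            - p.mu * p.r * p.zeta
        )
        J[iR, iV] = -aR * R
        J[iR, iZ] = -p.gZ * R

    if has_i:
        J[iI, iS] = a * V
        J[iI, iI] = -D0 - p.gZ * Z
        J[iI, iV] = a * S + (aR * R if has_r else 0.0)
        J[iI, iZ] = -p.gZ * I
        if has_r:
            J[iI, iR] = aR * V
        J[iV, iS] = -c * V
        J[iV, iI] = b
        J[iV, iV] = -p.dV - c * S - (cR * R if has_r else 0.0) - 2 * p.dV2 * V
        if has_r:
            J[iV, iR] = -cR * V
    else:
        J[iV, iS] = (p.beta * p.epsV - 1.0) * c * V
        J[iV, iV] = (
            (p.beta * p.epsV - 1.0) * c * S
            + ((p.beta * p.epsVR - 1.0) * cR * R if has_r else 0.0)
            - p.dV
            - 2 * p.dV2 * V
        )
        if has_r:
            J[iV, iR] = (p.beta * p.epsVR - 1.0) * cR * V

    grazed = S + I + R
    J[iZ, iS] = p.epsZ * p.gZ * Z
    if has_i:
        J[iZ, iI] = p.epsZ * p.gZ * Z
    if has_r:
        J[iZ, iR] = p.epsZ * p.gZ * Z
    J[iZ, iZ] = p.epsZ * p.gZ * grazed - p.dZ - 2 * p.dZ2 * Z

    idx = [COMPARTMENTS.index(n) for n in active_compartments(model_id)]
    return J[np.ix_(idx, idx)]


def finite_difference_jacobian(
    model_id: str, state: np.ndarray, p: CommunityParams, eps: float = 1.0e-7
) -> np.ndarray:
    """Central-difference Jacobian used to cross-check the analytic one."""
    idx = [COMPARTMENTS.index(n) for n in active_compartments(model_id)]
    y0 = np.asarray(state, dtype=float)
    n = len(idx)
    J = np.zeros((n, n))
    for col, k in enumerate(idx):
        h = eps * max(1.0, abs(y0[k]))
        yp, ym = y0.copy(), y0.copy()
        yp[k] += h
        ym[k] = max(ym[k] - h, 0.0)
        fp = rhs(model_id, yp, p)[idx]
        fm = rhs(model_id, ym, p)[idx]
        J[:, col] = (fp - fm) / (yp[k] - ym[k])
    return J


def jacobian_stability(
    model_id: str, p: CommunityParams, state: np.ndarray
) -> float:
    """Spectral abscissa (largest real eigenvalue part) of the Jacobian at a
    steady state.  Rejects inputs whose residual exceeds the steady tolerance."""
    res = float(np.max(np.abs(rhs(model_id, state, p))))
    if res > STEADY_INPUT_TOL:
        raise ValueError(
            f"state is not steady (|rhs| = {res:.3e} > {STEADY_INPUT_TOL:.0e})"
        )
    eigs = np.linalg.eigvals(jacobian(model_id, state, p))
    return float(np.max(eigs.real))


# ---------------------------------------------------------------------------
# SIVZ steady states


def _state(S=0.0, I=0.0, V=0.0, R=0.0, Z=0.0) -> np.ndarray:
    """Pack possibly-infeasible (negative) roots without validation."""
    return np.array([S, I, V, R, Z], dtype=np.float64)


def _result(model_id, label, y, p) -> EquilibriumResult:
    y = np.where(np.abs(y) < 1e-30, 0.0, y)
    feasible = bool(np.all(y >= 0))
    residual = float(np.max(np.abs(rhs(model_id, np.clip(y, 0, None), p)))) if feasible else np.inf
    if feasible and residual <= STEADY_INPUT_TOL:
        lam = float(
            np.max(np.linalg.eigvals(jacobian(model_id, y, p)).real)
        )
    else:
        lam = np.nan
    return EquilibriumResult(
        model_id=model_id,
        label=label,
        state=y,
        max_real_eigenvalue=lam,
        feasible=feasible,
        residual=residual,
    )


def _sz_state(p: CommunityParams):
    """Host–grazer steady state (V = I = 0)."""
    L = 1.0 / (p.tauK * p.K)
    if p.dZ2 == 0:
        S = p.dZ / (p.epsZ * p.gZ)
        Z = (p.mu - p.dS - L * S) / p.gZ
    else:
        S = (p.mu - p.dS + p.gZ * p.dZ / p.dZ2) / (
            L + p.epsZ * p.gZ**2 / p.dZ2
        )
        Z = (p.epsZ * p.gZ * S - p.dZ) / p.dZ2
    return S, Z


def _siv_state(p: CommunityParams):
    """Host–virus steady state of the infected-class model (Z = 0)."""
    a = p.epsV * p.phiS / p.Qv
    b = p.beta * p.Qv / (p.tau * p.Qp)
    c = p.phiS / p.Qp
    L = 1.0 / (p.tauK * p.K)
    D0 = p.dS + 1.0 / p.tau
    if p.dV2 == 0:
        den = a * b - D0 * c
        if den <= 0:
            return None
        S = D0 * p.dV / den
    else:
        den = a * b / D0 - c + p.dV2 * L / a
        if den <= 0:
            return None
        S = (p.dV + p.dV2 * (p.mu - p.dS) / a) / den
    V = (p.mu - p.dS - L * S) / a
    I = a * S * V / D0
    return S, I, V


def _sivz_interior(p: CommunityParams, starts=None):
    """Full interior state via damped Newton on the reduced (S, Z) system."""
    a = p.epsV * p.phiS / p.Qv
    b = p.beta * p.Qv / (p.tau * p.Qp)
    c = p.phiS / p.Qp
    L = 1.0 / (p.tauK * p.K)
    D0 = p.dS + 1.0 / p.tau

    def unpack(S, Z):
        with np.errstate(all="ignore"):
            V = (p.mu - p.dS - p.gZ * Z - L * S) / a
            I = a * S * V / (D0 + p.gZ * Z)
        return V, I

    def F(x):
        S, Z = x
        V, I = unpack(S, Z)
        f1 = a * b * S - (D0 + p.gZ * Z) * (p.dV + c * S + p.dV2 * V)
        if p.dZ2 > 0:
            f2 = p.epsZ * p.gZ * (S + I) - p.dZ - p.dZ2 * Z
        else:
            f2 = p.epsZ * p.gZ * (S + I) - p.dZ
        return np.array([f1, f2])

    S_sz, Z_sz = _sz_state(p)
    if starts is None:
        starts = [
            (S_sz, max(Z_sz, 1e-8)),
            (0.5 * S_sz, 0.5 * max(Z_sz, 1e-8)),
            (2.0 * S_sz, 0.1 * max(Z_sz, 1e-8)),
            (0.1 * S_sz, max(Z_sz, 1e-8)),
        ]
        siv = _siv_state(p)
        if siv is not None and siv[0] > 0:
            starts += [
                (siv[0], 1e-6),
                (siv[0], 0.3 * max(Z_sz, 1e-6)),
                (0.5 * (siv[0] + S_sz), 0.5 * max(Z_sz, 1e-8)),
            ]
        starts += [
            (f * S_sz, z * max(Z_sz, 1e-8))
            for f in (0.03, 0.3, 3.0)
            for z in (0.03, 0.3, 3.0)
        ]
    for x0 in starts:
        if x0[0] <= 0:
            continue
        sol = optimize.root(F, np.array(x0, dtype=float), method="hybr",
                            options={"xtol": 1e-13})
        if not sol.success:
            continue
        S, Z = sol.x
        V, I = unpack(S, Z)
        if min(S, I, V, Z) <= 0:
            continue
        return S, I, V, Z
    return None


def sivz_equilibria(p: CommunityParams, case: str | None = None):
    """All feasible steady states of the infected-class host–virus–grazer
    model, residual-verified.

    ``case`` optionally asserts the quadratic-mortality configuration
    (``'dV2=0,dZ2>0'`` or ``'dV2>0,dZ2>0'``); a mismatch with ``p`` raises.
    Infeasible class roots are returned with ``feasible=False`` so callers
    can see why a class is absent.
    """
    p.validate("sivz")
    if case is not None:
        want_v2 = ">0" in case.split(",")[0]
        want_z2 = ">0" in case.split(",")[1] if "," in case else True
        if want_v2 != (p.dV2 > 0) or want_z2 != (p.dZ2 > 0):
            raise ValueError(f"case {case!r} inconsistent with params")
    L = 1.0 / (p.tauK * p.K)
    out = [_result("sivz", "extinction", _state(), p)]

    S_only = (p.mu - p.dS) / L
    out.append(_result("sivz", "S_only", _state(S=S_only), p))

    S, Z = _sz_state(p)
    out.append(_result("sivz", "SZ", _state(S=S, Z=Z), p))

    siv = _siv_state(p)
    if siv is not None:
        out.append(
            _result("sivz", "SIV", _state(S=siv[0], I=siv[1], V=siv[2]), p)
        )
    interior = _sivz_interior(p)
    if interior is not None:
        S, I, V, Z = interior
        out.append(_result("sivz", "interior", _state(S=S, I=I, V=V, Z=Z), p))
    return out


# ---------------------------------------------------------------------------
# SIVRZ steady states


_SIVRZ_LABELS = {
    # (S level, V present, R level, Z present) -> catalogue label
    ("*", True, "*", True): "SIVRZ_interior",
    ("*", True, "d", True): "SIVZ_dR",
    ("d", True, "*", True): "dS_IVRZ",
    ("*", True, "d", False): "SIV_dR",
    ("*", True, "*", False): "SIVR",
    ("d", True, "*", False): "dS_IVR",
    ("*", False, "d", True): "SZ_dR",
    ("d", False, "*", True): "dS_RZ",
    ("*", False, "d", False): "S_dR",
    ("d", False, "*", False): "dS_R",
}


def _classify_sivrz_state(y, p, delta_threshold):
    counts = counts_from_molar(y, p)
    S_c, _, V_c, R_c, Z_c = counts
    if max(counts) <= 1.0:
        return "extinction"
    s_lvl = "d" if S_c < delta_threshold else "*"
    r_lvl = "d" if R_c < delta_threshold else "*"
    v = V_c > 1.0
    z = Z_c > 1.0
    return _SIVRZ_LABELS.get((s_lvl, v, r_lvl, z), f"other({s_lvl},{v},{r_lvl},{z})")


def _sivrz_starts(p: CommunityParams):
    """Deterministic multistart seeds biased towards each catalogue class."""
    starts = []
    # S-dominant seeds from the SIVZ problem (R slaved to mutation inflow)
    for eq in sivz_equilibria(p.with_(phiR=0.0, r=0.0, env_label=None)):
        if not eq.feasible:
            continue
        S, I, V, _, Z = eq.state
        if S <= 0:
            continue
        R = p.r * S * 10.0
        starts.append([S, max(I, 0.0), max(V, 0.0), R, max(Z, 0.0)])
    # R-dominant seeds: solve the mirrored problem where the resistant type
    # plays host (growth μζ, adsorption φR, infection probability εVR)
    mirrored = p.with_(
        mu=p.mu * p.zeta, phiS=p.phiR, epsV=p.epsVR, phiR=0.0, r=0.0,
        env_label=None,
    )
    if mirrored.phiS > 0:
        mirror_eqs = sivz_equilibria(mirrored)
    else:
        mirror_eqs = sivz_equilibria(mirrored.with_(phiS=1e-30))
    for eq in mirror_eqs:
        if not eq.feasible:
            continue
        R, I, V, _, Z = eq.state
        if R <= 0:
            continue
        S = p.r * R * 10.0
        starts.append([S, max(I, 0.0), max(V, 0.0), R, max(Z, 0.0)])
    # mixed seeds: abundant S *and* R, with the virus sustained by S;
    # needed for the genuinely shared interior states (e.g. full resistance)
    host_scale = p.dZ / (p.epsZ * p.gZ)
    for eq in sivz_equilibria(p.with_(phiR=0.0, r=0.0, env_label=None)):
        if not eq.feasible or eq.state[0] <= 0 or eq.state[2] <= 0:
            continue
        S, I, V, _, Z = eq.state
        for R0 in (host_scale, 0.25 * p.K, 4.0 * host_scale):
            starts.append([S, I, V, R0, max(Z, 1e-6)])
            starts.append([S, I, V, R0, 1e-8])
    return starts


def sivrz_equilibria(
    p: CommunityParams,
    case: str | None = None,
    *,
    delta_threshold: float = DELTA_THRESHOLD_COUNT,
):
    """Steady states of the resistant-type infected-class model.

    All catalogue classes are attempted from deterministic class-biased
    seeds; roots are residual-verified, de-duplicated and labelled by the
    presence pattern of each compartment (δ meaning below the trace-abundance
    threshold in count units).  With ``r = 0`` the system reduces exactly to
    the SIVZ catalogue.
    """
    p.validate("sivrz")
    if case is not None:
        want_v2 = ">0" in case.split(",")[0]
        if want_v2 != (p.dV2 > 0):
            raise ValueError(f"case {case!r} inconsistent with params")
    out = [_result("sivrz", "extinction", _state(), p)]
    idx = [0, 1, 2, 3, 4]

    def full_rhs(x):
        y = np.clip(x, 0.0, None)
        return rhs("sivrz", y, p)

    found: list[np.ndarray] = []
    for x0 in _sivrz_starts(p):
        sol = optimize.root(full_rhs, np.array(x0, dtype=float), method="hybr",
                            options={"xtol": 1e-13})
        if not sol.success:
            continue
        y = np.clip(sol.x, 0.0, None)
        if float(np.max(np.abs(rhs("sivrz", y, p)))) > STEADY_INPUT_TOL:
            continue
        if any(np.allclose(y, f, rtol=1e-6, atol=1e-14) for f in found):
            continue
        found.append(y)
    for y in found:
        label = _classify_sivrz_state(y, p, delta_threshold)
        out.append(_result("sivrz", label, y, p))
    return out


# ---------------------------------------------------------------------------
# attained-state classification


def classify_attained_state(
    traj,
    equilibria: list,
    *,
    delta_threshold: float = DELTA_THRESHOLD_COUNT,
) -> str:
    """Label a finished trajectory with its nearest feasible equilibrium class.

    Distance is relative Euclidean between the final-year mean state and each
    feasible equilibrium; compartment presence flags break ties.
    """
    sel = traj.final_year()
    mean_state = traj.states[sel].mean(axis=0)
    present = counts_from_molar(mean_state, traj.params) > 1.0
    best_label, best_dist = "extinction", np.inf
    for eq in equilibria:
        if not eq.feasible:
            continue
        scale = np.maximum(np.abs(eq.state), np.abs(mean_state))
        scale[scale == 0] = 1.0
        dist = float(np.linalg.norm((eq.state - mean_state) / scale))
        eq_present = counts_from_molar(eq.state, traj.params) > 1.0
        if np.array_equal(eq_present, present):
            dist *= 0.5  # presence agreement wins ties
        if dist < best_dist:
            best_label, best_dist = eq.label, dist
    return best_label
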