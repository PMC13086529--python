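"""JIT-compiled numerical cores: model right-hand sides and the fixed-step
RK4 integrator.

The state layout is the canonical 5-vector ``[S, I, V, R, Z]`` in
μmolN·L⁻¹ and the parameter vector follows
:data:`phytovz.params.PARAM_ORDER`.  Model variants are selected with the
two boolean flags ``has_i`` (explicit infected class) and ``has_r``
(resistant type).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# indices into the packed parameter vector (see params.PARAM_ORDER)
_MU, _DS, _PHIS, _PHIR, _EPSV, _EPSVR, _TAU, _BETA, _DV, _DV2 = range(10)
_GZ, _EPSZ, _DZ, _DZ2, _K, _TAUK, _R, _ZETA, _GAMMA, _QP, _QV, _QZ = range(10, 22)


@njit(cache=False)
def rhs_core(y, par, has_i, has_r, out):
    """Time derivative of the 5-compartment state, written into ``out``."""
    S, I, V, R, Z = y[0], y[1], y[2], y[3], y[4]
    mu = par[_MU]
    dS = par[_DS]
    phiS = par[_PHIS]
    phiR = par[_PHIR]
    epsV = par[_EPSV]
    epsVR = par[_EPSVR]
    tau = par[_TAU]
    beta = par[_BETA]
    dV = par[_DV]
    dV2 = par[_DV2]
    gZ = par[_GZ]
    epsZ = par[_EPSZ]
    dZ = par[_DZ]
    dZ2 = par[_DZ2]
    K = par[_K]
    tauK = par[_TAUK]
    r = par[_R]
    zeta = par[_ZETA]
    Qp = par[_QP]
    Qv = par[_QV]

    R_eff = R if has_r else 0.0
    lim = (S + R_eff) / (tauK * K)  # shared bottom-up control, d⁻¹

    infS = epsV * phiS / Qv * S * V       # successful infections of S
    adsS = phiS / Qp * S * V              # viral loss by adsorption to S
    infR = epsVR * phiR / Qv * R * V if has_r else 0.0
    adsR = phiR / Qp * R * V if has_r else 0.0

    dSdt = mu * S - dS * S - infS - gZ * Z * S - lim * S
    if has_r:
        dSdt += mu * r * (zeta * R - S)
        dRdt = (
            mu * zeta * R
            - dS * R
            - lim * R
            - infR
            - gZ * Z * R
            + mu * r * (S - zeta * R)
        )
    else:
        dRdt = 0.0

    if has_i:
        dIdt = infS + infR - dS * I - I / tau - gZ * Z * I
        dVdt = (
            beta / tau * (Qv / Qp) * I - dV * V - adsS - adsR - dV2 * V * V
        )
    else:
        dIdt = 0.0
        # without an I class the burst is instantaneous upon infection
        dVdt = (
            beta * epsV * phiS / Qp * S * V
            + (beta * epsVR * phiR / Qp * R * V if has_r else 0.0)
            - dV * V
            - adsS
            - adsR
            - dV2 * V * V
        )

    grazed = S + (I if has_i else 0.0) + R_eff
    dZdt = epsZ * gZ * grazed * Z - dZ * Z - dZ2 * Z * Z

    out[0] = dSdt
    out[1] = dIdt
    out[2] = dVdt
    out[3] = dRdt
    out[4] = dZdt


@njit(cache=False)
def rk4_integrate_core(y0, par, has_i, has_r, dt, n_steps, record_every):
    """Classical fixed-step RK4 with post-step clipping at zero.

    Records the state every ``record_every`` steps (including the initial
    state).  Returns ``(states, n_clip, bad_step)`` where ``bad_step`` is the
    1-based step index at which a non-finite value first appeared (0 when the
    integration stayed finite; integration stops there).
    """
    n_rec = n_steps // record_every + 1
    states = np.empty((n_rec, 5), dtype=np.float64)
    y = y0.copy()
    states[0] = y
    k1 = np.empty(5)
    k2 = np.empty(5)
    k3 = np.empty(5)
    k4 = np.empty(5)
    yt = np.empty(5)
    n_clip = 0
    bad_step = 0
    rec = 1
    for step in range(1, n_steps + 1):
        rhs_core(y, par, has_i, has_r, k1)
        for j in range(5):
            yt[j] = y[j] + 0.5 * dt * k1[j]
        rhs_core(yt, par, has_i, has_r, k2)
        for j in range(5):
            yt[j] = y[j] + 0.5 * dt * k2[j]
        rhs_core(yt, par, has_i, has_r, k3)
        for j in range(5):
            yt[j] = y[j] + dt * k3[j]
        rhs_core(yt, par, has_i, has_r, k4)
        finite = True
        for j in range(5):
            y[j] = y[j] + dt / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
            if y[j] < 0.0:
                y[j] = 0.0
                n_clip += 1
            if not np.isfinite(y[j]):
                finite = False
        if not finite:
            bad_step = step
            break
        if step % record_every == 0:
            states[rec] = y
            rec += 1
    if bad_step != 0:
        # truncate records at the last finite state
        states = states[:rec]
    return states, n_clip, bad_step
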