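"""Equilibrium-based grid-search fitting to field target concentrations.

The searched dimensions are the virus–host interaction and mortality
parameters that field data constrain least directly: the (fitted) adsorption
rate, the intracellular resistance (inverse infection probability), the
growth cost of resistance, and the linear/quadratic predator mortalities.
Each parameter combination is scored by the coexistence steady state of the
infected-class model in every environment — computed with a vectorised
damped-Newton solve of the reduced (S, Z) system — and ranked by the
weighted mean of the per-environment total absolute relative errors to the
target concentrations, subject to the ecological constraint screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import TargetSet
from .params import CommunityParams

_FIT_DIMS = ("phi", "intracellular_resistance", "cost", "dV", "dV2", "dZ2")


@dataclass
class SearchSpace:
    """Grids over the fitted dimensions.

    Keys: ``phi`` (adsorption rate, L·d⁻¹), ``intracellular_resistance``
    (1/εVR ≥ 1), ``cost`` (1 − ζ ∈ [0, 0.5]), ``dV`` (d⁻¹), ``dV2``, ``dZ2``
    (quadratic units).  Grids are reproducible from point counts and the
    log/linear spacing rule; ``extra_points`` lets callers pin specific
    values into a dimension.
    """

    grids: dict

    @classmethod
    def default(
        cls,
        n_log: int = 8,
        n_lin: int = 6,
        extra_points: dict | None = None,
        include_zero_dV2: bool = True,
    ) -> "SearchSpace":
        grids = {
            "phi": np.geomspace(1e-12, 1e-8, n_log),
            "intracellular_resistance": np.geomspace(1.0, 1e4, n_log),
            "cost": np.linspace(0.0, 0.5, n_lin),
            "dV": np.geomspace(0.01, 1.0, n_log),
            "dV2": np.geomspace(10.0, 2000.0, n_log),
            "dZ2": np.linspace(2.0, 30.0, n_lin),
        }
        if include_zero_dV2:
            grids["dV2"] = np.concatenate([[0.0], grids["dV2"]])
        for dim, pts in (extra_points or {}).items():
            grids[dim] = np.unique(np.concatenate([grids[dim], np.atleast_1d(pts)]))
        return cls(grids=grids)

    def combos(self) -> pd.DataFrame:
        mesh = np.meshgrid(*(self.grids[d] for d in _FIT_DIMS), indexing="ij")
        return pd.DataFrame({d: m.ravel() for d, m in zip(_FIT_DIMS, mesh)})


def resistance_factors(p: CommunityParams, phi_th: float) -> tuple:
    """(extracellular, intracellular, total) resistance factors.

    Extracellular resistance is the theoretical encounter kernel over the
    realised adsorption rate; intracellular resistance is the inverse
    infection probability.
    """
    if phi_th is None or not np.isfinite(phi_th):
        raise ValueError("phi_th must be a finite encounter rate")
    phi_fit = p.phiR if p.phiR > 0 else p.phiS
    if phi_fit <= 0:
        return (np.inf, 1.0 / p.epsVR if p.epsVR > 0 else np.inf, np.inf)
    eps = p.epsVR if p.phiR > 0 else p.epsV
    extra = phi_th / phi_fit
    intra = 1.0 / eps if eps > 0 else np.inf
    return (extra, intra, extra * intra)


# ---------------------------------------------------------------------------
# vectorised interior equilibrium of the infected-class model


def _interior_vec(par: dict, max_iter: int = 120):
    """Damped-Newton solve of the reduced (S, Z) interior system, vectorised
    over parameter combinations.  Returns (S, I, V, Z, converged)."""
    mu, dS, phi, eps, tau, beta = (
        par["mu"], par["dS"], par["phi"], par["eps"], par["tau"], par["beta"]
    )
    dV, dV2, gZ, epsZ, dZ, dZ2 = (
        par["dV"], par["dV2"], par["gZ"], par["epsZ"], par["dZ"], par["dZ2"]
    )
    K, tauK, Qp, Qv = par["K"], par["tauK"], par["Qp"], par["Qv"]

    a = eps * phi / Qv
    b = beta * Qv / (tau * Qp)
    c = phi / Qp
    L = 1.0 / (tauK * K)
    D0 = dS + 1.0 / tau

    def residuals(S, Z):
        with np.errstate(all="ignore"):
            denom = D0 + gZ * Z
            V = (mu - dS - gZ * Z - L * S) / a
            I = a * S * V / denom
            f1 = a * b * S - denom * (dV + c * S + dV2 * V)
            f2 = epsZ * gZ * (S + I) - dZ - dZ2 * Z
        return f1, f2, V, I

    # start from the host–grazer state
    S = np.where(
        dZ2 > 0,
        (mu - dS + gZ * dZ / np.where(dZ2 > 0, dZ2, 1.0))
        / (L + epsZ * gZ**2 / np.where(dZ2 > 0, dZ2, 1.0)),
        dZ / (epsZ * gZ),
    )
    Z = np.where(dZ2 > 0, (epsZ * gZ * S - dZ) / np.where(dZ2 > 0, dZ2, 1.0),
                 (mu - dS - L * S) / gZ)
    S = np.clip(S, 1e-30, None)
    Z = np.clip(Z, 1e-12, None)

    hS = 1e-7
    for _ in range(max_iter):
        f1, f2, V, I = residuals(S, Z)
        with np.errstate(all="ignore"):
            dSh = hS * np.maximum(np.abs(S), 1e-12)
            dZh = hS * np.maximum(np.abs(Z), 1e-12)
            f1S, f2S, _, _ = residuals(S + dSh, Z)
            f1Z, f2Z, _, _ = residuals(S, Z + dZh)
            j11 = (f1S - f1) / dSh
            j21 = (f2S - f2) / dSh
            j12 = (f1Z - f1) / dZh
            j22 = (f2Z - f2) / dZh
            det = j11 * j22 - j12 * j21
            det = np.where(np.abs(det) < 1e-300, np.nan, det)
            stepS = (f1 * j22 - f2 * j12) / det
            stepZ = (j11 * f2 - j21 * f1) / det
            # damping: keep the iterate positive
            stepS = np.clip(stepS, -0.9 * np.abs(S) - 1e-30, 0.9 * np.abs(S) + 1e3)
            S_new = S - stepS
            Z_new = Z - stepZ
            S = np.where(np.isfinite(S_new) & (S_new > 0), S_new, S * 0.5)
            Z = np.where(np.isfinite(Z_new) & (Z_new > 0), Z_new, Z * 0.5)
    f1, f2, V, I = residuals(S, Z)
    scale1 = np.maximum(np.abs(a * b * S), 1e-30)
    scale2 = np.maximum(np.abs(dZ), 1e-30)
    converged = (
        np.isfinite(f1)
        & np.isfinite(f2)
        & (np.abs(f1) / scale1 < 1e-8)
        & (np.abs(f2) / scale2 < 1e-6)
    )
    return S, I, V, Z, converged


def _stability_vec(par: dict, S, I, V, Z):
    """Spectral abscissa of the (S, I, V, Z) Jacobian, batched."""
    mu, dS, phi, eps, tau, beta = (
        par["mu"], par["dS"], par["phi"], par["eps"], par["tau"], par["beta"]
    )
    dV, dV2, gZ, epsZ, dZ, dZ2 = (
        par["dV"], par["dV2"], par["gZ"], par["epsZ"], par["dZ"], par["dZ2"]
    )
    K, tauK, Qp, Qv = par["K"], par["tauK"], par["Qp"], par["Qv"]
    a = eps * phi / Qv
    b = beta * Qv / (tau * Qp)
    c = phi / Qp
    L = 1.0 / (tauK * K)
    D0 = dS + 1.0 / tau
    n = np.broadcast(S, Z).size
    J = np.zeros((n, 4, 4))
    J[:, 0, 0] = mu - dS - a * V - gZ * Z - 2 * L * S
    J[:, 0, 2] = -a * S
    J[:, 0, 3] = -gZ * S
    J[:, 1, 0] = a * V
    J[:, 1, 1] = -(D0 + gZ * Z)
    J[:, 1, 2] = a * S
    J[:, 1, 3] = -gZ * I
    J[:, 2, 0] = -c * V
    J[:, 2, 1] = b
    J[:, 2, 2] = -dV - c * S - 2 * dV2 * V
    J[:, 3, 0] = epsZ * gZ * Z
    J[:, 3, 1] = epsZ * gZ * Z
    J[:, 3, 3] = epsZ * gZ * (S + I) - dZ - 2 * dZ2 * Z
    bad = ~np.isfinite(J).all(axis=(1, 2))
    J[bad] = 0.0
    eigs = np.linalg.eigvals(J)
    lam = eigs.real.max(axis=1)
    lam[bad] = np.nan
    return lam


def grid_search(
    base_by_env: dict,
    targets_by_env: dict,
    space: SearchSpace | None = None,
    *,
    require_stable: bool = True,
) -> tuple:
    """Score every parameter combination against every environment.

    ``base_by_env`` maps environment name → fully resolved
    :class:`CommunityParams` (environment factors applied); ``targets_by_env``
    maps the same names → :class:`~phytovz.metrics.TargetSet`.  Returns
    ``(ranked, tally)``: a DataFrame of constraint-satisfying combinations in
    ascending weighted-error order, and a per-reason rejection tally.
    Deterministic given the grids.
    """
    space = space or SearchSpace.default()
    combos = space.combos()
    n = len(combos)
    phi = combos["phi"].to_numpy()
    inv_eps = combos["intracellular_resistance"].to_numpy()
    cost = combos["cost"].to_numpy()
    dV = combos["dV"].to_numpy()
    dV2 = combos["dV2"].to_numpy()
    dZ2 = combos["dZ2"].to_numpy()

    ok_all = np.ones(n, dtype=bool)
    tally: dict = {}
    D_by_env = {}
    per_env_cols = {}
    for env, p in base_by_env.items():
        t: TargetSet = targets_by_env[env]
        par = dict(
            mu=p.mu * (1.0 - cost),
            dS=p.dS,
            phi=phi,
            eps=1.0 / inv_eps,
            tau=p.tau,
            beta=p.beta,
            dV=dV,
            dV2=dV2,
            gZ=p.gZ,
            epsZ=p.epsZ,
            dZ=p.dZ,
            dZ2=dZ2,
            K=p.K,
            tauK=p.tauK,
            Qp=p.Qp,
            Qv=p.Qv,
        )
        S, I, V, Z, conv = _interior_vec(par)
        feasible = conv & (S > 0) & (I > 0) & (V > 0) & (Z > 0)
        lam = _stability_vec(par, S, I, V, Z)
        stable = feasible & (lam < 0) if require_stable else feasible

        P_count = (S + I) / p.Qp
        V_count = V / p.Qv
        Z_count = Z / p.Qz
        with np.errstate(all="ignore"):
            pct_I = 100.0 * I / (S + I)
            mV = (I / (S + I)) / p.tau
            mZ = p.gZ * Z
            pct_Vm = 100.0 * mV / (mV + mZ + p.dS)
            vp = V_count / P_count
            D_e = 100.0 * (
                np.abs(P_count - t.targets["P"]) / t.targets["P"]
                + np.abs(V_count - t.targets["V"]) / t.targets["V"]
                + np.abs(Z_count - t.targets["Z"]) / t.targets["Z"]
            )
        lo_i, hi_i = t.percent_infected_bounds
        lo_v, hi_v = t.percent_viral_mortality_bounds
        constraints = (
            (pct_I >= lo_i)
            & (pct_I <= hi_i)
            & (pct_Vm >= lo_v)
            & (pct_Vm <= hi_v)
            & ((vp > 1.0) | (not t.require_VP_above_one))
        )
        tally[f"{env}:infeasible"] = int((~feasible).sum())
        tally[f"{env}:unstable"] = int((feasible & ~(lam < 0)).sum())
        tally[f"{env}:constraints"] = int((stable & ~constraints).sum())
        ok_all &= stable & constraints
        D_by_env[env] = D_e
        per_env_cols.update(
            {
                f"P_count_{env}": P_count,
                f"V_count_{env}": V_count,
                f"Z_count_{env}": Z_count,
                f"percent_infected_{env}": pct_I,
                f"percent_viral_mortality_{env}": pct_Vm,
                f"VP_ratio_{env}": vp,
                f"D_{env}": D_e,
            }
        )

    weights = {env: targets_by_env[env].weight for env in base_by_env}
    wsum = sum(weights.values())
    D_bar = sum(weights[env] * D_by_env[env] for env in base_by_env) / wsum

    table = combos.copy()
    for k, v in per_env_cols.items():
        table[k] = v
    table["D_bar"] = D_bar
    table["accepted"] = ok_all
    tally["accepted"] = int(ok_all.sum())
    ranked = (
        table[table["accepted"]]
        .sort_values("D_bar", kind="mergesort")
        .reset_index(drop=True)
    )
    return ranked, tally


def top_model_statistics(
    ranked: pd.DataFrame, phi_th: float, n: int = 200
) -> dict:
    """Parameter ranges and resistance correlation across the top ``n`` fits.

    The extracellular (φth/φ) vs. intracellular (1/εVR) resistance
    correlation is the product–moment coefficient on log10-transformed
    factors (they span orders of magnitude), with a two-sided t-test p-value.
    """
    if ranked.empty:
        raise ValueError("no accepted fits to summarise")
    top = ranked.head(n)
    flagged_short = len(top) < n
    out = {
        "n_used": len(top),
        "short_of_n": flagged_short,
        "ranges": {
            dim: (float(top[dim].min()), float(top[dim].max()))
            for dim in _FIT_DIMS
        },
        "best": {dim: float(top[dim].iloc[0]) for dim in _FIT_DIMS},
    }
    extra = phi_th / top["phi"].to_numpy()
    intra = top["intracellular_resistance"].to_numpy()
    out["best"]["extracellular_resistance"] = float(extra[0])
    out["best"]["total_resistance"] = float(extra[0] * intra[0])
    out["ranges"]["extracellular_resistance"] = (
        float(extra.min()), float(extra.max())
    )
    out["ranges"]["total_resistance"] = (
        float((extra * intra).min()), float((extra * intra).max())
    )
    if len(top) > 2 and np.ptp(np.log10(extra)) > 0 and np.ptp(np.log10(intra)) > 0:
        r, pval = stats.pearsonr(np.log10(extra), np.log10(intra))
    else:
        r, pval = np.nan, np.nan
    out["resistance_correlation"] = float(r)
    out["resistance_correlation_p"] = float(pval)
    return out
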