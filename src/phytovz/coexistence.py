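"""Invasion analysis and modern coexistence theory (MCT) machinery.

Mutual invasibility (Chesson's criterion) is assessed between the two
predators of the infected-class model: the virus — treated as the coupled
infected-cell/free-virus (I, V) subsystem — invading the host–grazer
resident, and the grazer invading the host–virus resident.  When a resident
fluctuates, invasion growth rates are averaged over one detected periodic
cycle of the susceptible host; the virus rate on a fluctuating resident is
the Floquet exponent of the periodically forced linear (I, V) subsystem.

The MCT decomposition splits each predator's growth rate into a
fluctuation-free part (resources frozen at their cycle means) and
nonlinearity terms (the gain or loss from letting one resource fluctuate at
a time); invader-minus-resident differences of these parts are the
"relative" mechanisms of coexistence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .dynamics import (
    DAYS_PER_YEAR,
    DEFAULT_STEP_D,
    IntegrationDiverged,
    Trajectory,
    classify_outcome,
    integrate,
)
from .params import CommunityParams, state_vector

#: default peak-detection prominence, as a fraction of the series range
PEAK_PROMINENCE_FRACTION = 0.05


@dataclass
class CycleWindow:
    """Index window [start, end] spanning one periodic cycle of S."""

    start: int
    end: int
    is_cycle: bool  # False when the resident is steady (final-year window)

    @property
    def slice(self) -> slice:
        return slice(self.start, self.end + 1)


@dataclass
class InvasionRecord:
    """Growth-rate decomposition of one invader against one resident."""

    invader: str
    resident: str
    replicate: int
    mean_growth: float
    fluctuation_free: float
    nonlinearity_S: float
    nonlinearity_I: float
    interaction: float
    relative_mean: float = np.nan
    relative_fluctuation_free: float = np.nan
    relative_nonlinearity_S: float = np.nan
    relative_nonlinearity_I: float = np.nan

    @property
    def closure_error(self) -> float:
        return abs(
            self.mean_growth
            - (
                self.fluctuation_free
                + self.nonlinearity_S
                + self.nonlinearity_I
                + self.interaction
            )
        )


@dataclass
class MutualInvasibilityResult:
    verdict: str  # 'coexistence' | 'exclusion' | 'not_assessable'
    records: list
    virus_rates: np.ndarray  # NaN where the replicate's resident collapsed
    zoo_rates: np.ndarray
    n_collapsed_replicates: int = 0

    @property
    def all_replicates_positive(self) -> bool:
        """Mutual invasibility in every replicate (collapsed replicates fail)."""
        return bool(
            len(self.virus_rates)
            and self.n_collapsed_replicates == 0
            and np.all(self.virus_rates > 0)
            and np.all(self.zoo_rates > 0)
        )

    @property
    def any_replicate_positive(self) -> bool:
        ok = (self.virus_rates > 0) & (self.zoo_rates > 0)
        return bool(len(self.virus_rates) and np.any(ok[np.isfinite(self.virus_rates)]))


# ---------------------------------------------------------------------------
# per-capita growth rates


def virus_percapita_growth(state: np.ndarray, p: CommunityParams) -> float:
    """Per-capita growth rate of the free virus (d⁻¹):
    (β/τ)(Qv/Qp)(I/V) − dV − (φS/Qp)·S − dV2·V."""
    S, I, V, _, _ = (float(x) for x in state)
    if V <= 0:
        raise ValueError("per-capita virus growth undefined for V = 0")
    return (
        p.beta / p.tau * (p.Qv / p.Qp) * (I / V)
        - p.dV
        - p.phiS / p.Qp * S
        - p.dV2 * V
    )


def zoo_percapita_growth(state: np.ndarray, p: CommunityParams) -> float:
    """Per-capita growth rate of the grazer (d⁻¹): εZ·gZ·(S+I) − dZ − dZ2·Z."""
    S, I, _, _, Z = (float(x) for x in state)
    return p.epsZ * p.gZ * (S + I) - p.dZ - p.dZ2 * Z


# ---------------------------------------------------------------------------
# resident attractors


def resident_cycle(
    S_series: np.ndarray,
    *,
    step: float = DEFAULT_STEP_D,
    prominence_fraction: float = PEAK_PROMINENCE_FRACTION,
    samples_per_year: int | None = None,
) -> CycleWindow:
    """Locate one periodic cycle of S (last full peak-to-peak window).

    The series must cover at least two years past transients.  With no
    detected peaks (steady resident) the final year of the series is
    returned with ``is_cycle=False``.
    """
    S_series = np.asarray(S_series, dtype=float)
    spy = samples_per_year or int(round(DAYS_PER_YEAR / step))
    if S_series.size < 2 * spy:
        raise ValueError("series must cover at least two years")
    rng = S_series.max() - S_series.min()
    if rng <= 0:
        return CycleWindow(S_series.size - spy, S_series.size - 1, False)
    peaks, _ = find_peaks(S_series, prominence=prominence_fraction * rng)
    if len(peaks) < 2:
        return CycleWindow(S_series.size - spy, S_series.size - 1, False)
    return CycleWindow(int(peaks[-2]), int(peaks[-1]), True)


def simulate_resident(
    which: str,
    p: CommunityParams,
    *,
    state0: np.ndarray | None = None,
    duration: float = 20.0 * DAYS_PER_YEAR,
    step: float = DEFAULT_STEP_D,
    keep_years: float = 2.0,
) -> tuple[Trajectory, bool]:
    """Simulate a single-predator resident system.

    ``which`` is 'siv' (virus resident, grazer absent) or 'sz' (grazer
    resident, virus absent).  Returns the trajectory truncated to the last
    ``keep_years`` years (full temporal resolution) and a collapse flag.
    """
    if which == "siv":
        y0 = state0 if state0 is not None else state_vector(
            S=0.5 * p.K, V=1.0e3 * p.Qv
        )
        model = "sivz"
    elif which == "sz":
        y0 = state0 if state0 is not None else state_vector(
            S=0.5 * p.K, Z=1.0e3 * p.Qz
        )
        model = "sivz"
    else:
        raise ValueError("resident must be 'siv' or 'sz'")
    try:
        traj = integrate(model, p, y0, step=step, duration=duration)
    except IntegrationDiverged:
        return None, True
    rec = classify_outcome(traj, p)
    if which == "siv":
        collapsed = not (rec.present.get("S") or rec.present.get("V"))
        # a virus resident that lost its virus is not a usable SIV attractor
        resident_ok = rec.present.get("V", False) and rec.present.get("S", False)
        collapsed = not resident_ok
    else:
        collapsed = not (rec.present.get("S") and rec.present.get("Z"))
    sel = traj.window(traj.final_time - keep_years * DAYS_PER_YEAR)
    short = Trajectory(
        model_id=traj.model_id,
        times=traj.times[sel],
        states=traj.states[sel],
        step=traj.step,
        params=p,
        n_clipped=traj.n_clipped,
    )
    return short, collapsed


# ---------------------------------------------------------------------------
# invasion growth rates


def _iv_jacobian(S: float, Z: float, p: CommunityParams) -> np.ndarray:
    """Jacobian of the rare (I, V) invader subsystem at frozen resident state."""
    D0 = p.dS + 1.0 / p.tau
    a = p.epsV * p.phiS / p.Qv
    b = p.beta * p.Qv / (p.tau * p.Qp)
    return np.array(
        [
            [-D0 - p.gZ * Z, a * S],
            [b, -p.dV - p.phiS / p.Qp * S],
        ]
    )


def virus_invasion_eigenvalue(S: float, Z: float, p: CommunityParams) -> float:
    """Largest real eigenvalue part of the frozen (I, V) subsystem."""
    return float(np.max(np.linalg.eigvals(_iv_jacobian(S, Z, p)).real))


def _floquet_rate(
    S_series: np.ndarray, Z_series: np.ndarray, step: float, p: CommunityParams
) -> float:
    """Dominant Floquet exponent of the periodically forced (I, V) system.

    Integrates the fundamental matrix over one cycle with RK4, sampling the
    forcing on the stored grid (midpoint values by linear interpolation);
    returns log(spectral radius)/T.
    """
    n = S_series.size
    T = (n - 1) * step
    Phi = np.eye(2)
    for k in range(n - 1):
        J0 = _iv_jacobian(S_series[k], Z_series[k], p)
        Jm = _iv_jacobian(
            0.5 * (S_series[k] + S_series[k + 1]),
            0.5 * (Z_series[k] + Z_series[k + 1]),
            p,
        )
        J1 = _iv_jacobian(S_series[k + 1], Z_series[k + 1], p)
        k1 = J0 @ Phi
        k2 = Jm @ (Phi + 0.5 * step * k1)
        k3 = Jm @ (Phi + 0.5 * step * k2)
        k4 = J1 @ (Phi + step * k3)
        Phi = Phi + step / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    rho = float(np.max(np.abs(np.linalg.eigvals(Phi))))
    if rho <= 0:
        return -np.inf
    return float(np.log(rho) / T)


def invasion_growth_rate(
    invader: str, p: CommunityParams, resident_traj: Trajectory
) -> float:
    """Invasion growth rate (d⁻¹) of one predator on the other's attractor.

    * grazer invading: cycle (or final-year) time average of its per-capita
      growth with Z = 0;
    * virus invading: Floquet exponent of the linearised (I, V) subsystem
      over the resident cycle, reducing to the frozen-Jacobian eigenvalue for
      a steady resident.
    """
    S = resident_traj.states[:, 0]
    win = resident_cycle(S, step=resident_traj.step)
    sl = win.slice
    S_w = resident_traj.states[sl, 0]
    I_w = resident_traj.states[sl, 1]
    Z_w = resident_traj.states[sl, 4]
    t_w = resident_traj.times[sl]
    if invader == "zooplankton":
        rates = p.epsZ * p.gZ * (S_w + I_w) - p.dZ
        return float(np.trapezoid(rates, t_w) / (t_w[-1] - t_w[0]))
    if invader == "virus":
        if not win.is_cycle:
            return virus_invasion_eigenvalue(float(S_w.mean()), float(Z_w.mean()), p)
        return _floquet_rate(S_w, Z_w, resident_traj.step, p)
    raise ValueError("invader must be 'virus' or 'zooplankton'")


# ---------------------------------------------------------------------------
# Chesson's mutual invasibility


def chesson_mutual_invasibility(
    p: CommunityParams,
    replicates: int = 10,
    *,
    seed: int = 0,
    duration: float = 20.0 * DAYS_PER_YEAR,
    step: float = DEFAULT_STEP_D,
    ic_spread: float = 1.0,
) -> MutualInvasibilityResult:
    """Chesson's criterion across seeded replicates of the invasion analysis.

    Replicates randomise the resident initial conditions (log-uniformly
    around the defaults, spread ``ic_spread`` in log10 units), which
    randomises the attained attractor near regime borders.  A replicate whose
    virus resident (SIV) collapses is a failed replicate; the verdict is
    ``'not_assessable'`` only when every replicate's SIV resident collapses.
    """
    rng = np.random.default_rng(seed)
    virus_rates, zoo_rates, records = [], [], []
    n_collapsed = 0
    for rep in range(replicates):
        if rep == 0:
            siv0 = sz0 = None
        else:
            f = 10.0 ** rng.uniform(-ic_spread, ic_spread, size=4)
            siv0 = state_vector(S=0.5 * p.K * f[0], V=1.0e3 * p.Qv * f[1])
            sz0 = state_vector(S=0.5 * p.K * f[2], Z=1.0e3 * p.Qz * f[3])
        siv_traj, siv_collapsed = simulate_resident(
            "siv", p, state0=siv0, duration=duration, step=step
        )
        if siv_collapsed:
            n_collapsed += 1
            virus_rates.append(np.nan)
            zoo_rates.append(np.nan)
            continue
        sz_traj, sz_collapsed = simulate_resident(
            "sz", p, state0=sz0, duration=duration, step=step
        )
        if sz_collapsed:
            n_collapsed += 1
            virus_rates.append(np.nan)
            zoo_rates.append(np.nan)
            continue
        mu_z = invasion_growth_rate("zooplankton", p, siv_traj)
        mu_v = invasion_growth_rate("virus", p, sz_traj)
        zoo_rates.append(mu_z)
        virus_rates.append(mu_v)
        records.extend(mct_decomposition(p, siv_traj, replicate=rep))
    virus_rates = np.asarray(virus_rates)
    zoo_rates = np.asarray(zoo_rates)
    if n_collapsed == replicates:
        verdict = "not_assessable"
    else:
        ok = np.isfinite(virus_rates)
        verdict = (
            "coexistence"
            if np.all(virus_rates[ok] > 0) and np.all(zoo_rates[ok] > 0)
            and n_collapsed == 0
            else "exclusion"
        )
    return MutualInvasibilityResult(
        verdict=verdict,
        records=records,
        virus_rates=virus_rates,
        zoo_rates=zoo_rates,
        n_collapsed_replicates=n_collapsed,
    )


# ---------------------------------------------------------------------------
# MCT decomposition


def _zoo_rate_fn(S, I, p):
    return p.epsZ * p.gZ * (S + I) - p.dZ


def _virus_rate_fn(S, Z, p):
    """Frozen-environment growth of the (I, V) subsystem: the dominant
    eigenvalue λ = (tr + sqrt(tr² − 4·det))/2 of the 2×2 Jacobian, which is
    a nonlinear (concave) function of S.  Vectorised over S/Z arrays."""
    S = np.asarray(S, dtype=float)
    Z = np.broadcast_to(np.asarray(Z, dtype=float), S.shape)
    D0 = p.dS + 1.0 / p.tau
    a = p.epsV * p.phiS / p.Qv
    b = p.beta * p.Qv / (p.tau * p.Qp)
    j11 = -D0 - p.gZ * Z
    j22 = -p.dV - p.phiS / p.Qp * S
    tr = j11 + j22
    det = j11 * j22 - a * S * b
    disc = tr * tr - 4.0 * det
    lam = np.where(
        disc >= 0,
        0.5 * (tr + np.sqrt(np.maximum(disc, 0.0))),
        0.5 * tr,
    )
    return lam if lam.shape else float(lam)


def mct_decomposition(
    p: CommunityParams,
    resident_traj: Trajectory,
    *,
    replicate: int = 0,
) -> list:
    """Decompose predator growth rates over one resident cycle.

    The resident is the host–virus (SIV) attractor and the grazer is the
    invader.  For each predator the growth rate is evaluated (i) along the
    fluctuating resources, (ii) with all resources frozen at cycle means
    (fluctuation-free), and (iii) with one resource fluctuating at a time
    (nonlinearity in S, in I); the interaction term closes the budget
    exactly.  Relative components are invader minus resident.
    """
    S = resident_traj.states[:, 0]
    win = resident_cycle(S, step=resident_traj.step)
    sl = win.slice
    S_w = resident_traj.states[sl, 0]
    I_w = resident_traj.states[sl, 1]
    t_w = resident_traj.times[sl]
    T = t_w[-1] - t_w[0]

    def avg(series):
        return float(np.trapezoid(series, t_w) / T)

    S_bar, I_bar = avg(S_w), avg(I_w)

    # grazer (invader, Z -> 0)
    z_mean = avg(_zoo_rate_fn(S_w, I_w, p))
    z_ff = _zoo_rate_fn(S_bar, I_bar, p)
    z_nlS = avg(_zoo_rate_fn(S_w, I_bar, p)) - z_ff
    z_nlI = avg(_zoo_rate_fn(S_bar, I_w, p)) - z_ff
    z_int = z_mean - z_ff - z_nlS - z_nlI

    # virus (resident): frozen-environment subsystem growth, Z = 0
    v_rates = _virus_rate_fn(S_w, 0.0, p)
    v_mean = avg(v_rates)
    v_ff = float(_virus_rate_fn(S_bar, 0.0, p))
    v_nlS = v_mean - v_ff  # S is the only fluctuating resource of this rate
    v_nlI = 0.0
    v_int = 0.0

    zoo = InvasionRecord(
        invader="zooplankton",
        resident="virus",
        replicate=replicate,
        mean_growth=z_mean,
        fluctuation_free=z_ff,
        nonlinearity_S=z_nlS,
        nonlinearity_I=z_nlI,
        interaction=z_int,
        relative_mean=z_mean - v_mean,
        relative_fluctuation_free=z_ff - v_ff,
        relative_nonlinearity_S=z_nlS - v_nlS,
        relative_nonlinearity_I=z_nlI - v_nlI,
    )
    vir = InvasionRecord(
        invader="virus",
        resident="virus",
        replicate=replicate,
        mean_growth=v_mean,
        fluctuation_free=v_ff,
        nonlinearity_S=v_nlS,
        nonlinearity_I=v_nlI,
        interaction=v_int,
    )
    return [zoo, vir]
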