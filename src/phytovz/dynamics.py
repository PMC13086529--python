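"""Model dynamics: right-hand sides, RK4 integration and outcome
classification.

The four variants share the state layout ``[S, I, V, R, Z]``:

* ``svz``   — susceptible host, free virus (instantaneous burst), grazer;
* ``sivz``  — adds an explicit infected class with latent period τ;
* ``svrz``  — adds a (partially) resistant host type fed by mutation;
* ``sivrz`` — both extensions.

Simulations follow the study conditions: 20 model years (25 for the
competitive-exclusion runs of the ``svz`` variant) at a 30-minute RK4 step,
with compartments clipped at zero after each full step.  A compartment is
deemed present when its count concentration exceeds 1 ind·L⁻¹ in the final
year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import rhs_core, rk4_integrate_core
from .params import (
    COMPARTMENTS,
    CommunityParams,
    active_compartments,
    counts_from_molar,
    default_initial_state,
    model_flags,
)

DAYS_PER_YEAR = 365.0
DEFAULT_STEP_D = 1.0 / 48.0  # 30 minutes
#: existence threshold, ind·L⁻¹
PRESENCE_THRESHOLD_COUNT = 1.0
#: oscillation threshold on the amplitude spectrum, ind·L⁻¹
OSCILLATION_THRESHOLD_COUNT = 1.0


@dataclass
class Trajectory:
    """A simulated time series of one model variant.

    ``states`` holds molar concentrations (μmolN·L⁻¹) on the uniform time
    grid ``times`` (days); ``params`` is the parameter snapshot the run used.
    """

    model_id: str
    times: np.ndarray
    states: np.ndarray
    step: float
    params: CommunityParams
    n_clipped: int = 0

    @property
    def final_time(self) -> float:
        return float(self.times[-1])

    def counts(self) -> np.ndarray:
        """State series in count concentrations (ind·L⁻¹)."""
        return counts_from_molar(self.states, self.params)

    def window(self, t_start: float, t_end: float | None = None) -> np.ndarray:
        """Boolean mask selecting samples with t_start <= t <= t_end."""
        if t_end is None:
            t_end = self.final_time
        return (self.times >= t_start) & (self.times <= t_end)

    def final_year(self) -> np.ndarray:
        return self.window(self.final_time - DAYS_PER_YEAR)


@dataclass
class LysateFluxes:
    """Lysis-product fluxes to the dissolved and particulate organic pools."""

    J_DON: float
    J_PON: float

    @property
    def total(self) -> float:
        return self.J_DON + self.J_PON


@dataclass
class OutcomeRecord:
    """Presence/absence and oscillation summary of one simulation."""

    present: dict
    oscillatory: bool
    collapsed: bool

    @property
    def code(self) -> str:
        """Compact regime code, e.g. ``'S*V*Z'`` for full coexistence."""
        if self.collapsed:
            return "0"
        return "".join(k for k, v in self.present.items() if v)

    def coexistence(self) -> bool:
        """Do both predators (V and Z) persist?"""
        return bool(self.present.get("V") and self.present.get("Z"))


def rhs(model_id: str, state: np.ndarray, p: CommunityParams) -> np.ndarray:
    """Time derivative (μmolN·L⁻¹·d⁻¹) of ``state`` under one model variant."""
    has_i, has_r = model_flags(model_id)
    p.validate(model_id)
    y = np.asarray(state, dtype=np.float64)
    if y.shape != (5,):
        raise ValueError("state must be a 5-vector [S, I, V, R, Z]")
    if np.any(y < 0):
        raise ValueError("state components must be non-negative")
    if not has_i and y[1] != 0:
        raise ValueError(f"model {model_id!r} has no infected class but I != 0")
    if not has_r and y[3] != 0:
        raise ValueError(f"model {model_id!r} has no resistant type but R != 0")
    out = np.empty(5)
    rhs_core(y, p.to_array(), has_i, has_r, out)
    return out


def lysate_fluxes(I: float, p: CommunityParams) -> LysateFluxes:
    """Shunt/shuttle fluxes J_DON, J_PON (μmolN·L⁻¹·d⁻¹) from lysis of I.

    The cell nitrogen not packaged into new virions leaves as lysate, split
    γ : (1 − γ) between the dissolved and particulate pools.
    """
    if I < 0:
        raise ValueError("I must be non-negative")
    leak = (1.0 / p.tau - p.beta * p.Qv / (p.tau * p.Qp)) * I
    return LysateFluxes(J_DON=p.gamma * leak, J_PON=(1.0 - p.gamma) * leak)


class IntegrationDiverged(RuntimeError):
    """Raised when a state became non-finite during integration."""


def integrate(
    model_id: str,
    p: CommunityParams,
    state0: np.ndarray | None = None,
    *,
    step: float = DEFAULT_STEP_D,
    duration: float = 20.0 * DAYS_PER_YEAR,
    record_every: int = 1,
) -> Trajectory:
    """Integrate one model variant with classical fixed-step RK4.

    Deterministic given ``(state0, p)``.  States are clipped at zero after
    each full step; a non-finite state aborts with a diagnostic naming the
    step and compartment.
    """
    has_i, has_r = model_flags(model_id)
    p.validate(model_id)
    if step <= 0:
        raise ValueError("step must be positive")
    if state0 is None:
        state0 = default_initial_state(model_id, p)
    y0 = np.asarray(state0, dtype=np.float64)
    if np.any(y0 < 0):
        raise ValueError("initial state must be non-negative")
    n_steps = int(round(duration / step))
    states, n_clip, bad_step = rk4_integrate_core(
        y0, p.to_array(), has_i, has_r, float(step), n_steps, int(record_every)
    )
    if bad_step != 0:
        last = states[-1]
        worst = COMPARTMENTS[int(np.argmax(~np.isfinite(last)))] if not np.all(
            np.isfinite(last)
        ) else "?"
        raise IntegrationDiverged(
            f"non-finite state at step {bad_step} (t = {bad_step * step:.3f} d), "
            f"model {model_id!r}, first bad compartment {worst}"
        )
    times = np.arange(states.shape[0]) * (step * record_every)
    return Trajectory(
        model_id=model_id,
        times=times,
        states=states,
        step=step * record_every,
        params=p,
        n_clipped=int(n_clip),
    )


def classify_outcome(
    traj: Trajectory,
    p: CommunityParams | None = None,
    *,
    threshold: float = PRESENCE_THRESHOLD_COUNT,
    mode: str = "max",
) -> OutcomeRecord:
    """Presence/absence classification over the final simulated year.

    A compartment is present when its count concentration exceeds
    ``threshold`` (ind·L⁻¹) in the final year — by default at any sample
    (``mode='max'``); ``mode='mean'`` uses the final-year mean instead.
    """
    p = p or traj.params
    if traj.final_time < DAYS_PER_YEAR:
        raise ValueError("trajectory must cover at least one year")
    sel = traj.final_year()
    counts = counts_from_molar(traj.states[sel], p)
    stat = counts.max(axis=0) if mode == "max" else counts.mean(axis=0)
    active = active_compartments(traj.model_id)
    present = {
        name: bool(stat[COMPARTMENTS.index(name)] > threshold) for name in active
    }
    collapsed = not any(present.values())
    return OutcomeRecord(
        present=present,
        oscillatory=detect_oscillation(traj),
        collapsed=collapsed,
    )


def detect_oscillation(
    traj: Trajectory,
    *,
    threshold: float = OSCILLATION_THRESHOLD_COUNT,
    compartment: str = "V",
) -> bool:
    """Fourier test for sustained oscillations in the final year.

    Takes the raw (undetrended) final-year series of ``compartment`` in count
    units, removes only the DC component and flags the run oscillatory when
    the largest amplitude-spectrum modulus (2|FFT|/n) exceeds ``threshold``
    ind·L⁻¹.
    """
    sel = traj.final_year()
    idx = COMPARTMENTS.index(compartment)
    quota = {"S": traj.params.Qp, "I": traj.params.Qp, "V": traj.params.Qv,
             "R": traj.params.Qp, "Z": traj.params.Qz}[compartment]
    series = traj.states[sel, idx] / quota
    n = series.size
    if n < 4 or np.all(series == series[0]):
        return False
    spec = np.abs(np.fft.rfft(series)) * 2.0 / n
    return bool(spec[1:].max() > threshold)


@dataclass
class RegimeGrid:
    """Outcome classification over a 2-D parameter grid (axis1 × axis2)."""

    model_id: str
    axis1_name: str
    axis2_name: str
    axis1: np.ndarray
    axis2: np.ndarray
    outcomes: list  # nested [i][j] OutcomeRecord
    coexistence: np.ndarray  # bool (n1, n2)

    def to_long_table(self):
        import pandas as pd

        rows = []
        for i, a1 in enumerate(self.axis1):
            for j, a2 in enumerate(self.axis2):
                rec = self.outcomes[i][j]
                rows.append(
                    {
                        self.axis1_name: a1,
                        self.axis2_name: a2,
                        "code": rec.code,
                        "coexistence": rec.coexistence(),
                        "oscillatory": rec.oscillatory,
                        "collapsed": rec.collapsed,
                    }
                )
        return pd.DataFrame(rows)


def regime_grid(
    model_id: str,
    base: CommunityParams,
    axis1: np.ndarray,
    axis2: np.ndarray | None = None,
    *,
    axis1_name: str = "phiS",
    axis2_name: str = "tau",
    duration: float = 20.0 * DAYS_PER_YEAR,
    step: float = DEFAULT_STEP_D,
    record_every: int = 12,
    state0: np.ndarray | None = None,
) -> RegimeGrid:
    """Classify simulated outcomes over a 2-D parameter grid.

    Each cell runs one full simulation from the default (or given) initial
    state and classifies its outcome.  ``axis2=None`` collapses the grid to a
    single row (useful for the latent-period-free ``svz``/``svrz`` variants).
    """
    axis1 = np.asarray(axis1, dtype=float)
    axis2 = np.asarray(axis2, dtype=float) if axis2 is not None else np.array([np.nan])
    if axis1.ndim != 1 or axis2.ndim != 1:
        raise ValueError("axes must be 1-D")
    if axis1.size > 1 and np.any(np.diff(axis1) <= 0):
        raise ValueError("axis1 must be strictly increasing")
    if axis2.size > 1 and np.any(np.diff(axis2) <= 0):
        raise ValueError("axis2 must be strictly increasing")
    outcomes: list[list[OutcomeRecord]] = []
    coex = np.zeros((axis1.size, axis2.size), dtype=bool)
    for i, a1 in enumerate(axis1):
        row = []
        for j, a2 in enumerate(axis2):
            updates = {axis1_name: float(a1)}
            if not np.isnan(a2):
                updates[axis2_name] = float(a2)
            p = base.with_(**updates)
            try:
                traj = integrate(
                    model_id, p, state0,
                    step=step, duration=duration, record_every=record_every,
                )
                rec = classify_outcome(traj, p)
            except IntegrationDiverged:
                rec = OutcomeRecord(
                    present={k: False for k in active_compartments(model_id)},
                    oscillatory=False,
                    collapsed=True,
                )
            row.append(rec)
            coex[i, j] = rec.coexistence()
        outcomes.append(row)
    return RegimeGrid(
        model_id=model_id,
        axis1_name=axis1_name,
        axis2_name=axis2_name,
        axis1=axis1,
        axis2=axis2,
        outcomes=outcomes,
        coexistence=coex,
    )
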