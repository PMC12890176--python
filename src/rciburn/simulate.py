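"""Trajectory integration, healing-event detection and derived series.

The damaged-fibroblast pool in the surrounding tissue is decoupled from the
rest of the system (its balance has only the two constant first-order loss
rates), so its closed-form exponential is substituted during integration
and the remaining 15 states are integrated with a stiff-capable adaptive
solver.

"Healed" and "debris resolved" are operationalised as the first time the
damage (resp. debris) level drops below a small absolute threshold and
stays below it for a sustained window; the thresholds live in
:class:`EventThresholds` and are deliberately configuration, not biology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .initial import resting_steady_levels
from .model import IDX, N_STATES, STATE_NAMES, Exposure, _rhs
from .parameters import ParameterSet

__all__ = [
    "EventThresholds",
    "SolverOptions",
    "Trajectory",
    "fstd_closed_form",
    "simulate",
    "resolution_times",
    "m1_ratio",
    "damage_peak_time",
    "healed_steady_state",
    "trajectory_to_frame",
    "trajectory_summary",
]

_FSTD = IDX["F_st_d"]
_OTHER = np.array([i for i in range(N_STATES) if i != _FSTD])


@dataclass(frozen=True, slots=True)
class EventThresholds:
    """Thresholds for wound-resolution event detection.

    ``healed_level``/``resolved_level`` are absolute levels on the unitless
    damage and debris variables; a crossing only counts if the level stays
    below threshold for ``sustain_hours`` (guards against solver ripple).
    """

    healed_level: float = 0.02
    resolved_level: float = 0.02
    sustain_hours: float = 12.0

    def __post_init__(self) -> None:
        if min(self.healed_level, self.resolved_level, self.sustain_hours) <= 0:
            raise ValueError("event thresholds must all be > 0")


@dataclass(frozen=True, slots=True)
class SolverOptions:
    """Integrator configuration (stiff-capable by default)."""

    method: str = "LSODA"
    rtol: float = 1e-6
    atol: float = 1e-9
    grid_step_hours: float = 0.1

    def __post_init__(self) -> None:
        if self.method not in ("LSODA", "BDF", "Radau", "RK45", "DOP853"):
            raise ValueError(f"unknown solver method {self.method!r}")
        if self.rtol <= 0 or self.atol <= 0 or self.grid_step_hours <= 0:
            raise ValueError("solver tolerances and grid step must be > 0")


@dataclass(slots=True)
class Trajectory:
    """Dense solution of one scenario.

    ``states`` has one row per time point, columns in the canonical state
    order; ``success`` is False when the integrator failed or produced
    non-finite values (a feasibility verdict input, never an exception).
    """

    times: np.ndarray
    states: np.ndarray
    success: bool
    message: str = ""
    exposure: Exposure | None = None

    def series(self, name: str) -> np.ndarray:
        return self.states[:, IDX[name]]


def fstd_closed_form(t, f0: float, k: float, d: float):
    """Damaged-fibroblast pool ``F0 * exp(-(k + d) t)``.

    ``k`` is the recruitment rate to the wound and ``d`` the decay rate;
    with no source term the pool is a pure exponential, integrated
    analytically instead of numerically.
    """
    if f0 < 0:
        raise ValueError(f"initial level must be >= 0, got {f0}")
    if k <= 0 or d <= 0:
        raise ValueError(f"rates must be > 0, got k={k}, d={d}")
    return f0 * np.exp(-(k + d) * np.asarray(t, dtype=float))


def simulate(
    state0: np.ndarray,
    params: ParameterSet,
    exposure: Exposure,
    horizon_hours: float,
    options: SolverOptions | None = None,
) -> Trajectory:
    """Integrate the system from ``state0`` over ``[0, horizon_hours]``.

    Returns a dense trajectory on a uniform grid.  Integration failures and
    non-finite states are recorded on the returned :class:`Trajectory`
    rather than raised, so feasibility screening can consume them.
    """
    if horizon_hours <= 0:
        raise ValueError(f"horizon must be > 0, got {horizon_hours}")
    if options is None:
        options = SolverOptions()
    state0 = np.asarray(state0, dtype=float)
    if state0.shape != (N_STATES,):
        raise ValueError(f"state0 must have shape ({N_STATES},), got {state0.shape}")

    pv = tuple(params.to_vector().tolist())
    dose = exposure.dose_gy
    fstd0 = state0[_FSTD]
    fstd_rate = params.ksttb_d + params.dfr_d

    def rhs15(t: float, y15: np.ndarray) -> np.ndarray:
        full = np.empty(N_STATES)
        full[_OTHER] = y15
        full[_FSTD] = fstd0 * math.exp(-fstd_rate * t)
        return _rhs(t, full, pv, dose)[_OTHER]

    t_eval = np.arange(0.0, horizon_hours + options.grid_step_hours / 2,
                       options.grid_step_hours)
    t_eval[-1] = min(t_eval[-1], horizon_hours)
    try:
        sol = solve_ivp(
            rhs15, (0.0, horizon_hours), state0[_OTHER],
            method=options.method, rtol=options.rtol, atol=options.atol,
            t_eval=t_eval,
        )
    except (ValueError, FloatingPointError, OverflowError) as exc:
        return Trajectory(
            times=np.array([0.0]), states=state0[None, :],
            success=False, message=f"integration error: {exc}", exposure=exposure,
        )

    if not sol.success or not np.all(np.isfinite(sol.y)):
        return Trajectory(
            times=sol.t, states=np.full((len(sol.t), N_STATES), np.nan),
            success=False, message=sol.message or "non-finite state",
            exposure=exposure,
        )

    states = np.empty((len(sol.t), N_STATES))
    states[:, _OTHER] = sol.y.T
    states[:, _FSTD] = fstd_closed_form(sol.t, fstd0, params.ksttb_d, params.dfr_d)
    # tiny negative undershoots from the adaptive solver are clipped
    np.clip(states, 0.0, None, out=states)
    return Trajectory(times=sol.t, states=states, success=True,
                      message=sol.message or "", exposure=exposure)


def _first_sustained_crossing(
    times: np.ndarray, series: np.ndarray, level: float, sustain_hours: float
) -> float | None:
    """First time ``series`` drops below ``level`` and stays there for
    ``sustain_hours`` (a run reaching the end of the grid must still span
    the sustain window to count)."""
    below = series < level
    if not below.any():
        return None
    edges = np.flatnonzero(np.diff(below.astype(np.int8)))
    starts = [0] if below[0] else []
    starts += [int(i) + 1 for i in edges if below[i + 1]]
    ends = [int(i) for i in edges if below[i]] + ([len(below) - 1] if below[-1] else [])
    for s, e in zip(starts, ends):
        if times[e] - times[s] >= sustain_hours:
            return float(times[s])
    return None


def resolution_times(
    traj: Trajectory, thresholds: EventThresholds | None = None
) -> tuple[float | None, float | None]:
    """(healing time, debris-resolution time) in hours; ``None`` if the
    level never sustains below its threshold within the horizon."""
    if thresholds is None:
        thresholds = EventThresholds()
    if not traj.success:
        raise ValueError("resolution_times requires a successful trajectory")
    healing = _first_sustained_crossing(
        traj.times, traj.series("Dam_tb"),
        thresholds.healed_level, thresholds.sustain_hours,
    )
    debris = _first_sustained_crossing(
        traj.times, traj.series("Deb_tb"),
        thresholds.resolved_level, thresholds.sustain_hours,
    )
    return healing, debris


def m1_ratio(traj: Trajectory, eps: float = 1e-12) -> np.ndarray:
    """M1 fraction of the activated macrophage response, ``M1/(M1+M2)``.

    Points where the total activated pool is numerically zero are undefined
    and returned as NaN.
    """
    m1 = traj.series("M1_tb")
    total = m1 + traj.series("M2_tb")
    out = np.full_like(total, np.nan)
    mask = total > eps
    out[mask] = m1[mask] / total[mask]
    return out


def damage_peak_time(traj: Trajectory) -> float:
    """Time of maximum damage (earliest grid point on ties)."""
    return float(traj.times[int(np.argmax(traj.series("Dam_tb")))])


def healed_steady_state(params: ParameterSet) -> np.ndarray:
    """Fixed point of the system with the wound fully resolved.

    Damage, debris, pathogen and every activated population are zero; the
    surrounding tissue sits at its resting influx/decay balance, and the
    wound fibroblast pool at the balance of recruitment from the
    surrounding tissue against net removal ``df - kf`` (baseline
    proliferation ``kf`` must be slower than decay ``df`` for the healed
    state to be finite).
    """
    if params.df <= params.kf:
        raise ValueError(
            "healed steady state undefined: baseline fibroblast proliferation "
            f"kf={params.kf} must be < wound decay df={params.df}"
        )
    levels = resting_steady_levels(params)
    state = np.zeros(N_STATES)
    state[IDX["M_st_ud"]] = levels.M_st_0
    state[IDX["L_st_ud"]] = levels.L_st_0
    state[IDX["F_st_ud"]] = levels.F_st_0
    state[IDX["F_tb"]] = params.ksttb_ud * levels.F_st_0 / (params.df - params.kf)
    return state


def trajectory_to_frame(traj: Trajectory) -> pd.DataFrame:
    """Tidy long-format frame: (time_h, variable, value)."""
    frames = [
        pd.DataFrame({
            "time_h": traj.times,
            "variable": name,
            "value": traj.states[:, i],
        })
        for i, name in enumerate(STATE_NAMES)
    ]
    return pd.concat(frames, ignore_index=True)


def trajectory_summary(
    traj: Trajectory, thresholds: EventThresholds | None = None
) -> dict:
    """JSON-ready scalar summary of one trajectory."""
    if not traj.success:
        return {"success": False, "message": traj.message}
    healing_h, debris_h = resolution_times(traj, thresholds)
    return {
        "success": True,
        "healing_h": healing_h,
        "debris_h": debris_h,
        "peak_h": damage_peak_time(traj),
        "final_P": float(traj.series("P_tb")[-1]),
    }
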