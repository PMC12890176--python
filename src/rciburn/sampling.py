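"""Latin-hypercube feasibility screening and representative-set selection.

Because dose-response data for combined burn + irradiation injury do not
exist, plausible kinetic parameters are found by constraint, not by fit:
candidate sets are drawn by Latin hypercube sampling over broad initial
ranges, screened by a cheap healed-state stability predicate, then each
survivor is simulated for the two reference burn severities (no radiation)
and kept only if

(a) the integration succeeds with finite states,
(b) debris resolves before damage in both severities, and
(c) the superficial burn heals within 4.667 +/- 0.5 days and the
    superficial partial-thickness burn within 7.833 +/- 0.5 days.

The accepted cohort defines refined per-parameter bounds and a
*representative* set: the member whose trajectories are closest (weighted
MSE) to the cohort's temporal mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import qmc

from .initial import build_initial_state
from .model import Exposure
from .parameters import ESTIMATE_SET, FIX_SET, PARAM_NAMES, ParameterSet
from .simulate import (
    EventThresholds,
    SolverOptions,
    resolution_times,
    simulate,
)

__all__ = [
    "SamplingDesign",
    "FeasibilityVerdict",
    "SUPERFICIAL_WINDOW_DAYS",
    "PARTIAL_WINDOW_DAYS",
    "FEASIBILITY_HORIZON_HOURS",
    "load_initial_ranges",
    "default_design",
    "baseline_parameters",
    "default_stability_predicate",
    "lhs_sample",
    "assess_feasibility",
    "run_feasibility",
    "refine_bounds",
    "select_representative",
]

#: Healing-time acceptance windows (days): reported burn-resolution times
#: for the two severities, +/- half a day.
SUPERFICIAL_WINDOW_DAYS = (4.667 - 0.5, 4.667 + 0.5)
PARTIAL_WINDOW_DAYS = (7.833 - 0.5, 7.833 + 0.5)

#: Simulation horizon for the screen: past the upper partial-thickness
#: window edge with margin for the sustain check.
FEASIBILITY_HORIZON_HOURS = 228.0


def load_initial_ranges() -> dict[str, tuple[float, float]]:
    """Shipped initial sampling ranges, name -> (min, max)."""
    path = resources.files("rciburn.data") / "initial_ranges.yaml"
    with path.open() as fh:
        raw = yaml.safe_load(fh)
    return {name: (float(lo), float(hi)) for name, (lo, hi) in raw.items()}


@dataclass(frozen=True)
class SamplingDesign:
    """LHS design: which parameters vary, over what ranges, how many draws.

    Parameters in ``fix_set`` are pinned to the midpoint of their initial
    range (their baseline value); ``estimate_set`` parameters are sampled.
    """

    ranges: dict[str, tuple[float, float]]
    n_samples: int
    seed: int
    estimate_set: tuple[str, ...] = ESTIMATE_SET
    fix_set: tuple[str, ...] = FIX_SET

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise ValueError("n_samples must be >= 0")
        missing = set(self.estimate_set) | set(self.fix_set) - set(self.ranges)
        missing -= set(self.ranges)
        if missing:
            raise ValueError(f"no range given for parameters: {sorted(missing)}")
        overlap = set(self.estimate_set) & set(self.fix_set)
        if overlap:
            raise ValueError(f"parameters both estimated and fixed: {sorted(overlap)}")
        for name, (lo, hi) in self.ranges.items():
            if not lo < hi:
                raise ValueError(f"range for {name!r} must have min < max, got ({lo}, {hi})")

    def midpoint(self, name: str) -> float:
        lo, hi = self.ranges[name]
        return 0.5 * (lo + hi)


def default_design(n_samples: int = 5000, seed: int = 0) -> SamplingDesign:
    """Design over the shipped initial ranges and influential-parameter split."""
    return SamplingDesign(ranges=load_initial_ranges(), n_samples=n_samples, seed=seed)


def baseline_parameters(design: SamplingDesign | None = None) -> ParameterSet:
    """Baseline set: every parameter at the midpoint of its initial range."""
    if design is None:
        design = default_design(n_samples=0)
    return ParameterSet.from_dict({n: design.midpoint(n) for n in PARAM_NAMES})


def lhs_sample(design: SamplingDesign) -> list[ParameterSet]:
    """Draw ``n_samples`` parameter sets by Latin hypercube sampling.

    Stratified per dimension (one draw per equal-probability bin) over the
    ``estimate_set`` parameters; fixed parameters are pinned at their
    baseline midpoints.  Reproducible for a given seed.
    """
    if design.n_samples == 0:
        return []
    names = list(design.estimate_set)
    sampler = qmc.LatinHypercube(d=len(names), seed=design.seed)
    unit = sampler.random(design.n_samples)
    lo = np.array([design.ranges[n][0] for n in names])
    hi = np.array([design.ranges[n][1] for n in names])
    scaled = qmc.scale(unit, lo, hi)
    fixed = {n: design.midpoint(n) for n in design.fix_set}
    out = []
    for row in scaled:
        values = dict(fixed)
        values.update(zip(names, row.tolist()))
        out.append(ParameterSet.from_dict(values))
    return out


def default_stability_predicate(params: ParameterSet) -> bool:
    """Cheap pre-simulation screen for a stable healed state.

    Requires positive decay rates (guaranteed by construction), baseline
    wound-fibroblast proliferation slower than decay (``df > kf``, else the
    healed fibroblast level diverges) and a sub-critical pathogen growth
    rate (``kpg < kpb*sb/mu_b``, else the pathogen-free healed state is
    unstable).  Pluggable: pass any predicate to :func:`run_feasibility`.
    """
    return params.df > params.kf and params.kpg < params.kpb * params.sb / params.mu_b


@dataclass(frozen=True)
class FeasibilityVerdict:
    """Outcome of the three-criterion screen for one parameter set."""

    passed_numerics: bool
    passed_ordering: bool
    passed_windows: bool
    healing_h: dict = field(default_factory=dict)
    reason: str = ""

    @property
    def accepted(self) -> bool:
        return self.passed_numerics and self.passed_ordering and self.passed_windows


def assess_feasibility(
    params: ParameterSet,
    thresholds: EventThresholds | None = None,
    options: SolverOptions | None = None,
) -> FeasibilityVerdict:
    """Simulate both reference severities at zero dose and apply (a)-(c)."""
    if thresholds is None:
        thresholds = EventThresholds()
    exposure = Exposure(fluence=0.0, dose_gy=0.0)
    healing: dict[str, float | None] = {}
    windows = {"superficial": SUPERFICIAL_WINDOW_DAYS,
               "superficial-partial": PARTIAL_WINDOW_DAYS}
    dam0 = {"superficial": 0.1, "superficial-partial": 0.9}

    for severity in ("superficial", "superficial-partial"):
        state0 = build_initial_state(exposure, params, dam0=dam0[severity])
        traj = simulate(state0, params, exposure, FEASIBILITY_HORIZON_HOURS, options)
        if not traj.success:
            return FeasibilityVerdict(
                False, False, False, healing,
                reason=f"{severity}: {traj.message}",
            )
        heal_h, debris_h = resolution_times(traj, thresholds)
        healing[severity] = heal_h
        if heal_h is None or debris_h is None:
            return FeasibilityVerdict(
                True, False, False, healing,
                reason=f"{severity}: damage or debris unresolved within horizon",
            )
        if debris_h >= heal_h:
            return FeasibilityVerdict(
                True, False, False, healing,
                reason=f"{severity}: debris resolved after damage",
            )
        lo_d, hi_d = windows[severity]
        if not lo_d <= heal_h / 24.0 <= hi_d:
            return FeasibilityVerdict(
                True, True, False, healing,
                reason=f"{severity}: healing {heal_h / 24.0:.2f} d outside "
                       f"[{lo_d:.3f}, {hi_d:.3f}] d",
            )
    return FeasibilityVerdict(True, True, True, healing, reason="")


def run_feasibility(
    design: SamplingDesign,
    thresholds: EventThresholds | None = None,
    options: SolverOptions | None = None,
    stability: Callable[[ParameterSet], bool] | None = default_stability_predicate,
    progress: bool = False,
) -> tuple[pd.DataFrame, list[ParameterSet]]:
    """Screen a full LHS draw; return the manifest and the accepted sets.

    The manifest has one row per sample: verdict booleans, healing times,
    reject reason and every parameter value — enough to reproduce or audit
    any single decision.
    """
    candidates = lhs_sample(design)
    rows = []
    accepted: list[ParameterSet] = []
    iterator = enumerate(candidates)
    if progress:
        from tqdm import tqdm  # pragma: no cover - cosmetic only

        iterator = tqdm(list(iterator), desc="feasibility")
    for i, params in iterator:
        if stability is not None and not stability(params):
            verdict = FeasibilityVerdict(
                False, False, False, {}, reason="stability predicate failed"
            )
        else:
            verdict = assess_feasibility(params, thresholds, options)
        if verdict.accepted:
            accepted.append(params)
        rows.append({
            "sample_id": i,
            "seed": design.seed,
            "accepted": verdict.accepted,
            "passed_numerics": verdict.passed_numerics,
            "passed_ordering": verdict.passed_ordering,
            "passed_windows": verdict.passed_windows,
            "healing_superficial_h": verdict.healing_h.get("superficial"),
            "healing_partial_h": verdict.healing_h.get("superficial-partial"),
            "reason": verdict.reason,
            **params.to_dict(),
        })
    return pd.DataFrame(rows), accepted


def refine_bounds(accepted: Sequence[ParameterSet]) -> dict[str, tuple[float, float]]:
    """Elementwise (min, max) over the accepted cohort.

    With a single accepted set every range is degenerate (min == max);
    callers should draw more samples before using such bounds for a
    sensitivity screen.
    """
    if not accepted:
        raise ValueError(
            "no accepted parameter sets: increase the number of LHS samples"
        )
    matrix = np.array([p.to_vector() for p in accepted])
    lo = matrix.min(axis=0)
    hi = matrix.max(axis=0)
    return {name: (float(a), float(b)) for name, a, b in zip(PARAM_NAMES, lo, hi)}


def _cohort_trajectories(
    accepted: Sequence[ParameterSet],
    t_grid: np.ndarray,
    options: SolverOptions | None,
) -> np.ndarray:
    """States for both severities on a common grid, stacked to shape
    (n_sets, n_times, 32)."""
    exposure = Exposure(fluence=0.0, dose_gy=0.0)
    horizon = float(t_grid[-1])
    step = float(t_grid[1] - t_grid[0])
    opts = options or SolverOptions()
    opts = SolverOptions(method=opts.method, rtol=opts.rtol, atol=opts.atol,
                         grid_step_hours=step)
    stacks = []
    for params in accepted:
        per_severity = []
        for dam0 in (0.1, 0.9):
            state0 = build_initial_state(exposure, params, dam0=dam0)
            traj = simulate(state0, params, exposure, horizon, opts)
            if not traj.success:
                raise RuntimeError("accepted set failed to re-simulate")
            per_severity.append(traj.states[: len(t_grid)])
        stacks.append(np.concatenate(per_severity, axis=1))
    return np.array(stacks)


def select_representative(
    accepted: Sequence[ParameterSet],
    t_grid: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    options: SolverOptions | None = None,
) -> tuple[ParameterSet, pd.DataFrame]:
    """Pick the accepted set closest to the cohort's temporal mean.

    Every accepted set is re-simulated for both severities; per state
    variable, the squared deviation from the cohort's pointwise temporal
    mean is averaged over time, weighted (default: inverse variance of the
    mean series, so each variable contributes on a comparable scale) and
    summed.  Returns the argmin-MSE set (first index on ties) and a ranking
    frame with each candidate's weighted MSE and coefficient of
    determination R^2 against the cohort mean.
    """
    if len(accepted) == 0:
        raise ValueError("select_representative requires at least one accepted set")
    if t_grid is None:
        t_grid = np.arange(0.0, FEASIBILITY_HORIZON_HOURS + 0.5, 1.0)
    t_grid = np.asarray(t_grid, dtype=float)
    stacks = _cohort_trajectories(accepted, t_grid, options)  # (S, T, V)
    mean = stacks.mean(axis=0)  # (T, V)
    if weights is None:
        var = mean.var(axis=0)  # variance over time of the mean series
        weights = np.where(var > 1e-12, 1.0 / np.maximum(var, 1e-12), 0.0)
    weights = np.asarray(weights, dtype=float)

    dev = stacks - mean[None, :, :]
    mse = (weights[None, :] * (dev**2).mean(axis=1)).sum(axis=1)
    ss_res = (dev**2).sum(axis=(1, 2))
    ss_tot = ((mean - mean.mean(axis=0)) ** 2).sum() * np.ones(len(accepted))
    r2 = 1.0 - ss_res / np.where(ss_tot > 0, ss_tot, np.inf)

    ranking = pd.DataFrame({
        "candidate": np.arange(len(accepted)),
        "weighted_mse": mse,
        "r_squared": r2,
    }).sort_values("weighted_mse", kind="stable").reset_index(drop=True)
    best = int(np.argmin(mse))  # argmin -> first index on exact ties
    return accepted[best], ranking
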