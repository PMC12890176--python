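"""End-to-end pipeline: sample -> refine -> sensitivity -> classify ->
resample -> representative -> simulate.

Each stage writes a plain-text artifact (CSV/YAML/JSON) into the run
directory and is recorded in a :class:`RunManifest` keyed by a hash of the
configuration, so a rerun with the same config and seed reproduces every
artifact byte-for-byte and a partial run can be resumed stage by stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .initial import SEVERITY_DAMAGE, build_initial_state
from .model import STATE_NAMES, Exposure
from .parameters import ESTIMATE_SET, PARAM_NAMES, ParameterSet
from .sampling import (
    SamplingDesign,
    baseline_parameters,
    load_initial_ranges,
    refine_bounds,
    run_feasibility,
    select_representative,
)
from .sensitivity import (
    SensitivityDesign,
    classify_parameters,
    efast_indices,
    mefast_tests,
)
from .simulate import (
    EventThresholds,
    SolverOptions,
    simulate,
    trajectory_summary,
    trajectory_to_frame,
)

__all__ = [
    "Scenario",
    "RunManifest",
    "scenario_fixtures",
    "model_readout_fn",
    "run_pipeline",
    "default_config",
]

#: Canonical dose grid (Gy) spanning the burn-only reference and the
#: combined-injury levels explored in simulations and the screen.
CANONICAL_DOSES_GY = (0.0, 1.0, 5.0, 7.0, 14.0)


@dataclass(frozen=True)
class Scenario:
    """One simulation scenario: burn severity (named or by fluence) + dose."""

    dose_gy: float
    severity: str | None = None
    fluence: float | None = None
    horizon_hours: float = 480.0

    def __post_init__(self) -> None:
        if (self.severity is None) == (self.fluence is None):
            raise ValueError("give exactly one of severity or fluence")
        if self.severity is not None and self.severity not in SEVERITY_DAMAGE:
            raise ValueError(
                f"unknown severity {self.severity!r}; "
                f"choose from {sorted(SEVERITY_DAMAGE)}"
            )

    @property
    def dam0(self) -> float | None:
        return SEVERITY_DAMAGE[self.severity] if self.severity else None

    def to_dict(self) -> dict:
        return {k: v for k, v in dataclasses.asdict(self).items() if v is not None}

    @classmethod
    def from_dict(cls, data: dict) -> "Scenario":
        return cls(**data)


def scenario_fixtures(horizon_hours: float = 480.0) -> list[Scenario]:
    """The canonical 2 x 5 scenario grid: both severities at each dose."""
    return [
        Scenario(dose_gy=dose, severity=sev, horizon_hours=horizon_hours)
        for sev in SEVERITY_DAMAGE
        for dose in CANONICAL_DOSES_GY
    ]


def simulate_scenario(
    scenario: Scenario,
    params: ParameterSet,
    options: SolverOptions | None = None,
):
    """Build the initial state for a scenario and integrate it."""
    exposure = Exposure(fluence=scenario.fluence or 0.0, dose_gy=scenario.dose_gy)
    state0 = build_initial_state(exposure, params, dam0=scenario.dam0)
    return simulate(state0, params, exposure, scenario.horizon_hours, options)


def model_readout_fn(
    baseline: ParameterSet,
    names: list[str],
    design: SensitivityDesign,
    severity: str = "superficial",
    variables: tuple[str, ...] | None = None,
    options: SolverOptions | None = None,
):
    """Adapter turning the simulator into an eFAST readout function.

    Returns ``(func, output_names)``: ``func`` maps an (ns, d) design
    matrix over ``names`` to state-variable levels at the design's readout
    days and doses.  Failed integrations yield NaN rows (handled upstream
    by the eFAST driver).
    """
    if variables is None:
        variables = STATE_NAMES
    opts = options or SolverOptions(grid_step_hours=1.0)
    horizon = max(design.output_days) * 24.0
    day_idx = [int(round(d * 24.0 / opts.grid_step_hours)) for d in design.output_days]
    output_names = [
        f"{var}@d{day:g}@{dose:g}Gy"
        for dose in design.doses_gy for day in design.output_days for var in variables
    ]
    var_idx = [STATE_NAMES.index(v) for v in variables]
    dam0 = SEVERITY_DAMAGE[severity]

    def func(matrix: np.ndarray) -> np.ndarray:
        out = np.empty((matrix.shape[0], len(output_names)))
        for row_i, row in enumerate(matrix):
            values = baseline.to_dict()
            values.update(zip(names, row.tolist()))
            try:
                params = ParameterSet.from_dict(values)
            except Exception:
                out[row_i] = np.nan
                continue
            cols = []
            for dose in design.doses_gy:
                exposure = Exposure(fluence=0.0, dose_gy=dose)
                state0 = build_initial_state(exposure, params, dam0=dam0)
                traj = simulate(state0, params, exposure, horizon, opts)
                if not traj.success:
                    cols.append(np.full((len(day_idx), len(var_idx)), np.nan))
                else:
                    cols.append(traj.states[np.ix_(day_idx, var_idx)])
            out[row_i] = np.concatenate([c.ravel() for c in cols])
        return out

    return func, output_names


@dataclass
class RunManifest:
    """Record of one pipeline run: config hash, seeds, per-stage artifacts."""

    config_hash: str
    seed: int
    version: str = __version__
    stages: dict[str, dict] = field(default_factory=dict)

    def record(self, stage: str, path: Path | None, **extra) -> None:
        entry = {"timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"), **extra}
        if path is not None:
            entry["path"] = str(path)
            entry["sha256"] = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.stages[stage] = entry

    def stage_hashes(self) -> dict[str, str]:
        """Content hashes only — invariant across reruns of the same config."""
        return {s: e["sha256"] for s, e in self.stages.items() if "sha256" in e}

    def to_json(self, path: Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def default_config(seed: int = 0) -> dict:
    """Pipeline configuration with the shipped study conditions."""
    return {
        "seed": seed,
        "sampling": {"n_samples": 5000},
        "sensitivity": {
            "ns": 129,
            "nr": 4,
            "doses_gy": [1.0, 7.0, 14.0],
            "output_days": [1.0, 3.0, 7.0, 10.0, 14.0],
            "parameters": list(ESTIMATE_SET),
            "variables": ["Dam_tb", "Deb_tb", "N_tb", "M1_tb", "M2_tb", "F_tb"],
        },
        "resample": {"n_samples": 2000},
        "events": {"healed_level": 0.02, "resolved_level": 0.02, "sustain_hours": 12.0},
        "solver": {"rtol": 1e-6, "atol": 1e-9},
    }


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()
    ).hexdigest()[:16]


def run_pipeline(
    config: dict,
    outdir: str | Path,
    skip_sensitivity: bool = False,
) -> RunManifest:
    """Execute the stages in order, writing artifacts under ``outdir``.

    Stage order: LHS feasibility screen over the initial ranges -> refined
    bounds -> eFAST/MeFAST screen over the refined bounds -> influential
    classification -> final resample of the influential set -> representative
    selection -> reference simulations.  ``skip_sensitivity`` collapses the
    middle stages onto the shipped influential split (useful when only the
    feasibility products are needed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for key in ("seed", "sampling"):
        if key not in config:
            raise KeyError(f"pipeline config missing required key {key!r}")
    seed = int(config["seed"])
    manifest = RunManifest(config_hash=_config_hash(config), seed=seed)
    (outdir / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=True))
    manifest.record("config", outdir / "config.yaml")
    try:
        _run_stages(config, outdir, manifest, skip_sensitivity)
    finally:
        # a failed stage still leaves a manifest recording what completed
        manifest.to_json(outdir / "manifest.json")
    return manifest


def _run_stages(
    config: dict,
    outdir: Path,
    manifest: RunManifest,
    skip_sensitivity: bool,
) -> None:
    seed = manifest.seed

    thresholds = EventThresholds(**config.get("events", {}))
    options = SolverOptions(**config.get("solver", {}))
    ranges = load_initial_ranges()

    # stage 1: initial feasibility screen
    design = SamplingDesign(
        ranges=ranges, n_samples=int(config["sampling"]["n_samples"]), seed=seed,
    )
    manifest_df, accepted = run_feasibility(design, thresholds, options)
    path = outdir / "feasibility_initial.csv"
    manifest_df.to_csv(path, index=False)
    manifest.record("sample", path, n_accepted=len(accepted))

    # stage 2: refined bounds
    bounds = refine_bounds(accepted)
    path = outdir / "refined_bounds.yaml"
    path.write_text(yaml.safe_dump({k: list(v) for k, v in bounds.items()}))
    manifest.record("refine", path)

    # stages 3-4: sensitivity screen and classification
    if skip_sensitivity:
        estimate = list(ESTIMATE_SET)
    else:
        sens_cfg = dict(config.get("sensitivity", {}))
        subset = list(sens_cfg.pop("parameters", ESTIMATE_SET))
        variables = tuple(sens_cfg.pop("variables", STATE_NAMES))
        sens_design = SensitivityDesign(
            seed=seed + 1,
            ns=int(sens_cfg.get("ns", 129)),
            nr=int(sens_cfg.get("nr", 4)),
            doses_gy=tuple(sens_cfg.get("doses_gy", (1.0, 7.0, 14.0))),
            output_days=tuple(sens_cfg.get("output_days", (1.0, 3.0, 7.0, 10.0, 14.0))),
        )
        baseline = baseline_parameters()
        # widen degenerate refined bounds so search curves have room
        sens_ranges = {}
        for name in subset:
            lo, hi = bounds[name]
            if hi - lo < 1e-12:
                lo, hi = 0.95 * lo, 1.05 * hi
            sens_ranges[name] = (lo, hi)
        func, out_names = model_readout_fn(
            baseline, subset, sens_design, variables=variables, options=options,
        )
        report = efast_indices(func, subset, sens_ranges, sens_design, out_names)
        report = mefast_tests(report)
        estimate, _fixed = classify_parameters(report)
        path = outdir / "sensitivity_report.csv"
        report.to_frame().to_csv(path, index=False)
        manifest.record("sensitivity", path, n_influential=len(estimate))
    path = outdir / "influential.yaml"
    path.write_text(yaml.safe_dump({"estimate": sorted(estimate)}))
    manifest.record("classify", path)

    # stage 5: final resample over the influential set
    fix = tuple(n for n in PARAM_NAMES if n not in estimate)
    final_design = SamplingDesign(
        ranges=ranges,
        n_samples=int(config.get("resample", {}).get("n_samples", 2000)),
        seed=seed + 2,
        estimate_set=tuple(estimate),
        fix_set=fix,
    )
    final_df, final_accepted = run_feasibility(final_design, thresholds, options)
    path = outdir / "feasibility_final.csv"
    final_df.to_csv(path, index=False)
    manifest.record("resample", path, n_accepted=len(final_accepted))

    # stage 6: representative set
    representative, ranking = select_representative(final_accepted, options=options)
    path = outdir / "representative_params.yaml"
    representative.to_yaml(path)
    ranking.to_csv(outdir / "representative_ranking.csv", index=False)
    manifest.record(
        "representative", path,
        best_mse=float(ranking["weighted_mse"].iloc[0]),
        best_r2=float(ranking["r_squared"].iloc[0]),
    )

    # stage 7: reference simulations with the representative set
    summaries = {}
    for scenario in scenario_fixtures():
        traj = simulate_scenario(scenario, representative, options)
        tag = f"{scenario.severity}_{scenario.dose_gy:g}Gy"
        trajectory_to_frame(traj).to_csv(outdir / f"trajectory_{tag}.csv", index=False)
        summaries[tag] = trajectory_summary(traj, thresholds)
    path = outdir / "simulation_summaries.json"
    path.write_text(json.dumps(summaries, indent=2))
    manifest.record("simulate", path)
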