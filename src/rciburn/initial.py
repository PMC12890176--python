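"""Initial conditions for a locally irradiated thermal burn.

The full 16-component initial state is assembled from three dose/fluence
rules:

* resident monocytes, lymphocytes and fibroblasts in the surrounding tissue
  sit at their healed steady-state totals and are split into undamaged and
  damaged fractions by linear-quadratic (LQ) survival curves,
  ``S(DR) = exp(-alpha*DR - beta*DR^2)``;
* wound damage and debris start at a level mapped from thermal fluence by a
  piecewise-quadratic map calibrated so a superficial burn gives 0.1 and a
  superficial partial-thickness burn gives 0.9;
* pathogen is seeded only when radiation is present, scaled linearly between
  zero and the carrying capacity by burn severity.

All wound-site cell populations start at zero (thermal injury is assumed to
kill every viable cell at the burn), and tissue-resident neutrophils do not
exist, so the resting-neutrophil state starts at zero as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import IDX, N_STATES, Exposure
from .parameters import ParameterSet

__all__ = [
    "LQCoefficients",
    "FluenceMap",
    "RestingLevels",
    "DEFAULT_LQ_TABLE",
    "load_lq_table",
    "DEFAULT_FLUENCE_MAP",
    "SEVERITY_DAMAGE",
    "REFERENCE_FLUENCE",
    "lq_survival_fraction",
    "resting_steady_levels",
    "surrounding_initial_state",
    "fluence_to_damage",
    "pathogen_initial",
    "build_initial_state",
]


@dataclass(frozen=True, slots=True)
class LQCoefficients:
    """Linear-quadratic survival coefficients (per Gy, per Gy^2)."""

    alpha: float
    beta: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError(
                f"LQ coefficients must be >= 0, got alpha={self.alpha}, beta={self.beta}"
            )


def load_lq_table(path) -> dict[str, LQCoefficients]:
    """Read an LQ coefficient table from CSV (cell_type, alpha, beta)."""
    import csv

    table = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            table[row["cell_type"]] = LQCoefficients(
                alpha=float(row["alpha"]), beta=float(row["beta"])
            )
    if not table:
        raise ValueError(f"{path}: empty LQ coefficient table")
    return table


def _packaged_lq_table() -> dict[str, LQCoefficients]:
    from importlib import resources

    path = resources.files("rciburn.data") / "lq_coefficients.csv"
    return load_lq_table(str(path))


#: Survival-curve fits used to split the resident populations by dose
#: (monocytes alpha = 0.1826; lymphocytes 0.3481/0.0723 per Gy, Gy^2;
#: fibroblasts 0.5084/0.0549), shipped as data/lq_coefficients.csv.
DEFAULT_LQ_TABLE: dict[str, LQCoefficients] = _packaged_lq_table()

#: Named burn severities and their damage/debris anchors.
SEVERITY_DAMAGE: dict[str, float] = {
    "superficial": 0.1,
    "superficial-partial": 0.9,
}

#: Fluence (J/cm^2) of the most severe burn considered; sets the damage
#: level used to normalise the pathogen seeding.
REFERENCE_FLUENCE = 19.0


@dataclass(frozen=True, slots=True)
class FluenceMap:
    """Piecewise map from thermal fluence (J/cm^2) to the damage constant.

    Below ``f_low`` the fluence is sub-threshold and produces no damage.
    On the middle branch (epidermal injury) the shared quadratic
    ``q(f) = a f^2 + b f + c`` is scaled by ``scale_mid``; above ``f_high``
    (dermal involvement) it is scaled by ``scale_high`` and offset.  The
    default multipliers 100/3 and 80/3 make the two branches exactly
    continuous at ``f_high`` = 5.168, where both evaluate to ~0.1 — the
    superficial-burn anchor.
    """

    a: float = -8.9795e-5
    b: float = 7.2019e-3
    c: float = -3.1822e-2
    f_low: float = 5.016
    f_high: float = 5.168
    scale_mid: float = 100.0 / 3.0
    scale_high: float = 80.0 / 3.0
    offset_high: float = 0.02

    def __post_init__(self) -> None:
        if not self.f_low < self.f_high:
            raise ValueError(
                f"f_low must be < f_high, got {self.f_low} >= {self.f_high}"
            )

    def quadratic(self, f: float) -> float:
        return self.a * f * f + self.b * f + self.c


DEFAULT_FLUENCE_MAP = FluenceMap()


@dataclass(frozen=True, slots=True)
class RestingLevels:
    """Healed steady-state totals of the resident populations."""

    M_st_0: float
    L_st_0: float
    F_st_0: float


def lq_survival_fraction(dose_gy: float, coeff: LQCoefficients) -> float:
    """Surviving fraction ``exp(-alpha*DR - beta*DR^2)`` after dose ``DR``."""
    if dose_gy < 0:
        raise ValueError(f"dose must be >= 0, got {dose_gy}")
    return math.exp(-coeff.alpha * dose_gy - coeff.beta * dose_gy * dose_gy)


def resting_steady_levels(params: ParameterSet) -> RestingLevels:
    """Healed steady-state totals implied by influx/decay balance.

    Each resident population settles at its blood(-or-connective-tissue)
    influx rate divided by its total removal rate; for fibroblasts the
    removal includes both decay and recruitment to the wound compartment,
    so the total is ``sf / (dfr_ud + ksttb_ud)``.
    """
    return RestingLevels(
        M_st_0=params.smr / params.dmr_ud,
        L_st_0=params.slr / params.dlr_ud,
        F_st_0=params.sf / (params.dfr_ud + params.ksttb_ud),
    )


def surrounding_initial_state(
    params: ParameterSet,
    dose_gy: float,
    lq_table: dict[str, LQCoefficients] | None = None,
) -> np.ndarray:
    """Surrounding-tissue components of the initial state (length 16).

    Resident totals are split into undamaged (``total * survival``) and
    damaged (``total * (1 - survival)``) by the LQ curves; resting
    neutrophils have no tissue-resident population and start at zero.
    Only the seven surrounding-tissue slots are populated.
    """
    if lq_table is None:
        lq_table = DEFAULT_LQ_TABLE
    levels = resting_steady_levels(params)
    state = np.zeros(N_STATES)
    for cell, total, ud_key, d_key in (
        ("monocyte", levels.M_st_0, "M_st_ud", "M_st_d"),
        ("lymphocyte", levels.L_st_0, "L_st_ud", "L_st_d"),
        ("fibroblast", levels.F_st_0, "F_st_ud", "F_st_d"),
    ):
        surv = lq_survival_fraction(dose_gy, lq_table[cell])
        state[IDX[ud_key]] = total * surv
        state[IDX[d_key]] = total * (1.0 - surv)
    return state


def fluence_to_damage(fluence: float, fmap: FluenceMap | None = None) -> float:
    """Initial damage/debris level produced by a thermal fluence."""
    if fluence < 0:
        raise ValueError(f"fluence must be >= 0, got {fluence}")
    if fmap is None:
        fmap = DEFAULT_FLUENCE_MAP
    if fluence < fmap.f_low:
        return 0.0
    q = fmap.quadratic(fluence)
    if fluence <= fmap.f_high:
        return fmap.scale_mid * q
    return fmap.scale_high * q + fmap.offset_high


def pathogen_initial(
    dam0: float,
    dose_gy: float,
    params: ParameterSet,
    dam_max: float | None = None,
) -> float:
    """Initial pathogen load: zero without radiation, else severity-scaled.

    With radiation present, skin-flora contamination is seeded proportional
    to burn severity, reaching the carrying capacity ``P_inf`` at the
    damage level of the reference fluence (19 J/cm^2).
    """
    if dam_max is None:
        dam_max = fluence_to_damage(REFERENCE_FLUENCE)
    if not 0 <= dam0 <= dam_max:
        raise ValueError(f"dam0 must be in [0, {dam_max}], got {dam0}")
    if dose_gy == 0:
        return 0.0
    return params.P_inf * (dam0 / dam_max)


def build_initial_state(
    exposure: Exposure,
    params: ParameterSet,
    lq_table: dict[str, LQCoefficients] | None = None,
    fmap: FluenceMap | None = None,
    dam0: float | None = None,
) -> np.ndarray:
    """Full 16-component initial state for an exposure.

    ``dam0`` overrides the fluence map with a direct damage/debris level —
    used for the named severities (superficial = 0.1, superficial
    partial-thickness = 0.9).  All wound cell populations start at zero.
    """
    state = surrounding_initial_state(params, exposure.dose_gy, lq_table)
    if dam0 is None:
        dam0 = fluence_to_damage(exposure.fluence, fmap)
    state[IDX["Dam_tb"]] = dam0
    state[IDX["Deb_tb"]] = dam0
    state[IDX["P_tb"]] = pathogen_initial(
        dam0, exposure.dose_gy, params,
        dam_max=fluence_to_damage(REFERENCE_FLUENCE, fmap),
    )
    return state
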