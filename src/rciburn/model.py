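"""Right-hand side of the burn + local-irradiation compartmental ODE system.

Two compartments are modelled: the thermal-burn wound site (activated
neutrophils ``N_tb``, M1/M2 macrophages, pro-/anti-inflammatory T
lymphocytes ``L1_tb``/``L2_tb``, fibroblasts ``F_tb``, pathogen ``P_tb``,
plus the unitless damage ``Dam_tb`` and debris ``Deb_tb`` levels) and the
surrounding irradiated tissue (resting neutrophils and undamaged/damaged
resident monocytes, lymphocytes and fibroblasts).  Radiation enters three
ways: a linear-quadratic split of resident populations into undamaged and
damaged at time zero (see :mod:`rciburn.initial`), a dose-dependent delay
of blood-stream influx (microvascular damage), and inhibition of repair
processes driven by the damaged resident populations.

State layout (fixed order used by every array in the package)::

    0  N_st_ud   resting neutrophils, surrounding tissue
    1  M_st_ud   undamaged resident monocytes
    2  M_st_d    damaged resident monocytes
    3  L_st_ud   undamaged resident lymphocytes
    4  L_st_d    damaged resident lymphocytes
    5  F_st_ud   undamaged resident fibroblasts
    6  F_st_d    damaged resident fibroblasts
    7  Dam_tb    damaged tissue (unitless)
    8  Deb_tb    cellular debris (unitless)
    9  N_tb      activated neutrophils, wound
    10 M1_tb     classically activated macrophages, wound
    11 M2_tb     alternatively activated macrophages, wound
    12 F_tb      fibroblasts, wound
    13 L1_tb     pro-inflammatory T lymphocytes, wound
    14 L2_tb     anti-inflammatory T lymphocytes, wound
    15 P_tb      pathogen, wound
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .parameters import InvalidParameterError, ParameterSet

__all__ = [
    "STATE_NAMES",
    "N_STATES",
    "M2_INHIBITION_DOSE_GY",
    "Exposure",
    "ActivationRates",
    "inhibitory_omega",
    "hill_omega",
    "dose_delay_v",
    "activation_rates",
    "rhs",
]

STATE_NAMES: tuple[str, ...] = (
    "N_st_ud", "M_st_ud", "M_st_d", "L_st_ud", "L_st_d", "F_st_ud", "F_st_d",
    "Dam_tb", "Deb_tb", "N_tb", "M1_tb", "M2_tb", "F_tb", "L1_tb", "L2_tb",
    "P_tb",
)
N_STATES = len(STATE_NAMES)
IDX = {name: i for i, name in enumerate(STATE_NAMES)}

#: Prompt dose (Gy) at and above which M2 activation is inhibited by the
#: damaged resident monocyte pool.  Below this dose activation proceeds at
#: the uninhibited rate.
M2_INHIBITION_DOSE_GY = 2.0


@dataclass(frozen=True, slots=True)
class Exposure:
    """Injury severity inputs.

    Parameters
    ----------
    fluence
        Thermal fluence of the flash burn, J/cm^2.
    dose_gy
        Prompt locally-absorbed radiation dose, Gy.  ``0`` encodes a
        burn-only scenario.
    """

    fluence: float
    dose_gy: float

    def __post_init__(self) -> None:
        if self.fluence < 0:
            raise ValueError(f"thermal fluence must be >= 0, got {self.fluence}")
        if self.dose_gy < 0:
            raise ValueError(f"radiation dose must be >= 0, got {self.dose_gy}")


@dataclass(frozen=True, slots=True)
class ActivationRates:
    """Instantaneous activation rates (per hour) at the wound site."""

    Rn: float
    Rm1: float
    Rm2: float
    Rl1: float
    Rl2: float


def inhibitory_omega(x: float, inhibitors: Sequence[tuple[float, float]] = ()) -> float:
    """Inhibitory function: ``x / (1 + sum((Y/Y_inf)^2))``.

    Each ``(Y, Y_inf)`` pair contributes a squared saturating inhibition
    term; an empty list leaves ``x`` unchanged.  Strictly decreasing in
    every inhibitor level ``Y`` and never exceeds ``x`` for ``x >= 0``.
    """
    denom = 1.0
    for y, y_inf in inhibitors:
        if y_inf <= 0:
            raise InvalidParameterError(
                f"inhibition saturation must be > 0, got {y_inf}"
            )
        denom += (y / y_inf) ** 2
    return x / denom


def hill_omega(x: float, n: float, x_half: float) -> float:
    """Hill function ``x^n / (x_half^n + x^n)``; 0.5 at ``x == x_half``."""
    if x_half <= 0:
        raise InvalidParameterError(f"half-saturation must be > 0, got {x_half}")
    if x < 0:
        raise ValueError(f"hill input must be >= 0, got {x}")
    if n < 1:
        raise InvalidParameterError(f"hill exponent must be >= 1, got {n}")
    if x == 0.0:
        return 0.0
    xn = x**n
    return xn / (x_half**n + xn)


def dose_delay_v(t: float, dose_gy: float, gamma: float) -> float:
    """Dose-dependent influx recovery ``1 - exp(-gamma * DR * t)``.

    Models delayed extravasation through radiation-damaged microvasculature:
    identically 1 with no dose, 0 immediately after exposure, saturating to
    1 as the vasculature recovers.  ``gamma`` has units 1/(Gy h).
    """
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    if gamma <= 0:
        raise InvalidParameterError(f"gamma must be > 0, got {gamma}")
    if dose_gy == 0:
        return 1.0
    return 1.0 - math.exp(-gamma * dose_gy * t)


def activation_rates(state: np.ndarray, params: ParameterSet, dose_gy: float) -> ActivationRates:
    """Activation rates of wound-site immune populations for one state.

    ``Rm2`` is the *uninhibited* alternative-activation rate; the extra
    inhibition by the damaged resident monocyte pool (applied only when the
    prompt dose is at least :data:`M2_INHIBITION_DOSE_GY`) is introduced by
    the flux assembly in :func:`rhs`, not here.
    """
    s = np.asarray(state, dtype=float)
    p = params
    deb, n = s[IDX["Deb_tb"]], s[IDX["N_tb"]]
    m1, m2, f = s[IDX["M1_tb"]], s[IDX["M2_tb"]], s[IDX["F_tb"]]
    l1, l2, path = s[IDX["L1_tb"]], s[IDX["L2_tb"]], s[IDX["P_tb"]]

    rn = inhibitory_omega(
        p.knd * deb + p.knp * path + p.knn * n,
        [(m2, p.M2_inf), (l2, p.L21_inf)],
    )
    rm1 = inhibitory_omega(
        p.km1d * deb + p.km1p * path + p.km1n * n + p.km1m1 * m1 + p.km1l1 * l1,
        [(m2, p.M2_inf), (l2, p.L21_inf)],
    )
    rm2 = inhibitory_omega(
        p.km2m1 * m1 + p.km2m2 * m2 + p.km2l2 * l2,
        [(n, p.N1_inf), (m1, p.M11_inf), (f, p.F_inf)],
    )
    rl1 = inhibitory_omega(p.kl1 * m1, [(l2, p.L21_inf)])
    rl2 = inhibitory_omega(p.kl2 * m2, [(f, p.F_inf)])
    return ActivationRates(Rn=rn, Rm1=rm1, Rm2=rm2, Rl1=rl1, Rl2=rl2)


def rhs(t: float, state: np.ndarray, params: ParameterSet, exposure: Exposure) -> np.ndarray:
    """Time derivative of the full 16-component state.

    States are clipped at zero on entry: the phagocytosis and decay terms
    can numerically overshoot during stiff transients, and all fluxes are
    defined for non-negative populations only.
    """
    return _rhs(t, np.asarray(state, dtype=float), params.to_vector(), exposure.dose_gy)


def _rhs(t: float, state: np.ndarray, pv: np.ndarray, dose_gy: float) -> np.ndarray:
    """Fast path: parameters pre-flattened to the canonical vector."""
    (N1_inf, N2_inf, M11_inf, M12_inf, M2_inf, F_inf, L21_inf, L22_inf,
     Deb_dam_inf, Deb_H, N_H, M1_H,
     gamma_n, gamma_m, gamma_l, gamma_f, omega_m2, omega_f, omega_dam,
     kdn, kdm1, rho_dam, kdf, kdnp, kdm1p, kdm2p, ddeb,
     snr, dnr, knd, knp, knn, knm1p, knm2p, dn,
     smr, dmr_ud, dmr_d, km1d, km1p, km1n, km1m1, km1l1,
     km2m1, km2m2, km2l2, theta_m1m2, dm1, dm2,
     slr, dlr_ud, dlr_d, kl1, kl2, dl,
     sf, ksttb_ud, ksttb_d, kf, alpha_dam, alpha_m2, dfr_ud, dfr_d, df,
     kpg, P_inf, kpb, sb, mu_b, kbp, kpn, kpm1, kpm2) = pv

    y = np.maximum(state, 0.0)
    (n_st, m_st_ud, m_st_d, l_st_ud, l_st_d, f_st_ud, f_st_d,
     dam, deb, n, m1, m2, f, l1, l2, p) = y

    # dose-delayed blood-stream influx (microvascular damage)
    if dose_gy == 0.0:
        v_n = v_m = v_l = v_f = 1.0
    else:
        v_n = 1.0 - math.exp(-gamma_n * dose_gy * t)
        v_m = 1.0 - math.exp(-gamma_m * dose_gy * t)
        v_l = 1.0 - math.exp(-gamma_l * dose_gy * t)
        v_f = 1.0 - math.exp(-gamma_f * dose_gy * t)

    # activation rates
    inh_m2l2 = 1.0 + (m2 / M2_inf) ** 2 + (l2 / L21_inf) ** 2
    rn = (knd * deb + knp * p + knn * n) / inh_m2l2
    rm1 = (km1d * deb + km1p * p + km1n * n + km1m1 * m1 + km1l1 * l1) / inh_m2l2
    rm2 = (km2m1 * m1 + km2m2 * m2 + km2l2 * l2) / (
        1.0 + (n / N1_inf) ** 2 + (m1 / M11_inf) ** 2 + (f / F_inf) ** 2
    )
    # M2 activation is additionally inhibited by the damaged resident
    # monocyte pool, but only at prompt doses >= 2 Gy.
    if dose_gy >= M2_INHIBITION_DOSE_GY:
        rm2_eff = rm2 / (1.0 + (m_st_d / omega_m2) ** 2)
    else:
        rm2_eff = rm2
    rl1 = (kl1 * m1) / (1.0 + (l2 / L21_inf) ** 2)
    rl2 = (kl2 * m2) / (1.0 + (f / F_inf) ** 2)

    # collateral damage/debris generation: steep (Hill n=6) response to the
    # L2-inhibited neutrophil and M1 levels
    n_inh = n / (1.0 + (l2 / L22_inf) ** 2)
    m1_inh = m1 / (1.0 + (l2 / L22_inf) ** 2)
    gen = kdn * _hill6(n_inh, N_H) + kdm1 * _hill6(m1_inh, M1_H)

    dam_res = dam / (1.0 + (deb / Deb_dam_inf) ** 2)
    deb_ph = deb / (Deb_H + deb)  # Hill exponent 1 phagocytosis saturation
    m1_n_inh = m1 / (1.0 + (n / N1_inf) ** 2)
    m2_n_inh = m2 / (1.0 + (n / N1_inf) ** 2)

    d_dam = (
        gen
        - rho_dam * dam_res
        - (f / (1.0 + (f_st_d / omega_dam) ** 2)) * kdf * dam_res
    )
    d_deb = (
        gen
        - kdnp * n * deb_ph
        - kdm1p * m1_n_inh * deb_ph
        - kdm2p * m2_n_inh * deb_ph
        - ddeb * deb
    )

    d_n_st = v_n * snr * dam - rn * n_st - dnr * n_st
    d_n = rn * n_st - knm1p * n * m1_n_inh - knm2p * n * m2_n_inh - dn * n

    d_m_st_ud = v_m * smr - rm1 * m_st_ud - rm2_eff * m_st_ud - dmr_ud * m_st_ud
    d_m_st_d = -rm1 * m_st_d - rm2_eff * m_st_d - dmr_d * m_st_d
    m1_to_m2 = theta_m1m2 * (knm1p * n * m1_n_inh)
    d_m1 = rm1 * (m_st_ud + m_st_d) - m1_to_m2 - dm1 * m1
    d_m2 = rm2_eff * (m_st_ud + m_st_d) + m1_to_m2 - dm2 * m2

    d_l_st_ud = v_l * slr - rl1 * l_st_ud - rl2 * l_st_ud - dlr_ud * l_st_ud
    d_l_st_d = -rl1 * l_st_d - rl2 * l_st_d - dlr_d * l_st_d
    d_l1 = rl1 * (l_st_ud + l_st_d) - dl * l1
    d_l2 = rl2 * (l_st_ud + l_st_d) - dl * l2

    d_f_st_ud = v_f * sf - ksttb_ud * f_st_ud - dfr_ud * f_st_ud
    d_f_st_d = -ksttb_d * f_st_d - dfr_d * f_st_d
    d_f = (
        (1.0 / (1.0 + (f_st_d / omega_f) ** 2))
        * (f / (1.0 + (n / N2_inf) ** 2 + (m1 / M12_inf) ** 2))
        * (kf + alpha_dam * dam + alpha_m2 * m2)
        + ksttb_ud * f_st_ud
        + ksttb_d * f_st_d
        - df * f
    )

    d_p = (
        kpg * p * (1.0 - p / P_inf)
        - kpb * sb * p / (mu_b + kbp * p)
        - kpn * p * n
        - kpm1 * p * m1_n_inh
        - kpm2 * p * m2_n_inh
    )

    return np.array([
        d_n_st, d_m_st_ud, d_m_st_d, d_l_st_ud, d_l_st_d, d_f_st_ud, d_f_st_d,
        d_dam, d_deb, d_n, d_m1, d_m2, d_f, d_l1, d_l2, d_p,
    ])


def _hill6(x: float, x_half: float) -> float:
    if x == 0.0:
        return 0.0
    x6 = x**6
    return x6 / (x_half**6 + x6)
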