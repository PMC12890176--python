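"""Independent term-by-term oracle for the model right-hand side.

Deliberately naive and self-contained: every flux is written out directly
from the model equations using plain dict arithmetic, with no imports from
the package's model code.  Used to cross-check the production RHS.
"""

from __future__ import annotations

import math


def omega_i(x, pairs):
    return x / (1.0 + sum((y / y_inf) ** 2 for y, y_inf in pairs))


def omega_h(x, n, x_half):
    if x == 0:
        return 0.0
    return x**n / (x_half**n + x**n)


def v_delay(t, dr, gamma):
    if dr == 0:
        return 1.0
    return 1.0 - math.exp(-gamma * dr * t)


def naive_rhs(t: float, s: dict, p: dict, dr: float) -> dict:
    """Derivatives keyed by state name; ``s`` maps state name -> level."""
    s = {k: max(v, 0.0) for k, v in s.items()}

    rn = omega_i(
        p["knd"] * s["Deb_tb"] + p["knp"] * s["P_tb"] + p["knn"] * s["N_tb"],
        [(s["M2_tb"], p["M2_inf"]), (s["L2_tb"], p["L21_inf"])],
    )
    rm1 = omega_i(
        p["km1d"] * s["Deb_tb"] + p["km1p"] * s["P_tb"] + p["km1n"] * s["N_tb"]
        + p["km1m1"] * s["M1_tb"] + p["km1l1"] * s["L1_tb"],
        [(s["M2_tb"], p["M2_inf"]), (s["L2_tb"], p["L21_inf"])],
    )
    rm2 = omega_i(
        p["km2m1"] * s["M1_tb"] + p["km2m2"] * s["M2_tb"] + p["km2l2"] * s["L2_tb"],
        [(s["N_tb"], p["N1_inf"]), (s["M1_tb"], p["M11_inf"]), (s["F_tb"], p["F_inf"])],
    )
    if dr >= 2.0:
        rm2_eff = omega_i(rm2, [(s["M_st_d"], p["omega_m2"])])
    else:
        rm2_eff = rm2
    rl1 = omega_i(p["kl1"] * s["M1_tb"], [(s["L2_tb"], p["L21_inf"])])
    rl2 = omega_i(p["kl2"] * s["M2_tb"], [(s["F_tb"], p["F_inf"])])

    gen = (
        p["kdn"] * omega_h(omega_i(s["N_tb"], [(s["L2_tb"], p["L22_inf"])]), 6, p["N_H"])
        + p["kdm1"] * omega_h(omega_i(s["M1_tb"], [(s["L2_tb"], p["L22_inf"])]), 6, p["M1_H"])
    )
    dam_res = omega_i(s["Dam_tb"], [(s["Deb_tb"], p["Deb_dam_inf"])])
    deb_ph = omega_h(s["Deb_tb"], 1, p["Deb_H"])

    d = {}
    d["Dam_tb"] = (
        gen
        - p["rho_dam"] * dam_res
        - omega_i(s["F_tb"], [(s["F_st_d"], p["omega_dam"])]) * p["kdf"] * dam_res
    )
    d["Deb_tb"] = (
        gen
        - p["kdnp"] * s["N_tb"] * deb_ph
        - p["kdm1p"] * omega_i(s["M1_tb"], [(s["N_tb"], p["N1_inf"])]) * deb_ph
        - p["kdm2p"] * omega_i(s["M2_tb"], [(s["N_tb"], p["N1_inf"])]) * deb_ph
        - p["ddeb"] * s["Deb_tb"]
    )
    d["N_st_ud"] = (
        v_delay(t, dr, p["gamma_n"]) * p["snr"] * s["Dam_tb"]
        - rn * s["N_st_ud"] - p["dnr"] * s["N_st_ud"]
    )
    d["N_tb"] = (
        rn * s["N_st_ud"]
        - p["knm1p"] * s["N_tb"] * omega_i(s["M1_tb"], [(s["N_tb"], p["N1_inf"])])
        - p["knm2p"] * s["N_tb"] * omega_i(s["M2_tb"], [(s["N_tb"], p["N1_inf"])])
        - p["dn"] * s["N_tb"]
    )
    d["M_st_ud"] = (
        v_delay(t, dr, p["gamma_m"]) * p["smr"]
        - rm1 * s["M_st_ud"] - rm2_eff * s["M_st_ud"] - p["dmr_ud"] * s["M_st_ud"]
    )
    d["M_st_d"] = -rm1 * s["M_st_d"] - rm2_eff * s["M_st_d"] - p["dmr_d"] * s["M_st_d"]
    transition = p["theta_m1m2"] * (
        p["knm1p"] * s["N_tb"] * omega_i(s["M1_tb"], [(s["N_tb"], p["N1_inf"])])
    )
    d["M1_tb"] = rm1 * (s["M_st_ud"] + s["M_st_d"]) - transition - p["dm1"] * s["M1_tb"]
    d["M2_tb"] = rm2_eff * (s["M_st_ud"] + s["M_st_d"]) + transition - p["dm2"] * s["M2_tb"]
    d["L_st_ud"] = (
        v_delay(t, dr, p["gamma_l"]) * p["slr"]
        - rl1 * s["L_st_ud"] - rl2 * s["L_st_ud"] - p["dlr_ud"] * s["L_st_ud"]
    )
    d["L_st_d"] = -rl1 * s["L_st_d"] - rl2 * s["L_st_d"] - p["dlr_d"] * s["L_st_d"]
    d["L1_tb"] = rl1 * (s["L_st_ud"] + s["L_st_d"]) - p["dl"] * s["L1_tb"]
    d["L2_tb"] = rl2 * (s["L_st_ud"] + s["L_st_d"]) - p["dl"] * s["L2_tb"]
    d["F_st_ud"] = (
        v_delay(t, dr, p["gamma_f"]) * p["sf"]
        - p["ksttb_ud"] * s["F_st_ud"] - p["dfr_ud"] * s["F_st_ud"]
    )
    d["F_st_d"] = -p["ksttb_d"] * s["F_st_d"] - p["dfr_d"] * s["F_st_d"]
    d["F_tb"] = (
        omega_i(1.0, [(s["F_st_d"], p["omega_f"])])
        * omega_i(s["F_tb"], [(s["N_tb"], p["N2_inf"]), (s["M1_tb"], p["M12_inf"])])
        * (p["kf"] + p["alpha_dam"] * s["Dam_tb"] + p["alpha_m2"] * s["M2_tb"])
        + p["ksttb_ud"] * s["F_st_ud"] + p["ksttb_d"] * s["F_st_d"]
        - p["df"] * s["F_tb"]
    )
    d["P_tb"] = (
        p["kpg"] * s["P_tb"] * (1.0 - s["P_tb"] / p["P_inf"])
        - p["kpb"] * p["sb"] * s["P_tb"] / (p["mu_b"] + p["kbp"] * s["P_tb"])
        - p["kpn"] * s["P_tb"] * s["N_tb"]
        - p["kpm1"] * s["P_tb"] * omega_i(s["M1_tb"], [(s["N_tb"], p["N1_inf"])])
        - p["kpm2"] * s["P_tb"] * omega_i(s["M2_tb"], [(s["N_tb"], p["N1_inf"])])
    )
    return d
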