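"""Kinetic parameters of the radiation-combined-injury (RCI) burn model.

Every rate, saturation and inhibition constant of the two-compartment
burn + local-irradiation ODE system lives in a single flat
:class:`ParameterSet`.  Names follow the field's symbols with unicode
replaced by ASCII: a trailing ``_inf`` is a saturation constant (Y-infinity
in an inhibitory function), ``_ud``/``_d`` distinguish rates acting on
undamaged vs radiation-damaged resident populations, and the time unit is
hours throughout.

The Hill exponent of the collateral-damage terms is a structural constant
(``N_HILL = 6``), not a tunable parameter.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "ParameterSet",
    "InvalidParameterError",
    "PARAM_GROUPS",
    "PARAM_NAMES",
    "ESTIMATE_SET",
    "FIX_SET",
]

#: Parameter names by functional group (order defines the canonical
#: flattened parameter vector used by the samplers).
PARAM_GROUPS: dict[str, tuple[str, ...]] = {
    "inhibition": (
        "N1_inf", "N2_inf", "M11_inf", "M12_inf", "M2_inf", "F_inf",
        "L21_inf", "L22_inf", "Deb_dam_inf", "Deb_H", "N_H", "M1_H",
    ),
    "radiation": (
        "gamma_n", "gamma_m", "gamma_l", "gamma_f",
        "omega_m2", "omega_f", "omega_dam",
    ),
    "damage_debris": (
        "kdn", "kdm1", "rho_dam", "kdf", "kdnp", "kdm1p", "kdm2p", "ddeb",
    ),
    "neutrophil": (
        "snr", "dnr", "knd", "knp", "knn", "knm1p", "knm2p", "dn",
    ),
    "macrophage": (
        "smr", "dmr_ud", "dmr_d", "km1d", "km1p", "km1n", "km1m1", "km1l1",
        "km2m1", "km2m2", "km2l2", "theta_m1m2", "dm1", "dm2",
    ),
    "lymphocyte": (
        "slr", "dlr_ud", "dlr_d", "kl1", "kl2", "dl",
    ),
    "fibroblast": (
        "sf", "ksttb_ud", "ksttb_d", "kf", "alpha_dam", "alpha_m2",
        "dfr_ud", "dfr_d", "df",
    ),
    "pathogen": (
        "kpg", "P_inf", "kpb", "sb", "mu_b", "kbp", "kpn", "kpm1", "kpm2",
    ),
}

PARAM_NAMES: tuple[str, ...] = tuple(
    name for group in PARAM_GROUPS.values() for name in group
)

#: Parameters flagged influential by the global sensitivity screen and
#: therefore re-sampled in the final feasibility stage; all others are
#: pinned at the midpoint of their initial range.
ESTIMATE_SET: tuple[str, ...] = (
    # inhibition
    "N1_inf", "M11_inf", "M2_inf",
    # radiation-related
    "gamma_n", "gamma_m", "omega_f",
    # damage and debris
    "kdnp", "kdm1p",
    # neutrophils
    "knd", "snr", "knm1p", "dn",
    # macrophages
    "km1d", "km1n", "km2m1", "smr", "dmr_ud", "dm1", "km1p",
    # lymphocytes
    "kl1",
    # pathogen
    "kpg", "P_inf", "kpb", "sb", "kbp", "kpn",
)

FIX_SET: tuple[str, ...] = tuple(
    n for n in PARAM_NAMES if n not in ESTIMATE_SET
)


class InvalidParameterError(ValueError):
    """A parameter value or configuration key is not admissible."""


def _post_init(self) -> None:
    for name in PARAM_NAMES:
        value = getattr(self, name)
        if not (value > 0.0):
            raise InvalidParameterError(
                f"parameter {name!r} must be strictly positive, got {value!r}"
            )


def _to_dict(self) -> dict[str, float]:
    """Flat name -> value mapping in canonical order."""
    return {name: float(getattr(self, name)) for name in PARAM_NAMES}


def _from_dict(cls, mapping: Mapping[str, float]) -> "ParameterSet":
    """Build from a flat mapping; unknown or missing keys are rejected."""
    unknown = set(mapping) - set(PARAM_NAMES)
    if unknown:
        raise InvalidParameterError(f"unknown parameter keys: {sorted(unknown)}")
    missing = set(PARAM_NAMES) - set(mapping)
    if missing:
        raise InvalidParameterError(f"missing parameter keys: {sorted(missing)}")
    return cls(**{k: float(v) for k, v in mapping.items()})


def _replace(self, **changes: float) -> "ParameterSet":
    return dataclasses.replace(self, **changes)


def _to_vector(self) -> np.ndarray:
    """Values in canonical :data:`PARAM_NAMES` order."""
    return np.array([getattr(self, name) for name in PARAM_NAMES])


def _from_vector(cls, vector) -> "ParameterSet":
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (len(PARAM_NAMES),):
        raise InvalidParameterError(
            f"expected vector of length {len(PARAM_NAMES)}, got {vector.shape}"
        )
    return cls(**dict(zip(PARAM_NAMES, vector.tolist())))


def _to_yaml(self, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _from_yaml(cls, path) -> "ParameterSet":
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise InvalidParameterError(f"{path}: expected a flat mapping")
    return cls.from_dict(data)


# 73 required float fields; generated from the registry so the dataclass,
# the samplers and the config reader can never drift apart.
ParameterSet = dataclasses.make_dataclass(
    "ParameterSet",
    [(name, float) for name in PARAM_NAMES],
    frozen=True,
    slots=True,
    namespace={
        "N_HILL": 6,
        "__post_init__": _post_init,
        "to_dict": _to_dict,
        "from_dict": classmethod(_from_dict),
        "replace": _replace,
        "to_vector": _to_vector,
        "from_vector": classmethod(_from_vector),
        "to_yaml": _to_yaml,
        "from_yaml": classmethod(_from_yaml),
        "__module__": __name__,
    },
)
ParameterSet.__doc__ = (
    "Flat, immutable set of the model's kinetic constants (per-hour rates,\n"
    "saturation levels, and unitless fractions).  All values must be\n"
    "strictly positive; the Hill exponent ``N_HILL = 6`` is structural."
)
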