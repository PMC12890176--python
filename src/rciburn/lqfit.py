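"""Linear-quadratic survival-curve fitting for dose-dependent initial splits.

Clonogenic survival after an acute dose ``D`` is modelled as
``S(D) = exp(-alpha*D - beta*D^2)``.  The fit minimises the residual sum of
squares on the survival scale (not log-survival) with a derivative-free
Nelder-Mead simplex from a fixed start — the conventional way these curves
are regressed when only a handful of dose points are available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .initial import LQCoefficients

__all__ = ["SurvivalTable", "FitResult", "fit_lq", "synthetic_survival_table"]


@dataclass(frozen=True)
class SurvivalTable:
    """Dose-survival data: doses in Gy, surviving fractions in (0, 1]."""

    doses: tuple[float, ...]
    fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.doses) != len(self.fractions):
            raise ValueError("doses and fractions must have equal length")
        if len(set(self.doses)) < 2:
            raise ValueError("need at least 2 distinct doses")
        if any(d < 0 for d in self.doses):
            raise ValueError("doses must be >= 0")
        if any(not 0 < f <= 1 for f in self.fractions):
            raise ValueError("fractions must be in (0, 1]")

    @classmethod
    def from_csv(cls, path) -> "SurvivalTable":
        df = pd.read_csv(path)
        return cls(tuple(df["dose"]), tuple(df["fraction"]))


@dataclass(frozen=True)
class FitResult:
    coefficients: LQCoefficients
    rss: float

    def to_dict(self) -> dict:
        return {
            "alpha": self.coefficients.alpha,
            "beta": self.coefficients.beta,
            "rss": self.rss,
        }


_START = (0.1, 0.01)  # documented simplex start (alpha, beta)


def fit_lq(
    table: SurvivalTable,
    order: Literal["linear", "linear-quadratic"] = "linear-quadratic",
) -> FitResult:
    """Least-squares LQ coefficients for a survival table.

    ``order="linear"`` pins ``beta = 0`` (pure exponential).  Negative
    trial coefficients are clipped to zero inside the objective, so the
    returned ``alpha, beta`` are always admissible.
    """
    doses = np.asarray(table.doses, dtype=float)
    fractions = np.asarray(table.fractions, dtype=float)

    def model(alpha: float, beta: float) -> np.ndarray:
        return np.exp(-alpha * doses - beta * doses**2)

    if order == "linear":
        def objective(x):
            a = max(x[0], 0.0)
            return float(((model(a, 0.0) - fractions) ** 2).sum())
        res = minimize(objective, [_START[0]], method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 2000})
        alpha, beta = max(float(res.x[0]), 0.0), 0.0
    elif order == "linear-quadratic":
        def objective(x):
            a, b = max(x[0], 0.0), max(x[1], 0.0)
            return float(((model(a, b) - fractions) ** 2).sum())
        res = minimize(objective, list(_START), method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 4000})
        alpha, beta = max(float(res.x[0]), 0.0), max(float(res.x[1]), 0.0)
    else:
        raise ValueError(f"unknown order {order!r}")

    if not res.success and res.fun > 1e-6:
        raise RuntimeError(f"LQ fit did not converge: {res.message}")
    rss = float(((model(alpha, beta) - fractions) ** 2).sum())
    return FitResult(LQCoefficients(alpha=alpha, beta=beta), rss)


def synthetic_survival_table(
    coeff: LQCoefficients,
    doses: Sequence[float],
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> SurvivalTable:
    """Survival table generated from known coefficients.

    Optional multiplicative log-normal noise (``noise_sigma`` on the log
    scale) mimics assay scatter; fractions are clipped into (0, 1].
    """
    doses = np.asarray(doses, dtype=float)
    frac = np.exp(-coeff.alpha * doses - coeff.beta * doses**2)
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng()
        frac = frac * np.exp(rng.normal(0.0, noise_sigma, size=len(doses)))
    frac = np.clip(frac, 1e-12, 1.0)
    return SurvivalTable(tuple(doses.tolist()), tuple(frac.tolist()))
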