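"""Variance-based global sensitivity: eFAST indices and the MeFAST battery.

The extended Fourier Amplitude Sensitivity Test (eFAST) drives every
parameter along a space-filling search curve

    x_j(s) = 1/2 + (1/pi) * arcsin(sin(w_j * s + phi_j)),

assigning the parameter of interest the highest interference-free frequency
``w_max = (NS - 1) / (2 * Mi)`` and the complementary set low frequencies.
The first-order index ``Si`` is the fraction of output variance at the
harmonics of ``w_max``; the total-order index ``STi`` is one minus the
fraction below ``w_max / 2``.  Repeating the curve with ``NR`` random phase
shifts yields a resampling distribution for each index.

A *dummy parameter* — sampled like the others but never entering the model
— provides the null distribution.  The MeFAST battery compares each
parameter's index resamples with the dummy's by a two-sample t-test, a
one-way ANOVA with Tukey's HSD, and the Wilcoxon rank-sum test; parameters
significant under the configured aggregation rule are classified "estimate"
(influential, worth constraining) and the rest "fix".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DUMMY_NAME",
    "SensitivityDesign",
    "SensitivityReport",
    "efast_sample",
    "efast_indices_from_output",
    "efast_indices",
    "mefast_tests",
    "classify_parameters",
]

DUMMY_NAME = "_dummy"


@dataclass(frozen=True)
class SensitivityDesign:
    """eFAST sampling configuration.

    ``ns`` points per search curve (>= 65 so the interference factor
    ``mi = 4`` leaves room for four clean harmonics), ``nr`` random phase
    resamples per parameter.  ``output_days`` and ``doses_gy`` describe the
    model readout grid used by the full-model screen.
    """

    ns: int = 2000
    nr: int = 32
    mi: int = 4
    seed: int = 0
    alpha: float = 0.05
    output_days: tuple[float, ...] = (1.0, 3.0, 7.0, 10.0, 14.0)
    doses_gy: tuple[float, ...] = (1.0, 7.0, 14.0)
    include_dummy: bool = True

    def __post_init__(self) -> None:
        if self.ns < 4 * self.mi**2 + 1:
            raise ValueError(
                f"ns must be >= 4*mi^2+1 = {4 * self.mi**2 + 1} "
                f"for interference factor mi={self.mi}, got {self.ns}"
            )
        if self.nr < 1:
            raise ValueError("nr must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class SensitivityReport:
    """Indices and test outcomes of one eFAST/MeFAST run.

    ``si``/``sti`` have shape (n_params, n_outputs, nr): per-parameter,
    per-readout resampling distributions of the first- and total-order
    indices.  Test p-values (filled by :func:`mefast_tests`) have shape
    (n_params, n_outputs); the dummy row carries NaN.
    """

    param_names: list[str]
    output_names: list[str]
    si: np.ndarray
    sti: np.ndarray
    design: SensitivityDesign
    p_t: np.ndarray | None = None
    p_anova: np.ndarray | None = None
    p_wilcoxon: np.ndarray | None = None
    influential: dict[str, bool] = field(default_factory=dict)

    @property
    def dummy_index(self) -> int:
        return self.param_names.index(DUMMY_NAME)

    def mean_indices(self) -> pd.DataFrame:
        """Tidy frame of resample-averaged Si/STi per parameter and output."""
        rows = []
        for i, p in enumerate(self.param_names):
            for j, o in enumerate(self.output_names):
                rows.append({
                    "parameter": p, "output": o,
                    "Si": float(self.si[i, j].mean()),
                    "STi": float(self.sti[i, j].mean()),
                })
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        """Full tidy report: indices, p-values and the influential flag."""
        df = self.mean_indices()
        for name, arr in (("p_t", self.p_t), ("p_anova", self.p_anova),
                          ("p_wilcoxon", self.p_wilcoxon)):
            if arr is not None:
                df[name] = [
                    float(arr[self.param_names.index(r.parameter),
                              self.output_names.index(r.output)])
                    for r in df.itertuples()
                ]
        if self.influential:
            df["influential"] = [self.influential.get(p, False) for p in df["parameter"]]
        return df


def _frequencies(n_params: int, ns: int, mi: int) -> tuple[int, np.ndarray]:
    """Highest interference-free frequency and the complementary set."""
    w_max = (ns - 1) // (2 * mi)
    if w_max < 1:
        raise ValueError("ns too small for the interference factor")
    w_comp_max = max(1, w_max // (2 * mi))
    others = n_params - 1
    if others == 0:
        return w_max, np.array([], dtype=int)
    if w_comp_max >= others:
        # spread complementary frequencies evenly over [1, w_comp_max]
        comp = np.floor(np.linspace(1, w_comp_max, others)).astype(int)
    else:
        comp = 1 + (np.arange(others) % w_comp_max)
    return w_max, comp


def efast_sample(
    names: Sequence[str],
    ranges: Mapping[str, tuple[float, float]],
    design: SensitivityDesign,
) -> list[list[np.ndarray]]:
    """Design matrices ``[param_of_interest][resample] -> (ns, d)``.

    Each matrix holds one search curve: the parameter of interest runs at
    the high frequency, all others at complementary low frequencies, with
    fresh random phases per resample (seeded from ``design.seed``).
    """
    d = len(names)
    rng = np.random.default_rng(design.seed)
    s = (2.0 * np.pi / design.ns) * np.arange(design.ns)
    w_max, comp = _frequencies(d, design.ns, design.mi)
    lo = np.array([ranges[n][0] for n in names])
    hi = np.array([ranges[n][1] for n in names])
    all_matrices = []
    for i in range(d):
        freqs = np.empty(d)
        freqs[i] = w_max
        freqs[[j for j in range(d) if j != i]] = comp
        per_resample = []
        for _ in range(design.nr):
            phi = rng.uniform(0.0, 2.0 * np.pi, size=d)
            x = 0.5 + (1.0 / np.pi) * np.arcsin(np.sin(freqs[None, :] * s[:, None] + phi[None, :]))
            per_resample.append(lo + x * (hi - lo))
        all_matrices.append(per_resample)
    return all_matrices


def _spectrum_indices(y: np.ndarray, ns: int, mi: int, w_max: int) -> tuple[float, float]:
    """(Si, STi) of one output series along one search curve."""
    y = y - y.mean()
    coeffs = np.fft.rfft(y) / ns
    power = np.abs(coeffs[1:]) ** 2  # frequency 1 .. ns//2
    total = 2.0 * power.sum()
    if total <= 0:
        return 0.0, 0.0
    harmonics = [p * w_max for p in range(1, mi + 1) if p * w_max <= len(power)]
    v_first = 2.0 * sum(power[h - 1] for h in harmonics)
    cutoff = max(1, w_max // 2)
    v_comp = 2.0 * power[:cutoff].sum()
    return float(v_first / total), float(1.0 - v_comp / total)


def efast_indices_from_output(
    outputs: np.ndarray,
    design: SensitivityDesign,
) -> tuple[np.ndarray, np.ndarray]:
    """Si/STi from precomputed curve outputs of shape (d, nr, ns, n_out)."""
    d, nr, ns, n_out = outputs.shape
    w_max, _ = _frequencies(d, ns, design.mi)
    si = np.empty((d, n_out, nr))
    sti = np.empty((d, n_out, nr))
    for i in range(d):
        for r in range(nr):
            for k in range(n_out):
                si[i, k, r], sti[i, k, r] = _spectrum_indices(
                    outputs[i, r, :, k], ns, design.mi, w_max
                )
    return si, sti


def efast_indices(
    func: Callable[[np.ndarray], np.ndarray],
    names: Sequence[str],
    ranges: Mapping[str, tuple[float, float]],
    design: SensitivityDesign,
    output_names: Sequence[str] | None = None,
) -> SensitivityReport:
    """Run the full eFAST screen for a vector-valued model readout.

    ``func`` maps a design matrix of shape (ns, d) — columns in ``names``
    order — to outputs of shape (ns, n_outputs).  A dummy parameter on
    (0, 1) is appended internally (never passed to ``func``) unless the
    design disables it.  Readout failures (NaN rows) are replaced by the
    curve's mean output with a warning, keeping the spectrum estimable.
    """
    n_user = len(names)
    names = list(names)
    ranges = dict(ranges)
    if design.include_dummy:
        names = names + [DUMMY_NAME]
        ranges[DUMMY_NAME] = (0.0, 1.0)
    matrices = efast_sample(names, ranges, design)

    probe = np.asarray(func(matrices[0][0][:, :n_user]), dtype=float)
    if probe.ndim == 1:
        probe = probe[:, None]
    n_out = probe.shape[1]
    if output_names is None:
        output_names = [f"y{k}" for k in range(n_out)]

    outputs = np.empty((len(names), design.nr, design.ns, n_out))
    for i, per_resample in enumerate(matrices):
        for r, mat in enumerate(per_resample):
            y = np.asarray(func(mat[:, :n_user]), dtype=float)
            if y.ndim == 1:
                y = y[:, None]
            bad = ~np.isfinite(y).all(axis=1)
            if bad.any():
                import warnings

                warnings.warn(
                    f"{bad.sum()} readout failures on curve ({names[i]}, resample {r}); "
                    "points replaced by the curve mean",
                    stacklevel=2,
                )
                y[bad] = np.nanmean(np.where(np.isfinite(y), y, np.nan), axis=0)
            outputs[i, r] = y
    si, sti = efast_indices_from_output(outputs, design)
    return SensitivityReport(
        param_names=names, output_names=list(output_names),
        si=si, sti=sti, design=design,
    )


def mefast_tests(report: SensitivityReport, alpha: float | None = None) -> SensitivityReport:
    """Fill the three-test battery comparing each parameter to the dummy.

    Per output, each parameter's NR-resample index distribution is compared
    with the dummy's: Welch two-sample t-test; one-way ANOVA over all
    parameters with Tukey's HSD giving the adjusted parameter-vs-dummy
    p-value; Wilcoxon rank-sum.  The battery runs on both the first- and
    total-order indices and reports, per test, the smaller of the two
    p-values (a parameter is flagged if *either* index separates from the
    dummy).  Requires NR >= 2.
    """
    if report.design.nr < 2:
        raise ValueError("MeFAST tests require at least 2 resamples (nr >= 2)")
    if alpha is None:
        alpha = report.design.alpha
    d = len(report.param_names)
    n_out = len(report.output_names)
    idx_dummy = report.dummy_index
    p_t = np.full((d, n_out), np.inf)
    p_anova = np.full((d, n_out), np.inf)
    p_wilcoxon = np.full((d, n_out), np.inf)

    for indices in (report.si, report.sti):
        for k in range(n_out):
            groups = [indices[i, k] for i in range(d)]
            dummy = groups[idx_dummy]
            spread = max(float(np.ptp(g)) for g in groups)
            tukey = None
            if spread > 0:
                try:
                    tukey = stats.tukey_hsd(*groups)
                except ValueError:  # degenerate groups
                    tukey = None
            for i in range(d):
                if i == idx_dummy:
                    continue
                g = groups[i]
                if np.ptp(g) == 0 and np.ptp(dummy) == 0 and g[0] == dummy[0]:
                    pt = pw = pa = 1.0
                else:
                    pt = stats.ttest_ind(g, dummy, equal_var=False).pvalue
                    pw = stats.ranksums(g, dummy).pvalue
                    pa = tukey.pvalue[i, idx_dummy] if tukey is not None else 1.0
                p_t[i, k] = min(p_t[i, k], pt)
                p_anova[i, k] = min(p_anova[i, k], pa)
                p_wilcoxon[i, k] = min(p_wilcoxon[i, k], pw)
    for arr in (p_t, p_anova, p_wilcoxon):
        arr[idx_dummy, :] = np.nan
    report.p_t = p_t
    report.p_anova = p_anova
    report.p_wilcoxon = p_wilcoxon
    return report


def classify_parameters(
    report: SensitivityReport,
    alpha: float | None = None,
    min_significant_tests: int = 2,
) -> tuple[list[str], list[str]]:
    """Split parameters into (estimate, fix) lists.

    A parameter is influential — selected for estimation — when at least
    ``min_significant_tests`` of the three battery tests reject the dummy
    null at level ``alpha`` for at least one readout.  Everything else is
    fixed at its baseline.  The rule is deliberately a simple majority
    vote; pass ``min_significant_tests=3`` for a stricter unanimous rule.
    """
    if report.p_t is None:
        raise ValueError("run mefast_tests before classification")
    if alpha is None:
        alpha = report.design.alpha
    estimate, fix = [], []
    for i, name in enumerate(report.param_names):
        if name == DUMMY_NAME:
            continue
        votes = np.stack([
            report.p_t[i] < alpha,
            report.p_anova[i] < alpha,
            report.p_wilcoxon[i] < alpha,
        ])  # (3, n_outputs)
        influential = bool((votes.sum(axis=0) >= min_significant_tests).any())
        report.influential[name] = influential
        (estimate if influential else fix).append(name)
    return estimate, fix
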