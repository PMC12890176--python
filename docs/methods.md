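# Methods

## Model structure and assumptions

The simulator treats a flash burn with concurrent prompt local irradiation
as a well-mixed two-compartment system. The wound compartment tracks the
unitless damage and debris levels, activated innate and adaptive cell
populations, fibroblasts, and a pathogen load; the surrounding irradiated
tissue acts as the reservoir between the bloodstream and the wound, with
each resident population (monocytes, lymphocytes, fibroblasts) split into
an undamaged and a radiation-damaged pool. Core assumptions:

* **Well-mixed compartments.** No spatial gradients; immune-cell
  infiltration is a flux between compartments, not a front.
* **Instantaneous exposure.** Both the thermal fluence and the radiation
  dose act at `t = 0`: the fluence sets the initial damage/debris level
  (all wound cells are assumed killed), the dose sets the LQ survival split
  of the resident pools and parameterises the influx-delay function.
* **Cytokines are implicit.** Signalling is folded into mass-action and
  saturating interaction terms (`Ω_i`, `Ω_H`) between cell populations.
* **Damaged pools are sources of dysfunction.** Damaged resident
  monocytes inhibit M2 activation (only at ≥ 2 Gy, as a hard dose switch),
  damaged fibroblasts inhibit wound-fibroblast proliferation and damage
  resolution. Damaged pools receive no influx and decay faster than their
  undamaged counterparts.
* **Collateral damage is steep.** Neutrophil/M1-driven damage and debris
  generation uses Hill exponent 6 (a structural constant, not a sampled
  parameter): collateral injury is negligible until the inflammatory
  infiltrate crosses its half-saturation level.

The damaged-fibroblast pool obeys a pure two-rate exponential decay, so its
closed form `F₀·exp(−(k+d)t)` is substituted during integration and the
remaining 15 states are integrated numerically.

One structural point deserves note: the dose-delay function
`v = 1 − exp(−γ D_R t)` recovers *faster* at higher dose (the product
`γ·D_R` grows with dose). Consequently, influx-driven quantities rebound
sooner after 14 Gy than after 5 Gy, and dose-monotone outcomes must come
from the initial LQ splits and the damaged-pool inhibitions rather than
from the influx delay. This drives two documented behaviours: the
dose-monotonicity of healing and damage-peak times is robust for the
superficial scenario but can invert between 5 and 14 Gy for the
partial-thickness scenario (whose healing occurs after the damaged-pool
gradients have faded), and the resident monocyte pool under combined
injury can transiently exceed its burn-only level by a few percent of
resting (the ≥ 2 Gy switch suppresses the M2-activation drain on the
pool). The suppression check in the acceptance suite therefore allows an
excess of 5% of the resting level — a numeric reading of what is a
figure-level comparison.

## Parameters

All 73 kinetic constants live in a flat `ParameterSet` (units: per-hour
rates, per-Gy·hour `γ`s, unitless saturation levels and fractions).
Defaults are the midpoints of the shipped initial sampling ranges
(`src/rciburn/data/initial_ranges.yaml`, each `baseline·(1 ± 0.5)`); the
baseline was hand-calibrated during model development so that the
midpoint set heals a superficial burn near 4.67 d and a partial-thickness
burn near 7.83 d at zero dose, with debris resolving first, and shows the
expected dose-graded delays. Parameters that matter most:

| group | key parameters | role |
| --- | --- | --- |
| damage resolution | `rho_dam` (0.0075/h), `kdf` (0.125/h) | background vs fibroblast-mediated damage removal |
| fibroblast drive | `kf`, `alpha_dam` (0.04), `alpha_m2` (0.26) | proliferation fuelled by damage and M2 signals |
| dose delay | `gamma_n/m/l/f` (0.01 /Gy·h) | influx suppression after irradiation |
| M2 switch | `omega_m2` (0.12) | strength of damaged-monocyte inhibition of M2 activation at ≥ 2 Gy |
| pathogen | `kpg` (0.12/h), `kpb·sb/mu_b`, `kbp` (1.0) | growth vs strongly saturating background clearance |

The pathogen group is parameterised in a bistable regime: the pathogen-free
healed state is locally stable (`kpg < kpb·sb/mu_b`, part of the default
stability predicate), yet the background clearance saturates strongly
(`mu_b = 0.05 ≪ kbp·P`), so a large inoculum — a severe burn plus
radiation — can escape to a sustained infection. With the shipped ranges
the representative set clears pathogen in every canonical scenario while a
substantial minority of accepted sets sustain infection in the 14-Gy
partial-thickness scenario, matching the intended "mostly resolves, can
become chronic" behaviour.

The estimate/fix split (26 estimated, 47 fixed) follows the influential-
parameter screen; fixed parameters are pinned at their range midpoint in
the final resampling stage.

## Initial conditions

* Resident totals are the healed steady states implied by influx/decay
  balance: `M̄ = smr/dmr_ud`, `L̄ = slr/dlr_ud`,
  `F̄ = sf/(dfr_ud + ksttb_ud)` (the fibroblast denominator is the *sum*
  of decay and wound-recruitment rates — the fixed point of the resident
  fibroblast balance).
* LQ survival coefficients: monocytes α = 0.1826; lymphocytes α = 0.3481,
  β = 0.0723; fibroblasts α = 0.5084, β = 0.0549 (per Gy, per Gy²).
* The fluence map is zero below 5.016 J/cm², `(100/3)·q(f)` on
  `[5.016, 5.168]` and `(80/3)·q(f) + 0.02` above, with
  `q(f) = −8.9795×10⁻⁵ f² + 7.2019×10⁻³ f − 3.1822×10⁻²`. The multipliers
  100/3 and 80/3 make the branches continuous at 5.168 (to ~5×10⁻⁶, the
  precision of the printed coefficients), where both equal the superficial
  anchor ≈ 0.1. The map is left unclipped; the damage level at the
  reference fluence 19 J/cm² (~1.96) defines the normalisation of the
  pathogen seeding. Named severities bypass the map
  (superficial → 0.1, superficial-partial → 0.9).
* Pathogen starts at `P_∞ · Dam₀/Dam_max` when any radiation is present,
  zero otherwise.

## Numerical choices

* **Integrator** LSODA (stiff-capable, adaptive), `rtol 1e-6`,
  `atol 1e-9`, dense output every 0.1 h. States are clipped at zero on RHS
  entry (phagocytosis terms can overshoot numerically) and on the stored
  grid; healing times shift by < 1% under tenfold tighter tolerances.
* **Events.** "Healed" = damage < 0.02 sustained for 12 h (same rule for
  debris). The levels are configuration, not biology: the model's damage
  variable has no clinical calibration below ~0.1, and the sustain window
  suppresses solver ripple. Damage-peak time is the grid argmax, earliest
  point on ties.
* **Feasibility screen** simulates both severities at zero dose over
  228 h; healing windows are 4.667 ± 0.5 d (superficial) and
  7.833 ± 0.5 d (partial). The pre-simulation stability predicate (all
  rates positive, `df > kf`, `kpg < kpb·sb/mu_b`) is pluggable.
* **Representative selection** re-simulates each accepted set for both
  severities on a 1-h grid, averages the cohort per variable and time, and
  ranks by inverse-variance-weighted MSE against that mean (R² reported;
  first index wins exact ties).
* **eFAST** uses interference factor `M_i = 4`, highest frequency
  `(NS−1)/(2M_i)`, complementary frequencies cycled on `[1, w_max/(2M_i)]`,
  and `NR` random phase shifts; `STi = 1 − V(ω ≤ w_max/2)/V`. Reference
  settings NS = 2000, NR = 32 are used in the estimator checks; the
  full-model screen defaults to NS = 129, NR = 4 over six wound variables
  at days {1,3,7,10,14} and doses {1,7,14} Gy, which keeps a pipeline run
  on one CPU in minutes. The MeFAST battery (Welch t, ANOVA + Tukey HSD,
  Wilcoxon rank-sum; α = 0.05) compares each parameter's index resamples
  to the dummy's for both Si and STi and reports the smaller p-value per
  test; a parameter is influential when ≥ 2 of 3 tests reject for at
  least one readout (majority rule, configurable).

## What the synthetic data do and do not show

All inputs here are synthetic by necessity — no quantitative dataset for
combined burn + local irradiation exists. The feasibility pipeline
emulates the *constraints* a clinician would impose (healing windows,
debris-before-damage ordering, numerical sanity), not measurements; the LQ
fitting fixtures are generated from the published coefficient values, not
raw survival assays. Passing tests therefore demonstrate internal
consistency, correct implementation of the stated mechanisms, and
qualitative agreement with the described injury courses — they do not
validate the model against animal or clinical data, and absolute cell
counts are in arbitrary units (resting levels of order one).

## Known limitations

* Local injury only: no systemic inflammation, hematopoietic loss, or
  total-body-surface-area effects; pathogen escape should not be read as a
  sepsis prediction.
* The 2-Gy M2 switch is a hard threshold in dose space, inherited from the
  stated rule; dose-response near 2 Gy is discontinuous by construction.
* The influx-delay form recovers faster at higher dose (see above); between
  two high doses the model can order some outcomes counter-intuitively.
* The depth-of-damage physics behind the fluence map (bioheat transfer and
  Arrhenius kinetics) is not re-derived; only the resulting piecewise map
  is implemented, with its branch constants configurable.
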