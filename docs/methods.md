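# Methods

## Scope and modelling stance

`cyclesim` is a *semi-mechanistic* generator: it does not integrate
differential equations of the HPO axis. Instead, each hormone's daily
trajectory is a parametric curve (Gaussian bumps, a sinusoid, or a flat
level) whose parameters are sampled per subject and per cycle, with a small
number of physiological couplings imposed as hard constraints — the LH
surge follows the pre-ovulatory estradiol peak by 1.5–2 d, FSH is
suppressed when noise-free estradiol exceeds 100 pg/mL, and GnRH drive
rises peri-ovulation. This buys reproducibility and cheap large-cohort
generation at the cost of causal fidelity: interventions cannot be
simulated, only phenotypes described.

## Time axis and observation model

Simulations run on a fixed grid of `G = 28` observation days per cycle,
rescaled to the subject- and cycle-specific length `L` by
`t = 1 + (d−1)/(G−1) · (L−1)`; thus day 1 maps to `t = 1` and day `G` to
`t = L` for every cycle. Observations are
`Y(t) = Y_true(t) + ε(t)`, `ε ~ N(0, σ_Y²(t))`, independently across days
and hormones.

For eumenorrheic E2 and LH the noise SD is amplified near the respective
event center `c` (the pre-ovulatory E2 peak `μ₁`; the LH surge day):
`σ²(t) = σ_base²·(1 + κ·exp(−(t−c)²/(2·1.2²)))` with `κ_E2 = 1.5`,
`κ_LH = 2.0` and a fixed 1.2-day amplification width. All other hormones
use a constant subject-level SD; AMH, being trait-like, carries no daily
noise at all.

Two different truncation mechanisms are used deliberately:

- **Parameter draws** are truncated by *rejection* (redraw until inside the
  physiologic range), so no probability mass piles up at the bounds and
  cohort summary statistics stay unbiased.
- **Observations** are truncated by *clipping* to generous physiologic caps
  (E2 600, E1 300 pg/mL; LH 100, FSH 30 mIU/mL; AMH 12, T 3 ng/mL;
  GnRH 3 AU; everything floored at 0). Clipping preserves the record count
  and the center of the noise law; at default parameters it alters < 1 % of
  observations (the run summary logs the exact rate — the main contributor
  is the low eumenorrheic estrone level meeting the zero floor).

## Default parameter distributions

Level parameters are truncated normals, width/lag/phase parameters are
uniforms over their physiologic ranges. The key defaults (all overridable
per run through `SimulationConfig.overrides` or the YAML config):

| Parameter | Eumenorrheic | PCOS-like |
|---|---|---|
| cycle length (d) | N(28, 2) → [24, 35] | N(35, 6) → [28, 60] |
| age (y) | U[20, 45] | U[20, 45] |
| BMI (kg/m²) | N(24.0, 2.5) | N(28.0, 3.2) |
| E2 baseline / level (pg/mL) | N(20, 5) → [10, 30] | N(33, 9) → [10, 60] |
| E2 pre-ovulatory peak (pg/mL) | N(267, 28), untruncated | — |
| E2 luteal peak (pg/mL) | N(125, 12) → [100, 150] | — |
| E1 level (pg/mL) | 0.7 × E2(t) | N(115, 12) → [80, 150] |
| LH baseline / level (mIU/mL) | N(7, 2) → [2, 12] | N(18, 3.4) → [12, 25] |
| LH surge peak (mIU/mL) | N(56.5, 6.4) → [35, 80] | no surge |
| FSH baseline / level (mIU/mL) | N(7.8, 1.1) → [5, 10] | N(5.2, 0.5) → [4, 8] |
| AMH (ng/mL) | N(2.9, 0.4) → [1, 4] | α ~ N(5.7, 0.58), trait → [4, 8] |
| AMH BMI slope (ng/mL per unit) | — | −0.055 |
| Testosterone baseline (ng/mL) | N(0.40, 0.04) → [0.2, 0.6] | N(1.25, 0.12) → [0.8, 2.0] |
| GnRH baseline / level (AU) | N(1.00, 0.05) | N(1.37, 0.06) → [1.3, 1.6] |
| σ₁ / σ₂ / σ_LH / σ_GnRH (d) | U[0.9,1.3] / U[1.5,2.5] / U[0.6,0.9] / U[0.8,1.2] | — |
| FSH bumps α_early / α_periov (mIU/mL) | U[1.0, 2.0] / U[0.8, 1.6] | — |
| T sinusoid amplitude (ng/mL) / phase | U[0.02, 0.06] / U[0, 2π] | same |

Per-cycle timing (eumenorrheic): surge day = `L/2 + N(0, 0.5 d)` jitter;
`μ₁ = surge − Δ`, `Δ ~ U[1.5, 2.0]` d; `μ₂ = μ₁ + δ`, `δ ~ U[5.5, 7.5]` d;
draws violating `1 < μ₁ < μ₂ < L` are re-drawn. FSH feedback:
`β_E2 = 0.01` mIU/mL per pg/mL above `θ_E2 = 100` pg/mL, early bump center
2 d, peri-ovulatory bump and GnRH bump centered at `surge − 1` d. The GnRH
bump amplitude is 22 % of the subject's baseline. Base noise SDs:
E2 10, E1 10 pg/mL; LH 1.5, FSH 0.6 mIU/mL; T 0.03 ng/mL; GnRH 0.04 AU.

**Calibration.** The level centers/SDs were fixed once, by Monte-Carlo, so
that the *observed* cohort summaries land on the reference values (e.g.
early-follicular E2 ≈ 20.5 ± 11.5 pg/mL pooled over days 1–5, surge-day
LH ≈ 53 mIU/mL, observed E2 peak ≈ 259 ± 30 with ~98 % of cycles reaching
200 pg/mL). Because peak centers are continuous while the grid has ~1-day
spacing, the observed daily maximum of a narrow bump under-shoots its peak
parameter by 3–7 %; the E2-peak and LH-peak centers (267, 56.5) sit above
the target observed means (259, 52.9) by exactly that discretization loss.

**Choices where the design was open.**

- The luteal E2 width σ₂ ~ U[1.5, 2.5] d makes the luteal rise broader
  than the pre-ovulatory surge, matching the canonical biphasic shape.
- Eumenorrheic estrone is not part of the reference equations (E1 is
  modelled only for PCOS); `E1 = 0.7·E2` is a package extension so the
  E1/E2 ratio feature is defined for both phenotypes. It contrasts sharply
  (≈ 0.7 vs ≫ 1) regardless of the exact factor.
- `β_BMI = −0.055` was chosen from the closed form
  `r = β·σ_BMI/√(β²σ_BMI² + σ_α²)` (σ_BMI = 3.2, σ_α = 0.58) to produce the
  reported AMH–BMI correlation ≈ −0.28/−0.29; slopes of order −0.5 would
  push most PCOS AMH traits outside [4, 8].
- `β_E2 = 0.01` gives a mild 1–2 mIU/mL peri-ovulatory FSH dip; values
  above ~0.05 would drive FSH to its zero floor during every surge.
- Age is U[20, 45] (mean 32.5, SD 7.2), consistent with the reported
  cohort mean age 32 ± 6.
- The minute-resolution GnRH pulse train (U[60, 90]-min interpulse
  intervals, 5-min pulse width, amplitude calibrated so a baseline day
  integrates to ~1 AU) is implemented but off by default; the daily-area
  bump is the primary GnRH model.

## Phases, flags and labels

Eumenorrheic days are labelled peri-ovulatory within ±1 d of the surge
center, follicular before and luteal after; the ±1 d half-width is a
package convention (only the surge-flag window, ±0.5 d, is prescribed).
The LH-surge flag is 1 where observed LH ≥ 30 mIU/mL within ±0.5 d of the
surge center. PCOS cycles carry no surge fields; every day is labelled
`anovulatory` and never flagged, which keeps the phase columns total and
the feature matrix complete.

## Reproducibility

All randomness flows from one master seed. Each subject draws from two
substreams spawned from `SeedSequence([master_seed, subject_index])` — one
for parameters, one for observation noise — so (a) re-running a config is
byte-identical, (b) a subject's data are invariant to cohort composition,
and (c) ablating noise does not perturb the sampled parameters.

## Features and discrimination

Per subject, over all cycles concatenated: mean/SD/max of each hormone
(sample SD, ddof = 1; exact 0 for constant columns), LH/FSH and E1/E2
ratios computed as ratios of means, phase-day proportions, and
cycle-length mean/SD (single-cycle SD is 0 by convention, with a warning).
The `pca6` preset — the six mean levels of E2, FSH, LH, AMH, testosterone
and GnRH — feeds PCA, k-means and the classifier; the `full` vector is
exported for other uses. Structurally constant features (e.g. the AMH
daily SD) are dropped before standardization and listed in the report.

Standardization is column-wise z-scoring with sample SD; in the supervised
evaluation it is fitted on the training split only. PCA signs are fixed by
making each component's largest-magnitude loading positive. k-means uses
10 seeded restarts; its label-agreement score (best cluster-to-class
assignment) is reporting-only. The logistic model carries weak L2
regularization (C = 1000) solely to keep the MLE finite on separable
classes; at this strength it does not alter any reported metric. PCOS is
the positive class for sensitivity/specificity; AUC uses the ranked
decision scores.

## What the generator does and does not emulate

The synthetic cohort reproduces the *population summary statistics* and
the *qualitative temporal architecture* of ovulatory and anovulatory
cycles: biphasic E2, a brief LH surge 1.5–2 d after the E2 peak, biphasic
FSH with estradiol suppression, trait-like AMH, phenotype contrasts in
AMH/T/LH/GnRH/E1. It does not emulate assay error structure, missing or
irregular sampling, luteal-phase progesterone (not modelled at all),
inhibin, PCOS sub-phenotypes, insulin-resistance comorbidity, anovulatory
cycles in otherwise eumenorrheic subjects, or temporal-shape diversity
beyond the parametric families. Consequently the perfect discrimination
metrics show that the *intended* class signatures are present and
recoverable — a generator self-consistency result — not that real PCOS
cohorts are separable with these features.

## Problem sizes and numerics

The default run (550 subjects × 3 cycles × 28 days = 46,200 records) and
the full analysis complete in a few seconds on one CPU; the scaled
AMH–BMI correlation arm uses 2,000 PCOS subjects. Rejection sampling caps
at 10,000 iterations and raises a configuration error (distribution
incompatible with its bounds) rather than looping; cycle-event placement
retries up to 1,000 times. CSVs are written with 6-significant-digit
floats, the stated round-trip precision of the dataset contract.
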