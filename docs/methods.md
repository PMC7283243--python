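# Methods

This note records the models, estimators, numerical choices and synthetic
data conditions behind `tnfkin`, and what the test suite does and does not
demonstrate.

## Physical picture and model forms

TNF-α is bioactive as a non-covalent homotrimer. Tethered to a biosensor
surface under buffer flow, the trimer decays into monomers; the normalized
signal relaxes mono-exponentially, `y(t) = −A·e^(−k·t) + y0`, and *k* is
the monomerization rate (reference free-trimer value 1.66 × 10⁻³ s⁻¹). The
reverse process, re-trimerization from free TNF-α, has a concentration
onset near 10 nM and completes within minutes above 200 nM but no
established rate law; the generator models it phenomenologically (logistic
soft onset in log concentration) for demonstrations only, and no estimator
consumes those traces.

Scavenger binding is treated as 1:1: each immobilized site binds one
analyte independently. Dissociation follows `A·e^(−k_off·t) + y0`;
association at constant analyte concentration *c* follows
`−A·e^(−k_obs·t) + y0` with k_obs = c·k_on + k_off. When a surface is only
partially protected, trimer decay (fast) and scavenger release (slow)
superimpose as a bi-exponential with one shared offset. Affinity is
K_D = k_off/k_on, with first-order error propagation
se(K_D)/K_D = √((se_on/k_on)² + (se_off/k_off)²).

For solution titrations both partners sit at picomolar levels comparable to
K_D, so the free-ligand approximation fails; the bound fraction is the
exact quadratic mass-action root
`b = ((R_T+L_T+K_D) − √((R_T+L_T+K_D)² − 4 R_T L_T))/(2 R_T)`, evaluated in
the cancellation-free form `2 L_T/(s + √(s²−4 R_T L_T))`. The assay reads
out residual *free* receptor, so the fitted response is
`y = y0 + A·(1 − b)`. For multivalent partners (trimeric antigen, bivalent
IgG) the 1:1 isotherm underestimates the steepness of the true dose
response; fitted values are effective affinities and are flagged as
approximations in the workflow output.

## Estimators

All nonlinear fits use trust-region-reflective least squares with rates
optimized as log-parameters, which enforces positivity and conditions
problems whose rates span 10⁻⁵–10⁻² s⁻¹. Standard errors come from the
linearized covariance (JᵀJ)⁻¹·s² at the optimum.

- **Global dissociation**: one shared k_off, free amplitude/offset per
  curve, pooled residuals. Per-curve fits are always computed as well; the
  reported k_off uncertainty is the SEM of those per-curve rates (absent
  for a single curve).
- **Global association**: shared k_on with k_off fixed from the
  dissociation fit; analyte concentrations are treated as exact.
- **Bi-exponential global fit**: shared fast/slow rates, per-curve
  amplitudes. Initialization is multi-start: the slow rate from a
  mono-exponential fit of the trace tails (last 25 %), the fast rate from
  the early-phase residual, plus ×5 and ×0.2 perturbations of the fast
  seed; lowest residual sum of squares wins, and rates are ordered
  k_fast > k_slow afterwards. If either component's amplitude is within 3×
  the residual noise, the fit is flagged effectively mono-exponential.
- **Decay-shape selection** (mono vs bi) requires agreement of two
  criteria: small-sample-corrected AIC and an F-test on residual sums of
  squares (2 extra parameters, α = 0.05 by default). Disagreement keeps the
  simpler model and sets an "ambiguous" flag.
- **Flat-trace guard**: a decay rate is only reported when the amplitude
  *realized within the record*, |A|·(1−e^(−k·T)), exceeds 5× the residual
  noise sd (configurable). The realized amplitude matters because a
  near-flat trace can be fitted by an arbitrarily large asymptote amplitude
  paired with a vanishing rate; pure-noise fits reach ~2–3σ realized
  amplitude by chance, so the factor is set above that.
- **Titration fit**: least squares over (log K_D, A, y0) with the receptor
  total fixed. Confidence intervals use a seeded residual bootstrap
  (default 1000 resamples) with leverage-adjusted residuals r/√(1−h) and
  studentized (bootstrap-t) intervals on the log-K_D scale: on 12-point
  designs the plain percentile interval is noticeably anti-conservative,
  while bootstrap-t attains nominal coverage. When the fitted K_D falls
  below one tenth of the receptor total (configurable) the titration is
  depletion-limited — the transition midpoint pins at R_T regardless of
  K_D — and only an upper bound ("K_D < x") is reported; likewise when the
  grid does not bracket the transition.

## Synthetic data conditions

Generators are pure functions of (parameters, seed). Noise is additive,
homoscedastic, independent per point — the simplest model consistent with
normalized traces, and the default sigma is 1 % of the unit amplitude.
Defaults mirror the reference protocols:

| quantity | default | unit |
| --- | --- | --- |
| monomerization window | 2000 s at 2 s spacing | s |
| association / dissociation | 260 s at 1 s; 18 000 s at 6 s | s |
| concentration series | 1, 2, 4, 8 | nM |
| association steady state | A_max·c/(c+K_D) (1:1 Langmuir level) | – |
| titration grid | 12 points, 7 pM–15 nM, log-spaced | M |
| panel window | 4200 s at 10 s, triplicates | s |
| free-trimer rate anchor | 1.66 × 10⁻³ | s⁻¹ |
| panel rate anchors | 0 (IgGs); 4.0 × 10⁻⁵ (Adalimumab/Infliximab Fab); 2.0 × 10⁻⁴ (Certolizumab/Etanercept); 1.66 × 10⁻³/3 (Golimumab Fab) | s⁻¹ |

The kinetic amplitude structure (Langmuir steady state) is a modelling
choice: the rate law fixes only k_obs, not amplitudes. Dissociation-phase
sampling (6 s) is likewise a choice; no sampling rate is prescribed by the
protocols the generators emulate.

What the generators deliberately omit: mass-transport limitation and
analyte rebinding (suppressed experimentally by low surface density and
high flow in the assays emulated), heteroscedastic or correlated noise,
surface heterogeneity, and higher-order complex formation. Passing recovery
tests therefore shows the estimators are correct and well-calibrated under
the stated statistical model, not that real sensorgrams meet that model.

## Panel classification

Triplicates are averaged point-wise before fitting (per-replicate fits are
kept for the SEM). A scavenger whose averaged trace fails the flat-trace
guard is classed `full_suppression`; otherwise the ratio k_mono/k_free sets
the class: < 0.054 strong, < 0.20 moderate, else weak. The boundaries are
the geometric midpoints between the anchor rates above (√(4×10⁻⁵·2×10⁻⁴)
≈ 8.9×10⁻⁵ and √(2×10⁻⁴·5.5×10⁻⁴) ≈ 3.3×10⁻⁴, divided by the free rate),
so each anchor sits a factor ≈ 2 from its nearest boundary on the log
scale. They live in `RunConfig` and are echoed into every report. The
suppression factor is k_free/k_mono, 1 for the buffer control by
construction; rows are ordered by increasing rate so class bands never
interleave.

## Sizing

The DR→D_H calibration is a user-supplied strictly monotone table,
interpolated with a shape-preserving PCHIP spline; the inverse is obtained
by root finding on the same interpolant (consistency to 10⁻⁹ nm), and
extrapolation outside the calibrated range is refused. The trimer fraction
is a linear scale between the measured end-state diameters (5.6 nm trimer,
3.9 nm monomer), clipped to [0, 1] — an operational coordinate, not a
friction model of mixed populations. Classification of a measured diameter
uses the measured anchors only; consistency with the PDB-predicted ranges
(5.76–6.10 nm trimer, 4.39–4.44 nm monomer) is reported separately so the
two provenances never mix silently. The measured trimer diameter sits
slightly below the predicted range; no correction factor is applied.

## Problem sizes in the reproduction script

`scripts/acceptance.py` uses: noiseless end-to-end fits of all four assay
orientations (≈ 13 000 points each); 100 independent seeds for each
stochastic figure (rate bias, titration coverage with 1000 bootstrap
resamples per seed, panel ranking); a 10×10×10 log grid over three decades
for the isotherm-vs-root-solve comparison. Total runtime ≈ 2 minutes on one
CPU.

## Known limitations

- Everything is 1:1; avidity, rebinding and interlinked-complex formation
  appear only as flags (residual-complex offsets, ambiguous decay shape),
  not as mechanistic models.
- A slower-than-k_slow third dissociation process, visible as a residual
  offset, is flagged but never fitted (a tri-exponential would be poorly
  identifiable on these designs).
- The re-trimerization generator is phenomenological and excluded from all
  quantitative claims.
- The molar basis of TNF-α concentrations is monomer-equivalent throughout
  (consistent with the 10 nM ↔ 175 ng/ml pairing at 17.5 kg/mol); no
  trimer-stoichiometry correction is applied to kinetic concentrations.
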