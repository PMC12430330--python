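# Methods

This note documents the models behind each pipeline stage, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that affect results.

## Force conversion and adhesion extraction

Raw curves are deflection-signal-vs-piezo-position traces.  With normal
spring constant *k* (N/m) and deflection sensitivity (nm per signal unit),
Hooke's law gives the force in pN as `F = k * sensitivity * signal * 1000`.
Default calibration: k = 0.2 N/m (a soft contact-mode lever), sensitivity
25 nm per signal unit.

**Baseline.** A least-squares line is fitted to the farthest 30% of retract
positions (the non-contact tail) and subtracted from both segments.  The
tail fraction is a convention, not an estimate: any fraction that stays
clear of the adhesion well works, and 30% leaves a comfortable margin at the
default sweep extent (100 nm free travel vs. a jump-off within the first
40%).  Fewer than 8 tail points is refused.

**Event detection.** The adhesion force is the magnitude of the minimum
(most attractive) corrected retract force.  An unbinding event is declared
when that magnitude reaches `5 × sd_robust`, where `sd_robust` is
1.4826 × the median absolute deviation of the corrected tail forces.  The
MAD is used because the tail may itself contain the tail of an adhesion
feature or an occasional spike; 5 robust SDs keeps the false-event rate on
pure-noise curves well below 1% (measured ≈ 0 in 1000 curves at default
noise).  The boundary is closed (magnitude exactly at threshold counts as
an event), and a curve with no attractive excursion reports *no event* —
never an adhesion of 0 pN.  Attractive forces are negative internally;
reported adhesion is the positive magnitude.

## Ensemble statistics

Histograms use Freedman–Diaconis bin widths unless a width is supplied.
The Gaussian `A exp(−(x−μ)²/2σ²)` is fitted to bin counts by nonlinear
least squares, initialised at the modal bin centre, the sample SD and the
maximum count, with σ bounded positive; non-convergence (e.g. all-equal
input) is reported via a flag, never raised.  The fitted centre μ is the
reported peak; its SE comes from the fit covariance.  Both the fit SE and
the sample spread are available because reported "± SD" conventions vary.

Box statistics use linear-interpolation quartiles and 1.5×IQR whiskers.
Percent reductions are `100·(initial−final)/initial`, rounded to the
nearest integer with ties away from zero — the convention that reproduces
quoted "~37%"-style figures from their printed force values.

Welch's unpaired t-test (Welch–Satterthwaite df, two-sided p) drives star
annotations.  Two threshold tables are provided: `methods`
(0.05/0.01/0.001/0.0001, the default) and `captions` (with ** at 0.005), a
discrepancy that exists in published reporting conventions; the choice is a
config option rather than silently resolved.  Degenerate input (both groups
zero-variance, equal means) reports t = 0, p = 1 with a flag.

## Poisson decomposition

Model: the rupture force of one contact is `f = F_0 + N·F_i + ε` with
`N ~ Poisson(λ)` and measurement noise ε.  Across groups of contacts that
share an acquisition context but differ in λ, mean and variance obey
`σ²ₘ = μₘ·F_i − F_i·F_0` (plus `ε`-variance, see below).  Estimation is an
unweighted OLS of group variance on group mean — matching the straight-line
fit the method conventionally uses — with a WLS variant (weights = group
sizes) behind a flag.

Conventions and caveats:

- **Grouping.** Default: sequential chunks of 30 curves (300 curves per
  condition → 10 groups).  `random` (seeded) and `spatial` (sort by a
  caller-supplied 1-D acquisition coordinate, then chunk) schemes are
  provided; which grouping a given instrument protocol implies is not
  standardised, so the scheme is always explicit.  Leftover curves are
  dropped and logged.
- **Standard errors.** Reported SEs use the HC3 small-sample
  heteroscedasticity-robust covariance: residuals are variance-of-variance
  estimates whose spread grows with the mean, and with ~6–10 groups plain
  OLS SEs under-cover (≈84% for a nominal-95% 2-SE interval in simulation,
  vs ≈93% with HC3).  `F_0 = −intercept/slope` gets its SE by first-order
  (delta-method) propagation from the slope/intercept covariance.
- **Noise bias.** Measurement noise inflates every group variance by
  noise², which the intercept absorbs: recovered F₀ is biased low by
  ≈ noise²/F_i (3 pN at 10 pN noise and F_i ≈ 33 pN).  The noise variance
  is deliberately not subtracted — doing so would require an independent
  noise estimate — and the bias is documented instead.
- **Attenuation.** Group means are noisy regressors, attenuating the slope
  by Σvar(μ̂ₘ)/Sxx (well under 1% at ≥100 curves/group for the default λ
  spread).
- **Validity flags.** A fit with slope ≤ 0 or intercept ≥ 0 contradicts the
  model's sign structure; it is returned as-is with `valid=False`, never
  negated.  All-equal group means raise an error.

## Friction

Loop half-width: `V_f = |mean over positions of (trace − retrace)/2|`,
averaged over the central 80% of the scan line to avoid turnaround
artifacts; per-position half-widths are available for diagnostics.  A
common offset cancels exactly, and swapping scan directions flips only the
sign, which the absolute value removes.

Calibration: `F_f = (3/2) · K_f · (h/l) · (V_f/S)`, with K_f the lateral
spring coefficient (N/m), h the tip height, l the cantilever length (only
the ratio enters) and S the lateral detector sensitivity taken as *signal
units per nm*, so `V_f/S` is a length and the product is a force (pN).
The grouping of this expression and the unit of S are conventions fixed
here and exposed through the `Calibration` type; published symbol lists are
ambiguous on both.  Defaults: K_f = 80 N/m, h = 17 µm, l = 450 µm,
S = 0.02 signal units/nm.

Constant-load mode requires every loop to carry a load tag (nN; the study
condition uses 1 nN) and refuses untagged loops rather than guessing.

## Topography

Height maps are rectangular grids (nm) with a lateral pixel scale.  Sa and
Sq are the mean absolute and RMS deviation from the mean of the
first-order (least-squares) plane-leveled grid, over the full scan area.
Average surface height is computed on the grid as given, relative to a
caller-supplied reference height (e.g. a bare-substrate level) — heights
are layer properties relative to a reference plane, not molecule sizes —
and leveling order is recorded in the result.  Sq ≥ Sa always
(Cauchy–Schwarz), with equality for constant-magnitude deviations.

## Synthetic-data generator

The generator realises exactly the statistical structure each stage
assumes, with one explicit seed per call and bit-identical reproduction.

- **Rupture forces**: `f_0 + Poisson(λ)·f_i + Normal(0, noise_sd)`, clipped
  at zero with clipped draws flagged (physical forces are non-negative; the
  flag preserves auditability).
- **Force curves**: piecewise linear — a contact ramp (slope a configurable
  fraction of the cantilever stiffness), a flat baseline with optional
  linear drift and Gaussian signal noise, and a single triangular adhesion
  well on retraction whose jump-off sits exactly on the sampling grid, so
  zero-noise extraction round-trips to floating point.  Default grid:
  0.25 nm spacing, 5 nm contact depth, 100 nm free travel.
- **Friction loops**: `trace/retrace = offset ± v_f + noise`.
- **Height maps**: a flat substrate plus Poisson-placed Gaussian bumps.
  Defaults (512² pixels over 1 µm², substrate 6.9 nm, 2100 bumps of mean
  amplitude 1.6 nm, SD 0.5 nm, lateral width 20 nm) were tuned once so the
  layer sits ≈8.2 nm above the substrate (target 8.5: a 15.4 nm protein
  layer over a 6.9 nm substrate reference) with Sq ≈ 2.7 nm (target 2.6).
  `compaction_factor` scales the bump field multiplicatively.

**Field-sweep scenario.** The simulated study uses the published
per-condition (drug × field) F_i/F₀ values as ground truth; mean bond count
λ = 8 per contact (chosen so simulated adhesion peaks f₀ + λ·f_i fall in
the published 228–372 pN window) with 25 pN rupture noise, and per-group λ
varying linearly over λ ± 3 across the 10 sequential groups — the
group-level heterogeneity the variance–mean regression needs.  Friction
and compaction interpolate linearly in field between published anchors;
where an endpoint is unpublished, an assumed reduction (documented in
`forcespec.sweep`) stands in.  Topograph seeds depend on the drug only, so
a drug's layer is the *same* bump field imaged under increasing compaction,
as for a repeatedly scanned area.  Sizes per condition: 300 curves (10
groups of 30), 100 loops per friction mode, 2 topographs at 128² pixels
(bump count scaled with area to preserve density).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: multi-bond cascades with distinct rupture
distances within one curve, worm-like-chain elasticity before rupture,
instrument drift that is nonlinear or correlated across curves, tip wear
and contamination, spatially correlated surface heterogeneity, and any
actual field physics — the "field effect" is a phenomenological parameter
scaling only.  Consequently the roughness reduction in the scenario tracks
the compaction factor exactly rather than the weaker coupling real layers
show.

## Known limitations

- Per-condition F_i/F₀ estimates at realistic ensemble sizes (300 curves)
  carry SEs of ~10 pN — larger than the true few-pN differences between
  adjacent field strengths — so monotone field trends are assessable for
  adhesion, friction and topography but not for the decomposition
  parameters; decomposition accuracy is established by dedicated
  replication experiments instead.
- A 2-SE interval on the regression slope from ~6–20 points has true
  coverage ≈0.92–0.95, not the asymptotic 95%; coverage claims are
  therefore verified over hundreds of replicates.
- The no-event threshold assumes a stationary noise floor within each
  curve's tail; bursty noise would need a different detector.
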