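# Methods

## Network model

CaM is modelled with one lumped Ca²⁺ site per lobe: each lobe's pair of
EF hands binds cooperatively and is collapsed into a single site filled
by `h` Ca²⁺ ions (default `h = 2`). A state is the triple (N-lobe loaded,
C-lobe loaded, MLCK bound), giving an 8-vertex cube. The three
mechanisms are truncations of the cube: the random mechanism (Model 1)
keeps every MLCK-bound vertex, the partially ordered mechanism (Model 2)
keeps only those with the C-lobe loaded, and the fully ordered mechanism
(Model 3) only the fully loaded one. EF-hand knockout variants force the
dead lobe's occupancy to zero, truncating further.

Two modelling assumptions matter:

* **Clamped free Ca²⁺.** Free Ca²⁺ is an independent variable, not a
  conserved species — experimentally enforced by EGTA-buffered
  calibration solutions. Consequently the MLCK-free CaM ensemble
  pre-equilibrates at every Ca²⁺ level and MLCK binding is *exactly* a
  bimolecular reaction with the weight-averaged constant `K_eff(x)`;
  the closed-form binding quadratic is not an approximation.
* **State-weight parameterization.** The network is parameterized by the
  Boltzmann weight of each MLCK-free Ca-occupancy state (apo ≡ 1) plus
  one MLCK association constant per Ca state. The twelve edge constants
  of the cube are weight ratios, so detailed balance around every face
  holds by construction, and the edge constants that no printed limit
  pins down are never needed individually.

## Parameters

| parameter | meaning | default | units |
|---|---|---|---|
| K₉ | apo CaM–MLCK association | 0.078 | μM⁻¹ |
| K₄ | C-lobe-loaded CaM–MLCK association | 16.7 | μM⁻¹ |
| K₂ | fully loaded CaM–MLCK association | 1000 | μM⁻¹ |
| K_M(N-only) | N-lobe-only-loaded CaM–MLCK association | 16.7 | μM⁻¹ |
| k_C (alias K₆) | C-lobe Ca²⁺ association weight | 0.25 | μM⁻ʰ |
| k_N | N-lobe Ca²⁺ association weight | 0.01 | μM⁻ʰ |
| h | Ca²⁺ ions lumped per site | 2 | — |

K₉, K₄ and K₂ are literature reference values. The remaining three are
not pinned by any printed limit and are package defaults: the N-only
MLCK constant is set to the same magnitude as the single-lobe C-only
constant (no discrimination claim depends on it), and the lobe weights
correspond to effective per-lobe dissociation constants of ~2 μM
(C-lobe) and ~10 μM (N-lobe), in the range of macroscopic CaM
Ca²⁺-binding constants. With these defaults the predicted wild-type
curve is flat below ~0.1 μM free Ca²⁺ and saturates by ~3 μM, matching
the qualitative shape of the measured titrations — in particular,
predicted binding inside the zero-Ca²⁺ test band (0–0.038 μM) is
negligible (<0.5%), as observed. Every quantitative discrimination
target lives in the x→0 or saturating-x limit, where the lobe weights
and `h` cancel; `h` is configurable because it shapes only the
mid-curve.

Concentrations are in μM throughout; no unit inference is attempted
(configuration keys carry units in their names, e.g. `K9_per_uM`).

## Numerical choices

* `fraction_bound` uses the cancellation-free root form
  `2KC / (1 + K(C+M) + √(1 + 2K(C+M) + K²(C−M)²))`; it returns exactly 0
  for `K = 0` or `C = 0`.
* The independent verification route `fraction_bound_numeric_oracle`
  solves the full mass-action system by bracketed Brent root-finding on
  free MLCK over [0, M_tot] at machine-precision tolerances, then sums
  the MLCK-bound state concentrations (avoiding catastrophic
  cancellation at small fractions). Closed form and solver agree to
  1e-9 relative over random networks; failure to bracket raises with
  the offending inputs.
* Structural zeros are produced by the admissibility logic, never by
  underflow: a variant with no MLCK-competent state returns a flagged
  zero curve (`structural_zero=True`) rather than an error.
* The "high-Ca" regime is evaluated both as the analytic limit and at
  the finite experimental maximum x = 39 μM; with reference parameters
  the two agree to 3 significant figures. Quantities defined at
  experimental conditions (the assay-sensitivity margin, the
  Monte-Carlo study) use the finite evaluation so the C-lobe weight
  participates.

## Synthetic data generator

The generator emulates the plate-reader FRET experiment: four CaM
variants (wild type, N-lobe knockout, C-lobe knockout, quadruple
knockout at 15/16/8/3 replicates) plus a reporter-only baseline (13
replicates) across a 14-point free-Ca²⁺ ladder from 0 to 39 μM that
contains the named experimental conditions (0, 0.038, 0.1, 0.35, 1.35,
3, 39 μM); the seven unnamed points follow the calibration-buffer series
with approximately geometric spacing.

The expected emission ratio is an affine map of the true model fraction,
`r(x) = r0 + Δr·F(x)` with defaults `r0 = 0.5`, `Δr = 0.5` — the map is
explicit and configurable because the measured ratio need not be 1:1
with fraction bound. Noise is multiplicative log-normal applied *per
emission channel* (default CV 2%), not to the ratio, since ratios of
noisy channels are what the assay measures; log-normal keeps intensities
positive, and the ratio mean equals `r(x)` up to O(cv²). All randomness
flows from explicit seeds; identical seeds give identical datasets, and
every dataset carries its ground-truth fractions for recovery tests.

What the generator does *not* emulate: spectral bleed-through,
photobleaching, instrument gain drift, plate edge effects, or any
nonlinearity between binding and FRET efficiency. Passing end-to-end
tests therefore show that the *statistical pipeline* recovers the
generating mechanism under the assay's nominal noise structure — not
that the real instrument is this well behaved. The channel-level noise
magnitude is a stand-in (the study reports no per-channel CVs).

The on-bead generator produces bound/unbound band intensities
proportional to F and 1−F over a constant background; the
background-corrected percent-binding estimator recovers F in
expectation.

## Observed-call rule and discrimination

A condition is called "binding" (B) only when two one-tailed
Mann–Whitney *U* tests against reporter-only baseline are both
significant at α = 0.05: one on the endpoint emission ratios (x = 0 for
the zero-Ca²⁺ regime, x = 39 μM for the high regime) and one on
per-replicate trapezoid AUCs (over 0 ≤ x ≤ 0.038 μM for the zero regime,
the complete curve for the high regime). The exact null distribution is
used when both groups have ≤ 20 observations and no ties; otherwise the
normal approximation with continuity and tie correction. p-values are
unadjusted, mirroring the reported analysis; whether the original calls
used a formal α is not stated, so the α = 0.05 conjunction is this
package's explicit rule.

`classify_models` reports two falsification counts per model.
`n_falsified_rows` counts mismatching (mutant, regime) conditions and
partitions the conditions together with `n_correct`. `n_falsified`
counts *distinct falsified predictions*: conditions where a model makes
the identical claim — same regime, same call, same predicted fraction,
as with the mutant-independent zero-Ca²⁺ prediction (at x = 0 no lobe is
loaded, so every variant behaves identically) — collapse into one. The
published counts (two falsified predictions for the random model, one
for the fully ordered model, six correct conditions for the partially
ordered model) correspond to `n_falsified` for the first two figures and
to condition counts for the third; both are exposed because no single
counting rule reproduces all three published figures.

The pipeline simulates all four variants but classifies the six
conditions of the published table (the quadruple mutant is simulated for
completeness and reported in the observed calls only).

## Sensitivity analyses

* **K₉ sweep.** Zero-Ca²⁺ binding under the random model over a
  (K₉, CaM_tot) grid; monotone increasing in both, which motivates the
  high-CaM (35.65 μM) confirmation condition where 73.5% binding is
  predicted at reference K₉ and 21.7% at K₉/10.
* **(K₄, K₆) Monte-Carlo.** The N-mutant prediction of the partially
  ordered model at 39 μM Ca²⁺, re-evaluated for 200,000 random
  (K₄, K₆) pairs drawn from [0.01v, 100v] around the reference values.
  The default law is log-uniform (the interval spans four orders of
  magnitude around a scale parameter); uniform sampling is available
  since the original description says only "chosen at random". A
  deterministic 100×100 log-spaced grid scan serves as the oracle for
  the Monte-Carlo minimum. Under the log-uniform law with this package's
  K₆ parameterization the observed minimum is ≈9% (at the low-K₄,
  low-K₆ corner), lower than the ≈18% floor reported for the original
  calculation — the sampling law and the exact functional role of K₆
  there are not recoverable, so this distribution is exploratory, not a
  reproduction target.
* **Assay margin.** The partially ordered model at 39 μM Ca²⁺ with
  22.9 nM reporter predicts 46.0% vs 54.4% reporter bound at 11.45 vs
  13.74 nM CaM (+8.4 points at finite x; +8.5 at the analytic limit),
  the margin the FRET assay was shown to resolve.

## Problem sizes

Default analysis runs use the 14-point ladder with the study's replicate
counts (770 wells per simulated study), 200,000 Monte-Carlo draws, and
100 independent seeds for the end-to-end discrimination check; the test
suite uses the same sizes except 20,000 Monte-Carlo draws in the
property checks.

## Known limitations

* The mid-curve shape (hence any EC₅₀ read off the predicted curves)
  depends on the unprinted lobe weights and on `h`; only the limiting
  fractions are quantitative claims.
* The edge-labelled import of individually specified cube-edge constants
  is not implemented; networks are specified by state weights.
* The dose-response fit is a descriptive 4-parameter logistic on linear
  x, as in the original analysis tooling; it is not derived from the
  network model and is not used for discrimination.
* Mann–Whitney power at 3 replicates (quadruple mutant) is limited; its
  conditions are simulated and reported but carry no discrimination
  weight in the six-row table.
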