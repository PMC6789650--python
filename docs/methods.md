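# Methods

## The assay and its model

`specunmix` implements a discontinuous UV/Vis assay for reactions that
interconvert a nucleoside and its free nucleobase. A sample aliquot is
quenched into aqueous NaOH (typically 100 mM, pH ≈ 13), transferred to
a UV-transparent 96-well plate, and its absorption spectrum recorded
from 250 to 350 nm in 1 nm steps. At this pH the free nucleobase is
deprotonated and aromatically tautomerized, which broadens and
red-shifts its spectrum, while the N1-substituted nucleoside (pKa far
above the aqueous range) retains a neutral-like spectrum. The two pure
spectra are linearly independent, and a mixture spectrum is their
molar-fraction-weighted sum.

Three processing steps recover the composition of a measured spectrum:

1. **Blank correction.** The solvent-only spectrum (NaOH blank,
   averaged over the plate's blank wells) is subtracted pointwise.
   Grids must match exactly; nothing is resampled implicitly.
2. **Isosbestic normalization.** For a two-species system at constant
   total concentration there is a wavelength λᵢⱼ — the isosbestic
   point — where all mixtures absorb identically. Dividing each
   blank-corrected spectrum by its absorbance at λᵢⱼ maps it to
   A(λᵢⱼ) = 1 and removes total concentration, optical pathlength and
   dilution/pipetting errors exactly. Molar extinction coefficients
   are never needed.
3. **Constrained least squares.** The normalized sample spectrum is
   fit as Σᵢ xᵢYᵢ over a wavelength window, with 0 ≤ xᵢ ≤ 1 and
   Σxᵢ = 1. The xᵢ are molar fractions of the UV-active compounds.

### Solver

The sum constraint is eliminated by parameterizing the first M−1
fractions (x_M = 1 − Σ others). For M = 2 — the assay's standard case —
the reduced problem is minimize_t ‖r₀ − t·d‖² with t ∈ [0, 1],
d = Y₁ − Y₂, r₀ = Y_k − Y₂: a one-dimensional convex quadratic whose
global optimum is the unconstrained minimizer ⟨d, r₀⟩/⟨d, d⟩ clipped to
the box. It is computed in closed form — no iteration, no tolerance,
no starting point — so results are exactly reproducible and successive
calls agree to machine precision. For M > 2 the package minimizes the
same objective with SLSQP (analytic gradient, uniform-composition
start, ftol 1e-14), followed by a projection of sub-machine-epsilon
constraint violations. A brute-force estimator (`unmix_grid_oracle`)
enumerates the objective on a fraction grid (default step 1e-4) and
shares no code with the solver; the test suite requires both routes to
agree.

### Standard errors

With J the Jacobian of the residual with respect to the free
fractions (for the linear model, J = −(A_free − a_M·1ᵀ)), the
covariance is s²(JᵀJ)⁻¹ with s² = SS_res/(n − (M−1)); the error of the
dependent fraction follows from Var(x_M) = 1ᵀC1. These are one-sigma
Gauss–Markov errors of a linear model and are only meaningful at an
interior optimum; when the estimate sits on a bound (a pure sample)
the result is flagged `se_reliable = False`.

### Isosbestic point handling

The isosbestic wavelength is normally a characterized compound
constant supplied via configuration (the shipped default is the
thymidine/thymine value, 278 nm, window 250–310 nm). It can also be
detected from equal-molar pure spectra: the detector locates sign
changes of the difference spectrum, refines each by linear
interpolation, and snaps the result to the nearest grid point (the
normalization divides by a *measured* grid value, so the anchor must
lie on the grid; the sub-nm crossing is available separately).
Photometric noise can split one physical crossing into several sign
changes within a nanometre or two; crossings spanning ≤ 2 nm are
therefore treated as one at their mean, while genuinely distinct
crossings raise an ambiguity error listing the candidates, resolvable
by a search range or an explicit wavelength. Normalization refuses
signals at or below 0.01 AU (configurable): near the blank level
(~0.03 AU) the division would amplify noise without bound.

### Wavelength windows

Fitting uses an inclusive wavelength window, by default the full
250–350 nm grid or a compound-specific range from configuration.
Restricting the window to the region from the isosbestic point upward
(e.g. 275–310 nm for the thymidine pair) discards the deep-UV region
where solvent absorbance and photometric noise are worst, and
measurably improves accuracy at extreme compositions (see the worked
example in the README). Residuals are unweighted; a per-wavelength
weight vector is accepted but defaults to one.

## Synthetic data generator

No instrument data ship with the package; the `synthetic` module
generates spectra with the statistical structure the assay assumes, so
every pipeline stage is testable end to end.

* **Pure spectra** are sums of Gaussian bands in wavelength space, one
  band set per protonation state, blended by the Henderson–Hasselbalch
  weight w = 1/(1+10^(pH−pKa)). Three presets emulate a natural
  pyrimidine pair (dT/thymine, maxima 266/287 nm, isosbestic 278 nm),
  a second pyrimidine pair (262/284 nm, 273 nm) and a purine pair
  (258/277 nm, 268 nm). Band amplitudes are solved so that each pair's
  equal-molar crossing falls exactly on its grid wavelength, keeping
  the grid-snapped normalization bias-free for noiseless round trips.
  The shapes are calibrated only to these qualitative features, not
  fitted to real spectra.
* **Measurement model.** A well's raw spectrum is
  scale·Σxᵢ·Sᵢ + blank + ε. `scale` combines concentration and a
  per-well dilution/pathlength factor (default U(0.9, 1.1)) — the
  error normalization must cancel. The blank is a flat instrumental
  offset (0.020 AU) plus a solvent absorbance edge
  0.12·exp(−(λ−250)/12) AU emulating alkaline NaOH, totalling
  ≈ 0.032 AU at 278 nm; each well's solvent term is scaled by
  1 + N(0, 0.10) for pipetting variation, so subtracting the measured
  blank leaves a small systematic residual concentrated below
  ~275 nm. Photometric noise is Gaussian per wavelength with
  σ = 0.005 AU, inflated toward the deep UV by a factor
  1 + 3·exp(−(λ−250)/12) (low lamp energy plus high total absorbance).
  The imperfect blank cancellation and the deep-UV noise are the
  mechanisms that make window restriction pay off; both levels were
  chosen once to satisfy the emulation's structural requirements
  (monotone degradation with noise, a single well-posed crossing, the
  benefit of window restriction) and then frozen.
* **Designs.** The standard validation design is six compositions
  (0–100% base in 20% steps) in duplicate per compound pair, with two
  blank wells and quadruplicate reference wells per compound (averaged
  before normalization), at 100 µM total UV-active compound and pH 13,
  seed 20190715. Progress series follow a single-exponential approach
  to equilibrium, conversion(t) = x_eq·(1 − e^(−k_obs·t)).

What the generator does *not* emulate: correlated (smooth) baseline
wobble, stray-light compression at high absorbance, temperature drift,
compound instability at high pH, and the small spectral differences
between ribo- and 2'-deoxyribonucleosides. Passing tests therefore
demonstrate the pipeline's correctness and its robustness to the
modelled error sources, not instrument-specific performance.

## Validation statistics

Agreement between designed ("actual") and estimated ("predicted")
molar fractions is scored on the percent scale, each replicate a
separate data point: R² = 1 − SS_res/SS_tot with
SS_res = Σ(predicted−actual)² and SS_tot = Σ(actual−mean(actual))²,
and RMSD = √(SS_res/n) in percentage points. These are the standard
definitions: R² is 1 for perfect prediction and 0 for predicting the
design mean, and is undefined (an error) when all designed values
coincide. Designed fractions must be physical (0–100, summing to 100);
predicted fractions tolerate ±5 pp excursions so unconstrained
comparator methods (e.g. HPLC quantification) remain representable.
A `compare_methods` utility reports per-sample absolute differences
between two methods' estimates.

## Kinetics utilities

Time-stamped unmixing results are assembled (sorted by time) into
progress curves of conversion = base molar fraction. The sampling
arithmetic converts reaction-stock to in-well concentrations
(stock·V_sample/V_final; e.g. 2 mM stock, 30 µL into 500 µL → 120 µM).
The initial rate is the ordinary-least-squares slope of conversion vs
time over points below a conversion threshold (default 10%),
multiplied by the substrate concentration. The fit is forced through
the origin by default because conversion is exactly zero when the
enzyme is added (configurable off). The secant nature of the estimate
biases it low on saturating curves; the bias shrinks monotonically
with the threshold, which the test suite checks.

## Numerical and design choices

* Grids are validated (strictly increasing, uniform step) and never
  resampled implicitly; `regrid` exists for explicit interpolation.
* Negative absorbances after blank correction are allowed (noise at
  low signal); values below −0.05 AU trigger a warning.
* Fractions returned by the solver satisfy the box and sum constraints
  to ≤ 1e-9 including at active bounds.
* All synthetic randomness flows through one seeded NumPy generator
  per plate; noise variates are drawn even at zero noise level so that
  different noise settings share the same solvent/dilution
  realization.
* Plate CSVs are written with `%.17g` floats and read with
  round-trip parsing, so write→read is value-exact.
* CLI exit codes: 0 success, 1 data/convergence failure, 2 usage;
  results go to files, logs to stderr, and each run writes a manifest
  (arguments, input digests, version) beside its output.

## Known limitations

Two-component unmixing is the designed scope; M > 2 works but offers
no collinearity diagnostics. The window is user-chosen — no automatic
wavelength selection is performed. Standard errors assume i.i.d.
residuals, which the deep-UV noise model violates for full-window
fits; they are best read as repeatability indicators. pKa estimation,
extinction-coefficient determination and kinetic model fitting beyond
the initial-rate slope are out of scope.
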