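# Methods

## The kinetic model

The package integrates elementary mass-action kinetics over fifteen
species.  Each nucleotide (GDP, GTP) exists as a fluorescent mant-labeled
pool and an unlabeled pool, assumed kinetically identical; the label only
determines visibility in the FRET observable.  The reversible steps are

| step | forward / reverse | defaults |
|---|---|---|
| Tu + GDP ⇌ Tu·GDP | k₁ / k₋₁ | 2.1 × 10⁶ M⁻¹s⁻¹ / 1.4 × 10⁻³ s⁻¹ |
| Tu + GTP ⇌ Tu·GTP | k₅ / k₋₅ | 3.9 × 10⁵ M⁻¹s⁻¹ / 1.4 × 10⁻² s⁻¹ |
| Tu·GDP + Ts ⇌ Tu·GDP·Ts | k₃ / k₋₃ | 2.68 × 10⁷ M⁻¹s⁻¹ / 2000 s⁻¹ |
| Tu·Ts + GDP ⇌ Tu·GDP·Ts | k₄ / k₋₄ | derived / 2000 s⁻¹ |
| Tu·GTP + Ts ⇌ Tu·GTP·Ts | k₆ / k₋₆ | 2.92 × 10⁷ M⁻¹s⁻¹ / 1500 s⁻¹ |
| Tu·Ts + GTP ⇌ Tu·GTP·Ts | k₇ / k₋₇ | derived / 4500 s⁻¹ |
| Tu + Ts ⇌ Tu·Ts (optional) | k₂ / k₋₂ | 10⁷ M⁻¹s⁻¹ / derived |

Internal units are molar and seconds; reporting converts to the
conventional scaled units.  Integration uses LSODA with rtol 10⁻⁸ and
atol 10⁻¹² M (the nucleotide-release steps make the system moderately
stiff at working EF-Ts concentrations); conserved totals (EF-Tu, EF-Ts,
each of the four nucleotide pools) hold to 10⁻⁹ relative along every
trajectory.  Equilibria are found by staged long-horizon integration with
a bounded least-squares polish of `dy/dt = 0` under the conserved totals;
without the direct Tu + Ts path the binding graph is a tree, so the fixed
point satisfies detailed balance for any parameter values.

### Choice of the unidentifiable constants

An EF-Ts titration identifies only the combinations
k₃/(1 + k₋₃/k₋₄) = 13.4 × 10⁶ and k₆/(1 + k₋₆/k₋₇) = 21.9 × 10⁶ M⁻¹s⁻¹,
not the elementary ternary-complex constants.  The package fixes them by
two physical requirements:

1. **Catalytic cycling.**  In a titration, sub-stoichiometric EF-Ts must
   turn over many EF-Tu·nucleotide complexes.  The steady-state fraction
   of EF-Ts tied up in intermediates ("busy fraction") has two parts: time
   inside the ternary complexes, ∝ 1/(q(1−q)(k_off,Ts + k_rel)) with
   q = k_off,Ts/(k_off,Ts + k_rel), and time in Tu·Ts waiting for a chase
   nucleotide to rebind, which works out to
   [Tu·nucleotide]·K₂/(K_nuc·[chase]) — independent of the partition.
   Whatever EF-Ts spends "busy" is missing from the free pool and scales
   the apparent titration slope down by the same factor.  The defaults
   keep the total busy fraction below ~1% at the standard design
   (0.15 µM complex, 30 µM chase): fast ternary-complex turnover
   (k₋₃ = k₋₄ = 2000 s⁻¹; k₋₆ = 1500, k₋₇ = 4500 s⁻¹, i.e. a
   release-committed GTP branch) and a Tu·Ts affinity of 30 nM.
2. **Thermodynamic consistency.**  With the direct Tu + Ts path present,
   each exchange cycle must close: K₁K₃ = K₂K₄ and K₅K₆ = K₂K₇.  k₄ and
   k₇ are therefore *derived* (≈1.2 × 10⁹ and 3.7 × 10⁷ M⁻¹s⁻¹).  The
   derived k₄ sits at the upper end of plausible small-molecule association
   rates; it is a consequence of the consistency constraints on a synthetic
   truth and harmless numerically.

Tetracycline is **not** a kinetic species: ground truths at different
tetracycline levels share identical rate constants, and the drug enters
only as an additive fluorescence background.  `GroundTruth.with_effect`
(and the pipeline's `effect_hook`) multiplies chosen constants to create
the counterfactuals used in power analysis.

## Observation model

signal(t) = c₀ + α_tet·[tet] + β·[EF-Tu-bound mant](t) + ε.

* `α_tet` is the tetracycline emission that leaks through the 430 ± 10 nm
  band-pass window: `passband_fraction(spectrum) × brightness`.  The
  bundled spectra are synthetic Gaussian stand-ins (mant peaked at 440 nm,
  tetracycline at 520 nm); measured spectra can be supplied as two-column
  CSV.  The absolute tetracycline/mant brightness ratio under 280 nm
  excitation is a free calibration.
* Dead time 1.5 ms; points before it are discarded.
* Noise has three components, all seeded:
  - white Gaussian point noise, sd = 0.5% of the trace's dynamic range;
  - **shot-to-shot rate jitter** (CV 3%): each replicate trace carries one
    multiplicative perturbation of its time scale, modeling temperature
    and mixing variation between shots.  This is what makes replicate
    apparent rates scatter by a few percent — the scatter that averaging
    n > 10 traces and quoting the standard error of the mean is designed
    to handle.  With white noise alone, replicate rates would agree to
    ~0.1% and replicate statistics would be decorative.
  - **titration-point concentration error** (CV 2%): each concentration in
    a titration is one dilution, shared by all its replicates, so this
    term scatters points about the secondary-plot line *without* showing
    in their error bars — the familiar look of real secondary plots.

GTPase quench series use sd = max(2% of signal, 0.02 µM); protection
decays use 2% multiplicative (log-normal) noise.

## Synthetic designs (the study conditions)

* Association: 0.3 µM EF-Tu, mant-GDP 0.5–5 µM (mant-GTP 1–10 µM),
  n = 11 traces per concentration.
* Chase: complex preformed from 0.6 µM EF-Tu + 6 µM mant-nucleotide
  (syringe), mixed 1:1 with 60 µM unlabeled nucleotide; n = 10.
* EF-Ts titration: 0.15 µM complex post-mix, EF-Ts 0.05–0.45 µM
  (apparent rates ≤ a few s⁻¹, far below the release step), chase
  present; n = 12 per concentration.  The generator refuses grids whose
  predicted apparent rate exceeds 20% of the release step.
* GTPase: 10 µM EF-Tu, 20 µM GTP, six early quench points at 0.5–4%
  substrate consumption plus three saturating points, n = 3 replicates,
  paired no-enzyme background series (background rate 10⁻⁴ µM/s, a
  package constant).  Quench times are placed by target consumption under
  the condition's nominal rate, since no standard grid exists.
* Protection: intact fraction at 8 log-spaced times over 3 half-lives
  (1.08 µM Phe-tRNA, 1.5 µM EF-Tu or none).

Every generator is a pure, cached function of (design, truth, seed); the
ODE part is computed once per condition and only the noise is redrawn
across replicates and seeds.

## Estimators

* **Transient fits** follow F(t) = F∞ + A·exp(−k_app·t), nonlinear least
  squares with data-driven starts (plateau from the last 10% of points,
  rate from a log-linear fit of the early deviation) and up to three
  jittered restarts; an amplitude smaller than twice the residual sd is
  reported as a failure, never silently.
* **Association**: replicates averaged per concentration; concentrations
  below five-fold excess over EF-Tu are excluded when at least three
  remain (ligand depletion bends those points off the line; above ~5× the
  depletion shifts only the intercept — the closed-form relaxation rate
  is k_on([L] − [Tu]) + k_off in the tight-binding limit).  The slope of
  the weighted line is the association constant.
* **Chase**: mean apparent rate across replicates, divided by the
  exchange-relaxation factor (1 + B/F) — bound pool over total free
  nucleotide — which corrects the ~1% rebinding bias at finite chase
  excess.  The correction uses only design metadata.
* **EF-Ts titration**: ascending concentrations are retained while a
  running quadratic-curvature test stays insignificant (α = 0.05, minimum
  four points); the weighted slope is the combined stimulated constant.
* **GTPase**: pointwise background subtraction; points with ≤10% of the
  substrate consumed enter a pooled straight-line fit across replicates;
  the slope is divided by (1 − mean consumed fraction), the first-order
  depletion correction.  Pooling (rather than averaging three per-replicate
  slopes) gives the slope SE ~16 degrees of freedom; an SEM over three
  values has two, too few to support a meaningful 2·SE interval.
* **Protection**: log-linear weighted fit of ln(intact) versus time —
  exact maximum likelihood under multiplicative noise — with
  t½ = ln 2/k and its propagated SE.

### Uncertainty conventions

Secondary-plot fits use effective-variance weighting: each point's
variance is its replicate SEM plus (slope·x·CV)² for the declared 2%
concentration precision, iterated with the slope.  Parameter errors are
propagated from these known variances and inflated by max(1, √χ²_red)
(the standard scale-factor convention: trusted error bars can widen, but
never narrow, the quoted uncertainty).  SEs estimated from few values are
widened by t₀.₉₇₅,dof/1.96 so that ±2 SE keeps near-nominal coverage at
any replicate count.  Condition comparisons use a two-sided z-test at
α = 0.05 with no multiple-testing correction (conclusions are drawn per
constant); `power_of_detection` Monte-Carlos the probability that a
multiplicative effect on one constant is detected by that test.

## What the synthetic data do and do not emulate

The generators reproduce the *statistical structure* the staged analysis
assumes: single-exponential transients with replicate-level rate scatter,
linear secondary plots with point-level concentration error, linear
initial phases with saturation, first-order decays.  They do not emulate
photobleaching, inner-filter effects, detector nonlinearity, baseline
drift, scintillation counting statistics (Gaussian noise stands in),
tRNA aminoacylation chemistry, or ribosome binding kinetics (ribosome
stimulation enters only as a different turnover rate).  Passing tests
therefore show that the pipeline's estimators are unbiased and correctly
calibrated under the model's assumptions — not that those assumptions
exhaust real instrument behavior.  GTP hydrolysis is deliberately absent
from the exchange scheme; multiple-turnover hydrolysis is modeled
empirically at the observable level (linear phase with exponential
substrate depletion), as the assays analyze it.

## Numerical choices and degenerate inputs

Integrator tolerances rtol 10⁻⁸ / atol 10⁻¹² M (configurable); simulation
windows cover ~5–6 relaxation times plus a 30% margin so rate jitter can
be sampled off the grid by interpolation.  Zero-rate reactions are
dropped from the scheme; an all-zero parameter set yields a constant
trajectory.  A chase without excess unlabeled nucleotide triggers a
warning (the fitted rate then reflects exchange equilibrium, not the
off-rate).  Titration grids outside the linear regime are rejected at
generation time.  Single-replicate estimates carry NaN SEs and an
explicit flag.  Equilibrium solving raises if the flux residual cannot be
driven down.  Problem sizes throughout (hundreds of traces per suite,
≤ 10⁵ ODE steps) keep a full default pipeline run to a few seconds.

## Known limitations

* The titration slope under-recovers the combined constants by ~0.2%
  (GDP) to ~0.7% (GTP) from residual EF-Ts sequestration in intermediates;
  this is physics of the finite design, well inside the quoted errors.
* The observation model's replicate-variability magnitudes (3% rate
  jitter, 2% concentration error) are declared package constants, not
  fitted to any instrument; absolute tetracycline brightness is likewise
  a free calibration.
* Only the combinations of ternary-complex constants are data-constrained;
  the elementary defaults are one consistent choice among many.
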