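# Methods

This note documents the physical models, estimation procedures, synthetic
generators, numerical choices, and limitations of the `lamella` package.
Every empirical number quoted here was measured with the package's own
synthetic generators and analysis code.

## 1. Binding isotherm (`lamella.binding`)

### Model

A peptide P at total concentration `C_pt` binds a patch of `n` lipids with
dissociation constant `K_D`:

```
K_D = [P_free][L_free]/n / [P_bound]
```

Writing `f` for the bound fraction of peptide and `C_lt` for the total
lipid concentration, mass action gives the quadratic

```
n·C_pt·f² − (n·C_pt + n·K_D + C_lt)·f + C_lt = 0
```

whose stable root (the smaller one, always in [0, 1]) is evaluated with a
numerically safe discriminant. The spectroscopic observable is the
normalized mean residue ellipticity, modeled as a linear reporter of the
bound fraction:

```
nMRE(f) = 1 + f·(nMRE_max − 1)
```

so nMRE = 1 for fully free peptide and nMRE_max at saturation. Unit tests
verify the root against an independent bisection of the mass-action balance
to 1e-9, plus monotonicity and both limits.

### Titration schedule

The standard schedule mirrors an automated CD titration: 300 µL of 20 µM
peptide receives 20 additions of 10 µL of 3 mM lipid vesicles. Both
analytes dilute with each step; the schedule object tracks the exact lipid
concentration and peptide dilution factor per point, including the
zero-lipid baseline point.

### Inference

`fit_binding` samples the posterior of (log10 K_D, n, nMRE_max, noise SD)
with emcee (default 24 walkers x 2500 steps, half discarded as burn-in).
Priors: log-uniform K_D over a broad window, uniform n and nMRE_max,
half-normal noise SD. The likelihood is Gaussian per point; multiple
titration curves pool into one likelihood. A least-squares pre-fit seeds
the walkers. Convergence is declared from the integrated autocorrelation
time (chain length > 50·τ for every parameter); non-convergence flags the
result. A posterior mass of nMRE_max concentrated near 1 flags
`no_binding`.

A single 20-point curve with 0.3 nMRE noise constrains ln K_D only to
about ±0.7, far too loose to resolve integer-rounded targets. The
acceptance computations therefore pool 400 replicate curves per
composition, sized so that two posterior standard deviations of the pooled
K_D ratio fit inside the rounding band.

## 2. Diffraction reduction (`lamella.diffraction`)

### Peak picking

The trace is counts versus Q (2θ input converts via Q = 4π·sin(θ)/λ).
Candidates come from `scipy.signal.find_peaks` with a prominence threshold
of five times a robust noise estimate (median absolute successive
difference of the trace). Candidates closer than five bin widths merge (keeping the
more prominent), preventing degenerate double-Gaussian fits on one noisy
peak top. Each surviving candidate window is fit with a Gaussian plus
linear background by `lmfit`; a peak is kept only if its fitted integrated
area exceeds five times the area's standard error. This integrated
significance gate is what rejects Poisson background bumps that pass a
pointwise prominence test on a 3000-bin trace.

### Lattice regression

Candidate orders h are assigned by rounding q/Δq from the strongest-peak
spacing; the repeat d follows from a weighted least-squares regression of
q_h on h through the origin, weights 1/σ² from the fitted center errors.
Peaks whose center error is not finite get zero weight — at high h their
leverage (∝ h²) would otherwise dominate the slope. With these three
safeguards, reduction of a rendered 200k-count five-order pattern recovered
|d − 54.9| ≤ 0.003 Å on 40/40 random seeds. Systematically large
regression residuals flag a possible multi-lattice signature.

### Two-lattice deconvolution

Every bipartition of the peaks (exact for ≤ 12 peaks; more are truncated
to the 12 strongest) is indexed and fitted; the assignment minimizing the
total squared residual wins, and the split is accepted only if its BIC
beats the single-lattice fit by a margin of 10. Coincident lattices return
a degenerate/no-split flag. On superposed 58.6/55.3 Å patterns the split
was recovered within 0.002 Å on 25/25 seeds.

### Structure factors

Order-by-order intensities integrate over fixed windows around each
predicted q_h after subtracting a linear background anchored at the window
edges; |F(h)| = sqrt(corrected integrated intensity), with optional
per-order multiplicative corrections (absorption, extinction) supplied by
the caller, and errors delta-method-propagated from Poisson counting
statistics. Orders with no significant intensity integrate
to near zero rather than being dropped, so downstream Fourier synthesis
sees a complete order list.

## 3. SLD profiles (`lamella.profiles`)

### Phasing by contrast variation

For a centrosymmetric bilayer, each F(h) is real with sign ±1. Amplitudes
respond linearly to an isotopic contrast coordinate (the D2O fraction x, or
the labeled-lipid fraction). For each order, the measured |F| across the
series is fit by a signed line in the contrast coordinate over all sign
assignments; assignments within tolerance of the best χ² are admissible,
and more than one admissible assignment marks the order ambiguous. Signs
are well determined for amplitudes above ~10σ; orders near a node of their
contrast line (|F| comparable to its uncertainty) are genuinely
undetermined, which the tests respect.

### Fourier synthesis and component fitting

The profile on one repeat is the truncated cosine series
ρ(z) = (2/d)·Σ_h F(h)·cos(2πhz/d). Gaussian components are fit *in
structure-factor space*: a Gaussian pair at ±z0 (area A each, width σ)
contributes 2A·cos(2πhz0/d)·exp(−2π²h²σ²/d²), so the data and model are
compared where the noise is defined, order by order with 1/σ² weights. A
mirrored-pair constraint ties the two halves of a symmetric label
distribution. On noiseless five-order data the pair fit returns the
planted center and FWHM to better than 1e-3 Å.

### Monte-Carlo resampling

`mc_resample` redraws the signed amplitudes within their Gaussian errors,
reruns any downstream estimator, and reports ensemble means and SDs.
Failed draws are counted and excessive failure flags the result.

### Absolute-scale calibration and its bias correction

A lipid deuteration label of known magnitude (7 deuterons on a fraction
`lf` of lipids, Δb = 1.041e-4 Å per H→D) fixes the instrument scale: the
measured integral of the labeled-minus-unlabeled difference profile must
equal lf·7·Δb per lipid. The measured integral comes from a mirrored-pair
Gaussian fit to the difference structure factors.

Under noise this fit is biased: the likelihood is even in the pair center,
so maximum-likelihood centers fold toward zero, deflating the fitted area
(measured at +0.70% on the calibration scale in isolation, which
propagated to roughly +3 waters per peptide). `calibrate_amplitude`
removes this with a parametric bootstrap: it simulates 50 mock order sets
from the fitted component model at the data's own error bars, refits each,
and subtracts the mean offset between refit and fit. After correction the
isolated scale bias measured −0.48%, and the full analysis chain recovered
a mean of 115.4 (median 112.9) waters per peptide over 120 independent
series with 114 planted. This is a standard bootstrap bias correction,
computed from the data's own noise model at run time — no constant is
tuned.

### Waters per peptide

With x the D2O fraction, the exchanged scattering length per lipid

```
B = Δb·x·(2·r·w_P + N_x·r + 2·w_L)
```

accounts for 2 exchangeable protons per water, N_x exchangeable peptide
protons at peptide-to-lipid ratio r, and a baseline of w_L waters per
lipid. Inverting for w_P is closed-form; a negative result flags the
accounting. Defaults: w_L = 9.4, N_x = 57, r = 1/25.

The acceptance computation reports the median over 51 independent contrast
series: one series propagates two small differences of large phased
amplitudes into B, giving a per-series SD of ~26 waters, so a median of 51
(SD ≈ 5) is needed for a ±15 acceptance band — the same
replication-for-precision reasoning as the pooled titrations.

### Neutron-reflectometry thinning

`percent_thinning(t0, Δt)` is the percentage decrease of a hydrocarbon
thickness, e.g. a 3.68 Å decrease on 30.44 Å is 12%.

## 4. Hydration shells (`lamella.hydration`)

Distances use the nearest-solute-point convention (surface proximity for
an extended solute), with minimum-image wrapping when a box is given.
g(r) normalizes by the mean water density in the analysis volume; because
nearest-distance "shells" around a multi-point solute are not spherical
annuli, shell volumes are estimated by seeded Monte-Carlo integration, and
the conservation test (Σ g·ρ·V_shell equals the direct count) guards the
normalization. Shell boundaries are the minima after successive g(r)
maxima; a maximum counts only if it is prominent (10% of the g range) and
exceeds 1 by twice the standard error over frames — a featureless
ideal-gas bath therefore yields no shells and a flag, rather than noise
bumps. Boundary SDs come from re-localizing on curves resampled within the
over-frame scatter.

## 5. Synthetic generators (`lamella.synthetic`)

Every generator plants known ground truth and records it in a JSON audit:
titration curves (binding parameters, schedule, noise), rendered powder
patterns (d, F(h), Gaussian peak shape, flat background, Poisson counts),
two-phase superpositions, contrast series (per-set true signed F and the
instrument scale), and hydration frames (shell radii, counts, jitter,
background bath). The default bilayer model is a plausible fluid-PC
anatomy — mirrored headgroup maxima, a central methyl trough, an
inter-bilayer water envelope responding to x, a label pair at ±1.87 Å
carrying 7·Δb per labeled lipid, and a peptide envelope carrying the
exchangeable-proton response; its shapes are test fixtures, not structural
claims. Generators are bit-reproducible under a fixed seed and emit
exactly the text formats the analysis stages read.

## 6. Numerical choices

- Quadratic root via the stable form to avoid cancellation at small K_D.
- Peak fitting with bounded lmfit least squares and multi-start jitter on
  non-convergence.
- Weighted regressions propagate parameter SDs from the weighted normal
  equations with effective counts (zero-weight points excluded).
- Component fits run in F-space, matching the measurement noise model,
  with real-space fitting retained as a fallback for profiles lacking
  order data.
- All stochastic code takes explicit seeds; reruns of the pipeline are
  byte-identical.

## 7. Limitations

- The diffraction forward model has Gaussian peaks on a flat background
  with Poisson counting only: no mosaic spread, geometric (Lorentz)
  factors, absorption, or beam-profile effects, and the reduction applies
  no such corrections by default (hooks exist for per-order corrections),
  so rendered and reduced amplitudes share one convention.
- Phasing assumes strict centrosymmetry and linear contrast response;
  signs of orders near a contrast-line node are genuinely undetermined.
- The waters-per-peptide accounting treats exchangeable-proton counts and
  the baseline hydration as known inputs; errors there propagate linearly
  into w_P.
- The binding model assumes independent lipid patches (no cooperativity or
  electrostatic surface-partitioning correction), a single bound state,
  and a linear nMRE reporter.
- Hydration analysis treats waters as points and the solute as rigid;
  shell volumes are Monte-Carlo estimates with their own (seeded) noise.
- The two-lattice search is exact only up to 12 peaks and assumes exactly
  one or two lattices.
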