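# lamella

Analysis toolkit for membrane-active peptide biophysics. It covers the full
chain used to characterize how an amphipathic peptide such as tilapia
piscidin 4 (TP4) partitions into and restructures lipid bilayers:

1. **Binding isotherms** (`lamella.binding`) — a modified-Langmuir model for
   circular-dichroism titrations, where the normalized mean residue
   ellipticity (nMRE) reports the bound fraction. A Bayesian MCMC fit
   (emcee) returns posteriors for the dissociation constant K_D, the
   stoichiometry n (lipids per bound peptide), and the saturation nMRE.
2. **Diffraction reduction** (`lamella.diffraction`) — peak picking on
   lamellar X-ray/neutron traces, weighted lattice regression for the repeat
   spacing d, deconvolution of two superposed lamellar phases, and
   integration of order-by-order structure-factor amplitudes.
3. **Scattering-length-density profiles** (`lamella.profiles`) — phase
   (sign) assignment by D2O/H2O and deuterated-lipid contrast variation,
   Fourier synthesis of centrosymmetric SLD profiles, deuterium difference
   profiles, Gaussian component fitting with a mirrored-pair constraint,
   Monte-Carlo error propagation, absolute-scale calibration against a
   known deuteration label, and waters-per-peptide accounting.
4. **Hydration shells** (`lamella.hydration`) — g(r) of water around a
   solute under the nearest-solute-point convention, shell boundaries at the
   minima after each significant maximum, and per-shell water counts.
5. **Synthetic data** (`lamella.synthetic`) — forward simulators for every
   input above. Each generator plants known ground truth and writes it to a
   JSON audit file, so every analysis result can be scored against what was
   planted.
6. **Pipeline** (`lamella.pipeline`, `lamella.cli`) — a `lamella` command
   that chains the stages from a YAML config with unit-suffixed keys,
   logging, resolved-config snapshots, per-stage JSON reports, and an
   aggregated `report.json`.

## Worked example: reduce a lamellar pattern

Config (`run.yaml`):

```yaml
run:
  stages: [simulate, reduce-diffraction]
  seed: 11
  outdir: out
simulate:
  kind: pattern
  d_angstrom: 54.9
  total_counts: 200000
reduce-diffraction:
  input: pattern.txt
  hmax: 5
```

```text
$ lamella run --config run.yaml
INFO lamella: lamella 0.1.0 seed=11 stages=['simulate', 'reduce-diffraction']
INFO lamella: simulate(pattern) wrote 2 file(s)
INFO lamella: reduce-diffraction: 4 peaks, d = 54.899 Å
```

`out/` then contains the rendered pattern, its ground-truth audit, a
resolved-config snapshot, the run log, per-stage reports, integrated
structure factors, and `report.json`, whose lattice block reads:

```json
{
  "d": 54.898735100962824,
  "d_sd": 0.002411473813287683,
  "flagged_multilattice": false,
  "max_abs_residual": 0.00012525536262830705
}
```

The planted repeat was 54.9 Å. The exit status is 0 when no stage flagged a
problem, 1 when any stage did, and 2 on config errors.

## Worked example: binding isotherm fit

```python
import lamella as lm

curves = [lm.generate_titration(lm.BINDING_PRESETS["POPC"], seed=s)[0]
          for s in range(100)]
post = lm.fit_binding(curves, sampler_settings=lm.SamplerSettings(seed=1))
print("converged:", post.converged)
for k in ("kd", "n_lipids", "nmre_max"):
    lo, hi = post.ci68[k]
    print(f"{k:9s} median {post.medians[k]:.3g}  68% CI [{lo:.3g}, {hi:.3g}]")
```

Output (planted truth: K_D = 11.2 µM, n = 19, nMRE_max = 14.7; each curve
carries Gaussian noise of 0.3 nMRE):

```text
converged: True
kd        median 1.02e-05  68% CI [9.7e-06, 1.07e-05]
n_lipids  median 19.7  68% CI [19.3, 20.1]
nmre_max  median 14.6  68% CI [14.5, 14.6]
```

A single 20-point titration constrains ln K_D only to ~0.7, so pooled
replicates are needed for tight estimates; K_D and n are anti-correlated
along the usual binding-ridge, which is why individual 68% intervals can
sit slightly off the planted values at moderate replication.

## Reproduction

Run the test suite (unit, property-based, and acceptance-criterion tests):

```bash
python -m pytest -o addopts= -p no:cacheprovider -q tests/
```

Run the acceptance script, which recomputes every headline number from
scratch — it plants ground truth, runs the full analysis chains, and writes
a JSON summary:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Typical output:

```text
t1 19 (n=400)     # lipids per bound peptide, PC bilayers
t2 6 (n=400)      # K_D ratio, PC vs PC/PS
t3 54.9 (n=200000)  # lamellar repeat, Å
t4 58.6 (n=2000000) # larger repeat of a two-phase split, Å
t5 1.85 (n=100)   # label pair center |z|, Å (planted 1.87)
t6 15 (n=100)     # label envelope FWHM, Å
t7 115.4 (n=51)   # waters per peptide (planted 114)
```

Values t5 and t7 are stochastic recoveries (Monte-Carlo ensembles and
noisy contrast series); their run-to-run scatter is documented in
`docs/methods.md`. All other values are stable across seeds at the printed
precision.

## Documentation

`docs/methods.md` describes the physical models, the estimation procedures,
the synthetic generators and their scope, numerical choices (including the
parametric-bootstrap debiasing of the calibration scale), and known
limitations.
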