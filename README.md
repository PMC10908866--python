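# mtdyn

Rigidity mapping and binding analysis for microtubule-associated-protein
NMR data.

Microtubule-associated protein 7 (MAP7) binds the microtubule lattice
through a 112-residue microtubule-binding domain (MTBD, residues 59–170).
Dynamics-edited magic-angle-spinning solid-state NMR separates this domain
into the parts that move with the lattice and the parts that stay
disordered: dipolar (cross-polarization) transfers survive only at rigid
sites, scalar (J-based) transfers only at mobile ones.  Combined with
solution-state titrations of tubulin C-terminal-tail (CTT) peptides and
calorimetry, the experiments localise the rigid helical core, the flexible
termini, and the electrostatic CTT interaction sites.

`mtdyn` implements the desk-reproducible analysis chain behind that kind of
study, for spectroscopists who want each step testable in isolation:

* **Spectral-editing classification** — match dipolar/scalar CH peak lists
  against an assignment table (greedy nearest-neighbour on the normalised
  distance `d = max(|ΔδC|/tol_C, |ΔδH|/tol_H)`, with ambiguity flagging in
  crowded regions), call every residue rigid / flexible / both /
  unobserved, and segment the profile into flexible arms around the
  longest rigid core.
* **Quantitation** — box integration of rastered 2D spectra, residue-type
  abundance as `region integral / single-resonance reference integral`
  with `error = count / SNR`, conformational population ratios, and
  secondary-shift helicity deltas `Δ = δ(solid) − δ(solution)` (positive
  ΔCA / negative ΔCB ⇒ helix).
* **CSP titrations** — `CSP = √(Δδ_H² + (0.154·Δδ_N)²)`, linewidth/SNR
  error propagation, mean-plus-one-standard-deviation significance
  threshold, contiguous-stretch detection, global fast-exchange K_D fits
  and ionic-strength trend analysis.
* **Binding models** — the exact single-site mass-balance ("quadratic")
  bound fraction, the Wiseman heat-per-injection ITC isotherm with
  overflow-cell dilution bookkeeping, and quadratic fluorescence
  anisotropy, each with a statsmodels-style `Model.fit() → Results`
  interface (`ITCModel`, `AnisotropyModel`, `CSPTitrationModel`).
* **Synthetic data** — seeded generators for every input (edited peak
  lists, rasters, NH titration series, thermograms, anisotropy curves,
  attenuation pairs) with known ground truth, so each stage closes the
  loop generator → analysis → truth.

## Worked example

```python
from mtdyn import (ITCSchedule, BindingGroundTruth, NoiseModel,
                   generate_itc_thermogram, fit_itc)

schedule = ITCSchedule(cell_volume_uL=164, cell_conc_uM=15,
                       syringe_conc_uM=150, injection_volume_uL=2,
                       n_injections=25, temperature_C=37)
truth = BindingGroundTruth(kd_uM=0.94, n=0.51, dh_kcal_mol=-8.0)
thermo = generate_itc_thermogram(schedule, truth,
                                 NoiseModel(seed=1, baseline_sd=0.2))
print(fit_itc(thermo).summary())
```

prints

```
ITC 1:1 binding fit
----------------------------------------------
K_D                  1.27 +/- 0.28 uM
stoichiometry       0.498 +/- 0.025
dH                  -8.64 +/- 0.73 kcal/mol
offset             0.0686 uJ
c value              5.88
RSS                0.9178 uJ^2
converged      True
```

i.e. from 25 simulated injections of 150 µM titrant into a 164 µL cell of
15 µM binding sites, the fitter recovers a micromolar dissociation
constant and a stoichiometry of ~0.5 titrant per site, each within one to
two standard errors of the generating truth (0.94 µM, 0.51) for this noise
seed; across 100 seeds the medians land on the truth (see the test
suite).  The `c value` (n·[sites]/K_D ≈ 6) confirms the titration sits in
the reliably fittable regime.

The same pattern runs end to end from the shell:

```sh
mtdyn fixtures --seed 1 --out bundle        # synthetic dataset, known truth
mtdyn classify --dipolar bundle/dipolar.peaks --scalar bundle/scalar.peaks \
      --shifts bundle/solution_shifts.csv --out results
mtdyn fit-fa --series bundle/anisotropy.csv
```

The `classify` step reports a flexible N-arm up to residue ~69, a rigid
core ~70–148 and a flexible C-arm from ~149, and the CSP stage finds the
two significant stretches 82–88 and 141–146.

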