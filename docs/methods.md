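# Methods

This note documents the models implemented in `mtdyn`, the defaults and
their rationale, what the synthetic-data generators do and do not emulate,
and the numerical choices made where the design was genuinely open.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The construct and packaged data

All analyses address a 112-residue microtubule-binding domain (MTBD)
numbered 59–170 in UniProt convention.  Because the package must build and
test without network access, it ships `data/mtbd_synthetic.fasta`, a
**synthetic stand-in sequence**: length, numbering and every residue
identity the analyses depend on (the P59/V60/L61… termini, the
82-AAREIVW-88 and 141-AVVRRT-146 stretches, a single Ile and Trp) are
preserved; the remaining positions are filled with a realistic
glutamate/lysine-rich helical composition.  Counts of residue types other
than those constrained therefore do not reproduce the real protein, and
`predicted_counts` results are meaningful only relative to this stand-in.

`data/reference_shifts.csv` packages two reference-shift sources:
`bmrb_average` (approximate database-average chemical shifts with standard
deviations, an approximate literature snapshot rather than any specific
database release) and `random_coil` (standard random-coil values for
CA/CB/HA).  The library is static and versioned in-repo; nothing is
fetched at run time.  Mean helical secondary shifts of +2.6 ppm (CA) and
−0.4 ppm (CB) are used wherever a helical offset is applied.

## Spectral-editing classification

Dipolar (cross-polarization) magnetisation transfer requires rigid sites;
scalar (J/INEPT) transfer survives only at mobile ones.  Overlaying both
edited 2D CH spectra on an assignment table therefore classifies residues.

**Matching.**  Each observed peak is assigned to the target minimising the
normalised distance `d = max(|ΔδC|/tol_C, |ΔδH|/tol_H)`, accepted when
`d ≤ 1`.  Default tolerances are 0.05 ppm (¹H) and 0.5 ppm (¹³C) — the
scale of typical CH linewidths; there is no standard overlay tolerance, so
these are package defaults, configurable everywhere.  Assignment-table
targets take priority over database-average fallbacks (used only for
residue types absent from the table); ties break on smaller `d`, then
lower residue number, which makes matching deterministic and invariant to
peak-list order.  A match is flagged **ambiguous** when a target of a
different residue explains the peak nearly as well (second-best `d` within
0.3 of the best, in tolerance units).  In crowded regions — and a
112-residue E/K-rich helix is genuinely crowded — such peaks cannot safely
be attributed to a single residue; they are retained as secondary
evidence but never decide a residue's dynamic state.  The 0.3 margin
trades ~1 in 8 true attributions (which is tolerable because every residue
carries several resonances) for rejection of most cross-residue
confusions.

**Calling.**  Backbone resonances (CA/HA, CB/HB) attributed unambiguously
are the primary evidence: a residue is `both` only if each channel carries
unambiguous backbone evidence, `rigid`/`flexible` if only one does.
Side-chain-only or ambiguous evidence yields annotations ("rigid
backbone, mobile side chain", "side-chain evidence only") and, when no
backbone evidence exists at all, a side-chain-based fallback call.

**Segmentation.**  The rigid core is the longest contiguous run that
starts and ends on a rigid/both call, contains no flexible call, and is at
least `min_run = 3` residues long; unobserved residues inside the run are
absorbed, because spectral overlap is non-evidence of flexibility, and
single-residue islands are suppressed (isolated exceptions inside a
flexible arm survive as atom-level annotations, not segmentation breaks).
The remainder forms the N- and C-terminal flexible arms.

**Geometry.**  An ideal α-helix rises 1.5 Å per residue; spans are counted
inclusively, `length_nm = (last − first + 1) × 1.5 / 10`.

## Quantitation

2D spectra are rasterised as sums of intensity-normalised 2D Gaussians
(the analytic volume of each peak equals its intensity) on regular ppm
grids; with ≥5 samples per FWHM the discrete box integral conserves the
volume to well under 1%.  Default linewidths mirror the line broadening of
the underlying experiments (120 Hz dipolar / 30 Hz scalar at 700 MHz):
¹H FWHM 0.17 / 0.05 ppm, ¹³C FWHM 0.5 / 0.2 ppm.

Residue-type abundance in a region is the region integral divided by the
arithmetic mean integral of configured single-resonance reference peaks
(mean, not median, matching the "average signal intensity" convention);
its error bar is `count / SNR`, with SNR = maximum height in the region
over the baseline noise standard deviation.  The baseline rectangle
defaults to a region the generator guarantees empty; for real data it must
be user-specified.  Default region rectangles ship in `data/regions.json`
as database mean ± 2 sd per residue-type/atom class; they are package
defaults, configurable per spectrum.  Population ratios of two conformations are
ratios of two such abundances and are invariant to global intensity
rescaling.

Helicity deltas compare, per residue type and atom (CA, CB), the mean
solid-state shift against the mean solution shift over the comparison
window A70–E148 (configurable).  Positive ΔCA or negative ΔCB is flagged
helical-consistent; non-consistent types are reported, never suppressed.

## CSP titrations

`CSP = √(Δδ_H² + (α·Δδ_N)²)` with the conventional ¹⁵N weight α = 0.154
(reported in all outputs; no per-glycine special case).  Position errors
are linewidth/SNR per dimension; first-order propagation gives
`σ_CSP = √((Δδ_H σ_H)² + (α² Δδ_N σ_N)²) / CSP`, with the zero-CSP limit
`√(σ_H² + (α σ_N)²)`.  The linearisation is accurate when shifts exceed
their uncertainties (verified against Monte-Carlo in the tests).

Significance uses threshold = mean + one sample standard deviation
(ddof = 1) of measurable CSPs, strictly exceeded; prolines (no amide) and
exchange-broadened residues are excluded from the statistics and reported
separately.  Stretches are maximal runs of ≥ `min_len = 3` consecutive
significant residues — long enough to suppress singleton noise, short
enough never to fragment the 6–7-residue interaction stretches.  The
endpoint CSP (zero-ligand vs highest ligand point) defines the profile;
the full-series fit is separate.

The titration fit is a global fast-exchange model: `CSP_r(L) = Δδmax_r ·
FB_P(L)` with the protein-bound fraction from the exact mass-balance
quadratic at fixed protein concentration and one K_D shared across
residues (by default the top quartile of end-point movers, so the fit uses
residues that actually respond).  Flat profiles are flagged
unidentifiable rather than fitted.

For salt series the significance threshold is fixed at the lowest
(reference) ionic strength and applied across conditions: a
self-referential per-condition threshold would rescale with the screening
decay and could never report abolition.  The trend statistic is Kendall's
tau of maximum CSP versus salt.  The generator implements screening as
`Δδmax · exp(−κ·[salt])` with κ = 0.006 mM⁻¹ by default — purely a test
harness encoding for a qualitative electrostatic trend, not a physical
Debye model.

## Binding models

**Bound fraction.**  For a single site,
`FB = ((K_D + L_t + P_t) − √((K_D + L_t + P_t)² − 4 L_t P_t)) / (2 L_t)`,
the exact mass-balance solution for the fraction of ligand bound, with the
limit `P_t/(P_t + K_D)` at `L_t → 0`.

**ITC.**  The cell heat content after injection *i* is `Q(i) = ΔH·V₀·C(i)`
with complex concentration `C` from the quadratic at site concentration
`n·M_t(i)`.  A fixed-volume (overflow) cell is assumed: every injection of
volume *v* dilutes existing contents by `(1 − v/V₀)` and the observed heat
is `q_i = Q(i) − Q(i−1)(1 − v/V₀) + offset`, which accounts for complex
carried out in the displaced volume.  Vendor conventions differ in
unpublished details; this one is standard for fixed-volume cells and is
what the generator and fitter share.  Because displaced material leaves
the cell, the heat sum equals `n·M₀·ΔH·V₀` exactly only in the
small-injection limit; the conservation test uses v/V₀ = 0.002.  Fits run
over (log₁₀ K_D, n, ΔH, offset) by Levenberg–Marquardt (lmfit), K_D on a
log scale for stability and reported in linear µM; the first injection is
excluded by default (syringe-tip diffusion corrupts it in practice, and
the generator can simulate that), and fits with c = n·M₀/K_D outside
[0.5, 5000] are flagged.

**Anisotropy.**  `r = r_free + (r_bound − r_free)·FB` with FB the bound
fraction of the labelled probe.  Fits run over (log₁₀ K_D, r_free,
r_bound); series whose fitted amplitude is within three residual standard
deviations of zero are flagged unidentifiable.

## Synthetic study conditions

The generators default to the documented study conditions and are not
tuning knobs: ITC at 164 µL cell / 15 µM sites / 150 µM syringe / 2 µL ×
25 injections with truth (K_D 0.94 µM, n 0.51); anisotropy with a 1 µM
probe over a 0–200 µM two-fold dilution series with truth K_D 91.3 µM;
CSP titrations of 80 µM protein with ligand 0–800 µM (ten-fold excess at
the endpoint); rigidity ground truth with flexible arms 59–69 and
149–170, transitional residues 70 and 148 in both channels, and mobile
Ile-86 methyls on a rigid backbone.  The ITC enthalpy is not among the documented
conditions; −8 kcal/mol is a realistic exothermic choice for a µM
protein–protein interaction.  Noise defaults are chosen as realistic
instrument noise: peak-position jitter of one third of the matching
tolerance per dimension (solid state) or 0.003/0.02 ppm ¹H/¹⁵N
(solution), 5%/3% relative intensity noise, 2% raster baseline noise,
0.2 µJ per-injection heat noise, 0.003 anisotropy noise.  All randomness
is Gaussian, independent per point, and flows through explicit integer
seeds; identical seeds give bit-identical outputs.

What the generators do **not** emulate: chemical-exchange broadening and
intermediate-exchange loss (TROSY attenuation is a single uniform factor,
as only an aggregate decrease is knowable), correlated peak movements,
baseline distortions and t₁ noise, non-Gaussian lineshapes, titration
dilution of the protein, and any coupling between rigidity and CSP
responses.  Passing closed-loop tests therefore demonstrates correctness
of the estimators under these idealised conditions, not robustness to
every artefact of real spectra.

## Problem sizes

The simulation studies run at the sizes the analyses document: 100
replicates for ITC and anisotropy recovery, 100 seeds for noisy rigidity
recovery, 50 seeds for population-ratio stability, 500 random instances
for the stretch-detection oracle and 200 for the segmentation oracle;
rasters are 1100 × 760 points.  The full test suite completes in well
under a minute on one CPU.

## Known limitations

* The stand-in sequence limits sequence-derived counts to internal
  consistency; swap in the real FASTA for real-data work.
* Region boundaries and the reference-shift snapshot are approximate;
  absolute abundance figures from real spectra will depend on both.
* The matcher is greedy per peak; a global optimal-assignment matcher
  could in principle resolve crowded regions slightly better.
* `fit_titration_kd` assumes fast exchange throughout; residues entering
  intermediate exchange should be excluded (they are flagged broadened,
  not modelled).
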