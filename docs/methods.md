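# Methods

## Spectral normalisation

The statistic the pipeline is built around is the normalised integrated
fluorescence intensity of one paired measurement,

    I_int = (Σ_band (I(λ) − B_F)) · t_L / ((Σ_laser (L(λ) − B_L)) · t_F),

with all sums taken over native grid samples in closed (endpoint-inclusive)
bands and backgrounds estimated per spectrum as the mean over 350–450 nm.
Conventions chosen here, where the procedure admits latitude:

- **Endpoint-inclusive bands, no interpolation.** Spectrometer grids are
  dense (~0.5 nm), so the inclusion convention is numerically immaterial,
  and the statistic is defined as a discrete sum over recorded samples.
- **No smoothing before summation.** Band integration already averages
  over many samples; pre-smoothing would correlate noise without benefit.
- **Negative background-subtracted samples are retained.** Clipping at
  zero would bias pure-noise spectra toward positive I_int; retaining sign
  makes noise integrate to ≈0 in expectation.
- **Strict pairing.** Every fluorescence spectrum must have a laser
  spectrum recorded within 30 s; unpaired or widely separated records are
  rejected at load, because normalising against a laser measurement taken
  under different probe contact produces anomalous values. A non-positive
  laser band sum raises a dedicated error (occluded probe) rather than
  returning infinity.

## Time-course statistics

- **Baseline subtraction** removes the mean of pre-ingestion I_int values
  (residual offset from imperfect background subtraction, e.g. when the
  skin autofluorescence is not spectrally flat). Absolute AUC values
  therefore quantify dye signal only; they are a convention, and only AUC
  *ratios* between conditions are comparison-safe across conventions.
- **Peak = first prominent local maximum**, not the global maximum. At
  sensing sites where blood vessels are deep (forearm, wrist), dye leaking
  from blood into the epidermis drives a slow, late rise that can exceed
  the blood-concentration peak; the physiological marker is the first
  peak. Localisation uses a centred moving average (default width 300 s,
  chosen ≈5 sampling intervals, well below typical peak widths of
  ~1500 s+) and a prominence threshold of 10 % of the excursion above
  baseline; smoothing is used *only* to localise the peak — the reported
  intensity and all AUCs come from the unsmoothed curve. On a symmetric
  noiseless peak the smoothed argmax equals the exact argmax for any
  window below the peak width; on asymmetric peaks it can shift by up to
  ~window/4 toward the flatter flank, bounding the default localisation
  error at ~75 s.
- **Detection significance.** A curve whose excursion above baseline is
  below 5 standard deviations of the pre-ingestion baseline (when at least
  three baseline points exist) raises "no peak": an excursion
  indistinguishable from the noise floor is a non-detection, not a peak.
  This is what makes the oral-ICG scenario correctly unanalysable.
- **AUC-to-peak** integrates the baseline-subtracted curve from ingestion
  to the detected peak with the trapezoid rule (irregular sampling is
  handled natively; boundary values are interpolated linearly). Time is
  rescaled to hours so that a ~1 h uptake window yields an AUC of the same
  order as the peak intensity. Monotone refinements of the sampling grid
  change the trapezoidal AUC by <2 % at the default 60 s interval.

## Labelling stoichiometry

FITC molarity comes from Beer–Lambert (ε = 77,000 M⁻¹cm⁻¹ at 494 nm);
dextran molarity from mass concentration divided by the *unlabelled*
dextran molecular weight (an approximation that ignores the conjugate's
added FITC mass, <10 % for the ratios of interest). Per-glucose ratios
use the anhydroglucose residue mass 162.14 g/mol (glucose 180.16 minus
one water per glycosidic bond) — this is the constant that makes a 0.74
FITC-per-chain ratio on 6 kDa dextran correspond to 0.020 mol FITC per
mol glucose, and a 1 g dose of 4 kDa dextran at ratios 0.002–0.02
correspond to 4.8–48 mg of FITC. When several absorbance measurements at
different concentrations are supplied, the per-measurement ratios are
averaged; under exact linearity this coincides with a line fit through
the concentration series.

## Synthetic data generator

### Kinetic model

A linear compartment chain with first-order rates (all 1/s):

    stomach --k_ge--> gut --f_perm·k_abs--> blood --k_el--> eliminated
                       \--(1−f_perm)·k_abs--> eliminated
    blood --k_leak--> dermis --k_derm--> epidermis --k_clr_epi--> eliminated

solved exactly via the matrix exponential (the generator matrix has
zero column sums, so mass conservation holds to machine precision; no
step-size error). IV dosing starts the dose in blood. The probe signal at
a site is `w_blood·blood(t) + w_epidermis·epidermis(t)` with site presets
fingertip (1.0, 0.1), arm (0.5, 1.0), wrist (0.4, 1.0) — fingertip is the
most blood-weighted, matching its proximity to vessels.

The **dermis transit stage** is a deliberate model choice: with a single
epidermal pool fed directly from blood, once the blood curve enters
terminal decay both the blood term's decline and the epidermal inflow are
proportional to blood, so the summed site signal is provably unimodal and
cannot reproduce the observed two-phase arm/wrist curve (initial peak,
dip, later higher rise). One transit stage delays the epidermal
accumulation enough to produce that shape.

Default rates (overridable everywhere): k_ge = 1/600 (water) or 1/2000
(milkshake), k_abs = 1/400, f_perm = 0.4 (fluorescein), k_el = 1/3600
(fluorescein) or 0.0033 (ICG, i.e. 20 %/min, mid-range of the reported
hepatic clearance), k_leak = 1/3000, k_derm = 1/6000, k_clr_epi = 1/50000.
These place the water-scenario uptake peak ~25 min after ingestion and
give the arm-site curve a first peak near the blood peak with ~15 %
prominence before the late epidermal rise.

Scenario-specific choices:

- **Sugar scenario**: the hyperosmolar load both doubles f_perm (0.4→0.8)
  and slows gastric emptying (k_ge 1/600→1/1200). Doubling f_perm alone
  scales the blood curve exactly ×2 (AUC ratio exactly 2.0, peak time
  unchanged); the added emptying delay reproduces the observed later peak
  and pushes the AUC-to-peak ratio above 2.
- **Oral ICG**: f_perm = 0.0005 — ICG is essentially not absorbed across
  the gut wall, which together with its fast blood clearance keeps the
  transcutaneous signal below the detection limit.
- **FITC-Dextran low dose**: optical gain scaled down ×37 000 relative to
  fluorescein (only ~0.5 % of the conjugate mass is FITC, and the emitted
  signal per unit blood amount is correspondingly tiny), leaving the
  emission below the read-noise floor while the eliminated compartment
  (renal recovery) is nonzero — detectable in urine, not through skin.

### Optical forward model

Fluorescence spectrum (counts) on a 350–900 nm grid at 0.5 nm:

    [bg_floor + bg_auto·exp(−(λ−350)/60 nm) + g·signal·N(λ; 520, 15 nm)]
        · t_F · p

with gain g = 37 counts·s⁻¹ per unit signal, laser-power factor p drawn
once per time point (CV 5 %), plus optional Poisson shot noise and
Gaussian read noise (SD 5 counts). The paired laser spectrum is a narrow
Gaussian (σ = 1 nm) at the excitation wavelength scaled by the *same* p
and its own 1 ms integration time. Because everything scales with t·p,
the normalisation cancels exposure and power exactly in the noiseless
model. The decaying-exponential autofluorescence term makes the 350–450 nm
background estimate overshoot the in-band background slightly, leaving a
small constant negative offset in I_int — deliberately retained as a
realistic imperfection that the baseline-subtraction stage removes (with a
spectrally flat background the offset is exactly zero).

**Adaptive acquisition**: each record's integration time is the number of
500 ms frames needed for the expected in-band counts to reach 4×10⁴
(capped at 10 frames, flagged below-threshold), so dim records integrate
longer — exercising the integration-time normalisation end to end.

### What the generator does and does not emulate

Emulated: S-shaped oral uptake; gastric-emptying and permeability
contrasts; site-dependent two-phase curves; IV bolus decay; ICG
non-detectability; laser-power fluctuation; skin autofluorescence
background; shot/read noise; adaptive exposure. Not emulated: radiative
transport in tissue (depth-dependent attenuation is collapsed into static
site weights), melanin/BMI inter-subject variability, probe-inclination
artefacts, circadian/meal physiology, nonlinear (saturable) absorption,
and any absolute radiometric calibration — absolute I_int and AUC values
are in arbitrary normalised units, so passing tests validate orderings,
ratios, shapes and invariances, not absolute clinical values.

## Problem sizes and numerical choices

Tests and the acceptance script use sessions of 121–241 records (1–4 h at
60 s intervals, 1101-sample spectra), which keep the full suite in the
tens-of-seconds range while leaving every curve feature well resolved.
Flatness and degenerate-input tolerances: intensity ranges below 1e-12
are "flat"; peak detection requires ≥3 post-ingestion points; monotone
curves fall back to the global maximum with a warning rather than failing.
Closed-form oracles (two- and three-exponential absorption chains) agree
with the matrix-exponential solver to better than 1e-9 relative; the
instant-gastric-emptying limit is realised exactly by placing the dose in
the gut as the initial state rather than by a numerically large k_ge.

## Known limitations

- The compartmental rates are plausible defaults, not fitted values; the
  package deliberately does not attempt kinetic parameter estimation from
  clinical curves (deconvolution of k_ge/k_abs/k_el is ill-posed at this
  sampling density without reference measurements).
- AUC-to-peak is reported without correction for elimination during the
  uptake window.
- The per-glucose stoichiometry assumes all chain mass is anhydroglucose
  residues and ignores end-group and FITC mass corrections.
- Peak localisation on strongly asymmetric peaks inherits a small
  smoothing-induced shift (bounded above); reduce the window for sharply
  asymmetric data.
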