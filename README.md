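# fluorogut

Analysis toolkit for **transcutaneous fluorescence spectroscopy of gut
function**: a non-invasive technique in which a person drinks an oral dose
of a fluorescent contrast agent (fluorescein, ICG or FITC-Dextran) and a
fibre-optic probe held against the skin tracks the dye's passage from the
gut into the blood stream. The shape of the resulting intensity-vs-time
curve carries physiology: the time to the first peak reflects gastric
emptying rate, and the area under the curve up to that peak reflects
intestinal permeability. The package is aimed at researchers processing
such spectrometer sessions and at anyone prototyping analysis methods for
them against realistic synthetic data.

## What it computes

**Normalised integrated fluorescence intensity.** Each time point pairs a
fluorescence spectrum *I*(λ) (integration time *t<sub>F</sub>*) with a
backscattered-laser spectrum *L*(λ) (integration time *t<sub>L</sub>*).
With per-spectrum backgrounds *B<sub>F</sub>*, *B<sub>L</sub>* estimated
as the mean intensity over a signal-free window (350–450 nm),

```
         ( Σ_{λ=500}^{580} (I(λ) − B_F) ) · t_L
I_int = ─────────────────────────────────────────
         ( Σ_{λ=485}^{492} (L(λ) − B_L) ) · t_F
```

(emission band 500–580 nm and laser band 485–492 nm for fluorescein;
800–880 nm and 778–785 nm for ICG). Measuring the laser power *at the
skin* makes I_int robust to laser fluctuation, probe pressure and skin
tone.

**Time-course statistics.** `detect_peak` finds the *first* prominent
local maximum after ingestion (at forearm/wrist sites the signal rises
again later as dye leaks into the epidermis — that late rise is not a
permeability signal), and `auc_to_peak` integrates the baseline-subtracted
curve from ingestion to that peak (trapezoid rule, reported in
intensity·hours). AUC ratios between conditions quantify permeability
changes, e.g. with/without a hyperosmolar sugar load.

**Dye-labelling stoichiometry.** Beer–Lambert concentration
(ε = 77,000 M⁻¹cm⁻¹ for FITC at 494 nm), FITC:dextran molar ratio from
absorbance series, conversion to mol FITC per mol glucose residue
(162.14 g/mol anhydroglucose), and the effective FITC mass carried by an
oral FITC-Dextran dose.

**Synthetic sessions.** A five-compartment linear kinetic model
(stomach → gut → blood → dermis → epidermis, with elimination), an optical
forward model (skin autofluorescence background + Gaussian emission line +
shot/read noise, common laser-power factor per time point) and the
instrument's adaptive 500 ms-frame acquisition generate complete sessions
for six scenarios (`fluorescein_water`, `fluorescein_milkshake`,
`fluorescein_sugar`, `icg_oral`, `iv_bolus`, `fitc_dextran_lowdose`), so
the whole pipeline is testable without clinical data.

## Worked example

```sh
fluorogut simulate --scenario fluorescein_water --seed 42 --out demo
fluorogut analyze --manifest demo/manifest.yaml
```

prints

```json
{
  "dye": "fluorescein",
  "t_peak_s": 2460.0,
  "time_to_peak_s": 1560.0,
  "i_peak": 0.010238836816193881,
  "auc_to_peak": 0.002853580195159395,
  "baseline": -0.0002799791419323119,
  "warnings": []
}
```

Dye was ingested 900 s into the session; the uptake peak occurs 1560 s
(26 min) later at a normalised intensity of ≈0.010, and the permeability
marker (AUC from ingestion to peak) is ≈0.0029 intensity·h. Comparing
scenarios reproduces the expected physiology: the milkshake scenario peaks
later than water (slower gastric emptying), the sugar scenario's AUC is
more than twice the water scenario's (raised permeability), and the oral
ICG scenario yields a "no peak" error — the dye is cleared from blood at
~20 %/min and never accumulates above the noise floor.

The stoichiometry CLI:

```sh
$ fluorogut dye-calc dose --dose-g 1 --dextran-mw 4000 --ratio-per-glucose 0.002
effective FITC dose: 4.798 mg
$ fluorogut dye-calc dose --dose-g 1 --dextran-mw 4000 --ratio-per-glucose 0.02
effective FITC dose: 47.98 mg
```

i.e. a 1 g oral dose of commercial 4 kDa FITC-Dextran (labelled at
0.002–0.02 mol FITC per mol glucose) carries only 4.8–48 mg of FITC,
which is why it is hard to detect through skin at that dose.

## Layout

- `fluorogut.spectra` — spectra, bands, background estimation, I_int
- `fluorogut.timecourse` — time-course assembly, peak, AUC-to-peak
- `fluorogut.dye_chemistry` — Beer–Lambert and labelling-ratio calculations
- `fluorogut.synthetic` — kinetic model, optical forward model, scenarios
- `fluorogut.io` / `fluorogut.cli` — file formats, manifests, `fluorogut` CLI

See `docs/methods.md` for the model, parameter defaults and limitations.
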