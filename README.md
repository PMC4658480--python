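# hairpinmelt

Atom-resolution analysis of the thermal folding/unfolding of β-hairpin
peptides, combining four experimental readouts in one pipeline:

* **per-proton NMR melt curves** — each proton's chemical shift δ(T) across a
  temperature series is fitted with a five-parameter Boltzmann sigmoid,
  giving that proton its own melting temperature Tm;
* **Tm landscape** — the set of per-proton Tms is summarised into folding
  events (supervised Gaussian summaries per structural class, plus blind
  1-D Gaussian-mixture model selection by BIC) and ordered into a folding
  sequence (higher Tm = earlier formation on cooling);
* **DSC** — excess heat capacity after onset/offset chord baseline removal,
  calorimetric enthalpy ΔH_cal by peak integration, van't Hoff enthalpy via
  the two-state relation, and the cooperativity ratio r_vH = ΔH_vH/ΔH_cal;
* **secondary Hα shifts and ¹⁵N relaxation** — ΔδHα structure profiling
  against random-coil references, and mono-exponential R1/R2 +
  heteronuclear NOE fitting.

It is written for peptide-folding spectroscopists who have per-proton shift
tables, DSC traces or relaxation intensity tables and want per-atom melting
temperatures, an event-level folding hierarchy, and a calorimetric
cooperativity verdict from one reproducible toolchain.  Because raw melt
spectra are rarely deposited, the package ships a synthetic-data generator
with full ground truth, so every stage is verified by parameter recovery.

## Models

Per-proton melt curve (fitted by `MeltCurveModel`):

```
δ(T) = B·(T − x0) + A2 + (A1 − A2) / (1 + exp((T − x0)/dx))
```

with starting/final amplitudes A1/A2 (ppm), baseline slope B (ppm/K),
midpoint x0 ≡ Tm (K) and logistic width dx (K).

DSC van't Hoff enthalpy from the excess heat capacity:

```
ΔH_vH = 4·R·Tm²·Cp_exc(Tm) / ΔH_cal ,   ΔH_cal = ∫ Cp_exc dT
```

with Tm the temperature of the Cp_exc maximum and R = 8.314 J·mol⁻¹·K⁻¹.
r_vH ≈ 1 marks a cooperative two-state transition; r_vH ≫ 1 a broad,
non-cooperative or multi-event process.

Relaxation decays: I(t) = I0·e^(−R·t); heteronuclear NOE = I_sat/I_unsat
with a fixed 5% uncertainty.

## Worked example

```python
import numpy as np
import hairpinmelt as hm

# synthetic 30-proton hairpin dataset with known class structure
series, truth = hm.generate_melt_series(hm.default_melt_spec(seed=1))
fits = [hm.fit_melt_curve(s) for s in series]
accepted, rejected = hm.filter_fits(fits)
cmap = {hm.ProtonID(int(r.residue_number), r.atom_name, r.residue_type):
        r.class_label for r in truth.itertuples()}
print(hm.TmLandscape(accepted, cmap).fit(seed=1).summary())

# noiseless DSC round trip at the hairpin's calorimetric parameters
T = np.arange(250.0, 400.0, 0.05)
th, _ = hm.generate_dsc_thermogram(
    hm.DSCSimSpec(dh_vh=127.1, dh_cal=3.9, tm=316.4, temperatures=T))
print(hm.DSCAnalysis(th, onset=T[0], offset=T[-1]).fit().summary())
```

prints

```
Folding sequence (first-forming event on cooling first):
  1.      trp  Tm =  319.87 +/- 0.73 K  (n=12)
       |dTm| = 0.55 K vs combined SD 1.10 K -> superimposed
  2.     turn  Tm =  319.32 +/- 0.37 K  (n=5)
       |dTm| = 2.89 K vs combined SD 1.05 K -> successive
  3.   strand  Tm =  316.43 +/- 0.67 K  (n=13)
Blind mixture selection: k = 2
  component: mean  319.68 K, sd 0.69 K, weight 0.57
  component: mean  316.41 K, sd 0.63 K, weight 0.43

DSC analysis
  Tm               = 315.85 K
  Cp_exc(Tm)       = 0.1491 kJ/mol/K
  dH_cal           = 3.898 kJ/mol
  dH_vH            = 126.92 kJ/mol
  r_vH             = 32.56  (non-cooperative)
  T_1/2 (enthalpy) = 316.52 K (width 6.51 K)
```

Reading: the tryptophan ring protons melt highest (fold first on cooling),
nearly together with the turn (|ΔTm| smaller than the combined SDs →
"superimposed"), while the strand protons melt ~3 K lower as a clearly
separate, successive event.  The DSC side recovers the generator's
enthalpies to well under a percent and flags the transition as
non-cooperative (r_vH ≈ 33 ≫ 1), consistent with the multi-event landscape.

A command-line interface mirrors the library
(`hairpinmelt simulate | fit-melt | landscape | dsc | secshift | relax | run`);
`hairpinmelt run config.yaml` executes a config-driven pipeline and writes
JSON reports with seeds, versions and input checksums.

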