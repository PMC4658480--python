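# Methods

## Scope and model

`hairpinmelt` analyses the thermal folding/unfolding of a short β-hairpin
peptide at atomic resolution.  The underlying physical picture is that each
observable proton reports a local, effectively two-state order/disorder
transition with its own midpoint temperature, while the calorimetric trace
integrates all of them; a hierarchical (multi-event) folding pathway then
shows up as clustered per-proton Tms together with a van't Hoff ratio far
above 1.

### Per-proton melt model

Each proton's chemical shift versus temperature is fitted with a Boltzmann
sigmoid plus a linear baseline anchored at the midpoint:

δ(T) = B·(T − x0) + A2 + (A1 − A2)/(1 + exp((T − x0)/dx))

* A1, A2 (ppm): low- and high-temperature plateau shifts.
* B (ppm/K): baseline slope, modelling the smooth temperature drift of
  shifts outside the transition.  Anchoring the baseline at x0 keeps B and
  the plateaus identifiable.
* x0 (K): the transition midpoint, reported as that proton's Tm.
* dx (K): logistic width.  Melting-curve software often calls this "the
  slope at x0"; the actual slope there is (A2 − A1)/(4·dx) + B.  We treat
  dx strictly as the width parameter.

Fitting is (optionally weighted) nonlinear least squares
(`scipy.optimize.curve_fit`, trust-region reflective) with 1σ uncertainties
from the covariance.  Initialisation is deterministic: a coarse scan over
candidate midpoints (every observed temperature plus the steepest
finite-difference location) × widths {1, 2, 5, 10, 20} K, with the linear
parameters (A1, A2, B) solved exactly at each node; the best node seeds the
optimiser.  Bounds x0 ∈ [min T − 10, max T + 10] K and dx ∈ [0.5, 50] K
keep the optimiser out of degenerate plateau solutions; a solution pinned
at those bounds is flagged `converged=False` rather than raised.

Curve selection: fits are accepted when the amplitude-to-noise ratio
|A1 − A2|/σ_resid ≥ 5, R² ≥ 0.9 and the fit converged (all configurable).
The amplitude rule is checked first so a genuinely flat curve is reported
as amplitude-limited.  These thresholds are conservative conventions, not
measured constants: a transition of 0.1 ppm (the smallest generated
amplitude) at the default 0.005 ppm noise has amplitude-to-noise 20.

### Tm landscape

Supervised grouping is primary: protons are assigned to structural classes
(strand / turn / tryptophan side chains) by a user-editable class map, and
each class is summarised by its unweighted mean Tm, unbiased SD and a
normality check (Shapiro–Wilk plus QQ correlation; reported, never a hard
gate — with n ≤ 13 per class these are descriptive).  Blind event detection
is a separate operation: 1-D Gaussian mixtures for k = 1..k_max (≤ 4)
fitted with 10 seeded restarts and a 10⁻⁴ K² variance floor, k selected by
BIC.  Blind separation of clusters < 1 K apart with SDs of a few tenths of
a kelvin is statistically marginal at n = 30, which is exactly why the
supervised path exists; the blind path is meant for the coarse question
"one event or several?".

The folding sequence orders events by descending mean Tm (on cooling, the
highest-Tm element forms first), ties broken lexicographically by label.
Adjacent events are flagged "successive" when |Δmean| exceeds the *sum* of
the two SDs and "superimposed" otherwise.  The sum (rather than quadrature)
was chosen deliberately: it asks whether the ±1σ bands of the two event
distributions are disjoint, which matches the qualitative reading that two
events ~0.8 K apart with SDs 0.6 and 0.3 K overlap, while events ~3 K apart
do not.

### DSC

Processing follows standard peptide calorimetry: optional buffer–buffer
reference subtraction (linear interpolation onto the sample grid,
restricted to the overlap); a chemical baseline taken as the straight line
through the scan values at the onset and offset temperatures; excess heat
capacity Cp_exc = Cp − baseline inside the window and 0 outside; ΔH_cal by
trapezoidal integration; and

ΔH_vH = 4·R·Tm²·Cp_exc(Tm)/ΔH_cal

with Tm defined as the temperature of the Cp_exc maximum (not the half-area
point; for a broad transition the 1/T² skew puts the maximum ~0.5 K below
the thermodynamic midpoint, which is documented rather than corrected).
The ratio r_vH = ΔH_vH/ΔH_cal gets a verdict: two-state in [0.8, 1.25],
non-cooperative above 4, intermediate otherwise — conventional, fully
configurable thresholds.

The cumulative excess enthalpy is additionally fitted with
Y(T) = ΔH·(1 − 1/(1 + exp((T − T_half)/w))).  The width w is a required
extra parameter: without it the logistic has a fixed 1 K scale and cannot
match arbitrary transition widths; w is reported with the fit.

Onset/offset default to an automatic heuristic (grow linear segments from
each scan end while residuals stay below 2× a robust noise SD); manual
values always win, mirroring how practitioners actually pick these points.

**Scan-window caveat.**  The chord baseline removes, besides the instrument
baseline, the chord under the true excess curve between the window ends.
When the transition is broader than the scan (a 127 kJ/mol van't Hoff width
is ~50 K, wider than a 280–350 K scan), this systematically *understates*
ΔH_cal (by ~6–7% at the packaged parameters) and correspondingly
*overstates* ΔH_vH and r_vH — a well-known property of broad-transition
calorimetry, not an implementation artefact.  Round-trip validation of the
pipeline therefore uses windows spanning the full transition (e.g.
250–400 K at the packaged parameters), where recovery is better than 0.1%
for ΔH_cal and 0.2% for ΔH_vH; analyses on the instrument window are
reported as computed, caveat included.

### Secondary shifts and relaxation

ΔδHα = δ_obs − δ_random-coil per residue and temperature, classified strand
(≥ +0.1 ppm), helix (≤ −0.1 ppm) or coil — the community ±0.1 ppm
convention, configurable.  The default reference table is the Wishart et
al. (1995, J. Biomol. NMR 5, 67) random-coil Hα set; any mapping may be
substituted, and profile differences are exactly linear in the reference
table.  No neighbour-sequence or temperature corrections are applied by
default.

R1/R2 rates come from unweighted least squares of I(t) = I0·e^(−R·t)
(≥ 3 delays; uncertainties from the covariance); the heteronuclear NOE is
the saturated/unsaturated peak-height ratio with its uncertainty fixed at
5% of the value.  Profile differences propagate uncertainties in
quadrature.  No exchange correction or model-free analysis is attempted.

## Synthetic data: what it emulates and what it does not

The generators draw data from exactly the models the fitting stages assume,
with every drawn parameter recorded, so recovery tests are well-posed.

* **Melt curves.** The packaged default emulates a 17-residue hairpin
  (KQLLWIRSGDRPWYYTS) with 30 usable proton curves in three Tm classes —
  strand 316.5 ± 0.5 K (13 protons), turn 319.3 ± 0.3 K (5), Trp ring
  320.1 ± 0.6 K (12) — on the 278–343 K grid in 5 K steps.  The roster
  reproduces the 6 HN / 7 Hα / 5 aliphatic / 12 aromatic atom split; the
  exact per-class counts are an apportionment from the residue lists (the
  counts themselves are an interpolation) and stay configurable.  Per-curve
  width is 5 K, amplitudes 0.1–0.5 ppm with random sign, baseline slopes
  ±0.003 ppm/K — values chosen once so transitions are resolvable on a 5 K
  grid — and i.i.d. Gaussian shift noise of 0.005 ppm, a typical
  read-off/temperature-calibration scatter for well-resolved TOCSY peaks.
  A mutant-like preset draws all 30 Tms from a single 311 ± 0.9 K cluster.
* **DSC.** Cp_exc(T) = ΔH_cal·(ΔH_vH/(R·T²))·K/(1+K)², K the two-state
  equilibrium constant — i.e. ΔH_cal × d(unfolded fraction)/dT.  Area and
  width are independently settable, so any r_vH is producible.  Two
  identities anchor the tests: the peak height at Tm equals
  ΔH_cal·ΔH_vH/(4·R·Tm²) exactly, and the integral over a grid equals
  ΔH_cal times the fraction of the transition the grid captures (hence
  area-conservation tests use spanning grids).
* **Relaxation.** Mono-exponential decays on the standard delay sets
  (R1: 10–400 ms, R2: 15–165 ms) plus Gaussian noise; NOE pairs as
  (ratio·I0, I0).

Not emulated: peak overlap and misassignment, curved instrument baselines,
scan-rate kinetics, aggregation/irreversibility, temperature-dependent
noise, exchange contributions to R2, neighbour effects on random-coil
references.  Passing recovery tests therefore demonstrates the estimators
are correct and well-calibrated for the assumed data-generating process;
they do not certify robustness to pathologies the generator does not
produce.

## Numerical choices

* Gas constant R = 8.314 J·mol⁻¹·K⁻¹ (8.314×10⁻³ in kJ units used
  internally); temperatures kelvin everywhere (°C only behind an explicit
  reader flag), shifts ppm, heat capacities kJ·mol⁻¹·K⁻¹, delays s.
* Melt fit optimiser tolerances 10⁻¹³ (xtol/ftol/gtol) so algebraic
  equivariances hold to ~10⁻⁸ on exact data.
* Mixture selection: BIC, full covariance, reg_covar 10⁻⁴ K², 10 restarts,
  fixed random_state → bitwise deterministic and permutation invariant.
* DSC window endpoints tolerate 10⁻⁶-scale float round-off at scan edges.
* Degenerate inputs: singleton classes get SD 0 and an undefined normality
  flag; all-equal Tms select k = 1 via the variance floor; ΔH_cal = 0 makes
  the van't Hoff relation undefined and raises; logistic enthalpy fits on
  non-monotone (heavy-noise) cumulative curves return `converged=False`.
* Ties in event ordering break lexicographically by label so reports are
  reproducible byte-for-byte.

## Problem sizes

Recovery experiments use 20 seeds × 30 curves (landscape and mutant
detection; ~600 five-parameter fits per experiment), 50 seeds for the
bias/spread property, 0.05 K DSC grids (1 400–3 000 points) and 1 000
replicates for the normality-calibration check.  These sizes give
standard errors comfortably below the tolerances being asserted while the
whole suite runs in well under a minute of CPU.

## Known limitations

* The per-proton model is strictly two-state per curve; double-sigmoid or
  globally coupled (shared-Tm) fits are out of scope.
* The DSC stage does not deconvolve the excess curve into sequential
  sub-transitions; r_vH ≫ 1 is reported as non-cooperative without
  resolving how many events contribute.
* Blind mixture selection is reliable for well-separated clusters
  (≳ several combined SDs) and intentionally conservative otherwise.
* Absolute ΔδHα values depend on the choice of random-coil reference set;
  profiles computed with different references are comparable only through
  the documented linearity.
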