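# Methods

## The quantitation model

Each target peptide is monitored as a light/heavy stable-isotope pair at a
scheduled retention time and, when FAIMS is on, a per-precursor
compensation voltage. The analyte amount is obtained by direct isotope
ratio: summed (or single) fragment XIC area of the analyte channel divided
by the reference channel, times the known reference spike (5 fmol = 5000
amol) over the column load (1 µg), giving amol/µg. No calibration
regression is fitted — the isotope pair makes the relative response unity
by construction, and the reverse-dilution curve is used only to *validate*
the quantitative range, not to back-fit amounts. Accuracy at a dilution
level is therefore mean measured ÷ nominal, computed from the same direct
ratio.

Chemistry: monoisotopic residue masses (pyteomics `std_aa_mass`), water
18.010565, proton 1.00727646, fixed carbamidomethyl-C +57.021464, heavy
labels +8.014199 (K) / +10.008269 (R) on the C-terminal residue — hence on
every y ion and no b ion. Display rounding is half-up to 2 decimals,
matching printed method tables. One bundled method row (LVVVGACGVGK 2+)
prints 0.005 Th above the exact computation — a half-ulp rounding artifact
of the source table — so table validation uses the printed precision
(±0.01 Th) as its band; the test suite pins this row as the only one
deviating by more than 0.005 Th.

## The synthetic acquisition model

`simulate_run` emulates one scheduled-PRM injection:

* **Scheduling.** One MS/MS scan per channel per duty cycle
  (`cycle_time_s`, default 3.3 s — six points across a ~20 s peak) inside
  the target's retention window (default ±2 min; the bundled studies narrow
  this to ±0.35–0.4 min purely to keep run sizes small).
* **Elution.** Gaussian, FWHM `peak_fwhm_s` (default 11.8 s, ~20 s base),
  apex jittered per run (σ 1 s) identically for both channels — coelution
  of an isotope pair is exact by construction.
* **Ion counting.** Signal flux (ions/ms) = amount × `response_factor` ×
  g(t) / 100, where `response_factor` is ions per amol per scan at the apex
  at a full 100 ms fill. Total flux F sets the injection time
  min(100 ms, 10⁶/F) — the AGC contract — and every centroid's ion count is
  an independent Poisson draw of its flux × fill time. Reported intensities
  are ions/ms, so chromatogram heights are fill-time invariant and XIC
  areas are comparable across AGC-limited and time-limited scans. The
  scan's total ion count is the sum of all drawn counts (the vendor
  RawOvFtT analog).
* **Fragments.** Each target monitors its five largest-ordinal singly
  charged y ions inside [200, 1300] Th. Signal splits over a fixed
  per-target Dirichlet-drawn fractional pattern, identical for light and
  heavy — a true isotope pair fragments identically, which is what makes
  the 70–130% fragment-ratio criterion satisfiable on clean data.
* **Background.** Structureless and uniform in m/z over [200, 1300] Th at
  `background_flux` ions/ms (FAIMS multiplies it by the per-target
  retention fraction). Sampling is stratified exactly: within ±0.02 Th of
  each monitored fragment, background is drawn ion-by-ion (so extraction
  sees honestly sampled in-tolerance background); the remainder is
  coarse-grained into 40 centroids kept out of those zones. This is an
  exact decomposition of the uniform model, chosen for speed, not an
  approximation of it.
* **Handling noise.** A per-run, per-channel lognormal factor
  (`measurement_cv`) on the delivered amount models spiking/pipetting
  variability; it is deliberately *not* applied to the background.
* **Interferences.** Optional Gaussian interferents at a named fragment
  m/z with an apex offset, used to exercise the flagging rules; the default
  background model contains no structured isobars.

What the generator does **not** model: chromatographic drift and tailing,
ionization suppression, isotope envelopes, centroiding artifacts, MS1
scans, FAIMS transmission physics (a per-target scalar stands in for it).
Passing tests therefore demonstrate the *analysis chain's* correctness and
statistical behaviour under the stated error model, not performance on
real instrument files.

## Analysis conventions

* **Extraction** sums centroids within ±10 ppm (narrower than the peak
  width at the 30 K resolution the method acquires at; configurable).
  Summation, not nearest-centroid, for robustness to centroid splitting.
* **Peak boundaries** are detected on the *reference* channel (light for
  LOQ curves and blanks, where the light spike is constant; heavy for
  clinical samples) from the 3-point-smoothed summed XIC: walk out from the
  apex to the first point at or below 1% of apex, or a local minimum below
  10%, capped at the schedule window. Boundaries apply unchanged to the
  analyte channel. Smoothing spreads a peak base by one sample per side,
  so boundaries recover a triangular base within two cycle times (and
  always bracket it). No baseline subtraction — background is
  characterized separately from blanks, and subtracting would count it
  twice. Trapezoidal integration; area is not invariant to inserting
  zero points *inside* the boundaries (a property no trapezoid rule has),
  only outside them.
* **CV-scan analysis** smooths with the same 3-point window; the plateau
  (default 0.9 × max) and half-max (0.5 ×) ranges are the supra-threshold
  runs *containing the apex*, with linearly interpolated endpoints. The
  apex-run convention (rather than "widest run") guarantees
  half-max ⊇ plateau ∋ optimum on any curve; on unimodal transmission
  curves — the instrument use case — the two conventions coincide. Ties at
  the maximum resolve to the most negative voltage, the scan direction.
* **LLOQ rules.** Level pass ⇔ replicate CV < 20% (sample SD, n−1) ∧ mean
  accuracy ∈ [80, 120]% ∧ mean fragment ratio ∈ [70, 130]%. For the summed
  fragment set the ratio criterion uses the unweighted mean of per-fragment
  mean channel ratios. The quantitative range is the longest contiguous
  passing run (ties → the run with the higher levels; an isolated passing
  level below a failing gap is excluded). Replicate curves merge to the
  lower LLOQ / higher ULOQ. Fold reductions are rounded to the nearest
  integer because the threefold grid makes true ratios 2.98–3.01.
  "Best fragment" = lowest merged LLOQ in curve context, highest reference
  area in single-sample context.
* **Background accounting** uses the scan's total injected ion count, not
  extracted fragment intensity: FAIMS and quadrupole selection act before
  the analyzer, so in a blank's heavy window everything injected is
  background. The group comparison is a Welch t test (safer than pooled
  variance at n = 7 vs 4; pooled is available) with the mean-difference CI
  from Welch–Satterthwaite df; the improved group's own mean and
  one-sample CI are reported alongside, since published summaries quote
  either form.
* **Interference flagging**: a fragment is excluded when its relative
  abundance deviates > 30% between channels (the 70–130% rubric) or its
  apex shifts by > 0.5 peak widths. Both thresholds are configurable and
  recorded in the run log; they are this package's operationalization of
  what is done by manual review on real data.
* **Cohort reporting**: per-gene latent truths (HER2 log-uniform over the
  30-fold clinical range 200–6000 amol/µg by default), peptides of a gene
  sharing the truth up to a 10% lognormal peptide-level factor; IHC classes
  from thresholds (500/1500/4000 amol/µg) on a blurred copy of the HER2
  truth. Below-LLOQ amounts are flagged, never censored. A within-class
  outlier is a sample at or above the next-higher class's median.

## Calibrated validation designs

`faimsprm.designs` freezes the study conditions used to validate the
statistics end to end; parameters were derived from the Poisson/lognormal
error model first and then confirmed by simulation:

* **LLOQ recovery** — one precursor, no FAIMS, response factor 0.27
  ions/amol/scan, background 56 ions/ms, 2% handling CV, 24 replicates ×
  10 levels. Ion yield puts the true replicate CV at ~21% at the 15 amol
  level and ~14% at 46 amol (the designed crossing of the 20% limit), and
  the in-tolerance background bias (~5 amol) puts accuracy at ~125% at 15
  amol and ~111% at 46 amol, so the 46 amol level is the designed LLOQ.
  Replicate count matters here: the sampling SD of a 4-replicate sample CV
  is ~half the CV itself, which would make single-grid-level recovery a
  coin flip under any noise setting; 24 replicates make the recovery
  probability per curve ≈ 98%.
* **Coupling** — the same curve at background 280 ions/ms under FAIMS
  retention 0.2 vs 0.9 (all seeds shared): more retained background means
  more bias and a higher LLOQ, so the strong-reduction curve's LLOQ must
  not exceed the weak one's.
* **Retention recovery** — 26 blank injections per condition (~320 heavy
  scans inside the light-defined windows); the median ions-per-scan ratio
  estimates the retention fraction, with a delta-method SE from the
  Poisson median SE 1.2533·√λ/√n.

## Numerical and degenerate-input conventions

Half-up rounding only at display time; all internal comparisons on full
precision. Empty scans zero-fill XICs. All-zero reference traces raise
(no-peak / no-signal / cannot-assess) rather than returning silent zeros.
Replicates with no detectable light reference are excluded with a logged
warning; a level with fewer than two usable replicates is unevaluable and
cannot pass. Zero no-FAIMS background medians make percent reduction
undefined (NaN, reported missing). Every random draw descends from one
integer seed through `SeedSequence` spawning; reruns are byte-identical,
which the suite checks on serialized scan streams and on the full study
output directory.

## Known limitations

The background-ion model is unstructured; real FFPE matrix background has
isobaric structure that would make interference flagging earn its keep
more often than here. The simulator's FAIMS effect is a scalar
transmission/retention pair, so CV-scan analysis and quantitation are
exercised on separate synthetic inputs rather than one physical model.
Fragment panels are fixed to singly charged y ions (the published
quantifier choice); b ions are computed by the chemistry layer but not
monitored. The default end-to-end study uses smaller retention windows and
scan counts than an instrument would record, chosen so a full 192-injection
study with its analysis completes in seconds; all such sizes are config
fields, and the run log records the values used.
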