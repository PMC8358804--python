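# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `efferentquant`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## ABR model and threshold detector

**Record model.** A waveform is a uniformly sampled record starting at
stimulus onset (default 24.4 samples/ms ≈ the common 24.414 kHz evoked-
potential digitisation, 10 ms duration). A series holds one record per
stimulus level, 10–90 dB SPL in 10-dB steps.

**Detector.** The response criterion is two-sided exceedance of the
baseline mean by more than `k` baseline SDs (default k = 2), sustained for
at least `min_run` consecutive samples inside the closed 1.4–5.0 ms
analysis window. Choices and why:

- *Baseline window* `[0, 1.0) ms`, half-open, sample SD (ddof = 1). The
  1.4 ms closed-field conduction delay guarantees this window is
  pre-response.
- *Two-sided* exceedance: alternating-polarity click stimulation makes
  the voltage sign a montage convention; a "significant voltage change"
  has no preferred sign.
- *`min_run` default 0.20 ms* (5 samples at 24.4 kHz). The run length is
  the detector's only free knob and is calibrated, not guessed: with a
  24-sample baseline the SD estimate is noisy enough to inflate per-sample
  exceedance far above the idealised 4.55%, and a calibration sweep
  (400 all-noise + 400 signal-bearing simulated series) measured
  false-positive (uncensored all-noise) series rates of ~7%, ~1.5% and 0%
  at 0.10, 0.20 and 0.25 ms, with within-one-step threshold recovery of
  97.3%, 99.5% and 100%. 0.20 ms meets the ≤5% false-positive design
  target with margin while leaving recovery essentially perfect.
- *Degenerate baseline* (SD = 0): any in-window deviation from the mean
  counts as a response and the call is flagged, rather than dividing by
  zero or silently failing.
- *Threshold policy* `minimal` (the lowest responding level — the
  defining wording) by default; `monotone` (lowest level above which all
  levels respond) is available for series with spurious low-level calls.
- An optional zero-phase 500–3,000 Hz Butterworth band-pass is provided
  for raw inputs but is off by default: acquisition normally band-limits
  the record already.

**Wave metrics.** Latency is stimulus onset to positive peak; amplitude is
peak-to-peak from the nearest preceding local minimum. Peak selection uses
`scipy.signal.find_peaks` with a prominence floor of 2× baseline SD (peak
selection has no standard definition; the floor is a parameter).

**Estimator bias.** Because estimated thresholds snap up to the level grid,
the mean estimated threshold exceeds the mean underlying (continuous) true
threshold by up to half a step; e.g. a cell with true mean 33.3 dB
(SD 5.2) estimates near 45 dB on a 10-dB grid. Shift analyses are
differences of grid values and are unaffected to first order.

## Synthetic ABR generator

Each wave is a biphasic transient — a positive Gaussian lobe minus a
leading negative lobe, shifted so the positive peak falls exactly at the
nominal latency and scaled to unit peak-to-peak — so the standard latency
and amplitude definitions apply exactly to the rendered truth. Four waves
by default (latencies 1.9/2.8/3.6/4.4 ms at 90 dB, relative amplitudes
1.0/0.8/0.9/0.6, width σ = 0.15 ms), with latency stretching 0.01 ms/dB of
attenuation. At level L ≥ threshold the complex's peak-to-peak amplitude is
`0.1 µV/dB × (L − threshold + 10)`; below threshold the signal is exactly
zero. Post-averaging noise is i.i.d. Gaussian per sample (default SD
0.15 µV): simulating the 1000-sweep average directly is statistically
identical to averaging 1000 sweeps and ~1000× cheaper. The no-noise limit
(`noise_sd = 0`) is allowed so that exact threshold recovery is testable.

## Cochlear geometry

The place–frequency map is Greenwood-form, `F(x) = A(10^{ax} − k)` with
`x` the fraction of arc length from the apex; defaults are Greenwood's rat
constants (A = 0.398 kHz, a = 2.2, k = 0.631; span ≈ 0.15–63 kHz, covering
2.8–45.2 kHz). Constants are configuration — no species' constants are
hard-coded as truth. Arc positions always use the *measured* trace length;
the 9,400 µm Wistar reference figure is only a normalisation default for
simulation (real measured cochleae average ~8.1 mm). Polyline
interpolation is linear between digitised points; coordinates are 0-based
µm, y-down. Orientation (apex-first vs base-first traces) is a flag,
apex-first by default.

## Image model and quantitative ICC

**Scene.** 8-bit dark-on-light fields (DAB-like), default 560×560 px at
0.2 µm/px (25 px/µm², 112×112 µm ≈ a ×40 camera field). Background is
Gaussian (mean 200, SD 4 gray). Terminal buttons are non-touching ellipses
(axis ratio 0.75–1, area-preserving, spacing by major axis + 2 px) whose
per-button gray encodes an OD drawn from the condition's OD profile
(transmission convention gray = 255·10^−OD, floor OD 0.30 so that a
stained terminal is by definition detectably dark). Button count is
Poisson with density 40 per 10,000 µm² of usable area. The mean-area
profile over frequency is Gaussian in log₂-frequency: floor 5.5 µm², peak
10.5 µm² at 11.3 kHz, width 0.75 octaves, within-field SD 1.8 µm² — the
sham cochleotopic profile.

**Fascicle band.** A connected wavy band of efferent fiber fascicles
(bottom 15% of the frame, OD 0.85 ± noise) is rendered spatially disjoint
from the buttons and is *not* scaled by group effects. This is a modelling
point, not decoration: the field z-normalisation
`(OD_button − OD_field)/SD_field` cancels any intensity change shared by
the entire scene, and on a pure buttons-on-background image the normalised
OD of a button saturates at √((1−p)/p) (p = stained-area fraction),
measuring stained *area*, not staining *intensity*. Terminal depletion
spares the passing fascicles; that stable immunoreactive mass anchors the
field statistics so that normalised button OD tracks the terminals' ChAT
content. Consequently simulated normalised-OD magnitudes (≈0.7–1.5) are
scene-dependent and are not calibrated to any published table's absolute
values; only orderings and contrasts are meaningful.

**Segmentation.** Components strictly darker than the threshold,
8-connected, area-gated to 0.5–80 µm² (the band and macrophages fall above
the gate; noise specks below). The pipeline applies one *global* gray
threshold (default 150) to every image — the scene guarantees a wide gray
gap between stained structures (≤ ~130 across all conditions) and
unstained structure (≥ ~165) — matching a step-filter-calibrated
acquisition where one density threshold serves all images. Automatic
per-image thresholding (triangle method; Otsu optional) remains available
for standalone use: triangle rather than Otsu because stained objects
occupy only a few percent of the field and Otsu's between-class criterion
drifts into the object class on such unbalanced histograms. Area is pixel
count × pitch², so 25 px = 1.0 µm² exactly at default pitch.

**Calibration.** Gray→OD is a monotone piecewise-linear interpolant through
the 11 step-filter readings (default: ideal transmission curve
OD = log₁₀(255/gray) sampled at OD 0–2). Queries outside the calibrated
range clamp to the end segments with a warning. When a measured table is
supplied, the curve — not the log formula — is authoritative.

**Densitometry.** A button's *mean gray* is converted to OD (the gray-level
densitometry convention), not per-pixel ODs averaged; the difference is a
Jensen term well under the calibration step. Field statistics use the
population SD (the field is the full pixel population). The 30 buttons per
field are a seeded uniform random sample standing in for manual selection
(no reproducible manual rule exists); when fewer than 30 exist, all are
used with a warning.

**Immune cells.** Candidates darker than a robust background cut
(median − 4·MAD-SD) are classified by equivalent diameter and
immunoreactivity (mean OD above field mean + 1 SD): 10–20 µm and dark →
immunoreactive macrophage; 5–10 µm and not dark → monocyte; everything
else (buttons, the band) is ignored. Rates normalise per 1,000 µm of
cochlear length. The simulator renders macrophages at OD 0.9 ("intense"
immunoreactivity) and monocytes at background −35 gray; the generator's
class diameters (12–20, 6–10 µm) sit inside the classifier's bands so that
rendered and counted classes agree.

## Study generator

Default design: groups SC / AT / ES_AT, 6 animals per group, protocol days
(0, 12, 13, 14, 19, 26); AT and ES_AT animals split half short-term
(day 13) and half long-term (day 26) terminal; all animals contribute ABR
at every day (the generator does not model euthanasia attrition).
Injected effects are configuration with defaults taken from the study
design this emulates where printed, chosen once where not:

- *Thresholds* (mean, SD, dB): baseline cells (7, 1.5) — i.e. true
  thresholds just below the lowest level so estimates sit at 10 dB; AT
  day 13 (30, 6.32), day 14 (21.66, 4.08), day 19 (13.33, 5.16); ES/ES_AT
  day 12 (33.33, 5.16), day 13–14 (8, 2).
- *Area/OD scales* relative to sham, from the published condition means
  (area 8.14/9.11/11.36/11.33 vs 10.00; OD 3.37/3.26/4.34/5.14 vs 4.30):
  AT+1d (0.814, 0.784); ES_AT+1d (0.911, 0.758); AT+14d (1.136, 1.009);
  ES_AT+14d (1.133, 1.195).
- *Immune rates* per 1,000 µm (qualitative in the source; fixed once):
  SC (0.2, 0.3); AT+1d (1.5, 1.0); ES_AT+1d (0.8, 0.6); AT+14d (0.5,
  0.4); ES_AT+14d (0.3, 0.3).

Button area and OD are drawn independently per button; the generator does
not impose a size–OD correlation, so the per-condition correlation table
is structurally reproduced (layout, coefficients, p-values) but its
coefficients hover near zero rather than matching any published values —
correlation *recovery* is validated separately on data with an imposed
ρ = −0.58.

Determinism: every entry point takes one integer seed; the study generator
and pipeline fan it out through `numpy.random.SeedSequence`, so a manifest
(config + seed) reproduces every table byte-identically.

## Statistics

- **Friedman**: midranks within blocks, tie-corrected quotient
  χ² = (k−1)·Σ(Rⱼ − n(k+1)/2)² / (Σr² − nk(k+1)²/4); all-tied data give
  χ² = 0, p = 1. Post hoc default is Dunn-type comparison of rank means,
  z = ΔR̄/√(k(k+1)/6n), Bonferroni-adjusted, against the baseline level
  (day 0) by default. Rationale: at n = 3–6 subjects the exact Wilcoxon
  signed-rank p cannot fall below 2/2ⁿ, so a Wilcoxon post hoc can never
  survive Bonferroni at these sizes; the rank-mean procedure is the one
  major statistics packages attach to the related-samples Friedman test.
  Wilcoxon and all-pairs variants are available.
- **Mann–Whitney**: exact two-sided p by full enumeration of all
  C(n, n_a) splits of the pooled midranks (conditional on observed ties)
  for n ≤ 12 — the group sizes here; p = min(1, 2·min(P(U≤u), P(U≥u))).
  Tie-corrected normal approximation otherwise.
- **One-way ANOVA**: textbook sums of squares; all-zero within-group
  variance with unequal means yields an infinite F, flagged rather than
  silent. Bonferroni post hoc uses pooled-MSE pairwise t; Games–Howell
  uses Welch df and the studentized-range distribution
  (`scipy.stats.studentized_range`), validated against a 10⁶-draw
  Monte-Carlo range simulation to <10⁻³.
- **Two-way ANOVA**: statsmodels OLS with Type II sums of squares
  (appropriate for unbalanced data without interaction emphasis); empty
  cells error by name.
- **Correlations**: Pearson and Spearman both always reported; a
  `coefficient` column is selected by a Shapiro screen at 0.05 on both
  variables. Zero-variance inputs flag the row.
- All tests two-sided, α = 0.05.

## Validation problem sizes

The self-validation suite (`efferentquant.evaluation`, exercised by
`tests/test_acceptance.py` and `scripts/acceptance.py`) uses: 1,000 random
waveforms for detector-oracle equivalence; 200 series each for threshold
recovery and false-positive censoring; 100 frames for segmentation
exactness; 100 simulated cochleae (6 fields each) for cochleotopic peak
recovery; full enumeration for Mann–Whitney at n ≤ 8 and 100 random tables
for the Friedman oracle; 10⁶ Monte-Carlo draws for the studentized range;
1,000 replicates per test for null calibration; and 50 replicate studies
at n = 6/group for the end-to-end qualitative pattern. These sizes give
Monte-Carlo standard errors comfortably below the margins asserted while
keeping the whole suite to a few minutes on one CPU.

## What passing tests do and do not show

The generator emulates the *structure* of real data — averaged evoked
potentials with level-dependent wave complexes, dark-stained terminals on
a bright field with a tonotopic size gradient, group × day effect
injection — not its full texture: no stimulus artifacts or myogenic noise,
no staining gradients, uneven illumination, focus loss or touching
terminals, no within-animal left/right ear structure, and independent
area/OD draws. Exact segmentation counts, in particular, certify the
measurement chain on well-separated objects, not performance on degraded
real micrographs. Threshold-recovery rates are specific to the simulated
noise model; on real records the detector's operating point should be
re-checked against an expert-scored sample. The statistical layer, by
contrast, is validated against oracles that do not depend on the
generator at all.

## Other limitations

- No acoustic trauma, cochlear micromechanics or electrode-current
  modelling; effects are injected at the measurement level.
- Waves are ordinal peaks; no physiological wave I–V attribution, and the
  detector applies the 2SD rule to the whole 1.4–5 ms window rather than
  tracking a specific wave.
- Z-stack deep-focus fusion is out of scope (frames are assumed fused); a
  max-contrast fusion utility ships untested against reference stacks.
- Whether one- or two-sided exceedance and what minimum excursion duration
  define a "significant voltage change" are unstated in the source
  convention; both are exposed as parameters and the defaults documented
  above.
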