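# Methods

This note documents the models, conventions and numerical choices behind
`mbcav`, what its synthetic data does and does not emulate, and the known
limitations.

## Acoustic quantification

**Pipeline.** A passive-cavitation-detector recording is a timed sample
stream with a sonication onset, pulse length and drive frequency f₀
(defaults: 30 ms pre + 5 ms pulse + 15 ms post at 125 MHz, f₀ = 1.04 MHz).
Analysis proceeds: Butterworth band-pass → windowing → PSD → noise
normalization → band integrals → group statistics.

**Filtering.** 5th-order Butterworth band-pass, 0.3–10 MHz corners, applied
forward–backward (`sosfiltfilt`). Zero-phase filtering keeps onset timing
unskewed; the price is that the effective magnitude response is the square
of the single-pass response (≈ double attenuation in dB in the stopbands),
which is documented rather than compensated. The low-pass corner must lie
below Nyquist.

**PSD convention.** One-sided, window-power-normalized periodogram: the
windowed segment is zero-padded to `next_fast_len(fs / 200 Hz)` so the
frequency spacing is ≤ 200 Hz, and scaled so that ∫PSD df equals the
windowed mean square divided by mean(w²). This makes Parseval checks exact
(a unit-amplitude tone integrates to 0.5) for both rectangular and Hanning
windows. Two window recipes are provided: a 500 µs rectangular window at
onset for overall cavitation, and 200 µs Hanning windows sliding by 100 µs
(50% overlap; 49 full windows over a 5 ms pulse) for temporal evolution.

**Noise normalization.** Both signal and noise PSDs are divided by the
*scalar* mean of the noise PSD over [f₀, 3f₀] (a per-bin division would
whiten the receiver response, which the analysis does not assume). The noise
window has the same length and taper as the signal window and is taken from
the pre-onset segment, rightmost placement ending 1 ms before onset to avoid
trigger transients (flush against onset if the pre-onset segment is short).
All normalized quantities are invariant to a global amplitude rescaling of
the raw record.

**Bands.** Peak bands are 10 kHz wide, centred at the maximum PSD bin within
±10 kHz of the nominal order frequency (the search halfwidth equals one
band width; the analysis convention is "the located peak", and ±10 kHz is
one reasonable, fixed choice). The third-order families are reported as
pooled pairs (1/3+2/3 and 4/3+5/3). Broadband IC power is the mean of two
40 kHz integrals at 3.42f₀ and 3.58f₀ — between-harmonic loci inside the
receiver band. Relative peaks divide the peak band's mean PSD by the pooled
mean over two flanking reference bands per component (e.g. (0.45–0.47)f₀ +
(0.53–0.55)f₀ for 1/2f₀). Integration is trapezoidal over the padded grid
with the band edges clipped by linear interpolation, which makes a flat PSD
integrate to exactly level × width regardless of grid alignment. Note that
at f₀ = 1.04 MHz the lower 1/3f₀ reference band (0.28–0.30)f₀ begins at
0.291 MHz, marginally below the 0.3 MHz high-pass corner; bands are
validated against the PSD grid, not against the receiver band.

**Two caveats worth knowing.**
*Peak-location bias on noise:* because the peak band is centred on a
located maximum, pure noise yields relative peaks whose mean is above 1
(≈ 1.3 for the default geometry) with a wide spread — selection of the
maximum among correlated bins. Tests therefore compare the white-noise
ratio to 1 within the Monte-Carlo spread, not to 1 exactly.
*Zero-padding vs discrete sums:* padded-grid band integrals agree with a
brute-force sum over the unpadded DFT in the mean (< 2% over random
recordings, 100 kHz bands) but fluctuate band-by-band on noise-dominated
spectra, because zero-padding interpolates the periodogram and a finite band
picks up cross-terms between neighbouring independent bins. This is a
property of the estimator pair, not an implementation error.

**Group statistics.** Right-tail two-sample t-tests assuming equal
variances between consecutive pressure groups (is the higher-pressure group
elevated?) and between signal and noise summaries. Raw one-sided p-values
are reported, mirroring an uncorrected multi-band analysis; a `holm=True`
flag adds Holm-adjusted values. Zero pooled variance is an error, not a
p-value.

## Event statistics

Event tables carry one row per sonicated vessel with the outcome chain
activation → fate {remained | extravasated | unclear} → RBC leakage
{none | transient | sustained} → flow reversal {transient | sustained}.
Row invariants (no fate, leakage or reversal without activation; an
extravasation time exactly when the fate is extravasated) are enforced at
I/O time, rejecting offending rows individually with a report.

Rates are normalized by the vessels in each (pressure group × caliber bin)
cell; empty cells are flagged, never divided. Pressure groups follow the
acquisition scales: network low = {0.5, 1}, intermediate = {2}, high = {3}
MPa; single-vessel low = {1}, intermediate = {2, 2.5}, high = {3, 3.5} MPa.
Default caliber bin edges are 5, 10, 20, 40, 70, 100, 180, 300 µm —
expressing the diameters the observations single out (smallest detectable
5–10 µm, extravasation up to 56 µm at 1 MPa and 180 µm at 3 MPa) — and are
configurable. Fate probabilities are conditioned on *all* activations
(unclear fates are a separate outcome column, not removed from the
denominator); leakage-given-fate conditions on the fate count. Percentages
are presented at nearest-integer rounding with raw fractions always
retained. Bifurcation proximity is reported at a 50 µm threshold with a
second value at 100 µm, since both thresholds appear in this literature;
rows without a recorded distance are excluded and counted. The
optical–acoustic summary uses a rank (Spearman) correlation of per-FOV
leakage fraction against IC power per size group {5–20, 20–50, ≥50 µm},
with a label-permutation p-value (10,000 permutations by default) — a rank
statistic because no linear or threshold form is assumed; groups with fewer
than 3 FOVs are flagged not computed.

### Packaged observed counts

The printed event tallies ship as JSON: 4742 vessels, 486 activations;
per-pressure activations 38/162/286, fates 20+13+5, 29+109+24, 9+226+51,
RBC leakage 17/124/255, transient reversals 35/–/160; pooled 348
extravasations with 335 leaking and 58 retained bubbles with 0 leaks; a
timing histogram of 3.8% < 0.1 ms, 60% in 0.2–0.3 ms, 36.2% in 0.4–5 ms.
Entries not printed directly (the 2 MPa vessel total 1402 and fate split,
the 3 MPa unclear count 51) are derived by subtraction and flagged.
`expand_to_records()` reconstructs a deterministic per-vessel table
reproducing every tally exactly; quantities the tallies do not constrain
are filled conservatively (leakage routed through extravasated rows first,
split 13/109/213 across pressures so the pooled 335/348 holds, remainder on
unclear-fate rows; sustained reversals placed on leaking rows; the unprinted
2 MPa transient-reversal count interpolated at 118; vessel geometry left
missing). One presentation quirk: the printed 2 MPa leakage percentage (76%)
truncates 124/162 = 76.54%, whose nearest-integer rounding is 77; the
package reports the exact fraction and standard rounding.

### Event simulator

`generate_event_table` draws the chain per vessel with probabilities that
may vary by pressure; the defaults are calibrated to the packaged counts
(activation 38/1932 → 286/1408, extravasation 13/38 → 226/286, leakage |
extravasation 335/348 pooled, transient reversal 35/38 → 160/286, with the
2 MPa reversal default 0.73 interpolated). Leakage is drawn only through the
extravasation branch — the chain the taxonomy defines — so simulated tables
are slightly more conservative than the observed tallies, where some
leakage rows carry unclear fates. Extravasation times come from the
timing histogram (uniform within bins). Diameters are log-normal (median
25 µm, σ_log = 0.65, clipped to 5–300 µm), bifurcation distances
exponential (scale 80 µm), FOVs of ~45 vessels: plausible microvascular
geometry, not fitted to data.

## Morphometry

Walls are traced on profiles normal to a centerline polyline: the profile
is sampled at 0.5 px steps (cubic interpolation), the lumen located at the
intensity minimum, and each wall placed at the signed gradient extremum on
its side, refined by a parabolic fit (sub-pixel). A profile is invalid when
an extremum fails both a noise-relative (4× tail SD) and an absolute
(0.04 intensity/px) gradient floor — washed-out or occluded boundary
stretches; gaps are filled by linear interpolation/extrapolation from the
adjacent valid profiles of the same wall, emulating boundary extrapolation
across damaged sections. A frame with > 50% invalid profiles is flagged
invalid.

D₀ is the mean of all valid pre-onset diameters (averaging suppresses
speckle noise; a single pre-sonication measurement is the manual-analysis
analogue). Rapid deformation is the extreme of (D−D₀)/D₀ by magnitude over
[onset, onset + 1 ms] with its sign (dilation +, constriction −); sustained
deformation is the change at the frame nearest onset + 1 s (within a 50 ms
tolerance) — "the change at 1 s" being the only consistent reading of a
single-time-point maximum — and is flagged unavailable when that frame is
missing or untraceable. Symmetric vs asymmetric-local classification is an
input label on phantoms, not inferred. Measured accuracy on phantoms:
±0.5 px on widths of 20–100 px including 30° rotation and occlusion, rapid
deformation within ±2 points over 5–50% amplitudes.

## PIV

Preprocessing (for binarized real-data workflows): optional inversion so
particles are bright, stripe suppression by zeroing the zero-vertical-
frequency line of the 2-D spectrum excluding DC (the locus of image content
constant along the vertical axis, i.e. purely vertical stripes — the chosen
reading of "removing the real axis in the frequency domain"), Gaussian
smoothing (σ = 1 px), histogram equalization, a circular maximum filter of
radius 2, and Niblack thresholding (window 25 px, k = −0.2; the method is
named in this workflow without parameters, so these are standard defaults).

Velocimetry: three passes with 64/32/16 px windows at 50% overlap. Each
window pair is mean-subtracted and cross-correlated via FFT (full linear
correlation); the triangular overlap weighting is divided out before the
peak search — without this the peak is biased toward zero lag by ≈
σ²_corr/(W−|d|), which is exactly the few-percent underestimation a naive
implementation shows — and lags beyond half a window are masked. The peak
is refined with a 3-point Gaussian fit (parabolic fallback when a neighbour
is non-positive). Cells fail validation when textureless, when the NCC
coefficient at the peak is < 0.2, or by a normalized-median outlier test
against the 3×3 neighbourhood (threshold 2.0, ε = 0.1 px); later passes
interpolate a median-filled copy of the previous field as their window
offset, but reported fields keep invalid cells masked. Measured accuracy:
uniform shifts in [−6, 6] px recovered to ~0.02 px RMS on speckle phantoms.

Sequence analysis: frames whose global mean absolute difference from the
previous frame exceeds 5× the median pre-onset inter-frame difference are
excluded (bubble-appearance motion); frame skipping divides displacements
by the (1 + skip) frame interval spanned. The signed along-vessel velocity
projects each field's valid-cell mean onto the pre-onset flow direction
(or an explicit axis); a reversal is a sign flip beyond 0.05 mm/s,
transient if the original direction recovers within the sequence. An
optional ROI mask (from phantom ground truth) keeps static background
windows out of spatial means.

## Synthetic data: what it emulates, what it does not

The RF generator reproduces the *structure* of a recording — pre/pulse/post
segments, constant-amplitude spectral components with uniform-random phases
(no phase information exists to emulate), a band-limited (0.3–10 MHz)
Gaussian broadband burst whose amplitude decays exponentially with a 0.5 ms
time constant (a single-parameter model of "decays to noise within
0.5 ms"), and a stationary Gaussian noise floor. Component amplitudes are
free parameters: the source figures are display-only, so defaults are
merely graded plausibly (dominant drive, weaker harmonics and sub/ultra-
harmonics). No bubble physics (Rayleigh–Plesset/Marmottant), no transducer
field, no receiver transfer function: passing spectral tests shows the
*quantification* is correct, not that real cavitation spectra look like
this.

The frame phantom is an additive intensity model: a dark anti-aliased
vessel band along a polyline (half-intensity point exactly at the wall
radius, so gradient tracing is unbiased), speckle blobs advected along the
centerline in arc-length coordinates (wrapping at the ends, so particle
count is conserved under uniform flow) with transverse positions scaled to
the instantaneous diameter, a dark-rimmed bubble disc from its appearance
time, optional vertical stripes, Gaussian PSF blur, and optional Gaussian
noise. It has no shear in the velocity profile (the profile is spatially
uniform per frame), no out-of-plane motion, no illumination gradients, and
no real RBC contrast statistics. Event-table defaults are calibrated to the
packaged counts so default simulations statistically resemble the observed
incidences; that is a calibration of the *generator*, not evidence about
the estimators.

## Problem sizes and tolerances in the test suite

Spectral tests run at 25 MHz sampling with shortened pre/post segments
(5 ms pre, 5 ms pulse where the sliding analysis needs it) — all components
lie below 3.8 MHz, so any rate > 2× that is equivalent for band arithmetic
and the full 125 MHz default remains the I/O and CLI default. Calibration
tests use 10,000 t-test replicates, 150 permutation replicates × 999
permutations, and event recovery at 100/1,000/10,000 vessels with CI
coverage over 100 replicates (a single 95% CI draw fails 5% of the time by
construction, so coverage is the meaningful statement). Phantoms are
96–160 px; PIV accuracy uses 12–20 seeded speckle pairs. Key asserted
tolerances: Parseval 1%, tone-in-band recovery 5% (rectangular-window
sidelobe leakage), deformation ±2 points, PIV 0.2 px RMS, stripe
suppression ≥ 20 dB, IC spectrogram drop > 10 dB.

## Known limitations

- Event labels are inputs; there is no automated event detection from
  video.
- The PIV implementation is a faithful multipass NCC scheme, not a
  bit-exact replica of any interactive PIV package; window deformation
  (shear within a window) is not modelled.
- Sub-10 µm vessels, jetting, and bubble radial dynamics are outside scope
  — they are unresolvable at the emulated frame rates.
- Absolute pressure calibration of emissions and receiver deconvolution
  are not implemented; all band powers are relative (noise-normalized).
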