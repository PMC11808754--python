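# Methods

## Line-scan model

An acquisition is a 1D sequence of pixels along a single raster line.
Distances are physical positions in µm, 0-based, measured at the pixel
start; pixel i sits at i × pixel_size. Spot intervals
[center − width/2, center + width/2) are closed on the left and open on the
right so that spot/gap partitions of the pixel axis never overlap and
integrals are exactly additive. The transverse pixel dimension (1000 µm on
the instrument this models) has no effect in a 1D model and is not carried.

The default geometry is an 11-spot array of 3 mm spots spanning 50 mm
edge-to-edge, centered on a 55 mm scan sampled at 50 µm pixels
(1100 pixels). `default_layout` places n equally pitched spots whose outer
edges touch the requested span.

## Simulator

The simulator deposits each analyte inside its declared spots with one of
three intra-spot density profiles over the normalized coordinate
u ∈ [−1, 1]:

- **ring** — symmetric truncated-Gaussian pair at |u| = 0.85, σ = 0.1
  (coffee-ring solute enrichment at the droplet perimeter, typical of
  peptides);
- **center** — truncated Gaussian at u = 0, σ = 0.35 (center-concentrated
  carbohydrates);
- **uniform** — constant (evenly spread exogenous compounds).

Each profile is normalized to integrate to 1 over [−1, 1]; returned values
are densities and exceed 1 at profile maxima. The per-pixel deposit is
base_intensity × density(u) × signal_factor, so the total deposited
intensity per spot is conserved across profiles up to grid discretization.

**Rate response.** signal_factor(r) = (reference_rate / r)^signal_exponent
with exponent 1 by default — the dwell-time proportionality
pixel_size / r. The delocalization factor is 1 at the slowest rate
(reference_rate, 50 µm/s), falls linearly by delocalization_drop (0.60) to
the knee (125 µm/s), and is constant beyond it. Delocalized signal is
spread **uniformly** over all pixels outside sample-role spots (gaps,
solvent blanks, media blanks) at delocalization_level (0.05) of the
analyte's per-pixel base amplitude; whether carryover is directional is not
observable in the data this emulates, and the uniform choice is the
simplest model consistent with background appearing in blank spots. Setting
delocalization_level = 0 disables the background entirely (used by the
localization tests).

**Noise** is additive Gaussian (mean baseline_level = 5 counts,
sd = 2 counts against a default base intensity of 1000) applied to every
species channel at every pixel and clipped at zero. One generator seeded
per run draws in pixel order, so runs are bit-reproducible. Every species
carries its first three theoretical isotopologues; the lock-mass species is
present at every pixel.

What the simulator does **not** emulate: chemical background other than the
panel species, profile-mode peak shapes, detector saturation, spray
instability beyond what spatial normalization corrects, ion suppression
between analytes, and directional carryover. Passing tests therefore
demonstrate the correctness of the processing arithmetic under the stated
model, not robustness to every artifact of real spectra.

## Rate optimization

The sweep simulates one run per rate (default grid 50–225 µm/s in 25 µm/s
steps — eight rates spanning the printed 3.70–16.67 min acquisition window
over 50 mm), extracts the summed monoisotopic XIC of the fatty-acid panel,
and computes the signal ratio per sample spot: per-pixel mean inside the
spot over per-pixel mean in the reference region. Per-pixel means (not raw
sums) make unequal region lengths comparable. Two reference definitions are
supported — solvent-blank spot intervals (default, the operational
blank-spot comparison) and inter-spot gaps — because the delocalized
background can be read either way; both give the same optimum under the
default model. A floor of 10⁻⁹ × trace maximum guards empty denominators.

The expected ratio has the closed form

    R(r) = (s(r)·w̄·T + C·b) / (s(r)·d(r)·L·T + C·b)

with s the signal factor, d the delocalization factor, w̄ ≈ 0.5 the mean
in-spot density, T the summed base intensity, L the delocalization level,
b the noise mean and C the channel count. Below the knee the denominator's
decline outpaces the numerator's 1/r decay and R rises; past the knee d is
constant, the background approaches the noise floor and R falls — an
interior maximum at the knee. `closed_form_ratio` evaluates this directly
and the test suite requires the stochastic sweep to agree with it within
5%; with delocalization_drop = 0 the closed form is strictly decreasing and
the sweep must select the slowest rate. Ties in the argmax break toward the
faster rate, since throughput is the point of the exercise.

## Lock mass and normalization

The lock-mass reference m/z is computed from the leucine enkephalin formula
C28H37N5O7 for the run's polarity, never hard-coded. Correction is a single
multiplicative factor per pixel (adequate for ≤ 20 ppm drifts; no
polynomial recalibration), anchored on the most intense peak within the
search window; pixels without a lock peak (allowed up to 10% of the run)
inherit the nearest anchored pixel's factor by interpolation. Planted
linear distortions up to 20 ppm are recovered to ≤ 0.5 ppm residual on
noiseless runs (≤ 0.1 ppm at 10 ppm).

Spatial normalization divides per-pixel intensities by lock/mean(lock)
after smoothing the lock trace with a 5-pixel moving median (guarding
single-pixel dropouts), preserving overall scale and leaving spot-to-spot
ratios unchanged when the lock channel is constant. Normalization is per
pixel; per-spot normalization can be had by normalizing integrated tables
instead.

## Quantification and tables

Media-blank subtraction removes the blank row's value from every feature
column, flooring at zero and retaining the flagged blank row.
Analyte-by-analyte normalization scales each feature column to its own
maximum. %CV is the sample (n−1) standard deviation over the mean, × 100.
Replicate reproducibility is assessed on **raw** integrated tables: blank
subtraction drives near-zero channels whose %CV is unbounded and
uninformative, and the reproducibility claim concerns measured signals.

## Annotation

Monoisotopic masses come from formula parsing against isotope tables
(pyteomics); adduct m/z arithmetic includes the electron mass (sub-ppm, but
within the 5 ppm regime). Isotopic envelopes are aggregated by neutron
count via per-element convolution with binary exponentiation, each peak
carrying its abundance-weighted mean mass, max-normalized. The envelope of
an adduct ion neglects the isotope contribution of the adduct atoms
themselves (one H or Na; < 0.1% on relative abundances).

The similarity metric behind the "80% envelope similarity" criterion is not
pinned down by the workflow this implements; cosine similarity over the
first three matched isotopologues is used for its scale invariance, with
the threshold at 0.80. Fewer than two matched positions yields similarity
0 (no shape information). Hits are ranked by similarity, then |ppm|.
Bundled panels (fatty acids, peptide hormones, maltose series, exogenous
compounds) are formula lists; all values are computed at import.

## Statistics

Feature detection pools all peaks, clusters m/z by single-linkage with a
10 ppm gap rule, and keeps the top 500 features by total integrated
intensity across sample spots ("most abundant" = total integral, not max
pixel; configurable). The hypothesis test behind the volcano is Welch's
two-sample t-test on log₂(intensity + ε), ε = 10⁻⁶ of the table maximum;
fold changes are ratios of group means on blank-subtracted,
pre-normalization intensities. No multiple-testing correction is applied
by default, matching the raw p ≤ 0.05 / |FC| ≥ 2 convention;
Benjamini–Hochberg is available by flag. PCA is mean-centered (optionally
unit-variance) via scikit-learn.

## Problem sizes and determinism

Simulated validation runs use the full 1100-pixel, 11-spot geometry; sweep
validation covers eight rates × six replicates; oracle-equivalence tests
run 1000 random instances; planted-truth statistics use 500-feature tables
at 3-vs-3 replicates. These sizes exercise every code path at the scale the
workflow targets while keeping the suite fast. All randomness flows
through explicit seeds; identical seeds give bit-identical runs, tables and
sweeps.

## Known limitations

- Continuous (profile-mode) spectra are handled by local-maximum window
  picking only; no centroiding algorithm.
- The simulator's delocalization is spatially uniform; real carryover is
  plausibly directional.
- Annotation is mass + envelope only — isomers are indistinguishable
  without fragmentation data.
- Absolute quantitation is out of scope; titers are relative.
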