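# Methods

## The analysis chain and its assumptions

`otoraman` treats a study as a collection of per-site Raman spectra on a
shared, calibrated wavenumber axis, each site belonging to a specimen
and carrying a gross (otoscopic) label: *cholesteatoma* or
*myringosclerosis*. The chain assumes:

- the axis is strictly ascending, wavenumber-calibrated, and corrected
  for system response upstream (instrument-side);
- intensities are detector counts, shot-noise limited, with occasional
  1–2 channel cosmic-ray transients;
- the broad tissue autofluorescence background is present and is *not*
  removed at any stage — baseline subtraction risks introducing
  artifacts, so the multivariate models see raw (despiked) counts and
  early principal components are expected to be baseline-dominated;
- mineralization is spatially heterogeneous within myringosclerosis
  tissue, so class membership is decided per site, not per specimen.

## Cosmic-ray despiking

A Hampel filter: each channel is compared to the median of its
7-channel window; the deviation is scored against 1.4826 × the windowed
MAD and channels exceeding robust-z 8 are replaced by the local median.
Two numerical choices matter:

- **MAD floor.** A 7-sample MAD is erratic enough that ordinary shot
  noise would be flagged at z = 8 every few hundred channels; the local
  scale is therefore floored at the spectrum-wide median absolute
  residual against the running median. Both quantities are medians, so
  genuine spikes do not inflate them.
- **Fixed-point iteration.** The filter is reapplied until a pass
  replaces nothing (≤ 10 passes). A converged spectrum is a fixed point,
  making `despike` exactly idempotent and catching the flank channel of
  two-channel events once the taller neighbor is gone.

Replacing more than 2% of channels (configurable) raises a data-quality
error instead of silently rewriting the spectrum.

## Mineralization screen

Myringosclerosis sites are called *mineralized* when a significant peak
exists inside the 20 cm⁻¹ band centered at 960 cm⁻¹ (the apatite ν₁(PO₄)
mode). The statistic is the height of the tallest in-band local maximum
above a linear chord spanning the band, divided by a robust noise scale;
the default threshold is 5. Cholesteatoma sites pass through unscreened.

Detector details, each chosen for variance control:

- chord endpoints are means of up to 3 channels per side (a single
  noisy endpoint channel shifts the whole chord and dominates the
  false-call rate);
- the chord residual is smoothed by a 3-channel moving average and the
  noise scaled by 1/√3 — a crude matched filter, since real bands span
  several channels while shot noise is white and cosmic-ray stubs are
  1–2 channels wide;
- the noise scale comes from first differences in a signal-free flank
  window (default 1750–1800 cm⁻¹), MAD-scaled and divided by √2, and is
  floored at the Poisson limit √(median counts): a photon-counting
  channel is never quieter than shot noise, so even idealized noise-free
  input faces a meaningful threshold;
- equal in-band maxima resolve toward the band center.

Because both numerator and denominator scale linearly with the spectrum
(whenever empirical noise is at or above the shot floor), the decision
is invariant to multiplying a spectrum by a positive constant; raising
the threshold can only remove calls (monotone screen).

## PCA

Centered, unscaled PCA via SVD; 7 components by default, fit pooled for
the RadViz embedding and per class for marker inspection. Loading signs
follow the largest-magnitude-element-positive convention so fits are
bit-reproducible. Since the baseline stays in the data, marker bands
(960/1044 cm⁻¹ for mineralized plaques; 1005/1447/1654 cm⁻¹ for
cholesteatoma) are searched across all seven |loading| curves, not only
PC1.

## RadViz

Selected PCs become equally spaced unit-circle anchors (first anchor at
90°); per-dimension scores are min-max standardized to [0, 1] and each
site maps to the standardized-score-weighted mean of anchor positions.
Conventions: an all-zero standardized row (a 0/0 in the formula) maps to
the origin; a zero-range dimension maps to constant 0 with a warning.
Anchor PCs are chosen by a one-way variance-ratio statistic
(between-class variance of scores over within-class variance), top-k
with ties broken by ascending PC index, order preserved by index — an
objective stand-in for a manual "selectively chosen" set, overridable by
an explicit list.

## PLS-DA

PLS2 components are extracted by the NIPALS recursion on centered
spectra and centered one-hot class responses: alternating
weight/score/loading updates to convergence (relative tolerance 1e-10,
≤ 500 inner iterations), then rank-one deflation of both blocks.
X-score vectors are mutually orthogonal by construction; the fitted map
is condensed to B = W(PᵀW)⁻¹Qᵀ. Prediction is argmax of the continuous
responses, ties resolving to the earlier class in sorted order.

The latent-variable count is free: by default it is selected by 5-fold
cross-validated accuracy over 1–10 on the first training split of an
evaluation and then reused across iterations (re-selecting per iteration
would multiply runtime for no observed change in rates); any fixed count
can be passed instead, and the shipped pipeline defaults use 3.

## Resampled evaluation and negative control

Each of 100 iterations: (i) every class is downsampled at site
granularity to the smallest class's site count (fresh each iteration,
which debiases the rate estimates relative to balancing once);
(ii) sites split 60/40 per class into train/test — never the same site
on both sides, audited programmatically; (iii) PLS-DA fit on train
spectra, test spectra predicted; (iv) per-class correct rates are
computed per iteration and averaged. Binary tasks additionally report
PPV/NPV/sensitivity/specificity/overall accuracy from the summed
confusion matrix (zero-denominator ratios are NaN and flagged, never 0)
and a ROC curve pooled over all test-set scores, swept over unique
thresholds with tied scores grouped, endpoints (0,0)/(1,1) included, and
trapezoid AUC.

The negative control permutes class labels across sites each iteration
(class sizes preserved, a separate RNG stream so the split sequence is
identical to the true evaluation) and reruns the same pipeline; for c
balanced classes the mean overall rate must collapse to ~1/c. A debug
hook forcing the identity permutation reproduces the true evaluation
exactly.

All evaluation randomness derives from one plan seed; the pipeline
derives per-stage seeds as SHA-256("{seed}:{stage}") mod 2³¹ so any
stage replays in isolation and end-to-end reruns are byte-identical.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not any particular instrument. Per phenotype it renders baseline + band
profiles on a 600–1800 cm⁻¹ axis at 2 cm⁻¹ (Lorentzian for sharp
ring/mineral modes, fwhm 7–18 cm⁻¹; Gaussian, broader, for the amide-I
envelope), with amplitudes in a versioned band table
(`band_tables.yaml`, v2):

- **cholesteatoma** — keratin/collagen set 956, 1005, 1032, 1128, 1447,
  1654, 1680 cm⁻¹;
- **mineralized myringosclerosis** — 748, 948, 960, 1044 cm⁻¹ plus weak
  1447/1654. A single substitution scalar d ∈ [0, 1] (default 0.7)
  models carbonate/silicate substitution of the apatite lattice:
  fwhm(960) = f₀(1 + 0.8 d), amplitude(1044) = a₁₀₄₄ d,
  amplitude(948) = a₉₄₈(1 − d), so d = 0 is the pure-apatite limit with
  a resolved 948/960 doublet and no 1044 feature, and the 1044/960
  height ratio grows monotonically with d;
- **non-mineralized myringosclerosis** — the cholesteatoma protein set
  at 70% amplitude (the 956 cm⁻¹ CH₂ rock stays keratin-specific) plus
  faint 960/1048 traces at 5% of the mineralized amplitudes, modelling
  biochemically altered lesion margins.

All three classes share one autofluorescence baseline polynomial
(order 3 in the normalized axis coordinate, scale 800 counts):
autofluorescence varies specimen to specimen but is not a class marker,
so class information lives in the bands alone.

Heterogeneity has two log-normal components, each with between-specimen
sd above the within-specimen (site) sd: a *band-amplitude* factor g
(sd 0.35 / 0.12) scaling bands relative to baseline, and an overall
*intensity* multiplier m (sd 0.15 / 0.05) scaling the whole spectrum.
A noise-free spectrum is exactly (baseline + g·bands)·m, both factors
recorded per spectrum. The band-amplitude sd is set roughly equal to
the 30% amplitude gap between the two protein phenotypes, which is what
makes those classes genuinely confusable — mirroring the published
regime where the mineralized class classifies far better than either
protein class — while the phosphate markers keep the mineralized class
distinct. Shot noise is Poisson on total counts; cosmic rays are planted
per spectrum with Poisson(rate 1) events, 1–2 channels wide, 500–3000
counts, all recorded in metadata. The default cohort is 8 specimens ×
10 sites per class (240 spectra) — sized for stable resampling
statistics, not to mimic the (unstated) clinical per-class counts.

What the generator does **not** model: instrument response and
wavelength-dependent throughput, fluorophore photobleaching kinetics,
spatial correlation between neighboring sites, non-Poisson detector
noise (read noise, etaloning), and any real biochemical covariance
between bands. Passing tests therefore demonstrate that the chain
recovers structure *of the kind assumed*, at realistic counting noise —
not clinical performance.

## Degenerate inputs and tie rules

- Descending input axes are reversed (flagged); non-monotonic axes are
  errors. Axes differing by < ½ channel step are interpolated onto the
  common grid (flagged); more, an error.
- A despike pass altering > 2% of channels raises rather than rewrites.
- Screen ties (equal maxima) resolve toward the band center; PLS-DA
  argmax ties resolve to the earlier class; anchor-selection ties
  resolve to the lower PC index.
- Classes need ≥ 2 sites for resampling and > n_components spectra for
  per-class PCA; violations raise with the class named.

## Known limitations

- The despiking and detection thresholds are literature-typical
  defaults, not tuned to any instrument; both are exposed in config.
- The screen detects, it does not quantify: no 948/960 deconvolution or
  substitution-degree estimation from data.
- Balanced per-iteration downsampling discards data in unbalanced
  cohorts; rates are averages over iterations, so they are not the rates
  of any single fitted model.
- RadViz is a visualization aid; distances in the disk are not metric
  and depend on anchor order, which is not optimized.
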