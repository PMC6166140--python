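# Methods

## The measurement problem

Regulated exocytosis of Weibel–Palade bodies releases VWF onto the
endothelial surface. When anti-VWF antibody is present in the medium it
captures the released protein in place, so each fusion event becomes a
fixed fluorescent patch ("exocytic site"). Events that recruited the
contractile actomyosin ring expel more cargo and leave larger patches;
the fraction of sites larger than 2 µm² therefore proxies the
ring-recruitment probability of a secretagogue. The pipeline segments
those patches in 96-well confocal screens (nine fields of view per
well, eight wells per condition is the reference geometry; a full
864-field dataset holds roughly 10 000 cells) and reduces them to
per-well statistics.

## Segmentation

Stages, applied to the VWF channel:

1. **Gaussian denoising**, σ = 1 px by default (reflect boundary).
   The blur is part of the detection operator; all downstream stages see
   the smoothed image, while intensities reported per site come from
   the raw channel.
2. **Moment-preserving (Tsai) threshold.** The 256-bin histogram over
   the image's min–max range is replaced by the bilevel distribution
   (p₀ at z₀, 1−p₀ at z₁) that preserves the first three gray-level
   moments; the threshold is the smallest gray level whose cumulative
   fraction reaches p₀, and foreground is strictly greater than the
   threshold (this makes the two-level worked example exact). Constant
   images and single-bin histograms raise a degenerate-input error.
   *Applicability envelope*: the method locates the threshold from
   histogram shape, so it requires the foreground tail to carry
   non-negligible moment leverage — roughly f·a² ≳ 1 for foreground
   pixel fraction f and amplitude a in units of the background noise
   sd. Antibody-stained sites on a confocal plate reader easily satisfy
   this (signal-to-background ≈ 10, peak-to-noise ≈ 100); on
   near-empty or extremely dim images the bilevel solution collapses
   into the background mode. A guard treats any field whose mask would
   exceed 25 % foreground as signal-free (logged), which converts that
   failure mode into an empty site table instead of thousands of noise
   objects.
3. **Marker-based watershed.** Markers are local maxima of the
   Euclidean distance transform of the mask (minimum separation 2 px;
   connected plateau maxima merged into one marker). The EDT is
   smoothed with a σ = 1 px Gaussian before peak detection because
   rasterised objects carry near-plateau maxima broken by sub-0.1-px
   dips that would otherwise over-split (measured: 18/100 failures on
   overlapping-disc pairs without smoothing, 0/100 with). Flooding the
   negated (smoothed) EDT within the mask assigns every foreground
   pixel exactly one 8-connected label.
4. **Resolution-limit filter.** The minimum credible object area is a
   disc at the Rayleigh diameter d = 0.61 λ/NA: cutoff = π(d/2)²
   (0.2195 µm² at NA 0.6, λ = 0.52 µm, the 40× air lens configuration).
   Objects strictly below the cutoff are removed ("beneath" read as
   strict); survivors are relabelled contiguously.
5. **Morphometrics** per label: area (px count × pixel size²),
   equivalent diameter, perimeter, 0-based centroid, fitted-ellipse
   eccentricity, mean and integrated raw intensity. Area is the
   scientifically loaded field; the rest of the record set is our
   choice of standard region properties.

**Nuclei counting** reuses the same pipeline on the nuclear channel
with a 20 µm² minimum object area (a HUVEC nucleus is ~50–200 µm²);
degenerate channels count zero with a warning rather than erroring, so
blank wells do not abort a plate. Sites per cell divides well-summed
site counts by well-summed nuclei counts.

**Validation** against annotated centres uses greedy one-to-one
matching by increasing centroid distance, with per-site acceptance
radius 2·√(area/π) (or a fixed radius if configured); precision =
matched/detected, recall = matched/annotated, undefined ratios are
reported missing.

## Statistics

The statistical unit is the well: counts are summed over a well's
fields before ratios, areas are pooled within the well, and conditions
are summarised as mean ± SEM (sample sd, n−1) over wells. "Large" is
strictly greater than 2 µm²; a site of exactly 2 µm² is not large.
Wells with zero sites have no defined large-site proportion and are
excluded from condition means with a logged count. Area distributions
are compared with the two-sample KS statistic evaluated at all pooled
sample points (ties exact); the p-value uses the asymptotic Kolmogorov
distribution at effective size nm/(n+m) and is approximate for small
samples. Drug effects are reported as the ratio of mean large-site
proportions (treated/control) with first-order propagation of both
SEMs — whether control uncertainty should propagate was an open choice;
we propagate it. Fixation time-courses report per-timepoint mean ± SEM
of per-well site counts; single-well timepoints report SEM 0 and are
flagged by n = 1.

## String lengths

Strings arrive as binary masks or polylines. Masks are skeletonised per
8-connected component; a simple open skeleton is walked end-to-end and
measured as a chord-subsampled polyline (every 4th pixel) plus 0.5 px
per end — the medial axis of a round-capped ribbon ends at the cap
centres, so only pixel-centre discretisation is lost at the tips.
Chord subsampling replaces the classical (1, √2) chain-code weighting,
which overestimates smooth curves by up to ~8 % at intermediate
orientations; the chain-code sum remains as the fallback for branched
or closed skeletons. Measured accuracy on rendered generator strings:
worst case 3.7 % over 120 strings, ~1 % on straight segments at 0°,
22.5° and 45°. Components shorter than 2 px are discarded. Per-image
percentages use bins [0, 25), [25, 50], (50, ∞) µm — the middle bin is
closed on both ends ("between 25 and 50" read inclusively) — and are
summarised as mean ± SEM across images.

## Fusion-event kinetics

Events carry a time on the 5-s frame grid of a 600-s movie and a
ring-positive flag. Frequencies are binned at 50 s by default (the
0–50 s / 50–200 s phrasing of the underlying observations); events
outside [0, 600] s are rejected with a logged count. The percentage
positive is reported overall, per window (closed interval), and per
bin (missing for empty bins); a logistic recruitment curve
p(t) = p₀ + (p₁−p₀)/(1+exp(−(t−t₁/₂)/τ)) is fitted to per-bin
fractions weighted by event counts.

## Synthetic data generator

The generator emulates the screen's acquisition: 688×512 px fields at
0.3 µm/px (~206×154 µm, plausible for a 40× air lens; the true pixel
size was not recorded, so this is a declared default), nuclei as
discs of radius 4 µm, cells per field Poisson with mean 10 000/864 ≈
11.57, sites Poisson(rate × cells) placed uniformly within 10 µm of a
parent nucleus, site areas from a two-mode log-normal mixture. Default
modes (log-mean, log-sd): small (ln 0.8, 0.3), large (ln 4.5, 0.25),
chosen so the small mode is ≤ 2 µm² and the large mode > 2 µm² each
with probability ≥ 0.99 — enforced at construction, so the ground-truth
large-site fraction equals the mixture weight to binomial error. The
large-mode weight is a generator parameter standing in for ring
recruitment (≈0.15 histamine, ≈0.40 histamine/adrenalin/IBMX, ≈0.65
PMA); it is not a mechanistic model of actomyosin contraction.

Sites are rendered as elliptical blobs with a Gaussian intensity
profile truncated at half maximum, so the deposited footprint is an
ellipse of exactly the drawn area (the conventional FWHM definition of
spot area). A pure untruncated Gaussian has no intrinsic footprint and
makes measured area a strong function of threshold placement
(× ln(peak/T)/ln 2); truncation keeps the interior profile smooth and
peaked at the ground-truth centre pixel while making area recovery
robust to exactly where the global threshold lands in the
background–signal gap. Default amplitudes: sites 2000 counts, nuclei
1200, over a 200-count background with an optional smooth gradient
(30 counts), Poisson shot noise and Gaussian read noise (sd 10),
clipped and rounded to 16-bit. With the noise model zeroed the render
is exactly reproducible and noiseless.

Time-courses draw each field's plateau complement of sites once and
give every site an activation time — Exponential(τ) for
histamine-like "fast_saturating" kinetics (complete by ~10 min for
τ = 3 min), Uniform(0, 20 min) for PMA-like "linear" release — so
counts are cumulative and sites persist across timepoints, emulating
parallel wells fixed at increasing times. Fusion events are Poisson on
the frame grid with a user rate function; ring flags are Bernoulli
with constant or logistic (monotone non-decreasing) probability.
Strings are random-walk polylines (2 µm steps, Gaussian heading
increments, sd 0.12 rad) whose summed segment length equals the drawn
target exactly, rasterised and dilated by 1 px on separate canvases.

Determinism: every field's RNG is seeded by SeedSequence(master seed,
CRC-32 of the well id, field index), so identical seeds give
bit-identical images, ground truth and event tables, independently of
generation order.

What the generator does **not** emulate: cell shape and membrane
boundaries (site placement is a disc around the nucleus), 3-D stacks,
photobleaching, illumination-field structure beyond a linear ramp,
spatial correlation between sites, or flow-chamber physics for
strings. A green recovery test therefore establishes correctness of
the algorithms on images matching the stated acquisition model, not
robustness to every real-microscope artefact.

## Numerical choices and limitations

- Histograms for thresholding: 256 equal-width bins over min–max;
  thresholds are reported as bin centres; tie-break is the smallest
  gray level reaching p₀.
- Moment-system degeneracy (constant image, < 2 occupied bins,
  non-positive variance) raises a typed error; the field-level driver
  converts it to an empty site table for the VWF channel and a zero
  count for nuclei.
- Watershed connectivity is 8-connected throughout; objects touching
  the field edge are kept.
- Detection requires site contrast well above the noise floor (see the
  applicability envelope above): at signal-to-background 5 with
  realistic noise the measured plate-level F1 is ≥ 0.9 and count bias
  within 10 %, but at peak-to-noise-sd ratios near 5 the
  moment-preserving threshold fails by construction — this is a
  property of the algorithm family, not of the implementation.
- Segmentation slightly inflates the large-site proportion (merging of
  nearby small sites, blur at edges; typically +0.03–0.05 at default
  density), which stays within binomial error at per-condition sample
  sizes used in the tests.
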