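# Methods

## Imaging model

Brightfield H-DAB immunohistochemistry is modelled with the Beer–Lambert
law: stain amounts add linearly in optical density,
OD_c = −log₁₀(I_c / I₀) with I₀ = 255 per 8-bit channel. Intensities are
floored at 1 before the log, bounding the OD at log₁₀ 255 ≈ 2.407 and
keeping the transform deterministic on saturated pixels. A pixel's OD
vector is decomposed as c_H·**v**_H + c_D·**v**_D + c_R·**v**_R, where
**v**_H, **v**_D are unit reference vectors for haematoxylin and DAB
(Ruifrok–Johnston values by default, configurable under `stains:` in the
YAML config) and **v**_R = **v**_H × **v**_D completes the basis when no
residual vector is supplied. The 3×3 system is solved exactly per pixel;
negative concentrations, which arise only from noise or off-model colours,
are clamped to 0 so the channels satisfy the physical nonnegativity
invariant. No stain-vector estimation (Macenko/Vahadane) or cross-slide
normalisation is attempted; images already split into H/DAB channels are
accepted as-is.

## Segmentation

Nuclei are segmented from the haematoxylin OD channel alone:

* **Threshold.** Otsu on a 256-bin histogram of the channel by default, or
  a fixed OD cut. Foreground is *strictly* greater than the threshold, so
  a constant channel yields an empty mask. Published systems of this kind
  tune their thresholds by hand; every parameter here is exposed in config
  with the defaults below.
* **Distance transform.** Exact Euclidean distance of each foreground
  pixel to its nearest background pixel (centre-to-centre, pixel units),
  divided by the per-ROI maximum so that peak height becomes a relative
  quantity in [0, 1]. Degenerate inputs are defined explicitly: an
  all-background mask maps to all zeros, an all-foreground mask to all
  ones. The implementation is verified in tests against a brute-force
  O(N²) nearest-zero search.
* **Seeds.** Regional maxima of the normalised map (8-connected by
  default), one representative per equal-valued plateau (topmost, then
  leftmost pixel — an arbitrary but fixed rule that makes seeding
  deterministic), filtered at `min_height` (default 0.1) and thinned by
  greedy non-maximum suppression in decreasing-value order with pairwise
  separation ≥ `min_distance` (default 3 µm converted via mpp, i.e. below
  the smallest expected nucleus radius).
* **Watershed.** Flooding of the negated distance map from the seeds,
  restricted to the mask. Each seed produces exactly one label; foreground
  components that received no seed (possible when `min_height` filters
  their maxima) remain background.
* **Size gate.** Instances outside [`min_area_um2`, `max_area_um2`]
  (default 10–400 µm², spanning typical nuclear cross-sections) are
  removed and the survivors renumbered contiguously. This gate is what
  suppresses sub-nuclear debris specks — the dominant false-positive mode
  of intensity-based scorers — and oversized clumps.

An elliptical nucleus has a single regional maximum of its distance
transform at the centre (values decrease monotonically along the medial
axis toward the poles), so well-separated elliptical nuclei are neither
split nor merged under the defaults; strongly concave or dumbbell-shaped
objects are split at the ridge, which is the intended behaviour for
touching nuclei.

## Classification and scoring

A nucleus is positive iff its mean DAB OD over the instance mask is ≥
`dab_threshold` (default 0.15 OD; a median statistic is available). The
default operationalises "staining of any intensity is positive" while
tolerating deconvolution bleed-through; at threshold 0 every nucleus is
positive. Raising the threshold can only reduce the positive count
(tested as a monotonicity property).

ROI membership is by centroid: a nucleus belongs to an ROI iff the pixel
covering its centroid is inside the rasterised polygon (pixel centre
(c+0.5, r+0.5), boundary-inclusive). This makes counts deterministic and
prevents double counting across adjacent ROIs; whether border-straddling
nuclei should instead count fractionally is a genuinely open convention.
PI = 100·n_pos/n_total at full precision internally, displayed at 0.1 pp.
An ROI with no nuclei is flagged `no_cells_in_roi` with an undefined PI —
0 % is a real biological value and must not be conflated with "nothing
found". Physical areas use the shoelace polygon area × mpp² × 10⁻⁶, with a
warning (not an error) outside the 0.0203–3.1473 mm² range typical of
clinical ROIs.

## Concordance statistics

Discordance between two readers over the same ROIs is
RMSE = √(mean (a−b)²); study-level discordance is the arithmetic mean of
the upper-triangle pairwise RMSEs, and the improvement between study
rounds is 100·(pre−post)/pre percent. Bland–Altman agreement reports the
mean paired difference and the limits of agreement mean ± 1.96·SD of the
differences — the interval expected to contain ≈95 % of differences. Some
reports call this interval a "95 % confidence interval"; the formula
implemented is the limits-of-agreement one, and the SD uses the n−1
denominator by default (`ddof=0` switches to the population SD).
Agreement with the automated scorer is the percentage of ROIs whose
automated score a reader accepted. Absolute manual-vs-assisted errors are
binned into half-open 10-point brackets [0,10), …, [80,90), with the last
bracket [90,100] closed. Display precision follows reporting convention —
RMSE to 2 decimals, rates and reductions to 1 — while full precision is
kept internally.

## Synthetic data

`simulate_roi_image` renders nuclei as ellipses (semi-major axis uniform
on 3–5 µm, axis ratio 0.8–1.0, random orientation) with centres
rejection-sampled at ≥ 11 µm pairwise separation on a white background at
0.5 µm/px. Every nucleus carries haematoxylin OD 0.7; positives
additionally carry DAB OD 0.6. The number of positives is exact-count
(round(fraction × n), randomly placed), so the true PI has no sampling
error. OD maps are composed to RGB through the same Beer–Lambert model the
deconvolution inverts, Gaussian pixel noise (SD 3 intensity units) is
added and the result clipped to uint8. Optional sub-nuclear DAB-coloured
debris specks and a `pleomorphic_fraction` of double-size nuclei exercise
the two failure modes intensity-based scorers are known for. Everything is
deterministic for a fixed seed.

What the generator does *not* emulate: tissue texture and stromal
background, stain intensity variation within and across slides, scanner
noise statistics, overlapping/touching nuclei, and tumour-vs-normal
discrimination. Passing recovery tests on these fields therefore
demonstrates the correctness of the algorithmic chain under its own
imaging model, not clinical-grade accuracy on real slides.

`simulate_study` draws a slides × ROIs grid with per-ROI true PIs from a
mixture — 70 % uniform on 0–10 %, 30 % uniform on 10–100 % — reflecting
that most clinical ROIs score low; the mixture is configurable.
`simulate_reader_scores` models visual scoring as
clamp(round(anchor + bias + N(0, σ²))): unassisted readers are anchored to
the truth with large σ, AI-assisted readers to the automated score with
small σ, reproducing the two-round (washout) study design. The default
rounding interval for general use is 5 pp, the stricter end of typical
5–10 % visual scoring intervals.

`two_round_reader_panel` encodes the canonical concordance experiment:
three round-1 readers with σ = 10 pp and biases (+5, −5, 0) pp — pairwise
mean differences of about +10, +5 and −5 pp, the magnitudes typical of
unassisted Ki-67 scoring — and three round-2 readers with σ = 1.8 pp
anchored to the automated score, bias 0. In this experiment interval
rounding is disabled so the stated σ values are the only noise sources
(5-pp quantisation would add ≈ 25/12 pp² of variance per reader and
depress the measured reduction by several points). With a shared anchor
the expected reduction is ≈ 100·(1 − σ₂/σ₁) = 82 %; clamping at the 0 %
boundary truncates round-1 noise on the low-PI majority of ROIs and pulls
the realised value down by one to three points, which the validation band
(82 ± 5) absorbs.

## Problem sizes and numerical choices

Validation experiments run on 384×384 px fields (0.5 µm/px) with 60–80
nuclei — large enough that Otsu sees a clearly bimodal histogram and
exact-count PIs hit values like 2.5 % exactly, small enough for quick,
repeated replication (20 seeds per experiment, 10 study seeds × 440 ROIs
for the concordance recovery). Seeds are spawned from a single
command-line seed and kept below 2³¹. All randomness flows through
`numpy.random.default_rng`; reruns are byte-identical.

## Known limitations

* The published systems' exact thresholds, peak parameters and
  recalibration against nucleus oversplitting are not public; this package
  reproduces the mechanisms with its own documented defaults.
* No CNN segmentation, hotspot search, whole-slide tiling, or
  tumour/inflammation discrimination; ROIs are taken as given.
* Published per-ROI reader scores are unavailable, so pairwise RMSE
  *matrix entries* and Bland–Altman means/limits of real studies cannot be
  recomputed from raw data — only their arithmetic consequences (mean
  discordances, reductions, rates) and simulation-based structural echoes
  are validated.
* Agreement-rate arithmetic note: 416/440 = 94.5 % to one decimal; one
  published table prints 94.6 % for this ratio. The operation returns the
  arithmetically correct value.
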