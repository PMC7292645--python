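# Methods

`sacquant` quantifies three assays used to study chromosome-segregation
fidelity in budding yeast: the colony-sectoring chromosome-loss assay, the
fluorescence of kinetochore clusters (including estimating how many
kinetochores an unattached cluster contains), and OD600 growth-curve
doubling times. Each pipeline is validated end-to-end against synthetic
data with known ground truth; this note records the models, the parameters
that matter, and the design choices where the procedure was genuinely open.

## Colony counting and sector classification

**Assay.** Cells carrying a nonessential chromosome fragment (CFIII with
*SUP11*) are plated on low-adenine medium; cells that lose the fragment
accumulate red pigment. A colony that is fully red, or half red / half
white ("half-sectored", a loss at the first division after plating), is
scored as one chromosome-missegregation event, and the readout is events
per 1000 colonies plated. Because some red colonies reflect losses that
occurred before plating, this rate overestimates the true per-division loss
rate; no correction is attempted.

**Segmentation.** A plate photograph is reduced to the red channel,
median-filtered (disk radius 2 px), and background-flattened by a white
top-hat whose disk radius (default 25 px) exceeds the largest expected
colony radius. The red channel, not luminance, carries the contrast: red
pigment absorbs green light, so in luminance a red colony sits barely above
dark agar and a global threshold treats the two colony classes
asymmetrically, while in the red channel cream and red colonies are nearly
equally bright. Foreground is `threshold_scale` (0.45) times the Otsu split
of the flattened raster — Otsu lands midway between agar and colony modes,
and scaling down includes the dim 1-px colony rims symmetrically for both
colour classes — with an absolute floor (0.05) so blank plates produce no
foreground. Touching colonies are separated by watershed on the negated
Euclidean distance transform, seeded at distance-map peaks at least
0.8 × (median colony radius) apart. Peak separation rather than peak depth
is the seeding criterion because rasterised overlapping colonies produce
shallow spurious maxima in the contact neck whose depth overlaps that of
genuine peaks; they always lie within a colony radius of a genuine peak and
are therefore suppressed spatially. The median colony radius is estimated
as the median per-component maximum of the distance transform (the
inscribed radius), which remains accurate when touching colonies merge into
one component. Components below `min_area` (30 px) are discarded as debris.

**Colour classification.** The image is converted to L\*a\*b and each
colony's `red_fraction` is the fraction of its pixels with a\* (the
red–green axis) above a threshold. Two robustness measures matter in
practice. First, the threshold defaults to Otsu over colony pixels' a\*
values, but the Otsu value is accepted only inside a plausibility band
(8–35 a\* units); outside it — which happens whenever a plate has no red
colonies at all, or only red ones, so the a\* distribution is unimodal and
Otsu splits noise — a fixed fallback (15) is used instead. Second, the
fraction is computed over the one-pixel-eroded colony interior: rim pixels
blend colony and agar colour and would otherwise bias half-sector fractions
several points below one half. Classes: `red_fraction ≥ 0.9` → red,
`≥ 0.45` → half-sectored, else white. The half threshold sits at 0.45
rather than 0.50 so an exactly-half sector survives pixelisation jitter;
fractions below one half are not loss events and are labelled white. Fully
red colonies count as loss events by default (`include_full_red=False`
restricts scoring to first-division events).

**Statistics.** Events and totals are pooled across plates;
`rate_per_1000 = 1000·events/n` with an exact Clopper–Pearson 95% interval
(appropriate for event counts of order 3–18). Two strains are compared by
the rate ratio and a two-sided Fisher's exact test on the pooled 2×2 table.

## Spot fluorescence and unattached-kinetochore counts

Budding yeast has 16 chromosomes with one microtubule per kinetochore; in
metaphase the kinetochores form two diffraction-unresolved clusters of 16,
so cluster fluorescence is proportional to kinetochore number. A
measurement is: combine the z-stack (default: sum of all planes, which
preserves total signal; max projection and brightest-plane are options
since the original convention is not fixed), find the maximum-intensity
pixel (ties break to the smallest (row, col)), integrate the 6×6-pixel box
anchored so the maximum occupies box position (2, 2) — an even box has no
centre pixel, so the anchor is stated for reproducibility — and subtract
36 × the median of the background region. The background region is the
one-pixel ring immediately surrounding the box, or a caller-designated
nearby 6×6 area when the ring is unusable (e.g. a spot near the image
edge or a neighbouring structure). Corrected intensities may be slightly
negative from noise; a measurement is flagged when it falls below −3σ of
the background scatter propagated to the box sum.

The unattached-kinetochore estimate compares the corrected intensity of the
off-axis cluster (marked by checkpoint-protein recruitment) with total
kinetochore fluorescence: `estimate = round(N·f_u/(f_u + f_s))` with
N = 32 by default. The denominator includes the unattached cluster itself
(the alternative — spindle fluorescence alone — would make the ratio a
ratio-to-remainder and is not used; callers wanting it can form it from
the raw measurements). Rounding is banker's (half to even), negative
corrected inputs are clipped to zero with a warning, and the estimate is
bounded in [0, N] and monotone in `f_u` by construction. Cross-strain
scatter values are normalised by dividing by the arithmetic mean of a
designated reference population (e.g. wild type, or nocodazole-treated
cells).

## Growth curves and doubling times

Wells are inoculated at OD600 0.05 and read every 20 minutes. The linear
section of each curve is the maximal contiguous run of readings whose OD
lies inside a fixed range (default 0.1–0.5, above the inoculum and below
static-culture saturation); the same range must be applied to every well of
an experiment, which `fit_experiment` enforces. Window selection tests a
3-point edge-padded running median of the trace so a single spiky read
cannot break the run (a monotone trace is a fixed point of this smoother,
so clean curves are untouched); the fit always uses raw readings. At least
4 in-range points are required. Ordinary least squares of log10(OD) on time
gives the slope, and the doubling time is log10(2)/slope, in minutes. A
non-positive slope flags the well non-growing (NaN doubling time) rather
than raising, so batch fits proceed past dead wells. Blank-well subtraction
is off by default. `percent_change(t, t_ref) = 100·(t − t_ref)/t_ref`
expresses strain comparisons, e.g. 164 vs 144 min → +13.9%.

## Exact statistics

Fisher's exact test computes the two-sided p-value by the probability-mass
rule: the sum of hypergeometric probabilities, over all tables with the
observed margins, of tables as or less probable than the observed one
(ties admitted within relative tolerance 1e-12). This is the convention of
the common commercial implementations; mid-p and doubling conventions
differ and are not offered. Probabilities are evaluated in log space with
log-gamma so totals of several thousand do not overflow. The odds ratio is
the sample (a·d)/(b·c), flagged infinite when b·c = 0. The Clopper–Pearson
interval uses the beta-quantile construction with exact 0/1 bounds at
k = 0 and k = n. `mean_sem` is the arithmetic mean and sd/√n with the
n−1 denominator; it is NaN-flagged below two values.

## Synthetic data: what it emulates and what it does not

The generators define the conditions under which every pipeline is
validated. All randomness flows from one explicit integer seed per call;
identical arguments and seed give bit-identical outputs.

**Plates** carry a requested number of colonies (the assay plates
~200–300 cells per plate) as anti-aliased cream disks (radius 8–14 px by
default) on dark agar, placed by rejection sampling with minimum centre
distance `min_sep_factor·(r_i + r_j)` (1.2 for well-separated plates, 0.8
to force touching pairs that stress the watershed); an attempt budget turns
impossible packings into an explicit error. Each colony is independently a
loss event with probability `loss_fraction` (default 0.004, the order of
the measured wild-type rate); a loss is rendered as a red circular wedge
covering half the colony area (a first-division, half-sectored event) with
probability `half_given_loss`, otherwise the whole colony. Labels follow
the wedge fraction deterministically: 0 → white, [0.5, 0.9) →
half-sectored, ≥ 0.9 → red. Per-colony brightness jitter (±5%) and an
optional linear illumination ramp exercise the background flattening. Not
modelled: agar texture, colony morphology variability, specular highlights,
camera optics — so passing tests demonstrate correctness of the
segmentation/classification logic, not robustness to every photographic
artefact of real plates.

**Spot stacks** default to ten planes at 200 nm spacing. Each spot is an
isotropic (in array coordinates) 3-D Gaussian whose integral over the whole
stack equals its total photon count, computed per voxel from the Gaussian
CDF so that noiseless stacks conserve intensity to well under 1% (tail
truncation only); a constant background is added per pixel and Poisson
noise applied on request — photon counting is the dominant noise source of
the real camera regime, and no PSF asymmetry, chromatic shift or read noise
is modelled. The two-cluster cell generator places an unattached cluster
and a spindle cluster (intensities proportional to their kinetochore
counts, default 2000 photons per kinetochore over background 100/pixel,
giving integrated SNR ≈ 10 for a single kinetochore) in opposite image
halves with positional jitter.

**Growth curves** follow the logistic
`OD(t) = K / (1 + ((K − OD0)/OD0)·2^(−t/T))` sampled every `interval`
minutes with additive Gaussian read noise truncated at zero (defaults:
OD0 = 0.05, interval = 20 min, T = 144 min, noise 0.005 OD, 24 h). The
plateau K defaults to 1.0, a realistic static-culture ceiling;
`capacity = inf` gives the pure exponential `OD0·2^(t/T)`. Recovery
validations run in that exponential-phase regime: the window-average slope
of a saturating culture measures the doubling time *over the window*, which
for a logistic is systematically longer than the t→0 parameter T (by
roughly mean(OD)/K), so exact recovery of T is only a well-posed check when
the fit window sits far below the plateau. This mirrors laboratory
practice, where the fit window is placed in the early near-exponential
phase.

## Numerical choices and degenerate inputs

- Coordinates are 0-based (row, col); areas in pixels; no physical
  calibration anywhere (pixel size and magnification are metadata only).
- `locate_spot` on a constant image warns and returns the ROI origin by
  the tie rule; `measure_spot` raises at image borders unless a nearby
  background area is supplied; an all-zero denominator in the count
  estimator raises rather than guessing.
- Loss-rate estimation requires n > 0; a zero-event comparison flags the
  rate ratio undefined instead of raising.
- Validation problem sizes (20 plates of 250 colonies for counting, 500
  colonies for classification, 200 cells per true count noiseless and 60
  under Poisson noise, 100 noisy growth curves, exhaustive Fisher
  enumeration for row sums ≤ 30) were chosen so each check is estimated
  from hundreds of independent draws while the whole suite completes in a
  few minutes.

## Known limitations

- The colour model assumes red pigment shifts a\* strongly; weakly
  pigmented ("pink") sectors would need a recalibrated threshold band.
- Sector geometry is not used: a colony that is 50% red in scattered
  patches would be scored half-sectored although it is not a
  first-division event; real half-sectored colonies are contiguous halves.
- The unattached-count estimator assumes the two clusters are resolved
  and that fluorescence per kinetochore is identical in both; bleaching
  or focal-plane loss would bias it low.
- Doubling-time estimates depend on the chosen OD window; the package
  enforces a common window per experiment but cannot know which window a
  particular published panel used, so the window is always user-overridable.
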