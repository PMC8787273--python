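# Methods

This note documents the models, parameter choices and numerical decisions
behind `spindlemorph`, and what the synthetic-data suites do and do not
demonstrate about real micrographs.

## 1. The measurement model

### Diameter difference ratio (DDR)

A myotube's class is decided by the ratio of its largest to smallest
local diameter. We measure the full width profile rather than two manual
caliper readings: the fibre mask is skeletonised, the ordered medial-axis
path is taken as the longest path through the skeleton graph (double
breadth-first search), and the local width at each path point is twice
the Euclidean distance transform there, in µm. This is a reproducible
superset of the manual two-point measurement; DDR is the profile's
max/min. Widths are measured perpendicular to the local axis by
construction of the distance transform (the inscribed-disc convention).

Numerical details, chosen once and fixed:

- **Half-pixel correction.** `2·EDT` reports *w* for even and *w + 1* for
  odd pixel widths; widths are computed as `2·EDT − 0.5` px so the
  discretisation error is centred at ±0.5 px.
- **Skeleton offset.** A rasterised skeleton can sit half a pixel off the
  true medial axis; the distance transform is sampled through a 3×3
  maximum filter along the path.
- **Profile smoothing.** A running median (window 9) suppresses
  single-pixel rasterisation dips without biasing monotone stretches.
- **Tip exclusion.** Medial points closer to a path end than 1.5× their
  own inscribed radius cannot report a correct diameter (the disc leaks
  past the fibre tip) and are excluded, as is a 2% arc-length trim per
  end. The 1.5 factor also removes diagonal corner spurs produced by
  skeletonisation of flat-capped fibres (spur points satisfy
  `distance-to-end < √2 × radius`).
- **Interference.** Profile points whose inscribed disc comes within one
  pixel of another instance's mask are excluded — the algorithmic form of
  only measuring diameters "not interfered by an overlapping myotube".
- **Degenerate masks.** Skeletons shorter than 3 points, or profiles with
  fewer than 2 retained points, flag the instance unmeasurable; it is
  excluded from DDR statistics rather than guessed at.

Verified accuracy: on axis-aligned rectangles and ellipses the profile
agrees with a brute-force per-column scan within one pixel everywhere
(both quantities quantised to the pixel grid); on rendered fibres at the
default 0.65 µm/px, measured DDR tracks the generator's closed-form truth
to ≈ ±3% (SD) with isolated thin-fibre instances reaching ~12%.

### Thresholds and classification

Per-class mean and **sample** SD (n−1; the training set is a small sample)
give `linear_cutoff = mean + SD` and `bag_cutoff = mean − SD`. Derivation
fails loudly if the cutoffs cross ("populations not separable") — with
10 training fibres per class this genuinely happens for unlucky samples,
which is why the published summary cutoffs (2.18 / 2.71) are the default.
Both boundaries are inclusive to their named class, compared with a 1e-9
relative tolerance so that printed two-decimal cutoffs behave as written;
the open interval between them is *unassigned*.

Field summaries default to class percentages over **all** retained
myotubes (the three percentages sum to 100). `denominator="assigned"`
reports bag/linear shares of the assigned subset instead; because both
training distributions overlap the unassigned band, the assigned-share is
the estimand that matches a known bag/linear mixing fraction, and it is
what the parameter-recovery suites use.

### Nuclei and myogenic metrics

Nuclei are detected as local maxima of the Gaussian-smoothed DAPI channel
above an Otsu floor; two nuclei closer than about half the minimum
diameter merge into one maximum and are counted once (declumping by
maxima). A nucleus belongs to a myotube iff its centroid pixel lies
inside the mask (boundary pixels inclusive); a centroid inside two
overlapping masks is assigned to neither and flagged. A *myotube* is an
actin component with ≥ 3 nuclei. Fusion efficiency = nuclei inside
retained myotubes ÷ all detected nuclei × 100. Area per myonucleus is the
per-instance area/nuclei ratio averaged over instances.

### Marker-intensity pipeline

The background threshold is the smallest integer grey level *T* such that
at most 1% of the initially positive pixels (> 0) of a primary-negative
image remain above *T*; minimality is guaranteed by construction from the
sorted positive values and cross-checked against a brute-force scan.
Subtraction is **masking**: pixels ≤ *T* become 0, pixels above keep
their value — coverage and summed-intensity formulas count signal "above
background", which masking implements exactly (a value shift would not).
One calibration serves all images of an acquisition batch (same camera
and settings). Integer thresholds only, on the native bit depth.
A nucleus is marker-positive iff ≥ 50% of its pixels are non-zero after
subtraction (`positive_fraction` configurable and reported).

### Expression arithmetic

Triplicate Ct values are averaged (replicate SD > 0.5 cycles raises a QC
flag); ΔCt subtracts the reference gene (Csnk2a2) within sample; ΔΔCt
subtracts the same-plate control-group mean ΔCt; fold = 2^−ΔΔCt. Primer
efficiency is recorded and gate-checked (90–115% inclusive, r² > 0.95
strict, single melt peak) but not used to correct folds — plain 2^−ΔΔCt
is the default, matching the assay convention; QC rules whose column is
absent from a primer table are recorded as not evaluated rather than
guessed. Myh isoform composition linearises each gene as 2^−ΔCt and takes
per-sample shares — summing raw cycles has no proportional meaning, and
the reference gene cancels from the share. Western blots use the
two-step adjusted relative density: band ÷ loading control per lane, then
÷ the mean control-lane ratio per target. Viability folds are computed on
blank-corrected Rfu means.

### Statistics

Each two-group outcome passes a normality gate: Shapiro-Wilk per group
(α = 0.05) on the — optionally square-root transformed — data; both
normal → pooled two-sided t-test (Welch by flag), otherwise Mann-Whitney
U. The transform is applied *before* the gate and the test, never after.
Factorial outcomes use OLS two-way ANOVA with **type-II** sums of squares
(the cell counts are unbalanced) and Tukey HSD over all cells; marker
intensities are square-root transformed first. Nuclei-per-myotube counts
are overdispersed and use log-link negative-binomial regression with
treatment and type terms, dispersion estimated by maximum likelihood;
effects are reported as rate ratios. Every result carries n, group means
± SEM, the gate branch taken and star codes (*** < 0.001, ** < 0.01,
* < 0.05).

## 2. The synthetic-data generator

The generator is first-class code: it renders fields whose statistical
structure matches the two study arms, records ground truth before
rendering, and is bit-reproducible for a fixed (params, seed).

**Condition parameters** (per FOV, defaults = the study arms):

| parameter | control | Nrg-1 |
|---|---|---|
| bag fraction | 0.0852 | 0.4161 |
| myotubes (Poisson mean) | 8.33 | 9.22 |
| nuclei | 104.8 | 136.3 |
| fusion efficiency | 0.4688 | 0.4741 |
| nuclei per linear / bag myotube | 5.48 / 8.09 | 6.10 / 8.33 |
| area per myonucleus (µm²) | 645.3 | 537.9 |
| marker intensity linear / bag | 0.88 / 1.85 | 2.50 / 6.13 |
| positive-nuclei fraction linear / bag | 0.486 / 0.55 | 0.58 / 0.7212 |

DDR distributions are N(1.81, 0.37²) for linear and N(4.03, 1.32²) for
bag, truncated at > 1, in both arms. The positive-nuclei fractions for
control-bag and treated-linear are not reported by the study (only that
myotube type was the significant factor); 0.55 and 0.58 interpolate
between the two reported values preserving the type ordering.

**Geometry.** Fibres are straight-axis tubes. Linear fibres ramp from
w_min to w_max (ratio = drawn DDR) between flat plateau caps sized
`0.9·w + 0.03·L`, so the true extrema lie inside the measurable interior
(the tip-exclusion zone covers ~1.5 inscribed radii). Bag fibres carry a
Gaussian equatorial bulge with σ = L/7 — full width at half maximum ≈ a
third of the fibre — returning to within ~1% of w_min at the poles. A
closed-form profile makes the recorded true DDR exact. Bag geometry is
kept fibre-like (L ≥ 4·w_max; small bags render proportionally thinner,
floor 6 µm) because a bulge wider than it is long has no line-like medial
axis. Base width w_min ~ U(8, 12) µm, w_max capped at 50 µm. Fibre length
is solved from the profile integral so that area = (area per nucleus) ×
(nuclei count) × U(0.85, 1.15). Instances are placed without overlap
(3 px clearance); an optional overlap mode exists for exclusion-rule
tests.

**Nuclei.** Counts per myotube are negative-binomial (var = µ + 0.17µ²,
i.e. ≈ 2× the mean at these counts — the study reports overdispersion but
no dispersion estimate) resampled to the ≥ 3 floor that defines a myotube
(a small documented upward shift of the realised mean). Linear nuclei
spread along the axis; bag nuclei cluster at the equator
(s ~ N(L/2, (L/8)²)). Nucleus centres keep ≥ 7.5 µm separation so maxima
detection is well-posed; nuclei render as Gaussian blobs of 10 µm nominal
diameter (size unreported; typical C2C12 myonucleus). Unfused
mononuclear cells — actin discs with one nucleus — are added at Poisson
rate `nuclei_per_fov × (1 − fusion efficiency)`, which makes both the
total nuclei count and the fusion efficiency correct in expectation
simultaneously (the two published settings are mutually consistent to
within sampling error).

**Channels and noise.** 16-bit grey levels at 0.65 µm/px (unreported;
typical for the stated microscope class). Actin level ~25 000 with ±15%
per-instance jitter. Marker cytoplasm is `class intensity × 8000` grey
levels with gamma-texture (shape 4) inside the fibre; marker-positive
nuclei render as bright nuclear discs, negative nuclei as strong nuclear
exclusion (×0.05). A mean-preserving lognormal factor (CV 0.9, from the
study's per-myotube SEMs) gives between-myotube biological spread — this
is what makes the two-way ANOVA's interaction term behave as observed.
The marker grey-level scale was fixed once so that, after the 99%-rule
calibration at the default camera noise, the arm-level
intensity-per-nucleus contrast lands near the study's ≈3.5-fold; the
shortfall of a few percent comes from sub-threshold masking and 16-bit
saturation of the brightest bag myotubes, both deliberate camera realism.
Camera noise is additive Gaussian, SD = 2% of the 16-bit range, applied
last and clipped — strong enough that calibration is non-trivial, weak
enough that Otsu segmentation is exact.

**Assay tables** invert the analysis arithmetic exactly: Ct tables fix a
per-gene control ΔCt and shift the treated ΔCt by −log₂(fold), so a
zero-noise table round-trips to the requested fold at machine precision;
likewise blot tables (per-lane loading ~U(800, 1200), ratio × fold) and
Rfu tables (media blanks + condition means).

**What the synthetic fields do not emulate:** point-spread blur and
chromatic offsets, uneven illumination, curved or branching fibres,
debris and staining artefacts, 3-D structure, and segmentation ambiguity
beyond simple contact. Passing the recovery suites therefore shows the
*measurement chain* is correct and unbiased under the generative
assumptions — not that segmentation would be this clean on real
micrographs, where manual curation or a learned segmenter would replace
the Otsu step behind the same interfaces.

## 3. Reproducibility and problem sizes

Every stochastic routine takes an explicit integer seed
(`numpy.random.default_rng`); the pipeline fans one top-level seed into
per-stage children via `(seed × 1 000 003 + k) mod 2³¹`. The test suite's
simulation sizes are chosen for tight-but-fast inference on one CPU:
50 fields per arm for parameter recovery (3 SE bands), 40 paired fields
for the intensity-fold check, 2 000 null datasets for the gated test's
size, 1024² px default FOV. The acceptance script's quantities are
analytic (cutoffs) or single-image (calibration) and run in seconds.

## 4. Known limitations

- DDR from inscribed discs slightly under-reports caliper widths on
  strongly curved bulges; the fibre-like length constraint bounds this at
  a few percent.
- Declumping by smoothed maxima undercounts heavily confluent nuclei; the
  generator's separation floor sidesteps what real clustered cultures
  would not.
- The negative-binomial model treats every myotube as independent across
  fields and wells, mirroring the study's n-convention (technical wells
  as replicates) without endorsing it.
- Primer efficiency is recorded, not used to correct folds; an
  efficiency-corrected mode would change folds for efficiencies far from
  100%.
- The ≥ 3-nuclei floor truncates the negative-binomial left tail, so the
  realised nuclei-per-myotube mean sits a few percent above the nominal
  parameter.
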