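# Methods

This note documents the models implemented in `petalvision`, their
assumptions, the default parameter values and the reasoning behind the
design choices that were genuinely open.

## Reflectance spectra

Spectra are relative reflectance against a white standard, stored as
fractions (white = 1.0). Percent-scaled input (0–100) is converted once,
at the CSV reader, so a stray factor of 100 cannot reach the index
ratios. Field spectroradiometers of the class emulated here cover
325–1075 nm at ~3 nm resolution; because the pigment index addresses
exact wavelengths (550/700/800 nm), spectra are linearly interpolated
onto a 1 nm grid before index work. Linear interpolation is exact for
on-grid points, never extrapolates, and is idempotent. Repeated scans of
one petal are combined by a pointwise arithmetic mean (25 scans is the
emulated protocol). No smoothing is applied by default; a boxcar
smoother exists but nothing in the pipeline calls it.

The peak metric is the maximum reflectance between 325 and 600 nm,
reported with its wavelength. Peak-shape tools differ on whether
"height" means the absolute maximum or the height above the local
trough; both conventions are exposed (`baseline="none"` /
`"window_min"`) and the absolute maximum is the default.

## Anthocyanin reflectance index

`ARI = (R800/R550) − (R800/R700)`. Anthocyanins absorb near 550 nm, so
R550 falls as pigment accumulates and the index rises; the R700 term
compensates for scattering and chlorophyll absorption tails. The index
is invariant to a common scaling of the spectrum and strictly decreasing
in R550. Ordinates are point values on the 1 nm grid by default; a ±5 nm
band mean is available for noisy single scans but off by default, since
the index is defined on point wavelengths. Petals where R550 or R700 is
zero get an explicit undefined-index report instead of being dropped.
Where statistics require a log transform of ARI the natural log is used
(the base only shifts the log-likelihood by a constant; the choice is
recorded here because conventions differ).

## Pollinator visual models

For each photoreceptor class i, the quantum catch of a stimulus R(λ)
under illuminant I(λ) is `Q_i = ∫ R S_i I dλ` (trapezoidal rule).
Receptors adapt to the viewing background — green foliage — which von
Kries normalization expresses as `q_i = Q_i / Q_i(background)`. A petal
spectrally identical to foliage therefore has q = 1 on every receptor
and maps to the achromatic point of every space; this fixed point is
verified to 1e-10 in the tests. All visual computations are restricted
to 325–700 nm: insect photoreceptors do not reach the NIR, so the long
petal spectra are trimmed before integration.

**Sensitivities.** Receptor curves are generated from the Govardovskii
A1 visual-pigment template (α-band plus Gaussian β-band,
peak-normalized), parameterized only by λmax. Defaults: bee UV/B/G =
344/436/556 nm (honeybee-like); fly R7p/R7y/R8p/R8y = 330/350/430/530 nm;
butterfly u/s/m/l = 360/440/530/600 nm. Template curves are smooth
idealizations of measured sensitivities; every λmax lives in
`defaults.yaml`, so species-specific curves can be dropped in without
touching code.

**Illuminant and background.** The CIE D65 table (10 nm, 300–780 nm) is
embedded and converted to relative quanta (power × λ), because
photoreceptors count photons. The background is a closed-form synthetic
green-leaf reflectance (low blue/red, modest 555 nm peak, red-edge
rise) — strictly positive on any grid, which the adaptation step
requires.

**Color spaces.**

* *Bee hexagon*: receptor excitation `E = q/(q+1)` (hyperbolic
  transduction), then `x = (√3/2)(E_G − E_UV)`,
  `y = E_B − (E_UV + E_G)/2`. With 0 < E < 1 every locus lies inside
  the unit hexagon. Sectors are the six 60° wedges whose centres are the
  three receptor directions (pure green at −30°, blue at 90°, UV at
  210°) and their bisectors; labels are configuration.
* *Fly categorical space*: opponent coordinates
  `cx = q_R7p − q_R8p`, `cy = q_R7y − q_R8y`; a color category is a
  quadrant sign pattern. The quadrant → name map is a configuration
  table (default: (+,+) Fly UV, (−,+) Fly Purple, (−,−) Fly Blue,
  (+,−) Fly Yellow); the literature figures that name the categories do
  not pin the sign convention down, so it is deliberately explicit and
  auditable rather than hard-coded. A coordinate exactly at zero is
  labelled "boundary", never silently assigned.
* *Butterfly tetrahedron*: catches normalized to `Σq = 1` and mapped as
  a convex combination of the vertices of a regular tetrahedron with
  unit circumradius and centroid at the origin (u at (0,0,1)). Equal
  catches give the centroid; a pure single-receptor stimulus its vertex.
* *Luminance*: the adapted catch of the longest-wavelength receptor of
  each guild (green for bees, R8y for flies, l for butterflies).

No receptor-noise discriminability model is used: the perceptibility
rules below are plain distance thresholds, so adding noise-scaled units
would change the scale without changing any decision.

## Perceptibility

Discrimination criteria per guild (chosen so that discrimination
corresponds to at least ~60% correct choices in behavioural work): flies
discriminate two stimuli iff they fall in different quadrants; bees iff
the Euclidean hexagon distance is ≥ 0.09 units; butterflies iff the
difference on a single relative-catch axis (default u, the UV receptor)
is ≥ 0.03, with an alternative Euclidean-in-tetrahedron mode.

Group-level scoring ("how many treated petals look different from the
control group?") is not uniquely defined by a pairwise rule. Two modes
are shipped: distance to the control-group **centroid** (default — it
matches the common practice of drawing one reference envelope around the
control cloud) and **strict** all-pairs mode (perceptible from every
control petal). For clustered groups the centroid mode is the more
permissive; both are provided precisely so this choice can be
sensitivity-analysed, and neither is claimed to reproduce any particular
published fraction.

## Statistics

* **PERMANOVA.** Spectra are compared as multivariate profiles:
  square-root transform (damping the leverage of high-reflectance
  wavelengths), Bray–Curtis dissimilarity `Σ|x−y|/Σ(x+y)`, and
  Anderson's pseudo-F from `SS_total = Σ_{i<j} d²/N` and the pooled
  within-group analogue. The permutation p-value is
  `(1 + #{F* ≥ F}) / (1 + B)` over B seeded label permutations; an
  exact mode enumerates all distinct label arrangements for small
  designs and is tested against a brute-force oracle. The description
  "squared then root transformed" found in field protocols is read as
  the square-root transform x → √x: squaring followed by a square root
  is the identity on non-negative data and cannot affect any
  dissimilarity, so it cannot be what is meant. Both `sqrt` and `none`
  are selectable.
* **Planned contrasts.** Single-df F tests of `Σ c_g·mean_g = 0` inside
  the one-way (or ANCOVA) model, fitted by OLS with cell-means coding;
  with a covariate the contrast applies to covariate-adjusted means.
  Named codings: orthogonal-polynomial linear increase/decrease
  ((−1,0,1)/√2 for three equally spaced levels), middle-vs-rest
  (−1,2,−1), and control-vs-rest (2,−1,−1). Null calibration (rejection
  at ~5% under a true null) is part of the acceptance suite.
* **ANOVA/ANCOVA.** Sequential (type-I) sums of squares with the
  covariate entered first. A design with zero total or residual variance
  reports F as undefined (NaN) rather than 0.
* **Random-intercept selection.** The plant-level model
  `y = Xβ + b_plant + ε`, `b ~ N(0, σ²_plant)`, is fitted by **maximum
  likelihood** (not REML) so AIC values are comparable across different
  fixed-effect structures — a deliberate divergence from mixed-model
  software defaults, which REML-fit. The likelihood is profiled to the
  single variance ratio λ = σ²_plant/σ²_resid (block-diagonal algebra
  via Sherman–Morrison) and maximized by bounded 1-D search with
  absolute tolerance 1e-8; λ = 0 is always evaluated explicitly so the
  boundary solution is exact. AIC counts fixed effects plus both
  variance parameters. The treatment statistic is a likelihood-ratio χ²
  (labelled as such; Wald statistics would differ slightly).
* No multiple-testing correction is applied anywhere; p-values are
  reported raw.

## Ozone exposure and chamber microclimate

AOT40 accumulates `max(0, c − 40 nL L⁻¹)` over the daylight fumigation
window, interpreted as the eight hourly records with timestamps starting
07:00–14:00 (a 07:00–15:00 fumigation day). Missing hours are skipped
and counted in a coverage report; there is no gap-filling. VPD uses the
Magnus form `es = 0.6108·exp(17.27 T/(T+237.3))`, `VPD = es(1−RH/100)`,
applied per hourly record and then averaged — never to period-mean T and
RH, because es is convex in T and the two orders of operation disagree.

The module embeds the summary table of a 37-day OTC fumigation campaign
(four treatments: AMB, CFA, NFA, FU+) and recomputes the derived
percentages (charcoal filtration efficiency, relative O₃ enrichment,
chamber deltas for temperature, RH, VPD and PAR) directly from the
tabulated cells; these recomputations are what `scripts/acceptance.py`
reports as t1–t7.

## Synthetic data generator

The generator is the package's test bed: it produces data with the
statistical structure the analysis assumes, not radiative-transfer
petal optics.

**Spectrum model.** `R(λ) = scale·[base(λ) − depth·G(λ;550,60) +
0.06·G(λ;380,25)] + noise`, where base ramps logistically from 0.45 to a
0.85 NIR plateau across a 680 nm red edge, G is a unit Gaussian, depth
defaults to 0.25 and Gaussian noise has sd 0.01 (clipped to (1e-6, 1]).
This guarantees the anthocyanin signature — a trough near 550 nm, a UV
bump, R800 > R550 and hence ARI > 0. A parameter combination that would
drive the clean spectrum non-positive on more than 1% of the grid is an
error, so clipping only ever trims rare noise excursions.

**Treatment effects (defaults).** Reflectance scale 1.00/1.08/1.15 for
CFA/NFA/FU+ (overall brightening with exposure); an extra trough
deepening of 0.06 in NFA only (the non-linear anthocyanin response —
elevated ARI at ambient ozone but not under filtration or
supplementation); petal-area multipliers 1.000/0.802/0.750, i.e. mean
reductions of 19.8% and 25% versus CFA. AMB mirrors NFA for every
petal trait, making all chamber-effect comparisons null by
construction. Plant-to-plant variation (sd 0.05) enters additively on
the spectrum scale and as a mean-one lognormal factor on area — a
modest, realistic between-plant spread. Petal-area noise is lognormal
with coefficient of variation 0.25 (areas are positive and
right-skewed).

**Design and seeding.** The default design mirrors the emulated field
study: four treatments × two plants × nine petals. Each plant's random
stream is seeded by (dataset seed, treatment index, plant index), so
datasets are byte-reproducible and a plant's data do not change when
other treatments are added or removed.

**O₃ series.** A day-time sine profile (zero at night, peak early
afternoon) scaled in closed form so the 07–15 h mean equals the
requested target exactly; a constant-profile mode and optional clipped
Gaussian noise are available. The closed-form AOT40 of the noise-free
series is exported for testing.

**Effect recovery.** `estimate_area_reductions` recovers the configured
area reductions by simulating datasets of 200 petals per treatment
(25 plants × 8 petals) and averaging the per-dataset estimate
`100·(1 − mean_T/mean_CFA)` over 20 replicate datasets whose seeds
derive from one base seed. A single dataset of this size estimates the
reduction with a standard deviation of roughly 2 percentage points
(petal CV 0.25 and plant variation propagate into the ratio of means);
averaging replicates separates the calibrated effect from that sampling
noise, which is the quantity the recovery check is about. Per-replicate
values are returned alongside the mean so the single-dataset spread
remains visible.

**What the generator does not emulate.** Real petal spectra have
correlated, wavelength-dependent noise, instrument artefacts at the
detector seams, and pigment-structure interactions (epidermal
micromorphology, co-pigmentation) that a three-component closed form
cannot produce. Passing tests therefore demonstrate that the pipeline
recovers known structure of this idealized kind, not that any specific
field result would be reproduced.

## Numerical conventions

* 1 nm working grids built inclusively (`make_grid(lo, hi)`); linear
  interpolation throughout, no extrapolation anywhere.
* Permutation tie handling: permuted statistics count as extreme when
  `F* ≥ F_obs − 1e-12`, so exact ties favour the conservative side.
* Profile-likelihood search over log λ on [−12, 8] with xatol 1e-8,
  plus an explicit λ = 0 evaluation for the boundary case.
* Bee hexagon loci within 1e-12 of the origin are labelled
  "achromatic" instead of being forced into a sector.
* Degenerate ANOVA designs (zero variance) report NaN statistics rather
  than 0, and undefined ARI values are reported per petal, never
  silently dropped.

## Known limitations

* Template sensitivities approximate, rather than reproduce, measured
  photoreceptor curves; guild defaults are genus-level stand-ins.
* The green-leaf background and D65 quanta conversion fix one viewing
  condition; gap light or overcast illumination would shift all loci.
* The mixed model supports a single random intercept (plant); crossed
  or nested deeper structures are out of scope.
* Perceptibility fractions depend on the reference-set mode (centroid
  vs strict); no claim is made that either reproduces published
  percentages, whose scoring protocol is not fully specified.
* PERMANOVA assumes exchangeability under the null; with strong
  heteroscedasticity between groups the pseudo-F conflates location and
  dispersion effects.
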