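# Methods

## Scope and data model

The package estimates the perilymph volume of the guinea-pig scala tympani
(ST) and its partition around a cochlear-implant array. Its central object
is the cumulative volume profile `V(θ)` — perilymph volume (μL) enclosed
between the round-window station (θ = 0°) and cochlear angle θ, stored as
knots on an angular grid and interpolated with a monotone piecewise cubic
(PCHIP), which cannot create non-monotone segments between knots. Units are
mm / mm² / μL (1 mm³ ≡ 1 μL) throughout; angles are degrees from the
round-window center, increasing apically.

## Geometry pipeline

Input is a set of closed ST contours drawn in midmodiolar half-planes
(angular stations, 22.5° apart by default, arbitrary monotone grids
accepted). Per station the pipeline computes the shoelace area and
area-weighted centroid (contours are closed last→first; self-intersections
are detected with shapely and rejected; coplanarity with the slicing
half-plane is enforced to 1e-6 mm).

**Volume rule.** The increment between adjacent sections of areas A₀, A₁
whose centroids are d mm apart is the conical-frustum rule
`d·(A₀ + A₁ + √(A₀A₁))/3` — exact for a linearly tapering tube and equal to
the prism rule for constant area. d is the Euclidean distance between area
centroids (the ST centerline), not the lateral-wall arc. A trapezoid rule
(`d·(A₀ + A₁)/2`) is available behind a flag for sensitivity checks; it is
never smaller than the frustum value.

**Lateral wall and footprint.** The lateral wall is the per-station contour
point with maximal perpendicular distance to the modiolar axis (ties broken
deterministically by lowest point index). Basal-turn wall points (≤ 360°)
are projected onto the plane perpendicular to the axis; *A* is the longest
chord between projected points whose segment passes within ε of the
projected axis (default ε = 0.1 mm, doubled with a warning if no chord
qualifies; the ε actually used is reported), anchored at the round-window
side among ties; *B* is the projected extent perpendicular to the A-chord.
This chord-through-axis operationalization is a reconstruction of the
established footprint measurement; results outside the plausible adult
ranges (A ∈ [3.0, 5.0] mm, B ∈ [2.0, 3.5] mm) trigger a warning, not an
error.

## Footprint → volume model

* **ECA.** `BTL = 1.18·A + 2.69·B − cross`, with the cross term
  `0.72·√(A·B)` by default. The product variant `0.72·A·B` is retained as
  `printed_product` but maps the observed footprint range (A 3.46–4.37,
  B 2.51–2.99 mm) to BTL ≈ 4.2 mm and hence negative volumes through the
  V(360°) regression, contradicting reported BTL medians of 9.09–9.68 mm;
  the geometric-mean form yields 9.4–10.1 mm. Both variants are exposed,
  neither is silently altered.
* **V(360°) regression.** `V = 1.38·BTL − 8.36` μL; predictions ≤ 0 raise
  an error naming the minimum valid BTL (6.058 mm). Refitting on cohorts is
  supported (ordinary least squares); the packaged coefficients are never
  re-derived from unavailable raw data.
* **Canonical mean profile.** The packaged profile is a synthesized knot
  table (22.5° grid, 0–1080°), not a digitization: it satisfies exactly the
  published anchors — V(0°) = 0, V(360°) = 4.4 μL, V(1080°) = 5.3 μL (83%
  of the total in the basal turn) — with a rapid basal rise (≈65% of the
  basal-turn volume by 180°), a slope plateau within 270–340° followed by a
  drop into the second turn (the basal cross-section-area plateau), and a
  slow apical decay. Construction: a volume density with exponential basal
  decay (τ = 260°), constant plateau, cosine drop to a level solved so the
  apical fraction is exactly 0.9/4.4, and apical exponential tail
  (τ = 700°), integrated and frozen. Users can substitute their own cohort
  profile (`build_mean_profile` or a profile CSV).
* **Normalization.** Cohort mean profiles are built per-specimen (each
  divided by its own V(360°)) by default, which makes the common-shape
  claim directly testable; cohort-mean normalization is available.
* **Log fit.** `V(θ) = a·ln(1 + θ/b)`, chosen because it passes through
  the origin; fitted by least squares (scipy `curve_fit`, positive bounds).
  Fitted to the canonical profile it overshoots the measured shape below
  180° — the documented reason the log method is the least accurate
  basally.

## Electrode, insertion, partition, dosing

The array is a straight conical frustum inserted tip-first: diameter
`d(x) = d_tip + (d_basal − d_tip)·x/L` at distance x from the tip
(defaults L = 5 mm, d 0.3/0.6 mm). The inserted volume is the closed-form
frustum integral `π·eid·(d₀² + d₀d₁ + d₁²)/12`. A coating adds twice its
thickness (default 50 μm) to every diameter on the lateral surface only;
an optional flat end-cap disc approximates a coated tip face.

Insertion depth (EID) maps to insertion angle (IA) by pooled ordinary
least squares over measured pairs (both surgical approaches on one line by
default, optional per-approach intercept offsets); the inverse map is
exact. The perilymph partition for an insertion reaching angle IA from an
entry at angle θ₀ (0 for round window; a cochleostomy requires an explicit
entry angle — no silent default, since it controls the basal pocket) is

    basal = V(θ₀), apical = V(θ_max) − V(IA),
    implant = inserted array volume,
    surrounding = V(IA) − V(θ₀) − implant,

which sums to V(θ_max) identically; a negative surrounding volume (array
displacing more than the local scala holds) is an error reporting the
deficit. The net-volume curve spreads the array volume over [θ₀, IA] by a
linear arc-length↔angle map; this affects only the curve, never the three
totals. Dosing: mass (μg) = concentration (μg/μL) × volume (μL), or
mol/L × volume × molar mass for molar concentrations.

## Evaluation

`loocv_volume` re-derives the full chain — normalized mean profile, log
fit, V(360°)-on-BTL regression — on all-but-one specimen and scores the
held-out profile from its footprint alone, per angle (22.5° grid by
default); summaries report per-angle median, IQR and median |dV|. A model
evaluated on data generated exactly from that model yields machine-zero
errors (tested for scaling, log and the insertion regression).
`loocv_insertion` reports the Bland–Altman-style median deviation and
median absolute deviation of predicted vs measured IA.

Group comparisons use the two-sided Mann–Whitney U test: the exact
distribution when both groups have ≤ 12 observations and no ties, a
full-enumeration permutation test when ties are present and pooled n ≤ 16,
and a tie-corrected normal approximation otherwise (the method used is
reported per pair). Bonferroni correction multiplies by the number of
pairwise comparisons (10 for five groups), capped at 1. Outliers are
flagged by the 1.5×IQR rule within groups. RSD = 100·SD/mean with the n−1
sample SD.

## Synthetic data

`make_synthetic_cochlea` builds a descending helix: lateral-wall envelope
`R(θ) = (1 − decay)^(θ/360)·E(θ)` with an elliptical base E (circular by
default; calibrated to a target footprint when one is given), centerline
rise proportional to θ, and elliptical cross-sections (96-point polygons,
semi-axes inflated by √(2π/(n·sin 2π/n)) so the polygon area equals the
target area exactly) sized so the cumulative volume follows a requested
shape (canonical by default) up to a requested total. Defaults — basal
envelope radius 1.9 mm, decay 0.30/turn, rise 0.75 mm/turn, 3 turns, 5.3 μL,
section ellipticity 0.75 — emulate adult guinea-pig proportions (apex
radius ≈ 0.65 mm, height ≈ 2.3 mm). `radius_decay = 0` is accepted so the
degenerate torus-segment case (closed-form volume) is expressible for
validation.

**Ground truth.** The exact volume of the generated solid follows from the
cylindrical-coordinate identity V = ∫A(θ)·r̄(θ) dθ (sections lie in
half-planes through the axis; r̄ is the section-centroid radius), evaluated
by Simpson quadrature at 0.1° — independent of the station/frustum
pipeline it validates. Footprint truth comes from the continuous basal
envelope at 0.05° resolution.

`sample_population` draws cohorts with the published statistics: (A, B)
bivariate normal, 3.8 ± 0.2 and 2.8 ± 0.1 mm with correlation √0.31 (sign
positive, matching the reported significant positive correlation);
V(360°) = 1.38·BTL − 8.36 plus a Gaussian residual of SD 0.279 μL (0.57 μL
population SD × √(1 − 0.76), so BTL explains 76% of the variance);
profiles are the canonical shape with 5% multiplicative jitter on knot
increments (monotonicity preserved), rescaled through the specimen's
V(360°). The jitter level is a tuning choice that places LOOCV error
magnitudes at the sub-0.5 μL scale of real cohorts, not a measured value.
All randomness flows through explicit integer seeds; identical seeds give
identical cohorts.

What the generator does **not** emulate: μCT noise and imaging artifacts,
segmentation difficulty differences between strains/preparations,
non-helical anatomical irregularities, or measured per-angle profile
covariance beyond independent increment jitter. Passing tests therefore
demonstrate correctness of the computational chain under a realistic
geometric and statistical model, not agreement with any particular real
animal.

## Numerical choices and known limitations

* Monotone PCHIP everywhere a profile is interpolated; cumulative knot
  values are clamped non-decreasing within 1e-9 at construction.
* The frustum-rule estimate is compared to the exact swept-solid volume.
  On the default geometry the two agree within 0.5% at 22.5° stations. The
  rule has a known **positive bias on strongly non-circular geometry**:
  Euclidean centroid chords count the radial excursion of the centroid
  path (eccentric footprints, steep decay) and its axial climb (tall rise)
  as tube length, which the cylindrical volume measure does not. For a
  target footprint B/A ≈ 0.74 the bias is a few percent; it does not
  shrink with finer stations. The tests assert the bias's sign and bound
  rather than hiding it.
* Fixed-point solution of the section size (a ← √(target/(πe(R − sa)))) is
  capped at the feasibility maximum 2R/(3s); non-convergence or sections
  that do not fit the envelope raise an informative error.
* Exact Mann–Whitney enumeration is limited to pooled n ≤ 16 when ties are
  present (full `itertools.combinations` scan); beyond that the
  tie-corrected asymptotic test is used and labeled.
* LOOCV and acceptance computations use a 38-specimen cohort and the
  22.5° grid (49 angles, 0–1080°), matching the reported evaluation
  set-up; the whole suite runs in seconds on one CPU.
* The insertion regression cannot reproduce the originally fitted
  slope/intercept (never published); it fits whatever dataset it is given
  and reports R².
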