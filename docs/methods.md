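# Methods

## Geometric model

A trileaflet aortic root is reduced to a landmark set in an arbitrary
right-handed millimetre frame: an ordered contour along the basal cusp
insertion line, the three cusp nadirs (L/R/N), the three commissure apices
(NL/LR/RN), and per-cusp geometric height (gH) and effective height (eH)
supplied as scalar attributes. No image data are handled; landmarks are
assumed pre-extracted (manually or by a segmentation algorithm) on a CT
workstation. All derived quantities are invariant under rigid motion of
the landmark set, which the test suite asserts to 1e-9 relative.

**VBR plane.** The virtual basal ring plane is the exact plane through the
three nadirs, its normal oriented toward the commissure centroid. A
least-squares fit over the whole contour was considered and rejected: the
nadirs define the basal ring in the surgical convention, and an exact
three-point plane keeps the commissural heights interpretable as heights
above the nadir level.

**Ring size.** The annulus contour is projected orthogonally onto the VBR
plane; area comes from the shoelace formula and perimeter from the edge
sum. The estimated VBR diameter treats the ring as a circle and averages
the two circle-equivalents, ½·(2√(A/π) + P/π). Averaging (rather than
picking one) uses both printed quantities symmetrically and reproduces the
reference expert value (A = 621.3 mm², P = 88.9 mm → 28.2 mm). Because
2√(A/π) is concave in A, sizing a *mean* root slightly overestimates the
mean of per-root sizes (Jensen gap, asserted as a property test); group
means of the nonlinear outputs therefore agree with tables of per-patient
means only to ~0.1–0.2 mm, and the tests treat them accordingly.

**Major/minor diameter.** Extremal lengths of chords through the contour
centroid (ray-cast against the polygon boundary), matching the clinical
caliper convention, not PCA eigen-lengths. Ellipticity index =
major/minor ≥ 1 by construction; > 1.2 flags an oval ring.

**Commissure-derived quantities.** CCA is the circumcircle area of the
three apices (closed-form 3D circumcenter; collinear apices raise a
degenerate-geometry error). ICDs are straight-line 3D chords a (NL–LR),
b (LR–RN), c (RN–NL), each subtending one cusp (L, R, N respectively).
Commissural height d is the signed perpendicular distance from the VBR
plane; a negative value warns (landmark below the annulus) rather than
errors, since the measurement remains well-defined.

**Cusp angles.** α, β, γ = 360°·(a, b, c)/Σ — proportional allocation of
the circumference, not chord-subtended central angles. Proportional
allocation is the convention that reproduces the published group-mean
angles from the published group-mean ICDs (111.5°/127.2° from
32.0/36.5/34.8 mm); chord-angle conversion does not. γ is computed as
360 − (α + β) so the closure is exact in floating point.

**Predicted commissural height.** Fixing a commissure to the straight
graft wall removes its radial offset e = √(CCA/π) − VBR/2 (radii, not
diameters; this variant reproduces the published R–N value 25.8 mm from
d = 24.9 mm, CCA = 1330.7 mm², VBR = 28.0 mm), so the height along the
wall is f = √(d² + e²) ≥ d, with equality iff e = 0. A commissure circle
smaller than the basal ring (unphysiological, can arise from noisy
landmarks) clamps e to 0 with a warning.

**Coaptation.** cCH = gH − VBR/2; negative values are allowed and flagged,
as they are exactly what downsizing is meant to repair.

## Planner

Defaults encode the published protocol; all are configurable via
`PlannerConfig` / YAML:

| parameter | default | meaning |
|---|---|---|
| available_graft_sizes | 30, 32, 34 mm | graft inventory |
| oversize_min/max | 6 / 8 mm | graft over planned VBR |
| bottom_margin | 4 mm | graft-bottom plication over planned VBR |
| downsizing_trigger_vbr | 30 mm | VBR above which downsizing applies |
| downsizing_mm | 3 mm | reduction (middle of the 2–4 mm range) |
| crimp_height | 1.5 mm | one graft fabric crimp |
| cch_warn_threshold | 4 mm | minimum coaptation reserve before warning |
| sov_warning_threshold | 50 mm | mean sinus diameter above which CP prediction degrades |

Open choices resolved here, as this package's conventions:

- the graft is the *smallest* admissible size (the protocol states only
  the 6–8 mm window); exceeding the window warns (`OVERSIZE_EXCEEDED`);
- predicted CHs and cCHs in the plan are recomputed against the *target*
  (post-downsizing) VBR, since the commissures are positioned on the
  reconstructed root — identical to the measured values when no
  downsizing applies;
- crimp counts round half-up (a crimp is a visual ruler, no published
  rounding rule);
- the STJ circumferential reduction π·(graft − planned VBR) is split into
  three equal inter-commissural panels;
- the `SOV_GT_50` warning triggers on the *mean* of the three sinus
  diameters;
- the 4 mm coaptation warning threshold is conservative: achieved values
  in published series are 5–6 mm, with recent recommendations of 8–9 mm;
  it is a configurable flag, not a clinical rule.

Commissure marks place the reference commissure (default NL) at arc 0 and
walk NL → α → LR → β → RN; positions are reported in degrees and in mm
(angle × π·graft/360). Mark closure (arcs summing to the circumference)
holds to 1e-6.

## Agreement statistics

Differences are rater_b − rater_a; rater_a is the reference (expert), so
the error rate |b−a|/a·100 is deliberately asymmetric under rater swap
(asserted in a test), while absolute error |b−a| is symmetric. SEs are
sample SD/√n. The ICC is the two-way random-effects, absolute-agreement,
single-measure form ICC(2,1) with the F-based 95% CI (computed via
pingouin and cross-checked in the tests against a direct two-way ANOVA
variance-components calculation): the question posed — can the algorithm
*replace* the expert — requires penalizing systematic offsets, which
consistency-form ICCs ignore. Bland–Altman limits are bias ± 1.96·SD of
the differences; the fixed-error check is a two-sided one-sample t-test of
the differences against zero (p = 1/0 conventions for the zero-variance
degenerate cases). Multi-rater tables are handled pairwise plus a
mean-of-experts vs algorithm comparison.

Calibration facts the test suite verifies: simulated tables with case SD
3 mm and rater noise SD 1 mm give mean ICC ≈ σ_c²/(σ_c²+σ_n²) = 0.90
(±0.03 over 200 replicates of n = 50); Bland–Altman limits cover ≈ 95% of
normal differences; the fixed-error test holds its 5% nominal size.

## Synthetic roots

The generator emulates a CT landmark export: an elliptical ring of
semi-axes (a, b) sampled at 360 points in the z = 0 plane, nadirs on the
ring, commissures at radius r and per-commissure heights/angles on the
root axis. Ground truth is analytic — ellipse area πab, perimeter by the
complete elliptic integral of the second kind (machine precision),
commissure chords/circumradius in closed form — and always refers to the
noise-free, untransformed root, so rigid-transform equivariance and
noise-free recovery (areas/perimeters to 0.02% contour discretization,
distances to 1e-6 mm) are testable directly.

**Noise model.** Contour annotation error is spatially correlated —
workstation contours are smooth spline traces — so contour noise is a
smooth periodic perturbation (random Fourier harmonics of order 1–3,
radial and vertical, pointwise SD = `noise_sd`), while the discretely
annotated landmarks (nadirs, commissures) receive iid isotropic Gaussian
noise of the same SD. White per-point noise on a 360-point polygon would
triple its perimeter at 0.5 mm SD, which no human or algorithmic
annotation does; with the smooth model the estimated diameter stays
unbiased within 0.1 mm at 0.5 mm noise (Monte-Carlo, asserted).

**Cohort presets.** `ct_group` and `control_group` draw each parameter
from independent normals (truncated at physical bounds) whose means/SDs
emulate the preoperative CT statistics of a published surgical cohort and
its controls — e.g. estimated VBR diameter 28.0 ± 3.2 mm, CCA
1330.7 ± 403.3 mm², commissural heights 22.6/23.0/24.9 mm. The ring is
parameterized by circle-equivalent diameter and an ellipticity ratio
(mean 1.25 ± 0.15, truncated at 1) because an ellipse's area and
perimeter are not independently specifiable; cusp angles are drawn around
the published means and renormalized to 360°. AR grades follow the
cohorts' categorical frequencies.

What the emulation does **not** capture: correlations between parameters
(large roots have large CCAs in patients; draws here are independent),
non-planar saddle-shaped annuli, bicuspid or dissected anatomy, and any
real segmentation failure mode. Passing recovery tests therefore
demonstrates correctness of the geometry and planning arithmetic, not
clinical accuracy of any upstream landmark algorithm.

## Numerical conventions and problem sizes

Full precision is kept internally; CSV export rounds to 0.1 mm/°/% (the
clinical display convention), JSON is lossless. Contours use 360 points by
default (discretization error ≤ 0.005% in area). Degenerate inputs:
collinear nadirs/commissures raise errors; negative heights, clamped
radial offsets, oversize violations and low coaptation raise warnings or
plan warning codes, never silent changes. Stochastic test sizes — 200 ICC
replicates, 10,000 Bland–Altman differences, 1000 type-I replicates at
n = 50, 100-root cohorts — were chosen so that each check's sampling error
is well below the asserted tolerance while the whole suite runs in well
under a minute of statistics time.

## Limitations

- The commissural-position model assumes a circular planned ring; with
  very large sinuses (mean > 50 mm) the circle approximation of an oval
  root degrades, which the planner surfaces as the `SOV_GT_50` warning
  rather than attempting a correction.
- Effective height is carried as an input attribute only; no geometric
  recomputation is attempted.
- No DICOM, mesh, hemodynamic or bicuspid support; cusp-repair decisions
  beyond the low-coaptation flag are out of scope.
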