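# Methods

## Coordinate frame and geometric substrate

Every section lives in a per-section 2D frame: `x` lateral (µm), `z` axial
depth (µm) increasing posteriorly. Boundary curves (ILM, Bruch's membrane,
anterior lamina cribrosa surface, ALCS) are polylines with strictly
increasing `x` and linear interpolation between samples; all distance and
intersection queries are solved in closed form per segment, so polyline
inputs are measured exactly. Device-specific calibration (pixel-to-µm
scaling by corneal curvature) is assumed to have happened upstream: the
package takes µm-calibrated curves as given. A curve segment lying exactly
on a query line is reported as an explicit collinear-overlap error, never a
silent answer.

## Index definitions and conventions

* **BMO reference line**: the line through the temporal and nasal Bruch's
  membrane opening points; its length is the BMO width `W`.
* **HRW** (per rim side): distance along the BMO reference line from the
  BMO point to the nearest ILM–line crossing on that side of the point
  (temporal side: crossings with `x < bmo_temporal.x`; nasal mirrored).
  No crossing on a side flags the rim unmeasurable and the value is
  excluded from aggregation.
* **MRW** (per rim side): minimum Euclidean distance from the BMO point to
  the ILM polyline (segment projection, not vertex-only). This is the
  per-horizontal-section minimum, not the radial-scan BMO-MRW protocol.
  MRW ≤ HRW holds by construction (the HRW crossing is itself an ILM
  point), so per-section HMR = HRW/MRW ≥ 1.
* **LCCI**: perpendiculars dropped posteriorly from both BMO points to the
  ALCS define two foot points; the chord between them is the depth
  reference; `LCCD` is the maximum perpendicular depth of the ALCS below
  that chord, restricted laterally to the span between the feet (the
  lamina outside the opening is not considered); `LCCI = 100·LCCD/W`.
  LCCI is invariant under uniform scaling of the section and, like all
  indices, under rigid motions.
* **Laterality** is normalised at ingest so temporal is always smaller `x`.
* **HMR aggregation**: the ratio is formed per measurement (per rim side,
  per scan) and then averaged like any other index. It is *not* the ratio
  of the aggregated HRW and MRW means — for skewed rim distributions the
  two differ substantially.

## Per-eye aggregation protocol

Nine target scans per eye: offsets −2/0/+2 (scans two intervals apart,
32 µm per interval) at each of three locations placed at fractions 0.25,
0.5 and 0.75 of the vertical disc diameter (an explicit reading of
"equidistant", which is otherwise underdetermined). A scan obscured by an
overlying vessel is flagged and replaced by an adjacent (±1 offset) scan;
flagged scans never enter aggregation. The location value is the
unweighted mean of its usable scans (1–3); the eye value is the unweighted
mean of the three locations. Overall HRW/MRW average the temporal and
nasal sides with equal per-section weight; the temporal-only variants use
the temporal side alone. An eye with a scan-less location is flagged
`incomplete` and drops out of cohort analyses.

## Synthetic cohort generator

The generator emulates the study population so the full pipeline can be
exercised without imaging data. Three groups: NTG, CRAO, and healthy
fellow eyes of the CRAO subjects (same subject age and sex), 31 eyes each
by default. Per-eye latent indices and covariates are drawn from
independent truncated normals whose moments are the packaged group
parameter file (`data/group_parameters.yaml`); widths are truncated above
10 µm, LCCI above 0, and MRW* is constrained to ≤ 0.98·HRW* by truncating
its conditional draw (a bounded pair-resample handles HRW* draws that
leave no room). Truncated draws use inverse-CDF sampling, which is
distribution-identical to rejection resampling but deterministic and
loop-free. One root seed; per-eye child seeds derive from
(seed, group index, eye index), so cohorts are reproducible and
order-independent.

Geometry is *rendered to match the latent values*: in a canonical frame
(BMO line horizontal, temporal BMO point at the origin) the ILM of each
rim side runs from a peripheral tail through the reference-line crossing
at exactly HRW*, spirals in to graze the circle of radius MRW* around the
BMO point, and descends to the cup floor, with every other radius kept
above MRW*; the ALCS is a parabola through the perpendicular foot points
with apex depth LCCI*·W/100. The construct-then-measure residual is below
0.05 µm. The BMO width per scan follows the elliptical disc geometry
(disc area and ovality, long axis vertical): the horizontal chord at the
scan's vertical position. Each section is then rigidly rotated (small
random tilt, SD 0.4°, clipped so curves stay x-monotone) and translated —
transformations that provably change no index. Per-scan variability is
mean-preserving multiplicative jitter, `value·(1 + N(0, 0.02))` by
default; vessel shadows occur at rate 0.02 per target scan.

**What the generator does not emulate.** Indices are independent within an
eye apart from the MRW ≤ 0.98·HRW constraint; no within-group
HRW–LCCI correlation is imposed (between-group mean differences alone
produce the pooled negative association). Rim-side asymmetry, OCT speckle,
segmentation error and longitudinal change are absent. Consequently,
passing tests demonstrate that the *measurement and analysis machinery* is
correct and well calibrated on geometry with known truth — not that the
generator reproduces every joint property of real eyes. Two visible
consequences, documented rather than hidden: (1) the truncation pulls the
realised NTG mean MRW ≈ 20 µm below the nominal parameter (the nominal
MRW and HRW moments are mutually inconsistent with MRW < HRW for a
non-trivial share of draws), which only widens the MRW group separation;
(2) HMR, which is never sampled directly, comes out larger than the
printed group values because the independent draws put small MRW* under
large HRW* more often than real eyes do.

## Screening and matching

Exclusion rules are deterministic, order-independent, and strict at their
boundaries: incomplete CRAO, neovascular glaucoma, ovality > 1.3 or
torsion > 15°, more than five sections with quality score ≤ 15, spherical
equivalent outside [−8, +3] D (cylinder outside [−3, +3] D when recorded),
prior intraocular surgery, retinal/neurological disease, maximum IOP
> 21 mmHg, branch artery occlusion, glaucoma history. The fixture pools
(121 NTG, 90 CRAO) assign exclusion attributes to fixed leading row
blocks, so the exclusion counts (76 and 59) are exact, and embed one
near-duplicate NTG candidate per eligible CRAO eye so a full 31-pair
matched set exists. Matching is greedy nearest-neighbour on z-standardised
age, IOP at OCT, disc area and global RNFL, accepted only within
per-variable calipers (defaults 5 y, 3 mmHg, 0.3 mm², 10 µm — the matching
algorithm and tolerances are design choices, not reported values);
ties break lexicographically, making the result deterministic. Optimal
(Hungarian) and propensity matching were deliberately left out.

## Statistics

Three-group comparisons are gated per variable by Shapiro–Wilk at
α = 0.05 in every group: one-way ANOVA with Tukey HSD when all pass,
otherwise Kruskal–Wallis with Dunn's rank test, Bonferroni-corrected over
the three pairs (the post-hoc after Kruskal–Wallis is a design choice;
Dunn/Bonferroni is conservative, and an occasional significant omnibus
with no significant pair is expected behaviour). The post-hoc pattern
string (e.g. `NTG < CRAO < healthy`) orders groups by mean and joins
adjacent groups with `<` only when their pairwise test is significant.
Two-group comparisons are gated the same way (Welch t vs Mann–Whitney;
paired t vs Wilcoxon on differences, with all-zero differences returning
p = 1). Age is compared NTG vs CRAO only, since healthy fellow eyes share
subject age. Interobserver agreement is ICC(2,1) — two-way random
effects, absolute agreement, single measures — with the F-based 95% CI
computed from the mean squares. The HRW-on-LCCI association is ordinary
least squares pooled over NTG and CRAO; only its direction and
significance are meaningful claims. No multiplicity correction is applied
across variables, mirroring the analysis plan.

## Numerical choices and problem sizes

Polyline sampling in the renderer is curvature-adaptive (sub-0.05 µm chord
error near the minimum-rim arc; 10 µm-scale elsewhere); straight curves
carry only their defining vertices. Geometry tolerances: 1e-9 µm for
on-line tests, 1 µm for BMO-on-BM validation. Replicate studies use 200
cohorts of 31 eyes per group — large enough that the median of group
means is stable to a fraction of a standard error — and the null
calibration of the omnibus gate uses 1000 triplets of n = 31. Section
JSON is written at 2-decimal µm precision, which round-trips bit-
identically and is far below measurement noise.

## Known limitations

Horizontal-section MRW underestimates the true (radial) minimum rim
width; the generator's independence assumptions make HMR and within-group
correlations unrealistic; screening fixtures are engineered for exact
counts, so they validate rule logic, not prevalence estimation; and the
greedy matcher does not guarantee a maximum-cardinality matching in
adversarial configurations (the fixtures avoid them by construction).
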