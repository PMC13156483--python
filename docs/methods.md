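# Methods

This note documents the models and procedures craniomorph implements, the
parameter choices that matter, what the synthetic-cohort generator does and
does not emulate, and the numerical decisions a maintainer should know about.

## Coordinate conventions and the canonical frame

All 3D configurations live in a head frame with the midsagittal plane at
x = 0 (right positive), the anteroposterior axis y (anterior positive), and
the superoinferior axis z (superior positive); units are mm. Because
"projected" measurements (distances between parallel planes through two
landmarks) and the signed snout deviation are frame-dependent,
`align_canonical` fits this frame per specimen before they are evaluated:

* the midsagittal plane is the least-squares plane through the scheme's
  midline landmarks (the anterior nasal tip is deliberately excluded from the
  midline set, since it deviates laterally in asymmetric animals);
* the anteroposterior axis is the basion→nasion chord projected into that
  plane — a cephalometric-style anatomical chord rather than a principal
  axis, so the frame is pinned by two specific landmarks and does not rotate
  when other midline landmarks move;
* z completes the right-handed frame, with signs fixed by the bilateral pairs
  (right = +x) and the anterior/superior hints.

Linear, angular, and area measurements are frame-invariant and are evaluated
in the stored frame. The two hemimandibles are assumed co-registered in the
common head frame (required only by the bigonial span, which crosses sides).

## The measurement panel

A `MeasurementDefinition` maps named landmarks to a scalar: `linear`
(Euclidean distance), `projected` (|coordinate difference| along a canonical
axis), `angular` (vertex angle, degrees in [0, 180]), `area` (magnitude of
the polygon vector area), `span` (distance between the same landmark on the
left and right configurations), and `deviation` (signed axial-plane snout
angle). Root centroid size (RCS) is the square root of the summed squared
landmark distances from their centroid. Bilateral measurements are averaged
across sides *before* normalization; lengths are normalized by the
structure's RCS and areas by RCS² (the squared convention keeps area ratios
dimensionless; the linear alternative is not offered). Angles are never
normalized. Mandibular values are normalized by the mean of the left and
right hemimandible RCS. A missing side degrades to the present side with a
`single-<side>` provenance flag rather than dropping the specimen.

Snout deviation is the angle at the nasion between the internasal midline
reference point and the anterior nasal point, measured in the axial plane and
signed positive to the right. Grading is relative to the control group: with
m the largest control deviation magnitude, |d| ≤ m is *none*,
m < |d| < 2m is *mild*, |d| ≥ 2m is *pronounced*. The boundary cases are
unavoidable conventions: |d| = m grades *none* and |d| = 2m grades
*pronounced* by default (`boundary_pronounced_inclusive=False` moves the 2m
boundary to mild). The control "range" is interpreted as [0, max |d|] over
controls; a signed min–max interval would grade one-sided deviations
differently and is not implemented.

Eruption is scored from a cusp-state table (one row per specimen × jaw ×
cusp, states `fully_unobstructed` / `partially_covered` / `covered`): the
per-specimen score is the count of fully unobstructed cusp tips, summarized
per genotype with the percent difference vs the control mean.

## Univariate statistics

Group comparisons use the unpaired two-tailed Welch t-test
(Welch–Satterthwaite df). Two degenerate regimes are handled explicitly:
samples that are constant to machine precision with equal means give
t = 0, p = 1 (coordinate arithmetic through threaded BLAS can differ by one
ulp between analytically identical specimens, which must not masquerade as
evidence), and constant samples with materially distinct means give complete
separation (p = 0). FDR control defaults to the two-stage step-up
(`statsmodels` `fdr_tsbh`, the common desktop-statistics default behind
"FDR Q = 5"), with plain Benjamini–Hochberg selectable. A measurement is
flagged *meaningful* only when it is an FDR discovery **and** p < .01
(the stringent screen). Cohen's *d* uses the pooled n−1-weighted SD even
though the test is Welch — the two are conventionally paired in this
literature. Intraobserver CV uses the n−1 pair SD divided by the pair mean
(×100), replicable when < 10%. ICC(A,1) follows the two-way,
single-rater, absolute-agreement definition,
ICC = (MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE)), with the standard
F-based 95% interval; it is cross-checked against an independent
implementation in the tests. The two-way ANOVA for staining-ratio tables is
an ordinary balanced OLS decomposition via statsmodels.

By convention each experimental genotype is compared to control only;
comparing the two experimental groups requires an explicit
`allow_cross_experimental` override.

## Geometric morphometrics

Ordinary Procrustes superimposition centers both configurations, scales the
moving one to the target's centroid size, and applies the optimal *proper*
rotation (SVD with the last singular direction flipped if needed; reflections
are never part of the optimum — mirroring of right-side outlines is always an
explicit, involutive step). Generalized Procrustes analysis scales every
configuration to unit centroid size and alternates rotation-to-consensus with
consensus re-estimation until the summed squared deviation changes by less
than 1e-10 (cap 200 iterations; non-convergence returns a flagged result).
Semilandmarks are treated as fixed points — no sliding.

Shape PCA decomposes the aligned coordinates about their mean; axes
explaining more than 10% of shape variance form the retained set used by the
multivariate model (the threshold is configurable). Reconstruction from all
axes is exact to numerical precision.

The multivariate model (`ShapeMANCOVA`) regresses shape scores on categorical
factors (sum-to-zero contrasts; interactions as column products) and a
centered log-centroid-size covariate. Inference is by residual randomization:
for each term, the type III sum of squares is the residual-SS difference
between the model without that term and the full model; the null distribution
permutes the reduced-model residuals (the observed arrangement is always
counted, so p ∈ [1/(iterations+1), 1]). Permutation tail counts use a
1e-12 relative tie tolerance so exactly degenerate constructions (e.g. a
planted common slope) count their ties as exceedances rather than splitting
them on floating-point noise. Pairwise group tests measure Euclidean
distances between group mean vectors (null: the model without the group
term); pairwise allometry tests compare per-group slope vectors of shape on
centered log size by angle and length difference (null: the common-slope
model). Default iterations are 10 000 with an explicit seed.

**Exchangeability caveat.** RRPP permutes observation rows. When both
hemimandible outlines of a specimen enter the model, their residuals share
the specimen's individual shape variation and are not exchangeable rows; the
permutation null is then anticonservative for specimen-level factors. The
pipeline mirrors the two-sides-with-a-side-factor design this literature
uses, but calibration claims (and the model-reduction recovery test) are
made on independent-error data. For confirmatory work on real data, analyze
one side per specimen or side-averaged shapes.

**Model reduction.** Backward elimination repeatedly drops the
highest-p non-significant term, interactions strictly before the main
effects they contain; the log-size covariate is protected and never dropped.
Specimen identity is not a default term: with one genotype per animal it is
perfectly aliased with genotype, and supplying it raises the collinearity
error naming the aliased terms. The reduction's significance level defaults
to 0.05 for exploratory use, but the recovery test uses the stringent 0.01:
with ~5–6 null candidate terms, per-term retention at level α makes the
chance of the clean final model roughly (1−α)⁵ — about 77% at .05 and about
95% at .01 — so the stringent level is what makes "only the real terms
survive" the expected outcome rather than a coin flip.

## The synthetic-cohort generator

The generator emulates a three-genotype (control / LOF / GOF) P10 mouse
micro-CT study: 6 + 6 + 8 animals by default, each contributing a 28-landmark
cranium, two 11-landmark hemimandibles, and two 59-point lateral outlines of
the coronoid–condylar–angular process region. The templates are exactly
bilaterally symmetric functional stand-ins (named midline points and
mirrored pairs at plausible P10 proportions), not a digitized atlas.

**Planted effects.** The effect map assigns signed percent changes to named
panel measurements per genotype; the defaults are the magnitudes such a study
reports (midface hypoplasia, wider transverse widths and shorter molar fields
in LOF; macrocephaly, shorter palate, longer zygoma, micrognathia, process
dysmorphology and wider bigonial span in GOF). Each effect displaces a fixed
"mobile" landmark subset along a fixed direction; all displacement magnitudes
of a genotype are solved *jointly* (Newton/least-squares to 1e-10 relative)
so that every planted measurement — by default the centroid-size-normalized
value, since that is the scale percent changes are reported on — hits
template × (1 + pct/100) exactly at zero noise, even when effects share
landmarks. `plant_on="raw"` plants raw-value targets instead. Unsolvable
demands (e.g. a negative area) raise an effect-conflict error naming the
measurements.

Because normalized values are coupled through centroid size, the solver also
constrains each affected structure's RCS to the template value (the study
conditions include unchanged cranial and mandibular centroid sizes). The
constraint is satisfied by rigidly translating the block of landmarks that no
planted measurement touches along the anatomical anteroposterior chord — a
rigid translation leaves every unplanted within-block measurement, every
cross-side span, and the chord-pinned projection frame untouched, so planted
effects are exact *and* unplanted measurements carry zero systematic drift.
If a custom effect map leaves no free block, a uniform scale is used instead
(then unplanted normalized values shift together by the scale factor).

**Randomness.** One counter-based Philox stream per cohort drives everything:
lognormal size multipliers (σ = 0.03, litter-scale scatter), isotropic
per-coordinate landmark noise (σ = 0.04 mm, chosen to give within-group CVs
of roughly 1–2% across the panel — the low-noise regime implied by
intraobserver CV well under 10%), balanced shuffled sexes, asymmetry
assignment, and outline variation. The construction order per specimen is:
genotype effects (template-level, deterministic) → size scaling → snout
rotation → noise.

**Asymmetry.** Exactly round(penetrance × n) specimens per genotype are drawn
without replacement and given a rightward rotation of the anterior nasal
landmark about the canonical vertical axis through the nasion, with the angle
uniform on a configurable range (default 2–10°). Defaults are penetrance 0.5
for LOF and 0.375 for GOF — three affected animals in each mutant group, with
controls at zero. Because grading is relative to the noisy control maximum,
unaffected mutants can occasionally grade mild by chance, exactly as in a
real control-referenced classification.

**Outlines.** The 59-point outline is a periodic spline through anatomical
anchors (coronoid peak, sigmoid notch, condylar head, angular process,
ventral border); the right side is the mirrored left plus independent noise.
GOF outlines carry a smooth dysmorphology field (shorter, flatter coronoid;
pinched condylar neck; down-tilted angular process; ~0.6 mm peak
displacement), and a per-genotype allometric field — oriented along the
negative dysmorphology direction, so smaller animals lie further toward the
dysmorphic shape — scaled by log size (default slope 10 mm per log-unit in
GOF only). Three low-frequency sinusoidal modes (σ = 0.3 mm each) add
specimen-level shape variation shared by the two sides, which spreads the PC
spectrum over several axes as real cohorts show.

**Eruption.** Cusp counts target the control baseline (mean 8 of 13 cusps
fully unobstructed) times (1 + pct/100) per genotype and jaw, with ±0.7-count
rounding jitter; defaults plant the LOF delays (−46.5% mandibular, −36.5%
maxillary).

## What passing tests do and do not show

The generator provides exact ground truth, so the test suite demonstrates
that the pipeline recovers what was planted: percent changes to ±1.5 points
at study sample sizes and exactly at zero noise, penetrance counts exactly,
calibrated type-I error for the Welch and RRPP tests, and FDR control in
mixed simulations. It does not demonstrate performance on real micro-CT
data: real landmarking error is anisotropic and landmark-specific, real
effects deform whole bones rather than measurement-defining subsets, real
within-group shape variation is not three sinusoidal modes, and real
hemimandibles are digitized, not mirrored copies. The generator also cannot
say which FDR variant or projection frame the original software used; both
FDR procedures are provided and the frame is fully specified here.

## Numerical choices

* GPA convergence 1e-10 on the objective, 200-iteration cap; consensus
  rescaled to unit centroid size each sweep.
* Rotations via SVD with determinant correction; degenerate (all-coincident)
  configurations are rejected.
* Permutation p-values count the observed arrangement; tail comparisons use a
  1e-12 relative tie tolerance.
* Welch degeneracy thresholds: within-sample SD ≤ 1e-12 × mean scale counts
  as constant; mean difference ≤ 1e-9 × scale as equal.
* The angle at a zero-length arm returns 0 with a degeneracy flag by default
  (`on_degenerate="raise"` to fail instead).
* Landmark CSVs are written at 17 significant digits and parsed with
  round-trip float precision, so cohort files are coordinate-lossless.

## Known limitations

* The landmark schemes are functional stand-ins sufficient for the panel, not
  a reproduction of any published atlas (the cranial scheme carries 28
  landmarks — 10 midline, 9 bilateral pairs — the minimum that expresses the
  panel without forcing planted effects to fight over landmarks).
* Mandible measurements assume co-registered hemimandibles; there is no
  cross-side registration step.
* The RRPP row-exchangeability caveat above applies to any design with
  repeated observations per specimen.
* No thin-plate-spline warps, sliding semilandmarks, image handling, or bone
  density/microarchitecture analysis; eruption enters as a scored table, and
  staining ratios as a numeric table.
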