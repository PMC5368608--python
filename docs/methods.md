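# Methods

This note documents the models, defaults and numerical choices behind
`cinestrain`, and what the synthetic validation does and does not show.

## 1. Deforming phantoms with closed-form strain

**Short-axis annulus.** The myocardial ring is modelled as a 2-D annulus
(default R_endo = 25 mm, R_epi = 33 mm — a normal-sized mid-ventricular LV)
contracting incompressibly. The endocardial radius follows
R_endo(t) = R_endo·(1 − a·s(t)) with contraction fraction a (default 0.2,
i.e. 20% peak endocardial radius reduction, matching normal endocardial
circumferential shortening) and a raised-cosine systolic waveform s(t)
rising 0→1 at the peak frame and returning to 0 at the cycle end. Area
conservation between the endocardium and any material circle fixes the
kinematics:

    r′(r, t) = sqrt(r² − R_endo² + R_endo(t)²)

which gives exact engineering strains Ecc = r′/r − 1 and Err = r/r′ − 1.
Incompressible wall thickening alone therefore produces an
endocardium-to-epicardium circumferential strain gradient (|Ecc| strictly
decreasing in r) — the transmural gradient the pipeline must recover. The
cavity (r < R_endo) deforms by uniform scaling, continuous with the annulus
map, so the whole image warp is smooth and invertible.

**Long-axis band.** A straight vertical wall strip (default 80 × 8 mm)
whose material points slide along the midline such that the local
longitudinal engineering strain equals ε(s, t) = s(t)·[ε_base +
(ε_apex − ε_base)·s], linear in the normalized base-to-apex coordinate s.
Defaults ε_base = −24.0%, ε_apex = −13.2% mirror normative basal and apical
longitudinal shortening; the base anchor is fixed (the apex moves toward
the base), approximating atrioventricular-plane descent viewed from a
base-fixed frame.

**Imaging.** Both phantoms render a fixed band-limited Gaussian random
texture (correlation length 3 mm, unit SD) sampled at the analytically
inverted deformation, with additive white Gaussian noise (SD 0.05, i.e.
SNR ≈ 20 — a clean cine acquisition). 25 frames per cycle and ~1 mm pixels
match routine reconstruction. The phantoms deliberately do **not** model MR
physics (bSSFP banding, coil shading, through-plane motion, twist); passing
phantom recovery demonstrates that the tracking/strain chain is correct on
in-plane deformations with known truth, not that it is robust to every
acquisition artifact of real cine data.

## 2. Tracking

The vendor deformation-registration algorithms used for pixel-wise
feature-tracking strain are unpublished, so tracking here is a documented
equivalent whose every parameter is exposed:

* **Pairwise registration:** SimpleITK fast symmetric-forces demons on a
  3-level pyramid (shrink 4/2/1; 60/40/30 iterations; pre-shrink Gaussian
  smoothing σ = shrink/2 px), Gaussian regularization of the update field
  (σ = 2 mm, fluid-like) and of the displacement field (σ = 1 mm,
  diffusion-like). Deterministic; no stochastic sampling.
* **Reference-to-frame fields:** consecutive pairwise fields composed with
  bilinear interpolation outward from the end-diastolic reference frame
  (the Lagrangian convention — strain needs material tracking), then each
  composed field is **refined** by 30 full-resolution demons iterations
  registering the reference directly to that frame, initialized at the
  composition. Composition alone accumulates a per-step regularization
  bias that flattens transmural strain gradients; the direct refinement
  removes it (phantom layer-mean Ecc bias drops from ~1.5 to ~0.3
  strain-points) while the sequential pass supplies a capture-range-safe
  initialization.
* **Drift correction** (on by default): one extra registration from the
  last frame back to the reference measures the full-cycle residual, which
  is subtracted from the composed fields with a linear ramp in frame
  number, enforcing near-zero displacement after a full cycle.
* Convergence is reported, never silently ignored: each field carries the
  final demons RMS change and the full-resolution warped MSE after every
  pyramid level (monotone by construction of the refinement schedule).

Registration is strictly 2-D per slice/view, as in per-slice clinical
feature-tracking analysis; through-plane motion is out of scope.

## 3. Geometry

Contours live in physical mm (pixel centers at integer multiples of the
spacing; index (0,0) at the origin). The myocardial mask is center-sampled
point-in-polygon (inside epicardium, outside endocardium). Transmural depth
is d = dist_endo / (dist_endo + dist_epi) from exact point-to-polyline
distances — a dual signed-distance construction valid for non-circular
contours, linear in radius for concentric circles. Layers split at
d = 1/3 and 2/3 with half-open intervals [0,1/3), [1/3,2/3), [2/3,1]; a
pixel exactly on a boundary line goes to the outer layer (the boundary
rule is not specified anywhere authoritative; the tie-break is documented
and tested). Radial directions point outward from the endocardial centroid;
circumferential is the +90° rotation. The six wall segments (Ant, Antsep,
Sep, Inf, Post, Lat) are equal 60° sectors clockwise from a user-supplied
anterior reference ray — the anatomical anchor (RV insertion) cannot be
inferred from a single contour pair, so it is a required input.

Level selection in a base-to-apex stack: basal = first slice excluding the
outflow tract (user input), mid = middle slice (ties toward the apex),
apical = midpoint of apex and mid slices rounded toward the apex. For the
4-chamber view, basal/mid/apical are equal thirds of the wall-midline arc
length (the source convention is unstated; equal thirds is the symmetric
choice and is tested as such).

## 4. Strain

Strain is the **directional engineering strain** ‖F·e‖ − 1 with
F = I + ∇u computed by central differences in mm (one-sided at image
borders), reported in %. Engineering strain is chosen because it makes the
annulus oracle exact (Ecc = r′/r − 1); directional Green–Lagrange,
e·(FᵀF−I)e/2, is available via `measure="green"`. Peak systolic strain is
the signed whole-cycle extremum of the **region-mean** curve (maximum for
Err, minimum for Ecc/Ell, earliest frame on ties) — averaging before peak
detection, since region curves are what the workflow displays and reports;
pixel-wise peaks averaged afterwards would be systematically larger.

## 5. Cohort simulator

Per subject and strain direction, the six regional peaks (three layers,
three levels) are drawn from a multivariate normal: sex-specific means
(defaults = the published sex-stratified normative tables; 70 female / 60
male at n = 130), the pooled normative SDs, and an exchangeable
within-subject correlation ρ = 0.6. ρ is unreported in the source tables —
0.6 is a typical within-subject correlation for regional strain measures
and is an exposed assumption, not a fitted value. Age is truncated-normal
(47.3 ± 16.9 years on [18, 83]); for a cell with reported age correlation
r the value is μ + σ(r·z_age + sqrt(1−r²)·z), which preserves the marginal
SD and targets the sample correlation. Age effects are applied to the
signed strain value (positive r = value increases with age); the reported
correlations carry no explicit sign convention for negative-valued
strains. Level-cell age correlations are unreported and default to zero.
Globals and gradients are always derived from the drawn cells with the
exact aggregation rules, never drawn independently.

One printed sex-stratified cell (female endocardial Err, 39.5%) is
internally inconsistent with the pooled table (34.2%) and its own printed
p-value (0.759 against male 34.0%); the default uses the reconstructed
34.5%, which restores both. The pooled normative global Ell (−15.4%)
equals the mean of the *layer* means rather than the level means (−17.3%)
that the stated global rule produces; the level-mean rule is implemented
as stated and the inconsistency left with the source.

## 6. Statistics

* Normality: Shapiro–Wilk at α = 0.05 per condition; all-normal →
  repeated-measures ANOVA with Tukey post-hoc, otherwise Friedman.
* The RM-ANOVA F and Tukey q are computed directly from the two-way
  (subject × condition) mean squares, vectorized over replicate axes so
  that calibration studies (5,000-replicate type-I error) run in seconds;
  the implementation is cross-checked against pingouin in the test suite
  and against a hand-worked table.
* ICC: two-way mixed-effects, absolute agreement, single measurement —
  ICC(2,1) = (MSR − MSE)/(MSR + (k−1)MSE + k(MSC − MSE)/n) — the standard
  choice for intra-/inter-observer imaging studies (matches pingouin's
  ICC(A,1)).
* Within-subject CV = (SD of paired differences / √2) / grand mean of
  |measurements| × 100. A pure constant offset gives CV = 0 by design:
  systematic bias belongs to Bland–Altman (bias = mean(first − second),
  95% limits = bias ± 1.96·SD), not to CV.
* Regression: univariable Pearson r + slope, multivariable OLS
  (statsmodels); rank-deficient designs are rejected naming the collinear
  columns.

## 7. Problem sizes and numerical choices

Tests run the phantoms at 96–128 px and 9–25 frames — sizes at which the
closed-form recovery tolerances (layer-mean peak Ecc within 1.5
strain-points, median endpoint error < 0.5 px) hold with margin; the
acceptance phantom uses the full default conditions (128 px, 25 frames,
default noise). Monte-Carlo checks use 10⁴–10⁵ subjects for moment
recovery and 5,000 replicates for the ANOVA type-I calibration. All
randomness flows through explicit integer seeds (`numpy.random.default_rng`);
registration is deterministic, so end-to-end runs are bit-reproducible.

## 8. Known limitations

* Radial strain near the endocardium is recovered with a larger negative
  bias than Ecc (the radial derivative of u across an 8-px wall is the
  hardest quantity for any regularized registration); the source cohort
  itself reports radial strain as heterogeneous and highly variable, and
  no radial recovery tolerance is claimed.
* Longitudinal layer structure in the band phantom is transmurally uniform
  by construction, so it validates level (base–apex) decomposition but not
  transmural Ell gradients.
* No torsion/twist, strain rate, diastolic indices, 3-D registration, or
  automatic segmentation; contours are inputs.
* The phantom noise model (additive white Gaussian on a smooth texture) is
  a lower bound on the difficulty of real cine data.
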