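# Methods

## Cast geometry

All geometry is landmark-derived; nothing depends on the axes a cast was
scanned in, and every measurement is rigid-motion invariant (verified to
1e−6 mm in the tests). Coordinates are millimetres throughout — STL files
carry no units, so this is asserted, not detected.

**Reference planes.** The *gingival plane* is the total-least-squares plane
through the palatal dento-gingival junction midpoints of all teeth: the SVD
of the centred point cloud gives the direction of least variance as the
normal. Sign conventions make every plane deterministic: the
largest-magnitude normal component is taken positive, and oriented
(clipping) planes are flipped so that the anatomical interior — the vault
side, identified by the mid-raphe landmark, or the anterior side, identified
by the incisive papilla — is the negative half-space. The *mid-palatal
plane* contains the least-squares line through the three raphe landmarks
projected onto the gingival plane and is orthogonal to it by construction
(the orthogonality residual is asserted below 1e−9). The *posterior plane*
is transverse (orthogonal to both) through the midpoint of the most-distal
palatal points of the terminal teeth. A general transverse-plane
constructor is exposed for per-antimere planes, but no default measurement
binds to it.

**Missing landmarks.** A missing landmark is data, not an error, provided
its antimere exists. Completion reflects the whole configuration across the
current mid-sagittal estimate, relabels left/right names, rigidly
superimposes the mirrored copy onto the original over all shared landmarks
(Kabsch/Procrustes, rotation + translation, no scaling, single pass), and
reads the missing coordinate off the superimposed copy. On an exactly
symmetric cast this restores the mirror image to machine precision; under a
structured 0.1–0.2 mm left/right asymmetry the imputation error stays below
0.2 mm in the generator-based tests. Midline (raphe) landmarks cannot be
imputed this way and must be present.

**Depths.** Anterior and posterior depth are the distance from the
inter-canine and inter-molar dento-gingival lines to the deepest point of
the vault on the mid-palatal raphe. Operationally, candidate vertices lie
within ±0.5 mm (configurable) of the mid-palatal plane *and* of the
transverse plane containing the reference line, on the vault side of the
gingival plane; the depth is the maximum drop below the line measured along
the gingival normal. At the deepest point that drop equals the
perpendicular point-to-line distance (a half-cylinder of radius 10 under
the line yields exactly 10), and a flat palate correctly yields zero. The
band makes the measure robust to tessellation; the residual bias is
O(band²/depth), about 0.03 mm at the defaults.

**Area and volume.** The palate is clipped by the gingival and posterior
planes (triangles straddling a plane are split; vertices within 1e−7 mm of
a plane count as interior). Surface area sums the clipped vault triangles
only — cap polygons are excluded, since the trait is the area *of the
palate*, while the volume is the *enclosed* region. Volume uses the
divergence theorem with the reference origin placed on the intersection
line of the two clipping planes: both planar caps then contribute zero
flux, so the enclosed volume is the (absolute) signed-tetrahedron sum over
the vault triangles alone and the caps never need triangulating. A
precondition check verifies that every open boundary edge lies on one of
the clipping planes; anything else is reported as non-closable. Against
closed forms, a hemisphere's area and a half-ellipsoid's volume are
reproduced within 1% at icosphere subdivision 5, and clipped-cube volumes
are exact to 1e−9.

## Synthetic data

**Twin traits.** Pairs are drawn from a bivariate normal with common mean,
total variance V and within-pair correlation r_MZ = A + C + D,
r_DZ = A/2 + C + D/4, where A, C, D, E are the standardized variance
components (non-negative, summing to one, C and D never both positive —
they are not separately identifiable in twins reared together). Simulating
at the trait level rather than via genomes is exact for this model class,
which constrains only second moments. Longitudinal cohorts draw each stage
independently (the per-stage univariate analyses never use the cross-stage
correlation); attrition removes whole pairs uniformly at random within
zygosity, i.e. missing completely at random. Pairs share sex. Everything is
deterministic given the seed.

Default conditions are the study sizes this package models: 104 MZ + 124 DZ
pairs, three dentition stages (primary/mixed/permanent, mean ages
5.8/9.4/14.3 years) with attrition to 170 pairs at the permanent stage, and
per-stage trait means, SDs and variance components typical of palatal
dimensions in children (e.g. posterior depth 10.6 ± 1.3 mm with A = 0.89 in
the primary dentition; palatal area 753.7 ± 78.4 mm² with A = 0.37,
C = 0.32).

**Palate casts.** The vault is a laterally tapered dome: superellipse
cross-sections (degree 2.5) lofted along the raphe axis, with half-width
and depth profiles interpolated by cosine blends so that the slopes vanish
at the canine and molar reference lines. That choice is what makes the
ground truth exact: canine and molar dento-gingival landmarks sit exactly
`anterior_width`/`posterior_width` apart, the vault apex depths under those
lines are exactly the depth parameters (the zero slope keeps the band
search from drifting), and the papilla sits exactly `ap_length` anterior to
the distal plane. All dento-gingival landmarks lie on the z = 0 rim, so the
gingival plane is exact. Reference area comes from Gauss–Jacobi quadrature
of the parametric surface — the area element has an integrable
(1 − u²)^(1/q − 1) rim singularity (the wall is vertical there), which that
weight absorbs; volume has a semi-closed form via the superellipse fill
factor 2B(1/q, 1 + 1/q)/q. The optional asymmetry perturbation rotates the
right-side landmarks rigidly about the raphe axis (largest displacement ≈
the parameter, in mm) — a structured left/right difference like real casts
show, which the mirroring completion can largely compensate, rather than
per-landmark noise, which nothing could recover.

What the generator does *not* emulate: rugae and surface texture, tooth
crowns (landmarks are placed directly, so landmarking error is out of
scope), gingival margin curvature (the rim is planar), and
non-convex vault profiles. Passing tests therefore demonstrate correctness
of plane construction, clipping, integration and the estimators — not
robustness to digitization error on real casts, which the method-error
tooling is for.

## Descriptive and reliability statistics

Descriptive tables give mean, SD (n − 1) and n per stage × trait ×
{Overall, M, F, MZ, DZ}; percent change from the primary dentition is
100 (m_stage − m_primary)/m_primary to one decimal. The intraclass
correlation is the one-way random-effects form for clusters of two,
(MS_between − MS_within)/(MS_between + MS_within) — twin pairs have no
rater structure, and the estimate is exactly invariant under within-pair
swaps. Duplicate-measurement error reports both Dahlberg √(Σd²/2n) and the
mean-corrected method-of-moments estimator √(Σ(d − d̄)²/2(n − 1)); the two
differ exactly by the systematic offset term (Dahlberg² = MME²(n−1)/n +
d̄²/2), so reporting both separates random from systematic error.
Two-sample comparisons default to Welch's t (a flag restores pooled-variance
Student's t) with a Bonferroni threshold α/m, m defaulting to the seven
traits. Twin data are clustered by family; the naive two-sample tests
ignore that, so every comparison row carries a `clustered` caveat flag (the
type-I error simulations in the tests show the inflation on heritable
traits). The family random-intercept model is fitted by maximum likelihood
through statsmodels MixedLM (ML, not REML), with derivative-free fallbacks
when the family variance sits on the zero boundary.

## Twin variance-component models

The joint MZ + DZ likelihood depends on the data only through per-zygosity
sufficient statistics (n, Σ(x₁+x₂), Σ(x₁²+x₂²), Σx₁x₂), and for any fixed
standardized composition the grand mean and total variance have closed-form
MLEs (mû = β/α with (1+r)-weighted first moments; V̂ = Q(mû)/2N). Fitting
therefore reduces to a deterministic bounded search over the standardized
simplex: one-dimensional (Brent) for AE/CE, two-dimensional (Nelder–Mead
from the method-of-moments start plus two fixed perturbations, with
explicit single-component edge polishing) for ACE/ADE, and trivial for E.
No random starts, no seeds; identical data give identical fits, and
components may sit exactly on the zero boundary. The optimum matches an
independent dense grid search over raw (a, e, mu) within 1e−3 in −2lnL on
small fixtures, and the saturated model (closed form from per-group MLE
moments) bounds every structured fit from below.

A single grand mean is shared across zygosities and twins (no mean
structure is modelled). Fitting happens on the raw trait scale and is
standardized afterwards, so V is reported in trait units². Free parameters
count the simplex coordinates plus V and mu (AE: 3, ACE/ADE: 4, E: 2);
AIC = −2lnL + 2k.

**Selection** follows the standard ladder: each sub-model is tested against
the full model of its branch (ACE; ADE for the dominance branch) by χ² LRT
at α = 0.05, survivors are ranked by parameter count, and AIC breaks ties
among equally simple non-nested survivors (AE vs CE). The naive χ²
reference is the default; the 50:50 boundary mixture for a variance
component pinned at zero is available behind a flag, and the null
simulations confirm the naive test is conservative there. DE is excluded
from the default candidate set — dominance without additive variance is
biologically implausible — but can be requested explicitly.

**Confidence intervals** are profile-likelihood: each bound of a
standardized component is where the concentrated −2lnL rises by the χ²₁
95% quantile (3.841), found by bisection with the at-most-1-D inner
re-optimization, clamped to [0, 1]. Coverage at the default study size is
inside [90%, 98%] in the simulation tests. A component estimated at zero
gets a lower bound of exactly zero.

**Heritability** is h² = a²/V — the dominance share is excluded from the
numerator but kept in the denominator for ADE fits.

## Problem sizes and numerical choices

The test suite and the acceptance script use 500 simulate-and-refit
replicates for parameter-recovery checks, 300–400 replicates for coverage
and type-I error, icosphere subdivision 5 (~20k faces) for analytic-shape
oracles, and 0.25–0.5 mm tessellation for synthetic casts; these sizes make
the Monte-Carlo error comfortably smaller than the tolerances they are
checked against. Scalar searches run to xatol 1e−12 (1-D) and the simplex
search to fatol 1e−9, just above the float noise of a −2lnL of order 10³.
Clipping classifies vertices within 1e−7 mm of a plane as interior to avoid
sliver triangles; plane orthogonality and unit-normal invariants are
enforced at 1e−9.

## Known limitations

* No multivariate or longitudinal (Cholesky) twin models; each trait ×
  stage is analysed univariately.
* No sex-limitation or gene–environment interaction models; random mating,
  equal shared environments for MZ and DZ, and no G×E covariance are
  assumed.
* No REML option for the mixed model, and no age/sex adjustment before the
  variance-component fits (sexes are pooled).
* Mesh handling is limited to STL and degenerate-face dropping; no mesh
  repair, automatic landmarking, or curvature-based shape analysis.
* The naive two-sample comparisons ignore twin clustering (flagged per row).
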