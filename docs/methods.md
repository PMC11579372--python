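# Methods

`tdcshead` is a synthetic test bed for a causal question in neurostimulation:
do people with psychosis receive a weaker transcranial direct-current
stimulation (tDCS) field at the dorsolateral prefrontal cortex (dlPFC), and
is that difference driven by BMI through scalp thickness?  The package
implements every computational stage of that question — head model, field
physics, tissue geometry, cohort statistics, causal mediation — on phantoms
and synthetic cohorts where the ground truth is known, so each stage can be
validated against an independent reference.

## Head phantom

The head is a concentric five-tissue sphere: scalp, skull, cerebrospinal
fluid (CSF), gray matter, white matter.  Default outer radii are 78 / 71 /
65 / 63 / 60 mm, i.e. layer thicknesses of 7 mm scalp, 6 mm skull, 2 mm
CSF and 3 mm gray matter — adult frontal-anatomy scale.  A sphere has no
gyral folding; the mechanism under study (layer thickness attenuating an
injected current) survives that simplification, and spherical geometry is
what makes analytic cross-checks possible for both the field solver and the
thickness algorithm.

Meshing places points on concentric Fibonacci-lattice shells — one shell
per tissue boundary plus fill shells so no radial gap exceeds the target
edge length (default 5 mm; the interior below 55 mm radius is coarsened by
×1.7 since nothing is measured there) — and triangulates them jointly with
Delaunay.  Elements are labeled by the radial band containing their
centroid, with boundary ties assigned outward.  The only randomness is one
rotation per shell from a seeded generator, so a fixed seed reproduces the
mesh byte-for-byte.  Note the 5 mm default edge exceeds the 2 mm CSF layer,
which the constructor warns about: labels in that shell are noisy at the
element scale but correct on average, and every validation tolerance is
stated in units of the edge length.

Electrodes are 5×5 cm, 5 mm thick sponges (saline conductivity 1.0 S/m)
at phantom analogues of the 10-10 positions Fp1, Fp2 and F3 (anode left,
as in frontal tDCS for cognition).  The square footprint is selected in
geodesic coordinates on the curved scalp, giving areas within a few percent
of 25 cm²; the patch is extruded radially and each surface prism is split
around its centroid into eight tetrahedra, with shared quad faces cut along
the diagonal through the smallest global node index so neighbouring prisms
conform.  Attachment never relabels head elements.

## Field solver

The stimulation field obeys the quasi-static conduction equation
∇·(σ∇φ) = 0 with isotropic per-tissue conductivity, E = −∇φ.  Defaults
(S/m): scalp 0.465, compact-bone skull 0.010, CSF 1.654, gray matter 0.275,
white matter 0.126, sponge 1.0.  Discretisation is first-order (P1)
tetrahedral FEM with element-wise constant fields.  Boundary conditions are
Dirichlet: +1 V / −1 V on the two sponge contact surfaces, and the linear
solution is rescaled to the montage's target current (2 mA default), which
solves the target-current problem exactly.  Small systems (≤ 20 000 free
nodes) use a sparse direct factorisation; larger ones a
Jacobi-preconditioned conjugate gradient at relative tolerance 1e-10.

The injected current is the sum of discrete nodal residuals K·φ over a
contact node set — the FEM-consistent flux, so anode and cathode currents
cancel to rounding by construction; an independent test integrates σE·n
over an interior separating surface instead.

Solver validation uses two analytic references: (i) a homogeneous slab with
full-face plate electrodes, where the field is uniform and the FEM is exact
to machine precision; (ii) the classic three-shell sphere (radii 80/85/92
mm, conductivities 0.33/0.0042/0.33 S/m) against an independent Legendre-
series solution for point current injection at antipodal poles, written
with per-layer scaled radial bases so the series is stable to high order.
Because the FEM uses finite Dirichlet caps (15 mm geodesic radius) and the
series uses point electrodes, potentials are compared after aligning the
additive constant (a current-source potential is defined only up to a
constant, and unequal discrete cap footprints shift the FEM zero level),
on radial samples at polar angles 50°–130°, i.e. away from the electrodes.
At 4 mm edge length the offset-aligned relative L2 discrepancy is ~1.2 %.

ROI field extraction averages |E| over elements whose centroid lies within
a 10 mm ball (20 mm variant available) around a gray-matter target, volume-
weighted by default (an unweighted flag exists for sensitivity checks), and
restricted to gray-matter elements by default with a flag to include all
tissues.  The dlPFC analogues are fixed unit directions at mid-gray-matter
radius; real-head MNI coordinates are metadata only, since no MRI transform
exists for a phantom.  An empty ROI raises rather than returning zero.

## Tissue-thickness algorithm

Thickness at a location is measured by walking inward from the scalp
surface.  Sources are outer-scalp boundary triangles within a 10 mm ROI of
the location.  For each source triangle centre the algorithm finds the
nearest point anywhere on the target tissue's boundary surface (exact
point-to-triangle projection, KD-tree candidate pruning with a safe search
radius, ties broken by lowest face index), accepts the measurement only if
the direction to the foot point lies within 45° of the source's inward
normal (the perpendicularity check, applied at every layer), and averages
accepted distances.  The unique foot-point triangles then seed the next
layer: scalp→skull gives scalp thickness, skull→CSF skull thickness,
CSF→gray CSF thickness, and gray→white cortical thickness.  Scalp-to-cortex
thickness is the sum of the first three by definition — cortex is reported
alongside but deliberately excluded from the aggregate.  The ROI ball is
Euclidean rather than geodesic (negligible difference at 10 mm on
head-scale curvature).

Distances run from surface-triangle centres, not tetrahedron centroids:
centroid-to-centroid measurement would overestimate each layer by about
half an element, and on a flat slab the surface convention recovers layer
thicknesses exactly, which is the test that pins the convention down.  On
the sphere phantom each layer is recovered within half an edge length.

## Synthetic cohorts

`simulate_cohort` draws three groups with the demographic structure of the
motivating psychosis cohort: BMI means (SD) 25.5 (5.5) for controls, 31.4
(7.4) for psychosis, 29.1 (6.6) for first-degree relatives; ages ~38/39/45
(SD ~13); male fractions 0.48/0.57/0.32.  BMI and age are truncated
normals (BMI in [14, 60], age in [18, 90]) whose location is solved so the
*truncated* mean equals the target — truncation would otherwise bias the
group means upward by ~0.2 kg/m².  An optional medication mixture draws
psychosis BMI from medicated (31.6, SD 6.3; fraction 0.67) vs unmedicated
(28.0, SD 7.0) components instead of the group marginal; it is off by
default so the marginal matches the demographic table.

Outcomes realise the causal chain.  Scalp thickness is linear in BMI:
intercept 2.5 mm, slope 0.15 mm per BMI unit, Gaussian noise (SD 0.5 mm),
floored at 2 mm — the slope is a free parameter (no published mm-per-BMI
value exists); the default puts a BMI-30 subject at the phantom's 7 mm
scalp.  Skull, CSF and cortex thicknesses are group-independent noise
around the phantom anatomy (6±0.6, 2±0.3, 3±0.3 mm), matching the finding
that only scalp and the aggregate differ robustly.  ROI field strength
comes either from a per-subject FEM solve (mode="fem", small cohorts) or
from a monotone surrogate: a shape-preserving PCHIP interpolant through
FEM solutions on a 6-point scalp-thickness ladder (3–13 mm), one curve per
montage × hemisphere, linearly extended outside the calibrated range.
Field noise is multiplicative log-normal (log-SD 0.15), since fields are
positive.  With the BMI→thickness slope set to zero the entire downstream
group difference vanishes — the mediation null used for calibration tests.

What the generator does *not* emulate: real gyral anatomy and per-subject
skull/CSF covariance with group, medication dose-response, and any direct
(non-thickness) group effect on the field.  Passing tests therefore show
that the analysis chain recovers the causal structure it assumes, not that
the real-data effect sizes are reproduced — those depend on a restricted
clinical dataset that is out of scope here.

## Statistics

Group comparisons are OLS regressions of each outcome on group (control=0)
adjusting for age and sex (male=1), reported with the group coefficient,
SE, t, p and Cohen's f² in the R²-increment form
f² = (R²_full − R²_reduced)/(1 − R²_full) with the reduced model dropping
only the group term.  The standard battery is 8 outcomes (4 ROI fields, 4
thicknesses) × 2 contrasts = 16 tests at Bonferroni α = 0.05/16 ≈ 0.003;
corrected alphas are reported raw and at one-significant-figure precision.

The sensitivity analysis inverts the noncentral-F power function of the
partial F test (df₁=1) by monotone root finding.  The noncentrality
convention is λ = f²·N (total-sample), which reproduces the design's
printed minimum detectable effects (f² = 0.04 at N = 179 with 3
predictors, 0.07 at N = 116); λ = f²·(df_denom + df_test + 1) is available
as an option since both conventions circulate in power software.

Demographic tests: Wilcoxon rank-sum with W reported in the R
`wilcox.test` convention (the Mann-Whitney U of the first sample) — exact
enumeration for small untied samples, otherwise normal approximation with
tie and continuity corrections; Yates-corrected chi-squared for the 2×2
sex table; one-sample Kolmogorov-Smirnov against either a fitted normal or
N(0,1) (the latter yields D ≈ 1 for any unstandardised scale such as raw
age or BMI, and is how a reported D = 1 arises).

## Mediation

Two covariate-adjusted linear models (no treatment×mediator interaction):
mediator ~ treatment + age + sex, and outcome ~ treatment + mediator + age
+ sex.  The average causal mediation effect is the coefficient product
ACME = a·b, the average direct effect ADE is the treatment coefficient of
the outcome model, and for nested OLS fits total = ACME + ADE holds as an
algebraic identity — the total also equals the group coefficient of the
outcome regression without the mediator.  Uncertainty is a nonparametric
pairs bootstrap (subjects resampled as whole rows; 1000 draws by default)
with percentile intervals and two-sided bootstrap p-values
p = 2·min(frac ≤ 0, frac ≥ 0), floored at 2/n_boot.  Proportion mediated
is 100·ACME/total from the point estimates; when ACME and total disagree
in sign the signed ratio is returned as-is and should be read with care.
Classification: "full" if ACME is significant and ADE is not at the chosen
alpha, "partial" if both are, "none" otherwise; the alpha is a parameter
(the battery applies its Bonferroni-corrected 0.05/12).  Note the p-value
floor interacts with the corrected alpha: at n_boot = 300 the smallest
attainable p (1/150) can never pass 0.05/12, so family-corrected mediation
calls use the full 1000 draws.

## Pipeline and reproducibility

`run_study` chains cohort → outcomes → 16-regression family → 12-mediation
family, logging each stage with wall time and deriving all stage seeds from
the single config seed; identical config gives byte-identical report CSVs.
The 12 mediation rows are: BMI → each of the 4 field outcomes, BMI → scalp
and scalp-to-cortex thickness, scalp-to-cortex → each field outcome, and
scalp → the two F3-Fp2 field outcomes.  Surrogate calibration is
deterministic given the layer spec, so one calibration may be shared across
seeds unchanged.

## Problem sizes

Validation runs use desk-scale meshes chosen as the coarsest that leave
clear margin on every tolerance: 5 mm edge for the five-tissue phantom
(~20 k nodes, ~120 k tets), 4 mm for the three-shell analytic comparison
(~48 k nodes), a 6-point calibration ladder, 200 replicate datasets for
mediation coverage (bootstrap reduced to 300 there; the floor interaction
above does not matter for coverage), 500 null simulations, and 20 seeded
end-to-end runs of 150+150 subjects.

## Known limitations

Spherical anatomy (no gyri, no spongy/compact bone split, no fat layer,
no eyes or blood); isotropic conductivity with no capacitive effects; a
single sponge layer per electrode (no connector or gel sub-layers);
surrogate accuracy limited to the calibrated thickness range; linear
no-interaction mediation only, with no sensitivity analysis for
unmeasured confounding of the mediator-outcome path.
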