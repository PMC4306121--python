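# Methods

This note documents the models implemented in `plaquemech`, the choices made
where the underlying study left the method open, and what the synthetic-data
generators do and do not establish.

## Constitutive model

Plaque and wall are modelled as incompressible, isotropic hyperelastic
solids with the third-order reduced-polynomial (Yeoh) strain energy

    W(I1) = C10 (I1 - 3) + C20 (I1 - 3)^2 + C30 (I1 - 3)^3   [MPa],

a function of the first invariant only. This makes the model identifiable
from a single uniaxial planar-shear test, where the principal stretches are
(λ, 1, 1/λ) and I1 = λ² + 1 + λ⁻². The loading-direction Cauchy stress used
for fitting is the standard incompressible planar-shear result

    σ = 2 (λ² − λ⁻²) W′(I1).

This closed form is not taken on trust: the test suite checks it against
central-difference differentiation of the energy along the deformation path
(σ = λ dŴ/dλ with Ŵ(λ) = W(I1(λ))) to relative 1e-6.

C10 must be positive (µ = 2·C10 is the small-strain shear modulus); negative
C20 is admissible and occurs in the femoral groups, producing their initial
softening.

**Material stability.** The source analysis states only that fitting
"ensures stability" without defining the criterion. We use monotonicity of
the planar-shear stress in the fitted deformation mode as the operational
proxy for Drucker stability: the analytic tangent dσ/dλ is evaluated on a
dense grid (default 10⁴ points) over a closed stretch interval containing
λ = 1, and the first grid point with non-positive tangent is reported. For
C10 > 0, C20 = C30 = 0 the tangent is globally positive, which the property
tests assert. All six shipped coefficient sets are stable up to their
groups' ultimate stretches.

## Coefficient fitting

Group-average curves are built by pooling all (λ, σ) points of a group and
least-squares fitting a single polynomial in (λ − 1) without constant term,
so the average passes through the undeformed point (1, 0), then sampling it
on a uniform grid truncated at the group's mean ultimate failure stretch.
The default polynomial degree is 4: the energy is cubic in (I1 − 3), but the
stress carries the extra geometric factor 2(λ² − λ⁻²), and a cubic in
(λ − 1) leaves ~1e-3 MPa of systematic lack-of-fit over a typical failure
range where a quartic tracks the model to ~1e-5 MPa. The degree is a
parameter for users who want the stiffer smoothing.

Yeoh coefficients are then fitted to the averaged curve by bounded
least squares in stress space (`scipy.optimize.least_squares`), with C10
bounded below at 1e-6 MPa to exclude degenerate zero-stiffness optima. The
stress is linear in the coefficients, so the problem is convex; the fit is
nevertheless run from multiple seeded starting points because stability
enforcement works by *rejection and restart* — candidates that fail the
stability check are discarded and the best stable optimum is kept, leaving
the objective identical to a plain stress-difference minimisation. If no
start yields a stable optimum, a fallback refit adds a soft penalty on
negative tangent stiffness over the data's stretch range. R² is computed on
stress values about their mean (the natural basis, since the objective is a
stress-space residual).

`YeohCurveFitter` exposes this as a scikit-learn regressor (`fit`/`predict`/
`score`, `get_params`, fitted attributes with trailing underscores), so it
composes with sklearn pipelines and model selection; `fit_yeoh` is the
functional wrapper.

## FTIR Ca:Li grading

The Ca:Li ratio is the phosphate band area (1180–900 cm⁻¹) divided by the
total lipid area: the CH₂ stretch region (2972–2845 cm⁻¹) plus the lipid
ester carbonyl band. Choices where the protocol is silent:

- **Ester band width.** The position "1730 cm⁻¹" is a peak, not a window;
  we integrate 1750–1710 cm⁻¹ (a typical carbonyl band width), configurable.
  Because the ester peak is not always detectable, its contribution is the
  baseline-corrected area clipped at zero — absent peaks contribute nothing.
- **Baseline.** A local straight line joining the spectrum values at the two
  band edges is subtracted before trapezoidal integration, and negative
  areas are clipped at zero. This mimics instrument-software area tools,
  and makes areas exactly invariant to any global linear baseline (asserted
  as a property test). Spectra are resampled to the instrument's uniform
  2 cm⁻¹ grid before integration.
- **Class boundaries.** The published intervals (1–1.5, 1.5–2, 2–3) are
  open at every boundary, which leaves the boundary points unassigned. We
  use half-open intervals [lo, hi): a ratio of exactly 1.5 grades
  *moderately*, exactly 2 grades *heavily*. Ratios ≤ 1 or ≥ 3 are
  `unclassified`. The tie-break is arbitrary but documented, and affects
  only measure-zero inputs.

`CalcificationClassifier` wraps the rule as a scikit-learn classifier whose
thresholds are parameters, not learned quantities; `fit` only validates them
and records the classes.

## Revascularisation mechanics

The published simulation is a 2D plane-strain quarter model of a concentric
stenosis meshed with >4×10⁵ elements. A concentric two-layer annulus with
symmetric boundary conditions is, however, an axisymmetric problem: we solve
the exact 1D radial reduction instead of meshing.

With plane strain (λz = 1) and exact incompressibility the motion is fully
determined by annular area conservation, r = √(R² + ri² − Ri²), giving
λθ = r/R and λr = 1/λθ. The radial stress follows from one ODE,

    dσrr/dr = (σθθ − σrr)/r,    σrr(r_outer) = 0,

with σθθ − σrr = 2(λθ² − λθ⁻²) W′(I1), σzz − σrr = 2(1 − λθ⁻²) W′(I1) and
I1 = λθ² + λθ⁻² + 1. Because λθ > 1 throughout an expansion, the component
ordering is σθθ > σzz > σrr and the maximum principal stress is the hoop
stress. Exact incompressibility (no volumetric term) matches the energy
actually given; the published FE compressibility treatment is unstated.

**Numerics.** The reference grid (default 4000 points) is geometrically
refined toward the lumen, where hoop-stretch gradients are steepest, and
always contains a node at the plaque/wall interface so no quadrature
interval straddles the material discontinuity. σrr is accumulated by
per-interval 5-point Gauss–Legendre quadrature of the analytic integrand;
`equilibrium_residual` re-evaluates every interval with a 15-point rule and
reports the worst discrepancy (plus the outer-boundary traction), giving a
non-circular a-posteriori error measure. Grid-doubling leaves the reported
stress at 0.8 mm unchanged to relative 1e-6.

Two independent cross-checks guard the solver: a brute-force 1e5-point
quadrature of the classical incompressible-cylinder formula (single layer),
and a 500-node displacement-driven finite-difference solver that minimises
the total energy of a compressible Yeoh material with a volumetric penalty
κ/2 (J − 1)², κ = 1000·C10. The FD comparison uses hoop-stress error
normalised by the profile maximum, excluding the first 10% of the annulus
next to the clamped lumen node, and agrees within 1% (typically 0.4%).

**Extrapolation beyond failure.** Revascularisation drives the plaque far
past every group's ultimate stretch (λθ ≈ 9 at the lumen). The solver
deliberately extrapolates the strain-energy curve — this mirrors the
published analysis, which is precisely about what such extrapolation does to
aortic-vs-femoral model choice — and emits a warning rather than an error
when a material loses monotonicity over the induced stretch range.

## Undocumented modelling choices (defaults and sensitivity)

Three inputs of the headline comparison are not documented in the source
and are therefore explicit configuration, with a sensitivity sweep built
into the pipeline:

- **Wall material** is never specified. Default: neo-Hookean with
  C10 = 0.05 MPa (µ = 0.1 MPa, a soft healthy media/adventitia). Options:
  any Yeoh coefficients, `plaque` (wall shares the plaque model), `none`
  (no wall layer; the plaque outer surface is traction-free). A literally
  rigid outer boundary is kinematically inconsistent with plane-strain
  incompressibility — the motion is fully determined by the lumen
  displacement — so `none` stands in for that limit.
- **Stenosis-percentage reference.** The geometry table reads "% of SFA
  diameter" while the model figure says the plaque obstructs 90% "of the
  luminal diameter". The SFA reading makes the revascularised lumen exceed
  the healthy lumen, which is geometrically inconsistent for a concentric
  plaque, so the default is `healthy_lumen`; both conventions are
  implemented.
- **Depth convention.** "0.8 mm from the lumen" defaults to the deformed
  configuration (results are reported post-revascularisation); measuring in
  the reference configuration and mapping forward is supported.
- **Outer radius.** The printed wall thickness (0.48 mm) disagrees with the
  printed diameters ((6.87 − 5.95)/2 = 0.46 mm). Default: outer radius =
  SFA diameter / 2; `honour_wall_thickness` switches to the printed 0.48.

The sensitivity appendix sweeps both stenosis references × both depth
conventions × wall C10 ∈ {0.01, 0.05, 0.2} MPa. Under the default
configuration the calcified-aortic / heavily-calcified-femoral fold change
at 0.8 mm is ≈ 343, and it stays between ≈ 320 and ≈ 590 over the whole
grid — the conclusion (a two-orders-of-magnitude overestimate from using
aortic data) is insensitive to every undocumented choice.

## Failure assessment

Computed states are compared against each group's mean ultimate failure
point (stretch and Cauchy stress); standard deviations are carried where
reported (the hypocellular aortic group has none) but the headline
comparison uses means only, matching the single dashed failure lines of the
source. Failure requires *strict* exceedance: a stress exactly equal to the
criterion mean is "not failed" (arbitrary, documented, measure-zero).
Default mode compares stress; stretch and either-quantity modes exist.

## Synthetic data

No deposited data exist, so the generators create inputs with the
statistical structure the analysis assumes, with full ground truth stored
alongside:

- **Stress–stretch curves** are Yeoh model evaluations on [1, λ_fail] with
  λ_fail ~ Normal(group ultimate mean, SD) truncated above 1.05, and
  multiplicative Gaussian stress noise (default CV 5%, the scatter scale of
  soft-tissue testing; multiplicative because scatter grows with stress,
  and it preserves the exact zero at λ = 1).
- **FTIR spectra** are sums of Gaussian bands on the instrument's 2 cm⁻¹
  grid over 4000–700 cm⁻¹: a CH₂ doublet at 2922/2858 cm⁻¹ (σ = 4 cm⁻¹),
  the ester carbonyl at 1730 cm⁻¹ (σ = 6 cm⁻¹), and one broad phosphate ν₃
  band at 1030 cm⁻¹ (σ = 30 cm⁻¹; ν₃ dominates the 1180–900 window). Band
  areas are set in closed form so phosphate/(CH₂ + ester) equals the target
  Ca:Li exactly; band widths are chosen so every peak sits ≥ 3σ inside its
  integration window, keeping the endpoint-baseline area within ~1% of the
  closed form. A linear baseline (removed exactly by the area tool) and
  additive Gaussian noise (default 2e-4 AU rms, typical of a 16-scan ATR
  acquisition at 2 cm⁻¹) complete the spectrum.
- **Cohorts** pair curves and spectra per femoral group with Ca:Li targets
  drawn uniformly ≥ 0.1 inside the class intervals, defaulting to the
  study-sized 7/6/7 split.

All generators are bit-reproducible given their seed.

**What a green test establishes — and what it does not.** The generators
produce data *from the fitted model family*: recovery tests therefore
establish correctness of the estimation machinery (identifiability,
optimiser, averaging), not adequacy of the Yeoh family for real tissue.
Real plaque curves contain toe-region artefacts, hysteresis and
heterogeneous rupture; real spectra contain water-vapour lines, ATR
penetration-depth effects and curved scattering baselines. None of these
are emulated, and the classification accuracy obtained here is an upper
bound on field performance.

## Known limitations

- Concentric, axisymmetric geometry only; no eccentric plaques, fibrous
  caps, residual stresses, or device contact — deliberately, since the
  question is the material-model effect in isolation.
- Isotropic Yeoh only; anisotropic fibre models need structural data that
  uniaxial testing cannot supply.
- The headline fold change depends on extrapolating the strain energy far
  beyond the tested stretch range; it quantifies model-choice sensitivity,
  not a physically attained stress.
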