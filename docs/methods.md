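# Methods

## Transport model

The tissue is treated as a rigid isotropic porous medium (putamenal gray
matter; diffusion-tensor measurements place its fractional anisotropy below
the gray-matter threshold, so a scalar effective diffusivity is adequate).
Binding of the infused protein is neglected, and transcapillary loss is
folded into a single first-order elimination rate. With interstitial fluid
incompressible and ISF production ignored over the ~1–2 h infusion
timescale, continuity gives the radial interstitial velocity

    v_r(r) = Q / (4 pi phi r^2),

and the normalized concentration C(r, t) = C_ISF/C0 on r in [r'_0, R_max]
obeys

    dC/dt = (D/lambda^2) (1/r^2) d/dr (r^2 dC/dr) - v_r dC/dr - k C.

The post-infusion phase is the same equation with v_r = 0. The solver runs
internally in cgs units (cm, s); constructors accept uL/min, mL and h^-1
and convert once.

### Parameters and defaults

| parameter | symbol | default | units | note |
|---|---|---|---|---|
| porosity | phi | 0.3 | — | enlarged-ECS value for infused tissue (normal ~0.2) |
| elimination rate | k | 3.72e-2 | h^-1 | from the two-compartment fit (below) |
| Vd/Vi ratio | — | 3.87 | — | empirical primate putamen value |
| GDNF free diffusivity | D | 1.3e-6 | cm^2/s | Stokes–Einstein extrapolation from a 26.5 kDa NGF conjugate; stored as a constant |
| GDNF tortuosity | lambda | 2.2 | — | macromolecule in striatal ISF |
| Gd-DTPA diffusivity | D | 4.1e-6 | cm^2/s | MW^(−1/3) scaling of D_GDNF, stored rounded to 2 s.f. (raw scaling gives 4.14e-6) |
| Gd-DTPA tortuosity | lambda | 1.6 | — | upper end of the 1.5–1.6 small-molecule range; configurable |
| source radius | r'_0 | 0.2 | cm | numerical source sphere, not the physical tip (0.03 cm): avoids the 1/r^2 velocity singularity |
| infusion volume | Vi | 0.105 | mL | simulation volume for the rate comparison |
| outer radius | R_max | 3.0 | cm | run aborts if C(R_max) > 1e-6 |

The effective diffusivity is D/lambda^2, giving Gd-DTPA a ~6-fold transport
advantage over GDNF; molecular-weight scaling for other species uses
D ∝ MW^(−1/3) (Stokes–Einstein drag on a sphere of volume ∝ mass). No
temperature/viscosity-explicit Stokes–Einstein form is implemented — only
the ratio law.

## Numerical scheme

Finite-volume method of lines on a uniform radial grid (default 1200 cells
on [0.2, 3.0] cm, dr ≈ 23 um). Because 4 pi r^2 phi v_r = Q is constant in
r, the advective amount flux through any face is exactly Q·C_face, so the
conservative and advective forms coincide and the discrete scheme
telescopes to exact mass book-keeping. C_face is reconstructed by van Leer
flux-limited upwind: at the Peclet numbers reached here (up to ~180 at the
source) a centered scheme oscillates and first-order upwind smears the
front; the limiter keeps the front monotone and 2–3 cells wide. Time
integration is explicit SSP-RK2 under a combined stability bound
dt = cfl · min(dr/v_max, dr^2/2D, 0.05/k) with cfl = 0.4; the advective
bound at the inner face dominates during infusion. The reaction bound is an
accuracy (not stability) limit so that decay is exact to ~1e-5 even when it
is the only active term.

Verification built into the test suite: the pure-convection front lands on
the method-of-characteristics radius (r'_0^3 + 3Vi/4 pi phi)^(1/3) =
0.451 cm for Vi = 0.105 mL within one grid cell; the pump-off phase matches
the spherical-shell diffusion Green's function to 0.03% L2; infused mass
obeys dM/dt = Q C0 − kM to <1%; halving the grid spacing moves the C = 0.5
crossing radius by <0.05%.

### Inner boundary: the effective source condition

The physical statement — fluid leaves a small sphere at rate Q carrying
concentration C0 — does not by itself fix the numerical source condition,
and the choice matters for absolute distribution radii. Two modes are
provided:

* **flux** (default): total solute flux through the r'_0 sphere fixed at
  Q·C0·(source-strength). Mass-conserving: with elimination off the tissue
  holds exactly Q·C0·t. Under this mode the C = 0.5 front of a 0.105 mL
  infusion sits at ~0.45 cm — the advective mass-balance limit.
* **concentration**: C pinned to (source-strength) at r'_0, which feeds
  additional solute into the tissue by diffusion across the source surface
  and yields somewhat larger distribution radii.

A `source_strength` factor is exposed for calibrating either mode against
experimental tracer data. The package deliberately reports what each mode
implies rather than tuning the source to any particular published radius;
mode-independent quantities (orderings across rates, homogeneity trends,
tracer/drug ratios) are the ones asserted in tests. Notably the simulated
tracer/drug Vd ratios under the default mode (1.20 at T = 0, 1.53 at
T = 2 h) are insensitive to this ambiguity because the source condition is
common to both species.

A related, physically irreducible point: two infusions of equal volume at 3
and 5 uL/min produce fronts at the same radius but of different width —
front width grows like sqrt(2 D t_inf) and the slower infusion runs 5/3
longer — so their profiles agree closely in every integral measure
(r_half, Vd, homogeneity within ~1%) while differing pointwise by up to
~0.07 on the front shoulder. "Near-identity" of high-rate profiles should
therefore be read in the integral sense.

The post-infusion inner boundary is zero-flux (no sink at the catheter);
the outer boundary is C = 0 with a runtime check that the profile has
decayed below 1e-6 at R_max.

## Elimination kinetics

Two independent estimates of k:

1. **Two-compartment fit.** Central compartment = brain extracellular
   space; elimination k10 from central, exchange k12/k21 with a peripheral
   pool. The central amount after a bolus is the closed-form biexponential
   with hybrid rates alpha, beta (roots of s^2 − (k10+k12+k21)s + k10·k21).
   Fitting minimises least squares on log amounts — the standard surrogate
   for a proportional error model; the assay's true error structure is
   unavailable — using bounded trust-region least squares from five
   log-spaced multi-starts. The two dose groups (15 and 3 ug) are fit
   jointly with shared rate constants and initial amounts fixed to the
   administered doses (dose-proportional kinetics); fits are in amount
   space (ug in whole striatum). Standard errors come from the Gauss–Newton
   J'J approximation at the optimum. Since k12 << k10, the terminal decline
   over the first week is governed by k10 alone and k_el ≈ k10 =
   3.72e-2 h^-1 (half-life ln 2 / k ≈ 18.6 h ≈ 19 h); a warning is raised
   if k12/k10 > 0.1.
2. **ISF bulk flow.** With ISF produced at 0.17 uL/(g·min), a 1.8 g rat
   brain drains Q_ISF = 0.306 uL/min through V_ISF = phi × 1800 uL =
   540 uL, giving k = Q_ISF/V_ISF = 3.40e-2 h^-1 (brain mass cancels).
   Brain density is taken as 1 g/mL.

Their ~10% agreement supports slow interstitial outflow as the dominant
clearance route for a protein that does not cross the intact BBB — which
is also why elimination is switched off in the drug-vs-tracer comparison:
over a 2 h window it affects both species nearly equally.

## Infusion-phase loss

Lumped balance under: constant intratarget concentration C0 during the
short infusion, Vd ∝ Vi, constant Q, diffusion and binding negligible.
Closed form A_Loss(t) = Q C0 (Vd/Vi)(t − (1 − e^{−kt})/k), evaluated with
expm1 so the k → 0 limit returns exactly 0 and the small-kt quadratic
regime (Q C0 (Vd/Vi) k t^2/2) is accurate. An independent ODE-integration
route (`loss_numeric`) agrees to 1e-8 relative and backs the closed form
in tests.

## Target geometry

The posterior dorsal putamen is modelled as a box from atlas measurements
(length 1.92, height 1.15, width 1.12/0.90 cm at two levels) and the
per-catheter Vd projected at 0.5 mL (two catheters per putamen). Shapes:
sphere V = (4/3) pi r^3, and hemisphere-plus-reflux-cylinder
V = (2/3) pi r^3 + pi r^2 h with total length r + h. Solving the cylinder
for a fixed total length uses bisection on the monotone cubic (residual
< 1e-9 mL). Shape extents are compared per dimension against the box with
the cylinder axis assumed aligned with the long axis — catheter
inclination is a documented non-feature. The ~8 uL catheter dead volume is
reported but never subtracted (negligible against 0.5 mL). The 0.98 cm
sphere overflows the 0.90 cm width level; a 0.59 × 1.90 cm cylinder fits.

## Synthetic data

`generate_pk_dataset` emulates the striatal PK study design the fitting
stage expects: two CED doses (15, 3 ug), whole-striatum amounts at days 3,
7, 14, 21, 28, biexponential decline under the reference rate constants.
Noise is mean-preserving lognormal proportional error, default CV 10% —
the conventional model for ELISA-type assays — with additive and
noise-free options; identical seeds give identical datasets. What it does
not emulate: inter-animal variability structure (single pooled error
level), assay limits of quantification, or sampling-time jitter — so
passing recovery tests demonstrate estimator correctness under the assumed
error model, not robustness to real assay pathologies. In a 100-replicate
study at CV 10% the k10 estimator shows <1% bias and ~93% coverage of the
±2 SE interval.

## Problem sizes and runtime choices

Default solver resolution (1200 cells) resolves the front to ~2 cells and
keeps any single infusion simulation under ~2 s; the full four-rate
comparison plus the two-species tracer comparison runs in a few seconds,
and the 100-replicate PK simulation study in ~3 s. Grid-convergence
checks compare 600- vs 1200-cell runs. These sizes are the package's
defaults because the reported quantities (crossing radii, volumes, ratios)
are already converged well below their displayed precision at this
resolution.

## Known limitations

* One-dimensional spherical symmetry: no anisotropic or DTI-informed
  geometry, no white-matter pathways, no tissue segmentation.
* No catheter fluid mechanics: backflow along the track is represented
  only geometrically (the reflux cylinder), not dynamically.
* Rigid pore structure: no poroelastic deformation or infusion-induced
  edema beyond the enlarged porosity value.
* The effective source condition is under-determined (above); absolute
  distribution radii carry that systematic uncertainty, orderings and
  ratios do not.
* Single-subject (pooled) PK fitting only; no mixed-effects or Bayesian
  machinery.
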