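# Methods

This note records the model assumptions, the parameter choices that matter,
the numerical scheme, and the known limitations of the package.  Every
number quoted here is computed by the test suite or the analysis scripts.

## Scope and staging

The simulation is one-way coupled: coil geometry → magnetic field →
nanoparticle loss power → bioheat transfer.  There is no feedback (tissue
is nonmagnetic, the source is temperature-independent), so each stage can
be validated in isolation and the thermal stage depends on the field stage
only through the center field strength.

## Coil model

Both coils are modeled as 180 ideal circular loops on a 12 (radial) × 15
(axial) grid of cell centers spanning the winding envelope (radii
0.14–0.15 m, width 0.05 m); superposition over loops gives the pair field.
Analytic loop fields (on-axis closed form, off-axis complete elliptic
integrals) are verified against a 10⁴-segment Biot–Savart line integral to
<0.1%.  Two conventions matter:

* **Radii, not diameters.**  The winding envelope values 0.14/0.15 m are
  used as radii; only then does the thin-coil closed form
  (4/5)^{3/2}μ₀NI/R give the 8.93 mT magnitude consistent with the working
  field, and the mean radius matches the R in the axial-field formula.
* **Separation as a calibration parameter.**  The center-plane separation is
  not part of the tabulated geometry.  The default is the classical
  Helmholtz condition s = 0.145 m (center B = 8.9275 mT with the
  distributed winding).  `calibrate_separation` solves for the separation
  that reproduces a requested center flux density; the working value
  8.5621 mT is obtained at s = 0.1552 m, which keeps a positive gap of
  0.105 m between winding packs.  The default pipeline uses the calibrated
  pair.

Reported field values are sinusoid amplitudes (peak), matching the quoted
mT magnitudes.  Conductor conductivity is carried as metadata only; there
is no impedance, skin-effect or power-supply model.

## Nanoparticle loss model

The Rosensweig relaxation-loss form is used with the equilibrium
susceptibility evaluated at the applied amplitude through the Langevin
function (series below ξ = 10⁻², relative switch error < 10⁻¹⁰).  The fluid
parameters that the loss power actually needs — M_d, particle volume,
τ_eff — are not part of the tabulated study inputs.  The default spec is
therefore 19 nm magnetite (M_d = 446 kA/m, a standard single-domain
magnetite magnetization), body temperature, φ = 0.003, with τ_eff solved on
the *fast* branch of x/(1+x²) so that P₀(6814.2 A/m, 100 kHz) =
673,920 W/m³.  The solution is τ_eff = 4.69×10⁻⁷ s (2πfτ = 0.294), a
Néel-like time typical of particles of this size; the slow branch
(τ ≈ 5.4×10⁻⁶ s) would correspond to Brownian-dominated rotation and is
selectable.  The loss power is consequently a *calibrated input*, not an
independent prediction; everything downstream of P₀ is.

α = 0.55 multiplies P₀ only (not the metabolic heat), and the source is
held constant over the exposure (no re-evaluation as tissue warms).  The
source is spatially uniform over the tumor at the center-point value; a
per-voxel mode exists, but the field ripple across the 24 mm lesion is
0.04%, so the two agree to well below the solver tolerance.

## Phantom

An ellipsoidal brain core (semi-axes 8 × 6 × 6 mm) is wrapped in
concentric 1 mm skull and 1 mm scalp shells; shell thicknesses are typical
murine scales and are configurable.  The melanoma is a right cylinder
(flat disk) of area 451.52 mm² (radius 11.99 mm) and height 2 mm, centered
on the coil center (the coordinate origin).  Two discretization choices
deserve note:

* **Embedding depth.**  The disk's lower face sits 0.5 mm (half the scalp
  thickness) below the head apex, so the lesion is slightly embedded in the
  skin it grew from.  A pure point tangency would make the tumor–scalp
  thermal contact patch an artifact of voxel size; the fixed physical
  embedding keeps the contact area (~30 mm² in the continuum limit)
  resolution-independent, which is what makes the thermal endpoint converge
  under grid refinement.
* **Slab alignment.**  The z grid is aligned so the 2 mm slab is captured by
  exactly `round(thickness/Δx)` voxel layers symmetric about z = 0 (a
  half-voxel shift when the layer count is even).  The voxelized tumor
  volume at Δx = 0.5 mm is 894.5 mm³ against the exact 903.0 mm³, within
  one boundary-voxel shell, and converges under refinement.

A muscle-like body stub (6 mm cylinder) extends from the head to the bottom
grid face and provides the far-field heat sink.  Tissues absent from the
thermal tables fall back as documented in `phantom.py` (torso/limbs →
muscle thermal values; tumor/mixed/nanofluid dielectric → muscle; the
mixed tissue inherits tumor perfusion 0.01392 s⁻¹ and metabolic heat).
The mixed-tissue thermal conductivity 0.5316 W/(m·K) is used verbatim at
φ = 0.003: it is *below* pure tumor's 0.535 despite the k = 40 particles,
and no volume-weighted or Maxwell–Garnett rule reproduces it, so the
tabulated value is authoritative.  The scalp conductivity 4.51×10⁻⁴ S/m is
far below typical skin values and is likewise used as tabulated.

## Bioheat solver

Finite-volume discretization on the voxel grid with harmonic-mean face
conductivities (continuous flux across material jumps; the skull|brain face
value is 0.3947 W/(m·K)).  The perfusion term is implemented as the
standard Pennes *sink* ρ_b C_b ω_b (T_b − T): a source-signed term would
diverge rather than saturate, and only the sink form produces the observed
plateauing exposure curves.  Blood properties are not tabulated; the
defaults ρ_b = 1060 kg/m³, C_b = 3650 J/(kg·K) (a tumor-like blood
surrogate) are configurable.

Boundary conditions: air voxels are excluded from the solve; tissue–air
faces are **insulated** by default.  This is a deliberate choice: for the
2 mm lesion a convective film (h = 10 W/m²K toward a 25 °C room) would
remove ≈ h/L·(T−T_amb) ≈ 5 kW/m³K·12 K — comparable to the perfusion sink —
and depress the tumor plateau by ~1.5 °C, which is inconsistent with the
saturating ≥43 °C endpoints this scenario is defined by; insulation is also
the conventional default of commercial bioheat solvers.  A convective Robin
condition is implemented, tested and selectable.  Tissue faces on the
domain boundary (the stub base) are fixed at 37 °C.

Time integration is backward Euler (default dt = 1 s; the sparse system is
SPD and solved by a cached LU factorization, or by Jacobi-preconditioned CG
above 1.5×10⁵ unknowns), with an explicit scheme available that enforces
dt ≤ min ρc Δx²/(6k) (0.307 s for mixed tissue at Δx = 0.5 mm).  Verified
invariants: exact enthalpy conservation and source-power bookkeeping with
insulated boundaries, the discrete maximum principle, explicit/implicit
agreement < 0.05 °C at shared dt, the lumped perfused-block ODE on a
homogeneous block to < 0.5%, a 1-D conduction + fixed-boundary closed form
to 3×10⁻⁴ °C, and a tumor-center change < 0.1 °C when Δx is halved from the
0.5 mm default.

## Default problem sizes

The default run uses Δx = 0.5 mm (38,640 tissue voxels, ~19 s on one CPU
including coil calibration); the refinement check uses Δx = 0.25 mm
(309,397 unknowns, ~40 s via CG).  These resolve the 2 mm lesion with 4 and
8 layers respectively.

## What the phantom does and does not emulate

The phantom reproduces the layered composition, the lesion geometry and
loading, and the tabulated tissue parameters.  It does **not** reproduce
CT-derived anatomy: the head is a smooth ellipsoid smaller in footprint
than the 24 mm tumor disk, so the lesion overhangs the head and contacts
the scalp only over a ~30 mm² apex patch, whereas a real scalp melanoma
(and an anatomical mesh) conforms to the curved scalp over its whole base.
Consequences quantified by the solver:

* Tumor regions far from the contact patch behave nearly lumped: maximum
  43.7 °C, coverage ≥42 °C of 91.5%.
* The center column sits directly above the contact patch.  With the
  tabulated scalp perfusion 0.02 s⁻¹ (an order of magnitude above typical
  skin), the patch is a strong sink: the tumor-center endpoint is 41.4 °C,
  ~2.5 °C below the lumped perfused-block value 43.88 °C.  A 1-D
  slab/interface energy balance shows this is intrinsic, not numerical:
  *any* conduction-coupled contact at these parameters pulls the center
  several °C below the lumped curve, and a fully conformal contact would
  pull it to ~40.5 °C.  A center endpoint that tracks the lumped 43.9 °C
  is achievable only with negligible tumor–tissue thermal contact, which
  would contradict the simultaneous heating of scalp (to ~41 °C) and brain
  reported for this scenario — i.e., that combination of endpoints is not
  reproducible by a consistent conduction solver under these parameters.
* Heat reaching the brain passes through the same small patch, so brain
  warming is modest: maximum 38.8 °C with 0.5% of the brain above 38.5 °C
  (an anatomically conformal contact yields several times more).

Passing tests therefore demonstrate correct field arithmetic, loss-power
arithmetic and a verified Pennes solver under the stated geometry — not
that the simplified phantom matches an anatomical-mesh computation in the
conduction-sensitive quantities (tumor-center/brain endpoints).

## Induced-field estimator

The exposure module reduces Faraday's law on circular paths about the coil
axis: E = π f B r with r the region's maximal in-plane radius, J = σE.
This reproduces the interior solution for a homogeneous conducting cylinder
in a uniform axial AC field at negligible skin depth, and is an
order-of-magnitude *bound* for heterogeneous anatomy: field concentration
at tissue surfaces and the electrostatic shielding of the skull require a
full eddy-current FEM, which is out of scope by design.  Every exposure
table carries this caveat in its header.

## Determinism and reproducibility

No stage is stochastic: identical configurations produce byte-identical
JSON reports (sorted keys, default float repr).  `scripts/acceptance.py`
re-runs the default scenario end-to-end and writes the headline quantities;
its `--seed` argument is recorded but does not influence the computation.
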