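# Methods

This note records the model as implemented, the parameter choices that
matter, the numerics, and what the synthetic phantom experiments do and
do not demonstrate.

## Model structure

The simulator advances a macroscopic state u = (c, l, F) — cancer
density, non-fibre ECM, fibre ECM magnitude — plus a quasi-static
nutrient field σ on a regular cell-centred lattice, coupled to two
cell-scale processes. All densities are nondimensional volume
fractions; ρ(u) = c + l + F is the occupied fraction. Time is measured
in days; one computational stage is Δt = 1/5 day, so a 45-stage
experiment covers nine days and a 900-day treatment timeline is 4500
stages. Lengths are measured in voxel units of the phantom grid
(spacing configurable; the phantom carries an affine so NIfTI
import/export is consistent).

Each stage performs, in order:

1. **Nutrients.** The stationary diffusion–uptake equation
   0 = ∇·(D_σ/(c+F+p₀)∇σ) − d_σcσ is solved on the current Ω(t) with
   σ = σ_nor on the outer interface. Red-black successive
   over-relaxation (ω = 1.8) on a 7-point stencil with harmonic-mean
   face coefficients, sup-norm residual tolerance 1e-8, warm-started
   from the previous stage. A sparse direct solve of the identical
   discretisation serves as the test oracle.
2. **Treatment rates.** Radiotherapy contributes a spatially uniform
   kill rate r̄(j_m)ψ(t) per fraction (linear–quadratic r̄ = αD + βD²);
   chemotherapy contributes μbK/(K+sc)(1−e^{−ζW})ρ_g(i_k)ψ(t), the
   Holling type-II factor realising the Norton–Simon effect. The
   printed form of the exponential kill factor, (1−e^{ζW}), is negative
   for positive ζ and W; the implementation uses b(1−e^{−ζW}) and keeps
   the literal form behind `TherapyParams.literal_exponential_kill` for
   comparison. Delivery bumps ψ are C¹ asymmetric mollifier lobes with
   peak 1 at the administration time (midday), rise 0.1 day and decay
   0.4 day; peak-normalisation (rather than unit integral) was chosen
   so the fraction intensity r̄ carries the full magnitude.
3. **Macro advance.** Heun predictor–corrector on c with (i) the full
   anisotropic diffusion ∇∇:[D_T c] in conservative flux form — exact
   two-point normal differences plus face-averaged tangential central
   differences, reducing to the 7-point Laplacian for isotropic D_T and
   exact on quadratics; (ii) the adhesion advection −∇·(c𝒜) with
   fifth-order WENO reconstruction upwinded by the face velocity
   (verified ≥ 4th order on smooth data); (iii) logistic proliferation
   μΨ_p(σ)c(1−ρ)⁺ and death dΨ_d(σ)c with cosine ramps between the
   necrotic threshold σ_n and the optimal level σ_p; (iv) the two
   treatment sinks. Face fluxes across ∂Ω(t) and the grid frame are
   zeroed (zero-flux), so transport conserves mass inside Ω exactly;
   negative densities from the corrector are clipped with the clipped
   mass logged. The adhesion velocity integrates
   K(‖y‖)[ŷ(S_cc c + S_cl l) + ŷ_f S_cF F](1−ρ)⁺ over a sensing ball of
   radius R_s with the truncated-cone kernel K = 1 − r/R_s; the fibre
   term projects the sampled fibre axis into the hemisphere of ŷ
   (fibres are axial). Adhesion and the nutrient rate fields are frozen
   over the two Heun evaluations; the chemo saturation uses the
   stage-entry density.
4. **ECM decay.** F and l decay exponentially where cancer is present,
   with therapy-specific additional rates active only while a delivery
   bump is nonzero; the exact integrator F ← F·exp(−cβΔt) is used, and
   the decay factor is mirrored multiplicatively onto the micro-fibre
   mass so F = ‖θ_f‖₂ stays consistent.
5. **Fibre rearrangement.** The cell flux ℱ = D_T∇c + c∇·D_T − c𝒜,
   mediated against the fibre orientation by w = c/(c+F), gives the
   rearrangement vector r = wℱ + (1−w)θ_f. Each macro voxel's
   micro-mass parcels are displaced by `realloc_gain`·r·Δt (capped at
   one macro voxel), with trilinear deposition on the global micro
   lattice so mass crossing micro-domain faces lands in the
   neighbouring domain; total fibre mass is conserved to machine
   precision. Rearrangement is applied only where cells are present
   (c > 1e-6): where c = 0 the weight vanishes and letting fibres
   self-advect along θ_f would be an artefact.
6. **Boundary proteolysis and domain growth.** Cubic micro-domains
   (edge ε = 4 voxels, 8³ micro cells) are centred on (subsampled, at
   most `max_cubes`) boundary voxels. The MDE source at a micro node is
   the mean cancer density over the inside part of a sup-norm ball of
   radius γ_h = 1.5 voxels, smooth-stepped to zero ρ = 0.5 voxels
   outside the interface; the MDE density then diffuses (explicit
   flux-form heat steps, auto-substepped for stability, zero-flux
   walls, null initial data), so the cube total equals the
   time-integrated source exactly. Outside micro cells carrying more
   MDE than the cube mean form the significant degradation pattern: if
   their mass exceeds `omega_threshold` of the cube total, the boundary
   point is assigned the mass-weighted first-moment direction and a
   magnitude `xi_mag`·(significant outside mass). Because per-stage
   magnitudes are sub-voxel, a `DomainEvolver` banks advances per
   boundary voxel and rasterises the displacement segment once a full
   voxel has accumulated; the domain is monotone non-decreasing
   (therapy reduces density, never the footprint — the moving-boundary
   law only ever invades).

## Seeding and assimilation

Ω(0) is the pre-surgical oedema mask; the resected cavity is the
pre-surgical tumour mask and Γ its lattice boundary. Rather than
casting a ray per voxel, the normal-ray coordinate υ of an oedema voxel
is its Euclidean distance to the cavity and the ray length
q = υ + distance-to-oedema-exterior — equivalent for smooth Γ and O(N).
(An explicit marching + bisection `normal_ray_distance` is provided and
tested against analytic sphere/ellipsoid intersections.) Case 1 uses
the normalised mollifier profile R⁻¹ψ₁(υ/R), R = q/ξ (compact support;
vanishes before the oedema boundary); case 2 the half-Gaussian with
σ̃ = q/ξ (strictly positive up to the boundary). The three-mask
composition multiplies the profile by α_sc on the cavity mask and α_it
on the initial-tumour mask (the cavity, the more recent observation,
takes precedence where they overlap); the field is zero outside the
oedema and is rescaled to the peak density c_max = 0.1. Peak
normalisation was chosen over mass normalisation because the Gaussian
case is only specified up to proportionality while the maximum initial
density is pinned at 0.1. The non-cancer initial fields are
l(x,0) = min(h(x), 1−c(x,0)) with the heterogeneous profile
h = 1/2 + ¼sin³(7πy₁y₂y₃)sin(7πy₁/y₂/y₃) on the reference cube
[−1.5,1.5]³ (so h = 1/2 at the centre), σ(x,0) = 0.4 everywhere, and
F(x,0) from the micro-fibre initialiser.

Assimilation binarises the simulated density at a detection threshold
(default 0.05 — what a scan can plausibly see; config-exposed) and
scores the Euclidean norm of the binary difference against each mask,
taking the maximum over observation times. Runs whose disagreement
exceeds 5000 voxels at any observation are halted and scored infinite.
The controller moves dyadically — over-spread (detected volume above
the mask volume at the worst time) doubles ξ, under-spread halves it
with the admissible floor ξ > 1 — and once a bracket exists the search
bisects in log₂ξ, returning the evaluated ξ with minimal objective.

## Synthetic phantom

The phantom emulates the imaging-derived inputs: an ellipsoidal brain,
a white-matter shell whose tract tangents are nested horizontal arcs,
grey matter elsewhere, and spherical tumour/oedema masks (oedema
strictly containing the tumour). Tensors are trace-3 with
dominant/transverse eigenvalue ratio 10:1 along the tract tangent in
white matter and 1.2:1 with random orientation in grey matter, so
white-matter fractional anisotropy strictly exceeds grey-matter FA.
The tumour diffusion tensor mixes them as
D_T = D_c(gm·I + wm·D̂) with D̂ trace-normalised (config-selectable).
Micro-fibre domains (5³ micro cells per macro voxel) are filled with
straight unit-cross-section stripes — random orientations in grey
matter, tract-aligned in white matter — until the occupied volume first
reaches 35%, so the overshoot is bounded by one stripe's volume and the
initial fibre fraction is F ≈ 0.35. For speed the per-voxel
initialiser draws from a seeded library of fill-until realisations
(grey matter) and caches one realisation per quantised tract direction
(white matter, 24-bin axial quantisation, ≤ ~7° direction error); every
library member is a faithful realisation of the fill-until rule, and
the whole construction is a pure function of (spec, seed).

What the phantom does *not* emulate: real cortical geometry, tract
crossings and curvature statistics, registration/segmentation error,
mass effect and post-surgical tissue deformation, and scanner noise.
Passing phantom tests therefore demonstrates the internal consistency
of the coupled scheme and the qualitative containment behaviour, not
clinical predictive accuracy.

## Parameters

Kinetic and treatment defaults (all config-exposed; rates per day):

| parameter | default | meaning |
|---|---|---|
| μ | 0.4 | proliferation rate |
| d | 0.15 | death rate |
| S_cc, S_cl, S_cF | 0.3, 0.1, 0.3 | adhesion strengths |
| R_s | 2 voxels | adhesion sensing radius |
| D_c | 0.2 voxel²/day | diffusion scale of D_T |
| β_F, β_l | 0.5, 0.3 | baseline ECM decay |
| β_·Chemo, β_·Radio | 0.1 | therapy-induced ECM decay |
| D_σ, d_σ, p₀ | 1.0, 2.0, 0.5 | nutrient transport/uptake/permeability |
| σ_nor, σ_p, σ_n | 1.0, 0.6, 0.2 | nutrient levels (σ_nor > σ_p > σ_n) |
| α, β | 0.3 Gy⁻¹, 0.03 Gy⁻² | LQ coefficients (α/β = 10 Gy) |
| b, ζ, W, K, s | 0.4, 1, 1, 1, 1 | chemo kill, sensitivity, dose, capacity, Norton–Simon extent |
| D_m | 3.0 voxel²/day | MDE diffusivity |
| ω_threshold, ξ_mag | 0.02, 2.0 | boundary-relocation trigger and gain |

The σ-thresholds place the initial level 0.4 mid-ramp, so proliferation
starts at half its maximum and accelerates near the well-nourished
boundary — the intended necrotic-core/proliferating-rim structure. The
LQ coefficients keep the conventional α/β = 10 Gy ratio for gliomas at
a magnitude that produces a visible but not annihilating per-fraction
kill at desk scale. D_m and the relocation trigger were set so that
enzyme released at the interface crosses it within one stage
(√(2D_mΔt) ≈ 1 voxel) and a fully occupied rim advances the boundary
by a few tenths of a voxel per stage — without this the lattice
boundary could never move. These are modelling choices, not fits.

## Numerical choices and degenerate inputs

* WENO5 ghost cells by even reflection, consistent with zero-flux;
  boundary faces are closed, so the advection step is exactly
  conservative. CFL with the defaults: D_cΔt/h² = 0.04.
* The Heun corrector clips negative densities; cumulative clipped mass
  is reported per stage (~1e-3 of total mass per stage in the default
  experiment).
* w(0,0) := 0 in the rearrangement weight (no cells ⇒ no flux
  mediation); θ_f of an exactly isotropic micro-domain falls back to a
  fixed axis with the correct magnitude (measure-zero case).
* Tensors read from NIfTI are projected to SPD by clipping eigenvalues
  below 1e-12 of the trace; the number of clipped voxels is reported.
* A single-voxel domain is flagged degenerate (no defined normal);
  indicators touching the grid frame are geometry errors.
* The SOR fixed point is verified independent of ω and against a
  sparse direct solve of the same matrix to 1e-8.

## Problem sizes

The standard experiment grid is 32³ (spacing 1), tumour radius 3
centred, oedema radius 11, 45 stages; the assimilation demonstrations
use 24³ with truncated (6-stage) forward runs and observations at
stages 3 and 6. These sizes resolve the phenomena of interest — the
oedema shell spans 8 voxels, so controller values up to ξ ≈ 10 produce
lattice-distinguishable seedings, while larger ξ values collapse onto
the cavity-hugging limit and properly tie — and keep a full
experiment sweep to a few minutes on one CPU.

## Known limitations

* The boundary can only advance (invasion); regression of the domain
  footprint under therapy is deliberately excluded — treatment empties
  the density instead.
* One cancer phenotype; no vasculature or angiogenesis; nutrient
  transport is quasi-static.
* Chemotherapy has no pharmacokinetics: W is constant per
  administration and all drugs act as dose-rescaled equivalents via the
  per-day factor set {1, 1.1, 1.5, 2, 2.4, 2.5, 2.8}.
* Delivery is spatially uniform over the domain (no dose painting).
* For controllers whose length scale q/ξ falls below one voxel, the
  lattice cannot distinguish seedings; the containment experiment then
  reports ties rather than strict decreases.
* The adhesion operator and the boundary relocation law follow the
  framework this model family builds on; their coefficient values here
  are desk-scale choices, not calibrated biology.
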