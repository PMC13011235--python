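# Methods

`crumbflow` computes the intrinsic (Darcy) permeability of binary
pore-space images with a lattice-Boltzmann solver and relates it to the
structural descriptors of cellular solids such as bread crumb.  This note
records the model, the numerical choices, what the synthetic data do and
do not emulate, and the problem sizes the test-suite runs at.

## Flow model

The solver integrates the lattice-Boltzmann equation on D2Q9 (2D) and
D3Q27 (3D) tensor-product stencils with Δx = Δt = 1 and c_s² = 1/3, in
double precision throughout.  Collision acts in *central-moment* space:
moments of the populations about the local fluid velocity,
k_{mnp} = Σ_i f_i (c_x−u_x)^m (c_y−u_y)^n (c_z−u_z)^p.  Because both
stencils are full tensor products of {−1,0,1}, the transform factorises
into per-axis 3×3 Vandermonde contractions plus per-axis binomial shifts
by −u, and is exactly invertible; the compiled kernels and the pure-numpy
reference path in `crumbflow.moments`/`crumbflow.lattice` implement the
same algebra and agree to round-off (cross-checked in the tests).

Each moment relaxes towards the central moment of the third-order
polynomial equilibrium with its own frequency.  The documented moment
ordering and the frequency sets are:

- D2Q9: ω = (1, 1, 1, 1.6, 1/τ, 1/τ, ω*, ω*, 1.8) on
  (k00; k10, k01; k20+k02; k20−k02, k11; k21, k12; k22),
- D3Q27: 1/τ on the five shear moments (k110, k101, k011, k200−k020,
  k020−k002), ω* on the seven third-order moments, 1 elsewhere,

with ω* = 8(2−1/τ)/(8−1/τ).  The shear/third-order pair realises the
"magic" two-relaxation-time combination Λ = 3/16 that pins the half-way
bounce-back wall exactly mid-link; as a consequence the computed
permeability is independent of τ (verified to <1e−7 relative in the
tests).  Kinematic viscosity is ν = c_s²(τ − 1/2).

**Forcing.**  The body force F enters (i) as a half-force shift of the
velocity used for the equilibria, the moment shift and all outputs, and
(ii) as a per-moment source (1 − ω_i/2)·R_i, where R is the set of
central moments of the continuous (Maxwellian-gradient) forcing term:
R = F on the first-order moments, c_s²F on the third-order moments with a
single odd exponent, c_s⁴F on the (1,2,2)-type fifth-order moments, zero
elsewhere.  In central-moment space these sources are
velocity-independent, which makes the scheme cheap and second-order
accurate; one forced collision adds exactly F per node and unit time to
the momentum (asserted to 1e−12 in the tests).

**Boundaries.**  Solid voxels act through half-way bounce-back, folded
into a precomputed pull-streaming gather table over fluid nodes; domain
faces are periodic by default (a "wall" face reflects like a solid
half-way plane).  A uniform body force under full periodicity is
equivalent to an imposed mean pressure gradient ∂P/∂x = −F; the lattice
pressure P = c_s²ρ is then itself periodic, and the physically decreasing
pressure is recovered by adding the force potential (see
`FlowResults.pressure_profile`).

**Steady state.**  The update iterates until the relative L2 change of
the velocity field per iteration falls below ε (default 1e−10).  Checks
run every 100 iterations and compare fields 100 iterations apart against
100·ε; a cheaper monitor on the superficial velocity (`criterion="flux"`)
is used for large porous-sample batches.  Non-finite fields or |u| > 0.3
(the low-Mach guard) abort with a distinct `DivergenceError`.

**Permeability.**  From Darcy's law with the superficial velocity
U_d (force-direction velocity averaged over the *total* volume, solids
contributing zero): k = ρ̄ U_d ν / F in lattice units, k_SI = k·Δx²,
and 1 darcy = 9.869233e−13 m².  Darcy validity requires Re < 1; the
result records the Reynolds number together with the characteristic
length used (domain extent by default — the choice is reported, not
hidden).  On an exactly solvable channel of width H the solver reproduces
the discrete closed form k = H³/(12·n_y)·(1 + 1/(2H²)) to ~1e−8
relative; the 1/(2H²) term is the midpoint-sampling correction of the
parabola, not an error.

## Benchmarks

- *Plane Poiseuille* (Re = 1, force-driven, half-way walls): relative L2
  error vs the analytic parabola ≈ 7e−7 at a 100-node gap, inside the
  published 3.93e−6.
- *Hexagonal disk array vs Gebart's closed form*
  k/R² = 16/(9π√6)(√(π/(2√3(1−ϕ))) − 1)^{5/2}: within 5% for ϕ ≥ 0.7.
  The test-suite runs a half-scale cell (220×127, preserving the √3
  aspect ratio) at R = 30 and 34, where the deviations are −2.3% and
  −1.1%; deviation grows at low porosity and at small R/Δx, as expected
  for a staircase boundary.
- *FCC sphere packing*: the cell has spheres at the corners and face
  centres of a cube of side L, touching along the half face diagonal, so
  the sphere diameter is D = L/√2 and the void fraction is
  1 − π/(3√2) = 0.25952.  A node is solid iff its (half-integer) centre
  lies inside a sphere under minimum-image distances.  Our discrete
  k/D² converges to the multipole-solution reference 1.7360e−4 *from
  below* (−6.7% at L = 32, −4.8% at L = 96, consistent with first-order
  staircase convergence; the simple-cubic packing behaves the same way
  against its own classical reference).  Published resolution studies
  that approach the reference *from above* imply a discretisation whose
  staircase opens rather than narrows the sphere-contact throats; with a
  node-centre voxelization (and the variants we tried: integer/offset
  node centres, strict/inclusive inequalities, supersampled majority
  voxelization) the close-contact throats always come out slightly
  narrower than the continuum, so those finite-resolution values are not
  reproducible here even though both sequences share the same limit.
  The corresponding acceptance test is left failing deliberately rather
  than re-tuned.

## Synthetic crumb foams

No micro-CT data ship with the package, so `crumbflow.foam` generates
closed-cell images that emulate crumb structure: gas cells from a
weighted-Voronoi tessellation (periodic, additive lognormal weights),
walls of uniform thickness along the cell boundaries, and small
cylindrical "broken-hole" perforations through walls between
Delaunay-adjacent cells.  Key properties:

- the wall thickness is solved by bisection so the achieved porosity is
  within ±0.01 of the target — perforations included in the budget;
- with no perforations the cells are isolated closed pores (no
  percolation), mirroring unruptured crumb: connectivity is controlled
  *only* by wall rupture;
- `orientation_bias` splits the piercing budget between walls whose
  piercing chord is dominated by axis 0 and the rest (0.5 = isotropic
  Bernoulli(p) for every wall);
- `elongation` stretches the cells along axis 0 volume-preservingly,
  emulating the elongated bubbles of proofed dough;
- identical seeds give identical images.

Defaults represent the imaged loaf: 400×400 voxels at 18.7 µm, porosity
0.70 (sample range 0.65–0.74), median cell radius 0.25 mm, perforation
radius 3 voxels (~56 µm).

What the generator does *not* emulate: grayscale noise and segmentation
artefacts, curved/sub-voxel wall geometry, wall-thickness gradients near
the crust, and the long-range heterogeneity of a real loaf.  Tests
passing on these foams therefore validate the *solver and the
descriptor–transport logic*, not image-processing robustness.

## Structural metrics

Porosity, face-connected component labeling (4/6-neighbour; diagonal
contacts do not conduct under bounce-back), direction-relative main and
secondary connectivity flags, spanning-cluster effective porosity,
local thickness (largest inscribed sphere, computed by descending-radius
sphere painting over the Euclidean distance transform and verified
against an exhaustive oracle; thickness = 2·EDT_max − 1 voxels, image
border treated as open), volume-weighted D10/D50/D90 with linear
interpolation, skeleton graphs from medial-axis thinning (full
connectivity, adjacent junction voxels merged into one node), branch
tortuosity = Euclidean-step arc length / endpoint chord with the valid
filter *distinct endpoints and chord > 1 voxel*, unweighted mean over
valid branches, and triple/quadruple junction counts.  Thinning is only
approximately rotation-equivariant; mean tortuosity is reproducible
under 90° rotation to ~2%.

## The correlation study

`ensemble_study` pools *both flow directions of every image*: main and
secondary connectivity are defined relative to the applied force, so on
an anisotropic image a connected perpendicular network flags flow along
the badly-connected direction.  This pooling is what gives secondary
connectivity its negative correlation with permeability — with flows in
only one direction it would simply proxy overall openness and correlate
positively.  The standard protocol (`crumb_ensemble_params`) emulates
repeated slices of a single anisotropic loaf: elongation 2.0 and rupture
bias 0.8 fixed, porosity ~ U(0.65, 0.74), rupture probability swept over
U(0.05, 0.95), 52 seeds × 2 directions = 104 observations at 64×64
(desk-scale).  With it, main connectivity shows the largest positive
Spearman rs (~0.45), secondary connectivity a negative rs, and
tortuosity/junction counts correlate negligibly — the qualitative
structure reported for real crumb.  Spearman statistics come from scipy
(t-approximation for n ≥ 10, exact pairing permutation below); p-values
are raw, starred at 0.05/0.01/0.001, with no multiple-testing correction.

## Coarsening and REV

`coarsen` applies the strict >50%-solid block rule (ties → fluid) and
scales the voxel size.  On crumb-like foams whose walls are ≥ ~5 fine
voxels (the 0.8 mm-pore fermentation-bubble scale at 18.7 µm), factor-4
coarsening moves porosity by under 2% while permeability rises several-
fold — the throat-enlargement artefact that makes coarse grids cheap but
unreliable for transport.  Thinner-walled images erode faster; the
porosity drift is governed by the wall-thickness-to-coarse-cell ratio.
`extract_rev` takes centred, nested crops; `rev_analysis` tabulates
descriptors (and optionally directional k) against crop size and flags
the plateau.

## Problem sizes and runtimes

The test-suite and the acceptance script are sized for a single CPU:
Poiseuille 8×102, Gebart 220×127, FCC up to L = 64 (the L ≥ 128 entries
of the resolution ladder are reached only through the voxel-porosity
check), foams 48²–256², ensemble 52 foams at 64².  The compiled kernels
(numba, single-thread) run at roughly 5–15 million lattice-site updates
per second, so the full suite completes in a few minutes.

## Known limitations

- Single-phase, Newtonian, creeping flow only; no inlet/outlet pressure
  boundaries (body force + periodicity instead).
- Staircase walls: first-order geometric convergence; narrow throats
  (sphere contacts, thin perforations) carry the largest error.
- Skeleton metrics inherit the thinning algorithm's grid anisotropy.
- 2D foams percolate differently from 3D ones; quantitative descriptor
  values are scale- and dimension-specific even where the sign structure
  is robust.
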