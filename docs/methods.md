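# Methods

`poresim` couples a continuum electrokinetic description of a nanopore with
Brownian-dynamics (BD) sampling of protein trajectories.  This note records
the model equations, the numerical choices behind each module, the defaults
and why they were chosen, and the known limitations.

## Geometry and units

Pores are axisymmetric: a piecewise-linear wall-radius profile R(z) over a
channel of length L (z = 0 at the upper entry, z increasing upward), an
optional planar membrane slab, and a cylindrical electrolyte reservoir.
Square cross-sections and box reservoirs (the DNA origami pore is nominally
6 × 6 nm²) are represented by circles of equal area in this reference mode;
the nominal shape is kept in the spec metadata.  All user-facing lengths
are nm, voltages mV at the CLI (volts in the library), currents A
internally; conversion to SI happens at module boundaries.

Meshes are structured, graded tensor grids in (r, z) with cell-wise region
tags (fluid, wall, membrane, protein).  Grading anchors refine near walls
(default 0.25 nm), charged walls (electric-double-layer resolution,
default 0.035–0.05 nm at 1 M where the Debye length is 0.30 nm), the
protein surface, and the channel mouths, growing to 1.5–2 nm in the
reservoir.  When a protein sphere is meshed, grid edges are aligned with
its equatorial radius and poles so the staircase representation has the
exact radial extent where the conduction gap is narrowest; this measurably
reduces the blockade's sensitivity to mesh realization.  Defaults were set
by refinement studies on the toy-cylinder conductance and the DNA-pore
blockade (the suite re-checks stability under refinement).

## Continuum solver (PNPS)

The steady Poisson–Nernst–Planck–Stokes system for a symmetric monovalent
electrolyte is discretized with finite volumes on the axisymmetric grid:

* **Poisson** over the whole domain with per-material permittivity
  (water 80.2, protein 2, DNA 12, lipid 2, SiN 7, gold 6.9, SAM 2.7) and
  surface charge entering as face sheet-charges on tagged fluid–solid
  faces.  Electrode plates are Dirichlet surfaces at the reservoir top and
  bottom; the applied voltage V is φ(bottom/trans) − φ(top/cis), so
  negative bias points the field from cis to trans and drives a positively
  charged protein down the pore.
* **Nernst–Planck** on fluid cells with Scharfetter–Gummel exponential
  fitting; the face Péclet number combines electromigration and advection,
  which keeps concentrations positive and makes the discrete fluxes exactly
  conservative (the current integral is cross-section independent to
  round-off, which the suite asserts).  Ion diffusivities are tensor fields
  evaluated at faces (D_rr on radial, D_zz on axial faces).
* **Stokes** on a MAC staggered grid with the electric body force
  −C_F(c⁺−c⁻)∇φ, no-slip on solids, and "do-nothing" (zero pseudo-traction)
  open boundaries at the reservoir top/bottom so electroosmotic through-flow
  is not artificially blocked.

The blocks are coupled by a damped Gummel fixed point (default relaxation
0.5, relative residual 10⁻⁶, 80 iterations) with a Boltzmann-consistent
linearization of the Poisson step — the ionic charge is linearized as
c± exp(∓qδφ/kT), which adds a stabilizing diagonal and makes the iteration
robust through 1 M double layers.  The conical solid-state pore at ±200 mV
converges with stronger damping (relaxation 0.3, ≤400 iterations), which
its workflows set.  The Stokes matrix is factorized once per mesh and
re-used across Gummel iterations (and voltages).

Validation oracles: the uncharged 5 nm × 20 nm cylinder reproduces the
series model L/(σπR²) + 2·(1/4σR) (channel plus two Hall access
resistances) within 0.5%; zero bias yields machine-zero current and
velocity; the current is antisymmetric in V.

**Forces.**  F_el integrates (uniform protein volume-charge density) × E
over the protein region.  F_drag is evaluated by a momentum balance of a
two-cell fluid shell around the protein: the fluid stress integrated over
grid-aligned control faces plus the electric body force inside the shell;
this avoids one-sided stress evaluation on the staircase sphere surface.
A low-salt, permittivity-matched configuration recovers F_el = QE to 5%,
and a translating sphere recovers Stokes drag (below).

## Hydrodynamics and hindered diffusivity

The friction tensor of a sphere is computed from Stokes solves with unit
boundary velocity on the sphere ("LRNH").  For on-axis spheres, two
two-dimensional solves give the full tensor: the axial problem is the
axisymmetric mode m = 0, and the transverse problem is solved in the
azimuthal Fourier mode m = 1 with amplitude fields
(u_r cos θ, −u_θ sin θ, u_z cos θ, p cos θ); the m = 1 reduction of the
vector Laplacian couples u_r and u_θ through −(2η/r²)(u_r − u_θ) terms and
adds −u_z/r² to the axial momentum.  Drag is evaluated from the viscous
dissipation (F·U = ∫2η e:e dV for rigid motion with quiescent far field),
which is markedly more robust on staircase spheres than surface tractions.
Mesh sizing is gap-adaptive (sphere surface ≈ a/10, sharpened to gap/8 near
walls).  D = kT γ⁻¹ (Einstein relation).

A sphere centred in a wide open domain recovers 6πηa within ~2% in both
directions.  Against the closed-form plane-wall factors, numerical factors
agree within 5% for h/a ∈ [1.2, 10] when the domain is wide (R ≈ 150a);
in narrower domains the comparison is confounded by lateral-wall
corrections that do not cancel between the near-wall and reference solves.

Closed forms: parallel motion uses the Faxén series
1 − (9/16)s + (1/8)s³ − (45/256)s⁴ − (1/16)s⁵, s = a/h (h the centre-to-
wall distance); perpendicular motion uses the Padé form
(6g² + 2ag)/(6g² + 9ag + 2a²) in the surface gap g = h − a, which has the
correct lubrication limit at contact.  The g-form was chosen (rather than
evaluating the same expression in h) because only it matches the numerical
LRNH oracle within the 5% band across the whole range.

Four field models map these ingredients onto a pore:

* `bulk_constant` — D₀I everywhere (Stokes–Einstein, ion radius 0.11 nm
  chosen so D₀ matches measured bulk diffusivities).
* `r_dependent` — plane-wall factors of the distance to the nearest wall,
  in the eigenframe of the nearest-wall normal.  An explicit protein
  counts as a wall, which couples the ion diffusivity to the protein
  position during blockade computations.
* `z_dependent` — centerline LRNH tensors (PCHIP-interpolated between
  stations; 20 stations by default, 5 in the packaged workflows where the
  bore is uniform) extended radially.
* `combined_rz` — the r-model rescaled per z so its centerline value
  equals the centerline LRNH tensor; the scale is clipped at 1 so the
  normalization can only shrink.  This is the reference model.  On the
  centerline it equals `z_dependent` by construction; in wide pores it
  tracks direct LRNH within 10% at interior on-axis points.

Degenerate inputs: factors are floored at 10⁻³ in the slip regime where
the bore is comparable to the particle (instead of extrapolating below
zero).  `lrnh_numeric` is available pointwise for on-axis spheres only —
off-axis spheres break axisymmetry and would require 3-D solves; off-axis
the closed-form models are the operative description, which mirrors the
approximation hierarchy the field models encode.  At the centerline of a
cylindrical pore the nearest-wall eigenframe makes the azimuthal and axial
factors equal, which overconstrains the true (transversely isotropic)
tensor; the error is confined to the axis neighbourhood and does not
enter D_rr/D_zz used by the continuum solver.

## Force/current tables and interpolation

Forces and currents are sampled once per study onto a structured (r, z)
table covering channel and near-reservoir (default spacing 1 nm in the
channel, 2 nm outside; several hundred admissible positions for the
presets).  On-axis stations (default every 2 nm; 4–8 nm in the scaled
workflows) are *explicit*: the protein is meshed and the full PNPS system
re-solved.  Off-axis entries use a *point-particle* closure on the
protein-free solution, F = QE(x) + γ(x)u(x), with γ from the protein's
hindered-diffusivity field — off-axis explicit solves would break
axisymmetry.  Off-axis currents reuse the on-axis blockade profile at equal
z inside the channel (the radial clearance there is a fraction of a
nanometre) relaxing to the open-pore current over ~2 pore radii in the
reservoir; blockade amplitudes are therefore most accurate for in-channel
positions, which dominate every event's signal.  Interpolation is
multilinear on the structured grid, exact at nodes and non-overshooting;
inadmissible nodes are filled with the nearest valid value and masked.

## Brownian dynamics

The discretized overdamped Langevin update is

    x' = x + dt ∇·D + (dt/kT) D F + √(2dt) C ξ,   D = CCᵀ,

with C from a batch Cholesky (eigenvalue-clipped symmetrization as a
fallback) and ∇·D by central differences with a 0.05 nm stencil directly
on the tensor field (a stencil-refinement test guards the choice).  The
spurious-drift term is what keeps a spatially varying D sampling the
correct stationary law; the suite verifies a uniform density under a 4×
diffusivity gradient and a Boltzmann distribution in a harmonic trap
(χ² at the 1% level, with the O(dt) Euler–Maruyama variance inflation
1/(1 − θ/2) accounted for).

Steps that would penetrate a wall are truncated by bisection to stop
10⁻³ nm before contact (hard-sphere reflection).  Termination follows the
preset rules: translocation when the centre passes the far channel end,
escape when it leaves a boundary region beyond the entry (the 10 × 10 ×
12 nm³ box above the DNA-pore entry, as an equal-area cylinder in the
axisymmetric mode), or a step cap (5×10⁵ by default) as an explicit
`max_steps` flag.  Termination is evaluated on the raw proposal, before
reflection, so the escape surface is not masked by the domain boundary.
Time steps are 0.2 ns (DNA pore) and 1 ns (solid-state pore); toy tests
choose dt so that √(6D dt) is well below the smallest geometric feature.

Randomness comes from counter-based Philox streams keyed by (global seed,
trajectory index), consumed in aligned blocks: each trajectory's noise is
reproducible bit-for-bit regardless of how trajectories are batched.

## Binding and events

A binding site is a tethered spherical receptor (binding zone: spherical
shell between centre distances r_prot + r_rec and the centre-to-site
threshold r_b) or a wall region (r_rec = 0; r_b measured from the protein
surface, default 0.2 nm).  While the centre is in the zone, adsorptions
are Poisson with rate R_a = k_a c_b, c_b = (10³ N_A V_b)⁻¹ mol/L.  Binding
durations are exponential with Bell-law mean k_d⁻¹ exp(−|F|δ/kT), using
the force magnitude recorded at the in-zone step (a bead model defines no
bond direction; δ = 0 disables force dependence and is the DNA-pore
default).  Multiple adsorptions drawn in one step apply sequentially.
Because binding never alters a trajectory's spatial shape, events can be
generated after the fact, and rare-binding statistics use trajectory
resampling: pick a random trajectory, redraw bindings, assemble the event
(duration = free time + bound time; amplitude = time-weighted average of
the blockades).  The resampler conditions exactly on the drawn total count
(multinomial site split, uniform step assignment), with a fast path for
the overwhelmingly common zero-binding events.

Event analytics: k_off = 1/mean(τ_off) with bootstrap CIs; exponential and
two-component-mixture dwell-time fits by direct maximum likelihood
(Nelder–Mead, 10 random multistarts, left-censoring by survival
renormalization — e.g. discarding events below 100 μs that recordings
would filter); voltage dependence as a least-squares line in log₁₀ k_off.

## Packaged study workflows and problem sizes

`poresim.workflows` fixes the study conditions: DNA pore at 1 M KCl,
trypsin as a 2.078 nm sphere with +5q, −80 mV for blockades and ensembles,
−100 mV for the open-pore current, EDL-resolving meshes (0.035 nm at the
charged wall, 0.04 nm at the protein surface), 5 centerline stations, and
500-trajectory ensembles; the solid-state workflow runs the printed
receptor/rate constants (k_a 1.5×10⁵ /(M s) solution vs 5.2×10⁶ inferred,
k_d 25×10⁻³ /s, δ = 0.55 nm, binding radius 5.75 nm, receptor at 95% of
the channel height and 2.75 nm off the wall) at a deliberately reduced
scale — O(10²) trajectories resampled into O(10⁶) events rather than 10⁵
trajectories into 10⁷⁺ events — which reproduces the rare-binding
structure (≥99.97% of events unbound; binding fraction linear in k_a) with
order-of-magnitude absolute fractions.

## What the synthetic conditions do and do not show

The generator-side geometry idealizes pores as rigid axisymmetric solids:
no DNA-duplex flexibility or lateral membrane pressure (which is precisely
why the nominal 6 nm DNA pore conducts several-fold more than measured and
why the blockade-matching width is the informative output), no atomistic
charge maps (the protein-channel preset is a parameterized profile built
from headline dimensions only; its absolute conductance is therefore
indicative, not predictive), no protein rotation or conformational
dynamics, no finite-ion-size corrections in the continuum equations, and
no hydrodynamic memory.  Passing tests demonstrate internal consistency
against analytic and numerical oracles and reproduction of the modeled
system's statistics — not agreement with any particular experimental
recording beyond the quantities explicitly compared.

## Known limitations

* Explicit (meshed-protein) solves exist on the axis only; off-axis force
  and blockade entries are closures (documented above).
* The staircase representation of spheres limits single-solve drag
  accuracy to a few percent; dissipation-based drags and aligned equator
  edges mitigate but do not eliminate this.
* The Gummel iteration needs stronger damping at high bias and strong
  surface charge; there is no automatic continuation in voltage.
* Simulated solid-state transit times are several-fold shorter than the
  recorded 1–10 μs under the printed drive parameters, so absolute
  rare-binding fractions at reduced scale are order-of-magnitude.
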