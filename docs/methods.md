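# Methods

## Model

The system is a planar film of grafted, cohesive homopolymers (FG Nups) in
contact with a reservoir of cohesive hard spheres (NTRs).  All equilibrium
structure follows from a grand-potential functional of the one-dimensional
density profiles ρᵢ(z) and the polymer mean field w(z):

Ω = F_ideal-gas + F_ideal-polymer + F_mean-field + F_external
  + F_exchange + F_cohesion + F_hard-sphere

with the terms:

* **Ideal gas** — ∫ρᵢ(ln λ³ρ̂ᵢ − 1) for each free species.  Thermal
  wavelengths are set to one length unit: they shift each chemical
  potential by a constant that cancels once densities are referenced to
  the reservoir, so no observable depends on them.
* **Ideal polymer** — −N ln Z_c[w] for N freely jointed chains of M
  tangent beads in the field w(z), with a rigid bond whose z-marginal is
  uniform on [−ℓ, ℓ] (the exact projection of an isotropically oriented
  rod).  Z_c is evaluated by forward/backward transfer-matrix propagators;
  the polymer is canonical (fixed chain number), particles are grand
  canonical.
* **Mean field** — the compensating −∫w ρ₃ term that makes w a free
  variational field.
* **External** — a WCA wall 4ε_ext[(σ/z)¹² − (σ/z)⁶] + ε_ext for
  z < dᵢ (σᵢ = 2^(−1/6)dᵢ), ε_ext = 20 kT, applied to every species.
* **Exchange** — −μᵢ∫ρᵢ for the free species.  The reservoir convention
  is "direct ρ_bulk": μ_exc = 0 and the stated concentration is the
  reservoir activity.  At µM concentrations the self-consistent far-field
  density then equals the stated concentration to ≲1 %; an explicit
  μ_exc per species is supported (used e.g. by the wall-theorem test to
  pin a dense reservoir at exactly η = 0.2).
* **Cohesion** — mean-field double convolutions with laterally integrated
  Morse kernels (below).
* **Hard sphere** — White Bear FMT plus a Yu–Wu chain-connectivity
  correction, via planar weighted densities.

Minimisation gives, for particles, ρᵢ = ρ_bulk,i·exp(μ_exc,i + cᵢ(z) −
Σⱼ(U_ij ⊛ ρⱼ) − V_ext,i) and, for the field, w = −c₃ + Σⱼ(U_3j ⊛ ρⱼ) +
V_ext,3, with cᵢ = −βδF_hs/δρᵢ the one-body direct correlation function
(standard liquid-state sign; the non-interacting limit reduces to the
barometric profile, which the test suite asserts).

## Cohesion kernels

Pair cohesion is based on the Morse potential
u(r) = ε(e^(−2α(r−d_ij)) − 2e^(−α(r−d_ij))) with a single inverse range
α = 6 nm⁻¹ and contact distance d_ij = (dᵢ + dⱼ)/2.  Because excluded
volume is already carried by the hard-sphere functional, only the
*cohesive part* of the Morse enters the mean field: u is kept where it is
negative (r ≥ r₀ = d_ij − ln2/α) and set to zero inside r₀, where the
Morse turns repulsive.  Including the soft e^(+2αd_ij) core would
double-count repulsion on a scale of 10²–10¹⁷ kT·nm² and make every
kernel net-repulsive; with the cohesive part only, every parametrised
kernel has a negative integral (net attraction), the calibrated
ε_FG-FG = 0.275 kT reproduces the 26 ± 2 nm film thickness with the
sensitivity dτ/dε ≈ −100 nm/kT (so the stated ±0.025 kT uncertainty maps
onto ±2 nm), and inert probes of ≥4 nm meet barriers of order 10 kT —
the three anchors that jointly fix this convention.

The lateral integral U(z) = 2π∫_{|z|} r u(r) dr has a closed form
(verified against adaptive quadrature); kernels are tabulated on grid
offsets, shifted by −U(z_cut) and truncated at z_cut = 2d_ij, making them
continuous at the cutoff and exactly zero beyond.  Shift-then-truncate
versus truncate-then-shift are identical here.

## Discretisation and numerics

* Grid: L = 1024 slices of Δz = 0.117 nm (midpoints z_k = (k+½)Δz), box
  height 119.8 nm ≫ film thickness, so the top of the box is a bulk
  reservoir.  Convolutions pad with zero below the wall and with the
  reservoir density above the box.
* FMT weights are integrated exactly over each Δz bin, so every discrete
  kernel quadrature equals its analytic sphere measure (∫w₃ = 4πR³/3
  etc.) to machine precision, partial edge bins included.
* The removable n₃ → 0 singularity of the third White Bear term is
  evaluated by Taylor series below n₃ = 10⁻³ (limit 1/(24π)); local
  packing n₃ ≥ 1 raises an overpacking signal that the solver treats as a
  failed step.
* The chain functional uses total-mixture weighted densities inside the
  contact value y and the polymer-only n₀ as prefactor (the convention
  that reproduces the one-component contact value (1−η/2)/(1−η)³ and
  keeps the functional variationally consistent — the finite-difference
  identity cᵢ = −δF/δρᵢ is a property test).  The chain contribution to
  the *particle* correlations is retained: dropping it suppresses NTR
  binding almost entirely, incompatible with µM-range adsorption at
  ε ≈ 2.4 kT.
* ζ = 1 − (n_v2/n₂)² is set to 1 (derivatives 0) where n₂ vanishes.
* Chain propagators renormalise every step (peak division) and accumulate
  the logs into ln Z_c; bead marginals are normalised per bead, making
  bead-count conservation exact at every iteration.  The recursion runs
  in a numba JIT when available, with an algebraically identical numpy
  path (equality is itself a test).
* Grafting: bead 1 is confined to the first slice where the bead wall
  potential drops below ε_ext (≈ z = d₃), i.e. immediately above the wall
  exclusion; the slice index is overridable.  Bond length ℓ = d₃
  (tangent beads).

## Solver

Damped Picard iteration in fictitious time: x ← x + Δt(target(x) − x) for
w and each particle profile, with the polymer density recomputed from w
each step.  Δt starts at 0.002, grows 2 %/step to at most 0.01, and is
halved (with rollback to the best state) if the relaxation itself
misbehaves.  Particle targets are trust-region-capped at e² times the
current profile (plus a small refill floor) so that early Boltzmann
factors of e^(+20) cannot overshoot into overpacked states; the cap never
binds at a fixed point.  Once the residual falls below 1, type-II
Anderson mixing (depth 4) over the damped map accelerates the linear
tail (typically 5–10×); a misstep — divergence, overpacking, or a 3×
residual jump after an accelerated step — reverts to the best state,
flushes the mixing history and re-enters plain relaxation for a cooldown
window that doubles on repetition.  The converged answer is independent
of the path (asserted by warm- vs cold-start tests).

The residual is the sup norm of the Euler–Lagrange violation:
max(|w − w_target|∞, maxᵢ|ln(ρᵢ/ρ_target,i)|∞ outside the wall region).
Default tolerance 10⁻⁸ — far below the precision of any reported
observable (thickness to 0.01 nm).  Unconverged runs are returned flagged,
never silently.

At convergence the two PMF forms — −ln(ρ/ρ_bulk) and the explicit sum
−c + V_ext + Σ(U⊛ρ) − μ_exc — agree pointwise to the residual; their
discrepancy bounds the physical error of a solution.

## Observables: definitions and windows

* τ: smallest z containing 95 % of the polymer density, linearly
  interpolated within the crossing slice.
* Γ: rectangle-rule ∫₀^τ ρ̂ dz including the partial top slice,
  converted to pmol/cm² (1 nm⁻² = 166.05 pmol/cm²).
* Packing fraction η = ρ̂·πd³/6 (a true volume fraction; the
  dimensionless ρ̂·d·A column is also emitted for figure-style plots).
  η(z) is a local quantity of the 1D profile: sharp packing layers can
  push its peak above 1 even though the smoothed FMT fraction n₃ stays
  below 1.
* Well depth/location: −min W and argmin over the film interior,
  windowed from wall contact (z = dᵢ) to τ + 5 nm; the same window is
  used for inert-probe barrier maxima.  The window is a convention of
  this package (wells and barriers of the reference system are far from
  its edges).
* Overlap coefficient: ∫min(p₁, p₂)dz of the film-restricted
  (z ≤ τ + 5 nm) normalised profiles; the margin keeps the film-surface
  layer of an expelled species inside the comparison region.  Demixing
  threshold 0.5 (the qualitative notions "substantial overlap" vs
  "sufficiently separated" need a number to become a classifier); it is
  a config parameter, and the phase
  labels (size-driven / cohesion-driven / both) use a ±0.2 band around
  ratio 1.  A species with Γ below 10⁻³ pmol/cm² counts as separated by
  expulsion.

## What the reference parameter set does and does not reproduce

All computed numbers quoted here are produced by the test suite and
`scripts/acceptance.py`; none are transcribed.  With the calibrated
parameters the package reproduces: the bare-film thickness (26.2 nm,
inside the 26 ± 2 nm band); size-monotone inert exclusion with ~10 kT
barriers at ≥4 nm; wall-adjacent packing maxima ≥0.15 for single NTRs at
10 µM; the roughly twofold well-depth reduction between 0.01 and 10 µM;
the expulsion of Imp-β to the film surface under NTF2 crowding, with an
interior barrier; monotone isotherms; and demixing of the NTF2/Imp-β
pair versus full mixing of identical particles.

Quantitatively, this implementation binds NTRs a few kT more strongly
than the originally reported behaviour of this system (wells of ≈13 kT
rather than ≈9 kT at
0.01 µM; a well-depth change of 5.3 kT rather than 4–5 kT, hence an
Arrhenius ratio of ≈195 rather than ≈100; the ternary Imp-β well at
≈29 nm rather than ≈25 nm).  The NTR binding free energy is a small
difference of two ~80 kT quantities (mean-field attraction versus
hard-sphere insertion work), so few-percent differences in kernel or
functional discretisation shift wells by kTs; the NTR cohesion strengths
were originally calibrated against experimental isotherms, which are
external data outside this package's scope, so the printed ε values are
used unmodified rather than recalibrated.

## Limitations

* Strict planarity (1D): no lateral structure, no pore geometry; the
  height-segregated demixing found here is not the only segregation mode
  a cylindrical pore allows.
* Homopolymer FG Nups and uniformly cohesive NTRs: no sequence detail,
  no binding-site multivalency, no cargo.
* No NTR–NTR attraction, by construction.
* Mean-field cohesion and FMT excluded volume neglect short-range
  attraction–correlation coupling; the cohesive-core convention (zero
  inside r₀) is exact only to the extent that core configurations are
  suppressed by packing.
* Equilibrium only: the Arrhenius ratio helper is illustrative
  arithmetic on well depths, not a kinetic calculation.
* Concentrations ≫10 µM of the 6 nm species produce strong layering;
  solves remain convergent but slower, and packing-peak observables
  become sensitive to Δz.
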