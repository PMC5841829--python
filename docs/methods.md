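# Methods

This note documents the models implemented in `multicell`, the
numerical choices behind them, the reference parameter set, and what
the desk-scale showcase configurations do and do not demonstrate.

## Microenvironment

The chemical microenvironment is a vector of substrate densities on a
uniform Cartesian mesh (default voxel edge Δx = 20 µm, comparable to
one cell diameter — the cell-centered source discretization below is
accurate when voxels are at least cell-sized).  Each substrate evolves
under diffusion (D, µm²/min), linear decay (λ, 1/min), bulk
supply/uptake toward a saturation density, and cell-centered
sources/sinks.

One step of length dt applies, in order (first-order operator
splitting, each piece unconditionally stable):

1. **Bulk source/sink**, backward Euler per voxel:
   ρ ← (ρ + dt·S·ρ*) / (1 + dt·(S+U)).
2. **Cell sources/sinks**, backward Euler in the voxel containing each
   cell center, with the cell's volume W_k as source weight:
   ρ ← (ρ + dt·(W_k/V_voxel)·S_k·ρ*_k) / (1 + dt·(W_k/V_voxel)·(S_k+U_k)).
   The W_k/V_voxel scaling keeps total secreted mass independent of
   voxel size.  Cells sharing a voxel are applied sequentially in
   ascending cell order; the ordering effect is O(dt²).  The
   backward-Euler form guarantees ρ ≥ 0 regardless of sink strength.
   For a population whose positions, volumes and rates are frozen
   between the (much less frequent) cell and mechanics updates, the
   per-voxel factors are precomputed once and re-applied each
   diffusion step.
3. **Diffusion-decay** by the locally one-dimensional (LOD) method:
   one backward-Euler, centered-difference 1-D solve along x, then y,
   then z (fixed order, for regression determinism), each sweep
   carrying λ/3 of the decay.  Every strip along an axis shares the
   same tridiagonal matrix, so the Thomas forward-sweep coefficients
   are computed once per (axis length, D·dt/Δx², λ·dt/3) and cached;
   the sweeps themselves are numba-compiled loops.  Zero-flux closure
   modifies the first/last diagonal entries, which makes the matrix
   column-sum-preserving: with λ = 0 and no sources, total mass is
   conserved to round-off.

**Boundary conditions.**  The domain faces are zero-flux by default.
Per-voxel Dirichlet overrides (used for, e.g., a fixed 38 mmHg oxygen
tension at the boundary of a culture domain) are re-imposed after
every sweep and sub-step; they are applied on boundary voxels, not
ghost voxels.

**Accuracy.**  The scheme is first-order in time and second-order in
space.  On an oxygen-like problem (D = 10⁵ µm²/min, λ = 0.01/min,
cell-like sinks, Dirichlet boundary) at dt = 0.01 min and Δx = 20 µm,
the maximum relative error against a dt/100 reference is well under
5% (≈0.4% at 1 mm³; `scripts/acceptance.py` recomputes this).  Note
one discretization artifact of strong sinks: a per-step backward-Euler
sink of strength λ_c removes at most a factor 1/(1+λ_c·dt), so the
effective continuous-time uptake saturates at ln(1+λ_c·dt)/dt; very
strong uptake therefore requires a small diffusion step.

## Cell volume

Each cell tracks total, fluid, nuclear-solid and cytoplasmic-solid
volumes (V, V_F, V_NS, V_CS) relaxing toward phenotype-set targets:

    dV_F/dt  = r_F (f_F·V − V_F)
    dV_NS/dt = r_N (V_NS* − V_NS)
    dV_CS/dt = r_C (f_CN·V_NS* − V_CS)

integrated by forward Euler with targets evaluated at the step start
(the alternative end-of-step evaluation differs at O(dt²)).  Negative
overshoot at very large dt clamps at zero with a warning rather than
erroring.  The identities V = V_F + V_NS + V_CS and V = V_N + V_C hold
after every operation; since only total fluid is modeled, the
nuclear/cytoplasmic compartments split the fluid proportionally so
both share the cell-wide fluid fraction (keeps nuclear radius
well-defined for geometry and rendering).  Radii derive from volumes
assuming spheres.

Cycle and death steer the cell by moving targets: V_NS* doubles on
cycle re-entry (Q → K1) and halves — along with every sub-volume — at
division; apoptosis sets f_F = f_CN = V_NS* = 0 with apoptotic rate
constants; necrosis sets f_CN = V_NS* = 0 and f_F = 1 (oncotic
swelling) until the volume passes the rupture threshold (2× the
mature volume by default), after which f_F = 0 with a slow fluid-loss
rate; dead cells are removed at V ≤ 20 µm³, apoptotic cells also after
the apoptosis duration T_A.

Exact solutions of this linear system (including the forced fluid
equation) are implemented in closed form and used as the oracle for
convergence testing.  At dt = 6 min the maximum relative error over
proliferating, apoptotic and necrotic trajectories is ≈1.7%,
converging at first order.  Errors are measured relative to each
compartment's characteristic magnitude (its largest exact value over
the trajectory, including t = 0): an exponentially decaying
compartment is not judged against its own vanishing tail, where any
explicit integrator's relative error grows without bound while the
absolute error is negligible.

## Cycle and death

A cycle model is a directed graph of phases with per-edge transition
rates r_ij (1/min), runtime-mutable per cell, optional arrest
predicates, entry/exit hooks, and one division-marked edge.  Per step,
a stochastic edge fires with probability r_ij·dt (clamped to 1, with a
warning when r·dt > 1); a fixed-duration edge fires on the step where
the accumulated phase time first reaches 1/r_ij.  Death uses the exact
exponential form 1 − exp(−r·dt); the cycle uses the linear form — both
as conventionally printed, equal to O((r·dt)²).  Per-step Bernoulli
trials (rather than pre-sampled waiting times) keep rates freely
mutable mid-phase; the resulting waits are geometric with mean exactly
1/r at the step resolution.

Built-in models:

* **Ki67-advanced**: K1 (Ki67⁺ pre-division) → K2 (Ki67⁺
  post-division) → Q (Ki67⁻ quiescent) → K1.  Division occurs on
  traversal of the K1 → K2 edge, so both daughters begin in K2.  The
  quiescence exit rate is r_Q1 = (1/T̄_Q)·max{(pO₂ − pO₂_hyp)/(p̄O₂ −
  pO₂_hyp), 0}.  K1/K2 durations are deterministic in the tumor
  examples and exponential in the stochastic validation.
* **Live**: one phase with a division-marked self-edge at a mutable
  birth rate.

Death: each live cell carries an apoptosis rate r_A and a necrosis
rate r_N.  Stochastic necrosis ramps linearly from 0 at
pO₂_threshold (5 mmHg) to r_N,max (1/360 min⁻¹) at pO₂_crit
(2.5 mmHg); deterministic necrosis is the r_N → ∞ limit (certain
death below threshold).  If both death draws fire in one step,
apoptosis wins (the paper-silent tie is broken by fixed precedence).
Apoptotic cells stop secreting and taking up; necrotic cells stop
secreting at onset and stop uptake at lysis (membrane rupture) — dead
cells' substrate exchange is not otherwise specified by the model, and
these defaults are configurable.

**Mean-field validation.**  The expected sub-population counts of the
all-exponential Ki67-advanced model with stochastic-duration apoptosis
satisfy a linear ODE system (with the K1 outflux doubled into K2 by
division and apoptotic cells cleared at rate 1/T_A), solved here by
matrix exponential.  One hundred replicate cohort simulations (initial
100 quiescent cells, 24 h) match that ODE within 3 Monte-Carlo
standard errors at both dt = 6 min and dt = 60 min.  The cohort driver
exercises the real transition and death-draw code but holds volumes at
equilibrium so that apoptotic clearance is governed purely by the
sampled duration, matching the ODE's clearance term.

## Mechanics, motility, motion

Velocities follow from an inertialess force balance with finite-range
pair potentials.  The gradient forms are
∇φ_{n,R}(x) = (1 − ‖x‖/R)^{n+1} x̂ (adhesion) and
∇ψ_{n,R}(x) = −(1 − ‖x‖/R)^{n+1} x̂ (repulsion), zero beyond R, with
smoothness n = 1.  Adhesion acts within the summed maximum adhesion
distances (R_A = 1.25 R by default), repulsion within the summed
radii; cross-type coefficients combine as geometric means, making pair
contributions equal and opposite.  Exactly coincident centers repel
along +x jittered by a cell-index-seeded generator (deterministic
symmetry breaking).  Basement membranes are signed-distance surfaces
(plane, and a capped-cylinder "test tube" duct) with the single-cell
analogues of the same potentials.  Dead cells keep their mechanics
until removal — necessary for the emergent cracked/void structure of
necrotic cores, where shrinking cells continue to adhere.

Motility is a biased persistent random walk: with probability
dt/T_per per mechanics step the migration velocity is redrawn as
s_mot·((1−b)ξ + b·d̂)/‖·‖ with ξ uniform on the sphere; the optional
bias hook (chemotaxis) updates d̂, b, s_mot from the local field
gradient just before the redraw, and the new velocity applies
immediately.

Positions advance by second-order Adams-Bashforth,
x ← x + dt(3/2 v − 1/2 v_prev), bootstrapped with forward Euler when
no previous velocity exists (first step, and both daughters after a
division, so the pair moves symmetrically).  Velocities for all cells
are computed against a frozen position snapshot before any position
moves — a two-phase contract that makes the per-cell loops
order-independent and parallelizable in principle; structural changes
(division, removal, grid re-registration) happen only in serial
phases.  The implementation is single-threaded.

**Interaction grid.**  Cells register in cubic mechanics voxels of
edge 30 µm (asserted ≥ the maximum interaction distance, ≈21 µm for
reference cells).  Candidate neighbors are the 27-voxel Moore
neighborhood, so |N(i)| ≤ 27·V_mech/min_j V_j: 54·V_mech/V when live
cells dominate (minimum volume V/2, a fresh daughter) and
2700·V_mech/V when dead cells dominate (removal at V/100).  The
per-step pair enumeration is fully vectorized (sorted voxel hashing);
pair counts grow linearly with n at fixed density.

**Accuracy.**  Two overlapping reference cells relax to a 16.0 µm
equilibrium spacing; at dt_mech = 0.1 min the spacing error against a
fine-dt reference is ≈0.02%, converging at second order in the
asymptotic regime (dt ≤ 0.2 min; larger steps are pre-asymptotic),
with strictly monotone relaxation.  A compressed 150–600-cell cluster
(scaled from the published 50,000-cell test) decompresses
monotonically with diameter errors ≤5% at the default step.

## Orchestration

Three clocks: dt_diff = 0.01 min, dt_mech = 0.1 min, dt_cells = 6 min
(warned if dt_diff > dt_mech/10).  Each iteration: save if due (first
snapshot at t = 0) → microenvironment update → if due, per-cell
phenotype hook, death draw, cycle advance, volume step, then serial
division/removal queues (death wins when both are flagged) → if due,
motility redraw, velocity computation, custom rules and elastic
attachments, position updates, grid refresh → t += dt_diff.  Events
falling exactly on t_max still run (without a further transport
step).  Clock comparisons use a half-diffusion-step slack so that
~10⁶ float additions cannot drift an event across a boundary.

Randomness is split into five independent, seeded streams (cycle and
death draws, motility, initialization, division placement, contact
rules), so toggling one stochastic feature leaves the others'
trajectories unchanged; a given seed reproduces runs bit-for-bit.
Snapshots (CSV cell tables with full-precision floats + HDF5 fields)
round-trip exactly; together with serialized RNG states, a
mechanics-free stochastic run restored from a snapshot continues
identically to an uninterrupted run.  Mid-run restarts of moving
populations restart the Adams-Bashforth history with an Euler step
(velocity history is not serialized) — an O(dt²) perturbation.

## Reference parameters

Breast-epithelium-like defaults (all in `multicell/reference.py`):
mature volume 2494 µm³ (radius 8.41 µm), fluid fraction 0.75, nuclear
solid target 135 µm³, volume rates r_F = 3/h, r_N = 0.33/h,
r_C = 0.27/h; oxygen D = 10⁵ µm²/min, decay 0.01/min, per-cell uptake
10/min, physioxic boundary 38 mmHg; Ki67-advanced durations T₁ = 13 h,
T₂ = 2.5 h, T̄_Q = 74.35 h at 38 mmHg with hypoxic cutoff 5 mmHg;
apoptosis rate 5.32·10⁻⁵/min with duration T_A = 8.6 h and apoptotic
volume rates (3, 1, 0.35)/h; necrosis thresholds 5/2.5 mmHg,
r_N,max = 1/6 h⁻¹, swelling fluid rate 0.67/h, post-lysis fluid rate
0.05/h, rupture at 2× mature volume, removal at 20 µm³; mechanics
c_cca = 0.4, c_ccr = 10 µm/min, R_A = 1.25 R, n = 1.  These are
reference magnitudes from the breast-cancer modeling literature and
are exposed for editing in one place.

## Desk-scale showcase surrogates

The showcase systems published at 10⁵–10⁶ cells over 2–4 weeks are
run here with hundreds of cells over hours to two days.  Two coherent
rescalings make the same phenomena appear at that size:

* **Space ÷ ~6, D ∝ s².**  Shrinking all lengths by a factor s while
  scaling diffusivities by s² preserves the shape of the quasi-steady
  substrate profiles.  The scaled oxygen D = 2·10³ µm²/min gives an
  oxygen penetration length of ~15 µm, so hypoxia (< 5 mmHg) and a
  necrotic core emerge at spheroid radii of 60–100 µm instead of
  several hundred µm.
* **Cycle durations ÷ 6.**  Compressing T₁, T₂, T̄_Q by one factor
  reproduces the rim-limited, late-time-linear growth regime within a
  48 h window instead of ~18 days.

With these, the scaled spheroid (300–400 seed cells, 400–600 µm
domain, dt_diff = 0.05 min) shows: division restricted to the outer
shell (mean Ki67⁺ radius exceeds the viable average); a sharp
perinecrotic interface under deterministic necrosis versus substantial
viable/necrotic intermixing under stochastic necrosis (measured as
the viable fraction among cells in hypoxic voxels); and late-time
linear diameter growth.  The diameter is measured as the sphere
enclosing 90% of total cell volume around the volume-weighted
centroid, with a 3-point moving average before the linear fit — at a
few hundred cells a single division or removal moves the boundary by
~1 µm, a granularity the published populations average out.

The biorobot, anti-cancer biorobot, heterogeneity and tumor-immune
examples implement their published rule sets directly (receptor-gated
chemoattractant secretion, elastic worker-cargo adhesions with
k = 0.05/min, release above a c₁ threshold or below pO₂_drop =
10 mmHg, drug damage d[damage]/dt = r_damage[drug] − r_repair[damage]
with kill probability r_death·[damage]·dt folded into the apoptosis
rate, oncoprotein p ~ N(1, 0.3) clipped to [0, 2] scaling cycle entry
and immunogenicity, immune adhesion/kill/detach at rates
0.2, 1/15, 1/30 min⁻¹ with migration bias b = 0.5).  The immune and
anti-cancer rates are reference placeholders at desk scale; the
anti-cancer workers home on the cargo signal c₂ (there are no
directors in that variant) and pause where it is absent.

**What passing these tests shows — and does not.**  The showcase
assertions demonstrate that the implemented rules produce the
qualitative emergent behaviors (selection, round trips, perinecrotic
mixing, linear fronts) under the scaled surrogates.  They do not
reproduce published magnitudes (10⁶-cell counts, 18-day growth
curves, the ~1 cm/year DCIS rate); the full-scale DCIS configuration
(1 mm duct, 30 days, unscaled parameters) is provided as the
long-running `multicell validate --suite dcis-growth` check.

## Known limitations

No advective transport; no extracellular-matrix mechanics, polarized
adhesion, or cell morphology beyond spheres; single-threaded reference
implementation (the phase contracts admit parallel per-cell maps);
the interaction grid uses a single voxel size, so packings with a wide
spread of cell sizes pay the worst-case candidate bound; strong sinks
saturate under backward Euler as noted above; snapshot restart resets
the velocity-history term.
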