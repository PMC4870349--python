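# Methods

`gliaxon` simulates regenerating spinal-cord axons crawling over the surface
of a glial scar under the combined guidance of three diffusible factor
classes.  This note records the model, the numerics, the parameter choices,
and — importantly — the places where the model statement is under-determined
and what this package decided there.

## Model

**Guidance fields.**  Three concentrations ρ1, ρ2, ρ3 (μM) obey linear
reaction-diffusion equations with point sources,

    ∂ρi/∂t = Di ∇²ρi − k-i ρi + Σ_s σ δ(r − r_s),

* ρ1 — attractant (neurotrophic factors, e.g. NGF) released at constant rate
  σ1 by each target cell; long-ranged (decay length √(D1/k-1) = 1000 μm).
* ρ2 — inhibitor (CSPGs associated with the scar surface) released at the
  growth cones at rate σ2 = σ20 (1 − R_L); short-ranged (√(D2/k-2) = 30 μm).
* ρ3 — promoter (Schwann-cell derived adhesion/growth molecules) released at
  the growth cones at rate σ3 = σ30 R_L; short-ranged.

R_L = ρ1/(Kd + ρ1) is the receptor-ligand bound fraction; it switches the
cone-released output from inhibitor-dominated (far from targets) to
promoter-dominated (near targets).

**Growth law.**  A growth cone is an overdamped point particle: velocity
proportional to the chemotactic force,

    dr/dt = (1/μ) Σi λi p_i,    p_i = ∇ρi |Δr| / ρΣ,    ρΣ = Σi ρi,

with |Δr| ≈ 20 μm the sensing diameter.  p_i is the relative concentration
difference across the cone, so the law is invariant under a common rescaling
of all concentrations and of Kd.  λ1, λ3 > 0 (attraction), λ2 < 0
(repulsion); only the mobilities λi/μ matter (default 1 μm s⁻¹ per unit p).

**Scar surface.**  The scar is an ellipsoid of revolution, r(z) =
ra√(1−(z−z0)²/rz²).  Cones move on the surface: the drawing speed Vz is the
dynamical coordinate and the horizontal velocity follows from the constraint,
Vr = ra²(z0−z)Vz/(rz² r).  A cone reaching the top polar cap (r < 0.02 ra)
has cleared the scar and moves unconstrained.

## Numerics

**Lattice Boltzmann solver.**  D3Q7 BGK (rest weight 1/4, link weight 1/8,
cs² = 1/4); no advection appears in the equations, so the 7-velocity stencil
is sufficient and cheapest.  Di = cs²(τi−½)Δx²/Δt with one shared Δt chosen
so the largest-D factor gets τ = 1 (all τ then lie in (½, 1], which also
keeps populations non-negative).  Decay is a multiplicative post-stream sink
(mass follows (1−kΔt)ⁿ exactly); sources deposit σΔt of concentration per
step, spread trilinearly over the host cell (point deposition is available
but makes a moving source's self-field jump from node to node).  The scar
interior and the six domain faces are zero-flux via half-way bounce-back,
which conserves mass to round-off; the decay length ≪ L makes the wall
placement immaterial for the study geometries.

Accuracy: the steady single-source field matches the screened Green's
function Q e^{−d√(k/D)}/(4πDd) within 5% for d ∈ [5Δx, 1000 μm] (the
acceptance suite measures this); the residual error is near-field stencil
anisotropy plus the zero-flux image bias of a finite box.  The relaxation
choice τ ≤ ~1 matters: large τ (≥1.25) inflates the on-axis near field.

**Source units.**  σ is interpreted as a per-node concentration rate: one
source adds σΔt (μM) to its host cell per step, i.e. a continuum source
strength Q = σΔx³.  With the default grid this places the attractant field
between ~0.01 Kd at the axon ring and ~10² Kd at the target nodes — the
concentration window in which growth cones respond.  The alternative reading
(σ as an absolute amount rate) gives fields ~10⁻⁷ Kd, far below any receptor
response; note that every *ratio* the growth law uses is independent of this
choice, which only fixes the absolute scale relative to Kd.

**Burn-in.**  The attractant field does not depend on the cones, so it is
established once per geometry: initialized from the superposed analytic
screened-source solutions (zeroed inside the scar) and relaxed by LBM until
the relative mass change per step falls below 1e-6 (at least 1000 steps, so
the diffusion shadow of the scar forms).  Zero-field initialization is
available (`init="zero"`) and is what the mass-balance tests use.

**Field-growth coupling.**  The cone-released fields relax ~40× faster than
the attractant and ~10⁴× faster than the cones move, so they are treated
quasi-statically: every `couple_every` (200) growth steps, and only if some
cone has moved ≥ 0.02 cells since the last refresh, the mobile sources are
repositioned and the inhibitor/promoter fields re-relaxed (≈4/(k2Δt) steps).
The tight movement threshold is not cosmetic: if the self-field is allowed to
trail its cone by even a few μm, its local gradient acts as a spurious
tangential push comparable to the attractant signal.

**Sensing.**  Cones sense along the substrate: the gradient entering the
growth law is the directional derivative along the surface meridian, from two
symmetric sample points ±Δx along the tangent, and the velocity is directed
along the tangent (its z-component is the drawing speed).  Release and
sensing happen at the cone body center, half a cell outward from the wall.
These two choices remove the two dominant wall artifacts of Cartesian
sampling at an obstacle boundary (one-sided stencil fallback into the scar,
and solid-masked deposition shifting the self-spike downhill), both of which
otherwise overwhelm the physical signal.  The literal formulation (vertical
force component with Cartesian central differences,
`force_projection="vertical"`) is retained for sensitivity analysis.
Interpolation is trilinear with solid nodes excluded and weights
renormalized.

**Growth integration.**  Explicit Euler with Δt_g = 1 s, re-projected
radially onto the surface each step (residual < 1e-9).  The sampled velocity
is reused for as many unit steps as keep the fastest cone's displacement
below 0.1 cells (velocity batching) — a pure performance device, since the
fields are frozen between refreshes.  A cone connects when it comes within
max(|Δr|, Δx/2) of a target (the half-cell floor reflects that the discrete
field cannot localize a target more sharply); it stalls — irreversibly — when
Vz ≤ 1e-4 μm/s for 50 consecutive steps, or when it senses no factor at all
for that long.  t_max defaults to twice the meridian arc length divided by
0.01 μm/s, the low end of the physiological growth band.

## Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| D1 | attractant diffusion | 100 | μm²/s |
| √(D1/k-1) | attractant decay length | 1000 | μm |
| D1/D2 = D1/D3 | diffusion ratio | 10/3 | — |
| k-1/k-2 = k-1/k-3 | decay ratio | 3e-3 | — |
| Kd | dissociation constant | 1 | nM |
| σ1 | attractant release per target node | 6e-3 | μM/s |
| η2, η3 | σ20/σ1, σ30/σ1 | 0.03 | — |
| λ1/μ (=−λ2/μ=λ3/μ) | mobility | 1 | μm/s |
| |Δr| | sensing diameter | 20 | μm |
| L | domain side | 6720 | μm |
| scar | sphere radius (baseline) | 0.26 L | μm |
| axons / targets | 12 + 12, rings at z = z0 ∓ 0.9 rz | — | — |

The 12 axons start equally spaced on the bottom ring; targets mirror them
near the top (in a longitudinal section the target ring appears as two
circular patches).  Ring latitudes ±0.9 and the 12-target
count are configurable.

## Scales: full and desk presets

The full preset is the physical configuration above on a 96³ lattice
(Δx = 70 μm).  The desk preset shrinks all lengths and the attractant decay
length by 4 (L = 1680 μm, λ = 250 μm, |Δr| = 5 μm) on a 64³ lattice and
rescales σ1 so the attractant level relative to Kd matches the full-scale
reference discretization (Q/(D·distance) invariant).  All ratio-type groups
(ra/L, L/λ, Δr/λ, η's, λi ratios, kiΔt) are preserved, so the desk runs
exercise the same regime ~20× faster; absolute speeds are comparable because
the growth law is dimensionless in concentrations and the mobility is
unchanged.  Tests and the acceptance script use the desk preset; a full-scale
run of the baseline takes a few hours on one core.

## What the model does and does not reproduce

With the inhibitor and promoter switched off (η2 = η3 = 0) the baseline
sphere scenario behaves exactly as expected of the attractant/geometry model:
all 12 axons climb the scar and connect, with drawing speeds 0.008–0.05 μm/s
(population average ≈ 0.026), inside the physiological band for regenerating
axons.  Increasing η2 monotonically lowers the average drawing speed, and
larger scars slow growth.

The model does **not** reproduce fast growth at η2 = 3%.  The reason is
structural, not numerical: the growth law divides the attractant signal by
the *total* concentration at the cone, and the cone's own inhibitor source is
evaluated at the cone itself.  With the default ratios, a point source
releasing at 3% of σ1 produces, at the cone's own sensing scale (~20 μm),
a concentration an order of magnitude above the attractant that has decayed
over ~3 e-folding lengths from the targets:

    ρ2_self/ρ1 ≈ η2 · (D1/D2) · [e^(−r/30)/r] / [Σ_j e^(−d_j/1000)/d_j] ≈ 19 (η2/0.03)

at r = 20 μm — a ratio independent of both the source-unit convention and the
lattice spacing.  The relative attractant signal is therefore diluted ~15×
whenever the cone secretes, the drawing speed falls to ~10⁻³ μm/s, and no
axon crosses the scar within the simulation horizon at any η2 ≥ 3%.
Reference outcomes with full connectivity at η2 = 3% are only compatible
with a cone that is nearly insensitive to its own secretion; lacking any
stated mechanism or scale for such a cutoff, this package implements the
equations as written and documents the discrepancy rather than tuning an
unphysical regularization.  Consequences for the studies: the η2 sweep's
*trend* (speed and connectivity non-increasing in η2) holds; its absolute
values at η2 ≥ 3% are crawl/stall outcomes; the scar-geometry ordering is
demonstrated in the growing (η2 = 0) regime, where it reflects the diffusion
shadow and path length of the scar, while at η2 = 3% the per-case averages
are stall transients.

## Synthetic data and limitations

There is no external data; every input is generated by the configuration
machinery (ring placements, ellipsoid masks, analytic seeds).  What passing
tests show is internal consistency of the solver (conservation, Green's
function accuracy, constraint fidelity, scale invariance) and the qualitative
guidance phenomenology; they cannot validate biological parameter values, the
ellipsoidal scar idealization, tip-only secretion (axon shafts also carry
sources in reality), the absence of growth-cone noise, branching and
axon-axon interactions, or mechanical scar properties — all outside the
model's scope.
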