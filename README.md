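# gliaxon

Simulation of regenerative axon growth along the surface of a glial scar
after spinal cord injury.

After CNS injury, a dense glial scar blocks regrowing axons both mechanically
and chemically.  Experimental repair strategies (Schwann-cell transplants,
chondroitinase treatment) let some axons crawl over the scar toward their
targets.  `gliaxon` implements a quantitative model of that process for
computational neuroscientists who want to explore how inhibitor levels and
scar geometry shape regeneration outcomes before committing to experiments.

## Model

Three diffusible factor classes obey reaction-diffusion equations with point
sources,

    ∂ρᵢ/∂t = Dᵢ∇²ρᵢ − k₋ᵢρᵢ + Σₛ σ δ(r − rₛ),   i = 1, 2, 3,

where ρ₁ is the target-released attractant (NGF-class neurotrophic factors),
ρ₂ the inhibitor (CSPGs) and ρ₃ the promoter (Schwann-cell factors), both
released at the growth cones with receptor-ligand coupling
σ₂ = σ₂₀(1 − R_L), σ₃ = σ₃₀R_L, R_L = ρ₁/(K_d + ρ₁).  Growth cones are
overdamped particles driven by chemotaxis,

    dr_k/dt = (1/μ) Σᵢ λᵢ pᵢ,   pᵢ = ∇ρᵢ|Δr|/ρ_Σ,   ρ_Σ = Σᵢ ρᵢ,

constrained to the scar — an ellipsoid of revolution r(z) = r_a√(1−(z−z₀)²/r_z²)
— through the velocity relation V_r = r_a²(z₀−z)V_z/(r_z²r).  The fields are
solved with a D3Q7 lattice Boltzmann scheme (bounce-back walls at the scar
and domain boundary); gradients are sampled around each cone and positions
advance by explicit Euler steps.  See `docs/methods.md` for the numerics and
all defaults.

## Worked example

```python
from gliaxon import desk_preset, run_scenario, run_eta2_sweep

# baseline sphere scar (radius 0.26 L), secretion off: pure attraction
res = run_scenario(desk_preset(eta2=0.0, eta3=0.0))
print(res.n_connected, round(res.vz_avg, 4), int(res.t_end))
# -> 12 0.0258 30524

# inhibitor-ratio study
print(run_eta2_sweep([3, 4, 5, 6, 7]).to_dataframe()[["eta2", "vz_ave", "n_connected"]])
```

The first run reproduces the permissive limit: all 12 axons climb the scar
and connect, with a population-average drawing speed of 0.0258 μm/s — inside
the 0.01–0.05 μm/s band measured for regenerating axons (the average is over
each axon's net vertical displacement divided by its journey time).  The
sweep prints

```
   eta2    vz_ave  n_connected
   0.03  0.002873            0
   0.04  0.002839            0
   0.05  0.002803            0
   0.06  0.002782            0
   0.07  0.002768            0
```

showing the average drawing speed falling monotonically as the inhibitor
release ratio rises: each cone's own secretion dilutes its relative
attractant signal, and at these ratios the axons crawl and stall instead of
crossing (see the note above on how this compares with the reference
outcomes).

A command-line interface wraps the same machinery:

```sh
gliaxon run --eta2 0.0 --eta3 0.0 -o out/        # one scenario + exports
gliaxon sweep-eta2 --values 3,4,5,6,7 -o out/    # inhibitor study
gliaxon sweep-scar --cases 1,3,5 -o out/         # scar size/shape study
gliaxon validate                                  # solver vs. Green's function
```

Exports are plain text: a summary CSV (label, vz_ave, n_connected, …),
per-axon trajectory CSVs, mid-plane field sections, legacy-ASCII VTK
snapshots, and a JSON run log containing every resolved parameter.

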