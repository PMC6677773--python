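# Methods

## Model

`flockhunt` simulates `n` self-propelled prey disks and one predator disk
inside a rigid square arena `[0, L]²` whose boundary is tiled by fixed
wall disks of radius `r_w`. Dynamics are Newtonian; for prey `i`,

    m ẍᵢ = ξᵢ (F_sp + F_c + F_e) + F_pp ,

where ξᵢ ∈ {0, 1} is the state of living — a dead prey keeps only its
contact forces and drifts as a passive disk. The predator obeys the same
structure with the hunting thrust in place of escape and no ξ gate:

- **Self-propulsion** `F_sp = m (β − α|v|²) v̂` saturates at `√(β/α)`.
  Below a resolvable speed (`10⁻⁹·√(β/α)`) the direction falls back to a
  persistent per-agent heading so motion restarts deterministically.
- **Coordination** `F_c = C_v dᵢ (v̄ − vᵢ)`, where `v̄` is the arithmetic
  mean velocity of the prey within the influence radius `r_i` (self
  included; dead neighbours are averaged by default, since their bodies
  are physically present — a `coordination_live_only` flag excludes
  them). For the lone predator the same term reduces to the friction
  `−C_v d_P v_P`, which is what cripples the hunt at high coordination.
- **Disk interactions** are linear springs on the surface separation
  `λ = |rᵢ−rⱼ| − (dᵢ+dⱼ)/2`. The default `full_spring` mode uses the
  contact stiffness `k_n` on overlap (λ<0) and a much softer cohesion
  stiffness `k_a` on the attractive branch (0<λ, centre distance ≤ r_i).
  `literal_attraction` (attraction only) and `contact_only` are
  selectable. Walls and the predator disk always interact contact-only;
  prey feel the predator's disk but the predator feels walls only, so
  the prey–prey momentum balance is the only third-law invariant.
- **Escape** `F_e = m β_e x̂` away from the predator acts on *agitated*
  prey — live prey whose centre is within the detection radius `r_d` of
  the predator — once behaviour activates at τ_h. Agitation clears the
  moment the predator leaves the zone.
- **Hunting** `F_h = M (β_h − γ|v_P|²) x̂` toward the locked target while
  the state machine is in its hunt stage.

### Hunting state machine

SEARCH selects the nearest live prey within `R_d` (ties to the lowest
index) and enters WAIT. WAIT runs for `t_w`; if the target leaves `R_d`
the hunt fails back to SEARCH. HUNT applies the pursuit thrust until
either the time-out `t_TO` (failure) or the kill. Whenever the *marked*
target is within the sure-kill radius `R_k` — in WAIT or HUNT — it dies
immediately and the predator enters SATISFY (handling time `t_s`),
skipping intermediate stages. Non-target prey inside `R_k` are immune
(predator confusion); prey keep fleeing during SATISFY. All zone tests
are inclusive (≤) and centre-to-centre; stage clocks advance by `dt` and
fire at their bound. A non-consuming predator leaves corpses in the
arena; `consuming = true` removes the victim from every subsequent
computation.

## Parameters

Geometry follows the published zone ratios: `R = 4r`, `r_w = r`,
`r_d = 20r`, `R_d = r_d`, `R_i = 10R`, `R_k = 1.25R` (≈ `R + r`: a kill
requires contact), `r_i = 2κr`. The literal headline geometry
(n = 2808 disks of radius 0.0625 in a unit square) is geometrically
infeasible — its disk area is ~34 L² — so the absolute prey radius comes
from a packing fraction: `r = √(φ_pack L²/(π n))` with φ_pack = 0.10.
The physics depends on the zone ratios, not on the absolute radius.

Free force scales are fixed as: `m = 1`, `β = 1`, `α = 1` (prey terminal
speed 1), `M = 16` (mass ∝ area for a 4× radius), `γ = α`, `β_h = 1`.
The user-facing knobs are the dimensionless groups, resolved by
`SimulationConfig.from_groups`:

| group | meaning | default | study range |
|---|---|---|---|
| χ = C_v L√L/(m√β) | coordination vs propulsion | 604 | 121–6039 |
| ℵ = mβ_e/(Mβ_h) | escape vs hunting force | 0.5 | 0.0625–1.25 |
| κ = r_i/2r | influence zone in diameters | 5 | 2–8 |

ℵ is normalised by the zero-velocity hunting magnitude `Mβ_h`, the only
velocity-independent choice for the velocity-dependent pursuit thrust.
Stage times (`t_h = 3.95`, `t_w = t_s = 0.08`, `t_TO = 0.32`) and the
run length are τ-valued and converted through `t = τ√(L/β)`.

Numerical stiffnesses: `k_n = 10⁴` resolves contacts (static overlap at
the escape speed ~3 stays below one prey radius); the cohesion stiffness
`k_a` is sized so the peak attractive pull (at λ = r_i − 2r) is **0.1 m β**.
This weak-cohesion choice matters: cohesion of order the propulsion
scale or larger collapses the swarm into a dense droplet that bounces
around the arena, which destroys the milling regime entirely. At 0.1 the
swarm spans the confinement and the expected progression appears —
rotational order highest in the milling band of χ, polarization rising
monotonically toward the dynamically parallel band.

## Numerics

Velocity-Verlet with `dt = 0.1·√(m/k_n)` (ten steps per spring time,
= 10⁻³ at the defaults). The acceleration from the end of the previous
step is cached, so each step costs one force evaluation; the closing
evaluation uses the predicted velocity `v + a₀dt` for the
velocity-dependent terms (exact classical Verlet for position-dependent
forces, second order on the harmonic test). Behavioural flags (agitation,
stage, kills) update at the start of each step from the current
positions; the position update of that same step still uses the cached
acceleration, a one-step (10⁻³) lag that is far below every behavioural
timescale (t_w = 80 steps).

Neighbour search is a cell linked list with cell size ≥ r_i, exact and
inclusive at the cutoff. The engine's force kernel (numba) re-implements
the assembly in one vectorised pass; the test suite pins it to the pure
reference functions at 10⁻¹⁰ on random states.

Degenerate inputs: coincident centres raise in the pure functions
(escape substitutes a seeded random unit vector; the kernel uses the
prey's persistent heading on this measure-zero path). A centre that
crosses a wall line — possible at finite `dt` for a fast impact, because
the wall row is one disk deep — is pushed back by the continuation of
the spring law, `k_n(depth + r + r_w)` toward the interior; without this
rule fast prey tunnel between wall disks and leave the arena.

Initial conditions (the model's only randomness): prey placed by seeded
rejection sampling with no overlaps, moving at the terminal speed in
uniformly random directions; the predator starts at rest at
(0.93 L, 0.43 L) by default. Ensembles vary the predator start — the
canonical point plus seeded uniform draws in the inner 80% of the box —
with per-member placement seeds derived once from the ensemble seed.
Runs are bit-reproducible from (config, seed, start).

## Scaled study

The published protocol (n = 2808, τ = 316, twenty predator starts per
case, dozens of grid points) is a cluster-scale computation. The
package's study helpers (`flockhunt.study`) run the same protocol at
n = 300, τ_end = 60, five predator starts per case — sizes chosen so the
qualitative trends resolve on a single CPU in minutes: Φ rising with χ
across the regime bands {604, 3020, 6039} and with κ ∈ {2, 5, 8};
survivors non-decreasing in ℵ ∈ {0.1, 0.5, 1.0}; near-linear growth of
the ensemble-mean death count after activation; rotational order higher
in the milling band than the parallel band. At this scale the regime
*boundaries* in χ shift relative to the full-scale system (the
coordination force carries the agent diameter, which grows as n shrinks
at fixed packing), so comparisons are trend-wise, not point-wise.

## What the synthetic conditions do and do not show

All inputs are generated by the model itself; there is no behavioural
noise term, no perception error, and no hydrodynamic interaction — the
"viscous fluid" enters only through the friction-like coordination
term. Disorder at low χ is therefore purely collision- and wall-driven.
Passing trends show the implementation reproduces the model's collective
phenomenology at desk scale; they say nothing about real animal groups,
about the full-scale quantitative curves, or about regimes outside the
studied ranges.

## Known limitations

- One predator only; `N_pred` is validated to 1.
- No torque or body-orientation dynamics: heading is the velocity
  direction with a persistent fallback.
- The literal Table-style geometry is only accepted when it is
  geometrically feasible; the packing-fraction rescaling is this
  package's choice.
- Observables treat an empty live population as undefined; the engine
  records NaN polarization once every prey is dead (consuming mode).
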