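# Methods

This document specifies the definitions and numerical choices behind each
module, in enough detail to reproduce every number the package prints.

Conventions: positions in micrometres (µm), times in minutes, angles in
radians measured from the +x axis and folded to `[0, π)` (nematic symmetry).
The closed-form module `theory` works in SI units and ships converters.

## Cell geometry (`types`, `_geometry`)

Cells are spherocylinders: a rectangle of pole-to-pole length `L` and width
`W` with semicircular caps; the footprint area is `(L − W)W + πW²/4`.
Contact between two cells reduces to the closest distance between their
shaft segments (clamped segment–segment closest points, vectorised); two
cells overlap when that distance is below `W` (equal widths assumed).

## Agent-based colony generator (`synth.grow_colony`)

Every cell elongates exponentially, `dL/dt = Λ L` with `Λ = 0.014 /min` by
default, so the total footprint `Σ LᵢW` grows as `exp(Λt)` exactly. A cell
divides when it reaches its division length (default 4 µm, lognormal 10%
spread to desynchronise divisions) into two cells of pole-to-pole length
`L/2` offset `±L/4` along the axis with a 2° angular kick; this conserves
`Σ LᵢW` across division and yields a 2 µm → 4 µm cell cycle. Steric
interactions are linear springs on the pairwise penetration depth with
overdamped (quasi-static) position and orientation updates; the
stiffness-to-friction ratio is chosen so residual overlaps stay below a few
percent of `W` at each recorded frame. The generator is deterministic given
its seed.

## Passive hard-spherocylinder Monte Carlo (`synth.PassiveMC`)

`N` rods with lengths uniform in `[2, 4]` µm and width 0.9 µm in a periodic
square box sized to area fraction 0.8 (the packing fraction measured on the
agent-based colonies via their boundary polygon is ≈ 0.8–0.9). Metropolis
moves are single-particle translations (≤ 0.15 µm) and rotations
(≤ 0.15 rad), accepted iff hard-core overlap free — detailed balance holds
by construction for a hard potential.

Initial conditions:

- `init="aligned"` (default): a dense packing of rows of parallel rods
  (first-fit-decreasing row filling). At area fraction 0.8 this is the
  orientationally ordered branch that dense hard-rod systems equilibrate on;
  the sampler then explores it ergodically.
- `init="isotropic"`: random sequential insertion at area fraction ≤ 0.3 in
  an inflated box, followed by jamming-style compression (rescale, resolve
  overlaps by pushing along contact normals, sweep) down to the target box.
  This quenches into an isotropic jammed glass whose correlation anisotropy
  plateaus near 1.3; it is retained as an explicit non-equilibrium option.

For correlation analysis of periodic configurations, `periodic_images`
pads the frame with image cells within a margin of the walls and the
original cells are used as correlation seeds.

## Coarse-graining (`fields`)

Each cell is smeared onto the grid with a separable profile in its body
frame `(u, v)`:

    f(u, v) = ¼ [tanh((u+L/2)/σ) − tanh((u−L/2)/σ)]
                [tanh((v+W/2)/σ) − tanh((v−W/2)/σ)],

which integrates to `L·W` for any smoothing length `σ` (default 0.9 µm ≈ W)
and equals `tanh(L/2σ)·tanh(W/2σ)` at the cell centre. The density is
`ρ = Σᵢ fᵢ` and the order-parameter field is

    Q = Σᵢ fᵢ (2 νᵢνᵢ − I),    S = √(Qxx² + Qxy²),

with director angle `½ atan2(Qxy, Qxx)`. Default grid spacing is `W/3`.

## Order metrics (`order`)

**Global order.** `S(N) = √(⟨cos 2θ⟩² + ⟨sin 2θ⟩²)`, equivalently
`(1/N)√(Σᵢⱼ cos 2(θᵢ−θⱼ))` (kept as an independent code path); 1 for perfect
alignment, r.m.s. `1/√N` for random orientations.

**Correlation lengths.** For each seed cell the sharp (`σ → 0`, top-hat) Q
field is sampled along rays `±ν` (parallel) and `±ν̄` (perpendicular) from
the centroid at bin midpoints `(k+½)dr`, contracted with the seed's own
unit tensor: `C(s) = ⟨Σ_{j owns point} 2 cos 2(θ_seed − θⱼ)⟩`. Lengths are
midpoint-rule integrals `l = ∫C ds / C(0)`. Calibration is exact: one
isolated cell gives `l∥ = L/2` and `l⊥ = W/2`; a side-by-side pair leaves
`l∥ = L/2` and an end-on (in-line) pair leaves `l⊥ = W/2` because the second
cell lies off the measurement ray in each case.

**Shape, boundary, anchoring.** Colony axes come from the second moment of
the cell-mass distribution (including each cell's own rectangle moment).
The boundary loop is the alpha shape (circumradius cutoff 2× median cell
length) of the centroids, falling back to the convex hull; the anchoring
angle ψ is the acute angle between a cell's axis and the central-difference
tangent of the closed boundary polygon at its centroid.

**Kinematics.** Frame-to-frame greedy nearest-neighbour tracking (one-to-one,
links beyond 2 µm rejected, contested links dropped, length drops > 30%
treated as divisions with no velocity row). The expansion rate is the slope
of the azimuthally averaged radial velocity (colony-centre motion
subtracted, fit inside 90% of the inscribed radius); because overdamped
rearrangements are jerky, `expansion_rate` averages the slope over the last
6 frame intervals. The growth-rate profile regresses `ln L(t)` in sliding
windows that exclude divisions, binned by radius.

## Defect analysis (`defects`)

Topological charge density (from central differences):

    q = (1/2π)(∂ₓQxx ∂ᵧQxy − ∂ₓQxy ∂ᵧQxx),

whose integral over a disc containing one defect equals its winding number.
Detection: local extrema of `|q|` above 0.1× the peak of an isolated
analytic ±1/2 defect at the working resolution (calibrated and cached at
startup), non-maximum suppression within 3 grid spacings (tied symmetric
maxima deduplicated per sign). The charge is assigned by explicit
branch-corrected director winding on a loop of 4 spacings: increments folded
into `(−π/2, π/2]`, summed, and quantised to half-integers. Comet polarity
of +1/2 defects is `p̂ = −∇·Q/|∇·Q|` with `(∇·Q)ₓ = ∂ₓQxx + ∂ᵧQxy`,
`(∇·Q)ᵧ = ∂ₓQxy − ∂ᵧQxx`. For an isolated +1/2 defect with local phase φ₀
this gives `p̂ = −(cos 2φ₀, sin 2φ₀)`; nearby defects shift the local phase
and hence the polarity, which is physical, not an artefact. Tracking links
same-charge detections greedily within 3 µm per frame.

`make_defect_field` builds analytic oracle fields with director angle
`φ(r) = Σₖ mₖ atan2(y−yₖ, x−xₖ) + phaseₖ`, `S = 1` with a smooth
`tanh(r/r_core)` core cutoff — the winding around each core is exactly `mₖ`.

## Continuum model (`continuum`)

Fields `ρ(x, t)`, `Q(x, t)` on a square grid (closed box), explicit Euler:

- density: `∂ₜρ + ∇·(ρv) = Λρ`, growth switched off where `ρ > 2ρ₀`
  (nutrient/contact saturation); conservative face-upwind fluxes;
- force balance (dry limit, friction-dominated): `γρ v = ∇·σ` with
  `σ = −p I − a Q`, `p = G max(ρ/ρ₀ − 1, 0)` and activity `a = a₀ρ`;
  `v = 0` where `ρ < ρ₀/2` (no colony);
- order parameter: `∂ₜQ + v·∇Q = K̂∇²Q + α(ρ)Q − β|Q|²Q + ξ(strain) +
  co-rotation`, with `α = α₀(ρ − ρ₀/2)`, `β = α₀ρ₀/2`, `|Q|² = 2(Qxx²+Qxy²)`,
  flow-alignment `ξ = 0.7` and vorticity co-rotation `(+2wQxy, −2wQxx)`,
  `w = ½(∂ᵧvₓ − ∂ₓv_y)`.

Bulk fixed point: `2S*² = α/β`, equal to 1 at `ρ = ρ₀`. Defaults
`Λ = 0.001, a₀ = 0.02, G = γ = ρ₀ = 1, α₀ = K̂ = 0.01, ξ = 0.7, dx = 1,
dt = 0.1`; the constructor enforces both explicit-Euler stability bounds
`dt < dx²/(4K̂)` and `dt < ¼ dx² γρ₀/G` (pressure diffusivity `G/(γρ₀)`).
The initial condition is a uniform disc of radius 10 with ±0.01 Q noise.

Diagnostics: colony radius from the `ρ > ρ₀/2` area; expansion slope from
the azimuthally averaged radial velocity; boundary anchoring from the
density-gradient tangent in the interface band `0.25ρ₀ < ρ < 0.75ρ₀`;
interior disorder as the fraction of points (radius < 0.75 R, `ρ > 0.75ρ₀`)
with `2S² < 0.25`. The turbulence scan runs a list of activities to a common
radius and reports the first whose interior low-order fraction exceeds 1%,
as the dimensionless control parameter `a₀ρ₀/(γ̂K̂) = a₀/(γK̂)` (with
`γ̂ = γρ₀`).

## Closed forms (`theory`)

- Hubble relation: uniform growth imposes `∇·v = Λ`; the radially symmetric
  solution is `v_r = (Λ/2) r`, so `H = Λ/2`.
- Stress propagation length `l_σ = √(G/(γ̂Λ))` (growth stress spreads
  diffusively with diffusivity `G/γ̂` during one doubling time `1/Λ`).
- 1D colony stress: `σ_yy(y) = −P₀ − ½Λγ̂(y₀² − y²)` from
  `dσ_yy/dy = γ̂ v_y`, `v_y = Λy`; curvature `γ̂Λ`.
- Torque on a tilted rod in the growth flow, by quadrature of
  `∫ γ v_y(y₀ + l sinθ) l cosθ dl = γΛL³ sin2θ / 24`, hence the alignment
  rate `dθ/dt = (γL³/24ζ)(∂_y v_y) sin 2θ`, and in 2D
  `dθ/dt = (ξ g′(r) r / 4S) sin 2(θ − φ)` — zero for uniform growth
  (`g′ = 0`), so growth alone neither aligns nor destroys order.
- Bulk fixed point `2S*² = max(α/β, 0)`; screening length `l_s = √(η/γ̂)`;
  three labelled estimates of the active length `l_a` (wet balance `√(K/a)`,
  cell scale `L`, dry relaxational coherence/√control-parameter), reported
  side by side because the dry growing system does not pin the form.

## I/O and pipeline (`io`, `cli`)

Track tables are CSV/TSV with columns `frame, time_min, cell_id, x_um, y_um,
length_um, width_um, angle_rad` (optional `parent_id`); malformed input
(missing columns/values, duplicate `(frame, cell_id)`, non-monotonic or
inconsistent times) raises `TrackParseError` naming the offending row.
Fields round-trip through HDF5 with grid metadata. Every pipeline output
carries a 12-hex configuration hash and the seed; reruns with the same
configuration are byte-identical. The `activecolony` CLI exposes `synth`,
`analyze`, `sim`, `defects`, `theory` and `report`.

## Reproducibility

All stochastic components consume a single integer seed through
`numpy.random.default_rng`; identical seeds give bit-identical colonies, MC
chains and simulations. `scripts/acceptance.py --seed N --out results.json`
recomputes the package's acceptance quantities from scratch, deriving all
child seeds from `--seed`.
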