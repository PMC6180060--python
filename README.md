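# activecolony

Tools for studying growing two-dimensional bacterial colonies as active
nematic liquid crystals. Rod-shaped cells that elongate and divide behave
like an active nematic: steric interactions order them locally, growth
drives flows that create and move ±1/2 topological defects, and the colony
edge anchors cells tangentially. This package provides, in one place:

- an **agent-based generator** of growing colonies (exponential elongation,
  symmetric division, overdamped steric repulsion) and a **passive
  hard-spherocylinder Monte Carlo** control without growth;
- **Q-tensor coarse-graining** of tracked cells onto a grid (density, order
  parameter `S`, director);
- **order metrics**: global nematic order `S(N)`, directional correlation
  lengths `l∥`/`l⊥`, colony shape, boundary anchoring angles, cell tracking,
  radial ("Hubble") expansion fits and growth-rate profiles;
- **defect analysis**: topological charge density, branch-corrected winding
  numbers, ±1/2 detection with comet polarity, tracking and charge
  statistics;
- a **continuum model** of the growing colony (density + Q-tensor dynamics
  in the dry, friction-dominated limit) with diagnostics including a scan
  for the onset of activity-driven interior disorder;
- **closed-form theory**: `H = Λ/2` expansion, stress-propagation length,
  1D stress profile, growth-induced alignment rates, bulk order fixed point
  and active length-scale estimates;
- a **CLI and I/O layer** (track tables in CSV/TSV, fields in HDF5,
  reproducible hashed configurations).

See `docs/methods.md` for precise definitions and numerical choices.

## Worked example

Grow a 300-cell colony and measure its nematic state (deterministic given
the seed):

```python
from activecolony.synth import grow_colony, GrowthParams
from activecolony.fields import Grid, q_tensor_field
from activecolony.order import (global_order, correlation_functions,
                                correlation_lengths, boundary_anchoring,
                                expansion_rate)
from activecolony.defects import detect_defects

series = grow_colony(GrowthParams(seed=1), n_final=300, record_every=5.0)
frame = series[-1]

print(global_order(frame))                      # 0.134  (macroscopically disordered)
l_par, l_perp = correlation_lengths(
    correlation_functions(frame, r_max=12.0))
print(l_par, l_perp)                            # 2.11 um, 1.71 um  (local domains)
print(boundary_anchoring(frame).median_psi)     # 22.2 deg  (tangential anchoring)
print(expansion_rate(series))                   # 0.00582 /min  ~ 0.42 * growth rate
qf = q_tensor_field(frame, Grid.for_frame(frame))
dets = detect_defects(qf)
print(sum(d.charge > 0 for d in dets),
      sum(d.charge < 0 for d in dets))          # 7 +1/2, 7 -1/2  (net charge 0)
```

The colony is disordered globally (`S(N) = 0.134 ≈ 1/√N·2.3`) yet ordered
locally (`l∥ > cell width`), expands slower than the naive `v = Λr`
(`H/Λ = 0.42 < 0.5` because growth stress relaxes through rearrangements),
anchors tangentially at its edge, and carries equal numbers of +1/2 and
−1/2 defects.

The same analysis from the shell:

```bash
activecolony synth --n-final 300 --seed 1 --out tracks.csv
activecolony analyze tracks.csv --out-dir analysis/
activecolony report analysis/
```

Two-cell calibration of the correlation lengths (exact closed forms): two
2 µm × 1 µm cells abreast give `l∥ = L/2 = 1.0 µm`; two cells in a line give
`l⊥ = W/2 = 0.5 µm`.

Continuum model and theory:

```bash
activecolony sim --t-end 1000 --a0 0.02 --out fields.h5   # prints diagnostics JSON
activecolony theory                                        # closed-form estimates table
```

`activecolony theory` prints, for the default material parameters
(`G = 3 kPa`, `γ̂ = 10¹⁵ Pa s m⁻²`, `Λ = 0.014 /min`), a stress-propagation
length `l_σ = 113 µm` — the scale above which a colony must buckle or
rearrange rather than expand affinely.

## Testing and reproduction

```bash
python -m pytest -q tests/           # unit, property and acceptance tests
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`scripts/acceptance.py` recomputes the package's acceptance quantities from
scratch — analytic ratios (Hubble `H/Λ = 0.5`, torque coefficient
denominator 24, bulk order `2S² = 1`), the two-cell correlation calibration
(1 µm / 0.5 µm), the vanishing net charge of a defect pair, the onset
control parameter of interior disorder in the continuum model
(`a₀ρ₀/(γ̂K̂) ≈ 2`), and the isotropy (`l∥/l⊥ ≈ 1`) of the passive Monte
Carlo control — deriving all randomness from `--seed`.

## Layout

```
src/activecolony/
  types.py      cell/frame/series containers
  _geometry.py  spherocylinder contact geometry
  synth.py      colony generator, passive MC, analytic defect fields
  fields.py     Q-tensor coarse-graining
  order.py      order metrics, correlations, tracking, expansion fits
  defects.py    charge density, winding, detection, tracking, statistics
  continuum.py  continuum growth model and diagnostics
  theory.py     closed forms (SI units)
  io.py         track tables, HDF5 fields, analysis pipeline
  cli.py        command-line interface
docs/methods.md detailed methods
scripts/acceptance.py  end-to-end acceptance quantities
```
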