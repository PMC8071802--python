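# stalkpath

Minimum free-energy paths (MFEPs) for the first step of membrane fusion —
formation of the *stalk*, the hourglass-shaped hydrophobic bridge that
connects two apposed lipid membranes.  The package implements the complete
field-based transition-path machinery used to study stalk formation between
highly curved vesicles and between planar bilayers, and makes every stage
exercisable on synthetic systems (analytic free-energy functionals,
constructed membrane density fields, a toy Langevin sampler) without any
molecular-dynamics engine.

It is written for researchers in membrane biophysics and coarse-grained
simulation who want a tested, reusable implementation of:

- **Density order parameter** — the hydrophobic (lipid-tail) particle number
  density m(c) on a collocation grid, mapped from particle coordinates with
  a linear cloud-in-cell kernel,
  m̂(c) = (1/ΔV) Σᵢ Π(c, rᵢ), Π(c, r) = ∏_α max(0, 1 − |r_α − c_α|/ΔL_α),
  with minimum-image distances on periodic boxes.  The mapping conserves
  mass exactly: Σ_c m̂(c)·ΔV = N.
- **Field-theoretic umbrella sampling** — a harmonic restraint
  ΔH = (κ/2) Σ_c (n(c) − n̂(c))² coupling the sampled per-cell counts to a
  target field (κ = 50 kJ/mol by default), its analytic per-particle forces,
  and the strong-restraint chemical-potential estimator
  μ(c) = ∂F/(ΔV ∂m(c)) ≈ (κΔV/k_BT)·[m(c) − ⟨m̂(c)⟩], accurate to O(1/κ).
- **String method** — a path m_s(c), s ∈ [0, 1], of n replicas relaxed by
  Allen-Cahn steps m ← m − ε·μ and redistributed to uniform arc length by
  per-cell cubic splines.  At convergence the chemical potential
  perpendicular to the path vanishes: the path is the MFEP through the
  saddle point of F[m].
- **Thermodynamic integration** —
  ΔF(s) = ∫₀ˢ ds′ ΔV Σ_c μ_s′(c)·dm_s′(c)/ds′, giving the barrier
  ΔF_b = max_s ΔF(s) and the endpoint (stalk) excess ΔF(1) in k_BT.
- **Stalk geometry** — iso-density interfaces at the hydrophobic threshold
  2.2 nm⁻³: intermembrane distance d_w, area-equivalent stalk diameter
  d_st, azimuthally averaged (R, z) density maps, and thickness profiles.
- **Apposition (Derjaguin) model** — the dehydration free energy of bringing
  membranes into contact, Δf_flat(d_w) = A·exp(−d_w/λ) per unit area with
  λ = 0.28 nm for POPC, and ΔF_dehydr = π·R_v·λ·Δf_flat(d_w) for two equal
  vesicles of outer radius R_v.

## Worked example

The zeroth stage of fusion — apposition.  Bringing two planar POPC membrane
patches of 36 nm² to d_w = 1.2 nm costs far more free energy than bringing
two small vesicles (R_v = 9.2 nm) to the same distance:

```bash
$ stalkpath appose --Rv 9.2 --dw 1.2 --area 36
vesicle pair (R_v = 9.2 nm, d_w = 1.2 nm): 9.71 kBT
planar patch (36.0 nm^2, d_w = 1.2 nm): 43.20 kBT
```

The vesicle number is π·9.2·0.28·1.2 ≈ 9.71 k_BT — curvature makes
dehydration roughly four times cheaper for this patch size, which is why
small vesicles can reach stalk-forming distances spontaneously.

The string method on an analytic curved double-well landscape
F(x, y) = (x² − 1)² + 2(y − x²/2)², whose minima (±1, ½) and saddle (0, 0)
are known exactly:

```python
from stalkpath import StringMFEP, StringConfig
from stalkpath.synthetic import CurvedDoubleWellLandscape

land = CurvedDoubleWellLandscape(c=2.0)
a, b = land.minima
cfg = StringConfig(epsilon=0.05, max_iterations=3000,
                   tol_disp=1e-7, tol_F=1e-9, clip_negative=False)
res = StringMFEP(land, start=land.field_from_xy(*a),
                 end=land.field_from_xy(*b), n_replicas=25, config=cfg).fit()
print(res.summary())
```

```
Minimum Free-Energy Path (string method)
================================================
replicas               : 25
grid                   : (1, 1, 2)
iterations             : 63
converged              : True
provider calls         : 1575
barrier  dF_b  [kBT]   : 0.999973
barrier position s_b   : 0.5000
endpoint excess [kBT]  : -4.23266e-16
```

The converged barrier matches the exact saddle height (1 k_BT) to 3·10⁻⁵
relative, and `res.field_at(res.s_barrier)` sits on the saddle to ~10⁻⁶ per
coordinate.  `res.profile.plot()` draws ΔF(s); `res.path` holds the replica
fields for geometric analysis.

Constructed membrane fields exercise the geometry end of the pipeline:

```python
from stalkpath import GridSpec, intermembrane_distance, stalk_diameter
from stalkpath.synthetic import (bilayer_centers_for_gap,
                                 make_bilayer_field, make_stalk_field)

grid = GridSpec((24, 24, 60), (7.2, 7.2, 12.0))
base = make_bilayer_field(grid, bilayer_centers_for_gap(1.2, z_mid=6.0))
stalk = make_stalk_field(base, neck_radius=1.6)
intermembrane_distance(base)   # 1.186  (built: 1.2 nm, half-cell accuracy)
stalk_diameter(stalk)          # 3.231  (built: 3.236 nm at the threshold)
```

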