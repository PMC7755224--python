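# mtled

Meshless simulation of needle insertion into soft tissue and tissue
surrogates, built on total Lagrangian explicit dynamics (MTLED) with a
two-parameter **kinematic** needle–tissue interaction model.

## The problem

Needle-based procedures (biopsy, brachytherapy, deep-electrode placement,
drug delivery) need to predict where the target tissue moves while the
needle deforms it. Mechanistic contact/cutting models require patient-specific
material and friction parameters that are rarely known. This package instead
poses insertion as a Dirichlet problem — tissue next to the needle is
*driven* by the needle's known motion — which makes the computed displacement
field only weakly sensitive to material properties. The interaction model has
two image-identifiable parameters:

* **ε_p** — puncture strain: surface indentation switches to penetration when
  the maximum principal Green strain at the entry site exceeds it;
* **C_D** — deformation coefficient: nodes in a sleeve around the shaft are
  displaced by the fraction C_D of the needle travel since they were reached
  (identified from images as C_D = U₂/U₁, surface deflection over insertion
  depth; ≈ 0.4 for silicone gel on a smooth needle).

The solid is an unstructured node cloud with background tetrahedra used only
for one-point quadrature; displacements are approximated with modified
moving least squares (MMLS) shape functions, the material is a one-term
Ogden model in principal stretches,

  W = (2μ/a²)(J^(−a/3)(λ₁^a + λ₂^a + λ₃^a) − 3) + (1/D)(J − 1)²,

(neo-Hookean at a = 2), stresses are second Piola–Kirchhoff, and the static
solution is found by damped explicit central differences (dynamic
relaxation). See `docs/methods.md` for the numerics.

## Worked example

```python
import mtled
from mtled.approximation import build_cell_gradient_table
from mtled.dynamics import SolverSettings, run_quasi_static
from mtled.needle import KinematicParams, NeedleDriver, NeedleSpec

# ~3,000-node gel cylinder, diameter 30 mm, height 17 mm
grid = mtled.generate_cylinder_grid(15.0, 17.0, 3000, seed=1)
table = build_cell_gradient_table(grid.nodes, grid.cells,
                                  grid.cell_volumes, grid.quad_points)

gel = mtled.MaterialParams(a=-1.3, mu=722.0, D=5.57738e-5)   # Sylgard-like
spec = NeedleSpec(entry_point=[0, 0, 17.0], axis=[0, 0, -1],
                  diameter=1.6, max_depth=15.0)
driver = NeedleDriver(grid, spec, KinematicParams(eps_p=1e-5, cd=0.4))

res = run_quasi_static(grid, table, [gel], driver, [5.0, 15.0],
                       SolverSettings(),
                       fixed_nodes=grid.boundary_sets["bottom"])
for depth, force in zip(res.depths, res.reaction_forces):
    print(f"depth {depth:5.1f} mm   needle force {force:.3f} N")
u = res.displacements[-1]
print("deepest tissue displacement:", round(u[:, 2].min(), 3), "mm")
```

prints (seed 1):

```
depth   5.0 mm   needle force 0.025 N
depth  15.0 mm   needle force 0.198 N
deepest tissue displacement: -6.0 mm
```

The deepest displacement is C_D × 15 mm = 6 mm — the tissue at the entry
point follows 40 % of the needle travel. The force at full insertion is the
axial reaction the gel exerts on the needle; scaling μ by 100 (with D/100)
leaves the displacement field unchanged and scales the force by exactly 100,
which is the point of the kinematic formulation.

Short, runnable demonstrations of each capability live in `examples/`.

## Command line

```sh
mtled fixtures cylinder cyl.vtk --target-nodes 3000 --seed 1
mtled simulate run.yaml
mtled convergence run.yaml 7480,17730,30294
mtled material-sensitivity run.yaml variants.yaml
mtled compare fieldA.csv fieldRef.csv
```

Configs are YAML (see `examples/run.yaml`); every run writes a provenance
log with the fully resolved configuration, versions and seed.

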