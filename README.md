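# embryomech

Mechanics of the cellularization-stage *Drosophila* epithelium, rebuilt as a
tested simulation and analysis pipeline.  The package is aimed at tissue
biophysicists who probe embryos with soft cantilevers or ferrofluid droplets
and need (a) a whole-embryo mechanical model to fit their force/displacement
traces against and (b) the quantification machinery — kymographs,
deformation-profile collapse, decay-constant fits, probe calibration — that
turns raw movies into those traces.

## What is modelled

The embryo is an ellipsoid (511 x 184 um) tiled with a disordered hexagonal
cell network.  Cells are open prisms: apical and lateral surfaces are
triangulated Hookean spring networks with compartment constants
`k_apical`, `k_lateral`, `k_basal` (nN/um); the basal side is open, leaving
only a floppy rim of basal springs.  The interior fluid is 1000 cP Stokes
flow inside a rigid no-slip vitelline shell with a ~1 cP perivitelline film.
Two dynamics backends move the network:

* an **immersed-boundary** backend — node forces are spread to a fluid grid,
  the shell-bounded Stokes problem is solved with regularized Stokeslets,
  and velocities are interpolated back;
* a **constant-drag** backend (velocity = force/gamma) for the simplified
  flat-lattice experiments and cheap whole-embryo runs.

An in-silico cantilever drives one lateral cell edge at 0.5 um/s for 60 s,
holds 60 s, then releases; the applied force is extracted with a
Lagrange-multiplier constraint solve.  A triangulated spring sheet measures
out at `E = 2k/sqrt(3)` with Poisson ratio `nu = 1/3`; per-spring stress is
`k (L - L0)`.  The flat-lattice module contrasts Maxwell-rigid triangular
networks with floppy honeycombs, the topological dichotomy that explains why
apical stiffness governs recoil while basal/lateral stiffness governs the
loading force.  The cantilever module is clamped-free Euler-Bernoulli beam
mechanics (`F = 3EI d/L^3`; drag calibration via slender-body theory).
See `docs/methods.md` for assumptions, parameters and limitations.

## Worked example

```python
import embryomech as em
from embryomech.elastic_network import measure_sheet_moduli
from embryomech.network_rheology import (
    triangular_patch, hexagonal_patch, run_patch_experiment,
    effective_relaxation_time, residual_deformation,
)
from embryomech.cantilever_calibration import CantileverSpec, force_from_deflection

sheet = measure_sheet_moduli(triangular_patch(n_rows=32, n_cols=32, spacing=1.0, k=1.0))
print(f"sheet modulus E/k = {sheet.youngs_E:.3f}, Poisson ratio = {sheet.poisson_nu:.3f}")

probe = CantileverSpec(tip_length=50.0, cross_section=("circular", 1.0),
                       youngs_modulus_MPa=2.1)
print(f"force at 5 um tip deflection: {force_from_deflection(probe, 5.0):.3f} nN")

proto = em.PullProtocol(loading_speed=0.5, loading_duration=60.0,
                        holding_duration=0.0, unloading_duration=240.0,
                        pull_direction=(0.0, 1.0, 0.0))
for build, name in ((triangular_patch, "triangular"), (hexagonal_patch, "hexagonal")):
    rec = run_patch_experiment(build(n_rows=24, n_cols=24, spacing=8.0,
                                     k=0.035, gamma=1.0), proto)
    t_end = rec.unloading_trace()[0][-1]
    print(f"{name:>10}: F_max = {em.max_force(rec):.2f} nN, "
          f"relaxation time = {effective_relaxation_time(rec):.0f} s, "
          f"residual deformation = {residual_deformation(rec, t_end):.2f}")
```

prints

```
sheet modulus E/k = 1.156, Poisson ratio = 0.333
force at 5 um tip deflection: 0.198 nN
triangular: F_max = 3.50 nN, relaxation time = 220 s, residual deformation = 0.26
 hexagonal: F_max = 1.91 nN, relaxation time = 567 s, residual deformation = 0.54
```

The sheet behaves as an isotropic elastic sheet with `nu = 1/3`; a 2.1 MPa
PDMS tip of 1 um radius and 50 um length converts 5 um of deflection into
about 0.2 nN.  At equal spring constant the stiff triangular lattice takes
nearly twice the force to deform, yet relaxes back far faster and more
completely than the floppy honeycomb, which stalls with half its deformation
frozen in — the signature that loading forces probe floppy (basal/lateral)
stiffness while recoil probes stiff (apical) stiffness.

A whole-embryo pull at desk scale:

```python
from embryomech.pipeline import desk_scale_embryo, run_sweep
mesh, backend = desk_scale_embryo(n_cells=96, seed=1, resolution=24.0)
df = run_sweep([em.ElasticParams.uniform(k) for k in (0.001, 0.05)],
               mesh, protocol=em.PullProtocol(unloading_duration=240.0),
               backend=backend, record_interval=0.25)
```

yields a table of `F_max_nN`, `tau_s` and `recoil` per parameter set, with
the loading force rising and the relaxation time falling as `k` grows.

There is also a CLI (`embryomech mesh|pull|patch|quantify|calibrate|synth|sweep`),
each subcommand taking `--config`, `--seed`, `--out-dir` and writing a JSON
run manifest next to its outputs (meshes as VTK/PLY, series as CSV, movies
as TIFF).

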