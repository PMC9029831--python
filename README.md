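# pmfsurf

Reconstruction of two-parameter adsorption free-energy surfaces (potentials
of mean force) for a rod-like nanocrystal at a water–oil interface, plus the
companion analyses of the thin water layer that stabilizes adsorption:
interfacial water orientation distributions and anisotropic self-diffusion.

The package is aimed at molecular-simulation practitioners who restrain a
crystal at a sequence of configurations (distance *x* from the interface,
rotation θz about the crystal axis), log the instantaneous force component
fx and torque component Tz on the crystal at each grid node, and want the
free-energy landscape, its adsorption states and barriers, and the
properties of the confined water — with every stage testable against
synthetic data of known ground truth.

## The method

For a crystal whose axis is parallel to a flat water–oil interface, the
Helmholtz free energy depends only on (x, θz), and the mean force and mean
torque exerted on the crystal are minus its gradient:

    ⟨fx⟩ = −∂F/∂x,    ⟨Tz⟩ = −∂F/∂θz.

`pmfsurf` reconstructs F on a regular grid by thermodynamic integration:

1. **Sampling** (`pmfsurf.timeseries`): per-node time series are trimmed of
   their equilibration transient (default 1 ns) and block-averaged into
   ⟨fx⟩, ⟨Tz⟩ with standard errors.
2. **Boundary integration** (`pmfsurf.pmf`): each constant-θz row is
   integrated in x by the trapezoid rule from the bulk-water reference plane
   (F ≡ 0 at x_min). The mean of the per-row end values defines the
   water→oil transfer free energy ΔF_w→o, imposed as the x_max boundary.
3. **Relaxation**: interior nodes are iteratively replaced by the mean of
   the four neighbour-predicted values (trapezoid force/torque increments)
   until the largest update falls below tolerance. The fixed point — the
   solution of a sparse discrete-Poisson-like system, also available
   directly via `oracle_least_squares` — reconciles the noisy, slightly
   curl-carrying measured field into a single-valued surface.
4. **Refinement**: a finer grid around the adsorption region is relaxed
   with all four edges pinned to the coarse surface (bilinear
   interpolation).
5. **States and barriers** (`pmfsurf.surface`): strict local minima of
   ΔF(x, θz) = F − F(bulk water) are the adsorption states; the barrier
   between two states is the exact minimax saddle over 8-connected grid
   paths.

The water-layer analyses operate on extended-XYZ trajectories of O,H,H
water (`pmfsurf.orient`, `pmfsurf.msd`): dipole polar angle θ relative to
the interface normal with exact sinθ Jacobian correction, the in-plane H–H
angle φ folded to [0°, 90°], and per-axis mean-square displacement of
strictly gap-resident molecules with D_α = ½ · slope of MSD_α(t).

`pmfsurf.synth` generates every input with known ground truth: multi-well
analytic landscapes whose sampled gradients integrate back exactly under
the trapezoid stencil (plus optional Gaussian/AR(1) sampling noise), and
gap-confined Brownian water with planted anisotropic diffusion and
orientation bias.

## Worked example

```python
from pmfsurf import benchmark

res = benchmark.run_surface_benchmark(seed=7, noise_sem=0.01)
print(f"water->oil transfer free energy: {res['dFw2o']:.1f} kcal/mol")
for s in res["states"]:
    print(f"state {s.label}: x = {s.node[0]:+.0f} A, theta_z = {s.node[1]:.0f} deg, "
          f"dF = {s.dF:.3f} kcal/mol")
```

prints

```
water->oil transfer free energy: 318.0 kcal/mol
state A: x = -18 A, theta_z = 95 deg, dF = -3.569 kcal/mol
state B: x = -21 A, theta_z = 85 deg, dF = -3.446 kcal/mol
state C: x = -17 A, theta_z = 135 deg, dF = -2.369 kcal/mol
```

This samples noisy gradients (standard error 0.01 kcal/mol/Å per node) of
the planted benchmark landscape on the 13×12 coarse grid, reconstructs the
surface, refines the 16×16 window around the adsorption region, and
recovers the three planted adsorption states: the strongly hydrophilic
crystal is ~318 kcal/mol more stable in water than in oil, yet adsorbs at
the interface in three shallow minima a few kcal/mol deep — a direct-contact
state and two states separated from the oil by a thin water layer.

The same pipeline is scriptable from the shell:

```sh
pmfsurf synth field --out-dir fixtures --seed 7
pmfsurf pmf --manifest fixtures/manifest.tsv --grid coarse --out F.tsv
pmfsurf minima --surface F.tsv --grid coarse --out states.tsv
pmfsurf synth traj --kind b --seed 3 --out gap.xyz
pmfsurf msd --traj gap.xyz --slab -21:-16 --out msd.tsv
pmfsurf orient --traj gap.xyz --slab -21:-16 --out hist
```

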