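# Methods

## Physical setting and model

A parallelepiped nanocrystal (the bundled bookkeeping describes a 4×4-chain
cellulose-II crystal, 8 anhydroglucose residues per chain, 21 atoms per
residue → 2688 atoms) is restrained at a flat water–oil interface with its
chain axis parallel to the interface. Symmetry reduces its configuration to
two coordinates: the centre-of-mass distance x from the interface (Å;
negative = water side) and the rotation θz about the axis (degrees, period
180° by crystal symmetry). The free energy F(x, θz) is the potential of
mean force: its negative gradient equals the ensemble-averaged force
component ⟨fx⟩ (kcal/mol/Å) and torque component ⟨Tz⟩ (kcal/mol/rad)
exerted on the crystal.

Internal units are kcal/mol, Å, radians and ps throughout; SI force/torque
values (N, N·m, as MD engines log them) are converted on input using
1 kcal/mol = 6.947695e-21 J per entity. Torque terms always enter the
discrete equations with Δθz in radians — energy = torque × angle only holds
in radian measure — even though grids are declared in degrees.

## Surface reconstruction

Sampling files are trimmed at a configurable equilibration cutoff (default
1000 ps — equilibration is judged by inspection in practice, not by rule)
and averaged. The standard error uses non-overlapping block means (default
block 100 samples) because MD samples are strongly correlated;
statistical-inefficiency methods beyond block averaging are out of scope.

Reconstruction proceeds in the steps described in the README. Numerical
choices:

* **Integration rule.** Trapezoid everywhere — the per-edge increment
  between neighbouring nodes is ½(g_i + g_{i+1})Δ. The relaxation update
  replaces an interior node by the mean of the two-to-four values its
  neighbours predict through those increments, so line integration,
  relaxation and the direct solve are mutually consistent by construction.
* **Boundaries.** F ≡ 0 on the x_min edge (bulk water); the x_max edge is
  set to the constant ΔF_w→o, the mean over θz of the per-row line
  integrals. The per-row scatter about that mean is pure sampling noise,
  since in either bulk phase the torque vanishes and F cannot depend
  on θz.
* **θz topology.** The coarse grid treats θz as periodic (period 180°); the
  refinement grid is non-periodic with all four edges Dirichlet. Both
  behaviours sit behind `GridSpec.theta_periodic`, and a non-periodic grid
  without θ-edge data uses a one-sided (2–3 neighbour) stencil at the θ
  edges.
* **Convergence.** Iteration stops when the largest node update in a full
  deterministic sweep is below `tol` (default 1e-10 kcal/mol) or after
  `max_iter` single-node updates (default 1e6). The default sweep picks
  nodes with a seeded random generator and interleaves a deterministic
  sweep for the convergence check; an ordered Gauss–Seidel mode is
  provided. The fixed point is the solution of a strictly diagonally
  dominant sparse linear system, hence independent of sweep order and seed;
  `oracle_least_squares` solves that system directly and is used as the
  cross-check in tests rather than as the production path.
* **Refinement boundaries.** Fine-edge nodes that do not coincide with
  coarse nodes are filled by bilinear interpolation of the coarse surface
  (periodic θ extension where applicable) — the lowest-order choice.
  Whatever structure the coarse grid cannot resolve is therefore slightly
  misrepresented on the fine boundary; with the narrow-well benchmark below
  this contributes an error of a few times 0.01 kcal/mol inside the fine
  window, the dominant systematic of the refined surface.
* **States and barriers.** Minima use strict 4-neighbour comparison (the
  relaxation stencil); nodes tied with a neighbour are not minima, so flat
  noise plateaus are never double-reported. Barriers use 8-connected
  minimax paths computed exactly by a Dijkstra-style search with
  path-maximum cost; both one-sided barriers are reported, since which one
  is quoted depends on the escape direction. Sub-grid saddle refinement is
  out of scope.

## Water-layer analyses

* **Orientation.** The dipole direction is the geometric bisector from O
  through the H–H midpoint — identical in direction to the charge dipole
  for rigid symmetric 3-site water, without carrying a force-field
  definition. θ is measured against the interface normal (+x, water→oil);
  φ is the angle between the H→H vector and d×n, folded to [0°, 90°]
  because hydrogen labels are arbitrary. φ is undefined (and excluded from
  histograms) exactly at the poles. θ histograms divide counts by the exact
  per-bin integral of sinθ (cos θ_lo − cos θ_hi), which is finite at the
  pole bins where the midpoint rule would diverge; an isotropic sample is
  then flat in expectation, bin by bin. φ carries a uniform measure and is
  not corrected. Intra-molecular vectors are minimum-imaged, so molecules
  split across the periodic boundary are handled.
* **Diffusion.** Only molecules whose oxygen stays inside the declared x
  slab at every frame of the window enter the statistics (strict residency;
  the oxygen stands in for the molecule — the centre-of-mass offset is
  negligible for these statistics). Coordinates are defensively unwrapped
  before displacement analysis; an inter-frame jump of half a box or more
  raises an error naming the frame and molecule. MSD uses every frame as a
  time origin. D_α = ½ × OLS slope of MSD_α over a fit window, default
  [25%, 50%] of the maximum lag ("sufficiently large t" is not a sharp
  notion); the maximum lag defaults to half the window so late lags retain
  adequate origin counts. Negative fitted slopes are clamped to D = 0 with
  a warning. Å²/ps equals 1e-8 m²/s exactly, the unit diffusion tables are
  printed in.

## Synthetic ground truth

The generators define the conditions under which the pipeline is validated.

* **Landscape.** Three negative Gaussian wells on a sigmoidal water→oil
  ramp of height 318 kcal/mol. Well centres and depths are the benchmark's
  planted adsorption states: (−18 Å, 95°, 3.586), (−21 Å, 85°, 3.460),
  (−17 Å, 135°, 2.384) kcal/mol. Widths are σx = 0.6 Å, σθ = 3°: narrow
  enough that the three states — two of which are only 3 Å / 10° apart —
  remain distinct strict minima on the 1 Å × 5° refinement grid and that
  the refinement-window boundary rows stay clean. The ramp half-width is
  1 Å so the transfer step is fully developed outside the refinement
  window [−25, −10] Å. This landscape reproduces the planted state
  geometry and depths, not the saddle structure between them: with narrow
  wells on a flat background the inter-well barriers are of the order of
  the well depths, so the benchmark does not emulate shallow ~0.2 kcal/mol
  inter-well barriers; barrier extraction is validated against exhaustive
  path enumeration instead.
* **Gradient sampling.** By default node values are *trapezoid-consistent*:
  constructed (by solving the per-row/per-column chain equations, anchored
  to the analytic derivatives) so the discrete field integrates back to the
  planted surface exactly. Noiseless reconstruction is then exact to solver
  tolerance, which separates solver defects from discretization bias in
  tests; analytic-derivative sampling (`consistent=False`) is available and
  carries the O(Δ²) bias a real measurement would. On a θ-periodic grid
  with an even node count the cyclic trapezoid system is solvable only
  without the Nyquist (alternating) component of each row's increments;
  that component is removed and the returned ground truth reflects it
  (≤ ~0.02 kcal/mol near the wells on the coarse grid, zero on
  θ-independent rows). Noise is i.i.d. Gaussian per node with standard
  error σ/√n_samples; a time-series mode writes per-node AR(1) series
  (configurable autocorrelation time) for exercising the block-averaging
  stage. The benchmark noise level, sem 0.01 kcal/mol/Å (and kcal/mol/rad),
  corresponds to e.g. σ = 1 over 10⁴ effective samples.
* **Gap water.** Oxygen positions follow anisotropic Brownian steps
  (variance 2 D_α Δt per axis), reflected at the slab walls in x and
  wrapped periodically in y, z; "leaver" molecules random-walk just outside
  the slab so residency filtering has something to reject. Hydrogens sit at
  rigid geometry (O–H 0.9572 Å, H–O–H 104.52°) with orientations redrawn
  each frame from a tunable bias: sphere density ∝ exp(κθ sinθ − s cosθ)
  (κθ concentrates dipoles in the interface plane, the small tilt s pushes
  the preference just past 90°, toward the crystal) and in-plane density
  ∝ exp(κφ cos 2φ) (aligning the H–H axis with the interface). The
  benchmark fixtures plant the reference diffusion rows — Type B
  (hydrophilic-face gap): D = (0.01, 0.17, 0.12) Å²/ps with 101 residents;
  Type C (oleophilic-face gap): D = (0.0025, 0.078, 0.085) with 148;
  bulk: 0.27 isotropic — in a 5 Å slab over 0.5 ns at 1 ps frames. Only
  upper bounds (0.02, 0.005) are physically meaningful for the wall-limited
  D_x, so the fixtures plant half the bound as the free value. Because the
  fixtures are free Brownian motion (no caging transient), validation and
  the acceptance script fit the better-sampled 25–75 ps window rather than
  the late-lag default.
* **What the fixtures do not emulate.** No molecular mechanics: no
  hydrogen-bond network, no orientational time correlation (orientations
  are redrawn each frame), no coupling between position and orientation, no
  groove-adsorbed sub-population, and interfaces that are perfectly flat
  and fixed. Passing tests therefore demonstrate that the estimators
  recover known statistical structure at realistic sample sizes — not that
  real interfacial water behaves like the generator.

## Problem sizes

The default validation sizes mirror the reference study where it states
them: a 13×12 coarse grid (−30…30 Å × one 180° period), a 16×16 fine grid
(−25…−10 Å × 75…150°), ~100–150 gap molecules sampled for 0.5 ns, 1e5
orientation samples for distribution tests. These run in seconds; all
components scale to substantially larger grids and trajectories, with the
direct sparse solve recommended up to ~50×50 grids and relaxation beyond.

## Known limitations

* The reconstruction assumes the measured field is close to conservative;
  grossly curl-carrying inputs are silently averaged into the nearest
  consistent surface. `torque_integrate_check` reports per-row loop
  residuals as the diagnostic.
* ΔF_w→o inherits any systematic error of the row integrals; only its
  statistical scatter is reduced by averaging over θz rows.
* Strict residency biases the diffusion sample toward slower molecules in
  real data (fast molecules leave the slab); the synthetic walls make the
  fixture immune to this, so the bias is not quantified here.
* Orientation histograms pool all frames; no statistical dependence
  correction is applied to the χ²-style comparisons in the tests beyond
  drawing independent orientations in the generator.
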