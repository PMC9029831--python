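"""Canonical study conditions: grids, planted landscape, gap-water fixtures.

These constants pin down the reference study this package re-analyses: a
4x4-chain cellulose-II nanocrystal restrained at a water-octane interface,
sampled on a coarse 13x12 (x, θz) grid over -30..+30 Å x 0..180° and refined
on a 16x16 grid over -25..-10 Å x 75..150°. The planted benchmark landscape
carries the study's three adsorption states —

* Type A, direct crystal-oil contact, (-18 Å, 95°), ΔF = -3.586 kcal/mol
* Type B, hydrophilic-face/water-layer/oil, (-21 Å, 85°), ΔF = -3.460
* Type C, oleophilic-face/water-layer/oil, (-17 Å, 135°), ΔF = -2.384

— on a 318 kcal/mol water→oil ramp, and the gap-water fixtures plant the
study's anisotropic diffusion coefficients (Å²/ps ≡ 1e-8 m²/s):

* Type B gap: D_y = 0.17, D_z = 0.12, ~101 resident molecules
* Type C gap: D_y = 0.078, D_z = 0.085, ~148 resident molecules
* bulk water: D = 0.27 isotropic

D_x is wall-limited in the 5 Å gaps; only upper bounds (0.02 and 0.005) are
meaningful, so the fixtures plant half the bound as the free value.
"""

from __future__ import annotations

import numpy as np

from .pmf import GridSpec, refine_fine_grid, relax_surface, set_boundaries
from .surface import find_local_minima, transfer_free_energy
from .synth import GapSpec, NoiseSpec, SurfaceSpec, Well, make_surface, sample_gradient_field

__all__ = [
    "coarse_grid",
    "fine_grid",
    "three_well_spec",
    "planted_minima",
    "gap_spec_type_b",
    "gap_spec_type_c",
    "bulk_water_spec",
    "md_total_steps",
    "surface_width_ratio",
    "run_surface_benchmark",
]

TRANSFER_FREE_ENERGY = 318.0  # kcal/mol, water -> oil
WELL_TABLE = (
    ("A", -18.0, 95.0, 3.586),
    ("B", -21.0, 85.0, 3.460),
    ("C", -17.0, 135.0, 2.384),
)
# narrow wells keep the three states distinct on the fine grid and leave the
# refinement-window boundary rows clean
WELL_WIDTH_X = 0.6  # Å
WELL_WIDTH_THETA = 3.0  # degrees

OLEOPHILIC_WIDTH = 36.0  # Å, crystal face widths
HYDROPHILIC_WIDTH = 20.0

PLANTED_D_TYPE_B = (0.01, 0.17, 0.12)  # Å²/ps; D_x at half the 0.02 bound
PLANTED_D_TYPE_C = (0.0025, 0.078, 0.085)  # D_x at half the 0.005 bound
PLANTED_D_BULK = 0.27
GAP_SLAB = (-21.0, -16.0)  # 5 Å water layer


def coarse_grid() -> GridSpec:
    """13 x 12 nodes: -30..+30 Å step 5, one θz period 0..180° step 15."""
    return GridSpec(-30.0, 30.0, 5.0, 0.0, 180.0, 15.0, theta_periodic=True)


def fine_grid() -> GridSpec:
    """16 x 16 nodes: -25..-10 Å step 1, 75..150° step 5 (non-periodic)."""
    return GridSpec(-25.0, -10.0, 1.0, 75.0, 150.0, 5.0, theta_periodic=False)


def three_well_spec() -> SurfaceSpec:
    """The benchmark landscape: three planted states on the transfer ramp.

    The ramp half-width (1 Å) keeps the transfer step fully developed
    outside the refinement window, so the fine-grid boundary rows are flat.
    """
    wells = tuple(
        Well(x=x, theta=th, depth=depth, width_x=WELL_WIDTH_X, width_theta=WELL_WIDTH_THETA)
        for _, x, th, depth in WELL_TABLE
    )
    return SurfaceSpec(wells=wells, ramp_height=TRANSFER_FREE_ENERGY,
                       ramp_center=0.0, ramp_width=1.0)


def planted_minima() -> list[dict]:
    """Ground-truth adsorption states of the benchmark landscape.

    ΔF is the analytic surface value at the planted node relative to the
    bulk-water plane (well tails and ramp are negligible there, so these
    equal minus the planted depths to ~1e-10).
    """
    surf = make_surface(three_well_spec())
    ref = float(surf.value(coarse_grid().x_min, 0.0))
    return [
        {"label": label, "x": x, "theta": th, "dF": float(surf.value(x, th)) - ref}
        for label, x, th, _ in WELL_TABLE
    ]


def gap_spec_type_b(seed: int = 0) -> GapSpec:
    """Hydrophilic-face gap water: fast y (crossing chains), ordered layer."""
    return GapSpec(
        slab=GAP_SLAB, box=(40.0, 25.0, 25.0), n_molecules=101,
        D=PLANTED_D_TYPE_B, dt=1.0, n_frames=501,
        kappa_theta=2.0, tilt=0.4, kappa_phi=2.0, seed=seed, n_leavers=10,
    )


def gap_spec_type_c(seed: int = 0) -> GapSpec:
    """Oleophilic-face gap water: slower, more structured layer."""
    return GapSpec(
        slab=GAP_SLAB, box=(40.0, 25.0, 25.0), n_molecules=148,
        D=PLANTED_D_TYPE_C, dt=1.0, n_frames=501,
        kappa_theta=2.0, tilt=0.4, kappa_phi=2.0, seed=seed, n_leavers=10,
    )


def bulk_water_spec(seed: int = 0) -> GapSpec:
    """Free isotropic reference water (slab wide enough that walls are idle)."""
    return GapSpec(
        slab=(-20.0, 20.0), box=(40.0, 25.0, 25.0), n_molecules=148,
        D=(PLANTED_D_BULK,) * 3, dt=1.0, n_frames=501, seed=seed,
    )


def md_total_steps(duration_ns: float = 2.5, timestep_fs: float = 0.5) -> int:
    """MD step count implied by the sampling duration and timestep (5e6)."""
    return round(duration_ns * 1e6 / timestep_fs)


def surface_width_ratio(
    oleophilic: float = OLEOPHILIC_WIDTH, hydrophilic: float = HYDROPHILIC_WIDTH
) -> float:
    """Oleophilic : hydrophilic face width ratio (36:20 = 1.8)."""
    return oleophilic / hydrophilic


def run_surface_benchmark(
    seed: int = 0,
    noise_sem: float | None = 0.01,
    tol: float = 1e-10,
    sweep_mode: str = "random",
) -> dict:
    """Full reconstruction pipeline on the benchmark landscape.

    Samples the coarse and fine gradient fields (node sem ``noise_sem`` in
    kcal/mol/Å resp. kcal/mol/rad; None = noiseless), reconstructs the
    coarse surface, refines the fine window, and extracts the adsorption
    states. Returns surfaces, recovered states (three deepest), the
    recovered ΔF_w→o and the planted ground truth.
    """
    ss = np.random.SeedSequence(seed)
    sub = [int(s) for s in ss.generate_state(4, dtype=np.uint32) >> np.uint32(1)]
    surf = make_surface(three_well_spec())
    cg, fg = coarse_grid(), fine_grid()

    def noise(node_seed: int) -> NoiseSpec | None:
        if noise_sem is None:
            return None
        # sigma/sqrt(n) = noise_sem with the study's 3e5-sample runs in mind
        return NoiseSpec(sigma_f=noise_sem * 100.0, sigma_T=noise_sem * 100.0,
                         n_samples=10_000, seed=node_seed)

    coarse_field, coarse_truth = sample_gradient_field(surf, cg, noise(sub[0]))
    bc = set_boundaries(coarse_field)
    coarse_surface = relax_surface(coarse_field, bc, tol=tol, seed=sub[1],
                                   sweep_mode=sweep_mode)
    fine_field, fine_truth = sample_gradient_field(surf, fg, noise(sub[2]))
    fine_surface = refine_fine_grid(coarse_surface, fine_field, tol=tol,
                                    seed=sub[3], sweep_mode=sweep_mode)
    states = find_local_minima(fine_surface, neighborhood=4)[:3]
    return {
        "coarse_field": coarse_field,
        "coarse_truth": coarse_truth,
        "coarse_surface": coarse_surface,
        "fine_field": fine_field,
        "fine_truth": fine_truth,
        "fine_surface": fine_surface,
        "states": states,
        "dFw2o": transfer_free_energy(coarse_surface),
        "planted": planted_minima(),
        "dFw2o_true": coarse_truth.dFw2o,
    }
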