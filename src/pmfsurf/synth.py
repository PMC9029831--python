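"""Synthetic ground-truth generators for every stage of the pipeline.

Three generators mirror the three kinds of raw data the analysis consumes:

* an analytic multi-well free-energy landscape F(x, θz) — negative Gaussian
  wells on a sigmoidal water→oil ramp — whose gradients are sampled onto a
  grid, optionally with Gaussian node noise or as full AR(1) time series;
* gap-confined water trajectories: anisotropic Brownian oxygen motion with
  reflective walls in x and periodic y, z, plus rigid-geometry hydrogens
  drawn from a tunable orientation bias;
* crystal bookkeeping (chains x chains x residues x atoms) for the model
  nanocrystal.

Gradient sampling is, by default, *trapezoid-consistent*: node values are
constructed so that the discrete trapezoid sums reproduce the planted
surface exactly, making noiseless reconstruction exact to solver tolerance.
(Analytic-derivative sampling is available with ``consistent=False``; it
carries an O(Δ²) discretization bias like any real measurement.) On a
θ-periodic grid with an even node count the cyclic trapezoid system only
admits a solution after the Nyquist (alternating) component of each row's
increments is removed; the projection is applied and the returned discrete
truth surface accounts for it, so "truth" always means exactly what the
field encodes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .errors import PmfsurfError
from .pmf import FreeEnergySurface, GradientField, GridSpec
from .trajectory import Trajectory

__all__ = [
    "Well",
    "SurfaceSpec",
    "NoiseSpec",
    "GapSpec",
    "CrystalSpec",
    "AnalyticSurface",
    "make_surface",
    "sample_gradient_field",
    "write_gradient_timeseries",
    "sample_orientations",
    "brownian_gap_trajectory",
    "crystal_atom_count",
]

# rigid 3-site water geometry (TIP3P-like)
_OH_LENGTH = 0.9572  # Å
_HOH_HALF_ANGLE = math.radians(104.52 / 2.0)


@dataclass(frozen=True)
class Well:
    """Negative Gaussian well: center (Å, deg), depth (kcal/mol, > 0), widths."""

    x: float
    theta: float
    depth: float
    width_x: float
    width_theta: float

    def __post_init__(self) -> None:
        if self.width_x <= 0 or self.width_theta <= 0:
            raise PmfsurfError("well widths must be positive")


@dataclass(frozen=True)
class SurfaceSpec:
    """Sum of negative Gaussian wells on a sigmoidal x-ramp.

    The ramp emulates the water→oil transfer free energy: it rises from ~0
    in bulk water to ``ramp_height`` in bulk oil over a half-width
    ``ramp_width`` centred at ``ramp_center`` (the interface).
    """

    wells: tuple[Well, ...] = ()
    ramp_height: float = 0.0
    ramp_center: float = 0.0
    ramp_width: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "wells", tuple(self.wells))
        if self.ramp_width <= 0:
            raise PmfsurfError("ramp_width must be positive")


class AnalyticSurface:
    """Closed-form F(x, θz) with exact partial derivatives.

    ``value``/``dF_dx``/``dF_dtheta_deg`` broadcast over arrays; ``fx`` and
    ``Tz`` give the mean force and torque exerted on the crystal, i.e. minus
    the gradient, with Tz per radian.
    """

    def __init__(self, spec: SurfaceSpec):
        self.spec = spec

    def _sigmoid(self, x):
        u = (np.asarray(x, dtype=float) - self.spec.ramp_center) / self.spec.ramp_width
        return 1.0 / (1.0 + np.exp(-u))

    def value(self, x, theta):
        x = np.asarray(x, dtype=float)
        theta = np.asarray(theta, dtype=float)
        out = self.spec.ramp_height * self._sigmoid(x)
        for w in self.spec.wells:
            out = out - w.depth * np.exp(
                -((x - w.x) ** 2) / (2 * w.width_x**2)
                - ((theta - w.theta) ** 2) / (2 * w.width_theta**2)
            )
        return out

    def dF_dx(self, x, theta):
        x = np.asarray(x, dtype=float)
        theta = np.asarray(theta, dtype=float)
        s = self._sigmoid(x)
        out = self.spec.ramp_height * s * (1.0 - s) / self.spec.ramp_width
        for w in self.spec.wells:
            gauss = np.exp(
                -((x - w.x) ** 2) / (2 * w.width_x**2)
                - ((theta - w.theta) ** 2) / (2 * w.width_theta**2)
            )
            out = out + w.depth * gauss * (x - w.x) / w.width_x**2
        return out

    def dF_dtheta_deg(self, x, theta):
        x = np.asarray(x, dtype=float)
        theta = np.asarray(theta, dtype=float)
        out = np.zeros(np.broadcast(x, theta).shape)
        for w in self.spec.wells:
            gauss = np.exp(
                -((x - w.x) ** 2) / (2 * w.width_x**2)
                - ((theta - w.theta) ** 2) / (2 * w.width_theta**2)
            )
            out = out + w.depth * gauss * (theta - w.theta) / w.width_theta**2
        return out

    def fx(self, x, theta):
        return -self.dF_dx(x, theta)

    def Tz(self, x, theta):
        """Torque per radian: -dF/dθ with θ in radians."""
        return -(180.0 / math.pi) * self.dF_dtheta_deg(x, theta)

    def check_gradient(self, x, theta, h: float = 1e-5) -> float:
        """Max relative error of the analytic gradient vs central differences."""
        fd_x = (self.value(x + h, theta) - self.value(x - h, theta)) / (2 * h)
        fd_t = (self.value(x, theta + h) - self.value(x, theta - h)) / (2 * h)
        scale = 1.0 + np.abs(fd_x) + np.abs(fd_t)
        err_x = np.abs(fd_x - self.dF_dx(x, theta)) / scale
        err_t = np.abs(fd_t - self.dF_dtheta_deg(x, theta)) / scale
        return float(max(err_x.max(), err_t.max()))


def make_surface(spec: SurfaceSpec) -> AnalyticSurface:
    """Build the analytic surface object for a spec."""
    return AnalyticSurface(spec)


@dataclass(frozen=True)
class NoiseSpec:
    """Sampling-noise model for gradient fields.

    Node means receive Gaussian noise of standard error sigma/√n_samples.
    In time-series mode (``write_gradient_timeseries``) each node gets an
    AR(1) series of ``n_samples`` points with marginal std sigma and
    autocorrelation time ``ac_time`` (ps; 0 = white).
    """

    sigma_f: float = 0.0
    sigma_T: float = 0.0
    n_samples: int = 1
    seed: int = 0
    ac_time: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_f < 0 or self.sigma_T < 0:
            raise PmfsurfError("noise sigmas must be >= 0")
        if self.n_samples < 1:
            raise PmfsurfError("n_samples must be >= 1")

    @property
    def sem_f(self) -> float:
        return self.sigma_f / math.sqrt(self.n_samples)

    @property
    def sem_T(self) -> float:
        return self.sigma_T / math.sqrt(self.n_samples)


def _solve_chain(drops: np.ndarray, step: float, anchor: np.ndarray, cyclic: bool) -> np.ndarray:
    """Node gradient values g with ½(g_k + g_{k+1})·step = drops_k exactly.

    ``drops`` are per-edge free-energy drops F_k - F_{k+1} (cyclic chains
    include the wrap edge). The one-parameter solution family alternates in
    sign; the free parameter is fixed to the member closest to ``anchor``
    (the analytic gradient) for open/even-cyclic chains, or by the closure
    condition for odd cycles.
    """
    n_nodes = drops.size if cyclic else drops.size + 1
    g = np.empty(drops.size + 1)
    g[0] = 0.0
    for k in range(drops.size):
        g[k + 1] = 2.0 * drops[k] / step - g[k]
    if cyclic:
        if n_nodes % 2 == 1:
            t = g[-1] / 2.0
        else:
            if abs(g[-1]) > 1e-8 * (1.0 + np.abs(drops).max() / step):
                raise PmfsurfError(
                    "cyclic trapezoid system inconsistent; project the Nyquist "
                    "component of the increments first"
                )
            signs = (-1.0) ** np.arange(n_nodes)
            t = float(np.mean((anchor - g[:-1]) * signs))
        nodes = g[:-1]
    else:
        signs = (-1.0) ** np.arange(n_nodes)
        t = float(np.mean((anchor - g) * signs))
        nodes = g
    return nodes + ((-1.0) ** np.arange(n_nodes)) * t


def discrete_truth(surface: AnalyticSurface, grid: GridSpec) -> np.ndarray:
    """Planted surface at the nodes, adjusted for cyclic representability.

    On θ-periodic grids with an even node count the alternating (Nyquist)
    component of each row's θ-increments cannot be carried by trapezoid-
    consistent torques; it is removed here, which perturbs odd θ-columns by
    the per-row Nyquist amplitude (zero for θ-independent rows, tiny for
    well tails resolved by the grid).
    """
    X, TH = np.meshgrid(grid.x_nodes, grid.theta_nodes, indexing="ij")
    F = surface.value(X, TH)
    if grid.theta_periodic and grid.ntheta % 2 == 0:
        nt = grid.ntheta
        rolled = np.roll(F, -1, axis=1)
        g = F - rolled  # cyclic increments per row
        signs = (-1.0) ** np.arange(nt)
        a = (g * signs).sum(axis=1) / nt
        F = F + np.outer(a, np.arange(nt) % 2)
    return F


def sample_gradient_field(
    surface: AnalyticSurface,
    grid: GridSpec,
    noise: NoiseSpec | None = None,
    consistent: bool = True,
) -> tuple[GradientField, FreeEnergySurface]:
    """Sample fx = -∂F/∂x and Tz = -∂F/∂θz onto the grid.

    Returns the field plus the ground-truth surface it encodes, gauged so
    the x_min row averages zero (the reconstruction's reference gauge).
    With ``consistent=True`` (default) the noiseless field integrates back
    to the truth exactly under the trapezoid stencil; noise, when given, is
    i.i.d. Gaussian per node with std sigma/√n_samples.
    """
    X, TH = np.meshgrid(grid.x_nodes, grid.theta_nodes, indexing="ij")
    if consistent:
        F = discrete_truth(surface, grid)
        fx = np.empty(grid.shape)
        Tz = np.empty(grid.shape)
        ana_fx = surface.fx(X, TH)
        ana_Tz = surface.Tz(X, TH)
        for j in range(grid.ntheta):
            drops = F[:-1, j] - F[1:, j]
            fx[:, j] = _solve_chain(drops, grid.dx, ana_fx[:, j], cyclic=False)
        for i in range(grid.nx):
            if grid.theta_periodic:
                drops = F[i, :] - np.roll(F[i, :], -1)
            else:
                drops = F[i, :-1] - F[i, 1:]
            Tz[i, :] = _solve_chain(
                drops, grid.dtheta_rad, ana_Tz[i, :], cyclic=grid.theta_periodic
            )
    else:
        F = surface.value(X, TH)
        fx = surface.fx(X, TH)
        Tz = surface.Tz(X, TH)
    gauge = float(np.mean(F[0, :]))
    truth = F - gauge
    fx_sem = Tz_sem = None
    if noise is not None and (noise.sigma_f > 0 or noise.sigma_T > 0):
        rng = np.random.default_rng(noise.seed)
        fx = fx + rng.normal(0.0, noise.sem_f, size=grid.shape)
        Tz = Tz + rng.normal(0.0, noise.sem_T, size=grid.shape)
        fx_sem = np.full(grid.shape, noise.sem_f)
        Tz_sem = np.full(grid.shape, noise.sem_T)
    field = GradientField(grid=grid, fx=fx, Tz=Tz, fx_sem=fx_sem, Tz_sem=Tz_sem)
    truth_surface = FreeEnergySurface(
        grid=grid, F=truth, dFw2o=float(np.mean(truth[-1, :]))
    )
    return field, truth_surface


def _ar1(mean: float, sigma: float, n: int, dt: float, ac_time: float, rng) -> np.ndarray:
    phi = math.exp(-dt / ac_time) if ac_time > 0 else 0.0
    innovations = rng.normal(0.0, sigma * math.sqrt(1.0 - phi * phi), size=n)
    innovations[0] = rng.normal(0.0, sigma)
    series = lfilter([1.0], [1.0, -phi], innovations)
    return mean + series


def write_gradient_timeseries(
    surface: AnalyticSurface,
    grid: GridSpec,
    noise: NoiseSpec,
    out_dir,
    dt_ps: float = 0.005,
    consistent: bool = True,
) -> Path:
    """Write one AR(1) sampling file per grid node plus a manifest and a
    ground-truth JSON sidecar; returns the manifest path.

    Each file has columns t, fx, Tz in internal units (kcal/mol/Å,
    kcal/mol/rad); the series means are the (noise-free) planted gradients.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    field, truth = sample_gradient_field(surface, grid, noise=None, consistent=consistent)
    rng = np.random.default_rng(noise.seed)
    rows = []
    t = dt_ps * np.arange(noise.n_samples)
    for i, x in enumerate(grid.x_nodes):
        for j, th in enumerate(grid.theta_nodes):
            name = f"node_x{x:+08.2f}_t{th:06.2f}.tsv"
            series_f = _ar1(field.fx[i, j], noise.sigma_f, noise.n_samples, dt_ps, noise.ac_time, rng)
            series_T = _ar1(field.Tz[i, j], noise.sigma_T, noise.n_samples, dt_ps, noise.ac_time, rng)
            with open(out_dir / name, "w") as handle:
                handle.write("# synthetic sampling series (internal units)\n")
                handle.write("t\tfx\tTz\n")
                for k in range(noise.n_samples):
                    handle.write(f"{t[k]:.17g}\t{series_f[k]:.17g}\t{series_T[k]:.17g}\n")
            rows.append((x, th, name))
    manifest = out_dir / "manifest.tsv"
    with open(manifest, "w") as handle:
        handle.write("x\ttheta\tpath\n")
        for x, th, name in rows:
            handle.write(f"{x:.10g}\t{th:.10g}\t{name}\n")
    sidecar = {
        "dFw2o_true": truth.dFw2o,
        "wells": [vars(w) for w in surface.spec.wells],
        "ramp_height": surface.spec.ramp_height,
        "sigma_f": noise.sigma_f,
        "sigma_T": noise.sigma_T,
        "n_samples": noise.n_samples,
        "ac_time_ps": noise.ac_time,
        "seed": noise.seed,
    }
    (out_dir / "ground_truth.json").write_text(json.dumps(sidecar, indent=2))
    return manifest


# ---------------------------------------------------------------------------
# gap-water trajectories


@dataclass(frozen=True)
class GapSpec:
    """Anisotropic Brownian water in a reflective x-slab, periodic in y, z.

    ``D`` is the free (unconfined) per-axis diffusion (Å²/ps); the x walls
    at the slab bounds are what limit the *measured* D_x. ``kappa_theta``
    biases dipoles toward the interface plane (θ = 90°), ``tilt`` shifts the
    preference slightly past 90° (dipole toward the crystal), ``kappa_phi``
    aligns the H–H axis with the interface (φ = 0). All zero = isotropic.
    ``n_leavers`` molecules start just outside the slab (within
    ``leaver_margin``) and random-walk there, so strict residency filtering
    has something to reject.
    """

    slab: tuple[float, float] = (-21.0, -16.0)
    box: tuple[float, float, float] = (40.0, 25.0, 25.0)
    n_molecules: int = 100
    D: tuple[float, float, float] = (0.1, 0.1, 0.1)
    dt: float = 1.0
    n_frames: int = 501
    kappa_theta: float = 0.0
    tilt: float = 0.0
    kappa_phi: float = 0.0
    seed: int = 0
    n_leavers: int = 0
    leaver_margin: float = 3.0

    def __post_init__(self) -> None:
        lo, hi = self.slab
        if hi <= lo:
            raise PmfsurfError("slab must have positive width")
        if hi - lo > self.box[0]:
            raise PmfsurfError("slab wider than the box")
        if any(d < 0 for d in self.D):
            raise PmfsurfError("diffusion coefficients must be >= 0")
        if self.dt <= 0 or self.n_frames < 1:
            raise PmfsurfError("dt must be > 0 and n_frames >= 1")


def _reflect(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold coordinates into [lo, hi] by specular reflection."""
    width = hi - lo
    y = np.mod(values - lo, 2.0 * width)
    y = np.where(y > width, 2.0 * width - y, y)
    return lo + y


def sample_orientations(
    n: int,
    kappa_theta: float = 0.0,
    tilt: float = 0.0,
    kappa_phi: float = 0.0,
    rng=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` molecular orientations: unit dipoles d̂ and unit H→H axes.

    The dipole polar angle (relative to +x) follows the density on the
    sphere ∝ exp(kappa_theta·sinθ - tilt·cosθ); azimuth is uniform. The
    in-plane H–H angle φ follows ∝ exp(kappa_phi·cos 2φ). Everything is
    rejection-sampled, so the zero-bias case is exactly isotropic.
    """
    rng = np.random.default_rng(rng)

    def rejection(weight, bound, size):
        out = np.empty(0)
        while out.size < size:
            prop = rng.uniform(-1.0, 1.0, size=2 * (size - out.size) + 16)
            keep = rng.uniform(0.0, 1.0, size=prop.size) < weight(prop) / bound
            out = np.concatenate([out, prop[keep]])
        return out[:size]

    if kappa_theta == 0.0 and tilt == 0.0:
        cos_t = rng.uniform(-1.0, 1.0, size=n)
    else:
        bound = math.exp(kappa_theta + abs(tilt))
        cos_t = rejection(
            lambda c: np.exp(kappa_theta * np.sqrt(1.0 - c**2) - tilt * c), bound, n
        )
    sin_t = np.sqrt(1.0 - cos_t**2)
    psi = rng.uniform(0.0, 2.0 * math.pi, size=n)
    d = np.column_stack([cos_t, sin_t * np.cos(psi), sin_t * np.sin(psi)])
    if kappa_phi == 0.0:
        phi = rng.uniform(0.0, 2.0 * math.pi, size=n)
    else:
        # map [-1,1] proposals onto [0, 2π)
        bound = math.exp(kappa_phi)
        raw = rejection(
            lambda u: np.exp(kappa_phi * np.cos(2.0 * math.pi * (u + 1.0))), bound, n
        )
        phi = math.pi * (raw + 1.0)
    # in-plane frame: e1 along d x n, e2 completing it
    normal = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(d, normal)
    norms = np.linalg.norm(e1, axis=1)
    polar = norms < 1e-12
    if np.any(polar):
        e1[polar] = np.cross(d[polar], np.array([0.0, 1.0, 0.0]))
        norms[polar] = np.linalg.norm(e1[polar], axis=1)
    e1 /= norms[:, None]
    e2 = np.cross(d, e1)
    r_hh = np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2
    return d, r_hh


def brownian_gap_trajectory(spec: GapSpec) -> Trajectory:
    """Generate a gap-water trajectory per the spec; fully seeded.

    Oxygen steps are Gaussian with per-axis variance 2·D_α·dt, reflected at
    the slab walls in x and wrapped periodically in y and z. Hydrogens are
    placed at rigid water geometry around each oxygen with orientations
    redrawn each frame from the biased distribution (orientational dynamics are
    not modelled; the orientation statistics, not their time correlation,
    are the target).
    """
    rng = np.random.default_rng(spec.seed)
    total = spec.n_molecules + spec.n_leavers
    lo, hi = spec.slab
    box = np.array(spec.box)
    pos = np.empty((total, 3))
    pos[: spec.n_molecules, 0] = rng.uniform(lo, hi, size=spec.n_molecules)
    if spec.n_leavers:
        pos[spec.n_molecules :, 0] = rng.uniform(
            hi, hi + spec.leaver_margin, size=spec.n_leavers
        )
    pos[:, 1] = rng.uniform(0.0, box[1], size=total)
    pos[:, 2] = rng.uniform(0.0, box[2], size=total)
    sigma = np.sqrt(2.0 * np.asarray(spec.D) * spec.dt)
    coords = np.empty((spec.n_frames, total, 3, 3))
    times = spec.dt * np.arange(spec.n_frames)
    for k in range(spec.n_frames):
        if k > 0:
            pos = pos + rng.normal(0.0, 1.0, size=(total, 3)) * sigma
            pos[: spec.n_molecules, 0] = _reflect(pos[: spec.n_molecules, 0], lo, hi)
            if spec.n_leavers:
                pos[spec.n_molecules :, 0] = _reflect(
                    pos[spec.n_molecules :, 0], lo - spec.leaver_margin, hi + spec.leaver_margin
                )
            pos[:, 1] = np.mod(pos[:, 1], box[1])
            pos[:, 2] = np.mod(pos[:, 2], box[2])
        d, r_hh = sample_orientations(
            total, spec.kappa_theta, spec.tilt, spec.kappa_phi, rng
        )
        arm = _OH_LENGTH * (
            math.cos(_HOH_HALF_ANGLE) * d[:, None, :]
            + math.sin(_HOH_HALF_ANGLE) * np.stack([-r_hh, r_hh], axis=1)
        )
        coords[k, :, 0, :] = pos
        coords[k, :, 1:, :] = pos[:, None, :] + arm
    boxes = np.tile(box, (spec.n_frames, 1))
    return Trajectory(times=times, boxes=boxes, coords=coords)


# ---------------------------------------------------------------------------
# crystal bookkeeping


@dataclass(frozen=True)
class CrystalSpec:
    """Nanocrystal composition: chains in cross-section, residues per chain,
    atoms per anhydroglucose residue (C6H10O5 = 21 under periodic chain
    bonding)."""

    chains_x: int = 4
    chains_y: int = 4
    units_per_chain: int = 8
    atoms_per_unit: int = 21

    def __post_init__(self) -> None:
        if min(self.chains_x, self.chains_y, self.units_per_chain, self.atoms_per_unit) < 1:
            raise PmfsurfError("all crystal spec fields must be positive")


def crystal_atom_count(spec: CrystalSpec = CrystalSpec()) -> int:
    """Total atoms = chains_x · chains_y · units_per_chain · atoms_per_unit."""
    return spec.chains_x * spec.chains_y * spec.units_per_chain * spec.atoms_per_unit
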