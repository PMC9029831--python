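"""Free-energy surface reconstruction from a gridded mean-force / mean-torque field.

The crystal's restrained degrees of freedom are its distance x from the
water-oil interface (Å) and its rotation θz about the chain axis (degrees,
period 180° by crystal symmetry). The mean force ⟨fx⟩ and mean torque ⟨Tz⟩
exerted on the crystal are minus the partial derivatives of the free energy
F(x, θz), so F is recovered by thermodynamic integration of the sampled
gradient field:

* each constant-θz row is line-integrated in x (trapezoid rule) from the
  bulk-water reference plane at x_min, where F ≡ 0;
* the per-row end values at x_max scatter only through sampling noise; their
  mean defines the water→oil transfer free energy ΔF_w→o, which is imposed
  as a constant Dirichlet boundary on the x_max edge;
* interior nodes are then relaxed: each node is replaced by the mean of the
  four values its neighbours predict through the trapezoid force/torque
  increments. The fixed point of this update is the solution of a sparse
  linear system (a discrete Poisson-like reconciliation of the noisy,
  generally curl-carrying field) and is independent of sweep order.

Torque enters the stencil with Δθz in radians and Tz in kcal/mol/rad, since
energy = torque x angle only holds for radian measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse
import scipy.sparse.linalg
from scipy.interpolate import RegularGridInterpolator

from .errors import DomainError, FormatError, PmfsurfError
from .timeseries import Dialect, mean_and_sem, read_timeseries, to_internal, trim_equilibration

__all__ = [
    "GridSpec",
    "GradientField",
    "FreeEnergySurface",
    "BoundaryCondition",
    "line_integrate_x",
    "set_boundaries",
    "relax_surface",
    "refine_fine_grid",
    "torque_integrate_check",
    "oracle_least_squares",
    "field_from_table",
    "field_from_manifest",
]

THETA_PERIOD_DEG = 180.0


@dataclass(frozen=True)
class GridSpec:
    """Regular (x, θz) grid.

    For a periodic θz axis the range must cover exactly one 180° period and
    ``theta_max`` is the excluded duplicate endpoint, e.g. 0 ≤ θz < 180 with
    Δθz = 15° gives 12 nodes. Non-periodic axes include both endpoints.
    """

    x_min: float
    x_max: float
    dx: float
    theta_min: float
    theta_max: float
    dtheta: float
    theta_periodic: bool = False

    def __post_init__(self) -> None:
        for span, step, name in (
            (self.x_max - self.x_min, self.dx, "x"),
            (self.theta_max - self.theta_min, self.dtheta, "theta"),
        ):
            if step <= 0 or span <= 0:
                raise PmfsurfError(f"{name} range/spacing must be positive")
            if abs(span / step - round(span / step)) > 1e-9:
                raise PmfsurfError(f"{name} range is not divisible by its spacing")
        if self.theta_periodic:
            if abs((self.theta_max - self.theta_min) - THETA_PERIOD_DEG) > 1e-9:
                raise PmfsurfError(
                    "periodic theta range must cover exactly one 180 degree period"
                )

    @property
    def nx(self) -> int:
        return round((self.x_max - self.x_min) / self.dx) + 1

    @property
    def ntheta(self) -> int:
        n = round((self.theta_max - self.theta_min) / self.dtheta)
        return n if self.theta_periodic else n + 1

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nx, self.ntheta)

    @property
    def x_nodes(self) -> np.ndarray:
        return self.x_min + self.dx * np.arange(self.nx)

    @property
    def theta_nodes(self) -> np.ndarray:
        """θz node positions in degrees."""
        return self.theta_min + self.dtheta * np.arange(self.ntheta)

    @property
    def dtheta_rad(self) -> float:
        return float(np.deg2rad(self.dtheta))


def _as_grid_array(grid: GridSpec, values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != grid.shape:
        raise PmfsurfError(f"{name} has shape {arr.shape}, grid expects {grid.shape}")
    if not np.all(np.isfinite(arr)):
        raise PmfsurfError(f"{name} contains non-finite values")
    return arr


@dataclass
class GradientField:
    """Mean force fx (kcal/mol/Å) and mean torque Tz (kcal/mol/rad) per node.

    Both are the force/torque exerted ON the crystal, so fx = -∂F/∂x and
    Tz = -∂F/∂θz; F rises where fx is negative. Arrays are indexed [i, j]
    with i over x nodes and j over θz nodes.
    """

    grid: GridSpec
    fx: np.ndarray
    Tz: np.ndarray
    fx_sem: np.ndarray | None = None
    Tz_sem: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.fx = _as_grid_array(self.grid, self.fx, "fx")
        self.Tz = _as_grid_array(self.grid, self.Tz, "Tz")
        if self.fx_sem is not None:
            self.fx_sem = _as_grid_array(self.grid, self.fx_sem, "fx_sem")
        if self.Tz_sem is not None:
            self.Tz_sem = _as_grid_array(self.grid, self.Tz_sem, "Tz_sem")


@dataclass
class FreeEnergySurface:
    """F (kcal/mol) on the grid, gauged so the reference plane is exactly 0.

    ``reference_value`` is the F value of the bulk-water reference plane in
    this surface's gauge (0 for surfaces built by :func:`relax_surface`, and
    inherited unchanged through fine-grid refinement). ``dFw2o`` stores the
    water→oil transfer free energy when the surface was built with
    :func:`set_boundaries`.
    """

    grid: GridSpec
    F: np.ndarray
    reference_value: float = 0.0
    dFw2o: float | None = None

    def __post_init__(self) -> None:
        self.F = _as_grid_array(self.grid, self.F, "F")

    def to_frame(self) -> pd.DataFrame:
        x, th = np.meshgrid(self.grid.x_nodes, self.grid.theta_nodes, indexing="ij")
        return pd.DataFrame(
            {"x": x.ravel(), "theta": th.ravel(), "F": self.F.ravel()}
        )

    def to_tsv(self, path) -> None:
        # shortest-exact float repr, so values round-trip losslessly
        with open(path, "w") as handle:
            handle.write("x\ttheta\tF\n")
            for x, th, F in self.to_frame().itertuples(index=False):
                handle.write(f"{x!r}\t{th!r}\t{F!r}\n")

    @classmethod
    def from_tsv(cls, path, grid: GridSpec, **kwargs) -> "FreeEnergySurface":
        frame = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
        for col in ("x", "theta", "F"):
            if col not in frame.columns:
                raise FormatError(f"{path}: missing column {col!r}")
        F = np.full(grid.shape, np.nan)
        xi = np.rint((frame["x"].to_numpy() - grid.x_min) / grid.dx).astype(int)
        tj = np.rint((frame["theta"].to_numpy() - grid.theta_min) / grid.dtheta).astype(int)
        F[xi, tj] = frame["F"].to_numpy()
        if not np.all(np.isfinite(F)):
            raise FormatError(f"{path}: does not cover every node of the grid")
        return cls(grid=grid, F=F, **kwargs)


@dataclass
class BoundaryCondition:
    """Dirichlet data for the relaxation.

    x_min/x_max edges are always fixed; θz edges are fixed only when the
    corresponding arrays are given (fine-grid refinement), otherwise the θz
    direction is either periodic (grid flag) or free (one-sided stencil).
    """

    x_min_values: np.ndarray
    x_max_values: np.ndarray
    theta_min_values: np.ndarray | None = None
    theta_max_values: np.ndarray | None = None
    dFw2o: float | None = None


def line_integrate_x(field: GradientField, theta_index: int) -> np.ndarray:
    """Trapezoidal cumulative integral of -fx along one θz row; F(x_min) = 0."""
    fx = field.fx[:, theta_index]
    increments = -0.5 * (fx[:-1] + fx[1:]) * field.grid.dx
    return np.concatenate(([0.0], np.cumsum(increments)))


def set_boundaries(field: GradientField) -> BoundaryCondition:
    """Fix both x edges: F(x_min) = 0 and F(x_max) = ΔF_w→o for every θz.

    ΔF_w→o is the arithmetic mean over θz of the per-row line integrals;
    the per-row scatter about it is pure sampling noise, since the true end
    value cannot depend on θz in either bulk phase.
    """
    nt = field.grid.ntheta
    ends = np.array([line_integrate_x(field, j)[-1] for j in range(nt)])
    dFw2o = float(np.mean(ends))
    return BoundaryCondition(
        x_min_values=np.zeros(nt),
        x_max_values=np.full(nt, dFw2o),
        dFw2o=dFw2o,
    )


def _free_nodes(grid: GridSpec, bc: BoundaryCondition) -> list[tuple[int, int]]:
    nx, nt = grid.shape
    theta_fixed = bc.theta_min_values is not None or bc.theta_max_values is not None
    js = range(nt)
    nodes = []
    for i in range(1, nx - 1):
        for j in js:
            if theta_fixed and (
                (j == 0 and bc.theta_min_values is not None)
                or (j == nt - 1 and bc.theta_max_values is not None)
            ):
                continue
            nodes.append((i, j))
    return nodes


def _apply_boundaries(F: np.ndarray, bc: BoundaryCondition) -> None:
    F[0, :] = bc.x_min_values
    F[-1, :] = bc.x_max_values
    if bc.theta_min_values is not None:
        F[:, 0] = bc.theta_min_values
    if bc.theta_max_values is not None:
        F[:, -1] = bc.theta_max_values


def _neighbor_predictions(
    F: np.ndarray, field: GradientField, i: int, j: int
) -> list[float]:
    """Values predicted for node (i,j) by each neighbour via Eq.-5 trapezoid terms."""
    grid = field.grid
    fx, Tz = field.fx, field.Tz
    dx, dth = grid.dx, grid.dtheta_rad
    nt = grid.ntheta
    preds = [
        F[i - 1, j] - 0.5 * (fx[i - 1, j] + fx[i, j]) * dx,
        F[i + 1, j] + 0.5 * (fx[i, j] + fx[i + 1, j]) * dx,
    ]
    if grid.theta_periodic:
        jm, jp = (j - 1) % nt, (j + 1) % nt
        preds.append(F[i, jm] - 0.5 * (Tz[i, jm] + Tz[i, j]) * dth)
        preds.append(F[i, jp] + 0.5 * (Tz[i, j] + Tz[i, jp]) * dth)
    else:
        if j > 0:
            preds.append(F[i, j - 1] - 0.5 * (Tz[i, j - 1] + Tz[i, j]) * dth)
        if j < nt - 1:
            preds.append(F[i, j + 1] + 0.5 * (Tz[i, j] + Tz[i, j + 1]) * dth)
    return preds


def _initial_guess(field: GradientField, bc: BoundaryCondition) -> np.ndarray:
    """Row-wise line integrals, linearly corrected to meet the x_max boundary."""
    grid = field.grid
    F = np.empty(grid.shape)
    ramp = (grid.x_nodes - grid.x_min) / (grid.x_max - grid.x_min)
    for j in range(grid.ntheta):
        row = line_integrate_x(field, j) + bc.x_min_values[j]
        row += (bc.x_max_values[j] - row[-1]) * ramp
        F[:, j] = row
    _apply_boundaries(F, bc)
    return F


def relax_surface(
    field: GradientField,
    boundaries: BoundaryCondition,
    max_iter: int = 1_000_000,
    tol: float = 1e-10,
    seed: int | None = 0,
    sweep_mode: str = "random",
) -> FreeEnergySurface:
    """Iterative nodewise relaxation to the trapezoid-consistent surface.

    Each update replaces a free node by the mean of its neighbour
    predictions. ``sweep_mode='random'`` picks free nodes with a seeded
    generator (with a deterministic full sweep interleaved for the
    convergence check); ``'ordered'`` is plain Gauss–Seidel. Both converge
    to the same fixed point, which is also the direct solution of
    :func:`oracle_least_squares`. ``max_iter`` counts single-node updates;
    iteration stops once the largest update in a full sweep drops below
    ``tol`` (kcal/mol).
    """
    if sweep_mode not in ("random", "ordered"):
        raise PmfsurfError(f"unknown sweep_mode {sweep_mode!r}")
    grid = field.grid
    free = _free_nodes(grid, boundaries)
    F = _initial_guess(field, boundaries)
    if not free:
        return FreeEnergySurface(grid=grid, F=F, dFw2o=boundaries.dFw2o)
    rng = np.random.default_rng(seed)
    updates = 0
    residual = np.inf
    while updates < max_iter:
        if sweep_mode == "random":
            for k in rng.integers(0, len(free), size=len(free)):
                i, j = free[k]
                F[i, j] = np.mean(_neighbor_predictions(F, field, i, j))
            updates += len(free)
        # deterministic sweep; doubles as the convergence check
        residual = 0.0
        for i, j in free:
            new = float(np.mean(_neighbor_predictions(F, field, i, j)))
            residual = max(residual, abs(new - F[i, j]))
            F[i, j] = new
        updates += len(free)
        if residual < tol:
            break
    else:
        warnings.warn(
            f"relaxation did not converge in {max_iter} updates "
            f"(last sweep residual {residual:.3e} kcal/mol)",
            stacklevel=2,
        )
    return FreeEnergySurface(grid=grid, F=F, dFw2o=boundaries.dFw2o)


def oracle_least_squares(
    field: GradientField, boundaries: BoundaryCondition
) -> FreeEnergySurface:
    """Direct sparse solve of the relaxation's stationarity system.

    For every free node, m·F_ij - Σ F_neighbours = Σ (trapezoid increments),
    with m the number of neighbours — exactly the fixed-point condition of
    :func:`relax_surface`. Deterministic; intended for small grids.
    """
    grid = field.grid
    free = _free_nodes(grid, boundaries)
    F = _initial_guess(field, boundaries)
    if not free:
        return FreeEnergySurface(grid=grid, F=F, dFw2o=boundaries.dFw2o)
    index = {node: k for k, node in enumerate(free)}
    n = len(free)
    A = scipy.sparse.lil_matrix((n, n))
    b = np.zeros(n)
    fx, Tz = field.fx, field.Tz
    dx, dth = grid.dx, grid.dtheta_rad
    nt = grid.ntheta
    for (i, j), k in index.items():
        terms: list[tuple[tuple[int, int], float]] = [
            ((i - 1, j), -0.5 * (fx[i - 1, j] + fx[i, j]) * dx),
            ((i + 1, j), +0.5 * (fx[i, j] + fx[i + 1, j]) * dx),
        ]
        if grid.theta_periodic:
            jm, jp = (j - 1) % nt, (j + 1) % nt
            terms.append(((i, jm), -0.5 * (Tz[i, jm] + Tz[i, j]) * dth))
            terms.append(((i, jp), +0.5 * (Tz[i, j] + Tz[i, jp]) * dth))
        else:
            if j > 0:
                terms.append(((i, j - 1), -0.5 * (Tz[i, j - 1] + Tz[i, j]) * dth))
            if j < nt - 1:
                terms.append(((i, j + 1), +0.5 * (Tz[i, j] + Tz[i, j + 1]) * dth))
        A[k, k] = len(terms)
        for node, increment in terms:
            b[k] += increment
            if node in index:
                A[k, index[node]] -= 1.0
            else:
                b[k] += F[node]  # Dirichlet neighbour
    solution = scipy.sparse.linalg.spsolve(A.tocsr(), b)
    for (i, j), k in index.items():
        F[i, j] = solution[k]
    return FreeEnergySurface(grid=grid, F=F, dFw2o=boundaries.dFw2o)


def refine_fine_grid(
    coarse: FreeEnergySurface, fine_field: GradientField, **relax_kwargs
) -> FreeEnergySurface:
    """Relax a fine grid whose four edges are pinned to the coarse surface.

    Edge values at fine nodes that do not coincide with coarse nodes are
    obtained by bilinear interpolation of the coarse surface (periodic θz
    extension when the coarse grid wraps). The fine θz axis is non-periodic:
    both θz edges are Dirichlet.
    """
    cg, fg = coarse.grid, fine_field.grid
    if fg.theta_periodic:
        raise PmfsurfError("fine grid must be non-periodic in theta")
    theta_hi = cg.theta_max if cg.theta_periodic else cg.theta_nodes[-1]
    if not (
        fg.x_min >= cg.x_min - 1e-9
        and fg.x_max <= cg.x_max + 1e-9
        and fg.theta_min >= cg.theta_min - 1e-9
        and fg.theta_nodes[-1] <= theta_hi + 1e-9
    ):
        raise DomainError("fine grid extends beyond the coarse domain")
    if cg.theta_periodic:
        theta_axis = np.concatenate([cg.theta_nodes, [cg.theta_min + THETA_PERIOD_DEG]])
        values = np.concatenate([coarse.F, coarse.F[:, :1]], axis=1)
    else:
        theta_axis, values = cg.theta_nodes, coarse.F
    interp = RegularGridInterpolator((cg.x_nodes, theta_axis), values, method="linear")

    def edge(xs, ths):
        return interp(np.column_stack([xs, ths]))

    fx_nodes, fth_nodes = fg.x_nodes, fg.theta_nodes
    bc = BoundaryCondition(
        x_min_values=edge(np.full(fg.ntheta, fg.x_min), fth_nodes),
        x_max_values=edge(np.full(fg.ntheta, fg.x_max), fth_nodes),
        theta_min_values=edge(fx_nodes, np.full(fg.nx, fth_nodes[0])),
        theta_max_values=edge(fx_nodes, np.full(fg.nx, fth_nodes[-1])),
        dFw2o=coarse.dFw2o,
    )
    fine = relax_surface(fine_field, bc, **relax_kwargs)
    fine.reference_value = coarse.reference_value
    return fine


def torque_integrate_check(
    field: GradientField, x_index: int
) -> tuple[np.ndarray, float]:
    """Cumulative trapezoid of -Tz along θz at fixed x, plus the loop residual.

    On a periodic axis the residual |F(θ0 + 180°) - F(θ0)| vanishes for a
    curl-free (exactly integrable) field and measures sampling inconsistency
    otherwise. For rows in either bulk phase (x = ±30 Å) ⟨Tz⟩ is essentially
    zero, so the profile itself should be flat there.
    """
    grid = field.grid
    Tz = field.Tz[x_index, :]
    if grid.theta_periodic:
        Tz = np.concatenate([Tz, Tz[:1]])
    increments = -0.5 * (Tz[:-1] + Tz[1:]) * grid.dtheta_rad
    profile = np.concatenate(([0.0], np.cumsum(increments)))
    if grid.theta_periodic:
        residual = abs(profile[-1] - profile[0])
        profile = profile[:-1]
    else:
        residual = 0.0
    return profile, float(residual)


# ---------------------------------------------------------------------------
# I/O: pre-averaged tables and per-node time-series manifests


def field_from_table(path, grid: GridSpec) -> GradientField:
    """Read a pre-averaged TSV with columns x, theta, fx, Tz[, fx_sem, Tz_sem]."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    for col in ("x", "theta", "fx", "Tz"):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    arrays = {}
    xi = np.rint((frame["x"].to_numpy() - grid.x_min) / grid.dx).astype(int)
    tj = np.rint((frame["theta"].to_numpy() - grid.theta_min) / grid.dtheta).astype(int)
    for col in ("fx", "Tz", "fx_sem", "Tz_sem"):
        if col not in frame.columns:
            arrays[col] = None
            continue
        arr = np.full(grid.shape, np.nan)
        arr[xi, tj] = frame[col].to_numpy()
        if not np.all(np.isfinite(arr)):
            raise FormatError(f"{path}: column {col!r} does not cover every grid node")
        arrays[col] = arr
    return GradientField(
        grid=grid, fx=arrays["fx"], Tz=arrays["Tz"],
        fx_sem=arrays["fx_sem"], Tz_sem=arrays["Tz_sem"],
    )


def field_from_manifest(
    manifest_path,
    grid: GridSpec,
    dialect: Dialect | None = None,
    equilibration_ps: float = 1000.0,
    block_size: int = 100,
) -> GradientField:
    """Build a GradientField from per-node sampling files.

    The manifest is a TSV with columns x, theta, path (relative paths are
    resolved against the manifest's directory). Each file is read, trimmed
    at ``equilibration_ps``, block-averaged, and converted to internal
    units.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path, sep="\t", comment="#")
    for col in ("x", "theta", "path"):
        if col not in manifest.columns:
            raise FormatError(f"{manifest_path}: missing column {col!r}")
    dialect = dialect or Dialect()
    fx = np.full(grid.shape, np.nan)
    Tz = np.full(grid.shape, np.nan)
    fx_sem = np.full(grid.shape, np.nan)
    Tz_sem = np.full(grid.shape, np.nan)
    for row in manifest.itertuples(index=False):
        i = round((row.x - grid.x_min) / grid.dx)
        j = round((row.theta - grid.theta_min) / grid.dtheta)
        node_path = Path(row.path)
        if not node_path.is_absolute():
            node_path = manifest_path.parent / node_path
        ts = trim_equilibration(read_timeseries(node_path, dialect), equilibration_ps)
        est_f = to_internal(mean_and_sem(ts, "fx", block_size), ts.units["fx"], "force")
        est_T = to_internal(mean_and_sem(ts, "Tz", block_size), ts.units["Tz"], "torque")
        fx[i, j], fx_sem[i, j] = est_f.mean, est_f.sem
        Tz[i, j], Tz_sem[i, j] = est_T.mean, est_T.sem
    if not (np.all(np.isfinite(fx)) and np.all(np.isfinite(Tz))):
        raise FormatError(f"{manifest_path}: manifest does not cover every grid node")
    return GradientField(grid=grid, fx=fx, Tz=Tz, fx_sem=fx_sem, Tz_sem=Tz_sem)
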