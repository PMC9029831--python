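"""Adsorption states, transfer free energy and barriers on a reconstructed surface.

The adsorption free energy ΔF(x, θz) = F(x, θz) - F(reference plane) is
measured from the bulk-water plane at x = x_min, where F has no θz
dependence by construction. Its strict local minima are the adsorption
states; the barrier between two states is defined as the minimax saddle: the
smallest, over all 8-connected grid paths joining them, of the largest F
encountered along the path.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .errors import ConsistencyError, DegeneratePairError, DomainError, PmfsurfError
from .pmf import FreeEnergySurface

__all__ = [
    "AdsorptionState",
    "BarrierResult",
    "adsorption_free_energy",
    "find_local_minima",
    "barrier_height",
    "transfer_free_energy",
]

_LABELS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass(frozen=True)
class AdsorptionState:
    """A strict local minimum of the surface."""

    node: tuple[float, float]  # (x in Å, θz in degrees)
    dF: float  # kcal/mol relative to the bulk-water reference plane
    label: str
    index: tuple[int, int] = (0, 0)  # grid indices (i, j)


@dataclass(frozen=True)
class BarrierResult:
    """Minimax saddle between two adsorption states, with per-well barriers."""

    state_a: AdsorptionState
    state_b: AdsorptionState
    saddle_value: float
    barrier_from_a: float
    barrier_from_b: float


def adsorption_free_energy(surface: FreeEnergySurface) -> np.ndarray:
    """ΔF grid: F minus the (constant) value of the x_min reference row.

    Raises ConsistencyError if the reference row varies by more than 1e-9 —
    the reconstruction pins it to a single Dirichlet value, so any spread
    indicates the surface was not built through the standard pipeline.
    """
    ref_row = surface.F[0, :]
    if np.ptp(ref_row) > 1e-9:
        raise ConsistencyError(
            f"reference row at x = {surface.grid.x_min} Å varies by {np.ptp(ref_row):.3e}"
        )
    return surface.F - ref_row[0]


def _neighbors(grid, i: int, j: int, connectivity: int):
    nx, nt = grid.shape
    if connectivity == 4:
        offsets = ((-1, 0), (1, 0), (0, -1), (0, 1))
    elif connectivity == 8:
        offsets = (
            (-1, 0), (1, 0), (0, -1), (0, 1),
            (-1, -1), (-1, 1), (1, -1), (1, 1),
        )
    else:
        raise PmfsurfError("connectivity must be 4 or 8")
    for di, dj in offsets:
        ni, nj = i + di, j + dj
        if ni < 0 or ni >= nx:
            continue
        if grid.theta_periodic:
            nj %= nt
        elif nj < 0 or nj >= nt:
            continue
        yield ni, nj


def find_local_minima(
    surface: FreeEnergySurface,
    neighborhood: int = 4,
    region: tuple[tuple[float, float], tuple[float, float]] | None = None,
    min_depth: float | None = None,
) -> list[AdsorptionState]:
    """Strict local minima, sorted ascending by ΔF and labelled A, B, C, ...

    A node qualifies only if strictly lower than every neighbour in the
    chosen connectivity (θz wrap respected on periodic grids); nodes equal
    to a neighbour are excluded, so flat plateaus are never reported.
    ``region`` restricts candidates to ((x_lo, x_hi), (θ_lo, θ_hi)) in
    physical units; neighbours are still compared across the full grid.
    ``min_depth`` optionally drops minima with ΔF above the threshold.
    """
    grid = surface.grid
    if region is not None:
        (x_lo, x_hi), (th_lo, th_hi) = region
        if x_lo < grid.x_min - 1e-9 or x_hi > grid.x_max + 1e-9:
            raise DomainError("region x range outside grid")
    F = surface.F
    minima = []
    for i in range(grid.nx):
        for j in range(grid.ntheta):
            x, th = grid.x_nodes[i], grid.theta_nodes[j]
            if region is not None and not (
                x_lo - 1e-9 <= x <= x_hi + 1e-9 and th_lo - 1e-9 <= th <= th_hi + 1e-9
            ):
                continue
            if all(F[i, j] < F[ni, nj] for ni, nj in _neighbors(grid, i, j, neighborhood)):
                dF = float(F[i, j] - surface.reference_value)
                if min_depth is None or dF <= min_depth:
                    minima.append(((i, j), (x, th), dF))
    minima.sort(key=lambda m: m[2])
    return [
        AdsorptionState(node=node, dF=dF, label=_LABELS[k % 26], index=idx)
        for k, (idx, node, dF) in enumerate(minima)
    ]


def barrier_height(
    surface: FreeEnergySurface, a: AdsorptionState, b: AdsorptionState
) -> BarrierResult:
    """Exact minimax saddle between two minima over 8-connected grid paths.

    Dijkstra-style search with path cost = max F along the path (endpoints
    included); the first time ``b`` is settled its cost is the saddle value.
    Both one-sided barriers (saddle - F(well)) are reported; which one the
    experimentalist quotes depends on the direction of escape.
    """
    if a.index == b.index:
        raise DegeneratePairError("barrier requested between a state and itself")
    grid = surface.grid
    F = surface.F
    best = np.full(grid.shape, np.inf)
    start, goal = a.index, b.index
    best[start] = F[start]
    heap = [(F[start], start)]
    while heap:
        level, node = heapq.heappop(heap)
        if level > best[node]:
            continue
        if node == goal:
            break
        for nb in _neighbors(grid, *node, 8):
            new_level = max(level, F[nb])
            if new_level < best[nb]:
                best[nb] = new_level
                heapq.heappush(heap, (new_level, nb))
    saddle = float(best[goal])
    return BarrierResult(
        state_a=a,
        state_b=b,
        saddle_value=saddle,
        barrier_from_a=saddle - float(F[start]),
        barrier_from_b=saddle - float(F[goal]),
    )


def transfer_free_energy(surface: FreeEnergySurface) -> float:
    """The stored water→oil transfer free energy ΔF_w→o (kcal/mol)."""
    if surface.dFw2o is None:
        raise PmfsurfError(
            "surface carries no transfer free energy; build it with set_boundaries"
        )
    return float(surface.dFw2o)
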