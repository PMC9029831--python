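"""Per-axis mean-square displacement and anisotropic diffusion of gap water.

Only molecules resident in the gap slab for the entire sampling window enter
the statistics, following the strict residency rule; the oxygen position
stands in for the molecule. Displacements use every frame as a time origin:

    MSD_α(t) = ⟨ (α_i(t0 + t) - α_i(t0))² ⟩ over molecules i and origins t0.

The diffusion coefficient per axis is half the slope of MSD_α(t) at large
lag (for 1D diffusion MSD = 2 D t). Å²/ps is numerically identical to
1e-8 m²/s, the unit diffusion tables are conventionally printed in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import AmbiguityError, PmfsurfError
from .trajectory import Trajectory

__all__ = [
    "MSDCurve",
    "DiffusionResult",
    "gap_residents",
    "unwrap_pbc",
    "msd_curve",
    "fit_diffusion",
]


@dataclass
class MSDCurve:
    """lag (ps, starting at 0), per-axis MSD (Å²), and pair counts per lag."""

    lag: np.ndarray
    msd_x: np.ndarray
    msd_y: np.ndarray
    msd_z: np.ndarray
    n_pairs: np.ndarray


@dataclass(frozen=True)
class DiffusionResult:
    """Per-axis D in 1e-8 m²/s (numerically Å²/ps) and the fit window used."""

    D_x: float
    D_y: float
    D_z: float
    fit_window: tuple[float, float]
    n_residents: int = 0


def gap_residents(
    traj: Trajectory, slab: tuple[float, float], window: tuple[float, float]
) -> list[int]:
    """Molecules whose oxygen x stays inside ``slab`` at every frame of ``window``."""
    t0, t1 = window
    frame_mask = (traj.times >= t0) & (traj.times <= t1)
    if not np.any(frame_mask):
        raise PmfsurfError(f"no frames in window [{t0}, {t1}] ps")
    ox = traj.oxygen[frame_mask, :, 0]
    inside = (ox >= slab[0]) & (ox <= slab[1])
    ids = [int(m) for m in np.nonzero(inside.all(axis=0))[0]]
    if not ids:
        warnings.warn("no molecules are resident in the slab for the whole window",
                      stacklevel=2)
    return ids


def unwrap_pbc(traj: Trajectory) -> Trajectory:
    """Remove periodic jumps so oxygen displacements are continuous.

    Each inter-frame oxygen displacement is shifted by the integer number of
    box lengths that minimizes it; the accumulated shift is applied to the
    whole molecule (hydrogens follow their oxygen). The first frame is
    unchanged. Raises AmbiguityError when a minimized jump still reaches
    half a box — the frame spacing is then too coarse to unwrap.
    """
    coords = traj.coords.copy()
    oxy = traj.oxygen
    shift = np.zeros((traj.n_molecules, 3))
    for k in range(1, traj.n_frames):
        box = traj.boxes[k]
        disp = oxy[k] - oxy[k - 1]
        wraps = np.round(disp / box)
        adjusted = disp - wraps * box
        bad = np.abs(adjusted) >= box / 2.0
        if np.any(bad):
            m, axis = np.argwhere(bad)[0]
            raise AmbiguityError(
                f"ambiguous jump of {adjusted[m, axis]:.2f} Å (half box "
                f"{box[axis] / 2:.2f} Å) for molecule {m}, axis {axis}, frame {k}"
            )
        shift -= wraps * box
        coords[k] += shift[:, None, :]
    return Trajectory(times=traj.times.copy(), boxes=traj.boxes.copy(), coords=coords)


def msd_curve(traj: Trajectory, ids, max_lag: float) -> MSDCurve:
    """Multiple-origin per-axis MSD over the selected (unwrapped) molecules."""
    ids = list(ids)
    if not ids:
        raise PmfsurfError("ids must be non-empty")
    times = traj.times
    if times.size < 2:
        raise PmfsurfError("need at least two frames")
    dt = float(times[1] - times[0])
    if not np.allclose(np.diff(times), dt, rtol=1e-6, atol=1e-9):
        raise PmfsurfError("frames must be uniformly spaced in time")
    span = times[-1] - times[0]
    if max_lag >= span:
        warnings.warn(
            f"max_lag {max_lag} ps >= window length {span} ps; truncating",
            stacklevel=2,
        )
        max_lag = span
    n_lags = int(round(max_lag / dt)) + 1
    pos = traj.oxygen[:, ids, :]  # (nf, n_sel, 3)
    nf, n_sel = pos.shape[:2]
    msd = np.zeros((n_lags, 3))
    n_pairs = np.zeros(n_lags, dtype=int)
    n_pairs[0] = nf * n_sel
    for k in range(1, n_lags):
        delta = pos[k:] - pos[:-k]
        msd[k] = np.mean(delta**2, axis=(0, 1))
        n_pairs[k] = (nf - k) * n_sel
    return MSDCurve(
        lag=dt * np.arange(n_lags),
        msd_x=msd[:, 0],
        msd_y=msd[:, 1],
        msd_z=msd[:, 2],
        n_pairs=n_pairs,
    )


def fit_diffusion(
    curve: MSDCurve,
    fit_window: tuple[float, float] | None = None,
    n_residents: int = 0,
) -> DiffusionResult:
    """Least-squares slope of MSD over the fit window; D = slope / 2.

    The default window is [25%, 50%] of the maximum lag — late enough for
    the ballistic/caging transient to have passed, early enough that many
    origin pairs still contribute. Negative fitted slopes (possible for
    fully wall-limited axes plus noise) are clamped to D = 0 with a warning.
    """
    max_lag = float(curve.lag[-1])
    if fit_window is None:
        fit_window = (0.25 * max_lag, 0.5 * max_lag)
    lo, hi = fit_window
    keep = (curve.lag >= lo) & (curve.lag <= hi)
    if keep.sum() < 3:
        raise PmfsurfError(f"fit window [{lo}, {hi}] ps contains fewer than 3 lags")
    lags = curve.lag[keep]
    Ds = []
    for series in (curve.msd_x, curve.msd_y, curve.msd_z):
        slope = float(np.polyfit(lags, series[keep], 1)[0])
        if slope < 0:
            warnings.warn("negative MSD slope clamped to D = 0", stacklevel=2)
            slope = 0.0
        Ds.append(slope / 2.0)
    return DiffusionResult(
        D_x=Ds[0], D_y=Ds[1], D_z=Ds[2], fit_window=(lo, hi), n_residents=n_residents
    )
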