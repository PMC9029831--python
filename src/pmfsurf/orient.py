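"""Orientation angles of gap water and Jacobian-corrected distributions.

Two angles describe a water molecule relative to the interface normal n̂
(the +x unit vector, pointing from the water phase toward the oil):

* θ ∈ [0°, 180°]: polar angle between the molecular dipole direction d̂ and
  n̂. θ = 90° means the dipole lies in the interface plane; θ > 90° tips the
  dipole back toward the water phase / crystal.
* φ ∈ [0°, 90°]: rotation about d̂, measured as the angle between the H→H
  vector and d̂ x n̂. φ = 0 means the H–H axis is parallel to the interface.
  Because the two hydrogens are interchangeable, φ is folded to [0°, 90°].

Raw θ counts carry the spherical sinθ measure: an isotropic sample piles up
near 90°. Dividing by the exact per-bin integral of sinθ removes it, so an
isotropic sample yields a flat corrected distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyDistributionError, GeometryError
from .trajectory import Trajectory

__all__ = [
    "OrientationAngles",
    "AngularDistribution",
    "water_vectors",
    "orientation_angles",
    "jacobian_corrected_hist",
    "phi_hist_conditional",
    "trajectory_orientation_angles",
]

#: interface normal: from the water phase toward the oil.
NORMAL = np.array([1.0, 0.0, 0.0])

_OH_MIN, _OH_MAX = 0.5, 1.5  # Å sanity window for covalent O-H
_POLE_TOL = 1e-12


@dataclass(frozen=True)
class OrientationAngles:
    """theta in [0, 180] degrees; phi in [0, 90] degrees or NaN at the poles."""

    theta: float
    phi: float

    @property
    def phi_defined(self) -> bool:
        return np.isfinite(self.phi)


@dataclass(frozen=True)
class AngularDistribution:
    """Normalized probability density per degree: sum(p) * bin width = 1."""

    bin_edges: np.ndarray
    probability: np.ndarray
    corrected: bool

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def _minimum_image(v: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return v
    return v - box * np.round(v / box)


def water_vectors(
    molecule: np.ndarray, box: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Unit dipole direction d̂ and unit H→H vector for one O,H,H molecule.

    The dipole is computed geometrically as the bisector from O through the
    midpoint of the two hydrogens — identical in direction to the charge
    dipole for any rigid symmetric 3-site water model. Intra-molecular
    vectors are minimum-imaged when a box is given, so molecules split
    across a periodic boundary are handled correctly.
    """
    molecule = np.asarray(molecule, dtype=float)
    if molecule.shape != (3, 3):
        raise GeometryError(f"molecule must be (3, 3) O,H,H coordinates, got {molecule.shape}")
    oh1 = _minimum_image(molecule[1] - molecule[0], box)
    oh2 = _minimum_image(molecule[2] - molecule[0], box)
    for oh in (oh1, oh2):
        r = np.linalg.norm(oh)
        if not (_OH_MIN <= r <= _OH_MAX):
            raise GeometryError(f"O-H distance {r:.3f} Å outside [{_OH_MIN}, {_OH_MAX}]")
    bisector = oh1 + oh2
    norm_b = np.linalg.norm(bisector)
    hh = oh2 - oh1
    norm_hh = np.linalg.norm(hh)
    if norm_b < 1e-9 or norm_hh < 1e-9:
        raise GeometryError("degenerate water geometry (collinear or coincident atoms)")
    return bisector / norm_b, hh / norm_hh


def orientation_angles(
    d: np.ndarray, r_hh: np.ndarray, n: np.ndarray = NORMAL
) -> OrientationAngles:
    """Angles (θ, φ) of one molecule; φ is NaN when d̂ is exactly at a pole."""
    d = np.asarray(d, dtype=float)
    r_hh = np.asarray(r_hh, dtype=float)
    n = np.asarray(n, dtype=float)
    theta = float(np.degrees(np.arccos(np.clip(np.dot(d, n), -1.0, 1.0))))
    u = np.cross(d, n)
    norm_u = np.linalg.norm(u)
    if norm_u < _POLE_TOL:
        return OrientationAngles(theta=theta, phi=float("nan"))
    cos_phi = abs(np.dot(r_hh, u) / norm_u)
    phi = float(np.degrees(np.arccos(np.clip(cos_phi, 0.0, 1.0))))
    return OrientationAngles(theta=theta, phi=phi)


def jacobian_corrected_hist(theta_samples, bins: int) -> AngularDistribution:
    """P(θ) with the sinθ Jacobian removed, normalized to unit integral.

    Counts in each bin are divided by the exact integral of sinθ over the
    bin, cos(lo) - cos(hi), which stays finite at the poles where the bin
    midpoint value of sinθ would vanish.
    """
    theta = np.asarray(theta_samples, dtype=float)
    theta = theta[np.isfinite(theta)]
    if theta.size == 0:
        raise EmptyDistributionError("no theta samples")
    if bins < 2:
        raise EmptyDistributionError("need at least 2 bins")
    edges = np.linspace(0.0, 180.0, bins + 1)
    counts, _ = np.histogram(theta, bins=edges)
    rad = np.deg2rad(edges)
    weights = np.cos(rad[:-1]) - np.cos(rad[1:])  # exact ∫ sinθ dθ per bin
    density = counts / weights
    width = edges[1] - edges[0]
    probability = density / (density.sum() * width)
    return AngularDistribution(bin_edges=edges, probability=probability, corrected=True)


def phi_hist_conditional(
    samples, theta_window: tuple[float, float], bins: int
) -> AngularDistribution:
    """Histogram of φ restricted to samples whose θ lies in ``theta_window``.

    No Jacobian correction: φ is a rotation about the dipole axis and its
    natural measure is uniform. Pole samples (φ undefined) are excluded.
    """
    theta = np.array([s.theta for s in samples], dtype=float)
    phi = np.array([s.phi for s in samples], dtype=float)
    lo, hi = theta_window
    keep = (theta >= lo) & (theta <= hi) & np.isfinite(phi)
    if not np.any(keep):
        raise EmptyDistributionError(f"no samples with theta in [{lo}, {hi}] degrees")
    edges = np.linspace(0.0, 90.0, bins + 1)
    counts, _ = np.histogram(phi[keep], bins=edges)
    width = edges[1] - edges[0]
    probability = counts / (counts.sum() * width)
    return AngularDistribution(bin_edges=edges, probability=probability, corrected=False)


def trajectory_orientation_angles(
    traj: Trajectory, slab: tuple[float, float] | None = None
) -> list[OrientationAngles]:
    """Pooled (θ, φ) samples over all frames and molecules, optionally
    restricted per frame to molecules whose oxygen x lies in ``slab``."""
    out = []
    for k in range(traj.n_frames):
        box = traj.boxes[k]
        for m in range(traj.n_molecules):
            if slab is not None:
                ox = traj.coords[k, m, 0, 0]
                if not (slab[0] <= ox <= slab[1]):
                    continue
            d, r_hh = water_vectors(traj.coords[k, m], box)
            out.append(orientation_angles(d, r_hh))
    return out
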