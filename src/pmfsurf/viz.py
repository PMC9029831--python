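"""Optional figure output. Numerical TSVs are the contract; these are side views."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .msd import MSDCurve
from .orient import AngularDistribution
from .pmf import FreeEnergySurface


def plot_surface(surface: FreeEnergySurface, path, contours: int = 20) -> None:
    """Filled contour map of F(x, θz)."""
    grid = surface.grid
    fig, ax = plt.subplots(figsize=(6, 4.5))
    mesh = ax.contourf(grid.x_nodes, grid.theta_nodes, surface.F.T, levels=contours)
    fig.colorbar(mesh, ax=ax, label="F [kcal/mol]")
    ax.set_xlabel("x [Å]")
    ax.set_ylabel(r"$\theta_z$ [deg]")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_msd(curve: MSDCurve, path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for series, label in ((curve.msd_x, "x"), (curve.msd_y, "y"), (curve.msd_z, "z")):
        ax.plot(curve.lag, series, label=label)
    ax.set_xlabel("lag [ps]")
    ax.set_ylabel(r"MSD [$\AA^2$]")
    ax.legend(title="axis")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_distribution(dist: AngularDistribution, path, xlabel: str = "angle [deg]") -> None:
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.stairs(dist.probability, dist.bin_edges, fill=True, alpha=0.6)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("probability density [1/deg]")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
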