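"""Water trajectory container and extended-XYZ I/O.

Frames hold O,H,H coordinates per molecule in an orthorhombic periodic box.
The extended-XYZ dialect used is the common one: per-frame comment line with
``Lattice="Lx 0 0 0 Ly 0 0 0 Lz" Properties=species:S:1:pos:R:3 Time=<ps>``
and one ``<species> x y z`` line per atom, molecules stored as consecutive
O,H,H triples in a stable order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .errors import FormatError, PmfsurfError

__all__ = ["Trajectory", "read_extxyz", "write_extxyz"]

_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')
_TIME_RE = re.compile(r"Time=([-+0-9.eE]+)")


@dataclass
class Trajectory:
    """times (nf,) in ps; boxes (nf, 3) in Å; coords (nf, n_mol, 3, 3) in Å.

    The third axis orders atoms as O, H, H. Molecule identity and ordering
    are stable across frames.
    """

    times: np.ndarray
    boxes: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        nf = self.times.size
        if self.boxes.shape != (nf, 3):
            raise PmfsurfError(f"boxes shape {self.boxes.shape} != ({nf}, 3)")
        if np.any(self.boxes <= 0):
            raise PmfsurfError("box lengths must be positive")
        if self.coords.ndim != 4 or self.coords.shape[0] != nf or self.coords.shape[2:] != (3, 3):
            raise PmfsurfError(
                f"coords shape {self.coords.shape} != (n_frames, n_molecules, 3, 3)"
            )

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def n_molecules(self) -> int:
        return self.coords.shape[1]

    @property
    def oxygen(self) -> np.ndarray:
        """Oxygen positions, shape (n_frames, n_molecules, 3)."""
        return self.coords[:, :, 0, :]


def write_extxyz(traj: Trajectory, path) -> None:
    with open(path, "w") as handle:
        n_atoms = 3 * traj.n_molecules
        for k in range(traj.n_frames):
            Lx, Ly, Lz = traj.boxes[k]
            handle.write(f"{n_atoms}\n")
            handle.write(
                f'Lattice="{Lx:.10g} 0.0 0.0 0.0 {Ly:.10g} 0.0 0.0 0.0 {Lz:.10g}" '
                f"Properties=species:S:1:pos:R:3 Time={traj.times[k]:.10g}\n"
            )
            frame = traj.coords[k].reshape(-1, 3)
            for a, (x, y, z) in enumerate(frame):
                species = "O" if a % 3 == 0 else "H"
                handle.write(f"{species} {x:.10f} {y:.10f} {z:.10f}\n")


def read_extxyz(path) -> Trajectory:
    """Read an extended-XYZ water trajectory (consecutive O,H,H triples)."""
    times, boxes, frames = [], [], []
    with open(path) as handle:
        lines = handle.read().splitlines()
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n_atoms = int(lines[pos].strip())
        except ValueError:
            raise FormatError(f"{path}: expected atom count at line {pos + 1}") from None
        comment = lines[pos + 1]
        lattice_match = _LATTICE_RE.search(comment)
        if not lattice_match:
            raise FormatError(f"{path}: frame at line {pos + 1} lacks a Lattice entry")
        lattice = np.fromstring(lattice_match.group(1), sep=" ").reshape(3, 3)
        if np.any(np.abs(lattice - np.diag(np.diag(lattice))) > 1e-9):
            raise FormatError(f"{path}: only orthorhombic boxes are supported")
        time_match = _TIME_RE.search(comment)
        times.append(float(time_match.group(1)) if time_match else float(len(times)))
        boxes.append(np.diag(lattice))
        if n_atoms % 3 != 0:
            raise FormatError(f"{path}: atom count {n_atoms} is not a multiple of 3")
        atoms = np.empty((n_atoms, 3))
        for a in range(n_atoms):
            parts = lines[pos + 2 + a].split()
            species = parts[0]
            expected = "O" if a % 3 == 0 else "H"
            if species != expected:
                raise FormatError(
                    f"{path}: atom {a} of frame {len(frames)} is {species!r}, "
                    f"expected {expected!r} (molecules must be O,H,H triples)"
                )
            atoms[a] = [float(v) for v in parts[1:4]]
        frames.append(atoms.reshape(-1, 3, 3))
        pos += 2 + n_atoms
    if not frames:
        raise FormatError(f"{path}: no frames")
    return Trajectory(
        times=np.array(times), boxes=np.array(boxes), coords=np.array(frames)
    )
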