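"""Trajectory container and plain-text I/O.

The native on-disk format is extended XYZ: one block per frame, with the
comment line carrying the box, periodicity and frame interval as key=value
pairs.  LAMMPS text dumps (orthogonal boxes) are supported read-only so
externally generated trajectories can replace the surrogate.  Coordinates
are stored wrapped; :func:`unwrap_positions` reconstructs continuous paths
for displacement analysis.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from os import PathLike
from typing import IO, Mapping, Union

import numpy as np

__all__ = [
    "Trajectory",
    "TrajectoryFormatError",
    "write_xyz",
    "read_xyz",
    "read_lammps_dump",
    "unwrap_positions",
]

Source = Union[str, PathLike, IO[str]]


class TrajectoryFormatError(ValueError):
    """Malformed or unsupported trajectory text."""


@dataclass
class Trajectory:
    """Time-ordered particle coordinates with species labels.

    ``positions`` has shape (n_frames, n_particles, 3) in angstrom; the
    particle order and labels are constant across frames;
    ``frame_interval`` is the time between recorded frames in ps.
    """

    positions: np.ndarray
    species_labels: list[str]
    box: tuple[float, float, float]
    periodic: tuple[bool, bool, bool] = (True, True, True)
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (frames, particles, 3)")
        if len(self.species_labels) != self.positions.shape[1]:
            raise ValueError("one species label per particle required")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    def select(self, species) -> np.ndarray:
        """Indices of particles whose label is in ``species`` (str or set)."""
        if isinstance(species, str):
            species = {species}
        idx = np.array([i for i, l in enumerate(self.species_labels)
                        if l in species], dtype=np.intp)
        if idx.size == 0:
            raise ValueError(f"species {sorted(species)} not present in trajectory")
        return idx


# --------------------------------------------------------------------------
# Extended XYZ
# --------------------------------------------------------------------------

def _open(source: Source, mode: str):
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    return open(source, mode), True


def write_xyz(traj: Trajectory, destination: Source) -> None:
    """Write an extended-XYZ file (6-decimal coordinates)."""
    fh, close = _open(destination, "w")
    try:
        lx, ly, lz = traj.box
        lattice = f"{lx:.6f} 0.0 0.0 0.0 {ly:.6f} 0.0 0.0 0.0 {lz:.6f}"
        pbc = " ".join("T" if p else "F" for p in traj.periodic)
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_particles}\n")
            fh.write(
                f'Lattice="{lattice}" Properties=species:S:1:pos:R:3 '
                f'pbc="{pbc}" frame_interval={traj.frame_interval:.9g}\n')
            for lab, (x, y, z) in zip(traj.species_labels, traj.positions[f]):
                fh.write(f"{lab} {x:.6f} {y:.6f} {z:.6f}\n")
    finally:
        if close:
            fh.close()


_KV = re.compile(r'(\w+)=(?:"([^"]*)"|(\S+))')


def _parse_comment(line: str) -> dict[str, str]:
    return {m.group(1): m.group(2) if m.group(2) is not None else m.group(3)
            for m in _KV.finditer(line)}


def read_xyz(source: Source) -> Trajectory:
    """Read an (extended) XYZ file written by this package or a third party.

    The first four whitespace-separated columns of each atom line are used
    (label x y z); extra per-atom columns are ignored.  The box is taken
    from a diagonal ``Lattice``; ``pbc`` and ``frame_interval`` keys are
    honoured when present.
    """
    fh, close = _open(source, "r")
    try:
        frames: list[np.ndarray] = []
        labels: list[str] | None = None
        box = None
        periodic = (True, True, True)
        interval = 1.0
        lineno = 0
        frameno = 0
        while True:
            header = fh.readline()
            lineno += 1
            if not header.strip():
                if header == "":
                    break
                continue
            frameno += 1
            try:
                nat = int(header.split()[0])
            except ValueError:
                raise TrajectoryFormatError(
                    f"line {lineno}: expected an atom count, got {header!r}")
            comment = fh.readline()
            lineno += 1
            kv = _parse_comment(comment)
            if "Lattice" in kv:
                vals = [float(v) for v in kv["Lattice"].split()]
                if len(vals) != 9:
                    raise TrajectoryFormatError(
                        f"frame {frameno}: Lattice must have 9 components")
                off = [vals[i] for i in (1, 2, 3, 5, 6, 7)]
                if any(abs(v) > 1e-9 for v in off):
                    raise TrajectoryFormatError(
                        f"frame {frameno}: non-orthogonal Lattice unsupported")
                box = (vals[0], vals[4], vals[8])
            if "pbc" in kv:
                periodic = tuple(t.upper().startswith("T")
                                 for t in kv["pbc"].split())
            if "frame_interval" in kv:
                interval = float(kv["frame_interval"])
            flabels = []
            coords = np.empty((nat, 3))
            for i in range(nat):
                line = fh.readline()
                lineno += 1
                parts = line.split()
                if len(parts) < 4:
                    raise TrajectoryFormatError(
                        f"frame {frameno}, line {lineno}: expected "
                        f"'label x y z', got {line!r}")
                flabels.append(parts[0])
                try:
                    coords[i] = [float(parts[1]), float(parts[2]),
                                 float(parts[3])]
                except ValueError:
                    raise TrajectoryFormatError(
                        f"frame {frameno}, line {lineno}: unparsable "
                        f"coordinate in {line!r}")
            if labels is None:
                labels = flabels
            elif flabels != labels:
                raise TrajectoryFormatError(
                    f"frame {frameno}: atom count or labels differ from frame 1")
            frames.append(coords)
        if not frames:
            raise TrajectoryFormatError("no frames found")
        if box is None:
            mx = np.max([f.max(axis=0) for f in frames], axis=0)
            box = tuple(float(v) for v in mx)
        return Trajectory(np.stack(frames), labels, box, periodic, interval)
    finally:
        if close:
            fh.close()


# --------------------------------------------------------------------------
# LAMMPS dump (text, orthogonal boxes)
# --------------------------------------------------------------------------

def read_lammps_dump(source: Source, label_map: Mapping[int, str],
                     frame_interval: float = 1.0) -> Trajectory:
    """Read a LAMMPS text dump with ``id type`` and ``x y z`` or ``xs ys zs``.

    Atoms are reordered by id; scaled coordinates are unscaled by the box;
    integer types are mapped to labels through ``label_map``.  Triclinic
    boxes and missing columns raise :class:`TrajectoryFormatError`.
    """
    fh, close = _open(source, "r")
    try:
        frames = []
        labels_ref = None
        box = None
        periodic = (True, True, True)
        line = fh.readline()
        while line:
            if not line.startswith("ITEM: TIMESTEP"):
                line = fh.readline()
                continue
            fh.readline()  # timestep value
            item = fh.readline()
            if "NUMBER OF ATOMS" not in item:
                raise TrajectoryFormatError("expected ITEM: NUMBER OF ATOMS")
            nat = int(fh.readline())
            item = fh.readline()
            if "BOX BOUNDS" not in item:
                raise TrajectoryFormatError("expected ITEM: BOX BOUNDS")
            if "xy" in item or "xz" in item or "yz" in item:
                raise TrajectoryFormatError("triclinic boxes are unsupported")
            flags = item.split()[3:6]
            if len(flags) == 3:
                periodic = tuple(f.startswith("pp") for f in flags)
            lo = np.empty(3)
            hi = np.empty(3)
            for k in range(3):
                parts = fh.readline().split()
                lo[k], hi[k] = float(parts[0]), float(parts[1])
            box = tuple(float(h - l) for l, h in zip(lo, hi))
            item = fh.readline()
            if not item.startswith("ITEM: ATOMS"):
                raise TrajectoryFormatError("expected ITEM: ATOMS")
            cols = item.split()[2:]
            try:
                c_id = cols.index("id")
                c_type = cols.index("type")
            except ValueError:
                raise TrajectoryFormatError("dump must contain id and type columns")
            scaled = False
            if all(c in cols for c in ("x", "y", "z")):
                cxyz = [cols.index(c) for c in ("x", "y", "z")]
            elif all(c in cols for c in ("xs", "ys", "zs")):
                cxyz = [cols.index(c) for c in ("xs", "ys", "zs")]
                scaled = True
            else:
                raise TrajectoryFormatError(
                    "dump must contain x y z or xs ys zs columns")
            ids = np.empty(nat, dtype=np.int64)
            types = np.empty(nat, dtype=np.int64)
            coords = np.empty((nat, 3))
            for i in range(nat):
                parts = fh.readline().split()
                if len(parts) < len(cols):
                    raise TrajectoryFormatError(
                        f"truncated atom line in dump (atom {i + 1})")
                ids[i] = int(parts[c_id])
                types[i] = int(parts[c_type])
                coords[i] = [float(parts[c]) for c in cxyz]
            order = np.argsort(ids, kind="stable")
            types = types[order]
            coords = coords[order]
            if scaled:
                coords = lo + coords * (hi - lo)
            try:
                labels = [label_map[int(t)] for t in types]
            except KeyError as exc:
                raise TrajectoryFormatError(f"atom type {exc} missing from label_map")
            if labels_ref is None:
                labels_ref = labels
            elif labels != labels_ref:
                raise TrajectoryFormatError("atom identities differ across frames")
            frames.append(coords)
            line = fh.readline()
        if not frames:
            raise TrajectoryFormatError("no frames found in dump")
        return Trajectory(np.stack(frames), labels_ref, box, periodic,
                          frame_interval)
    finally:
        if close:
            fh.close()


def unwrap_positions(traj: Trajectory) -> np.ndarray:
    """Continuous (unwrapped) coordinates via cumulative minimum-image steps.

    Valid while per-frame displacements stay below half the box length.
    """
    box = np.asarray(traj.box)
    d = np.diff(traj.positions, axis=0)
    for k in range(3):
        if traj.periodic[k]:
            d[..., k] -= box[k] * np.round(d[..., k] / box[k])
    out = np.empty_like(traj.positions)
    out[0] = traj.positions[0]
    np.cumsum(d, axis=0, out=d)
    out[1:] = traj.positions[0] + d
    return out
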