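"""Spatial observables: binned number densities and potential-energy maps.

Binning convention (shared bit-for-bit with :mod:`ionmdmc.markov`): bins
are half-open ``[edge, edge + bin)`` anchored at coordinate 0, with index
``floor(x / bin)``; the final bin absorbs the box remainder.  2D fields are
stored row-major with the first listed axis slowest.

"Accumulated" and "time-averaged" densities are the same visit counts under
different normalization: totals over all frames, or divided by the frame
count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .system import SystemModel
from .trajectory import Trajectory

__all__ = [
    "DensityField",
    "EnergyField",
    "FieldComparison",
    "grid_edges",
    "bin_indices",
    "density",
    "potential_energy_map",
    "compare_fields",
]


def grid_edges(length: float, bin_size: float) -> np.ndarray:
    """Bin edges covering [0, length) with the final bin closed."""
    n = int(np.ceil(length / bin_size - 1e-12))
    return np.arange(n + 1) * bin_size


def bin_indices(coords: np.ndarray, bin_size: float, n_bins: int) -> np.ndarray:
    """floor(x / bin), clipped into the final (closed) bin."""
    idx = np.floor(coords / bin_size).astype(np.int64)
    return np.minimum(idx, n_bins - 1)


@dataclass
class DensityField:
    """Binned occupancy of one species set along one or two axes."""

    axes: tuple[int, ...]
    bin_size: float
    edges: tuple[np.ndarray, ...]
    values: np.ndarray
    mode: str                       # "accumulated" | "time_averaged"
    species: Optional[str] = None

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def normalized(self) -> np.ndarray:
        total = self.values.sum()
        if total == 0:
            raise ValueError("cannot normalize an empty field")
        return self.values / total

    def to_csv(self, destination) -> None:
        """Edge/value columns (2D fields flattened row-major)."""
        import csv
        close = False
        fh = destination
        if not hasattr(fh, "write"):
            fh = open(fh, "w", newline="")
            close = True
        try:
            w = csv.writer(fh)
            if len(self.axes) == 1:
                w.writerow([f"edge_axis{self.axes[0]}", "value"])
                for e, v in zip(self.edges[0][:-1], self.values):
                    w.writerow([f"{e:.6g}", f"{v:.10g}"])
            else:
                w.writerow([f"edge_axis{self.axes[0]}",
                            f"edge_axis{self.axes[1]}", "value"])
                for i, e0 in enumerate(self.edges[0][:-1]):
                    for j, e1 in enumerate(self.edges[1][:-1]):
                        w.writerow([f"{e0:.6g}", f"{e1:.6g}",
                                    f"{self.values[i, j]:.10g}"])
        finally:
            if close:
                fh.close()


@dataclass
class EnergyField:
    """Per-bin mean potential energy of the occupying particles.

    Bins never visited hold NaN in ``values`` and 0 in ``occupancy`` --
    empty, not zero-energy.
    """

    axes: tuple[int, ...]
    bin_size: float
    edges: tuple[np.ndarray, ...]
    values: np.ndarray
    occupancy: np.ndarray
    species: Optional[str] = None

    @property
    def empty_mask(self) -> np.ndarray:
        return self.occupancy == 0


@dataclass
class FieldComparison:
    """Signed per-bin difference plus summary scalars."""

    diff: np.ndarray   # a - b, raw values
    l1: float          # L1 distance after normalizing each field to sum 1
    rmse: float        # root-mean-square of the raw differences


def _resolve_axes(axes) -> tuple[int, ...]:
    if isinstance(axes, int):
        axes = (axes,)
    axes = tuple(int(a) for a in axes)
    if not 1 <= len(axes) <= 2 or any(a not in (0, 1, 2) for a in axes):
        raise ValueError("axes must be one or two of {0, 1, 2}")
    if len(set(axes)) != len(axes):
        raise ValueError("axes must be distinct")
    return axes


def density(traj: Trajectory, species, axes, bin_size: float = 0.5,
            mode: str = "accumulated") -> DensityField:
    """Count particle visits per spatial bin over all frames.

    ``mode='time_averaged'`` divides the counts by the number of frames, so
    the field sums to the mean per-frame particle count of the species;
    ``mode='accumulated'`` keeps raw totals (count x n_frames).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    if mode not in ("accumulated", "time_averaged"):
        raise ValueError("mode must be 'accumulated' or 'time_averaged'")
    axes = _resolve_axes(axes)
    idx = traj.select(species)
    edges = tuple(grid_edges(traj.box[a], bin_size) for a in axes)
    nb = tuple(len(e) - 1 for e in edges)
    coords = traj.positions[:, idx, :]
    flat = np.zeros(1, dtype=np.int64)
    for a, n in zip(axes, nb):
        flat = flat * n + bin_indices(coords[..., a].ravel(), bin_size, n)
    counts = np.bincount(flat, minlength=int(np.prod(nb))).astype(float)
    values = counts.reshape(nb)
    if mode == "time_averaged":
        values = values / traj.n_frames
    name = species if isinstance(species, str) else ",".join(sorted(species))
    return DensityField(axes, bin_size, edges, values, mode, name)


def potential_energy_map(traj: Trajectory, system: SystemModel, species,
                         axes, bin_size: float = 0.5) -> EnergyField:
    """Bin-averaged instantaneous potential energy of a species.

    Every occupying particle contributes its external energy plus half of
    its pair sums (surrogate re-scoring for imported trajectories); the
    field holds the per-bin mean over all frames.
    """
    from .dynamics import per_particle_energies
    from .system import Configuration

    axes = _resolve_axes(axes)
    idx = traj.select(species)
    edges = tuple(grid_edges(traj.box[a], bin_size) for a in axes)
    nb = tuple(len(e) - 1 for e in edges)
    size = int(np.prod(nb))
    esum = np.zeros(size)
    occ = np.zeros(size, dtype=np.int64)
    for f in range(traj.n_frames):
        cfg = Configuration(traj.positions[f].copy(), traj.species_labels,
                            traj.box)
        en = per_particle_energies(cfg, system)[idx]
        coords = traj.positions[f, idx, :]
        flat = np.zeros(len(idx), dtype=np.int64)
        for a, n in zip(axes, nb):
            flat = flat * n + bin_indices(coords[:, a], bin_size, n)
        np.add.at(esum, flat, en)
        np.add.at(occ, flat, 1)
    with np.errstate(invalid="ignore"):
        values = np.where(occ > 0, esum / np.maximum(occ, 1), np.nan)
    name = species if isinstance(species, str) else ",".join(sorted(species))
    return EnergyField(axes, bin_size, edges, values.reshape(nb),
                       occ.reshape(nb), name)


def compare_fields(a: DensityField, b: DensityField) -> FieldComparison:
    """Per-bin signed difference map plus L1 (of normalized fields) and RMSE."""
    if a.axes != b.axes or a.mode != b.mode or a.shape != b.shape:
        raise ValueError("fields have mismatched axes, mode or binning")
    for ea, eb in zip(a.edges, b.edges):
        if ea.shape != eb.shape or not np.allclose(ea, eb):
            raise ValueError("fields have mismatched bin edges")
    diff = a.values - b.values
    l1 = float(np.abs(a.normalized() - b.normalized()).sum())
    rmse = float(np.sqrt(np.mean(diff ** 2)))
    return FieldComparison(diff, l1, rmse)
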