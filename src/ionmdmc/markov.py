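"""The MDMC core: spatial-state discretization, transition-matrix
estimation and Monte Carlo chain sampling.

A trajectory is discretized on a grid of spatial cells (the states, 0.5 A
mesh by default); ordered state pairs at a fixed lag are counted into an
N x N matrix, which row-normalizes into the probability transition matrix.
Chains sampled from that matrix reproduce the occupancy statistics (and,
through run lengths, residence times) of the source trajectory.  Particles
of one species are pooled into a single single-particle chain; interactions
enter only through the empirical statistics.

State indexing matches :mod:`ionmdmc.fields` bit-for-bit (half-open bins
anchored at 0, row-major with the first axis slowest), so chain occupancies
and trajectory densities compare cell by cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

from . import _kernels as K
from .fields import DensityField, bin_indices, grid_edges
from .trajectory import Trajectory

__all__ = [
    "StateGrid",
    "TransitionCounts",
    "TransitionMatrix",
    "MarkovChain",
    "assign_states",
    "count_transitions",
    "estimate_matrix",
    "run_mc",
    "stationary_distribution",
    "chain_occupancy",
    "save_matrix",
    "load_matrix",
]


@dataclass(frozen=True)
class StateGrid:
    """Spatial discretization of the box on a subset of axes."""

    axes: tuple[int, ...]
    bin_size: float
    box: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be > 0")
        if not 1 <= len(self.axes) <= 3 or len(set(self.axes)) != len(self.axes):
            raise ValueError("axes must be a distinct subset of {0, 1, 2}")

    @property
    def edges(self) -> tuple[np.ndarray, ...]:
        return tuple(grid_edges(self.box[a], self.bin_size) for a in self.axes)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(e) - 1 for e in self.edges)

    @property
    def n_states(self) -> int:
        return int(np.prod(self.shape))

    def state_of(self, coords: np.ndarray) -> np.ndarray:
        """Map (..., 3) wrapped coordinates to flat state indices."""
        coords = np.asarray(coords)
        box = np.asarray(self.box)
        for a in self.axes:
            c = coords[..., a]
            if np.any(c < 0) or np.any(c >= box[a] + self.bin_size):
                raise ValueError(
                    f"coordinate outside box on axis {a}; wrap positions first")
        flat = np.zeros(coords.shape[:-1], dtype=np.int64)
        for a, n in zip(self.axes, self.shape):
            flat = flat * n + bin_indices(coords[..., a], self.bin_size, n)
        return flat

    def unravel(self, states: np.ndarray) -> tuple[np.ndarray, ...]:
        return np.unravel_index(np.asarray(states), self.shape)


@dataclass
class TransitionCounts:
    grid: StateGrid
    lag: int
    counts: sp.csr_matrix           # N x N nonnegative integers
    species: Optional[str] = None

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class TransitionMatrix:
    """Row-stochastic N x N matrix over the grid states.

    ``visited`` flags states observed as sources; under the ``restrict``
    policy ``active`` holds the original indices of the retained states and
    the matrix is compacted to them.
    """

    grid: StateGrid
    lag: int
    probabilities: sp.csr_matrix
    visited: np.ndarray
    active: Optional[np.ndarray] = None
    species: Optional[str] = None

    @property
    def n(self) -> int:
        return self.probabilities.shape[0]

    def row_sum_error(self) -> float:
        rs = np.asarray(self.probabilities.sum(axis=1)).ravel()
        return float(np.max(np.abs(rs - 1.0)))


@dataclass
class MarkovChain:
    """A sampled state sequence; one step spans frame_interval x lag."""

    states: np.ndarray
    step_time: float
    seed: Optional[int] = None

    @property
    def n_steps(self) -> int:
        return len(self.states) - 1


def assign_states(traj: Trajectory, grid: StateGrid,
                  species=None) -> np.ndarray:
    """Per-particle state sequences, shape (n_selected, n_frames)."""
    for a in grid.axes:
        if grid.box[a] < traj.box[a] - 1e-9:
            raise ValueError("grid does not cover the trajectory box")
    if species is None:
        idx = np.arange(traj.n_particles)
    else:
        idx = traj.select(species)
    seq = grid.state_of(traj.positions[:, idx, :])   # (F, P)
    return np.ascontiguousarray(seq.T)


def count_transitions(sequences: np.ndarray, grid: StateGrid, lag: int = 1,
                      species: Optional[str] = None) -> TransitionCounts:
    """Pool ordered (state_t, state_{t+lag}) pairs over all particles."""
    seq = np.atleast_2d(np.asarray(sequences, dtype=np.int64))
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if seq.shape[1] <= lag:
        raise ValueError("sequences shorter than lag + 1")
    i = seq[:, :-lag].ravel()
    j = seq[:, lag:].ravel()
    n = grid.n_states
    counts = sp.coo_matrix(
        (np.ones(i.size, dtype=np.int64), (i, j)), shape=(n, n)).tocsr()
    counts.sum_duplicates()
    return TransitionCounts(grid, lag, counts, species)


def estimate_matrix(counts: TransitionCounts,
                    empty_policy: str = "self_loop") -> TransitionMatrix:
    """Row-normalize transition counts into a stochastic matrix.

    Unvisited source states get a unit diagonal entry (``self_loop``,
    preserves the grid geometry) or are removed with compacted indices
    (``restrict``).
    """
    c = counts.counts.tocsr().astype(float)
    row_sums = np.asarray(c.sum(axis=1)).ravel()
    visited = row_sums > 0
    if not visited.any():
        raise ValueError("all-zero count matrix")
    if empty_policy == "self_loop":
        inv = np.zeros_like(row_sums)
        inv[visited] = 1.0 / row_sums[visited]
        probs = sp.diags(inv) @ c
        probs = (probs + sp.diags((~visited).astype(float))).tocsr()
        active = None
    elif empty_policy == "restrict":
        active = np.flatnonzero(visited)
        sub = c[active][:, active]
        rs = np.asarray(sub.sum(axis=1)).ravel()
        dead = rs == 0  # rows whose mass pointed only at removed states
        rs[dead] = 1.0
        probs = (sp.diags(1.0 / rs) @ sub).tocsr()
        if dead.any():
            probs = (probs + sp.diags(dead.astype(float))).tocsr()
        visited = np.ones(active.size, dtype=bool)
    else:
        raise ValueError("empty_policy must be 'self_loop' or 'restrict'")
    probs.sort_indices()
    return TransitionMatrix(counts.grid, counts.lag, probs, visited, active,
                            counts.species)


def run_mc(T: TransitionMatrix, n_steps: int, initial, seed: int,
           step_time: Optional[float] = None) -> MarkovChain:
    """Sample a Monte Carlo chain of ``n_steps`` transitions from ``T``.

    ``initial`` is a state index or a probability vector over states; with
    a ``restrict``-policy matrix, state indices refer to the original grid
    and must be active.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    P = T.probabilities
    if np.isscalar(initial):
        s0 = int(initial)
        if T.active is not None:
            pos = np.searchsorted(T.active, s0)
            if pos >= T.active.size or T.active[pos] != s0:
                raise ValueError(f"initial state {s0} was removed by the "
                                 "restrict policy")
            s0 = int(pos)
        if not 0 <= s0 < T.n:
            raise ValueError("initial state out of range")
    else:
        p0 = np.asarray(initial, dtype=float)
        if T.active is not None and p0.size != T.n:
            p0 = p0[T.active]
        p0 = p0 / p0.sum()
        s0 = int(rng.choice(p0.size, p=p0))

    # per-row cumulative probabilities for inverse-CDF sampling
    cum = P.data.copy()
    for r in range(T.n):
        lo, hi = P.indptr[r], P.indptr[r + 1]
        np.cumsum(cum[lo:hi], out=cum[lo:hi])
        if hi > lo:
            cum[hi - 1] = 1.0 + 1e-15  # guard against roundoff at the tail
    out = np.empty(n_steps + 1, dtype=np.int64)
    rands = rng.random(n_steps)
    K.sample_chain(P.indptr, P.indices, cum, s0, rands, out)
    if T.active is not None:
        out = T.active[out]
    if step_time is None:
        step_time = float(T.lag)
    return MarkovChain(out, step_time, seed)


def stationary_distribution(T: TransitionMatrix, tol: float = 1e-12,
                            max_iter: int = 1_000_000) -> np.ndarray:
    """Left fixed vector pi = pi P with sum 1, by damped power iteration.

    The iteration mixes half the identity into each step, which leaves the
    fixed point unchanged but converges on periodic chains.  On reducible
    chains this returns the distribution reached from uniform mass on the
    visited states.
    """
    P = T.probabilities
    pi = np.asarray(T.visited, dtype=float)
    pi /= pi.sum()
    for _ in range(max_iter):
        nxt = 0.5 * pi + 0.5 * (P.T @ pi)
        delta = np.abs(nxt - pi).sum()
        pi = nxt
        if delta < tol:
            pi = pi / pi.sum()
            return pi
    raise RuntimeError("power iteration failed to converge")


def chain_occupancy(chain: MarkovChain, grid: StateGrid) -> DensityField:
    """Visit counts of a chain mapped back to spatial bins (accumulated
    mode, layout-compatible with trajectory densities)."""
    counts = np.bincount(chain.states, minlength=grid.n_states).astype(float)
    return DensityField(grid.axes, grid.bin_size, grid.edges,
                        counts.reshape(grid.shape), "accumulated")


# --------------------------------------------------------------------------
# Sparse-triplet persistence
# --------------------------------------------------------------------------

def save_matrix(T: TransitionMatrix, destination) -> None:
    """Persist as text triplets ``i j probability`` with a metadata header."""
    close = False
    fh = destination
    if not hasattr(fh, "write"):
        fh = open(fh, "w")
        close = True
    try:
        g = T.grid
        fh.write(f"# axes={','.join(map(str, g.axes))} bin_size={g.bin_size:.9g} "
                 f"box={','.join(f'{b:.9g}' for b in g.box)} lag={T.lag} "
                 f"species={T.species or '-'} n={T.n}\n")
        if T.active is not None:
            fh.write("# active=" + ",".join(map(str, T.active)) + "\n")
        coo = T.probabilities.tocoo()
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i} {j} {v:.17g}\n")
    finally:
        if close:
            fh.close()


def load_matrix(source) -> TransitionMatrix:
    close = False
    fh = source
    if not hasattr(fh, "read"):
        fh = open(fh)
        close = True
    try:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError("matrix file must start with a metadata header")
        kv = dict(tok.split("=", 1) for tok in header[1:].split())
        axes = tuple(int(a) for a in kv["axes"].split(","))
        box = tuple(float(b) for b in kv["box"].split(","))
        grid = StateGrid(axes, float(kv["bin_size"]), box)
        lag = int(kv["lag"])
        species = None if kv.get("species") in (None, "-") else kv["species"]
        n = int(kv["n"])
        active = None
        pos = fh.tell()
        line = fh.readline()
        if line.startswith("# active="):
            active = np.array([int(x) for x in line.split("=", 1)[1].split(",")],
                              dtype=np.int64)
        else:
            fh.seek(pos)
        rows, cols, vals = [], [], []
        for line in fh:
            if not line.strip():
                continue
            i, j, v = line.split()
            rows.append(int(i))
            cols.append(int(j))
            vals.append(float(v))
        probs = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
        visited = np.asarray(probs.sum(axis=1)).ravel() > 0
        return TransitionMatrix(grid, lag, probs, visited, active, species)
    finally:
        if close:
            fh.close()
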