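"""Overdamped-Langevin trajectory generator with an implicit membrane.

The integrator is the Euler-Maruyama discretization of position Langevin
dynamics,

    dx = F/gamma dt + sqrt(2 kB T dt / gamma) xi,

whose stationary law is the Boltzmann distribution of the total potential.
The potential is a truncated pair term (Lennard-Jones 9-6 by default plus a
screened Coulomb) and an external membrane term: a repulsive slab outside
the pore cylinder, an in-pore confinement barrier, gaussian entrance wells
at the pore mouths, and the species-selective electric-field ramp.

Unlike-species Lennard-Jones parameters follow the Waldman-Hagler
combining rules.  The default friction (24.94 kJ/mol ps/A^2) sets the free
diffusion coefficient to kB*300K/gamma = 0.1 A^2/ps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from .system import (Configuration, SpeciesSpec, SystemModel,
                     build_initial_configuration, simulation_species,
                     WATER_SITE)
from .trajectory import Trajectory
from .units import COULOMB, EV_PER_ANG, KB

__all__ = [
    "SimParams",
    "combine_lj",
    "pair_energy",
    "external_potential",
    "total_forces",
    "total_potential_energy",
    "per_particle_energies",
    "run_simulation",
    "simulate_harmonic_1d",
    "DEFAULT_FRICTION",
]

#: kJ/mol ps / A^2; gives D = kB*300/gamma = 0.1 A^2/ps for a free particle.
DEFAULT_FRICTION = KB * 300.0 / 0.1


@dataclass(frozen=True)
class SimParams:
    """Integrator settings.  ``dt`` in ps, ``friction`` in kJ/mol ps/A^2."""

    n_steps: int
    dt: float = 0.005
    friction: float = DEFAULT_FRICTION
    temperature: float = 300.0
    record_every: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.friction <= 0:
            raise ValueError("dt and friction must be > 0")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")


def combine_lj(eps_i: float, sigma_i: float, eps_j: float, sigma_j: float
               ) -> tuple[float, float]:
    """Waldman-Hagler combining rules for unlike Lennard-Jones pairs.

    sigma_ij = ((sigma_i^6 + sigma_j^6)/2)^(1/6),
    eps_ij   = 2 sqrt(eps_i eps_j) sigma_i^3 sigma_j^3 / (sigma_i^6 + sigma_j^6).

    Unit-agnostic; epsilons may be zero (ideal particles) but sigmas must be
    positive.
    """
    if sigma_i <= 0 or sigma_j <= 0 or eps_i < 0 or eps_j < 0:
        raise ValueError("sigmas must be > 0 and epsilons >= 0")
    s_i6 = sigma_i ** 6
    s_j6 = sigma_j ** 6
    sigma_ij = ((s_i6 + s_j6) / 2.0) ** (1.0 / 6.0)
    eps_ij = 2.0 * math.sqrt(eps_i * eps_j) * (sigma_i ** 3) * (sigma_j ** 3) / (s_i6 + s_j6)
    return eps_ij, sigma_ij


def pair_energy(r: float, eps_ij: float, sigma_ij: float, q_i: float,
                q_j: float, screening_length: float = 5.0,
                cutoff: float = 12.0, lj_form: str = "9-6",
                dielectric: float = 10.0):
    """Pair potential at separation ``r`` (A), in kJ/mol.

    LJ 9-6: eps (2 (s/r)^9 - 3 (s/r)^6), minimum -eps at r = sigma.
    LJ 12-6: the standard 4 eps ((s/r)^12 - (s/r)^6) form.
    Coulomb: C q_i q_j exp(-r/lambda) / (eps_r r).
    Exactly zero at and beyond the cutoff.  Vectorized over ``r``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair separation must be > 0")
    s = sigma_ij / r
    s6 = s ** 6
    if lj_form == "9-6":
        lj = eps_ij * (2.0 * s6 ** 1.5 - 3.0 * s6)
    elif lj_form == "12-6":
        lj = 4.0 * eps_ij * (s6 ** 2 - s6)
    else:
        raise ValueError("lj_form must be '9-6' or '12-6'")
    coul = COULOMB / dielectric * q_i * q_j * np.exp(-r / screening_length) / r
    e = np.where(r < cutoff, lj + coul, 0.0)
    return float(e) if e.ndim == 0 else e


# --------------------------------------------------------------------------
# System -> kernel tables
# --------------------------------------------------------------------------

def _ext_params(system: SystemModel) -> np.ndarray:
    g = system.geometry
    if g.channel_axis != 2:
        raise NotImplementedError("kernels assume the channel along z (axis 2)")
    ext = np.zeros(K.EXT_SIZE)
    ext[K.EXT_ZLO] = g.slab_lo
    ext[K.EXT_ZHI] = g.slab_hi
    ext[K.EXT_WZ] = g.wall_edge_width
    ext[K.EXT_WB] = g.barrier_edge_width
    ext[K.EXT_CX], ext[K.EXT_CY] = g.pore_center
    ext[K.EXT_RPORE] = g.pore_radius
    ext[K.EXT_WR] = g.pore_edge_width
    ext[K.EXT_WALLH] = g.wall_height
    wells = list(g.entrance_well_positions)[:2]
    ext[K.EXT_NWELL] = len(wells)
    for i, off in enumerate(wells):
        ext[K.EXT_WELL_Z1 + i] = g.slab_center + off
    ext[K.EXT_WELL_S] = g.well_width
    ext[K.EXT_RWELL] = g.well_radius
    ext[K.EXT_WRW] = g.well_radius_width
    fa, fb = system.field.resolved_region(g)
    ext[K.EXT_FA] = fa
    ext[K.EXT_FB] = fb
    ext[K.EXT_BOFF] = g.barrier_offset
    ext[K.EXT_FUNNEL] = g.funnel_length
    return ext


class _Tables:
    """Per-species kernel tables derived from a SystemModel."""

    def __init__(self, system: SystemModel):
        sim = simulation_species(system)
        self.labels = [sp.label for sp in sim]
        self.index = {lab: i for i, lab in enumerate(self.labels)}
        ns = len(sim)
        self.eps = np.zeros((ns, ns))
        self.sig6 = np.zeros((ns, ns))
        self.qq = np.zeros((ns, ns))
        pref = COULOMB / system.dielectric
        for i, a in enumerate(sim):
            for j, b in enumerate(sim):
                e, s = combine_lj(a.epsilon, a.sigma, b.epsilon, b.sigma)
                pair = {a.label, b.label}
                if pair == {"Na+", WATER_SITE}:
                    e *= system.na_water_polarity
                self.eps[i, j] = e
                self.sig6[i, j] = s ** 6
                self.qq[i, j] = pref * a.charge * b.charge
        g = system.geometry

        def _bfac(sp):
            if sp.is_water:
                return g.water_barrier_factor
            if sp.charge < 0:
                return g.anion_barrier_factor
            return 1.0

        self.barrier = np.array([g.channel_barrier * _bfac(sp) for sp in sim])
        self.well = np.array([
            g.entrance_well_depth * (1.0 if sp.is_water else g.ion_well_factor)
            for sp in sim])
        fmag = system.field.gradient * EV_PER_ANG * system.field.direction
        self.qf = np.array([
            sp.charge * fmag if sp.label in system.field.acts_on else 0.0
            for sp in sim])
        self.ext = _ext_params(system)
        # a zero cutoff disables the pair machinery entirely (ideal gas)
        interacting = np.any(self.eps != 0.0) or np.any(self.qq != 0.0)
        self.cutoff2 = system.cutoff ** 2 if interacting else 0.0
        self.lam = system.screening_length
        self.lj_form = K.LJ_9_6 if system.lj_form == "9-6" else K.LJ_12_6

    def species_index(self, labels) -> np.ndarray:
        try:
            return np.array([self.index[l] for l in labels], dtype=np.int32)
        except KeyError as exc:
            raise KeyError(f"label {exc} not a mobile species of this system")


def external_potential(position, species: SpeciesSpec | str,
                       geometry, field) -> float:
    """External (membrane + field) potential for one particle, kJ/mol.

    ``species`` may be a SpeciesSpec or a simulated-particle label
    ('Na+', 'Cl-', 'W').  Water-class species see the full entrance-well
    depth and the reduced confinement barrier.
    """
    if isinstance(species, SpeciesSpec):
        label = WATER_SITE if species.name == "O_water" else species.name
        charge = 0.0 if species.name == "O_water" else species.charge
    else:
        label = species
        charge = {"Na+": 1.0, "Cl-": -1.0}.get(label, 0.0)
    is_water = label == WATER_SITE

    g = geometry
    ext = np.zeros(K.EXT_SIZE)
    ext[K.EXT_ZLO] = g.slab_lo
    ext[K.EXT_ZHI] = g.slab_hi
    ext[K.EXT_WZ] = g.wall_edge_width
    ext[K.EXT_WB] = g.barrier_edge_width
    ext[K.EXT_CX], ext[K.EXT_CY] = g.pore_center
    ext[K.EXT_RPORE] = g.pore_radius
    ext[K.EXT_WR] = g.pore_edge_width
    ext[K.EXT_WALLH] = g.wall_height
    wells = list(g.entrance_well_positions)[:2]
    ext[K.EXT_NWELL] = len(wells)
    for i, off in enumerate(wells):
        ext[K.EXT_WELL_Z1 + i] = g.slab_center + off
    ext[K.EXT_WELL_S] = g.well_width
    ext[K.EXT_RWELL] = g.well_radius
    ext[K.EXT_WRW] = g.well_radius_width
    fa, fb = field.resolved_region(g)
    ext[K.EXT_FA] = fa
    ext[K.EXT_FB] = fb
    ext[K.EXT_BOFF] = g.barrier_offset
    ext[K.EXT_FUNNEL] = g.funnel_length

    bfac = (g.water_barrier_factor if is_water
            else g.anion_barrier_factor if charge < 0 else 1.0)
    barrier = np.array([g.channel_barrier * bfac])
    well = np.array([g.entrance_well_depth *
                     (1.0 if is_water else g.ion_well_factor)])
    qf = np.array([charge * field.gradient * EV_PER_ANG * field.direction
                   if label in field.acts_on else 0.0])
    p = np.asarray(position, dtype=float)
    e, _, _, _ = K.ext_energy_force(p[0], p[1], p[2], 0, ext, barrier, well, qf)
    return float(e)


# --------------------------------------------------------------------------
# Forces and energies
# --------------------------------------------------------------------------

def total_forces(config: Configuration, system: SystemModel,
                 include_external: bool = True) -> np.ndarray:
    """Analytic forces -grad(U) on every particle, kJ/mol/A."""
    tab = _Tables(system)
    sidx = tab.species_index(config.species_labels)
    pos = np.ascontiguousarray(config.positions)
    box = np.asarray(system.geometry.box)
    pbc = np.asarray(system.geometry.periodic)
    forces, bad = K.total_forces_kernel(
        pos, box, pbc, sidx, tab.eps, tab.sig6, tab.qq, tab.lam, tab.cutoff2,
        tab.lj_form, tab.ext, tab.barrier, tab.well, tab.qf,
        include_external)
    if bad >= 0:
        raise ValueError(f"overlapping particles (pair involving particle {bad})")
    return forces


def _pair_energy_matrix(pos, box, pbc, sidx, tab):
    """Dense pairwise energies (upper triangle), used by the energy maps."""
    n = pos.shape[0]
    d = pos[:, None, :] - pos[None, :, :]
    for k in range(3):
        if pbc[k]:
            d[..., k] -= box[k] * np.round(d[..., k] / box[k])
    r2 = np.einsum("ijk,ijk->ij", d, d)
    iu = np.triu_indices(n, 1)
    r = np.sqrt(r2[iu])
    eps = tab.eps[sidx[iu[0]], sidx[iu[1]]]
    sig6 = tab.sig6[sidx[iu[0]], sidx[iu[1]]]
    qq = tab.qq[sidx[iu[0]], sidx[iu[1]]]
    with np.errstate(divide="ignore", invalid="ignore"):
        s6 = sig6 / r ** 6
        if tab.lj_form == K.LJ_9_6:
            lj = eps * (2.0 * s6 ** 1.5 - 3.0 * s6)
        else:
            lj = 4.0 * eps * (s6 ** 2 - s6)
        coul = qq * np.exp(-r / tab.lam) / r
    e = np.where(r < np.sqrt(tab.cutoff2), lj + coul, 0.0)
    mat = np.zeros((n, n))
    mat[iu] = e
    return mat + mat.T


def per_particle_energies(config: Configuration, system: SystemModel) -> np.ndarray:
    """Instantaneous energy per particle: external plus half its pair sums."""
    tab = _Tables(system)
    sidx = tab.species_index(config.species_labels)
    pos = np.asarray(config.positions, dtype=float)
    box = np.asarray(system.geometry.box)
    pbc = np.asarray(system.geometry.periodic)
    emat = _pair_energy_matrix(pos, box, pbc, sidx, tab)
    epair = 0.5 * emat.sum(axis=1)
    eext = np.array([
        K.ext_energy_force(pos[i, 0], pos[i, 1], pos[i, 2], sidx[i], tab.ext,
                           tab.barrier, tab.well, tab.qf)[0]
        for i in range(pos.shape[0])])
    return epair + eext


def total_potential_energy(config: Configuration, system: SystemModel) -> float:
    """Total potential energy, kJ/mol (pair sums counted once)."""
    return float(per_particle_energies(config, system).sum())


# --------------------------------------------------------------------------
# Integration
# --------------------------------------------------------------------------

_CHUNK = 4000


def run_simulation(system: SystemModel, params: SimParams,
                   config: Configuration | None = None) -> Trajectory:
    """Integrate overdamped Langevin dynamics and record a trajectory.

    When no starting configuration is given, one is packed from
    ``params.seed``.  The noise stream is seeded independently of the
    packing so the run is reproducible bit-for-bit from (system, params).
    """
    if config is None:
        config = build_initial_configuration(system, params.seed)
    tab = _Tables(system)
    sidx = tab.species_index(config.species_labels)
    pos = np.ascontiguousarray(config.positions.copy())
    n = pos.shape[0]
    box = np.asarray(system.geometry.box, dtype=float)
    pbc = np.asarray(system.geometry.periodic)

    n_frames = params.n_steps // params.record_every + 1
    frames = np.empty((n_frames, n, 3))
    frames[0] = pos

    sig = math.sqrt(2.0 * KB * params.temperature * params.dt / params.friction)
    rng = np.random.Generator(np.random.PCG64(
        np.random.SeedSequence((params.seed, 1))))

    skin = 1.2
    npmax = n * (n - 1) // 2
    pi = np.empty(npmax, dtype=np.int32)
    pj = np.empty(npmax, dtype=np.int32)
    peps = np.empty(npmax)
    psig6 = np.empty(npmax)
    pqq = np.empty(npmax)
    state = np.array([0, 1], dtype=np.int64)  # [npairs, needs_rebuild]
    disp = np.zeros((n, 3))
    max_move = 0.3  # A per step, drift cap (numerical safeguard)

    step0 = 0
    remaining = params.n_steps
    while remaining > 0:
        m = min(_CHUNK, remaining)
        noise = rng.standard_normal((m, n, 3)) * sig
        status, step, part = K.run_chunk(
            pos, box, pbc, sidx, tab.eps, tab.sig6, tab.qq, tab.lam,
            tab.cutoff2, tab.lj_form, tab.ext, tab.barrier, tab.well, tab.qf,
            params.dt, params.friction, noise, skin, pi, pj, peps, psig6,
            pqq, state, disp, frames, params.record_every, step0, max_move)
        if status == 1:
            raise RuntimeError(
                f"overlapping particles at step {step} (particle {part})")
        if status == 2:
            raise RuntimeError(
                f"non-finite coordinate at step {step} for particle {part}")
        step0 += m
        remaining -= m

    return Trajectory(
        positions=frames,
        species_labels=list(config.species_labels),
        box=tuple(box),
        periodic=tuple(bool(b) for b in pbc),
        frame_interval=params.dt * params.record_every,
    )


def simulate_harmonic_1d(k_spring: float, n_steps: int, dt: float = 0.005,
                         friction: float = DEFAULT_FRICTION,
                         temperature: float = 300.0, record_every: int = 1,
                         seed: int = 0, x0: float = 0.0) -> np.ndarray:
    """Single 1D particle in a harmonic well U = k x^2 / 2 (validation aid).

    Returns the recorded positions; their histogram must converge to the
    Boltzmann gaussian exp(-k x^2 / (2 kB T)).
    """
    sig = math.sqrt(2.0 * KB * temperature * dt / friction)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, 1))))
    out = np.empty(n_steps // record_every + 1)
    out[0] = x0
    x = x0
    step0 = 0
    remaining = n_steps
    while remaining > 0:
        m = min(200_000, remaining)
        noise = rng.standard_normal(m) * sig
        x = K.harmonic_chunk(x, k_spring, dt / friction, noise, out,
                             record_every, step0)
        step0 += m
        remaining -= m
    return out
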