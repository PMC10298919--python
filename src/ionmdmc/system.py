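"""Molecular composition, channel geometry and field setup.

The reference system is a saline reservoir split by a six-layer graphene
slab pierced by a single sub-nanometre pore.  The slab itself is implicit:
its species are kept for composition bookkeeping, while mechanically it
acts through an external potential (see :mod:`ionmdmc.dynamics`).  Water is
coarse-grained to a single neutral site carrying the oxygen Lennard-Jones
parameters; the hydrogen rows remain as bookkeeping entries so that the
tabulated composition (counts, masses, charges) is preserved verbatim.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .units import KB

__all__ = [
    "SpeciesSpec",
    "ChannelGeometry",
    "FieldSpec",
    "SystemModel",
    "SimSpecies",
    "Configuration",
    "default_system",
    "desk_system",
    "bulk_system",
    "fluid_net_charge",
    "simulation_species",
    "build_initial_configuration",
    "WATER_SITE",
    "FLUID_SPECIES",
]

#: Label of the coarse-grained single-site water particle in trajectories.
WATER_SITE = "W"

#: Species whose charges must balance (the fluid phase incl. water H bookkeeping).
FLUID_SPECIES = ("Na+", "Cl-", "O_water", "H_water")


@dataclass(frozen=True)
class SpeciesSpec:
    """One molecular component: count, molar mass, charge and LJ parameters.

    ``epsilon`` is in kJ/mol and ``sigma`` in nm (the conventional force
    field units); everything else downstream works in angstrom.
    """

    name: str
    count: int
    molar_mass: float  # g/mol
    charge: float      # e
    epsilon: float     # kJ/mol
    sigma: float       # nm
    mobile: bool = True

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"species {self.name}: count must be >= 0")
        if self.epsilon < 0:
            raise ValueError(f"species {self.name}: epsilon must be >= 0")
        if self.sigma <= 0:
            raise ValueError(f"species {self.name}: sigma must be > 0")


@dataclass(frozen=True)
class ChannelGeometry:
    """Orthogonal box with an implicit membrane slab and one cylindrical pore.

    Beyond the structural fields, the geometry carries the calibration
    constants of the implicit-membrane potential (wall height, edge widths,
    in-pore confinement barrier, entrance-well shape).  They are plain data
    so a run is reproducible from its serialized configuration alone.
    Lengths in angstrom, energies in kJ/mol.
    """

    box: tuple[float, float, float] = (26.1766, 30.3968, 68.0527)
    periodic: tuple[bool, bool, bool] = (True, True, True)
    channel_axis: int = 2
    slab_center: float = 68.0527 / 2.0
    n_layers: int = 6
    layer_spacing: float = 3.4
    pore_diameter: float = 5.405
    pore_center: tuple[float, float] = (26.1766 / 2.0, 30.3968 / 2.0)
    #: depth of the entrance/exit wells for water (4 kBT at 300 K)
    entrance_well_depth: float = 4.0 * KB * 300.0
    #: well centres as offsets from slab_center along the channel axis;
    #: the defaults sit just inside the slab faces (pore-mouth adsorption sites)
    entrance_well_positions: tuple[float, ...] = (-7.2, 7.2)

    # --- implicit-membrane calibration constants (shipped defaults) ---
    wall_height: float = 1000.0        # slab repulsion off-pore, kJ/mol
    wall_edge_width: float = 0.5       # logistic width of the wall edges, A
    channel_barrier: float = 220.0     # in-pore confinement barrier for cations, kJ/mol
    barrier_edge_width: float = 1.3    # logistic width of the barrier shoulders, A
    barrier_offset: float = 1.5        # barrier shoulders pushed outward from the slab faces, A
    water_barrier_factor: float = 0.03  # water: low (H-bond assisted) confinement barrier
    anion_barrier_factor: float = 0.02  # Cl-: shallow enough to graze under cation Coulomb drag
    ion_well_factor: float = 0.0       # the wells are H-bond sites: water only
    pore_edge_width: float = 0.35      # radial softness of the pore wall, A
    funnel_length: float = 2.0         # widening of the radial gate at the faces, A
    well_width: float = 0.5            # gaussian sigma of the entrance wells, A
    well_radius: float = 3.5           # radial localization of the wells, A
    well_radius_width: float = 0.5     # radial logistic width of the wells, A

    def __post_init__(self) -> None:
        ax = self.channel_axis
        if ax not in (0, 1, 2):
            raise ValueError("channel_axis must be 0, 1 or 2")
        thickness = (self.n_layers - 1) * self.layer_spacing
        if self.slab_lo < 0 or self.slab_hi > self.box[ax]:
            raise ValueError(
                f"slab of thickness {thickness} A centred at {self.slab_center} A "
                f"does not fit inside the box (L={self.box[ax]} A)"
            )
        if self.pore_diameter <= 0:
            raise ValueError("pore_diameter must be > 0")
        t0, t1 = (i for i in range(3) if i != ax)
        r = self.pore_diameter / 2.0
        cx, cy = self.pore_center
        if not (r <= cx <= self.box[t0] - r and r <= cy <= self.box[t1] - r):
            raise ValueError("pore does not fit inside the transverse box face")

    @property
    def slab_thickness(self) -> float:
        return (self.n_layers - 1) * self.layer_spacing

    @property
    def slab_lo(self) -> float:
        return self.slab_center - self.slab_thickness / 2.0

    @property
    def slab_hi(self) -> float:
        return self.slab_center + self.slab_thickness / 2.0

    @property
    def pore_radius(self) -> float:
        return self.pore_diameter / 2.0

    @property
    def transverse_axes(self) -> tuple[int, int]:
        return tuple(i for i in range(3) if i != self.channel_axis)  # type: ignore[return-value]


@dataclass(frozen=True)
class FieldSpec:
    """Uniform electric field acting on selected species in a sub-region.

    ``gradient`` is in V/A; the force on a charge q (in e) is
    ``q * gradient * 96.485 kJ/mol/A`` along ``direction`` on the channel
    axis, applied only while the particle is inside ``region``.
    """

    gradient: float = 0.0
    region: Optional[tuple[float, float]] = None  # None -> left face to right slab face
    acts_on: frozenset[str] = frozenset({"Na+"})
    direction: int = 1

    def __post_init__(self) -> None:
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")
        if self.region is not None and self.region[0] >= self.region[1]:
            raise ValueError("field region must be a nonempty interval")

    def resolved_region(self, geometry: ChannelGeometry) -> tuple[float, float]:
        if self.region is not None:
            lo, hi = self.region
            if lo < 0 or hi > geometry.box[geometry.channel_axis]:
                raise ValueError("field region must lie inside the box")
            return (lo, hi)
        return (0.0, geometry.slab_hi)


@dataclass(frozen=True)
class SystemModel:
    """Full model: composition + geometry + field + thermodynamic state."""

    species: tuple[SpeciesSpec, ...]
    geometry: ChannelGeometry = field(default_factory=ChannelGeometry)
    field: FieldSpec = field(default_factory=FieldSpec)
    temperature: float = 300.0       # K
    pair_cutoff: float = 1.2         # nm
    screening_length: float = 5.0    # A, screened-Coulomb decay
    lj_form: str = "9-6"
    dielectric: float = 10.0         # relative permittivity absorbed in the prefactor
    na_water_polarity: float = 3.0   # boost of the Na+/water cross epsilon

    def __post_init__(self) -> None:
        if self.lj_form not in ("9-6", "12-6"):
            raise ValueError("lj_form must be '9-6' or '12-6'")
        net = fluid_net_charge(self)
        if abs(net) > 1e-9:
            raise ValueError(f"fluid composition is not charge neutral (net {net} e)")

    @property
    def cutoff(self) -> float:
        """Pair cutoff in angstrom."""
        return self.pair_cutoff * 10.0

    def species_by_name(self, name: str) -> SpeciesSpec:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(name)

    def replace(self, **kwargs) -> "SystemModel":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class SimSpecies:
    """A species as simulated: label, per-particle charge and LJ parameters in A."""

    label: str
    count: int
    charge: float    # e, as used by the simulator
    epsilon: float   # kJ/mol
    sigma: float     # A
    is_water: bool = False


@dataclass
class Configuration:
    """Simulation state: wrapped positions plus per-particle species labels."""

    positions: np.ndarray          # (P, 3), A
    species_labels: list[str]
    box: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be a (P, 3) array")
        if len(self.species_labels) != self.positions.shape[0]:
            raise ValueError("one species label per particle required")


# --------------------------------------------------------------------------
# Reference composition (graphene slab / saline; PCFF-style parameters)
# --------------------------------------------------------------------------

_TABLE = (
    #            name         count  M        q      eps    sigma(nm)  mobile
    SpeciesSpec("Na+",         34,  22.99,    1.0,  0.738, 0.39624, True),
    SpeciesSpec("Cl-",         34,  35.453,  -1.0,  0.305, 0.3915,  True),
    SpeciesSpec("O_water",   1076,  15.9994, -0.82, 0.274, 0.3608,  True),
    SpeciesSpec("H_water",   2152,   1.00797, 0.41, 0.013, 0.1098,  False),
    SpeciesSpec("H_graphene",  54,   1.00797, 0.0,  0.02,  0.2995,  False),
    SpeciesSpec("C_graphene", 1650,  12.01115, 0.0, 0.064, 0.401,   False),
)


def default_system() -> SystemModel:
    """The reference system: tabulated composition, slit-pore geometry,
    field acting on Na+ only, 300 K, 1.2 nm cutoff."""
    return SystemModel(species=_TABLE)


def desk_system(n_na: int = 8, n_cl: int = 8, n_water: int = 84,
                gradient: float = 0.0) -> SystemModel:
    """A reduced composition (~100 mobile particles) with the reference
    geometry and parameters, sized for desk-scale benchmark runs."""
    if n_na != n_cl:
        raise ValueError("equal Na+ and Cl- counts required for neutrality")
    species = tuple(
        dataclasses.replace(
            s,
            count={
                "Na+": n_na, "Cl-": n_cl,
                "O_water": n_water, "H_water": 2 * n_water,
            }.get(s.name, s.count),
        )
        for s in _TABLE
    )
    return SystemModel(species=species, field=FieldSpec(gradient=gradient))


def bulk_system(n_particles: int, box: tuple[float, float, float] = (30.0, 30.0, 30.0),
                epsilon: float = 0.0, sigma: float = 0.3,
                temperature: float = 300.0) -> SystemModel:
    """A membrane-free box of one neutral species (``epsilon=0`` gives an
    ideal gas).  Used for free-diffusion and equilibrium checks."""
    geom = ChannelGeometry(
        box=box, slab_center=box[2] / 2.0, n_layers=2, layer_spacing=1.0,
        pore_center=(box[0] / 2.0, box[1] / 2.0),
        wall_height=0.0, channel_barrier=0.0, entrance_well_depth=0.0,
    )
    sp = (SpeciesSpec("X", n_particles, 1.0, 0.0, epsilon, sigma, True),)
    return SystemModel(species=sp, geometry=geom,
                       field=FieldSpec(gradient=0.0, acts_on=frozenset()),
                       temperature=temperature)


def fluid_net_charge(system: SystemModel) -> float:
    """Net charge (e) of the fluid composition, bookkeeping entries included."""
    return float(sum(s.count * s.charge for s in system.species
                     if s.name in FLUID_SPECIES or s.mobile))


def simulation_species(system: SystemModel) -> list[SimSpecies]:
    """Map the composition onto the particles the surrogate actually moves.

    Mobile ions keep their parameters; the water oxygen becomes the neutral
    single-site water particle ``W`` (O LJ parameters, zero charge).
    """
    out: list[SimSpecies] = []
    for s in system.species:
        if not s.mobile:
            continue
        if s.name == "O_water":
            out.append(SimSpecies(WATER_SITE, s.count, 0.0, s.epsilon,
                                  s.sigma * 10.0, is_water=True))
        else:
            out.append(SimSpecies(s.name, s.count, s.charge, s.epsilon,
                                  s.sigma * 10.0))
    return out


# --------------------------------------------------------------------------
# Initial packing
# --------------------------------------------------------------------------

def _lattice_pack(n: int, box: np.ndarray, ax: int, zlo: float, zhi: float,
                  min_sep: float, rng: np.random.Generator) -> np.ndarray:
    """Jittered FCC sites outside the slab; deterministic in rng.

    A face-centred lattice reaches liquid-like densities that random
    sequential addition cannot.
    """
    a_ref = min_sep * np.sqrt(2.0)          # cubic cell edge at contact
    counts = np.maximum((box / a_ref).astype(int), 1)
    cell = box / counts                     # stretched cells tile the box
    half_diags = 0.5 * np.sqrt(cell[0] ** 2 + cell[1] ** 2),         0.5 * np.sqrt(cell[0] ** 2 + cell[2] ** 2),         0.5 * np.sqrt(cell[1] ** 2 + cell[2] ** 2)
    nn = min(half_diags + (cell.min(),))
    basis = np.array([[0.0, 0.0, 0.0], [0.5, 0.5, 0.0],
                      [0.5, 0.0, 0.5], [0.0, 0.5, 0.5]])
    idx = np.stack(np.meshgrid(*[np.arange(c) for c in counts],
                               indexing="ij"), axis=-1).reshape(-1, 3)
    sites = ((idx[:, None, :] + basis[None, :, :] + 0.25)
             * cell).reshape(-1, 3)
    sites = sites[(sites[:, ax] <= zlo) | (sites[:, ax] >= zhi)]
    # per-axis jitter: a pair can close by 2*sqrt(3)*jitter in the worst case
    jitter = max(0.0, min(0.3, (nn - min_sep) / (2.0 * np.sqrt(3.0)) * 0.9))
    if len(sites) < n or nn - 2.0 * np.sqrt(3.0) * jitter < min_sep - 1e-9:
        raise RuntimeError(
            f"packing failed: only {len(sites)} lattice sites with separation "
            f">= 0.85 sigma for {n} particles")
    chosen = sites[rng.choice(len(sites), size=n, replace=False)]
    return chosen + rng.uniform(-1.0, 1.0, size=chosen.shape) * jitter


def build_initial_configuration(system: SystemModel, seed: int,
                                max_attempts: int = 10_000) -> Configuration:
    """Random non-overlapping placement of all mobile particles.

    Particles are placed uniformly in the box outside the membrane slab with
    every pair separated by at least ``0.85 * sigma_ij`` (Waldman-Hagler
    cross sigma).  Deterministic for a given seed.
    """
    from .dynamics import combine_lj  # local import to avoid a cycle

    sim = simulation_species(system)
    labels: list[str] = []
    sig = []
    for sp in sim:
        labels.extend([sp.label] * sp.count)
        sig.extend([sp.sigma] * sp.count)
    n = len(labels)
    sigs = np.asarray(sig)
    uniq = sorted(set(sigs))
    min_sep = {}
    for a in uniq:
        for b in uniq:
            _, s_ab = combine_lj(1.0, a, 1.0, b)
            min_sep[(a, b)] = 0.85 * s_ab
    max_sep = max(min_sep.values()) if min_sep else 1.0

    geom = system.geometry
    box = np.asarray(geom.box)
    ax = geom.channel_axis
    margin = 1.0
    zlo, zhi = geom.slab_lo - margin, geom.slab_hi + margin

    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))

    # dense compositions exceed the random-sequential-addition jamming
    # fraction; place those on a jittered lattice instead
    free_vol = float(np.prod(box)) * (1.0 - (zhi - zlo) / box[ax])
    rsa_fraction = n * (4.0 / 3.0) * np.pi * (max_sep / 2.0) ** 3 / free_vol
    if rsa_fraction > 0.3:
        pos = _lattice_pack(n, box, ax, zlo, zhi, max_sep, rng)
        order = rng.permutation(n)
        return Configuration(pos[order], labels, tuple(box))

    cell = max(max_sep, 1e-6)
    ncell = np.maximum((box / cell).astype(int), 1)
    grid: dict[tuple[int, int, int], list[int]] = {}
    pos = np.empty((n, 3))

    def cell_of(p):
        return tuple(np.minimum((p / box * ncell).astype(int), ncell - 1))

    for i in range(n):
        placed = False
        for _ in range(max_attempts):
            p = rng.random(3) * box
            if zlo < p[ax] < zhi:
                continue
            c = cell_of(p)
            ok = True
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dz in (-1, 0, 1):
                        cc = ((c[0] + dx) % ncell[0], (c[1] + dy) % ncell[1],
                              (c[2] + dz) % ncell[2])
                        for j in grid.get(cc, ()):
                            d = p - pos[j]
                            d -= box * np.round(d / box)
                            if np.dot(d, d) < min_sep[(sigs[i], sigs[j])] ** 2:
                                ok = False
                                break
                        if not ok:
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                pos[i] = p
                grid.setdefault(c, []).append(i)
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"packing failed: could not place particle {i} ({labels[i]}) "
                f"with separation >= 0.85 sigma in {max_attempts} attempts"
            )
    return Configuration(pos, labels, tuple(box))
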