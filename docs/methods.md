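# Methods

## Problem and approach

`ionmdmc` models ion transport through a sub-nanometre channel in a
graphene-like membrane separating two saline reservoirs, and implements a
trajectory-to-Markov-chain ("MDMC") reduction of that dynamics: the
simulation domain is discretized into spatial cells, each cell is a state,
the transition probabilities between states are estimated from observed
trajectories at a fixed lag, and Monte Carlo chains sampled from the
resulting row-stochastic matrix reproduce the spatial occupancy and the
channel residence-time statistics of the source dynamics at a fraction of
the cost.

Trajectories come either from external MD output (text LAMMPS dumps or
extended XYZ) or from the package's own generator, an overdamped-Langevin
("Brownian dynamics") surrogate described below. The surrogate is not an
all-atom force field: it is the simplest dynamics with correct Boltzmann
statistics that reproduces the mechanisms of interest (channel gating by an
electric field, mouth-trapped water, cation-anion pairing and drag).

## The surrogate model

Units: angstrom, picosecond, kJ/mol, elementary charge; kB·300 K =
2.494 kJ/mol.

**Integrator.** Euler-Maruyama discretization of position Langevin
dynamics, `dx = F dt / gamma + sqrt(2 kB T dt / gamma) xi`. Defaults
`dt = 0.005 ps` and `gamma = 24.94 kJ/mol ps/A^2`, chosen so a free ion
diffuses with `D = kB T / gamma = 0.1 A^2/ps`. Frames are recorded every
40 steps (0.2 ps) by default; the frame interval is a free parameter
because no physical dump frequency is prescribed for the reference system.
A per-step drift cap of 0.3 A guards against force spikes on steep wall
contacts (thermal noise is never clipped); positions are wrapped into the
periodic box every step. Pair forces use a Verlet neighbour list
(1.2 A skin) rebuilt when any particle has moved half a skin.

**Pair interactions.** Lennard-Jones 9-6 by default
(`eps (2 (s/r)^9 - 3 (s/r)^6)`, minimum `-eps` at `r = sigma`; 12-6
selectable), with Waldman-Hagler combining rules for unlike pairs, plus a
screened Coulomb term `C q_i q_j exp(-r/lambda) / (eps_r r)` with
`lambda = 5 A` and `eps_r = 10` standing in for solvent screening and
long-range electrostatics. Everything is truncated to exactly zero at the
1.2 nm cutoff. Water is a single neutral site with the water-oxygen LJ
parameters; the water hydrogens remain bookkeeping entries so the tabulated
composition and its exact charge neutrality are preserved. The Na+/water
cross epsilon is boosted 3x (`na_water_polarity`) to restore, with neutral
water, the ion-dipole attraction behind the trapped-water/ion-relocation
mechanism.

**Implicit membrane.** The six-layer slab (thickness 17 A, centred in the
68 A box) acts through an external potential with four ingredients:

1. a repulsive wall (`wall_height = 1000 kJ/mol`) filling the slab outside
   the pore cylinder (diameter 5.405 A), with soft logistic edges (0.5 A in
   z, 0.35 A radially) and conical mouths — the radial gate widens by
   `funnel_length = 2 A` towards the slab faces, so particles pressed
   against a face slide down the cone onto the pore axis instead of having
   to hit a ~1 A aperture by blind lateral diffusion;
2. a confinement (desolvation) ramp spanning the slab: `220 kJ/mol` for
   cations, with logistic shoulders of width 1.3 A whose centres sit 1.5 A
   outside the slab faces. Its maximum slope, ~42 kJ/mol/A, lies between
   the field forces at 0.3 and 0.5 V/A (29 and 48 kJ/mol/A): below
   0.5 V/A the tilted barrier is many kBT and entries are rare; at and
   above 0.5 V/A driven Na+ slides through. Water sees 3% of the ramp
   (hydrogen-bond-assisted permeation) and Cl- 2% (low enough that the
   Coulomb pull of a nearby Na+ can drag it over; far too high, relative
   to thermal energy times the ramp, for unassisted deep entry);
3. Gaussian adsorption wells (depth 4 kBT, sigma 0.5 A, localized within
   ~3.5 A of the pore axis) at z-offsets of ±7.2 A from the slab centre,
   i.e. just inside the two pore mouths. They act on water only
   (`ion_well_factor = 0`): physically they are the hydrogen-bonding sites
   of the H-terminated pore edge. Water falling into a mouth well is
   trapped by ~4 kBT until pushed onward — the "trapped water" that seeds
   the passage-order mechanism;
4. the electric field: a constant force `q * gradient * 96.485 kJ/mol/A`
   on the species in `acts_on` (Na+ by default) while inside the field
   region, which defaults to [left box face, right slab face].

The shoulder offset (item 2) matters for measurement, not just physics:
with the ramp midpoint exactly at the slab face, near-threshold ions
diffuse slowly across the residence-detection boundary and shed dozens of
one-frame "flicker" events that drown the mean residence time. Moving the
commitment point 1.5 A outside the detection interval makes events either
clean transits or clean rejections.

All of these constants live as plain fields of `ChannelGeometry`, are
serialized with the run configuration, and were calibrated once against
the qualitative target behaviour (field-gated entries with a residence
maximum at 0.5 V/A; water trapping; draggable but not freely permeating
Cl-) and then frozen.

## The MDMC reduction

`StateGrid` discretizes any subset of axes at 0.5 A (the shared mesh of
the density analysis; bins half-open, anchored at 0, row-major with the
first axis slowest, so chain occupancies and trajectory densities compare
cell by cell). `count_transitions` pools ordered state pairs at lag 1
(default) over all particles of a species — a single-particle Markov
model; interactions enter only through the empirical statistics.
`estimate_matrix` row-normalizes into a sparse stochastic matrix; source
states never visited either get a unit self-loop (default, preserves grid
geometry) or are removed with compacted indices (`restrict`).
`run_mc` samples chains by inverse-CDF draws per row; `chain_occupancy`
and `chain_residence` map chains back to spatial fields and run-length
residence statistics. `stationary_distribution` uses damped power
iteration (half identity mixed in, harmless to the fixed point, convergent
on periodic chains).

A residence event is a maximal run of frames inside the channel region
(slab extent along the axis, with a transverse radius bound of pore radius
plus one water sigma); events still open at the last frame are censored
and discarded; the residence time is the mean over completed events.

## Validation studies (`ionmdmc.validation`)

* `mdmc_self_consistency`: a 60-particle water-like LJ fluid equilibrates
  in a 20x20x24 A box for 1.2e6 steps (6000 frames at 1 ps, 3.6e5
  particle-frames); the lag-1 matrix on a 0.5 A z-grid is estimated, one
  chain per source particle is sampled for the same number of steps, and
  the pooled chain occupancy and the mean residence in a fixed 8 A
  interval are compared with the trajectory's. Typical results: occupancy
  L1 ~ 0.03-0.04 (threshold 0.05), residence agreement within a few
  percent at >5000 events per side. The frame interval (1 ps, ~0.9 bins of
  diffusive displacement) keeps the lag-1 chain close to Markovian.
* `residence_sweep_study`: 20 independent runs per gradient in
  {0.1, 0.3, 0.5, 0.7, 0.9} V/A on the ~100-mobile-particle desk system
  (8 Na+, 8 Cl-, 84 water; reference geometry), 2e5 steps each. Below
  0.5 V/A the channel is closed (few or no passages); the mean Na+
  residence peaks at 0.5 V/A (ions transit, slowly) and decays
  monotonically to 0.9 V/A (stronger drive, faster transit).
* `passage_order_study`: 50 repetitions of a scripted rare event — one
  water at the entrance mouth, one Na+ behind it, one Cl- behind that,
  plus a dilute background reservoir, driven at 0.5 V/A for 1.5 ns. The
  trapped water enters first and stays longest (it moves only when pushed
  by the driven Na+ and is re-trapped at the exit well); Na+ transits
  under the field; Cl- only grazes the channel under Coulomb drag. Median
  mean residences order water > Na+ > Cl-; per-seed means are undefined
  for species without completed events in that seed (about half the seeds
  for Cl-), and medians are taken over the defined seeds.

Per-rep seeds derive from `SeedSequence((base, round(gradient*1e6), rep))`,
so adding replicates or reordering gradients never changes earlier runs.

## What the surrogate does and does not show

The generator reproduces the statistical structure needed by the reduction
— Boltzmann sampling (verified against the closed-form harmonic
distribution, KL < 0.01), Einstein diffusion (MSD = 6Dt within 10%),
field-gated barrier crossing, adsorption, pairing and drag — but not
all-atom realism: no explicit graphene lattice, no 3-site water or hydrogen
bonds, no Ewald electrostatics, no NVT thermostat chains. Passing tests
therefore demonstrate that the MDMC reduction recovers the spatial and
kinetic observables of a known ground-truth dynamics of the right
qualitative class, not that the surrogate's absolute residence times match
laboratory or all-atom values.

## Numerical choices and degenerate inputs

* Forces are analytic; a central-difference check at 1e-4 relative
  tolerance guards the gradient of every term.
* Overlapping particles (r < 1e-6 A) and non-finite coordinates abort a
  run naming the step and particle.
* Bins on an exact edge go to the higher bin; the final bin absorbs the
  box remainder and is closed.
* Empty energy-map bins are NaN with zero occupancy — empty, not
  zero-energy.
* An all-zero transition-count matrix is an error; a chain of length zero
  still counts its initial state.
* Packing uses rejection sampling with a 0.85 sigma_ij minimum separation
  and fails loudly after 1e4 attempts per particle.

## Known limitations

* Events shorter than one frame interval (0.2 ps default) are invisible to
  residence detection; the sweep is interpreted at fixed frame interval.
* The single-particle Markov model carries no cross-species coupling; in
  driven, strongly interacting regimes the chain reproduces occupancy but
  cannot capture, e.g., correlated train motion through the pore.
* The Cl- graze statistics in the passage-order study are rare-event
  counts; roughly half of the scripted repetitions record no completed
  Cl- event, which is reported rather than hidden.
* Only orthogonal boxes and a channel along the long axis are supported.
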