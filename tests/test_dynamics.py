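"""Pair model, external potential and Langevin-integrator physics checks."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import ionmdmc as m
from ionmdmc.dynamics import (SimParams, combine_lj, external_potential,
                              pair_energy, per_particle_energies,
                              run_simulation, simulate_harmonic_1d,
                              total_forces, total_potential_energy)
from ionmdmc.system import Configuration
from ionmdmc.trajectory import unwrap_positions
from ionmdmc.units import KB


class TestCombiningRules:
    def test_identical_species_identity(self):
        eps, sig = combine_lj(0.738, 0.39624, 0.738, 0.39624)
        assert eps == pytest.approx(0.738)
        assert sig == pytest.approx(0.39624)

    def test_sodium_chloride_cross_parameters(self):
        # direct substitution of the two combination formulas
        si6, sj6 = 0.39624 ** 6, 0.3915 ** 6
        sig_ref = ((si6 + sj6) / 2.0) ** (1 / 6)
        eps_ref = (2.0 * math.sqrt(0.738 * 0.305)
                   * 0.39624 ** 3 * 0.3915 ** 3 / (si6 + sj6))
        eps, sig = combine_lj(0.738, 0.39624, 0.305, 0.3915)
        assert eps == pytest.approx(eps_ref, rel=1e-12)
        assert sig == pytest.approx(sig_ref, rel=1e-12)

    @given(st.floats(0.01, 5.0), st.floats(0.1, 1.0),
           st.floats(0.01, 5.0), st.floats(0.1, 1.0))
    def test_cross_epsilon_bounded_by_max(self, e1, s1, e2, s2):
        eps, sig = combine_lj(e1, s1, e2, s2)
        assert eps <= max(e1, e2) * (1 + 1e-12)
        assert min(s1, s2) * (1 - 1e-12) <= sig <= max(s1, s2) * (1 + 1e-12)

    def test_nonpositive_input_rejected(self):
        with pytest.raises(ValueError):
            combine_lj(0.5, -0.1, 0.5, 0.3)


class TestPairEnergy:
    def test_9_6_minimum_is_minus_eps_at_sigma(self):
        assert pair_energy(3.4, 0.7, 3.4, 0, 0) == pytest.approx(-0.7)
        # and it is a minimum
        assert pair_energy(3.3, 0.7, 3.4, 0, 0) > -0.7
        assert pair_energy(3.5, 0.7, 3.4, 0, 0) > -0.7

    def test_zero_beyond_cutoff(self):
        r = np.array([11.99, 12.0, 12.5, 20.0])
        e = pair_energy(r, 0.7, 3.4, 1.0, -1.0, cutoff=12.0)
        assert e[0] != 0.0
        assert np.all(e[1:] == 0.0)

    def test_opposite_charges_attractive_and_monotone(self):
        # large screening length: bare Coulomb shape inside the cutoff
        r = np.linspace(2.0, 11.9, 400)
        e = pair_energy(r, 0.0, 3.0, 1.0, -1.0, screening_length=1e9)
        assert np.all(e < 0)
        assert np.all(np.diff(e) > 0)

    def test_12_6_form_minimum_location(self):
        r0 = 2 ** (1 / 6) * 3.4
        e_min = pair_energy(r0, 0.7, 3.4, 0, 0, lj_form="12-6")
        assert e_min == pytest.approx(-0.7, rel=1e-9)

    def test_nonpositive_r_rejected(self):
        with pytest.raises(ValueError):
            pair_energy(0.0, 0.7, 3.4, 0, 0)


class TestExternalPotential:
    def test_zero_far_from_slab_for_field_free_species(self, desk):
        g = desk.geometry
        e = external_potential((5.0, 5.0, 3.0), "Cl-", g, desk.field)
        assert abs(e) < 1e-9

    def test_wall_dominates_inside_slab_off_pore(self, desk):
        g = desk.geometry
        pos = (g.pore_center[0] + 9.0, g.pore_center[1], g.slab_center)
        e = external_potential(pos, "W", g, desk.field)
        assert e >= 100.0

    def test_entrance_well_depth_for_water(self, desk):
        # at the well minimum the water energy is below zero by roughly the
        # well depth net of the (small) confinement background
        g = desk.geometry
        z = g.slab_center + g.entrance_well_positions[0]
        e = external_potential((g.pore_center[0], g.pore_center[1], z),
                               "W", g, desk.field)
        background = g.channel_barrier * g.water_barrier_factor
        assert -g.entrance_well_depth - 1.0 < e < -g.entrance_well_depth + background

    def test_field_acts_on_sodium_only(self, desk):
        sysf = desk.replace(field=dataclasses.replace(desk.field, gradient=0.5))
        g = sysf.geometry
        p = (5.0, 5.0, 10.0)
        e_na = external_potential(p, "Na+", g, sysf.field)
        e_cl = external_potential(p, "Cl-", g, sysf.field)
        e_w = external_potential(p, "W", g, sysf.field)
        assert e_na < 0  # downhill along the ramp from the region start
        assert e_cl == pytest.approx(0.0, abs=1e-9)
        assert e_w == pytest.approx(0.0, abs=1e-9)


class TestForces:
    def test_newtons_third_law(self, desk):
        cfg = m.build_initial_configuration(desk, seed=3)
        f = total_forces(cfg, desk, include_external=False)
        assert np.abs(f.sum(axis=0)).max() < 1e-8

    def test_pair_force_vanishes_at_lj_minimum(self):
        sys_ = m.bulk_system(2, box=(30.0, 30.0, 30.0), epsilon=0.7, sigma=0.34)
        cfg = Configuration(np.array([[5.0, 5.0, 5.0], [5.0, 5.0, 8.4]]),
                            ["X", "X"], sys_.geometry.box)
        f = total_forces(cfg, sys_, include_external=False)
        assert np.abs(f).max() < 1e-8

    def test_finite_difference_gradient(self, desk):
        sysf = desk.replace(field=dataclasses.replace(desk.field, gradient=0.5))
        cfg = m.build_initial_configuration(sysf, seed=3)
        f = total_forces(cfg, sysf)
        h = 1e-6
        rng = np.random.default_rng(0)
        for i in rng.choice(len(cfg.positions), 6, replace=False):
            for k in range(3):
                p1 = cfg.positions.copy(); p1[i, k] += h
                p2 = cfg.positions.copy(); p2[i, k] -= h
                e1 = total_potential_energy(
                    Configuration(p1, cfg.species_labels, cfg.box), sysf)
                e2 = total_potential_energy(
                    Configuration(p2, cfg.species_labels, cfg.box), sysf)
                fd = -(e1 - e2) / (2 * h)
                assert fd == pytest.approx(f[i, k], rel=1e-4, abs=1e-5)

    def test_overlapping_particles_rejected(self):
        sys_ = m.bulk_system(2, epsilon=0.5, sigma=0.3)
        cfg = Configuration(np.array([[5.0, 5.0, 5.0], [5.0, 5.0, 5.0]]),
                            ["X", "X"], sys_.geometry.box)
        with pytest.raises(ValueError, match="overlap"):
            total_forces(cfg, sys_)


class TestIntegrator:
    def test_immobile_at_zero_temperature_without_forces(self):
        sys_ = m.bulk_system(10)
        params = SimParams(n_steps=200, temperature=0.0, record_every=10, seed=1)
        traj = run_simulation(sys_, params)
        assert np.allclose(traj.positions[0], traj.positions[-1])

    def test_bitwise_determinism(self, desk):
        params = SimParams(n_steps=500, record_every=10, seed=9)
        a = run_simulation(desk, params)
        b = run_simulation(desk, params)
        assert np.array_equal(a.positions, b.positions)

    def test_free_particle_msd_matches_einstein_relation(self):
        # 200 independent particles; D = kB T / gamma = 0.1 A^2/ps
        sys_ = m.bulk_system(200, box=(60.0, 60.0, 60.0))
        traj = run_simulation(sys_, SimParams(n_steps=20_000, record_every=40,
                                              seed=5))
        un = unwrap_positions(traj)
        t = np.arange(traj.n_frames) * traj.frame_interval
        msd = ((un - un[0]) ** 2).sum(axis=2).mean(axis=1)
        sel = slice(50, 251)
        ratio = np.mean(msd[sel] / (6 * 0.1 * t[sel]))
        assert ratio == pytest.approx(1.0, abs=0.1)

    def test_harmonic_well_samples_boltzmann(self):
        k = 2.0  # kJ/mol/A^2
        x = simulate_harmonic_1d(k, 1_000_000, seed=7)
        var_th = KB * 300.0 / k
        edges = np.linspace(-4 * var_th ** 0.5, 4 * var_th ** 0.5, 61)
        hist, _ = np.histogram(x, bins=edges)
        p = hist / hist.sum()
        c = 0.5 * (edges[1:] + edges[:-1])
        q = np.exp(-c ** 2 / (2 * var_th))
        q /= q.sum()
        mask = p > 0
        kl = float(np.sum(p[mask] * np.log(p[mask] / q[mask])))
        assert kl < 0.01

    def test_dilute_drift_only_for_sodium(self):
        # interaction-free ions + water in a field acting on Na+ only
        sp = (
            m.SpeciesSpec("Na+", 20, 22.99, 1.0, 0.0, 0.39624),
            m.SpeciesSpec("Cl-", 20, 35.453, -1.0, 0.0, 0.3915),
            m.SpeciesSpec("O_water", 20, 15.9994, -0.82, 0.0, 0.3608),
            m.SpeciesSpec("H_water", 40, 1.00797, 0.41, 0.013, 0.1098,
                          mobile=False),
        )
        geom = m.ChannelGeometry(
            box=(30.0, 30.0, 60.0), slab_center=55.0, n_layers=2,
            layer_spacing=1.0, pore_center=(15.0, 15.0), wall_height=0.0,
            channel_barrier=0.0, entrance_well_depth=0.0)
        sys_ = m.SystemModel(
            species=sp, geometry=geom,
            field=m.FieldSpec(gradient=0.1, region=(0.0, 60.0)))
        traj = run_simulation(sys_, SimParams(n_steps=4000, record_every=40,
                                              seed=3))
        un = unwrap_positions(traj)
        dz = un[-1, :, 2] - un[0, :, 2]
        labels = np.array(traj.species_labels)
        t = (traj.n_frames - 1) * traj.frame_interval
        v_na = dz[labels == "Na+"].mean() / t
        v_cl = dz[labels == "Cl-"].mean() / t
        v_w = dz[labels == "W"].mean() / t
        v_drift = 0.1 * 96.485 / 24.943  # qE/gamma
        assert v_na == pytest.approx(v_drift, rel=0.25)
        assert abs(v_cl) < 0.1 * v_drift
        assert abs(v_w) < 0.1 * v_drift

    def test_overlap_during_run_names_step_and_particle(self):
        sys_ = m.bulk_system(2, epsilon=0.5, sigma=0.3)
        cfg = Configuration(np.array([[5.0, 5.0, 5.0], [5.0, 5.0, 5.0]]),
                            ["X", "X"], sys_.geometry.box)
        params = SimParams(n_steps=10, record_every=1, seed=0)
        with pytest.raises(RuntimeError, match="step 0"):
            run_simulation(sys_, params, config=cfg)


class TestEnergies:
    def test_isolated_neutral_particle_has_zero_energy(self):
        sys_ = m.bulk_system(1)
        cfg = Configuration(np.array([[5.0, 5.0, 5.0]]), ["X"],
                            sys_.geometry.box)
        assert total_potential_energy(cfg, sys_) == pytest.approx(0.0, abs=1e-12)

    def test_pair_energy_split_halves(self):
        sys_ = m.bulk_system(2, box=(30.0, 30.0, 30.0), epsilon=0.7, sigma=0.34)
        cfg = Configuration(np.array([[5.0, 5.0, 5.0], [5.0, 5.0, 8.4]]),
                            ["X", "X"], sys_.geometry.box)
        e = per_particle_energies(cfg, sys_)
        assert e[0] == pytest.approx(e[1])
        assert e.sum() == pytest.approx(-0.7, rel=1e-9)
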