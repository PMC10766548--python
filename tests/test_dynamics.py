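"""Integrator physics, uncertainty-triggered sampling runs, metadynamics."""

import math

import numpy as np
import pytest

from uddal import (
    BiasParams,
    Configuration,
    ThermostatParams,
    UNITS,
    init_velocities,
    langevin_step,
    metadynamics_energy,
    run_md,
    run_metadynamics,
    run_sampling_md,
)
from uddal.core_io import KINETIC_TO_ENERGY
from uddal.dynamics import BondDifferenceCV, CoordinateCV, MetadynamicsState
from uddal.uncertainty_bias import energy_variance, rho


class Harmonic1D:
    """V = ½k(x−x0)² on the x coordinate of a single atom; y, z frozen."""

    def __init__(self, k=3.0, x0=0.0):
        self.k, self.x0 = k, x0

    def __call__(self, config):
        x = config.positions[0, 0]
        forces = np.zeros_like(config.positions)
        forces[0, 0] = -self.k * (x - self.x0)
        return 0.5 * self.k * (x - self.x0) ** 2, forces

    def frozen_mask(self, config):
        mask = np.zeros((config.n_atoms, 3), dtype=bool)
        mask[0, 1:] = True
        return mask


class TestInitVelocities:
    def test_zero_temperature_gives_zero_velocities(self, single_atom):
        out = init_velocities(single_atom, 0.0, seed=1)
        assert np.array_equal(out.velocities, np.zeros((1, 3)))

    def test_deterministic_under_seed(self, single_atom):
        a = init_velocities(single_atom, 300.0, seed=4)
        b = init_velocities(single_atom, 300.0, seed=4)
        assert np.array_equal(a.velocities, b.velocities)

    def test_equipartition_at_large_sample(self):
        n = 10_000
        config = Configuration(species=["H"] * n, positions=np.zeros((n, 3)))
        out = init_velocities(config, 350.0, seed=0)
        ke_per_atom = out.kinetic_energy() / n
        expected = 1.5 * UNITS.boltzmann_constant * 350.0
        assert ke_per_atom == pytest.approx(expected, rel=0.02)


class TestIntegrator:
    def test_zero_force_zero_friction_is_uniform_motion(self, single_atom):
        pot = lambda c: (0.0, np.zeros((1, 3)))  # noqa: E731
        thermostat = ThermostatParams(temperature=0.0, friction=0.0, dt=1.0, seed=0)
        config = single_atom.copy()
        config.velocities = np.array([[0.01, -0.02, 0.005]])
        rng = np.random.default_rng(0)
        c = config
        for _ in range(100):
            c, _, _ = langevin_step(c, pot, thermostat, rng)
        assert np.allclose(c.positions, config.velocities * 100.0, rtol=1e-12)

    def test_symplectic_limit_energy_conservation(self, single_atom):
        """Friction 0, T 0: total energy drift stays at the O(dt²) scale."""
        pot = Harmonic1D(k=3.0)
        dt = 0.05
        thermostat = ThermostatParams(temperature=0.0, friction=0.0, dt=dt, seed=0)
        config = single_atom.copy()
        config.positions = np.array([[0.4, 0.0, 0.0]])
        config.velocities = np.zeros((1, 3))
        rng = np.random.default_rng(0)
        e0 = pot(config)[0]
        c, forces = config, None
        drift = 0.0
        for _ in range(10_000):
            c, _, forces = langevin_step(c, pot, thermostat, rng, forces)
            e = pot(c)[0] + c.kinetic_energy()
            drift = max(drift, abs(e - e0))
        omega_dt = dt * math.sqrt(3.0 * 4.184e-4 / 1.0)
        assert drift <= 5.0 * e0 * omega_dt**2

    def test_thermal_average_kinetic_energy(self, single_atom):
        """Time-averaged KE of a thermostatted 1D oscillator ≈ k_B·T/2."""
        pot = Harmonic1D(k=3.0)
        thermostat = ThermostatParams(temperature=350.0, friction=0.05, dt=0.5, seed=3)
        config = init_velocities(single_atom, 350.0, seed=3, frozen_mask=pot.frozen_mask(single_atom))
        rng = np.random.default_rng(thermostat.seed)
        c, forces = config, None
        ke = []
        for step in range(60_000):
            c, _, forces = langevin_step(c, pot, thermostat, rng, forces)
            if step >= 10_000:
                ke.append(c.kinetic_energy())
        expected = 0.5 * UNITS.boltzmann_constant * 350.0
        assert np.mean(ke) == pytest.approx(expected, rel=0.1)


class TestSamplingMD:
    def test_immediate_termination_when_seed_exceeds_threshold(
        self, small_mb_ensemble, mb_initial_dataset
    ):
        config = mb_initial_dataset.samples[0].configuration
        result = run_sampling_md(
            small_mb_ensemble,
            BiasParams(A=1.0, B=0.5),
            config,
            ThermostatParams(seed=0),
            threshold=1e-9,
            max_steps=100,
        )
        assert result.termination == "threshold_met"
        assert result.steps_run == 0
        assert result.selected_index == 0

    def test_unreachable_threshold_runs_full_budget(
        self, small_mb_ensemble, mb_initial_dataset
    ):
        result = run_sampling_md(
            small_mb_ensemble,
            BiasParams(A=1.0, B=0.5, active=False),
            mb_initial_dataset.samples[0].configuration,
            ThermostatParams(seed=1),
            threshold=1e9,
            max_steps=300,
        )
        assert result.termination == "step_limit"
        assert result.steps_run == 300
        # selected frame is the stored max-ρ frame
        assert result.rhos[result.selected_index] == result.rhos.max()
        # earliest-index tie-break: no earlier stored frame attains the max
        first = int(np.flatnonzero(result.rhos == result.rhos.max())[0])
        assert result.selected_index == first

    def test_stored_rho_consistent_with_member_energies(
        self, small_mb_ensemble, mb_initial_dataset
    ):
        result = run_sampling_md(
            small_mb_ensemble,
            BiasParams(A=5.0, B=0.8),
            mb_initial_dataset.samples[2].configuration,
            ThermostatParams(seed=5),
            threshold=1e9,
            max_steps=200,
        )
        n_atoms = 1
        for r, me in zip(result.rhos, result.member_energies):
            sigma = math.sqrt(energy_variance(me))
            assert abs(r - rho(sigma, len(me), n_atoms)) <= 1e-12

    def test_threshold_met_selection_satisfies_threshold(
        self, small_mb_ensemble, mb_initial_dataset
    ):
        thr = 0.25
        for seed in range(4):
            result = run_sampling_md(
                small_mb_ensemble,
                BiasParams(A=10.0, B=1.0),
                mb_initial_dataset.samples[seed].configuration,
                ThermostatParams(seed=seed),
                threshold=thr,
                max_steps=2_000,
            )
            if result.termination == "threshold_met":
                assert result.rhos[result.selected_index] >= thr

    def test_inactive_bias_matches_plain_md_bitwise(
        self, small_mb_ensemble, mb_initial_dataset
    ):
        config = mb_initial_dataset.samples[1].configuration
        thermostat = ThermostatParams(seed=77)
        sampled = run_sampling_md(
            small_mb_ensemble,
            BiasParams(A=37.0, B=2.0, active=False),
            config,
            thermostat,
            threshold=1e9,
            max_steps=500,
        )
        plain = run_md(small_mb_ensemble, config, thermostat, 500)
        by_step = {s: f.positions for s, f in zip(plain.step_indices, plain.frames)}
        common = [s for s in sampled.step_indices if s in by_step]
        assert len(common) >= 50
        for s, f in zip(sampled.step_indices, sampled.frames):
            if s in by_step:
                assert np.array_equal(f.positions, by_step[s])

    def test_escalation_raises_A_after_budget_fraction(
        self, small_mb_ensemble, mb_initial_dataset
    ):
        params = BiasParams(
            A=2.0, B=5.0, active=True, escalation_fraction=0.5, escalation_factor=1.15
        )
        result = run_sampling_md(
            small_mb_ensemble,
            params,
            mb_initial_dataset.samples[0].configuration,
            ThermostatParams(seed=8),
            threshold=1e9,
            max_steps=100,
        )
        hist = np.array(result.bias_history)
        assert hist[0] == 2.0
        assert hist[-1] == pytest.approx(2.3)
        assert np.all(hist[49:] == pytest.approx(2.3))
        assert params.A == 2.0  # caller's params untouched


class TestMetadynamics:
    def make_state(self, widths=(0.2,), tau=10):
        return MetadynamicsState(
            cv_definitions=[CoordinateCV(0, 0)],
            widths=np.array(widths),
            height=1.5,
            deposition_interval=tau,
        )

    def test_empty_history_is_zero(self):
        assert metadynamics_energy([0.3], self.make_state()) == 0.0

    def test_value_at_deposit_center_is_height(self):
        state = self.make_state()
        state.deposit(np.array([0.4]))
        assert metadynamics_energy([0.4], state) == pytest.approx(1.5, abs=1e-15)

    def test_one_width_displacement(self):
        state = self.make_state(widths=(0.2,))
        state.deposit(np.array([0.0]))
        expected = 1.5 * math.exp(-0.5)
        assert metadynamics_energy([0.2], state) == pytest.approx(expected, abs=1e-12)

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError):
            MetadynamicsState(
                cv_definitions=[CoordinateCV(0, 0)],
                widths=np.array([0.0]),
                height=1.0,
                deposition_interval=5,
            )

    def test_deposit_count_is_floor_steps_over_tau(self, mb):
        config = mb.default_seed_configuration()
        thermostat = ThermostatParams(temperature=300.0, dt=0.5, seed=2)
        _, state = run_metadynamics(
            mb, [CoordinateCV(0, 0)], 0.3, [0.1], 7, thermostat, config, 100
        )
        assert len(state.centers) == 100 // 7

    def test_zero_height_matches_unbiased_md_bitwise(self, mb):
        config = mb.default_seed_configuration()
        thermostat = ThermostatParams(temperature=300.0, dt=0.5, seed=6)
        meta, _ = run_metadynamics(
            mb, [CoordinateCV(0, 0)], 0.0, [0.1], 10, thermostat, config, 200
        )
        plain = run_md(mb, config, thermostat, 200)
        for a, b in zip(meta.frames, plain.frames):
            assert np.array_equal(a.positions, b.positions)

    def test_metadynamics_promotes_double_well_crossings(self, dw):
        """Filling the seeded well drives proton transfer that plain
        low-temperature dynamics essentially never shows."""
        from uddal.analysis import count_crossings

        config = dw.default_seed_configuration()
        cv = BondDifferenceCV(0, 1, 2)
        crossings_meta, crossings_plain = [], []
        for seed in range(6):
            thermostat = ThermostatParams(temperature=350.0, dt=0.5, seed=100 + seed)
            meta, _ = run_metadynamics(
                dw, [cv], 0.4, [0.15], 100, thermostat, config, 20_000,
                store_stride=1_000,
            )
            plain_meta, _ = run_metadynamics(
                dw, [cv], 0.0, [0.15], 100, thermostat, config, 20_000,
                store_stride=1_000,
            )
            crossings_meta.append(count_crossings(meta.cv_history[:, 0], -0.3, 0.3))
            crossings_plain.append(
                count_crossings(plain_meta.cv_history[:, 0], -0.3, 0.3)
            )
        assert np.median(crossings_meta) > np.median(crossings_plain)
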