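"""Core bias mathematics: variance, ρ, bias energy/forces, B calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uddal import (
    BiasParams,
    bias_energy,
    bias_forces,
    biased_energy_forces,
    calibrate_bias_width,
    energy_variance,
    force_ratio,
    rho,
)
from uddal.ensemble import EnsemblePrediction


def make_prediction(member_energies, member_forces):
    e = np.asarray(member_energies, dtype=float)
    f = np.asarray(member_forces, dtype=float)
    return EnsemblePrediction(
        member_energies=e,
        member_forces=f,
        mean_energy=float(e.mean()),
        mean_forces=f.mean(axis=0),
    )


finite_energies = st.lists(
    st.floats(-50, 50, allow_nan=False), min_size=2, max_size=12
)


class TestVariance:
    def test_identical_members_have_zero_variance(self):
        assert energy_variance([3.3] * 8) == 0.0

    def test_one_through_eight(self):
        # mean 4.5, Σ(dev²) = 42, halved -> 21
        assert energy_variance(np.arange(1.0, 9.0)) == pytest.approx(21.0, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(finite_energies, st.floats(-100, 100, allow_nan=False))
    def test_translation_invariance(self, energies, shift):
        a = energy_variance(energies)
        b = energy_variance(np.asarray(energies) + shift)
        assert b == pytest.approx(a, rel=1e-9, abs=1e-9)

    def test_requires_two_members(self):
        with pytest.raises(ValueError):
            energy_variance([1.0])


class TestRho:
    def test_printed_worked_value(self):
        assert rho(0.15, 8, 10) == pytest.approx(0.0237, abs=5e-4)

    def test_zero_spread_gives_zero(self):
        assert rho(0.0, 8, 10) == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(finite_energies, st.integers(1, 30))
    def test_equals_population_std_over_sqrt_atoms(self, energies, n_atoms):
        e = np.asarray(energies)
        sigma = math.sqrt(energy_variance(e))
        via_formula = rho(sigma, len(e), n_atoms)
        via_std = float(e.std()) / math.sqrt(n_atoms)
        assert abs(via_formula - via_std) <= 1e-12 * max(1.0, via_std)


class TestBiasEnergy:
    def test_zero_uncertainty_gives_exactly_zero(self):
        assert bias_energy(0.0, BiasParams(A=15.4, B=0.12), 8, 10) == 0.0

    def test_large_uncertainty_approaches_minus_A(self):
        e = bias_energy(100.0, BiasParams(A=15.4, B=0.12), 8, 10)
        assert e == pytest.approx(-15.4, abs=1e-6)

    def test_near_minimum_worked_value(self):
        e = bias_energy(0.15**2, BiasParams(A=15.4, B=0.12), 8, 10)
        assert e == pytest.approx(-0.298, abs=1e-3)
        assert 15.4 + e == pytest.approx(15.1, abs=0.05)

    def test_inactive_returns_zero(self):
        p = BiasParams(A=15.4, B=0.12, active=False)
        assert bias_energy(5.0, p, 8, 10) == 0.0

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError):
            BiasParams(A=1.0, B=0.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.floats(0, 1e4, allow_nan=False),
        st.floats(0, 1e4, allow_nan=False),
        st.floats(0.1, 50, allow_nan=False),
        st.floats(0.01, 5, allow_nan=False),
    )
    def test_monotone_nonincreasing_and_bounded(self, s1, s2, A, B):
        p = BiasParams(A=A, B=B)
        lo, hi = sorted((s1, s2))
        e_lo, e_hi = bias_energy(lo, p, 8, 4), bias_energy(hi, p, 8, 4)
        assert e_hi <= e_lo + 1e-12
        for e in (e_lo, e_hi):
            # mathematically E_bias ∈ (−A, 0]; the lower bound is attained
            # in floating point once the exponential underflows
            assert -A <= e <= 0.0


class TestBiasForces:
    def test_identical_members_give_zero_force(self):
        pred = make_prediction([2.0] * 6, np.tile(np.ones((1, 2, 3)), (6, 1, 1)))
        f = bias_forces(pred, BiasParams(A=5.0, B=0.3))
        assert np.array_equal(f, np.zeros((2, 3)))

    def test_matches_finite_differences_of_composed_map(
        self, small_mb_ensemble, mb_initial_dataset
    ):
        """Analytic F_bias equals central differences of r -> E_bias(σ_E²(r))."""
        params = BiasParams(A=10.0, B=0.8)
        ens = small_mb_ensemble
        h = 1e-5

        def e_bias_at(config):
            pred = ens.predict(config)
            return bias_energy(
                energy_variance(pred.member_energies), params, pred.n_members, 1
            )

        for k in (0, 11, 60, 111):
            config = mb_initial_dataset.samples[k].configuration
            pred = ens.predict(config)
            f = bias_forces(pred, params)
            for d in range(2):
                cp, cm = config.copy(), config.copy()
                cp.positions[0, d] += h
                cm.positions[0, d] -= h
                fd = -(e_bias_at(cp) - e_bias_at(cm)) / (2 * h)
                assert fd == pytest.approx(f[0, d], rel=1e-5, abs=1e-8)

    def test_pushes_uphill_in_uncertainty(self, small_mb_ensemble, mb_initial_dataset):
        """F_bias projects non-negatively onto ∇σ_E² everywhere tested."""
        params = BiasParams(A=10.0, B=0.8)
        ens = small_mb_ensemble
        h = 1e-5
        for k in range(0, 125, 10):
            config = mb_initial_dataset.samples[k].configuration
            f = bias_forces(ens.predict(config), params)
            grad = np.zeros(2)
            for d in range(2):
                cp, cm = config.copy(), config.copy()
                cp.positions[0, d] += h
                cm.positions[0, d] -= h
                sp = energy_variance(ens.predict(cp).member_energies)
                sm = energy_variance(ens.predict(cm).member_energies)
                grad[d] = (sp - sm) / (2 * h)
            assert float(f[0, :2] @ grad) >= -1e-10


class TestCombinedSurface:
    def test_zero_magnitude_equals_plain_mean(self, small_mb_ensemble, mb_initial_dataset):
        config = mb_initial_dataset.samples[5].configuration
        pred = small_mb_ensemble.predict(config)
        e, f = biased_energy_forces(pred, BiasParams(A=0.0, B=0.5))
        assert e == pred.mean_energy
        assert np.array_equal(f, pred.mean_forces)

    def test_total_forces_match_finite_differences(
        self, small_mb_ensemble, mb_initial_dataset
    ):
        params = BiasParams(A=10.0, B=0.8)
        ens = small_mb_ensemble
        config = mb_initial_dataset.samples[20].configuration
        _, f = biased_energy_forces(ens.predict(config), params)
        h = 1e-5
        for d in range(2):
            cp, cm = config.copy(), config.copy()
            cp.positions[0, d] += h
            cm.positions[0, d] -= h
            ep, _ = biased_energy_forces(ens.predict(cp), params)
            em, _ = biased_energy_forces(ens.predict(cm), params)
            assert -(ep - em) / (2 * h) == pytest.approx(f[0, d], rel=1e-5, abs=1e-8)

    def test_energy_lowered_by_at_most_A(self, small_mb_ensemble, mb_initial_dataset):
        params = BiasParams(A=3.0, B=0.2)
        for k in (0, 40, 80):
            pred = small_mb_ensemble.predict(
                mb_initial_dataset.samples[k].configuration
            )
            e, _ = biased_energy_forces(pred, params)
            assert pred.mean_energy - params.A < e <= pred.mean_energy


class TestForceRatio:
    def test_zero_bias_gives_zero(self):
        f = np.ones((4, 3))
        assert force_ratio([(np.zeros((4, 3)), f)]) == 0.0

    def test_equal_fields_give_one(self):
        f = np.random.default_rng(0).normal(0, 1, (4, 3))
        assert force_ratio([(f, f)]) == pytest.approx(1.0, rel=1e-12)

    def test_two_atom_average(self):
        f_true = np.array([[1.0, 0, 0], [2.0, 0, 0]])
        f_bias = np.array([[0.2, 0, 0], [1.2, 0, 0]])
        assert force_ratio([(f_bias, f_true)]) == pytest.approx(0.4, abs=1e-12)

    def test_all_atoms_excluded_is_an_error(self):
        with pytest.raises(ValueError, match="excluded"):
            force_ratio([(np.ones((2, 3)), np.zeros((2, 3)))])


def _synthetic_calibration_set(seed=0, n=40, n_members=8, n_atoms=3):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        e = rng.normal(0, 0.5, n_members)
        f = rng.normal(0, 2.0, (n_members, n_atoms, 3))
        f_true = rng.normal(0, 5.0, (n_atoms, 3))
        out.append((make_prediction(e, f), f_true))
    return out


class TestCalibration:
    def test_reproduces_target_ratio(self):
        samples = _synthetic_calibration_set()
        B, ok = calibrate_bias_width(samples, params_A=10.0, target_r=0.36)
        assert ok
        params = BiasParams(A=10.0, B=B)
        r = force_ratio([(bias_forces(p, params), ft) for p, ft in samples])
        assert r == pytest.approx(0.36, rel=0.05)

    def test_doubling_A_recalibrates_to_same_ratio(self):
        samples = _synthetic_calibration_set()
        B1, _ = calibrate_bias_width(samples, params_A=10.0, target_r=0.36)
        B2, _ = calibrate_bias_width(samples, params_A=20.0, target_r=0.36)
        for A, B in ((10.0, B1), (20.0, B2)):
            r = force_ratio(
                [(bias_forces(p, BiasParams(A=A, B=B)), ft) for p, ft in samples]
            )
            assert r == pytest.approx(0.36, rel=0.05)

    def test_zero_target_returns_upper_bound_with_warning(self):
        samples = _synthetic_calibration_set()
        with pytest.warns(UserWarning):
            B, ok = calibrate_bias_width(samples, params_A=10.0, target_r=0.0)
        assert not ok
        assert B == 1e3

    def test_unreachable_target_flags_failure(self):
        samples = _synthetic_calibration_set()
        with pytest.warns(UserWarning):
            _, ok = calibrate_bias_width(samples, params_A=1e-6, target_r=0.36)
        assert not ok
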