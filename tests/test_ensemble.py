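"""Committee structure, training determinism, fit quality, and prediction."""

import numpy as np
import pytest

from uddal import (
    Configuration,
    Dataset,
    LabeledSample,
    TrainingConfig,
    make_cv_splits,
    train_ensemble,
)
from uddal.ensemble import load_ensemble, save_ensemble


class TestCVSplits:
    def test_even_split_16_into_8(self):
        folds = make_cv_splits(16, 8, seed=0)
        sizes = np.bincount(folds, minlength=8)
        assert np.all(sizes == 2)
        assert set(folds) == set(range(8))

    def test_uneven_split_17_into_8(self):
        sizes = np.bincount(make_cv_splits(17, 8, seed=0), minlength=8)
        assert sorted(sizes) == [2] * 7 + [3]

    def test_deterministic_under_seed(self):
        assert np.array_equal(make_cv_splits(40, 8, 3), make_cv_splits(40, 8, 3))
        assert not np.array_equal(make_cv_splits(40, 8, 3), make_cv_splits(40, 8, 4))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            make_cv_splits(5, 8, 0)


def _linear_dataset(n=150, seed=5):
    rng = np.random.default_rng(seed)
    a, b = np.array([1.3, -0.7]), 0.4
    samples = []
    for _ in range(n):
        xy = rng.uniform(-1, 1, 2)
        pos = np.zeros((1, 3))
        pos[0, :2] = xy
        f = np.zeros((1, 3))
        f[0, :2] = -a
        samples.append(
            LabeledSample(
                Configuration(species=["X"], positions=pos),
                energy=float(a @ xy + b),
                forces=f,
            )
        )
    return Dataset(samples, [0] * n)


def test_simple_target_gives_tight_committee_agreement():
    """A smooth, low-complexity energy function is fit by every member, so
    the in-domain committee spread collapses."""
    ds = _linear_dataset()
    ens = train_ensemble(
        ds, TrainingConfig(seed=3, max_epochs=2000), n_members=8, hidden_sizes=(16, 8)
    )
    sigmas = [ens.sigma(s.configuration) for s in ds.samples[::5]]
    assert np.median(sigmas) < 1e-2


def test_training_is_deterministic():
    ds = _linear_dataset(n=40)
    kw = dict(n_members=3, hidden_sizes=(8, 4))
    e1 = train_ensemble(ds, TrainingConfig(seed=9, max_epochs=40), **kw)
    e2 = train_ensemble(ds, TrainingConfig(seed=9, max_epochs=40), **kw)
    for m1, m2 in zip(e1.members, e2.members):
        for W1, W2 in zip(m1.weights_, m2.weights_):
            assert np.array_equal(W1, W2)
    e3 = train_ensemble(ds, TrainingConfig(seed=10, max_epochs=40), **kw)
    assert not np.array_equal(e1.members[0].weights_[0], e3.members[0].weights_[0])


def test_hold_one_out_structure(mb_ensemble):
    """Every sample is held out of exactly one member's training folds."""
    folds = mb_ensemble.cv_assignment
    member_folds = [m.fold_index for m in mb_ensemble.members]
    assert sorted(member_folds) == list(range(8))
    for i, f in enumerate(folds):
        holders = [j for j in member_folds if j == f]
        assert len(holders) == 1


def test_dataset_too_small_rejected():
    ds = _linear_dataset(n=10)
    with pytest.raises(ValueError, match="too small"):
        train_ensemble(ds, TrainingConfig(seed=0, max_epochs=5), n_members=8)


class TestPrediction:
    def test_means_are_arithmetic_means(self, small_mb_ensemble, mb_initial_dataset):
        pred = small_mb_ensemble.predict(mb_initial_dataset.samples[3].configuration)
        assert pred.mean_energy == pytest.approx(
            float(pred.member_energies.mean()), rel=1e-12
        )
        assert np.allclose(
            pred.mean_forces, pred.member_forces.mean(axis=0), rtol=1e-12, atol=0
        )

    def test_member_forces_match_finite_differences(
        self, small_mb_ensemble, mb_initial_dataset
    ):
        config = mb_initial_dataset.samples[7].configuration
        pred = small_mb_ensemble.predict(config)
        h = 1e-5
        for d in range(2):  # z is frozen for the planar toy
            cp, cm = config.copy(), config.copy()
            cp.positions[0, d] += h
            cm.positions[0, d] -= h
            ep = small_mb_ensemble.predict(cp).member_energies
            em = small_mb_ensemble.predict(cm).member_energies
            fd = -(ep - em) / (2 * h)
            assert np.allclose(fd, pred.member_forces[:, 0, d], rtol=1e-5, atol=1e-7)

    def test_descriptor_mismatch_rejected(self, small_mb_ensemble):
        c3 = Configuration(species=["O", "H", "O"], positions=np.eye(3))
        with pytest.raises(ValueError):
            small_mb_ensemble.predict(c3)

    def test_uncertainty_grows_out_of_domain(self, mb_ensemble, mb_initial_dataset, mb):
        """Committee spread far from the training data exceeds the in-domain
        median — the premise that disagreement flags extrapolation."""
        in_domain = np.median(
            [mb_ensemble.sigma(s.configuration) for s in mb_initial_dataset.samples[::5]]
        )
        far = mb.default_seed_configuration()
        far.positions = far.positions.copy()
        far.positions[0, :2] = [1.4, -0.3]  # far corner of the landscape
        assert mb_ensemble.sigma(far) > in_domain


def test_serialization_roundtrip(tmp_path, small_mb_ensemble, mb_initial_dataset):
    save_ensemble(small_mb_ensemble, tmp_path / "ens")
    back = load_ensemble(tmp_path / "ens")
    config = mb_initial_dataset.samples[0].configuration
    a = small_mb_ensemble.predict(config)
    b = back.predict(config)
    assert np.array_equal(a.member_energies, b.member_energies)
    assert np.array_equal(a.member_forces, b.member_forces)
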