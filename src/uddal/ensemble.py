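"""Query-by-committee ensembles of small energy/force regressors.

The committee is built the standard way for neural-network potentials: a
k-fold cross-validation split of the dataset yields k members (default
N_M = 8), each trained with its own weight-initialisation seed on all folds
but one, the retained data further divided 14:1:1 into train/validation/test.
Ensemble disagreement on a configuration is the uncertainty signal the whole
method runs on.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core_io import Configuration, Dataset
from .descriptors import Descriptor, InverseDistances, PlanarCoordinates, make_descriptor
from .mlp import MLPSurrogate, TrainingConfig

__all__ = [
    "TrainingConfig",
    "EnsemblePrediction",
    "Ensemble",
    "make_cv_splits",
    "train_ensemble",
    "save_ensemble",
    "load_ensemble",
]


@dataclass
class EnsemblePrediction:
    """All member predictions for one configuration, plus their means."""

    member_energies: np.ndarray  # (N_M,), kcal/mol
    member_forces: np.ndarray  # (N_M, N_A, 3), kcal/mol/Å
    mean_energy: float
    mean_forces: np.ndarray  # (N_A, 3)

    @property
    def n_members(self) -> int:
        return len(self.member_energies)

    @property
    def n_atoms(self) -> int:
        return self.member_forces.shape[1]


def make_cv_splits(n_samples: int, k: int, seed: int) -> np.ndarray:
    """Assign each sample to exactly one of ``k`` folds, sizes within 1.

    Member ``j`` later trains on every fold except ``j`` (hold-one-out
    committee structure).  Deterministic under ``seed``.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    if n_samples < k:
        raise ValueError(f"cannot split {n_samples} samples into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_samples)
    folds = np.empty(n_samples, dtype=int)
    folds[order] = np.arange(n_samples) % k
    return folds


class Ensemble:
    """A trained committee with shared descriptor and target scaling.

    Member evaluation is vectorised: all members share one architecture, so
    their weights are stacked and every member is evaluated in a single pass
    per MD step.
    """

    def __init__(
        self,
        members: list[MLPSurrogate],
        descriptor: Descriptor,
        cv_assignment: np.ndarray,
        feature_mean: np.ndarray,
        feature_std: np.ndarray,
        energy_offset: float,
        energy_scale: float,
        master_seed: int = 0,
    ):
        if len(members) < 2:
            raise ValueError("an ensemble needs at least 2 members")
        self.members = members
        self.descriptor = descriptor
        self.cv_assignment = np.asarray(cv_assignment, dtype=int)
        self.feature_mean = np.asarray(feature_mean, dtype=float)
        self.feature_std = np.asarray(feature_std, dtype=float)
        self.energy_offset = float(energy_offset)
        self.energy_scale = float(energy_scale)
        self.master_seed = int(master_seed)
        self._stacked: list[tuple[np.ndarray, np.ndarray]] | None = None

    @property
    def n_members(self) -> int:
        return len(self.members)

    def frozen_mask(self, config: Configuration) -> np.ndarray | None:
        return self.descriptor.frozen_mask(config)

    def _stack(self) -> list[tuple[np.ndarray, np.ndarray]]:
        if self._stacked is None:
            self._stacked = [
                (
                    np.stack([m.weights_[l] for m in self.members]),
                    np.stack([m.biases_[l] for m in self.members]),
                )
                for l in range(len(self.members[0].weights_))
            ]
        return self._stacked

    def predict(self, config: Configuration) -> EnsemblePrediction:
        """Evaluate every member on one configuration; populate the means."""
        feat, jac = self.descriptor.transform(config)
        if feat.shape[0] != self.feature_mean.shape[0]:
            raise ValueError(
                "descriptor dimensionality does not match the training descriptor"
            )
        xs = (feat - self.feature_mean) / self.feature_std
        # Jeff[d, a, c]: net-space gradient -> real-space force contribution
        jeff = self.energy_scale * jac / self.feature_std[:, None, None]

        stacked = self._stack()
        M = self.n_members
        a = np.broadcast_to(xs, (M, xs.shape[0]))
        zs, phis, acts = [], [], [a]
        for W, b in stacked[:-1]:
            z = np.einsum("moi,mi->mo", W, a) + b
            p = np.exp(-(z**2))
            zs.append(z)
            phis.append(p)
            a = p
            acts.append(a)
        W_out, b_out = stacked[-1]
        e_net = np.einsum("moi,mi->mo", W_out, a)[:, 0] + b_out[:, 0]

        delta = W_out[:, 0, :].copy()  # (M, n_last)
        for (W, _), z, p in zip(reversed(stacked[:-1]), reversed(zs), reversed(phis)):
            dz = (-2.0 * z * p) * delta
            delta = np.einsum("mo,moi->mi", dz, W)
        # member forces: F_i = −Σ_d g_id · Jeff[d]
        member_forces = -np.einsum("md,dac->mac", delta, jeff)
        member_energies = e_net * self.energy_scale + self.energy_offset

        return EnsemblePrediction(
            member_energies=member_energies,
            member_forces=member_forces,
            mean_energy=float(member_energies.mean()),
            mean_forces=member_forces.mean(axis=0),
        )

    def mean_energy_forces(self, config: Configuration) -> tuple[float, np.ndarray]:
        pred = self.predict(config)
        return pred.mean_energy, pred.mean_forces

    def __call__(self, config: Configuration) -> tuple[float, np.ndarray]:
        """Energy/force-provider contract: the plain ensemble-mean surface.

        Applies the same frozen-degree-of-freedom masking as the sampling
        driver, so unbiased-MD trajectories are bit-identical to sampling-MD
        trajectories with an inactive bias under the same seed.
        """
        pred = self.predict(config)
        forces = pred.mean_forces
        mask = self.frozen_mask(config)
        if mask is not None:
            forces = np.where(mask, 0.0, forces)
        return pred.mean_energy, forces

    def sigma(self, config: Configuration) -> float:
        """Ensemble energy spread σ_E (kcal/mol) at a configuration."""
        from .uncertainty_bias import energy_variance

        return float(np.sqrt(energy_variance(self.predict(config).member_energies)))


def _prepare_arrays(dataset: Dataset, descriptor: Descriptor):
    X, J, E, F = [], [], [], []
    for s in dataset.samples:
        feat, jac = descriptor.transform(s.configuration)
        X.append(feat)
        J.append(jac.reshape(jac.shape[0], -1))
        E.append(s.energy)
        F.append(s.forces.ravel())
    return (np.array(X), np.array(J), np.array(E), np.array(F))


def train_ensemble(
    dataset: Dataset,
    config: TrainingConfig | None = None,
    n_members: int = 8,
    descriptor: Descriptor | None = None,
    hidden_sizes=(32, 16, 8),
) -> Ensemble:
    """Train a hold-one-out committee on a labeled dataset.

    One master seed (``config.seed``) fans out to the CV shuffle and the
    per-member weight-initialisation seeds, so retraining with the same seed
    is bit-identical.  Members whose training diverges are dropped with a
    warning; fewer than two survivors is an error.
    """
    config = config or TrainingConfig()
    n = len(dataset)
    if n < 2 * n_members:
        raise ValueError(
            f"dataset of {n} samples is too small for {n_members} members "
            f"(need at least {2 * n_members})"
        )
    if descriptor is None:
        descriptor = make_descriptor(dataset.samples[0].configuration)

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(n_members + 1)
    cv_seed = int(children[0].generate_state(1)[0] & 0x7FFFFFFF)
    member_seeds = [int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in children[1:]]

    folds = make_cv_splits(n, n_members, cv_seed)
    X, Jf, E, F = _prepare_arrays(dataset, descriptor)

    feature_mean = X.mean(axis=0)
    feature_std = np.maximum(X.std(axis=0), 1e-8)
    energy_offset = float(E.mean())
    energy_scale = float(E.std()) if E.std() > 1e-8 else 1.0

    Xs = (X - feature_mean) / feature_std
    yE = (E - energy_offset) / energy_scale
    # Jeff maps the net-space input gradient to real-space forces
    Jeff = energy_scale * Jf / feature_std[None, :, None]
    # net-space energy loss is rescaled; real-space force loss is kept by
    # folding the scale into Jeff targets: train on yE (scaled) + F (real),
    # with Jeff providing consistency between the two spaces.
    F_scaled = F / energy_scale
    Jeff_scaled = Jeff / energy_scale

    members: list[MLPSurrogate] = []
    r_tr, r_val, r_te = config.split_ratio
    denom = r_tr + r_val + r_te
    for j in range(n_members):
        retained = np.flatnonzero(folds != j)
        rng = np.random.default_rng(member_seeds[j] ^ 0x5DEECE66)
        retained = rng.permutation(retained)
        n_ret = len(retained)
        n_val = max(1, int(round(n_ret * r_val / denom))) if n_ret >= 4 else 0
        n_test = max(1, int(round(n_ret * r_te / denom))) if n_ret >= 4 else 0
        train_idx = retained[: n_ret - n_val - n_test]
        val_idx = retained[n_ret - n_val - n_test : n_ret - n_test]
        model = MLPSurrogate(
            hidden_sizes=hidden_sizes, seed=member_seeds[j], fold_index=j
        )
        try:
            model.fit(
                Xs[train_idx],
                yE[train_idx],
                Jeff_scaled[train_idx],
                F_scaled[train_idx],
                config,
                X_val=Xs[val_idx] if n_val else None,
                yE_val=yE[val_idx] if n_val else None,
                Jeff_val=Jeff_scaled[val_idx] if n_val else None,
                F_val=F_scaled[val_idx] if n_val else None,
            )
        except FloatingPointError as exc:
            warnings.warn(f"ensemble member {j} aborted: {exc}", stacklevel=2)
            continue
        members.append(model)
    if len(members) < 2:
        raise RuntimeError("fewer than two ensemble members trained successfully")
    return Ensemble(
        members=members,
        descriptor=descriptor,
        cv_assignment=folds,
        feature_mean=feature_mean,
        feature_std=feature_std,
        energy_offset=energy_offset,
        energy_scale=energy_scale,
        master_seed=config.seed,
    )


def save_ensemble(ensemble: Ensemble, directory) -> None:
    """Serialize an ensemble: one weights file per member + JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, m in enumerate(ensemble.members):
        np.savez(directory / f"member_{i}.npz", **m.to_arrays())
    desc = ensemble.descriptor
    manifest = {
        "n_members": ensemble.n_members,
        "member_seeds": [m.seed for m in ensemble.members],
        "member_folds": [m.fold_index for m in ensemble.members],
        "hidden_sizes": list(ensemble.members[0].hidden_sizes),
        "cv_assignment": ensemble.cv_assignment.tolist(),
        "feature_mean": ensemble.feature_mean.tolist(),
        "feature_std": ensemble.feature_std.tolist(),
        "energy_offset": ensemble.energy_offset,
        "energy_scale": ensemble.energy_scale,
        "master_seed": ensemble.master_seed,
        "descriptor": {
            "name": desc.name,
            "n_atoms": getattr(desc, "n_atoms", 1),
        },
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_ensemble(directory) -> Ensemble:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    dspec = manifest["descriptor"]
    if dspec["name"] == "planar_coordinates":
        descriptor: Descriptor = PlanarCoordinates()
    elif dspec["name"] == "inverse_distances":
        descriptor = InverseDistances(dspec["n_atoms"])
    else:
        raise ValueError(f"unknown descriptor {dspec['name']!r}")
    members = []
    for i in range(manifest["n_members"]):
        arrays = dict(np.load(directory / f"member_{i}.npz"))
        members.append(
            MLPSurrogate.from_arrays(
                arrays,
                hidden_sizes=tuple(manifest["hidden_sizes"]),
                seed=manifest["member_seeds"][i],
                fold_index=manifest["member_folds"][i],
            )
        )
    return Ensemble(
        members=members,
        descriptor=descriptor,
        cv_assignment=np.array(manifest["cv_assignment"]),
        feature_mean=np.array(manifest["feature_mean"]),
        feature_std=np.array(manifest["feature_std"]),
        energy_offset=manifest["energy_offset"],
        energy_scale=manifest["energy_scale"],
        master_seed=manifest["master_seed"],
    )
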