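"""Small fully-connected energy regressors with exact analytic forces.

Each surrogate maps a feature vector to a scalar energy through hidden
layers with Gaussian activations, φ(z) = exp(−z²), and a linear output.
Forces are the exact negative gradient of the predicted energy with respect
to atomic positions, obtained by back-propagating through the network and
chain-ruling through the descriptor Jacobian.

Training minimises

    L = MSE(energy) + w_F · MSE(force components)

with Adam.  The gradient of the force term with respect to the weights is a
double-backpropagation quantity; it is computed exactly here by a
tangent-augmented forward pass followed by a reverse pass (no finite
differences anywhere in training).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TrainingConfig", "MLPSurrogate"]


@dataclass
class TrainingConfig:
    """Optimisation schedule for one surrogate.

    Defaults follow the standard small-potential recipe: lr 1e-3, batch 32,
    early stopping with 50-epoch patience, learning-rate annealing by 0.5 on
    each stop, termination once the learning rate falls below 1e-5, Adam.
    ``split_ratio`` divides each member's retained data 14:1:1 into
    train/validation/test.  ``max_epochs`` bounds the total epoch count
    across annealing stages (the schedule alone is open-ended).
    """

    initial_lr: float = 1e-3
    batch_size: int = 32
    patience_epochs: int = 50
    annealing_factor: float = 0.5
    min_lr: float = 1e-5
    split_ratio: tuple[int, int, int] = (14, 1, 1)
    optimizer: str = "adam"
    force_weight: float = 1.0
    max_epochs: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.annealing_factor < 1.0):
            raise ValueError("annealing_factor must lie in (0, 1)")
        if self.min_lr >= self.initial_lr:
            raise ValueError("min_lr must be below initial_lr")
        if self.optimizer.lower() != "adam":
            raise ValueError("only the adam optimizer is supported")


def _phi(z):
    return np.exp(-(z**2))


def _phi_prime(z, phi):
    return -2.0 * z * phi


def _phi_second(z, phi):
    return (4.0 * z**2 - 2.0) * phi


class MLPSurrogate:
    """One committee member: an MLP energy model over a fixed descriptor.

    Parameters
    ----------
    hidden_sizes : widths of the Gaussian-activated hidden layers.
    seed : weight-initialisation seed (committee members differ in it).
    fold_index : which cross-validation fold this member holds out.
    """

    def __init__(self, hidden_sizes=(32, 16, 8), seed: int = 0, fold_index: int = -1):
        self.hidden_sizes = tuple(int(h) for h in hidden_sizes)
        self.seed = int(seed)
        self.fold_index = int(fold_index)
        self.n_features_in_: int | None = None
        self.weights_: list[np.ndarray] | None = None
        self.biases_: list[np.ndarray] | None = None
        self.history_: dict = {}

    # -- parameters ------------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "hidden_sizes": self.hidden_sizes,
            "seed": self.seed,
            "fold_index": self.fold_index,
        }

    def set_params(self, **params) -> "MLPSurrogate":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _init_weights(self, n_features: int) -> None:
        rng = np.random.default_rng(self.seed)
        sizes = (n_features, *self.hidden_sizes, 1)
        self.weights_, self.biases_ = [], []
        n_layers = len(sizes) - 1
        for li, (n_in, n_out) in enumerate(zip(sizes[:-1], sizes[1:])):
            self.weights_.append(rng.normal(0.0, 1.0 / np.sqrt(n_in), (n_out, n_in)))
            if li < n_layers - 1:
                # spread the Gaussian-unit centers: at b = 0 every unit sits
                # on the flat top of exp(−z²) and gradients vanish
                self.biases_.append(rng.normal(0.0, 0.7, n_out))
            else:
                self.biases_.append(np.zeros(n_out))
        self.n_features_in_ = n_features

    # -- forward / gradients --------------------------------------------
    def _forward(self, X: np.ndarray):
        """Forward pass; returns energies (B,) and per-layer caches."""
        a = X
        acts, zs, phis = [a], [], []
        n_hidden = len(self.hidden_sizes)
        for l in range(n_hidden):
            z = a @ self.weights_[l].T + self.biases_[l]
            p = _phi(z)
            zs.append(z)
            phis.append(p)
            a = p
            acts.append(a)
        E = a @ self.weights_[-1].T + self.biases_[-1]
        return E[:, 0], acts, zs, phis

    def predict_energy(self, X: np.ndarray) -> np.ndarray:
        E, *_ = self._forward(np.atleast_2d(X))
        return E

    def predict_with_gradient(self, X: np.ndarray):
        """Energies (B,) and input gradients dE/dX (B, D)."""
        X = np.atleast_2d(X)
        E, acts, zs, phis = self._forward(X)
        delta = np.broadcast_to(self.weights_[-1], (X.shape[0], self.weights_[-1].shape[1])).copy()
        for l in range(len(self.hidden_sizes) - 1, -1, -1):
            dz = _phi_prime(zs[l], phis[l]) * delta
            delta = dz @ self.weights_[l]
        return E, delta

    # -- training --------------------------------------------------------
    def _loss_and_grads(self, X, yE, Jeff, F, force_weight):
        """Exact loss and parameter gradients for one batch.

        Jeff : (B, D, K) effective descriptor Jacobians (already carrying any
            feature/energy scaling), K = 3·N_A flattened force components.
        F : (B, K) target forces in the same scaled space.
        """
        B = X.shape[0]
        n_hidden = len(self.hidden_sizes)
        E, acts, zs, phis = self._forward(X)

        # input gradient g = dE/dx via reverse pass
        delta = np.broadcast_to(
            self.weights_[-1], (B, self.weights_[-1].shape[1])
        ).copy()
        for l in range(n_hidden - 1, -1, -1):
            dz = _phi_prime(zs[l], phis[l]) * delta
            delta = dz @ self.weights_[l]
        g = delta  # (B, D)

        gW = [np.zeros_like(W) for W in self.weights_]
        gb = [np.zeros_like(b) for b in self.biases_]

        # --- energy term -------------------------------------------------
        err = E - yE
        loss = float(np.mean(err**2))
        ebar = (2.0 / B) * err  # (B,)
        gW[-1] += (ebar[:, None] * acts[-1]).sum(axis=0)[None, :]
        gb[-1] += np.array([ebar.sum()])
        abar = ebar[:, None] * self.weights_[-1]  # (B, n_L)
        for l in range(n_hidden - 1, -1, -1):
            zbar = _phi_prime(zs[l], phis[l]) * abar
            gW[l] += zbar.T @ acts[l]
            gb[l] += zbar.sum(axis=0)
            abar = zbar @ self.weights_[l]

        # --- force term (double backprop) --------------------------------
        if force_weight > 0.0 and Jeff is not None:
            K = F.shape[1]
            p_pred = -np.einsum("bdk,bd->bk", Jeff, g)
            resid = F - p_pred  # = Jeffᵀ g + F
            loss += force_weight * float(np.mean(resid**2))
            V = np.einsum("bdk,bk->bd", Jeff, resid) * (2.0 * force_weight / (B * K))

            # tangent forward along V (reusing cached z)
            t = V
            ts, tzs = [t], []
            for l in range(n_hidden):
                tz = t @ self.weights_[l].T
                tzs.append(tz)
                t = _phi_prime(zs[l], phis[l]) * tz
                ts.append(t)
            # h = Σ_b t_L[b]·w_out ; backprop h through the augmented graph
            gW[-1] += ts[-1].sum(axis=0)[None, :]
            tbar = np.broadcast_to(
                self.weights_[-1], (B, self.weights_[-1].shape[1])
            ).copy()
            abar = np.zeros_like(tbar)
            for l in range(n_hidden - 1, -1, -1):
                pp = _phi_prime(zs[l], phis[l])
                zbar = pp * abar + _phi_second(zs[l], phis[l]) * tzs[l] * tbar
                tzbar = pp * tbar
                gW[l] += zbar.T @ acts[l] + tzbar.T @ ts[l]
                gb[l] += zbar.sum(axis=0)
                abar = zbar @ self.weights_[l]
                tbar = tzbar @ self.weights_[l]

        return loss, gW, gb

    def _full_loss(self, X, yE, Jeff, F, force_weight) -> float:
        E, g = self.predict_with_gradient(X)
        loss = float(np.mean((E - yE) ** 2))
        if force_weight > 0.0 and Jeff is not None and len(F):
            p_pred = -np.einsum("bdk,bd->bk", Jeff, g)
            loss += force_weight * float(np.mean((F - p_pred) ** 2))
        return loss

    def fit(
        self,
        X: np.ndarray,
        yE: np.ndarray,
        Jeff: np.ndarray | None,
        F: np.ndarray | None,
        config: TrainingConfig,
        X_val=None,
        yE_val=None,
        Jeff_val=None,
        F_val=None,
    ) -> "MLPSurrogate":
        """Train with Adam under the early-stopping/annealing schedule.

        The monitored quantity is the validation energy MSE (training loss
        when no validation split exists).  When it fails to improve for
        ``patience_epochs`` epochs, training restarts from the current
        weights with the learning rate multiplied by ``annealing_factor``,
        and terminates once the rate drops below ``min_lr`` (or the total
        ``max_epochs`` budget is exhausted).  The best-validation checkpoint
        seen across all stages is restored at the end.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        yE = np.asarray(yE, dtype=float)
        if self.weights_ is None:
            self._init_weights(X.shape[1])
        has_val = X_val is not None and len(X_val) > 0
        w_F = config.force_weight

        rng = np.random.default_rng(self.seed + 7919)
        m = [np.zeros_like(W) for W in self.weights_] + [
            np.zeros_like(b) for b in self.biases_
        ]
        v = [np.zeros_like(p) for p in m]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t_adam = 0

        lr = config.initial_lr
        best_loss = np.inf
        best_W = [W.copy() for W in self.weights_]
        best_b = [b.copy() for b in self.biases_]
        stall = 0
        n = X.shape[0]
        epochs_run = 0
        monitor_history: list[float] = []

        while lr >= config.min_lr and epochs_run < config.max_epochs:
            order = rng.permutation(n)
            for start in range(0, n, config.batch_size):
                idx = order[start : start + config.batch_size]
                loss, gW, gb = self._loss_and_grads(
                    X[idx],
                    yE[idx],
                    None if Jeff is None else Jeff[idx],
                    None if F is None else F[idx],
                    w_F,
                )
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss in member seed={self.seed}"
                    )
                grads = gW + gb
                params = self.weights_ + self.biases_
                t_adam += 1
                corr1 = 1.0 - beta1**t_adam
                corr2 = 1.0 - beta2**t_adam
                for p, grad, mi, vi in zip(params, grads, m, v):
                    mi *= beta1
                    mi += (1 - beta1) * grad
                    vi *= beta2
                    vi += (1 - beta2) * grad**2
                    p -= lr * (mi / corr1) / (np.sqrt(vi / corr2) + eps)
            epochs_run += 1

            if has_val:
                monitor = float(np.mean((self.predict_energy(X_val) - yE_val) ** 2))
            else:
                monitor = float(np.mean((self.predict_energy(X) - yE) ** 2))
            monitor_history.append(monitor)
            if monitor < best_loss - 1e-12:
                best_loss = monitor
                best_W = [W.copy() for W in self.weights_]
                best_b = [b.copy() for b in self.biases_]
                stall = 0
            else:
                stall += 1
            if stall >= config.patience_epochs:
                # restart from the *current* weights at a lower rate; the
                # globally best checkpoint is restored only at the end
                lr *= config.annealing_factor
                stall = 0

        self.weights_ = best_W
        self.biases_ = best_b
        self.history_ = {
            "epochs": epochs_run,
            "best_monitor_loss": best_loss,
            "monitor": monitor_history,
            "final_lr": lr,
        }
        return self

    # -- serialization ---------------------------------------------------
    def to_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, (W, b) in enumerate(zip(self.weights_, self.biases_)):
            out[f"W{i}"] = W
            out[f"b{i}"] = b
        return out

    @classmethod
    def from_arrays(cls, arrays: dict, hidden_sizes, seed: int, fold_index: int):
        model = cls(hidden_sizes=hidden_sizes, seed=seed, fold_index=fold_index)
        n_layers = len(hidden_sizes) + 1
        model.weights_ = [np.asarray(arrays[f"W{i}"]) for i in range(n_layers)]
        model.biases_ = [np.asarray(arrays[f"b{i}"]) for i in range(n_layers)]
        model.n_features_in_ = model.weights_[0].shape[1]
        return model
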