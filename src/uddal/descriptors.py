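"""Differentiable structural descriptors mapping configurations to features.

The uncertainty-bias machinery is descriptor-agnostic; these two minimal
descriptors cover the toy systems.  Each descriptor returns both the feature
vector and its Jacobian with respect to Cartesian positions so predicted
energies can be chain-ruled into forces.
"""

from __future__ import annotations

import numpy as np

from .core_io import Configuration

__all__ = ["Descriptor", "PlanarCoordinates", "InverseDistances", "make_descriptor"]


class Descriptor:
    """Contract: transform(config) -> (features (D,), jacobian (D, N, 3))."""

    name: str = "descriptor"
    n_features: int = 0

    def transform(self, config: Configuration) -> tuple[np.ndarray, np.ndarray]:
        raise NotImplementedError

    def frozen_mask(self, config: Configuration) -> np.ndarray | None:
        return None


class PlanarCoordinates(Descriptor):
    """Raw (x, y) of a single point particle on a 2D landscape."""

    name = "planar_coordinates"
    n_features = 2

    def transform(self, config: Configuration) -> tuple[np.ndarray, np.ndarray]:
        if config.n_atoms != 1:
            raise ValueError("PlanarCoordinates expects a single-particle configuration")
        feat = config.positions[0, :2].copy()
        jac = np.zeros((2, 1, 3))
        jac[0, 0, 0] = 1.0
        jac[1, 0, 1] = 1.0
        return feat, jac

    def frozen_mask(self, config: Configuration) -> np.ndarray:
        mask = np.zeros((config.n_atoms, 3), dtype=bool)
        mask[0, 2] = True
        return mask


class InverseDistances(Descriptor):
    """Vector of inverse pairwise distances 1/r_ij (all unordered pairs).

    Translation- and rotation-invariant; suitable for small molecular toys.
    """

    name = "inverse_distances"

    def __init__(self, n_atoms: int):
        self.n_atoms = n_atoms
        self.pairs = [(i, j) for i in range(n_atoms) for j in range(i + 1, n_atoms)]
        self.n_features = len(self.pairs)

    def transform(self, config: Configuration) -> tuple[np.ndarray, np.ndarray]:
        if config.n_atoms != self.n_atoms:
            raise ValueError(
                f"descriptor built for {self.n_atoms} atoms, got {config.n_atoms}"
            )
        pos = config.positions
        feat = np.zeros(self.n_features)
        jac = np.zeros((self.n_features, self.n_atoms, 3))
        for k, (i, j) in enumerate(self.pairs):
            rij = pos[i] - pos[j]
            r = np.linalg.norm(rij)
            feat[k] = 1.0 / r
            # d(1/r)/d r_i = −r_ij / r³
            g = -rij / r**3
            jac[k, i] = g
            jac[k, j] = -g
        return feat, jac


def make_descriptor(config: Configuration) -> Descriptor:
    """Default descriptor choice: planar coordinates for one-particle 2D
    toys, inverse pairwise distances otherwise."""
    if config.n_atoms == 1:
        return PlanarCoordinates()
    return InverseDistances(config.n_atoms)
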