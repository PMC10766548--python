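"""Analytic ground-truth potentials standing in for an expensive reference method.

Two landscapes are provided, matched to the two sampling problems the
active-learning machinery is exercised on:

* :class:`MuellerBrown` — the classic 2D surface with three minima separated
  by barriers, rescaled so the barriers land in the few-kcal/mol regime of
  small-molecule conformational changes.  A single point particle moving on
  it is the desk-scale analog of a molecule exploring conformational space.
* :class:`DoubleWellBond` — a 3-atom heavy–light–heavy toy whose shared
  proton sits in a symmetric quartic double well along the heavy–heavy axis:
  the analog of an intramolecular proton-transfer reaction.

Every oracle returns analytic forces that are the exact negative gradient of
its energy; tests verify this against central finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .core_io import Configuration, Dataset, LabeledSample

__all__ = [
    "OraclePotential",
    "MuellerBrown",
    "DoubleWellBond",
    "generate_initial_dataset",
    "local_minimize",
]


class OraclePotential:
    """Callable contract: Configuration -> (energy kcal/mol, forces kcal/mol/Å).

    ``frozen_mask`` marks degrees of freedom the dynamics must not move
    (used to embed 2D point-particle landscapes in the 3D MD engine).
    """

    name: str = "oracle"

    def __call__(self, config: Configuration) -> tuple[float, np.ndarray]:
        raise NotImplementedError

    def frozen_mask(self, config: Configuration) -> np.ndarray | None:
        return None

    def default_seed_configuration(self) -> Configuration:
        raise NotImplementedError


# Literature-standard Müller–Brown constants.
_MB_A = np.array([-200.0, -100.0, -170.0, 15.0])
_MB_a = np.array([-1.0, -1.0, -6.5, 0.7])
_MB_b = np.array([0.0, 0.0, 11.0, 0.6])
_MB_c = np.array([-10.0, -10.0, -6.5, 0.7])
_MB_x0 = np.array([1.0, 0.0, -0.5, -1.0])
_MB_y0 = np.array([0.0, 0.5, 1.5, 1.0])

# Published approximate stationary points, used as starting guesses for
# numerical refinement (minima then saddles).
_MB_MINIMA_GUESS = [(-0.558, 1.442), (0.623, 0.028), (-0.050, 0.467)]
_MB_SADDLE_GUESS = [(-0.822, 0.624), (0.212, 0.293)]


def muller_brown(position, scale: float = 1.0) -> tuple[float, np.ndarray]:
    """Energy and gradient of the (optionally rescaled) Müller–Brown surface.

    The surface is the sum of four 2D exponential terms; the gradient is
    analytic.  ``scale`` multiplies the whole surface (default 1, i.e. the
    literature energy units).
    """
    x, y = float(position[0]), float(position[1])
    dx, dy = x - _MB_x0, y - _MB_y0
    terms = _MB_A * np.exp(_MB_a * dx**2 + _MB_b * dx * dy + _MB_c * dy**2)
    energy = scale * float(terms.sum())
    gx = scale * float(np.sum(terms * (2.0 * _MB_a * dx + _MB_b * dy)))
    gy = scale * float(np.sum(terms * (_MB_b * dx + 2.0 * _MB_c * dy)))
    return energy, np.array([gx, gy])


@dataclass
class MuellerBrown(OraclePotential):
    """Müller–Brown landscape as a single-particle molecular oracle.

    The particle is a unit-mass species "X" whose z coordinate is frozen at
    zero.  ``scale`` (default 0.1) rescales the surface so the two barriers
    out of the global basin are a few kcal/mol, keeping published bias
    heuristics (A of order a few times the barrier) meaningful.
    """

    scale: float = 0.1
    name: str = "muller_brown"

    def __call__(self, config: Configuration) -> tuple[float, np.ndarray]:
        if config.n_atoms != 1:
            raise ValueError("MuellerBrown expects a single-particle configuration")
        energy, grad = muller_brown(config.positions[0, :2], self.scale)
        forces = np.zeros_like(config.positions)
        forces[0, :2] = -grad
        return energy, forces

    def frozen_mask(self, config: Configuration) -> np.ndarray:
        mask = np.zeros((config.n_atoms, 3), dtype=bool)
        mask[0, 2] = True
        return mask

    def default_seed_configuration(self) -> Configuration:
        gm = self.minima()[0]
        pos = np.zeros((1, 3))
        pos[0, :2] = gm
        return Configuration(species=["X"], positions=pos, tag="mb_global_minimum")

    def minima(self) -> list[np.ndarray]:
        """The three local minima, refined numerically, global first."""
        pts = []
        for guess in _MB_MINIMA_GUESS:
            res = minimize(
                lambda p: muller_brown(p, self.scale)[0],
                np.asarray(guess, dtype=float),
                jac=lambda p: muller_brown(p, self.scale)[1],
                method="BFGS",
                tol=1e-12,
            )
            pts.append(res.x)
        pts.sort(key=lambda p: muller_brown(p, self.scale)[0])
        return pts

    def saddles(self) -> list[np.ndarray]:
        """The two first-order saddle points (gradient roots), lowest first."""
        from scipy.optimize import root

        pts = []
        for guess in _MB_SADDLE_GUESS:
            res = root(
                lambda p: muller_brown(p, self.scale)[1],
                np.asarray(guess, dtype=float),
                tol=1e-12,
            )
            pts.append(res.x)
        pts.sort(key=lambda p: muller_brown(p, self.scale)[0])
        return pts

    def escape_barrier(self) -> float:
        """Barrier from the global basin to its adjacent basin, kcal/mol."""
        gm_e = muller_brown(self.minima()[0], self.scale)[0]
        saddle_e = min(muller_brown(s, self.scale)[0] for s in self.saddles())
        return saddle_e - gm_e


@dataclass
class DoubleWellBond(OraclePotential):
    """Symmetric proton-transfer toy: heavy–light–heavy (atoms A, H, B).

    The proton's displacement d along the heavy–heavy axis, measured from the
    midpoint, feels a symmetric quartic double well

        E_dw(d) = barrier · ((d² − d0²)/d0²)²

    with minima at d = ±d0 and a configurable barrier at the midpoint
    (default 6.3 kcal/mol, the proton-transfer barrier regime the bias
    magnitude rule A = barrier is exercised against).  Harmonic restraints
    hold the heavy–heavy separation near its rest length and the proton near
    the axis.  All forces are analytic.
    """

    barrier: float = 6.3
    d0: float = 0.35  # Å, off-center minimum displacement
    heavy_sep: float = 2.5  # Å, rest heavy–heavy distance
    k_sep: float = 100.0  # kcal/mol/Ų
    k_perp: float = 40.0  # kcal/mol/Ų
    species: tuple[str, str, str] = ("O", "H", "O")
    name: str = "double_well_bond"

    def __call__(self, config: Configuration) -> tuple[float, np.ndarray]:
        if config.n_atoms != 3:
            raise ValueError("DoubleWellBond expects exactly 3 atoms (heavy, H, heavy)")
        rA, rH, rB = config.positions
        Rvec = rB - rA
        R = float(np.linalg.norm(Rvec))
        u = Rvec / R
        v = rH - 0.5 * (rA + rB)
        d = float(np.dot(v, u))
        p = v - d * u  # off-axis proton displacement

        w = (d * d - self.d0**2) / self.d0**2
        e_dw = self.barrier * w * w
        de_dd = self.barrier * 2.0 * w * (2.0 * d / self.d0**2)

        e_sep = 0.5 * self.k_sep * (R - self.heavy_sep) ** 2
        de_dR = self.k_sep * (R - self.heavy_sep)

        p2 = float(np.dot(p, p))
        e_perp = 0.5 * self.k_perp * p2

        energy = e_dw + e_sep + e_perp

        # d-gradients:  ∂d/∂rH = u;  ∂d/∂rA = −u/2 − p/R;  ∂d/∂rB = −u/2 + p/R
        gd_H = u
        gd_A = -0.5 * u - p / R
        gd_B = -0.5 * u + p / R
        # |p|² gradients: ∂/∂rH = 2p; ∂/∂rA = p(2d/R − 1); ∂/∂rB = −p(2d/R + 1)
        gp2_H = 2.0 * p
        gp2_A = p * (2.0 * d / R - 1.0)
        gp2_B = -p * (2.0 * d / R + 1.0)

        grad = np.zeros((3, 3))
        grad[0] = de_dd * gd_A + de_dR * (-u) + 0.5 * self.k_perp * gp2_A
        grad[1] = de_dd * gd_H + 0.5 * self.k_perp * gp2_H
        grad[2] = de_dd * gd_B + de_dR * u + 0.5 * self.k_perp * gp2_B
        return energy, -grad

    def default_seed_configuration(self) -> Configuration:
        half = 0.5 * self.heavy_sep
        pos = np.array(
            [
                [-half, 0.0, 0.0],
                [-self.d0, 0.0, 0.0],  # proton in the left well
                [half, 0.0, 0.0],
            ]
        )
        return Configuration(
            species=list(self.species), positions=pos, tag="dw_left_minimum"
        )

    def proton_displacement(self, config: Configuration) -> float:
        """Signed proton displacement d along the heavy–heavy axis, Å."""
        rA, rH, rB = config.positions
        Rvec = rB - rA
        u = Rvec / np.linalg.norm(Rvec)
        return float(np.dot(rH - 0.5 * (rA + rB), u))


def local_minimize(oracle: OraclePotential, config: Configuration) -> tuple[Configuration, float]:
    """Relax a configuration on the oracle; returns (minimized copy, energy)."""
    shape = config.positions.shape
    mask = oracle.frozen_mask(config)
    base = config.positions.copy()

    def fun(x):
        c = config.copy()
        pos = x.reshape(shape)
        if mask is not None:
            pos = np.where(mask, base, pos)
        c.positions = pos
        e, f = oracle(c)
        g = -f
        if mask is not None:
            g = np.where(mask, 0.0, g)
        return e, g.ravel()

    res = minimize(fun, config.positions.ravel(), jac=True, method="BFGS", tol=1e-12)
    out = config.copy()
    pos = res.x.reshape(shape)
    if mask is not None:
        pos = np.where(mask, base, pos)
    out.positions = pos
    out.velocities = None
    return out, float(res.fun)


def generate_initial_dataset(
    oracle: OraclePotential,
    seed_config: Configuration,
    temperature: float = 350.0,
    dt: float = 0.5,
    n_steps: int = 10_000,
    stride: int = 80,
    seed: int = 0,
    friction: float = 0.01,
    energy_window: float = 10.0,
) -> Dataset:
    """Harvest an initial near-minimum training set from a short trajectory.

    Runs a thermostatted Langevin trajectory on the oracle starting from
    ``seed_config`` and keeps every ``stride``-th frame, labeled with oracle
    energy and forces — floor(n_steps/stride) samples in total.  With the
    defaults (10,000 steps of 0.5 fs, stride 80) this yields 125 samples
    spanning the near-equilibrium neighbourhood of the seeding minimum.

    ``energy_window`` guards the near-minimum premise: the generator aborts
    if any harvested sample lies more than that many kcal/mol above the local
    minimum reachable from ``seed_config``.
    """
    from .dynamics import ThermostatParams, run_md

    if stride < 1:
        raise ValueError("stride must be >= 1")
    if n_steps < stride:
        raise ValueError("n_steps must be >= stride")

    thermostat = ThermostatParams(
        temperature=temperature, friction=friction, dt=dt, seed=seed
    )
    result = run_md(oracle, seed_config, thermostat, n_steps, store_stride=stride)
    # frames are stored at steps stride, 2·stride, ...; drop the step-0 frame
    kept = [
        (f, e, fo)
        for f, e, fo, s in zip(
            result.frames, result.energies, result.forces, result.step_indices
        )
        if s > 0 and s % stride == 0
    ]
    if not np.all(np.isfinite([e for _, e, _ in kept])):
        raise FloatingPointError("trajectory diverged: non-finite oracle energy")

    _, e_min = local_minimize(oracle, seed_config)
    samples = []
    for fi, (frame, energy, forces) in enumerate(kept):
        if energy >= e_min + energy_window:
            raise ValueError(
                f"initial-dataset frame {fi} lies {energy - e_min:.3f} kcal/mol above "
                f"the seeding minimum (window {energy_window}); not a near-minimum set"
            )
        c = frame.copy()
        c.velocities = None
        c.tag = f"init_{fi}"
        samples.append(LabeledSample(configuration=c, energy=energy, forces=forces))
    return Dataset(samples=samples, provenance=[0] * len(samples))
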