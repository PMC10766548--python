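"""Langevin molecular dynamics on any energy/force provider.

One integrator serves three drivers:

* :func:`run_md` — plain thermostatted dynamics on an oracle or on the
  ensemble-mean surface.
* :func:`run_sampling_md` — dynamics on the (optionally biased) committee
  surface with uncertainty-triggered termination: the run stops at the first
  frame whose ρ reaches the selection threshold, or returns the maximum-ρ
  frame if the step limit is hit first.
* :func:`run_metadynamics` — the collective-variable baseline, depositing
  repulsive Gaussians along user-chosen CVs at a fixed interval.

The integrator is BAOAB-discretised Langevin; with zero friction and zero
temperature it reduces exactly to velocity Verlet.  All three drivers share
one step routine and one random-number stream discipline, so an inactive
bias (or zero Gaussian height) leaves trajectories bit-identical to the
unbiased run under the same seed.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core_io import FORCE_TO_ACCEL, UNITS, Configuration
from .ensemble import Ensemble
from .uncertainty_bias import (
    BiasParams,
    biased_energy_forces,
    energy_variance,
    rho,
)

__all__ = [
    "ThermostatParams",
    "MDResult",
    "MetadynamicsState",
    "CollectiveVariable",
    "BondLengthCV",
    "CoordinateCV",
    "BondDifferenceCV",
    "init_velocities",
    "langevin_step",
    "run_md",
    "run_sampling_md",
    "metadynamics_energy",
    "run_metadynamics",
]


@dataclass
class ThermostatParams:
    """Langevin thermostat settings: T (K), friction (fs⁻¹), dt (fs), seed."""

    temperature: float = 350.0
    friction: float = 0.01
    dt: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.friction < 0:
            raise ValueError("friction must be non-negative")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")


@dataclass
class MDResult:
    """A (strided) trajectory with per-frame diagnostics.

    ``frames[selected_index]`` is the frame the sampler hands to the oracle:
    under ``threshold_met`` termination it satisfies ρ ≥ threshold; under
    ``step_limit`` it is the maximum-ρ frame (earliest on ties), retained
    exactly even when it falls off the storage stride.
    """

    frames: list[Configuration]
    energies: np.ndarray  # ensemble-mean or oracle energy per stored frame
    step_indices: list[int]
    termination: str  # "threshold_met" | "step_limit" | "failed"
    steps_run: int
    forces: list[np.ndarray] = field(default_factory=list)
    rhos: np.ndarray | None = None
    member_energies: np.ndarray | None = None  # (n_stored, N_M)
    selected_index: int | None = None
    bias_history: list[float] = field(default_factory=list)
    cv_history: np.ndarray | None = None
    failed: bool = False

    @property
    def selected_frame(self) -> Configuration:
        if self.selected_index is None:
            raise ValueError("no frame was selected in this run")
        return self.frames[self.selected_index]


def init_velocities(
    config: Configuration,
    temperature: float,
    seed: int | np.random.Generator = 0,
    frozen_mask: np.ndarray | None = None,
) -> Configuration:
    """Draw Maxwell–Boltzmann velocities at the given temperature.

    Deterministic under ``seed``; at T = 0 all velocities are zero.  Frozen
    degrees of freedom get zero velocity.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = config.copy()
    sigma = np.sqrt(
        UNITS.boltzmann_constant * temperature * FORCE_TO_ACCEL / config.masses
    )[:, None]
    v = sigma * rng.standard_normal((config.n_atoms, 3))
    if frozen_mask is not None:
        v[frozen_mask] = 0.0
    out.velocities = v
    return out


def _frozen_mask_of(potential, config: Configuration) -> np.ndarray | None:
    fm = getattr(potential, "frozen_mask", None)
    if callable(fm):
        return fm(config)
    return fm


def _step(pos, vel, forces, half_dt, acc_w, c1, c2, vsig, rng, frozen):
    """BAOAB substeps up to the final kick; returns (new_pos, half-updated v)."""
    v = vel + half_dt * forces * acc_w
    x = pos + half_dt * v
    xi = rng.standard_normal(pos.shape)
    v = c1 * v + c2 * vsig * xi
    if frozen is not None:
        v[frozen] = 0.0
    x = x + half_dt * v
    return x, v


def _kick(v, forces, half_dt, acc_w, frozen):
    v = v + half_dt * forces * acc_w
    if frozen is not None:
        v[frozen] = 0.0
    return v


def _integrator_consts(config: Configuration, thermostat: ThermostatParams):
    m = config.masses[:, None]
    acc_w = FORCE_TO_ACCEL / m
    c1 = math.exp(-thermostat.friction * thermostat.dt)
    c2 = math.sqrt(max(0.0, 1.0 - c1 * c1))
    vsig = np.sqrt(UNITS.boltzmann_constant * thermostat.temperature * FORCE_TO_ACCEL / m)
    return 0.5 * thermostat.dt, acc_w, c1, c2, vsig


def langevin_step(
    config: Configuration,
    potential,
    thermostat: ThermostatParams,
    rng: np.random.Generator,
    forces: np.ndarray | None = None,
) -> tuple[Configuration, float, np.ndarray]:
    """Advance one BAOAB step; returns (new config, energy, forces at it).

    ``forces`` may pass in the cached evaluation at the current positions to
    avoid recomputing it.  Raises on non-finite forces, with the offending
    configuration attached to the exception.
    """
    if config.velocities is None:
        raise ValueError("configuration must carry velocities")
    frozen = _frozen_mask_of(potential, config)
    if forces is None:
        _, forces = potential(config)
    half_dt, acc_w, c1, c2, vsig = _integrator_consts(config, thermostat)
    x, v = _step(
        config.positions, config.velocities, forces, half_dt, acc_w, c1, c2, vsig, rng, frozen
    )
    new = config.copy()
    new.positions = x
    energy, new_forces = potential(new)
    if not (np.isfinite(energy) and np.all(np.isfinite(new_forces))):
        err = FloatingPointError("non-finite energy/forces during dynamics")
        err.configuration = new  # type: ignore[attr-defined]
        raise err
    new.velocities = _kick(v, new_forces, half_dt, acc_w, frozen)
    return new, float(energy), new_forces


def _prepare_run(potential, seed_config: Configuration, thermostat: ThermostatParams):
    rng = np.random.default_rng(thermostat.seed)
    frozen = _frozen_mask_of(potential, seed_config)
    config = seed_config.copy()
    if config.velocities is None:
        config = init_velocities(config, thermostat.temperature, rng, frozen)
    return rng, frozen, config


def run_md(
    potential,
    seed_config: Configuration,
    thermostat: ThermostatParams,
    n_steps: int,
    store_stride: int = 10,
) -> MDResult:
    """Plain Langevin MD; stores every ``store_stride``-th frame (and the last)."""
    rng, frozen, config = _prepare_run(potential, seed_config, thermostat)
    energy, forces = potential(config)
    half_dt, acc_w, c1, c2, vsig = _integrator_consts(config, thermostat)

    frames, energies, flist, steps = [config.copy()], [float(energy)], [forces.copy()], [0]
    pos, vel = config.positions.copy(), config.velocities.copy()
    for step in range(1, n_steps + 1):
        pos, v = _step(pos, vel, forces, half_dt, acc_w, c1, c2, vsig, rng, frozen)
        work = config.copy()
        work.positions = pos
        energy, forces = potential(work)
        if not (np.isfinite(energy) and np.all(np.isfinite(forces))):
            raise FloatingPointError(
                f"non-finite oracle energy/forces at step {step}"
            )
        vel = _kick(v, forces, half_dt, acc_w, frozen)
        if step % store_stride == 0 or step == n_steps:
            snap = config.copy()
            snap.positions = pos.copy()
            snap.velocities = vel.copy()
            frames.append(snap)
            energies.append(float(energy))
            flist.append(forces.copy())
            steps.append(step)
    return MDResult(
        frames=frames,
        energies=np.array(energies),
        step_indices=steps,
        termination="step_limit",
        steps_run=n_steps,
        forces=flist,
    )


def run_sampling_md(
    ensemble: Ensemble,
    bias_params: BiasParams,
    seed_config: Configuration,
    thermostat: ThermostatParams,
    threshold: float,
    max_steps: int,
    store_stride: int = 10,
) -> MDResult:
    """Uncertainty-terminated sampling MD on the (biased) committee surface.

    ρ is evaluated at every step — the member energies and forces are
    already computed for the forces, so the check is free.  The run stops at
    the first frame with ρ ≥ threshold; if the step limit is reached, the
    maximum-ρ frame is selected (earliest index on ties).  When the bias is
    active and the run passes ``escalation_fraction`` of its step budget
    without terminating, A is multiplied by ``escalation_factor`` once.

    With ``bias_params.active`` False (or A = 0) the trajectory is
    bit-identical to plain ensemble-mean MD under the same seed.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    params = replace(bias_params)
    rng, frozen, config = _prepare_run(ensemble, seed_config, thermostat)
    half_dt, acc_w, c1, c2, vsig = _integrator_consts(config, thermostat)
    n_atoms = config.n_atoms

    def evaluate(c: Configuration):
        pred = ensemble.predict(c)
        if not (
            np.all(np.isfinite(pred.member_energies))
            and np.all(np.isfinite(pred.member_forces))
        ):
            raise FloatingPointError("non-finite ensemble prediction")
        energy, forces = biased_energy_forces(pred, params)
        if frozen is not None:
            forces = np.where(frozen, 0.0, forces)
        sigma_sq = energy_variance(pred.member_energies)
        r = rho(math.sqrt(sigma_sq), pred.n_members, n_atoms)
        return pred, energy, forces, r

    frames: list[Configuration] = []
    energies: list[float] = []
    rhos: list[float] = []
    member_e: list[np.ndarray] = []
    steps: list[int] = []
    bias_history: list[float] = []

    def store(c, pos, vel, e_mean, r, me, step):
        snap = c.copy()
        snap.positions = pos.copy()
        snap.velocities = None if vel is None else vel.copy()
        frames.append(snap)
        energies.append(e_mean)
        rhos.append(r)
        member_e.append(me.copy())
        steps.append(step)

    pred, _, forces, r0 = evaluate(config)
    store(config, config.positions, config.velocities, pred.mean_energy, r0, pred.member_energies, 0)

    def result(termination, steps_run, selected):
        return MDResult(
            frames=frames,
            energies=np.array(energies),
            step_indices=steps,
            termination=termination,
            steps_run=steps_run,
            rhos=np.array(rhos),
            member_energies=np.array(member_e),
            selected_index=selected,
            bias_history=bias_history,
        )

    if r0 >= threshold:
        return result("threshold_met", 0, 0)

    best_rho, best_step = r0, 0
    best_frame = (config.positions.copy(), pred.mean_energy, pred.member_energies.copy())
    esc_step = int(params.escalation_fraction * max_steps)
    escalated = False
    pos, vel = config.positions.copy(), config.velocities.copy()

    for step in range(1, max_steps + 1):
        if (
            params.active
            and not escalated
            and esc_step > 0
            and step == esc_step
        ):
            params.A *= params.escalation_factor
            escalated = True
        pos, v = _step(pos, vel, forces, half_dt, acc_w, c1, c2, vsig, rng, frozen)
        work = config.copy()
        work.positions = pos
        try:
            pred, _, forces, r = evaluate(work)
        except FloatingPointError:
            return MDResult(
                frames=frames,
                energies=np.array(energies),
                step_indices=steps,
                termination="failed",
                steps_run=step,
                rhos=np.array(rhos),
                member_energies=np.array(member_e),
                selected_index=None,
                bias_history=bias_history,
                failed=True,
            )
        if not (np.isfinite(pred.mean_energy) and np.all(np.isfinite(forces))):
            return MDResult(
                frames=frames,
                energies=np.array(energies),
                step_indices=steps,
                termination="failed",
                steps_run=step,
                rhos=np.array(rhos),
                member_energies=np.array(member_e),
                selected_index=None,
                bias_history=bias_history,
                failed=True,
            )
        vel = _kick(v, forces, half_dt, acc_w, frozen)
        if params.active:
            bias_history.append(params.A)

        if r >= threshold:
            store(config, pos, vel, pred.mean_energy, r, pred.member_energies, step)
            return result("threshold_met", step, len(frames) - 1)
        if r > best_rho:
            best_rho, best_step = r, step
            best_frame = (pos.copy(), pred.mean_energy, pred.member_energies.copy())
        if step % store_stride == 0:
            store(config, pos, vel, pred.mean_energy, r, pred.member_energies, step)

    # step limit: make sure the max-ρ frame is stored exactly, then select it
    if best_step not in steps:
        idx = bisect.bisect_left(steps, best_step)
        snap = config.copy()
        snap.positions = best_frame[0]
        snap.velocities = None
        frames.insert(idx, snap)
        energies.insert(idx, best_frame[1])
        rhos.insert(idx, best_rho)
        member_e.insert(idx, best_frame[2])
        steps.insert(idx, best_step)
    selected = steps.index(best_step)
    return result("step_limit", max_steps, selected)


# ---------------------------------------------------------------------------
# Metadynamics baseline
# ---------------------------------------------------------------------------


class CollectiveVariable:
    """Contract: value_and_grad(config) -> (s, ds/dpositions (N, 3))."""

    def value_and_grad(self, config: Configuration) -> tuple[float, np.ndarray]:
        raise NotImplementedError


class BondLengthCV(CollectiveVariable):
    """Distance between two atoms, Å."""

    def __init__(self, i: int, j: int):
        self.i, self.j = i, j

    def value_and_grad(self, config: Configuration):
        rij = config.positions[self.i] - config.positions[self.j]
        r = float(np.linalg.norm(rij))
        grad = np.zeros_like(config.positions)
        grad[self.i] = rij / r
        grad[self.j] = -rij / r
        return r, grad


class CoordinateCV(CollectiveVariable):
    """A raw Cartesian coordinate of one atom (for 2D landscape toys)."""

    def __init__(self, atom: int, axis: int):
        self.atom, self.axis = atom, axis

    def value_and_grad(self, config: Configuration):
        grad = np.zeros_like(config.positions)
        grad[self.atom, self.axis] = 1.0
        return float(config.positions[self.atom, self.axis]), grad


class BondDifferenceCV(CollectiveVariable):
    """Asymmetry coordinate r(a,h) − r(h,b): tracks proton transfer."""

    def __init__(self, a: int, h: int, b: int):
        self.left = BondLengthCV(a, h)
        self.right = BondLengthCV(h, b)

    def value_and_grad(self, config: Configuration):
        r1, g1 = self.left.value_and_grad(config)
        r2, g2 = self.right.value_and_grad(config)
        return r1 - r2, g1 - g2


@dataclass
class MetadynamicsState:
    """Deposited-Gaussian history along the chosen collective variables."""

    cv_definitions: list[CollectiveVariable]
    widths: np.ndarray  # b_i per CV
    height: float  # W, constant (standard metadynamics)
    deposition_interval: int  # τ, in steps
    centers: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.widths = np.asarray(self.widths, dtype=float)
        if np.any(self.widths <= 0):
            raise ValueError("Gaussian widths must be positive")
        if self.deposition_interval < 1:
            raise ValueError("deposition interval must be >= 1")

    def deposit(self, s: np.ndarray) -> None:
        self.centers.append(np.asarray(s, dtype=float).copy())


def metadynamics_energy(cv_values, state: MetadynamicsState) -> float:
    """History-dependent bias: Σ_k W·exp[−Σ_i (s_i − s_i(kτ))²/(2b_i²)]."""
    s = np.asarray(cv_values, dtype=float)
    if s.shape[0] != len(state.cv_definitions):
        raise ValueError("CV dimensionality mismatch")
    if not state.centers:
        return 0.0
    centers = np.array(state.centers)  # (K, n_cv)
    z = (s[None, :] - centers) / state.widths[None, :]
    return state.height * float(np.sum(np.exp(-0.5 * np.sum(z**2, axis=1))))


def _metadynamics_energy_grad(s: np.ndarray, state: MetadynamicsState):
    if not state.centers:
        return 0.0, np.zeros_like(s)
    centers = np.array(state.centers)
    d = s[None, :] - centers
    z2 = np.sum((d / state.widths[None, :]) ** 2, axis=1)
    g = state.height * np.exp(-0.5 * z2)  # (K,)
    energy = float(np.sum(g))
    # dE/ds_i = Σ_k g_k · (−(s_i − c_ki)/b_i²)
    grad = -np.sum(g[:, None] * d / (state.widths[None, :] ** 2), axis=0)
    return energy, grad


def run_metadynamics(
    potential,
    cv_definitions: list[CollectiveVariable],
    height: float,
    widths,
    deposition_interval: int,
    thermostat: ThermostatParams,
    seed_config: Configuration,
    max_steps: int,
    store_stride: int = 10,
) -> tuple[MDResult, MetadynamicsState]:
    """Langevin dynamics on base energy + metadynamics bias.

    A Gaussian is deposited at the current CV values after every
    ``deposition_interval``-th step, so the history holds
    floor(steps/τ) deposits.  Forces include the analytic CV-gradient
    chain-rule term.  With ``height`` = 0 the trajectory is bit-identical
    to unbiased MD under the same seed.
    """
    if not cv_definitions:
        raise ValueError("need at least one collective variable")
    state = MetadynamicsState(
        cv_definitions=list(cv_definitions),
        widths=widths,
        height=float(height),
        deposition_interval=int(deposition_interval),
    )
    base_frozen = _frozen_mask_of(potential, seed_config)

    def provider(c: Configuration):
        e0, f0 = potential(c)
        vals, grads = [], []
        for cv in state.cv_definitions:
            v, g = cv.value_and_grad(c)
            vals.append(v)
            grads.append(g)
        s = np.array(vals)
        e_meta, de_ds = _metadynamics_energy_grad(s, state)
        f_meta = -sum(de_ds[i] * grads[i] for i in range(len(grads)))
        return e0 + e_meta, f0 + f_meta

    provider.frozen_mask = lambda c: base_frozen  # type: ignore[attr-defined]

    rng, frozen, config = _prepare_run(provider, seed_config, thermostat)
    half_dt, acc_w, c1, c2, vsig = _integrator_consts(config, thermostat)

    energy, forces = provider(config)
    s0 = np.array([cv.value_and_grad(config)[0] for cv in state.cv_definitions])
    frames, energies, steps = [config.copy()], [float(energy)], [0]
    cv_history = [s0]
    pos, vel = config.positions.copy(), config.velocities.copy()
    for step in range(1, max_steps + 1):
        pos, v = _step(pos, vel, forces, half_dt, acc_w, c1, c2, vsig, rng, frozen)
        work = config.copy()
        work.positions = pos
        energy, forces = provider(work)
        if not (np.isfinite(energy) and np.all(np.isfinite(forces))):
            raise FloatingPointError(f"non-finite energy/forces at step {step}")
        vel = _kick(v, forces, half_dt, acc_w, frozen)
        s = np.array([cv.value_and_grad(work)[0] for cv in state.cv_definitions])
        cv_history.append(s)
        if step % state.deposition_interval == 0:
            state.deposit(s)
        if step % store_stride == 0 or step == max_steps:
            snap = config.copy()
            snap.positions = pos.copy()
            snap.velocities = vel.copy()
            frames.append(snap)
            energies.append(float(energy))
            steps.append(step)
    result = MDResult(
        frames=frames,
        energies=np.array(energies),
        step_indices=steps,
        termination="step_limit",
        steps_run=max_steps,
        cv_history=np.array(cv_history),
    )
    return result, state
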