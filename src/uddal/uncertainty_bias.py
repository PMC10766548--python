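"""Uncertainty estimation and the uncertainty-driven bias potential.

The committee disagreement on a configuration is summarised by

    σ_E² = ½ Σ_i (Ê_i − Ê)²                      (ensemble energy variance)
    ρ    = sqrt(2 / (N_M·N_A)) · σ_E             (per-atom-normalised estimator)

Note the ½ prefactor in σ_E² — it is nonstandard but deliberate; the
sqrt(2/(N_M·N_A)) factor in ρ compensates, so ρ equals the population
standard deviation of the member energies divided by sqrt(N_A).

The bias energy deepens smoothly with uncertainty,

    E_bias(σ_E²) = A·[exp(−σ_E² / (N_M·N_A·B²)) − 1] ∈ (−A, 0],

so dynamics on the combined surface Ê + E_bias is pushed toward
configurations the committee disagrees about.  Bias forces follow by the
chain rule and need only quantities already computed for the MD step:

    −∂σ_E²/∂r = Σ_i (Ê_i − Ê)(f̂_i − f̂).

The width B is chosen so that the ratio r of bias-force to true-force
magnitudes on early unbiased-AL samples matches an empirical target
(~0.36); :func:`calibrate_bias_width` automates that choice.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .ensemble import EnsemblePrediction

__all__ = [
    "BiasParams",
    "UncertaintyReport",
    "energy_variance",
    "rho",
    "uncertainty_report",
    "bias_energy",
    "bias_forces",
    "biased_energy_forces",
    "force_ratio",
    "calibrate_bias_width",
]


@dataclass
class BiasParams:
    """Magnitude A (kcal/mol), width B (kcal/mol), and activation state.

    A bounds the bias depth; B sets the uncertainty scale at which bias
    forces peak.  Both are context-dependent empirical choices: A of order
    the barriers of interest (up to ~5× for conformational problems), B near
    the in-domain ensemble spread σ_E, or calibrated to the bias/true force
    ratio.  ``escalation_fraction``/``escalation_factor`` implement the
    mid-trajectory A boost applied when a sampling run has spent that
    fraction of its step budget without meeting the uncertainty criterion.
    """

    A: float
    B: float
    active: bool = True
    escalation_fraction: float = 0.7
    escalation_factor: float = 1.15

    def __post_init__(self) -> None:
        if self.A < 0:
            raise ValueError("bias magnitude A must be >= 0")
        if self.B <= 0:
            raise ValueError("bias width B must be > 0")


@dataclass
class UncertaintyReport:
    """σ_E², σ_E and ρ for one configuration."""

    sigma_sq: float  # (kcal/mol)²
    sigma: float  # kcal/mol
    rho: float  # kcal·mol⁻¹·N_A^(−1/2)
    n_members: int
    n_atoms: int


def energy_variance(member_energies) -> float:
    """Ensemble disagreement σ_E² = ½ Σ_i (Ê_i − Ê)², (kcal/mol)²."""
    e = np.asarray(member_energies, dtype=float)
    if e.size < 2:
        raise ValueError("need at least 2 member energies")
    if not np.all(np.isfinite(e)):
        raise ValueError("member energies must be finite")
    return 0.5 * float(np.sum((e - e.mean()) ** 2))


def rho(sigma: float, n_members: int, n_atoms: int) -> float:
    """Uncertainty estimator ρ = sqrt(2/(N_M·N_A))·σ_E."""
    if n_members <= 0 or n_atoms <= 0:
        raise ValueError("member and atom counts must be positive")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    return math.sqrt(2.0 / (n_members * n_atoms)) * sigma


def uncertainty_report(prediction: EnsemblePrediction) -> UncertaintyReport:
    sigma_sq = energy_variance(prediction.member_energies)
    sigma = math.sqrt(sigma_sq)
    return UncertaintyReport(
        sigma_sq=sigma_sq,
        sigma=sigma,
        rho=rho(sigma, prediction.n_members, prediction.n_atoms),
        n_members=prediction.n_members,
        n_atoms=prediction.n_atoms,
    )


def bias_energy(
    sigma_sq: float, params: BiasParams, n_members: int, n_atoms: int
) -> float:
    """E_bias = A·[exp(−σ_E²/(N_M·N_A·B²)) − 1]; zero when inactive."""
    if not params.active:
        return 0.0
    if sigma_sq < 0:
        raise ValueError("sigma_sq must be non-negative")
    return params.A * (
        math.exp(-sigma_sq / (n_members * n_atoms * params.B**2)) - 1.0
    )


def _bias_energy_derivative(
    sigma_sq: float, params: BiasParams, n_members: int, n_atoms: int
) -> float:
    """dE_bias/dσ_E² = −A/(N_M·N_A·B²)·exp(−σ_E²/(N_M·N_A·B²)) < 0."""
    denom = n_members * n_atoms * params.B**2
    return -params.A / denom * math.exp(-sigma_sq / denom)


def bias_forces(prediction: EnsemblePrediction, params: BiasParams) -> np.ndarray:
    """Per-atom bias forces, kcal/mol/Å.

    F_bias = E_bias′(σ_E²) · Σ_i (Ê_i − Ê)(f̂_i − f̂); since E_bias′ < 0 the
    force pushes along +∇σ_E², uphill in uncertainty.
    """
    if not params.active:
        return np.zeros_like(prediction.mean_forces)
    de = prediction.member_energies - prediction.mean_energy  # (M,)
    df = prediction.member_forces - prediction.mean_forces  # (M, N, 3)
    grad_sigma_sq_neg = np.einsum("m,mac->ac", de, df)  # = −∂σ_E²/∂r
    sigma_sq = energy_variance(prediction.member_energies)
    deriv = _bias_energy_derivative(
        sigma_sq, params, prediction.n_members, prediction.n_atoms
    )
    return deriv * grad_sigma_sq_neg


def biased_energy_forces(
    prediction: EnsemblePrediction, params: BiasParams
) -> tuple[float, np.ndarray]:
    """The combined surface: (Ê + E_bias, f̂ + F_bias).

    With the bias inactive this returns the plain ensemble means exactly
    (and with A = 0 the added terms are exact zeros), so unbiased dynamics
    is bit-for-bit the A → 0 limit of biased dynamics.
    """
    if not params.active:
        return prediction.mean_energy, prediction.mean_forces
    sigma_sq = energy_variance(prediction.member_energies)
    e_bias = bias_energy(sigma_sq, params, prediction.n_members, prediction.n_atoms)
    f_bias = bias_forces(prediction, params)
    return prediction.mean_energy + e_bias, prediction.mean_forces + f_bias


def force_ratio(structures, floor: float = 1e-8) -> float:
    """Mean ratio of bias-force to true-force magnitudes, r.

    ``structures`` is a list of (bias force field, true force field) pairs,
    each (N_A, 3).  r = (1/(N_S·N_A)) Σ_I Σ_J ‖F_bias_IJ‖/‖F_true_IJ‖.
    Atoms whose true-force norm falls below ``floor`` are excluded from the
    average (and counted); if every atom is excluded the ratio is undefined.
    """
    ratios: list[float] = []
    n_excluded = 0
    for f_bias, f_true in structures:
        f_bias = np.asarray(f_bias, dtype=float).reshape(-1, 3)
        f_true = np.asarray(f_true, dtype=float).reshape(-1, 3)
        nb = np.linalg.norm(f_bias, axis=1)
        nt = np.linalg.norm(f_true, axis=1)
        ok = nt >= floor
        n_excluded += int(np.sum(~ok))
        ratios.extend((nb[ok] / nt[ok]).tolist())
    if not ratios:
        raise ValueError(
            f"all {n_excluded} atoms excluded: true-force norms below {floor}"
        )
    if n_excluded:
        warnings.warn(
            f"force_ratio: excluded {n_excluded} atoms with near-zero true force",
            stacklevel=2,
        )
    return float(np.mean(ratios))


def _ratio_at_B(samples, A: float, B: float) -> float:
    params = BiasParams(A=A, B=B, active=True)
    pairs = [(bias_forces(pred, params), f_true) for pred, f_true in samples]
    return force_ratio(pairs)


def calibrate_bias_width(
    md_al_samples,
    params_A: float,
    target_r: float = 0.36,
    b_min: float = 1e-4,
    b_max: float = 1e3,
    rtol: float = 0.05,
    n_grid: int = 61,
) -> tuple[float, bool]:
    """Choose B so the bias/true force ratio on early-AL samples matches
    ``target_r``.

    ``md_al_samples`` is a list of (EnsemblePrediction, true force field)
    pairs from the initial unbiased-AL iterations.  r(B) vanishes in both
    the B → 0 and B → ∞ limits and peaks in between, so the search first
    scans a log-spaced grid to locate the peak and then bisects on the
    decreasing branch above it, where r is monotone (verified via the
    bracketing sign change rather than assumed).  Returns ``(B, ok)``;
    ``ok`` is False when no bracket exists (target above the achievable
    peak, or nonpositive), in which case the nearest bracket endpoint is
    returned with a warning.
    """
    if not md_al_samples:
        raise ValueError("need at least one calibration sample")
    if target_r <= 0.0:
        warnings.warn(
            "calibrate_bias_width: target_r <= 0 is only reached as B -> inf; "
            "returning the upper search bound",
            stacklevel=2,
        )
        return b_max, False

    grid = np.geomspace(b_min, b_max, n_grid)
    r_grid = np.array([_ratio_at_B(md_al_samples, params_A, b) for b in grid])
    i_peak = int(np.argmax(r_grid))
    if r_grid[i_peak] < target_r:
        warnings.warn(
            f"calibrate_bias_width: peak ratio {r_grid[i_peak]:.4f} below target "
            f"{target_r}; returning the peak-ratio width",
            stacklevel=2,
        )
        return float(grid[i_peak]), False

    # decreasing branch: find the first grid point past the peak below target
    j = i_peak
    while j < n_grid - 1 and r_grid[j] >= target_r:
        j += 1
    lo, hi = grid[max(j - 1, i_peak)], grid[j]
    if r_grid[j] >= target_r:  # never fell below target before b_max
        warnings.warn(
            "calibrate_bias_width: no sign change in the bracket; returning b_max",
            stacklevel=2,
        )
        return b_max, False

    for _ in range(200):
        mid = math.sqrt(lo * hi)  # bisection in log B
        r_mid = _ratio_at_B(md_al_samples, params_A, mid)
        if abs(r_mid - target_r) <= rtol * target_r:
            return float(mid), True
        if r_mid > target_r:
            lo = mid
        else:
            hi = mid
    return float(math.sqrt(lo * hi)), True
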