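"""Diagnostics over persisted AL runs: time-to-threshold curves, sampled-
energy histograms, bond-length distributions, and basin occupancy on toy
landscapes.  Everything here is a pure function of stored records and
datasets, so reports regenerate bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .active_learning import ALRoundRecord
from .core_io import Configuration, Dataset
from .toy_oracles import MuellerBrown, OraclePotential, local_minimize

__all__ = [
    "ComparisonReport",
    "time_to_threshold",
    "energy_histogram",
    "pair_distance_distribution",
    "assign_basin",
    "basin_occupancy",
    "region_counts",
    "comparison_table",
    "count_crossings",
]


def time_to_threshold(records: list[ALRoundRecord]) -> pd.DataFrame:
    """Mean steps-to-termination per AL iteration.

    Step-limited simulations contribute their full step budget, so a flat
    curve at the limit means the uncertainty criterion is no longer met.
    """
    if not records:
        raise ValueError("no records")
    rows = [
        {
            "iteration": r.iteration,
            "mean_steps": float(np.mean(r.steps)),
            "mean_md_time_fs": r.mean_md_time_fs,
            "n_threshold_met": sum(t == "threshold_met" for t in r.terminations),
            "bias_active": r.bias_active,
        }
        for r in records
    ]
    return pd.DataFrame(rows).set_index("iteration")


def energy_histogram(
    dataset: Dataset,
    oracle: OraclePotential,
    bins: int = 30,
    reference: float | None = None,
    min_iteration: int = 0,
    bin_range: tuple[float, float] | None = None,
    normalized: bool = False,
):
    """Histogram of oracle energies relative to the landscape minimum.

    ``reference`` overrides the energy origin (default: the oracle energy of
    the relaxed seed configuration).  ``min_iteration`` filters out early
    iterations (e.g. those before bias activation), mirroring how sampled
    data are compared only over the iterations where the samplers differ.
    """
    if bins < 2:
        raise ValueError("need at least 2 bins")
    if reference is None:
        _, reference = local_minimize(oracle, oracle.default_seed_configuration())
    keep = [i for i, p in enumerate(dataset.provenance) if p >= min_iteration]
    energies = dataset.energies[keep] - reference
    counts, edges = np.histogram(energies, bins=bins, range=bin_range)
    if normalized:
        total = counts.sum()
        return counts / max(total, 1), edges
    return counts, edges


def pair_distance_distribution(
    frames: list[Configuration] | Dataset,
    pair: tuple[int, int],
    bins: int = 30,
):
    """Distance histogram for one atom pair, plus its population s.d.

    The spread of spectator-bond distances is the fingerprint that separates
    uncertainty-biased low-T sampling (narrow) from plain high-T sampling
    (broad).
    """
    if isinstance(frames, Dataset):
        frames = frames.configurations()
    i, j = pair
    n_atoms = frames[0].n_atoms
    if not (0 <= i < n_atoms and 0 <= j < n_atoms):
        raise IndexError(f"atom pair {pair} out of range for {n_atoms} atoms")
    d = np.array(
        [float(np.linalg.norm(f.positions[i] - f.positions[j])) for f in frames]
    )
    counts, edges = np.histogram(d, bins=bins)
    return counts, edges, float(d.std())


def assign_basin(oracle: OraclePotential, config: Configuration) -> int:
    """Index of the local minimum reached by gradient descent from ``config``.

    Defined for oracles exposing ``minima()`` (the Müller–Brown toy); basin 0
    is the global minimum.  Configurations that do not relax into any known
    minimum (off-landscape excursions where the surface is essentially flat)
    are assigned −1.
    """
    if not isinstance(oracle, MuellerBrown):
        raise TypeError("basin assignment is defined for the Müller–Brown oracle")
    minima = oracle.minima()
    pos = config.positions[0, :2]
    from .toy_oracles import muller_brown

    with np.errstate(over="ignore", invalid="ignore"):
        res = minimize(
            lambda p: muller_brown(p, oracle.scale)[0],
            pos,
            jac=lambda p: muller_brown(p, oracle.scale)[1],
            method="BFGS",
            tol=1e-10,
        )
    if not np.all(np.isfinite(res.x)):
        return -1
    dists = [float(np.linalg.norm(res.x - m)) for m in minima]
    if min(dists) > 0.05:
        return -1
    return int(np.argmin(dists))


def basin_occupancy(
    oracle: MuellerBrown, dataset: Dataset, min_iteration: int = 0
) -> dict[int, int]:
    """Sample counts per basin (keyed by minimum index, 0 = global; −1 holds
    off-landscape samples that relax into no known minimum)."""
    counts: dict[int, int] = {i: 0 for i in range(len(oracle.minima()))}
    counts[-1] = 0
    for sample, prov in zip(dataset.samples, dataset.provenance):
        if prov < min_iteration:
            continue
        counts[assign_basin(oracle, sample.configuration)] += 1
    return counts


def region_counts(
    oracle: MuellerBrown,
    dataset: Dataset,
    energy_cut: float | None = None,
    min_iteration: int = 0,
) -> dict[str, int]:
    """Split samples into the seeded low-energy region vs everything else.

    The "low" region is the seeded (global) basin below its escape barrier:
    a sample counts as low when its oracle energy lies less than
    ``energy_cut`` (default: the escape barrier) above the global minimum
    *and* it relaxes back into that basin.  Everything else — other basins,
    barrier tops, high-energy wall configurations — counts as "high".  This
    is the landscape analog of counting non-equilibrium-region points in a
    low-dimensional embedding of sampled conformers.
    """
    _, e_min = local_minimize(oracle, oracle.default_seed_configuration())
    cut = oracle.escape_barrier() if energy_cut is None else energy_cut
    low = high = 0
    for sample, prov in zip(dataset.samples, dataset.provenance):
        if prov < min_iteration:
            continue
        is_low = (sample.energy - e_min) < cut and assign_basin(
            oracle, sample.configuration
        ) == 0
        if is_low:
            low += 1
        else:
            high += 1
    return {"low": low, "high": high}


def count_crossings(series: np.ndarray, lo: float, hi: float) -> int:
    """Full transitions of a 1D coordinate between two wells.

    Counts entries into the opposite well (below ``lo`` / above ``hi``) after
    having been in the other; excursions that do not reach the far well are
    not counted.
    """
    state = 0  # -1 left, +1 right, 0 undecided
    crossings = 0
    for s in np.asarray(series, dtype=float):
        if s <= lo:
            if state == 1:
                crossings += 1
            state = -1
        elif s >= hi:
            if state == -1:
                crossings += 1
            state = 1
    return crossings


@dataclass
class ComparisonReport:
    """Scenario-resolved diagnostics assembled from compare_samplers output."""

    time_series: pd.DataFrame  # per-iteration mean steps, one column/scenario
    energy_histograms: dict[str, tuple[np.ndarray, np.ndarray]]
    basin_counts: pd.DataFrame | None
    normalized: bool = False


def comparison_table(
    results: dict,
    oracle: OraclePotential,
    bins: int = 30,
    min_iteration: int = 0,
    normalized: bool = False,
) -> ComparisonReport:
    """Aggregate compare_samplers output into one report."""
    series = {}
    hists = {}
    basin_rows = {}
    all_e = np.concatenate(
        [r["dataset"].energies for r in results.values()]
    )
    _, ref = local_minimize(oracle, oracle.default_seed_configuration())
    rng_e = (0.0, float(all_e.max() - ref))
    for name, r in results.items():
        series[name] = time_to_threshold(r["records"])["mean_steps"]
        hists[name] = energy_histogram(
            r["dataset"],
            oracle,
            bins=bins,
            min_iteration=min_iteration,
            bin_range=rng_e,
            normalized=normalized,
        )
        if isinstance(oracle, MuellerBrown):
            basin_rows[name] = basin_occupancy(
                oracle, r["dataset"], min_iteration=min_iteration
            )
    basins = pd.DataFrame(basin_rows).T if basin_rows else None
    return ComparisonReport(
        time_series=pd.DataFrame(series),
        energy_histograms=hists,
        basin_counts=basins,
        normalized=normalized,
    )
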