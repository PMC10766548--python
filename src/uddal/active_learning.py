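"""The outer active-learning loop.

Each iteration trains a fresh hold-one-out committee on all data collected
so far, launches ``n_sims_per_iteration`` uncertainty-terminated MD runs
from randomly drawn near-minimum seed geometries, labels each selected
frame with the oracle, and appends the new samples.  The uncertainty bias
stays off for the first iterations (an under-trained committee surface is
not smooth enough to bias safely) and is switched on at
``active_from_iteration``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .core_io import Configuration, Dataset, LabeledSample
from .ensemble import Ensemble, TrainingConfig, train_ensemble
from .dynamics import MDResult, ThermostatParams, run_sampling_md
from .uncertainty_bias import BiasParams

__all__ = ["ALConfig", "ALRoundRecord", "run_al_iteration", "run_al", "compare_samplers"]


def _derived_seed(*parts: int) -> int:
    """Deterministic sub-seed from a tuple of integers, below 2^31."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class ALConfig:
    """Active-learning protocol settings.

    Defaults are desk-scale (20 iterations of 5,000 steps); the full-scale
    protocol (200,000 steps at 1 fs, 16 simulations per iteration, ρ
    threshold 0.35, bias from iteration 15) uses the same fields.
    """

    n_sims_per_iteration: int = 16
    threshold: float = 0.35  # ρ, kcal·mol⁻¹·N_A^(−1/2)
    max_steps: int = 5_000
    dt: float = 1.0  # fs
    temperature: float = 350.0  # K
    friction: float = 0.01  # fs⁻¹
    bias: BiasParams = field(default_factory=lambda: BiasParams(A=15.4, B=0.12))
    active_from_iteration: int = 15
    n_iterations: int = 20
    seed_pool_size: int = 25
    seed: int = 0
    store_stride: int = 10

    def __post_init__(self) -> None:
        if min(
            self.n_sims_per_iteration,
            self.max_steps,
            self.seed_pool_size,
        ) <= 0 or self.n_iterations < 0:
            raise ValueError("counts must be positive")
        if self.active_from_iteration < 1:
            raise ValueError("active_from_iteration must be >= 1")


@dataclass
class ALRoundRecord:
    """Per-iteration bookkeeping behind the time-to-threshold diagnostics."""

    iteration: int
    steps: list[int]
    terminations: list[str]
    selected_rhos: list[float]
    samples: list[LabeledSample]
    mean_md_time_fs: float
    bias_active: bool
    ensemble_seed: int
    n_failed: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "iteration": self.iteration,
                "steps": self.steps,
                "terminations": self.terminations,
                "selected_rhos": self.selected_rhos,
                "mean_md_time_fs": self.mean_md_time_fs,
                "bias_active": self.bias_active,
                "ensemble_seed": self.ensemble_seed,
                "n_failed": self.n_failed,
            }
        )


def run_al_iteration(
    ensemble: Ensemble,
    oracle,
    config: ALConfig,
    iteration: int,
    seed_pool: list[Configuration],
) -> tuple[list[LabeledSample], ALRoundRecord]:
    """One AL round: parallel-in-seed MD runs, selection, oracle labeling.

    Each simulation draws its starting geometry uniformly (with replacement)
    from the seed pool and runs with an independent seed derived from the
    master seed, so reruns with the same master seed are identical and the
    per-simulation results are order-independent.  Failed (non-finite) runs
    yield no sample for their slot.
    """
    bias_active = iteration >= config.active_from_iteration
    bias = replace(config.bias, active=bias_active)

    samples: list[LabeledSample] = []
    steps: list[int] = []
    terminations: list[str] = []
    selected_rhos: list[float] = []
    n_failed = 0
    for sim in range(config.n_sims_per_iteration):
        pick_rng = np.random.default_rng(_derived_seed(config.seed, iteration, sim, 1))
        seed_config = seed_pool[int(pick_rng.integers(len(seed_pool)))]
        thermostat = ThermostatParams(
            temperature=config.temperature,
            friction=config.friction,
            dt=config.dt,
            seed=_derived_seed(config.seed, iteration, sim, 2),
        )
        result = run_sampling_md(
            ensemble,
            bias,
            seed_config,
            thermostat,
            threshold=config.threshold,
            max_steps=config.max_steps,
            store_stride=config.store_stride,
        )
        steps.append(result.steps_run)
        terminations.append(result.termination)
        if result.failed:
            n_failed += 1
            warnings.warn(
                f"iteration {iteration} sim {sim}: dynamics diverged, slot skipped",
                stacklevel=2,
            )
            continue
        frame = result.selected_frame.copy()
        frame.velocities = None
        frame.tag = f"al_it{iteration}_sim{sim}"
        energy, forces = oracle(frame)
        samples.append(LabeledSample(configuration=frame, energy=energy, forces=forces))
        selected_rhos.append(float(result.rhos[result.selected_index]))
    if not samples:
        raise RuntimeError(f"iteration {iteration}: every simulation failed")
    record = ALRoundRecord(
        iteration=iteration,
        steps=steps,
        terminations=terminations,
        selected_rhos=selected_rhos,
        samples=samples,
        mean_md_time_fs=float(np.mean(steps)) * config.dt,
        bias_active=bias_active,
        ensemble_seed=ensemble.master_seed,
        n_failed=n_failed,
    )
    return samples, record


def run_al(
    oracle,
    initial_dataset: Dataset,
    config: ALConfig,
    training_config: TrainingConfig | None = None,
    n_members: int = 8,
    hidden_sizes=(32, 16, 8),
    workdir=None,
) -> tuple[Dataset, list[ALRoundRecord], Ensemble]:
    """Run the full AL protocol from an initial near-minimum dataset.

    The committee is retrained from scratch each iteration on the strict
    superset of all accumulated data, with cross-validation folds re-drawn
    under an iteration-derived seed.  The seed pool for MD initialisation is
    the first ``seed_pool_size`` configurations of the initial dataset.
    Growth is exactly append-only: ``initial + Σ_iters (n_sims − failures)``
    samples, each carrying its iteration index as provenance.
    """
    training_config = training_config or TrainingConfig()
    if len(initial_dataset) == 0:
        raise ValueError("initial dataset must be non-empty")
    seed_pool = [
        s.configuration for s in initial_dataset.samples[: config.seed_pool_size]
    ]
    dataset = Dataset(
        samples=list(initial_dataset.samples),
        provenance=list(initial_dataset.provenance),
    )
    records: list[ALRoundRecord] = []
    workdir = Path(workdir) if workdir is not None else None
    if workdir is not None:
        workdir.mkdir(parents=True, exist_ok=True)

    ensemble: Ensemble | None = None
    for iteration in range(1, config.n_iterations + 1):
        tc = replace(training_config, seed=_derived_seed(config.seed, iteration, 0, 0))
        ensemble = train_ensemble(
            dataset, tc, n_members=n_members, hidden_sizes=hidden_sizes
        )
        samples, record = run_al_iteration(
            ensemble, oracle, config, iteration, seed_pool
        )
        dataset.extend(samples, iteration)
        records.append(record)
        if workdir is not None:
            with open(workdir / "records.jsonl", "a") as fh:
                fh.write(record.to_json() + "\n")

    if ensemble is None:  # n_iterations == 0
        tc = replace(training_config, seed=_derived_seed(config.seed, 0, 0, 0))
        ensemble = train_ensemble(
            dataset, tc, n_members=n_members, hidden_sizes=hidden_sizes
        )
    if workdir is not None:
        from .core_io import save_dataset

        save_dataset(dataset, workdir / "dataset")
    return dataset, records, ensemble


@dataclass
class Scenario:
    """One sampler condition in a controlled comparison."""

    name: str
    temperature: float
    bias_active: bool
    active_from_iteration: int | None = None  # None -> config default


def compare_samplers(
    oracle,
    initial_dataset: Dataset,
    scenarios: list[Scenario],
    config: ALConfig,
    training_config: TrainingConfig | None = None,
    n_members: int = 8,
    hidden_sizes=(32, 16, 8),
) -> dict:
    """Run the AL protocol once per scenario from identical initial state.

    Scenarios share the master seed and initial dataset and may differ only
    in temperature and bias activation, so differences in the outputs are
    attributable to the sampler alone.  Returns a dict keyed by scenario
    name with the final dataset, round records, and ensemble for each.
    """
    results: dict[str, dict] = {}
    for scenario in scenarios:
        scfg = replace(
            config,
            temperature=scenario.temperature,
            active_from_iteration=(
                scenario.active_from_iteration
                if scenario.bias_active and scenario.active_from_iteration is not None
                else (
                    config.active_from_iteration
                    if scenario.bias_active
                    else config.n_iterations + 1  # never activates
                )
            ),
        )
        dataset, records, ensemble = run_al(
            oracle,
            initial_dataset,
            scfg,
            training_config,
            n_members=n_members,
            hidden_sizes=hidden_sizes,
        )
        results[scenario.name] = {
            "dataset": dataset,
            "records": records,
            "ensemble": ensemble,
            "config": scfg,
        }
    return results
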