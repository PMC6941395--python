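"""Monte Carlo draws of cohort-level outcome totals.

For each (scenario, outcome, arm) a vector of ``replicates`` group totals is
drawn. Count outcomes use the negative binomial: the total of ``n`` i.i.d.
NB(mu, k) patients is itself NB(n*mu, n*k) (sums of independent negative
binomials with a common success probability add their size parameters), so
group totals are drawn in a single aggregate call — exactly equal in
distribution to summing per-patient draws, and much faster. Binary outcomes
use Binomial(n, p) directly. Arm totals are added replicate-by-replicate to
give the cohort total.

Reproducibility: every (scenario label, outcome name, arm) triple gets its own
random stream derived by hashing the triple into a :class:`numpy.random.SeedSequence`
together with the master seed. Streams are therefore independent, and adding a
scenario or outcome never perturbs the draws of existing ones.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .parameters import (
    BinaryOutcomeParams,
    ConfigError,
    CountOutcomeParams,
    ScenarioAllocation,
    StudyParameterSet,
)

__all__ = [
    "TotalSamples",
    "SimulationResult",
    "substream",
    "sample_count_total",
    "sample_binary_total",
    "simulate_scenario_outcome",
    "run_simulation",
    "expected_total",
]


def substream(master_seed: int, *keys: str) -> np.random.Generator:
    """Deterministic, independent random stream for a labelled sub-task.

    The keys are hashed (BLAKE2b) into four 32-bit words that are mixed with
    the master seed in a ``SeedSequence``; distinct key tuples yield
    independent streams, and the mapping is stable across runs and platforms.
    """
    digest = hashlib.blake2b("\x1f".join(keys).encode("utf-8"), digest_size=16).digest()
    words = [int(w) for w in np.frombuffer(digest, dtype=np.uint32)]
    return np.random.default_rng(np.random.SeedSequence([int(master_seed)] + words))


@dataclass(frozen=True)
class TotalSamples:
    """Replicate vector of cohort (or arm) totals for one outcome."""

    scenario_label: str
    outcome_name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values))
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("values must be a non-empty 1-D vector")

    @property
    def replicates(self) -> int:
        return int(self.values.size)


def sample_count_total(
    n_patients: int,
    params: CountOutcomeParams,
    replicates: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Totals of ``n_patients`` i.i.d. negative-binomial counts, per replicate.

    Uses the aggregate form NB(n*mu, n*k). numpy parameterises the negative
    binomial by (size n, success probability p) with mean ``n*(1-p)/p``, so
    ``p = k_tot / (k_tot + mu_tot)``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if n_patients < 0:
        raise ValueError("n_patients must be non-negative")
    if n_patients == 0:
        return np.zeros(replicates, dtype=np.int64)
    mu_tot = n_patients * params.mean_per_patient
    k_tot = n_patients * params.dispersion
    p = k_tot / (k_tot + mu_tot)
    return rng.negative_binomial(k_tot, p, size=replicates).astype(np.int64)


def sample_binary_total(
    n_patients: int,
    params: BinaryOutcomeParams,
    replicates: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Binomial(n_patients, p) event totals, one per replicate."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if n_patients < 0:
        raise ValueError("n_patients must be non-negative")
    return rng.binomial(n_patients, params.probability, size=replicates).astype(np.int64)


def simulate_scenario_outcome(
    allocation: ScenarioAllocation,
    qwt_params: CountOutcomeParams | BinaryOutcomeParams,
    swt_params: CountOutcomeParams | BinaryOutcomeParams,
    replicates: int,
    master_seed: int,
    outcome_name: str = "outcome",
) -> TotalSamples:
    """Cohort totals for one outcome under one allocation.

    The two arms are drawn from independent streams and added replicate by
    replicate.
    """
    if type(qwt_params) is not type(swt_params):
        raise ConfigError(
            f"arm parameter types differ: {type(qwt_params).__name__} vs "
            f"{type(swt_params).__name__}"
        )
    sampler = (
        sample_count_total
        if isinstance(qwt_params, CountOutcomeParams)
        else sample_binary_total
    )
    qwt = sampler(
        allocation.n_qwt,
        qwt_params,
        replicates,
        substream(master_seed, allocation.label, outcome_name, "QWT"),
    )
    swt = sampler(
        allocation.n_swt,
        swt_params,
        replicates,
        substream(master_seed, allocation.label, outcome_name, "SWT"),
    )
    return TotalSamples(allocation.label, outcome_name, qwt + swt)


@dataclass(frozen=True)
class SimulationResult:
    """All replicate vectors of a run, keyed by (scenario label, outcome name)."""

    samples: dict[tuple[str, str], TotalSamples]
    scenarios: tuple[ScenarioAllocation, ...]
    replicates: int
    master_seed: int

    def __getitem__(self, key: tuple[str, str]) -> TotalSamples:
        return self.samples[key]

    @property
    def baseline(self) -> ScenarioAllocation:
        for s in self.scenarios:
            if s.baseline:
                return s
        raise ConfigError("no scenario flagged as baseline")


def run_simulation(
    params: StudyParameterSet,
    scenarios: list[ScenarioAllocation] | tuple[ScenarioAllocation, ...],
    replicates: int,
    master_seed: int,
) -> SimulationResult:
    """Draw every (scenario, outcome) replicate vector for the study."""
    if not scenarios:
        raise ConfigError("at least one scenario is required")
    if replicates < 1:
        raise ConfigError("replicates must be >= 1")
    samples: dict[tuple[str, str], TotalSamples] = {}
    for alloc in scenarios:
        for spec in params.outcomes:
            samples[(alloc.label, spec.name)] = simulate_scenario_outcome(
                alloc, spec.qwt, spec.swt, replicates, master_seed, spec.name
            )
    return SimulationResult(samples, tuple(scenarios), replicates, master_seed)


def expected_total(
    allocation: ScenarioAllocation,
    qwt_params: CountOutcomeParams | BinaryOutcomeParams,
    swt_params: CountOutcomeParams | BinaryOutcomeParams,
) -> float:
    """Closed-form expectation n_qwt*mu_qwt + n_swt*mu_swt (no sampling)."""
    def _mean(p):
        return p.mean_per_patient if isinstance(p, CountOutcomeParams) else p.probability

    return allocation.n_qwt * _mean(qwt_params) + allocation.n_swt * _mean(swt_params)
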