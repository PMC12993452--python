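"""Data-discovery simulation: how far a researcher gets before RIP interferes.

Each run simulates a fresh researcher issuing sequence queries for randomly
chosen catalogued variants until the RIP algorithm occludes one (their first
false negative) or a query cap is reached. Aggregated over runs and over a
grid of (simulated) cohort sizes, this quantifies the privacy/utility
trade-off: small cohorts make rare variants dangerous to answer, large
cohorts dilute the membership evidence of every answer.

Simulated sizes reuse one genotyped cohort and vary only the N entering the
risk formula (``Dataset.size_override``): protection depends on N through the
risk alone, so materialising ever larger genotype sets would add cost without
changing what is measured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import query_engine
from .attack_sim import _sequence_query
from .query_engine import UserContext
from .rip import RIPConfig, RIPState, query_risk
from .variant_store import Dataset, SFSParams, generate_cohort, PANEL_F_MIN

__all__ = [
    "DiscoveryExperiment",
    "RunRecord",
    "DiscoverySummary",
    "run_discovery",
    "scaling_experiment",
    "make_discovery_dataset",
]


@dataclass(frozen=True)
class DiscoveryExperiment:
    """Parameters of a discovery scaling experiment.

    ``dataset_sizes`` are the simulated cohort sizes N; ``n_runs`` researchers
    are simulated per size, each capped at ``max_queries`` random variants.
    """

    dataset_sizes: tuple[int, ...] = (2504, 10_000, 25_000, 100_000)
    n_runs: int = 100
    max_queries: int = 100
    p: float = 0.1
    seed: int = 0
    n_subjects: int = 2504
    n_variants: int = 10_000

    def __post_init__(self) -> None:
        if self.n_runs < 1 or self.max_queries < 1:
            raise ValueError("n_runs and max_queries must be >= 1")


@dataclass
class RunRecord:
    """One researcher's run: successes before the first occlusion."""

    successful_queries: int
    zero_run: bool
    first_variant_id: str
    first_frequency: float
    occluded: bool


@dataclass
class DiscoverySummary:
    """Per-size aggregate of a discovery experiment."""

    dataset_size: int
    n_runs: int
    max_queries: int
    mean_queries: float
    zero_run_fraction: float
    runs: list[RunRecord] = field(default_factory=list)


def make_discovery_dataset(
    n_subjects: int = 2504,
    n_variants: int = 10_000,
    seed: int = 0,
    access_level: str = "registered",
) -> Dataset:
    """A Beacon-catalog cohort for the discovery and collusion experiments.

    Population frequencies follow the 1/f spectrum down to the reference-panel
    resolution (one allele in a 500k-subject panel); every catalogued variant
    has at least one carrier, as in a real Beacon, which stores only variants
    observed in its cohort even when their panel frequency is far below 1/(2N).
    """
    return generate_cohort(
        n_subjects,
        n_variants,
        sfs=SFSParams(f_min=PANEL_F_MIN, ascertained=True),
        seed=seed,
        dataset_id="discovery",
        access_level=access_level,
    )


def run_discovery(
    dataset: Dataset,
    p: float,
    max_queries: int = 100,
    n_runs: int = 100,
    seed: int = 0,
    config: RIPConfig | None = None,
) -> DiscoverySummary:
    """Simulate ``n_runs`` fresh researchers querying random variants.

    Each run draws ``max_queries`` catalogued variants uniformly without
    replacement (repeats would be recalled from history for free and bias the
    mean upward) and issues sequence queries through the full RIP-guarded
    stack under a fresh user identity. The run ends at the first occlusion —
    a "no" for a variant that is in fact present — or at the cap. A *zero
    run* is a run whose very first query is occluded.
    """
    if len(dataset.variants) < max_queries:
        raise ValueError(
            f"dataset holds {len(dataset.variants)} variants; need >= {max_queries}"
        )
    config = config or RIPConfig(p=p)
    if config.p != p:
        raise ValueError("config.p disagrees with the p argument")
    rng = np.random.default_rng(seed)
    state = RIPState(config)
    records: list[RunRecord] = []
    n_variants = len(dataset.variants)
    for run_i in range(n_runs):
        user = UserContext(user_id=f"researcher-{seed}-{run_i}", status="authenticated")
        picks = rng.choice(n_variants, size=max_queries, replace=False)
        successes = 0
        occluded = False
        first = dataset.variants[int(picks[0])]
        for vi in picks:
            variant = dataset.variants[int(vi)]
            responses = query_engine.respond(
                _sequence_query(variant), user, [dataset], state
            )
            assert len(responses) == 1 and responses[0].rip_applied
            present = dataset.cohort.carrier_indices(variant.variant_id).size > 0
            if not responses[0].exists and present:
                occluded = True
                break
            # a "yes", or a truthful "no" for an absent variant, is unadulterated
            successes += 1
        records.append(
            RunRecord(
                successful_queries=successes,
                zero_run=occluded and successes == 0,
                first_variant_id=first.variant_id,
                first_frequency=first.population_frequency,
                occluded=occluded,
            )
        )
    return DiscoverySummary(
        dataset_size=dataset.effective_size,
        n_runs=n_runs,
        max_queries=max_queries,
        mean_queries=float(np.mean([r.successful_queries for r in records])),
        zero_run_fraction=float(np.mean([r.zero_run for r in records])),
        runs=records,
    )


def zero_run_predicate(first_frequency: float, n: int, p: float,
                       frequency_floor: float | None = None) -> bool:
    """Closed form for a zero run: the first variant's risk exceeds -ln(p).

    With fresh budgets, the first query is occluded exactly when its risk is
    beyond the full budget of some carrier, i.e. query_risk(f, N) > -ln p.
    """
    kwargs = {} if frequency_floor is None else {"frequency_floor": frequency_floor}
    return query_risk(first_frequency, n, **kwargs) > -math.log(p)


def scaling_experiment(
    experiment: DiscoveryExperiment,
    dataset: Dataset | None = None,
) -> tuple[list[DiscoverySummary], tuple[float, float]]:
    """Run the discovery simulation across simulated cohort sizes.

    All sizes share one genotyped cohort and one frequency spectrum; only the
    N used by the risk formula varies (``size_override``). Returns one
    summary per size plus the least-squares linear fit (slope, intercept) of
    mean successful queries against N, since that mean grows roughly linearly
    with cohort size.
    """
    base = dataset or make_discovery_dataset(
        experiment.n_subjects, experiment.n_variants, seed=experiment.seed
    )
    summaries: list[DiscoverySummary] = []
    # Common random numbers: every size sees the same researchers issuing the
    # same query sequences, so size comparisons are paired rather than
    # confounded by fresh sampling noise.
    for size in experiment.dataset_sizes:
        sized = Dataset(
            dataset_id=base.dataset_id,
            access_level=base.access_level,
            cohort=base.cohort,
            variants=base.variants,
            size_override=int(size),
        )
        summaries.append(
            run_discovery(
                sized,
                experiment.p,
                max_queries=experiment.max_queries,
                n_runs=experiment.n_runs,
                seed=experiment.seed,
            )
        )
    sizes = np.array([s.dataset_size for s in summaries], dtype=float)
    means = np.array([s.mean_queries for s in summaries], dtype=float)
    if len(summaries) >= 2:
        slope, intercept = np.polyfit(sizes, means, 1)
    else:
        slope, intercept = 0.0, float(means[0]) if len(means) else 0.0
    return summaries, (float(slope), float(intercept))
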