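"""Membership-inference machinery and simulated re-identification attacks.

The attacker tests H0 ("the target is not in the Beacon cohort") against H1
("the target is in the cohort") with a log-likelihood ratio Λ over a series
of Boolean answers about variants the target is known to carry. Negative Λ
favours membership; the attack reaches significance α once Λ <= ln(α).

Three scoring rules are provided:

* ``lrt_general`` — the full test with mismatch probability δ between the
  attacker's copy of the target genome and the Beacon content;
* ``lrt_optimal`` — the attacker's best case δ = 0, where every answer must
  be "yes" and each contributes ln(1 - (1 - f)^(2N));
* ``lrt_collusion`` — the RIP-aware variant in which a "no" may be a
  deliberate false negative with probability ρ, contributing
  ln((1 - f)^2 / ρ) in favour of H0.

The attack simulators drive the real query-engine + RIP stack, so their
outcomes certify the served code path rather than a shortcut model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import query_engine, rip as rip_mod
from .query_engine import Query, UserContext
from .rip import RIPConfig, RIPState, query_risk
from .variant_store import Dataset, Variant

__all__ = [
    "ResponseSeries",
    "AttackParams",
    "AttackResult",
    "loglik_series",
    "lrt_general",
    "lrt_optimal",
    "lrt_collusion",
    "run_optimal_attack",
    "attack_experiment",
    "min_colluders",
    "run_collusion_attack",
]


@dataclass
class ResponseSeries:
    """Boolean Beacon answers paired with the variants' population frequencies."""

    answers: Sequence[bool]
    frequencies: Sequence[float]

    def __post_init__(self) -> None:
        if len(self.answers) != len(self.frequencies):
            raise ValueError("answers and frequencies must have equal length")

    def __len__(self) -> int:
        return len(self.answers)


@dataclass(frozen=True)
class AttackParams:
    """Attack-model parameters: cohort size N, mismatch δ, RIP false-negative
    rate ρ, and the target significance α."""

    N: int
    delta: float = 0.0
    rho: float = 1.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("cohort size N must be >= 1")
        if not 0.0 <= self.delta < 1.0:
            raise ValueError("delta must lie in [0, 1)")
        if not 0.0 < self.rho <= 1.0:
            raise ValueError("rho must lie in (0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class AttackResult:
    """Outcome of one simulated attack."""

    target_subject_id: str
    queries_until_occlusion: int
    lambda_trace: list[float] = field(default_factory=list)
    n_false_negatives: int = 0
    attackers_used: int = 1
    attacker_net_lambda: list[float] | None = None

    @property
    def final_lambda(self) -> float:
        return self.lambda_trace[-1] if self.lambda_trace else 0.0


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------


def loglik_series(series: ResponseSeries, prob_positive: Callable[[float], float]) -> float:
    """Log-likelihood of a Boolean answer series under a response model.

    ``prob_positive(f)`` gives Pr(answer = yes) for a variant of population
    frequency f. An observed answer whose model probability is 0 yields -inf
    (the series is impossible under that model).
    """
    total = 0.0
    for x, f in zip(series.answers, series.frequencies):
        pr = prob_positive(f)
        if not 0.0 <= pr <= 1.0:
            raise ValueError(f"prob_positive returned {pr}, outside [0, 1]")
        p_obs = pr if x else 1.0 - pr
        if p_obs == 0.0:
            return -math.inf
        total += math.log(p_obs)
    return total


def _log_one_minus_pow(f: float, n: int) -> float:
    """ln(1 - (1 - f)^(2N)), computed stably; -inf at f = 0."""
    if f <= 0.0:
        return -math.inf
    if f >= 1.0:
        return 0.0
    t = 2.0 * n * math.log1p(-f)
    inner = -math.expm1(t)
    return math.log(inner) if inner < 1.0 else 0.0


def lrt_general(series: ResponseSeries, params: AttackParams) -> float:
    """Membership log-likelihood ratio with mismatch probability δ in (0, 1).

    Λ = Σ ln((1-f)²/δ) + x · ln( δ/(1-f)² · (1-(1-f)^{2N}) / (1-δ(1-f)^{2N-2}) ).
    """
    if not 0.0 < params.delta < 1.0:
        raise ValueError("lrt_general requires delta in (0, 1); use lrt_optimal for delta = 0")
    n, d = params.N, params.delta
    total = 0.0
    for x, f in zip(series.answers, series.frequencies):
        log_q2 = 2.0 * math.log1p(-f)  # ln (1-f)^2
        total += log_q2 - math.log(d)
        if x:
            pow_2n = math.exp(2.0 * n * math.log1p(-f)) if f < 1.0 else 0.0
            pow_2n_2 = math.exp((2.0 * n - 2.0) * math.log1p(-f)) if f < 1.0 else 0.0
            total += (
                math.log(d)
                - log_q2
                + _log_one_minus_pow(f, n)
                - math.log1p(-d * pow_2n_2)
            )
    return total


def lrt_optimal(frequencies: Sequence[float], n: int) -> float:
    """Best-case (δ = 0) membership statistic over an all-"yes" series.

    Λ = Σ ln(1 - (1 - f_i)^(2N)) <= 0; more negative means stronger evidence
    for membership. A frequency of exactly 0 yields -inf (such a variant
    would identify its carrier perfectly).
    """
    return sum(_log_one_minus_pow(f, n) for f in frequencies)


def lrt_collusion(series: ResponseSeries, n: int, rho: float) -> float:
    """RIP-aware membership statistic with false-negative probability ρ.

    A "yes" contributes ln(1 - (1-f)^{2N}) as in the optimal test; a "no"
    contributes ln((1-f)²/ρ), which for informative (rare) variants and
    plausible ρ is positive and sets the attack back towards H0.
    """
    if not 0.0 < rho <= 1.0:
        raise ValueError("rho must lie in (0, 1]")
    total = 0.0
    for x, f in zip(series.answers, series.frequencies):
        if x:
            total += _log_one_minus_pow(f, n)
        else:
            total += 2.0 * math.log1p(-f) - math.log(rho)
    return total


# ---------------------------------------------------------------------------
# Simulated attacks through the serving stack
# ---------------------------------------------------------------------------


def _target_variants_rarest_first(dataset: Dataset, target_subject_id: str) -> list[Variant]:
    try:
        target_idx = dataset.cohort.subject_ids.index(target_subject_id)
    except ValueError:
        raise ValueError(f"target {target_subject_id!r} is not a cohort member") from None
    carried = [
        dataset.variant_by_id(vid)
        for vid in dataset.cohort.variant_ids_of_subject(target_idx)
    ]
    carried.sort(key=lambda v: (v.population_frequency, v.variant_id))
    return carried


def _sequence_query(variant: Variant) -> Query:
    return Query(
        subtype="sequence",
        referenceName=variant.reference_name,
        start=variant.start,
        referenceBases=variant.reference_bases,
        alternateBases=variant.alternate_bases,
    )


def _ask(
    variant: Variant, user: UserContext, dataset: Dataset, state: RIPState
) -> bool:
    responses = query_engine.respond(_sequence_query(variant), user, [dataset], state)
    assert len(responses) == 1 and responses[0].rip_applied
    return responses[0].exists


def run_optimal_attack(
    dataset: Dataset,
    target_subject_id: str,
    config: RIPConfig,
    seed: int = 0,
    user_id: str | None = None,
    state: RIPState | None = None,
    max_queries: int = 100,
) -> AttackResult:
    """Single-attacker optimal strategy against the RIP-guarded stack.

    Issues sequence queries for the target's carried variants in ascending
    order of population frequency (rarest first) until the first false
    negative — the moment a query surpasses the attacker's remaining budget
    for some carrier — or until ``max_queries``. Returns the count of
    successful queries and the running Λ of the accumulated positives.

    ``max_queries`` caps the run: under a bounded frequency spectrum a target
    may carry too little aggregate evidence ever to exhaust the budget.
    """
    state = state or RIPState(RIPConfig(p=config.p, frequency_floor=config.frequency_floor))
    user = UserContext(
        user_id=user_id or f"attacker-{target_subject_id}-{seed}", status="authenticated"
    )
    n = dataset.effective_size
    trace: list[float] = []
    lam = 0.0
    successes = 0
    for variant in _target_variants_rarest_first(dataset, target_subject_id)[:max_queries]:
        if _ask(variant, user, dataset, state):
            successes += 1
            lam += _log_one_minus_pow(
                max(variant.population_frequency, config.frequency_floor), n
            )
            trace.append(lam)
        else:
            return AttackResult(target_subject_id, successes, trace, n_false_negatives=1)
    return AttackResult(target_subject_id, successes, trace)


def attack_experiment(
    dataset: Dataset,
    n_targets: int,
    config: RIPConfig,
    seed: int = 0,
    max_queries: int = 100,
) -> tuple[list[AttackResult], dict[str, float]]:
    """Optimal attacks on ``n_targets`` random subjects, one fresh attacker each.

    Returns the per-target results and a summary (mean / min / max successful
    queries), the headline privacy-assessment numbers.
    """
    rng = np.random.default_rng(seed)
    n_subjects = dataset.cohort.size
    picks = rng.choice(n_subjects, size=min(n_targets, n_subjects), replace=False)
    state = RIPState(config)
    results = [
        run_optimal_attack(
            dataset,
            dataset.cohort.subject_ids[int(i)],
            config,
            seed=seed,
            user_id=f"attacker-{k}",
            state=state,
            max_queries=max_queries,
        )
        for k, i in enumerate(picks)
    ]
    counts = [r.queries_until_occlusion for r in results]
    summary = {
        "n_targets": float(len(results)),
        "mean_queries": float(np.mean(counts)) if counts else 0.0,
        "min_queries": float(min(counts)) if counts else 0.0,
        "max_queries": float(max(counts)) if counts else 0.0,
    }
    return results, summary


def min_colluders(p: float, alpha: float) -> int:
    """Smallest number of p-aware colluders able to reach significance α.

    Each colluder can extract at most -ln(p) nats of membership evidence
    before the budget stops them; evidence adds across colluders who know p
    and skip unaffordable variants, so k attackers reach α once
    k·(-ln p) >= -ln α, i.e. k = ceil(ln α / ln p). If α >= p a single
    attacker already fits within one budget.
    """
    if not 0.0 < p < 1.0 or not 0.0 < alpha < 1.0:
        raise ValueError("p and alpha must lie in (0, 1)")
    if alpha >= p:
        return 1
    lp, la = -math.log(p), -math.log(alpha)
    k = math.ceil(la / lp)
    # guard the ceiling against floating-point edge cases
    while k > 1 and (k - 1) * lp >= la:
        k -= 1
    while k * lp < la:
        k += 1
    return k


def run_collusion_attack(
    dataset: Dataset,
    target_subject_id: str,
    n_attackers: int,
    knows_p: bool,
    config: RIPConfig,
    seed: int = 0,
    alpha: float = 0.05,
    state: RIPState | None = None,
    max_queries_per_attacker: int = 200,
    target_variants: Sequence[Variant] | None = None,
) -> AttackResult:
    """Colluding attackers pooling evidence about one target.

    With ``knows_p=True`` the group plays the optimal collusion strategy: it
    skips variants whose individual risk exceeds a fresh budget (those can
    never be answered), spends each attacker's budget greedily on the
    riskiest affordable variants, and hands over to the next attacker once
    the current budget cannot afford the next variant. Evidence is scored
    with the best-case statistic over the positive answers, and the attack
    stops once Λ <= ln(α) or attackers/variants run out.

    With ``knows_p=False`` the group queries rarest-first and must treat
    every "no" as possibly genuine: answers are scored with the RIP-aware
    statistic, estimating the false-negative probability from the running
    statistic as ρ = 1/(1 + exp(Λ)) (a uniform prior on membership). Each
    attacker retires at their first "no"; the next resumes with the next
    variant. ``attacker_net_lambda`` records each attacker's net effect on Λ.

    If the target is not in the cohort, queries are issued for the rarest
    catalogued variants instead and every true answer is negative.
    """
    if n_attackers < 1:
        raise ValueError("n_attackers must be >= 1")
    state = state or RIPState(config)
    n = dataset.effective_size
    budget = config.budget
    in_cohort = target_subject_id in dataset.cohort.subject_ids
    if target_variants is not None:
        variants = sorted(
            target_variants, key=lambda v: (v.population_frequency, v.variant_id)
        )
    elif in_cohort:
        variants = _target_variants_rarest_first(dataset, target_subject_id)
    else:
        # The target is not a cohort member and no external genome was given:
        # model the attacker's known target variants as phantoms that mirror
        # the rarest catalogued frequencies but sit at unoccupied positions,
        # so every probe is truthfully absent from the Beacon.
        rarest = sorted(
            dataset.variants, key=lambda v: (v.population_frequency, v.variant_id)
        )
        base = max((v.start for v in dataset.variants), default=0) + 10
        variants = [
            Variant(
                variant_id=f"phantom.{k}",
                reference_name=v.reference_name,
                start=base + 3 * k,
                end=base + 3 * k + 1,
                reference_bases="A",
                alternate_bases="T",
                population_frequency=v.population_frequency,
            )
            for k, v in enumerate(rarest)
        ]

    def risk_of(v: Variant) -> float:
        return query_risk(v.population_frequency, n, config.frequency_floor)

    users = [
        UserContext(user_id=f"colluder-{seed}-{k}", status="authenticated")
        for k in range(n_attackers)
    ]
    lam = 0.0
    trace: list[float] = []
    successes = 0
    false_negatives = 0
    log_alpha = math.log(alpha)

    if knows_p:
        affordable = [v for v in variants if risk_of(v) <= budget]
        affordable.sort(key=lambda v: (-risk_of(v), v.variant_id))
        attacker = 0
        remaining = budget
        used = 1 if affordable else 0
        for v in affordable:
            r = risk_of(v)
            if r > remaining:
                attacker += 1
                if attacker >= n_attackers:
                    break
                remaining = budget
                used += 1
            answer = _ask(v, users[attacker], dataset, state)
            remaining -= r
            if answer:
                successes += 1
                lam += _log_one_minus_pow(
                    max(v.population_frequency, config.frequency_floor), n
                )
            else:
                false_negatives += 1
            trace.append(lam)
            if lam <= log_alpha:
                break
        return AttackResult(
            target_subject_id,
            successes,
            trace,
            n_false_negatives=false_negatives,
            attackers_used=max(used, 1),
        )

    # p-unaware collusion: rarest first, RIP-aware scoring
    net: list[float] = []
    idx = 0
    for user in users:
        lam_start = lam
        queries = 0
        while idx < len(variants) and queries < max_queries_per_attacker:
            v = variants[idx]
            idx += 1
            queries += 1
            f = max(v.population_frequency, config.frequency_floor)
            answer = _ask(v, user, dataset, state)
            if answer:
                successes += 1
                lam += _log_one_minus_pow(f, n)
                trace.append(lam)
                if lam <= log_alpha:
                    break
            else:
                false_negatives += 1
                rho = 1.0 / (1.0 + math.exp(min(lam, 700.0)))
                lam += 2.0 * math.log1p(-f) - math.log(rho)
                trace.append(lam)
                break  # this attacker retires at their first negative
        net.append(lam - lam_start)
        if idx >= len(variants) or lam <= log_alpha:
            break
    return AttackResult(
        target_subject_id,
        successes,
        trace,
        n_false_negatives=false_negatives,
        attackers_used=len(net),
        attacker_net_lambda=net,
    )
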