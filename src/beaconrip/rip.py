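"""The Re-Identification Prevention (RIP) algorithm.

Every (user, data subject) pair holds a statistical-power budget initialised
to -ln(p), where p is the smallest membership-test p-value the server is
willing to let a user reach about any subject. Each Boolean answer about a
variant carried by a subject spends, from that subject's budget, the
magnitude of the evidence the answer contributes to the membership
likelihood-ratio test:

    risk(f, N) = -ln(1 - (1 - f)^(2N))

with f the variant's population frequency and N the cohort size. A variant
whose risk exceeds any carrier's remaining budget is occluded (removed from
the response, producing a deliberate false negative); answered variants
debit every carrier. Repeated queries are recalled from a history log without
touching budgets, and budgets can be recomputed from that history when a
dataset grows.

All budgets and risks are in nats (natural logarithm throughout).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .query_engine import DatasetResponse, Query, UserContext, canonicalize
from .variant_store import DEFAULT_FREQUENCY_FLOOR, Dataset, Variant

__all__ = [
    "RIPConfig",
    "BudgetLedger",
    "HistoryEntry",
    "HistoryLog",
    "RIPState",
    "initial_budget",
    "query_risk",
    "apply_rip",
    "recompute_budgets",
]


class IntegrityError(ValueError):
    """History references a dataset or variant that no longer exists."""


def initial_budget(p: float) -> float:
    """Initial per-(user, subject) budget, -ln(p) nats.

    p is the significance floor: the lowest membership-test p-value a single
    user may reach about any data subject.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"significance floor p must lie in (0, 1), got {p}")
    return -math.log(p)


def query_risk(f: float, n: int, frequency_floor: float = DEFAULT_FREQUENCY_FLOOR) -> float:
    """Evidence (nats) a positive answer about a variant contributes.

    Computes -ln(1 - (1 - f)^(2N)) stably: via log1p/expm1 so that tiny f with
    large N (where (1-f)^(2N) is close to 1) and common f (where the power
    underflows and the risk is indistinguishable from 0) are both handled
    without catastrophic cancellation. f below ``frequency_floor`` is clamped
    up to the floor, keeping the risk finite.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    f = max(float(f), frequency_floor)
    if f >= 1.0:
        return 0.0
    t = 2.0 * n * math.log1p(-f)  # ln((1-f)^(2N)) <= 0
    inner = -math.expm1(t)  # 1 - (1-f)^(2N), in (0, 1]
    if inner >= 1.0:
        return 0.0
    return -math.log(inner)


@dataclass
class RIPConfig:
    """RIP deployment parameters.

    ``p`` is deployment-confidential: publishing it would let colluding users
    optimise their strategy, so it must never be echoed in responses or logs.
    """

    p: float = 0.1
    frequency_floor: float = DEFAULT_FREQUENCY_FLOOR

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError("significance floor p must lie in (0, 1)")
        if not 0.0 < self.frequency_floor <= 1.0:
            raise ValueError("frequency floor must lie in (0, 1]")

    @property
    def budget(self) -> float:
        return initial_budget(self.p)

    def __repr__(self) -> str:  # the value of p stays out of logs and tracebacks
        return "RIPConfig(p=<confidential>, frequency_floor=%g)" % self.frequency_floor


class BudgetLedger:
    """Remaining budget per (user, subject), lazily initialised to -ln(p).

    Only pairs that have actually been debited are stored; an absent entry
    means an untouched budget.
    """

    def __init__(self, config: RIPConfig, entries: Mapping[tuple[str, str], float] | None = None):
        self.config = config
        self.entries: dict[tuple[str, str], float] = dict(entries or {})

    def remaining(self, user_id: str, subject_id: str) -> float:
        return self.entries.get((user_id, subject_id), self.config.budget)

    def spend(self, user_id: str, subject_id: str, amount: float) -> None:
        remaining = self.remaining(user_id, subject_id)
        self.entries[(user_id, subject_id)] = max(0.0, remaining - amount)

    def copy(self) -> "BudgetLedger":
        return BudgetLedger(self.config, self.entries)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, BudgetLedger) and self.entries == other.entries

    # --- persistence: TSV with 17 significant digits -----------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        tmp = path.with_suffix(path.suffix + ".tmp")
        with tmp.open("w") as fh:
            fh.write("user_id\tsubject_id\tremaining_budget\n")
            for (uid, sid), budget in sorted(self.entries.items()):
                fh.write(f"{uid}\t{sid}\t{budget:.17g}\n")
        tmp.replace(path)  # atomic on POSIX

    @classmethod
    def load(cls, path: str | Path, config: RIPConfig) -> "BudgetLedger":
        entries: dict[tuple[str, str], float] = {}
        with Path(path).open() as fh:
            header = fh.readline()
            for line in fh:
                uid, sid, budget = line.rstrip("\n").split("\t")
                entries[(uid, sid)] = float(budget)
        return cls(config, entries)


@dataclass(frozen=True)
class HistoryEntry:
    """One RIP-mediated query: its key, stored answer, and per-variant fate."""

    user_id: str
    dataset_id: str
    canonical_query: str
    stored_response: bool
    returned_variant_ids: tuple[str, ...]
    occluded_variant_ids: tuple[str, ...]

    def to_json(self) -> str:
        return json.dumps(
            {
                "userId": self.user_id,
                "datasetId": self.dataset_id,
                "canonicalQuery": self.canonical_query,
                "storedResponse": self.stored_response,
                "returnedVariantIds": list(self.returned_variant_ids),
                "occludedVariantIds": list(self.occluded_variant_ids),
            }
        )

    @classmethod
    def from_json(cls, line: str) -> "HistoryEntry":
        obj = json.loads(line)
        return cls(
            user_id=obj["userId"],
            dataset_id=obj["datasetId"],
            canonical_query=obj["canonicalQuery"],
            stored_response=obj["storedResponse"],
            returned_variant_ids=tuple(obj["returnedVariantIds"]),
            occluded_variant_ids=tuple(obj["occludedVariantIds"]),
        )


class HistoryLog:
    """Ordered, append-only log of RIP-mediated queries with a recall index."""

    def __init__(self, entries: Iterable[HistoryEntry] = ()):
        self.entries: list[HistoryEntry] = []
        self._index: dict[tuple[str, str, str], HistoryEntry] = {}
        for entry in entries:
            self.append(entry)

    def append(self, entry: HistoryEntry) -> None:
        key = (entry.user_id, entry.dataset_id, entry.canonical_query)
        if key in self._index:
            raise ValueError(f"duplicate history entry for {key}")
        self.entries.append(entry)
        self._index[key] = entry

    def recall(self, user_id: str, dataset_id: str, canonical_query: str) -> HistoryEntry | None:
        return self._index.get((user_id, dataset_id, canonical_query))

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    # --- persistence: JSON lines, append-only ------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        tmp = path.with_suffix(path.suffix + ".tmp")
        with tmp.open("w") as fh:
            for entry in self.entries:
                fh.write(entry.to_json() + "\n")
        tmp.replace(path)

    def append_to_file(self, entry: HistoryEntry, path: str | Path) -> None:
        with Path(path).open("a") as fh:
            fh.write(entry.to_json() + "\n")
            fh.flush()

    @classmethod
    def load(cls, path: str | Path) -> "HistoryLog":
        path = Path(path)
        if not path.exists():
            return cls()
        with path.open() as fh:
            return cls(HistoryEntry.from_json(line) for line in fh if line.strip())


@dataclass
class RIPState:
    """Bundle of the mutable RIP serving state."""

    config: RIPConfig
    ledger: BudgetLedger = None  # type: ignore[assignment]
    history: HistoryLog = field(default_factory=HistoryLog)

    def __post_init__(self) -> None:
        if self.ledger is None:
            self.ledger = BudgetLedger(self.config)


def apply_rip(
    query: Query,
    matched: Sequence[Variant],
    user: UserContext,
    dataset: Dataset,
    ledger: BudgetLedger,
    history: HistoryLog,
    config: RIPConfig,
) -> DatasetResponse:
    """Filter a matched variant list through the budget algorithm.

    Repeated queries (same user, dataset and canonical key) are recalled from
    the history with no budget effect. Otherwise each matched variant is
    kept only if its risk fits within the remaining budget of *every* carrier;
    kept variants debit all their carriers (the server cannot know which
    subject an attacker targets), occluded variants debit nobody. The response
    is Boolean: present iff at least one variant survived.
    """
    if user.user_id is None:
        raise ValueError("RIP-mediated access requires an identified user")
    key = canonicalize(query)
    prior = history.recall(user.user_id, dataset.dataset_id, key)
    if prior is not None:
        return DatasetResponse(
            dataset.dataset_id, exists=prior.stored_response, rip_applied=True
        )

    n = dataset.effective_size
    kept: list[str] = []
    occluded: list[str] = []
    for variant in matched:
        risk = query_risk(variant.population_frequency, n, config.frequency_floor)
        carrier_ids = dataset.cohort.carrier_subject_ids(variant.variant_id)
        if any(risk > ledger.remaining(user.user_id, sid) for sid in carrier_ids):
            occluded.append(variant.variant_id)
            continue
        for sid in carrier_ids:
            ledger.spend(user.user_id, sid, risk)
        kept.append(variant.variant_id)

    exists = bool(kept)
    history.append(
        HistoryEntry(
            user_id=user.user_id,
            dataset_id=dataset.dataset_id,
            canonical_query=key,
            stored_response=exists,
            returned_variant_ids=tuple(kept),
            occluded_variant_ids=tuple(occluded),
        )
    )
    return DatasetResponse(dataset.dataset_id, exists=exists, rip_applied=True)


def recompute_budgets(
    history: HistoryLog,
    datasets: Mapping[str, Dataset] | Sequence[Dataset],
    config: RIPConfig,
) -> BudgetLedger:
    """Rebuild the ledger by replaying the history against current cohorts.

    Replays, in order, the debits of every history entry's returned variants
    using the *current* cohort size N of each dataset. Replay never occludes:
    past answers are immutable, only their cost is re-assessed (a grown
    dataset makes past answers cheaper, so remaining budgets can only grow).
    """
    if not isinstance(datasets, Mapping):
        datasets = {d.dataset_id: d for d in datasets}
    ledger = BudgetLedger(config)
    for entry in history:
        dataset = datasets.get(entry.dataset_id)
        if dataset is None:
            raise IntegrityError(f"history references unknown dataset {entry.dataset_id!r}")
        n = dataset.effective_size
        for vid in entry.returned_variant_ids:
            try:
                variant = dataset.variant_by_id(vid)
            except KeyError as exc:
                raise IntegrityError(
                    f"history references unknown variant {vid!r} in {entry.dataset_id!r}"
                ) from exc
            risk = query_risk(variant.population_frequency, n, config.frequency_floor)
            for sid in dataset.cohort.carrier_subject_ids(vid):
                ledger.spend(entry.user_id, sid, risk)
    return ledger
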