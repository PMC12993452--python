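"""Beacon v2 genomic query subtypes, access-tier resolution, and routing.

Six query subtypes are supported: ``sequence``, ``range``, ``gene``,
``bracket``, ``genomicAllele`` and ``aminoacidChange``, each with the
mandatory/optional parameter cardinalities of the Beacon v2 specification.
Datasets a user cannot access in full are either omitted from the response or
served through the re-identification prevention (RIP) filter, which downgrades
every response to Boolean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Any, Sequence

from .variant_store import Dataset, Variant

if TYPE_CHECKING:  # pragma: no cover
    from .rip import RIPState

__all__ = [
    "Query",
    "UserContext",
    "DatasetResponse",
    "QueryValidationError",
    "resolve_access",
    "match_variants",
    "canonicalize",
    "respond",
]

SUBTYPES = ("sequence", "range", "gene", "bracket", "genomicAllele", "aminoacidChange")
GRANULARITIES = ("boolean", "count", "record")
USER_STATUSES = ("unauthenticated", "authenticated", "researcher")

#: mandatory parameters per subtype
_MANDATORY: dict[str, tuple[str, ...]] = {
    "sequence": ("referenceName", "start", "referenceBases", "alternateBases"),
    "range": ("referenceName", "start", "end"),
    "gene": ("geneId",),
    "bracket": ("referenceName", "start", "end"),
    "genomicAllele": ("genomicAlleleShortForm",),
    "aminoacidChange": ("geneId", "aminoacidChange"),
}

#: optional parameters per subtype (beyond the mandatory ones)
_OPTIONAL: dict[str, tuple[str, ...]] = {
    "sequence": (),
    "range": (
        "variantType",
        "alternateBases",
        "aminoacidChange",
        "variantMinLength",
        "variantMaxLength",
    ),
    "gene": (
        "variantType",
        "alternateBases",
        "aminoacidChange",
        "variantMinLength",
        "variantMaxLength",
    ),
    "bracket": ("variantType",),
    "genomicAllele": (),
    "aminoacidChange": (),
}

#: parameters that are mutually exclusive where present together
_EXCLUSIVE = ("variantType", "alternateBases", "aminoacidChange")


class QueryValidationError(ValueError):
    """The query does not conform to its subtype schema."""


@dataclass
class Query:
    """A structured Beacon genomic query.

    For the ``bracket`` subtype, ``start`` and ``end`` are two-element
    sequences ``[low, high]``; for all other subtypes they are single
    integers. Coordinates are 0-based interbase.
    """

    subtype: str
    granularity: str = "boolean"
    referenceName: str | None = None
    start: int | Sequence[int] | None = None
    end: int | Sequence[int] | None = None
    referenceBases: str | None = None
    alternateBases: str | None = None
    variantType: str | None = None
    aminoacidChange: str | None = None
    variantMinLength: int | None = None
    variantMaxLength: int | None = None
    geneId: str | None = None
    genomicAlleleShortForm: str | None = None

    _FIELDS = (
        "referenceName",
        "start",
        "end",
        "referenceBases",
        "alternateBases",
        "variantType",
        "aminoacidChange",
        "variantMinLength",
        "variantMaxLength",
        "geneId",
        "genomicAlleleShortForm",
    )

    @classmethod
    def from_json(cls, obj: dict[str, Any]) -> "Query":
        """Build a query from a JSON object using Beacon parameter names."""
        unknown = set(obj) - set(cls._FIELDS) - {"subtype", "granularity"}
        if unknown:
            raise QueryValidationError(f"unknown query fields: {sorted(unknown)}")
        if "subtype" not in obj:
            raise QueryValidationError("missing mandatory field: subtype")
        q = cls(**obj)
        q.validate()
        return q

    def validate(self) -> None:
        if self.subtype not in SUBTYPES:
            raise QueryValidationError(f"unknown subtype {self.subtype!r}")
        if self.granularity not in GRANULARITIES:
            raise QueryValidationError(f"unknown granularity {self.granularity!r}")
        for name in _MANDATORY[self.subtype]:
            if getattr(self, name) is None:
                raise QueryValidationError(
                    f"{self.subtype} query: missing mandatory parameter {name!r}"
                )
        allowed = set(_MANDATORY[self.subtype]) | set(_OPTIONAL[self.subtype])
        for name in self._FIELDS:
            if getattr(self, name) is not None and name not in allowed:
                raise QueryValidationError(
                    f"{self.subtype} query: parameter {name!r} not permitted"
                )
        if self.subtype == "bracket":
            for name in ("start", "end"):
                val = getattr(self, name)
                if not isinstance(val, (list, tuple)) or len(val) != 2:
                    raise QueryValidationError(
                        f"bracket query: {name} must hold exactly two coordinates"
                    )
        else:
            for name in ("start", "end"):
                val = getattr(self, name)
                if val is not None and not isinstance(val, int):
                    raise QueryValidationError(
                        f"{self.subtype} query: {name} must be a single integer"
                    )
        exclusive = [n for n in _EXCLUSIVE if getattr(self, n) is not None]
        if self.subtype in ("range", "gene") and len(exclusive) > 1:
            raise QueryValidationError(
                f"{self.subtype} query: parameters {exclusive} are mutually exclusive"
            )


@dataclass(frozen=True)
class UserContext:
    """Who is asking: declared status plus explicit dataset authorizations."""

    user_id: str | None = None
    status: str = "unauthenticated"
    authorized_dataset_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.status not in USER_STATUSES:
            raise ValueError(f"unknown user status {self.status!r}")
        object.__setattr__(
            self, "authorized_dataset_ids", frozenset(self.authorized_dataset_ids)
        )
        if self.status == "unauthenticated" and self.authorized_dataset_ids:
            raise ValueError("unauthenticated users cannot hold authorizations")


@dataclass
class DatasetResponse:
    """Per-dataset answer. Under RIP only the Boolean ``exists`` is present."""

    dataset_id: str
    exists: bool
    count: int | None = None
    records: list[dict[str, Any]] | None = None
    rip_applied: bool = False

    def __post_init__(self) -> None:
        if self.rip_applied and (self.count is not None or self.records is not None):
            raise ValueError("RIP responses must be Boolean-only")

    def to_json(self) -> dict[str, Any]:
        out: dict[str, Any] = {
            "datasetId": self.dataset_id,
            "exists": self.exists,
            "ripApplied": self.rip_applied,
        }
        if self.count is not None:
            out["count"] = self.count
        if self.records is not None:
            out["records"] = self.records
        return out


def resolve_access(user: UserContext, dataset: Dataset) -> str:
    """Resolve the access mode for a (user, dataset) pair: full / rip / none.

    Public datasets are fully open. Unauthenticated users see nothing else.
    Authenticated users get RIP-mediated access to registered and controlled
    datasets; researchers get full access to registered datasets and RIP on
    controlled ones; an explicit authorization grants full access everywhere.
    """
    if dataset.access_level == "public":
        return "full"
    if user.status == "unauthenticated":
        return "none"
    if dataset.dataset_id in user.authorized_dataset_ids:
        return "full"
    if dataset.access_level == "registered" and user.status == "researcher":
        return "full"
    return "rip"


def _alt_length(variant: Variant) -> int:
    return len(variant.alternate_bases)


def _passes_optional_filters(variant: Variant, query: Query) -> bool:
    if query.variantType is not None and variant.variant_type != query.variantType:
        return False
    if (
        query.alternateBases is not None
        and variant.alternate_bases != query.alternateBases.upper()
    ):
        return False
    if (
        query.aminoacidChange is not None
        and variant.aminoacid_change != query.aminoacidChange
    ):
        return False
    if query.variantMinLength is not None and _alt_length(variant) < query.variantMinLength:
        return False
    if query.variantMaxLength is not None and _alt_length(variant) > query.variantMaxLength:
        return False
    return True


def match_variants(query: Query, dataset: Dataset) -> list[Variant]:
    """Return the stored variants matched by ``query``.

    Sequence queries are exact allele matches; range queries use half-open
    overlap on [start, end); bracket queries are inclusive on both bracket
    bounds; gene and aminoacid-change queries match annotations exactly.
    """
    query.validate()
    st = query.subtype
    if st == "sequence":
        return dataset.find_sequence(
            query.referenceName, query.start, query.referenceBases, query.alternateBases
        )
    if st == "range":
        return [
            v
            for v in dataset.variants
            if v.reference_name == query.referenceName
            and v.start < query.end
            and v.end > query.start
            and _passes_optional_filters(v, query)
        ]
    if st == "gene":
        return [
            v
            for v in dataset.variants
            if v.gene_id is not None
            and v.gene_id == query.geneId
            and _passes_optional_filters(v, query)
        ]
    if st == "bracket":
        (s1, s2), (e1, e2) = query.start, query.end
        return [
            v
            for v in dataset.variants
            if v.reference_name == query.referenceName
            and s1 <= v.start <= s2
            and e1 <= v.end <= e2
            and (query.variantType is None or v.variant_type == query.variantType)
        ]
    if st == "genomicAllele":
        return [
            v
            for v in dataset.variants
            if v.genomic_allele_short_form is not None
            and v.genomic_allele_short_form == query.genomicAlleleShortForm
        ]
    # aminoacidChange
    return [
        v
        for v in dataset.variants
        if v.gene_id == query.geneId and v.aminoacid_change == query.aminoacidChange
    ]


def canonicalize(query: Query) -> str:
    """Deterministic canonical key for a query.

    Parameter order and base case are normalised; granularity is excluded
    because RIP responses are Boolean regardless of the requested granularity,
    so two queries differing only in granularity carry identical information.
    """
    query.validate()
    parts = [f"subtype={query.subtype}"]
    for name in sorted(Query._FIELDS):
        val = getattr(query, name)
        if val is None:
            continue
        if name in ("referenceBases", "alternateBases"):
            val = val.upper()
        if isinstance(val, (list, tuple)):
            val = ",".join(str(int(x)) for x in val)
        parts.append(f"{name}={val}")
    return "|".join(parts)


def _full_response(query: Query, dataset: Dataset, matched: list[Variant]) -> DatasetResponse:
    if query.granularity == "boolean":
        return DatasetResponse(dataset.dataset_id, exists=bool(matched))
    if query.granularity == "count":
        return DatasetResponse(dataset.dataset_id, exists=bool(matched), count=len(matched))
    records = [
        {
            "variantId": v.variant_id,
            "referenceName": v.reference_name,
            "start": v.start,
            "end": v.end,
            "referenceBases": v.reference_bases,
            "alternateBases": v.alternate_bases,
            "variantType": v.variant_type,
            "geneId": v.gene_id,
        }
        for v in matched
    ]
    return DatasetResponse(
        dataset.dataset_id, exists=bool(matched), count=len(matched), records=records
    )


def respond(
    query: Query,
    user: UserContext,
    datasets: Sequence[Dataset],
    rip_state: "RIPState | None" = None,
) -> list[DatasetResponse]:
    """Execute a query for a user across datasets, honouring access tiers.

    Inaccessible datasets are omitted entirely (an explicit "no access" entry
    would itself leak the dataset's existence). RIP-mediated datasets yield
    Boolean-only responses with ``rip_applied=True``; requests for count or
    record granularity are downgraded, not rejected.
    """
    from . import rip as _rip  # deferred to avoid an import cycle

    query.validate()
    responses: list[DatasetResponse] = []
    for dataset in datasets:
        access = resolve_access(user, dataset)
        if access == "none":
            continue
        matched = match_variants(query, dataset)
        if access == "full":
            responses.append(_full_response(query, dataset, matched))
        else:
            if rip_state is None:
                raise ValueError(
                    "RIP-mediated access requires a RIPState (ledger/history/config)"
                )
            responses.append(
                _rip.apply_rip(
                    query,
                    matched,
                    user,
                    dataset,
                    rip_state.ledger,
                    rip_state.history,
                    rip_state.config,
                )
            )
    return responses
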