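"""Variant, cohort and dataset containers, synthetic cohort generation, and I/O.

A :class:`Dataset` couples a diploid cohort (subjects and per-variant carrier
sets) with a variant catalog annotated with *population* allele frequencies.
The population frequency is external reference-panel information (in a real
deployment it comes from a resource such as Ensembl), distinct from the
empirical in-cohort frequency; it is the ``f`` that enters the
re-identification risk formula.

Coordinates are 0-based interbase internally (the Beacon v2 convention); VCF
input/output is 1-based and converted at the boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

__all__ = [
    "Variant",
    "Cohort",
    "Dataset",
    "SFSParams",
    "DEFAULT_FREQUENCY_FLOOR",
    "generate_cohort",
    "load_vcf",
    "write_vcf",
    "load_frequency_table",
    "write_frequency_table",
    "load_manifest",
    "write_manifest",
]

#: Frequency assigned to variants with no annotated population frequency.
#: A frequency of 0 would make the re-identification risk infinite; the floor
#: (one allele in a panel of a million diploid genomes) makes unannotated
#: variants maximally protected but finite.
DEFAULT_FREQUENCY_FLOOR = 1.0 / (2 * 10**6)

VALID_BASES = frozenset("ACGTN")
VARIANT_TYPES = frozenset({"SNP", "INS", "DEL", "DUP", "INV", "CNV"})
ACCESS_LEVELS = ("public", "registered", "controlled")


class ConfigurationError(ValueError):
    """Invalid generator or store configuration."""


class VCFParseError(ValueError):
    """Malformed or unsupported VCF content."""


class FrequencyTableError(ValueError):
    """Invalid frequency sidecar content."""


@dataclass(slots=True)
class Variant:
    """A genomic variant with coordinates, alleles and annotations.

    ``start``/``end`` are 0-based interbase. ``population_frequency`` is the
    external reference-panel allele frequency in [0, 1].
    """

    variant_id: str
    reference_name: str
    start: int
    end: int
    reference_bases: str
    alternate_bases: str
    population_frequency: float
    variant_type: str | None = None
    gene_id: str | None = None
    aminoacid_change: str | None = None
    genomic_allele_short_form: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(
                f"variant {self.variant_id}: need 0 <= start <= end, "
                f"got [{self.start}, {self.end}]"
            )
        self.reference_bases = self.reference_bases.upper()
        self.alternate_bases = self.alternate_bases.upper()
        for bases in (self.reference_bases, self.alternate_bases):
            if not set(bases) <= VALID_BASES:
                raise ValueError(f"variant {self.variant_id}: invalid bases {bases!r}")
        if not 0.0 <= self.population_frequency <= 1.0:
            raise ValueError(
                f"variant {self.variant_id}: population frequency "
                f"{self.population_frequency} outside [0, 1]"
            )
        if self.variant_type is not None and self.variant_type not in VARIANT_TYPES:
            raise ValueError(
                f"variant {self.variant_id}: unknown variant type {self.variant_type!r}"
            )

    @property
    def key(self) -> str:
        """Sidecar-table key, ``referenceName:pos1based:REF>ALT``."""
        return (
            f"{self.reference_name}:{self.start + 1}:"
            f"{self.reference_bases}>{self.alternate_bases}"
        )


@dataclass
class Cohort:
    """Ordered subjects plus per-variant carrier sets.

    Carriers are stored as sorted arrays of subject *indices* into
    ``subject_ids``; a subject is a carrier when it holds at least one copy of
    the alternate allele (carriage is binary, matching Boolean responses).
    """

    subject_ids: list[str]
    carriers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.subject_ids) < 1:
            raise ValueError("a cohort needs at least one subject")
        n = len(self.subject_ids)
        for vid, idx in self.carriers.items():
            arr = np.asarray(idx, dtype=np.int32)
            if arr.size and (arr.min() < 0 or arr.max() >= n):
                raise ValueError(f"carrier indices for {vid} outside the cohort")
            self.carriers[vid] = np.unique(arr)

    @property
    def size(self) -> int:
        return len(self.subject_ids)

    def carrier_indices(self, variant_id: str) -> np.ndarray:
        return self.carriers.get(variant_id, np.empty(0, dtype=np.int32))

    def carrier_subject_ids(self, variant_id: str) -> list[str]:
        return [self.subject_ids[i] for i in self.carrier_indices(variant_id)]

    def variant_ids_of_subject(self, subject_index: int) -> list[str]:
        """Variant ids carried by one subject (inverted carrier index).

        The first call builds a flat CSR-style index over all carrier sets;
        carrier sets are treated as immutable once the cohort is constructed.
        """
        cache = getattr(self, "_inverted", None)
        if cache is None:
            vids = list(self.carriers)
            if vids:
                flat = np.concatenate([self.carriers[v] for v in vids])
                lengths = np.fromiter(
                    (self.carriers[v].size for v in vids), dtype=np.int64, count=len(vids)
                )
            else:
                flat = np.empty(0, dtype=np.int32)
                lengths = np.empty(0, dtype=np.int64)
            offsets = np.concatenate([[0], np.cumsum(lengths)])
            cache = (vids, flat, offsets)
            self._inverted = cache
        vids, flat, offsets = cache
        hits = np.flatnonzero(flat == subject_index)
        rows = np.searchsorted(offsets, hits, side="right") - 1
        return [vids[r] for r in rows]


@dataclass
class Dataset:
    """A named variant collection with an access tier and its cohort.

    ``size_override`` replaces the cohort size in risk computations only; it
    supports simulating how a larger cohort behind the same variant catalog
    would be protected, without materialising the extra genotypes.
    """

    dataset_id: str
    access_level: str
    cohort: Cohort
    variants: list[Variant]
    size_override: int | None = None

    def __post_init__(self) -> None:
        if self.access_level not in ACCESS_LEVELS:
            raise ValueError(
                f"access level must be one of {ACCESS_LEVELS}, got {self.access_level!r}"
            )
        self._by_id: dict[str, Variant] = {}
        self._by_seq: dict[tuple[str, int, str, str], list[Variant]] = {}
        for v in self.variants:
            if v.variant_id in self._by_id:
                raise ValueError(f"duplicate variant id {v.variant_id}")
            self._by_id[v.variant_id] = v
            k = (v.reference_name, v.start, v.reference_bases, v.alternate_bases)
            self._by_seq.setdefault(k, []).append(v)

    @property
    def effective_size(self) -> int:
        """Cohort size N used in risk computations."""
        return self.size_override if self.size_override is not None else self.cohort.size

    def variant_by_id(self, variant_id: str) -> Variant:
        return self._by_id[variant_id]

    def find_sequence(
        self, reference_name: str, start: int, reference_bases: str, alternate_bases: str
    ) -> list[Variant]:
        key = (reference_name, start, reference_bases.upper(), alternate_bases.upper())
        return list(self._by_seq.get(key, ()))


# ---------------------------------------------------------------------------
# Synthetic cohort generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SFSParams:
    """Site-frequency-spectrum parameters for the synthetic generator.

    The default spectrum has density proportional to 1/f (the rare-skewed
    shape of neutral-theory expectations) truncated to
    ``[f_min, f_max]``. When ``f_min`` is None it defaults to one allele in
    the cohort, ``1 / (2 * n_subjects)``.

    ``ascertained=True`` models a Beacon variant *catalog*: every stored
    variant was observed in the cohort, so one uniformly chosen carrier is
    guaranteed per variant while the annotated population frequency still
    follows the (external panel) spectrum. This reproduces how a real Beacon
    holds cohort singletons whose reference-panel frequency is far below
    1/(2N).
    """

    f_min: float | None = None
    f_max: float = 0.5
    ascertained: bool = False

    def resolve_f_min(self, n_subjects: int) -> float:
        f_min = self.f_min if self.f_min is not None else 1.0 / (2 * n_subjects)
        if not (0.0 < f_min <= self.f_max <= 1.0):
            raise ConfigurationError(
                f"need 0 < f_min <= f_max <= 1, got [{f_min}, {self.f_max}]"
            )
        return f_min


#: Reference-panel frequency resolution used for experiment cohorts: one
#: allele in a 500k-subject panel (biobank scale).
PANEL_F_MIN = 1e-6

_BASES = np.array(list("ACGT"))


def generate_cohort(
    n_subjects: int,
    n_variants: int,
    sfs: SFSParams | None = None,
    seed: int = 0,
    dataset_id: str = "synthetic",
    access_level: str = "registered",
    reference_name: str = "1",
    frequencies: Sequence[float] | None = None,
    gene_block: int = 100,
) -> Dataset:
    """Generate a synthetic diploid cohort with annotated frequencies.

    Each subject carries variant i independently with probability
    ``1 - (1 - f_i)^2`` (diploid carriage of an allele at population frequency
    f_i, Hardy-Weinberg). The annotated ``population_frequency`` is the
    generative f, not the realised in-cohort fraction, mirroring the use of
    external panel frequencies distinct from Beacon content.

    Deterministic given ``seed``. ``frequencies`` overrides the spectrum draw
    (one value per variant). Variants are SNPs on a single contig, assigned
    gene identifiers in blocks of ``gene_block`` for gene-based queries.
    """
    if n_subjects < 1 or n_variants < 1:
        raise ConfigurationError("n_subjects and n_variants must be >= 1")
    sfs = sfs or SFSParams()
    rng = np.random.default_rng(seed)

    if frequencies is not None:
        f = np.asarray(frequencies, dtype=float)
        if f.shape != (n_variants,):
            raise ConfigurationError("frequencies must have one entry per variant")
        if np.any((f < 0) | (f > 1)):
            raise ConfigurationError("frequencies must lie in [0, 1]")
    else:
        f_min = sfs.resolve_f_min(n_subjects)
        # inverse-CDF draw from density ∝ 1/f on [f_min, f_max]
        u = rng.random(n_variants)
        f = f_min * (sfs.f_max / f_min) ** u

    subject_ids = [f"S{i:06d}" for i in range(n_subjects)]
    starts = 100 + 3 * np.arange(n_variants)
    ref_idx = rng.integers(0, 4, size=n_variants)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_variants)) % 4

    carrier_prob = 1.0 - (1.0 - f) ** 2
    carriers: dict[str, np.ndarray] = {}
    variants: list[Variant] = []
    chunk = max(1, 8_000_000 // max(n_subjects, 1))
    for lo in range(0, n_variants, chunk):
        hi = min(lo + chunk, n_variants)
        draws = rng.random((hi - lo, n_subjects))
        hits = draws < carrier_prob[lo:hi, None]
        for j in range(lo, hi):
            idx = np.nonzero(hits[j - lo])[0].astype(np.int32)
            if sfs.ascertained and idx.size == 0:
                idx = np.array([rng.integers(0, n_subjects)], dtype=np.int32)
            vid = f"{dataset_id}.v{j}"
            carriers[vid] = idx
            variants.append(
                Variant(
                    variant_id=vid,
                    reference_name=reference_name,
                    start=int(starts[j]),
                    end=int(starts[j]) + 1,
                    reference_bases=str(_BASES[ref_idx[j]]),
                    alternate_bases=str(_BASES[alt_idx[j]]),
                    population_frequency=float(f[j]),
                    variant_type="SNP",
                    gene_id=f"GENE{j // gene_block}",
                )
            )

    cohort = Cohort(subject_ids=subject_ids, carriers=carriers)
    return Dataset(
        dataset_id=dataset_id,
        access_level=access_level,
        cohort=cohort,
        variants=variants,
    )


# ---------------------------------------------------------------------------
# VCF I/O (minimal subset: CHROM, POS, ID, REF, ALT, FORMAT GT)
# ---------------------------------------------------------------------------


def write_vcf(dataset: Dataset, path: str | Path) -> None:
    """Write the dataset as an uncompressed VCF 4.2 with diploid GT fields.

    Carriers are written as 0/1 heterozygotes (carriage is binary throughout;
    zygosity is not tracked). Population frequencies travel in the sidecar
    table, not the VCF.
    """
    path = Path(path)
    header = pysam.VariantHeader()
    contigs = sorted({v.reference_name for v in dataset.variants})
    max_end = max((v.end for v in dataset.variants), default=0)
    for contig in contigs:
        header.contigs.add(contig, length=max_end + 1000)
    header.formats.add("GT", 1, "String", "Genotype")
    for sid in dataset.cohort.subject_ids:
        header.add_sample(sid)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(dataset.variants, key=lambda v: (v.reference_name, v.start)):
            rec = out.new_record(
                contig=v.reference_name,
                start=v.start,
                stop=max(v.end, v.start + len(v.reference_bases) or 1),
                alleles=(v.reference_bases, v.alternate_bases or "<DEL>"),
                id=v.variant_id,
            )
            carrier_idx = set(dataset.cohort.carrier_indices(v.variant_id).tolist())
            for i, sid in enumerate(dataset.cohort.subject_ids):
                rec.samples[sid]["GT"] = (0, 1) if i in carrier_idx else (0, 0)
            out.write(rec)


def load_vcf(
    path: str | Path,
    dataset_id: str | None = None,
    access_level: str = "registered",
    frequency_floor: float = DEFAULT_FREQUENCY_FLOOR,
) -> Dataset:
    """Load a VCF 4.x with diploid GT fields into a :class:`Dataset`.

    One :class:`Variant` is produced per ALT allele per record (multi-allelic
    records are decomposed); the carriers of each are the samples whose GT
    contains that ALT allele index. VCF 1-based positions are converted to
    0-based interbase. Frequencies are initialised to ``frequency_floor``
    until a sidecar table is attached.
    """
    path = Path(path)
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VCFParseError(f"cannot parse VCF {path}: {exc}") from exc

    with vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise VCFParseError(f"{path}: no samples in VCF header")
        variants: list[Variant] = []
        carriers: dict[str, np.ndarray] = {}
        for line_no, rec in enumerate(vcf, start=1):
            if "GT" not in rec.format:
                raise VCFParseError(f"{path}: record {line_no} has no GT field")
            alts = rec.alts or ()
            gts = [rec.samples[s].get("GT") for s in samples]
            for alt_i, alt in enumerate(alts, start=1):
                alt_bases = "" if alt in ("<DEL>", "*") else alt
                vid = rec.id or f"{rec.contig}:{rec.pos}:{rec.ref}>{alt_bases}"
                if len(alts) > 1:
                    vid = f"{vid}#{alt_i}"
                try:
                    variant = Variant(
                        variant_id=vid,
                        reference_name=rec.contig,
                        start=rec.start,  # pysam already 0-based
                        end=rec.start + max(len(rec.ref), 1),
                        reference_bases=rec.ref,
                        alternate_bases=alt_bases,
                        population_frequency=frequency_floor,
                    )
                except ValueError as exc:
                    raise VCFParseError(f"{path}: record {line_no}: {exc}") from exc
                idx = [
                    i
                    for i, gt in enumerate(gts)
                    if gt is not None and alt_i in {a for a in gt if a is not None}
                ]
                variants.append(variant)
                carriers[vid] = np.asarray(idx, dtype=np.int32)

    cohort = Cohort(subject_ids=samples, carriers=carriers)
    return Dataset(
        dataset_id=dataset_id or path.stem,
        access_level=access_level,
        cohort=cohort,
        variants=variants,
    )


# ---------------------------------------------------------------------------
# Frequency sidecar (TSV: variant_key <TAB> frequency)
# ---------------------------------------------------------------------------


def write_frequency_table(dataset: Dataset, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("variant_key\tfrequency\n")
        for v in dataset.variants:
            fh.write(f"{v.key}\t{v.population_frequency:.17g}\n")


def load_frequency_table(
    path: str | Path,
    dataset: Dataset,
    frequency_floor: float = DEFAULT_FREQUENCY_FLOOR,
) -> list[str]:
    """Attach population frequencies from a sidecar TSV to ``dataset``.

    Matching is by ``referenceName:pos1based:REF>ALT`` key. Unmatched variants
    receive ``frequency_floor`` and their ids are returned so callers can
    report them. Duplicate keys with conflicting values are rejected.
    """
    path = Path(path)
    table: dict[str, float] = {}
    with path.open() as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "variant_key":  # header
                continue
            if len(parts) < 2:
                raise FrequencyTableError(f"{path}:{line_no}: expected 2 columns")
            key = parts[0]
            try:
                freq = float(parts[1])
            except ValueError as exc:
                raise FrequencyTableError(
                    f"{path}:{line_no}: frequency {parts[1]!r} is not a number"
                ) from exc
            if not 0.0 <= freq <= 1.0:
                raise FrequencyTableError(
                    f"{path}:{line_no}: frequency {freq} outside [0, 1]"
                )
            if key in table and table[key] != freq:
                raise FrequencyTableError(
                    f"{path}:{line_no}: conflicting duplicate entry for {key}"
                )
            table[key] = freq

    unmatched: list[str] = []
    for v in dataset.variants:
        if v.key in table:
            v.population_frequency = table[v.key]
        else:
            v.population_frequency = frequency_floor
            unmatched.append(v.variant_id)
    return unmatched


# ---------------------------------------------------------------------------
# Dataset manifest (JSON: datasetId, accessLevel, VCF path, frequency path)
# ---------------------------------------------------------------------------


def write_manifest(
    path: str | Path, dataset_id: str, access_level: str, vcf_path: str, freq_path: str
) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "datasetId": dataset_id,
                "accessLevel": access_level,
                "vcf": vcf_path,
                "frequencies": freq_path,
            },
            indent=2,
        )
        + "\n"
    )


def load_manifest(path: str | Path, frequency_floor: float = DEFAULT_FREQUENCY_FLOOR) -> Dataset:
    """Load a dataset (VCF + frequency sidecar) described by a JSON manifest."""
    path = Path(path)
    spec = json.loads(path.read_text())
    base = path.parent
    dataset = load_vcf(
        base / spec["vcf"],
        dataset_id=spec["datasetId"],
        access_level=spec["accessLevel"],
        frequency_floor=frequency_floor,
    )
    freq = spec.get("frequencies")
    if freq:
        load_frequency_table(base / freq, dataset, frequency_floor=frequency_floor)
    return dataset
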