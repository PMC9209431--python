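"""Domain types shared across the two-hit discovery pipeline.

Coordinates are 1-based inclusive throughout (VCF convention); BED input is
converted at the I/O boundary.  Genotypes use the closed vocabulary
``hom_ref / het / hom_alt / missing``; consequence classes use the closed
vocabulary in :data:`CONSEQUENCE_CLASSES`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "CONSEQUENCE_CLASSES",
    "PROTEIN_ALTERING_CLASSES",
    "TRUNCATING_CLASSES",
    "GENOTYPES",
    "ConfigError",
    "InputError",
    "AnnotatedVariant",
    "VariantTable",
    "Individual",
    "Pedigree",
    "CnvSegment",
    "GeneModel",
    "PhaseBlock",
    "ExtendedHaplotype",
    "LohCall",
    "CandidateGene",
]

CONSEQUENCE_CLASSES = frozenset(
    {
        "missense",
        "nonsense",
        "splice_site",
        "stop_lost",
        "frameshift",
        "inframe",
        "synonymous",
        "other",
    }
)

#: Classes with the potential to alter protein function (the filter vocabulary).
PROTEIN_ALTERING_CLASSES = frozenset(
    {"missense", "nonsense", "splice_site", "stop_lost", "frameshift", "inframe"}
)

#: Classes that truncate the protein; never triaged out on predicted-impact scores.
TRUNCATING_CLASSES = frozenset({"nonsense", "frameshift", "stop_lost"})

GENOTYPES = ("hom_ref", "het", "hom_alt", "missing")


class ConfigError(ValueError):
    """Invalid configuration (CLI exit code 3)."""


class InputError(ValueError):
    """Malformed or missing input data (CLI exit code 2)."""


@dataclass(frozen=True)
class AnnotatedVariant:
    """One biallelic germline or somatic variant with its annotations.

    ``genotypes`` is ordered like the owning table's ``sample_ids``.
    ``phase_set``/``phased_allele`` carry linked-read local phasing: the id of
    the phase block and the local haplotype index (1 or 2) holding the alt
    allele, for samples where the call is phased (a per-sample dict).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    filter_status: str = "PASS"
    gene: str = ""
    vclass: str = "other"
    af_esp: Optional[float] = None
    af_exac: Optional[float] = None
    af_gnomad: Optional[float] = None
    cadd_phred: Optional[float] = None
    polyphen: Optional[str] = None
    sift: Optional[str] = None
    genotypes: tuple[str, ...] = ()
    phase_set: dict[str, str] = field(default_factory=dict, compare=False)
    phased_allele: dict[str, int] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.vclass not in CONSEQUENCE_CLASSES:
            raise ValueError(f"unknown consequence class {self.vclass!r}")
        for af in (self.af_esp, self.af_exac, self.af_gnomad):
            if af is not None and not 0.0 <= af <= 1.0:
                raise ValueError(f"allele frequency {af} outside [0, 1]")
        for g in self.genotypes:
            if g not in GENOTYPES:
                raise ValueError(f"unknown genotype {g!r}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def genotype_of(self, sample_index: int) -> str:
        return self.genotypes[sample_index]


@dataclass
class VariantTable:
    """An ordered collection of biallelic variants over a fixed sample panel."""

    records: list[AnnotatedVariant]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        for rec in self.records:
            if rec.genotypes and len(rec.genotypes) != n:
                raise ValueError(
                    f"record {rec.key}: {len(rec.genotypes)} genotypes for "
                    f"{n} samples"
                )
        keys = [r.key for r in self.records]
        if len(set(keys)) != len(keys):
            dup = next(k for k in keys if keys.count(k) > 1)
            raise ValueError(f"duplicate variant key {dup}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in table") from None

    def genotype(self, rec: AnnotatedVariant, sample_id: str) -> str:
        return rec.genotypes[self.sample_index(sample_id)]

    def subset(self, keep) -> "VariantTable":
        """New table with the records for which ``keep(record)`` is true."""
        return VariantTable(
            records=[r for r in self.records if keep(r)],
            sample_ids=list(self.sample_ids),
        )


@dataclass(frozen=True)
class Individual:
    id: str
    father_id: str = "0"
    mother_id: str = "0"
    sex: int = 0
    phenotype: str = "unknown"  # affected | unaffected | unknown

    @property
    def is_founder(self) -> bool:
        return self.father_id in ("0", "") and self.mother_id in ("0", "")


@dataclass
class Pedigree:
    individuals: list[Individual]

    def __post_init__(self) -> None:
        ids = [i.id for i in self.individuals]
        if len(set(ids)) != len(ids):
            dup = next(x for x in ids if ids.count(x) > 1)
            raise InputError(f"duplicate individual id {dup!r} in pedigree")
        known = set(ids) | {"0", ""}
        for i in self.individuals:
            if i.father_id not in known or i.mother_id not in known:
                raise InputError(f"individual {i.id}: unresolved parent id")

    @property
    def affected_ids(self) -> list[str]:
        return [i.id for i in self.individuals if i.phenotype == "affected"]

    @property
    def unaffected_ids(self) -> list[str]:
        return [i.id for i in self.individuals if i.phenotype == "unaffected"]

    def __iter__(self):
        return iter(self.individuals)


@dataclass(frozen=True)
class CnvSegment:
    """A somatic copy-number segment, 1-based inclusive internally."""

    chrom: str
    start: int
    end: int
    sample: str
    log2: float = 0.0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")

    @property
    def is_deletion(self) -> bool:
        return self.log2 < 0.0

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start <= end and start <= self.end


@dataclass(frozen=True)
class GeneModel:
    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene}: start {self.start} > end {self.end}")


@dataclass
class PhaseBlock:
    """A locally phased block with per-local-haplotype barcode counts.

    Local haplotype labels 1/2 are an arbitrary gauge: any algorithm consuming
    blocks must be invariant under swapping (hap1_count, hap2_count) together
    with the phased-allele assignments of the block.
    """

    block_id: str
    chrom: str
    start: int
    end: int
    sample: str
    hap1_count: int
    hap2_count: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"block {self.block_id}: start > end")
        if self.hap1_count < 0 or self.hap2_count < 0:
            raise InputError(
                f"block {self.block_id}: negative barcode count"
            )

    @property
    def total(self) -> int:
        return self.hap1_count + self.hap2_count

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos <= self.end


@dataclass
class ExtendedHaplotype:
    """A stitched Mb-scale haplotype over a region, with a deleted-hap call.

    ``orientation`` maps block_id -> flip bit: 0 means the block's local hap 1
    is global haplotype A (retained), 1 means local hap 1 is global haplotype B
    (deleted candidate).  Blocks absent from the mapping were unorientable.
    """

    chrom: str
    start: int
    end: int
    orientation: dict[str, int]
    pooled_count_a: int
    pooled_count_b: int
    deleted_haplotype: str  # "A" | "B" | "indeterminate"
    pooled_p: float
    block_p: dict[str, float]

    def __post_init__(self) -> None:
        if self.deleted_haplotype not in ("A", "B", "indeterminate"):
            raise ValueError(f"bad deleted_haplotype {self.deleted_haplotype!r}")


@dataclass
class LohCall:
    """Cis/trans assignment of a candidate allele across a somatic deletion."""

    variant_key: str
    fate: str  # wildtype_lost | mutant_lost | indeterminate
    supporting_block: Optional[str] = None
    p_value: Optional[float] = None
    reason: str = ""

    def __post_init__(self) -> None:
        if self.fate not in ("wildtype_lost", "mutant_lost", "indeterminate"):
            raise ValueError(f"bad fate {self.fate!r}")


@dataclass
class CandidateGene:
    """A gene surviving the germline funnel, with somatic evidence and triage."""

    gene: str
    germline_variant_keys: list[str]
    deletion_samples: set[str] = field(default_factory=set)
    somatic_variant_keys: dict[str, list[str]] = field(default_factory=dict)
    polyphen_benign: bool = False
    sift_tolerated: bool = False
    cadd_low: bool = False
    status: str = "candidate"  # candidate | triaged_out
    loh_calls: dict[str, LohCall] = field(default_factory=dict)

    def somatic_evidence_samples(self) -> set[str]:
        return self.deletion_samples | {
            s for s, keys in self.somatic_variant_keys.items() if keys
        }


def _copy_with(obj, **kw):
    return replace(obj, **kw)
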