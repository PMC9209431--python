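"""The germline filtering funnel for a dominant familial predisposition.

Three filters applied to a joint pedigree callset, in any order (they
commute: each is a pure per-record predicate):

1. quality — keep FILTER=PASS records only;
2. shared-in-affected — keep variants carried (>= 1 alt allele) by every
   affected sibling; unaffected carriage is allowed (incomplete penetrance);
3. protein-altering — keep consequence classes with the potential to change
   the protein (missense, nonsense, splice site, stop lost, frameshift,
   in-frame);
4. population frequency — keep variants whose maximum allele frequency over
   the available population databases is below a threshold (default 1%);
   variants absent from every database are retained.

The funnel report records per-stage SNV/indel counts and collapses the final
stage to distinct genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import (
    ConfigError,
    InputError,
    Pedigree,
    PROTEIN_ALTERING_CLASSES,
    VariantTable,
)

__all__ = [
    "filter_pass",
    "filter_shared_in_affected",
    "filter_protein_altering",
    "filter_population_frequency",
    "summarize_funnel",
    "run_germline_funnel",
    "FunnelReport",
]

PRESENT_GENOTYPES = frozenset({"het", "hom_alt"})


@dataclass
class FunnelStage:
    name: str
    n_snv: int
    n_indel: int

    @property
    def total(self) -> int:
        return self.n_snv + self.n_indel


@dataclass
class FunnelReport:
    stages: list[FunnelStage]
    final_genes: dict[str, list[str]] = field(default_factory=dict)
    final_variants: list[dict] = field(default_factory=list)
    af_aggregation: str = "max_over_databases"

    def __post_init__(self) -> None:
        totals = [s.total for s in self.stages]
        if any(a < b for a, b in zip(totals, totals[1:])):
            raise ValueError("funnel stage counts must be non-increasing")

    @property
    def final_gene_count(self) -> int:
        return len(self.final_genes)

    def to_dict(self) -> dict:
        return {
            "stages": [
                {"name": s.name, "snv": s.n_snv, "indel": s.n_indel,
                 "total": s.total}
                for s in self.stages
            ],
            "final_genes": {g: sorted(k) for g, k in self.final_genes.items()},
            "final_variants": list(self.final_variants),
            "final_gene_count": self.final_gene_count,
            "af_aggregation": self.af_aggregation,
        }


def filter_pass(table: VariantTable) -> VariantTable:
    """Keep only records whose FILTER is PASS."""
    return table.subset(lambda r: r.filter_status == "PASS")


def filter_shared_in_affected(
    table: VariantTable,
    pedigree: Pedigree,
    missing_as_present: bool = False,
) -> VariantTable:
    """Keep variants carried by every affected individual.

    "Carried" means genotype het or hom_alt.  A missing genotype in an
    affected individual counts as not carried unless ``missing_as_present``.
    Unaffected individuals are unconstrained (incomplete penetrance).
    """
    affected = pedigree.affected_ids
    if not affected:
        raise InputError("pedigree contains no affected individuals")
    try:
        idx = [table.sample_index(s) for s in affected]
    except KeyError as exc:
        raise InputError(f"affected sample missing from table: {exc}") from exc

    allowed = PRESENT_GENOTYPES | ({"missing"} if missing_as_present else set())
    return table.subset(
        lambda r: all(r.genotypes[i] in allowed for i in idx)
    )


def filter_protein_altering(table: VariantTable) -> VariantTable:
    """Keep consequence classes with the potential to alter the protein."""
    return table.subset(lambda r: r.vclass in PROTEIN_ALTERING_CLASSES)


def filter_population_frequency(
    table: VariantTable, threshold: float = 0.01
) -> VariantTable:
    """Keep variants rare in every population database.

    A record is retained iff the maximum over its available database AFs is
    strictly below ``threshold``; a record absent from all databases is
    treated as unobserved (AF 0) and retained.
    """
    if not 0.0 < threshold <= 1.0:
        raise ConfigError(f"AF threshold {threshold} outside (0, 1]")

    def rare(r) -> bool:
        afs = [a for a in (r.af_esp, r.af_exac, r.af_gnomad) if a is not None]
        return max(afs, default=0.0) < threshold

    return table.subset(rare)


def summarize_funnel(
    stages: list[tuple[str, VariantTable]]
) -> FunnelReport:
    """Per-stage SNV/indel counts plus the distinct-gene collapse of the
    final stage (SNV = single-base ref and alt; anything else is an indel)."""
    report_stages = []
    for name, table in stages:
        n_snv = sum(1 for r in table if r.is_snv)
        report_stages.append(FunnelStage(name, n_snv, len(table) - n_snv))
    final_genes: dict[str, list[str]] = {}
    final_variants: list[dict] = []
    if stages:
        for r in stages[-1][1]:
            final_genes.setdefault(r.gene or "intergenic", []).append(r.key)
            final_variants.append(
                {
                    "key": r.key,
                    "gene": r.gene,
                    "vclass": r.vclass,
                    "polyphen": r.polyphen,
                    "sift": r.sift,
                    "cadd_phred": r.cadd_phred,
                }
            )
    return FunnelReport(
        stages=report_stages,
        final_genes=final_genes,
        final_variants=final_variants,
    )


def run_germline_funnel(
    table: VariantTable,
    pedigree: Pedigree,
    af_threshold: float = 0.01,
    missing_as_present: bool = False,
) -> tuple[FunnelReport, VariantTable]:
    """Apply the full funnel in the canonical order and summarise it."""
    t0 = table
    t1 = filter_pass(t0)
    t2 = filter_shared_in_affected(t1, pedigree, missing_as_present)
    t3 = filter_protein_altering(t2)
    t4 = filter_population_frequency(t3, af_threshold)
    report = summarize_funnel(
        [
            ("input", t0),
            ("pass", t1),
            ("shared_in_affected", t2),
            ("protein_altering", t3),
            ("rare_in_population", t4),
        ]
    )
    return report, t4
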