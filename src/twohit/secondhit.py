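"""Somatic second-hit intersection and predicted-impact triage.

A germline candidate gene becomes a two-hit candidate when every affected
tumor shows somatic evidence against it: a somatic copy-number deletion
overlapping the gene, or a qualifying somatic small variant (PASS,
protein-altering, rare — the same operators as the germline funnel).

Triage then eliminates candidates whose germline variant is predicted benign
by all three impact annotations simultaneously (PolyPhen benign AND SIFT
tolerated AND a low CADD score); truncating variants are never triaged out,
and missing scores never count against a candidate.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Optional

from .model import (
    AnnotatedVariant,
    CandidateGene,
    CnvSegment,
    GeneModel,
    InputError,
    TRUNCATING_CLASSES,
    VariantTable,
)
from .filtering import (
    filter_pass,
    filter_population_frequency,
    filter_protein_altering,
)

__all__ = [
    "overlap_deletions_with_genes",
    "find_somatic_small_variant_hits",
    "intersect_two_hit_candidates",
    "triage_by_predicted_impact",
]


def overlap_deletions_with_genes(
    segments: Iterable[CnvSegment],
    gene_models: Iterable[GeneModel],
) -> dict[str, set[str]]:
    """Map gene -> samples whose deletion segments intersect it by >= 1 base.

    Only deletion segments count.  Intervals are 1-based inclusive; a segment
    ending at the base before a gene starts does not overlap it.
    """
    by_chrom: dict[str, list[CnvSegment]] = defaultdict(list)
    for seg in segments:
        if seg.is_deletion:
            by_chrom[seg.chrom].append(seg)
    for segs in by_chrom.values():
        segs.sort(key=lambda s: s.start)
    out: dict[str, set[str]] = {}
    for gene in gene_models:
        hit = {
            seg.sample
            for seg in by_chrom.get(gene.chrom, ())
            if seg.start <= gene.end and gene.start <= seg.end
        }
        if hit:
            out[gene.gene] = hit
    return out


def find_somatic_small_variant_hits(
    somatic_tables: dict[str, VariantTable],
    genes: Optional[set[str]] = None,
    af_threshold: float = 0.01,
) -> dict[str, dict[str, list[str]]]:
    """Map gene -> tumor sample -> qualifying somatic variant keys.

    Qualifying means PASS, protein-altering, and rare in the population
    databases (the germline funnel's operators applied to somatic calls).
    ``genes`` optionally restricts the scan.
    """
    out: dict[str, dict[str, list[str]]] = defaultdict(dict)
    for sample, table in somatic_tables.items():
        kept = filter_population_frequency(
            filter_protein_altering(filter_pass(table)), af_threshold
        )
        for rec in kept:
            if not rec.gene:
                continue
            if genes is not None and rec.gene not in genes:
                continue
            out[rec.gene].setdefault(sample, []).append(rec.key)
    return dict(out)


def intersect_two_hit_candidates(
    germline_genes: dict[str, list[str]],
    deletion_hits: dict[str, set[str]],
    small_variant_hits: dict[str, dict[str, list[str]]],
    affected_tumors: list[str],
    require_all_tumors: bool = True,
) -> list[CandidateGene]:
    """Intersect germline candidate genes with per-tumor somatic evidence.

    A gene qualifies iff it has a germline hit and somatic evidence (deletion
    overlap OR qualifying small variant) in every affected tumor (or any
    tumor, when ``require_all_tumors`` is off).
    """
    if not affected_tumors:
        raise InputError("affected tumor list is empty")
    out = []
    for gene in sorted(germline_genes):
        dels = deletion_hits.get(gene, set())
        smalls = small_variant_hits.get(gene, {})
        evidence = [
            t for t in affected_tumors if t in dels or smalls.get(t)
        ]
        ok = (len(evidence) == len(affected_tumors)) if require_all_tumors \
            else bool(evidence)
        if ok:
            out.append(
                CandidateGene(
                    gene=gene,
                    germline_variant_keys=sorted(germline_genes[gene]),
                    deletion_samples={t for t in affected_tumors if t in dels},
                    somatic_variant_keys={
                        t: sorted(smalls[t]) for t in smalls if smalls.get(t)
                    },
                )
            )
    return out


def triage_by_predicted_impact(
    candidates: list[CandidateGene],
    germline_table: VariantTable,
    cadd_low_threshold: float = 10.0,
) -> list[CandidateGene]:
    """Mark candidates whose germline hit looks benign on all three scores.

    A candidate is ``triaged_out`` iff every one of its germline variants is
    simultaneously PolyPhen benign, SIFT tolerated and CADD below the
    threshold — and the gene has no truncating germline variant.  Missing
    scores never trigger triage.  Candidates are annotated in place and the
    same list is returned.
    """
    by_key: dict[str, AnnotatedVariant] = {r.key: r for r in germline_table}
    for cand in candidates:
        recs = [by_key[k] for k in cand.germline_variant_keys if k in by_key]
        if any(r.vclass in TRUNCATING_CLASSES for r in recs):
            cand.status = "candidate"
            continue
        benign = []
        for r in recs:
            cand.polyphen_benign = cand.polyphen_benign or r.polyphen == "benign"
            cand.sift_tolerated = cand.sift_tolerated or r.sift == "tolerated"
            cand.cadd_low = cand.cadd_low or (
                r.cadd_phred is not None and r.cadd_phred < cadd_low_threshold
            )
            benign.append(
                r.polyphen == "benign"
                and r.sift == "tolerated"
                and r.cadd_phred is not None
                and r.cadd_phred < cadd_low_threshold
            )
        cand.status = "triaged_out" if benign and all(benign) else "candidate"
    return candidates
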