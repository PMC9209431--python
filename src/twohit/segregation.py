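"""Haplotype sharing among siblings in a window around the candidate allele.

The reference sibling's candidate-bearing haplotype is reconstructed from the
phased germline calls of the phase set holding the candidate, restricted to a
window (default 0.8 Mb) around it.  Every sibling is then scored for carriage
of that haplotype: phased heterozygous sites contribute through the sibling's
own phase sets (each phase set's label orientation is chosen to maximise
matches — labels are a per-block gauge), homozygous sites contribute directly
(both of a homozygote's haplotypes carry the same allele), and missing or
unphased sites are skipped.  A sibling is flagged a carrier of the candidate
haplotype when its best-matching similarity over enough comparable sites
clears a threshold.  The verdict asks whether every affected sibling carries
the candidate haplotype; unaffected carriers are reported, never penalised
(incomplete penetrance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .model import AnnotatedVariant, InputError, Pedigree, VariantTable

__all__ = [
    "Window",
    "extract_window_haplotypes",
    "match_sibling_haplotypes",
    "cross_check_genotype",
    "SegregationResult",
]


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int
    end: int

    @classmethod
    def around(cls, variant: AnnotatedVariant, width: int = 800_000) -> "Window":
        half = width // 2
        return cls(variant.chrom, max(1, variant.pos - half), variant.pos + half)

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass
class SiblingMatch:
    sample: str
    similarity: Optional[float]
    comparable_sites: int
    carrier: Optional[bool]  # None = indeterminate (too few sites)


@dataclass
class SegregationResult:
    window: Window
    reference: str
    candidate_key: str
    informative_sites: int
    matches: dict[str, SiblingMatch]
    all_affected_share: bool
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "window": [self.window.chrom, self.window.start, self.window.end],
            "reference": self.reference,
            "candidate": self.candidate_key,
            "informative_sites": self.informative_sites,
            "siblings": {
                s: {
                    "similarity": m.similarity,
                    "comparable_sites": m.comparable_sites,
                    "carrier": m.carrier,
                }
                for s, m in self.matches.items()
            },
            "all_affected_share": self.all_affected_share,
            "warnings": list(self.warnings),
        }


def extract_window_haplotypes(
    table: VariantTable, window: Window, sample: str
) -> dict[str, tuple[Optional[int], Optional[int]]]:
    """Per-site haplotype alleles for one sample over the window.

    Returns ``{variant_key: (allele_on_hap1, allele_on_hap2)}`` restricted to
    sites where both haplotype alleles are known: phased heterozygous sites
    (local labels, gauge per phase set) and homozygous sites (both haplotypes
    carry the same allele).  Missing or unphased-het sites are omitted
    (absent marks).
    """
    out: dict[str, tuple[Optional[int], Optional[int]]] = {}
    idx = table.sample_index(sample)
    for rec in table:
        if not window.contains(rec.chrom, rec.pos):
            continue
        gt = rec.genotypes[idx]
        if gt == "hom_ref":
            out[rec.key] = (0, 0)
        elif gt == "hom_alt":
            out[rec.key] = (1, 1)
        elif gt == "het" and sample in rec.phase_set:
            local = rec.phased_allele[sample]
            out[rec.key] = (1, 0) if local == 1 else (0, 1)
    return out


def _phase_set_of(rec: AnnotatedVariant, sample: str) -> Optional[str]:
    return rec.phase_set.get(sample)


def match_sibling_haplotypes(
    table: VariantTable,
    pedigree: Pedigree,
    candidate: AnnotatedVariant,
    reference: str,
    window: Optional[Window] = None,
    min_sites: int = 20,
    min_similarity: float = 0.95,
) -> SegregationResult:
    """Score every sibling for carriage of the candidate-bearing haplotype.

    The reference haplotype is the set of alleles on the reference sample's
    candidate-carrying local haplotype, over heterozygous sites phased into
    the same phase set as the candidate and lying inside the window.
    """
    window = window or Window.around(candidate)
    ref_idx = table.sample_index(reference)
    if candidate.genotypes[ref_idx] not in ("het", "hom_alt"):
        raise InputError(
            f"reference {reference} does not carry candidate {candidate.key}"
        )
    ref_block = candidate.phase_set.get(reference)
    ref_hap_index = candidate.phased_allele.get(reference)
    if ref_block is None or ref_hap_index is None:
        raise InputError(
            f"candidate {candidate.key} is not phased in reference {reference}"
        )

    # reference haplotype: alleles on the candidate-bearing local haplotype
    ref_alleles: dict[str, int] = {}
    by_key: dict[str, AnnotatedVariant] = {}
    for rec in table:
        if not window.contains(rec.chrom, rec.pos):
            continue
        if rec.genotypes[ref_idx] != "het":
            continue
        if _phase_set_of(rec, reference) != ref_block:
            continue
        local = rec.phased_allele[reference]
        ref_alleles[rec.key] = 1 if local == ref_hap_index else 0
        by_key[rec.key] = rec

    result_matches: dict[str, SiblingMatch] = {}
    warnings: list[str] = []
    sample_ids = [
        i.id for i in pedigree if i.id in table.sample_ids and not i.is_founder
    ]
    for s in sample_ids:
        if s == reference:
            result_matches[s] = SiblingMatch(s, 1.0, len(ref_alleles), True)
            continue
        sib = extract_window_haplotypes(table, window, s)
        hom_match = hom_total = 0
        by_block: dict[str, list[tuple[int, tuple[int, int]]]] = {}
        for key, ref_allele in ref_alleles.items():
            pair = sib.get(key)
            if pair is None:
                continue
            if pair[0] == pair[1]:
                hom_total += 1
                hom_match += int(pair[0] == ref_allele)
            else:
                block = _phase_set_of(by_key[key], s)
                by_block.setdefault(block, []).append((ref_allele, pair))
        het_match = het_total = 0
        for _block, pairs in by_block.items():
            m0 = sum(int(p[0] == ref) for ref, p in pairs)
            m1 = sum(int(p[1] == ref) for ref, p in pairs)
            het_match += max(m0, m1)  # per-phase-set label orientation
            het_total += len(pairs)
        comparable = hom_total + het_total
        if comparable == 0:
            result_matches[s] = SiblingMatch(s, None, 0, None)
            warnings.append(f"{s}: no comparable sites")
            continue
        similarity = (hom_match + het_match) / comparable
        if comparable < min_sites:
            result_matches[s] = SiblingMatch(s, similarity, comparable, None)
            warnings.append(
                f"{s}: only {comparable} comparable sites (< {min_sites})"
            )
        else:
            result_matches[s] = SiblingMatch(
                s, similarity, comparable, similarity >= min_similarity
            )

    affected = [s for s in pedigree.affected_ids if s in result_matches]
    determinate = [s for s in affected if result_matches[s].carrier is not None]
    verdict = bool(determinate) and all(
        result_matches[s].carrier for s in determinate
    )
    return SegregationResult(
        window=window,
        reference=reference,
        candidate_key=candidate.key,
        informative_sites=len(ref_alleles),
        matches=result_matches,
        all_affected_share=verdict,
        warnings=warnings,
    )


def cross_check_genotype(
    result: SegregationResult,
    table: VariantTable,
    candidate: AnnotatedVariant,
) -> dict[str, str]:
    """Compare haplotype-based carrier calls with direct genotype carriage.

    Returns per-sibling flags: ``concordant``, ``discordant`` or
    ``indeterminate`` (haplotype call unavailable or genotype missing).
    """
    flags: dict[str, str] = {}
    for s, match in result.matches.items():
        gt = table.genotype(candidate, s)
        if match.carrier is None or gt == "missing":
            flags[s] = "indeterminate"
            continue
        carries = gt in ("het", "hom_alt")
        flags[s] = "concordant" if carries == match.carrier else "discordant"
    return flags
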