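"""Phase-block stitching across a somatic deletion and LOH allele assignment.

Inside a hemizygous deletion the retained haplotype keeps its linked-read
barcodes while the deleted one loses a fraction ``d`` of them, so each locally
phased block shows an allelic imbalance between its two (arbitrarily
labelled) haplotypes.  Stitching proceeds in three steps:

1. per block, an exact two-sided binomial test (success probability 1/2,
   minimum-likelihood two-sided rule) of the barcode counts;
2. region-level significance by Fisher's combination of the per-block
   p-values — a gauge-invariant statistic that involves no block selection,
   so its null calibration is nominal (conservative, since exact binomial
   p-values are discrete);
3. if the region is significant, blocks individually significant at ``alpha``
   are oriented so that their depleted local haplotype maps to global
   haplotype B; the oriented counts are pooled and one more binomial test on
   the pooled counts yields the extended haplotype's p-value.  Haplotype B is
   called deleted when that pooled p is below ``alpha``.

A candidate allele is then assigned cis/trans: its local phased-allele index,
mapped through its block's flip bit, lands on the retained (A) or deleted (B)
global haplotype — wildtype lost or mutant lost respectively.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from scipy import stats

from .model import (
    AnnotatedVariant,
    ExtendedHaplotype,
    LohCall,
    PhaseBlock,
)

__all__ = [
    "Region",
    "block_imbalance_test",
    "stitch_extended_haplotype",
    "classify_candidate_allele",
]


@dataclass(frozen=True)
class Region:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")

    def overlaps(self, block: PhaseBlock) -> bool:
        return (
            block.chrom == self.chrom
            and block.start <= self.end
            and self.start <= block.end
        )


def block_imbalance_test(hap1_count: int, hap2_count: int) -> tuple[float, str]:
    """Exact two-sided binomial test of barcode imbalance between haplotypes.

    Returns ``(p, depleted)`` where depleted is ``"hap1"``, ``"hap2"`` or
    ``"tie"``.  Zero total counts give p = 1 with a tie.
    """
    if hap1_count < 0 or hap2_count < 0:
        raise ValueError("barcode counts must be nonnegative")
    total = hap1_count + hap2_count
    if total == 0:
        return 1.0, "tie"
    p = stats.binomtest(hap1_count, total, 0.5, alternative="two-sided").pvalue
    if hap1_count == hap2_count:
        depleted = "tie"
    else:
        depleted = "hap1" if hap1_count < hap2_count else "hap2"
    return float(min(p, 1.0)), depleted


def _fisher_combination(pvalues: list[float]) -> float:
    """Fisher's combined probability over independent two-sided p-values."""
    if not pvalues:
        return 1.0
    import math

    stat = -2.0 * sum(math.log(max(p, 1e-300)) for p in pvalues)
    return float(stats.chi2.sf(stat, 2 * len(pvalues)))


def stitch_extended_haplotype(
    blocks: Iterable[PhaseBlock],
    region: Region,
    min_total_count: int = 10,
    alpha: float = 0.05,
) -> ExtendedHaplotype:
    """Stitch the blocks overlapping ``region`` into an extended haplotype.

    Blocks with fewer than ``min_total_count`` barcodes are uninformative.
    The deleted haplotype is ``B`` when the region-level combined test and
    the pooled binomial test both clear ``alpha``; otherwise
    ``indeterminate``.
    """
    in_region = [b for b in blocks if region.overlaps(b)]
    informative = [b for b in in_region if b.total >= min_total_count]
    block_p: dict[str, float] = {}
    depleted: dict[str, str] = {}
    for b in in_region:
        p, dep = block_imbalance_test(b.hap1_count, b.hap2_count)
        block_p[b.block_id] = p
        depleted[b.block_id] = dep

    combined_p = _fisher_combination([block_p[b.block_id] for b in informative])

    orientation: dict[str, int] = {}
    pooled_a = pooled_b = 0
    if combined_p < alpha:
        for b in informative:
            if block_p[b.block_id] < alpha and depleted[b.block_id] != "tie":
                # flip bit 1 means local hap1 is global B (deleted side)
                flip = 1 if depleted[b.block_id] == "hap1" else 0
                orientation[b.block_id] = flip
                if flip:
                    pooled_b += b.hap1_count
                    pooled_a += b.hap2_count
                else:
                    pooled_a += b.hap1_count
                    pooled_b += b.hap2_count

    if orientation:
        pooled_p, _ = block_imbalance_test(pooled_b, pooled_a)
    else:
        pooled_p = 1.0
    called = bool(orientation) and combined_p < alpha and pooled_p < alpha
    return ExtendedHaplotype(
        chrom=region.chrom,
        start=region.start,
        end=region.end,
        orientation=orientation,
        pooled_count_a=pooled_a,
        pooled_count_b=pooled_b,
        deleted_haplotype="B" if called else "indeterminate",
        pooled_p=float(pooled_p),
        block_p=block_p,
    )


def classify_candidate_allele(
    candidate: AnnotatedVariant,
    sample: str,
    blocks: Iterable[PhaseBlock],
    extended: ExtendedHaplotype,
) -> LohCall:
    """Assign the candidate's alt allele to the retained or deleted haplotype.

    ``sample`` is the germline individual whose phasing of the candidate is
    used; ``blocks`` are the tumor phase blocks that fed the stitcher (block
    ids shared with the germline phase sets).
    """
    key = candidate.key
    if extended.deleted_haplotype == "indeterminate":
        return LohCall(key, "indeterminate", reason="extended haplotype indeterminate")
    block_id = candidate.phase_set.get(sample)
    local = candidate.phased_allele.get(sample)
    if block_id is None or local is None:
        return LohCall(key, "indeterminate", reason="candidate unphased")
    if block_id not in extended.orientation:
        # fall back to the block containing the candidate position
        containing = [
            b.block_id for b in blocks
            if b.contains(candidate.chrom, candidate.pos)
            and b.block_id in extended.orientation
        ]
        if not containing:
            return LohCall(
                key, "indeterminate",
                reason=f"block {block_id} unoriented",
                p_value=extended.pooled_p,
            )
        block_id = containing[0]
    flip = extended.orientation[block_id]
    # local hap1 -> global A when flip == 0; global B when flip == 1
    on_deleted = (local == 1) == (flip == 1)
    fate = "mutant_lost" if on_deleted else "wildtype_lost"
    return LohCall(
        key, fate, supporting_block=block_id, p_value=extended.pooled_p
    )
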