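"""Exact imbalance test, stitching, gauge invariance, and LOH calls."""

import math

import numpy as np
import pytest
from scipy import stats

from twohit.haplotype import (
    Region,
    block_imbalance_test,
    classify_candidate_allele,
    stitch_extended_haplotype,
)
from twohit.model import AnnotatedVariant, PhaseBlock


def two_sided_binom_enumeration(k, n):
    """Independent oracle: minimum-likelihood two-sided rule by enumeration."""
    pmf = [math.comb(n, i) * 0.5**n for i in range(n + 1)]
    obs = pmf[k]
    return sum(p for p in pmf if p <= obs * (1 + 1e-12))


@pytest.mark.parametrize(
    "counts,expected_p,expected_dep",
    [
        ((5, 5), 1.0, "tie"),
        ((0, 20), 2 * 0.5**20, "hap1"),
        ((3, 7), 0.34375, "hap1"),
        ((7, 3), 0.34375, "hap2"),
        ((0, 0), 1.0, "tie"),
    ],
)
def test_imbalance_examples(counts, expected_p, expected_dep):
    p, dep = block_imbalance_test(*counts)
    assert p == pytest.approx(expected_p, rel=1e-9)
    assert dep == expected_dep


def test_imbalance_matches_enumeration_oracle():
    rng = np.random.default_rng(0)
    cases = [(k, n) for n in range(1, 41) for k in range(n + 1)]
    for n in rng.integers(41, 201, size=60):
        cases.append((int(rng.integers(0, n + 1)), int(n)))
    for k, n in cases:
        p, _ = block_imbalance_test(k, n - k)
        assert p == pytest.approx(two_sided_binom_enumeration(k, n), rel=1e-9)


def _blocks(counts, gauge=None, block_len=100_000):
    """Blocks tiling chr3 from constructed (retained, deleted) count pairs.

    gauge[j] == 1 swaps the local labels of block j.  Returns blocks plus the
    truth map block_id -> local hap index of the deleted chromosome.
    """
    gauge = gauge or [0] * len(counts)
    blocks, truth = [], {}
    pos = 1
    for j, ((ret, dele), u) in enumerate(zip(counts, gauge)):
        c1, c2 = (ret, dele) if u == 0 else (dele, ret)
        bid = f"B{j}"
        blocks.append(
            PhaseBlock(bid, "chr3", pos, pos + block_len - 1, "T", c1, c2)
        )
        truth[bid] = 2 if u == 0 else 1
        pos += block_len
    return blocks, truth, Region("chr3", 1, pos - 1)


def test_stitch_constructed_fixture_pools_counts():
    """Ten blocks of (2, 40) orient consistently; the pooled p equals the
    single binomial test on the pooled counts."""
    gauge = [0, 1] * 5
    blocks, truth, region = _blocks([(40, 2)] * 10, gauge)
    ext = stitch_extended_haplotype(blocks, region)
    assert ext.deleted_haplotype == "B"
    assert len(ext.orientation) == 10
    assert (ext.pooled_count_a, ext.pooled_count_b) == (400, 20)
    assert ext.pooled_p == pytest.approx(block_imbalance_test(20, 400)[0])
    for bid, flip in ext.orientation.items():
        maps_deleted_to_b = (truth[bid] == 1) == (flip == 1)
        assert maps_deleted_to_b


def test_gauge_invariance_single_block_flip():
    base_gauge = [0] * 6
    blocks, _, region = _blocks([(50, 10)] * 6, base_gauge)
    base = stitch_extended_haplotype(blocks, region)
    for j in range(6):
        gauge = list(base_gauge)
        gauge[j] = 1
        flipped, _, _ = _blocks([(50, 10)] * 6, gauge)
        ext = stitch_extended_haplotype(flipped, region)
        assert ext.deleted_haplotype == base.deleted_haplotype
        assert (ext.pooled_count_a, ext.pooled_count_b) == (
            base.pooled_count_a, base.pooled_count_b
        )
        assert ext.pooled_p == base.pooled_p
        assert ext.block_p == base.block_p
        # the flipped block's orientation bit flips; others are unchanged
        for bid in ext.orientation:
            expected = base.orientation[bid] ^ (bid == f"B{j}")
            assert ext.orientation[bid] == expected


def test_low_count_blocks_left_unoriented():
    blocks, _, region = _blocks([(40, 2)] * 4 + [(4, 0)], [0] * 5)
    ext = stitch_extended_haplotype(blocks, region, min_total_count=10)
    assert "B4" not in ext.orientation
    assert ext.deleted_haplotype == "B"


def test_no_blocks_is_indeterminate():
    ext = stitch_extended_haplotype([], Region("chr3", 1, 100))
    assert ext.deleted_haplotype == "indeterminate"
    assert ext.orientation == {}


def test_null_calibration_indeterminate():
    """With balanced counts (no deletion) the stitcher stays indeterminate in
    at least 95% of seeded simulations at alpha = 0.05."""
    indeterminate = 0
    for seed in range(200):
        rng = np.random.default_rng([seed, 12])
        counts = [
            (int(rng.poisson(50)), int(rng.poisson(50))) for _ in range(5)
        ]
        gauge = [int(g) for g in rng.integers(0, 2, 5)]
        blocks, _, region = _blocks(counts, gauge, block_len=500_000)
        ext = stitch_extended_haplotype(blocks, region)
        indeterminate += ext.deleted_haplotype == "indeterminate"
    assert indeterminate >= 190


def test_power_correct_deleted_call():
    """With 60% depletion and pooled expected counts of 250 per haplotype the
    deleted haplotype is recovered in at least 99% of seeded simulations."""
    correct = 0
    for seed in range(200):
        rng = np.random.default_rng([seed, 11])
        counts = [
            (int(rng.poisson(50)), int(rng.poisson(50 * 0.4)))
            for _ in range(5)
        ]
        gauge = [int(g) for g in rng.integers(0, 2, 5)]
        blocks, truth, region = _blocks(counts, gauge, block_len=500_000)
        ext = stitch_extended_haplotype(blocks, region)
        ok = ext.deleted_haplotype == "B"
        if ok:
            for bid, flip in ext.orientation.items():
                if (truth[bid] == 1) != (flip == 1):
                    ok = False
        correct += ok
    assert correct >= 198


def _candidate(pos, sample, block_id, local):
    return AnnotatedVariant(
        chrom="chr3", pos=pos, ref="C", alt="T",
        genotypes=("het",),
        phase_set={sample: block_id}, phased_allele={sample: local},
    )


def test_classify_candidate_cis_trans():
    gauge = [0, 1, 0]
    blocks, truth, region = _blocks([(60, 5)] * 3, gauge)
    ext = stitch_extended_haplotype(blocks, region)
    assert ext.deleted_haplotype == "B"
    # block B1 is label-swapped: its local hap 1 is the deleted chromosome
    on_deleted = _candidate(150_000, "S", "B1", truth["B1"])
    on_retained = _candidate(150_000, "S", "B1", 3 - truth["B1"])
    assert classify_candidate_allele(on_deleted, "S", blocks, ext).fate == \
        "mutant_lost"
    assert classify_candidate_allele(on_retained, "S", blocks, ext).fate == \
        "wildtype_lost"


def test_classify_unphased_or_unoriented_is_indeterminate():
    blocks, _, region = _blocks([(60, 5), (60, 5), (0, 0)], [0, 0, 0])
    ext = stitch_extended_haplotype(blocks, region)
    assert ext.deleted_haplotype == "B"
    unphased = AnnotatedVariant(
        chrom="chr3", pos=150_000, ref="C", alt="T", genotypes=("het",)
    )
    call = classify_candidate_allele(unphased, "S", blocks, ext)
    assert call.fate == "indeterminate" and "unphased" in call.reason
    # candidate in the zero-count (unorientable) block
    zero_block = _candidate(250_000, "S", "B2", 1)
    call = classify_candidate_allele(zero_block, "S", blocks, ext)
    assert call.fate == "indeterminate"


def test_indeterminate_extended_blocks_classification():
    blocks, _, region = _blocks([(20, 19), (21, 20)], [0, 0])
    ext = stitch_extended_haplotype(blocks, region)
    assert ext.deleted_haplotype == "indeterminate"
    call = classify_candidate_allele(
        _candidate(50_000, "S", "B0", 1), "S", blocks, ext
    )
    assert call.fate == "indeterminate"


def test_pooled_depleted_agrees_with_block_majority():
    rng = np.random.default_rng(5)
    for _ in range(20):
        counts = [
            (int(rng.poisson(40)), int(rng.poisson(15))) for _ in range(6)
        ]
        gauge = [int(g) for g in rng.integers(0, 2, 6)]
        blocks, truth, region = _blocks(counts, gauge)
        ext = stitch_extended_haplotype(blocks, region)
        if ext.deleted_haplotype != "B":
            continue
        # every oriented block maps its observed minority to B, so the pooled
        # call agrees with all (hence the majority) of per-block calls
        for b in blocks:
            if b.block_id in ext.orientation:
                flip = ext.orientation[b.block_id]
                minority_local = 1 if b.hap1_count < b.hap2_count else 2
                assert (minority_local == 1) == (flip == 1)
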