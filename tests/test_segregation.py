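"""Sibling haplotype sharing around the candidate allele."""

import pytest

from twohit.model import AnnotatedVariant, InputError, VariantTable
from twohit.segregation import (
    Window,
    cross_check_genotype,
    extract_window_haplotypes,
    match_sibling_haplotypes,
)
from twohit.simulate import CohortConfig, simulate_cohort, simulate_phase_blocks


def phased_table(site_specs, samples):
    """site_specs: list of (pos, {sample: (gt, block, local_alt_hap)})."""
    records = []
    for pos, calls in site_specs:
        gts, ps, pa = [], {}, {}
        for s in samples:
            gt, block, local = calls.get(s, ("hom_ref", None, None))
            gts.append(gt)
            if block is not None:
                ps[s] = block
                pa[s] = local
        records.append(
            AnnotatedVariant(
                chrom="chr1", pos=pos, ref="A", alt="T",
                genotypes=tuple(gts), phase_set=ps, phased_allele=pa,
            )
        )
    return VariantTable(records=records, sample_ids=list(samples))


def two_sib_pedigree(affected=("R", "S")):
    from twohit.model import Individual, Pedigree

    inds = [Individual("F", "0", "0", 1, "unknown"),
            Individual("M", "0", "0", 2, "unknown")]
    for s in ("R", "S"):
        inds.append(
            Individual(s, "F", "M", 1,
                       "affected" if s in affected else "unaffected")
        )
    return Pedigree(inds)


def make_shared_table(n_sites=25, flip_s_labels=False, mismatches=0):
    """R and S share R's hap-1 haplotype at every site (minus mismatches)."""
    specs = []
    for i in range(n_sites):
        pos = 1000 + i * 100
        allele_on_shared = i % 2  # alternating alt/ref on the shared haplotype
        s_allele = allele_on_shared if i >= mismatches else 1 - allele_on_shared
        r_local = 1 if allele_on_shared else 2
        s_local = (1 if s_allele else 2) if not flip_s_labels else \
            (2 if s_allele else 1)
        specs.append(
            (pos, {
                "R": ("het", "R_B0001", r_local),
                "S": ("het", "S_B0001", s_local),
            })
        )
    return phased_table(specs, ["R", "S"])


def test_identical_sibling_similarity_one():
    table = make_shared_table()
    candidate = table.records[1]  # alt on R's hap 1
    res = match_sibling_haplotypes(
        table, two_sib_pedigree(), candidate, "R", min_sites=10
    )
    assert res.matches["S"].similarity == 1.0
    assert res.matches["S"].carrier is True
    assert res.all_affected_share is True


def test_similarity_gauge_invariant_under_label_swap():
    plain = make_shared_table(flip_s_labels=False)
    swapped = make_shared_table(flip_s_labels=True)
    ped = two_sib_pedigree()
    for table in (plain, swapped):
        res = match_sibling_haplotypes(
            table, ped, table.records[1], "R", min_sites=10
        )
        assert res.matches["S"].similarity == 1.0


def test_mismatching_sibling_not_carrier():
    table = make_shared_table(mismatches=8)
    res = match_sibling_haplotypes(
        table, two_sib_pedigree(), table.records[9], "R", min_sites=10
    )
    assert res.matches["S"].similarity < 0.95
    assert res.matches["S"].carrier is False
    assert res.all_affected_share is False


def test_too_few_sites_is_indeterminate_with_warning():
    table = make_shared_table(n_sites=5)
    res = match_sibling_haplotypes(
        table, two_sib_pedigree(), table.records[1], "R", min_sites=20
    )
    assert res.matches["S"].carrier is None
    assert any("S" in w for w in res.warnings)
    # the indeterminate affected sibling is excluded from the verdict
    assert res.all_affected_share is True


def test_reference_must_carry_and_be_phased():
    table = make_shared_table()
    ped = two_sib_pedigree()
    non_carrier = AnnotatedVariant(
        chrom="chr1", pos=999_999, ref="A", alt="T",
        genotypes=("hom_ref", "het"),
        phase_set={"S": "S_B0001"}, phased_allele={"S": 1},
    )
    table2 = VariantTable(
        records=table.records + [non_carrier], sample_ids=table.sample_ids
    )
    with pytest.raises(InputError):
        match_sibling_haplotypes(table2, ped, non_carrier, "R")


def test_extract_window_haplotypes_marks():
    table = phased_table(
        [
            (100, {"R": ("het", "R_B1", 1)}),
            (200, {"R": ("het", None, None)}),   # unphased het: absent
            (300, {"R": ("hom_alt", None, None)}),
            (400, {"R": ("missing", None, None)}),
        ],
        ["R"],
    )
    haps = extract_window_haplotypes(table, Window("chr1", 1, 1000), "R")
    assert haps == {
        "chr1:100:A:T": (1, 0),
        "chr1:300:A:T": (1, 1),
    }
    assert extract_window_haplotypes(
        table, Window("chr1", 5000, 6000), "R"
    ) == {}


def test_cohort_carrier_calls_match_genotypes_without_recombination():
    """With recombination off, haplotype-based carrier calls equal direct
    genotype carriage at the candidate for every sibling."""
    for seed in (2, 3):
        cfg = CohortConfig(seed=seed, recombination_rate=0.0)
        cohort = simulate_cohort(cfg)
        simulate_phase_blocks(cohort)
        causal = next(
            r for r in cohort.germline if r.key == cohort.truth.causal_variant
        )
        reference = next(
            s for s in cohort.affected_ids if s in causal.phase_set
        )
        res = match_sibling_haplotypes(
            cohort.germline, cohort.pedigree, causal, reference
        )
        flags = cross_check_genotype(res, cohort.germline, causal)
        assert "discordant" not in flags.values()
        # carriers among determinate calls are exactly the truth carriers
        for s, m in res.matches.items():
            if m.carrier is not None:
                assert m.carrier == (s in cohort.truth.carrier_ids)


def test_all_affected_share_in_default_cohort(default_cohort, default_blocks):
    cohort = default_cohort
    causal = next(
        r for r in cohort.germline if r.key == cohort.truth.causal_variant
    )
    reference = next(s for s in cohort.affected_ids if s in causal.phase_set)
    res = match_sibling_haplotypes(
        cohort.germline, cohort.pedigree, causal, reference
    )
    assert res.all_affected_share is True
    determinate_affected = [
        s for s in cohort.affected_ids if res.matches[s].carrier is not None
    ]
    assert determinate_affected  # the verdict rests on real evidence
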