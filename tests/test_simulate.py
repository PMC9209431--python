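"""Generator tests: planted truth, Mendelian transmission, phase blocks."""

import json

import numpy as np
import pytest
from scipy import stats

from twohit.haplotype import block_imbalance_test
from twohit.model import ConfigError
from twohit.pipeline import write_cohort_inputs
from twohit.simulate import (
    CohortConfig,
    TruthRecord,
    emit_truth,
    load_truth,
    plant_decoys,
    simulate_cohort,
    simulate_phase_blocks,
    tumor_of,
)


def small_config(seed, **kw):
    kw.setdefault("n_background_variants", 0)
    kw.setdefault("n_somatic_background", 0)
    return CohortConfig(seed=seed, **kw)


def test_default_truth_structure(default_cohort):
    truth = default_cohort.truth
    assert len(default_cohort.sibling_ids) == 8
    assert len(truth.affected_ids) == 4
    assert len(truth.carrier_ids) == 6
    assert set(truth.affected_ids) <= set(truth.carrier_ids)
    kinds = sorted(d["kind"] for d in truth.decoy_genes)
    assert kinds == ["germline_only"] * 3 + ["mutant_deleted"] + ["somatic_only"] * 3


def test_causal_variant_het_in_exactly_carriers(default_cohort):
    c = default_cohort
    rec = next(r for r in c.germline if r.key == c.truth.causal_variant)
    assert rec.vclass == c.config.causal_class
    assert rec.af_gnomad == c.config.causal_pop_af
    carriers = {
        s for s, g in zip(c.sibling_ids, rec.genotypes) if g == "het"
    }
    assert carriers == set(c.truth.carrier_ids)
    assert all(
        g == "hom_ref"
        for s, g in zip(c.sibling_ids, rec.genotypes)
        if s not in carriers
    )


def test_every_affected_tumor_deletes_causal_gene(default_cohort):
    c = default_cohort
    gene = next(g for g in c.gene_models if g.gene == c.truth.causal_gene)
    for s in c.affected_ids:
        t = tumor_of(s)
        dels = [
            seg for seg in c.segments
            if seg.sample == t and seg.is_deletion
            and seg.overlaps(gene.chrom, gene.start, gene.end)
        ]
        assert dels, f"tumor {t} lacks a deletion over the causal gene"
        assert t in c.truth.deleted_haplotype
        assert c.truth.deleted_haplotype[t]["chromosome"] == "maternal"


def test_no_background_gives_only_planted_variants():
    c = simulate_cohort(small_config(5))
    # causal + mutant-deleted decoy + 3 germline-only decoys
    assert len(c.germline) == 5
    genes = {r.gene for r in c.germline}
    planted = {c.truth.causal_gene} | {
        d["gene"] for d in c.truth.decoy_genes
        if d["kind"] in ("germline_only", "mutant_deleted")
    }
    assert genes == planted


def test_mendelian_consistency(default_cohort):
    """Genotypes equal the transmission mosaics applied to parental carriage."""
    c = default_cohort
    for rec in c.germline.records[::7]:
        carrier = c.origin[rec.key]
        for i, s in enumerate(c.sibling_ids):
            pat, mat = c.transmissions[s]
            n_alt = int(carrier[pat.hap_at(rec.pos)]) + int(
                carrier[mat.hap_at(rec.pos)]
            )
            assert rec.genotypes[i] == ("hom_ref", "het", "hom_alt")[n_alt]
    # paternal mosaics use only paternal haplotypes, with few crossovers
    for s in c.sibling_ids:
        pat, mat = c.transmissions[s]
        assert set(pat.haps) <= {0, 1} and set(mat.haps) <= {2, 3}
        assert len(pat.breakpoints) == len(pat.haps) - 1


def test_seeded_determinism_byte_identical(tmp_path):
    outs = []
    for sub in ("a", "b"):
        c = simulate_cohort(CohortConfig(seed=9, n_background_variants=300))
        gb, tb = simulate_phase_blocks(c)
        paths = write_cohort_inputs(c, gb, tb, tmp_path / sub)
        outs.append(paths)
    for key in ("germline_vcf", "ped", "genes_bed", "cnv_bed",
                "barcodes_tsv", "truth_json"):
        assert outs[0][key].read_bytes() == outs[1][key].read_bytes()


def test_blocks_tile_region(default_cohort, default_blocks):
    germline_blocks, tumor_blocks = default_blocks
    length = default_cohort.config.region_length
    for blocks in list(germline_blocks.values()) + list(tumor_blocks.values()):
        spans = sorted((b.start, b.end) for b in blocks)
        assert spans[0][0] == 1 and spans[-1][1] == length
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert s2 == e1 + 1  # contiguous and disjoint


def test_complete_depletion_zeroes_deleted_haplotype():
    cfg = small_config(3, deletion_fraction_depletion=1.0)
    c = simulate_cohort(cfg)
    _, tumor_blocks = simulate_phase_blocks(c)
    gene = next(g for g in c.gene_models if g.gene == c.truth.causal_gene)
    checked = 0
    for t, blocks in tumor_blocks.items():
        dels = [
            (s, e) for (s, e, chrom) in c.tumor_deletions[t]
            if chrom == "maternal"
        ]
        for b in blocks:
            if any(s <= b.start and b.end <= e for s, e in dels):
                assert min(b.hap1_count, b.hap2_count) == 0
                checked += 1
    assert checked > 10


def test_null_depletion_counts_balanced_uniform_p():
    """Under d=0 the pooled in-deletion counts show only sampling noise:
    the exact binomial p is uniform across seeds (KS check)."""
    ps = []
    for seed in range(200):
        cfg = small_config(seed, deletion_fraction_depletion=0.0)
        c = simulate_cohort(cfg)
        _, tumor_blocks = simulate_phase_blocks(c)
        t = tumor_of(c.affected_ids[0])
        ds, de, _ = c.tumor_deletions[t][0]
        inside = [
            b for b in tumor_blocks[t] if ds <= b.start and b.end <= de
        ]
        a = sum(b.hap1_count for b in inside)
        b_ = sum(b.hap2_count for b in inside)
        ps.append(block_imbalance_test(a, b_)[0])
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_plant_decoys_on_decoyless_cohort():
    base_cfg = small_config(21, n_decoy_germline_only=0,
                            n_decoy_somatic_only=0,
                            include_mutant_deleted_decoy=False)
    base = simulate_cohort(base_cfg)
    assert base.truth.decoy_genes == []
    assert len(base.germline) == 1  # just the causal variant

    full_cfg = small_config(21)
    planted = plant_decoys(base, full_cfg)
    kinds = sorted(d["kind"] for d in planted.truth.decoy_genes)
    assert kinds == ["germline_only"] * 3 + ["mutant_deleted"] + ["somatic_only"] * 3
    assert len(planted.germline) == 5
    assert base.truth.decoy_genes == []  # original untouched
    mut = [d for d in planted.truth.decoy_genes if d["kind"] == "mutant_deleted"]
    assert len(mut) == 1


def test_truth_round_trip_and_invariants(tmp_path):
    for seed in range(10):
        c = simulate_cohort(small_config(seed))
        path = tmp_path / f"truth{seed}.json"
        emit_truth(c.truth, path)
        back = load_truth(path)
        assert back == c.truth
        assert set(back.affected_ids) <= set(back.carrier_ids)
        for s in back.affected_ids:
            assert tumor_of(s) in back.deleted_haplotype


def test_truth_record_rejects_inconsistency():
    with pytest.raises(ValueError):
        TruthRecord(
            causal_gene="G1", causal_variant="chr1:1:A:T",
            carrier_ids=["a"], affected_ids=["a", "b"],
            deleted_haplotype={}, decoy_genes=[],
        )


@pytest.mark.parametrize(
    "kw",
    [
        {"n_affected": 6, "n_unaffected_carriers": 4},  # exceeds siblings
        {"deletion_fraction_depletion": 1.5},
        {"region_length": 0},
        {"causal_class": "synonymous"},
        {"class_weights": {"missense": 0.5}},
    ],
)
def test_invalid_configs_rejected(kw):
    with pytest.raises(ConfigError):
        simulate_cohort(CohortConfig(seed=0, **kw))


def test_truth_json_is_schema_complete(tmp_path):
    c = simulate_cohort(small_config(2))
    path = tmp_path / "t.json"
    emit_truth(c.truth, path)
    doc = json.loads(path.read_text())
    assert set(doc) == {
        "causal_gene", "causal_variant", "carrier_ids", "affected_ids",
        "deleted_haplotype", "decoy_genes",
    }
    for t, entry in doc["deleted_haplotype"].items():
        assert set(entry) == {"chromosome", "parental_hap"}
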