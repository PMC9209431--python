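"""End-to-end pipeline driver: funnel → second hit → LOH → segregation.

``analyze_cohort`` runs the analysis on in-memory objects; ``run_pipeline``
drives it from a YAML configuration that either references input files or
contains a ``simulate`` block.  The report is a plain JSON-serialisable dict
(``report_version: 1``) and is deterministic given inputs and seed.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict, fields
from pathlib import Path
from typing import Optional

import yaml

from .model import (
    AnnotatedVariant,
    CnvSegment,
    ConfigError,
    GeneModel,
    InputError,
    Pedigree,
    PhaseBlock,
    TRUNCATING_CLASSES,
    VariantTable,
)
from . import io as tio
from .filtering import run_germline_funnel
from .secondhit import (
    find_somatic_small_variant_hits,
    intersect_two_hit_candidates,
    overlap_deletions_with_genes,
    triage_by_predicted_impact,
)
from .haplotype import Region, classify_candidate_allele, stitch_extended_haplotype
from .segregation import Window, cross_check_genotype, match_sibling_haplotypes
from .stats import TwoByTwoTable, multi_phenotype_screen
from .simulate import CohortConfig, simulate_cohort, simulate_phase_blocks

__all__ = ["PipelineParams", "analyze_cohort", "run_pipeline", "write_cohort_inputs"]

REPORT_VERSION = 1


@dataclass
class PipelineParams:
    af_threshold: float = 0.01
    cadd_low_threshold: float = 10.0
    min_total_count: int = 10
    alpha: float = 0.05
    window_kb: int = 800
    min_sites: int = 20
    min_similarity: float = 0.95
    require_all_tumors: bool = True
    missing_as_present: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineParams":
        names = {f.name for f in fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ConfigError(f"unknown pipeline parameters: {sorted(unknown)}")
        return cls(**d)


def _pick_candidate_variant(
    keys: list[str], table: VariantTable
) -> Optional[AnnotatedVariant]:
    """Prefer a truncating variant; otherwise the first germline hit."""
    recs = [r for r in table if r.key in set(keys)]
    for r in recs:
        if r.vclass in TRUNCATING_CLASSES:
            return r
    return recs[0] if recs else None


def _loh_for_candidate(
    rec: AnnotatedVariant,
    gene: GeneModel,
    segments: list[CnvSegment],
    tumor_blocks: dict[str, list[PhaseBlock]],
    tumor_individual: dict[str, str],
    affected_tumors: list[str],
    params: PipelineParams,
) -> dict[str, dict]:
    calls = {}
    for tumor in affected_tumors:
        dels = [
            s for s in segments
            if s.sample == tumor and s.is_deletion
            and s.overlaps(gene.chrom, gene.start, gene.end)
        ]
        if not dels:
            calls[tumor] = {"fate": "indeterminate", "reason": "no overlapping deletion"}
            continue
        region = Region(
            gene.chrom, min(s.start for s in dels), max(s.end for s in dels)
        )
        blocks = tumor_blocks.get(tumor, [])
        extended = stitch_extended_haplotype(
            blocks, region, params.min_total_count, params.alpha
        )
        call = classify_candidate_allele(
            rec, tumor_individual.get(tumor, tumor), blocks, extended
        )
        calls[tumor] = {
            "fate": call.fate,
            "p_value": call.p_value,
            "supporting_block": call.supporting_block,
            "reason": call.reason,
            "deleted_haplotype": extended.deleted_haplotype,
            "pooled_counts": [extended.pooled_count_a, extended.pooled_count_b],
        }
    return calls


def analyze_cohort(
    germline: VariantTable,
    pedigree: Pedigree,
    somatic_tables: dict[str, VariantTable],
    segments: list[CnvSegment],
    gene_models: list[GeneModel],
    tumor_blocks: dict[str, list[PhaseBlock]],
    tumor_individual: Optional[dict[str, str]] = None,
    params: Optional[PipelineParams] = None,
) -> dict:
    """Run funnel, intersection, triage, LOH and segregation; return a report."""
    params = params or PipelineParams()
    if not pedigree.affected_ids:
        raise InputError("pipeline requires at least one affected individual")
    report: dict = {"report_version": REPORT_VERSION, "params": asdict(params)}

    funnel, final_table = run_germline_funnel(
        germline, pedigree, params.af_threshold, params.missing_as_present
    )
    report["funnel"] = funnel.to_dict()

    if not somatic_tables:
        report["status"] = "germline_only"
        report["candidates"] = []
        report["wildtype_lost_genes"] = []
        return report
    report["status"] = "complete"

    affected_tumors = sorted(somatic_tables)
    if tumor_individual is None:
        tumor_individual = {
            t: (t[:-2] if t.endswith("_T") else t) for t in affected_tumors
        }
    germline_genes = {
        g: keys for g, keys in funnel.final_genes.items() if g != "intergenic"
    }
    deletion_hits = overlap_deletions_with_genes(segments, gene_models)
    small_hits = find_somatic_small_variant_hits(
        somatic_tables, af_threshold=params.af_threshold
    )
    candidates = intersect_two_hit_candidates(
        germline_genes, deletion_hits, small_hits,
        affected_tumors, params.require_all_tumors,
    )
    triage_by_predicted_impact(candidates, germline, params.cadd_low_threshold)

    gene_by_name = {g.gene: g for g in gene_models}
    wildtype_lost_genes = []
    cand_rows = []
    for cand in candidates:
        row = {
            "gene": cand.gene,
            "germline_variants": cand.germline_variant_keys,
            "deletion_tumors": sorted(cand.deletion_samples),
            "somatic_variant_tumors": sorted(cand.somatic_variant_keys),
            "status": cand.status,
            "triage": {
                "polyphen_benign": cand.polyphen_benign,
                "sift_tolerated": cand.sift_tolerated,
                "cadd_low": cand.cadd_low,
            },
        }
        rec = _pick_candidate_variant(cand.germline_variant_keys, final_table)
        if cand.status == "candidate" and rec is not None \
                and cand.gene in gene_by_name:
            loh = _loh_for_candidate(
                rec, gene_by_name[cand.gene], segments, tumor_blocks,
                tumor_individual, affected_tumors, params,
            )
            row["loh"] = loh
            fates = [c["fate"] for c in loh.values()]
            determinate = [f for f in fates if f != "indeterminate"]
            if determinate and all(f == "wildtype_lost" for f in determinate):
                wildtype_lost_genes.append(cand.gene)
            row["candidate_variant"] = rec.key
        cand_rows.append(row)
    report["candidates"] = cand_rows
    report["wildtype_lost_genes"] = sorted(wildtype_lost_genes)

    # segregation for every gene whose determinate LOH calls are all
    # wildtype-lost (the putative causal genes)
    segregation = {}
    for gene in report["wildtype_lost_genes"]:
        keys = germline_genes[gene]
        rec = _pick_candidate_variant(keys, final_table)
        if rec is None:
            continue
        reference = next(
            (
                s for s in pedigree.affected_ids
                if s in germline.sample_ids
                and germline.genotype(rec, s) in ("het", "hom_alt")
                and s in rec.phase_set
            ),
            None,
        )
        if reference is None:
            segregation[gene] = {"status": "no phased affected carrier"}
            continue
        window = Window.around(rec, params.window_kb * 1000)
        result = match_sibling_haplotypes(
            germline, pedigree, rec, reference, window,
            params.min_sites, params.min_similarity,
        )
        seg = result.to_dict()
        seg["genotype_cross_check"] = cross_check_genotype(result, germline, rec)
        segregation[gene] = seg
    report["segregation"] = segregation
    return report


# ---------------------------------------------------------------------------
# file-level driver


def write_cohort_inputs(cohort, germline_blocks, tumor_blocks, out_dir) -> dict:
    """Write a simulated cohort to disk in the pipeline's input formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    contigs = {cohort.chrom: cohort.config.region_length + 1000}
    paths = {
        "germline_vcf": out / "germline.vcf",
        "ped": out / "family.ped",
        "genes_bed": out / "genes.bed",
        "cnv_bed": out / "segments.bed",
        "barcodes_tsv": out / "tumor_barcodes.tsv",
        "germline_barcodes_tsv": out / "germline_barcodes.tsv",
        "truth_json": out / "truth.json",
    }
    tio.write_variant_table(cohort.germline, paths["germline_vcf"], contigs)
    tio.write_pedigree(cohort.pedigree, paths["ped"])
    tio.write_gene_models(cohort.gene_models, paths["genes_bed"])
    tio.write_segments(cohort.segments, paths["cnv_bed"])
    all_tumor = [b for blocks in tumor_blocks.values() for b in blocks]
    all_germ = [b for blocks in germline_blocks.values() for b in blocks]
    tio.write_barcode_counts(all_tumor, paths["barcodes_tsv"])
    tio.write_barcode_counts(all_germ, paths["germline_barcodes_tsv"])
    somatic_paths = {}
    for tumor, table in cohort.somatic.items():
        p = out / f"somatic_{tumor}.vcf"
        tio.write_variant_table(table, p, contigs)
        somatic_paths[tumor] = p
    paths["somatic_vcfs"] = somatic_paths
    from .simulate import emit_truth

    emit_truth(cohort.truth, paths["truth_json"])
    return paths


def _require(path, what: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise InputError(f"missing input {what}: {p}")
    return p


def _load_association_counts(path) -> dict[str, TwoByTwoTable]:
    tables = {}
    with open(_require(path, "association counts")) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        needed = {"phenotype", "a", "b", "c", "d"}
        if reader.fieldnames is None or not needed <= set(reader.fieldnames):
            raise InputError(f"{path}: counts TSV needs columns {sorted(needed)}")
        for row in reader:
            tables[row["phenotype"]] = TwoByTwoTable(
                int(row["a"]), int(row["b"]), int(row["c"]), int(row["d"])
            )
    return tables


def run_pipeline(config_path, seed: Optional[int] = None) -> dict:
    """Run the full pipeline from a YAML config; return the report dict.

    The config holds either a ``simulate`` block (cohort-generator settings)
    or an ``inputs`` block with file paths; plus optional ``params`` and
    ``association_counts``.  ``seed`` overrides the simulate block's seed.
    """
    cfg_path = _require(config_path, "config")
    with open(cfg_path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"{config_path}: config must be a mapping")
    if ("simulate" in cfg) == ("inputs" in cfg):
        raise ConfigError("config needs exactly one of 'simulate' or 'inputs'")
    params = PipelineParams.from_dict(cfg.get("params") or {})

    if "simulate" in cfg:
        sim = dict(cfg["simulate"] or {})
        if seed is not None:
            sim["seed"] = int(seed)
        try:
            cc = CohortConfig(**sim)
        except TypeError as exc:
            raise ConfigError(f"bad simulate block: {exc}") from exc
        cohort = simulate_cohort(cc)
        _, tumor_blocks = simulate_phase_blocks(cohort)
        report = analyze_cohort(
            cohort.germline, cohort.pedigree, cohort.somatic, cohort.segments,
            cohort.gene_models, tumor_blocks, params=params,
        )
        report["truth"] = cohort.truth.to_dict()
    else:
        inputs = cfg["inputs"] or {}
        germline = tio.load_variant_table(
            _require(inputs.get("germline_vcf", ""), "germline VCF"), "germline"
        )
        pedigree = tio.load_pedigree(_require(inputs.get("ped", ""), "pedigree"))
        genes = tio.load_gene_models(
            _require(inputs.get("genes_bed", ""), "gene models")
        )
        somatic = {}
        for tumor, path in (inputs.get("somatic_vcfs") or {}).items():
            somatic[tumor] = tio.load_variant_table(
                _require(path, f"somatic VCF {tumor}"), "somatic"
            )
        segments = (
            tio.load_segments(_require(inputs["cnv_bed"], "CNV segments"))
            if inputs.get("cnv_bed") else []
        )
        tumor_blocks: dict[str, list[PhaseBlock]] = {}
        if inputs.get("barcodes_tsv"):
            for b in tio.load_barcode_counts(
                _require(inputs["barcodes_tsv"], "barcode counts")
            ):
                tumor_blocks.setdefault(b.sample, []).append(b)
        report = analyze_cohort(
            germline, pedigree, somatic, segments, genes, tumor_blocks,
            tumor_individual=cfg.get("tumor_individuals"), params=params,
        )

    if cfg.get("association_counts"):
        tables = _load_association_counts(cfg["association_counts"])
        report["association"] = multi_phenotype_screen(tables, params.alpha)
    return report


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
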