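"""Readers and writers for the on-disk formats.

VCF v4.2 (via pysam) carries variant annotations in INFO
(GENE, VCLASS, AF_ESP, AF_EXAC, AF_GNOMAD, CADD_PHRED, POLYPHEN, SIFT, all
Number=A) and local phasing in FORMAT GT (phased ``|`` calls) + PS.  BED is
0-based half-open on disk and converted to the package's 1-based inclusive
coordinates at this boundary.  PED is 6-column; phenotype 2 = affected,
1 = unaffected, 0/-9 = unknown.  Barcode counts travel as a headered TSV.

Phase-set ids: VCF PS is an integer; the block id string used everywhere else
is reconstructed as ``{sample}_B{PS:04d}`` (and emitted that way), so phase
sets in a germline VCF line up with block ids in the matching barcode TSV.
"""

from __future__ import annotations

import logging
import re
from typing import Iterable, Optional

import pysam

from .model import (
    AnnotatedVariant,
    CnvSegment,
    GeneModel,
    Individual,
    InputError,
    Pedigree,
    PhaseBlock,
    VariantTable,
)

logger = logging.getLogger("twohit")

__all__ = [
    "load_variant_table",
    "write_variant_table",
    "load_segments",
    "write_segments",
    "load_gene_models",
    "write_gene_models",
    "load_pedigree",
    "write_pedigree",
    "load_barcode_counts",
    "write_barcode_counts",
]

_INFO_FIELDS = {
    "GENE": ("String", "Gene symbol"),
    "VCLASS": ("String", "Consequence class"),
    "AF_ESP": ("Float", "ESP population allele frequency"),
    "AF_EXAC": ("Float", "ExAC population allele frequency"),
    "AF_GNOMAD": ("Float", "gnomAD population allele frequency"),
    "CADD_PHRED": ("Float", "CADD Phred-scaled score"),
    "POLYPHEN": ("String", "PolyPhen prediction"),
    "SIFT": ("String", "SIFT prediction"),
}

_GT_MAP = {0: "hom_ref", 1: "het", 2: "hom_alt"}
_PS_RE = re.compile(r"^(?P<sample>.+)_B(?P<num>\d+)$")


def _block_id(sample: str, ps: int) -> str:
    return f"{sample}_B{ps:04d}"


def _ps_int(block_id: str) -> Optional[int]:
    m = _PS_RE.match(block_id)
    return int(m.group("num")) if m else None


def _info_allele(value, index: int):
    """Pick the per-allele entry of an INFO value (Number=A or scalar)."""
    if isinstance(value, tuple):
        if index < len(value):
            value = value[index]
        else:
            value = value[0] if value else None
    if isinstance(value, str) and value in (".", ""):
        return None
    return value


def load_variant_table(path, dialect: str = "germline") -> VariantTable:
    """Load a VCF into a :class:`VariantTable`, splitting multi-allelic sites.

    ``dialect`` is ``germline`` or ``somatic``; both use the same schema (the
    distinction only labels log messages).  Unknown INFO keys are ignored with
    a warning; missing annotation keys become missing values.
    """
    if dialect not in ("germline", "somatic"):
        raise InputError(f"unknown VCF dialect {dialect!r}")
    path = str(path)
    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise InputError(f"{path}: cannot parse VCF header: {exc}") from exc
    with vf:
        samples = list(vf.header.samples)
        known = set(_INFO_FIELDS)
        header_keys = set(vf.header.info.keys())
        for key in sorted(header_keys - known):
            logger.warning("%s: ignoring unknown INFO key %s", path, key)
        for key in sorted(known - header_keys):
            logger.warning(
                "%s: %s VCF lacks INFO key %s; values treated as missing",
                path, dialect, key,
            )
        has_ps = "PS" in vf.header.formats
        available = known & header_keys
        records: list[AnnotatedVariant] = []
        seen: set[str] = set()
        for line_no, rec in enumerate(vf, start=1):
            try:
                records.extend(
                    _parse_record(rec, samples, seen, has_ps, available)
                )
            except (ValueError, KeyError) as exc:
                raise InputError(
                    f"{path}: malformed record #{line_no} "
                    f"({rec.chrom}:{rec.pos}): {exc}"
                ) from exc
    return VariantTable(records=records, sample_ids=samples)


def _parse_record(rec, samples: list[str], seen: set[str], has_ps: bool,
                  available: set[str]) -> list[AnnotatedVariant]:
    out = []
    alts = rec.alts or ()
    filters = list(rec.filter.keys())
    filter_status = "PASS" if (not filters or filters == ["PASS"]) else filters[0]
    for k, alt in enumerate(alts):
        info = {}
        for key in _INFO_FIELDS:
            raw = rec.info.get(key) if key in available else None
            info[key] = _info_allele(raw, k) if raw is not None else None
        genotypes, phase_set, phased_allele = [], {}, {}
        for s in samples:
            call = rec.samples[s]
            alleles = call.get("GT")
            if alleles is None or all(a is None for a in alleles):
                genotypes.append("missing")
                continue
            n_alt = sum(1 for a in alleles if a == k + 1)
            genotypes.append(_GT_MAP[min(n_alt, 2)])
            if n_alt == 1 and call.phased and len(alleles) == 2:
                ps = call.get("PS") if has_ps else None
                if ps is not None:
                    phase_set[s] = _block_id(s, int(ps))
                    phased_allele[s] = 1 if alleles[0] == k + 1 else 2
        key = f"{rec.chrom}:{rec.pos}:{rec.ref}:{alt}"
        if key in seen:
            raise ValueError(f"duplicate variant {key}")
        seen.add(key)
        out.append(
            AnnotatedVariant(
                chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                filter_status=filter_status,
                gene=info["GENE"] or "",
                vclass=info["VCLASS"] or "other",
                af_esp=_maybe_float(info["AF_ESP"]),
                af_exac=_maybe_float(info["AF_EXAC"]),
                af_gnomad=_maybe_float(info["AF_GNOMAD"]),
                cadd_phred=_maybe_float(info["CADD_PHRED"]),
                polyphen=info["POLYPHEN"],
                sift=info["SIFT"],
                genotypes=tuple(genotypes),
                phase_set=phase_set,
                phased_allele=phased_allele,
            )
        )
    return out


def _maybe_float(v) -> Optional[float]:
    return None if v is None else round(float(v), 6)


def write_variant_table(table: VariantTable, path,
                        contigs: Optional[dict[str, int]] = None) -> None:
    """Write a table as uncompressed VCF v4.2 with phased GT + PS."""
    header = pysam.VariantHeader()
    if contigs is None:
        contigs = {}
        for rec in table.records:
            contigs[rec.chrom] = max(
                contigs.get(rec.chrom, 0), rec.pos + len(rec.ref) + 1
            )
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    header.filters.add("q10", None, None, "Low quality")
    for key, (vtype, desc) in _INFO_FIELDS.items():
        header.info.add(key, "A", vtype, desc)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("PS", 1, "Integer", "Phase set (block ordinal)")
    for s in table.sample_ids:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in sorted(table.records, key=lambda r: (r.chrom, r.pos, r.alt)):
            row = out.new_record(
                contig=rec.chrom, start=rec.pos - 1,
                stop=rec.pos - 1 + len(rec.ref),
                alleles=(rec.ref, rec.alt),
            )
            if rec.filter_status == "PASS":
                row.filter.add("PASS")
            else:
                row.filter.add(rec.filter_status)
            if rec.gene:
                row.info["GENE"] = (rec.gene,)
            row.info["VCLASS"] = (rec.vclass,)
            for key, val in (
                ("AF_ESP", rec.af_esp), ("AF_EXAC", rec.af_exac),
                ("AF_GNOMAD", rec.af_gnomad), ("CADD_PHRED", rec.cadd_phred),
            ):
                if val is not None:
                    row.info[key] = (val,)
            if rec.polyphen:
                row.info["POLYPHEN"] = (rec.polyphen,)
            if rec.sift:
                row.info["SIFT"] = (rec.sift,)
            for i, s in enumerate(table.sample_ids):
                gt = rec.genotypes[i] if rec.genotypes else "missing"
                call = row.samples[s]
                if gt == "missing":
                    call["GT"] = (None, None)
                elif gt == "hom_ref":
                    call["GT"] = (0, 0)
                elif gt == "hom_alt":
                    call["GT"] = (1, 1)
                elif s in rec.phase_set:
                    ps = _ps_int(rec.phase_set[s])
                    call["GT"] = (1, 0) if rec.phased_allele.get(s) == 1 else (0, 1)
                    call.phased = True
                    if ps is not None:
                        call["PS"] = ps
                else:
                    call["GT"] = (0, 1)
            out.write(row)


# ---------------------------------------------------------------------------
# BED


def _read_bed_rows(path, min_cols: int) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < min_cols:
                raise InputError(
                    f"{path}: line {line_no}: expected >= {min_cols} columns"
                )
            yield line_no, cols


def load_segments(path) -> list[CnvSegment]:
    """Load CNV segments from BED (chrom, start, end, sample, log2)."""
    out = []
    for line_no, cols in _read_bed_rows(path, 5):
        start, end = int(cols[1]), int(cols[2])
        if start >= end:
            raise InputError(
                f"{path}: line {line_no}: start {start} >= end {end}"
            )
        out.append(
            CnvSegment(cols[0], start + 1, end, cols[3], float(cols[4]))
        )
    return sorted(out, key=lambda s: (s.chrom, s.start, s.end, s.sample))


def write_segments(segments: list[CnvSegment], path) -> None:
    with open(path, "w") as fh:
        for s in sorted(segments, key=lambda x: (x.chrom, x.start, x.end, x.sample)):
            fh.write(f"{s.chrom}\t{s.start - 1}\t{s.end}\t{s.sample}\t{s.log2}\n")


def load_gene_models(path) -> list[GeneModel]:
    """Load gene models from BED (chrom, start, end, gene)."""
    out = []
    for line_no, cols in _read_bed_rows(path, 4):
        start, end = int(cols[1]), int(cols[2])
        if start >= end:
            raise InputError(
                f"{path}: line {line_no}: start {start} >= end {end}"
            )
        out.append(GeneModel(cols[3], cols[0], start + 1, end))
    return sorted(out, key=lambda g: (g.chrom, g.start, g.end))


def write_gene_models(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda x: (x.chrom, x.start, x.end)):
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene}\n")


# ---------------------------------------------------------------------------
# PED


_PHENOTYPE_IN = {"2": "affected", "1": "unaffected", "0": "unknown", "-9": "unknown"}
_PHENOTYPE_OUT = {"affected": "2", "unaffected": "1", "unknown": "0"}


def load_pedigree(path) -> Pedigree:
    """Load a 6-column PED file."""
    individuals = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 6:
                raise InputError(f"{path}: line {line_no}: expected 6 columns")
            _fam, iid, fid, mid, sex, phen = cols[:6]
            if phen not in _PHENOTYPE_IN:
                raise InputError(
                    f"{path}: line {line_no}: bad phenotype code {phen!r}"
                )
            individuals.append(
                Individual(iid, fid, mid, int(sex), _PHENOTYPE_IN[phen])
            )
    if not individuals:
        raise InputError(f"{path}: empty pedigree")
    return Pedigree(individuals)


def write_pedigree(ped: Pedigree, path, family_id: str = "FAM1") -> None:
    with open(path, "w") as fh:
        for i in ped.individuals:
            fh.write(
                f"{family_id}\t{i.id}\t{i.father_id or '0'}\t"
                f"{i.mother_id or '0'}\t{i.sex}\t{_PHENOTYPE_OUT[i.phenotype]}\n"
            )


# ---------------------------------------------------------------------------
# barcode TSV


_BARCODE_COLS = ["block_id", "chrom", "start", "end",
                 "hap1_count", "hap2_count", "sample"]


def load_barcode_counts(path) -> list[PhaseBlock]:
    """Load phase-block barcode counts from a headered TSV."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _BARCODE_COLS:
            raise InputError(
                f"{path}: bad barcode header {header!r}; expected {_BARCODE_COLS}"
            )
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != len(_BARCODE_COLS):
                raise InputError(f"{path}: line {line_no}: wrong column count")
            c1, c2 = int(cols[4]), int(cols[5])
            if c1 < 0 or c2 < 0:
                raise InputError(
                    f"{path}: line {line_no}: negative barcode count"
                )
            out.append(
                PhaseBlock(cols[0], cols[1], int(cols[2]), int(cols[3]),
                           cols[6], c1, c2)
            )
    return out


def write_barcode_counts(blocks: list[PhaseBlock], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_BARCODE_COLS) + "\n")
        for b in blocks:
            fh.write(
                f"{b.block_id}\t{b.chrom}\t{b.start}\t{b.end}\t"
                f"{b.hap1_count}\t{b.hap2_count}\t{b.sample}\n"
            )
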