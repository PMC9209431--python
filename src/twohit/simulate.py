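"""Seeded synthetic cohorts with planted two-hit ground truth.

The generator emulates the statistical structure of a familial two-hit
discovery study: an 8-sibling sibship segregating a rare truncating allele
(heterozygous in all four affected siblings plus two unaffected carriers —
incomplete penetrance), tumors from every affected sibling carrying a somatic
deletion that removes the wildtype haplotype at the causal gene, decoy genes
that exercise each elimination rule of the pipeline, and linked-read phase
blocks whose per-haplotype barcode counts are depleted on the deleted
haplotype inside tumor deletions.

Genotypes are produced by explicit Mendelian transmission from two simulated
parents: each sibling's two chromosomes are mosaics of the corresponding
parent's two haplotypes with a Poisson number of crossovers.  Local phase
labels are independently randomised per block (the label gauge), so any
consumer must be gauge-invariant.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .model import (
    AnnotatedVariant,
    CnvSegment,
    ConfigError,
    GeneModel,
    Individual,
    Pedigree,
    PhaseBlock,
    PROTEIN_ALTERING_CLASSES,
    VariantTable,
)

__all__ = [
    "CohortConfig",
    "TruthRecord",
    "Cohort",
    "simulate_cohort",
    "simulate_phase_blocks",
    "plant_decoys",
    "emit_truth",
    "load_truth",
    "tumor_of",
]

#: Default consequence-class mix for background variants (exome-like).
DEFAULT_CLASS_WEIGHTS = {
    "synonymous": 0.35,
    "missense": 0.40,
    "other": 0.10,
    "inframe": 0.03,
    "frameshift": 0.04,
    "splice_site": 0.04,
    "nonsense": 0.03,
    "stop_lost": 0.01,
}

_PARENTAL_HAPS = ("F1", "F2", "M1", "M2")  # 0,1 paternal; 2,3 maternal


def tumor_of(sample_id: str) -> str:
    """Tumor sample id for a sibling's tumor."""
    return f"{sample_id}_T"


@dataclass
class CohortConfig:
    """Study conditions for one simulated cohort.

    Defaults mirror the structure of the motivating pedigree: eight siblings,
    four affected, the causal allele also carried by two unaffected siblings.
    """

    n_siblings: int = 8
    n_affected: int = 4
    n_unaffected_carriers: int = 2
    region_length: int = 5_000_000
    chrom: str = "chr3"
    n_background_variants: int = 2000
    causal_class: str = "nonsense"
    causal_pop_af: float = 0.001
    background_af_alpha: float = 0.5
    background_af_beta: float = 5.0
    class_weights: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS))
    recombination_rate: float = 0.05
    n_decoy_germline_only: int = 3
    n_decoy_somatic_only: int = 3
    include_mutant_deleted_decoy: bool = True
    deletion_fraction_depletion: float = 0.6
    barcode_rate: float = 8.0  # expected barcodes per haplotype per 100 kb
    block_mean_length: int = 250_000
    causal_deletion_length: int = 2_000_000
    decoy_deletion_length: int = 1_000_000
    n_somatic_background: int = 40
    non_pass_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_siblings < 1:
            raise ConfigError("n_siblings must be >= 1")
        if self.n_affected < 1:
            raise ConfigError("n_affected must be >= 1")
        if self.n_affected + self.n_unaffected_carriers > self.n_siblings:
            raise ConfigError(
                "n_affected + n_unaffected_carriers exceeds n_siblings"
            )
        for name in ("causal_pop_af", "deletion_fraction_depletion",
                     "non_pass_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        # d = 0 is allowed: it disables depletion (null-calibration runs)
        if self.region_length < 1:
            raise ConfigError("region_length must be positive")
        total = sum(self.class_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class_weights sum to {total}, expected 1")
        if self.causal_class not in PROTEIN_ALTERING_CLASSES:
            raise ConfigError(
                f"causal_class {self.causal_class!r} is not protein-altering"
            )


@dataclass
class TruthRecord:
    """Planted ground truth: the acceptance surface of a synthetic cohort.

    ``deleted_haplotype`` maps each affected tumor to the chromosome
    (``paternal``/``maternal``) and the parental haplotype label at the causal
    locus that its deletion removes.
    """

    causal_gene: str
    causal_variant: str
    carrier_ids: list[str]
    affected_ids: list[str]
    deleted_haplotype: dict[str, dict[str, str]]
    decoy_genes: list[dict[str, str]]

    def __post_init__(self) -> None:
        if not set(self.affected_ids) <= set(self.carrier_ids):
            raise ValueError("affected_ids must be a subset of carrier_ids")
        if self.causal_gene in {d["gene"] for d in self.decoy_genes}:
            raise ValueError("causal gene cannot also be a decoy")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TruthRecord":
        return cls(**d)


@dataclass
class _Mosaic:
    """One transmitted chromosome: alternating parental-haplotype segments."""

    breakpoints: list[int]       # sorted interior breakpoints
    haps: list[int]              # parental hap index per segment (global 0..3)

    def hap_at(self, pos: int) -> int:
        return self.haps[bisect.bisect_right(self.breakpoints, pos)]

    def flipped(self, pair: tuple[int, int]) -> "_Mosaic":
        a, b = pair
        swap = {a: b, b: a}
        return _Mosaic(list(self.breakpoints), [swap[h] for h in self.haps])


@dataclass
class Cohort:
    """A simulated cohort plus the generator-internal state used to extend it."""

    config: CohortConfig
    pedigree: Pedigree
    sibling_ids: list[str]
    affected_ids: list[str]
    carrier_ids: list[str]
    gene_models: list[GeneModel]
    germline: VariantTable
    somatic: dict[str, VariantTable]
    segments: list[CnvSegment]
    truth: TruthRecord
    # internals
    transmissions: dict[str, tuple[_Mosaic, _Mosaic]]
    origin: dict[str, tuple[bool, bool, bool, bool]]
    tumor_deletions: dict[str, list[tuple[int, int, str]]]  # (start, end, chromosome)

    @property
    def chrom(self) -> str:
        return self.config.chrom

    @property
    def tumor_ids(self) -> list[str]:
        return [tumor_of(s) for s in self.affected_ids]

    def alt_chromosome(self, sample: str, variant: AnnotatedVariant) -> Optional[str]:
        """For a het call, which chromosome (paternal/maternal) holds the alt."""
        pat, mat = self.transmissions[sample]
        carrier = self.origin[variant.key]
        on_pat = carrier[pat.hap_at(variant.pos)]
        on_mat = carrier[mat.hap_at(variant.pos)]
        if on_pat == on_mat:
            return None  # hom or absent: not a het site
        return "paternal" if on_pat else "maternal"


def _make_gene_models(config: CohortConfig) -> list[GeneModel]:
    spacing, width = 100_000, 30_000
    n = max((config.region_length - 60_000 - width) // spacing + 1, 0)
    genes = []
    for i in range(n):
        start = 60_000 + i * spacing
        genes.append(GeneModel(f"GENE{i + 1:03d}", config.chrom, start, start + width))
    return genes


def _gene_nearest(genes: list[GeneModel], pos: int) -> GeneModel:
    return min(genes, key=lambda g: abs((g.start + g.end) // 2 - pos))


def _draw_mosaic(rng: np.random.Generator, length: int, rate: float,
                 hap_pair: tuple[int, int]) -> _Mosaic:
    n_cross = int(rng.poisson(rate))
    breaks = sorted(int(b) for b in rng.integers(2, length, size=n_cross))
    start = int(rng.integers(0, 2))
    haps = [hap_pair[(start + i) % 2] for i in range(n_cross + 1)]
    return _Mosaic(breaks, haps)


def _genotype_from(carrier, pat_hap: int, mat_hap: int) -> str:
    n_alt = int(carrier[pat_hap]) + int(carrier[mat_hap])
    return ("hom_ref", "het", "hom_alt")[n_alt]


class _Builder:
    """Accumulates variants and somatic events while the cohort is planted."""

    def __init__(self, config: CohortConfig, rng: np.random.Generator):
        config.validate()
        self.config = config
        self.rng = rng
        self.chrom = config.chrom
        self.sibling_ids = [f"III_{i + 1}" for i in range(config.n_siblings)]
        self.affected_ids = self.sibling_ids[: config.n_affected]
        self.carrier_ids = self.sibling_ids[
            : config.n_affected + config.n_unaffected_carriers
        ]
        self.gene_models = _make_gene_models(config)
        self.transmissions: dict[str, tuple[_Mosaic, _Mosaic]] = {}
        self.origin: dict[str, tuple] = {}
        self.germline: list[AnnotatedVariant] = []
        self.somatic: dict[str, list[AnnotatedVariant]] = {
            tumor_of(s): [] for s in self.affected_ids
        }
        self.segments: list[CnvSegment] = []
        self.tumor_deletions: dict[str, list[tuple[int, int, str]]] = {
            tumor_of(s): [] for s in self.affected_ids
        }
        self.used_positions: set[int] = set()
        self.decoy_records: list[dict[str, str]] = []
        self.deleted_haplotype: dict[str, dict[str, str]] = {}
        self.causal_gene: Optional[GeneModel] = None
        self.causal_key: Optional[str] = None
        self.reserved_genes: set[str] = set()

    # -- transmission -------------------------------------------------------

    def draw_transmissions(self) -> None:
        cfg = self.config
        for s in self.sibling_ids:
            pat = _draw_mosaic(self.rng, cfg.region_length,
                               cfg.recombination_rate, (0, 1))
            mat = _draw_mosaic(self.rng, cfg.region_length,
                               cfg.recombination_rate, (2, 3))
            self.transmissions[s] = (pat, mat)

    def orient_at_causal(self, pos: int) -> None:
        """Relabel each sibling's paternal mosaic so F1 at ``pos`` is carried by
        exactly the designated carriers (a label choice within the Mendelian
        model, not a change to the crossover process)."""
        for s in self.sibling_ids:
            pat, mat = self.transmissions[s]
            want = 0 if s in self.carrier_ids else 1
            if pat.hap_at(pos) != want:
                self.transmissions[s] = (pat.flipped((0, 1)), mat)

    # -- variant plumbing ---------------------------------------------------

    def genotypes_for(self, pos: int, carrier) -> tuple[str, ...]:
        out = []
        for s in self.sibling_ids:
            pat, mat = self.transmissions[s]
            out.append(_genotype_from(carrier, pat.hap_at(pos), mat.hap_at(pos)))
        return tuple(out)

    def fresh_position(self, lo: int, hi: int) -> int:
        for _ in range(1000):
            pos = int(self.rng.integers(lo, hi + 1))
            if pos not in self.used_positions:
                self.used_positions.add(pos)
                return pos
        raise ConfigError("could not place a variant: position space exhausted")

    def add_germline(self, pos: int, carrier, **kw) -> AnnotatedVariant:
        rec = AnnotatedVariant(
            chrom=self.chrom, pos=pos,
            genotypes=self.genotypes_for(pos, carrier), **kw,
        )
        self.origin[rec.key] = tuple(bool(c) for c in carrier)
        self.germline.append(rec)
        return rec

    def shared_parental_hap(self, pos: int) -> Optional[int]:
        """A parental haplotype carried by every affected sibling at ``pos``."""
        options = []
        for h in range(4):
            side = 0 if h < 2 else 1
            if all(
                self.transmissions[s][side].hap_at(pos) == h
                for s in self.affected_ids
            ):
                options.append(h)
        if not options:
            return None
        return options[int(self.rng.integers(0, len(options)))]

    # -- planted content ----------------------------------------------------

    def plant_causal(self) -> None:
        cfg = self.config
        genes = self.gene_models
        if not genes:
            raise ConfigError("region too short to hold any gene")
        target = int(cfg.region_length * 0.6)
        self.causal_gene = _gene_nearest(genes, target)
        self.reserved_genes.add(self.causal_gene.gene)
        center = (self.causal_gene.start + self.causal_gene.end) // 2
        self.orient_at_causal(center)
        self.used_positions.add(center)
        carrier = (True, False, False, False)  # paternal haplotype F1
        rec = self.add_germline(
            center, carrier, ref="C", alt="T", filter_status="PASS",
            gene=self.causal_gene.gene, vclass=cfg.causal_class,
            af_exac=cfg.causal_pop_af, af_gnomad=cfg.causal_pop_af,
            cadd_phred=35.0,
        )
        self.causal_key = rec.key
        # somatic second hit: delete the wildtype (maternal) haplotype
        half = cfg.causal_deletion_length // 2
        start = max(1, center - half)
        end = min(cfg.region_length, center + half)
        for s in self.affected_ids:
            t = tumor_of(s)
            self.tumor_deletions[t].append((start, end, "maternal"))
            self.segments.append(
                CnvSegment(self.chrom, start, end, t, log2=-1.0)
            )
            _, mat = self.transmissions[s]
            self.deleted_haplotype[t] = {
                "chromosome": "maternal",
                "parental_hap": _PARENTAL_HAPS[mat.hap_at(center)],
            }

    def _free_genes(self, avoid_intervals: list[tuple[int, int]]) -> list[GeneModel]:
        out = []
        for g in self.gene_models:
            if g.gene in self.reserved_genes:
                continue
            if any(g.start <= e and s <= g.end for s, e in avoid_intervals):
                continue
            out.append(g)
        return out

    def deletion_footprints(self) -> list[tuple[int, int]]:
        return [
            (s, e)
            for dels in self.tumor_deletions.values()
            for (s, e, _c) in dels
        ]

    def plant_mutant_deleted_decoy(self) -> None:
        cfg = self.config
        target = int(cfg.region_length * 0.16)
        free = [
            g for g in self._free_genes(self.deletion_footprints())
            if abs((g.start + g.end) // 2 - target) < cfg.region_length // 4
        ]
        if not free:
            raise ConfigError("gene-space exhausted: no site for deleted decoy")
        gene = _gene_nearest(free, target)
        self.reserved_genes.add(gene.gene)
        center = (gene.start + gene.end) // 2
        hap = self.shared_parental_hap(center)
        if hap is None:
            hap = 0  # rare crossover case: falls back to F1, may not segregate
        carrier = tuple(i == hap for i in range(4))
        pos = self.fresh_position(center - 5000, center + 5000)
        self.add_germline(
            pos, carrier, ref="G", alt="A", filter_status="PASS",
            gene=gene.gene, vclass="missense", af_gnomad=0.002, af_exac=0.002,
            cadd_phred=24.0, polyphen="probably_damaging", sift="deleterious",
        )
        chromosome = "paternal" if hap < 2 else "maternal"
        half = cfg.decoy_deletion_length // 2
        start = max(1, center - half)
        end = min(cfg.region_length, center + half)
        for s in self.affected_ids:
            t = tumor_of(s)
            self.tumor_deletions[t].append((start, end, chromosome))
            self.segments.append(CnvSegment(self.chrom, start, end, t, log2=-1.0))
        self.decoy_records.append({"gene": gene.gene, "kind": "mutant_deleted"})

    def plant_germline_only_decoys(self, n: int) -> None:
        free = self._free_genes(self.deletion_footprints())
        if len(free) < n:
            raise ConfigError("gene-space exhausted for germline-only decoys")
        idx = self.rng.choice(len(free), size=n, replace=False)
        for i in sorted(int(j) for j in idx):
            gene = free[i]
            self.reserved_genes.add(gene.gene)
            center = (gene.start + gene.end) // 2
            hap = self.shared_parental_hap(center)
            if hap is None:
                hap = 0
            carrier = tuple(k == hap for k in range(4))
            pos = self.fresh_position(gene.start, gene.end)
            self.add_germline(
                pos, carrier, ref="A", alt="G", filter_status="PASS",
                gene=gene.gene, vclass="missense", af_gnomad=0.003,
                af_exac=0.003, cadd_phred=26.0,
                polyphen="probably_damaging", sift="deleterious",
            )
            self.decoy_records.append({"gene": gene.gene, "kind": "germline_only"})

    def plant_somatic_only_decoys(self, n: int) -> None:
        free = self._free_genes(self.deletion_footprints())
        if len(free) < n:
            raise ConfigError("gene-space exhausted for somatic-only decoys")
        idx = self.rng.choice(len(free), size=n, replace=False)
        for i in sorted(int(j) for j in idx):
            gene = free[i]
            self.reserved_genes.add(gene.gene)
            for s in self.affected_ids:
                pos = self.fresh_position(gene.start, gene.end)
                rec = AnnotatedVariant(
                    chrom=self.chrom, pos=pos, ref="T", alt="C",
                    filter_status="PASS", gene=gene.gene, vclass="missense",
                    cadd_phred=22.0, genotypes=("het",),
                )
                self.somatic[tumor_of(s)].append(rec)
            self.decoy_records.append({"gene": gene.gene, "kind": "somatic_only"})

    # -- background ---------------------------------------------------------

    def gene_at(self, pos: int) -> str:
        for g in self.gene_models:
            if g.start <= pos <= g.end:
                return g.gene
        return ""

    def _draw_class(self) -> str:
        classes = list(self.config.class_weights)
        probs = np.fromiter(self.config.class_weights.values(), float)
        return classes[int(self.rng.choice(len(classes), p=probs / probs.sum()))]

    def _draw_alleles(self, vclass: str) -> tuple[str, str]:
        """Indel classes get length-changing alleles; the rest are SNVs."""
        is_indel = vclass in ("frameshift", "inframe") or (
            vclass == "splice_site" and self.rng.random() < 0.5
        )
        if not is_indel:
            return "A", "C"
        return ("A", "ACT") if self.rng.random() < 0.5 else ("ACT", "A")

    def _draw_scores(self, vclass: str, rng: np.random.Generator) -> dict:
        out: dict = {}
        if vclass == "missense":
            out["polyphen"] = ("benign", "possibly_damaging",
                               "probably_damaging")[int(rng.integers(0, 3))]
            out["sift"] = ("tolerated", "deleterious")[int(rng.integers(0, 2))]
        if vclass in PROTEIN_ALTERING_CLASSES:
            out["cadd_phred"] = float(np.round(rng.gamma(4.0, 5.0), 3))
        else:
            out["cadd_phred"] = float(np.round(rng.gamma(1.5, 2.0), 3))
        return out

    def plant_background(self, n: int) -> None:
        cfg, rng = self.config, self.rng
        # planted genes stay clean: their filter behaviour is the ground truth
        avoid = [(g.start, g.end) for g in self.gene_models
                 if g.gene in self.reserved_genes]
        for _ in range(n):
            while True:
                pos = self.fresh_position(1, cfg.region_length)
                if not any(a <= pos <= b for a, b in avoid):
                    break
            af = float(rng.beta(cfg.background_af_alpha, cfg.background_af_beta))
            af = min(max(af, 1e-5), 0.999)
            # parental carriage conditioned on at least one carrier haplotype:
            # draw the carrier count from Binomial(4, af) truncated at >= 1,
            # then place the carriers uniformly
            q = 1.0 - af
            weights = np.array(
                [4 * af * q**3, 6 * af**2 * q**2, 4 * af**3 * q, af**4]
            )
            k = 1 + int(rng.choice(4, p=weights / weights.sum()))
            carrier = np.zeros(4, dtype=bool)
            carrier[rng.choice(4, size=k, replace=False)] = True
            vclass = self._draw_class()
            ref, alt = self._draw_alleles(vclass)
            filt = "PASS" if rng.random() >= cfg.non_pass_fraction else "q10"
            jitter = float(np.exp(rng.normal(0.0, 0.15)))
            af_esp = None if rng.random() < 0.3 else min(af * jitter, 1.0)
            self.add_germline(
                pos, carrier, ref=ref, alt=alt, filter_status=filt,
                gene=self.gene_at(pos), vclass=vclass,
                af_gnomad=float(np.round(af, 6)),
                af_exac=float(np.round(min(af * jitter, 1.0), 6)),
                af_esp=None if af_esp is None else float(np.round(af_esp, 6)),
                **self._draw_scores(vclass, rng),
            )

    def plant_somatic_background(self, n_per_tumor: int) -> None:
        cfg, rng = self.config, self.rng
        avoid = [(g.start, g.end) for g in self.gene_models
                 if g.gene in self.reserved_genes]
        for s in self.affected_ids:
            t = tumor_of(s)
            for _ in range(n_per_tumor):
                while True:
                    pos = self.fresh_position(1, cfg.region_length)
                    if not any(a <= pos <= b for a, b in avoid):
                        break
                vclass = self._draw_class()
                ref, alt = self._draw_alleles(vclass)
                filt = "PASS" if rng.random() >= 0.1 else "q10"
                self.somatic[t].append(
                    AnnotatedVariant(
                        chrom=self.chrom, pos=pos, ref=ref, alt=alt,
                        filter_status=filt, gene=self.gene_at(pos),
                        vclass=vclass, genotypes=("het",),
                        **self._draw_scores(vclass, rng),
                    )
                )

    # -- assembly -----------------------------------------------------------

    def build(self) -> Cohort:
        cfg = self.config
        father, mother = "II_1", "II_2"
        individuals = [
            Individual(father, "0", "0", 1, "unknown"),
            Individual(mother, "0", "0", 2, "unknown"),
        ]
        for i, s in enumerate(self.sibling_ids):
            phen = "affected" if s in self.affected_ids else "unaffected"
            individuals.append(Individual(s, father, mother, 1 + i % 2, phen))
        pedigree = Pedigree(individuals)

        germline = VariantTable(
            records=sorted(self.germline, key=lambda r: r.pos),
            sample_ids=list(self.sibling_ids),
        )
        somatic = {
            t: VariantTable(records=sorted(v, key=lambda r: r.pos),
                            sample_ids=[t])
            for t, v in self.somatic.items()
        }
        truth = TruthRecord(
            causal_gene=self.causal_gene.gene,
            causal_variant=self.causal_key,
            carrier_ids=list(self.carrier_ids),
            affected_ids=list(self.affected_ids),
            deleted_haplotype=dict(self.deleted_haplotype),
            decoy_genes=list(self.decoy_records),
        )
        segments = sorted(
            self.segments, key=lambda g: (g.chrom, g.start, g.end, g.sample)
        )
        return Cohort(
            config=cfg, pedigree=pedigree, sibling_ids=self.sibling_ids,
            affected_ids=list(self.affected_ids),
            carrier_ids=list(self.carrier_ids),
            gene_models=self.gene_models, germline=germline, somatic=somatic,
            segments=segments, truth=truth, transmissions=self.transmissions,
            origin=self.origin, tumor_deletions=self.tumor_deletions,
        )


def simulate_cohort(config: Optional[CohortConfig] = None) -> Cohort:
    """Generate one cohort with planted causal gene, decoys and background.

    Deterministic given ``config`` (including ``config.seed``).
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng([int(config.seed), 0])
    b = _Builder(config, rng)
    b.draw_transmissions()
    b.plant_causal()
    if config.include_mutant_deleted_decoy:
        b.plant_mutant_deleted_decoy()
    b.plant_germline_only_decoys(config.n_decoy_germline_only)
    b.plant_somatic_only_decoys(config.n_decoy_somatic_only)
    b.plant_background(config.n_background_variants)
    b.plant_somatic_background(config.n_somatic_background)
    return b.build()


def plant_decoys(cohort: Cohort, config: CohortConfig) -> Cohort:
    """Inject the configured decoy genes into a cohort generated without them.

    Returns a new cohort; ``cohort`` itself is not modified.
    """
    cfg = CohortConfig(**{**asdict(config), "class_weights": dict(config.class_weights)})
    rng = np.random.default_rng([int(cfg.seed), 7])
    b = _Builder(cfg, rng)
    b.transmissions = {
        s: (_Mosaic(list(p.breakpoints), list(p.haps)),
            _Mosaic(list(m.breakpoints), list(m.haps)))
        for s, (p, m) in cohort.transmissions.items()
    }
    b.germline = list(cohort.germline.records)
    b.origin = dict(cohort.origin)
    b.somatic = {t: list(tab.records) for t, tab in cohort.somatic.items()}
    b.segments = list(cohort.segments)
    b.tumor_deletions = {t: list(v) for t, v in cohort.tumor_deletions.items()}
    b.used_positions = {r.pos for r in cohort.germline.records}
    b.causal_gene = next(
        g for g in cohort.gene_models if g.gene == cohort.truth.causal_gene
    )
    b.causal_key = cohort.truth.causal_variant
    b.deleted_haplotype = dict(cohort.truth.deleted_haplotype)
    b.reserved_genes = {cohort.truth.causal_gene} | {
        d["gene"] for d in cohort.truth.decoy_genes
    }
    b.decoy_records = list(cohort.truth.decoy_genes)
    if cfg.include_mutant_deleted_decoy and not any(
        d["kind"] == "mutant_deleted" for d in b.decoy_records
    ):
        b.plant_mutant_deleted_decoy()
    have_g = sum(d["kind"] == "germline_only" for d in b.decoy_records)
    have_s = sum(d["kind"] == "somatic_only" for d in b.decoy_records)
    if cfg.n_decoy_germline_only > have_g:
        b.plant_germline_only_decoys(cfg.n_decoy_germline_only - have_g)
    if cfg.n_decoy_somatic_only > have_s:
        b.plant_somatic_only_decoys(cfg.n_decoy_somatic_only - have_s)
    return b.build()


# ---------------------------------------------------------------------------
# phase blocks


def _partition_region(rng: np.random.Generator, length: int,
                      mean_len: int) -> list[tuple[int, int]]:
    """Tile [1, length] with contiguous blocks, lengths ~ Exp(mean_len)."""
    if length < 1:
        raise ConfigError("empty region: cannot draw phase blocks")
    blocks, pos = [], 1
    min_len = max(mean_len // 10, 1)
    while pos <= length:
        ln = max(int(rng.exponential(mean_len)), min_len)
        end = min(pos + ln - 1, length)
        blocks.append((pos, end))
        pos = end + 1
    return blocks


def _deleted_overlap(start: int, end: int,
                     dels: list[tuple[int, int, str]], chromosome: str) -> int:
    """Bases of [start, end] lying inside deletions on the given chromosome."""
    covered = 0
    for ds, de, dc in dels:
        if dc != chromosome:
            continue
        lo, hi = max(start, ds), min(end, de)
        if lo <= hi:
            covered += hi - lo + 1
    return covered


def simulate_phase_blocks(
    cohort: Cohort, config: Optional[CohortConfig] = None
) -> tuple[dict[str, list[PhaseBlock]], dict[str, list[PhaseBlock]]]:
    """Draw per-sample phase blocks and barcode counts; phase het variants.

    Returns ``(germline_blocks, tumor_blocks)`` keyed by sample / tumor id.
    Each sibling's tumor shares the sibling's block partition and gauge (the
    phasing comes from the same linked-read library); tumor barcode counts on
    a deleted chromosome are thinned by ``1 - deletion_fraction_depletion``
    over the deleted fraction of the block.  Germline het variants are
    annotated in place with ``phase_set`` and ``phased_allele`` per sample.
    """
    config = config or cohort.config
    rng = np.random.default_rng([int(config.seed), 1])
    d = config.deletion_fraction_depletion
    rate = config.barcode_rate / 100_000.0  # per hap per base
    germline_blocks: dict[str, list[PhaseBlock]] = {}
    tumor_blocks: dict[str, list[PhaseBlock]] = {}

    het_by_sample: dict[str, list[AnnotatedVariant]] = {
        s: [] for s in cohort.sibling_ids
    }
    for rec in cohort.germline.records:
        for i, s in enumerate(cohort.sibling_ids):
            if rec.genotypes[i] == "het":
                het_by_sample[s].append(rec)

    for s in cohort.sibling_ids:
        parts = _partition_region(rng, config.region_length,
                                  config.block_mean_length)
        swaps = rng.integers(0, 2, size=len(parts))
        starts = [p[0] for p in parts]
        tumor = tumor_of(s)
        dels = cohort.tumor_deletions.get(tumor, [])
        g_list, t_list = [], []
        for j, (bs, be) in enumerate(parts):
            bid = f"{s}_B{j + 1:04d}"
            u = int(swaps[j])  # 0: local hap1 = paternal; 1: local hap1 = maternal
            length = be - bs + 1
            lam = rate * length
            g1, g2 = int(rng.poisson(lam)), int(rng.poisson(lam))
            g_list.append(PhaseBlock(bid, cohort.chrom, bs, be, s, g1, g2))
            if tumor in cohort.somatic:
                lams = []
                for h in (1, 2):
                    chromosome = "paternal" if (h == 1) == (u == 0) else "maternal"
                    inside = _deleted_overlap(bs, be, dels, chromosome)
                    lams.append(rate * ((length - inside) + (1.0 - d) * inside))
                t1, t2 = int(rng.poisson(lams[0])), int(rng.poisson(lams[1]))
                t_list.append(PhaseBlock(bid, cohort.chrom, bs, be, tumor, t1, t2))
        germline_blocks[s] = g_list
        if tumor in cohort.somatic:
            tumor_blocks[tumor] = t_list

        # phase het variants into the sample's blocks
        for rec in het_by_sample[s]:
            j = bisect.bisect_right(starts, rec.pos) - 1
            bs, be = parts[j]
            if not (bs <= rec.pos <= be):
                continue
            chromosome = cohort.alt_chromosome(s, rec)
            if chromosome is None:
                continue
            u = int(swaps[j])
            local = 1 if (chromosome == "paternal") == (u == 0) else 2
            rec.phase_set[s] = f"{s}_B{j + 1:04d}"
            rec.phased_allele[s] = local

    return germline_blocks, tumor_blocks


# ---------------------------------------------------------------------------
# truth serialization


def emit_truth(truth: TruthRecord, path) -> None:
    """Write the planted ground truth as JSON."""
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_truth(path) -> TruthRecord:
    with open(path) as fh:
        return TruthRecord.from_dict(json.load(fh))
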