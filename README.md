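# twohit

Familial two-hit tumor-suppressor discovery: a tested, reusable pipeline for
finding a germline predisposition allele in a sibship and confirming its
somatic "second hit" in the carriers' tumors.

The package is aimed at cancer-genetics analysts working with a small pedigree
(here: an eight-sibling sibship with four affected members) that has joint
germline exome calls, per-tumor somatic small-variant and copy-number calls,
and linked-read phasing. It implements:

1. **Germline filtering funnel** — keep variants that are `PASS`, carried
   (≥ 1 alt allele) by *every* affected sibling (unaffected carriers allowed:
   incomplete penetrance), protein-altering (missense, nonsense, splice site,
   stop lost, frameshift, in-frame), and rare
   (max population AF over ESP/ExAC/gnomAD < 1%).
2. **Somatic second-hit intersection** — a funnel gene becomes a two-hit
   candidate iff every affected tumor shows a somatic deletion overlapping the
   gene or a qualifying somatic small variant in it; candidates whose germline
   variant is simultaneously PolyPhen-benign, SIFT-tolerated and low-CADD are
   triaged out (truncating variants never are).
3. **Haplotype stitching & LOH assignment** — inside a hemizygous deletion the
   deleted haplotype loses a fraction *d* of its linked-read barcodes. Each
   locally phased block with counts (n₁, n₂) gets an exact two-sided binomial
   test against Binomial(n₁+n₂, ½); region-level significance is Fisher's
   combination of the per-block p-values (invariant to the per-block label
   gauge); significant blocks are oriented so their depleted local haplotype
   maps to global haplotype B, counts are pooled, and one more binomial test
   on the pooled counts yields the extended haplotype's p-value. Mapping the
   candidate allele's phased position through its block's orientation gives
   the cis/trans call: **wildtype lost** (mutant retained — real LOH of a
   tumor suppressor) or **mutant lost** (the candidate is eliminated).
4. **Pedigree segregation** — within a 0.8 Mb window the candidate-bearing
   haplotype of a reference sibling is compared against every sibling's
   phased haplotypes; the verdict asks whether all affected siblings share it.
5. **Association statistics** — allele-count 2×2 tables: cross-product odds
   ratio OR = ad/bc with Woolf 95% CI exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)),
   Fisher's exact test, a logistic fit whose OR equals the cross-product OR
   (identity used as a cross-check), genotype concordance, and Pearson χ²
   for r×c contingency tables.

A first-class synthetic-cohort generator (`twohit.simulate`) produces seeded
cohorts with Mendelian transmission from two simulated parents, a planted
rare truncating allele heterozygous in all four affected plus two unaffected
siblings, per-tumor deletions removing the wildtype haplotype, decoy genes
for every elimination path (germline-only, somatic-only, mutant-deleted), and
phase blocks with haplotype-specific barcode depletion — ground truth
included, so the whole pipeline is testable end to end.

## Worked example

```sh
twohit simulate --seed 1 --out-dir cohort
# wrote cohort inputs to cohort (2005 germline variants, 4 tumors)

twohit filter-germline --vcf cohort/germline.vcf --ped cohort/family.ped \
    --out funnel.json
# final stage: 65 SNVs + 9 indels in 19 genes

twohit second-hit --germline-candidates funnel.json \
    --somatic-vcf cohort/somatic_III_1_T.vcf --somatic-vcf cohort/somatic_III_2_T.vcf \
    --somatic-vcf cohort/somatic_III_3_T.vcf --somatic-vcf cohort/somatic_III_4_T.vcf \
    --cnv cohort/segments.bed --genes cohort/genes.bed --out candidates.json
# 10 two-hit genes, 10 after triage: GENE006, GENE008, GENE010, GENE020,
# GENE025, GENE027, GENE030, GENE033, GENE034, GENE040

twohit haplotype --barcodes cohort/tumor_barcodes.tsv \
    --region chr3:1975000-3975000 --candidate chr3:2975000:C:T \
    --germline-vcf cohort/germline.vcf --sample III_1 --tumor III_1_T --out loh.json
# chr3:2975000:C:T: wildtype_lost (deleted haplotype B, pooled p 1.92e-06)

twohit segregate --germline-vcf cohort/germline.vcf --ped cohort/family.ped \
    --candidate chr3:2975000:C:T --out seg.json
# all affected share candidate haplotype: True
```

Reading the output: the funnel reduces 2,005 joint germline variants to 74 in
19 genes; ten of those genes also carry somatic evidence in all four tumors.
The planted causal gene is `GENE030` (check `cohort/truth.json`): its
candidate allele `chr3:2975000:C:T` sits on the *retained* haplotype while
the other haplotype is significantly barcode-depleted (pooled p ≈ 2 × 10⁻⁶),
i.e. the tumor deleted the wildtype copy — a classic two-hit configuration —
and all four affected siblings share the candidate-bearing haplotype. Decoy
`GENE008` also reaches the candidate list but its LOH call is `mutant_lost`,
which eliminates it.

`twohit run-all --config config.yaml --seed 1 --out-dir out` drives the same
stages from one YAML file (either an `inputs:` block with file paths or a
`simulate:` block) and writes a single versioned `report.json`.

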