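# Methods

## The analysis model

The pipeline operationalises the two-hit tumor-suppressor hypothesis in a
family: a rare germline loss-of-function allele segregates with disease under
a dominant model with incomplete penetrance, and the tumors of affected
carriers somatically inactivate the remaining wildtype copy — typically by a
copy-number deletion. Evidence is assembled in four stages (germline funnel,
somatic intersection, LOH haplotype analysis, pedigree segregation), each of
which only ever removes or annotates candidates; nothing downstream can
resurrect a gene eliminated upstream.

### Germline funnel

The three substantive filters are pure per-record predicates, so they
commute, are idempotent and are individually monotone; the test suite asserts
all three algebraic properties. Decisions embedded in the funnel:

- *Carriage*, not genotype, defines sharing: an affected individual counts as
  a carrier with either one or two alt alleles. A missing genotype in an
  affected individual counts as **not** carried (conservative); the
  `missing_as_present` switch flips this.
- Population frequency is aggregated as the **maximum** over the available
  databases (ESP, ExAC, gnomAD), compared strictly (`< 0.01` by default).
  A variant absent from every database is treated as unobserved and kept.
- SNV/indel classification is by allele length (both alleles single-base =
  SNV), since funnels conventionally report the two counts separately.

### Somatic second hit

"Somatic alteration" means either a deletion segment overlapping the gene by
at least one base (1-based inclusive intervals; adjacency is not overlap) or
a somatic small variant that passes the same PASS/impact/rarity operators as
the germline funnel. By default evidence is required in **every** affected
tumor (`require_all_tumors`), which is the stringent reading of a shared
predisposition; the switch admits any-tumor evidence.

Impact triage removes a candidate only when all three benign signals concur —
PolyPhen benign AND SIFT tolerated AND CADD below 10 (Phred scale,
configurable). Missing scores never count against a candidate, and truncating
classes (nonsense, frameshift, stop-lost) are never triaged out: predicted
benignness of a truncation is not credible evidence.

### Phase-block stitching and the LOH call

Linked-read phasing yields blocks whose two haplotype labels are arbitrary
per block (a gauge). Inside a hemizygous deletion the deleted haplotype
retains a fraction `1 − d` of its barcode rate, so each block's counts
(n₁, n₂) are informative about which *local* label is on the deleted
chromosome. The stitcher:

1. computes an exact two-sided binomial p per block (success probability ½,
   minimum-likelihood two-sided rule — the sum of point probabilities no
   larger than the observed one);
2. decides whether the region shows imbalance at all by **Fisher's
   combination** of the per-block p-values of blocks with at least
   `min_total_count` (default 10) barcodes. This statistic is invariant under
   any per-block label swap and involves no block selection, so its null
   calibration is nominal — in fact conservative, because exact binomial
   p-values are discrete. A naive "pool whichever blocks look significant"
   rule is anticonservative under the null (any one lucky block would drive
   the pooled call) and is deliberately not used;
3. if the combined test clears `alpha` (default 0.05), orients each
   individually significant block so that its depleted local haplotype maps
   to global haplotype B, sums the oriented counts, and reports one more
   exact binomial test on the pooled counts as the extended haplotype's
   p-value. Haplotype B is called deleted when that pooled p also clears
   `alpha`; otherwise the region is `indeterminate`.

Measured operating characteristics (recomputed by `scripts/acceptance.py`):
with `d = 0.6` and a pooled expectation of ≥ 200 barcodes per haplotype the
deleted haplotype is recovered in ≈ 100% of seeded simulations; with `d = 0`
the call is indeterminate in ≈ 96–97% of simulations at `alpha = 0.05`.

The candidate allele's fate follows by mapping its phased local haplotype
index through its block's orientation bit: on the retained haplotype →
`wildtype_lost` (true LOH; the mutant copy is what remains), on the deleted
haplotype → `mutant_lost` (the gene is eliminated as a suppressor candidate).
Unphased candidates, unoriented blocks and indeterminate regions all yield
`indeterminate` with a reason code. Orientation is driven only by blocks
overlapping the queried deletion; propagating orientation across an entire
chromosome arm is out of scope.

### Pedigree segregation

The reference sibling's candidate-bearing haplotype is the allele vector of
the phase set containing the candidate, restricted to a window (default
0.8 Mb) around it. Because labels are a per-block gauge, a sibling's
similarity is computed per phase set: within each of the sibling's phase
sets the orientation maximising matches is taken, homozygous sites contribute
directly (both of a homozygote's haplotypes are known), and unphased or
missing sites are skipped. Similarity is pooled matches over pooled
comparable sites; a sibling is a carrier of the haplotype at
`similarity ≥ 0.95` with ≥ 20 comparable sites (both configurable), and
siblings below the site minimum are excluded from the verdict with a
warning rather than guessed. Unaffected carriers are reported, never
penalised. A genotype cross-check compares haplotype-based carrier calls
with direct carriage of the candidate and lists discordances (possible with
a crossover between the candidate and the window edge).

### Association statistics

The 2×2 allelic table uses the cross-product odds ratio with a Woolf
(log-normal) 95% CI; a zero cell triggers the Haldane–Anscombe +0.5
correction (flagged) unless continuity is off, in which case undefined ORs
raise. Exact p-values are Fisher's two-sided test; the logistic route (GLM
with binomial family and frequency weights, converged to |Δℓ| < 10⁻¹⁰)
exists because for a single binary predictor its fitted OR must equal the
cross-product OR — an identity the tests assert to 10⁻⁶, which guards both
routes. The phenotype screen reports every phenotype, flags `p < 0.05`, and
adds a Bonferroni column for information only; no correction is applied to
the flagging rule, matching the nominal-threshold reporting convention. No
covariates, relatedness adjustment or genomic control are modelled: the
population-scale machinery (imputation, long-range phasing, genealogy
propagation) is out of scope, and printed cohort-scale effect sizes are not
reproduction targets at desk scale.

## The synthetic cohort generator

The generator emulates the *statistical structure* of the motivating study,
not its sequences:

- **One linear region** (default 5 Mb, `chr3`) stands in for the genome, with
  gene models of 30 kb every 100 kb. Multi-region support would be a config
  list; desk scale does not need it.
- **Transmission**: two parents with haplotypes (F1, F2) and (M1, M2); each
  sibling's two chromosomes are mosaics with Poisson(0.05) crossovers per
  meiosis. Penetrance is modelled by explicit carrier/affected counts
  (4 affected + 2 unaffected carriers of 8 by default) rather than a
  probability, so the default cohort reproduces the pedigree exactly. The
  causal carrier set is made exact by choosing each sibling's paternal label
  orientation at the causal locus — a label choice within the Mendelian
  model, not a distortion of the crossover process.
- **Causal gene**: a nonsense allele at population AF 0.001 on F1, centered
  near 3.0 Mb; every affected tumor carries a 2 Mb deletion centered on the
  gene removing the maternal (wildtype) chromosome. The deletion-to-region
  ratio (~0.4) mirrors the arm-scale deletions such studies observe.
- **Decoys**: three germline-only genes (pass the funnel, no somatic
  evidence), three somatic-only genes (somatic hits, no qualifying germline
  variant), and one mutant-deleted gene (germline hit plus deletions in all
  tumors — but the deletion removes the mutant-carrying chromosome, so its
  truthful LOH call is `mutant_lost`). Germline decoys are planted on a
  parental haplotype shared by all affected siblings at the decoy locus.
  Planted genes are kept free of background variants: a random background
  variant inside a decoy gene can create a second, genuine two-hit
  configuration that would invalidate the decoy's truth label.
- **Background**: 2,000 variants with AF ~ Beta(0.5, 5), an exome-like
  consequence-class mix, 5% non-PASS records, indel alleles for indel
  classes, and plausible CADD/PolyPhen/SIFT annotations. Parental carriage
  is drawn conditional on at least one carrier haplotype so every record
  segregates.
- **Phase blocks**: per-sample exponential partition (mean 250 kb) of the
  region; barcode counts are Poisson with 8 expected barcodes per haplotype
  per 100 kb — the count model is a modelling choice, as linked-read
  pipelines do not publish one. Tumor blocks share the individual's partition
  and gauge (same library), with the deleted chromosome's rate scaled by
  `1 − d` over the deleted fraction of each block. Local labels are
  randomised per block, forcing every consumer to solve the gauge.

What the generator does **not** model — read-level noise, genotyping error,
tumor purity and subclonality beyond the single depletion factor `d`,
population LD structure — bounds what the passing tests show: they validate
the *logic* of the pipeline (filter algebra, intersection, gauge-invariant
stitching, calibration of the exact tests) under clean Mendelian data, not
robustness to caller artifacts.

## Numerical and degenerate-input choices

- Exact binomial and Fisher tests come from scipy (`binomtest`,
  `fisher_exact`); the test suite re-derives both by enumeration as
  independent oracles. Zero-count blocks give p = 1 with a tie flag.
- Coordinates are 1-based inclusive internally (VCF convention); BED is
  converted at the I/O boundary, and boundary cases (first/last base) are
  tested. Multi-allelic VCF records are split into biallelic records with
  per-allele (`Number=A`) annotations; unknown INFO keys warn and are
  ignored.
- VCF `PS` tags are integers; block ids are rendered as
  `{sample}_B{PS:04d}` so germline phase sets align with barcode-TSV block
  ids.
- Reports are plain JSON (`report_version: 1`) with sorted keys and no
  timestamps, so identical inputs and seed give byte-identical reruns.
- All randomness flows through `numpy.random.default_rng` seeded from the
  cohort seed (with fixed stream offsets for the generator's independent
  stages), giving byte-identical outputs for identical configurations.

## Problem sizes

The bundled acceptance computation uses 50 default cohorts for the
truth-recovery sweep and 1,000 simulated deletion regions each for the
stitcher's power and null calibration; the test suite uses 200-seed versions
of the same simulations. These sizes give sub-percent Monte-Carlo error on
the reported rates while keeping a full run in tens of seconds on one CPU.

## Known limitations

- The segregation similarity rule (per-phase-set best orientation) can
  overstate similarity for very short phase sets; the ≥ 20 comparable-site
  minimum is the guard, and short-set siblings are reported indeterminate.
- The wildtype-lost gene set on a default cohort contains the causal gene
  but also neighbouring genes inside the same deletion that carry their own
  shared rare variants — exactly the haplotype-hitchhiking ambiguity real
  studies resolve with functional follow-up.
- With extreme depletion and tiny blocks, orientation can fail everywhere
  while the combined test is significant; the result is deliberately
  `indeterminate` rather than an unoriented guess.
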