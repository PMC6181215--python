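# skimqtl

Bin mapping, QTL scanning and GWAS for skim-sequenced recombinant inbred
line (RIL) populations.

Low-coverage ("skim", ~0.3×) whole-genome resequencing of a biparental RIL
population yields sparse, noisy parent-coded SNP calls. `skimqtl`
implements the downstream analysis as a tested pipeline:

- **popsim** — synthetic-data generator: explicit single-seed-descent
  pedigree simulation (Poisson crossovers, no interference) with true
  breakpoints retained for oracle testing, a call-level skim observation
  model (missingness + genotyping error), and balanced multi-environment
  phenotypes with planted additive QTL, pleiotropic loci, G×E variance and
  a fully penetrant Mendelian binary trait.
- **genotypes** — MAF/line-missingness filtering, 18-call sliding-window
  genotype calling (≥12 calls from one parent ⇒ homozygous), breakpoint
  detection with raw-call refinement of each transition interval, and
  population-level bin construction on a 100-kb grid (intervals without
  recombination in the whole population are merged into bins; one marker
  per bin, `bin_<chrom>_<start>`).
- **linkmap** — recombination fractions for selfed RILs
  (r = R/(2−2R)), Kosambi/Haldane map functions, and sum-of-adjacent-rf
  (SARF) ripple verification of the physical marker order.
- **qtlscan** — Haley–Knott interval mapping and composite interval
  mapping with forward-selected cofactors, genome-wide permutation LOD
  thresholds, additive effects/PVE, joint multi-QTL PVE, and a two-locus
  interaction (epistasis) regression.
- **gwas** — VanRaden kinship, PCA covariates, EMMAX-style mixed-linear-
  model association with Bonferroni thresholds.
- **quantstats** — balanced-design ANOVA variance components
  (environments fixed; genotype and G×E random), entry-mean broad-sense
  heritability H² = s²g/[s²g + s²ge/e + s²/(re)], phenotypic and genetic
  correlations, and a two-platform agreement utility.
- **haplotypes** — hierarchical clustering of a genomic region
  (normalised Hamming distance, average linkage) with per-cluster trait
  summaries, ANOVA and pairwise Welch t-tests.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end acceptance criteria
(breakpoint-oracle equivalence, skim-condition recovery, bin-construction
oracle, LOD regression oracle, permutation calibration, pleiotropic-QTL
recovery, heritability round-trip, GWAS reductions, Kosambi closed form,
haplotype recovery).

The acceptance report script exercises the whole pipeline on a simulated
population and writes the (empty — see below) target report:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

There are no fixed numeric targets: bin counts, LOD scores and map lengths
are all functions of the input data, so acceptance is property-based.

## CLI

```sh
skimqtl simulate --config scenario.json --seed 1 --out sim/
skimqtl binmap   --vcf sim/genotypes.vcf --window 18 --hom-min 12 \
                 --interval-kb 100 --chrom-lengths sim/chrom_lengths.json --out bins/
skimqtl map      --markers bins/bin_markers.tsv --out map.tsv
skimqtl scan     --markers bins/bin_markers.tsv --pheno sim/phenotypes.tsv \
                 --n-perm 1000 --seed 7 --out scan/
skimqtl gwas     --vcf sim/genotypes.vcf --pheno sim/phenotypes.tsv \
                 --trait Pro --pcs 3 --out gwas/
skimqtl stats    --pheno sim/phenotypes.tsv --out stats/
skimqtl haplo    --vcf sim/genotypes.vcf --region 20:32500000-34100000 --k 2 \
                 --pheno sim/phenotypes.tsv --trait Pro --out haplo/
```

A scenario JSON lists chromosomes (name, length_bp, length_cm and either
`n_snps` or explicit `snp_positions`), pedigree (`n_lines`, `generation`),
the observation model (`observation_rate`, `error_rate`), and traits
(planted QTL as `[chrom, bp, additive_effect]`, variance components,
`n_environments`, `n_replicates`, optional `mendelian_locus`). See
`tests/test_io_cli.py` for a worked example.

## Conventions

- Genotype codes: A (first parent) / B (second parent); het and
  undetermined calls are treated as missing by the RIL pipeline.
- Additive coding: A homozygote −1, B homozygote +1; a positive additive
  effect means the B allele increases the trait.
- Coordinates: 1-based bp in VCF/TSV, 0-based half-open in BED.
- Window calling slides over observed (non-missing) calls only.
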