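# panelgwas

Statistical machinery for comparing GWAS results across genotype-imputation
reference panels and for characterizing founder-population allele-frequency
enrichment — exercised end-to-end on synthetic cohorts with known ground
truth.

## What's inside

| Module | Purpose |
| --- | --- |
| `panelgwas.synth` | Synthetic diploid cohorts (Hardy–Weinberg genotypes, planted causal effects), imputed panels with AF-dependent quality and panel-specific variant dropout, reference-population AFs with planted fold enrichment, coalescent-style genealogies carrying a single-origin mutation, multi-array genotype batches, SV callsets with planted near-duplicates. Every generator is deterministic under a seed and records its ground truth. |
| `panelgwas.assoc` | Rank-inverse-normal transform, covariate-adjusted OLS association (single-variant and vectorized scan), forward stepwise conditional analysis for index-variant selection. |
| `panelgwas.loci` | MAC/INFO filtering (strict `MAC > 20`, `INFO > 0.3` boundaries) and window-merge calling of independent genome-wide-significant loci (±500 kb windows, overlapping/adjacent windows merged transitively, lead = lowest P). |
| `panelgwas.compare` | Cross-approach locus matching into a Venn partition (≥1 bp overlap, transitive closure), per-subset lead-variant summaries, per-individual variant recovery/concordance between panels, relative recovery ratios for enriched variants. |
| `panelgwas.permute` | AF-stratified permutation tests: median paired imputation-quality difference (two-tailed, null-median centered) and fold-change of lead-variant proportions (one-tailed), both with add-one correction and bootstrap CIs. |
| `panelgwas.enrich` | Fold enrichment (cohort MAF ≥ 0.1% and cohort/reference ratio ≥ 4), Fisher exact odds ratios (+0.5 zero-cell correction), variant-prioritization rule chain (ClinVar/pLoF, MAF ≤ 1%, CADD ≥ 15 or SpliceAI ≥ 0.8), MRCA-based carrier inference on genealogies, per-region carrier-frequency bootstrap CIs. |
| `panelgwas.qc` | Array batch-effect Gaussian LRT (`G ~ 1 + PC1..PC4 + array` vs reduced; chi-square with `n_arrays − 1` df, Bonferroni filter) and SV near-duplicate deduplication (≤100 bp breakpoint windows, equal-AC → drop shorter, <1% AC/AF difference → drop lower AC). |

## CLI

Installed as `panelgwas`:

```bash
panelgwas simulate --config config.yaml --out-dir out/ --genealogy-leaves 64 --sv-count 200
panelgwas assoc --dosages out/dosages.tsv --pheno out/phenotype.tsv --out stats.tsv
panelgwas call-loci --stats stats.tsv --out-bed loci.bed --out-json loci.json
panelgwas compare --loci-json local.json --loci-json global.json --loci-json meta.json \
    --out-partition partition.tsv
panelgwas permute --leads leads.tsv --pool pool.tsv --out perm.json --n-perm 10000 --seed 1
panelgwas enrich --annot annot.tsv --out enriched.tsv
panelgwas carriers --newick out/genealogy.nwk --known L3,L17 --out carriers.json
panelgwas qc-batch --genotypes batches.tsv --out lrt.tsv
panelgwas qc-svdedup --svs out/svs.tsv --out-kept kept.tsv --out-removed removed.tsv
```

A minimal `config.yaml`:

```yaml
n_individuals: 2000
n_variants: 500
seed: 7
n_causal: 2
effect_sizes: [0.3, 0.3]
```

## Notes and deliberate simplifications

- Association testing is plain OLS: synthetic cohorts contain unrelated
  individuals, so no polygenic/LOCO predictor is needed.
- The meta panel copies, per variant, the member panel with the higher
  imputation quality (ties favor the local panel) rather than performing
  weighted meta-imputation.
- Genealogies are simple binary coalescent-style trees; no recombination,
  demography, or ARG inference.
- PC covariate surrogates are standard normals independent of genotype.
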