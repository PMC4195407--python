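# rhm — regional heritability mapping

`rhm` is a toolkit for mapping quantitative trait loci (QTL) by **regional
heritability mapping**: instead of testing SNPs one at a time, it slides a
window of adjacent SNPs along the genome and asks how much phenotypic
variance the window explains jointly.  For each window it fits the mixed
model

    y = 1μ + u_q + u_g + e,   u_q ~ N(0, σ²_q Q),  u_g ~ N(0, σ²_g G),  e ~ N(0, σ²_e I)

with `Q` the genomic relationship matrix (GRM) of the window's SNPs and
`G` the whole-genome GRM, estimates the regional heritability
h²_reg = σ²_q/(σ²_q+σ²_g+σ²_e) by AI-REML, and tests the window with a
likelihood-ratio test whose null is the boundary mixture ½δ₀ + ½χ²₁.
Bonferroni thresholds come from N = m/w effective tests; for a
10,000-SNP genome the genome-wide/suggestive LRT thresholds are
10.83/6.64, 12.12/7.88 and 13.83/9.55 at window sizes 100, 50 and 20.
Window regions that individually carry several weak alleles — invisible
to single-SNP association — can reach significance this way, which is
the method's point.

The package is aimed at quantitative/statistical geneticists working
with dense SNP panels in structured (e.g. livestock) populations.  It
also provides: pedigree relationship matrices (tabular method),
bivariate REML genetic correlations, regional-EBV pleiotropy screening,
a joint all-regions variance partition, the GRAMMAR two-step
association comparator, and a synthetic-data generator that emulates
the 16th QTL-MAS workshop benchmark (3,000 individuals, 5 × 99.95 Mb
chromosomes, ~10,000 SNPs, three correlated milk-type traits) so every
stage is testable without external downloads.

## Worked example

```python
import numpy as np
from rhm import (SimConfig, QtlEffect, simulate_dataset, compute_grm,
                 run_scan, call_qtl)

qtl = [QtlEffect(1, 40_000_000, (0.40, 0.30, 0.0)),
       QtlEffect(2, 60_000_000, (0.0, 0.20, -0.30))]
cfg = SimConfig(n_founders=100, n_generations=3, n_chromosomes=2,
                n_snps_per_chrom=150, qtl_spec=qtl, seed=3)
ped, genotypes, marker_map, phenotypes, truth = simulate_dataset(cfg)

result = run_scan(genotypes, marker_map, phenotypes, "trait1", w=20, s=10)
print(result.table.sort_values("lrt", ascending=False)
      [["chromosome", "region_index", "bp_start", "lrt", "h2_reg", "level"]].head(3))
for c in call_qtl(result):
    print(c.chromosome, c.bp_start, c.bp_end, round(c.peak_lrt, 2), c.level)
```

Output:

```
   chromosome  region_index  bp_start       lrt    h2_reg       level
4           1             5  27319667  6.783500  0.129991  suggestive
3           1             4  20656333  2.214880  0.045905        none
5           1             6  33983000  1.486808  0.053304        none
1 27319667 39980000 6.78 suggestive
```

The peak window (chromosome 1, region 5, LRT 6.78 ≥ the suggestive
threshold for this 300-SNP genome) spans 27.3–40.0 Mb and contains the
planted 40-Mb QTL; its regional heritability estimate is 0.13.  At this
toy size (300 individuals) only the larger QTL is detectable — power
grows with n, as the full-size test suite verifies.

The same pipeline is scriptable from the shell:

```sh
rhm simulate --seed 1 --out data/
rhm scan --ped data/sim.ped --map data/sim.map --pheno data/sim.pheno.tsv \
         --trait trait1 --window 20 --step 10 --out results/
rhm thresholds --m-snps 10000 --window 20
```

Every command writes TSV tables plus a JSON manifest (inputs,
parameters, seed, thresholds) from which its outputs can be reproduced.

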