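# popexpr

Population transcriptome expression-variation analysis for common-garden
transplant designs.

When a set of natural plant populations is grown in two contrasting field
environments — one near the native habitat, one harsh — per-individual
RNA-seq lets you ask what drives gene-expression variation at the
population level: the environment, the source population, the genotype
(haplotype) an individual carries, or their interaction. `popexpr`
implements that analysis as a tested, reusable pipeline:

* **Population expression level** `E_p` — per gene and environment, the
  arithmetic mean FPKM over the n individuals sampled there.
* **Population expression diversity** `E_d` — a bounded index of how
  unevenly total expression is shared among individuals,
  `E_d = 1 − H/ln n` with `H = −Σ p_i ln p_i`, `p_i = E_i / Σ E_i`
  (0 = perfectly even, → 1 as one individual dominates). Gini–Simpson and
  CV-based alternates are available.
* **Cross-environment change** — the `E_p` ratio (transplant / native)
  and the `E_d` change (transplant − native), with genes classed as
  conserved when the ratio lies in [0.5, 2] and the change in
  [−0.25, 0.25] (boundaries inclusive), and the 3 × 3 cross of those
  labels forming a nine-group classification.
* **Nucleotide diversity** π per gene from transcript SNPs, after
  filtering (keep a SNP iff quality > 10, missing fraction < 10 %, minor
  allele frequency > 0.05):
  `π = (1/L) Σ_j (m_j/(m_j−1)) · 2 p̂_j (1−p̂_j)` over the surviving
  sites, where L is the transcript length and p̂_j the allele frequency
  among the m_j non-missing alleles at site j.
* **Haplotype phasing** for genes with fewer than 10 SNPs via the
  Excoffier–Slatkin EM algorithm over pooled individuals, assigning each
  individual its maximum-posterior ("best guess") haplotype pair.
  Externally phased reconstructions (PHASE-style TSV) are accepted as a
  drop-in alternative.
* **Two-way fixed-effect ANOVA** per gene on log2(FPKM + 1) — environment
  × population on all genes and environment × diplotype on the phased
  genes — with Type II sums of squares, Storey's positive-FDR q-values
  (Benjamini–Hochberg optional), Wilcoxon rank-sum comparisons between
  equal-count gene bins, and an eight-group classification by which of
  the environment / haplotype / interaction effects are significant.

Because the original field data are not needed to validate the methods,
the package ships a first-class synthetic-data generator that reproduces
the study design (14 populations × 2 environments × 3 clonally
transplanted individuals per population, biallelic SNPs under
Hardy–Weinberg equilibrium, planted effects on configurable gene
fractions) together with the ground truth of every planted effect, so
every stage is verifiable end to end.

## Worked example

```python
from popexpr import SimulationConfig, simulate_dataset, gene_stats_table, fit_all_genes
from popexpr.expression_stats import correlate_ep

cfg = SimulationConfig(n_genes=1000, seed=42)      # defaults mirror the study design
matrix, meta, snp_tables, truth = simulate_dataset(cfg)

stats = gene_stats_table(matrix, meta)
r, p = correlate_ep(stats["Ep_native"].to_numpy(), stats["Ep_new"].to_numpy())
print(f"E_p correlation between gardens: r = {r:.3f}")

effects = fit_all_genes(matrix, meta, model="pop_env")
env = effects[effects["term"] == "factorA"]
print(f"genes with environment effect (q < 0.05): {env['significant'].sum()} "
      f"({env['significant'].mean():.1%})")
```

prints

```
E_p correlation between gardens: r = 0.870
genes with environment effect (q < 0.05): 173 (17.3%)
```

The correlation says mean expression levels are strongly preserved across
gardens even though individual genes shift; 154 of the 1000 genes carry a
planted 2-SD environment effect (the default fraction is 15.4 %), and the
ANOVA recovers essentially all of them plus the expected share of
false positives at q < 0.05.

The same analysis is available from the shell:

```bash
popexpr simulate --n-genes 1000 --seed 42 --outdir data/
popexpr stats --expression data/expression.tsv --metadata data/metadata.tsv \
    --native-env native --out stats.tsv
popexpr run-all --config config.yaml      # full pipeline from a YAML config
```

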