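# Methods

This note documents the statistical model behind each stage of `popexpr`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions a maintainer
should know about.

## Study design and data model

The pipeline targets a reciprocal common-garden transplant: individuals
from several natural populations are grown simultaneously in two field
environments, one designated *native* (the denominator of all
cross-environment ratios) and one *transplant*. Each individual is
clonally replicated, so the same genotype is expressed in both gardens;
expression differences between the gardens therefore reflect environment
and genotype-by-environment effects rather than genetic turnover between
sites. Inputs are a genes × individuals FPKM matrix (TSV), per-sample
population/environment metadata (TSV), transcript SNP genotypes (VCF with
CHROM = transcript ID, 1-based positions), and optionally externally
phased haplotypes.

Genes enter the analysis only if expressed (FPKM > 0) in at least half
the individuals of *each* environment (`ceil(n_env / 2)`, so "exactly
half" passes).

## Expression statistics

For a gene's FPKM values E_1..E_n in one environment:

* `E_p = mean(E_i)` — the population expression level. The arithmetic
  mean is used because E_p aggregates individual FPKM into a single
  population abundance; it preserves additivity when comparing
  environments.
* `E_d = 1 − H / ln n`, with H the Shannon entropy of the shares
  `p_i = E_i / ΣE`. The index is 0 when all individuals express equally
  and approaches 1 when a single individual carries all expression. A
  bounded index is required because the conservation band for E_d change
  is an absolute ±0.25; an entropy-based evenness index additionally
  increases with the spread of expression across the population, which is
  the property the diversity analyses rely on. Gini–Simpson
  (`1 − (1 − Σp_i²)/(1 − 1/n)`) and a rescaled coefficient of variation
  (`cv/(cv+1)`) are provided as alternates; the metric used is recorded
  in every output header.
* The `E_p` ratio is transplant/native; genes with native `E_p = 0` have
  an undefined ratio and are excluded from ratio-based analyses but kept
  elsewhere. Conservation bands are `0.5 ≤ ratio ≤ 2` and
  `−0.25 ≤ ΔE_d ≤ 0.25`, with **inclusive** boundaries (a deliberate
  convention, applied consistently and tested on the boundary grid).
  The 3 × 3 cross of {down, conserved, up} × {shrunk, conserved,
  enlarged} yields the nine-group classification.

Equal-count binning (quintiles of E_p, quartiles of π by default) is
rank-based with stable tie-breaking; when n is not divisible by k the
lower bins take the extra genes. Labels are therefore invariant under any
strictly monotone transform of the binned statistic, and deterministic.
Bin contrasts use the Mann–Whitney rank-sum test: exact enumeration when
the pooled sample is ≤ 12 and tie-free, otherwise the normal
approximation with tie and continuity corrections (scipy's
implementation, checked against a full-permutation oracle in the tests).

## Nucleotide diversity

SNPs are kept iff quality > 10 AND missing fraction < 0.10 AND minor
allele frequency > 0.05, each computed over the sample group being
analysed; boundary values (quality = 10, missing = 10 %, MAF = 0.05) are
excluded. Missingness is computed as an exact count ratio to avoid
floating-point drift at the 10 % boundary. By default the filter and π
are evaluated per environment (diversity is reported separately in each
garden); a joint-filter switch is provided because it is equally
defensible to filter once across all individuals.

Per gene, π is the per-site unbiased expected heterozygosity summed over
surviving SNP sites and divided by transcript length L:

    π = (1/L) Σ_j (m_j/(m_j−1)) · 2 p̂_j (1−p̂_j)

with p̂_j the non-reference allele frequency among the m_j non-missing
alleles at site j. This equals the average pairwise allele difference
over all sampled allele pairs (asserted against a brute-force pairwise
oracle), and dividing by full transcript length puts values in the
10⁻⁶–10⁻³ range typical of plant transcriptome cohorts. Sites with fewer
than two non-missing alleles contribute zero; genes with no surviving
SNPs have π = 0 and are analysed as the "without SNP" class. L is a
required input because "gene length" could equally be assembled
transcript length or covered length; the choice is the caller's.

The genotype model is diploid throughout; for paleo-polyploid genomes the
input VCF's ploidy convention is taken at face value. This is a known
limitation.

## Haplotype phasing

Genes with 1–9 post-filter SNPs are phased (more SNPs make
frequency-based phasing unreliable at n = 80). All individuals from both
gardens are pooled — the two garden samples of one individual are clones,
so pooling doubles nothing but the evidence per genotype. The phaser is
the Excoffier–Slatkin EM algorithm on haplotype frequencies under
Hardy–Weinberg equilibrium: the E-step distributes each multi-site
genotype over its compatible haplotype pairs in proportion to
`c·f_a·f_b` (c = 2 for heterozygous pairs), the M-step re-estimates
frequencies from expected counts. Missing genotypes are marginalised over
both alleles. Convergence: max frequency change < 1e-8 or 500
iterations; the log-likelihood is asserted non-decreasing every
iteration. The best of `n_restarts` runs (uniform start plus random
Dirichlet starts) is kept, and each individual receives its
maximum-posterior compatible pair, ties broken lexicographically.

This is a deliberate substitution for coalescent-prior phasing software:
the downstream ANOVA needs only best-guess diplotype labels, and the EM
estimate is the maximum-likelihood solution for unrelated individuals.
Users wanting coalescent-aware reconstructions can supply them as a
PHASE-style TSV through the io module. The EM implementation is verified
against an independent direct-search ML oracle (simplex grid scan plus
multistart Nelder–Mead in softmax coordinates) on small instances.

The ANOVA "haplotype" factor is the diplotype label (unordered haplotype
pair). Labels carried by fewer than 2 individuals are merged into a
single "rare" level to keep the model estimable; genes whose factor then
has fewer than 2 levels are dropped from the haplotype ANOVA. Coding
haplotype dosage per individual instead of the diplotype label would be a
reasonable alternative; the label was chosen because it makes no
additivity assumption.

## Effect models

Per gene, expression is modelled as a fixed-effect two-way layout with
interaction — environment × population on all genes, environment ×
diplotype on the phased genes — on the response log2(FPKM + 1). The log
response stabilises the strong mean–variance coupling of FPKM; a raw
scale switch exists. Sums of squares are Type II, computed as residual
sum-of-squares differences between nested models via precomputed
orthonormal design bases (a single set of projections serves every gene
that shares a factor layout, making the 2,000-gene fits a few matrix
products). Type II reduces to the classical balanced decomposition and is
order-invariant under the mild unbalance that dropped individuals cause;
agreement with statsmodels' `anova_lm(typ=2)` is asserted in the tests on
balanced and unbalanced designs. Degenerate fits (zero residual variance)
report p = 0 for terms with positive SS, p = NaN for constant responses,
and carry a flag; designs with an empty factor-level cell drop the
interaction term with a flag.

Per-term p-values are pooled across genes and converted to q-values with
Storey's positive-FDR estimator (fixed λ = 0.5, π̂₀ clipped to
[1/m, 1]); Benjamini–Hochberg is the π₀ = 1 special case and is checked
against statsmodels. Significance flags use q < α (default 0.05), with a
raw-p switch because per-gene "P < 0.05" summaries are also conventional
for this analysis. The eight-group classification labels each phased gene
with the subset of {E, H, H×E} effects that are significant.

## Synthetic data

The generator emulates the study design, not any particular dataset.
Defaults: 14 populations × 3 individuals × 2 environments (84 samples;
optional dropout of 2 individuals per garden reproduces the 40+40
unbalanced variant), gene baselines μ_g ~ Normal(3.0, 1.5) on the ln-FPKM
scale (median FPKM ≈ 20, spanning ~4 orders of magnitude), residual SD
0.5 ln-units, and planted effects on deterministic gene counts
(`round(frac · n_genes)`): environment 15.4 %, population 3.0 %,
interaction 2.6 %, haplotype effects on 19.9 % of genes (necessarily
within the 47 % of genes that carry SNPs). These fractions mirror the
significant-effect rates the analysis typically reports for this design,
so that recovery experiments run at realistic signal density. Effect
magnitudes default to 2 residual SD with random sign; an absolute
ln-scale override exists so zero-noise sanity checks can plant exact
fold-changes.

Expression is generated as `log FPKM = μ_g + β_E·env + u_pop + h·dose +
γ·(env × dose or env × pop) + ε`, i.e. effects are multiplicative on the
FPKM scale: a planted β_E = ln 2 makes the true E_p ratio exactly 2 in
the zero-noise limit, aligning planted effects with the conservation
band. Simulated FPKM is therefore strictly positive; optional per-cell
zero-inflation (`frac_expression_dropout`) supplies the zeros the
expression filter exists for. Genotypes come from a per-gene pool of 2–4
haplotypes (frequencies Dirichlet-drawn, per-site MAF kept inside the
configured range where achievable) with diplotypes drawn under HWE; the
haplotype-effect dose counts copies of the most frequent haplotype. SNP
counts per gene are drawn from a decreasing distribution on 1..9 so all
simulated genes are phaseable.

What the generator does **not** emulate: read-level sampling noise
(FPKM is treated as a continuous measurement, not a count — no negative
binomial overdispersion), linkage between genes, population structure in
allele frequencies (haplotype pools are shared across populations, which
is consistent with the weak-structure regime the design assumes),
expression correlation between genes, and mapping artefacts. Passing
recovery tests therefore demonstrates the statistical machinery is
correct and calibrated under the stated model, not that real RNA-seq
noise matches that model.

## Numerical conventions and determinism

All randomness flows from a single top-level seed; stage seeds are
derived via CRC-based SeedSequence spawning, so identical config + seed
gives byte-identical output bundles (asserted in tests). Output tables
carry a header comment with the tool version and a hash of the producing
configuration (output directory excluded, since where results land must
not change their identity). TSV is tab-separated UTF-8 with '.' decimals
and no quoting; VCF output is minimal uncompressed v4.2 text. Genotype
codes are non-reference allele counts {0, 1, 2} with −1 for missing;
input phase (`0|1` vs `0/1`) is ignored because phasing happens
downstream.

Problem sizes in the test-suite and acceptance computations (2,000-gene
cohorts, 10,000-replicate calibration loops, 80-individual phasing
instances) were chosen as the smallest sizes at which the binomial /
Monte-Carlo error of each checked quantity is comfortably below its
assertion tolerance.

## Known limitations

* Diploid genotype model (see above).
* The EM phaser ignores recombination and mutation structure; for genes
  with many rare haplotypes its best-guess pairs are less reliable than
  coalescent-prior methods, which is why phasing is restricted to
  low-SNP genes and external reconstructions are accepted.
* Storey's π̂₀ uses a single fixed λ rather than the smoother; at very
  small gene counts q-values are conservative.
* FPKM normalisation is taken as given; no attempt is made to correct
  library-composition effects.
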