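"""Synthetic common-garden population-transcriptome datasets.

Emulates the study design the pipeline targets: 14 source populations,
each contributing 3 clonally propagated individuals to two common-garden
environments (the same genotype grown in both gardens), with bulk FPKM
expression per gene and individual plus biallelic transcript SNPs for a
configurable fraction of genes.

Expression is generated on the log scale per gene g and sample i:

    log(FPKM) = mu_g + beta_E * env_i + u_pop(i) + h(diplotype_gi)
                + gamma * (env x hap  or  env x pop) + eps,
    eps ~ Normal(0, residual_log_sd)

so effects are multiplicative on the FPKM scale (a planted beta_E of
ln 2 doubles the true population expression level in the transplant
garden) and simulated FPKM is strictly positive; optional zero-inflation
(``frac_expression_dropout``) emulates undetected transcripts.

Planted effect genes are chosen deterministically as round(frac * n_genes)
random genes per effect; effect magnitudes are expressed in units of the
residual SD.  Genotypes are drawn under Hardy-Weinberg equilibrium from a
per-gene haplotype pool; the two garden samples of one individual share a
genotype (the transplant is clonal).  The ground truth of every planted
effect, haplotype pool and diplotype is returned for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GeneSNPTable, SampleMetadata, ValidationError

#: default distribution of per-gene SNP counts (support 1..9, phasing range)
DEFAULT_SNP_COUNT_PROBS = (0.30, 0.20, 0.14, 0.10, 0.08, 0.06, 0.05, 0.04, 0.03)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the emulated design.

    Fractions of effect-carrying genes default to the significant-gene
    fractions reported for the real cohort (environment 15.4%, population
    3.0%, interaction 2.6%, haplotype 19.9% of phased genes), and roughly
    47% of genes carry SNPs.
    """

    n_genes: int = 500
    n_populations: int = 14
    individuals_per_population_per_env: int = 3
    dropout_per_env: int = 0  # the study discarded 2 individuals per garden
    env_names: tuple[str, str] = ("native", "transplant")  # native first
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.5
    frac_env_effect: float = 0.154
    frac_pop_effect: float = 0.030
    frac_hap_effect: float = 0.199
    frac_interaction: float = 0.026
    effect_size_sd_units: float = 2.0
    effect_size_log: float | None = None  # absolute ln-scale magnitude override
    residual_log_sd: float = 0.5
    frac_expression_dropout: float = 0.0  # per-cell zero-inflation
    frac_genes_with_snps: float = 0.47
    snp_count_probs: tuple[float, ...] = DEFAULT_SNP_COUNT_PROBS
    max_haplotypes: int = 4
    allele_freq_range: tuple[float, float] = (0.1, 0.5)
    gene_length_range: tuple[int, int] = (300, 3000)
    frac_missing_genotypes: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (
            self.frac_env_effect,
            self.frac_pop_effect,
            self.frac_hap_effect,
            self.frac_interaction,
            self.frac_genes_with_snps,
            self.frac_missing_genotypes,
            self.frac_expression_dropout,
        )
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValidationError("all fractions must lie in [0, 1]")
        if self.effect_size_sd_units < 0 or self.residual_log_sd < 0:
            raise ValidationError("effect sizes and residual SD must be >= 0")
        if len(self.snp_count_probs) > 9:
            raise ValidationError("SNP counts must stay below 10 (phasing range)")
        if abs(sum(self.snp_count_probs) - 1.0) > 1e-9:
            raise ValidationError("snp_count_probs must sum to 1")
        if self.frac_hap_effect > self.frac_genes_with_snps + 1e-12:
            raise ValidationError(
                "frac_hap_effect cannot exceed frac_genes_with_snps: "
                "haplotype effects need SNPs"
            )
        if self.n_populations < 2 or self.individuals_per_population_per_env < 1:
            raise ValidationError("design needs >= 2 populations and >= 1 individual")
        lo, hi = self.allele_freq_range
        if not 0 < lo <= hi < 1:
            raise ValidationError("allele_freq_range must satisfy 0 < lo <= hi < 1")


@dataclass
class TruthTable:
    """Ground truth of a simulated dataset.

    ``genes`` has one row per gene: effect flags (consistent with nonzero
    effect sizes), planted effect sizes on the log scale, SNP count and
    gene length.  ``haplotypes`` maps gene -> (haplotype strings, their
    frequencies); ``diplotypes`` maps gene -> {individual: (hap1, hap2)}.
    """

    genes: pd.DataFrame
    haplotypes: dict[str, tuple[list[str], np.ndarray]] = field(default_factory=dict)
    diplotypes: dict[str, dict[str, tuple[str, str]]] = field(default_factory=dict)
    population_effects: dict[str, dict[str, float]] = field(default_factory=dict)


def simulate_genotypes(
    haplotypes: list[str],
    haplotype_freqs: np.ndarray,
    n_individuals: int,
    rng: np.random.Generator | int,
) -> tuple[list[tuple[str, str]], np.ndarray]:
    """Draw diplotypes under HWE and derive the per-site genotype matrix.

    Each individual receives two independent haplotypes from the pool;
    genotype codes are the per-site sums of the two haplotypes' alleles.
    Returns (diplotypes, genotype matrix of shape (n_sites, n_individuals)).
    """
    if len(haplotypes) == 0:
        raise ValidationError("empty haplotype pool")
    freqs = np.asarray(haplotype_freqs, dtype=float)
    if freqs.shape != (len(haplotypes),):
        raise ValidationError("haplotype/frequency length mismatch")
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValidationError(f"haplotype frequencies sum to {freqs.sum()}, not 1")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    n_sites = len(haplotypes[0])
    hap_arr = np.array([[int(c) for c in h] for h in haplotypes])  # (k, s)
    picks = rng.choice(len(haplotypes), size=(n_individuals, 2), p=freqs)
    diplotypes = [
        (haplotypes[a], haplotypes[b]) if haplotypes[a] <= haplotypes[b]
        else (haplotypes[b], haplotypes[a])
        for a, b in picks
    ]
    genotypes = (hap_arr[picks[:, 0]] + hap_arr[picks[:, 1]]).T  # (s, n)
    assert genotypes.shape == (n_sites, n_individuals)
    return diplotypes, genotypes


def _random_haplotype_pool(
    n_sites: int, rng: np.random.Generator, config: SimulationConfig
) -> tuple[list[str], np.ndarray]:
    """A pool of distinct haplotypes whose per-site minor allele
    frequencies land inside ``allele_freq_range`` where achievable."""
    k = int(rng.integers(2, min(config.max_haplotypes, 2**n_sites) + 1))
    lo, hi = config.allele_freq_range
    for _ in range(50):
        haps = set()
        while len(haps) < k:
            haps.add("".join(rng.choice(("0", "1"), size=n_sites)))
        haps = sorted(haps)
        freqs = rng.dirichlet(np.full(k, 2.0))
        hap_arr = np.array([[int(c) for c in h] for h in haps])
        site_p = freqs @ hap_arr
        maf = np.minimum(site_p, 1 - site_p)
        if (maf >= lo).all() and (maf <= hi).all():
            return haps, freqs
    return haps, freqs  # best effort; rare for small n_sites


def _pick_effect_genes(
    rng: np.random.Generator, candidates: np.ndarray, frac: float, n_total: int
) -> np.ndarray:
    """round(frac * n_total) genes chosen uniformly among ``candidates``."""
    n_eff = min(int(round(frac * n_total)), len(candidates))
    return rng.choice(candidates, size=n_eff, replace=False)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleMetadata, dict[str, GeneSNPTable], TruthTable]:
    """Generate one full synthetic dataset; fully reproducible given the seed."""
    rng = np.random.default_rng(config.seed)
    native, transplant = config.env_names
    n_genes = config.n_genes
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]

    # design: individuals (genets) with a clonal ramet in each garden
    individuals, populations = [], []
    for p in range(config.n_populations):
        pop = f"P{p + 1:02d}"
        for i in range(config.individuals_per_population_per_env):
            individuals.append(f"{pop}_i{i + 1}")
            populations.append(pop)
    n_ind = len(individuals)

    meta_rows = []
    for env in (native, transplant):
        for ind, pop in zip(individuals, populations):
            meta_rows.append(
                {"sample_id": f"{ind}_{env}", "individual": ind,
                 "population": pop, "environment": env}
            )
    meta_df = pd.DataFrame(meta_rows)
    if config.dropout_per_env:
        drop_idx = []
        for env in (native, transplant):
            env_rows = meta_df.index[meta_df["environment"] == env].to_numpy()
            drop_idx.extend(rng.choice(env_rows, config.dropout_per_env, replace=False))
        meta_df = meta_df.drop(index=drop_idx).reset_index(drop=True)
    meta = SampleMetadata(table=meta_df, native_env=native)
    sample_ids = meta_df["sample_id"].tolist()
    sample_ind = meta_df["individual"].to_numpy()
    sample_pop = meta_df["population"].to_numpy()
    sample_env = (meta_df["environment"] == transplant).to_numpy(dtype=float)

    # which genes carry SNPs, and how many
    all_genes = np.arange(n_genes)
    snp_gene_idx = np.sort(
        rng.choice(all_genes, int(round(config.frac_genes_with_snps * n_genes)),
                   replace=False)
    )
    snp_gene_set = set(snp_gene_idx.tolist())
    snp_counts = rng.choice(
        np.arange(1, len(config.snp_count_probs) + 1),
        size=len(snp_gene_idx),
        p=np.asarray(config.snp_count_probs),
    )
    gene_lengths = rng.integers(
        config.gene_length_range[0], config.gene_length_range[1] + 1, size=n_genes
    )

    # planted effects (deterministic counts)
    env_genes = set(_pick_effect_genes(rng, all_genes, config.frac_env_effect, n_genes).tolist())
    pop_genes = set(_pick_effect_genes(rng, all_genes, config.frac_pop_effect, n_genes).tolist())
    hap_genes = set(
        _pick_effect_genes(rng, snp_gene_idx, config.frac_hap_effect, n_genes).tolist()
    )
    int_genes = set(
        _pick_effect_genes(rng, all_genes, config.frac_interaction, n_genes).tolist()
    )

    shift = (
        config.effect_size_log
        if config.effect_size_log is not None
        else config.effect_size_sd_units * config.residual_log_sd
    )
    baseline = rng.normal(config.baseline_log_mean, config.baseline_log_sd, n_genes)

    truth_rows = []
    haplotypes: dict[str, tuple[list[str], np.ndarray]] = {}
    diplotypes: dict[str, dict[str, tuple[str, str]]] = {}
    pop_effects: dict[str, dict[str, float]] = {}
    snp_tables: dict[str, GeneSNPTable] = {}
    pop_levels = sorted(set(populations))
    log_expr = np.empty((n_genes, len(sample_ids)))

    snp_count_of = dict(zip(snp_gene_idx.tolist(), snp_counts.tolist()))
    for gi, gene_id in enumerate(gene_ids):
        x = np.full(len(sample_ids), baseline[gi])
        beta_env = 0.0
        if gi in env_genes:
            beta_env = shift * rng.choice((-1.0, 1.0))
            x += beta_env * sample_env
        if gi in pop_genes:
            offsets = dict(zip(pop_levels, rng.normal(0.0, shift, len(pop_levels))))
            pop_effects[gene_id] = offsets
            x += np.array([offsets[p] for p in sample_pop])

        dose = np.zeros(len(sample_ids))
        hap_effect = 0.0
        if gi in snp_gene_set:
            n_sites = snp_count_of[gi]
            haps, freqs = _random_haplotype_pool(n_sites, rng, config)
            ind_dips, ind_geno = simulate_genotypes(haps, freqs, n_ind, rng)
            dip_of = dict(zip(individuals, ind_dips))
            haplotypes[gene_id] = (haps, freqs)
            diplotypes[gene_id] = dip_of
            # focal haplotype = most frequent; dose = copies carried
            focal = haps[int(np.argmax(freqs))]
            ind_dose = {
                ind: (d[0] == focal) + (d[1] == focal) for ind, d in dip_of.items()
            }
            dose = np.array([ind_dose[ind] for ind in sample_ind], dtype=float)
            if gi in hap_genes:
                hap_effect = shift * rng.choice((-1.0, 1.0))
                x += hap_effect * dose

            # genotype matrix indexed by genet; ramets share the genotype
            ind_index = {ind: j for j, ind in enumerate(individuals)}
            geno_samples = ind_geno[:, [ind_index[i] for i in sample_ind]]
            if config.frac_missing_genotypes > 0:
                miss = rng.random(geno_samples.shape) < config.frac_missing_genotypes
                geno_samples = np.where(miss, -1, geno_samples)
            length = int(gene_lengths[gi])
            positions = np.sort(
                rng.choice(np.arange(1, length + 1), n_sites, replace=False)
            )
            snp_tables[gene_id] = GeneSNPTable(
                gene_id=gene_id,
                gene_length=length,
                positions=positions,
                quality=rng.uniform(30.0, 60.0, n_sites),
                genotypes=geno_samples,
                sample_ids=sample_ids,
            )

        interaction = 0.0
        interaction_type = ""
        if gi in int_genes:
            interaction = shift * rng.choice((-1.0, 1.0))
            if gi in snp_gene_set:
                interaction_type = "env_x_hap"
                x += interaction * dose * sample_env
            else:
                interaction_type = "env_x_pop"
                offsets = dict(zip(pop_levels, rng.normal(0.0, shift, len(pop_levels))))
                pop_effects.setdefault(gene_id, {})
                x += np.array([offsets[p] for p in sample_pop]) * sample_env

        if config.residual_log_sd > 0:
            x += rng.normal(0.0, config.residual_log_sd, len(sample_ids))
        log_expr[gi] = x
        truth_rows.append(
            {
                "gene_id": gene_id,
                "has_env_effect": gi in env_genes,
                "has_pop_effect": gi in pop_genes,
                "has_hap_effect": gi in hap_genes,
                "has_interaction": gi in int_genes,
                "env_effect": beta_env,
                "hap_effect": hap_effect,
                "interaction_effect": interaction,
                "interaction_type": interaction_type,
                "n_snps": snp_count_of.get(gi, 0),
                "gene_length": int(gene_lengths[gi]),
            }
        )

    fpkm = np.exp(log_expr)
    if config.frac_expression_dropout > 0:
        fpkm = np.where(
            rng.random(fpkm.shape) < config.frac_expression_dropout, 0.0, fpkm
        )
    matrix = ExpressionMatrix(gene_ids=gene_ids, sample_ids=sample_ids, values=fpkm)
    truth = TruthTable(
        genes=pd.DataFrame(truth_rows).set_index("gene_id", drop=False),
        haplotypes=haplotypes,
        diplotypes=diplotypes,
        population_effects=pop_effects,
    )
    return matrix, meta, snp_tables, truth


def gene_lengths_of(snp_tables: dict[str, GeneSNPTable]) -> dict[str, int]:
    return {g: t.gene_length for g, t in snp_tables.items()}
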