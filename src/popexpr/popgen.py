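"""SNP filtering and per-gene nucleotide diversity from transcript SNPs.

SNPs are filtered with the study thresholds (kept iff quality > 10,
missing fraction < 0.10 and minor allele frequency > 0.05, all boundaries
exclusive on the keep side).  Nucleotide diversity per gene is the
per-site unbiased expected heterozygosity summed over the remaining SNP
sites and divided by the transcript length L:

    pi = (1/L) * sum_j (m_j / (m_j - 1)) * 2 * p_j * (1 - p_j)

where p_j is the non-reference allele frequency among the m_j non-missing
alleles at site j (two alleles per diploid).  This equals the average
pairwise allele difference over all sampled allele pairs at each site.
Both filtering and pi are computed per environment group, since diversity
is reported separately in each garden.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import MISSING, GeneSNPTable, SampleMetadata

QUALITY_MIN = 10.0  # kept iff quality > this
MISSING_MAX = 0.10  # kept iff missing fraction < this
MAF_MIN = 0.05  # kept iff MAF > this


def allele_counts(genotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (non-reference allele count, non-missing allele count)."""
    geno = np.asarray(genotypes)
    observed = geno != MISSING
    alt = np.where(observed, geno, 0).sum(axis=-1)
    m = 2 * observed.sum(axis=-1)
    return alt.astype(float), m.astype(float)


def filter_snps(
    table: GeneSNPTable,
    sample_ids: list[str] | None = None,
    quality_min: float = QUALITY_MIN,
    missing_max: float = MISSING_MAX,
    maf_min: float = MAF_MIN,
) -> GeneSNPTable:
    """Apply the quality / missingness / MAF filter to one gene's SNPs.

    ``sample_ids`` restricts the genotype columns (e.g. to one
    environment's individuals) before computing missingness and MAF; the
    returned table contains only those samples.  A SNP at any boundary
    (quality == 10, missing == 10%, MAF == 0.05) is excluded.
    """
    if sample_ids is not None:
        table = table.subset_samples(sample_ids)
    if table.n_snps == 0:
        return table
    n_samples = len(table.sample_ids)
    observed = table.genotypes != MISSING
    # exact count ratio (1 - observed/n drifts off the 10% boundary)
    missing_frac = (n_samples - observed.sum(axis=1)) / n_samples
    alt, m = allele_counts(table.genotypes)
    with np.errstate(invalid="ignore"):
        p = np.where(m > 0, alt / np.maximum(m, 1), np.nan)
    maf = np.minimum(p, 1.0 - p)
    keep = (
        (table.quality > quality_min)
        & (missing_frac < missing_max)
        & np.nan_to_num(maf > maf_min, nan=False)
    )
    return table.subset_snps(keep)


def compute_pi(table: GeneSNPTable) -> float:
    """Nucleotide diversity of one gene from its (filtered) SNP sites.

    Sites with fewer than 2 non-missing alleles contribute 0.  A gene with
    no SNPs has pi = 0.
    """
    if table.n_snps == 0:
        return 0.0
    alt, m = allele_counts(table.genotypes)
    valid = m >= 2
    p = np.where(valid, alt / np.maximum(m, 1), 0.0)
    correction = np.where(valid, m / np.maximum(m - 1, 1), 0.0)
    per_site = correction * 2.0 * p * (1.0 - p)
    return float(per_site.sum() / table.gene_length)


def pairwise_pi_oracle(table: GeneSNPTable) -> float:
    """Brute-force pi: average pairwise allele difference over all sampled
    allele pairs at each site, summed and divided by gene length.

    Independent of :func:`compute_pi`; used as its oracle in tests.
    """
    total = 0.0
    for j in range(table.n_snps):
        alleles: list[int] = []
        for g in table.genotypes[j]:
            if g == MISSING:
                continue
            alleles.extend([1] * g + [0] * (2 - g))
        m = len(alleles)
        if m < 2:
            continue
        diffs = sum(
            alleles[a] != alleles[b] for a in range(m) for b in range(a + 1, m)
        )
        total += diffs / (m * (m - 1) / 2)
    return total / table.gene_length


def diversity_table(
    tables: dict[str, GeneSNPTable],
    meta: SampleMetadata,
    gene_ids: list[str] | None = None,
    per_environment: bool = True,
    **filter_kwargs,
) -> pd.DataFrame:
    """Per-gene, per-environment diversity records.

    Columns: gene_id, env, n_snps (post-filter), has_snp, pi.  Genes in
    ``gene_ids`` missing from ``tables`` get zero-SNP records.  With
    ``per_environment`` (default) the SNP filter is applied within each
    environment's samples; otherwise jointly across all samples, with pi
    still computed per environment on the jointly surviving sites.
    """
    if gene_ids is None:
        gene_ids = sorted(tables)
    envs = meta.environments
    env_samples = {e: meta.samples_in_env(e) for e in envs}
    rows = []
    for gene in gene_ids:
        table = tables.get(gene)
        for env in envs:
            if table is None:
                n_snps, pi = 0, 0.0
            elif per_environment:
                filtered = filter_snps(table, env_samples[env], **filter_kwargs)
                n_snps, pi = filtered.n_snps, compute_pi(filtered)
            else:
                joint = filter_snps(table, **filter_kwargs)
                env_table = joint.subset_samples(
                    [s for s in env_samples[env] if s in joint.sample_ids]
                )
                n_snps, pi = env_table.n_snps, compute_pi(env_table)
            rows.append(
                {
                    "gene_id": gene,
                    "env": env,
                    "n_snps": n_snps,
                    "has_snp": n_snps > 0,
                    "pi": pi,
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "env", "n_snps", "has_snp", "pi"])


def group_by_snp_presence(
    diversity: pd.DataFrame, env: str
) -> tuple[set[str], set[str]]:
    """Disjoint exhaustive split of genes into (with SNP, without SNP) in one environment."""
    sub = diversity[diversity["env"] == env]
    with_snp = set(sub.loc[sub["has_snp"], "gene_id"])
    without_snp = set(sub.loc[~sub["has_snp"], "gene_id"])
    return with_snp, without_snp
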