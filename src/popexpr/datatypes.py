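"""Core in-memory containers for the population expression-variation pipeline.

All containers are lightweight dataclasses around numpy/pandas objects,
validated on construction so that downstream stages can assume the
invariants (non-negative FPKM, biallelic genotype codes, sorted SNP
positions, exactly two environments).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1  # genotype code for a missing diploid call


class FormatError(ValueError):
    """A file or table violates the expected format."""


class ValidationError(ValueError):
    """Well-formed input whose content violates a domain invariant."""


@dataclass
class ExpressionMatrix:
    """Genes x individuals FPKM matrix.

    Parameters
    ----------
    gene_ids : list of str
        Unique gene/transcript identifiers (rows).
    sample_ids : list of str
        Unique individual identifiers (columns).
    values : ndarray of shape (n_genes, n_samples)
        Non-negative FPKM values; NaN is not allowed.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene IDs in expression matrix")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample IDs in expression matrix")
        if np.isnan(self.values).any():
            raise ValidationError("expression matrix contains NaN values")
        if (self.values < 0).any():
            raise ValidationError("expression matrix contains negative FPKM values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            gene_ids=[str(g) for g in df.index],
            sample_ids=[str(s) for s in df.columns],
            values=df.to_numpy(dtype=float),
        )

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(self.gene_ids, list(sample_ids), self.values[:, idx])


@dataclass
class SampleMetadata:
    """Per-individual population and environment labels.

    The design has exactly two environments; ``native_env`` names the one
    used as the denominator of cross-environment ratios.
    """

    table: pd.DataFrame  # columns: sample_id, population, environment
    native_env: str

    def __post_init__(self) -> None:
        required = {"sample_id", "population", "environment"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"metadata missing columns: {sorted(missing)}")
        self.table = self.table.astype(
            {"sample_id": str, "population": str, "environment": str}
        ).reset_index(drop=True)
        if self.table["sample_id"].duplicated().any():
            dups = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"]
            raise FormatError(f"duplicate sample IDs in metadata: {sorted(set(dups))}")
        envs = self.environments
        if len(envs) != 2:
            raise ValidationError(
                f"expected exactly 2 environment levels, got {len(envs)}: {envs}"
            )
        if self.native_env not in envs:
            raise ValidationError(
                f"native environment {self.native_env!r} not among environments {envs}"
            )

    @property
    def environments(self) -> list[str]:
        return sorted(self.table["environment"].unique())

    @property
    def new_env(self) -> str:
        return next(e for e in self.environments if e != self.native_env)

    @property
    def populations(self) -> list[str]:
        return sorted(self.table["population"].unique())

    def samples_in_env(self, env: str) -> list[str]:
        return self.table.loc[self.table["environment"] == env, "sample_id"].tolist()

    def check_against_matrix(self, matrix: ExpressionMatrix) -> None:
        known = set(self.table["sample_id"])
        missing = [s for s in matrix.sample_ids if s not in known]
        if missing:
            raise ValidationError(
                f"samples present in expression matrix but absent from metadata: {missing}"
            )


@dataclass
class GeneSNPTable:
    """Filtered biallelic SNPs of one gene in transcript coordinates.

    Genotypes count non-reference alleles per diploid individual:
    0, 1, 2 or :data:`MISSING`.  Rows are SNP sites (positions strictly
    increasing, 1-based), columns are samples.
    """

    gene_id: str
    gene_length: int
    positions: np.ndarray  # (n_snps,) int, 1-based
    quality: np.ndarray  # (n_snps,) float
    genotypes: np.ndarray  # (n_snps, n_samples) int in {0,1,2,MISSING}
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.quality = np.asarray(self.quality, dtype=float)
        self.genotypes = np.asarray(self.genotypes, dtype=int)
        if self.gene_length <= 0:
            raise ValidationError(f"{self.gene_id}: gene_length must be positive")
        n = len(self.positions)
        if self.quality.shape != (n,) or self.genotypes.shape[0] != n:
            raise ValidationError(f"{self.gene_id}: inconsistent SNP array shapes")
        if n and self.genotypes.shape[1] != len(self.sample_ids):
            raise ValidationError(f"{self.gene_id}: genotype/sample count mismatch")
        if n:
            if (self.positions < 1).any() or (self.positions > self.gene_length).any():
                raise ValidationError(
                    f"{self.gene_id}: SNP position outside [1, {self.gene_length}]"
                )
            if (np.diff(self.positions) <= 0).any():
                raise ValidationError(
                    f"{self.gene_id}: SNP positions not strictly increasing"
                )
            bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
            if bad.any():
                raise ValidationError(f"{self.gene_id}: invalid genotype codes")

    @property
    def n_snps(self) -> int:
        return len(self.positions)

    def subset_snps(self, keep: np.ndarray) -> "GeneSNPTable":
        keep = np.asarray(keep)
        return GeneSNPTable(
            gene_id=self.gene_id,
            gene_length=self.gene_length,
            positions=self.positions[keep],
            quality=self.quality[keep],
            genotypes=self.genotypes[keep] if self.n_snps else self.genotypes,
            sample_ids=self.sample_ids,
        )

    def subset_samples(self, sample_ids: list[str]) -> "GeneSNPTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return GeneSNPTable(
            gene_id=self.gene_id,
            gene_length=self.gene_length,
            positions=self.positions,
            quality=self.quality,
            genotypes=self.genotypes[:, idx] if self.n_snps else self.genotypes,
            sample_ids=list(sample_ids),
        )


def canonical_diplotype(hap1: str, hap2: str) -> tuple[str, str]:
    """Order-free (sorted) representation of a haplotype pair."""
    return (hap1, hap2) if hap1 <= hap2 else (hap2, hap1)


@dataclass
class DiplotypeAssignment:
    """Phased haplotype pairs of one gene for all individuals.

    ``pairs`` maps sample_id to the canonical (sorted) haplotype pair;
    haplotypes are strings over {0,1} with one character per filtered SNP.
    """

    gene_id: str
    pairs: dict[str, tuple[str, str]]
    posteriors: dict[str, float] = field(default_factory=dict)
    hap_freqs: dict[str, float] = field(default_factory=dict)
    log_likelihood: float = float("nan")

    def __post_init__(self) -> None:
        self.pairs = {
            s: canonical_diplotype(h1, h2) for s, (h1, h2) in self.pairs.items()
        }
        lengths = {len(h) for pair in self.pairs.values() for h in pair}
        if len(lengths) > 1:
            raise ValidationError(
                f"{self.gene_id}: haplotype strings of unequal length {lengths}"
            )
        for pair in self.pairs.values():
            for h in pair:
                if set(h) - {"0", "1"}:
                    raise ValidationError(
                        f"{self.gene_id}: haplotype alleles must be 0/1, got {h!r}"
                    )
        if self.hap_freqs:
            total = sum(self.hap_freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(
                    f"{self.gene_id}: haplotype frequencies sum to {total}, not 1"
                )

    @property
    def n_snps(self) -> int:
        for pair in self.pairs.values():
            return len(pair[0])
        return 0
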