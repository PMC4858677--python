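"""Readers and writers for the pipeline's on-disk formats.

Expression matrices, sample metadata, phased haplotypes and result tables
are tab-separated UTF-8 text ('.' decimal, no quoting); SNPs are VCF v4.x
with CHROM holding the transcript/gene ID and 1-based positions.  Output
tables carry a leading ``#`` comment line recording the tool version and a
hash of the configuration that produced them; readers skip such lines.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datatypes import (
    MISSING,
    DiplotypeAssignment,
    ExpressionMatrix,
    FormatError,
    GeneSNPTable,
    SampleMetadata,
    ValidationError,
)

__version__ = "0.1.0"

logger = logging.getLogger(__name__)


def config_hash(config: object) -> str:
    """Short stable hash of any JSON-serialisable configuration object."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _header_comment(config: object | None) -> str:
    h = config_hash(config) if config is not None else "none"
    return f"# popexpr v{__version__} config={h}\n"


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# ---------------------------------------------------------------------------
# Expression matrix


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples FPKM matrix from TSV.

    First column holds gene IDs, header row holds sample IDs, body is
    numeric.  Duplicate IDs raise :class:`FormatError`; NaN or negative
    cells raise :class:`ValidationError`.
    """
    df = _read_tsv(path, index_col=0, dtype_backend="numpy_nullable")
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise FormatError(f"duplicate gene IDs: {dups}")
    if df.columns.duplicated().any():
        raise FormatError("duplicate sample IDs in header")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric expression value: {exc}") from exc
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        values=values,
    )


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, config: object | None = None
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_comment(config))
        matrix.to_frame().to_csv(fh, sep="\t", index_label="gene_id", lineterminator="\n")


# ---------------------------------------------------------------------------
# Sample metadata


def read_sample_metadata(
    path: str | Path,
    native_env: str,
    matrix: ExpressionMatrix | None = None,
) -> SampleMetadata:
    """Read per-sample population/environment labels from TSV.

    ``native_env`` designates the environment used as the denominator of
    cross-environment ratios.  If ``matrix`` is given, every matrix sample
    must be present in the metadata.
    """
    df = _read_tsv(path, dtype=str)
    meta = SampleMetadata(table=df, native_env=native_env)
    if matrix is not None:
        meta.check_against_matrix(matrix)
    return meta


def write_sample_metadata(
    meta: SampleMetadata, path: str | Path, config: object | None = None
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_comment(config))
        meta.table.to_csv(fh, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# SNP VCF


def _genotype_code(gt_types_entry: int) -> int:
    # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
    return {0: 0, 1: 1, 2: MISSING, 3: 2}[gt_types_entry]


def read_snp_vcf(
    path: str | Path, gene_lengths: dict[str, int]
) -> dict[str, GeneSNPTable]:
    """Read per-gene SNP genotypes from a VCF.

    CHROM is interpreted as the gene/transcript ID.  Multiallelic records
    are skipped (count logged); genes absent from ``gene_lengths`` are
    skipped with a warning.  Genotypes map to non-reference allele counts
    {0, 1, 2} with ``./.`` as missing; phase in the input is ignored.
    Every gene in ``gene_lengths`` gets a table, possibly with zero SNPs.
    """
    per_gene: dict[str, dict[str, list]] = {
        g: {"pos": [], "qual": [], "geno": []} for g in gene_lengths
    }
    n_multi = 0
    skipped_genes: set[str] = set()
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    for record in vcf:
        if len(record.ALT) != 1:
            n_multi += 1
            continue
        gene = record.CHROM
        if gene not in per_gene:
            skipped_genes.add(gene)
            continue
        codes = [_genotype_code(t) for t in record.gt_types]
        per_gene[gene]["pos"].append(record.POS)
        per_gene[gene]["qual"].append(record.QUAL if record.QUAL is not None else 0.0)
        per_gene[gene]["geno"].append(codes)
    vcf.close()
    if n_multi:
        logger.info("skipped %d multiallelic VCF records", n_multi)
    if skipped_genes:
        logger.warning(
            "skipped %d VCF genes absent from gene_lengths: %s",
            len(skipped_genes),
            sorted(skipped_genes)[:10],
        )

    tables: dict[str, GeneSNPTable] = {}
    for gene, length in gene_lengths.items():
        d = per_gene[gene]
        order = np.argsort(d["pos"], kind="stable") if d["pos"] else []
        tables[gene] = GeneSNPTable(
            gene_id=gene,
            gene_length=int(length),
            positions=np.asarray(d["pos"], dtype=int)[order] if d["pos"] else np.empty(0, int),
            quality=np.asarray(d["qual"], dtype=float)[order] if d["pos"] else np.empty(0),
            genotypes=(
                np.asarray(d["geno"], dtype=int)[order]
                if d["pos"]
                else np.empty((0, len(sample_ids)), int)
            ),
            sample_ids=sample_ids,
        )
    return tables


_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_snp_vcf(
    tables: dict[str, GeneSNPTable], path: str | Path, config: object | None = None
) -> None:
    """Write gene SNP tables as a minimal uncompressed VCF v4.2 file."""
    sample_ids: list[str] | None = None
    for t in tables.values():
        if t.sample_ids:
            sample_ids = t.sample_ids
            break
    if sample_ids is None:
        sample_ids = []
    buf = _io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write(f"##source=popexpr_v{__version__}\n")
    if config is not None:
        buf.write(f"##popexpr_config={config_hash(config)}\n")
    for gene_id in sorted(tables):
        buf.write(f"##contig=<ID={gene_id},length={tables[gene_id].gene_length}>\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_ids)
        + "\n"
    )
    for gene_id in sorted(tables):
        t = tables[gene_id]
        for j in range(t.n_snps):
            gts = "\t".join(_GT_STRING[g] for g in t.genotypes[j])
            buf.write(
                f"{gene_id}\t{t.positions[j]}\t.\tA\tG\t{t.quality[j]:g}\t.\t.\tGT\t{gts}\n"
            )
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


# ---------------------------------------------------------------------------
# Phased haplotypes (PHASE-style best-guess reconstructions)


def read_phased_haplotypes(
    path: str | Path,
    snp_tables: dict[str, GeneSNPTable] | None = None,
) -> dict[str, DiplotypeAssignment]:
    """Read best-guess diplotypes from TSV rows (gene_id, sample_id, hap1, hap2[, posterior]).

    Haplotype pairs are stored unordered.  If ``snp_tables`` is given, each
    haplotype string length must equal the gene's filtered SNP count.
    """
    df = _read_tsv(path, dtype={"gene_id": str, "sample_id": str, "hap1": str, "hap2": str})
    required = {"gene_id", "sample_id", "hap1", "hap2"}
    if missing := required - set(df.columns):
        raise FormatError(f"phased haplotype table missing columns: {sorted(missing)}")
    out: dict[str, DiplotypeAssignment] = {}
    for gene_id, sub in df.groupby("gene_id", sort=True):
        pairs = {
            row.sample_id: (row.hap1, row.hap2) for row in sub.itertuples(index=False)
        }
        posteriors = (
            {row.sample_id: float(row.posterior) for row in sub.itertuples(index=False)}
            if "posterior" in sub.columns
            else {}
        )
        assignment = DiplotypeAssignment(
            gene_id=str(gene_id), pairs=pairs, posteriors=posteriors
        )
        if snp_tables is not None:
            if gene_id not in snp_tables:
                raise ValidationError(f"phased gene {gene_id!r} absent from SNP tables")
            expected = snp_tables[gene_id].n_snps
            if assignment.n_snps != expected:
                raise ValidationError(
                    f"{gene_id}: haplotype length {assignment.n_snps} != "
                    f"filtered SNP count {expected}"
                )
        out[str(gene_id)] = assignment
    return out


def write_phased_haplotypes(
    assignments: dict[str, DiplotypeAssignment],
    path: str | Path,
    config: object | None = None,
) -> None:
    rows = []
    for gene_id in sorted(assignments):
        a = assignments[gene_id]
        for sample_id in sorted(a.pairs):
            h1, h2 = a.pairs[sample_id]
            rows.append(
                {
                    "gene_id": gene_id,
                    "sample_id": sample_id,
                    "hap1": h1,
                    "hap2": h2,
                    "posterior": a.posteriors.get(sample_id, float("nan")),
                }
            )
    df = pd.DataFrame(rows, columns=["gene_id", "sample_id", "hap1", "hap2", "posterior"])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_comment(config))
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Generic result tables


def write_table(df: pd.DataFrame, path: str | Path, config: object | None = None) -> None:
    """Write a result table as TSV with the version/config header comment."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_comment(config))
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path)


def write_gene_lengths(lengths: dict[str, int], path: str | Path) -> None:
    df = pd.DataFrame(
        {"gene_id": sorted(lengths), "length": [lengths[g] for g in sorted(lengths)]}
    )
    write_table(df, path)


def read_gene_lengths(path: str | Path) -> dict[str, int]:
    df = _read_tsv(path, dtype={"gene_id": str, "length": int})
    return dict(zip(df["gene_id"], df["length"]))
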