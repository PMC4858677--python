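"""End-to-end orchestration: simulate/read inputs, run every stage, write results.

The pipeline is a chain of pure stages over TSV/VCF interfaces:

    expression filter -> E_p/E_d statistics -> SNP filter + pi -> phasing
    -> two-way ANOVA (env x population, env x diplotype) -> classifications

Each stage's outputs are written as TSV next to a machine-readable
``summary.json`` holding the stage-by-stage gene counts, effect-group
counts and bin-comparison rank-sum tables.  Identical config + seed gives
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import effect_models, expression_stats, io, phasing, popgen, synthetic_data
from .datatypes import ExpressionMatrix, GeneSNPTable, SampleMetadata, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a run needs; exactly one of input paths / simulation block."""

    # inputs (file mode)
    expression_path: str | None = None
    metadata_path: str | None = None
    vcf_path: str | None = None
    gene_lengths_path: str | None = None
    phased_path: str | None = None  # optional externally phased diplotypes
    # or a simulation block
    simulation: synthetic_data.SimulationConfig | None = None

    native_env: str = "native"
    ed_metric: str = "shannon"
    ep_band: tuple[float, float] = expression_stats.EP_BAND
    ed_band: tuple[float, float] = expression_stats.ED_BAND
    snp_quality_min: float = popgen.QUALITY_MIN
    snp_missing_max: float = popgen.MISSING_MAX
    snp_maf_min: float = popgen.MAF_MIN
    snp_filter_per_environment: bool = True
    phasing_max_snps: int = phasing.MAX_SNPS_DEFAULT
    phasing_restarts: int = 5
    fdr_method: str = "storey"
    alpha: float = 0.05
    use_q_for_classification: bool = True
    ep_bins: int = 5
    pi_bins: int = 4
    response: str = "log2"
    seed: int = 0
    outdir: str = "popexpr_out"

    def __post_init__(self) -> None:
        file_mode = self.expression_path is not None
        if file_mode == (self.simulation is not None):
            raise ValidationError(
                "config must provide either input paths or a simulation block"
            )
        if file_mode and (self.metadata_path is None):
            raise ValidationError("file mode requires metadata_path")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if not 0 <= self.snp_missing_max <= 1 or not 0 <= self.snp_maf_min < 0.5:
            raise ValidationError("SNP filter thresholds out of range")
        if self.phasing_max_snps < 1 or self.ep_bins < 2 or self.pi_bins < 2:
            raise ValidationError("invalid phasing/binning settings")

    def as_dict(self) -> dict:
        # outdir is excluded: where results land must not change their identity
        d = dataclasses.asdict(self)
        d.pop("outdir", None)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            sim = synthetic_data.SimulationConfig(**sim)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(simulation=sim, **raw)


def _seed_for(config: PipelineConfig, stage: str) -> int:
    """Stage seed derived deterministically from the top-level seed."""
    stage_key = zlib.crc32(stage.encode()) % (2**31)
    return int(
        np.random.SeedSequence([config.seed, stage_key]).generate_state(1)[0] % (2**31)
    )


def load_inputs(
    config: PipelineConfig,
) -> tuple[ExpressionMatrix, SampleMetadata, dict[str, GeneSNPTable]]:
    """Read or simulate the pipeline inputs; simulated inputs are also
    written to the output directory in their on-disk formats."""
    outdir = Path(config.outdir)
    if config.simulation is not None:
        sim_cfg = dataclasses.replace(config.simulation, seed=_seed_for(config, "simulate"))
        matrix, meta, snp_tables, truth = synthetic_data.simulate_dataset(sim_cfg)
        outdir.mkdir(parents=True, exist_ok=True)
        cfg_dict = config.as_dict()
        io.write_expression_matrix(matrix, outdir / "expression.tsv", cfg_dict)
        io.write_sample_metadata(meta, outdir / "metadata.tsv", cfg_dict)
        io.write_snp_vcf(snp_tables, outdir / "snps.vcf", cfg_dict)
        io.write_gene_lengths(synthetic_data.gene_lengths_of(snp_tables),
                              outdir / "gene_lengths.tsv")
        io.write_table(truth.genes.reset_index(drop=True), outdir / "truth.tsv", cfg_dict)
        return matrix, meta, snp_tables
    for name in ("expression_path", "metadata_path"):
        p = getattr(config, name)
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"{name} does not exist: {p}")
    if config.vcf_path is not None and not Path(config.vcf_path).exists():
        raise FileNotFoundError(f"vcf_path does not exist: {config.vcf_path}")
    matrix = io.read_expression_matrix(config.expression_path)
    meta = io.read_sample_metadata(config.metadata_path, config.native_env, matrix)
    snp_tables: dict[str, GeneSNPTable] = {}
    if config.vcf_path is not None:
        if config.gene_lengths_path is None:
            raise ValidationError("vcf_path requires gene_lengths_path")
        lengths = io.read_gene_lengths(config.gene_lengths_path)
        snp_tables = io.read_snp_vcf(config.vcf_path, lengths)
    return matrix, meta, snp_tables


def phase_genes(
    snp_tables: dict[str, GeneSNPTable],
    config: PipelineConfig,
    gene_ids: list[str] | None = None,
) -> dict[str, phasing.DiplotypeAssignment]:
    """EM-phase every gene with 1..max_snps SNPs after the joint filter.

    All samples (both gardens) are pooled for phasing, as the two garden
    samples of one individual are clones.
    """
    assignments = {}
    seed0 = _seed_for(config, "phase")
    genes = sorted(snp_tables) if gene_ids is None else [g for g in gene_ids if g in snp_tables]
    for i, gene_id in enumerate(genes):
        filtered = popgen.filter_snps(
            snp_tables[gene_id],
            quality_min=config.snp_quality_min,
            missing_max=config.snp_missing_max,
            maf_min=config.snp_maf_min,
        )
        if not 1 <= filtered.n_snps <= config.phasing_max_snps:
            continue
        assignments[gene_id] = phasing.phase_gene_em(
            filtered,
            max_snps=config.phasing_max_snps,
            n_restarts=config.phasing_restarts,
            seed=(seed0 + i) % (2**31),
        )
    return assignments


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the result bundle; returns the summary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # run log without timestamps so identical runs stay byte-identical
    pkg_logger = logging.getLogger("popexpr")
    log_handler = logging.FileHandler(outdir / "run.log", mode="w", encoding="utf-8")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    pkg_logger.addHandler(log_handler)
    pkg_logger.setLevel(logging.INFO)
    try:
        return _run_stages(config, outdir)
    finally:
        pkg_logger.removeHandler(log_handler)
        log_handler.close()


def _run_stages(config: PipelineConfig, outdir: Path) -> dict:
    cfg_dict = config.as_dict()
    summary: dict = {"config_hash": io.config_hash(cfg_dict), "stages": {}}

    def stage(name):
        logger.info("stage: %s", name)
        return summary["stages"].setdefault(name, {})

    try:
        matrix, meta, snp_tables = load_inputs(config)
    except Exception as exc:
        raise RuntimeError(f"stage 'load_inputs' failed: {exc}") from exc

    s = stage("filter")
    kept = expression_stats.filter_expressed_genes(matrix, meta)
    s["genes_total"] = matrix.n_genes
    s["genes_expressed"] = len(kept)
    logger.info("expression filter: %d -> %d genes", matrix.n_genes, len(kept))

    s = stage("expression_stats")
    stats_df = expression_stats.gene_stats_table(matrix, meta, kept, config.ed_metric)
    io.write_table(stats_df, outdir / "gene_stats.tsv", cfg_dict)
    defined = stats_df[stats_df["nine_group"] != ""]
    r, p = expression_stats.correlate_ep(
        stats_df["Ep_native"].to_numpy(), stats_df["Ep_new"].to_numpy()
    )
    s["ep_correlation_r"] = round(r, 6)
    s["ep_correlation_p"] = float(p)
    s["conserved_ep_fraction"] = round(
        float((defined["ep_class"] == "conserved").mean()), 6
    )
    s["nine_group_counts"] = defined["nine_group"].value_counts().sort_index().to_dict()

    s = stage("diversity")
    div_df = popgen.diversity_table(
        snp_tables, meta, gene_ids=kept,
        per_environment=config.snp_filter_per_environment,
        quality_min=config.snp_quality_min,
        missing_max=config.snp_missing_max,
        maf_min=config.snp_maf_min,
    )
    io.write_table(div_df, outdir / "diversity.tsv", cfg_dict)
    for env in meta.environments:
        with_snp, without = popgen.group_by_snp_presence(div_df, env)
        sub = div_df[(div_df["env"] == env) & div_df["has_snp"]]
        s[env] = {
            "genes_with_snp": len(with_snp),
            "genes_without_snp": len(without),
            "pi_min": float(sub["pi"].min()) if len(sub) else 0.0,
            "pi_max": float(sub["pi"].max()) if len(sub) else 0.0,
            "pi_mean": float(sub["pi"].mean()) if len(sub) else 0.0,
        }

    s = stage("phasing")
    if config.phased_path is not None:
        assignments = io.read_phased_haplotypes(config.phased_path)
    else:
        assignments = phase_genes(snp_tables, config, gene_ids=kept)
    io.write_phased_haplotypes(assignments, outdir / "phased.tsv", cfg_dict)
    s["genes_phased"] = len(assignments)

    s = stage("effects")
    gene_rows = {g: i for i, g in enumerate(matrix.gene_ids)}
    kept_matrix = ExpressionMatrix(
        gene_ids=kept,
        sample_ids=matrix.sample_ids,
        values=matrix.values[[gene_rows[g] for g in kept]],
    )
    effects_pop = effect_models.fit_all_genes(
        kept_matrix, meta, model="pop_env", response=config.response,
        fdr_method=config.fdr_method, alpha=config.alpha,
    )
    io.write_table(effects_pop, outdir / "effects_pop_env.tsv", cfg_dict)
    crit = "q" if config.use_q_for_classification else "p"
    s["pop_env"] = _effect_counts(effects_pop, crit, config.alpha,
                                  {"factorA": "environment", "factorB": "population",
                                   "interaction": "pop_x_env"})

    phased_in_matrix = {g: a for g, a in assignments.items() if g in set(kept)}
    if phased_in_matrix:
        effects_hap = effect_models.fit_all_genes(
            kept_matrix, meta, diplotypes=phased_in_matrix, model="hap_env",
            response=config.response, fdr_method=config.fdr_method, alpha=config.alpha,
        )
        io.write_table(effects_hap, outdir / "effects_hap_env.tsv", cfg_dict)
        s["hap_env"] = _effect_counts(effects_hap, crit, config.alpha,
                                      {"factorA": "environment", "factorB": "haplotype",
                                       "interaction": "hap_x_env"})
        eight = effect_models.classify_eight_groups(
            effects_hap, use_q=config.use_q_for_classification, alpha=config.alpha
        )
        io.write_table(
            eight.rename_axis("gene_id").reset_index(), outdir / "eight_groups.tsv", cfg_dict
        )
        s["eight_group_counts"] = eight.value_counts().sort_index().to_dict()
    else:
        effects_hap = None
        s["hap_env"] = {}
        s["eight_group_counts"] = {}

    s = stage("bin_comparisons")
    s["tables"] = {}
    # E_p ratio across E_p(native) quintiles
    ratio_ok = defined[defined["Ep_native"] > 0]
    if len(ratio_ok) >= config.ep_bins:
        labels = expression_stats.bin_equal_count(
            ratio_ok["Ep_native"].to_numpy(), config.ep_bins
        )
        comp = effect_models.compare_bins(ratio_ok["Ep_ratio"], labels)
        io.write_table(comp, outdir / "wilcoxon_ep_bins.tsv", cfg_dict)
        s["tables"]["ep_ratio_by_ep_bins"] = comp.to_dict("records")
    # statistics across pi quartiles (per environment, genes with SNPs)
    for env in meta.environments:
        sub = div_df[(div_df["env"] == env) & div_df["has_snp"]]
        merged = sub.merge(defined, on="gene_id")
        if len(merged) >= config.pi_bins:
            labels = expression_stats.bin_equal_count(
                merged["pi"].to_numpy(), config.pi_bins
            )
            ep_col = "Ep_native" if env == meta.native_env else "Ep_new"
            comp = effect_models.compare_bins(merged[ep_col], labels)
            s["tables"][f"ep_by_pi_bins_{env}"] = comp.to_dict("records")

    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return summary


def _effect_counts(effects: pd.DataFrame, crit: str, alpha: float,
                   names: dict[str, str]) -> dict:
    out = {}
    n_genes = effects["gene_id"].nunique()
    out["genes_tested"] = int(n_genes)
    for term, name in names.items():
        sub = effects[effects["term"] == term]
        hits = int((sub[crit] < alpha).sum())
        out[name] = {"significant": hits,
                     "fraction": round(hits / n_genes, 6) if n_genes else 0.0}
    return out


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
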