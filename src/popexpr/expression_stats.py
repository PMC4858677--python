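"""Population expression level and diversity statistics.

For each gene and environment the pipeline summarises the FPKM values of
the individuals sampled there as

* E_p — population expression level, the arithmetic mean FPKM, and
* E_d — population expression diversity, a bounded [0, 1] index of how
  unevenly total expression is shared among individuals (0 when all
  individuals express equally, approaching 1 when one individual
  dominates).

Cross-environment change is measured by the E_p ratio (new / native
environment) and the E_d change (new - native).  Genes are classified as
conserved / up / down (E_p ratio inside or outside [0.5, 2], boundaries
inclusive) and conserved / enlarged / shrunk (E_d change inside or outside
[-0.25, 0.25]), and the 3 x 3 cross of those labels forms the nine-group
classification.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, SampleMetadata, ValidationError

EP_BAND = (0.5, 2.0)  # conserved expression-level band (ratio scale)
ED_BAND = (-0.25, 0.25)  # conserved expression-diversity band (difference scale)

ED_METRICS = ("shannon", "gini_simpson", "cv")


def filter_expressed_genes(matrix: ExpressionMatrix, meta: SampleMetadata) -> list[str]:
    """Genes expressed (FPKM > 0) in at least half the individuals of EACH environment.

    A gene is kept iff in every environment separately
    ``count(FPKM > 0) >= ceil(n_env / 2)``.
    """
    meta.check_against_matrix(matrix)
    keep = np.ones(matrix.n_genes, dtype=bool)
    col_index = {s: i for i, s in enumerate(matrix.sample_ids)}
    for env in meta.environments:
        samples = [s for s in meta.samples_in_env(env) if s in col_index]
        if not samples:
            raise ValidationError(f"no matrix samples in environment {env!r}")
        cols = [col_index[s] for s in samples]
        n_expressed = (matrix.values[:, cols] > 0).sum(axis=1)
        keep &= n_expressed >= int(np.ceil(len(cols) / 2))
    return [g for g, k in zip(matrix.gene_ids, keep) if k]


def compute_ep(values: np.ndarray) -> float:
    """Population expression level: arithmetic mean FPKM over individuals."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValidationError("E_p requires at least 2 individuals")
    return float(values.mean())


def compute_ed(values: np.ndarray, metric: str = "shannon") -> float:
    """Population expression diversity in [0, 1].

    shannon (default)
        ``1 - H/ln(n)`` where H is the Shannon entropy of the expression
        shares p_i = E_i / sum(E).  0 = perfectly even, -> 1 as one
        individual dominates.
    gini_simpson
        ``1 - (1 - sum p_i^2) / (1 - 1/n)``, the complement of the
        normalised Gini-Simpson evenness.
    cv
        coefficient of variation rescaled as ``cv / (cv + 1)`` to [0, 1).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValidationError("E_d requires at least 2 individuals")
    total = values.sum()
    if total <= 0:
        raise ValidationError("E_d undefined for an all-zero expression vector")
    n = values.size
    if metric == "shannon":
        p = values / total
        p = p[p > 0]
        entropy = -(p * np.log(p)).sum()
        return float(1.0 - entropy / np.log(n))
    if metric == "gini_simpson":
        p = values / total
        return float(1.0 - (1.0 - (p**2).sum()) / (1.0 - 1.0 / n))
    if metric == "cv":
        cv = values.std(ddof=1) / values.mean()
        return float(cv / (cv + 1.0))
    raise ValueError(f"unknown E_d metric {metric!r}; choose from {ED_METRICS}")


def compute_ep_ratio(ep_new: float, ep_native: float) -> float:
    """E_p(new) / E_p(native); NaN (excluded from ratio analyses) if the denominator is 0."""
    if ep_native < 0 or ep_new < 0:
        raise ValidationError("E_p values must be non-negative")
    if ep_native == 0:
        return float("nan")
    return ep_new / ep_native


def classify_conservation(
    ratio: float, ed_change: float
) -> tuple[str, str, str]:
    """Classify one gene by E_p ratio and E_d change (band boundaries inclusive).

    Returns ``(ep_class, ed_class, nine_group)`` where ep_class is down /
    conserved / up, ed_class is shrunk / conserved / enlarged, and
    nine_group is their ordered pair ``"<ep_class>:<ed_class>"``.
    """
    if np.isnan(ratio):
        raise ValidationError("E_p ratio undefined; gene excluded from classification")
    lo, hi = EP_BAND
    if ratio < lo:
        ep_class = "down"
    elif ratio > hi:
        ep_class = "up"
    else:
        ep_class = "conserved"
    lo_d, hi_d = ED_BAND
    if ed_change < lo_d:
        ed_class = "shrunk"
    elif ed_change > hi_d:
        ed_class = "enlarged"
    else:
        ed_class = "conserved"
    return ep_class, ed_class, f"{ep_class}:{ed_class}"


def bin_equal_count(values: np.ndarray, k: int) -> np.ndarray:
    """Rank-split values into k groups of (near-)equal size, labels 1..k.

    Group sizes differ by at most one; when n is not divisible by k the
    lower-numbered (smaller-statistic) groups take the extra members.
    Ties are broken by stable input order, so labels are deterministic.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"cannot split {n} values into {k} groups")
    order = np.argsort(values, kind="stable")
    base, extra = divmod(n, k)
    sizes = [base + 1 if g < extra else base for g in range(k)]
    labels = np.empty(n, dtype=int)
    start = 0
    for g, size in enumerate(sizes, start=1):
        labels[order[start : start + size]] = g
        start += size
    return labels


def correlate_ep(
    ep_native: np.ndarray, ep_new: np.ndarray, log2_transform: bool = False
) -> tuple[float, float]:
    """Pearson correlation of per-gene E_p between the two environments.

    ``log2_transform`` applies log2(E_p + 1) to both vectors first (display
    parity with cumulative-distribution plots); the p-value comes from the
    t distribution with n - 2 degrees of freedom.
    """
    x = np.asarray(ep_native, dtype=float)
    y = np.asarray(ep_new, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValidationError("correlation requires equal-length vectors of size >= 3")
    if log2_transform:
        x = np.log2(x + 1.0)
        y = np.log2(y + 1.0)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def gene_stats_table(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    gene_ids: list[str] | None = None,
    ed_metric: str = "shannon",
) -> pd.DataFrame:
    """Per-gene statistics table over the expression-filtered genes.

    Columns: gene_id, Ep_native, Ep_new, Ed_native, Ed_new, Ep_ratio,
    Ed_change, ep_class, ed_class, nine_group.  Genes whose E_p ratio is
    undefined (native E_p = 0) carry NaN ratio and empty class labels.
    """
    if gene_ids is None:
        gene_ids = filter_expressed_genes(matrix, meta)
    col_index = {s: i for i, s in enumerate(matrix.sample_ids)}
    native_cols = [col_index[s] for s in meta.samples_in_env(meta.native_env) if s in col_index]
    new_cols = [col_index[s] for s in meta.samples_in_env(meta.new_env) if s in col_index]
    gene_index = {g: i for i, g in enumerate(matrix.gene_ids)}

    rows = []
    for gene in gene_ids:
        v = matrix.values[gene_index[gene]]
        v_nat, v_new = v[native_cols], v[new_cols]
        ep_nat, ep_new = compute_ep(v_nat), compute_ep(v_new)
        ed_nat = compute_ed(v_nat, ed_metric) if v_nat.sum() > 0 else np.nan
        ed_new = compute_ed(v_new, ed_metric) if v_new.sum() > 0 else np.nan
        ratio = compute_ep_ratio(ep_new, ep_nat)
        ed_change = ed_new - ed_nat
        if np.isnan(ratio) or np.isnan(ed_change):
            ep_class = ed_class = nine = ""
        else:
            ep_class, ed_class, nine = classify_conservation(ratio, ed_change)
        rows.append(
            {
                "gene_id": gene,
                "Ep_native": ep_nat,
                "Ep_new": ep_new,
                "Ed_native": ed_nat,
                "Ed_new": ed_new,
                "Ep_ratio": ratio,
                "Ed_change": ed_change,
                "ep_class": ep_class,
                "ed_class": ed_class,
                "nine_group": nine,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "Ep_native", "Ep_new", "Ed_native", "Ed_new",
            "Ep_ratio", "Ed_change", "ep_class", "ed_class", "nine_group",
        ],
    )
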