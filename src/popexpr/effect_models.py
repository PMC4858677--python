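"""Per-gene two-way fixed-effect ANOVA, FDR control and effect classification.

Expression variation of each gene is partitioned by a fixed-effect linear
model with two crossed factors and their interaction — environment x
population on all genes, and environment x diplotype ("haplotype" factor)
on the phased genes.  Sums of squares are Type II, which reduces to the
classical two-way decomposition on balanced designs and remains
order-invariant on the mildly unbalanced ones.  The response is
log2(FPKM + 1) by default.

Per-term p-values are pooled across genes and converted to q-values with
Storey's positive false discovery rate estimator (Benjamini-Hochberg
available); genes are then classified by which of the environment,
haplotype and interaction effects are significant at q < alpha (8 possible
subsets).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import orth

from .datatypes import ExpressionMatrix, SampleMetadata, ValidationError
from .phasing import DiplotypeAssignment, diplotype_factor

logger = logging.getLogger(__name__)

TERMS = ("factorA", "factorB", "interaction", "residual")


def _dummies(codes: np.ndarray) -> np.ndarray:
    """Full-rank treatment dummies (first level dropped)."""
    levels = np.unique(codes)
    return (codes[:, None] == levels[None, 1:]).astype(float)


def _residual_projector(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthonormal column basis U of the design and its rank; RSS(y) =
    y'y - ||U'y||^2."""
    u = orth(x)
    return u, u.shape[1]


class _TwoWayDesign:
    """Precomputed projections for one (factorA, factorB) layout.

    Reused across all genes sharing the layout, so fitting thousands of
    genes is a handful of matrix products.
    """

    def __init__(self, factor_a: np.ndarray, factor_b: np.ndarray):
        factor_a = np.asarray(factor_a)
        factor_b = np.asarray(factor_b)
        if factor_a.shape != factor_b.shape:
            raise ValidationError("factor vectors must have equal length")
        self.n = len(factor_a)
        la, lb = np.unique(factor_a), np.unique(factor_b)
        if len(la) < 2 or len(lb) < 2:
            raise ValidationError("each factor needs at least 2 levels")
        counts = pd.crosstab(factor_a, factor_b).to_numpy()
        if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
            raise ValidationError("empty factor level")
        self.any_empty_cell = bool((counts == 0).any())

        ones = np.ones((self.n, 1))
        da, db = _dummies(factor_a), _dummies(factor_b)
        dab = (da[:, :, None] * db[:, None, :]).reshape(self.n, -1)
        self.bases = {}
        self.ranks = {}
        for name, cols in {
            "A": np.hstack([ones, da]),
            "B": np.hstack([ones, db]),
            "AB": np.hstack([ones, da, db]),
            "full": np.hstack([ones, da, db, dab]),
        }.items():
            self.bases[name], self.ranks[name] = _residual_projector(cols)
        self.df_a = len(la) - 1
        self.df_b = len(lb) - 1
        self.df_ab = self.ranks["full"] - self.ranks["AB"]
        self.df_resid = self.n - self.ranks["full"]
        self.interaction_estimable = self.df_ab > 0
        if self.df_resid < 1:
            raise ValidationError("no residual degrees of freedom")

    def rss(self, y: np.ndarray) -> dict[str, np.ndarray]:
        """Residual sums of squares of all four nested models.

        ``y`` is (n_obs,) or (n_obs, n_genes); returns per-model arrays of
        shape (n_genes,).
        """
        y = np.atleast_2d(np.asarray(y, dtype=float).T).T  # (n, g)
        total = (y**2).sum(axis=0)
        return {
            name: np.maximum(total - (u.T @ y).__pow__(2).sum(axis=0), 0.0)
            for name, u in self.bases.items()
        }

    def anova(self, y: np.ndarray) -> pd.DataFrame:
        """Type II ANOVA of one or many response vectors.

        Returns a long table with one row per (gene, term).  Degenerate
        fits (zero residual variance) carry p = 0 and ``degenerate`` =
        True when any effect SS is positive, p = NaN when the response is
        constant.
        """
        rss = self.rss(y)
        g = len(rss["full"])
        ss = {
            "factorA": np.maximum(rss["B"] - rss["AB"], 0.0),
            "factorB": np.maximum(rss["A"] - rss["AB"], 0.0),
            "interaction": np.maximum(rss["AB"] - rss["full"], 0.0),
            "residual": rss["full"],
        }
        df = {
            "factorA": self.df_a,
            "factorB": self.df_b,
            "interaction": self.df_ab,
            "residual": self.df_resid,
        }
        ms_resid = ss["residual"] / self.df_resid
        scale = np.maximum((np.atleast_2d(np.asarray(y, dtype=float).T) ** 2).sum(axis=1), 1.0)
        degenerate = ms_resid <= 1e-12 * scale / self.n
        rows = []
        for term in ("factorA", "factorB", "interaction"):
            if term == "interaction" and not self.interaction_estimable:
                rows.append(
                    pd.DataFrame(
                        {
                            "term": term,
                            "sum_sq": np.zeros(g),
                            "df": 0,
                            "F": np.nan,
                            "p": np.nan,
                            "degenerate": degenerate,
                            "dropped": True,
                        }
                    )
                )
                continue
            with np.errstate(divide="ignore", invalid="ignore"):
                f = (ss[term] / df[term]) / ms_resid
                p = stats.f.sf(f, df[term], self.df_resid)
            # zero residual variance: effect present -> p=0, constant y -> NaN
            effect_present = ss[term] > 1e-12 * scale
            p = np.where(degenerate, np.where(effect_present, 0.0, np.nan), p)
            f = np.where(degenerate, np.inf, f)
            rows.append(
                pd.DataFrame(
                    {
                        "term": term,
                        "sum_sq": ss[term],
                        "df": df[term],
                        "F": f,
                        "p": p,
                        "degenerate": degenerate,
                        "dropped": False,
                    }
                )
            )
        resid = pd.DataFrame(
            {
                "term": "residual",
                "sum_sq": ss["residual"],
                "df": self.df_resid,
                "F": np.nan,
                "p": np.nan,
                "degenerate": degenerate,
                "dropped": False,
            }
        )
        rows.append(resid)
        out = pd.concat(rows, ignore_index=True)
        out["gene_index"] = np.tile(np.arange(g), len(rows))
        return out


def anova_two_way(
    y: np.ndarray, factor_a: np.ndarray, factor_b: np.ndarray
) -> pd.DataFrame:
    """Type II two-way fixed-effect ANOVA with interaction for one response.

    Returns a table with rows factorA, factorB, interaction, residual and
    columns sum_sq, df, F, p (plus degenerate/dropped flags).  When a
    factor-level combination is empty the interaction is inestimable and
    dropped with a logged flag.
    """
    design = _TwoWayDesign(np.asarray(factor_a), np.asarray(factor_b))
    if not design.interaction_estimable:
        logger.warning("interaction inestimable (empty cell); term dropped")
    table = design.anova(np.asarray(y, dtype=float))
    return table.drop(columns="gene_index").set_index("term")


def log2_response(values: np.ndarray) -> np.ndarray:
    return np.log2(np.asarray(values, dtype=float) + 1.0)


def fit_all_genes(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    diplotypes: dict[str, DiplotypeAssignment] | None = None,
    model: str = "pop_env",
    response: str = "log2",
    fdr_method: str = "storey",
    alpha: float = 0.05,
    min_group_size: int = 2,
) -> pd.DataFrame:
    """Fit the two-way model to every eligible gene and control the FDR.

    ``model="pop_env"`` crosses environment with source population on all
    genes; ``model="hap_env"`` crosses environment with each phased gene's
    diplotype factor (genes whose factor collapses below 2 levels are
    skipped).  Per-term p-values are pooled across genes for q-value
    computation.  Returns a long table: gene_id, model, term, sum_sq, df,
    F, p, q, significant (q < alpha), degenerate, dropped.
    """
    if model not in ("pop_env", "hap_env"):
        raise ValueError(f"unknown model {model!r}")
    if model == "hap_env" and diplotypes is None:
        raise ValidationError("model='hap_env' requires diplotype assignments")
    meta.check_against_matrix(matrix)
    transform = log2_response if response == "log2" else np.asarray
    sample_ids = matrix.sample_ids
    meta_indexed = meta.table.set_index("sample_id")
    env = meta_indexed.loc[sample_ids, "environment"].to_numpy()

    records: list[pd.DataFrame] = []
    if model == "pop_env":
        pop = meta_indexed.loc[sample_ids, "population"].to_numpy()
        design = _TwoWayDesign(env, pop)
        y = transform(matrix.values).T  # (n_samples, n_genes)
        table = design.anova(y)
        table["gene_id"] = np.asarray(matrix.gene_ids)[table["gene_index"]]
        records.append(table.drop(columns="gene_index"))
    else:
        gene_index = {g: i for i, g in enumerate(matrix.gene_ids)}
        for gene_id in sorted(diplotypes):
            if gene_id not in gene_index:
                continue
            factor = diplotype_factor(diplotypes[gene_id], min_group_size)
            if factor is None:
                continue
            try:
                dip = np.array([factor[s] for s in sample_ids])
            except KeyError as exc:
                raise ValidationError(
                    f"{gene_id}: no diplotype for sample {exc.args[0]!r}"
                ) from exc
            try:
                design = _TwoWayDesign(env, dip)
            except ValidationError:
                continue  # factor degenerate within this layout
            y = transform(matrix.values[gene_index[gene_id]])
            table = design.anova(y)
            table["gene_id"] = gene_id
            records.append(table.drop(columns="gene_index"))
    if not records:
        raise ValidationError(f"no eligible genes for model {model!r}")
    out = pd.concat(records, ignore_index=True)
    out["model"] = model
    out["q"] = np.nan
    out["significant"] = False
    for term in ("factorA", "factorB", "interaction"):
        mask = (out["term"] == term) & out["p"].notna()
        if mask.any():
            q = control_fdr(out.loc[mask, "p"].to_numpy(), method=fdr_method)
            out.loc[mask, "q"] = q
            out.loc[mask, "significant"] = q < alpha
    cols = ["gene_id", "model", "term", "sum_sq", "df", "F", "p", "q",
            "significant", "degenerate", "dropped"]
    return out[cols]


# ---------------------------------------------------------------------------
# Multiple testing


def control_fdr(
    pvals: np.ndarray, method: str = "storey", lambda_: float = 0.5
) -> np.ndarray:
    """q-values controlling the (positive) false discovery rate.

    ``storey`` estimates the null proportion pi0 with the fixed-lambda
    estimator ``#{p > lambda} / ((1 - lambda) m)`` (capped to [1/m, 1]);
    ``bh`` is the Benjamini-Hochberg special case pi0 = 1.  q-values are
    monotone non-decreasing in p.
    """
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    if method == "storey":
        pi0 = (p > lambda_).sum() / ((1.0 - lambda_) * m)
        pi0 = float(np.clip(pi0, 1.0 / m, 1.0))
    elif method == "bh":
        pi0 = 1.0
    else:
        raise ValueError(f"unknown FDR method {method!r}")
    order = np.argsort(p, kind="stable")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Rank-sum comparisons between gene bins


def wilcoxon_rank_sum(
    x: np.ndarray, y: np.ndarray, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U rank-sum test between two gene groups.

    Exact enumeration when the pooled sample size is at most 12 and there
    are no ties; otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def compare_bins(
    values: pd.Series, labels: np.ndarray, alternative: str = "two-sided"
) -> pd.DataFrame:
    """Pairwise rank-sum tests between every two bins of a statistic.

    Returns rows (group_a, group_b, n_a, n_b, U, p) for a < b.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    rows = []
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            xa, xb = values[labels == a], values[labels == b]
            u, p = wilcoxon_rank_sum(xa, xb, alternative)
            rows.append(
                {"group_a": a, "group_b": b, "n_a": xa.size, "n_b": xb.size,
                 "U": u, "p": p}
            )
    return pd.DataFrame(rows, columns=["group_a", "group_b", "n_a", "n_b", "U", "p"])


# ---------------------------------------------------------------------------
# Eight-group effect classification (environment x haplotype model)

EIGHT_GROUP_TERMS = {"factorA": "E", "factorB": "H", "interaction": "HxE"}


def classify_eight_groups(
    effects: pd.DataFrame, use_q: bool = True, alpha: float = 0.05
) -> pd.Series:
    """Label each phased gene by its significant effect subset.

    The label joins the significant members of {E, H, HxE} with "+"
    ("none" when empty): 2^3 = 8 possible labels.  ``use_q`` switches
    between q-value flags (default) and raw p < alpha.
    """
    sub = effects[effects["term"].isin(EIGHT_GROUP_TERMS)].copy()
    crit = sub["q"] if use_q else sub["p"]
    sub["hit"] = crit < alpha
    labels = {}
    for gene_id, grp in sub.groupby("gene_id", sort=True):
        parts = [
            EIGHT_GROUP_TERMS[t]
            for t in ("factorA", "factorB", "interaction")
            if grp.loc[grp["term"] == t, "hit"].any()
        ]
        labels[gene_id] = "+".join(parts) if parts else "none"
    return pd.Series(labels, name="eight_group")
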