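import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.stats.multitest import multipletests

from popexpr.datatypes import ExpressionMatrix, SampleMetadata, ValidationError
from popexpr.effect_models import (
    anova_two_way,
    classify_eight_groups,
    compare_bins,
    control_fdr,
    fit_all_genes,
    wilcoxon_rank_sum,
)
from popexpr.synthetic_data import SimulationConfig, simulate_dataset


def _balanced_factors(n_a=2, n_b=4, reps=3):
    a = np.repeat([f"a{i}" for i in range(n_a)], n_b * reps)
    b = np.tile(np.repeat([f"b{j}" for j in range(n_b)], reps), n_a)
    return a, b


class TestAnovaTwoWay:
    def test_matches_statsmodels_type2_unbalanced(self):
        rng = np.random.default_rng(0)
        a = np.array(["x"] * 10 + ["y"] * 14)
        b = rng.choice(["u", "v", "w"], size=24)
        y = rng.normal(size=24) + (a == "y") * 0.8 + (b == "w") * 0.5
        ours = anova_two_way(y, a, b)
        fit = ols("y ~ C(A)*C(B)", pd.DataFrame({"y": y, "A": a, "B": b})).fit()
        ref = sm.stats.anova_lm(fit, typ=2)
        for our_term, ref_term in [("factorA", "C(A)"), ("factorB", "C(B)"),
                                   ("interaction", "C(A):C(B)"),
                                   ("residual", "Residual")]:
            assert ours.loc[our_term, "sum_sq"] == pytest.approx(
                ref.loc[ref_term, "sum_sq"], rel=1e-9
            )
            if our_term != "residual":
                assert ours.loc[our_term, "p"] == pytest.approx(
                    ref.loc[ref_term, "PR(>F)"], rel=1e-9
                )

    def test_balanced_interaction_closed_form(self):
        # 2x2, n per cell, cell means (0,0,0,delta), no noise:
        # SS_interaction = n * delta^2 / 4
        delta, n = 1.7, 2
        a = np.repeat(["a0", "a1"], 2 * n)
        b = np.tile(np.repeat(["b0", "b1"], n), 2)
        y = np.where((a == "a1") & (b == "b1"), delta, 0.0)
        table = anova_two_way(y, a, b)
        assert table.loc["interaction", "sum_sq"] == pytest.approx(
            n * delta**2 / 4, rel=1e-9
        )

    def test_balanced_ss_decomposition_and_type1_equivalence(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a, b = _balanced_factors(2, int(rng.integers(2, 6)), int(rng.integers(2, 4)))
            y = rng.normal(size=len(a))
            table = anova_two_way(y, a, b)
            ss_total = ((y - y.mean()) ** 2).sum()
            assert table["sum_sq"].sum() == pytest.approx(ss_total, rel=1e-9)
            # Type II equals sequential SS on balanced data, either order
            fit = ols("y ~ C(A)*C(B)",
                      pd.DataFrame({"y": y, "A": a, "B": b})).fit()
            seq = sm.stats.anova_lm(fit, typ=1)
            assert table.loc["factorA", "sum_sq"] == pytest.approx(
                seq.loc["C(A)", "sum_sq"], rel=1e-8
            )
            assert table.loc["factorB", "sum_sq"] == pytest.approx(
                seq.loc["C(B)", "sum_sq"], rel=1e-8
            )

    def test_constant_response_degenerate(self):
        a, b = _balanced_factors()
        table = anova_two_way(np.full(len(a), 3.0), a, b)
        assert table["degenerate"].all()
        assert table.loc["factorA", "sum_sq"] == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(table.loc["factorA", "p"])

    def test_zero_noise_effect_gives_p_zero(self):
        a, b = _balanced_factors()
        y = (a == "a1").astype(float)
        table = anova_two_way(y, a, b)
        assert table.loc["factorA", "p"] == 0.0
        assert table.loc["factorA", "degenerate"]

    def test_confounded_interaction_dropped(self):
        # factor B nested in A: every (a, b) cell seen only for matching pairs
        a = np.repeat(["a0", "a1"], 6)
        b = np.repeat(["b0", "b1", "b2", "b3"], 3)
        y = np.random.default_rng(1).normal(size=12)
        table = anova_two_way(y, a, b)
        assert table.loc["interaction", "dropped"]
        assert np.isnan(table.loc["interaction", "p"])


class TestFitAllGenes:
    def test_output_covers_all_eligible_genes(self, small_sim):
        matrix, meta, _, _ = small_sim
        out = fit_all_genes(matrix, meta, model="pop_env")
        assert out["gene_id"].nunique() == matrix.n_genes
        assert set(out["term"]) == {"factorA", "factorB", "interaction", "residual"}

    def test_hap_env_requires_diplotypes(self, small_sim):
        matrix, meta, _, _ = small_sim
        with pytest.raises(ValidationError, match="diplotype"):
            fit_all_genes(matrix, meta, model="hap_env")

    def test_environment_effect_recovery(self):
        cfg = SimulationConfig(
            n_genes=400, frac_env_effect=0.5, frac_pop_effect=0.0,
            frac_hap_effect=0.0, frac_interaction=0.0, frac_genes_with_snps=0.0,
            effect_size_sd_units=2.0, seed=21,
        )
        matrix, meta, _, truth = simulate_dataset(cfg)
        out = fit_all_genes(matrix, meta, model="pop_env")
        env = out[out["term"] == "factorA"].set_index("gene_id")
        flagged = set(env.index[env["significant"]])
        planted = set(truth.genes.index[truth.genes["has_env_effect"]])
        sensitivity = len(flagged & planted) / len(planted)
        assert sensitivity >= 0.95


class TestControlFdr:
    def test_all_ones(self):
        q = control_fdr(np.ones(10))
        np.testing.assert_allclose(q, 1.0)

    def test_bh_step_up_example(self):
        q = control_fdr(np.array([0.01, 0.02, 0.03, 0.04]), method="bh")
        np.testing.assert_allclose(q, 0.04)

    def test_bh_matches_statsmodels(self):
        rng = np.random.default_rng(2)
        p = rng.random(500) ** 2
        ours = control_fdr(p, method="bh")
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_q_monotone_in_p_and_bounded_by_storey(self):
        rng = np.random.default_rng(4)
        p = rng.random(300)
        for method in ("storey", "bh"):
            q = control_fdr(p, method=method)
            order = np.argsort(p)
            assert (np.diff(q[order]) >= -1e-12).all()
            assert ((q >= 0) & (q <= 1)).all()
        # Storey q-values never exceed BH q-values (pi0 <= 1)
        assert (control_fdr(p, "storey") <= control_fdr(p, "bh") + 1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            control_fdr(np.array([0.5, 1.2]))


class TestWilcoxon:
    def test_exact_small_sample(self):
        _, p = wilcoxon_rank_sum(np.array([1.0, 2.0]), np.array([3.0, 4.0]))
        assert p == pytest.approx(1 / 3)

    def test_identical_samples_p_one(self):
        x = np.array([1.0, 2.0, 3.0])
        _, p = wilcoxon_rank_sum(x, x.copy())
        assert p == pytest.approx(1.0)

    def test_exact_matches_permutation_oracle(self):
        rng = np.random.default_rng(9)
        for n1 in range(1, 5):
            for n2 in range(n1, 8 - n1 + 1):
                pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))
                x, y = pooled[:n1], pooled[n1:]
                _, p = wilcoxon_rank_sum(x, y)
                p_oracle = _permutation_pvalue(x, y)
                assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_rank_sum(np.array([]), np.array([1.0]))

    def test_compare_bins_shape(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=100)
        labels = np.repeat([1, 2, 3, 4], 25)
        out = compare_bins(values, labels)
        assert len(out) == 6  # C(4,2) pairs
        assert ((out["p"] >= 0) & (out["p"] <= 1)).all()


def _permutation_pvalue(x, y):
    """Two-sided exact Mann-Whitney p by full enumeration of partitions."""
    pooled = np.concatenate([x, y])
    n1 = len(x)

    def u_stat(xs, ys):
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)

    u_obs = u_stat(x, y)
    mu = n1 * len(y) / 2
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        u = u_stat(xs, ys)
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
        total += 1
    return count / total


class TestEightGroups:
    def _effects(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "term", "p", "q"])

    def test_hand_enumerated_labels(self):
        rows = []
        combos = {
            "g_none": (0.5, 0.5, 0.5),
            "g_E": (0.001, 0.5, 0.5),
            "g_H": (0.5, 0.001, 0.5),
            "g_EH": (0.001, 0.001, 0.5),
            "g_all": (0.001, 0.001, 0.001),
        }
        for gene, (pe, ph, pi_) in combos.items():
            rows += [
                (gene, "factorA", pe, pe),
                (gene, "factorB", ph, ph),
                (gene, "interaction", pi_, pi_),
            ]
        labels = classify_eight_groups(self._effects(rows))
        assert labels["g_none"] == "none"
        assert labels["g_E"] == "E"
        assert labels["g_H"] == "H"
        assert labels["g_EH"] == "E+H"
        assert labels["g_all"] == "E+H+HxE"

    def test_partition_is_exhaustive(self, small_sim):
        matrix, meta, snp_tables, _ = small_sim
        from popexpr.pipeline import PipelineConfig, phase_genes

        cfg = PipelineConfig(expression_path="x", metadata_path="y", seed=1)
        assignments = phase_genes(snp_tables, cfg)
        out = fit_all_genes(matrix, meta, diplotypes=assignments, model="hap_env")
        labels = classify_eight_groups(out)
        valid = {"none", "E", "H", "HxE", "E+H", "E+HxE", "H+HxE", "E+H+HxE"}
        assert set(labels.unique()) <= valid
        assert labels.index.nunique() == out["gene_id"].nunique()
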