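import math

import numpy as np
import pandas as pd
import pytest

from cogtex._errors import CogtexError, ConfigError
from cogtex.io import ExpressionMatrix, Scale
from cogtex.coexpression import (
    TRIMMED,
    CoexpressionModel,
    aggregate_minimum,
    correlation_matrix,
    covariate_strata,
    discretize_three_levels,
    g_statistic,
    ischemia_two_means,
    make_subsample_design,
    matrix_inventory,
    stratify_covariates,
    zscore_by_cluster,
)


def _codes_from_table(O):
    """Expand a 3x3 contingency table into two code vectors."""
    a, b = [], []
    for i in range(3):
        for j in range(3):
            a += [i] * int(O[i][j])
            b += [j] * int(O[i][j])
    return np.array(a), np.array(b)


def _g_oracle(O, floor=True):
    """Independent brute-force G: explicit loops, no shared code paths."""
    O = np.asarray(O, float)
    n = O.sum()
    g = 0.0
    for i in range(3):
        for j in range(3):
            if O[i, j] == 0:
                continue
            e = O[i].sum() * O[:, j].sum() / n
            if floor:
                e = max(e, 1.0 if O[i, j] > 4 else 0.5)
            g += O[i, j] * math.log(O[i, j] / e)
    return 2.0 * g


class TestSubsampleDesign:
    def _clusters(self, sizes):
        ids, labels = [], []
        for c, n in sizes.items():
            for i in range(n):
                ids.append(f"{c}_{i}")
                labels.append(c)
        return pd.Series(labels, index=ids)

    def test_deterministic_and_exhaustive_at_exact_size(self):
        clusters = self._clusters({"A": 70, "B": 100})
        d1 = make_subsample_design(clusters, base_seed=3)
        d2 = make_subsample_design(clusters, base_seed=3)
        assert d1.indices == d2.indices
        for r in range(d1.n_reps):
            assert sorted(d1.indices[r]["A"]) == sorted(clusters.index[clusters == "A"])
            assert len(set(d1.indices[r]["B"])) == 70  # without repetition

    def test_reps_differ_for_oversized_clusters(self):
        clusters = self._clusters({"B": 100})
        d = make_subsample_design(clusters, base_seed=0, n_reps=5)
        draws = {tuple(sorted(d.indices[r]["B"])) for r in range(5)}
        assert len(draws) > 1

    def test_undersized_cluster_strict_vs_lenient(self):
        clusters = self._clusters({"A": 69})
        with pytest.raises(CogtexError, match="'A'"):
            make_subsample_design(clusters, strict=True)
        with pytest.warns(UserWarning, match="using all"):
            d = make_subsample_design(clusters, strict=False, n_reps=2)
        assert len(d.indices[0]["A"]) == 69


class TestCorrelations:
    def test_linear_and_monotone_relations(self):
        x = np.linspace(0, 5, 30)
        df = pd.DataFrame([x, 2 * x + 1, np.exp(x)], index=["x", "lin", "exp"])
        p = correlation_matrix(df, "pearson")
        s = correlation_matrix(df, "spearman")
        assert p.loc["x", "lin"] == pytest.approx(1.0)
        assert s.loc["x", "exp"] == pytest.approx(1.0)
        assert p.loc["x", "exp"] < 1.0
        assert (np.diag(p.to_numpy()) == 1.0).all()

    def test_constant_gene_zeroed_with_flag(self):
        df = pd.DataFrame([[1.0, 2, 3], [5, 5, 5]], index=["a", "b"])
        with pytest.warns(UserWarning, match="constant"):
            p = correlation_matrix(df)
        assert p.loc["a", "b"] == 0.0
        assert p.loc["b", "b"] == 1.0

    def test_symmetry_and_sample_minimum(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(5, 20)))
        p = correlation_matrix(df)
        np.testing.assert_allclose(p.to_numpy(), p.to_numpy().T)
        with pytest.raises(CogtexError, match="3 samples"):
            correlation_matrix(df.iloc[:, :2])


class TestDiscretization:
    def test_trimodal_mixture_recovered(self):
        rng = np.random.default_rng(3)
        x = np.concatenate(
            [rng.normal(0, 0.3, 300), rng.normal(5, 0.3, 300), rng.normal(10, 0.3, 300)]
        )
        true = np.repeat([0, 1, 2], 300)
        d = discretize_three_levels(x)
        kept = d.codes != TRIMMED
        assert (d.codes[kept] == true[kept]).mean() >= 0.99
        assert (np.diff(d.centroids) > 0).all()

    def test_all_equal_degenerate_mid(self):
        d = discretize_three_levels(np.full(50, 3.0))
        assert d.degenerate
        assert (d.codes == 1).all()

    def test_trim_is_strict_beyond_bounds(self):
        x = np.concatenate([[0.0], np.linspace(1, 2, 998), [100.0]])
        d = discretize_three_levels(x)
        lo, hi = d.trim_bounds
        assert (d.codes[(x >= lo) & (x <= hi)] != TRIMMED).all()
        assert d.codes[0] == TRIMMED and d.codes[-1] == TRIMMED


class TestGStatistic:
    def test_independence_gives_zero(self):
        O = [[10, 10, 10]] * 3
        a, b = _codes_from_table(O)
        t = g_statistic(a, b)
        assert t.g == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(t.observed, 10.0)

    def test_balanced_diagonal_closed_form(self):
        O = np.diag([30, 30, 30])
        a, b = _codes_from_table(O)
        t = g_statistic(a, b)
        assert t.g == pytest.approx(180 * math.log(3))  # 2N ln 3, N=90

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle_with_flooring(self, seed):
        rng = np.random.default_rng(seed)
        O = rng.integers(0, 12, size=(3, 3))
        O[0, 0] = rng.integers(0, 2)  # force some tiny/zero cells
        if O.sum() == 0:
            O[1, 1] = 5
        a, b = _codes_from_table(O)
        t = g_statistic(a, b)
        assert t.g == pytest.approx(_g_oracle(O, floor=True))
        t_raw = g_statistic(a, b, floor=False)
        assert t_raw.g == pytest.approx(_g_oracle(O, floor=False))

    def test_flooring_changes_only_tiny_expected_cells(self):
        # one observed cell with raw E ~ 0.03: floored to 0.5 before the log
        O = np.array([[1, 0, 0], [0, 30, 0], [0, 0, 30]])
        a, b = _codes_from_table(O)
        raw = g_statistic(a, b, floor=False)
        floored = g_statistic(a, b, floor=True)
        assert raw.expected[0, 0] < 0.5
        assert floored.expected_floored[0, 0] == 0.5
        assert floored.g < raw.g

    def test_trimmed_samples_excluded_pairwise(self):
        a = np.array([0, 1, 2, TRIMMED, 0, 1])
        b = np.array([0, 1, 2, 0, TRIMMED, 1])
        t = g_statistic(a, b)
        assert t.observed.sum() == 4  # two samples dropped

    def test_null_mean_near_chisq_df4(self):
        rng = np.random.default_rng(1)
        gs = []
        for _ in range(400):
            a = rng.integers(0, 3, 200)
            b = rng.integers(0, 3, 200)
            gs.append(g_statistic(a, b).g)
        assert np.mean(gs) == pytest.approx(4.0, rel=0.15)


class TestZscoreModality:
    def test_zscore_per_cluster_and_sd_zero_flagged(self):
        df = pd.DataFrame([[1.0, 2, 3, 7, 7, 7]], index=["g"],
                          columns=[f"s{j}" for j in range(6)])
        clusters = pd.Series(["A"] * 3 + ["B"] * 3, index=df.columns)
        z = zscore_by_cluster(df, clusters)
        np.testing.assert_allclose(z.loc["g"].iloc[:3], [-1, 0, 1])
        np.testing.assert_allclose(z.loc["g"].iloc[3:], 0.0)  # constant cluster

    def test_invariance_to_per_cluster_constant(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(4, 40)), columns=[f"s{j}" for j in range(40)])
        clusters = pd.Series(["A"] * 20 + ["B"] * 20, index=df.columns)
        shifted = df.copy()
        shifted.loc[df.index[0], clusters == "A"] += 100.0
        za = zscore_by_cluster(df, clusters)
        zb = zscore_by_cluster(shifted, clusters)
        np.testing.assert_allclose(za.to_numpy(), zb.to_numpy(), atol=1e-12)


class TestMinimumAggregation:
    def _mats(self, values):
        return [pd.DataFrame([[1.0, v], [v, 1.0]], index=list("ab"), columns=list("ab"))
                for v in values]

    @pytest.mark.parametrize(
        "reps, expected, flagged",
        [
            ([0.9, 0.8, 0.85], 0.8, False),
            ([-0.9, -0.7], -0.7, False),
            ([0.5, -0.4], -0.4, True),
        ],
    )
    def test_smallest_magnitude_sign_preserved(self, reps, expected, flagged):
        mat, flags = aggregate_minimum(self._mats(reps), "pearson")
        assert mat.loc["a", "b"] == pytest.approx(expected)
        assert bool(flags.loc["a", "b"]) is flagged

    def test_min_dominates_every_rep(self):
        rng = np.random.default_rng(7)
        reps = [pd.DataFrame(rng.uniform(-1, 1, (6, 6))) for _ in range(10)]
        reps = [(m + m.T) / 2 for m in reps]
        agg, _ = aggregate_minimum(reps, "pearson")
        stack = np.stack([m.to_numpy() for m in reps])
        assert (np.abs(agg.to_numpy()) <= np.abs(stack).min(axis=0) + 1e-12).all()

    def test_g_uses_plain_minimum(self):
        reps = [pd.DataFrame([[np.nan, 5.0], [5.0, np.nan]]),
                pd.DataFrame([[np.nan, 2.0], [2.0, np.nan]])]
        agg, _ = aggregate_minimum(reps, "g")
        assert agg.iloc[0, 1] == 2.0
        assert np.isnan(agg.iloc[0, 0])


class TestCovariateStrata:
    def _table(self, ages, sexes=None, ischemia=None):
        n = len(ages)
        return pd.DataFrame(
            {
                "sex": sexes or ["male"] * n,
                "age": ages,
                "ischemia_time": ischemia if ischemia is not None else [100.0] * n,
            },
            index=[f"s{i}" for i in range(n)],
        )

    def test_age_boundaries_inclusive_middle(self):
        t = self._table([30, 50, 55, 59, 70], ischemia=[10, 12, 300, 310, 200])
        strata = covariate_strata(t)
        assert strata["age_lt50"] == ["s0"]
        assert strata["age_50_59"] == ["s1", "s2", "s3"]
        assert strata["age_gt59"] == ["s4"]

    def test_ischemia_two_means_min_max_init(self):
        labels, boundary = ischemia_two_means(np.array([10.0, 12, 300, 310]))
        np.testing.assert_array_equal(labels, [0, 0, 1, 1])
        assert 12 < boundary < 300

    def test_strata_partition_within_each_variable(self):
        rng = np.random.default_rng(9)
        t = self._table(
            ages=rng.integers(20, 80, 50),
            sexes=list(rng.choice(["male", "female"], 50)),
            ischemia=rng.choice([50.0, 900.0], 50),
        )
        strata = covariate_strata(t)
        assert sorted(strata["sex_male"] + strata["sex_female"]) == sorted(t.index)
        assert sorted(strata["age_lt50"] + strata["age_50_59"] + strata["age_gt59"]) == sorted(t.index)
        assert sorted(strata["ischemia_low"] + strata["ischemia_high"]) == sorted(t.index)


class TestInventory:
    @pytest.mark.parametrize(
        "kwargs, total",
        [
            (dict(), 140),  # published configuration
            (dict(n_modalities=1, n_reps=1, n_metrics=1, n_strata=0), 2),
            (dict(n_strata=0), 126),
        ],
    )
    def test_counts(self, kwargs, total):
        inv = matrix_inventory(**kwargs)
        assert inv["total"] == total
        assert inv["per_rep"] + inv["covariate"] + inv["minimum"] == total


@pytest.fixture(scope="module")
def fitted(planted_cohort):
    from cogtex.preprocess import log_quantile_normalize

    norm = log_quantile_normalize(planted_cohort.expr)
    sub_genes = norm.values.index[:20]
    expr = ExpressionMatrix(norm.values.loc[sub_genes], Scale.LOG10P1)
    model = CoexpressionModel(
        expr, planted_cohort.samples["tissue"], metrics=("pearson",),
        modality="tpm", n_per=70, n_reps=3,
    )
    return model, model.fit(seed=1)


class TestModel:
    def test_single_rep_reduces_to_direct_correlation(self, planted_cohort):
        from cogtex.preprocess import log_quantile_normalize

        norm = log_quantile_normalize(planted_cohort.expr)
        expr = ExpressionMatrix(norm.values.iloc[:10], Scale.LOG10P1)
        model = CoexpressionModel(expr, planted_cohort.samples["tissue"],
                                  metrics=("pearson",), modality="tpm",
                                  n_per=70, n_reps=1)
        res = model.fit(seed=2)
        direct = correlation_matrix(expr.values[res.design.samples_for_rep(0)])
        pd.testing.assert_frame_equal(res.per_rep["pearson"][0], direct)
        pd.testing.assert_frame_equal(res.min_matrix("pearson"), direct)

    def test_same_seed_identical_fit(self, fitted):
        model, res = fitted
        res2 = model.fit(seed=1)
        for a, b in zip(res.per_rep["pearson"], res2.per_rep["pearson"]):
            pd.testing.assert_frame_equal(a, b)

    def test_matrices_symmetric_and_min_dominated(self, fitted):
        _, res = fitted
        stack = np.stack([m.to_numpy() for m in res.per_rep["pearson"]])
        agg = res.min_matrix("pearson").to_numpy()
        np.testing.assert_allclose(agg, agg.T)
        assert (np.abs(agg) <= np.abs(stack).min(axis=0) + 1e-12).all()

    def test_summary_and_pair_report(self, fitted):
        _, res = fitted
        text = res.summary()
        assert "pearson" in text and "repetitions:     3" in text
        genes = res.model.expr.gene_ids
        pair = res.pair("pearson", genes[0], genes[1])
        assert len(pair["reps"]) == 3
        assert abs(pair["min"]) <= min(abs(v) for v in pair["reps"]) + 1e-12

    def test_scale_and_modality_validation(self, planted_cohort):
        with pytest.raises(CogtexError, match="LOG10P1"):
            CoexpressionModel(planted_cohort.expr, planted_cohort.samples["tissue"])
        from cogtex.preprocess import log_quantile_normalize

        norm = log_quantile_normalize(planted_cohort.expr)
        with pytest.raises(ConfigError, match="modality"):
            CoexpressionModel(norm, planted_cohort.samples["tissue"], modality="nope")

    def test_opposite_slopes_detected_only_at_system_level(self):
        # two clusters with opposite within-cluster slopes but strongly
        # aligned cluster means: high Pearson on log values, ~0 on z-scores
        rng = np.random.default_rng(11)
        n = 60
        x1 = rng.normal(0, 1, n)
        x2 = rng.normal(5, 1, n)
        g1 = np.concatenate([x1, x2])
        g2 = np.concatenate([-x1, 10 - x2 + 10])  # slope -1 in both clusters
        df = pd.DataFrame([g1, g2], index=["a", "b"],
                          columns=[f"s{j}" for j in range(2 * n)])
        clusters = pd.Series(["C1"] * n + ["C2"] * n, index=df.columns)
        r_sys = correlation_matrix(df).loc["a", "b"]
        r_tis = correlation_matrix(zscore_by_cluster(df, clusters)).loc["a", "b"]
        assert r_sys > 0.8
        assert r_tis < -0.8  # within-cluster slope dominates the z modality

    def test_stratified_estimates_cover_seven_strata(self, planted_cohort):
        from cogtex.preprocess import log_quantile_normalize

        norm = log_quantile_normalize(planted_cohort.expr)
        expr = ExpressionMatrix(norm.values.iloc[:8], Scale.LOG10P1)
        with pytest.warns(UserWarning):
            strata, results = stratify_covariates(
                expr, planted_cohort.samples, planted_cohort.samples["tissue"],
                n_per=20, seed=0,
            )
        assert len(strata) == 7
        assert {m for _, m in results} == {"tpm", "zscore"}
        for (_, _), mat in results.items():
            np.testing.assert_allclose(mat.to_numpy(), mat.to_numpy().T)
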