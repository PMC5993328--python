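import numpy as np
import pandas as pd
import pytest

from _oracles import mann_whitney_exact
from conftest import make_fitness_table
from dmsenv.constraints import (
    EXCLUDED,
    SUBSETS,
    assign_subsets,
    cluster_correlations,
    cross_env_correlation_resample,
    feature_fitness_correlations,
    mann_whitney_u,
    subset_significance,
    subset_significance_test,
    subsetwise_selection,
)
from dmsenv.selection import s_point_estimate, survival_from_fitness_table


def features_frame(ddg, dist, start=1):
    n = len(ddg)
    return pd.DataFrame(
        {
            "position": np.arange(start, start + n),
            "wt": ["A"] * n,
            "mut": ["V"] * n,
            "ddG": ddg,
            "dist_active": dist,
        }
    )


def table_from_f(f_values, start=1, synonymous=False):
    recs = [
        (start + i, "A", "V", synonymous, f, f) if f is not None else (start + i, "A", "V", synonymous, None, None)
        for i, f in enumerate(f_values)
    ]
    return make_fitness_table(recs)


class TestFeatureFitnessCorrelations:
    def test_feature_equal_to_fitness_gives_one(self):
        f = list(np.linspace(-2, 2, 20))
        tables = {"env": table_from_f(f)}
        feats = features_frame(f, [10.0] * 20)
        m = feature_fitness_correlations(tables, feats, feature_cols=["ddG"])
        assert m.r.loc["ddG", "env"] == pytest.approx(1.0)

    def test_permuted_feature_uncorrelated(self):
        rng = np.random.default_rng(0)
        hits = 0
        f = list(rng.normal(size=500))
        tables = {"env": table_from_f(f)}
        for seed in range(20):
            perm = list(np.random.default_rng(seed).permutation(f))
            feats = features_frame(perm, [10.0] * 500)
            m = feature_fitness_correlations(tables, feats, feature_cols=["ddG"])
            hits += abs(m.r.loc["ddG", "env"]) < 0.15
        assert hits >= 19  # >= 95% of seeds

    def test_constant_feature_is_na(self):
        f = list(np.linspace(-2, 2, 20))
        tables = {"env": table_from_f(f)}
        feats = features_frame([1.0] * 20, [10.0] * 20)
        m = feature_fitness_correlations(tables, feats, feature_cols=["ddG"])
        assert np.isnan(m.r.loc["ddG", "env"])

    def test_small_cells_are_na(self):
        f = [0.1, 0.2, 0.3]
        tables = {"env": table_from_f(f)}
        feats = features_frame([1.0, 2.0, 3.0], [5.0, 6.0, 7.0])
        m = feature_fitness_correlations(tables, feats, feature_cols=["ddG"])
        assert np.isnan(m.r.loc["ddG", "env"])  # n < 10


class TestClusterCorrelations:
    def _matrix(self, data, envs):
        from dmsenv.constraints import CorrelationMatrix

        r = pd.DataFrame(data, columns=envs)
        r.index = [f"feat{i}" for i in range(len(data))]
        return CorrelationMatrix(r=r, p=r * 0, n=(r * 0).astype(int))

    def test_identical_columns_adjacent(self):
        m = self._matrix(
            [[0.9, 0.9, -0.5], [0.8, 0.8, -0.1], [-0.7, -0.7, 0.6]],
            ["e1", "e2", "e3"],
        )
        out = cluster_correlations(m)
        i1, i2 = out.col_order.index("e1"), out.col_order.index("e2")
        assert abs(i1 - i2) == 1  # distance 0 -> merged first

    def test_three_point_hand_agglomeration(self):
        # rows at (0,0), (0,1), (0,5): first merge rows 0,1 (d=1)
        m = self._matrix([[0.0, 0.0], [0.0, 1.0], [0.0, 5.0]], ["e1", "e2"])
        out = cluster_correlations(m)
        i0, i1 = out.row_order.index("feat0"), out.row_order.index("feat1")
        assert abs(i0 - i1) == 1

    def test_permutation_leaves_merge_heights_unchanged(self):
        from scipy.cluster.hierarchy import average
        from scipy.spatial.distance import pdist

        rng = np.random.default_rng(1)
        data = rng.normal(size=(6, 4))
        heights = sorted(average(pdist(data)).T[2])
        perm = rng.permutation(6)
        heights_p = sorted(average(pdist(data[perm])).T[2])
        np.testing.assert_allclose(heights, heights_p)


class TestAssignSubsets:
    def test_clear_corner_cases(self):
        rng = np.random.default_rng(5)
        ddg = list(rng.uniform(0, 4, size=99)) + [-5.0]
        dist = list(rng.uniform(5, 35, size=99)) + [39.9]
        feats = features_frame(ddg, dist)
        a = assign_subsets(feats)
        # last mutant: lowest ddG percentile, highest distance -> FB
        assert a.labels.iloc[-1] == "FB"

    def test_band_exclusion(self):
        ddg = list(np.linspace(0, 10, 101))
        dist = list(np.linspace(5, 35, 101))
        feats = features_frame(ddg, dist)
        a = assign_subsets(feats, band=10.0)
        pct = 100 * (np.arange(101) + 1) / 101
        in_band = (pct > 40) & (pct < 60)
        assert (a.labels.to_numpy() == EXCLUDED)[in_band].all()

    def test_uniform_features_match_bruteforce_oracle(self):
        rng = np.random.default_rng(9)
        n = 1000
        ddg = rng.uniform(-1, 5, size=n)
        dist = rng.uniform(3, 40, size=n)
        feats = features_frame(list(ddg), list(dist))
        a = assign_subsets(feats)

        # independent oracle: sort-based percentile ranks + median rules
        def pct_ranks(v):
            order = np.argsort(np.argsort(v))
            return 100.0 * (order + 1) / len(v)

        pg, pd_ = pct_ranks(ddg), pct_ranks(dist)
        mg, md = np.median(ddg), np.median(dist)
        expected = []
        for i in range(n):
            if 40 < pg[i] < 60 or 40 < pd_[i] < 60:
                expected.append(EXCLUDED)
            elif ddg[i] <= mg:
                expected.append("FB" if dist[i] >= md else "FcB")
            else:
                expected.append("cFB" if dist[i] >= md else "cFcB")
        assert a.labels.tolist() == expected
        counts = a.labels.value_counts()
        for subset in SUBSETS:
            assert counts[subset] == pytest.approx(160, abs=40)  # ~ (0.4)^2 * 1000

    def test_monotone_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        ddg = list(rng.uniform(-1, 5, size=200))
        dist = list(rng.uniform(3, 40, size=200))
        a = assign_subsets(features_frame(ddg, dist))
        b = assign_subsets(features_frame(list(np.exp(ddg)), list(np.array(dist) ** 3)))
        assert a.labels.tolist() == b.labels.tolist()

    def test_degenerate_distribution_error(self):
        feats = features_frame([1.0] * 10, list(range(10)))
        with pytest.raises(ValueError, match="degenerate"):
            assign_subsets(feats)


class TestSubsetwiseSelection:
    def test_restriction_to_all_equals_global(self):
        rng = np.random.default_rng(4)
        f = [float(x) if x > -3 else None for x in rng.normal(-1, 2, size=80)]
        table = table_from_f(f)
        syn = table_from_f([0.0] * 20, start=1000, synonymous=True)
        table = pd.concat([table, syn], ignore_index=True)
        feats = features_frame(list(rng.uniform(-1, 5, 80)), list(rng.uniform(3, 40, 80)))
        assignment = assign_subsets(feats)
        assignment.labels[:] = "FB"  # everything in one subset
        subset_s, posteriors = subsetwise_selection({"env": table}, feats, assignment, seed=0)
        fb = subset_s[(subset_s["environment"] == "env") & (subset_s["subset"] == "FB")].iloc[0]
        global_s = s_point_estimate(survival_from_fitness_table(table))
        assert fb["s"] == pytest.approx(global_s, abs=0.05)
        assert fb["n"] == 80

    def test_two_mutant_toy_matches_closed_form(self):
        table = pd.concat(
            [table_from_f([0.5, None]), table_from_f([0.0] * 30, start=100, synonymous=True)],
            ignore_index=True,
        )
        feats = features_frame([0.0, 5.0], [30.0, 10.0])
        assignment = assign_subsets(features_frame(list(np.linspace(-1, 5, 2)), [30.0, 10.0]))
        assignment.labels[:] = ["FB", "cFcB"]
        subset_s, posteriors = subsetwise_selection(
            {"env": table}, feats, assignment, n_draws=40_000, seed=1
        )
        # FB: k=1, n=1 -> E[v] = 2/3; syn: k=30, n=30 -> E[v] = 31/32
        post = posteriors[("env", "FB")]
        assert post.v_non.mean() == pytest.approx(2 / 3, abs=0.01)
        assert post.v_syn.mean() == pytest.approx(31 / 32, abs=0.01)


class TestMannWhitney:
    def test_hand_u_statistic(self):
        assert mann_whitney_u([1, 2], [3, 4]) == 4.0

    def test_identical_vectors_half(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        u, p = subset_significance_test(x, x.copy())
        assert p == pytest.approx(0.5)

    def test_separated_length8_matches_enumeration_oracle(self):
        x = np.arange(8, dtype=float)
        y = x + 100
        u, p = subset_significance_test(x, y)
        u_o, p_o = mann_whitney_exact(x, y)
        assert (u, p) == (u_o, pytest.approx(p_o))
        assert p == pytest.approx(0.5 / 12870)  # mid-p at the extreme

    def test_random_small_samples_match_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            x = rng.integers(0, 5, size=5).astype(float)
            y = rng.integers(0, 5, size=4).astype(float)
            u, p = subset_significance_test(x, y)
            u_o, p_o = mann_whitney_exact(x, y)
            assert u == u_o
            assert p == pytest.approx(p_o)

    def test_subset_significance_frame(self):
        rows = []
        for env in range(5):
            rows += [
                {"environment": f"e{env}", "subset": "FB", "s": 0.01 * env},
                {"environment": f"e{env}", "subset": "cFB", "s": 0.5 + 0.01 * env},
                {"environment": f"e{env}", "subset": "FcB", "s": 0.3 + 0.01 * env},
                {"environment": f"e{env}", "subset": "cFcB", "s": 0.8 + 0.01 * env},
            ]
        out = subset_significance(pd.DataFrame(rows))
        assert set(out["subset"]) == {"cFB", "FcB", "cFcB"}
        assert (out["p_one_sided"] < 0.05).all()


class TestCrossEnvResample:
    def _setup(self, f_a, f_b, n=40):
        table_a = table_from_f(f_a)
        table_b = table_from_f(f_b)
        rng = np.random.default_rng(0)
        feats = features_frame(list(rng.uniform(-1, 5, n)), list(rng.uniform(3, 40, n)))
        assignment = assign_subsets(feats, band=0.0)
        return table_a, table_b, feats, assignment

    def test_perfect_correlation_degenerate_at_one(self):
        f = list(np.linspace(-3, 3, 40))
        a, b, feats, assignment = self._setup(f, f)
        res = cross_env_correlation_resample(a, b, feats, assignment, n_boot=200, seed=0)
        for subset, draws in res.draws.items():
            assert np.allclose(draws[~np.isnan(draws)], 1.0)
        ok = res.summary.dropna(subset=["median"])
        assert (ok["median"] == 1.0).all()

    def test_small_subsets_na(self):
        f = list(np.linspace(-3, 3, 6))
        a, b, feats, assignment = self._setup(f, f, n=6)
        res = cross_env_correlation_resample(a, b, feats, assignment, n_boot=50, seed=0)
        assert res.summary["median"].isna().any()

    def test_seed_determinism(self):
        rng = np.random.default_rng(12)
        f_a = list(rng.normal(size=40))
        f_b = list(0.8 * np.array(f_a) + rng.normal(scale=0.4, size=40))
        a, b, feats, assignment = self._setup(f_a, f_b)
        r1 = cross_env_correlation_resample(a, b, feats, assignment, n_boot=100, seed=5)
        r2 = cross_env_correlation_resample(a, b, feats, assignment, n_boot=100, seed=5)
        for subset in r1.draws:
            np.testing.assert_array_equal(r1.draws[subset], r2.draws[subset])
        pd.testing.assert_frame_equal(r1.contrasts, r2.contrasts)
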