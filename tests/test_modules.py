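"""Z-scoring, module clustering, stage labels, correlations and overlap statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from sumowaves import ConfigurationError, ParameterError, ValidationError, modules, simulate, slam


class TestZscoreRows:
    def test_simple_row(self):
        z = modules.zscore_rows(pd.DataFrame([[1.0, 2.0, 3.0]]))
        assert np.allclose(z.values.to_numpy(), [[-1.0, 0.0, 1.0]])

    def test_constant_row_zeroed_and_flagged(self):
        df = pd.DataFrame([[5.0, 5.0, 5.0]], index=["flat"])
        z = modules.zscore_rows(df)
        assert (z.values.to_numpy() == 0).all()
        assert z.constant_rows == ("flat",)

    def test_random_matrix_moments(self):
        rng = np.random.default_rng(0)
        z = modules.zscore_rows(pd.DataFrame(rng.normal(size=(100, 4))))
        assert np.abs(z.values.mean(axis=1)).max() < 1e-12
        assert np.abs(z.values.std(axis=1, ddof=1) - 1).max() < 1e-12

    def test_idempotent_on_nonconstant_rows(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(20, 5)))
        once = modules.zscore_rows(df).values
        twice = modules.zscore_rows(once).values
        assert np.allclose(once, twice, atol=1e-12)


class TestClusterModules:
    def test_separable_profiles_recovered_exactly(self):
        a = np.tile([5.0, -5.0, 0.0, 0.0], (10, 1))
        b = np.tile([-5.0, 5.0, 0.0, 0.0], (10, 1))
        rng = np.random.default_rng(2)
        df = pd.DataFrame(np.vstack([a, b]) + rng.normal(0, 0.1, (20, 4)))
        assignment = modules.cluster_modules(df, k=2, seed=0)
        truth = [0] * 10 + [1] * 10
        assert adjusted_rand_score(truth, assignment.labels) == 1.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(50, 4)))
        a1 = modules.cluster_modules(df, k=4, seed=9)
        a2 = modules.cluster_modules(df, k=4, seed=9)
        assert (a1.labels == a2.labels).all()

    def test_k_exceeding_rows_rejected(self):
        with pytest.raises(ParameterError):
            modules.cluster_modules(pd.DataFrame(np.eye(3)), k=5)


class TestAssignStage:
    @pytest.mark.parametrize(
        "centroid,stage",
        [
            ((2.0, 0.0, 0.0, -1.0), "PA"),
            ((-1.0, 0.0, 0.0, 2.0), "MA"),
            ((0.0, 2.0, 2.0, 0.0), "CE"),
        ],
    )
    def test_argmax_over_stage_means(self, centroid, stage):
        s = pd.Series(centroid, index=["d-2", "d1", "d3", "d7"])
        assert modules.assign_stage(s) == stage

    def test_tie_breaks_to_earlier_stage(self, caplog):
        s = pd.Series([1.0, 1.0, 1.0, 1.0], index=["d-2", "d1", "d3", "d7"])
        assert modules.assign_stage(s) == "PA"

    def test_unmapped_time_point_rejected(self):
        s = pd.Series([1.0, 2.0], index=["d-2", "d99"])
        with pytest.raises(ConfigurationError):
            modules.assign_stage(s)

    def test_stage_labels_invariant_under_cluster_relabeling(self):
        rng = np.random.default_rng(4)
        profiles = {
            "PA": [3.0, 0.0, 0.0, 0.0], "CE": [0.0, 3.0, 3.0, 0.0],
            "MA": [0.0, 0.0, 0.0, 3.0],
        }
        rows, truth = [], []
        for stage, prof in profiles.items():
            for _ in range(15):
                rows.append(np.asarray(prof) + rng.normal(0, 0.2, 4))
                truth.append(stage)
        df = pd.DataFrame(rows, columns=["d-2", "d1", "d3", "d7"])
        for seed in (0, 1, 2):  # different seeds may permute cluster ids
            a = modules.assign_stages(modules.cluster_modules(df, k=3, seed=seed))
            got = [a.stages[int(m)] for m in a.labels]
            assert got == truth


class TestProfileCorrelation:
    def test_identical_and_negated_profiles(self):
        a = pd.DataFrame([[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]], index=["x", "y"])
        b = pd.DataFrame([[2.0, 4.0, 6.0, 8.0], [-1.0, -2.0, -3.0, -4.0]], index=["x", "y"])
        out = modules.profile_correlation(a, b).set_index("feature_id")
        assert out.loc["x", "r"] == pytest.approx(1.0)
        assert out.loc["y", "r"] == pytest.approx(-1.0)
        bins = modules.correlation_bins(out["r"])
        assert bins[9] == 1 and bins[0] == 1 and bins.sum() == 2

    def test_zero_variance_profile_undefined(self):
        a = pd.DataFrame([[1.0, 1.0, 1.0]], index=["x"])
        b = pd.DataFrame([[1.0, 2.0, 3.0]], index=["x"])
        out = modules.profile_correlation(a, b)
        assert not out["defined"].iloc[0]
        assert modules.correlation_bins(out["r"]).sum() == 0

    def test_too_few_matched_points_rejected(self):
        a = pd.DataFrame([[1.0, 2.0]], columns=["t1", "t2"])
        with pytest.raises(ParameterError):
            modules.profile_correlation(a, a)

    def test_planted_rho_mean_matches_monte_carlo_oracle(self):
        """Mean sample r over many planted rho=0.8 features matches an MC oracle."""
        rho, n_points, n_features = 0.8, 4, 1000
        cov = np.array([[1.0, rho], [rho, 1.0]])

        def draw(rng, n_feat):
            z = rng.multivariate_normal([0, 0], cov, size=(n_feat, n_points))
            return z[:, :, 0], z[:, :, 1]

        # independent oracle: per-pair np.corrcoef on a large separate sample
        rng_oracle = np.random.default_rng(100)
        a_o, b_o = draw(rng_oracle, 20000)
        r_oracle = np.array([np.corrcoef(x, y)[0, 1] for x, y in zip(a_o, b_o)])
        expected_mean, sd = r_oracle.mean(), r_oracle.std(ddof=1)

        rng = np.random.default_rng(7)
        a, b = draw(rng, n_features)
        idx = [f"f{i}" for i in range(n_features)]
        cols = [f"t{j}" for j in range(n_points)]
        out = modules.profile_correlation(
            pd.DataFrame(a, index=idx, columns=cols),
            pd.DataFrame(b, index=idx, columns=cols),
        )
        se = sd / math.sqrt(n_features)
        assert abs(out["r"].mean() - expected_mean) <= 3 * se


def _oracle_hypergeom_upper(k, n, m, N):
    total = math.comb(N, m)
    return sum(math.comb(n, i) * math.comb(N - n, m - i) for i in range(k, min(n, m) + 1)) / total


class TestHypergeom:
    def test_small_exact_example(self):
        assert modules.hypergeom_overrep(2, 2, 2, 4) == pytest.approx(1 / 6, abs=1e-12)

    def test_k_zero_is_one(self):
        assert modules.hypergeom_overrep(0, 5, 5, 20) == pytest.approx(1.0)

    def test_matches_bruteforce_summation_grid(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            N = int(rng.integers(5, 60))
            n = int(rng.integers(1, N + 1))
            m = int(rng.integers(1, N + 1))
            k = int(rng.integers(max(0, n + m - N), min(n, m) + 1))
            got = modules.hypergeom_overrep(k, n, m, N)
            assert got == pytest.approx(_oracle_hypergeom_upper(k, n, m, N), abs=1e-12)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValidationError):
            modules.hypergeom_overrep(5, 2, 2, 4)


def _oracle_bh(p):
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [None] * n
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        val = min(p[i] * n / rank, prev)
        adj[i] = val
        prev = val
    return adj


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert modules.bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_closed_form_triple(self):
        assert np.allclose(modules.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_matches_stepup_oracle_and_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(13)
        for _ in range(20)  :
            p = rng.uniform(size=int(rng.integers(1, 80)))
            ours = modules.bh_adjust(p)
            assert np.allclose(ours, _oracle_bh(list(p)), atol=1e-12)
            theirs = sm.multipletests(p, method="fdr_bh")[1]
            assert np.allclose(ours, theirs, atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30),
           st.randoms(use_true_random=False))
    def test_stable_under_permutation(self, p, rnd):
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        direct = modules.bh_adjust(p)
        permuted = modules.bh_adjust([p[i] for i in perm])
        assert np.allclose([direct[i] for i in perm], permuted, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            modules.bh_adjust([1.5])


class TestNbLrt:
    def _groups(self, n_groups, n_rep):
        return [np.arange(g * n_rep, (g + 1) * n_rep) for g in range(n_groups)]

    def test_null_pvalues_roughly_uniform(self):
        # many replicates per group so the chi-square asymptotics apply
        rng = np.random.default_rng(19)
        groups = self._groups(4, 25)
        r, mu = 10.0, 100.0
        pvals = [
            modules.nb_lrt(rng.negative_binomial(r, r / (r + mu), size=100), groups)
            for _ in range(400)
        ]
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 1e-3  # no gross miscalibration

    def test_strong_shift_detected(self):
        rng = np.random.default_rng(23)
        groups = self._groups(2, 3)
        r = 1 / 0.05
        y = np.concatenate([
            rng.negative_binomial(r, r / (r + 100.0), size=3),
            rng.negative_binomial(r, r / (r + 1000.0), size=3),
        ])
        assert modules.nb_lrt(y, groups) < 1e-4

    def test_poisson_limit_agrees_with_poisson_lrt(self):
        """At tiny dispersion, -log10 p tracks an explicit Poisson LRT within 10%."""
        rng = np.random.default_rng(29)
        groups = self._groups(2, 5)
        y = np.concatenate([rng.poisson(100.0, 5), rng.poisson(160.0, 5)])

        def poisson_lrt(y):
            mu_f = np.concatenate([np.full(5, y[:5].mean()), np.full(5, y[5:].mean())])
            mu_r = np.full(10, y.mean())
            stat = 2 * (stats.poisson.logpmf(y, mu_f).sum() - stats.poisson.logpmf(y, mu_r).sum())
            return stats.chi2.sf(stat, 1)

        p_ours = modules.nb_lrt(y, groups)
        p_pois = poisson_lrt(y)
        assert abs(np.log10(p_ours) - np.log10(p_pois)) <= 0.1 * abs(np.log10(p_pois))

    def test_all_zero_feature_p_one(self):
        assert modules.nb_lrt(np.zeros(6), self._groups(2, 3)) == 1.0


class TestOverlapReport:
    def test_two_set_example(self):
        rep = modules.overlap_report({"A": {"a", "b"}, "B": {"b", "c"}})
        assert rep[("A",)] == 1 and rep[("B",)] == 1 and rep[("A", "B")] == 1

    def test_disjoint_sets(self):
        rep = modules.overlap_report({"A": {"a"}, "B": {"b"}})
        assert rep[("A", "B")] == 0

    def test_matches_bruteforce_set_algebra(self):
        rng = np.random.default_rng(31)
        universe = list(range(50))
        sets = {
            name: set(rng.choice(universe, size=rng.integers(5, 30), replace=False).tolist())
            for name in ("A", "B", "C")
        }
        rep = modules.overlap_report(sets)
        for x in universe:
            membership = tuple(sorted(n for n in sets if x in sets[n]))
            if membership:
                rep[membership] -= 1
        assert all(v == 0 for v in rep.values())


def test_planted_modules_recovered_through_full_stack():
    """Generator -> size factors -> normalize -> log2 -> Z -> k-means -> stages."""
    cfg = simulate.SimConfig(seed=0, n_genes=60)
    counts, truth, _ = simulate.gen_timecourse_counts(cfg)
    factors = slam.size_factors(counts)
    normed = slam.normalize_counts(counts, factors)
    averaged = slam.replicate_average(normed)[list(cfg.time_points)]
    z = modules.zscore_rows(np.log2(averaged + 1.0))
    assignment = modules.assign_stages(modules.cluster_modules(z, k=3, seed=0))
    truth = truth.set_index("gene_id")
    ari = adjusted_rand_score(truth["truth_module"], assignment.labels[truth.index])
    stages = pd.Series(
        [assignment.stages[int(m)] for m in assignment.labels], index=assignment.labels.index
    )
    accuracy = (stages[truth.index] == truth["truth_stage"]).mean()
    assert ari >= 0.9
    assert accuracy >= 0.9
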