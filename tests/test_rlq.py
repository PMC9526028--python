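import numpy as np
import pandas as pd
import pytest

from ecofilter.data_model import CommunityMatrix, SiteTable, TraitTable
from ecofilter.rlq import (
    correspondence_analysis,
    hill_smith,
    permutation_test,
    rlq,
    run_rlq,
    sequential_combine,
    total_coinertia,
    weighted_pca_env,
)


def make_cm(abund):
    abund = np.asarray(abund)
    return CommunityMatrix([f"s{i}" for i in range(abund.shape[0])],
                           [f"sp{j}" for j in range(abund.shape[1])], abund)


def make_traits(df, kinds):
    return TraitTable(df, {k: {"kind": v, "weight": 1.0}
                           for k, v in kinds.items()})


class TestCA:
    def test_diagonal_table_perfect_association(self):
        ca = correspondence_analysis(make_cm([[5, 0], [0, 5]]))
        assert len(ca.eigenvalues) == 1
        assert ca.eigenvalues[0] == pytest.approx(1.0)

    def test_direct_eigendecomposition_oracle(self):
        # chi-square-metric eigenproblem solved independently
        L = np.array([[4.0, 1, 2], [2, 6, 1], [1, 2, 5]])
        ca = correspondence_analysis(make_cm(L))
        P = L / L.sum()
        r, c = P.sum(1), P.sum(0)
        S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        eig_oracle = np.sort(np.linalg.eigvalsh(S @ S.T))[::-1]
        eig_oracle = eig_oracle[eig_oracle > 1e-12]
        np.testing.assert_allclose(ca.eigenvalues, eig_oracle, atol=1e-10)

    def test_independence_table_zero_eigenvalues(self):
        # rank-1 table = outer product of margins
        rows = np.array([2, 3, 5])
        cols = np.array([1, 4])
        ca = correspondence_analysis(make_cm(np.outer(rows, cols)))
        assert len(ca.eigenvalues) == 0

    def test_eigenvalues_bounded_by_one(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            L = rng.integers(0, 6, (4, 3))
            if (L.sum(0) == 0).any() or (L.sum(1) == 0).any():
                continue
            ca = correspondence_analysis(make_cm(L))
            assert (ca.eigenvalues <= 1 + 1e-10).all()
            assert (ca.eigenvalues >= -1e-12).all()

    def test_mass_and_score_invariants(self):
        rng = np.random.default_rng(1)
        L = rng.integers(1, 9, (6, 4))
        ca = correspondence_analysis(make_cm(L))
        assert ca.row_weights.sum() == pytest.approx(1.0)
        assert ca.col_weights.sum() == pytest.approx(1.0)
        for k, lam in enumerate(ca.eigenvalues):
            assert ca.row_weights @ ca.row_scores[:, k] == \
                pytest.approx(0.0, abs=1e-10)
            assert ca.row_weights @ ca.row_scores[:, k] ** 2 == \
                pytest.approx(lam, abs=1e-10)

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError, match="filter"):
            correspondence_analysis(make_cm([[1, 2], [0, 0]]))

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            correspondence_analysis(make_cm([[0, 0], [0, 0]]))


class TestWeightedPca:
    def test_constant_column_errors(self):
        env = pd.DataFrame({"a": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="variance"):
            weighted_pca_env(env, np.full(3, 1 / 3))

    def test_weighted_moments(self):
        rng = np.random.default_rng(2)
        env = pd.DataFrame({"a": rng.normal(size=8),
                            "b": rng.uniform(size=8)})
        w = rng.dirichlet(np.ones(8))
        t = weighted_pca_env(env, w)
        for j in range(2):
            assert w @ t.table[:, j] == pytest.approx(0.0, abs=1e-10)
            assert w @ t.table[:, j] ** 2 == pytest.approx(1.0, abs=1e-10)

    def test_equal_weights_reduce_to_plain_zscores(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=10)
        env = pd.DataFrame({"a": x})
        t = weighted_pca_env(env, np.full(10, 0.1))
        z = (x - x.mean()) / x.std(ddof=0)
        np.testing.assert_allclose(t.table[:, 0], z, atol=1e-10)


class TestHillSmith:
    def test_all_quantitative_reduces_to_weighted_pca(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"a": rng.normal(size=7), "b": rng.uniform(size=7)},
                          index=[f"sp{i}" for i in range(7)])
        tt = make_traits(df, {"a": "continuous", "b": "continuous"})
        w = rng.dirichlet(np.ones(7))
        hs = hill_smith(tt, w)
        pca = weighted_pca_env(df, w)
        np.testing.assert_allclose(hs.table, pca.table, atol=1e-10)
        np.testing.assert_allclose(hs.col_metric, pca.col_metric)

    def test_all_nominal_matches_mca_oracle(self):
        # MCA oracle: CA of the indicator matrix. With Q nominal variables
        # and the (indicator/p_m - 1, metric p_m) convention, the
        # cross-product eigenvalues equal Q times the MCA eigenvalues.
        df = pd.DataFrame({"u": ["a", "a", "b", "b", "c", "c"],
                           "v": ["x", "y", "x", "y", "x", "y"]},
                          index=[f"sp{i}" for i in range(6)])
        tt = make_traits(df, {"u": "nominal", "v": "nominal"})
        w = np.full(6, 1 / 6)
        hs = hill_smith(tt, w)
        C = (hs.table * w[:, None]).T @ hs.table  # weighted cross-product
        C = np.sqrt(hs.col_metric)[:, None] * C * np.sqrt(hs.col_metric)
        eig = np.sort(np.linalg.eigvalsh(C))[::-1]
        eig = eig[eig > 1e-10]

        indicator = pd.get_dummies(df).astype(int).to_numpy()
        mca = correspondence_analysis(make_cm(indicator))
        q = 2  # number of nominal variables
        np.testing.assert_allclose(eig / q, mca.eigenvalues, atol=1e-10)

    def test_relabeling_categories_leaves_eigenvalues_unchanged(self):
        rng = np.random.default_rng(5)
        L = rng.integers(1, 5, (8, 6))
        cm = make_cm(L)
        env = pd.DataFrame({"e": rng.normal(size=8)}, index=cm.site_ids)
        df = pd.DataFrame({"u": rng.choice(list("abc"), 6),
                           "c": rng.normal(size=6)}, index=cm.species_ids)
        relabel = {"a": "zebra", "b": "yak", "c": "xerus"}
        df2 = df.assign(u=df["u"].map(relabel))
        kinds = {"u": "nominal", "c": "continuous"}
        ca = correspondence_analysis(cm)
        env_t = weighted_pca_env(env, ca.row_weights)
        r1 = rlq(env_t, ca, hill_smith(make_traits(df, kinds), ca.col_weights))
        r2 = rlq(env_t, ca, hill_smith(make_traits(df2, kinds), ca.col_weights))
        np.testing.assert_allclose(r1.eigenvalues, r2.eigenvalues, atol=1e-10)

    def test_zero_frequency_level_dropped_with_warning(self):
        df = pd.DataFrame({"u": ["a", "a", "b"]},
                          index=[f"sp{i}" for i in range(3)])
        tt = make_traits(df, {"u": "nominal"})
        with pytest.warns(UserWarning, match="zero weighted"):
            hs = hill_smith(tt, np.array([0.5, 0.5, 0.0]))
        assert hs.table.shape[1] == 1  # level "b" dropped

    def test_weight_length_mismatch(self):
        df = pd.DataFrame({"u": ["a", "b"]}, index=["sp0", "sp1"])
        with pytest.raises(ValueError):
            hill_smith(make_traits(df, {"u": "nominal"}), np.ones(3) / 3)


def random_setup(rng, n=10, m=6, n_env=2, nominal=True):
    L = rng.integers(0, 5, (n, m))
    L[L.sum(1) == 0, 0] = 1
    L[:, L.sum(0) == 0] += 1
    cm = make_cm(L)
    env = pd.DataFrame(
        {f"e{k}": rng.normal(size=n) for k in range(n_env)},
        index=cm.site_ids)
    cols = {"c": rng.normal(size=m)}
    kinds = {"c": "continuous"}
    if nominal:
        cols["u"] = rng.choice(list("ab"), m)
        kinds["u"] = "nominal"
    traits = make_traits(pd.DataFrame(cols, index=cm.species_ids), kinds)
    return cm, env, traits


class TestRlq:
    def test_one_env_one_trait_equals_fourth_corner_squared(self):
        rng = np.random.default_rng(6)
        cm, env, traits = random_setup(rng, n_env=1, nominal=False)
        ca = correspondence_analysis(cm)
        env_t = weighted_pca_env(env, ca.row_weights)
        trait_t = hill_smith(traits, ca.col_weights)
        res = rlq(env_t, ca, trait_t)
        # direct fourth-corner statistic between the standardized variables
        x = env_t.table[:, 0]
        y = trait_t.table[:, 0]
        r, c = ca.row_weights, ca.col_weights
        fc = sum(r[i] * c[j] * ca.standardized[i, j] * x[i] * y[j]
                 for i in range(cm.n_sites) for j in range(cm.n_species))
        assert res.eigenvalues[0] == pytest.approx(fc**2, abs=1e-10)
        assert res.total_coinertia == pytest.approx(fc**2, abs=1e-10)

    def test_trace_identity(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            cm, env, traits = random_setup(rng)
            ca = correspondence_analysis(cm)
            env_t = weighted_pca_env(env, ca.row_weights)
            trait_t = hill_smith(traits, ca.col_weights)
            res = rlq(env_t, ca, trait_t)
            direct = total_coinertia(env_t, ca, trait_t)
            assert res.eigenvalues.sum() == pytest.approx(direct, abs=1e-8)
            assert res.total_coinertia == pytest.approx(direct, abs=1e-8)

    def test_eigenvalues_nonnegative_decreasing(self):
        rng = np.random.default_rng(8)
        cm, env, traits = random_setup(rng, n=12, m=8, n_env=3)
        ca = correspondence_analysis(cm)
        res = rlq(weighted_pca_env(env, ca.row_weights), ca,
                  hill_smith(traits, ca.col_weights))
        eig = res.eigenvalues
        assert (eig >= -1e-12).all()
        assert (np.diff(eig) <= 1e-12).all()

    def test_constant_trait_column_errors(self):
        rng = np.random.default_rng(9)
        cm, env, _ = random_setup(rng, nominal=False)
        bad = make_traits(
            pd.DataFrame({"c": np.ones(cm.n_species)}, index=cm.species_ids),
            {"c": "continuous"})
        ca = correspondence_analysis(cm)
        with pytest.raises(ValueError, match="variance"):
            hill_smith(bad, ca.col_weights)

    def test_orthogonal_rotation_invariance_of_coinertia(self):
        rng = np.random.default_rng(10)
        cm, env, traits = random_setup(rng, n_env=2)
        ca = correspondence_analysis(cm)
        trait_t = hill_smith(traits, ca.col_weights)
        base = total_coinertia(weighted_pca_env(env, ca.row_weights), ca,
                               trait_t)
        theta = 0.83
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        w = ca.row_weights
        # rotate the (already weighted-standardized) columns, bypassing
        # re-standardization: rotation preserves the weighted metric
        from ecofilter.rlq import OrdinationTriplet

        zt = weighted_pca_env(env, w)
        rotated = OrdinationTriplet(zt.table @ R, w, zt.col_metric,
                                    ["r1", "r2"])
        assert total_coinertia(rotated, ca, trait_t) == \
            pytest.approx(base, abs=1e-10)

    def test_simultaneous_reordering_invariance(self):
        rng = np.random.default_rng(11)
        cm, env, traits = random_setup(rng)
        ca = correspondence_analysis(cm)
        r1 = rlq(weighted_pca_env(env, ca.row_weights), ca,
                 hill_smith(traits, ca.col_weights))
        pi = rng.permutation(cm.n_sites)
        pj = rng.permutation(cm.n_species)
        cm2 = CommunityMatrix([cm.site_ids[i] for i in pi],
                              [cm.species_ids[j] for j in pj],
                              cm.abundance[np.ix_(pi, pj)])
        ca2 = correspondence_analysis(cm2)
        r2 = rlq(weighted_pca_env(env.iloc[pi], ca2.row_weights), ca2,
                 hill_smith(traits.subset(cm2.species_ids), ca2.col_weights))
        np.testing.assert_allclose(r1.eigenvalues, r2.eigenvalues, atol=1e-10)

    def test_dimension_mismatch_errors(self):
        rng = np.random.default_rng(12)
        cm, env, traits = random_setup(rng)
        ca = correspondence_analysis(cm)
        bad_env = weighted_pca_env(env.iloc[:5],
                                   np.full(5, 0.2))
        with pytest.raises(ValueError, match="sites"):
            rlq(bad_env, ca, hill_smith(traits, ca.col_weights))

    def test_normed_species_scores_unit_norm(self):
        rng = np.random.default_rng(13)
        cm, env, traits = random_setup(rng)
        ca = correspondence_analysis(cm)
        res = rlq(weighted_pca_env(env, ca.row_weights), ca,
                  hill_smith(traits, ca.col_weights))
        for k in range(len(res.eigenvalues)):
            norm = ca.col_weights @ res.species_scores_normed.iloc[:, k]**2
            assert norm == pytest.approx(1.0, abs=1e-8)


def study_tables(rng, n=16, m=8, coupled=False):
    imp = rng.uniform(0, 0.9, n)
    closed = (1 - imp) * rng.uniform(0.2, 0.6, n)
    sites = SiteTable(pd.DataFrame({
        "impervious_250": imp, "open_green_250": 1 - imp - closed,
        "closed_green_250": closed,
    }, index=[f"s{i}" for i in range(n)]), (250,))
    mu = rng.uniform(0, 1, m)
    if coupled:
        lam = np.exp(2.0 - 18.0 * (mu[None, :] - imp[:, None]) ** 2)
    else:
        lam = np.full((n, m), 2.0)
    L = rng.poisson(lam)
    L[L.sum(1) == 0, 0] = 1
    L[:, L.sum(0) == 0] += 1
    cm = make_cm(L)
    traits = make_traits(
        pd.DataFrame({"mu": mu, "u": rng.choice(list("ab"), m)},
                     index=cm.species_ids),
        {"mu": "continuous", "u": "nominal"})
    return cm, sites, traits


class TestPermutationTest:
    def test_p_at_least_lower_bound(self):
        rng = np.random.default_rng(14)
        cm, sites, traits = study_tables(rng)
        res = permutation_test(cm, sites, traits, "model2", n_perm=99, rng=0)
        assert res.p_value >= 1 / 100

    def test_bad_model_and_nperm(self):
        rng = np.random.default_rng(15)
        cm, sites, traits = study_tables(rng)
        with pytest.raises(ValueError):
            permutation_test(cm, sites, traits, "model9", n_perm=9)
        with pytest.raises(ValueError):
            permutation_test(cm, sites, traits, "model2", n_perm=0)

    def test_power_on_strongly_coupled_toy(self):
        # trait equals the species' environmental optimum; 20 sites x 10 sp
        rng = np.random.default_rng(16)
        cm, sites, traits = study_tables(rng, n=20, m=10, coupled=True)
        p2 = permutation_test(cm, sites, traits, "model2", n_perm=999,
                              rng=1).p_value
        p4 = permutation_test(cm, sites, traits, "model4", n_perm=999,
                              rng=2).p_value
        assert sequential_combine(p2, p4) <= 0.01

    def test_model4_invariant_to_trait_relabeling(self):
        rng = np.random.default_rng(17)
        cm, sites, traits = study_tables(rng)
        relabeled = TraitTable(
            traits.traits.assign(u=traits.traits["u"].map(
                {"a": "left", "b": "right"})),
            dict(traits.variable_spec))
        r1 = permutation_test(cm, sites, traits, "model4", n_perm=49, rng=3)
        r2 = permutation_test(cm, sites, relabeled, "model4", n_perm=49, rng=3)
        np.testing.assert_allclose(r1.permuted, r2.permuted, atol=1e-10)
        assert r1.p_value == r2.p_value

    def test_model2_invariant_to_env_affine_transform(self):
        rng = np.random.default_rng(18)
        cm, sites, traits = study_tables(rng)
        df = sites.data.copy()
        # affine transform of one environment column (validation skipped
        # via empty scales: the transformed columns are no longer proportions)
        df["impervious_250"] = df["impervious_250"] * 3.0 + 0.5
        r1 = permutation_test(cm, sites, traits, "model2", n_perm=49, rng=4)
        r2 = permutation_test(cm, SiteTable(df, ()), traits, "model2",
                              n_perm=49, rng=4)
        np.testing.assert_allclose(r1.permuted, r2.permuted, atol=1e-8)

    def test_run_rlq_wrapper(self):
        rng = np.random.default_rng(19)
        cm, sites, traits = study_tables(rng)
        res = run_rlq(cm, sites, traits, 250)
        assert res.total_coinertia == pytest.approx(
            res.eigenvalues.sum(), abs=1e-8)


class TestSequentialCombine:
    def test_max_rule(self):
        assert sequential_combine(0.01, 0.99) == 0.99
        assert sequential_combine(0.03, 0.04) == 0.04

    def test_matches_decision_rule_oracle(self):
        # reject at alpha iff BOTH component tests reject
        rng = np.random.default_rng(20)
        alpha = 0.05
        for _ in range(1000):
            p2, p4 = rng.uniform(0.001, 1, 2)
            combined = sequential_combine(p2, p4)
            assert (combined < alpha) == (p2 < alpha and p4 < alpha)

    def test_bounds(self):
        with pytest.raises(ValueError):
            sequential_combine(0.0, 0.5)
        with pytest.raises(ValueError):
            sequential_combine(0.5, 1.5)
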