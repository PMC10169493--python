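import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from sklearn.metrics import adjusted_rand_score

from enterolink import SimConfig, WgcnaParams, fit_modules, module_trait_correlation
from enterolink.simulate import simulate_metabolome
from enterolink.wgcna import (
    _scale_free_fit,
    adjacency,
    cor_pvalue_student,
    detect_modules,
    merge_modules,
    module_eigengenes,
    pick_soft_power,
    tom_similarity,
)


def _frame(X):
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, index=[f"s{i}" for i in range(X.shape[0])], columns=[f"f{j}" for j in range(X.shape[1])])


def _planted(seed, n_blocks=5, per_block=20, rho=0.8, n=12):
    cfg = SimConfig(
        n_type1=n // 2, n_type2=n - n // 2, within_block_cor=rho,
        n_features={"rumen_metab": n_blocks * per_block, "serum_metab": 10, "milk_metab": 10},
        n_blocks={"rumen_metab": n_blocks, "serum_metab": 2, "milk_metab": 2},
        seed=seed,
    )
    om, truth = simulate_metabolome(cfg, "rumen_metab")
    return om.data, pd.Series(truth.block_map["rumen_metab"])


class TestAdjacency:
    def test_negative_correlation_zeroed(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        X = _frame(np.column_stack([x, -x + np.array([0.1, -0.2, 0.3, -0.1, 0.2, -0.3])]))
        a = adjacency(X, beta=6)
        assert a.iloc[0, 1] == 0.0

    def test_power_law_applied_to_positive_correlation(self, rng):
        X = _frame(rng.normal(size=(30, 4)))
        c = np.corrcoef(X.to_numpy(), rowvar=False)
        a = adjacency(X, beta=3)
        i, j = 0, 1
        expected = max(c[i, j], 0.0) ** 3
        assert a.iloc[i, j] == pytest.approx(expected)

    def test_perfect_correlation_unit_adjacency(self):
        x = np.arange(8.0)
        X = _frame(np.column_stack([x, 2 * x + 1]))
        for beta in (1, 6, 12):
            assert adjacency(X, beta).iloc[0, 1] == pytest.approx(1.0)


class TestTom:
    def test_identical_neighbor_profiles_unit_overlap(self):
        # nodes 0,1 joined with weight 1 and sharing identical binary
        # neighbourhoods: full topological overlap
        A = np.array(
            [[1, 1, 1.0, 1.0], [1, 1, 1.0, 1.0], [1.0, 1.0, 1, 0.0], [1.0, 1.0, 0.0, 1]]
        )
        tom = tom_similarity(pd.DataFrame(A))
        assert tom.iloc[0, 1] == pytest.approx(1.0)

    def test_isolated_pair_zero_overlap(self):
        A = np.eye(4)
        tom = tom_similarity(pd.DataFrame(A))
        assert tom.iloc[0, 1] == 0.0

    def test_hand_computed_four_node_case(self):
        A = np.array(
            [
                [1.0, 0.6, 0.3, 0.0],
                [0.6, 1.0, 0.5, 0.2],
                [0.3, 0.5, 1.0, 0.4],
                [0.0, 0.2, 0.4, 1.0],
            ]
        )
        tom = tom_similarity(pd.DataFrame(A))
        # direct formula for (0,1): L = a02*a21 + a03*a31, k0 = .9, k1 = 1.3
        L = 0.3 * 0.5 + 0.0 * 0.2
        expected = (L + 0.6) / (min(0.9, 1.3) + 1 - 0.6)
        assert tom.iloc[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_range_symmetry_diagonal(self, rng):
        A = rng.random((10, 10))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        tom = tom_similarity(pd.DataFrame(A)).to_numpy()
        assert tom.min() >= 0.0 and tom.max() <= 1.0
        assert np.allclose(tom, tom.T)
        assert np.allclose(np.diag(tom), 1.0)

    def test_asymmetric_input_rejected(self, rng):
        A = rng.random((5, 5))
        with pytest.raises(ValueError):
            tom_similarity(pd.DataFrame(A))


class TestDetectModules:
    def test_two_perfect_blocks_recovered(self, rng):
        t = rng.normal(size=12)
        u = rng.normal(size=12)
        X = _frame(np.column_stack([np.outer(t, np.ones(6)), np.outer(u, np.ones(6))])
                   + rng.normal(0, 0.01, size=(12, 12)))
        params = WgcnaParams(beta=6, min_module_size=3)
        ms = fit_modules(X, params)
        assert ms.n_modules == 2
        a = ms.assignment
        assert a.iloc[:6].nunique() == 1 and a.iloc[6:].nunique() == 1
        assert a.iloc[0] != a.iloc[-1]

    def test_min_size_above_feature_count_all_unassigned(self, rng):
        X = _frame(rng.normal(size=(10, 6)))
        adj = adjacency(X, 6)
        assignment = detect_modules(1 - tom_similarity(adj), WgcnaParams(beta=6, min_module_size=50))
        assert (assignment == 0).all()

    def test_planted_five_blocks_recovered(self):
        """ARI >= 0.8 against the planted block map at rho = 0.8, over seeds."""
        aris = []
        for seed in range(5):
            X, blocks = _planted(seed)
            ms = fit_modules(X, WgcnaParams(beta=18))
            mask = ms.assignment > 0
            aris.append(adjusted_rand_score(blocks[ms.assignment.index][mask], ms.assignment[mask]))
        assert np.mean(aris) >= 0.8

    def test_feature_permutation_equivariance(self):
        X, _ = _planted(2, n_blocks=3, per_block=10)
        params = WgcnaParams(beta=12)
        ms1 = fit_modules(X, params)
        rng = np.random.default_rng(0)
        perm = rng.permutation(X.columns)
        ms2 = fit_modules(X[perm], params)
        ari = adjusted_rand_score(ms1.assignment[X.columns], ms2.assignment[X.columns])
        assert ari == pytest.approx(1.0)


class TestEigengenes:
    def test_identical_features_full_variance_explained(self, rng):
        t = rng.normal(size=10)
        X = _frame(np.column_stack([t] * 5))
        assignment = pd.Series([1] * 5, index=X.columns)
        eig, ve = module_eigengenes(X, assignment)
        assert ve["ME1"] == pytest.approx(1.0)
        z = (t - t.mean()) / t.std(ddof=0)
        assert abs(np.corrcoef(eig["ME1"], z)[0, 1]) == pytest.approx(1.0)

    def test_sign_flip_equivariance(self, rng):
        X = _frame(rng.normal(size=(10, 4)))
        assignment = pd.Series([1] * 4, index=X.columns)
        e1, _ = module_eigengenes(X, assignment)
        e2, _ = module_eigengenes(-X, assignment)
        assert np.allclose(e1["ME1"], -e2["ME1"], atol=1e-10)

    def test_variance_explained_matches_svd(self, rng):
        X = _frame(rng.normal(size=(12, 6)))
        assignment = pd.Series([1] * 6, index=X.columns)
        _, ve = module_eigengenes(X, assignment)
        Z = (X - X.mean()) / X.std(ddof=0)
        s = np.linalg.svd(Z.to_numpy(), compute_uv=False)
        assert ve["ME1"] == pytest.approx(s[0] ** 2 / (s**2).sum())

    def test_eigengene_is_unit_norm(self, rng):
        X = _frame(rng.normal(size=(9, 5)))
        eig, _ = module_eigengenes(X, pd.Series([1] * 5, index=X.columns))
        assert np.linalg.norm(eig["ME1"]) == pytest.approx(1.0)


class TestMerge:
    def test_highly_correlated_modules_merged(self, rng):
        t = rng.normal(size=12)
        X = _frame(
            np.column_stack(
                [np.outer(t, np.ones(5)) + rng.normal(0, 0.3, (12, 5)),
                 np.outer(t, np.ones(5)) + rng.normal(0, 0.3, (12, 5))]
            )
        )
        assignment = pd.Series([1] * 5 + [2] * 5, index=X.columns)
        merged = merge_modules(X, assignment, merge_cor=0.75)
        assert merged.nunique() == 1

    def test_merge_cor_near_one_is_identity(self, rng):
        X, _ = _planted(1, n_blocks=3, per_block=8)
        ms = fit_modules(X, WgcnaParams(beta=12, merge_cor=0.999999))
        adj = adjacency(X, 12)
        raw = detect_modules(1 - tom_similarity(adj), WgcnaParams(beta=12, merge_cor=0.999999))
        assert ms.assignment[raw.index].nunique() == raw.nunique()

    def test_termination_at_fixed_point(self, rng):
        X = _frame(rng.normal(size=(10, 20)))
        assignment = pd.Series([1 + j % 4 for j in range(20)], index=X.columns)
        merged = merge_modules(X, assignment, merge_cor=0.2)
        again = merge_modules(X, merged, merge_cor=0.2)
        assert (merged == again).all()


class TestSoftPower:
    def test_power_law_connectivities_fit_well(self, rng):
        # k drawn from an exact discrete power law: p(k) ~ k^-2
        k = np.repeat(np.arange(1, 11), (1000 / np.arange(1, 11) ** 2).astype(int))
        r2, slope = _scale_free_fit(k.astype(float), n_bins=10)
        assert r2 >= 0.95
        assert slope < 0

    def test_vacuous_target_picks_smallest_power(self, rng):
        # the fit index is signed (negative for anti-scale-free slopes), so a
        # target of -1 is satisfied by every candidate
        X = _frame(rng.normal(size=(12, 30)))
        beta, diag = pick_soft_power(X, candidate_powers=(2, 4, 6), r2_target=-1.0)
        assert beta == 2

    def test_diagnostics_row_per_candidate(self, rng):
        X = _frame(rng.normal(size=(12, 30)))
        _, diag = pick_soft_power(X, candidate_powers=(1, 3, 5, 7), r2_target=0.99)
        assert len(diag) == 4


class TestModuleTrait:
    def test_zero_correlation_p_one(self):
        r = cor_pvalue_student(np.array([0.0]), 12)
        assert r[0] == pytest.approx(1.0)

    def test_perfect_correlation_p_zero(self):
        assert cor_pvalue_student(np.array([1.0]), 12)[0] == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_t_cdf(self):
        # r = 0.6, n = 12 -> t = 0.6*sqrt(10)/sqrt(0.64) = 2.3717
        t = 0.6 * np.sqrt(10) / np.sqrt(1 - 0.36)
        expected = 2 * st.t.sf(t, df=10)
        assert cor_pvalue_student(np.array([0.6]), 12)[0] == pytest.approx(expected, rel=1e-12)

    def test_table_shape_and_alignment(self, rng):
        eig = pd.DataFrame(rng.normal(size=(12, 3)), columns=["ME1", "ME2", "ME3"],
                           index=[f"s{i}" for i in range(12)])
        traits = pd.DataFrame({"MPY": rng.normal(size=12)}, index=eig.index)
        tab = module_trait_correlation(eig, traits)
        assert len(tab) == 3
        with pytest.raises(ValueError):
            module_trait_correlation(eig, traits.iloc[::-1])
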