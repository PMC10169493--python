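import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from sklearn.cross_decomposition import PLSRegression

from enterolink import differential_metabolites, opls_da, pathway_enrichment, preprocess
from enterolink.metabolome import DifferentialCriteria, PreprocessParams


def _frame(X, prefix="m"):
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, index=[f"s{i}" for i in range(X.shape[0])],
                        columns=[f"{prefix}{j}" for j in range(X.shape[1])])


class TestPreprocess:
    def test_low_detection_feature_dropped(self, rng):
        X = _frame(rng.random((10, 3)) + 1.0)
        X.iloc[[0, 4, 5, 9], 0] = np.nan  # 60% detected in each group
        res = preprocess(X, labels=[1] * 5 + [2] * 5)
        assert "m0" in res.dropped_detection

    def test_detection_within_one_group_suffices(self, rng):
        X = _frame(rng.random((10, 2)) + 1.0)
        X.iloc[5:, 0] = np.nan  # 100% in group1, 0% in group2
        res = preprocess(X, labels=[1] * 5 + [2] * 5)
        assert "m0" not in res.dropped_detection

    def test_qc_rsd_filter(self, rng):
        X = _frame(rng.random((8, 2)) + 1.0)
        qc = pd.DataFrame({"m0": [1.0, 1.02, 0.98], "m1": [1.0, 2.0, 0.2]})  # m1 RSD >> 0.3
        res = preprocess(X, qc=qc)
        assert "m1" in res.dropped_qc and "m0" not in res.dropped_qc

    def test_sum_normalization_equalizes_totals(self, rng):
        X = _frame(rng.random((6, 5)) + 0.5)
        res = preprocess(X)
        sums = res.data.sum(axis=1)
        assert np.allclose(sums, sums.iloc[0])

    def test_missing_values_imputed_with_feature_minimum(self):
        X = _frame([[1.0, 4.0], [2.0, np.nan], [3.0, 6.0], [1.5, 5.0], [2.5, 4.5]])
        res = preprocess(X, params=PreprocessParams(detection_frac=0.8))
        assert not res.data.isna().any().any()

    def test_idempotent_on_processed_matrix(self, rng):
        X = _frame(rng.random((6, 5)) + 0.5)
        first = preprocess(X)
        second = preprocess(first.data)
        assert second.dropped_detection == [] and second.dropped_qc == []
        assert np.allclose(second.data.to_numpy(), first.data.to_numpy(), atol=1e-12)

    def test_all_features_dropped_rejected(self):
        X = _frame([[np.nan, np.nan]] * 4 + [[1.0, 1.0]])
        with pytest.raises(ValueError):
            preprocess(X, params=PreprocessParams(detection_frac=0.9))


class TestOplsDa:
    def test_class_column_dominates_prediction(self, rng):
        y = np.array([1] * 6 + [2] * 6)
        X = _frame(rng.normal(size=(12, 10)))
        X["m0"] = np.where(y == 1, -1.0, 1.0) + rng.normal(0, 0.01, 12)
        fit = opls_da(X, y, n_ortho=1, seed=0)
        assert fit.r2y > 0.95
        assert fit.vip["m0"] == fit.vip.max()

    def test_permuted_labels_negative_q2(self, rng):
        """Ensemble-mean Q2Y under label permutation is non-positive."""
        X = _frame(rng.normal(size=(12, 40)))
        y = np.array([1] * 6 + [2] * 6)
        q2s = []
        for seed in range(10):
            perm = np.random.default_rng(seed).permutation(y)
            q2s.append(opls_da(X, perm, n_ortho=1, seed=seed).q2y)
        assert np.mean(q2s) <= 0.0

    def test_zero_ortho_reduces_to_pls(self, rng):
        X = _frame(rng.normal(size=(14, 8)))
        y = np.array([1] * 7 + [2] * 7)
        fit = opls_da(X, y, n_ortho=0, seed=0)
        pls = PLSRegression(n_components=1, scale=True)
        pls.fit(X.to_numpy(), np.where(y == 1, -1.0, 1.0))
        r = np.corrcoef(fit.scores, pls.x_scores_[:, 0])[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-8)

    def test_predictive_orthogonal_scores_uncorrelated(self, rng):
        X = _frame(rng.normal(size=(12, 15)))
        y = np.array([1] * 6 + [2] * 6)
        X["m0"] = np.where(y == 1, -1.0, 1.0) + rng.normal(0, 0.3, 12)
        fit = opls_da(X, y, n_ortho=2, seed=1)
        for t_o in fit.ortho_scores:
            assert abs(np.dot(fit.scores, t_o)) / len(t_o) < 1e-6 or abs(
                np.corrcoef(fit.scores, t_o)[0, 1]
            ) < 0.3

    def test_singleton_class_rejected(self, rng):
        X = _frame(rng.normal(size=(5, 4)))
        with pytest.raises(ValueError):
            opls_da(X, [1, 2, 2, 2, 2])


class TestVip:
    def test_mean_squared_vip_is_one(self, rng):
        X = _frame(rng.normal(size=(12, 25)))
        y = np.array([1] * 6 + [2] * 6)
        fit = opls_da(X, y, seed=0)
        assert (fit.vip**2).mean() == pytest.approx(1.0, abs=1e-8)

    def test_symmetric_features_equal_vip(self, rng):
        base = np.where(np.arange(12) < 6, -1.0, 1.0)
        noise = rng.normal(0, 0.2, size=(12, 4))
        X = _frame(base[:, None] + noise)
        # make all features exchangeable copies of the class signal
        fit = opls_da(X, [1] * 6 + [2] * 6, n_ortho=0, seed=0)
        assert fit.vip.std() < 0.1

    def test_planted_informative_feature_max_vip(self, rng):
        y = np.array([1] * 6 + [2] * 6)
        X = _frame(rng.normal(size=(12, 30)))
        X["m5"] = np.where(y == 1, 0.0, 2.0) + rng.normal(0, 0.2, 12)
        fit = opls_da(X, y, seed=2)
        assert fit.vip.idxmax() == "m5"


class TestDifferentialCriteria:
    @pytest.mark.parametrize(
        "vip_v,ratio,q,expected",
        [
            (1.2, 2.5, 0.01, True),   # all gates pass
            (0.9, 3.0, 0.001, False), # VIP gate fails
            (1.5, 1.0, 0.01, False),  # ratio gate fails
            (1.5, 0.4, 0.01, True),   # downward fold change passes
            (1.5, 2.5, 0.2, False),   # q gate fails
        ],
    )
    def test_methods_preset_gates(self, vip_v, ratio, q, expected):
        crit = DifferentialCriteria.preset("methods")
        assert crit.evaluate(vip_v, ratio, q) is expected

    def test_results_preset_ignores_ratio(self):
        crit = DifferentialCriteria.preset("results")
        assert crit.evaluate(1.2, 1.0, 0.01)

    def test_differential_table_pass_reproducible(self, rng):
        y = np.array([1] * 6 + [2] * 6)
        X = _frame(np.abs(rng.normal(size=(12, 20))) + 0.5)
        X["m0"] = np.where(y == 1, 1.0, 8.0) * np.exp(rng.normal(0, 0.05, 12))
        logX = np.log10(X)
        fit = opls_da(logX, y, seed=0)
        table = differential_metabolites(logX, y, fit.vip, X_prelog=X)
        t = table.table
        crit = DifferentialCriteria()
        recomputed = [crit.evaluate(v, r, q) for v, r, q in zip(t["vip"], t["ratio"], t["q"])]
        assert list(t["pass"]) == recomputed
        assert t.set_index("feature").loc["m0", "pass"]


class TestPathwayEnrichment:
    def _map(self):
        rows = []
        for i in range(20):
            rows.append((f"met{i}", "P1", "pathway one"))
        for i in range(20, 40):
            rows.append((f"met{i}", "P2", "pathway two"))
        return pd.DataFrame(rows, columns=["metabolite_id", "pathway_id", "pathway_name"])

    def test_tail_sum_matches_closed_form(self):
        universe = [f"met{i}" for i in range(100)]
        pmap = self._map()
        diff = [f"met{i}" for i in range(5)] + [f"met{i}" for i in range(50, 55)]
        out = pathway_enrichment(diff, universe, pmap).set_index("pathway_id")
        # 2x2: K=20 in P1, n=10 differential, k=5 overlap, N=100
        expected = sum(
            st.hypergeom.pmf(k, 100, 20, 10) for k in range(5, 11)
        )
        assert out.loc["P1", "p"] == pytest.approx(expected, rel=1e-9)

    def test_concentrated_hit_minimal_p(self):
        universe = [f"met{i}" for i in range(40)]
        pmap = pd.DataFrame(
            {"metabolite_id": [f"met{i}" for i in range(3)], "pathway_id": "P", "pathway_name": "p"}
        )
        out = pathway_enrichment([f"met{i}" for i in range(3)], universe, pmap)
        from math import comb

        assert out.iloc[0]["p"] == pytest.approx(1 / comb(40, 3), rel=1e-9)

    def test_null_p_distribution_roughly_uniform(self):
        universe = [f"met{i}" for i in range(40)]
        pmap = self._map()[: 40]
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(200):
            diff = list(rng.choice(universe, size=10, replace=False))
            out = pathway_enrichment(diff, universe, pmap)
            ps.extend(out["p"])
        assert np.mean(ps) > 0.3  # enrichment p is conservative/discrete but not skewed small

    def test_diff_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            pathway_enrichment(["x"], ["y"], self._map())

    def test_empty_pathway_skipped_with_note(self):
        universe = [f"met{i}" for i in range(5)]
        with pytest.warns(UserWarning, match="skipped"):
            out = pathway_enrichment(["met0"], universe, self._map())
        assert "P2" not in set(out["pathway_id"])
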