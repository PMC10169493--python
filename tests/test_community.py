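import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from enterolink import alpha_diversity, anosim, mann_whitney_bh, rarefy, vfa_summary
from enterolink.community import prevalence_abundance_filter, VFA_ACIDS
from enterolink.datatypes import DistanceMatrix
from enterolink.simulate import SimConfig, VFA_GROUP_MEANS, simulate_vfa_table


def _dm(D):
    ids = [f"s{i}" for i in range(len(D))]
    return DistanceMatrix(pd.DataFrame(D, index=ids, columns=ids))


class TestRarefy:
    def test_depth_equals_total_row_unchanged(self):
        counts = pd.DataFrame([[3, 4, 5]], index=["s1"], columns=list("abc"))
        out = rarefy(counts, 12, seed=0)
        pd.testing.assert_frame_equal(out, counts)

    def test_output_sums_equal_depth(self):
        counts = pd.DataFrame([[100, 200, 50], [30, 400, 70]], index=["s1", "s2"], columns=list("abc"))
        out = rarefy(counts, 80, seed=1)
        assert (out.sum(axis=1) == 80).all()

    def test_repeat_same_seed_identical(self):
        counts = pd.DataFrame([[100, 200, 50]], index=["s1"], columns=list("abc"))
        pd.testing.assert_frame_equal(rarefy(counts, 80, seed=7), rarefy(counts, 80, seed=7))

    def test_hypergeometric_mean(self):
        counts = pd.DataFrame([[100, 300, 600]], index=["s1"], columns=list("abc"))
        depth = 200
        draws = np.array([rarefy(counts, depth, seed=s).iloc[0].to_numpy() for s in range(300)])
        expected = depth * counts.iloc[0].to_numpy() / 1000
        assert np.allclose(draws.mean(axis=0), expected, atol=2.0)

    def test_insufficient_depth_names_sample(self):
        counts = pd.DataFrame([[1, 2]], index=["cow1"], columns=list("ab"))
        with pytest.raises(ValueError, match="cow1"):
            rarefy(counts, 100)


class TestAlphaDiversity:
    def test_uniform_shannon_is_log_s(self):
        counts = pd.DataFrame([[7] * 5], index=["s1"], columns=list("abcde"))
        assert alpha_diversity(counts, "shannon")["s1"] == pytest.approx(np.log(5))

    def test_single_taxon_zero_diversity(self):
        counts = pd.DataFrame([[9, 0, 0]], index=["s1"], columns=list("abc"))
        assert alpha_diversity(counts, "shannon")["s1"] == pytest.approx(0.0)
        assert alpha_diversity(counts, "simpson")["s1"] == pytest.approx(0.0)

    def test_chao1_singleton_doubleton_formula(self):
        # S_obs = 10, F1 = 2, F2 = 1 -> chao1 = 10 + 2*1/(2*2) = 10.5
        counts = pd.DataFrame([[1, 1, 2] + [5] * 7], index=["s1"], columns=[f"t{i}" for i in range(10)])
        assert alpha_diversity(counts, "chao1")["s1"] == pytest.approx(10.5)

    def test_empty_sample_rejected(self):
        counts = pd.DataFrame([[0, 0]], index=["s1"], columns=list("ab"))
        with pytest.raises(ValueError):
            alpha_diversity(counts, "shannon")


class TestAnosim:
    def test_perfect_separation_r_one(self):
        pts = np.array([[0.0], [0.1], [0.2], [5.0], [5.1], [5.2]])
        D = _dm(squareform(pdist(pts)))
        res = anosim(D, [1, 1, 1, 2, 2, 2], n_perm=999, seed=0)
        assert res.R == pytest.approx(1.0)
        # only 20 distinct splits at n=6: the exact one-sided p is 2/20
        assert res.p == pytest.approx(0.1, abs=0.03)

    def test_null_ensemble_mean_r_near_zero(self):
        rng = np.random.default_rng(3)
        rs = []
        for _ in range(20):
            pts = rng.normal(size=(8, 2))
            D = _dm(squareform(pdist(pts)))
            rs.append(anosim(D, [1, 1, 1, 1, 2, 2, 2, 2], n_perm=49, seed=1).R)
        assert abs(np.mean(rs)) < 0.15

    def test_permutation_p_matches_exhaustive_enumeration(self):
        """n=6, two groups of 3: exact p over all 20 label splits."""
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(6, 2))
        Dm = squareform(pdist(pts))
        labels = np.array([1, 1, 1, 2, 2, 2])
        iu = np.triu_indices(6, 1)
        ranks = rankdata(Dm[iu])

        def r_of(lab):
            same = lab[iu[0]] == lab[iu[1]]
            return (ranks[~same].mean() - ranks[same].mean()) / (len(ranks) / 2)

        r_obs = r_of(labels)
        count = sum(
            r_of(np.array([1 if i in combo else 2 for i in range(6)])) >= r_obs - 1e-12
            for combo in itertools.combinations(range(6), 3)
        )
        exact_p = count / 20
        res = anosim(_dm(Dm), labels, n_perm=9999, seed=2)
        assert res.R == pytest.approx(r_obs)
        assert res.p == pytest.approx(exact_p, abs=0.02)

    def test_singleton_group_rejected(self):
        D = _dm(squareform(pdist(np.arange(4.0)[:, None])))
        with pytest.raises(ValueError):
            anosim(D, [1, 2, 2, 2])


class TestMannWhitneyBH:
    def test_extreme_groups_exact_p(self):
        mat = pd.DataFrame({"f": [1, 2, 3, 4, 5, 6]}, index=[f"s{i}" for i in range(6)])
        res = mann_whitney_bh(mat, [1, 1, 1, 2, 2, 2])
        row = res.table.iloc[0]
        assert row["stat"] == pytest.approx(0.0)
        assert row["p"] == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        mat = pd.DataFrame({"f": [5.0] * 6}, index=[f"s{i}" for i in range(6)])
        res = mann_whitney_bh(mat, [1, 1, 1, 2, 2, 2])
        assert res.table.iloc[0]["p"] == 1.0
        assert bool(res.table.iloc[0]["constant"])

    def test_bh_stepup_hand_case(self):
        """(0.01, 0.02, 0.03, 0.04) with m=4 -> all q = 0.04."""
        from statsmodels.stats.multitest import multipletests

        q = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_q_never_below_p_and_monotone(self, rng):
        mat = pd.DataFrame(
            rng.normal(size=(12, 30)),
            index=[f"s{i}" for i in range(12)],
            columns=[f"f{j}" for j in range(30)],
        )
        res = mann_whitney_bh(mat, [1] * 6 + [2] * 6)
        t = res.table.sort_values("p")
        assert (t["q"].to_numpy() >= t["p"].to_numpy() - 1e-12).all()
        assert (np.diff(t["q"].to_numpy()) >= -1e-12).all()

    def test_exact_and_normal_approximation_agree(self, rng):
        x, y = rng.normal(0, 1, 10), rng.normal(0.5, 1, 10)
        mat = pd.DataFrame({"f": np.concatenate([x, y])}, index=[f"s{i}" for i in range(20)])
        lab = [1] * 10 + [2] * 10
        p_exact = mann_whitney_bh(mat, lab, method="exact").table.iloc[0]["p"]
        p_norm = mann_whitney_bh(mat, lab, method="asymptotic").table.iloc[0]["p"]
        assert abs(p_exact - p_norm) < 0.01


class TestPrevalenceFilter:
    def test_feature_above_threshold_everywhere_kept(self):
        mat = pd.DataFrame({"f": [6.0] * 8}, index=[f"s{i}" for i in range(8)])
        out = prevalence_abundance_filter(mat, 5.0, 0.5, [1] * 4 + [2] * 4)
        assert "f" in out.columns

    def test_feature_below_half_prevalence_in_one_group_dropped(self):
        # 40% above threshold in group2 (2 of 5)
        mat = pd.DataFrame({"f": [6, 6, 6, 6] + [6, 6, 0, 0, 0]}, index=[f"s{i}" for i in range(9)])
        out = prevalence_abundance_filter(mat, 5.0, 0.5, [1] * 4 + [2] * 5)
        assert "f" not in out.columns

    def test_zero_thresholds_identity(self, rng):
        mat = pd.DataFrame(rng.random((5, 4)) + 0.1, index=list("abcde"), columns=list("wxyz"))
        out = prevalence_abundance_filter(mat, 0.0, 0.0)
        pd.testing.assert_frame_equal(out, mat)


class TestVfaSummary:
    def test_reference_means_give_printed_tvfa(self):
        vfa = simulate_vfa_table(SimConfig(seed=0), sd_scale=0.0)
        s = vfa_summary(vfa, vfa.group_label.to_numpy())
        assert s.group_means.loc["TVFA", "group1"] == pytest.approx(136.47, abs=1e-9)

    def test_identical_samples_sem_zero_p_one(self):
        df = pd.DataFrame(
            np.tile(VFA_GROUP_MEANS["type1"].to_numpy(), (6, 1)),
            index=[f"s{i}" for i in range(6)],
            columns=list(VFA_GROUP_MEANS.index),
        )
        s = vfa_summary(df, [1, 1, 1, 2, 2, 2])
        assert np.allclose(s.sem, 0.0, atol=1e-12)
        assert (s.anova_p == 1.0).all()
        assert s.flags

    def test_two_group_anova_matches_t_test(self):
        vfa = simulate_vfa_table(SimConfig(seed=3))
        lab = vfa.group_label.to_numpy()
        s = vfa_summary(vfa, lab)
        x = vfa.data.loc[lab == 1, "acetate"]
        y = vfa.data.loc[lab == 2, "acetate"]
        t_p = st.ttest_ind(x, y, equal_var=True).pvalue
        assert s.anova_p["acetate"] == pytest.approx(t_p, rel=1e-9)

    def test_ap_is_mean_of_per_sample_ratios(self):
        vfa = simulate_vfa_table(SimConfig(seed=4))
        lab = vfa.group_label.to_numpy()
        s = vfa_summary(vfa, lab)
        manual = (vfa.data.loc[lab == 1, "acetate"] / vfa.data.loc[lab == 1, "propionate"]).mean()
        assert s.group_means.loc["A/P", "group1"] == pytest.approx(manual)

    def test_missing_acid_column_rejected(self):
        df = pd.DataFrame({"acetate": [1.0, 2.0]}, index=["s1", "s2"])
        with pytest.raises(ValueError, match="propionate"):
            vfa_summary(df, [1, 2])
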