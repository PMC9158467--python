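import numpy as np
import pandas as pd
import pytest

import prolncs as P
from tests.conftest import random_survival


class TestScoreGeneSets:
    def test_hand_stepped_random_walk(self):
        """3 genes A>B>C, set={A}, alpha=0: running (P_hit - P_miss) per
        step is (1, 0.5, 0), so the sum score is 1.5."""
        expr = P.ExpressionMatrix(
            pd.DataFrame({"s1": [3.0, 2.0, 1.0]}, index=["A", "B", "C"])
        )
        act = P.score_gene_sets(
            expr, P.GeneSetCollection({"S": ["A"]}), alpha=0.0, min_size=1
        )
        assert act.values.loc["S", "s1"] == pytest.approx(1.5, abs=1e-12)

    def test_all_gene_set_dropped_with_warning(self):
        expr = P.ExpressionMatrix(
            pd.DataFrame({"s1": [3.0, 1.0], "s2": [1.0, 2.0]}, index=["A", "B"])
        )
        sets = P.GeneSetCollection({"ALL": ["A", "B"], "OK": ["A"]})
        with pytest.warns(UserWarning, match="dropped"):
            act = P.score_gene_sets(expr, sets, min_size=1)
        assert list(act.values.index) == ["OK"]

    def test_error_when_nothing_overlaps(self):
        expr = P.ExpressionMatrix(
            pd.DataFrame({"s1": [3.0, 1.0]}, index=["A", "B"])
        )
        with pytest.raises(ValueError, match="no gene set"):
            with pytest.warns(UserWarning):
                P.score_gene_sets(expr, P.GeneSetCollection({"X": ["Z"]}), min_size=1)

    def test_identical_samples_identical_scores(self, gene_sets, cohort):
        mrna = cohort[0]
        dup = mrna.values.iloc[:, :3].copy()
        dup["clone"] = dup.iloc[:, 0]
        act = P.score_gene_sets(P.ExpressionMatrix(dup), gene_sets)
        pd.testing.assert_series_equal(
            act.values.iloc[:, 0], act.values["clone"], check_names=False
        )

    def test_monotone_transform_invariance(self, gene_sets, cohort):
        """Scores are rank-based: exp() of one sample's values changes nothing."""
        mrna = cohort[0]
        sub = mrna.values.iloc[:, :5].copy()
        base = P.score_gene_sets(P.ExpressionMatrix(sub), gene_sets)
        sub.iloc[:, 2] = np.exp(sub.iloc[:, 2] / 4.0)
        trans = P.score_gene_sets(P.ExpressionMatrix(sub), gene_sets)
        np.testing.assert_allclose(
            base.values.iloc[:, 2], trans.values.iloc[:, 2], atol=1e-12
        )

    def test_gsva_variant_separates_subtypes(self, gene_sets, cohort):
        mrna, _, _, truth = cohort
        sub = P.ExpressionMatrix(mrna.values.iloc[:, :60])
        act = P.score_gene_sets(sub, gene_sets, method="gsva")
        assert act.method == "gsva"
        lab = truth.subtype_vector(act.sample_ids)
        row = act.values.loc["PATHWAY_01"]
        assert row[lab == "S2"].mean() > row[lab == "S1"].mean()

    def test_normalize_flag_rescales(self, gene_sets, cohort):
        sub = P.ExpressionMatrix(cohort[0].values.iloc[:, :10])
        raw = P.score_gene_sets(sub, gene_sets, normalize=False).values
        nrm = P.score_gene_sets(sub, gene_sets, normalize=True).values
        span = raw.to_numpy().max() - raw.to_numpy().min()
        np.testing.assert_allclose(nrm, raw / span, atol=1e-12)


class TestDifferentialActivity:
    def test_planted_shift_has_smallest_p(self, gene_sets):
        rng = np.random.default_rng(0)
        vals = pd.DataFrame(
            rng.normal(size=(7, 100)),
            index=list(gene_sets),
            columns=[f"s{i}" for i in range(100)],
        )
        vals.iloc[0, 50:] += 2.0
        act = P.ActivityMatrix(vals)
        res = P.differential_activity(act, list(vals.columns[50:]), list(vals.columns[:50]))
        assert res["p"].idxmin() == "PATHWAY_01"
        assert res.loc["PATHWAY_01", "delta"] == pytest.approx(2.0, abs=0.5)

    def test_constant_row_is_null(self):
        rng = np.random.default_rng(1)
        vals = pd.DataFrame(rng.normal(size=(3, 20)), index=list("abc"))
        vals.iloc[2] = 5.0
        res = P.differential_activity(
            P.ActivityMatrix(vals), list(vals.columns[:10]), list(vals.columns[10:])
        )
        assert res.loc["c", "t_stat"] == 0.0
        assert res.loc["c", "p"] == 1.0

    def test_overlapping_groups_rejected(self, activity):
        cols = activity.sample_ids
        with pytest.raises(ValueError, match="disjoint"):
            P.differential_activity(activity, cols[:5], cols[4:9])

    def test_permutation_null_controls_fdr(self, activity):
        rng = np.random.default_rng(5)
        cols = np.array(activity.sample_ids)
        n_flag = 0
        n_perm = 100
        for _ in range(n_perm):
            perm = rng.permutation(cols)
            res = P.differential_activity(activity, list(perm[:100]), list(perm[100:]))
            n_flag += (res["fdr"] < 0.05).sum()
        assert n_flag / (n_perm * len(activity.set_names)) <= 0.05


class TestKmOptimalCutoff:
    def test_perfect_separation(self):
        # low-score group survives long, high-score group fails early; the
        # log-rank-optimal boundary must fall in the score gap
        rng = np.random.default_rng(2)
        score = np.r_[rng.uniform(0, 1, 30), rng.uniform(2, 3, 30)]
        times = np.r_[rng.uniform(20, 30, 30), rng.uniform(1, 5, 30)]
        surv = P.SurvivalTable(
            pd.DataFrame(
                {"time": times, "event": 1}, index=[f"s{i}" for i in range(60)]
            )
        )
        cut, chi2, p = P.km_optimal_cutoff(score, surv)
        assert 1.0 < cut < 2.0
        assert p < 1e-6

    def test_no_events_error(self):
        surv = P.SurvivalTable(
            pd.DataFrame(
                {"time": np.arange(1, 21, dtype=float), "event": 0},
                index=[f"s{i}" for i in range(20)],
            )
        )
        with pytest.raises(ValueError, match="no events"):
            P.km_optimal_cutoff(np.arange(20.0), surv)

    def test_identical_scores_error(self):
        rng = np.random.default_rng(3)
        surv = random_survival(rng, 30)
        with pytest.raises(ValueError, match="no admissible"):
            P.km_optimal_cutoff(np.ones(30), surv)

    def test_min_prop_half_odd_n_has_no_split(self):
        # both arms must reach ceil(0.5*31) = 16 samples: impossible at n=31
        rng = np.random.default_rng(4)
        surv = random_survival(rng, 31, censor_frac=0.0)
        with pytest.raises(ValueError, match="no admissible"):
            P.km_optimal_cutoff(np.arange(31.0), surv, min_prop=0.5)

    def test_min_prop_even_n(self):
        rng = np.random.default_rng(6)
        n = 30
        surv = random_survival(rng, n, censor_frac=0.0)
        score = np.arange(n, dtype=float)
        cut, _, _ = P.km_optimal_cutoff(score, surv, min_prop=0.5)
        assert cut == pytest.approx(14.5)
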