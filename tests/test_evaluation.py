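import numpy as np
import pandas as pd
import pytest

import prolncs as P
from tests.conftest import random_survival


def brute_force_cindex(score, time, event):
    """All-pairs oracle: concordant / comparable with 0.5 for score ties."""
    conc = comp = 0.0
    n = len(score)
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and event[i] == 1:
                comp += 1
                if score[i] > score[j]:
                    conc += 1
                elif score[i] == score[j]:
                    conc += 0.5
    if comp == 0:
        raise ValueError("no comparable pairs")
    return conc / comp


def rank_auc(cases, controls):
    """Mann-Whitney AUC of cases over controls."""
    from scipy.stats import rankdata

    x = np.r_[cases, controls]
    r = rankdata(x)
    u = r[: len(cases)].sum() - len(cases) * (len(cases) + 1) / 2
    return u / (len(cases) * len(controls))


class TestHarrellCindex:
    def test_perfect_ranking(self):
        surv = P.SurvivalTable(
            pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": 1}, index=list("abc"))
        )
        assert P.harrell_cindex(np.array([3.0, 2.0, 1.0]), surv) == 1.0

    def test_constant_scores_half(self):
        rng = np.random.default_rng(0)
        surv = random_survival(rng, 40)
        assert P.harrell_cindex(np.ones(40), surv) == 0.5

    def test_negation_symmetry(self):
        rng = np.random.default_rng(1)
        surv = random_survival(rng, 50)
        s = rng.normal(size=50)
        assert P.harrell_cindex(s, surv) == pytest.approx(
            1.0 - P.harrell_cindex(-s, surv), abs=1e-12
        )

    def test_matches_brute_force_on_censored_data(self):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(10, 50))
            s = rng.normal(size=n)
            surv = random_survival(rng, n, lp=0.5 * s, censor_frac=0.3)
            want = brute_force_cindex(s, surv.time, surv.event)
            assert P.harrell_cindex(s, surv) == pytest.approx(want, abs=1e-12)

    def test_no_comparable_pairs_error(self):
        surv = P.SurvivalTable(
            pd.DataFrame({"time": [5.0, 5.0], "event": [0, 0]}, index=list("ab"))
        )
        with pytest.raises(ValueError):
            P.harrell_cindex(np.array([1.0, 2.0]), surv)


class TestTimeDependentAuc:
    def test_equals_rank_auc_without_censoring(self):
        rng = np.random.default_rng(2)
        n = 300
        s = rng.normal(size=n)
        surv = random_survival(rng, n, lp=0.8 * s, censor_frac=0.0)
        t = float(np.quantile(surv.time, 0.6))
        res = P.time_dependent_auc(s, surv, [t])[0]
        cases = s[(surv.time <= t)]
        controls = s[surv.time > t]
        assert res.auc == pytest.approx(rank_auc(cases, controls), abs=1e-12)
        assert res.n_cases == len(cases) and res.n_controls == len(controls)

    def test_perfect_separation(self):
        surv = P.SurvivalTable(
            pd.DataFrame(
                {"time": np.r_[np.arange(1, 11), np.arange(20, 30)], "event": 1},
                index=[f"s{i}" for i in range(20)],
            )
        )
        s = np.r_[np.arange(20, 10, -1), np.arange(10, 0, -1)].astype(float)
        res = P.time_dependent_auc(s, surv, [15.0])[0]
        assert res.auc == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(3)
        n = 1000
        surv = random_survival(rng, n, censor_frac=0.2)
        s = rng.normal(size=n)
        res = P.time_dependent_auc(s, surv, [float(np.median(surv.time))])[0]
        assert abs(res.auc - 0.5) < 0.05

    def test_horizon_beyond_followup_error(self):
        rng = np.random.default_rng(4)
        surv = random_survival(rng, 50)
        with pytest.raises(ValueError, match="beyond"):
            P.time_dependent_auc(rng.normal(size=50), surv, [surv.time.max() * 2])


class TestCompareCindices:
    def test_identical_scores_null(self):
        rng = np.random.default_rng(5)
        n = 120
        s = rng.normal(size=n)
        surv = random_survival(rng, n, lp=0.5 * s)
        delta, p = P.compare_cindices(s, s.copy(), surv, n_boot=100, seed=0)
        assert delta == 0.0
        assert p == pytest.approx(1.0)

    def test_swap_negates_delta(self):
        rng = np.random.default_rng(6)
        n = 150
        a = rng.normal(size=n)
        surv = random_survival(rng, n, lp=0.8 * a)
        b = rng.normal(size=n)
        d1, p1 = P.compare_cindices(a, b, surv, n_boot=200, seed=1)
        d2, p2 = P.compare_cindices(b, a, surv, n_boot=200, seed=1)
        assert d1 == pytest.approx(-d2, abs=1e-12)
        assert p1 == pytest.approx(p2)

    def test_prognostic_beats_noise(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(40 + seed)
            n = 350
            a = rng.normal(size=n)
            surv = random_survival(rng, n, lp=0.8 * a, censor_frac=0.3)
            b = rng.normal(size=n)
            d, p = P.compare_cindices(a, b, surv, n_boot=200, seed=seed)
            wins += (d > 0) and (p < 0.05)
        assert wins >= 9

    def test_small_sample_warns(self):
        rng = np.random.default_rng(7)
        surv = random_survival(rng, 30)
        with pytest.warns(UserWarning, match="50"):
            P.compare_cindices(
                rng.normal(size=30), rng.normal(size=30), surv, n_boot=50, seed=0
            )


class TestCorrelateWithScore:
    def _features(self, rows, cols):
        return pd.DataFrame(rows, columns=cols)

    def test_score_itself_flagged(self):
        rng = np.random.default_rng(8)
        cols = [f"s{i}" for i in range(60)]
        score = pd.Series(rng.normal(size=60), index=cols)
        feats = pd.DataFrame(
            [score.to_numpy(), -score.to_numpy(), rng.normal(size=60)],
            index=["same", "anti", "noise"], columns=cols,
        )
        res = P.correlate_with_score(feats, score)
        assert res.loc["same", "r"] == pytest.approx(1.0)
        assert res.loc["anti", "r"] == pytest.approx(-1.0)
        assert bool(res.loc["same", "flagged"]) and bool(res.loc["anti", "flagged"])
        assert not bool(res.loc["noise", "flagged"])

    def test_constant_feature_skipped(self):
        rng = np.random.default_rng(9)
        cols = [f"s{i}" for i in range(30)]
        score = pd.Series(rng.normal(size=30), index=cols)
        feats = pd.DataFrame(
            [np.ones(30), rng.normal(size=30)], index=["const", "ok"], columns=cols
        )
        with pytest.warns(UserWarning, match="constant"):
            res = P.correlate_with_score(feats, score)
        assert "const" not in res.index and "ok" in res.index

    def test_pearson_matches_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(10)
        cols = [f"s{i}" for i in range(40)]
        score = pd.Series(rng.normal(size=40), index=cols)
        feats = pd.DataFrame(rng.normal(size=(5, 40)), columns=cols,
                             index=[f"f{i}" for i in range(5)])
        res = P.correlate_with_score(feats, score, method="pearson")
        for f in feats.index:
            r, p = stats.pearsonr(feats.loc[f], score)
            assert res.loc[f, "r"] == pytest.approx(r, abs=1e-12)
            assert res.loc[f, "p"] == pytest.approx(p, abs=1e-9)

    def test_spearman_matches_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(11)
        cols = [f"s{i}" for i in range(40)]
        score = pd.Series(rng.normal(size=40), index=cols)
        feats = pd.DataFrame(rng.normal(size=(4, 40)), columns=cols,
                             index=[f"f{i}" for i in range(4)])
        res = P.correlate_with_score(feats, score, method="spearman")
        for f in feats.index:
            r, _ = stats.spearmanr(feats.loc[f], score)
            assert res.loc[f, "r"] == pytest.approx(r, abs=1e-12)
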