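import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import prolncs as P
from prolncs.prolnc import _es_from_positions


def residual_partial_corr(x, y, z):
    """Independent oracle: correlation of the OLS residuals of x~z and y~z."""
    zc = np.c_[np.ones_like(z), z]
    rx = x - zc @ np.linalg.lstsq(zc, x, rcond=None)[0]
    ry = y - zc @ np.linalg.lstsq(zc, y, rcond=None)[0]
    return np.corrcoef(rx, ry)[0, 1]


def brute_force_es(order_is_hit, w, weight=1.0):
    """Walk the full list step by step and return the signed max deviation."""
    hits = np.asarray(order_is_hit, dtype=bool)
    wts = np.abs(np.asarray(w, dtype=float)) ** weight
    wh = wts[hits].sum()
    n, m = hits.size, int(hits.sum())
    run, best = 0.0, 0.0
    for i in range(n):
        if hits[i]:
            run += wts[i] / wh if wh > 0 else 1.0 / m
        else:
            run -= 1.0 / (n - m)
        if abs(run) > abs(best) or (abs(run) == abs(best) and run > best):
            best = run  # magnitude ties resolve to the positive deviation
    return best


class TestPurityAdjustedAssociation:
    def test_matches_residual_regression_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = int(rng.integers(5, 60))
            x, y, z = rng.normal(size=(3, n))
            rec = P.purity_adjusted_association(x, y, z)
            assert rec.pcc == pytest.approx(residual_partial_corr(x, y, z), abs=1e-10)
            assert rec.dof == n - 3

    def test_reduces_to_pearson_when_z_orthogonal(self):
        # construct x, y exactly uncorrelated with z
        rng = np.random.default_rng(1)
        z = rng.normal(size=40)
        zc = (z - z.mean()) / np.linalg.norm(z - z.mean())
        x = rng.normal(size=40)
        x = x - (x @ zc) * zc
        y = rng.normal(size=40)
        y = y - (y @ zc) * zc
        rec = P.purity_adjusted_association(x, y, z)
        assert rec.pcc == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_zero_pcc_gives_p_one(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=30)
        x = rng.normal(size=30)
        zc = np.c_[np.ones(30), z]
        rx = x - zc @ np.linalg.lstsq(zc, x, rcond=None)[0]
        y = rng.normal(size=30)
        ry = y - zc @ np.linalg.lstsq(zc, y, rcond=None)[0]
        ry = ry - (ry @ rx) / (rx @ rx) * rx  # orthogonalize residuals
        rec = P.purity_adjusted_association(x, ry + zc @ [0, 0], z)
        assert abs(rec.pcc) < 1e-10
        assert rec.t_stat == pytest.approx(0.0, abs=1e-8)
        assert rec.p == pytest.approx(1.0, abs=1e-8)

    def test_errors(self):
        n = 10
        rng = np.random.default_rng(3)
        x, y, z = rng.normal(size=(3, n))
        with pytest.raises(ValueError, match="constant"):
            P.purity_adjusted_association(np.ones(n), y, z)
        with pytest.raises(ValueError, match="collinear"):
            P.purity_adjusted_association(z.copy(), y, z)
        with pytest.raises(ValueError):
            P.purity_adjusted_association(x[:4], y[:4], z[:4])


class TestBuildRankList:
    def _mats(self, seed=0, n=40, g=30):
        rng = np.random.default_rng(seed)
        cols = [f"s{i}" for i in range(n)]
        mrna = pd.DataFrame(
            rng.normal(size=(g, n)), index=[f"M{i:03d}" for i in range(g)], columns=cols
        )
        purity = pd.Series(rng.uniform(0.3, 1, n), index=cols)
        return mrna, purity, cols

    def test_self_like_mrna_ranks_first(self):
        mrna, purity, cols = self._mats()
        lnc = pd.DataFrame(
            [mrna.loc["M005"] + np.random.default_rng(1).normal(0, 1e-6, len(cols))],
            index=["LNC"], columns=cols,
        )
        rl = P.build_rank_list("LNC", mrna, lnc, purity)
        assert rl.table.index[0] == "M005"

    def test_negating_lncrna_reverses_order(self):
        mrna, purity, cols = self._mats(seed=5)
        rng = np.random.default_rng(6)
        lv = rng.normal(size=len(cols))
        lnc = pd.DataFrame([lv], index=["LNC"], columns=cols)
        rl = P.build_rank_list("LNC", mrna, lnc, purity)
        rl_neg = P.build_rank_list("LNC", mrna, -lnc, purity)
        np.testing.assert_allclose(
            rl.table["oi"].to_numpy(), -rl_neg.table["oi"].to_numpy()[::-1], atol=1e-12
        )

    def test_oi_capped_at_320(self):
        mrna, purity, cols = self._mats(seed=7, n=500)
        lnc = pd.DataFrame([mrna.iloc[0]], index=["LNC"], columns=cols)
        with pytest.warns(UserWarning, match="capped"):
            rl = P.build_rank_list("LNC", mrna, lnc, purity)
        assert rl.table["oi"].max() <= 320.0


class TestPrerankedGsea:
    def _ranked(self):
        return P.RankedList(
            "L", pd.DataFrame({"oi": [2.0, 1.0, -1.0, -2.0]}, index=list("ABCD"))
        )

    def test_hand_stepped_top_hit(self):
        res = P.preranked_gsea(self._ranked(), {"A"}, weight=1, n_perm=20, seed=0)
        assert res.es == pytest.approx(1.0, abs=1e-12)

    def test_hand_stepped_bottom_hit(self):
        res = P.preranked_gsea(self._ranked(), {"D"}, weight=1, n_perm=20, seed=0)
        assert res.es == pytest.approx(-1.0, abs=1e-12)

    def test_all_genes_error(self):
        with pytest.raises(ValueError, match="no misses"):
            P.preranked_gsea(self._ranked(), set("ABCD"), n_perm=10, seed=0)

    def test_empty_intersection_error(self):
        with pytest.raises(ValueError, match="no genes"):
            P.preranked_gsea(self._ranked(), {"Z"}, n_perm=10, seed=0)

    def test_es_matches_brute_force_walk(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(4, 25))
            m = int(rng.integers(1, n))
            oi = np.sort(rng.normal(size=n))[::-1]
            pos = np.sort(rng.choice(n, size=m, replace=False))
            hits = np.zeros(n, dtype=bool)
            hits[pos] = True
            got = _es_from_positions(pos, np.abs(oi))[0]
            want = brute_force_es(hits, oi)
            assert got == pytest.approx(want, abs=1e-12)

    def test_mirror_symmetry(self):
        """Reversing the list and negating OI flips the ES sign."""
        rng = np.random.default_rng(12)
        for _ in range(50):
            n = int(rng.integers(5, 20))
            m = int(rng.integers(1, n))
            oi = np.sort(rng.normal(size=n))[::-1]
            pos = np.sort(rng.choice(n, size=m, replace=False))
            hits = np.zeros(n, dtype=bool)
            hits[pos] = True
            es = brute_force_es(hits, oi)
            es_mirror = brute_force_es(hits[::-1], -oi[::-1])
            assert abs(es) == pytest.approx(abs(es_mirror), abs=1e-12)
            # es == es_mirror happens only when max and -min tie in magnitude
            # and both resolve to the positive deviation; otherwise the sign
            # must flip exactly
            if abs(es - es_mirror) > 1e-9:
                assert es == pytest.approx(-es_mirror, abs=1e-12)


class TestFinalSignificanceIndex:
    @pytest.mark.parametrize(
        "fdr,es,expect",
        [(0.0, 0.6, 1.0), (0.5, -2.0, 0.0), (0.25, -0.3, -0.5), (0.0, 0.0, 0.0)],
    )
    def test_values(self, fdr, es, expect):
        assert P.final_significance_index(fdr, es) == pytest.approx(expect)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            P.final_significance_index(1.2, 0.5)

    @given(
        fdr=st.floats(0.0, 1.0, allow_nan=False),
        es=st.floats(-5.0, 5.0, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bounds_and_monotonicity(self, fdr, es):
        fsi = P.final_significance_index(fdr, es)
        assert -1.0 <= fsi <= 1.0
        if es > 0 and fdr < 0.99:
            assert P.final_significance_index(fdr + 0.01, es) <= fsi


class TestRunProlnc:
    def test_recovers_planted_modulators(self, gene_sets):
        mrna, lnc, _, truth = P.generate_cohort(
            gene_sets, 300, 2.0, 0.2, 60, 0.8, 0.3, seed=3
        )
        tab = P.run_prolnc(lnc, mrna, pd.Series(truth.purity), gene_sets,
                           n_perm=200, seed=7)
        flagged = {(r.lnc_id, r.pathway) for r in tab[tab.flagged].itertuples()}
        tp = len(flagged & truth.modulator_pairs)
        assert tp / len(truth.modulator_pairs) >= 0.9
        assert len(flagged - truth.modulator_pairs) <= max(1, 0.01 * len(tab))

    def test_flag_rule_algebra(self, gene_sets):
        mrna, lnc, _, truth = P.generate_cohort(
            gene_sets, 120, 2.0, 0.3, 20, 0.8, 0.3, seed=5
        )
        tab = P.run_prolnc(lnc, mrna, pd.Series(truth.purity), gene_sets,
                           n_perm=100, seed=1, fdr_max=0.001)
        neg = tab[tab.flagged & (tab.es < 0)]
        assert (neg["fsi"] <= -(1 - 2 * 0.001)).all()
        assert tab["fsi"].between(-1, 1).all()
        # fsi sign follows es sign wherever fdr < 0.5
        conf = tab[tab.fdr < 0.5]
        assert (np.sign(conf.fsi) == np.sign(conf.es)).all()

    def test_purity_confounding_controlled(self, gene_sets):
        """Non-modulator lncRNAs load on purity like pathway genes do; the
        partial-correlation adjustment must keep them unflagged."""
        mrna, lnc, _, truth = P.generate_cohort(
            gene_sets, 250, 2.0, 0.0, 40, 0.0, 0.3, seed=13
        )
        tab = P.run_prolnc(lnc, mrna, pd.Series(truth.purity), gene_sets,
                           n_perm=150, seed=2)
        assert tab.flagged.mean() <= 0.001 * 1.5 + 1e-9
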