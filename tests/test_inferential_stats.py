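"""Classical inference layer against independent algebra."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from crowdsolve import (
    PoolSpec,
    chisq_pass_fail,
    estimate_iq,
    hierarchical_regression,
    sample_pool,
    score_responses,
    screen_by_crt,
    spearman_corr,
    summarize,
    welch_t,
    welch_t_samples,
)


class TestSummarize:
    def test_constant_scores_have_zero_sd(self, bank):
        resp = sample_pool(PoolSpec(n_workers=5, items=bank, seed=0))
        keyed = {it.item_id: it for it in bank}
        for col in resp.columns:
            resp[col] = keyed[col].correct  # everyone right on everything
        table = summarize(score_responses(resp, bank))
        assert (table["sd"] == 0).all()
        assert table.loc["HBT", "mean"] == 9

    def test_small_example(self):
        # totals {1,2,3}: mean 2, median 2, SD 1 — checked through a 1-item
        # scale where workers answer correctly 1, 2 and 3 times is overkill;
        # use the arithmetic directly on a CRT column
        from crowdsolve.items import ItemSpec

        items = [
            ItemSpec(f"crt_{i}", "CRT", ("correct", "lure"), "correct",
                     lure="lure")
            for i in range(3)
        ]
        rows = [
            ["correct", "lure", "lure"],
            ["correct", "correct", "lure"],
            ["correct", "correct", "correct"],
        ]
        resp = pd.DataFrame(rows, index=["w1", "w2", "w3"],
                            columns=[it.item_id for it in items])
        table = summarize(score_responses(resp, items))
        assert table.loc["CRT", "mean"] == 2
        assert table.loc["CRT", "median"] == 2
        assert table.loc["CRT", "sd"] == 1

    def test_empty_subset_rejected(self, scores95):
        with pytest.raises(ValueError, match="empty"):
            summarize(scores95, subset=[])

    def test_study_scale_means_recovered_across_seeds(self, bank):
        # median-across-seeds summary at N=95 tracks the calibration anchors
        anchors = {"CRT": 1.27, "RSPM": 4.76, "HBT": 3.63,
                   "SRT_incongruent": 1.45, "SRT_congruent": 3.66}
        means = {k: [] for k in anchors}
        for seed in range(100):
            resp = sample_pool(PoolSpec(n_workers=95, items=bank, seed=seed))
            table = summarize(score_responses(resp, bank))
            for k in anchors:
                means[k].append(table.loc[k, "mean"])
        for k, target in anchors.items():
            assert abs(np.median(means[k]) - target) <= 0.15, k


class TestSpearman:
    def test_perfect_monotone(self):
        x = [3.0, 1.0, 4.0, 1.5, 5.0, 9.0]
        assert spearman_corr(x, x)[0] == pytest.approx(1.0)
        assert spearman_corr(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_matches_rank_formula_with_ties(self):
        x = [1.0, 2.0, 2.0, 3.0, 5.0, 4.0]
        y = [2.0, 1.0, 4.0, 4.0, 6.0, 5.0]

        def avg_ranks(v):
            v = np.asarray(v)
            order = np.argsort(v, kind="mergesort")
            ranks = np.empty(len(v))
            i = 0
            while i < len(v):
                j = i
                while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                    j += 1
                ranks[order[i: j + 1]] = (i + j) / 2 + 1
                i = j + 1
            return ranks

        rx, ry = avg_ranks(x), avg_ranks(y)
        ref = np.sum((rx - rx.mean()) * (ry - ry.mean())) / np.sqrt(
            np.sum((rx - rx.mean()) ** 2) * np.sum((ry - ry.mean()) ** 2)
        )
        assert spearman_corr(x, y)[0] == pytest.approx(ref, abs=1e-10)

    def test_constant_vector_flagged(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestWelch:
    def test_identical_summaries(self):
        res = welch_t(5.0, 1.0, 20, 5.0, 1.0, 20)
        assert res.t == 0.0
        assert res.ci_low == pytest.approx(-res.ci_high)

    def test_raw_samples_match_summary_path(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 30), rng.normal(0.5, 2, 40)
        a = welch_t_samples(x, y)
        b = welch_t(
            x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y)
        )
        assert a == b

    def test_equals_pooled_t_for_equal_variance_and_n(self):
        # with s1 = s2 and n1 = n2 the Welch statistic and df reduce to the
        # classical pooled two-sample t
        res = welch_t(3.0, 1.2, 25, 2.0, 1.2, 25)
        se_pooled = 1.2 * np.sqrt(2 / 25)
        assert res.t == pytest.approx(1.0 / se_pooled)
        assert res.df == pytest.approx(48.0)

    def test_degenerate_sds_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            welch_t(1.0, 0.0, 10, 2.0, 0.0, 10)

    def test_ci_contains_point_difference(self):
        res = welch_t(2.63, 0.65, 35, 0.48, 0.50, 60)
        assert res.ci_low < res.mean_diff < res.ci_high


class TestChiSquare:
    def _screen(self, passed, failed):
        from crowdsolve.scoring import ScreenResult

        return ScreenResult(threshold=2, passed=tuple(passed),
                            failed=tuple(failed))

    def _item(self):
        from crowdsolve.items import ItemSpec

        return ItemSpec("q", "HBT", ("A", "B"), "A", lure="B")

    def _responses(self, pass_correct, pass_wrong, fail_correct, fail_wrong):
        rows, idx = [], []
        for grp, (nc, nw) in (("p", (pass_correct, pass_wrong)),
                              ("f", (fail_correct, fail_wrong))):
            for i in range(nc):
                rows.append("A"); idx.append(f"{grp}{i}c")
            for i in range(nw):
                rows.append("B"); idx.append(f"{grp}{i}w")
        return pd.DataFrame({"q": rows}, index=idx)

    def test_equal_proportions_give_zero(self):
        resp = self._responses(5, 5, 8, 8)
        screen = self._screen([f"p{i}{s}" for i in range(5) for s in "cw"],
                              [f"f{i}{s}" for i in range(8) for s in "cw"])
        res = chisq_pass_fail(self._item(), resp, screen)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_perfect_separation_closed_form(self):
        # [[10, 0], [0, 10]]: chi2 = n (ad - bc)^2 / (r1 r2 c1 c2) = 20
        resp = self._responses(10, 0, 0, 10)
        screen = self._screen([f"p{i}c" for i in range(10)],
                              [f"f{i}w" for i in range(10)])
        res = chisq_pass_fail(self._item(), resp, screen)
        assert res.chi2 == pytest.approx(20.0, abs=1e-10)
        assert res.df == 1

    def test_matches_closed_form_generally(self):
        resp = self._responses(12, 5, 7, 14)
        screen = self._screen(
            [f"p{i}c" for i in range(12)] + [f"p{i}w" for i in range(5)],
            [f"f{i}c" for i in range(7)] + [f"f{i}w" for i in range(14)],
        )
        res = chisq_pass_fail(self._item(), resp, screen)
        a, b, c, d = 12, 5, 7, 14
        n = a + b + c + d
        ref = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d)
        )
        assert res.chi2 == pytest.approx(ref, abs=1e-10)

    def test_row_swap_invariance(self):
        resp = self._responses(12, 5, 7, 14)
        passed = [f"p{i}c" for i in range(12)] + [f"p{i}w" for i in range(5)]
        failed = [f"f{i}c" for i in range(7)] + [f"f{i}w" for i in range(14)]
        r1 = chisq_pass_fail(self._item(), resp, self._screen(passed, failed))
        r2 = chisq_pass_fail(self._item(), resp, self._screen(failed, passed))
        assert r1.chi2 == pytest.approx(r2.chi2, abs=1e-12)

    def test_zero_marginal_flagged(self):
        resp = self._responses(0, 10, 0, 10)
        screen = self._screen([f"p{i}w" for i in range(10)],
                              [f"f{i}w" for i in range(10)])
        res = chisq_pass_fail(self._item(), resp, screen)
        assert res.degenerate and np.isnan(res.p)

    def test_belief_bias_items_separate_screened_workers(
        self, pool95, bank, screen95
    ):
        # screened workers answer the belief-bias syllogisms better: most
        # incongruent items show a significant pass/fail contrast
        n_sig = 0
        for it in bank:
            if it.scale == "SRT_incongruent":
                res = chisq_pass_fail(it, pool95, screen95)
                n_sig += (not res.degenerate) and res.p < 0.05
        assert n_sig >= 3


def _twelve_row_data():
    # fixed hand dataset: no randomness, moderate collinearity
    return pd.DataFrame(
        {
            "age": [23, 35, 47, 52, 29, 61, 44, 38, 55, 26, 49, 33],
            "female": [1, 0, 1, 0, 1, 0, 0, 1, 1, 0, 1, 0],
            "education": [0, 1, 1, 0, 1, 1, 0, 0, 1, 0, 1, 1],
            "iq": [98, 112, 104, 95, 120, 108, 99, 103, 116, 92, 110, 107],
            "passed": [0, 1, 1, 0, 1, 1, 0, 0, 1, 0, 1, 0],
            "score": [2, 6, 5, 1, 8, 6, 3, 2, 7, 1, 6, 4],
        }
    )


class TestHierarchicalRegression:
    BLOCKS = [["age", "female", "education"], ["iq"], ["passed"]]

    def test_outcome_in_block_one_saturates(self):
        data = _twelve_row_data()
        data["score"] = data["age"].astype(float)
        res = hierarchical_regression(data, "score", self.BLOCKS)
        assert res[0].r_squared == pytest.approx(1.0, abs=1e-12)
        assert res[1].delta_r_squared == pytest.approx(0.0, abs=1e-10)
        assert res[2].delta_r_squared == pytest.approx(0.0, abs=1e-10)

    def test_matches_explicit_normal_equations(self):
        data = _twelve_row_data()
        res = hierarchical_regression(data, "score", self.BLOCKS)
        n = len(data)

        def z(v):
            v = np.asarray(v, dtype=float)
            return (v - v.mean()) / v.std(ddof=1)

        y = z(data["score"])
        prev_r2 = 0.0
        cum = []
        for bi, block in enumerate(self.BLOCKS):
            cum += block
            X = np.column_stack([np.ones(n)] + [z(data[c]) for c in cum])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            resid = y - X @ beta
            r2 = 1.0 - resid @ resid / (y @ y)
            dk = len(block)
            df2 = n - len(cum) - 1
            delta_f = ((r2 - prev_r2) / dk) / ((1.0 - r2) / df2)
            for j, c in enumerate(cum):
                assert res[bi].beta[c] == pytest.approx(beta[j + 1], abs=1e-10)
            assert res[bi].r_squared == pytest.approx(r2, abs=1e-10)
            assert res[bi].delta_f == pytest.approx(delta_f, abs=1e-8)
            assert res[bi].delta_f_p == pytest.approx(
                sps.f.sf(delta_f, dk, df2), abs=1e-10
            )
            prev_r2 = r2

    def test_nested_r2_never_decreases_and_adj_below_r2(self):
        data = _twelve_row_data()
        res = hierarchical_regression(data, "score", self.BLOCKS)
        for r in res:
            assert r.delta_r_squared >= -1e-12
            assert r.adj_r_squared <= r.r_squared + 1e-12

    def test_rank_deficiency_names_columns(self):
        data = _twelve_row_data()
        data["age_copy"] = data["age"]
        with pytest.raises(ValueError, match="age"):
            hierarchical_regression(
                data, "score", [["age", "age_copy", "female"]]
            )

    def test_orthogonal_predictor_beta_equals_zero_order_r(self):
        rng = np.random.default_rng(8)
        n = 200
        x1 = rng.normal(size=n)
        x1 -= x1.mean()
        x2 = rng.normal(size=n)
        x2 -= x2.mean()
        x2 -= x1 * (x1 @ x2) / (x1 @ x1)  # exactly orthogonal, still centred
        x1 /= x1.std(ddof=1)
        x2 /= x2.std(ddof=1)
        y = 0.5 * x1 + 0.3 * x2 + rng.normal(size=n)
        data = pd.DataFrame({"x1": x1, "x2": x2, "y": y})
        res = hierarchical_regression(data, "y", [["x1", "x2"]])
        r_x2 = np.corrcoef(x2, y)[0, 1]
        assert res[0].beta["x2"] == pytest.approx(r_x2, abs=1e-10)

    def test_crt_indicator_improves_prediction(self, pool95, bank, scores95,
                                               screen95):
        from crowdsolve import sample_demographics

        demo = sample_demographics(95, seed=0)
        data = demo.copy()
        data["estimated_iq"] = estimate_iq(
            scores95.totals["RSPM"].to_numpy(),
            scores95.totals["RSPM"].to_numpy(),
        )
        passed = set(screen95.passed)
        data["passed_crt"] = [int(w in passed) for w in scores95.totals.index]
        blocks = [["age", "female", "tertiary_education"], ["estimated_iq"],
                  ["passed_crt"]]
        for outcome in ("HBT", "SRT_incongruent"):
            data[outcome] = scores95.totals[outcome]
            res = hierarchical_regression(data, outcome, blocks)
            assert res[2].delta_r_squared > 0


class TestEstimateIQ:
    def test_anchors(self):
        ref = [2.0, 4.0, 6.0]
        assert estimate_iq(4.0, ref) == pytest.approx(100.0)
        assert estimate_iq(6.0, ref) == pytest.approx(115.0)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError, match="zero SD"):
            estimate_iq(4.0, [3.0, 3.0, 3.0])

    def test_affine_invariance_of_standardised_regression(self):
        data = _twelve_row_data()
        raw = hierarchical_regression(data, "score", [["iq", "female"]])
        data2 = data.copy()
        data2["iq"] = estimate_iq(data["iq"].to_numpy(), data["iq"].to_numpy())
        mapped = hierarchical_regression(data2, "score", [["iq", "female"]])
        for c in ("iq", "female"):
            assert mapped[0].beta[c] == pytest.approx(raw[0].beta[c], abs=1e-12)
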