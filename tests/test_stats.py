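"""Statistics: global scores, sliding windows, rank tests, regression, ICC."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gliaquant import stats
from gliaquant.synth import generate_score_table


def _table(rows):
    return pd.DataFrame(
        rows, columns=["animal_id", "group", "z_index", "z_norm", "ami", "ais"]
    )


class TestAnimalGlobalScores:
    def test_plane_mean(self):
        t = _table(
            [
                ("a1", "g", 0, 0.0, 4.0, 1.0),
                ("a1", "g", 1, 100.0, 6.0, 3.0),
                ("a2", "g", 0, 0.0, 8.0, 2.0),
            ]
        )
        out = stats.animal_global_scores(t)
        assert len(out) == 2
        row = out.set_index("animal_id").loc["a1"]
        assert row["ami"] == 5.0 and row["ais"] == 2.0

    def test_missing_planes_excluded(self):
        t = _table(
            [("a1", "g", 0, 0.0, np.nan, np.nan), ("a1", "g", 1, 100.0, 7.0, 2.0)]
        )
        out = stats.animal_global_scores(t)
        assert out.loc[0, "ami"] == 7.0

    def test_unscored_animal_dropped_with_warning(self):
        t = _table(
            [("a1", "g", 0, 0.0, np.nan, np.nan), ("a2", "g", 0, 0.0, 5.0, 1.0)]
        )
        with pytest.warns(UserWarning, match="a1"):
            out = stats.animal_global_scores(t)
        assert list(out["animal_id"]) == ["a2"]


class TestSpearman:
    def test_monotone_and_antitone(self):
        assert stats.spearman([1, 2, 3], [10, 20, 30])[0] == pytest.approx(1.0)
        assert stats.spearman([1, 2, 3], [30, 20, 10])[0] == pytest.approx(-1.0)

    def test_exact_permutation_p_for_perfect_ranking(self):
        # only the identity and reversal permutations reach |rho| = 1
        rho, p = stats.spearman([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / math.factorial(5))

    def test_ties_match_midrank_pearson_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0])
        y = np.array([5.0, 7.0, 6.0, 6.0, 9.0])

        def midranks(v):
            order = np.argsort(v, kind="mergesort")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2
                i = j
            return ranks

        rx, ry = midranks(x), midranks(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert stats.spearman(x, y)[0] == pytest.approx(expected)

    def test_constant_vector_is_missing(self):
        rho, p = stats.spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(rho) and math.isnan(p)

    def test_pairwise_complete(self):
        rho, _ = stats.spearman([1, 2, np.nan, 3, 4], [2, 4, 9, 6, 8])
        assert rho == pytest.approx(1.0)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.lists(st.integers(-1000, 1000), min_size=5, max_size=12, unique=True))
    def test_invariant_under_monotone_transform(self, xs):
        xs = np.asarray(xs, dtype=float) / 20.0
        rng = np.random.default_rng(0)
        ys = rng.normal(size=len(xs))
        rho1, _ = stats.spearman(xs, ys)
        rho2, _ = stats.spearman(np.exp(xs / 25.0), ys)
        assert rho1 == pytest.approx(rho2)


class TestKruskalDunn:
    def test_identical_groups_no_separation(self):
        res = stats.kruskal_dunn({"a": [3, 3], "b": [3, 3], "c": [3, 3]})
        assert res.h == 0.0 and res.p == 1.0
        assert (res.pairwise["p_raw"] == 1.0).all()

    def test_hand_computed_h(self):
        # ranks 1..6 split as {1,2,3} vs {4,5,6}: H = 27/7
        res = stats.kruskal_dunn({"lo": [1, 2, 3], "hi": [10, 20, 30]})
        assert res.h == pytest.approx(27 / 7)

    def test_dunn_z_closed_form(self):
        res = stats.kruskal_dunn({"lo": [1, 2, 3], "hi": [10, 20, 30]})
        z = abs(res.pairwise.iloc[0]["z"])
        # (5 - 2) / sqrt((6*7/12) * (1/3 + 1/3))
        assert z == pytest.approx(3 / math.sqrt(3.5 * (2 / 3)))

    def test_tie_correction_matches_formula(self, rng):
        groups = {
            "a": [1.0, 2.0, 2.0, 4.0],
            "b": [2.0, 5.0, 6.0],
            "c": [6.0, 7.0, 8.0, 8.0],
        }
        res = stats.kruskal_dunn(groups)
        pooled = np.concatenate(list(groups.values()))
        from scipy.stats import norm, rankdata

        ranks = rankdata(pooled)
        n = len(pooled)
        _, counts = np.unique(pooled, return_counts=True)
        var = n * (n + 1) / 12 - np.sum(counts**3 - counts) / (12 * (n - 1))
        r_a, r_b = ranks[:4].mean(), ranks[4:7].mean()
        z_ab = (r_a - r_b) / math.sqrt(var * (1 / 4 + 1 / 3))
        row = res.pairwise.set_index(["group_1", "group_2"]).loc[("a", "b")]
        assert row["z"] == pytest.approx(z_ab)
        assert row["p_raw"] == pytest.approx(2 * norm.sf(abs(z_ab)))

    def test_invariant_under_monotone_transform(self):
        groups = {"a": [1.0, 4.0, 2.0], "b": [8.0, 6.0, 9.0], "c": [3.0, 7.0, 5.0]}
        res1 = stats.kruskal_dunn(groups)
        res2 = stats.kruskal_dunn(
            {k: list(np.exp(np.asarray(v) / 3)) for k, v in groups.items()}
        )
        assert res1.h == pytest.approx(res2.h)


class TestValidationRegression:
    def test_identity_fit(self):
        manual = np.array([1.0, 3.0, 5.0, 7.0, 9.0])
        res = stats.validation_regression(manual, manual)
        assert res.slope == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)
        assert not res.outliers.any()

    def test_exact_linear_scaling(self):
        manual = np.array([1.0, 2.0, 3.0, 4.0])
        res = stats.validation_regression(manual, 2 * manual)
        assert res.slope == pytest.approx(2.0)

    def test_matches_normal_equations_oracle(self):
        manual = np.array([1.0, 2.0, 4.0, 6.0, 9.0])
        auto = np.array([2.1, 2.9, 6.2, 7.8, 13.0])
        res = stats.validation_regression(manual, auto)
        sxx = np.sum((manual - manual.mean()) ** 2)
        slope = np.sum((manual - manual.mean()) * (auto - auto.mean())) / sxx
        intercept = auto.mean() - slope * manual.mean()
        resid = auto - (intercept + slope * manual)
        se = math.sqrt(np.sum(resid**2) / 3 / sxx)
        from scipy.stats import t as t_dist

        half = t_dist.ppf(0.975, 3) * se
        assert res.slope == pytest.approx(slope)
        assert res.intercept == pytest.approx(intercept)
        assert res.slope_ci[0] == pytest.approx(slope - half)
        assert res.slope_ci[1] == pytest.approx(slope + half)

    def test_outlier_flag_and_refit(self):
        manual = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        auto = np.array([1.0, 2.0, 3.0, 4.0, 15.0])  # last differs by 10 > 6
        res = stats.validation_regression(manual, auto)
        assert res.outliers.tolist() == [False] * 4 + [True]
        assert res.refit_slope == pytest.approx(1.0)

    def test_degenerate_manual_rejected(self):
        with pytest.raises(ValueError):
            stats.validation_regression([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestIcc3k:
    def test_perfect_agreement(self):
        ratings = np.array([[1, 1, 1], [2, 2, 2], [4, 4, 4], [0, 0, 0]])
        assert stats.icc3k(ratings).icc == pytest.approx(1.0)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        ratings = rng.normal(size=(12, 3)) + rng.normal(size=(12, 1)) * 2
        res = stats.icc3k(ratings)
        df = pd.DataFrame(
            [
                {"target": i, "rater": j, "score": ratings[i, j]}
                for i, j in itertools.product(range(12), range(3))
            ]
        )
        ref = pingouin.intraclass_corr(
            data=df, targets="target", raters="rater", ratings="score"
        )
        # pingouin labels two-way mixed / consistency / average as ICC(C,k)
        expected = ref.loc[ref["Type"] == "ICC(C,k)", "ICC"].item()
        assert res.icc == pytest.approx(expected)
        expected_f = ref.loc[ref["Type"] == "ICC(C,k)", "F"].item()
        assert res.f == pytest.approx(expected_f)

    def test_random_permutations_near_zero(self):
        # independent rater permutations carry no target effect; with enough
        # targets the estimator's small-sample bias is below 0.1
        rng = np.random.default_rng(0)
        base = np.arange(30, dtype=float)
        iccs = []
        for _ in range(500):
            ratings = np.column_stack([rng.permutation(base) for _ in range(3)])
            iccs.append(stats.icc3k(ratings).icc)
        assert abs(np.mean(iccs)) < 0.1

    def test_zero_target_variance_rejected(self):
        with pytest.raises(ValueError):
            stats.icc3k(np.array([[1, 2], [1, 2]]))


class TestSlidingWindow:
    @staticmethod
    def _three_animal_table():
        rows = []
        rng = np.random.default_rng(5)
        for a in range(3):
            for z in range(11):
                ami = 10 + 2 * a + 0.1 * z + rng.normal(0, 0.1)
                rows.append((f"a{a}", "g", z, 10.0 * z, ami, 30 - ami))
        return _table(rows)

    def test_constant_scores_constant_windows(self):
        rows = [
            (f"a{a}", "g", z, 10.0 * z, 5.0 + a, 1.0) for a in range(3) for z in range(11)
        ]
        profiles, _ = stats.sliding_window(_table(rows), width=10, step=10)
        assert profiles["ami_mean"].nunique() == 1
        assert profiles["ami_mean"].iloc[0] == pytest.approx(6.0)
        # SEM comes from between-animal spread only: sd({5,6,7})/sqrt(3)
        assert profiles["ami_sem"].iloc[0] == pytest.approx(1 / math.sqrt(3))

    def test_perfect_antitone_link_gives_rho_minus_one(self):
        _, corr = stats.sliding_window(self._three_animal_table(), width=10, step=5)
        usable = corr[corr["usable"]]
        assert len(usable) > 0
        assert (usable["rho"] == -1.0).all()

    def test_matches_brute_force_windowing_oracle(self):
        table = self._three_animal_table()
        profiles, _ = stats.sliding_window(table, width=10, step=5)
        for _, row in profiles.iterrows():
            c = row["window_center"]
            lo, hi = max(0.0, c - 5), min(100.0, c + 5)
            means = []
            for a in table["animal_id"].unique():
                sub = table[table["animal_id"] == a]
                if hi >= 100:
                    sel = (sub["z_norm"] >= lo) & (sub["z_norm"] <= hi)
                else:
                    sel = (sub["z_norm"] >= lo) & (sub["z_norm"] < hi)
                if sel.any():
                    means.append(sub.loc[sel, "ami"].mean())
            assert row["ami_mean"] == pytest.approx(np.mean(means))
            assert row["n_animals"] == len(means)

    def test_full_width_window_reproduces_global_scores(self):
        table = self._three_animal_table()
        profiles, _ = stats.sliding_window(table, width=100, step=50)
        mid = profiles[profiles["window_center"] == 50.0]
        global_scores = stats.animal_global_scores(table)
        assert mid["ami_mean"].iloc[0] == pytest.approx(global_scores["ami"].mean())

    def test_too_few_animals_flagged_unusable(self):
        rows = [(f"a{a}", "g", z, 50.0, 5.0 + a + z, 9.0 - a - z) for a in range(2) for z in range(2)]
        _, corr = stats.sliding_window(_table(rows), width=10, step=50)
        assert not corr["usable"].any()


class TestGeneratedScoreTables:
    def test_planted_antitone_link_exact(self):
        t = generate_score_table(
            n_per_group=4, slope=-0.5, noise_sd=0.0, ami_plane_sd=0.3, seed=2
        )
        rho, _ = stats.spearman(t["ami"], t["ais"])
        assert rho == pytest.approx(-1.0)

    def test_group_offsets_detected(self):
        t = generate_score_table(n_per_group=10, seed=4)
        g = stats.animal_global_scores(t)
        res = stats.kruskal_dunn(
            {name: grp["ami"].to_numpy() for name, grp in g.groupby("group")}
        )
        assert res.p < 0.05
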