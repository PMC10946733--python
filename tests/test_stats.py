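"""Behavioural statistics tests: repeated-measures ANOVA against brute-force
sums-of-squares and pingouin oracles, Greenhouse-Geisser epsilon, Bonferroni
post-hocs, outlier trimming and the covariate correlation screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from touchersp.stats import (
    StatsError,
    _gg_epsilon,
    _orthonormal_contrasts,
    correlation_screen,
    outlier_trim,
    posthoc_pairwise,
    rm_anova,
)


def long_table(Y, f1="texture", f2="block"):
    """n x a x b cell-mean array -> long DataFrame."""
    n, a, b = Y.shape
    rows = []
    for s in range(n):
        for i in range(a):
            for j in range(b):
                rows.append(
                    {"subject": f"s{s}", f1: f"{f1}{i}", f2: f"{f2}{j}", "y": Y[s, i, j]}
                )
    return pd.DataFrame(rows)


def brute_force_rm_anova(Y):
    """Independent cell-means oracle for the two-way within-subject ANOVA."""
    n, a, b = Y.shape
    grand = Y.mean()
    SS = {}
    SS["A"] = n * b * sum((Y[:, i, :].mean() - grand) ** 2 for i in range(a))
    SS["B"] = n * a * sum((Y[:, :, j].mean() - grand) ** 2 for j in range(b))
    SS["AB"] = 0.0
    for i in range(a):
        for j in range(b):
            SS["AB"] += n * (
                Y[:, i, j].mean() - Y[:, i, :].mean() - Y[:, :, j].mean() + grand
            ) ** 2
    SS["AS"] = 0.0
    for s in range(n):
        for i in range(a):
            SS["AS"] += b * (
                Y[s, i, :].mean() - Y[s].mean() - Y[:, i, :].mean() + grand
            ) ** 2
    SS["BS"] = 0.0
    for s in range(n):
        for j in range(b):
            SS["BS"] += a * (
                Y[s, :, j].mean() - Y[s].mean() - Y[:, :, j].mean() + grand
            ) ** 2
    SS["ABS"] = 0.0
    for s in range(n):
        for i in range(a):
            for j in range(b):
                SS["ABS"] += (
                    Y[s, i, j]
                    - Y[s, i, :].mean()
                    - Y[s, :, j].mean()
                    - Y[:, i, j].mean()
                    + Y[s].mean()
                    + Y[:, i, :].mean()
                    + Y[:, :, j].mean()
                    - grand
                ) ** 2
    out = {}
    for eff, err, df1, df2 in (
        ("A", "AS", a - 1, (a - 1) * (n - 1)),
        ("B", "BS", b - 1, (b - 1) * (n - 1)),
        ("AB", "ABS", (a - 1) * (b - 1), (a - 1) * (b - 1) * (n - 1)),
    ):
        F = (SS[eff] / df1) / (SS[err] / df2)
        np2 = SS[eff] / (SS[eff] + SS[err])
        out[eff] = (F, df1, df2, np2)
    out["SS"] = SS
    return out


class TestRmAnova:
    def test_matches_brute_force_oracle(self, rng):
        Y = rng.standard_normal((5, 2, 4)) + np.arange(4) * 0.5
        res = rm_anova(long_table(Y), "y", ["texture", "block"])
        oracle = brute_force_rm_anova(Y)
        for eff, key in (("texture", "A"), ("block", "B"), ("texture*block", "AB")):
            row = res[res.effect == eff].iloc[0]
            F, df1, df2, np2 = oracle[key]
            assert row["F"] == pytest.approx(F, abs=1e-9)
            assert row["df1"] == df1 and row["df2"] == df2
            assert row["np2"] == pytest.approx(np2, abs=1e-9)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        Y = rng.standard_normal((6, 2, 3))
        tab = long_table(Y, "texture", "condition")
        res = rm_anova(tab, "y", ["texture", "condition"])
        ref = pg.rm_anova(
            data=tab, dv="y", within=["texture", "condition"], subject="subject",
            detailed=True,
        )
        for eff_name, ref_name in (
            ("texture", "texture"),
            ("condition", "condition"),
            ("texture*condition", "texture * condition"),
        ):
            mine = res[res.effect == eff_name].iloc[0]
            theirs = ref[ref.Source == ref_name].iloc[0]
            assert mine["F"] == pytest.approx(theirs["F"], rel=1e-6)
            assert mine["p"] == pytest.approx(theirs["p_unc"], rel=1e-6)

    def test_epsilon_exactly_one_for_two_levels(self, rng):
        Y = rng.standard_normal((6, 2, 3))
        res = rm_anova(long_table(Y), "y", ["texture", "block"])
        assert res[res.effect == "texture"].iloc[0]["eps"] == 1.0

    def test_epsilon_near_one_for_compound_symmetry(self, rng):
        """Compound-symmetric data (iid subject x condition effects) satisfy
        sphericity, so epsilon should approach 1 at large n."""
        n, k = 200, 4
        Y = rng.standard_normal((n, 1, k)) + rng.standard_normal((n, 1, 1))
        C = _orthonormal_contrasts(k)
        D = Y[:, 0, :] @ C.T
        assert _gg_epsilon(D) == pytest.approx(1.0, abs=0.05)

    def test_ss_decomposition(self, rng):
        Y = rng.standard_normal((5, 2, 4))
        oracle = brute_force_rm_anova(Y)
        SS = oracle["SS"]
        n = 5
        ss_subj = 2 * 4 * sum((Y[s].mean() - Y.mean()) ** 2 for s in range(n))
        total = ((Y - Y.mean()) ** 2).sum()
        parts = ss_subj + sum(SS[k] for k in ("A", "B", "AB", "AS", "BS", "ABS"))
        assert parts == pytest.approx(total, abs=1e-9)

    def test_one_way_design(self, rng):
        Y = rng.standard_normal((6, 3))
        tab = long_table(Y[:, :, None], "condition", "dummy").drop(columns="dummy")
        res = rm_anova(tab, "y", ["condition"])
        assert len(res) == 1
        assert res.iloc[0]["df1"] == 2 and res.iloc[0]["df2"] == 10

    def test_unbalanced_rejected(self, rng):
        tab = long_table(rng.standard_normal((4, 2, 2)))
        tab = tab.iloc[:-1]
        with pytest.raises(StatsError, match="unbalanced"):
            rm_anova(tab, "y", ["texture", "block"])

    @given(seed=st.integers(0, 1000))
    @settings(deadline=None, max_examples=20)
    def test_gg_bounds(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(3, 6)
        D = rng.standard_normal((8, k - 1))
        eps = _gg_epsilon(D)
        assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0 + 1e-12


class TestPosthoc:
    def test_null_effect_gives_p_one(self, rng):
        # per-subject offsets but identical level effects -> t = 0, p = 1
        base = rng.standard_normal(6)
        rows = []
        for s in range(6):
            for lvl in ("a", "b", "c"):
                rows.append({"subject": f"s{s}", "condition": lvl, "y": base[s]})
        out = posthoc_pairwise(pd.DataFrame(rows), "y", "condition")
        assert (out["p_adj"] == 1.0).all()

    def test_bonferroni_multiplication(self, rng):
        rows = []
        for s in range(8):
            for lvl, eff in (("a", 0.0), ("b", 1.0), ("c", 0.3)):
                rows.append(
                    {"subject": f"s{s}", "condition": lvl,
                     "y": eff + rng.normal(0, 1.0)}
                )
        out = posthoc_pairwise(pd.DataFrame(rows), "y", "condition")
        assert len(out) == 3
        for _, r in out.iterrows():
            assert r["p_adj"] == pytest.approx(min(1.0, r["p"] * 3), abs=1e-12)
            assert r["p_adj"] >= r["p"]  # monotone

    def test_paired_t_closed_form(self):
        """Hand-computed paired t on a 4-subject toy table."""
        a = np.array([3.0, 5.0, 4.0, 6.0])
        b = np.array([2.0, 4.0, 4.0, 3.0])
        d = a - b
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(4))
        rows = [
            {"subject": f"s{i}", "condition": c, "y": v}
            for i, (va, vb) in enumerate(zip(a, b))
            for c, v in (("a", va), ("b", vb))
        ]
        out = posthoc_pairwise(pd.DataFrame(rows), "y", "condition")
        assert abs(out.iloc[0]["t"]) == pytest.approx(abs(t_hand), rel=1e-12)


class TestOutlierTrim:
    def test_extreme_value_removed(self):
        vals = [1.0] * 9 + [9.0]  # |z| = 2.846
        tab = pd.DataFrame({"g": "x", "v": vals})
        out = outlier_trim(tab, "v", ["g"])
        assert len(out) == 9 and 9.0 not in out["v"].values

    def test_identical_values_kept(self):
        tab = pd.DataFrame({"g": "x", "v": [2.0] * 6})
        assert len(outlier_trim(tab, "v", ["g"])) == 6

    def test_exactly_two_sd_kept(self):
        tab = pd.DataFrame({"g": "x", "v": [-0.5, -0.5, -0.5, -0.5, 0.0, 2.0]})
        assert len(outlier_trim(tab, "v", ["g"])) == 6


class TestCorrelationScreen:
    def _means(self, rng, speed_null=True):
        rows = []
        for s in range(8):
            load = 100 + rng.normal(0, 15)
            for tex, mu in (("hessian", 0.55), ("silk", 0.35)):
                rows.append(
                    {
                        "subject": f"s{s:02d}",
                        "texture": tex,
                        "median_friction": 2.0 * load / 100 * mu,
                        "median_load": load,
                        "median_speed": rng.normal(100, 20),
                    }
                )
        return pd.DataFrame(rows)

    def test_perfect_proportionality_combined(self, rng):
        means = self._means(rng)
        plan = correlation_screen(means)
        key = "median_friction~median_load|hessian"
        assert plan["correlations"][key]["r"] == pytest.approx(1.0)
        assert "median_friction" in plan["combine"]
        assert "median_load" in plan["combine"]

    def test_condition_free_speed_excluded(self, rng):
        means = self._means(rng)
        # a speed ANOVA with no significant effects marks speed for exclusion
        anova_tables = {
            "median_speed": pd.DataFrame({"p_corr": [0.4, 0.6, 0.9]}),
            "median_friction": pd.DataFrame({"p_corr": [1e-4, 0.2, 0.3]}),
            "median_load": pd.DataFrame({"p_corr": [0.2, 1e-3, 0.4]}),
        }
        plan = correlation_screen(means, anova_tables)
        assert plan["exclude"] == ["median_speed"]
        assert plan["covariates"] == ["median_friction", "median_load"]

    def test_pearson_closed_form(self):
        """Pearson r on a 5-point toy set equals the covariance ratio."""
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 7.0])
        r_hand = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        from scipy.stats import pearsonr

        assert pearsonr(x, y).statistic == pytest.approx(r_hand, rel=1e-12)

    def test_too_few_subjects(self, rng):
        means = self._means(rng).iloc[:4]
        with pytest.raises(StatsError):
            correlation_screen(means)
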