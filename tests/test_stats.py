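"""Statistics layer: formula oracles, degenerate inputs, identities."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from perivaq.stats import anova_posthoc, mixed_model, regression_partial, unpaired_t
from perivaq.synth import generate_rodent_measures


class TestAnova:
    def test_dunnett_produces_k_minus_1_comparisons(self, rng):
        vals = rng.normal(0, 1, 80)
        g = np.repeat(list("abcd"), 20)
        res = anova_posthoc(vals, g, correction="dunnett", reference="a")
        assert len(res.comparisons) == 3
        assert all("- a" in c for c in res.comparisons["contrast"])

    def test_tukey_produces_all_pairs(self, rng):
        vals = rng.normal(0, 1, 80)
        g = np.repeat(list("abcd"), 20)
        res = anova_posthoc(vals, g, correction="tukey")
        assert len(res.comparisons) == 6

    @pytest.mark.parametrize("correction", ["tukey", "sidak"])
    def test_adjusted_at_least_raw(self, rng, correction):
        for _ in range(5):
            vals = rng.normal(0, 1, 60)
            g = np.repeat(list("abc"), 20)
            res = anova_posthoc(vals, g, correction=correction)
            assert (res.comparisons["p_adj"] >= res.comparisons["p_raw"] - 1e-12).all()
            assert res.comparisons["p_adj"].between(0, 1).all()

    def test_zero_variance_distinct_means_handled(self):
        vals = np.repeat([1.0, 2.0, 3.0], 5)
        g = np.repeat(list("abc"), 5)
        res = anova_posthoc(vals, g, correction="dunnett", reference="a")
        assert np.isinf(res.effects["F"].iloc[0])
        assert res.pvalue == 0.0
        assert (res.comparisons["p_adj"] == 0.0).all()

    def test_singleton_group_named_in_error(self):
        with pytest.raises(ValueError, match="'b'"):
            anova_posthoc([1.0, 2.0, 3.0], ["a", "a", "b"])

    def test_f_matches_scipy_oracle(self, rng):
        vals = rng.normal(0, 1, 45)
        g = np.repeat(list("abc"), 15)
        res = anova_posthoc(vals, g)
        f, p = sps.f_oneway(*(vals[g == k] for k in "abc"))
        assert res.effects["F"].iloc[0] == pytest.approx(f, rel=1e-10)
        assert res.pvalue == pytest.approx(p, rel=1e-10)

    def test_two_way_reports_interaction(self, rng):
        n = 10
        rows = []
        for f1 in ("wt", "ko"):
            for f2 in ("vehicle", "drug"):
                mu = 1.0 if (f1 == "ko" and f2 == "drug") else 0.0
                rows.append(
                    pd.DataFrame(
                        {"v": rng.normal(mu, 0.5, n), "f1": f1, "f2": f2}
                    )
                )
        df = pd.concat(rows)
        res = anova_posthoc(df.v, df.f1, design="two_way", correction="tukey", factor2=df.f2)
        assert set(res.effects["term"]) == {"f1", "f2", "f1:f2"}
        assert len(res.comparisons) == 6  # 4 cells -> 6 pairs


class TestMixed:
    def test_single_cluster_rejected_with_advice(self):
        df = pd.DataFrame(
            {"value": np.arange(8.0), "group": ["a", "b"] * 4, "animal": "m1"}
        )
        with pytest.raises(ValueError, match="fixed-effects"):
            mixed_model(df)

    def test_balanced_zero_cluster_variance_matches_anova(self, rng):
        # no planted animal effect: fixed-effect estimates reduce to group means
        df = generate_rodent_measures(animal_sd=0.0, residual_sd=5.0, seed=3)
        sub = df[df.compartment == "neuropil"]
        res = mixed_model(sub, cluster_col="animal")
        means = sub.groupby("group")["value"].mean()
        est = res.effects.set_index("term").loc["C(group)[T.young]", "estimate"]
        assert est == pytest.approx(means["young"] - means["aged"], abs=1e-6)

    def test_variance_components_recovered(self):
        errs_re, errs_resid = [], []
        for s in range(12):
            rng = np.random.default_rng(400 + s)
            rows = []
            for c in range(12):
                b = rng.normal(0, 1.0)
                for _ in range(10):
                    rows.append({"value": b + rng.normal(0, 0.5), "group": "g1" if c < 6 else "g2", "animal": f"m{c}"})
            res = mixed_model(pd.DataFrame(rows), cluster_col="animal")
            errs_re.append(abs(res.extras["cluster_sd"] - 1.0))
            errs_resid.append(abs(res.extras["residual_sd"] - 0.5))
        assert np.median(errs_re) < 0.25
        assert np.median(errs_resid) < 0.125

    def test_missing_values_tolerated(self):
        df = generate_rodent_measures(seed=5)
        sub = df[df.compartment == "pv_endfoot"].copy()
        sub.loc[sub.index[:10], "value"] = np.nan
        res = mixed_model(sub, cluster_col="animal")
        assert np.isfinite(res.pvalue)

    def test_posthoc_sidak_adjustment_monotone(self):
        df = generate_rodent_measures(seed=6)
        sub = df[df.compartment == "pv_astro"]
        res = mixed_model(sub, cluster_col="animal", correction="sidak")
        assert (res.comparisons["p_adj"] >= res.comparisons["p_raw"] - 1e-12).all()


class TestRegression:
    def test_exact_line(self):
        x = np.linspace(0, 10, 20)
        df = pd.DataFrame({"y": 2.0 * x, "x": x})
        res = regression_partial(df, "y", "x")
        assert res.effects["estimate"].iloc[0] == pytest.approx(2.0)
        assert res.r2 == pytest.approx(1.0)

    def test_frisch_waugh_identity(self, rng):
        df = pd.DataFrame(
            {
                "y": rng.normal(size=60),
                "x": rng.normal(size=60),
                "z1": rng.normal(size=60),
                "z2": rng.normal(size=60),
            }
        )
        res = regression_partial(df, "y", "x", ("z1", "z2"))
        pairs = res.extras["partial_pairs"]
        slope = np.linalg.lstsq(
            np.column_stack([pairs[:, 0], np.ones(len(pairs))]), pairs[:, 1], rcond=None
        )[0][0]
        assert abs(slope - res.effects["estimate"].iloc[0]) < 1e-10

    def test_partial_slope_unbiased_under_confounding(self, rng):
        # z confounds x and y; the covariate-adjusted slope recovers 0.5
        marginal, partial = [], []
        for _ in range(50):
            z = rng.normal(size=200)
            x = 0.7 * z + rng.normal(size=200) * np.sqrt(1 - 0.49)
            y = 0.5 * x + 1.0 * z + rng.normal(size=200)
            df = pd.DataFrame({"y": y, "x": x, "z": z})
            partial.append(
                regression_partial(df, "y", "x", ("z",)).effects["estimate"].iloc[0]
            )
            marginal.append(regression_partial(df, "y", "x").effects["estimate"].iloc[0])
        assert np.mean(partial) == pytest.approx(0.5, abs=0.05)
        assert abs(np.mean(marginal) - 0.5) > 0.2  # marginal slope is biased

    def test_collinear_design_identified(self):
        x = np.linspace(0, 1, 30)
        df = pd.DataFrame({"y": np.random.default_rng(0).normal(size=30), "x": x, "z": 2 * x})
        with pytest.raises(ValueError, match="collinear"):
            regression_partial(df, "y", "x", ("z",))


class TestTTest:
    def test_identical_samples(self):
        res = unpaired_t([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.effects["t"].iloc[0] == 0.0
        assert res.pvalue == 1.0

    def test_matches_welch_formula_oracle(self, rng):
        for _ in range(10):
            a, b = rng.normal(0, 1, 15), rng.normal(0.5, 2, 25)
            res = unpaired_t(a, b)
            va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
            t = (a.mean() - b.mean()) / np.sqrt(va + vb)
            df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
            p = 2 * sps.t.sf(abs(t), df)
            assert res.effects["t"].iloc[0] == pytest.approx(t, abs=1e-10)
            assert res.pvalue == pytest.approx(p, abs=1e-10)

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            unpaired_t([1.0], [1.0, 2.0])
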