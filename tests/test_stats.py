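"""The inference battery against closed forms and independent implementations."""

import numpy as np
import pandas as pd
import pytest

from phenocage.core import CriterionResult, ValidationError
from phenocage.stats import (
    bonferroni,
    compare_groups,
    mantel_cox,
    normality_gate,
    one_sample_vs_chance,
    three_way_errors,
)

GROUPS = ["wildtype_male", "mdx_male", "wildtype_female", "mdx_female"]


def crit(sid, k=None, total=300):
    return CriterionResult(sid, k, k is None, total if k is None else max(k, 1))


def two_group_logrank_oracle(d1, e1, d2, e2):
    """Closed-form single-stratum two-group log-rank chi-square.

    Textbook computation over the pooled distinct event times: at each
    event time t, O1 accumulates group-1 events and E1 the hypergeometric
    expectation n1(t) * d(t) / n(t); the variance term is
    d(t) * (n1/n) * (1 - n1/n) * (n - d) / (n - 1).
    """
    d1, e1 = np.asarray(d1, float), np.asarray(e1, bool)
    d2, e2 = np.asarray(d2, float), np.asarray(e2, bool)
    times = np.unique(np.concatenate([d1[e1], d2[e2]]))
    O1 = E1 = V = 0.0
    for t in times:
        n1 = np.sum(d1 >= t)
        n2 = np.sum(d2 >= t)
        n = n1 + n2
        dd1 = np.sum((d1 == t) & e1)
        dd2 = np.sum((d2 == t) & e2)
        d = dd1 + dd2
        if n == 0 or d == 0:
            continue
        O1 += dd1
        E1 += n1 * d / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O1 - E1) ** 2 / V if V > 0 else 0.0


class TestNormalityGate:
    def test_normal_groups_usually_parametric(self):
        rng = np.random.default_rng(0)
        parametric = 0
        reps = 60
        for _ in range(reps):
            vals = {g: rng.normal(10, 2, 15) for g in GROUPS}
            gate, _ = normality_gate(vals)
            parametric += gate == "parametric"
        # four independent Shapiro tests at alpha=0.05: expect ~0.95^4=81%
        assert 0.65 <= parametric / reps <= 0.95

    def test_heavy_tailed_group_goes_nonparametric(self):
        rng = np.random.default_rng(1)
        vals = {g: rng.normal(10, 2, 15) for g in GROUPS[:3]}
        vals[GROUPS[3]] = rng.lognormal(0, 2.5, 15)
        gate, table = normality_gate(vals)
        assert gate == "nonparametric"

    def test_constant_group_forced_nonparametric_with_warning(self):
        vals = {"a": np.ones(10), "b": np.random.default_rng(2).normal(0, 1, 10)}
        with pytest.warns(UserWarning, match="constant"):
            gate, table = normality_gate(vals)
        assert gate == "nonparametric"

    def test_tiny_group_forced_nonparametric(self):
        vals = {"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0, 2.5]}
        with pytest.warns(UserWarning, match="n < 3"):
            gate, _ = normality_gate(vals)
        assert gate == "nonparametric"


class TestCompareGroups:
    def test_identical_groups_nothing_significant(self):
        base = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = compare_groups({g: base for g in GROUPS}, gate="parametric")
        assert res.p_value == pytest.approx(1.0)
        assert (res.contrasts["p_adj"] == 1.0).all()

    def test_three_sd_shift_detected(self):
        rng = np.random.default_rng(3)
        detected = 0
        reps = 20
        for _ in range(reps):
            vals = {g: rng.normal(10, 2, 15) for g in GROUPS}
            vals["mdx_female"] = rng.normal(16, 2, 15)  # +3 SD
            res = compare_groups(vals, gate="parametric")
            row = res.contrasts[res.contrasts["contrast"]
                                == "wildtype_female vs mdx_female"]
            detected += float(row["p_adj"].iloc[0]) < 0.05
        assert detected >= 19

    def test_anova_agrees_with_statsmodels(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        rng = np.random.default_rng(4)
        for _ in range(20):
            vals = {g: rng.normal(rng.uniform(5, 15), rng.uniform(1, 3), 12)
                    for g in GROUPS}
            res = compare_groups(vals, gate="parametric")
            df = pd.concat(
                [pd.DataFrame({"y": v, "g": k}) for k, v in vals.items()],
                ignore_index=True)
            table = sm.stats.anova_lm(smf.ols("y ~ C(g)", df).fit(), typ=2)
            assert res.statistic == pytest.approx(float(table["F"].iloc[0]),
                                                  abs=1e-6)
            assert res.p_value == pytest.approx(float(table["PR(>F)"].iloc[0]),
                                                abs=1e-9)

    def test_kruskal_branch_runs_dunn(self):
        rng = np.random.default_rng(5)
        vals = {g: rng.lognormal(0, 1, 15) for g in GROUPS}
        res = compare_groups(vals, gate="nonparametric")
        assert res.test == "kruskal_wallis" and res.adjustment == "dunn"
        assert (res.contrasts["p_adj"] >= res.contrasts["p_raw"] - 1e-12).all()

    def test_bonferroni_exact(self):
        assert bonferroni(0.03, 2) == pytest.approx(0.06)
        assert bonferroni(0.7, 2) == 1.0

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(6)
        for gate in ("parametric", "nonparametric"):
            vals = {g: rng.normal(0, 1, 10) for g in GROUPS}
            res = compare_groups(vals, gate=gate)
            assert (res.contrasts["p_adj"] >= res.contrasts["p_raw"] - 1e-12).all()

    def test_missing_group_in_planned_pair_errors(self):
        with pytest.raises(ValidationError):
            compare_groups({"a": [1.0, 2.0]}, gate="parametric",
                           planned_pairs=[("a", "b")])


class TestMantelCox:
    def test_identical_groups_null(self):
        res = mantel_cox({
            "a": [crit(f"a{i}", 30 + 7 * i) for i in range(10)],
            "b": [crit(f"b{i}", 30 + 7 * i) for i in range(10)],
        }, pairwise_pairs=[("a", "b")])
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_extreme_separation(self):
        res = mantel_cox({
            "a": [crit(f"a{i}", 30) for i in range(12)],
            "b": [crit(f"b{i}", None, total=500) for i in range(12)],
        }, pairwise_pairs=[("a", "b")])
        assert res.p_value < 0.001

    def test_all_censored_reported_undefined(self):
        res = mantel_cox({
            "a": [crit(f"a{i}", None) for i in range(5)],
            "b": [crit(f"b{i}", None) for i in range(5)],
        })
        assert res.statistic is None and res.note is not None

    def test_agrees_with_closed_form_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            d1 = rng.integers(30, 400, size=15)
            d2 = rng.integers(30, 400, size=15)
            e1 = rng.random(15) > 0.2
            e2 = rng.random(15) > 0.2
            res = mantel_cox({
                "a": [crit(f"a{i}", int(d) if e else None,
                           total=int(d)) for i, (d, e) in enumerate(zip(d1, e1))],
                "b": [crit(f"b{i}", int(d) if e else None,
                           total=int(d)) for i, (d, e) in enumerate(zip(d2, e2))],
            }, pairwise_pairs=[("a", "b")])
            oracle = two_group_logrank_oracle(d1, e1, d2, e2)
            assert res.statistic == pytest.approx(oracle, rel=1e-6)


class TestThreeWayErrors:
    def _frame(self, rng, day_effect=0.0):
        rows = []
        for g in ("wildtype", "mdx"):
            for s in ("male", "female"):
                for d in ("RL1", "RL2"):
                    mu = 30.0 - (day_effect if d == "RL2" else 0.0)
                    for _ in range(15):
                        rows.append({
                            "genotype": g, "sex": s, "day": d,
                            "perseverative": rng.normal(mu, 5.0),
                            "neutral": rng.normal(8.0, 2.0),
                        })
        return pd.DataFrame(rows)

    def test_strong_day_effect_detected(self):
        rng = np.random.default_rng(8)
        hits = 0
        for _ in range(10):
            tables = three_way_errors(self._frame(rng, day_effect=15.0))
            t = tables["perseverative"]
            assert t.loc["C(day)", "PR(>F)"] < 0.05
            others = [ix for ix in t.index
                      if ix not in ("C(day)", "Residual")]
            hits += (t.loc[others, "PR(>F)"] > 0.05).all()
        # six null terms at alpha=0.05 all stay quiet with prob ~0.95^6=0.74
        assert hits >= 5

    def test_all_zero_errors_degenerate_warning(self):
        df = pd.DataFrame([
            {"genotype": g, "sex": s, "day": d, "perseverative": 0,
             "neutral": 0}
            for g in ("wildtype", "mdx") for s in ("male", "female")
            for d in ("RL1", "RL2") for _ in range(3)
        ])
        with pytest.warns(UserWarning, match="degenerate"):
            tables = three_way_errors(df)
        assert tables["perseverative"]["F"].isna().all()

    def test_empty_cell_named(self):
        rng = np.random.default_rng(9)
        df = self._frame(rng)
        df = df[~((df.genotype == "mdx") & (df.sex == "female")
                  & (df.day == "RL2"))]
        with pytest.raises(ValidationError, match="mdx.*female.*RL2"):
            three_way_errors(df)

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(10)
        df = self._frame(rng, day_effect=5.0)
        ours = three_way_errors(df)["perseverative"]
        ref = pingouin.anova(data=df.rename(columns={"perseverative": "y"}),
                             dv="y", between=["genotype", "sex", "day"])
        ref = ref.set_index("Source")
        for term, ref_term in [("C(genotype)", "genotype"), ("C(sex)", "sex"),
                               ("C(day)", "day")]:
            assert ours.loc[term, "F"] == pytest.approx(
                float(ref.loc[ref_term, "F"]), rel=1e-6)


class TestOneSampleVsChance:
    def test_values_at_chance(self):
        res = one_sample_vs_chance({"g": [25.0] * 6}, chance_pct=25.0)
        assert res["t"].iloc[0] == 0.0 and res["p"].iloc[0] == 1.0

    def test_symmetric_values_t_zero(self):
        res = one_sample_vs_chance({"g": [20.0, 30.0, 15.0, 35.0]},
                                   chance_pct=25.0)
        assert res["t"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_three_sd_above_chance(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(25.0 + 9.0, 3.0, 15)
        res = one_sample_vs_chance({"g": vals}, chance_pct=25.0)
        assert res["p"].iloc[0] < 0.01

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            one_sample_vs_chance({"g": [25.0]})
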