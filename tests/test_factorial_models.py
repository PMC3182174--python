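"""F tails, two-way and mixed ANOVA, Levene, Dixon, FDR."""
import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from fatbody import (
    Design,
    bh_fdr,
    dixon_outlier,
    f_tail_p,
    fit_mixed_anova,
    levene_check,
    mixed_anova_all,
    two_way_anova,
)
from fatbody.errors import DomainError


class TestFTail:
    @pytest.mark.parametrize(
        "F, df1, df2, printed",
        [
            (14.89, 1, 59, 0.0002849),
            (4.3019, 1, 40, 0.04455),
            (4.7652, 1, 56, 0.03325),
            (11.7385, 1, 580, 0.0006555),
        ],
    )
    def test_reproduces_published_triplets(self, F, df1, df2, printed):
        assert f_tail_p(F, df1, df2) == pytest.approx(printed, rel=5e-4)

    def test_zero_statistic_gives_one(self):
        assert f_tail_p(0.0, 3, 17) == 1.0

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            f_tail_p(1.0, 0, 5)
        with pytest.raises(DomainError):
            f_tail_p(-1.0, 1, 5)


class TestTwoWayAnova:
    def _balanced(self, effect=1.0, jitter=None):
        geno = ["L"] * 6 + ["H"] * 6
        treat = (["C"] * 3 + ["K"] * 3) * 2
        base = np.array([effect if t == "K" else 0.0 for t in treat])
        if jitter is None:
            jitter = np.tile([-0.01, 0.0, 0.01], 4)
        return base + jitter, geno, treat

    def test_pure_treatment_shift(self):
        values, geno, treat = self._balanced()
        res = two_way_anova(values, geno, treat)
        assert res.table.loc["treatment", "p"] < 1e-9
        # identical jitter pattern in both genotypes: genotype SS is exactly 0
        assert res.table.loc["genotype", "F"] == pytest.approx(0.0, abs=1e-20)

    def test_treatment_f_invariant_to_genotype_relabel(self):
        rng = np.random.default_rng(1)
        values, geno, treat = self._balanced(jitter=rng.normal(0, 0.3, 12))
        f1 = two_way_anova(values, geno, treat).table.loc["treatment", "F"]
        flipped = ["H" if g == "L" else "L" for g in geno]
        f2 = two_way_anova(values, flipped, treat).table.loc["treatment", "F"]
        assert f1 == pytest.approx(f2, abs=1e-10)

    def test_unbalanced_sizes_and_planted_direction(self):
        rng = np.random.default_rng(2)
        sizes = {"CL": 11, "KL": 10, "CH": 12, "KH": 11}
        rows = []
        for g, n in sizes.items():
            shift = 0.8 if g[0] == "K" else 0.0
            for _ in range(n):
                rows.append((shift + rng.normal(0, 0.4), g[1], g[0]))
        df = pd.DataFrame(rows, columns=["value", "genotype", "treatment"])
        res = two_way_anova(df["value"], df["genotype"], df["treatment"])
        assert res.table.loc["treatment", "p"] < 0.01
        means = df.groupby("treatment")["value"].mean()
        assert means["K"] > means["C"]

    def test_permuted_labels_give_uniform_p(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=24)
        geno = np.array(["L", "H"] * 12)
        treat = np.array(["C"] * 12 + ["K"] * 12)
        ps = []
        for _ in range(300):
            ps.append(
                two_way_anova(values, geno, rng.permutation(treat)).table.loc[
                    "treatment", "p"
                ]
            )
        frac = np.mean(np.array(ps) < 0.1)
        assert abs(frac - 0.1) < 3 * np.sqrt(0.1 * 0.9 / 300) + 0.02


class TestMixedAnova:
    def _sim(self, seed=0, tau=0.0, reps=1):
        d = Design.from_groups(n_replicates=4, ages=(7, 9, 11))
        rng = np.random.default_rng(seed)
        sample_effect = pd.Series(rng.normal(0, tau, len(d.samples)), index=d.samples)
        rows = {}
        for s in d.samples:
            meta = d.frame.loc[s]
            mu = (
                0.5 * (meta["treatment"] == "K")
                + 0.3 * (meta["genotype"] == "H")
                - 0.4 * (int(meta["age"]) - 7) / 2
            )
            rows[s] = mu + sample_effect[s] + rng.normal(0, 0.3)
        return pd.Series(rows), d

    def test_single_measurement_equals_fixed_three_way(self):
        values, d = self._sim(seed=4)
        res = fit_mixed_anova(values, d)
        assert res.method == "fixed-reduction"
        assert res.random_variance == 0.0
        df = pd.DataFrame(
            {
                "value": values,
                "treatment": d.frame["treatment"],
                "genotype": d.frame["genotype"],
                "age": d.frame["age"].astype(str),
            }
        )
        model = smf.ols("value ~ C(treatment) * C(genotype) * C(age)", data=df).fit()
        aov = sm.stats.anova_lm(model, typ=2)
        for effect in res.table.index:
            key = ":".join(f"C({f})" for f in effect.split(":"))
            assert res.table.loc[effect, "F"] == pytest.approx(
                float(aov.loc[key, "F"]), abs=1e-6
            )

    def test_replicated_measurements_use_sample_level_error(self):
        values, d = self._sim(seed=5)
        # duplicate each sample measurement exactly: within-sample variance 0,
        # so the containment fit must equal the single-measurement fit
        dup = pd.concat([values, values])
        res_dup = fit_mixed_anova(dup, d)
        res_one = fit_mixed_anova(values, d)
        assert res_dup.method == "containment"
        assert res_dup.random_variance == pytest.approx(0.0, abs=1e-20)
        for effect in res_one.table.index:
            assert res_dup.table.loc[effect, "F"] == pytest.approx(
                res_one.table.loc[effect, "F"], abs=1e-8
            )

    def test_collapsed_factor_marked_untestable(self):
        values, d = self._sim(seed=6)
        one_age = d.frame.index[d.frame["age"] == 7]
        res = fit_mixed_anova(values.loc[one_age], d)
        assert "age" in res.untestable
        assert "treatment:genotype:age" in res.untestable
        assert "treatment" in res.table.index

    def test_null_proteins_rarely_fdr_significant(self):
        d = Design.from_groups(n_replicates=4, ages=(7, 9, 11))
        rng = np.random.default_rng(7)
        values = pd.DataFrame(
            rng.normal(size=(40, len(d.samples))),
            index=[f"p{i}" for i in range(40)],
            columns=d.samples,
        )
        out = mixed_anova_all(values, d)
        assert (out.groupby("effect")["significant"].mean() <= 0.05).all()


class TestLevene:
    def test_matches_scipy_mean_centered(self, rng):
        groups = [rng.normal(size=8), rng.normal(size=10), rng.normal(size=7)]
        labels = np.repeat(["a", "b", "c"], [8, 10, 7])
        w, p = levene_check(np.concatenate(groups), labels)
        sw, sp = stats.levene(*groups, center="mean")
        assert w == pytest.approx(sw, abs=1e-10)
        assert p == pytest.approx(sp, abs=1e-10)

    def test_inflated_group_detected(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(0, 10, 40)
        _, p = levene_check(np.concatenate([a, b]), ["a"] * 40 + ["b"] * 40)
        assert p < 1e-6

    def test_equidistant_degenerate_case(self):
        values = [0.0, 2.0, 10.0, 12.0]
        w, p = levene_check(values, ["a", "a", "b", "b"])
        assert w == 0.0 and p == 1.0


class TestDixon:
    def test_extreme_value_rejected(self):
        res = dixon_outlier([1.0, 2.0, 3.0, 100.0])
        assert res.statistic == "r10"
        assert res.Q == pytest.approx(97 / 99)
        assert res.suspect == 100.0 and res.rejected

    def test_symmetric_triple_not_rejected(self):
        res = dixon_outlier([1.0, 2.0, 3.0])
        assert res.Q == pytest.approx(0.5)
        assert not res.rejected

    def test_constant_vector_degenerate(self):
        res = dixon_outlier([5.0, 5.0, 5.0, 5.0])
        assert res.degenerate and not res.rejected

    def test_sample_size_domain(self):
        with pytest.raises(DomainError):
            dixon_outlier([1.0, 2.0])
        with pytest.raises(DomainError):
            dixon_outlier(list(range(31)))

    def test_larger_samples_use_r22(self, rng):
        x = np.concatenate([rng.normal(size=19), [40.0]])
        res = dixon_outlier(x)
        assert res.statistic == "r22"
        assert res.rejected


class TestBhFdr:
    def test_hand_computed_step_up(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged_and_all_ones(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_never_below_raw_and_order_invariant(self, rng):
        p = rng.uniform(size=50)
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all()
        order = rng.permutation(50)
        assert np.allclose(q[order], bh_fdr(p[order]))

    def test_nan_passthrough(self):
        q = bh_fdr([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and not np.isnan(q[0])
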