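import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings as hyp_settings
from hypothesis import strategies as st
from scipy import stats

from plastinorm import mixed_anova as ma
from plastinorm.synthetic_data import ValidationError

from conftest import flat_table, quadratic_table


def holm_oracle(pvals):
    """Definition-based oracle: the adjusted p of H_i is the smallest level
    at which the step-down procedure rejects H_i."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    for target in range(m):
        candidates = sorted({min(1.0, (m - k) * p[order[k]]) for k in range(m)} | {1.0})
        best = 1.0
        for alpha in candidates:
            # run Holm at level alpha and see whether H_target is rejected
            rejected = set()
            for k in range(m):
                if p[order[k]] <= alpha / (m - k):
                    rejected.add(order[k])
                else:
                    break
            if target in rejected:
                best = alpha
                break
        adjusted[target] = best
    return adjusted


class TestHolmAdjust:
    def test_hand_worked_pair(self):
        assert np.allclose(ma.holm_adjust([0.01, 0.04]), [0.02, 0.04])

    def test_cap_at_one(self):
        assert np.allclose(ma.holm_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_single_value_unchanged(self):
        assert ma.holm_adjust([0.2]) == pytest.approx([0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            ma.holm_adjust([0.5, 1.5])
        with pytest.raises(ValidationError):
            ma.holm_adjust([-0.1])

    @given(st.lists(st.integers(0, 100), min_size=1, max_size=6))
    @hyp_settings(max_examples=200, deadline=None)
    def test_matches_definition_oracle(self, grid_points):
        p = np.array(grid_points) / 100.0
        assert np.allclose(ma.holm_adjust(p), holm_oracle(p), atol=1e-12)

    def test_between_bonferroni_bounds(self, rng):
        for _ in range(50):
            p = rng.uniform(0, 1, rng.integers(1, 8))
            adj = ma.holm_adjust(p)
            assert np.all(adj >= p - 1e-15)
            assert np.all(adj <= np.minimum(1.0, p * p.size) + 1e-15)


class TestFitMixedModel:
    def test_ols_limit_recovers_cell_means(self):
        table = flat_table({"a": 1.0, "b": 2.0, "c": 3.5}, sigma=0.3, seed=1)
        spec = ma.MixedModelSpec(fixed=("genotype",))
        fit = ma.fit_mixed_model(table, spec)
        fitted = fit.X @ fit.beta
        cell_means = table.groupby("genotype")["rate_mm_per_hr"].transform("mean")
        assert np.allclose(fitted, cell_means, atol=1e-10)

    def test_two_group_f_equals_t_squared(self):
        table = flat_table({"a": 1.0, "b": 1.3}, sigma=0.3, seed=2, n_replicates=2)
        fit = ma.fit_mixed_model(table, ma.MixedModelSpec(fixed=("genotype",)))
        res = ma.type3_tests(fit)
        ya = table[table["genotype"] == "a"]["rate_mm_per_hr"]
        yb = table[table["genotype"] == "b"]["rate_mm_per_hr"]
        t = stats.ttest_ind(ya, yb)
        row = res.fixed.iloc[0]
        assert row["f_value"] == pytest.approx(t.statistic**2, abs=1e-8)
        assert row["df_den"] == pytest.approx(len(ya) + len(yb) - 2, abs=1e-8)
        assert row["p_value"] == pytest.approx(t.pvalue, abs=1e-10)

    def test_variance_component_recovery(self):
        # 100 per-parameter-style datasets with sigma2_G = 0.04
        estimates = []
        for seed in range(100):
            rng = np.random.default_rng([10, seed])
            rows = []
            for i in range(12):
                u = rng.normal(0, 0.2)
                for s in [1.0, 2.0, 3.0]:
                    for rep in range(3):
                        rows.append({
                            "genotype": f"g{i}", "setting": s,
                            "rate_mm_per_hr": 2.0 + u + rng.normal(0, 0.3),
                        })
            fit = ma.fit_mixed_model(
                pd.DataFrame(rows),
                ma.MixedModelSpec(fixed=("setting",), random=("genotype",)),
            )
            estimates.append(fit.variance_components["genotype"])
        assert abs(np.mean(estimates) - 0.04) < 0.3 * 0.04

    def test_aliased_term_rejected(self):
        table = flat_table({"a": 1.0, "b": 2.0}, seed=3)
        table["mechanism"] = np.where(table["genotype"] == "a", "m1", "m2")
        spec = ma.MixedModelSpec(fixed=("genotype", "mechanism"))
        with pytest.raises(ValidationError, match="aliased"):
            ma.fit_mixed_model(table, spec)

    def test_empty_table_rejected(self):
        table = flat_table({"a": 1.0}, seed=4).assign(missing_flag=1)
        with pytest.raises(ValidationError):
            ma.fit_mixed_model(table, ma.MixedModelSpec(fixed=("setting",)))


class TestType3Satterthwaite:
    def test_balanced_random_intercept_exact_df(self):
        # groups nested in two treatments: denominator df = g - 2 exactly
        rng = np.random.default_rng(11)
        g, n = 12, 5
        rows = []
        for i in range(g):
            treat = "t1" if i < g // 2 else "t2"
            u = rng.normal(0, 0.4)
            for _ in range(n):
                rows.append({
                    "genotype": f"g{i}", "mechanism": treat,
                    "rate_mm_per_hr": 2.0 + (0.3 if treat == "t1" else 0.0)
                    + u + rng.normal(0, 0.25),
                })
        fit = ma.fit_mixed_model(
            pd.DataFrame(rows),
            ma.MixedModelSpec(fixed=("mechanism",), random=("genotype",)),
        )
        res = ma.type3_tests(fit)
        assert res.fixed.iloc[0]["df_den"] == pytest.approx(g - 2, abs=1e-8)

    def test_balanced_random_intercept_f_matches_anova_oracle(self):
        # classical nested ANOVA: F = MS(treatment) / MS(groups within)
        rng = np.random.default_rng(12)
        g, n = 10, 4
        rows = []
        for i in range(g):
            treat = "t1" if i < g // 2 else "t2"
            u = rng.normal(0, 0.4)
            for _ in range(n):
                rows.append({
                    "genotype": f"g{i}", "mechanism": treat,
                    "rate_mm_per_hr": 2.0 + (0.5 if treat == "t1" else 0.0)
                    + u + rng.normal(0, 0.25),
                })
        df = pd.DataFrame(rows)
        fit = ma.fit_mixed_model(
            df, ma.MixedModelSpec(fixed=("mechanism",), random=("genotype",))
        )
        res = ma.type3_tests(fit)
        gm = df.groupby(["mechanism", "genotype"])["rate_mm_per_hr"].mean()
        grand = df["rate_mm_per_hr"].mean()
        tm = df.groupby("mechanism")["rate_mm_per_hr"].mean()
        ss_treat = n * (g // 2) * np.sum((tm - grand) ** 2)
        ss_group = n * np.sum((gm - tm.reindex(gm.index.get_level_values(0)).values) ** 2)
        f_oracle = (ss_treat / 1) / (ss_group / (g - 2))
        assert res.fixed.iloc[0]["f_value"] == pytest.approx(f_oracle, rel=1e-6)

    def test_balanced_two_way_mixed_matches_mean_square_oracle(self):
        # fixed setting, random genotype and genotype x setting:
        # F(setting) = MS(setting) / MS(interaction)
        rng = np.random.default_rng(13)
        g, e, n = 8, 4, 3
        rows = []
        for i in range(g):
            u = rng.normal(0, 0.3)
            w = rng.normal(0, 0.25, e)
            for k in range(e):
                for _ in range(n):
                    rows.append({
                        "genotype": f"g{i}", "setting": float(k),
                        "rate_mm_per_hr": 2.0 + 0.2 * k + u + w[k]
                        + rng.normal(0, 0.2),
                    })
        df = pd.DataFrame(rows)
        fit = ma.fit_mixed_model(
            df,
            ma.MixedModelSpec(fixed=("setting",), random=("genotype", "setting:genotype")),
        )
        res = ma.type3_tests(fit)
        grand = df["rate_mm_per_hr"].mean()
        sm = df.groupby("setting")["rate_mm_per_hr"].mean()
        gm = df.groupby("genotype")["rate_mm_per_hr"].mean()
        cm = df.groupby(["genotype", "setting"])["rate_mm_per_hr"].mean()
        ss_e = g * n * np.sum((sm - grand) ** 2)
        ss_int = n * sum(
            (cm[gt, s] - gm[gt] - sm[s] + grand) ** 2
            for gt in gm.index for s in sm.index
        )
        f_oracle = (ss_e / (e - 1)) / (ss_int / ((g - 1) * (e - 1)))
        row = res.fixed.set_index("term").loc["setting"]
        assert row["f_value"] == pytest.approx(f_oracle, rel=1e-5)
        assert row["df_den"] == pytest.approx((g - 1) * (e - 1), rel=1e-5)

    def test_f_invariant_to_term_order(self):
        table = quadratic_table({"a": 30.0, "b": 33.0}, sigma=0.25, seed=14)
        specs = [
            ma.MixedModelSpec(fixed=perm)
            for perm in itertools.permutations(("genotype", "setting", "genotype:setting"))
        ]
        results = []
        for spec in specs:
            res = ma.type3_tests(ma.fit_mixed_model(table, spec))
            results.append(res.fixed.set_index("term")["f_value"].sort_index())
        for other in results[1:]:
            pd.testing.assert_series_equal(results[0], other, atol=1e-8, rtol=0)

    def test_survives_random_missingness(self, rng):
        table = quadratic_table({"a": 30.0, "b": 28.0, "c": 34.0}, sigma=0.25, seed=15)
        drop = rng.choice(len(table), size=int(0.02 * len(table)), replace=False)
        table = table.drop(index=drop)
        fit = ma.fit_mixed_model(
            table,
            ma.MixedModelSpec(
                fixed=("setting",), random=("genotype", "setting:genotype")
            ),
        )
        res = ma.type3_tests(fit)
        assert np.isfinite(res.fixed[["f_value", "df_den", "p_value"]]).all().all()


class TestLrtRandomEffects:
    @staticmethod
    def _dataset(sigma_g, seed, g=12, n=9):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(g):
            u = rng.normal(0, sigma_g)
            for k in range(n):
                rows.append({
                    "genotype": f"g{i}", "setting": float(k % 3),
                    "rate_mm_per_hr": 2.0 + u + rng.normal(0, 0.3),
                })
        return pd.DataFrame(rows)

    def test_chi2_nonnegative(self):
        for seed in range(5):
            fit = ma.fit_mixed_model(
                self._dataset(0.1, seed),
                ma.MixedModelSpec(fixed=("setting",), random=("genotype",)),
            )
            out = ma.lrt_random_effects(fit, "genotype")
            assert out["chi2"] >= 0.0

    def test_null_variance_gives_large_p(self):
        pvals = []
        for seed in range(30):
            fit = ma.fit_mixed_model(
                self._dataset(0.0, [20, seed]),
                ma.MixedModelSpec(fixed=("setting",), random=("genotype",)),
            )
            pvals.append(ma.lrt_random_effects(fit, "genotype")["p"])
        assert np.median(pvals) >= 0.3

    def test_power_with_large_variance(self):
        # ICC 0.5: sigma_g = sigma_e, 26 groups x 30 obs
        hits = 0
        for seed in range(15):
            rng = np.random.default_rng([21, seed])
            rows = []
            for i in range(26):
                u = rng.normal(0, 0.3)
                for k in range(30):
                    rows.append({
                        "genotype": f"g{i}", "setting": float(k % 3),
                        "rate_mm_per_hr": 2.0 + u + rng.normal(0, 0.3),
                    })
            fit = ma.fit_mixed_model(
                pd.DataFrame(rows),
                ma.MixedModelSpec(fixed=("setting",), random=("genotype",)),
            )
            hits += ma.lrt_random_effects(fit, "genotype")["p"] < 0.001
        assert hits >= 14

    def test_unknown_term_rejected(self):
        fit = ma.fit_mixed_model(
            self._dataset(0.1, 22),
            ma.MixedModelSpec(fixed=("setting",), random=("genotype",)),
        )
        with pytest.raises(ValidationError):
            ma.lrt_random_effects(fit, "setting:genotype")


class TestPairwiseControlTests:
    def test_single_mutant_adjusted_equals_raw(self):
        table = quadratic_table({"4200": 33.0, "m1": 30.0}, sigma=0.25, seed=30)
        out = ma.pairwise_control_tests(table, "4200", "temperature")
        assert len(out) == 1
        assert out["p_adjusted"].iloc[0] == pytest.approx(out["p_raw"].iloc[0])

    def test_missing_control_rejected(self):
        table = quadratic_table({"m1": 30.0, "m2": 31.0}, seed=31)
        with pytest.raises(ValidationError):
            ma.pairwise_control_tests(table, "4200", "temperature")

    def test_adjustment_monotone(self):
        table = quadratic_table(
            {"4200": 33.0, "m1": 30.0, "m2": 33.0, "m3": 25.0}, sigma=0.25, seed=32
        )
        out = ma.pairwise_control_tests(table, "4200", "temperature")
        assert (out["p_adjusted"] >= out["p_raw"] - 1e-12).all()

    def test_elevation_shift_keeps_interaction_null(self):
        # a pure elevation change must not trigger the interaction test:
        # raw interaction p-values stay uniform under this null
        pvals = []
        for seed in range(200):
            table = flat_table({"4200": 3.0, "m1": 2.5}, sigma=0.2, seed=[40, seed])
            out = ma.pairwise_control_tests(table, "4200", "temperature")
            pvals.append(out["p_raw"].iloc[0])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_detects_shape_change(self):
        table = quadratic_table({"4200": 33.7, "m1": 25.3}, sigma=0.2, seed=41)
        out = ma.pairwise_control_tests(table, "4200", "temperature")
        assert out["significant"].iloc[0]
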