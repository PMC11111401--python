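import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from paleoresil.stat_synthesis import (
    describe,
    eta_squared,
    fit_frequency_model,
    fit_mixed,
    stepwise_ic,
)


def synth_table(
    rng,
    n_regions=8,
    per_region=20,
    slope=0.0,
    region_sd=0.3,
    noise_sd=1.0,
    response="resistance",
):
    """Downturn-level table with a known standardized effect of log-frequency."""
    rows = []
    for r in range(n_regions):
        intercept = rng.normal(0.0, region_sd)
        lf = rng.normal(0.0, 1.0, size=per_region)  # already z-scaled predictor
        y = intercept + slope * lf + rng.normal(0.0, noise_sd, size=per_region)
        for i in range(per_region):
            rows.append(
                {
                    "region": f"R{r}",
                    response: y[i],
                    "log_frequency": lf[i],
                    "frequency": float(np.exp(lf[i])),
                    "pace": float(rng.uniform(0, 1)),
                    "duration": float(rng.uniform(20, 600)),
                    "time_to_min": 0.0,
                    "category": str(rng.choice(["environmental", "cultural", "mixed", "unclear"])),
                    "dist_type": str(rng.choice(["aridity", "mobility", "cooling"])),
                    "land_use": str(rng.choice(["hunter-gatherer", "agriculture"])),
                    "change": bool(rng.uniform() < 0.3),
                }
            )
    df = pd.DataFrame(rows)
    df["time_to_min"] = df["duration"] * df["pace"]
    if response != "resilience":
        df["resilience"] = df[response]
    if response != "resistance":
        df["resistance"] = df[response]
    return df


class TestDescribe:
    def test_symmetric_sample_has_small_skew(self):
        rng = np.random.default_rng(0)
        table = synth_table(rng, n_regions=5, per_region=200)
        table["duration"] = rng.normal(300, 40, size=len(table))
        table["time_to_min"] = rng.normal(100, 10, size=len(table))
        rep = describe(table)
        assert abs(rep.skewness["duration"]) < 0.15
        assert abs(rep.skewness["time_to_min"]) < 0.15

    def test_duration_classes_partition(self):
        rng = np.random.default_rng(1)
        table = synth_table(rng)
        rep = describe(table)
        assert rep.duration_classes["count"].sum() == len(table)
        assert rep.duration_classes["proportion"].sum() == pytest.approx(1.0)

    def test_anova_df_reflects_four_categories(self):
        rng = np.random.default_rng(2)
        table = synth_table(rng, n_regions=6, per_region=10)
        rep = describe(table)
        assert rep.anova["resistance"]["df_between"] == 3

    def test_eta_squared_closed_form(self):
        # two groups tightly clustered at 0 and 1: nearly all variance between
        y = np.concatenate([np.zeros(50), np.ones(50)]) + np.random.default_rng(3).normal(0, 1e-6, 100)
        g = ["a"] * 50 + ["b"] * 50
        assert eta_squared(y, g) == pytest.approx(1.0, abs=1e-6)
        # exact decomposition on a hand fixture
        assert eta_squared([0, 2, 4, 6], ["a", "a", "b", "b"]) == pytest.approx(0.8)

    def test_anova_matches_permutation_oracle(self):
        rng = np.random.default_rng(4)
        table = synth_table(rng, n_regions=5, per_region=40)  # null: category carries nothing
        rep = describe(table)
        F_obs = rep.anova["resistance"]["F"]
        y = table["resistance"].to_numpy()
        g = table["category"].to_numpy()
        sizes = [(g == c).sum() for c in np.unique(g)]
        perm_rng = np.random.default_rng(99)
        perm = []
        for _ in range(400):
            yp = perm_rng.permutation(y)
            chunks = np.split(yp, np.cumsum(sizes)[:-1])
            perm.append(st.f_oneway(*chunks)[0])
        # permutation p-value within sampling error of the parametric one
        p_perm = float(np.mean(np.array(perm) >= F_obs))
        assert abs(p_perm - rep.anova["resistance"]["p"]) < 0.15

    def test_insufficient_rows_rejected(self):
        with pytest.raises(ValueError):
            describe(pd.DataFrame({"duration": [1.0]}))


class TestFitMixed:
    def test_type_one_error_control(self):
        # pure-noise response: slope rarely "significant"
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            table = synth_table(rng, slope=0.0)
            res = fit_mixed(table, "resistance", ["log_frequency"])
            if abs(res.coefficients.loc["log_frequency", "stat"]) < 2:
                hits += 1
        assert hits >= 0.9 * n_seeds

    def test_slope_recovery(self):
        rng = np.random.default_rng(7)
        table = synth_table(rng, n_regions=16, per_region=50, slope=0.4, noise_sd=1.0)
        res = fit_mixed(table, "resistance", ["log_frequency"])
        assert res.converged
        assert res.coef("log_frequency") == pytest.approx(0.4, abs=0.1)
        # standardized coefficient has the same sign and is attenuated by noise scaling
        assert res.standardized.loc["log_frequency", "coef"] > 0

    def test_single_region_matches_ols(self):
        rng = np.random.default_rng(8)
        table = synth_table(rng, n_regions=1, per_region=60, slope=0.5)
        with pytest.warns(UserWarning, match="single region"):
            res = fit_mixed(table, "resistance", ["log_frequency"])
        x = table["log_frequency"].to_numpy()
        y = table["resistance"].to_numpy()
        beta = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert res.coef("log_frequency") == pytest.approx(beta, abs=1e-3)

    def test_missing_response_rows_dropped(self):
        rng = np.random.default_rng(9)
        table = synth_table(rng)
        table.loc[table.index[:5], "resistance"] = np.nan
        res = fit_mixed(table, "resistance", ["log_frequency"])
        assert res.dropped_rows == 5
        assert res.n_obs == len(table) - 5


class TestStepwise:
    def test_predictive_candidate_selected(self):
        chosen = 0
        n_seeds = 15
        for seed in range(n_seeds):
            rng = np.random.default_rng(2000 + seed)
            table = synth_table(rng, n_regions=10, per_region=20, slope=0.6, noise_sd=0.8)
            res = stepwise_ic(table, "resistance", ["log_frequency", "pace", "change"])
            if "log_frequency" in res.fixed:
                chosen += 1
        assert chosen >= 0.9 * n_seeds

    def test_all_noise_mostly_empty(self):
        empty = 0
        n_seeds = 15
        for seed in range(n_seeds):
            rng = np.random.default_rng(3000 + seed)
            table = synth_table(rng, slope=0.0)
            res = stepwise_ic(table, "resistance", ["log_frequency", "pace", "change"])
            if not res.fixed:
                empty += 1
        assert empty > n_seeds / 2

    def test_deterministic(self):
        rng = np.random.default_rng(11)
        table = synth_table(rng, slope=0.4)
        r1 = stepwise_ic(table, "resistance", ["log_frequency", "pace"])
        r2 = stepwise_ic(table, "resistance", ["log_frequency", "pace"])
        assert r1.fixed == r2.fixed
        assert r1.aic == r2.aic


class TestFrequencyModel:
    def make_table(self, rng, ag_multiplier=1.0, n_regions=12, per_region=15):
        rows = []
        for r in range(n_regions):
            land_use = "agriculture" if r % 2 == 0 else "hunter-gatherer"
            base = rng.normal(0.0, 0.2)
            for _ in range(per_region):
                lf = base + np.log(ag_multiplier if land_use == "agriculture" else 1.0) + rng.normal(0, 0.4)
                rows.append(
                    {
                        "region": f"R{r}",
                        "log_frequency": lf,
                        "frequency": float(np.exp(lf)),
                        "land_use": land_use,
                        "change": bool(rng.uniform() < 0.3),
                        "dist_type": str(rng.choice(["aridity", "mobility"])),
                        "pace": float(rng.uniform(0, 1)),
                    }
                )
        return pd.DataFrame(rows)

    def test_constructed_contrast_recovered(self):
        rng = np.random.default_rng(21)
        table = self.make_table(rng, ag_multiplier=2.0)
        res = fit_frequency_model(table)
        term = [t for t in res.coefficients.index if "agriculture" in t][0]
        assert res.coefficients.loc[term, "coef"] > 0
        assert res.coefficients.loc[term, "p"] < 0.05

    def test_permuted_labels_mostly_null(self):
        nulls = 0
        n_seeds = 12
        for seed in range(n_seeds):
            rng = np.random.default_rng(4000 + seed)
            table = self.make_table(rng, ag_multiplier=1.0)
            res = fit_frequency_model(table)
            term = [t for t in res.coefficients.index if "agriculture" in t][0]
            if abs(res.coefficients.loc[term, "stat"]) < 2:
                nulls += 1
        assert nulls >= 0.9 * n_seeds

    def test_rare_level_merged(self):
        rng = np.random.default_rng(23)
        table = self.make_table(rng)
        table.loc[table.index[0], "land_use"] = "marine foraging"  # one row only
        with pytest.warns(UserWarning, match="merged into 'mixed'"):
            res = fit_frequency_model(table)
        assert not any("marine" in t for t in res.coefficients.index)
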