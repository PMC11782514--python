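"""Panel preprocessing, the mixed model, and the classical test layer."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from colonoidquant import stats, synthetic
from colonoidquant.stats import (
    TestResult,
    adjust_fits_bh,
    bh_adjust,
    filter_detection_range,
    fit_lmm,
    log2_elisa,
    paired_t,
    preprocess_panel,
    report_pvalues,
    rm_anova_sidak,
    sidak_adjust,
    significance_tier,
)
from colonoidquant.synthetic import PanelSimConfig


def _panel_from_tokens(tokens, analyte="A"):
    return pd.DataFrame(
        {
            "donor": [f"D{i}" for i in range(len(tokens))],
            "oxygen": "2%",
            "condition": "DMSO",
            "analyte": analyte,
            "token": tokens,
        }
    )


class TestPreprocess:
    def test_oor_low_substitution(self):
        out = preprocess_panel(_panel_from_tokens(["OOR <", "12", "30"]))
        assert sorted(out.value) == [6.0, 12.0, 30.0]
        assert out.loc[out.oor_low, "value"].iloc[0] == 6.0

    def test_asterisk_stripped(self):
        out = preprocess_panel(_panel_from_tokens(["45.2*"]))
        assert out.value.iloc[0] == 45.2

    def test_numeric_tokens_unchanged(self):
        out = preprocess_panel(_panel_from_tokens(["1.5", "2.5"]))
        assert list(out.value) == [1.5, 2.5]
        assert not out.oor_low.any() and not out.oor_high.any()

    def test_oor_high_flagged_without_value(self):
        out = preprocess_panel(_panel_from_tokens(["OOR >", "100"]))
        assert out.oor_high.iloc[0] and pd.isna(out.value.iloc[0])

    def test_all_oor_low_rejected(self):
        with pytest.raises(ValueError, match="out-of-range"):
            preprocess_panel(_panel_from_tokens(["OOR <", "OOR <"]))


class TestDetectionRangeFilter:
    def test_low_analyte_dropped_high_retained(self):
        panel = preprocess_panel(
            pd.concat(
                [
                    _panel_from_tokens(["2", "2", "2"], analyte="LOW"),
                    _panel_from_tokens(["100", "100", "100"], analyte="HIGH"),
                ]
            )
        )
        filtered, retained = filter_detection_range(panel, lower=10.0, upper=10000.0)
        assert retained == ["HIGH"]
        assert set(filtered.analyte) == {"HIGH"}

    def test_synthetic_panel_in_range_count(self):
        frames = []
        for i in range(5):
            frames.append(_panel_from_tokens([f"{50 * (i + 1)}"] * 4, analyte=f"IN{i}"))
        for i in range(3):
            frames.append(_panel_from_tokens(["1.0"] * 4, analyte=f"OUT{i}"))
        _, retained = filter_detection_range(preprocess_panel(pd.concat(frames)))
        assert len(retained) == 5

    def test_oor_high_fraction_drop(self):
        panel = preprocess_panel(
            _panel_from_tokens(["OOR >", "OOR >", "500", "500"], analyte="SAT")
        )
        _, retained = filter_detection_range(panel, max_oor_high_fraction=0.1)
        assert retained == []


class TestLmm:
    def test_noise_free_equals_cell_mean_contrasts(self):
        cfg = PanelSimConfig(
            n_donors=3, condition_effects={"TOFA": 0.5, "BUD": -0.3},
            oxygen_effect=0.2, donor_sd=0.0, residual_sd=0.0, seed=1,
        )
        panel = preprocess_panel(synthetic.simulate_chemokine_panel(cfg))
        fit = fit_lmm(panel)
        assert fit.singular  # zero variance components flagged, not raised
        est = dict(zip(fit.contrasts.term, fit.contrasts.estimate))
        # generator tokens carry 6 significant digits; contrasts must match
        # the planted cell-mean differences to that precision
        assert est["condition[TOFA]"] == pytest.approx(0.5, abs=1e-4)
        assert est["condition[BUD]"] == pytest.approx(-0.3, abs=1e-4)
        assert est["oxygen[20%]"] == pytest.approx(0.2, abs=1e-4)

    def test_matches_lme4_reml(self, tmp_path):
        """REML fixed effects and variance components agree with lme4."""
        cfg = PanelSimConfig(
            n_donors=5, condition_effects={"TOFA": 0.4, "BUD": -0.2},
            oxygen_effect=0.3, donor_sd=0.3, residual_sd=0.25, seed=11,
        )
        panel = preprocess_panel(synthetic.simulate_chemokine_panel(cfg))
        fit = fit_lmm(panel)
        csv = tmp_path / "panel.csv"
        panel.to_csv(csv, index=False)
        out = tmp_path / "lme4.csv"
        script = f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        d$condition <- relevel(factor(d$condition), ref="DMSO")
        d$oxygen <- relevel(factor(d$oxygen), ref="2%")
        m <- lmer(log(value) ~ condition * oxygen + (1|donor), data=d, REML=TRUE)
        fe <- fixef(m)
        vc <- as.data.frame(VarCorr(m))
        write.csv(data.frame(term=names(fe), estimate=unname(fe)), "{out}", row.names=FALSE)
        write.csv(vc, "{tmp_path / 'vc.csv'}", row.names=FALSE)
        """
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = pd.read_csv(out)
        # term naming differs between backends; compare sorted estimates
        mine = np.sort(fit.contrasts.estimate.to_numpy())
        lme4 = np.sort(ref[ref.term != "(Intercept)"].estimate.to_numpy())
        np.testing.assert_allclose(mine, lme4, atol=1e-4)
        vc = pd.read_csv(tmp_path / "vc.csv")
        assert fit.donor_intercept_sd == pytest.approx(vc.sdcor.iloc[0], abs=1e-3)
        assert fit.residual_sd == pytest.approx(vc.sdcor.iloc[1], abs=1e-3)

    def test_effect_recovery_short_run(self):
        ests = []
        for seed in range(25):
            cfg = PanelSimConfig(
                n_donors=6, condition_effects={"TOFA": 0.5}, donor_sd=0.3,
                residual_sd=0.2, seed=seed,
            )
            fit = fit_lmm(preprocess_panel(synthetic.simulate_chemokine_panel(cfg)))
            row = fit.contrasts[fit.contrasts.term == "condition[TOFA]"]
            ests.append(float(row.estimate.iloc[0]))
        assert np.mean(ests) == pytest.approx(0.5, abs=0.05)

    def test_doubled_noise_widens_standard_errors(self):
        ses = {}
        for label, resid_sd in (("low", 0.2), ("high", 0.4)):
            acc = []
            for seed in range(15):
                cfg = PanelSimConfig(n_donors=6, donor_sd=0.3, residual_sd=resid_sd, seed=seed)
                fit = fit_lmm(preprocess_panel(synthetic.simulate_chemokine_panel(cfg)))
                acc.append(fit.contrasts.se.mean())
            ses[label] = np.mean(acc)
        assert ses["high"] > ses["low"]

    def test_nonpositive_values_rejected(self):
        panel = _panel_from_tokens(["1.0", "2.0"]).assign(value=[1.0, -1.0], oor_high=False)
        with pytest.raises(ValueError):
            fit_lmm(panel)

    def test_adjust_fits_pools_bh(self):
        fits = []
        for seed, analyte in [(0, "A"), (1, "B")]:
            cfg = PanelSimConfig(
                n_donors=4, baseline_log_mean={analyte: 4.0}, donor_sd=0.2,
                residual_sd=0.2, seed=seed,
            )
            fits.append(fit_lmm(preprocess_panel(synthetic.simulate_chemokine_panel(cfg))))
        pooled = adjust_fits_bh(fits)
        assert (pooled.p_adj >= pooled.p_raw - 1e-12).all()
        assert "p_adj" in fits[0].contrasts


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        out = bh_adjust([0.01, 0.04, 0.03, 0.002])
        np.testing.assert_allclose(out, [0.02, 0.04, 0.04, 0.008])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_equal_ps_fixed_point(self):
        np.testing.assert_allclose(bh_adjust([0.05, 0.05, 0.05]), [0.05] * 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=60, deadline=None)
    def test_matches_step_up_oracle(self, ps):
        """Step-up oracle computed from the definition."""
        p = np.asarray(ps, dtype=float)
        m = len(p)
        order = np.argsort(p, kind="stable")
        ranked = p[order]
        oracle_sorted = np.minimum.accumulate((ranked * m / np.arange(1, m + 1))[::-1])[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(oracle_sorted, 1.0)
        np.testing.assert_allclose(bh_adjust(p), oracle, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=20), st.randoms())
    @settings(max_examples=30, deadline=None)
    def test_permutation_invariant(self, ps, rnd):
        idx = list(range(len(ps)))
        rnd.shuffle(idx)
        base = bh_adjust(ps)
        shuffled = bh_adjust([ps[i] for i in idx])
        np.testing.assert_allclose(shuffled, base[idx], atol=1e-12)


class TestPairedT:
    def test_hand_computed_example(self):
        res = paired_t(np.array([1.0, 2.0, 3.0]), np.array([2.0, 2.0, 5.0]))
        assert abs(res.statistic) == pytest.approx(np.sqrt(3), abs=1e-9)
        assert res.df == 2
        assert res.p_raw == pytest.approx(0.2254, abs=2e-3)

    def test_swap_negates_t_same_p(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=8), rng.normal(size=8)
        r1, r2 = paired_t(a, b), paired_t(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_raw == pytest.approx(r2.p_raw)

    def test_identical_groups_rejected(self):
        a = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="identical"):
            paired_t(a, a)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="pairs"):
            paired_t(np.array([1.0, 2.0]), np.array([2.0, 1.0]))


def _grid(n_subj=4, k=3, seed=0, effect=None):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subj):
        block = rng.normal(0, 1)
        for c in range(k):
            val = block + rng.normal(0, 0.5) + (effect[c] if effect else 0.0)
            rows.append({"donor": f"S{s}", "condition": f"C{c}", "value": val})
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_constant_grid_f_zero_p_one(self):
        df = _grid()
        df["value"] = 7.0
        anova, _ = rm_anova_sidak(df)
        assert anova.statistic == 0.0 and anova.p_raw == 1.0

    def test_sidak_closed_form(self):
        assert sidak_adjust(0.05, 3) == pytest.approx(0.142625, abs=1e-9)

    def test_matches_sum_of_squares_oracle(self):
        """F equals an independent repeated-measures ANOVA (statsmodels
        AnovaRM) to 1e-10 on a random complete grid."""
        from statsmodels.stats.anova import AnovaRM

        df = _grid(n_subj=5, k=4, seed=3, effect=[0.0, 0.3, -0.2, 0.5])
        anova, _ = rm_anova_sidak(df)
        ref = AnovaRM(df, depvar="value", subject="donor", within=["condition"]).fit()
        f_ref = float(ref.anova_table["F Value"].iloc[0])
        p_ref = float(ref.anova_table["Pr > F"].iloc[0])
        assert anova.statistic == pytest.approx(f_ref, abs=1e-10)
        assert anova.p_raw == pytest.approx(p_ref, abs=1e-10)

    def test_posthoc_sidak_adjustment(self):
        df = _grid(n_subj=5, k=3, seed=4, effect=[0.0, 1.0, 0.0])
        _, posthoc = rm_anova_sidak(df, contrasts=[("C0", "C1"), ("C0", "C2"), ("C1", "C2")])
        for res in posthoc:
            assert res.p_adjusted == pytest.approx(sidak_adjust(res.p_raw, 3))
            assert res.p_adjusted >= res.p_raw

    def test_incomplete_grid_lists_missing(self):
        df = _grid().query("~(donor == 'S0' and condition == 'C2')")
        with pytest.raises(ValueError, match="missing"):
            rm_anova_sidak(df)


class TestElisaAndReporting:
    def test_log2_values(self):
        np.testing.assert_allclose(log2_elisa([8.0, 1.0]), [3.0, 0.0])

    def test_log2_round_trip(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(-5, 5, size=20)
        np.testing.assert_allclose(log2_elisa(2.0**x), x, atol=1e-12)

    def test_log2_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            log2_elisa([1.0, 0.0])

    @pytest.mark.parametrize(
        "p, included, tier",
        [(0.19, True, ""), (0.25, False, None), (0.0005, True, "***"),
         (0.03, True, "*"), (5e-5, True, "****")],
    )
    def test_report_threshold_and_tiers(self, p, included, tier):
        res = TestResult(comparison="x", statistic=1.0, df=5, p_raw=p)
        report = report_pvalues([res])
        assert (len(report) == 1) is included
        if included:
            assert report.tier.iloc[0] == tier

    def test_adjusted_p_preferred(self):
        res = TestResult(comparison="x", statistic=1.0, df=5, p_raw=0.01, p_adjusted=0.5)
        assert report_pvalues([res]).empty

    def test_tier_boundaries(self):
        assert significance_tier(0.04) == "*"
        assert significance_tier(0.05) == ""
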