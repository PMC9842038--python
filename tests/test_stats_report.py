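import numpy as np
import pytest
from scipy import stats

from calciscope import (
    ValidationError,
    dunnett_montecarlo,
    one_way_anova,
    run_study,
    two_way_anova,
    welch_t,
)


class TestWelchT:
    def test_identical_samples(self):
        res = welch_t([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_antisymmetry(self, rng):
        a, b = rng.random(8), rng.random(9) + 0.3
        r1, r2 = welch_t(a, b), welch_t(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_formula_by_hand(self):
        """{1,2,3,4} vs {2,3,4,5}: both variances 5/3, so
        t = -1/sqrt(5/6) and Welch-Satterthwaite df = 6 exactly."""
        res = welch_t([1, 2, 3, 4], [2, 3, 4, 5])
        t_expect = -1.0 / np.sqrt(5.0 / 6.0)
        p_expect = 2 * stats.t.sf(abs(t_expect), 6.0)
        assert res.statistic == pytest.approx(t_expect, abs=1e-12)
        assert res.p_value == pytest.approx(p_expect, abs=1e-12)

    def test_small_sample_rejected(self):
        with pytest.raises(ValidationError):
            welch_t([1.0], [1, 2, 3])


class TestOneWayAnova:
    def test_identical_groups_null(self):
        g = {"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]}
        res = one_way_anova(g, posthoc="dunnett", control="a")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert all(p == pytest.approx(1.0) for _, p in res.posthoc)

    def test_f_equals_t_squared_for_two_groups(self, rng):
        a, b = rng.random(7), rng.random(7) + 0.2
        res = one_way_anova({"a": a, "b": b})
        t = stats.ttest_ind(a, b, equal_var=True)
        assert res.statistic == pytest.approx(t.statistic**2)
        assert res.p_value == pytest.approx(t.pvalue)

    def test_dunnett_matches_montecarlo_reference(self, rng):
        """Adjusted p's agree with an independent 1e6-draw simulation of
        the max-|t| null for balanced many-to-one contrasts."""
        n = 8
        groups = {
            "ctrl": rng.normal(0, 1, n),
            "t1": rng.normal(0.8, 1, n),
            "t2": rng.normal(0.2, 1, n),
        }
        res = one_way_anova(groups, posthoc="dunnett", control="ctrl")
        # observed statistics recomputed from the data
        s2 = np.mean([np.var(v, ddof=1) for v in groups.values()])
        t_obs = [
            (groups[lab].mean() - groups["ctrl"].mean()) / np.sqrt(2 * s2 / n)
            for lab in ("t1", "t2")
        ]
        p_mc = dunnett_montecarlo(t_obs, n_groups=3, n_per_group=n, n_draws=1_000_000, seed=7)
        for (pair, p_impl), p_ref in zip(res.posthoc, p_mc):
            assert p_impl == pytest.approx(p_ref, abs=0.005)

    def test_adjusted_p_at_least_unadjusted(self, rng):
        n = 6
        groups = {lab: rng.normal(m, 1, n) for lab, m in [("c", 0), ("x", 1.0), ("y", 0.5)]}
        res = one_way_anova(groups, posthoc="dunnett", control="c")
        for (lab, ctrl), p_adj in res.posthoc:
            p_raw = stats.ttest_ind(groups[lab], groups[ctrl], equal_var=True).pvalue
            assert p_adj >= p_raw - 1e-9

    def test_tukey_pairs_cover_all(self, rng):
        groups = {lab: rng.random(5) for lab in "abc"}
        res = one_way_anova(groups, posthoc="tukey")
        assert len(res.posthoc) == 3

    def test_missing_control_rejected(self, rng):
        with pytest.raises(ValidationError):
            one_way_anova({"a": rng.random(4), "b": rng.random(4)}, posthoc="dunnett")


class TestTwoWayAnova:
    @staticmethod
    def hand_decomposition(values, fa, fb):
        """Balanced two-factor sums of squares from grand/marginal/cell means."""
        import itertools

        values = np.asarray(values, float)
        fa, fb = np.asarray(fa), np.asarray(fb)
        la, lb = sorted(set(fa)), sorted(set(fb))
        n = len(values) // (len(la) * len(lb))
        grand = values.mean()
        ss_a = sum(
            (values[fa == a].mean() - grand) ** 2 * (fa == a).sum() for a in la
        )
        ss_b = sum(
            (values[fb == b].mean() - grand) ** 2 * (fb == b).sum() for b in lb
        )
        ss_cells = sum(
            ((values[(fa == a) & (fb == b)].mean() - grand) ** 2) * n
            for a, b in itertools.product(la, lb)
        )
        ss_ab = ss_cells - ss_a - ss_b
        ss_err = sum(
            ((values[(fa == a) & (fb == b)] - values[(fa == a) & (fb == b)].mean()) ** 2).sum()
            for a, b in itertools.product(la, lb)
        )
        return ss_a, ss_b, ss_ab, ss_err

    def make_fixture(self, rng, interaction=0.0):
        eff_a = {"f": 0.0, "m": 1.0}
        eff_b = {"om": 0.0, "cm": 2.0}
        vals, fa, fb = [], [], []
        for a in eff_a:
            for b in eff_b:
                for _ in range(4):
                    bump = interaction if (a == "m" and b == "cm") else 0.0
                    vals.append(eff_a[a] + eff_b[b] + bump + rng.normal(0, 0.3))
                    fa.append(a)
                    fb.append(b)
        return np.array(vals), fa, fb

    def test_additive_noiseless_interaction_zero(self):
        vals, fa, fb = [], [], []
        for a, ea in [("f", 0.0), ("m", 1.0)]:
            for b, eb in [("om", 0.0), ("cm", 2.0)]:
                for r in range(3):
                    vals.append(ea + eb + 0.01 * r)  # same within-cell pattern
                    fa.append(a)
                    fb.append(b)
        res = two_way_anova(vals, fa, fb)
        assert res.effects["interaction"][0] == pytest.approx(0.0, abs=1e-18)

    def test_relabeling_invariance(self, rng):
        vals, fa, fb = self.make_fixture(rng, interaction=1.0)
        res1 = two_way_anova(vals, fa, fb)
        swap = {"f": "group1", "m": "group2"}
        res2 = two_way_anova(vals, [swap[a] for a in fa], fb)
        for key in res1.effects:
            assert res1.effects[key][1] == pytest.approx(res2.effects[key][1])

    def test_sums_of_squares_match_hand_decomposition(self, rng):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols
        import pandas as pd

        vals, fa, fb = self.make_fixture(rng, interaction=1.5)
        ss_a, ss_b, ss_ab, ss_err = self.hand_decomposition(vals, fa, fb)
        df = pd.DataFrame({"value": vals, "fa": fa, "fb": fb})
        table = sm.stats.anova_lm(
            ols("value ~ C(fa) + C(fb) + C(fa):C(fb)", data=df).fit(), typ=2
        )
        assert table.loc["C(fa)", "sum_sq"] == pytest.approx(ss_a)
        assert table.loc["C(fb)", "sum_sq"] == pytest.approx(ss_b)
        assert table.loc["C(fa):C(fb)", "sum_sq"] == pytest.approx(ss_ab)
        assert table.loc["Residual", "sum_sq"] == pytest.approx(ss_err)
        # and the module reports the same interaction F
        res = two_way_anova(vals, fa, fb)
        df_err = len(vals) - 4
        f_ab = (ss_ab / 1) / (ss_err / df_err)
        assert res.effects["interaction"][0] == pytest.approx(f_ab)

    def test_unbalanced_rejected(self, rng):
        vals, fa, fb = self.make_fixture(rng)
        with pytest.raises(ValidationError, match="nbalanced"):
            two_way_anova(np.append(vals, 1.0), fa + ["f"], fb + ["om"])


class TestRunStudy:
    CONFIG = {
        "seed": 1,
        "calibration": 2.73,
        "stages": ["vk", "corrlength"],
        "threshold": "auto",
        "max_lag": 64,
        "groups": [
            {"label": "female_CM", "preset": "female_CM", "n_images": 3,
             "overrides": {"height_px": 256, "width_px": 256}},
            {"label": "male_CM", "preset": "male_CM", "n_images": 3,
             "overrides": {"height_px": 256, "width_px": 256}},
        ],
        "comparisons": [
            {"metric": "correlation_length_um", "test": "welch",
             "groups": ["male_CM", "female_CM"]},
        ],
    }

    def test_bookkeeping_contract(self):
        report = run_study(self.CONFIG)
        assert len(report.per_image_table) == 6
        assert set(report.per_image_table["condition"]) == {"female_CM", "male_CM"}
        assert report.per_image_table["source_id"].is_unique
        assert len(report.comparisons) == 1
        assert 0 <= report.comparisons[0].p_value <= 1

    def test_rerun_is_byte_identical(self, tmp_path):
        cfg1 = dict(self.CONFIG, outdir=str(tmp_path / "r1"))
        cfg2 = dict(self.CONFIG, outdir=str(tmp_path / "r2"))
        run_study(cfg1)
        run_study(cfg2)
        for name in ("per_image.csv", "comparisons.csv", "report.json", "run.log"):
            assert (tmp_path / "r1" / name).read_bytes() == (tmp_path / "r2" / name).read_bytes()

    def test_yaml_config_roundtrip(self, tmp_path):
        import yaml

        p = tmp_path / "study.yaml"
        p.write_text(yaml.safe_dump(self.CONFIG))
        report = run_study(p)
        assert len(report.per_image_table) == 6


class TestTypeICalibration:
    def test_welch_rejection_rate_under_null(self):
        """Under a global null the Welch test rejects at ~alpha."""
        rng = np.random.default_rng(2024)
        a = rng.normal(size=(2000, 10))
        b = rng.normal(size=(2000, 10))
        p = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
        # sanity: the same data through the module API on a few rows
        for i in range(3):
            assert welch_t(a[i], b[i]).p_value == pytest.approx(p[i])
        rate = (p < 0.05).mean()
        assert 0.03 <= rate <= 0.07
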