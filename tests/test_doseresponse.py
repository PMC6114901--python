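"""Normalization, Hill fitting, benchmark dose, mortality modelling and
potency metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from goitroscan import doseresponse as dr
from goitroscan import synth


def embryo_table(rows):
    return pd.DataFrame(
        rows, columns=["compound", "concentration_uM", "replicate", "pixel_sum"]
    )


def curve_points(hill, concs, compound="x", replicate=1):
    return pd.DataFrame(
        {
            "compound": compound,
            "replicate": replicate,
            "concentration_uM": concs,
            "fold_induction": hill(np.asarray(concs, dtype=float)),
            "n_embryos": 24,
            "low_n": False,
        }
    )


CONCS = [0.0, 10.0, 30.0, 100.0, 300.0, 1000.0]


class TestNormalize:
    def test_equal_sums_give_unit_fold(self):
        table = embryo_table(
            [["x", c, 1, 500.0] for c in CONCS for _ in range(3)]
        )
        norm = dr.normalize_to_control(table)
        assert (norm["fold_induction"] == 1.0).all()

    def test_simple_arithmetic(self):
        table = embryo_table(
            [["x", 0.0, 1, 900.0], ["x", 0.0, 1, 1100.0], ["x", 10.0, 1, 2100.0]]
        )
        norm = dr.normalize_to_control(table)
        fold = norm.loc[norm["concentration_uM"] == 10.0, "fold_induction"].iloc[0]
        assert fold == pytest.approx(2.1)

    def test_control_fold_exactly_one_per_replicate(self):
        rng = np.random.default_rng(0)
        rows = [
            ["x", c, rep, float(rng.uniform(100, 1000))]
            for rep in (1, 2)
            for c in CONCS
            for _ in range(5)
        ]
        norm = dr.normalize_to_control(embryo_table(rows))
        ctrl = norm[norm["concentration_uM"] == 0.0]
        assert (ctrl["fold_induction"] == 1.0).all()  # exact, not approximate

    def test_flagged_embryos_excluded(self):
        table = embryo_table([["x", 0.0, 1, 100.0], ["x", 10.0, 1, 200.0]])
        table["flagged"] = [False, False]
        extra = embryo_table([["x", 10.0, 1, 1e9]])
        extra["flagged"] = True
        norm = dr.normalize_to_control(pd.concat([table, extra]))
        fold = norm.loc[norm["concentration_uM"] == 10.0, "fold_induction"].iloc[0]
        assert fold == pytest.approx(2.0)

    def test_generator_roundtrip_noise_free(self):
        hill = dr.HillParameters(Min=1, Max=2, EC50=100, slope=2)
        spec = synth.ResponseSimSpec(
            concentrations=tuple(CONCS), n_embryos_per_conc=6, hill=hill,
            embryo_cv=0.0, seed=0,
        )
        norm = dr.normalize_to_control(synth.generate_response_dataset(spec))
        for _, row in norm.iterrows():
            assert row["fold_induction"] == pytest.approx(
                hill(row["concentration_uM"]), rel=1e-12
            )

    def test_missing_control_rejected(self):
        with pytest.raises(ValueError, match="no control"):
            dr.normalize_to_control(embryo_table([["x", 10.0, 1, 100.0]] * 4))

    def test_zero_control_mean_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            dr.normalize_to_control(
                embryo_table([["x", 0.0, 1, 0.0], ["x", 10.0, 1, 5.0]])
            )

    def test_low_n_flag(self):
        rows = [["x", 0.0, 1, 100.0]] * 12 + [["x", 10.0, 1, 150.0]] * 9
        norm = dr.normalize_to_control(embryo_table(rows))
        assert not norm.loc[norm["concentration_uM"] == 0.0, "low_n"].iloc[0]
        assert norm.loc[norm["concentration_uM"] == 10.0, "low_n"].iloc[0]


class TestFitHill:
    def test_noise_free_recovery_to_six_digits(self):
        gen = dr.HillParameters(Min=1, Max=2, EC50=100, slope=2)
        pts = pd.concat(
            [curve_points(gen, CONCS, replicate=r) for r in (1, 2)]
        )
        fit = dr.fit_hill(pts)
        assert fit.Max == pytest.approx(2.0, rel=1e-6)
        assert fit.EC50 == pytest.approx(100.0, rel=1e-6)
        assert fit.slope == pytest.approx(2.0, rel=1e-6)

    def test_flat_response_reports_no_induction(self):
        flat = dr.HillParameters(Min=1, Max=1, EC50=100, slope=2)
        fit = dr.fit_hill(curve_points(flat, CONCS))
        assert fit.no_induction
        assert np.isnan(fit.EC50)

    def test_repression_reports_no_induction(self):
        down = dr.HillParameters(Min=1, Max=0.7, EC50=100, slope=2)
        fit = dr.fit_hill(curve_points(down, CONCS))
        assert fit.no_induction

    def test_too_few_concentrations_rejected(self):
        gen = dr.HillParameters(Min=1, Max=2, EC50=100, slope=2)
        with pytest.raises(ValueError, match=">= 4"):
            dr.fit_hill(curve_points(gen, [0.0, 10.0, 100.0, 1000.0]))

    def test_mc_recovery_within_three_ses(self):
        gen = dr.HillParameters(Min=1, Max=2.1, EC50=279, slope=3.3)
        concs = (0.0, *np.geomspace(279 / 6, 279 * 6, 5))
        rng = np.random.default_rng(4)
        est = []
        for _ in range(200):
            dataset = synth.generate_response_dataset(
                synth.ResponseSimSpec(
                    concentrations=concs, n_embryos_per_conc=24, hill=gen,
                    embryo_cv=0.1, seed=int(rng.integers(2**31)),
                )
            )
            fit = dr.fit_hill(dr.normalize_to_control(dataset))
            est.append(fit.EC50)
        est = np.asarray(est)
        mc_se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - 279.0) <= 3 * mc_se


class TestExcludeDecliningTop:
    def _norm(self, folds, concs=(10.0, 30.0, 100.0, 300.0)):
        return pd.DataFrame(
            {
                "compound": "x",
                "replicate": 1,
                "concentration_uM": concs,
                "fold_induction": folds,
                "n_embryos": 24,
                "low_n": False,
            }
        )

    def test_monotone_response_unchanged(self):
        norm = self._norm([1.1, 1.5, 1.9, 2.1])
        out, excluded = dr.exclude_declining_top(norm)
        assert len(out) == 4 and excluded == {}

    def test_collapsing_top_removed(self):
        norm = self._norm([1.3, 1.8, 2.1, 1.2])
        out, excluded = dr.exclude_declining_top(norm)
        assert excluded == {"x": 300.0}
        assert 300.0 not in out["concentration_uM"].values

    def test_small_dip_within_margin_kept(self):
        norm = self._norm([1.3, 1.8, 2.1, 2.1 * 0.97])
        out, excluded = dr.exclude_declining_top(norm)
        assert len(out) == 4 and excluded == {}

    def test_at_most_one_removed(self):
        norm = self._norm([2.4, 2.1, 1.5, 1.1], concs=(10.0, 30.0, 100.0, 300.0))
        out, excluded = dr.exclude_declining_top(norm)
        assert len(out) == 3  # only the top concentration goes


class TestComputeBmd:
    def test_half_max_target_returns_ec50_exactly(self):
        for max_, p, ec50 in [(2.1, 3.3, 279.0), (1.5, 0.7, 12.0), (3.0, 6.0, 5e3)]:
            params = dr.HillParameters(Min=1, Max=max_, EC50=ec50, slope=p)
            assert dr.compute_bmd(params, (1 + max_) / 2) == ec50

    def test_closed_form_matches_root_finding(self):
        # independent oracle: solve hill(x) = target numerically
        rng = np.random.default_rng(8)
        for _ in range(200):
            max_ = rng.uniform(1.3, 3.0)
            p = rng.uniform(0.5, 6.0)
            ec50 = 10 ** rng.uniform(0, 4)
            params = dr.HillParameters(Min=1, Max=max_, EC50=ec50, slope=p)
            bmd = dr.compute_bmd(params, 1.2)
            oracle = brentq(
                lambda x: params(x) - 1.2, ec50 * 1e-8, ec50 * 1e8,
                xtol=1e-300, rtol=1e-14,
            )
            assert abs(bmd - oracle) / oracle < 1e-9

    def test_reference_value_from_oracle(self):
        # frozen from the root-finding oracle for Min=1, Max=2.1,
        # EC50=279, p=3.3, target 1.2
        params = dr.HillParameters(Min=1, Max=2.1, EC50=279, slope=3.3)
        assert dr.compute_bmd(params, 1.2) == pytest.approx(176.8728, rel=1e-6)

    def test_target_outside_asymptotes_rejected(self):
        params = dr.HillParameters(Min=1, Max=1.15, EC50=100, slope=2)
        with pytest.raises(ValueError, match="asymptote"):
            dr.compute_bmd(params, 1.2)
        with pytest.raises(ValueError):
            dr.compute_bmd(params, 0.9)

    @given(
        st.floats(1.3, 3.0),
        st.floats(0.5, 6.0),
        st.floats(0.0, 4.0),
        st.floats(0.05, 0.95),
        st.floats(0.05, 0.95),
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_bmd_strictly_increasing_in_target(self, max_, p, log_ec50, q1, q2):
        if abs(q1 - q2) < 1e-3:
            return
        params = dr.HillParameters(Min=1, Max=max_, EC50=10**log_ec50, slope=p)
        t1 = 1 + (max_ - 1) * min(q1, q2)
        t2 = 1 + (max_ - 1) * max(q1, q2)
        assert dr.compute_bmd(params, t1) < dr.compute_bmd(params, t2)


class TestFitMortality:
    def _table(self, concs, dead, n=20):
        return pd.DataFrame(
            {
                "compound": "x",
                "concentration_uM": concs,
                "n_exposed": n,
                "n_dead": dead,
            }
        )

    def test_midpoint_of_clean_sigmoid(self):
        t = self._table([10, 32, 100, 316, 1000], [0, 0, 10, 20, 20])
        fit = dr.fit_mortality(t)
        assert fit.lc50 == pytest.approx(100.0, rel=1e-3)

    def test_no_deaths_is_censored(self):
        t = self._table([10, 32, 100, 316, 1000], [0, 0, 0, 0, 0])
        fit = dr.fit_mortality(t)
        assert fit.censored and fit.lc50 == 1000.0

    def test_all_or_nothing_interval_estimate(self):
        t = self._table([10, 32, 100, 316, 1000], [0, 0, 0, 20, 20])
        fit = dr.fit_mortality(t)
        assert fit.method == "interval"
        assert fit.lc50 == pytest.approx(np.sqrt(100 * 316), rel=1e-9)

    def test_mc_recovery_within_20pct(self):
        rng = np.random.default_rng(9)
        concs = np.geomspace(100 / 4, 100 * 4, 6)
        hits = 0
        for _ in range(200):
            t = synth.generate_mortality_dataset(
                100.0, 3.0, concs, 25, seed=int(rng.integers(2**31))
            )
            fit = dr.fit_mortality(t)
            hits += np.isfinite(fit.lc50) and abs(fit.lc50 - 100) / 100 <= 0.2
        assert hits >= 180

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            dr.fit_mortality(self._table([10, 100, 1000], [25, 0, 0], n=20))


class TestPotencyMetrics:
    def test_tdi_identity(self):
        assert dr.compute_tdi(100.0, 100.0) == 1.0

    @pytest.mark.parametrize(
        "lc50, ec50, displayed",
        [(5197, 3.4, 1529), (28800, 279, 103), (78922, 366, 216), (42428, 637, 67)],
    )
    def test_tdi_display_rounding(self, lc50, ec50, displayed):
        assert dr.round_half_up(dr.compute_tdi(lc50, ec50)) == displayed

    def test_tdi_undefined_without_ec50(self):
        assert np.isnan(dr.compute_tdi(100.0, float("nan")))

    def test_tdi_scale_invariant(self):
        assert dr.compute_tdi(5197, 3.4) == dr.compute_tdi(5197 * 7.3, 3.4 * 7.3)

    def test_baseline_constant_model(self):
        assert dr.baseline_toxicity(5.0, (0.0, np.log10(1000))) == pytest.approx(1000)

    def test_baseline_tenfold_per_logd_unit(self):
        q = (-1.0, 5.0)
        assert dr.baseline_toxicity(1.0, q) == pytest.approx(
            dr.baseline_toxicity(0.0, q) / 10.0
        )

    def test_baseline_calibration_anchor(self):
        # calibration check: coefficients chosen so log D 0.24 -> 60590 uM
        slope = -0.9246972962839432
        intercept = np.log10(60590.0) - slope * 0.24
        assert dr.baseline_toxicity(0.24, (slope, intercept)) == pytest.approx(60590.0)

    def test_toxic_ratio_annotations(self):
        ratio, baseline_like = dr.toxic_ratio(100.0, 100.0)
        assert ratio == 1.0 and baseline_like
        ratio, baseline_like = dr.toxic_ratio(1400.0, 100.0)
        assert ratio == pytest.approx(14.0) and not baseline_like
        # boundary: exactly 10 is NOT baseline-like (strict < rule)
        ratio, baseline_like = dr.toxic_ratio(1000.0, 100.0)
        assert ratio == pytest.approx(10.0) and not baseline_like

    def test_toxic_ratio_scale_invariant(self):
        r1, _ = dr.toxic_ratio(1400.0, 100.0)
        r2, _ = dr.toxic_ratio(1400.0 * 3.7, 100.0 * 3.7)
        assert r1 == pytest.approx(r2)


class TestRanking:
    EC50S = {
        "resorcinol": 3.4,
        "KClO4": 137.0,
        "methimazole": 279.0,
        "PTU": 334.0,
        "ETU": 366.0,
        "pyrazole": 637.0,
        "phloroglucinol": 1096.0,
    }
    TDIS = {
        "resorcinol": 1529.0,
        "phloroglucinol": 443.0,
        "KClO4": 241.0,
        "ETU": 216.0,
        "methimazole": 103.0,
        "pyrazole": 67.0,
        "PTU": 11.0,
    }

    def test_ec50_ranking_order(self):
        reports = [
            dr.PotencyReport(compound=k, ec50=v) for k, v in self.EC50S.items()
        ]
        ranked = dr.rank_compounds(reports, key="EC50")
        assert [r.compound for r in ranked] == [
            "resorcinol", "KClO4", "methimazole", "PTU", "ETU",
            "pyrazole", "phloroglucinol",
        ]

    def test_tdi_ranking_order(self):
        reports = [dr.PotencyReport(compound=k, tdi=v) for k, v in self.TDIS.items()]
        ranked = dr.rank_compounds(reports, key="TDI")
        assert ranked[0].compound == "resorcinol"
        assert ranked[-1].compound == "PTU"

    def test_undefined_keys_sort_last(self):
        reports = [
            dr.PotencyReport(compound="a", ec50=float("nan")),
            dr.PotencyReport(compound="b", ec50=5.0),
        ]
        ranked = dr.rank_compounds(reports, key="EC50")
        assert [r.compound for r in ranked] == ["b", "a"]

    def test_singleton(self):
        reports = [dr.PotencyReport(compound="only", ec50=1.0)]
        assert dr.rank_compounds(reports) == reports
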