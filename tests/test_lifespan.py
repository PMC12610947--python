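"""Kaplan-Meier summaries, log-rank testing, and two-stage hit calling."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from agerank.errors import ValidationError
from agerank.lifespan import (
    GroupSummary,
    adjust_and_call,
    bonferroni_within_batch,
    compare_to_control,
    kaplan_meier,
    km_curve,
    lifespan_summaries,
    logrank_test,
    maximum_lifespan,
    percent_extension,
    restricted_mean,
    round_half_away,
)

from conftest import make_lifespan


def hand_logrank(days_a, events_a, days_b, events_b):
    """Independent oracle: explicit hypergeometric O-E table computation."""
    recs = [(d, e, 0) for d, e in zip(days_a, events_a)] + [
        (d, e, 1) for d, e in zip(days_b, events_b)
    ]
    event_times = sorted({d for d, e, _ in recs if e == 1})
    O = E = V = 0.0
    for t in event_times:
        at_risk = [(d, e, g) for d, e, g in recs if d >= t]
        n = len(at_risk)
        n_a = sum(1 for d, e, g in at_risk if g == 0)
        d_t = sum(1 for d, e, g in at_risk if e == 1 and d == t)
        d_a = sum(1 for d, e, g in at_risk if e == 1 and d == t and g == 0)
        O += d_a
        E += d_t * n_a / n
        if n > 1:
            V += d_t * (n_a / n) * (1 - n_a / n) * (n - d_t) / (n - 1)
    chi2 = (O - E) ** 2 / V
    return chi2, float(sps.chi2.sf(chi2, 1))


class TestKaplanMeier:
    def test_uncensored_steps(self):
        kmf = kaplan_meier(make_lifespan([10, 20, 30]))
        sf = kmf.survival_function_.iloc[:, 0]
        np.testing.assert_allclose(sf.loc[[10.0, 20.0, 30.0]], [2 / 3, 1 / 3, 0.0])

    def test_censored_before_death(self):
        """Censoring at day 5 leaves one animal at risk at the day-10 death."""
        kmf = kaplan_meier(make_lifespan([5, 10], [0, 1]))
        assert kmf.survival_function_.iloc[:, 0].loc[10.0] == pytest.approx(0.0)

    def test_curve_monotone_in_unit_interval(self, rng):
        tbl = make_lifespan(rng.gamma(5, 4, 80), rng.integers(0, 2, 80))
        tbl.loc[0, "event"] = 1
        curve = km_curve(tbl)
        s = curve["survival"].to_numpy()
        assert np.all(np.diff(s) <= 1e-12)
        assert np.all((0 <= s) & (s <= 1))

    def test_all_censored_rejected(self):
        with pytest.raises(ValidationError):
            kaplan_meier(make_lifespan([3, 4], [0, 0]))


class TestSummaries:
    def test_no_censoring_reduces_to_sample_statistics(self):
        s = lifespan_summaries(make_lifespan([10, 20, 30]))
        assert s.mean == pytest.approx(20.0)
        assert s.median == pytest.approx(20.0)
        assert s.n_subjects == 3

    def test_median_is_first_day_survival_half_or_less(self):
        # S = 3/4, 2/4, 1/4, 0 -> first day with S <= 0.5 is day 2
        s = lifespan_summaries(make_lifespan([1, 2, 3, 4]))
        assert s.median == pytest.approx(2.0)

    def test_decile_maximum_single_animal(self):
        s = lifespan_summaries(make_lifespan(np.arange(1, 11)))
        assert s.maximum == pytest.approx(10.0)

    def test_decile_maximum_two_animals(self):
        days = np.arange(1, 21)  # top decile = top 2 deaths
        assert maximum_lifespan(days) == pytest.approx(19.5)

    def test_alternative_maximum_conventions(self):
        days = np.arange(1, 21)
        assert maximum_lifespan(days, "longest") == 20.0
        assert maximum_lifespan(days, "p90") == pytest.approx(np.percentile(days, 90))
        with pytest.raises(ValidationError):
            maximum_lifespan(days, "nope")

    def test_no_censoring_se_identity(self, rng):
        """Greenwood RMST variance equals the biased sample variance over n."""
        days = rng.normal(22, 3, 50)
        _, var = restricted_mean(make_lifespan(days))
        assert np.sqrt(var) == pytest.approx(days.std(ddof=0) / np.sqrt(50), rel=1e-9)

    def test_restricted_mean_against_integration_oracle(self, rng):
        """Brute-force numerical integral of the KM step function."""
        days = rng.gamma(8, 3, 60)
        events = (rng.uniform(size=60) > 0.25).astype(int)
        events[:5] = 1
        tbl = make_lifespan(days, events)
        rmst, _ = restricted_mean(tbl)
        kmf = kaplan_meier(tbl)
        tau = float(tbl["day"].max())
        grid = np.linspace(0, tau, 400_001)
        surv = kmf.survival_function_at_times(grid).to_numpy()
        brute = np.trapezoid(surv, grid)
        assert rmst == pytest.approx(brute, abs=5e-3)

    def test_restricted_mean_matches_lifelines_point_estimate(self, rng):
        from lifelines.utils import restricted_mean_survival_time

        days = rng.gamma(8, 3, 40)
        events = (rng.uniform(size=40) > 0.3).astype(int)
        events[0] = 1
        tbl = make_lifespan(days, events)
        kmf = kaplan_meier(tbl)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = restricted_mean_survival_time(kmf, t=float(tbl["day"].max()))
        assert restricted_mean(tbl)[0] == pytest.approx(float(ref), rel=1e-9)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        a = make_lifespan([5, 9, 13, 20])
        chi2, p = logrank_test(a, a.copy())
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_three_vs_three_hand_fixture(self):
        """Hand hypergeometric computation: chi2 = (3 - 1.15)^2 / 0.6775."""
        a, b = make_lifespan([1, 2, 3]), make_lifespan([4, 5, 6], group="B")
        chi2, p = logrank_test(a, b)
        assert chi2 == pytest.approx(1.85**2 / 0.6775, rel=1e-12)
        ref_chi2, ref_p = hand_logrank([1, 2, 3], [1, 1, 1], [4, 5, 6], [1, 1, 1])
        assert chi2 == pytest.approx(ref_chi2, rel=1e-12)
        assert p == pytest.approx(ref_p, rel=1e-12)

    def test_matches_hand_oracle_with_censoring_and_ties(self, rng):
        days_a = [2, 2, 5, 7, 7, 11]
        events_a = [1, 0, 1, 1, 1, 0]
        days_b = [3, 5, 5, 9, 12, 12]
        events_b = [1, 1, 0, 1, 1, 1]
        chi2, p = logrank_test(
            make_lifespan(days_a, events_a), make_lifespan(days_b, events_b, group="B")
        )
        ref_chi2, ref_p = hand_logrank(days_a, events_a, days_b, events_b)
        assert chi2 == pytest.approx(ref_chi2, rel=1e-9)
        assert p == pytest.approx(ref_p, rel=1e-9)

    def test_symmetric_and_scale_invariant(self):
        a = make_lifespan([2, 4, 9, 15], [1, 1, 0, 1])
        b = make_lifespan([5, 8, 12, 20], [1, 1, 1, 1], group="B")
        chi2_ab, p_ab = logrank_test(a, b)
        chi2_ba, p_ba = logrank_test(b, a)
        assert chi2_ab == pytest.approx(chi2_ba)
        a2, b2 = a.copy(), b.copy()
        a2["day"] *= 24.0
        b2["day"] *= 24.0
        chi2_scaled, _ = logrank_test(a2, b2)
        assert chi2_scaled == pytest.approx(chi2_ab)

    def test_consistent_with_permutation_oracle(self):
        """Asymptotic p orders small fixtures the same way as the exact
        permutation distribution of the statistic."""
        fixtures = [
            ([1, 2, 3], [4, 5, 6]),
            ([1, 4, 5], [2, 3, 6]),
            ([1, 3, 5], [2, 4, 6]),
        ]
        asym_ps, perm_ps = [], []
        for da, db in fixtures:
            chi2_obs, p = logrank_test(
                make_lifespan(da), make_lifespan(db, group="B")
            )
            pooled = da + db
            stats = []
            for idx_a in itertools.combinations(range(6), 3):
                ga = [pooled[i] for i in idx_a]
                gb = [pooled[i] for i in range(6) if i not in idx_a]
                stats.append(logrank_test(make_lifespan(ga), make_lifespan(gb, group="B"))[0])
            perm_p = np.mean([s >= chi2_obs - 1e-12 for s in stats])
            asym_ps.append(p)
            perm_ps.append(perm_p)
        assert np.argsort(asym_ps).tolist() == np.argsort(perm_ps).tolist()

    def test_group_without_event_rejected(self):
        with pytest.raises(ValidationError):
            logrank_test(make_lifespan([1, 2], [0, 0]), make_lifespan([1, 2]))


class TestExtensionAndHits:
    def _summary(self, group, mean, median=22.0, maximum=27.0):
        return GroupSummary(group, 100, mean, 0.4, median, maximum)

    def test_equal_means_zero_percent(self):
        ext = percent_extension(self._summary("t", 20.0), self._summary("c", 20.0))
        assert ext["mean"] == 0.0

    def test_fifteen_percent(self):
        ext = percent_extension(self._summary("t", 23.0), self._summary("c", 20.0))
        assert ext["mean"] == pytest.approx(15.0)

    def test_zero_control_rejected(self):
        with pytest.raises(ValidationError):
            percent_extension(self._summary("t", 23.0), self._summary("c", 0.0))

    @pytest.mark.parametrize(
        "x,expected", [(2.5, 3), (3.5, 4), (-2.5, -3), (14.49, 14), (0.0, 0)]
    )
    def test_round_half_away(self, x, expected):
        assert round_half_away(x) == expected

    def _stage(self, rows):
        return pd.DataFrame(
            [
                {"batch": b, "group": g, "is_test_clone": True,
                 "pct_ext_mean": e, "raw_p": p}
                for b, g, e, p in rows
            ]
        )

    def test_two_stage_hit(self):
        ini = self._stage([("b1", "c1", 10.0, 0.01)])
        val = self._stage([("b1", "c1", 9.0, 0.01)])
        out = adjust_and_call(ini, val).set_index("clone")
        assert bool(out.loc["c1", "hit"])

    def test_low_extension_blocks_hit(self):
        ini = self._stage([("b1", "c1", 4.0, 1e-9)])
        val = self._stage([("b1", "c1", 20.0, 1e-9)])
        out = adjust_and_call(ini, val).set_index("clone")
        assert not bool(out.loc["c1", "hit"])
        assert out.loc["c1", "status"] == "not_hit"

    def test_bonferroni_family_is_test_clones_in_batch(self):
        ini = self._stage(
            [("b1", f"c{i}", 10.0, 0.02) for i in range(5)]
            + [("b2", "c9", 10.0, 0.02)]
        )
        adj = bonferroni_within_batch(ini).set_index("group")
        assert adj.loc["c0", "adjusted_p"] == pytest.approx(0.10)
        assert adj.loc["c9", "adjusted_p"] == pytest.approx(0.02)
        assert (adj["adjusted_p"] >= adj["raw_p"] - 1e-15).all()

    def test_failed_initial_is_not_hit_without_validation(self):
        ini = self._stage([("b1", "c1", 2.0, 0.5)])
        val = self._stage([])
        out = adjust_and_call(ini, val if len(val) else pd.DataFrame(columns=ini.columns))
        assert out.set_index("clone").loc["c1", "status"] == "not_hit"

    def test_passer_missing_from_validation_not_evaluable(self):
        ini = self._stage([("b1", "c1", 10.0, 0.001)])
        out = adjust_and_call(ini, pd.DataFrame(columns=ini.columns)).set_index("clone")
        assert out.loc["c1", "status"] == "not_evaluable"
        assert not bool(out.loc["c1", "hit"])

    def test_validation_failure_blocks_hit(self):
        ini = self._stage([("b1", "c1", 10.0, 0.001)])
        val = self._stage([("b1", "c1", 8.0, 0.9)])
        out = adjust_and_call(ini, val).set_index("clone")
        assert out.loc["c1", "status"] == "not_hit"


class TestCompareToControl:
    def test_batch_without_control_rejected(self):
        tbl = make_lifespan([1, 2, 3], group="clone1")
        with pytest.raises(ValidationError):
            compare_to_control(tbl, "GFP")

    def test_results_against_direct_computation(self, rng):
        ctrl = make_lifespan(rng.gamma(20, 1.1, 60), group="GFP")
        test = make_lifespan(rng.gamma(22, 1.1, 60), group="clone1")
        tbl = pd.concat([ctrl, test], ignore_index=True)
        out = compare_to_control(tbl, "GFP").set_index("group")
        s_t = lifespan_summaries(test)
        s_c = lifespan_summaries(ctrl)
        assert out.loc["clone1", "mean"] == pytest.approx(s_t.mean)
        assert out.loc["clone1", "pct_ext_mean"] == pytest.approx(
            100 * (s_t.mean - s_c.mean) / s_c.mean
        )
        chi2, p = logrank_test(test, ctrl)
        assert out.loc["clone1", "raw_p"] == pytest.approx(p)
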