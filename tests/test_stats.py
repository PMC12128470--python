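"""Questionnaire scoring, test routing, ROC/AUC, bootstrap and Youden."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from noxim.errors import ValidationError
from noxim.metrics import NightMetrics
from noxim.stats import (
    ParticipantRecord,
    bootstrap_auc_ci,
    classify_ams,
    compare_groups,
    prediction_table,
    roc_analysis,
    roc_auc,
    score_gsqs,
    youden_threshold,
)

from _oracles import oracle_auc, oracle_best_youden


class TestAmsRule:
    @pytest.mark.parametrize(
        "items,expected",
        [
            ((1, 1, 1, 0), True),  # total 3 with headache
            ((0, 2, 2, 1), False),  # total 5 but no headache
            ((0, 0, 0, 0), False),
            ((2, 0, 1, 0), True),
            ((1, 0, 1, 0), False),  # headache present, total below 3
            ((3, 3, 3, 3), True),
        ],
    )
    def test_rule(self, items, expected):
        assert classify_ams(items) is expected

    def test_out_of_range_item_rejected(self):
        with pytest.raises(ValidationError):
            classify_ams((4, 0, 0, 0))
        with pytest.raises(ValidationError):
            classify_ams((1, 1, 1))


class TestGsqs:
    def test_floor_and_ceiling(self):
        assert score_gsqs([False] * 15) == 0
        assert score_gsqs([True] * 15) == 14  # first item is unscored

    def test_single_scored_item(self):
        resp = [False] * 15
        resp[5] = True
        assert score_gsqs(resp) == 1

    def test_wrong_count_rejected(self):
        with pytest.raises(ValidationError):
            score_gsqs([True] * 14)


class TestRouting:
    def test_normal_samples_route_to_t_test(self):
        """Same-normal groups pass both Shapiro checks ~(1-alpha)^2 of the time."""
        rng = np.random.default_rng(123)
        hits = sum(
            compare_groups(rng.normal(size=12), rng.normal(size=12)).test_used
            == "t-test"
            for _ in range(1000)
        )
        assert 0.86 <= hits / 1000 <= 0.94

    def test_exponential_samples_usually_route_to_mann_whitney(self):
        # Shapiro-Wilk power against an exponential at n=12 is ~0.55 per
        # group, so the nonparametric route wins in roughly 4 of 5 draws
        rng = np.random.default_rng(99)
        hits = sum(
            compare_groups(rng.exponential(size=12), rng.exponential(size=12)).test_used
            == "mann-whitney"
            for _ in range(400)
        )
        assert hits / 400 >= 0.70

    def test_heavy_skew_routes_to_mann_whitney(self):
        rng = np.random.default_rng(7)
        hits = sum(
            compare_groups(
                rng.lognormal(0, 1.5, 12), rng.lognormal(0, 1.5, 12)
            ).test_used
            == "mann-whitney"
            for _ in range(200)
        )
        assert hits / 200 >= 0.95

    def test_constant_groups_handled(self):
        cmp = compare_groups([5.0] * 6, [5.0] * 6)
        assert cmp.test_used == "mann-whitney"
        assert cmp.p_value == pytest.approx(1.0)

    def test_summaries_match_route(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(10, 1, 12), rng.normal(10, 1, 12)
        cmp = compare_groups(a, b)
        if cmp.test_used == "t-test":
            assert cmp.summary_a == pytest.approx((a.mean(), a.std(ddof=1)))
        cmp2 = compare_groups(np.exp(a * 3), np.exp(b * 3))
        assert cmp2.test_used == "mann-whitney"
        q1, _, q3 = np.percentile(np.exp(a * 3), [25, 50, 75])
        assert cmp2.summary_a[1] == pytest.approx(q3 - q1)

    def test_small_groups_rejected(self):
        with pytest.raises(ValidationError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 7, 8, 9], [0, 0, 0, 1, 1, 1]) == 1.0

    def test_constant_predictor_is_half(self):
        assert roc_auc([5] * 8, [0, 1] * 4) == 0.5

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_matches_pairwise_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        vals = np.round(rng.normal(size=n), 1)  # rounding induces ties
        y = rng.random(n) < 0.5
        if y.all() or not y.any():
            y[0], y[-1] = True, False
        auc = roc_auc(vals, y, "higher")
        assert auc == pytest.approx(oracle_auc(vals, y))
        assert auc == pytest.approx(roc_auc(-vals, y, "lower"))
        if len(np.unique(vals)) == n:  # sklearn cross-check (no ties needed)
            assert auc == pytest.approx(roc_auc_score(y, vals))

    def test_negation_symmetry(self):
        rng = np.random.default_rng(2)
        vals, y = rng.normal(size=12), np.array([True] * 5 + [False] * 7)
        assert roc_auc(vals, y) == pytest.approx(1 - roc_auc(-vals, y))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        vals, y = rng.normal(size=14), rng.random(14) < 0.4
        y[0], y[1] = True, False
        assert roc_auc(np.exp(vals), y) == pytest.approx(roc_auc(vals, y))

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([1, 2, 3], [True, True, True])


class TestBootstrap:
    def test_perfect_separation_ci_degenerate(self):
        vals = [1, 2, 3, 7, 8, 9]
        y = [False] * 3 + [True] * 3
        lo, hi = bootstrap_auc_ci(vals, y, n_boot=500, rng=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_same_seed_reproduces(self):
        rng = np.random.default_rng(4)
        vals, y = rng.normal(size=12), np.array([True] * 6 + [False] * 6)
        a = bootstrap_auc_ci(vals, y, n_boot=1000, rng=42)
        b = bootstrap_auc_ci(vals, y, n_boot=1000, rng=42)
        assert a == b

    def test_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(5)
        vals, y = rng.normal(size=16), np.array([True] * 8 + [False] * 8)
        vals[:8] += 1.0
        lo, hi = bootstrap_auc_ci(vals, y, n_boot=4000, rng=1)
        assert lo <= roc_auc(vals, y) <= hi

    def test_width_shrinks_with_n(self):
        rng = np.random.default_rng(6)

        def avg_width(n, reps=25):
            widths = []
            for _ in range(reps):
                cases = rng.normal(1.2, 1, n)
                controls = rng.normal(0, 1, n)
                lo, hi = bootstrap_auc_ci(
                    np.concatenate([cases, controls]),
                    [True] * n + [False] * n,
                    n_boot=800,
                    rng=rng,
                )
                widths.append(hi - lo)
            return np.mean(widths)

        assert avg_width(24) < avg_width(6)


class TestYouden:
    def test_perfect_separation(self):
        thr, sens, spec = youden_threshold(
            [70, 71, 72, 80, 81, 82], [1, 1, 1, 0, 0, 0], "lower"
        )
        assert sens == spec == 1.0
        assert 72 < thr < 80

    def test_constant_predictor_no_discrimination(self):
        thr, sens, spec = youden_threshold([5.0] * 8, [0, 1] * 4, "higher")
        assert sens + spec - 1 == pytest.approx(0.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_j_matches_bruteforce_maximum(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        vals = np.round(rng.normal(size=n), 1)
        y = rng.random(n) < 0.5
        if y.all() or not y.any():
            y[0], y[-1] = True, False
        thr, sens, spec = youden_threshold(vals, y, "higher")
        assert sens + spec - 1 == pytest.approx(oracle_best_youden(list(vals), list(y)))
        # returned threshold actually achieves the returned operating point
        pos = vals > thr
        assert (pos & y).sum() / y.sum() == pytest.approx(sens)
        assert (~pos & ~y).sum() / (~y).sum() == pytest.approx(spec)

    def test_orientation_maps_threshold_back_to_raw_units(self):
        vals = np.array([77.0, 75.0, 74.0, 80.0, 81.0, 82.0])
        y = np.array([True, True, True, False, False, False])
        thr, sens, spec = youden_threshold(vals, y, "lower")
        assert sens == spec == 1.0
        assert ((vals < thr) == y).all()


class TestRocAnalysisAndTables:
    @staticmethod
    def _metrics(**kw):
        base = dict(
            mean_spo2=77,
            min_spo2=68,
            morning_spo2=78,
            delta_spo2=0.5,
            tst80=70,
            mean_hr=75,
            n_desat=120,
            odi=20.0,
            mean_desat_duration=19,
            hypoxic_burden=10,
            valid_fraction=0.99,
        )
        base.update(kw)
        return NightMetrics(**base)

    def _records(self, rng, n=12, coupled=True, group="pre-term"):
        recs = []
        for i in range(n):
            mean = float(rng.normal(77, 3))
            p_ams = 1 / (1 + np.exp(2.0 * (mean - 77))) if coupled else 0.5
            ams = rng.random() < p_ams
            recs.append(
                ParticipantRecord(
                    participant_id=f"x{i}",
                    group=group,
                    lls_evening=(0, 0, 0, 0),
                    lls_morning=(1, 1, 1, 0) if ams else (0, 0, 0, 0),
                    gsqs_responses=(False,) * 15,
                    metrics=self._metrics(
                        mean_spo2=mean,
                        n_desat=int(rng.integers(50, 500)),
                    ),
                )
            )
        # recompute odi as count / 6 h so the two stay proportional
        for j, r in enumerate(recs):
            recs[j] = ParticipantRecord(
                r.participant_id,
                r.group,
                r.lls_evening,
                r.lls_morning,
                r.gsqs_responses,
                self._metrics(
                    mean_spo2=r.metrics.mean_spo2,
                    n_desat=r.metrics.n_desat,
                    odi=r.metrics.n_desat / 6.0,
                ),
            )
        return recs

    def test_flag_requires_ci_above_half(self):
        rng = np.random.default_rng(8)
        vals = np.concatenate([rng.normal(3, 1, 8), rng.normal(0, 1, 8)])
        y = [True] * 8 + [False] * 8
        res = roc_analysis(vals, y, "x", "higher", n_boot=2000, rng=1)
        assert res.better_than_random == (res.ci_low > 0.5)
        assert res.ci_low <= res.auc <= res.ci_high

    def test_unflagged_has_no_threshold(self):
        rng = np.random.default_rng(9)
        res = roc_analysis(
            rng.normal(size=12), [True, False] * 6, "x", "higher", n_boot=500, rng=2
        )
        assert not res.better_than_random
        assert np.isnan(res.youden_threshold)

    def test_count_and_odi_rows_identical(self):
        rng = np.random.default_rng(10)
        tab = prediction_table(self._records(rng), n_boot=400, seed=0)
        sub = tab[tab.stratum == "pre-term"].set_index("predictor")
        assert sub.loc["n_desat", "auc"] == sub.loc["odi", "auc"]

    def test_single_class_stratum_isolated(self):
        rng = np.random.default_rng(11)
        recs = self._records(rng, group="pre-term") + [
            ParticipantRecord(
                f"t{i}",
                "term-born",
                (0, 0, 0, 0),
                (0, 0, 0, 0),  # every control AMS-negative
                (False,) * 15,
                self._metrics(),
            )
            for i in range(6)
        ]
        tab = prediction_table(recs, n_boot=300, seed=0)
        term = tab[tab.stratum == "term-born"]
        assert term.auc.isna().all() and (term.note != "").all()
        pre = tab[tab.stratum == "pre-term"]
        assert pre.auc.notna().all()

    def test_coupled_cohort_flags_mean_spo2(self):
        rng = np.random.default_rng(12)
        tab = prediction_table(self._records(rng, n=12), n_boot=2000, seed=3)
        row = tab[(tab.stratum == "pre-term") & (tab.predictor == "mean_spo2")].iloc[0]
        assert row.auc > 0.7

    def test_record_properties(self):
        r = ParticipantRecord(
            "p", "pre-term", (1, 1, 1, 0), (0, 0, 0, 0),
            tuple([True] * 15), self._metrics(),
        )
        assert r.ams_evening and not r.ams_morning
        assert r.gsqs_score == 14
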