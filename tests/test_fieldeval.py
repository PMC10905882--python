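"""Count-based confusion, BA, summaries, correlation/regression, diel profiles."""

from datetime import datetime

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from trapsense import fieldeval, simulate
from trapsense.fieldeval import ConfusionCounts, CycleCounts
from trapsense.types import TARGET_CLASSES, ClassLabel, CollectionCycle, DetectorNoise, FieldScenario

counts = st.integers(min_value=0, max_value=10_000)


def matching_oracle(sensor_pos, manual_pos, manual_neg):
    """Best-case event-level matching: pair sensor calls with manual events."""
    matched = 0
    sensor_left, manual_left = sensor_pos, manual_pos
    while sensor_left > 0 and manual_left > 0:
        matched += 1
        sensor_left -= 1
        manual_left -= 1
    fp = sensor_left
    fn = manual_left
    tn = max(manual_neg - fp, 0)
    return matched, fp, fn, tn


class TestCountConfusion:
    @pytest.mark.parametrize(
        "sensor,manual,neg,expected",
        [
            (5, 5, 10, (5, 0, 0, 10)),
            (8, 10, 20, (8, 0, 2, 20)),
            (12, 10, 20, (10, 2, 0, 18)),
        ],
    )
    def test_quoted_rules(self, sensor, manual, neg, expected):
        c = fieldeval.count_confusion(sensor, manual, neg)
        assert (c.tp, c.fp, c.fn, c.tn) == expected

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            fieldeval.count_confusion(-1, 0, 0)

    def test_excess_false_positives_flagged(self):
        c = fieldeval.count_confusion(30, 10, 5)
        assert c.fp_exceeds_negatives and c.tn == 0

    @given(counts, counts, counts)
    def test_conservation_laws(self, s, m, n):
        c = fieldeval.count_confusion(s, m, n)
        assert c.tp + c.fn == m
        assert c.tp + c.fp == s
        if c.fp <= n:
            assert c.tn + c.fp == n

    @given(counts, counts, counts)
    def test_matches_event_matching_oracle(self, s, m, n):
        c = fieldeval.count_confusion(s, m, n)
        assert (c.tp, c.fp, c.fn, c.tn) == matching_oracle(s, m, n)


class TestBalancedAccuracy:
    @pytest.mark.parametrize(
        "conf,se,sp,ba",
        [
            ((5, 0, 0, 10), 1.0, 1.0, 100.0),
            ((8, 0, 2, 20), 0.8, 1.0, 90.0),
            ((10, 2, 0, 18), 1.0, 0.9, 95.0),
        ],
    )
    def test_formula(self, conf, se, sp, ba):
        m = fieldeval.balanced_accuracy(ConfusionCounts(*conf))
        assert m.se == pytest.approx(se)
        assert m.sp == pytest.approx(sp)
        assert m.ba_pct == pytest.approx(ba)
        assert not m.partial

    def test_undefined_components(self):
        no_pos = fieldeval.balanced_accuracy(ConfusionCounts(0, 1, 0, 9))
        assert no_pos.se is None and no_pos.partial
        assert no_pos.ba == no_pos.sp
        no_neg = fieldeval.balanced_accuracy(ConfusionCounts(5, 0, 1, 0))
        assert no_neg.sp is None and no_neg.partial
        assert no_neg.ba == no_neg.se
        neither = fieldeval.balanced_accuracy(ConfusionCounts(0, 0, 0, 0))
        assert neither.ba is None

    @given(counts, counts, counts, st.integers(1, 50))
    def test_scale_invariance(self, s, m, n, k):
        a = fieldeval.balanced_accuracy(fieldeval.count_confusion(s, m, n))
        b = fieldeval.balanced_accuracy(fieldeval.count_confusion(k * s, k * m, k * n))
        if a.ba is not None:
            assert b.ba == pytest.approx(a.ba)


def make_cycle(cid, sensor_per_class, manual_per_class, nontarget, excluded=False):
    return CycleCounts(
        cycle_id=cid,
        start=None,
        end=None,
        manual=dict(zip(TARGET_CLASSES, manual_per_class)),
        manual_nontarget=nontarget,
        sensor=dict(zip(TARGET_CLASSES, sensor_per_class)),
        sensor_target_total=sum(sensor_per_class),
        excluded=excluded,
    )


class TestTargetDetectionEvaluation:
    def test_perfect_cycles(self):
        cycles = [make_cycle(f"C{i}", [5, 2, 9, 1], [5, 2, 9, 1], 10) for i in range(4)]
        df, summary = fieldeval.evaluate_target_detection(cycles)
        assert summary.mean == summary.median == 100.0
        assert summary.iqr == 0.0

    def test_simple_summary(self):
        # BAs 90, 95, 100 by construction
        cycles = [
            make_cycle("a", [8, 0, 0, 0], [10, 0, 0, 0], 20),
            make_cycle("b", [12, 0, 0, 0], [10, 0, 0, 0], 20),
            make_cycle("c", [10, 0, 0, 0], [10, 0, 0, 0], 20),
        ]
        df, summary = fieldeval.evaluate_target_detection(cycles)
        assert sorted(df["ba_pct"]) == [90.0, 95.0, 100.0]
        assert summary.mean == pytest.approx(95.0)
        assert summary.median == pytest.approx(95.0)

    def test_excluded_cycles_dropped(self):
        cycles = [
            make_cycle("a", [5, 0, 0, 0], [5, 0, 0, 0], 5),
            make_cycle("bad", [0, 0, 0, 0], [50, 0, 0, 0], 5, excluded=True),
        ]
        df, summary = fieldeval.evaluate_target_detection(cycles)
        assert list(df["cycle_id"]) == ["a"]
        with pytest.raises(ValueError):
            fieldeval.evaluate_target_detection([cycles[1]])

    @staticmethod
    def _simulate_noise(noise, seed):
        cycles = [
            CollectionCycle(f"C{i}", datetime(2021, 7, 1 + 2 * i, 9),
                            datetime(2021, 7, 2 + 2 * i, 9))
            for i in range(12)
        ]
        scen = FieldScenario(
            cycles=cycles,
            class_intensities={ClassLabel.CULEX_F: 300.0, ClassLabel.NON_TARGET: 300.0},
            diel_profile=simulate.default_diel_profiles(),
        )
        _, truth = simulate.simulate_field_trial(
            scen, detector_noise=noise, rng_seed=seed, synthesize_waveforms=False
        )
        _, summary = fieldeval.evaluate_target_detection(truth)
        return summary

    def test_known_miss_rate_recovered(self):
        # 5% misses, no false alarms: Se ~ 0.95, Sp ~ 1 -> mean BA ~ 97.5%
        summary = self._simulate_noise(DetectorNoise(miss_rate=0.05), seed=1)
        assert summary.mean == pytest.approx(97.5, abs=1.0)

    def test_known_false_alarm_rate_recovered(self):
        # 5% false alarms on an equal non-target pool: Se ~ 1, Sp ~ 0.95
        summary = self._simulate_noise(DetectorNoise(false_alarm_rate=0.05), seed=2)
        assert summary.mean == pytest.approx(97.5, abs=1.0)

    def test_symmetric_errors_compensate_in_count_based_scoring(self):
        # equal miss and false-alarm rates cancel within a cycle: the sensor
        # total tracks the manual total, so count-based BA exceeds the
        # event-level BA of 95% — aggregate counts cannot see paired errors
        summary = self._simulate_noise(
            DetectorNoise(miss_rate=0.05, false_alarm_rate=0.05), seed=3
        )
        assert summary.mean > 97.5


class TestGenusSexEvaluation:
    def test_perfect_agreement(self):
        cycles = [make_cycle(f"C{i}", [5, 2, 9, 1], [5, 2, 9, 1], 10) for i in range(3)]
        df, per_class, pooled, overall = fieldeval.evaluate_genus_sex(cycles)
        assert overall == pytest.approx(100.0)
        assert pooled.mean == pytest.approx(100.0)

    def test_overcount_hits_specificity_only(self):
        # AEDES_F sensor = 2x manual in one cycle: its Se stays 1, Sp drops;
        # other classes' Se unchanged
        base = make_cycle("a", [10, 5, 20, 5], [10, 5, 20, 5], 0)
        over = make_cycle("b", [20, 5, 20, 5], [10, 5, 20, 5], 0)
        df, *_ = fieldeval.evaluate_genus_sex([base, over])
        b = df[df["cycle_id"] == "b"].set_index("class")
        assert b.loc["AEDES_F", "se"] == 1.0
        assert b.loc["AEDES_F", "sp"] == pytest.approx(1 - 10 / 30)
        for cls in ("AEDES_M", "CULEX_F", "CULEX_M"):
            assert b.loc[cls, "se"] == 1.0

    def test_recovers_designed_confusion(self):
        # fixed class-confusion matrix; oracle = same count rules applied to
        # the expected (infinite-sample) counts
        cm = np.full((4, 4), 0.1 / 3) + np.eye(4) * (0.9 - 0.1 / 3)
        cycles = [
            CollectionCycle(f"C{i}", datetime(2021, 7, 1 + 2 * i, 9),
                            datetime(2021, 7, 2 + 2 * i, 9))
            for i in range(10)
        ]
        lam = {ClassLabel.AEDES_F: 120.0, ClassLabel.AEDES_M: 80.0,
               ClassLabel.CULEX_F: 200.0, ClassLabel.CULEX_M: 60.0}
        scen = FieldScenario(
            cycles=cycles, class_intensities=lam,
            diel_profile=simulate.default_diel_profiles(),
        )
        _, truth = simulate.simulate_field_trial(
            scen, detector_noise=DetectorNoise(class_confusion=cm),
            rng_seed=2, synthesize_waveforms=False,
        )
        _, per_class, _, _ = fieldeval.evaluate_genus_sex(truth)

        lam_vec = np.array([lam[c] for c in TARGET_CLASSES])
        expected_sensor = lam_vec @ cm
        for i, cls in enumerate(TARGET_CLASSES):
            manual = lam_vec[i]
            neg = lam_vec.sum() - manual
            conf = fieldeval.count_confusion(
                round(expected_sensor[i] * 100), round(manual * 100), round(neg * 100)
            )
            design_ba = fieldeval.balanced_accuracy(conf).ba_pct
            assert per_class[cls].mean == pytest.approx(design_ba, abs=2.5)


class TestCorrelationRegression:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        assert fieldeval.pearson_correlation(x, 2 * x + 1).r == pytest.approx(1.0)
        assert fieldeval.pearson_correlation(x, -x).r == pytest.approx(-1.0)

    def test_hand_computed_r(self):
        res = fieldeval.pearson_correlation([1, 2, 3], [2, 4, 5])
        assert res.r == pytest.approx(0.98198, abs=1e-4)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            fieldeval.pearson_correlation([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            fieldeval.pearson_correlation([1, 2], [1, 2])

    def test_exact_regression(self):
        x = np.arange(10.0)
        res = fieldeval.linear_regression(2 * x + 1, x)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_constant_response(self):
        res = fieldeval.linear_regression(np.full(5, 3.0), np.arange(5.0))
        assert res.slope == pytest.approx(0.0)
        assert res.r_squared == pytest.approx(0.0)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            fieldeval.linear_regression(np.arange(5.0), np.full(5, 3.0))

    def test_noisy_line_slope_within_ci(self):
        # sampling-distribution oracle: known sigma, fixed design
        rng = np.random.default_rng(44)
        n, sigma, slope = 44, 5.0, 0.9
        x = rng.uniform(0, 100, n)
        y = slope * x + rng.normal(0, sigma, n)
        res = fieldeval.linear_regression(y, x)
        se = sigma / np.sqrt(np.sum((x - x.mean()) ** 2))
        assert abs(res.slope - slope) <= 1.96 * se


class TestAggregateIdentity:
    def test_same_sign_cycles_sum_exactly(self):
        per = [(8, 10), (5, 9), (0, 3)]  # sensor <= manual everywhere
        tp_sum = sum(fieldeval.count_confusion(s, m, 0).tp for s, m in per)
        agg = fieldeval.count_confusion(sum(s for s, _ in per), sum(m for _, m in per), 0)
        assert tp_sum == agg.tp

    @given(st.lists(st.tuples(counts, counts), min_size=1, max_size=10))
    def test_per_cycle_tp_never_exceeds_aggregate(self, pairs):
        tp_sum = sum(fieldeval.count_confusion(s, m, 0).tp for s, m in pairs)
        agg = fieldeval.count_confusion(
            sum(s for s, _ in pairs), sum(m for _, m in pairs), 0
        )
        assert tp_sum <= agg.tp


class TestActivityProfile:
    def test_single_hour_concentration(self):
        ts = [datetime(2021, 6, 1 + i, 6, 15) for i in range(30)]
        events = pd.DataFrame({"timestamp": ts, "genus": "Aedes"})
        prof = fieldeval.compute_activity_profile(
            events, datetime(2021, 6, 1), datetime(2021, 6, 30, 23, 59)
        )
        aedes = prof[prof["genus"] == "Aedes"].set_index("hour")["mean_count"]
        assert aedes[6] == pytest.approx(1.0)
        assert aedes.drop(6).eq(0).all()

    def test_empty_events(self):
        prof = fieldeval.compute_activity_profile(
            pd.DataFrame(columns=["timestamp", "genus"]),
            datetime(2021, 6, 1),
            datetime(2021, 6, 30),
        )
        assert prof.empty

    def test_bimodal_aedes_peaks_recovered(self):
        cycles = [
            CollectionCycle(f"C{i}", datetime(2021, 7, 1 + i, 0),
                            datetime(2021, 7, 2 + i, 0))
            for i in range(0, 20, 2)
        ]
        scen = FieldScenario(
            cycles=cycles,
            class_intensities={ClassLabel.AEDES_F: 120.0},
            diel_profile=simulate.default_diel_profiles(),
        )
        stream, _ = simulate.simulate_field_trial(
            scen, rng_seed=3, synthesize_waveforms=False
        )
        events = pd.DataFrame(
            {"timestamp": [r.timestamp for r in stream],
             "genus": [r.true_label.genus for r in stream]}
        )
        prof = fieldeval.compute_activity_profile(
            events, cycles[0].start, cycles[-1].end
        )
        hourly = (
            prof[prof["genus"] == "Aedes"].groupby("hour")["mean_count"].mean()
        )
        top2 = set(hourly.nlargest(2).index)
        assert top2 == {6, 19}


class TestCycleCountsIO:
    def test_roundtrip(self, tmp_path):
        cycles = [
            CycleCounts(
                cycle_id="T1C01",
                start=datetime(2021, 7, 5, 9),
                end=datetime(2021, 7, 6, 9),
                manual={c: i + 1 for i, c in enumerate(TARGET_CLASSES)},
                manual_nontarget=42,
                sensor={c: i for i, c in enumerate(TARGET_CLASSES)},
                sensor_target_total=6,
                excluded=True,
                exclusion_reason="depredation",
            )
        ]
        path = tmp_path / "counts.csv"
        fieldeval.write_cycle_counts(cycles, path)
        back = fieldeval.read_cycle_counts(path)
        assert back[0] == cycles[0]
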