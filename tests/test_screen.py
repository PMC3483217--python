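"""Thrashing classifier, survival estimators, and screen arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from longnet.io import DataError
from longnet.screen import (
    LONG,
    NONE,
    SHORT,
    EffectMeasure,
    ScreenSummary,
    SurvivalDataset,
    ThrashingRecord,
    classify_thrashing,
    extrapolate_verified,
    fold_improvement,
    km_estimate,
    logrank_test,
    percent_changes,
    primary_detection_rates,
    summarize_effects,
    verification_frequency,
)

CONTROL = (0.90, 0.80, 0.60, 0.40)


def _record(treated, control=CONTROL):
    return ThrashingRecord(gene="g", survival_fraction=treated, control_fraction=control)


def _deaths(*times, label="x"):
    return SurvivalDataset(label=label, times=tuple(times), events=(True,) * len(times))


def logrank_oracle(a: SurvivalDataset, b: SurvivalDataset) -> float:
    """Hand-rolled risk-set-table chi-square, independent of lifelines."""
    event_times = sorted({t for t, e in zip(a.times + b.times,
                                            a.events + b.events) if e})
    obs = exp = var = 0.0
    for t in event_times:
        na = sum(1 for x in a.times if x >= t)
        nb = sum(1 for x in b.times if x >= t)
        da = sum(1 for x, e in zip(a.times, a.events) if e and x == t)
        db = sum(1 for x, e in zip(b.times, b.events) if e and x == t)
        n, d = na + nb, da + db
        obs += da
        exp += d * na / n
        if n > 1:
            var += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    return (obs - exp) ** 2 / var


class TestClassifyThrashing:
    def test_consistent_increase_is_long(self):
        assert classify_thrashing(_record((1.0, 0.92, 0.70, 0.50))) == LONG

    def test_identical_is_none(self):
        assert classify_thrashing(_record(CONTROL)) == NONE

    def test_consistent_decrease_is_short(self):
        assert classify_thrashing(_record((0.79, 0.70, 0.52, 0.34))) == SHORT

    def test_opposite_direction_timepoint_blocks_call(self):
        # 3 of 4 up but one strong drop: "consistent" must reject it
        control = (0.6, 0.6, 0.6, 0.6)
        treated = tuple(c * f for c, f in zip(control, (1.25, 1.25, 1.25, 0.75)))
        assert classify_thrashing(_record(treated, control)) == NONE

    def test_two_timepoints_insufficient(self):
        control = (0.6, 0.6, 0.6, 0.6)
        treated = tuple(c * f for c, f in zip(control, (1.25, 1.25, 1.0, 1.0)))
        assert classify_thrashing(_record(treated, control)) == NONE

    def test_zero_control_timepoint_excluded(self):
        rec = ThrashingRecord(
            gene="g",
            survival_fraction=(0.9, 0.9, 0.9, 0.5),
            control_fraction=(0.7, 0.7, 0.7, 0.0),
        )
        assert classify_thrashing(rec) == LONG

    def test_all_indeterminate_errors(self):
        rec = ThrashingRecord(
            gene="g",
            survival_fraction=(0.1, 0.1, 0.1, 0.1),
            control_fraction=(0.0, 0.0, 0.0, 0.0),
        )
        with pytest.raises(DataError, match="indeterminate"):
            classify_thrashing(rec)

    @given(st.lists(
        st.floats(-0.5, 0.5).filter(lambda x: abs(abs(x) - 0.1) > 1e-6),
        min_size=4, max_size=4,
    ))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_antisymmetry(self, changes):
        control = (0.6, 0.6, 0.6, 0.6)
        up = tuple(min(1.0, max(0.0, c * (1 + ch))) for c, ch in zip(control, changes))
        down = tuple(min(1.0, max(0.0, c * (1 - ch))) for c, ch in zip(control, changes))
        call_up = classify_thrashing(_record(up, control))
        call_down = classify_thrashing(_record(down, control))
        assert {LONG: SHORT, SHORT: LONG, NONE: NONE}[call_up] == call_down

    @given(st.lists(st.floats(-0.5, 0.5), min_size=4, max_size=4),
           st.floats(0.05, 0.2), st.floats(0.05, 0.4))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_threshold_monotonicity(self, changes, thr, bump):
        control = (0.6, 0.6, 0.6, 0.6)
        treated = tuple(min(1.0, max(0.0, c * (1 + ch))) for c, ch in zip(control, changes))
        lo = classify_thrashing(_record(treated, control), threshold=thr)
        hi = classify_thrashing(_record(treated, control), threshold=thr + bump)
        # a directional call can only weaken to none as the threshold rises;
        # none may become directional when an opposing time point drops below
        # the veto threshold, but a call never flips between long and short
        assert (lo, hi) not in {(LONG, SHORT), (SHORT, LONG)}
        if lo in (LONG, SHORT):
            assert hi in (lo, NONE)


class TestKaplanMeier:
    def test_two_deaths(self):
        res = km_estimate(_deaths(10, 20))
        assert res.mean == pytest.approx(15.0)
        assert res.median == pytest.approx(10.0)

    def test_single_death(self):
        res = km_estimate(_deaths(7))
        assert res.mean == pytest.approx(7.0)

    def test_all_censored_errors(self):
        ds = SurvivalDataset(label="x", times=(5.0, 6.0), events=(False, False))
        with pytest.raises(DataError, match="death"):
            km_estimate(ds)

    def test_censoring_raises_curve(self):
        uncensored = _deaths(5, 10, 15, 20)
        censored = SurvivalDataset(
            label="x", times=(5, 10, 15, 20), events=(True, False, True, True)
        )
        assert km_estimate(censored).mean > km_estimate(uncensored).mean

    @given(st.lists(st.floats(1, 40), min_size=1, max_size=15))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_mean_equals_arithmetic_mean_without_censoring(self, times):
        res = km_estimate(_deaths(*times))
        assert res.mean == pytest.approx(np.mean(times), rel=1e-9)


class TestLogrank:
    def test_identical_groups(self):
        a = _deaths(5, 10, 15, label="a")
        b = _deaths(5, 10, 15, label="b")
        stat, p = logrank_test(a, b)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        _, p = logrank_test(_deaths(5, 5, 5), _deaths(50, 50, 50))
        assert p < 0.05

    def test_matches_hand_computed_risk_table(self):
        a = _deaths(1, 3, 5, label="a")
        b = _deaths(2, 4, 6, label="b")
        stat, _ = logrank_test(a, b)
        assert stat == pytest.approx(logrank_oracle(a, b), abs=1e-10)

    def test_requires_deaths(self):
        censored = SurvivalDataset(label="c", times=(5.0,), events=(False,))
        with pytest.raises(DataError):
            logrank_test(censored, _deaths(5, 6))


class TestPercentChanges:
    def test_uniform_shift(self):
        eff = percent_changes(_deaths(*[25] * 8), _deaths(*[20] * 8))
        assert eff.pct_delta_mean == pytest.approx(25.0)
        assert eff.pct_delta_max == pytest.approx(25.0)

    def test_identical(self):
        eff = percent_changes(_deaths(10, 20, 30, 40), _deaths(10, 20, 30, 40))
        assert eff.pct_delta_mean == pytest.approx(0.0)

    def test_quartile_arithmetic(self):
        eff = percent_changes(_deaths(10, 20, 30, 40), _deaths(10, 20, 30, 32))
        assert eff.pct_delta_mean == pytest.approx(100 * 2 / 23)
        assert eff.pct_delta_max == pytest.approx(25.0)

    def test_needs_four_deaths(self):
        with pytest.raises(DataError):
            percent_changes(_deaths(10, 20, 30), _deaths(10, 20, 30, 40))


class TestScreenArithmetic:
    def test_verification_frequency(self):
        s = ScreenSummary(374, 101, 55, 45, 12, 19, 11)
        assert verification_frequency(s, LONG) == 5.1
        assert verification_frequency(s, SHORT) == 2.9
        zero = ScreenSummary(100, 0, 0, 0, 0, 0, 0)
        assert verification_frequency(zero, LONG) == 0.0

    def test_funnel_invariant_enforced(self):
        with pytest.raises(DataError):
            ScreenSummary(10, 5, 0, 6, 0, 2, 0)  # retested > preliminary

    def test_extrapolation(self):
        assert extrapolate_verified(101, 45, 19, 374) == (42, 11.2)
        assert extrapolate_verified(55, 12, 11, 374) == (50, 13.4)
        assert extrapolate_verified(10, 10, 10, 100) == (10, 10.0)

    def test_fold_improvement(self):
        assert fold_improvement(5.0, [5.0]) == (1, 1.0)
        fold, raw = fold_improvement(2.0, [1.0, 3.0])
        assert (fold, raw) == (1, 1.0)
        with pytest.raises(DataError):
            fold_improvement(5.0, [0.0])

    def test_summarize_single_effect(self):
        assert summarize_effects([EffectMeasure("g", 5.0, 4.0)], LONG) == (1, 5.0, 1)

    def test_summarize_dedups_by_gene(self):
        effects = [EffectMeasure("g", 8.0, 0.0), EffectMeasure("g", 8.0, 0.0),
                   EffectMeasure("h", 12.0, 0.0)]
        assert summarize_effects(effects, LONG) == (2, 10.0, 1)

    def test_detection_rates(self):
        assert primary_detection_rates(147, 47, 21) == (46, 32, 14)
        assert primary_detection_rates(184, 45, 27) == (39, 24, 15)
        assert primary_detection_rates(43, 9, 7) == (37, 21, 16)
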