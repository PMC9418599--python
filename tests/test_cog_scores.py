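import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from tapjid.cog_scores import (
    MIN_TRIALS,
    POSTURES,
    compute_scores,
    finger_scales,
    score_corsi,
    score_nback,
    score_reaction_time,
    score_task_switch,
)


def _rt_df(rts, correct=None, task_cols=True):
    n = len(rts)
    df = pd.DataFrame(
        {
            "rt_ms": rts,
            "correct": correct if correct is not None else [True] * n,
        }
    )
    return df


class TestReactionTime:
    def test_median_and_valid(self):
        df = _rt_df([300, 320, 340] * 5)
        res = score_reaction_time(df, "srt")
        assert res.value == 320
        assert res.valid

    def test_eleven_trials_invalid_but_scored(self):
        df = _rt_df([300] * 11)
        res = score_reaction_time(df, "srt")
        assert res.value == 300
        assert not res.valid

    def test_crt_24_trials(self):
        df = _rt_df([400, 500] * 12)
        res = score_reaction_time(df, "crt")
        assert res.value == 450
        assert res.valid

    def test_crt_minimum_is_24(self):
        df = _rt_df([400] * 23)
        assert not score_reaction_time(df, "crt").valid
        assert score_reaction_time(_rt_df([400] * 24), "crt").valid

    def test_zero_correct_invalid_no_exception(self):
        df = _rt_df([300] * 15, correct=[False] * 15)
        res = score_reaction_time(df, "srt")
        assert np.isnan(res.value)
        assert not res.valid

    def test_too_slow_counts_as_executed_not_correct(self):
        df = _rt_df([300] * 12 + [3500])
        res = score_reaction_time(df, "srt")
        assert res.value == 300
        assert res.n_executed == 13

    def test_median_invariant_to_order_and_duplication(self, rng):
        rts = rng.uniform(200, 800, 15)
        base = score_reaction_time(_rt_df(rts), "srt").value
        shuffled = score_reaction_time(_rt_df(rng.permutation(rts)), "srt").value
        doubled = score_reaction_time(_rt_df(np.tile(rts, 2)), "srt").value
        assert base == shuffled == doubled


def _switch_df(pure_rts, mixed_switch, mixed_nonswitch):
    rows = []
    for rt in pure_rts:
        rows.append(("pure_shape", rt, False))
    for rt in mixed_switch:
        rows.append(("mixed", rt, True))
    for rt in mixed_nonswitch:
        rows.append(("mixed", rt, False))
    df = pd.DataFrame(rows, columns=["block_type", "rt_ms", "is_switch_trial"])
    df["correct"] = True
    return df


class TestTaskSwitch:
    def test_global_cost(self):
        df = _switch_df([500] * 10, [650] * 5, [650] * 5)
        g, _ = score_task_switch(df)
        assert g.value == pytest.approx(0.30)

    def test_local_cost(self):
        df = _switch_df([500] * 10, [700] * 5, [600] * 5)
        _, l = score_task_switch(df)
        assert l.value == pytest.approx((700 - 600) / 600)
        assert l.value == pytest.approx(0.1667, abs=5e-4)

    def test_equal_medians_zero_cost(self):
        df = _switch_df([500] * 10, [500] * 5, [500] * 5)
        g, l = score_task_switch(df)
        assert g.value == 0.0
        assert l.value == 0.0

    def test_missing_block_invalid(self):
        df = pd.DataFrame(
            {
                "block_type": ["mixed"] * 12,
                "rt_ms": [500.0] * 12,
                "is_switch_trial": [True, False] * 6,
                "correct": [True] * 12,
            }
        )
        g, _ = score_task_switch(df)
        assert not g.valid

    def test_minimum_trials(self):
        df = _switch_df([500] * 4, [650] * 4, [600] * 3)  # 11 trials
        g, _ = score_task_switch(df)
        assert not g.valid


def _corsi_df(rows):
    return pd.DataFrame(
        {
            "trial_index": range(len(rows)),
            "sequence_length": [r[0] for r in rows],
            "correct": [r[1] for r in rows],
        }
    )


class TestCorsi:
    def test_termination_after_two_consecutive_errors(self):
        rows = [(l, True) for l in range(2, 7)] + [(7, False), (7, False)]
        res = score_corsi(_corsi_df(rows))
        assert res.value == 6
        assert res.valid

    def test_full_span_nine(self):
        rows = [(l, True) for l in range(2, 10)]
        assert score_corsi(_corsi_df(rows)).value == 9

    def test_two_errors_at_start_span_zero(self):
        rows = [(2, False), (2, False)]
        res = score_corsi(_corsi_df(rows))
        assert res.value == 0
        assert res.valid  # two trials were executed

    def test_single_trial_invalid(self):
        res = score_corsi(_corsi_df([(2, True)]))
        assert not res.valid

    def test_single_error_does_not_terminate(self):
        rows = [(2, True), (3, False), (3, True), (4, True)]
        assert score_corsi(_corsi_df(rows)).value == 4


def _nback_df(n_targets, n_nontargets, hits, fas):
    rows = []
    for i in range(n_targets):
        rows.append((True, i < hits))
    for i in range(n_nontargets):
        rows.append((False, i < fas))
    return pd.DataFrame(rows, columns=["is_target", "responded"])


class TestNback:
    def test_dprime_oracle_value(self):
        # hit 0.9, fa 0.1 -> d' = z(0.9) - z(0.1) = 2*1.28155 = 2.5631
        df = _nback_df(30, 60, hits=27, fas=6)
        res = score_nback(df)
        oracle = norm.ppf(0.9) - norm.ppf(0.1)
        assert res.value == pytest.approx(oracle, abs=1e-9)
        assert res.value == pytest.approx(2.5631, abs=5e-4)
        assert res.valid

    def test_hit_equals_fa_zero(self):
        df = _nback_df(30, 30, hits=15, fas=15)
        assert score_nback(df).value == pytest.approx(0.0, abs=1e-12)

    def test_perfect_hit_rate_clipped_finite(self):
        df = _nback_df(30, 60, hits=30, fas=6)
        res = score_nback(df)
        assert np.isfinite(res.value)
        expected = norm.ppf(1 - 1 / 60) - norm.ppf(0.1)
        assert res.value == pytest.approx(expected, abs=1e-9)

    def test_minimum_30_trials(self):
        assert not score_nback(_nback_df(10, 19, 9, 2)).valid
        assert score_nback(_nback_df(10, 20, 9, 2)).valid

    def test_no_targets_invalid(self):
        res = score_nback(_nback_df(0, 30, 0, 3))
        assert not res.valid

    def test_antisymmetry(self):
        a = score_nback(_nback_df(30, 30, hits=24, fas=6)).value
        b = score_nback(_nback_df(30, 30, hits=6, fas=24)).value
        assert a == pytest.approx(-b, abs=1e-12)

    def test_monotone_in_hits(self):
        vals = [
            score_nback(_nback_df(30, 30, hits=h, fas=6)).value
            for h in (10, 15, 20, 25)
        ]
        assert all(x < y for x, y in zip(vals, vals[1:]))


class TestFingerScales:
    def test_right_thumb_first(self):
        ranks = {p: i + 1 for i, p in enumerate(POSTURES)}
        ranks["right_thumb"] = 1
        ranks["left_thumb"] = 2
        # keep a permutation: swap the displaced ranks
        ranks = dict(zip(POSTURES, [2, 1, 3, 4, 5, 6, 7, 8]))
        t, _ = finger_scales(ranks)
        assert t == 1.0

    def test_worst_thumb_rank(self):
        # all four thumb postures at ranks 5..8
        ranks = dict(zip(POSTURES, [5, 6, 7, 8, 1, 2, 3, 4]))
        t, d = finger_scales(ranks)
        assert t == pytest.approx((8 - 5) / 7)
        assert d == pytest.approx((8 - 7) / 7)

    def test_dual_thumb_example(self):
        # both-thumbs portrait at 4, landscape at 6 -> (8-4)/7
        ranks = dict(zip(POSTURES, [1, 2, 4, 6, 3, 5, 7, 8]))
        _, d = finger_scales(ranks)
        assert d == pytest.approx(0.5714, abs=5e-4)

    def test_non_permutation_rejected(self):
        with pytest.raises(ValueError, match="permutation"):
            finger_scales([1, 1, 2, 3, 4, 5, 6, 7])

    @settings(max_examples=50, deadline=None)
    @given(st.permutations(list(range(1, 9))))
    def test_monotone_promotion(self, perm):
        t0, d0 = finger_scales(perm)
        # promote the best thumb posture to rank 1 by swapping
        idx = int(np.argmin([perm[i] for i in range(4)]))
        target = perm[idx]
        swapped = [1 if r == target else (target if r == 1 else r) for r in perm]
        t1, d1 = finger_scales(swapped)
        assert t1 >= t0
        assert 0.0 <= t1 <= 1.0 and 0.0 <= d1 <= 1.0


def test_compute_scores_table(small_cohort):
    scores = compute_scores(small_cohort.trials)
    assert len(scores) == small_cohort.participants.shape[0]
    for col in (
        "srt_median_ms",
        "crt_median_ms",
        "global_cost",
        "local_cost",
        "corsi_span",
        "nback_dprime",
    ):
        assert col in scores.columns
    assert scores["crt_valid"].all()
    assert scores["corsi_span"].between(0, 9).all()


def test_min_trial_constants_exact():
    assert MIN_TRIALS == {"srt": 12, "crt": 24, "switch": 12, "corsi": 2, "nback": 30}
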