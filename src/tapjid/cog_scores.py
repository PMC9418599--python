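"""Per-participant cognitive test scores from trial-level records.

Scores: median simple/choice reaction times, global and local switch
costs (ratio-normalized), Corsi span with the two-consecutive-error
termination rule, and 2-back sensitivity d' with extreme-rate clipping.
Each score carries a validity flag enforcing the minimum-trial rules
(12 srt / 24 crt / 12 switch / 2 corsi / 30 nback).  Finger-preference
ranks over the eight posture images are converted to the two 0–1 scales.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "MIN_TRIALS",
    "POSTURES",
    "THUMB_POSTURES",
    "DUAL_THUMB_POSTURES",
    "ScoreResult",
    "score_reaction_time",
    "score_task_switch",
    "score_corsi",
    "score_nback",
    "finger_scales",
    "compute_scores",
]

#: minimum successfully executed trials required for a valid score
MIN_TRIALS = {"srt": 12, "crt": 24, "switch": 12, "corsi": 2, "nback": 30}

#: the eight on-screen posture images, in canonical order
POSTURES = (
    "left_thumb",
    "right_thumb",
    "both_thumbs_portrait",
    "both_thumbs_landscape",
    "left_index",
    "right_index",
    "left_middle",
    "right_middle",
)
THUMB_POSTURES = POSTURES[:4]
DUAL_THUMB_POSTURES = POSTURES[2:4]

#: responses slower than this count as executed but not correct
TOO_SLOW_MS = 3000.0


@dataclass
class ScoreResult:
    value: float
    valid: bool
    n_executed: int


def _executed(trials: pd.DataFrame) -> pd.Series:
    """A trial is 'successfully executed' if a response was registered."""
    if "rt_ms" in trials.columns:
        return trials["rt_ms"].notna()
    return pd.Series(True, index=trials.index)


def _correct_rts(trials: pd.DataFrame) -> np.ndarray:
    ok = trials["correct"].astype(bool) & trials["rt_ms"].notna()
    ok &= trials["rt_ms"] <= TOO_SLOW_MS
    return trials.loc[ok, "rt_ms"].to_numpy(dtype=float)


def score_reaction_time(trials: pd.DataFrame, task: str) -> ScoreResult:
    """Median RT (ms) over correct trials for ``task`` in {'srt', 'crt'}."""
    if task not in ("srt", "crt"):
        raise ValueError(f"task must be 'srt' or 'crt', got {task!r}")
    n_exec = int(_executed(trials).sum())
    rts = _correct_rts(trials)
    if rts.size == 0:
        return ScoreResult(float("nan"), False, n_exec)
    return ScoreResult(
        float(np.median(rts)), n_exec >= MIN_TRIALS[task], n_exec
    )


def score_task_switch(trials: pd.DataFrame) -> tuple[ScoreResult, ScoreResult]:
    """(global_cost, local_cost) from a cued shape/color switching task.

    global = (median mixed − median pure) / median pure, pooling the shape
    and color pure blocks; local = (median mixed switch − median mixed
    non-switch) / median mixed non-switch.  Correct trials only.
    """
    n_exec = int(_executed(trials).sum())
    valid_n = n_exec >= MIN_TRIALS["switch"]
    ok = trials["correct"].astype(bool) & trials["rt_ms"].notna()
    ok &= trials["rt_ms"] <= TOO_SLOW_MS
    t = trials.loc[ok]
    pure = t.loc[t["block_type"].isin(["pure_shape", "pure_color"]), "rt_ms"]
    mixed = t.loc[t["block_type"] == "mixed"]
    if len(pure) == 0 or len(mixed) == 0:
        return (
            ScoreResult(float("nan"), False, n_exec),
            ScoreResult(float("nan"), False, n_exec),
        )
    pure_med = float(pure.median())
    global_cost = (float(mixed["rt_ms"].median()) - pure_med) / pure_med
    sw = mixed.loc[mixed["is_switch_trial"].astype(bool), "rt_ms"]
    ns = mixed.loc[~mixed["is_switch_trial"].astype(bool), "rt_ms"]
    if len(sw) == 0 or len(ns) == 0:
        local = ScoreResult(float("nan"), False, n_exec)
    else:
        ns_med = float(ns.median())
        local = ScoreResult(
            (float(sw.median()) - ns_med) / ns_med, valid_n, n_exec
        )
    return ScoreResult(global_cost, valid_n, n_exec), local


def score_corsi(trials: pd.DataFrame) -> ScoreResult:
    """Corsi span: longest correctly reproduced sequence length.

    Trials are scanned in order; the test terminates at two consecutive
    errors or once a 9-item sequence is correctly ordered.
    """
    t = trials.sort_values("trial_index") if "trial_index" in trials.columns else trials
    span = 0
    consec_errors = 0
    n_seen = 0
    for length, correct in zip(t["sequence_length"], t["correct"]):
        n_seen += 1
        if bool(correct):
            consec_errors = 0
            span = max(span, int(length))
            if int(length) >= 9:
                break
        else:
            consec_errors += 1
            if consec_errors >= 2:
                break
    return ScoreResult(float(span), n_seen >= MIN_TRIALS["corsi"], n_seen)


def score_nback(trials: pd.DataFrame) -> ScoreResult:
    """2-back sensitivity d' = z(hit rate) − z(false-alarm rate).

    Rates are clipped to [1/(2N), 1 − 1/(2N)] within each class (N = class
    trial count) so extreme proportions give a finite d'.
    """
    n_exec = len(trials)
    targets = trials["is_target"].astype(bool)
    responded = trials["responded"].astype(bool)
    n_t = int(targets.sum())
    n_nt = int((~targets).sum())
    if n_t == 0 or n_nt == 0:
        return ScoreResult(float("nan"), False, n_exec)
    hit = np.clip(
        responded[targets].mean(), 1.0 / (2 * n_t), 1.0 - 1.0 / (2 * n_t)
    )
    fa = np.clip(
        responded[~targets].mean(), 1.0 / (2 * n_nt), 1.0 - 1.0 / (2 * n_nt)
    )
    dprime = float(norm.ppf(hit) - norm.ppf(fa))
    return ScoreResult(dprime, n_exec >= MIN_TRIALS["nback"], n_exec)


def finger_scales(ranks) -> tuple[float, float]:
    """Convert posture ranks (1 = most used … 8 = least) to the two scales.

    ``ranks`` is a mapping posture-name → rank or a sequence of 8 ranks in
    :data:`POSTURES` order.  Each scale is (8 − best relevant rank) / 7,
    so 1.0 means the relevant posture is the most used image and 0.0 the
    least.
    """
    if isinstance(ranks, Mapping):
        missing = [p for p in POSTURES if p not in ranks]
        if missing:
            raise ValueError(f"missing posture rank(s): {missing}")
        rank_of = {p: int(ranks[p]) for p in POSTURES}
    else:
        seq = list(ranks)
        if len(seq) != 8:
            raise ValueError("expected 8 ranks")
        rank_of = {p: int(r) for p, r in zip(POSTURES, seq)}
    if sorted(rank_of.values()) != list(range(1, 9)):
        raise ValueError("ranks must be a permutation of 1..8")
    thumb_best = min(rank_of[p] for p in THUMB_POSTURES)
    dual_best = min(rank_of[p] for p in DUAL_THUMB_POSTURES)
    return (8 - thumb_best) / 7.0, (8 - dual_best) / 7.0


def compute_scores(trials: pd.DataFrame) -> pd.DataFrame:
    """Score every participant in a trial table; one row per participant.

    Columns follow the scores.csv interface with per-score validity flags
    and, when present in the input, the per-task test day.
    """
    rows = []
    for pid, t in trials.groupby("participant_id", sort=True):
        row: dict[str, object] = {"participant_id": pid}
        by_task = {task: grp for task, grp in t.groupby("task")}
        for task, col in (("srt", "srt_median_ms"), ("crt", "crt_median_ms")):
            if task in by_task:
                res = score_reaction_time(by_task[task], task)
                row[col] = res.value
                row[f"{task}_valid"] = res.valid
            else:
                row[col] = float("nan")
                row[f"{task}_valid"] = False
        if "switch" in by_task:
            g, l = score_task_switch(by_task["switch"])
            row["global_cost"], row["global_cost_valid"] = g.value, g.valid
            row["local_cost"], row["local_cost_valid"] = l.value, l.valid
        else:
            row["global_cost"] = row["local_cost"] = float("nan")
            row["global_cost_valid"] = row["local_cost_valid"] = False
        if "corsi" in by_task:
            res = score_corsi(by_task["corsi"])
            row["corsi_span"], row["corsi_valid"] = res.value, res.valid
        else:
            row["corsi_span"], row["corsi_valid"] = float("nan"), False
        if "nback" in by_task:
            res = score_nback(by_task["nback"])
            row["nback_dprime"], row["nback_valid"] = res.value, res.valid
        else:
            row["nback_dprime"], row["nback_valid"] = float("nan"), False
        if "test_day" in t.columns:
            for task, grp in by_task.items():
                days = grp["test_day"].dropna()
                if len(days):
                    row[f"{task}_test_day"] = days.iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)
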