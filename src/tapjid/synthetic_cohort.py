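"""Synthetic tappigraphy cohort generator.

Produces participants, session-structured touch streams, screen episodes
and trial-level cognitive records so that the full pipeline can run
without any external data.  Inter-touch intervals are drawn from an
age-dependent two-component log-normal mixture anchored at ~100 ms
(fast) and ~4 s (slow); the weight of the fast component declines
linearly with age.  A latent standard-normal "pace" factor loads
positively on the fast-component weight and negatively on the
slow-component mean, planting both consistent and inconsistent residual
couplings between distant JID bins.

Because consecutive intervals are drawn independently, the expected JID
of a participant has a closed form (product of kernel-smoothed Gaussian
mixtures), from which the planted per-bin age/factor effect signs are
derived deterministically (:func:`expected_jid`, :class:`PlantedTruth`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy.stats import norm

from .jid_core import JIDConfig

__all__ = [
    "CohortSpec",
    "PlantedTruth",
    "CohortData",
    "generate_cohort",
    "expected_jid",
    "build_truth",
    "worked_example_stream",
    "write_cohort",
]

#: recording start anchor (2021-01-04 00:00 UTC), epoch ms
BASE_EPOCH_MS = 1_609_718_400_000
MS_PER_DAY = 86_400_000


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort; defaults mirror the target
    population (bimodal ages 25/63, 62.5% female) and the two headline
    ITI time scales (~100 ms and ~4 s)."""

    n_participants: int = 150
    seed: int = 0
    # demographics
    age_modes: tuple[float, float] = (25.0, 63.0)
    age_sds: tuple[float, float] = (6.0, 8.0)
    age_mix: float = 0.5
    age_range: tuple[float, float] = (16.0, 86.0)
    female_prop: float = 0.625
    # recording structure
    days: int = 14
    sessions_per_day: float = 6.0
    sessions_per_day_age_slope: float = 0.03
    touches_per_session_mean: float = 25.0
    # ITI mixture (log10 ms)
    iti_fast_mean: float = 2.0
    iti_slow_mean: float = 3.6
    iti_fast_sd: float = 0.25
    iti_slow_sd: float = 0.3
    fast_weight_base: float = 0.75  # at the youngest age
    fast_weight_age_slope: float = 0.0065  # decline per year
    fast_weight_clip: tuple[float, float] = (0.05, 0.95)
    # latent pace factor loadings
    pace_weight_loading: float = 0.06
    pace_slow_mean_loading: float = 0.1
    # apps
    social_apps: tuple[str, ...] = ("social_1", "social_2", "browser_1")
    other_apps: tuple[str, ...] = ("app_1", "app_2", "app_3", "app_4")
    p_social_start: float = 0.35
    app_switch_prob: float = 0.06
    # cognitive generator: per-year age slopes and baselines at the
    # youngest age (slopes follow the reported real-cohort magnitudes)
    srt_base_ms: float = 280.0
    srt_age_slope: float = 0.65
    crt_base_ms: float = 450.0
    crt_age_slope: float = 3.42
    global_cost_base: float = 0.2
    global_cost_age_slope: float = 0.001
    local_cost_base: float = 0.1
    corsi_base: float = 6.5
    corsi_age_slope: float = -0.0305
    nback_dprime_base: float = 2.8
    nback_dprime_age_slope: float = -0.018
    # planted-truth thresholding: a bin belongs to a truth region when its
    # |Δ log10 mass| over the age range is at least this fraction of the max
    truth_effect_frac: float = 0.25

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.days < 1 or self.sessions_per_day <= 0:
            raise ValueError("infeasible recording spec (zero days/sessions)")
        if self.touches_per_session_mean < 2:
            raise ValueError("touches_per_session_mean must be >= 2")
        for p in (self.female_prop, self.p_social_start, self.app_switch_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    @property
    def all_apps(self) -> tuple[str, ...]:
        return self.social_apps + self.other_apps

    def fast_weight(self, age, f=0.0):
        """Fast-component mixture weight for a given age and pace factor."""
        w = (
            self.fast_weight_base
            - self.fast_weight_age_slope * (np.asarray(age) - self.age_range[0])
            + self.pace_weight_loading * np.asarray(f)
        )
        return np.clip(w, *self.fast_weight_clip)

    def slow_mean(self, f=0.0):
        return self.iti_slow_mean - self.pace_slow_mean_loading * np.asarray(f)


@dataclass
class PlantedTruth:
    """Deterministic ground truth derived from the cohort spec.

    ``age_sign``/``factor_sign`` hold the sign of the analytic derivative
    of each bin's expected log10 mass with respect to age / pace factor;
    ``truth_mask`` marks bins whose age effect magnitude reaches the
    configured fraction of the maximum.
    """

    age_sign: np.ndarray  # (nb, nb) int in {-1, 0, +1}
    age_effect: np.ndarray  # (nb, nb) float, |Δ log10 mass| across ages
    truth_mask: np.ndarray  # (nb, nb) bool
    factor_sign: np.ndarray  # (nb, nb) int
    cognitive_slopes: dict[str, float]

    def pair_label(self, coord_i, coord_j) -> str:
        """Expected consistent/inconsistent label for a bin pair."""
        si = self.age_sign[tuple(coord_i)]
        sj = self.age_sign[tuple(coord_j)]
        fi = self.factor_sign[tuple(coord_i)]
        fj = self.factor_sign[tuple(coord_j)]
        prod = int(si) * int(sj) * int(fi) * int(fj)
        if prod == 0:
            return "undetermined"
        return "consistent" if prod > 0 else "inconsistent"

    def to_json(self, path) -> None:
        payload = {
            "age_sign": self.age_sign.tolist(),
            "age_effect": self.age_effect.tolist(),
            "truth_mask": self.truth_mask.astype(int).tolist(),
            "factor_sign": self.factor_sign.tolist(),
            "cognitive_slopes": self.cognitive_slopes,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            age_sign=np.asarray(d["age_sign"], dtype=int),
            age_effect=np.asarray(d["age_effect"], dtype=float),
            truth_mask=np.asarray(d["truth_mask"], dtype=bool),
            factor_sign=np.asarray(d["factor_sign"], dtype=int),
            cognitive_slopes=d["cognitive_slopes"],
        )


@dataclass
class CohortData:
    participants: pd.DataFrame
    events: pd.DataFrame
    episodes: pd.DataFrame
    trials: pd.DataFrame
    truth: PlantedTruth


# ---------------------------------------------------------------------------
# closed-form expected JID


def expected_jid(
    spec: CohortSpec,
    config: JIDConfig | None = None,
    age: float = 50.0,
    f: float = 0.0,
) -> np.ndarray:
    """Expected JID mass grid for a participant of given age/pace factor.

    Consecutive intervals are iid draws from the log-normal mixture, so
    the kernel-smoothed joint density factorizes into the product of two
    identical Gaussian-mixture marginals evaluated at the bin centers.
    """
    config = config or JIDConfig()
    h2 = config.kde_bandwidth**2
    c = config.bin_centers_log10
    w = float(spec.fast_weight(age, f))
    mu_s = float(spec.slow_mean(f))
    g = w * norm.pdf(c, spec.iti_fast_mean, np.sqrt(spec.iti_fast_sd**2 + h2)) + (
        1.0 - w
    ) * norm.pdf(c, mu_s, np.sqrt(spec.iti_slow_sd**2 + h2))
    masses = np.outer(g, g)
    return masses / masses.sum()


def build_truth(spec: CohortSpec, config: JIDConfig | None = None) -> PlantedTruth:
    """Derive per-bin age/factor effect signs from the analytic model."""
    config = config or JIDConfig()
    lo_age, hi_age = spec.age_range
    eps = 1e-12
    p_lo = np.log10(expected_jid(spec, config, age=lo_age) + eps)
    p_hi = np.log10(expected_jid(spec, config, age=hi_age) + eps)
    d_age = p_hi - p_lo
    mid = 0.5 * (lo_age + hi_age)
    q_lo = np.log10(expected_jid(spec, config, age=mid, f=-1.0) + eps)
    q_hi = np.log10(expected_jid(spec, config, age=mid, f=+1.0) + eps)
    d_f = q_hi - q_lo
    effect = np.abs(d_age)
    mask = effect >= spec.truth_effect_frac * effect.max()
    return PlantedTruth(
        age_sign=np.sign(d_age).astype(int),
        age_effect=effect,
        truth_mask=mask,
        factor_sign=np.sign(d_f).astype(int),
        cognitive_slopes={
            "srt": spec.srt_age_slope,
            "crt": spec.crt_age_slope,
            "global_cost": spec.global_cost_age_slope,
            "corsi": spec.corsi_age_slope,
            "nback": spec.nback_dprime_age_slope,
        },
    )


# ---------------------------------------------------------------------------
# stream generation


def _draw_ages(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    ages = np.empty(spec.n_participants)
    lo, hi = spec.age_range
    for i in range(spec.n_participants):
        while True:
            mode = 0 if rng.random() < spec.age_mix else 1
            a = rng.normal(spec.age_modes[mode], spec.age_sds[mode])
            if lo <= a <= hi:
                ages[i] = a
                break
    return ages


def _app_sequence(
    n: int, spec: CohortSpec, rng: np.random.Generator
) -> np.ndarray:
    apps = np.empty(n, dtype=object)
    pool = spec.all_apps
    if rng.random() < spec.p_social_start:
        cur = spec.social_apps[rng.integers(len(spec.social_apps))]
    else:
        cur = spec.other_apps[rng.integers(len(spec.other_apps))]
    for i in range(n):
        apps[i] = cur
        if rng.random() < spec.app_switch_prob:
            nxt = cur
            while nxt == cur:
                nxt = pool[rng.integers(len(pool))]
            cur = nxt
    return apps


def _participant_stream(
    pid: str, age: float, f: float, spec: CohortSpec, rng: np.random.Generator
):
    """Events and episodes of one participant over the recording period."""
    w = float(spec.fast_weight(age, f))
    mu_s = float(spec.slow_mean(f))
    rate = max(
        spec.sessions_per_day
        - spec.sessions_per_day_age_slope * (age - spec.age_range[0]),
        0.5,
    )
    ev_ts: list[np.ndarray] = []
    ev_apps: list[np.ndarray] = []
    episodes: list[tuple[int, int]] = []
    for day in range(spec.days):
        n_sess = max(int(rng.poisson(rate)), 1 if day in (0, spec.days - 1) else 0)
        if day == 0:
            # anchor the first session near the period start so the
            # recording span reliably covers the requested number of days
            t = BASE_EPOCH_MS + int(rng.uniform(0, 600_000))
        elif day == spec.days - 1:
            t = (
                BASE_EPOCH_MS
                + day * MS_PER_DAY
                + MS_PER_DAY
                - int(rng.uniform(1_800_000, 3_600_000))
            )
        else:
            t = BASE_EPOCH_MS + day * MS_PER_DAY + int(rng.uniform(0, 2 * 3_600_000))
        for _ in range(n_sess):
            n_touch = 2 + int(rng.poisson(spec.touches_per_session_mean - 2))
            comp = rng.random(n_touch - 1) < w
            logs = np.where(
                comp,
                rng.normal(spec.iti_fast_mean, spec.iti_fast_sd, n_touch - 1),
                rng.normal(mu_s, spec.iti_slow_sd, n_touch - 1),
            )
            itis = np.maximum(np.round(10.0**logs), 1.0).astype(np.int64)
            ts = t + np.concatenate([[0], np.cumsum(itis)])
            ev_ts.append(ts)
            ev_apps.append(_app_sequence(n_touch, spec, rng))
            episodes.append((int(ts[0] - 10), int(ts[-1] + 10)))
            # next session starts after a clear off-screen gap
            t = int(ts[-1]) + int(rng.exponential(900_000)) + 120_000
    ts_all = np.concatenate(ev_ts)
    apps_all = np.concatenate(ev_apps)
    events = pd.DataFrame(
        {
            "participant_id": pid,
            "timestamp_ms": ts_all,
            "app_id": apps_all,
        }
    )
    eps = pd.DataFrame(episodes, columns=["on_ms", "off_ms"])
    eps.insert(0, "participant_id", pid)
    return events, eps


# ---------------------------------------------------------------------------
# cognitive trial generation


def _rt_trials(
    pid, task, n, mean, sd, rng, p_correct=0.97, test_day=None
) -> pd.DataFrame:
    rt = np.maximum(rng.normal(mean, sd, n), 150.0)
    return pd.DataFrame(
        {
            "participant_id": pid,
            "task": task,
            "trial_index": np.arange(n),
            "rt_ms": rt,
            "correct": rng.random(n) < p_correct,
            "block_type": "none",
            "is_switch_trial": False,
            "sequence_length": 0,
            "is_target": False,
            "responded": True,
            "test_day": test_day,
        }
    )


def _switch_trials(pid, age, spec, rng, test_day) -> pd.DataFrame:
    pure_mean = 500.0 + 2.0 * (age - spec.age_range[0])
    g = spec.global_cost_base + spec.global_cost_age_slope * (age - spec.age_range[0])
    l = spec.local_cost_base
    frames = []
    idx = 0
    for block, n in (("pure_shape", 20), ("pure_color", 20)):
        rt = np.maximum(rng.normal(pure_mean, 60.0, n), 150.0)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "task": "switch",
                    "trial_index": np.arange(idx, idx + n),
                    "rt_ms": rt,
                    "correct": rng.random(n) < 0.95,
                    "block_type": block,
                    "is_switch_trial": False,
                    "sequence_length": 0,
                    "is_target": False,
                    "responded": True,
                    "test_day": test_day,
                }
            )
        )
        idx += n
    n = 100
    is_switch = rng.random(n) < 0.5
    ns_mean = pure_mean * (1.0 + g)
    rt = np.where(
        is_switch,
        rng.normal(ns_mean * (1.0 + l), 70.0, n),
        rng.normal(ns_mean, 70.0, n),
    )
    frames.append(
        pd.DataFrame(
            {
                "participant_id": pid,
                "task": "switch",
                "trial_index": np.arange(idx, idx + n),
                "rt_ms": np.maximum(rt, 150.0),
                "correct": rng.random(n) < 0.93,
                "block_type": "mixed",
                "is_switch_trial": is_switch,
                "sequence_length": 0,
                "is_target": False,
                "responded": True,
                "test_day": test_day,
            }
        )
    )
    return pd.concat(frames, ignore_index=True)


def _corsi_trials(pid, age, spec, rng, test_day) -> pd.DataFrame:
    span = int(
        np.clip(
            round(
                spec.corsi_base
                + spec.corsi_age_slope * (age - spec.age_range[0])
                + rng.normal(0.0, 0.8)
            ),
            1,
            9,
        )
    )
    rows = []
    idx = 0
    for length in range(2, 10):
        if length <= span:
            rows.append((length, True))
            idx += 1
        else:
            rows.append((length, False))
            rows.append((length, False))
            break
    df = pd.DataFrame(rows, columns=["sequence_length", "correct"])
    df.insert(0, "participant_id", pid)
    df.insert(1, "task", "corsi")
    df.insert(2, "trial_index", np.arange(len(df)))
    df["rt_ms"] = np.nan
    df["block_type"] = "none"
    df["is_switch_trial"] = False
    df["is_target"] = False
    df["responded"] = True
    df["test_day"] = test_day
    return df


def _nback_trials(pid, age, spec, rng, test_day) -> pd.DataFrame:
    n = 90
    d = float(
        np.clip(
            spec.nback_dprime_base
            + spec.nback_dprime_age_slope * (age - spec.age_range[0])
            + rng.normal(0.0, 0.3),
            0.2,
            5.0,
        )
    )
    is_target = rng.random(n) < 1.0 / 3.0
    p_resp = np.where(is_target, norm.cdf(d / 2.0), norm.cdf(-d / 2.0))
    responded = rng.random(n) < p_resp
    return pd.DataFrame(
        {
            "participant_id": pid,
            "task": "nback",
            "trial_index": np.arange(n),
            "rt_ms": np.where(responded, rng.normal(520.0, 80.0, n), np.nan),
            "correct": responded == is_target,
            "block_type": "none",
            "is_switch_trial": False,
            "sequence_length": 0,
            "is_target": is_target,
            "responded": responded,
            "test_day": test_day,
        }
    )


# ---------------------------------------------------------------------------
# cohort assembly


def generate_cohort(spec: CohortSpec) -> CohortData:
    """Generate a deterministic synthetic cohort from a single seed."""
    rng = np.random.default_rng(spec.seed)
    ages = _draw_ages(spec, rng)
    genders = np.where(rng.random(spec.n_participants) < spec.female_prop, 2, 1)
    pace = rng.standard_normal(spec.n_participants)

    lo = spec.age_range[0]
    thumb = np.clip(
        0.9 - 0.004 * (ages - lo) + rng.normal(0, 0.1, ages.size), 0.0, 1.0
    )
    dual = np.clip(
        0.7 - 0.005 * (ages - lo) + rng.normal(0, 0.15, ages.size), 0.0, 1.0
    )
    years = np.clip(12.0 - 0.05 * (ages - lo) + rng.normal(0, 2.0, ages.size), 0.5, 25.0)
    screen = np.clip(rng.normal(5.5, 0.5, ages.size), 4.0, 7.0)

    test_date = (
        date(2021, 1, 4) + timedelta(days=spec.days // 2)
    ).isoformat()

    pids = [f"P{i:04d}" for i in range(spec.n_participants)]
    ev_frames, ep_frames, trial_frames = [], [], []
    for i, pid in enumerate(pids):
        ev, ep = _participant_stream(pid, ages[i], pace[i], spec, rng)
        ev_frames.append(ev)
        ep_frames.append(ep)
        a = ages[i]
        trial_frames.append(
            _rt_trials(
                pid, "srt", 25,
                spec.srt_base_ms + spec.srt_age_slope * (a - lo) + rng.normal(0, 15),
                40.0, rng, test_day=test_date,
            )
        )
        trial_frames.append(
            _rt_trials(
                pid, "crt", 50,
                spec.crt_base_ms + spec.crt_age_slope * (a - lo) + rng.normal(0, 20),
                60.0, rng, test_day=test_date,
            )
        )
        trial_frames.append(_switch_trials(pid, a, spec, rng, test_date))
        trial_frames.append(_corsi_trials(pid, a, spec, rng, test_date))
        trial_frames.append(_nback_trials(pid, a, spec, rng, test_date))

    participants = pd.DataFrame(
        {
            "participant_id": pids,
            "age_years": ages,
            "gender": genders,
            "thumb_pref": thumb,
            "dual_thumb_pref": dual,
            "years_smartphone": years,
            "screen_size_inch": screen,
        }
    )
    return CohortData(
        participants=participants,
        events=pd.concat(ev_frames, ignore_index=True),
        episodes=pd.concat(ep_frames, ignore_index=True),
        trials=pd.concat(trial_frames, ignore_index=True),
        truth=build_truth(spec),
    )


def worked_example_stream() -> tuple[pd.DataFrame, pd.DataFrame]:
    """A fixed six-touch single-session stream (5 ITIs, 4 joint pairs)."""
    ts = np.array([0, 120, 380, 900, 4900, 5020], dtype=np.int64) + BASE_EPOCH_MS
    events = pd.DataFrame(
        {
            "participant_id": "demo",
            "timestamp_ms": ts,
            "app_id": "app_1",
        }
    )
    episodes = pd.DataFrame(
        {
            "participant_id": ["demo"],
            "on_ms": [int(ts[0] - 10)],
            "off_ms": [int(ts[-1] + 10)],
        }
    )
    return events, episodes


def write_cohort(data: CohortData, outdir) -> None:
    """Write events/episodes/participants/trials CSVs and truth.json."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    data.events.to_csv(out / "events.csv", index=False)
    data.episodes.to_csv(out / "episodes.csv", index=False)
    data.participants.to_csv(out / "participants.csv", index=False)
    data.trials.to_csv(out / "trials.csv", index=False)
    data.truth.to_json(out / "truth.json")
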