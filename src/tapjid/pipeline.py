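"""Pipeline orchestration: cohort filtering, JID construction, the three
analyses (age maps, cognitive maps, residual pairs) and artifact output.

Every artifact bundle embeds the serialized run configuration, its hash,
the seed and the package version, so reruns with identical configuration
are reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aging_residuals import ResidualMatrix, classify_pairs, two_step_residuals
from .binwise_glm import (
    BinStatsMap,
    ClusterResult,
    build_response,
    cluster_correct,
    make_design,
    mass_univariate,
)
from .cog_scores import compute_scores
from .event_store import (
    extract_itis,
    filter_cohort,
    load_episodes,
    load_events,
    load_participants,
    segment_sessions,
    window_around_test,
)
from .jid_core import EmptyJIDError, JIDConfig, compute_jid, select_pairs

__all__ = [
    "RunConfig",
    "CohortTooSmallError",
    "EmptyAnalysisError",
    "TASK_SCORE_COLUMNS",
    "build_cohort_jids",
    "age_analysis",
    "cognitive_analysis",
    "residual_analysis",
    "run_age_analysis",
    "run_cognitive_analysis",
    "run_residual_analysis",
    "run_all",
]

log = logging.getLogger("tapjid")

#: maps a task name to (score column, validity column) in the scores table
TASK_SCORE_COLUMNS = {
    "srt": ("srt_median_ms", "srt_valid"),
    "crt": ("crt_median_ms", "crt_valid"),
    "global_cost": ("global_cost", "global_cost_valid"),
    "local_cost": ("local_cost", "local_cost_valid"),
    "corsi": ("corsi_span", "corsi_valid"),
    "nback": ("nback_dprime", "nback_valid"),
}


class CohortTooSmallError(ValueError):
    """Fewer participants than the minimum-n guard allows."""


class EmptyAnalysisError(RuntimeError):
    """No participant satisfies the analysis prerequisites."""


@dataclass
class RunConfig:
    data_dir: str = "."
    out_dir: str = "runs"
    variant: str = "full"
    social_apps: tuple[str, ...] = ("social_1", "social_2", "browser_1")
    n_bins_per_dim: int = 50
    log10_range_ms: tuple[float, float] = (0.5, 5.0)
    kde_bandwidth: float = 0.1
    n_boot: int = 1000
    cluster_alpha: float = 0.05
    cluster_p: float = 0.05
    fdr_alpha: float = 0.001
    connectivity: int = 8
    seed: int = 0
    min_n: int = 20
    min_days: float = 7.0
    min_interactions: int = 100
    window_days: int = 10
    pair_min_dist: int = 5
    pair_r2_min: float = 0.1
    utc_offset_hours: float = 0.0

    def jid_config(self, variant: str | None = None) -> JIDConfig:
        return JIDConfig(
            n_bins_per_dim=self.n_bins_per_dim,
            log10_range_ms=tuple(self.log10_range_ms),
            kde_bandwidth=self.kde_bandwidth,
            variant=variant or self.variant,
            social_app_ids=frozenset(self.social_apps),
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["social_apps"] = list(self.social_apps)
        d["log10_range_ms"] = list(self.log10_range_ms)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "social_apps" in raw:
            raw["social_apps"] = tuple(raw["social_apps"])
        if "log10_range_ms" in raw:
            raw["log10_range_ms"] = tuple(raw["log10_range_ms"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# stage helpers (in-memory API used by tests and the runners)


def build_cohort_jids(
    events: pd.DataFrame,
    episodes: pd.DataFrame,
    config: JIDConfig,
    participant_ids=None,
) -> tuple[list[str], np.ndarray, dict]:
    """Per-participant JID feature matrix.

    Returns (ids, masses (n × bins²), audit).  Participants without a
    single eligible interval pair are excluded and listed in the audit.
    """
    sessions = segment_sessions(events, episodes)
    by_pid: dict[str, list] = {}
    for s in sessions:
        by_pid.setdefault(s.participant_id, []).append(s)
    if participant_ids is None:
        participant_ids = sorted(by_pid)
    ids, rows, excluded = [], [], []
    for pid in participant_ids:
        seqs = [extract_itis(s) for s in by_pid.get(pid, [])]
        pairs = select_pairs(seqs, config)
        try:
            grid = compute_jid(pairs, config) if len(pairs) else None
        except EmptyJIDError:
            grid = None
        if grid is None:
            excluded.append(pid)
            continue
        ids.append(pid)
        rows.append(grid.feature_vector())
    audit = {
        "n_requested": len(participant_ids),
        "n_with_jid": len(ids),
        "excluded_no_pairs": excluded,
        "n_touches_dropped_outside_episodes": sessions.n_dropped,
    }
    if not rows:
        raise EmptyAnalysisError("no participant yielded any interval pair")
    return ids, np.vstack(rows), audit


def _guard_min_n(n: int, min_n: int) -> None:
    if n < min_n:
        raise CohortTooSmallError(
            f"only {n} participants available; minimum is {min_n}"
        )


@dataclass
class AnalysisResult:
    """Stats + cluster correction for one model, with its inputs kept for
    downstream residual analysis."""

    ids: list[str]
    response: np.ndarray
    X: np.ndarray
    names: list[str]
    predictor: str
    stats: BinStatsMap
    clusters: ClusterResult
    audit: dict = field(default_factory=dict)


def age_analysis(
    participants: pd.DataFrame,
    events: pd.DataFrame,
    episodes: pd.DataFrame,
    cfg: RunConfig,
    extended: bool = False,
) -> AnalysisResult:
    """Bin-wise regression of the JID on age + gender (+ covariates)."""
    kept, filter_audit = filter_cohort(
        events, min_days=cfg.min_days, min_interactions=cfg.min_interactions
    )
    ids, M, jid_audit = build_cohort_jids(
        events[events["participant_id"].isin(kept)],
        episodes,
        cfg.jid_config(),
        participant_ids=kept,
    )
    meta = participants.set_index("participant_id").loc[ids]
    cols = {"age": meta["age_years"].to_numpy(), "gender": meta["gender"].to_numpy()}
    if extended:
        from .jid_core import usage_per_day

        ev_by_pid = dict(tuple(events.groupby("participant_id")))
        cols["usage"] = np.array(
            [usage_per_day(ev_by_pid[p], cfg.utc_offset_hours) for p in ids]
        )
        for col, name in (
            ("thumb_pref", "thumb_pref"),
            ("years_smartphone", "years"),
            ("dual_thumb_pref", "dual_thumb_pref"),
            ("screen_size_inch", "screen_size"),
        ):
            cols[name] = meta[col].to_numpy()
    keep = np.all(np.isfinite(np.column_stack(list(cols.values()))), axis=1)
    ids = [p for p, k in zip(ids, keep) if k]
    M = M[keep]
    cols = {k: v[keep] for k, v in cols.items()}
    _guard_min_n(len(ids), cfg.min_n)
    Y = build_response(M, already_stacked=True)
    X, names = make_design(cols)
    stats = mass_univariate(Y, X, names)
    clusters = cluster_correct(
        stats,
        Y,
        X,
        "age",
        n_boot=cfg.n_boot,
        alpha=cfg.cluster_alpha,
        cluster_p=cfg.cluster_p,
        connectivity=cfg.connectivity,
        seed=cfg.seed,
    )
    log.info(
        "age analysis: n=%d, %d cluster(s), %d significant",
        len(ids),
        len(clusters.clusters),
        clusters.n_significant,
    )
    return AnalysisResult(
        ids, Y, X, names, "age", stats, clusters,
        audit={"filter": filter_audit.to_dict("records"), **jid_audit},
    )


def cognitive_analysis(
    participants: pd.DataFrame,
    events: pd.DataFrame,
    episodes: pd.DataFrame,
    trials: pd.DataFrame,
    task: str,
    cfg: RunConfig,
) -> AnalysisResult:
    """Bin-wise regression of test-window JIDs on a cognitive score + gender."""
    if task not in TASK_SCORE_COLUMNS:
        raise ValueError(
            f"unknown task {task!r}; expected one of {sorted(TASK_SCORE_COLUMNS)}"
        )
    score_col, valid_col = TASK_SCORE_COLUMNS[task]
    scores = compute_scores(trials).set_index("participant_id")
    kept, _ = filter_cohort(
        events, min_days=cfg.min_days, min_interactions=cfg.min_interactions
    )
    day_col_task = "switch" if task in ("global_cost", "local_cost") else task
    day_col = f"{day_col_task}_test_day"
    excluded = {"invalid_score": [], "no_window_data": []}
    rows, ids, score_vals, gender_vals = [], [], [], []
    meta = participants.set_index("participant_id")
    config = cfg.jid_config()
    for pid in kept:
        if pid not in scores.index or not bool(scores.loc[pid, valid_col]):
            excluded["invalid_score"].append(pid)
            continue
        value = scores.loc[pid, score_col]
        if not np.isfinite(value):
            excluded["invalid_score"].append(pid)
            continue
        test_day = scores.loc[pid].get(day_col) if day_col in scores.columns else None
        ev = events[events["participant_id"] == pid]
        if test_day is not None and isinstance(test_day, str):
            ev = window_around_test(ev, test_day, window_days=cfg.window_days)
        if len(ev) == 0:
            excluded["no_window_data"].append(pid)
            continue
        try:
            _, M, _ = build_cohort_jids(ev, episodes, config, participant_ids=[pid])
        except EmptyAnalysisError:
            excluded["no_window_data"].append(pid)
            continue
        ids.append(pid)
        rows.append(M[0])
        score_vals.append(float(value))
        gender_vals.append(float(meta.loc[pid, "gender"]))
    if not ids:
        raise EmptyAnalysisError(f"no participant eligible for task {task!r}")
    _guard_min_n(len(ids), cfg.min_n)
    Y = build_response(np.vstack(rows), already_stacked=True)
    X, names = make_design(
        {"score": np.asarray(score_vals), "gender": np.asarray(gender_vals)}
    )
    stats = mass_univariate(Y, X, names)
    clusters = cluster_correct(
        stats,
        Y,
        X,
        "score",
        n_boot=cfg.n_boot,
        alpha=cfg.cluster_alpha,
        cluster_p=cfg.cluster_p,
        connectivity=cfg.connectivity,
        seed=cfg.seed,
    )
    return AnalysisResult(
        ids, Y, X, names, "score", stats, clusters, audit={"excluded": excluded}
    )


def residual_analysis(
    age_result: AnalysisResult, cfg: RunConfig
) -> tuple[ResidualMatrix, pd.DataFrame]:
    """Two-step residualization + pairwise consistency classification."""
    gender = age_result.X[:, age_result.names.index("gender")]
    age = age_result.X[:, age_result.names.index("age")]
    res = two_step_residuals(
        age_result.response, gender, age, age_result.clusters.sig_mask
    )
    if res.n_bins < 2:
        return res, pd.DataFrame(
            columns=[
                "bin_i_row", "bin_i_col", "bin_j_row", "bin_j_col",
                "distance", "r", "r2", "p", "fdr_pass", "retained", "label",
            ]
        )
    pairs = classify_pairs(
        res,
        min_dist=cfg.pair_min_dist,
        r2_min=cfg.pair_r2_min,
        alpha=cfg.fdr_alpha,
    )
    return res, pairs


# ---------------------------------------------------------------------------
# file-based runners


def _load_inputs(cfg: RunConfig):
    d = Path(cfg.data_dir)
    participants = load_participants(d / "participants.csv")
    events = load_events(d / "events.csv")
    episodes = load_episodes(d / "episodes.csv")
    trials_path = d / "trials.csv"
    trials = pd.read_csv(trials_path) if trials_path.exists() else None
    return participants, events, episodes, trials


def _write_manifest(outdir: Path, cfg: RunConfig, extra: dict) -> None:
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "version": __version__,
        **extra,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def _write_stats(outdir: Path, result: AnalysisResult, model: str) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for pname in result.names:
        for stat in ("beta", "t", "p"):
            np.savetxt(
                outdir / f"{model}_{pname}_{stat}.csv",
                result.stats.map(pname, stat),
                delimiter=",",
            )
    np.savetxt(outdir / f"{model}_r2.csv", result.stats.r2, delimiter=",")
    clusters = [
        {
            "bins": c.bins.tolist(),
            "mass": c.mass,
            "p_corrected": c.p_corrected,
            "significant": c.significant,
        }
        for c in result.clusters.clusters
    ]
    with open(outdir / f"clusters_{model}.json", "w") as fh:
        json.dump(
            {
                "clusters": clusters,
                "mass_threshold": result.clusters.mass_threshold,
                "n_boot": result.clusters.n_boot,
                "alpha": result.clusters.alpha,
                "cluster_p": result.clusters.cluster_p,
                "seed": result.clusters.seed,
            },
            fh,
            indent=1,
        )


def run_age_analysis(cfg: RunConfig) -> AnalysisResult:
    participants, events, episodes, _ = _load_inputs(cfg)
    result = age_analysis(participants, events, episodes, cfg)
    outdir = Path(cfg.out_dir) / "age"
    _write_stats(outdir, result, "age")
    _write_manifest(outdir, cfg, {"n_participants": len(result.ids)})
    return result


def run_cognitive_analysis(cfg: RunConfig, task: str) -> AnalysisResult:
    participants, events, episodes, trials = _load_inputs(cfg)
    if trials is None:
        raise FileNotFoundError("trials.csv not found in data_dir")
    result = cognitive_analysis(participants, events, episodes, trials, task, cfg)
    outdir = Path(cfg.out_dir) / f"cognitive_{task}"
    _write_stats(outdir, result, task)
    _write_manifest(outdir, cfg, {"n_participants": len(result.ids)})
    return result


def run_residual_analysis(
    cfg: RunConfig, age_result: AnalysisResult | None = None
) -> pd.DataFrame:
    if age_result is None:
        age_result = run_age_analysis(cfg)
    res, pairs = residual_analysis(age_result, cfg)
    outdir = Path(cfg.out_dir) / "residuals"
    outdir.mkdir(parents=True, exist_ok=True)
    pairs.to_csv(outdir / "residual_pairs.csv", index=False)
    # per-bin max-R² summary maps for each label
    nb = age_result.clusters.sig_mask.shape[0]
    for label in ("consistent", "inconsistent"):
        grid = np.zeros((nb, nb))
        sub = pairs[pairs["label"] == label]
        for _, row in sub.iterrows():
            for r, c in (
                (int(row["bin_i_row"]), int(row["bin_i_col"])),
                (int(row["bin_j_row"]), int(row["bin_j_col"])),
            ):
                grid[r, c] = max(grid[r, c], row["r2"])
        np.savetxt(outdir / f"max_r2_{label}.csv", grid, delimiter=",")
    _write_manifest(outdir, cfg, {"n_pairs": int(len(pairs))})
    return pairs


def run_all(cfg: RunConfig, tasks: tuple[str, ...] = ("crt",)) -> dict:
    """Execute the three analyses and return their results keyed by name."""
    results: dict[str, object] = {}
    age_result = run_age_analysis(cfg)
    results["age"] = age_result
    for task in tasks:
        try:
            results[f"cognitive_{task}"] = run_cognitive_analysis(cfg, task)
        except EmptyAnalysisError as exc:
            log.warning("cognitive analysis %s skipped: %s", task, exc)
            results[f"cognitive_{task}"] = None
    results["residual_pairs"] = run_residual_analysis(cfg, age_result)
    return results
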