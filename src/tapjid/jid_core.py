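"""Joint-interval distributions (JIDs) on the fixed log10 grid.

A JID is the 2-D probability mass of consecutive inter-touch-interval
pairs (k, k+1), estimated with an isotropic Gaussian KDE (bandwidth 0.1 in
log10 units) on log10-transformed intervals and discretized on a 50×50
grid spanning 10^0.5–10^5 ms.  Three variants are supported: *full* (all
within-session pairs), *social* (pairs whose bounding touches are all on
configured social/browser apps) and *transition* (pairs of app-switching
intervals).

The KDE is evaluated at bin centers, converted to bin masses by the bin
area, and renormalized to sum to one, so the grid is a proper probability
mass function regardless of kernel mass falling outside the range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .event_store import MS_PER_DAY, ITISequence

__all__ = [
    "JIDConfig",
    "JIDGrid",
    "EmptyJIDError",
    "select_pairs",
    "compute_jid",
    "jid_entropy",
    "usage_per_day",
    "write_jid",
    "read_jid",
]

VARIANTS = ("full", "social", "transition")


class EmptyJIDError(ValueError):
    """No interval pairs (or no in-range kernel mass) to build a JID from."""


@dataclass(frozen=True)
class JIDConfig:
    """Grid and kernel configuration shared across a population."""

    n_bins_per_dim: int = 50
    log10_range_ms: tuple[float, float] = (0.5, 5.0)
    kde_bandwidth: float = 0.1
    variant: str = "full"
    social_app_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.n_bins_per_dim < 2:
            raise ValueError("n_bins_per_dim must be >= 2")
        lo, hi = self.log10_range_ms
        if not lo < hi:
            raise ValueError("log10_range_ms must be (lower, upper)")
        if self.kde_bandwidth <= 0:
            raise ValueError("kde_bandwidth must be > 0")
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )
        object.__setattr__(
            self, "social_app_ids", frozenset(self.social_app_ids)
        )

    @property
    def bin_edges_log10(self) -> np.ndarray:
        lo, hi = self.log10_range_ms
        return np.linspace(lo, hi, self.n_bins_per_dim + 1)

    @property
    def bin_centers_log10(self) -> np.ndarray:
        e = self.bin_edges_log10
        return 0.5 * (e[:-1] + e[1:])

    @property
    def bin_area_log10(self) -> float:
        lo, hi = self.log10_range_ms
        w = (hi - lo) / self.n_bins_per_dim
        return w * w

    @property
    def n_features(self) -> int:
        return self.n_bins_per_dim**2


@dataclass
class JIDGrid:
    """Discretized joint-interval distribution.

    ``masses[i, j]`` is the probability mass of (k in bin i, k+1 in bin j);
    rows index the leading interval k.
    """

    masses: np.ndarray
    bin_edges_log10: np.ndarray
    n_pairs_used: int
    variant: str
    config: JIDConfig

    @property
    def shape(self) -> tuple[int, int]:
        return self.masses.shape  # type: ignore[return-value]

    def feature_vector(self) -> np.ndarray:
        """Flatten to the 2500-long feature vector (k-bin major)."""
        return self.masses.ravel()

    def validate(self) -> None:
        if self.masses.shape != (self.config.n_bins_per_dim,) * 2:
            raise ValueError("grid shape does not match config")
        if np.any(self.masses < 0):
            raise ValueError("negative mass")
        if self.n_pairs_used >= 1 and abs(self.masses.sum() - 1.0) > 1e-9:
            raise ValueError("JID masses must sum to 1")


def select_pairs(
    sequences: Iterable[ITISequence], config: JIDConfig
) -> np.ndarray:
    """Collect consecutive (k, k+1) interval pairs for the configured variant.

    Returns an (n_pairs, 2) float array of intervals in ms.  Pairs never
    span sessions.

    * ``full`` — all consecutive pairs within a session.
    * ``social`` — pairs where all three bounding touches are on apps in
      ``config.social_app_ids``.
    * ``transition`` — the per-session sub-sequence of intervals whose
      bounding touches differ in app, re-paired consecutively.
    """
    social = config.social_app_ids
    out: list[np.ndarray] = []
    for seq in sequences:
        iv = np.asarray(seq.intervals_ms, dtype=float)
        if config.variant == "transition":
            tmask = seq.lead_apps != seq.trail_apps
            iv = iv[tmask]
            if iv.size >= 2:
                out.append(np.column_stack([iv[:-1], iv[1:]]))
            continue
        if iv.size < 2:
            continue
        pairs = np.column_stack([iv[:-1], iv[1:]])
        if config.variant == "social":
            in_social = np.isin(seq.lead_apps, list(social)) if social else np.zeros(
                iv.size, dtype=bool
            )
            trail_social = np.isin(seq.trail_apps, list(social)) if social else np.zeros(
                iv.size, dtype=bool
            )
            # touches bounding pair i are touches i, i+1, i+2
            keep = in_social[:-1] & trail_social[:-1] & trail_social[1:]
            pairs = pairs[keep]
        if pairs.size:
            out.append(pairs)
    if not out:
        return np.empty((0, 2), dtype=float)
    return np.vstack(out)


def compute_jid(pairs: np.ndarray, config: JIDConfig) -> JIDGrid:
    """Gaussian-KDE joint-interval distribution on the configured grid.

    Coordinates are log10(ms).  The isotropic kernel factorizes, so the
    kernel sum at every bin center is the product of the per-axis Gaussian
    profiles; the result equals the brute-force per-center kernel sum to
    floating-point accuracy.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array of intervals in ms")
    if pairs.shape[0] == 0:
        raise EmptyJIDError("cannot build a JID from zero interval pairs")
    if np.any(pairs <= 0):
        raise ValueError("intervals must be positive")
    h = config.kde_bandwidth
    centers = config.bin_centers_log10
    # aggregate duplicate pairs into normalized weights so the grid is
    # bit-identical under duplication of the whole pair set
    uniq, counts = np.unique(pairs, axis=0, return_counts=True)
    weights = counts / counts.sum()
    logs = np.log10(uniq)
    gx = np.exp(-0.5 * ((centers[None, :] - logs[:, 0:1]) / h) ** 2)
    gy = np.exp(-0.5 * ((centers[None, :] - logs[:, 1:2]) / h) ** 2)
    density = gx.T @ (weights[:, None] * gy) / (2.0 * np.pi * h * h)
    masses = density * config.bin_area_log10
    total = masses.sum()
    if total <= 0:
        raise EmptyJIDError("no kernel mass falls inside the grid range")
    masses /= total
    grid = JIDGrid(
        masses=masses,
        bin_edges_log10=config.bin_edges_log10,
        n_pairs_used=int(pairs.shape[0]),
        variant=config.variant,
        config=config,
    )
    grid.validate()
    return grid


def jid_entropy(grid: JIDGrid) -> float:
    """Shannon entropy of the JID in bits, over bins with positive mass."""
    if abs(grid.masses.sum() - 1.0) > 1e-9:
        raise ValueError("grid is not normalized")
    p = grid.masses[grid.masses > 0]
    return float(-(p * np.log2(p)).sum())


def usage_per_day(events: pd.DataFrame, utc_offset_hours: float = 0.0) -> float:
    """log10 of the median daily touch count, zero-touch days excluded.

    Days are calendar 24-h periods in a fixed timezone (default UTC).
    """
    if len(events) == 0:
        raise ValueError("no events")
    shift = int(utc_offset_hours * 3_600_000)
    days = (events["timestamp_ms"].to_numpy(dtype=np.int64) + shift) // MS_PER_DAY
    counts = pd.Series(days).value_counts()
    return float(np.log10(counts.median()))


def write_jid(grid: JIDGrid, csv_path, sidecar_path=None) -> None:
    """Write masses as a bare 50×50 CSV plus a JSON sidecar of metadata."""
    np.savetxt(csv_path, grid.masses, delimiter=",")
    if sidecar_path is None:
        sidecar_path = str(csv_path) + ".json"
    meta = {
        "bin_edges_log10": grid.bin_edges_log10.tolist(),
        "kde_bandwidth": grid.config.kde_bandwidth,
        "n_pairs_used": grid.n_pairs_used,
        "variant": grid.variant,
        "n_bins_per_dim": grid.config.n_bins_per_dim,
        "log10_range_ms": list(grid.config.log10_range_ms),
        "social_app_ids": sorted(grid.config.social_app_ids),
    }
    with open(sidecar_path, "w") as fh:
        json.dump(meta, fh, indent=1)


def read_jid(csv_path, sidecar_path=None) -> JIDGrid:
    if sidecar_path is None:
        sidecar_path = str(csv_path) + ".json"
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    config = JIDConfig(
        n_bins_per_dim=meta["n_bins_per_dim"],
        log10_range_ms=tuple(meta["log10_range_ms"]),
        kde_bandwidth=meta["kde_bandwidth"],
        variant=meta["variant"],
        social_app_ids=frozenset(meta["social_app_ids"]),
    )
    masses = np.loadtxt(csv_path, delimiter=",")
    return JIDGrid(
        masses=masses,
        bin_edges_log10=np.asarray(meta["bin_edges_log10"], dtype=float),
        n_pairs_used=meta["n_pairs_used"],
        variant=meta["variant"],
        config=config,
    )
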