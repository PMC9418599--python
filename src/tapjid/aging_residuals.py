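"""Residual-based pace-of-aging analysis.

Bin responses inside the cluster-corrected significant mask are
residualized in two steps — gender first, then age — and the remaining
per-participant residuals are correlated across all bin pairs further
apart than 5 bins.  Pairs with R² > 0.1 surviving BH-FDR (α = 0.001) are
labeled *consistent* when the correlation sign times the two age-slope
signs is positive (accelerated aging in one bin predicts accelerated
aging in the other) and *inconsistent* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .binwise_glm import fdr_correct

__all__ = ["ResidualMatrix", "two_step_residuals", "classify_pairs"]


@dataclass
class ResidualMatrix:
    """Age-regression residuals restricted to significant bins.

    ``residuals`` is participants × bins; ``slope_sign[j]`` is the sign of
    the step-2 age slope of bin j; ``coords[j]`` its (row, col) grid index.
    """

    residuals: np.ndarray
    slope_sign: np.ndarray
    coords: np.ndarray  # (m, 2) int
    slopes: np.ndarray | None = None  # raw step-2 age slopes, if available

    @property
    def n_bins(self) -> int:
        return int(self.coords.shape[0])


def _residualize(Y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS residuals of each column of Y on [1, x]; returns (resid, slopes)."""
    X = np.column_stack([np.ones_like(x, dtype=float), np.asarray(x, dtype=float)])
    beta = np.linalg.lstsq(X, Y, rcond=None)[0]
    return Y - X @ beta, beta[1]


def two_step_residuals(
    Y: np.ndarray,
    gender: np.ndarray,
    age: np.ndarray,
    sig_mask: np.ndarray,
) -> ResidualMatrix:
    """Gender-then-age residualization of the masked response columns."""
    Y = np.asarray(Y, dtype=float)
    sig_mask = np.asarray(sig_mask, dtype=bool)
    coords = np.argwhere(sig_mask)
    if coords.size == 0:
        return ResidualMatrix(
            residuals=np.empty((Y.shape[0], 0)),
            slope_sign=np.empty(0, dtype=int),
            coords=coords,
            slopes=np.empty(0),
        )
    nb = sig_mask.shape[0]
    flat_idx = coords[:, 0] * nb + coords[:, 1]
    Ysub = Y[:, flat_idx]
    step1, _ = _residualize(Ysub, np.asarray(gender, dtype=float))
    step2, slopes = _residualize(step1, np.asarray(age, dtype=float))
    return ResidualMatrix(
        residuals=step2,
        slope_sign=np.sign(slopes).astype(int),
        coords=coords,
        slopes=slopes,
    )


def classify_pairs(
    res: ResidualMatrix,
    min_dist: int = 5,
    r2_min: float = 0.1,
    alpha: float = 0.001,
    metric: str = "chebyshev",
) -> pd.DataFrame:
    """Correlate age residuals across distant bin pairs and label them.

    All pairs with bin distance strictly greater than ``min_dist`` are
    tested; BH-FDR at ``alpha`` runs over that whole candidate set.  A
    pair is retained (``retained`` column) when it passes FDR *and* has
    R² > ``r2_min``; only retained pairs get a label.  The label is the
    sign of corr(i, j) × slope_sign(i) × slope_sign(j): +1 → consistent,
    −1 → inconsistent.
    """
    m = res.n_bins
    cols = [
        "bin_i_row",
        "bin_i_col",
        "bin_j_row",
        "bin_j_col",
        "distance",
        "r",
        "r2",
        "p",
        "fdr_pass",
        "retained",
        "label",
    ]
    if m < 2:
        return pd.DataFrame(columns=cols)
    n = res.residuals.shape[0]
    if n < 4:
        raise ValueError("need at least 4 participants for a correlation test")
    coords = res.coords.astype(float)
    diff = np.abs(coords[:, None, :] - coords[None, :, :])
    if metric == "chebyshev":
        dist = diff.max(axis=2)
    elif metric == "euclidean":
        dist = np.sqrt((diff**2).sum(axis=2))
    else:
        raise ValueError("metric must be 'chebyshev' or 'euclidean'")
    iu, ju = np.triu_indices(m, k=1)
    far = dist[iu, ju] > min_dist
    iu, ju = iu[far], ju[far]
    if iu.size == 0:
        return pd.DataFrame(columns=cols)
    C = np.corrcoef(res.residuals, rowvar=False)
    r = np.clip(C[iu, ju], -1.0, 1.0)
    r2 = r**2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r2, np.finfo(float).tiny))
    p = 2.0 * sps.t.sf(np.abs(t), n - 2)
    fdr_pass = fdr_correct(p, alpha=alpha)
    retained = fdr_pass & (r2 > r2_min)
    sign = np.sign(r).astype(int) * res.slope_sign[iu] * res.slope_sign[ju]
    label = np.where(
        retained, np.where(sign > 0, "consistent", "inconsistent"), ""
    )
    return pd.DataFrame(
        {
            "bin_i_row": res.coords[iu, 0],
            "bin_i_col": res.coords[iu, 1],
            "bin_j_row": res.coords[ju, 0],
            "bin_j_col": res.coords[ju, 1],
            "distance": dist[iu, ju],
            "r": r,
            "r2": r2,
            "p": p,
            "fdr_pass": fdr_pass,
            "retained": retained,
            "label": label,
        }
    )
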