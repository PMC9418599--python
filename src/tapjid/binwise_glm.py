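"""Mass univariate robust regression over JID bins with 2-D cluster
bootstrap correction.

Each of the 2500 bins is regressed on the design (age or cognitive score
plus gender, optionally usage / finger / screen covariates) with
iteratively reweighted least squares (Tukey bisquare, c = 4.685, MAD
scale).  Per-bin t maps are corrected across the grid by 2-D clustering:
supra-threshold bins (two-sided p < cluster_p on the predictor of
interest) are grouped into 8-connected components whose summed t² is
compared against a resampling distribution of the maximum cluster mass
under the null (Freedman–Lane permutation by default; a participant
bootstrap of the predictor-centered response is available).

R² and F are reported from the unweighted fit evaluated at the converged
robust coefficients; per-coefficient t/p use the M-estimator covariance
(with Huber's small-sample correction) at n − p dof.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy import stats as sps

__all__ = [
    "RankDeficientError",
    "BinFit",
    "BinStatsMap",
    "Cluster",
    "ClusterResult",
    "build_response",
    "make_design",
    "fit_bin",
    "scalar_robust_regression",
    "mass_univariate",
    "cluster_correct",
    "fdr_correct",
]

BISQUARE_C = 4.685
MAD_TO_SIGMA = 0.6744897501960817  # Phi^-1(0.75)


class RankDeficientError(ValueError):
    """Design matrix is rank deficient; names the offending columns."""


# ---------------------------------------------------------------------------
# design / response construction


def build_response(jids, already_stacked: bool = False) -> np.ndarray:
    """Stack JIDs into a participants × bins log10 response matrix.

    Zeros are replaced by the minimum positive mass found anywhere in the
    population *before* the log10 transform.  Accepts a list of
    :class:`~tapjid.jid_core.JIDGrid` or a pre-stacked 2-D mass array.
    """
    if already_stacked:
        M = np.asarray(jids, dtype=float)
    else:
        grids = list(jids)
        if not grids:
            raise ValueError("need at least one JID")
        shapes = {g.masses.shape for g in grids}
        if len(shapes) != 1:
            raise ValueError("all JIDs must share one grid configuration")
        M = np.vstack([g.feature_vector() for g in grids])
    if np.any(M < 0) or not np.all(np.isfinite(M)):
        raise ValueError("masses must be finite and nonnegative")
    pos = M[M > 0]
    if pos.size == 0:
        raise ValueError("all masses are zero; nothing to log-transform")
    gmin = pos.min()
    if np.any((M == 0).all(axis=0)):
        import warnings

        warnings.warn(
            "column(s) with zero mass across the whole cohort were replaced "
            "by the population minimum everywhere",
            stacklevel=2,
        )
    return np.log10(np.where(M > 0, M, gmin))


def make_design(
    columns: dict[str, np.ndarray], add_intercept: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Assemble a design matrix from named columns (intercept appended last)."""
    names = list(columns)
    cols = [np.asarray(columns[k], dtype=float) for k in names]
    n = cols[0].size
    if any(c.size != n for c in cols):
        raise ValueError("all design columns must have equal length")
    if add_intercept:
        cols.append(np.ones(n))
        names.append("intercept")
    X = np.column_stack(cols)
    if not np.all(np.isfinite(X)):
        raise ValueError("design matrix contains missing/non-finite values")
    _check_rank(X, names)
    return X, names


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    n, p = X.shape
    if n <= p:
        raise RankDeficientError(
            f"need more rows ({n}) than predictors ({p}) for residual dof"
        )
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    bad = [names[i] for i in np.flatnonzero(diag <= tol)]
    if bad:
        raise RankDeficientError(
            f"design matrix is rank deficient; collinear column(s): {bad}"
        )


# ---------------------------------------------------------------------------
# fitting


def _ols_beta(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Least-squares coefficients, (p, n_cols)."""
    return np.linalg.lstsq(X, Y, rcond=None)[0]


def _irls_beta(
    X: np.ndarray,
    Y: np.ndarray,
    c: float = BISQUARE_C,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> np.ndarray:
    """Batched IRLS with Tukey bisquare weights; Y is (n, B)."""
    n, p = X.shape
    beta = _ols_beta(X, Y)
    for _ in range(max_iter):
        R = Y - X @ beta
        med = np.median(R, axis=0)
        mad = np.median(np.abs(R - med), axis=0)
        scale = mad / MAD_TO_SIGMA
        # perfect-fit columns: keep unit weights (u -> 0)
        safe = np.where(scale > 0, scale, np.inf)
        u = R / (c * safe)
        w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        # columns where too few points keep weight: fall back to OLS weights
        dead = w.sum(axis=0) < p
        if np.any(dead):
            w[:, dead] = 1.0
        A = np.einsum("np,nb,nq->bpq", X, w, X, optimize=True)
        b = np.einsum("np,nb->bp", X, w * Y, optimize=True)
        try:
            new = np.linalg.solve(A, b[..., None])[..., 0].T
        except np.linalg.LinAlgError:
            new = np.stack(
                [np.linalg.lstsq(A[i], b[i], rcond=None)[0] for i in range(A.shape[0])],
                axis=1,
            )
        delta = np.max(np.abs(new - beta))
        beta = new
        if delta < tol:
            break
    return beta


def _robust_variance_factor(
    X: np.ndarray, R: np.ndarray, c: float = BISQUARE_C
) -> np.ndarray:
    """Per-column coefficient-variance factor of the bisquare IRLS fit.

    Standard M-estimator asymptotics with Huber's small-sample correction:
    Var(beta) = k² · [Σ ψ(r/s)² s² / (n−p)] / (mean ψ')² · (X'X)⁻¹,
    k = 1 + (p/n) · var(ψ') / (mean ψ')².
    """
    n, p = X.shape
    med = np.median(R, axis=0)
    s = np.median(np.abs(R - med), axis=0) / MAD_TO_SIGMA
    s = np.where(s > 0, s, np.inf)
    z = R / s
    zz = z / c
    inside = np.abs(zz) < 1.0
    psi = np.where(inside, z * (1.0 - zz**2) ** 2, 0.0)
    dpsi = np.where(inside, (1.0 - zz**2) * (1.0 - 5.0 * zz**2), 0.0)
    m1 = dpsi.mean(axis=0)
    m1 = np.where(np.abs(m1) > 1e-12, m1, 1.0)
    k = 1.0 + (p / n) * dpsi.var(axis=0) / m1**2
    scale_est = np.einsum("nb,nb->b", psi, psi * s**2) / (n - p)
    return k**2 * scale_est / m1**2


def _stats_at(
    X: np.ndarray, Y: np.ndarray, beta: np.ndarray, robust: bool = False
) -> dict[str, np.ndarray]:
    """t/p/R²/F at given coefficients from the unweighted residuals.

    With ``robust=True`` the per-coefficient standard errors use the
    M-estimator covariance (calibrated for the IRLS fit); R² and F always
    come from the unweighted residuals at the given coefficients.
    """
    n, p = X.shape
    dof = n - p
    R = Y - X @ beta
    rss = np.einsum("nb,nb->b", R, R)
    ybar = Y.mean(axis=0)
    tss = np.einsum("nb,nb->b", Y - ybar, Y - ybar)
    sigma2 = rss / dof
    xtx_inv_diag = np.diag(np.linalg.inv(X.T @ X))
    var_fac = _robust_variance_factor(X, R) if robust else sigma2
    se = np.sqrt(np.outer(xtx_inv_diag, var_fac))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
        pvals = 2.0 * sps.t.sf(np.abs(t), dof)
        r2 = np.where(tss > 0, 1.0 - rss / np.where(tss > 0, tss, 1.0), 0.0)
        r2 = np.clip(r2, 0.0, 1.0)
        if p > 1:
            fstat = (tss - rss) / (p - 1) / np.where(sigma2 > 0, sigma2, np.inf)
            fstat = np.maximum(fstat, 0.0)
            f_p = sps.f.sf(fstat, p - 1, dof)
        else:
            fstat = np.zeros_like(rss)
            f_p = np.ones_like(rss)
    return {"t": t, "p": pvals, "se": se, "r2": r2, "f": fstat, "f_p": f_p}


@dataclass
class BinFit:
    """Regression result for a single response column."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    r2: float
    f: float
    f_p: float
    n: int

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def tstat(self, name: str) -> float:
        return float(self.t[self.names.index(name)])

    def pvalue(self, name: str) -> float:
        return float(self.p[self.names.index(name)])


def fit_bin(
    y: np.ndarray,
    X: np.ndarray,
    names: Sequence[str] | None = None,
    estimator: str = "irls",
) -> BinFit:
    """Robust (or plain OLS) regression of one response column on X."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or y.size != X.shape[0]:
        raise ValueError("X must be (n, p) with n matching len(y)")
    names = list(names) if names is not None else [f"x{i}" for i in range(X.shape[1])]
    _check_rank(X, names)
    Y = y[:, None]
    beta = _irls_beta(X, Y) if estimator == "irls" else _ols_beta(X, Y)
    st = _stats_at(X, Y, beta, robust=estimator == "irls")
    return BinFit(
        names=names,
        beta=beta[:, 0],
        se=st["se"][:, 0],
        t=st["t"][:, 0],
        p=st["p"][:, 0],
        r2=float(st["r2"][0]),
        f=float(st["f"][0]),
        f_p=float(st["f_p"][0]),
        n=int(y.size),
    )


def scalar_robust_regression(
    y: np.ndarray,
    X: np.ndarray,
    names: Sequence[str] | None = None,
) -> BinFit:
    """Robust multiple regression for scalar outcomes (usage, entropy, ...)."""
    return fit_bin(y, X, names=names, estimator="irls")


@dataclass
class BinStatsMap:
    """Per-bin regression output arranged as 2-D maps.

    ``beta``/``t``/``p`` are (n_predictors, nb, nb); ``r2``/``f`` are
    (nb, nb).  Row index is the k-bin, column index the (k+1)-bin.
    """

    names: list[str]
    beta: np.ndarray
    t: np.ndarray
    p: np.ndarray
    r2: np.ndarray
    f: np.ndarray
    n: int

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.r2.shape  # type: ignore[return-value]

    def map(self, name: str, stat: str = "t") -> np.ndarray:
        idx = self.names.index(name)
        return getattr(self, stat)[idx]


def mass_univariate(
    Y: np.ndarray,
    X: np.ndarray,
    names: Sequence[str] | None = None,
    estimator: str = "irls",
) -> BinStatsMap:
    """Fit every response column independently and assemble grid maps."""
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    names = list(names) if names is not None else [f"x{i}" for i in range(X.shape[1])]
    if Y.ndim != 2 or Y.shape[0] != X.shape[0]:
        raise ValueError("Y must be (n_participants, n_bins) aligned with X")
    _check_rank(X, names)
    nb = int(round(np.sqrt(Y.shape[1])))
    if nb * nb != Y.shape[1]:
        raise ValueError("number of response columns must be a perfect square")
    beta = _irls_beta(X, Y) if estimator == "irls" else _ols_beta(X, Y)
    st = _stats_at(X, Y, beta, robust=estimator == "irls")
    p_dim = X.shape[1]
    return BinStatsMap(
        names=names,
        beta=beta.reshape(p_dim, nb, nb),
        t=st["t"].reshape(p_dim, nb, nb),
        p=st["p"].reshape(p_dim, nb, nb),
        r2=st["r2"].reshape(nb, nb),
        f=st["f"].reshape(nb, nb),
        n=int(Y.shape[0]),
    )


# ---------------------------------------------------------------------------
# cluster correction


@dataclass
class Cluster:
    bins: np.ndarray  # (m, 2) int row/col indices
    mass: float
    p_corrected: float
    significant: bool


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    sig_mask: np.ndarray  # (nb, nb) bool
    cluster_p: float
    alpha: float
    n_boot: int
    connectivity: int
    mass_threshold: float
    seed: int | None = None

    @property
    def n_significant(self) -> int:
        return sum(c.significant for c in self.clusters)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 8:
        return np.ones((3, 3), dtype=bool)
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    raise ValueError("connectivity must be 4 or 8")


def _cluster_masses(
    supra: np.ndarray, weight: np.ndarray, structure: np.ndarray
) -> tuple[np.ndarray, list[np.ndarray], np.ndarray]:
    labels, n = ndimage.label(supra, structure=structure)
    if n == 0:
        return np.empty(0), [], labels
    masses = ndimage.sum_labels(weight, labels, index=np.arange(1, n + 1))
    members = [np.argwhere(labels == i + 1) for i in range(n)]
    return np.asarray(masses, dtype=float), members, labels


def _max_cluster_mass(
    supra: np.ndarray, weight: np.ndarray, structure: np.ndarray
) -> float:
    """Largest cluster mass only — fast path for the null resamples."""
    labels, n = ndimage.label(supra, structure=structure)
    if n == 0:
        return 0.0
    return float(
        ndimage.sum_labels(weight, labels, index=np.arange(1, n + 1)).max()
    )


def _boot_pf(
    X: np.ndarray, Y: np.ndarray, j: int, mass_stat: str = "tsq"
) -> tuple[np.ndarray, np.ndarray]:
    """OLS per-column p-value of predictor j and cluster weight, fast path."""
    n, p = X.shape
    dof = n - p
    beta = _ols_beta(X, Y)
    R = Y - X @ beta
    rss = np.einsum("nb,nb->b", R, R)
    sigma2 = rss / dof
    xtx_inv_jj = np.linalg.inv(X.T @ X)[j, j]
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(xtx_inv_jj * sigma2)
        t = np.where(se > 0, beta[j] / se, 0.0)
        pvals = 2.0 * sps.t.sf(np.abs(t), dof)
        if mass_stat == "tsq":
            weight = t**2
        else:
            ybar = Y.mean(axis=0)
            tss = np.einsum("nb,nb->b", Y - ybar, Y - ybar)
            weight = np.maximum(
                (tss - rss) / (p - 1) / np.where(sigma2 > 0, sigma2, np.inf), 0.0
            )
    return pvals, weight


def cluster_correct(
    stats: BinStatsMap,
    Y: np.ndarray,
    X: np.ndarray,
    predictor: str,
    n_boot: int = 1000,
    alpha: float = 0.05,
    cluster_p: float = 0.05,
    connectivity: int = 8,
    seed: int | None = None,
    mass_stat: str = "tsq",
    null_method: str = "permutation",
) -> ClusterResult:
    """Resampling 2-D cluster correction of the per-bin maps.

    Observed clusters are 8-connected components of bins with two-sided
    p < ``cluster_p`` on ``predictor``; cluster mass is the sum of the
    predictor's t² over member bins (``mass_stat='tsq'``, default) or of
    the full-model F (``mass_stat='f'``).  The null distribution of the
    maximum cluster mass is built from ``n_boot`` resamples under H0; a
    cluster is significant when its mass exceeds the (1 − alpha) null
    quantile, and corrected p = fraction of null maxima ≥ its mass.

    ``null_method='permutation'`` (default) uses Freedman–Lane: the
    residuals of the nuisance-only model are row-permuted jointly across
    bins (preserving cross-bin dependence), re-added to the nuisance fit,
    and refit with the full design.  ``null_method='bootstrap'`` removes
    the predictor's fitted effect and resamples participants with
    replacement; with the maximum statistic this is markedly conservative
    because one shared resampling pattern modulates the whole t-field, so
    it is not the default.

    The t² mass keeps the null exchangeable with the observed statistic:
    the H0 response retains the *fitted* nuisance effects, which would
    make a full-model F noncentral in the nuisance coefficients.
    """
    if n_boot < 20:
        raise ValueError("n_boot < 20 gives an unstable null quantile; refuse")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    if mass_stat not in ("tsq", "f"):
        raise ValueError("mass_stat must be 'tsq' or 'f'")
    if null_method not in ("permutation", "bootstrap"):
        raise ValueError("null_method must be 'permutation' or 'bootstrap'")
    j = stats.names.index(predictor)
    structure = _structure(connectivity)
    nb = stats.grid_shape[0]

    supra = stats.p[j] < cluster_p
    obs_weight = stats.t[j] ** 2 if mass_stat == "tsq" else stats.f
    obs_masses, obs_members, _ = _cluster_masses(supra, obs_weight, structure)

    rng = np.random.default_rng(seed)
    n = X.shape[0]
    boot_max = np.zeros(n_boot)
    if null_method == "permutation":
        Xr = np.delete(X, j, axis=1)
        beta_red = _ols_beta(Xr, Y)
        fitted_red = Xr @ beta_red
        R_red = Y - fitted_red
        p_dim = X.shape[1]
        dof = n - p_dim
        tcrit2 = float(sps.t.ppf(1.0 - cluster_p / 2.0, dof)) ** 2
        proj = np.linalg.pinv(X)
        xtx_inv = np.linalg.inv(X.T @ X)
        for b in range(n_boot):
            perm = rng.permutation(n)
            Yb = fitted_red + R_red[perm]
            beta_b = proj @ Yb
            Rb = Yb - X @ beta_b
            sigma2 = np.einsum("nb,nb->b", Rb, Rb) / dof
            with np.errstate(divide="ignore", invalid="ignore"):
                t2 = np.where(
                    sigma2 > 0, beta_b[j] ** 2 / (xtx_inv[j, j] * sigma2), 0.0
                )
            if mass_stat == "tsq":
                weight_b = t2
            else:
                ybar = Yb.mean(axis=0)
                tss = np.einsum("nb,nb->b", Yb - ybar, Yb - ybar)
                rss = sigma2 * dof
                with np.errstate(divide="ignore", invalid="ignore"):
                    weight_b = np.maximum(
                        (tss - rss)
                        / (p_dim - 1)
                        / np.where(sigma2 > 0, sigma2, np.inf),
                        0.0,
                    )
            boot_max[b] = _max_cluster_mass(
                (t2 > tcrit2).reshape(nb, nb),
                weight_b.reshape(nb, nb),
                structure,
            )
    else:
        # H0 response: strip the fitted predictor effect, keep nuisance fits
        beta_full = _ols_beta(X, Y)
        Y0 = Y - np.outer(X[:, j], beta_full[j])
        for b in range(n_boot):
            for _ in range(100):
                idx = rng.integers(0, n, n)
                Xb = X[idx]
                if np.linalg.matrix_rank(Xb) == X.shape[1]:
                    break
            else:  # pragma: no cover - pathological designs only
                raise RuntimeError("could not draw a full-rank bootstrap design")
            pvals, weight_b = _boot_pf(Xb, Y0[idx], j, mass_stat=mass_stat)
            boot_max[b] = _max_cluster_mass(
                (pvals < cluster_p).reshape(nb, nb),
                weight_b.reshape(nb, nb),
                structure,
            )

    threshold = float(np.quantile(boot_max, 1.0 - alpha)) if alpha < 1.0 else -np.inf
    clusters = []
    sig_mask = np.zeros((nb, nb), dtype=bool)
    for mass, members in zip(obs_masses, obs_members):
        p_corr = float(np.mean(boot_max >= mass))
        significant = bool(mass > threshold)
        if significant:
            sig_mask[members[:, 0], members[:, 1]] = True
        clusters.append(Cluster(members, float(mass), p_corr, significant))
    return ClusterResult(
        clusters=clusters,
        sig_mask=sig_mask,
        cluster_p=cluster_p,
        alpha=alpha,
        n_boot=n_boot,
        connectivity=connectivity,
        mass_threshold=threshold,
        seed=seed,
    )


def fdr_correct(pvals, alpha: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up: boolean rejection mask at level alpha."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    below = ranked <= (np.arange(1, m + 1) / m) * alpha
    mask = np.zeros(m, dtype=bool)
    if np.any(below):
        k = np.max(np.flatnonzero(below))
        mask[order[: k + 1]] = True
    return mask
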