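"""Per-marker linear mixed-model association engine.

The model per marker is

    y = X beta + mu + eps,   mu ~ N(0, sigma2_mu * K),  eps ~ N(0, sigma2_eps * I),

so Cov(y) = sigma2_mu * K + sigma2_eps * I.  Variance components are
estimated by restricted maximum likelihood (REML) through a single
symmetric eigendecomposition of K: writing K = U D U', rotating y and X by
U' diagonalizes the covariance, and the restricted likelihood becomes a
one-dimensional profile over the ratio lambda = sigma2_mu / sigma2_eps,
maximized by a coarse grid on log lambda in [-10, 10] followed by bounded
refinement.  A Haseman–Elston-type method-of-moments estimator
(``anova_mom``) is provided as the classical analysis-of-variance
alternative.  Fixed effects are then estimated by generalized least
squares under the plugged-in covariance and tested with a Wald statistic
against the standard normal reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.optimize import minimize_scalar
from scipy.stats import norm, t as t_dist

from .kinship import KinshipMatrix
from .options import CovarianceSpec, build_covariance_spec, draw_one_per_family
from .simulate import SimulatedDataset

__all__ = [
    "VarianceComponents",
    "AssociationResult",
    "reml_variance_components",
    "anova_variance_components",
    "restricted_loglik",
    "gls_fit",
    "fit_marker",
    "fit_all",
    "write_association_tsv",
    "write_manhattan_tsv",
]

LOG_LAMBDA_BOUNDS = (-10.0, 10.0)
GRID_POINTS = 100
REFINE_XATOL = 1e-8
# likelihood differences below this are treated as ties; ties resolve to the
# lower boundary (sigma2_mu = 0), which handles the K = I flat-profile case
_FLAT_TOL = 1e-10

_TINY_P = 1e-300


@dataclass(frozen=True)
class VarianceComponents:
    sigma2_mu: float
    sigma2_eps: float
    method: str  # "reml" | "anova_mom"
    converged: bool
    boundary: bool  # True if an estimate was clamped at the parameter edge


@dataclass(frozen=True)
class AssociationResult:
    marker_id: str
    option: str
    estimate: float
    std_error: float
    statistic: float
    p_value: float
    n_used: int
    variance_components: Optional[VarianceComponents] = None


class SingularDesignError(np.linalg.LinAlgError):
    pass


# ---------------------------------------------------------------------------
# spectral REML machinery
# ---------------------------------------------------------------------------


class SpectralBasis:
    """Eigendecomposition of K plus the rotated design, shared across markers.

    The fixed-effect design is identical for every marker of a study, so the
    decomposition and the rotated X are computed once and reused.
    """

    def __init__(self, K: np.ndarray, X: np.ndarray):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n, p = X.shape
        if n <= p:
            raise SingularDesignError(f"need n > p, got n={n}, p={p}")
        if np.linalg.matrix_rank(X) < p:
            raise SingularDesignError("design matrix X is rank deficient")
        d, U = np.linalg.eigh(np.asarray(K, dtype=float))
        if d[0] < -1e-8 * max(1.0, abs(d[-1])):
            raise ValueError(
                f"K is not positive semidefinite (smallest eigenvalue {d[0]:.3e})"
            )
        self.d = np.clip(d, 0.0, None)
        self.U = U
        self.X = X
        self.n, self.p = n, p
        self.Xt = U.T @ X
        _, self.logdet_xtx = np.linalg.slogdet(X.T @ X)

    def rotate(self, y: np.ndarray) -> np.ndarray:
        return self.U.T @ np.asarray(y, dtype=float)

    # -- profiled restricted likelihood at a given ratio ------------------
    def _profile(self, yt: np.ndarray, lam: float):
        """GLS under H = lam*K + I in rotated coordinates.

        Returns (neg_restricted_loglik, rss_w, beta, A) where sigma2_eps is
        profiled out as rss_w / (n - p) and A = X' H^-1 X.
        """
        w = 1.0 / (lam * self.d + 1.0)
        Xw = self.Xt * w[:, None]
        A = self.Xt.T @ Xw
        beta = np.linalg.solve(A, Xw.T @ yt)
        resid = yt - self.Xt @ beta
        rss_w = float(np.sum(w * resid * resid))
        np_ = self.n - self.p
        sign, logdet_a = np.linalg.slogdet(A)
        if sign <= 0:
            raise SingularDesignError("X' H^-1 X is singular")
        logdet_h = float(np.sum(np.log(lam * self.d + 1.0)))
        sigma2 = max(rss_w / np_, 1e-300)
        ll = -0.5 * (
            np_ * (np.log(2.0 * np.pi * sigma2) + 1.0)
            + logdet_h
            + logdet_a
            - self.logdet_xtx
        )
        return -ll, rss_w, beta, A

    def _neg_ll_grid(self, Yt: np.ndarray, log_lams: np.ndarray) -> np.ndarray:
        """Vectorized profiled negative restricted log-likelihood.

        ``Yt``: rotated responses, shape (n, m).  Returns (len(log_lams), m).
        """
        np_ = self.n - self.p
        out = np.empty((len(log_lams), Yt.shape[1]))
        for i, ll_lam in enumerate(log_lams):
            lam = np.exp(ll_lam)
            w = 1.0 / (lam * self.d + 1.0)
            Xw = self.Xt * w[:, None]
            A = self.Xt.T @ Xw
            sign, logdet_a = np.linalg.slogdet(A)
            if sign <= 0:
                out[i] = np.inf
                continue
            B = np.linalg.solve(A, Xw.T @ Yt)  # p x m
            resid = Yt - self.Xt @ B
            rss_w = np.sum(w[:, None] * resid * resid, axis=0)
            logdet_h = float(np.sum(np.log(lam * self.d + 1.0)))
            sigma2 = np.maximum(rss_w / np_, 1e-300)
            out[i] = 0.5 * (
                np_ * (np.log(2.0 * np.pi * sigma2) + 1.0)
                + logdet_h
                + logdet_a
                - self.logdet_xtx
            )
        return out

    def _is_degenerate(self, yt: np.ndarray) -> bool:
        """True when the response has (numerically) zero residual variation,
        e.g. a constant vector with an intercept in X."""
        _, rss_ols, _, _ = self._profile(yt, 0.0)
        scale = max(float(yt @ yt), 1.0)
        return rss_ols <= 1e-24 * scale

    def reml_one(self, yt: np.ndarray) -> VarianceComponents:
        """REML variance components for one rotated response."""
        lo, hi = LOG_LAMBDA_BOUNDS
        if self._is_degenerate(yt):
            return VarianceComponents(0.0, 0.0, "reml", True, True)
        grid = np.linspace(lo, hi, GRID_POINTS)
        neg = self._neg_ll_grid(yt[:, None], grid)[:, 0]
        best = int(np.argmin(neg))
        return self._refine(yt, grid, neg, best)

    def _refine(
        self, yt: np.ndarray, grid: np.ndarray, neg: np.ndarray, best: int
    ) -> VarianceComponents:
        lo, hi = LOG_LAMBDA_BOUNDS
        np_ = self.n - self.p
        left = grid[max(best - 1, 0)]
        right = grid[min(best + 1, len(grid) - 1)]
        res = minimize_scalar(
            lambda g: self._profile(yt, float(np.exp(g)))[0],
            bounds=(left, right),
            method="bounded",
            options={"xatol": REFINE_XATOL},
        )
        g_opt, f_opt = float(res.x), float(res.fun)
        # flat or boundary profiles resolve to the lower edge: sigma2_mu = 0
        f_lo = self._profile(yt, float(np.exp(lo)))[0]
        if f_lo <= f_opt + _FLAT_TOL:
            _, rss_ols, _, _ = self._profile(yt, 0.0)
            return VarianceComponents(0.0, rss_ols / np_, "reml", True, True)
        boundary = g_opt >= hi - 1e-6
        if boundary:
            g_opt = hi
        lam = float(np.exp(g_opt))
        _, rss_w, _, _ = self._profile(yt, lam)
        sigma2_eps = rss_w / np_
        return VarianceComponents(
            lam * sigma2_eps, sigma2_eps, "reml", bool(res.success), boundary
        )

    def reml_many(self, Yt: np.ndarray) -> list[VarianceComponents]:
        """REML per column of the rotated response matrix ``Yt`` (n x m).

        The coarse grid is evaluated for all markers at once; refinement is
        per marker and identical to :meth:`reml_one`.
        """
        lo, hi = LOG_LAMBDA_BOUNDS
        grid = np.linspace(lo, hi, GRID_POINTS)
        neg = self._neg_ll_grid(Yt, grid)
        out = []
        for j in range(Yt.shape[1]):
            yt = Yt[:, j]
            if self._is_degenerate(yt):
                out.append(VarianceComponents(0.0, 0.0, "reml", True, True))
                continue
            out.append(self._refine(yt, grid, neg[:, j], int(np.argmin(neg[:, j]))))
        return out

    def gls_rotated(self, yt: np.ndarray, vc: VarianceComponents):
        """GLS point estimate and coefficient covariance under the fitted V."""
        if vc.sigma2_mu + vc.sigma2_eps <= 0.0:
            v_diag = np.ones_like(self.d)
        else:
            v_diag = vc.sigma2_mu * self.d + vc.sigma2_eps
            v_diag = np.maximum(v_diag, 1e-12)
        w = 1.0 / v_diag
        Xw = self.Xt * w[:, None]
        A = self.Xt.T @ Xw
        beta = np.linalg.solve(A, Xw.T @ yt)
        cov = np.linalg.inv(A)
        return beta, cov


def restricted_loglik(
    y: np.ndarray,
    X: np.ndarray,
    K: KinshipMatrix | np.ndarray,
    sigma2_mu: float,
    sigma2_eps: float,
) -> float:
    """Restricted log-likelihood of (sigma2_mu, sigma2_eps), spectral route.

    Uses the standard residual-contrast form
    ``-0.5 [ (n-p) log 2pi + log|V| + log|X'V^-1 X| - log|X'X| + r'V^-1 r ]``
    with r the GLS residual under V = sigma2_mu*K + sigma2_eps*I.
    """
    Kv = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    basis = SpectralBasis(Kv, X)
    yt = basis.rotate(y)
    v_diag = sigma2_mu * basis.d + sigma2_eps
    if np.any(v_diag <= 0):
        raise ValueError("V must be positive definite")
    w = 1.0 / v_diag
    Xw = basis.Xt * w[:, None]
    A = basis.Xt.T @ Xw
    beta = np.linalg.solve(A, Xw.T @ yt)
    resid = yt - basis.Xt @ beta
    quad = float(np.sum(w * resid * resid))
    _, logdet_a = np.linalg.slogdet(A)
    logdet_v = float(np.sum(np.log(v_diag)))
    np_ = basis.n - basis.p
    return -0.5 * (
        np_ * np.log(2.0 * np.pi) + logdet_v + logdet_a - basis.logdet_xtx + quad
    )


def reml_variance_components(
    y: np.ndarray, X: np.ndarray, K: KinshipMatrix | np.ndarray
) -> VarianceComponents:
    """REML estimates of (sigma2_mu, sigma2_eps) for one response vector.

    When the ratio profile is flat (e.g. K = I, where only the total
    variance is identified) the estimate resolves to the boundary
    sigma2_mu = 0 with sigma2_eps the residual mean square.
    """
    Kv = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    basis = SpectralBasis(Kv, X)
    return basis.reml_one(basis.rotate(y))


def anova_variance_components(
    y: np.ndarray, X: np.ndarray, K: KinshipMatrix | np.ndarray
) -> VarianceComponents:
    """Method-of-moments (Haseman–Elston-type) variance components.

    Regresses the off-diagonal products of OLS residuals on the matching
    entries of K (no intercept) to estimate sigma2_mu, then takes
    sigma2_eps as the residual mean square minus the fitted family share.
    Negative estimates are clamped to zero with ``boundary=True``.
    """
    Kv = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if n <= p:
        raise SingularDesignError(f"need n > p, got n={n}, p={p}")
    iu = np.triu_indices(n, k=1)
    k_off = Kv[iu]
    if float(np.ptp(k_off)) == 0.0:
        raise ValueError(
            "K has constant off-diagonal entries; the moment regression is degenerate"
        )
    if float(np.ptp(y)) == 0.0:
        return VarianceComponents(0.0, 0.0, "anova_mom", True, True)
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    e = y - X @ beta_ols
    cross = e[iu[0]] * e[iu[1]]
    denom = float(np.sum(k_off * k_off))
    sigma2_mu = float(np.sum(k_off * cross) / denom)
    ms = float(e @ e) / (n - p)
    boundary = False
    if sigma2_mu < 0.0:
        sigma2_mu, boundary = 0.0, True
    sigma2_eps = ms - sigma2_mu  # unit diagonal of K
    if sigma2_eps < 0.0:
        sigma2_eps, boundary = 0.0, True
    return VarianceComponents(sigma2_mu, sigma2_eps, "anova_mom", True, boundary)


# ---------------------------------------------------------------------------
# GLS / OLS fixed-effect fits
# ---------------------------------------------------------------------------


def gls_fit(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    """Generalized least squares under a known covariance V.

    Returns ``(beta, cov_beta)`` with ``beta = (X'V^-1X)^-1 X'V^-1 y`` and
    ``cov_beta = (X'V^-1X)^-1``, computed through a Cholesky factorization
    of V rather than an explicit inverse.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    V = np.asarray(V, dtype=float)
    try:
        c = scipy.linalg.cho_factor(V, lower=True)
    except np.linalg.LinAlgError as exc:
        cond = float(np.linalg.cond(V))
        raise SingularDesignError(
            f"V is not positive definite (condition number {cond:.3e})"
        ) from exc
    ViX = scipy.linalg.cho_solve(c, X)
    Viy = scipy.linalg.cho_solve(c, y)
    A = X.T @ ViX
    sign, _ = np.linalg.slogdet(A)
    if sign <= 0 or np.linalg.cond(A) > 1e12:
        raise SingularDesignError(
            f"X'V^-1X is singular or ill-conditioned "
            f"(condition number {np.linalg.cond(A):.3e})"
        )
    beta = np.linalg.solve(A, X.T @ Viy)
    cov = np.linalg.inv(A)
    return beta, cov


def _ols_stats(y: np.ndarray, X: np.ndarray, coef_index: int):
    """OLS estimate, SE and residual df for the tested coefficient."""
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (n - p)
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(max(sigma2 * xtx_inv[coef_index, coef_index], 1e-300)))
    return float(beta[coef_index]), se, n - p


def _wald_p(z: float, df: Optional[int] = None) -> float:
    if df is None:
        p = 2.0 * norm.sf(abs(z))
    else:
        p = 2.0 * t_dist.sf(abs(z), df)
    return float(max(p, _TINY_P))


def fit_marker(
    y: np.ndarray,
    X: np.ndarray,
    spec: CovarianceSpec,
    vc_method: str = "reml",
    coef_index: int = 0,
    marker_id: str = "",
    use_t: bool = False,
) -> AssociationResult:
    """Fit one marker under a modeling option.

    ``y`` and ``X`` are aligned to ``spec.universe``; the representative
    option subsets rows to the active ids first.  The kinship option
    estimates variance components, plugs V = sigma2_mu*K + sigma2_eps*I
    into GLS and reports a Wald test; the other options reduce to OLS.
    ``use_t`` switches the reference distribution to t with residual
    degrees of freedom (intended for the small-n representative option).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    idx = spec.active_indices()
    y_a, X_a = y[idx], X[idx]
    n_used = len(idx)
    if spec.option == "kinship":
        if vc_method == "reml":
            basis = SpectralBasis(spec.matrix.values, X_a)
            yt = basis.rotate(y_a)
            vc = basis.reml_one(yt)
            beta, cov = basis.gls_rotated(yt, vc)
        elif vc_method == "anova_mom":
            vc = anova_variance_components(y_a, X_a, spec.matrix)
            V = vc.sigma2_mu * spec.matrix.values + vc.sigma2_eps * np.eye(n_used)
            if vc.sigma2_mu + vc.sigma2_eps <= 0.0:
                V = np.eye(n_used)
            beta, cov = gls_fit(y_a, X_a, V)
        else:
            raise ValueError(f"unknown vc_method {vc_method!r}")
        est = float(beta[coef_index])
        se = float(np.sqrt(max(cov[coef_index, coef_index], 1e-300)))
        stat = est / se
        return AssociationResult(
            marker_id, spec.option, est, se, stat, _wald_p(stat), n_used, vc
        )
    est, se, df = _ols_stats(y_a, X_a, coef_index)
    stat = est / se
    return AssociationResult(
        marker_id,
        spec.option,
        est,
        se,
        stat,
        _wald_p(stat, df if use_t else None),
        n_used,
        None,
    )


def _ols_many(Y: np.ndarray, X: np.ndarray, coef_index: int):
    """Vectorized OLS across marker columns; matches :func:`_ols_stats`."""
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    sigma2 = np.einsum("ij,ij->j", resid, resid) / (n - p)
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[coef_index, coef_index], 1e-300))
    return beta[coef_index], se, n - p


def fit_all(
    dataset: SimulatedDataset,
    option: str,
    vc_method: str = "reml",
    representative_seed: Optional[int] = None,
    use_t: bool = False,
) -> pd.DataFrame:
    """Fit every marker of a dataset under one modeling option.

    Returns one row per marker with columns marker_id, option, n_used,
    estimate, std_error, statistic, p_value, sigma2_mu, sigma2_eps,
    boundary.  The representative option draws its one-per-family subset
    once per call from ``representative_seed``.  Variance components are
    re-estimated independently per marker.
    """
    if option == "representative":
        if representative_seed is None:
            raise ValueError("representative option requires representative_seed")
        reps = draw_one_per_family(dataset.families, representative_seed)
        spec = build_covariance_spec("representative", dataset.kinship, reps)
    else:
        spec = build_covariance_spec(option, dataset.kinship)

    coef_index = dataset.tested_coef_index
    idx = spec.active_indices()
    Y, X = dataset.responses[idx], dataset.covariates[idx]
    m = dataset.m
    n_used = len(idx)

    if option == "kinship" and vc_method == "reml":
        basis = SpectralBasis(spec.matrix.values, X)
        Yt = basis.U.T @ Y
        vcs = basis.reml_many(Yt)
        rows = []
        for j, vc in enumerate(vcs):
            beta, cov = basis.gls_rotated(Yt[:, j], vc)
            est = float(beta[coef_index])
            se = float(np.sqrt(max(cov[coef_index, coef_index], 1e-300)))
            stat = est / se
            rows.append(
                (
                    dataset.marker_ids[j],
                    est,
                    se,
                    stat,
                    _wald_p(stat),
                    vc.sigma2_mu,
                    vc.sigma2_eps,
                    vc.boundary,
                )
            )
        df = pd.DataFrame(
            rows,
            columns=[
                "marker_id",
                "estimate",
                "std_error",
                "statistic",
                "p_value",
                "sigma2_mu",
                "sigma2_eps",
                "boundary",
            ],
        )
    elif option == "kinship":
        results = [
            fit_marker(
                dataset.responses[:, j],
                dataset.covariates,
                spec,
                vc_method=vc_method,
                coef_index=coef_index,
                marker_id=dataset.marker_ids[j],
            )
            for j in range(m)
        ]
        df = pd.DataFrame(
            {
                "marker_id": [r.marker_id for r in results],
                "estimate": [r.estimate for r in results],
                "std_error": [r.std_error for r in results],
                "statistic": [r.statistic for r in results],
                "p_value": [r.p_value for r in results],
                "sigma2_mu": [r.variance_components.sigma2_mu for r in results],
                "sigma2_eps": [r.variance_components.sigma2_eps for r in results],
                "boundary": [r.variance_components.boundary for r in results],
            }
        )
    else:
        est, se, dof = _ols_many(Y, X, coef_index)
        stat = est / se
        if use_t:
            p = np.maximum(2.0 * t_dist.sf(np.abs(stat), dof), _TINY_P)
        else:
            p = np.maximum(2.0 * norm.sf(np.abs(stat)), _TINY_P)
        df = pd.DataFrame(
            {
                "marker_id": list(dataset.marker_ids),
                "estimate": est,
                "std_error": se,
                "statistic": stat,
                "p_value": p,
                "sigma2_mu": np.nan,
                "sigma2_eps": np.nan,
                "boundary": False,
            }
        )
    df.insert(1, "option", option)
    df.insert(2, "n_used", n_used)
    return df


def write_association_tsv(results: pd.DataFrame, path: str | Path) -> None:
    results.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_manhattan_tsv(results: pd.DataFrame, path: str | Path) -> None:
    """Marker index vs -log10 p, ready for Manhattan-style plotting."""
    out = pd.DataFrame(
        {
            "marker_index": np.arange(len(results)),
            "marker_id": results["marker_id"].to_numpy(),
            "neg_log10_p": -np.log10(results["p_value"].to_numpy()),
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
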