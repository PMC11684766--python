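"""Radial multivariable MR: estimation, Q decomposition, outliers, pruning.

The multivariable radial model regresses Γ̂_j/σ̂_Yj on the K signed
square-root weights γ̂_kj/σ̂_Yj through the origin; its coefficients are the
direct-effect estimates β̂_IVWk, identical to an inverse-variance-weighted
(1/σ̂²_Yj) regression of Γ̂_j on the γ̂_kj.  For each exposure the per-SNP
ratio can be adjusted by subtracting the fitted contribution of the other
exposures, after which the squared vertical distance of the adjusted radial
point from the exposure's fitted line is the SNP's contribution Q_kj to the
exposure-specific heterogeneity statistic Q_k = Σ_j Q_kj.

Under the signed square-root convention the adjusted residual is the common
weighted regression residual for every reference exposure, so the Q_k
coincide across exposures (and equal the radial residual sum of squares);
the per-exposure API is kept because the adjusted plots and the ratio
adjustment are genuinely exposure-specific.

Outliers are SNPs whose Q_kj p-value (χ²₁) falls below a threshold for any
exposure; iterative pruning removes them and refits until none remain, with
the adjustment terms recomputed from the refreshed estimates each round.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import RadialPoint, SummaryDataset
from .univariable import f_statistics

logger = logging.getLogger(__name__)

__all__ = ["RadialFit", "PruneTrace", "mvmr_weights", "fit_radial_mvmr",
           "adjust_points", "exposure_Q", "detect_outliers", "prune_iterative",
           "conditional_F"]


@dataclass(frozen=True)
class RadialFit:
    """Result of a multivariable radial IVW fit.

    ``per_snp_Q`` is a (J, K) array of per-SNP heterogeneity contributions
    Q_kj (one column per exposure) with p-values ``per_snp_Q_p`` from χ²₁;
    ``Q_exposure`` are the exposure-specific global statistics with p-values
    from χ²(J−K).  ``conditional_F`` reports per-exposure conditional
    instrument strength (NaN when exposure standard errors were unavailable).
    """

    exposure_names: list[str]
    snp_ids: list[str]
    beta: np.ndarray
    se: np.ndarray
    p_values: np.ndarray
    Q_exposure: np.ndarray
    Q_p_values: np.ndarray
    per_snp_Q: np.ndarray
    per_snp_Q_p: np.ndarray
    conditional_F: np.ndarray
    n_snps_used: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "exposure": self.exposure_names,
            "estimate": self.beta,
            "se": self.se,
            "p_value": self.p_values,
            "Q": self.Q_exposure,
            "Q_p_value": self.Q_p_values,
            "conditional_F": self.conditional_F,
            "n_snps": self.n_snps_used,
        })

    def per_snp_table(self) -> pd.DataFrame:
        J, K = self.per_snp_Q.shape
        return pd.DataFrame({
            "snp": np.repeat(self.snp_ids, K),
            "exposure": np.tile(self.exposure_names, J),
            "Q": self.per_snp_Q.ravel(),
            "Q_p_value": self.per_snp_Q_p.ravel(),
        })


@dataclass(frozen=True)
class PruneTrace:
    """Iteration-by-iteration record of outlier pruning.

    ``iterations`` holds (removed_snp_ids, refitted RadialFit) pairs in
    order; removed sets are disjoint across iterations.  ``converged`` is
    True when the final fit has no per-SNP p-value below the threshold.
    """

    iterations: list[tuple[list[str], RadialFit]]
    final_fit: RadialFit
    converged: bool
    alpha: float = 0.05

    @property
    def removed_snp_ids(self) -> list[str]:
        return [s for removed, _ in self.iterations for s in removed]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (removed, fit) in enumerate(self.iterations, start=1):
            for name, b in zip(fit.exposure_names, fit.beta):
                rows.append({"iteration": i, "n_removed": len(removed),
                             "removed_snps": ",".join(removed),
                             "exposure": name, "estimate": b,
                             "n_snps": fit.n_snps_used})
        return pd.DataFrame(rows)


def _drop_null_snps(ds: SummaryDataset) -> SummaryDataset:
    """Remove SNPs with zero estimated association for every exposure."""
    null = (ds.gamma == 0).all(axis=1)
    if null.any():
        logger.warning("dropping %d SNP(s) with zero association for all exposures",
                       int(null.sum()))
        ds = ds.subset(~null)
    return ds


def mvmr_weights(ds: SummaryDataset) -> np.ndarray:
    """First-order radial weights w_kj = γ̂²_kj/σ̂²_Yj as a (J, K) matrix."""
    return ds.gamma ** 2 / ds.se_Gamma[:, None] ** 2


def _design(ds: SummaryDataset) -> tuple[np.ndarray, np.ndarray]:
    """Signed radial design: columns γ̂_kj/σ̂_Yj and response Γ̂_j/σ̂_Yj."""
    inv = 1.0 / ds.se_Gamma
    return ds.gamma * inv[:, None], ds.Gamma * inv


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    K = X.shape[1]
    rank = np.linalg.matrix_rank(X)
    if rank < K:
        # name the offending exposures via the smallest right singular vector
        _, _, vt = np.linalg.svd(X, full_matrices=False)
        involved = [names[k] for k in np.nonzero(np.abs(vt[-1]) > 1e-8)[0]]
        raise ValueError("collinear exposure associations: "
                         + ", ".join(involved or names))


def fit_radial_mvmr(ds: SummaryDataset) -> RadialFit:
    """Fit the multivariable radial IVW model.

    Requires J ≥ K+1 SNPs (after removing SNPs with all-zero exposure
    associations) and a full-column-rank association matrix.  Standard
    errors are model-based weighted-least-squares SEs with the residual
    standard deviation floored at 1, p-values two-sided normal; the global
    exposure Q is referred to χ²(J−K), each Q_kj to χ²₁.
    """
    ds = _drop_null_snps(ds)
    J, K = ds.gamma.shape
    if J <= K:
        raise ValueError(f"need more SNPs than exposures: J={J} <= K={K}")
    X, y = _design(ds)
    _check_rank(X, ds.exposure_names)
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    sigma2 = rss / (J - K)
    cov = max(1.0, sigma2) * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    p = 2 * stats.norm.sf(np.abs(beta) / se)

    Qkj, Qk = _exposure_Q_arrays(resid, K)
    try:
        condF = conditional_F(ds)
    except ValueError:
        condF = np.full(K, np.nan)
    return RadialFit(
        exposure_names=list(ds.exposure_names),
        snp_ids=list(ds.snp_ids),
        beta=beta, se=se, p_values=p,
        Q_exposure=Qk,
        Q_p_values=stats.chi2.sf(Qk, df=J - K),
        per_snp_Q=Qkj,
        per_snp_Q_p=stats.chi2.sf(Qkj, df=1),
        conditional_F=condF,
        n_snps_used=J,
    )


def _exposure_Q_arrays(resid: np.ndarray, K: int) -> tuple[np.ndarray, np.ndarray]:
    # Signed square roots make the adjusted residual for every reference
    # exposure equal to the common regression residual, so Q_kj = e_j².
    Qj = resid ** 2
    Qkj = np.tile(Qj[:, None], (1, K))
    return Qkj, Qkj.sum(axis=0)


def exposure_Q(ds: SummaryDataset, fit: RadialFit,
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Recompute (Q_k, Q_kj, per-SNP p-values) for a frozen fit on ``ds``.

    Uses the fit's direct-effect estimates for the adjustment terms; SNP ids
    must match the fit.
    """
    ds = _drop_null_snps(ds)
    if list(ds.snp_ids) != list(fit.snp_ids):
        raise ValueError("dataset SNPs do not match the fitted SNPs")
    X, y = _design(ds)
    resid = y - X @ fit.beta
    Qkj, Qk = _exposure_Q_arrays(resid, ds.n_exposures)
    return Qk, Qkj, stats.chi2.sf(Qkj, df=1)


def adjust_points(ds: SummaryDataset, fit: RadialFit) -> list[RadialPoint]:
    """Radial points for all (SNP, exposure) pairs, unadjusted and adjusted.

    For reference exposure k the unadjusted ordinate is the ratio estimate
    times the square-root weight (equal to ±Γ̂_j/σ̂_Yj, the sign carried by
    γ̂_kj so that y/x is the Wald ratio); the adjusted ordinate subtracts the
    fitted contribution Σ_{m≠k} β̂_IVWm γ̂_mj/σ̂_Yj of the other exposures.
    The squared vertical distance of each adjusted point from the line
    through the origin with slope β̂_IVWk equals Q_kj.
    """
    ds = _drop_null_snps(ds)
    if list(ds.snp_ids) != list(fit.snp_ids):
        raise ValueError("dataset SNPs do not match the fitted SNPs")
    J, K = ds.gamma.shape
    inv = 1.0 / ds.se_Gamma
    sign = np.where(ds.gamma < 0, -1.0, 1.0)
    x = np.abs(ds.gamma) * inv[:, None]
    y_un = sign * (ds.Gamma * inv)[:, None]
    total = (ds.gamma * inv[:, None]) @ fit.beta
    other = total[:, None] - ds.gamma * inv[:, None] * fit.beta[None, :]
    y_adj = y_un - sign * other
    F = f_statistics(ds)
    return [
        RadialPoint(snp_id=ds.snp_ids[j], exposure=ds.exposure_names[k],
                    x=float(x[j, k]), y_unadjusted=float(y_un[j, k]),
                    y_adjusted=float(y_adj[j, k]), per_exposure_F=float(F[j, k]))
        for j in range(J) for k in range(K)
    ]


def detect_outliers(fit: RadialFit, alpha: float = 0.05,
                    bonferroni: bool = False) -> list[str]:
    """SNPs with a per-SNP Q p-value below ``alpha`` for any exposure.

    Returns ids sorted by their minimum p-value across exposures, most
    extreme first.  ``bonferroni`` divides the threshold by the number of
    SNPs tested.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    thresh = alpha / fit.n_snps_used if bonferroni else alpha
    min_p = fit.per_snp_Q_p.min(axis=1)
    idx = np.nonzero(min_p < thresh)[0]
    return [fit.snp_ids[j] for j in idx[np.argsort(min_p[idx], kind="stable")]]


def prune_iterative(ds: SummaryDataset, alpha: float = 0.05, max_iter: int = 50,
                    bonferroni: bool = False) -> PruneTrace:
    """Iteratively remove outlying SNPs and refit until none remain.

    Each round refits the radial MVMR model (recomputing the adjustment
    terms from the refreshed estimates), flags SNPs at the ``alpha``
    per-SNP threshold, and removes them.  Removal never brings the dataset
    below K+1 SNPs: if a round would, only the most extreme SNPs are removed
    down to that floor, with a warning.  Requires J ≥ K+2 initially.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if max_iter < 0:
        raise ValueError("max_iter must be >= 0")
    ds = _drop_null_snps(ds)
    J, K = ds.gamma.shape
    if J < K + 2:
        raise ValueError(f"need J >= K+2 SNPs to prune, got J={J}, K={K}")

    fit = fit_radial_mvmr(ds)
    iterations: list[tuple[list[str], RadialFit]] = []
    converged = False
    for _ in range(max_iter):
        flagged = detect_outliers(fit, alpha, bonferroni)
        if not flagged:
            converged = True
            break
        floor = K + 1
        if fit.n_snps_used - len(flagged) < floor:
            n_removable = fit.n_snps_used - floor
            logger.warning("pruning halted: removing all %d flagged SNPs would leave "
                           "fewer than K+1=%d; removing the %d most extreme only",
                           len(flagged), floor, n_removable)
            flagged = flagged[:n_removable]
            if not flagged:
                converged = False
                break
        ds = ds.drop(flagged)
        fit = fit_radial_mvmr(ds)
        iterations.append((flagged, fit))
        converged = len(detect_outliers(fit, alpha, bonferroni)) == 0
    return PruneTrace(iterations=iterations, final_fit=fit, converged=converged,
                      alpha=alpha)


def conditional_F(ds: SummaryDataset) -> np.ndarray:
    """Q-based conditional instrument-strength F-statistic per exposure.

    For each exposure k, regress γ̂_kj/σ̂_xkj on the other exposures'
    associations γ̂_mj/σ̂_xkj without intercept; the weighted residual sum of
    squares Q_xk = Σ_j (γ̂_kj − Σ_m δ̂_m γ̂_mj)²/σ̂²_xkj scaled by 1/(J−K+1)
    measures how strongly the instruments predict exposure k conditional on
    the others.  For K=1 this is the mean univariable F-statistic.
    """
    J, K = ds.gamma.shape
    if J < K + 1:
        raise ValueError(f"need J >= K+1 SNPs, got J={J}, K={K}")
    if not np.isfinite(ds.se_gamma).all() or (ds.se_gamma <= 0).any():
        raise ValueError("conditional F requires positive SNP-exposure standard "
                         "errors for every exposure; supply se.<exposure> columns")
    F = np.empty(K)
    for k in range(K):
        inv = 1.0 / ds.se_gamma[:, k]
        yk = ds.gamma[:, k] * inv
        others = [m for m in range(K) if m != k]
        if others:
            Xk = ds.gamma[:, others] * inv[:, None]
            delta, *_ = np.linalg.lstsq(Xk, yk, rcond=None)
            resid = yk - Xk @ delta
        else:
            resid = yk
        F[k] = float(resid @ resid) / (J - K + 1)
    return F
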