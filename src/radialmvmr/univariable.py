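"""Univariable radial (Galbraith) IVW estimation and heterogeneity decomposition.

The per-SNP Wald ratio β̂_j = Γ̂_j/γ̂_j with first-order weight
w_j = γ̂_j²/σ̂_Yj² admits an equivalent regression formulation: regressing
β̂_j√w_j on √w_j through the origin recovers the inverse-variance-weighted
estimate, and the vertical residual of each SNP is its square-root
contribution to Cochran's Q.  This module implements that estimator, the
exact Q decomposition, and the per-SNP outlier rule (Q_j p-value below a
significance threshold against χ²₁).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import SummaryDataset

logger = logging.getLogger(__name__)

__all__ = ["UnivariableFit", "ratio_estimates", "fit_radial_ivw",
           "univariable_outliers", "f_statistics"]


@dataclass(frozen=True)
class UnivariableFit:
    """Result of a univariable radial IVW fit.

    ``per_snp`` has one row per SNP used, with the ratio estimate, weight,
    individual Q_j and its χ²₁ p-value.  Σ_j Q_j equals ``Q_global`` exactly.
    """

    exposure: str
    beta_ivw: float
    se: float
    p_value: float
    Q_global: float
    Q_p_value: float
    per_snp: pd.DataFrame
    n_snps_used: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "exposure": [self.exposure],
            "estimate": [self.beta_ivw],
            "se": [self.se],
            "p_value": [self.p_value],
            "Q": [self.Q_global],
            "Q_p_value": [self.Q_p_value],
            "n_snps": [self.n_snps_used],
        })

    def per_snp_table(self) -> pd.DataFrame:
        return self.per_snp.copy()


def _exposure_index(ds: SummaryDataset, exposure: str | int) -> int:
    if isinstance(exposure, (int, np.integer)):
        return int(exposure)
    try:
        return ds.exposure_names.index(str(exposure))
    except ValueError:
        raise KeyError(f"unknown exposure {exposure!r}; have {ds.exposure_names}") from None


def ratio_estimates(ds: SummaryDataset, exposure: str | int) -> pd.DataFrame:
    """Per-SNP Wald ratios and first-order weights for one exposure.

    Returns a DataFrame with columns ``snp``, ``ratio`` (Γ̂_j/γ̂_j) and
    ``weight`` (γ̂_j²/σ̂_Yj²).  SNPs with γ̂_j = 0 exactly have an undefined
    ratio and are excluded with a logged count; raises if none remain.
    """
    k = _exposure_index(ds, exposure)
    g = ds.gamma[:, k]
    nonzero = g != 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.warning("ratio_estimates: excluded %d SNP(s) with zero association "
                       "for exposure %s", n_dropped, ds.exposure_names[k])
    if not nonzero.any():
        raise ValueError(f"all SNP associations are zero for exposure "
                         f"{ds.exposure_names[k]!r}")
    g = g[nonzero]
    Gamma = ds.Gamma[nonzero]
    seY = ds.se_Gamma[nonzero]
    return pd.DataFrame({
        "snp": [s for s, keep in zip(ds.snp_ids, nonzero) if keep],
        "ratio": Gamma / g,
        "weight": g ** 2 / seY ** 2,
    })


def fit_radial_ivw(ds: SummaryDataset, exposure: str | int) -> UnivariableFit:
    """Fit the univariable radial IVW model for one exposure.

    The slope of the no-intercept regression of β̂_j√w_j on √w_j equals the
    closed-form weighted mean Σw_jβ̂_j / Σw_j.  The standard error is the
    model-based weighted-regression SE with the residual standard deviation
    floored at 1: fixed-effect when the data are under-dispersed,
    multiplicative random-effects when over-dispersed.  Q_j = w_j(β̂_j−β̂)²
    with the global Q referred to χ²(J−1) and each Q_j to χ²₁.
    """
    per = ratio_estimates(ds, exposure)
    J = len(per)
    if J < 2:
        raise ValueError(f"need at least 2 SNPs with nonzero association, got {J}")
    w = per["weight"].to_numpy()
    ratio = per["ratio"].to_numpy()
    sw = np.sqrt(w)
    x, y = sw, ratio * sw
    beta = float((x * y).sum() / (x * x).sum())
    Qj = w * (ratio - beta) ** 2
    Q = float(Qj.sum())
    sigma2 = Q / (J - 1)
    se = float(np.sqrt(max(1.0, sigma2) / (x * x).sum()))
    p = float(2 * stats.norm.sf(abs(beta) / se))
    per = per.assign(Q=Qj, Q_p_value=stats.chi2.sf(Qj, df=1))
    k = _exposure_index(ds, exposure)
    return UnivariableFit(
        exposure=ds.exposure_names[k],
        beta_ivw=beta, se=se, p_value=p,
        Q_global=Q, Q_p_value=float(stats.chi2.sf(Q, df=J - 1)),
        per_snp=per, n_snps_used=J,
    )


def univariable_outliers(fit: UnivariableFit, alpha: float = 0.05) -> list[str]:
    """SNPs whose individual Q_j p-value is below ``alpha``, most extreme first."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    flagged = fit.per_snp[fit.per_snp["Q_p_value"] < alpha]
    return flagged.sort_values("Q_p_value")["snp"].tolist()


def f_statistics(ds: SummaryDataset) -> np.ndarray:
    """Per-SNP univariable instrument-strength F-statistics, γ̂²_kj/σ̂²_xkj (J×K)."""
    return ds.gamma ** 2 / ds.se_gamma ** 2
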