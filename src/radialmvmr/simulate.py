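"""Individual-level data generation for the verification studies.

The generator draws biallelic genotype counts under Hardy–Weinberg
equilibrium (MAF uniform on a configurable range), builds K correlated
exposures from group-structured SNP effects plus a shared confounder and
correlated residual noise, and an outcome as a linear combination of the
exposures, per-SNP direct (pleiotropic) effects, the confounder and noise:

    X_ki = Σ_j γ_kj G_ji + q_k U_i + ε_Xki
    Y_i  = Σ_k β_k X_ki + Σ_j α_j G_ji + q_Y U_i + ε_Yi

Every exposure GWAS and the outcome GWAS are computed in separate,
non-overlapping samples by single-SNP least-squares regressions, yielding a
:class:`~radialmvmr.data.SummaryDataset` of the kind the estimators consume.

Two stock designs are provided.  ``SimConfig.simulation_one`` uses 240 SNPs
in 8 equal groups: groups 1–7 cover every nonempty subset of three exposures
(effects N(0,10), resampled until |γ|≥2); group 8 is split into three
subgroups of 10 associated with one exposure each and carrying a direct
effect on the outcome (N(10,5), resampled until |α|≥2, so overwhelmingly
positive/directional).  ``SimConfig.simulation_two`` uses
groups 1–7 only (210 SNPs) and gives a random fraction of SNPs a direct
effect whose sign is random (balanced pleiotropy) or aligned with the SNP's
effect on a randomly chosen associated exposure (unbalanced/directional).

Residual scales default to values chosen so that instrument strength and
outlier detectability sit where a well-powered GWAS consortium analysis
would put them (conditional F around 100 at N=200,000, directional outliers
of typical size ~10 detectable individually); see docs/methods.md for the
calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data import SummaryDataset
from .mvmr import conditional_F, fit_radial_mvmr, prune_iterative

__all__ = ["SimConfig", "SimResult", "generate_individual_data",
           "run_simulation_study"]

#: exposure subsets instrumented by groups 1..7 (indices into the exposures)
_GROUPS_17: tuple[tuple[int, ...], ...] = (
    (0,), (1,), (2,), (0, 1), (0, 2), (1, 2), (0, 1, 2))

_DEFAULT_RESID_COR = ((1.0, 0.5, -0.5), (0.5, 1.0, 0.25), (-0.5, 0.25, 1.0))


@dataclass(frozen=True)
class SimConfig:
    """Full parameterisation of the data-generating process.

    Defaults reproduce the three-exposure verification design with
    β = (1, 0.2, −0.5) at N = 200,000 per (non-overlapping) sample.
    """

    n_per_sample: int = 200_000
    n_snps_per_group: int = 30
    beta_true: tuple[float, ...] = (1.0, 0.2, -0.5)
    gamma_sd: float = 10.0
    gamma_min_abs: float = 2.0
    alpha_mean: float = 10.0
    alpha_sd: float = 5.0
    alpha_min_abs: float = 2.0
    direct_effect_group: bool = True          # include group 8
    pleiotropy_proportion: float = 0.0        # fraction of group 1-7 SNPs with α ≠ 0
    pleiotropy_mode: str = "unbalanced"       # 'balanced' | 'unbalanced'
    exposure_residual_sd: float = 142.0
    outcome_residual_sd: float = 1300.0
    residual_cor: tuple[tuple[float, ...], ...] = _DEFAULT_RESID_COR
    confounder_effect_x: tuple[float, ...] = (30.0, 30.0, 30.0)
    confounder_effect_y: float = 30.0
    maf_range: tuple[float, float] = (0.1, 0.4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps_per_group < 0:
            raise ValueError("n_snps_per_group must be >= 0")
        if not 0 <= self.pleiotropy_proportion <= 1:
            raise ValueError("pleiotropy_proportion must be in [0, 1]")
        if self.pleiotropy_mode not in ("balanced", "unbalanced"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.gamma_min_abs > 0 and self.gamma_sd == 0:
            raise ValueError("cannot satisfy |gamma| >= gamma_min_abs with gamma_sd=0")
        if (self.direct_effect_group and self.alpha_min_abs > 0
                and self.alpha_sd == 0 and abs(self.alpha_mean) < self.alpha_min_abs):
            raise ValueError("cannot satisfy |alpha| >= alpha_min_abs")
        if not 0 < self.maf_range[0] <= self.maf_range[1] < 1:
            raise ValueError("maf_range must satisfy 0 < lo <= hi < 1")

    @property
    def n_exposures(self) -> int:
        return len(self.beta_true)

    @property
    def n_snps(self) -> int:
        n_groups = 7 + (1 if self.direct_effect_group else 0)
        return n_groups * self.n_snps_per_group

    @classmethod
    def simulation_one(cls, seed: int = 0, n_per_sample: int = 200_000,
                       **kwargs) -> "SimConfig":
        """Single-dataset design: 8 groups of 30 SNPs incl. the direct-effect group."""
        return cls(seed=seed, n_per_sample=n_per_sample, direct_effect_group=True,
                   pleiotropy_proportion=0.0, **kwargs)

    @classmethod
    def simulation_two(cls, pleiotropy_proportion: float, pleiotropy_mode: str,
                       seed: int = 0, n_per_sample: int = 100_000,
                       **kwargs) -> "SimConfig":
        """Sensitivity design: groups 1–7 with a configurable pleiotropic fraction."""
        return cls(seed=seed, n_per_sample=n_per_sample, direct_effect_group=False,
                   pleiotropy_proportion=pleiotropy_proportion,
                   pleiotropy_mode=pleiotropy_mode, **kwargs)


@dataclass(frozen=True)
class SimResult:
    """A generated dataset together with ground-truth bookkeeping."""

    dataset: SummaryDataset
    beta_true: np.ndarray
    gamma_true: np.ndarray          # (J, K) direct SNP-exposure effects
    alpha_true: np.ndarray          # (J,) direct SNP-outcome effects
    group_labels: np.ndarray        # (J,) int group 1..8
    pleiotropic_ids: list[str]      # SNPs with alpha != 0
    maf: np.ndarray
    exposure_correlation: np.ndarray  # realized corr(X) in the outcome sample
    config: SimConfig


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      min_abs: float, size: int, max_tries: int = 1000) -> np.ndarray:
    x = rng.normal(mean, sd, size)
    for _ in range(max_tries):
        bad = np.abs(x) < min_abs
        if not bad.any():
            return x
        x[bad] = rng.normal(mean, sd, int(bad.sum()))
    raise ValueError("could not satisfy the |value| >= min_abs truncation; "
                     "check the effect distribution parameters")


def _draw_design(cfg: SimConfig, rng: np.random.Generator,
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw true γ (J×K), α (J,) and group labels for the configured design."""
    K = cfg.n_exposures
    n = cfg.n_snps_per_group
    J = cfg.n_snps
    gamma = np.zeros((J, K))
    alpha = np.zeros(J)
    labels = np.zeros(J, dtype=int)
    groups = _GROUPS_17 if K == 3 else tuple(
        s for s in _GROUPS_17 if all(k < K for k in s))
    for g, exps in enumerate(groups[:7]):
        sl = slice(g * n, (g + 1) * n)
        labels[sl] = g + 1
        for k in exps:
            gamma[sl, k] = _truncated_normal(rng, 0.0, cfg.gamma_sd,
                                             cfg.gamma_min_abs, n)
    if cfg.direct_effect_group:
        base = 7 * n
        labels[base:] = 8
        bounds = np.linspace(0, n, K + 1).astype(int)   # K equal subgroups
        for k in range(K):
            sl = slice(base + bounds[k], base + bounds[k + 1])
            g = _truncated_normal(rng, 0.0, cfg.gamma_sd, cfg.gamma_min_abs,
                                  bounds[k + 1] - bounds[k])
            gamma[sl, k] = g
            alpha[sl] = _truncated_normal(rng, cfg.alpha_mean, cfg.alpha_sd,
                                          cfg.alpha_min_abs, g.size)
    if cfg.pleiotropy_proportion > 0:
        n17 = 7 * n
        m = int(round(cfg.pleiotropy_proportion * n17))
        chosen = rng.choice(n17, size=m, replace=False)
        mag = np.abs(_truncated_normal(rng, cfg.alpha_mean, cfg.alpha_sd,
                                       cfg.alpha_min_abs, m))
        if cfg.pleiotropy_mode == "balanced":
            sign = rng.choice([-1.0, 1.0], size=m)
        else:
            # unbalanced: aligned with a randomly chosen associated exposure
            sign = np.empty(m)
            for i, j in enumerate(chosen):
                assoc = np.nonzero(gamma[j] != 0)[0]
                k = assoc[rng.integers(assoc.size)]
                sign[i] = 1.0 if gamma[j, k] >= 0 else -1.0
        alpha[chosen] = mag * sign
    return gamma, alpha, labels


def _draw_genotypes(rng: np.random.Generator, n: int, maf: np.ndarray) -> np.ndarray:
    """Biallelic HWE genotype counts, float32 (n individuals × J SNPs)."""
    u1 = rng.random((n, maf.size), dtype=np.float32)
    u2 = rng.random((n, maf.size), dtype=np.float32)
    return ((u1 < maf) + (u2 < maf)).astype(np.float32)


def _single_snp_gwas(G: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP simple-regression estimates and standard errors, vectorised."""
    n = G.shape[0]
    Gm = G.mean(axis=0, dtype=np.float64)
    sg = (G.astype(np.float64) ** 2).sum(axis=0) - n * Gm ** 2
    yc = (y - y.mean()).astype(np.float32)
    cross = (G.T @ yc).astype(np.float64)
    bhat = cross / sg
    syy = float(np.dot(yc, yc))
    rss = np.maximum(syy - bhat ** 2 * sg, 0.0)
    se = np.sqrt(rss / ((n - 2) * sg))
    return bhat, se


def _exposure_sample(cfg: SimConfig, k: int, gamma: np.ndarray, maf: np.ndarray,
                     seed: np.random.SeedSequence) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    G = _draw_genotypes(rng, cfg.n_per_sample, maf)
    U = rng.standard_normal(cfg.n_per_sample)
    eps = rng.normal(0.0, cfg.exposure_residual_sd, cfg.n_per_sample)
    X = G @ gamma[:, k].astype(np.float32) + cfg.confounder_effect_x[k] * U + eps
    return _single_snp_gwas(G, X)


def _outcome_sample(cfg: SimConfig, gamma: np.ndarray, alpha: np.ndarray,
                    maf: np.ndarray, seed: np.random.SeedSequence,
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    K = cfg.n_exposures
    G = _draw_genotypes(rng, cfg.n_per_sample, maf)
    U = rng.standard_normal(cfg.n_per_sample)
    cor = np.asarray(cfg.residual_cor, dtype=float)[:K, :K]
    L = np.linalg.cholesky(cor)
    E = rng.standard_normal((cfg.n_per_sample, K)) @ (L.T * cfg.exposure_residual_sd)
    X = (G @ gamma.astype(np.float32)
         + np.asarray(cfg.confounder_effect_x[:K]) * U[:, None] + E)
    Y = (X @ np.asarray(cfg.beta_true) + G @ alpha.astype(np.float32)
         + cfg.confounder_effect_y * U
         + rng.normal(0.0, cfg.outcome_residual_sd, cfg.n_per_sample))
    Gh, seY = _single_snp_gwas(G, Y)
    xcor = np.corrcoef(X, rowvar=False) if K > 1 else np.ones((1, 1))
    return Gh, seY, xcor


def generate_individual_data(cfg: SimConfig) -> SimResult:
    """Generate one two-sample summary dataset under the configured process.

    K+1 mutually independent samples of ``cfg.n_per_sample`` individuals are
    drawn (one GWAS per exposure plus one for the outcome), each yielding
    single-SNP regression estimates and standard errors.  Reproducible
    bit-for-bit from ``cfg.seed``.
    """
    root = np.random.SeedSequence(cfg.seed)
    K = cfg.n_exposures
    design_seed, *sample_seeds = root.spawn(K + 2)
    rng = np.random.default_rng(design_seed)
    gamma, alpha, labels = _draw_design(cfg, rng)
    maf = rng.uniform(*cfg.maf_range, cfg.n_snps).astype(np.float32)

    J = cfg.n_snps
    gh = np.empty((J, K))
    seh = np.empty((J, K))
    for k in range(K):
        gh[:, k], seh[:, k] = _exposure_sample(cfg, k, gamma, maf, sample_seeds[k])
    Gh, seY, xcor = _outcome_sample(cfg, gamma, alpha, maf, sample_seeds[K])

    snp_ids = [f"rs{j + 1}" for j in range(J)]
    ds = SummaryDataset(
        snp_ids=snp_ids,
        exposure_names=[f"X{k + 1}" for k in range(K)],
        gamma=gh, se_gamma=seh, Gamma=Gh, se_Gamma=seY,
    )
    return SimResult(
        dataset=ds,
        beta_true=np.asarray(cfg.beta_true, dtype=float),
        gamma_true=gamma, alpha_true=alpha, group_labels=labels,
        pleiotropic_ids=[snp_ids[j] for j in np.nonzero(alpha != 0)[0]],
        maf=np.asarray(maf, dtype=float),
        exposure_correlation=xcor,
        config=cfg,
    )


def run_simulation_study(proportions: Sequence[float], modes: Sequence[str],
                         n_reps: int, base_config: SimConfig | None = None,
                         alpha: float = 0.05, seed: int = 0,
                         max_iter: int = 50) -> pd.DataFrame:
    """Replicate the sensitivity study over a pleiotropy grid.

    For each (mode, proportion) cell, ``n_reps`` datasets are generated and
    analysed with the radial MVMR estimator with and without iterative
    outlier pruning.  Returns a tidy table with, per exposure and analysis:
    the mean estimate, the empirical SE (SD of estimates across replicates),
    the mean exposure Q with its mean p-value, the mean conditional F and
    the mean number of SNPs retained.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    base = base_config or SimConfig.simulation_two(0.0, "balanced",
                                                   n_per_sample=100_000)
    root = np.random.SeedSequence(seed)
    rows = []
    for mode in modes:
        for prop in proportions:
            est = {False: [], True: []}
            qs = {False: [], True: []}
            qp = {False: [], True: []}
            fs = {False: [], True: []}
            ns = {False: [], True: []}
            for child in root.spawn(n_reps):
                cfg = replace(base, pleiotropy_proportion=float(prop),
                              pleiotropy_mode=mode,
                              seed=int(child.generate_state(1)[0] % (2 ** 31)))
                ds = generate_individual_data(cfg).dataset
                fit = fit_radial_mvmr(ds)
                pruned = prune_iterative(ds, alpha=alpha, max_iter=max_iter).final_fit
                for is_pruned, f in ((False, fit), (True, pruned)):
                    est[is_pruned].append(f.beta)
                    qs[is_pruned].append(f.Q_exposure)
                    qp[is_pruned].append(f.Q_p_values)
                    fs[is_pruned].append(f.conditional_F)
                    ns[is_pruned].append(f.n_snps_used)
            for is_pruned in (False, True):
                b = np.array(est[is_pruned])
                for k, name in enumerate(ds.exposure_names):
                    rows.append({
                        "mode": mode, "pleiotropy_proportion": float(prop),
                        "pruned": is_pruned, "exposure": name,
                        "mean_estimate": b[:, k].mean(),
                        "empirical_se": b[:, k].std(ddof=1) if n_reps > 1 else np.nan,
                        "mean_Q": np.array(qs[is_pruned])[:, k].mean(),
                        "mean_Q_p_value": np.array(qp[is_pruned])[:, k].mean(),
                        "mean_conditional_F": np.array(fs[is_pruned])[:, k].mean(),
                        "mean_n_snps": float(np.mean(ns[is_pruned])),
                        "n_reps": n_reps,
                    })
    return pd.DataFrame(rows)
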