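"""Summary-data model and delimited-text I/O.

The unit of analysis is a harmonised two-sample summary dataset: for each of
J independent SNPs, an estimated association with every exposure (``gamma``,
with standard errors ``se_gamma``) and with the outcome (``Gamma``, standard
error ``se_Gamma``).  Effect alleles are assumed to be aligned across all
columns upstream; no strand or palindrome handling is performed here.

The flat-file convention is tab-separated text with columns

    snp  beta.<exposure>  se.<exposure> ...  beta.outcome  se.outcome

one row per SNP, matching the usual two-sample summary-data ecosystem.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["SummaryDataset", "RadialPoint", "format_dataset", "read_dataset",
           "write_dataset", "write_results"]


@dataclass(frozen=True)
class SummaryDataset:
    """Harmonised per-SNP GWAS summary statistics for K exposures and one outcome.

    Attributes
    ----------
    snp_ids : list of str
        Unique SNP identifiers, length J.
    exposure_names : list of str
        Exposure labels, length K; column order is preserved in all outputs.
    gamma : (J, K) ndarray
        SNP-exposure associations (per-allele effect units).
    se_gamma : (J, K) ndarray
        Standard errors of ``gamma``; strictly positive.
    Gamma : (J,) ndarray
        SNP-outcome associations.
    se_Gamma : (J,) ndarray
        Standard errors of ``Gamma``; strictly positive.
    """

    snp_ids: list[str]
    exposure_names: list[str]
    gamma: np.ndarray
    se_gamma: np.ndarray
    Gamma: np.ndarray
    se_Gamma: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "snp_ids", [str(s) for s in self.snp_ids])
        object.__setattr__(self, "exposure_names", [str(e) for e in self.exposure_names])
        gamma = np.atleast_2d(np.asarray(self.gamma, dtype=float))
        se_gamma = np.atleast_2d(np.asarray(self.se_gamma, dtype=float))
        Gamma = np.asarray(self.Gamma, dtype=float).ravel()
        se_Gamma = np.asarray(self.se_Gamma, dtype=float).ravel()
        J, K = gamma.shape
        if len(self.snp_ids) != J or Gamma.shape != (J,) or se_Gamma.shape != (J,):
            raise ValueError("inconsistent number of SNPs across fields")
        if len(self.exposure_names) != K or se_gamma.shape != (J, K):
            raise ValueError("inconsistent number of exposures across fields")
        if len(set(self.snp_ids)) != J:
            dup = sorted({s for s in self.snp_ids if self.snp_ids.count(s) > 1})
            raise ValueError(f"duplicate SNP ids: {', '.join(dup)}")
        for name, arr in (("gamma", gamma), ("se_gamma", se_gamma),
                          ("Gamma", Gamma), ("se_Gamma", se_Gamma)):
            if not np.isfinite(arr).all():
                raise ValueError(f"non-finite values in {name}")
        for name, bad_rows in (("se_gamma", (se_gamma <= 0).any(axis=1)),
                               ("se_Gamma", se_Gamma <= 0)):
            if bad_rows.any():
                snps = [self.snp_ids[j] for j in np.nonzero(bad_rows)[0]]
                raise ValueError(f"non-positive standard error in {name} for SNP(s): "
                                 f"{', '.join(snps)}")
        object.__setattr__(self, "gamma", gamma)
        object.__setattr__(self, "se_gamma", se_gamma)
        object.__setattr__(self, "Gamma", Gamma)
        object.__setattr__(self, "se_Gamma", se_Gamma)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_exposures(self) -> int:
        return len(self.exposure_names)

    def subset(self, mask_or_ids) -> "SummaryDataset":
        """Restrict to a boolean mask over rows or an iterable of SNP ids."""
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            idx = np.nonzero(mask_or_ids)[0]
        else:
            wanted = set(map(str, mask_or_ids))
            idx = np.array([j for j, s in enumerate(self.snp_ids) if s in wanted], dtype=int)
        return SummaryDataset(
            snp_ids=[self.snp_ids[j] for j in idx],
            exposure_names=list(self.exposure_names),
            gamma=self.gamma[idx],
            se_gamma=self.se_gamma[idx],
            Gamma=self.Gamma[idx],
            se_Gamma=self.se_Gamma[idx],
        )

    def drop(self, snp_ids) -> "SummaryDataset":
        """Remove the given SNP ids."""
        unwanted = set(map(str, snp_ids))
        keep = np.array([s not in unwanted for s in self.snp_ids])
        return self.subset(keep)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with the package's flat-file column vocabulary."""
        data: dict[str, object] = {"snp": self.snp_ids}
        for k, name in enumerate(self.exposure_names):
            data[f"beta.{name}"] = self.gamma[:, k]
            data[f"se.{name}"] = self.se_gamma[:, k]
        data["beta.outcome"] = self.Gamma
        data["se.outcome"] = self.se_Gamma
        return pd.DataFrame(data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SummaryDataset):
            return NotImplemented
        return (self.snp_ids == other.snp_ids
                and self.exposure_names == other.exposure_names
                and np.array_equal(self.gamma, other.gamma)
                and np.array_equal(self.se_gamma, other.se_gamma)
                and np.array_equal(self.Gamma, other.Gamma)
                and np.array_equal(self.se_Gamma, other.se_Gamma))


@dataclass(frozen=True)
class RadialPoint:
    """One plottable observation of a radial MVMR plot.

    ``x`` is the square-root weight |γ̂_kj|/σ̂_Yj (non-negative); the point is
    reflected through the origin when γ̂_kj < 0 so that y/x always equals the
    univariable ratio estimate Γ̂_j/γ̂_kj.  ``y_adjusted`` subtracts the fitted
    contributions of the other exposures, after which the vertical distance to
    the exposure's fitted line is the square-root heterogeneity contribution.
    """

    snp_id: str
    exposure: str
    x: float
    y_unadjusted: float
    y_adjusted: float
    per_exposure_F: float


def format_dataset(raw_table: pd.DataFrame, exposure_names: Sequence[str] | None = None,
                   ) -> SummaryDataset:
    """Validate a raw summary-statistics table into a :class:`SummaryDataset`.

    Parameters
    ----------
    raw_table : DataFrame
        One row per SNP with columns ``snp``, ``beta.<exposure>`` and
        ``se.<exposure>`` for each exposure, and ``beta.outcome`` /
        ``se.outcome``.
    exposure_names : sequence of str, optional
        Exposure labels to use, in order.  Default: inferred from the
        ``beta.*`` columns in their order of appearance.

    Rows containing any missing or non-finite field are dropped with a logged
    count.  Duplicate SNP ids, non-positive standard errors and fewer than
    K+1 complete rows raise ``ValueError``.
    """
    df = pd.DataFrame(raw_table)
    if "snp" not in df.columns:
        raise ValueError("input table must contain a 'snp' column")
    if exposure_names is None:
        exposure_names = [c[len("beta."):] for c in df.columns
                          if c.startswith("beta.") and c != "beta.outcome"]
    exposure_names = [str(e) for e in exposure_names]
    if not exposure_names:
        raise ValueError("no exposures found (expected beta.<exposure> columns)")
    cols = []
    for name in exposure_names:
        for c in (f"beta.{name}", f"se.{name}"):
            if c not in df.columns:
                raise ValueError(f"missing column {c!r}")
            cols.append(c)
    for c in ("beta.outcome", "se.outcome"):
        if c not in df.columns:
            raise ValueError(f"missing column {c!r}")
        cols.append(c)

    snp = df["snp"].astype(str)
    dup = snp[snp.duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicate SNP ids: {', '.join(sorted(dup))}")

    values = df[cols].apply(pd.to_numeric, errors="coerce")
    complete = np.isfinite(values.to_numpy(dtype=float)).all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("format_dataset: dropped %d row(s) with missing or non-finite fields",
                    n_dropped)
    df = df.loc[complete]
    values = values.loc[complete]

    K = len(exposure_names)
    if len(df) < K + 1:
        raise ValueError(f"need at least K+1={K + 1} complete rows, got {len(df)}")

    for name in exposure_names + ["outcome"]:
        se = values[f"se.{name}"].to_numpy(dtype=float)
        if (se <= 0).any():
            bad = df["snp"].astype(str).to_numpy()[se <= 0]
            raise ValueError(f"non-positive se.{name} for SNP(s): {', '.join(bad)}")

    return SummaryDataset(
        snp_ids=df["snp"].astype(str).tolist(),
        exposure_names=exposure_names,
        gamma=values[[f"beta.{e}" for e in exposure_names]].to_numpy(dtype=float),
        se_gamma=values[[f"se.{e}" for e in exposure_names]].to_numpy(dtype=float),
        Gamma=values["beta.outcome"].to_numpy(dtype=float),
        se_Gamma=values["se.outcome"].to_numpy(dtype=float),
    )


def read_dataset(path, exposure_names: Sequence[str] | None = None) -> SummaryDataset:
    """Read a tab-separated summary-statistics file (see :func:`format_dataset`)."""
    return format_dataset(pd.read_csv(path, sep="\t", float_precision="round_trip"),
                          exposure_names)


def write_dataset(ds: SummaryDataset, path) -> None:
    """Write a dataset as tab-separated text; numeric text round-trips exactly."""
    ds.to_frame().to_csv(path, sep="\t", index=False)


def write_results(fit, path) -> tuple[Path, Path]:
    """Write a fit's per-exposure summary and per-SNP Q tables as TSV.

    ``path`` is used as a prefix: ``<path>.exposures.tsv`` holds one row per
    exposure (estimate, SE, p, Q, Q p-value, conditional F when available) and
    ``<path>.snp_q.tsv`` one row per (SNP, exposure) with Q_kj and its p-value.
    Returns the two paths written.
    """
    prefix = Path(path)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    summary_path = prefix.with_name(prefix.name + ".exposures.tsv")
    snp_path = prefix.with_name(prefix.name + ".snp_q.tsv")
    fit.summary().to_csv(summary_path, sep="\t", index=False)
    fit.per_snp_table().to_csv(snp_path, sep="\t", index=False)
    return summary_path, snp_path
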