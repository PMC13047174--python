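"""Taylor's power-law fits and the standardized V–β parameter space.

For one subject followed over time, each feature i has a temporal mean μ_i and
standard deviation σ_i of its relative abundance.  Microbial time series obey
Taylor's power law σ = V·μ^β: β = 1/2 corresponds to Poisson-like fluctuation,
β = 1 to exponential-like fluctuation, and V is the dispersion a hypothetical
feature of relative abundance ~1 would attain.  Per-subject (V, β) estimates
come from ordinary least squares of log10 σ on log10 μ; cohorts are compared
in a z-scored parameter space relative to a reference group, with
bivariate-normal coverage regions (68% / 98%) analogous to confidence
ellipses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import FeatureTable, SampleMetadata, to_relative

__all__ = [
    "TaylorFit",
    "CoverageEllipse",
    "temporal_moments",
    "fit_taylor",
    "fit_cohort",
    "standardize_params",
    "reference_region",
]

logger = logging.getLogger(__name__)


@dataclass
class TaylorFit:
    """Per-subject Taylor's-law parameters with fit diagnostics."""

    subject_id: Optional[str]
    V: float
    beta: float
    n_features_used: int
    r_squared: float
    se_V: float
    se_beta: float
    z_V: Optional[float] = None
    z_beta: Optional[float] = None


def temporal_moments(series) -> tuple[np.ndarray, np.ndarray]:
    """Temporal mean and SD (denominator n−1) per feature.

    ``series`` is a timepoints × features matrix of relative abundances for a
    single subject; at least 3 time points are required for a meaningful SD.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 2:
        raise ValueError("series must be a timepoints × features matrix")
    if x.shape[0] < 3:
        raise ValueError(f"temporal moments require ≥ 3 timepoints, got {x.shape[0]}")
    return x.mean(axis=0), x.std(axis=0, ddof=1)


def fit_taylor(moments, min_features: int = 20, subject_id: Optional[str] = None,
               log_base: float = 10.0) -> TaylorFit:
    """OLS fit of the power law σ = V·μ^β in log space.

    ``moments`` is the (μ, σ) pair from :func:`temporal_moments`.  Features
    with μ = 0 or σ = 0 are excluded (their logarithm is undefined); the fit
    requires at least ``min_features`` remaining.  β is the slope — invariant
    to the log base — and V is the back-transformed intercept.
    """
    mu, sd = (np.asarray(m, dtype=float) for m in moments)
    keep = (mu > 0) & (sd > 0)
    n_used = int(keep.sum())
    dropped = mu.size - n_used
    if dropped:
        logger.debug("fit_taylor: excluded %d features with zero mean or SD", dropped)
    if n_used < min_features:
        raise ValueError(
            f"only {n_used} features usable after filtering; need ≥ {min_features}"
        )
    lx = np.log(mu[keep]) / np.log(log_base)
    ly = np.log(sd[keep]) / np.log(log_base)
    res = stats.linregress(lx, ly)
    V = float(log_base ** res.intercept)
    # delta method: se(V) = |dV/d intercept| * se(intercept) = V ln(base) se
    se_V = float(V * np.log(log_base) * res.intercept_stderr)
    return TaylorFit(
        subject_id=subject_id,
        V=V,
        beta=float(res.slope),
        n_features_used=n_used,
        r_squared=float(res.rvalue ** 2),
        se_V=se_V,
        se_beta=float(res.stderr),
    )


def fit_cohort(table: FeatureTable, meta: SampleMetadata,
               min_features: int = 20, min_timepoints: int = 3) -> pd.DataFrame:
    """Fit Taylor's law for every subject in a cohort table.

    Counts tables are converted to relative abundances first.  Returns one row
    per successfully fitted subject (subject_id, group, V, beta, diagnostics);
    subjects with too few time points or usable features are skipped with a
    log message.
    """
    meta.require_samples(table)
    rel = to_relative(table) if table.mode == "counts" else table
    md = meta.data.loc[rel.data.index]
    rows = []
    for subject, sub_md in md.groupby("subject_id", sort=True):
        ordered = sub_md.sort_values("timepoint")
        if ordered["timepoint"].nunique() < min_timepoints:
            logger.warning("subject %s has < %d timepoints; skipped", subject,
                           min_timepoints)
            continue
        series = rel.data.loc[ordered.index].to_numpy()
        try:
            fit = fit_taylor(temporal_moments(series), min_features=min_features,
                             subject_id=subject)
        except ValueError as exc:
            logger.warning("subject %s not fitted: %s", subject, exc)
            continue
        rows.append({
            "subject_id": subject,
            "group": sub_md["group"].iloc[0],
            "V": fit.V,
            "beta": fit.beta,
            "n_features_used": fit.n_features_used,
            "r_squared": fit.r_squared,
            "se_V": fit.se_V,
            "se_beta": fit.se_beta,
        })
    return pd.DataFrame(rows)


def standardize_params(fits: pd.DataFrame, reference_group: str) -> pd.DataFrame:
    """Standardize (V, β) to z-scores against a reference group.

    z_V = (V − mean_ref(V)) / sd_ref(V), likewise z_beta; the reference group
    itself then has mean 0 and SD 1 on both axes.
    """
    ref = fits[fits["group"] == reference_group]
    if len(ref) < 3:
        raise ValueError(
            f"reference group {reference_group!r} has {len(ref)} fits; need ≥ 3"
        )
    out = fits.copy()
    for col, zcol in (("V", "z_V"), ("beta", "z_beta")):
        mean = ref[col].mean()
        sd = ref[col].std(ddof=1)
        if sd == 0:
            raise ValueError(f"reference group has zero spread in {col}")
        out[zcol] = (out[col] - mean) / sd
    return out


@dataclass
class CoverageEllipse:
    """Bivariate-normal coverage region in the standardized (z_V, z_beta) plane."""

    center: np.ndarray
    cov: np.ndarray
    coverage: float
    radius2: float  # chi-square(2) quantile for the coverage level

    def mahalanobis_sq(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - self.center
        return np.einsum("ij,jk,ik->i", pts, np.linalg.inv(self.cov), pts)

    def contains(self, points) -> np.ndarray:
        """Boolean membership for an (n, 2) array of standardized points."""
        return self.mahalanobis_sq(points) <= self.radius2

    @property
    def axes_and_angle(self) -> tuple[float, float, float]:
        """Semi-axis lengths (major, minor) and orientation angle in radians."""
        evals, evecs = np.linalg.eigh(self.cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        a, b = np.sqrt(evals * self.radius2)
        angle = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
        return float(a), float(b), angle


def reference_region(fits: pd.DataFrame, coverage: float = 0.68,
                     reference_group: Optional[str] = None) -> CoverageEllipse:
    """Coverage ellipse of the reference group in standardized coordinates.

    Fits must carry ``z_V``/``z_beta`` columns (see :func:`standardize_params`).
    The region is the bivariate-normal ellipse at the chi-square(2) quantile
    of the requested coverage (0.68 and 0.98 are the conventional inner/outer
    regions).
    """
    if not 0 < coverage < 1:
        raise ValueError("coverage must lie in (0, 1)")
    if {"z_V", "z_beta"} - set(fits.columns):
        raise ValueError("fits lack standardized coordinates; run standardize_params")
    ref = fits if reference_group is None else fits[fits["group"] == reference_group]
    if len(ref) < 5:
        raise ValueError(f"need ≥ 5 reference fits, got {len(ref)}")
    pts = ref[["z_V", "z_beta"]].to_numpy()
    cov = np.cov(pts, rowvar=False, ddof=1)
    if np.linalg.matrix_rank(cov) < 2 or np.linalg.det(cov) <= 0:
        raise ValueError("degenerate covariance of reference points")
    return CoverageEllipse(
        center=pts.mean(axis=0),
        cov=cov,
        coverage=coverage,
        radius2=float(stats.chi2.ppf(coverage, df=2)),
    )
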