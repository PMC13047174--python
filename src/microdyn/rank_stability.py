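"""Rank trajectories and the rank stability index (RSI).

At each time point the features of one subject (or of a group-pooled series)
are ranked by abundance, rank 1 being the most abundant.  A feature's total
rank displacement D across consecutive time points is turned into

    RSI = (1 − D / ((N − 1)(t − 1)))^p

with N ranked features and t time points: 1 for a feature whose rank never
changes, 0 for one oscillating between the extreme ranks.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io_tables import FeatureTable, SampleMetadata, to_relative

__all__ = ["rank_series", "rank_hops", "rsi", "rsi_profile"]


def rank_series(series) -> np.ndarray:
    """Rank features at each time point (1 = most abundant).

    ``series`` is a timepoints × features array.  Ties are broken
    deterministically by ascending feature position (column order), so equal
    abundances receive distinct, reproducible ranks.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 2:
        raise ValueError("series must be a timepoints × features matrix")
    t, n = x.shape
    if n < 2:
        raise ValueError("ranking requires at least 2 features")
    if t < 2:
        raise ValueError("ranking requires at least 2 timepoints")
    ranks = np.empty((t, n), dtype=np.int64)
    cols = np.arange(n)
    for k in range(t):
        order = np.lexsort((cols, -x[k]))  # descending abundance, then column
        ranks[k, order] = np.arange(1, n + 1)
    return ranks


def rank_hops(ranks) -> int:
    """Total rank displacement D = Σ_k |rank_{k+1} − rank_k| of one feature."""
    r = np.asarray(ranks)
    if r.ndim != 1 or r.size < 2:
        raise ValueError("rank trajectory must be 1-D with length ≥ 2")
    return int(np.abs(np.diff(r)).sum())


def rsi(D: float, N: int, t: int, p: float = 1.0) -> float:
    """Rank stability index (1 − D/((N−1)(t−1)))^p ∈ [0, 1]."""
    if N < 2 or t < 2:
        raise ValueError("RSI requires N ≥ 2 features and t ≥ 2 timepoints")
    if p <= 0:
        raise ValueError("exponent p must be positive")
    dmax = (N - 1) * (t - 1)
    if not 0 <= D <= dmax:
        raise ValueError(f"D={D} outside [0, {dmax}] for N={N}, t={t}")
    return float((1.0 - D / dmax) ** p)


def _unit_rsi(sub: pd.DataFrame, p: float) -> pd.Series:
    """RSI per feature for one unit's timepoints × features abundance frame.

    Features never observed in the unit are excluded (they carry no
    dynamics); the rest are ranked at every time point, zeros tied at the
    bottom and broken by feature identifier.
    """
    observed = sub.columns[(sub.to_numpy() > 0).any(axis=0)]
    sub = sub[sorted(observed)]
    t, n = sub.shape
    if n < 2:
        raise ValueError("unit has fewer than 2 observed features")
    ranks = rank_series(sub.to_numpy())
    d = np.abs(np.diff(ranks, axis=0)).sum(axis=0)
    dmax = (n - 1) * (t - 1)
    return pd.Series((1.0 - d / dmax) ** p, index=sub.columns)


def rsi_profile(table: FeatureTable, meta: SampleMetadata, scope: str = "subject",
                p: float = 1.0) -> pd.DataFrame:
    """Per-feature RSI values for every subject (or group).

    ``scope="subject"`` ranks each subject's own time series;
    ``scope="group"`` first averages relative abundances across the group's
    subjects at each time point and ranks the pooled series.  Units with a
    single time point are skipped with a warning.

    Returns a features × units frame; features absent from a unit are NaN.
    """
    if scope not in ("subject", "group"):
        raise ValueError("scope must be 'subject' or 'group'")
    meta.require_samples(table)
    rel = to_relative(table) if table.mode == "counts" else table
    md = meta.data.loc[rel.data.index]
    key = "subject_id" if scope == "subject" else "group"
    profiles = {}
    for unit, sub_md in md.groupby(key, sort=True):
        if scope == "subject":
            ordered = sub_md.sort_values("timepoint")
            if ordered["timepoint"].nunique() < 2:
                warnings.warn(f"{key} {unit!r} has fewer than 2 timepoints; skipped")
                continue
            series = rel.data.loc[ordered.index]
        else:
            pooled = (
                rel.data.loc[sub_md.index]
                .groupby(sub_md["timepoint"])
                .mean()
                .sort_index()
            )
            if len(pooled) < 2:
                warnings.warn(f"{key} {unit!r} has fewer than 2 timepoints; skipped")
                continue
            series = pooled
        profiles[unit] = _unit_rsi(series, p)
    out = pd.DataFrame(profiles)
    out.index.name = "feature_id"
    out.columns.name = key
    return out
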