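"""Alpha diversity, pairwise similarity and the nonparametric tests around them.

Shannon entropy is reported in nats.  Chao1 uses the bias-corrected form,
which is defined even when no doubletons are observed.  Hypothesis tests wrap
scipy's implementations (exact p-values for small samples without ties,
normal approximation with tie/continuity corrections otherwise) and return a
uniform :class:`TestResult` record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import FeatureTable, SampleMetadata, to_relative

__all__ = [
    "TestResult",
    "shannon",
    "chao1",
    "observed_richness",
    "jaccard_index",
    "bray_curtis",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "bh_fdr",
    "alpha_series",
    "paired_endpoint_difference",
]


@dataclass
class TestResult:
    """Outcome of a single hypothesis test."""

    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]
    fdr_q: Optional[float] = None

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


def _as_vector(x, name="counts") -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if (v < 0).any():
        raise ValueError(f"{name} contains negative entries")
    return v


def shannon(counts) -> float:
    """Shannon diversity H = −Σ p_i ln p_i, in nats."""
    v = _as_vector(counts)
    total = v.sum()
    if total <= 0:
        raise ValueError("cannot compute Shannon diversity of an all-zero vector")
    p = v[v > 0] / total
    return float(-(p * np.log(p)).sum())


def observed_richness(counts) -> int:
    return int((_as_vector(counts) > 0).sum())


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1−1)/(2(F2+1)).

    Requires integer counts; singleton/doubleton frequencies are meaningless
    on relative abundances.
    """
    v = _as_vector(counts)
    if not np.allclose(v, np.round(v)):
        raise ValueError("Chao1 requires integer counts")
    v = np.round(v).astype(np.int64)
    s_obs = int((v > 0).sum())
    f1 = int((v == 1).sum())
    f2 = int((v == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def jaccard_index(a, b, presence_threshold: float = 0.0) -> float:
    """Fraction of shared features: |A ∩ B| / |A ∪ B| on presence sets.

    A feature is present when its abundance exceeds ``presence_threshold``.
    """
    av = _as_vector(a, "a") > presence_threshold
    bv = _as_vector(b, "b") > presence_threshold
    if av.shape != bv.shape:
        raise ValueError("samples live in different feature spaces")
    union = (av | bv).sum()
    if union == 0:
        raise ValueError("Jaccard undefined: both samples are empty")
    return float((av & bv).sum() / union)


def bray_curtis(a, b) -> float:
    """Bray-Curtis dissimilarity Σ|a_i − b_i| / Σ(a_i + b_i)."""
    av = _as_vector(a, "a")
    bv = _as_vector(b, "b")
    if av.shape != bv.shape:
        raise ValueError("samples live in different feature spaces")
    denom = (av + bv).sum()
    if denom <= 0:
        raise ValueError("Bray-Curtis undefined: both samples are all-zero")
    return float(np.abs(av - bv).sum() / denom)


def mann_whitney(x, y, alternative: str = "two-sided") -> TestResult:
    """Mann–Whitney U test between two independent samples."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size == 0 or yv.size == 0:
        raise ValueError("Mann–Whitney requires non-empty samples")
    res = stats.mannwhitneyu(xv, yv, alternative=alternative, method="auto")
    return TestResult(float(res.statistic), float(res.pvalue), "mann-whitney",
                      (xv.size, yv.size))


def wilcoxon_signed_rank(d, alternative: str = "two-sided") -> TestResult:
    """Wilcoxon signed-rank test on paired differences (zeros dropped)."""
    dv = np.asarray(d, dtype=float)
    dv = dv[dv != 0]
    if dv.size == 0:
        raise ValueError("all paired differences are zero")
    res = stats.wilcoxon(dv, alternative=alternative, correction=True, method="auto")
    return TestResult(float(res.statistic), float(res.pvalue), "wilcoxon", (dv.size,))


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    ok = ~np.isnan(p)
    q = np.full_like(p, np.nan)
    if ok.any():
        if p[ok].min() < 0 or p[ok].max() > 1:
            raise ValueError("p-values must lie in [0, 1]")
        q[ok] = stats.false_discovery_control(p[ok], method="bh")
    return q


# ---------------------------------------------------------------------------
# cohort-level alpha diversity


def _rarefy(counts: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    out = np.zeros_like(counts)
    for i, row in enumerate(counts):
        total = int(row.sum())
        picked = rng.choice(np.repeat(np.arange(row.size), row.astype(int)),
                            size=depth, replace=False)
        np.add.at(out[i], picked, 1)
    return out


def alpha_series(table: FeatureTable, meta: SampleMetadata,
                 rarefy: bool = False, seed: int = 0) -> pd.DataFrame:
    """Per-sample Shannon and Chao1, joined to subject/group/timepoint.

    Computed on raw counts by default; ``rarefy=True`` subsamples every sample
    to the minimum observed depth first (seeded).
    """
    if table.mode != "counts":
        raise ValueError("alpha diversity requires a counts-mode table")
    meta.require_samples(table)
    counts = table.data.to_numpy()
    if rarefy:
        depth = int(counts.sum(axis=1).min())
        counts = _rarefy(counts, depth, np.random.default_rng(seed))
    records = []
    md = meta.data
    for sid, row in zip(table.data.index, counts):
        records.append({
            "sample_id": sid,
            "shannon": shannon(row),
            "chao1": chao1(row),
            "richness": observed_richness(row),
            "subject_id": md.at[sid, "subject_id"],
            "group": md.at[sid, "group"],
            "timepoint": int(md.at[sid, "timepoint"]),
        })
    return pd.DataFrame(records).set_index("sample_id")


def paired_endpoint_difference(alpha: pd.DataFrame, metric: str = "shannon",
                               t_first: int = 1, t_last: int = 10) -> pd.DataFrame:
    """First-to-last time point change in an alpha-diversity metric.

    Per subject the difference metric@t_last − metric@t_first is formed
    (subjects missing either endpoint are dropped with a warning).  Each
    group's differences are tested against zero (Wilcoxon signed-rank) and
    every group pair is compared (Mann–Whitney on the differences);
    Benjamini–Hochberg correction is applied across the whole family.

    Returns a frame with columns comparison, kind, statistic, p_value, q_value,
    n and mean_difference.
    """
    if metric not in alpha.columns:
        raise ValueError(f"metric {metric!r} not in alpha series")
    first = alpha[alpha["timepoint"] == t_first].set_index("subject_id")[metric]
    last = alpha[alpha["timepoint"] == t_last].set_index("subject_id")[metric]
    complete = first.index.intersection(last.index)
    dropped = set(first.index).symmetric_difference(last.index)
    if dropped:
        warnings.warn(f"subjects missing an endpoint dropped: {sorted(dropped)}")
    diffs = (last.loc[complete] - first.loc[complete]).rename("difference")
    groups = alpha.drop_duplicates("subject_id").set_index("subject_id")["group"]
    by_group = {g: diffs.loc[[s for s in complete if groups[s] == g]]
                for g in sorted(groups.loc[complete].unique())}

    rows = []
    for g, d in by_group.items():
        if len(d) < 2:
            warnings.warn(f"group {g!r} has fewer than 2 complete subjects; skipped")
            continue
        try:
            res = wilcoxon_signed_rank(d.values)
            stat, p = res.statistic, res.p_value
        except ValueError:  # all differences zero
            stat, p = np.nan, np.nan
        rows.append({"comparison": g, "kind": "within-group", "statistic": stat,
                     "p_value": p, "n": len(d), "mean_difference": float(d.mean())})
    group_names = [g for g, d in by_group.items() if len(d) >= 2]
    for i, ga in enumerate(group_names):
        for gb in group_names[i + 1:]:
            res = mann_whitney(by_group[ga].values, by_group[gb].values)
            rows.append({"comparison": f"{ga} vs {gb}", "kind": "between-groups",
                         "statistic": res.statistic, "p_value": res.p_value,
                         "n": len(by_group[ga]) + len(by_group[gb]),
                         "mean_difference": float(by_group[ga].mean() - by_group[gb].mean())})
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    return out
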