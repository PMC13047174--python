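"""Distance matrices, ordination, PERMANOVA and consecutive-pair stability.

PERMANOVA is implemented from the distance-based sums of squares: with n
samples in a groups,

    SS_total  = Σ_{i<j} d²_ij / n
    SS_within = Σ_g Σ_{i<j ∈ g} d²_ij / n_g
    F = (SS_between / (a − 1)) / (SS_within / (n − a))

and the p-value is obtained by permuting group labels, counting the observed
statistic among the permutations so p ≥ 1/(n_perm + 1).  An exhaustive mode
enumerates every distinct label assignment for small n.  Ordination is
classical PCoA (Gower double-centering) via scikit-bio.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
import skbio

from .io_tables import FeatureTable, SampleMetadata, aggregate_median_by_subject, to_relative
from .diversity import TestResult, alpha_series, bh_fdr, mann_whitney

__all__ = [
    "DistanceMatrix",
    "PermanovaResult",
    "distance_matrix",
    "rsi_distance_matrix",
    "pcoa",
    "permanova",
    "consecutive_stability",
    "stability_tests",
    "event_split_compare",
]

_METRICS = ("jaccard", "bray_curtis", "euclidean")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with sample identifiers."""

    ids: list
    data: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.abs(np.diag(self.data)).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix diagonal must be zero")
        if (self.data < 0).any():
            raise ValueError("distances must be non-negative")

    def to_skbio(self) -> "skbio.DistanceMatrix":
        return skbio.DistanceMatrix(self.data, ids=[str(i) for i in self.ids])


def _nan_euclidean(x: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distance ignoring coordinates missing in either row."""
    n = x.shape[0]
    out = np.zeros((n, n))
    finite = ~np.isnan(x)
    for i in range(n):
        for j in range(i + 1, n):
            both = finite[i] & finite[j]
            if not both.any():
                raise ValueError("rows share no observed features")
            diff = x[i, both] - x[j, both]
            out[i, j] = out[j, i] = np.sqrt((diff ** 2).sum())
    return out


def distance_matrix(table, metric: str, presence_threshold: float = 0.0) -> DistanceMatrix:
    """All pairwise distances between the rows of a table.

    ``jaccard`` uses presence/absence (distance = 1 − similarity);
    ``bray_curtis`` expects abundances; ``euclidean`` tolerates NaNs by
    pairwise exclusion (used for rank-stability profiles).
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {_METRICS}")
    if isinstance(table, FeatureTable):
        df = table.data
    else:
        df = pd.DataFrame(table)
    if len(df) < 2:
        raise ValueError("need at least 2 rows")
    x = df.to_numpy(dtype=float)
    if metric == "jaccard":
        d = squareform(pdist(x > presence_threshold, metric="jaccard"))
    elif metric == "bray_curtis":
        d = squareform(pdist(x, metric="braycurtis"))
    else:
        d = _nan_euclidean(x) if np.isnan(x).any() else squareform(pdist(x))
    return DistanceMatrix(list(df.index), d, metric)


def rsi_distance_matrix(profiles: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distances between per-unit RSI profiles (features × units),
    with features missing from either unit excluded pairwise."""
    return distance_matrix(profiles.T, metric="euclidean")


def pcoa(dm: DistanceMatrix, n_axes: int = 2):
    """Principal coordinates analysis of a distance matrix.

    Returns (coordinates DataFrame, eigenvalues Series, proportion explained
    Series).  Gower double-centering of −d²/2 followed by eigendecomposition;
    negative eigenvalues of semimetric inputs are reported but not used for
    coordinates, and a request beyond the positive spectrum is truncated with
    a warning.
    """
    n = dm.data.shape[0]
    centering = np.eye(n) - np.full((n, n), 1.0 / n)
    gower = -0.5 * centering @ (dm.data ** 2) @ centering
    evals, evecs = np.linalg.eigh((gower + gower.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    eigvals = pd.Series(evals, name="eigenvalue")
    n_positive = int((evals > 1e-12).sum())
    if n_axes > n_positive:
        warnings.warn(
            f"requested {n_axes} axes but only {n_positive} positive eigenvalues; truncated"
        )
        n_axes = n_positive
    coords = pd.DataFrame(
        evecs[:, :n_axes] * np.sqrt(evals[:n_axes]),
        index=list(dm.ids),
        columns=[f"PC{i + 1}" for i in range(n_axes)],
    )
    positive_total = evals[evals > 0].sum()
    prop = pd.Series(np.where(evals > 0, evals / positive_total, 0.0),
                     name="proportion_explained")
    return coords, eigvals, prop


@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    df_between: int
    df_within: int
    seed: Optional[int] = None


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        mask = codes == g
        ng = int(mask.sum())
        ss_within += d2[np.ix_(mask, mask)].sum() / (2.0 * ng)
    ss_between = ss_total - ss_within
    return (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))


def permanova(dm: DistanceMatrix, labels, n_perm: int = 600,
              seed: Optional[int] = 0, permutations: str = "random") -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    ``labels`` assigns each sample to a group (aligned with ``dm.ids``).
    ``permutations="exhaustive"`` enumerates every distinct label arrangement
    instead of sampling (feasible only for small n); the observed assignment
    is then counted once among them.
    """
    labels = np.asarray(pd.Series(list(labels)).astype(str))
    if labels.size != len(dm.ids):
        raise ValueError("labels length does not match distance matrix")
    uniq, codes = np.unique(labels, return_inverse=True)
    a = uniq.size
    if a < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        small = uniq[sizes < 2].tolist()
        raise ValueError(f"groups with fewer than 2 members: {small}")
    d2 = dm.data ** 2
    n = d2.shape[0]
    f_obs = _pseudo_f(d2, codes, a)

    if permutations == "exhaustive":
        seen = set()
        count_ge = 0
        for perm in itertools.permutations(codes):
            if perm in seen:
                continue
            seen.add(perm)
            if _pseudo_f(d2, np.asarray(perm), a) >= f_obs - 1e-12:
                count_ge += 1
        total = len(seen)
        return PermanovaResult(f_obs, count_ge / total, total, a - 1, n - a, None)

    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_perm):
        if _pseudo_f(d2, rng.permutation(codes), a) >= f_obs - 1e-12:
            count_ge += 1
    p = (1 + count_ge) / (n_perm + 1)
    return PermanovaResult(f_obs, p, n_perm, a - 1, n - a, seed)


# ---------------------------------------------------------------------------
# consecutive-pair stability


def consecutive_stability(table: FeatureTable, meta: SampleMetadata,
                          level: str = "taxonomic",
                          presence_threshold: float = 0.0) -> pd.DataFrame:
    """Jaccard similarity between each subject's adjacent time-point samples.

    A missing time point breaks adjacency: if T2 is absent, neither T1→T2 nor
    T2→T3 is formed.  Subjects contributing no pair are dropped with a
    warning.  Returns rows (subject_id, group, interval, t_from,
    jaccard_similarity, level).
    """
    meta.require_samples(table)
    md = meta.data.loc[table.data.index]
    presence = table.data.to_numpy() > presence_threshold
    pos = {sid: k for k, sid in enumerate(table.data.index)}
    rows = []
    for subject, sub_md in md.groupby("subject_id", sort=True):
        ordered = sub_md.sort_values("timepoint")
        tps = ordered["timepoint"].to_numpy()
        sids = ordered.index.to_numpy()
        made_pair = False
        for k in range(len(tps) - 1):
            if tps[k + 1] != tps[k] + 1:
                continue
            A = presence[pos[sids[k]]]
            B = presence[pos[sids[k + 1]]]
            union = (A | B).sum()
            if union == 0:
                continue
            made_pair = True
            rows.append({
                "subject_id": subject,
                "group": sub_md["group"].iloc[0],
                "interval": f"T{tps[k]}-T{tps[k] + 1}",
                "t_from": int(tps[k]),
                "jaccard_similarity": float((A & B).sum() / union),
                "level": level,
            })
        if not made_pair:
            warnings.warn(f"subject {subject!r} has no adjacent time-point pair")
    return pd.DataFrame(rows)


def stability_tests(series: pd.DataFrame) -> pd.DataFrame:
    """Mann–Whitney comparisons of consecutive-pair Jaccard similarities.

    Two families, each FDR-corrected separately: within one group between
    pairs of intervals, and between groups at the same interval.  Cells with
    fewer than 2 observations are skipped.
    """
    rows = []
    intervals = sorted(series["t_from"].unique())
    groups = sorted(series["group"].unique())

    def cell(g, t):
        return series.loc[(series["group"] == g) & (series["t_from"] == t),
                          "jaccard_similarity"].to_numpy()

    for g in groups:
        for i, ta in enumerate(intervals):
            for tb in intervals[i + 1:]:
                xa, xb = cell(g, ta), cell(g, tb)
                if len(xa) < 2 or len(xb) < 2:
                    continue
                r = mann_whitney(xa, xb)
                rows.append({
                    "family": "within-group", "group": g,
                    "comparison": f"T{ta}-T{ta + 1} vs T{tb}-T{tb + 1}",
                    "statistic": r.statistic, "p_value": r.p_value,
                    "n": len(xa) + len(xb),
                })
    for t in intervals:
        for i, ga in enumerate(groups):
            for gb in groups[i + 1:]:
                xa, xb = cell(ga, t), cell(gb, t)
                if len(xa) < 2 or len(xb) < 2:
                    continue
                r = mann_whitney(xa, xb)
                rows.append({
                    "family": "between-groups", "group": f"{ga} vs {gb}",
                    "comparison": f"T{t}-T{t + 1}",
                    "statistic": r.statistic, "p_value": r.p_value,
                    "n": len(xa) + len(xb),
                })
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = np.nan
        for fam in out["family"].unique():
            mask = out["family"] == fam
            out.loc[mask, "q_value"] = bh_fdr(out.loc[mask, "p_value"].to_numpy())
    return out


def event_split_compare(table: FeatureTable, meta: SampleMetadata, event: str,
                        n_perm: int = 600, seed: int = 0,
                        metric: str = "bray_curtis") -> dict:
    """Compare community state before vs after a per-subject event.

    Subjects with samples on both sides are aggregated to per-side median
    relative-abundance profiles (at least 3 such subjects required);
    PERMANOVA with before/after labels tests the compositional shift, and
    Mann–Whitney tests on per-sample Shannon and Chao1 assess the diversity
    change.  ``table`` must be in counts mode.
    """
    if table.mode != "counts":
        raise ValueError("event_split_compare requires a counts-mode table")
    if event not in meta.data.columns:
        raise ValueError(f"event column {event!r} missing from metadata")
    md = meta.data
    status = md[event]
    sided = md[status.isin(["before", "after"])]
    per_subject = sided.groupby("subject_id")[event].nunique()
    both = per_subject[per_subject == 2].index
    if len(both) < 3:
        raise ValueError(
            f"need ≥ 3 subjects with samples on both sides of {event!r}, got {len(both)}"
        )
    keep = sided.index[sided["subject_id"].isin(both)]
    sub_table = FeatureTable(table.data.loc[keep], mode="counts")
    sub_meta = meta.subset(keep)

    agg, labels = aggregate_median_by_subject(to_relative(sub_table), sub_meta, event=event)
    dm = distance_matrix(agg, metric=metric)
    perm = permanova(dm, labels["event_status"], n_perm=n_perm, seed=seed)

    alpha = alpha_series(sub_table, sub_meta)
    side = sub_meta.data.loc[alpha.index, event]
    alpha_tests = {}
    for m in ("shannon", "chao1"):
        alpha_tests[m] = mann_whitney(alpha.loc[side == "before", m].to_numpy(),
                                      alpha.loc[side == "after", m].to_numpy())
    return {"permanova": perm, "alpha": alpha_tests,
            "n_subjects": int(len(both)),
            "n_samples": {"before": int((side == "before").sum()),
                          "after": int((side == "after").sum())}}
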