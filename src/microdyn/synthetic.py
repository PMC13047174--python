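"""Synthetic longitudinal cohorts with controlled Taylor-law structure.

The generator emulates a three-group cohort (toddlers, adolescents, adults)
sampled at ten time points: per-subject taxonomic count tables whose
mean–variance scaling follows Taylor's power law σ = V·μ^β at prescribed
group-level (V, β); a many-to-one taxa→function redundancy map projecting the
taxonomic counts onto a functional table; an optional early instability
window (a compositional turnover between the first two time points of one
group); and an optional weaning-like event that shifts composition and
evenness for part of one group.

Temporal fluctuation is generated as *balanced profiles*: for every feature a
non-negative temporal pattern with exact sample mean and sample standard
deviation matching the target power law, arranged randomly in time.  This
makes the realized SD–mean relation of each subject match (V, β) by
construction, up to multinomial sequencing noise at the configured depth
(which is subtracted from the latent variance where feasible).  Because the
sample coefficient of variation of non-negative data cannot exceed √t, target
CVs above that bound are capped at the spike-profile limit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .io_tables import FeatureTable, SampleMetadata

__all__ = [
    "SyntheticConfig",
    "CohortData",
    "balanced_profile",
    "simulate_taylor_subject",
    "simulate_iid_subject",
    "redundancy_map",
    "simulate_cohort",
]

logger = logging.getLogger(__name__)

#: age in months at the first time point, per group; steps of 4 months follow
_BASE_AGE_MONTHS = {"toddler": 20, "adolescent": 140, "adult": 420}


def balanced_profile(mean: float, sd: float, t: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Non-negative length-``t`` profile with exact sample mean and SD.

    For moderate dispersion the profile is a standardized Gaussian shape
    scaled to the target moments; when that would go negative, a spike
    profile (k elevated values, t−k depressed, chosen to stay ≥ 0) is used.
    Sample statistics use denominator t−1, matching the downstream moment
    estimator.  The sample CV of non-negative data is bounded by √t; targets
    beyond the bound are capped.
    """
    if t < 2:
        raise ValueError("profile needs at least 2 timepoints")
    if mean <= 0:
        raise ValueError("profile mean must be positive")
    if sd < 0:
        raise ValueError("profile SD must be non-negative")
    if sd == 0:
        return np.full(t, mean)
    cv = sd / mean
    z = rng.normal(size=t)
    if z.std(ddof=1) > 0:
        zs = (z - z.mean()) / z.std(ddof=1)
        if cv * zs.min() > -1.0:
            return mean * (1.0 + cv * zs)
    # spike profile: k entries at mean + (t-k)a, t-k entries at mean - k*a
    def cv_max(k: int) -> float:
        return np.sqrt(t * (t - k) / ((t - 1) * k))

    k = next((k for k in range(t - 1, 0, -1) if cv_max(k) >= cv), 1)
    capped = min(cv, cv_max(k) * (1.0 - 1e-9))
    if capped < cv:
        logger.debug("balanced_profile: CV %.3g capped at support bound %.3g",
                     cv, capped)
    alpha = capped * mean * np.sqrt((t - 1) / (t * k * (t - k)))
    x = np.full(t, mean - k * alpha)
    x[:k] = mean + (t - k) * alpha
    return rng.permutation(x)


def _log_uniform_means(n: int, lo: float, hi: float,
                       rng: np.random.Generator) -> np.ndarray:
    m = np.exp(rng.uniform(np.log(lo), np.log(hi), n))
    return m / m.sum()


def simulate_taylor_subject(n_features: int, V: float, beta: float,
                            n_timepoints: int = 10, depth: int = 100_000,
                            seed: Optional[int] = None,
                            rng: Optional[np.random.Generator] = None,
                            mean_range: tuple[float, float] = (1e-3, 3e-2),
                            means: Optional[np.ndarray] = None) -> np.ndarray:
    """One subject's timepoints × features count table obeying σ = V·μ^β.

    Feature mean abundances are log-uniform on ``mean_range`` (normalized to
    a composition) unless ``means`` is given.  Latent profile variance is
    reduced by the expected multinomial counting variance at ``depth`` so the
    observed relative abundances realize the target relation.  The default
    mean range keeps every feature in the regime where biological variance
    dominates sequencing noise at the default depth.
    """
    if V <= 0:
        raise ValueError("V must be positive")
    if not 0 < beta <= 1.5:
        raise ValueError("beta must lie in (0, 1.5]")
    if n_features < 20:
        raise ValueError("need at least 20 features")
    if n_timepoints < 2 or depth <= 0:
        raise ValueError("invalid timepoint count or depth")
    if rng is None:
        rng = np.random.default_rng(seed)
    if means is None:
        means = _log_uniform_means(n_features, *mean_range, rng)
    else:
        means = np.asarray(means, dtype=float)
        if means.shape != (n_features,) or (means <= 0).any():
            raise ValueError("means must be positive with length n_features")
        means = means / means.sum()
    target_var = (V * means ** beta) ** 2
    latent_var = np.maximum(target_var - means * (1 - means) / depth, 0.0)
    x = np.empty((n_timepoints, n_features))
    for i in range(n_features):
        x[:, i] = balanced_profile(means[i], np.sqrt(latent_var[i]), n_timepoints, rng)
    probs = x / x.sum(axis=1, keepdims=True)
    counts = np.empty_like(x, dtype=np.int64)
    for k in range(n_timepoints):
        counts[k] = rng.multinomial(depth, probs[k])
    return counts


def simulate_iid_subject(n_features: int, n_timepoints: int,
                         rng: np.random.Generator, dist: str = "exponential",
                         mean_range: tuple[float, float] = (1e-4, 1e-1)) -> np.ndarray:
    """Abundances drawn independently at each time point from a named family.

    ``"exponential"`` gives per-feature SD equal to the mean (β = 1, V = 1);
    ``"poisson"`` gives variance equal to the mean on the count scale
    (β = 1/2 on the SD scale).  Feature means are log-uniform on
    ``mean_range``.  Returns a timepoints × features abundance matrix.
    """
    lo, hi = mean_range
    means = np.exp(rng.uniform(np.log(lo), np.log(hi), n_features))
    if dist == "exponential":
        return rng.exponential(means, size=(n_timepoints, n_features))
    if dist == "poisson":
        return rng.poisson(means, size=(n_timepoints, n_features)).astype(float)
    raise ValueError(f"unknown distribution {dist!r}")


def redundancy_map(n_features: int, n_functions: int, redundancy: float,
                   seed: Optional[int] = None,
                   rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Binary taxa × functions incidence matrix.

    Every taxon maps to at least one function, every function receives at
    least one taxon (when shapes permit), and the mean number of taxa per
    function approximates ``redundancy``.  With ``redundancy = 1`` and equal
    shapes the result is a permutation matrix.
    """
    if redundancy < 1:
        raise ValueError("redundancy must be ≥ 1")
    if n_functions > n_features * redundancy:
        raise ValueError(
            f"infeasible: {n_functions} functions cannot each receive "
            f"~{redundancy} of {n_features} taxa"
        )
    target_edges = int(round(n_functions * redundancy))
    if target_edges > n_features * n_functions:
        raise ValueError("requested redundancy exceeds a full incidence matrix")
    if rng is None:
        rng = np.random.default_rng(seed)
    m = np.zeros((n_features, n_functions), dtype=np.int8)
    # phase 1: each taxon gets one function, cycling a shuffled function list
    shuffled = rng.permutation(n_functions)
    for i in range(n_features):
        m[i, shuffled[i % n_functions]] = 1
    # phase 2: cover any function still empty
    for j in np.flatnonzero(m.sum(axis=0) == 0):
        m[rng.integers(n_features), j] = 1
    # phase 3: add random absent edges up to the target count
    deficit = target_edges - int(m.sum())
    if deficit > 0:
        zeros = np.flatnonzero(m.ravel() == 0)
        picked = rng.choice(zeros, size=min(deficit, zeros.size), replace=False)
        m.ravel()[picked] = 1
    return m


@dataclass
class SyntheticConfig:
    """Study conditions for a simulated cohort.

    Defaults mirror the emulated study: 12 toddlers, 13 adolescents and 35
    adults followed over 10 time points at ~100,000 reads per sample, with
    toddlers the most volatile group, a compositional turnover between their
    first two time points, and a weaning-like event (three quarters of the
    toddlers weaned at an interior time point, the rest already weaned at
    entry) that shifts composition and increases evenness afterwards.
    """

    n_subjects: dict = field(default_factory=lambda: {
        "toddler": 12, "adolescent": 13, "adult": 35})
    n_timepoints: int = 10
    n_features: int = 300
    sequencing_depth: int = 100_000
    mean_range: tuple = (3e-6, 3e-2)
    subject_profile_sd: float = 0.6  # log-SD of per-subject deviation from the
    # shared cohort abundance template
    group_volatility: dict = field(default_factory=lambda: {
        "toddler": 0.35, "adolescent": 0.18, "adult": 0.15})
    group_beta: dict = field(default_factory=lambda: {
        "toddler": 0.75, "adolescent": 0.85, "adult": 0.85})
    subject_cv: float = 0.08  # between-subject lognormal jitter on V and beta
    n_functions: int = 100
    redundancy: float = 3.0
    instability_window: Optional[tuple] = ("toddler", (1, 2))
    event_name: Optional[str] = "weaning"
    event_group: str = "toddler"
    event_fraction: float = 0.75  # fraction with the event inside the study
    event_tilt: float = 2.2  # pre-event evenness tilt exponent (>1 = less even)
    event_shift_sd: float = 0.6  # log-SD of the shared post-event abundance shift
    seed: int = 0

    def validate(self) -> None:
        if self.n_timepoints < 2 or self.n_features < 20:
            raise ValueError("need ≥ 2 timepoints and ≥ 20 features")
        if self.sequencing_depth <= 0 or self.n_functions <= 0:
            raise ValueError("depth and function count must be positive")
        if self.redundancy < 1:
            raise ValueError("redundancy must be ≥ 1")
        if set(self.group_volatility) != set(self.n_subjects) or \
           set(self.group_beta) != set(self.n_subjects):
            raise ValueError("volatility/beta must be given for every group")
        for g, v in self.group_volatility.items():
            if v <= 0:
                raise ValueError(f"volatility for {g!r} must be positive")
        for g, b in self.group_beta.items():
            if not 0 < b <= 1.5:
                raise ValueError(f"beta for {g!r} must lie in (0, 1.5]")
        if any(n <= 0 for n in self.n_subjects.values()):
            raise ValueError("subject counts must be positive")
        if not 0 <= self.event_fraction <= 1:
            raise ValueError("event_fraction must lie in [0, 1]")


@dataclass
class CohortData:
    """A simulated cohort: taxa and function tables plus sample metadata."""

    taxa: FeatureTable
    functions: FeatureTable
    metadata: SampleMetadata
    redundancy_matrix: np.ndarray
    config: SyntheticConfig


def _tilt(means: np.ndarray, gamma: float) -> np.ndarray:
    tilted = means ** gamma
    return tilted / tilted.sum()


def simulate_cohort(cfg: SyntheticConfig) -> CohortData:
    """Simulate the full cohort described by ``cfg`` (deterministic per seed)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    T = cfg.n_timepoints
    rmap = redundancy_map(cfg.n_features, cfg.n_functions, cfg.redundancy, rng=rng)

    # shared cohort abundance template; subjects deviate from it log-normally
    template = _log_uniform_means(cfg.n_features, *cfg.mean_range, rng)
    # shared post-event shift: the same taxa rise or fall in every subject
    event_shift = np.exp(rng.normal(0.0, cfg.event_shift_sd, cfg.n_features))

    taxa_rows, meta_rows, sample_ids = [], [], []
    for group in cfg.n_subjects:
        V_g = cfg.group_volatility[group]
        beta_g = cfg.group_beta[group]
        has_event = cfg.event_name is not None and group == cfg.event_group
        for s in range(cfg.n_subjects[group]):
            subject = f"{group}{s + 1:02d}"
            V_s = V_g * float(np.exp(rng.normal(0, cfg.subject_cv)))
            beta_s = float(np.clip(beta_g * np.exp(rng.normal(0, cfg.subject_cv)),
                                   0.05, 1.5))
            base = template * np.exp(rng.normal(0, cfg.subject_profile_sd,
                                                cfg.n_features))
            base = base / base.sum()
            if has_event:
                weaned_in_study = s < round(cfg.event_fraction * cfg.n_subjects[group])
                # first "after" time point; 1 means already weaned at entry
                event_tp = int(rng.integers(2, T)) if weaned_in_study else 1
                shifted = base * event_shift
                shifted = shifted / shifted.sum()
                mean_traj = np.array([
                    _tilt(base, cfg.event_tilt) if tp < event_tp else shifted
                    for tp in range(1, T + 1)
                ])
            else:
                event_tp = None
                mean_traj = np.tile(base, (T, 1))

            ref_mean = mean_traj.mean(axis=0)
            target_var = (V_s * ref_mean ** beta_s) ** 2
            latent_var = np.maximum(
                target_var - ref_mean * (1 - ref_mean) / cfg.sequencing_depth, 0.0)
            fluct = np.empty((T, cfg.n_features))
            for i in range(cfg.n_features):
                cv = np.sqrt(latent_var[i]) / ref_mean[i]
                fluct[:, i] = balanced_profile(1.0, cv, T, rng)

            if cfg.instability_window is not None and \
                    group == cfg.instability_window[0]:
                # compositional turnover: an independent community occupies the
                # first window time point, fluctuating and tilted like its
                # neighbours so evenness statistics are unaffected
                turnover_tp = cfg.instability_window[1][0]
                fresh = _log_uniform_means(cfg.n_features, *cfg.mean_range, rng)
                if has_event and event_tp is not None and turnover_tp < event_tp:
                    fresh = _tilt(fresh, cfg.event_tilt)
                mean_traj[turnover_tp - 1] = fresh

            x = mean_traj * fluct

            probs = x / x.sum(axis=1, keepdims=True)
            for tp in range(1, T + 1):
                counts = rng.multinomial(cfg.sequencing_depth, probs[tp - 1])
                sid = f"{subject}.T{tp:02d}"
                taxa_rows.append(counts)
                sample_ids.append(sid)
                row = {
                    "subject_id": subject,
                    "group": group,
                    "timepoint": tp,
                    "age_months": _BASE_AGE_MONTHS.get(group, 0) + 4 * (tp - 1),
                }
                if has_event:
                    row[cfg.event_name] = "before" if tp < event_tp else "after"
                elif cfg.event_name is not None:
                    row[cfg.event_name] = np.nan
                meta_rows.append(row)

    feature_ids = [f"ASV{i + 1:04d}" for i in range(cfg.n_features)]
    function_ids = [f"FUNC{j + 1:04d}" for j in range(cfg.n_functions)]
    taxa_df = pd.DataFrame(np.vstack(taxa_rows), index=sample_ids,
                           columns=feature_ids)
    taxa_df.index.name = "sample_id"
    func_df = pd.DataFrame(taxa_df.to_numpy() @ rmap, index=sample_ids,
                           columns=function_ids)
    func_df.index.name = "sample_id"
    meta_df = pd.DataFrame(meta_rows, index=sample_ids)
    meta_df.index.name = "sample_id"
    return CohortData(
        taxa=FeatureTable(taxa_df, mode="counts"),
        functions=FeatureTable(func_df, mode="counts"),
        metadata=SampleMetadata(meta_df),
        redundancy_matrix=rmap,
        config=cfg,
    )
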