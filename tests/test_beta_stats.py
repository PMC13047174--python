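import itertools

import numpy as np
import pandas as pd
import pytest
import skbio
from skbio.stats.distance import permanova as skbio_permanova

from microdyn.beta_stats import (
    DistanceMatrix,
    consecutive_stability,
    distance_matrix,
    event_split_compare,
    pcoa,
    permanova,
    rsi_distance_matrix,
    stability_tests,
)
from microdyn.diversity import bray_curtis, jaccard_index
from microdyn.io_tables import FeatureTable, SampleMetadata


def _ft(rows, ids=None, mode="counts"):
    ids = ids or [f"s{i}" for i in range(len(rows))]
    cols = [f"f{j}" for j in range(len(rows[0]))]
    return FeatureTable(pd.DataFrame(rows, index=ids, columns=cols, dtype=float),
                        mode=mode)


class TestDistanceMatrix:
    def test_duplicated_rows_have_zero_distance(self):
        t = _ft([[1, 2, 0], [1, 2, 0], [0, 0, 5]])
        dm = distance_matrix(t, "bray_curtis")
        assert dm.data[0, 1] == 0.0
        assert dm.data[0, 2] > 0

    def test_symmetry_for_random_tables(self):
        rng = np.random.default_rng(0)
        t = _ft(rng.integers(0, 20, size=(6, 10)).tolist())
        for metric in ("jaccard", "bray_curtis", "euclidean"):
            dm = distance_matrix(t, metric)
            assert np.allclose(dm.data, dm.data.T)
            assert np.allclose(np.diag(dm.data), 0.0)

    def test_matches_pairwise_metric_calls(self):
        rows = [[0.5, 0.5, 0.0], [0.2, 0.3, 0.5], [0.0, 0.1, 0.9]]
        t = _ft(rows, mode="relative")
        dm_bc = distance_matrix(t, "bray_curtis")
        dm_j = distance_matrix(t, "jaccard")
        for i, j in itertools.combinations(range(3), 2):
            assert dm_bc.data[i, j] == pytest.approx(bray_curtis(rows[i], rows[j]))
            assert dm_j.data[i, j] == pytest.approx(1 - jaccard_index(rows[i], rows[j]))

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError, match="unknown metric"):
            distance_matrix(_ft([[1], [2]]), "canberra")

    def test_nan_euclidean_for_rsi_profiles(self):
        prof = pd.DataFrame({"u1": [1.0, 0.5, np.nan], "u2": [0.8, np.nan, 0.2],
                             "u3": [0.9, 0.4, 0.1]})
        dm = rsi_distance_matrix(prof)
        assert dm.data[0, 1] == pytest.approx(0.2)  # only feature 0 shared
        assert dm.data[0, 2] == pytest.approx(np.sqrt(0.01 + 0.01))


class TestPcoa:
    def test_points_on_a_line_recovered(self):
        xs = np.array([0.0, 1.0, 3.0, 6.0])
        d = np.abs(xs[:, None] - xs[None, :])
        dm = DistanceMatrix(list("abcd"), d, "euclidean")
        coords, eigvals, prop = pcoa(dm, n_axes=2)
        gaps = np.diff(np.sort(coords["PC1"].to_numpy()))
        assert np.allclose(np.sort(gaps), np.sort(np.diff(xs)), atol=1e-8)
        assert eigvals.iloc[1] == pytest.approx(0.0, abs=1e-8)

    def test_euclidean_reconstruction(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(7, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        dm = DistanceMatrix([f"p{i}" for i in range(7)], d, "euclidean")
        coords, _, _ = pcoa(dm, n_axes=2)
        rec = coords.to_numpy()
        d_rec = np.linalg.norm(rec[:, None] - rec[None, :], axis=-1)
        assert np.allclose(d_rec, d, atol=1e-8)

    def test_semimetric_reports_negative_eigenvalues(self):
        rng = np.random.default_rng(2)
        t = _ft((rng.random((8, 12)) * (rng.random((8, 12)) < 0.4)).tolist())
        dm = distance_matrix(t, "jaccard")
        _, eigvals, _ = pcoa(dm, n_axes=2)
        assert (eigvals < -1e-12).any()

    def test_excess_axes_truncated_with_warning(self):
        xs = np.array([0.0, 1.0, 2.0])
        d = np.abs(xs[:, None] - xs[None, :])
        dm = DistanceMatrix(list("abc"), d, "euclidean")
        with pytest.warns(UserWarning, match="truncated"):
            coords, _, _ = pcoa(dm, n_axes=3)
        assert coords.shape[1] == 1


def _brute_force_permanova(d, labels):
    """Independent oracle: pseudo-F via group-centroid sums of squares in the
    Gower-centered inner-product space, and exhaustive label enumeration."""
    labels = np.asarray(labels)
    n = len(labels)
    d2 = d ** 2

    def f_stat(lab):
        groups = np.unique(lab)
        sst = d2[np.triu_indices(n, 1)].sum() / n
        ssw = 0.0
        for g in groups:
            idx = np.flatnonzero(lab == g)
            pairs = [(i, j) for i, j in itertools.combinations(idx, 2)]
            ssw += sum(d2[i, j] for i, j in pairs) / len(idx)
        a = len(groups)
        return ((sst - ssw) / (a - 1)) / (ssw / (n - a))

    f_obs = f_stat(labels)
    seen = set()
    count = 0
    for perm in set(itertools.permutations(labels)):
        if f_stat(np.array(perm)) >= f_obs - 1e-12:
            count += 1
        seen.add(perm)
    return f_obs, count / len(seen)


class TestPermanova:
    def _toy(self, seed=0, n_per=4, sep=0.0):
        rng = np.random.default_rng(seed)
        pts = np.vstack([rng.normal(0, 1, (n_per, 3)),
                         rng.normal(sep, 1, (n_per, 3))])
        ids = [f"s{i}" for i in range(2 * n_per)]
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        labels = ["a"] * n_per + ["b"] * n_per
        return DistanceMatrix(ids, d, "euclidean"), labels

    def test_exhaustive_matches_brute_force_oracle(self):
        dm, labels = self._toy(seed=3, n_per=4, sep=1.5)
        res = permanova(dm, labels, permutations="exhaustive")
        f_oracle, p_oracle = _brute_force_permanova(dm.data, labels)
        assert res.pseudo_F == pytest.approx(f_oracle, rel=1e-12)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_pseudo_f_matches_skbio(self):
        dm, labels = self._toy(seed=4, n_per=5, sep=1.0)
        res = permanova(dm, labels, n_perm=99, seed=0)
        sk = skbio_permanova(dm.to_skbio(), grouping=labels, permutations=9)
        assert res.pseudo_F == pytest.approx(float(sk["test statistic"]), rel=1e-9)

    def test_perfect_separation_hits_floor(self):
        # n_per=8 makes a chance re-creation of the observed split by one of
        # the 600 label permutations (which would tie the statistic) unlikely
        dm, labels = self._toy(seed=5, n_per=8, sep=50.0)
        res = permanova(dm, labels, n_perm=600, seed=1)
        assert res.p_value == pytest.approx(1 / 601)

    def test_seed_reproducible(self):
        dm, labels = self._toy(seed=6, sep=0.8)
        p1 = permanova(dm, labels, n_perm=99, seed=7).p_value
        p2 = permanova(dm, labels, n_perm=99, seed=7).p_value
        assert p1 == p2

    def test_singleton_group_rejected(self):
        dm, _ = self._toy()
        with pytest.raises(ValueError, match="fewer than 2"):
            permanova(dm, ["a"] * 7 + ["b"], n_perm=9)


class TestConsecutiveStability:
    def _pair_table(self, rows, tps, subject="A"):
        ids = [f"{subject}t{tp}" for tp in tps]
        t = _ft(rows, ids=ids)
        md = pd.DataFrame({"subject_id": subject, "group": "g", "timepoint": tps},
                          index=ids)
        return t, SampleMetadata(md)

    def test_identical_adjacent_samples_give_one(self):
        t, md = self._pair_table([[1, 1, 0], [2, 5, 0]], [1, 2])
        out = consecutive_stability(t, md)
        assert out["jaccard_similarity"].iloc[0] == 1.0

    def test_disjoint_adjacent_samples_give_zero(self):
        t, md = self._pair_table([[1, 0], [0, 3]], [1, 2])
        assert consecutive_stability(t, md)["jaccard_similarity"].iloc[0] == 0.0

    def test_missing_timepoint_breaks_adjacency(self):
        t, md = self._pair_table([[1, 0], [1, 1], [1, 1]], [1, 3, 4])
        out = consecutive_stability(t, md)
        assert out["interval"].tolist() == ["T3-T4"]

    def test_subject_without_pairs_warned_and_dropped(self):
        t, md = self._pair_table([[1, 0], [1, 1]], [1, 5])
        with pytest.warns(UserWarning, match="A"):
            out = consecutive_stability(t, md)
        assert len(out) == 0

    def test_functional_more_stable_than_taxonomic(self, cohort):
        tax = consecutive_stability(cohort.taxa, cohort.metadata, level="taxonomic")
        fun = consecutive_stability(cohort.functions, cohort.metadata,
                                    level="functional")
        merged = tax.merge(fun, on=["subject_id", "interval"], suffixes=("_t", "_f"))
        assert (merged["jaccard_similarity_f"] > merged["jaccard_similarity_t"]).mean() > 0.9


class TestStabilityTests:
    def test_families_and_fdr_columns(self, cohort):
        series = consecutive_stability(cohort.taxa, cohort.metadata)
        out = stability_tests(series)
        assert set(out["family"]) == {"within-group", "between-groups"}
        assert out["q_value"].notna().all()
        t12 = out[(out["family"] == "between-groups") &
                  (out["comparison"] == "T1-T2") &
                  (out["group"].str.contains("toddler"))]
        assert (t12["p_value"] < 0.01).all()

    def test_single_interval_series_has_no_within_comparisons(self):
        series = pd.DataFrame({
            "subject_id": list("abcdefgh"),
            "group": ["g1"] * 4 + ["g2"] * 4,
            "interval": "T1-T2", "t_from": 1,
            "jaccard_similarity": np.linspace(0.2, 0.9, 8),
            "level": "taxonomic",
        })
        out = stability_tests(series)
        assert (out["family"] == "between-groups").all()


class TestEventSplit:
    def test_cohort_event_detected(self, cohort):
        res = event_split_compare(cohort.taxa, cohort.metadata, "weaning",
                                  n_perm=299, seed=0)
        assert res["alpha"]["shannon"].p_value < 0.05
        assert res["alpha"]["chao1"].p_value < 0.05
        assert 0 < res["permanova"].p_value <= 1
        assert res["n_subjects"] >= 3

    def test_one_sided_event_rejected(self):
        ids = [f"s{i}" for i in range(6)]
        t = _ft(np.eye(6).tolist(), ids=ids)
        md = pd.DataFrame({
            "subject_id": ["A", "A", "B", "B", "C", "C"],
            "group": "g", "timepoint": [1, 2] * 3,
            "weaning": ["after"] * 6,
        }, index=ids)
        with pytest.raises(ValueError, match="both sides"):
            event_split_compare(t, SampleMetadata(md), "weaning")
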