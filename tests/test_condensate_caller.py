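import warnings

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from denovoscape.condensate_caller import (
    CondensateCall,
    ReductionConfig,
    age_enrichment,
    call_enriched_clusters,
    call_high_confidence,
    cluster,
    reduce_dimensions,
    zscore_columns,
)
from denovoscape.datasets import ProteinRecord, SequenceSet
from denovoscape.idr_features import FeatureMatrix


def _matrix(values, normalized=True):
    values = np.asarray(values, dtype=float)
    return FeatureMatrix(
        protein_ids=[f"p{i}" for i in range(values.shape[0])],
        feature_names=[f"f{j}" for j in range(values.shape[1])],
        values=values,
        normalized=normalized,
    )


def _blobs(rng, centers, n_each, dim, spread=1.0):
    points, labels = [], []
    for k, c in enumerate(centers):
        pts = rng.normal(0, spread, size=(n_each, dim)) + np.asarray(c)
        points.append(pts)
        labels += [k] * n_each
    return np.vstack(points), np.array(labels)


class TestReduction:
    def test_shape_contract(self):
        rng = np.random.default_rng(1)
        m = _matrix(rng.normal(size=(100, 10)))
        out = reduce_dimensions(m, ReductionConfig(n_components=5, seed=0,
                                                   method="pca"))
        assert out.shape == (100, 5)

    def test_n_components_must_be_smaller_than_features(self):
        m = _matrix(np.random.default_rng(0).normal(size=(50, 5)))
        with pytest.raises(ValueError):
            reduce_dimensions(m, ReductionConfig(n_components=5, method="pca"))

    @pytest.mark.parametrize("method", ["pca", "umap"])
    def test_deterministic_for_fixed_seed(self, method):
        rng = np.random.default_rng(2)
        m = _matrix(rng.normal(size=(60, 8)))
        cfg = ReductionConfig(n_components=2, seed=7, method=method,
                              n_neighbors=10)
        a = reduce_dimensions(m, cfg)
        b = reduce_dimensions(m, cfg)
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("method", ["pca", "umap"])
    def test_planted_blob_geometry_preserved(self, method):
        rng = np.random.default_rng(3)
        centers = [np.zeros(10), np.full(10, 10.0)]  # 10 sigma apart
        pts, labels = _blobs(rng, centers, 50, 10)
        m = _matrix(pts)
        red = reduce_dimensions(m, ReductionConfig(n_components=2, seed=1,
                                                   method=method))
        c0, c1 = red[labels == 0].mean(axis=0), red[labels == 1].mean(axis=0)
        gap = np.linalg.norm(c0 - c1)
        radius = max(
            np.linalg.norm(red[labels == 0] - c0, axis=1).max(),
            np.linalg.norm(red[labels == 1] - c1, axis=1).max(),
        )
        assert gap > radius

    def test_zscore_constant_column(self):
        z = zscore_columns(np.array([[1.0, 2.0], [1.0, 4.0]]))
        assert np.allclose(z[:, 0], 0.0)


class TestClustering:
    def test_three_separated_blobs_recovered(self):
        rng = np.random.default_rng(4)
        centers = [(0, 0), (30, 0), (0, 30)]
        pts, truth = _blobs(rng, centers, 150, 2)
        ids = [f"p{i}" for i in range(len(truth))]
        labels = cluster(pts, ids, min_cluster_size=100, min_samples=50)
        found = np.array([labels[i] for i in ids])
        assert len(set(found) - {-1}) == 3
        assert adjusted_rand_score(truth, found) == pytest.approx(1.0)

    def test_subthreshold_all_noise(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(size=(50, 2))
        ids = [f"p{i}" for i in range(50)]
        with pytest.warns(UserWarning):
            labels = cluster(pts, ids, min_cluster_size=100)
        assert set(labels.values()) == {-1}

    def test_duplication_stability(self):
        rng = np.random.default_rng(6)
        pts, _ = _blobs(rng, [(0, 0), (25, 25)], 120, 2)
        ids = [f"p{i}" for i in range(len(pts))]
        labels1 = cluster(pts, ids, min_cluster_size=60, min_samples=30)
        doubled = np.vstack([pts, pts])
        ids2 = ids + [f"q{i}" for i in range(len(pts))]
        labels2 = cluster(doubled, ids2, min_cluster_size=60, min_samples=30)
        n1 = len(set(labels1.values()) - {-1})
        n2 = len(set(labels2.values()) - {-1})
        assert n1 == n2


class TestEnrichedClusters:
    def _labels(self, sizes, positives_per_cluster, n_background=0):
        """Construct labels with given cluster sizes; positives placed first."""
        labels, positives = {}, []
        pid = 0
        for c, (size, npos) in enumerate(zip(sizes, positives_per_cluster)):
            for j in range(size):
                name = f"p{pid}"
                labels[name] = c
                if j < npos:
                    positives.append(name)
                pid += 1
        for _ in range(n_background):
            labels[f"p{pid}"] = -1
            pid += 1
        return labels, positives

    def test_all_positives_in_one_cluster(self):
        labels, positives = self._labels([50, 200], [40, 0], n_background=100)
        assert call_enriched_clusters(labels, positives) == {0}

    def test_greedy_coverage_hand_case(self):
        # positives split 60% / 29% / 11%; 0.85 target needs the top two
        labels, positives = self._labels(
            [70, 40, 20, 300], [60, 29, 11, 0], n_background=50
        )
        assert call_enriched_clusters(labels, positives,
                                      coverage_target=0.85) == {0, 1}

    def test_proportional_null_selects_nothing(self):
        # positives spread proportionally to cluster size: no enrichment
        rng = np.random.default_rng(7)
        labels = {}
        positives = []
        pid = 0
        for c, size in enumerate([200, 300, 500]):
            for _ in range(size):
                name = f"p{pid}"
                labels[name] = c
                if rng.random() < 0.05:
                    positives.append(name)
                pid += 1
        with pytest.warns(UserWarning):
            out = call_enriched_clusters(labels, positives)
        assert out == set()

    def test_noise_cluster_ineligible(self):
        labels = {f"p{i}": -1 for i in range(100)}
        labels.update({f"q{i}": 0 for i in range(10)})
        positives = [f"p{i}" for i in range(40)]  # all positives in noise
        with pytest.warns(UserWarning):
            assert call_enriched_clusters(labels, positives) == set()

    def test_no_positives_rejected(self):
        labels, _ = self._labels([50], [0])
        with pytest.raises(ValueError):
            call_enriched_clusters(labels, [])

    def test_coverage_property(self):
        rng = np.random.default_rng(8)
        for trial in range(20):
            n_clusters = int(rng.integers(2, 6))
            sizes = rng.integers(30, 200, size=n_clusters).tolist()
            pos = [int(rng.integers(0, min(20, s))) for s in sizes]
            if sum(pos) == 0:
                continue
            labels, positives = self._labels(sizes, pos)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                selected = call_enriched_clusters(labels, positives)
            if selected:
                covered = sum(p for c, p in enumerate(pos) if c in selected)
                assert covered / sum(pos) >= 0.85


class TestHighConfidenceCalls:
    def test_score_boundary_inclusive(self):
        labels = {"a": 0, "b": 0}
        calls = call_high_confidence(labels, {0}, {"a": 0.5, "b": 0.4999})
        by_id = {c.protein_id: c for c in calls}
        assert by_id["a"].high_confidence
        assert not by_id["b"].high_confidence

    def test_noise_cluster_never_called(self):
        calls = call_high_confidence({"a": -1}, {0}, {"a": 0.9})
        assert not calls[0].high_confidence

    def test_positives_not_emitted(self):
        labels = {"a": 0, "pos1": 0}
        calls = call_high_confidence(labels, {0}, {"a": 0.9},
                                     positive_ids={"pos1"})
        assert [c.protein_id for c in calls] == ["a"]

    def test_missing_score_listed(self):
        with pytest.raises(KeyError, match="b"):
            call_high_confidence({"a": 0, "b": 0}, {0}, {"a": 0.9})

    def test_cutoff_monotonicity(self):
        rng = np.random.default_rng(9)
        labels = {f"p{i}": int(rng.integers(-1, 3)) for i in range(200)}
        scores = {p: float(rng.uniform(0, 1)) for p in labels}
        lo = {c.protein_id for c in
              call_high_confidence(labels, {0, 1}, scores, cutoff=0.3)
              if c.high_confidence}
        hi = {c.protein_id for c in
              call_high_confidence(labels, {0, 1}, scores, cutoff=0.7)
              if c.high_confidence}
        assert hi <= lo

    def test_invariant_high_confidence_implies_enriched(self):
        with pytest.raises(ValueError):
            CondensateCall("a", 0.9, 0, in_enriched_cluster=False,
                           high_confidence=True)


class TestAgeEnrichment:
    def _records_and_calls(self, design):
        """design: {group: (n_total, n_called)} with representative ages."""
        ages = {"young": 2.0, "intermediate": 10.0, "old": 50.0}
        records, calls = [], []
        i = 0
        for group, (n, n_called) in design.items():
            for j in range(n):
                pid = f"{group}{j}"
                records.append(ProteinRecord(pid, "MK", age_mya=ages[group]))
                called = j < n_called
                calls.append(CondensateCall(pid, 0.9 if called else 0.1,
                                            0 if called else -1,
                                            called, called))
                i += 1
        return calls, records

    def test_fold_ratio_arithmetic(self):
        calls, records = self._records_and_calls(
            {"young": (1000, 10), "old": (1000, 66)}
        )
        out = age_enrichment(calls, records)
        assert out["fold_vs_young"]["old"] == pytest.approx(6.6)

    def test_equal_fractions_fold_one(self):
        calls, records = self._records_and_calls(
            {"young": (100, 10), "intermediate": (100, 10), "old": (100, 10)}
        )
        out = age_enrichment(calls, records)
        assert all(v == pytest.approx(1.0) for v in out["fold_vs_young"].values())
        assert out["p"] == pytest.approx(1.0)

    def test_zero_young_fraction_gives_na(self):
        calls, records = self._records_and_calls(
            {"young": (100, 0), "old": (100, 10)}
        )
        with pytest.warns(UserWarning):
            out = age_enrichment(calls, records)
        assert out["fold_vs_young"]["old"] is None

    def test_monte_carlo_planted_enrichment(self):
        """Planted 5x enrichment in old at n=2,000 recovers a fold in [4, 6]
        in >= 95% of simulations."""
        rng = np.random.default_rng(10)
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            records, calls = [], []
            for j in range(2000):
                pid = f"y{j}"
                records.append(ProteinRecord(pid, "MK", age_mya=2.0))
                called = rng.random() < 0.10
                calls.append(CondensateCall(pid, 0.9, 0, called, called))
            for j in range(2000):
                pid = f"o{j}"
                records.append(ProteinRecord(pid, "MK", age_mya=50.0))
                called = rng.random() < 0.50
                calls.append(CondensateCall(pid, 0.9, 0, called, called))
            out = age_enrichment(calls, records)
            fold = out["fold_vs_young"]["old"]
            if fold is not None and 4.0 <= fold <= 6.0:
                hits += 1
        assert hits / n_sim >= 0.95
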