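"""High-confidence condensate calling from IDR feature matrices.

The workflow mirrors a feature-space triage of condensate propensity
predictions: z-score the feature matrix, reduce it to a small number of
dimensions (UMAP, or PCA as a fully deterministic alternative), cluster
densely populated regions (HDBSCAN), find the clusters that concentrate the
experimentally supported condensate formers (the positive reference set),
and call a candidate high-confidence when it shares such a cluster *and*
its propensity score passes the cutoff (>= 0.5, inclusive).  Age-group
enrichment of the resulting calls is summarised as fold changes against the
youngest group plus a Pearson chi-square test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from denovoscape.idr_features import FeatureMatrix


@dataclass(frozen=True)
class ReductionConfig:
    """Dimensionality-reduction settings.

    ``umap`` follows the original workflow (nonlinear, seeded); ``pca`` is
    a bit-stable linear alternative used where exact reproducibility
    matters more than manifold structure.
    """

    n_components: int = 5
    n_neighbors: int = 15
    seed: int = 0
    method: str = "umap"

    def __post_init__(self) -> None:
        if self.n_components < 2:
            raise ValueError("n_components must be >= 2")
        if self.n_neighbors < 2:
            raise ValueError("n_neighbors must be >= 2")
        if self.method not in ("umap", "pca"):
            raise ValueError(f"method must be 'umap' or 'pca', got {self.method!r}")


@dataclass(frozen=True)
class CondensateCall:
    """Per-protein outcome of the high-confidence calling step."""

    protein_id: str
    picnic_score: float
    cluster_id: int
    in_enriched_cluster: bool
    high_confidence: bool

    def __post_init__(self) -> None:
        if self.high_confidence and not self.in_enriched_cluster:
            raise ValueError("high_confidence call outside an enriched cluster")


def zscore_columns(values: np.ndarray) -> np.ndarray:
    """Column-wise z-scores; constant columns map to 0."""
    values = np.asarray(values, dtype=float)
    mu = values.mean(axis=0)
    sd = values.std(axis=0)
    sd[sd == 0] = 1.0
    return (values - mu) / sd


def reduce_dimensions(matrix: FeatureMatrix, config: ReductionConfig) -> np.ndarray:
    """Z-score the features, then project to ``n_components`` dimensions.

    Deterministic for a fixed seed (UMAP: fixed ``random_state``, single
    threaded; PCA: fully deterministic).
    """
    n, p = matrix.values.shape
    if config.n_components >= p:
        raise ValueError(
            f"n_components ({config.n_components}) must be < feature count ({p})"
        )
    z = zscore_columns(matrix.values)
    if config.method == "pca":
        from sklearn.decomposition import PCA

        model = PCA(n_components=config.n_components, random_state=config.seed,
                    svd_solver="full")
        return model.fit_transform(z)
    import umap

    model = umap.UMAP(
        n_components=config.n_components,
        n_neighbors=min(config.n_neighbors, n - 1),
        random_state=config.seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.asarray(model.fit_transform(z), dtype=float)


def cluster(
    reduced: np.ndarray,
    protein_ids: Sequence[str],
    min_cluster_size: int = 100,
    min_samples: int = 50,
) -> dict[str, int]:
    """Density-based hierarchical clustering (HDBSCAN); -1 labels noise.

    The defaults match the full-scale workflow (minimum cluster size 100,
    ``min_samples`` 50); desk-scale runs pass proportionally smaller
    values.  With fewer rows than ``min_cluster_size`` every point is
    labelled noise, with a warning.
    """
    reduced = np.asarray(reduced, dtype=float)
    if reduced.shape[0] != len(protein_ids):
        raise ValueError("one id per row required")
    if reduced.shape[0] < min_cluster_size:
        warnings.warn(
            f"{reduced.shape[0]} rows < min_cluster_size {min_cluster_size}; "
            "labelling everything noise"
        )
        return {pid: -1 for pid in protein_ids}
    from sklearn.cluster import HDBSCAN

    model = HDBSCAN(min_cluster_size=min_cluster_size, min_samples=min_samples,
                    copy=True)
    labels = model.fit_predict(reduced)
    return {pid: int(lbl) for pid, lbl in zip(protein_ids, labels)}


def call_enriched_clusters(
    labels: Mapping[str, int],
    positive_ids: Iterable[str],
    coverage_target: float = 0.85,
    alpha: float = 0.05,
) -> set[int]:
    """Select the clusters that concentrate the positive reference set.

    Clusters are ranked by positive count and taken greedily until the
    cumulative fraction of positives covered reaches ``coverage_target``;
    each selected cluster must additionally be significantly enriched for
    positives under a one-sided hypergeometric test at
    Benjamini-Hochberg-adjusted ``alpha``.  The noise label (-1) is never
    eligible.  Returns an empty set (with a warning) when no selection
    reaching the coverage target exists.
    """
    positives = {p for p in positive_ids if p in labels}
    if not positives:
        raise ValueError("no positives present among labelled proteins")
    n_total = len(labels)
    n_pos = len(positives)
    clusters = sorted({c for c in labels.values() if c != -1})
    pos_in = {c: 0 for c in clusters}
    size = {c: 0 for c in clusters}
    for pid, c in labels.items():
        if c == -1:
            continue
        size[c] += 1
        if pid in positives:
            pos_in[c] += 1
    if not clusters:
        warnings.warn("no non-noise clusters; empty selection")
        return set()
    pvals = {
        c: float(stats.hypergeom.sf(pos_in[c] - 1, n_total, n_pos, size[c]))
        for c in clusters
    }
    significant = _benjamini_hochberg(pvals, alpha)
    ranked = sorted(clusters, key=lambda c: (-pos_in[c], c))
    selected: set[int] = set()
    covered = 0
    for c in ranked:
        if c not in significant or pos_in[c] == 0:
            continue
        selected.add(c)
        covered += pos_in[c]
        if covered / n_pos >= coverage_target:
            return selected
    warnings.warn(
        f"positive coverage target {coverage_target} not reachable with "
        "significantly enriched clusters; empty selection"
    )
    return set()


def _benjamini_hochberg(pvals: Mapping[int, float], alpha: float) -> set[int]:
    items = sorted(pvals.items(), key=lambda kv: kv[1])
    m = len(items)
    passing: set[int] = set()
    max_k = 0
    for rank, (_, p) in enumerate(items, 1):
        if p <= alpha * rank / m:
            max_k = rank
    for rank, (c, _) in enumerate(items, 1):
        if rank <= max_k:
            passing.add(c)
    return passing


def call_high_confidence(
    labels: Mapping[str, int],
    enriched_clusters: set[int],
    picnic_scores: Mapping[str, float],
    cutoff: float = 0.5,
    positive_ids: Iterable[str] = (),
) -> list[CondensateCall]:
    """Emit per-candidate condensate calls.

    ``high_confidence`` requires membership in an enriched cluster *and* a
    propensity score at or above ``cutoff`` (a score of exactly 0.5
    passes).  Reference positives are never emitted as calls.
    """
    positives = set(positive_ids)
    candidates = [pid for pid in labels if pid not in positives]
    missing = [pid for pid in candidates if pid not in picnic_scores]
    if missing:
        raise KeyError(f"missing propensity score for: {sorted(missing)}")
    calls = []
    for pid in candidates:
        c = labels[pid]
        in_enriched = c in enriched_clusters
        score = float(picnic_scores[pid])
        calls.append(CondensateCall(
            protein_id=pid,
            picnic_score=score,
            cluster_id=c,
            in_enriched_cluster=in_enriched,
            high_confidence=in_enriched and score >= cutoff,
        ))
    return calls


def age_enrichment(
    calls: Sequence[CondensateCall], records
) -> dict:
    """Age-group enrichment of high-confidence calls.

    Returns per-group called fractions (calls normalised by group size),
    fold-enrichment of each group against the young group, and a Pearson
    chi-square test on the called-vs-not by age-group table.  When the
    young fraction is zero, fold enrichments are NA with a warning.
    """
    by_id = {rec.id: rec for rec in records}
    group_total: dict[str, int] = {}
    group_called: dict[str, int] = {}
    called_ids = {c.protein_id for c in calls if c.high_confidence}
    for c in calls:
        rec = by_id.get(c.protein_id)
        if rec is None:
            raise KeyError(f"no record for called protein {c.protein_id}")
        g = rec.age_group
        if g == "NA":
            raise ValueError(f"called protein {c.protein_id} has no age group")
        group_total[g] = group_total.get(g, 0) + 1
        if c.protein_id in called_ids:
            group_called[g] = group_called.get(g, 0) + 1
    groups = sorted(group_total)
    fractions = {g: group_called.get(g, 0) / group_total[g] for g in groups}
    young = fractions.get("young")
    folds: dict[str, float | None] = {}
    for g in groups:
        if young is None or young == 0:
            folds[g] = None
        else:
            folds[g] = fractions[g] / young
    if young == 0 or young is None:
        warnings.warn("young called fraction is zero/absent; fold-enrichment NA")
    table = np.array([
        [group_called.get(g, 0) for g in groups],
        [group_total[g] - group_called.get(g, 0) for g in groups],
    ])
    if len(groups) >= 2 and (table.sum(axis=0) > 0).all() and (table.sum(axis=1) > 0).all():
        res = stats.chi2_contingency(table, correction=False)
        chi2, p = float(res.statistic), float(res.pvalue)
    else:
        chi2, p = float("nan"), float("nan")
    return {
        "groups": groups,
        "total": {g: group_total[g] for g in groups},
        "called": {g: group_called.get(g, 0) for g in groups},
        "fraction": fractions,
        "fold_vs_young": folds,
        "chi2": chi2,
        "p": p,
    }
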