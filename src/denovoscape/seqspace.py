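"""Embedding-space analysis: pooling, L1 distances, class comparisons.

Per-residue embedding matrices (protein language-model style, one fixed-D
vector per residue) are mean-pooled to one vector per protein; pairwise
Manhattan (L1) distances over the pooled vectors support within/between
class distance summaries, one-sided Mann-Whitney U comparisons, and
cross-class nearest-neighbour lookup.

The embedder is a pluggable contract: anything mapping a sequence to an
L x D matrix works.  :class:`HashedKmerEmbedder` is a deterministic
hashed-k-mer stand-in used for desk-scale runs and tests; it is synthetic
and carries no learned biology.
"""

from __future__ import annotations

import hashlib
import itertools
import warnings
from dataclasses import dataclass
from math import comb
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist

#: pooled assignments enumerated exactly for the Mann-Whitney test up to
#: this combined sample size (C(14,7) = 3,432 assignments at the limit)
MWU_EXACT_MAX_N = 14

#: block edge for streamed pairwise distance computation; results are
#: independent of the block size
L1_BLOCK = 512


@dataclass(frozen=True)
class ResidueEmbedding:
    """Per-residue embedding matrix (L x D) for one protein."""

    protein_id: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] < 1:
            raise ValueError(f"{self.protein_id}: need a non-empty L x D matrix")
        if not np.isfinite(m).all():
            raise ValueError(f"{self.protein_id}: non-finite embedding values")
        object.__setattr__(self, "matrix", m)


@dataclass
class EmbeddingMatrix:
    """Pooled fixed-dimension vectors, one row per protein."""

    protein_ids: list[str]
    vectors: np.ndarray
    class_labels: list[str]

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape[0] != len(self.protein_ids):
            raise ValueError("one vector per protein required")
        if len(self.class_labels) != len(self.protein_ids):
            raise ValueError("one class label per protein required")
        if not np.isfinite(self.vectors).all():
            raise ValueError("non-finite embedding values")


class Embedder(Protocol):
    """Contract: map a sequence to an L x D per-residue matrix."""

    dim: int

    def embed(self, protein_id: str, sequence: str) -> ResidueEmbedding: ...


class HashedKmerEmbedder:
    """Deterministic synthetic embedder based on hashed k-mer indicators.

    Each residue is represented by indicator features of the k-mers covering
    it, hashed into ``dim`` buckets with a stable (seeded) hash.  Pooling
    over residues therefore yields a scaled hashed k-mer count profile of
    the sequence — a crude but deterministic stand-in for language-model
    embeddings, sufficient to exercise the distance analysis.
    """

    def __init__(self, dim: int = 64, k: int = 3, seed: int = 0) -> None:
        if dim < 2 or k < 1:
            raise ValueError("need dim >= 2 and k >= 1")
        self.dim = dim
        self.k = k
        self.seed = seed

    def _bucket(self, kmer: str) -> int:
        h = hashlib.blake2b(
            f"{self.seed}:{kmer}".encode(), digest_size=8
        ).digest()
        return int.from_bytes(h, "big") % self.dim

    def embed(self, protein_id: str, sequence: str) -> ResidueEmbedding:
        seq = sequence.upper()
        L = len(seq)
        out = np.zeros((L, self.dim))
        for start in range(max(1, L - self.k + 1)):
            kmer = seq[start:start + self.k]
            j = self._bucket(kmer)
            for i in range(start, min(L, start + self.k)):
                out[i, j] += 1.0
        return ResidueEmbedding(protein_id, out)


def pool_embedding(res: ResidueEmbedding) -> np.ndarray:
    """Column-wise arithmetic mean over residues (special tokens excluded)."""
    return res.matrix.mean(axis=0)


def pairwise_l1(
    embeddings: EmbeddingMatrix, block: int = L1_BLOCK
) -> np.ndarray:
    """Symmetric n x n Manhattan distance matrix over pooled vectors.

    Computed in blocks so large sets stream through modest memory; the
    result is independent of the block size.
    """
    v = embeddings.vectors
    n = v.shape[0]
    out = np.zeros((n, n))
    for i0 in range(0, n, block):
        i1 = min(n, i0 + block)
        for j0 in range(i0, n, block):
            j1 = min(n, j0 + block)
            d = cdist(v[i0:i1], v[j0:j1], metric="cityblock")
            out[i0:i1, j0:j1] = d
            out[j0:j1, i0:i1] = d.T
    np.fill_diagonal(out, 0.0)
    return out


def _class_indices(labels: Sequence[str]) -> dict[str, np.ndarray]:
    classes: dict[str, list[int]] = {}
    for i, lbl in enumerate(labels):
        classes.setdefault(lbl, []).append(i)
    return {c: np.array(ix) for c, ix in classes.items()}


def class_pair_distances(
    dist: np.ndarray, class_labels: Sequence[str], a: str, b: str
) -> np.ndarray:
    """Flat distances for a class pair: upper-triangle within, all cross pairs between."""
    idx = _class_indices(class_labels)
    if a not in idx or b not in idx:
        raise KeyError(f"unknown class in pair ({a!r}, {b!r})")
    ia, ib = idx[a], idx[b]
    if a == b:
        sub = dist[np.ix_(ia, ia)]
        iu = np.triu_indices(len(ia), k=1)
        return sub[iu]
    return dist[np.ix_(ia, ib)].ravel()


def group_distance_summary(
    dist: np.ndarray, class_labels: Sequence[str]
) -> dict[tuple[str, str], dict]:
    """Median/quartile summaries for every class pair.

    Within-class summaries use upper-triangle pairs only (no self-pairs);
    between-class summaries use all cross pairs.  Singleton classes yield
    an NA within-summary with a warning.
    """
    classes = sorted(_class_indices(class_labels))
    out: dict[tuple[str, str], dict] = {}
    for i, a in enumerate(classes):
        for b in classes[i:]:
            vals = class_pair_distances(dist, class_labels, a, b)
            if vals.size == 0:
                warnings.warn(f"no pairs for class pair ({a}, {b}); NA summary")
                out[(a, b)] = {"median": None, "q1": None, "q3": None, "n": 0}
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            out[(a, b)] = {
                "median": float(med), "q1": float(q1), "q3": float(q3),
                "n": int(vals.size),
            }
    return out


def mwu_one_sided(
    x: Sequence[float], y: Sequence[float], alternative: str = "greater"
) -> tuple[float, float]:
    """One-sided Mann-Whitney U test of ``x`` against ``y``.

    ``alternative="greater"`` tests whether values in ``x`` tend to exceed
    those in ``y``.  Exact permutation p-value (ties handled via midranks)
    when ``len(x) + len(y) <= MWU_EXACT_MAX_N``; tie- and
    continuity-corrected normal approximation otherwise.  Returns
    ``(U of x, p)``; fully tied samples give p = 1 with a warning.
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values tied across both samples; p = 1")
        u = x.size * y.size / 2
        return float(u), 1.0

    n, m = x.size, y.size
    if n + m <= MWU_EXACT_MAX_N:
        ranks = stats.rankdata(pooled)
        u_obs = _u_from_ranks(ranks[:n], n, m)
        if alternative == "less":
            u_obs_cmp = n * m - u_obs
        else:
            u_obs_cmp = u_obs
        count = 0
        total = comb(n + m, n)
        idx_all = range(n + m)
        for combo in itertools.combinations(idx_all, n):
            u_perm = _u_from_ranks(ranks[list(combo)], n, m)
            if alternative == "less":
                u_perm = n * m - u_perm
            if u_perm >= u_obs_cmp - 1e-12:
                count += 1
        return float(u_obs), count / total
    res = stats.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def _u_from_ranks(ranks_x: np.ndarray, n: int, m: int) -> float:
    return float(np.sum(ranks_x) - n * (n + 1) / 2)


def nearest_cross_class(
    dist: np.ndarray,
    protein_ids: Sequence[str],
    class_labels: Sequence[str],
    from_class: str,
    to_class: str,
) -> dict[str, tuple[str, float]]:
    """Per ``from_class`` protein: the nearest ``to_class`` protein and distance.

    Ties broken by lexicographically smallest target id.
    """
    idx = _class_indices(class_labels)
    if to_class not in idx or idx[to_class].size == 0:
        raise ValueError(f"to_class {to_class!r} is empty")
    if from_class not in idx:
        raise ValueError(f"from_class {from_class!r} is empty")
    to_ids = [protein_ids[j] for j in idx[to_class]]
    order = sorted(range(len(to_ids)), key=lambda k: to_ids[k])
    to_cols = idx[to_class][order]
    to_ids_sorted = [to_ids[k] for k in order]
    out: dict[str, tuple[str, float]] = {}
    for i in idx[from_class]:
        row = dist[i, to_cols]
        k = int(np.argmin(row))  # first minimum = lexicographically smallest id
        out[protein_ids[i]] = (to_ids_sorted[k], float(row[k]))
    return out


# ---------------------------------------------------------------------------
# IO: pooled embedding container (NPZ + id manifest TSV)
# ---------------------------------------------------------------------------

def write_embeddings(emb: EmbeddingMatrix, npz_path: str | Path,
                     manifest_path: str | Path) -> None:
    np.savez_compressed(npz_path, vectors=emb.vectors)
    with open(manifest_path, "w") as fh:
        fh.write("id\tclass_label\n")
        for pid, lbl in zip(emb.protein_ids, emb.class_labels):
            fh.write(f"{pid}\t{lbl}\n")


def read_embeddings(npz_path: str | Path, manifest_path: str | Path) -> EmbeddingMatrix:
    import pandas as pd

    vectors = np.load(npz_path)["vectors"]
    df = pd.read_csv(manifest_path, sep="\t", dtype=str)
    return EmbeddingMatrix(
        protein_ids=list(df["id"]),
        vectors=vectors,
        class_labels=list(df["class_label"]),
    )
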