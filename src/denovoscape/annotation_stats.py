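"""Functional-annotation filtering and group-comparison statistics.

Gene Ontology predictions (DeepFRI-style rows: protein, GO id, GO class,
confidence score) are filtered at a confidence cutoff (score >= 0.5,
inclusive) and summarised as per-class annotated fractions — the fraction
of *proteins* with at least one surviving term per GO class, not the number
of terms.  Group comparisons use Fisher's exact test (two-sided,
probability-mass rule) and Pearson's chi-square.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

GO_CLASSES = ("MF", "BP", "CC")
_GO_ID = re.compile(r"^GO:\d{7}$")


@dataclass(frozen=True)
class GoAnnotation:
    protein_id: str
    go_id: str
    go_class: str
    score: float

    def __post_init__(self) -> None:
        if not _GO_ID.match(self.go_id):
            raise ValueError(f"malformed GO id {self.go_id!r}")
        if self.go_class not in GO_CLASSES:
            raise ValueError(f"go_class must be one of {GO_CLASSES}")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0,1]")


def filter_annotations(
    annotations: Iterable[GoAnnotation], cutoff: float = 0.5
) -> list[GoAnnotation]:
    """Keep annotations with confidence score >= cutoff (0.5 passes)."""
    return [a for a in annotations if a.score >= cutoff]


def annotated_fraction(
    annotations: Iterable[GoAnnotation],
    protein_ids: Iterable[str],
    go_class: str,
) -> float:
    """Fraction of proteins carrying at least one annotation in ``go_class``.

    Counts proteins, not terms: a protein with five CC terms contributes
    once.  Annotations for proteins outside the universe are ignored.
    """
    universe = set(protein_ids)
    if not universe:
        raise ValueError("protein set is empty")
    if go_class not in GO_CLASSES:
        raise ValueError(f"go_class must be one of {GO_CLASSES}")
    annotated = {
        a.protein_id for a in annotations
        if a.go_class == go_class and a.protein_id in universe
    }
    return len(annotated) / len(universe)


def compare_groups_fisher(
    group_a: tuple[int, int], group_b: tuple[int, int]
) -> tuple[float, float]:
    """Fisher's exact test on the 2x2 (annotated, not) x (group A, group B) table.

    Returns ``(sample odds ratio, two-sided p)``; the p-value follows the
    probability-mass rule (sum of hypergeometric tables no more probable
    than the observed one).  The odds ratio is inf/nan for zero cells.
    """
    table = np.array([group_a, group_b])
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate table (zero margin)")
    res = stats.fisher_exact(table, alternative="two-sided")
    a, b = group_a
    c, d = group_b
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    return odds, float(res.pvalue)


def age_annotation_test(
    annotated_by_group: Mapping[str, tuple[int, int]]
) -> tuple[float, int, float]:
    """Pearson chi-square on the annotated-vs-not x age-group table.

    ``annotated_by_group`` maps group name to (annotated, not-annotated)
    counts.  Returns ``(statistic, dof, p)``.
    """
    groups = sorted(annotated_by_group)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    table = np.array([annotated_by_group[g] for g in groups]).T
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate table (zero margin)")
    res = stats.chi2_contingency(table, correction=False)
    if (res.expected_freq < 5).any():
        warnings.warn("expected cell count < 5; chi-square approximation is rough")
    return float(res.statistic), int(res.dof), float(res.pvalue)


def read_annotations_tsv(path: str | Path) -> list[GoAnnotation]:
    """Read an annotation TSV with columns (protein_id, go_id, go_class, score)."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "go_id": str})
    return [
        GoAnnotation(row.protein_id, row.go_id, row.go_class, float(row.score))
        for row in df.itertuples(index=False)
    ]
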