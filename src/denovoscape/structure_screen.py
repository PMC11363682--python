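"""Structural triage of predicted structures and structure-search hits.

Implements the pre-simulation screen (disorder and helix-content filters),
trajectory RMSD summarisation, structure-search hit filtering (TM-score,
target coverage, taxon exclusion), best-hit selection across simulation
replicates, ECOD architecture assignment, and the associated group
statistics.

Per-residue disorder scores (flDPnn-style), DSSP secondary-structure
strings, RMSD series, hit tables and the ECOD target->architecture map are
all consumed as plain TSV inputs; the upstream predictors are out of scope.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DSSP_ALPHABET = frozenset("HGIEBTS-")

#: columns of the tab-separated hit table; ``tm_score`` is taken at face
#: value under whatever normalisation the upstream search reported.
HIT_COLUMNS = ("query", "target", "tm_score", "target_coverage", "taxon",
               "replicate", "evalue")

#: mapping from Foldseek easy-search default output columns to hit fields
#: (documented convention for users converting raw search output).
FOLDSEEK_COLUMN_MAP = {
    "query": "query",
    "target": "target",
    "alntmscore": "tm_score",
    "tcov": "target_coverage",
    "taxname": "taxon",
    "evalue": "evalue",
}


@dataclass(frozen=True)
class DisorderProfile:
    """Per-residue disorder propensities in [0, 1] for one protein."""

    protein_id: str
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.scores) == 0:
            raise ValueError(f"{self.protein_id}: empty disorder profile")
        if any(not (0.0 <= s <= 1.0) for s in self.scores):
            raise ValueError(f"{self.protein_id}: disorder scores outside [0,1]")


@dataclass(frozen=True)
class SecondaryStructureString:
    """DSSP-style per-residue secondary structure codes."""

    protein_id: str
    codes: str

    def __post_init__(self) -> None:
        bad = set(self.codes) - DSSP_ALPHABET
        if bad:
            raise ValueError(
                f"{self.protein_id}: codes outside DSSP alphabet: {sorted(bad)}"
            )
        if len(self.codes) == 0:
            raise ValueError(f"{self.protein_id}: empty secondary structure")


@dataclass(frozen=True)
class TrajectorySet:
    """RMSD series (Angstrom) for the simulation replicates of one protein."""

    protein_id: str
    replicates: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        if len(self.replicates) == 0:
            raise ValueError(f"{self.protein_id}: no replicates")
        for i, rep in enumerate(self.replicates):
            if len(rep) == 0:
                raise ValueError(f"{self.protein_id}: replicate {i} empty")
            if any(v < 0 for v in rep):
                raise ValueError(f"{self.protein_id}: negative RMSD in replicate {i}")


@dataclass(frozen=True)
class StructureHit:
    """One structure-search alignment row."""

    query_id: str
    target_id: str
    tm_score: float
    target_coverage: float
    target_taxon: str
    replicate: int | None = None
    evalue: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.tm_score <= 1.0):
            raise ValueError(f"tm_score {self.tm_score} outside [0,1]")
        if not (0.0 <= self.target_coverage <= 1.0):
            raise ValueError(f"target_coverage {self.target_coverage} outside [0,1]")


@dataclass(frozen=True)
class EcodAssignment:
    """A query assigned the ECOD architecture of its best filtered hit."""

    query_id: str
    target_id: str
    architecture: str
    tm_score: float


# ---------------------------------------------------------------------------
# Pre-simulation screen
# ---------------------------------------------------------------------------

def disorder_fraction(profile: DisorderProfile, cutoff: float = 0.5) -> float:
    """Fraction of residues with disorder score >= ``cutoff``.

    Binary disorder calls (0/1 per residue) pass through unchanged at the
    default cutoff, so both score and binary predictor outputs are
    supported.
    """
    scores = np.asarray(profile.scores)
    return float(np.count_nonzero(scores >= cutoff) / scores.size)


def helix_fraction(
    ss: SecondaryStructureString, helix_codes: frozenset | set = frozenset("H")
) -> float:
    """Fraction of residues in helical states (default: alpha-helix 'H' only)."""
    bad = set(helix_codes) - DSSP_ALPHABET
    if bad:
        raise ValueError(f"helix codes outside DSSP alphabet: {sorted(bad)}")
    return sum(1 for c in ss.codes if c in helix_codes) / len(ss.codes)


def filter_for_simulation(
    records,
    profiles: Mapping[str, DisorderProfile],
    ss_strings: Mapping[str, SecondaryStructureString],
    disorder_max: float = 0.30,
    helix_max: float = 0.95,
    disorder_cutoff: float = 0.5,
    helix_codes: frozenset | set = frozenset("H"),
):
    """Keep records suitable for simulation refinement.

    A record survives iff its disorder fraction is strictly below
    ``disorder_max`` *and* its helix fraction strictly below ``helix_max``
    (both "less than" rules; a protein at exactly 30% disorder is excluded).
    """
    from denovoscape.datasets import SequenceSet

    missing = [r.id for r in records if r.id not in profiles or r.id not in ss_strings]
    if missing:
        raise KeyError(f"missing disorder/ss data for: {sorted(missing)}")
    out = SequenceSet(name="simulation_candidates")
    for rec in records:
        d = disorder_fraction(profiles[rec.id], cutoff=disorder_cutoff)
        h = helix_fraction(ss_strings[rec.id], helix_codes=helix_codes)
        if d < disorder_max and h < helix_max:
            out.add(rec)
    return out


def mean_rmsd(traj: TrajectorySet) -> float:
    """Two-level trajectory average: mean over replicates of per-replicate frame means.

    Replicates are weighted equally regardless of frame count (this is not
    the pooled-frame mean).
    """
    return float(np.mean([np.mean(rep) for rep in traj.replicates]))


# ---------------------------------------------------------------------------
# Hit filtering and ECOD assignment
# ---------------------------------------------------------------------------

def filter_hits(
    hits: Iterable[StructureHit],
    tm_min: float = 0.5,
    coverage_min: float = 0.8,
    exclude_taxa: Iterable[str] = (),
) -> list[StructureHit]:
    """Apply the hit-quality and taxon filters.

    Keep a hit iff TM-score is strictly greater than ``tm_min``, target
    coverage is at least ``coverage_min`` (inclusive), and the target taxon
    does not fall under any excluded clade (case-insensitive prefix match,
    so ``"Drosophila"`` excludes every *Drosophila* species — removing hits
    to orthologous proteins within the query clade).
    """
    prefixes = tuple(t.lower() for t in exclude_taxa)
    out = []
    for h in hits:
        if h.tm_score <= tm_min:
            continue
        if h.target_coverage < coverage_min:
            continue
        if prefixes and h.target_taxon.lower().startswith(prefixes):
            continue
        out.append(h)
    return out


def best_hit_per_query(hits: Iterable[StructureHit]) -> dict[str, StructureHit]:
    """Per query, the single best hit across replicates.

    Maximises TM-score; ties broken by lower e-value (missing e-values sort
    last), then lexicographically smallest target id.
    """
    def sort_key(h: StructureHit):
        ev = h.evalue if h.evalue is not None else math.inf
        return (-h.tm_score, ev, h.target_id)

    best: dict[str, StructureHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or sort_key(h) < sort_key(cur):
            best[h.query_id] = h
    return best


def assign_ecod(
    best_hits: Mapping[str, StructureHit],
    ecod_map: Mapping[str, str],
) -> tuple[list[EcodAssignment], list[str]]:
    """Assign each query the ECOD architecture of its best hit.

    Returns ``(assignments, unmapped_query_ids)``; queries whose best-hit
    target lacks an architecture annotation are reported, not silently
    dropped.
    """
    assignments: list[EcodAssignment] = []
    unmapped: list[str] = []
    for qid in sorted(best_hits):
        hit = best_hits[qid]
        arch = ecod_map.get(hit.target_id)
        if arch is None:
            unmapped.append(qid)
        else:
            assignments.append(
                EcodAssignment(qid, hit.target_id, arch, hit.tm_score)
            )
    return assignments, unmapped


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def architecture_age_test(
    assignments: Sequence[EcodAssignment], all_records
) -> tuple[float, int, float]:
    """Pearson chi-square: are structurally assigned proteins distributed
    across age groups as expected from group sizes?

    Builds the 2 x k (assigned vs not, by age group) contingency table and
    tests homogeneity; returns ``(statistic, dof, p)``.  Warns when any
    expected cell is below 5 (asymptotic approximation questionable).
    """
    assigned_ids = {a.query_id for a in assignments}
    groups: dict[str, list[int]] = {}
    for rec in all_records:
        g = rec.age_group
        if g == "NA":
            continue
        row = groups.setdefault(g, [0, 0])
        row[0 if rec.id in assigned_ids else 1] += 1
    if len(groups) < 2:
        raise ValueError("need >= 2 age groups with records")
    table = np.array([groups[g] for g in sorted(groups)]).T  # 2 x k
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate contingency table (zero margin)")
    res = stats.chi2_contingency(table, correction=False)
    if (res.expected_freq < 5).any():
        warnings.warn("expected cell count < 5; chi-square approximation is rough")
    return float(res.statistic), int(res.dof), float(res.pvalue)


def correlate_rmsd_tm(
    rmsd_by_protein: Mapping[str, float],
    tm_by_protein: Mapping[str, float],
) -> tuple[float, float]:
    """Pearson correlation between simulation RMSD and best-hit TM-score.

    Computed on proteins present in both maps; two-sided p-value from the
    t approximation.  Requires >= 3 pairs with nonzero variance.
    """
    ids = sorted(set(rmsd_by_protein) & set(tm_by_protein))
    if len(ids) < 3:
        raise ValueError(f"need >= 3 paired observations, got {len(ids)}")
    x = np.array([rmsd_by_protein[i] for i in ids])
    y = np.array([tm_by_protein[i] for i in ids])
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the samples")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# TSV readers
# ---------------------------------------------------------------------------

def read_disorder_tsv(path: str | Path) -> dict[str, DisorderProfile]:
    """Read per-residue disorder scores: columns (id, position, score)."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    profiles = {}
    for pid, sub in df.groupby("id", sort=False):
        sub = sub.sort_values("position")
        profiles[pid] = DisorderProfile(pid, tuple(float(s) for s in sub["score"]))
    return profiles


def read_ss_tsv(path: str | Path) -> dict[str, SecondaryStructureString]:
    """Read secondary-structure strings: columns (id, codes)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {row.id: SecondaryStructureString(row.id, row.codes)
            for row in df.itertuples(index=False)}


def read_rmsd_tsv(path: str | Path, unit: str = "angstrom") -> dict[str, TrajectorySet]:
    """Read RMSD series: columns (id, replicate, frame, rmsd).

    ``unit`` may be ``"angstrom"`` (native) or ``"nm"`` (converted on read).
    """
    scale = {"angstrom": 1.0, "nm": 10.0}.get(unit)
    if scale is None:
        raise ValueError(f"unknown RMSD unit {unit!r}")
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    out = {}
    for pid, sub in df.groupby("id", sort=False):
        reps = []
        for _, rep in sub.groupby("replicate", sort=True):
            rep = rep.sort_values("frame")
            reps.append(tuple(float(v) * scale for v in rep["rmsd"]))
        out[pid] = TrajectorySet(pid, tuple(reps))
    return out


def read_hits_tsv(path: str | Path) -> list[StructureHit]:
    """Read a hit table with columns ``HIT_COLUMNS``."""
    df = pd.read_csv(path, sep="\t", dtype={"query": str, "target": str})
    hits = []
    for row in df.itertuples(index=False):
        rep = None if pd.isna(row.replicate) else int(row.replicate)
        ev = None if pd.isna(row.evalue) else float(row.evalue)
        hits.append(StructureHit(row.query, row.target, float(row.tm_score),
                                 float(row.target_coverage), row.taxon, rep, ev))
    return hits


def read_ecod_map(path: str | Path) -> dict[str, str]:
    """Read the target -> ECOD architecture map: columns (target_id, architecture)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["target_id"], df["architecture"]))
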