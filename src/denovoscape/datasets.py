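"""Sequence sets, metadata curation, and length-matched reference sampling.

De novo protein candidates carry a class label (``DN`` de novo, ``C``
conserved, ``R-DN``/``R-C`` their composition-matched randomisations,
``POSITIVE`` reference condensate formers), an emergence origin (intergenic
``denovo`` vs intronic ``denovo-intron``), and an evolutionary age in million
years, binned into young (<5 mya), intermediate (5-30 mya) and old (>30 mya)
groups.
"""

from __future__ import annotations

import math
import warnings
from bisect import bisect_left, insort
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
CLASS_LABELS = frozenset({"DN", "C", "R-DN", "R-C", "POSITIVE", "OTHER"})
EMERGENCE_ORIGINS = frozenset({"denovo", "denovo-intron", "NA"})
AGE_GROUPS = ("young", "intermediate", "old", "NA")


class FastaParseError(ValueError):
    """Raised for malformed FASTA input, with the offending line number."""


class DuplicateIdError(ValueError):
    """Raised when a sequence set would contain repeated identifiers."""


def assign_age_group(age_mya: float | None) -> str:
    """Bin an emergence age (million years) into young/intermediate/old.

    Boundaries: ``age < 5`` young, ``5 <= age <= 30`` intermediate,
    ``age > 30`` old.  Negative or missing ages map to ``"NA"`` with a
    warning.
    """
    if age_mya is None or (isinstance(age_mya, float) and math.isnan(age_mya)):
        return "NA"
    if age_mya < 0:
        warnings.warn(f"negative age {age_mya} mya; assigning NA age group")
        return "NA"
    if age_mya < 5:
        return "young"
    if age_mya <= 30:
        return "intermediate"
    return "old"


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with curation metadata.

    ``sequence`` is over the 20 canonical amino-acid letters; ``X`` is
    tolerated on input (flagged via :attr:`has_x`) but excluded from
    composition statistics downstream.  ``age_group`` is derived from
    ``age_mya`` and must stay consistent with it.
    """

    id: str
    sequence: str
    class_label: str = "OTHER"
    emergence_origin: str = "NA"
    age_mya: float | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"{self.id}: sequence must have length >= 1")
        seq = self.sequence.upper()
        bad = set(seq) - set(CANONICAL_AA) - {"X"}
        if bad:
            raise ValueError(f"{self.id}: non-canonical residues {sorted(bad)}")
        if set(seq) == {"X"}:
            raise ValueError(f"{self.id}: all-'X' sequence rejected")
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"{self.id}: unknown class label {self.class_label!r}")
        if self.emergence_origin not in EMERGENCE_ORIGINS:
            raise ValueError(
                f"{self.id}: unknown emergence origin {self.emergence_origin!r}"
            )
        object.__setattr__(self, "sequence", seq)

    @property
    def age_group(self) -> str:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return assign_age_group(self.age_mya)

    @property
    def has_x(self) -> bool:
        return "X" in self.sequence

    def __len__(self) -> int:
        return len(self.sequence)


class SequenceSet:
    """An ordered collection of :class:`ProteinRecord` with unique ids."""

    def __init__(self, records: Iterable[ProteinRecord] = (), name: str = "") -> None:
        self.name = name
        self._records: list[ProteinRecord] = []
        self._index: dict[str, int] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: ProteinRecord) -> None:
        if rec.id in self._index:
            raise DuplicateIdError(f"duplicate id {rec.id!r} in set {self.name!r}")
        self._index[rec.id] = len(self._records)
        self._records.append(rec)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self._records)

    def __contains__(self, rec_id: str) -> bool:
        return rec_id in self._index

    def __getitem__(self, rec_id: str) -> ProteinRecord:
        return self._records[self._index[rec_id]]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self._records]

    @property
    def records(self) -> list[ProteinRecord]:
        return list(self._records)

    def lengths(self) -> list[int]:
        return [len(r) for r in self._records]

    def subset(self, ids: Iterable[str], name: str = "") -> "SequenceSet":
        wanted = set(ids)
        return SequenceSet(
            (r for r in self._records if r.id in wanted), name=name or self.name
        )

    def filter_class(self, class_label: str, name: str = "") -> "SequenceSet":
        return SequenceSet(
            (r for r in self._records if r.class_label == class_label),
            name=name or class_label,
        )

    def __repr__(self) -> str:
        return f"SequenceSet(name={self.name!r}, n={len(self)})"


# ---------------------------------------------------------------------------
# FASTA / metadata IO
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, name: str = "") -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`.

    The id is the first whitespace-delimited header token; the remainder of
    the header is kept as the record description.  Sequences are uppercased.
    Duplicate ids and text before the first header are rejected.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: expected '>' header, got {line[:30]!r}"
                )
            break
    out = SequenceSet(name=name or path.stem)
    seen_dupes: list[str] = []
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            desc = rec.description[len(rec.id):].strip()
            try:
                out.add(ProteinRecord(id=rec.id, sequence=str(rec.seq),
                                      description=desc))
            except DuplicateIdError:
                seen_dupes.append(rec.id)
    if seen_dupes:
        raise DuplicateIdError(f"{path}: duplicate ids {sorted(set(seen_dupes))}")
    return out


def write_fasta(sset: SequenceSet, path: str | Path) -> None:
    """Write one record per entry, sequence on a single line (round-trip safe)."""
    with open(path, "w") as fh:
        for rec in sset:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n{rec.sequence}\n")


def read_metadata(path: str | Path) -> dict[str, dict]:
    """Read the metadata sidecar TSV (id, class_label, emergence_origin, age_mya)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"id", "class_label", "emergence_origin", "age_mya"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    meta: dict[str, dict] = {}
    for row in df.itertuples(index=False):
        age = None if row.age_mya in ("NA", "") else float(row.age_mya)
        meta[row.id] = {
            "class_label": row.class_label,
            "emergence_origin": row.emergence_origin,
            "age_mya": age,
        }
    return meta


def write_metadata(sset: SequenceSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tclass_label\temergence_origin\tage_mya\n")
        for rec in sset:
            age = "NA" if rec.age_mya is None else f"{rec.age_mya:g}"
            fh.write(f"{rec.id}\t{rec.class_label}\t{rec.emergence_origin}\t{age}\n")


def apply_metadata(sset: SequenceSet, meta: dict[str, dict]) -> SequenceSet:
    """Return a new set with metadata fields attached where available."""
    out = SequenceSet(name=sset.name)
    for rec in sset:
        m = meta.get(rec.id)
        out.add(replace(rec, **m) if m else rec)
    return out


# ---------------------------------------------------------------------------
# Curation
# ---------------------------------------------------------------------------

def dedupe_by_key(sset: SequenceSet, key: str, policy: str = "drop-all") -> SequenceSet:
    """Remove records sharing a duplicated key value.

    ``policy="drop-all"`` (default) removes *every* member of a duplicated
    key group — the safe choice when shared identifiers may indicate
    mislabeled identity.  ``policy="keep-first"`` keeps the first occurrence.
    Survivor order is preserved.
    """
    if policy not in ("drop-all", "keep-first"):
        raise ValueError(f"unknown dedupe policy {policy!r}")
    probe = sset.records[0] if len(sset) else None
    if probe is not None and not hasattr(probe, key):
        raise KeyError(f"unknown record field {key!r}")
    counts: dict[object, int] = {}
    for rec in sset:
        k = getattr(rec, key)
        counts[k] = counts.get(k, 0) + 1
    out = SequenceSet(name=sset.name)
    emitted: set = set()
    for rec in sset:
        k = getattr(rec, key)
        if counts[k] == 1:
            out.add(rec)
        elif policy == "keep-first" and k not in emitted:
            emitted.add(k)
            out.add(rec)
    return out


def sample_length_matched(
    target_lengths: Sequence[int],
    pool: SequenceSet,
    seed: int,
    exclude_sequences: Iterable[str] = (),
) -> SequenceSet:
    """Sample pool records matching a target length distribution.

    For each target length the unused pool record of nearest length is
    taken (ties broken by a seeded RNG), without replacement.  Pool records
    whose sequence is duplicated within the pool or appears in
    ``exclude_sequences`` are removed before sampling — mirroring the removal
    of reference sequences redundant with the query set.
    """
    if len(pool) == 0:
        raise ValueError("pool is empty")
    excluded = {s.upper() for s in exclude_sequences}
    seq_counts: dict[str, int] = {}
    for rec in pool:
        seq_counts[rec.sequence] = seq_counts.get(rec.sequence, 0) + 1
    candidates = [
        rec for rec in pool
        if seq_counts[rec.sequence] == 1 and rec.sequence not in excluded
    ]
    if len(candidates) < len(target_lengths):
        raise ValueError(
            f"pool exhausted: {len(candidates)} usable records for "
            f"{len(target_lengths)} targets"
        )
    rng = np.random.default_rng(seed)
    # sorted (length, tiebreak, index) supports nearest-length bisection
    keyed = sorted(
        (len(rec), float(rng.random()), i) for i, rec in enumerate(candidates)
    )
    order = list(range(len(target_lengths)))
    rng.shuffle(order)
    chosen: dict[int, int] = {}  # target position -> candidate index
    for pos in order:
        t = target_lengths[pos]
        if not keyed:
            raise ValueError(f"pool exhausted at target length {t}")
        j = bisect_left(keyed, (t,))
        best = None
        for cand in (j - 1, j):
            if 0 <= cand < len(keyed):
                if best is None or abs(keyed[cand][0] - t) < abs(keyed[best][0] - t):
                    best = cand
        chosen[pos] = keyed[best][2]
        keyed.pop(best)
    out = SequenceSet(name=f"{pool.name}_matched")
    for pos in range(len(target_lengths)):
        out.add(candidates[chosen[pos]])
    return out
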