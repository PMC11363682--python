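"""Composition-matched random sequence generation (the R-DN / R-C sets).

Given a source set, emit one random sequence per source record with exactly
the source's multiset of lengths.  Two modes:

``permutation``
    All source residues are pooled, shuffled with a seeded RNG and re-split
    at the source lengths, so the pooled amino-acid composition is conserved
    *exactly*.
``iid``
    Residues are drawn independently from the pooled source frequency
    vector, conserving composition in expectation only.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from denovoscape.datasets import ProteinRecord, SequenceSet

MODES = ("permutation", "iid")


@dataclass(frozen=True)
class RandomizerConfig:
    mode: str = "permutation"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")


def pooled_composition(source: SequenceSet) -> Counter:
    """Pooled residue counts over all source sequences ('X' excluded)."""
    counts: Counter = Counter()
    for rec in source:
        counts.update(c for c in rec.sequence if c != "X")
    return counts


def randomize_set(
    source: SequenceSet,
    config: RandomizerConfig,
    class_label: str | None = None,
) -> SequenceSet:
    """Generate the randomised counterpart of ``source``.

    Output ids are the source ids suffixed ``"_rand"``; lengths match
    record-for-record.  ``class_label`` optionally sets the label on the
    generated records (e.g. ``"R-DN"``).
    """
    if len(source) == 0:
        raise ValueError("cannot randomize an empty set")
    rng = np.random.default_rng(config.seed)
    lengths = source.lengths()
    out = SequenceSet(name=f"{source.name}_rand")
    label = class_label if class_label is not None else "OTHER"

    if config.mode == "permutation":
        pool = np.array(list("".join(rec.sequence for rec in source)))
        rng.shuffle(pool)
        offsets = np.concatenate([[0], np.cumsum(lengths)])
        for rec, lo, hi in zip(source, offsets[:-1], offsets[1:]):
            seq = "".join(pool[lo:hi])
            out.add(ProteinRecord(id=f"{rec.id}_rand", sequence=seq, class_label=label))
    else:  # iid
        counts = pooled_composition(source)
        letters = sorted(counts)
        total = sum(counts.values())
        probs = np.array([counts[a] / total for a in letters])
        alphabet = np.array(letters)
        for rec in source:
            seq = "".join(rng.choice(alphabet, size=len(rec), p=probs))
            out.add(ProteinRecord(id=f"{rec.id}_rand", sequence=seq, class_label=label))
    return out
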