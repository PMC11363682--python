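"""Whole-sequence IDR-associated features and the feature matrix.

Computes the sequence features commonly associated with the biological
functions of intrinsically disordered regions — composition fractions,
charge statistics (NCPR, FCR, charge asymmetry), Das-Pappu charge
patterning (kappa), Shannon sequence complexity, Kyte-Doolittle hydropathy,
and per-letter homorepeat lengths — and assembles them into a named matrix
with explicit length-normalisation and exclusion provenance.

Conventions: histidine is treated as neutral; terminal charges are ignored;
'X' residues are excluded from composition statistics.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

POSITIVE = frozenset("KR")
NEGATIVE = frozenset("DE")
AROMATIC = frozenset("FWY")
ALIPHATIC = frozenset("AILMV")
POLAR = frozenset("STNQ")
AA20 = "ACDEFGHIKLMNPQRSTVWY"

# Kyte-Doolittle hydropathy scale
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

KAPPA_EXHAUSTIVE_MAX_LEN = 12
KAPPA_BLOB_SIZES = (5, 6)


def _canonical(seq: str) -> str:
    """Uppercase and drop 'X' placeholders (excluded from statistics)."""
    seq = seq.upper().replace("X", "")
    if not seq:
        raise ValueError("sequence empty after removing 'X' residues")
    return seq


# ---------------------------------------------------------------------------
# Charge features
# ---------------------------------------------------------------------------

def net_charge_per_residue(seq: str) -> float:
    """NCPR = (count(K,R) - count(D,E)) / length, in [-1, 1]."""
    seq = _canonical(seq)
    pos = sum(1 for c in seq if c in POSITIVE)
    neg = sum(1 for c in seq if c in NEGATIVE)
    return (pos - neg) / len(seq)


def fraction_charged(seq: str) -> float:
    """FCR = count(K,R,D,E) / length, in [0, 1]."""
    seq = _canonical(seq)
    return sum(1 for c in seq if c in POSITIVE | NEGATIVE) / len(seq)


def charge_asymmetry(seq: str) -> float:
    """Global charge asymmetry sigma = (f+ - f-)^2 / (f+ + f-); 0 when uncharged."""
    seq = _canonical(seq)
    return _sigma(_charge_vector(seq))


def _charge_vector(seq: str) -> tuple[int, ...]:
    return tuple(1 if c in POSITIVE else (-1 if c in NEGATIVE else 0) for c in seq)


def _sigma(charges: Sequence[int]) -> float:
    n = len(charges)
    fp = sum(1 for c in charges if c > 0) / n
    fm = sum(1 for c in charges if c < 0) / n
    if fp + fm == 0:
        return 0.0
    return (fp - fm) ** 2 / (fp + fm)


def _blobs(charges: Sequence[int], size: int) -> list[Sequence[int]]:
    # non-overlapping blobs; truncated final blob included
    return [charges[i:i + size] for i in range(0, len(charges), size)]


def _delta(charges: Sequence[int], size: int) -> float:
    glob = _sigma(charges)
    return float(np.mean([(_sigma(b) - glob) ** 2 for b in _blobs(charges, size)]))


def _delta_max(charges: Sequence[int], size: int) -> float:
    """Maximum delta over rearrangements of the same charge composition.

    Exhaustive over distinct arrangements for short sequences; for longer
    sequences the maximally segregated arrangement is taken from the six
    orderings of the (+, neutral, -) blocks.
    """
    n = len(charges)
    npos = sum(1 for c in charges if c > 0)
    nneg = sum(1 for c in charges if c < 0)
    if n <= KAPPA_EXHAUSTIVE_MAX_LEN:
        # enumerate distinct arrangements by charge positions (multinomial
        # count, not n! raw permutations)
        best = 0.0
        positions = range(n)
        for pos_idx in itertools.combinations(positions, npos):
            rest = [i for i in positions if i not in pos_idx]
            for neg_idx in itertools.combinations(rest, nneg):
                arrangement = [0] * n
                for i in pos_idx:
                    arrangement[i] = 1
                for i in neg_idx:
                    arrangement[i] = -1
                best = max(best, _delta(arrangement, size))
        return best
    nzero = n - npos - nneg
    blocks = {"+": [1] * npos, "-": [-1] * nneg, "0": [0] * nzero}
    best = 0.0
    for order in itertools.permutations("+-0"):
        arrangement = [c for key in order for c in blocks[key]]
        best = max(best, _delta(arrangement, size))
    return best


def kappa(seq: str, blob_sizes: Sequence[int] = KAPPA_BLOB_SIZES) -> float | None:
    """Das-Pappu charge-patterning kappa in [0, 1].

    0 = charges well mixed along the chain, 1 = maximally segregated for
    the given composition.  For each blob size, delta is the mean squared
    deviation of blob-wise charge asymmetry from the global asymmetry;
    kappa averages delta / delta_max over blob sizes, where delta_max is
    the delta of the most segregated arrangement of the same composition.
    Returns ``None`` (with a warning) for sequences with fewer than two
    charged residues, for which patterning is undefined.
    """
    seq = _canonical(seq)
    charges = _charge_vector(seq)
    n_charged = sum(1 for c in charges if c != 0)
    if n_charged < 2:
        warnings.warn("kappa undefined for < 2 charged residues; returning NA")
        return None
    ratios = []
    for size in blob_sizes:
        d = _delta(charges, size)
        dmax = _delta_max(charges, size)
        if dmax == 0:
            continue
        ratios.append(d / dmax)
    if not ratios:
        warnings.warn("kappa undefined (zero delta_max); returning NA")
        return None
    return float(np.clip(np.mean(ratios), 0.0, 1.0))


# ---------------------------------------------------------------------------
# Complexity / hydropathy / repeats / spacing
# ---------------------------------------------------------------------------

def sequence_complexity(seq: str) -> float:
    """Normalised Shannon entropy of amino-acid usage, in [0, 1].

    H = -sum f_a log f_a / log 20; 0 for a homopolymer, 1 for uniform usage
    of all 20 letters.  Base-free (any log base gives the same value).
    """
    seq = _canonical(seq)
    counts = np.array([seq.count(a) for a in AA20], dtype=float)
    freqs = counts[counts > 0] / len(seq)
    return float(-(freqs * np.log(freqs)).sum() / math.log(20))


def mean_hydropathy(seq: str) -> float:
    """Mean Kyte-Doolittle hydropathy over all residues."""
    seq = _canonical(seq)
    return float(np.mean([KYTE_DOOLITTLE[c] for c in seq]))


def max_homorepeat(seq: str) -> dict[str, int]:
    """Longest single-letter run per amino acid (0 for absent letters)."""
    seq = _canonical(seq)
    runs = {a: 0 for a in AA20}
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        runs[seq[i]] = max(runs[seq[i]], j - i)
        i = j
    return runs


def aromatic_spacing(seq: str) -> float:
    """Mean gap between consecutive aromatic residues, scaled by length.

    Excluded from the default catalog (a specifically discarded feature);
    implemented so the exclusion is a policy, not a gap.
    """
    seq = _canonical(seq)
    pos = [i for i, c in enumerate(seq) if c in AROMATIC]
    if len(pos) < 2:
        return 0.0
    gaps = np.diff(pos)
    return float(np.mean(gaps) / len(seq))


def omega_aromatic(seq: str) -> float:
    """Patterning of aromatic residues against all others (kappa-style).

    Excluded from the default catalog by the same policy as
    :func:`aromatic_spacing`.
    """
    seq = _canonical(seq)
    binary = tuple(1 if c in AROMATIC else -1 for c in seq)
    if sum(1 for c in binary if c > 0) < 2:
        return 0.0
    ratios = []
    for size in KAPPA_BLOB_SIZES:
        d = _delta(binary, size)
        dmax = _delta_max(binary, size)
        if dmax > 0:
            ratios.append(d / dmax)
    return float(np.clip(np.mean(ratios), 0.0, 1.0)) if ratios else 0.0


def kappa_star(seq: str) -> float:
    """Single-blob-size (5) kappa variant; excluded from the default catalog."""
    seq = _canonical(seq)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        k = kappa(seq, blob_sizes=(5,))
    return 0.0 if k is None else k


# ---------------------------------------------------------------------------
# Catalog and matrix assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureDef:
    name: str
    func: Callable[[str], float]
    length_dependent: bool = False
    excluded: bool = False


class FeatureCatalog:
    """Named feature definitions with length-dependence and exclusion flags.

    The default catalog (~48 features) covers the cited feature families:
    per-letter and group composition fractions, charge (NCPR, FCR,
    asymmetry), patterning (kappa), complexity, hydropathy, per-letter
    homorepeat run lengths and sequence length.  Users may register
    additional features; the downstream pipeline is agnostic to catalog
    size.
    """

    def __init__(self, entries: Iterable[FeatureDef] = ()) -> None:
        self._entries: dict[str, FeatureDef] = {}
        for e in entries:
            self.register(e)

    def register(self, entry: FeatureDef) -> None:
        if entry.name in self._entries:
            raise ValueError(f"feature {entry.name!r} already registered")
        self._entries[entry.name] = entry

    @property
    def names(self) -> list[str]:
        return list(self._entries)

    @property
    def active_names(self) -> list[str]:
        return [n for n, e in self._entries.items() if not e.excluded]

    @property
    def excluded_names(self) -> list[str]:
        return [n for n, e in self._entries.items() if e.excluded]

    def __getitem__(self, name: str) -> FeatureDef:
        return self._entries[name]

    def __len__(self) -> int:
        return len(self._entries)

    def with_exclusions(self, excluded: Iterable[str]) -> "FeatureCatalog":
        excluded = set(excluded)
        unknown = excluded - set(self._entries)
        if unknown:
            raise KeyError(f"unknown features in exclusion list: {sorted(unknown)}")
        out = FeatureCatalog()
        for name, e in self._entries.items():
            out.register(FeatureDef(name, e.func, e.length_dependent,
                                    excluded=name in excluded))
        return out


def _kappa_or_zero(seq: str) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        k = kappa(seq)
    return 0.0 if k is None else k


def default_catalog() -> FeatureCatalog:
    """Build the default feature catalog.

    ``aromatic_spacing``, ``omega_aromatic*`` and ``kappa*`` are registered
    but excluded, mirroring the discard policy of the condensate workflow
    (binding-motif count features are simply not part of this catalog).
    """
    entries: list[FeatureDef] = []
    for a in AA20:
        entries.append(FeatureDef(
            f"frac_{a}", lambda s, a=a: _canonical(s).count(a) / len(_canonical(s))
        ))
    entries += [
        FeatureDef("frac_aromatic",
                   lambda s: sum(1 for c in _canonical(s) if c in AROMATIC)
                   / len(_canonical(s))),
        FeatureDef("frac_aliphatic",
                   lambda s: sum(1 for c in _canonical(s) if c in ALIPHATIC)
                   / len(_canonical(s))),
        FeatureDef("frac_polar",
                   lambda s: sum(1 for c in _canonical(s) if c in POLAR)
                   / len(_canonical(s))),
        FeatureDef("ncpr", net_charge_per_residue),
        FeatureDef("fcr", fraction_charged),
        FeatureDef("charge_asymmetry", charge_asymmetry),
        FeatureDef("kappa", _kappa_or_zero),
        FeatureDef("complexity", sequence_complexity),
        FeatureDef("hydropathy_mean", mean_hydropathy),
        FeatureDef("length", lambda s: float(len(_canonical(s)))),
    ]
    for a in AA20:
        entries.append(FeatureDef(
            f"maxrun_{a}", lambda s, a=a: float(max_homorepeat(s)[a]),
            length_dependent=True,
        ))
    entries += [
        FeatureDef("aromatic_spacing", aromatic_spacing, excluded=True),
        FeatureDef("omega_aromatic*", omega_aromatic, excluded=True),
        FeatureDef("kappa*", kappa_star, excluded=True),
    ]
    return FeatureCatalog(entries)


@dataclass
class FeatureMatrix:
    """Proteins x features value matrix with normalisation provenance."""

    protein_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    normalized: bool = False
    length_dependent: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.protein_ids), len(self.feature_names)):
            raise ValueError("matrix shape does not match ids x features")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains missing/non-finite values")

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]

    def to_tsv(self, path: str | Path) -> None:
        """Write the matrix as TSV plus a JSON sidecar with provenance."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(self.feature_names) + "\n")
            for pid, row in zip(self.protein_ids, self.values):
                fh.write(pid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
        sidecar = {
            "feature_names": self.feature_names,
            "normalized": self.normalized,
            "length_dependent": self.length_dependent,
            "n_proteins": len(self.protein_ids),
        }
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump(sidecar, fh, indent=1)


def compute_feature_matrix(
    sset,
    catalog: FeatureCatalog | None = None,
    features: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Evaluate every non-excluded catalog feature for every sequence.

    ``features`` optionally restricts the computation to named features;
    explicitly requesting an excluded feature raises, naming the exclusion
    rule.  Undefined feature values (e.g. patterning of an uncharged
    sequence) enter the matrix as 0 so that no cell is missing.
    """
    catalog = catalog if catalog is not None else default_catalog()
    if features is None:
        names = catalog.active_names
    else:
        names = list(features)
        for n in names:
            if n not in catalog.names:
                raise KeyError(f"unknown feature {n!r}")
            if catalog[n].excluded:
                raise ValueError(
                    f"feature {n!r} is excluded from this catalog by the "
                    "condensate-workflow discard policy; re-register or use "
                    "with_exclusions() to override"
                )
    ids = [rec.id for rec in sset]
    values = np.empty((len(ids), len(names)))
    for i, rec in enumerate(sset):
        for j, n in enumerate(names):
            values[i, j] = catalog[n].func(rec.sequence)
    return FeatureMatrix(
        protein_ids=ids,
        feature_names=names,
        values=values,
        normalized=False,
        length_dependent=[n for n in names if catalog[n].length_dependent],
    )


def normalize_length_dependent(
    matrix: FeatureMatrix, lengths: Mapping[str, int] | Sequence[int]
) -> FeatureMatrix:
    """Divide length-dependent (count-type) features by each row's sequence length."""
    if matrix.normalized:
        raise ValueError("feature matrix is already normalized")
    if isinstance(lengths, Mapping):
        lens = np.array([lengths[pid] for pid in matrix.protein_ids], dtype=float)
    else:
        lens = np.asarray(lengths, dtype=float)
        if lens.shape[0] != len(matrix.protein_ids):
            raise ValueError("one length per row required")
    values = matrix.values.copy()
    for name in matrix.length_dependent:
        j = matrix.feature_names.index(name)
        values[:, j] = values[:, j] / lens
    return FeatureMatrix(
        protein_ids=list(matrix.protein_ids),
        feature_names=list(matrix.feature_names),
        values=values,
        normalized=True,
        length_dependent=list(matrix.length_dependent),
    )
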