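"""Seeded synthetic input bundle with planted ground truth.

Generates, from one seed, every input the pipeline consumes — sequence
FASTA + metadata, per-residue disorder scores, secondary-structure strings,
trajectory RMSD series, structure-search hit tables with decoys, an ECOD
architecture map, condensate propensity scores, a positive reference list,
GO annotation tables, and pooled embeddings — together with the planted
truth each stage should recover.  All fixtures are synthetic stand-ins for
external predictor outputs; they emulate the statistical structure the
analysis assumes (class-shifted amino-acid compositions, planted
disorder/helix fractions, planted structure hits, a positive condensate set
concentrated in feature space, class-separated embeddings), not the
predictors themselves.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from denovoscape.datasets import (
    ProteinRecord,
    SequenceSet,
    write_fasta,
    write_metadata,
)
from denovoscape.randomizer import RandomizerConfig, randomize_set
from denovoscape.seqspace import HashedKmerEmbedder

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _normalized(freqs: Mapping[str, float]) -> np.ndarray:
    v = np.array([freqs.get(a, 0.0) for a in AA20], dtype=float)
    if (v < 0).any() or v.sum() == 0:
        raise ValueError("invalid composition vector")
    return v / v.sum()


#: background composition for conserved proteins (roughly proteome-like)
FREQ_CONSERVED = {
    "A": 0.080, "C": 0.015, "D": 0.054, "E": 0.067, "F": 0.039, "G": 0.071,
    "H": 0.022, "I": 0.059, "K": 0.058, "L": 0.097, "M": 0.024, "N": 0.040,
    "P": 0.047, "Q": 0.039, "R": 0.055, "S": 0.066, "T": 0.053, "V": 0.069,
    "W": 0.011, "Y": 0.029,
}

#: background de novo composition: shifted toward the residues enriched in
#: intergenic translations (I/F/K/N up, charged/aliphatic balance changed)
FREQ_DENOVO = {
    "A": 0.055, "C": 0.020, "D": 0.040, "E": 0.048, "F": 0.055, "G": 0.050,
    "H": 0.028, "I": 0.085, "K": 0.075, "L": 0.105, "M": 0.030, "N": 0.060,
    "P": 0.040, "Q": 0.035, "R": 0.045, "S": 0.075, "T": 0.055, "V": 0.055,
    "W": 0.014, "Y": 0.030,
}

#: condensate regime A: acidic, low-complexity (E/D/G/S rich)
FREQ_CONDENSATE_A = {
    "A": 0.020, "C": 0.001, "D": 0.150, "E": 0.220, "F": 0.004, "G": 0.190,
    "H": 0.005, "I": 0.005, "K": 0.030, "L": 0.010, "M": 0.004, "N": 0.030,
    "P": 0.070, "Q": 0.060, "R": 0.010, "S": 0.160, "T": 0.025, "V": 0.005,
    "W": 0.001, "Y": 0.004,
}

#: condensate regime B: basic, aromatic-sticker flavoured (R/K/Y/S/G rich)
FREQ_CONDENSATE_B = {
    "A": 0.020, "C": 0.001, "D": 0.015, "E": 0.025, "F": 0.015, "G": 0.170,
    "H": 0.010, "I": 0.005, "K": 0.140, "L": 0.010, "M": 0.004, "N": 0.030,
    "P": 0.060, "Q": 0.060, "R": 0.180, "S": 0.170, "T": 0.025, "V": 0.005,
    "W": 0.002, "Y": 0.075,
}

NON_TARGET_TAXA = (
    "Homo sapiens", "Mus musculus", "Danio rerio", "Saccharomyces cerevisiae",
    "Caenorhabditis elegans", "Arabidopsis thaliana",
)
EXCLUDED_TAXA_EXAMPLES = ("Drosophila melanogaster", "Drosophila simulans")
ARCHITECTURES = (
    "alpha bundles", "alpha arrays", "beta sandwiches", "a+b two layers",
    "alpha/beta barrels", "few secondary structure elements",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic bundle.

    Defaults define a desk-scale counterpart of the full-scale analysis:
    150 proteins per class (DN, C and their randomisations) plus 40
    positive reference condensate formers, 60 planted condensate-forming
    de novo proteins split over two composition regimes, log-normal
    lengths, and clustering parameters scaled from 100/50 to 30/15 in
    proportion to the smaller dataset.
    """

    n_per_class: int = 150
    n_positives: int = 40
    n_planted_condensate: int = 60
    length_mu: float = 4.3       # log-normal location of sequence lengths
    length_sigma: float = 0.45
    min_length: int = 30
    max_length: int = 400
    n_planted_hits: int = 25
    n_decoy_queries: int = 40
    frac_fail_disorder: float = 0.25
    frac_fail_helix: float = 0.15
    embedding_dim: int = 64
    #: per-dimension centroid offset magnitude per class (embedding space)
    centroid_geometry: Mapping[str, float] = field(
        default_factory=lambda: {
            "DN": 0.0, "R-DN": 0.5, "R-C": 0.7, "C": 3.0, "POSITIVE": 0.3,
        }
    )
    embedding_noise: float = 0.5
    #: age-group counts for the de novo set (young, intermediate, old)
    age_counts: tuple[int, int, int] = (90, 30, 30)
    #: relative weight of each age group when planting condensate formers
    condensate_age_weights: Mapping[str, float] = field(
        default_factory=lambda: {"young": 1.0, "intermediate": 6.0, "old": 6.0}
    )
    #: per-class probability of a confident CC/MF/BP annotation
    go_annotation_rates: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "DN": {"MF": 0.20, "BP": 0.25, "CC": 0.33},
            "R-DN": {"MF": 0.18, "BP": 0.22, "CC": 0.19},
        }
    )
    #: extra CC annotation odds for older de novo proteins
    go_cc_age_rates: Mapping[str, float] = field(
        default_factory=lambda: {"young": 0.28, "intermediate": 0.45, "old": 0.60}
    )
    min_cluster_size: int = 30   # desk-scale counterpart of 100
    min_samples: int = 15        # desk-scale counterpart of 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted_condensate > self.n_per_class:
            raise ValueError("n_planted_condensate cannot exceed n_per_class")
        if sum(self.age_counts) != self.n_per_class:
            raise ValueError("age_counts must sum to n_per_class")
        if self.n_planted_hits + self.n_decoy_queries > self.n_per_class:
            raise ValueError("too many hit queries for n_per_class")
        if min(self.n_per_class, self.n_positives) <= 0:
            raise ValueError("counts must be positive")


@dataclass
class GroundTruth:
    """Planted truth for every emitted protein and hit row."""

    class_label: dict[str, str]
    age_group: dict[str, str]
    condensate: dict[str, bool]
    passes_sim: dict[str, bool]
    hit_target: dict[str, str | None]
    hit_architecture: dict[str, str | None]
    hit_row_pass: list[bool]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "class_label": self.class_label,
            "age_group": self.age_group,
            "condensate": self.condensate,
            "passes_sim": self.passes_sim,
            "hit_target": self.hit_target,
            "hit_architecture": self.hit_architecture,
            "hit_row_pass": self.hit_row_pass,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            class_label=d["class_label"],
            age_group=d["age_group"],
            condensate=d["condensate"],
            passes_sim=d["passes_sim"],
            hit_target=d["hit_target"],
            hit_architecture=d["hit_architecture"],
            hit_row_pass=d["hit_row_pass"],
        )


def _sample_lengths(rng: np.random.Generator, n: int, cfg: SyntheticConfig) -> np.ndarray:
    lens = np.exp(rng.normal(cfg.length_mu, cfg.length_sigma, size=n))
    return np.clip(np.round(lens), cfg.min_length, cfg.max_length).astype(int)


def _draw_sequence(rng: np.random.Generator, length: int, freqs: np.ndarray) -> str:
    return "".join(rng.choice(list(AA20), size=length, p=freqs))


def generate_bundle(config: SyntheticConfig, out_dir: str | Path) -> dict:
    """Write the full synthetic bundle into ``out_dir``.

    Returns a dict of output paths plus the :class:`GroundTruth`.  Fully
    reproducible: the same config (including seed) yields byte-identical
    files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    seeds = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("sequences", "ages", "condensate", "screen", "hits", "picnic",
             "go", "embeddings"),
            root.spawn(8),
        )
    }
    rand_seed_dn, rand_seed_c = (
        int(s.generate_state(1)[0] % (2 ** 31)) for s in root.spawn(2)
    )

    truth = GroundTruth({}, {}, {}, {}, {}, {}, [])

    # --- de novo set with ages, planted condensate regimes -----------------
    rng = seeds["sequences"]
    age_rng = seeds["ages"]
    cond_rng = seeds["condensate"]
    n_young, n_inter, n_old = config.age_counts
    age_groups = ["young"] * n_young + ["intermediate"] * n_inter + ["old"] * n_old
    # allocate planted condensate formers across age groups in proportion
    # to group size x configured weight (largest-remainder rounding), then
    # sample members within each group
    group_members: dict[str, list[int]] = {}
    for i, g in enumerate(age_groups):
        group_members.setdefault(g, []).append(i)
    mass = {g: len(m) * config.condensate_age_weights[g]
            for g, m in group_members.items()}
    total_mass = sum(mass.values())
    quota = {g: config.n_planted_condensate * mass[g] / total_mass
             for g in group_members}
    alloc = {g: min(len(group_members[g]), int(quota[g])) for g in group_members}
    remainders = sorted(group_members, key=lambda g: quota[g] - int(quota[g]),
                        reverse=True)
    k = 0
    while sum(alloc.values()) < config.n_planted_condensate:
        g = remainders[k % len(remainders)]
        if alloc[g] < len(group_members[g]):
            alloc[g] += 1
        k += 1
    planted_idx: set[int] = set()
    for g in sorted(group_members):
        planted_idx.update(
            cond_rng.choice(group_members[g], size=alloc[g],
                            replace=False).tolist()
        )
    freq_dn = _normalized(FREQ_DENOVO)
    freq_a = _normalized(FREQ_CONDENSATE_A)
    freq_b = _normalized(FREQ_CONDENSATE_B)
    dn_lengths = _sample_lengths(rng, config.n_per_class, config)
    dn = SequenceSet(name="DN")
    planted_sorted = sorted(planted_idx)
    for i in range(config.n_per_class):
        pid = f"DN{i + 1:04d}"
        g = age_groups[i]
        if g == "young":
            age = float(age_rng.uniform(0.5, 4.9))
        elif g == "intermediate":
            age = float(age_rng.uniform(5.0, 30.0))
        else:
            age = float(age_rng.uniform(30.5, 80.0))
        if i in planted_idx:
            # condensate formers are long, IDR-dominated proteins
            length = int(rng.integers(150, config.max_length + 1))
            regime = freq_a if planted_sorted.index(i) % 2 == 0 else freq_b
            seq = _draw_sequence(rng, length, regime)
        else:
            seq = _draw_sequence(rng, dn_lengths[i], freq_dn)
        origin = "denovo" if rng.random() < 0.6 else "denovo-intron"
        dn.add(ProteinRecord(pid, seq, class_label="DN",
                             emergence_origin=origin, age_mya=round(age, 2)))
        truth.class_label[pid] = "DN"
        truth.age_group[pid] = g
        truth.condensate[pid] = i in planted_idx

    # --- conserved set -----------------------------------------------------
    freq_c = _normalized(FREQ_CONSERVED)
    c_lengths = _sample_lengths(rng, config.n_per_class, config)
    conserved = SequenceSet(name="C")
    for i in range(config.n_per_class):
        pid = f"C{i + 1:04d}"
        seq = _draw_sequence(rng, c_lengths[i], freq_c)
        age = float(age_rng.uniform(40.0, 150.0))
        conserved.add(ProteinRecord(pid, seq, class_label="C", age_mya=round(age, 1)))
        truth.class_label[pid] = "C"
        truth.age_group[pid] = "old"
        truth.condensate[pid] = False

    # --- randomized counterparts -------------------------------------------
    r_dn = randomize_set(dn, RandomizerConfig("permutation", rand_seed_dn), "R-DN")
    r_c = randomize_set(conserved, RandomizerConfig("permutation", rand_seed_c), "R-C")
    for rec in r_dn:
        truth.class_label[rec.id] = "R-DN"
        truth.age_group[rec.id] = "NA"
        truth.condensate[rec.id] = False
    for rec in r_c:
        truth.class_label[rec.id] = "R-C"
        truth.age_group[rec.id] = "NA"
        truth.condensate[rec.id] = False

    # --- positive reference condensate formers -----------------------------
    positives = SequenceSet(name="POSITIVE")
    for i in range(config.n_positives):
        pid = f"POS{i + 1:03d}"
        regime = freq_a if i % 2 == 0 else freq_b
        seq = _draw_sequence(rng, int(rng.integers(150, config.max_length + 1)),
                             regime)
        positives.add(ProteinRecord(pid, seq, class_label="POSITIVE"))
        truth.class_label[pid] = "POSITIVE"
        truth.age_group[pid] = "NA"
        truth.condensate[pid] = True

    all_records = SequenceSet(name="bundle")
    for sset in (dn, conserved, r_dn, r_c, positives):
        for rec in sset:
            all_records.add(rec)

    write_fasta(all_records, out / "sequences.fasta")
    write_metadata(all_records, out / "metadata.tsv")
    with open(out / "positives.txt", "w") as fh:
        for rec in positives:
            fh.write(rec.id + "\n")

    # --- disorder profiles and secondary structure (DN only) ---------------
    scr = seeds["screen"]
    n_dn = len(dn)
    fail_dis = set(scr.choice(n_dn, size=round(config.frac_fail_disorder * n_dn),
                              replace=False).tolist())
    fail_hel = set(scr.choice(n_dn, size=round(config.frac_fail_helix * n_dn),
                              replace=False).tolist())
    ss_codes = np.array(list("HET S-G".replace(" ", "S")))
    with open(out / "disorder.tsv", "w") as dfh, open(out / "ss.tsv", "w") as sfh:
        dfh.write("id\tposition\tscore\n")
        sfh.write("id\tcodes\n")
        for i, rec in enumerate(dn):
            L = len(rec)
            # plant the disordered fraction exactly on either side of 30%
            frac = (scr.uniform(0.35, 0.9) if i in fail_dis
                    else scr.uniform(0.02, 0.25))
            n_high = int(round(frac * L))
            n_high = min(L, max(0, n_high))
            high_pos = set(scr.choice(L, size=n_high, replace=False).tolist())
            for pos in range(L):
                s = (scr.uniform(0.5, 1.0) if pos in high_pos
                     else scr.uniform(0.0, 0.4999))
                dfh.write(f"{rec.id}\t{pos + 1}\t{s:.4f}\n")
            # plant the helix fraction on either side of 95%
            if i in fail_hel:
                n_h = L if scr.random() < 0.5 else int(math.ceil(0.96 * L))
            else:
                n_h = int(round(scr.uniform(0.05, 0.80) * L))
            helix_pos = set(scr.choice(L, size=min(n_h, L), replace=False).tolist())
            codes = "".join(
                "H" if pos in helix_pos else str(scr.choice(list("ETS-G")))
                for pos in range(L)
            )
            sfh.write(f"{rec.id}\t{codes}\n")
            passes = (i not in fail_dis) and (n_h / L < 0.95)
            truth.passes_sim[rec.id] = bool(passes)

    # --- structure hits, decoys, RMSD, ECOD map ----------------------------
    hrng = seeds["hits"]
    survivors = [rec.id for rec in dn if truth.passes_sim[rec.id]]
    if len(survivors) < config.n_planted_hits:
        raise ValueError("not enough screen survivors to plant structure hits")
    hit_queries = sorted(
        hrng.choice(len(survivors), size=config.n_planted_hits,
                    replace=False).tolist()
    )
    hit_query_ids = [survivors[j] for j in hit_queries]
    remaining = [rec.id for rec in dn if rec.id not in set(hit_query_ids)]
    decoy_ids = [
        remaining[j] for j in sorted(
            hrng.choice(len(remaining), size=min(config.n_decoy_queries,
                                                 len(remaining)),
                        replace=False).tolist()
        )
    ]
    ecod_map: dict[str, str] = {}
    rows: list[tuple] = []
    for qi, qid in enumerate(hit_query_ids):
        target = f"T{qi + 1:04d}"
        arch = ARCHITECTURES[qi % len(ARCHITECTURES)]
        ecod_map[target] = arch
        best_tm = float(hrng.uniform(0.55, 0.95))
        best_rep = int(hrng.integers(1, 4))
        taxon = NON_TARGET_TAXA[qi % len(NON_TARGET_TAXA)]
        for rep in (1, 2, 3):
            tm = best_tm if rep == best_rep else max(
                0.51, best_tm - float(hrng.uniform(0.01, 0.1))
            )
            cov = float(hrng.uniform(0.8, 1.0))
            ev = float(10 ** -hrng.uniform(3, 10))
            rows.append((qid, target, tm, cov, taxon, rep, ev))
            truth.hit_row_pass.append(True)
        truth.hit_target[qid] = target
        truth.hit_architecture[qid] = arch
    for qi, qid in enumerate(decoy_ids):
        target = f"D{qi + 1:04d}"
        mode = qi % 3
        if mode == 0:      # fails the TM-score rule (<= 0.5)
            tm, cov, taxon = float(hrng.uniform(0.1, 0.5)), float(hrng.uniform(0.8, 1.0)), NON_TARGET_TAXA[qi % len(NON_TARGET_TAXA)]
        elif mode == 1:    # fails the coverage rule (< 0.8)
            tm, cov, taxon = float(hrng.uniform(0.55, 0.9)), float(hrng.uniform(0.1, 0.79)), NON_TARGET_TAXA[qi % len(NON_TARGET_TAXA)]
        else:              # within-clade hit, excluded by taxon
            tm, cov, taxon = float(hrng.uniform(0.55, 0.9)), float(hrng.uniform(0.8, 1.0)), EXCLUDED_TAXA_EXAMPLES[qi % 2]
        ev = float(10 ** -hrng.uniform(1, 6))
        rows.append((qid, target, tm, cov, taxon, int(hrng.integers(1, 4)), ev))
        truth.hit_row_pass.append(False)
        if qi % 2 == 0:
            ecod_map[target] = ARCHITECTURES[qi % len(ARCHITECTURES)]
        truth.hit_target[qid] = None
        truth.hit_architecture[qid] = None
    for rec in dn:
        truth.hit_target.setdefault(rec.id, None)
        truth.hit_architecture.setdefault(rec.id, None)
    with open(out / "hits.tsv", "w") as fh:
        fh.write("query\ttarget\ttm_score\ttarget_coverage\ttaxon\treplicate\tevalue\n")
        for q, t, tm, cov, tax, rep, ev in rows:
            fh.write(f"{q}\t{t}\t{tm:.4f}\t{cov:.4f}\t{tax}\t{rep}\t{ev:.3e}\n")
    with open(out / "ecod_map.tsv", "w") as fh:
        fh.write("target_id\tarchitecture\n")
        for t in sorted(ecod_map):
            fh.write(f"{t}\t{ecod_map[t]}\n")

    # RMSD: flexibility decreases with structural similarity (negative
    # RMSD / TM-score correlation planted among hit-bearing proteins)
    best_tm_by_query = {qid: 0.0 for qid in hit_query_ids}
    for q, _, tm, _, _, _, _ in rows:
        if q in best_tm_by_query:
            best_tm_by_query[q] = max(best_tm_by_query[q], tm)
    with open(out / "rmsd.tsv", "w") as fh:
        fh.write("id\treplicate\tframe\trmsd\n")
        for rec in dn:
            if not truth.passes_sim[rec.id]:
                continue
            tm = best_tm_by_query.get(rec.id)
            if tm is not None:
                base = 12.0 - 10.0 * tm + float(hrng.normal(0, 0.8))
                base = max(0.5, base)
            else:
                base = float(hrng.uniform(4.0, 12.0))
            for rep in (1, 2, 3):
                level = base + float(hrng.normal(0, 0.3))
                for frame in range(1, 21):
                    v = max(0.0, level + float(hrng.normal(0, 0.2)))
                    fh.write(f"{rec.id}\t{rep}\t{frame}\t{v:.3f}\n")

    # --- condensate propensity scores --------------------------------------
    prng = seeds["picnic"]
    with open(out / "picnic.tsv", "w") as fh:
        fh.write("id\tscore\n")
        for rec in list(dn) + list(positives):
            if truth.condensate[rec.id]:
                s = float(prng.beta(8, 2))
            else:
                s = float(prng.beta(2, 8))
            fh.write(f"{rec.id}\t{s:.4f}\n")

    # --- GO annotations ----------------------------------------------------
    grng = seeds["go"]
    go_counter = 0
    with open(out / "go.tsv", "w") as fh:
        fh.write("protein_id\tgo_id\tgo_class\tscore\n")
        for sset, label in ((dn, "DN"), (r_dn, "R-DN")):
            rates = config.go_annotation_rates[label]
            for rec in sset:
                for go_class in ("MF", "BP", "CC"):
                    rate = rates[go_class]
                    if label == "DN" and go_class == "CC":
                        rate = config.go_cc_age_rates[truth.age_group[rec.id]]
                    if grng.random() < rate:
                        go_counter += 1
                        score = float(grng.uniform(0.5, 1.0))
                        fh.write(f"{rec.id}\tGO:{go_counter:07d}\t{go_class}"
                                 f"\t{score:.3f}\n")
                    if grng.random() < 0.2:  # sub-threshold noise annotation
                        go_counter += 1
                        score = float(grng.uniform(0.0, 0.4999))
                        fh.write(f"{rec.id}\tGO:{go_counter:07d}\t{go_class}"
                                 f"\t{score:.3f}\n")

    # --- pooled embeddings --------------------------------------------------
    erng = seeds["embeddings"]
    dim = config.embedding_dim
    embedder = HashedKmerEmbedder(dim=dim, k=3, seed=config.seed)
    sign_vectors = {
        cls: erng.choice([-1.0, 1.0], size=dim)
        for cls in ("DN", "R-DN", "R-C", "C", "POSITIVE")
    }
    ids, labels, vectors = [], [], []
    for rec in all_records:
        cls = truth.class_label[rec.id]
        pooled = embedder.embed(rec.id, rec.sequence).matrix.mean(axis=0)
        offset = config.centroid_geometry[cls] * sign_vectors[cls]
        noise = erng.normal(0, config.embedding_noise, size=dim)
        ids.append(rec.id)
        labels.append(cls)
        vectors.append(pooled + offset + noise)
    np.savez_compressed(out / "embeddings.npz", vectors=np.array(vectors))
    with open(out / "embeddings_manifest.tsv", "w") as fh:
        fh.write("id\tclass_label\n")
        for pid, lbl in zip(ids, labels):
            fh.write(f"{pid}\t{lbl}\n")

    truth.to_json(out / "ground_truth.json")

    return {
        "fasta": out / "sequences.fasta",
        "metadata": out / "metadata.tsv",
        "positives": out / "positives.txt",
        "disorder": out / "disorder.tsv",
        "ss": out / "ss.tsv",
        "rmsd": out / "rmsd.tsv",
        "hits": out / "hits.tsv",
        "ecod_map": out / "ecod_map.tsv",
        "picnic": out / "picnic.tsv",
        "go": out / "go.tsv",
        "embeddings": out / "embeddings.npz",
        "embeddings_manifest": out / "embeddings_manifest.tsv",
        "ground_truth": out / "ground_truth.json",
        "truth": GroundTruth.from_json(out / "ground_truth.json"),
    }
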