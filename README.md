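# denovoscape

Desk-scale analysis pipeline for characterising **de novo proteins** —
proteins translated from formerly nongenic (intergenic or intronic) DNA
that lack homology to conserved protein families. Motivated by the
*Drosophila* de novo protein complement, the package answers, from
sequences plus tabular predictor outputs: which candidates are structured
enough to simulate, which resemble known folds, which are likely
biomolecular-condensate formers, how functional annotation varies with
evolutionary age, and where de novo proteins sit in language-model sequence
space relative to conserved and random sequences.

It is aimed at molecular-evolution and structural-bioinformatics groups who
already run the heavyweight predictors (structure prediction and MD
refinement, per-residue disorder, DSSP, structure search, condensate
propensity scoring, GO prediction, protein language models) and need the
*downstream* analysis to be reproducible, testable and scriptable. All
predictor outputs enter as plain TSV/FASTA/NPZ; a synthetic-data module
generates a complete seeded input bundle with planted ground truth, so the
entire pipeline runs and is tested without any external download.

## What it computes

- **Curation** (`datasets`): class labels (DN de novo, C conserved,
  R-DN/R-C randomised, POSITIVE reference condensate formers), emergence
  origins, age groups — young (<5 mya), intermediate (5–30 mya),
  old (>30 mya) — drop-all deduplication, and length-matched reference
  sampling.
- **Randomisation** (`randomizer`): random sequence sets with exactly the
  source length multiset and, in permutation mode, exactly the pooled
  amino-acid composition (`iid` mode matches composition in expectation).
- **Structural triage** (`structure_screen`): simulation pre-filter
  (disorder fraction < 30% at score cutoff 0.5 **and** α-helix fraction
  < 95%), two-level replicate RMSD means, structure-hit filtering
  (TM-score > 0.5 strict, target coverage ≥ 0.8 inclusive, within-clade
  taxa excluded by prefix), best-hit-per-query across replicates, ECOD
  architecture assignment, and the age-group chi-square / RMSD–TM Pearson
  statistics.
- **IDR features** (`idr_features`): ~48 whole-sequence features —
  composition fractions, NCPR/FCR, charge asymmetry, Das–Pappu patterning
  κ (κ = mean over blob sizes of δ/δ_max, δ the blob-wise deviation of
  charge asymmetry σ = (f₊−f₋)²/(f₊+f₋) from its global value), normalised
  Shannon complexity H = −Σ f log f / log 20, Kyte–Doolittle hydropathy,
  homorepeat run lengths — with explicit length normalisation and the
  standard exclusions (`kappa*`, `omega_aromatic*`, `aromatic_spacing`).
- **Condensate calling** (`condensate_caller`): z-score → 5-D reduction
  (UMAP or PCA) → HDBSCAN → positive-enriched cluster selection (greedy
  coverage ≥ 0.85 with BH-adjusted hypergeometric tests) → high-confidence
  calls (enriched cluster **and** propensity score ≥ 0.5) → age-group fold
  enrichment.
- **Annotation statistics** (`annotation_stats`): GO score filtering
  (≥ 0.5), per-class annotated protein fractions, Fisher's exact and
  Pearson chi-square group comparisons.
- **Sequence space** (`seqspace`): mean-pooled per-residue embeddings,
  blockwise pairwise Manhattan (L1) distances, within/between-class
  summaries, exact/approximate one-sided Mann–Whitney U tests, cross-class
  nearest neighbours.
- **Synthetic data** (`synthetic_data`): the seeded bundle with planted
  truth behind every stage.

See `docs/methods.md` for the model, conventions and study conditions.

## Worked example

Generate a synthetic bundle and run the whole pipeline:

```bash
denovoscape synth --seed 1 --out bundle/
denovoscape run --bundle bundle/ --seed 1 --out run/
```

The run directory contains per-stage outputs (`screen_report.json`,
`features.tsv`, `condensate_calls.tsv`, `age_enrichment.json`,
`gostats.json`, `seqspace.json`) and a `manifest.json` with the config
hash, seed and per-stage row counts. With seed 1 the screen report reads

```json
{
 "n_dn": 150,
 "n_sim_survivors": 96,
 "n_assigned": 25,
 "rmsd_tm_pearson_r": -0.787,
 ...
}
```

meaning: of 150 de novo candidates, 96 pass the disorder/helix pre-filter,
25 end up structurally assigned to an ECOD architecture through their best
filtered hit, and mean simulation RMSD anti-correlates with best-hit
TM-score (flexible proteins resemble known structures less) — exactly the
structure planted by the generator. The condensate stage calls 59 of 150
candidates high-confidence (the bundle plants 60; F1 = 0.99 against the
planted truth), with fold enrichments of 6.0× (intermediate) and 5.75×
(old) relative to young proteins. The sequence-space stage reports median
L1 distances of 191.2 (DN↔C) versus 35.8 (within DN) and 45.0 (DN↔R-DN):
de novo proteins sit far from conserved proteins and close to random
sequences of matched composition.

The same operations are importable directly:

```python
from denovoscape import read_fasta, randomize_set, RandomizerConfig
dn = read_fasta("bundle/sequences.fasta")
rand = randomize_set(dn, RandomizerConfig(mode="permutation", seed=7))
```

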