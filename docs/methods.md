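# Methods

`denovoscape` re-implements, at desk scale, a multi-stage characterisation
of de novo proteins — proteins translated from formerly nongenic DNA, which
lack homology to conserved families. The pipeline takes protein sequences
plus the tabular outputs of external predictors (per-residue disorder,
secondary structure, trajectory RMSD, structure-search hits, condensate
propensity scores, GO predictions, per-residue embeddings) and runs the
downstream analysis: curation, composition-matched randomisation,
structural triage, IDR-feature-based condensate calling, annotation group
statistics, and embedding-space distance analysis. The heavyweight
predictors themselves (structure prediction, MD simulation, disorder/DSSP
inference, structure search, condensate scoring, language-model inference)
are out of scope; a synthetic-data generator emulates their outputs with
planted ground truth so every stage is testable offline.

## Dataset model

Each protein carries a class label — `DN` (de novo), `C` (conserved),
`R-DN`/`R-C` (their composition-matched randomisations), `POSITIVE`
(reference condensate formers) — an emergence origin (`denovo` intergenic
vs `denovo-intron` intronic), and an age in million years (mya), binned as
young (<5), intermediate (5–30, both ends inclusive) and old (>30). The
inclusive-intermediate boundary convention is a package decision; the
source conventions state only "<5", "5–30", ">30".

Curation removes records sharing a duplicated key with a **drop-all**
policy (every member of the duplicated group is removed; `keep-first` is
available). `X` residues are tolerated on input, flagged, and excluded from
all composition statistics; all-`X` records are rejected.

Length-matched reference sampling takes, for each target length, the
unused pool record of nearest length (ties seeded-random), without
replacement, after removing pool sequences that are internally duplicated
or redundant with an exclusion set.

## Randomisation

`randomize_set` emits one random sequence per source record with exactly
the source length multiset. `permutation` mode (default) pools all source
residues, shuffles with a seeded generator and re-splits at the source
lengths, conserving the **pooled** amino-acid composition exactly. `iid`
mode draws residues independently from the pooled frequency vector
(conservation in expectation). Pooled rather than per-sequence matching is
a package decision; both interpretations of "same composition
distribution" are covered by the two modes. All randomness flows through
one named `numpy` generator per call; there is no global RNG state.

## Structural triage

- **Disorder fraction**: share of residues with disorder score ≥ 0.5
  (binary predictor calls pass through unchanged at this cutoff).
- **Helix fraction**: share of DSSP `H` residues by default; `{H,G,I}`
  selectable.
- **Simulation filter**: keep proteins with disorder fraction **< 0.30**
  and helix fraction **< 0.95** (both strict; a protein at exactly 30%
  disorder is excluded).
- **RMSD summary**: unweighted two-level mean — mean over replicates of the
  per-replicate frame mean — not the pooled-frame mean, so replicates with
  different frame counts weigh equally.
- **Hit filter**: keep a structure-search hit iff TM-score **> 0.5**
  (strict), target coverage **≥ 0.8** (inclusive), and the target taxon
  does not match an excluded clade by case-insensitive prefix (excluding
  within-clade hits removes orthologues of the queries). The TM-score
  column is taken at face value under whatever normalisation the search
  tool reported; the convention is the caller's to record.
- **Best hit per query**: maximum TM-score across simulation replicates;
  ties broken by smaller e-value, then lexicographically smallest target.
- **ECOD assignment**: the best hit's target is looked up in a
  target→architecture map; unmapped targets are reported, never silently
  dropped.
- Statistics: Pearson chi-square (no continuity correction) on the
  assigned-vs-not × age-group table, with a warning when any expected cell
  is < 5; Pearson correlation (t-approximation p) between per-protein mean
  RMSD and best-hit TM-score.

## IDR features

The default catalog holds ~48 whole-sequence features: per-letter and
group (aromatic FWY, aliphatic AILMV, polar STNQ) composition fractions;
net charge per residue (NCPR, histidine neutral, termini ignored); fraction
of charged residues (FCR); global charge asymmetry σ = (f₊−f₋)²/(f₊+f₋);
Das–Pappu charge patterning κ; normalised Shannon complexity
H = −Σ f·log f / log 20; mean Kyte–Doolittle hydropathy; per-letter maximum
homorepeat run lengths; and raw length. Three features — `aromatic_spacing`,
`omega_aromatic*`, `kappa*` — are implemented but **excluded by default**,
mirroring the discard policy of the condensate workflow; requesting one
explicitly raises. Binding-motif count features are not part of the
catalog. Users can register additional features; the downstream pipeline is
catalog-size agnostic.

κ details: residue charges are +1 (K, R), −1 (D, E), 0 otherwise. For blob
sizes 5 and 6, the sequence is cut into **non-overlapping blobs with the
truncated final blob included** (a package decision; sliding windows are
the common alternative and give the same qualitative behaviour, including
κ = 1 for the fully segregated diblock). δ is the mean squared deviation of
blob σ from the global σ; δ_max is computed exhaustively over distinct
charge arrangements for length ≤ 12 (enumerated by charge positions, so
the cost is the multinomial count) and from the six (+/0/−) block orderings
otherwise. κ = mean over blob sizes of δ/δ_max, clipped to [0,1]; sequences
with < 2 charged residues have no defined patterning and yield NA (entered
as 0 when a complete matrix is required).

Length normalisation divides only features flagged length-dependent (the
run-length counts) by each protein's length; normalising twice raises. The
raw `length` column is deliberately not divided by itself and is kept as an
ordinary feature.

## Condensate calling

The feature matrix over candidate (DN) proteins plus the positive
reference set is z-scored per column (constant columns map to 0), reduced
to 5 dimensions, and density-clustered:

- **Reduction**: UMAP (the original workflow's choice; seeded,
  single-threaded, `n_neighbors` 15) or PCA. The pipeline default at desk
  scale is PCA, which is bit-stable and fully deterministic; UMAP is
  selectable with `reduction_method: umap`.
- **Clustering**: HDBSCAN (scikit-learn implementation), noise labelled −1.
  Full-scale parameters are minimum cluster size 100 / `min_samples` 50;
  the desk-scale bundle scales these linearly with dataset size to 30/15.
- **Enriched clusters**: "shares a cluster with a large fraction of the
  positives" is operationalised as: rank clusters by positive count, select
  greedily until cumulative positive coverage ≥ 0.85, requiring each
  selected cluster to pass a one-sided hypergeometric over-representation
  test at Benjamini–Hochberg-adjusted α = 0.05. The noise label is never
  eligible; if no selection reaches the coverage target the result is empty
  with a warning. The coverage/test combination reproduces the intended
  outcome pattern (a couple of positive-dense clusters) while refusing
  giant background clusters.
- **High-confidence calls**: candidate is called iff it sits in an enriched
  cluster **and** its condensate propensity score ≥ 0.5 (inclusive).
  Positives themselves are never emitted as calls.
- **Age enrichment**: per-group called fraction (calls normalised by group
  size), fold enrichment against the young group (NA with warning when the
  young fraction is 0), and a Pearson chi-square on the called-vs-not ×
  age-group table.

## Annotation statistics

GO predictions are filtered at score ≥ 0.5 (inclusive). Per-class annotated
fractions count **proteins** with at least one surviving term in the class
(MF/BP/CC), not terms; a protein annotated in several classes counts in
each. Group comparisons: Fisher's exact test (two-sided, probability-mass
rule, scipy) with the sample odds ratio, and Pearson chi-square for
age-group tables. The protein universe is an explicit argument, since
fraction denominators depend on which candidate set is being summarised.

## Embedding space

Per-residue embedding matrices (L × D; D = 1280 for the real language
model, 64 in the synthetic bundle) are mean-pooled over residues (special
tokens excluded by contract). Pairwise Manhattan (L1) distances are
computed blockwise (block edge 512 rows) so n = 5,000, D = 1280 fits in
modest memory; results are independent of block size. Within-class
summaries use upper-triangle pairs only; between-class summaries all cross
pairs. The one-sided Mann–Whitney U test is exact (full enumeration of
label assignments, midranks for ties) when n + m ≤ 14 — at most
C(14,7) = 3,432 assignments — and uses the tie- and continuity-corrected
normal approximation above that. Cross-class nearest neighbours break
distance ties by lexicographically smallest id. Note that pairwise
distances are not independent observations; the Mann–Whitney p-values here
(as in the original analysis) are descriptive.

The bundled `HashedKmerEmbedder` is a deterministic synthetic stand-in: it
hashes the k-mers covering each residue into `dim` buckets with a stable
seeded hash. It carries no learned biology; any object mapping a sequence
to an L × D matrix satisfies the embedder contract.

## Synthetic bundle (study conditions)

Defaults: 150 proteins per class (DN, C; R-DN/R-C derived by permutation
randomisation) + 40 positives; log-normal lengths (μ = 4.3, σ = 0.45,
clipped to 30–400 aa); de novo age split 90/30/30 young/intermediate/old.
60 DN proteins are planted as condensate formers, drawn 150–400 aa from two
sharply distinct low-complexity composition regimes (acidic E/D/G/S-rich
and basic R/K/Y/S-rich — the regimes must be concentrated enough in feature
space that density clustering at the scaled parameters recovers them);
positives are drawn from the same regimes. Planted formers are allocated
across age groups proportionally to group size × weight (1:6:6), giving
fold enrichments near 6. Condensate propensity scores are Beta(8,2) for
planted/positive proteins and Beta(2,8) for background. Disorder and helix
fractions are planted on either side of the 30%/95% filter boundaries
(25%/15% of DN fail). 25 screen survivors receive true structure hits
(TM ∈ U(0.55,0.95), coverage ∈ U(0.8,1.0), non-target-clade taxa) over 3
replicates plus an ECOD architecture; 40 decoys each fail exactly one
filter rule. RMSD levels decrease linearly in best-hit TM-score (planted
negative correlation). GO annotation rates are class- and age-structured
(CC: 0.33 for DN overall vs 0.19 for R-DN, rising with age within DN).
Pooled embeddings are hashed 3-mer profiles plus a per-class ±magnitude
centroid offset (DN 0, R-DN 0.5, R-C 0.7, C 3.0 per dimension) and
Gaussian noise (σ = 0.5), so de novo proteins sit far from conserved ones
and closer to both randomised sets.

What the bundle does **not** emulate: real predictor error structure,
sequence homology, phylogenetic correlation between proteins, realistic
pLDDT/structure content, or the true 131-feature catalog of the full-scale
workflow. Passing tests therefore demonstrate that the downstream logic
recovers planted statistical structure, not that the upstream predictors
are accurate on real proteomes.

## Determinism and numerical choices

Every stochastic step takes an explicit seed; bundle generation is
byte-identical per seed (child generators spawned from one seed sequence).
The pipeline manifest records a config hash, the seed and per-stage
row counts; identical config + seed reproduces identical counts (PCA mode
is bit-stable; UMAP is stable for a fixed seed and a single thread).
Chi-square tests never apply the Yates correction. Degenerate inputs
(empty profiles, zero-margin tables, < 3 correlation pairs, zero variance,
singleton classes) raise or return NA with a warning rather than producing
silent numbers.

## Problem sizes

The default test and acceptance runs use the desk-scale bundle (640
proteins, 190-protein condensate universe, 600-protein distance analysis),
exhaustive statistical oracles up to n + m ≤ 10 (Mann–Whitney), table
totals ≤ 20 (Fisher) and charge-sequence length ≤ 8 (patterning), and
5-seed repetition for the planted-truth recovery checks. These sizes were
chosen so the complete suite exercises every operation and oracle in a few
minutes on one CPU.

## Known limitations

- The feature catalog is ~48 features, not the original 131; the workflow
  is catalog-agnostic but absolute cluster shapes will differ on real data.
- "Large fraction" for enriched clusters has no canonical definition; the
  greedy-coverage + hypergeometric operationalisation is one defensible
  choice and is fully parameterised.
- Whether clustering should run on the 5-D reduction or the raw feature
  matrix is ambiguous in the source workflow; the default clusters on the
  reduction (raw-feature mode available by reducing to fewer components or
  calling `cluster` directly on the z-scored matrix).
- Mann–Whitney on pairwise distances ignores pair dependence (descriptive
  use only).
- The synthetic embedder and bundle are stand-ins; no claim about real
  language-model geometry follows from desk-scale results.
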