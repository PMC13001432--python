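# Methods

## Scope and model

`chemprofiler` reimplements, as a local library and CLI, the computational
core of a chemical-bioprofiling and QSAR workflow over sparse public
screening data:

1. a **record store** of (compound, assay, outcome) observations joined to a
   compound→structure registry;
2. a **bioprofiler** that turns those records into a chemicals × assays
   matrix over {1, −1, 0}, ranks assays by mutual information with an
   overall activity label, and imputes untested cells with per-assay
   random-forest classifiers;
3. an **assay-relevance ranker** based on Bayesian-smoothed active rates;
4. a **structure curator** (standardization + duplicate policies);
5. a **QSAR builder/predictor** over three feature schemes and three
   learners; and
6. a **synthetic-data generator** that plants known structure→activity rules
   so every pipeline can be verified against ground truth.

## Record store

Outcomes take five states: `active`, `probe`, `inactive`, `inconclusive`,
`unspecified` (parsed case-insensitively). Records are merged with the
registry on compound id; compounds whose InChI is empty or lacks the
`InChI=` prefix are dropped — a cheap, deterministic validity proxy.
Conflicting outcomes for the same (compound, assay) pair resolve by the
precedence `active > probe > inactive > inconclusive > unspecified`. Only
the active-wins case is forced by the problem definition; the remainder of
the ordering is this package's choice, ranking defined results above
undefined ones. `probe` (an active chemical probe) is grouped with actives
in every downstream tally and encoding, following the convention of the
source database. The persistent store is a directory of two plain CSVs;
the contract is only "load once, query by cid/InChIKey/aid offline".

## Bioprofile and mutual-information assay selection

Matrix encoding: 1 for active/probe, −1 for inactive, 0 for
inconclusive/unspecified/untested. Columns are restricted to assays with at
least one active entry — an assay that never fired carries no contrast for
profiling. Each chemical's overall label is 1 iff its row contains any 1.

For MI scoring, columns are first binarized: 1 stays 1; −1 and 0 both
become 0 (only a confirmed active is treated as evidence of activity; an
inactive and an untested cell are equally "not known active"). The score is
the plug-in (empirical) discrete mutual information in nats,

    MI(X, Y) = Σ_{a,b} p̂(a,b) · ln( p̂(a,b) / (p̂(a) p̂(b)) ),

implemented directly from the 2×2 joint table. The plug-in estimator was
chosen because it is the standard classification-MI convention and is
exactly checkable by hand; tests verify it against an independent
brute-force evaluation and against `sklearn.metrics.mutual_info_score` to
1e−9. The number of assays selected defaults to 50 (CLI-configurable); no
canonical value exists for this cutoff, and 50 keeps desk-scale runtime
while exercising the selection mechanism.

## Gap filling

For each selected assay, up to 500 actives and 500 inactives are sampled
uniformly without replacement (seeded) from the compounds tested in that
assay; assays with fewer than 100 usable compounds in either class are
rejected. A random-forest classifier (500 trees, seed-controlled — the
hyperparameters are package defaults, chosen for stability on 2048-bit
inputs) is trained on ECFP6 fingerprints: circular Morgan fingerprints of
radius 3 (diameter 6) hashed to 2048 bits. Model quality is reported from
stratified 5-fold cross-validation (accuracy, precision, recall, F1,
ROC-AUC; per fold plus mean ± sd), mirroring the QSAR module's protocol;
CV can be disabled when only the imputations are needed. Imputation
replaces each 0 in the selected columns by the hard class at the 0.5
active-probability threshold; observed entries are never modified, a
provenance mask (observed / imputed / unpredictable) is returned, and
probabilities are available as a side table. Unselected columns are dropped
from the complete profile rather than imputed.

Training compounds are taken from the assay's tested compounds as such; if
the profiled chemicals were themselves tested in the assay they can appear
in the training sample. This mirrors the workflow being modeled but is a
known leakage risk when gap-fill metrics are read as estimates of
imputation accuracy on the profiled set.

## Assay-relevance ranking

With Active_i and Inactive_i the per-assay counts,

    active_rate_i = Active_i / (Active_i + Inactive_i)
    μ             = Σ_i Active_i / Σ_i (Active_i + Inactive_i)
    score_i       = (Active_i + k·μ) / (Active_i + Inactive_i + k),  k = 100

μ is the **pooled** hit rate (ratio of sums), not the mean of per-assay
rates; assays with no active/inactive calls are excluded from both sums
(their terms would otherwise be 0/0) and their own rate is *undefined*
rather than 0, while their score degenerates cleanly to μ. The score is a
posterior-mean-style shrinkage of the raw rate toward μ with k pseudo-counts:
monotone in each count, always strictly inside (0, 1) for 0 < μ < 1, equal
to the raw rate as k → 0 and to μ as k → ∞. Assays are ranked by score
descending (ties by ascending aid, for determinism) and the table truncated
to the top 500 by default. Inconclusive counts are tallied and reported but
enter no formula.

## Structure curation

Flagging reports, without altering the structure: parse failures (which
short-circuit all other checks), valence problems, kekulization/bond
problems, undesirable fragments (multi-fragment inputs and atoms outside
the organic element subset, i.e. salts/solvents/metals), and
invalid/ambiguous stereochemistry (unassigned stereocenters, ambiguous
double bonds). Stereo problems are flagged but never "fixed".

Standardization uses RDKit's `rdMolStandardize` operations: sanitize +
normalize (SMIRKS-based functional-group normalization, kekulization,
hydrogen handling), largest-fragment parent selection (dropping recognized
salt/solvent fragments; ties by heavy-atom count then canonical order), and
charge neutralization. The result is canonical SMILES plus the standardized
InChIKey, and is a fixed point: re-standardizing is a no-op (tested on the
full fixture library).

Duplicates group by standardized InChIKey. Policies: `highest`, `lowest`,
`average`, `remove`. `average` on a binary dataset is only accepted for
unanimous groups — the mean of disagreeing 0/1 labels is not a label — and
raises otherwise; under `highest`/`lowest` an active (1) counts as higher.
The curated dataset is renamed `<name>_curated` by default. Flagged but
parseable structures (e.g. metals) are kept with their issues attached;
exclusion is a CLI flag (`--drop-flagged`), not a default.

## QSAR

Feature schemes: ECFP6, FCFP6 (as ECFP6 but with pharmacophoric feature
invariants), both 2048-bit radius-3; and a fixed, versioned list of 20
standard 2D physicochemical descriptors (`features.PHYSCHEM_DESCRIPTORS`),
z-scored. For the descriptor scheme the scaler lives *inside* the sklearn
pipeline, so cross-validation refits it on each training fold and no test
statistics leak into scaling; a test asserts this by comparing against a
deliberately leaky pre-scaled variant on a shifted fixture.

Learners: random forest, SVM, k-NN, for classification and regression.
Hyperparameters are tuned by grid search with 5-fold CV (stratified for
classification) over small default grids — RF {100, 500 trees} × {depth
∞, 20}; SVM {C 0.1, 1, 10} × {rbf, linear}; kNN {k 3, 5, 7} × {uniform,
distance} — sized to keep grid search real at desk scale. The best
configuration is re-evaluated fold by fold for the reported metrics and
refit on all data. Classification reports accuracy, precision, recall, F1,
ROC-AUC and, in the "AUC" slot, precision–recall AUC (the metric list
being modeled names both "AUC" and "ROC AUC" without defining the former;
PR-AUC is this package's documented reading). Regression reports R², MSE,
MAPE. Classification labels use the fixed 0.5 probability threshold; for
SVMs the thresholded probabilities come from Platt calibration on training
folds while ranking metrics use decision scores. The model suite trains
all scheme × algorithm cells (nine by default), records per-cell failures
without aborting, and flags the best model by mean CV ROC-AUC
(classification) or R² (regression), ties by accuracy / lower MSE then
name. Prediction removes invalid structures (reported separately) and
emits a `<ModelName>_Prediction` column, plus a probability column for
classifiers.

Chemical-space embedding: PCA on the standardized descriptor set, top three
components, coordinates keyed by compound id with the activity label for
coloring. Explained variances are non-increasing by construction; the
embedding is reproducible up to per-axis sign.

## Synthetic data

Structures come from a deterministic scaffold + substituent grammar —
benzene, pyridine, cyclohexane and short alkanes decorated at one to three
sites with nitro, chloro, fluoro, bromo, hydroxyl, amino, methyl — then
canonicalized and deduplicated (875 distinct structures; each named rule
matches roughly a third of the library, except halogen ~75% and aromatic
~62%). Sampling is seeded and without replacement, so libraries are
reproducible and substructure rules carry real signal in fingerprint space.

Bioassay worlds: informative assays label chemicals by substructure match,
flipped with probability `noise_rate`; background assays fire with
probability `background_active_rate` (default 0.05, a typical
high-throughput-screening hit-rate scale); each cell is withheld with
probability `missing_rate`; the complete truth matrix is retained. QSAR
datasets plant one rule with label-flip noise (binary; classes balanced by
stratified sampling from matching/non-matching pools) or with activity =
heavy-atom count + 3·(rule match) + Gaussian noise (continuous).

What the generator does **not** emulate: plate and batch artifacts,
frequent hitters, realistic hit-rate and assay-size distributions,
structural diversity beyond the grammar, and activity cliffs. Passing
recovery tests therefore shows the pipelines are implemented correctly and
can extract a planted signal, not that they attain any particular accuracy
on real screening data.

## Verification conditions and problem sizes

Chosen once as the package's standard verification settings:

- MI planted-assay recovery: 100 replicate worlds of 100 chemicals × 10
  assays, one noise-free informative assay, background rate 0.05; the
  informative assay must rank first in ≥ 95 replicates.
- Gap-fill recovery: 10 worlds of 600 chemicals × 3 rule-driven assays
  (nitro/hydroxyl/amino, so both classes clear the 100-compound minimum),
  30% missingness, noise-free; ≥ 90% of imputed entries must match truth.
- QSAR recovery: 400-compound nitro-rule dataset with 5% label noise,
  RF + ECFP6 under the default grid; mean CV ROC-AUC ≥ 0.9, with a
  label-shuffled null expected at 0.5 ± 0.1.
- Curation: a 200-structure fixture (190 library structures, salts,
  zwitterions, invalid strings, duplicates) for idempotence and record
  conservation.

`scripts/acceptance.py` recomputes these quantities from scratch at a given
seed and writes them as JSON.

## Numerical choices and edge cases

- MI uses natural logarithms; 0·ln 0 terms are skipped; results are clamped
  at 0 against floating-point underflow. A single-chemical profile gives
  MI 0 for every assay.
- Ties everywhere (assay selection, ranking, best-model choice, fragment
  choice) break lexicographically so reruns are byte-identical.
- `active_rate` with an empty denominator is `None`/NaN, never an
  exception; μ over only-empty assays is an error.
- Random sampling uses `numpy.random.default_rng(seed)`; identical seeds
  reproduce every sample, CV split and fitted model exactly.
- Heatmaps cluster rows and columns by average-linkage hierarchical
  clustering on Euclidean distance (a standard default; no linkage is
  canonical for this display) and write the leaf orders as text so the
  ordering is testable; single-row/column profiles render unclustered.

## Known limitations

- The store is CSV-backed and loaded in memory; it targets method-scale
  data, not the full public bioactivity corpus.
- FCFP6 uses RDKit's Morgan feature invariants, which approximate (not
  reproduce bit-for-bit) other vendors' functional-class fingerprints.
- Gap-fill training can overlap the profiled chemicals (see above).
- The curation step standardizes and flags but does not attempt tautomer
  canonicalization beyond the normalizer's transforms.
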