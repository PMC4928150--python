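# Methods

## Model

`kinvar` treats pathogenicity prediction for kinase missense variants as
binary classification ("disease" vs "neutral") with a bagged ensemble of
26 decision trees. Each tree is grown on a bootstrap sample of the training
variants; at every split a random subset of 5 features is considered
(⌊log₂ 25⌋ + 1, the classic forest default for this feature count;
configurable, e.g. to √F). Class priors are left untouched — no resampling
or reweighting — so the posterior reflects the ~1:2.6 disease:neutral
imbalance of the training material. The reported `p_disease` is the mean
leaf class probability across trees; a variant is called pathogenic when
`p_disease ≥ 0.5`, with exact ties resolved to "disease" (consistent with
the deduplication rule below, which also prefers the pathogenic
interpretation in ambiguity).

## Features

Twenty-five features in a fixed, versioned order (`FEATURE_ORDER`,
version `kinvar-25-v1`).

**Log-odds annotation features.** For category *c* with disease/neutral
counts (d_c, n_c) and class totals (D, N):

    lor(c) = log2( ((d_c + ξ)/D) / ((n_c + ξ)/N) ),   ξ = 1e-20.

The pseudocount is applied exactly as stated, only in the numerators: a
category observed in one class only therefore gets |lor| ≈ 60–70. These
extremes are deliberate and not clipped; trees split on thresholds, so the
magnitude is harmless, and clipping would silently change the documented
formula. Three tables are built: kinase group (one category per variant),
GO terms (a variant counts toward every term in its protein's direct
annotation set expanded with all `is_a`/`part_of` ancestors — the relation
set is configurable since propagation practice varies), and domains (a
variant counts toward a domain only when its position lies inside one of
that protein's intervals for it; a position inside two overlapping domains
counts toward, and later sums, both). A category with zero variants of both
classes never enters a table; at featurization time categories absent from
a table contribute 0 (zero evidence), which keeps prediction total for
unseen proteins, groups and terms. Sum features: `sum_go_lor` over the
ancestor-expanded term set, `sum_pfam_lor` over covering domains,
`kinase_group_lor` as the single group lor (0 if the group was unseen).

**Physicochemical deltas.** Mutant minus wild-type differences on four
published scales: Kyte–Doolittle hydropathy, Zamyatnin residue volume
(A^3), C-beta branching ({V, I, T} = 1) and formal side-chain charge
(K, R = +1; D, E = −1; H treated as neutral at physiological pH). Only the
hydropathy scale is canonical to the method; the other three are the
standard community choices and each is a swappable data table. Direction
(mutant − wild-type) is a convention; only consistency matters to trees.

**Residue-level flags and conservation.** Binary flags for the twelve
UniProt site categories at the variant position, their OR (`any_uniprot`),
Phospho.ELM and FireDB membership; and the precomputed SIFT score in
[0, 1] (consumed, never recomputed from alignments). A missing SIFT score
is imputed with the *training-split* median — not a global value — so the
imputation obeys the same leakage discipline as the log-odds tables. If a
training split has no observed scores at all, 0.5 (the uninformative
midpoint) is used.

**Encoding.** Wild-type and mutant residues are one-hot encoded over the
fixed 20-letter alphabet, expanding the 25 semantic features to a 63-column
numeric matrix; the encoding is recorded on the fitted model
(`encoder_spec_`) and the feature-order version is checked when a persisted
model is loaded.

## Evaluation protocol

Proteins (not variants) are permuted uniformly at random and split into k
near-equal bins (sizes differ by at most one); every variant inherits its
protein's bin. Each bin serves once as evaluation set; predictions are
accumulated over all folds and summarised by a single pooled confusion
matrix — the headline numbers — with per-fold means ± sd also available,
since pooled and fold-averaged statistics differ slightly and both
conventions occur in practice.

`lor_scope` controls where the log-odds tables come from:

* `train_fold` (default): tables and imputation are rebuilt per fold from
  the nine training bins. This is the strict mode: an instrumented
  contributor set on every table proves that no held-out variant's label
  entered any training-fold count.
* `full_dataset`: tables are built once from all labelled variants, which
  matches formulas defined over a whole variant compendium but lets
  evaluation labels into the features; retained for comparison only.

The five statistics are the standard confusion-matrix formulas with
pathogenic as positive class. Degenerate cases (a zero factor under the
MCC root, or an empty positive-prediction set — both routine for constant
predictors such as the majority baseline) report 0 with a `degenerate`
flag instead of raising. The majority-class baseline accuracy
max(D, N)/(D+N) is the reference point every result is compared against.

Feature relevance: information gain IG = H(y) − Σ_v p(v) H(y|v) in bits.
Numeric features are discretized with Fayyad–Irani recursive entropy
minimization under the MDL stopping rule (default) or equal-frequency
deciles (`bins`); features with at most two distinct values are used as
categories outright (a binary feature needs no cut search, and the MDL
penalty would otherwise spuriously zero it on small samples); missing
values form their own bin; gains are floored at 0 against rounding. Ties
in the ranking are broken by the fixed feature order.

## Data handling

Variant tables are deduplicated on (protein, position, wt, mut): when
duplicate rows disagree, a pathogenic record wins; otherwise a classified
(neutral) record beats unclassified; otherwise the first-seen label stands.
Every collapse is logged in the dataset provenance along with the source
file digest. Coordinates are 1-based inclusive (UniProt numbering)
everywhere. Only the 20 canonical residues are accepted; B/Z/X/U are parse
errors because the scales and encoding are undefined for them. Ontology
files are an OBO subset; obsolete terms are dropped, edges to obsolete
parents are discarded, references to undeclared terms and cycles are
structural errors.

## Synthetic kinome

The generator emulates the statistical structure the classifier exploits,
with dimensions matching the real training compendium (459 proteins, 15
groups, 3689 variants, 27.7 % pathogenic): pathogenic variants allocated
preferentially to proteins in "risk" groups and proteins carrying "risk"
GO terms (odds multipliers), tilted into domain intervals, given
conservation scores from a Beta distribution whose mean sits `sift_shift`
below the neutral mean of 0.5 (disease scores concentrate near 0), and
placed on functionally annotated residues more often. Two shipped presets
define the study conditions: **strong** (group/GO odds 8, domain odds 4,
sift_shift 0.3, site hit probability 12 % vs 2 %) for recovery checks, and
**null** (all odds 1, no shift, equal site rates) as false-positive
control. Identifiers are synthetic; no real accessions, GO ids or kinase
sequences are imitated. The generator does **not** reproduce phylogenetic
correlation between paralogous kinases, realistic GO term depth
distributions, hotspot clustering along the sequence, or annotation-
database errors — so green tests demonstrate that the pipeline recovers
the kinds of signal it models, not that real-data performance figures
transfer.

## Numerical and reproducibility choices

All randomness flows from explicit integer seeds through
`numpy.random.default_rng` / scikit-learn `random_state`; identical
(data, seed, config) reproduce byte-identical outputs, and every CLI run
writes a manifest (effective config, input digests, version, wall-clock).
Within cross-validation, fold f trains with `random_state = seed + f` so
folds are independent but reproducible. Problem sizes used by the shipped
checks: the end-to-end recovery statistics use the full-size presets
(3689 variants, k = 10, 26 trees) with 20-seed medians; the forest-size
plateau is measured on sizes {10, 14, 18, 22, 26, 30}, which brackets the
10–30 range the plateau claim covers; the permutation-null bound on
information gain uses n = 2000.

## Known limitations

* Real-data performance depends on annotation-resource versions (GO
  release, SIFT source, domain definitions); only ordering-level, not
  value-level, reproduction of feature rankings should be expected across
  versions.
* With `lor_scope=train_fold`, proteins whose group/terms are rare may see
  weaker features in some folds; this is the honest price of leak-free
  evaluation.
* No probability calibration and no ROC/AUC machinery; the five statistics
  above are the evaluation surface.
* Native UniProt flat-file/XML variant pages are not parsed; inputs are
  the canonical TSV dialects (a converter is a plausible future feature).
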