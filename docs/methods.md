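# Methods

## The model

The triage classifier is a random forest over a fixed-order pairwise feature
vector. Pairs are unordered: both proteins' identifiers are stored in
lexicographic order and every featurizer is symmetric, so F(a,b) = F(b,a) by
construction. Per-pair sources (evidence counts, association channels,
co-fractionation row statistics, scaled disease-similarity cosines, retained
co-expression scores, externally computed interaction probabilities) enter
directly; per-protein vectors enter as cosine similarities (or a probability
dot product for compartment localization); per-protein scalars enter as
(min, max) over the two proteins, which preserves symmetry without choosing a
bait/prey orientation. Missing inputs are imputed to 0 and flagged in a
parallel mask — the single imputation rule used everywhere.

The exact published feature list is not available as machine-readable
configuration, so the registry is configuration-driven
(`features.FeatureRegistry`): the shipped default covers every featurizer
construction the data sources support (23 features over the synthetic
stores) and a digest of the registry travels with every trained model so
score files are attributable to a feature definition.

### Forest hyperparameters

`ForestConfig(n_trees=250, criterion="log_loss", bootstrap=False,
seed=17232)`. No class weighting, no calibration beyond the forest's native
probability. Determinism: identical inputs and seeds give bitwise-identical
score vectors (asserted in tests).

### Composition sweep

Each of the six reference sets enters a training combination at a fraction
from {0, 0.33, 0.66, 1} (the literal decimal constants, not 1/3 and 2/3);
subset size is round-half-up(f·N). The per-set permutation depends only on
(master seed, set name), so the 0.33 subset of a set is nested inside its
0.66 subset and identical across combinations — this makes the sweep
cacheable and means "the same fraction of a set" denotes the same pairs
everywhere. Enumeration excludes all-zero positives and all-zero negatives:
(|F|^P − 1)(|F|^N − 1) combinations, 3,825 at the defaults. Pruning removes
combinations training on 100% of *both* positive sets (nothing held out),
those with *no* decoys, and those omitting either positive source; at the
defaults 1,920 survive. A survivor count of 1,921 has been reported for the
same rules; the enumeration here is exhaustive and reproducible, and the
±1 discrepancy is asserted in the tests rather than absorbed.

If a combination ends up single-class after subsampling it is skipped, not
trained. Selection sorts by median rank ascending, then count of ranks < 100
descending ("below 100" read strictly); exact ties prefer a structure-decoy-
trained model, and any remaining tie breaks lexicographically on the
fraction tuple so selection is deterministic.

## Geometry and confidence predicates

* **Contact:** two residues across chains are in contact when *any*
  heavy-atom pair is strictly closer than 5 Å; a chain pair "interacts" at
  ≥ 10 contacting residue pairs. Hydrogens are ignored; only the first
  alternate location is kept; residues are renumbered 1-based per chain over
  modeled residues.
* **Crosslink consistency:** every reported crosslink's Cα–Cα distance
  strictly below 36 Å (`mode="all"`, the default; a fractional mode exists
  because the stringency of "consistent" is a judgment call).
* **Contact-positive (C+):** a prediction set is C+ when any model has ≥ 5
  interchain residue pairs with PAE ≤ cutoff *in both matrix directions*.
  The PAE cutoff is a package choice, default 8 Å, exposed as a parameter —
  the upstream convention behind "predicted with confidence" is not
  published, so the knob is explicit rather than hard-wired.

Boundary semantics throughout: distances strict (< 5 Å, < 36 Å), count
thresholds inclusive (≥ 10, ≥ 5), evidence score gates strict (> 700 for
novelty, > 990 for contamination), screening score floor inclusive
(≥ 0.088). Each is pinned by a unit test.

## Reference sets

Structure positives are unique proteome pairs whose mapped chains interact
in ≥ 1 structure; decoys are pairs co-occurring in a structure but never in
direct contact anywhere (a pair positive in any structure is never emitted
as a decoy). Crosslink pairs split on whether ≥ 1 of their predicted models
is consistent with all reported links. Random sets draw unique heterodimers
uniformly without replacement, deterministically per (master seed, set
name). The contamination filter removes candidate negatives carrying
evidence through homology; the identity/coverage gates (50%/70% for
evidence-count and structure-homology rules, 90%/90% for the STRING rule)
apply to the mapping that transferred the evidence, with direct evidence
treated as a perfect mapping. Coverage is computed on the query length, and
the STRING rule accepts either the physical or the combined channel — both
conventions are unstated upstream and documented here as package choices.

## FDR estimation

Cohorts of `n_pos` positives and `ratio·n_pos` filtered random negatives are
scored; at each cutoff on a 0–1 grid (step 0.01; a call is score ≥ cutoff)
TPR and FPR convert to FDR under the interactome prior
(200,000 true / 199.8M false pairs by default; planted studies use the
planted prior). A repetition that makes no calls at a cutoff contributes
FDR 0 there and is counted in `n_silent_reps`. The reported curve is the
mean over repetitions (100 at full scale; fixture studies use 5–10, which
keeps Monte-Carlo error well below the tolerances being checked).

The estimator is validated against a fully known population: ~2×10⁶ pairs
over 2,000 proteins, 2,000 planted true pairs (1:~999), scores drawn from a
near-zero Beta for background and a high Beta for true pairs with a 10%
"missed" fraction (overall AUC ≈ 0.95, mimicking classifier output whose
negative mass sits near zero — a clipped-Gaussian scorer cannot reach 90%
precision under a 1:999 prior because its negative tail is too heavy). The
estimated FDR at the cutoff reaching 90% estimated precision agrees with the
exact population FDR at that cutoff to well within 3 percentage points.

## Synthetic fixtures

The generator plants a ground truth and emulates the statistical structure
the classifier assumes, not the biology itself:

* **Vectors:** true pairs share a latent component
  (v_b ← √(1−w²)·v_b + w·v_a, default w = 0.9), giving graded cosine
  elevation like real co-dependency profiles; binary screen-hit vectors copy
  bits with probability w; localization probabilities are pulled toward the
  partner's compartment mix.
* **Evidence:** true pairs draw counts from elevated distributions
  (detection count 1 + Poisson(3), the dominant planted signal, mirroring
  how database evidence dominates real feature importances); ~1% of
  non-pairs receive stray low counts and mid-range association scores as
  background noise.
* **Geometry:** chains are Cα/Cβ beads on 20 Å grids so the distance
  predicates hold or fail by large margins; contact structures plant an
  *exact* residue-pair contact count (verified internally against the
  counting oracle) and PAE matrices plant an exact confident-cell count.
* **Annotation:** alignment tables are consistent with planted clusters
  (perfect self-hits, ~95%-identity co-member hits), GO descriptions come in
  near-duplicate template families, crosslinks sample contacting or
  far-apart bead pairs per the requested violation fraction.

What passing tests therefore show: the *operations* are correct (counting,
thresholds, set algebra, estimator calibration) and the *pipeline* recovers
strong planted signal. What they do not show: performance on real omics
data, where signal is weaker, missingness is structured, features are
correlated with study bias, and real published performance numbers
(median ranks, AUCs, C+ fractions at proteome scale) apply — those require
the real feature corpus and real structure predictions and are explicitly
out of scope for the fixture runs.

## Problem sizes and numerical choices

The end-to-end demonstration uses a 200-protein proteome with 50 true pairs,
a reduced fraction grid {0, 0.66, 1} (216 trained combinations), 10 held-out
ranking experiments, 1:99 held-out ROC, and 10-repetition FDR cohorts at
1:99 — sizes chosen so a complete run finishes in about a minute on one CPU
while still exercising every pipeline stage. Median uses the lower-middle
convention for even counts. Rounding of the scaled disease-similarity score
is half-away-from-zero ("nearest integer" upstream leaves the half case
open). Co-expression top-k retention breaks score ties by partner identifier
and pair lookup takes the maximum over both retention directions. Greedy GO
clustering visits terms in ascending identifier order and compares against
the *founding* representative only — order and anchor are reproducibility
conventions, not published rules. Intra-cluster seed pairs expand to all
within-cluster unordered pairs (self-pairs dropped), a documented extension
of the cross-cluster rule.

## Known limitations

* The feature registry is a reconstruction of the described featurizers, not
  the published feature table; real-data feature importances will differ.
* Homology-transferred evidence uses a single (identity, coverage) per
  candidate pair rather than a full per-protein alignment graph.
* The C+ confidence rule (symmetric PAE ≤ 8 Å) is a documented default, not
  a published constant; results are monotone in the cutoff.
* Edit-distance similarity of GO descriptions is a lexical proxy; it will
  merge lexically similar but semantically distinct terms and vice versa.
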