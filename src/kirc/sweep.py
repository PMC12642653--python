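"""Dataset-composition sweep, forest training, pruning and final selection.

Training-set composition is itself a hyperparameter: each of the six
reference sets enters a combination at a fraction drawn from {0, 0.33, 0.66,
1}, every admissible assignment is trained as its own random forest, and the
sweep is pruned to combinations that (i) hold out part of both positive sets,
(ii) keep some decoys, and (iii) use both positive sources. The surviving
classifiers are ranked by their proteome-wide ranking performance and the
best one (preferring structure-decoy-trained models among exact ties) becomes
the triage model.

With 2 positive sets, 4 negative sets and 4 fraction levels the enumeration
has (4^2 - 1) x (4^4 - 1) = 3,825 combinations, of which 1,920 survive
pruning under the rules above.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from ._util import derive_seed, stable_digest
from .errors import ParameterError
from .features import FeatureCache
from .pairs import PairKey
from .refsets import DECOY_SETS, NEGATIVE_SETS, POSITIVE_SETS, RefSet

logger = logging.getLogger(__name__)

DEFAULT_FRACTIONS = (0.0, 0.33, 0.66, 1.0)
KIRC_SCORE_FLOOR = 0.088
MAX_COMBINED_LENGTH = 3600


@dataclass(frozen=True)
class DatasetCombo:
    """Fraction of each reference set used for training, keyed by set name."""

    fractions: tuple[tuple[str, float], ...]

    @classmethod
    def of(cls, mapping: Mapping[str, float]) -> "DatasetCombo":
        return cls(tuple(sorted((str(k), float(v)) for k, v in mapping.items())))

    def fraction(self, name: str) -> float:
        for k, v in self.fractions:
            if k == name:
                return v
        return 0.0

    def as_dict(self) -> dict[str, float]:
        return dict(self.fractions)


@dataclass(frozen=True)
class ForestConfig:
    """Hyperparameters of the pair classifier's random forest."""

    n_trees: int = 250
    criterion: str = "log_loss"
    bootstrap: bool = False
    seed: int = 17232


@dataclass
class TrainedClassifier:
    combo: DatasetCombo
    config: ForestConfig
    registry_hash: str
    model: RandomForestClassifier
    feature_names: tuple[str, ...] = ()

    def score_matrix(self, X: np.ndarray) -> np.ndarray:
        """Interaction probability per row (positive-class probability)."""
        proba = self.model.predict_proba(X)
        pos_col = list(self.model.classes_).index(1)
        return proba[:, pos_col]

    @property
    def feature_importances(self) -> dict[str, float]:
        imp = self.model.feature_importances_
        return dict(zip(self.feature_names, (float(v) for v in imp)))


@dataclass
class SweepResult:
    combo: DatasetCombo
    median_rank: float
    n_rank_below_100: int
    classifier: TrainedClassifier | None = None


def enumerate_combos(
    pos_sets: Sequence[str] = POSITIVE_SETS,
    neg_sets: Sequence[str] = NEGATIVE_SETS,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
) -> list[DatasetCombo]:
    """All fraction assignments with >=1 nonzero positive and >=1 nonzero negative.

    Count equals (|F|^P - 1) * (|F|^N - 1).
    """
    if not fractions:
        raise ParameterError("empty fraction set")
    if not pos_sets or not neg_sets:
        raise ParameterError("need at least one set of each polarity")
    fr = tuple(float(f) for f in fractions)
    combos = []
    for pos_assign in itertools.product(fr, repeat=len(pos_sets)):
        if all(f == 0.0 for f in pos_assign):
            continue
        for neg_assign in itertools.product(fr, repeat=len(neg_sets)):
            if all(f == 0.0 for f in neg_assign):
                continue
            combos.append(DatasetCombo.of(
                dict(zip(pos_sets, pos_assign)) | dict(zip(neg_sets, neg_assign))
            ))
    return combos


def prune_combos(
    combos: Sequence[DatasetCombo],
    pos_sets: Sequence[str] = POSITIVE_SETS,
    decoy_sets: Sequence[str] = DECOY_SETS,
) -> list[DatasetCombo]:
    """Apply the three pruning rules to the enumerated sweep.

    Removed are combinations that (1) train on 100% of BOTH positive sets
    (nothing left for testing), (2) train without any decoys, or (3) omit
    either positive source entirely. Order-independent and idempotent.
    """
    out = []
    for combo in combos:
        pos_fr = [combo.fraction(s) for s in pos_sets]
        if all(f == 1.0 for f in pos_fr):
            continue
        if any(f == 0.0 for f in pos_fr):
            continue
        if all(combo.fraction(s) == 0.0 for s in decoy_sets):
            continue
        out.append(combo)
    return out


def prune_classifiers(
    sweep: Sequence[tuple[DatasetCombo, object]],
    pos_sets: Sequence[str] = POSITIVE_SETS,
    decoy_sets: Sequence[str] = DECOY_SETS,
) -> list[tuple[DatasetCombo, object]]:
    keep = set(prune_combos([c for c, _ in sweep], pos_sets, decoy_sets))
    return [(c, clf) for c, clf in sweep if c in keep]


def subsample_refset(refset: RefSet, fraction: float, seed: int) -> list[PairKey]:
    """A deterministic fractional subset: size = round-half-up(fraction * N).

    The permutation depends only on (seed, set name), so smaller fractions of
    the same set are nested inside larger ones and identical across combos.
    """
    members = sorted(refset.members)
    size = int(np.floor(fraction * len(members) + 0.5))
    if size >= len(members):
        return members
    rng = np.random.default_rng(derive_seed(seed, "subsample", refset.name))
    order = rng.permutation(len(members))
    return [members[i] for i in order[:size]]


def train_classifier(
    combo: DatasetCombo,
    refsets: Mapping[str, RefSet],
    features: FeatureCache,
    config: ForestConfig = ForestConfig(),
    master_seed: int | None = None,
) -> TrainedClassifier | None:
    """Train one forest on the sampled composition; None when a class is empty.

    Pairs sampled into both polarities keep the positive label (positive
    precedence). Deterministic for fixed seeds.
    """
    seed = config.seed if master_seed is None else master_seed
    labels: dict[PairKey, int] = {}
    # Negatives first, then positives override: positive precedence.
    for want_label, value in (("negative", 0), ("positive", 1)):
        for name, refset in refsets.items():
            if refset.label != want_label or combo.fraction(name) == 0.0:
                continue
            for pair in subsample_refset(refset, combo.fraction(name), seed):
                labels[pair] = value
    pairs = sorted(labels)
    y = np.array([labels[p] for p in pairs], dtype=int)
    if len(np.unique(y)) < 2:
        logger.info("combo %s skipped: single class after subsampling", combo)
        return None
    X = features.matrix(pairs)
    model = RandomForestClassifier(
        n_estimators=config.n_trees,
        random_state=config.seed,
        criterion=config.criterion,
        bootstrap=config.bootstrap,
    )
    model.fit(X, y)
    return TrainedClassifier(
        combo, config, features.registry.registry_hash, model, features.registry.names
    )


def select_final(results: Sequence[SweepResult], pdb_decoy_set: str = "PDB_Decoy") -> SweepResult:
    """Pick the winning classifier from the evaluated sweep.

    Sort by median rank (ascending), then by the number of test pairs ranked
    below 100 (descending). Among classifiers tied on both metrics, prefer
    one trained on structure decoys; remaining ties break lexicographically
    on the fraction tuple for determinism.
    """
    if not results:
        raise ParameterError("empty sweep")
    best_metric = min((r.median_rank, -r.n_rank_below_100) for r in results)
    tied = [r for r in results if (r.median_rank, -r.n_rank_below_100) == best_metric]
    decoy_trained = [r for r in tied if r.combo.fraction(pdb_decoy_set) > 0.0]
    pool = decoy_trained or tied
    return min(pool, key=lambda r: r.combo.fractions)


def build_screening_set(
    proteome_lengths: Mapping[str, int],
    scores: Mapping[PairKey, float],
    score_floor: float = KIRC_SCORE_FLOOR,
    max_combined_length: int = MAX_COMBINED_LENGTH,
    redundancy_clusters: Mapping[str, str] | None = None,
) -> tuple[list[tuple[PairKey, float]], list[tuple[PairKey, str]]]:
    """Select the pairs nominated for structure prediction.

    Keeps heterodimers scoring at or above the floor whose combined length
    does not exceed the cap, one representative (the best-scoring) per
    redundant cluster pair, ordered by descending score. Returns the kept
    list and an exclusion log of (pair, reason).
    """
    excluded: list[tuple[PairKey, str]] = []
    candidates: list[tuple[PairKey, float]] = []
    for pair, score in scores.items():
        if pair.is_homodimer:
            excluded.append((pair, "homodimer"))
            continue
        if score < score_floor:
            excluded.append((pair, "below_score_floor"))
            continue
        combined = proteome_lengths[pair.id_a] + proteome_lengths[pair.id_b]
        if combined > max_combined_length:
            excluded.append((pair, "combined_length"))
            continue
        candidates.append((pair, float(score)))
    candidates.sort(key=lambda ps: (-ps[1], ps[0]))
    if redundancy_clusters:
        seen: set[tuple[str, str]] = set()
        kept = []
        for pair, score in candidates:
            ca = redundancy_clusters.get(pair.id_a, pair.id_a)
            cb = redundancy_clusters.get(pair.id_b, pair.id_b)
            key = (ca, cb) if ca <= cb else (cb, ca)
            if key in seen:
                excluded.append((pair, "redundant"))
                continue
            seen.add(key)
            kept.append((pair, score))
        candidates = kept
    return candidates, excluded
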