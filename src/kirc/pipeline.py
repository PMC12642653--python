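"""End-to-end orchestration on planted fixtures.

Ties the modules into the two-step screen: build reference sets from planted
structures and crosslinks, featurize, sweep training compositions, select the
triage classifier, score the whole (fixture) proteome, apply the screening
rules, and calibrate FDR on simulated cohorts. Also provides the post-
prediction filter (C+ calling over a directory of PAE files) and a planted
FDR-recovery study used to validate the estimator.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._util import derive_seed, rng_for, stable_digest
from .annotation import classify_novelty, go_pair_jaccard
from .errors import ParameterError
from .evaluate import (
    FDRCurve,
    RankExperiment,
    fdr_simulation,
    pipeline_recall,
    rank_partner,
    roc_auc,
    summarize_ranks,
)
from .features import FeatureCache
from .pairs import PairKey, n_hetero_pairs, sample_unique_pairs
from .refsets import (
    RefSet,
    build_pdb_decoy_set,
    build_pdb_positive_set,
    build_random_set,
    build_xlms_sets,
)
from .simulate import (
    FixtureSpec,
    PlantedInteractome,
    generate_contact_structure,
    generate_crosslinks,
    generate_interactome,
)
from .structgeom import (
    DEFAULT_PAE_CUTOFF_A,
    MIN_CONFIDENT_PAIRS,
    count_confident_interchain_pairs,
    is_contact_positive,
    load_pae,
)
from .sweep import (
    DatasetCombo,
    ForestConfig,
    SweepResult,
    TrainedClassifier,
    build_screening_set,
    enumerate_combos,
    prune_combos,
    select_final,
    train_classifier,
)

logger = logging.getLogger(__name__)

DEMO_FRACTIONS = (0.0, 0.66, 1.0)


@dataclass
class DemoScreenResult:
    """Everything the fixture-scale end-to-end run produces."""

    interactome: PlantedInteractome
    refsets: dict[str, RefSet]
    n_combos_trained: int
    sweep_results: list[SweepResult]
    selected: SweepResult
    median_rank: int
    n_rank_below_100: int
    held_out_auc: float
    top_feature: str
    screening_set: list[tuple[PairKey, float]]
    fdr_curve: FDRCurve
    elapsed_s: float


def build_fixture_refsets(
    interactome: PlantedInteractome,
    n_pdb_pos: int | None = None,
    n_xlms_pos: int | None = None,
    n_xlms_decoy: int | None = None,
    n_random: int = 600,
    n_xlms_random: int | None = None,
    n_held_out: int = 10,
) -> tuple[dict[str, RefSet], list[PairKey]]:
    """Derive the six reference sets from planted structures and crosslinks.

    The last ``n_held_out`` true pairs are held out of every training set for
    ranking experiments and ROC evaluation. Structure-derived positives come
    with a non-contacting third chain so each structure also yields decoys;
    crosslink positives get geometrically consistent links, crosslink decoys
    get fully violating ones.
    """
    spec = interactome.spec
    ids = interactome.protein_ids
    true_sorted = sorted(interactome.true_pairs)
    n_train = len(true_sorted) - n_held_out
    if n_pdb_pos is None:
        n_pdb_pos = (n_train * 5) // 8  # roughly the 5:3 split of the two sources
    if n_xlms_pos is None:
        n_xlms_pos = n_train - n_pdb_pos
    if n_xlms_decoy is None:
        n_xlms_decoy = n_xlms_pos
    if n_xlms_random is None:
        n_xlms_random = min(200, n_hetero_pairs(2 * (n_xlms_pos + n_xlms_decoy)) // 2)
    if n_pdb_pos + n_xlms_pos + n_held_out > len(true_sorted):
        raise ParameterError("not enough planted true pairs for the requested split")
    held_out = true_sorted[-n_held_out:]
    pdb_pairs = true_sorted[:n_pdb_pos]
    xlms_pairs = true_sorted[n_pdb_pos:n_pdb_pos + n_xlms_pos]

    rng = rng_for(spec.seed, "refset-extras")
    structures = []
    chain_map: dict[tuple[str, str], str] = {}
    for pair in pdb_pairs:
        extra = ids[int(rng.integers(len(ids)))]
        while extra in (pair.id_a, pair.id_b):
            extra = ids[int(rng.integers(len(ids)))]
        st = generate_contact_structure(pair.id_a, pair.id_b, 12, spec.seed,
                                        extra_chain=extra)
        structures.append(st)
        chain_map[(st.structure_id, "A")] = pair.id_a
        chain_map[(st.structure_id, "B")] = pair.id_b
        chain_map[(st.structure_id, "C")] = extra
    positives = build_pdb_positive_set(structures, chain_map)
    decoys = build_pdb_decoy_set(structures, chain_map, positives)

    xlms_input, preds, cmaps = [], {}, {}
    for pair in xlms_pairs:
        st = generate_contact_structure(pair.id_a, pair.id_b, 12, spec.seed)
        links = generate_crosslinks(st, pair.id_a, pair.id_b, 3, 0.0, spec.seed)
        xlms_input.append((pair, links))
        preds[pair] = [st]
        cmaps[pair] = {pair.id_a: "A", pair.id_b: "B"}
    decoy_candidates = sample_unique_pairs(
        ids, n_xlms_decoy, rng_for(spec.seed, "xlms-decoys"),
        exclude=frozenset(interactome.true_pairs),
    )
    for pair in decoy_candidates:
        st = generate_contact_structure(pair.id_a, pair.id_b, 0, spec.seed)
        links = generate_crosslinks(st, pair.id_a, pair.id_b, 3, 1.0, spec.seed)
        xlms_input.append((pair, links))
        preds[pair] = [st]
        cmaps[pair] = {pair.id_a: "A", pair.id_b: "B"}
    xlms_pos, xlms_decoy = build_xlms_sets(xlms_input, preds, chain_maps=cmaps)

    xlms_ids = sorted({pid for p in xlms_pos.members | xlms_decoy.members for pid in p})
    refsets = {
        "PDB": positives,
        "XLMS": xlms_pos,
        "PDB_Decoy": decoys,
        "XLMS_Decoy": xlms_decoy,
        "Random": build_random_set(ids, n_random, spec.seed, name="Random"),
        "XLMS_Random": build_random_set(
            ids, n_xlms_random, spec.seed, restrict_to=xlms_ids, name="XLMS_Random"
        ),
    }
    # Held-out pairs never appear in any training set.
    for refset in refsets.values():
        refset.members -= set(held_out)
    return refsets, held_out


def run_demo_screen(
    spec: FixtureSpec | None = None,
    seed: int = 0,
    fractions: Sequence[float] = DEMO_FRACTIONS,
    forest: ForestConfig = ForestConfig(),
    n_held_out: int = 10,
    fdr_reps: int = 10,
    fdr_n_pos: int = 10,
    fdr_ratio: int = 99,
) -> DemoScreenResult:
    """Full fixture-scale screen: simulate, sweep, select, score, calibrate."""
    t0 = time.monotonic()
    spec = spec or FixtureSpec(seed=seed)
    interactome = generate_interactome(spec)
    refsets, held_out = build_fixture_refsets(interactome, n_held_out=n_held_out)
    cache = FeatureCache(interactome.registry, interactome.stores)
    ids = interactome.protein_ids

    combos = prune_combos(enumerate_combos(fractions=fractions))
    experiments = [RankExperiment(p.id_a, p.id_b) for p in held_out]
    training_pairs = set().union(*(r.members for r in refsets.values()))

    results: list[SweepResult] = []
    for combo in combos:
        clf = train_classifier(combo, refsets, cache, forest, master_seed=spec.seed)
        if clf is None:
            continue

        def score_fn(pairs: Sequence[PairKey], _clf=clf) -> np.ndarray:
            return _clf.score_matrix(cache.matrix(list(pairs)))

        ranks = [rank_partner(score_fn, exp, ids) for exp in experiments]
        median, below = summarize_ranks(ranks)
        results.append(SweepResult(combo, median, below, clf))
    if not results:
        raise ParameterError("no trainable combination in the sweep")
    selected = select_final(results)
    clf = selected.classifier

    def score_fn(pairs: Sequence[PairKey]) -> np.ndarray:
        return clf.score_matrix(cache.matrix(list(pairs)))

    # Held-out ROC: held-out positives vs fresh random negatives (1:99).
    neg = sample_unique_pairs(
        ids, 99 * len(held_out), rng_for(spec.seed, "heldout-negatives"),
        exclude=frozenset(interactome.true_pairs) | training_pairs,
    )
    eval_pairs = list(held_out) + neg
    labels = [1] * len(held_out) + [0] * len(neg)
    auc = roc_auc(score_fn(eval_pairs), labels)

    top_feature = max(clf.feature_importances.items(), key=lambda kv: kv[1])[0]

    # Proteome-wide scoring + screening rules.
    all_pairs = [
        PairKey(ids[i], ids[j])
        for i in range(len(ids)) for j in range(i + 1, len(ids))
    ]
    scores = dict(zip(all_pairs, score_fn(all_pairs)))
    lengths = {p.protein_id: p.length for p in interactome.proteome}
    screening, _excluded = build_screening_set(lengths, scores)

    # FDR calibration on simulated cohorts under the planted prior.
    n_false = n_hetero_pairs(len(ids)) - len(interactome.true_pairs)
    curve = fdr_simulation(
        score_fn, held_out, ids, reps=fdr_reps, n_pos=fdr_n_pos, ratio=fdr_ratio,
        filter_fn=lambda cands: set(cands) - interactome.true_pairs,
        n_true=len(interactome.true_pairs), n_false=n_false,
        seed=derive_seed(spec.seed, "fdr"),
    )
    return DemoScreenResult(
        interactome, refsets, len(results), results, selected,
        selected.median_rank, selected.n_rank_below_100, auc, top_feature,
        screening, curve, time.monotonic() - t0,
    )


# ---------------------------------------------------------------------------
# Planted FDR-recovery study


@dataclass
class FdrStudyResult:
    scorer_auc: float
    cutoff_90_precision: float
    estimated_fdr: float
    population_fdr: float
    n_pairs: int


def planted_fdr_study(
    seed: int,
    n_proteins: int = 2000,
    n_true: int = 2000,
    n_pos: int = 250,
    ratio: int = 999,
    reps: int = 5,
    pos_beta: tuple[float, float] = (6.0, 2.5),
    neg_beta: tuple[float, float] = (0.6, 18.0),
    miss_rate: float = 0.10,
) -> FdrStudyResult:
    """Validate the cohort FDR estimator against a fully known population.

    A planted interactome of ``n_true`` true pairs inside the full pair
    universe gets label-dependent scores shaped like classifier output:
    background pairs draw from a near-zero Beta distribution, true pairs from
    a high Beta except for a ``miss_rate`` fraction the scorer misses
    entirely (overall AUC ~0.95 at the defaults). The cohort estimator's FDR
    at the cutoff reaching 90% estimated precision is compared with the
    exact population FDR at the same cutoff.
    """
    ids = [f"P{i + 1:06d}" for i in range(n_proteins)]
    m = n_proteins
    total = n_hetero_pairs(m)
    rng = rng_for(seed, "planted-universe")
    true_flat = np.sort(rng.choice(total, size=n_true, replace=False))
    scores_all = rng.beta(neg_beta[0], neg_beta[1], size=total)
    missed = rng.random(n_true) < miss_rate
    scores_all[true_flat] = np.where(
        missed,
        rng.beta(neg_beta[0], neg_beta[1], size=n_true),
        rng.beta(pos_beta[0], pos_beta[1], size=n_true),
    )
    true_mask = np.zeros(total, dtype=bool)
    true_mask[true_flat] = True

    iu0, iu1 = np.triu_indices(m, k=1)
    # flat index of pair (i < j): i*m - i*(i+1)/2 + (j - i - 1)
    def flatten(i: np.ndarray, j: np.ndarray) -> np.ndarray:
        return i * m - (i * (i + 1)) // 2 + (j - i - 1)

    def pair_ints(pairs: Sequence[PairKey]) -> tuple[np.ndarray, np.ndarray]:
        a = np.array([int(p.id_a[1:]) - 1 for p in pairs])
        b = np.array([int(p.id_b[1:]) - 1 for p in pairs])
        return a, b

    def score_fn(pairs: Sequence[PairKey]) -> np.ndarray:
        a, b = pair_ints(pairs)
        return scores_all[flatten(a, b)]

    true_pairs = [PairKey(ids[iu0[k]], ids[iu1[k]]) for k in true_flat]
    true_set = frozenset(true_pairs)

    curve = fdr_simulation(
        score_fn, true_pairs, ids, reps=reps, n_pos=n_pos, ratio=ratio,
        filter_fn=lambda cands: set(cands) - true_set,
        n_true=n_true, n_false=total - n_true,
        seed=derive_seed(seed, "fdr-study"),
    )
    cutoff = curve.cutoff_at_precision(0.90)
    est = curve.fdr_at(cutoff)
    called = scores_all >= cutoff
    n_called = int(called.sum())
    pop_fdr = float((called & ~true_mask).sum() / n_called) if n_called else 0.0
    auc = roc_auc(
        np.concatenate([scores_all[true_mask][:5000], scores_all[~true_mask][:50000]]),
        np.concatenate([np.ones(min(n_true, 5000)), np.zeros(50000)]),
    )
    return FdrStudyResult(auc, cutoff, est, pop_fdr, total)


# ---------------------------------------------------------------------------
# Post-prediction filtering (C+)


def run_postfilter(
    prediction_dir: str | Path,
    min_pairs: int = MIN_CONFIDENT_PAIRS,
    pae_cutoff: float = DEFAULT_PAE_CUTOFF_A,
    evidence=None,
    pdb_plus: set[PairKey] | None = None,
    annotations: Mapping[str, set[str]] | None = None,
    go_assignment=None,
) -> tuple[pd.DataFrame, float]:
    """Scan ``{idA}__{idB}/model_k.pae.json`` predictions and call C+ per pair.

    Returns the annotated table and the overall C+ fraction. Malformed files
    flag the pair unreadable; unknown directory names are quarantined.
    """
    rows = []
    root = Path(prediction_dir)
    pair_dirs = sorted(d for d in root.iterdir() if d.is_dir()) if root.exists() else []
    if not pair_dirs:
        logger.warning("no prediction directories under %s", root)
    for d in pair_dirs:
        parts = d.name.split("__")
        if len(parts) != 2:
            logger.warning("quarantined unrecognized prediction dir %s", d.name)
            continue
        pair = PairKey.of(parts[0], parts[1])
        counts, readable = [], True
        for f in sorted(d.glob("model_*.pae.json")):
            try:
                with open(f) as fh:
                    doc = json.load(fh)
                chain_lengths = doc["chain_lengths"]
                pred = load_pae(f, chain_lengths, model_id=f.stem)
                counts.append(count_confident_interchain_pairs(pred, pae_cutoff))
            except Exception:
                readable = False
                logger.warning("unreadable PAE file %s", f)
        c_plus = bool(counts) and max(counts) >= min_pairs
        row = {
            "id_a": pair.id_a, "id_b": pair.id_b,
            "n_models": len(counts),
            "confident_pairs_per_model": ";".join(str(c) for c in counts),
            "c_plus": c_plus, "readable": readable,
        }
        if evidence is not None and pdb_plus is not None:
            row["novelty"] = classify_novelty(pair, evidence, pdb_plus)
        if annotations is not None and go_assignment is not None:
            j = go_pair_jaccard(pair, annotations, go_assignment)
            row["go_jaccard"] = np.nan if j is None else j
        rows.append(row)
    table = pd.DataFrame(rows)
    frac = float(table["c_plus"].mean()) if len(table) else 0.0
    logger.info("C+ fraction: %.3f over %d pairs", frac, len(table))
    return table, frac


def run_triage(
    interactome: PlantedInteractome,
    classifier: TrainedClassifier,
    score_floor: float = 0.088,
    max_combined_length: int = 3600,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every heterodimeric pair and apply the screening rules.

    Returns (kept table with score and rank, exclusion log) carrying the
    config digest for provenance.
    """
    cache = FeatureCache(interactome.registry, interactome.stores)
    ids = interactome.protein_ids
    all_pairs = [
        PairKey(ids[i], ids[j])
        for i in range(len(ids)) for j in range(i + 1, len(ids))
    ]
    scores = dict(zip(all_pairs, classifier.score_matrix(cache.matrix(all_pairs))))
    lengths = {p.protein_id: p.length for p in interactome.proteome}
    kept, excluded = build_screening_set(
        lengths, scores, score_floor=score_floor,
        max_combined_length=max_combined_length,
    )
    digest = stable_digest({
        "registry": interactome.registry.to_config(),
        "score_floor": score_floor,
        "max_combined_length": max_combined_length,
        "seed": interactome.spec.seed,
    })
    kept_df = pd.DataFrame(
        [(p.id_a, p.id_b, s, r + 1) for r, (p, s) in enumerate(kept)],
        columns=["id_a", "id_b", "score", "rank"],
    )
    kept_df.attrs["config_digest"] = digest
    excl_df = pd.DataFrame(
        [(p.id_a, p.id_b, reason) for p, reason in excluded],
        columns=["id_a", "id_b", "reason"],
    )
    excl_df.attrs["config_digest"] = digest
    return kept_df, excl_df
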