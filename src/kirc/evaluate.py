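"""Ranking experiments, ROC evaluation and simulated-interactome FDR.

The ranking experiment measures how a classifier places a bait protein's
known partner among all proteome candidates (competition ranking: rank = 1 +
number of strictly higher-scoring candidates). The FDR estimator builds
labeled cohorts at the interactome's assumed 1:999 positive:negative ratio —
250 held-out positives against 249,750 contamination-filtered random pairs,
with a 30% oversample of candidates (324,675) to survive filtering — scores
them, and converts per-cutoff TPR/FPR into an estimated FDR under a prior of
200,000 true and 199.8 million false pairs in the proteome. The cohort
procedure repeats (100 times at full scale) and the reported curve is the
mean across repetitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._util import derive_seed
from .errors import ParameterError, ShortfallError
from .pairs import PairKey, sample_unique_pairs

N_TRUE_PRIOR = 200_000
N_FALSE_PRIOR = 199_800_000


@dataclass(frozen=True)
class RankExperiment:
    bait: str
    true_partner: str


@dataclass(frozen=True)
class RankResult:
    rank: int
    list_size: int

    def __post_init__(self) -> None:
        if not (1 <= self.rank <= self.list_size):
            raise ParameterError(f"rank {self.rank} outside [1, {self.list_size}]")


def rank_partner(
    score_fn: Callable[[Sequence[PairKey]], np.ndarray],
    exp: RankExperiment,
    proteome_ids: Sequence[str],
    exclude: frozenset[str] | set[str] = frozenset(),
) -> RankResult:
    """Competition rank of the true partner among all proteome candidates.

    The bait itself is excluded from the candidate list, as are any ids in
    ``exclude`` (e.g. training positives sharing the bait). Ties with the
    true partner do not worsen its rank (strict-greater rule).
    """
    candidates = [p for p in proteome_ids if p != exp.bait and p not in exclude]
    if exp.true_partner not in candidates:
        raise ParameterError(f"partner {exp.true_partner} absent from candidate list")
    pairs = [PairKey.of(exp.bait, c) for c in candidates]
    scores = np.asarray(score_fn(pairs), dtype=float)
    partner_score = scores[candidates.index(exp.true_partner)]
    rank = 1 + int(np.sum(scores > partner_score))
    return RankResult(rank, len(candidates))


def summarize_ranks(results: Sequence[RankResult]) -> tuple[int, int]:
    """(median rank, count of ranks < 100); lower-middle median for even n."""
    if not results:
        raise ParameterError("no rank results")
    ranks = sorted(r.rank for r in results)
    median = ranks[(len(ranks) - 1) // 2]
    return median, sum(1 for r in ranks if r < 100)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC via the Mann-Whitney rank statistic; ties contribute one half."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ParameterError("both classes required for AUC")
    r = rankdata(s)  # average ranks handle ties as 1/2
    return float((r[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def fdr_from_rates(
    tpr: float,
    fpr: float,
    n_true: float = N_TRUE_PRIOR,
    n_false: float = N_FALSE_PRIOR,
) -> float:
    """Convert (TPR, FPR) at a cutoff to an estimated FDR under the prior.

    fdr = fpr * n_false / (fpr * n_false + tpr * n_true); no calls -> 0.
    """
    if tpr < 0 or fpr < 0 or tpr > 1 or fpr > 1:
        raise ParameterError(f"rates outside [0, 1]: tpr={tpr}, fpr={fpr}")
    denom = fpr * n_false + tpr * n_true
    if denom == 0.0:
        return 0.0
    return fpr * n_false / denom


@dataclass
class FdrCohort:
    pairs: list[PairKey]
    labels: np.ndarray
    n_candidates_generated: int
    n_negatives_sampled: int


def make_fdr_cohort(
    positives_pool: Sequence[PairKey],
    proteome_ids: Sequence[str],
    n_pos: int = 250,
    ratio: int = 999,
    oversample: float = 1.3,
    filter_fn: Callable[[Sequence[PairKey]], set[PairKey]] | None = None,
    seed: int = 0,
) -> FdrCohort:
    """One labeled cohort at a 1:ratio positive:negative balance.

    ``ceil(oversample * ratio * n_pos)`` candidate random heterodimer pairs
    are generated, ``filter_fn`` removes inadvertent positives, and exactly
    ``ratio * n_pos`` survivors are sampled alongside ``n_pos`` positives
    drawn from the held-out pool. Deterministic per seed.
    """
    rng = np.random.default_rng(derive_seed(seed, "fdr-cohort"))
    n_neg = ratio * n_pos
    n_cand = math.ceil(oversample * n_neg)
    pool = sorted(set(positives_pool))
    if len(pool) < n_pos:
        raise ParameterError(f"positive pool has {len(pool)} < {n_pos} pairs")
    pos_idx = rng.choice(len(pool), size=n_pos, replace=False)
    positives = [pool[i] for i in sorted(pos_idx)]
    candidates = sample_unique_pairs(proteome_ids, n_cand, rng)
    if filter_fn is not None:
        surviving_set = filter_fn(candidates)
        survivors = [p for p in candidates if p in surviving_set]
    else:
        survivors = list(candidates)
    if len(survivors) < n_neg:
        raise ShortfallError(
            f"only {len(survivors)} negatives survived filtering; need {n_neg} — "
            "increase the oversample factor"
        )
    neg_idx = rng.choice(len(survivors), size=n_neg, replace=False)
    negatives = [survivors[i] for i in sorted(neg_idx)]
    pairs = positives + negatives
    labels = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    return FdrCohort(pairs, labels, n_cand, n_neg)


def default_cutoff_grid() -> np.ndarray:
    return np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)


def rates_at_cutoffs(
    scores: np.ndarray, labels: np.ndarray, cutoffs: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized TPR/FPR at each cutoff; a call is score >= cutoff."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = np.sort(scores[labels == 1])
    neg = np.sort(scores[labels == 0])
    n_pos, n_neg = len(pos), len(neg)
    tpr = (n_pos - np.searchsorted(pos, cutoffs, side="left")) / max(n_pos, 1)
    fpr = (n_neg - np.searchsorted(neg, cutoffs, side="left")) / max(n_neg, 1)
    return tpr, fpr


@dataclass
class FDRCurve:
    """Mean cutoff -> (TPR, FPR, FDR) table across cohort repetitions."""

    table: pd.DataFrame  # columns: cutoff, tpr, fpr, fdr, n_reps, n_silent_reps
    n_true: float = N_TRUE_PRIOR
    n_false: float = N_FALSE_PRIOR

    def fdr_at(self, cutoff: float) -> float:
        idx = (self.table["cutoff"] - cutoff).abs().idxmin()
        return float(self.table.loc[idx, "fdr"])

    def cutoff_at_precision(self, precision: float) -> float:
        """Smallest grid cutoff whose estimated precision (1 - FDR) >= target."""
        ok = self.table[(1.0 - self.table["fdr"]) >= precision]
        if ok.empty:
            raise ParameterError(f"no cutoff reaches precision {precision}")
        return float(ok["cutoff"].iloc[0])

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def fdr_simulation(
    score_fn: Callable[[Sequence[PairKey]], np.ndarray],
    positives_pool: Sequence[PairKey],
    proteome_ids: Sequence[str],
    reps: int = 100,
    cutoffs: np.ndarray | None = None,
    n_pos: int = 250,
    ratio: int = 999,
    oversample: float = 1.3,
    filter_fn: Callable[[Sequence[PairKey]], set[PairKey]] | None = None,
    n_true: float = N_TRUE_PRIOR,
    n_false: float = N_FALSE_PRIOR,
    seed: int = 0,
) -> FDRCurve:
    """Repeat the cohort procedure and average per-cutoff TPR/FPR/FDR.

    Repetitions where no call is made at a cutoff (TPR = FPR = 0) contribute
    FDR 0 there and are counted in the ``n_silent_reps`` column.
    """
    grid = default_cutoff_grid() if cutoffs is None else np.asarray(cutoffs, dtype=float)
    tpr_sum = np.zeros_like(grid)
    fpr_sum = np.zeros_like(grid)
    fdr_sum = np.zeros_like(grid)
    silent = np.zeros_like(grid)
    for rep in range(reps):
        cohort = make_fdr_cohort(
            positives_pool, proteome_ids, n_pos=n_pos, ratio=ratio,
            oversample=oversample, filter_fn=filter_fn,
            seed=derive_seed(seed, "rep", rep),
        )
        scores = np.asarray(score_fn(cohort.pairs), dtype=float)
        tpr, fpr = rates_at_cutoffs(scores, cohort.labels, grid)
        fdr = np.array([
            fdr_from_rates(t, f, n_true, n_false) for t, f in zip(tpr, fpr)
        ])
        silent += (tpr == 0) & (fpr == 0)
        tpr_sum += tpr
        fpr_sum += fpr
        fdr_sum += fdr
    table = pd.DataFrame({
        "cutoff": grid,
        "tpr": tpr_sum / reps,
        "fpr": fpr_sum / reps,
        "fdr": fdr_sum / reps,
        "n_reps": reps,
        "n_silent_reps": silent.astype(int),
    })
    return FDRCurve(table, n_true, n_false)


@dataclass(frozen=True)
class RecallLedger:
    """Per-component recall of the two-step screen at its high-confidence thresholds."""

    kirc: float = 0.68
    afm: float = 0.40
    spoc: float = 0.27

    def components(self) -> tuple[float, ...]:
        return (self.kirc, self.afm, self.spoc)


def pipeline_recall(ledger: RecallLedger | Sequence[float]) -> float:
    """Overall recall of a serial pipeline: the product of component recalls."""
    comps = ledger.components() if isinstance(ledger, RecallLedger) else tuple(ledger)
    if any(c < 0 or c > 1 for c in comps):
        raise ParameterError("component recalls must lie in [0, 1]")
    return float(np.prod(comps))
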