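"""Omics stores and assembly of the fixed-order pairwise feature vector.

The classifier sees each candidate pair as a numeric vector assembled from
heterogeneous per-protein and per-pair data sources:

* :class:`VectorStore` — protein -> numeric vector (gene-effect profiles,
  CRISPR-screen hit vectors, perturbation-response profiles, sequence
  embeddings, compartment localization probabilities). Pairwise features are
  cosine similarities or probability-overlap dot products.
* :class:`ScalarStore` — protein -> scalar (integrated abundance, cluster
  size, mean pLDDT). Asymmetric per-protein scalars enter as (min, max) over
  the two proteins so the vector is symmetric under pair order.
* :class:`PairScoreStore` — pair -> scalar (database evidence counts, STRING
  channel scores, co-fractionation row statistics, scaled disease-similarity
  cosines, retained co-expression scores, deep-learning interaction
  probabilities consumed as-is).

Missing inputs are imputed to 0 with a parallel missing mask — the single
imputation rule used throughout.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from ._util import stable_digest
from .errors import ParameterError, ShapeMismatchError
from .pairs import PairKey

MISSING = None  # sentinel: featurizers return None, assembly imputes 0 + mask


@dataclass
class VectorStore:
    source_name: str
    dim: int
    entries: dict[str, np.ndarray] = field(default_factory=dict)

    def put(self, pid: str, vec: Sequence[float]) -> None:
        arr = np.asarray(vec, dtype=float)
        if arr.shape != (self.dim,):
            raise ShapeMismatchError(
                f"{self.source_name}[{pid}]: length {arr.shape} != declared dim {self.dim}"
            )
        self.entries[pid] = arr

    def get(self, pid: str) -> np.ndarray | None:
        return self.entries.get(pid)

    def to_json(self, path: str | Path) -> None:
        doc = {pid: [float(v) for v in vec] for pid, vec in sorted(self.entries.items())}
        with open(path, "w") as fh:
            json.dump({"source": self.source_name, "dim": self.dim, "entries": doc}, fh,
                      sort_keys=True, separators=(",", ":"))

    @classmethod
    def from_json(cls, path: str | Path) -> "VectorStore":
        with open(path) as fh:
            doc = json.load(fh)
        store = cls(doc["source"], int(doc["dim"]))
        for pid, vec in doc["entries"].items():
            store.put(pid, vec)
        return store


@dataclass
class ScalarStore:
    source_name: str
    entries: dict[str, float] = field(default_factory=dict)

    def get(self, pid: str) -> float | None:
        return self.entries.get(pid)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"source": self.source_name,
                       "entries": {k: float(v) for k, v in sorted(self.entries.items())}},
                      fh, sort_keys=True, separators=(",", ":"))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScalarStore":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(doc["source"], {k: float(v) for k, v in doc["entries"].items()})


@dataclass
class PairScoreStore:
    """Pair-keyed scalars, serialized as the nested id -> id -> value dialect."""

    source_name: str
    entries: dict[PairKey, float] = field(default_factory=dict)

    def put(self, pair: PairKey, value: float) -> None:
        self.entries[pair] = float(value)

    def get(self, pair: PairKey) -> float | None:
        return self.entries.get(pair)

    def to_json(self, path: str | Path) -> None:
        nested: dict[str, dict[str, float]] = {}
        for pair, v in self.entries.items():
            nested.setdefault(pair.id_a, {})[pair.id_b] = float(v)
        with open(path, "w") as fh:
            json.dump({"source": self.source_name, "entries": nested}, fh,
                      sort_keys=True, separators=(",", ":"))

    @classmethod
    def from_json(cls, path: str | Path) -> "PairScoreStore":
        with open(path) as fh:
            doc = json.load(fh)
        store = cls(doc["source"])
        for a, inner in doc["entries"].items():
            for b, v in inner.items():
                store.put(PairKey.of(a, b), v)
        return store


# ---------------------------------------------------------------------------
# Featurizers


def cosine_pair_feature(store: VectorStore, pair: PairKey) -> float | None:
    """Cosine similarity of the two protein vectors; missing/zero -> missing."""
    va, vb = store.get(pair.id_a), store.get(pair.id_b)
    if va is None or vb is None:
        return MISSING
    na, nb = float(np.linalg.norm(va)), float(np.linalg.norm(vb))
    if na == 0.0 or nb == 0.0:
        return MISSING
    return float(np.dot(va, vb) / (na * nb))


def overlap_dot_feature(store: VectorStore, pair: PairKey) -> float | None:
    """Dot product of two probability vectors (compartment co-localization)."""
    va, vb = store.get(pair.id_a), store.get(pair.id_b)
    if va is None or vb is None:
        return MISSING
    return float(np.dot(va, vb))


def cofrac_row_stats(row: Sequence[float | None]) -> tuple[float | None, float | None, float | None]:
    """(mean, median, max) over present values of one co-fractionation row.

    Missing entries (None/NaN) are ignored; an all-missing row yields a
    missing triple.
    """
    present = [float(v) for v in row if v is not None and not (isinstance(v, float) and math.isnan(v))]
    if not present:
        return (MISSING, MISSING, MISSING)
    arr = np.asarray(present)
    return (float(arr.mean()), float(np.median(arr)), float(arr.max()))


def avg_missense_profile(per_residue_scores: np.ndarray) -> np.ndarray:
    """Per-residue mean over the 19 possible substitutions (scores on 0-100)."""
    arr = np.asarray(per_residue_scores, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 19:
        raise ShapeMismatchError(f"expected (L, 19) matrix, got {arr.shape}")
    return arr.mean(axis=1)


def scale_disgenet(score: float) -> int:
    """Scale a [0, 1] similarity to an integer in [0, 1000], half away from zero."""
    if not (0.0 <= score <= 1.0):
        raise ParameterError(f"similarity {score} outside [0, 1]")
    return int(math.floor(score * 1000.0 + 0.5))


def biogrid_pair_count(records: Iterable[tuple[str, str]],
                       source_name: str = "biogrid_detect_count") -> PairScoreStore:
    """Count occurrences of each unique canonical pair across raw observations."""
    store = PairScoreStore(source_name)
    for a, b in records:
        pair = PairKey.of(str(a), str(b))
        store.entries[pair] = store.entries.get(pair, 0.0) + 1.0
    return store


def coexpression_top_k(
    scores: Mapping[str, Sequence[tuple[str, float]]],
    k: int = 500,
    source_name: str = "coexpression",
) -> PairScoreStore:
    """Retain each gene's top-k partners by score; ties broken by partner id.

    Pair lookup returns the maximum over both retention directions.
    """
    store = PairScoreStore(source_name)
    for gene, partners in scores.items():
        ranked = sorted(partners, key=lambda ps: (-ps[1], ps[0]))[:k]
        for partner, score in ranked:
            pair = PairKey.of(gene, partner)
            prev = store.entries.get(pair)
            if prev is None or score > prev:
                store.entries[pair] = float(score)
    return store


# ---------------------------------------------------------------------------
# Registry and assembly

FEATURE_KINDS = ("cosine", "overlap_dot", "pair_score", "scalar_min", "scalar_max")


@dataclass(frozen=True)
class FeatureSpec:
    name: str
    kind: str
    source: str  # key into the stores mapping
    missing: str = "zero"

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ParameterError(f"unknown featurizer kind {self.kind!r}")


@dataclass(frozen=True)
class FeatureRegistry:
    specs: tuple[FeatureSpec, ...]

    def __post_init__(self) -> None:
        names = [s.name for s in self.specs]
        if len(names) != len(set(names)):
            raise ParameterError("duplicate feature names in registry")

    def __len__(self) -> int:
        return len(self.specs)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.specs)

    @property
    def registry_hash(self) -> str:
        return stable_digest([(s.name, s.kind, s.source, s.missing) for s in self.specs])

    def to_config(self) -> list[dict]:
        return [
            {"name": s.name, "kind": s.kind, "source": s.source, "missing": s.missing}
            for s in self.specs
        ]

    @classmethod
    def from_config(cls, items: Sequence[Mapping]) -> "FeatureRegistry":
        return cls(tuple(
            FeatureSpec(d["name"], d["kind"], d["source"], d.get("missing", "zero"))
            for d in items
        ))


@dataclass
class FeatureVector:
    pair: PairKey
    values: np.ndarray
    missing_mask: np.ndarray


def _scalar_minmax(store: ScalarStore, pair: PairKey) -> tuple[float | None, float | None]:
    a, b = store.get(pair.id_a), store.get(pair.id_b)
    present = [v for v in (a, b) if v is not None]
    if len(present) < 2:
        return (MISSING, MISSING)
    return (min(present), max(present))


def assemble_pair_features(
    pair: PairKey,
    registry: FeatureRegistry,
    stores: Mapping[str, VectorStore | ScalarStore | PairScoreStore],
    known_ids: frozenset[str] | set[str] | None = None,
) -> FeatureVector:
    """Assemble the ordered feature vector for one pair.

    Missing inputs are imputed to 0 with the mask set; the result is
    guaranteed finite and identical for (a, b) and (b, a) by canonical pair
    ordering and symmetric featurizers.
    """
    if known_ids is not None:
        for pid in pair:
            if pid not in known_ids:
                raise KeyError(f"unknown protein id {pid!r} in {pair}")
    values = np.zeros(len(registry))
    mask = np.zeros(len(registry), dtype=bool)
    for i, spec in enumerate(registry.specs):
        store = stores.get(spec.source)
        v: float | None
        if store is None:
            v = MISSING
        elif spec.kind == "cosine":
            v = cosine_pair_feature(store, pair)
        elif spec.kind == "overlap_dot":
            v = overlap_dot_feature(store, pair)
        elif spec.kind == "pair_score":
            v = store.get(pair)
        elif spec.kind == "scalar_min":
            v = _scalar_minmax(store, pair)[0]
        elif spec.kind == "scalar_max":
            v = _scalar_minmax(store, pair)[1]
        else:  # pragma: no cover - guarded by FeatureSpec
            raise ParameterError(spec.kind)
        if v is None or not np.isfinite(v):
            mask[i] = True
        else:
            values[i] = float(v)
    return FeatureVector(pair, values, mask)


def assemble_matrix(
    pairs: Sequence[PairKey],
    registry: FeatureRegistry,
    stores: Mapping[str, VectorStore | ScalarStore | PairScoreStore],
) -> np.ndarray:
    """Stack feature vectors for many pairs into an (n_pairs, n_features) array."""
    out = np.zeros((len(pairs), len(registry)))
    for i, pair in enumerate(pairs):
        out[i] = assemble_pair_features(pair, registry, stores).values
    return out


class FeatureCache:
    """Memoizing wrapper so each pair is featurized at most once per run."""

    def __init__(self, registry: FeatureRegistry, stores: Mapping[str, object]) -> None:
        self.registry = registry
        self.stores = stores
        self._cache: dict[PairKey, np.ndarray] = {}

    def vector(self, pair: PairKey) -> np.ndarray:
        v = self._cache.get(pair)
        if v is None:
            v = assemble_pair_features(pair, self.registry, self.stores).values
            self._cache[pair] = v
        return v

    def matrix(self, pairs: Sequence[PairKey]) -> np.ndarray:
        return np.stack([self.vector(p) for p in pairs]) if pairs else np.zeros((0, len(self.registry)))


def default_registry(store_names: Iterable[str]) -> FeatureRegistry:
    """The standard feature list over whichever sources are available.

    Covers every construction the pipeline's data sources support: evidence
    counts, STRING channels, cosine similarities over profile/embedding
    stores, localization overlap, co-fractionation row statistics, abundance
    and structure-cluster scalars as (min, max), the scaled disease-similarity
    cosine, retained co-expression scores, and a deep-learning interaction
    probability passed through unchanged.
    """
    available = set(store_names)
    catalogue: list[FeatureSpec] = [
        FeatureSpec("intact_count", "pair_score", "intact"),
        FeatureSpec("biogrid_detect_count", "pair_score", "biogrid"),
        FeatureSpec("string_physical", "pair_score", "string_physical"),
        FeatureSpec("string_combined", "pair_score", "string_combined"),
        FeatureSpec("depmap_cosine", "cosine", "depmap"),
        FeatureSpec("orcs_cosine", "cosine", "orcs"),
        FeatureSpec("proteomehd_cosine", "cosine", "proteomehd"),
        FeatureSpec("embedding_cosine", "cosine", "embeddings"),
        FeatureSpec("localization_overlap", "overlap_dot", "localization"),
        FeatureSpec("cofrac_mean", "pair_score", "cofrac_mean"),
        FeatureSpec("cofrac_median", "pair_score", "cofrac_median"),
        FeatureSpec("cofrac_max", "pair_score", "cofrac_max"),
        FeatureSpec("abundance_min", "scalar_min", "abundance"),
        FeatureSpec("abundance_max", "scalar_max", "abundance"),
        FeatureSpec("cluster_size_min", "scalar_min", "cluster_size"),
        FeatureSpec("cluster_size_max", "scalar_max", "cluster_size"),
        FeatureSpec("plddt_min", "scalar_min", "cluster_plddt"),
        FeatureSpec("plddt_max", "scalar_max", "cluster_plddt"),
        FeatureSpec("missense_mean_min", "scalar_min", "missense_mean"),
        FeatureSpec("missense_mean_max", "scalar_max", "missense_mean"),
        FeatureSpec("disgenet_cosine", "pair_score", "disgenet"),
        FeatureSpec("coexpression_score", "pair_score", "coexpression"),
        FeatureSpec("rf2ppi_score", "pair_score", "rf2ppi"),
    ]
    return FeatureRegistry(tuple(s for s in catalogue if s.source in available))
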