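"""Construction of the six labeled reference pair sets.

Two positive collections (structure-derived direct interactors; crosslink-
consistent predicted complexes) and four negative collections (structure
decoys — co-occurring but non-contacting chains; crosslink-inconsistent
predictions; and two random-pairing sets) drive classifier training. A
contamination filter removes candidate negatives that carry interaction
evidence through homology (IntAct counts, structure-homology pairs, very
high STRING scores).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import derive_seed, rng_for
from .pairs import PairKey, ProteinRecord, sample_unique_pairs
from .structgeom import (
    ComplexStructure,
    Crosslink,
    MIN_CONTACT_PAIRS,
    count_interchain_contacts,
    crosslink_consistent,
    is_interacting_chain_pair,
)

logger = logging.getLogger(__name__)

REFSET_NAMES = ("PDB", "XLMS", "PDB_Decoy", "XLMS_Decoy", "Random", "XLMS_Random")
POSITIVE_SETS = ("PDB", "XLMS")
NEGATIVE_SETS = ("PDB_Decoy", "XLMS_Decoy", "Random", "XLMS_Random")
DECOY_SETS = ("PDB_Decoy", "XLMS_Decoy")


@dataclass
class RefSet:
    """A named, labeled collection of canonical pairs with provenance notes."""

    name: str
    label: str  # "positive" | "negative"
    members: set[PairKey] = field(default_factory=set)
    provenance: dict[PairKey, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in ("positive", "negative"):
            raise ValueError(f"label must be positive/negative, got {self.label!r}")

    def __len__(self) -> int:
        return len(self.members)

    def add(self, pair: PairKey, note: str = "") -> None:
        self.members.add(pair)
        if note:
            self.provenance[pair] = note


@dataclass(frozen=True)
class AlignmentHit:
    query: str
    target: str
    pct_identity: float
    e_value: float
    aln_length: int
    query_coverage: float = 0.0
    target_coverage: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValueError(f"pct_identity out of range: {self.pct_identity}")
        if self.e_value <= 0:
            raise ValueError(f"e_value must be positive: {self.e_value}")


@dataclass(frozen=True)
class Evidence:
    intact_count: int = 0
    biogrid_count: int = 0
    string_physical: int = 0
    string_combined: int = 0


class EvidenceTable:
    """Pair -> (IntAct count, BioGRID count, STRING physical/combined scores)."""

    def __init__(self, entries: Mapping[PairKey, Evidence] | None = None) -> None:
        self.entries: dict[PairKey, Evidence] = dict(entries or {})

    def get(self, pair: PairKey) -> Evidence:
        return self.entries.get(pair, Evidence())

    def __setitem__(self, pair: PairKey, ev: Evidence) -> None:
        self.entries[pair] = ev

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "EvidenceTable":
        df = pd.read_csv(path, sep="\t")
        table = cls()
        for r in df.itertuples():
            table[PairKey.of(str(r.id_a), str(r.id_b))] = Evidence(
                int(r.intact_count),
                int(r.biogrid_count),
                int(r.string_physical),
                int(r.string_combined),
            )
        return table

    def write_tsv(self, path: str | Path) -> None:
        rows = [
            (p.id_a, p.id_b, e.intact_count, e.biogrid_count, e.string_physical, e.string_combined)
            for p, e in sorted(self.entries.items())
        ]
        pd.DataFrame(
            rows,
            columns=["id_a", "id_b", "intact_count", "biogrid_count", "string_physical", "string_combined"],
        ).to_csv(path, sep="\t", index=False)


def _mapped_chain_pairs(
    structure: ComplexStructure, chain_map: Mapping
) -> list[tuple[str, str, PairKey]]:
    """All unordered pairs of mapped chains yielding heterodimeric protein pairs.

    ``chain_map`` may be keyed by chain id or by (structure_id, chain_id);
    unmapped chains are skipped.
    """
    mapped = []
    for c in structure.chains:
        pid = chain_map.get((structure.structure_id, c.chain_id), chain_map.get(c.chain_id))
        if pid is not None:
            mapped.append((c.chain_id, pid))
    out = []
    for i in range(len(mapped)):
        for j in range(i + 1, len(mapped)):
            ca, pa = mapped[i]
            cb, pb = mapped[j]
            if pa == pb:
                continue
            out.append((ca, cb, PairKey.of(pa, pb)))
    return out


def build_pdb_positive_set(
    structures: Sequence[ComplexStructure],
    chain_map: Mapping[str, str],
    min_pairs: int = MIN_CONTACT_PAIRS,
    cutoff: float = 5.0,
) -> RefSet:
    """Unique proteome pairs whose mapped chains directly interact in >=1 structure."""
    if not structures:
        warnings.warn("no structures supplied; positive set is empty")
    refset = RefSet("PDB", "positive")
    for st in structures:
        for ca, cb, pair in _mapped_chain_pairs(st, chain_map):
            if pair in refset.members:
                continue
            summary = count_interchain_contacts(st, ca, cb, cutoff)
            if is_interacting_chain_pair(summary, min_pairs):
                refset.add(pair, f"{st.structure_id}:{ca}-{cb}:{summary.contact_pairs}")
    return refset


def build_pdb_decoy_set(
    structures: Sequence[ComplexStructure],
    chain_map: Mapping[str, str],
    positives: RefSet,
    min_pairs: int = MIN_CONTACT_PAIRS,
    cutoff: float = 5.0,
) -> RefSet:
    """Pairs co-occurring in a structure but never in direct contact anywhere.

    A pair that qualifies as positive in ANY structure is never a decoy.
    """
    refset = RefSet("PDB_Decoy", "negative")
    for st in structures:
        for ca, cb, pair in _mapped_chain_pairs(st, chain_map):
            if pair in positives.members or pair in refset.members:
                continue
            refset.add(pair, f"co-occur {st.structure_id}:{ca}-{cb}")
    # Positive precedence across structures.
    refset.members -= positives.members
    return refset


def build_xlms_sets(
    xlms_pairs: Sequence[tuple[PairKey, Sequence[Crosslink]]],
    preds: Mapping[PairKey, Sequence[ComplexStructure]],
    cutoff: float = 36.0,
    chain_maps: Mapping[PairKey, Mapping[str, str]] | None = None,
) -> tuple[RefSet, RefSet]:
    """Split crosslinked pairs into consistency positives and decoys.

    A pair is positive when at least one of its (up to three) predicted
    structures is geometrically consistent with all reported crosslinks;
    otherwise it is a decoy. Pairs without predictions are excluded.
    """
    pos = RefSet("XLMS", "positive")
    neg = RefSet("XLMS_Decoy", "negative")
    for pair, links in xlms_pairs:
        models = preds.get(pair, ())
        if not models:
            warnings.warn(f"{pair}: no predictions; excluded from XLMS sets")
            continue
        cmap = chain_maps.get(pair) if chain_maps else None
        ok = any(
            crosslink_consistent(m, links, cutoff=cutoff, chain_map=cmap) for m in models
        )
        (pos if ok else neg).add(pair, f"{len(models)} models; consistent={ok}")
    return pos, neg


def build_random_set(
    proteome: Sequence[ProteinRecord] | Sequence[str],
    n: int,
    seed: int,
    restrict_to: Iterable[str] | None = None,
    name: str = "Random",
    allow_self: bool = False,
) -> RefSet:
    """Uniform random heterodimeric pairs, deterministic per (seed, set name)."""
    ids = [p.protein_id if isinstance(p, ProteinRecord) else str(p) for p in proteome]
    if restrict_to is not None:
        allowed = set(restrict_to)
        ids = [i for i in ids if i in allowed]
    if allow_self:
        raise NotImplementedError("self-pairs are excluded from the screen")
    rng = rng_for(seed, "random-set", name)
    refset = RefSet(name, "negative")
    for pair in sample_unique_pairs(ids, n, rng):
        refset.add(pair, "random")
    return refset


def filter_contaminants(
    candidates: Iterable[PairKey],
    evidence: EvidenceTable,
    pdb_homolog_pairs: Mapping[PairKey, tuple[float, float]] | set[PairKey],
    string_cutoff: int = 990,
    mapping_quality: Mapping[PairKey, tuple[float, float]] | None = None,
) -> tuple[set[PairKey], list[tuple[PairKey, str]]]:
    """Remove candidate negatives that look like real interactors.

    Three exclusion rules, each gated on the identity/coverage of the homology
    mapping that transferred the evidence (identity in percent, coverage as a
    fraction of the query length; direct evidence counts as 100% / 1.0):

    1. IntAct evidence count >= 2, mapping >= 50% identity and >= 70% coverage;
    2. membership in the structure-homology interaction set, same gates;
    3. STRING score (physical or combined channel) strictly > ``string_cutoff``,
       mapping >= 90% identity and >= 90% coverage.

    Returns the surviving candidates and a removal log of (pair, rule).
    """
    if isinstance(pdb_homolog_pairs, set) or not hasattr(pdb_homolog_pairs, "get"):
        pdb_homolog_pairs = {p: (100.0, 1.0) for p in pdb_homolog_pairs}
    kept: set[PairKey] = set()
    removed: list[tuple[PairKey, str]] = []
    for pair in sorted(set(candidates)):
        idt, cov = (mapping_quality or {}).get(pair, (100.0, 1.0))
        ev = evidence.get(pair)
        if ev.intact_count >= 2 and idt >= 50.0 and cov >= 0.70:
            removed.append((pair, "intact"))
            continue
        if pair in pdb_homolog_pairs:
            h_idt, h_cov = pdb_homolog_pairs[pair]
            if h_idt >= 50.0 and h_cov >= 0.70:
                removed.append((pair, "pdb_homolog"))
                continue
        if max(ev.string_physical, ev.string_combined) > string_cutoff and idt >= 90.0 and cov >= 0.90:
            removed.append((pair, "string"))
            continue
        kept.add(pair)
    for pair, rule in removed:
        logger.debug("filtered %s by rule %s", pair, rule)
    return kept, removed


# ---------------------------------------------------------------------------
# I/O

BLAST_TAB_COLUMNS = [
    "query", "target", "pident", "alnlen", "mismatch", "gapopen",
    "qstart", "qend", "tstart", "tend", "evalue", "bits",
]


def read_alignment_tsv(path: str | Path, query_lengths: Mapping[str, int] | None = None) -> list[AlignmentHit]:
    """Read 12-column blast-tab alignments; tolerates a header row."""
    first = pd.read_csv(path, sep="\t", nrows=1, header=None)
    has_header = not str(first.iloc[0, 2]).replace(".", "", 1).isdigit()
    df = pd.read_csv(
        path, sep="\t", header=0 if has_header else None,
        names=BLAST_TAB_COLUMNS,
    )
    hits = []
    for r in df.itertuples():
        qlen = (query_lengths or {}).get(str(r.query))
        qcov = float(r.alnlen) / qlen if qlen else 0.0
        hits.append(
            AlignmentHit(
                str(r.query), str(r.target), float(r.pident), float(r.evalue),
                int(r.alnlen), query_coverage=min(qcov, 1.0),
            )
        )
    return hits


def write_refset_tsv(refset: RefSet, path: str | Path) -> None:
    rows = [
        (p.id_a, p.id_b, refset.name, refset.label, refset.provenance.get(p, ""))
        for p in sorted(refset.members)
    ]
    pd.DataFrame(rows, columns=["id_a", "id_b", "set_name", "label", "provenance"]).to_csv(
        path, sep="\t", index=False
    )


def read_refset_tsv(path: str | Path) -> RefSet:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    name = str(df["set_name"].iloc[0]) if len(df) else Path(path).stem
    label = str(df["label"].iloc[0]) if len(df) else "negative"
    refset = RefSet(name, label)
    for r in df.itertuples():
        refset.add(PairKey.of(str(r.id_a), str(r.id_b)), str(r.provenance))
    return refset
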