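"""Structure-homolog pair mapping, novelty classification and GO similarity.

Chains of experimental structures are mapped to proteome accessions through
their best sequence alignment (highest identity, then lowest E-value, then
longest alignment); contacting mapped chain pairs yield proteome interaction
pairs, which are expanded through sequence-cluster membership (all cross
products of the two clusters). Screen hits are then classified by prior
evidence into structure-homolog / experimental / functional-only / novel
categories, and per-pair functional agreement is measured as the Jaccard
index of GO-term clusters, where terms are greedily grouped by normalized
Levenshtein similarity of their descriptions.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib

from .errors import ParameterError
from .pairs import PairKey
from .refsets import AlignmentHit, EvidenceTable
from .structgeom import (
    ComplexStructure,
    MIN_CONTACT_PAIRS,
    count_interchain_contacts,
    is_interacting_chain_pair,
)

MIN_ALIGNMENT_LENGTH = 6
MIN_ALIGNMENT_IDENTITY = 30.0
STRING_EVIDENCE_CUTOFF = 700
MIN_CHAIN_RESIDUES = 8  # short peptides are excluded at ingestion

NOVELTY_CATEGORIES = ("pdb_homolog", "experimental", "string_functional", "novel")


@dataclass(frozen=True)
class SequenceCluster:
    representative: str
    members: frozenset[str]
    identity_level: float = 90.0
    coverage_level: float = 0.9


@dataclass(frozen=True)
class GOTerm:
    term_id: str
    description: str


@dataclass
class GOClusterAssignment:
    term_to_cluster: dict[str, int]
    cluster_representatives: dict[int, str]  # cluster id -> founding term id


@dataclass(frozen=True)
class InteractionCluster:
    member_pairs: frozenset[PairKey]
    earliest_structure_date: datetime.date
    best_score: float


def select_best_alignment(
    hits: Sequence[AlignmentHit],
    min_aln_length: int = MIN_ALIGNMENT_LENGTH,
    min_identity: float = MIN_ALIGNMENT_IDENTITY,
) -> AlignmentHit | None:
    """Best surviving hit for one query; None when nothing passes the gates.

    Priority: highest identity, lowest E-value, longest alignment; a final
    stable tie-break on target id keeps the choice deterministic.
    """
    surviving = [
        h for h in hits
        if h.aln_length >= min_aln_length and h.pct_identity >= min_identity
    ]
    if not surviving:
        return None
    return min(surviving, key=lambda h: (-h.pct_identity, h.e_value, -h.aln_length, h.target))


def find_homolog_pairs(
    structures: Sequence[ComplexStructure],
    chain_best_hits: Mapping[tuple[str, str], str],
    min_pairs: int = MIN_CONTACT_PAIRS,
    cutoff: float = 5.0,
) -> set[PairKey]:
    """Unique proteome pairs whose mapped chains are in contact in >=1 structure.

    ``chain_best_hits`` maps (structure_id, chain_id) to the proteome
    accession of the chain's best alignment; unmapped chains are skipped.
    """
    found: set[PairKey] = set()
    for st in structures:
        mapped = [
            (c.chain_id, chain_best_hits[(st.structure_id, c.chain_id)])
            for c in st.chains
            if (st.structure_id, c.chain_id) in chain_best_hits and len(c) >= MIN_CHAIN_RESIDUES
        ]
        for i in range(len(mapped)):
            for j in range(i + 1, len(mapped)):
                ca, pa = mapped[i]
                cb, pb = mapped[j]
                if pa == pb:
                    continue
                pair = PairKey.of(pa, pb)
                if pair in found:
                    continue
                summary = count_interchain_contacts(st, ca, cb, cutoff)
                if is_interacting_chain_pair(summary, min_pairs):
                    found.add(pair)
    return found


def expand_by_clusters(
    pairs: Iterable[PairKey], clusters: Sequence[SequenceCluster]
) -> set[PairKey]:
    """Expand interactions to all cross-products of the two member clusters.

    An intra-cluster seed pair expands to every within-cluster unordered pair
    (self-pairs dropped). Each protein must belong to exactly one cluster;
    proteins without a cluster act as singletons. Output is a superset of the
    input and the operation is idempotent.
    """
    membership: dict[str, frozenset[str]] = {}
    for cl in clusters:
        for pid in cl.members:
            if pid in membership and membership[pid] != cl.members:
                raise ParameterError(f"protein {pid} assigned to two clusters")
            membership[pid] = cl.members
    out: set[PairKey] = set()
    for pair in pairs:
        ma = membership.get(pair.id_a, frozenset([pair.id_a]))
        mb = membership.get(pair.id_b, frozenset([pair.id_b]))
        for a in ma:
            for b in mb:
                if a != b:
                    out.add(PairKey.of(a, b))
    return out


def classify_novelty(
    pair: PairKey,
    evidence: EvidenceTable,
    pdb_plus: set[PairKey],
    string_cutoff: int = STRING_EVIDENCE_CUTOFF,
) -> str:
    """Mutually exclusive novelty call with fixed priority.

    pdb_homolog > experimental (IntAct or BioGRID count >= 2, or STRING
    physical > cutoff) > string_functional (combined > cutoff only) > novel.
    """
    if pair in pdb_plus:
        return "pdb_homolog"
    ev = evidence.get(pair)
    if ev.intact_count >= 2 or ev.biogrid_count >= 2 or ev.string_physical > string_cutoff:
        return "experimental"
    if ev.string_combined > string_cutoff:
        return "string_functional"
    return "novel"


def post_training_recall(
    clusters: Sequence[InteractionCluster],
    date_floor: datetime.date,
    date_ceiling: datetime.date,
    score_cutoff: float = 0.86,
) -> float:
    """Cluster-level recall on interactions first resolved inside a date window.

    A cluster counts as recovered when the highest score among its member
    pairs exceeds the cutoff.
    """
    eligible = [
        c for c in clusters if date_floor < c.earliest_structure_date < date_ceiling
    ]
    if not eligible:
        raise ParameterError("no interaction clusters inside the date window")
    return sum(1 for c in eligible if c.best_score > score_cutoff) / len(eligible)


def levenshtein_norm_similarity(a: str, b: str) -> float:
    """1 - editDistance(a, b) / max(|a|, |b|); two empty strings -> 1."""
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    dist = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def cluster_go_terms(terms: Sequence[GOTerm], threshold: float = 0.75) -> GOClusterAssignment:
    """Greedy single-pass description clustering.

    Terms are visited in ascending term_id order; a term joins the first
    existing cluster whose FOUNDING representative's description similarity
    is strictly above the threshold, otherwise it founds a new cluster.
    """
    assignment: dict[str, int] = {}
    founders: list[tuple[int, GOTerm]] = []
    for term in sorted(terms, key=lambda t: t.term_id):
        placed = False
        for cid, founder in founders:
            if levenshtein_norm_similarity(term.description, founder.description) > threshold:
                assignment[term.term_id] = cid
                placed = True
                break
        if not placed:
            cid = len(founders)
            founders.append((cid, term))
            assignment[term.term_id] = cid
    return GOClusterAssignment(
        assignment, {cid: t.term_id for cid, t in founders}
    )


def go_pair_jaccard(
    pair: PairKey,
    annotations: Mapping[str, Iterable[str]],
    assignment: GOClusterAssignment,
) -> float | None:
    """Jaccard index of the two proteins' GO-term clusters; None when both empty."""
    def clusters_of(pid: str) -> set[int]:
        return {
            assignment.term_to_cluster[t]
            for t in annotations.get(pid, ())
            if t in assignment.term_to_cluster
        }

    ca, cb = clusters_of(pair.id_a), clusters_of(pair.id_b)
    union = ca | cb
    if not union:
        return None
    return len(ca & cb) / len(union)


# ---------------------------------------------------------------------------
# File readers


def read_gaf_annotations(path: str | Path) -> dict[str, set[str]]:
    """Protein -> set of GO term ids from a GAF 2.x file (biopython parser)."""
    from Bio.UniProt import GOA

    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for rec in GOA.gafiterator(fh):
            out.setdefault(rec["DB_Object_ID"], set()).add(rec["GO_ID"])
    return out


def read_obo_terms(path: str | Path) -> list[GOTerm]:
    """GO term ids and names from an OBO 1.4 file (obonet)."""
    import obonet

    graph = obonet.read_obo(str(path))
    return [
        GOTerm(node, data.get("name", ""))
        for node, data in sorted(graph.nodes(data=True))
    ]


def read_cluster_tsv(path: str | Path, identity: float = 90.0, coverage: float = 0.9) -> list[SequenceCluster]:
    """TSV of (representative, member) rows into SequenceClusters."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", header=None, names=["representative", "member"])
    groups: dict[str, set[str]] = {}
    for r in df.itertuples():
        groups.setdefault(str(r.representative), set()).add(str(r.member))
    return [
        SequenceCluster(rep, frozenset(members), identity, coverage)
        for rep, members in sorted(groups.items())
    ]
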