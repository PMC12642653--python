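"""Canonical protein identities and unordered pair keys.

Every pair of proteins in the pipeline is addressed by a :class:`PairKey`
whose two accessions are stored in lexicographic order, so that (A, B) and
(B, A) always name the same object. Homodimers are representable but flagged,
because the screening set itself is restricted to heterodimers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import CapacityError

AMINO_ALPHABET = "ACDEFGHIKLMNPQRSTVWYXU"


@dataclass(frozen=True, order=True)
class PairKey:
    """Unordered protein pair in canonical (lexicographic) order."""

    id_a: str
    id_b: str

    def __post_init__(self) -> None:
        if self.id_a > self.id_b:
            raise ValueError(
                f"PairKey not canonical: {self.id_a!r} > {self.id_b!r}; use PairKey.of()"
            )

    @classmethod
    def of(cls, a: str, b: str) -> "PairKey":
        return cls(a, b) if a <= b else cls(b, a)

    @property
    def is_homodimer(self) -> bool:
        return self.id_a == self.id_b

    def other(self, pid: str) -> str:
        if pid == self.id_a:
            return self.id_b
        if pid == self.id_b:
            return self.id_a
        raise KeyError(f"{pid} is not a member of {self}")

    def __iter__(self):
        return iter((self.id_a, self.id_b))


@dataclass(frozen=True)
class ProteinRecord:
    """A proteome entry: accession, sequence and cached length."""

    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set(AMINO_ALPHABET)
        if bad:
            raise ValueError(f"{self.protein_id}: non-amino-acid letters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


def read_proteome_fasta(path: str | Path) -> list[ProteinRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord(rec.id, str(rec.seq).upper()))
    return records


def write_proteome_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.protein_id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def n_hetero_pairs(n_proteins: int) -> int:
    return n_proteins * (n_proteins - 1) // 2


def sample_unique_pairs(
    ids: Sequence[str],
    n: int,
    rng: np.random.Generator,
    exclude: frozenset[PairKey] | set[PairKey] = frozenset(),
) -> list[PairKey]:
    """Draw ``n`` distinct heterodimeric PairKeys uniformly without replacement.

    Deterministic for a given generator state. Raises :class:`CapacityError`
    when the universe (minus exclusions) cannot supply ``n`` pairs.
    """
    ids = sorted(set(ids))
    m = len(ids)
    total = n_hetero_pairs(m)
    if n > total - len(exclude):
        raise CapacityError(
            f"requested {n} unique pairs but only {total - len(exclude)} available"
        )
    if total <= 50_000_000:
        # Index the upper triangle directly: uniform without replacement in one draw.
        iu0, iu1 = np.triu_indices(m, k=1)
        order = rng.permutation(total)
        out: list[PairKey] = []
        arr = np.asarray(ids, dtype=object)
        for k in order:
            pk = PairKey(arr[iu0[k]], arr[iu1[k]])
            if pk in exclude:
                continue
            out.append(pk)
            if len(out) == n:
                break
        return out
    # Rejection sampling for very large universes.
    seen: set[PairKey] = set(exclude)
    out = []
    while len(out) < n:
        batch = rng.integers(0, m, size=(max(2 * (n - len(out)), 1024), 2))
        for i, j in batch:
            if i == j:
                continue
            pk = PairKey.of(ids[i], ids[j])
            if pk in seen:
                continue
            seen.add(pk)
            out.append(pk)
            if len(out) == n:
                break
    return out
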