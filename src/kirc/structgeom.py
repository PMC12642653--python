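"""Geometry and confidence operations on multi-chain structures.

Implements the three structural predicates the triage pipeline relies on:

* interchain residue-residue contact counting (any heavy-atom distance
  strictly below 5 A; a chain pair "interacts" when >= 10 such residue pairs
  exist in at least one structure);
* crosslink consistency of a predicted complex (every reported crosslink's
  C-alpha/C-alpha distance strictly below 36 A);
* confident interchain residue pairs in a predicted-aligned-error (PAE)
  matrix, the basis of the contact-positive ("C+") call: a prediction is C+
  when any of its models has at least 5 interchain residue pairs whose PAE is
  symmetrically at or below the cutoff.

Structures are held in a light container (:class:`ComplexStructure`) so that
synthetic fixtures can be built directly; PDB/mmCIF files are read through
gemmi and converted. Hydrogens are ignored for contact counting and only the
first alternate location of each atom is kept.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    CrosslinkMappingError,
    EmptyChainError,
    ParameterError,
    ShapeMismatchError,
    UnknownChainError,
)

CONTACT_DISTANCE_A = 5.0
MIN_CONTACT_PAIRS = 10
CROSSLINK_DISTANCE_A = 36.0
MIN_CONFIDENT_PAIRS = 5
DEFAULT_PAE_CUTOFF_A = 8.0


@dataclass(frozen=True)
class Residue:
    """One modeled residue: 1-based index, 3-letter name, atoms as (name, x, y, z)."""

    index: int
    name: str
    atoms: tuple[tuple[str, float, float, float], ...]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"residue {self.name}{self.index} has no atoms")

    def ca(self) -> tuple[float, float, float] | None:
        for aname, x, y, z in self.atoms:
            if aname == "CA":
                return (x, y, z)
        return None


@dataclass(frozen=True)
class Chain:
    chain_id: str
    residues: tuple[Residue, ...]

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ComplexStructure:
    structure_id: str
    chains: tuple[Chain, ...]
    release_date: datetime.date | None = None

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise UnknownChainError(f"{self.structure_id}: no chain {chain_id!r}")

    @property
    def chain_ids(self) -> tuple[str, ...]:
        return tuple(c.chain_id for c in self.chains)


@dataclass(frozen=True)
class ContactSummary:
    chain_a: str
    chain_b: str
    contact_pairs: int


@dataclass(frozen=True)
class Crosslink:
    protein_a: str
    residue_a: int
    protein_b: str
    residue_b: int


@dataclass
class PAEPrediction:
    """A predicted-aligned-error matrix plus the chain lengths it concatenates."""

    model_id: str
    pae: np.ndarray
    chain_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        self.pae = np.asarray(self.pae, dtype=float)
        self.chain_lengths = tuple(int(n) for n in self.chain_lengths)
        n = sum(self.chain_lengths)
        if self.pae.shape != (n, n):
            raise ShapeMismatchError(
                f"{self.model_id}: PAE shape {self.pae.shape} != ({n}, {n}) "
                f"from chain lengths {self.chain_lengths}"
            )
        if np.any(self.pae < 0):
            raise ParameterError(f"{self.model_id}: negative PAE entries")


def _is_hydrogen(atom_name: str) -> bool:
    name = atom_name.strip()
    return bool(name) and name.lstrip("0123456789").startswith("H")


def _chain_heavy_atoms(chain: Chain) -> tuple[np.ndarray, np.ndarray]:
    """Heavy-atom coordinates and the residue index each atom belongs to."""
    coords, owners = [], []
    for ri, res in enumerate(chain.residues):
        for aname, x, y, z in res.atoms:
            if _is_hydrogen(aname):
                continue
            coords.append((x, y, z))
            owners.append(ri)
    return np.asarray(coords, dtype=float), np.asarray(owners, dtype=int)


def count_interchain_contacts(
    structure: ComplexStructure,
    chain_a: str,
    chain_b: str,
    cutoff: float = CONTACT_DISTANCE_A,
) -> ContactSummary:
    """Count residue pairs across two chains with ANY heavy-atom distance < cutoff.

    Each (residue in a, residue in b) pair counts at most once regardless of
    how many atom pairs fall under the cutoff. The boundary is strict: an atom
    pair at exactly ``cutoff`` does not count.
    """
    if chain_a == chain_b:
        raise ParameterError("chain_a and chain_b must be distinct")
    ca, cb = structure.chain(chain_a), structure.chain(chain_b)
    for c in (ca, cb):
        if len(c) == 0:
            raise EmptyChainError(f"{structure.structure_id}:{c.chain_id} has no residues")
    xa, ra = _chain_heavy_atoms(ca)
    xb, rb = _chain_heavy_atoms(cb)
    pairs: set[tuple[int, int]] = set()
    if len(xa) and len(xb):
        tree = cKDTree(xb)
        for ai, neighbours in enumerate(tree.query_ball_point(xa, r=cutoff)):
            if not neighbours:
                continue
            d = np.linalg.norm(xb[neighbours] - xa[ai], axis=1)
            for bi, dist in zip(neighbours, d):
                if dist < cutoff:  # strict boundary
                    pairs.add((ra[ai], rb[bi]))
    return ContactSummary(chain_a, chain_b, len(pairs))


def is_interacting_chain_pair(
    summary: ContactSummary, min_pairs: int = MIN_CONTACT_PAIRS
) -> bool:
    """True when the chain pair has at least ``min_pairs`` contacting residue pairs."""
    if min_pairs < 0:
        raise ParameterError("min_pairs must be non-negative")
    return summary.contact_pairs >= min_pairs


def crosslink_consistent(
    structure: ComplexStructure,
    links: Sequence[Crosslink],
    cutoff: float = CROSSLINK_DISTANCE_A,
    mode: str = "all",
    fraction: float | None = None,
    chain_map: Mapping[str, str] | None = None,
) -> bool:
    """Is the structure geometrically consistent with reported crosslinks?

    A link is satisfied when the C-alpha/C-alpha distance of its two residues
    is strictly below ``cutoff``. ``mode="all"`` (default) requires every link
    to be satisfied; ``mode="fraction"`` requires at least ``fraction`` of
    them. ``chain_map`` maps protein ids to chain ids; by default chain ids
    are taken to be the protein ids themselves.
    """
    if mode not in ("all", "fraction"):
        raise ParameterError(f"unknown mode {mode!r}")
    if mode == "fraction" and fraction is None:
        raise ParameterError("mode='fraction' requires a fraction")
    if not links:
        return True

    def resolve(pid: str, residue: int, link: Crosslink) -> np.ndarray:
        cid = chain_map.get(pid, pid) if chain_map else pid
        try:
            chain = structure.chain(cid)
        except UnknownChainError as exc:
            raise CrosslinkMappingError(f"cannot resolve {link}: {exc}") from exc
        if not (1 <= residue <= len(chain)):
            raise CrosslinkMappingError(
                f"cannot resolve {link}: residue {residue} outside chain {cid}"
            )
        ca = chain.residues[residue - 1].ca()
        if ca is None:
            raise CrosslinkMappingError(f"cannot resolve {link}: residue lacks CA atom")
        return np.asarray(ca)

    n_ok = 0
    for link in links:
        a = resolve(link.protein_a, link.residue_a, link)
        b = resolve(link.protein_b, link.residue_b, link)
        if float(np.linalg.norm(a - b)) < cutoff:
            n_ok += 1
    if mode == "all":
        return n_ok == len(links)
    return n_ok / len(links) >= fraction


def count_confident_interchain_pairs(pred: PAEPrediction, pae_cutoff: float) -> int:
    """Interchain residue pairs whose PAE is <= cutoff in BOTH directions.

    Requires exactly two chains; intra-chain cells are ignored.
    """
    if len(pred.chain_lengths) != 2:
        raise ParameterError(
            f"{pred.model_id}: expected 2 chains, got {len(pred.chain_lengths)}"
        )
    n1 = pred.chain_lengths[0]
    ab = pred.pae[:n1, n1:]
    ba = pred.pae[n1:, :n1].T
    return int(np.sum((ab <= pae_cutoff) & (ba <= pae_cutoff)))


def is_contact_positive(
    preds: Sequence[PAEPrediction],
    min_pairs: int = MIN_CONFIDENT_PAIRS,
    pae_cutoff: float = DEFAULT_PAE_CUTOFF_A,
) -> bool:
    """C+ call: any model has >= ``min_pairs`` confident interchain residue pairs."""
    if not preds:
        raise ParameterError("no predictions supplied")
    if len(preds) > 5:
        raise ParameterError("at most 5 models per pair expected")
    return any(
        count_confident_interchain_pairs(p, pae_cutoff) >= min_pairs for p in preds
    )


def translate(structure: ComplexStructure, dx: float, dy: float, dz: float) -> ComplexStructure:
    """Rigidly translate a whole structure (used by invariance checks)."""
    chains = tuple(
        Chain(
            c.chain_id,
            tuple(
                Residue(
                    r.index,
                    r.name,
                    tuple((n, x + dx, y + dy, z + dz) for n, x, y, z in r.atoms),
                )
                for r in c.residues
            ),
        )
        for c in structure.chains
    )
    return ComplexStructure(structure.structure_id, chains, structure.release_date)


# ---------------------------------------------------------------------------
# File I/O


def load_structure(path: str | Path, structure_id: str | None = None) -> ComplexStructure:
    """Read a PDB or mmCIF file into a :class:`ComplexStructure` via gemmi.

    Keeps the first model and the first alternate location of each atom;
    residues are renumbered sequentially (1-based) over modeled residues.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    chains = []
    for ch in model:
        residues = []
        for idx, res in enumerate(ch, start=1):
            atoms = []
            seen: set[str] = set()
            for atom in res:
                if atom.name in seen:  # keep first altloc only
                    continue
                seen.add(atom.name)
                atoms.append((atom.name, atom.pos.x, atom.pos.y, atom.pos.z))
            if atoms:
                residues.append(Residue(idx, res.name, tuple(atoms)))
        chains.append(Chain(ch.name, tuple(residues)))
    date = None
    try:
        raw = st.info.get("_pdbx_database_status.recvd_initial_deposition_date", "")
        if raw:
            date = datetime.date.fromisoformat(raw)
    except Exception:
        date = None
    return ComplexStructure(structure_id or st.name or Path(path).stem, tuple(chains), date)


def write_structure_pdb(structure: ComplexStructure, path: str | Path) -> None:
    """Write a :class:`ComplexStructure` as a PDB file via gemmi."""
    import gemmi

    st = gemmi.Structure()
    st.name = structure.structure_id
    model = gemmi.Model("1")
    for ch in structure.chains:
        chain = gemmi.Chain(ch.chain_id)
        for res in ch.residues:
            r = gemmi.Residue()
            r.name = res.name
            r.seqid = gemmi.SeqId(res.index, " ")
            for aname, x, y, z in res.atoms:
                a = gemmi.Atom()
                a.name = aname
                a.element = gemmi.Element(aname[:1])
                a.pos = gemmi.Position(x, y, z)
                r.add_atom(a)
            chain.add_residue(r)
        model.add_chain(chain)
    st.add_model(model)
    st.write_pdb(str(path))


def load_pae(
    path: str | Path,
    chain_lengths: Sequence[int],
    model_id: str | None = None,
) -> PAEPrediction:
    """Read a PAE matrix from JSON (ColabFold dialect).

    Accepts a top-level object (or one-element list of objects) holding the
    matrix under ``"pae"`` or ``"predicted_aligned_error"``.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if isinstance(doc, list):
        if not doc:
            raise ShapeMismatchError(f"{path}: empty JSON list")
        doc = doc[0]
    matrix = doc.get("pae", doc.get("predicted_aligned_error"))
    if matrix is None:
        raise ShapeMismatchError(
            f"{path}: no 'pae' or 'predicted_aligned_error' key"
        )
    return PAEPrediction(model_id or Path(path).stem, np.asarray(matrix), tuple(chain_lengths))


def write_pae(pred: PAEPrediction, path: str | Path) -> None:
    doc = {
        "pae": [[round(float(v), 2) for v in row] for row in pred.pae],
        "chain_lengths": list(pred.chain_lengths),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, separators=(",", ":"), sort_keys=True)


def read_crosslinks_tsv(path: str | Path) -> list[Crosslink]:
    """TSV with columns protein_a, residue_a, protein_b, residue_b."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return [
        Crosslink(str(r.protein_a), int(r.residue_a), str(r.protein_b), int(r.residue_b))
        for r in df.itertuples()
    ]
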