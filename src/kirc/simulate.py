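"""Planted-interactome fixture generation.

Everything the pipeline consumes can be generated synthetically with a known
ground truth: a random proteome, a planted set of true interaction pairs, and
omics stores in which true pairs carry signal — correlated profile vectors
(a shared latent component raises their cosine similarity), elevated database
evidence counts, high association scores — while non-pairs are independent
background. Structures are planted with an exact number of interchain residue
contacts, PAE matrices with an exact number of confident interchain cells,
and annotation files (alignments, sequence clusters, GO, crosslinks) are
self-consistent with the planted truth.

Geometry is schematic by design: chains are beads on 20 A grids so that the
distance predicates (<5 A contact, <36 A crosslink) hold or fail by large
margins, which is all the downstream operations observe.

Determinism: every artifact draws from a generator seeded by stable hashing
of (master seed, artifact name), so regeneration from the same spec is
byte-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import derive_seed, rng_for, stable_digest
from .errors import ParameterError
from .features import (
    FeatureRegistry,
    PairScoreStore,
    ScalarStore,
    VectorStore,
    avg_missense_profile,
    cofrac_row_stats,
    coexpression_top_k,
    default_registry,
    scale_disgenet,
)
from .pairs import (
    AMINO_ALPHABET,
    PairKey,
    ProteinRecord,
    n_hetero_pairs,
    sample_unique_pairs,
    write_proteome_fasta,
)
from .refsets import Evidence, EvidenceTable
from .structgeom import (
    Chain,
    ComplexStructure,
    Crosslink,
    PAEPrediction,
    Residue,
    count_interchain_contacts,
    write_pae,
    write_structure_pdb,
)

RESIDUE_NAMES = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)
_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for a planted interactome."""

    seed: int
    n_proteins: int = 200
    length_range: tuple[int, int] = (50, 200)
    n_true_pairs: int = 50
    latent_weight: float = 0.9          # shared-component weight for true-pair vectors
    biogrid_true_lambda: float = 3.0    # true-pair counts ~ 1 + Poisson(lambda)
    biogrid_noise_rate: float = 0.01    # fraction of all pairs given a stray count
    intact_true_lambda: float = 1.2
    string_true_range: tuple[int, int] = (400, 1000)
    rf2ppi_true_beta: tuple[float, float] = (6.0, 2.0)
    rf2ppi_false_beta: tuple[float, float] = (2.0, 6.0)
    cofrac_n_experiments: int = 10
    cofrac_missing_rate: float = 0.2
    depmap_dim: int = 1095
    orcs_dim: int = 1243
    proteomehd_dim: int = 294
    embedding_dim: int = 1024
    localization_dim: int = 10

    def __post_init__(self) -> None:
        if self.n_true_pairs > n_hetero_pairs(self.n_proteins):
            raise ParameterError("n_true_pairs exceeds heterodimeric capacity")


@dataclass
class PlantedInteractome:
    spec: FixtureSpec
    proteome: list[ProteinRecord]
    true_pairs: set[PairKey]
    stores: dict[str, object]
    evidence: EvidenceTable
    registry: FeatureRegistry

    @property
    def protein_ids(self) -> list[str]:
        return [p.protein_id for p in self.proteome]


def generate_proteome(
    n: int, length_range: tuple[int, int], seed: int
) -> list[ProteinRecord]:
    """Random sequences with ids P000001... over the 20-letter alphabet."""
    if n == 0:
        warnings.warn("empty proteome requested")
        return []
    rng = rng_for(seed, "proteome")
    lo, hi = length_range
    records = []
    for i in range(1, n + 1):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(list(_AA20), size=length))
        records.append(ProteinRecord(f"P{i:06d}", seq))
    return records


def _mix_vectors(base: dict[str, np.ndarray], true_pairs: Sequence[PairKey], w: float) -> None:
    """Give each true pair a shared latent component (in place)."""
    for pair in sorted(true_pairs):
        va, vb = base[pair.id_a], base[pair.id_b]
        base[pair.id_b] = np.sqrt(max(1.0 - w * w, 0.0)) * vb + w * va


def plant_feature_signal(
    spec: FixtureSpec,
    proteome: Sequence[ProteinRecord],
    true_pairs: set[PairKey],
) -> tuple[dict[str, object], EvidenceTable]:
    """Build every omics store with planted signal for the true pairs."""
    ids = [p.protein_id for p in proteome]
    w = spec.latent_weight
    stores: dict[str, object] = {}

    # Real-valued profile stores: shared latent component for true pairs.
    for name, dim in (
        ("depmap", spec.depmap_dim),
        ("proteomehd", spec.proteomehd_dim),
        ("embeddings", spec.embedding_dim),
    ):
        rng = rng_for(spec.seed, "store", name)
        base = {pid: rng.standard_normal(dim) for pid in ids}
        _mix_vectors(base, sorted(true_pairs), w)
        store = VectorStore(name, dim)
        for pid in ids:
            store.put(pid, base[pid])
        stores[name] = store

    # Binary CRISPR-screen hit vectors: true pairs copy bits with prob w.
    rng = rng_for(spec.seed, "store", "orcs")
    bits = {pid: (rng.random(spec.orcs_dim) < 0.05).astype(float) for pid in ids}
    for pair in sorted(true_pairs):
        copy_mask = rng.random(spec.orcs_dim) < w
        bits[pair.id_b] = np.where(copy_mask, bits[pair.id_a], bits[pair.id_b])
    orcs = VectorStore("orcs", spec.orcs_dim)
    for pid in ids:
        orcs.put(pid, bits[pid])
    stores["orcs"] = orcs

    # Compartment probabilities: true pairs pulled toward the same compartment.
    rng = rng_for(spec.seed, "store", "localization")
    loc = {pid: rng.dirichlet(np.full(spec.localization_dim, 0.5)) for pid in ids}
    for pair in sorted(true_pairs):
        mixed = w * loc[pair.id_a] + (1.0 - w) * loc[pair.id_b]
        loc[pair.id_b] = mixed / mixed.sum()
    locstore = VectorStore("localization", spec.localization_dim)
    for pid in ids:
        locstore.put(pid, loc[pid])
    stores["localization"] = locstore

    # Per-protein scalars.
    rng = rng_for(spec.seed, "store", "scalars")
    stores["abundance"] = ScalarStore(
        "abundance", {pid: float(rng.lognormal(2.0, 1.0)) for pid in ids}
    )
    stores["cluster_size"] = ScalarStore(
        "cluster_size", {pid: float(rng.integers(1, 200)) for pid in ids}
    )
    stores["cluster_plddt"] = ScalarStore(
        "cluster_plddt", {pid: float(rng.uniform(50, 95)) for pid in ids}
    )
    missense = ScalarStore("missense_mean")
    for p in proteome:
        profile = rng.uniform(0, 100, size=(p.length, 19))
        missense.entries[p.protein_id] = float(avg_missense_profile(profile).mean())
    stores["missense_mean"] = missense

    # Pair evidence: counts, association channels, co-fractionation statistics.
    rng = rng_for(spec.seed, "store", "evidence")
    biogrid = PairScoreStore("biogrid")
    intact = PairScoreStore("intact")
    s_phys = PairScoreStore("string_physical")
    s_comb = PairScoreStore("string_combined")
    disgenet = PairScoreStore("disgenet")
    rf2ppi = PairScoreStore("rf2ppi")
    cofrac = {k: PairScoreStore(f"cofrac_{k}") for k in ("mean", "median", "max")}

    def put_cofrac(pair: PairKey, mu: float) -> None:
        row = rng.normal(mu, 0.15, size=spec.cofrac_n_experiments)
        row[rng.random(spec.cofrac_n_experiments) < spec.cofrac_missing_rate] = np.nan
        mean, median, mx = cofrac_row_stats(list(row))
        if mean is not None:
            cofrac["mean"].put(pair, mean)
            cofrac["median"].put(pair, median)
            cofrac["max"].put(pair, mx)

    for pair in sorted(true_pairs):
        biogrid.put(pair, 1.0 + float(rng.poisson(spec.biogrid_true_lambda)))
        intact.put(pair, float(rng.poisson(spec.intact_true_lambda)))
        lo, hi = spec.string_true_range
        phys = int(rng.integers(lo, hi))
        s_phys.put(pair, phys)
        s_comb.put(pair, min(phys + int(rng.integers(0, 50)), 1000))
        disgenet.put(pair, scale_disgenet(float(rng.uniform(0.3, 1.0))))
        a, b = spec.rf2ppi_true_beta
        rf2ppi.put(pair, float(rng.beta(a, b)))
        put_cofrac(pair, 0.6)

    # Background noise on a sample of non-pairs.
    n_noise = int(spec.biogrid_noise_rate * n_hetero_pairs(len(ids)))
    if n_noise:
        noise_pairs = sample_unique_pairs(
            ids, n_noise, rng_for(spec.seed, "noise-pairs"), exclude=frozenset(true_pairs)
        )
        for pair in noise_pairs:
            biogrid.put(pair, float(rng.integers(1, 3)))
            a, b = spec.rf2ppi_false_beta
            rf2ppi.put(pair, float(rng.beta(a, b)))
            put_cofrac(pair, 0.1)
            if rng.random() < 0.1:
                s_comb.put(pair, int(rng.integers(600, 900)))

    for key, store in (
        ("biogrid", biogrid), ("intact", intact), ("string_physical", s_phys),
        ("string_combined", s_comb), ("disgenet", disgenet), ("rf2ppi", rf2ppi),
        ("cofrac_mean", cofrac["mean"]), ("cofrac_median", cofrac["median"]),
        ("cofrac_max", cofrac["max"]),
    ):
        stores[key] = store

    # Co-expression: true pairs ranked high, passed through top-k retention.
    rng = rng_for(spec.seed, "store", "coexpression")
    coexpr_scores: dict[str, list[tuple[str, float]]] = {pid: [] for pid in ids}
    for pair in sorted(true_pairs):
        s = float(rng.uniform(5.0, 10.0))
        coexpr_scores[pair.id_a].append((pair.id_b, s))
    for pid in ids:
        partners = rng.choice(len(ids), size=5, replace=False)
        for j in partners:
            if ids[j] != pid:
                coexpr_scores[pid].append((ids[j], float(rng.uniform(0.0, 3.0))))
    stores["coexpression"] = coexpression_top_k(coexpr_scores, k=500)

    evidence = EvidenceTable()
    for pair in set(biogrid.entries) | set(intact.entries) | set(s_comb.entries):
        evidence[pair] = Evidence(
            int(intact.get(pair) or 0),
            int(biogrid.get(pair) or 0),
            int(s_phys.get(pair) or 0),
            int(s_comb.get(pair) or 0),
        )
    return stores, evidence


def generate_interactome(spec: FixtureSpec) -> PlantedInteractome:
    """Generate the full planted interactome in memory."""
    proteome = generate_proteome(spec.n_proteins, spec.length_range, spec.seed)
    ids = [p.protein_id for p in proteome]
    true_pairs = set(
        sample_unique_pairs(ids, spec.n_true_pairs, rng_for(spec.seed, "true-pairs"))
    )
    stores, evidence = plant_feature_signal(spec, proteome, true_pairs)
    registry = default_registry(stores.keys())
    return PlantedInteractome(spec, proteome, true_pairs, stores, evidence, registry)


# ---------------------------------------------------------------------------
# Structures, PAE matrices, annotation files


def generate_contact_structure(
    id_a: str,
    id_b: str,
    k_contacts: int,
    seed: int,
    n_residues: int | None = None,
    extra_chain: str | None = None,
) -> ComplexStructure:
    """Two-chain bead structure with EXACTLY ``k_contacts`` residue pairs < 5 A.

    Residues sit on a 20 A grid; the first ``k_contacts`` residues of chain B
    are placed 3 A from their chain-A counterparts, the rest 1000 A away. An
    optional third chain (never in contact) supports decoy construction. The
    planted count is verified against the contact-counting oracle.
    """
    if k_contacts < 0:
        raise ParameterError("k_contacts must be non-negative")
    rng = rng_for(seed, "structure", id_a, id_b, k_contacts)
    n = n_residues or max(12, k_contacts + 2)
    if k_contacts > n:
        raise ParameterError("k_contacts exceeds chain length")

    def bead(index: int, x: float, y: float, z: float) -> Residue:
        name = RESIDUE_NAMES[int(rng.integers(0, 20))]
        jx, jy, jz = rng.uniform(-0.1, 0.1, size=3)
        return Residue(index, name, (
            ("CA", x + jx, y + jy, z + jz),
            ("CB", x + jx, y + jy + (1.2 if y <= 0 else -1.2), z + jz),
        ))

    chain_a = Chain("A", tuple(bead(i + 1, 20.0 * i, 0.0, 0.0) for i in range(n)))
    b_res = []
    for i in range(n):
        if i < k_contacts:
            b_res.append(bead(i + 1, 20.0 * i, 3.0, 0.0))
        else:
            b_res.append(bead(i + 1, 20.0 * i, 1000.0, 0.0))
    chain_b = Chain("B", tuple(b_res))
    chains = [chain_a, chain_b]
    if extra_chain is not None:
        chains.append(
            Chain("C", tuple(bead(i + 1, 20.0 * i, -1000.0, 0.0) for i in range(n)))
        )
    st = ComplexStructure(f"synth_{id_a}_{id_b}", tuple(chains))
    planted = count_interchain_contacts(st, "A", "B").contact_pairs
    if planted != k_contacts:
        raise RuntimeError(
            f"planted geometry produced {planted} contacts, wanted {k_contacts}"
        )
    return st


def generate_pae(
    n1: int,
    n2: int,
    n_confident: int,
    pae_cutoff: float,
    seed: int,
    model_id: str = "model_1",
) -> PAEPrediction:
    """PAE matrix with exactly ``n_confident`` symmetric low-PAE interchain cells."""
    if n_confident > n1 * n2:
        raise ParameterError("n_confident exceeds interchain cell count")
    rng = rng_for(seed, "pae", model_id, n_confident)
    n = n1 + n2
    mat = rng.uniform(pae_cutoff + 5.0, 30.0, size=(n, n))
    # realistic low intra-chain error
    mat[:n1, :n1] = rng.uniform(1.0, 4.0, size=(n1, n1))
    mat[n1:, n1:] = rng.uniform(1.0, 4.0, size=(n2, n2))
    flat = rng.choice(n1 * n2, size=n_confident, replace=False)
    for k in flat:
        i, j = divmod(int(k), n2)
        v = rng.uniform(1.0, pae_cutoff)
        mat[i, n1 + j] = v
        mat[n1 + j, i] = rng.uniform(1.0, pae_cutoff)
    np.fill_diagonal(mat, 0.0)
    return PAEPrediction(model_id, mat, (n1, n2))


def generate_crosslinks(
    structure: ComplexStructure,
    id_a: str,
    id_b: str,
    n_links: int,
    violation_fraction: float,
    seed: int,
) -> list[Crosslink]:
    """Crosslinks sampled from a planted structure.

    Satisfied links join contacting bead pairs (CA-CA distance 3 A); violating
    links join the far-apart region (1000 A), so the <36 A predicate fails.
    """
    rng = rng_for(seed, "crosslinks", id_a, id_b)
    chain_a, chain_b = structure.chains[0], structure.chains[1]
    close = [
        i for i in range(min(len(chain_a), len(chain_b)))
        if abs(chain_b.residues[i].ca()[1] - chain_a.residues[i].ca()[1]) < 36.0
    ]
    far = [
        i for i in range(min(len(chain_a), len(chain_b)))
        if abs(chain_b.residues[i].ca()[1] - chain_a.residues[i].ca()[1]) >= 36.0
    ]
    n_bad = int(round(violation_fraction * n_links))
    n_good = n_links - n_bad
    if n_good > len(close) or n_bad > len(far):
        raise ParameterError("structure cannot supply the requested link mix")
    links = []
    for i in rng.choice(close, size=n_good, replace=False) if n_good else []:
        links.append(Crosslink(id_a, int(i) + 1, id_b, int(i) + 1))
    for i in rng.choice(far, size=n_bad, replace=False) if n_bad else []:
        links.append(Crosslink(id_a, int(i) + 1, id_b, int(i) + 1))
    return links


GO_DESCRIPTION_TEMPLATES = (
    "protein kinase activity",
    "dna replication initiation",
    "microtubule organizing center assembly",
    "ubiquitin ligase complex",
    "ribosome biogenesis",
    "membrane transport regulation",
    "chromatin remodeling complex",
    "rna splicing factor activity",
)


def generate_go_fixtures(
    proteome: Sequence[ProteinRecord],
    true_pairs: set[PairKey],
    seed: int,
    share_prob: float = 0.7,
) -> tuple[list, dict[str, set[str]]]:
    """GO terms with template-derived descriptions plus per-protein annotations.

    Terms come in near-duplicate description families (edit similarity > 0.75
    within a family, far below across families); true pairs share annotation
    terms with probability ``share_prob``.
    """
    from .annotation import GOTerm

    rng = rng_for(seed, "go")
    terms: list[GOTerm] = []
    k = 0
    for tmpl in GO_DESCRIPTION_TEMPLATES:
        for variant in (tmpl, tmpl + "s"):
            k += 1
            terms.append(GOTerm(f"GO:{k:07d}", variant))
    term_ids = [t.term_id for t in terms]
    annotations: dict[str, set[str]] = {}
    for p in proteome:
        n_terms = int(rng.integers(1, 4))
        annotations[p.protein_id] = set(rng.choice(term_ids, size=n_terms, replace=False))
    for pair in sorted(true_pairs):
        if rng.random() < share_prob:
            shared = str(rng.choice(sorted(annotations[pair.id_a])))
            annotations[pair.id_b].add(shared)
    return terms, annotations


def generate_sequence_clusters(
    proteome: Sequence[ProteinRecord], seed: int, n_multi: int = 10
) -> list:
    """Partition of the proteome into clusters: ``n_multi`` doubletons + singletons."""
    from .annotation import SequenceCluster

    rng = rng_for(seed, "clusters")
    ids = sorted(p.protein_id for p in proteome)
    order = rng.permutation(len(ids))
    clusters = []
    used = 0
    for _ in range(n_multi):
        if used + 2 > len(ids):
            break
        members = frozenset(ids[i] for i in order[used:used + 2])
        clusters.append(SequenceCluster(min(members), members))
        used += 2
    for i in order[used:]:
        clusters.append(SequenceCluster(ids[i], frozenset([ids[i]])))
    return clusters


def generate_alignment_table(
    proteome: Sequence[ProteinRecord], clusters: Sequence, seed: int
) -> pd.DataFrame:
    """Blast-tab hits consistent with the planted clusters.

    Every protein has a perfect self-hit; cluster co-members align at ~95%
    identity, so the planted homolog is always the best non-self hit.
    """
    rng = rng_for(seed, "alignments")
    lengths = {p.protein_id: p.length for p in proteome}
    rows = []
    for p in proteome:
        rows.append((p.protein_id, p.protein_id, 100.0, p.length, 0, 0,
                     1, p.length, 1, p.length, 1e-50, p.length * 2.0))
    for cl in clusters:
        members = sorted(cl.members)
        for a in members:
            for b in members:
                if a == b:
                    continue
                aln = min(lengths[a], lengths[b])
                rows.append((a, b, round(float(rng.uniform(92, 98)), 1), aln, 2, 0,
                             1, aln, 1, aln, 1e-30, aln * 1.8))
    return pd.DataFrame(rows, columns=[
        "query", "target", "pident", "alnlen", "mismatch", "gapopen",
        "qstart", "qend", "tstart", "tend", "evalue", "bits",
    ])


# ---------------------------------------------------------------------------
# Fixture tree writer


def write_fixture_tree(interactome: PlantedInteractome, out_dir: str | Path) -> None:
    """Write the complete fixture tree in the dialects the ingest code reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = interactome.spec

    write_proteome_fasta(interactome.proteome, out / "proteome.fasta")
    pd.DataFrame(
        sorted((p.id_a, p.id_b) for p in interactome.true_pairs),
        columns=["id_a", "id_b"],
    ).to_csv(out / "true_pairs.tsv", sep="\t", index=False)

    stores_dir = out / "stores"
    stores_dir.mkdir(exist_ok=True)
    for name, store in sorted(interactome.stores.items()):
        store.to_json(stores_dir / f"{name}.json")
    interactome.evidence.write_tsv(out / "evidence.tsv")

    clusters = generate_sequence_clusters(interactome.proteome, spec.seed)
    pd.DataFrame(
        sorted((cl.representative, m) for cl in clusters for m in cl.members)
    ).to_csv(out / "clusters.tsv", sep="\t", index=False, header=False)
    generate_alignment_table(interactome.proteome, clusters, spec.seed).to_csv(
        out / "alignments.tsv", sep="\t", index=False
    )

    terms, annotations = generate_go_fixtures(
        interactome.proteome, interactome.true_pairs, spec.seed
    )
    go_dir = out / "go"
    go_dir.mkdir(exist_ok=True)
    with open(go_dir / "terms.obo", "w") as fh:
        fh.write("format-version: 1.4\n")
        for t in terms:
            fh.write(f"\n[Term]\nid: {t.term_id}\nname: {t.description}\n")
    with open(go_dir / "annotations.gaf", "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for pid in sorted(annotations):
            for term in sorted(annotations[pid]):
                cols = ["UniProtKB", pid, pid, "", term, "GO_REF:0000001", "IEA",
                        "", "P", "", "", "protein", "taxon:9606", "20250101",
                        "SYNTH", "", ""]
                fh.write("\t".join(cols) + "\n")

    # Structures + PAE + crosslinks for the first few true pairs.
    st_dir = out / "structures"
    pae_dir = out / "pae"
    st_dir.mkdir(exist_ok=True)
    pae_dir.mkdir(exist_ok=True)
    xl_rows = []
    for pair in sorted(interactome.true_pairs)[:10]:
        st = generate_contact_structure(pair.id_a, pair.id_b, 12, spec.seed)
        name = f"{pair.id_a}__{pair.id_b}"
        pair_dir = pae_dir / name
        pair_dir.mkdir(exist_ok=True)
        write_structure_pdb(st, st_dir / f"{name}.pdb")
        n1, n2 = len(st.chains[0]), len(st.chains[1])
        for k in range(1, 4):
            pred = generate_pae(n1, n2, 8, 8.0, derive_seed(spec.seed, name, k),
                                model_id=f"model_{k}")
            write_pae(pred, pair_dir / f"model_{k}.pae.json")
        for link in generate_crosslinks(st, pair.id_a, pair.id_b, 3, 0.0, spec.seed):
            xl_rows.append((link.protein_a, link.residue_a, link.protein_b, link.residue_b))
    pd.DataFrame(xl_rows, columns=["protein_a", "residue_a", "protein_b", "residue_b"]).to_csv(
        out / "crosslinks.tsv", sep="\t", index=False
    )
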