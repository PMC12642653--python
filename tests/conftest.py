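import numpy as np
import pytest

from kirc.pairs import PairKey
from kirc.simulate import FixtureSpec, generate_interactome
from kirc.structgeom import Chain, ComplexStructure, Residue


def random_two_chain_structure(rng: np.random.Generator, max_res: int = 15) -> ComplexStructure:
    """A random two-chain structure with 1-3 atoms per residue in a 30 A box."""
    def chain(cid: str) -> Chain:
        n = int(rng.integers(3, max_res + 1))
        residues = []
        for i in range(n):
            n_atoms = int(rng.integers(1, 4))
            atoms = tuple(
                (name, *map(float, rng.uniform(0, 30, size=3)))
                for name in ("CA", "CB", "CG")[:n_atoms]
            )
            residues.append(Residue(i + 1, "ALA", atoms))
        return Chain(cid, tuple(residues))

    return ComplexStructure("random", (chain("A"), chain("B")))


def brute_force_contacts(structure: ComplexStructure, chain_a: str, chain_b: str,
                         cutoff: float = 5.0) -> int:
    """O(atoms^2) independent oracle for interchain residue-pair contacts."""
    ca, cb = structure.chain(chain_a), structure.chain(chain_b)
    count = 0
    for ra in ca.residues:
        for rb in cb.residues:
            hit = False
            for _, xa, ya, za in ra.atoms:
                for _, xb, yb, zb in rb.atoms:
                    d = ((xa - xb) ** 2 + (ya - yb) ** 2 + (za - zb) ** 2) ** 0.5
                    if d < cutoff:
                        hit = True
            if hit:
                count += 1
    return count


@pytest.fixture(scope="session")
def small_interactome():
    """A 60-protein planted interactome shared across module tests."""
    return generate_interactome(FixtureSpec(seed=7, n_proteins=60, n_true_pairs=20))


@pytest.fixture(scope="session")
def demo_screen_result():
    """The full fixture-scale end-to-end screen (200 proteins, 50 true pairs)."""
    from kirc.pipeline import run_demo_screen

    return run_demo_screen(seed=11)


def pair(a: str, b: str) -> PairKey:
    return PairKey.of(a, b)
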