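"""Shared fixtures: small peptide graphs, conformers and graph builders."""

import numpy as np
import pytest
from rdkit import Chem

from cppspace.structures import (MolecularGraph, PeptideSequence,
                                 build_peptide_graph, generate_conformer,
                                 topological_distances)

PENETRATIN_SEQ = "RQIKIWFQNRRMKWKK"


def graph_from_smiles(smiles: str, name: str = "mol") -> MolecularGraph:
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    return MolecularGraph(id=name, mol=mol)


def bare_carbon_graph(n: int) -> MolecularGraph:
    """A chain of n carbons with no hydrogens at all (radical centers)."""
    rw = Chem.RWMol()
    for _ in range(n):
        a = Chem.Atom(6)
        a.SetNoImplicit(True)
        rw.AddAtom(a)
    for i in range(n - 1):
        rw.AddBond(i, i + 1, Chem.BondType.SINGLE)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_FINDRADICALS)
    return MolecularGraph(id=f"C{n}", mol=mol)


def random_connected_distance_matrix(rng: np.random.Generator, n: int):
    """Topological distance matrix of a random connected graph on n nodes.

    Built from a random spanning tree plus a few extra edges; distances via
    breadth-first search (independent of any package code path).
    """
    edges = set()
    order = rng.permutation(n)
    for i in range(1, n):
        j = order[rng.integers(0, i)]
        edges.add(tuple(sorted((int(order[i]), int(j)))))
    for _ in range(rng.integers(0, n)):
        a, b = rng.integers(0, n, 2)
        if a != b:
            edges.add(tuple(sorted((int(a), int(b)))))
    adj = {i: [] for i in range(n)}
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    d = np.full((n, n), -1, dtype=int)
    for src in range(n):
        d[src, src] = 0
        queue = [src]
        while queue:
            cur = queue.pop(0)
            for nb in adj[cur]:
                if d[src, nb] < 0:
                    d[src, nb] = d[src, cur] + 1
                    queue.append(nb)
    return d


@pytest.fixture(scope="session")
def gly_graph():
    return build_peptide_graph(PeptideSequence("G", "G"))


@pytest.fixture(scope="session")
def gg_graph():
    return build_peptide_graph(PeptideSequence("GG", "GG"))


@pytest.fixture(scope="session")
def gg_conformer(gg_graph):
    return generate_conformer(gg_graph, seed=11)


@pytest.fixture(scope="session")
def asn_graph():
    return build_peptide_graph(PeptideSequence("N", "N"))


@pytest.fixture(scope="session")
def residue_graphs():
    """All 20 free amino-acid graphs with their distance matrices."""
    out = {}
    for aa in "ACDEFGHIKLMNPQRSTVWY":
        g = build_peptide_graph(PeptideSequence(aa, aa))
        out[aa] = (g, topological_distances(g))
    return out
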