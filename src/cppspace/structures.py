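"""Peptide structures: sequences, molecular graphs, conformers, distances.

Linear peptides are built from one-letter sequences as neutral, hydrogen-
explicit molecules with free amine/free acid termini (the most fundamental,
non-amidated form).  Residues are condensed with loss of one water per amide
bond, so the molecular formula of an n-mer equals the sum of the residue
formulas minus (n-1)*H2O.  3D conformers come from seeded distance-geometry
embedding followed by MMFF force-field minimization; 3D descriptor values are
therefore conformer-dependent and not comparable bit-for-bit with values from
other geometry engines, which is why downstream checks are property-based.

Topological distances are bond-count shortest paths over the hydrogen-depleted
graph, the domain of the 2D descriptor families.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, TextIO

import numpy as np
from Bio import SeqIO
from rdkit import Chem
from rdkit.Chem import AllChem

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


class SequenceError(ValueError):
    """Raised for malformed sequence input."""


class StructureError(ValueError):
    """Raised when a molecular structure cannot be built or embedded."""


@dataclass(frozen=True)
class PeptideSequence:
    """A linear peptide in one-letter code with free termini by default."""

    id: str
    residues: str
    n_terminus_free: bool = True
    c_terminus_free: bool = True

    def __post_init__(self):
        if len(self.residues) < 1:
            raise SequenceError(f"{self.id}: empty sequence")
        for pos, aa in enumerate(self.residues, start=1):
            if aa not in STANDARD_AA:
                raise SequenceError(
                    f"record {self.id!r}: non-standard residue {aa!r} at "
                    f"position {pos}; non-standard monomers must be "
                    f"supplied as SDF"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class MolecularGraph:
    """Hydrogen-explicit molecular graph of one peptide.

    Wraps an RDKit Mol; ``residue_of_atom`` maps atom index to 0-based
    residue index (-1 where unknown, e.g. for SDF imports without residue
    annotation).
    """

    id: str
    mol: Chem.Mol
    residue_of_atom: dict[int, int] = field(default_factory=dict)

    @property
    def n_atoms(self) -> int:
        return self.mol.GetNumAtoms()

    @property
    def elements(self) -> list[str]:
        return [a.GetSymbol() for a in self.mol.GetAtoms()]

    @property
    def formula(self) -> str:
        from rdkit.Chem.rdMolDescriptors import CalcMolFormula

        return CalcMolFormula(self.mol)

    def heavy_atom_indices(self) -> list[int]:
        return [a.GetIdx() for a in self.mol.GetAtoms() if a.GetAtomicNum() > 1]

    def heavy_mol(self) -> Chem.Mol:
        return Chem.RemoveHs(self.mol)


@dataclass
class Conformer:
    """3D coordinates (Å) aligned to the MolecularGraph atom order."""

    coordinates: np.ndarray  # (n_atoms, 3)
    method: str = "ETKDGv3+MMFF94"
    seed: int = 0

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise StructureError("coordinates must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise StructureError("non-finite conformer coordinates")


@dataclass
class TopologicalDistanceMatrix:
    """Bond-count shortest paths over the hydrogen-depleted atom set."""

    d: np.ndarray  # symmetric integer matrix
    atom_map: list[int]  # depleted index -> graph (H-explicit) atom index

    def __post_init__(self):
        self.d = np.asarray(self.d)
        if not np.all(np.isfinite(self.d)):
            raise StructureError("disconnected heavy-atom graph")
        self.d = self.d.astype(int)


def parse_sequences(stream: TextIO | str) -> list[PeptideSequence]:
    """Parse FASTA text into PeptideSequence records (order preserved).

    The record id is the first whitespace-delimited token of the header.
    An empty stream yields an empty list.  Non-standard letters raise a
    SequenceError naming the record and position.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    out = []
    for rec in SeqIO.parse(stream, "fasta"):
        out.append(PeptideSequence(id=rec.id, residues=str(rec.seq).upper()))
    return out


def build_peptide_graph(seq: PeptideSequence) -> MolecularGraph:
    """Instantiate the neutral, hydrogen-explicit structure of a peptide.

    Residues are joined by amide bonds with loss of one water each; the
    N-terminus is a free amine and the C-terminus a free carboxylic acid.
    """
    mol = Chem.MolFromSequence(seq.residues)
    if mol is None:
        raise StructureError(f"{seq.id}: could not build peptide structure")
    mol = Chem.AddHs(mol)
    Chem.SanitizeMol(mol)
    residue_of_atom = {}
    for atom in mol.GetAtoms():
        info = atom.GetPDBResidueInfo()
        if info is not None:
            residue_of_atom[atom.GetIdx()] = info.GetResidueNumber() - 1
    # hydrogens added after the fact inherit the residue of their heavy atom
    for atom in mol.GetAtoms():
        if atom.GetIdx() not in residue_of_atom:
            nbrs = atom.GetNeighbors()
            if nbrs and nbrs[0].GetIdx() in residue_of_atom:
                residue_of_atom[atom.GetIdx()] = residue_of_atom[nbrs[0].GetIdx()]
    return MolecularGraph(id=seq.id, mol=mol, residue_of_atom=residue_of_atom)


def generate_conformer(graph: MolecularGraph, seed: int = 7,
                       max_attempts: int = 5) -> Conformer:
    """Seeded distance-geometry embed + MMFF94 minimization.

    Deterministic for a fixed (graph, seed); bonded distances land in the
    physical 0.7–2.2 Å window.  Retries with derived seeds on embedding
    failure before raising.
    """
    mol = Chem.Mol(graph.mol)
    params = AllChem.ETKDGv3()
    params.useRandomCoords = True
    last_seed = seed
    for attempt in range(max_attempts):
        last_seed = seed + 7919 * attempt
        params.randomSeed = last_seed
        if AllChem.EmbedMolecule(mol, params) == 0:
            break
    else:
        raise StructureError(f"{graph.id}: conformer embedding failed "
                             f"after {max_attempts} attempts")
    try:
        AllChem.MMFFOptimizeMolecule(mol, maxIters=2000)
    except Exception:
        pass  # unminimized embed still satisfies the geometric invariants
    coords = mol.GetConformer().GetPositions()
    return Conformer(coordinates=np.asarray(coords, dtype=float),
                     method="ETKDGv3+MMFF94", seed=last_seed)


def topological_distances(graph: MolecularGraph) -> TopologicalDistanceMatrix:
    """All-pairs bond-count distances over the hydrogen-depleted graph."""
    heavy = graph.heavy_atom_indices()
    if not heavy:
        raise StructureError(f"{graph.id}: no heavy atoms")
    # distance matrix of the full graph restricted to heavy atoms equals the
    # heavy-graph distance matrix: shortest paths never route through H leaves
    full = Chem.GetDistanceMatrix(graph.mol)
    sub = full[np.ix_(heavy, heavy)]
    if not np.all(np.isfinite(sub)):
        raise StructureError(f"{graph.id}: disconnected heavy-atom graph")
    return TopologicalDistanceMatrix(d=sub, atom_map=heavy)


# ---------------------------------------------------------------------------
# SDF interchange: one molecule per record, peptide id in the title line.

def write_sdf(path, graphs: Iterable[MolecularGraph],
              conformers: dict[str, Conformer] | None = None) -> None:
    writer = Chem.SDWriter(str(path))
    try:
        writer.SetKekulize(True)
        for g in graphs:
            mol = Chem.Mol(g.mol)
            mol.SetProp("_Name", g.id)
            if conformers and g.id in conformers:
                conf = Chem.Conformer(mol.GetNumAtoms())
                for i, (x, y, z) in enumerate(conformers[g.id].coordinates):
                    conf.SetAtomPosition(i, (float(x), float(y), float(z)))
                mol.RemoveAllConformers()
                mol.AddConformer(conf, assignId=True)
            writer.write(mol)
    finally:
        writer.close()


def read_sdf(path) -> list[tuple[MolecularGraph, Conformer | None]]:
    """Read molecules (e.g. non-standard monomers) from an SDF v2000 file."""
    out = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    for mol in supplier:
        if mol is None:
            raise StructureError(f"unreadable record in {path}")
        mol = Chem.AddHs(mol, addCoords=mol.GetNumConformers() > 0)
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{len(out)}"
        graph = MolecularGraph(id=name, mol=mol)
        conf = None
        if mol.GetNumConformers() > 0:
            conf = Conformer(coordinates=np.asarray(
                mol.GetConformer().GetPositions(), dtype=float), method="sdf")
        out.append((graph, conf))
    return out
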