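"""Molecular descriptors: Geary autocorrelation, 3D-MoRSE, WHIM symmetry,
graph pattern counts and constitutional scalars.

Conventions
-----------
* 2D families (Geary, binary N-N fingerprint, N..S topological-distance sum,
  tertiary-carbon / ether / secondary-amide counts) operate on the
  hydrogen-depleted graph; 3D families (3D-MoRSE, WHIM) and constitutional
  scalars (MW, mean polarizability) operate on the full hydrogen-explicit
  structure.
* Atomic weights are always carbon-scaled (w(C) = 1); scheme ``u`` is unit
  weights.
* A descriptor that is mathematically undefined for a molecule (no atom pair
  at the requested lag, zero weight variance, rank-deficient geometry) yields
  NaN — the undefined marker — never a fabricated zero.

Descriptor names mirror the Dragon strings ("GATS5m", "Mor15p", "G2e",
"B04[N-N]", "T(N.S)", "nCt", "nROR", "nRCONHR", "MW", "Mp") so published
QSPR tables can be cross-referenced textually.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .properties import AtomPropertyTable, default_properties
from .structures import Conformer, MolecularGraph, TopologicalDistanceMatrix, topological_distances

UNDEFINED = float("nan")


@dataclass(frozen=True)
class DescriptorConfig:
    """Grid of descriptor columns to compute.

    geary_lags: topological lags k for GATS (weighted schemes only — unit
    weights have zero variance, so GATSku is undefined by construction).
    morse_signals: scattering-signal indices s_idx (s = s_idx - 1 in 1/Å).
    whim_components: principal axes for the directional symmetry index G.
    """

    geary_lags: tuple[int, ...] = tuple(range(1, 9))
    geary_schemes: tuple[str, ...] = ("m", "v", "e", "p")
    morse_signals: tuple[int, ...] = tuple(range(1, 33))
    morse_schemes: tuple[str, ...] = ("u", "m", "v", "e", "p")
    whim_components: tuple[int, ...] = (1, 2, 3)
    whim_schemes: tuple[str, ...] = ("u", "m", "v", "e", "p")
    whim_tolerance: float = 0.15
    include_3d: bool = True

    def __post_init__(self):
        if any(k < 1 for k in self.geary_lags):
            raise ValueError("geary lags must be >= 1")
        if any(s < 1 for s in self.morse_signals):
            raise ValueError("morse signals must be >= 1")
        if not set(self.whim_components) <= {1, 2, 3}:
            raise ValueError("whim components must be in {1,2,3}")

    def column_names(self) -> list[str]:
        cols = [f"GATS{k}{w}" for k in self.geary_lags for w in self.geary_schemes]
        if self.include_3d:
            cols += [f"Mor{s}{w}" for s in self.morse_signals for w in self.morse_schemes]
            cols += [f"G{m}{w}" for m in self.whim_components for w in self.whim_schemes]
        cols += ["B04[N-N]", "T(N.S)", "nCt", "nROR", "nRCONHR", "MW", "Mp"]
        return cols


# ---------------------------------------------------------------------------
# numeric kernels (array-level, independently testable against brute force)

def geary_from_arrays(weights: np.ndarray, dist: np.ndarray, lag: int) -> float:
    """Geary autocorrelation GATS_k over an arbitrary weighted graph.

    GATS_k = [ sum_{d_ij=k} (w_i - w_j)^2 / (2 Delta_k) ]
             / [ sum_i (w_i - wbar)^2 / (A - 1) ]

    with the numerator sum over ordered pairs and Delta_k their count.
    NaN when no pair sits at lag k or the weights have zero variance.
    """
    w = np.asarray(weights, dtype=float)
    d = np.asarray(dist)
    A = w.size
    if A < 2:
        raise ValueError("Geary autocorrelation needs at least 2 atoms")
    mask = d == lag
    delta = int(mask.sum())  # ordered pairs
    denom = np.sum((w - w.mean()) ** 2) / (A - 1)
    if delta == 0 or denom == 0.0:
        return UNDEFINED
    diff2 = (w[:, None] - w[None, :]) ** 2
    num = diff2[mask].sum() / (2.0 * delta)
    return float(num / denom)


def morse_from_arrays(weights: np.ndarray, coords: np.ndarray, signal: int) -> float:
    """3D-MoRSE Mor_s = sum_{i<j} w_i w_j sinc(s * r_ij), s = signal - 1 (1/Å)."""
    w = np.asarray(weights, dtype=float)
    xyz = np.asarray(coords, dtype=float)
    A = w.size
    if A < 2:
        raise ValueError("3D-MoRSE needs at least 2 atoms")
    s = float(signal - 1)
    iu = np.triu_indices(A, k=1)
    diffs = xyz[iu[0]] - xyz[iu[1]]
    r = np.sqrt((diffs ** 2).sum(axis=1))
    x = s * r
    # np.sinc is sin(pi x)/(pi x); we need sin(x)/x with sinc(0)=1
    vals = np.where(x == 0.0, 1.0, np.sin(x) / np.where(x == 0.0, 1.0, x))
    return float(np.sum(w[iu[0]] * w[iu[1]] * vals))


def whim_symmetry_from_arrays(weights: np.ndarray, coords: np.ndarray,
                              component: int, tolerance: float = 0.15) -> float:
    """Directional WHIM symmetry index gamma_m along weighted principal axis m.

    Atoms are scored by projection on axis m of the weighted covariance of the
    centered coordinates.  n_s counts atoms possessing a mirror partner
    (t_j ≈ -t_i within tolerance; |t_i| <= tolerance is self-paired),
    n_a = A - n_s, and

        gamma_m = 1 / (1 + H),
        H = -(n_s/A) log2(n_s/A) - n_a (1/A) log2(1/A)

    (zero-count terms dropped).  gamma_m in (0, 1], 1 = fully symmetric.
    NaN for a degenerate axis (zero eigenvalue beyond the geometric rank).
    """
    w = np.asarray(weights, dtype=float)
    xyz = np.asarray(coords, dtype=float)
    A = w.size
    if A < 2:
        raise ValueError("WHIM needs at least 2 atoms")
    if component not in (1, 2, 3):
        raise ValueError("component must be 1, 2 or 3")
    wn = w / w.sum()
    center = (wn[:, None] * xyz).sum(axis=0)
    x = xyz - center
    cov = (wn[:, None] * x).T @ x
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    lam = evals[component - 1]
    if lam <= max(1e-12, 1e-9 * max(evals[0], 1.0)):
        return UNDEFINED
    t = x @ evecs[:, component - 1]
    n_s = 0
    for i in range(A):
        if abs(t[i]) <= tolerance:
            n_s += 1
            continue
        if np.any(np.abs(t + t[i]) <= tolerance):
            n_s += 1
    n_a = A - n_s
    H = 0.0
    if n_s > 0:
        H -= (n_s / A) * np.log2(n_s / A)
    if n_a > 0:
        H -= n_a * (1.0 / A) * np.log2(1.0 / A)
    return float(1.0 / (1.0 + H))


# ---------------------------------------------------------------------------
# graph-level API

def _heavy_weights(graph: MolecularGraph, dmat: TopologicalDistanceMatrix,
                   scheme: str, table: AtomPropertyTable) -> np.ndarray:
    elements = [graph.mol.GetAtomWithIdx(i).GetSymbol() for i in dmat.atom_map]
    return np.asarray(table.weights(elements, scheme))


def geary_autocorrelation(graph: MolecularGraph, dmat: TopologicalDistanceMatrix,
                          scheme: str, lag: int,
                          table: AtomPropertyTable | None = None) -> float:
    table = table or default_properties()
    w = _heavy_weights(graph, dmat, scheme, table)
    return geary_from_arrays(w, dmat.d, lag)


def morse_signal(graph: MolecularGraph, conformer: Conformer, scheme: str,
                 signal: int, table: AtomPropertyTable | None = None) -> float:
    table = table or default_properties()
    w = np.asarray(table.weights(graph.elements, scheme))
    return morse_from_arrays(w, conformer.coordinates, signal)


def whim_symmetry(graph: MolecularGraph, conformer: Conformer, scheme: str,
                  component: int, tolerance: float = 0.15,
                  table: AtomPropertyTable | None = None) -> float:
    table = table or default_properties()
    w = np.asarray(table.weights(graph.elements, scheme))
    return whim_symmetry_from_arrays(w, conformer.coordinates, component, tolerance)


_AMIDE_SMARTS = Chem.MolFromSmarts("[CX3](=O)[NX3;H1][#6]")


def graph_pattern_descriptors(graph: MolecularGraph,
                              dmat: TopologicalDistanceMatrix | None = None) -> dict:
    """Binary / count descriptors over the hydrogen-depleted graph.

    B04[N-N]  presence of an N,N pair at topological distance 4
    T(N.S)    sum of topological distances over all (N, S) pairs (0 if none)
    nCt       tertiary sp3 carbons: three carbon neighbours, one hydrogen
    nROR      aliphatic ethers: O with two single bonds to sp3 non-carbonyl C
    nRCONHR   secondary amides C(=O)-N(H)-C (one per amide nitrogen)
    """
    if dmat is None:
        dmat = topological_distances(graph)
    mol = graph.mol
    symbols = [mol.GetAtomWithIdx(i).GetSymbol() for i in dmat.atom_map]
    n_idx = [i for i, s in enumerate(symbols) if s == "N"]
    s_idx = [i for i, s in enumerate(symbols) if s == "S"]

    b04 = 0
    for a in range(len(n_idx)):
        for b in range(a + 1, len(n_idx)):
            if dmat.d[n_idx[a], n_idx[b]] == 4:
                b04 = 1
    tns = int(sum(dmat.d[i, j] for i in n_idx for j in s_idx))

    nct = 0
    for atom in mol.GetAtoms():
        if atom.GetSymbol() != "C" or str(atom.GetHybridization()) != "SP3":
            continue
        heavy_nbrs = [n for n in atom.GetNeighbors() if n.GetAtomicNum() > 1]
        if (len(heavy_nbrs) == 3 and atom.GetTotalNumHs(includeNeighbors=True) == 1
                and all(n.GetSymbol() == "C" for n in heavy_nbrs)):
            nct += 1

    nror = 0
    for atom in mol.GetAtoms():
        if atom.GetSymbol() != "O":
            continue
        heavy_nbrs = [n for n in atom.GetNeighbors() if n.GetAtomicNum() > 1]
        if len(heavy_nbrs) != 2:
            continue
        bonds_single = all(
            mol.GetBondBetweenAtoms(atom.GetIdx(), n.GetIdx()).GetBondType()
            == Chem.BondType.SINGLE for n in heavy_nbrs)
        carbons_ok = all(
            n.GetSymbol() == "C" and str(n.GetHybridization()) == "SP3"
            for n in heavy_nbrs)
        if bonds_single and carbons_ok:
            nror += 1

    matches = mol.GetSubstructMatches(_AMIDE_SMARTS)
    amide_n = {m[2] for m in matches}  # one motif per amide nitrogen
    return {"B04[N-N]": b04, "T(N.S)": tns, "nCt": nct, "nROR": nror,
            "nRCONHR": len(amide_n)}


def constitutional(graph: MolecularGraph,
                   table: AtomPropertyTable | None = None) -> dict:
    """MW (g/mol, full H-explicit structure) and mean carbon-scaled
    polarizability Mp = (1/A) * sum_i p_i / p_C."""
    table = table or default_properties()
    elements = graph.elements
    mw = sum(table.value(el, "mass") for el in elements)
    mp = float(np.mean([table.carbon_scaled(el, "polarizability")
                        for el in elements]))
    return {"MW": mw, "Mp": mp}


# ---------------------------------------------------------------------------

@dataclass
class DescriptorCalculator:
    """Transformer mapping peptides to a named descriptor matrix.

    ``transform`` takes a list of (MolecularGraph, Conformer-or-None) pairs
    and returns a peptides x descriptors DataFrame (NaN = undefined cell).
    Stateless; provided in estimator form so it slots into pipelines.
    """

    config: DescriptorConfig = field(default_factory=DescriptorConfig)
    table: AtomPropertyTable | None = None

    def get_params(self, deep: bool = True) -> dict:
        return {"config": self.config, "table": self.table}

    def set_params(self, **params) -> "DescriptorCalculator":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "DescriptorCalculator":
        return self

    def transform(self, peptides: list[tuple[MolecularGraph, Conformer | None]]
                  ) -> pd.DataFrame:
        cfg, table = self.config, self.table or default_properties()
        if not peptides:
            raise ValueError("empty peptide list")
        if cfg.include_3d:
            missing = [g.id for g, c in peptides if c is None]
            if missing:
                raise ValueError(
                    f"3D descriptor families enabled but conformers missing "
                    f"for: {', '.join(missing)}")
        rows = []
        ids = []
        for graph, conf in peptides:
            dmat = topological_distances(graph)
            row: dict[str, float] = {}
            for k in cfg.geary_lags:
                for w in cfg.geary_schemes:
                    row[f"GATS{k}{w}"] = geary_autocorrelation(
                        graph, dmat, w, k, table)
            if cfg.include_3d:
                for s in cfg.morse_signals:
                    for w in cfg.morse_schemes:
                        row[f"Mor{s}{w}"] = morse_signal(graph, conf, w, s, table)
                for m in cfg.whim_components:
                    for w in cfg.whim_schemes:
                        row[f"G{m}{w}"] = whim_symmetry(
                            graph, conf, w, m, cfg.whim_tolerance, table)
            row.update(graph_pattern_descriptors(graph, dmat))
            row.update(constitutional(graph, table))
            rows.append(row)
            ids.append(graph.id)
        mat = pd.DataFrame(rows, index=ids, columns=cfg.column_names(),
                           dtype=float)
        mat.index.name = "peptide_id"
        return mat


def compute_descriptor_matrix(peptides, config: DescriptorConfig | None = None,
                              table: AtomPropertyTable | None = None) -> pd.DataFrame:
    """Functional wrapper over DescriptorCalculator."""
    return DescriptorCalculator(config or DescriptorConfig(), table).transform(peptides)


def write_descriptor_csv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, na_rep="NA")


def read_descriptor_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0, na_values=["NA"])
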