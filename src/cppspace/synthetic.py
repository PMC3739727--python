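"""Synthetic fixtures with the statistical structure the analysis assumes.

Three generators cover the pipeline's inputs:

* peptide sets with chemical-class structure (cationic / amphipathic /
  hydrophobic and mixtures), optionally including the fixed reference
  peptides (penetratin, R9, Tat 48-60);
* multi-study uptake tables with known true relative uptake, study-specific
  multiplicative scales, heterogeneous units/techniques and configurable
  positive-control availability — the setting the CP-response machinery is
  designed for.  True uptake spans roughly three orders of magnitude
  (log-uniform over [0.001, 3]); responses are linear in concentration with
  multiplicative log-normal noise, so the normalization assumptions hold by
  construction and estimator error is attributable to the noise and the
  study design;
* descriptor/response datasets with known sparse linear structure for
  stepwise-MLR recovery tests.

All generators are pure functions of (configuration, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cp_response import PENETRATIN, STUDY_COLUMNS
from .structures import PeptideSequence

#: fixed reference peptides (id -> sequence)
REFERENCE_PEPTIDES = {
    PENETRATIN: "RQIKIWFQNRRMKWKK",
    "R9": "RRRRRRRRR",
    "tat48-60": "GRKKRRQRRRPPQ",
}

CHEMICAL_CLASSES = ("C", "A", "AC", "H", "CH")

#: incubation concentrations (µM) drawn from the printed literature set
CONCENTRATIONS_UM = (
    0.01, 0.2, 0.1, 0.33, 0.4, 0.8, 1.0, 1.8, 2.0, 2.5, 3.0, 3.1, 3.5, 4.0,
    4.5, 5.0, 6.0, 6.3, 7.5, 10.0, 12.5, 15.0, 20.0, 25.0, 30.0, 40.0, 50.0,
    100.0, 110.0, 200.0, 400.0, 800.0, 1600.0,
)

_UNIT_TECHNIQUES = [
    ("MFI", "flow cytometry"),
    ("pmol/mg protein", "RP-HPLC"),
    ("% of added peptide", "spectrofluorometry"),
    ("a.u.", "CLSM image analysis"),
]

_HYDROPHOBIC = "AGLPV"
_CATIONIC = "RK"
_POLAR = "STNQ"


@dataclass
class SyntheticGroundTruth:
    """Everything the generators decided, for closed-loop checks."""

    true_uptake: dict[str, float]
    chemical_class: dict[str, str] = field(default_factory=dict)
    study_scale: dict[str, float] = field(default_factory=dict)
    study_unit: dict[str, str] = field(default_factory=dict)
    study_controls: dict[str, list[str]] = field(default_factory=dict)
    noise_sigma: float = 0.0
    beta: dict[str, float] = field(default_factory=dict)
    qspr_noise_sd: float = 0.0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _sample_sequence(rng: np.random.Generator, length: int, cls: str) -> str:
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    if cls == "C":
        # cationic: arginine/lysine-rich stretch (at least 40% R+K guaranteed)
        while True:
            out = [rng.choice(list(_CATIONIC)) if rng.random() < 0.65
                   else rng.choice(list(alphabet)) for _ in range(length)]
            if sum(aa in _CATIONIC for aa in out) >= 0.4 * length:
                break
    elif cls == "H":
        out = [rng.choice(list(_HYDROPHOBIC)) if rng.random() < 0.7
               else rng.choice(list(alphabet)) for _ in range(length)]
    elif cls in ("A", "AC", "CH"):
        # amphipathic: alternating hydrophobic / hydrophilic blocks
        hydrophilic = _CATIONIC if cls != "A" else _CATIONIC + _POLAR
        out = []
        block = max(2, int(rng.integers(2, 5)))
        use_hydro = bool(rng.random() < 0.5)
        while len(out) < length:
            pool = _HYDROPHOBIC if use_hydro else hydrophilic
            for _ in range(block):
                if len(out) >= length:
                    break
                out.append(rng.choice(list(pool)))
            use_hydro = not use_hydro
    else:
        raise ValueError(f"unknown chemical class {cls!r}")
    return "".join(out)


def simulate_peptides(n: int, class_mix: dict[str, float] | None = None,
                      length_range: tuple[int, int] = (5, 30),
                      seed: int = 0, include_references: bool = False
                      ) -> tuple[list[PeptideSequence], dict[str, str]]:
    """Class-conditioned random peptides; deterministic under seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    class_mix = class_mix or {"C": 0.35, "A": 0.2, "AC": 0.2, "H": 0.15,
                              "CH": 0.1}
    if abs(sum(class_mix.values()) - 1.0) > 1e-9:
        raise ValueError("class mix must sum to 1")
    if any(c not in CHEMICAL_CLASSES for c in class_mix):
        raise ValueError("unknown class in mix")
    rng = np.random.default_rng(seed)
    classes = rng.choice(list(class_mix), size=n, p=list(class_mix.values()))
    peptides = []
    labels = {}
    if include_references:
        for pid, seq in REFERENCE_PEPTIDES.items():
            peptides.append(PeptideSequence(id=pid, residues=seq))
            labels[pid] = "C" if pid != PENETRATIN else "AC"
    for i, cls in enumerate(classes):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        pid = f"syn{i:03d}"
        peptides.append(PeptideSequence(
            id=pid, residues=_sample_sequence(rng, length, cls)))
        labels[pid] = str(cls)
    return peptides, labels


def _author_class(cp: float) -> str:
    """Map a true relative uptake to the five verbal classes by magnitude."""
    if cp < 0.01:
        return "no"
    if cp < 0.1:
        return "low"
    if cp < 0.5:
        return "medium"
    if cp < 1.0:
        return "cpp"
    return "high"


def simulate_ground_truth(peptide_ids: list[str], seed: int = 0,
                          low: float = 0.001, high: float = 3.0
                          ) -> SyntheticGroundTruth:
    """True relative uptake, log-uniform over ~3 orders of magnitude; the
    reference (penetratin) is pinned at 1 when present."""
    rng = np.random.default_rng(seed)
    uptake = {}
    for pid in peptide_ids:
        if pid == PENETRATIN:
            uptake[pid] = 1.0
        else:
            uptake[pid] = float(np.exp(rng.uniform(np.log(low), np.log(high))))
    return SyntheticGroundTruth(true_uptake=uptake)


def simulate_uptake_studies(ground_truth: SyntheticGroundTruth,
                            n_studies: int = 30,
                            design: dict[str, float] | None = None,
                            sigma: float = 0.3,
                            peptides_per_study: int = 12,
                            records_per_peptide: int = 1,
                            seed: int = 0) -> list[pd.DataFrame]:
    """Multi-study uptake tables P = trueUptake * C * scale * LogNormal(0, σ).

    ``design`` gives the fractions of studies carrying penetratin, an
    alternative positive control, or no control at all.  Studies are tagged
    with a unit and technique; the study scale is the unit's base response
    level times a log-normal study effect, so responses are comparable only
    after normalization.
    """
    design = design or {"penetratin": 0.6, "alt_control": 0.25, "none": 0.15}
    if abs(sum(design.values()) - 1.0) > 1e-9:
        raise ValueError("design fractions must sum to 1")
    rng = np.random.default_rng(seed)
    gt = ground_truth
    pids = [p for p in gt.true_uptake if p not in REFERENCE_PEPTIDES]
    alt_controls = [p for p in REFERENCE_PEPTIDES if p != PENETRATIN]
    for pid in REFERENCE_PEPTIDES:
        if pid not in gt.true_uptake:
            gt.true_uptake[pid] = 1.0 if pid == PENETRATIN else float(
                np.exp(rng.uniform(np.log(0.1), np.log(2.0))))
    gt.noise_sigma = sigma

    kinds = (["penetratin"] * round(design.get("penetratin", 0) * n_studies)
             + ["alt_control"] * round(design.get("alt_control", 0) * n_studies)
             + ["none"] * n_studies)[:n_studies]
    unit_base = {u: 10.0 ** (i - 1) for i, (u, _) in enumerate(_UNIT_TECHNIQUES)}

    tables = []
    for s, kind in enumerate(kinds):
        study_id = f"study{s:03d}"
        unit, technique = _UNIT_TECHNIQUES[int(rng.integers(len(_UNIT_TECHNIQUES)))]
        scale = unit_base[unit] * float(rng.lognormal(0.0, 0.5))
        roster = list(rng.choice(pids, size=min(peptides_per_study, len(pids)),
                                 replace=False))
        controls = []
        if kind == "penetratin":
            controls.append(PENETRATIN)
            if rng.random() < 0.5:  # co-measured alternative control -> RFs
                controls.append(alt_controls[int(rng.integers(len(alt_controls)))])
        elif kind == "alt_control":
            controls.append(alt_controls[int(rng.integers(len(alt_controls)))])
        rows = []
        for pid in roster + controls:
            for _ in range(records_per_peptide):
                c_um = float(rng.choice(CONCENTRATIONS_UM))
                noise = float(rng.lognormal(0.0, sigma)) if sigma > 0 else 1.0
                rows.append({
                    "study_id": study_id,
                    "peptide_id": pid,
                    "technique": technique,
                    "unit": unit,
                    "response": gt.true_uptake[pid] * c_um * scale * noise,
                    "concentration_value": c_um,
                    "concentration_unit": "uM",
                    "timepoint": 60.0,
                    "is_positive_control": pid in controls,
                    "author_class": _author_class(gt.true_uptake[pid]),
                })
        gt.study_scale[study_id] = scale
        gt.study_unit[study_id] = unit
        gt.study_controls[study_id] = controls
        tables.append(pd.DataFrame(rows, columns=STUDY_COLUMNS))
    return tables


def simulate_qspr_dataset(n_rows: int = 150, n_cols: int = 50,
                          n_true: int = 3,
                          effect_sizes: tuple[float, ...] | None = None,
                          noise_sd: float | None = None,
                          target_r2: float = 0.6,
                          corr_block: tuple[int, int, float] | None = None,
                          seed: int = 0
                          ) -> tuple[pd.DataFrame, np.ndarray, SyntheticGroundTruth]:
    """Sparse linear descriptor->response dataset: y = X beta + N(0, sd).

    Columns are standard normal; ``corr_block=(i, j, r)`` makes column j a
    noisy copy of column i with correlation r (to exercise the 0.95 pruning).
    If ``noise_sd`` is None it is set from ``target_r2`` via the population
    signal variance sum(beta²).
    """
    if n_true > n_cols:
        raise ValueError("n_true exceeds n_cols")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_rows, n_cols))
    if corr_block is not None:
        i, j, r = corr_block
        X[:, j] = r * X[:, i] + np.sqrt(1 - r * r) * rng.standard_normal(n_rows)
    cols = [f"d{k:03d}" for k in range(n_cols)]
    if effect_sizes is None:
        effect_sizes = tuple(1.0 + 0.5 * k for k in range(n_true))
    beta = np.zeros(n_cols)
    true_idx = rng.choice(n_cols, size=n_true, replace=False)
    for k, idx in enumerate(true_idx):
        beta[idx] = effect_sizes[k % len(effect_sizes)]
    signal_var = float(np.sum(beta ** 2))
    if noise_sd is None:
        noise_sd = (np.sqrt(signal_var * (1 - target_r2) / target_r2)
                    if signal_var > 0 else 1.0)
    y = X @ beta + rng.normal(0.0, noise_sd, size=n_rows)
    gt = SyntheticGroundTruth(
        true_uptake={},
        beta={cols[i]: float(beta[i]) for i in range(n_cols) if beta[i] != 0},
        qspr_noise_sd=float(noise_sd),
    )
    return pd.DataFrame(X, columns=cols), y, gt


def write_fixture_bundle(directory, peptides: list[PeptideSequence],
                         tables: list[pd.DataFrame],
                         ground_truth: SyntheticGroundTruth) -> dict[str, str]:
    """FASTA + per-study CSVs + ground-truth JSON under one directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fasta = directory / "peptides.fasta"
    with open(fasta, "w") as fh:
        for p in peptides:
            fh.write(f">{p.id}\n{p.residues}\n")
    paths = {"fasta": str(fasta)}
    for i, t in enumerate(tables):
        p = directory / f"study_{i:03d}.csv"
        t.to_csv(p, index=False)
        paths[f"study_{i:03d}"] = str(p)
    gt_path = directory / "ground_truth.json"
    gt_path.write_text(ground_truth.to_json())
    paths["ground_truth"] = str(gt_path)
    return paths
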