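# cppspace

Chemical-functional space analysis of **cell-penetrating peptides (CPPs)** —
short (5–30 aa) peptides that cross cell membranes and ferry cargoes such as
siRNA or proteins into cells.

Quantitative uptake measurements for CPPs are scattered across studies that
differ in technique (flow cytometry, RP-HPLC, spectrofluorometry, …), units,
incubation concentrations, cell lines and positive controls, so raw numbers
cannot be compared directly. `cppspace` implements:

1. **A unified CP-response.** Each measured response *P* at incubation
   concentration *C* is concentration-normalized to *p = P/C* and referred to
   the reference CPP penetratin:
   - penetratin in the same study: `CP = p_CPP / p_pen`;
   - another positive control PC in the study:
     `CP = (p_CPP / p_PC) · RF(PC)`, where the response factor
     `RF(PC) = median over studies of p_PC / p_pen` (so `RF(penetratin) ≡ 1`);
   - no control: `CP = p_CPP / median_u(p_pen)` over all studies reporting
     the same unit *u*.

   Peptides measured in several studies get the median of their study-level
   CP values.
2. **Molecular descriptors** of hydrogen-explicit peptide structures built
   from sequence (free amine / free acid termini) with seeded 3D conformers:
   Geary autocorrelations `GATS_k(w)`, 3D-MoRSE signals
   `Mor_s(w) = Σ_{i<j} w_i w_j · sin(s·r_ij)/(s·r_ij)`, directional WHIM
   symmetry indices `G_m(w)`, pattern counts (`B04[N-N]`, `T(N.S)`, `nCt`,
   `nROR`, `nRCONHR`) and constitutional scalars (`MW`, `Mp`), with atomic
   weights carbon-scaled by mass / van der Waals volume / Sanderson
   electronegativity / polarizability.
3. **Chemical-space exploration**: constant/correlation pruning
   (|r| > 0.95), z-scaling, PCA with cumulative R² and cross-validated Q²,
   feature selection by predicted variation (> 0.30), and average-linkage
   Euclidean clustering with per-cluster median CP-responses.
4. **Robust QSPR**: iterative Grubbs outlier screening (α = 0.05), stepwise
   MLR with partial-F entry/removal (p ≤ 0.05 / p ≥ 0.10), and a
   noise-replicate analysis — ten refits under multiplicative response noise
   in [0.90, 1.10] — that keeps the descriptors retained in more than half
   of the models.
5. **Synthetic data generators** reproducing the statistical structure of
   multi-study uptake compilations, used throughout the test suite for
   closed-loop recovery checks.

Estimators follow scikit-learn conventions (`fit`/`transform`/`predict`,
`get_params`, fitted attributes with trailing underscores) and compose with
sklearn pipelines; module-level functions are thin wrappers.

## Worked example

```python
import pandas as pd
from cppspace import (normalize_records, response_factors, compute_cp_table,
                      parse_sequences, build_peptide_graph,
                      generate_conformer, compute_descriptor_matrix)

studies = pd.DataFrame([
    # study A: penetratin measured alongside two analytes (direct route)
    ("A", "penetratin", "FACS", "MFI", 120.0, 5.0, "uM", 60, True,  None),
    ("A", "pep1",       "FACS", "MFI", 300.0, 5.0, "uM", 60, False, None),
    ("A", "tat",        "FACS", "MFI",  26.4, 5.0, "uM", 60, True,  None),
    # study B: only tat as control (bridged route via its response factor)
    ("B", "tat",  "RP-HPLC", "pmol/mg",  8.0, 2.0, "uM", 30, True,  None),
    ("B", "pep2", "RP-HPLC", "pmol/mg", 40.0, 2.0, "uM", 30, False, None),
], columns=["study_id", "peptide_id", "technique", "unit", "response",
            "concentration_value", "concentration_unit", "timepoint",
            "is_positive_control", "author_class"])

norm = normalize_records(studies)
rf = response_factors(norm)
cp = compute_cp_table(norm, rf)
print(cp.per_peptide[["cp_median", "n_studies"]])
```

```
            cp_median  n_studies
peptide_id
penetratin       1.00          1
pep1             2.50          1
pep2             1.10          1
tat              0.22          2
```

Penetratin, normalized against itself, scores exactly 1. `pep1` takes the
direct route: (300/5) / (120/5) = 2.5. In study B penetratin is absent, so
`tat` bridges: its response factor is (26.4/5)/(120/5) = 0.22, and
`pep2` gets (40/2) / (8/2) × 0.22 = 1.10 — on penetratin's scale even though
the two studies share neither technique nor unit.

Descriptors come straight from sequence:

```python
g = build_peptide_graph(parse_sequences(">gg\nGG\n")[0])
mat = compute_descriptor_matrix([(g, generate_conformer(g, seed=7))])
print(mat[["GATS1m", "Mor1u", "nRCONHR", "MW", "Mp"]].round(3))
```

```
            GATS1m  Mor1u  nRCONHR       MW     Mp
peptide_id
gg           1.089  136.0      1.0  132.119  0.568
```

Diglycine has 17 atoms, so the zero-angle scattering signal `Mor1u` counts
the 17·16/2 = 136 atom pairs; `nRCONHR` finds its single peptide bond; `MW`
is 2 × 75.07 − 18.02 (one water lost in condensation).

The full pipeline runs from a JSON config:

```bash
cppspace simulate --out fixtures/ --n-peptides 40 --n-studies 30 --seed 1
cppspace all --config cfg.json --out report/ --seed 1
```

producing the CP-response table, response-factor table, PCA summary
(eigenvalue / R² / Q² per component), dendrogram (Newick), cluster median
CP-responses and the robust-MLR coefficient report, plus a manifest with the
seed and file checksums for reproducibility.

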