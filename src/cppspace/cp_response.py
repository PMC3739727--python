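"""Unified cell-penetrating (CP) response from heterogeneous uptake studies.

Literature uptake measurements differ in technique, unit, incubation
concentration and positive controls, so raw responses are not comparable
across studies.  The CP-response makes them comparable under five working
assumptions: cell-line/label differences are neglected, negative-control
uptake is negligible, the maximal value over time is used, an in-study
positive control acts as internal standard, and influx is linear in the
extracellular concentration.  Each response P at concentration C is first
concentration-normalized to p = P/C, then referred to penetratin:

* same-study penetratin present:       CP = p_CPP / p_pen            (direct)
* another positive control present:    CP = (p_CPP / p_PC) * RF(PC)  (bridged)
* no control:                          CP = p_CPP / median_u(p_pen)  (unit-matched)

where RF(PC) is the median over studies of p_PC / p_pen (so RF(penetratin)=1
by construction) and median_u is the median penetratin normalized response
over all studies reporting the same unit.  A peptide measured in several
studies gets the median of its study-level CP values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PENETRATIN = "penetratin"

#: canonical StudyTable CSV header
STUDY_COLUMNS = [
    "study_id", "peptide_id", "technique", "unit", "response",
    "concentration_value", "concentration_unit", "timepoint",
    "is_positive_control", "author_class",
]

AUTHOR_CLASSES = ["no", "low", "medium", "cpp", "high"]

#: editable keyword table mapping authors' verbal judgements to the five
#: classes (no / low / medium / cpp / high)
AUTHOR_CLASS_KEYWORDS = {
    "no": ["no cpp", "non-penetrating", "not cell-penetrating", "no uptake"],
    "low": ["low cpp", "low efficient", "low effective", "slow",
            "nearly unmeasurable"],
    "medium": ["medium cpp", "efficient", "effective"],
    "cpp": ["cpp", "cell-penetrating"],
    "high": ["high cpp", "highly", "extremely effective",
             "extremely efficient", "rapid"],
}

_CONC_FACTORS_TO_UM = {
    "nm": 1e-3, "um": 1.0, "µm": 1.0, "μm": 1.0, "mm": 1e3, "m": 1e6,
}


class UptakeDataError(ValueError):
    pass


def concentration_to_um(value: float, unit: str) -> float:
    """Canonicalize a molar concentration to µM."""
    key = str(unit).strip().lower()
    if key not in _CONC_FACTORS_TO_UM:
        raise UptakeDataError(f"unparseable concentration unit {unit!r}")
    return float(value) * _CONC_FACTORS_TO_UM[key]


def validate_study_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in STUDY_COLUMNS if c not in df.columns
               and c not in ("timepoint", "author_class")]
    if missing:
        raise UptakeDataError(f"study table missing columns: {missing}")
    df = df.copy()
    if "timepoint" not in df.columns:
        df["timepoint"] = np.nan
    if "author_class" not in df.columns:
        df["author_class"] = None
    # protocol quality (non-fixed cells, extracellular peptide removed or
    # quenched): records failing it are kept but flagged; filtering is an
    # explicit option, never implicit
    if "protocol_ok" not in df.columns:
        df["protocol_ok"] = True
    if (df["response"] < 0).any():
        bad = df.index[df["response"] < 0][0]
        raise UptakeDataError(f"negative response at row {bad}")
    if (df["concentration_value"] <= 0).any():
        bad = df.index[df["concentration_value"] <= 0][0]
        raise UptakeDataError(f"non-positive concentration at row {bad}")
    return df


def filter_quality(df: pd.DataFrame) -> pd.DataFrame:
    """Keep only records from protocol-conforming studies (non-fixed cells,
    extracellular peptide washed or quenched)."""
    df = validate_study_table(df)
    return df[df["protocol_ok"].astype(bool)].reset_index(drop=True)


def normalize_records(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse timepoints and attach concentration-normalized responses.

    Within each (study, peptide, concentration) the maximal response over
    time is kept (time-effect assumption); concentrations are canonicalized
    to µM and p = P / C[µM] is attached.
    """
    df = validate_study_table(df)
    df["concentration_um"] = [
        concentration_to_um(v, u)
        for v, u in zip(df["concentration_value"], df["concentration_unit"])
    ]
    keys = ["study_id", "peptide_id", "concentration_um"]
    idx = df.groupby(keys)["response"].idxmax()
    out = df.loc[idx].copy()
    out["p"] = out["response"] / out["concentration_um"]
    return out.reset_index(drop=True)


@dataclass
class ResponseFactorTable:
    """Median penetratin-referred ratios for the positive controls."""

    factors: pd.DataFrame  # index control id; columns rf, n_ratios
    ratios: dict[str, list[float]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def rf(self, control: str) -> float:
        return float(self.factors.loc[control, "rf"])

    def __contains__(self, control: str) -> bool:
        return control in self.factors.index


def _study_median_p(norm: pd.DataFrame, study: str, peptide: str) -> float:
    sel = norm[(norm["study_id"] == study) & (norm["peptide_id"] == peptide)]
    return float(sel["p"].median()) if len(sel) else np.nan


def response_factors(norm: pd.DataFrame,
                     reference: str = PENETRATIN) -> ResponseFactorTable:
    """RF per positive control: median over co-measured studies of p_PC/p_ref."""
    controls = sorted(
        set(norm.loc[norm["is_positive_control"].astype(bool), "peptide_id"]))
    ratios: dict[str, list[float]] = {}
    warnings: list[str] = []
    for pc in controls:
        if pc == reference:
            continue
        rlist = []
        for study in norm.loc[norm["peptide_id"] == pc, "study_id"].unique():
            p_ref = _study_median_p(norm, study, reference)
            p_pc = _study_median_p(norm, study, pc)
            if np.isfinite(p_ref) and np.isfinite(p_pc) and p_ref > 0:
                rlist.append(p_pc / p_ref)
        if rlist:
            ratios[pc] = rlist
        else:
            warnings.append(
                f"control {pc!r} never co-measured with {reference!r}; excluded")
    rows = {reference: {"rf": 1.0, "n_ratios": 1}}
    for pc, rlist in ratios.items():
        rows[pc] = {"rf": float(np.median(rlist)), "n_ratios": len(rlist)}
    factors = pd.DataFrame.from_dict(rows, orient="index")
    factors.index.name = "control"
    ratios[reference] = [1.0]
    return ResponseFactorTable(factors=factors, ratios=ratios, warnings=warnings)


@dataclass
class CPResponseTable:
    """Study-level and aggregated per-peptide CP-responses."""

    per_study: pd.DataFrame   # study_id, peptide_id, cp, equation
    per_peptide: pd.DataFrame  # index peptide_id; cp_median, n_studies, author_class

    def cp(self, peptide: str) -> float:
        return float(self.per_peptide.loc[peptide, "cp_median"])


def compute_cp_table(norm: pd.DataFrame, rf_table: ResponseFactorTable,
                     reference: str = PENETRATIN) -> CPResponseTable:
    """Dispatch the three normalization routes and aggregate per peptide.

    Priority when several controls co-occur in a study: the reference itself,
    then the RF-known control with the most contributing ratios, ties broken
    alphabetically.  A peptide whose unit-matched route finds no reference
    records anywhere is flagged uncomputable (cp = NaN), never dropped.
    """
    # global per-unit median reference response (unit-matched route)
    ref_rows = norm[norm["peptide_id"] == reference]
    unit_median = ref_rows.groupby("unit")["p"].median().to_dict()

    records = []
    for study, sdf in norm.groupby("study_id"):
        peptides = sdf["peptide_id"].unique()
        has_ref = reference in set(peptides)
        controls = sorted(set(
            sdf.loc[sdf["is_positive_control"].astype(bool), "peptide_id"]))
        rf_controls = [c for c in controls if c != reference and c in rf_table]
        # most-supported control first, alphabetical tie-break
        rf_controls.sort(key=lambda c: (-rf_table.factors.loc[c, "n_ratios"], c))
        for pep in peptides:
            pdf = sdf[sdf["peptide_id"] == pep]
            if has_ref:
                p_ref = _study_median_p(sdf, study, reference)
                cps = pdf["p"] / p_ref
                cp, eq = float(cps.median()), 1
            elif rf_controls:
                pc = rf_controls[0]
                p_pc = _study_median_p(sdf, study, pc)
                cps = (pdf["p"] / p_pc) * rf_table.rf(pc)
                cp, eq = float(cps.median()), 2
            else:
                unit = pdf["unit"].iloc[0]
                ref_med = unit_median.get(unit, np.nan)
                if not np.isfinite(ref_med) or ref_med <= 0:
                    cp, eq = np.nan, 3
                else:
                    cp, eq = float((pdf["p"] / ref_med).median()), 3
            records.append({"study_id": study, "peptide_id": pep,
                            "cp": cp, "equation": eq})
    per_study = pd.DataFrame(records)

    author = (norm.dropna(subset=["author_class"])
              .groupby("peptide_id")["author_class"].first()
              if norm["author_class"].notna().any() else pd.Series(dtype=object))
    agg_rows = {}
    for pep, g in per_study.groupby("peptide_id"):
        vals = g["cp"].dropna()
        agg_rows[pep] = {
            "cp_median": float(vals.median()) if len(vals) else np.nan,
            "n_studies": int(len(vals)),
            "uncomputable": len(vals) == 0,
            "author_class": author.get(pep, None),
        }
    per_peptide = pd.DataFrame.from_dict(agg_rows, orient="index")
    per_peptide.index.name = "peptide_id"
    return CPResponseTable(per_study=per_study, per_peptide=per_peptide)


def class_summary(cp_table: CPResponseTable) -> pd.DataFrame:
    """Five-number summary of CP-responses per author class, class-ordered."""
    df = cp_table.per_peptide.dropna(subset=["cp_median", "author_class"])
    rows = {}
    for cls in AUTHOR_CLASSES:
        vals = df.loc[df["author_class"] == cls, "cp_median"].to_numpy(float)
        if vals.size == 0:
            continue
        rows[cls] = {
            "n": int(vals.size),
            "min": float(vals.min()),
            "q1": float(np.percentile(vals, 25)),
            "median": float(np.median(vals)),
            "q3": float(np.percentile(vals, 75)),
            "max": float(vals.max()),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "author_class"
    return out


def map_author_keyword(text: str) -> str | None:
    """Map an author's verbal uptake judgement to one of the five classes."""
    t = str(text).strip().lower()
    for cls in ("no", "low", "high", "medium"):  # specific before generic
        if any(k in t for k in AUTHOR_CLASS_KEYWORDS[cls]):
            return cls
    if any(k in t for k in AUTHOR_CLASS_KEYWORDS["cpp"]):
        return "cpp"
    return None
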