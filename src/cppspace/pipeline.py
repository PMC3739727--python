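"""End-to-end orchestration: structures -> descriptors -> CP-response ->
chemical space -> QSPR, with a JSON-configurable report bundle.

Every random draw descends from the single master seed recorded in the
manifest, so a run is reproducible from its manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import chemspace, cp_response, descriptors, qspr, structures


@dataclass
class PipelineConfig:
    """All numeric settings of the analysis, defaulting to the published
    protocol: correlation pruning at |r| > 0.95, feature selection at
    predicted variation > 0.30, 7-fold Q², stepwise MLR at p_enter 0.05 /
    p_remove 0.10, Grubbs alpha 0.05, ten multiplicative-noise replicates
    over [0.90, 1.10]."""

    fasta: str | None = None
    sdf: str | None = None
    study_csvs: list[str] = field(default_factory=list)
    descriptor_config: dict = field(default_factory=dict)
    strict_protocol: bool = False
    mw_divide: bool = False
    corr_threshold: float = 0.95
    feature_threshold: float = 0.30
    pca_components: int = 5
    cv_folds: int = 7
    hca_k: int = 6
    p_enter: float = 0.05
    p_remove: float = 0.10
    grubbs_alpha: float = 0.05
    n_noise_replicates: int = 10
    noise_low: float = 0.90
    noise_high: float = 1.10
    log_response: bool = False
    seed: int = 0

    def __post_init__(self):
        for name in ("corr_threshold", "feature_threshold", "p_enter",
                     "p_remove", "grubbs_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.n_noise_replicates < 0:
            raise ValueError("n_noise_replicates must be >= 0")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _file_checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def load_study_tables(paths: list[str]) -> pd.DataFrame:
    frames = []
    for p in paths:
        try:
            frames.append(cp_response.validate_study_table(pd.read_csv(p)))
        except (ValueError, KeyError) as exc:
            raise PipelineError("cp_response", f"corrupt study table {p}: {exc}")
    if not frames:
        raise PipelineError("cp_response", "no study tables supplied")
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: PipelineConfig, out_dir, force: bool = False) -> dict:
    """Execute every stage and write the report bundle; returns the manifest."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise PipelineError("report", f"output directory {out} is not empty "
                                      f"(use force to overwrite)")
    out.mkdir(parents=True, exist_ok=True)

    # --- structures -------------------------------------------------------
    try:
        peptides = []
        if config.fasta:
            seqs = structures.parse_sequences(Path(config.fasta).read_text())
            for s in seqs:
                g = structures.build_peptide_graph(s)
                c = structures.generate_conformer(g, seed=config.seed)
                peptides.append((g, c))
        if config.sdf:
            peptides.extend(structures.read_sdf(config.sdf))
        if not peptides:
            raise ValueError("no peptide inputs (fasta or sdf) configured")
    except (ValueError, OSError) as exc:
        raise PipelineError("structures", str(exc))

    # --- descriptors ------------------------------------------------------
    try:
        dconf = descriptors.DescriptorConfig(**config.descriptor_config)
        matrix = descriptors.compute_descriptor_matrix(peptides, dconf)
        descriptors.write_descriptor_csv(matrix, out / "descriptors.csv")
    except ValueError as exc:
        raise PipelineError("descriptors", str(exc))

    # --- cp_response ------------------------------------------------------
    try:
        records = load_study_tables(config.study_csvs)
        if config.strict_protocol:
            records = cp_response.filter_quality(records)
        norm = cp_response.normalize_records(records)
        rf = cp_response.response_factors(norm)
        cp_table = cp_response.compute_cp_table(norm, rf)
        rf.factors.to_csv(out / "response_factors.csv")
        per_pep = cp_table.per_peptide
        per_study = cp_table.per_study
        per_study.to_csv(out / "cp_table_per_study.csv", index=False)
        per_pep.to_csv(out / "cp_table.csv")
        summary = cp_response.class_summary(cp_table)
        summary.to_csv(out / "class_summary.csv")
    except (ValueError, KeyError) as exc:
        raise PipelineError("cp_response", str(exc))

    # --- chemspace --------------------------------------------------------
    try:
        if config.mw_divide:
            matrix = chemspace.divide_by_mw(matrix)
        reduced, removal_log = chemspace.reduce_descriptors(
            matrix, config.corr_threshold)
        removal_log.to_csv(out / "removal_log.tsv", sep="\t", index=False)
        scaled = chemspace.zscale(reduced)
        n_comp = min(config.pca_components, len(scaled) - 1,
                     scaled.shape[1])
        pca = chemspace.pca_fit(scaled, n_comp, config.cv_folds, config.seed)
        pca.summary().to_csv(out / "pca_summary.csv")
        pca.scores_.to_csv(out / "pca_scores.csv")
        pca.loadings_.to_csv(out / "pca_loadings.csv")
        selected = chemspace.feature_select(pca, config.feature_threshold)
        k = min(config.hca_k, len(scaled))
        dendro, labels, cluster_cp = chemspace.hca_cluster(
            scaled, k, per_pep["cp_median"])
        (out / "dendrogram.nwk").write_text(dendro.to_newick() + "\n")
        cluster_df = pd.DataFrame({"cluster": labels})
        cluster_df.to_csv(out / "clusters.csv")
        if cluster_cp is not None:
            cluster_cp.to_csv(out / "cluster_median_cp.csv")
    except ValueError as exc:
        raise PipelineError("chemspace", str(exc))

    # --- qspr -------------------------------------------------------------
    try:
        common = [p for p in scaled.index
                  if p in per_pep.index and np.isfinite(per_pep.loc[p, "cp_median"])]
        if len(common) < 10:
            raise ValueError(f"only {len(common)} peptides have both "
                             f"descriptors and a CP-response")
        y = per_pep.loc[common, "cp_median"].to_numpy(float)
        if config.log_response:
            y = np.log10(y)
        kept, removed = qspr.grubbs_outliers(y, config.grubbs_alpha)
        rows = [common[i] for i in kept]
        Xq = scaled.loc[rows, selected]
        sel = qspr.robust_selection(
            Xq, y[kept], n_replicates=config.n_noise_replicates,
            noise_low=config.noise_low, noise_high=config.noise_high,
            seed=config.seed, majority_threshold=None)
        report = sel.report()
        report.to_csv(out / "robust_mlr.tsv", sep="\t")
        qspr_info = {
            "n_outliers_removed": int(len(removed)),
            "n_observations": int(len(kept)),
            "robust_descriptors": sel.robust_set_,
        }
    except ValueError as exc:
        raise PipelineError("qspr", str(exc))

    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "qspr": qspr_info,
        "files": {},
    }
    for p in sorted(out.iterdir()):
        if p.name != "manifest.json":
            manifest["files"][p.name] = _file_checksum(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
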