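"""End-to-end orchestration of the five-stage study design.

Discovery: simulate (or load) a cohort, QC and transform, test/impute the
immunoassay panel, build the Neurodegeneration Score composite, run the
proteome-wide mediation screen over the four synaptic markers, and validate
candidates against the composite.  Validation: re-test the validated set in
independent cohorts, stratify association scans by amyloid status, and
regress clinical outcome columns on the mediator composite.  Every stage
writes plain-text artifacts and is recorded in a JSON manifest with the
seeds needed to reproduce it.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import adjusted_regression, proteome_scan
from .composite import composite_score
from .impute import iterative_impute
from .io import CovariateTable, OutcomePanel, ProteinMatrix, write_matrix
from .mcar import little_mcar_test
from .mediation import mediation_screen, replicate_screen, validate_mediators
from .qc import apply_qc, log_transform, replicate_cv
from .simulate import (
    SimConfig,
    generate_multi_cohort,
    inject_replicates_and_missingness,
    mask_mcar,
)

__all__ = ["RunManifest", "run_discovery", "run_validation", "prepare_cohort"]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    package_version: str
    stages: list[dict] = field(default_factory=list)
    timestamp: str = ""

    def add_stage(self, name: str, outputs: list[str], **info) -> None:
        self.stages.append({"stage": name, "outputs": outputs, **info})

    def write(self, path: Path) -> None:
        self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S")
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _config_hash(config: SimConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def prepare_cohort(
    matrix: ProteinMatrix,
    panel: OutcomePanel,
    covariates: CovariateTable,
    missing_rate: float,
    seed: int,
    n_imputations: int = 5,
):
    """QC -> log transform -> panel MCAR test -> panel imputation -> composite.

    Returns (log10 matrix, log2 imputed panel frame, composite, diagnostics).
    """
    matrix, qc_report = apply_qc(matrix)
    matrix = log_transform(matrix, base=10)
    panel_log = np.log2(panel.values) if panel.transform == "raw" else panel.values

    diagnostics: dict = {
        "qc_samples_removed": qc_report.n_samples_removed,
        "qc_analytes_removed": qc_report.n_analytes_removed,
        "n_samples": matrix.shape[0],
        "n_analytes": matrix.shape[1],
    }
    if missing_rate > 0:
        panel_log = mask_mcar(panel_log, missing_rate, seed=seed)
        little = little_mcar_test(panel_log)
        diagnostics["little_d2"] = little.statistic
        diagnostics["little_p"] = little.p_value
        imp = iterative_impute(panel_log, n_imputations=n_imputations, seed=seed)
        panel_log = imp.pooled
    composite = composite_score(panel_log.loc[matrix.values.index], anchor_id=panel_log.columns[0])
    diagnostics["composite_variance_explained"] = composite.variance_explained
    return matrix, panel_log, composite, diagnostics


def run_discovery(config: SimConfig, outdir: str | Path, n_boot: int = 500, fdr: float = 0.05):
    """Simulate a discovery cohort and run the screen end-to-end."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=_config_hash(config), seed=config.seed, package_version=__version__
    )

    cohorts = generate_multi_cohort(config)
    matrix, covariates, panel, truth = cohorts[0]
    aug, pairs, _mask = inject_replicates_and_missingness(
        matrix, config.cv_target, 0.0, seed=config.seed
    )
    cv_table, frac_ok = replicate_cv(aug, pairs)
    cv_path = outdir / "replicate_cv.tsv"
    cv_table.to_csv(cv_path, sep="\t")
    manifest.add_stage("replicate_cv", [str(cv_path)], frac_below_20pct=frac_ok)

    matrix_log, panel_log, composite, diagnostics = prepare_cohort(
        matrix, panel, covariates, config.missing_rate, config.seed
    )
    qc_path = outdir / "qc_report.json"
    qc_path.write_text(json.dumps(diagnostics, indent=2))
    manifest.add_stage("qc_transform_impute", [str(qc_path)], **diagnostics)

    screen = mediation_screen(
        matrix_log, truth.exposure_id, panel_log, covariates,
        fdr=fdr, n_boot=n_boot, seed=config.seed,
    )
    for name, table in screen.tables.items():
        p = outdir / f"mediation_{name}.tsv"
        table.to_csv(p, sep="\t")
        manifest.add_stage(f"screen_{name}", [str(p)], n_passed=int(table["passed"].sum()))

    validated, vtable = validate_mediators(
        screen.candidates, matrix_log, truth.exposure_id, composite.scores,
        covariates, fdr=fdr, n_boot=n_boot, seed=config.seed,
    )
    screen.validated = validated
    sets_path = outdir / "mediator_sets.json"
    sets_path.write_text(json.dumps(
        {"candidates": screen.candidates, "validated": validated,
         "criteria": screen.criteria, "planted": truth.mediator_ids}, indent=2))
    comp_path = outdir / "neurodegeneration_score.tsv"
    pd.DataFrame({"pc1": composite.scores}).to_csv(comp_path, sep="\t")
    manifest.add_stage("validate", [str(sets_path), str(comp_path)],
                       n_candidates=len(screen.candidates), n_validated=len(validated))
    manifest.write(outdir / "manifest.json")
    return screen, composite, truth, manifest


def run_validation(
    config: SimConfig,
    validated: list[str],
    outdir: str | Path,
    n_boot: int = 500,
    fdr: float = 0.05,
    clinical_columns: tuple[str, ...] = ("processing_speed_ms", "fa_slf"),
):
    """Replicate the validated set in independent cohorts and stratify by amyloid."""
    if config.n_cohorts < 2:
        raise ValueError("validation needs at least one extra cohort (n_cohorts >= 2)")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=_config_hash(config), seed=config.seed, package_version=__version__
    )

    cohorts = generate_multi_cohort(config)
    prepared = []
    for matrix, covariates, panel, truth in cohorts[1:]:
        m, _pl, comp, _diag = prepare_cohort(matrix, panel, covariates, config.missing_rate, config.seed)
        prepared.append((m, covariates, comp.scores))
    truth = cohorts[0][3]

    table, rate = replicate_screen(
        validated, prepared, truth.exposure_id, fdr=fdr, n_boot=n_boot, seed=config.seed
    )
    rep_path = outdir / "replication.tsv"
    table.to_csv(rep_path, sep="\t")
    manifest.add_stage("replicate", [str(rep_path)], replication_rate=rate)

    strat_paths = []
    for matrix, covariates, comp_scores in prepared[:1]:
        if "amyloid_status" not in covariates.data.columns:
            raise ValueError("amyloid stratification requested but labels missing")
        for status in ("negative", "positive"):
            sub = covariates.data["amyloid_status"] == status
            scan = proteome_scan(matrix, comp_scores, covariates, subgroup=sub,
                                 exclude=(truth.exposure_id,))
            p = outdir / f"scan_amyloid_{status}.tsv"
            scan.to_csv(p, sep="\t")
            strat_paths.append(str(p))
    manifest.add_stage("amyloid_stratified_scans", strat_paths)

    clin_rows = []
    matrix, covariates, comp_scores = prepared[0]
    members = [v for v in validated if v in matrix.values.columns]
    if len(members) >= 2:
        med_pc1 = composite_score(matrix.values[members]).scores
        for col in clinical_columns:
            if col not in covariates.data.columns:
                import warnings
                warnings.warn(f"clinical outcome {col!r} absent; regression skipped")
                continue
            res = adjusted_regression(
                covariates.data[col], med_pc1,
                covariates.data[["age", "sex"]], analyte_id=col,
            )
            clin_rows.append({"outcome": col, "beta_std": res.beta_std,
                              "se": res.se, "p": res.p, "n": res.n})
    clin_path = outdir / "clinical_associations.tsv"
    pd.DataFrame(clin_rows).to_csv(clin_path, sep="\t", index=False)
    manifest.add_stage("clinical_composites", [str(clin_path)])
    manifest.write(outdir / "manifest.json")
    return table, rate, manifest
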