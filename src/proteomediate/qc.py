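"""QC filtering, log transforms, and technical-replicate CV.

The QC convention follows aptamer-array practice: samples carrying
``RowCheck = "FLAG"`` and analytes carrying ``ColCheck = "FLAG"`` are
removed before any transform; raw relative-fluorescence values are then
log10 (aptamer) or log2 (immunoassay) transformed to approximate normality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ProteinMatrix

__all__ = ["QCReport", "apply_qc", "log_transform", "replicate_cv"]


@dataclass
class QCReport:
    n_samples_removed: int
    n_analytes_removed: int
    flagged_samples: list[str]
    flagged_analytes: list[str]


def apply_qc(matrix: ProteinMatrix) -> tuple[ProteinMatrix, QCReport]:
    """Drop flagged samples and analytes; idempotent."""
    flagged_samples = [s for s in matrix.sample_ids if matrix.row_check[s] == "FLAG"]
    flagged_analytes = [
        a for a in matrix.analyte_ids if matrix.analyte_meta.loc[a, "col_check"] == "FLAG"
    ]
    if len(flagged_samples) == len(matrix.sample_ids):
        raise ValueError("all samples flagged by QC")
    if len(flagged_analytes) == len(matrix.analyte_ids):
        raise ValueError("all analytes flagged by QC")
    keep_s = [s for s in matrix.sample_ids if s not in set(flagged_samples)]
    keep_a = [a for a in matrix.analyte_ids if a not in set(flagged_analytes)]
    out = matrix.copy_with(
        values=matrix.values.loc[keep_s, keep_a],
        analyte_meta=matrix.analyte_meta.loc[keep_a],
        row_check=matrix.row_check.loc[keep_s],
    )
    report = QCReport(
        n_samples_removed=len(flagged_samples),
        n_analytes_removed=len(flagged_analytes),
        flagged_samples=flagged_samples,
        flagged_analytes=flagged_analytes,
    )
    return out, report


def log_transform(matrix: ProteinMatrix, base: int = 10) -> ProteinMatrix:
    """Log-transform raw values (base 10 for aptamer data, 2 for immunoassays)."""
    if base not in (10, 2):
        raise ValueError("base must be 10 or 2")
    if matrix.transform != "raw":
        raise ValueError(f"matrix already transformed ({matrix.transform})")
    vals = matrix.values.to_numpy(dtype=float)
    bad = np.argwhere(~np.isnan(vals) & (vals <= 0))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-positive value at sample {matrix.sample_ids[i]!r}, "
            f"analyte {matrix.analyte_ids[j]!r}"
        )
    logged = np.log10(vals) if base == 10 else np.log2(vals)
    return matrix.copy_with(
        values=pd.DataFrame(logged, index=matrix.values.index, columns=matrix.values.columns),
        transform=f"log{base}",
    )


def inverse_log_transform(matrix: ProteinMatrix) -> ProteinMatrix:
    """Undo :func:`log_transform` (used for round-trip checks)."""
    if matrix.transform == "raw":
        raise ValueError("matrix is already on the raw scale")
    base = 10.0 if matrix.transform == "log10" else 2.0
    return matrix.copy_with(values=np.power(base, matrix.values), transform="raw")


def replicate_cv(
    matrix: ProteinMatrix,
    duplicate_pairs: list[tuple[str, str]],
    threshold: float = 20.0,
) -> tuple[pd.Series, float]:
    """Per-analyte replicate CV%% and the fraction of analytes below threshold.

    CV per pair = sd/mean x 100 on raw-scale values (n-1 denominator),
    averaged over pairs per analyte.
    """
    if matrix.transform != "raw":
        raise ValueError("replicate CV is computed on raw-scale values")
    missing = [s for pair in duplicate_pairs for s in pair if s not in matrix.values.index]
    if missing:
        raise KeyError(f"duplicate pair samples not in matrix: {missing}")
    cvs = np.zeros((len(duplicate_pairs), matrix.shape[1]))
    for p, (s1, s2) in enumerate(duplicate_pairs):
        pair = matrix.values.loc[[s1, s2]].to_numpy(dtype=float)
        mean = pair.mean(axis=0)
        if np.any(np.nan_to_num(mean) == 0):
            raise ValueError(f"pair ({s1}, {s2}) has zero mean for some analyte")
        sd = pair.std(axis=0, ddof=1)
        cvs[p] = sd / mean * 100.0
    per_analyte = pd.Series(np.nanmean(cvs, axis=0), index=matrix.values.columns, name="cv_pct")
    frac_below = float((per_analyte < threshold).mean())
    return per_analyte, frac_below
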