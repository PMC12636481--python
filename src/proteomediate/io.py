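"""Containers and readers/writers for proteomics and covariate tables.

Two on-disk dialects are supported: plain delimited tables (samples in rows,
analytes in columns) and a minimal aptamer-array dialect — tab-delimited with
caret-prefixed section headers carrying the per-analyte metadata (including
the ColCheck QC flag) and the per-sample RowCheck flag alongside the
relative-fluorescence values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "ProteinMatrix",
    "CovariateTable",
    "OutcomePanel",
    "read_matrix",
    "write_matrix",
    "write_adat",
]

AMYLOID_VOCAB = frozenset({"negative", "positive", "unknown"})


@dataclass
class ProteinMatrix:
    """Sample x analyte abundance table with QC flags and transform state.

    ``values`` holds raw relative-fluorescence/concentration units until a
    log transform flips ``transform``; raw values must be strictly positive
    (NaN marks a missing cell).
    """

    values: pd.DataFrame
    analyte_meta: pd.DataFrame
    row_check: pd.Series
    platform: str = "aptamer"
    transform: str = "raw"

    def __post_init__(self) -> None:
        if self.platform not in {"aptamer", "immunoassay"}:
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.transform not in {"raw", "log10", "log2"}:
            raise ValueError(f"unknown transform {self.transform!r}")
        if list(self.values.columns) != list(self.analyte_meta.index):
            raise ValueError("analyte metadata does not match value columns")
        if list(self.values.index) != list(self.row_check.index):
            raise ValueError("row_check does not match sample ids")
        if self.transform == "raw":
            vals = self.values.to_numpy(dtype=float)
            if np.any(vals[~np.isnan(vals)] <= 0):
                raise ValueError("raw abundances must be strictly positive")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def analyte_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy_with(self, **kwargs) -> "ProteinMatrix":
        return replace(self, **kwargs)


@dataclass
class CovariateTable:
    """One row per sample: age (years), sex code, cohort, amyloid status,
    plus optional clinical outcome columns (processing speed, per-tract FA).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids in covariates: {dups}")
        if "age" in self.data and (self.data["age"] <= 0).any():
            raise ValueError("ages must be positive")
        if "amyloid_status" in self.data:
            bad = set(self.data["amyloid_status"].dropna().unique()) - AMYLOID_VOCAB
            if bad:
                raise ValueError(f"unknown amyloid status values: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def aligned(self, sample_ids) -> pd.DataFrame:
        return self.data.loc[list(sample_ids)]


@dataclass
class OutcomePanel:
    """Per-sample values for a small set of named outcome markers."""

    values: pd.DataFrame
    transform: str = "raw"

    def __post_init__(self) -> None:
        if self.values.columns.has_duplicates:
            raise ValueError("marker names must be unique")
        if self.transform not in {"raw", "log10", "log2"}:
            raise ValueError(f"unknown transform {self.transform!r}")

    @property
    def marker_names(self) -> list[str]:
        return list(self.values.columns)


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups}")


def read_matrix(path, dialect: str = "delimited", platform: str = "aptamer",
                transform: str = "raw") -> ProteinMatrix:
    """Read a sample x analyte matrix.

    ``delimited``: TSV/CSV with sample ids in the first column and analyte
    ids in the header; optional ``RowCheck`` column and ``ColCheck`` header
    row are recognised if present.  ``adat``: the caret-sectioned dialect
    written by :func:`write_adat`.
    """
    if dialect == "adat":
        return _read_adat(path, platform=platform, transform=transform)
    if dialect != "delimited":
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = "," if str(path).endswith(".csv") else "\t"
    frame = pd.read_csv(path, sep=sep, index_col=0)
    _check_unique(frame.index, "sample ids")
    _check_unique(frame.columns, "analyte ids")
    row_check = pd.Series("PASS", index=frame.index)
    if "RowCheck" in frame.columns:
        row_check = frame.pop("RowCheck").astype(str)
    meta = pd.DataFrame(
        {
            "analyte_id": frame.columns,
            "target": frame.columns,
            "gene": frame.columns,
            "col_check": "PASS",
        }
    ).set_index("analyte_id")
    return ProteinMatrix(
        values=frame.astype(float),
        analyte_meta=meta,
        row_check=row_check,
        platform=platform,
        transform=transform,
    )


def _read_adat(path, platform: str = "aptamer", transform: str = "raw") -> ProteinMatrix:
    sections: dict[str, list[list[str]]] = {}
    current = None
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("^"):
                current = line[1:].strip()
                sections[current] = []
                continue
            if current is None:
                raise ValueError("malformed header: content before the first ^SECTION")
            sections[current].append(line.split("\t"))
    for needed in ("COL_DATA", "ROW_DATA"):
        if needed not in sections:
            raise ValueError(f"malformed file: missing ^{needed} section")

    col_rows = {row[0]: row[1:] for row in sections["COL_DATA"]}
    if "SeqId" not in col_rows:
        raise ValueError("malformed COL_DATA: no SeqId row")
    analyte_ids = col_rows["SeqId"]
    _check_unique(analyte_ids, "analyte ids")
    meta = pd.DataFrame(
        {
            "analyte_id": analyte_ids,
            "target": col_rows.get("Target", analyte_ids),
            "gene": col_rows.get("Gene", analyte_ids),
            "col_check": col_rows.get("ColCheck", ["PASS"] * len(analyte_ids)),
        }
    ).set_index("analyte_id")

    header, *rows = sections["ROW_DATA"]
    if header[0] != "SampleId":
        raise ValueError("malformed ROW_DATA: first column must be SampleId")
    has_rowcheck = len(header) > 1 and header[1] == "RowCheck"
    first_val = 2 if has_rowcheck else 1
    sample_ids = [r[0] for r in rows]
    _check_unique(sample_ids, "sample ids")
    row_check = pd.Series(
        [r[1] if has_rowcheck else "PASS" for r in rows], index=sample_ids, dtype=str
    )
    values = pd.DataFrame(
        [[float(v) if v != "" else np.nan for v in r[first_val:]] for r in rows],
        index=sample_ids,
        columns=analyte_ids,
    )
    return ProteinMatrix(
        values=values, analyte_meta=meta, row_check=row_check,
        platform=platform, transform=transform,
    )


def write_matrix(matrix: ProteinMatrix, path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    matrix.values.to_csv(path, sep=sep, index_label="sample_id")


def write_adat(matrix: ProteinMatrix, path) -> None:
    """Write the caret-sectioned dialect read back by ``read_matrix``."""
    with open(path, "w") as fh:
        fh.write("^HEADER\n")
        fh.write(f"Platform\t{matrix.platform}\n")
        fh.write("^COL_DATA\n")
        fh.write("SeqId\t" + "\t".join(matrix.analyte_ids) + "\n")
        fh.write("Target\t" + "\t".join(matrix.analyte_meta["target"].astype(str)) + "\n")
        fh.write("Gene\t" + "\t".join(matrix.analyte_meta["gene"].astype(str)) + "\n")
        fh.write("ColCheck\t" + "\t".join(matrix.analyte_meta["col_check"].astype(str)) + "\n")
        fh.write("^ROW_DATA\n")
        fh.write("SampleId\tRowCheck\t" + "\t".join(matrix.analyte_ids) + "\n")
        for sid in matrix.sample_ids:
            vals = matrix.values.loc[sid]
            cells = ["" if pd.isna(v) else repr(float(v)) for v in vals]
            fh.write(f"{sid}\t{matrix.row_check[sid]}\t" + "\t".join(cells) + "\n")
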