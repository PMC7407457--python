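"""Readers and writers for the pipeline's plain-text formats.

Formats
-------
- marker TSV: rows = genotype IDs, columns = marker IDs, values 0/1/2 or NA
- VCF (read-only): diploid biallelic records mapped to dosages; multiallelic
  records are skipped with a logged count
- plot CSV: env, rep, block, genotype, value
- BLUE CSV: env, genotype, blue
- GRM CSV: square matrix with genotype IDs as header and index
- design mask CSV: env, genotype, set in {calibration, prediction}
- predictions CSV: env, genotype, set, observed, predicted
- variance components JSON

All CSVs are comma-separated UTF-8 with a header row; missing marker calls
are written as NA (never ".").
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .designs import AllocationDesign
from .markers import GRMatrix, MarkerMatrix

__all__ = [
    "read_markers", "write_markers", "read_markers_vcf",
    "read_plots", "write_plots", "read_blues", "write_blues",
    "read_grm", "write_grm", "read_mask", "write_mask",
    "write_varcomps", "read_varcomps",
]

logger = logging.getLogger(__name__)


def write_markers(markers: MarkerMatrix, path) -> None:
    df = pd.DataFrame(
        markers.dosage, index=markers.genotype_ids, columns=markers.marker_ids
    )
    with np.errstate(invalid="ignore"):
        df = df.astype("Int64")  # keeps 0/1/2 integral, NA for missing
    df.to_csv(path, sep="\t", na_rep="NA", index_label="genotype")


def read_markers(path, fmt: str = "tsv") -> MarkerMatrix:
    """Load a dosage matrix from marker TSV or VCF."""
    if fmt == "vcf":
        return read_markers_vcf(path)
    if fmt != "tsv":
        raise ValueError(f"unknown marker format {fmt!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], dtype=str)
    if df.empty:
        raise ValueError(f"empty marker file: {path}")
    dosage = np.full(df.shape, np.nan)
    for j, col in enumerate(df.columns):
        for i, v in enumerate(df[col]):
            if pd.isna(v):
                continue
            if v not in ("0", "1", "2"):
                raise ValueError(
                    f"invalid dosage {v!r} at genotype {df.index[i]!r}, "
                    f"marker {col!r} in {path}"
                )
            dosage[i, j] = float(v)
    return MarkerMatrix(
        genotype_ids=df.index.to_numpy(dtype=object),
        marker_ids=df.columns.to_numpy(dtype=object),
        dosage=dosage,
    )


def read_markers_vcf(path) -> MarkerMatrix:
    """Read diploid biallelic VCF records as alternate-allele dosages.

    GT fields map 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2, missing -> NA.
    Records with more (or fewer) than one ALT allele are skipped; the count
    of skipped records is logged.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples, dtype=object)
    if samples.size == 0:
        raise ValueError(f"VCF has no samples: {path}")
    cols, ids, skipped = [], [], 0
    for var in vcf:
        if len(var.ALT) != 1:
            skipped += 1
            continue
        col = np.full(samples.size, np.nan)
        for i, gt in enumerate(var.genotypes):
            a, b = gt[0], gt[1]
            if a >= 0 and b >= 0:
                col[i] = float(a + b)
        cols.append(col)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
    vcf.close()
    if skipped:
        logger.info("skipped %d non-biallelic VCF record(s) in %s", skipped, path)
    if not cols:
        raise ValueError(f"no usable biallelic records in {path}")
    return MarkerMatrix(
        genotype_ids=samples,
        marker_ids=np.asarray(ids, dtype=object),
        dosage=np.column_stack(cols),
    )


def _read_table(path, required: tuple) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def read_plots(path) -> pd.DataFrame:
    return _read_table(path, ("env", "rep", "block", "genotype", "value"))


def write_plots(plots: pd.DataFrame, path) -> None:
    plots.to_csv(path, index=False)


def read_blues(path) -> pd.DataFrame:
    return _read_table(path, ("env", "genotype", "blue"))


def write_blues(blues: pd.DataFrame, path) -> None:
    blues.to_csv(path, index=False)


def write_grm(grm: GRMatrix, path) -> None:
    pd.DataFrame(grm.G, index=grm.genotype_ids, columns=grm.genotype_ids).to_csv(
        path, index_label="genotype"
    )


def read_grm(path) -> GRMatrix:
    df = pd.read_csv(path, index_col=0)
    return GRMatrix(
        genotype_ids=df.index.to_numpy(dtype=object),
        G=df.to_numpy(dtype=float),
    )


def write_mask(design: AllocationDesign, path) -> None:
    rows = [(e, g, "calibration") for e, g in sorted(design.calibration_cells)]
    rows += [(e, g, "prediction") for e, g in sorted(design.prediction_cells)]
    pd.DataFrame(rows, columns=["env", "genotype", "set"]).to_csv(path, index=False)


def read_mask(path) -> pd.DataFrame:
    df = _read_table(path, ("env", "genotype", "set"))
    bad = set(df["set"]) - {"calibration", "prediction"}
    if bad:
        raise ValueError(f"{path}: invalid set label(s) {sorted(bad)}")
    return df


def write_varcomps(varcomps: dict, path) -> None:
    Path(path).write_text(json.dumps(varcomps, indent=2, sort_keys=True) + "\n")


def read_varcomps(path) -> dict:
    return json.loads(Path(path).read_text())
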