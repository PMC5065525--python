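"""Plain-text I/O: count TSVs, sample sheets, BED intervals, allc methylation
calls, allelic SNP tables, and qPCR plate CSVs.

All formats are uncompressed text so fixtures stay inspectable. BED is 0-based
half-open; allc positions are 1-based.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .core import CountMatrix, SampleSheet

PathLike = Union[str, Path]

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
ALLC_COLUMNS = ["chrom", "pos", "strand", "context", "meth_reads", "total_reads"]


class CountMatrixParseError(ValueError):
    pass


class SampleMismatchError(ValueError):
    pass


def read_count_matrix(path: PathLike, sheet: Optional[SampleSheet] = None) -> CountMatrix:
    """Read a feature x sample TSV; first column is the feature id.

    When a sample sheet is given, the file's sample set must match it exactly
    and columns are reordered to sheet order.
    """
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline()
    if not header_line.strip():
        raise CountMatrixParseError(f"{path}: no header")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    samples = list(df.columns)
    mat = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(samples):
        for i, raw in enumerate(df[col]):
            try:
                value = int(raw)
            except (TypeError, ValueError):
                raise CountMatrixParseError(
                    f"{path}: non-integer count {raw!r} at feature "
                    f"{df.index[i]!r}, sample {col!r}"
                ) from None
            mat[i, j] = value
    cm = CountMatrix(list(df.index), samples, mat)
    if sheet is not None:
        declared = set(sheet.sample_ids)
        present = set(samples)
        missing = sorted(declared - present)
        extra = sorted(present - declared)
        if missing or extra:
            raise SampleMismatchError(
                f"{path}: sample mismatch vs sheet; missing={missing} extra={extra}"
            )
        cm = cm.subset_samples(sheet.sample_ids)
    return cm


def write_count_matrix(cm: CountMatrix, path: PathLike) -> None:
    df = cm.to_frame()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


def read_sample_sheet(path: PathLike) -> SampleSheet:
    df = pd.read_csv(path, dtype={"sample_id": str, "replicate": int})
    if "stage" in df.columns:
        df["stage"] = df["stage"].where(df["stage"].notna(), None)
    else:
        df["stage"] = None
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: PathLike) -> None:
    df = sheet.frame.copy()
    df["stage"] = df["stage"].fillna("")
    df.to_csv(path, index=False)


def read_bed(path: PathLike) -> pd.DataFrame:
    """Read BED (>=3 columns); returns the canonical 6 columns."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    df = df.iloc[:, : min(6, df.shape[1])]
    df.columns = BED_COLUMNS[: df.shape[1]]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if "name" not in df.columns:
        df["name"] = [f"region_{i}" for i in range(len(df))]
    if "score" not in df.columns:
        df["score"] = 0
    df["score"] = pd.to_numeric(df["score"], errors="coerce").fillna(0).astype(int)
    if "strand" not in df.columns:
        df["strand"] = "."
    if (df["start"] >= df["end"]).any():
        bad = df.loc[df["start"] >= df["end"], "name"].tolist()
        raise ValueError(f"{path}: start >= end for {bad}")
    return df[BED_COLUMNS]


def write_bed(regions: pd.DataFrame, path: PathLike) -> None:
    df = regions.copy()
    for col, default in (("score", 0), ("strand", ".")):
        if col not in df.columns:
            df[col] = default
    df[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_allc(path: PathLike) -> pd.DataFrame:
    """allc-style TSV: chrom, pos (1-based), strand, context, meth, total."""
    df = pd.read_csv(
        path,
        sep="\t",
        names=ALLC_COLUMNS,
        dtype={"chrom": str, "pos": int, "strand": str, "context": str,
               "meth_reads": int, "total_reads": int},
    )
    if (df["meth_reads"] > df["total_reads"]).any():
        raise ValueError(f"{path}: meth_reads > total_reads")
    return df


def write_allc(calls: pd.DataFrame, path: PathLike) -> None:
    calls[ALLC_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_allelic_table(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "sample_id": str})
    required = {"gene_id", "sample_id", "ref_reads", "alt_reads"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "escapes_xci" not in df.columns:
        df["escapes_xci"] = False
    df["ref_reads"] = df["ref_reads"].astype(int)
    df["alt_reads"] = df["alt_reads"].astype(int)
    if (df[["ref_reads", "alt_reads"]] < 0).any().any():
        raise ValueError(f"{path}: negative read counts")
    return df


def write_allelic_table(table: pd.DataFrame, path: PathLike) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_te_annotation(path: PathLike) -> pd.DataFrame:
    """TE annotation TSV with columns id, family, subfamily, chrom, start, end, strand."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "chrom": str})
    required = {"id", "family", "subfamily", "chrom", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_te_annotation(anno: pd.DataFrame, path: PathLike) -> None:
    anno.to_csv(path, sep="\t", index=False)


def read_bedgraph(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"],
                     dtype={"chrom": str, "start": int, "end": int, "value": float})
    return df


def write_bedgraph(df: pd.DataFrame, path: PathLike) -> None:
    df[["chrom", "start", "end", "value"]].to_csv(path, sep="\t", header=False, index=False)


def read_qpcr_plate(path: PathLike) -> pd.DataFrame:
    """Plate CSV with columns well_type (standard|unknown), id, log10_fraction, ct.

    Non-detect wells carry an empty ct field.
    """
    rows = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            ct = rec.get("ct", "")
            rows.append({
                "well_type": rec["well_type"],
                "id": rec["id"],
                "log10_fraction": float(rec["log10_fraction"]) if rec.get("log10_fraction") else np.nan,
                "ct": float(ct) if ct not in ("", None, "NA") else np.nan,
                "condition": rec.get("condition", ""),
            })
    return pd.DataFrame(rows)


def write_qpcr_plate(plate: pd.DataFrame, path: PathLike) -> None:
    df = plate.copy()
    df.to_csv(path, index=False, na_rep="")
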