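"""TE-gene expression correlation by distance bin and orientation."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import TEGenePair


@dataclass
class CorrelationBinSummary:
    bin: str
    orientation: Optional[str]
    n_pairs: int
    correlations: np.ndarray
    median_r: float


def _row_lookup(expr: pd.DataFrame) -> dict[str, np.ndarray]:
    return {fid: expr.loc[fid].to_numpy(dtype=float) for fid in expr.index}


def te_gene_correlation(
    pairs: Sequence[TEGenePair],
    te_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    method: str = "pearson",
) -> tuple[pd.DataFrame, list[CorrelationBinSummary], int]:
    """Per-pair correlation of log-scale expression across shared samples.

    ``te_expr`` / ``gene_expr`` are feature-indexed DataFrames of
    log2(normalized+1) values over identical sample columns. Pairs whose TE or
    gene row has zero variance are dropped and counted. Returns (per-pair
    table, per-bin summaries with in_gene split by orientation, n_dropped).
    """
    if list(te_expr.columns) != list(gene_expr.columns):
        raise ValueError("TE and gene expression must share sample columns")
    if te_expr.shape[1] < 3:
        raise ValueError("need >= 3 samples for correlation")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    te_rows = _row_lookup(te_expr)
    gene_rows = _row_lookup(gene_expr)

    records = []
    n_dropped = 0
    for p in pairs:
        if p.distance_bin is None:
            continue
        t = te_rows.get(p.te_id)
        g = gene_rows.get(p.gene_id)
        if t is None or g is None:
            raise KeyError(f"missing expression row for pair ({p.te_id}, {p.gene_id})")
        if np.std(t) == 0 or np.std(g) == 0:
            n_dropped += 1
            continue
        if method == "pearson":
            r = stats.pearsonr(t, g).statistic
        else:
            r = stats.spearmanr(t, g).statistic
        records.append({
            "te_id": p.te_id, "gene_id": p.gene_id, "distance_bin": p.distance_bin,
            "orientation": p.orientation, "r": float(r),
        })
    per_pair = pd.DataFrame(records, columns=["te_id", "gene_id", "distance_bin",
                                              "orientation", "r"])

    summaries = []
    for bin_name, group in per_pair.groupby("distance_bin", sort=True):
        summaries.append(CorrelationBinSummary(
            bin=bin_name, orientation=None, n_pairs=len(group),
            correlations=group["r"].to_numpy(),
            median_r=float(group["r"].median()),
        ))
        if bin_name == "in_gene":
            for orient, og in group.groupby("orientation", sort=True):
                summaries.append(CorrelationBinSummary(
                    bin=bin_name, orientation=orient, n_pairs=len(og),
                    correlations=og["r"].to_numpy(),
                    median_r=float(og["r"].median()),
                ))
    return per_pair, summaries, n_dropped


def summaries_to_frame(summaries: Sequence[CorrelationBinSummary]) -> pd.DataFrame:
    return pd.DataFrame([
        {"bin": s.bin, "orientation": s.orientation if s.orientation else "all",
         "n_pairs": s.n_pairs, "median_r": s.median_r}
        for s in summaries
    ])
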