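"""SNP-based allele-specific expression on the X chromosome and dosage ratios."""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import CountMatrix, SampleSheet, Thresholds
from .te_expression import normalize

ALLELIC_CLASSES = ("monoallelic_ref", "monoallelic_alt", "biallelic", "uninformative")


def filter_informative(
    table: pd.DataFrame,
    samples: Sequence[str],
    min_reads: int = 10,
) -> list[str]:
    """Genes with at least ``min_reads`` total reads in every sample listed."""
    sub = table[table["sample_id"].isin(samples)].copy()
    extra = set(sub["sample_id"]) - set(samples)
    if extra:
        raise ValueError(f"table samples not under comparison: {sorted(extra)}")
    sub["total"] = sub["ref_reads"] + sub["alt_reads"]
    pivot = sub.pivot_table(index="gene_id", columns="sample_id", values="total",
                            aggfunc="sum", fill_value=0)
    pivot = pivot.reindex(columns=list(samples), fill_value=0)
    keep = pivot[(pivot >= min_reads).all(axis=1)].index.tolist()
    if not keep:
        warnings.warn("no informative genes after read filter")
    return sorted(keep)


def classify_allelic(
    table: pd.DataFrame,
    biallelic_band: float = 0.20,
    min_reads: int = 10,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per (gene, sample) allelic class from the alt-allele ratio.

    Biallelic iff the minor-allele fraction is at least ``biallelic_band``;
    otherwise monoallelic toward the major allele. Records with fewer than
    ``min_reads`` total reads are uninformative with a null ratio. Also
    returns the per-sample biallelic fraction among informative calls.
    """
    total = table["ref_reads"] + table["alt_reads"]
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = table["alt_reads"] / total
    informative = total >= min_reads
    # minor fraction from integer counts: exact ref/alt swap symmetry
    with np.errstate(invalid="ignore", divide="ignore"):
        minor = np.minimum(table["ref_reads"], table["alt_reads"]) / total
    cls = np.where(
        ~informative, "uninformative",
        np.where(minor >= biallelic_band, "biallelic",
                 np.where(ratio > 0.5, "monoallelic_alt", "monoallelic_ref")),
    )
    calls = pd.DataFrame({
        "gene_id": table["gene_id"],
        "sample_id": table["sample_id"],
        "allelic_ratio": ratio.where(informative, np.nan),
        "class": cls,
    })
    inf = calls[calls["class"] != "uninformative"]
    frac = inf.groupby("sample_id").apply(
        lambda g: (g["class"] == "biallelic").mean(), include_groups=False)
    return calls, frac


def dosage_ratio(
    expression: CountMatrix,
    x_genes: Sequence[str],
    autosome_genes: Sequence[str],
    group1: Sequence[str],
    group2: Sequence[str],
    use_normalized: bool = True,
) -> float:
    """X:autosome expression ratio of group1 divided by that of group2."""
    x_genes, autosome_genes = list(x_genes), list(autosome_genes)
    if not x_genes or not autosome_genes:
        raise ValueError("both gene sets must be non-empty")
    if use_normalized:
        values, _ = normalize(expression)
    else:
        values = expression.counts.astype(float)
    mat = pd.DataFrame(values, index=expression.feature_ids,
                       columns=expression.sample_ids)

    def xa(samples: Sequence[str]) -> float:
        auto = mat.loc[autosome_genes, list(samples)].to_numpy().sum()
        if auto == 0:
            raise ValueError("zero autosomal expression in a group")
        return mat.loc[x_genes, list(samples)].to_numpy().sum() / auto

    xa2 = xa(group2)
    if xa2 == 0:
        raise ValueError("zero X-linked expression in group2")
    return float(xa(group1) / xa2)
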