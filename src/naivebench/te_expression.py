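"""Normalization, differential expression, family polarization, top-N
composition, top-SD clustering, and PCA over locus-level count matrices.

The differential test is a Welch t on log2(normalized + 1) with
Benjamini-Hochberg adjustment across detected features. The original study
does not name its engine; this self-contained proxy keeps the published
gates (fold cutoff, p / adjusted-p cutoff) configurable and auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core import CountMatrix, Thresholds, round_half_up

DE_COLUMNS = ["feature_id", "base_mean", "log2fc", "p", "padj", "call", "detected"]


def normalize(cm: CountMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Median-of-ratios size factors; returns (normalized matrix, factors).

    Features with a zero in any sample are excluded from factor estimation.
    If none remain, falls back to library-size scaling with a warning.
    """
    if cm.n_samples < 2:
        raise ValueError("normalization needs >= 2 samples")
    counts = cm.counts.astype(float)
    all_positive = (counts > 0).all(axis=1)
    if all_positive.any():
        ref = counts[all_positive]
        geo_mean = np.exp(np.log(ref).mean(axis=1))
        factors = np.median(ref / geo_mean[:, None], axis=0)
    else:
        warnings.warn("no feature positive in all samples; library-size fallback")
        lib = counts.sum(axis=0)
        factors = lib / lib.mean()
    normalized = counts / factors[None, :]
    return normalized, factors


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def _welch_log_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Welch two-sided t-test p-values; degenerate rows handled."""
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(b, a, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.isnan(p)
    if degenerate.any():
        equal_means = np.isclose(b.mean(axis=1), a.mean(axis=1))
        p[degenerate & equal_means] = 1.0
        p[degenerate & ~equal_means] = 0.0
    return p


def differential_expression(
    cm: CountMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    thresholds: Thresholds = Thresholds(),
    labels: tuple[str, str] = ("A", "B"),
    use_raw_p: bool = False,
    detection_mean: float = 1.0,
) -> pd.DataFrame:
    """Per-feature DE of group B over group A.

    A feature is detected iff its normalized mean is >= ``detection_mean`` in
    at least one group; BH adjustment runs across detected features only.
    ``call`` is ``up_in_<label>`` gated by the fold cutoff and padj (or raw p
    with ``use_raw_p``).
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    sub = cm.subset_samples(group_a + group_b)
    normalized, _ = normalize(sub)
    ia = np.arange(len(group_a))
    ib = np.arange(len(group_a), len(group_a) + len(group_b))
    mean_a = normalized[:, ia].mean(axis=1)
    mean_b = normalized[:, ib].mean(axis=1)
    detected = (mean_a >= detection_mean) | (mean_b >= detection_mean)

    logm = np.log2(normalized + 1.0)
    log2fc = logm[:, ib].mean(axis=1) - logm[:, ia].mean(axis=1)
    p = np.full(cm.n_features, np.nan)
    p[detected] = _welch_log_t(logm[detected][:, ia], logm[detected][:, ib])
    padj = np.full(cm.n_features, np.nan)
    padj[detected] = bh_adjust(p[detected])

    gate = p < thresholds.p_cutoff if use_raw_p else padj < thresholds.padj_cutoff
    min_lfc = np.log2(thresholds.fold_cutoff)
    call = np.where(
        detected & gate & (log2fc >= min_lfc), f"up_in_{labels[1]}",
        np.where(detected & gate & (log2fc <= -min_lfc), f"up_in_{labels[0]}", "no_change"),
    )
    return pd.DataFrame({
        "feature_id": cm.feature_ids,
        "base_mean": normalized.mean(axis=1),
        "log2fc": log2fc,
        "p": p,
        "padj": padj,
        "call": call,
        "detected": detected,
    })


@dataclass(frozen=True)
class PolarizationSummary:
    family: str
    n_detected: int
    n_de: int
    pct_de: float
    n_up_naive: int
    n_up_primed: int
    pct_up_naive_of_de: float
    pct_up_primed_of_de: float


def polarization_summary(
    de: pd.DataFrame,
    families: Mapping[str, str],
    naive_label: str = "naive",
    primed_label: str = "primed",
) -> list[PolarizationSummary]:
    """Per-family detected/DE/direction counts with printed-style percentages."""
    missing = [f for f in de["feature_id"] if f not in families]
    if missing:
        raise ValueError(f"features without family labels: {missing[:5]}...")
    fam = de["feature_id"].map(families)
    out = []
    for family in sorted(fam.unique()):
        sub = de[fam == family]
        det = sub[sub["detected"]]
        n_detected = len(det)
        n_up_naive = int((det["call"] == f"up_in_{naive_label}").sum())
        n_up_primed = int((det["call"] == f"up_in_{primed_label}").sum())
        n_de = n_up_naive + n_up_primed
        out.append(PolarizationSummary(
            family=family,
            n_detected=n_detected,
            n_de=n_de,
            pct_de=round_half_up(100.0 * n_de / n_detected, 1) if n_detected else float("nan"),
            n_up_naive=n_up_naive,
            n_up_primed=n_up_primed,
            pct_up_naive_of_de=round_half_up(100.0 * n_up_naive / n_de, 1) if n_de else float("nan"),
            pct_up_primed_of_de=round_half_up(100.0 * n_up_primed / n_de, 1) if n_de else float("nan"),
        ))
    return out


def polarization_to_frame(rows: Sequence[PolarizationSummary]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])


def top_n_composition(
    de: pd.DataFrame,
    n: int,
    subfamilies: Mapping[str, str],
    rank_key: str = "abs",
) -> tuple[dict[str, int], int]:
    """Tally subfamily membership among the top-n DE features by fold change.

    ``rank_key``: "abs" ranks by \\|log2fc\\|, "signed" by log2fc (toward the
    B group), "signed_neg" toward the A group. Ties at rank n are included;
    the actual n used is returned.
    """
    de_set = de[de["call"] != "no_change"]
    if n > len(de_set):
        raise ValueError(f"n={n} exceeds {len(de_set)} differentially expressed features")
    if rank_key == "abs":
        key = de_set["log2fc"].abs()
    elif rank_key == "signed":
        key = de_set["log2fc"]
    elif rank_key == "signed_neg":
        key = -de_set["log2fc"]
    else:
        raise ValueError(f"unknown rank_key {rank_key!r}")
    ordered = de_set.assign(_key=key).sort_values(
        ["_key", "feature_id"], ascending=[False, True])
    cutoff = ordered["_key"].iloc[n - 1]
    top = ordered[ordered["_key"] >= cutoff]
    tally: dict[str, int] = {}
    for fid in top["feature_id"]:
        sub = subfamilies.get(fid, "unknown")
        tally[sub] = tally.get(sub, 0) + 1
    return tally, len(top)


def _sample_correlation_linkage(logm: np.ndarray) -> np.ndarray:
    corr = np.corrcoef(logm.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    return hierarchy.linkage(squareform(dist, checks=False), method="average")


def top_sd_cluster(
    cm: CountMatrix, n_top: int
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Select n_top features by SD of log2(normalized+1); average-linkage
    clustering of samples on 1 - Pearson distance; returns k=2 labels."""
    if n_top > cm.n_features:
        raise ValueError(f"n_top={n_top} exceeds {cm.n_features} features")
    normalized, _ = normalize(cm)
    logm = np.log2(normalized + 1.0)
    sd = logm.std(axis=1, ddof=1)
    if np.all(sd == 0):
        raise ValueError("zero variance: all features constant across samples")
    order = np.lexsort((np.array(cm.feature_ids), -sd))
    idx = order[:n_top]
    selected = [cm.feature_ids[i] for i in idx]
    linkage = _sample_correlation_linkage(logm[idx])
    labels = hierarchy.fcluster(linkage, t=2, criterion="maxclust")
    return selected, linkage, labels


def family_cluster_matrix(
    cm: CountMatrix, families: Mapping[str, str], wanted: set[str]
) -> CountMatrix:
    keep = [f for f in cm.feature_ids if families.get(f) in wanted]
    if not keep:
        raise ValueError(f"no features in families {sorted(wanted)}")
    return cm.subset_features(keep)


def pca(
    cm: CountMatrix, feature_subset: Optional[Sequence[str]] = None
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of samples on centered log2(normalized+1).

    Returns (coordinates [samples x 2], variance-explained fractions). Sign
    convention: the largest-magnitude feature loading of each PC is positive.
    """
    if cm.n_samples < 3:
        raise ValueError("PCA needs >= 3 samples")
    sub = cm if feature_subset is None else cm.subset_features(list(feature_subset))
    if sub.n_features < 2:
        raise ValueError("PCA needs >= 2 features")
    normalized, _ = normalize(sub)
    logm = np.log2(normalized + 1.0)
    x = logm.T - logm.T.mean(axis=0)  # samples x features, feature-centered
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    var = s**2
    var_explained = var / var.sum() if var.sum() > 0 else var
    coords = u[:, :2] * s[:2]
    return coords, var_explained[:2]
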