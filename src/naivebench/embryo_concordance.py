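"""Stage-specific feature detection in single-cell embryo profiles and
concordance with the naive/primed differential-expression calls."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .core import CountMatrix, SampleSheet, Thresholds
from .te_expression import _sample_correlation_linkage, normalize


@dataclass
class StageSpecificSet:
    stage: str
    table: pd.DataFrame  # columns: feature_id, p, fold

    @property
    def feature_ids(self) -> list[str]:
        return self.table["feature_id"].tolist()


def stage_specific_features(
    embryo: CountMatrix,
    sheet: SampleSheet,
    thresholds: Thresholds = Thresholds(),
    min_cells: int = 3,
) -> list[StageSpecificSet]:
    """Per stage, features enriched vs the pool of all other cells.

    Test: two-sided Wilcoxon rank-sum on log2(normalized+1), plus a mean-fold
    gate (normalized means, pseudocount 1) at ``thresholds.fold_cutoff``.
    Stages with fewer than ``min_cells`` cells are excluded with a warning.
    A feature may be specific to several stages.
    """
    stage_cells = {
        stage: [s for s in sheet.samples_in_stage(stage) if s in embryo.sample_ids]
        for stage in sheet.frame["stage"].dropna().unique()
    }
    stage_cells = {k: v for k, v in stage_cells.items() if v}
    usable = {}
    for stage, cells in stage_cells.items():
        if len(cells) < min_cells:
            warnings.warn(f"stage {stage!r} has {len(cells)} < {min_cells} cells; excluded")
        else:
            usable[stage] = cells
    if len(usable) < 2:
        raise ValueError("need >= 2 stages with enough cells")

    normalized, _ = normalize(embryo)
    logm = np.log2(normalized + 1.0)
    col = {s: i for i, s in enumerate(embryo.sample_ids)}
    all_cells = [c for cells in usable.values() for c in cells]

    out = []
    for stage in sorted(usable):
        in_idx = [col[c] for c in usable[stage]]
        out_idx = [col[c] for c in all_cells if c not in set(usable[stage])]
        a = logm[:, in_idx]
        b = logm[:, out_idx]
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.mannwhitneyu(a, b, axis=1, alternative="two-sided")
        p = np.asarray(res.pvalue, dtype=float)
        p[np.isnan(p)] = 1.0
        mean_in = normalized[:, in_idx].mean(axis=1)
        mean_out = normalized[:, out_idx].mean(axis=1)
        fold = (mean_in + 1.0) / (mean_out + 1.0)
        keep = (p < thresholds.p_cutoff) & (fold >= thresholds.fold_cutoff)
        table = pd.DataFrame({
            "feature_id": np.array(embryo.feature_ids)[keep],
            "p": p[keep],
            "fold": fold[keep],
        }).reset_index(drop=True)
        out.append(StageSpecificSet(stage=stage, table=table))
    return out


@dataclass
class ConcordanceRow:
    stage: str
    n_specific: int
    frac_up_naive: float
    frac_up_primed: float
    frac_no_change: float


def concordance(
    stage_sets: Sequence[StageSpecificSet],
    de: pd.DataFrame,
    naive_label: str = "naive",
    primed_label: str = "primed",
) -> list[ConcordanceRow]:
    """Fraction of each stage-specific set called up-in-naive / up-in-primed /
    unchanged in the ESC differential-expression result. Members absent from
    the DE table count as no_change."""
    call = dict(zip(de["feature_id"], de["call"]))
    rows = []
    for ss in stage_sets:
        n = len(ss.feature_ids)
        if n == 0:
            rows.append(ConcordanceRow(ss.stage, 0, float("nan"), float("nan"), float("nan")))
            continue
        calls = [call.get(f, "no_change") for f in ss.feature_ids]
        n_naive = sum(c == f"up_in_{naive_label}" for c in calls)
        n_primed = sum(c == f"up_in_{primed_label}" for c in calls)
        rows.append(ConcordanceRow(
            stage=ss.stage,
            n_specific=n,
            frac_up_naive=n_naive / n,
            frac_up_primed=n_primed / n,
            frac_no_change=(n - n_naive - n_primed) / n,
        ))
    return rows


def concordance_to_frame(rows: Sequence[ConcordanceRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])


def quantile_scale_to(reference: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Map each target column onto the reference's pooled quantile profile."""
    ref_sorted = np.sort(reference, axis=0).mean(axis=1)
    out = np.empty_like(target, dtype=float)
    for j in range(target.shape[1]):
        ranks = stats.rankdata(target[:, j], method="average") - 1
        q = ranks / max(target.shape[0] - 1, 1)
        out[:, j] = np.interp(q, np.linspace(0, 1, ref_sorted.size), ref_sorted)
    return out


def family_cluster(
    embryo: CountMatrix,
    esc: CountMatrix,
    families: Mapping[str, str],
    wanted: set[str],
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Joint clustering of embryo cells and ESC samples on one TE family set.

    The two matrices are quantile-scaled to the embryo profile before
    clustering (cross-dataset normalization is otherwise unspecified).
    Returns (sample order, linkage, k=2 labels).
    """
    keep = [f for f in embryo.feature_ids
            if families.get(f) in wanted and f in set(esc.feature_ids)]
    if not keep:
        raise ValueError(f"no shared features in families {sorted(wanted)}")
    emb = embryo.subset_features(keep)
    e = esc.subset_features(keep)
    if emb.n_samples + e.n_samples < 2:
        raise ValueError("need >= 2 samples total")
    emb_norm, _ = normalize(emb)
    esc_norm, _ = normalize(e)
    emb_log = np.log2(emb_norm + 1.0)
    esc_log = np.log2(esc_norm + 1.0)
    esc_scaled = quantile_scale_to(emb_log, esc_log)
    joint = np.hstack([emb_log, esc_scaled])
    linkage = _sample_correlation_linkage(joint)
    labels = hierarchy.fcluster(linkage, t=2, criterion="maxclust")
    return emb.sample_ids + e.sample_ids, linkage, labels
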