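"""Methylome summaries: global and regional coverage-weighted levels, the
overexpressed-TE methylation contrast, imprinted-DMR erasure classification,
and X-linked promoter-CGI methylation distributions.

Levels are always coverage-weighted: sum(meth_reads) / sum(total_reads) over
the sites in scope. CpG calls on the two strands are kept separate (allc
convention, no dyad merging).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import SampleSheet, Thresholds

MIN_DMR_SITES = 5  # DMRs with fewer covered CpGs are ineligible


def global_level(calls: pd.DataFrame, context: str) -> Optional[float]:
    """Coverage-weighted methylation over all sites of one context."""
    sub = calls[calls["context"] == context]
    total = int(sub["total_reads"].sum())
    if total == 0:
        warnings.warn(f"no covered sites in context {context!r}")
        return None
    return float(sub["meth_reads"].sum() / total)


def region_levels(
    calls: pd.DataFrame, regions: pd.DataFrame, context: str
) -> pd.DataFrame:
    """Weighted level per BED region (0-based half-open; membership on pos-1).

    Returns a DataFrame indexed by region name with columns
    weighted_level (NaN when uncovered), n_sites, mean_coverage.
    """
    sub = calls[calls["context"] == context]
    out_level = np.full(len(regions), np.nan)
    out_sites = np.zeros(len(regions), dtype=int)
    out_cov = np.full(len(regions), np.nan)
    by_chrom = {c: g.sort_values("pos") for c, g in sub.groupby("chrom")}
    for i, reg in enumerate(regions.itertuples(index=False)):
        g = by_chrom.get(reg.chrom)
        if g is None:
            continue
        pos = g["pos"].to_numpy()
        lo = np.searchsorted(pos, reg.start + 1, side="left")
        hi = np.searchsorted(pos, reg.end, side="right")
        if hi <= lo:
            continue
        meth = g["meth_reads"].to_numpy()[lo:hi]
        total = g["total_reads"].to_numpy()[lo:hi]
        covered = total > 0
        out_sites[i] = int(covered.sum())
        tot = int(total.sum())
        if tot > 0:
            out_level[i] = meth.sum() / tot
            out_cov[i] = total[covered].mean() if covered.any() else np.nan
    return pd.DataFrame({
        "region_id": regions["name"].to_numpy(),
        "context": context,
        "weighted_level": out_level,
        "n_sites": out_sites,
        "mean_coverage": out_cov,
    }).set_index("region_id")


def overexpressed_te_methylation(
    levels: pd.Series,
    overexpressed_ids: Sequence[str],
    background_ids: Sequence[str],
) -> tuple[float, float, Optional[float]]:
    """Median methylation of overexpressed vs background elements plus a
    two-sided Mann-Whitney p (None when either set has < 3 non-null levels)."""
    over = levels.reindex(overexpressed_ids).dropna().to_numpy()
    back = levels.reindex(background_ids).dropna().to_numpy()
    if over.size == 0 or back.size == 0:
        raise ValueError("both sets must have non-null levels")
    median_over = float(np.median(over))
    median_back = float(np.median(back))
    if over.size < 3 or back.size < 3:
        return median_over, median_back, None
    p = float(stats.mannwhitneyu(over, back, alternative="two-sided").pvalue)
    return median_over, median_back, p


@dataclass
class DMRCall:
    dmr_id: str
    primed_level: Optional[float]
    naive_level: Optional[float]
    reprimed_level: Optional[float]
    eligible: bool
    verdict: str  # erased | retained | ineligible
    reason: str = ""


def classify_imprinted_dmrs(
    primed: pd.DataFrame,
    naive: pd.DataFrame,
    reprimed: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
    denominator: str = "eligible",
) -> tuple[list[DMRCall], float]:
    """Trajectory rule: a DMR with intermediate primed methylation is erased
    iff both naive and re-primed levels fall below the erase cutoff; otherwise
    retained. DMRs outside the primed band, missing a state level, or with
    too few covered CpGs in any state are ineligible.

    ``denominator`` "eligible" divides erased by erased+retained;
    "all" divides by the full DMR count.
    """
    if denominator not in ("eligible", "all"):
        raise ValueError("denominator must be 'eligible' or 'all'")
    ids = list(primed.index)
    if set(ids) != set(naive.index) or set(ids) != set(reprimed.index):
        raise ValueError("DMR ids must match across the three states")
    lo, hi = thresholds.intermediate_band
    calls = []
    for dmr_id in ids:
        lv = {}
        reason = ""
        for name, df in (("primed", primed), ("naive", naive), ("reprimed", reprimed)):
            level = df.loc[dmr_id, "weighted_level"]
            n_sites = df.loc[dmr_id, "n_sites"] if "n_sites" in df.columns else MIN_DMR_SITES
            if pd.isna(level):
                reason = f"missing {name} level"
                lv[name] = None
            elif n_sites < MIN_DMR_SITES:
                reason = f"{name} has {int(n_sites)} < {MIN_DMR_SITES} covered CpGs"
                lv[name] = float(level)
            else:
                lv[name] = float(level)
        if reason:
            calls.append(DMRCall(dmr_id, lv["primed"], lv["naive"], lv["reprimed"],
                                 False, "ineligible", reason))
            continue
        eligible = lo <= lv["primed"] <= hi
        if not eligible:
            calls.append(DMRCall(dmr_id, lv["primed"], lv["naive"], lv["reprimed"],
                                 False, "ineligible", "primed level outside intermediate band"))
            continue
        erased = (lv["naive"] < thresholds.erase_level
                  and lv["reprimed"] < thresholds.erase_level)
        calls.append(DMRCall(dmr_id, lv["primed"], lv["naive"], lv["reprimed"],
                             True, "erased" if erased else "retained"))
    n_erased = sum(c.verdict == "erased" for c in calls)
    n_eligible = sum(c.eligible for c in calls)
    denom = n_eligible if denominator == "eligible" else len(calls)
    fraction_erased = n_erased / denom if denom else float("nan")
    return calls, fraction_erased


def dmr_calls_to_frame(calls: Sequence[DMRCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls])


def xlinked_cgi_methylation(
    per_sample_levels: Mapping[str, pd.Series],
    sheet: SampleSheet,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Per-sample distribution of X-linked promoter-CGI methylation.

    Flags samples whose median sits in the intermediate band — the signature
    of an inactive X in female primed lines. Raises if a sample has no
    non-null region levels.
    """
    lo, hi = thresholds.intermediate_band
    rows = []
    for sample_id, levels in per_sample_levels.items():
        vals = pd.Series(levels).dropna().to_numpy(dtype=float)
        if vals.size == 0:
            raise ValueError(f"sample {sample_id!r}: all region levels null")
        med = float(np.median(vals))
        rows.append({
            "sample_id": sample_id,
            "state": sheet.state_of(sample_id),
            "sex": sheet.frame.set_index("sample_id").loc[sample_id, "sex"],
            "n_regions": int(vals.size),
            "median": med,
            "q25": float(np.percentile(vals, 25)),
            "q75": float(np.percentile(vals, 75)),
            "intermediate": bool(lo <= med <= hi),
        })
    return pd.DataFrame(rows)
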