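"""ChIP/input log-ratio metaprofiles anchored at TE 5' ends."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import TELocus


@dataclass
class CoverageTrack:
    """Per-chromosome read counts on a fixed-width bin grid."""

    bin_width: int
    bins: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        self.bins = {c: np.asarray(v, dtype=float) for c, v in self.bins.items()}
        for chrom, v in self.bins.items():
            if (v < 0).any():
                raise ValueError(f"{chrom}: negative bin counts")

    @property
    def total_reads(self) -> float:
        return float(sum(v.sum() for v in self.bins.values()))

    @classmethod
    def from_bedgraph(cls, df: pd.DataFrame, bin_width: int) -> "CoverageTrack":
        bins: dict[str, np.ndarray] = {}
        for chrom, g in df.groupby("chrom"):
            n = int(np.ceil(g["end"].max() / bin_width))
            arr = np.zeros(n)
            for row in g.itertuples(index=False):
                if row.start % bin_width or row.end % bin_width:
                    raise ValueError("bedGraph intervals must align to the bin grid")
                arr[row.start // bin_width: row.end // bin_width] = row.value
            bins[chrom] = arr
        return cls(bin_width=bin_width, bins=bins)

    def to_bedgraph(self) -> pd.DataFrame:
        rows = []
        for chrom in sorted(self.bins):
            for i, v in enumerate(self.bins[chrom]):
                rows.append({"chrom": chrom, "start": i * self.bin_width,
                             "end": (i + 1) * self.bin_width, "value": v})
        return pd.DataFrame(rows)


@dataclass
class Metaprofile:
    offsets: np.ndarray  # bp, [-halfwidth .. +halfwidth]
    mean_log_ratio: np.ndarray
    n_anchors: int
    n_truncated: int = 0


def metaprofile(
    chip: CoverageTrack,
    input_: CoverageTrack,
    anchors: Sequence[TELocus],
    halfwidth: int = 20_000,
    eps: float = 1.0,
) -> Metaprofile:
    """Average log2(chip/input) in +/-halfwidth windows around anchor 5' ends.

    Both tracks are depth-normalized to a fixed target (mean 10 reads per
    bin), so scaling either track leaves the profile unchanged; ``eps``
    pseudo-reads per bin stabilize the ratio. The anchor is the start for +
    strand loci and the end for - strand; minus-strand windows are reversed so
    offsets run 5'->3'. Windows running off a chromosome are truncated (NaN
    padding, counted in ``n_truncated``).
    """
    if chip.bin_width != input_.bin_width:
        raise ValueError("tracks must share a bin grid")
    bw = chip.bin_width
    if halfwidth % bw:
        raise ValueError("halfwidth must be a multiple of bin_width")
    w = halfwidth // bw
    if chip.total_reads == 0 or input_.total_reads == 0:
        raise ValueError("empty track")
    n_bins_total = sum(len(v) for v in chip.bins.values())
    target = 10.0 * n_bins_total
    chip_scale = target / chip.total_reads
    input_scale = target / input_.total_reads

    n_offsets = 2 * w + 1
    acc = np.zeros(n_offsets)
    cnt = np.zeros(n_offsets, dtype=int)
    n_truncated = 0
    n_used = 0
    for a in anchors:
        c = chip.bins.get(a.chrom)
        i = input_.bins.get(a.chrom)
        if c is None or i is None:
            continue
        anchor_bp = a.start if a.strand == "+" else a.end - 1
        center = anchor_bp // bw
        lo, hi = center - w, center + w + 1
        window = np.full(n_offsets, np.nan)
        s_lo, s_hi = max(lo, 0), min(hi, len(c))
        if s_lo > lo or s_hi < hi:
            n_truncated += 1
        if s_hi <= s_lo:
            continue
        ratio = np.log2((c[s_lo:s_hi] * chip_scale + eps)
                        / (i[s_lo:s_hi] * input_scale + eps))
        window[s_lo - lo: s_hi - lo] = ratio
        if a.strand == "-":
            window = window[::-1]
        ok = ~np.isnan(window)
        acc[ok] += window[ok]
        cnt[ok] += 1
        n_used += 1
    if n_used == 0:
        raise ValueError("no usable anchors")
    with np.errstate(invalid="ignore"):
        mean = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    offsets = np.arange(-w, w + 1) * bw
    return Metaprofile(offsets=offsets, mean_log_ratio=mean,
                       n_anchors=n_used, n_truncated=n_truncated)


def metaprofile_to_frame(mp: Metaprofile) -> pd.DataFrame:
    return pd.DataFrame({"offset_bp": mp.offsets, "mean_log2_ratio": mp.mean_log_ratio})
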