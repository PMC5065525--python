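"""TE/gene interval models, LTR7-HERVH merging, and nearest-gene distance bins."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

DISTANCE_BINS = ("in_gene", "lt2.5kb", "2.5_5kb", "5_10kb", "10_20kb")
# half-open [lo, hi) bp edges for the non-overlap bins
_BIN_EDGES = ((0, 2_500, "lt2.5kb"), (2_500, 5_000, "2.5_5kb"),
              (5_000, 10_000, "5_10kb"), (10_000, 20_000, "10_20kb"))


@dataclass
class TELocus:
    id: str
    family: str
    subfamily: str
    chrom: str
    start: int
    end: int
    strand: str
    merged: bool = False
    constituents: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.id}: strand must be + or -")


@dataclass
class GeneLocus:
    id: str
    chrom: str
    start: int
    end: int
    strand: str
    is_krab_zfp: bool = False
    is_imprinted: bool = False
    is_x_linked: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.id}: start must be < end")


@dataclass
class TEGenePair:
    te_id: str
    gene_id: str
    distance: int
    distance_bin: Optional[str]
    orientation: str  # sense | antisense


def merge_ltr_int(loci: Sequence[TELocus], max_gap: int = 50) -> list[TELocus]:
    """Merge an LTR7 sitting 5'-adjacent to an HERVH-int into one element.

    On the + strand the LTR7 must end at most ``max_gap`` bp before the
    HERVH-int start; on the - strand it must start at most ``max_gap`` bp after
    the HERVH-int end. Everything else passes through unchanged. Idempotent:
    merged elements (family "LTR7-HERVH") are never re-merged.
    """
    ordered = sorted(loci, key=lambda l: (l.chrom, l.start, l.end, l.id))
    if [l.id for l in ordered] != [l.id for l in loci]:
        raise ValueError("loci must be sorted by (chrom, start)")
    _warn_same_family_overlaps(ordered)

    consumed: set[int] = set()
    out: list[TELocus] = []
    for i, a in enumerate(ordered):
        if i in consumed:
            continue
        partner = None
        if a.family in ("LTR7", "HERVH-int"):
            for j in range(i + 1, len(ordered)):
                b = ordered[j]
                if j in consumed:
                    continue
                if b.chrom != a.chrom or b.start - a.end > max_gap:
                    break
                if _is_five_prime_pair(a, b, max_gap):
                    partner = (j, b)
                    break
        if partner is None:
            out.append(a)
            continue
        j, b = partner
        consumed.add(j)
        out.append(TELocus(
            id=f"{a.id}|{b.id}",
            family="LTR7-HERVH",
            subfamily="LTR7-HERVH",
            chrom=a.chrom,
            start=min(a.start, b.start),
            end=max(a.end, b.end),
            strand=a.strand,
            merged=True,
            constituents=(a.id, b.id),
        ))
    return out


def _is_five_prime_pair(a: TELocus, b: TELocus, max_gap: int) -> bool:
    """True if (a, b) in coordinate order form LTR7 5' of HERVH-int."""
    if a.strand != b.strand or a.chrom != b.chrom:
        return False
    gap = b.start - a.end
    if gap < 0 or gap > max_gap:
        return False
    if a.strand == "+":
        return a.family == "LTR7" and b.family == "HERVH-int"
    return a.family == "HERVH-int" and b.family == "LTR7"


def _warn_same_family_overlaps(ordered: Sequence[TELocus]) -> None:
    for a, b in zip(ordered, ordered[1:]):
        if a.chrom == b.chrom and a.family == b.family and b.start < a.end:
            warnings.warn(
                f"overlapping same-family loci kept: {a.id}, {b.id}",
                stacklevel=3,
            )


def interval_distance(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Edge-to-edge gap between half-open intervals; 0 means overlap."""
    if a_start < b_end and b_start < a_end:
        return 0
    if a_end <= b_start:
        return b_start - a_end
    return a_start - b_end


def distance_to_bin(distance: int, overlapping: bool) -> Optional[str]:
    if overlapping:
        return "in_gene"
    for lo, hi, name in _BIN_EDGES:
        if lo <= distance < hi:
            return name
    return None


def assign_te_to_gene(
    tes: Sequence[TELocus],
    genes: Sequence[GeneLocus],
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[TEGenePair], list[str], list[TEGenePair]]:
    """Pair each TE with its closest gene by edge-to-edge distance.

    Overlap wins with distance 0 and bin "in_gene". Ties break toward the
    smaller gene_id. Returns (pairs, unpaired TE ids on gene-less chromosomes,
    random-control pairs built by permuting the gene assignment with ``rng``).
    """
    by_chrom: dict[str, list[GeneLocus]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    pairs: list[TEGenePair] = []
    unpaired: list[str] = []
    for te in tes:
        cands = by_chrom.get(te.chrom)
        if not cands:
            unpaired.append(te.id)
            continue
        best: Optional[GeneLocus] = None
        best_d = None
        for g in cands:
            d = interval_distance(te.start, te.end, g.start, g.end)
            if best_d is None or d < best_d or (d == best_d and g.id < best.id):
                best, best_d = g, d
        overlapping = best_d == 0 and te.start < best.end and best.start < te.end
        pairs.append(TEGenePair(
            te_id=te.id,
            gene_id=best.id,
            distance=best_d,
            distance_bin=distance_to_bin(best_d, overlapping),
            orientation="sense" if te.strand == best.strand else "antisense",
        ))

    random_pairs: list[TEGenePair] = []
    if rng is not None and pairs:
        gene_ids = [p.gene_id for p in pairs]
        perm = rng.permutation(len(gene_ids))
        for p, k in zip(pairs, perm):
            random_pairs.append(TEGenePair(
                te_id=p.te_id, gene_id=gene_ids[k], distance=-1,
                distance_bin="random", orientation=p.orientation,
            ))
    return pairs, unpaired, random_pairs


def te_loci_from_frame(anno: pd.DataFrame) -> list[TELocus]:
    return [
        TELocus(id=r.id, family=r.family, subfamily=r.subfamily, chrom=r.chrom,
                start=int(r.start), end=int(r.end), strand=r.strand)
        for r in anno.itertuples(index=False)
    ]


def pairs_to_frame(pairs: Iterable[TEGenePair]) -> pd.DataFrame:
    return pd.DataFrame([
        {"te_id": p.te_id, "gene_id": p.gene_id, "distance": p.distance,
         "distance_bin": p.distance_bin, "orientation": p.orientation}
        for p in pairs
    ])
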