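"""Synthetic input generators with the statistical structure the analyses
assume, plus the named presets used by the acceptance suite.

Every generator is a pure function of its configuration and seed: negative-
binomial RNA-seq counts with naive/primed family polarization, single-cell
embryo matrices with stage markers, bisulfite call tables with imprinted-DMR
trajectories and X-linked CGI structure, allelic SNP counts, distance-coupled
TE-gene expression, ChIP/input tracks, and qPCR dilution plates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotations import GeneLocus, TELocus
from .chromatin_profile import CoverageTrack
from .chimera_qpcr import QpcrPlate
from .core import CountMatrix, SampleSheet, substream

DEFAULT_FAMILY_COUNTS = {
    "SVA": 2000,
    "HERVH-int": 2000,
    "LTR7": 1500,
    "LTR5_Hs": 500,
    "L1": 3000,
    "AluY": 3000,
}

NAIVE_FAMILIES = ("SVA", "LTR5_Hs")
PRIMED_FAMILIES = ("HERVH-int", "LTR7")

SVA_SUBFAMILIES = ("SVA_A", "SVA_B", "SVA_C", "SVA_D", "SVA_E", "SVA_F")
SVA_SUBFAMILY_WEIGHTS = (0.08, 0.12, 0.10, 0.45, 0.15, 0.10)

_FAMILY_LENGTH = {"SVA": 1500, "HERVH-int": 5000, "LTR7": 450,
                  "LTR5_Hs": 1000, "L1": 3000, "AluY": 300}

TOY_CHROMS = ("chrS1", "chrS2", "chrS3", "chrS4", "chrS5")


@dataclass
class MethylomeConfig:
    n_cpg: int = 20_000
    n_ch: int = 20_000
    coverage_mean: int = 30
    global_cpg: Mapping[str, float] = field(default_factory=lambda: {
        "primed": 0.810, "naive_5iLA": 0.269, "reprimed": 0.780})
    global_ch: Mapping[str, float] = field(default_factory=lambda: {
        "primed": 0.0060, "naive_5iLA": 0.0019, "reprimed": 0.0050})
    sex: Mapping[str, str] = field(default_factory=dict)  # sample -> sex; default female
    n_x_cgi: int = 100
    cpgs_per_cgi: int = 8
    x_cgi_intermediate: float = 0.50
    x_cgi_low: float = 0.08

    def __post_init__(self) -> None:
        if self.coverage_mean < 1:
            raise ValueError("coverage_mean must be >= 1")
        for d in (self.global_cpg, self.global_ch):
            for state, level in d.items():
                if not 0.0 <= level <= 1.0:
                    raise ValueError(f"level for {state} outside [0,1]")


@dataclass
class ImprintConfig:
    n_dmrs: int = 100
    n_erased: int = 77
    cpgs_per_dmr: int = 20
    primed_level_range: tuple[float, float] = (0.40, 0.60)
    erased_level: float = 0.05
    protected_reprimed_level: float = 0.50

    def __post_init__(self) -> None:
        if self.n_erased > self.n_dmrs:
            raise ValueError("n_erased must be <= n_dmrs")
        lo, hi = self.primed_level_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("primed_level_range must be an interval in [0,1]")


@dataclass
class AllelicConfig:
    n_genes: int = 200
    coverage_mean: int = 50
    biallelic_fraction: Mapping[str, float] = field(default_factory=lambda: {
        "primed": 0.1, "naive_5iLA": 0.9})
    error_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.coverage_mean < 1:
            raise ValueError("coverage_mean must be >= 1")
        for state, f in self.biallelic_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"biallelic_fraction[{state}] outside [0,1]")


@dataclass
class ConcordanceConfig:
    marker_stage: str = "morula"
    n_markers: int = 876
    n_naive_up: int = 543
    n_background: int = 1124
    stages: tuple[str, ...] = ("eight_cell", "morula", "late_blastocyst_EPI")
    cells_per_stage: int = 8
    marker_families: tuple[str, ...] = ("SVA", "LTR5_Hs")

    def __post_init__(self) -> None:
        if self.n_naive_up > self.n_markers:
            raise ValueError("n_naive_up must be <= n_markers")
        if self.marker_stage not in self.stages:
            raise ValueError("marker_stage must be one of stages")
        if len(self.stages) < 2 or self.cells_per_stage < 5:
            raise ValueError("need >= 2 stages and >= 5 cells per stage")


@dataclass
class QpcrConfig:
    standards_log10: tuple[float, ...] = (-1.0, -2.0, -3.0, -4.0, -5.0)
    slope: float = -3.321928094887362  # -1/log10(2): perfect doubling
    intercept: float = 12.0
    noise_sd: float = 0.15
    ct_ceiling: float = 40.0
    # condition -> (n_embryos, list of true positive fractions among them)
    conditions: Mapping[str, tuple[int, tuple[float, ...]]] = field(
        default_factory=lambda: {
            "naive_4iLA": (660, (3e-4, 2e-4, 1e-4, 5e-4, 1.5e-4, 1e-4)),
            "naive_5iLA": (139, (2e-4,)),
        })

    def __post_init__(self) -> None:
        span = max(self.standards_log10) - min(self.standards_log10)
        if span < 4:
            raise ValueError("dilution series must span >= 4 decades")


@dataclass
class SimConfig:
    seed: int = 0
    n_te_loci: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_FAMILY_COUNTS))
    n_genes: int = 300
    n_replicates: int = 3
    states: tuple[str, ...] = ("primed", "naive_5iLA")
    library_size: float = 3_000_000.0
    dispersion: float = 0.03
    effect_log2fc: float = 2.0
    polarized_fraction: float = 0.9
    methylome: MethylomeConfig = field(default_factory=MethylomeConfig)
    imprint: ImprintConfig = field(default_factory=ImprintConfig)
    allelic: AllelicConfig = field(default_factory=AllelicConfig)
    concordance: ConcordanceConfig = field(default_factory=ConcordanceConfig)
    qpcr: QpcrConfig = field(default_factory=QpcrConfig)

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0.0 <= self.polarized_fraction <= 1.0:
            raise ValueError("polarized_fraction must be in [0,1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """Gamma-Poisson draw: mean ``mean``, variance mean + phi*mean^2."""
    mean = np.asarray(mean, dtype=float)
    if phi == 0:
        return rng.poisson(mean)
    lam = rng.gamma(1.0 / phi, mean * phi)
    return rng.poisson(lam)


def _place_loci(rng: np.random.Generator, families: Sequence[str],
                lengths: Sequence[int]) -> pd.DataFrame:
    """Non-overlapping coordinates on toy chromosomes, round-robin."""
    n = len(families)
    chrom_idx = np.arange(n) % len(TOY_CHROMS)
    cursors = {c: 10_000 for c in TOY_CHROMS}
    rows = []
    strands = rng.choice(["+", "-"], size=n)
    gaps = rng.integers(2_000, 20_000, size=n)
    for i in range(n):
        chrom = TOY_CHROMS[chrom_idx[i]]
        start = cursors[chrom]
        end = start + lengths[i]
        cursors[chrom] = end + int(gaps[i])
        rows.append({"chrom": chrom, "start": start, "end": end, "strand": strands[i]})
    return pd.DataFrame(rows)


@dataclass
class TESim:
    counts: CountMatrix
    annotation: pd.DataFrame  # id, family, subfamily, chrom, start, end, strand
    truth: pd.DataFrame       # te_id, family, subfamily, true_direction
    sheet: SampleSheet


def _esc_sheet(states: Sequence[str], n_replicates: int,
               sex: str = "female") -> SampleSheet:
    records = []
    for state in states:
        for rep in range(1, n_replicates + 1):
            records.append({"sample_id": f"{state}_r{rep}", "state": state,
                            "stage": None, "sex": sex, "replicate": rep})
    return SampleSheet.from_records(records)


def gen_te_counts(cfg: SimConfig, seed: Optional[int] = None) -> TESim:
    """Locus-level TE counts with naive/primed family polarization.

    Designated loci of SVA/LTR5_Hs carry +effect_log2fc in naive states and
    HERVH-int/LTR7 loci carry it in primed; the truth table records each
    locus's true direction (naive_up / primed_up / none).
    """
    rng = substream(cfg.seed if seed is None else seed, "te_counts")
    ids, families, subfams, lengths = [], [], [], []
    for family in sorted(cfg.n_te_loci):
        count = cfg.n_te_loci[family]
        for i in range(count):
            ids.append(f"{family}_{i:05d}")
            families.append(family)
            if family == "SVA":
                subfams.append(rng.choice(SVA_SUBFAMILIES, p=SVA_SUBFAMILY_WEIGHTS))
            else:
                subfams.append(family)
            lengths.append(max(100, int(rng.normal(_FAMILY_LENGTH.get(family, 1000), 100))))
    coords = _place_loci(rng, families, lengths)
    anno = pd.DataFrame({"id": ids, "family": families, "subfamily": subfams})
    anno = pd.concat([anno, coords], axis=1)

    fam_arr = np.array(families)
    polarized = rng.random(len(ids)) < cfg.polarized_fraction
    direction = np.where(
        np.isin(fam_arr, NAIVE_FAMILIES) & polarized, "naive_up",
        np.where(np.isin(fam_arr, PRIMED_FAMILIES) & polarized, "primed_up", "none"))
    truth = pd.DataFrame({"te_id": ids, "family": families,
                          "subfamily": subfams, "true_direction": direction})

    sheet = _esc_sheet(cfg.states, cfg.n_replicates)
    n_feat = len(ids)
    baseline = (cfg.library_size / n_feat) * rng.lognormal(0.0, 0.8, size=n_feat)
    effect = 2.0 ** cfg.effect_log2fc
    sample_factor = rng.lognormal(0.0, 0.1, size=len(sheet.sample_ids))
    cols = []
    for j, sid in enumerate(sheet.sample_ids):
        state = sheet.state_of(sid)
        mean = baseline.copy()
        if state.startswith("naive"):
            mean = np.where(direction == "naive_up", mean * effect, mean)
        elif state in ("primed", "reprimed"):
            mean = np.where(direction == "primed_up", mean * effect, mean)
        cols.append(_nb_counts(rng, mean * sample_factor[j], cfg.dispersion))
    counts = CountMatrix(ids, sheet.sample_ids, np.column_stack(cols))
    return TESim(counts=counts, annotation=anno, truth=truth, sheet=sheet)


@dataclass
class EmbryoSim:
    counts: CountMatrix
    sheet: SampleSheet
    truth: pd.DataFrame  # feature_id, marker_stage (or "none")


def gen_embryo_counts(
    cfg: SimConfig,
    feature_ids: Sequence[str],
    markers: Mapping[str, Sequence[str]],
    seed: Optional[int] = None,
    baseline: Optional[np.ndarray] = None,
) -> EmbryoSim:
    """Single-cell embryo counts; each stage's markers are elevated by
    effect_log2fc in that stage only."""
    cc = cfg.concordance
    if len(cc.stages) < 2 or cc.cells_per_stage < 5:
        raise ValueError("need >= 2 stages and >= 5 cells per stage")
    rng = substream(cfg.seed if seed is None else seed, "embryo_counts")
    feature_ids = list(feature_ids)
    marker_stage = pd.Series("none", index=feature_ids, dtype=object)
    for stage, feats in markers.items():
        if stage not in cc.stages:
            raise ValueError(f"marker stage {stage!r} not in configured stages")
        marker_stage.loc[list(feats)] = stage

    records = []
    for stage in cc.stages:
        for k in range(1, cc.cells_per_stage + 1):
            records.append({"sample_id": f"{stage}_c{k}", "state": "embryo",
                            "stage": stage, "sex": "unknown", "replicate": k})
    sheet = SampleSheet.from_records(records)

    n_feat = len(feature_ids)
    if baseline is None:
        baseline = (cfg.library_size / max(n_feat, 1)) * rng.lognormal(0.0, 0.8,
                                                                       size=n_feat)
    effect = 2.0 ** cfg.effect_log2fc
    cols = []
    for sid in sheet.sample_ids:
        stage = sheet.frame.set_index("sample_id").loc[sid, "stage"]
        mean = np.where(marker_stage.to_numpy() == stage, baseline * effect, baseline)
        cols.append(_nb_counts(rng, mean, cfg.dispersion))
    counts = CountMatrix(feature_ids, sheet.sample_ids, np.column_stack(cols))
    truth = pd.DataFrame({"feature_id": feature_ids,
                          "marker_stage": marker_stage.to_numpy()})
    return EmbryoSim(counts=counts, sheet=sheet, truth=truth)


@dataclass
class ConcordanceSim:
    embryo: EmbryoSim
    esc: TESim
    truth: pd.DataFrame  # te_id, is_marker, is_naive_up


def gen_concordance(cfg: SimConfig, seed: Optional[int] = None) -> ConcordanceSim:
    """Joint embryo + ESC simulation for a stage-concordance preset.

    ``n_markers`` TEs (drawn from the naive-biased families) are elevated in
    the marker stage of the embryo matrix; a designated subset of
    ``n_naive_up`` of them additionally carries naive upregulation in the ESC
    matrix. Background TEs carry neither.
    """
    seed = cfg.seed if seed is None else seed
    cc = cfg.concordance
    rng = substream(seed, "concordance_design")
    n_total = cc.n_markers + cc.n_background
    # marker-family pool 1.5x the marker count: markers must be a proper
    # subset or stage elevation is a constant shift invisible to correlation
    per_marker_family = (3 * cc.n_markers) // (2 * len(cc.marker_families)) + 1
    fam_counts = {f: per_marker_family for f in cc.marker_families}
    fam_counts["L1"] = cc.n_background // 2
    fam_counts["AluY"] = n_total - sum(fam_counts.values())

    te_cfg = replace(cfg, n_te_loci=fam_counts, polarized_fraction=0.0, seed=seed)
    esc = gen_te_counts(te_cfg, seed=seed)

    marker_pool = esc.truth.loc[
        esc.truth["family"].isin(cc.marker_families), "te_id"].to_numpy()
    marker_ids = rng.choice(marker_pool, size=cc.n_markers, replace=False)
    naive_up_ids = set(rng.choice(marker_ids, size=cc.n_naive_up, replace=False))
    # matched primed-up background set keeps the DE landscape balanced so
    # median-of-ratios normalization does not absorb the naive effect
    background_pool = esc.truth.loc[
        ~esc.truth["family"].isin(cc.marker_families), "te_id"].to_numpy()
    n_primed_up = min(cc.n_naive_up, len(background_pool))
    primed_up_ids = set(rng.choice(background_pool, size=n_primed_up, replace=False))

    # rebuild ESC counts with the designated directions
    direction = np.where(
        np.isin(esc.counts.feature_ids, list(naive_up_ids)), "naive_up",
        np.where(np.isin(esc.counts.feature_ids, list(primed_up_ids)),
                 "primed_up", "none"))
    truth = esc.truth.copy()
    truth["true_direction"] = direction
    rng2 = substream(seed, "concordance_esc")
    n_feat = esc.counts.n_features
    baseline = (cfg.library_size / n_feat) * rng2.lognormal(0.0, 0.8, size=n_feat)
    effect = 2.0 ** cfg.effect_log2fc
    cols = []
    for sid in esc.sheet.sample_ids:
        state = esc.sheet.state_of(sid)
        if state.startswith("naive"):
            mean = np.where(direction == "naive_up", baseline * effect, baseline)
        else:
            mean = np.where(direction == "primed_up", baseline * effect, baseline)
        cols.append(_nb_counts(rng2, mean, cfg.dispersion))
    esc = TESim(
        counts=CountMatrix(esc.counts.feature_ids, esc.sheet.sample_ids,
                           np.column_stack(cols)),
        annotation=esc.annotation, truth=truth, sheet=esc.sheet)

    # sharing the per-locus baseline keeps cross-dataset correlation structure
    # driven by state, not by dataset identity
    embryo = gen_embryo_counts(
        cfg, esc.counts.feature_ids, {cc.marker_stage: list(marker_ids)},
        seed=seed, baseline=baseline)
    marker_set = set(marker_ids)
    joint = pd.DataFrame({
        "te_id": esc.counts.feature_ids,
        "is_marker": [f in marker_set for f in esc.counts.feature_ids],
        "is_naive_up": [f in naive_up_ids for f in esc.counts.feature_ids],
    })
    return ConcordanceSim(embryo=embryo, esc=esc, truth=joint)


@dataclass
class MethylomeSim:
    calls: dict[str, pd.DataFrame]  # sample_id -> allc-style table
    samples: pd.DataFrame           # sample_id, state, sex
    regions: dict[str, pd.DataFrame]  # "dmrs", "x_cgi" BED frames
    dmr_truth: pd.DataFrame         # dmr_id, truth in {erased, protected}


def _binom_calls(rng, n_sites, coverage_mean, level) -> tuple[np.ndarray, np.ndarray]:
    total = np.maximum(rng.poisson(coverage_mean, size=n_sites), 1)
    meth = rng.binomial(total, np.broadcast_to(level, n_sites))
    return meth, total


def gen_methylome(cfg: SimConfig, seed: Optional[int] = None) -> MethylomeSim:
    """Per-sample bisulfite call tables: global CpG/CH backbones at the
    per-state design levels, imprinted DMRs following the erased/protected
    trajectories, and X-linked promoter CGIs (intermediate only in female
    primed/re-primed samples)."""
    seed = cfg.seed if seed is None else seed
    mc, ic = cfg.methylome, cfg.imprint
    rng = substream(seed, "methylome")

    states = list(mc.global_cpg)
    samples = pd.DataFrame({
        "sample_id": states,
        "state": states,
        "sex": [mc.sex.get(s, "female") for s in states],
    })

    # site coordinates (shared across samples)
    cpg_pos = 1 + 20 * np.arange(mc.n_cpg)                 # chrS1
    ch_pos = 1 + 20 * np.arange(mc.n_ch)                   # chrS3
    dmr_rows, dmr_pos = [], []
    cursor = 10_000
    for d in range(ic.n_dmrs):
        start = cursor
        end = start + ic.cpgs_per_dmr * 50
        dmr_rows.append({"chrom": "chrS2", "start": start, "end": end,
                         "name": f"DMR_{d:03d}", "score": 0, "strand": "."})
        dmr_pos.append(start + 1 + 50 * np.arange(ic.cpgs_per_dmr))
        cursor = end + 5_000
    dmrs = pd.DataFrame(dmr_rows, columns=["chrom", "start", "end", "name",
                                           "score", "strand"])
    cgi_rows, cgi_pos = [], []
    cursor = 10_000
    for c in range(mc.n_x_cgi):
        start = cursor
        end = start + mc.cpgs_per_cgi * 40
        cgi_rows.append({"chrom": "chrX", "start": start, "end": end,
                         "name": f"XCGI_{c:03d}", "score": 0, "strand": "."})
        cgi_pos.append(start + 1 + 40 * np.arange(mc.cpgs_per_cgi))
        cursor = end + 4_000
    x_cgi = pd.DataFrame(cgi_rows, columns=["chrom", "start", "end", "name",
                                            "score", "strand"])

    erased_truth = np.array(["erased"] * ic.n_erased
                            + ["protected"] * (ic.n_dmrs - ic.n_erased))
    rng.shuffle(erased_truth)
    lo, hi = ic.primed_level_range
    primed_dmr_levels = rng.uniform(lo, hi, size=ic.n_dmrs)
    dmr_truth = pd.DataFrame({"dmr_id": dmrs["name"], "truth": erased_truth,
                              "primed_level": primed_dmr_levels})

    def state_dmr_level(state: str, d: int) -> float:
        if state in ("primed",):
            return primed_dmr_levels[d]
        if state == "reprimed":
            return (ic.erased_level if erased_truth[d] == "erased"
                    else ic.protected_reprimed_level)
        return ic.erased_level  # naive states: demethylated either way

    calls: dict[str, pd.DataFrame] = {}
    for row in samples.itertuples(index=False):
        parts = []
        meth, total = _binom_calls(rng, mc.n_cpg, mc.coverage_mean,
                                   mc.global_cpg[row.state])
        parts.append(pd.DataFrame({"chrom": "chrS1", "pos": cpg_pos, "strand": "+",
                                   "context": "CpG", "meth_reads": meth,
                                   "total_reads": total}))
        meth, total = _binom_calls(rng, mc.n_ch, mc.coverage_mean,
                                   mc.global_ch.get(row.state, 0.0))
        parts.append(pd.DataFrame({"chrom": "chrS3", "pos": ch_pos, "strand": "+",
                                   "context": "CH", "meth_reads": meth,
                                   "total_reads": total}))
        for d in range(ic.n_dmrs):
            level = state_dmr_level(row.state, d)
            meth, total = _binom_calls(rng, ic.cpgs_per_dmr, mc.coverage_mean, level)
            parts.append(pd.DataFrame({"chrom": "chrS2", "pos": dmr_pos[d],
                                       "strand": "+", "context": "CpG",
                                       "meth_reads": meth, "total_reads": total}))
        intermediate_x = (row.sex == "female"
                          and row.state in ("primed", "reprimed"))
        x_level = mc.x_cgi_intermediate if intermediate_x else mc.x_cgi_low
        for c in range(mc.n_x_cgi):
            meth, total = _binom_calls(rng, mc.cpgs_per_cgi, mc.coverage_mean, x_level)
            parts.append(pd.DataFrame({"chrom": "chrX", "pos": cgi_pos[c],
                                       "strand": "+", "context": "CpG",
                                       "meth_reads": meth, "total_reads": total}))
        calls[row.sample_id] = pd.concat(parts, ignore_index=True)

    return MethylomeSim(calls=calls, samples=samples,
                        regions={"dmrs": dmrs, "x_cgi": x_cgi},
                        dmr_truth=dmr_truth)


@dataclass
class AllelicSim:
    table: pd.DataFrame  # gene_id, sample_id, ref_reads, alt_reads, escapes_xci
    truth: pd.DataFrame  # gene_id, sample_id, truth_class
    sheet: SampleSheet


def gen_allelic_counts(cfg: SimConfig, seed: Optional[int] = None) -> AllelicSim:
    """Per-gene, per-sample (ref, alt) reads: monoallelic genes split ~1:0
    with a small error rate; biallelic genes are Beta-balanced."""
    seed = cfg.seed if seed is None else seed
    ac = cfg.allelic
    rng = substream(seed, "allelic")
    states = list(ac.biallelic_fraction)
    sheet = _esc_sheet(states, 1)
    genes = [f"XG_{i:04d}" for i in range(ac.n_genes)]
    rows, truth_rows = [], []
    for state in states:
        sid = f"{state}_r1"
        bi = rng.random(ac.n_genes) < ac.biallelic_fraction[state]
        coverage = np.maximum(rng.poisson(ac.coverage_mean, size=ac.n_genes), 1)
        for g in range(ac.n_genes):
            if bi[g]:
                ratio = rng.beta(20, 20)
                truth_class = "biallelic"
            else:
                toward_alt = rng.random() < 0.5
                ratio = 1.0 - ac.error_rate if toward_alt else ac.error_rate
                truth_class = "monoallelic_alt" if toward_alt else "monoallelic_ref"
            alt = rng.binomial(coverage[g], ratio)
            rows.append({"gene_id": genes[g], "sample_id": sid,
                         "ref_reads": int(coverage[g] - alt), "alt_reads": int(alt),
                         "escapes_xci": False})
            truth_rows.append({"gene_id": genes[g], "sample_id": sid,
                               "truth_class": truth_class})
    return AllelicSim(table=pd.DataFrame(rows), truth=pd.DataFrame(truth_rows),
                      sheet=sheet)


@dataclass
class TeGeneSim:
    tes: list[TELocus]
    genes: list[GeneLocus]
    te_expr: pd.DataFrame    # log2 expression, features x samples
    gene_expr: pd.DataFrame
    design_r: Mapping[str, float]


_BIN_TARGET_R = {"in_gene": 0.80, "lt2.5kb": 0.65, "2.5_5kb": 0.50,
                 "5_10kb": 0.35, "10_20kb": 0.20}
_BIN_OFFSET = {"in_gene": 0, "lt2.5kb": 1_000, "2.5_5kb": 3_000,
               "5_10kb": 7_000, "10_20kb": 15_000}


def gen_te_gene_coupled(cfg: SimConfig, n_samples: int = 12,
                        seed: Optional[int] = None) -> TeGeneSim:
    """TE-gene pairs whose expression coupling decays with genomic distance.

    Each gene gets one TE placed in a designated distance bin; the TE's
    log-expression is a noisy copy of the gene's with correlation set by the
    bin. Coupling carries no strand effect.
    """
    seed = cfg.seed if seed is None else seed
    rng = substream(seed, "te_gene")
    bins = list(_BIN_TARGET_R)
    genes, tes = [], []
    gene_expr, te_expr = {}, {}
    spacing = 120_000
    for i in range(cfg.n_genes):
        gstart = 50_000 + i * spacing
        gend = gstart + 20_000
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"G_{i:04d}"
        genes.append(GeneLocus(id=gid, chrom="chrS1", start=gstart, end=gend,
                               strand=strand))
        bin_name = bins[i % len(bins)]
        offset = _BIN_OFFSET[bin_name]
        if bin_name == "in_gene":
            t_start = gstart + 5_000
        else:
            t_start = gend + offset
        tid = f"T_{i:04d}"
        tes.append(TELocus(id=tid, family="SVA", subfamily="SVA_D", chrom="chrS1",
                           start=t_start, end=t_start + 1_500,
                           strand="+" if rng.random() < 0.5 else "-"))
        g_vals = rng.normal(5.0, 2.0, size=n_samples)
        r = _BIN_TARGET_R[bin_name]
        noise = rng.normal(0.0, 2.0, size=n_samples)
        t_vals = r * (g_vals - 5.0) + np.sqrt(1 - r**2) * noise + 4.0
        gene_expr[gid] = g_vals
        te_expr[tid] = t_vals
    samples = [f"s{j}" for j in range(n_samples)]
    return TeGeneSim(
        tes=tes, genes=genes,
        te_expr=pd.DataFrame(te_expr, index=samples).T,
        gene_expr=pd.DataFrame(gene_expr, index=samples).T,
        design_r=dict(_BIN_TARGET_R),
    )


@dataclass
class ChipSim:
    chip: CoverageTrack
    input: CoverageTrack
    anchors: list[TELocus]


def gen_chip_tracks(cfg: SimConfig, n_anchors: int = 50, bin_width: int = 100,
                    enrichment: float = 3.0, seed: Optional[int] = None) -> ChipSim:
    """Poisson input track plus a ChIP track enriched around anchor 5' ends."""
    seed = cfg.seed if seed is None else seed
    rng = substream(seed, "chip")
    spacing = 45_000
    chrom_len = 60_000 + n_anchors * spacing
    n_bins = chrom_len // bin_width
    input_bins = rng.poisson(10.0, size=n_bins).astype(float)
    chip_bins = rng.poisson(10.0, size=n_bins).astype(float)
    anchors = []
    for i in range(n_anchors):
        start = 30_000 + i * spacing
        strand = "+" if i % 2 == 0 else "-"
        anchors.append(TELocus(id=f"A_{i:03d}", family="SVA", subfamily="SVA_D",
                               chrom="chrS1", start=start, end=start + 1_500,
                               strand=strand))
        five_prime = start if strand == "+" else start + 1_500 - 1
        center = five_prime // bin_width
        lo, hi = max(center - 5, 0), min(center + 6, n_bins)
        chip_bins[lo:hi] += rng.poisson(10.0 * enrichment, size=hi - lo)
    return ChipSim(
        chip=CoverageTrack(bin_width=bin_width, bins={"chrS1": chip_bins}),
        input=CoverageTrack(bin_width=bin_width, bins={"chrS1": input_bins}),
        anchors=anchors,
    )


def gen_qpcr_plate(cfg: SimConfig, seed: Optional[int] = None) -> QpcrPlate:
    """Standards on an ideal log-linear curve plus embryo unknowns; wells whose
    expected ct exceeds the ceiling come out as non-detects."""
    seed = cfg.seed if seed is None else seed
    qc = cfg.qpcr
    rng = substream(seed, "qpcr")

    def ct_of(fraction: float) -> float:
        ct = qc.intercept + qc.slope * np.log10(fraction)
        if qc.noise_sd > 0:
            ct += rng.normal(0.0, qc.noise_sd)
        return float(ct)

    standards = pd.DataFrame({
        "log10_fraction": qc.standards_log10,
        "ct": [ct_of(10.0**lf) for lf in qc.standards_log10],
    })
    rows = []
    for condition, (n_embryos, positives) in qc.conditions.items():
        fractions = np.zeros(n_embryos)
        fractions[: len(positives)] = positives
        rng.shuffle(fractions)
        for k, f in enumerate(fractions):
            ct = ct_of(f) if f > 0 else np.inf
            rows.append({"id": f"{condition}_e{k:04d}", "condition": condition,
                         "ct": ct if ct < qc.ct_ceiling else np.nan})
    unknowns = pd.DataFrame(rows)
    return QpcrPlate(standards=standards, unknowns=unknowns, ct_ceiling=qc.ct_ceiling)


# ---------------------------------------------------------------------------
# Named presets pinning all parameters used by the acceptance targets.

def get_preset(name: str) -> SimConfig:
    if name == "default":
        return SimConfig()
    if name == "imprint_4iLA":
        return SimConfig(
            states=("primed", "naive_4iLA"),
            methylome=MethylomeConfig(
                n_cpg=2_000, n_ch=2_000,
                global_cpg={"primed": 0.752, "naive_4iLA": 0.332, "reprimed": 0.780},
                global_ch={"primed": 0.0032, "naive_4iLA": 0.0029, "reprimed": 0.0060}),
            imprint=ImprintConfig(n_dmrs=100, n_erased=77, cpgs_per_dmr=20),
        )
    if name == "imprint_5iLA":
        return SimConfig(
            methylome=MethylomeConfig(
                n_cpg=2_000, n_ch=2_000,
                global_cpg={"primed": 0.810, "naive_5iLA": 0.269, "reprimed": 0.780},
                global_ch={"primed": 0.0060, "naive_5iLA": 0.0019, "reprimed": 0.0050}),
            imprint=ImprintConfig(n_dmrs=100, n_erased=71, cpgs_per_dmr=20),
        )
    if name == "methylome_global":
        # pure global backbone: no DMR or CGI sites mixed into the table
        return SimConfig(
            methylome=MethylomeConfig(
                n_cpg=100_000, n_ch=100_000,
                global_cpg={"primed": 0.810, "naive_5iLA": 0.269},
                global_ch={"primed": 0.0060, "naive_5iLA": 0.0019},
                n_x_cgi=0),
            imprint=ImprintConfig(n_dmrs=0, n_erased=0),
        )
    if name == "concordance_morula":
        return SimConfig(concordance=ConcordanceConfig(
            marker_stage="morula", n_markers=876, n_naive_up=543, n_background=1124))
    if name == "concordance_epiblast":
        return SimConfig(concordance=ConcordanceConfig(
            marker_stage="late_blastocyst_EPI", n_markers=475, n_naive_up=299,
            n_background=1525))
    raise KeyError(f"unknown preset {name!r}")


PRESET_NAMES = ("default", "imprint_4iLA", "imprint_5iLA", "methylome_global",
                "concordance_morula", "concordance_epiblast")
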