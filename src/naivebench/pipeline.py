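"""End-to-end pipeline: YAML config in, per-stage TSV tables and one
deterministic JSON summary out."""

from __future__ import annotations

import json
import logging
from dataclasses import replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import simulate
from .allelic_x import classify_allelic, filter_informative
from .annotations import assign_te_to_gene, pairs_to_frame
from .chimera_qpcr import call_embryos, fit_standard_curve, summaries_to_frame
from .chromatin_profile import metaprofile, metaprofile_to_frame
from .core import Thresholds, substream
from .embryo_concordance import concordance, concordance_to_frame, stage_specific_features
from .methylome import (classify_imprinted_dmrs, dmr_calls_to_frame, global_level,
                        region_levels, xlinked_cgi_methylation)
from .te_expression import (differential_expression, polarization_summary,
                            polarization_to_frame)
from .te_gene_regulation import summaries_to_frame as corr_summaries_to_frame
from .te_gene_regulation import te_gene_correlation

log = logging.getLogger("naivebench")

STAGE_NAMES = ("te_de", "concordance", "te_gene", "methylome", "allelic",
               "profile", "chimera")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config_path: str | Path, seed: Optional[int] = None,
                 outdir: Optional[str | Path] = None) -> dict:
    """Run every configured stage on synthetic presets; returns the summary.

    The config maps stage names to settings (``preset`` plus overrides);
    missing stage sections are skipped and noted. Given the same config and
    seed, the written JSON summary is byte-identical between runs.
    """
    with open(config_path) as fh:
        config = yaml.safe_load(fh) or {}
    seed = int(config.get("seed", 0) if seed is None else seed)
    outdir = Path(outdir or config.get("outdir", "naivebench_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    thresholds = Thresholds().with_overrides(config.get("thresholds", {}))
    log.info("thresholds: %s", thresholds.as_dict())

    summary: dict = {"seed": seed, "thresholds": thresholds.as_dict(),
                     "stages": {}, "skipped": []}
    for stage in STAGE_NAMES:
        section = config.get(stage)
        if section is None:
            summary["skipped"].append(stage)
            log.info("stage %s skipped: no config section", stage)
            continue
        runner = globals()[f"_stage_{stage}"]
        try:
            summary["stages"][stage] = runner(section or {}, thresholds, seed, outdir)
        except Exception as exc:  # abort with stage name and cause
            raise StageError(stage, exc) from exc

    summary = _round_floats(summary)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _sim_config(section: dict, seed: int) -> simulate.SimConfig:
    cfg = simulate.get_preset(section.get("preset", "default"))
    return replace(cfg, seed=seed)


def _stage_te_de(section, thresholds, seed, outdir) -> dict:
    cfg = _sim_config(section, seed)
    sim = simulate.gen_te_counts(cfg)
    naive = sim.sheet.samples_in_state(*[s for s in cfg.states if s.startswith("naive")])
    primed = sim.sheet.samples_in_state("primed")
    de = differential_expression(sim.counts, primed, naive, thresholds,
                                 labels=("primed", "naive"))
    families = dict(zip(sim.truth["te_id"], sim.truth["family"]))
    pol = polarization_summary(de, families)
    de.to_csv(outdir / "te_de.tsv", sep="\t", index=False)
    polarization_to_frame(pol).to_csv(outdir / "te_polarization.tsv", sep="\t", index=False)
    truth_up = sim.truth["true_direction"] == "naive_up"
    called_up = de.set_index("feature_id")["call"].reindex(sim.truth["te_id"]) == "up_in_naive"
    sens = float((truth_up & called_up.to_numpy()).sum() / truth_up.sum()) if truth_up.any() else None
    return {"n_features": sim.counts.n_features,
            "n_de": int((de["call"] != "no_change").sum()),
            "naive_up_sensitivity": sens}


def _stage_concordance(section, thresholds, seed, outdir) -> dict:
    cfg = _sim_config({"preset": section.get("preset", "concordance_morula")}, seed)
    sim = simulate.gen_concordance(cfg)
    sets = stage_specific_features(sim.embryo.counts, sim.embryo.sheet, thresholds)
    de = differential_expression(
        sim.esc.counts, sim.esc.sheet.samples_in_state("primed"),
        sim.esc.sheet.samples_in_state(*[s for s in cfg.states if s.startswith("naive")]),
        thresholds, labels=("primed", "naive"))
    rows = concordance(sets, de)
    concordance_to_frame(rows).to_csv(outdir / "concordance.tsv", sep="\t", index=False)
    pd.concat([s.table.assign(stage=s.stage) for s in sets]).to_csv(
        outdir / "stage_specific.tsv", sep="\t", index=False)
    marker = {r.stage: r for r in rows}.get(cfg.concordance.marker_stage)
    return {"marker_stage": cfg.concordance.marker_stage,
            "n_specific": marker.n_specific if marker else 0,
            "frac_up_naive": marker.frac_up_naive if marker else None}


def _stage_te_gene(section, thresholds, seed, outdir) -> dict:
    cfg = _sim_config(section, seed)
    sim = simulate.gen_te_gene_coupled(cfg)
    pairs, unpaired, random_pairs = assign_te_to_gene(
        sim.tes, sim.genes, rng=substream(seed, "te_gene_random"))
    per_pair, summaries, n_dropped = te_gene_correlation(
        list(pairs) + list(random_pairs), sim.te_expr, sim.gene_expr)
    per_pair.to_csv(outdir / "te_gene_pairs.tsv", sep="\t", index=False)
    corr_summaries_to_frame(summaries).to_csv(
        outdir / "te_gene_bins.tsv", sep="\t", index=False)
    return {"n_pairs": len(per_pair), "n_dropped": n_dropped,
            "median_r_by_bin": {s.bin: s.median_r for s in summaries
                                if s.orientation is None}}


def _stage_methylome(section, thresholds, seed, outdir) -> dict:
    cfg = _sim_config({"preset": section.get("preset", "imprint_5iLA")}, seed)
    sim = simulate.gen_methylome(cfg)
    states = {r.state: r.sample_id for r in sim.samples.itertuples(index=False)}
    globals_ = {}
    for sample_id, calls in sim.calls.items():
        globals_[sample_id] = {
            "mCpG": global_level(calls, "CpG"),
            "mCH": global_level(calls, "CH"),
        }
    naive_state = next(s for s in states if s.startswith("naive"))
    levels = {
        name: region_levels(sim.calls[states[name]], sim.regions["dmrs"], "CpG")
        for name in ("primed", naive_state, "reprimed") if name in states
    }
    calls_out, frac = classify_imprinted_dmrs(
        levels["primed"], levels[naive_state], levels["reprimed"], thresholds)
    dmr_calls_to_frame(calls_out).to_csv(outdir / "dmr_calls.tsv", sep="\t", index=False)
    per_sample = {
        sid: region_levels(c, sim.regions["x_cgi"], "CpG")["weighted_level"]
        for sid, c in sim.calls.items()
    }
    sheet = simulate.SampleSheet(sim.samples.assign(stage=None, replicate=1))
    xsum = xlinked_cgi_methylation(per_sample, sheet, thresholds)
    xsum.to_csv(outdir / "x_cgi_summary.tsv", sep="\t", index=False)
    return {"global": globals_, "fraction_erased": frac,
            "x_intermediate_samples": xsum.loc[xsum["intermediate"], "sample_id"].tolist()}


def _stage_allelic(section, thresholds, seed, outdir) -> dict:
    cfg = _sim_config(section, seed)
    sim = simulate.gen_allelic_counts(cfg)
    informative = filter_informative(sim.table, sim.sheet.sample_ids,
                                     thresholds.min_allelic_reads)
    table = sim.table[sim.table["gene_id"].isin(informative)]
    calls, frac = classify_allelic(table, min_reads=thresholds.min_allelic_reads)
    calls.to_csv(outdir / "allelic_calls.tsv", sep="\t", index=False)
    return {"n_informative_genes": len(informative),
            "biallelic_fraction": {k: float(v) for k, v in frac.items()}}


def _stage_profile(section, thresholds, seed, outdir) -> dict:
    cfg = _sim_config(section, seed)
    sim = simulate.gen_chip_tracks(cfg)
    mp = metaprofile(sim.chip, sim.input, sim.anchors,
                     halfwidth=thresholds.metaprofile_halfwidth)
    metaprofile_to_frame(mp).to_csv(outdir / "metaprofile.tsv", sep="\t", index=False)
    center = int(np.argmin(np.abs(mp.offsets)))
    return {"n_anchors": mp.n_anchors,
            "center_log2_ratio": float(mp.mean_log_ratio[center])}


def _stage_chimera(section, thresholds, seed, outdir) -> dict:
    cfg = _sim_config(section, seed)
    plate = simulate.gen_qpcr_plate(cfg)
    curve = fit_standard_curve(plate.standards)
    per_embryo, summaries = call_embryos(plate, thresholds.detection_limit, curve)
    per_embryo.to_csv(outdir / "chimera_embryos.tsv", sep="\t", index=False)
    summaries_to_frame(summaries).to_csv(outdir / "chimera_summary.tsv", sep="\t",
                                         index=False)
    return {"slope": curve.slope, "efficiency": curve.efficiency,
            "pct_positive": {s.condition: s.pct_positive for s in summaries}}
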