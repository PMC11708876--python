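"""Stage orchestration: quantify -> differential -> GSEA -> library -> screen.

Each stage is a function over in-memory objects plus a file-level wrapper;
:func:`run_pipeline` chains them from a validated config, writing every
table with a provenance header (package version, seed, config hash).  All
stochastic stages draw from seeds derived from the config seed, so a
fixed config reproduces results byte for byte.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .annotation import read_annotation, select_primary
from .config import ConfigError
from .difftrans import (DifferentialResults, ModeratedS2B, NBDifferential,
                        TranslationEfficiency)
from .gsea import gsea_permutation, rank_genes
from .io_tables import (SampleSheet, config_hash, read_alignments, read_counts,
                        read_gmt, read_tsv, write_fasta, write_tsv)
from .quantify import assign_psites, occupancy_matrix, quantify_samples
from .screen_analysis import DropoutScreen
from .screen_design import assemble_oligos, build_library, select_candidates

log = logging.getLogger("riboscreen.pipeline")

DIFF_METRICS = ("RNA", "RO", "UORF_RO", "TE", "S2B")


def quantify_stage(cfg: dict, sheet: SampleSheet) -> pd.DataFrame:
    records = read_annotation(cfg["annotation"])
    models = select_primary(records)
    tx_lengths = {tid: rec.tx_len for tid, rec in records.items()}
    aln_dir = Path(cfg["alignments"])
    profiles = {}
    for s in sheet.subset(assay="RPF"):
        path = aln_dir / f"alignments_{s.sample_id}.tsv"
        if not path.exists():
            raise FileNotFoundError(f"missing alignment table {path}")
        aln = read_alignments(path)
        profiles[s.sample_id] = assign_psites(
            aln, tx_lengths, offset=cfg["psite_offset"],
            len_range=(cfg["footprint_min_len"], cfg["footprint_max_len"]))
    occupancy = quantify_samples(
        profiles, models, start_window_nt=cfg["start_window_nt"],
        s2b_min_rpf=cfg["s2b_min_rpf"], s2b_min_cds_len=cfg["s2b_min_cds_len"],
        s2b_multiplier=cfg["s2b_multiplier"])
    return occupancy


def diff_stage(occupancy: pd.DataFrame, rna_counts: pd.DataFrame,
               sheet: SampleSheet, cfg: dict
               ) -> dict[str, DifferentialResults]:
    rpf = sheet.subset(assay="RPF")
    rna = sheet.subset(assay="RNA")
    rpf_cond = [s.condition for s in rpf]
    rna_cond = [s.condition for s in rna]
    uniq = list(dict.fromkeys(rpf_cond))
    contrast = (uniq[1], uniq[0])
    kw = dict(min_mean_count=cfg["min_mean_count"],
              dispersion_prior_sd=cfg["dispersion_prior_sd"])

    ro = occupancy_matrix(occupancy, "RO", rpf.sample_ids)
    uorf = occupancy_matrix(occupancy, "uORF_RO", rpf.sample_ids)
    s2b = occupancy_matrix(occupancy, "s2b", rpf.sample_ids)
    rna_mat = rna_counts[rna.sample_ids]

    results = {
        "RNA": NBDifferential(rna_mat, rna_cond, contrast, "RNA", **kw).fit(),
        "RO": NBDifferential(ro, rpf_cond, contrast, "RO", **kw).fit(),
        "UORF_RO": NBDifferential(uorf, rpf_cond, contrast, "UORF_RO", **kw).fit(),
        "TE": TranslationEfficiency(rna_mat, ro, rna_cond, rpf_cond,
                                    contrast, **kw).fit(),
        "S2B": ModeratedS2B(s2b, rpf_cond, contrast).fit(),
    }
    return results


def gsea_stage(diff: DifferentialResults, gene_sets: dict[str, list[str]],
               cfg: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    use_adj = diff.metric != "S2B"   # s2b rankings use raw p
    ranked = rank_genes(diff.table, use_adjusted=use_adj, cap=cfg["gsea_cap"])
    res = gsea_permutation(ranked, gene_sets, n_perm=cfg["gsea_n_perm"],
                           seed=cfg["seed"] + 11, weight=cfg["gsea_weight"],
                           min_set=cfg["gsea_min_set"],
                           max_set=cfg["gsea_max_set"])
    return res, ranked


def design_stage(results: dict[str, DifferentialResults], pools: pd.DataFrame,
                 cfg: dict, positive_control_genes: list[str] | None = None):
    targets = select_candidates(
        results["TE"].table, results["S2B"].table, results["RO"].table,
        results["RNA"].table, results["UORF_RO"].table,
        te_adjp_max=cfg["te_adjp_max"], s2b_p_max=cfg["s2b_p_max"],
        ro_adjp_max=cfg["ro_adjp_max"], rna_adjp_min=cfg["rna_adjp_min"],
        uorf_adjp_max=cfg["uorf_adjp_max"],
        s2b_use_adjusted_p=cfg["s2b_use_adjusted_p"])
    library, manifest = build_library(
        targets, pools, n_nontargeting=cfg["n_nontargeting"],
        positive_control_genes=positive_control_genes,
        n_per_region=cfg["n_guides_per_region"], seed=cfg["seed"] + 23,
        flank5=cfg["flank5"], flank3=cfg["flank3"])
    oligos = assemble_oligos(library, cfg["flank5"], cfg["flank3"])
    return targets, library, manifest, oligos


def screen_stage(counts: pd.DataFrame, library: pd.DataFrame,
                 sheet: SampleSheet, cfg: dict):
    model = DropoutScreen(counts, library, sheet,
                          pseudocount=cfg["screen_pseudocount"])
    return model.fit(n_resamples=cfg["screen_n_resamples"],
                     seed=cfg["seed"] + 37, fdr=cfg["screen_fdr"])


def run_pipeline(cfg: dict) -> dict[str, Path]:
    """Run all configured stages in order; fail before any stage runs if a
    named input is missing.  Returns the written output paths."""
    out_dir = Path(cfg["out_dir"])
    meta = {"seed": cfg["seed"], "config": config_hash(cfg)}

    required = ["annotation", "alignments", "rna_counts", "sample_sheet"]
    missing = [k for k in required if not cfg.get(k)]
    if missing:
        raise ConfigError(f"pipeline config must name inputs: {missing}")
    for key in required + [k for k in ("gene_sets", "guide_pools",
                                       "screen_counts") if cfg.get(k)]:
        if not Path(cfg[key]).exists():
            raise FileNotFoundError(f"input {key} not found: {cfg[key]}")

    out_dir.mkdir(parents=True, exist_ok=True)
    sheet = SampleSheet.read(cfg["sample_sheet"])
    outputs: dict[str, Path] = {}

    log.info("stage quantify")
    occupancy = quantify_stage(cfg, sheet)
    outputs["occupancy"] = out_dir / "occupancy.tsv"
    write_tsv(occupancy, outputs["occupancy"], **meta)

    log.info("stage difftrans")
    rna_counts = read_counts(cfg["rna_counts"], sheet.subset(assay="RNA"))
    rna_counts.index = rna_counts.index.get_level_values(0)
    results = diff_stage(occupancy, rna_counts, sheet, cfg)
    for metric, res in results.items():
        outputs[f"diff_{metric}"] = out_dir / f"diff_{metric}.tsv"
        res.write(outputs[f"diff_{metric}"], **meta)

    if cfg.get("gene_sets"):
        log.info("stage gsea")
        sets = read_gmt(cfg["gene_sets"])
        gsea_res, ranked = gsea_stage(results["TE"], sets, cfg)
        outputs["gsea"] = out_dir / "gsea_TE.tsv"
        write_tsv(gsea_res, outputs["gsea"], **meta)
        outputs["ranked"] = out_dir / "ranked_TE.tsv"
        write_tsv(ranked, outputs["ranked"], **meta)

    library = None
    if cfg.get("guide_pools"):
        log.info("stage screen_design")
        pools = read_tsv(cfg["guide_pools"])
        targets, library, manifest, oligos = design_stage(results, pools, cfg)
        outputs["targets"] = out_dir / "targets.tsv"
        write_tsv(targets, outputs["targets"], **meta)
        outputs["library"] = out_dir / "library.tsv"
        write_tsv(library, outputs["library"], **meta)
        outputs["manifest"] = out_dir / "manifest.tsv"
        write_tsv(manifest.to_frame(), outputs["manifest"], **meta)
        outputs["oligos"] = out_dir / "oligos.fasta"
        write_fasta(oligos, outputs["oligos"])

    if cfg.get("screen_counts"):
        log.info("stage screen_analysis")
        if cfg.get("library"):
            library = read_tsv(cfg["library"])
        if library is None:
            raise ConfigError("screen scoring needs a library (config key "
                              "'library' or a guide_pools design stage)")
        sheet_path = cfg.get("screen_sample_sheet") or cfg["sample_sheet"]
        screen_sheet = SampleSheet.read(sheet_path)
        counts = read_counts(cfg["screen_counts"], screen_sheet,
                             key_cols=("guide_id",))
        counts.index = counts.index.get_level_values(0)
        res = screen_stage(counts, library, screen_sheet, cfg)
        outputs["screen"] = out_dir / "screen_genes.tsv"
        res.write(outputs["screen"], out_dir / "screen_guides.tsv", **meta)
        outputs["screen_guides"] = out_dir / "screen_guides.tsv"
    return outputs
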