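"""End-to-end orchestration from a single config, with a run manifest.

Stages: synthetic-data generation (or loading real inputs) -> peak atlas ->
specificity/enrichment -> metagene quantification -> interactome filtering.
Every figure-equivalent output is a named TSV in the output directory; the
manifest records the config hash, seed, package version, per-stage row
counts and warning counts.  Reruns with an identical config are
byte-identical for all deterministic (TSV) outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, atlas as atlas_mod, io, metagene as mg, simulate as sim
from .interactome import filter_interactors, compare_sets, records_from_frame, \
    interactor_frame
from .specificity import (associate_loci, category_enrichment,
                          define_specific_genes, geneset_score, specificity_z)

log = logging.getLogger("chromdyn")

STAGES = ("simulate", "atlas", "specificity", "metagene", "interactome")


@dataclass
class PipelineConfig:
    """Paper-default thresholds plus input selection (synthetic or real)."""

    seed: int = 0
    outdir: str = "chromdyn_out"
    synthetic: bool = True
    sim: sim.SimConfig | None = None
    inputs: dict[str, str] = field(default_factory=dict)  # real-input paths
    window: int = 2000            # locus -> TSS association window (bp)
    fc_threshold: float = 2.0     # specific-gene fold change
    q_threshold: float = 0.01
    expr_threshold: float = 100.0  # expressed / not-expressed cut
    tss_half: int = 500
    flank: int = 3000
    body_bins: int = 100
    summit_half_window: int = 2000
    min_peptides: int = 1
    min_intensity: float = 1e6
    min_ratio: float = 2.0
    smooth_patterns: bool = False
    make_plots: bool = False

    def __post_init__(self) -> None:
        for name in ("window", "fc_threshold", "q_threshold", "expr_threshold",
                     "tss_half", "flank", "summit_half_window", "min_intensity",
                     "min_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.synthetic and self.inputs:
            raise ValueError("config must select exactly one of synthetic "
                             "generation or real input paths")
        if not self.synthetic and not self.inputs:
            raise ValueError("non-synthetic runs need input paths")
        if self.synthetic and self.sim is None:
            self.sim = sim.SimConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_cfg = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim_cfg is not None:
            cfg.sim = sim.SimConfig(**sim_cfg)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, counts: dict, key: str,
           index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)
    counts[key] = int(len(df))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written as JSON)."""
    out = io.ensure_dir(cfg.outdir)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "stages": [],
        "row_counts": {},
        "warnings": 0,
    }
    counts = manifest["row_counts"]

    if not cfg.synthetic:
        raise NotImplementedError(
            "real-input orchestration: run the stage subcommands on your "
            "files; the end-to-end driver currently covers synthetic runs")

    # -- simulate ----------------------------------------------------------
    log.info("stage simulate")
    data = sim.simulate_study(cfg.sim, with_tracks=True)
    inputs = io.ensure_dir(out / "inputs")
    io.write_genes_bed(inputs / "annotation.bed", data.genes)
    io.write_expression(inputs / "expression.tsv", data.expression.table)
    peak_dir = io.ensure_dir(inputs / "peaks")
    for (arm, tp), peaks in data.peak_sets.items():
        df = pd.DataFrame(
            [(p.interval.chrom, p.interval.start, p.interval.end,
              f"{arm}_{tp}_{i}", p.score, ".", p.score, -1, -1,
              p.summit - p.interval.start)
             for i, p in enumerate(peaks)], columns=io.NARROWPEAK_COLUMNS)
        io.write_narrowpeak(peak_dir / f"{arm}_{tp}.narrowPeak", df)
    track_dir = io.ensure_dir(inputs / "tracks")
    for (arm, tp), df in data.tracks.items():
        io.write_bedgraph(track_dir / f"{arm}_{tp}.bedGraph", df)
    for ct, df in data.proteomics.items():
        df.to_csv(inputs / f"proteomics_{ct}.tsv", sep="\t", index=False)
    for name, df in data.truth.to_frames().items():
        _write(df, inputs / f"truth_{name}.tsv", counts, f"truth_{name}",
               index=False)
    counts["genes"] = len(data.genes)
    manifest["stages"].append("simulate")

    # -- atlas -------------------------------------------------------------
    log.info("stage atlas")
    peak_sets = {
        sid: atlas_mod.peaks_from_narrowpeak(
            io.read_narrowpeak(peak_dir / f"{sid[0]}_{sid[1]}.narrowPeak"), sid)
        for sid in data.cfg.samples
    }
    unified = atlas_mod.unify_peaks(peak_sets.values())
    matrix = atlas_mod.presence_matrix(unified, peak_sets, data.cfg.samples)
    io.write_bed6(out / "atlas.bed", unified, names=matrix.locus_ids)
    counts["atlas_loci"] = len(unified)
    _write(matrix.to_frame(), out / "presence_matrix.tsv", counts,
           "presence_matrix")
    dynamic = atlas_mod.select_dynamic(matrix)
    categories = atlas_mod.classify_matrix(matrix, smooth=cfg.smooth_patterns)
    categories["dynamic"] = dynamic
    _write(categories, out / "locus_categories.tsv", counts, "locus_categories")
    counts["dynamic_loci"] = int(dynamic.sum())
    manifest["stages"].append("atlas")

    # -- specificity -------------------------------------------------------
    log.info("stage specificity")
    expr = io.read_expression(inputs / "expression.tsv")
    ed = data.expression
    sets = define_specific_genes(expr, ed.esc_cols, ed.episc_cols,
                                 cfg.fc_threshold, cfg.q_threshold)
    io.write_gene_sets(out / "gene_sets.tsv",
                       {"naive": sets.naive, "primed": sets.primed,
                        "unchanged": sets.unchanged})
    counts["naive_genes"] = len(sets.naive)
    counts["primed_genes"] = len(sets.primed)
    z = specificity_z(expr, ed.esc_cols, ed.episc_cols)
    z.to_frame().to_csv(out / "specificity_z.tsv", sep="\t")
    genes = io.read_annotation(inputs / "annotation.bed", "bed12")
    assoc = associate_loci(unified, genes, cfg.window,
                           locus_ids=matrix.locus_ids)
    cat_map = dict(categories["category"])
    enrich = category_enrichment(cat_map, assoc, z, sets.stats["log2fc"])
    _write(enrich, out / "category_enrichment.tsv", counts,
           "category_enrichment")
    tc = expr[ed.timecourse_cols]
    lineage_sets = {
        name.split(":", 1)[1]: members
        for name, members in (
            (lab, data.truth.genes_with_label(lab))
            for lab in sorted({l for l in data.truth.gene_labels.values()
                               if l.startswith("lineage:")}))
    }
    score_rows, p_rows = [], []
    for set_name, members in (("naive", sets.naive), ("primed", sets.primed),
                              *sorted(lineage_sets.items())):
        if not members or not sets.unchanged:
            continue
        gs = geneset_score(tc, members, sets.unchanged)
        score_rows.append(pd.Series(gs.scores, name=set_name))
        p_rows.append(pd.Series(gs.pvalues, name=set_name))
    _write(pd.DataFrame(score_rows), out / "geneset_scores.tsv", counts,
           "geneset_scores")
    _write(pd.DataFrame(p_rows), out / "geneset_pvalues.tsv", counts,
           "geneset_pvalues")
    manifest["stages"].append("specificity")

    # -- metagene ----------------------------------------------------------
    log.info("stage metagene")
    arm_kd, tp_last = data.cfg.arms[1], data.cfg.timepoints[-1]
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        track = mg.normalize_cpm(mg.load_track(
            track_dir / f"{arm_kd}_{tp_last}.bedGraph",
            bin_size=data.cfg.track_bin_size))
        expr_mean = expr[ed.esc_cols + ed.episc_cols].mean(axis=1)
        classes = mg.classify_expression(expr_mean, cfg.expr_threshold)
        gene_by_id = {g.gene_id: g for g in genes}
        profile_rows = {}
        for cls in mg.EXPRESSION_CLASSES:
            members = [gene_by_id[g] for g in classes.index[classes == cls]]
            if not members:
                continue
            prof = mg.scaled_metagene(track, members, cfg.flank, cfg.body_bins)
            profile_rows[cls] = prof.values
        prof_df = pd.DataFrame(profile_rows).T
        _write(prof_df, out / "metagene_profiles.tsv", counts,
               "metagene_profiles")
        ratios = mg.tss_body_ratio(track, genes, cfg.tss_half)
        _write(ratios, out / "tss_body_ratio.tsv", counts, "tss_body_ratio")
        summits = [(p.interval.chrom, p.summit)
                   for p in peak_sets[(arm_kd, tp_last)]]
        sp = mg.summit_profile(track, summits, cfg.summit_half_window)
        _write(pd.DataFrame(sp.matrix), out / "summit_matrix.tsv", counts,
               "summit_matrix")
        pd.DataFrame({"mean": sp.mean}).to_csv(out / "summit_mean.tsv", sep="\t")
    manifest["warnings"] += len(caught)
    manifest["stages"].append("metagene")

    # -- interactome -------------------------------------------------------
    log.info("stage interactome")
    isets = {}
    for ct in sorted(data.proteomics):
        records = records_from_frame(io.read_proteomics(inputs / f"proteomics_{ct}.tsv"))
        isets[ct] = filter_interactors(records, cfg.min_peptides,
                                       cfg.min_intensity, cfg.min_ratio,
                                       cell_type=ct)
        _write(interactor_frame(isets[ct]), out / f"interactors_{ct}.tsv",
               counts, f"interactors_{ct}", index=False)
        counts[f"passing_{ct}"] = len(isets[ct].passing)
    cts = sorted(isets)
    if len(cts) == 2:
        cmpres = compare_sets(isets[cts[0]], isets[cts[1]])
        overlap = pd.DataFrame({
            "group": ["common", f"{cts[0]}_only", f"{cts[1]}_only"],
            "count": cmpres.counts,
            "names": [",".join(cmpres.common), ",".join(cmpres.a_only),
                      ",".join(cmpres.b_only)],
        })
        _write(overlap, out / "interactor_overlap.tsv", counts,
               "interactor_overlap", index=False)
    manifest["stages"].append("interactome")

    if cfg.make_plots:
        from . import plotting
        plotting.plot_metagene(prof_df, out / "metagene_profiles.png")
        plotting.plot_summit_heatmap(sp.matrix, out / "summit_heatmap.png")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
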