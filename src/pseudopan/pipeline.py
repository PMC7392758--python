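"""End-to-end pipeline over a synthetic multi-strain dataset.

Stage order follows the annotation workflow: channel merging, total
complement estimation, unitary calling, pangenome construction, tree
building, and transcription/essentiality statistics.  Every output file is
listed in a JSON manifest with content hashes and the resolved
configuration, so two runs with the same seed produce byte-identical
manifests.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import activity, annotate, count_model, io, pangenome, phylo, unitary
from .simulate import SimConfig, plant_unitary_scenario, simulate_dataset

log = logging.getLogger("pseudopan")

STAGES = ("simulate", "merge", "estimate", "unitary", "pangenome", "trees", "activity")


@dataclass
class RunConfig:
    """Resolved pipeline configuration; threshold defaults are the study's."""

    seed: int = 0
    out_dir: str = "pipeline_out"
    sim_overrides: dict = field(default_factory=dict)
    min_overlap_bp: int = 1
    min_len_bp: int = 100
    max_len_bp: int = 5000
    min_identity: float = 40.0
    min_coverage: float = 0.5
    reciprocal_overlap: float = 0.90
    bounds_grid: tuple = (0.90, 0.5, 0.25, 0.0)
    supergene_fraction: float = 0.5
    fpkm_cutoff: float = 2.0
    mappability_min_len: int = 100
    log_level: str = "INFO"


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    cfg = config
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    def register(relpath):
        files.append(str(relpath))
        return out / relpath

    # -- simulate ----------------------------------------------------------
    sim_cfg = SimConfig(seed=cfg.seed, **cfg.sim_overrides)
    log.info("simulate: seed=%d n_strains=%d n_genes=%d",
             sim_cfg.seed, sim_cfg.n_strains, sim_cfg.n_genes)
    ds = simulate_dataset(sim_cfg)
    for rel in io.write_dataset(ds, out / "dataset"):
        files.append(f"dataset/{rel}")

    # -- merge -------------------------------------------------------------
    merged = {}
    level_rows = []
    (out / "merged").mkdir(exist_ok=True)
    for s in ds.strains:
        recs = annotate.merge_calls(ds.auto[s], ds.manual[s],
                                    min_overlap_bp=cfg.min_overlap_bp)
        kept, removed = annotate.filter_false_positives(
            recs, min_len_bp=cfg.min_len_bp, max_len_bp=cfg.max_len_bp,
            min_identity=cfg.min_identity, min_coverage=cfg.min_coverage)
        kept = annotate.assign_haplotypes(kept, ds.haplotypes[s])
        merged[s] = kept
        io.write_bed_plus(kept, register(f"merged/{s}.bed"))
        pd.DataFrame([(r.uid, ";".join(reasons)) for r, reasons in removed],
                     columns=["uid", "reasons"]).to_csv(
            register(f"merged/{s}.removed.tsv"), sep="\t", index=False)
        levels = pd.Series([r.level for r in kept]).value_counts().to_dict()
        level_rows.append({"strain": s, "n_merged": len(kept),
                           "level1": levels.get(1, 0), "level2": levels.get(2, 0),
                           "level3": levels.get(3, 0), "n_removed": len(removed)})
        log.info("merge %s: levels used min_overlap=%d bp, FP filter [%d, %d] bp, "
                 "identity >= %.1f, coverage >= %.2f", s, cfg.min_overlap_bp,
                 cfg.min_len_bp, cfg.max_len_bp, cfg.min_identity, cfg.min_coverage)
    pd.DataFrame(level_rows).to_csv(register("merge_summary.tsv"), sep="\t", index=False)

    # -- estimate ----------------------------------------------------------
    est = count_model.estimate_table(ds.counts, reference=sim_cfg.reference_strain,
                                     calibration=ds.calibration_strain)
    est.to_csv(register("estimates.tsv"), sep="\t", index=False)

    # -- unitary -----------------------------------------------------------
    scen = plant_unitary_scenario(seed=cfg.seed)
    unis, rejected = unitary.call_unitaries(
        scen["candidates"], scen["known_pseudogenes"], scen["ortholog_table"],
        scen["coding_loci"], scen["ncrna_loci"], scen["lifted_coding"],
        scen["paralog_table"], min_len_bp=cfg.min_len_bp)
    unitary.review_report(unis + rejected).to_csv(
        register("unitary_report.tsv"), sep="\t", index=False)

    # -- pangenome ---------------------------------------------------------
    strains = ds.strains
    coding = {s: [(r.chrom, r.start, r.end) for r in ds.gene_coords[s].itertuples()]
              for s in strains}
    matches = []
    for a in strains:
        for b in strains:
            if a < b:
                matches += pangenome.map_orthologs(
                    merged[a], merged[b], ds.liftovers[(a, b)],
                    overlap_threshold=cfg.reciprocal_overlap, exclude_loci=coding[b])
    all_records = [r for s in strains for r in merged[s]]
    entries = pangenome.collapse_pangenome(matches, all_records)
    labels, class_counts = pangenome.classify_conservation(entries, strains)
    labels.to_csv(register("pangenome.tsv"), sep="\t")
    bounds = pangenome.strain_specific_bounds(
        {s: merged[s] for s in strains}, ds.liftovers, threshold_grid=cfg.bounds_grid)
    bounds.to_csv(register("strain_specific_bounds.tsv"), sep="\t")

    # -- trees -------------------------------------------------------------
    matrix = phylo.presence_absence_matrix(entries, strains)
    binary_tree = phylo.binary_cluster_tree(matrix)
    register("tree_binary.nwk").write_text(binary_tree.to_newick() + "\n")

    universal = [e for e in entries if e.conservation_class == "universal"]
    # entry -> simulation class id via the shared uid prefix convention
    entry_cls = {}
    for e in universal:
        cls = {u.rsplit(".", 1)[0] for u in e.member_uids}
        if len(cls) == 1:
            entry_cls[e.pan_uid] = cls.pop()
    usable = [p for p, c in entry_cls.items()
              if all(c in ds.sequences[s] for s in strains)]
    supergene_tree_rf = None
    if len(usable) >= 4:
        cls_tab = ds.classes.set_index("class_id")
        order = {p: (cls_tab.loc[entry_cls[p], "chrom"],
                     int(cls_tab.loc[entry_cls[p], "anc_start"])) for p in usable}
        seq_by_strain = {s: {p: ds.sequences[s][entry_cls[p]] for p in usable}
                         for s in strains}
        sg = phylo.build_supergenes(usable, seq_by_strain,
                                    sample_fraction=cfg.supergene_fraction,
                                    seed=cfg.seed, order_key=order)
        dm = phylo.distance_matrix(sg.sequences)
        nj_tree = phylo.neighbor_joining(dm, outgroup=sim_cfg.outgroup)
        register("tree_supergene.nwk").write_text(nj_tree.to_newick() + "\n")
        supergene_tree_rf = nj_tree.rf_distance(ds.tree)

    ref = sim_cfg.reference_strain
    proc = [r for r in merged[ref] if r.biotype == "processed"]
    hist, modes = phylo.age_distribution(proc)
    hist.to_csv(register("age_distribution.tsv"), sep="\t", index=False)
    loci_rows = []
    for s in strains:
        if s == ref:
            continue
        pres, chg, frac = phylo.locus_conservation(merged[s], merged[ref],
                                                   ds.liftovers[(s, ref)])
        loci_rows.append({"strain": s, "preserved": pres, "changed": chg,
                          "fraction": frac})
    pd.DataFrame(loci_rows).to_csv(register("locus_conservation.tsv"),
                                   sep="\t", index=False)

    # -- activity ----------------------------------------------------------
    quant = activity.quantifiable_records(merged[ref], ds.mappability[ref],
                                          min_len_bp=cfg.mappability_min_len)
    quant_uids = [r.uid for r in quant if r.uid in ds.pseudogene_fpkm[ref].index]
    tx = activity.transcribed_any(ds.pseudogene_fpkm[ref].loc[quant_uids],
                                  cfg.fpkm_cutoff)
    expr_mean = ds.gene_fpkm.mean(axis=1)
    is_parent = ds.genes.set_index("gene_id")["is_parent"].reindex(expr_mean.index)
    contrast = activity.parent_expression_contrast(expr_mean.to_numpy(),
                                                   is_parent.to_numpy())
    per_parent = {}
    for bt in ("processed", "duplicated"):
        cnt = ds.classes[ds.classes.biotype == bt].groupby("parent_id").size()
        tab = ds.genes.set_index("gene_id")
        y = cnt.reindex(tab.index).fillna(0)
        per_parent[bt] = activity.paralog_pseudogene_fit(
            tab["paralogs"].to_numpy(), y.to_numpy(), biotype=bt)
    ess = ds.essentiality.set_index("gene_id")["essential"].reindex(expr_mean.index)
    logexpr = np.log1p(expr_mean).to_numpy()

    def try_fit(fn):
        # degenerate small designs (e.g. almost every gene a parent) are
        # reported as inestimable rather than aborting the run
        try:
            return fn(ess.to_numpy(), is_parent.to_numpy(float), logexpr), None
        except ValueError as exc:
            return None, str(exc)

    lpm, lpm_err = try_fit(activity.fit_lpm)
    probit, probit_err = try_fit(activity.fit_probit)
    try:
        enrich = activity.essentiality_enrichment(ess.to_numpy(),
                                                  is_parent.to_numpy(bool))
    except ValueError:
        enrich = None
    activity_summary = {
        "n_quantifiable": len(quant_uids),
        "n_transcribed": len(tx),
        "transcribed_fraction": len(tx) / len(quant_uids) if quant_uids else None,
        "fpkm_cutoff": cfg.fpkm_cutoff,
        "parent_contrast": contrast,
        "paralog_fits": per_parent,
        "lpm_marginal_effect": lpm.marginal_effect if lpm else None,
        "lpm_error": lpm_err,
        "probit_marginal_effect": probit.marginal_effect if probit else None,
        "probit_error": probit_err,
        "essentiality_enrichment": enrich,
    }
    register("activity.json").write_text(json.dumps(activity_summary, sort_keys=True,
                                                    indent=1, default=float))

    # -- manifest ----------------------------------------------------------
    manifest = {
        "config": dataclasses.asdict(cfg),
        "stages": list(STAGES),
        "summary": {
            "n_strains": len(strains),
            "pangenome_entries": len(entries),
            "conservation_counts": class_counts,
            "n_unitaries": len(unis),
            "supergene_rf_to_truth": supergene_tree_rf,
            "binary_rf_to_truth": binary_tree.rf_distance(ds.tree),
            "age_modes": modes[:2],
        },
        "files": {f: io.file_sha256(out / f) for f in sorted(files)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest
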