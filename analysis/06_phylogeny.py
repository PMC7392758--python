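"""Pseudogene-based phylogenetics and age structure.

Two independent signals reconstruct the strain tree: binary
presence/absence of pangenome entries (Jaccard + average linkage) and a
TN93 + neighbour-joining tree over per-strain supergenes (concatenated
sequences of half the universally conserved pseudogenes, same order in
every strain).  Percent identity to the parent recovers the two
retrotransposition bursts; locus-conservation fractions against the
reference follow an inverse-logarithmic divergence-time curve; and
conserved-pseudogene sharing shows no correlation with subspecies genome
fractions.
Writes trees, the age histogram, and fit tables under results/.
"""

import numpy as np
import pandas as pd

from _common import RESULTS, load_dataset
from pseudopan.pangenome import (classify_conservation, collapse_pangenome,
                                 map_orthologs)
from pseudopan.phylo import (age_distribution, binary_cluster_tree,
                             build_supergenes, distance_matrix,
                             fit_divergence_curve, introgression_correlation,
                             locus_conservation, neighbor_joining,
                             presence_absence_matrix)

ds = load_dataset()
cfg = ds.config

matches = []
for a in ds.strains:
    for b in ds.strains:
        if a < b:
            matches += map_orthologs(ds.truth_records[a], ds.truth_records[b],
                                     ds.liftovers[(a, b)])
records = [r for s in ds.strains for r in ds.truth_records[s]]
entries = collapse_pangenome(matches, records)
classify_conservation(entries, ds.strains)

# binary presence/absence tree
btree = binary_cluster_tree(presence_absence_matrix(entries, ds.strains))
(RESULTS / "tree_binary.nwk").write_text(btree.to_newick() + "\n")
print(f"binary presence/absence tree: RF distance to truth = "
      f"{btree.rf_distance(ds.tree)}")

# supergene TN93 + NJ tree
cons = ds.conservation_truth()
usable = [c for c, v in cons.items() if v == "universal"
          and all(c in ds.sequences[s] for s in ds.strains)]
cls_tab = ds.classes.set_index("class_id")
order = {c: (cls_tab.loc[c, "chrom"], int(cls_tab.loc[c, "anc_start"]))
         for c in usable}
seqs = {s: {c: ds.sequences[s][c] for c in usable} for s in ds.strains}
sg = build_supergenes(usable, seqs, sample_fraction=0.5, seed=cfg.seed,
                      order_key=order)
njt = neighbor_joining(distance_matrix(sg.sequences), outgroup=cfg.outgroup)
(RESULTS / "tree_supergene.nwk").write_text(njt.to_newick() + "\n")
print(f"supergene tree: {len(sg.members)} of {len(usable)} conserved "
      f"pseudogenes sampled, {sg.length:,} bp per strain, RF to truth = "
      f"{njt.rf_distance(ds.tree)}")

# age distribution
proc = [r for s in ds.strains for r in ds.truth_records[s]
        if r.biotype == "processed"]
hist, modes = age_distribution(proc, bin_width_pct=0.5)
hist.to_csv(RESULTS / "age_distribution.tsv", sep="\t", index=False)
print(f"age-distribution modes (percent identity, by prominence): "
      f"{[round(m, 2) for m in modes[:2]]} -- bursts were placed at "
      f"{sorted(cfg.burst_identities)}")

# locus conservation and the inverse-log divergence curve
ref = cfg.reference_strain
names, tdist = ds.tree.leaf_distance_matrix()
ref_i = names.index(ref)
rows = []
for s in ds.strains:
    if s == ref:
        continue
    common = {r.ens_id for r in ds.truth_records[s]} & \
        {r.ens_id for r in ds.truth_records[ref]}
    recs = [r for r in ds.truth_records[s] if r.ens_id in common]
    pres, chg, frac = locus_conservation(recs, ds.truth_records[ref],
                                         ds.liftovers[(s, ref)])
    rows.append({"strain": s, "preserved": pres, "changed": chg,
                 "fraction": frac,
                 "divergence_time": tdist[ref_i, names.index(s)] / 2})
loci = pd.DataFrame(rows)
loci.to_csv(RESULTS / "locus_conservation.tsv", sep="\t", index=False)
a, b, r2 = fit_divergence_curve(list(zip(loci["fraction"].clip(upper=1.0),
                                         loci["divergence_time"])))
print(f"locus conservation {loci['fraction'].min():.3f}-"
      f"{loci['fraction'].max():.3f}; inverse-log fit t = "
      f"{a:.3f} + {b:.3f} ln(f), R^2 = {r2:.3f}")

# introgression check: conserved sharing vs subspecies genome fraction
wild = ds.strains[1]
shared, fracs = [], []
rng = np.random.default_rng(cfg.seed)
for s in ds.strains:
    if s in (ref, wild, cfg.outgroup):
        continue
    both = {r.ens_id for r in ds.truth_records[s]} & \
        {r.ens_id for r in ds.truth_records[wild]}
    shared.append(len(both) / len(ds.truth_records[s]))
    segs = ds.haplotypes[s]
    total = sum(x.end - x.start for x in segs)
    fracs.append(sum(x.end - x.start for x in segs if x.label == "musculus") / total)
r, p = introgression_correlation(shared, fracs)
print(f"conserved sharing vs subspecies fraction (n={len(shared)}): "
      f"r = {r:.3f}, p = {p:.3f} "
      f"({'no significant correlation' if p > 0.05 else 'correlated'})")
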