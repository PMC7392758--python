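"""Transcription calling and parent-gene statistics.

Pseudogenes are quantified only where they retain a uniquely mappable
exon piece longer than 100 bp, then called transcribed at FPKM > 2.
Parents are contrasted against non-parents (Mann-Whitney), pseudogene
counts are fitted against paralog counts (linear for duplicated,
logarithmic for processed), and gene essentiality is modelled with a
linear probability model and a probit, reporting the parent-status
marginal effect.
Writes results/activity_summary.json.
"""

import json

import numpy as np

from _common import RESULTS, load_dataset
from pseudopan.activity import (disablement_density_trend,
                                essentiality_enrichment, fit_lpm, fit_probit,
                                paralog_pseudogene_fit,
                                parent_expression_contrast,
                                quantifiable_records, transcribed_any)

ds = load_dataset()
cfg = ds.config
ref = cfg.reference_strain

quant = quantifiable_records(ds.truth_records[ref], ds.mappability[ref])
uids = [r.uid for r in quant]
tx = transcribed_any(ds.pseudogene_fpkm[ref].loc[uids], cfg.transcription_cutoff)
print(f"{len(quant)}/{len(ds.truth_records[ref])} pseudogenes quantifiable after "
      f"the mappability filter; {len(tx)} transcribed at FPKM > "
      f"{cfg.transcription_cutoff} ({len(tx) / len(quant):.1%}; generator "
      f"truth rate {cfg.frac_transcribed})")

expr = ds.gene_fpkm.mean(axis=1)
parents = ds.genes.set_index("gene_id")["is_parent"].reindex(expr.index)
contrast = parent_expression_contrast(expr.to_numpy(), parents.to_numpy())
print(f"parent vs non-parent expression: median difference "
      f"{contrast['median_difference']:.2f} FPKM, Mann-Whitney p = "
      f"{contrast['p_value']:.2e}")

fits = {}
tab = ds.genes.set_index("gene_id")
for bt in ("processed", "duplicated"):
    cnt = ds.classes[ds.classes.biotype == bt].groupby("parent_id").size()
    y = cnt.reindex(tab.index).fillna(0)
    fits[bt] = paralog_pseudogene_fit(tab["paralogs"].to_numpy(),
                                      y.to_numpy(), biotype=bt)
print(f"paralogs vs pseudogene count: duplicated slope "
      f"{fits['duplicated']['b']:+.3f} (linear), processed slope "
      f"{fits['processed']['b']:+.3f} (log fit; negative = large families "
      f"make few processed copies each)")

logexpr = np.log1p(expr).to_numpy()
ess = ds.essentiality.set_index("gene_id")["essential"].reindex(expr.index)
lpm = fit_lpm(ess.to_numpy(), parents.to_numpy(float), logexpr)
prob = fit_probit(ess.to_numpy(), parents.to_numpy(float), logexpr)
enrich = essentiality_enrichment(ess.to_numpy(), parents.to_numpy(bool))
print(f"essentiality: naive enrichment {enrich:.2f}x among parents; marginal "
      f"effect of parent status {lpm.marginal_effect:+.3f} (LPM) / "
      f"{prob.marginal_effect:+.3f} (probit) controlling for transcription")

trend = disablement_density_trend(
    [r for s in ds.strains for r in ds.truth_records[s]])
print(f"disablements per bp vs divergence: slope {trend['slope']:.2e}, "
      f"Spearman rho = {trend['spearman_rho']:.3f}")

summary = {
    "n_quantifiable": len(quant), "n_transcribed": len(tx),
    "transcribed_fraction": len(tx) / len(quant),
    "parent_contrast": contrast, "paralog_fits": fits,
    "lpm_marginal_effect": lpm.marginal_effect,
    "probit_marginal_effect": prob.marginal_effect,
    "essentiality_enrichment": enrich,
    "disablement_trend": trend,
}
(RESULTS / "activity_summary.json").write_text(
    json.dumps(summary, indent=1, sort_keys=True, default=float))
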