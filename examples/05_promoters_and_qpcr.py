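"""Promoter regulation analysis and qPCR validation.

Extracts the 2-kb promoters of the planted candidates, scans them for
cis-acting elements on both strands, tests TF-family enrichment by
hypergeometric test with BH correction (the MYB binding site is planted,
so MYB tops the table), then back-computes a Ct table from expression,
applies 2^-ddCt and reports the concordance R^2 with the FPKM matrix.
"""

from lignanscreen.promoter import (
    categorize_elements,
    extract_promoters,
    scan_motifs,
    tf_enrichment,
)
from lignanscreen.qpcr import concordance, ddct
from lignanscreen.simulate import (
    SimConfig,
    default_panels,
    simulate_ct,
    simulate_expression,
    simulate_pangenome,
)

cfg = SimConfig(rng_seed=7)
ds = simulate_pangenome(cfg)
candidates = sorted(ds.truth.candidate_genes)

cand_models = [g for g in ds.gene_models["var1"] if g.gene_id in candidates]
promoters = extract_promoters(cand_models, ds.genome, cfg.promoter_length)
occurrences = scan_motifs(promoters, list(ds.elements))
categories = categorize_elements(occurrences, list(ds.elements), candidates)
print("cis-element occurrences per functional category:")
print(categories.to_string())

enrichment = tf_enrichment(set(candidates), ds.binding_map,
                           set(ds.truth.reference_genes))
print("\nTF-family enrichment (top 3):")
print(enrichment.head(3).to_string(index=False))

expr = simulate_expression(cfg, ds.truth)
panels = default_panels(cfg)
white = expr.subset(varieties=[panels.white_variety], tissue="seed")
ct = simulate_ct(white, candidates, ds.truth.reference_housekeeping,
                 ct_sd=0.2, seed=3)
relative = ddct(ct, ds.truth.reference_housekeeping, white.fpkm.columns[0])
r2 = concordance(relative, white.fpkm.loc[candidates, relative.columns])
print(f"\nqPCR vs RNA-seq concordance R^2 = {r2:.4f}")
print("(log2 relative expression against log2 FPKM+1 over all",
      f"{relative.size} gene x stage points)")
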