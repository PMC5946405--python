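"""Gene-set enrichment of associated intervals with a relocation null.

Derives LD-independent associated intervals by greedy clumping at a grid of
p-value thresholds, counts how many land in the gene set built from the
annotation's signal-carrying intervals, and calibrates significance by
relocating intervals (SNP- and gene-density matched) 1,000 times, with
bootstrap correction across thresholds.
"""

import evoenrich as ev

ds = ev.generate(ev.SyntheticConfig(noncentrality=3.0, seed=7))
spans = ev.gene_spans(ds.genes)
signal_ivs = [iv for iv in ds.annotations["target"].intervals if ds.truth[iv.label]]
gene_set = [g for g in spans if any(g.overlaps(iv) for iv in signal_ivs)]
print(f"gene set: {len(gene_set)} genes containing the signal intervals")

report = ev.run_inrich(ds.gwas, ds.ld, gene_set, spans,
                       n_perm=1000, n_boot=500, seed=11)
print(report.table().to_string(index=False))
print(f"\nenrichment declared (any corrected p < 0.05): {report.enriched}")
print("observed_k counts associated intervals overlapping the gene set; the")
print("corrected p is the bootstrap multiplicity-adjusted relocation p-value.")
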