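"""Simulate a GWAS with planted annotation signal and read it off a QQ curve.

Generates a 10k-SNP genome where 10% of the target annotation's intervals
carry association signal (z-scores with mean 3), assigns SNPs to the
annotation by position and LD, and compares the subset's corrected QQ curve
with the full GWAS.
"""

import evoenrich as ev

ds = ev.generate(ev.SyntheticConfig(noncentrality=3.0, seed=7))
print(f"genome: {len(ds.gwas)} SNPs, {len(ds.ld)} LD pairs, "
      f"{len(ds.annotations['target'])} target intervals "
      f"({sum(ds.truth.values())} carry signal)")

binning = ev.ld_bin(ds.gwas, ds.annotations["target"], ds.ld, r2_min=0.8)
prop = ev.snp_proportion(binning, ds.gwas)
print(f"binned: {len(binning.positional_ids)} SNPs positionally, "
      f"{len(binning.ld_ids)} after LD expansion "
      f"({100 * prop.ld:.2f}% of the GWAS)")

full, sub, summary = ev.stratified_qq(ds.gwas, binning.ld_ids, "target")
print(f"global lambda_GC = {full.lambda_gc:.4f}  (≈1: no inflation planted)")
print(f"subset min corrected p = {summary.min_p_subset:.2e}; "
      f"crosses 5e-8: {summary.crosses_gws}")
print("deflection (observed - expected at expected -log10 p of 1..5):")
print("   ", ", ".join("nan" if d != d else f"{d:+.3f}" for d in summary.deflection))
print("positive deflection at the top quantiles = the annotation's SNPs are")
print("enriched for association relative to the uniform expectation.")
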