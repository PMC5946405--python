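"""Why LD binning: annotation SNPs missing from a GWAS are recovered by proxy.

Drops 60% of the target annotation's genotyped SNPs from the GWAS table
(the LD reference is unaffected) and shows that LD binning still assigns
SNPs to intervals that positional binning now misses.
"""

import evoenrich as ev

ds = ev.generate(ev.SyntheticConfig(seed=3))
thinned = ev.plant_missingness(ds, drop_fraction=0.6, seed=42)

for label, d in (("complete GWAS", ds), ("60% interval SNPs dropped", thinned)):
    pos = ev.positional_bin(d.gwas, d.annotations["target"])
    ld = ev.ld_bin(d.gwas, d.annotations["target"], d.ld, r2_min=0.8)
    empty = sum(1 for ids in pos.per_interval.values() if not ids)
    empty_ld = sum(1 for ids in ld.per_interval_ld.values() if not ids)
    print(f"{label}:")
    print(f"  positional: {len(pos.positional_ids):4d} SNPs, "
          f"{empty} intervals left empty")
    print(f"  LD-based:   {len(ld.ld_ids):4d} SNPs, "
          f"{empty_ld} intervals left empty")

print("\npositional binning loses the dropped SNPs outright; LD binning keeps")
print("tagging the intervals through block partners at r2 >= 0.8, so the")
print("annotation's signal remains testable in a GWAS that skipped those SNPs.")
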