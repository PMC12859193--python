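"""Bootstrap comparison of PV counts between gene selection classes.

Genes under positive selection are planted with higher mean PV counts
than genes under negative selection; the bootstrap test on log2(count+1)
gene means detects the difference.
"""

from paleopv.selection import bootstrap_group_test
from paleopv.synth import SimulationConfig, simulate_selection_table

cfg = SimulationConfig(seed=21)
genes = [f"GENE{i:03d}" for i in range(60)]
table = simulate_selection_table(cfg, genes)

for cls in ("positive", "neutral", "negative"):
    counts = table.counts_for(cls)
    print(f"{cls:>9}: {len(counts)} genes, mean {counts.mean():.2f} PVs/gene")

res = bootstrap_group_test(table, "positive", "negative", n_boot=10_000, seed=21)
print(f"\nmean log2(count+1): positive {res.mean_a:.3f} vs negative {res.mean_b:.3f}")
print(f"two-sided bootstrap P = {res.p_value:.4f} (10,000 gene resamples)")
# A small P indicates positively selected genes systematically carry more
# pathogenic variants than negatively selected ones.
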