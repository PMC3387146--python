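"""Simulate a labeled case-control cohort with planted taxa effects.

Draws a taxa-by-sample count table at 454-era sequencing depth (negative
binomial around 2690 reads/sample) with ten taxa shifted 2^1.5-fold in the
disease class, and prints what a downstream analysis gets to see.
"""

from ampliclass import CohortSpec, default_planted, normalize, simulate_cohort

spec = CohortSpec(
    n_per_class={"control": 24, "IBD": 67},   # cohort sizes
    n_taxa=200,
    planted_taxa=default_planted(10, 1.5),    # (taxon index, log2 fold change)
    seed=0,
)
table, labels, truth = simulate_cohort(spec)
depths = table.counts.sum(axis=0)

print(f"samples: {len(table.samples)}  taxa: {len(table.features)}")
print(f"depth: mean {depths.mean():.0f}, sd {depths.std():.0f} reads/sample")
frac_rare = (normalize(table).frequencies.mean(axis=1) < 0.01).mean()
print(f"taxa below 1% mean abundance: {100 * frac_rare:.0f}%")
print("\nplanted effects (ground truth):")
print(truth.planted.to_string(index=False))
# A positive lfc means the taxon is enriched in the IBD class; these are the
# effects the association and classification stages should recover.
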