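"""The three genome-size estimators, on the published tick-cell-line inputs.

Coverage extrapolation divides total aligned bases by the coverage mode of
unique (haplotype-separated) sequence to get the combined-haplotype size;
the duplication route corrects an assembly span by the fraction of
single-copy genes found duplicated.  The three haploid estimates land
within 0.07 Gbp of each other, the agreement that supports a ~2.2-2.3 Gbp
haploid genome behind a 2.7 Gbp assembly.
"""

from ploidyscope import sizeest

# short-read route: 39.9 Gbp mapped at a 9x unique-sequence mode
short = sizeest.size_from_coverage(39.9e9, 9)
d, h = sizeest.rounded_gbp_pair(short.diploid_size)
print(f"short-read coverage : diploid {d} Gbp -> haploid {h} Gbp")

# long-read route: 151.93 Gbp of contig-aligned sequence at a 34x mode
long = sizeest.size_from_coverage(151.93e9, 34)
d, h = sizeest.rounded_gbp_pair(long.diploid_size)
print(f"long-read coverage  : diploid {d} Gbp -> haploid {h} Gbp")

# duplication route: 2.67 Gbp span, 28% of single-copy genes duplicated
dup = sizeest.size_from_duplication(2.67e9, 0.28)
print(f"duplication-adjusted: haploid {dup.haploid_size / 1e9:.2f} Gbp")

summary = sizeest.consolidate([short, long, dup])
print(f"spread across methods: {summary['spread'] / 1e9:.2f} Gbp")
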