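"""Haplotype and nucleotide diversity from a small aligned sample.

Builds five control-region-like sequences forming two haplotypes (three
and two copies, four substitutions apart) and computes the summary
statistics a per-population diversity table reports.
"""

import numpy as np

from haplerode.diversity import haplotype_diversity, nucleotide_diversity
from haplerode.haplotypes import collapse_haplotypes, segregating_sites
from haplerode.seqio import Alignment

rng = np.random.default_rng(0)
base = rng.choice(list("ACGT"), size=60)
variant = base.copy()
for col in rng.choice(60, size=4, replace=False):
    variant[col] = {"A": "C", "C": "G", "G": "T", "T": "A"}[variant[col]]

aln = Alignment(
    [f"s{i}" for i in range(5)],
    ["".join(base)] * 3 + ["".join(variant)] * 2,
)
inv = collapse_haplotypes(aln)
counts = list(inv.haplotype_counts().values())

print(f"n = {len(aln)} sequences")
print(f"haplotypes = {len(inv.haplotype_ids)} with copy numbers {counts}")
print(f"polymorphic sites P = {segregating_sites(aln)}")
print(f"haplotype diversity h = {haplotype_diversity(counts):.2f}")
print(f"nucleotide diversity pi = {nucleotide_diversity(aln):.2f} pairwise differences")

# h = 0.60 is the unbiased estimator n(1 - sum p_i^2)/(n - 1) for p = (3/5, 2/5);
# pi = 2.40 because 6 of the 10 sequence pairs are identical and 4 differ at 4 sites.
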