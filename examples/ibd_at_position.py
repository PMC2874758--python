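"""Expected IBD sharing along the chromosome for one full-sib family.

The variance-component model localizes QTL through the position-specific
IBD matrix: between markers, the expected proportion of alleles shared
identical-by-descent among sibs is inferred from the flanking markers,
marginalizing over the parents' unknown linkage phases.
"""

import numpy as np

import qtlshrink as qs
from qtlshrink.ibd import IbdEngine

genome, truth = qs.chromosome_design()
dataset, sim = qs.simulate_dataset(genome, truth, n_families=10,
                                   sibs_per_family=4, rng_seed=2)
engine = IbdEngine(dataset)

np.set_printoptions(precision=3, suppress=True)
for lam in (15.0, 45.0):
    print(f"\nfamily 0, expected IBD at {lam:g} cM:")
    print(engine.block_matrix(0, lam))

qtl_index = 1  # the 45-cM QTL
realized = sim.realized_ibd(qtl_index, dataset.family_sizes)[0]
print("\nrealized IBD at the 45-cM QTL (from the simulator's allele ids):")
print(realized)
print("\nOff-diagonal entries near 0, 0.5 or 1 show sib pairs sharing 0, 1 "
      "or 2 parental haplotypes; the conditional expectation tracks the "
      "realized sharing up to recombination uncertainty between markers.")
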