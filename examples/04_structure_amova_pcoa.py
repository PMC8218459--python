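"""Hierarchical AMOVA, pairwise FST and PCoA on an island-model dataset.

Simulates two regions of two populations each (strong between-region,
mild within-region divergence) and partitions the molecular variance.
"""

import numpy as np

from ssrgbas import genotyping as gt
from ssrgbas import popgen as pg
from ssrgbas import simdata as sd

loci = sd.make_tetranucleotide_loci(15, seed=5)
base = sd.make_pop_model(loci, n_pops=2, n_ind_per_pop=1, fst_target=0.25,
                         inbreeding_f=0.0, seed=1)
region_freqs = sd.draw_population_allele_freqs(base, seed=2)

entries, pop_map, regions = {}, {}, {}
for r in range(2):
    anc = {l: (base.ancestral_freqs[l][0], region_freqs[r][l])
           for l in base.ancestral_freqs}
    model = sd.PopModel(2, 15, 0.05, 0.0, anc)
    freqs = sd.draw_population_allele_freqs(model, seed=3 + r)
    truth = sd.simulate_genotypes(freqs, model, seed=5 + r,
                                  sample_prefix=f"R{r + 1}P")
    for (s, l), pair in truth.entries.items():
        entries[(s, l)] = tuple(sorted(f"{l}:{a}.{b}" for a, b in pair))
    for s, p in truth.pop_map.items():
        pop_map[s] = p
        regions[p] = f"region{r + 1}"

matrix = gt.GenotypeMatrix(sorted(pop_map), sorted({l for _, l in entries}),
                           entries, pop_map, {})

res = pg.amova(matrix, regions=regions, n_perm=999, seed=9)
print(res.table.round(3).to_string(index=False))
print(f"\noverall FST = {res.fst:.3f}; permutation p-values: "
      f"{ {k: round(v, 3) for k, v in res.p_values.items()} }")

fst, pvals = pg.pairwise_fst(matrix, n_perm=199, seed=11)
print("\npairwise FST:")
print(fst.round(3).to_string())

D = pg.squared_genotypic_distance(matrix)
pc = pg.pcoa(D, n_axes=3, squared=True)
print("\nPCoA variance explained:",
      ", ".join(f"axis {i + 1}: {v:.2f}%"
                for i, v in enumerate(pc.percent_variance)))
# Most among-group variance sits between regions (the deep split), a small
# share between populations within regions, the rest within populations --
# matching the nested FST values the simulation planted.
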