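"""Simulate four generations of assortative mating and watch LD build up.

Generation 1 is a randomly mating founder population; generations 2-4 apply
exact rank matching on the outcome trait.  Because all loci recombine freely,
any growth in genetic variance or correlation is driven purely by AM-induced
gametic-phase disequilibrium.
"""

import numpy as np

from amadjust import ArchitectureSpec, SortingSpec, evolve

arch = ArchitectureSpec(
    n_individuals=4_000,  # scaled down so the example runs in seconds
    n_snps=1_000,
    n_chrom=20,
    pleiotropy_mode="full",
    effect_correlation=0.5,
)
result = evolve(arch, SortingSpec("outcome"), n_generations=4, seed=7)

v0 = result[0].traits.g_y.var()
print("gen  Var(g_Y)/founder   rg(Z,Y)")
for gen in result:
    t = gen.traits
    rg = np.corrcoef(t.g_z, t.g_y)[0, 1]
    print(f"{gen.population.generation:>3}  {t.g_y.var() / v0:>15.3f}   {rg:>7.3f}")

print(
    "\nThe sorted trait's genetic variance inflates generation after"
    "\ngeneration, and the genetic correlation rises with it, even though"
    "\nthe per-SNP effects never change: that is AM-induced LD."
)
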