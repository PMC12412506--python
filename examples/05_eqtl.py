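"""Genotype-stratified expression testing on a simulated cis-eQTL.

Simulates 89 subjects with an additive genotype effect on expression and
compares the genotype groups with the Wilcoxon-Mann-Whitney test.
"""

import numpy as np

from var2func.eqtl import eqtl_by_genotype
from var2func.synth import gen_expression

rng = np.random.default_rng(0)
genotypes = rng.binomial(2, 0.4, size=89)
table = gen_expression(genotypes, beta=2.0, noise_sd=1.0, seed=0)

results = eqtl_by_genotype(table)
print(results.to_string(index=False))
# Each row is one genotype contrast: the risk-allele homozygotes show the
# highest median expression, and the 0-vs-2 contrast is the most
# significant — the pattern expected when the risk allele boosts the
# target gene's expression additively.
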