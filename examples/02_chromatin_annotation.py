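"""Rank candidate variants by open-chromatin evidence.

Plants one variant covered by 29 of 30 ATAC-seq and 5 of 6 H3K27ac
experiments among 41 decoy variants, builds the variant x experiment
overlap matrix, and ranks by per-assay support.
"""

import numpy as np
import pandas as pd

from var2func.chromatin import build_evidence, rank_variants
from var2func.synth import gen_peak_sets

rng = np.random.default_rng(1)
experiments = gen_peak_sets(
    ("chr11", 43_664_000, 43_765_000),
    {"ATAC": 30, "H3K27ac": 6},
    [(43_714_768, {"ATAC": 29, "H3K27ac": 5})],
    seed=1)
variants = pd.DataFrame({
    "snp_id": ["rs_candidate"] + [f"rs_decoy{k}" for k in range(41)],
    "chrom": "chr11",
    "pos": [43_714_768] + list(rng.integers(43_664_001, 43_765_000, size=41)),
})

ranked = rank_variants(build_evidence(variants, experiments))
print(ranked.head(5).to_string(index=False))
# The planted candidate tops the ranking: it sits in accessible chromatin
# in 29 ATAC and 5 H3K27ac experiments, the profile of a putative enhancer
# variant, while decoys only hit scattered background peaks.
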