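"""Call a planted enhancer-promoter loop from synthetic Hi-C contacts.

Generates a 200-bin, 10-kb-resolution contact matrix with power-law
distance decay and a fivefold loop between bins 10 and 40, fits the decay
model, and calls significant interactions (BH FDR 5% and observed/expected
ratio >= 2).
"""

from var2func.hic import ContactMatrix, annotate_anchor, call_interactions, fit_decay
from var2func.synth import gen_contacts

triplets = gen_contacts(n_bins=200, resolution=10_000, total_reads=2_000_000,
                        decay_alpha=1.0, loop_spec=[(10, 40, 5.0)], seed=0)
matrix = ContactMatrix(triplets)
decay = fit_decay(matrix)
print(f"fitted decay exponent alpha = {decay.alpha:.3f} (generator used 1.0)")

calls = call_interactions(matrix, decay, alpha_fdr=0.05, ratio_min=2.0)
features = [("chr11", 100_000, 110_000, "variant_anchor"),
            ("chr11", 400_000, 410_000, "promoter")]
sig = annotate_anchor(calls[calls["significant"]], features)
print(sig.to_string(index=False))
# The only significant pair is the planted loop: its observed count is ~5x
# the distance-decay expectation (the distance-normalised interaction
# frequency), linking the variant-bearing bin to the promoter bin.
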