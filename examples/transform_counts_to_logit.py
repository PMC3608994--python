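"""Put sequencing counts and qPCR readouts on the common logit scale.

Sequencing platforms yield (taxon count, total reads); qPCR yields a cycle
threshold difference dCT with implied frequency 2**dCT.  Both are mapped to
log-odds so every platform measures the same latent quantity.
"""

import numpy as np

from platsem import empirical_logit, generate_counts, qpcr_to_logit

rng = np.random.default_rng(3)
true_freq = rng.uniform(0.02, 0.4, size=8)
depth = 500
counts = generate_counts(true_freq, depth=depth, seed=3)
logits = empirical_logit(counts, depth)

print("true freq   count/500   empirical logit   true logit")
for p, c, l in zip(true_freq, counts, logits):
    print(f"  {p:6.3f}     {c:5d}       {l:8.3f}        {np.log(p/(1-p)):8.3f}")

dct = np.log2(true_freq)  # a qPCR assay reading the same frequencies
print("\nqPCR dCT -> logit (same frequencies):", np.round(qpcr_to_logit(dct), 3))
print("\nThe smoothing constant 0.5 keeps the transform finite even for zero")
print("counts; at this depth the empirical logit tracks the true log-odds.")
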