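"""Simulate platform data from a known truth and recover it by refitting.

The generator draws a latent abundance per subject and linear platform
readouts with chosen loadings and error variances — exactly the structure
the model assumes — so refitting must recover the generating values as the
sample grows.
"""

import numpy as np

from platsem import ModelSpec, fit_model, moments_from_data, reliability
from platsem.synthetic_data import faecalibacterium_truth, generate

truth = faecalibacterium_truth(n=20_000)  # study-calibrated parameter regime
data = generate(truth, seed=11)
fit = fit_model(moments_from_data(data),
                ModelSpec(indicator_names=list(truth.platform_names)),
                compute_se=False)

print("parameter            truth     estimate")
for i, name in enumerate(truth.platform_names):
    print(f"  loading {name:10s} {truth.loadings[i]:7.3f}  "
          f"{fit.estimates.loadings[i]:9.3f}")
print(f"  latent variance    {truth.latent_variance:7.3f}  "
      f"{fit.estimates.latent_variance:9.3f}")
rep = reliability(fit)
print("  reliabilities      ", np.round(truth.reliabilities(), 3),
      "->", np.round(rep.reliability, 3))
print(f"\nchi2 = {fit.chi_square:.2f} on df = {fit.df}: at n = 20000 a "
      f"correctly specified model still fits, and every")
print("parameter lands on its generating value to sampling precision.")
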