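"""Estimate admixture proportions for simulated study individuals.

Generates a four-population reference panel, simulates admixed individuals
with known ancestral proportions, and computes their ancestral spectra:
principal scores, ancestral information (the BLUE of the ancestral
proportion) and the maximum-likelihood estimate.
"""

import numpy as np

from ancspec import (
    AdmixtureDesign,
    SimConfig,
    compute_spectrum,
    simulate_genotypes,
    simulate_panel,
)

panel = simulate_panel(
    SimConfig(populations=("AFR", "EAS", "EUR", "SAS"), m_per_pop=10_000, seed=21)
)

truth = {"AFR": 0.5, "EAS": 0.3, "EUR": 0.2, "SAS": 0.0}
design = AdmixtureDesign.constant(truth, 100)
geno = simulate_genotypes(panel, design, seed=22)

result = compute_spectrum(geno, panel, mle=True)

print("true proportions:", truth)
print("population order:", result.populations)
print("mean principal score:      ", np.round(result.scores.mean(axis=0), 4))
print("mean ancestral information:", np.round(result.info.mean(axis=0), 4))
print("mean MLE:                  ", np.round(result.mle.mean(axis=0), 4))
print("sd score vs sd information:",
      np.round(result.scores.std(axis=0, ddof=1), 4),
      np.round(result.info.std(axis=0, ddof=1), 4))
print(
    "\nBoth estimators are unbiased for the ancestral proportions; the\n"
    "equal-weight ancestral information has the smaller spread (it is the\n"
    "best linear unbiased estimator), and the SAS component is exactly zero\n"
    "because these individuals carry no SAS-specific alleles."
)
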