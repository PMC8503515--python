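"""How drifted cohorts and imperfect proxies move the ancestral information.

The ancestral information compares a cohort's specific-allele counts with
a reference expectation, so two real-data phenomena shift it predictably:
(1) a cohort whose specific-allele frequencies run above the reference's
gets information > 1; (2) a bottlenecked population in which only a
fraction of the reference's specific sites are still polymorphic gets
information shrunk by that fraction.
"""

import numpy as np

from ancspec import SimConfig, compute_spectrum, simulate_drifted_population, simulate_panel

rng = np.random.default_rng(41)
f = rng.uniform(0.01, 0.05, 20_000)
f_ref = f * (0.016 / f.mean())  # reference MAFs, mean 0.016
panel = simulate_panel(
    SimConfig(populations=("EUR",), m_per_pop=20_000, explicit_mafs={"EUR": f_ref}, seed=0)
)

# cohort with inflated frequencies: mean MAF 0.021 against reference 0.016
inflated = simulate_drifted_population(panel, 99, scale=0.021 / 0.016, seed=42)
info_inflated = compute_spectrum(inflated, panel).info[:, 0]

# bottlenecked cohort: only ~11% of specific sites still polymorphic
retain = 5454 / 50_000
bottleneck = simulate_drifted_population(panel, 99, scale=1.0, retain_fraction=retain, seed=43)
info_bottleneck = compute_spectrum(bottleneck, panel).info[:, 0]

print(f"mean information, inflated cohort   : {info_inflated.mean():.3f} "
      f"(analytic 0.021/0.016 = {0.021 / 0.016:.4f})")
print(f"mean information, bottlenecked cohort: {info_bottleneck.mean():.3f} "
      f"(analytic retained fraction = {retain:.4f})")
print(
    "\nInformation above one is reported untouched — it signals that the\n"
    "cohort's specific-allele frequencies exceed the reference's, not an\n"
    "estimation failure; information far below one against a plausible\n"
    "ancestor signals a poor proxy (bottleneck loss of specific alleles)."
)
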