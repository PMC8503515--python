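"""Closed-form eigenstructure of the expected GRM from specific SNPs.

Builds the empirical genetic relationship matrix of unadmixed reference
individuals, compares it with its analytic expectation (block-diagonal,
compound-symmetric), and checks the closed-form eigenvalues against a
dense eigensolver: one population-informative eigenvalue per population
plus a repeated noise eigenvalue.
"""

import numpy as np

from ancspec import (
    AdmixtureDesign,
    SimConfig,
    build_egrm,
    build_grm_ps,
    egrm_eigen,
    egrm_params,
    simulate_genotypes,
    simulate_panel,
)

panel = simulate_panel(SimConfig(populations=("EAS", "EUR"), m_per_pop=20_000, seed=31))
n_k = 20
design = AdmixtureDesign(
    ("EAS", "EUR"),
    np.repeat(np.eye(2), n_k, axis=0),
    labels=("EAS",) * n_k + ("EUR",) * n_k,
)
geno = simulate_genotypes(panel, design, seed=32)

z = build_grm_ps(geno)
params = egrm_params(panel, {"EAS": n_k, "EUR": n_k})
expected = build_egrm(params)
summary = egrm_eigen(params)

cross = np.abs(z.matrix[:n_k, n_k:]).max()
dev = np.abs(z.matrix - expected.matrix).max()
print(f"max |cross-population GRM entry| : {cross} (exactly zero by construction)")
print(f"max |Z - E[Z]| entrywise         : {dev:.5f}")
print(summary.to_frame().to_string(index=False))
numeric = np.sort(np.linalg.eigvalsh(expected.matrix))[::-1]
print("dense solver top eigenvalues     :", np.round(numeric[:2], 6))
print(
    "\nThe empirical GRM concentrates around its expectation as the panel\n"
    "grows; only the K top eigenpairs (one per population) carry population\n"
    "structure, which is why the estimators project onto those directions\n"
    "instead of eigendecomposing anything."
)
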