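"""Synthetic panels and genotypes under the binomial admixture model.

An individual with ancestral proportions p_n1..p_nK inherits each of its
two haplotypes independently: a haplotype comes from population k with
probability p_nk and then carries population k's specific allele at SNP m
with probability f_km.  Its minor-allele count at a population-k SNP is
therefore Binomial(2, p_nk * f_km), independent across SNPs and
individuals.  Diploid sampling is used throughout (rather than the 0/1
rare-allele approximation) so that downstream handling of homozygous
counts is exercised; for small f the two coincide.

:func:`simulate_drifted_population` adds the two expectation-level
departures seen in real cohorts measured against an external reference
panel: frequency inflation/deflation (a cohort whose specific-allele MAFs
sit above or below the reference's) and bottleneck loss (a fraction of the
reference's specific sites simply not polymorphic in the cohort).  Both
move the expected ancestral information multiplicatively, to
scale * retain_fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import AdmixtureDesign, GenotypeMatrix, SnpPanel

_GENOTYPE_CHUNK = 256  # individuals per draw; bounds peak memory at large M


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a synthetic panel.

    ``maf_law`` draws each SNP's reference MAF uniformly from the closed
    interval; ``explicit_mafs`` (population -> array) overrides it.  The
    defaults mirror a typical reference-panel design: four continental
    reference populations, 50,000 specific SNPs each, MAFs in [0.01, 0.05].
    """

    populations: tuple[str, ...] = ("POP1", "POP2", "POP3", "POP4")
    m_per_pop: int | Mapping[str, int] = 50_000
    maf_law: tuple[float, float] = (0.01, 0.05)
    explicit_mafs: Mapping[str, Sequence[float]] | None = None
    seed: int = 0
    ploidy: int = 2

    def __post_init__(self) -> None:
        low, high = self.maf_law
        if not (0 < low <= high <= 0.5):
            raise ValueError("maf_law must satisfy 0 < low <= high <= 0.5")
        if self.ploidy != 2:
            raise ValueError("only diploid simulation is supported")

    def sizes(self) -> dict[str, int]:
        if isinstance(self.m_per_pop, Mapping):
            out = {p: int(self.m_per_pop[p]) for p in self.populations}
        else:
            out = {p: int(self.m_per_pop) for p in self.populations}
        if any(m < 1 for m in out.values()):
            raise ValueError("m_per_pop must be >= 1 for every population")
        return out


def simulate_panel(config: SimConfig) -> SnpPanel:
    """Draw a synthetic population-specific SNP panel.

    SNPs are laid out on one synthetic chromosome per population with
    consecutive 1-based positions; alleles are fixed A (minor) / C.
    Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    sizes = config.sizes()
    parts = []
    for chrom, pop in enumerate(config.populations, start=1):
        m = sizes[pop]
        if config.explicit_mafs is not None and pop in config.explicit_mafs:
            maf = np.asarray(config.explicit_mafs[pop], dtype=float)
            if maf.size != m:
                raise ValueError(f"explicit MAFs for {pop!r} must have length {m}")
            if np.any(maf <= 0) or np.any(maf > 0.5):
                raise ValueError("explicit MAFs must lie in (0, 0.5]")
        else:
            low, high = config.maf_law
            maf = rng.uniform(low, high, size=m)
        parts.append(
            pd.DataFrame(
                {
                    "CHROM": str(chrom),
                    "POS": np.arange(1, m + 1),
                    "ID": [f"{pop}_snp{i:06d}" for i in range(1, m + 1)],
                    "MINOR": "A",
                    "OTHER": "C",
                    "POP": pop,
                    "MAF": maf,
                }
            )
        )
    df = pd.concat(parts, ignore_index=True)
    df = df.sort_values(["POP", "CHROM", "POS"], kind="mergesort").reset_index(drop=True)
    return SnpPanel(df)


def _binomial_counts(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """Binomial(2, probs) draws, skipping all-zero rows, chunked for memory.

    Sampled as the sum of two independent Bernoulli haplotype draws —
    the exact same distribution, an order of magnitude faster than a
    generic binomial sampler at these matrix sizes.
    """
    out = np.zeros(probs.shape)
    nz_rows = np.flatnonzero(probs.max(axis=1) > 0) if probs.size else np.array([], int)
    for start in range(0, nz_rows.size, _GENOTYPE_CHUNK):
        rows = nz_rows[start : start + _GENOTYPE_CHUNK]
        p = probs[rows]
        draws = (rng.random(p.shape) < p).astype(float)
        draws += rng.random(p.shape) < p
        out[rows] = draws
    return out


def simulate_genotypes(
    panel: SnpPanel, design: AdmixtureDesign, seed: int
) -> GenotypeMatrix:
    """Simulate diploid genotypes for an admixture design against a panel.

    For individual n and a SNP specific to population k, the minor-allele
    count is Binomial(2, p_nk * f_km).  An individual with p_nk = 0 carries
    exactly zero population-k alleles, and a pure member (p_nk = 1) has the
    reference genotype distribution Binomial(2, f_km) at its own SNPs.
    """
    missing = [p for p in design.populations if p not in panel.populations]
    if missing:
        raise ValueError(f"design references populations not in the panel: {missing}")
    rng = np.random.default_rng(seed)
    n = design.n_individuals
    values = np.zeros((n, panel.M))
    for j, pop in enumerate(design.populations):
        p_col = design.proportions[:, j]
        if not p_col.any():
            continue
        idx = panel.block(pop)
        f = panel.maf[idx]
        if p_col.max() * f.max() > 1.0:
            raise ValueError(
                f"p * f exceeds 1 for population {pop!r}: not a probability"
            )
        values[:, idx] = _binomial_counts(rng, p_col[:, None] * f[None, :])
    sample_ids = [f"sim{i:05d}" for i in range(1, n + 1)]
    pops = list(design.labels) if design.labels is not None else None
    return GenotypeMatrix(
        values=values,
        sample_ids=sample_ids,
        snp_ids=panel.snp_ids,
        populations=pops,
        variants=panel.df[["CHROM", "POS", "ID"]]
        .assign(A1=panel.df["MINOR"], A2=panel.df["OTHER"])
        .reset_index(drop=True),
        validate=False,
    )


def simulate_drifted_population(
    panel: SnpPanel,
    n_individuals: int,
    scale: float | Mapping[str, float],
    retain_fraction: float | Mapping[str, float] = 1.0,
    seed: int = 0,
    label: str = "drifted",
) -> GenotypeMatrix:
    """Simulate a cohort whose allele frequencies drifted from the reference.

    Per population, genotypes are drawn at frequency ``scale * f`` on a
    uniformly chosen retained subset of that population's panel SNPs
    (``retain_fraction`` of them, at least one when the fraction is
    positive) and are zero on the rest.  The expected ancestral information
    measured against the unmodified reference panel is analytically
    ``scale * retain_fraction`` per population (for uniform retention, in
    expectation over the retained subset).

    ``scale = 1, retain_fraction = 1`` reproduces the law of
    :func:`simulate_genotypes` for a pure population member.
    """
    rng = np.random.default_rng(seed)
    pops = panel.populations
    scales = (
        {p: float(scale[p]) for p in pops}
        if isinstance(scale, Mapping)
        else {p: float(scale) for p in pops}
    )
    retains = (
        {p: float(retain_fraction[p]) for p in pops}
        if isinstance(retain_fraction, Mapping)
        else {p: float(retain_fraction) for p in pops}
    )
    values = np.zeros((n_individuals, panel.M))
    for pop in pops:
        r = retains[pop]
        if not (0 < r <= 1):
            raise ValueError(f"retain_fraction for {pop!r} must lie in (0, 1]")
        idx = panel.block(pop)
        f = scales[pop] * panel.maf[idx]
        if np.any(f > 0.5):
            raise ValueError(
                f"scaled frequency exceeds 0.5 for population {pop!r}"
            )
        keep = np.sort(rng.choice(idx.size, size=max(1, round(r * idx.size)), replace=False))
        kept_cols = idx[keep]
        probs = np.broadcast_to(f[keep], (n_individuals, kept_cols.size)).copy()
        values[:, kept_cols] = _binomial_counts(rng, probs)
    sample_ids = [f"{label}{i:05d}" for i in range(1, n_individuals + 1)]
    return GenotypeMatrix(
        values=values,
        sample_ids=sample_ids,
        snp_ids=panel.snp_ids,
        populations=[label] * n_individuals,
        validate=False,
    )
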