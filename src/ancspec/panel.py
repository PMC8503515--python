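"""Selection of population-specific SNPs from reference genotypes.

A SNP is *population specific* when it is polymorphic (minor-allele
frequency f > 0) in exactly one of the K reference populations and
monomorphic in all others.  Panels are drawn from the specific SNPs inside
a per-population MAF window, typically [0.01, 0.05]: specific alleles in
that range are common enough to be sampled reliably yet rare enough to be
recent, population-private mutations.

The pipeline is: :func:`compute_maf` (per-population frequencies with a
single, pooled minor-allele designation per SNP), then
:func:`select_specific_snps` (eligibility + seeded subsampling), then
optionally :func:`tabulate_panel` for summary counts.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, PopulationAssignment, SnpPanel

MAF_STRATA = [0.005, 0.01, 0.05, 0.10]


def _default_variants(geno: GenotypeMatrix) -> pd.DataFrame:
    """Synthesize variant metadata when the genotype source carries none."""
    m = geno.n_snps
    return pd.DataFrame(
        {
            "CHROM": ["1"] * m,
            "POS": np.arange(1, m + 1, dtype=int),
            "ID": geno.snp_ids,
            "A1": ["A"] * m,
            "A2": ["B"] * m,
        }
    )


def compute_maf(
    genotypes: GenotypeMatrix, assignment: PopulationAssignment
) -> pd.DataFrame:
    """Per-population minor-allele frequencies of every SNP.

    The minor allele is designated once per SNP on the pooled reference
    sample (frequency <= 0.5 over all reference individuals; at exactly 0.5
    the lexicographically smaller allele character wins), and per-population
    frequencies are reported for that allele.  Missing calls are excluded
    from numerator and denominator; a population with no observed calls at a
    SNP gets frequency NaN there, which makes the SNP ineligible for panels.

    Returns a frame with columns CHROM, POS, ID, MINOR, OTHER and one
    frequency column per reference population.
    """
    pops = assignment.reference_populations
    if not pops:
        raise ValueError("assignment contains no reference populations")
    sample_rows = {s: i for i, s in enumerate(genotypes.sample_ids)}
    try:
        pop_rows = {
            p: np.array([sample_rows[s] for s in assignment.samples_in(p)], dtype=np.intp)
            for p in pops
        }
    except KeyError as exc:
        raise ValueError(f"assignment sample {exc} not found in genotypes") from None

    x = genotypes.values  # NaN = missing
    variants = genotypes.variants if genotypes.variants is not None else _default_variants(genotypes)
    variants = variants.reset_index(drop=True)

    # Pooled counted-allele (A1) frequency across all reference samples.
    ref_rows = np.concatenate([pop_rows[p] for p in pops])
    pooled_copies = np.nansum(x[ref_rows], axis=0)
    pooled_called = 2.0 * np.sum(~np.isnan(x[ref_rows]), axis=0)
    with np.errstate(invalid="ignore"):
        pooled_freq = np.where(pooled_called > 0, pooled_copies / pooled_called, np.nan)

    a1 = variants["A1"].to_numpy(dtype=object)
    a2 = variants["A2"].to_numpy(dtype=object)
    # flip when A1 is the pooled major allele; lexicographic tie-break at 0.5
    tie = pooled_freq == 0.5
    flip = (pooled_freq > 0.5) | (tie & (a2 < a1))
    minor = np.where(flip, a2, a1)
    other = np.where(flip, a1, a2)

    out = pd.DataFrame(
        {
            "CHROM": variants["CHROM"].astype(str),
            "POS": variants["POS"].astype(int),
            "ID": variants["ID"].astype(str),
            "MINOR": minor,
            "OTHER": other,
        }
    )
    for p in pops:
        rows = x[pop_rows[p]]
        copies = np.nansum(rows, axis=0)
        called = 2.0 * np.sum(~np.isnan(rows), axis=0)
        with np.errstate(invalid="ignore"):
            freq = np.where(called > 0, copies / called, np.nan)
        out[p] = np.where(flip, 1.0 - freq, freq)
    return out


def _per_population(value, pops: list[str], what: str) -> dict:
    if isinstance(value, Mapping):
        missing = [p for p in pops if p not in value]
        if missing:
            raise ValueError(f"{what} missing for populations {missing}")
        return {p: value[p] for p in pops}
    return {p: value for p in pops}


def select_specific_snps(
    mafs: pd.DataFrame,
    maf_window: tuple[float, float] | Mapping[str, tuple[float, float]],
    panel_size: int | Mapping[str, int],
    seed: int,
) -> SnpPanel:
    """Draw the population-specific SNP panel.

    A SNP is eligible for population k iff its frequency is positive in k,
    exactly zero in every other reference population (NaN disqualifies), and
    inside k's closed MAF window.  ``panel_size`` SNPs are then drawn
    uniformly without replacement per population with a seeded generator, so
    identical inputs and seed give identical panels.

    Raises ``ValueError`` when a population has fewer eligible SNPs than
    requested, naming the population and both counts.
    """
    pops = [c for c in mafs.columns if c not in ("CHROM", "POS", "ID", "MINOR", "OTHER")]
    if not pops:
        raise ValueError("MAF table has no population frequency columns")
    windows = _per_population(maf_window, pops, "maf_window")
    sizes = _per_population(panel_size, pops, "panel_size")

    freq = mafs[pops].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    chosen_parts: list[pd.DataFrame] = []
    for j, pop in enumerate(sorted(pops)):
        col = pops.index(pop)
        low, high = windows[pop]
        own = freq[:, col]
        others = np.delete(freq, col, axis=1)
        eligible = (
            (own > 0)
            & (own >= low)
            & (own <= high)
            & np.all(others == 0, axis=1)  # NaN compares False -> disqualified
        )
        idx = np.flatnonzero(eligible)
        want = int(sizes[pop])
        if idx.size < want:
            raise ValueError(
                f"population {pop!r}: only {idx.size} eligible SNPs, "
                f"panel_size {want} requested"
            )
        pick = np.sort(rng.choice(idx, size=want, replace=False))
        part = mafs.iloc[pick][["CHROM", "POS", "ID", "MINOR", "OTHER"]].copy()
        part["POP"] = pop
        part["MAF"] = mafs.iloc[pick][pop].to_numpy(dtype=float)
        part = part.sort_values(["CHROM", "POS"], kind="mergesort")
        chosen_parts.append(part)

    df = pd.concat(chosen_parts, ignore_index=True) if chosen_parts else pd.DataFrame(
        columns=["CHROM", "POS", "ID", "MINOR", "OTHER", "POP", "MAF"]
    )
    return SnpPanel(df)


def tabulate_panel(
    panel: SnpPanel, pop_sizes: Mapping[str, int] | None = None
) -> pd.DataFrame:
    """Counts of panel SNPs per population and cumulative MAF stratum.

    Strata are cumulative thresholds (MAF > 0.5%, > 1%, > 5%, > 10%).  When
    ``pop_sizes`` gives the reference sample sizes, a singleton column is
    added (a singleton carries exactly one minor-allele copy, f = 1/(2N_k)).
    The final ``Total`` row sums the population rows.
    """
    pops = panel.populations
    cols = ["N_SNPS"]
    if pop_sizes is not None:
        cols.append("SINGLETON")
    cols += [f"MAF>{t:g}" for t in MAF_STRATA]

    rows = {}
    for p in pops:
        maf = panel.df.loc[panel.df["POP"] == p, "MAF"].to_numpy(dtype=float)
        row = [len(maf)]
        if pop_sizes is not None:
            singleton_f = 1.0 / (2.0 * pop_sizes[p])
            row.append(int(np.sum(np.isclose(maf, singleton_f))))
        row += [int(np.sum(maf > t)) for t in MAF_STRATA]
        rows[p] = row
    table = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    table.loc["Total"] = table.sum(axis=0)
    table.index.name = "POP"
    return table
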