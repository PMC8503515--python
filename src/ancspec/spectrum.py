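"""Principal scores and ancestral information — the core inference.

Both estimators are linear in the genotype vector and need only the
reference minor-allele frequencies of the panel SNPs, never an
eigendecomposition of study-sample data.  Writing mu_km = 2 f_km for the
expected minor-allele count of a population-k member:

* principal score      a_nk = sum_m X(n,m) mu_km / sum_m mu_km^2
  (projection onto the asymptotic principal direction of population k;
  unbiased for the ancestral proportion, MAF-proportional weights, maximum
  variance among the two);

* ancestral information p_nk = sum_{m in G_k} X(n,m) / sum_{m in G_k} mu_km
  (observed count of population-k-specific alleles over its reference
  expectation; equal weights; the best linear unbiased estimator of the
  ancestral proportion for rare alleles).

Ancestral information is deliberately NOT constrained to sum to one across
populations, and values above one are reported untouched: an information of
1.3 legitimately arises when a cohort's specific-allele frequencies exceed
the reference MAFs.  A maximum-likelihood estimate under the rare-allele
binomial genotype model is available as a cross-check via
:func:`mle_ancestral_information`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .containers import GenotypeMatrix, PopulationAssignment, SnpPanel

_MLE_BRACKET_EPS = 1e-9
_MLE_XTOL = 1e-10


@dataclass(frozen=True)
class LoadingVectors:
    """Per-population loading vectors over the panel's M SNPs.

    ``b`` (M x K) holds the principal-score loadings mu_k / sum(mu_k^2),
    ``d`` (M x K) the ancestral-information loadings (constant 1/sum(mu_k)
    on population k's SNPs).  ``v`` holds the unit-norm principal
    directions mu_k / sqrt(sum mu_k^2), exposed for users who want
    orthonormal projections rather than proportion-scaled scores.  All
    vectors are zero outside their population's SNP block.
    """

    populations: tuple[str, ...]
    snp_ids: tuple[str, ...]
    b: np.ndarray
    d: np.ndarray
    v: np.ndarray
    sum_mu: np.ndarray   # per population: sum of mu over its block
    sum_mu2: np.ndarray  # per population: sum of mu^2 over its block


@dataclass
class SpectrumResult:
    """Per-individual ancestral spectrum.

    ``scores`` and ``info`` are N x K (principal scores, ancestral
    information); ``counts`` the raw per-population specific-allele counts;
    ``total`` the row sum of the information (not constrained to one);
    ``mle`` the optional maximum-likelihood estimates with ``mle_boundary``
    flagging individuals whose likelihood had no interior stationary point.
    """

    sample_ids: list[str]
    populations: tuple[str, ...]
    scores: np.ndarray
    info: np.ndarray
    counts: np.ndarray
    total: np.ndarray
    call_rate: np.ndarray
    mle: np.ndarray | None = None
    mle_boundary: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        data: dict[str, object] = {"SAMPLE": self.sample_ids}
        for j, p in enumerate(self.populations):
            data[f"SCORE_{p}"] = self.scores[:, j]
        for j, p in enumerate(self.populations):
            data[f"INFO_{p}"] = self.info[:, j]
        if self.mle is not None:
            for j, p in enumerate(self.populations):
                data[f"MLE_{p}"] = self.mle[:, j]
        data["TOTAL_INFO"] = self.total
        data["CALLRATE"] = self.call_rate
        return pd.DataFrame(data)


def make_loadings(panel: SnpPanel) -> LoadingVectors:
    """Loading vectors from the panel's reference MAFs.

    Scaled so that an unadmixed population-k member has expected principal
    score and expected ancestral information both equal to one.
    """
    if panel.M == 0:
        raise ValueError("panel is empty")
    pops = tuple(panel.populations)
    mu = panel.mu
    if np.any(mu <= 0):
        raise ValueError("all panel MAFs must be positive")
    m, k = panel.M, len(pops)
    b = np.zeros((m, k))
    d = np.zeros((m, k))
    v = np.zeros((m, k))
    sum_mu = np.empty(k)
    sum_mu2 = np.empty(k)
    for j, p in enumerate(pops):
        idx = panel.block(p)
        mu_k = mu[idx]
        sum_mu[j] = mu_k.sum()
        sum_mu2[j] = np.sum(mu_k**2)
        b[idx, j] = mu_k / sum_mu2[j]
        v[idx, j] = mu_k / np.sqrt(sum_mu2[j])
        d[idx, j] = 1.0 / sum_mu[j]
    return LoadingVectors(pops, tuple(panel.snp_ids), b, d, v, sum_mu, sum_mu2)


def _check_alignment(genotypes: GenotypeMatrix, loadings: LoadingVectors) -> None:
    if tuple(genotypes.snp_ids) != loadings.snp_ids:
        raise ValueError("genotype columns are not aligned to the loading vectors")


def _project(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Row-by-row X @ w.

    One matrix-vector product per individual, so each row's result is
    bitwise identical however many other individuals share the batch
    (a single gemm call may reorder summation with batch shape).
    """
    out = np.empty((x.shape[0], w.shape[1]))
    for i in range(x.shape[0]):
        out[i] = x[i] @ w
    return out


def principal_scores(
    genotypes: GenotypeMatrix, loadings: LoadingVectors, unit_norm: bool = False
) -> np.ndarray:
    """Project genotypes onto the reference principal directions.

    Returns an N x K array; with the default scaling a population-k member
    scores approximately 1 for k and exactly 0 for populations whose
    specific alleles it does not carry.  ``unit_norm`` projects onto the
    orthonormal directions instead.  Each row depends only on that
    individual's genotypes, so batch composition cannot change anyone's
    score.
    """
    _check_alignment(genotypes, loadings)
    w = loadings.v if unit_norm else loadings.b
    return _project(genotypes.filled(), w)


def ancestral_information(
    genotypes: GenotypeMatrix, loadings: LoadingVectors
) -> np.ndarray:
    """BLUE of the ancestral proportions: X d_k, one column per population.

    Equal-weight ratio of each individual's observed population-specific
    allele count to the reference expectation.  Non-negative, zero exactly
    when no specific allele is carried, unconstrained above.
    """
    _check_alignment(genotypes, loadings)
    return _project(genotypes.filled(), loadings.d)


def specific_allele_counts(
    genotypes: GenotypeMatrix, loadings: LoadingVectors
) -> np.ndarray:
    """Raw count of population-specific minor alleles per individual (N x K)."""
    _check_alignment(genotypes, loadings)
    return _project(genotypes.filled(), loadings.d * loadings.sum_mu)


def _mle_root(x01: np.ndarray, mu: np.ndarray) -> tuple[float, bool]:
    """Solve p * sum mu (1 - X)/(1 - p mu) = sum X for p on [0, (1-eps)/max mu]."""
    s = x01.sum()
    if s == 0:
        return 0.0, False
    hi = (1.0 - _MLE_BRACKET_EPS) / mu.max()
    carried = x01 > 0

    def score(p: float) -> float:
        return p * np.sum(mu[~carried] / (1.0 - p * mu[~carried])) - s

    if score(hi) < 0:  # likelihood still increasing at the bracket end
        return hi, True
    root = brentq(score, 0.0, hi, xtol=_MLE_XTOL)
    return float(root), False


def mle_ancestral_information(
    genotype_row: np.ndarray, panel: SnpPanel, population: str
) -> tuple[float, bool]:
    """Maximum-likelihood ancestral proportion for one individual/population.

    Under the rare-allele model each genotype is Bernoulli with success
    probability p * mu_km, so the likelihood is defined for X in {0, 1};
    homozygous counts are truncated to 1 with a warning.  Missing calls
    count as 0.  Returns ``(estimate, at_boundary)``: when the likelihood
    is monotone increasing on the admissible range (possible for carriers
    of unusually many specific alleles) the upper bracket end
    (1 - 1e-9)/max(mu_k) is returned with the flag set.
    """
    idx = panel.block(population)
    mu = panel.mu[idx]
    x = np.nan_to_num(np.asarray(genotype_row, dtype=float)[idx], nan=0.0)
    if np.any(x > 1):
        warnings.warn(
            "homozygous minor-allele counts truncated to 1 for the "
            "rare-allele likelihood",
            stacklevel=2,
        )
        x = np.minimum(x, 1.0)
    return _mle_root(x, mu)


def mle_ancestral_information_matrix(
    genotypes: GenotypeMatrix, panel: SnpPanel
) -> tuple[np.ndarray, np.ndarray]:
    """MLE spectrum for every individual and population (N x K, plus flags)."""
    genotypes.check_aligned(panel)
    pops = panel.populations
    n = genotypes.n_samples
    est = np.zeros((n, len(pops)))
    boundary = np.zeros((n, len(pops)), dtype=bool)
    x = np.minimum(genotypes.filled(), 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j, p in enumerate(pops):
            idx = panel.block(p)
            mu = panel.mu[idx]
            for i in range(n):
                est[i, j], boundary[i, j] = _mle_root(x[i, idx], mu)
    return est, boundary


def compute_spectrum(
    genotypes: GenotypeMatrix,
    panel: SnpPanel,
    mle: bool = False,
    unit_norm: bool = False,
) -> SpectrumResult:
    """Full ancestral spectrum of a genotype batch against a panel."""
    genotypes.check_aligned(panel)
    loadings = make_loadings(panel)
    miss = np.isnan(genotypes.values)
    call_rate = (
        1.0 - miss.mean(axis=1) if genotypes.n_snps else np.ones(genotypes.n_samples)
    )
    # fill missing once, and only when there is anything to fill
    x = np.where(miss, 0.0, genotypes.values) if miss.any() else genotypes.values
    scores = _project(x, loadings.v if unit_norm else loadings.b)
    codes = panel.pop_codes()
    if codes.size and np.all(np.diff(codes) >= 0):
        # contiguous population blocks: one pass, row-local (batch invariant)
        starts = np.searchsorted(codes, np.arange(len(loadings.populations)))
        counts = np.add.reduceat(x, starts, axis=1)
    else:
        counts = _project(x, loadings.d * loadings.sum_mu)
    info = counts / loadings.sum_mu
    result = SpectrumResult(
        sample_ids=list(genotypes.sample_ids),
        populations=loadings.populations,
        scores=scores,
        info=info,
        counts=counts,
        total=info.sum(axis=1),
        call_rate=call_rate,
    )
    if mle:
        result.mle, result.mle_boundary = mle_ancestral_information_matrix(
            genotypes, panel
        )
    return result


def summarize_spectra(
    result: SpectrumResult,
    assignment: PopulationAssignment,
    outlier_sd: float = 4.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group-wise summary of ancestral information and genetic outliers.

    Returns ``(summary, outliers)``: per labelled group, mean and standard
    deviation of each population's information and of the total; and the
    individuals any of whose information components deviates more than
    ``outlier_sd`` group standard deviations from their group mean.
    Standard deviations are sample SDs and undefined (NaN) for singleton
    groups, which therefore yield no outlier calls; in a degenerate group
    with zero spread, any deviation at all is flagged.
    """
    frame = result.to_frame()
    group = [assignment.population_of(s) for s in result.sample_ids]
    frame = frame.assign(GROUP=group)
    info_cols = [f"INFO_{p}" for p in result.populations] + ["TOTAL_INFO"]

    agg = frame.groupby("GROUP")[info_cols].agg(["mean", "std"])
    agg.columns = [f"{c}_{stat.upper()}" for c, stat in agg.columns]
    agg = agg.join(frame.groupby("GROUP").size().rename("N"))

    flags = []
    for _, row in frame.iterrows():
        g = row["GROUP"]
        flagged = []
        for c in info_cols:
            mean = agg.loc[g, f"{c}_MEAN"]
            sd = agg.loc[g, f"{c}_STD"]
            dev = abs(row[c] - mean)
            if np.isnan(sd):
                continue
            if (sd == 0 and dev > 0) or (sd > 0 and dev > outlier_sd * sd):
                flagged.append(c)
        if flagged:
            flags.append(
                {"SAMPLE": row["SAMPLE"], "GROUP": g, "COMPONENTS": ",".join(flagged)}
            )
    outliers = pd.DataFrame(flags, columns=["SAMPLE", "GROUP", "COMPONENTS"])
    return agg.reset_index(), outliers
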