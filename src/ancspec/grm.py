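"""Genetic relationship matrix from population-specific SNPs (GRM-PS).

With M panel SNPs and genotype matrix X (minor-allele counts), the GRM-PS
is Z = (1/M) X Xt.  Because every panel SNP is private to one reference
population, reference individuals carry no copies of other populations'
SNPs and Z is exactly block-diagonal over populations.

The expectation of Z has compound-symmetric blocks with closed-form
entries and eigenvalues:

    z_k   = (1/M) sum_{m in G_k} 2 f_km          (diagonal)
    z_kk  = (1/M) sum_{m in G_k} 4 f_km^2        (within-block off-diagonal)
    lambda_k = z_k + (N_k - 1) z_kk              (top, population-informative)
    z_k - z_kk = (1/M) sum_{m in G_k} sigma_km^2 (repeated, multiplicity N_k-1)

where sigma_km^2 = 2 f (1 - 2 f) is the genotypic variance under the
rare-allele 0/1 model.  Only the K top eigenpairs carry population
structure; the repeated eigenvalue is pure within-population noise.  These
utilities exist for validation and diagnostics — the inference path
(:mod:`ancspec.spectrum`) never eigendecomposes anything.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, SnpPanel


@dataclass(frozen=True)
class GrmPs:
    """A (possibly expected) GRM-PS: symmetric N x N matrix and normalizer M."""

    matrix: np.ndarray
    M: int
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.matrix, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("GRM must be square")
        object.__setattr__(self, "matrix", a)


@dataclass(frozen=True)
class EgrmParams:
    """Per-population parameters of the expected GRM-PS."""

    populations: tuple[str, ...]
    z: np.ndarray        # expected diagonal, per population
    zkk: np.ndarray      # expected within-block off-diagonal
    n: np.ndarray        # block (population) sample sizes
    M: int               # panel size used as normalizer

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        zkk = np.asarray(self.zkk, dtype=float)
        n = np.asarray(self.n, dtype=int)
        if not (len(self.populations) == z.size == zkk.size == n.size):
            raise ValueError("per-population arrays must share a length")
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "zkk", zkk)
        object.__setattr__(self, "n", n)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"POP": self.populations, "N": self.n, "Z_DIAG": self.z, "Z_OFF": self.zkk}
        )


@dataclass(frozen=True)
class EigenSummary:
    """Closed-form eigenstructure of the expected GRM-PS, per block."""

    populations: tuple[str, ...]
    top: np.ndarray           # lambda_k, population-informative
    repeated: np.ndarray      # z_k - z_kk
    multiplicity: np.ndarray  # N_k - 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "POP": self.populations,
                "LAMBDA": self.top,
                "REPEATED": self.repeated,
                "MULTIPLICITY": self.multiplicity,
            }
        )

    def all_eigenvalues(self) -> np.ndarray:
        """The full spectrum (top values plus repeats), descending."""
        vals = []
        for lam, rep, mult in zip(self.top, self.repeated, self.multiplicity):
            vals.append([lam])
            vals.append(np.full(int(mult), rep))
        return np.sort(np.concatenate(vals))[::-1]


def build_grm_ps(genotypes: GenotypeMatrix) -> GrmPs:
    """Empirical GRM-PS, Z = (1/M) X Xt; missing calls count zero copies."""
    if genotypes.n_snps == 0:
        raise ValueError("cannot build a GRM from zero SNPs")
    x = genotypes.filled()
    z = (x @ x.T) / genotypes.n_snps
    return GrmPs(matrix=z, M=genotypes.n_snps, sample_ids=list(genotypes.sample_ids))


def egrm_params(panel: SnpPanel, pop_sizes: Mapping[str, int]) -> EgrmParams:
    """Expected-GRM parameters z_k and z_kk from panel MAFs."""
    if panel.M == 0:
        raise ValueError("panel is empty")
    pops = panel.populations
    missing = [p for p in pops if p not in pop_sizes]
    if missing:
        raise ValueError(f"pop_sizes missing for populations {missing}")
    z = np.empty(len(pops))
    zkk = np.empty(len(pops))
    for i, p in enumerate(pops):
        f = panel.maf[panel.block(p)]
        z[i] = np.sum(2.0 * f) / panel.M
        zkk[i] = np.sum(4.0 * f**2) / panel.M
    n = np.array([int(pop_sizes[p]) for p in pops])
    return EgrmParams(tuple(pops), z, zkk, n, panel.M)


def egrm_eigen(params: EgrmParams) -> EigenSummary:
    """Closed-form eigenvalues of the expected GRM-PS.

    Each compound-symmetric block contributes one top eigenvalue
    lambda_k = z_k + (N_k - 1) z_kk with eigenvector 1/sqrt(N_k) inside the
    block, and an (N_k - 1)-fold repeated eigenvalue z_k - z_kk.
    """
    if np.any(params.n < 1):
        raise ValueError("block sizes must be >= 1")
    top = params.z + (params.n - 1) * params.zkk
    repeated = params.z - params.zkk
    return EigenSummary(params.populations, top, repeated, params.n - 1)


def build_egrm(params: EgrmParams) -> GrmPs:
    """Dense expected GRM-PS: block-diagonal, compound-symmetric blocks."""
    n_total = int(params.n.sum())
    out = np.zeros((n_total, n_total))
    start = 0
    for z, zkk, nk in zip(params.z, params.zkk, params.n):
        stop = start + int(nk)
        out[start:stop, start:stop] = zkk
        np.fill_diagonal(out[start:stop, start:stop], z)
        start = stop
    return GrmPs(matrix=out, M=params.M)
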