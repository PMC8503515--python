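"""Shared data containers for ancestral spectrum analysis.

The central objects are :class:`SnpPanel` (population-specific SNPs with
their reference minor-allele frequencies), :class:`GenotypeMatrix`
(minor-allele counts per sample and SNP), :class:`PopulationAssignment`
(sample -> population labels) and :class:`AdmixtureDesign` (true ancestral
proportions used by the simulator).
"""

from __future__ import annotations

from dataclasses import InitVar, dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Label used in assignment tables for non-reference (study/target) samples.
TARGET_LABEL = "target"

PANEL_COLUMNS = ["CHROM", "POS", "ID", "MINOR", "OTHER", "POP", "MAF"]


@dataclass(frozen=True)
class PopulationAssignment:
    """Mapping of sample IDs to population labels.

    Samples labelled :data:`TARGET_LABEL` are study individuals; all other
    labels denote reference populations.
    """

    sample_ids: tuple[str, ...]
    populations: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.populations):
            raise ValueError("sample_ids and populations differ in length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = pd.Index(self.sample_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValueError(f"duplicate sample IDs: {dupes}")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "PopulationAssignment":
        return cls(tuple(mapping.keys()), tuple(mapping.values()))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PopulationAssignment":
        return cls(
            tuple(str(s) for s in frame["SAMPLE"]),
            tuple(str(p) for p in frame["POP"]),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"SAMPLE": self.sample_ids, "POP": self.populations})

    @property
    def reference_populations(self) -> list[str]:
        """Sorted reference population labels (excludes the target label)."""
        return sorted({p for p in self.populations if p != TARGET_LABEL})

    def samples_in(self, population: str) -> list[str]:
        return [s for s, p in zip(self.sample_ids, self.populations) if p == population]

    def population_of(self, sample_id: str) -> str:
        try:
            return self.populations[self.sample_ids.index(sample_id)]
        except ValueError:
            raise KeyError(f"unknown sample ID: {sample_id}") from None

    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for p in self.populations:
            if p != TARGET_LABEL:
                out[p] = out.get(p, 0) + 1
        return out


@dataclass(frozen=True)
class SnpPanel:
    """An ordered panel of population-specific SNPs.

    Each SNP is specific to exactly one reference population ``POP`` and
    carries its minor-allele frequency ``MAF`` in that population.  Rows are
    sorted by population, then chromosome and position.  The expected
    minor-allele count of a population member is ``mu = 2 * MAF`` per SNP.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PANEL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"panel frame is missing columns {missing}")
        maf = self.df["MAF"].to_numpy(dtype=float)
        if len(maf) and not (np.all(maf > 0) and np.all(maf <= 0.5)):
            raise ValueError("panel MAFs must lie in (0, 0.5]")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def M(self) -> int:
        """Total number of panel SNPs."""
        return len(self.df)

    @property
    def populations(self) -> list[str]:
        """Population labels in panel (row-block) order."""
        seen: list[str] = []
        for p in self.df["POP"]:
            if p not in seen:
                seen.append(p)
        return seen

    @property
    def sizes(self) -> dict[str, int]:
        """Number of SNPs specific to each population (M_k)."""
        counts = self.df["POP"].value_counts()
        return {p: int(counts[p]) for p in self.populations}

    @property
    def snp_ids(self) -> list[str]:
        return [str(s) for s in self.df["ID"]]

    @property
    def maf(self) -> np.ndarray:
        return self.df["MAF"].to_numpy(dtype=float)

    @property
    def mu(self) -> np.ndarray:
        """Expected minor-allele count per SNP for a population member, 2f."""
        return 2.0 * self.maf

    def block(self, population: str) -> np.ndarray:
        """Column indices of the SNPs specific to ``population``."""
        idx = np.flatnonzero((self.df["POP"] == population).to_numpy())
        if idx.size == 0:
            raise KeyError(f"panel has no SNPs for population {population!r}")
        return idx

    def pop_codes(self) -> np.ndarray:
        """Per-SNP integer code of the specific population, in panel pop order."""
        order = {p: i for i, p in enumerate(self.populations)}
        return np.array([order[p] for p in self.df["POP"]], dtype=np.intp)


@dataclass
class GenotypeMatrix:
    """N x M matrix of minor-allele counts, NaN marking missing calls.

    Columns align with a :class:`SnpPanel` (same SNP order) when the matrix
    was built against one.  ``populations`` optionally labels samples.
    """

    values: np.ndarray
    sample_ids: list[str]
    snp_ids: list[str]
    populations: list[str] | None = None
    variants: pd.DataFrame | None = field(default=None, repr=False)
    #: set False by internal constructors whose values are valid by build
    validate: InitVar[bool] = True

    def __post_init__(self, validate: bool) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D array")
        n, m = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match row count")
        if len(self.snp_ids) != m:
            raise ValueError("snp_ids length does not match column count")
        if self.populations is not None and len(self.populations) != n:
            raise ValueError("populations length does not match row count")
        if validate and n:
            # valid entries are 0, 1, 2 or NaN: v(v-1)(v-2) is 0 or NaN then;
            # chunked to bound temporaries on large matrices
            step = max(1, (1 << 22) // max(m, 1))
            for start in range(0, n, step):
                v = self.values[start : start + step]
                with np.errstate(invalid="ignore"):
                    residue = v * (v - 1.0) * (v - 2.0)
                bad = residue != 0.0
                np.logical_and(bad, ~np.isnan(residue), out=bad)
                if bad.any():
                    raise ValueError("genotype values must be 0, 1, 2 or NaN")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def filled(self) -> np.ndarray:
        """Values with missing calls imputed as zero copies.

        For rare panel alleles homozygous-major is the overwhelmingly likely
        call, so a missing genotype contributes no minor-allele copies.
        """
        return np.nan_to_num(self.values, nan=0.0)

    def call_rate(self) -> np.ndarray:
        """Per-sample fraction of non-missing genotype calls."""
        if self.n_snps == 0:
            return np.ones(self.n_samples)
        return 1.0 - np.isnan(self.values).mean(axis=1)

    def subset_samples(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=np.intp)
        return GenotypeMatrix(
            values=self.values[idx].copy(),
            sample_ids=[self.sample_ids[i] for i in idx],
            snp_ids=list(self.snp_ids),
            populations=None
            if self.populations is None
            else [self.populations[i] for i in idx],
            variants=self.variants,
            validate=False,
        )

    def check_aligned(self, panel: SnpPanel) -> None:
        """Raise if the column order does not match the panel's SNP order."""
        if self.snp_ids != panel.snp_ids:
            raise ValueError(
                "genotype columns are not aligned to the panel "
                f"({self.n_snps} columns vs {panel.M} panel SNPs)"
            )


@dataclass(frozen=True)
class AdmixtureDesign:
    """True per-individual ancestral proportions used by the simulator.

    ``proportions`` is N x K, one column per entry of ``populations``;
    values are non-negative and typically (not necessarily) sum to one.
    """

    populations: tuple[str, ...]
    proportions: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "proportions", np.atleast_2d(np.asarray(self.proportions, dtype=float))
        )
        if self.proportions.shape[1] != len(self.populations):
            raise ValueError("proportions must have one column per population")
        if np.any(self.proportions < 0):
            raise ValueError("ancestral proportions must be non-negative")
        if self.labels is not None and len(self.labels) != self.proportions.shape[0]:
            raise ValueError("labels length does not match number of individuals")

    @property
    def n_individuals(self) -> int:
        return self.proportions.shape[0]

    @classmethod
    def pure(
        cls, population: str, n: int, populations: Iterable[str]
    ) -> "AdmixtureDesign":
        """``n`` unadmixed members of ``population``."""
        pops = tuple(populations)
        p = np.zeros((n, len(pops)))
        p[:, pops.index(population)] = 1.0
        return cls(pops, p, labels=tuple([population] * n))

    @classmethod
    def constant(
        cls,
        proportions: Mapping[str, float],
        n: int,
        label: str = "admixed",
    ) -> "AdmixtureDesign":
        """``n`` individuals sharing the same ancestral proportions."""
        pops = tuple(proportions.keys())
        row = np.array([proportions[p] for p in pops], dtype=float)
        return cls(pops, np.tile(row, (n, 1)), labels=tuple([label] * n))
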