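import numpy as np
import pandas as pd
import pytest

from ancspec import GenotypeMatrix, SnpPanel


def make_panel(mafs_by_pop: dict[str, list[float]]) -> SnpPanel:
    """Hand-build a small panel: one chromosome per population."""
    parts = []
    for chrom, (pop, mafs) in enumerate(sorted(mafs_by_pop.items()), start=1):
        parts.append(
            pd.DataFrame(
                {
                    "CHROM": str(chrom),
                    "POS": np.arange(1, len(mafs) + 1),
                    "ID": [f"{pop}_s{i}" for i in range(len(mafs))],
                    "MINOR": "A",
                    "OTHER": "C",
                    "POP": pop,
                    "MAF": mafs,
                }
            )
        )
    return SnpPanel(pd.concat(parts, ignore_index=True))


def make_genotypes(panel: SnpPanel, rows: list[list[float]],
                   sample_ids: list[str] | None = None) -> GenotypeMatrix:
    values = np.asarray(rows, dtype=float)
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(values.shape[0])]
    return GenotypeMatrix(values=values, sample_ids=sample_ids, snp_ids=panel.snp_ids)


@pytest.fixture
def two_pop_panel() -> SnpPanel:
    return make_panel({"P1": [0.1, 0.2], "P2": [0.05, 0.04, 0.03]})
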