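"""Shared fixtures: small hand-written abundance tables and helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cooccurnet.io_abundance import AbundanceTable


def make_table(
    counts: np.ndarray,
    taxa: list[str],
    lineages: dict | None = None,
    group: str = "YC",
    sample_type: str = "fecal",
    value_kind: str = "counts",
) -> AbundanceTable:
    """Build a one-cell AbundanceTable from a raw matrix."""
    counts = np.asarray(counts, dtype=float)
    samples = [f"s{i + 1}" for i in range(counts.shape[0])]
    data = pd.DataFrame(counts, index=samples, columns=taxa)
    metadata = pd.DataFrame(
        {"group": group, "sample_type": sample_type}, index=samples
    )
    if lineages is None:
        lineages = {t: {"genus": t} for t in taxa}
    return AbundanceTable(
        data=data, lineages=lineages, metadata=metadata, value_kind=value_kind
    )


@pytest.fixture
def tiny_table() -> AbundanceTable:
    """3 samples x 4 taxa, two phyla, counts."""
    lineages = {
        "Lactobacillus": {"kingdom": "Bacteria", "phylum": "Firmicutes", "genus": "Lactobacillus"},
        "Oscillospira": {"kingdom": "Bacteria", "phylum": "Firmicutes", "genus": "Oscillospira"},
        "Bacteroides": {"kingdom": "Bacteria", "phylum": "Bacteroidetes", "genus": "Bacteroides"},
        "Prevotella": {"kingdom": "Bacteria", "phylum": "Bacteroidetes", "genus": "Prevotella"},
    }
    counts = np.array(
        [
            [3.0, 5.0, 10.0, 2.0],
            [1.0, 7.0, 4.0, 8.0],
            [6.0, 2.0, 9.0, 3.0],
        ]
    )
    return make_table(
        counts,
        ["Lactobacillus", "Oscillospira", "Bacteroides", "Prevotella"],
        lineages,
    )


@pytest.fixture
def tiny_tsv(tmp_path, tiny_table):
    """The tiny table written as tsv_wide + metadata TSV."""
    from cooccurnet.io_abundance import write_abundance_table, write_metadata

    abundance = tmp_path / "abundance.tsv"
    metadata = tmp_path / "metadata.tsv"
    write_abundance_table(tiny_table, abundance, format="tsv_wide")
    write_metadata(tiny_table, metadata)
    return abundance, metadata
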