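"""Alpha-diversity indices and Gram-phenotype composition summaries.

Shannon entropy H = -sum p_i ln p_i (natural log by default, base-2
switchable) and the Gini-Simpson index 1 - sum p_i^2 (the classical
complement form 1/sum p_i^2 is available behind a flag) are computed per
sample on the normalised abundance vector.

The Gram summary maps each taxon to a Gram-stain class through a local
phenotype table (TSV: taxon_label, gram in {negative, positive, variable,
unknown}) and reports the abundance-weighted fraction of each class per
sample and per group.  Unmapped taxa resolve to ``unknown`` — a valid
class — so fractions over all classes always sum to 1.  A small packaged
default map covers the dominant mouse-gut phyla and genera.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_abundance import AbundanceTable

__all__ = [
    "GRAM_CLASSES",
    "PhenotypeMap",
    "load_phenotype_map",
    "default_phenotype_map",
    "shannon_index",
    "simpson_index",
    "diversity_table",
    "gram_summary",
]

GRAM_CLASSES = ("negative", "positive", "variable", "unknown")


@dataclass(frozen=True)
class PhenotypeMap:
    """Taxon label -> Gram class lookup; unmapped labels resolve to unknown."""

    mapping: Mapping[str, str]
    source: str = "user"

    def __post_init__(self) -> None:
        bad = {g for g in self.mapping.values() if g not in GRAM_CLASSES}
        if bad:
            raise ValueError(f"unknown gram classes in map: {sorted(bad)}")

    def gram(self, taxon_label: str) -> str:
        return self.mapping.get(taxon_label, "unknown")


def load_phenotype_map(path: str | Path, source: str | None = None) -> PhenotypeMap:
    """Read a phenotype-map TSV with columns taxon_label, gram."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"taxon_label", "gram"}.issubset(df.columns):
        raise ValueError("phenotype map TSV needs columns taxon_label, gram")
    return PhenotypeMap(
        mapping=dict(zip(df["taxon_label"], df["gram"])),
        source=source or str(path),
    )


def default_phenotype_map() -> PhenotypeMap:
    """The packaged default Gram map (dominant mouse-gut phyla and genera)."""
    ref = resources.files("cooccurnet").joinpath("data/default_gram_map.tsv")
    with resources.as_file(ref) as path:
        return load_phenotype_map(path, source="cooccurnet:default_gram_map.tsv")


def _normalise(abundances: Sequence[float]) -> np.ndarray:
    arr = np.asarray(abundances, dtype=float)
    if arr.ndim != 1:
        raise ValueError("abundance vector must be one-dimensional")
    if np.any(arr < 0):
        raise ValueError("abundances must be non-negative")
    total = arr.sum()
    if total <= 0:
        raise ValueError("abundance vector must contain a positive value")
    return arr / total


def shannon_index(abundances: Sequence[float], base: str = "e") -> float:
    """Shannon diversity H = -sum p_i log p_i over the positive fractions."""
    p = _normalise(abundances)
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    if base == "e":
        return h
    if base == "2":
        return h / np.log(2.0)
    raise ValueError("base must be 'e' or '2'")


def simpson_index(abundances: Sequence[float], form: str = "gini") -> float:
    """Simpson diversity: Gini-Simpson 1 - sum p_i^2 (default) or the
    inverse form 1 / sum p_i^2."""
    p = _normalise(abundances)
    ss = float((p**2).sum())
    if form == "gini":
        return 1.0 - ss
    if form == "inverse":
        return 1.0 / ss
    raise ValueError("form must be 'gini' or 'inverse'")


def diversity_table(table: AbundanceTable) -> pd.DataFrame:
    """Per-sample Shannon and Gini-Simpson indices with group/sample_type."""
    rows = []
    for sample in table.sample_ids:
        vec = table.data.loc[sample].to_numpy(dtype=float)
        rows.append(
            {
                "sample_id": sample,
                "group": table.metadata.loc[sample, "group"],
                "sample_type": table.metadata.loc[sample, "sample_type"],
                "shannon": shannon_index(vec),
                "simpson": simpson_index(vec),
            }
        )
    return pd.DataFrame(rows)


def gram_summary(table: AbundanceTable, phenotype_map: PhenotypeMap | None = None) -> pd.DataFrame:
    """Abundance-weighted Gram-class fractions per sample, with group labels.

    Requires a relative-abundance table so the per-class fractions are the
    community fractions; the four class columns sum to 1 per sample.
    """
    if phenotype_map is None:
        phenotype_map = default_phenotype_map()
    if table.value_kind != "relative":
        raise ValueError("gram_summary requires a relative-abundance table")
    classes = {taxon: phenotype_map.gram(taxon) for taxon in table.taxon_ids}
    rows = []
    for sample in table.sample_ids:
        vec = table.data.loc[sample]
        fractions = {cls: 0.0 for cls in GRAM_CLASSES}
        for taxon, value in vec.items():
            fractions[classes[taxon]] += float(value)
        rows.append(
            {
                "sample_id": sample,
                "group": table.metadata.loc[sample, "group"],
                "sample_type": table.metadata.loc[sample, "sample_type"],
                **fractions,
                "map_source": phenotype_map.source,
            }
        )
    return pd.DataFrame(rows)
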