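"""Reading, validation, rank collapse, normalisation and filtering of
taxon abundance tables.

The central container is :class:`AbundanceTable`: a samples x taxa matrix of
non-negative values (raw counts or relative abundances) together with one
taxonomic lineage per taxon and one metadata record (study group, sample
type) per sample.  Every downstream stage — pairwise association, network
construction, diversity — consumes this object.

Two on-disk formats are supported:

* ``tsv_wide`` — UTF-8, tab-separated; first column ``taxon_id``, second
  column ``lineage`` (semicolon-separated rank labels, optionally with
  greengenes-style ``k__``/``p__``/... prefixes), remaining columns one per
  sample.
* ``biom_json`` — BIOM v1.0 (JSON), dense or sparse ``matrix_type``; rows
  are taxa carrying a ``taxonomy`` metadata list, columns are samples.

Sample metadata travels in a separate TSV with columns ``sample_id``,
``group`` (YC|YP|AC|AP) and ``sample_type`` (fecal|mucosal|cecal).
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "SAMPLE_TYPES",
    "RANKS",
    "UNCLASSIFIED",
    "AbundanceTableError",
    "MalformedHeaderError",
    "NegativeValueError",
    "DuplicateIdError",
    "MetadataJoinError",
    "ZeroTotalSampleError",
    "InvalidRankError",
    "RankNotFoundError",
    "EmptyFilterError",
    "AbundanceTable",
    "parse_lineage",
    "read_metadata",
    "read_abundance_table",
    "write_abundance_table",
    "collapse_to_rank",
    "to_relative",
    "filter_taxa",
    "subset_samples",
]

GROUPS = ("YC", "YP", "AC", "AP")
SAMPLE_TYPES = ("fecal", "mucosal", "cecal")

#: canonical rank order used for positional lineage parsing
RANK_ORDER = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: the two analysis ranks accepted by :func:`collapse_to_rank`
RANKS = ("phylum", "genus")

#: label of the pooled taxon holding abundance unclassified at a rank
UNCLASSIFIED = "unclassified"

_GG_PREFIXES = {
    "k__": "kingdom",
    "p__": "phylum",
    "c__": "class",
    "o__": "order",
    "f__": "family",
    "g__": "genus",
    "s__": "species",
}

_REL_TOL = 1e-9


class AbundanceTableError(ValueError):
    """Base class for abundance-table validation and I/O failures."""


class MalformedHeaderError(AbundanceTableError):
    """File header does not match the declared dialect."""


class NegativeValueError(AbundanceTableError):
    """A negative abundance value was encountered."""


class DuplicateIdError(AbundanceTableError):
    """Duplicate sample or taxon identifier."""


class MetadataJoinError(AbundanceTableError):
    """Sample ids in the matrix and the metadata table do not match 1:1."""


class ZeroTotalSampleError(AbundanceTableError):
    """A sample with zero total abundance where a positive total is required."""


class InvalidRankError(AbundanceTableError):
    """A rank other than phylum or genus was requested."""


class RankNotFoundError(AbundanceTableError):
    """The requested rank is absent from every lineage."""


class EmptyFilterError(AbundanceTableError):
    """A taxon filter removed every taxon."""


def parse_lineage(lineage: str) -> dict[str, str]:
    """Parse a semicolon-separated lineage string into ``{rank: label}``.

    Accepts greengenes-style prefixed fields (``p__Firmicutes``) in any
    order, or plain labels assigned positionally kingdom -> species.  Empty
    fields (``p__`` with nothing after the prefix) are treated as
    unclassified at that rank and omitted from the result.
    """
    out: dict[str, str] = {}
    fields = [f.strip() for f in lineage.split(";")]
    positional = 0
    for fld in fields:
        if not fld:
            positional += 1
            continue
        prefix = fld[:3]
        if prefix in _GG_PREFIXES:
            label = fld[3:].strip()
            if label:
                out[_GG_PREFIXES[prefix]] = label
            positional += 1
        else:
            if positional < len(RANK_ORDER):
                out[RANK_ORDER[positional]] = fld
            positional += 1
    return out


@dataclass(frozen=True)
class AbundanceTable:
    """Samples x taxa abundance matrix with lineages and sample metadata.

    Parameters
    ----------
    data
        DataFrame indexed by sample id, one column per taxon id, all values
        >= 0.
    lineages
        Mapping taxon id -> ``{rank: label}`` (missing ranks = unclassified).
    metadata
        DataFrame indexed by sample id with columns ``group`` and
        ``sample_type``; must cover exactly the samples of ``data``.
    value_kind
        ``"counts"`` or ``"relative"``; relative rows must sum to 1 within
        1e-9.
    """

    data: pd.DataFrame
    lineages: Mapping[str, Mapping[str, str]]
    metadata: pd.DataFrame
    value_kind: str = "counts"

    def __post_init__(self) -> None:
        if self.value_kind not in ("counts", "relative"):
            raise AbundanceTableError(
                f"value_kind must be 'counts' or 'relative', got {self.value_kind!r}"
            )
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()].tolist()
            raise DuplicateIdError(f"duplicate sample ids: {dup}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()].tolist()
            raise DuplicateIdError(f"duplicate taxon ids: {dup}")
        values = self.data.to_numpy(dtype=float)
        if values.size and np.nanmin(values) < 0:
            raise NegativeValueError("abundance values must be non-negative")
        if np.isnan(values).any():
            raise AbundanceTableError("abundance values must not be NaN")
        missing = set(self.data.index) - set(self.metadata.index)
        extra = set(self.metadata.index) - set(self.data.index)
        if missing or extra:
            raise MetadataJoinError(
                f"metadata mismatch; samples without metadata: {sorted(missing)}, "
                f"metadata without samples: {sorted(extra)}"
            )
        for col in ("group", "sample_type"):
            if col not in self.metadata.columns:
                raise MetadataJoinError(f"metadata lacks required column {col!r}")
        bad_groups = set(self.metadata["group"]) - set(GROUPS)
        if bad_groups:
            raise MetadataJoinError(f"unknown group labels: {sorted(bad_groups)}")
        bad_types = set(self.metadata["sample_type"]) - set(SAMPLE_TYPES)
        if bad_types:
            raise MetadataJoinError(f"unknown sample types: {sorted(bad_types)}")
        for taxon in self.data.columns:
            if taxon not in self.lineages:
                raise AbundanceTableError(f"taxon {taxon!r} has no lineage record")
        if self.value_kind == "relative" and len(self.data):
            sums = values.sum(axis=1)
            off = np.abs(sums - 1.0) > _REL_TOL
            if off.any():
                bad = self.data.index[off].tolist()
                raise AbundanceTableError(
                    f"relative-abundance rows must sum to 1 within {_REL_TOL}: {bad}"
                )

    # -- convenience accessors -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def rank_label(self, taxon_id: str, rank: str) -> str | None:
        """Lineage label of *taxon_id* at *rank*, or None if unclassified."""
        return dict(self.lineages.get(taxon_id, {})).get(rank)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample-metadata TSV (sample_id, group, sample_type)."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group", "sample_type"}
    if not required.issubset(meta.columns):
        raise MalformedHeaderError(
            f"metadata TSV must carry columns {sorted(required)}, got {list(meta.columns)}"
        )
    if meta["sample_id"].duplicated().any():
        raise DuplicateIdError("duplicate sample_id in metadata")
    return meta.set_index("sample_id")


def _read_tsv_wide(path: Path) -> tuple[pd.DataFrame, dict[str, dict[str, str]]]:
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if list(df.columns[:2]) != ["taxon_id", "lineage"]:
        raise MalformedHeaderError(
            "tsv_wide requires first columns 'taxon_id', 'lineage'; "
            f"got {list(df.columns[:2])}"
        )
    if df.shape[1] < 3:
        raise MalformedHeaderError("tsv_wide has no sample columns")
    taxa = df["taxon_id"].astype(str)
    if taxa.duplicated().any():
        raise DuplicateIdError("duplicate taxon_id in abundance TSV")
    lineages = {t: parse_lineage(l) for t, l in zip(taxa, df["lineage"].astype(str))}
    matrix = df.drop(columns=["taxon_id", "lineage"])
    try:
        values = matrix.astype(float)
    except ValueError as exc:
        raise MalformedHeaderError(f"non-numeric abundance cell: {exc}") from exc
    data = values.T
    data.columns = list(taxa)
    data.index.name = "sample_id"
    return data, lineages


def _read_biom_json(path: Path) -> tuple[pd.DataFrame, dict[str, dict[str, str]]]:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    for key in ("rows", "columns", "shape", "matrix_type", "data"):
        if key not in doc:
            raise MalformedHeaderError(f"BIOM document lacks key {key!r}")
    n_taxa, n_samples = doc["shape"]
    taxa = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    if len(set(taxa)) != len(taxa):
        raise DuplicateIdError("duplicate row (taxon) ids in BIOM file")
    if len(set(samples)) != len(samples):
        raise DuplicateIdError("duplicate column (sample) ids in BIOM file")
    dense = np.zeros((n_taxa, n_samples), dtype=float)
    if doc["matrix_type"] == "dense":
        arr = np.asarray(doc["data"], dtype=float)
        if arr.shape != (n_taxa, n_samples):
            raise MalformedHeaderError("dense BIOM data does not match shape")
        dense = arr
    elif doc["matrix_type"] == "sparse":
        for i, j, v in doc["data"]:
            dense[int(i), int(j)] = float(v)
    else:
        raise MalformedHeaderError(f"unknown matrix_type {doc['matrix_type']!r}")
    lineages: dict[str, dict[str, str]] = {}
    for row in doc["rows"]:
        meta = row.get("metadata") or {}
        taxonomy = meta.get("taxonomy") or []
        lineages[row["id"]] = parse_lineage(";".join(taxonomy))
    data = pd.DataFrame(dense.T, index=samples, columns=taxa)
    data.index.name = "sample_id"
    return data, lineages


def read_abundance_table(
    path: str | Path,
    metadata_path: str | Path | None = None,
    *,
    format: str = "tsv_wide",
    metadata: pd.DataFrame | None = None,
) -> AbundanceTable:
    """Read and validate an abundance table (``value_kind="counts"``).

    One of *metadata_path* or a pre-read *metadata* frame must be supplied;
    the join on sample id must be exact (a :class:`MetadataJoinError`
    otherwise).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv_wide":
        data, lineages = _read_tsv_wide(path)
    elif format == "biom_json":
        data, lineages = _read_biom_json(path)
    else:
        raise AbundanceTableError(f"unknown format {format!r}")
    if metadata is None:
        if metadata_path is None:
            raise MetadataJoinError("sample metadata is required (path or frame)")
        metadata = read_metadata(metadata_path)
    if set(data.index) <= set(metadata.index):
        metadata = metadata.loc[data.index]  # align; surplus rows -> join error
    return AbundanceTable(
        data=data,
        lineages=lineages,
        metadata=metadata,
        value_kind="counts",
    )


def _lineage_string(lineage: Mapping[str, str]) -> str:
    return ";".join(lineage.get(rank, "") for rank in RANK_ORDER).rstrip(";")


def write_abundance_table(
    table: AbundanceTable, path: str | Path, *, format: str = "tsv_wide"
) -> None:
    """Write the matrix + lineages to *path* in ``tsv_wide`` or ``biom_json``.

    Sample metadata is NOT embedded; write it separately with
    :func:`write_metadata`.
    """
    path = Path(path)
    if format == "tsv_wide":
        out = pd.DataFrame(
            {
                "taxon_id": table.taxon_ids,
                "lineage": [
                    _lineage_string(table.lineages[t]) for t in table.taxon_ids
                ],
            }
        )
        mat = table.data.T.reset_index(drop=True)
        out = pd.concat([out, mat], axis=1)
        out.to_csv(path, sep="\t", index=False)
    elif format == "biom_json":
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "cooccurnet",
            "date": datetime.datetime.now().isoformat(),
            "matrix_type": "dense",
            "matrix_element_type": "float",
            "shape": [table.n_taxa, table.n_samples],
            "rows": [
                {
                    "id": t,
                    "metadata": {
                        "taxonomy": [
                            table.lineages[t].get(rank, "") for rank in RANK_ORDER
                        ]
                    },
                }
                for t in table.taxon_ids
            ],
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "data": table.data.T.to_numpy(dtype=float).tolist(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh)
    else:
        raise AbundanceTableError(f"unknown format {format!r}")


def write_metadata(table: AbundanceTable, path: str | Path) -> None:
    """Write the sample-metadata TSV companion of *table*."""
    meta = table.metadata.reset_index()
    cols = ["sample_id" if c == "index" else c for c in meta.columns]
    meta.columns = cols
    meta.to_csv(path, sep="\t", index=False)


def collapse_to_rank(table: AbundanceTable, rank: str) -> AbundanceTable:
    """Sum taxa sharing the same label at *rank* (phylum or genus).

    Taxa unclassified at the rank are pooled into an explicit
    ``unclassified`` taxon so per-sample totals are conserved exactly.
    Collapsed taxon order follows first appearance in the input.
    """
    if rank not in RANKS:
        raise InvalidRankError(f"rank must be one of {RANKS}, got {rank!r}")
    labels = [table.rank_label(t, rank) for t in table.taxon_ids]
    if all(lab is None for lab in labels):
        raise RankNotFoundError(f"rank {rank!r} absent from every lineage")
    order: list[str] = []
    members: dict[str, list[str]] = {}
    for taxon, lab in zip(table.taxon_ids, labels):
        key = lab if lab is not None else UNCLASSIFIED
        if key not in members:
            members[key] = []
            order.append(key)
        members[key].append(taxon)
    collapsed = pd.DataFrame(
        {key: table.data[members[key]].sum(axis=1) for key in order},
        index=table.data.index,
    )
    rank_idx = RANK_ORDER.index(rank)
    new_lineages: dict[str, dict[str, str]] = {}
    for key in order:
        if key == UNCLASSIFIED:
            new_lineages[key] = {}
            continue
        # keep ranks at or above the collapse rank from the first member
        first = dict(table.lineages[members[key][0]])
        kept = {
            r: lab
            for r, lab in first.items()
            if r in RANK_ORDER and RANK_ORDER.index(r) <= rank_idx
        }
        kept[rank] = key
        new_lineages[key] = kept
    return AbundanceTable(
        data=collapsed,
        lineages=new_lineages,
        metadata=table.metadata,
        value_kind=table.value_kind,
    )


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Convert counts to per-sample relative abundances (rows sum to 1)."""
    if table.value_kind != "counts":
        raise AbundanceTableError("to_relative requires value_kind='counts'")
    totals = table.data.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise ZeroTotalSampleError(
            f"samples with zero total abundance: {list(zero.index)}; drop them first"
        )
    rel = table.data.div(totals, axis=0)
    # renormalise to absorb float division error so the row-sum invariant holds
    rel = rel.div(rel.sum(axis=1), axis=0)
    return replace(table, data=rel, value_kind="relative")


def filter_taxa(
    table: AbundanceTable,
    min_prevalence: float = 0.25,
    top_k: int | None = None,
) -> AbundanceTable:
    """Drop rare taxa: keep taxa present (value > 0) in at least
    ``min_prevalence`` of samples, then (optionally) only the ``top_k`` taxa
    by mean abundance.  Input taxon order is preserved.
    """
    if not 0.0 <= min_prevalence <= 1.0:
        raise AbundanceTableError("min_prevalence must lie in [0, 1]")
    if top_k is not None and top_k < 1:
        raise AbundanceTableError("top_k must be a positive integer")
    presence = (table.data > 0).mean(axis=0)
    keep = [t for t in table.taxon_ids if presence[t] >= min_prevalence]
    if top_k is not None and len(keep) > top_k:
        means = table.data[keep].mean(axis=0)
        ranked = means.sort_values(ascending=False, kind="stable")
        chosen = set(ranked.index[:top_k])
        keep = [t for t in keep if t in chosen]
    if not keep:
        raise EmptyFilterError(
            f"filter (min_prevalence={min_prevalence}, top_k={top_k}) removed all taxa"
        )
    return replace(
        table,
        data=table.data[keep],
        lineages={t: table.lineages[t] for t in keep},
    )


def subset_samples(
    table: AbundanceTable,
    group: str | None = None,
    sample_type: str | None = None,
) -> AbundanceTable:
    """Restrict the table to samples of one group and/or sample type."""
    mask = pd.Series(True, index=table.metadata.index)
    if group is not None:
        mask &= table.metadata["group"] == group
    if sample_type is not None:
        mask &= table.metadata["sample_type"] == sample_type
    ids = table.metadata.index[mask]
    return replace(
        table, data=table.data.loc[ids], metadata=table.metadata.loc[ids]
    )
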