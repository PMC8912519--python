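"""One-command orchestration of the whole analysis.

For every analysis cell — group x sample type x taxonomic rank — the
pipeline subsets the samples, collapses taxa to the rank, filters rare
taxa, normalises to relative abundance, computes all pairwise rank
associations with permutation p-values, applies Benjamini-Hochberg FDR
within the cell, thresholds into a signed co-occurrence network, and writes
the association table, the network (GraphML + edge list), the network
summary, focal-taxon partner tables, per-sample alpha diversity and the
Gram-phenotype composition.  A top-level report aggregates the per-cell
counts, and a manifest lists every artifact so each reported number is
traceable to a file.

FDR families, filters and networks are strictly per cell; cross-cell
comparisons operate only on summaries.  All outputs are deterministic
functions of (inputs, config, seed): rerunning with the archived config
reproduces them byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io_abundance as io
from .correlation import pairwise_associations, write_associations
from .diversity import default_phenotype_map, diversity_table, gram_summary, load_phenotype_map
from .network import (
    CoOccurrenceNetwork,
    NetworkConfig,
    Provenance,
    build_network,
    export_network,
    focal_taxon_table,
    summarize_network,
)
from .synthetic import default_design, generate_study, load_design, save_design, write_study

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("cooccurnet")


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run depends on; archived into the output
    directory so the run is reproducible from its own artifacts."""

    # inputs: either an abundance + metadata TSV pair, or a synthetic design
    abundance_path: str | None = None
    metadata_path: str | None = None
    abundance_format: str = "tsv_wide"
    design_path: str | None = None
    synthetic: bool = False

    ranks: tuple[str, ...] = ("phylum", "genus")
    method: str = "gamma_paper"
    tau_threshold: float = 0.70
    alpha: float = 0.05
    alpha_applies_to: str = "q_value"
    min_prevalence: float = 0.25
    top_k_genus: int | None = 10
    top_k_phylum: int | None = None
    exclude_unclassified: bool = True
    focal_taxa: tuple[str, ...] = ("Lactobacillus",)
    phenotype_map_path: str | None = None
    max_exact_n: int = 8
    n_permutations: int = 999
    outdir: str = "out"
    seed: int = 0
    log_level: str = "INFO"

    def network_config(self) -> NetworkConfig:
        return NetworkConfig(
            tau_threshold=self.tau_threshold,
            alpha=self.alpha,
            alpha_applies_to=self.alpha_applies_to,
        )

    def top_k(self, rank: str) -> int | None:
        return self.top_k_genus if rank == "genus" else self.top_k_phylum

    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        doc["ranks"] = list(self.ranks)
        doc["focal_taxa"] = list(self.focal_taxa)
        return doc


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _cell_seed(seed: int, group: str, sample_type: str, rank: str) -> int:
    key = (
        io.GROUPS.index(group),
        io.SAMPLE_TYPES.index(sample_type),
        io.RANKS.index(rank),
    )
    ss = np.random.SeedSequence(entropy=seed, spawn_key=key)
    return int(ss.generate_state(1)[0] % (2**31))


def _load_input_table(config: RunConfig, outdir: Path) -> io.AbundanceTable:
    if config.synthetic or config.design_path:
        design = (
            load_design(config.design_path)
            if config.design_path
            else default_design(seed=config.seed)
        )
        tables = generate_study(design)
        data_dir = outdir / "synthetic_input"
        abundance_path, metadata_path = write_study(tables, data_dir)
        save_design(design, data_dir / "design.yaml")
        logger.info("generated synthetic study: %s", abundance_path)
        return io.read_abundance_table(
            abundance_path, metadata_path, format="tsv_wide"
        )
    if not config.abundance_path or not config.metadata_path:
        raise ValueError(
            "config must set abundance_path + metadata_path, or synthetic/design_path"
        )
    return io.read_abundance_table(
        config.abundance_path, config.metadata_path, format=config.abundance_format
    )


def _run_cell(
    table: io.AbundanceTable,
    group: str,
    sample_type: str,
    rank: str,
    config: RunConfig,
    cell_dir: Path,
) -> dict:
    """Run one analysis cell end to end; returns its report entry."""
    cell = io.subset_samples(table, group=group, sample_type=sample_type)
    if cell.n_samples == 0:
        raise ValueError("no samples in cell")
    collapsed = io.collapse_to_rank(cell, rank)
    n_taxa_before = collapsed.n_taxa
    filtered = io.filter_taxa(
        collapsed, min_prevalence=config.min_prevalence, top_k=config.top_k(rank)
    )
    if config.exclude_unclassified and io.UNCLASSIFIED in filtered.taxon_ids:
        keep = [t for t in filtered.taxon_ids if t != io.UNCLASSIFIED]
        filtered = dataclasses.replace(
            filtered,
            data=filtered.data[keep],
            lineages={t: filtered.lineages[t] for t in keep},
        )
    totals = filtered.data.sum(axis=1)
    nonzero = totals[totals > 0].index
    if len(nonzero) < len(filtered.data):
        dropped = sorted(set(filtered.data.index) - set(nonzero))
        logger.warning("cell %s/%s/%s: dropping zero-total samples %s",
                       sample_type, group, rank, dropped)
        filtered = dataclasses.replace(
            filtered,
            data=filtered.data.loc[nonzero],
            metadata=filtered.metadata.loc[nonzero],
        )
    relative = io.to_relative(filtered)
    logger.info(
        "cell %s/%s/%s: %d samples, %d taxa (of %d at rank)",
        sample_type, group, rank, relative.n_samples, relative.n_taxa, n_taxa_before,
    )
    result = pairwise_associations(
        relative,
        method=config.method,
        max_exact_n=config.max_exact_n,
        n_permutations=config.n_permutations,
        seed=_cell_seed(config.seed, group, sample_type, rank),
    )
    for ti, tj, reason in result.degenerate:
        logger.info("cell %s/%s/%s: degenerate pair %s-%s (%s)",
                    sample_type, group, rank, ti, tj, reason)
    cell_dir.mkdir(parents=True, exist_ok=True)
    write_associations(result, cell_dir / "associations.tsv")
    network = build_network(
        result,
        config.network_config(),
        Provenance(group=group, sample_type=sample_type, rank=rank),
    )
    export_network(network, cell_dir / "network.graphml", format="graphml")
    export_network(network, cell_dir / "edges.tsv", format="edgelist_tsv")
    export_network(network, cell_dir / "summary.json", format="summary_json")
    summary = summarize_network(network)
    focal_entries = {}
    for focal in config.focal_taxa:
        ft = focal_taxon_table(network, focal)
        rows = [
            {"focal": focal, "partner": p, "sign": "co_occurrence"}
            for p in ft.co_occurrence_partners
        ] + [
            {"focal": focal, "partner": p, "sign": "co_exclusion"}
            for p in ft.co_exclusion_partners
        ]
        pd.DataFrame(rows, columns=["focal", "partner", "sign"]).to_csv(
            cell_dir / f"focal_{focal}.tsv", sep="\t", index=False
        )
        focal_entries[focal] = {
            "n_co_occurrences": ft.n_co_occurrences,
            "n_co_exclusions": ft.n_co_exclusions,
        }
    div = diversity_table(relative)
    div.to_csv(cell_dir / "diversity.tsv", sep="\t", index=False, float_format="%.10g")
    pmap = (
        load_phenotype_map(config.phenotype_map_path)
        if config.phenotype_map_path
        else default_phenotype_map()
    )
    gram = gram_summary(relative, pmap)
    gram.to_csv(cell_dir / "gram.tsv", sep="\t", index=False, float_format="%.10g")
    return {
        "group": group,
        "sample_type": sample_type,
        "rank": rank,
        "n_samples": relative.n_samples,
        "n_taxa_at_rank": n_taxa_before,
        "n_taxa_analyzed": relative.n_taxa,
        "n_degenerate_pairs": len(result.degenerate),
        "n_nodes": summary.n_nodes,
        "n_associations": summary.n_associations,
        "n_co_occurrences": summary.n_co_occurrences,
        "n_co_exclusions": summary.n_co_exclusions,
        "focal": focal_entries,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the run report (also written to
    ``<outdir>/report.json``, with a manifest at ``<outdir>/manifest.json``).

    A failure inside one cell is logged and recorded; other cells proceed.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    table = _load_input_table(config, outdir)
    for name, p in (
        ("abundance", config.abundance_path),
        ("metadata", config.metadata_path),
    ):
        if p:
            logger.info("input %s sha256=%s", name, _sha256(Path(p)))
    cells = sorted(
        {
            (row.sample_type, row.group)
            for row in table.metadata.itertuples(index=False)
        },
        key=lambda c: (io.SAMPLE_TYPES.index(c[0]), io.GROUPS.index(c[1])),
    )
    report_cells = []
    failures = []
    for sample_type, group in cells:
        for rank in config.ranks:
            cell_dir = outdir / sample_type / group / rank
            try:
                entry = _run_cell(table, group, sample_type, rank, config, cell_dir)
                report_cells.append(entry)
            except Exception as exc:  # noqa: BLE001 — cell isolation is the contract
                logger.error(
                    "cell %s/%s/%s failed: %s", sample_type, group, rank, exc
                )
                failures.append(
                    {
                        "group": group,
                        "sample_type": sample_type,
                        "rank": rank,
                        "error": f"{type(exc).__name__}: {exc}",
                    }
                )
    report = {
        "config": config.to_dict(),
        "cells": report_cells,
        "failures": failures,
    }
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    artifacts = sorted(
        str(p.relative_to(outdir))
        for p in outdir.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump({"artifacts": artifacts}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
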