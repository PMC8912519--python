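"""Signed co-occurrence network construction and the summary surfaces the
analysis reports: per-network counts, per-taxon partner lists, focal-taxon
tables and paired network comparisons.

An edge is retained when the association is simultaneously strong
(|tau| >= tau_threshold, default 0.70) and significant (q-value — or
p-value, configurable — <= alpha, default 0.05).  Positive edges are
co-occurrences, negative edges co-exclusions.  Nodes are exactly the taxa
incident to at least one retained edge: a taxon with no surviving
association is not part of the network, which is why a taxon absent from a
group (degenerate in every pair) contributes no node there.

Node "strength" follows the convention of sizing nodes on a 1..9 integer
scale: degree linearly rescaled to that range (all nodes map to 9 when
every degree is equal).  The sum of |tau| over incident edges is attached
as an auxiliary attribute.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .correlation import PairAssociation, PairwiseResult

__all__ = [
    "NetworkConfig",
    "Provenance",
    "CoOccurrenceNetwork",
    "NetworkSummary",
    "FocalTaxonTable",
    "build_network",
    "summarize_network",
    "focal_taxon_table",
    "compare_networks",
    "export_network",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Edge-retention thresholds, recorded verbatim in every output."""

    tau_threshold: float = 0.70
    alpha: float = 0.05
    alpha_applies_to: str = "q_value"

    def __post_init__(self) -> None:
        if not 0.0 < self.tau_threshold <= 1.0:
            raise ValueError("tau_threshold must lie in (0, 1]")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if self.alpha_applies_to not in ("q_value", "p_value"):
            raise ValueError("alpha_applies_to must be 'q_value' or 'p_value'")

    def to_dict(self) -> dict:
        return {
            "tau_threshold": self.tau_threshold,
            "alpha": self.alpha,
            "alpha_applies_to": self.alpha_applies_to,
        }


@dataclass(frozen=True)
class Provenance:
    """Which analysis cell a network belongs to."""

    group: str
    sample_type: str
    rank: str

    def to_dict(self) -> dict:
        return {"group": self.group, "sample_type": self.sample_type, "rank": self.rank}


@dataclass
class CoOccurrenceNetwork:
    """Signed, weighted co-occurrence graph of one analysis cell.

    ``graph`` is an undirected networkx Graph whose nodes carry ``degree``,
    ``strength_scaled`` (1..9) and ``strength_tau`` (sum of incident |tau|)
    attributes and whose edges carry ``tau`` and ``sign``.
    """

    graph: nx.Graph
    config: NetworkConfig
    provenance: Provenance

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float, str]]:
        out = []
        for u, v, attrs in self.graph.edges(data=True):
            a, b = sorted((u, v))
            out.append((a, b, attrs["tau"], attrs["sign"]))
        return sorted(out)


@dataclass(frozen=True)
class NetworkSummary:
    """Headline counts of one network plus per-taxon signed partner lists."""

    n_nodes: int
    n_associations: int
    n_co_occurrences: int
    n_co_exclusions: int
    partners: dict[str, dict[str, list[str]]]
    provenance: Provenance | None = None
    config: NetworkConfig | None = None

    def to_dict(self) -> dict:
        out = {
            "n_nodes": self.n_nodes,
            "n_associations": self.n_associations,
            "n_co_occurrences": self.n_co_occurrences,
            "n_co_exclusions": self.n_co_exclusions,
            "partners": self.partners,
        }
        if self.provenance is not None:
            out["provenance"] = self.provenance.to_dict()
        if self.config is not None:
            out["config"] = self.config.to_dict()
        return out


def _scale_strength(degrees: dict[str, int]) -> dict[str, int]:
    """Linearly rescale node degrees to integers 1..9.

    A network whose degrees are all equal maps every node to 9 (all nodes
    are maximally connected relative to each other).
    """
    if not degrees:
        return {}
    dmin, dmax = min(degrees.values()), max(degrees.values())
    if dmax == dmin:
        return {node: 9 for node in degrees}
    return {
        node: 1 + round(8 * (deg - dmin) / (dmax - dmin))
        for node, deg in degrees.items()
    }


def build_network(
    associations: Sequence[PairAssociation] | PairwiseResult,
    config: NetworkConfig = NetworkConfig(),
    provenance: Provenance = Provenance("NA", "NA", "NA"),
) -> CoOccurrenceNetwork:
    """Threshold one family of associations into a signed network.

    A pair becomes an edge iff |tau| >= ``config.tau_threshold`` AND its
    q-value (or p-value, per ``config.alpha_applies_to``) <= ``config.alpha``.
    An empty network is a valid result.
    """
    if isinstance(associations, PairwiseResult):
        associations = associations.associations
    graph = nx.Graph()
    for assoc in associations:
        if assoc.taxon_i == assoc.taxon_j:
            raise ValueError(f"self-association for taxon {assoc.taxon_i!r}")
        crit = assoc.q_value if config.alpha_applies_to == "q_value" else assoc.p_value
        if abs(assoc.tau) >= config.tau_threshold and crit <= config.alpha:
            if graph.has_edge(assoc.taxon_i, assoc.taxon_j):
                raise ValueError(
                    f"duplicate pair {assoc.taxon_i!r}-{assoc.taxon_j!r}"
                )
            graph.add_edge(
                assoc.taxon_i,
                assoc.taxon_j,
                tau=assoc.tau,
                sign=assoc.sign,
                p_value=assoc.p_value,
                q_value=assoc.q_value,
            )
    degrees = {node: int(deg) for node, deg in graph.degree()}
    strengths = _scale_strength(degrees)
    for node in graph.nodes:
        graph.nodes[node]["degree"] = degrees[node]
        graph.nodes[node]["strength_scaled"] = strengths[node]
        graph.nodes[node]["strength_tau"] = float(
            sum(abs(attrs["tau"]) for _, _, attrs in graph.edges(node, data=True))
        )
    return CoOccurrenceNetwork(graph=graph, config=config, provenance=provenance)


def summarize_network(network: CoOccurrenceNetwork) -> NetworkSummary:
    """Count nodes/associations by sign and list each taxon's signed partners.

    Partner lists are ordered lexicographically by taxon id so summaries are
    byte-reproducible.
    """
    graph = network.graph
    n_pos = sum(1 for _, _, a in graph.edges(data=True) if a["sign"] == "co_occurrence")
    n_neg = sum(1 for _, _, a in graph.edges(data=True) if a["sign"] == "co_exclusion")
    partners: dict[str, dict[str, list[str]]] = {}
    for node in sorted(graph.nodes):
        pos = sorted(
            nbr for nbr in graph.neighbors(node)
            if graph.edges[node, nbr]["sign"] == "co_occurrence"
        )
        neg = sorted(
            nbr for nbr in graph.neighbors(node)
            if graph.edges[node, nbr]["sign"] == "co_exclusion"
        )
        partners[node] = {"co_occurrence": pos, "co_exclusion": neg}
    return NetworkSummary(
        n_nodes=graph.number_of_nodes(),
        n_associations=graph.number_of_edges(),
        n_co_occurrences=n_pos,
        n_co_exclusions=n_neg,
        partners=partners,
        provenance=network.provenance,
        config=network.config,
    )


@dataclass(frozen=True)
class FocalTaxonTable:
    """Signed partner listing of one focal taxon (one network)."""

    focal: str
    co_occurrence_partners: list[str]
    co_exclusion_partners: list[str]

    @property
    def n_co_occurrences(self) -> int:
        return len(self.co_occurrence_partners)

    @property
    def n_co_exclusions(self) -> int:
        return len(self.co_exclusion_partners)

    def to_dict(self) -> dict:
        return {
            "focal": self.focal,
            "n_co_occurrences": self.n_co_occurrences,
            "co_occurrence_partners": self.co_occurrence_partners,
            "n_co_exclusions": self.n_co_exclusions,
            "co_exclusion_partners": self.co_exclusion_partners,
        }


def focal_taxon_table(network: CoOccurrenceNetwork, focal: str) -> FocalTaxonTable:
    """Partners of one focal taxon, split by sign and ordered lexicographically.

    A focal taxon absent from the network (e.g. dropped as degenerate in a
    group where it never occurs) yields two empty lists.
    """
    graph = network.graph
    if focal not in graph:
        return FocalTaxonTable(focal, [], [])
    pos = sorted(
        nbr for nbr in graph.neighbors(focal)
        if graph.edges[focal, nbr]["sign"] == "co_occurrence"
    )
    neg = sorted(
        nbr for nbr in graph.neighbors(focal)
        if graph.edges[focal, nbr]["sign"] == "co_exclusion"
    )
    return FocalTaxonTable(focal, pos, neg)


def _edge_pairs(summary: NetworkSummary) -> set[tuple[str, str]]:
    pairs = set()
    for node, signed in summary.partners.items():
        for nbr in signed["co_occurrence"] + signed["co_exclusion"]:
            pairs.add(tuple(sorted((node, nbr))))
    return pairs


def compare_networks(a: NetworkSummary, b: NetworkSummary) -> dict:
    """Paired difference report (a minus b) for two same-cell-kind networks.

    Both summaries must describe the same rank and sample type; group may
    differ (young vs aging, control vs probiotic contrasts).
    """
    if a.provenance is not None and b.provenance is not None:
        if (a.provenance.rank, a.provenance.sample_type) != (
            b.provenance.rank,
            b.provenance.sample_type,
        ):
            raise ValueError(
                "summaries compare different cells: "
                f"{a.provenance.to_dict()} vs {b.provenance.to_dict()}"
            )
    edges_a, edges_b = _edge_pairs(a), _edge_pairs(b)
    shared = edges_a & edges_b
    union = edges_a | edges_b
    return {
        "delta_nodes": a.n_nodes - b.n_nodes,
        "delta_associations": a.n_associations - b.n_associations,
        "delta_co_occurrences": a.n_co_occurrences - b.n_co_occurrences,
        "delta_co_exclusions": a.n_co_exclusions - b.n_co_exclusions,
        "shared_edges": sorted(["-".join(p) for p in shared]),
        "unique_to_a": sorted(["-".join(p) for p in edges_a - edges_b]),
        "unique_to_b": sorted(["-".join(p) for p in edges_b - edges_a]),
        "edge_overlap": (len(shared) / len(union)) if union else 1.0,
    }


def export_network(
    network: CoOccurrenceNetwork, path: str | Path, format: str = "graphml"
) -> None:
    """Write a network as GraphML, edge-list TSV or summary JSON.

    GraphML carries the node attributes (degree, strength_scaled,
    strength_tau) and edge attributes (tau, sign, p_value, q_value); the
    edge TSV mirrors the association writer columns restricted to retained
    edges; summary JSON embeds counts + config + provenance.
    """
    path = Path(path)
    if format == "graphml":
        graph = network.graph.copy()
        graph.graph.update(network.config.to_dict())
        graph.graph.update(network.provenance.to_dict())
        nx.write_graphml(graph, path)
    elif format == "edgelist_tsv":
        rows = [
            {
                "taxon_i": u,
                "taxon_j": v,
                "tau": tau,
                "sign": sign,
                "p_value": network.graph.edges[u, v]["p_value"],
                "q_value": network.graph.edges[u, v]["q_value"],
            }
            for u, v, tau, sign in network.edges
        ]
        pd.DataFrame(
            rows, columns=["taxon_i", "taxon_j", "tau", "sign", "p_value", "q_value"]
        ).to_csv(path, sep="\t", index=False)
    elif format == "summary_json":
        summary = summarize_network(network)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        raise ValueError(f"unknown export format {format!r}")
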