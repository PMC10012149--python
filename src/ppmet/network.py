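"""Metabolite network topology, hub calls, and pathway over-representation.

A typed compound/reaction/enzyme/gene graph is assembled from a knowledge
base around the query ("input") metabolites; relative betweenness centrality
(fraction of all-pairs shortest paths through a node, normalized per
connected component so values live in [0, 1]) plus degree identify hub
nodes. Pathway enrichment is an upper-tail hypergeometric over-representation
test against a pathway library, with a topology-based impact score: the share
of a pathway's betweenness-centrality importance carried by the hit
compounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NODE_ROLES",
    "HubCriteria",
    "MetaboliteNetwork",
    "build_network",
    "betweenness_centrality",
    "identify_hubs",
    "ora_enrich",
    "pathway_impact",
    "read_sif",
    "write_sif",
    "read_gmt",
    "write_gmt",
]

NODE_ROLES = ("input_compound", "compound", "gene", "enzyme", "reaction")


@dataclass(frozen=True)
class HubCriteria:
    """Degree/centrality thresholds for hub calls.

    ``inclusive`` compares with >= (so a degree-10 node passes min_degree 10);
    ``strict`` uses >.
    """

    min_degree: int = 10
    min_bc: float = 0.1
    comparison: str = "inclusive"

    def validate(self) -> None:
        if self.min_degree < 0:
            raise ValueError("min_degree must be >= 0")
        if not (0 <= self.min_bc <= 1):
            raise ValueError("min_bc must lie in [0, 1]")
        if self.comparison not in ("strict", "inclusive"):
            raise ValueError(f"unknown comparison {self.comparison!r}")


@dataclass
class MetaboliteNetwork:
    graph: nx.Graph
    input_compounds: list[str]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_components(self) -> int:
        return nx.number_connected_components(self.graph) if self.n_nodes else 0

    def metrics(self) -> pd.DataFrame:
        bc = betweenness_centrality(self)
        rows = [
            {
                "node": n,
                "role": self.graph.nodes[n].get("role", "compound"),
                "degree": self.graph.degree(n),
                "bc": bc[n],
            }
            for n in self.graph.nodes
        ]
        df = pd.DataFrame(rows, columns=["node", "role", "degree", "bc"])
        return df.sort_values(
            ["degree", "bc"], ascending=False, kind="stable"
        ).reset_index(drop=True)

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, str(path))


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def build_network(
    input_compounds,
    knowledge_edges,
    roles: dict[str, str],
) -> MetaboliteNetwork:
    """Keep the knowledge-base components touched by the input compounds.

    Input compounds absent from the knowledge base are dropped with a
    warning (mirroring partially-annotatable query lists); present ones are
    re-flagged with role ``input_compound``.
    """
    edges = list(knowledge_edges)
    if not edges:
        raise ValueError("knowledge base is empty")
    kb = nx.Graph()
    for u, v in edges:
        if u == v:
            raise ValueError(f"self-loop on node {u!r} violates network invariants")
        kb.add_edge(u, v)
    for n in kb.nodes:
        role = roles.get(n, "compound")
        if role not in NODE_ROLES:
            raise ValueError(f"unknown node role {role!r} for {n!r}")
        kb.nodes[n]["role"] = role

    present = []
    for c in input_compounds:
        if c in kb:
            present.append(c)
        else:
            warnings.warn(f"input compound {c!r} not in knowledge base; dropped", stacklevel=2)

    keep_nodes: set[str] = set()
    for comp in nx.connected_components(kb):
        if any(c in comp for c in present):
            keep_nodes |= comp
    G = kb.subgraph(keep_nodes).copy()
    for c in present:
        G.nodes[c]["role"] = "input_compound"
    return MetaboliteNetwork(G, present)


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

def betweenness_centrality(network: MetaboliteNetwork | nx.Graph) -> dict[str, float]:
    """Relative betweenness in [0, 1], normalized within each connected
    component by (n-1)(n-2)/2 with fractional credit for tied shortest paths."""
    G = network.graph if isinstance(network, MetaboliteNetwork) else network
    bc: dict[str, float] = {}
    for comp in nx.connected_components(G):
        sub = G.subgraph(comp)
        bc.update(nx.betweenness_centrality(sub, normalized=True))
    return bc


def identify_hubs(
    network: MetaboliteNetwork | nx.Graph,
    criteria: HubCriteria | None = None,
    metrics: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Nodes passing both degree and betweenness thresholds, sorted by degree."""
    criteria = criteria or HubCriteria()
    criteria.validate()
    if metrics is None:
        net = network if isinstance(network, MetaboliteNetwork) else MetaboliteNetwork(network, [])
        metrics = net.metrics()
    if criteria.comparison == "inclusive":
        mask = (metrics["degree"] >= criteria.min_degree) & (metrics["bc"] >= criteria.min_bc)
    else:
        mask = (metrics["degree"] > criteria.min_degree) & (metrics["bc"] > criteria.min_bc)
    return (
        metrics.loc[mask]
        .sort_values("degree", ascending=False, kind="stable")
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# over-representation analysis
# ---------------------------------------------------------------------------

def ora_enrich(
    query_compounds,
    library: dict[str, set[str]],
    universe: set[str] | None = None,
    adjust: str = "holm_bonferroni",
    pathway_graphs: dict[str, list[tuple[str, str]]] | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of pathway sets in the query.

    ``p_raw = P(X >= hits)`` with population ``|universe|``, successes the
    pathway size and draws ``|query & universe|``. Adjustment is
    Holm-Bonferroni by default with Benjamini-Hochberg available. When
    ``pathway_graphs`` supplies per-pathway edge lists a topology impact is
    added per row.
    """
    query = set(query_compounds)
    if not query:
        raise ValueError("query compound list is empty")
    if adjust not in ("holm_bonferroni", "bh"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    if universe is None:
        universe = set().union(*library.values())
    for name, members in library.items():
        if not members <= universe:
            raise ValueError(f"pathway {name!r} is not a subset of the universe")
    draws = len(query & universe)
    M = len(universe)

    rows = []
    for name, members in library.items():
        hits = len(query & members)
        p_raw = float(stats.hypergeom.sf(hits - 1, M, len(members), draws)) if draws else 1.0
        p_raw = min(p_raw, 1.0)
        impact = np.nan
        if pathway_graphs is not None and name in pathway_graphs:
            impact = pathway_impact(pathway_graphs[name], query & members)
        rows.append((name, len(members), hits, p_raw, impact))
    df = pd.DataFrame(
        rows, columns=["pathway", "total_compounds", "hits", "p_raw", "impact"]
    )
    method = "holm" if adjust == "holm_bonferroni" else "fdr_bh"
    df["p_adjusted"] = multipletests(df["p_raw"].to_numpy(), method=method)[1]
    df = df[["pathway", "total_compounds", "hits", "p_raw", "p_adjusted", "impact"]]
    return df.sort_values(["p_adjusted", "p_raw"], kind="stable").reset_index(drop=True)


def pathway_impact(pathway_edges, hit_compounds) -> float:
    """Share of a pathway graph's betweenness importance held by the hits.

    If every node has zero betweenness (e.g. a clique), importance is spread
    uniformly so that full coverage still scores 1.0.
    """
    G = nx.Graph()
    G.add_edges_from(pathway_edges)
    if G.number_of_nodes() == 0:
        raise ValueError("pathway graph is empty")
    hits = set(hit_compounds)
    missing = hits - set(G.nodes)
    if missing:
        raise ValueError(f"hit compounds absent from pathway graph: {sorted(missing)}")
    bc = betweenness_centrality(G)
    total = sum(bc.values())
    if total == 0:
        return len(hits) / G.number_of_nodes()
    return sum(bc[h] for h in hits) / total


# ---------------------------------------------------------------------------
# file formats: SIF and GMT
# ---------------------------------------------------------------------------

def read_sif(path: str | Path) -> list[tuple[str, str]]:
    """SIF ``node <tab> relation <tab> node`` edge list."""
    edges = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed SIF line: {line!r}")
        src, _rel, *targets = parts
        for t in targets:
            edges.append((src, t))
    return edges


def write_sif(edges, path: str | Path, relation: str = "cr") -> None:
    lines = [f"{u}\t{relation}\t{v}" for u, v in edges]
    Path(path).write_text("\n".join(lines) + "\n")


def read_edge_csv(path: str | Path) -> list[tuple[str, str]]:
    """Two-column edge list CSV (header ``source,target``)."""
    df = pd.read_csv(path)
    return list(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def read_roles_csv(path: str | Path) -> dict[str, str]:
    """Node-role sidecar CSV (header ``node,role``)."""
    df = pd.read_csv(path)
    roles = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    bad = set(roles.values()) - set(NODE_ROLES)
    if bad:
        raise ValueError(f"unknown node roles in sidecar: {sorted(bad)}")
    return roles


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT ``name <tab> description <tab> member...`` pathway sets."""
    library: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        library[parts[0]] = set(parts[2:])
    return library


def write_gmt(library: dict[str, set[str]], path: str | Path) -> None:
    lines = [
        "\t".join([name, "na", *sorted(members)]) for name, members in library.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")
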