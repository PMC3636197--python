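"""Bipartite compound–target networks: construction, topology, centrality.

Networks connect small compounds to the protein targets they bind, either
from experimental affinity data or from a virtual-screening (docking)
campaign. Docking scores are positive and higher-is-better (pKd-like);
an edge from a score table is admitted only if its score clears both a
global threshold and the score of the target's own co-crystallized
reference ligand.

All topology and centrality computations run on an undirected simple
graph via networkx; betweenness is normalized by (N-1)(N-2)/2 and
computed on the full (possibly disconnected) graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sstats

EDGE_COLUMNS = ["compound_id", "target_id", "score", "source"]


@dataclass(frozen=True)
class InteractionEdge:
    """One compound–target interaction with a positive affinity-scale score."""

    compound_id: str
    target_id: str
    score: float
    source: str = "experimental"  # or "docking"


@dataclass
class BipartiteNetwork:
    """Undirected bipartite graph of compound and target nodes.

    The underlying :class:`networkx.Graph` stores a ``partition`` node
    attribute (``"compound"`` or ``"target"``) and a ``score`` edge
    attribute where one is known.
    """

    graph: nx.Graph

    @property
    def compounds(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("partition") == "compound"}

    @property
    def targets(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("partition") == "target"}

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass(frozen=True)
class NetworkStats:
    n_compounds: int
    n_targets: int
    n_edges: int
    mean_degree: float
    mean_shortest_path: float
    density: float
    n_components: int
    giant_fraction: float
    mean_targets_per_compound: float
    mean_hits_per_target: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares log-log fit of a degree histogram, P(k) = a * k**gamma."""

    coefficient: float
    gamma: float  # negative for decaying distributions
    r: float


# ---------------------------------------------------------------------------
# edge tables and admissibility
# ---------------------------------------------------------------------------

def edges_to_frame(edges: Iterable[InteractionEdge] | pd.DataFrame) -> pd.DataFrame:
    """Normalize an edge collection to a DataFrame with the standard columns."""
    if isinstance(edges, pd.DataFrame):
        df = edges.copy()
        if "source" not in df.columns:
            df["source"] = "experimental"
        if "score" not in df.columns:
            df["score"] = 1.0
        missing = {"compound_id", "target_id"} - set(df.columns)
        if missing:
            raise ValueError(f"edge table missing columns: {sorted(missing)}")
        return df[EDGE_COLUMNS]
    rows = [(e.compound_id, e.target_id, e.score, e.source) for e in edges]
    return pd.DataFrame(rows, columns=EDGE_COLUMNS)


def aggregate_edges(edges: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate (compound, target) rows, keeping the best score."""
    return (
        edges.sort_values("score", ascending=False)
        .drop_duplicates(["compound_id", "target_id"], keep="first")
        .sort_index()
        .reset_index(drop=True)
    )


def admissible_edges(
    edges: pd.DataFrame,
    threshold: float | None = None,
    reference_scores: Mapping[str, float] | pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Apply the docking admissibility rule to an aggregated edge table.

    With a threshold, an edge survives only if its score is strictly higher
    than the threshold *and* strictly higher than the reference-ligand score
    of its target. Without a threshold all edges survive.
    """
    edges = aggregate_edges(edges_to_frame(edges))
    if threshold is None:
        return edges
    refs = _reference_map(reference_scores)
    missing = set(edges["target_id"]) - set(refs)
    if missing:
        raise ValueError(
            f"reference score missing for target(s): {', '.join(sorted(missing)[:5])}"
            + ("..." if len(missing) > 5 else "")
        )
    ref_col = edges["target_id"].map(refs)
    keep = (edges["score"] > threshold) & (edges["score"] > ref_col)
    return edges[keep].reset_index(drop=True)


def _reference_map(reference_scores) -> dict[str, float]:
    if reference_scores is None:
        raise ValueError("reference_scores required when a threshold is given")
    if isinstance(reference_scores, pd.DataFrame):
        return dict(zip(reference_scores["target_id"], reference_scores["ref_score"].astype(float)))
    return {str(k): float(v) for k, v in reference_scores.items()}


def build_network(
    edges: Iterable[InteractionEdge] | pd.DataFrame,
    threshold: float | None = None,
    reference_scores: Mapping[str, float] | pd.DataFrame | None = None,
) -> BipartiteNetwork:
    """Build the bipartite compound–target graph from a score table.

    Nodes appear only through admitted edges, so compounds or targets whose
    every interaction is filtered out are dropped entirely.
    """
    adm = admissible_edges(edges, threshold, reference_scores)
    if adm.empty and threshold is None:
        raise ValueError("empty edge table")
    g = nx.Graph()
    for row in adm.itertuples(index=False):
        g.add_node(row.compound_id, partition="compound")
        g.add_node(row.target_id, partition="target")
        g.add_edge(row.compound_id, row.target_id, score=float(row.score))
    return BipartiteNetwork(graph=g)


def hit_rate(
    edges: Iterable[InteractionEdge] | pd.DataFrame,
    threshold: float,
    reference_scores: Mapping[str, float] | pd.DataFrame,
) -> float:
    """Fraction of screened compounds with at least one admissible interaction.

    The denominator is every distinct compound in the score table, hits or
    not — the virtual-screening hit-rate convention.
    """
    all_edges = edges_to_frame(edges)
    n_total = all_edges["compound_id"].nunique()
    if n_total == 0:
        raise ValueError("empty edge table")
    adm = admissible_edges(all_edges, threshold, reference_scores)
    return adm["compound_id"].nunique() / n_total


# ---------------------------------------------------------------------------
# centrality
# ---------------------------------------------------------------------------

def degree(network: BipartiteNetwork) -> dict[str, int]:
    """Node degree — the number of neighbors of each node."""
    _require_nonempty(network)
    return dict(network.graph.degree())


def betweenness(network: BipartiteNetwork, normalized: bool = True) -> dict[str, float]:
    """Brandes shortest-path betweenness on the full graph.

    Normalized by (N-1)(N-2)/2 for undirected graphs; endpoints are
    excluded and disconnected pairs contribute nothing.
    """
    _require_nonempty(network)
    return nx.betweenness_centrality(network.graph, normalized=normalized)


def centrality_table(network: BipartiteNetwork) -> pd.DataFrame:
    """Degree and normalized betweenness for every node, with its partition."""
    deg = degree(network)
    btw = betweenness(network)
    part = nx.get_node_attributes(network.graph, "partition")
    df = pd.DataFrame(
        {
            "node_id": list(deg),
            "partition": [part.get(n, "") for n in deg],
            "degree": [deg[n] for n in deg],
            "betweenness": [btw[n] for n in deg],
        }
    )
    return df.sort_values("node_id", ignore_index=True)


def rank_hubs_bottlenecks(
    centrality_records: pd.DataFrame, top_k: int = 10, partition: str | None = "compound"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank nodes as hubs (degree first) and bottlenecks (betweenness first).

    Hubs sort by degree descending with betweenness then node id breaking
    ties; bottlenecks symmetrically by betweenness first. By default only
    compound nodes are ranked.
    """
    if centrality_records.empty:
        raise ValueError("empty centrality table")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    df = centrality_records
    if partition is not None and "partition" in df.columns:
        df = df[df["partition"] == partition]
    hubs = df.sort_values(
        ["degree", "betweenness", "node_id"], ascending=[False, False, True], ignore_index=True
    ).head(top_k)
    bottlenecks = df.sort_values(
        ["betweenness", "degree", "node_id"], ascending=[False, False, True], ignore_index=True
    ).head(top_k)
    return hubs, bottlenecks


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

def components(network: BipartiteNetwork) -> tuple[list[set[str]], float]:
    """Connected components (largest first) and the giant-component fraction.

    Equal-sized components are ordered by their smallest node id, making
    the listing deterministic.
    """
    _require_nonempty(network)
    comps = sorted(nx.connected_components(network.graph), key=lambda c: (-len(c), min(c)))
    giant_fraction = len(comps[0]) / network.graph.number_of_nodes()
    return comps, giant_fraction


def mean_shortest_path(network: BipartiteNetwork) -> float:
    """Mean unweighted shortest-path length over connected node pairs.

    Pairs in different components are excluded (not counted as infinite),
    so the statistic stays finite on fragmented networks.
    """
    _require_nonempty(network)
    total = 0
    n_pairs = 0
    for comp in nx.connected_components(network.graph):
        sub = network.graph.subgraph(comp)
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            for d in dists.values():
                if d > 0:
                    total += d
                    n_pairs += 1
    if n_pairs == 0:
        raise ValueError("no connected node pairs")
    # each unordered pair counted twice
    return total / n_pairs


def density(network: BipartiteNetwork) -> float:
    """Graph density 2E / (N(N-1)) over all nodes (general-graph convention)."""
    n = network.graph.number_of_nodes()
    if n < 2:
        raise ValueError("density needs at least 2 nodes")
    return nx.density(network.graph)


def network_stats(network: BipartiteNetwork) -> NetworkStats:
    """Topology summary of a bipartite network."""
    g = network.graph
    n_c, n_t = len(network.compounds), len(network.targets)
    e = g.number_of_edges()
    n = g.number_of_nodes()
    comps, giant = components(network)
    return NetworkStats(
        n_compounds=n_c,
        n_targets=n_t,
        n_edges=e,
        mean_degree=2.0 * e / n,
        mean_shortest_path=mean_shortest_path(network),
        density=density(network),
        n_components=len(comps),
        giant_fraction=giant,
        mean_targets_per_compound=e / n_c if n_c else float("nan"),
        mean_hits_per_target=e / n_t if n_t else float("nan"),
    )


def density_from_mean_degree(mean_degree: float, n_nodes: int) -> float:
    """Density implied by a mean degree: <k> / (N - 1).

    Algebraically identical to 2E / (N(N-1)) since <k> = 2E/N; useful as a
    consistency check when only summary statistics of a network are known.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    return mean_degree / (n_nodes - 1)


def mean_hits_per_target_from(mean_targets_per_compound: float, n_compounds: int, n_targets: int) -> float:
    """Mean hits per target implied by the edge-count identity.

    Both sides of ``mean_targets_per_compound * n_compounds =
    mean_hits_per_target * n_targets`` equal the edge count of a bipartite
    graph.
    """
    if n_targets < 1:
        raise ValueError("need at least 1 target")
    return mean_targets_per_compound * n_compounds / n_targets


# ---------------------------------------------------------------------------
# scale-free fit
# ---------------------------------------------------------------------------

def fit_power_law(degree_sequence: Sequence[int]) -> PowerLawFit:
    """Fit P(k) = a * k**gamma to a degree histogram by log-log least squares.

    The histogram of raw frequencies is taken over degrees with nonzero
    frequency; ordinary least squares of log10(frequency) on log10(degree)
    gives ``gamma`` (the slope, negative for decaying distributions),
    ``a = 10**intercept`` and ``r``, the Pearson correlation of the log-log
    points.
    """
    deg = np.asarray(list(degree_sequence), dtype=int)
    deg = deg[deg > 0]
    values, counts = np.unique(deg, return_counts=True)
    if len(values) < 3:
        raise ValueError(f"need >= 3 distinct positive degrees to fit, got {len(values)}")
    lx = np.log10(values.astype(float))
    ly = np.log10(counts.astype(float))
    res = sstats.linregress(lx, ly)
    return PowerLawFit(coefficient=float(10.0 ** res.intercept), gamma=float(res.slope), r=float(res.rvalue))


def degree_sequence(network: BipartiteNetwork, partition: str | None = None) -> list[int]:
    """Degrees of all nodes, or of one partition only (``"compound"``/``"target"``)."""
    deg = degree(network)
    if partition is None:
        return list(deg.values())
    part = nx.get_node_attributes(network.graph, "partition")
    return [d for n, d in deg.items() if part.get(n) == partition]


# ---------------------------------------------------------------------------
# i/o
# ---------------------------------------------------------------------------

def write_graphml(network: BipartiteNetwork, path) -> None:
    nx.write_graphml(network.graph, path)


def read_edge_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return edges_to_frame(df)


def read_reference_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"target_id", "ref_score"} - set(df.columns)
    if missing:
        raise ValueError(f"reference table missing columns: {sorted(missing)}")
    return df


def _require_nonempty(network: BipartiteNetwork) -> None:
    if network.graph.number_of_nodes() == 0:
        raise ValueError("empty network")
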