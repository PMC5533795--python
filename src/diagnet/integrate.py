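"""Consensus integration of per-cohort diagnostic networks.

The overlap between diagnostic networks is quantified with the overlapping
rate

    100 · G^{1…n} / (G¹ + G² + … + Gⁿ − G^{1…n}),

where Gⁱ is the gene count of network i and G^{1…n} the number of genes
common to all n networks.  The denominator is implemented literally as the
sum of sizes minus the common count; for n > 2 this is not the union size
(genes shared by some but not all networks are counted multiply), which makes
the rate a conservative overlap measure for higher-order combinations.

The integrated (consensus) diagnostic network keeps genes and edges present
in at least k input networks (default 3), with support counts attached.
"""

from __future__ import annotations

from collections import Counter
from itertools import combinations

import networkx as nx
import pandas as pd


def _node_sets(networks):
    out = []
    for net in networks:
        out.append(set(net.nodes()) if isinstance(net, nx.Graph) else set(net))
    return out


def overlapping_rate(networks) -> float:
    """Overlap percentage of a combination of ≥ 2 networks (node sets or
    graphs); 0 iff the common intersection is empty.  For a pair the rate is
    100 iff the node sets are identical; for n > 2 the literal denominator
    caps the rate at 100/(n−1) even for identical sets."""
    sets = _node_sets(networks)
    if len(sets) < 2:
        raise ValueError("need at least 2 networks")
    common = set.intersection(*sets)
    denom = sum(len(s) for s in sets) - len(common)
    if denom == 0:
        # all sets empty; define the overlap of nothing as 0
        return 0.0
    return 100.0 * len(common) / denom


def overlap_profile(networks, sizes=None) -> pd.DataFrame:
    """Mean/min/max overlapping rate and common-gene count for every
    combination size (2..n by default), enumerating all combinations."""
    sets = _node_sets(networks)
    n = len(sets)
    if n < 2:
        raise ValueError("need at least 2 networks")
    if sizes is None:
        sizes = range(2, n + 1)
    rows = []
    for size in sizes:
        if not 2 <= size <= n:
            raise ValueError(f"combination size {size} out of range 2..{n}")
        rates, commons = [], []
        for combo in combinations(range(n), size):
            subset = [sets[i] for i in combo]
            rates.append(overlapping_rate(subset))
            commons.append(len(set.intersection(*subset)))
        rows.append(
            {
                "size": size,
                "n_combinations": len(rates),
                "mean_overlap": sum(rates) / len(rates),
                "min_overlap": min(rates),
                "max_overlap": max(rates),
                "mean_common_genes": sum(commons) / len(commons),
                "min_common_genes": min(commons),
                "max_common_genes": max(commons),
            }
        )
    return pd.DataFrame(rows).set_index("size")


def consensus_network(networks, k: int = 3, keep_isolated: bool = False) -> nx.Graph:
    """Consensus graph of genes and edges supported by ≥ k input networks.

    A node is kept iff it appears in ≥ k networks; an edge iff it appears in
    ≥ k networks and both endpoints are kept.  Support counts are stored as
    node/edge attributes and ``k`` on the graph.  Nodes kept by support but
    left without any retained edge are dropped unless ``keep_isolated``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    networks = list(networks)
    node_support = Counter()
    edge_support = Counter()
    for net in networks:
        node_support.update(set(net.nodes()))
        edge_support.update(frozenset(e) for e in net.edges() if e[0] != e[1])
    out = nx.Graph(k=k, n_networks=len(networks))
    for node, sup in node_support.items():
        if sup >= k:
            out.add_node(node, support=sup)
    for edge, sup in edge_support.items():
        a, b = sorted(edge)
        if sup >= k and a in out and b in out:
            out.add_edge(a, b, support=sup)
    if not keep_isolated:
        out.remove_nodes_from([n for n in list(out.nodes()) if out.degree(n) == 0])
    return out


def write_consensus(net: nx.Graph, path: str) -> None:
    """TSV edge list with node and edge support columns."""
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tedge_support\tsupport_a\tsupport_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in net.edges()):
            fh.write(
                f"{a}\t{b}\t{net.edges[a, b]['support']}\t"
                f"{net.nodes[a]['support']}\t{net.nodes[b]['support']}\n"
            )
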