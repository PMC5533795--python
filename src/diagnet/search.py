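"""Greedy active-subnetwork search with multi-round merge-and-shrink.

A module's score aggregates the differential t-scores of its member genes.
Three scoring methods are available:

``sum``
    Σ|t_i| — plain accumulated score (never favors stopping; kept as a
    configurable variant).
``norm_agg`` (default)
    Σ|t_i| / sqrt(k) — the size-normalized aggregate classical in active-module
    search; rewards concentrated signal, so greedy growth stops once frontier
    genes would dilute the module.
``mi``
    histogram mutual information between the binned |t| distributions of the
    module and of its neighbor frontier; an operational reading of scoring a
    module against its surroundings (excluded from head-to-head guarantees —
    the estimator is defined over the two empirical |t| samples).

One greedy expansion is run from every gene as seed; the top-k modules by
score are merged, and the search is repeated on the merged subgraph until the
node count reaches the stopping size (approximately 50 by default) or stops
shrinking.  All tie-breaks are lexicographic on gene symbols, so the search
is fully deterministic.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from diagnet.network import induce_subnetwork

_MONOTONE_METHODS = ("sum", "norm_agg")
METHODS = _MONOTONE_METHODS + ("mi",)


@dataclass
class SearchConfig:
    method: str = "norm_agg"
    top_k: int = 10
    stop_size: int = 50
    stop_slack: int = 5
    mi_bins: int = 8
    rng_seed: int | None = None

    def validate(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown scoring method: {self.method!r}")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.stop_size < 1:
            raise ValueError("stop_size must be >= 1")


@dataclass(frozen=True)
class ScoredModule:
    """A connected module found by greedy expansion."""

    nodes: frozenset
    score: float
    method: str
    seed_node: str

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass
class SearchResult:
    """Final diagnostic network: node set, induced graph, per-round summary."""

    nodes: frozenset
    graph: nx.Graph
    score: float
    method: str
    rounds: pd.DataFrame = field(repr=False, default=None)


def _check_scores(nodes, scores) -> None:
    missing = [n for n in nodes if n not in scores]
    if missing:
        raise KeyError(f"nodes without scores: {sorted(missing)[:5]}")


def _mi_score(nodes, scores, net, bins: int) -> float:
    """Histogram mutual information between the |t| samples of the module and
    of its frontier (treated as the two marginals of a paired occupancy
    distribution over equal-width bins)."""
    if net is None:
        raise ValueError("mi scoring requires the host graph")
    module = set(nodes)
    frontier = set()
    for n in module:
        frontier.update(net.neighbors(n))
    frontier -= module
    if not frontier:
        return 0.0
    a = np.abs([scores[n] for n in sorted(module)])
    c = np.abs([scores[n] for n in sorted(frontier)])
    lo = min(a.min(), c.min())
    hi = max(a.max(), c.max())
    if hi == lo:
        return 0.0
    edges = np.linspace(lo, hi, bins + 1)
    pa, _ = np.histogram(a, bins=edges)
    pc, _ = np.histogram(c, bins=edges)
    pa = pa / pa.sum()
    pc = pc / pc.sum()
    joint = np.outer(pa, pc)
    # occupancy coupling: overlap mass concentrated on the diagonal
    diag = np.minimum(pa, pc)
    joint = 0.5 * joint + 0.5 * np.diag(diag)
    joint /= joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    mask = joint > 0
    return float(
        (joint[mask] * np.log(joint[mask] / np.outer(px, py)[mask])).sum()
    )


def module_score(nodes, scores, method: str = "norm_agg", net=None, mi_bins: int = 8) -> float:
    """Score a node set under one of the scoring methods (see module docs)."""
    nodes = list(nodes)
    if not nodes:
        raise ValueError("empty module")
    _check_scores(nodes, scores)
    if method == "sum":
        return float(sum(abs(scores[n]) for n in nodes))
    if method == "norm_agg":
        return float(sum(abs(scores[n]) for n in nodes) / math.sqrt(len(nodes)))
    if method == "mi":
        return _mi_score(nodes, scores, net, mi_bins)
    raise ValueError(f"unknown scoring method: {method!r}")


def greedy_expand(net: nx.Graph, scores, seed: str, config: SearchConfig | None = None) -> ScoredModule:
    """Grow a module from ``seed`` by repeatedly adding the frontier node that
    gives the largest strict score increase; stop when no addition helps.

    For the monotone methods (``sum``, ``norm_agg``) the best candidate is the
    frontier node of largest |t|, so a max-heap over the frontier suffices;
    for ``mi`` every frontier candidate is evaluated.  Ties break
    lexicographically.
    """
    config = config or SearchConfig()
    config.validate()
    if seed not in net:
        raise KeyError(f"seed not in graph: {seed}")
    _check_scores([seed], scores)
    module = {seed}
    method = config.method
    if method in _MONOTONE_METHODS:
        abs_sum = abs(scores[seed])
        score = abs_sum  # k=1: both methods equal |t|
        frontier = []  # heap of (-|t|, gene)
        in_frontier = set()
        for nb in net.neighbors(seed):
            if nb not in in_frontier:
                heapq.heappush(frontier, (-abs(scores[nb]), nb))
                in_frontier.add(nb)
        while frontier:
            neg_t, gene = heapq.heappop(frontier)
            if gene in module:
                continue
            new_sum = abs_sum + (-neg_t)
            k = len(module) + 1
            new_score = new_sum if method == "sum" else new_sum / math.sqrt(k)
            if new_score <= score:
                break
            module.add(gene)
            abs_sum, score = new_sum, new_score
            for nb in net.neighbors(gene):
                if nb not in module and nb not in in_frontier:
                    _check_scores([nb], scores)
                    heapq.heappush(frontier, (-abs(scores[nb]), nb))
                    in_frontier.add(nb)
    else:
        score = module_score(module, scores, method, net, config.mi_bins)
        while True:
            frontier = set()
            for n in module:
                frontier.update(net.neighbors(n))
            frontier -= module
            best = None
            for gene in sorted(frontier):
                cand = module_score(module | {gene}, scores, method, net, config.mi_bins)
                if cand > score and (best is None or cand > best[0]):
                    best = (cand, gene)
            if best is None:
                break
            score = best[0]
            module.add(best[1])
    return ScoredModule(
        nodes=frozenset(module), score=float(score), method=method, seed_node=seed
    )


def search_round(net: nx.Graph, scores, config: SearchConfig | None = None) -> set:
    """One search round: greedy expansion from every node as seed, then the
    union of the node sets of the ``top_k`` modules by score.

    Module ranking ties break lexicographically on the sorted node tuple.
    """
    config = config or SearchConfig()
    config.validate()
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    modules = [greedy_expand(net, scores, seed, config) for seed in sorted(net.nodes())]
    modules.sort(key=lambda m: (-m.score, tuple(sorted(m.nodes))))
    union = set()
    for m in modules[: config.top_k]:
        union |= m.nodes
    return union


def iterate_search(net: nx.Graph, scores, config: SearchConfig | None = None) -> SearchResult:
    """Multi-round merge-and-shrink search producing the diagnostic network.

    Round r searches the subgraph induced by round r−1's merged node set; the
    node count is non-increasing.  Iteration stops once the count reaches
    ``stop_size + stop_slack`` or stops decreasing.  Returns the final node
    set with its induced subgraph and a per-round summary table.
    """
    config = config or SearchConfig()
    config.validate()
    current = net
    rows = []
    nodes = set(net.nodes())
    r = 0
    while True:
        if len(nodes) <= config.stop_size + config.stop_slack:
            break
        r += 1
        new_nodes = search_round(current, scores, config)
        current = current.subgraph(new_nodes).copy()
        score = module_score(new_nodes, scores, config.method, current, config.mi_bins)
        rows.append({"round": r, "n_nodes": len(new_nodes), "score": score})
        if len(new_nodes) == len(nodes):
            nodes = new_nodes
            break
        nodes = new_nodes
    graph = induce_subnetwork(net, nodes, drop_isolated=False)
    score = module_score(nodes, scores, config.method, graph, config.mi_bins) if nodes else 0.0
    rounds = pd.DataFrame(rows, columns=["round", "n_nodes", "score"])
    return SearchResult(
        nodes=frozenset(nodes),
        graph=graph,
        score=float(score),
        method=config.method,
        rounds=rounds,
    )
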