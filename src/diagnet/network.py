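"""Interaction-network model: parsing, induced subnetworks, degrees.

Networks are undirected simple :class:`networkx.Graph` objects over upper-cased
gene symbols; self-loops and parallel edges are never created.  Two input
dialects are supported: a plain two-column TSV edge list and the BioGRID TAB3
export, from which physical human-human interactions are kept by default.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field

import networkx as nx

# BioGRID TAB3 column headers used for filtering and symbol mapping
_TAB3_SYMBOL_A = "Official Symbol Interactor A"
_TAB3_SYMBOL_B = "Official Symbol Interactor B"
_TAB3_ORG_A = "Organism ID Interactor A"
_TAB3_ORG_B = "Organism ID Interactor B"
_TAB3_SYSTEM_TYPE = "Experimental System Type"


@dataclass
class ParseReport:
    """Per-file ingest accounting: kept + skipped rows equal the input rows."""

    path: str
    rows: int = 0
    kept: int = 0
    skipped_filter: int = 0
    skipped_self_loop: int = 0
    skipped_duplicate: int = 0
    skipped_malformed: int = 0
    messages: list = field(default_factory=list)

    @property
    def skipped(self) -> int:
        return (
            self.skipped_filter
            + self.skipped_self_loop
            + self.skipped_duplicate
            + self.skipped_malformed
        )


def _add_edge(net: nx.Graph, a: str, b: str, report: ParseReport) -> None:
    a, b = a.strip().upper(), b.strip().upper()
    if not a or not b:
        report.skipped_malformed += 1
        return
    if a == b:
        report.skipped_self_loop += 1
        return
    if net.has_edge(a, b):
        report.skipped_duplicate += 1
        return
    net.add_edge(a, b)
    report.kept += 1


def read_edge_list(
    path: str,
    dialect: str = "plain",
    organism: int = 9606,
    system_type: str = "physical",
) -> nx.Graph:
    """Read an interaction network from ``path``.

    ``dialect='plain'`` expects two tab-separated symbol columns per line
    (lines starting with ``#`` are ignored).  ``dialect='biogrid-tab3'``
    parses a BioGRID TAB3 export, keeping rows whose two organism IDs equal
    ``organism`` and whose experimental system type equals ``system_type``,
    and mapping interactors through the Official Symbol columns.  Self-loops
    and duplicate edges are dropped in both dialects; malformed rows are
    skipped with a warning.  The :class:`ParseReport` is attached to the
    returned graph as ``net.graph['parse_report']``.
    """
    if dialect not in ("plain", "biogrid-tab3"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    net = nx.Graph()
    report = ParseReport(path=path)
    with open(path, newline="") as fh:
        if dialect == "plain":
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                report.rows += 1
                parts = line.split("\t")
                if len(parts) < 2:
                    parts = line.split()
                if len(parts) < 2:
                    report.skipped_malformed += 1
                    report.messages.append(f"malformed line: {line[:60]!r}")
                    continue
                _add_edge(net, parts[0], parts[1], report)
        else:
            reader = csv.DictReader(fh, delimiter="\t")
            required = {
                _TAB3_SYMBOL_A,
                _TAB3_SYMBOL_B,
                _TAB3_ORG_A,
                _TAB3_ORG_B,
                _TAB3_SYSTEM_TYPE,
            }
            if reader.fieldnames is None or not required <= set(reader.fieldnames):
                raise ValueError(f"{path}: missing BioGRID TAB3 columns")
            for row in reader:
                report.rows += 1
                try:
                    org_a = int(row[_TAB3_ORG_A])
                    org_b = int(row[_TAB3_ORG_B])
                except (TypeError, ValueError):
                    report.skipped_malformed += 1
                    continue
                if org_a != organism or org_b != organism:
                    report.skipped_filter += 1
                    continue
                if row[_TAB3_SYSTEM_TYPE].strip().lower() != system_type:
                    report.skipped_filter += 1
                    continue
                _add_edge(net, row[_TAB3_SYMBOL_A], row[_TAB3_SYMBOL_B], report)
    if report.skipped_malformed:
        warnings.warn(
            f"{path}: skipped {report.skipped_malformed} malformed rows",
            stacklevel=2,
        )
    if net.number_of_edges() == 0:
        raise ValueError(f"{path}: no edges after parsing/filtering")
    net.graph["parse_report"] = report
    return net


def write_edge_list(net: nx.Graph, path: str, support: bool = False) -> None:
    """Write a two-column TSV edge list (optionally with edge support counts)."""
    with open(path, "w") as fh:
        if support:
            fh.write("gene_a\tgene_b\tsupport\n")
            for a, b, data in sorted(net.edges(data=True)):
                fh.write(f"{a}\t{b}\t{data.get('support', '')}\n")
        else:
            for a, b in sorted(tuple(sorted(e)) for e in net.edges()):
                fh.write(f"{a}\t{b}\n")


def write_sif(net: nx.Graph, path: str, relation: str = "pp") -> None:
    """Write the network in Cytoscape SIF format (isolated nodes on own lines)."""
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in net.edges()):
            fh.write(f"{a}\t{relation}\t{b}\n")
        for node in sorted(net.nodes()):
            if net.degree(node) == 0:
                fh.write(f"{node}\n")


def induce_subnetwork(net: nx.Graph, genes, drop_isolated: bool = True) -> nx.Graph:
    """Subgraph induced by ``genes``; by default genes left with no edge are
    dropped (a diagnostic network reports interacting genes only)."""
    keep = {str(g).upper() for g in genes} & set(net.nodes())
    sub = nx.Graph(net.subgraph(keep))
    if drop_isolated:
        sub.remove_nodes_from([n for n in list(sub.nodes()) if sub.degree(n) == 0])
    sub.graph.pop("parse_report", None)
    return sub


def degree(net: nx.Graph, gene: str) -> int:
    """Number of edges incident to ``gene``; unknown genes raise ``KeyError``."""
    gene = str(gene).upper()
    if gene not in net:
        raise KeyError(f"gene not in network: {gene}")
    return net.degree(gene)


def degree_table(net: nx.Graph) -> dict:
    """Mapping gene -> degree for every node of the network."""
    return dict(net.degree())
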