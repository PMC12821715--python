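"""Signed transcription-factor regulon networks for the screened genes.

Builds a two-level network from a curated edge-table snapshot (RegulonDB /
EcoCyc style): first-level edges are TF → screened-gene regulations;
second-level edges are regulations of those TFs themselves, giving one
level of upstream expansion. A TF that both activates and represses a
target carries a single ``dual`` edge, expanded into both sign-split
networks at export time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from arspattern.data_io import (
    LEVEL_GENE,
    LEVEL_TF,
    SIGN_ACTIVATION,
    SIGN_DUAL,
    SIGN_REPRESSION,
    RegulatoryEdge,
)

KIND_GENE = "gene"
KIND_TF = "tf"

ROLE_TARGET = "target"
ROLE_ACTIVATOR = "activator"
ROLE_REPRESSOR = "repressor"
ROLE_DUAL = "dual"


@dataclass
class RegulatoryNetwork:
    """Nodes + signed edges; ``flagged_edges`` are gene_level edges whose
    target was not in the input gene list (retained, since a snapshot may
    be broader than the screen)."""

    nodes: dict[str, dict] = field(default_factory=dict)  # name → {kind, role}
    edges: list[RegulatoryEdge] = field(default_factory=list)
    flagged_edges: list[RegulatoryEdge] = field(default_factory=list)

    def edge_set(self) -> set[tuple[str, str, str, str]]:
        return {(e.target_gene, e.regulator, e.sign, e.level) for e in self.edges}

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for name, attrs in self.nodes.items():
            g.add_node(name, **attrs)
        for e in self.edges:
            g.add_edge(
                e.regulator,
                e.target_gene,
                sign=e.sign,
                level=e.level,
                flagged=e in self.flagged_edges,
            )
        return g


@dataclass(frozen=True)
class DegreeSummary:
    """TF target-degree summary over first-level edges only."""

    n_tfs: int
    n_genes_covered: int
    n_genes_input: int
    tfs_with_multi_targets: int
    tfs_with_single_target: int


def _collapse_dual(edges: Iterable[RegulatoryEdge]) -> list[RegulatoryEdge]:
    """Merge activation+repression rows for the same (target, regulator,
    level) into a single dual edge."""
    signs: dict[tuple[str, str, str], set[str]] = {}
    for e in edges:
        signs.setdefault((e.target_gene, e.regulator, e.level), set()).add(e.sign)
    out = []
    for (target, reg, level), ss in signs.items():
        if SIGN_DUAL in ss or {SIGN_ACTIVATION, SIGN_REPRESSION} <= ss:
            sign = SIGN_DUAL
        else:
            sign = next(iter(ss))
        out.append(RegulatoryEdge(target, reg, sign, level))
    return out


def build_network(
    edges: Sequence[RegulatoryEdge], gene_list: Sequence[str]
) -> RegulatoryNetwork:
    """Assemble the two-level network for a list of screened genes.

    First-level edges whose target is in ``gene_list`` define the TF set;
    second-level (tf_level) edges are kept when they regulate one of those
    TFs. Gene-level edges onto genes outside the list are retained but
    flagged. Node roles: targets are genes; a TF is an activator,
    repressor, or dual according to the union of its edge signs.
    """
    if not gene_list:
        raise ValueError("gene list must be non-empty")
    genes = {g.lower() for g in gene_list}
    collapsed = _collapse_dual(edges)

    gene_edges = [e for e in collapsed if e.level == LEVEL_GENE]
    primary = [e for e in gene_edges if e.target_gene.lower() in genes]
    flagged = [e for e in gene_edges if e.target_gene.lower() not in genes]
    tfs = {e.regulator for e in primary} | {e.regulator for e in flagged}
    tf_edges = [e for e in collapsed if e.level == LEVEL_TF and e.target_gene in tfs]

    kept = primary + flagged + tf_edges
    net = RegulatoryNetwork(edges=kept, flagged_edges=list(flagged))

    regulators = {e.regulator for e in kept}
    for e in kept:
        if e.target_gene not in net.nodes:
            kind = KIND_TF if e.target_gene in regulators or e.level == LEVEL_TF else KIND_GENE
            net.nodes[e.target_gene] = {"kind": kind, "role": ROLE_TARGET}
    sign_sets: dict[str, set[str]] = {}
    for e in kept:
        sign_sets.setdefault(e.regulator, set()).add(e.sign)
    for reg, ss in sign_sets.items():
        if SIGN_DUAL in ss or {SIGN_ACTIVATION, SIGN_REPRESSION} <= ss:
            role = ROLE_DUAL
        elif ss == {SIGN_ACTIVATION}:
            role = ROLE_ACTIVATOR
        else:
            role = ROLE_REPRESSOR
        net.nodes[reg] = {"kind": KIND_TF, "role": role}
    return net


def split_by_sign(
    network: RegulatoryNetwork,
) -> tuple[RegulatoryNetwork, RegulatoryNetwork]:
    """(negative, positive) sub-networks; dual edges appear in both."""
    neg_edges = [e for e in network.edges if e.sign in (SIGN_REPRESSION, SIGN_DUAL)]
    pos_edges = [e for e in network.edges if e.sign in (SIGN_ACTIVATION, SIGN_DUAL)]

    def sub(edges: list[RegulatoryEdge]) -> RegulatoryNetwork:
        names = {e.regulator for e in edges} | {e.target_gene for e in edges}
        return RegulatoryNetwork(
            nodes={n: dict(network.nodes[n]) for n in names if n in network.nodes},
            edges=edges,
            flagged_edges=[e for e in edges if e in network.flagged_edges],
        )

    return sub(neg_edges), sub(pos_edges)


def degree_summary(
    network: RegulatoryNetwork, gene_list: Sequence[str] | None = None
) -> DegreeSummary:
    """Count TFs by number of distinct screened-gene targets.

    Only first-level edges count toward target degree; sign variants of
    the same (TF, gene) pair count the gene once. ``gene_list`` sets
    ``n_genes_input``; by default it is the covered gene set itself.
    """
    pairs = {
        (e.regulator, e.target_gene)
        for e in network.edges
        if e.level == LEVEL_GENE and e not in network.flagged_edges
    }
    by_tf: dict[str, set[str]] = {}
    for reg, gene in pairs:
        by_tf.setdefault(reg, set()).add(gene)
    covered = {g for _, g in pairs}
    n_input = len({g.lower() for g in gene_list}) if gene_list is not None else len(covered)
    multi = sum(1 for targets in by_tf.values() if len(targets) >= 2)
    return DegreeSummary(
        n_tfs=len(by_tf),
        n_genes_covered=len(covered),
        n_genes_input=n_input,
        tfs_with_multi_targets=multi,
        tfs_with_single_target=len(by_tf) - multi,
    )


def export_network(network: RegulatoryNetwork, path: str | Path, fmt: str) -> Path:
    """Write the network as ``graphml``, ``json`` (node-link), or ``edge_csv``."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(network.to_networkx(), path)
    elif fmt == "json":
        data = nx.node_link_data(network.to_networkx(), edges="edges")
        path.write_text(json.dumps(data, indent=2))
    elif fmt == "edge_csv":
        df = pd.DataFrame(
            [
                {
                    "target_gene": e.target_gene,
                    "regulator": e.regulator,
                    "sign": e.sign,
                    "level": e.level,
                }
                for e in network.edges
            ]
        )
        df.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown export format {fmt!r}")
    return path


def import_network_json(path: str | Path) -> RegulatoryNetwork:
    """Read back a node-link JSON export."""
    data = json.loads(Path(path).read_text())
    g = nx.node_link_graph(data, directed=True, edges="edges")
    edges = [
        RegulatoryEdge(t, s, attrs["sign"], attrs["level"])
        for s, t, attrs in g.edges(data=True)
    ]
    flagged = [
        RegulatoryEdge(t, s, attrs["sign"], attrs["level"])
        for s, t, attrs in g.edges(data=True)
        if attrs.get("flagged")
    ]
    nodes = {n: {"kind": a.get("kind"), "role": a.get("role")} for n, a in g.nodes(data=True)}
    return RegulatoryNetwork(nodes=nodes, edges=edges, flagged_edges=flagged)
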