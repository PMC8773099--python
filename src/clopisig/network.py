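"""Protein-interaction subnetwork around a set of signature genes.

From a user-supplied symbol-pair edge list (BioGRID TAB3-style columns), the
subnetwork keeps every signature gene plus any "bridge" protein lying on a
path of length at most ``max_path_length`` (default 2, i.e. a shared direct
interactor) between two distinct signature genes, together with all edges
induced among the kept nodes.  Signature genes absent from the edge list are
retained as isolated nodes with a warning.

Gene-symbol matching is case-insensitive and an alias table can merge
synonymous symbols before matching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

#: Published synonyms folded onto a canonical symbol before matching.
DEFAULT_ALIASES: dict[str, str] = {"LRBA1": "LRBA"}


@dataclass
class PPIGraph:
    """Induced subnetwork; node roles are 'signature' or 'bridge'."""

    graph: nx.Graph
    signature: list[str] = field(default_factory=list)
    bridges: list[str] = field(default_factory=list)

    @property
    def components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.graph)]

    def to_edge_tsv(self, path: str | Path) -> None:
        rows = sorted(tuple(sorted(e)) for e in self.graph.edges)
        pd.DataFrame(rows, columns=["symbol_a", "symbol_b"]).to_csv(
            path, sep="\t", index=False
        )

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, str(path))


def _canonical(symbol: str, aliases: Mapping[str, str]) -> str:
    s = str(symbol).upper()
    return aliases.get(s, s)


def build_subnetwork(
    edge_list: Iterable[tuple[str, str]],
    signature_genes: Sequence[str],
    max_path_length: int = 2,
    aliases: Mapping[str, str] | None = None,
) -> PPIGraph:
    """Signature genes plus bridge proteins on short signature-signature paths.

    A non-signature node v is kept iff dist(s1, v) + dist(v, s2) is at most
    ``max_path_length`` for two distinct signature genes s1, s2 (distances
    in the full interaction graph).  Self-loops and duplicate edges are
    ignored; edges are undirected.
    """
    if not signature_genes:
        raise ValueError("signature gene set must be non-empty")
    if max_path_length < 1:
        raise ValueError("max_path_length must be >= 1")
    aliases = {**DEFAULT_ALIASES, **(dict(aliases) if aliases else {})}

    full = nx.Graph()
    for a, b in edge_list:
        a, b = _canonical(a, aliases), _canonical(b, aliases)
        if a != b:
            full.add_edge(a, b)

    sig = sorted({_canonical(s, aliases) for s in signature_genes})
    absent = [s for s in sig if s not in full]
    if absent:
        warnings.warn(
            f"signature gene(s) absent from edge list, kept isolated: {absent}",
            stacklevel=2,
        )

    # depth-limited BFS distances from each present signature gene
    dists = {
        s: nx.single_source_shortest_path_length(full, s, cutoff=max_path_length - 1)
        for s in sig
        if s in full
    }
    bridges: set[str] = set()
    for v in full.nodes:
        if v in sig:
            continue
        dv = sorted(d[v] for d in dists.values() if v in d)
        if len(dv) >= 2 and dv[0] + dv[1] <= max_path_length:
            bridges.add(v)

    nodes = set(sig) | bridges
    sub = nx.Graph()
    sub.add_nodes_from(nodes)
    sub.add_edges_from(
        (u, v) for u, v in full.edges(nodes) if u in nodes and v in nodes
    )
    for v in sub.nodes:
        sub.nodes[v]["role"] = "signature" if v in sig else "bridge"
    return PPIGraph(graph=sub, signature=sig, bridges=sorted(bridges))


def component_summary(graph: PPIGraph) -> pd.DataFrame:
    """Connected components, largest first, ties by lexically smallest member."""
    comps = sorted(
        (sorted(c) for c in graph.components),
        key=lambda c: (-len(c), c[0]),
    )
    rows = [
        {
            "component": i + 1,
            "size": len(c),
            "n_signature": sum(graph.graph.nodes[v]["role"] == "signature" for v in c),
            "members": ",".join(c),
        }
        for i, c in enumerate(comps)
    ]
    return pd.DataFrame(rows, columns=["component", "size", "n_signature", "members"])


def load_example_edges() -> list[tuple[str, str]]:
    """Packaged synthetic interaction edge list.

    A small, hand-constructed stand-in for a BioGRID export: it connects
    the signature genes IQSEC1, PSD3, BTBD7, GLIS3 and LRBA through a few
    bridge proteins, plus unrelated decoy edges.  It is synthetic fixture
    data, not curated interaction evidence.
    """
    from .io import read_edge_list

    with resources.as_file(
        resources.files("clopisig.data") / "synthetic_ppi_edges.tsv"
    ) as p:
        return read_edge_list(p)
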