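"""Pathway-gene network export and run-level reports.

Significant enrichment terms and their overlap genes form a bipartite
graph: term nodes sized by degree (= overlap count), gene nodes
annotated with their regulation direction.  The graph is serialized as
GraphML plus a plain edge-list TSV; a JSON manifest records versions,
seed, configuration hash and the counts at every pipeline stage.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .enrichment import EnrichmentRow, enrichment_frame
from .io import DataError

__all__ = ["BipartiteNetwork", "build_network", "write_network", "write_manifest"]


@dataclass
class BipartiteNetwork:
    """Term-gene bipartite graph with summary counts."""

    graph: nx.Graph
    n_terms: int
    n_genes: int
    n_edges: int
    n_components: int

    @property
    def term_degrees(self) -> dict[str, int]:
        return {
            n: d for n, d in self.graph.degree()
            if self.graph.nodes[n]["kind"] == "term"
        }


def build_network(
    rows: list[EnrichmentRow],
    regulation: dict[str, str] | None = None,
) -> BipartiteNetwork:
    """Connect enrichment terms through their overlap genes.

    Every edge joins one term node and one gene node; a term's degree
    therefore equals its overlap count k.  Gene nodes carry an up/down
    direction when a regulation map is given.
    """
    g = nx.Graph()
    if not rows:
        warnings.warn("no enrichment rows: empty network")
        return BipartiteNetwork(g, 0, 0, 0, 0)
    regulation = regulation or {}
    for row in rows:
        g.add_node(
            f"term:{row.term_id}", kind="term", label=row.term_name,
            category=row.category, adj_p=float(row.adj_p),
        )
        for gene in sorted(row.overlap_genes):
            node = f"gene:{gene}"
            if node not in g:
                g.add_node(node, kind="gene", label=gene,
                           direction=regulation.get(gene, "unknown"))
            g.add_edge(f"term:{row.term_id}", node)
    n_terms = sum(1 for _, d in g.nodes(data=True) if d["kind"] == "term")
    n_genes = g.number_of_nodes() - n_terms
    return BipartiteNetwork(
        graph=g,
        n_terms=n_terms,
        n_genes=n_genes,
        n_edges=g.number_of_edges(),
        n_components=nx.number_connected_components(g),
    )


def write_network(net: BipartiteNetwork, out_dir: str | Path, stem: str) -> list[str]:
    """Write GraphML and an edge-list TSV; returns the file names."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    graphml = out_dir / f"{stem}.graphml"
    nx.write_graphml(net.graph, graphml)
    edges = [
        (u.split(":", 1)[1], v.split(":", 1)[1])
        if net.graph.nodes[u]["kind"] == "term" else (v.split(":", 1)[1], u.split(":", 1)[1])
        for u, v in sorted(net.graph.edges())
    ]
    tsv = out_dir / f"{stem}_edges.tsv"
    pd.DataFrame(edges, columns=["term_id", "gene_id"]).to_csv(
        tsv, sep="\t", index=False
    )
    return [graphml.name, tsv.name]


def write_enrichment_table(
    rows: list[EnrichmentRow], out_dir: str | Path, stem: str
) -> str:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{stem}.tsv"
    enrichment_frame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path.name


def _jsonify(obj):
    """JSON encoder fallback for numpy scalars."""
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_manifest(manifest: dict, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "manifest.json"
        with open(path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=_jsonify)
    except OSError as exc:
        raise DataError(f"cannot write manifest under {out_dir}: {exc}") from exc
    return path
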