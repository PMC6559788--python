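"""Property graph of compounds, enzymes and uses, with query patterns.

Node labels: ``Compound``, ``Enzyme``, ``Use``. Relationship types:

* ``SUBSTRUCTURE_SIMILARITY`` (Compound–Compound; score, zscore,
  significant, community_id) — stored once, canonical min-id → max-id,
  queried as undirected;
* ``TOXICITY_SIMILARITY`` (Compound–Compound; raw and normalised score);
* ``HAS_USE`` (Compound → Use);
* ``METABOLIZED_BY`` (Compound → Enzyme; the enzyme node carries its
  taxonomic-dominance score ``ecsd`` when available).

Exports: GraphML (portable, typed attributes) and a bulk-import CSV
dialect following the Neo4j importer header conventions (``id:ID``,
``:LABEL``, ``:START_ID``, ``:END_ID``, ``:TYPE``, ``prop:type``).
Queries return deterministic orderings: score descending, id ascending.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .network import SimilarityNetwork
from .toxicity import ToxicityEdge

logger = logging.getLogger(__name__)

NODE_LABELS = ("Compound", "Enzyme", "Use")
REL_TYPES = (
    "SUBSTRUCTURE_SIMILARITY",
    "TOXICITY_SIMILARITY",
    "HAS_USE",
    "METABOLIZED_BY",
)


@dataclass
class PropertyGraph:
    nodes: dict[str, tuple[str, dict]] = field(default_factory=dict)
    relationships: dict[tuple[str, str, str], dict] = field(default_factory=dict)
    skipped: dict[str, int] = field(default_factory=dict)

    def add_node(self, node_id: str, label: str, **props) -> None:
        if label not in NODE_LABELS:
            raise ValueError(f"unknown node label {label!r}")
        self.nodes[node_id] = (label, {k: v for k, v in props.items() if v is not None})

    def add_relationship(
        self, start: str, end: str, rel_type: str, **props
    ) -> bool:
        """Add one (start, end, type) relationship; duplicate triples and
        dangling endpoints are skipped with a tally."""
        if rel_type not in REL_TYPES:
            raise ValueError(f"unknown relationship type {rel_type!r}")
        if start not in self.nodes or end not in self.nodes:
            self.skipped[rel_type] = self.skipped.get(rel_type, 0) + 1
            return False
        key = (start, end, rel_type)
        if key in self.relationships:
            return False
        self.relationships[key] = {
            k: v for k, v in props.items() if v is not None
        }
        return True

    def label_counts(self) -> dict[str, int]:
        counts = {label: 0 for label in NODE_LABELS}
        for label, _ in self.nodes.values():
            counts[label] += 1
        return counts

    def neighbors(self, node_id: str, rel_type: str):
        """(other, props) over relationships of one type touching a node;
        similarity/toxicity types are treated as undirected."""
        undirected = rel_type in ("SUBSTRUCTURE_SIMILARITY", "TOXICITY_SIMILARITY")
        for (start, end, rtype), props in self.relationships.items():
            if rtype != rel_type:
                continue
            if start == node_id:
                yield end, props
            elif undirected and end == node_id:
                yield start, props


def assemble_graph(
    net: SimilarityNetwork,
    tox_edges: Mapping[tuple[str, str], ToxicityEdge] | None = None,
    enzyme_map: set[tuple[str, str]] | None = None,
    uses: Mapping[str, Sequence[str]] | None = None,
    ecsd_scores: Mapping[str, float] | None = None,
    categories: Mapping[str, str] | None = None,
    superclasses: Mapping[str, str] | None = None,
) -> PropertyGraph:
    """Assemble the full property graph from the pipeline's outputs.

    One Compound node per network node, one Enzyme node per EC in the
    map (with ``ecsd`` attached when scored), one Use node per distinct
    use label. References to unknown compounds are logged, skipped and
    tallied in ``graph.skipped``.
    """
    graph = PropertyGraph()
    membership = net.membership
    for node in sorted(net.nodes):
        attrs = net.node_attrs.get(node, {})
        graph.add_node(
            node,
            "Compound",
            category=(categories or {}).get(node, attrs.get("category")),
            superclass=(superclasses or {}).get(node, attrs.get("superclass")),
            community_id=membership.get(node),
        )
    ecsd_scores = ecsd_scores or {}
    for ec in sorted({ec for ec, _ in (enzyme_map or set())}):
        graph.add_node(f"EC:{ec}", "Enzyme", ec_number=ec, ecsd=ecsd_scores.get(ec))
    for label in sorted({u for us in (uses or {}).values() for u in us}):
        graph.add_node(f"USE:{label}", "Use", use_label=label)

    for pair, edge in sorted(net.edges.items()):
        graph.add_relationship(
            pair[0],
            pair[1],
            "SUBSTRUCTURE_SIMILARITY",
            score=edge.score,
            zscore=edge.zscore,
            significant=bool(edge.significant),
            community_id=edge.community_id,
        )
    for pair, tox in sorted((tox_edges or {}).items()):
        graph.add_relationship(
            pair[0],
            pair[1],
            "TOXICITY_SIMILARITY",
            score=tox.normalized_score,
            raw_score=tox.raw_score,
        )
    for ec, cid in sorted(enzyme_map or set()):
        graph.add_relationship(cid, f"EC:{ec}", "METABOLIZED_BY")
    for cid, labels in sorted((uses or {}).items()):
        for label in sorted(set(labels)):
            graph.add_relationship(cid, f"USE:{label}", "HAS_USE")
    for rel_type, n in graph.skipped.items():
        logger.warning("skipped %d %s rows with dangling references", n, rel_type)
    return graph


def _ordered(results: list[tuple[str, float]]) -> list[tuple[str, float]]:
    return sorted(results, key=lambda item: (-item[1], item[0]))


def significant_neighbors(
    graph: PropertyGraph, compound_id: str
) -> list[tuple[str, float]]:
    """Compounds linked by a significant substructure edge, best first."""
    if compound_id not in graph.nodes:
        raise KeyError(f"unknown compound {compound_id!r}")
    hits = [
        (other, float(props["score"]))
        for other, props in graph.neighbors(compound_id, "SUBSTRUCTURE_SIMILARITY")
        if props.get("significant")
    ]
    return _ordered(hits)


def dual_neighbors(
    graph: PropertyGraph,
    compound_id: str,
    min_struct: float = 0.0,
    min_tox: float = 0.0,
) -> list[tuple[str, float, float]]:
    """Compounds with BOTH a significant substructure edge (score >=
    min_struct) AND a toxicity edge (normalised score >= min_tox);
    ordered by substructure score descending then id."""
    struct = {
        cid: score
        for cid, score in significant_neighbors(graph, compound_id)
        if score >= min_struct
    }
    tox = {
        other: float(props["score"])
        for other, props in graph.neighbors(compound_id, "TOXICITY_SIMILARITY")
        if float(props["score"]) >= min_tox
    }
    hits = [
        (cid, struct[cid], tox[cid]) for cid in struct.keys() & tox.keys()
    ]
    return sorted(hits, key=lambda item: (-item[1], item[0]))


def substrate_pool_scan(
    graph: PropertyGraph, ec_number: str, seed_compound: str
) -> list[dict]:
    """Scan the seed's community for alternative substrates of an enzyme.

    Returns the compounds in the seed compound's chemical-similarity
    community that share a significant similarity edge with the seed,
    each annotated with whether it is already a known substrate of the
    EC (``metabolized_by_ec``) and its category — candidate competing
    substrates when the flag is false.
    """
    enzyme_node = f"EC:{ec_number}"
    if enzyme_node not in graph.nodes:
        raise KeyError(f"unknown enzyme {ec_number!r}")
    if seed_compound not in graph.nodes:
        raise KeyError(f"unknown compound {seed_compound!r}")
    seed_comm = graph.nodes[seed_compound][1].get("community_id")
    substrates = {
        start
        for (start, end, rtype) in graph.relationships
        if rtype == "METABOLIZED_BY" and end == enzyme_node
    }
    rows = []
    for other, score in significant_neighbors(graph, seed_compound):
        props = graph.nodes[other][1]
        if seed_comm is None or props.get("community_id") != seed_comm:
            continue
        rows.append(
            {
                "compound_id": other,
                "score": score,
                "metabolized_by_ec": other in substrates,
                "category": props.get("category"),
            }
        )
    return sorted(rows, key=lambda r: (-r["score"], r["compound_id"]))


# --- export / import ---------------------------------------------------

_CSV_TYPES = {bool: "boolean", int: "int", float: "float", str: "string"}


def export_graph(graph: PropertyGraph, path, fmt: str = "graphml") -> list[Path]:
    """Write the graph as GraphML (single file) or bulk-import CSV
    (nodes.csv + relationships.csv). Returns the written paths."""
    path = Path(path)
    if fmt == "graphml":
        g = nx.MultiDiGraph()
        for node_id, (label, props) in graph.nodes.items():
            g.add_node(node_id, label=label, **props)
        for (start, end, rtype), props in graph.relationships.items():
            g.add_edge(start, end, key=rtype, type=rtype, **props)
        path.parent.mkdir(parents=True, exist_ok=True)
        nx.write_graphml(g, path)
        return [path]
    if fmt == "csv":
        path.mkdir(parents=True, exist_ok=True)
        nodes_path = path / "nodes.csv"
        rels_path = path / "relationships.csv"
        _write_csv(
            nodes_path,
            ["id:ID", ":LABEL"],
            [
                (dict(props), [node_id, label])
                for node_id, (label, props) in sorted(graph.nodes.items())
            ],
        )
        _write_csv(
            rels_path,
            [":START_ID", ":END_ID", ":TYPE"],
            [
                (dict(props), [start, end, rtype])
                for (start, end, rtype), props in sorted(graph.relationships.items())
            ],
        )
        return [nodes_path, rels_path]
    raise ValueError(f"unknown export format {fmt!r}")


def _write_csv(path: Path, fixed_headers: list[str], rows) -> None:
    prop_types: dict[str, str] = {}
    for props, _ in rows:
        for key, value in props.items():
            prop_types.setdefault(key, _CSV_TYPES[type(value)])
    prop_cols = sorted(prop_types)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            fixed_headers + [f"{c}:{prop_types[c]}" for c in prop_cols]
        )
        for props, fixed in rows:
            writer.writerow(
                fixed
                + [
                    "" if c not in props else _csv_value(props[c])
                    for c in prop_cols
                ]
            )


def _csv_value(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    return repr(value) if isinstance(value, float) else str(value)


_CSV_PARSERS = {
    "boolean": lambda s: s == "true",
    "int": int,
    "float": float,
    "string": str,
}


def import_graph(path, fmt: str = "graphml") -> PropertyGraph:
    """Inverse of :func:`export_graph`; round trips preserve nodes,
    relationships and property values."""
    path = Path(path)
    graph = PropertyGraph()
    if fmt == "graphml":
        g = nx.read_graphml(path, force_multigraph=True)
        for node_id, attrs in g.nodes(data=True):
            attrs = dict(attrs)
            label = attrs.pop("label")
            graph.add_node(node_id, label, **attrs)
        for start, end, _key, attrs in g.edges(keys=True, data=True):
            attrs = dict(attrs)
            rtype = attrs.pop("type")
            graph.add_relationship(start, end, rtype, **attrs)
        return graph
    if fmt == "csv":
        for row in _read_csv(path / "nodes.csv"):
            graph.add_node(row.pop("id:ID"), row.pop(":LABEL"), **row)
        for row in _read_csv(path / "relationships.csv"):
            graph.add_relationship(
                row.pop(":START_ID"), row.pop(":END_ID"), row.pop(":TYPE"), **row
            )
        return graph
    raise ValueError(f"unknown import format {fmt!r}")


def _read_csv(path: Path) -> list[dict]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        rows = []
        for record in reader:
            row: dict = {}
            for col, raw in zip(header, record):
                if ":" in col and not col.startswith(":"):
                    name, typ = col.rsplit(":", 1)
                    if typ == "ID":
                        row[col] = raw
                        continue
                    if raw == "":
                        continue
                    row[name] = _CSV_PARSERS[typ](raw)
                else:
                    row[col] = raw
            rows.append(row)
    return rows


def write_node_summary(graph: PropertyGraph, path) -> None:
    counts = graph.label_counts()
    rel_counts: dict[str, int] = {t: 0 for t in REL_TYPES}
    for (_, _, rtype) in graph.relationships:
        rel_counts[rtype] += 1
    df = pd.DataFrame(
        [
            {"entity": k, "count": v}
            for k, v in list(counts.items()) + list(rel_counts.items())
        ]
    )
    df.to_csv(path, sep="\t", index=False)
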