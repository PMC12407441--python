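"""Readers and writers for the formats shared across pipeline stages.

TSV feature tables (samples in rows, ``NA`` missing marker), 3-column
interactome edge lists, GMT gene-set files, seed-map TSVs, and network
collections as XGMML (the distribution format for the published network
collections), GraphML, or plain edge-list TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from lxml import etree

from .assoc_map import AssociationTable, SeedMap
from .enrich import GeneSetCollection
from .omics_qc import AsvTable, MetaboliteTable
from .pulldown import Interactome, NetworkModule

__all__ = [
    "read_interactome_tsv", "write_interactome_tsv",
    "read_feature_table", "write_feature_table",
    "read_metabolite_table", "read_asv_table",
    "read_gmt", "write_gmt",
    "read_association_table", "write_association_table",
    "read_seed_map", "write_seed_map",
    "write_xgmml", "read_xgmml", "write_graphml", "write_module_edgelist",
    "write_json", "read_json",
]

NA = "NA"


# -- interactome ------------------------------------------------------------

def read_interactome_tsv(path: str | Path) -> Interactome:
    df = pd.read_csv(path, sep="\t", dtype={"protein_a": str, "protein_b": str})
    return Interactome.from_edges(
        list(df[["protein_a", "protein_b", "confidence"]].itertuples(index=False, name=None))
    )


def write_interactome_tsv(g: Interactome, path: str | Path) -> None:
    rows = sorted(
        (min(u, v), max(u, v), c) for u, v, c in g.graph.edges(data="confidence")
    )
    pd.DataFrame(rows, columns=["protein_a", "protein_b", "confidence"]).to_csv(
        path, sep="\t", index=False
    )


# -- feature tables ---------------------------------------------------------

def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", na_rep=NA, index_label="sample_id")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id", na_values=[NA])


def read_metabolite_table(
    path: str | Path, block_label: str = "plasma",
    metadata_path: str | Path | None = None,
) -> MetaboliteTable:
    meta = None
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t", index_col="sample_id")
    return MetaboliteTable(
        values=read_feature_table(path), block_label=block_label, sample_metadata=meta
    )


def read_asv_table(path: str | Path) -> AsvTable:
    return AsvTable(counts=read_feature_table(path).astype(np.int64))


# -- gene sets --------------------------------------------------------------

def read_gmt(path: str | Path, default_class: str = "ad") -> GeneSetCollection:
    """Read GMT; the description field carries the class label when set."""
    sets, labels = {}, {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        name, desc, *genes = line.rstrip("\n").split("\t")
        sets[name] = frozenset(g for g in genes if g)
        labels[name] = desc or default_class
    return GeneSetCollection(sets=sets, class_labels=labels)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, collection.class_labels[name], *sorted(collection.sets[name])])
        for name in sorted(collection.sets)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# -- associations and seed maps ---------------------------------------------

def read_association_table(path: str | Path) -> AssociationTable:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return AssociationTable.from_frame(df)


def write_association_table(table: AssociationTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_seed_map(path: str | Path) -> SeedMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    mapping: dict[str, set[str]] = {}
    for r in df.itertuples(index=False):
        mapping.setdefault(r.metabolite_id, set()).add(r.protein_id)
    return SeedMap({m: frozenset(ps) for m, ps in mapping.items()})


def write_seed_map(seed_map: SeedMap, path: str | Path) -> None:
    seed_map.to_frame().to_csv(path, sep="\t", index=False)


# -- network collections ----------------------------------------------------

def write_xgmml(modules: list[NetworkModule], g: Interactome, path: str | Path) -> None:
    """One XGMML document per collection, one <graph> element per network."""
    ns = "http://www.cs.rpi.edu/XGMML"
    root = etree.Element("collection")
    for m in sorted(modules, key=lambda x: x.network_id):
        graph = etree.SubElement(
            root, f"{{{ns}}}graph", label=m.network_id, directed="0",
            nsmap={None: ns},
        )
        meta = etree.SubElement(graph, f"{{{ns}}}att", name="linked_metabolites")
        meta.set("value", ";".join(sorted(m.linked_metabolites)))
        meta.set("type", "string")
        exempt = etree.SubElement(graph, f"{{{ns}}}att", name="cap_exempt")
        exempt.set("value", str(int(m.cap_exempt)))
        exempt.set("type", "integer")
        for node in sorted(m.nodes):
            el = etree.SubElement(graph, f"{{{ns}}}node", id=node, label=node)
            att = etree.SubElement(el, f"{{{ns}}}att", name="seed")
            att.set("value", str(int(node in m.seed_proteins)))
            att.set("type", "integer")
        for edge in sorted(tuple(sorted(e)) for e in m.edges):
            u, v = edge
            el = etree.SubElement(graph, f"{{{ns}}}edge", source=u, target=v)
            att = etree.SubElement(el, f"{{{ns}}}att", name="confidence")
            att.set("value", repr(g.graph.edges[u, v]["confidence"]))
            att.set("type", "real")
    Path(path).write_bytes(
        etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")
    )


def read_xgmml(path: str | Path) -> list[NetworkModule]:
    ns = {"x": "http://www.cs.rpi.edu/XGMML"}
    root = etree.parse(str(path)).getroot()
    modules = []
    for graph in root.findall("x:graph", ns):
        nodes, seeds = set(), set()
        for node in graph.findall("x:node", ns):
            nid = node.get("id")
            nodes.add(nid)
            att = node.find("x:att[@name='seed']", ns)
            if att is not None and att.get("value") == "1":
                seeds.add(nid)
        edges = frozenset(
            frozenset((e.get("source"), e.get("target")))
            for e in graph.findall("x:edge", ns)
        )
        met_att = graph.find("x:att[@name='linked_metabolites']", ns)
        mets = frozenset(
            m for m in (met_att.get("value") or "").split(";") if m
        ) if met_att is not None else frozenset()
        exempt_att = graph.find("x:att[@name='cap_exempt']", ns)
        modules.append(
            NetworkModule(
                network_id=graph.get("label"),
                nodes=frozenset(nodes),
                edges=edges,
                seed_proteins=frozenset(seeds),
                linked_metabolites=mets,
                cap_exempt=bool(int(exempt_att.get("value"))) if exempt_att is not None else False,
            )
        )
    return modules


def write_graphml(modules: list[NetworkModule], g: Interactome, path: str | Path) -> None:
    out = nx.Graph()
    for m in modules:
        for node in m.nodes:
            out.add_node(
                f"{m.network_id}::{node}",
                protein=node, network=m.network_id,
                seed=int(node in m.seed_proteins),
            )
        for e in m.edges:
            u, v = sorted(e)
            out.add_edge(
                f"{m.network_id}::{u}", f"{m.network_id}::{v}",
                confidence=g.graph.edges[u, v]["confidence"],
            )
    nx.write_graphml(out, str(path))


def write_module_edgelist(modules: list[NetworkModule], g: Interactome, path: str | Path) -> None:
    rows = [
        (m.network_id, *sorted(e), g.graph.edges[tuple(e)]["confidence"])
        for m in sorted(modules, key=lambda x: x.network_id)
        for e in sorted(tuple(sorted(x)) for x in m.edges)
    ]
    pd.DataFrame(
        rows, columns=["network_id", "protein_a", "protein_b", "confidence"]
    ).to_csv(path, sep="\t", index=False)


# -- json helpers -----------------------------------------------------------

def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
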