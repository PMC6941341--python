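"""XGMML network export/import and display filtering.

rGNNs are serialized as XGMML 1.0 documents loadable by Cytoscape:
rep_nodes carry their member count, pf_nodes their SeqCount, coverage
and frequency. Node size encodes member count / frequency for display.
Element order is deterministic so identical networks produce identical
files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from lxml import etree

from .exceptions import FormatError
from .gnn import RGNN

XGMML_NS = "http://www.cs.rpi.edu/XGMML"


@dataclass
class NetworkNode:
    id: str
    kind: str  # rep_node | pf_node
    size: float
    labels: dict[str, object] = field(default_factory=dict)


@dataclass
class NetworkEdge:
    source: str
    target: str
    weight: float


@dataclass
class NetworkDocument:
    label: str
    nodes: list[NetworkNode] = field(default_factory=list)
    edges: list[NetworkEdge] = field(default_factory=list)
    metadata: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate node ids in network document")
        known = set(ids)
        for e in self.edges:
            if e.source not in known or e.target not in known:
                raise ValueError(f"edge endpoint missing from nodes: {e.source}->{e.target}")


def rgnn_to_document(rgnn: RGNN) -> NetworkDocument:
    """Convert an rGNN into its exportable network form."""
    doc = NetworkDocument(
        label=f"rGNN {rgnn.query_family_id}",
        metadata={
            "query_family_id": rgnn.query_family_id,
            "n_neighborhoods": rgnn.n_neighborhoods,
            "n_phyla": rgnn.n_phyla,
        },
    )
    for rep in rgnn.rep_nodes:
        doc.nodes.append(
            NetworkNode(
                id=f"rep:{rep.rep_id}",
                kind="rep_node",
                size=float(len(rep.member_ids)),
                labels={"member_count": len(rep.member_ids), "representative": rep.representative_id},
            )
        )
    for p in rgnn.pf_nodes:
        doc.nodes.append(
            NetworkNode(
                id=f"pf:{p.family_id}",
                kind="pf_node",
                size=p.frequency_f,
                labels={"SeqCount": p.seq_count, "coverage": p.coverage, "frequency": p.frequency_f},
            )
        )
    for rep_id, fam, cov in rgnn.edges:
        doc.edges.append(NetworkEdge(source=f"rep:{rep_id}", target=f"pf:{fam}", weight=cov))
    return doc


def filter_for_display(doc: NetworkDocument, min_sequences: int = 0) -> NetworkDocument:
    """Drop nodes representing <= ``min_sequences`` sequences (display only).

    Mirrors the usual complexity reduction for figures; never applied on
    the analysis path.
    """
    if min_sequences <= 0:
        return doc
    keep = {
        n.id
        for n in doc.nodes
        if (n.kind == "rep_node" and n.size > min_sequences)
        or (n.kind == "pf_node" and int(n.labels.get("SeqCount", 0)) > min_sequences)
    }
    return NetworkDocument(
        label=doc.label,
        nodes=[n for n in doc.nodes if n.id in keep],
        edges=[e for e in doc.edges if e.source in keep and e.target in keep],
        metadata=dict(doc.metadata),
    )


def _att_type(value: object) -> tuple[str, str]:
    if isinstance(value, bool):
        return "boolean", str(value).lower()
    if isinstance(value, int):
        return "integer", str(value)
    if isinstance(value, float):
        return "real", repr(value)
    return "string", str(value)


def _att_value(type_: str, raw: str) -> object:
    if type_ == "integer":
        return int(raw)
    if type_ == "real":
        return float(raw)
    if type_ == "boolean":
        return raw == "true"
    return raw


def write_xgmml(doc: NetworkDocument, path: str | Path) -> None:
    """Write a well-formed XGMML 1.0 file with deterministic element order."""
    root = etree.Element("graph", nsmap={None: XGMML_NS})
    root.set("label", doc.label)
    root.set("directed", "0")
    for key in sorted(doc.metadata):
        type_, value = _att_type(doc.metadata[key])
        etree.SubElement(root, "att", name=key, type=type_, value=value)
    for node in doc.nodes:
        el = etree.SubElement(root, "node", id=node.id, label=node.id)
        etree.SubElement(el, "att", name="kind", type="string", value=node.kind)
        etree.SubElement(el, "att", name="size", type="real", value=repr(float(node.size)))
        for key in sorted(node.labels):
            type_, value = _att_type(node.labels[key])
            etree.SubElement(el, "att", name=key, type=type_, value=value)
        etree.SubElement(el, "graphics", type="ellipse", w=repr(20.0 + 10.0 * float(node.size)))
    for edge in doc.edges:
        el = etree.SubElement(root, "edge", source=edge.source, target=edge.target)
        etree.SubElement(el, "att", name="weight", type="real", value=repr(float(edge.weight)))
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True)


def read_xgmml(path: str | Path) -> NetworkDocument:
    """Parse an XGMML file back into a :class:`NetworkDocument`.

    Unknown graph-level attributes are preserved in ``metadata``; a
    pf_node lacking a SeqCount attribute triggers a warning and is kept
    with SeqCount 0.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"{path}: not well-formed XGMML: {exc}") from exc
    root = tree.getroot()
    ns = {"x": XGMML_NS} if root.tag.startswith("{") else None
    prefix = "x:" if ns else ""
    doc = NetworkDocument(label=root.get("label", ""))
    for att in root.findall(f"{prefix}att", ns):
        doc.metadata[att.get("name")] = _att_value(att.get("type", "string"), att.get("value", ""))
    for el in root.findall(f"{prefix}node", ns):
        labels: dict[str, object] = {}
        kind = "pf_node"
        size = 0.0
        for att in el.findall(f"{prefix}att", ns):
            name = att.get("name")
            value = _att_value(att.get("type", "string"), att.get("value", ""))
            if name == "kind":
                kind = str(value)
            elif name == "size":
                size = float(value)
            else:
                labels[name] = value
        if kind == "pf_node" and "SeqCount" not in labels:
            warnings.warn(f"pf_node {el.get('id')!r} lacks a SeqCount attribute; set to 0")
            labels["SeqCount"] = 0
        doc.nodes.append(NetworkNode(id=el.get("id"), kind=kind, size=size, labels=labels))
    for el in root.findall(f"{prefix}edge", ns):
        weight = 0.0
        for att in el.findall(f"{prefix}att", ns):
            if att.get("name") == "weight":
                weight = float(_att_value(att.get("type", "real"), att.get("value", "0")))
        doc.edges.append(NetworkEdge(source=el.get("source"), target=el.get("target"), weight=weight))
    return NetworkDocument(label=doc.label, nodes=doc.nodes, edges=doc.edges, metadata=doc.metadata)


def write_roc_pr_tables(points, out_dir: str | Path, stem: str = "sweep") -> None:
    """Write ROC- and PR-ready TSVs from a threshold sweep."""
    from .evaluation import sweep_frame

    out_dir = Path(out_dir)
    frame = sweep_frame(points)
    frame.to_csv(out_dir / f"{stem}.tsv", sep="\t", index=False)
    frame[["f_min", "FPR", "TPR"]].to_csv(out_dir / f"{stem}_roc.tsv", sep="\t", index=False)
    frame[["f_min", "TPR", "Precision"]].rename(columns={"TPR": "Recall"}).to_csv(
        out_dir / f"{stem}_pr.tsv", sep="\t", index=False
    )


def plot_sweep(points, out_path: str | Path) -> None:
    """Plot MCC vs f_min plus ROC and PR curves to one PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .evaluation import sweep_frame

    frame = sweep_frame(points)
    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    axes[0].plot(frame["f_min"], frame["MCC"], marker=".")
    axes[0].set_xlabel("f_min")
    axes[0].set_ylabel("MCC")
    axes[1].plot(frame["FPR"], frame["TPR"], marker=".")
    axes[1].set_xlabel("FPR")
    axes[1].set_ylabel("TPR")
    axes[2].plot(frame["TPR"], frame["Precision"], marker=".")
    axes[2].set_xlabel("Recall")
    axes[2].set_ylabel("Precision")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
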