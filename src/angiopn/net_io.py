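"""Readers and writers for Petri nets and support matrices.

Supported net formats:

* ``spped`` (read-only) — the XML dialect of the Snoopy editor, restricted to
  places, transitions, edges, markings, and logical (shadow) places.  Logical
  copies of a place are graphical conveniences; all copies sharing a name are
  merged into a single net vertex, summing arc weights where the merge makes
  parallel arcs collide, so the incidence matrix is preserved.
* ``pnml`` — the basic ISO Place/Transition subset; unknown elements are
  ignored with a logged warning.
* ``json`` — the native dialect
  ``{"places": [[id, name], ...], "transitions": [...], "arcs": [[src, dst, w], ...], "marking": {...}}``.
* ``incidence-csv`` — the incidence matrix with a ``place`` label column and
  one column per transition.  Reading reconstructs one arc per nonzero entry
  (sign gives direction, magnitude the weight); that encoding cannot express
  read arcs, so files written from non-pure nets are flagged and refused on
  read.

Support matrices travel as plain CSV: one invariant per row, first column the
invariant label, header of transition labels, binary cells.
"""

from __future__ import annotations

import csv
import json
import logging
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .core_net import NetValidationError, PetriNet, build_incidence_matrix, structural_report
from .invariants import SupportMatrix

__all__ = [
    "read_net",
    "write_net",
    "read_support_csv",
    "write_support_csv",
    "NET_FORMATS",
]

log = logging.getLogger(__name__)

NET_FORMATS = ("spped", "pnml", "json", "incidence-csv")

_EXT_TO_FORMAT = {
    ".spped": "spped",
    ".pnml": "pnml",
    ".xml": "pnml",
    ".json": "json",
    ".csv": "incidence-csv",
}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in NET_FORMATS:
            raise ValueError(f"unknown format {fmt!r}; choose from {NET_FORMATS}")
        return fmt
    try:
        return _EXT_TO_FORMAT[path.suffix.lower()]
    except KeyError:
        raise ValueError(f"cannot infer net format from suffix {path.suffix!r}")


def read_net(path: str | Path, format: str | None = None) -> PetriNet:
    """Parse a Petri net; ``format`` is inferred from the suffix when omitted."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "spped":
        return _read_spped(path)
    if fmt == "pnml":
        return _read_pnml(path)
    if fmt == "json":
        return _read_json(path)
    return _read_incidence_csv(path)


def write_net(net: PetriNet, path: str | Path, format: str | None = None) -> None:
    """Serialize ``net``; output is byte-stable for a fixed net.

    Writing SPPED is unsupported (read-only subset).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "spped":
        raise ValueError("writing the Snoopy dialect is not supported")
    if fmt == "pnml":
        _write_pnml(net, path)
    elif fmt == "json":
        _write_json(net, path)
    else:
        _write_incidence_csv(net, path)


# ---------------------------------------------------------------------------
# native JSON
# ---------------------------------------------------------------------------

def _read_json(path: Path) -> PetriNet:
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise NetValidationError(f"{path}: unparseable JSON at line {exc.lineno}") from exc
    try:
        marking = {str(k): int(v) for k, v in payload.get("marking", {}).items()}
        return PetriNet(
            payload["places"], payload["transitions"], payload["arcs"], marking
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise NetValidationError(f"{path}: malformed net JSON: {exc}") from exc


def _write_json(net: PetriNet, path: Path) -> None:
    payload = {
        "places": [[pid, name] for pid, name in net.places],
        "transitions": [[tid, name] for tid, name in net.transitions],
        "arcs": [[s, d, w] for (s, d), w in sorted(net.arcs.items())],
        "marking": {
            p: int(v) for p, v in sorted(net.initial_marking.items()) if v
        },
    }
    path.write_text(json.dumps(payload, indent=1) + "\n")


# ---------------------------------------------------------------------------
# PNML (basic Place/Transition subset)
# ---------------------------------------------------------------------------

def _strip_ns(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]

_PNML_KNOWN = {
    "pnml", "net", "page", "place", "transition", "arc", "name", "text",
    "initialMarking", "inscription", "graphics", "position", "offset",
    "dimension", "toolspecific",
}


def _read_pnml(path: Path) -> PetriNet:
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise NetValidationError(f"{path}: unparseable XML: {exc}") from exc

    def sub_text(el: ET.Element, tag: str) -> str | None:
        for child in el.iter():
            if _strip_ns(child.tag) == tag:
                text_el = next(
                    (c for c in child if _strip_ns(c.tag) == "text"), None
                )
                if text_el is not None and text_el.text:
                    return text_el.text.strip()
        return None

    places, transitions, arcs, marking = [], [], [], {}
    for el in root.iter():
        tag = _strip_ns(el.tag)
        if tag not in _PNML_KNOWN:
            log.warning("ignoring unknown PNML element <%s> in %s", tag, path)
        if tag == "place":
            pid = el.attrib["id"]
            places.append((pid, sub_text(el, "name") or pid))
            tokens = sub_text(el, "initialMarking")
            if tokens is not None and int(tokens):
                marking[pid] = int(tokens)
        elif tag == "transition":
            tid = el.attrib["id"]
            transitions.append((tid, sub_text(el, "name") or tid))
        elif tag == "arc":
            w = sub_text(el, "inscription")
            arcs.append(
                (el.attrib["source"], el.attrib["target"], int(w) if w else 1)
            )
    return PetriNet(places, transitions, arcs, marking)


def _write_pnml(net: PetriNet, path: Path) -> None:
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        '<pnml xmlns="http://www.pnml.org/version-2009/grammar/pnml">',
        '  <net id="net0" type="http://www.pnml.org/version-2009/grammar/ptnet">',
        "    <page id=\"page0\">",
    ]
    for pid, name in net.places:
        lines.append(f'      <place id="{pid}">')
        lines.append(f"        <name><text>{name}</text></name>")
        tokens = net.initial_marking.get(pid, 0)
        if tokens:
            lines.append(
                f"        <initialMarking><text>{tokens}</text></initialMarking>"
            )
        lines.append("      </place>")
    for tid, name in net.transitions:
        lines.append(f'      <transition id="{tid}">')
        lines.append(f"        <name><text>{name}</text></name>")
        lines.append("      </transition>")
    for i, ((src, dst), w) in enumerate(sorted(net.arcs.items())):
        lines.append(f'      <arc id="a{i}" source="{src}" target="{dst}">')
        if w != 1:
            lines.append(f"        <inscription><text>{w}</text></inscription>")
        lines.append("      </arc>")
    lines += ["    </page>", "  </net>", "</pnml>", ""]
    path.write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# Snoopy SPPED (read-only subset)
# ---------------------------------------------------------------------------

def _spped_attr(node: ET.Element, name: str) -> str | None:
    for attr in node.iter("attribute"):
        if attr.attrib.get("name") == name:
            # Snoopy nests the value as text, possibly inside CDATA
            text = "".join(attr.itertext()).strip()
            return text
    return None


def _read_spped(path: Path) -> PetriNet:
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise NetValidationError(f"{path}: unparseable XML: {exc}") from exc

    node_name: dict[str, str] = {}  # graphical node id -> canonical vertex id
    places: list[tuple[str, str]] = []
    transitions: list[tuple[str, str]] = []
    markings: dict[str, set[int]] = {}
    seen_vertices: set[str] = set()
    for nodeclass in root.iter("nodeclass"):
        kind = nodeclass.attrib.get("name", "")
        if kind not in ("Place", "Transition"):
            continue
        for node in nodeclass.iter("node"):
            gid = node.attrib["id"]
            name = _spped_attr(node, "Name") or gid
            node_name[gid] = name
            if kind == "Place":
                tokens = _spped_attr(node, "Marking")
                if tokens:
                    markings.setdefault(name, set()).add(int(float(tokens)))
                if name not in seen_vertices:
                    places.append((name, name))
            else:
                if name not in seen_vertices:
                    transitions.append((name, name))
            seen_vertices.add(name)
    marking: dict[str, int] = {}
    for name, values in markings.items():
        nonzero = {v for v in values if v}
        if len(nonzero) > 1:
            raise NetValidationError(
                f"logical place {name!r} has conflicting token counts {sorted(nonzero)}"
            )
        if nonzero:
            marking[name] = nonzero.pop()

    arcs: dict[tuple[str, str], int] = {}
    for edgeclass in root.iter("edgeclass"):
        if edgeclass.attrib.get("name", "Edge") != "Edge":
            log.warning(
                "ignoring unsupported edge class %r in %s",
                edgeclass.attrib.get("name"),
                path,
            )
            continue
        for edge in edgeclass.iter("edge"):
            try:
                src = node_name[edge.attrib["source"]]
                dst = node_name[edge.attrib["target"]]
            except KeyError as exc:
                raise NetValidationError(
                    f"{path}: edge references unknown node {exc}"
                ) from exc
            w = _spped_attr(edge, "Multiplicity")
            weight = int(float(w)) if w else 1
            # merging logical copies can make parallel arcs collide; weights add
            arcs[(src, dst)] = arcs.get((src, dst), 0) + weight
    return PetriNet(places, transitions, arcs, marking)


# ---------------------------------------------------------------------------
# incidence-matrix CSV
# ---------------------------------------------------------------------------

def _write_incidence_csv(net: PetriNet, path: Path) -> None:
    A = build_incidence_matrix(net)
    pure = structural_report(net).pure
    with path.open("w", newline="") as fh:
        fh.write(f"# pure={'true' if pure else 'false'}\n")
        writer = csv.writer(fh)
        writer.writerow(["place", *A.transition_ids])
        for i, pid in enumerate(A.place_ids):
            writer.writerow([pid, *(int(v) for v in A.entries[i])])


def _read_incidence_csv(path: Path) -> PetriNet:
    lines = path.read_text().splitlines()
    if lines and lines[0].startswith("#"):
        flag = lines[0]
        if "pure=false" in flag.replace(" ", "").lower():
            raise NetValidationError(
                f"{path}: flagged as written from a non-pure net; the incidence "
                "matrix cannot reconstruct its read arcs"
            )
        lines = lines[1:]
    reader = csv.reader(lines)
    header = next(reader)
    transitions = header[1:]
    places, arcs = [], []
    for row in reader:
        if not row:
            continue
        pid = row[0]
        places.append(pid)
        for tid, cell in zip(transitions, row[1:]):
            v = int(cell)
            if v > 0:
                arcs.append((tid, pid, v))
            elif v < 0:
                arcs.append((pid, tid, -v))
    return PetriNet(places, transitions, arcs, {})


# ---------------------------------------------------------------------------
# support-matrix CSV
# ---------------------------------------------------------------------------

def read_support_csv(path: str | Path) -> SupportMatrix:
    """Binary invariant x transition matrix from CSV (labels preserved in order)."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        col_labels = tuple(header[1:])
        row_labels, rows = [], []
        for r, row in enumerate(reader):
            if not row:
                continue
            row_labels.append(row[0])
            vals = []
            for c, cell in enumerate(row[1:]):
                if cell.strip() not in ("0", "1"):
                    raise ValueError(
                        f"{path}: non-binary cell {cell!r} at row "
                        f"{row[0]!r}, column {col_labels[c]!r}"
                    )
                vals.append(int(cell))
            rows.append(vals)
    entries = (
        np.array(rows, dtype=np.int8)
        if rows
        else np.zeros((0, len(col_labels)), dtype=np.int8)
    )
    return SupportMatrix(entries, tuple(row_labels), col_labels)


def write_support_csv(matrix: SupportMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["invariant", *matrix.col_labels])
        for label, row in zip(matrix.row_labels, matrix.entries):
            writer.writerow([label, *(int(v) for v in row)])
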