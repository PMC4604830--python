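"""NeXML serialization of synthetic supermatrices, with per-cell provenance.

The matrix is written as one NeXML 0.9 document (namespace
``http://www.nexml.org/2009``): a single ``otus`` block of taxa and a
single standard-characters block with two state symbols (0 = absent,
1 = present) plus a polymorphic state set {0, 1} encoding BOTH cells.
MISSING cells are simply not written.  Every written cell carries ``meta``
elements (``ps:support``) holding the full support records — source matrix,
published character and state, phenotype, asserted/inferred mode, and the
witness chain — so the provenance panel of a matrix editor can be
reconstructed from the file alone.

The provenance vocabulary lives in a small dedicated namespace
(``https://phenosynth.dev/terms#``); it is declared in the document and
documented here, but no compatibility with any external metadata schema is
claimed.  A lossless JSON dump and a values-only NEXUS export are also
provided.  Output is deterministic: stable element ordering and no
timestamps unless the caller supplies one.
"""

from __future__ import annotations

import json
import logging
from typing import Dict, List, Optional, Tuple

from lxml import etree

from .eq_model import EQPhenotype
from .ontology import Relation
from .synthesis import (
    CellValue,
    SupportMode,
    SupportRecord,
    SyntheticCell,
    SyntheticMatrix,
    TOOL_VERSION,
)

logger = logging.getLogger(__name__)

NEX_NS = "http://www.nexml.org/2009"
XSI_NS = "http://www.w3.org/2001/XMLSchema-instance"
PS_NS = "https://phenosynth.dev/terms#"
XSD_NS = "http://www.w3.org/2001/XMLSchema#"

_NSMAP = {None: NEX_NS, "nex": NEX_NS, "xsi": XSI_NS, "ps": PS_NS, "xsd": XSD_NS}

_STATE_IDS = {CellValue.ABSENT: "s0", CellValue.PRESENT: "s1", CellValue.BOTH: "sb"}
_SYMBOLS = {"s0": CellValue.ABSENT, "s1": CellValue.PRESENT, "sb": CellValue.BOTH}


class NexmlError(ValueError):
    pass


def _q(tag: str) -> str:
    return f"{{{NEX_NS}}}{tag}"


def _meta(parent, prop: str, content: str) -> None:
    etree.SubElement(
        parent,
        _q("meta"),
        {
            f"{{{XSI_NS}}}type": "nex:LiteralMeta",
            "property": prop,
            "datatype": "xsd:string",
            "content": content,
        },
    )


def _support_to_json(s: SupportRecord) -> str:
    return json.dumps(
        {
            "taxon": s.taxon,
            "matrix_id": s.matrix_id,
            "char_id": s.char_id,
            "state_id": s.state_id,
            "phenotype": s.phenotype.to_dict(),
            "value": s.value,
            "mode": s.mode.value,
            "chain": [[a, rel.value, b] for a, rel, b in s.chain],
        },
        sort_keys=True,
    )


def _support_from_json(text: str) -> SupportRecord:
    d = json.loads(text)
    return SupportRecord(
        taxon=d["taxon"],
        matrix_id=d["matrix_id"],
        char_id=d["char_id"],
        state_id=d["state_id"],
        phenotype=EQPhenotype.from_dict(d["phenotype"]),
        value=d["value"],
        mode=SupportMode(d["mode"]),
        chain=tuple((a, Relation(rel), b) for a, rel, b in d["chain"]),
    )


def build_nexml_tree(m: SyntheticMatrix) -> etree._ElementTree:
    root = etree.Element(
        _q("nexml"),
        {"version": "0.9", "generator": m.tool_version or TOOL_VERSION},
        nsmap=_NSMAP,
    )
    _meta(root, "ps:entityExpression", m.entity_expression)
    _meta(root, "ps:taxonExpression", m.taxon_expression)
    _meta(root, "ps:sourceMatrices", " ".join(m.source_ids))
    if m.timestamp:
        _meta(root, "ps:buildTimestamp", m.timestamp)

    otus = etree.SubElement(root, _q("otus"), {"id": "otus1"})
    otu_ids: Dict[str, str] = {}
    for i, taxon in enumerate(m.taxa):
        oid = f"t{i}"
        otu_ids[taxon] = oid
        etree.SubElement(otus, _q("otu"), {"id": oid, "label": taxon})

    chars = etree.SubElement(
        root,
        _q("characters"),
        {
            "id": "chars1",
            "otus": "otus1",
            f"{{{XSI_NS}}}type": "nex:StandardCells",
        },
    )
    fmt = etree.SubElement(chars, _q("format"))
    states = etree.SubElement(fmt, _q("states"), {"id": "states1"})
    etree.SubElement(states, _q("state"), {"id": "s0", "symbol": "0"})
    etree.SubElement(states, _q("state"), {"id": "s1", "symbol": "1"})
    poly = etree.SubElement(
        states, _q("polymorphic_state_set"), {"id": "sb", "symbol": "2"}
    )
    etree.SubElement(poly, _q("member"), {"state": "s0"})
    etree.SubElement(poly, _q("member"), {"state": "s1"})
    char_ids: Dict[str, str] = {}
    for i, entity in enumerate(m.characters):
        cid = f"c{i}"
        char_ids[entity] = cid
        etree.SubElement(
            fmt, _q("char"), {"id": cid, "states": "states1", "label": entity}
        )

    matrix_el = etree.SubElement(chars, _q("matrix"))
    for i, taxon in enumerate(m.taxa):
        row = etree.SubElement(
            matrix_el, _q("row"), {"id": f"r{i}", "otu": otu_ids[taxon]}
        )
        for entity in m.characters:
            cell = m.cell(taxon, entity)
            if cell.value is CellValue.MISSING:
                continue
            cell_el = etree.SubElement(
                row,
                _q("cell"),
                {"char": char_ids[entity], "state": _STATE_IDS[cell.value]},
            )
            for s in cell.supports:
                _meta(cell_el, "ps:support", _support_to_json(s))
    return etree.ElementTree(root)


def write_nexml(m: SyntheticMatrix, path: str) -> None:
    """Serialize the matrix to a NeXML 0.9 file (deterministic bytes)."""
    tree = build_nexml_tree(m)
    tree.write(
        path, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def read_nexml(path: str) -> SyntheticMatrix:
    """Read a NeXML file back into a :class:`SyntheticMatrix`.

    Inverse of :func:`write_nexml` on its own output.  Foreign NeXML files
    in the supported subset load in degraded mode: cell values are decoded
    from state symbols, supports are empty, and a warning is logged.
    """
    try:
        tree = etree.parse(path)
    except etree.XMLSyntaxError as exc:
        raise NexmlError(f"{path}: malformed XML: {exc}") from exc
    root = tree.getroot()
    if root.tag != _q("nexml"):
        raise NexmlError(f"{path}: not a NeXML document (root {root.tag})")

    def root_meta(prop: str) -> str:
        for el in root.findall(_q("meta")):
            if el.get("property") == prop:
                return el.get("content", "")
        return ""

    otus = root.find(_q("otus"))
    otu_labels: Dict[str, str] = {}
    if otus is not None:
        for otu in otus.findall(_q("otu")):
            otu_labels[otu.get("id")] = otu.get("label", otu.get("id"))

    chars_el = root.find(_q("characters"))
    characters: List[str] = []
    cells: Dict[Tuple[str, str], SyntheticCell] = {}
    char_labels: Dict[str, str] = {}
    state_values: Dict[str, CellValue] = {}
    degraded = False
    if chars_el is not None:
        fmt = chars_el.find(_q("format"))
        if fmt is not None:
            states_el = fmt.find(_q("states"))
            if states_el is not None:
                for st in states_el:
                    sid = st.get("id")
                    if st.tag == _q("state"):
                        state_values[sid] = (
                            CellValue.ABSENT
                            if st.get("symbol") == "0"
                            else CellValue.PRESENT
                        )
                    elif st.tag == _q("polymorphic_state_set"):
                        state_values[sid] = CellValue.BOTH
            for ch in fmt.findall(_q("char")):
                label = ch.get("label", ch.get("id"))
                char_labels[ch.get("id")] = label
                characters.append(label)
        matrix_el = chars_el.find(_q("matrix"))
        if matrix_el is not None:
            for row in matrix_el.findall(_q("row")):
                taxon = otu_labels.get(row.get("otu"))
                if taxon is None:
                    raise NexmlError(
                        f"{path}: row {row.get('id')} references unknown otu"
                    )
                for cell_el in row.findall(_q("cell")):
                    cid = cell_el.get("char")
                    sid = cell_el.get("state")
                    if cid not in char_labels:
                        raise NexmlError(f"{path}: cell references unknown char {cid!r}")
                    if sid not in state_values:
                        raise NexmlError(
                            f"{path}: cell references unknown state {sid!r}"
                        )
                    supports = tuple(
                        _support_from_json(meta.get("content", "{}"))
                        for meta in cell_el.findall(_q("meta"))
                        if meta.get("property") == "ps:support"
                    )
                    if not supports:
                        degraded = True
                    cells[(taxon, char_labels[cid])] = SyntheticCell(
                        value=state_values[sid], supports=supports
                    )
    if degraded and cells:
        logger.warning(
            "%s: some cells carry no ps:support provenance; loaded values only",
            path,
        )
    source_ids = tuple(s for s in root_meta("ps:sourceMatrices").split() if s)
    return SyntheticMatrix(
        characters=tuple(characters),
        taxa=tuple(otu_labels[oid] for oid in otu_labels),
        cells=cells,
        entity_expression=root_meta("ps:entityExpression"),
        taxon_expression=root_meta("ps:taxonExpression"),
        source_ids=source_ids,
        tool_version=root.get("generator", ""),
        timestamp=root_meta("ps:buildTimestamp") or None,
    )


def validate_nexml(path: str) -> List[str]:
    """Structural validation of a NeXML 0.9 document.

    Checks the constraints the standard imposes on this subset: correct
    namespace and version, globally unique ids, resolvable otus/otu/char/
    state references, legal state symbols, and polymorphic member
    references.  Returns a list of problems (empty means valid).
    """
    problems: List[str] = []
    try:
        tree = etree.parse(path)
    except etree.XMLSyntaxError as exc:
        return [f"malformed XML: {exc}"]
    root = tree.getroot()
    if root.tag != _q("nexml"):
        problems.append(f"root element is {root.tag}, expected {{{NEX_NS}}}nexml")
        return problems
    if root.get("version") != "0.9":
        problems.append(f"version is {root.get('version')!r}, expected '0.9'")

    ids: Dict[str, str] = {}
    for el in root.iter():
        eid = el.get("id")
        if eid is not None:
            if eid in ids:
                problems.append(f"duplicate id {eid!r}")
            ids[eid] = etree.QName(el).localname

    otus_ids = {el.get("id") for el in root.findall(_q("otus"))}
    for chars_el in root.findall(_q("characters")):
        if chars_el.get("otus") not in otus_ids:
            problems.append(
                f"characters {chars_el.get('id')!r} references unknown otus block"
            )
        fmt = chars_el.find(_q("format"))
        state_ids: Dict[str, str] = {}
        char_ids = set()
        if fmt is not None:
            for states_el in fmt.findall(_q("states")):
                symbols = set()
                for st in states_el:
                    if st.tag not in (_q("state"), _q("polymorphic_state_set"),
                                      _q("uncertain_state_set")):
                        continue
                    sid, sym = st.get("id"), st.get("symbol")
                    state_ids[sid] = sym
                    if sym in symbols:
                        problems.append(f"duplicate state symbol {sym!r}")
                    symbols.add(sym)
                    for member in st.findall(_q("member")):
                        if member.get("state") not in state_ids:
                            problems.append(
                                f"state set {sid!r} member references unknown state"
                            )
            for ch in fmt.findall(_q("char")):
                char_ids.add(ch.get("id"))
                if ch.get("states") not in {
                    s.get("id") for s in fmt.findall(_q("states"))
                }:
                    problems.append(
                        f"char {ch.get('id')!r} references unknown states block"
                    )
        otu_ids = {
            otu.get("id")
            for block in root.findall(_q("otus"))
            for otu in block.findall(_q("otu"))
        }
        matrix_el = chars_el.find(_q("matrix"))
        if matrix_el is not None:
            for row in matrix_el.findall(_q("row")):
                if row.get("otu") not in otu_ids:
                    problems.append(f"row {row.get('id')!r} references unknown otu")
                for cell_el in row.findall(_q("cell")):
                    if cell_el.get("char") not in char_ids:
                        problems.append("cell references unknown char")
                    if cell_el.get("state") not in state_ids:
                        problems.append("cell references unknown state")
    return problems


# ----------------------------------------------------------------------
# auxiliary dumps


def matrix_to_json(m: SyntheticMatrix) -> str:
    """Lossless JSON dump mirroring :class:`SyntheticMatrix`."""
    payload = {
        "characters": list(m.characters),
        "taxa": list(m.taxa),
        "entity_expression": m.entity_expression,
        "taxon_expression": m.taxon_expression,
        "source_ids": list(m.source_ids),
        "tool_version": m.tool_version,
        "timestamp": m.timestamp,
        "variability_basis": {k: v.value for k, v in sorted(m.variability_basis.items())},
        "cells": [
            {
                "taxon": taxon,
                "entity": entity,
                "value": cell.value.value,
                "supports": [json.loads(_support_to_json(s)) for s in cell.supports],
            }
            for (taxon, entity), cell in sorted(m.cells.items())
        ],
    }
    return json.dumps(payload, indent=1, sort_keys=True)


def matrix_from_json(text: str) -> SyntheticMatrix:
    from .synthesis import VariabilityBasis

    d = json.loads(text)
    cells = {
        (c["taxon"], c["entity"]): SyntheticCell(
            value=CellValue(c["value"]),
            supports=tuple(
                _support_from_json(json.dumps(s)) for s in c["supports"]
            ),
        )
        for c in d["cells"]
    }
    return SyntheticMatrix(
        characters=tuple(d["characters"]),
        taxa=tuple(d["taxa"]),
        cells=cells,
        entity_expression=d["entity_expression"],
        taxon_expression=d["taxon_expression"],
        source_ids=tuple(d["source_ids"]),
        tool_version=d["tool_version"],
        timestamp=d.get("timestamp"),
        variability_basis={
            k: VariabilityBasis(v) for k, v in d.get("variability_basis", {}).items()
        },
    )


def write_nexus(m: SyntheticMatrix, path: str) -> None:
    """Values-only NEXUS export (no provenance) for desktop matrix viewers."""
    symbol = {
        CellValue.PRESENT: "1",
        CellValue.ABSENT: "0",
        CellValue.BOTH: "(01)",
        CellValue.MISSING: "?",
    }
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"  DIMENSIONS NTAX={len(m.taxa)} NCHAR={len(m.characters)};",
        "  FORMAT DATATYPE=STANDARD SYMBOLS=\"01\" MISSING=?;",
        "  MATRIX",
    ]
    width = max((len(t) for t in m.taxa), default=0) + 2
    for taxon in m.taxa:
        row = "".join(symbol[m.cell(taxon, e).value] for e in m.characters)
        lines.append(f"  '{taxon}'".ljust(width + 2) + row)
    lines += ["  ;", "END;", ""]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines))
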