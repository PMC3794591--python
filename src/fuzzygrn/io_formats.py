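"""Readers and writers for the flat tab-separated network dialect, plus
SBML-qual (Level 3 qualitative models) and GraphML export.

The flat dialect is three UTF-8 TSV files with header rows, LF endings and
``#`` comment lines:

* ``entities.tsv`` — id, name, etype, parents (is-a parent ids joined by
  ``|``)
* ``transitions.tsv`` — id, process, inputs, outputs.  Input tokens are
  ``entity:role:direction:magnitude[:special]`` joined by ``;``; output
  tokens are ``entity:direction:magnitude:rtype``.
* ``evidence.tsv`` — transition_id, article, eclass, technique, quote

Free-text fields escape backslash, tab, CR and LF.  Loading is strict:
any malformed row aborts with file, line and column, and the assembled
network must pass full validation.  Writing is deterministic (rows sorted
by id), so write→read→write is byte-identical.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
from lxml import etree

from .curation import EVIDENCE_CLASSES, EvidenceRecord, classify_confidence
from .model import (
    DIRECTIONS,
    ETYPES,
    MAGNITUDES,
    SPECIALS,
    Entity,
    Network,
    RegulatoryState,
    Transition,
    TransitionInput,
    TransitionOutput,
    validate_network,
)

__all__ = [
    "FlatFileBundle",
    "FlatFormatError",
    "read_network",
    "write_network",
    "export_sbml_qual",
    "validate_sbml_qual",
    "parse_sbml_qual_topology",
    "export_graphml",
    "network_to_graph",
]


@dataclass(frozen=True)
class FlatFileBundle:
    """Paths of the three TSV files making up one network."""

    entities: Path
    transitions: Path
    evidence: Path

    @classmethod
    def in_dir(cls, directory) -> "FlatFileBundle":
        d = Path(directory)
        return cls(d / "entities.tsv", d / "transitions.tsv", d / "evidence.tsv")


class FlatFormatError(ValueError):
    """A malformed row, with file/line/column context."""

    def __init__(self, path, line_no, message, column=None):
        loc = f"{path}:{line_no}"
        if column:
            loc += f" (column {column})"
        super().__init__(f"{loc}: {message}")
        self.path = str(path)
        self.line_no = line_no
        self.column = column


def _escape(text: str) -> str:
    return (
        text.replace("\\", "\\\\").replace("\t", "\\t").replace("\n", "\\n").replace("\r", "\\r")
    )


def _unescape(text: str) -> str:
    out = []
    it = iter(range(len(text)))
    i = 0
    while i < len(text):
        c = text[i]
        if c == "\\" and i + 1 < len(text):
            nxt = text[i + 1]
            out.append({"\\": "\\", "t": "\t", "n": "\n", "r": "\r"}.get(nxt, "\\" + nxt))
            i += 2
        else:
            out.append(c)
            i += 1
    return "".join(out)


def _rows(path) -> list[tuple[int, list[str]]]:
    try:
        # importlib.resources traversables also expose read_text
        reader = path.read_text if hasattr(path, "read_text") else Path(path).read_text
        text = reader(encoding="utf-8")
    except FileNotFoundError:
        raise FlatFormatError(path, 0, "file not found")
    rows = []
    for line_no, line in enumerate(text.split("\n"), start=1):
        if not line or line.startswith("#"):
            continue
        rows.append((line_no, line.split("\t")))
    return rows


def _check_header(path, rows, expected):
    if not rows:
        raise FlatFormatError(path, 1, f"missing header row, expected {expected}")
    line_no, fields = rows[0]
    if fields != list(expected):
        raise FlatFormatError(path, line_no, f"bad header {fields!r}, expected {list(expected)}")
    return rows[1:]


def _enum(path, line_no, column, token, legal):
    if token not in legal:
        raise FlatFormatError(
            path, line_no, f"unknown token {token!r}; legal tokens: {', '.join(legal)}", column
        )
    return token


def _parse_input_token(path, line_no, token) -> TransitionInput:
    parts = token.split(":")
    if len(parts) not in (4, 5):
        raise FlatFormatError(
            path,
            line_no,
            f"bad input token {token!r}, expected entity:role:direction:magnitude[:special]",
            "inputs",
        )
    entity, role, direction, magnitude = parts[:4]
    special = parts[4] if len(parts) == 5 else "none"
    _enum(path, line_no, "inputs", role, ("signal", "tf"))
    _enum(path, line_no, "inputs", direction, DIRECTIONS)
    _enum(path, line_no, "inputs", magnitude, MAGNITUDES)
    _enum(path, line_no, "inputs", special, SPECIALS)
    try:
        state = RegulatoryState(direction=direction, magnitude=magnitude, special=special)
    except ValueError as exc:
        raise FlatFormatError(path, line_no, str(exc), "inputs")
    return TransitionInput(entity_id=entity, role=role, state=state)


def _parse_output_token(path, line_no, token) -> TransitionOutput:
    parts = token.split(":")
    if len(parts) != 4:
        raise FlatFormatError(
            path,
            line_no,
            f"bad output token {token!r}, expected entity:direction:magnitude:rtype",
            "outputs",
        )
    entity, direction, magnitude, rtype = parts
    _enum(path, line_no, "outputs", direction, ("up", "down"))
    _enum(path, line_no, "outputs", magnitude, ("weak", "medium", "strong"))
    _enum(path, line_no, "outputs", rtype, ("activation", "inhibition"))
    return TransitionOutput(entity_id=entity, direction=direction, magnitude=magnitude,
                            rtype=rtype)


def read_network(bundle: FlatFileBundle) -> Network:
    """Load and fully validate a network; any violation aborts the load."""
    entities = []
    rows = _check_header(bundle.entities, _rows(bundle.entities), ("id", "name", "etype",
                                                                   "parents"))
    seen_ids = set()
    for line_no, fields in rows:
        if len(fields) != 4:
            raise FlatFormatError(bundle.entities, line_no, f"expected 4 columns, got {len(fields)}")
        eid, name, etype, parents = fields
        _enum(bundle.entities, line_no, "etype", etype, ETYPES)
        if eid in seen_ids:
            raise FlatFormatError(bundle.entities, line_no, f"duplicate entity id {eid!r}", "id")
        seen_ids.add(eid)
        plist = tuple(p for p in parents.split("|") if p)
        try:
            entities.append(Entity(id=eid, name=_unescape(name), etype=etype, parents=plist))
        except ValueError as exc:
            raise FlatFormatError(bundle.entities, line_no, str(exc))

    transitions = []
    rows = _check_header(
        bundle.transitions, _rows(bundle.transitions), ("id", "process", "inputs", "outputs")
    )
    seen_ids = set()
    for line_no, fields in rows:
        if len(fields) != 4:
            raise FlatFormatError(
                bundle.transitions, line_no, f"expected 4 columns, got {len(fields)}"
            )
        tid, process, inputs, outputs = fields
        if tid in seen_ids:
            raise FlatFormatError(
                bundle.transitions, line_no, f"duplicate transition id {tid!r}", "id"
            )
        seen_ids.add(tid)
        ins = tuple(
            _parse_input_token(bundle.transitions, line_no, tok)
            for tok in inputs.split(";")
            if tok
        )
        outs = tuple(
            _parse_output_token(bundle.transitions, line_no, tok)
            for tok in outputs.split(";")
            if tok
        )
        if not ins:
            raise FlatFormatError(
                bundle.transitions, line_no, f"transition {tid!r} has no inputs", "inputs"
            )
        if not outs:
            raise FlatFormatError(
                bundle.transitions, line_no, f"transition {tid!r} has no outputs", "outputs"
            )
        transitions.append(
            Transition(id=tid, process=_unescape(process), inputs=ins, outputs=outs)
        )

    evidence = []
    rows = _check_header(
        bundle.evidence,
        _rows(bundle.evidence),
        ("transition_id", "article", "eclass", "technique", "quote"),
    )
    for line_no, fields in rows:
        if len(fields) != 5:
            raise FlatFormatError(bundle.evidence, line_no, f"expected 5 columns, got {len(fields)}")
        tid, article, eclass, technique, quote = fields
        _enum(bundle.evidence, line_no, "eclass", eclass, EVIDENCE_CLASSES)
        if not article:
            raise FlatFormatError(bundle.evidence, line_no, "article id is empty", "article")
        evidence.append(
            EvidenceRecord(
                transition_id=tid,
                article=_unescape(article),
                eclass=eclass,
                technique=_unescape(technique),
                quote=_unescape(quote),
            )
        )

    network = Network.from_lists(entities, transitions, evidence)
    violations = validate_network(network)
    if violations:
        msgs = "; ".join(v.message for v in violations[:10])
        raise FlatFormatError(
            bundle.entities.parent if hasattr(bundle.entities, "parent") else bundle.entities,
            0,
            f"network fails validation ({len(violations)} violations): {msgs}",
        )
    return network


def _input_token(inp: TransitionInput) -> str:
    base = f"{inp.entity_id}:{inp.role}:{inp.state.direction}:{inp.state.magnitude}"
    if inp.state.special != "none":
        base += f":{inp.state.special}"
    return base


def _output_token(out: TransitionOutput) -> str:
    return f"{out.entity_id}:{out.direction}:{out.magnitude}:{out.rtype}"


def write_network(network: Network, bundle: FlatFileBundle) -> None:
    """Write the three TSV files deterministically (rows sorted by id)."""
    for p in (bundle.entities, bundle.transitions, bundle.evidence):
        Path(p).parent.mkdir(parents=True, exist_ok=True)

    lines = ["id\tname\tetype\tparents"]
    for eid in sorted(network.entities):
        e = network.entities[eid]
        lines.append(f"{e.id}\t{_escape(e.name)}\t{e.etype}\t{'|'.join(e.parents)}")
    Path(bundle.entities).write_text("\n".join(lines) + "\n", encoding="utf-8")

    lines = ["id\tprocess\tinputs\toutputs"]
    for tid in sorted(network.transitions):
        t = network.transitions[tid]
        ins = ";".join(_input_token(i) for i in t.inputs)
        outs = ";".join(_output_token(o) for o in t.outputs)
        lines.append(f"{t.id}\t{_escape(t.process)}\t{ins}\t{outs}")
    Path(bundle.transitions).write_text("\n".join(lines) + "\n", encoding="utf-8")

    lines = ["transition_id\tarticle\teclass\ttechnique\tquote"]
    recs = sorted(
        network.evidence_records(),
        key=lambda r: (r.transition_id, r.article, r.eclass, r.technique, r.quote),
    )
    for r in recs:
        lines.append(
            f"{r.transition_id}\t{_escape(r.article)}\t{r.eclass}"
            f"\t{_escape(r.technique)}\t{_escape(r.quote)}"
        )
    Path(bundle.evidence).write_text("\n".join(lines) + "\n", encoding="utf-8")


# --------------------------------------------------------------------------
# SBML-qual

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
QUAL_NS = "http://www.sbml.org/sbml/level3/version1/qual/version1"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"

# 7-term scale embedded as discrete levels 0..6, neutral = 3
_LEVEL_OF = {
    ("down", "strong"): 0,
    ("down", "medium"): 1,
    ("down", "weak"): 2,
    ("up", "weak"): 4,
    ("up", "medium"): 5,
    ("up", "strong"): 6,
}


def _q(tag):
    return f"{{{QUAL_NS}}}{tag}"


def export_sbml_qual(network: Network, model_id: str = "grn") -> bytes:
    """Serialize the network as an SBML Level 3 qualitative model.

    Each entity becomes one qualitative species with maxLevel 6 (the seven
    discrete states, neutral = 3); each transition becomes one qual
    transition with signed inputs, its outputs, a default term at the
    neutral level and a function term whose result level encodes the first
    output's effect.
    """
    nsmap = {None: SBML_NS, "qual": QUAL_NS}
    sbml = etree.Element(
        "{%s}sbml" % SBML_NS,
        nsmap=nsmap,
        attrib={"level": "3", "version": "1", _q("required"): "true"},
    )
    model = etree.SubElement(sbml, "{%s}model" % SBML_NS, attrib={"id": model_id})
    comps = etree.SubElement(model, "{%s}listOfCompartments" % SBML_NS)
    etree.SubElement(
        comps, "{%s}compartment" % SBML_NS, attrib={"id": "cell", "constant": "true"}
    )

    targeted = {out.entity_id for tr in network.transitions.values() for out in tr.outputs}
    lqs = etree.SubElement(model, _q("listOfQualitativeSpecies"))
    for eid in sorted(network.entities):
        etree.SubElement(
            lqs,
            _q("qualitativeSpecies"),
            attrib={
                _q("id"): eid,
                _q("compartment"): "cell",
                _q("constant"): "false" if eid in targeted else "true",
                _q("maxLevel"): "6",
                _q("initialLevel"): "3",
            },
        )

    lot = etree.SubElement(model, _q("listOfTransitions"))
    for tid in sorted(network.transitions):
        tr = network.transitions[tid]
        t_el = etree.SubElement(lot, _q("transition"), attrib={_q("id"): tid})
        in_list = etree.SubElement(t_el, _q("listOfInputs"))
        for i, inp in enumerate(tr.inputs):
            sign = "positive" if inp.state.direction in ("up", "present") else "negative"
            etree.SubElement(
                in_list,
                _q("input"),
                attrib={
                    _q("id"): f"{tid}_in{i}",
                    _q("qualitativeSpecies"): inp.entity_id,
                    _q("transitionEffect"): "none",
                    _q("sign"): sign,
                },
            )
        out_list = etree.SubElement(t_el, _q("listOfOutputs"))
        for i, out in enumerate(tr.outputs):
            etree.SubElement(
                out_list,
                _q("output"),
                attrib={
                    _q("id"): f"{tid}_out{i}",
                    _q("qualitativeSpecies"): out.entity_id,
                    _q("transitionEffect"): "assignmentLevel",
                },
            )
        terms = etree.SubElement(t_el, _q("listOfFunctionTerms"))
        first = tr.outputs[0]
        ft = etree.SubElement(
            terms,
            _q("functionTerm"),
            attrib={_q("resultLevel"): str(_LEVEL_OF[(first.direction, first.magnitude)])},
        )
        math = etree.SubElement(ft, "{%s}math" % MATHML_NS, nsmap={None: MATHML_NS})
        apply_el = etree.SubElement(math, "{%s}apply" % MATHML_NS)
        etree.SubElement(apply_el, "{%s}and" % MATHML_NS)
        for inp in tr.inputs:
            cond = etree.SubElement(apply_el, "{%s}apply" % MATHML_NS)
            op = "geq" if inp.state.direction in ("up", "present") else "leq"
            etree.SubElement(cond, "{%s}%s" % (MATHML_NS, op))
            ci = etree.SubElement(cond, "{%s}ci" % MATHML_NS)
            ci.text = f" {inp.entity_id} "
            cn = etree.SubElement(
                cond, "{%s}cn" % MATHML_NS, attrib={"type": "integer"}
            )
            cn.text = " 4 " if op == "geq" else " 2 "
        etree.SubElement(terms, _q("defaultTerm"), attrib={_q("resultLevel"): "3"})

    return etree.tostring(sbml, xml_declaration=True, encoding="UTF-8", pretty_print=True)


def validate_sbml_qual(document: bytes) -> list[str]:
    """Structural consistency checks on an SBML-qual document.

    Returns a list of problems (empty when clean): unique ids, species
    references that resolve, levels within maxLevel, a default term per
    transition, and required attributes present.
    """
    problems: list[str] = []
    root = etree.fromstring(document)
    if etree.QName(root).localname != "sbml":
        return ["root element is not <sbml>"]
    model = root.find("{%s}model" % SBML_NS)
    if model is None:
        return ["missing <model>"]

    species = model.findall(f".//{_q('qualitativeSpecies')}")
    ids = [s.get(_q("id")) for s in species]
    if len(ids) != len(set(ids)):
        problems.append("duplicate qualitativeSpecies ids")
    max_level = {}
    for s in species:
        sid = s.get(_q("id"))
        if sid is None:
            problems.append("qualitativeSpecies without id")
            continue
        try:
            max_level[sid] = int(s.get(_q("maxLevel"), "0"))
        except ValueError:
            problems.append(f"species {sid}: non-integer maxLevel")
        init = s.get(_q("initialLevel"))
        if init is not None and int(init) > max_level.get(sid, 0):
            problems.append(f"species {sid}: initialLevel exceeds maxLevel")

    seen_tids = set()
    for t in model.findall(f".//{_q('transition')}"):
        tid = t.get(_q("id"), "?")
        if tid in seen_tids:
            problems.append(f"duplicate transition id {tid}")
        seen_tids.add(tid)
        for io_el, kind in [(i, "input") for i in t.findall(f".//{_q('input')}")] + [
            (o, "output") for o in t.findall(f".//{_q('output')}")
        ]:
            ref = io_el.get(_q("qualitativeSpecies"))
            if ref not in max_level:
                problems.append(f"transition {tid}: {kind} references unknown species {ref!r}")
        terms = t.find(_q("listOfFunctionTerms"))
        if terms is None or terms.find(_q("defaultTerm")) is None:
            problems.append(f"transition {tid}: missing defaultTerm")
            continue
        out_refs = [o.get(_q("qualitativeSpecies")) for o in t.findall(f".//{_q('output')}")]
        cap = min((max_level.get(r, 6) for r in out_refs if r in max_level), default=6)
        for term in list(terms):
            lvl = term.get(_q("resultLevel"))
            if lvl is None:
                problems.append(f"transition {tid}: term without resultLevel")
            elif int(lvl) > cap:
                problems.append(f"transition {tid}: resultLevel {lvl} exceeds maxLevel {cap}")
    return problems


def parse_sbml_qual_topology(document: bytes) -> dict[str, tuple[frozenset, frozenset]]:
    """Transition id → (input species set, output species set); used to
    check that export preserves the wiring."""
    root = etree.fromstring(document)
    topo = {}
    for t in root.findall(f".//{_q('transition')}"):
        tid = t.get(_q("id"))
        ins = frozenset(
            i.get(_q("qualitativeSpecies")) for i in t.findall(f".//{_q('input')}")
        )
        outs = frozenset(
            o.get(_q("qualitativeSpecies")) for o in t.findall(f".//{_q('output')}")
        )
        topo[tid] = (ins, outs)
    return topo


# --------------------------------------------------------------------------
# GraphML

def network_to_graph(network: Network) -> nx.DiGraph:
    """Bipartite digraph: entity nodes and transition nodes.

    Input edges run entity→transition (attrs role/direction/magnitude/
    special), output edges transition→entity (attrs direction/magnitude/
    rtype).  Transition nodes carry the process label and the pooled
    evidence confidence (high/low/unsupported).
    """
    g = nx.DiGraph()
    for eid in sorted(network.entities):
        e = network.entities[eid]
        g.add_node(eid, kind="entity", etype=e.etype, name=e.name)
    for tid in sorted(network.transitions):
        tr = network.transitions[tid]
        recs = network.evidence.get(tid, [])
        conf = classify_confidence(recs).value if recs else "unsupported"
        g.add_node(tid, kind="transition", process=tr.process, confidence=conf)
        for inp in tr.inputs:
            g.add_edge(
                inp.entity_id,
                tid,
                role=inp.role,
                direction=inp.state.direction,
                magnitude=inp.state.magnitude,
                special=inp.state.special,
            )
        for out in tr.outputs:
            g.add_edge(tid, out.entity_id, direction=out.direction, magnitude=out.magnitude,
                       rtype=out.rtype)
    return g


def export_graphml(network: Network) -> bytes:
    """GraphML serialization of the bipartite network graph."""
    g = network_to_graph(network)
    buf = io.BytesIO()
    nx.write_graphml(g, buf)
    return buf.getvalue()
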