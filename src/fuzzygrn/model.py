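"""Core data model for context-dependent gene regulatory interactions.

A regulatory interaction here is not a binary TF→TG edge but a multi-input
Petri-net transition: the inputs are the context signals (extra- or
intracellular conditions that enable the regulation) together with the
transcription factors in a required activity state, and the outputs are the
discretized expression effects on the target genes.  Entities live in a
small is-a ontology so that queries can generalize ("all regulations with a
non-fermentable carbon source as input" finds the ethanol-gated ones).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field, replace

__all__ = [
    "ETYPES",
    "DIRECTIONS",
    "MAGNITUDES",
    "SPECIALS",
    "Entity",
    "RegulatoryState",
    "TransitionInput",
    "TransitionOutput",
    "Transition",
    "Network",
    "Violation",
    "UnknownEntityError",
    "validate_network",
    "ancestors",
    "query_by_input",
]

ETYPES = ("gene", "tf", "signal", "condition", "complex")
DIRECTIONS = ("up", "down", "present", "absent")
MAGNITUDES = ("weak", "medium", "strong", "na")
SPECIALS = ("none", "knockout", "overexpression")


class UnknownEntityError(KeyError):
    """Raised when a query names an entity id that is not in the network."""

    def __init__(self, term: str):
        super().__init__(term)
        self.term = term

    def __str__(self) -> str:  # KeyError quotes its arg; we want a sentence
        return f"unknown entity: {self.term!r}"


@dataclass(frozen=True)
class Entity:
    """A gene, TF, signal, condition or complex, with is-a parent links."""

    id: str
    name: str
    etype: str
    parents: tuple[str, ...] = ()

    def __post_init__(self):
        if self.etype not in ETYPES:
            raise ValueError(f"etype must be one of {ETYPES}, got {self.etype!r}")
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"entity id must be a non-empty token without whitespace: {self.id!r}")
        object.__setattr__(self, "parents", tuple(self.parents))


@dataclass(frozen=True)
class RegulatoryState:
    """Discrete activity state of a regulator.

    TFs carry a direction (up/down) with a magnitude (weak/medium/strong, or
    na when the source states only the sign); signals and conditions use
    present/absent with magnitude na.  The special states knockout and
    overexpression are extreme perturbations and imply direction down and up
    respectively.
    """

    direction: str
    magnitude: str = "na"
    special: str = "none"

    def __post_init__(self):
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}, got {self.direction!r}")
        if self.magnitude not in MAGNITUDES:
            raise ValueError(f"magnitude must be one of {MAGNITUDES}, got {self.magnitude!r}")
        if self.special not in SPECIALS:
            raise ValueError(f"special must be one of {SPECIALS}, got {self.special!r}")
        if self.special == "knockout" and self.direction != "down":
            raise ValueError("special=knockout implies direction=down")
        if self.special == "overexpression" and self.direction != "up":
            raise ValueError("special=overexpression implies direction=up")
        if self.direction in ("present", "absent") and self.magnitude != "na":
            raise ValueError("present/absent states carry no magnitude (use na)")


@dataclass(frozen=True)
class TransitionInput:
    """One required input: an entity in a required state, as signal or TF."""

    entity_id: str
    role: str  # "signal" or "tf"
    state: RegulatoryState

    def __post_init__(self):
        if self.role not in ("signal", "tf"):
            raise ValueError(f"role must be 'signal' or 'tf', got {self.role!r}")


@dataclass(frozen=True)
class TransitionOutput:
    """Discretized expression effect on one target gene."""

    entity_id: str
    direction: str  # up or down
    magnitude: str  # weak, medium or strong — never na
    rtype: str = ""  # activation/inhibition; stored, re-derivable

    def __post_init__(self):
        if self.direction not in ("up", "down"):
            raise ValueError(f"output direction must be up or down, got {self.direction!r}")
        if self.magnitude not in ("weak", "medium", "strong"):
            raise ValueError(
                f"output magnitude must be weak, medium or strong, got {self.magnitude!r}"
            )
        if self.rtype not in ("", "activation", "inhibition"):
            raise ValueError(f"rtype must be activation or inhibition, got {self.rtype!r}")


@dataclass(frozen=True)
class Transition:
    """One multi-input regulation: context + TF states → TG effects."""

    id: str
    process: str
    inputs: tuple[TransitionInput, ...]
    outputs: tuple[TransitionOutput, ...]

    def __post_init__(self):
        object.__setattr__(self, "inputs", tuple(self.inputs))
        object.__setattr__(self, "outputs", tuple(self.outputs))

    def tf_inputs(self) -> tuple[TransitionInput, ...]:
        return tuple(i for i in self.inputs if i.role == "tf")

    def signal_inputs(self) -> tuple[TransitionInput, ...]:
        return tuple(i for i in self.inputs if i.role == "signal")


@dataclass(frozen=True)
class Violation:
    """One validation finding: where and what."""

    kind: str
    subject: str  # entity or transition id
    message: str


@dataclass
class Network:
    """A compiled regulatory network: entities, transitions and evidence.

    ``evidence`` maps transition id → list of EvidenceRecord (see the
    curation module); transitions without literature support simply have no
    entry.
    """

    entities: dict[str, Entity] = field(default_factory=dict)
    transitions: dict[str, Transition] = field(default_factory=dict)
    evidence: dict[str, list] = field(default_factory=dict)

    @classmethod
    def from_lists(cls, entities, transitions, evidence=()) -> "Network":
        ent = {}
        for e in entities:
            if e.id in ent:
                raise ValueError(f"duplicate entity id {e.id!r}")
            ent[e.id] = e
        trs = {}
        for t in transitions:
            if t.id in trs:
                raise ValueError(f"duplicate transition id {t.id!r}")
            trs[t.id] = t
        ev: dict[str, list] = {}
        for rec in evidence:
            ev.setdefault(rec.transition_id, []).append(rec)
        return cls(entities=ent, transitions=trs, evidence=ev)

    def evidence_records(self):
        for recs in self.evidence.values():
            yield from recs

    def __eq__(self, other):
        if not isinstance(other, Network):
            return NotImplemented
        if self.entities != other.entities or self.transitions != other.transitions:
            return False
        # evidence order within a transition is not meaningful
        keys = set(self.evidence) | set(other.evidence)
        for k in keys:
            a = sorted(map(repr, self.evidence.get(k, [])))
            b = sorted(map(repr, other.evidence.get(k, [])))
            if a != b:
                return False
        return True


def _ontology_cycles(network: Network) -> list[str]:
    """Ids of entities involved in an is-a cycle (empty when acyclic)."""
    # iterative DFS three-color cycle detection over child→parent edges
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {eid: WHITE for eid in network.entities}
    in_cycle: set[str] = set()
    for root in network.entities:
        if color[root] != WHITE:
            continue
        stack = [(root, iter(network.entities[root].parents))]
        color[root] = GRAY
        path = [root]
        while stack:
            node, it = stack[-1]
            advanced = False
            for p in it:
                if p not in network.entities:
                    continue
                if color[p] == GRAY:
                    # back edge: everything from p on the current path cycles
                    idx = path.index(p)
                    in_cycle.update(path[idx:])
                elif color[p] == WHITE:
                    color[p] = GRAY
                    stack.append((p, iter(network.entities[p].parents)))
                    path.append(p)
                    advanced = True
                    break
            if not advanced:
                color[node] = BLACK
                stack.pop()
                path.pop()
    return sorted(in_cycle)


def derive_rtype(transition: Transition, output: TransitionOutput) -> str:
    """Regulation type implied by a transition's stored input/output states.

    With a TF input the sign-product rule applies (equal TF/TG directions ⇒
    activation); signal-only transitions take the sign of the output itself,
    reading signal presence as a positive regulator.
    """
    from .curation import infer_transition_type

    tfs = transition.tf_inputs()
    if tfs:
        rtype, _ = infer_transition_type(tfs[0].state, output)
        return rtype
    return "activation" if output.direction == "up" else "inhibition"


def validate_network(network: Network) -> list[Violation]:
    """Check every structural invariant; return all violations found.

    Nothing is raised: curated files must be auditable, so every problem is
    reported with the offending entity/transition id.
    """
    out: list[Violation] = []

    for eid, ent in network.entities.items():
        for p in ent.parents:
            if p not in network.entities:
                out.append(
                    Violation("unknown-parent", eid, f"entity {eid!r} names unknown parent {p!r}")
                )
        if eid in ent.parents:
            out.append(Violation("self-parent", eid, f"entity {eid!r} is its own parent"))

    for eid in _ontology_cycles(network):
        out.append(Violation("ontology-cycle", eid, f"entity {eid!r} participates in an is-a cycle"))

    for tid, tr in network.transitions.items():
        if not tr.inputs:
            out.append(Violation("no-inputs", tid, f"transition {tid!r} has no inputs"))
        if not tr.outputs:
            out.append(Violation("no-outputs", tid, f"transition {tid!r} has no outputs"))
        seen: set[tuple[str, str]] = set()
        for inp in tr.inputs:
            key = (inp.entity_id, inp.role)
            if key in seen:
                out.append(
                    Violation(
                        "duplicate-input",
                        tid,
                        f"transition {tid!r} lists input ({inp.entity_id!r}, {inp.role!r}) twice",
                    )
                )
            seen.add(key)
            ent = network.entities.get(inp.entity_id)
            if ent is None:
                out.append(
                    Violation(
                        "unknown-entity",
                        tid,
                        f"transition {tid!r} references unknown entity {inp.entity_id!r}",
                    )
                )
                continue
            if inp.role == "signal" and ent.etype not in ("signal", "condition"):
                out.append(
                    Violation(
                        "role-mismatch",
                        tid,
                        f"transition {tid!r}: input {inp.entity_id!r} has role signal "
                        f"but etype {ent.etype!r}",
                    )
                )
            if inp.role == "tf" and ent.etype != "tf":
                out.append(
                    Violation(
                        "role-mismatch",
                        tid,
                        f"transition {tid!r}: input {inp.entity_id!r} has role tf "
                        f"but etype {ent.etype!r}",
                    )
                )
            if inp.state.direction in ("present", "absent") and ent.etype not in (
                "signal",
                "condition",
            ):
                out.append(
                    Violation(
                        "state-mismatch",
                        tid,
                        f"transition {tid!r}: present/absent state on non-signal "
                        f"entity {inp.entity_id!r}",
                    )
                )
        for outp in tr.outputs:
            ent = network.entities.get(outp.entity_id)
            if ent is None:
                out.append(
                    Violation(
                        "unknown-entity",
                        tid,
                        f"transition {tid!r} references unknown entity {outp.entity_id!r}",
                    )
                )
                continue
            if ent.etype not in ("gene", "tf"):
                out.append(
                    Violation(
                        "output-etype",
                        tid,
                        f"transition {tid!r}: output entity {outp.entity_id!r} has etype "
                        f"{ent.etype!r}, expected gene or tf",
                    )
                )
            if outp.rtype:
                expected = derive_rtype(tr, outp)
                if outp.rtype != expected:
                    out.append(
                        Violation(
                            "rtype-conflict",
                            tid,
                            f"transition {tid!r}: stored rtype {outp.rtype!r} for "
                            f"{outp.entity_id!r} conflicts with derived {expected!r}",
                        )
                    )

    for tid, recs in network.evidence.items():
        if tid not in network.transitions:
            out.append(
                Violation(
                    "unknown-transition",
                    tid,
                    f"evidence references unknown transition {tid!r}",
                )
            )
        for rec in recs:
            if not rec.article:
                out.append(
                    Violation("empty-article", tid, f"evidence for {tid!r} has an empty article id")
                )

    return out


def ancestors(network: Network, term: str) -> list[str]:
    """All is-a ancestors of ``term``, nearest first, term excluded.

    The order is a topological order of the ancestor sub-DAG (children
    before their parents), ties broken by id, so re-serialization cannot
    change it.
    """
    if term not in network.entities:
        raise UnknownEntityError(term)
    closure: set[str] = set()
    frontier = [term]
    while frontier:
        node = frontier.pop()
        for p in network.entities[node].parents:
            if p in network.entities and p not in closure:
                closure.add(p)
                frontier.append(p)
    closure.discard(term)
    # Kahn's algorithm on the induced sub-DAG, heap for deterministic ties
    nodes = closure | {term}
    indeg = {n: 0 for n in nodes}
    children: dict[str, list[str]] = {n: [] for n in nodes}
    for n in nodes:
        for p in network.entities[n].parents:
            if p in nodes:
                indeg[p] += 1
                children[n].append(p)
    heap = [n for n in nodes if indeg[n] == 0]
    heapq.heapify(heap)
    order: list[str] = []
    while heap:
        n = heapq.heappop(heap)
        if n != term:
            order.append(n)
        for p in children[n]:
            indeg[p] -= 1
            if indeg[p] == 0:
                heapq.heappush(heap, p)
    return order


def query_by_input(
    network: Network, term: str, include_specializations: bool = False
) -> list[Transition]:
    """Transitions with ``term`` (or, optionally, any of its ontology
    descendants) among their inputs.

    With ``include_specializations`` a query for "non-fermentable carbon
    source" also finds the transitions gated on ethanol, glycerol, etc.
    Results are ordered by transition id.
    """
    if term not in network.entities:
        raise UnknownEntityError(term)
    hits = []
    for tid in sorted(network.transitions):
        tr = network.transitions[tid]
        for inp in tr.inputs:
            if inp.entity_id == term:
                hits.append(tr)
                break
            if (
                include_specializations
                and inp.entity_id in network.entities
                and term in ancestors(network, inp.entity_id)
            ):
                hits.append(tr)
                break
    return hits
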