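"""Signed prior-knowledge networks (PKN) and their AND-gate hypergraph expansion.

A PKN is a signed directed graph over proteins.  Node roles follow the graph
structure: *stimuli* have no predecessors (the entry layer that can be clamped
by the environment), *readouts* have no successors (the measured output
layer), and every other node is an *inhibitor* (intermediate signalling
protein).  Candidate regulatory mechanisms are AND-conjunctions ("clauses") of
at most two signed regulators of a target; a Boolean network is a subset of
these clauses, with several clauses on the same target OR-ed together.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

STIMULUS = "stimulus"
INHIBITOR = "inhibitor"
READOUT = "readout"

#: sign-token dialects accepted by :func:`read_sif`
SIGN_DIALECTS = {
    "numeric": {"1": 1, "+1": 1, "-1": -1},
    "words": {"activates": 1, "inhibits": -1},
}


@dataclass(frozen=True, order=True)
class SignedEdge:
    """A signed directed interaction: ``source --(sign)--> target``."""

    source: str
    target: str
    sign: int

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise ValueError(f"edge sign must be +1 or -1, got {self.sign!r}")


@dataclass(frozen=True, order=True)
class Clause:
    """An AND-gate: conjunction of one or two signed regulators of ``target``.

    A literal ``(node, +1)`` reads "node is active"; ``(node, -1)`` reads
    "node is inactive".  The clause fires when all its literals hold.
    """

    target: str
    literals: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        lits = tuple(sorted(self.literals))
        object.__setattr__(self, "literals", lits)
        if not 1 <= len(lits) <= 2:
            raise ValueError("a clause has one or two literals")
        names = [n for n, _ in lits]
        if len(set(names)) != len(names):
            raise ValueError("clause literals must name distinct regulators")
        for _, s in lits:
            if s not in (1, -1):
                raise ValueError("literal sign must be +1 or -1")

    def __str__(self) -> str:  # e.g. "B <- A & !C"
        parts = [(n if s > 0 else "!" + n) for n, s in self.literals]
        return f"{self.target} <- " + " & ".join(parts)


class PKN:
    """Signed directed interaction network with structural node roles."""

    def __init__(self, edges: Iterable[SignedEdge], nodes: Iterable[str] = ()):
        self.edges: list[SignedEdge] = list(edges)
        node_set = set(nodes)
        for e in self.edges:
            node_set.add(e.source)
            node_set.add(e.target)
        self.nodes: tuple[str, ...] = tuple(sorted(node_set))
        self.roles: dict[str, str] = classify_roles(self)

    # -- structure ---------------------------------------------------------
    def predecessors(self, node: str) -> list[tuple[str, int]]:
        """Incoming (source, sign) pairs of ``node``, in edge order."""
        return [(e.source, e.sign) for e in self.edges if e.target == node]

    def successors(self, node: str) -> list[tuple[str, int]]:
        return [(e.target, e.sign) for e in self.edges if e.source == node]

    @property
    def stimuli(self) -> tuple[str, ...]:
        return tuple(n for n in self.nodes if self.roles[n] == STIMULUS)

    @property
    def inhibitors(self) -> tuple[str, ...]:
        return tuple(n for n in self.nodes if self.roles[n] == INHIBITOR)

    @property
    def readouts(self) -> tuple[str, ...]:
        return tuple(n for n in self.nodes if self.roles[n] == READOUT)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.source, e.target, sign=e.sign)
        return g

    def __repr__(self) -> str:
        return (
            f"PKN({len(self.nodes)} nodes: {len(self.stimuli)} stimuli, "
            f"{len(self.inhibitors)} inhibitors, {len(self.readouts)} readouts; "
            f"{len(self.edges)} edges)"
        )


@dataclass
class HyperGraph:
    """Full candidate clause set (the Boolean-network search space) of a PKN."""

    pkn: PKN
    clauses: list[Clause] = field(default_factory=list)

    def clauses_for(self, target: str) -> list[Clause]:
        return [c for c in self.clauses if c.target == target]


def classify_roles(pkn: PKN) -> dict[str, str]:
    """Assign structural roles from in/out-degree.

    in-degree 0 -> stimulus; out-degree 0 -> readout; otherwise inhibitor.
    Isolated nodes (degree 0) are an error; a PKN without stimuli is legal
    (e.g. fully cyclic entry layer) but logged.
    """
    if not pkn.edges:
        raise ValueError("no edges: cannot assign node roles")
    indeg = {n: 0 for n in pkn.nodes}
    outdeg = {n: 0 for n in pkn.nodes}
    for e in pkn.edges:
        outdeg[e.source] += 1
        indeg[e.target] += 1
    isolated = [n for n in pkn.nodes if indeg[n] == 0 and outdeg[n] == 0]
    if isolated:
        raise ValueError(f"isolated node(s) with no interactions: {isolated}")
    roles: dict[str, str] = {}
    for n in pkn.nodes:
        if indeg[n] == 0:
            roles[n] = STIMULUS
        elif outdeg[n] == 0:
            roles[n] = READOUT
        else:
            roles[n] = INHIBITOR
    if not any(r == STIMULUS for r in roles.values()):
        logger.warning("PKN has no stimuli (every node has a predecessor)")
    return roles


def read_sif(path, dialect: str = "numeric") -> PKN:
    """Parse a 3-column SIF file ``source  sign  target`` into a PKN.

    ``dialect`` selects the sign encoding of the middle token: ``numeric``
    ("1"/"-1", default) or ``words`` ("activates"/"inhibits").  Duplicate
    identical edges are collapsed with a warning; self-loops are kept in the
    edge list but flagged (they are excluded later from hypergraph expansion).
    """
    if dialect not in SIGN_DIALECTS:
        raise ValueError(f"unknown SIF dialect {dialect!r}")
    tokens = SIGN_DIALECTS[dialect]
    edges: list[SignedEdge] = []
    seen: set[SignedEdge] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected 3 fields, got {len(fields)}"
                )
            src, tok, tgt = fields
            if tok not in tokens:
                raise ValueError(
                    f"{path}: line {lineno}: unknown sign token {tok!r} "
                    f"for dialect {dialect!r}"
                )
            edge = SignedEdge(src, tgt, tokens[tok])
            if edge in seen:
                logger.warning("%s: line %d: duplicate edge %s collapsed", path, lineno, edge)
                continue
            if src == tgt:
                logger.warning("%s: line %d: self-loop on %s", path, lineno, src)
            seen.add(edge)
            edges.append(edge)
    if not edges:
        raise ValueError(f"{path}: no edges")
    return PKN(edges)


def write_sif(pkn: PKN, path) -> None:
    """Write tab-separated SIF in the numeric "1"/"-1" dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        for e in pkn.edges:
            fh.write(f"{e.source}\t{e.sign:d}\t{e.target}\n")


def expand_hypergraph(pkn: PKN, max_inputs: int = 2) -> HyperGraph:
    """Enumerate every candidate AND-gate clause of the PKN.

    For each non-stimulus node with *d* incoming edges (self-loops excluded)
    this emits the *d* single-literal clauses and, when ``max_inputs`` is 2,
    the C(d, 2) two-literal conjunctions over distinct regulators.  Clauses
    are returned in canonical order (target, then sorted literals).
    """
    if max_inputs not in (1, 2):
        raise ValueError("max_inputs must be 1 or 2")
    clauses: list[Clause] = []
    for node in pkn.nodes:
        if pkn.roles[node] == STIMULUS:
            continue
        incoming = [(s, sg) for s, sg in pkn.predecessors(node) if s != node]
        for lit in incoming:
            clauses.append(Clause(node, (lit,)))
        if max_inputs == 2:
            for a, b in itertools.combinations(incoming, 2):
                if a[0] == b[0]:  # same regulator with both signs: not a clause
                    continue
                clauses.append(Clause(node, (a, b)))
    clauses = sorted(set(clauses))
    return HyperGraph(pkn=pkn, clauses=clauses)


def search_space_size(hg: HyperGraph) -> int:
    """Number of Boolean networks in the search space: 2**|clauses| (exact)."""
    return 1 << len(hg.clauses)


def format_search_space(hg: HyperGraph) -> str:
    return f"2^{len(hg.clauses)}"
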