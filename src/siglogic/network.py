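"""Signed, weighted directed signaling networks.

A network is a directed graph whose nodes are molecular species (proteins,
receptors, abstract stimuli) and whose edges carry a sign — activating or
inhibiting — and a strength (weight) in [0, 1].  A designated subset of nodes,
the *input nodes*, are eligible to receive scheduled extracellular
perturbations (see :mod:`siglogic.perturbation`).

Two plain-text serialisations are supported:

* an edge-list dialect close to SIF: one edge per line,
  ``source sign weight target`` separated by whitespace or tabs, ``#``
  comments.  Directive comments ``#! nodes: ...`` and ``#! inputs: ...``
  optionally pin the node order, declare isolated nodes and mark input nodes,
  so that a write/read round-trip is exact; plain SIF-style readers skip them
  as comments.
* a JSON document ``{"nodes": [...], "input_nodes": [...], "edges":
  [{"source", "target", "sign", "weight"}, ...]}``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

__all__ = [
    "ACTIVATING",
    "INHIBITING",
    "Edge",
    "SignalingNetwork",
    "NetworkValidationError",
    "NetworkParseError",
    "read_network",
    "write_network",
]

ACTIVATING = "activating"
INHIBITING = "inhibiting"

Sign = Literal["activating", "inhibiting"]

_SIGN_TOKENS = {
    "+": ACTIVATING,
    "activate": ACTIVATING,
    "activating": ACTIVATING,
    "-": INHIBITING,
    "inhibit": INHIBITING,
    "inhibiting": INHIBITING,
}
_SIGN_CHAR = {ACTIVATING: "+", INHIBITING: "-"}


class NetworkValidationError(ValueError):
    """An edge or network violates a structural invariant."""


class NetworkParseError(ValueError):
    """A network file could not be parsed; the message names the line."""


@dataclass(frozen=True)
class Edge:
    """One signed, weighted interaction ``source -> target``.

    ``weight`` is the interaction strength in [0, 1]; the transmitted signal
    is the source's activity level times this weight.  Self-loops are
    rejected: a node's dependence on its own previous state is already built
    into the update rule via the degradation term.
    """

    source: str
    target: str
    sign: Sign
    weight: float

    def __post_init__(self) -> None:
        for name in ("source", "target"):
            ident = getattr(self, name)
            if not isinstance(ident, str) or not ident:
                raise NetworkValidationError(
                    f"edge {name} must be a nonempty string, got {ident!r}"
                )
        if self.sign not in (ACTIVATING, INHIBITING):
            raise NetworkValidationError(f"unknown edge sign {self.sign!r}")
        if not 0.0 <= self.weight <= 1.0:
            raise NetworkValidationError(
                f"edge weight must lie in [0, 1], got {self.weight!r} "
                f"({self.source}->{self.target})"
            )
        if self.source == self.target:
            raise NetworkValidationError(
                f"self-loop on {self.source!r} rejected: self-dependence is "
                "modeled by the degradation term, a self-edge would double-count"
            )


@dataclass(frozen=True)
class SignalingNetwork:
    """A validated directed signaling network.

    Parameters
    ----------
    nodes
        Node identifiers, in a fixed, meaningful order (the order of state
        vectors and trajectory rows).
    edges
        The interactions; at most one edge per ordered (source, target) pair.
    input_nodes
        Nodes eligible to receive scheduled perturbations, e.g. receptors.
    """

    nodes: tuple[str, ...]
    edges: tuple[Edge, ...]
    input_nodes: tuple[str, ...] = ()
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __init__(
        self,
        nodes: Iterable[str],
        edges: Iterable[Edge] = (),
        input_nodes: Iterable[str] = (),
    ) -> None:
        nodes = tuple(nodes)
        edges = tuple(edges)
        input_nodes = tuple(input_nodes)

        seen: dict[str, int] = {}
        for ident in nodes:
            if not isinstance(ident, str) or not ident:
                raise NetworkValidationError(
                    f"node identifiers must be nonempty strings, got {ident!r}"
                )
            if ident in seen:
                raise NetworkValidationError(f"duplicate node identifier {ident!r}")
            seen[ident] = len(seen)

        pairs: set[tuple[str, str]] = set()
        for e in edges:
            if e.source not in seen or e.target not in seen:
                raise NetworkValidationError(
                    f"edge {e.source}->{e.target} references an undeclared node"
                )
            if (e.source, e.target) in pairs:
                raise NetworkValidationError(
                    f"duplicate edge for pair ({e.source}, {e.target})"
                )
            pairs.add((e.source, e.target))

        for ident in input_nodes:
            if ident not in seen:
                raise NetworkValidationError(
                    f"input node {ident!r} is not a declared node"
                )
        if len(set(input_nodes)) != len(input_nodes):
            raise NetworkValidationError("duplicate entries in input_nodes")

        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "input_nodes", input_nodes)
        object.__setattr__(self, "_index", seen)

    # -- queries ---------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def __contains__(self, node: str) -> bool:
        return node in self._index

    def index_of(self, node: str) -> int:
        try:
            return self._index[node]
        except KeyError:
            raise KeyError(f"unknown node {node!r}") from None

    def parents_of(
        self, node: str
    ) -> tuple[list[tuple[str, float]], list[tuple[str, float]]]:
        """Incoming edges of ``node`` split by sign.

        Returns ``(activating, inhibiting)`` where each entry is a
        ``(parent, weight)`` pair; both lists are empty for parentless nodes.
        """
        if node not in self._index:
            raise KeyError(f"unknown node {node!r}")
        act = [(e.source, e.weight) for e in self.edges
               if e.target == node and e.sign == ACTIVATING]
        inh = [(e.source, e.weight) for e in self.edges
               if e.target == node and e.sign == INHIBITING]
        return act, inh

    def in_degree(self, node: str) -> int:
        act, inh = self.parents_of(node)
        return len(act) + len(inh)

    def with_weights(self, weights: Sequence[float]) -> "SignalingNetwork":
        """A copy with the same topology, signs and node order but new
        per-edge weights (in ``self.edges`` order)."""
        if len(weights) != len(self.edges):
            raise ValueError(
                f"expected {len(self.edges)} weights, got {len(weights)}"
            )
        new_edges = tuple(
            Edge(e.source, e.target, e.sign, float(w))
            for e, w in zip(self.edges, weights)
        )
        return SignalingNetwork(self.nodes, new_edges, self.input_nodes)


# -- serialisation -------------------------------------------------------


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in ("edge-list", "json"):
            raise ValueError(f"unknown network format {format!r}")
        return format
    return "json" if path.suffix.lower() == ".json" else "edge-list"


def read_network(path: str | Path, format: str | None = None) -> SignalingNetwork:
    """Read a network from ``path`` in ``edge-list`` or ``json`` format.

    With ``format=None`` the format is inferred from the suffix (``.json`` →
    JSON, anything else → edge-list).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    text = path.read_text()
    if fmt == "json":
        return _network_from_json(text, str(path))
    return _network_from_edge_list(text, str(path))


def write_network(
    net: SignalingNetwork, path: str | Path, format: str | None = None
) -> None:
    """Write ``net`` to ``path``; ``read_network`` of the result reproduces
    ``net`` exactly (node order, signs, weights to full precision)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        doc = {
            "nodes": list(net.nodes),
            "input_nodes": list(net.input_nodes),
            "edges": [
                {"source": e.source, "target": e.target,
                 "sign": e.sign, "weight": e.weight}
                for e in net.edges
            ],
        }
        path.write_text(json.dumps(doc, indent=1) + "\n")
        return
    lines = ["# siglogic edge list: source sign weight target"]
    if net.nodes:
        lines.append("#! nodes: " + " ".join(net.nodes))
    if net.input_nodes:
        lines.append("#! inputs: " + " ".join(net.input_nodes))
    for e in net.edges:
        lines.append(f"{e.source}\t{_SIGN_CHAR[e.sign]}\t{e.weight!r}\t{e.target}")
    path.write_text("\n".join(lines) + "\n")


def _network_from_json(text: str, source: str) -> SignalingNetwork:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise NetworkParseError(f"{source}: invalid JSON: {exc}") from exc
    if not isinstance(doc, dict) or "edges" not in doc:
        raise NetworkParseError(f"{source}: expected an object with an 'edges' key")
    edges = []
    for i, rec in enumerate(doc["edges"]):
        try:
            sign = _SIGN_TOKENS[str(rec["sign"]).lower()]
            edges.append(
                Edge(rec["source"], rec["target"], sign, float(rec["weight"]))
            )
        except NetworkValidationError:
            raise
        except (KeyError, TypeError, ValueError) as exc:
            raise NetworkParseError(f"{source}: malformed edge record {i}: {exc}") from exc
    declared = list(doc.get("nodes", []))
    # node set = declared nodes plus any endpoints not declared, in order of appearance
    known = set(declared)
    for e in edges:
        for ident in (e.source, e.target):
            if ident not in known:
                declared.append(ident)
                known.add(ident)
    return SignalingNetwork(declared, edges, tuple(doc.get("input_nodes", [])))


def _network_from_edge_list(text: str, source: str) -> SignalingNetwork:
    declared: list[str] = []
    inputs: list[str] = []
    edges: list[Edge] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if line.startswith("#!"):
            body = line[2:].strip()
            if body.startswith("nodes:"):
                declared.extend(body[len("nodes:"):].split())
            elif body.startswith("inputs:"):
                inputs.extend(body[len("inputs:"):].split())
            else:
                raise NetworkParseError(
                    f"{source}:{lineno}: unknown directive {line!r}"
                )
            continue
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 4:
            raise NetworkParseError(
                f"{source}:{lineno}: expected 4 columns "
                f"'source sign weight target', got {len(fields)}: {raw!r}"
            )
        src, sign_tok, weight_tok, dst = fields
        sign = _SIGN_TOKENS.get(sign_tok.lower())
        if sign is None:
            raise NetworkParseError(
                f"{source}:{lineno}: unknown sign token {sign_tok!r} "
                "(expected one of +, -, activate, inhibit)"
            )
        try:
            weight = float(weight_tok)
        except ValueError:
            raise NetworkParseError(
                f"{source}:{lineno}: weight {weight_tok!r} is not a number"
            ) from None
        edges.append(Edge(src, dst, sign, weight))
    # node set = declared nodes (if any) plus endpoints, in order of appearance
    known = set(declared)
    for e in edges:
        for ident in (e.source, e.target):
            if ident not in known:
                declared.append(ident)
                known.add(ident)
    return SignalingNetwork(declared, edges, tuple(inputs))
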