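"""Ontology graph loading and ancestor propagation.

GO annotations of a protein are propagated to every ancestor term ("true
path rule"): a protein directly annotated with a child term is implicitly
annotated with all its parents up to the subontology root.  By default both
``is_a`` and ``part_of`` edges are followed, the standard propagation
practice; the relation set is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import obonet

from ._exceptions import StructuralError, ValidationError

NAMESPACES = ("molecular_function", "biological_process", "cellular_component")

DEFAULT_RELATIONS = frozenset({"is_a", "part_of"})


@dataclass
class OntologyGraph:
    """A DAG of ontology terms with child -> parent edges.

    ``parents`` holds only the declared (direct) parents; use
    :meth:`ancestors` for the transitive closure.
    """

    terms: set[str]
    parents: dict[str, set[str]]
    namespace: dict[str, str] = field(default_factory=dict)
    _closure: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for child, ps in self.parents.items():
            if child not in self.terms:
                raise StructuralError(f"parent map references unknown term {child!r}")
            dangling = ps - self.terms
            if dangling:
                raise StructuralError(
                    f"term {child!r} has dangling parent(s) {sorted(dangling)}"
                )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from((c, p) for c, ps in self.parents.items() for p in ps)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return
        raise StructuralError(f"ontology contains a cycle: {cycle}")

    def ancestors(self, term: str) -> frozenset[str]:
        """Transitive parent closure of ``term``, excluding ``term`` itself."""
        if term not in self.terms:
            raise KeyError(f"unknown ontology term {term!r}")
        cached = self._closure.get(term)
        if cached is not None:
            return cached
        out: set[str] = set()
        stack = list(self.parents.get(term, ()))
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.parents.get(t, ()))
        result = frozenset(out)
        self._closure[term] = result
        return result

    def with_ancestors(self, terms: set[str]) -> frozenset[str]:
        """Expand a direct annotation set with all ancestors of its members."""
        out: set[str] = set()
        for t in terms:
            out.add(t)
            out.update(self.ancestors(t))
        return frozenset(out)


def ancestors(graph: OntologyGraph, term: str) -> frozenset[str]:
    """Functional alias for :meth:`OntologyGraph.ancestors`."""
    return graph.ancestors(term)


def read_ontology(
    path: str | Path,
    relations: frozenset[str] | set[str] = DEFAULT_RELATIONS,
) -> OntologyGraph:
    """Load an OBO file into an :class:`OntologyGraph`.

    Honours ``[Term]`` stanzas with ``id``, ``namespace``, ``is_a``,
    ``relationship: part_of`` and ``is_obsolete``; everything else is
    ignored.  Obsolete terms are dropped.  Edges of relation types outside
    ``relations`` are discarded.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{path}: file not found")

    # obonet silently materializes nodes for parents that were never declared
    # in a [Term] stanza, so declared/obsolete ids are scanned up front to
    # distinguish a dangling reference (error) from an obsolete parent
    # (edge dropped).
    declared: set[str] = set()
    obsolete: set[str] = set()
    current: str | None = None
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if line == "[Term]":
            current = None
        elif line.startswith("id: ") and current is None:
            current = line[4:].strip()
            declared.add(current)
        elif line.startswith("is_obsolete:") and current is not None:
            if line.split(":", 1)[1].strip().lower() == "true":
                obsolete.add(current)

    multigraph = obonet.read_obo(str(path), ignore_obsolete=True)

    terms: set[str] = declared - obsolete
    parents: dict[str, set[str]] = {}
    namespace: dict[str, str] = {}
    for term, data in multigraph.nodes(data=True):
        if term not in terms:
            continue
        ns = data.get("namespace")
        if ns is not None:
            if ns not in NAMESPACES:
                raise ValidationError(f"term {term!r}: unknown namespace {ns!r}")
            namespace[term] = ns
    for child, parent, rel in multigraph.edges(keys=True):
        if rel not in relations or child not in terms:
            continue
        if parent not in declared:
            raise StructuralError(f"term {child!r} references undeclared parent {parent!r}")
        if parent in obsolete:
            continue
        parents.setdefault(child, set()).add(parent)
    return OntologyGraph(terms=terms, parents=parents, namespace=namespace)


def write_ontology(graph: OntologyGraph, path: str | Path) -> None:
    """Serialize a graph as a minimal OBO document (round-trip aid).

    All parent edges are emitted as ``is_a``; the distinction between edge
    types is not preserved.
    """
    lines = ["format-version: 1.2", "ontology: kinvar-synthetic", ""]
    for term in sorted(graph.terms):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {term}")
        ns = graph.namespace.get(term)
        if ns:
            lines.append(f"namespace: {ns}")
        for parent in sorted(graph.parents.get(term, ())):
            lines.append(f"is_a: {parent}")
        lines.append("")
    Path(path).write_text("\n".join(lines))
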