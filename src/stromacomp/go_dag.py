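"""Gene Ontology DAG handling: parsing, annotation propagation, ancestry queries.

The enrichment machinery needs three things from the ontology side: a validated
biological-process DAG, gene annotations propagated upward along ``is_a``/``part_of``
edges (a gene annotated to a term is implicitly annotated to every ancestor of that
term), and ancestry tests used when comparing identified term sets against
gold-standard term lists.

Edges in :class:`GoDag` run child -> parent, so graph "descendants" of a node in
the networkx sense are its ontology ancestors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: Relations treated as ancestry when propagating annotations.
DEFAULT_RELATIONS = ("is_a", "part_of")

NAMESPACES = {"biological_process", "molecular_function", "cellular_component"}


class OboParseError(ValueError):
    """Raised when an OBO file cannot be parsed; names the offending line."""


class GoDagStructureError(ValueError):
    """Raised when the term graph violates structural invariants (e.g. a cycle)."""


class UnknownTermError(KeyError):
    """Raised when a term id is looked up that is not in the DAG."""


@dataclass(frozen=True)
class GoTerm:
    """A single ontology term.

    ``parents`` maps parent term id -> relation label (``is_a`` or ``part_of``).
    """

    term_id: str
    name: str
    namespace: str
    parents: Mapping[str, str] = field(default_factory=dict)


class GoDag:
    """A validated, single-namespace GO term DAG.

    Parameters
    ----------
    terms:
        Iterable of :class:`GoTerm`. Parent references must resolve to terms in
        the same iterable; edges to missing terms raise.
    """

    def __init__(self, terms: Iterable[GoTerm]):
        self.terms: dict[str, GoTerm] = {}
        graph = nx.DiGraph()
        for term in terms:
            if term.term_id in self.terms:
                raise GoDagStructureError(f"duplicate term id {term.term_id!r}")
            self.terms[term.term_id] = term
            graph.add_node(term.term_id)
        for term in self.terms.values():
            for parent, relation in term.parents.items():
                if parent not in self.terms:
                    raise GoDagStructureError(
                        f"term {term.term_id!r} has unknown parent {parent!r}"
                    )
                graph.add_edge(term.term_id, parent, relation=relation)
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise GoDagStructureError(f"cycle detected in term graph: {cycle}")
        self.graph = graph

    # -- basic queries ---------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def _require(self, term_id: str) -> None:
        if term_id not in self.terms:
            raise UnknownTermError(f"unknown term {term_id!r}")

    def parents(self, term_id: str) -> set[str]:
        self._require(term_id)
        return set(self.graph.successors(term_id))

    def children(self, term_id: str) -> set[str]:
        self._require(term_id)
        return set(self.graph.predecessors(term_id))

    def roots(self) -> set[str]:
        return {t for t in self.terms if self.graph.out_degree(t) == 0}

    def leaves(self) -> set[str]:
        return {t for t in self.terms if self.graph.in_degree(t) == 0}

    def ancestors(self, term_id: str) -> set[str]:
        """Transitive closure over parent edges, excluding the term itself."""
        self._require(term_id)
        return nx.descendants(self.graph, term_id)

    def descendants(self, term_id: str) -> set[str]:
        """All terms below ``term_id``, excluding the term itself."""
        self._require(term_id)
        return nx.ancestors(self.graph, term_id)

    def is_descendant_of_any(
        self, term_id: str, reference: set[str], strict: bool = False
    ) -> bool:
        """Whether ``term_id`` falls under any reference term.

        Inclusive mode (default) counts a term that is itself a member of
        ``reference``; strict mode requires the term to lie strictly below a
        reference term and not be a member itself. Overlap statistics use the
        inclusive convention, the "child node" statistic the strict one.
        """
        self._require(term_id)
        if term_id in reference:
            return not strict
        return bool(self.ancestors(term_id) & reference)

    def bottom_up_order(self) -> list[str]:
        """Terms sorted children-before-parents, ties broken by term id.

        Ordered by height (longest path down to a leaf), so every child of a
        term appears before the term itself; lexicographic tie-break makes the
        order reproducible.
        """
        height: dict[str, int] = {}
        for node in nx.topological_sort(self.graph):
            kids = list(self.graph.predecessors(node))
            height[node] = 0 if not kids else 1 + max(height[k] for k in kids)
        return sorted(self.terms, key=lambda t: (height[t], t))

    # -- export ----------------------------------------------------------

    def to_dot(self, term_ids: set[str] | None = None) -> str:
        """DOT rendering of the subgraph induced by ``term_ids`` (default: all)."""
        nodes = set(self.terms) if term_ids is None else set(term_ids)
        for t in nodes:
            self._require(t)
        lines = ["digraph go {", '  rankdir="BT";']
        for t in sorted(nodes):
            label = self.terms[t].name.replace('"', r"\"")
            lines.append(f'  "{t}" [label="{t}\\n{label}"];')
        for child, parent, data in self.graph.edges(data=True):
            if child in nodes and parent in nodes:
                lines.append(
                    f'  "{child}" -> "{parent}" [label="{data.get("relation", "is_a")}"];'
                )
        lines.append("}")
        return "\n".join(lines) + "\n"


@dataclass
class AnnotationSet:
    """Direct and ancestry-propagated gene -> term annotations.

    ``propagated`` is closed under parent edges; ``term_to_genes`` is the exact
    inverse of ``propagated``.
    """

    direct: dict[str, set[str]]
    propagated: dict[str, set[str]]
    term_to_genes: dict[str, set[str]]

    def genes(self) -> set[str]:
        return set(self.propagated)


def _prescan_obo(path: str) -> None:
    """Cheap line-level syntax check so parse errors can name a line."""
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("!"):
                continue
            if line.startswith("[") != line.endswith("]") and line.startswith("["):
                raise OboParseError(f"{path}:{lineno}: malformed stanza header {line!r}")
            if line.startswith("[") and line.endswith("]"):
                continue
            if ":" not in line:
                raise OboParseError(
                    f"{path}:{lineno}: expected 'key: value' line, got {line!r}"
                )


def parse_obo(
    path: str,
    namespace: str = "biological_process",
    relations: Iterable[str] = DEFAULT_RELATIONS,
) -> GoDag:
    """Parse an OBO 1.2 file into a single-namespace :class:`GoDag`.

    Obsolete terms are excluded; terms of other namespaces and edges to them are
    dropped with a logged count. Only ``relations`` (default ``is_a`` and
    ``part_of``) become parent edges.
    """
    if namespace not in NAMESPACES:
        raise ValueError(f"unknown namespace {namespace!r}")
    _prescan_obo(path)
    try:
        graph = obonet.read_obo(path, ignore_obsolete=True)
    except Exception as exc:  # pragma: no cover - obonet-internal failures
        raise OboParseError(f"failed to parse {path}: {exc}") from exc

    relations = set(relations)
    keep: dict[str, dict] = {}
    dropped_ns = 0
    for node, data in graph.nodes(data=True):
        ns = data.get("namespace", namespace)
        if ns != namespace:
            dropped_ns += 1
            continue
        keep[node] = data
    if dropped_ns:
        logger.info("parse_obo: dropped %d terms outside namespace %s", dropped_ns, namespace)

    terms = []
    for node, data in keep.items():
        parents: dict[str, str] = {}
        for _, parent, rel in graph.out_edges(node, keys=True):
            if rel in relations and parent in keep:
                parents[parent] = rel
        terms.append(
            GoTerm(
                term_id=node,
                name=data.get("name", node),
                namespace=namespace,
                parents=parents,
            )
        )
    return GoDag(terms)


def propagate_annotations(
    dag: GoDag,
    direct: Mapping[str, Iterable[str]],
    on_unknown: str = "drop",
) -> AnnotationSet:
    """Close direct annotations under ancestry.

    Each gene annotated to a term becomes annotated to every ancestor of that
    term. Annotations to terms absent from ``dag`` are dropped with a logged
    count (``on_unknown='drop'``) or raise (``on_unknown='error'``).
    """
    if on_unknown not in {"drop", "error"}:
        raise ValueError(f"on_unknown must be 'drop' or 'error', got {on_unknown!r}")
    clean_direct: dict[str, set[str]] = {}
    propagated: dict[str, set[str]] = {}
    term_to_genes: dict[str, set[str]] = {}
    n_unknown = 0
    # cache ancestor sets; annotation files typically reuse few distinct terms
    anc_cache: dict[str, set[str]] = {}
    for gene, term_ids in direct.items():
        kept: set[str] = set()
        for term in term_ids:
            if term not in dag:
                if on_unknown == "error":
                    raise UnknownTermError(
                        f"gene {gene!r} annotated to unknown term {term!r}"
                    )
                n_unknown += 1
                continue
            kept.add(term)
        if not kept:
            continue
        closure = set(kept)
        for term in kept:
            if term not in anc_cache:
                anc_cache[term] = dag.ancestors(term)
            closure |= anc_cache[term]
        clean_direct[gene] = kept
        propagated[gene] = closure
        for term in closure:
            term_to_genes.setdefault(term, set()).add(gene)
    if n_unknown:
        logger.warning("propagate_annotations: dropped %d annotations to unknown terms", n_unknown)
    return AnnotationSet(direct=clean_direct, propagated=propagated, term_to_genes=term_to_genes)
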