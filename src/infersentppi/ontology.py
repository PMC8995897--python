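"""Gene Ontology DAG: OBO parsing, structural queries, information content.

The GO graph is a rooted directed acyclic graph per namespace. Edges point
from child to parent and carry one of two relation types, ``is_a`` or
``part_of`` — the two relations the downstream similarity measures weight;
any other relation found in the OBO file is dropped (counted in
:attr:`GoGraph.n_dropped_edges`).

Information content follows the annotation-frequency (Resnik) definition:
``ic(t) = -ln(freq(t) / freq(root))`` where ``freq(t)`` counts distinct
(protein, term') annotation pairs with term' in the descendants-or-self
set of ``t``. Natural log throughout.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import obonet

GO_ID_RE = re.compile(r"GO:\d{7}$")

RELATIONS = ("is_a", "part_of")


class OboParseError(ValueError):
    """Raised when an OBO file cannot be parsed into a valid GO DAG."""


@dataclass
class GoTerm:
    """A single GO term: accession, name, namespace and typed parent edges."""

    term_id: str
    name: str
    namespace: str
    parents: list[tuple[str, str]] = field(default_factory=list)  # (parent_id, relation)
    obsolete: bool = False


class GoGraph:
    """The GO DAG over one or more namespaces.

    Parameters
    ----------
    terms : mapping of term_id -> GoTerm
    n_dropped_edges : number of edges whose relation type was neither
        ``is_a`` nor ``part_of`` and was therefore discarded at parse time.
    """

    def __init__(self, terms: Mapping[str, GoTerm], n_dropped_edges: int = 0):
        self.terms: dict[str, GoTerm] = dict(terms)
        self.n_dropped_edges = n_dropped_edges
        self._children: dict[str, list[tuple[str, str]]] = {t: [] for t in self.terms}
        for t in self.terms.values():
            for pid, rel in t.parents:
                if pid not in self.terms:
                    raise OboParseError(f"term {t.term_id} has unknown parent {pid}")
                if self.terms[pid].namespace != t.namespace:
                    raise OboParseError(
                        f"edge {t.term_id} -> {pid} crosses namespaces"
                    )
                self._children[pid].append((t.term_id, rel))
        self.roots: dict[str, str] = {}
        for t in self.terms.values():
            if not t.parents:
                if t.namespace in self.roots:
                    raise OboParseError(
                        f"namespace {t.namespace} has multiple roots: "
                        f"{self.roots[t.namespace]}, {t.term_id}"
                    )
                self.roots[t.namespace] = t.term_id
        self._validate_acyclic()
        self._depth_cache: dict[str, int] = {}

    # -- construction -------------------------------------------------

    def _validate_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for t in self.terms.values():
            for pid, _ in t.parents:
                g.add_edge(t.term_id, pid)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OboParseError(f"ontology graph contains a cycle: {cycle}")
        self._nx = g  # child -> parent edges

    # -- queries ------------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def namespace_of(self, term_id: str) -> str:
        return self.terms[term_id].namespace

    def root_of(self, term_id: str) -> str:
        return self.roots[self.namespace_of(term_id)]

    def parents(self, term_id: str) -> list[tuple[str, str]]:
        return self.terms[term_id].parents

    def children(self, term_id: str) -> list[tuple[str, str]]:
        """Typed child edges of ``term_id`` as (child_id, relation)."""
        return self._children[term_id]

    def ancestors(self, term_id: str) -> set[str]:
        """Transitive closure over parent edges, including the term itself."""
        if term_id not in self.terms:
            raise KeyError(term_id)
        return {term_id} | nx.descendants(self._nx, term_id)

    def descendants(self, term_id: str) -> set[str]:
        """Transitive closure over child edges, including the term itself."""
        if term_id not in self.terms:
            raise KeyError(term_id)
        return {term_id} | nx.ancestors(self._nx, term_id)

    def depth(self, term_id: str) -> int:
        """Length of the longest path from the namespace root to the term.

        The root has depth 0. Longest (not shortest) paths are the path
        primitive of the edge-based similarity measure implemented in
        :mod:`infersentppi.baselines`.
        """
        if term_id not in self.terms:
            raise KeyError(term_id)
        if term_id not in self._depth_cache:
            for t in self.topological_order():
                ps = self.terms[t].parents
                self._depth_cache[t] = (
                    0 if not ps else 1 + max(self._depth_cache[p] for p, _ in ps)
                )
        return self._depth_cache[term_id]

    def longest_path_length(self, ancestor: str, term_id: str) -> int:
        """Longest path length from ``ancestor`` down to ``term_id``.

        Raises ValueError if ``ancestor`` is not an ancestor of ``term_id``.
        """
        if ancestor == term_id:
            return 0
        anc = self.ancestors(term_id)
        if ancestor not in anc:
            raise ValueError(f"{ancestor} is not an ancestor of {term_id}")
        # DP over the induced ancestor subgraph, from ancestor downward
        best = {ancestor: 0}
        for t in self.topological_order():
            if t not in anc or t == ancestor:
                continue
            cand = [best[p] + 1 for p, _ in self.terms[t].parents if p in best]
            if cand:
                best[t] = max(cand)
        return best[term_id]

    def topological_order(self) -> list[str]:
        """Terms ordered roots first (every parent precedes its children)."""
        return list(reversed(list(nx.topological_sort(self._nx))))

    def common_ancestors(self, t1: str, t2: str) -> set[str]:
        return self.ancestors(t1) & self.ancestors(t2)


# module-level functional aliases matching the operation surface
def ancestors(g: GoGraph, term_id: str) -> set[str]:
    return g.ancestors(term_id)


def depth(g: GoGraph, term_id: str) -> int:
    return g.depth(term_id)


# -- OBO parsing ------------------------------------------------------


def _prescan_obo(path: str) -> None:
    """Cheap structural validation producing line-numbered errors.

    Checks only that every non-blank line inside a stanza is a
    ``tag: value`` pair; the full semantic parse is delegated to obonet.
    """
    with open(path) as fh:
        in_stanza = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("!"):
                continue
            if line.startswith("[") and line.endswith("]"):
                in_stanza = True
                continue
            if ":" not in line:
                where = "stanza" if in_stanza else "header"
                raise OboParseError(
                    f"{path}:{lineno}: malformed {where} line: {line!r}"
                )


def parse_obo(path: str) -> GoGraph:
    """Parse an OBO 1.2/1.4 flat file into a :class:`GoGraph`.

    Obsolete terms are dropped (obonet excludes them). Only ``is_a`` and
    ``relationship: part_of`` edges are retained; other relation types are
    counted into ``GoGraph.n_dropped_edges``.
    """
    _prescan_obo(path)
    try:
        net = obonet.read_obo(path)
    except Exception as exc:  # obonet raises assorted ValueErrors
        raise OboParseError(f"{path}: {exc}") from exc

    terms: dict[str, GoTerm] = {}
    dropped = 0
    for node, data in net.nodes(data=True):
        if not node.startswith("GO:"):
            continue
        terms[node] = GoTerm(
            term_id=node,
            name=data.get("name", ""),
            namespace=data.get("namespace", "biological_process"),
            parents=[],
        )
    for child, parent, rel in net.edges(keys=True):
        if child not in terms or parent not in terms:
            dropped += 1
            continue
        if rel in RELATIONS:
            terms[child].parents.append((parent, rel))
        else:
            dropped += 1
    for t in terms.values():
        t.parents.sort()
    return GoGraph(terms, n_dropped_edges=dropped)


# -- information content ----------------------------------------------


@dataclass
class IcTable:
    """Annotation-frequency information content per term.

    ``term_freq[t]`` counts distinct (protein, term') annotation pairs with
    term' in descendants-or-self(t); ``ic[t] = -ln(term_freq[t] /
    term_freq[root])``. Terms never reached by an annotation are absent:
    similarity calls touching them raise rather than silently scoring 0.
    """

    ic: dict[str, float]
    term_freq: dict[str, int]

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.ic

    def __getitem__(self, term_id: str) -> float:
        if term_id not in self.ic:
            raise KeyError(
                f"term {term_id} has no annotation-frequency IC "
                "(never annotated in the corpus)"
            )
        return self.ic[term_id]


def compute_ic(g: GoGraph, annotations) -> IcTable:
    """Compute the annotation-frequency IC table from a PGAA.

    ``annotations`` is a :class:`~infersentppi.annotation.WeightedAnnotationSet`
    (or any object with an ``axioms`` mapping protein -> [(term, weight)]).
    Weights do not enter the frequency count: frequency is over distinct
    (protein, term) pairs, propagated to every ancestor.
    """
    axioms = annotations.axioms
    if not axioms:
        raise ValueError("annotation set is empty; IC is undefined")
    freq: dict[str, int] = {}
    for protein, terms in axioms.items():
        for term_id, _w in terms:
            if term_id not in g:
                continue
            for a in g.ancestors(term_id):
                freq[a] = freq.get(a, 0) + 1
    if not freq:
        raise ValueError("no annotated term is present in the ontology")
    ic: dict[str, float] = {}
    for t, f in freq.items():
        root_f = freq[g.root_of(t)]
        ic[t] = -math.log(f / root_f)
    return IcTable(ic=ic, term_freq=freq)
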