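"""Phenotype ontology: is_a DAG, ancestor closures, information content, depth.

The ontology is a rooted (possibly multi-rooted) directed acyclic graph of
phenotype terms connected by ``is_a`` edges, in the style of the Human
Phenotype Ontology (HPO), the Mammalian Phenotype Ontology (MP), or a
cross-species merge of the two.  Three derived quantities drive everything
downstream:

* the *ancestor closure* of a term — the reflexive transitive closure over
  ``is_a``, implementing the true path rule (annotation with a term implies
  annotation with all of its ancestors);
* the *information content* IC(t) = -ln(n(t)/N), where n(t) is the number of
  annotated entities (diseases or mouse mutants) whose closure-expanded term
  set contains t, out of N entities in the corpus;
* the *depth* of a term — the length of the longest ``is_a`` path from the
  term up to a root.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

__all__ = [
    "Term",
    "Ontology",
    "OntologyError",
    "parse_obo",
    "write_obo",
    "compute_ic",
]


class OntologyError(ValueError):
    """Raised for structural problems: cycles, dangling references, unknown ids."""


@dataclass(frozen=True)
class Term:
    """A single ontology term.

    ``parent_ids`` are the direct ``is_a`` parents.  Obsolete terms carry no
    parents and are excluded from closures, IC and depth.
    """

    id: str
    name: str = ""
    parent_ids: frozenset[str] = field(default_factory=frozenset)
    obsolete: bool = False


class Ontology:
    """An is_a DAG of phenotype terms with precomputed closures and depths.

    Parameters
    ----------
    terms
        Mapping id -> :class:`Term`.  Validated on construction: every parent
        must exist and be non-obsolete, and the is_a graph must be acyclic.
    """

    def __init__(self, terms: Mapping[str, Term]):
        self.terms: dict[str, Term] = dict(terms)
        for term in self.terms.values():
            if not term.id:
                raise OntologyError("term with empty id")
            for pid in term.parent_ids:
                if pid not in self.terms:
                    raise OntologyError(
                        f"term {term.id!r} has is_a reference to unknown id {pid!r}"
                    )
            if term.obsolete and term.parent_ids:
                raise OntologyError(
                    f"obsolete term {term.id!r} must not carry parents"
                )

        # Live (non-obsolete) subgraph; edges point child -> parent.
        self._graph = nx.DiGraph()
        live = [t for t in self.terms.values() if not t.obsolete]
        self._graph.add_nodes_from(t.id for t in live)
        for term in live:
            for pid in term.parent_ids:
                if self.terms[pid].obsolete:
                    raise OntologyError(
                        f"term {term.id!r} has is_a reference to obsolete term {pid!r}"
                    )
                self._graph.add_edge(term.id, pid)

        if not nx.is_directed_acyclic_graph(self._graph):
            cycle = nx.find_cycle(self._graph)
            raise OntologyError(f"is_a cycle detected involving term {cycle[0][0]!r}")

        self.root_ids: frozenset[str] = frozenset(
            t.id for t in live if not t.parent_ids
        )

        # Closures and depths in topological order (parents before children).
        order = list(reversed(list(nx.topological_sort(self._graph))))
        self._closure: dict[str, frozenset[str]] = {}
        self._depth: dict[str, int] = {}
        for tid in order:
            parents = self.terms[tid].parent_ids
            clo: set[str] = {tid}
            for pid in parents:
                clo |= self._closure[pid]
            self._closure[tid] = frozenset(clo)
            self._depth[tid] = (
                0 if not parents else 1 + max(self._depth[p] for p in parents)
            )

        #: IC per term in nats; terms with zero annotation frequency are absent.
        self.ic: dict[str, float] = {}

    # -- basic queries -----------------------------------------------------

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    @property
    def live_term_ids(self) -> list[str]:
        """Ids of non-obsolete terms, in deterministic (insertion) order."""
        return [t.id for t in self.terms.values() if not t.obsolete]

    def _require_live(self, term_id: str) -> None:
        if term_id not in self.terms:
            raise OntologyError(f"unknown term id {term_id!r}")
        if self.terms[term_id].obsolete:
            raise OntologyError(f"term {term_id!r} is obsolete")

    def ancestors(self, term_id: str) -> frozenset[str]:
        """Reflexive transitive is_a closure of ``term_id`` (includes itself)."""
        self._require_live(term_id)
        return self._closure[term_id]

    def closure_of_set(self, term_ids: Iterable[str]) -> frozenset[str]:
        """Union of ancestor closures over a set of terms (true path rule)."""
        out: set[str] = set()
        for tid in term_ids:
            out |= self.ancestors(tid)
        return frozenset(out)

    def max_depth(self, term_id: str) -> int:
        """Length of the longest is_a path from ``term_id`` to any root."""
        self._require_live(term_id)
        return self._depth[term_id]

    @property
    def has_ic(self) -> bool:
        return bool(self.ic)


def parse_obo(stream: IO[str] | str) -> Ontology:
    """Parse an OBO 1.2-style flat file into an :class:`Ontology`.

    Only ``id``, ``name``, ``is_a`` and ``is_obsolete`` are interpreted;
    other relationship types are ignored with a warning.  Obsolete terms are
    retained but stripped of any parents.  An ``is_a`` reference to an id
    with no ``[Term]`` stanza, or a cycle, is an error.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    # obonet warns on the root logger when the optional header is minimal
    header_filter = lambda record: "ontology keys are both missing" not in record.getMessage()  # noqa: E731
    root_logger = logging.getLogger()
    root_logger.addFilter(header_filter)
    try:
        graph = obonet.read_obo(stream, ignore_obsolete=False)
    finally:
        root_logger.removeFilter(header_filter)

    ignored_relations = sorted(
        {key for _, _, key in graph.edges(keys=True) if key != "is_a"}
    )
    if ignored_relations:
        logger.warning(
            "ignoring non-is_a relationship types: %s", ", ".join(ignored_relations)
        )

    # obonet materializes is_a targets without their own stanza as bare nodes.
    dangling = [n for n, data in graph.nodes(data=True) if "name" not in data]
    if dangling:
        raise OntologyError(
            f"is_a references unknown term id {dangling[0]!r} "
            "(no [Term] stanza found)"
        )

    terms: dict[str, Term] = {}
    for tid, data in graph.nodes(data=True):
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        parents = frozenset() if obsolete else frozenset(
            p for c, p, key in graph.out_edges(tid, keys=True) if key == "is_a"
        )
        terms[tid] = Term(
            id=tid, name=data.get("name", ""), parent_ids=parents, obsolete=obsolete
        )
    return Ontology(terms)


def write_obo(ontology: Ontology, stream: IO[str]) -> None:
    """Serialize the subset dialect read by :func:`parse_obo` (UTF-8 text)."""
    stream.write("format-version: 1.2\n")
    for tid in sorted(ontology.terms):
        term = ontology.terms[tid]
        stream.write(f"\n[Term]\nid: {term.id}\nname: {term.name}\n")
        for pid in sorted(term.parent_ids):
            stream.write(f"is_a: {pid} ! {ontology.terms[pid].name}\n")
        if term.obsolete:
            stream.write("is_obsolete: true\n")


def compute_ic(
    ontology: Ontology, corpus: Iterable[tuple[str, Iterable[str]]]
) -> Ontology:
    """Set per-term information content from an annotation corpus.

    Each corpus entry is ``(source_id, term_ids)`` — a disease or mouse mutant
    with its raw phenotype-term set.  Term sets are closure-expanded before
    counting, so n(parent) >= n(child) and IC is antitone along is_a.  Terms
    annotating no source get no IC entry (treated as zero weight downstream,
    avoiding -ln 0).  Returns the same (mutated) ontology for chaining.
    """
    counts: dict[str, int] = {}
    n_sources = 0
    for _, term_ids in corpus:
        n_sources += 1
        for tid in ontology.closure_of_set(term_ids):
            counts[tid] = counts.get(tid, 0) + 1
    if n_sources == 0:
        raise ValueError("IC corpus is empty")
    ontology.ic = {
        tid: -math.log(n / n_sources) for tid, n in counts.items()
    }
    return ontology
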