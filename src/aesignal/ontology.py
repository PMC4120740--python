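"""In-memory model of an adverse-event ontology.

An ontology here is a set of term records connected by an asserted is-a DAG,
plus three kinds of extra structure used by the reasoner:

* ``located_in`` restrictions — an AE term may point at the single anatomical
  entity where its abnormal bodily process takes place;
* equivalence axioms — full definitions of anatomy-based AE groups of the
  form ``G == genus AND (located_in some filler)``;
* an anatomy partonomy — ``part_of`` pairs between anatomy terms.

AE terms follow a single-inheritance editorial policy: the clinical-outcome
parent is asserted and anatomy parents are obtained by reasoning, so an AE
term normally carries exactly one asserted parent.  Anatomy terms (imported
UBERON-style) may carry several is-a parents.  ``inferred_parents`` starts
empty and is populated by :func:`aesignal.reasoner.classify`.
"""

from __future__ import annotations

import bisect
import copy
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Set, Tuple

import networkx as nx

from .errors import OntologyError

TermId = str


@dataclass
class Term:
    """One ontology term.

    ``asserted_parents`` and ``xrefs`` are stored sorted and de-duplicated so
    that structural equality is insensitive to input order.  ``location`` is
    the filler of an optional ``located_in`` restriction; multi-location
    terms are rejected at load time.  ``is_anatomy`` separates anatomy terms
    from AE terms within the single ontology object.
    """

    id: TermId
    label: str = ""
    asserted_parents: List[TermId] = field(default_factory=list)
    location: Optional[TermId] = None
    xrefs: List[str] = field(default_factory=list)
    is_anatomy: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise OntologyError("term id must be non-empty")
        self.asserted_parents = sorted(set(self.asserted_parents))
        self.xrefs = sorted(set(self.xrefs))


@dataclass(frozen=True, order=True)
class EquivalenceAxiom:
    """Full definition ``defined_term == genus AND located_in location_filler``.

    ``genus`` is an AE term (typically the 'adverse event' root) and
    ``location_filler`` an anatomy term.
    """

    defined_term: TermId
    genus: TermId
    location_filler: TermId


@dataclass(frozen=True)
class Violation:
    """One structural problem reported by :meth:`Ontology.validate_structure`."""

    kind: str
    subject: TermId
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.kind}] {self.subject}: {self.message}"


@dataclass
class Ontology:
    terms: Dict[TermId, Term] = field(default_factory=dict)
    equivalence_axioms: List[EquivalenceAxiom] = field(default_factory=list)
    inferred_parents: Dict[TermId, List[TermId]] = field(default_factory=dict)
    anatomy_partonomy: List[Tuple[TermId, TermId]] = field(default_factory=list)
    # provenance of inferred edges; excluded from structural equality because
    # a serialization round-trip cannot reconstruct it
    inferred_provenance: Dict[Tuple[TermId, TermId], EquivalenceAxiom] = field(
        default_factory=dict, compare=False
    )

    # -- basic container protocol -------------------------------------------------
    def __contains__(self, term_id: TermId) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self) -> Iterator[Term]:
        return iter(self.terms.values())

    def label(self, term_id: TermId) -> str:
        return self.terms[term_id].label if term_id in self.terms else ""

    def is_anatomy(self, term_id: TermId) -> bool:
        self._require(term_id)
        return self.terms[term_id].is_anatomy

    def ae_terms(self) -> List[Term]:
        return [t for t in self.terms.values() if not t.is_anatomy]

    def anatomy_terms(self) -> List[Term]:
        return [t for t in self.terms.values() if t.is_anatomy]

    def copy(self) -> "Ontology":
        return copy.deepcopy(self)

    def _require(self, term_id: TermId) -> None:
        if term_id not in self.terms:
            raise OntologyError(f"unknown term id: {term_id!r}")

    # -- construction -------------------------------------------------------------
    def add_term(self, term: Term) -> "Ontology":
        """Add one term; its parents must already exist."""
        if term.id in self.terms:
            raise OntologyError(f"duplicate term id: {term.id!r}")
        if term.id in term.asserted_parents:
            raise OntologyError(f"term {term.id!r} lists itself as a parent")
        for parent in term.asserted_parents:
            if parent not in self.terms:
                raise OntologyError(
                    f"term {term.id!r} references missing parent {parent!r}"
                )
        self.terms[term.id] = term
        return self

    def add_terms(self, terms: Iterable[Term]) -> "Ontology":
        """Add a batch of terms that may reference each other as parents."""
        batch = list(terms)
        for term in batch:
            if term.id in self.terms:
                raise OntologyError(f"duplicate term id: {term.id!r}")
            self.terms[term.id] = term
        for term in batch:
            if term.id in term.asserted_parents:
                raise OntologyError(f"term {term.id!r} lists itself as a parent")
            for parent in term.asserted_parents:
                if parent not in self.terms:
                    raise OntologyError(
                        f"term {term.id!r} references missing parent {parent!r}"
                    )
        return self

    def add_axiom(self, axiom: EquivalenceAxiom) -> "Ontology":
        for ref in (axiom.defined_term, axiom.genus, axiom.location_filler):
            self._require(ref)
        if self.terms[axiom.genus].is_anatomy:
            raise OntologyError(f"axiom genus {axiom.genus!r} is an anatomy term")
        if not self.terms[axiom.location_filler].is_anatomy:
            raise OntologyError(
                f"axiom filler {axiom.location_filler!r} is not an anatomy term"
            )
        for existing in self.equivalence_axioms:
            if existing.defined_term == axiom.defined_term:
                if existing == axiom:
                    return self
                raise OntologyError(
                    f"term {axiom.defined_term!r} already carries a different "
                    "equivalence axiom (one full definition per term)"
                )
        bisect.insort(self.equivalence_axioms, axiom)
        return self

    def add_part_of(self, part: TermId, whole: TermId) -> "Ontology":
        self._require(part)
        self._require(whole)
        if not (self.terms[part].is_anatomy and self.terms[whole].is_anatomy):
            raise OntologyError(
                f"part_of must link anatomy terms: {part!r} part_of {whole!r}"
            )
        pair = (part, whole)
        if pair not in self.anatomy_partonomy:
            bisect.insort(self.anatomy_partonomy, pair)
        return self

    # -- queries ------------------------------------------------------------------
    def parents(self, term_id: TermId, include_inferred: bool = False) -> List[TermId]:
        self._require(term_id)
        out = list(self.terms[term_id].asserted_parents)
        if include_inferred:
            out.extend(self.inferred_parents.get(term_id, []))
        return out

    def ancestors(self, term_id: TermId, include_inferred: bool = False) -> Set[TermId]:
        """Reflexive-free transitive closure over parent edges."""
        self._require(term_id)
        seen: Set[TermId] = set()
        stack = self.parents(term_id, include_inferred)
        while stack:
            cur = stack.pop()
            if cur in seen:
                continue
            seen.add(cur)
            if cur in self.terms:
                stack.extend(self.parents(cur, include_inferred))
        return seen

    def roots(self) -> List[TermId]:
        return sorted(
            t.id for t in self.terms.values() if not t.asserted_parents
        )

    # -- validation ---------------------------------------------------------------
    def validate_structure(
        self, enforce_single_inheritance: bool = True
    ) -> List[Violation]:
        """Return every structural violation; an empty list means valid.

        Checks: dangling references (parents, locations, partonomy, axioms),
        self-parentage, cycles in the subsumption and anatomy graphs, non-
        anatomy ``located_in`` fillers, and — when enforcement is on — AE
        terms carrying two or more asserted parents.
        """
        out: List[Violation] = []
        for term in self.terms.values():
            if term.id in term.asserted_parents:
                out.append(
                    Violation("self-parent", term.id, "term is its own parent")
                )
            for parent in term.asserted_parents:
                if parent not in self.terms:
                    out.append(
                        Violation(
                            "dangling-parent",
                            term.id,
                            f"asserted parent {parent!r} does not exist",
                        )
                    )
            for parent in self.inferred_parents.get(term.id, []):
                if parent not in self.terms:
                    out.append(
                        Violation(
                            "dangling-parent",
                            term.id,
                            f"inferred parent {parent!r} does not exist",
                        )
                    )
            if term.location is not None:
                if term.location not in self.terms:
                    out.append(
                        Violation(
                            "dangling-location",
                            term.id,
                            f"located_in filler {term.location!r} does not exist",
                        )
                    )
                elif not self.terms[term.location].is_anatomy:
                    out.append(
                        Violation(
                            "location-not-anatomy",
                            term.id,
                            f"located_in filler {term.location!r} is not anatomy",
                        )
                    )
            if (
                enforce_single_inheritance
                and not term.is_anatomy
                and len(term.asserted_parents) > 1
            ):
                out.append(
                    Violation(
                        "multiple-inheritance",
                        term.id,
                        "AE term has %d asserted parents: %s"
                        % (len(term.asserted_parents), ", ".join(term.asserted_parents)),
                    )
                )
        for part, whole in self.anatomy_partonomy:
            for ref in (part, whole):
                if ref not in self.terms:
                    out.append(
                        Violation(
                            "dangling-partonomy",
                            part,
                            f"part_of endpoint {ref!r} does not exist",
                        )
                    )
            if all(r in self.terms for r in (part, whole)) and not (
                self.terms[part].is_anatomy and self.terms[whole].is_anatomy
            ):
                out.append(
                    Violation(
                        "partonomy-not-anatomy",
                        part,
                        f"part_of pair ({part!r}, {whole!r}) links non-anatomy terms",
                    )
                )
        for axiom in self.equivalence_axioms:
            for ref in (axiom.defined_term, axiom.genus, axiom.location_filler):
                if ref not in self.terms:
                    out.append(
                        Violation(
                            "dangling-axiom",
                            axiom.defined_term,
                            f"axiom references missing term {ref!r}",
                        )
                    )
            if axiom.genus in self.terms and self.terms[axiom.genus].is_anatomy:
                out.append(
                    Violation(
                        "axiom-genus-not-ae",
                        axiom.defined_term,
                        f"axiom genus {axiom.genus!r} is an anatomy term",
                    )
                )
            if (
                axiom.location_filler in self.terms
                and not self.terms[axiom.location_filler].is_anatomy
            ):
                out.append(
                    Violation(
                        "axiom-filler-not-anatomy",
                        axiom.defined_term,
                        f"axiom filler {axiom.location_filler!r} is not anatomy",
                    )
                )
        out.extend(self._cycle_violations())
        return out

    def _cycle_violations(self) -> List[Violation]:
        out: List[Violation] = []
        seen_components: Set[frozenset] = set()

        def check(graph: nx.DiGraph, kind: str) -> None:
            for component in nx.strongly_connected_components(graph):
                loop = len(component) > 1 or graph.has_edge(
                    next(iter(component)), next(iter(component))
                )
                if loop:
                    key = frozenset(component)
                    if key in seen_components:
                        continue
                    seen_components.add(key)
                    nodes = sorted(component)
                    out.append(
                        Violation(
                            "cycle", nodes[0], f"{kind} cycle through " + ", ".join(nodes)
                        )
                    )

        sub = nx.DiGraph()
        sub.add_nodes_from(self.terms)
        for term in self.terms.values():
            for parent in term.asserted_parents:
                if parent in self.terms:
                    sub.add_edge(term.id, parent)
        for child, parents in self.inferred_parents.items():
            for parent in parents:
                if child in self.terms and parent in self.terms:
                    sub.add_edge(child, parent)
        check(sub, "subsumption")

        anat = nx.DiGraph()
        anat.add_nodes_from(t.id for t in self.anatomy_terms())
        for term in self.anatomy_terms():
            for parent in term.asserted_parents:
                if parent in self.terms and self.terms[parent].is_anatomy:
                    anat.add_edge(term.id, parent)
        for part, whole in self.anatomy_partonomy:
            if part in self.terms and whole in self.terms:
                anat.add_edge(part, whole)
        check(anat, "anatomy")
        return out
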