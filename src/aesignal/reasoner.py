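"""Structural subsumption reasoner for anatomy-defined AE groups.

AE terms are asserted under their clinical-outcome parent only; anatomy
parents are recovered here.  For every equivalence axiom
``G == genus AND (located_in some F')`` and every AE term ``X`` whose
effective location ``F`` lies at or under ``F'`` in the anatomy hierarchy,
``X`` is placed under ``G`` whenever ``X`` already sits at or under the
genus.  The rule is saturated to a fixed point, so groups can chain through
one another; the final edge set is then transitively reduced so that
``inferred_parents`` holds only *direct* new parents (the full closure stays
available through ``Ontology.ancestors(..., include_inferred=True)``).

An AE term without its own ``located_in`` restriction inherits the filler of
its nearest asserted ancestor that has one; anatomy subsumption follows both
is-a and part_of edges by default (``use_partof=False`` restricts it to
is-a).  :func:`oracle_classify` re-implements the same contract as a naive
quadratic fixed point with no shared code, for use as an independent test
oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Set, Tuple

from .errors import ClassificationError, OntologyError
from .ontology import EquivalenceAxiom, Ontology, TermId


@dataclass(frozen=True)
class InferredEdge:
    """One reasoner-produced parent link with the axiom that yielded it."""

    child: TermId
    parent: TermId
    axiom: EquivalenceAxiom


def anatomy_subsumes(
    ontology: Ontology,
    general: TermId,
    specific: TermId,
    use_partof: bool = True,
) -> bool:
    """True iff ``specific`` reaches ``general`` through is-a and (optionally)
    part_of edges in the anatomy hierarchy; reflexive."""
    for term_id in (general, specific):
        if not ontology.is_anatomy(term_id):
            raise OntologyError(f"{term_id!r} is not an anatomy term")
    if general == specific:
        return True
    wholes: Dict[TermId, List[TermId]] = {}
    if use_partof:
        for part, whole in ontology.anatomy_partonomy:
            wholes.setdefault(part, []).append(whole)
    seen: Set[TermId] = {specific}
    stack = [specific]
    while stack:
        cur = stack.pop()
        nexts = list(ontology.terms[cur].asserted_parents) + wholes.get(cur, [])
        for nxt in nexts:
            if nxt == general:
                return True
            if nxt not in seen and nxt in ontology.terms:
                seen.add(nxt)
                stack.append(nxt)
    return False


def _effective_location(ontology: Ontology, term_id: TermId) -> Optional[TermId]:
    """Own located_in filler, else the nearest asserted ancestor's.

    Breadth-first by depth; among equally near ancestors the smallest filler
    id wins, making inheritance deterministic.
    """
    level = [term_id]
    seen = {term_id}
    while level:
        fillers = sorted(
            ontology.terms[t].location
            for t in level
            if t in ontology.terms and ontology.terms[t].location is not None
        )
        if fillers:
            return fillers[0]
        nxt: List[TermId] = []
        for t in level:
            if t not in ontology.terms:
                continue
            for parent in ontology.terms[t].asserted_parents:
                if parent not in seen:
                    seen.add(parent)
                    nxt.append(parent)
        level = nxt
    return None


def classify(ontology: Ontology, use_partof: bool = True) -> Ontology:
    """Return a copy of ``ontology`` with ``inferred_parents`` populated.

    Asserted edges are never touched.  Raises :class:`ClassificationError`
    when saturation would create a cycle (e.g. two defined groups that end up
    mutually subsuming each other).
    """
    result = ontology.copy()
    result.inferred_parents = {}
    result.inferred_provenance = {}
    ae_ids = [t.id for t in result.ae_terms()]

    # anatomy closure: filler -> set of anatomy ancestors-or-self
    anatomy_up: Dict[TermId, Set[TermId]] = {}
    for term in result.anatomy_terms():
        up = {term.id}
        stack = [term.id]
        wholes: Dict[TermId, List[TermId]] = {}
        if use_partof:
            for part, whole in result.anatomy_partonomy:
                wholes.setdefault(part, []).append(whole)
        while stack:
            cur = stack.pop()
            nexts = list(result.terms[cur].asserted_parents) + wholes.get(cur, [])
            for nxt in nexts:
                if nxt in result.terms and nxt not in up:
                    up.add(nxt)
                    stack.append(nxt)
        anatomy_up[term.id] = up

    location: Dict[TermId, Optional[TermId]] = {
        t: _effective_location(result, t) for t in ae_ids
    }
    inferred: Dict[TermId, Dict[TermId, EquivalenceAxiom]] = {}

    def up_closure(term_id: TermId) -> Set[TermId]:
        seen: Set[TermId] = set()
        stack = [term_id]
        while stack:
            cur = stack.pop()
            nexts = list(result.terms[cur].asserted_parents) + sorted(
                inferred.get(cur, {})
            )
            for nxt in nexts:
                if nxt in result.terms and nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return seen

    axioms = sorted(result.equivalence_axioms)
    changed = True
    guard = 0
    while changed:
        changed = False
        guard += 1
        if guard > len(result.terms) * max(1, len(axioms)) + 2:
            raise ClassificationError(
                "saturation failed to reach a fixed point", axioms
            )
        for term_id in ae_ids:
            filler = location[term_id]
            if filler is None or filler not in anatomy_up:
                continue
            above = None  # computed lazily per term and pass
            for axiom in axioms:
                target = axiom.defined_term
                if target == term_id or target not in result.terms:
                    continue
                if target in result.terms[term_id].asserted_parents:
                    continue
                if target in inferred.get(term_id, {}):
                    continue
                if axiom.location_filler not in anatomy_up[filler]:
                    continue
                if above is None:
                    above = up_closure(term_id)
                if axiom.genus != term_id and axiom.genus not in above:
                    continue
                inferred.setdefault(term_id, {})[target] = axiom
                above = None
                changed = True

    # cycle check on asserted + inferred edges
    def reachable(start: TermId, goal: TermId) -> bool:
        return goal in up_closure(start)

    bad_axioms = []
    for child, parent_map in inferred.items():
        for parent, axiom in parent_map.items():
            if child == parent or reachable(parent, child):
                bad_axioms.append(axiom)
    if bad_axioms:
        raise ClassificationError(
            "classification would introduce a cycle via axioms: "
            + ", ".join(sorted({a.defined_term for a in bad_axioms})),
            sorted(set(bad_axioms)),
        )

    # transitive reduction: keep an inferred edge only when the parent is not
    # reachable through some other parent (direct-parent semantics)
    for child in sorted(inferred):
        keep: Dict[TermId, EquivalenceAxiom] = {}
        others = list(result.terms[child].asserted_parents) + sorted(
            inferred[child]
        )
        for parent, axiom in inferred[child].items():
            redundant = any(
                mid != parent and (mid == parent or reachable(mid, parent))
                for mid in others
            )
            if not redundant:
                keep[parent] = axiom
        if keep:
            result.inferred_parents[child] = sorted(keep)
            for parent, axiom in keep.items():
                result.inferred_provenance[(child, parent)] = axiom
    return result


def inferred_edges(ontology: Ontology) -> List[InferredEdge]:
    """The reasoner's output as explicit edges with axiom provenance."""
    out = []
    for (child, parent), axiom in sorted(ontology.inferred_provenance.items()):
        out.append(InferredEdge(child, parent, axiom))
    return out


# ---------------------------------------------------------------------------
# Independent oracle: deliberately naive, shares no helpers with classify().
# ---------------------------------------------------------------------------

def oracle_classify(ontology: Ontology, use_partof: bool = True) -> Ontology:
    """Same contract as :func:`classify`, as a direct quadratic fixed point."""
    out = ontology.copy()
    out.inferred_parents = {}
    out.inferred_provenance = {}

    def naive_anatomy_reaches(general: TermId, specific: TermId) -> bool:
        if general == specific:
            return True
        frontier = [specific]
        visited = set(frontier)
        while frontier:
            node = frontier.pop(0)
            step = []
            step.extend(out.terms[node].asserted_parents)
            if use_partof:
                for part, whole in out.anatomy_partonomy:
                    if part == node:
                        step.append(whole)
            for nxt in step:
                if nxt == general:
                    return True
                if nxt in out.terms and nxt not in visited:
                    visited.add(nxt)
                    frontier.append(nxt)
        return False

    def naive_location(term_id: TermId) -> Optional[TermId]:
        ring = [term_id]
        visited = set(ring)
        while ring:
            found = [
                out.terms[t].location
                for t in ring
                if out.terms[t].location is not None
            ]
            if found:
                return sorted(found)[0]
            nxt = []
            for t in ring:
                for parent in out.terms[t].asserted_parents:
                    if parent in out.terms and parent not in visited:
                        visited.add(parent)
                        nxt.append(parent)
            ring = nxt
        return None

    edges: Dict[Tuple[TermId, TermId], EquivalenceAxiom] = {}

    def naive_above(term_id: TermId) -> Set[TermId]:
        visited: Set[TermId] = set()
        frontier = [term_id]
        while frontier:
            node = frontier.pop(0)
            step = list(out.terms[node].asserted_parents)
            for (child, parent) in edges:
                if child == node:
                    step.append(parent)
            for nxt in step:
                if nxt in out.terms and nxt not in visited:
                    visited.add(nxt)
                    frontier.append(nxt)
        return visited

    while True:
        added = False
        for term in out.terms.values():
            if term.is_anatomy:
                continue
            filler = naive_location(term.id)
            if filler is None or not out.terms.get(filler, None):
                continue
            if not out.terms[filler].is_anatomy:
                continue
            for axiom in sorted(out.equivalence_axioms):
                if axiom.defined_term == term.id:
                    continue
                if axiom.defined_term in term.asserted_parents:
                    continue
                if (term.id, axiom.defined_term) in edges:
                    continue
                if axiom.genus != term.id and axiom.genus not in naive_above(term.id):
                    continue
                if not naive_anatomy_reaches(axiom.location_filler, filler):
                    continue
                edges[(term.id, axiom.defined_term)] = axiom
                added = True
        if not added:
            break

    offenders = []
    for child, parent in edges:
        if child in naive_above(parent) or child == parent:
            offenders.append(edges[(child, parent)])
    if offenders:
        raise ClassificationError(
            "classification would introduce a cycle via axioms: "
            + ", ".join(sorted({a.defined_term for a in offenders})),
            sorted(set(offenders)),
        )

    for (child, parent), axiom in sorted(edges.items()):
        implied = False
        starts = list(out.terms[child].asserted_parents) + [
            p for (c, p) in edges if c == child and p != parent
        ]
        for start in starts:
            if start == parent or parent in naive_above(start):
                implied = True
                break
        if not implied:
            out.inferred_parents.setdefault(child, [])
            if parent not in out.inferred_parents[child]:
                out.inferred_parents[child].append(parent)
                out.inferred_provenance[(child, parent)] = axiom
    for child in out.inferred_parents:
        out.inferred_parents[child].sort()
    return out
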