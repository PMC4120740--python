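"""Reader and writer for a small OBO-1.4 flat-file dialect.

Supported stanza tags: ``id``, ``name``, ``is_a``, ``relationship:``
(``located_in`` and ``part_of`` only), ``intersection_of``, ``xref`` and
``is_obsolete`` (rejected).  An anatomy-defined AE group is encoded as the
standard pair of ``intersection_of`` lines::

    intersection_of: OAE_0000001            ! adverse event
    intersection_of: located_in UBERON_0001004  ! respiratory system

Anatomy terms are recognised by identifier prefix (``UBERON`` by default).
Inferred is-a edges produced by the reasoner are serialized with a trailing
``{is_inferred="true"}`` modifier so classified ontologies survive a
round-trip; comments after ``!`` are ignored on parse and regenerated from
term labels on write.  The writer emits a canonical form — stanzas sorted by
id, tags in fixed order, LF newlines — which is a fixed point of
``write(parse(.))``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import IO, List, Sequence, Tuple, Union

from .errors import OboFormatError, OntologyError
from .ontology import EquivalenceAxiom, Ontology, Term

DEFAULT_ANATOMY_PREFIXES: Tuple[str, ...] = ("UBERON",)
_MODIFIER_RE = re.compile(r"\{([^{}]*)\}")


@dataclass
class OboDocument:
    """Lexical view of an OBO file: header lines plus ordered term stanzas,
    each a list of (tag, value, modifier) triples with comments stripped."""

    header: List[str] = field(default_factory=list)
    stanzas: List[List[Tuple[str, str, str]]] = field(default_factory=list)


def _split_line(line: str) -> Tuple[str, str]:
    """Strip an unescaped '!' comment; return (payload, modifier)."""
    comment = line.find("!")
    if comment >= 0:
        line = line[:comment]
    match = _MODIFIER_RE.search(line)
    modifier = ""
    if match:
        modifier = match.group(1).strip()
        line = line[: match.start()] + line[match.end():]
    return line.strip(), modifier


def _read_document(text: str) -> OboDocument:
    doc = OboDocument()
    current: List[Tuple[str, str, str]] | None = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("["):
            if line != "[Term]":
                raise OboFormatError(f"unsupported stanza type: {line}")
            current = []
            doc.stanzas.append(current)
            continue
        payload, modifier = _split_line(line)
        if not payload:
            continue
        if ":" not in payload:
            raise OboFormatError(f"malformed line (no tag): {raw.strip()!r}")
        tag, _, value = payload.partition(":")
        tag, value = tag.strip(), value.strip()
        if current is None:
            doc.header.append(payload)
        else:
            current.append((tag, value, modifier))
    return doc


def _prefix(term_id: str) -> str:
    return term_id.split("_", 1)[0] if "_" in term_id else term_id


def parse_obo(
    source: Union[str, IO[str]],
    anatomy_prefixes: Sequence[str] = DEFAULT_ANATOMY_PREFIXES,
) -> Ontology:
    """Parse OBO-subset text (or a readable stream) into an :class:`Ontology`.

    Raises :class:`OboFormatError` on malformed stanzas, unknown relationship
    types, obsolete terms, dangling identifiers or cycles.
    """
    text = source if isinstance(source, str) else source.read()
    doc = _read_document(text)
    anatomy = tuple(anatomy_prefixes)

    ontology = Ontology()
    partonomy: List[Tuple[str, str]] = []
    axioms: List[EquivalenceAxiom] = []
    terms: List[Term] = []
    inferred: dict[str, list[str]] = {}

    for stanza in doc.stanzas:
        ids = [v for t, v, _ in stanza if t == "id"]
        if len(ids) != 1 or not ids[0]:
            raise OboFormatError("every [Term] stanza needs exactly one id tag")
        term_id = ids[0]
        label = ""
        parents: List[str] = []
        location: str | None = None
        xrefs: List[str] = []
        intersections: List[Tuple[str, str]] = []
        for tag, value, modifier in stanza:
            if tag == "id":
                continue
            if tag == "name":
                label = value
            elif tag == "is_a":
                if not value:
                    raise OboFormatError(f"{term_id}: empty is_a value")
                if 'is_inferred="true"' in modifier.replace(" ", ""):
                    inferred.setdefault(term_id, []).append(value)
                else:
                    parents.append(value)
            elif tag == "relationship":
                parts = value.split()
                if len(parts) != 2:
                    raise OboFormatError(
                        f"{term_id}: malformed relationship line {value!r}"
                    )
                rel, target = parts
                if rel == "located_in":
                    if location is not None:
                        raise OboFormatError(
                            f"{term_id}: more than one located_in restriction"
                        )
                    location = target
                elif rel == "part_of":
                    partonomy.append((term_id, target))
                else:
                    raise OboFormatError(
                        f"{term_id}: unknown relationship type {rel!r}"
                    )
            elif tag == "intersection_of":
                parts = value.split()
                if len(parts) == 1:
                    intersections.append(("genus", parts[0]))
                elif len(parts) == 2 and parts[0] == "located_in":
                    intersections.append(("located_in", parts[1]))
                else:
                    raise OboFormatError(
                        f"{term_id}: unsupported intersection_of line {value!r}"
                    )
            elif tag == "xref":
                if value:
                    xrefs.append(value)
            elif tag == "is_obsolete":
                if value.lower() == "true":
                    raise OboFormatError(
                        f"{term_id}: obsolete terms are not supported"
                    )
            else:
                raise OboFormatError(f"{term_id}: unsupported tag {tag!r}")
        if intersections:
            kinds = sorted(kind for kind, _ in intersections)
            if kinds != ["genus", "located_in"]:
                raise OboFormatError(
                    f"{term_id}: an equivalence axiom needs exactly one genus "
                    "line and one located_in line"
                )
            genus = next(v for k, v in intersections if k == "genus")
            filler = next(v for k, v in intersections if k == "located_in")
            axioms.append(EquivalenceAxiom(term_id, genus, filler))
        terms.append(
            Term(
                id=term_id,
                label=label,
                asserted_parents=parents,
                location=location,
                xrefs=xrefs,
                is_anatomy=_prefix(term_id) in anatomy,
            )
        )

    try:
        ontology.add_terms(terms)
        for part, whole in partonomy:
            ontology.add_part_of(part, whole)
        for axiom in axioms:
            ontology.add_axiom(axiom)
    except OntologyError as exc:
        raise OboFormatError(str(exc)) from exc
    for child, ips in inferred.items():
        for parent in ips:
            if parent not in ontology:
                raise OboFormatError(
                    f"{child}: inferred parent {parent!r} does not exist"
                )
        ontology.inferred_parents[child] = sorted(set(ips))

    hard = [
        v
        for v in ontology.validate_structure(enforce_single_inheritance=False)
        if v.kind.startswith("dangling") or v.kind == "cycle"
    ]
    if hard:
        raise OboFormatError("; ".join(str(v) for v in hard))
    return ontology


def write_obo(ontology: Ontology) -> str:
    """Serialize to canonical OBO-subset text (stanzas sorted by id)."""
    lines: List[str] = ["format-version: 1.4", ""]
    axioms_by_term: dict[str, List[EquivalenceAxiom]] = {}
    for axiom in sorted(ontology.equivalence_axioms):
        axioms_by_term.setdefault(axiom.defined_term, []).append(axiom)
    parts_by_term: dict[str, List[str]] = {}
    for part, whole in sorted(ontology.anatomy_partonomy):
        parts_by_term.setdefault(part, []).append(whole)

    def comment(term_id: str) -> str:
        label = ontology.label(term_id)
        return f" ! {label}" if label else ""

    for term_id in sorted(ontology.terms):
        term = ontology.terms[term_id]
        lines.append("[Term]")
        lines.append(f"id: {term.id}")
        if term.label:
            lines.append(f"name: {term.label}")
        for parent in sorted(term.asserted_parents):
            lines.append(f"is_a: {parent}{comment(parent)}")
        for parent in sorted(ontology.inferred_parents.get(term_id, [])):
            lines.append(f'is_a: {parent} {{is_inferred="true"}}{comment(parent)}')
        for axiom in axioms_by_term.get(term_id, []):
            lines.append(f"intersection_of: {axiom.genus}{comment(axiom.genus)}")
            lines.append(
                "intersection_of: located_in "
                f"{axiom.location_filler}{comment(axiom.location_filler)}"
            )
        if term.location is not None:
            lines.append(
                f"relationship: located_in {term.location}{comment(term.location)}"
            )
        for whole in parts_by_term.get(term_id, []):
            lines.append(f"relationship: part_of {whole}{comment(whole)}")
        for xref in sorted(term.xrefs):
            lines.append(f"xref: {xref}")
        lines.append("")
    return "\n".join(lines).rstrip("\n") + "\n"
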