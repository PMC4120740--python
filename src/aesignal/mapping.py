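"""Cross-reference mapping from flat terminology codes to ontology term ids.

Report databases code outcomes with flat dictionary terms (MedDRA-style
preferred terms); the ontology carries its own identifiers.  A mapping table
is a two-column TSV (``code<TAB>term_id``, optional header).  Many-to-one
mappings are allowed — several dictionary codes may point at one ontology
term — but one-to-many mappings are rejected at load time, and unmapped
codes are always retained and reported rather than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Dict, List, Sequence, Tuple, Union

from .errors import MappingError
from .ontology import Ontology, TermId


@dataclass
class MappingTable:
    entries: Dict[str, TermId] = field(default_factory=dict)
    source_name: str = ""

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, code: str) -> bool:
        return code in self.entries


def load_mapping(source: Union[str, IO[str]], source_name: str = "") -> MappingTable:
    """Parse a two-column TSV into a :class:`MappingTable`.

    A first row of ``code<TAB>term_id`` (any case) is treated as a header;
    lines starting with ``#`` are comments.  Duplicate codes — including a
    code mapped to two different terms — raise :class:`MappingError`.
    """
    text = source if isinstance(source, str) else source.read()
    entries: Dict[str, TermId] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
            raise MappingError(f"line {lineno}: malformed mapping row {line!r}")
        code, term_id = parts[0].strip(), parts[1].strip()
        if lineno == 1 and (code.lower(), term_id.lower()) == ("code", "term_id"):
            continue
        if code in entries:
            raise MappingError(
                f"line {lineno}: duplicate code {code!r} "
                f"(maps to both {entries[code]!r} and {term_id!r})"
                if entries[code] != term_id
                else f"line {lineno}: duplicate code {code!r}"
            )
        entries[code] = term_id
    return MappingTable(entries=entries, source_name=source_name)


def map_codes(
    table: MappingTable, ontology: Ontology, codes: Sequence[str]
) -> Tuple[List[TermId], List[str]]:
    """Map flat codes to term ids; returns ``(mapped, unmapped)``.

    Order-preserving and per-occurrence: every input code lands in exactly
    one of the two outputs, so ``len(mapped) + len(unmapped) == len(codes)``.
    A code that maps to a term missing from ``ontology`` is an integrity
    error, not an unmapped code.
    """
    mapped: List[TermId] = []
    unmapped: List[str] = []
    for code in codes:
        term_id = table.entries.get(code)
        if term_id is None:
            unmapped.append(code)
        elif term_id not in ontology:
            raise MappingError(
                f"code {code!r} maps to {term_id!r}, which is not in the ontology"
            )
        else:
            mapped.append(term_id)
    return mapped, unmapped
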