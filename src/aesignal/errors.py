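"""Exception hierarchy shared across the package."""


class AesignalError(Exception):
    """Base class for all package-specific errors."""


class OntologyError(AesignalError):
    """Structural problem in an in-memory ontology (duplicate id, dangling
    reference, self-parentage, cycle, unknown term)."""


class OboFormatError(AesignalError):
    """Malformed OBO-subset input (bad stanza, unknown relationship type,
    dangling identifier, cycle, obsolete term)."""


class ClassificationError(AesignalError):
    """The reasoner would introduce a cycle; carries the offending axioms."""

    def __init__(self, message, axioms=()):
        super().__init__(message)
        self.axioms = tuple(axioms)


class MappingError(AesignalError):
    """Bad cross-reference table (duplicate code, malformed row) or a mapped
    term missing from the companion ontology."""


class ReportFormatError(AesignalError):
    """Malformed spontaneous-report TSV (missing column, empty AE list,
    unparseable date, duplicate report id)."""


class DegenerateTableError(AesignalError):
    """A 2x2 contingency table with a zero margin where the requested
    statistic is undefined."""


class SimulationError(AesignalError):
    """Invalid simulation configuration (probabilities out of range,
    infeasible planted risk ratio, missing seed)."""
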