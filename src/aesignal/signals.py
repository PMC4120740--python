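"""Disproportionality screening of spontaneous adverse-event reports.

One report is one row of a passive-surveillance export (VAERS/FAERS style):
a patient received one coded medical intervention at time t1 and lists one
or more coded adverse-event outcomes, the earliest manifesting at onset time
t2.  For a target intervention and each AE term the reports are collapsed
into the classic 2x2 table

    ============================  =========  =============
                                  has AE     no AE
    ============================  =========  =============
    target intervention           a          b
    all other interventions       c          d
    ============================  =========  =============

counted at report level: a report contributes at most once to a cell per AE
term no matter how many of its codes map to that term.  Screening combines
the proportional reporting ratio PRR = [a/(a+b)] / [c/(c+d)], the Yates-
corrected Pearson chi-square for the 2x2 table, and a minimum case-count
filter; a pair is flagged only when it strictly exceeds all three thresholds
(defaults PRR > 2, chi2 > 4, cases > 0.2% of total reports).
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass
from datetime import date
from typing import IO, Dict, List, Optional, Sequence, Union

from .errors import DegenerateTableError, ReportFormatError
from .mapping import MappingTable, map_codes
from .ontology import Ontology, TermId

#: CDISC-style five-level causality assessment scale.
CAUSALITY_LEVELS = (
    "not related",
    "unlikely related",
    "possibly related",
    "probably related",
    "definitely related",
)

REPORT_COLUMNS = (
    "report_id",
    "intervention",
    "vax_date",
    "onset_date",
    "age",
    "sex",
    "causality",
    "ae_codes",
)


@dataclass
class ReportRecord:
    """One spontaneous report: intervention at ``t1``, coded outcomes with
    (optional) onset ``t2``, and optional patient attributes."""

    report_id: str
    intervention: str
    ae_codes: List[str]
    t1: date
    t2: Optional[date] = None
    patient_age: Optional[float] = None
    patient_sex: Optional[str] = None
    causality_level: Optional[str] = None
    source_row: Optional[int] = None


@dataclass(frozen=True)
class ContingencyTable:
    a: int  # target intervention, AE present
    b: int  # target intervention, AE absent
    c: int  # other interventions, AE present
    d: int  # other interventions, AE absent

    def __post_init__(self) -> None:
        for name in "abcd":
            value = getattr(self, name)
            if not isinstance(value, int) or value < 0:
                raise ValueError(f"cell {name} must be a non-negative integer")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class Issue:
    """A record-validation finding; ``severity`` is 'violation' or 'warning'."""

    severity: str
    message: str


@dataclass(frozen=True)
class Thresholds:
    """CODAE-style screening cutoffs, applied as strict inequalities."""

    prr_min: float = 2.0
    chi2_min: float = 4.0
    frac_min: float = 0.002


@dataclass
class SignalResult:
    intervention: str
    ae_term: TermId
    table: ContingencyTable
    prr: float
    chi2: float
    case_fraction: float
    passes: bool


def _parse_date(value: str, row: int, column: str) -> Optional[date]:
    value = value.strip()
    if not value:
        return None
    try:
        return date.fromisoformat(value)
    except ValueError as exc:
        raise ReportFormatError(
            f"row {row}: unparseable {column} {value!r}"
        ) from exc


def read_reports(source: Union[str, IO[str]]) -> List[ReportRecord]:
    """Parse the report TSV dialect (see :data:`REPORT_COLUMNS`).

    Parsing is lenient about temporal order — a report with onset before
    intervention is returned and left for :func:`validate_record` to flag —
    but strict about structure: missing columns, empty AE lists, unparseable
    dates, bad causality labels and duplicate report ids all raise
    :class:`ReportFormatError` with the offending row number.
    """
    if isinstance(source, str):
        lines = source.splitlines()
    else:
        lines = source.read().splitlines()
    reader = csv.DictReader(lines, delimiter="\t")
    header = reader.fieldnames or []
    missing = [c for c in REPORT_COLUMNS if c not in header]
    if missing:
        raise ReportFormatError("missing mandatory column(s): " + ", ".join(missing))
    records: List[ReportRecord] = []
    seen_ids: Dict[str, int] = {}
    for row_no, row in enumerate(reader, start=2):
        report_id = (row.get("report_id") or "").strip()
        intervention = (row.get("intervention") or "").strip()
        if not report_id:
            raise ReportFormatError(f"row {row_no}: empty report_id")
        if report_id in seen_ids:
            raise ReportFormatError(
                f"row {row_no}: duplicate report id {report_id!r} "
                f"(first seen at row {seen_ids[report_id]})"
            )
        seen_ids[report_id] = row_no
        if not intervention:
            raise ReportFormatError(f"row {row_no}: empty intervention")
        t1 = _parse_date(row.get("vax_date") or "", row_no, "vax_date")
        if t1 is None:
            raise ReportFormatError(f"row {row_no}: missing vax_date")
        t2 = _parse_date(row.get("onset_date") or "", row_no, "onset_date")
        codes = [c.strip() for c in (row.get("ae_codes") or "").split(";") if c.strip()]
        if not codes:
            raise ReportFormatError(f"row {row_no}: empty AE code list")
        age_text = (row.get("age") or "").strip()
        age = float(age_text) if age_text else None
        sex = (row.get("sex") or "").strip() or None
        causality = (row.get("causality") or "").strip() or None
        if causality is not None and causality not in CAUSALITY_LEVELS:
            raise ReportFormatError(
                f"row {row_no}: unknown causality level {causality!r}"
            )
        records.append(
            ReportRecord(
                report_id=report_id,
                intervention=intervention,
                ae_codes=codes,
                t1=t1,
                t2=t2,
                patient_age=age,
                patient_sex=sex,
                causality_level=causality,
                source_row=row_no,
            )
        )
    return records


def validate_record(record: ReportRecord) -> List[Issue]:
    """Check the temporal design rule: the intervention time t1 must precede
    (or equal) the onset time t2.  A missing onset is only a warning."""
    issues: List[Issue] = []
    if not record.ae_codes:
        issues.append(Issue("violation", "report lists no AE codes"))
    if record.t2 is None:
        issues.append(Issue("warning", "onset date (t2) missing"))
    elif record.t2 < record.t1:
        issues.append(
            Issue(
                "violation",
                f"onset {record.t2.isoformat()} precedes intervention "
                f"{record.t1.isoformat()}: t1 must precede t2",
            )
        )
    return issues


def build_tables(
    reports: Sequence[ReportRecord],
    target: str,
    mapping: MappingTable,
    ontology: Ontology,
) -> Dict[TermId, ContingencyTable]:
    """Collapse reports into one 2x2 table per observed AE term.

    Codes covered by ``mapping`` are counted under their ontology term;
    uncovered codes are kept as raw-code strata (with a warning) so coverage
    gaps stay visible.  The counting unit is the report.
    """
    if not reports:
        raise ReportFormatError("no reports supplied")
    interventions = {r.intervention for r in reports}
    if target not in interventions:
        raise ReportFormatError(f"target intervention {target!r} not in data")
    n_target = sum(1 for r in reports if r.intervention == target)
    n_other = len(reports) - n_target
    hits_target: Dict[TermId, int] = {}
    hits_other: Dict[TermId, int] = {}
    n_unmapped = 0
    for record in reports:
        mapped, unmapped = map_codes(mapping, ontology, record.ae_codes)
        n_unmapped += len(unmapped)
        bucket = hits_target if record.intervention == target else hits_other
        for term in set(mapped) | set(unmapped):
            bucket[term] = bucket.get(term, 0) + 1
    if n_unmapped:
        warnings.warn(
            f"{n_unmapped} AE code occurrence(s) had no ontology mapping and "
            "were retained as raw-code strata",
            stacklevel=2,
        )
    tables: Dict[TermId, ContingencyTable] = {}
    for term in sorted(set(hits_target) | set(hits_other)):
        a = hits_target.get(term, 0)
        c = hits_other.get(term, 0)
        tables[term] = ContingencyTable(a=a, b=n_target - a, c=c, d=n_other - c)
    return tables


def prr(table: ContingencyTable) -> float:
    """Proportional reporting ratio [a/(a+b)] / [c/(c+d)].

    ``+inf`` when the comparator row has no cases (c = 0, a > 0), ``0`` when
    the target row has none (a = 0, c > 0), ``nan`` when neither row has a
    case.  A table with no target-row reports at all is an error.
    """
    if table.a + table.b == 0:
        raise DegenerateTableError("no reports for the target intervention (a+b=0)")
    if table.a == 0:
        return 0.0 if table.c > 0 else math.nan
    if table.c == 0:
        return math.inf
    return (table.a / (table.a + table.b)) / (table.c / (table.c + table.d))


def chi_square(table: ContingencyTable, yates: bool = True) -> float:
    """Pearson chi-square for the 2x2 table, Yates-corrected by default:

        N * max(|ad - bc| - N/2, 0)^2 / ((a+b)(c+d)(a+c)(b+d))

    Raises :class:`DegenerateTableError` on a zero row or column margin.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    margins = ((a + b), (c + d), (a + c), (b + d))
    if any(m == 0 for m in margins):
        raise DegenerateTableError(
            f"degenerate margin in table (a={a}, b={b}, c={c}, d={d})"
        )
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2.0, 0.0)
    denom = float(margins[0]) * margins[1] * margins[2] * margins[3]
    return n * diff * diff / denom


def codae_detect(
    reports: Sequence[ReportRecord],
    target: str,
    mapping: MappingTable,
    ontology: Ontology,
    thresholds: Optional[Thresholds] = None,
    denominator: str = "all",
    yates: bool = True,
) -> List[SignalResult]:
    """Combined detection stage: one :class:`SignalResult` per AE term
    observed with the target intervention, flagged when PRR, chi-square and
    case fraction all strictly exceed their thresholds.

    ``denominator`` chooses the case-fraction base: ``"all"`` divides a by
    the total report count, ``"target"`` by the target-intervention count.
    Results are sorted by descending chi-square (undefined last), then term.
    """
    thresholds = thresholds or Thresholds()
    if min(thresholds.prr_min, thresholds.chi2_min, thresholds.frac_min) <= 0:
        raise ValueError("thresholds must be positive")
    if denominator not in ("all", "target"):
        raise ValueError("denominator must be 'all' or 'target'")
    tables = build_tables(reports, target, mapping, ontology)
    total = len(reports)
    results: List[SignalResult] = []
    for term, table in tables.items():
        if table.a == 0:
            continue  # not observed with the target
        ratio = prr(table)
        try:
            score = chi_square(table, yates=yates)
        except DegenerateTableError:
            score = math.nan
        base = total if denominator == "all" else table.a + table.b
        fraction = table.a / base
        passes = (
            ratio > thresholds.prr_min
            and score > thresholds.chi2_min  # False when nan
            and fraction > thresholds.frac_min
        )
        results.append(
            SignalResult(
                intervention=target,
                ae_term=term,
                table=table,
                prr=ratio,
                chi2=score,
                case_fraction=fraction,
                passes=passes,
            )
        )
    results.sort(
        key=lambda r: (-(r.chi2 if not math.isnan(r.chi2) else -math.inf), r.ae_term)
    )
    return results
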