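"""Seeded generators: fixture ontologies and VAERS-like report datasets.

Nothing here is derived from any hosted ontology release or real report
database; every object is synthetic and exists so that each pipeline stage
can be exercised and calibrated without downloads.

The report generator draws, for each report, one intervention from the
configured marginals and then an independent Bernoulli indicator per
vocabulary code with probability ``background * risk_ratio`` when the
(intervention, code) pair is planted and ``background`` otherwise.  Reports
are redrawn until they list at least one code, matching the fact that
spontaneous reports always list at least one symptom; this conditioning
inflates per-code rates by 1/(1 - P(no code)), which is why the default
study mix includes a few very common injection-site-style codes that keep
P(no code) small.  Intervention dates fall in one fixed calendar year and
onsets lag them by 0-30 days, so generated records always pass temporal
validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from importlib import resources
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np

from .errors import SimulationError
from .mapping import MappingTable
from .ontology import EquivalenceAxiom, Ontology, Term, TermId
from .signals import ReportRecord


@dataclass
class AeCode:
    """One vocabulary entry: flat code, per-report background probability,
    and the ontology term the code cross-references (None = unmapped)."""

    code: str
    background: float
    term: Optional[TermId] = None


@dataclass
class SimConfig:
    n_reports: int
    interventions: List[Tuple[str, float]]
    ae_vocab: List[AeCode]
    planted: List[Tuple[str, str, float]] = field(default_factory=list)
    seed: Optional[int] = None
    year: int = 2013

    def validate(self) -> None:
        if self.seed is None:
            raise SimulationError("a seed is mandatory")
        if self.n_reports < 1:
            raise SimulationError("n_reports must be positive")
        if not self.interventions or not self.ae_vocab:
            raise SimulationError("need at least one intervention and one AE code")
        total = sum(p for _, p in self.interventions)
        if any(p <= 0 for _, p in self.interventions) or abs(total - 1.0) > 1e-9:
            raise SimulationError("intervention marginals must be positive and sum to 1")
        for entry in self.ae_vocab:
            if not (0.0 < entry.background < 1.0 or entry.background == 1.0):
                raise SimulationError(
                    f"background probability for {entry.code!r} must be in (0, 1]"
                )
        codes = {e.code for e in self.ae_vocab}
        if len(codes) != len(self.ae_vocab):
            raise SimulationError("duplicate AE codes in vocabulary")
        ivs = {code for code, _ in self.interventions}
        for iv, code, rr in self.planted:
            if iv not in ivs:
                raise SimulationError(f"planted intervention {iv!r} not configured")
            if code not in codes:
                raise SimulationError(f"planted AE code {code!r} not in vocabulary")
            if rr <= 0:
                raise SimulationError("planted risk ratios must be positive")
            background = next(e.background for e in self.ae_vocab if e.code == code)
            if background * rr > 1.0:
                raise SimulationError(
                    f"infeasible planted pair ({iv}, {code}): "
                    f"background {background} x risk ratio {rr} exceeds 1"
                )


def simulate_reports(config: SimConfig) -> List[ReportRecord]:
    """Generate exactly ``config.n_reports`` records, reproducibly per seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    iv_codes = [code for code, _ in config.interventions]
    iv_probs = np.array([p for _, p in config.interventions])
    iv_idx = rng.choice(len(iv_codes), size=n, p=iv_probs)

    codes = [e.code for e in config.ae_vocab]
    probs = np.tile(np.array([e.background for e in config.ae_vocab]), (n, 1))
    for iv, code, rr in config.planted:
        rows = iv_idx == iv_codes.index(iv)
        probs[rows, codes.index(code)] *= rr

    draws = rng.random(probs.shape) < probs
    empty = ~draws.any(axis=1)
    while empty.any():
        idx = np.flatnonzero(empty)
        draws[idx] = rng.random((len(idx), len(codes))) < probs[idx]
        empty[idx] = ~draws[idx].any(axis=1)

    day_of_year = rng.integers(0, 365, size=n)
    lag = rng.integers(0, 31, size=n)
    ages = rng.integers(0, 90, size=n)
    sexes = rng.integers(0, 2, size=n)
    base = date(config.year, 1, 1)
    records: List[ReportRecord] = []
    code_array = np.array(codes)
    for i in range(n):
        t1 = base + timedelta(days=int(day_of_year[i]))
        records.append(
            ReportRecord(
                report_id=f"R{i + 1:07d}",
                intervention=iv_codes[iv_idx[i]],
                ae_codes=list(code_array[draws[i]]),
                t1=t1,
                t2=t1 + timedelta(days=int(lag[i])),
                patient_age=float(ages[i]),
                patient_sex="F" if sexes[i] else "M",
                causality_level=None,
            )
        )
    return records


def config_mapping(config: SimConfig) -> MappingTable:
    """Cross-reference table for every mapped code in the vocabulary."""
    entries = {e.code: e.term for e in config.ae_vocab if e.term is not None}
    return MappingTable(entries=entries, source_name="simulated")


def flat_ontology(config: SimConfig) -> Ontology:
    """A minimal ontology for a simulation: one root plus one AE term per
    mapped vocabulary code, each carrying its code as an xref."""
    ontology = Ontology()
    ontology.add_term(Term("OAE_0000001", label="adverse event"))
    for entry in sorted(config.ae_vocab, key=lambda e: e.code):
        if entry.term is None:
            continue
        ontology.add_term(
            Term(
                entry.term,
                label=f"{entry.code} AE",
                asserted_parents=["OAE_0000001"],
                xrefs=[f"MedDRA:{entry.code}"],
            )
        )
    return ontology


# ---------------------------------------------------------------------------
# Packaged fixture ontologies
# ---------------------------------------------------------------------------

def fixture_path(name: str) -> Path:
    """Path of a packaged fixture file (``figure4.obo``, ``upper.obo``,
    ``figure4_mapping.tsv``, ``toy_reports.tsv``)."""
    path = Path(str(resources.files("aesignal").joinpath("data", name)))
    if not path.exists():
        raise FileNotFoundError(f"no packaged fixture named {name!r}")
    return path



def make_figure4_fixture() -> Tuple[Ontology, MappingTable]:
    """The live-attenuated-influenza worked example, deterministically.

    Asserted hierarchy: the 'adverse event' root with an outcome branch
    'inflammation AE' -> 'respiratory system inflammation AE' (located in
    the respiratory system) above three located respiratory leaves, plus a
    cutaneous inflammation leaf, fever and cough; the anatomy-defined group
    'respiratory system AE' is asserted childless under the root and carries
    the equivalence axiom (genus 'adverse event', filler 'respiratory
    system').  Classification adds exactly one direct inferred edge:
    'respiratory system inflammation AE' -> 'respiratory system AE'.
    """
    ontology = Ontology()
    anatomy = [
        Term("UBERON_0001004", label="respiratory system", is_anatomy=True),
        Term("UBERON_0000004", label="nose", is_anatomy=True),
        Term("UBERON_0001042", label="pharynx", is_anatomy=True),
        Term("UBERON_0003126", label="trachea", is_anatomy=True),
        Term("UBERON_0002097", label="skin of body", is_anatomy=True),
        Term("UBERON_0000970", label="eye", is_anatomy=True),
    ]
    ontology.add_terms(anatomy)
    for part in ("UBERON_0000004", "UBERON_0001042", "UBERON_0003126"):
        ontology.add_part_of(part, "UBERON_0001004")
    root = "OAE_0000001"
    ontology.add_terms(
        [
            Term(root, label="adverse event"),
            Term("OAE_0000003", label="causal adverse event", asserted_parents=[root]),
            Term("OAE_0001001", label="inflammation AE", asserted_parents=[root]),
            Term(
                "OAE_0001002",
                label="respiratory system inflammation AE",
                asserted_parents=["OAE_0001001"],
                location="UBERON_0001004",
            ),
            Term(
                "OAE_0001003",
                label="rhinitis AE",
                asserted_parents=["OAE_0001002"],
                location="UBERON_0000004",
                xrefs=["MedDRA:10039083"],
            ),
            Term(
                "OAE_0001004",
                label="pharyngitis AE",
                asserted_parents=["OAE_0001002"],
                location="UBERON_0001042",
                xrefs=["MedDRA:10034835"],
            ),
            Term(
                "OAE_0001005",
                label="tracheitis AE",
                asserted_parents=["OAE_0001002"],
                location="UBERON_0003126",
                xrefs=["MedDRA:10044302"],
            ),
            Term(
                "OAE_0001006",
                label="fever AE",
                asserted_parents=[root],
                xrefs=["MedDRA:10016558"],
            ),
            Term(
                "OAE_0001007",
                label="cough AE",
                asserted_parents=[root],
                xrefs=["MedDRA:10011224"],
            ),
            Term(
                "OAE_0001009",
                label="dermatitis AE",
                asserted_parents=["OAE_0001001"],
                location="UBERON_0002097",
                xrefs=["MedDRA:10012431"],
            ),
            Term(
                "OAE_0002001",
                label="respiratory system AE",
                asserted_parents=[root],
                xrefs=["MedDRA:10038738"],
            ),
        ]
    )
    ontology.add_axiom(EquivalenceAxiom("OAE_0002001", root, "UBERON_0001004"))
    mapping = MappingTable(
        entries={
            "10039083": "OAE_0001003",
            "10034835": "OAE_0001004",
            "10044302": "OAE_0001005",
            "10016558": "OAE_0001006",
            "10011224": "OAE_0001007",
            "10012431": "OAE_0001009",
            "10038738": "OAE_0002001",
        },
        source_name="fixture MedDRA-style codes (synthetic)",
    )
    return ontology, mapping


def make_upper_fixture() -> Ontology:
    """Toy upper hierarchy: the AE root with intervention-, severity- and
    causality-based subtypes.  The 'causal adverse event' term's full
    definition (induced_by some medical intervention) is documentation-level
    semantics only and is not reasoned over."""
    ontology = Ontology()
    root = "OAE_0000001"
    ontology.add_terms(
        [
            Term(root, label="adverse event"),
            Term("OAE_0000003", label="causal adverse event", asserted_parents=[root]),
            Term("OAE_0000004", label="vaccine adverse event", asserted_parents=[root]),
            Term("OAE_0000005", label="drug adverse event", asserted_parents=[root]),
            Term("OAE_0000006", label="severe adverse event", asserted_parents=[root]),
            Term(
                "OAE_0000007",
                label="causal adverse event hypothesis",
                asserted_parents=[root],
            ),
        ]
    )
    return ontology


# ---------------------------------------------------------------------------
# Random ontologies (property-test instances)
# ---------------------------------------------------------------------------

def random_ontology(
    seed: int,
    max_terms: int = 40,
    max_axioms: int = 8,
) -> Ontology:
    """A random but structurally valid ontology: an anatomy DAG with is-a
    and part_of edges, a single-inheritance AE tree with sporadic located_in
    restrictions and xrefs, and random anatomy-defined group axioms."""
    rng = np.random.default_rng(seed)
    ontology = Ontology()
    n_anatomy = int(rng.integers(2, max(3, max_terms // 3)))
    n_ae = int(rng.integers(2, max(3, max_terms - n_anatomy)))

    anatomy_ids = [f"UBERON_9{i:06d}" for i in range(n_anatomy)]
    for i, term_id in enumerate(anatomy_ids):
        parents = []
        if i and rng.random() < 0.8:
            k = int(rng.integers(1, min(i, 2) + 1))
            parents = list(
                rng.choice(anatomy_ids[:i], size=min(k, i), replace=False)
            )
        ontology.add_term(
            Term(term_id, label=f"anatomy {i}", asserted_parents=parents,
                 is_anatomy=True)
        )
    for i in range(1, n_anatomy):
        if rng.random() < 0.3:
            whole = anatomy_ids[int(rng.integers(0, i))]
            ontology.add_part_of(anatomy_ids[i], whole)

    ae_ids = [f"OAE_9{i:06d}" for i in range(n_ae)]
    for i, term_id in enumerate(ae_ids):
        parents = [] if i == 0 else [ae_ids[int(rng.integers(0, i))]]
        location = None
        if i and rng.random() < 0.5:
            location = anatomy_ids[int(rng.integers(0, n_anatomy))]
        xrefs = [f"MedDRA:9{seed % 1000:03d}{i:04d}"] if rng.random() < 0.3 else []
        ontology.add_term(
            Term(
                term_id,
                label=f"AE {i}",
                asserted_parents=parents,
                location=location,
                xrefs=xrefs,
            )
        )
    n_axioms = int(rng.integers(0, max_axioms + 1))
    defined_seen = set()
    for _ in range(n_axioms):
        defined = ae_ids[int(rng.integers(1, n_ae))] if n_ae > 1 else ae_ids[0]
        if defined in defined_seen:
            continue  # one full definition per term
        defined_seen.add(defined)
        genus = ae_ids[int(rng.integers(0, n_ae))]
        filler = anatomy_ids[int(rng.integers(0, n_anatomy))]
        ontology.add_axiom(EquivalenceAxiom(defined, genus, filler))
    return ontology


# ---------------------------------------------------------------------------
# Reference study conditions
# ---------------------------------------------------------------------------

#: Detection-study defaults: a 50-code vocabulary in which three injection-
#: site-style codes are very common (backgrounds 0.6/0.5/0.4) and the rest
#: are rare (0.02), one target intervention given to 20% of reports, and one
#: planted pair on a rare code.  The common codes keep the at-least-one-code
#: conditioning mild so realized PRR stays close to the planted risk ratio.
STUDY_TARGET = "V1"
STUDY_PLANTED_CODE = "10000010"


def make_study_config(
    seed: int,
    n_reports: int = 20_000,
    risk_ratio: float = 8.0,
    background: float = 0.02,
    n_rare_codes: int = 47,
) -> SimConfig:
    vocab = [
        AeCode("10000001", 0.6, "OAE_8000001"),
        AeCode("10000002", 0.5, "OAE_8000002"),
        AeCode("10000003", 0.4, "OAE_8000003"),
    ]
    for i in range(n_rare_codes):
        code = f"100000{10 + i:02d}"
        vocab.append(AeCode(code, background, f"OAE_80000{10 + i:02d}"))
    return SimConfig(
        n_reports=n_reports,
        interventions=[(STUDY_TARGET, 0.2), ("V0", 0.8)],
        ae_vocab=vocab,
        planted=[(STUDY_TARGET, STUDY_PLANTED_CODE, risk_ratio)],
        seed=seed,
    )


def make_figure4_study_config(seed: int, n_reports: int = 5_000) -> SimConfig:
    """Study conditions for the enrichment demonstration: risk planted only
    on the three respiratory leaves of the packaged fixture."""
    vocab = [
        AeCode("10016558", 0.25, "OAE_0001006"),  # fever
        AeCode("10011224", 0.15, "OAE_0001007"),  # cough
        AeCode("10012431", 0.05, "OAE_0001009"),  # dermatitis
        AeCode("10039083", 0.02, "OAE_0001003"),  # rhinitis
        AeCode("10034835", 0.02, "OAE_0001004"),  # pharyngitis
        AeCode("10044302", 0.02, "OAE_0001005"),  # tracheitis
        AeCode("10038738", 0.02, "OAE_0002001"),  # respiratory disorder PT
    ]
    planted = [
        ("V1", "10039083", 8.0),
        ("V1", "10034835", 8.0),
        ("V1", "10044302", 8.0),
        ("V1", "10038738", 8.0),
    ]
    return SimConfig(
        n_reports=n_reports,
        interventions=[("V1", 0.2), ("V0", 0.8)],
        ae_vocab=vocab,
        planted=planted,
        seed=seed,
    )
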