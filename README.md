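# aesignal

Ontology-aware signal detection for spontaneous adverse-event reports.

Passive surveillance systems (VAERS, FAERS and their kin) collect voluntary
reports of adverse events (AEs) following a medical intervention — a
vaccination, a drug administration — with no causality implied. Two things
make these data hard to use well. First, the screening problem: which
(intervention, AE) pairs are reported disproportionately often?  Second, the
aggregation problem: the AE dictionary used for coding (MedDRA-style
preferred terms) is flat, so related findings such as rhinitis, pharyngitis
and tracheitis are invisible as a *group* unless an ontology supplies the
hierarchy. `aesignal` addresses both, for pharmacoepidemiologists and
ontology engineers who want the whole chain — ontology handling, reasoning,
screening, enrichment — reproducible from plain text files.

## What it computes

**Screening.** For a target intervention and each AE term, reports are
collapsed into the 2×2 table (a = target & AE, b = target without AE,
c = other & AE, d = other without AE), counted at report level. A pair is
flagged when it strictly exceeds all three cutoffs:

- proportional reporting ratio `PRR = [a/(a+b)] / [c/(c+d)] > 2`,
- Yates-corrected chi-square
  `χ² = N·(max(|ad−bc|−N/2, 0))² / ((a+b)(c+d)(a+c)(b+d)) > 4`,
- case count above 0.2 % of total reports.

**Reasoning.** AE ontologies in this style assert only the clinical-outcome
parent of a term ("respiratory system inflammation AE" *is_a* "inflammation
AE") and leave anatomy grouping to inference: a `located_in` restriction
ties each term to an anatomical entity, and anatomy-based groups are defined
by equivalence axioms such as

    'respiratory system AE'  ==  'adverse event' and (located_in some 'respiratory system')

The structural reasoner places every term whose effective location falls at
or under the axiom's filler (through the anatomy *is_a*/*part_of*
hierarchy) under the defined group, saturating to a fixed point. Single
inheritance of asserted parents is preserved; the anatomy parents arrive as
separately marked inferred edges.

**Enrichment.** Flagged terms are propagated to every asserted-or-inferred
ancestor; each group's overrepresentation is scored with the exact
hypergeometric upper tail P(X ≥ k) for k of n flagged terms falling among
the K of N universe terms under the group, with Benjamini–Hochberg
adjustment across groups.

A seeded synthetic-data module supplies everything needed to exercise the
pipeline without downloads: packaged toy ontologies (OBO-subset text),
MedDRA-style cross-reference tables, and a VAERS-like report generator with
planted intervention–AE risk elevations.

## Worked example

Simulate 5,000 reports in which intervention `V1` (20 % of reports) carries
an 8-fold risk on four respiratory codes, screen them, and test group
enrichment against the packaged fixture ontology:

```sh
aesignal simulate --config sim.yaml --out reports.tsv
aesignal detect  --reports reports.tsv --target V1 \
                 --ontology figure4.obo --mapping figure4_mapping.tsv \
                 --out results.tsv
aesignal enrich  --results results.tsv --ontology figure4.obo --out enrich.tsv
```

`results.tsv` (screening; the four planted respiratory terms pass, the
common background symptoms do not):

```text
term        a    b    c     d     prr       chi2     case_fraction  passes
OAE_0001004 237  740  197   3826  4.95379   369.309  0.0474         true
OAE_0001003 212  765  175   3848  4.98831   328.915  0.0424         true
OAE_0001005 215  762  190   3833  4.65951   313.13   0.043          true
OAE_0002001 210  767  197   3826  4.38943   287.393  0.042          true
OAE_0001006 356  621  2253  1770  0.650645  119.809  0.0712         false
OAE_0001007 191  786  1430  2593  0.549987  91.076   0.0382         false
OAE_0001009 80   897  461   3562  0.71457   8.37963  0.016          false
```

Here `a=237` means 237 of the 977 `V1` reports list pharyngitis, against
197 of 4,023 comparator reports — a reporting ratio of ~5, χ² ≈ 369, so the
pair is flagged. Fever (`OAE_0001006`) is *more* common in absolute terms
but proportionally under-reported with `V1` (PRR ≈ 0.65), so it fails.

`enrich.tsv` (grouping; all four hits fall under the anatomy-defined
respiratory group, which only exists as a parent after reasoning):

```text
group_id     group_label                          k  K  n  N  p          q
OAE_0002001  respiratory system AE                4  4  4  7  0.0285714  0.114286
OAE_0001002  respiratory system inflammation AE   3  3  4  7  0.114286   0.228571
OAE_0001001  inflammation AE                      3  4  4  7  0.371429   0.495238
OAE_0000001  adverse event                        4  7  4  7  1          1
```

`k=4, K=4` on the top row: all 4 flagged terms are among the 4 observed
terms at-or-under 'respiratory system AE', out of n=4 flagged in a universe
of N=7; the exact tail probability is 1/35 ≈ 0.0286.

The same pipeline is available as library calls (`simulate_reports`,
`codae_detect`, `classify`, `enrich_groups`); `aesignal classify` and
`aesignal validate` expose the reasoner and the structural/temporal
validators (e.g. every report's intervention date must precede its onset
date) on their own.

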