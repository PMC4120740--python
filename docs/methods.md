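# Methods

This note records the models, conventions and numerical choices behind
`aesignal`, in the order the pipeline runs.

## Ontology model

An ontology is a dictionary of term records plus three relation stores: the
asserted *is_a* DAG (on `Term.asserted_parents`), an anatomy partonomy
(`part_of` pairs between anatomy terms), and equivalence axioms of the
single supported shape `G == genus AND (located_in some filler)`. Anatomy
terms and AE terms live in one object, distinguished by a flag; on parse the
flag is derived from the identifier prefix (`UBERON` by default,
configurable), since the OBO dialect has no namespace tag. Each AE term may
carry at most one `located_in` filler; multi-location terms are rejected at
load with an explicit error, which keeps the inference rule set minimal.
Each term may carry at most one equivalence axiom (one full definition per
class).

The editorial policy modelled here is single inheritance for AE terms: the
clinical-outcome parent is asserted, anatomy parents are derived.
`validate_structure(enforce_single_inheritance=True)` reports every AE term
with two or more asserted parents, alongside cycles and dangling references;
anatomy terms are exempt because imported anatomy hierarchies routinely use
multiple parents. Validation returns violations rather than raising, so
corrupted inputs can be reported exhaustively.

The 'causal adverse event' term appears in fixtures as an ordinary child of
the root; its defining axiom (induced by some medical intervention) is
documentation-level semantics only. Reasoning over causality would need
instance-level data that spontaneous reports cannot supply, so no machinery
pretends otherwise.

## OBO dialect

Fixtures and interchange use a deliberately small OBO-1.4 subset: `id`,
`name`, `is_a`, `relationship: located_in`, `relationship: part_of`,
`intersection_of` (exactly a genus line plus a `located_in` line), `xref`,
and `is_obsolete` (rejected — obsolete terms are out of scope). Anything
else is a parse error, on the view that silently ignoring tags corrupts
round-trips. The writer is canonical — stanzas sorted by id, fixed tag
order, sorted `is_a`/`xref` lines, LF endings — and is a fixed point of
`write ∘ parse`. Inferred edges are serialized as `is_a` lines with a
trailing `{is_inferred="true"}` modifier, so a classified ontology can be
written and re-read without conflating asserted and inferred structure.
Comments after `!` are regenerated from labels, never parsed.

## Reasoner

The classification rule: for every equivalence axiom
`G == genus ⊓ located_in F'` and every AE term `X ≠ G` whose effective
location `F` satisfies `F' subsumes F` in the anatomy hierarchy, place `X`
under `G` if `X` is at-or-under the genus. Saturation repeats the rule until
nothing changes, so a term placed under one defined group can thereby
qualify for another (group chaining through inferred genus-descent is
included; a single-step reading cannot be distinguished on one-axiom
examples, and the saturated reading is the one a DL reasoner would give).

Three conventions, each switchable or reported rather than silent:

* **Anatomy subsumption** follows both *is_a* and *part_of* edges
  (propagation in the style of gene-annotation pipelines), reflexively.
  `use_partof=False` (CLI `--no-partof`) restricts to *is_a*.
* **Location inheritance**: an AE term without its own filler inherits the
  filler of its nearest asserted ancestor that has one, stopping at the
  first explicit filler (breadth-first; equally near candidates tie-break
  to the smallest filler id). Without this, leaves under a located group
  term would never trigger deeper anatomy groupings.
* **Direct-parent semantics**: after saturation the inferred edge set is
  transitively reduced — an edge `X → G` is dropped when `G` is already
  reachable from `X` through other (asserted or inferred) edges. The full
  closure is unchanged and available via
  `ancestors(..., include_inferred=True)`; `inferred_parents` then reads
  like the inferred hierarchy an ontology editor displays: each term gains
  only its *new direct* parents. On the packaged worked example this yields
  exactly one edge ('respiratory system inflammation AE' → 'respiratory
  system AE') even though the located leaves below also satisfy the axiom
  through their ancestor.

An edge derivable from several axioms keeps the lexicographically smallest
axiom as provenance. If saturation would create a cycle — e.g. two defined
groups with identical conditions and asserted fillers, which mutually
subsume — classification fails with the offending axioms listed; groups are
never merged, keeping the output a DAG. Asserted edges are never modified.

`oracle_classify` implements the identical contract as a naive quadratic
fixed point (re-scanning all (term, axiom) pairs with list-walk reachability
and no shared helpers). It exists purely as an independent check; the test
suite requires edge-for-edge agreement on 200 seeded random ontologies.

## Code mapping

Cross-reference tables are two-column TSVs (`code → term id`). Many-to-one
is allowed (flat preferred terms are finer than ontology terms); one-to-many
is rejected at load because a code that expands to several terms would make
report-level counting ambiguous. Unmapped codes are never dropped: they pass
through detection as raw-code strata with a warning, mirroring the coverage
gaps of real dictionaries, but they are excluded from enrichment (no
position in the hierarchy).

## Detection statistics

Cells are counted at report level — a report contributes at most once per AE
term however many of its codes map there — and duplicate report ids are
rejected at parse. PRR conventions at the boundaries: `+inf` when the
comparator row has no cases (a > 0, c = 0), `0` when the target row has none,
`nan` when neither. The chi-square is the 2×2 Pearson statistic with Yates
continuity correction (the convention of the PRR screening literature),
switchable to uncorrected; degenerate margins raise in the scalar API and
yield `nan` (never a pass) inside detection.

The case-count filter divides a by the total number of reports in the
dataset by default; "fraction of target-intervention reports" is available
via `denominator="target"` since the informal phrase "0.2 % of total
reports" admits both readings. All three cutoffs are strict inequalities: a
pair at PRR exactly 2.0 fails. No multiple-testing correction is applied at
the detection stage — the filter is a fixed operating point, not an
inferential procedure; correction appears only in enrichment.

## Enrichment

The universe is the set of AE terms observed in the dataset, not the whole
ontology, so unreported branches do not dilute the test. Group membership is
"at or under": a term counts toward itself and every asserted-or-inferred
ancestor, once, no matter how many paths lead there (DAG-safe set
semantics). Groups covering fewer than two universe terms are suppressed to
avoid trivially significant singletons. The tail probability is computed
exactly in integer arithmetic (`math.comb`, rationalized before the final
float), and Benjamini–Hochberg adjustment is delegated to
`statsmodels.stats.multitest`. Raw counts (k, K, n, N) are always reported
beside p and q so a purely descriptive reading remains possible.

## Synthetic data

The generator emulates the *structure* of spontaneous-report data, not its
content: one intervention per report drawn from configured marginals,
independent Bernoulli draws per vocabulary code (background probability,
multiplied by the risk ratio for planted pairs), intervention dates uniform
over one calendar year with onsets 0–30 days later. Reports are redrawn
until they list at least one code, because real spontaneous reports always
list a symptom. That conditioning inflates per-code rates by
1/(1 − P(no code)); the reference study vocabulary therefore includes three
very common codes (backgrounds 0.6 / 0.5 / 0.4, the injection-site-reaction
analogue) alongside 47 rare codes at background 0.02, keeping the inflation
below ~5 % so that realized PRR tracks the planted risk ratio (median
within 15 % at risk ratio 8). The reference detection study uses 20,000
reports, a target intervention covering 20 % of them, and one planted pair
at risk ratio 8 — large enough for near-certain recovery at the strict
filter, small enough that a 100-seed Monte-Carlo run completes in tens of
seconds.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data: symptom correlation (draws are
independent), coding error and duplicate submissions, secular reporting
trends, age/sex-dependent risk (the record fields exist; the generator does
not use them), and stimulated-reporting waves. Dates are constructed to
always satisfy the temporal rule, so temporal-validation tests corrupt
records explicitly.

The packaged fixture ontology (17 terms) reproduces the canonical inference
case: an outcome branch (inflammation) over three located respiratory
leaves plus a cutaneous leaf, a childless anatomy-defined respiratory
group, and a small partonomy under 'respiratory system'. Identifiers are
OAE/UBERON-*style*; the files are synthetic fixtures, not excerpts of any
hosted ontology release. The enrichment demonstration plants risk on the
respiratory codes only (5,000 reports), which makes 'respiratory system AE'
the uniquely top-ranked group (exact p = 1/35): the observed vocabulary
includes a code mapped to the group term itself, breaking the tie with the
asserted respiratory-inflammation subgroup that covers the same three
leaves.

## Numerical and interface choices

Term sets within a record are ordered deterministically everywhere (sorted
ids; stable tie-breaks by term id after the primary sort key), so identical
inputs give byte-identical outputs — the CLI guarantees this and the tests
assert it. Chi-square sorting places undefined (degenerate-margin) scores
last. All simulation randomness flows from a single mandatory integer seed
through numpy's `default_rng`; fixtures are seed-free and deterministic.
CLI outputs are written atomically (temp file + rename), exit codes are
0 / 1 / 2 for success / validation-or-data errors / usage errors, and every
run logs the package version and a SHA-256 digest of each input.

## Known limitations

The reasoner covers exactly the genus-plus-location fragment: no negation,
cardinality, role chains or general class expressions, and no attempt to
reproduce a tableau reasoner's behaviour beyond this fragment. The defined
group's own necessary conditions (G ⊑ genus) are expected to be asserted by
the modeller, as they are in the fixtures, not derived. Enrichment is the
plain hypergeometric over term sets; topology-aware variants (elim/weight
style) and permutation nulls are out of scope. The report dialect is a
minimal TSV; real export formats carry many more fields that are simply not
modelled.
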