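# Methods

This note documents the models, conventions and numerical choices behind
`mitekit`, in the order data flows through the toolkit.

## Entry model and counting convention

An entry describes exactly one tailoring enzyme encoded by one gene (one
entry per protein isoform). Mandatory content: a `MITE` + 7-digit accession
(`MITE0000000` is reserved), an enzyme name with at least one resolvable
sequence reference (UniProt or GenBank identifier), at least one reaction
rule — a generic reaction SMARTS with at least one example reaction and at
least one evidence code — and at least one DOI. Everything else (MIBiG,
Wikidata, Rhea, EC, auxiliary enzymes, descriptions) is optional. DOIs are
stored without resolver prefixes; dates are ISO-8601. Unknown fields survive
a parse/serialize round trip verbatim: the upstream standard evolves by
rolling release and a strict reader would reject tomorrow's records.

**Data points.** A "data point" is a leaf key–value pair of the serialized
entry; each element of a list of scalars counts once. Bookkeeping metadata —
`status` and the entire `changelog` — is excluded. This is one defensible
reading of "key-value pairs excluding metadata"; absolute data-point counts
are sensitive to it, and comparisons against externally published totals
should keep that in mind.

**Controlled vocabularies** (tailoring terms, evidence codes) ship as
editable text files under `mitekit/data/`; unknown terms are schema errors so
typos cannot silently fragment the vocabulary.

## Chemistry engine

Molecule identity is canonical isomeric SMILES equality (RDKit). Reaction
rules must use the generic Daylight grammar: exactly one reactant side, one
product side, an empty agent field at most. CXSMILES-style `|...|` extension
blocks are rejected outright — rejection is explicit, never a silent repair,
because repairing a proprietary construct would change rule semantics behind
the curator's back.

`apply_rule` enumerates **all symmetry-distinct template matches** and
returns the deduplicated set of product tuples rather than the first match:
regio-ambiguous rules must surface every outcome. Product tuples that fail
sanitization (e.g. kekulization of a partial structure) are dropped with a
warning instead of failing the application, since partial-structure
substrates legitimately produce some invalid tuples. A substrate the rule
does not recognize yields an empty product set, never an error — that *is*
the built-in substrate recognition.

**Matching policy.** Example verification compares canonical-SMILES
multisets. The default is stereo-strict with co-product subsets disabled;
both knobs are overridable per example (`stereo_strict`, `allow_subset`) for
deliberately partial examples. Wildcard atoms (`*`) are zero-valence dummies
that satisfy only explicit wildcard queries; letting them match arbitrary
atoms would make validation vacuous. No tautomer canonicalization is applied:
curators encode the intended tautomer, and silent rewriting can change which
rules match.

## Validation pipeline

Three per-entry stages (schema → chemistry → cross-references) plus
dataset-level checks, all running to completion so a curator sees the full
defect list in one pass. Chemistry failures always include both the expected
and the generated canonical SMILES. Identifier checks are purely syntactic
(MIBiG `BGC`+7 digits, UniProt accession grammar, numeric Rhea, four-field EC
with `-`/`n`-prefixed trailing components, `10.`-prefixed DOI, `Q`+digits
Wikidata); nothing is resolved over the network, keeping reports
deterministic and offline-testable. An entry with neither a MIBiG nor a Rhea
link, and a reaction without a Rhea id, are warnings, not errors: partial
coverage is a documented property of curated releases, not a defect.

## Query engine

Queries are pure expression trees (AND/OR/NOT over predicates). Substructure
predicates test the chosen scope (substrates/products/both) across all
example reactions; the reaction-pattern predicate requires the reactant
pattern to hit an example substrate **and** the product pattern to hit a
product of the *same* example — that co-occurrence semantics is this
package's definition. Sequence search uses Smith–Waterman local alignment
with BLOSUM62 and affine gaps (open 11, extend 1, BLASTp-like), and
identity = matches / alignment columns with gap columns counted, so a 0.7
threshold is comparable to common SSN practice. Ties between co-optimal
alignments resolve to the aligner's first enumerated alignment.

## Planner

`run_cascade` applies rules consecutively. When a rule yields several product
tuples the branch policy decides: `first-canonical` (lexicographically
smallest tuple) for reproducibility — the default — or `all-branches` for
exploration. When a tuple contains several molecules (proteolysis), the
largest fragment (heavy-atom count, ties by canonical SMILES) is carried
forward and the full tuple stays on record. States are identified by
canonical isomeric SMILES, so an epimerization genuinely changes state.

`search_pathway` is breadth-first over (intermediate, used-rules) states with
rule applications memoized; each rule is usable once unless flagged
`iterative`. It returns all minimal-length orderings that reach the target,
reconstructed from the shortest-path DAG in lexicographic accession order;
an optional `limit` truncates the enumeration (the state graph, not the
possibly factorial path set, bounds the search cost). A hard cap of 200 000
rule applications makes the contract total on adversarial pools.

**Modified-atom area** (`atom_diff`): atoms of the product outside the
maximum common substructure with the substrate, plus matched atoms whose
hydrogen count or formal charge changed (so a chlorination marks the chlorine
*and* its carbon). Pure stereo changes return the stereocenters whose parity
flipped, mapped through the shared flat skeleton. MCS is NP-hard, so the
computation is bounded (10 s timeout, 160 combined heavy atoms); beyond the
bound a canonical radius-2 atom-environment multiset diff stands in. Under
molecular symmetry the MCS atom map is not unique; the convention takes
RDKit's first match, which is deterministic but may pick either of two
equivalent sites.

## Analytics

**Statistics.** Percentages are computed over active entries and rounded
half-up to integer percent; an empty dataset reports them as not available.

**Differential reaction fingerprint.** For each side of a reaction, circular
substructure identifiers are enumerated per atom at radii 0..3 (radius-0
identifiers are element/degree/H-count triples; larger radii are canonical
fragment SMILES). The multiset symmetric difference between reactant- and
product-side identifiers is taken, and each surviving identifier is hashed
(keyed BLAKE2b, seed-dependent, platform-stable) into a 2048-bit vector. The
bits therefore encode exactly the substructure difference between the two
sides, and an identity reaction is the zero vector. Defaults (2048 bits,
radius 3, seed 42) are configuration; no bit-compatibility with other
differential-fingerprint implementations is claimed.

**k-NN reaction map.** Each node connects to its k nearest neighbours under
Jaccard distance on fingerprint bits (distance between two all-zero vectors
is 0); mutual edges are deduplicated and exact ties break by accession
order. Graph layout is presentation-only and carries no contract; a
minimum-spanning-tree layout can be derived from the edge weights if wanted.

**SSN.** All-pairs local alignment with the scoring above; an edge requires
identity ≥ threshold; orphans are degree-0 nodes. Published orphan fractions
from other pipelines depend on their alignment tool, score type and
threshold, so numeric agreement with any external SSN is not claimed.

## Synthetic data

The generator emulates the statistical shape of a curated release under
fixed, seeded conditions: default 10 entries; cross-reference coverage
fractions 0.89 MIBiG / 0.15 Rhea / 0.07 neither (realized exactly after
rounding to entry counts — 9/2/1 at n=10), matching the coverage profile a
curated tailoring-enzyme release reports; two 5-member sequence families
mutated at 5% per site from random 120-residue ancestors (pairwise ≈90%
identity within a family, far below any sensible threshold across families),
with entries beyond the family structure receiving independent random
sequences as deliberate SSN orphans. Reaction content comes from seven
named rule templates (halogenation, O-/N-methylation, hydroxylation,
acetylation, epimerization, macrolactamization); each entry's example is
produced by actually applying its rule, so the generator/validator closure —
every generated entry validates with zero errors — holds by construction.
What the generator does **not** emulate: real enzyme sequences (composition
is uniform over the 20 amino acids), realistic reaction-class frequencies,
multi-rule entries, or retired entries. Passing tests on synthetic data
therefore demonstrate the correctness of the machinery, not claims about any
real release.

The bottromycin-style cascade is hand-curated: a peptidic precursor (core
GPVVVFDC behind an N-terminal Met with a Gly-Ala follower stub) and ten
rules covering the maturation classes of bottromycin A2 — Met removal,
macroamidine formation (12-membered Gly-Pro-Val-Val ring), thiazoline
formation at Cys, three C-methylations (two Val side chains to *tert*-butyl,
Phe β-carbon), Asp epimerization, follower cleavage, oxidative
decarboxylation with aromatization to the thiazole, and O-methylation of the
Asp side chain. Every intermediate was recorded at curation time from single
rule applications, with each step's molecular-formula delta checked by hand
(−C5H9NOS; −H2O; −H2O; +CH2 ×3; stereo flip; −C5H10N2O3 +H2O; −CO2 −H2;
+CH2). Stereochemistry is specified only at the epimerized Asp α-carbon so
that rule templates stay robust; the fixture mirrors the reaction classes of
the real pathway, not the exact upstream SMARTS strings or the full natural
product structure.

## Problem sizes

Default test and acceptance runs use 10 generated entries plus the 10-entry
cascade (20 fingerprints, 10 sequences, ≤ 60-heavy-atom intermediates).
These sizes exercise every code path — including the all-orders pathway
search, whose state space is bounded by the dependency structure of the
cascade — while keeping the whole suite desk-scale. Larger datasets load
through the same `load_dataset` path (directory, zip or tar archive).

## Known limitations

* No kinetics, yields, cofactor stoichiometry or retro-biosynthesis in the
  planner; no 3D, pKa/protonation or tautomer handling in the chemistry
  engine; no atom-map inference for unmapped rules.
* Identifier validation is syntactic only; sequence–identifier consistency
  is not verified.
* The MCS-based modification area and the stereo-diff atom map are
  conventions, not unique mathematical objects, under molecular symmetry.
* `match_products` with `allow_subset` can mask genuinely missing products;
  it exists for curator-flagged partial examples only.
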